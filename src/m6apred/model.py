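"""Cost-sensitive gradient-boosted-tree classifier for imbalanced m6A data.

The learner is XGBoost configured for cost-sensitive imbalance learning:
the model is trained on the *entire* imbalanced sample set — no balanced
subsampling of negatives — with an asymmetric positive-class weight in
the binary log-loss objective and AUC as the training evaluation metric.
Default hyperparameters: L2 regularization (lambda) 700, tree depth 6,
learning rate (eta) 0.1, 400 boosting rounds, positive class weight 6.

Two entry levels are provided:

* :func:`train` / :class:`TrainedModel` — matrix-level primitives;
* :class:`M6AClassifier` — a model object built from a sample table and a
  SNP table, whose :meth:`~M6AClassifier.fit` runs SNP-position selection
  and feature assembly and returns an :class:`M6AClassifierResults` with
  predictions, importances and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from m6apred.evaluation import MetricSet, evaluate_predictions
from m6apred.features import feature_matrix
from m6apred.io import RunConfig, SampleTable, SnpTable
from m6apred.snp_selection import PositionRanking, select_snp_positions


@dataclass
class ModelConfig:
    """Boosting hyperparameters (defaults are the cost-sensitive setting)."""

    l2_regularization: float = 700.0
    max_tree_depth: int = 6
    learning_rate: float = 0.1
    boosting_rounds: int = 400
    positive_class_weight: float = 6.0
    objective: str = "binary:logistic"
    eval_metric: str = "auc"
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("l2_regularization", "max_tree_depth", "learning_rate",
                     "boosting_rounds", "positive_class_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def xgb_params(self) -> dict:
        return {
            "reg_lambda": self.l2_regularization,
            "max_depth": self.max_tree_depth,
            "eta": self.learning_rate,
            "objective": self.objective,
            "scale_pos_weight": self.positive_class_weight,
            "eval_metric": self.eval_metric,
            "seed": self.random_seed,
            "nthread": 1,
            "verbosity": 0,
        }


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus everything needed to reuse it."""

    booster: xgb.Booster
    feature_names: list[str]
    config: ModelConfig
    selected_positions: tuple[int, ...] | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature count {X.shape[1]} does not match the model's "
                f"{len(self.feature_names)}")
        dm = xgb.DMatrix(X, feature_names=self.feature_names)
        return self.booster.predict(dm)

    def feature_importance(self) -> pd.Series:
        """Split-count ('weight') importance per feature; unused features 0."""
        scores = self.booster.get_score(importance_type="weight")
        return pd.Series(
            [float(scores.get(name, 0.0)) for name in self.feature_names],
            index=self.feature_names, name="importance")


def train(X: np.ndarray, y: Sequence[int], config: ModelConfig | None = None,
          feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Fit the cost-sensitive booster on the full (imbalanced) matrix."""
    config = config or ModelConfig()
    X = np.asarray(X)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    if np.isnan(X).any():
        raise ValueError("feature matrix contains missing values")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise ValueError("feature_names length does not match the matrix")
    dm = xgb.DMatrix(X, label=y, feature_names=names)
    booster = xgb.train(config.xgb_params(), dm,
                        num_boost_round=config.boosting_rounds)
    return TrainedModel(booster=booster, feature_names=names, config=config)


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: positive iff probability >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probabilities) >= threshold).astype(np.int8)


def cross_validate(
    samples: SampleTable,
    snp_table: SnpTable,
    folds: int = 10,
    config: ModelConfig | None = None,
    run_config: RunConfig | None = None,
    use_snp_block: bool = True,
    feature_blocks: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Stratified k-fold CV with SNP selection re-run inside each fold.

    Re-selecting positions on each training fold keeps test folds unseen
    by every stage of the pipeline.  ``feature_blocks`` restricts the
    feature space (e.g. ``("binary",)``) for ablation comparisons.
    Returns one row per fold plus a 'mean' row.
    """
    config = config or ModelConfig()
    run_config = run_config or RunConfig()
    labels = samples.labels
    if int(labels.sum()) < folds:
        raise ValueError(f"need at least {folds} positives for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=run_config.random_seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        train_samples = samples.subset(tr)
        test_samples = samples.subset(te)
        snp_enabled = use_snp_block and (
            feature_blocks is None or "snp" in feature_blocks)
        if snp_enabled:
            ranking = select_snp_positions(train_samples, snp_table,
                                           k=run_config.snp_top_k,
                                           config=run_config)
            positions = ranking.selected_offsets
        else:
            positions = None
        Xtr, names = feature_matrix(train_samples, snp_table, positions,
                                    run_config, feature_blocks)
        Xte, _ = feature_matrix(test_samples, snp_table, positions,
                                run_config, feature_blocks)
        model = train(Xtr, train_samples.labels, config, names)
        pred = classify(model.predict_proba(Xte),
                        run_config.classification_threshold)
        _, ms = evaluate_predictions(test_samples.labels, pred)
        rows.append({"fold": fold, **ms.as_dict()})
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean()
    df = pd.concat([df, pd.DataFrame([{"fold": "mean", **mean.to_dict()}])],
                   ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# model-object layer


@dataclass
class M6AClassifier:
    """m6A site classifier over a sample table (model object; fit() to train).

    Parameters
    ----------
    samples : SampleTable
        Training candidates (both classes required).
    snp_table : SnpTable
        SNP-variant positions in transcript coordinates.
    config : RunConfig
        Window, k-mer, top-k and threshold settings.
    model_config : ModelConfig
        Boosting hyperparameters.
    """

    samples: SampleTable
    snp_table: SnpTable = field(default_factory=SnpTable)
    config: RunConfig = field(default_factory=RunConfig)
    model_config: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_files(cls, samples_path, snp_path=None, **kwargs) -> "M6AClassifier":
        from m6apred.io import read_sample_table, read_snp_table

        snp = read_snp_table(snp_path) if snp_path is not None else SnpTable()
        return cls(samples=read_sample_table(samples_path), snp_table=snp, **kwargs)

    def fit(self, use_snp_block: bool = True,
            ranking: PositionRanking | None = None) -> "M6AClassifierResults":
        """Select SNP positions (unless given), assemble features, train.

        Passing a precomputed ``ranking`` reuses earlier selection;
        ``use_snp_block=False`` drops the SNP block entirely.
        """
        self.samples.validate(self.config.window_length)
        if use_snp_block:
            if ranking is None:
                ranking = select_snp_positions(
                    self.samples, self.snp_table,
                    k=self.config.snp_top_k, config=self.config)
            positions = ranking.selected_offsets
        else:
            ranking, positions = None, None
        X, names = feature_matrix(self.samples, self.snp_table, positions,
                                  self.config)
        cfg = replace(self.model_config, random_seed=self.config.random_seed)
        model = train(X, self.samples.labels, cfg, names)
        model.selected_positions = positions
        return M6AClassifierResults(model=self, trained=model, ranking=ranking)


@dataclass
class M6AClassifierResults:
    """Fitted classifier: booster, SNP ranking, importances, summary."""

    model: M6AClassifier
    trained: TrainedModel
    ranking: PositionRanking | None

    @property
    def selected_positions(self) -> tuple[int, ...] | None:
        return self.trained.selected_positions

    def predict_proba(self, samples: SampleTable,
                      snp_table: SnpTable | None = None) -> np.ndarray:
        snp = snp_table if snp_table is not None else self.model.snp_table
        X, _ = feature_matrix(samples, snp, self.trained.selected_positions,
                              self.model.config)
        return self.trained.predict_proba(X)

    def predict_labels(self, samples: SampleTable,
                       snp_table: SnpTable | None = None,
                       threshold: float | None = None) -> np.ndarray:
        if threshold is None:
            threshold = self.model.config.classification_threshold
        return classify(self.predict_proba(samples, snp_table), threshold)

    def feature_importance(self) -> pd.Series:
        return self.trained.feature_importance()

    def evaluate(self, samples: SampleTable,
                 snp_table: SnpTable | None = None) -> MetricSet:
        pred = self.predict_labels(samples, snp_table)
        return evaluate_predictions(samples.labels, pred)[1]

    def save(self, path) -> None:
        from m6apred.io import save_model

        save_model(self.trained, path)

    def summary(self) -> str:
        n_pos, n_neg = self.model.samples.class_counts()
        cfg = self.trained.config
        imp = self.feature_importance()
        block_totals = imp.groupby(imp.index.str.split(".").str[0]).sum()
        lines = [
            "m6A cost-sensitive classifier",
            "=" * 46,
            f"training samples        {len(self.model.samples):>10d}",
            f"  positives / negatives {n_pos:>6d} / {n_neg} "
            f"(ratio 1:{n_neg / max(n_pos, 1):.1f})",
            f"features                {len(self.trained.feature_names):>10d}",
            f"boosting rounds         {cfg.boosting_rounds:>10d}",
            f"positive class weight   {cfg.positive_class_weight:>10.1f}",
            f"L2 regularization       {cfg.l2_regularization:>10.1f}",
            f"max tree depth          {cfg.max_tree_depth:>10d}",
            f"learning rate           {cfg.learning_rate:>10.2f}",
        ]
        if self.selected_positions is not None:
            lines.append("selected SNP offsets    "
                         + " ".join(f"{o:+d}" for o in self.selected_positions))
        lines.append("-" * 46)
        lines.append("split-count importance by feature block:")
        for name, total in block_totals.sort_values(ascending=False).items():
            lines.append(f"  {name:<10s} {int(total):>8d}")
        return "\n".join(lines)
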