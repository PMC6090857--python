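"""SNP-specificity position selection: Fisher's exact test + MRMR, fused.

For each window offset (-flank..+flank) the per-sample SNP state is a
binary variable.  Two rankings over offsets are computed on the training
samples:

* Fisher's exact test — the two-sided p-value of the 2x2 table
  (variant / no variant) x (positive / negative); small p means the
  variant frequency differs strongly between classes.
* MRMR (max-relevance min-redundancy) — greedy forward selection with
  the MID (difference) criterion: the first offset maximizes the mutual
  information I(x; class); each subsequent offset maximizes
  I(x; class) - (1/|S|) * sum over selected s of I(x; s).
  Mutual information is the plug-in estimate in bits over binary
  variables.  The selection index is the MRMR rank.

The final ranking averages the two ranks; the k offsets with the smallest
average are the SNP feature positions.  The selection is computed once on
training data and persisted with the model, so prediction-time feature
assembly reuses the training-time positions (no leakage from test labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from m6apred.features import snp_state_vector
from m6apred.io import RunConfig, SampleTable, SnpTable


def _offset_tiebreak(offset: int) -> tuple[int, int]:
    # smaller absolute offset first; negative before positive at equal |offset|
    return (abs(offset), 0 if offset < 0 else 1)


def state_matrix(samples: SampleTable, snp_table: SnpTable, flank: int) -> np.ndarray:
    """Per-sample binary SNP-state vectors, one row per sample, 2*flank+1 cols."""
    X = np.zeros((len(samples), 2 * flank + 1), dtype=np.int8)
    for i, row in enumerate(samples.df.itertuples(index=False)):
        X[i] = snp_state_vector(row.transcript_id, row.position,
                                row.transcript_length, snp_table, flank)
    return X


def fisher_position_test(states: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided Fisher's exact p-value per position (column of ``states``)."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("need both classes for the position test")
    pos, neg = labels == 1, labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    pvals = np.empty(states.shape[1])
    for j in range(states.shape[1]):
        a = int(states[pos, j].sum())        # variant, positive
        c = int(states[neg, j].sum())        # variant, negative
        table = [[a, n_pos - a], [c, n_neg - c]]
        pvals[j] = fisher_exact(table, alternative="two-sided")[1]
    return pvals


def binary_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits between two binary variables."""
    n = len(x)
    mi = 0.0
    for xv in (0, 1):
        px = np.count_nonzero(x == xv) / n
        if px == 0:
            continue
        for yv in (0, 1):
            py = np.count_nonzero(y == yv) / n
            pxy = np.count_nonzero((x == xv) & (y == yv)) / n
            if pxy > 0 and py > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return mi


def mrmr_order(states: np.ndarray, labels: np.ndarray,
               offsets: np.ndarray | None = None) -> list[int]:
    """Greedy MRMR (MID) selection order over positions; returns column indices.

    Zero-entropy (constant) positions carry no information and are appended
    after all informative positions, in offset order.
    """
    labels = np.asarray(labels)
    n_positions = states.shape[1]
    if offsets is None:
        offsets = np.arange(n_positions)
    constant = [j for j in range(n_positions)
                if states[:, j].min() == states[:, j].max()]
    candidates = [j for j in range(n_positions) if j not in set(constant)]
    relevance = {j: binary_mutual_information(states[:, j], labels)
                 for j in candidates}
    pair_mi: dict[tuple[int, int], float] = {}

    def redundancy(j: int, selected: list[int]) -> float:
        total = 0.0
        for s in selected:
            key = (min(j, s), max(j, s))
            if key not in pair_mi:
                pair_mi[key] = binary_mutual_information(states[:, j], states[:, s])
            total += pair_mi[key]
        return total / len(selected)

    order: list[int] = []
    remaining = list(candidates)
    while remaining:
        if not order:
            scores = [(relevance[j], j) for j in remaining]
        else:
            scores = [(relevance[j] - redundancy(j, order), j) for j in remaining]
        # deterministic tie-break: best score, then the offset tie-break
        best = max(scores,
                   key=lambda t: (t[0],) + tuple(-v for v in
                                                 _offset_tiebreak(int(offsets[t[1]]))))
        order.append(best[1])
        remaining.remove(best[1])
    order.extend(sorted(constant, key=lambda j: int(offsets[j])))
    return order


@dataclass
class PositionRanking:
    """Per-offset Fisher/MRMR ranks, their average, and the selected top-k.

    ``table`` columns: offset, fisher_p, fisher_rank, mrmr_rank,
    average_rank, selected.  ``selected_offsets`` preserves the ranked
    order (ascending average rank under the documented tie-breaks).
    """

    table: pd.DataFrame
    selected_offsets: tuple[int, ...]
    degenerate: bool = False

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PositionRanking":
        table = pd.read_csv(path, sep="\t")
        sel = table[table["selected"]].sort_values("average_rank")
        order = _selection_order(sel)
        return cls(table=table, selected_offsets=tuple(int(o) for o in order))


def _selection_order(subframe: pd.DataFrame) -> list[int]:
    rows = sorted(
        subframe.itertuples(index=False),
        key=lambda r: (r.average_rank, r.fisher_rank) + _offset_tiebreak(int(r.offset)),
    )
    return [int(r.offset) for r in rows]


def fuse_rankings(
    offsets: np.ndarray,
    fisher_p: np.ndarray,
    fisher_ranks: np.ndarray,
    mrmr_ranks: np.ndarray,
    k: int = 12,
) -> PositionRanking:
    """Average the two rankings and mark the k smallest-average offsets.

    Ties on the average are broken by the smaller Fisher rank, then the
    smaller absolute offset, then the negative offset first.
    """
    n = len(offsets)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available positions")
    average = (fisher_ranks + mrmr_ranks) / 2.0
    df = pd.DataFrame({
        "offset": offsets.astype(int),
        "fisher_p": fisher_p,
        "fisher_rank": fisher_ranks.astype(int),
        "mrmr_rank": mrmr_ranks.astype(int),
        "average_rank": average,
        "selected": False,
    })
    order = sorted(
        range(n),
        key=lambda i: (average[i], fisher_ranks[i])
        + _offset_tiebreak(int(offsets[i])),
    )
    chosen = order[:k]
    df.loc[chosen, "selected"] = True
    selected = tuple(int(offsets[i]) for i in chosen)
    return PositionRanking(table=df, selected_offsets=selected)


def select_snp_positions(
    samples: SampleTable,
    snp_table: SnpTable,
    k: int = 12,
    config: RunConfig | None = None,
) -> PositionRanking:
    """End-to-end SNP-specificity selection on training samples.

    Builds the per-sample state vectors, ranks offsets by the two-sided
    Fisher p-value and by MRMR selection order, fuses by average rank and
    keeps the top-k.  A corpus with no SNP variation at all is flagged
    degenerate (every rank is then a tie-break artifact).
    """
    config = config or RunConfig()
    flank = config.window_flank
    offsets = np.arange(-flank, flank + 1)
    states = state_matrix(samples, snp_table, flank)
    labels = samples.labels
    if labels.min() == labels.max():
        raise ValueError("training samples must contain both classes")

    degenerate = states.sum() == 0
    pvals = fisher_position_test(states, labels)
    fisher_order = sorted(
        range(len(offsets)),
        key=lambda i: (pvals[i],) + _offset_tiebreak(int(offsets[i])),
    )
    fisher_ranks = np.empty(len(offsets), dtype=int)
    fisher_ranks[fisher_order] = np.arange(1, len(offsets) + 1)

    mrmr_ranks = np.empty(len(offsets), dtype=int)
    mrmr_ranks[mrmr_order(states, labels, offsets)] = np.arange(1, len(offsets) + 1)

    ranking = fuse_rankings(offsets, pvals, fisher_ranks, mrmr_ranks, k=k)
    ranking.degenerate = bool(degenerate)
    return ranking
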