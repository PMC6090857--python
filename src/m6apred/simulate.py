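"""Synthetic corpora with the statistical structure the predictor assumes.

The generator produces random mature-transcript sequences, enumerates
their DRACH candidates, and assigns positive labels with the two
class-discriminating structures the real data exhibits:

* location bias — m6A sites concentrate near the stop codon / 3' UTR, so
  positives are drawn from the candidates with weights proportional to a
  normal density centered at the synthetic stop-codon position (default
  0.8 of the transcript length, sd 10% of length); negatives are uniform
  over the remaining DRACH candidates;
* SNP-state bias — at a chosen subset of window offsets (default
  {-2, -1, +2}) positive-class windows carry an SNP variant at an
  elevated rate (default 0.30) against a background rate (default 0.05)
  shared by every other offset and by negatives.

The negative:positive ratio is controlled exactly (default 10:1,
emulating the ~10.2:1 training corpus) by keeping every sampled positive
and drawing negatives without replacement to ratio * n_positives.

Sequence composition itself carries no class signal beyond the motif;
passing tests on these corpora therefore demonstrates that the pipeline
exploits location and SNP structure, not that it would reach real-data
accuracy, where sequence context matters too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from m6apred.io import SampleTable, SnpTable, TranscriptRecord
from m6apred.motifs import extract_window, scan_drach


@dataclass
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults emulate the study conditions."""

    n_transcripts: int = 100
    length_median: float = 2000.0      # lognormal median, nt
    length_log_sd: float = 0.35
    min_length: int = 300
    stop_codon_relative_position: float = 0.8
    positive_sd_fraction: float = 0.10  # sd of the location bump, fraction of length
    imbalance_ratio: float = 10.0       # negatives per positive
    snp_background_rate: float = 0.05
    planted_snp_offsets: tuple[int, ...] = (-2, -1, 2)
    planted_snp_rate: float = 0.30
    flank: int = 25
    location_bias: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snp_background_rate, self.planted_snp_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("SNP rates must be in [0, 1]")
        if any(abs(o) > self.flank for o in self.planted_snp_offsets):
            raise ValueError("planted offsets must lie within +/-flank")
        if self.imbalance_ratio < 1.0:
            raise ValueError("imbalance_ratio must be >= 1")


@dataclass
class SimulatedCorpus:
    transcripts: list[TranscriptRecord]
    samples: SampleTable
    snp_table: SnpTable
    truth: dict = field(default_factory=dict)


def simulate_corpus(config: SimulationConfig | None = None) -> SimulatedCorpus:
    """Generate a fully seeded corpus: FASTA-able transcripts, samples, SNPs.

    Raises if the transcripts do not contain enough DRACH candidates to
    realize the configured imbalance ratio.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.random_seed)

    transcripts: list[TranscriptRecord] = []
    candidates: list[tuple[int, str, int, int]] = []  # (tx index, id, pos, length)
    for t in range(config.n_transcripts):
        length = max(config.min_length,
                     int(rng.lognormal(np.log(config.length_median),
                                       config.length_log_sd)))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        stop = int(round(config.stop_codon_relative_position * length))
        rec = TranscriptRecord(id=f"synthtx{t:04d}", sequence=seq,
                               stop_codon_position=stop)
        transcripts.append(rec)
        for site in scan_drach(rec):
            candidates.append((t, rec.id, site.position, length))

    n_candidates = len(candidates)
    n_pos = int(n_candidates // (1.0 + config.imbalance_ratio))
    while n_pos > 0 and n_pos + int(round(config.imbalance_ratio * n_pos)) > n_candidates:
        n_pos -= 1
    n_neg = int(round(config.imbalance_ratio * n_pos))
    if n_pos < 1:
        raise ValueError(
            f"only {n_candidates} DRACH candidates; cannot realize "
            f"{config.imbalance_ratio}:1 with at least one positive")

    # location-weighted positive draw: weight ~ N(stop position, sd)
    if config.location_bias:
        weights = np.empty(n_candidates)
        for i, (t, _, pos, length) in enumerate(candidates):
            stop = transcripts[t].stop_codon_position
            sd = max(config.positive_sd_fraction * length, 1.0)
            weights[i] = np.exp(-0.5 * ((pos - stop) / sd) ** 2)
        weights /= weights.sum()
    else:
        weights = np.full(n_candidates, 1.0 / n_candidates)
    pos_idx = rng.choice(n_candidates, size=n_pos, replace=False, p=weights)
    pos_set = set(int(i) for i in pos_idx)
    remaining = [i for i in range(n_candidates) if i not in pos_set]
    neg_idx = rng.choice(len(remaining), size=n_neg, replace=False)
    neg_set = set(int(remaining[i]) for i in neg_idx)

    planted = set(config.planted_snp_offsets)
    rows = []
    kept = sorted(pos_set | neg_set)
    # SNP presence is drawn once per transcript coordinate: planted-offset
    # coordinates of positive windows at the elevated rate, every other
    # coordinate covered by a sampled window at the background rate.
    # Drawing per coordinate (not per sample) keeps the class-conditional
    # rates exact even where neighbouring candidate windows overlap.
    planted_coords: set[tuple[str, int]] = set()
    window_coords: set[tuple[str, int]] = set()
    for i in kept:
        t, tx_id, pos, length = candidates[i]
        label = 1 if i in pos_set else 0
        rows.append((tx_id, pos, length,
                     extract_window(transcripts[t], pos, config.flank), label))
        for offset in range(-config.flank, config.flank + 1):
            coord = pos + offset
            if not (1 <= coord <= length):
                continue
            if label == 1 and offset in planted:
                planted_coords.add((tx_id, coord))
            else:
                window_coords.add((tx_id, coord))
    snp_pairs: set[tuple[str, int]] = set()
    for coord in sorted(planted_coords):
        if rng.random() < config.planted_snp_rate:
            snp_pairs.add(coord)
    for coord in sorted(window_coords - planted_coords):
        if rng.random() < config.snp_background_rate:
            snp_pairs.add(coord)

    samples = SampleTable.from_rows(rows)
    truth = {
        "random_seed": config.random_seed,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "planted_snp_offsets": sorted(planted),
        "planted_snp_rate": config.planted_snp_rate,
        "snp_background_rate": config.snp_background_rate,
        "stop_codon_relative_position": config.stop_codon_relative_position,
        "positive_sites": [
            [candidates[i][1], candidates[i][2]] for i in sorted(pos_set)],
    }
    return SimulatedCorpus(transcripts=transcripts, samples=samples,
                           snp_table=SnpTable.from_pairs(snp_pairs), truth=truth)


# ---------------------------------------------------------------------------
# worked case fixtures

_WORKED_CASES = {
    # class sizes and the predictor's confusion counts for the two case
    # studies: c-Jun (25 verified m6A sites among 72 DRACH candidates;
    # 21 predicted positive, 18 true) and the HIV-1-related CBFB
    # transcript (12 positives among 62; 8 predicted positive, 5 true).
    "cjun": {"n_pos": 25, "n_neg": 47, "tp": 18, "fp": 3},
    "hiv1": {"n_pos": 12, "n_neg": 50, "tp": 5, "fp": 3},
}


def _random_drach_window(rng: np.random.Generator, flank: int) -> str:
    left = "".join(rng.choice(list("ACGU"), size=flank - 2))
    right = "".join(rng.choice(list("ACGU"), size=flank - 2))
    motif = (rng.choice(list("GAC")) + rng.choice(list("GA")) + "AC"
             + rng.choice(list("UAC")))
    return left + motif[:2] + "A" + motif[3:] + right


def simulate_worked_case(preset: str, flank: int = 25,
                         seed: int = 0) -> tuple[SampleTable, np.ndarray]:
    """A labeled fixture plus a prediction vector realizing the case study.

    The windows are synthetic stand-ins (random DRACH-conforming
    sequences); only the class sizes and the injected confusion structure
    reproduce the published case, so the fixture exercises the evaluation
    path end to end.
    """
    if preset not in _WORKED_CASES:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(_WORKED_CASES)}")
    spec = _WORKED_CASES[preset]
    rng = np.random.default_rng(seed)
    n = spec["n_pos"] + spec["n_neg"]
    length = 100 * (n + 1)
    rows = []
    for i in range(n):
        label = 1 if i < spec["n_pos"] else 0
        rows.append((f"{preset}_tx", 100 * (i + 1), length,
                     _random_drach_window(rng, flank), label))
    samples = SampleTable.from_rows(rows)
    predicted = np.zeros(n, dtype=np.int8)
    predicted[:spec["tp"]] = 1                              # true positives
    predicted[spec["n_pos"]:spec["n_pos"] + spec["fp"]] = 1  # false positives
    return samples, predicted
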