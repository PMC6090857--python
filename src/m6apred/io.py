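"""File formats, domain tables, and model persistence.

Coordinates are 1-based and fully closed on the mature transcript.  All
sequence input is upper-cased and 'T' is transliterated to 'U' (sources mix
DNA and RNA alphabets).  'N' is legal only as edge padding produced by
window extraction.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_WINDOW_CHARS = frozenset("ACGUN")
LABEL_POSITIVE = 1
LABEL_NEGATIVE = 0

_LABEL_ALIASES = {
    "positive": 1, "pos": 1, "1": 1, "true": 1,
    "negative": 0, "neg": 0, "0": 0, "false": 0,
}

MODEL_FORMAT_VERSION = 1

SAMPLE_COLUMNS = ["transcript_id", "position", "transcript_length", "window", "label"]


def normalize_sequence(seq: str) -> str:
    """Upper-case and transliterate the DNA alphabet to RNA (T -> U)."""
    return seq.upper().replace("T", "U")


@dataclass
class TranscriptRecord:
    """A mature transcript sequence with optional region annotation.

    ``stop_codon_position`` (1-based, optional) marks the boundary between the
    coding region and the 3' UTR; the simulator uses it to place the positive
    location bias, and it is ignored by feature extraction.
    """

    id: str
    sequence: str
    stop_codon_position: int | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SampleTable:
    """One row per candidate adenine: window sequence, coordinates, label.

    Backed by a DataFrame with columns transcript_id, position (1-based),
    transcript_length, window (odd-length string over {A,C,G,U,N} with 'A'
    at the center), label (1 positive / 0 negative).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)[SAMPLE_COLUMNS].astype(
            {"transcript_id": str, "position": np.int64,
             "transcript_length": np.int64, "window": str, "label": np.int8}
        )

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "SampleTable":
        df = pd.DataFrame(list(rows), columns=SAMPLE_COLUMNS)
        table = cls(df)
        table.validate()
        return table

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleTable):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def class_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative)."""
        n_pos = int(self.df["label"].sum())
        return n_pos, len(self.df) - n_pos

    def validate(self, window_length: int | None = None) -> None:
        """Check every invariant; raise ValueError naming the first bad row."""
        for i, row in enumerate(self.df.itertuples(index=False)):
            w = row.window
            if window_length is not None and len(w) != window_length:
                raise ValueError(
                    f"row {i} ({row.transcript_id}): window length {len(w)} "
                    f"!= configured {window_length}")
            if len(w) % 2 != 1:
                raise ValueError(
                    f"row {i} ({row.transcript_id}): window length {len(w)} is even")
            bad = set(w) - VALID_WINDOW_CHARS
            if bad:
                raise ValueError(
                    f"row {i} ({row.transcript_id}): illegal window characters {sorted(bad)}")
            if w[len(w) // 2] != "A":
                raise ValueError(
                    f"row {i} ({row.transcript_id}): window center is "
                    f"{w[len(w) // 2]!r}, expected 'A'")
            if not (1 <= row.position <= row.transcript_length):
                raise ValueError(
                    f"row {i} ({row.transcript_id}): position {row.position} outside "
                    f"transcript of length {row.transcript_length}")
            if row.label not in (0, 1):
                raise ValueError(f"row {i} ({row.transcript_id}): label {row.label}")

    def subset(self, index: Sequence[int]) -> "SampleTable":
        return SampleTable(self.df.iloc[list(index)].reset_index(drop=True))


@dataclass(frozen=True)
class SnpTable:
    """SNP-variant positions on transcripts, with set semantics.

    Entries are (transcript_id, 1-based position); duplicates collapse.
    """

    entries: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "SnpTable":
        entries = frozenset((str(t), int(p)) for t, p in pairs)
        for t, p in entries:
            if p < 1:
                raise ValueError(f"SNP position must be >= 1, got {t}:{p}")
        return cls(entries)

    def __contains__(self, item: tuple[str, int]) -> bool:
        return (item[0], int(item[1])) in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RunConfig:
    """Pipeline-wide knobs: window size, k-mer sizes, SNP top-k, threshold."""

    window_flank: int = 25
    kmer_sizes: tuple[int, ...] = (2, 3)
    snp_top_k: int = 12
    classification_threshold: float = 0.5
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_flank < 2:
            raise ValueError("window_flank must be >= 2 (the motif spans +/-2)")
        if self.snp_top_k > 2 * self.window_flank + 1:
            raise ValueError("snp_top_k cannot exceed the window length")
        if not (0.0 < self.classification_threshold < 1.0):
            raise ValueError("classification_threshold must be in (0, 1)")

    @property
    def window_length(self) -> int:
        return 2 * self.window_flank + 1


# ---------------------------------------------------------------------------
# sample tables


def _infer_dialect(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    ext = os.path.splitext(str(path))[1].lower()
    return {".csv": "csv", ".xlsx": "xlsx"}.get(ext, "tsv")


def _parse_label(value, row: int) -> int:
    key = str(value).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"row {row}: unrecognized label {value!r}")
    return _LABEL_ALIASES[key]


def read_sample_table(path, dialect: str | None = None) -> SampleTable:
    """Read a candidate-site table from TSV, CSV, or XLSX.

    Columns are resolved by header name (transcript_id, position,
    transcript_length, window, label).  Sequences are upper-cased with
    T -> U; any invariant violation raises ValueError naming the row.
    """
    dialect = _infer_dialect(path, dialect)
    if dialect == "xlsx":
        raw = pd.read_excel(path, dtype=str)
    else:
        raw = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"sample table {path}: missing columns {missing}")
    rows = []
    for i, row in enumerate(raw.itertuples(index=False)):
        try:
            position = int(row.position)
            length = int(row.transcript_length)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i}: non-integer coordinate field: {exc}") from exc
        window = normalize_sequence(str(row.window))
        rows.append((str(row.transcript_id), position, length, window,
                     _parse_label(row.label, i)))
    return SampleTable.from_rows(rows)


def write_sample_table(table: SampleTable, path, dialect: str | None = None) -> None:
    """Write a sample table; re-reading yields an equal table."""
    table.validate()
    dialect = _infer_dialect(path, dialect)
    out = table.df.copy()
    out["label"] = out["label"].map({1: "positive", 0: "negative"})
    if dialect == "xlsx":
        out.to_excel(path, index=False)
    else:
        out.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts; ids from the header up to the first whitespace."""
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for transcript {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(TranscriptRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[TranscriptRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# SNP tables


def read_snp_table(path) -> SnpTable:
    """Read SNP positions from 2-column TSV or minimal VCF.

    In VCF input the CHROM column is interpreted as the transcript id and POS
    as the 1-based transcript coordinate (input is already in transcript
    coordinates; no liftover).
    """
    pairs: list[tuple[str, int]] = []
    with open(path) as fh:
        first = fh.readline()
        is_vcf = first.startswith("##fileformat=VCF") or first.startswith("#CHROM")
        fh.seek(0)
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                pos = int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer position {fields[1]!r}") from exc
            pairs.append((fields[0], pos))
    del is_vcf  # same two leading columns either way
    return SnpTable.from_pairs(pairs)


def write_snp_table(table: SnpTable, path) -> None:
    with open(path, "w") as fh:
        for tx, pos in sorted(table.entries):
            fh.write(f"{tx}\t{pos}\n")


# ---------------------------------------------------------------------------
# model persistence


def save_model(model, path) -> None:
    """Persist a trained classifier as a versioned JSON artifact."""
    if os.path.isdir(path):
        raise ValueError(f"{path} is a directory")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "feature_names": list(model.feature_names),
        "selected_positions": list(model.selected_positions)
        if model.selected_positions is not None else None,
        "booster": model.booster.save_raw("json").decode("utf-8"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a classifier saved by :func:`save_model`.

    load(save(m)) produces bitwise-identical predictions on any matrix.
    """
    import xgboost as xgb

    from m6apred.model import ModelConfig, TrainedModel

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model artifact {path}: format version {version!r}, "
            f"expected {MODEL_FORMAT_VERSION}")
    booster = xgb.Booster()
    booster.load_model(bytearray(payload["booster"].encode("utf-8")))
    selected = payload["selected_positions"]
    return TrainedModel(
        booster=booster,
        feature_names=list(payload["feature_names"]),
        config=ModelConfig(**payload["config"]),
        selected_positions=tuple(selected) if selected is not None else None,
    )
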