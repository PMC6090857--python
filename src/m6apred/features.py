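"""Encode candidate-site windows into the 509-dimension feature space.

Block layout (fixed order, defaults in brackets):

====================  =====  ==================================================
block                 size   content
====================  =====  ==================================================
binary                4*L    per-position one-hot over A,C,G,U          [204]
cpd                   3*L    per-position chemical-property bits        [153]
density               L      cumulative same-nucleotide prefix freq.    [51]
kmer                  sum    k-mer frequencies, k in kmer_sizes         [80]
entropy               7      p_A, p_G, p_U, p_C, En, REn, IGS           [7]
location              2      absolute and relative site location        [2]
snp                   k      SNP states at the selected offsets         [12]
====================  =====  ==================================================

Total 509 at the defaults (flank 25, k-mers {2,3}, top-12 SNP positions).

'N' is edge padding only: it encodes as all-zero bits, gets density 0,
is excluded from k-mer windows and composition frequencies, and a padded
offset always has SNP state 0.

The entropy block keeps the relative entropy with the sign convention used
throughout this package's feature definitions: REn(s) = -sum_i p_i *
log2(p_i / p0) with the uniform reference p0 = 1/4.  Under that convention
REn = En - 2 and the information gain score IGS = En - REn is identically
2 bits for every window.  The constant is kept deliberately — the feature
definitions are reproduced exactly, and a constant column is harmless to
tree learners (it simply never splits).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from m6apred.io import RunConfig, SampleTable, SnpTable

ALPHABET = "ACGU"  # lexicographic order used everywhere

BINARY_CODE: Mapping[str, tuple[int, ...]] = {
    "A": (1, 0, 0, 0),
    "C": (0, 1, 0, 0),
    "G": (0, 0, 1, 0),
    "U": (0, 0, 0, 1),
    "N": (0, 0, 0, 0),
}

# ring number / hydrogen bonding / functional group
CPD_CODE: Mapping[str, tuple[int, ...]] = {
    "A": (1, 1, 1),
    "C": (0, 0, 1),
    "G": (1, 0, 0),
    "U": (0, 1, 0),
    "N": (0, 0, 0),
}


def _check_window(window: str) -> None:
    for i, ch in enumerate(window):
        if ch not in "ACGUN":
            raise ValueError(f"illegal character {ch!r} at window position {i}")


def encode_binary(window: str) -> np.ndarray:
    """Per-position 4-bit one-hot block (A,C,G,U); 'N' -> all zeros."""
    _check_window(window)
    return np.array([bit for ch in window for bit in BINARY_CODE[ch]], dtype=float)


def encode_cpd(window: str) -> np.ndarray:
    """Per-position 3-bit chemical-property block; 'N' -> all zeros."""
    _check_window(window)
    return np.array([bit for ch in window for bit in CPD_CODE[ch]], dtype=float)


def density(window: str) -> np.ndarray:
    """Cumulative nucleotide density: d_i = count of s_i in s_1..s_i over i.

    'N' positions get density 0 and never increment any letter's prefix
    count; the denominator stays the 1-based position index i.
    """
    _check_window(window)
    counts = dict.fromkeys(ALPHABET, 0)
    out = np.zeros(len(window))
    for i, ch in enumerate(window, start=1):
        if ch == "N":
            continue
        counts[ch] += 1
        out[i - 1] = counts[ch] / i
    return out


def kmer_frequencies(window: str, k: int) -> np.ndarray:
    """Frequencies of all 4^k k-mers over the window's sliding k-windows.

    The denominator is the number of valid (N-free) sliding windows;
    windows containing 'N' are excluded from numerator and denominator.
    """
    _check_window(window)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(window):
        raise ValueError(f"k={k} larger than window length {len(window)}")
    index = {"".join(km): i for i, km in enumerate(product(ALPHABET, repeat=k))}
    counts = np.zeros(4 ** k)
    valid = 0
    for i in range(len(window) - k + 1):
        kmer = window[i:i + k]
        if "N" in kmer:
            continue
        valid += 1
        counts[index[kmer]] += 1
    return counts / valid if valid else counts


def entropy_features(window: str) -> np.ndarray:
    """Composition + entropy block: (p_A, p_G, p_U, p_C, En, REn, IGS).

    Frequencies are over non-'N' characters; 0*log(0) := 0; the reference
    distribution p0 is uniform (1/4).  See the module docstring for the
    REn sign convention that makes IGS constant at 2 bits.
    """
    _check_window(window)
    n = sum(1 for ch in window if ch != "N")
    if n == 0:
        raise ValueError("window is all padding; composition undefined")
    p = {ch: window.count(ch) / n for ch in ALPHABET}
    nonzero = [p[ch] for ch in ALPHABET if p[ch] > 0]
    en = -sum(pi * np.log2(pi) for pi in nonzero)
    ren = -sum(pi * np.log2(pi / 0.25) for pi in nonzero)
    igs = en - ren
    return np.array([p["A"], p["G"], p["U"], p["C"], en, ren, igs])


def location_features(site_position: int, transcript_length: int) -> np.ndarray:
    """(absolute, relative) distance of the site from the transcript start.

    absolute = position - 1 nt (start site has distance 0);
    relative = absolute / transcript_length, in [0, 1).
    """
    if transcript_length < 1:
        raise ValueError("transcript_length must be >= 1")
    if not (1 <= site_position <= transcript_length):
        raise ValueError(
            f"position {site_position} outside transcript of length {transcript_length}")
    absolute = site_position - 1
    return np.array([absolute, absolute / transcript_length], dtype=float)


def snp_state_vector(
    transcript_id: str,
    site_position: int,
    transcript_length: int,
    snp_table: SnpTable,
    flank: int,
) -> np.ndarray:
    """0/1 SNP states for window offsets -flank..+flank (0 = the adenine).

    Offsets falling outside the transcript (edge padding) are 0.
    """
    out = np.zeros(2 * flank + 1)
    for j, offset in enumerate(range(-flank, flank + 1)):
        coord = site_position + offset
        if 1 <= coord <= transcript_length and (transcript_id, coord) in snp_table:
            out[j] = 1.0
    return out


ALL_BLOCKS = ("binary", "cpd", "density", "kmer", "entropy", "location", "snp")


@dataclass(frozen=True)
class FeatureLayout:
    """Named block layout of the assembled vector, with offsets and names.

    ``blocks`` restricts the layout to a subset of the block order (used
    for feature-space ablations); the 'snp' block additionally requires
    ``snp_offsets``.
    """

    flank: int = 25
    kmer_sizes: tuple[int, ...] = (2, 3)
    snp_offsets: tuple[int, ...] | None = None  # ranked order; None disables block
    blocks: tuple[str, ...] = ALL_BLOCKS

    def __post_init__(self) -> None:
        unknown = set(self.blocks) - set(ALL_BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature blocks {sorted(unknown)}")

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 1

    def enabled_blocks(self) -> tuple[str, ...]:
        return tuple(b for b in ALL_BLOCKS
                     if b in self.blocks
                     and not (b == "snp" and self.snp_offsets is None))

    def block_sizes(self) -> dict[str, int]:
        L = self.window_length
        sizes = {
            "binary": 4 * L,
            "cpd": 3 * L,
            "density": L,
            "kmer": sum(4 ** k for k in self.kmer_sizes),
            "entropy": 7,
            "location": 2,
            "snp": len(self.snp_offsets) if self.snp_offsets is not None else 0,
        }
        return {b: sizes[b] for b in self.enabled_blocks()}

    def block_offsets(self) -> dict[str, int]:
        offsets, cursor = {}, 0
        for name, size in self.block_sizes().items():
            offsets[name] = cursor
            cursor += size
        return offsets

    @property
    def n_features(self) -> int:
        return sum(self.block_sizes().values())

    def feature_names(self) -> list[str]:
        """Block-qualified names, e.g. binary.pos-25.A, kmer.2.GG, snp.pos-2."""
        offs = list(range(-self.flank, self.flank + 1))
        per_block = {
            "binary": [f"binary.pos{o:+d}.{ch}" for o in offs for ch in ALPHABET],
            "cpd": [f"cpd.pos{o:+d}.{prop}" for o in offs
                    for prop in ("ring", "hbond", "func")],
            "density": [f"density.pos{o:+d}" for o in offs],
            "kmer": [f"kmer.{k}.{''.join(km)}" for k in self.kmer_sizes
                     for km in product(ALPHABET, repeat=k)],
            "entropy": ["entropy.p_A", "entropy.p_G", "entropy.p_U",
                        "entropy.p_C", "entropy.En", "entropy.REn",
                        "entropy.IGS"],
            "location": ["location.absolute", "location.relative"],
            "snp": [f"snp.pos{o:+d}" for o in (self.snp_offsets or ())],
        }
        names: list[str] = []
        for b in self.enabled_blocks():
            names += per_block[b]
        return names


def assemble(
    transcript_id: str,
    position: int,
    transcript_length: int,
    window: str,
    snp_table: SnpTable | None,
    selected_positions: Sequence[int] | None,
    config: RunConfig,
    blocks: Sequence[str] | None = None,
) -> np.ndarray:
    """Concatenate the enabled blocks for one sample, in the fixed order.

    ``selected_positions`` are window offsets in their ranked order; the SNP
    block keeps only those offsets.  Passing None disables the SNP block
    (497 dimensions at defaults instead of 509).  ``blocks`` restricts the
    output to a subset of blocks for feature-space ablations.
    """
    if len(window) != config.window_length:
        raise ValueError(
            f"window length {len(window)} != configured {config.window_length}")
    layout = FeatureLayout(
        flank=config.window_flank, kmer_sizes=tuple(config.kmer_sizes),
        snp_offsets=tuple(selected_positions) if selected_positions is not None else None,
        blocks=tuple(blocks) if blocks is not None else ALL_BLOCKS)

    def snp_block() -> np.ndarray:
        full = snp_state_vector(transcript_id, position, transcript_length,
                                snp_table if snp_table is not None else SnpTable(),
                                config.window_flank)
        idx = [o + config.window_flank for o in selected_positions]
        return full[idx]

    builders = {
        "binary": lambda: encode_binary(window),
        "cpd": lambda: encode_cpd(window),
        "density": lambda: density(window),
        "kmer": lambda: np.concatenate(
            [kmer_frequencies(window, k) for k in config.kmer_sizes]),
        "entropy": lambda: entropy_features(window),
        "location": lambda: location_features(position, transcript_length),
        "snp": snp_block,
    }
    return np.concatenate([builders[b]() for b in layout.enabled_blocks()])


def feature_matrix(
    samples: SampleTable,
    snp_table: SnpTable | None,
    selected_positions: Sequence[int] | None,
    config: RunConfig | None = None,
    blocks: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the design matrix and its block-qualified column names."""
    config = config or RunConfig()
    layout = FeatureLayout(
        flank=config.window_flank,
        kmer_sizes=tuple(config.kmer_sizes),
        snp_offsets=tuple(selected_positions) if selected_positions is not None else None,
        blocks=tuple(blocks) if blocks is not None else ALL_BLOCKS,
    )
    X = np.empty((len(samples), layout.n_features))
    for i, row in enumerate(samples.df.itertuples(index=False)):
        X[i] = assemble(row.transcript_id, row.position, row.transcript_length,
                        row.window, snp_table, selected_positions, config, blocks)
    return X, layout.feature_names()
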