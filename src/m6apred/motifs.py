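"""DRACH-motif scanning and window extraction.

m6A deposition follows the degenerate consensus DRACH: the accepted 5-mers
are [G/A/C][G/A]AC[U/A/C] with the methylated adenine at the third
position.  Every matching adenine on a transcript is a candidate site;
negatives are simply the candidates that are not validated positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from m6apred.io import SampleTable, TranscriptRecord

DRACH_1 = frozenset("GAC")   # D position (offset -2 from the adenine)
DRACH_2 = frozenset("GA")    # R position (offset -1)
DRACH_5 = frozenset("UAC")   # H position (offset +2)


@dataclass(frozen=True)
class CandidateSite:
    """A DRACH-conforming adenine on a transcript (1-based position)."""

    transcript_id: str
    position: int
    motif_5mer: str


def is_drach(fivemer: str) -> bool:
    return (len(fivemer) == 5 and fivemer[2] == "A" and fivemer[3] == "C"
            and fivemer[0] in DRACH_1 and fivemer[1] in DRACH_2
            and fivemer[4] in DRACH_5)


def scan_drach(transcript: TranscriptRecord) -> list[CandidateSite]:
    """All DRACH-conforming adenines, in position order; overlaps included."""
    seq = transcript.sequence
    sites = []
    # adenine at 1-based position p means the 5-mer spans p-2 .. p+2
    for p in range(3, len(seq) - 1):
        fivemer = seq[p - 3:p + 2]
        if is_drach(fivemer):
            sites.append(CandidateSite(transcript.id, p, fivemer))
    return sites


def extract_window(transcript: TranscriptRecord, position: int, flank: int) -> str:
    """The 2*flank+1 window centered at ``position``, 'N'-padded at edges."""
    if not (1 <= position <= transcript.length):
        raise ValueError(
            f"position {position} outside transcript {transcript.id} "
            f"(length {transcript.length})")
    start = position - 1 - flank
    end = position - 1 + flank + 1
    left_pad = max(0, -start)
    right_pad = max(0, end - transcript.length)
    core = transcript.sequence[max(0, start):min(end, transcript.length)]
    return "N" * left_pad + core + "N" * right_pad


def build_samples(
    transcripts: Iterable[TranscriptRecord],
    positive_sites: Iterable[tuple[str, int]],
    flank: int = 25,
) -> SampleTable:
    """Enumerate every DRACH candidate as a row; label by the positive set.

    A supplied positive that does not conform to DRACH is retained as a
    positive row with a warning (validated positives are expected to
    conform, so a mismatch usually signals a coordinate problem).
    """
    positives = {(str(t), int(p)) for t, p in positive_sites}
    rows = []
    seen: set[tuple[str, int]] = set()
    for tx in transcripts:
        for site in scan_drach(tx):
            key = (tx.id, site.position)
            seen.add(key)
            rows.append((tx.id, site.position, tx.length,
                         extract_window(tx, site.position, flank),
                         1 if key in positives else 0))
        for key in sorted(positives - seen):
            if key[0] != tx.id:
                continue
            pos = key[1]
            if not (1 <= pos <= tx.length):
                raise ValueError(
                    f"positive site {key} outside transcript of length {tx.length}")
            warnings.warn(
                f"positive site {key} does not conform to DRACH; retained",
                stacklevel=2)
            seen.add(key)
            rows.append((tx.id, pos, tx.length,
                         extract_window(tx, pos, flank), 1))
    rows.sort(key=lambda r: (r[0], r[1]))
    return SampleTable.from_rows(rows)


def window_offsets(flank: int) -> Sequence[int]:
    """Window positions labeled -flank..+flank with 0 at the candidate adenine."""
    return list(range(-flank, flank + 1))
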