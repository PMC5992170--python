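"""Scanning sequences for cPPR binding sites.

A design's specificity string is matched against every window of a query
sequence by Hamming distance, with the wildcard N matching any base.
Coordinates are 0-based half-open in all machine output.  ssDNA has no
strand, so reverse-complement scanning is an explicit opt-in for dsDNA
inputs.

Also provides telomeric-primer annotation (splitting a primer into a 5'
spacer and a 3' segment in phase with a telomeric repeat unit) and a
G-quadruplex consensus flag.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

from .scaffold import CPPRDesign

__all__ = [
    "ScanHit",
    "TelomerePrimerAnnotation",
    "hamming_distance",
    "scan_sequence",
    "annotate_telomeric_primer",
    "has_g4_motif",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Four runs of >=3 G separated by 1-7 nt loops (standard G4 consensus).
G4_PATTERN = re.compile(r"G{3,}(?:[ACGTN]{1,7}G{3,}){3}")


def hamming_distance(a: str, b: str, weights: Sequence[float] | None = None) -> float:
    """Number of mismatching positions between equal-length strings.

    The wildcard N never counts as a mismatch in either string.  An optional
    per-position weight vector down-weights positions (e.g. the terminal
    target positions, which contribute least to binding); default uniform.
    Returns an int when weights are uniform.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    a, b = a.upper(), b.upper()
    if weights is None:
        return sum(x != y and x != "N" and y != "N" for x, y in zip(a, b))
    if len(weights) != len(a):
        raise ValueError("weight vector length must match sequence length")
    return sum(
        w for x, y, w in zip(a, b, weights) if x != y and x != "N" and y != "N"
    )


@dataclass(frozen=True)
class ScanHit:
    """A located match: half-open window [offset, offset+L) on the query."""

    offset: int
    mismatches: float
    matched_window: str
    strand: str = "+"

    @property
    def end(self) -> int:
        return self.offset + len(self.matched_window)


def scan_sequence(
    design: CPPRDesign | str,
    sequence: str,
    max_mismatch: float = 0,
    weights: Sequence[float] | None = None,
    revcomp: bool = False,
) -> list[ScanHit]:
    """All windows of ``sequence`` within ``max_mismatch`` of the design's
    specificity string, exhaustively over every window, sorted by
    (mismatches asc, offset asc).

    ``design`` may be a CPPRDesign or a raw specificity string.  A query
    shorter than the design yields an empty result with a warning.
    """
    spec = design.target if isinstance(design, CPPRDesign) else design.upper()
    seq = sequence.upper().replace("U", "T")
    L = len(spec)
    if len(seq) < L:
        warnings.warn(
            f"sequence ({len(seq)} nt) shorter than design ({L} nt); no windows",
            stacklevel=2,
        )
        return []
    hits = []
    strands = [("+", seq)]
    if revcomp:
        strands.append(("-", seq.translate(_COMPLEMENT)[::-1]))
    for strand, s in strands:
        for off in range(len(s) - L + 1):
            window = s[off : off + L]
            mm = hamming_distance(spec, window, weights)
            if mm <= max_mismatch:
                hits.append(ScanHit(off, mm, window, strand))
    hits.sort(key=lambda h: (h.mismatches, h.offset, h.strand))
    return hits


@dataclass(frozen=True)
class TelomerePrimerAnnotation:
    """Decomposition of a primer into a 5' spacer and a 3' telomeric suffix.

    The telomeric segment is the longest 3' suffix that is a substring of
    the repeat unit tiled indefinitely; ``phase_offset`` is the 0-based
    position within the unit at which that suffix starts.
    """

    primer: str
    unit: str
    spacer_len: int
    telo_len: int
    phase_offset: int

    @property
    def spacer(self) -> str:
        return self.primer[: self.spacer_len]

    @property
    def telomeric(self) -> str:
        return self.primer[self.spacer_len :]


def annotate_telomeric_primer(primer: str, unit: str = "TTAGGG") -> TelomerePrimerAnnotation:
    """Split ``primer`` into non-telomeric spacer and telomeric 3' suffix.

    E.g. the 33-nt extension-assay primer CTAGACCTGTCATCA + TTAGGG x3
    annotates as a 15-nt spacer plus an 18-nt telomeric segment.
    """
    if not primer or not unit:
        raise ValueError("primer and unit must be non-empty")
    primer, unit = primer.upper(), unit.upper()
    n = len(primer)
    # tile the unit to cover any suffix plus one extra period for phasing;
    # the leftmost occurrence of an in-phase suffix always starts within the
    # first period
    tiled = unit * (n // len(unit) + 2)
    telo_len = 0
    phase = 0
    for k in range(1, n + 1):
        pos = tiled.find(primer[n - k :])
        if pos == -1:
            break
        telo_len, phase = k, pos
    # a trailing coincidence shorter than one full unit (e.g. a lone A that
    # happens to occur in TTAGGG) is not a telomeric segment
    if telo_len < len(unit):
        telo_len, phase = 0, 0
    return TelomerePrimerAnnotation(primer, unit, n - telo_len, telo_len, phase)


def has_g4_motif(sequence: str) -> bool:
    """True iff the sequence matches the G-quadruplex consensus: four runs
    of >=3 G separated by loops of 1-7 nt."""
    return G4_PATTERN.search(sequence.upper().replace("U", "T")) is not None
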