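"""Desk-scale Bind-n-Seq analysis.

Bind-n-Seq selects a randomised ssDNA library on an immobilised protein and
sequences the bound pool alongside the unselected input.  This module
covers the downstream computation: anchored flank trimming with an exact
insert-length filter, per-position base frequencies with information
content, and discriminative k-mer enrichment of the selected pool over the
background, scored with a one-sided hypergeometric exact test and a
Bonferroni-style E-value.

Exact k-mer enrichment deliberately replaces regular-expression motif
elicitation: the quantity of interest — whether the designed target is the
most enriched k-mer and the predicted base dominates every position — is
testable without a heuristic motif search.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LibraryConstruct",
    "TrimTally",
    "EnrichmentResult",
    "PositionFrequencyMatrix",
    "trim_and_filter",
    "position_base_matrix",
    "exact_enrichment_test",
    "kmer_enrichment",
    "logo_information",
]

BASES = ("A", "C", "G", "T")

#: Printed library: 17-nt 5' flank, 10-nt randomised insert, 19-nt 3' flank.
DEFAULT_FLANK5 = "CTTTATCCAGCCCTCAC"
DEFAULT_FLANK3 = "CTATAGTGTCACCTAAATC"


@dataclass(frozen=True)
class LibraryConstruct:
    """Fixed flanks around the randomised insert of a Bind-n-Seq library."""

    flank5: str = DEFAULT_FLANK5
    insert_len: int = 10
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be non-empty")
        if self.insert_len < 1:
            raise ValueError("insert_len must be >= 1")

    @property
    def full_length(self) -> int:
        return len(self.flank5) + self.insert_len + len(self.flank3)

    def wrap(self, insert: str) -> str:
        return self.flank5 + insert + self.flank3


@dataclass
class TrimTally:
    """Bookkeeping for trim_and_filter rejections."""

    kept: int = 0
    rejected_flank: int = 0
    rejected_length: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.rejected_flank + self.rejected_length


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_and_filter(
    reads: Iterable[str],
    construct: LibraryConstruct | None = None,
    max_flank_mismatch: int = 1,
) -> tuple[list[str], TrimTally]:
    """Strip anchored flanks from merged reads and keep exact-length inserts.

    The 5' flank is matched at the read start and the 3' flank at the read
    end, each tolerating up to ``max_flank_mismatch`` substitutions.  Reads
    whose flanks do not match are tallied as flank rejections; trimmed
    inserts not exactly ``insert_len`` long are tallied as length
    rejections.  Nothing raises — all failures are tallied.
    """
    construct = construct or LibraryConstruct()
    f5, f3 = construct.flank5, construct.flank3
    inserts: list[str] = []
    tally = TrimTally()
    for read in reads:
        read = read.strip().upper()
        if len(read) < len(f5) + len(f3):
            tally.rejected_flank += 1
            continue
        if (
            _mismatches(read[: len(f5)], f5) > max_flank_mismatch
            or _mismatches(read[-len(f3) :], f3) > max_flank_mismatch
        ):
            tally.rejected_flank += 1
            continue
        insert = read[len(f5) : -len(f3)]
        if len(insert) != construct.insert_len:
            tally.rejected_length += 1
            continue
        inserts.append(insert)
        tally.kept += 1
    return inserts, tally


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts/frequencies over equal-length inserts."""

    counts: pd.DataFrame  # index: 0-based position, columns: A C G T
    frequencies: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        freq = self.counts.div(self.counts.sum(axis=1), axis=0)
        object.__setattr__(self, "frequencies", freq)

    @property
    def length(self) -> int:
        return len(self.counts)

    def information(self) -> pd.Series:
        """Information content per position in bits: 2 + sum f*log2 f."""
        f = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(f > 0, f * np.log2(f), 0.0)
        return pd.Series(2.0 + h.sum(axis=1), index=self.counts.index, name="bits")

    def logo_matrix(self) -> pd.DataFrame:
        """Frequencies scaled by per-position information, ready for a
        sequence-logo plot."""
        return self.frequencies.mul(self.information(), axis=0)


def position_base_matrix(inserts: Sequence[str]) -> PositionFrequencyMatrix:
    """Count bases per position over a collection of equal-length inserts."""
    if not inserts:
        raise ValueError("empty insert collection")
    L = len(inserts[0])
    if any(len(s) != L for s in inserts):
        raise ValueError("inserts have mixed lengths")
    arr = np.frombuffer("".join(s.upper() for s in inserts).encode(), dtype="S1")
    arr = arr.reshape(len(inserts), L)
    counts = pd.DataFrame(
        {b: (arr == b.encode()).sum(axis=0) for b in BASES},
        index=pd.RangeIndex(L, name="position"),
    )
    return PositionFrequencyMatrix(counts)


def exact_enrichment_test(
    count_sel: int, total_sel: int, count_bg: int, total_bg: int
) -> float:
    """One-sided (enrichment direction) hypergeometric tail probability for
    the 2x2 table (count_sel, total_sel-count_sel; count_bg, total_bg-count_bg).

    Under the null that the ``count_sel + count_bg`` occurrences are
    distributed between the pools by pool size alone, returns
    P(X >= count_sel) with X hypergeometric.
    """
    for v in (count_sel, total_sel, count_bg, total_bg):
        if v < 0:
            raise ValueError("negative counts")
    if count_sel > total_sel or count_bg > total_bg:
        raise ValueError("counts exceed totals")
    if total_sel < 1 or total_bg < 1:
        raise ValueError("totals must be >= 1")
    M = total_sel + total_bg
    K = count_sel + count_bg
    return float(stats.hypergeom.sf(count_sel - 1, M, K, total_sel))


@dataclass(frozen=True)
class EnrichmentResult:
    """A k-mer with its selected/background occurrence counts, exact-test
    p-value and Bonferroni-style E-value."""

    kmer: str
    count_selected: int
    total_selected: int
    count_background: int
    total_background: int
    p_value: float
    e_value: float

    @property
    def fold_enrichment(self) -> float:
        sel = self.count_selected / self.total_selected
        bg = self.count_background / self.total_background
        return math.inf if bg == 0 else sel / bg


def _kmer_counts(inserts: Iterable[str], k: int) -> tuple[Counter, int]:
    counts: Counter = Counter()
    windows = 0
    for s in inserts:
        s = s.upper()
        if len(s) < k:
            raise ValueError(f"insert shorter than k={k}: {s!r}")
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
            windows += 1
    return counts, windows


def kmer_enrichment(
    selected: Sequence[str], background: Sequence[str], k: int = 10
) -> list[EnrichmentResult]:
    """Test every k-mer occurring in the selected pool for enrichment over
    the background pool.

    Occurrences are counted over all windows of all inserts; totals are the
    window counts of each pool.  E-value = p x (number of distinct k-mers
    tested).  Sorted by p ascending, ties by selected count descending then
    lexicographic — so the most confidently enriched k-mer is first.
    """
    if not selected or not background:
        raise ValueError("both pools must be non-empty")
    sel_counts, sel_total = _kmer_counts(selected, k)
    bg_counts, bg_total = _kmer_counts(background, k)
    n_tested = len(sel_counts)
    results = [
        EnrichmentResult(
            kmer=kmer,
            count_selected=c,
            total_selected=sel_total,
            count_background=bg_counts.get(kmer, 0),
            total_background=bg_total,
            p_value=(p := exact_enrichment_test(c, sel_total, bg_counts.get(kmer, 0), bg_total)),
            e_value=min(p * n_tested, math.inf),
        )
        for kmer, c in sel_counts.items()
    ]
    results.sort(key=lambda r: (r.p_value, -r.count_selected, r.kmer))
    return results


def logo_information(matrix: PositionFrequencyMatrix) -> pd.Series:
    """Per-position information content in bits (0 = uniform, 2 = fixed)."""
    return matrix.information()


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV output."""
    return pd.DataFrame(
        [
            {
                "kmer": r.kmer,
                "count_selected": r.count_selected,
                "total_selected": r.total_selected,
                "count_background": r.count_background,
                "total_background": r.total_background,
                "p_value": r.p_value,
                "e_value": r.e_value,
            }
            for r in results
        ]
    )
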