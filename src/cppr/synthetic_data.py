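"""Synthetic Bind-n-Seq libraries with the statistical structure the
analysis assumes.

The generator emulates the printed library construct — fixed 5'/3' flanks
around a 10-nt uniformly randomised insert — and a bead pull-down in which
an insert with m mismatches to the design target is retained with
probability epsilon**m.  This is the simplest monotone selection model
consistent with binding degrading over the 1/3/5-mismatch probe series; no
attempt is made to fit real affinities, PCR bias or duplicate structure.
Sequencing errors, when requested, are substitution-only.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bindnseq import LibraryConstruct
from .scaffold import CPPRDesign

__all__ = [
    "SelectionModel",
    "generate_random_library",
    "select_library",
    "sample_selected_library",
    "emit_reads",
    "write_fastq",
    "read_fastq",
    "simulate_bindnseq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _to_strings(arr: np.ndarray) -> list[str]:
    return [row.tobytes().decode() for row in arr]


def _to_array(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype="S1")
    L = len(seqs[0])
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)


@dataclass(frozen=True)
class SelectionModel:
    """Bead pull-down stand-in: an insert with m mismatches to the design
    target survives selection with probability epsilon**m (epsilon**0 = 1)."""

    design: CPPRDesign | str
    epsilon: float
    seed: int = 0

    @property
    def target(self) -> str:
        d = self.design
        return d.target if isinstance(d, CPPRDesign) else d.upper()

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")


def generate_random_library(n: int, insert_len: int = 10, seed: int | np.random.Generator = 0) -> list[str]:
    """n inserts of uniform i.i.d. bases, reproducible given seed."""
    if n < 1 or insert_len < 1:
        raise ValueError("n and insert_len must be >= 1")
    rng = _rng(seed)
    return _to_strings(_BASES[rng.integers(0, 4, size=(n, insert_len))])


def _mismatch_counts(arr: np.ndarray, target: str) -> np.ndarray:
    t = np.frombuffer(target.encode(), dtype="S1")
    return (arr != t).sum(axis=1)


def select_library(
    library: Sequence[str], model: SelectionModel, rng: np.random.Generator | None = None
) -> list[str]:
    """Retain each insert independently with probability epsilon**m, where m
    is its Hamming distance to the model target."""
    target = model.target
    arr = _to_array(library)
    if arr.size and arr.shape[1] != len(target):
        raise ValueError(
            f"insert length {arr.shape[1]} != target length {len(target)}"
        )
    rng = rng or _rng(model.seed)
    if not arr.size:
        return []
    m = _mismatch_counts(arr, target)
    keep = rng.random(len(library)) < model.epsilon**m
    return _to_strings(arr[keep])


def sample_selected_library(
    n: int, model: SelectionModel, batch: int = 1_000_000
) -> list[str]:
    """Exactly n post-selection inserts: random candidates are streamed
    through the Bernoulli retention model in batches until n survive.

    With epsilon = 0.3 and a 10-nt target roughly 0.06% of uniform inserts
    survive, so a fixed selected sequencing depth (the quantity a real run
    reports) is obtained by running the selection to depth rather than
    thinning a fixed input pool.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    target = model.target
    rng = _rng(model.seed)
    out: list[str] = []
    while len(out) < n:
        cand = _BASES[rng.integers(0, 4, size=(batch, len(target)))]
        m = _mismatch_counts(cand, target)
        keep = rng.random(batch) < model.epsilon**m
        out.extend(_to_strings(cand[keep]))
    return out[:n]


def emit_reads(
    inserts: Iterable[str],
    construct: LibraryConstruct | None = None,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    quality: int = 40,
) -> list[SeqRecord]:
    """Wrap inserts in the library flanks as FASTQ-ready records.

    ``error_rate`` applies uniform substitution errors over the whole read
    (flanks included); quality is a constant placeholder score.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    construct = construct or LibraryConstruct()
    rng = _rng(seed)
    records = []
    for i, insert in enumerate(inserts):
        read = construct.wrap(insert)
        if error_rate > 0:
            chars = np.frombuffer(read.encode(), dtype="S1").copy()
            hit = np.nonzero(rng.random(len(chars)) < error_rate)[0]
            for j in hit:
                # substitute with one of the three other bases
                others = _BASES[_BASES != chars[j]]
                chars[j] = others[rng.integers(0, len(others))]
            read = chars.tobytes().decode()
        rec = SeqRecord(Seq(read), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(read)
        records.append(rec)
    return records


def write_fastq(records: Iterable[SeqRecord], path: str) -> int:
    return SeqIO.write(records, path, "fastq")


def read_fastq(source: str | io.TextIOBase) -> list[str]:
    """Read sequences (as strings) from a FASTQ file or handle."""
    return [str(rec.seq) for rec in SeqIO.parse(source, "fastq")]


def simulate_bindnseq(
    target: str,
    n: int = 20_000,
    epsilon: float = 0.3,
    error_rate: float = 0.0,
    seed: int = 42,
    construct: LibraryConstruct | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """End-to-end simulation: (selected reads, background reads), n each.

    The background pool is the unselected random library; the selected pool
    is drawn through the epsilon**m retention model to the same depth.
    Derived seeds keep the two pools and the error process independent.
    """
    construct = construct or LibraryConstruct()
    target = target.upper().replace("U", "T")
    ss = np.random.SeedSequence(seed)
    s_bg, s_sel, s_err_bg, s_err_sel = ss.spawn(4)
    background = generate_random_library(n, len(target), np.random.default_rng(s_bg))
    model = SelectionModel(design=target, epsilon=epsilon)
    sel_rng = np.random.default_rng(s_sel)
    selected: list[str] = []
    batch = 1_000_000
    while len(selected) < n:
        cand = _BASES[sel_rng.integers(0, 4, size=(batch, len(target)))]
        m = _mismatch_counts(cand, target)
        keep = sel_rng.random(batch) < model.epsilon**m
        selected.extend(_to_strings(cand[keep]))
    selected = selected[:n]
    sel_reads = emit_reads(selected, construct, error_rate, np.random.default_rng(s_err_sel))
    bg_reads = emit_reads(background, construct, error_rate, np.random.default_rng(s_err_bg))
    return sel_reads, bg_reads
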