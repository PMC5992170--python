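"""Assembly of consensus PPR proteins from nucleotide targets and back.

A cPPR is an N-terminal cap (MGNS by default), one 35-aa consensus repeat
per target nucleotide with the specificity residues at repeat-local
positions 5 and 35 chosen by the recognition code, and a C-terminal
solvating helix (VTYTTLISGLGKAG by default) that prevents fraying of the
final repeat.

Polarity: repeat 1 (N-terminal) reads the 5'-most target base, so repeats
1..R spell the target 5'->3'.  Repeat-local numbering follows the scheme in
which the specificity positions are 5 and 35; global residue numbers obey

    global = cap_len + repeat_len * (repeat - 1) + local_pos

which places e.g. Arg16 of repeat 5 at residue 160 in a standard 4-residue
capped design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .ppr_code import CodeTable, load_default_table, normalize_base

__all__ = [
    "RepeatTemplate",
    "CPPRDesign",
    "build_design",
    "parse_design",
    "global_residue_index",
    "repeat_local_from_global",
    "DEFAULT_N_CAP",
    "DEFAULT_C_HELIX",
]

DEFAULT_N_CAP = "MGNS"
DEFAULT_C_HELIX = "VTYTTLISGLGKAG"

REPEAT_LEN = 35
#: Repeat-local specificity slots substituted per target base.
VARIABLE_POSITIONS = (5, 35)
#: Structurally constrained positions of the consensus repeat (1-based):
#: Val2 sandwiches the bases, Lys13 binds the phosphate backbone, and the
#: Arg16/Glu18/Glu19 and Glu25/Glu26/Lys28 sets form the inter-repeat
#: hydrogen-bond networks on the b-helix face.
FIXED_POSITIONS = {2: "V", 13: "K", 16: "R", 18: "E", 19: "E", 25: "E", 26: "E", 28: "K"}


@dataclass(frozen=True)
class RepeatTemplate:
    """The 35-aa consensus repeat with variable slots at positions 5 and 35."""

    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != REPEAT_LEN:
            raise ValueError(f"repeat template must be {REPEAT_LEN} aa, got {len(seq)}")
        for pos, aa in FIXED_POSITIONS.items():
            if seq[pos - 1] != aa:
                raise ValueError(
                    f"template position {pos} must be {aa}, found {seq[pos - 1]}"
                )
        object.__setattr__(self, "sequence", seq)

    def with_pair(self, aa5: str, aa35: str) -> str:
        """Repeat sequence with the specificity slots substituted."""
        s = list(self.sequence)
        s[4] = aa5
        s[34] = aa35
        return "".join(s)

    @classmethod
    def from_file(cls, path: str | Path) -> "RepeatTemplate":
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#") and not ln.startswith(">")
        ]
        return cls("".join(lines))

    @classmethod
    def default(cls) -> "RepeatTemplate":
        with resources.as_file(resources.files("cppr.data") / "repeat_template.txt") as p:
            return cls.from_file(p)


@dataclass(frozen=True)
class CPPRDesign:
    """A designed cPPR: simultaneously a protein sequence and a nucleotide
    specificity string.

    ``repeats[i]`` is the (aa5, aa35) pair of repeat i+1, which reads
    ``target[i]``.
    """

    name: str
    target: str
    repeats: tuple[tuple[str, str], ...]
    n_cap: str
    c_helix: str
    protein: str

    def __post_init__(self) -> None:
        if len(self.repeats) != len(self.target):
            raise ValueError("one repeat per target nucleotide required")
        expect = len(self.n_cap) + REPEAT_LEN * len(self.repeats) + len(self.c_helix)
        if len(self.protein) != expect:
            raise ValueError(
                f"protein length {len(self.protein)} != cap+repeats+helix {expect}"
            )

    def __len__(self) -> int:
        """Number of repeats (= target length in nt)."""
        return len(self.repeats)

    def residue_range(self, repeat: int) -> tuple[int, int]:
        """1-based inclusive global residue range occupied by ``repeat``."""
        start = global_residue_index(repeat, 1, len(self.n_cap))
        return start, start + REPEAT_LEN - 1

    def to_json(self) -> str:
        """JSON sidecar with repeats, pairs, caps and residue ranges."""
        return json.dumps(
            {
                "name": self.name,
                "target": self.target,
                "n_cap": self.n_cap,
                "c_helix": self.c_helix,
                "repeats": [
                    {
                        "repeat": i + 1,
                        "base": self.target[i],
                        "aa5": p[0],
                        "aa35": p[1],
                        "residues": list(self.residue_range(i + 1)),
                    }
                    for i, p in enumerate(self.repeats)
                ],
            },
            indent=2,
        )


def build_design(
    target: str,
    template: RepeatTemplate | None = None,
    code: CodeTable | None = None,
    n_cap: str = DEFAULT_N_CAP,
    c_helix: str = DEFAULT_C_HELIX,
    name: str | None = None,
) -> CPPRDesign:
    """Design a cPPR protein binding ``target`` (5'->3', alphabet ACGTU).

    One repeat is emitted per base, with positions 5/35 set by the
    recognition code; repeat 1 reads the 5'-most base.
    """
    if not target:
        raise ValueError("empty target sequence")
    template = template or RepeatTemplate.default()
    code = code or load_default_table()
    bases = [normalize_base(b) for b in target]
    pairs = tuple(code.residues_for_base(b) for b in bases)
    protein = n_cap + "".join(template.with_pair(*p) for p in pairs) + c_helix
    return CPPRDesign(
        name=name or f"cPPR-{''.join(bases)}",
        target="".join(bases),
        repeats=pairs,
        n_cap=n_cap,
        c_helix=c_helix,
        protein=protein,
    )


def global_residue_index(
    repeat: int, local_pos: int, cap_len: int = len(DEFAULT_N_CAP), repeat_len: int = REPEAT_LEN
) -> int:
    """Global (1-based) residue number of ``local_pos`` in ``repeat``.

    E.g. repeat 5 local 16 with a 4-residue cap -> 160, matching the
    standardised annotation in which Arg160 is the Arg16 of repeat 5.
    """
    if repeat < 1:
        raise ValueError(f"repeat index must be >= 1, got {repeat}")
    if not 1 <= local_pos <= repeat_len:
        raise ValueError(f"local position {local_pos} outside 1..{repeat_len}")
    return cap_len + repeat_len * (repeat - 1) + local_pos


def repeat_local_from_global(
    index: int, cap_len: int = len(DEFAULT_N_CAP), repeat_len: int = REPEAT_LEN
) -> tuple[int, int]:
    """Inverse of :func:`global_residue_index`.

    Rejects indices inside the N-cap (the C-helix is open-ended and cannot
    be distinguished without knowing the repeat count, so callers slice it
    off first).
    """
    if index <= cap_len:
        raise ValueError(f"residue {index} lies in the N-terminal cap")
    off = index - cap_len - 1
    return off // repeat_len + 1, off % repeat_len + 1


def parse_design(
    protein: str,
    template: RepeatTemplate | None = None,
    code: CodeTable | None = None,
    n_cap: str = DEFAULT_N_CAP,
    c_helix: str = DEFAULT_C_HELIX,
    max_mismatch_frac: float = 0.2,
) -> str:
    """Predict the nucleotide target of a cPPR protein sequence.

    The protein must decompose as cap + 35*R + helix for integer R >= 1.
    Non-variable template positions may deviate up to ``max_mismatch_frac``
    per repeat so natural/variant PPRs can still be read; the specificity
    slots are always read as-is and non-canonical pairs yield the wildcard N.
    """
    template = template or RepeatTemplate.default()
    code = code or load_default_table()
    protein = protein.upper()
    body = len(protein) - len(n_cap) - len(c_helix)
    if body < REPEAT_LEN or body % REPEAT_LEN:
        raise ValueError(
            f"length {len(protein)} does not decompose as cap({len(n_cap)}) + "
            f"{REPEAT_LEN}*R + helix({len(c_helix)}); residual {body % REPEAT_LEN} aa"
        )
    n_rep = body // REPEAT_LEN
    fixed = [i for i in range(REPEAT_LEN) if (i + 1) not in VARIABLE_POSITIONS]
    max_mm = max_mismatch_frac * len(fixed)
    bases = []
    for r in range(n_rep):
        seg = protein[len(n_cap) + r * REPEAT_LEN : len(n_cap) + (r + 1) * REPEAT_LEN]
        mm = sum(seg[i] != template.sequence[i] for i in fixed)
        if mm > max_mm:
            raise ValueError(
                f"repeat {r + 1} deviates from the consensus template at {mm} "
                f"fixed positions (tolerance {max_mm:.1f})"
            )
        bases.append(code.base_for_residues(seg[4], seg[34]))
    return "".join(bases)
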