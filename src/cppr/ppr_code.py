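"""The modular PPR base-recognition code.

Consensus PPR (cPPR) repeats read one nucleotide each; the identity of the
bound base is set by the amino acids at repeat-local positions 5 and 35.
The canonical code is

    (T, N) -> A      (N, S) -> C
    (T, D) -> G      (N, D) -> T/U

The table is shipped as plain-text config (``data/code_table.tsv``) so that
extended codes from the literature can be added without code changes.  U and
T are not distinguished: the same residue pairs bind both RNA and ssDNA, so
all internal logic uses T and callers may render U for RNA display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = ["CodeTable", "load_default_table", "residues_for_base", "base_for_residues"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_BASES = ("A", "C", "G", "T")

#: Wildcard returned for residue pairs absent from the table.
WILDCARD = "N"


def normalize_base(base: str) -> str:
    """Upper-case a single base symbol, mapping U to T.

    Raises ``ValueError`` naming the symbol if it is not one of A, C, G, T, U.
    """
    b = base.upper()
    if b == "U":
        b = "T"
    if b not in _BASES:
        raise ValueError(f"unknown base symbol: {base!r}")
    return b


@dataclass(frozen=True)
class CodeTable:
    """Bidirectional mapping between (position-5, position-35) residue pairs
    and the nucleotide base they recognise.

    ``entries`` maps residue pairs to bases.  The first pair listed for each
    base is its canonical design pair, used for forward design.
    """

    entries: dict[tuple[str, str], str]
    _canonical: dict[str, tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        canonical: dict[str, tuple[str, str]] = {}
        for (aa5, aa35), base in self.entries.items():
            if aa5 not in _AA or aa35 not in _AA:
                raise ValueError(f"not one-letter amino acids: ({aa5!r}, {aa35!r})")
            if base not in _BASES:
                raise ValueError(f"invalid base {base!r} for pair ({aa5}, {aa35})")
            canonical.setdefault(base, (aa5, aa35))
        missing = [b for b in _BASES if b not in canonical]
        if missing:
            raise ValueError(f"code table lacks a pair for base(s): {', '.join(missing)}")
        object.__setattr__(self, "_canonical", canonical)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "CodeTable":
        """Build a table from (aa5, aa35, base) rows.

        A pair listed twice with conflicting bases violates injectivity and
        is rejected.
        """
        entries: dict[tuple[str, str], str] = {}
        for aa5, aa35, base in rows:
            key = (aa5.upper(), aa35.upper())
            b = normalize_base(base)
            if key in entries and entries[key] != b:
                raise ValueError(
                    f"residue pair ({key[0]}, {key[1]}) maps to both "
                    f"{entries[key]} and {b}"
                )
            entries[key] = b
        return cls(entries)

    @classmethod
    def from_file(cls, path: str | Path) -> "CodeTable":
        """Load a table from a whitespace/tab-delimited config file.

        Lines starting with ``#`` and a header line beginning with ``aa5``
        are ignored.
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("aa5"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"malformed code-table row: {line!r}")
            rows.append(tuple(fields))
        return cls.from_rows(rows)

    def residues_for_base(self, base: str) -> tuple[str, str]:
        """Canonical (aa5, aa35) pair recognising ``base`` (U treated as T)."""
        return self._canonical[normalize_base(base)]

    def base_for_residues(self, aa5: str, aa35: str) -> str:
        """Base recognised by a residue pair, or the wildcard ``N`` if the
        pair is not in the table.

        The wildcard fallback lets natural PPR sequences with non-canonical
        pairs still be parsed and scanned.
        """
        aa5, aa35 = aa5.upper(), aa35.upper()
        for aa in (aa5, aa35):
            if aa not in _AA:
                raise ValueError(f"not a one-letter amino-acid code: {aa!r}")
        return self.entries.get((aa5, aa35), WILDCARD)


def load_default_table() -> CodeTable:
    """The canonical four-entry code shipped with the package."""
    with resources.as_file(resources.files("cppr.data") / "code_table.tsv") as p:
        return CodeTable.from_file(p)


_DEFAULT: CodeTable | None = None


def _default() -> CodeTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_default_table()
    return _DEFAULT


def residues_for_base(base: str) -> tuple[str, str]:
    """Module-level shortcut using the default code table."""
    return _default().residues_for_base(base)


def base_for_residues(aa5: str, aa35: str) -> str:
    """Module-level shortcut using the default code table."""
    return _default().base_for_residues(aa5, aa35)
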