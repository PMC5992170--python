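"""Structural observables of cPPR solenoids from atomic coordinates.

Covers the measurements used to characterise the apo versus ssDNA-bound
states of a designed PPR protein: per-class heavy-atom counts, distance-
based hydrogen-bond detection, the inter-repeat b-helix hydrogen-bond
network (Arg16/Glu18/Glu19 and Lys28/Glu26 in repeat-local numbering), the
count of junctions whose network rearranges between two states, and the
superhelix extent.

Hydrogen bonds use a heavy-atom donor/acceptor (N/O) distance criterion
only — deposited models carry no hydrogens, so no angle term is applied.
The default cutoff is 3.5 Angstrom; some genuine but long bonds (e.g.
threonine-to-adenine contacts at 3.6-3.9 A) appear only at a 4.0 A cutoff.

Superhelix length is defined here as the maximum pairwise C-alpha distance;
the convention is recorded in the output.
"""

from __future__ import annotations

import math
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .scaffold import global_residue_index

__all__ = [
    "Atom",
    "StructureModel",
    "HydrogenBond",
    "JunctionNetwork",
    "read_structure",
    "count_atoms",
    "find_hbonds",
    "junction_networks",
    "compare_networks",
    "superhelix_length",
    "fetch_pdb",
]

_PROTEIN = set(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP "
    "TYR VAL MSE SEC PYL".split()
)
_DNA = {"DA", "DC", "DG", "DT", "DI", "DU"}
_RNA = {"A", "C", "G", "U", "I"}
_WATER = {"HOH", "WAT", "DOD"}

#: Side-chain donor/acceptor atoms used for the junction network.
ARG_SIDE = ("NE", "NH1", "NH2")
LYS_SIDE = ("NZ",)
GLU_SIDE = ("OE1", "OE2")

# minimum separation below which an N/O contact is treated as covalent
_COVALENT_FLOOR = 2.2


def classify_residue(resname: str) -> str:
    """protein / dna / rna / water / other, by residue name."""
    name = resname.strip().upper()
    if name in _PROTEIN:
        return "protein"
    if name in _DNA:
        return "dna"
    if name in _RNA:
        return "rna"
    if name in _WATER:
        return "water"
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_amino_acid():
            return "protein"
        if info.is_water():
            return "water"
        if info.is_nucleic_acid():
            return "dna" if name.startswith("D") else "rna"
    return "other"


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    res_name: str
    name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float
    altloc: str
    polymer_class: str

    def ref(self) -> str:
        return f"{self.chain}/{self.res_name}{self.res_num}/{self.name}"


class StructureModel:
    """Flattened atomic model with altlocs resolved and residues classified.

    After altloc resolution (highest occupancy, ties broken by the
    alphabetically first label) the key (chain, residue number, atom name)
    is unique.
    """

    def __init__(self, atoms: Sequence[Atom]):
        seen = set()
        for a in atoms:
            if not all(math.isfinite(c) for c in a.pos):
                raise ValueError(f"non-finite coordinates for {a.ref()}")
            key = (a.chain, a.res_num, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc resolution: {a.ref()}")
            seen.add(key)
        self.atoms = list(atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        return np.array([a.pos for a in (self.atoms if atoms is None else atoms)])

    def select(
        self,
        polymer_class: str | None = None,
        name: str | None = None,
        elements: set[str] | None = None,
    ) -> list[Atom]:
        out = self.atoms
        if polymer_class is not None:
            out = [a for a in out if a.polymer_class == polymer_class]
        if name is not None:
            out = [a for a in out if a.name == name]
        if elements is not None:
            out = [a for a in out if a.element in elements]
        return out

    def atom(self, chain: str | None, res_num: int, name: str) -> Atom | None:
        for a in self.atoms:
            if a.res_num == res_num and a.name == name and (chain is None or a.chain == chain):
                return a
        return None


def _resolve_altlocs(raw: list[Atom]) -> list[Atom]:
    best: dict[tuple[str, int, str], Atom] = {}
    for a in raw:
        key = (a.chain, a.res_num, a.name)
        prev = best.get(key)
        if prev is None or (a.occupancy, _neg_ord(a.altloc)) > (prev.occupancy, _neg_ord(prev.altloc)):
            best[key] = a
    return list(best.values())


def _neg_ord(altloc: str) -> float:
    # higher is better; earlier labels win ties, blank beats everything
    return -ord(altloc) if altloc else 0.0


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB file into a StructureModel (first model only)."""
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    raw: list[Atom] = []
    for chain in st[0]:
        for res in chain:
            cls = classify_residue(res.name)
            for at in res:
                raw.append(
                    Atom(
                        chain=chain.name,
                        res_num=res.seqid.num,
                        res_name=res.name,
                        name=at.name,
                        element=at.element.name.upper(),
                        pos=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        altloc=at.altloc if at.altloc != "\x00" else "",
                        polymer_class=cls,
                    )
                )
    return StructureModel(_resolve_altlocs(raw))


def count_atoms(model: StructureModel, polymer_class: str) -> int:
    """Non-hydrogen atom count for a polymer class (after altloc resolution)."""
    cls = polymer_class.strip().lower()
    if cls not in {"protein", "dna", "rna", "water", "other"}:
        raise ValueError(f"unknown polymer class: {polymer_class!r}")
    return sum(
        1 for a in model.select(polymer_class=cls) if a.element not in {"H", "D"}
    )


@dataclass(frozen=True)
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float


def find_hbonds(model: StructureModel, cutoff: float = 3.5) -> list[HydrogenBond]:
    """All inter-residue N/O--N/O contacts within ``cutoff`` Angstrom.

    Pairs within one residue, and contacts below 2.2 A (covalent range),
    are excluded.  Without hydrogens donor/acceptor assignment is by
    convention: nitrogen before oxygen, then input order.  Distances are
    rounded to 0.01 A.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    polar = [a for a in model.atoms if a.element in {"N", "O"}]
    if len(polar) < 2:
        return []
    xyz = np.array([a.pos for a in polar])
    tree = cKDTree(xyz)
    bonds = []
    for i, j in tree.query_pairs(cutoff):
        a, b = polar[i], polar[j]
        if (a.chain, a.res_num) == (b.chain, b.res_num):
            continue
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d < _COVALENT_FLOOR:
            continue
        if b.element == "N" and a.element == "O":
            a, b = b, a
        bonds.append(HydrogenBond(a, b, round(d, 2)))
    bonds.sort(key=lambda h: (h.donor.chain, h.donor.res_num, h.donor.name, h.distance))
    return bonds


@dataclass(frozen=True)
class JunctionFlags:
    """Presence of the three side-chain bonds at one inter-repeat junction.

    None means indeterminate (an expected residue or atom is missing from
    the model).
    """

    arg16_glu19: bool | None
    arg16_glu18: bool | None
    lys28_glu26: bool | None


@dataclass(frozen=True)
class JunctionNetwork:
    """Junction j (1..R-1) sits between repeats j and j+1; flags record the
    Arg16(j+1)-Glu19(j+1), Arg16(j+1)-Glu18(j) and Lys28(j)-Glu26(j+1)
    side-chain hydrogen bonds."""

    n_repeats: int
    junctions: tuple[JunctionFlags, ...]

    def __post_init__(self) -> None:
        if len(self.junctions) != self.n_repeats - 1:
            raise ValueError("an R-repeat design has exactly R-1 junctions")


def _sidechain_contact(
    model: StructureModel,
    chain: str | None,
    res_a: int,
    atoms_a: tuple[str, ...],
    res_b: int,
    atoms_b: tuple[str, ...],
    cutoff: float,
) -> bool | None:
    pa = [model.atom(chain, res_a, n) for n in atoms_a]
    pb = [model.atom(chain, res_b, n) for n in atoms_b]
    pa = [a for a in pa if a is not None]
    pb = [b for b in pb if b is not None]
    if not pa or not pb:
        return None
    for a in pa:
        for b in pb:
            d = math.dist(a.pos, b.pos)
            if _COVALENT_FLOOR <= d <= cutoff:
                return True
    return False


def junction_networks(
    model: StructureModel,
    n_repeats: int,
    cap_len: int = 4,
    cutoff: float = 3.5,
    chain: str | None = None,
) -> JunctionNetwork:
    """Evaluate the inter-repeat b-helix hydrogen-bond network.

    Residue numbers are derived from the cap + 35*(repeat-1) + local
    arithmetic, so the model numbering must match the design numbering
    (e.g. Arg16 of repeat 5 at residue 160 for a 4-residue cap).
    """
    flags = []
    for j in range(1, n_repeats):
        r_prev, r_next = j, j + 1
        arg16 = global_residue_index(r_next, 16, cap_len)
        glu19 = global_residue_index(r_next, 19, cap_len)
        glu18 = global_residue_index(r_prev, 18, cap_len)
        lys28 = global_residue_index(r_prev, 28, cap_len)
        glu26 = global_residue_index(r_next, 26, cap_len)
        flags.append(
            JunctionFlags(
                arg16_glu19=_sidechain_contact(model, chain, arg16, ARG_SIDE, glu19, GLU_SIDE, cutoff),
                arg16_glu18=_sidechain_contact(model, chain, arg16, ARG_SIDE, glu18, GLU_SIDE, cutoff),
                lys28_glu26=_sidechain_contact(model, chain, lys28, LYS_SIDE, glu26, GLU_SIDE, cutoff),
            )
        )
    return JunctionNetwork(n_repeats, tuple(flags))


def compare_networks(apo: JunctionNetwork, bound: JunctionNetwork) -> tuple[int, list[int]]:
    """Count junctions whose Arg16-Glu19 bond is present in the apo state
    and lost in the bound state.

    Returns (rearranged count, 1-based indices of indeterminate junctions,
    which are excluded from the count).
    """
    if apo.n_repeats != bound.n_repeats:
        raise ValueError("junction count mismatch between models")
    rearranged = 0
    indeterminate = []
    for j, (a, b) in enumerate(zip(apo.junctions, bound.junctions), start=1):
        if a.arg16_glu19 is None or b.arg16_glu19 is None:
            indeterminate.append(j)
            continue
        if a.arg16_glu19 and not b.arg16_glu19:
            rearranged += 1
    return rearranged, indeterminate


def superhelix_length(model: StructureModel) -> float:
    """Superhelix extent: maximum pairwise C-alpha distance (Angstrom)."""
    ca = [a for a in model.select(polymer_class="protein", name="CA")]
    if len(ca) < 2:
        raise ValueError("need at least 2 C-alpha atoms")
    return float(pdist(model.coords(ca)).max())


def fetch_pdb(accession: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry (e.g. 5ORM, 5ORQ) from RCSB for validation runs.

    Requires network access; the analysis functions themselves only read
    local files.
    """
    dest = Path(dest_dir) / f"{accession.lower()}.pdb"
    url = f"https://files.rcsb.org/download/{accession.upper()}.pdb"
    with urllib.request.urlopen(url) as r:
        dest.write_bytes(r.read())
    return dest
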