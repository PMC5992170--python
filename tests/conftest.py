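"""Shared fixtures: designs, and synthetic coordinate files.

The structure fixtures are synthetic: minimal PDB models built
programmatically to embody the geometries the structural metrics measure
(inter-repeat side-chain hydrogen bonds, C-alpha extent).  They are not
deposited coordinates.
"""

from __future__ import annotations

import pytest

from cppr import build_design
from cppr.scaffold import global_residue_index

TELO1_TARGET = "TTAGGGTTAG"


@pytest.fixture(scope="session")
def telo1_design():
    """A 10-repeat design against one phase of the telomeric repeat."""
    return build_design(TELO1_TARGET, name="telo1")


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    b: float = 20.0,
    element: str | None = None,
    altloc: str = " ",
    record: str = "ATOM",
) -> str:
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def solenoid_model(
    n_repeats: int = 10,
    extent: float = 104.0,
    broken_arg16_glu19_repeats: tuple[int, ...] = (),
    cap_len: int = 4,
) -> list[str]:
    """Synthetic cPPR solenoid skeleton.

    Per repeat: an Arg16 (CA + NH1), Glu18/Glu19/Glu26 (OE1) and Lys28 (NZ)
    laid out so every junction bond of the inter-repeat network is present
    at 2.9 A, except the Arg16-Glu19 bonds of ``broken_arg16_glu19_repeats``
    whose glutamate is displaced out of range.  Repeat CA atoms span
    ``extent`` Angstrom end to end.
    """
    dz = extent / (n_repeats - 1)
    lines = []
    serial = 1

    def add(name, resname, resnum, x, y, z):
        nonlocal serial
        lines.append(pdb_atom_line(serial, name, resname, "A", resnum, x, y, z))
        serial += 1

    for r in range(1, n_repeats + 1):
        zr = (r - 1) * dz
        arg16 = global_residue_index(r, 16, cap_len)
        add("CA", "ARG", arg16, 0.0, 0.0, zr)
        add("NH1", "ARG", arg16, 3.0, 0.0, zr)
        glu19_x = 3.0 + (9.0 if r in broken_arg16_glu19_repeats else 2.9)
        add("OE1", "GLU", global_residue_index(r, 19, cap_len), glu19_x, 0.0, zr)
        if r < n_repeats:  # Glu18(r) hydrogen-bonds Arg16(r+1)
            add("OE1", "GLU", global_residue_index(r, 18, cap_len), 3.0, 2.9, zr + dz)
            add("NZ", "LYS", global_residue_index(r, 28, cap_len), 10.0, 0.0, zr)
        if r > 1:  # Glu26(r) hydrogen-bonds Lys28(r-1)
            add("OE1", "GLU", global_residue_index(r, 26, cap_len), 10.0, 2.9, zr - dz)
    return lines


@pytest.fixture()
def apo_model_path(tmp_path):
    return write_pdb(tmp_path / "synthetic_apo.pdb", solenoid_model(extent=104.0))


@pytest.fixture()
def bound_model_path(tmp_path):
    lines = solenoid_model(extent=64.0, broken_arg16_glu19_repeats=(4, 6, 9))
    # a short ssDNA ligand and waters, for polymer classification
    serial = 900
    for i, (name, resname, resnum) in enumerate(
        [("P", "DT", 1), ("O5'", "DT", 1), ("N1", "DA", 2), ("O", "HOH", 501)]
    ):
        lines.append(
            pdb_atom_line(serial + i, name, resname, "B", resnum, 30.0 + 5 * i, 30.0, 0.0,
                          record="HETATM" if resname == "HOH" else "ATOM")
        )
    return write_pdb(tmp_path / "synthetic_bound.pdb", lines)
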