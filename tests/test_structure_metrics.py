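"""Coordinate parsing, hydrogen-bond detection and solenoid geometry.

All models here are synthetic, built in conftest; they encode the
geometries being measured, not deposited coordinates.
"""

import itertools
import math

import numpy as np
import pytest

from cppr.structure_metrics import (
    compare_networks,
    count_atoms,
    find_hbonds,
    junction_networks,
    read_structure,
    superhelix_length,
)
from conftest import pdb_atom_line, solenoid_model, write_pdb


def toy_model(tmp_path, lines, name="toy.pdb"):
    return read_structure(write_pdb(tmp_path / name, lines))


def drop_residue(lines, resname, resnum):
    return [l for l in lines
            if not (l[17:20].strip() == resname and l[22:26].strip() == str(resnum))]


class TestReadStructure:
    def test_three_atom_file(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0, 0),
            pdb_atom_line(3, "C", "ALA", "A", 1, 2.5, 1, 0),
        ])
        assert len(model) == 3
        assert model.atoms[0].polymer_class == "protein"

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0, occ=0.6, altloc="A"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 5, 0, 0, occ=0.4, altloc="B"),
        ])
        assert len(model) == 1
        assert model.atoms[0].pos[0] == pytest.approx(0.0)

    def test_altloc_tie_broken_by_first_label(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "CA", "ALA", "A", 1, 5, 0, 0, occ=0.5, altloc="B"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 0, 0, 0, occ=0.5, altloc="A"),
        ])
        assert model.atoms[0].altloc == "A"

    def test_polymer_classification(self, bound_model_path):
        model = read_structure(bound_model_path)
        classes = {a.polymer_class for a in model.atoms}
        assert {"protein", "dna", "water"} <= classes


class TestCountAtoms:
    def test_counts_by_class(self, bound_model_path):
        model = read_structure(bound_model_path)
        assert count_atoms(model, "dna") == 3
        assert count_atoms(model, "water") == 1
        assert count_atoms(model, "protein") == len(model) - 4

    def test_invariant_to_record_order(self, tmp_path):
        lines = solenoid_model(n_repeats=4, extent=30)
        model_a = toy_model(tmp_path, lines, "a.pdb")
        model_b = toy_model(tmp_path, lines[::-1], "b.pdb")
        assert count_atoms(model_a, "protein") == count_atoms(model_b, "protein")

    def test_unknown_class_rejected(self, tmp_path):
        model = toy_model(tmp_path, [pdb_atom_line(1, "CA", "ALA", "A", 1, 0, 0, 0)])
        with pytest.raises(ValueError, match="polymer class"):
            count_atoms(model, "lipid")


class TestFindHbonds:
    def test_pair_below_cutoff(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "O", "GLY", "A", 2, 2.9, 0, 0),
        ])
        (bond,) = find_hbonds(model)
        assert bond.distance == pytest.approx(2.9)
        assert bond.donor.element == "N"

    def test_pair_above_default_cutoff_needs_wider_setting(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "OG1", "THR", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "N1", "DA", "B", 1, 3.7, 0, 0),
        ])
        assert find_hbonds(model, cutoff=3.5) == []
        assert len(find_hbonds(model, cutoff=4.0)) == 1

    def test_same_residue_and_covalent_range_excluded(self, tmp_path):
        model = toy_model(tmp_path, [
            pdb_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0),
            pdb_atom_line(2, "O", "ALA", "A", 1, 2.9, 0, 0),  # same residue
            pdb_atom_line(3, "O", "GLY", "A", 2, -1.4, 0, 0),  # covalent range
        ])
        assert find_hbonds(model) == []

    def test_agrees_with_bruteforce_all_pairs(self, tmp_path):
        rng = np.random.default_rng(17)
        lines, serial = [], 1
        for res in range(1, 81):
            x, y, z = rng.uniform(0, 25, 3)
            for name in ("N", "O"):
                lines.append(pdb_atom_line(serial, name, "GLY", "A", res,
                                           round(x + serial % 3, 3), round(y, 3), round(z, 3)))
                serial += 1
        model = toy_model(tmp_path, lines)
        got = {(h.donor.ref(), h.acceptor.ref(), h.distance) for h in find_hbonds(model)}
        want = set()
        for a, b in itertools.combinations(model.atoms, 2):
            if (a.chain, a.res_num) == (b.chain, b.res_num):
                continue
            d = math.dist(a.pos, b.pos)
            if 2.2 <= d <= 3.5:
                if b.element == "N" and a.element == "O":
                    a, b = b, a
                want.add((a.ref(), b.ref(), round(d, 2)))
        assert got == want


class TestJunctions:
    def test_apo_network_fully_present(self, apo_model_path):
        net = junction_networks(read_structure(apo_model_path), n_repeats=10)
        assert len(net.junctions) == 9
        assert all(f.arg16_glu19 for f in net.junctions)
        assert all(f.arg16_glu18 for f in net.junctions)
        assert all(f.lys28_glu26 for f in net.junctions)

    def test_bound_network_broken_at_designed_junctions(self, bound_model_path):
        net = junction_networks(read_structure(bound_model_path), n_repeats=10)
        broken = [j + 1 for j, f in enumerate(net.junctions) if f.arg16_glu19 is False]
        # glutamates of repeats 4, 6 and 9 displaced -> junctions 3, 5, 8
        assert broken == [3, 5, 8]

    def test_displaced_glutamates_lose_all_bonds(self, tmp_path):
        lines = solenoid_model(n_repeats=4, extent=30,
                               broken_arg16_glu19_repeats=(2, 3, 4))
        net = junction_networks(toy_model(tmp_path, lines), n_repeats=4)
        assert [f.arg16_glu19 for f in net.junctions] == [False, False, False]

    def test_missing_residue_flags_indeterminate(self, tmp_path):
        # drop Glu19 of repeat 2 (residue 4 + 35 + 19 = 58)
        lines = drop_residue(solenoid_model(n_repeats=3, extent=20), "GLU", 58)
        net = junction_networks(toy_model(tmp_path, lines), n_repeats=3)
        assert net.junctions[0].arg16_glu19 is None
        assert net.junctions[1].arg16_glu19 is True


class TestCompare:
    def test_identical_networks_give_zero(self, apo_model_path):
        net = junction_networks(read_structure(apo_model_path), n_repeats=10)
        assert compare_networks(net, net) == (0, [])

    def test_synthetic_pair_rearranged_count(self, apo_model_path, bound_model_path):
        apo = junction_networks(read_structure(apo_model_path), n_repeats=10)
        bound = junction_networks(read_structure(bound_model_path), n_repeats=10)
        n, indet = compare_networks(apo, bound)
        assert (n, indet) == (3, [])

    def test_single_junction_difference(self, tmp_path):
        apo = junction_networks(
            toy_model(tmp_path, solenoid_model(n_repeats=4, extent=30), "a.pdb"), 4)
        bound = junction_networks(
            toy_model(tmp_path, solenoid_model(
                n_repeats=4, extent=30, broken_arg16_glu19_repeats=(3,)), "b.pdb"), 4)
        assert compare_networks(apo, bound) == (1, [])

    def test_indeterminate_junctions_reported_not_counted(self, tmp_path):
        full = solenoid_model(n_repeats=3, extent=20)
        apo = junction_networks(toy_model(tmp_path, full, "a.pdb"), 3)
        bound = junction_networks(toy_model(tmp_path, drop_residue(full, "GLU", 58), "b.pdb"), 3)
        assert compare_networks(apo, bound) == (0, [1])

    def test_junction_count_mismatch_rejected(self, tmp_path):
        a = junction_networks(toy_model(tmp_path, solenoid_model(3, 20), "a.pdb"), 3)
        b = junction_networks(toy_model(tmp_path, solenoid_model(4, 30), "b.pdb"), 4)
        with pytest.raises(ValueError, match="mismatch"):
            compare_networks(a, b)


class TestSuperhelix:
    def test_collinear_extent(self, tmp_path):
        lines = [pdb_atom_line(i + 1, "CA", "GLY", "A", i + 1, 0, 0, float(i))
                 for i in range(65)]
        assert superhelix_length(toy_model(tmp_path, lines)) == pytest.approx(64.0)

    def test_two_atoms(self, tmp_path):
        lines = [pdb_atom_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
                 pdb_atom_line(2, "CA", "GLY", "A", 2, 10, 0, 0)]
        assert superhelix_length(toy_model(tmp_path, lines)) == pytest.approx(10.0)

    def test_compaction_of_synthetic_pair(self, apo_model_path, bound_model_path):
        apo = superhelix_length(read_structure(apo_model_path))
        bound = superhelix_length(read_structure(bound_model_path))
        assert apo == pytest.approx(104.0, abs=0.5)
        assert bound == pytest.approx(64.0, abs=0.5)
        assert bound < apo

    def test_no_calpha_rejected(self, tmp_path):
        model = toy_model(tmp_path, [pdb_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0)])
        with pytest.raises(ValueError, match="C-alpha"):
            superhelix_length(model)
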