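"""Structure reading, alignment mapping, distances, contact statistics,
solvent accessibility, surface patches and superposition."""

import numpy as np
import pytest

from coevnet import structmap, synthdata
from coevnet.coevo import CoevolutionMatrix
from coevnet.errors import FormatError, MappingError
from coevnet.structmap import (
    contact_stats,
    distance_matrix,
    edge_map,
    map_structure,
    read_structure,
    solvent_accessibility,
    superpose_rmsd,
    surface_patches,
)

from conftest import make_alignment


def pdb_line(serial, name, resname, chain, resnum, xyz, occ=1.0, alt=" ",
             element=None):
    element = element or name[0]
    x, y, z = xyz
    return (f"ATOM  {serial:5d}  {name:<3s}{alt}{resname} {chain}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}\n")


@pytest.fixture
def three_residue_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, (0.0, 1.0, 0.0)),
        pdb_line(2, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), element="C"),
        pdb_line(3, "CA", "ARG", "A", 2, (3.0, 4.0, 0.0), element="C"),
        pdb_line(4, "CA", "ASN", "A", 3, (6.0, 8.0, 0.0), element="C"),
    ]
    p.write_text("".join(lines) + "END\n")
    return p


class TestReadStructure:
    def test_minimal_fixture_roundtrip(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        assert len(model) == 3
        assert model.sequence == "ARN"
        assert np.allclose(model.residues[1].ca, [3.0, 4.0, 0.0])

    def test_missing_chain_lists_available(self, three_residue_pdb):
        with pytest.raises(FormatError, match="A"):
            read_structure(three_residue_pdb, chain="B")

    def test_residue_without_ca_excluded(self, tmp_path):
        p = tmp_path / "noca.pdb"
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), element="C"),
            pdb_line(2, "N", "GLY", "A", 2, (1, 1, 1)),
            pdb_line(3, "CA", "ASN", "A", 3, (2, 2, 2), element="C"),
        ]
        p.write_text("".join(lines) + "END\n")
        model = read_structure(p)
        assert model.sequence == "AN"

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        p = tmp_path / "alt.pdb"
        lines = [
            pdb_line(1, "CA", "ALA", "A", 1, (0, 0, 0), occ=0.3, alt="A",
                     element="C"),
            pdb_line(2, "CA", "ALA", "A", 1, (9, 9, 9), occ=0.7, alt="B",
                     element="C"),
            pdb_line(3, "CA", "GLY", "A", 2, (1, 0, 0), element="C"),
        ]
        p.write_text("".join(lines) + "END\n")
        model = read_structure(p)
        assert len(model) == 2
        assert np.allclose(model.residues[0].ca, [9, 9, 9])


class TestMapStructure:
    def test_identical_reference_row_full_coverage(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        aln = make_alignment(["ARN", "ARD"], ids=["mini", "other"])
        rmap = map_structure(aln, model)
        assert len(rmap) == 3
        assert rmap.coverage == pytest.approx(1.0)

    def test_unresolved_residues_drop_columns(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        # alignment has 5 columns; the structure only resolves 3
        aln = make_alignment(["A-RN-", "ACRNE"], ids=["mini", "other"])
        rmap = map_structure(aln, model)
        assert len(rmap) == 3
        assert rmap.coverage == pytest.approx(3 / 5)

    def test_type_mismatch_is_hard_error(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        aln = make_alignment(["RRN", "ARN"], ids=["mini", "other"])
        with pytest.raises(MappingError, match="mismatch"):
            map_structure(aln, model)


class TestDistanceMatrix:
    def test_three_four_five_triangle(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        d = distance_matrix(model)
        assert d[0, 1] == pytest.approx(5.0)
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_translation_invariance(self, three_residue_pdb):
        model = read_structure(three_residue_pdb)
        d0 = distance_matrix(model)
        for r in model.residues:
            r.ca = r.ca + np.array([10.0, -3.0, 7.0])
        assert np.allclose(distance_matrix(model), d0)


class TestContactStats:
    def _uniform(self, n, dist_value):
        V = np.abs(np.random.default_rng(0).normal(size=(n, n)))
        V = (V + V.T) / 2
        D = CoevolutionMatrix(values=V)
        dist = np.full((n, n), dist_value, dtype=float)
        np.fill_diagonal(dist, 0.0)
        mask = np.zeros((n, n), dtype=bool)
        return D, dist, mask

    def test_all_contacts_empty_non_contact_class(self):
        D, dist, mask = self._uniform(6, 5.0)
        st = contact_stats(D, dist, mask)
        assert st.classes["non_contact"]["count"] == 0
        assert st.classes["contact"]["count"] == 15
        assert st.classes["non_contact"]["mean"] is None

    def test_boundary_value_is_non_contact(self):
        D, dist, mask = self._uniform(4, 12.0)
        st = contact_stats(D, dist, mask)
        assert st.classes["contact"]["count"] == 0
        assert st.classes["intermediate"]["count"] == 6

    def test_classes_partition_all_pairs(self):
        rng = np.random.default_rng(2)
        n = 12
        V = rng.normal(size=(n, n))
        D = CoevolutionMatrix(values=(V + V.T) / 2)
        coords = rng.random((n, 3)) * 40
        from scipy.spatial.distance import cdist
        dist = cdist(coords, coords)
        mask = np.zeros((n, n), dtype=bool)
        st = contact_stats(D, dist, mask)
        total = (st.classes["contact"]["count"]
                 + st.classes["intermediate"]["count"]
                 + st.classes["long_range"]["count"])
        assert total == n * (n - 1) // 2
        assert st.classes["non_contact"]["count"] == total - \
            st.classes["contact"]["count"]

    def test_planted_contacts_score_higher(self):
        """Coupled pairs placed < 12 A apart versus noise pairs > 20 A:
        the contact class shows the higher mean correlation."""
        n = 30
        V = np.zeros((n, n))
        contacts = [(0, 5), (1, 6), (2, 7)]
        for i, j in contacts:
            V[i, j] = V[j, i] = 2.0
        V += 0.01
        D = CoevolutionMatrix(values=(V + V.T) / 2)
        dist = np.full((n, n), 30.0)
        np.fill_diagonal(dist, 0.0)
        for i, j in contacts:
            dist[i, j] = dist[j, i] = 8.0
        mask = V > 1.0
        st = contact_stats(D, dist, mask)
        assert st.classes["contact"]["mean"] > st.classes["non_contact"]["mean"]
        assert st.classes["contact"]["F"] == pytest.approx(1.0)


class TestSolventAccessibility:
    def test_isolated_atom_closed_form(self):
        res = structmap.Residue(
            chain="A", number=1, aa="A", ca=np.zeros(3),
            atoms=[structmap.Atom(name="CA", element="C", coord=np.zeros(3))])
        model = structmap.StructureModel(residues=[res])
        area = solvent_accessibility(model, n_points=2000)[0]
        r = structmap.VDW_RADII["C"] + 1.4
        assert area == pytest.approx(4 * np.pi * r ** 2, rel=0.01)

    def test_distant_atoms_additive(self):
        def residue(x, num):
            c = np.array([x, 0.0, 0.0])
            return structmap.Residue(
                chain="A", number=num, aa="A", ca=c,
                atoms=[structmap.Atom(name="CA", element="C", coord=c)])
        model = structmap.StructureModel(residues=[residue(0, 1),
                                                   residue(100, 2)])
        areas = solvent_accessibility(model, n_points=1000)
        assert areas[0] == pytest.approx(areas[1], rel=1e-6)
        r = structmap.VDW_RADII["C"] + 1.4
        assert areas.sum() == pytest.approx(2 * 4 * np.pi * r ** 2, rel=0.01)

    def test_overlapping_atoms_occlude(self):
        def residue(x, num):
            c = np.array([x, 0.0, 0.0])
            return structmap.Residue(
                chain="A", number=num, aa="A", ca=c,
                atoms=[structmap.Atom(name="CA", element="C", coord=c)])
        model = structmap.StructureModel(residues=[residue(0, 1),
                                                   residue(1.0, 2)])
        areas = solvent_accessibility(model, n_points=1000)
        r = structmap.VDW_RADII["C"] + 1.4
        assert areas.sum() < 2 * 4 * np.pi * r ** 2 * 0.99

    def test_point_density_convergence(self):
        helix, _ = synthdata.generate_structure(10)
        a1 = solvent_accessibility(helix, n_points=1000)
        a2 = solvent_accessibility(helix, n_points=2000)
        assert np.abs(a1 - a2).max() / a2.max() < 0.02


class TestSurfacePatches:
    def test_constant_profiles_have_no_patches(self):
        assert surface_patches(np.ones(20), np.ones(20)) == []

    def test_planted_run_found(self):
        cons = np.zeros(20)
        acc = np.zeros(20)
        cons[5:11] = 1.0
        acc[5:11] = 1.0
        patches = surface_patches(cons, acc)
        assert len(patches) == 1
        assert (patches[0].start, patches[0].end) == (6, 11)
        assert patches[0].length == 6

    @pytest.mark.parametrize("run_len, expected", [(4, 0), (5, 1)])
    def test_length_boundary(self, run_len, expected):
        cons = np.zeros(30)
        acc = np.zeros(30)
        cons[10:10 + run_len] = 1.0
        acc[10:10 + run_len] = 1.0
        assert len(surface_patches(cons, acc)) == expected


class TestSuperposition:
    def test_self_superposition_zero(self):
        X = np.random.default_rng(1).random((6, 3)) * 10
        assert superpose_rmsd(X, X) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self):
        from scipy.spatial.transform import Rotation
        X = np.random.default_rng(2).random((8, 3)) * 10
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True)
        Y = R.apply(X) + np.array([5.0, -2.0, 9.0])
        assert superpose_rmsd(X, Y) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 3)) * 10
        Y = X + rng.normal(scale=0.5, size=X.shape)
        assert superpose_rmsd(X, Y) == pytest.approx(superpose_rmsd(Y, X),
                                                     abs=1e-9)

    def test_fewer_than_three_points_rejected(self):
        X = np.zeros((2, 3))
        with pytest.raises(ValueError):
            superpose_rmsd(X, X)


class TestEdgeMap:
    def _setup(self, n=6):
        rng = np.random.default_rng(5)
        V = np.abs(rng.normal(size=(n, n)))
        V = (V + V.T) / 2
        D = CoevolutionMatrix(values=V)
        seq = "ARNDEG"[:n]
        model, _ = synthdata.generate_structure(n, sequence=seq)
        aln = make_alignment([seq, seq.replace("A", "G", 1)],
                             ids=["synthetic-helix", "other"])
        rmap = map_structure(aln, model)
        dist = distance_matrix(model, rmap)
        return D, rmap, dist

    def test_empty_mask_empty_frame(self):
        D, rmap, dist = self._setup()
        frame = edge_map(D, np.zeros((6, 6), dtype=bool), rmap, dist)
        assert frame.empty

    def test_edge_count_matches_mask_popcount(self):
        D, rmap, dist = self._setup()
        mask = D.values > np.nanmedian(D.values)
        frame = edge_map(D, mask, rmap, dist)
        assert len(frame) == mask.sum() // 2

    def test_edge_annotations(self):
        D, rmap, dist = self._setup()
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 3] = mask[3, 0] = True
        frame = edge_map(D, mask, rmap, dist)
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row["res_i"] == "A1"
        assert row["res_j"] == "D4"
        assert row["dist_A"] == pytest.approx(dist[0, 3])
        assert row["class"] == "contact"
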