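import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pharmdock.core_chem import Atom, Bond, FeatureType, MolecularGraph
from pharmdock.protein_pharm import (BindingSiteBox, PharmGenConfig,
                                     build_forbidden, build_models,
                                     cluster_directional_field,
                                     cluster_hydrophobic_field,
                                     define_binding_site, read_model,
                                     score_grid, write_model)


def single_atom_ligand(pos=(0.0, 0.0, 0.0)):
    return MolecularGraph([Atom("C", np.array(pos))], [], "ref")


def carbonyl_receptor():
    """One carbonyl-like acceptor: O at origin, anchor C along -x."""
    atoms = [Atom("O", np.array([0.0, 0.0, 0.0])),
             Atom("C", np.array([-1.23, 0.0, 0.0]))]
    return MolecularGraph(atoms, [Bond(0, 1, order=2.0)], "carbonyl")


class TestBindingSite:
    def test_point_expansion(self):
        box = define_binding_site(carbonyl_receptor(), single_atom_ligand())
        np.testing.assert_allclose(box.min_corner, [-3, -3, -3])
        np.testing.assert_allclose(box.max_corner, [3, 3, 3])

    def test_two_atom_bbox(self):
        atoms = [Atom("C", np.zeros(3)), Atom("C", np.array([4.0, 0, 0]))]
        ref = MolecularGraph(atoms, [Bond(0, 1)], "ref")
        box = define_binding_site(carbonyl_receptor(), ref)
        np.testing.assert_allclose(box.min_corner, [-3, -3, -3])
        np.testing.assert_allclose(box.max_corner, [7, 3, 3])

    def test_explicit_box_identity(self):
        box = BindingSiteBox(np.zeros(3), np.ones(3))
        assert define_binding_site(carbonyl_receptor(), box) is box

    def test_invalid_box(self):
        with pytest.raises(ValueError):
            BindingSiteBox(np.ones(3), np.zeros(3))


class TestGridFields:
    def test_donor_field_minimum_on_lone_pair_axis(self):
        """The most favorable donor-probe position sits ~1.85 A from the
        acceptor along the carbonyl axis; checked against a dense 0.05 A scan."""
        rec = carbonyl_receptor()
        box = BindingSiteBox(np.array([0.5, -1.5, -1.5]), np.array([3.5, 1.5, 1.5]))
        field = score_grid(rec, box, FeatureType.DONOR, spacing=0.05)
        g = field.grid_coords()
        vmin = field.values.min()
        assert vmin < 0
        # every point attaining the optimum lies on the ideal-geometry plateau:
        # 1.85 +/- 0.25 A from the acceptor, within 30 deg of the C=O axis
        plateau = g[field.values == vmin]
        r = np.linalg.norm(plateau, axis=1)
        assert np.all(np.abs(r - 1.85) <= 0.25 + 1e-9)
        cosang = plateau[:, 0] / r
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30.0 + 1e-6)
        # and the ideal point itself attains it (dense scan oracle)
        ideal_idx = np.argmin(np.linalg.norm(g - [1.85, 0.0, 0.0], axis=1))
        assert field.values[ideal_idx] == pytest.approx(vmin, abs=1e-9)

    def test_hydrophobic_support_ends(self):
        rec = MolecularGraph([Atom("C", np.zeros(3))], [], "apolar")
        box = BindingSiteBox(np.array([6.5, -0.2, -0.2]), np.array([8.0, 0.2, 0.2]))
        field = score_grid(rec, box, FeatureType.HYDROPHOBIC, spacing=0.4)
        # whole box beyond r_ideal + 3.0 = 6.4 A: no favorable score anywhere
        assert np.all(field.values == 0.0)

    def test_scores_nonpositive_and_zero_inside_protein(self):
        rec = carbonyl_receptor()
        box = BindingSiteBox(np.array([-2, -2, -2.0]), np.array([4, 2, 2.0]))
        field = score_grid(rec, box, FeatureType.DONOR, spacing=0.4)
        assert np.all(field.values <= 0)
        g = field.grid_coords()
        inside = np.linalg.norm(g - rec.atoms[0].position, axis=1) <= rec.atoms[0].vdw_radius
        assert np.all(field.values[inside] == 0.0)

    def test_field_covariance_under_rotation(self):
        rec = carbonyl_receptor()
        box = BindingSiteBox(np.array([0.5, -1.5, -1.5]), np.array([3.5, 1.5, 1.5]))
        f0 = score_grid(rec, box, FeatureType.DONOR, spacing=0.5)
        # exact 90-degree rotation: a signed permutation keeps distances bitwise
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        rec_r = rec.with_coords(rec.coords @ rot.T)
        box_r = BindingSiteBox(*(np.sort(np.stack([box.min_corner @ rot.T,
                                                   box.max_corner @ rot.T]), axis=0)))
        f1 = score_grid(rec_r, box_r, FeatureType.DONOR, spacing=0.5)
        # same multiset of values after a 90 degree rotation of the grid
        np.testing.assert_allclose(np.sort(f0.values), np.sort(f1.values), atol=1e-6)


class TestClustering:
    def _blob_field(self, centres, radius=0.61, scale=0.05):
        """Synthetic hydrophobic field with compact steep favorable blobs."""
        from pharmdock.protein_pharm import GridField

        origin = np.array([-6.0, -6.0, -1.0])
        dims = (31, 31, 6)
        field = GridField(0.4, origin, dims, np.zeros(int(np.prod(dims))),
                          FeatureType.HYDROPHOBIC)
        g = field.grid_coords()
        v = np.zeros(len(g))
        for c in centres:
            v -= np.exp(-np.sum((g - c) ** 2, axis=1) / scale) * (np.linalg.norm(g - c, axis=1) < radius)
        field.values = v
        return field

    def test_two_blobs_give_separated_points(self):
        c1, c2 = np.array([-2.8, 0, 0]), np.array([2.8, 0, 0])
        field = self._blob_field([c1, c2])
        pts = cluster_hydrophobic_field(field, cutoff=1.5)
        assert len(pts) >= 2
        g = field.grid_coords()
        for c in (c1, c2):
            mask = (np.linalg.norm(g - c, axis=1) < 0.61) & (field.values < 0)
            w = -field.values[mask]
            centroid = np.average(g[mask], axis=0, weights=w)
            assert min(np.linalg.norm(p.position - centroid) for p in pts) <= 0.2

    def test_single_favorable_point(self):
        from pharmdock.protein_pharm import GridField

        field = GridField(0.4, np.zeros(3), (3, 3, 3), np.zeros(27), FeatureType.HYDROPHOBIC)
        field.values[13] = -1.0
        pts = cluster_hydrophobic_field(field, cutoff=1.5)
        assert len(pts) == 1
        np.testing.assert_allclose(pts[0].position, field.grid_coords()[13], atol=1e-12)
        assert pts[0].weight == pytest.approx(1.0)

    def test_no_favorable_points_empty(self):
        from pharmdock.protein_pharm import GridField

        field = GridField(0.4, np.zeros(3), (3, 3, 3), np.zeros(27), FeatureType.HYDROPHOBIC)
        assert cluster_hydrophobic_field(field, cutoff=1.5) == []

    def test_directional_patches_use_nearest_site(self):
        from pharmdock.protein_pharm import GridField

        field = GridField(0.4, np.array([-5.0, -0.4, -0.4]), (26, 3, 3),
                          np.zeros(26 * 9), FeatureType.DONOR)
        g = field.grid_coords()
        sites = np.array([[-4.0, 0, 0], [4.0, 0, 0]])
        v = np.zeros(len(g))
        for s in sites:
            v -= (np.linalg.norm(g - s, axis=1) < 1.2).astype(float)
        field.values = v
        pts = cluster_directional_field(field, sites, cutoff=2.0)
        assert pts
        for p in pts:
            d = np.linalg.norm(sites - p.position, axis=1)
            assert p.patch_id == int(np.argmin(d))

    def test_cutoff_monotonicity(self):
        field = self._blob_field([np.array([-2.8, 0, 0]), np.array([2.8, 0, 0]),
                                  np.array([0.0, 2.8, 0])])
        n_fine = len(cluster_hydrophobic_field(field, cutoff=1.0))
        n_coarse = len(cluster_hydrophobic_field(field, cutoff=2.0))
        assert n_fine >= n_coarse

    def test_clustering_deterministic(self):
        field = self._blob_field([np.array([-2.8, 0, 0]), np.array([2.8, 0, 0])])
        a = cluster_hydrophobic_field(field, cutoff=1.5)
        b = cluster_hydrophobic_field(field, cutoff=1.5)
        assert len(a) == len(b)
        for p, q in zip(a, b):
            np.testing.assert_array_equal(p.position, q.position)
            assert p.weight == q.weight


class TestForbidden:
    def test_within_vdw_only(self):
        rec = MolecularGraph([Atom("C", np.zeros(3))], [], "apolar")
        box = BindingSiteBox(-2 * np.ones(3), 2 * np.ones(3))
        pts = build_forbidden(rec, box, spacing=0.4)
        d = np.linalg.norm(pts, axis=1)
        assert len(pts) > 0
        assert np.all(d <= 1.7 + 1e-12)

    def test_empty_far_region(self):
        rec = MolecularGraph([Atom("C", np.array([50.0, 0, 0]))], [], "apolar")
        box = BindingSiteBox(-2 * np.ones(3), 2 * np.ones(3))
        assert len(build_forbidden(rec, box, spacing=0.4)) == 0

    def test_density_monotone_in_spacing(self):
        rec = MolecularGraph([Atom("C", np.zeros(3))], [], "apolar")
        box = BindingSiteBox(-2 * np.ones(3), 2 * np.ones(3))
        coarse = build_forbidden(rec, box, spacing=0.8)
        fine = build_forbidden(rec, box, spacing=0.4)
        assert len(fine) > len(coarse)


class TestModels:
    def test_sampling_model_types_restricted(self, toy):
        allowed = {FeatureType.DONOR, FeatureType.ACCEPTOR, FeatureType.HYDROPHOBIC}
        assert {p.type for p in toy.sampling_model.points} <= allowed

    def test_sampling_has_polar_and_hydrophobic(self, toy):
        types = {p.type for p in toy.sampling_model.points}
        assert FeatureType.DONOR in types
        assert FeatureType.HYDROPHOBIC in types

    def test_ranking_denser_than_sampling(self, toy):
        assert len(toy.ranking_model.points) >= len(toy.sampling_model.points)

    def test_points_inside_box(self, toy):
        lo = toy.box.min_corner - toy.config.spacing
        hi = toy.box.max_corner + toy.config.spacing
        for model in (toy.sampling_model, toy.ranking_model):
            for p in model.points:
                assert np.all(p.position >= lo) and np.all(p.position <= hi)

    def test_points_outside_protein_vdw(self, toy):
        heavy = toy.receptor.heavy_indices()
        coords = toy.receptor.coords[heavy]
        radii = np.array([toy.receptor.atoms[i].vdw_radius for i in heavy])
        for p in toy.ranking_model.points:
            d = np.linalg.norm(coords - p.position, axis=1)
            assert np.all(d > radii - 1e-9)

    def test_model_file_round_trip(self, toy, tmp_path):
        path = tmp_path / "model.txt"
        write_model(toy.sampling_model, path)
        back = read_model(path)
        assert back.density_label == "sampling"
        assert len(back.points) == len(toy.sampling_model.points)
        assert len(back.forbidden) == len(toy.sampling_model.forbidden)
        for a, b in zip(toy.sampling_model.points, back.points):
            assert a.type == b.type
            np.testing.assert_allclose(a.position, b.position, atol=5e-5)
            assert b.patch_id == a.patch_id
        # a second round trip is bit-exact
        path2 = tmp_path / "model2.txt"
        write_model(back, path2)
        assert path.read_text() == path2.read_text()
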