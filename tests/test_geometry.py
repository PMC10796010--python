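"""Superposition, RMSD/RMSF, Rg, helix axes, crossing angles, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from histonefold import geometry as geo
from histonefold.structio import SegmentSpec
from histonefold.synthetic_data import make_ideal_helix, make_two_helix_dimer

from oracles import grid_search_rmsd


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


class TestKabsch:
    def test_exact_recovery_of_rigid_transform(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        Y = X @ R.T + np.array([1.0, 2.0, 3.0])
        sup = geo.superpose_kabsch(X, Y)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, R, atol=1e-9)
        np.testing.assert_allclose(geo.apply_superposition(X, sup), Y, atol=1e-9)

    def test_agrees_with_rotation_grid_oracle(self):
        target = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        mobile = target.copy()
        mobile[2] = [0.0, 1.0, 1.0]
        fast = geo.superpose_kabsch(mobile, target).rmsd
        brute = grid_search_rmsd(mobile, target)
        assert fast == pytest.approx(brute, abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_five_point_sets_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mobile = rng.normal(size=(5, 3))
        target = rng.normal(size=(5, 3))
        fast = geo.superpose_kabsch(mobile, target).rmsd
        brute = grid_search_rmsd(mobile, target)
        assert fast <= brute + 1e-9  # grid can never beat the optimum
        assert fast == pytest.approx(brute, abs=1e-3)

    def test_mirror_image_of_chiral_set_not_matched(self):
        chiral = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        mirror = chiral * np.array([1.0, 1.0, -1.0])
        sup = geo.superpose_kabsch(mirror, chiral)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.1  # det=-1 solution would give 0

    def test_symmetry_and_determinant(self):
        rng = np.random.default_rng(4)
        A, B = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        ab = geo.superpose_kabsch(A, B)
        ba = geo.superpose_kabsch(B, A)
        assert ab.rmsd == pytest.approx(ba.rmsd, abs=1e-9)
        assert np.linalg.det(ab.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(7)
        A, B = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        base = geo.superpose_kabsch(A, B).rmsd
        for seed in range(5):
            R, t = random_rigid(seed)
            assert geo.superpose_kabsch(A @ R.T + t, B).rmsd == pytest.approx(
                base, abs=1e-9)

    def test_collinear_target_still_proper_and_valid(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        tilted = line @ Rotation.from_euler("y", 30, degrees=True).as_matrix().T
        sup = geo.superpose_kabsch(line, tilted)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            geo.superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_identical_and_rotated_frames_give_zero(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(9, 3))
        frames = [ref.copy()]
        for seed in range(3):
            R, t = random_rigid(seed)
            frames.append(ref @ R.T + t)
        np.testing.assert_allclose(geo.rmsd_series(frames, ref), 0.0, atol=1e-9)

    def test_single_displaced_atom_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(scale=8.0, size=(30, 3))
        frame = ref.copy()
        d = 2.0
        frame[4] += [0.0, 0.0, d]
        rmsd = geo.rmsd_series([frame], ref)[0]
        assert 0.0 < rmsd <= d
        # independent check: optimal rmsd via the rotation-grid oracle
        assert rmsd == pytest.approx(grid_search_rmsd(frame, ref), abs=1e-3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            geo.rmsd_series([np.zeros((4, 3))], np.zeros((5, 3)))


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        ref = np.random.default_rng(0).normal(size=(6, 3))
        assert np.allclose(geo.rmsf_profile([ref] * 4), 0.0)

    def test_rigidly_tumbling_body_has_zero_rmsf(self):
        ref = np.random.default_rng(1).normal(scale=4.0, size=(7, 3))
        frames = []
        for seed in range(6):
            R, t = random_rigid(seed)
            frames.append(ref @ R.T + t)
        assert np.all(geo.rmsf_profile(frames, align_to="mean") < 1e-9)

    def test_isotropic_gaussian_jitter_closed_form(self):
        # per-coordinate std s -> RMSF = s * sqrt(3); the rigid-body fit
        # absorbs 6 of the 3N fluctuation degrees of freedom, so enough
        # residues are needed for the closed form to hold within 5%
        rng = np.random.default_rng(3)
        ref = rng.normal(scale=20.0, size=(60, 3))
        s = 0.3
        frames = [ref + rng.normal(0.0, s, ref.shape) for _ in range(10_000)]
        profile = geo.rmsf_profile(frames, align_to="mean")
        np.testing.assert_allclose(profile, s * np.sqrt(3), rtol=0.05)

    def test_jitter_localized_to_one_residue(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(scale=15.0, size=(8, 3))
        frames = []
        for _ in range(200):
            f = ref.copy()
            f[5] += rng.normal(0.0, 0.5, 3)
            frames.append(f)
        profile = geo.rmsf_profile(frames, align_to="first")
        # the rigid-body fit redistributes a little of the displacement onto
        # the other residues, but the jittered one must stand clearly out
        assert np.argmax(profile) == 5
        assert profile[5] > 2 * np.delete(profile, 5).max()

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            geo.rmsf_profile([np.zeros((4, 3))])


class TestRadiusOfGyration:
    def test_two_points_two_angstroms_apart(self):
        assert geo.radius_of_gyration([[0, 0, 0], [2, 0, 0]]) == pytest.approx(1.0)

    def test_equilateral_triangle_analytic(self):
        a = 3.0
        tri = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0]])
        assert geo.radius_of_gyration(tri) == pytest.approx(a / np.sqrt(3))

    def test_direct_summation_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(scale=6.0, size=(50, 3))
        w = rng.uniform(1.0, 3.0, size=50)
        com = (w[:, None] * X).sum(0) / w.sum()
        direct = np.sqrt(sum(wi * ((xi - com) ** 2).sum() for wi, xi in zip(w, X))
                         / w.sum())
        assert geo.radius_of_gyration(X, w) == pytest.approx(direct, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 3))
        base = geo.radius_of_gyration(X)
        R, t = random_rigid(9)
        assert geo.radius_of_gyration(X @ R.T + t) == pytest.approx(base, abs=1e-9)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            geo.radius_of_gyration(np.zeros((3, 3)), [-1.0, 1.0, 1.0])


class TestHelixAxis:
    def test_straight_line_along_x(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        axis = geo.fit_helix_axis(pts)
        np.testing.assert_allclose(axis.direction, [1, 0, 0], atol=1e-12)
        assert axis.fit_rms == pytest.approx(0.0, abs=1e-12)

    def test_ideal_helix_axis_recovered(self):
        coords = make_ideal_helix(12, (0.0, 0.0, 1.0))
        axis = geo.fit_helix_axis(coords)
        assert np.degrees(np.arccos(np.clip(axis.direction @ [0, 0, 1], -1, 1))) < 2.0

    def test_reversed_traversal_flips_direction(self):
        coords = make_ideal_helix(12, (0.0, 0.0, 1.0))
        axis = geo.fit_helix_axis(coords[::-1])
        assert np.degrees(np.arccos(np.clip(axis.direction @ [0, 0, -1], -1, 1))) < 2.0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            geo.fit_helix_axis(np.ones((5, 3)))


class TestInterhelixAngle:
    def _axis(self, v):
        return geo.HelixAxis(np.zeros(3), np.asarray(v, float), None, 0.0)

    def test_parallel_and_antiparallel(self):
        u = self._axis([0, 0, 1.0])
        assert geo.interhelix_angle(u, u) == pytest.approx(0.0)
        assert geo.interhelix_angle(u, self._axis([0, 0, -1.0])) == pytest.approx(180.0)

    @pytest.mark.parametrize("angle", [0.0, 40.0, 60.0, 140.0, 180.0])
    def test_synthetic_bundle_angle_recovered(self, angle):
        dimer = make_two_helix_dimer(angle, n_res=20)
        measured = geo.crossing_angle(
            dimer, SegmentSpec("A", 1, 20), SegmentSpec("B", 1, 20))
        assert measured == pytest.approx(angle, abs=2.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_flip_complementarity_property(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=3)
        v = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        theta = geo.interhelix_angle(self._axis(u), self._axis(v))
        flipped = geo.interhelix_angle(self._axis(u), self._axis(-v))
        assert 0.0 <= theta <= 180.0
        assert flipped == pytest.approx(180.0 - theta, abs=1e-9)

    def test_endpoint_mode_available(self):
        dimer = make_two_helix_dimer(60.0, n_res=20)
        measured = geo.crossing_angle(
            dimer, SegmentSpec("A", 1, 20), SegmentSpec("B", 1, 20),
            mode="endpoints")
        assert measured == pytest.approx(60.0, abs=5.0)


class TestPairwiseAndClustering:
    def test_duplicate_and_rotated_frames_zero_matrix(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 3))
        R, t = random_rigid(3)
        M = geo.pairwise_rmsd_matrix([X, X.copy(), X @ R.T + t])
        np.testing.assert_allclose(M, 0.0, atol=1e-9)

    def test_matrix_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(9)
        frames = [rng.normal(size=(5, 3)) for _ in range(4)]
        M = geo.pairwise_rmsd_matrix(frames)
        assert np.allclose(M, M.T) and np.allclose(np.diag(M), 0.0)
        for i in range(4):
            for j in range(4):
                if i != j:
                    expected = geo.superpose_kabsch(frames[i], frames[j]).rmsd
                    assert M[i, j] == pytest.approx(expected, abs=1e-9)

    def test_all_zero_matrix_is_one_cluster(self):
        result = geo.cluster_conformations(np.zeros((5, 5)), cutoff=4.0)
        assert len(set(result.labels)) == 1

    def test_planted_two_group_partition(self):
        rng = np.random.default_rng(10)
        base = rng.normal(scale=5.0, size=(10, 3))
        groups = [base + rng.normal(0.0, 0.2, base.shape) for _ in range(4)]
        shifted = base + rng.normal(0.0, 8.0, base.shape)
        groups += [shifted + rng.normal(0.0, 0.2, base.shape) for _ in range(4)]
        M = geo.pairwise_rmsd_matrix(groups)
        result = geo.cluster_conformations(M, cutoff=5.0)
        labels = result.labels
        assert len(set(labels)) == 2
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        for lab, medoid in result.medoids.items():
            assert labels[medoid] == lab

    def test_singletons_below_min_distance(self):
        rng = np.random.default_rng(11)
        frames = [rng.normal(scale=20.0, size=(8, 3)) + 100 * k * np.array([1, 0, 0])
                  for k in range(5)]
        M = geo.pairwise_rmsd_matrix(frames)
        result = geo.cluster_conformations(M, cutoff=0.9 * M[M > 0].min())
        assert len(set(result.labels)) == 5

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            geo.cluster_conformations(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            geo.cluster_conformations(-np.ones((3, 3)) + np.eye(3))
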