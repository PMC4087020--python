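"""Gyration anisotropy, radial structure and SDS orientation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from micellemix.cgmodel import Frame, SystemTopology, Trajectory
from micellemix.shape import (
    gyration_anisotropy,
    orientation_angles,
    radial_profile,
    shape_by_size,
)


def single_frame_traj(frame):
    return Trajectory([frame])


def radial_sds_micelle(directions, radii=(4.5, 8.5, 12.5, 16.5),
                       center=(50.0, 50.0, 50.0), box=100.0, extra=()):
    """SDS molecules laid out radially: C4 innermost, SO3 outermost."""
    kinds = ["SDS"] * len(directions) + [k for k, _ in extra]
    top = SystemTopology(kinds)
    blocks = []
    for u in directions:
        u = np.asarray(u, float)
        u /= np.linalg.norm(u)
        blocks.append(np.asarray(center) + np.outer(radii, u))
    for _, pos in extra:
        blocks.append(np.atleast_2d(pos))
    return Frame(top, np.concatenate(blocks), box=box, time_us=1.0)


def antipodal_directions(n_pairs, rng):
    dirs = rng.normal(size=(n_pairs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.concatenate([dirs, -dirs])


class TestGyrationAnisotropy:
    def test_collinear_beads_are_linear(self):
        pts = np.outer(np.arange(5, dtype=float), [1.0, 2.0, -0.5])
        assert gyration_anisotropy(pts).k2 == pytest.approx(1.0)

    def test_tetrahedron_is_spherically_symmetric(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        assert gyration_anisotropy(pts).k2 == pytest.approx(0.0, abs=1e-12)

    def test_planar_moments_2_1_0(self):
        # points chosen so the principal moments are exactly (2, 1, 0)
        a, b = 2.0, np.sqrt(2.0)
        pts = np.array([[a, 0, 0], [-a, 0, 0], [0, b, 0], [0, -b, 0]])
        g = gyration_anisotropy(pts)
        assert (g.lambda_x, g.lambda_y, g.lambda_z) == pytest.approx((2, 1, 0))
        assert g.k2 == pytest.approx(1 / 3)

    def test_degenerate_point_reports_zero(self):
        assert gyration_anisotropy(np.zeros((4, 3))).k2 == 0.0

    def test_invariance_under_rigid_motion_and_scaling(self, rng):
        pts = rng.normal(size=(30, 3)) * [3.0, 1.5, 0.7]
        k2 = gyration_anisotropy(pts).k2
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = 2.7 * pts @ rot.T + rng.uniform(-50, 50, 3)
            assert gyration_anisotropy(moved).k2 == pytest.approx(k2, abs=1e-9)

    def test_bounded_on_random_bead_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            pts = rng.normal(size=(n, 3)) * rng.uniform(0.1, 20, 3)
            assert 0.0 <= gyration_anisotropy(pts).k2 <= 1.0

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            gyration_anisotropy(np.zeros((1, 3)))


class TestShapeBySize:
    def test_spherical_micelles_have_low_k2(self, rng):
        # 40 molecules with beads uniform in a ball: K^2 well below 0.1
        kinds = ["SDS"] * 40
        top = SystemTopology(kinds)
        r = 15.0 * rng.uniform(0, 1, (top.n_beads, 1)) ** (1 / 3)
        u = rng.normal(size=(top.n_beads, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        frame = Frame(top, 50.0 + r * u, box=100.0, time_us=1.0)
        df = shape_by_size(single_frame_traj(frame), window=(0.5, 1.5))
        assert df[df["size"] == 40]["mean_k2"].iloc[0] < 0.1

    def test_rod_aggregate_has_high_k2(self, rng):
        kinds = ["SDS"] * 20
        top = SystemTopology(kinds)
        axis = np.array([1.0, 0, 0])
        pos = (np.outer(np.linspace(0, 100, top.n_beads), axis)
               + rng.normal(scale=1.5, size=(top.n_beads, 3)) + 60.0)
        frame = Frame(top, np.mod(pos, 300.0), box=300.0, time_us=1.0)
        df = shape_by_size(single_frame_traj(frame), cutoff=10.0,
                           window=(0.5, 1.5))
        assert df["mean_k2"].iloc[0] > 0.4

    def test_near_collinear_dimer_is_anisotropic(self):
        kinds = ["SDS", "SDS"]
        top = SystemTopology(kinds)
        line = np.outer(np.arange(8, dtype=float) * 2.5, [1.0, 0, 0])
        frame = Frame(top, line + 20.0, box=100.0, time_us=1.0)
        df = shape_by_size(single_frame_traj(frame), window=(0.5, 1.5))
        assert df[df["size"] == 2]["mean_k2"].iloc[0] > 0.9

    def test_pbc_split_cluster_unwrapped_before_gyration(self):
        # a compact micelle straddling the box corner must not look huge
        kinds = ["SDS"] * 8
        top = SystemTopology(kinds)
        rng = np.random.default_rng(0)
        pos = rng.uniform(-4, 4, (top.n_beads, 3))  # blob centred at origin
        frame = Frame(top, np.mod(pos, 60.0), box=60.0, time_us=1.0)
        df = shape_by_size(single_frame_traj(frame), window=(0.5, 1.5))
        g_direct = gyration_anisotropy(pos)
        assert df["mean_k2"].iloc[0] == pytest.approx(g_direct.k2, abs=1e-9)


class TestRadialProfile:
    def test_planted_shell_peaks_in_correct_bin(self, rng):
        # antipodal placement keeps the COM exactly at the centre
        frame = radial_sds_micelle(antipodal_directions(12, rng))
        rp = radial_profile(single_frame_traj(frame), "SDS", "SO3",
                            window=(0.5, 1.5), min_cluster_size=5)
        assert rp.density.sum() == pytest.approx(1.0)
        assert rp.bin_edges[np.argmax(rp.density)] == 16.0  # bin containing 16.5
        rp_c4 = radial_profile(single_frame_traj(frame), "SDS", "C4",
                               window=(0.5, 1.5), min_cluster_size=5)
        assert rp_c4.bin_edges[np.argmax(rp_c4.density)] == 4.0  # bin containing 4.5

    def test_selector_normalisations_are_independent(self, rng):
        frame = radial_sds_micelle(antipodal_directions(10, rng))
        traj = single_frame_traj(frame)
        for bead in ("C4", "C2", "C1", "SO3"):
            rp = radial_profile(traj, "SDS", bead, window=(0.5, 1.5),
                                min_cluster_size=5)
            assert rp.density.sum() == pytest.approx(1.0)

    def test_unmatched_selector_rejected(self, rng):
        frame = radial_sds_micelle(antipodal_directions(10, rng))
        with pytest.raises(ValueError, match="matched no beads"):
            radial_profile(single_frame_traj(frame), "CA", "OCO",
                           window=(0.5, 1.5), min_cluster_size=5)

    def test_small_clusters_excluded(self, rng):
        frame = radial_sds_micelle(antipodal_directions(4, rng))
        with pytest.raises(ValueError):
            radial_profile(single_frame_traj(frame), "SDS", "SO3",
                           window=(0.5, 1.5), min_cluster_size=20)


class TestOrientationAngles:
    def test_tail_toward_com_is_zero_degrees(self, rng):
        frame = radial_sds_micelle(antipodal_directions(10, rng))
        ap = orientation_angles(single_frame_traj(frame), window=(0.5, 1.5),
                                min_cluster_size=5)
        # C4 sits on the SO3->COM axis, tail inward
        assert np.all(ap.angles < 1e-6)
        assert ap.frequency.sum() == pytest.approx(1.0)

    def test_tail_away_from_com_is_180_degrees(self, rng):
        # inverted layout: SO3 innermost, C4 outermost
        frame = radial_sds_micelle(antipodal_directions(10, rng),
                                   radii=(16.5, 12.5, 8.5, 4.5))
        ap = orientation_angles(single_frame_traj(frame), window=(0.5, 1.5),
                                min_cluster_size=5)
        assert np.all(ap.angles > 180 - 1e-6)

    def test_random_orientations_sin_weighted(self, rng):
        # molecular axes isotropic relative to the radial direction
        n = 400
        dirs = antipodal_directions(n // 2, rng)
        kinds = ["SDS"] * n
        top = SystemTopology(kinds)
        blocks = []
        center = np.array([60.0, 60.0, 60.0])
        for u in dirs:
            so3 = center + 10.0 * u
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            # chain from SO3 toward a random direction: C1, C2, C4
            blocks.append(np.array([so3 + 3 * axis, so3 + 2 * axis,
                                    so3 + 1 * axis, so3]))
        frame = Frame(top, np.concatenate(blocks), box=120.0, time_us=1.0)
        ap = orientation_angles(single_frame_traj(frame), cutoff=7.0,
                                window=(0.5, 1.5), min_cluster_size=50)
        assert ap.angles.mean() == pytest.approx(90.0, abs=6.0)
        # oracle: isotropic angles are arccos(uniform) distributed
        oracle = np.degrees(np.arccos(rng.uniform(-1, 1, 200000)))
        oracle_hist, _ = np.histogram(oracle, bins=ap.bin_edges)
        corr = np.corrcoef(ap.frequency, oracle_hist / oracle_hist.sum())[0, 1]
        assert corr > 0.9

    def test_invariant_under_global_rotation(self, rng):
        frame = radial_sds_micelle(antipodal_directions(10, rng))
        ap = orientation_angles(single_frame_traj(frame), window=(0.5, 1.5),
                                min_cluster_size=5)
        rot = Rotation.random(rng=rng).as_matrix()
        center = np.array([50.0, 50.0, 50.0])
        pos = (frame.positions - center) @ rot.T + center
        rotated = Frame(frame.topology, pos, frame.box, frame.time_us)
        ap2 = orientation_angles(single_frame_traj(rotated), window=(0.5, 1.5),
                                 min_cluster_size=5)
        np.testing.assert_allclose(np.sort(ap2.angles), np.sort(ap.angles),
                                   atol=1e-6)
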