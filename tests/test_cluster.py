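"""Micelle identification and aggregation statistics."""

import numpy as np
import pytest

from helpers import brute_force_clusters, same_partition
from micellemix.cgmodel import Frame, SystemTopology, Trajectory
from micellemix.cluster import (
    block_average,
    find_clusters,
    free_monomer_stats,
    noc_series,
    sds_content_by_size,
    size_distribution,
)
from micellemix.synth import ClusterSpec, ConfigSpec, build_configuration


def compact_molecule(anchor, kind="SDS", spread=1.0, rng=None):
    """Bead blob with the first bead exactly on the anchor."""
    from micellemix.cgmodel import TOPOLOGIES

    rng = rng or np.random.default_rng(0)
    n = TOPOLOGIES[kind].n_beads
    offsets = rng.uniform(-spread, spread, (n, 3))
    offsets[0] = 0.0
    return np.asarray(anchor, float) + offsets


def frame_from_anchors(anchors, kinds=None, box=200.0, spread=0.5, time_us=0.0):
    kinds = kinds or ["SDS"] * len(anchors)
    rng = np.random.default_rng(1)
    top = SystemTopology(kinds)
    blocks = [compact_molecule(a, k, spread, rng) for a, k in zip(anchors, kinds)]
    return Frame(top, np.mod(np.concatenate(blocks), box), box, time_us)


def random_dense_frame(rng, n_mols=15, box=30.0):
    kinds = [("SDS", "CA")[rng.integers(2)] for _ in range(n_mols)]
    anchors = rng.uniform(0, box, (n_mols, 3))
    return frame_from_anchors(list(anchors), kinds, box=box, spread=1.5)


class TestFindClusters:
    def test_constructed_pair_plus_singleton(self):
        # closest-bead gaps: A-B = 5, B-C = 30
        f = frame_from_anchors([(0, 0, 0), (5, 0, 0), (35, 0, 0)], spread=0.0)
        asg = find_clusters(f, cutoff=7.0)
        assert asg.n_clusters == 2
        assert same_partition(asg.labels, [0, 0, 1])

    def test_well_separated_molecules_stay_monomeric(self):
        # 60 molecules on a sparse lattice: the initial-state analogue
        grid = [(20.0 * i, 20.0 * j, 20.0 * k)
                for i in range(4) for j in range(4) for k in range(4)][:60]
        f = frame_from_anchors(grid, box=80.0, spread=0.5)
        assert find_clusters(f, cutoff=7.0).n_clusters == 60

    def test_matches_brute_force_components(self, rng):
        for _ in range(100):
            f = random_dense_frame(rng, n_mols=int(rng.integers(5, 21)))
            asg = find_clusters(f, cutoff=7.0)
            assert same_partition(asg.labels, brute_force_clusters(f, 7.0))

    def test_cutoff_is_strict(self):
        f = frame_from_anchors([(0, 0, 0), (7.0, 0, 0)], spread=0.0)
        assert find_clusters(f, cutoff=7.0).n_clusters == 2
        f2 = frame_from_anchors([(0, 0, 0), (6.999, 0, 0)], spread=0.0)
        assert find_clusters(f2, cutoff=7.0).n_clusters == 1

    def test_extreme_cutoffs(self, rng):
        f = random_dense_frame(rng)
        assert find_clusters(f, cutoff=1e-6).n_clusters == len(
            f.topology.surfactant_indices
        )
        assert find_clusters(f, cutoff=2 * f.box).n_clusters == 1
        with pytest.raises(ValueError):
            find_clusters(f, cutoff=0.0)

    def test_invariant_under_reordering_and_translation(self, rng):
        n = 12
        box = 30.0
        kinds = [("SDS", "CA")[rng.integers(2)] for _ in range(n)]
        blocks = [compact_molecule(a, k, 1.0, rng)
                  for a, k in zip(rng.uniform(0, box, (n, 3)), kinds)]
        top = SystemTopology(kinds)
        f = Frame(top, np.mod(np.concatenate(blocks), box), box, 0.0)
        base = find_clusters(f, 7.0)

        order = rng.permutation(n)
        top_p = SystemTopology([kinds[i] for i in order])
        g = Frame(top_p,
                  np.mod(np.concatenate([blocks[i] for i in order]), box),
                  box, 0.0)
        perm = find_clusters(g, 7.0)
        assert perm.n_clusters == base.n_clusters
        assert sorted(perm.sizes) == sorted(base.sizes)

        shifted = Frame(f.topology,
                        np.mod(f.positions + [11.3, -4.2, 27.9], f.box),
                        f.box, f.time_us)
        trans = find_clusters(shifted, 7.0)
        assert same_partition(trans.labels, base.labels)

    def test_sizes_conserve_molecule_count(self, rng):
        f = random_dense_frame(rng, n_mols=20)
        asg = find_clusters(f, 7.0)
        assert asg.sizes.sum() == 20
        assert np.all((asg.labels >= 0) & (asg.labels < asg.n_clusters))
        assert np.all((asg.sds_fraction >= 0) & (asg.sds_fraction <= 1))


class TestBlockAverage:
    def test_constant_series(self):
        times = np.arange(0.6, 10.0, 0.05)
        s = block_average(times, np.full_like(times, 18.0),
                         block_ns=100, window=(0.6, 10.0))
        assert len(s.block_mean) == 94
        np.testing.assert_allclose(s.block_mean, 18.0)
        assert s.overall_mean == pytest.approx(18.0)
        assert s.overall_sd == pytest.approx(0.0)

    def test_partial_trailing_block_dropped_with_warning(self):
        times = np.arange(0.0, 1.0, 0.01)
        with pytest.warns(UserWarning, match="partial block"):
            s = block_average(times, times, block_ns=300, window=(0.0, 1.0))
        assert len(s.block_mean) == 3

    def test_window_shorter_than_block_fails(self):
        with pytest.raises(ValueError, match="shorter than one block"):
            block_average(np.array([0.61]), np.array([1.0]),
                          block_ns=100, window=(0.6, 0.65))

    def test_empty_window_fails(self):
        with pytest.raises(ValueError):
            block_average(np.array([1.0]), np.array([1.0]),
                          block_ns=100, window=(2.0, 2.0))


def constant_trajectory(frame, times):
    return Trajectory([
        Frame(frame.topology, frame.positions, frame.box, time_us=t)
        for t in times
    ])


class TestWindowedStatistics:
    def test_noc_series_constant_trajectory(self, rng):
        f = random_dense_frame(rng)
        n = find_clusters(f, 7.0).n_clusters
        traj = constant_trajectory(f, np.arange(0.6, 2.0, 0.05))
        s = noc_series(traj, window=(0.6, 2.0))
        assert s.overall_mean == pytest.approx(n)
        assert s.overall_sd == pytest.approx(0.0)

    def test_single_frame_size_distribution(self):
        # one frame with clusters of sizes {1, 1, 12}
        spec = ConfigSpec(clusters=(ClusterSpec(6, 6),), free_sds=1, free_ca=1,
                          box=150.0, seed=2)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0, 1.1])
        dist = size_distribution(traj, window=(0.9, 1.2))
        assert dist.frequency.sum() == pytest.approx(1.0)
        lookup = dict(zip(dist.sizes, dist.frequency))
        assert lookup[1] == pytest.approx(2 / 3)
        assert lookup[12] == pytest.approx(1 / 3)

    def test_trimodal_planted_distribution(self):
        # planted sizes 1, 12 and 41: the histogram peaks exactly there
        spec = ConfigSpec(
            clusters=(ClusterSpec(28, 13), ClusterSpec(8, 4)),
            free_sds=1, free_ca=16, box=260.0, seed=4,
        )
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0, 1.1, 1.2])
        dist = size_distribution(traj, window=(0.9, 1.3))
        assert set(dist.modes) == {1, 12, 41}
        lookup = dict(zip(dist.sizes, dist.frequency))
        assert lookup[1] == pytest.approx(17 / 19)

    def test_sds_content_by_size(self):
        spec = ConfigSpec(clusters=(ClusterSpec(28, 13),), free_ca=2,
                          box=200.0, seed=5)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0, 1.1])
        comp = sds_content_by_size(traj, window=(0.9, 1.2))
        row41 = comp.table[comp.table["size"] == 41].iloc[0]
        assert row41["mean_x2"] == pytest.approx(28 / 41)
        # size 41 observed twice with identical composition -> sd 0;
        # x2 pooled with equal weight per cluster
        assert comp.overall_mean == pytest.approx((28 / 41 + 0 + 0) / 3)

    def test_sd_absent_for_single_observation(self):
        spec = ConfigSpec(clusters=(ClusterSpec(3, 2),), box=120.0, seed=6)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0])
        comp = sds_content_by_size(traj, window=(0.9, 1.1))
        assert np.isnan(comp.table["sd_x2"].iloc[0])

    def test_pure_cluster_compositions(self):
        spec = ConfigSpec(clusters=(ClusterSpec(10, 0), ClusterSpec(0, 8)),
                          box=200.0, seed=7)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0])
        comp = sds_content_by_size(traj, window=(0.9, 1.1))
        lookup = dict(zip(comp.table["size"], comp.table["mean_x2"]))
        assert lookup[10] == pytest.approx(1.0)
        assert lookup[8] == pytest.approx(0.0)

    def test_free_monomer_fraction(self):
        # 17 free CA next to a 43-molecule aggregate: 17/60 unaggregated
        spec = ConfigSpec(clusters=(ClusterSpec(28, 15),), free_ca=17,
                          box=260.0, seed=8)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0, 1.1])
        stats = free_monomer_stats(traj, window=(0.9, 1.2))
        assert stats.fraction_free == pytest.approx(17 / 60)
        assert stats.free_kind_fractions == {"CA": 1.0}

    def test_free_monomer_extremes(self):
        spec = ConfigSpec(clusters=(ClusterSpec(5, 5),), box=150.0, seed=9)
        frame, _ = build_configuration(spec)
        traj = constant_trajectory(frame, [1.0])
        assert free_monomer_stats(traj, window=(0.9, 1.1)).fraction_free == 0.0

        spec2 = ConfigSpec(free_sds=3, free_ca=3, box=150.0, seed=10)
        frame2, _ = build_configuration(spec2)
        traj2 = constant_trajectory(frame2, [1.0])
        assert free_monomer_stats(traj2, window=(0.9, 1.1)).fraction_free == 1.0
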