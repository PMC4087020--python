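"""Micelle identification and aggregation statistics.

Two or more surfactant molecules belong to the same cluster when the distance
between their closest beads is strictly below the cutoff (default 7 A, the
bead-contact criterion for this coarse-grained system).  Sodium ions and
water never take part in clustering.

Windowed statistics follow the block-averaging convention: the analysis
window (default 0.6-10 us, after the initial association transient) is tiled
with fixed blocks (default 100 ns); the reported mean and standard deviation
are taken over block means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cgmodel import Frame, Trajectory, minimum_image_distance

__all__ = [
    "ClusterAssignment",
    "BlockedSeries",
    "SizeDistribution",
    "CompositionBySize",
    "FreeMonomerStats",
    "find_clusters",
    "block_average",
    "noc_series",
    "size_distribution",
    "sds_content_by_size",
    "free_monomer_stats",
]

DEFAULT_CUTOFF = 7.0
DEFAULT_BLOCK_NS = 100.0
DEFAULT_WINDOW = (0.6, 10.0)


@dataclass
class ClusterAssignment:
    """Per-molecule cluster labels for the surfactants of one frame."""

    frame_time: float
    molecule_indices: np.ndarray  # topology indices of the clustered molecules
    molecule_kinds: np.ndarray
    labels: np.ndarray
    n_clusters: int
    sizes: np.ndarray
    sds_fraction: np.ndarray

    def cluster_members(self, label: int) -> np.ndarray:
        """Topology molecule indices belonging to one cluster."""
        return self.molecule_indices[self.labels == label]


def _surfactant_closest_distances(frame: Frame) -> tuple[np.ndarray, np.ndarray]:
    """Molecule-pair closest-bead distance matrix for the surfactants."""
    top = frame.topology
    mols = top.surfactant_indices
    if len(mols) == 0:
        raise ValueError("frame contains no surfactant molecules")
    bead_idx = np.concatenate([np.arange(top.mol_slice(i).start,
                                         top.mol_slice(i).stop) for i in mols])
    pos = frame.positions[bead_idx]
    owner = np.concatenate(
        [np.full(top.mol_slice(i).stop - top.mol_slice(i).start, k)
         for k, i in enumerate(mols)]
    )
    d = minimum_image_distance(pos[:, None, :], pos[None, :, :], frame.box)
    m = len(mols)
    dist = np.full((m, m), np.inf)
    # reduce bead-pair distances to per-molecule-pair minima
    np.minimum.at(dist, (owner[:, None].repeat(len(owner), 1),
                         owner[None, :].repeat(len(owner), 0)), d)
    np.fill_diagonal(dist, 0.0)
    return mols, dist


def find_clusters(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> ClusterAssignment:
    """Connected components of the closest-bead contact graph.

    An edge joins two surfactant molecules when their closest-bead
    minimum-image distance is strictly less than ``cutoff``.  Labels are
    assigned in order of first molecule index, so the assignment is
    deterministic.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    mols, dist = _surfactant_closest_distances(frame)
    m = len(mols)
    adj = csr_matrix((dist < cutoff).astype(np.int8))
    n_comp, raw = connected_components(adj, directed=False)
    # relabel components in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(m, dtype=int)
    for i, r in enumerate(raw):
        labels[i] = order.setdefault(int(r), len(order))
    kinds = np.array([frame.topology.molecule_kinds[i] for i in mols])
    sizes = np.bincount(labels, minlength=n_comp)
    sds = np.bincount(labels, weights=(kinds == "SDS").astype(float),
                      minlength=n_comp)
    return ClusterAssignment(
        frame_time=frame.time_us,
        molecule_indices=mols,
        molecule_kinds=kinds,
        labels=labels,
        n_clusters=int(n_comp),
        sizes=sizes,
        sds_fraction=sds / sizes,
    )


# ---------------------------------------------------------------------------
# windowed statistics


@dataclass
class BlockedSeries:
    """Block-averaged time series over an analysis window."""

    block_start: np.ndarray  # us
    block_mean: np.ndarray
    overall_mean: float
    overall_sd: float
    window: tuple[float, float]
    frame_times: np.ndarray
    frame_values: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"block_start_us": self.block_start, "block_mean": self.block_mean}
        )


def block_average(
    times: np.ndarray,
    values: np.ndarray,
    block_ns: float = DEFAULT_BLOCK_NS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> BlockedSeries:
    """Tile ``window`` with ``block_ns`` blocks and average within each.

    A trailing partial block is dropped with a warning; a window shorter than
    one block is an error.  The overall mean/sd are computed over block means
    (sd with ddof=1; NaN for a single block).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"empty analysis window {window}")
    block_us = block_ns / 1000.0
    n_blocks = int(np.floor((t1 - t0) / block_us + 1e-9))
    if n_blocks < 1:
        raise ValueError(
            f"window {window} us is shorter than one block ({block_ns} ns)"
        )
    if (t1 - t0) - n_blocks * block_us > 1e-9:
        warnings.warn(
            f"window {window} is not a whole number of {block_ns} ns blocks; "
            "dropping the trailing partial block",
            stacklevel=2,
        )
    in_win = (times >= t0) & (times < t0 + n_blocks * block_us)
    if not np.any(in_win):
        raise ValueError(f"no samples inside window {window}")
    tw, vw = times[in_win], values[in_win]
    idx = np.floor((tw - t0) / block_us).astype(int)
    counts = np.bincount(idx, minlength=n_blocks)
    sums = np.bincount(idx, weights=vw, minlength=n_blocks)
    if np.any(counts == 0):
        warnings.warn("some blocks contain no frames; they are dropped",
                      stacklevel=2)
    keep = counts > 0
    means = sums[keep] / counts[keep]
    starts = t0 + np.flatnonzero(keep) * block_us
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else float("nan")
    return BlockedSeries(
        block_start=starts,
        block_mean=means,
        overall_mean=float(np.mean(means)),
        overall_sd=sd,
        window=(t0, t1),
        frame_times=tw,
        frame_values=vw,
    )


def _window_assignments(
    traj: Trajectory, cutoff: float, window: tuple[float, float]
) -> list[ClusterAssignment]:
    return [find_clusters(f, cutoff) for f in traj.in_window(window)]


def noc_series(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    block_ns: float = DEFAULT_BLOCK_NS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> BlockedSeries:
    """Number-of-clusters time series, block-averaged over the window."""
    assignments = _window_assignments(traj, cutoff, window)
    times = np.array([a.frame_time for a in assignments])
    noc = np.array([a.n_clusters for a in assignments], dtype=float)
    return block_average(times, noc, block_ns, window)


@dataclass
class SizeDistribution:
    """Normalised cluster-size histogram pooled over frames."""

    sizes: np.ndarray
    frequency: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "frequency": self.frequency})

    @property
    def modes(self) -> np.ndarray:
        """Sizes at local maxima of the dense histogram (zeros filled in)."""
        dense = np.zeros(int(self.sizes.max()) + 2)
        dense[self.sizes.astype(int)] = self.frequency
        out = []
        for s in self.sizes.astype(int):
            if dense[s] > dense[s - 1] and dense[s] > dense[s + 1]:
                out.append(s)
        return np.array(out)


def size_distribution(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SizeDistribution:
    """Frequency of cluster sizes pooled over all frames in the window."""
    assignments = _window_assignments(traj, cutoff, window)
    all_sizes = np.concatenate([a.sizes for a in assignments])
    sizes, counts = np.unique(all_sizes, return_counts=True)
    return SizeDistribution(sizes=sizes, frequency=counts / counts.sum())


@dataclass
class CompositionBySize:
    """Mean/sd of the per-cluster SDS mole fraction x2 by cluster size."""

    table: pd.DataFrame  # columns: size, n, mean_x2, sd_x2
    overall_mean: float  # equal weight per cluster
    overall_sd: float


def sds_content_by_size(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> CompositionBySize:
    """SDS content of the aggregates as a function of cluster size.

    Every cluster observed in the window contributes one (size, x2) sample;
    the overall mean weights clusters equally.  The sd at sizes observed once
    is reported as NaN (absent), not zero.
    """
    assignments = _window_assignments(traj, cutoff, window)
    sizes = np.concatenate([a.sizes for a in assignments])
    x2 = np.concatenate([a.sds_fraction for a in assignments])
    df = pd.DataFrame({"size": sizes, "x2": x2})
    grouped = df.groupby("size")["x2"].agg(["count", "mean", "std"]).reset_index()
    table = grouped.rename(
        columns={"count": "n", "mean": "mean_x2", "std": "sd_x2"}
    )
    return CompositionBySize(
        table=table,
        overall_mean=float(np.mean(x2)),
        overall_sd=float(np.std(x2, ddof=1)) if len(x2) > 1 else float("nan"),
    )


@dataclass
class FreeMonomerStats:
    """Share of molecule-frames that remain unaggregated (size-1 clusters)."""

    fraction_free: float
    n_free: int
    n_total: int
    free_kind_fractions: dict  # among free monomers, share by molecule kind


def free_monomer_stats(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> FreeMonomerStats:
    """Fraction of unaggregated surfactants and its SDS/CA breakdown."""
    assignments = _window_assignments(traj, cutoff, window)
    n_total = 0
    n_free = 0
    kind_counts: dict[str, int] = {}
    for a in assignments:
        n_total += len(a.labels)
        free_mask = a.sizes[a.labels] == 1
        n_free += int(free_mask.sum())
        for k in a.molecule_kinds[free_mask]:
            kind_counts[k] = kind_counts.get(k, 0) + 1
    fractions = (
        {k: v / n_free for k, v in kind_counts.items()} if n_free else {}
    )
    return FreeMonomerStats(
        fraction_free=n_free / n_total,
        n_free=n_free,
        n_total=n_total,
        free_kind_fractions=fractions,
    )
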