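"""Micelle geometry: gyration tensor, shape anisotropy, radial structure and
SDS orientation.

The gyration tensor of a bead set is S = <(r - COM) (r - COM)^T> with equal
bead weights; its eigenvalues lambda_x >= lambda_y >= lambda_z give the
relative shape anisotropy

    K^2 = 1 - 3 (lx ly + ly lz + lx lz) / (lx + ly + lz)^2,

which is 0 for spherically symmetric arrangements and 1 for collinear ones.
Clusters are unwrapped by the minimum image relative to their first bead
before any centre-of-mass computation, so micelles split across the periodic
boundary are handled correctly (valid while a cluster fits in half a box).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgmodel import Frame, Trajectory, minimum_image_displacement
from .cluster import (
    DEFAULT_CUTOFF,
    DEFAULT_WINDOW,
    ClusterAssignment,
    find_clusters,
)

__all__ = [
    "GyrationResult",
    "RadialProfile",
    "AngleProfile",
    "gyration_anisotropy",
    "shape_by_size",
    "radial_profile",
    "orientation_angles",
    "unwrap_cluster",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLUSTER_SIZE = 20
_DEGENERATE_TRACE = 1e-12


@dataclass(frozen=True)
class GyrationResult:
    """Principal gyration moments (A^2, descending) and shape anisotropy."""

    lambda_x: float
    lambda_y: float
    lambda_z: float
    k2: float

    @property
    def radius_of_gyration(self) -> float:
        return float(np.sqrt(self.lambda_x + self.lambda_y + self.lambda_z))


def gyration_anisotropy(coords: np.ndarray) -> GyrationResult:
    """Gyration tensor eigenvalues and K^2 of an unwrapped bead set.

    Beads are weighted equally.  A fully degenerate set (all beads
    coincident) has zero trace and K^2 is defined as 0.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 2:
        raise ValueError("need at least 2 beads with 3 coordinates each")
    centred = coords - coords.mean(axis=0)
    tensor = centred.T @ centred / len(coords)
    lam = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    lam = np.clip(lam, 0.0, None)
    trace = lam.sum()
    if trace < _DEGENERATE_TRACE:
        return GyrationResult(0.0, 0.0, 0.0, 0.0)
    k2 = 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2] + lam[0] * lam[2]) / trace**2
    return GyrationResult(
        float(lam[0]), float(lam[1]), float(lam[2]), float(np.clip(k2, 0.0, 1.0))
    )


def unwrap_cluster(
    frame: Frame, assignment: ClusterAssignment, label: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Unwrapped bead coordinates of one cluster.

    Every bead is placed at the reference (first bead of the cluster's first
    molecule) plus its minimum-image displacement from that reference.
    Returns the concatenated coordinates and the per-molecule coordinate
    blocks, in cluster-member order.
    """
    members = assignment.cluster_members(label)
    ref = frame.molecule_positions(int(members[0]))[0]
    blocks: list[np.ndarray] = []
    for i in members:
        pos = frame.molecule_positions(int(i))
        blocks.append(ref + minimum_image_displacement(ref, pos, frame.box))
    return np.concatenate(blocks), blocks


def shape_by_size(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Mean K^2 per observed cluster size over the window.

    Returns a frame with columns size, n, mean_k2, sd_k2 (sd NaN when a size
    was observed once).  Size-1 clusters are included: a single molecule's
    beads still define a gyration tensor.
    """
    rows: list[tuple[int, float]] = []
    for frame in traj.in_window(window):
        asg = find_clusters(frame, cutoff)
        for label in range(asg.n_clusters):
            coords, _ = unwrap_cluster(frame, asg, label)
            rows.append((int(asg.sizes[label]), gyration_anisotropy(coords).k2))
    df = pd.DataFrame(rows, columns=["size", "k2"])
    out = df.groupby("size")["k2"].agg(["count", "mean", "std"]).reset_index()
    return out.rename(columns={"count": "n", "mean": "mean_k2", "std": "sd_k2"})


@dataclass
class RadialProfile:
    """Normalised histogram of bead distances from the cluster COM."""

    kind: str
    bead_name: str
    bin_edges: np.ndarray  # A
    density: np.ndarray  # sums to 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_A": 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:]),
                "density": self.density,
            }
        )

    @property
    def peak_r(self) -> float:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return float(centers[np.argmax(self.density)])


def radial_profile(
    traj: Trajectory,
    kind: str,
    bead_name: str,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    bin_width: float = 1.0,
    r_max: float = 40.0,
) -> RadialProfile:
    """Distribution of a bead type's distance from its micelle's COM.

    Only clusters of at least ``min_cluster_size`` molecules contribute;
    distances are measured after unwrapping, and the histogram is normalised
    to unit mass per selector.
    """
    distances: list[np.ndarray] = []
    matched = False
    for frame in traj.in_window(window):
        asg = find_clusters(frame, cutoff)
        top = frame.topology
        for label in range(asg.n_clusters):
            if asg.sizes[label] < min_cluster_size:
                continue
            coords, blocks = unwrap_cluster(frame, asg, label)
            com = coords.mean(axis=0)
            members = asg.cluster_members(label)
            for i, block in zip(members, blocks):
                mol = top.molecules[int(i)]
                if mol.kind != kind:
                    continue
                sel = [j for j, nm in enumerate(mol.bead_names) if nm == bead_name]
                if sel:
                    matched = True
                    d = np.linalg.norm(block[sel] - com, axis=1)
                    distances.append(d)
    if not matched:
        raise ValueError(
            f"selector ({kind}, {bead_name}) matched no beads in clusters of "
            f"size >= {min_cluster_size}"
        )
    all_d = np.concatenate(distances)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts, _ = np.histogram(all_d, bins=edges)
    return RadialProfile(
        kind=kind,
        bead_name=bead_name,
        bin_edges=edges,
        density=counts / counts.sum(),
    )


@dataclass
class AngleProfile:
    """Normalised histogram of the SDS orientation angle Theta (degrees)."""

    bin_edges: np.ndarray  # [0, 180]
    frequency: np.ndarray  # sums to 1
    n_molecules: int
    n_skipped: int
    angles: np.ndarray  # raw per-molecule angles, degrees

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta_deg": 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:]),
                "frequency": self.frequency,
            }
        )


def orientation_angles(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    bin_width_deg: float = 5.0,
) -> AngleProfile:
    """Orientation of SDS inside micelles.

    For each SDS molecule in a qualifying cluster, Theta is the angle between
    the molecular axis SO3 -> C4 and the radial direction SO3 -> cluster COM:
    Theta = 0 means the tail points at the micelle centre, 180 away from it.
    Molecules whose SO3 bead coincides with the COM are skipped and counted.
    """
    angles: list[float] = []
    n_skipped = 0
    for frame in traj.in_window(window):
        asg = find_clusters(frame, cutoff)
        top = frame.topology
        for label in range(asg.n_clusters):
            if asg.sizes[label] < min_cluster_size:
                continue
            coords, blocks = unwrap_cluster(frame, asg, label)
            com = coords.mean(axis=0)
            members = asg.cluster_members(label)
            for i, block in zip(members, blocks):
                mol = top.molecules[int(i)]
                if mol.kind != "SDS":
                    continue
                so3 = block[mol.bead_names.index("SO3")]
                c4 = block[mol.bead_names.index("C4")]
                v_mol = c4 - so3
                v_rad = com - so3
                n1, n2 = np.linalg.norm(v_mol), np.linalg.norm(v_rad)
                if n1 < 1e-9 or n2 < 1e-9:
                    n_skipped += 1
                    continue
                cosang = np.clip(v_mol @ v_rad / (n1 * n2), -1.0, 1.0)
                angles.append(float(np.degrees(np.arccos(cosang))))
    if n_skipped:
        logger.info("orientation_angles: skipped %d degenerate molecules",
                    n_skipped)
    if not angles:
        raise ValueError(
            f"no SDS molecules found in clusters of size >= {min_cluster_size}"
        )
    arr = np.array(angles)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    counts, _ = np.histogram(arr, bins=edges)
    return AngleProfile(
        bin_edges=edges,
        frequency=counts / counts.sum(),
        n_molecules=len(arr),
        n_skipped=n_skipped,
        angles=arr,
    )
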