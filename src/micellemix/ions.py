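"""Counterion condensation bookkeeping.

A sodium ion counts as *condensed* when its minimum-image distance to any
negatively charged surfactant bead (the SO3 head of SDS or the OCO
carboxylate of CA) is strictly below the cutoff (default 7 A, the same
contact criterion used for clustering); otherwise it is *free*.  The
partition is exhaustive: condensed + free = total in every frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cgmodel import Frame, Trajectory, minimum_image_distance
from .cluster import (
    DEFAULT_BLOCK_NS,
    DEFAULT_CUTOFF,
    DEFAULT_WINDOW,
    BlockedSeries,
    block_average,
)

__all__ = ["IonPartition", "classify_ions", "ion_series"]


@dataclass(frozen=True)
class IonPartition:
    """Condensed/free split of the sodium ions in one frame."""

    time_us: float
    n_condensed: int
    n_free: int

    @property
    def n_total(self) -> int:
        return self.n_condensed + self.n_free

    @property
    def condensed_fraction(self) -> float:
        return self.n_condensed / self.n_total if self.n_total else float("nan")


def _charged_bead_positions(frame: Frame) -> np.ndarray:
    top = frame.topology
    idx = np.concatenate(
        [top.bead_indices(kind="SDS", bead_name="SO3"),
         top.bead_indices(kind="CA", bead_name="OCO")]
    )
    return frame.positions[idx]


def classify_ions(frame: Frame, cutoff: float = DEFAULT_CUTOFF) -> IonPartition:
    """Partition the frame's Na+ ions into condensed and free."""
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    top = frame.topology
    na_idx = top.bead_indices(kind="NA")
    if len(na_idx) == 0:
        warnings.warn("frame contains no Na ions", stacklevel=2)
        return IonPartition(frame.time_us, 0, 0)
    charged = _charged_bead_positions(frame)
    if len(charged) == 0:
        raise ValueError("frame contains no charged surfactant beads")
    na_pos = frame.positions[na_idx]
    d = minimum_image_distance(na_pos[:, None, :], charged[None, :, :], frame.box)
    condensed = int(np.sum(d.min(axis=1) < cutoff))
    return IonPartition(frame.time_us, condensed, len(na_idx) - condensed)


def ion_series(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    block_ns: float = DEFAULT_BLOCK_NS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[BlockedSeries, BlockedSeries]:
    """Block-averaged (condensed, free) ion counts over the window."""
    parts = [classify_ions(f, cutoff) for f in traj.in_window(window)]
    times = np.array([p.time_us for p in parts])
    condensed = np.array([p.n_condensed for p in parts], dtype=float)
    free = np.array([p.n_free for p in parts], dtype=float)
    return (
        block_average(times, condensed, block_ns, window),
        block_average(times, free, block_ns, window),
    )
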