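"""Synthetic-data generation with known ground truth.

Three generators cover the three data classes the analysis code consumes:

* :func:`generate_curve` -- measurement curves (Boltzmann titration,
  two-segment or single-line conductivity, gamma-log c tensiometry) with
  additive Gaussian noise and the generating parameters attached;
* :func:`build_configuration` -- single frames with planted micelles, free
  monomers and a planted condensed/free Na+ split, constructed so the
  cluster and ion analyses recover the ground truth exactly;
* :func:`run_toy_aggregation` -- a desk-scale overdamped Langevin simulator
  of bead-chain surfactants with hydrophobic attraction (strongest between
  SDS tails), screened electrostatics and excluded volume, in a cubic
  periodic box.  It is a mechanistic toy: it reproduces the qualitative
  self-assembly pathway (monomers -> SDS-rich cores -> growth by cholate
  adsorption), not any force-field-level observable.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cgmodel import (
    Frame,
    SystemTopology,
    Trajectory,
    effective_concentration,
    minimum_image_distance,
)
from .cmcfit import MeasurementCurve, boltzmann

__all__ = [
    "CurveSpec",
    "ClusterSpec",
    "ConfigSpec",
    "ConfigTruth",
    "ToySimSpec",
    "generate_curve",
    "build_configuration",
    "run_toy_aggregation",
    "default_cluster_radius",
]


# ---------------------------------------------------------------------------
# measurement curves


@dataclass(frozen=True)
class CurveSpec:
    """Specification of one synthetic measurement curve.

    ``true_params`` by kind:

    * titration: x0 (mM), dx (mM), a_high (pre-micellar I1/I3 plateau),
      a_low (micellar plateau);
    * conductivity: either breakpoint/slope_pre/slope_post/intercept for a
      two-segment line, or slope/intercept for the breakpoint-free case;
    * tension: breakpoint (mM), slope_pre/slope_post (mN/m per decade),
      intercept -- the model is piecewise linear in log10(concentration).
    """

    kind: str
    true_params: dict
    noise_sd: float = 0.0
    n_points: int = 30
    x_range: tuple[float, float] = (1.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("titration", "conductivity", "tension"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.n_points < 6:
            raise ValueError("n_points must be at least 6")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _segmented_model(x: np.ndarray, p: dict) -> np.ndarray:
    if "breakpoint" in p:
        bp = p["breakpoint"]
        s1, s2 = p["slope_pre"], p["slope_post"]
        b = p.get("intercept", 0.0)
        y_bp = b + s1 * bp
        return np.where(x <= bp, b + s1 * x, y_bp + s2 * (x - bp))
    return p.get("intercept", 0.0) + p["slope"] * x


def generate_curve(spec: CurveSpec) -> MeasurementCurve:
    """Evaluate the specified model and add Gaussian noise (seeded)."""
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(*spec.x_range, spec.n_points)
    p = spec.true_params
    if spec.kind == "titration":
        y = boltzmann(x, p["a_low"], p["a_high"], p["x0"], p["dx"])
    elif spec.kind == "conductivity":
        y = _segmented_model(x, p)
    else:  # tension: piecewise linear in log10 c
        logp = dict(p)
        if "breakpoint" in logp:
            logp["breakpoint"] = math.log10(logp["breakpoint"])
        y = _segmented_model(np.log10(x), logp)
    y = y + rng.normal(0.0, spec.noise_sd, size=x.shape)
    return MeasurementCurve(x=x, y=y, kind=spec.kind, truth=dict(p))


# ---------------------------------------------------------------------------
# constructed configurations with planted truth

_CHAIN_STEP = 4.5  # A between successive molecule anchors inside a cluster
_BEAD_JITTER = 1.5  # A max offset of non-anchor beads from the anchor
_INTER_MARGIN = 16.0  # A guaranteed gap between distinct entities
_CONDENSED_RANGE = (2.5, 6.5)  # A, placement band for planted condensed Na
_FREE_NA_MIN = 10.0  # A, minimum charged-bead distance for free Na


@dataclass(frozen=True)
class ClusterSpec:
    """One planted micelle: composition, geometry and nominal radius (A)."""

    n_sds: int
    n_ca: int
    geometry: str = "sphere"
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.geometry not in ("sphere", "rod"):
            raise ValueError("geometry must be 'sphere' or 'rod'")
        if self.n_sds + self.n_ca < 1:
            raise ValueError("a cluster needs at least one molecule")

    @property
    def size(self) -> int:
        return self.n_sds + self.n_ca


def default_cluster_radius(n_molecules: int) -> float:
    """Nominal packing radius giving ~4.5 A anchor spacing in a sphere."""
    return max(6.0, 3.2 * n_molecules ** (1.0 / 3.0) + 2.0)


@dataclass(frozen=True)
class ConfigSpec:
    """Specification of a constructed frame with planted ground truth."""

    clusters: tuple[ClusterSpec, ...] = ()
    free_sds: int = 0
    free_ca: int = 0
    n_na: Optional[int] = None  # default: one per surfactant (neutral system)
    planted_condensed: int = 0
    box: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        n_na = self.n_surfactants if self.n_na is None else self.n_na
        object.__setattr__(self, "n_na", n_na)
        if self.planted_condensed > n_na:
            raise ValueError("planted_condensed exceeds the Na count")
        if self.planted_condensed > 0 and self.n_surfactants == 0:
            raise ValueError("cannot condense Na without charged beads")
        for c in self.clusters:
            r = c.radius if c.radius is not None else default_cluster_radius(c.size)
            if r >= self.box / 4:
                raise ValueError(
                    f"cluster radius {r:.1f} A must stay below box/4 "
                    f"({self.box / 4:.1f} A)"
                )

    @property
    def n_surfactants(self) -> int:
        return sum(c.size for c in self.clusters) + self.free_sds + self.free_ca


@dataclass
class ConfigTruth:
    """Planted ground truth accompanying a constructed frame."""

    labels: np.ndarray  # per surfactant molecule, cluster id
    sizes: np.ndarray
    sds_fraction: np.ndarray
    n_condensed: int
    n_free_na: int


def _place_entity_centers(
    rng: np.random.Generator, radii: Sequence[float], box: float
) -> np.ndarray:
    """Rejection-sample entity centres with guaranteed inter-entity gaps."""
    centers: list[np.ndarray] = []
    for k, r in enumerate(radii):
        for _ in range(5000):
            c = rng.uniform(0, box, 3)
            ok = all(
                minimum_image_distance(c, centers[j], box)
                > r + radii[j] + _INTER_MARGIN
                for j in range(k)
            )
            if ok:
                centers.append(c)
                break
        else:
            raise RuntimeError(
                f"could not pack {len(radii)} entities into a {box:.0f} A box; "
                "increase the box or reduce cluster sizes"
            )
    return np.array(centers)


def _cluster_anchors(
    rng: np.random.Generator, spec: ClusterSpec, center: np.ndarray, radius: float
) -> np.ndarray:
    """Anchor (first-bead) positions for a cluster's molecules.

    Anchors form a connected chain: each is ~4.5 A from an already placed
    one, guaranteeing the closest-bead contact criterion joins the cluster.
    """
    n = spec.size
    anchors = [center.copy()]
    if spec.geometry == "rod":
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        for i in range(1, n):
            lateral = rng.normal(scale=0.8, size=3)
            lateral -= (lateral @ axis) * axis
            anchors.append(center + axis * _CHAIN_STEP * i + lateral)
        return np.array(anchors)
    for _ in range(1, n):
        for _ in range(200):
            base = anchors[rng.integers(len(anchors))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = base + direction * _CHAIN_STEP
            if np.linalg.norm(cand - center) <= radius:
                anchors.append(cand)
                break
        else:  # fall back to growing from the centre
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            anchors.append(center + direction * min(radius, _CHAIN_STEP))
    return np.array(anchors)


def _molecule_beads(
    rng: np.random.Generator, kind: str, anchor: np.ndarray
) -> np.ndarray:
    """Compact bead blob: the first bead sits on the anchor, the rest within
    the jitter shell around it."""
    from .cgmodel import TOPOLOGIES

    n = TOPOLOGIES[kind].n_beads
    offsets = rng.uniform(-1, 1, size=(n, 3))
    norms = np.linalg.norm(offsets, axis=1, keepdims=True)
    offsets = offsets / np.maximum(norms, 1e-12) * rng.uniform(
        0.3, _BEAD_JITTER, size=(n, 1)
    )
    offsets[0] = 0.0
    return anchor + offsets


def build_configuration(spec: ConfigSpec) -> tuple[Frame, ConfigTruth]:
    """Construct a frame whose cluster/ion ground truth is known by design.

    Distinct clusters and free monomers are separated by more than 16 A
    (closest beads), molecules within a cluster form a 4.5 A contact chain,
    exactly ``planted_condensed`` Na ions sit within (2.5, 6.5) A of a
    charged bead and the remaining Na beyond 10 A of every charged bead.
    """
    rng = np.random.default_rng(spec.seed)
    radii = [
        (c.radius if c.radius is not None else default_cluster_radius(c.size))
        + _BEAD_JITTER
        for c in spec.clusters
    ]
    # rods extend along an axis; bound them by their half-length
    for i, c in enumerate(spec.clusters):
        if c.geometry == "rod":
            radii[i] = max(radii[i], c.size * _CHAIN_STEP / 2 + _BEAD_JITTER + 2)
    n_free = spec.free_sds + spec.free_ca
    radii += [_BEAD_JITTER + 1.0] * n_free
    centers = _place_entity_centers(rng, radii, spec.box)

    kinds: list[str] = []
    coords: list[np.ndarray] = []
    labels: list[int] = []
    for ci, c in enumerate(spec.clusters):
        r = c.radius if c.radius is not None else default_cluster_radius(c.size)
        anchors = _cluster_anchors(rng, c, centers[ci], r)
        mol_kinds = ["SDS"] * c.n_sds + ["CA"] * c.n_ca
        rng.shuffle(mol_kinds)
        for kind, anchor in zip(mol_kinds, anchors):
            kinds.append(kind)
            coords.append(_molecule_beads(rng, kind, anchor))
            labels.append(ci)
    next_label = len(spec.clusters)
    free_kinds = ["SDS"] * spec.free_sds + ["CA"] * spec.free_ca
    for j, kind in enumerate(free_kinds):
        kinds.append(kind)
        coords.append(_molecule_beads(rng, kind, centers[len(spec.clusters) + j]))
        labels.append(next_label)
        next_label += 1

    # charged beads of the surfactants placed so far
    charged: list[np.ndarray] = []
    for kind, block in zip(kinds, coords):
        if kind == "SDS":
            charged.append(block[3])  # SO3
        elif kind == "CA":
            charged.append(block[7])  # OCO
    charged_arr = np.array(charged) if charged else np.empty((0, 3))

    na_coords: list[np.ndarray] = []
    for _ in range(spec.planted_condensed):
        target = charged_arr[rng.integers(len(charged_arr))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        na_coords.append(target + direction * rng.uniform(*_CONDENSED_RANGE))
    n_free_na = spec.n_na - spec.planted_condensed
    placed = 0
    for _ in range(200000):
        if placed == n_free_na:
            break
        cand = rng.uniform(0, spec.box, 3)
        if len(charged_arr) == 0 or np.min(
            minimum_image_distance(cand[None, :], charged_arr, spec.box)
        ) > _FREE_NA_MIN:
            na_coords.append(cand)
            placed += 1
    if placed < n_free_na:
        raise RuntimeError("could not place free Na ions away from charges")

    kinds += ["NA"] * spec.n_na
    coords += [c[None, :] if c.ndim == 1 else c for c in na_coords]
    topology = SystemTopology(kinds)
    positions = np.mod(np.concatenate([np.atleast_2d(c) for c in coords]),
                       spec.box)
    frame = Frame(topology, positions, box=spec.box, time_us=0.0)
    labels_arr = np.array(labels, dtype=int)
    sizes = np.bincount(labels_arr) if len(labels_arr) else np.array([], dtype=int)
    kind_arr = np.array(kinds[: len(labels)])
    sds_frac = (
        np.bincount(labels_arr, weights=(kind_arr == "SDS").astype(float))
        / np.maximum(sizes, 1)
        if len(labels_arr)
        else np.array([])
    )
    truth = ConfigTruth(
        labels=labels_arr,
        sizes=sizes,
        sds_fraction=sds_frac,
        n_condensed=spec.planted_condensed,
        n_free_na=n_free_na,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# toy aggregation dynamics


@dataclass(frozen=True)
class ToySimSpec:
    """Parameters of the overdamped Langevin toy aggregation run.

    Defaults emulate the study composition (30 SDS + 30 CA + 60 Na+) in a
    cubic box whose volume corresponds to an effective surfactant
    concentration of ~12.3 mM (edge ~201 A).  Energies are in kT units,
    lengths in A; the nominal trajectory clock maps the full run onto
    ``total_time_us`` microseconds so the windowed analyses use the same
    conventions as a real trajectory.
    """

    n_sds: int = 30
    n_ca: int = 30
    box: float = 90.0
    attraction: float = 6.0  # hydrophobic well depth, kT
    attraction_range: float = 8.0  # A, Gaussian well width
    repulsion_range: float = 10.0  # A, electrostatic screening length
    coulomb_strength: float = 2.0
    step_size: float = 0.08  # reduced time; rms bead step ~0.4 A/axis
    n_steps: int = 2600
    stride: int = 13
    temperature: float = 1.0
    total_time_us: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        for name in ("box", "step_size", "temperature", "total_time_us"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def effective_concentration_mM(self) -> float:
        return effective_concentration(
            self.n_sds + self.n_ca, (self.box / 10.0) ** 3
        )


_BOND_R0 = 3.0
_BOND_K = 10.0
_CORE_RANGE = 4.0
_CORE_K = 12.0


def _toy_system(spec: ToySimSpec, rng: np.random.Generator):
    kinds = ["SDS"] * spec.n_sds + ["CA"] * spec.n_ca + ["NA"] * (
        spec.n_sds + spec.n_ca
    )
    top = SystemTopology(kinds)
    pos = np.empty((top.n_beads, 3))
    for i, mol in enumerate(top.molecules):
        sl = top.mol_slice(i)
        start = rng.uniform(0, spec.box, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        pos[sl] = start + np.outer(np.arange(mol.n_beads), axis * _BOND_R0)
    return top, np.mod(pos, spec.box)


def _hydrophobic_weights(top: SystemTopology) -> np.ndarray:
    """Per-bead attraction weight; SDS tails dominate, CA convex face weaker."""
    w = np.zeros(top.n_beads)
    w[(top.bead_kind == "SDS") & (top.bead_class == "hydrophobic")] = 1.0
    w[(top.bead_kind == "CA") & (top.bead_class == "hydrophobic")] = 0.3
    return w


def run_toy_aggregation(spec: ToySimSpec) -> Trajectory:
    """Overdamped Langevin dynamics of the toy surfactant system.

    Forces: harmonic bonds along each bead chain, a Gaussian attractive well
    between hydrophobic beads (SDS-SDS strongest, SDS-CA intermediate,
    CA-CA weakest), screened Coulomb forces between charged beads (like
    charges repel, Na+ is attracted to the anionic heads) and a soft
    excluded-volume core.  Intramolecular non-bonded pairs are excluded.
    Raises on numerical blow-up.
    """
    rng = np.random.default_rng(spec.seed)
    top, pos = _toy_system(spec, rng)
    n = top.n_beads
    box = np.float32(spec.box)
    pos = pos.astype(np.float32)

    bonds = []
    for i, mol in enumerate(top.molecules):
        sl = top.mol_slice(i)
        bonds.extend((j, j + 1) for j in range(sl.start, sl.stop - 1))
    bi = np.array([b[0] for b in bonds], dtype=int)
    bj = np.array([b[1] for b in bonds], dtype=int)

    w = _hydrophobic_weights(top)
    nb = (top.bead_molecule[:, None] != top.bead_molecule[None, :])
    ra2 = np.float32(spec.attraction_range**2)
    # precomputed pair coefficients (zero for intramolecular pairs)
    att_coef = (2.0 * spec.attraction / ra2 * np.outer(w, w) * nb).astype(
        np.float32
    )
    q = top.bead_charge
    elec_coef = (spec.coulomb_strength * np.outer(q, q) * nb).astype(np.float32)
    core_mask = nb.astype(np.float32)
    inv_lambda = np.float32(1.0 / spec.repulsion_range)
    dt = np.float32(spec.step_size)
    noise_scale = np.float32(
        math.sqrt(2.0 * spec.temperature * spec.step_size)
    )

    frames: list[Frame] = [Frame(top, pos.astype(float), box=spec.box,
                                 time_us=0.0)]
    for step in range(1, spec.n_steps + 1):
        disp = pos[None, :, :] - pos[:, None, :]
        disp -= box * np.round(disp / box)
        r2 = np.einsum("ijk,ijk->ij", disp, disp)
        r = np.sqrt(r2 + np.float32(1e-12))

        # pair force magnitude / r, positive = repulsive
        f_over_r = (
            -att_coef * np.exp(-r2 / ra2)
            + elec_coef * np.exp(-r * inv_lambda) / ((r2 + 1.0) * r)
            + _CORE_K * core_mask * np.maximum(0.0, 1.0 / r - 1.0 / _CORE_RANGE)
        )
        forces = np.einsum("ij,ijk->ik", -f_over_r, disp)

        dbond = pos[bj] - pos[bi]
        dbond -= box * np.round(dbond / box)
        rb = np.sqrt(np.einsum("ij,ij->i", dbond, dbond) + np.float32(1e-12))
        fb = (_BOND_K * (rb - _BOND_R0) / rb)[:, None] * dbond
        np.add.at(forces, bi, fb)
        np.add.at(forces, bj, -fb)

        drift = dt * forces
        # a deterministic step beyond a quarter box voids the integration
        if not np.all(np.isfinite(drift)) or np.max(np.abs(drift)) > box / 4:
            raise RuntimeError(
                f"toy dynamics became unstable at step {step} "
                f"(max step displacement {float(np.max(np.abs(drift))):.3g} A); "
                "reduce step_size or force strengths"
            )
        pos = pos + drift + noise_scale * rng.standard_normal(
            (n, 3), dtype=np.float32
        )
        pos = np.mod(pos, box)
        if step % spec.stride == 0:
            t = spec.total_time_us * step / spec.n_steps
            frames.append(Frame(top, pos.astype(float), box=spec.box,
                                time_us=t))
    return Trajectory(frames)
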