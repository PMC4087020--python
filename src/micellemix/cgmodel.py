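"""Coarse-grained system model: bead topologies, frames, trajectories, PBC geometry.

The coarse-grained mapping follows the Martini-style representation of the
NaCA/SDS system: sodium dodecylsulphate (SDS) is four beads -- three aliphatic
tail beads (C4, C2, C1) and the charged sulfate head (SO3, charge -1) -- and
the cholate anion (CA) is eight beads: the hydrophobic steroid-face beads
R1-R3, the hydroxyl-bearing hydrophilic face RO2/RO3/ROH, a tail bead C1 and
the charged carboxylate OCO (charge -1).  Sodium counterions (NA) and,
optionally, water (W) are single beads.

Internal length unit is the angstrom (GRO files, which are in nm, are
converted on read/write); time is carried in microseconds.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.constants import N_A

__all__ = [
    "BeadTopology",
    "SystemTopology",
    "Frame",
    "Trajectory",
    "TOPOLOGIES",
    "SURFACTANT_KINDS",
    "CHARGED_SURFACTANT_BEADS",
    "minimum_image_displacement",
    "minimum_image_distance",
    "closest_bead_distance",
    "effective_concentration",
    "read_gro",
    "write_gro",
    "read_xyz",
    "write_xyz",
]

HYDROPHOBIC = "hydrophobic"
HYDROPHILIC = "hydrophilic"
CHARGED = "charged"


@dataclass(frozen=True)
class BeadTopology:
    """Bead-level description of one molecule kind.

    ``bead_classes`` labels each site hydrophobic / hydrophilic / charged;
    ``charges`` are in elementary units.
    """

    kind: str
    bead_names: tuple[str, ...]
    bead_classes: tuple[str, ...]
    charges: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.bead_names) == len(self.bead_classes) == len(self.charges)):
            raise ValueError("bead_names, bead_classes and charges must align")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges))


SDS_TOPOLOGY = BeadTopology(
    kind="SDS",
    bead_names=("C4", "C2", "C1", "SO3"),
    bead_classes=(HYDROPHOBIC, HYDROPHOBIC, HYDROPHOBIC, CHARGED),
    charges=(0.0, 0.0, 0.0, -1.0),
)

# The C1 bead of cholate is taken as a hydrophobic tail site; R1-R3 are the
# convex steroid face, RO2/RO3/ROH the concave hydroxyl face, OCO the
# carboxylate.
CA_TOPOLOGY = BeadTopology(
    kind="CA",
    bead_names=("R1", "R2", "R3", "RO2", "RO3", "ROH", "C1", "OCO"),
    bead_classes=(
        HYDROPHOBIC,
        HYDROPHOBIC,
        HYDROPHOBIC,
        HYDROPHILIC,
        HYDROPHILIC,
        HYDROPHILIC,
        HYDROPHOBIC,
        CHARGED,
    ),
    charges=(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, -1.0),
)

NA_TOPOLOGY = BeadTopology(
    kind="NA", bead_names=("NA",), bead_classes=(CHARGED,), charges=(1.0,)
)

W_TOPOLOGY = BeadTopology(
    kind="W", bead_names=("W",), bead_classes=(HYDROPHILIC,), charges=(0.0,)
)

TOPOLOGIES: dict[str, BeadTopology] = {
    t.kind: t for t in (SDS_TOPOLOGY, CA_TOPOLOGY, NA_TOPOLOGY, W_TOPOLOGY)
}

SURFACTANT_KINDS = ("SDS", "CA")
#: (molecule kind, bead name) pairs carrying the anionic charge
CHARGED_SURFACTANT_BEADS = (("SDS", "SO3"), ("CA", "OCO"))


class SystemTopology:
    """Ordered list of molecules making up one simulation system.

    Molecule order is fixed; bead arrays are concatenated in that order.
    """

    def __init__(self, kinds: Sequence[str]):
        unknown = set(kinds) - set(TOPOLOGIES)
        if unknown:
            raise ValueError(f"unknown molecule kinds: {sorted(unknown)}")
        self.molecule_kinds: tuple[str, ...] = tuple(kinds)
        self.molecules: tuple[BeadTopology, ...] = tuple(
            TOPOLOGIES[k] for k in kinds
        )
        counts = np.array([m.n_beads for m in self.molecules], dtype=int)
        self._offsets = np.concatenate([[0], np.cumsum(counts)])
        self.bead_molecule = np.repeat(np.arange(len(kinds)), counts)
        self.bead_kind = np.array(
            [m.kind for m in self.molecules for _ in m.bead_names]
        )
        self.bead_name = np.array(
            [n for m in self.molecules for n in m.bead_names]
        )
        self.bead_class = np.array(
            [c for m in self.molecules for c in m.bead_classes]
        )
        self.bead_charge = np.array(
            [q for m in self.molecules for q in m.charges], dtype=float
        )

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def n_beads(self) -> int:
        return int(self._offsets[-1])

    @property
    def composition(self) -> Counter:
        return Counter(self.molecule_kinds)

    @property
    def net_charge(self) -> float:
        return float(self.bead_charge.sum())

    def mol_slice(self, i: int) -> slice:
        return slice(int(self._offsets[i]), int(self._offsets[i + 1]))

    def molecule_indices(self, kinds: Iterable[str]) -> np.ndarray:
        kinds = tuple(kinds)
        return np.array(
            [i for i, k in enumerate(self.molecule_kinds) if k in kinds],
            dtype=int,
        )

    @property
    def surfactant_indices(self) -> np.ndarray:
        return self.molecule_indices(SURFACTANT_KINDS)

    def bead_indices(
        self,
        kind: str | None = None,
        bead_name: str | None = None,
        bead_class: str | None = None,
    ) -> np.ndarray:
        mask = np.ones(self.n_beads, dtype=bool)
        if kind is not None:
            mask &= self.bead_kind == kind
        if bead_name is not None:
            mask &= self.bead_name == bead_name
        if bead_class is not None:
            mask &= self.bead_class == bead_class
        return np.flatnonzero(mask)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SystemTopology)
            and self.molecule_kinds == other.molecule_kinds
        )

    def __hash__(self) -> int:
        return hash(self.molecule_kinds)


@dataclass
class Frame:
    """One configuration: bead positions (angstrom) in a cubic periodic box."""

    topology: SystemTopology
    positions: np.ndarray
    box: float
    time_us: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (self.topology.n_beads, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"topology with {self.topology.n_beads} beads"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if not (self.box > 0):
            raise ValueError("box edge must be positive")

    def molecule_positions(self, i: int) -> np.ndarray:
        return self.positions[self.topology.mol_slice(i)]

    def wrapped(self) -> "Frame":
        """Return a copy with all coordinates wrapped into [0, box)."""
        return Frame(
            self.topology, np.mod(self.positions, self.box), self.box, self.time_us
        )


@dataclass
class Trajectory:
    """Time-ordered frames over a fixed molecular composition."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = [f.time_us for f in self.frames]
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        top = self.frames[0].topology
        if any(f.topology != top for f in self.frames):
            raise ValueError("composition must be constant across frames")

    @property
    def topology(self) -> SystemTopology:
        return self.frames[0].topology

    @property
    def composition(self) -> Counter:
        return self.topology.composition

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_us for f in self.frames])

    def in_window(self, window: tuple[float, float]) -> list[Frame]:
        t0, t1 = window
        if not t1 > t0:
            raise ValueError(f"empty analysis window {window}")
        out = [f for f in self.frames if t0 <= f.time_us <= t1]
        if not out:
            raise ValueError(f"no frames inside window {window}")
        return out

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image_displacement(p, q, box: float) -> np.ndarray:
    """Displacement q - p under the cubic minimum-image convention."""
    if not box > 0:
        raise ValueError("box edge must be positive")
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(p, q, box: float) -> np.ndarray | float:
    """Euclidean distance under the cubic minimum-image convention.

    Broadcasts over leading axes; the last axis must be the 3 coordinates.
    """
    d = minimum_image_displacement(p, q, box)
    r = np.sqrt(np.sum(d * d, axis=-1))
    return float(r) if np.ndim(r) == 0 else r


def closest_bead_distance(mol_a: np.ndarray, mol_b: np.ndarray, box: float) -> float:
    """Minimum over all bead pairs of the minimum-image distance."""
    a = np.atleast_2d(np.asarray(mol_a, dtype=float))
    b = np.atleast_2d(np.asarray(mol_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("molecules must contain at least one bead")
    d = minimum_image_distance(a[:, None, :], b[None, :, :], box)
    return float(np.min(d))


def effective_concentration(n_molecules: int, box_volume_nm3: float) -> float:
    """Concentration in mM of ``n_molecules`` in a box of ``box_volume_nm3``."""
    if n_molecules < 0:
        raise ValueError("molecule count must be non-negative")
    if not box_volume_nm3 > 0:
        raise ValueError("volume must be positive")
    volume_l = box_volume_nm3 * 1e-24
    return n_molecules / (N_A * volume_l) * 1e3


# ---------------------------------------------------------------------------
# file formats

_GRO_RESNAMES = {"SDS": "SDS", "CA": "CA", "NA": "NA", "W": "W"}


def read_gro(path: str | Path, keep_water: bool = False) -> Frame:
    """Read a single-frame GRO file (nm on disk, angstrom in memory).

    Residue names must be SDS / CA / NA (and W, kept only on request);
    residues are the molecules and must match the bead topologies.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    if u.dimensions is None:
        raise ValueError(f"{path}: GRO file carries no box vector")
    lx, ly, lz = u.dimensions[:3]
    if not (math.isclose(lx, ly, rel_tol=1e-4) and math.isclose(lx, lz, rel_tol=1e-4)):
        raise ValueError(f"{path}: only cubic boxes are supported")
    kinds: list[str] = []
    coords: list[np.ndarray] = []
    for res in u.residues:
        name = res.resname.strip()
        if name == "W" and not keep_water:
            continue
        if name not in TOPOLOGIES:
            raise ValueError(f"{path}: unknown residue name {name!r}")
        top = TOPOLOGIES[name]
        if len(res.atoms) != top.n_beads:
            raise ValueError(
                f"{path}: residue {name} has {len(res.atoms)} beads, "
                f"expected {top.n_beads}"
            )
        kinds.append(name)
        coords.append(res.atoms.positions)  # MDAnalysis reports angstrom
    topology = SystemTopology(kinds)
    return Frame(topology, np.concatenate(coords), box=float(lx))


def write_gro(frame: Frame, path: str | Path, title: str = "micellemix frame") -> None:
    """Write one frame as a GRO file (coordinates converted to nm)."""
    top = frame.topology
    lines = [title, f"{top.n_beads:5d}"]
    atom = 0
    for imol, mol in enumerate(top.molecules):
        pos = frame.molecule_positions(imol) / 10.0  # A -> nm
        for name, xyz in zip(mol.bead_names, pos):
            atom += 1
            lines.append(
                f"{(imol + 1) % 100000:5d}{_GRO_RESNAMES[mol.kind]:<5s}"
                f"{name:>5s}{atom % 100000:5d}"
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            )
    b = frame.box / 10.0
    lines.append(f"{b:10.5f}{b:10.5f}{b:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(traj: Trajectory | Frame, path: str | Path) -> None:
    """Write frames in the extended-XYZ dialect used by this package.

    Per frame: bead count; a comment line ``time_us=<t> box=<edge_A>``; then
    one line per bead: ``kind mol_index bead_name x y z`` (angstrom).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else [traj]
    with open(path, "w") as fh:
        for fr in frames:
            top = fr.topology
            fh.write(f"{top.n_beads}\n")
            fh.write(f"time_us={fr.time_us:.9g} box={fr.box:.9g}\n")
            for i in range(top.n_beads):
                x, y, z = fr.positions[i]
                fh.write(
                    f"{top.bead_kind[i]} {top.bead_molecule[i]} "
                    f"{top.bead_name[i]} {x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_xyz(path: str | Path) -> Trajectory:
    """Read a multi-frame extended-XYZ file written by :func:`write_xyz`."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        header = dict(tok.split("=") for tok in lines[i + 1].split())
        time_us = float(header["time_us"])
        box = float(header["box"])
        kinds_per_mol: dict[int, str] = {}
        pos = np.empty((n, 3))
        for j in range(n):
            kind, mol, _name, x, y, z = lines[i + 2 + j].split()
            kinds_per_mol.setdefault(int(mol), kind)
            pos[j] = (float(x), float(y), float(z))
        kinds = [kinds_per_mol[m] for m in sorted(kinds_per_mol)]
        frames.append(Frame(SystemTopology(kinds), pos, box=box, time_us=time_us))
        i += 2 + n
    return Trajectory(frames)
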