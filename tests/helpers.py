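"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np

from micellemix.cgmodel import Frame


def brute_min_image_distance(p, q, box):
    """Minimum distance over all 27 periodic images."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                shift = np.array([i, j, k]) * box
                best = min(best, float(np.linalg.norm(q + shift - p)))
    return best


_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


def brute_closest_bead_distance(mol_a, mol_b, box):
    """Closest bead pair by explicit enumeration of the 27 images."""
    a = np.asarray(mol_a, float)[:, None, None, :]
    b = np.asarray(mol_b, float)[None, :, None, :] + _SHIFTS[None, None] * box
    return float(np.min(np.linalg.norm(b - a, axis=-1)))


def brute_force_clusters(frame: Frame, cutoff: float):
    """Union-find connected components over exhaustive pair distances."""
    top = frame.topology
    mols = list(top.surfactant_indices)
    parent = list(range(len(mols)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ai in range(len(mols)):
        for bi in range(ai + 1, len(mols)):
            da = frame.molecule_positions(mols[ai])
            db = frame.molecule_positions(mols[bi])
            if brute_closest_bead_distance(da, db, frame.box) < cutoff:
                parent[find(ai)] = find(bi)
    roots = [find(i) for i in range(len(mols))]
    relabel = {}
    return np.array([relabel.setdefault(r, len(relabel)) for r in roots])


def brute_condensed_ions(frame: Frame, cutoff: float):
    """Exhaustive per-ion check against every charged surfactant bead."""
    top = frame.topology
    charged = [
        frame.positions[i]
        for i in range(top.n_beads)
        if (top.bead_kind[i], top.bead_name[i]) in (("SDS", "SO3"), ("CA", "OCO"))
    ]
    n_cond = 0
    for i in top.bead_indices(kind="NA"):
        d = min(
            brute_min_image_distance(frame.positions[i], c, frame.box)
            for c in charged
        )
        if d < cutoff:
            n_cond += 1
    return n_cond


def same_partition(labels_a, labels_b):
    """True when two labelings induce the same partition."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        return False
    map_ab, map_ba = {}, {}
    for a, b in zip(labels_a.tolist(), labels_b.tolist()):
        if map_ab.setdefault(a, b) != b or map_ba.setdefault(b, a) != a:
            return False
    return True
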