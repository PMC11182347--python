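"""Rigid-body superposition and configuration distances.

Distances between configurations of 3-D bead models are measured after
optimal translation + rotation (Kabsch superposition); for clusters of
identical particles an assignment step can additionally match particle
labels so that permutational isomers compare as identical.  Configurations
of non-Cartesian models (e.g. 2-D analytic surfaces) are compared by plain
Euclidean distance.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimally superpose ``mobile`` (n,3) onto ``target`` (n,3).

    Returns the transformed copy of ``mobile``; both inputs untouched.
    """
    mob = mobile - mobile.mean(axis=0)
    tgt = target - target.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt, mob)
    return rot.apply(mob) + target.mean(axis=0)


def aligned_distance(a: np.ndarray, b: np.ndarray, n_beads: int | None = None,
                     permute: bool = False) -> float:
    """RMS-free Euclidean distance between two configurations.

    For 3-D bead systems (``n_beads`` given, or inferred when the flat
    length is divisible by 3 and > 3) the distance is computed after
    optimal rigid-body superposition.  With ``permute=True`` identical
    particles are first matched by a linear assignment on interparticle
    distances (iterated once with re-superposition), which collapses
    permutational isomers of atomic clusters.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("configuration size mismatch")
    if n_beads is None:
        if a.size % 3 == 0 and a.size > 3:
            n_beads = a.size // 3
        else:
            return float(np.linalg.norm(a - b))
    pa = a.reshape(n_beads, 3)
    pb = b.reshape(n_beads, 3)
    if permute:
        moved = kabsch_superpose(pa, pb)
        for _ in range(2):
            row, col = linear_sum_assignment(cdist(moved, pb))
            order = np.empty(n_beads, dtype=int)
            order[col] = row
            pa = pa[order]
            moved = kabsch_superpose(pa, pb)
    moved = kabsch_superpose(pa, pb)
    return float(np.linalg.norm(moved - pb))
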