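"""Basin-hopping global optimisation.

Repeatedly perturb → locally minimise → Metropolis-accept on minimised
energies, recording every distinct minimum visited.  For bead chains the
perturbation is a torsional move (rigid rotation of the chain downstream
of one randomly chosen backbone dihedral, preserving bonds and angles
exactly — the coarse-grained analogue of a side-chain rotamer move); for
models without topology a random Cartesian displacement is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .align import aligned_distance
from .errors import NonConvergenceError
from .localopt import Minimum, minimize_coords, mode_spectrum
from .models import LJCluster, PotentialModel

__all__ = [
    "MinimaSet",
    "basin_hopping",
    "torsional_move",
    "lowest_k",
    "TorsionalMove",
    "CartesianMove",
]

ENERGY_TOL = 1e-6
DIST_TOL = 1e-3


@dataclass
class MinimaSet:
    """Deduplicated minima sorted by energy, plus run provenance."""

    minima: list[Minimum] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    permute_identical: bool = False

    def __len__(self) -> int:
        return len(self.minima)

    def __iter__(self):
        return iter(self.minima)

    @property
    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.minima])

    def contains(self, energy: float, coords: np.ndarray) -> bool:
        return self._find(energy, coords) is not None

    def _find(self, energy: float, coords: np.ndarray) -> int | None:
        es = self.energies
        lo = np.searchsorted(es, energy - ENERGY_TOL)
        hi = np.searchsorted(es, energy + ENERGY_TOL)
        for k in range(lo, hi):
            if self.permute_identical:
                # identical-particle clusters: energy degeneracy marks
                # permutational (and rotational) isomers as duplicates
                return k
            if aligned_distance(self.minima[k].coordinates,
                                coords) <= DIST_TOL:
                return k
        return None

    def add(self, minimum: Minimum) -> bool:
        """Insert keeping energy order; returns True if actually new."""
        if self._find(minimum.energy, minimum.coordinates) is not None:
            return False
        idx = int(np.searchsorted(self.energies, minimum.energy))
        self.minima.insert(idx, minimum)
        return True


class TorsionalMove:
    """Rotate the chain downstream of one random backbone dihedral."""

    def __init__(self, max_angle: float = np.pi / 2):
        self.max_angle = float(max_angle)

    def __repr__(self):
        return f"TorsionalMove(max_angle={self.max_angle:g})"

    def __call__(self, model: PotentialModel, config: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        return torsional_move(model, config, rng, self.max_angle)


class CartesianMove:
    """Uniform random displacement of every coordinate."""

    def __init__(self, max_step: float = 0.4):
        self.max_step = float(max_step)

    def __repr__(self):
        return f"CartesianMove(max_step={self.max_step:g})"

    def __call__(self, model: PotentialModel, config: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
        return config + rng.uniform(-self.max_step, self.max_step,
                                    size=config.size)


def torsional_move(model: PotentialModel, config: np.ndarray,
                   rng: np.random.Generator,
                   max_angle: float = np.pi / 2) -> np.ndarray:
    """One torsional perturbation; bond lengths and angles are preserved.

    Falls back to a Cartesian displacement (with a warning) if the model
    has no dihedral topology.
    """
    x = model.check_configuration(config).copy()
    topo = model.topology
    if topo is None or not topo.dihedrals:
        warnings.warn("model has no dihedral topology; using Cartesian move",
                      stacklevel=2)
        return CartesianMove()(model, x, rng)
    d_idx = int(rng.integers(len(topo.dihedrals)))
    angle = float(rng.uniform(-max_angle, max_angle))
    return rotate_dihedral(model, x, d_idx, angle)


def rotate_dihedral(model: PotentialModel, config: np.ndarray, d_idx: int,
                    angle: float) -> np.ndarray:
    """Rigidly rotate the chain downstream of dihedral ``d_idx`` by ``angle``."""
    x = model.check_configuration(config).copy()
    topo = model.topology
    if angle == 0.0:
        return x
    _, j, k, _ = topo.dihedrals[d_idx]
    pos = x.reshape(-1, 3)
    axis = pos[k] - pos[j]
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(angle * axis)
    downstream = slice(k + 1, None)
    pos[downstream] = rot.apply(pos[downstream] - pos[k]) + pos[k]
    return pos.ravel()


def basin_hopping(model: PotentialModel, start: np.ndarray, n_steps: int,
                  temperature: float = 1.0, move=None, seed: int = 0,
                  rms_tol: float = 1e-6) -> MinimaSet:
    """Run ``n_steps`` of basin-hopping from ``start``.

    Returns every distinct minimum visited (deduplicated by energy within
    1e-6, then aligned configuration distance within 1e-3; identical-
    particle permutations are matched for LJ clusters).  Fully
    reproducible for a fixed seed.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if move is None:
        move = (TorsionalMove() if model.topology is not None
                and model.topology.dihedrals else CartesianMove())
    rng = np.random.default_rng(seed)
    mset = MinimaSet(permute_identical=isinstance(model, LJCluster))

    def characterise(x, e):
        spec = mode_spectrum(model, x)
        return Minimum(energy=e, coordinates=x,
                       log_product_freq=spec.log_product_positive_freq,
                       n_zero_modes=spec.n_zero)

    x_cur, e_cur = minimize_coords(model, start, rms_tol)
    mset.add(characterise(x_cur, e_cur))
    n_accept = 0
    accepted_energies = []
    for _ in range(n_steps):
        x_trial = move(model, x_cur, rng)
        try:
            x_new, e_new = minimize_coords(model, x_trial, rms_tol)
        except NonConvergenceError:
            continue
        if not mset.contains(e_new, x_new):
            mset.add(characterise(x_new, e_new))
        # uniform drawn unconditionally so the random stream is identical
        # across temperatures for a fixed seed
        u = rng.random()
        if temperature == np.inf or e_new <= e_cur:
            accept = True
        elif temperature <= 0:
            accept = False
        else:
            accept = u < np.exp(-(e_new - e_cur) / temperature)
        if accept:
            x_cur, e_cur = x_new, e_new
            n_accept += 1
            accepted_energies.append(e_new)
    mset.provenance = dict(seed=seed, steps=n_steps, temperature=temperature,
                           move=repr(move), n_accepted=n_accept,
                           accepted_energies=accepted_energies)
    return mset


def lowest_k(mset: MinimaSet, k: int) -> MinimaSet:
    """The ``k`` lowest-energy members (all members if fewer), order kept."""
    if k < 1:
        raise ValueError("k must be >= 1")
    out = MinimaSet(minima=list(mset.minima[:k]),
                    provenance=dict(mset.provenance, lowest_k=k),
                    permute_identical=mset.permute_identical)
    return out
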