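"""Shared fixtures: analytic test models and independent oracles.

Oracles here deliberately avoid the package's own samplers: the dense-
grid stationary-point census of the Müller–Brown surface uses scipy's
generic optimisers and root finder directly, so the package results can
be checked against an independent code path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize as sciopt

from ktntools.models import MullerBrown, PotentialModel, make_muller_brown


class Quadratic1D(PotentialModel):
    """E = k/2 x^2 in one dimension (unit mass)."""

    dimension = 1
    name = "quad1d"

    def __init__(self, k: float = 1.0):
        self.k = k

    def energy_gradient(self, x):
        x = self.check_configuration(x)
        return float(0.5 * self.k * x[0] ** 2), np.array([self.k * x[0]])

    def energy(self, x):
        return self.energy_gradient(x)[0]


class DoubleWell1D(PotentialModel):
    """E = x^4 - x^2: minima at +-sqrt(1/2), saddle at 0."""

    dimension = 1
    name = "dw1d"

    def energy_gradient(self, x):
        x = self.check_configuration(x)
        return (float(x[0] ** 4 - x[0] ** 2),
                np.array([4.0 * x[0] ** 3 - 2.0 * x[0]]))

    def energy(self, x):
        return self.energy_gradient(x)[0]


class FourWell2D(PotentialModel):
    """Tilted quartic double-double well: four minima near (+-1, +-1).

    The tilt makes (-1, -1) the global minimum; every pair of edge-
    adjacent corners is connected through an index-1 saddle near the edge
    midpoint, giving a 4-cycle of minima for refinement tests.
    """

    dimension = 2
    name = "fourwell"

    def __init__(self, tilt=(0.3, 0.1)):
        self.tx, self.ty = tilt

    def energy_gradient(self, x):
        x = self.check_configuration(x)
        e = ((x[0] ** 2 - 1.0) ** 2 + (x[1] ** 2 - 1.0) ** 2
             + self.tx * x[0] + self.ty * x[1])
        g = np.array([4.0 * x[0] * (x[0] ** 2 - 1.0) + self.tx,
                      4.0 * x[1] * (x[1] ** 2 - 1.0) + self.ty])
        return float(e), g

    def energy(self, x):
        return self.energy_gradient(x)[0]


@pytest.fixture(scope="session")
def mb() -> MullerBrown:
    return make_muller_brown()


def _cluster_points(points, energies, tol=1e-4):
    out = []
    for p, e in zip(points, energies):
        for q, _ in out:
            if np.linalg.norm(p - q) < tol:
                break
        else:
            out.append((p, e))
    return out


@pytest.fixture(scope="session")
def mb_census(mb):
    """Independent stationary-point census of the Müller-Brown surface.

    Minima: BFGS descent (scipy) from a dense grid.  Saddles: Newton
    root-finding on the gradient from a coarse grid, classified by the
    eigenvalues of a finite-difference Hessian.
    """
    # the conventional plotting region of the surface; stationary points
    # outside it (one high-energy saddle exists near (-1.6, 0.45)) are not
    # part of the classic three-minimum / two-saddle census
    xs = np.linspace(-1.45, 1.1, 60)
    ys = np.linspace(-0.2, 2.0, 60)
    minima = []
    for x0 in xs[::3]:
        for y0 in ys[::3]:
            res = sciopt.minimize(mb.energy, np.array([x0, y0]),
                                  jac=mb.gradient, method="BFGS")
            if res.success and np.linalg.norm(res.x) < 10:
                minima.append((res.x, res.fun))
    minima = _cluster_points([m[0] for m in minima],
                             [m[1] for m in minima], tol=1e-3)
    minima.sort(key=lambda pe: pe[1])

    saddles = []
    for x0 in xs[::4]:
        for y0 in ys[::4]:
            sol = sciopt.root(mb.gradient, np.array([x0, y0]), tol=1e-12)
            if not sol.success or np.linalg.norm(mb.gradient(sol.x)) > 1e-8:
                continue
            if not (xs[0] <= sol.x[0] <= xs[-1]
                    and ys[0] <= sol.x[1] <= ys[-1]):
                continue
            h = 1e-5
            H = np.empty((2, 2))
            for i in range(2):
                dp = np.zeros(2)
                dp[i] = h
                H[:, i] = (mb.gradient(sol.x + dp) - mb.gradient(sol.x - dp)) \
                    / (2 * h)
            lam = np.linalg.eigvalsh(0.5 * (H + H.T))
            if lam[0] < -1e-8 < 1e-8 < lam[1]:
                saddles.append((sol.x, mb.energy(sol.x)))
    saddles = _cluster_points([s[0] for s in saddles],
                              [s[1] for s in saddles], tol=1e-3)
    saddles.sort(key=lambda pe: pe[1])
    return {"minima": minima, "saddles": saddles}


def make_random_network(rng, n_min=None, p_edge=0.6):
    """Random connected KTN with synthetic energies and mode products."""
    from ktntools.ktn import KTN
    from ktntools.localopt import Minimum
    from ktntools.tssearch import TransitionState

    net = KTN()
    if n_min is None:
        n_min = int(rng.integers(2, 9))
    for i in range(n_min):
        coords = rng.normal(size=3)
        m = Minimum(energy=float(rng.uniform(-10, 0)), coordinates=coords,
                    log_product_freq=float(rng.uniform(-2, 2)),
                    n_zero_modes=0)
        net.minima[i] = m
        m.id = i
        net._next_min_id = i + 1
    # spanning tree + extra random edges, ts energy above both minima
    tid = 0
    for j in range(1, n_min):
        i = int(rng.integers(0, j))
        e_ts = max(net.minima[i].energy, net.minima[j].energy) \
            + float(rng.uniform(0.5, 5.0))
        ts = TransitionState(energy=e_ts, coordinates=rng.normal(size=3),
                             negative_eigenvalue=-1.0,
                             log_product_freq=float(rng.uniform(-2, 2)),
                             minus_min_id=i, plus_min_id=j, id=tid)
        net.transition_states[tid] = ts
        tid += 1
    for i in range(n_min):
        for j in range(i + 1, n_min):
            if rng.random() < p_edge - 0.4:
                e_ts = max(net.minima[i].energy, net.minima[j].energy) \
                    + float(rng.uniform(0.5, 5.0))
                ts = TransitionState(
                    energy=e_ts, coordinates=rng.normal(size=3),
                    negative_eigenvalue=-1.0,
                    log_product_freq=float(rng.uniform(-2, 2)),
                    minus_min_id=i, plus_min_id=j, id=tid)
                net.transition_states[tid] = ts
                tid += 1
    net._next_ts_id = tid
    return net
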