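"""Transition-state location and connection.

Double-ended searches relax a doubly-nudged elastic band (DNEB) between
two minima; energy maxima along the relaxed band seed single-ended hybrid
eigenvector-following (HEF), which walks uphill along the lowest Hessian
eigenvector while minimising in the orthogonal complement until an exact
index-1 saddle is reached at RMS gradient 1e-6.  Each converged saddle is
then connected to its two minima by displacing along the negative
eigenvector and following approximate steepest-descent paths.  The
``connect_pair`` cycle (band → converge → connect → recurse on the closest
unconnected gap) is the discrete-path-sampling step used to grow kinetic
transition networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import aligned_distance
from .basinhopping import ENERGY_TOL, MinimaSet
from .errors import (KTNError, NonConvergenceError, PathologyError,
                     SaddleIndexError)
from .localopt import (Minimum, hessian, mode_spectrum, rms_gradient,
                       steepest_descent)
from .models import PotentialModel

__all__ = [
    "TransitionState",
    "dneb_band",
    "hef_converge",
    "connect_saddle",
    "connect_pair",
    "ConnectionResult",
]


@dataclass
class TransitionState:
    """A converged index-1 saddle point."""

    energy: float
    coordinates: np.ndarray
    negative_eigenvalue: float
    log_product_freq: float = 0.0
    minus_min_id: int = -1
    plus_min_id: int = -1
    id: int = -1

    def copy_with_id(self, new_id: int) -> "TransitionState":
        return TransitionState(self.energy, self.coordinates,
                               self.negative_eigenvalue,
                               self.log_product_freq,
                               self.minus_min_id, self.plus_min_id, new_id)


# --------------------------------------------------------------------------
# DNEB
# --------------------------------------------------------------------------

def _tangents(band: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Energy-weighted upwind tangents for the interior images."""
    n = band.shape[0]
    tau = np.zeros((n - 2, band.shape[1]))
    for i in range(1, n - 1):
        e_prev, e_i, e_next = energies[i - 1], energies[i], energies[i + 1]
        d_next = band[i + 1] - band[i]
        d_prev = band[i] - band[i - 1]
        if e_next > e_i > e_prev:
            t = d_next
        elif e_next < e_i < e_prev:
            t = d_prev
        else:
            dmax = max(abs(e_next - e_i), abs(e_prev - e_i))
            dmin = min(abs(e_next - e_i), abs(e_prev - e_i))
            if e_next >= e_prev:
                t = d_next * dmax + d_prev * dmin
            else:
                t = d_next * dmin + d_prev * dmax
        norm = np.linalg.norm(t)
        tau[i - 1] = t / norm if norm > 0 else t
    return tau


def dneb_band(model: PotentialModel, a: Minimum, b: Minimum,
              n_images: int | None = None, k_spring: float = 1.0,
              max_iter: int = 2000, force_tol: float = 1e-3) -> list[np.ndarray]:
    """Relax a doubly-nudged elastic band; return saddle candidates.

    The band holds ``n_images`` movable images on the straight line between
    the endpoint minima (endpoints fixed).  Each image feels the component
    of the true gradient perpendicular to the path tangent, the parallel
    spring force, and the doubly-nudged portion of the perpendicular
    spring force.  Candidates are the interior images that are local
    maxima of the relaxed energy profile.
    """
    xa = model.check_configuration(a.coordinates)
    xb = model.check_configuration(b.coordinates)
    dist = aligned_distance(xa, xb)
    if dist <= 1e-3:
        raise ValueError("endpoints coincide; nothing to connect")
    n_beads = model.n_beads()
    if n_beads is not None and xa.size == 3 * n_beads:
        # superpose b onto a so the straight-line interpolation does not
        # drag beads through each other for trivially rotated conformers
        from .align import kabsch_superpose
        xb = kabsch_superpose(xb.reshape(n_beads, 3),
                              xa.reshape(n_beads, 3)).ravel()
    if n_images is None:
        # image density scaled to the endpoint separation: ~2 images per
        # length unit, at least 11, capped for cost
        n_images = int(np.clip(2.0 * dist, 11, 31))
    n_total = n_images + 2
    t = np.linspace(0.0, 1.0, n_total)[:, None]
    band = (1.0 - t) * xa[None, :] + t * xb[None, :]

    def band_forces(band):
        energies = np.empty(n_total)
        grads = np.empty_like(band)
        for i in range(n_total):
            energies[i], grads[i] = model.energy_gradient(band[i])
        tau = _tangents(band, energies)
        forces = np.zeros_like(band)
        for i in range(1, n_total - 1):
            g = grads[i]
            th = tau[i - 1]
            g_perp = g - np.dot(g, th) * th
            d_next = band[i + 1] - band[i]
            d_prev = band[i] - band[i - 1]
            f_par = k_spring * (np.linalg.norm(d_next)
                                - np.linalg.norm(d_prev)) * th
            f_full = k_spring * (d_next - d_prev)
            f_perp = f_full - np.dot(f_full, th) * th
            gp_norm = np.linalg.norm(g_perp)
            if gp_norm > 1e-12:
                gh = g_perp / gp_norm
                f_star = f_perp - np.dot(f_perp, gh) * gh
            else:
                f_star = f_perp
            forces[i] = -g_perp + f_par + f_star
        return energies, forces

    # FIRE relaxation of the interior images
    dt, dt_max, alpha = 0.01, 0.1, 0.1
    n_up = 0
    vel = np.zeros_like(band)
    max_disp = 0.1
    for _ in range(max_iter):
        energies, forces = band_forces(band)
        fmax = float(np.max(np.abs(forces)))
        if fmax < force_tol:
            break
        power = float(np.sum(vel * forces))
        if power > 0:
            vn = np.linalg.norm(vel)
            fn = np.linalg.norm(forces)
            if fn > 0:
                vel = (1.0 - alpha) * vel + alpha * vn * forces / fn
            n_up += 1
            if n_up > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            vel[:] = 0.0
            dt *= 0.5
            alpha = 0.1
            n_up = 0
        vel += dt * forces
        disp = dt * vel
        norms = np.linalg.norm(disp[1:-1], axis=1)
        big = norms > max_disp
        if np.any(big):
            disp[1:-1][big] *= (max_disp / norms[big])[:, None]
        band[1:-1] += disp[1:-1]
    energies = np.array([model.energy(band[i]) for i in range(n_total)])
    cands = []
    for i in range(1, n_total - 1):
        if energies[i] > energies[i - 1] and energies[i] >= energies[i + 1]:
            cands.append(band[i].copy())
    return cands


# --------------------------------------------------------------------------
# hybrid eigenvector-following
# --------------------------------------------------------------------------

def _lowest_mode(model: PotentialModel, x: np.ndarray,
                 zero_tol: float = 1e-6) -> tuple[float, np.ndarray, np.ndarray,
                                                  np.ndarray]:
    """Eigen-decomposition helper: returns (lambda_min, v_min, lam, V)
    with zero modes (|lambda| <= zero_tol) excluded from the choice."""
    H = hessian(model, x)
    lam, V = np.linalg.eigh(H)
    nonzero = np.abs(lam) > zero_tol
    if not np.any(nonzero):
        raise KTNError("Hessian has no non-zero modes")
    idx = int(np.argmax(nonzero))  # eigenvalues sorted ascending
    return float(lam[idx]), V[:, idx], lam, V


def hef_converge(model: PotentialModel, start: np.ndarray,
                 rms_tol: float = 1e-6, max_iter: int = 300,
                 trust_radius: float = 0.2,
                 zero_tol: float = 1e-6) -> TransitionState:
    """Converge a saddle candidate to an exact index-1 transition state.

    Eigenvector-following step: uphill Newton-like displacement along the
    lowest non-zero Hessian eigenvector, downhill along all others, each
    component capped at the trust radius.  Raises
    :class:`SaddleIndexError` if the walk converges onto a stationary
    point with 0 or >= 2 negative eigenvalues.
    """
    x = model.check_configuration(start).copy()
    eps = 1e-8
    v_prev = None
    push_dir = 1.0
    n_convex = 0
    for it in range(max_iter):
        g = model.gradient(x)
        H = hessian(model, x)
        lam, V = np.linalg.eigh(H)
        nonzero = np.abs(lam) > zero_tol
        if not np.any(nonzero):
            raise KTNError("Hessian has no non-zero modes")
        if v_prev is None or lam[np.argmax(nonzero)] < -zero_tol:
            low = int(np.argmax(nonzero))  # lowest non-zero mode
        else:
            # mode following in convex regions: stay on the mode with the
            # largest overlap with the previous step's eigenvector, so
            # uphill pushes accumulate even when soft modes are nearly
            # degenerate and reorder between iterations
            overlaps = np.abs(V.T @ v_prev)
            overlaps[~nonzero] = -1.0
            low = int(np.argmax(overlaps))
        v = V[:, low]
        if v_prev is not None and float(np.dot(v, v_prev)) < 0:
            v = -v
        v_prev = v
        converged = rms_gradient(g) <= rms_tol
        if converged and lam[low] < -zero_tol:
            break
        if lam[low] > zero_tol:
            # convex region; give up if the uphill walk is not escaping
            n_convex += 1
            if n_convex > 120:
                raise NonConvergenceError(
                    "uphill walk trapped in a convex region", coords=x,
                    energy=model.energy(x), rms=rms_gradient(g))
        else:
            n_convex = 0
        gv = V.T @ g
        step = np.zeros_like(gv)
        for i in range(lam.size):
            if not nonzero[i] or i == low:
                continue
            step[i] = -gv[i] / (abs(lam[i]) + eps)      # downhill subspace
        dx = V @ np.clip(step, -trust_radius, trust_radius)
        g_b = float(np.dot(g, v))
        if lam[low] < -zero_tol:
            up = g_b / (abs(lam[low]) + eps)            # uphill Newton
            up = float(np.clip(up, -trust_radius, trust_radius))
        else:
            # still in a convex region: walk a fixed uphill displacement
            # along the softest mode; the push direction is persistent
            # (eigenvector sign continuity keeps it meaningful)
            if it == 0 and abs(g_b) > 1e-10:
                push_dir = float(np.sign(g_b))
            up = push_dir * 0.5 * trust_radius
        x = x + dx + up * v
    else:
        raise NonConvergenceError("HEF iteration cap reached", coords=x,
                                  energy=model.energy(x),
                                  rms=rms_gradient(model.gradient(x)))
    spec = mode_spectrum(model, x, zero_tol=zero_tol)
    if spec.n_negative != 1:
        raise SaddleIndexError(
            f"converged to index-{spec.n_negative} stationary point",
            n_negative=spec.n_negative, coords=x)
    neg = float(spec.eigenvalues[0])
    return TransitionState(energy=float(model.energy(x)), coordinates=x,
                           negative_eigenvalue=neg,
                           log_product_freq=spec.log_product_positive_freq)


def connect_saddle(model: PotentialModel, ts: TransitionState,
                   delta: float = 1e-2) -> tuple[Minimum, Minimum]:
    """Steepest-descent from either side of a saddle to its two minima."""
    lam_min, v, _, _ = _lowest_mode(model, ts.coordinates)
    if lam_min >= 0:
        raise SaddleIndexError("point has no negative mode", n_negative=0,
                               coords=ts.coordinates)
    minus = steepest_descent(model, ts.coordinates - delta * v)
    plus = steepest_descent(model, ts.coordinates + delta * v)
    return minus, plus


# --------------------------------------------------------------------------
# pairwise connection (discrete path sampling step)
# --------------------------------------------------------------------------

@dataclass
class ConnectionResult:
    """Outcome of :func:`connect_pair`: validated (min, ts, min) triples
    plus whether the two endpoints ended up in one connected component."""

    triples: list[tuple[Minimum, TransitionState, Minimum]] = field(
        default_factory=list)
    connected: bool = False

    def __iter__(self):
        return iter(self.triples)

    def __len__(self):
        return len(self.triples)


def _component(adjacency: dict[int, set[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adjacency.get(u, ()):
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen


def connect_pair(model: PotentialModel, a: Minimum, b: Minimum,
                 max_cycles: int = 10, n_images: int = 11,
                 k_spring: float = 1.0,
                 permute_identical: bool = False) -> ConnectionResult:
    """Iteratively connect two minima through saddles.

    Each cycle picks the closest pair of minima lying in different
    connected components of the growing local network (preferring pairs
    that would join the components of ``a`` and ``b``), runs a DNEB +
    HEF + steepest-descent search on it, and adds all validated triples.
    """
    mset = MinimaSet(permute_identical=permute_identical)
    mset.add(a)
    mset.add(b)
    if aligned_distance(a.coordinates, b.coordinates,
                        permute=permute_identical) <= 1e-3:
        raise ValueError("endpoints are the same minimum")
    triples: list[tuple[Minimum, TransitionState, Minimum]] = []
    ts_seen: list[tuple[float, frozenset]] = []
    attempted: set[tuple[int, int]] = set()

    def key_of(m: Minimum) -> int:
        return mset._find(m.energy, m.coordinates)

    result = ConnectionResult(triples=triples)
    for _ in range(max_cycles):
        adjacency: dict[int, set[int]] = {}
        for (m1, ts, m2) in triples:
            k1, k2 = key_of(m1), key_of(m2)
            adjacency.setdefault(k1, set()).add(k2)
            adjacency.setdefault(k2, set()).add(k1)
        ka, kb = key_of(a), key_of(b)
        comp_a = _component(adjacency, ka)
        if kb in comp_a:
            result.connected = True
            return result
        # candidate cross-component pairs, closest first, a<->b bridging first
        comp_b = _component(adjacency, kb)
        cands = []
        n = len(mset)
        for i in range(n):
            for j in range(i + 1, n):
                ci = _component(adjacency, i)
                if j in ci or (i, j) in attempted:
                    continue
                bridge = 0 if ((i in comp_a and j in comp_b)
                               or (i in comp_b and j in comp_a)) else 1
                d = aligned_distance(mset.minima[i].coordinates,
                                     mset.minima[j].coordinates,
                                     permute=permute_identical)
                cands.append((bridge, d, i, j))
        if not cands:
            return result
        cands.sort()
        _, _, i, j = cands[0]
        attempted.add((i, j))
        mi, mj = mset.minima[i], mset.minima[j]
        try:
            candidates = dneb_band(model, mi, mj, n_images=n_images,
                                   k_spring=k_spring)
        except (ValueError, PathologyError):
            continue
        for xc in candidates[:3]:
            try:
                ts = hef_converge(model, xc)
                m_minus, m_plus = connect_saddle(model, ts)
            except (SaddleIndexError, NonConvergenceError, PathologyError,
                    KTNError):
                continue
            pair_sig = frozenset((round(m_minus.energy, 6),
                                  round(m_plus.energy, 6)))
            dup = any(abs(ts.energy - e0) <= ENERGY_TOL and sig == pair_sig
                      for e0, sig in ts_seen)
            if dup:
                continue
            mset.add(m_minus)
            mset.add(m_plus)
            ts_seen.append((ts.energy, pair_sig))
            triples.append((m_minus, ts, m_plus))
    # final connectivity check after the last cycle
    adjacency = {}
    for (m1, ts, m2) in triples:
        k1, k2 = key_of(m1), key_of(m2)
        adjacency.setdefault(k1, set()).add(k2)
        adjacency.setdefault(k2, set()).add(k1)
    result.connected = key_of(b) in _component(adjacency, key_of(a))
    return result
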