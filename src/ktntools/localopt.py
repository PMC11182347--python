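"""Local minimisation, normal-mode analysis and steepest-descent paths.

The stationary-point primitives of the pipeline.  Minimisation uses a
limited-memory quasi-Newton method (L-BFGS, history 10) driven to an RMS
gradient of 1e-6 in the model's force units.  Normal modes come from a
central finite-difference Hessian of the analytic gradient, mass-weighted,
with eigenvalues within 1e-6 of zero classified as zero modes (rigid-body
translations/rotations for 3-D bead systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .errors import NonConvergenceError, PathologyError
from .models import PotentialModel

__all__ = [
    "Minimum",
    "ModeSpectrum",
    "minimize",
    "minimize_coords",
    "mode_spectrum",
    "hessian",
    "steepest_descent",
    "rms_gradient",
]

DEFAULT_RMS_TOL = 1e-6
ZERO_MODE_TOL = 1e-6
MAX_ITER = 10_000


@dataclass
class Minimum:
    """A converged local minimum of a potential-energy surface."""

    energy: float
    coordinates: np.ndarray
    log_product_freq: float = 0.0
    n_zero_modes: int = 0
    order_params: dict = field(default_factory=dict)
    id: int = -1

    def copy_with_id(self, new_id: int) -> "Minimum":
        return Minimum(self.energy, self.coordinates, self.log_product_freq,
                       self.n_zero_modes, dict(self.order_params), new_id)


@dataclass
class ModeSpectrum:
    """Eigenvalues of the (mass-weighted) Hessian, classified against a
    zero tolerance, plus the log product of positive normal-mode
    frequencies nu_j = sqrt(lambda_j) / (2 pi)."""

    eigenvalues: np.ndarray
    n_negative: int
    n_zero: int
    log_product_positive_freq: float

    @property
    def n_positive(self) -> int:
        return self.eigenvalues.size - self.n_negative - self.n_zero


def rms_gradient(g: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(g))))


def minimize_coords(model: PotentialModel, start: np.ndarray,
                    rms_tol: float = DEFAULT_RMS_TOL,
                    max_iter: int = MAX_ITER) -> tuple[np.ndarray, float]:
    """L-BFGS minimisation returning (coordinates, energy).

    Converged when the RMS gradient is <= ``rms_tol``; raises
    :class:`NonConvergenceError` (carrying the best point) otherwise.
    """
    x0 = model.check_configuration(start)
    # L-BFGS to a loose max-norm gradient first; for small systems a few
    # eigen-regularised Newton steps then polish to the tight RMS target
    # far cheaper than driving L-BFGS all the way down
    x = x0
    schedule = [max(1e-3, rms_tol), max(1e-4, rms_tol), rms_tol, rms_tol]
    for attempt, gtol in enumerate(schedule):
        res = _scipy_minimize(
            model.energy_gradient, x, jac=True, method="L-BFGS-B",
            options=dict(maxcor=20, maxiter=max_iter, maxfun=4 * max_iter,
                         gtol=gtol, ftol=1e-18),
        )
        x = res.x
        g = model.gradient(x)
        if x.size <= 100:
            for _ in range(8):
                if rms_gradient(g) <= rms_tol:
                    break
                H = hessian(model, x)
                lam, V = np.linalg.eigh(H)
                lam = np.where(np.abs(lam) < 1e-9, np.inf, np.abs(lam))
                step = V @ ((V.T @ g) / lam)
                x_new = x - step
                e_new, g_new = model.energy_gradient(x_new)
                if rms_gradient(g_new) >= rms_gradient(g):
                    break  # Newton not contracting; fall back to L-BFGS
                x, g = x_new, g_new
        if rms_gradient(g) <= rms_tol:
            return x, float(model.energy(x))
    raise NonConvergenceError(
        f"L-BFGS stalled at RMS gradient {rms_gradient(g):.3e} (tol {rms_tol:g})",
        coords=x, energy=float(res.fun), rms=rms_gradient(g))


def minimize(model: PotentialModel, start: np.ndarray,
             rms_tol: float = DEFAULT_RMS_TOL,
             max_iter: int = MAX_ITER,
             with_modes: bool = True) -> Minimum:
    """Minimise and return a fully characterised :class:`Minimum`."""
    x, e = minimize_coords(model, start, rms_tol, max_iter)
    if not with_modes:
        return Minimum(energy=e, coordinates=x)
    spec = mode_spectrum(model, x)
    return Minimum(energy=e, coordinates=x,
                   log_product_freq=spec.log_product_positive_freq,
                   n_zero_modes=spec.n_zero)


def hessian(model: PotentialModel, point: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Symmetrised central finite-difference Hessian of the analytic gradient."""
    x = model.check_configuration(point).copy()
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        xi = x[i]
        x[i] = xi + h
        gp = model.gradient(x)
        x[i] = xi - h
        gm = model.gradient(x)
        x[i] = xi
        H[:, i] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def mode_spectrum(model: PotentialModel, point: np.ndarray,
                  zero_tol: float = ZERO_MODE_TOL,
                  mass_weighted: bool = True) -> ModeSpectrum:
    """Normal-mode spectrum at a stationary point.

    Mass weighting divides H_ij by sqrt(m_i m_j); frequencies of positive
    modes are nu_j = sqrt(lambda_j)/(2 pi) in the model's unit system.
    """
    H = hessian(model, point)
    if mass_weighted:
        m = model.coordinate_masses()
        H = H / np.sqrt(np.outer(m, m))
    lam = np.linalg.eigvalsh(H)
    n_negative = int(np.sum(lam < -zero_tol))
    n_zero = int(np.sum(np.abs(lam) <= zero_tol))
    pos = lam[lam > zero_tol]
    log_prod = float(np.sum(np.log(np.sqrt(pos) / (2.0 * np.pi)))) if pos.size else 0.0
    return ModeSpectrum(eigenvalues=lam, n_negative=n_negative, n_zero=n_zero,
                        log_product_positive_freq=log_prod)


def steepest_descent(model: PotentialModel, start: np.ndarray,
                     step_cap: float = 0.05,
                     rms_tol: float = DEFAULT_RMS_TOL,
                     rms_handoff: float = 1e-3,
                     max_steps: int = 100_000,
                     energy_floor: float = -1e10,
                     coord_bound: float = 1e8,
                     with_modes: bool = True) -> Minimum:
    """Follow the negative gradient into the connected minimum.

    Small damped steps (capped displacement) keep the polyline close to
    the true steepest-descent path; once the gradient is small the search
    hands off to :func:`minimize` inside the basin.  Energy is
    non-increasing over accepted steps.
    """
    x = model.check_configuration(start).copy()
    e, g = model.energy_gradient(x)
    alpha = step_cap
    for _ in range(max_steps):
        rms = rms_gradient(g)
        if rms <= rms_handoff:
            break
        gnorm = np.linalg.norm(g)
        step = min(alpha, step_cap / gnorm) if gnorm > 0 else alpha
        x_new = x - step * g
        e_new = model.energy(x_new)
        if e_new <= e:
            x, e = x_new, model.energy(x_new)
            g = model.gradient(x)
            alpha = min(alpha * 1.2, step_cap)
        else:
            alpha *= 0.5
            if alpha < 1e-14:
                break
        if e < energy_floor or np.max(np.abs(x)) > coord_bound:
            raise PathologyError("steepest descent diverged")
    else:
        raise NonConvergenceError("steepest descent step cap exhausted",
                                  coords=x, energy=e, rms=rms_gradient(g))
    return minimize(model, x, rms_tol=rms_tol, with_modes=with_modes)
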