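"""Poincaré map, periodic-solution search and Floquet-type stability.

The Poincaré section is the apex immediately after the left-right reversal
(``zdot = 0`` in flight), with section state
``x = [z, th_F, th_H, thdot_F, thdot_H]``.  A period-one fixed point
``x* = P(x*)`` of the apex return map corresponds to steady trotting.  The
apex height ``z*`` is prescribed externally (it selects the energy level of
the one-parameter orbit family), so the root solve runs over the four roll
coordinates with ``z`` pinned and all five residual components checked:
energy conservation makes the fifth equation consistent at a solution.

Stability is judged from the eigenvalues of the finite-difference Jacobian
``J`` of ``P`` at ``x*``: with ``Lambda = max |lambda_i|``, the orbit is
(marginally) stable iff ``Lambda <= 1 + tol``.  The model is conservative,
so an eigenvalue sits at 1 (the energy-family direction) and asymptotic
stability is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .hybrid import (
    ATOL,
    RTOL,
    TOL_SIM,
    GaitError,
    GaitSequence,
    HalfCycleResult,
    apex_to_apex,
)

__all__ = [
    "PeriodicSolution",
    "poincare_map",
    "find_periodic",
    "poincare_jacobian",
    "stability",
    "analyze_stability",
    "PeriodicSolutionNotFound",
    "JacobianError",
]

RESIDUAL_TOL = 1e-8
STABILITY_TOL = 1e-3
_FAIL_RESIDUAL = 10.0

# deterministic seed ladder for the symmetric model: anti-symmetric apex
# states (th_F = -th_H, thdot_F = -thdot_H) on a coarse grid
_SEED_TH = np.linspace(0.05, 0.6, 8)
_SEED_THDOT = np.linspace(-1.5, 0.0, 7)


class PeriodicSolutionNotFound(RuntimeError):
    def __init__(self, message, best_residual=np.inf):
        super().__init__(message)
        self.best_residual = best_residual


class JacobianError(RuntimeError):
    pass


@dataclass
class PeriodicSolution:
    """A converged period-one trotting solution on the apex section."""

    params: object
    z_star: float
    x_star: np.ndarray
    residual: float
    sequence: GaitSequence
    half_cycle: HalfCycleResult
    tau_half: float
    eigenvalues: np.ndarray | None = None
    Lambda: float | None = None
    stable: bool | None = None

    def to_record(self) -> dict:
        rec = {
            "params": self.params.to_dict(),
            "z_star": self.z_star,
            "x_star": list(self.x_star),
            "residual": self.residual,
            "sequence_id": self.sequence.sequence_id,
            "phase_path": list(self.sequence.phase_path),
            "tau_half": self.tau_half,
        }
        if self.eigenvalues is not None:
            rec["eigenvalues"] = [
                {"re": float(ev.real), "im": float(ev.imag)} for ev in self.eigenvalues
            ]
            rec["Lambda"] = self.Lambda
            rec["stable"] = self.stable
        return rec


def poincare_map(x, p, rtol: float = RTOL, atol: float = ATOL) -> np.ndarray:
    """Apex return map P: one reversed half cycle projected onto the section."""
    return apex_to_apex(x, p, rtol=rtol, atol=atol).x_next


def _full_x(z_star, u):
    return np.array([z_star, u[0], u[1], u[2], u[3]])


def _residual(u, z_star, p, rtol, atol):
    x = _full_x(z_star, u)
    try:
        return x - poincare_map(x, p, rtol=rtol, atol=atol)
    except GaitError:
        return np.full(5, _FAIL_RESIDUAL)


def _solve_from(u0, z_star, p, rtol, atol, symmetric):
    """Damped least-squares refinement of a seed; returns (u, max-residual)."""
    if symmetric:
        def fun(v):
            r = _residual(np.array([v[0], -v[0], v[1], -v[1]]), z_star, p, rtol, atol)
            return r[[1, 3]]
        res = least_squares(
            fun, np.array([u0[0], u0[2]]), method="lm", diff_step=1e-6, xtol=1e-14,
            ftol=1e-14, gtol=1e-14, max_nfev=200,
        )
        u = np.array([res.x[0], -res.x[0], res.x[1], -res.x[1]])
    else:
        def fun(v):
            return _residual(v, z_star, p, rtol, atol)
        res = least_squares(
            fun, np.asarray(u0, dtype=float), method="lm", diff_step=1e-6,
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=300,
        )
        u = res.x
    full = _residual(u, z_star, p, rtol, atol)
    return u, float(np.max(np.abs(full)))


def find_periodic(
    p,
    z_star: float,
    x_guess=None,
    rtol: float = RTOL,
    atol: float = ATOL,
    tol_sim: float = TOL_SIM,
    residual_tol: float = RESIDUAL_TOL,
) -> PeriodicSolution:
    """Find the period-one trotting solution at prescribed apex height.

    If ``x_guess`` (a 5-component apex state or 4-component roll vector) is
    given it seeds the solve (continuation); otherwise a deterministic
    ladder of anti-symmetric seeds is tried, which targets the unique
    solution of the symmetric model and also converges for moderate
    asymmetry.
    """
    if not z_star > 0:
        raise ValueError("z_star must be positive")

    # a continuation guess is tried first; the deterministic anti-symmetric
    # ladder remains as fallback so a stale guess cannot strand the solve
    seeds = []
    if x_guess is not None:
        g = np.asarray(x_guess, dtype=float)
        seeds.append(g[1:] if g.size == 5 else g)
    for th in _SEED_TH:
        for thd in _SEED_THDOT:
            seeds.append(np.array([th, -th, thd, -thd]))

    symmetric = p.is_symmetric
    best = np.inf
    for u0 in seeds:
        first = _residual(u0, z_star, p, rtol, atol)
        if np.max(np.abs(first)) >= _FAIL_RESIDUAL:
            continue
        try:
            u, resid = _solve_from(u0, z_star, p, rtol, atol, symmetric)
        except GaitError:
            continue
        best = min(best, resid)
        if resid < residual_tol:
            x_star = _full_x(z_star, u)
            hc = apex_to_apex(x_star, p, rtol=rtol, atol=atol, tol_sim=tol_sim)
            return PeriodicSolution(
                params=p,
                z_star=z_star,
                x_star=x_star,
                residual=resid,
                sequence=hc.sequence,
                half_cycle=hc,
                tau_half=hc.tau_half,
            )
    raise PeriodicSolutionNotFound(
        f"no periodic solution found (best residual {best:.3g})", best_residual=best
    )


def poincare_jacobian(
    x_star, p, h: float = 1e-6, rtol: float = RTOL, atol: float = ATOL
) -> np.ndarray:
    """Central finite-difference Jacobian of the apex return map at x*."""
    x_star = np.asarray(x_star, dtype=float)
    J = np.empty((5, 5))
    for j in range(5):
        hj = h * max(1.0, abs(x_star[j]))
        xp = x_star.copy()
        xm = x_star.copy()
        xp[j] += hj
        xm[j] -= hj
        try:
            fp = poincare_map(xp, p, rtol=rtol, atol=atol)
            fm = poincare_map(xm, p, rtol=rtol, atol=atol)
        except GaitError as exc:
            raise JacobianError(
                f"perturbed trajectory left the trot automaton (component {j}); "
                "try a smaller step h"
            ) from exc
        J[:, j] = (fp - fm) / (2.0 * hj)
    return J


def stability(J: np.ndarray, tol: float = STABILITY_TOL):
    """Spectral-radius stability test: (Lambda, stable flag).

    Lambda is the largest eigenvalue modulus of J; the orbit is marginally
    stable iff Lambda <= 1 + tol (the tolerance absorbs finite-difference
    noise around the structural unit eigenvalue).
    """
    eig = np.linalg.eigvals(np.asarray(J, dtype=float))
    Lambda = float(np.max(np.abs(eig)))
    return Lambda, Lambda <= 1.0 + tol


def analyze_stability(
    sol: PeriodicSolution,
    h: float = 1e-6,
    tol: float = STABILITY_TOL,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> PeriodicSolution:
    """Fill eigenvalues / Lambda / stable on a converged solution (in place)."""
    J = poincare_jacobian(sol.x_star, sol.params, h=h, rtol=rtol, atol=atol)
    eig = np.linalg.eigvals(J)
    sol.eigenvalues = eig
    sol.Lambda = float(np.max(np.abs(eig)))
    sol.stable = sol.Lambda <= 1.0 + tol
    return sol
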