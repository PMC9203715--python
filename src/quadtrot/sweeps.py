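"""Parameter-space studies over the fore-aft asymmetry plane.

Capabilities:

* ``sequence_map`` — label each cell of an (eps_k, eps_mu) grid with the
  trot sequence (1, 5 or 9) of its periodic solution.
* ``estimate_a`` — the slope ``a`` of the line ``eps_mu = a eps_k`` on
  which the diagonal pair still touches down simultaneously (Sequence 1);
  below the line the fore leg leads (Sequence 5), above it the hind leg
  leads (Sequence 9).
* ``stability_map`` — the maximum Floquet modulus ``Lambda`` per cell.
* ``estimate_b`` — the half-width ``b`` of the unstable band around the
  Sequence-1 line, measured as the eps_mu distance from the line to the
  ``Lambda = 1`` crossing.
* ``symmetric_boundary`` — the critical mean inertia mu0 at which the
  symmetric model loses stability, for comparison with mu0 = kappa + 1/2.

All sweeps are continuation-ordered (each cell seeded from its solved
neighbor, marching away from the symmetric origin), which makes the
outputs deterministic and keeps the solver on the unique solution branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .periodic import (
    PeriodicSolutionNotFound,
    STABILITY_TOL,
    analyze_stability,
    find_periodic,
)

__all__ = [
    "BoundaryEstimate",
    "sequence_map",
    "stability_map",
    "estimate_a",
    "estimate_b",
    "symmetric_boundary",
]

BISECT_TOL = 1e-4  # bisection tolerance in the asymmetry fractions


@dataclass
class BoundaryEstimate:
    """Fit of the Sequence-1 line eps_mu = a eps_k and its unstable band."""

    a: float | None = None
    b: float | None = None
    points: list = field(default_factory=list)  # per-eps_k boundary points
    fit_residual: float | None = None

    def to_record(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "points": [list(map(float, pt)) for pt in self.points],
            "fit_residual": self.fit_residual,
        }


def _solve(p, z_star, guess, rtol, atol):
    return find_periodic(p, z_star, x_guess=guess, rtol=rtol, atol=atol)


def sequence_map(
    base: ModelParams,
    z_star: float,
    eps_k_grid,
    eps_mu_grid,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> pd.DataFrame:
    """Trot-sequence label per cell of the asymmetry grid.

    Returns a long-format DataFrame (eps_k, eps_mu, sequence_id, tau_half);
    sequence_id is -1 where the solver failed.  Cells are solved row-major
    from the origin, each seeded from its left (or lower) neighbor.
    """
    rows = []
    guess_row = None
    for eps_mu in np.asarray(eps_mu_grid, dtype=float):
        guess = guess_row
        first_in_row = True
        for eps_k in np.asarray(eps_k_grid, dtype=float):
            p = base.replace(eps_mu=float(eps_mu), eps_k=float(eps_k))
            try:
                sol = _solve(p, z_star, guess, rtol, atol)
                guess = sol.x_star
                if first_in_row:
                    guess_row = sol.x_star
                    first_in_row = False
                rows.append((eps_k, eps_mu, sol.sequence.sequence_id, sol.tau_half))
            except PeriodicSolutionNotFound:
                rows.append((eps_k, eps_mu, -1, np.nan))
    return pd.DataFrame(rows, columns=["eps_k", "eps_mu", "sequence_id", "tau_half"])


def stability_map(
    base: ModelParams,
    z_star: float,
    eps_k_grid,
    eps_mu_grid,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    h: float = 1e-6,
    tol: float = STABILITY_TOL,
) -> pd.DataFrame:
    """Maximum Floquet modulus Lambda and stability flag per grid cell."""
    rows = []
    guess_row = None
    for eps_mu in np.asarray(eps_mu_grid, dtype=float):
        guess = guess_row
        first_in_row = True
        for eps_k in np.asarray(eps_k_grid, dtype=float):
            p = base.replace(eps_mu=float(eps_mu), eps_k=float(eps_k))
            try:
                sol = _solve(p, z_star, guess, rtol, atol)
                guess = sol.x_star
                if first_in_row:
                    guess_row = sol.x_star
                    first_in_row = False
                sol = analyze_stability(sol, h=h, tol=tol, rtol=rtol, atol=atol)
                rows.append(
                    (eps_k, eps_mu, sol.sequence.sequence_id, sol.Lambda, sol.stable)
                )
            except PeriodicSolutionNotFound:
                rows.append((eps_k, eps_mu, -1, np.nan, False))
    return pd.DataFrame(
        rows, columns=["eps_k", "eps_mu", "sequence_id", "Lambda", "stable"]
    )


def _touchdown_split(p, z_star, guess, rtol, atol):
    """Signed fore-hind touchdown separation of the periodic solution.

    Positive when the fore leg touches first (Sequence-5 side), negative
    when the hind leg leads (Sequence-9 side).  Returns (split, x_star).
    """
    sol = _solve(p, z_star, guess, rtol, atol)
    t = sol.half_cycle.event_times()
    return t["hind_touchdown"] - t["fore_touchdown"], sol.x_star


def estimate_a(
    base: ModelParams,
    z_star: float,
    eps_k_grid=None,
    eps_mu_max: float = 0.45,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    xtol: float = BISECT_TOL,
) -> BoundaryEstimate:
    """Slope of the simultaneous-touchdown (Sequence-1) line through the
    origin of the (eps_k, eps_mu) plane.

    For each eps_k the fore-hind touchdown split changes sign in eps_mu;
    bisection locates the zero, and the slope is the least-squares fit of a
    line through the origin to the boundary points.
    """
    if eps_k_grid is None:
        eps_k_grid = np.linspace(0.05, 0.3, 6)
    points = []
    guess0 = None  # solution at (eps_k, 0), carried across the eps_k grid
    march = 0.02  # continuation step in eps_mu; small jumps keep the solver
    # on the unique branch (large seeding jumps can hop branches)
    for eps_k in np.asarray(eps_k_grid, dtype=float):
        try:
            s_prev, guess0 = _touchdown_split(
                base.replace(eps_k=float(eps_k), eps_mu=0.0), z_star, guess0, rtol, atol
            )
        except PeriodicSolutionNotFound:
            continue
        if s_prev <= 0:
            continue  # hind leg already leads at eps_mu = 0
        # march upward until the split changes sign
        lo, hi = 0.0, None
        g = guess0
        mu = march
        while mu <= eps_mu_max:
            try:
                s, g = _touchdown_split(
                    base.replace(eps_k=float(eps_k), eps_mu=float(mu)),
                    z_star, g, rtol, atol,
                )
            except PeriodicSolutionNotFound:
                break
            if s <= 0:
                hi = mu
                break
            lo = mu
            mu += march
        if hi is None:
            continue  # boundary beyond eps_mu_max at this eps_k
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            try:
                s, g = _touchdown_split(
                    base.replace(eps_k=float(eps_k), eps_mu=mid), z_star, g, rtol, atol
                )
            except PeriodicSolutionNotFound:
                break
            if s > 0:
                lo = mid
            else:
                hi = mid
        points.append((eps_k, 0.5 * (lo + hi)))
    if not points:
        raise PeriodicSolutionNotFound("no Sequence-1 boundary point could be located")
    pts = np.asarray(points)
    a = float(np.sum(pts[:, 0] * pts[:, 1]) / np.sum(pts[:, 0] ** 2))
    resid = float(np.sqrt(np.mean((pts[:, 1] - a * pts[:, 0]) ** 2)))
    return BoundaryEstimate(a=a, points=points, fit_residual=resid)


def _lambda_at(p, z_star, guess, rtol, atol, h):
    sol = _solve(p, z_star, guess, rtol, atol)
    sol = analyze_stability(sol, h=h, rtol=rtol, atol=atol)
    return sol.Lambda, sol.x_star


def estimate_b(
    base: ModelParams,
    z_star: float,
    a: float,
    eps_k_probes=(0.1, 0.2, 0.3),
    eps_mu_max: float = 0.45,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    h: float = 1e-6,
    tol: float = STABILITY_TOL,
    xtol: float = BISECT_TOL,
) -> BoundaryEstimate:
    """Half-width of the unstable band about the Sequence-1 line.

    At each probe eps_k, walks eps_mu away from the line (both directions)
    until Lambda drops through 1 + tol and bisects the crossing; b is the
    mean distance from the line to the crossing.  Returns b = 0 when the
    solution on the line itself is already stable.
    """
    distances = []
    points = []
    guess = None
    for eps_k in np.asarray(eps_k_probes, dtype=float):
        mu_line = a * eps_k
        try:
            lam_line, guess = _lambda_at(
                base.replace(eps_k=float(eps_k), eps_mu=float(mu_line)),
                z_star, guess, rtol, atol, h,
            )
        except PeriodicSolutionNotFound:
            continue
        if lam_line <= 1.0 + tol:
            distances.append(0.0)
            points.append((eps_k, mu_line, 0.0))
            continue
        for direction in (+1.0, -1.0):
            # bracket: expand until a stable point is found inside the box
            lo_d, hi_d = 0.0, None
            step = max(4 * xtol, 0.01)
            g = guess
            d = step
            while True:
                mu = mu_line + direction * d
                if mu < 0.0 or mu > eps_mu_max:
                    break
                try:
                    lam, g = _lambda_at(
                        base.replace(eps_k=float(eps_k), eps_mu=float(mu)),
                        z_star, g, rtol, atol, h,
                    )
                except PeriodicSolutionNotFound:
                    break
                if lam <= 1.0 + tol:
                    hi_d = d
                    break
                lo_d = d
                d *= 2.0
            if hi_d is None:
                # crossing not bracketed inside the parameter box: the band
                # extends beyond it in this direction
                distances.append(np.inf)
                points.append((eps_k, np.nan, np.inf))
                continue
            while hi_d - lo_d > xtol:
                mid = 0.5 * (lo_d + hi_d)
                try:
                    lam, g = _lambda_at(
                        base.replace(
                            eps_k=float(eps_k),
                            eps_mu=float(mu_line + direction * mid),
                        ),
                        z_star, g, rtol, atol, h,
                    )
                except PeriodicSolutionNotFound:
                    break
                if lam > 1.0 + tol:
                    lo_d = mid
                else:
                    hi_d = mid
            d_cross = 0.5 * (lo_d + hi_d)
            distances.append(d_cross)
            points.append((eps_k, mu_line + direction * d_cross, d_cross))
    if not distances:
        raise PeriodicSolutionNotFound("no stability boundary point could be located")
    return BoundaryEstimate(a=a, b=float(np.mean(distances)), points=points)


def symmetric_boundary(
    k0: float,
    kappa_grid,
    z_star: float,
    mu0_range=(0.4, 1.4),
    rtol: float = 1e-9,
    atol: float = 1e-11,
    h: float = 1e-6,
    tol: float = STABILITY_TOL,
    xtol: float = 1e-3,
) -> pd.DataFrame:
    """Critical mu0 of the symmetric model per kappa (Lambda = 1 crossing).

    Returns a DataFrame (kappa, mu0_critical, kappa_plus_half) for
    comparison with the linear-analysis boundary mu0 = kappa + 1/2.
    """
    rows = []
    for kappa in np.asarray(kappa_grid, dtype=float):
        lo, hi = mu0_range
        guess = None

        def lam_of(mu0, g):
            p = ModelParams(mu0=float(mu0), k0=k0, kappa=float(kappa))
            return _lambda_at(p, z_star, g, rtol, atol, h)

        try:
            lam_lo, guess = lam_of(lo, None)
            lam_hi, _ = lam_of(hi, guess)
        except PeriodicSolutionNotFound:
            rows.append((kappa, np.nan, kappa + 0.5))
            continue
        if not (lam_lo <= 1.0 + tol < lam_hi):
            rows.append((kappa, np.nan, kappa + 0.5))
            continue
        g = guess
        while hi - lo > xtol:
            mid = 0.5 * (lo + hi)
            try:
                lam, g = lam_of(mid, g)
            except PeriodicSolutionNotFound:
                break
            if lam <= 1.0 + tol:
                lo = mid
            else:
                hi = mid
        rows.append((kappa, 0.5 * (lo + hi), kappa + 0.5))
    return pd.DataFrame(rows, columns=["kappa", "mu0_critical", "kappa_plus_half"])
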