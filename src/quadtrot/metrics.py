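"""Locomotion characteristics of a periodic trotting solution.

The full gait cycle is two mirrored half cycles (the second is the
left-right reversal of the first, so the vertical motion repeats and the
roll angles flip sign).  All quantities are dimensionless except the roll
amplitudes, reported in degrees:

* ``tau_half`` — apex-to-apex duration (half the gait cycle).
* ``delta_z`` — peak-to-peak vertical COM excursion.
* ``duty_fore`` / ``duty_hind`` — stance duration of a leg over the full
  cycle duration; ``beta0`` is the mean over the four legs, which by
  left-right symmetry equals the fore/hind mean.
* ``grf_max_fore`` / ``grf_max_hind`` — peak leg-spring force magnitude in
  units of total body weight.
* ``roll_amp_fore`` / ``roll_amp_hind`` — max |theta| over the cycle
  (half the peak-to-peak excursion, by the cycle's mirror symmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ITHF, ITHH, IZ
from .periodic import PeriodicSolution

__all__ = ["GaitCharacteristics", "compute_characteristics"]


@dataclass(frozen=True)
class GaitCharacteristics:
    tau_half: float
    delta_z: float
    duty_fore: float
    duty_hind: float
    beta0: float
    grf_max_fore: float
    grf_max_hind: float
    roll_amp_fore: float  # degrees
    roll_amp_hind: float  # degrees

    # row labels match the published characteristics table
    _ROWS = (
        ("Half cycle duration", "tau_half"),
        ("Vertical COM displacement", "delta_z"),
        ("Hind roll amplitude (deg)", "roll_amp_hind"),
        ("Fore maximum GRF", "grf_max_fore"),
        ("Hind maximum GRF", "grf_max_hind"),
        ("Fore duty factor", "duty_fore"),
        ("Hind duty factor", "duty_hind"),
    )

    def to_series(self):
        import pandas as pd

        return pd.Series(
            {label: getattr(self, attr) for label, attr in self._ROWS}
        )


def compute_characteristics(
    sol: PeriodicSolution, params=None, n_samples: int = 4001
) -> GaitCharacteristics:
    """Evaluate the gait characteristics of a converged periodic solution.

    Extrema are taken on a dense sampling of the half cycle's piecewise
    interpolant (segment endpoints included); with thousands of samples of
    these smooth phases the extremum error is far below the 1e-3 level of
    interest.
    """
    p = params if params is not None else sol.params
    if sol.residual > 1e-6:
        raise ValueError("compute_characteristics requires a converged solution")
    hc = sol.half_cycle
    times = hc.event_times()
    cycle = 2.0 * hc.tau_half
    duty_fore = (times["fore_liftoff"] - times["fore_touchdown"]) / cycle
    duty_hind = (times["hind_liftoff"] - times["hind_touchdown"]) / cycle

    zs, th_f, th_h, f_fore, f_hind = [], [], [], [], []
    for seg in hc.segments:
        m = max(8, int(round(n_samples * (seg.t1 - seg.t0) / hc.tau_half)))
        y = seg.sol(np.linspace(seg.t0, seg.t1, m))
        zs.append(y[IZ])
        th_f.append(y[ITHF])
        th_h.append(y[ITHH])
        if seg.contact.fore:
            f_fore.append(np.abs(p.k_F * (y[IZ] + np.sin(y[ITHF]))))
        if seg.contact.hind:
            f_hind.append(np.abs(p.k_H * (y[IZ] - np.sin(y[ITHH]))))
    z = np.concatenate(zs)
    th_F = np.concatenate(th_f)
    th_H = np.concatenate(th_h)

    return GaitCharacteristics(
        tau_half=hc.tau_half,
        delta_z=float(z.max() - z.min()),
        duty_fore=float(duty_fore),
        duty_hind=float(duty_hind),
        beta0=float(0.5 * (duty_fore + duty_hind)),
        grf_max_fore=float(np.max(np.concatenate(f_fore))) if f_fore else 0.0,
        grf_max_hind=float(np.max(np.concatenate(f_hind))) if f_hind else 0.0,
        roll_amp_fore=float(np.degrees(np.max(np.abs(th_F)))),
        roll_amp_hind=float(np.degrees(np.max(np.abs(th_H)))),
    )
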