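"""Writers for trajectories, event logs and solution records.

All outputs embed the resolved model parameters and numerical tolerances so
a run can be reproduced exactly from its artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dynamics import CONTACTS, energy, leg_forces
from .hybrid import HalfCycleResult
from .periodic import PeriodicSolution

__all__ = ["trajectory_frame", "write_trajectory", "write_events", "write_solution"]


def trajectory_frame(hc: HalfCycleResult, params, n: int = 2001) -> pd.DataFrame:
    """Tabulate a half cycle: state, phase, leg forces and energy vs time."""
    tau, states, phases = hc.sample(n)
    rows = []
    for t, q, ph in zip(tau, states, phases):
        contact = CONTACTS[ph]
        f_FL, f_HR = leg_forces(q, contact, params)
        rows.append(
            dict(
                tau=t,
                z=q[0],
                th_F=q[1],
                th_H=q[2],
                zdot=q[3],
                thdot_F=q[4],
                thdot_H=q[5],
                phase=ph,
                f_FL=f_FL,
                f_HR=f_HR,
                energy=energy(q, contact, params),
            )
        )
    return pd.DataFrame(rows)


def write_trajectory(path, hc: HalfCycleResult, params, n: int = 2001) -> None:
    trajectory_frame(hc, params, n).to_csv(path, index=False)


def write_events(path, hc: HalfCycleResult, params=None, config: dict | None = None) -> None:
    rec = {
        "events": [ev.to_record() for ev in hc.events],
        "sequence_id": hc.sequence.sequence_id,
        "phase_path": list(hc.sequence.phase_path),
        "tau_half": hc.tau_half,
        "nonpair_violation": hc.nonpair_violation,
    }
    if params is not None:
        rec["params"] = params.to_dict()
    if config:
        rec["config"] = config
    Path(path).write_text(json.dumps(rec, indent=2))


def write_solution(path, sol: PeriodicSolution, config: dict | None = None) -> None:
    rec = sol.to_record()
    if config:
        rec["config"] = config
    Path(path).write_text(json.dumps(rec, indent=2))
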