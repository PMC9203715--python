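"""Hybrid (event-driven) simulation of one trot half cycle.

A half cycle runs from one apex (zero vertical velocity in flight,
immediately after the left-right reversal) to the next apex, chaining
continuous phases through the touchdown/liftoff automaton: the trajectory
leaves flight when a leg tip reaches the ground (its guard ``r`` crossing
zero from above) and a stance leg releases when its spring returns to
nominal length (``r`` crossing zero from below).  At the closing apex the
left-right reversal ``B_LR = diag(1, -1, -1, 1, -1, -1)`` is applied so the
next half cycle reuses the same diagonal pair.

The admissible phase paths are the nine trot sequences: both legs may touch
down (and lift off) together or in either order, but each leg touches
exactly once and a double-stance interval must exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, sin

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import (
    Contact,
    IZ,
    ITHF,
    ITHH,
    IZD,
    ITHDF,
    ITHDH,
    dynamics_rhs,
    event_values,
    nonpair_event_values,
)

__all__ = [
    "TransitionEvent",
    "GaitSequence",
    "HalfCycleResult",
    "apex_to_apex",
    "reverse_lr",
    "classify_sequence",
    "integrate_phase",
    "GaitError",
    "RunawayTrajectoryError",
    "GeometryViolationError",
    "GaitAssumptionError",
    "SequenceClassificationError",
]

# Default numerical settings: adaptive tolerances tight enough that energy
# drift per half cycle stays below 1e-8 and fixed-point residuals below 1e-8
# are meaningful; tol_sim merges touchdown/liftoff pairs into simultaneous
# events (far below the ~1.7 gait timescale, far above event-location error).
RTOL = 1e-10
ATOL = 1e-12
TOL_SIM = 1e-6
PHASE_TIME_BUDGET = 50.0
_IMMEDIATE_TOL = 1e-9

B_LR = np.array([1.0, -1.0, -1.0, 1.0, -1.0, -1.0])

_SEQUENCE_TABLE = {
    ("F", "DS", "F"): 1,
    ("F", "DS", "FS", "F"): 2,
    ("F", "DS", "HS", "F"): 3,
    ("F", "FS", "DS", "F"): 4,
    ("F", "FS", "DS", "FS", "F"): 5,
    ("F", "FS", "DS", "HS", "F"): 6,
    ("F", "HS", "DS", "F"): 7,
    ("F", "HS", "DS", "FS", "F"): 8,
    ("F", "HS", "DS", "HS", "F"): 9,
}


class GaitError(RuntimeError):
    """Base class for hybrid-simulation failures."""


class RunawayTrajectoryError(GaitError):
    """No guard event occurred within the phase time budget."""


class GeometryViolationError(GaitError):
    """A body rolled to |theta| >= pi/2 during stance."""


class GaitAssumptionError(GaitError):
    """The trajectory left the one-touchdown-per-leg trot automaton."""


class SequenceClassificationError(GaitError):
    """The phase path does not match any of the nine trot sequences."""


@dataclass(frozen=True)
class TransitionEvent:
    """A located guard crossing."""

    tau: float
    kind: str  # apex / fore_touchdown / hind_touchdown / fore_liftoff / hind_liftoff
    phase_before: str
    phase_after: str
    state: np.ndarray

    def to_record(self) -> dict:
        return {
            "tau": self.tau,
            "kind": self.kind,
            "phase_before": self.phase_before,
            "phase_after": self.phase_after,
        }


@dataclass(frozen=True)
class GaitSequence:
    """One of the nine trot foot-pattern classes."""

    sequence_id: int
    phase_path: tuple[str, ...]


@dataclass
class Segment:
    """One continuous phase of the half cycle with its dense interpolant."""

    contact: Contact
    t0: float
    t1: float
    sol: object | None  # scipy OdeSolution; None for zero-length segments

    def __call__(self, t):
        return self.sol(t)


@dataclass
class HalfCycleResult:
    """Apex-to-apex trajectory, its event log and the post-reversal state."""

    x_next: np.ndarray  # apex 5-state [z, th_F, th_H, thdot_F, thdot_H]
    events: list[TransitionEvent]
    segments: list[Segment]
    tau_half: float
    sequence: GaitSequence
    nonpair_violation: bool = False

    def sample(self, n: int = 2001):
        """Sample the trajectory on an (approximately) uniform time grid.

        Returns (tau, states, phases) where states is (n, 6) and phases a
        list of phase labels.  Segment endpoints are always included so no
        phase is skipped.
        """
        taus, states, phases = [], [], []
        total = self.tau_half
        for seg in self.segments:
            dur = seg.t1 - seg.t0
            m = max(2, int(round(n * dur / total)) + 1)
            t = np.linspace(seg.t0, seg.t1, m)
            y = seg.sol(t) if seg.sol is not None else None
            if y is None:
                continue
            taus.append(t)
            states.append(y.T)
            phases.extend([seg.contact.phase] * m)
        return np.concatenate(taus), np.vstack(states), phases

    def event_times(self) -> dict[str, float]:
        return {ev.kind: ev.tau for ev in self.events}


def reverse_lr(q: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Apply the left-right reversal B_LR at an apex state.

    Negates both roll angles and roll rates, leaving z and zdot unchanged;
    an involution.  Requires |zdot| < tol.
    """
    if abs(q[IZD]) >= tol:
        raise ValueError(f"reverse_lr called off the apex section (zdot={q[IZD]:g})")
    return B_LR * q


def _guard_fns(p):
    def r_fore(t, q):
        return q[IZ] + sin(q[ITHF])

    def r_hind(t, q):
        return q[IZ] - sin(q[ITHH])

    def r_apex(t, q):
        return q[IZD]

    return {"fore": r_fore, "hind": r_hind, "apex": r_apex}


def _guard_rate(kind: str, q: np.ndarray, qdot: np.ndarray) -> float:
    if kind == "fore":
        return qdot[IZ] + cos(q[ITHF]) * qdot[ITHF]
    if kind == "hind":
        return qdot[IZ] - cos(q[ITHH]) * qdot[ITHH]
    return qdot[IZD]


def integrate_phase(
    q0: np.ndarray,
    contact: Contact,
    p,
    guards: list[tuple[str, str, int]],
    t0: float = 0.0,
    rtol: float = RTOL,
    atol: float = ATOL,
    t_budget: float = PHASE_TIME_BUDGET,
):
    """Integrate one continuous phase until the first guard crossing.

    ``guards`` is a list of (event_kind, guard_name, direction) with
    guard_name in {"fore", "hind", "apex"} and direction -1 (descending
    crossing, touchdowns/apex) or +1 (ascending, liftoffs).

    Returns (ode_result, event_kind, t_event, q_event).  Raises
    RunawayTrajectoryError if no guard triggers within ``t_budget`` and
    GeometryViolationError if a stance body reaches |theta| >= pi/2.
    """
    fns = _guard_fns(p)
    event_fs = []
    for kind, name, direction in guards:
        f = fns[name]
        # each guard needs its own function object for scipy's bookkeeping
        g = (lambda ff: lambda t, q: ff(t, q))(f)
        g.terminal = True
        g.direction = direction
        event_fs.append(g)

    res = solve_ivp(
        lambda t, q: dynamics_rhs(q, contact, p),
        (t0, t0 + t_budget),
        q0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=event_fs,
    )
    if not res.success:
        raise GaitError(f"integrator failure: {res.message}")
    if (contact.fore or contact.hind) and np.max(np.abs(res.y[[ITHF, ITHH]])) >= np.pi / 2:
        raise GeometryViolationError("body rolled past pi/2 during stance")
    hits = [
        (t_ev[0], i)
        for i, t_ev in enumerate(res.t_events)
        if len(t_ev) > 0
    ]
    if not hits:
        raise RunawayTrajectoryError(
            f"no event within time budget {t_budget} in phase {contact.phase}"
        )
    t_event, idx = min(hits)
    q_event = res.sol(t_event)
    return res, guards[idx][0], t_event, q_event


def _immediate_guard(q, qdot, guards, p):
    """Return the kind of a guard that is already at zero and moving through
    it in the admissible direction (simultaneous-event handling)."""
    fns = _guard_fns(p)
    for kind, name, direction in guards:
        v = fns[name](0.0, q)
        if abs(v) < _IMMEDIATE_TOL and direction * _guard_rate(name, q, qdot) > 0:
            return kind
    return None


def apex_to_apex(
    x: np.ndarray,
    p,
    rtol: float = RTOL,
    atol: float = ATOL,
    tol_sim: float = TOL_SIM,
    t_budget: float = PHASE_TIME_BUDGET,
) -> HalfCycleResult:
    """Simulate one half cycle from a post-reversal apex state.

    ``x = [z, th_F, th_H, thdot_F, thdot_H]`` (zdot = 0 on the section).
    The trajectory is integrated through the phase automaton until the next
    apex, the phase path is classified into one of the nine trot sequences,
    and the left-right reversal is applied to produce ``x_next``.
    """
    x = np.asarray(x, dtype=float)
    q = np.array([x[0], x[1], x[2], 0.0, x[3], x[4]])
    _, r_F, r_H = event_values(q)
    if r_F <= 0 or r_H <= 0:
        raise GaitError(
            f"flight not admissible at apex state (r_F={r_F:g}, r_H={r_H:g})"
        )

    fore, hind = "pre", "pre"  # leg contact progress: pre -> down -> post
    t = 0.0
    events: list[TransitionEvent] = []
    segments: list[Segment] = []
    nonpair_min = np.inf

    while True:
        contact = Contact(fore == "down", hind == "down")
        guards: list[tuple[str, str, int]] = []
        if fore == "pre":
            guards.append(("fore_touchdown", "fore", -1))
        elif fore == "down":
            guards.append(("fore_liftoff", "fore", +1))
        if hind == "pre":
            guards.append(("hind_touchdown", "hind", -1))
        elif hind == "down":
            guards.append(("hind_liftoff", "hind", +1))
        in_flight = contact.phase == "F"
        touched = (fore != "pre") or (hind != "pre")
        if in_flight and touched:
            guards.append(("apex", "apex", -1))
            if fore == "post":
                guards.append(("fore_retouch", "fore", -1))
            if hind == "post":
                guards.append(("hind_retouch", "hind", -1))

        qdot = dynamics_rhs(q, contact, p)
        kind = _immediate_guard(q, qdot, guards, p)
        if kind is not None:
            t_event, q_event = t, q.copy()
        else:
            res, kind, t_event, q_event = integrate_phase(
                q, contact, p, guards, t0=t, rtol=rtol, atol=atol, t_budget=t_budget
            )
            segments.append(Segment(contact, t, t_event, res.sol))
            r_fr, r_hl = nonpair_event_values(q_event)
            samp = res.sol(np.linspace(t, t_event, 64))
            np_vals = np.minimum(
                samp[IZ] - np.sin(samp[ITHF]), samp[IZ] + np.sin(samp[ITHH])
            )
            nonpair_min = min(nonpair_min, float(np_vals.min()), r_fr, r_hl)

        if kind.endswith("_retouch"):
            raise GaitAssumptionError(
                "aerial re-contact of a lifted leg before the closing apex"
            )

        phase_before = contact.phase
        if kind == "fore_touchdown":
            fore = "down"
        elif kind == "fore_liftoff":
            fore = "post"
        elif kind == "hind_touchdown":
            hind = "down"
        elif kind == "hind_liftoff":
            hind = "post"
        phase_after = Contact(fore == "down", hind == "down").phase
        events.append(
            TransitionEvent(t_event, kind, phase_before, phase_after, q_event.copy())
        )
        t, q = t_event, q_event
        if kind == "apex":
            break

    sequence = classify_sequence(events, tol_sim=tol_sim)
    q_end = q.copy()
    q_end[IZD] = 0.0  # apex located to event tolerance; pin the section exactly
    q_plus = reverse_lr(q_end, tol=1e-7)
    x_next = np.array([q_plus[IZ], q_plus[ITHF], q_plus[ITHH], q_plus[ITHDF], q_plus[ITHDH]])
    return HalfCycleResult(
        x_next=x_next,
        events=events,
        segments=segments,
        tau_half=t,
        sequence=sequence,
        nonpair_violation=bool(nonpair_min < 0.0),
    )


def classify_sequence(events, tol_sim: float = TOL_SIM) -> GaitSequence:
    """Map a half cycle's event log to one of the nine trot sequences.

    Touchdowns (liftoffs) of the two legs separated by less than ``tol_sim``
    are merged into a simultaneous event, collapsing the intervening
    single-stance sliver into a direct flight<->double-stance transition.
    """
    times: dict[str, float] = {}
    for ev in events:
        if ev.kind in times and ev.kind != "apex":
            raise SequenceClassificationError(f"repeated event {ev.kind}")
        times[ev.kind] = ev.tau
    needed = {"fore_touchdown", "hind_touchdown", "fore_liftoff", "hind_liftoff"}
    if not needed <= set(times):
        raise SequenceClassificationError(
            f"half cycle missing events: {sorted(needed - set(times))}"
        )
    td_F, td_H = times["fore_touchdown"], times["hind_touchdown"]
    lo_F, lo_H = times["fore_liftoff"], times["hind_liftoff"]
    if lo_F < td_H - tol_sim or lo_H < td_F - tol_sim:
        raise SequenceClassificationError(
            "no double-stance interval: one leg lifted before the other touched"
        )
    path = ["F"]
    if abs(td_F - td_H) <= tol_sim:
        path.append("DS")
    elif td_F < td_H:
        path += ["FS", "DS"]
    else:
        path += ["HS", "DS"]
    if abs(lo_F - lo_H) <= tol_sim:
        pass
    elif lo_H < lo_F:
        path.append("FS")
    else:
        path.append("HS")
    path.append("F")
    key = tuple(path)
    if key not in _SEQUENCE_TABLE:
        raise SequenceClassificationError(f"phase path {key} not a trot sequence")
    return GaitSequence(_SEQUENCE_TABLE[key], key)
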