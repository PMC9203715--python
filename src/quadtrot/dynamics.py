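"""Continuous dynamics of the transverse-plane trotting model.

State vector (dimensionless): ``q = [z, th_F, th_H, zdot, thdot_F, thdot_H]``
where ``z = (Z - L0)/D`` is the COM height offset and ``th_F``, ``th_H`` are
the roll angles of the fore and hind bodies measured from horizontal.  Time
is dimensionless, ``tau = t / sqrt(D/g)``.

Between apex reversals only the diagonal pair FL (fore-left, lever arm
``d = +1``) and HR (hind-right, ``d = -1``) can be in stance.  A leg in
stance exerts the spring force ``f = k (z + d sin th)`` (negative in
compression, in units of total body weight); in swing it is force-free,
stays vertical at its nominal length, and its tip height is ``r = z +
d sin th``.  Touchdown and liftoff both occur at ``r = 0``, so the model is
energy conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, sin

import numpy as np

__all__ = [
    "Contact",
    "FLIGHT",
    "FORE_STANCE",
    "HIND_STANCE",
    "DOUBLE_STANCE",
    "full_state",
    "leg_forces",
    "dynamics_rhs",
    "event_values",
    "energy",
]

# Index layout of the 6-component state vector.
IZ, ITHF, ITHH, IZD, ITHDF, ITHDH = range(6)


@dataclass(frozen=True)
class Contact:
    """Which legs of the active diagonal pair are in stance."""

    fore: bool = False
    hind: bool = False

    @property
    def phase(self) -> str:
        """Phase label: F (flight), FS (fore stance), HS (hind stance) or
        DS (double stance)."""
        if self.fore and self.hind:
            return "DS"
        if self.fore:
            return "FS"
        if self.hind:
            return "HS"
        return "F"


FLIGHT = Contact(False, False)
FORE_STANCE = Contact(True, False)
HIND_STANCE = Contact(False, True)
DOUBLE_STANCE = Contact(True, True)

CONTACTS = {"F": FLIGHT, "FS": FORE_STANCE, "HS": HIND_STANCE, "DS": DOUBLE_STANCE}


def full_state(z, th_F, th_H, zdot=0.0, thdot_F=0.0, thdot_H=0.0) -> np.ndarray:
    """Assemble a state vector ``[z, th_F, th_H, zdot, thdot_F, thdot_H]``."""
    return np.array([z, th_F, th_H, zdot, thdot_F, thdot_H], dtype=float)


def leg_forces(q, contact: Contact, p) -> tuple[float, float]:
    """Dimensionless spring forces (f_FL, f_HR) of the active pair.

    Forces are in units of total body weight and are negative when the
    spring is compressed; a swing leg contributes zero.
    """
    f_FL = p.k_F * (q[IZ] + sin(q[ITHF])) if contact.fore else 0.0
    f_HR = p.k_H * (q[IZ] - sin(q[ITHH])) if contact.hind else 0.0
    return f_FL, f_HR


def dynamics_rhs(q, contact: Contact, p) -> np.ndarray:
    """Time derivative of the state under the given contact condition.

    Vertical:  zdd = -(f_FL + f_HR) - 1.
    Roll:      mu_F thdd_F = -( f_FL cos th_F + k_B (th_F - th_H))
               mu_H thdd_H = -(-f_HR cos th_H + k_B (th_H - th_F))
    (the FL leg acts with lever arm +1 on the fore body, HR with -1 on the
    hind body).
    """
    f_FL, f_HR = leg_forces(q, contact, p)
    k_B = p.k_B
    zdd = -(f_FL + f_HR) - 1.0
    thdd_F = -(f_FL * cos(q[ITHF]) + k_B * (q[ITHF] - q[ITHH])) / p.mu_F
    thdd_H = -(-f_HR * cos(q[ITHH]) + k_B * (q[ITHH] - q[ITHF])) / p.mu_H
    return np.array([q[IZD], q[ITHDF], q[ITHDH], zdd, thdd_F, thdd_H])


def event_values(q) -> tuple[float, float, float]:
    """Guard values ``(r_A, r_F, r_H)``.

    ``r_A = zdot`` vanishes at an apex; ``r_F = z + sin th_F`` and
    ``r_H = z - sin th_H`` vanish at touchdown/liftoff of legs FL and HR.
    """
    return q[IZD], q[IZ] + sin(q[ITHF]), q[IZ] - sin(q[ITHH])


def nonpair_event_values(q) -> tuple[float, float]:
    """Tip heights of the inactive pair (FR, HL), monitored diagnostically.

    These use the mirrored lever arms: ``r_FR = z - sin th_F``,
    ``r_HL = z + sin th_H``.  A negative value means the model's
    one-pair-per-half-cycle assumption is violated by the other pair.
    """
    return q[IZ] - sin(q[ITHF]), q[IZ] + sin(q[ITHH])


def energy(q, contact: Contact, p) -> float:
    """Total dimensionless mechanical energy.

    Kinetic + gravitational (zero at z = 0) + torsional-spring + engaged
    leg-spring energies.  Conserved along trajectories and continuous across
    touchdown/liftoff because springs engage at zero compression.
    """
    _, r_F, r_H = event_values(q)
    E = (
        0.5 * q[IZD] ** 2
        + 0.5 * p.mu_F * q[ITHDF] ** 2
        + 0.5 * p.mu_H * q[ITHDH] ** 2
        + q[IZ]
        + 0.5 * p.k_B * (q[ITHF] - q[ITHH]) ** 2
    )
    if contact.fore:
        E += 0.5 * p.k_F * r_F**2
    if contact.hind:
        E += 0.5 * p.k_H * r_H**2
    return E
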