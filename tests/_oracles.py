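"""Independent brute-force oracles used to cross-check the hybrid simulator.

These deliberately avoid the package's adaptive event-driven integration
path: a fixed-step classical RK4 marches the dynamics, guard crossings are
detected by sign change between steps and refined by bisection on the
sub-step, and the flight phase additionally has a closed-form solution
(quadratic in z, linear 2-DOF oscillation in the roll angles).
"""

from __future__ import annotations

import numpy as np

from quadtrot.dynamics import Contact, dynamics_rhs, event_values


def rk4_step(q, h, contact, p):
    f = lambda y: dynamics_rhs(y, contact, p)
    k1 = f(q)
    k2 = f(q + 0.5 * h * k1)
    k3 = f(q + 0.5 * h * k2)
    k4 = f(q + h * k3)
    return q + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _guard(q, which):
    r_a, r_f, r_h = event_values(q)
    return {"fore": r_f, "hind": r_h, "apex": r_a}[which]


def half_cycle_events(x, p, h=1e-4, t_max=10.0, n_bisect=60):
    """Event times of one apex-to-apex half cycle, by fixed-step RK4 with
    sign-change detection and sub-step bisection.

    Returns a dict kind -> time.  Assumes the trajectory follows one of the
    nine trot sequences (each leg touches down and lifts off once).
    """
    x = np.asarray(x, dtype=float)
    q = np.array([x[0], x[1], x[2], 0.0, x[3], x[4]])
    fore = hind = False
    fore_done = hind_done = False
    t = 0.0
    events = {}
    while t < t_max:
        contact = Contact(fore, hind)
        qn = rk4_step(q, h, contact, p)
        trig = None
        checks = (
            ("fore", -1, (not fore) and (not fore_done)),
            ("fore", +1, fore),
            ("hind", -1, (not hind) and (not hind_done)),
            ("hind", +1, hind),
            ("apex", -1, fore_done and hind_done and not fore and not hind),
        )
        qdot = dynamics_rhs(q, contact, p)
        for which, direction, active in checks:
            if not active:
                continue
            g0 = _guard(q, which)
            # a guard already at zero and moving through it fires at once
            # (simultaneous touchdowns/liftoffs of the pair)
            rate = {
                "fore": qdot[0] + np.cos(q[1]) * qdot[1],
                "hind": qdot[0] - np.cos(q[2]) * qdot[2],
                "apex": qdot[3],
            }[which]
            if abs(g0) < 1e-9 and direction * rate > 0:
                trig = (which, direction, 0.0)
                break
            g1 = _guard(qn, which)
            crossed = (direction == -1 and g0 > 0 >= g1) or (
                direction == +1 and g0 < 0 <= g1
            )
            if crossed:
                a, b = 0.0, h
                for _ in range(n_bisect):
                    m = 0.5 * (a + b)
                    gm = _guard(rk4_step(q, m, contact, p), which)
                    if (direction == -1 and gm > 0) or (direction == +1 and gm < 0):
                        a = m
                    else:
                        b = m
                trig = (which, direction, 0.5 * (a + b))
                break
        if trig is None:
            q, t = qn, t + h
            continue
        which, direction, dt = trig
        q = rk4_step(q, dt, contact, p)
        t += dt
        if which == "fore" and direction == -1:
            fore = True
            events["fore_touchdown"] = t
        elif which == "fore":
            fore, fore_done = False, True
            events["fore_liftoff"] = t
        elif which == "hind" and direction == -1:
            hind = True
            events["hind_touchdown"] = t
        elif which == "hind":
            hind, hind_done = False, True
            events["hind_liftoff"] = t
        else:
            events["apex"] = t
            return events
    raise RuntimeError("oracle ran out of time without reaching the apex")


def flight_closed_form(q0, p, t):
    """Closed-form flight trajectory (array of states at times t).

    In flight the vertical motion is ballistic and the roll pair obeys the
    linear system mu_F a'' = -k_B (a - b), mu_H b'' = -k_B (b - a), solved
    by modal decomposition.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    z0, a0, b0, zd0, ad0, bd0 = q0
    z = z0 + zd0 * t - 0.5 * t**2
    zd = zd0 - t
    kB = p.k_B
    M = np.array([[-kB / p.mu_F, kB / p.mu_F], [kB / p.mu_H, -kB / p.mu_H]])
    w, V = np.linalg.eig(M)  # eigenvalues 0 and -(kB/muF + kB/muH)
    Vi = np.linalg.inv(V)
    c0 = Vi @ np.array([a0, b0])
    cd0 = Vi @ np.array([ad0, bd0])
    modes = np.empty((2, t.size))
    dmodes = np.empty((2, t.size))
    for i in range(2):
        if abs(w[i]) < 1e-14:
            modes[i] = c0[i] + cd0[i] * t
            dmodes[i] = cd0[i]
        else:
            om = np.sqrt(-w[i])
            modes[i] = c0[i] * np.cos(om * t) + cd0[i] / om * np.sin(om * t)
            dmodes[i] = -c0[i] * om * np.sin(om * t) + cd0[i] * np.cos(om * t)
    ab = V @ modes
    abd = V @ dmodes
    return np.vstack([z, ab[0], ab[1], zd, abd[0], abd[1]]).T
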