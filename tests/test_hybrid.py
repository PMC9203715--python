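import numpy as np
import pytest

from quadtrot.dynamics import FLIGHT, energy, full_state
from quadtrot.hybrid import (
    SequenceClassificationError,
    TransitionEvent,
    apex_to_apex,
    classify_sequence,
    integrate_phase,
    reverse_lr,
)
from quadtrot.params import ModelParams

from _oracles import flight_closed_form, half_cycle_events


class TestReversal:
    def test_sign_flip_definition(self):
        q = np.array([0.06, 0.1, -0.2, 0.0, 0.3, -0.4])
        np.testing.assert_allclose(
            reverse_lr(q), [0.06, -0.1, 0.2, 0.0, -0.3, 0.4]
        )

    def test_involution(self):
        q = np.array([0.05, 0.2, 0.1, 0.0, -0.6, 0.4])
        np.testing.assert_allclose(reverse_lr(reverse_lr(q)), q)

    def test_rejected_off_apex(self):
        with pytest.raises(ValueError, match="apex"):
            reverse_lr(np.array([0.05, 0.2, 0.1, 0.3, -0.6, 0.4]))


def test_ballistic_flight_touchdown_time():
    """Free fall with level bodies: touchdown at z = 0 after sqrt(2 z0)."""
    p = ModelParams(mu0=0.62, k0=1.5, kappa=0.2)
    q0 = full_state(0.06, 0.0, 0.0)
    _, kind, t_event, q_event = integrate_phase(
        q0, FLIGHT, p, [("fore_touchdown", "fore", -1)]
    )
    assert kind == "fore_touchdown"
    assert t_event == pytest.approx(np.sqrt(2 * 0.06), abs=1e-10)
    assert q_event[0] == pytest.approx(0.0, abs=1e-10)


def test_flight_phase_matches_closed_form():
    """The flight dynamics (ballistic z, linear 2-DOF roll oscillation)
    agree with the modal closed-form solution."""
    p = ModelParams(mu0=0.62, k0=1.5, kappa=0.2, eps_mu=0.12)
    q0 = full_state(0.2, 0.25, -0.15, 0.1, -0.9, 0.5)
    res, _, t_event, _ = integrate_phase(
        q0, FLIGHT, p, [("fore_touchdown", "fore", -1)]
    )
    ts = np.linspace(0.0, t_event, 7)
    exact = flight_closed_form(q0, p, ts)
    np.testing.assert_allclose(res.sol(ts).T, exact, atol=1e-9)


class TestApexToApex:
    def test_symmetric_model_simultaneous_touchdown(self, dog_sym_solution):
        hc = dog_sym_solution.half_cycle
        times = hc.event_times()
        assert hc.sequence.sequence_id == 1
        assert abs(times["fore_touchdown"] - times["hind_touchdown"]) < 1e-9
        assert abs(times["fore_liftoff"] - times["hind_liftoff"]) < 1e-9

    def test_energy_conserved_over_half_cycle(self, dog_solution):
        p = dog_solution.params
        hc = dog_solution.half_cycle
        tau, states, phases = hc.sample(501)
        from quadtrot.dynamics import CONTACTS

        energies = [
            energy(q, CONTACTS[ph], p) for q, ph in zip(states, phases)
        ]
        assert np.ptp(energies) < 1e-8

    def test_deterministic(self, dog, dog_solution):
        p, _ = dog
        a = apex_to_apex(dog_solution.x_star, p)
        b = apex_to_apex(dog_solution.x_star, p)
        np.testing.assert_allclose(a.x_next, b.x_next, atol=1e-10)
        assert a.tau_half == b.tau_half

    def test_flight_inadmissible_apex_rejected(self, dog):
        p, _ = dog
        from quadtrot.hybrid import GaitError

        with pytest.raises(GaitError, match="admissible"):
            apex_to_apex(np.array([0.01, -0.6, 0.0, 0.0, 0.0]), p)

    def test_no_nonpair_violation_on_presets(self, dog_solution, horse_solution):
        assert not dog_solution.half_cycle.nonpair_violation
        assert not horse_solution.half_cycle.nonpair_violation


def _events(times):
    evs = []
    for kind, tau in sorted(times.items(), key=lambda kv: kv[1]):
        evs.append(TransitionEvent(tau, kind, "", "", None))
    return evs


class TestClassification:
    @pytest.mark.parametrize(
        "times, expected",
        [
            (dict(fore_touchdown=0.1, hind_touchdown=0.1, fore_liftoff=0.9, hind_liftoff=0.9), 1),
            (dict(fore_touchdown=0.1, hind_touchdown=0.1, fore_liftoff=0.9, hind_liftoff=0.8), 2),
            (dict(fore_touchdown=0.1, hind_touchdown=0.1, fore_liftoff=0.8, hind_liftoff=0.9), 3),
            (dict(fore_touchdown=0.1, hind_touchdown=0.2, fore_liftoff=0.9, hind_liftoff=0.9), 4),
            (dict(fore_touchdown=0.1, hind_touchdown=0.2, fore_liftoff=0.9, hind_liftoff=0.8), 5),
            (dict(fore_touchdown=0.1, hind_touchdown=0.2, fore_liftoff=0.8, hind_liftoff=0.9), 6),
            (dict(fore_touchdown=0.2, hind_touchdown=0.1, fore_liftoff=0.9, hind_liftoff=0.9), 7),
            (dict(fore_touchdown=0.2, hind_touchdown=0.1, fore_liftoff=0.9, hind_liftoff=0.8), 8),
            (dict(fore_touchdown=0.2, hind_touchdown=0.1, fore_liftoff=0.8, hind_liftoff=0.9), 9),
        ],
    )
    def test_all_nine_sequences(self, times, expected):
        seq = classify_sequence(_events(times))
        assert seq.sequence_id == expected

    def test_sub_tolerance_split_merges_to_simultaneous(self):
        times = dict(
            fore_touchdown=0.1,
            hind_touchdown=0.1 + 5e-7,
            fore_liftoff=0.9,
            hind_liftoff=0.9 - 5e-7,
        )
        assert classify_sequence(_events(times)).sequence_id == 1

    def test_missing_double_stance_rejected(self):
        times = dict(
            fore_touchdown=0.1, fore_liftoff=0.3, hind_touchdown=0.5, hind_liftoff=0.9
        )
        with pytest.raises(SequenceClassificationError, match="double-stance"):
            classify_sequence(_events(times))

    def test_incomplete_event_log_rejected(self):
        with pytest.raises(SequenceClassificationError, match="missing"):
            classify_sequence(_events(dict(fore_touchdown=0.1)))


@pytest.mark.parametrize(
    "which", ["dog_sym_solution", "dog_solution", "horse_solution"]
)
def test_event_times_match_fixed_step_oracle(which, request):
    """Adaptive event-driven integration agrees with an independent
    fixed-step RK4 + bisection oracle to 1e-6 on all event times."""
    sol = request.getfixturevalue(which)
    expected = sol.half_cycle.event_times()
    got = half_cycle_events(sol.x_star, sol.params, h=1e-4)
    for kind, t_ref in expected.items():
        assert got[kind] == pytest.approx(t_ref, abs=1e-6), kind
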