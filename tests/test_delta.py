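"""Delta-rule learner: update semantics, convergence, the closed-form oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marklearn.delta import (
    LearnerConfig,
    WeightMatrix,
    asymptote_oracle,
    detect_asymptote,
    train,
    update_weights,
)
from marklearn.language import CONSTANT_CUE, Event, generate_events


def ev(cues, outcomes, t=1):
    return Event(frozenset(cues), frozenset(outcomes), t)


class TestUpdate:
    def test_first_trial_from_zero(self):
        W = WeightMatrix([], [])
        W = update_weights(W, ev({"c", CONSTANT_CUE}, {"o"}), eta=0.01)
        assert W["c", "o"] == pytest.approx(0.01)
        assert W[CONSTANT_CUE, "o"] == pytest.approx(0.01)

    def test_negative_evidence(self):
        W = WeightMatrix(["c"], ["o", "p"], np.array([[0.5, 0.0]]))
        W = update_weights(W, ev({"c"}, {"p"}), eta=0.01)
        assert W["c", "o"] == pytest.approx(0.495)  # 0.5 + 0.01*(0 - 0.5)
        assert W["c", "p"] == pytest.approx(0.01)

    def test_absent_cue_rows_bitwise_unchanged(self, rng):
        values = rng.normal(size=(3, 2))
        W = WeightMatrix(["a", "b", "c"], ["o", "p"], values.copy())
        W2 = update_weights(W, ev({"a"}, {"o"}), eta=0.05)
        assert np.array_equal(W2.values[1:], values[1:])

    def test_simultaneous_update_uses_pretrial_activations(self):
        # both cues present: each row moves by eta*(1 - summed pre-trial act)
        W = WeightMatrix(["a", "b"], ["o"], np.array([[0.2], [0.3]]))
        W2 = update_weights(W, ev({"a", "b"}, {"o"}), eta=0.1)
        assert W2["a", "o"] == pytest.approx(0.2 + 0.1 * (1 - 0.5))
        assert W2["b", "o"] == pytest.approx(0.3 + 0.1 * (1 - 0.5))


class TestTrain:
    def test_matches_repeated_functional_updates(self, spec):
        events = generate_events(spec, "post", "sim1", 40, seed=5)
        traj = train(events, LearnerConfig(eta=0.01))
        W = WeightMatrix(traj.final.cue_index, traj.final.outcome_index)
        for e in events:
            W = update_weights(W, e, 0.01)
        assert np.allclose(W.values, traj.final.values, atol=1e-12)

    def test_deterministic(self, spec):
        events = generate_events(spec, "pre", "sim1", 200, seed=5)
        a = train(events, LearnerConfig()).final.values
        b = train(events, LearnerConfig()).final.values
        assert np.array_equal(a, b)

    def test_snapshot_equals_replay(self, spec):
        events = generate_events(spec, "pre", "sim1", 100, seed=5)
        traj = train(events, snapshots_at=[60])
        replay = train(
            events[:60],
            cue_labels=traj.final.cue_index,
            outcome_labels=traj.final.outcome_index,
        )
        assert np.array_equal(traj.snapshots[60].values, replay.final.values)

    def test_single_cooccurrence_converges_to_one_from_below(self):
        # summed weight follows s_t = 1 - (1 - 2*eta)^t exactly
        eta, n = 0.01, 400
        events = [ev({"c", CONSTANT_CUE}, {"o"}, t) for t in range(1, n + 1)]
        traj = train(events, LearnerConfig(eta=eta), snapshots_at=range(1, n + 1))
        s = np.array(
            [traj.at(t).values.sum() for t in range(1, n + 1)]
        )
        expected = 1 - (1 - 2 * eta) ** np.arange(1, n + 1)
        assert np.allclose(s, expected, atol=1e-12)
        assert (np.diff(s) > 0).all() and (s < 1).all()

    def test_numpy_fallback_matches_kernel(self, spec, monkeypatch):
        import marklearn._kernel as kernel

        events = generate_events(spec, "post", "sim1", 150, seed=2)
        fast = train(events, snapshots_at=[50]).final.values
        monkeypatch.setattr(kernel, "_HAVE_NUMBA", False)
        slow = train(events, snapshots_at=[50]).final.values
        assert np.array_equal(fast, slow)

    def test_eta_bounds(self):
        with pytest.raises(ValueError):
            LearnerConfig(eta=0.0)
        with pytest.raises(ValueError):
            LearnerConfig(eta=1.5)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_update_never_touches_absent_cues(seed):
    rng = np.random.default_rng(seed)
    cues = [f"c{i}" for i in range(5)]
    outs = [f"o{i}" for i in range(4)]
    W = WeightMatrix(cues, outs, rng.normal(size=(5, 4)))
    present = frozenset(rng.choice(cues, size=2, replace=False))
    outcome = frozenset([rng.choice(outs)])
    W2 = update_weights(W, Event(present, outcome), eta=0.1)
    for i, c in enumerate(cues):
        if c not in present:
            assert np.array_equal(W2.values[i], W.values[i])
        else:
            assert not np.array_equal(W2.values[i], W.values[i])


class TestOracle:
    def test_minimum_norm_split_for_single_event(self):
        oracle = asymptote_oracle([ev({"c", CONSTANT_CUE}, {"o"})])
        assert oracle["c", "o"] == pytest.approx(0.5)
        assert oracle[CONSTANT_CUE, "o"] == pytest.approx(0.5)

    def test_divergent_design_gives_conditional_probabilities(self):
        # single varying cue per trial, no constant: weight -> P(outcome | cue)
        stream = [(ev({"a"}, {"o1"}), 3.0), (ev({"a"}, {"o2"}), 1.0), (ev({"b"}, {"o2"}), 2.0)]
        oracle = asymptote_oracle(stream)
        assert oracle["a", "o1"] == pytest.approx(0.75)
        assert oracle["a", "o2"] == pytest.approx(0.25)
        assert oracle["b", "o2"] == pytest.approx(1.0)
        assert oracle["b", "o1"] == pytest.approx(0.0)

    def test_trained_weights_reach_divergent_conditionals(self, rng):
        pool = [ev({"a"}, {"o1"})] * 3 + [ev({"a"}, {"o2"})] + [ev({"b"}, {"o2"})] * 2
        events = [pool[i] for i in rng.integers(0, len(pool), size=12000)]
        traj = train(events, LearnerConfig(eta=0.01))
        assert traj.final["a", "o1"] == pytest.approx(0.75, abs=0.03)
        assert traj.final["b", "o2"] == pytest.approx(1.0, abs=0.03)

    def test_sim1_postmarking_long_run_matches_oracle(self, spec):
        events = generate_events(spec, "post", "sim1", 20 * 412, seed=3)
        traj = train(events, LearnerConfig(eta=0.01))
        oracle = asymptote_oracle(events, traj.final.cue_index, traj.final.outcome_index)
        assert np.abs(traj.final.values - oracle.values).max() < 0.02


class TestAsymptoteDetection:
    def test_constant_trajectory_detected_at_first_eligible_index(self):
        events = [ev({"c"}, {"o"}, t) for t in range(1, 31)]
        traj = train(events, LearnerConfig(eta=0.5))  # converges almost immediately
        traj.max_delta[:] = 0.0
        assert detect_asymptote(traj, tol=1e-9, window=10) == 10

    def test_zero_tolerance_never_reached_while_changing(self, spec):
        events = generate_events(spec, "pre", "sim1", 600, seed=1)
        traj = train(events)
        assert detect_asymptote(traj, tol=0.0, window=100) is None

    def test_monotone_in_tolerance(self, spec):
        events = generate_events(spec, "post", "sim1", 2000, seed=1)
        traj = train(events)
        hits = [detect_asymptote(traj, tol=t, window=412) for t in (1e-3, 2e-3, 5e-3)]
        cleaned = [h for h in hits if h is not None]
        assert cleaned == sorted(cleaned, reverse=True)
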