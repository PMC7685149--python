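"""Choice probabilities: ReLU-Luce rules, exclusions, untrained baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from marklearn.choice import (
    ChoiceProblem,
    eval_sim1,
    eval_sim2,
    luce_full,
    pairwise_mean_choice,
    relu,
)
from marklearn.delta import WeightMatrix
from marklearn.language import CONSTANT_CUE


class TestRelu:
    @pytest.mark.parametrize("x, y", [(-0.3, 0.0), (0.7, 0.7), (0.0, 0.0)])
    def test_scalar(self, x, y):
        assert relu(x) == y


class TestLuceFull:
    def test_two_alternatives(self):
        assert luce_full("t", ["t", "u"], {"t": 0.3, "u": 0.1}) == pytest.approx(0.75)

    def test_uniform_fallback(self):
        acts = {a: -0.2 for a in "abcd"}
        assert luce_full("a", list("abcd"), acts) == pytest.approx(0.25)

    def test_three_alternatives(self):
        acts = {"t": 0.2, "u": 0.2, "v": 0.1}
        assert luce_full("t", ["t", "u", "v"], acts) == pytest.approx(0.4)

    def test_errors(self):
        with pytest.raises(ValueError):
            luce_full("t", [], {})
        with pytest.raises(ValueError):
            luce_full("t", ["u"], {"u": 1.0})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=6))
    def test_distribution_normalizes(self, acts_list):
        alts = [f"a{i}" for i in range(len(acts_list))]
        acts = dict(zip(alts, acts_list))
        total = sum(luce_full(a, alts, acts) for a in alts)
        assert total == pytest.approx(1.0)


class TestPairwiseMean:
    def test_hand_computed_mean(self):
        acts = {"x": 0.4, "a": 0.1, "b": 0.4, "c": -0.2}
        res = pairwise_mean_choice(ChoiceProblem("x", ("a", "b", "c"), acts))
        assert res.per_pair == pytest.approx({"a": 0.8, "b": 0.5, "c": 1.0})
        assert res.probability_correct == pytest.approx((0.8 + 0.5 + 1.0) / 3)

    def test_untrained_baseline_is_exactly_half(self):
        acts = {k: 0.0 for k in "xabc"}
        res = pairwise_mean_choice(ChoiceProblem("x", ("a", "b", "c"), acts))
        assert res.probability_correct == 0.5

    def test_exclusion_drops_pair(self):
        acts = {"x": 0.4, "a": 0.4, "b": 0.1}
        res = pairwise_mean_choice(
            ChoiceProblem("x", ("a", "b"), acts, exclusions=frozenset({"a"}))
        )
        assert list(res.per_pair) == ["b"]
        assert res.probability_correct == pytest.approx(0.8)

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="x"):
            pairwise_mean_choice(
                ChoiceProblem("x", ("a",), {"x": 1.0, "a": 1.0}, frozenset({"a"}))
            )

    def test_problem_invariants(self):
        with pytest.raises(ValueError):
            ChoiceProblem("x", ("x", "a"), {})
        with pytest.raises(ValueError):
            ChoiceProblem("x", ("a",), {}, exclusions=frozenset({"b"}))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1, 1), min_size=3, max_size=5),
        st.floats(0.01, 100.0),
    )
    def test_invariant_to_positive_rescaling(self, acts_list, scale):
        alts = [f"a{i}" for i in range(len(acts_list) - 1)]
        acts = {"x": acts_list[0], **dict(zip(alts, acts_list[1:]))}
        scaled = {k: v * scale for k, v in acts.items()}
        p1 = pairwise_mean_choice(ChoiceProblem("x", tuple(alts), acts))
        p2 = pairwise_mean_choice(ChoiceProblem("x", tuple(alts), scaled))
        assert p1.probability_correct == pytest.approx(p2.probability_correct)


class TestCategoryEvaluation:
    def _untrained(self, spec, marking):
        if marking == "pre":
            cues = [f"marker{k}" for k in (1, 2, 3, 4)] + [CONSTANT_CUE]
            outs = sorted(
                spec.features.meaning_features | spec.features.form_features
            )
        else:
            cues = sorted(
                spec.features.meaning_features | spec.features.form_features
            ) + [CONSTANT_CUE]
            outs = [f"marker{k}" for k in (1, 2, 3, 4)]
        return WeightMatrix(cues, outs)

    def test_untrained_baseline_half_everywhere(self, spec):
        for marking in ("pre", "post"):
            W = self._untrained(spec, marking)
            for dim in ("meaning", "form"):
                table = eval_sim1(W, spec, marking, dim)
                assert (table["probability"] == 0.5).all()

    def test_postmarking_exclusions_follow_shared_sets(self, spec):
        W = self._untrained(spec, "post")
        form = eval_sim1(W, spec, "post", "form").set_index("noun_class")
        assert form.loc[2, "excluded"] == "marker4"
        assert form.loc[4, "excluded"] == "marker2"
        assert form.loc[1, "excluded"] == "" and form.loc[3, "excluded"] == ""
        meaning = eval_sim1(W, spec, "post", "meaning").set_index("noun_class")
        assert meaning.loc[3, "excluded"] == "marker4"
        assert meaning.loc[4, "excluded"] == "marker3"

    def test_premarking_reads_out_summed_set_activations(self, spec):
        W = self._untrained(spec, "pre")
        # give marker1 weight only to class-1 form features
        for f in spec.features.class_to_form_set[1]:
            W.values[W._cue_pos["marker1"], W._out_pos[f]] = 0.2
        table = eval_sim1(W, spec, "pre", "form").set_index("noun_class")
        # class 1: target set act 0.6 vs 0 and (shared O-features) partial acts
        assert table.loc[1, "probability"] > 0.5
        assert table.loc[2, "probability"] <= 0.5


class TestNounEvaluation:
    def test_untrained_postmarking_baseline(self, spec):
        W = WeightMatrix([CONSTANT_CUE], list(spec.objects))
        table = eval_sim2(W, spec, "post")
        assert (table["probability"] == 1 / 32).all()
        assert (table["n_alternatives"] == 32).all()

    def test_untrained_premarking_class_networks_baseline(self, spec):
        models = {
            k: WeightMatrix(
                [CONSTANT_CUE], [n.object_meaning for n in spec.nouns_of_class(k)]
            )
            for k in (1, 2, 3, 4)
        }
        table = eval_sim2(models, spec, "pre")
        assert (table["probability"] == 1 / 8).all()
        assert (table["n_alternatives"] == 8).all()

    def test_missing_class_model_rejected(self, spec):
        models = {1: WeightMatrix([CONSTANT_CUE], list(spec.objects))}
        with pytest.raises(ValueError, match="missing"):
            eval_sim2(models, spec, "pre")

    def test_marking_model_type_mismatch(self, spec):
        W = WeightMatrix([CONSTANT_CUE], list(spec.objects))
        with pytest.raises(ValueError):
            eval_sim2({k: W for k in (1, 2, 3, 4)}, spec, "post")
        with pytest.raises(ValueError):
            eval_sim2(W, spec, "pre")
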