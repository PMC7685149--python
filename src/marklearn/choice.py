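"""From outcome activations to choice probabilities.

Two Luce-style read-outs are used, both after rectifying activations at
zero (ReLU):

* **Pairwise-mean choice** -- the target's probability is computed against
  every competitor separately, ``ReLU(a_x) / (ReLU(a_x) + ReLU(a_y))``, and
  averaged.  This equalizes chance performance at exactly 1/2 when the two
  marking conditions offer different numbers of alternatives (three feature
  sets vs. four markers).  Binary choices in which *both* alternatives are
  genuinely licensed by the cue set (the deliberate class-2/class-4 form and
  class-3/class-4 meaning ambiguities) are excluded from the mean.
* **Full-set Luce choice** -- ``ReLU(a_x) / sum_y ReLU(a_y)`` over the whole
  alternative set, used for noun-to-object learning.

Degenerate 0/0 cases fall back to a uniform choice (0.5 per pair, 1/|O|
for the full set), which preserves the untrained baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .delta import WeightMatrix
from .language import CONSTANT_CUE, LanguageSpec, MarkerInventory

__all__ = [
    "ChoiceProblem",
    "ChoiceResult",
    "eval_sim1",
    "eval_sim2",
    "luce_full",
    "pairwise_mean_choice",
    "relu",
    "sim1_mean_difference",
    "sim2_mean_difference",
]


def relu(x):
    """Clamp negative activations to zero."""
    return np.maximum(x, 0.0)


def luce_full(target: str, alternatives: Sequence[str], activations: Mapping[str, float]) -> float:
    """Choice probability of ``target`` over the full alternative set.

    If every rectified activation is zero the choice is uniform
    (``1 / len(alternatives)``).
    """
    if len(alternatives) == 0:
        raise ValueError("alternative set must be non-empty")
    if target not in alternatives:
        raise ValueError(f"target {target!r} not among alternatives")
    acts = np.array([relu(float(activations[a])) for a in alternatives])
    denom = acts.sum()
    if denom == 0.0:
        return 1.0 / len(alternatives)
    return float(acts[list(alternatives).index(target)] / denom)


@dataclass(frozen=True)
class ChoiceProblem:
    target: str
    competitors: tuple[str, ...]
    activations: Mapping[str, float]
    exclusions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.target in self.competitors:
            raise ValueError("target must not be listed among competitors")
        if not self.exclusions <= set(self.competitors):
            raise ValueError("exclusions must name listed competitors")


@dataclass(frozen=True)
class ChoiceResult:
    probability_correct: float
    per_pair: dict[str, float] = field(default_factory=dict)


def pairwise_mean_choice(problem: ChoiceProblem) -> ChoiceResult:
    """Mean of binary rectified-Luce choices against each non-excluded competitor."""
    competitors = [c for c in problem.competitors if c not in problem.exclusions]
    if not competitors:
        raise ValueError(f"all pairs excluded for target {problem.target!r}")
    ax = relu(float(problem.activations[problem.target]))
    per_pair = {}
    for c in competitors:
        ay = relu(float(problem.activations[c]))
        per_pair[c] = 0.5 if ax + ay == 0.0 else float(ax / (ax + ay))
    return ChoiceResult(float(np.mean(list(per_pair.values()))), per_pair)


# ---------------------------------------------------------------------------
# Category-level (noun class) evaluation

Dimension = Literal["meaning", "form"]
ReluLevel = Literal["set", "feature"]


def _set_activation(W: WeightMatrix, cues: frozenset[str], features: frozenset[str],
                    relu_level: ReluLevel) -> float:
    acts = W.activations(cues)
    pos = {o: j for j, o in enumerate(W.outcome_index)}
    vals = [acts[pos[f]] for f in features if f in pos]
    if relu_level == "feature":
        return float(sum(relu(v) for v in vals))
    return float(sum(vals))


def eval_sim1(
    W: WeightMatrix,
    spec: LanguageSpec,
    marking: Literal["pre", "post"],
    dimension: Dimension,
    relu_level: ReluLevel = "set",
) -> pd.DataFrame:
    """Per-class correct-categorization probability on one feature dimension.

    Postmarking: the cue set is the class's feature set on ``dimension``
    plus the constant cue, and the four abstract markers are the choice
    alternatives; pairs whose competitor marker is equally licensed by the
    (shared) feature set are excluded.  Premarking: the cue set is the
    class's marker plus constant, candidate outcome sets are the three
    distinct feature sets on the dimension, each scored by its summed
    feature activations (rectified at the set level by default).
    """
    feats = spec.features
    rows = []
    if marking == "post":
        for k in (1, 2, 3, 4):
            cues = feats.feature_set(k, dimension) | {CONSTANT_CUE}
            acts = W.activation_map(cues)
            target = MarkerInventory.abstract_marker(k)
            competitors = tuple(
                MarkerInventory.abstract_marker(m) for m in (1, 2, 3, 4) if m != k
            )
            excl = frozenset(
                MarkerInventory.abstract_marker(m)
                for m in feats.ambiguous_classes(k, dimension)
            )
            res = pairwise_mean_choice(ChoiceProblem(target, competitors, acts, excl))
            rows.append((k, res.probability_correct, ",".join(sorted(excl))))
    elif marking == "pre":
        dim_sets = {feats.feature_set(k, dimension) for k in (1, 2, 3, 4)}
        for k in (1, 2, 3, 4):
            cues = frozenset({MarkerInventory.abstract_marker(k), CONSTANT_CUE})
            target_set = feats.feature_set(k, dimension)
            candidates = {frozenset(s): None for s in sorted(dim_sets, key=sorted)}
            acts = {
                "+".join(sorted(s)): relu(_set_activation(W, cues, s, relu_level))
                for s in candidates
            }
            target = "+".join(sorted(target_set))
            competitors = tuple(key for key in acts if key != target)
            res = pairwise_mean_choice(ChoiceProblem(target, competitors, acts))
            rows.append((k, res.probability_correct, ""))
    else:
        raise ValueError(f"unknown marking: {marking!r}")
    return pd.DataFrame(rows, columns=["noun_class", "probability", "excluded"]).assign(
        marking=marking, dimension=dimension
    )


def sim1_mean_difference(
    W_pre: WeightMatrix, W_post: WeightMatrix, spec: LanguageSpec, dimension: Dimension,
    relu_level: ReluLevel = "set",
) -> float:
    """Mean correct-choice probability, postmarking minus premarking."""
    post = eval_sim1(W_post, spec, "post", dimension, relu_level)["probability"].mean()
    pre = eval_sim1(W_pre, spec, "pre", dimension, relu_level)["probability"].mean()
    return float(post - pre)


# ---------------------------------------------------------------------------
# Noun-level (object) evaluation

Alternatives = Literal["model", "within_class"]


def eval_sim2(
    models: WeightMatrix | Mapping[int, WeightMatrix],
    spec: LanguageSpec,
    marking: Literal["pre", "post"],
    alternatives: Alternatives = "model",
) -> pd.DataFrame:
    """Per-noun probability of choosing the correct object.

    The cue set of a noun is its form feature set plus uniphones plus the
    constant cue.  The choice alternatives are, by default, the outcome
    index of the network being evaluated -- the set of objects that learner
    was actually discriminating.  A postmarking learner indexes all 32
    objects; a premarking class learner trained inside its reduced set
    indexes only the 8 within-class objects (untrained baselines 1/32 and
    1/8 respectively).  A learner whose stream contained other objects
    (e.g. the shared full-set phase, or an outcome-shuffled baseline run)
    correspondingly competes over all of them.  ``alternatives=
    "within_class"`` forces the noun's 8 class objects regardless of the
    model's index, for sensitivity analysis.
    """
    if marking == "post":
        if not isinstance(models, WeightMatrix):
            raise ValueError("postmarking evaluation expects a single trained matrix")
        W_by_class = {k: models for k in (1, 2, 3, 4)}
    elif marking == "pre":
        if isinstance(models, WeightMatrix):
            raise ValueError("premarking evaluation expects one model per noun class")
        missing = [k for k in (1, 2, 3, 4) if k not in models]
        if missing:
            raise ValueError(f"missing per-class model(s): {missing}")
        W_by_class = dict(models)
    else:
        raise ValueError(f"unknown marking: {marking!r}")
    rows = []
    for noun in spec.nouns:
        W = W_by_class[noun.noun_class]
        cues = (
            spec.features.class_to_form_set[noun.noun_class]
            | frozenset(spec.uniphones(noun.form))
            | {CONSTANT_CUE}
        )
        acts = W.activation_map(cues)
        if alternatives == "within_class" and marking == "pre":
            alts = [n.object_meaning for n in spec.nouns_of_class(noun.noun_class)]
            acts = {o: acts.get(o, 0.0) for o in alts}
        else:
            alts = list(W.outcome_index)
        if noun.object_meaning not in alts:
            # A network that never indexed the target object cannot choose it.
            p = 0.0
        else:
            p = luce_full(noun.object_meaning, alts, acts)
        rows.append((noun.form, noun.noun_class, noun.frequency, noun.object_meaning,
                     len(alts), p))
    return pd.DataFrame(
        rows,
        columns=["noun", "noun_class", "frequency", "object", "n_alternatives", "probability"],
    ).assign(marking=marking)


def sim2_mean_difference(
    pre_models: Mapping[int, WeightMatrix],
    post_model: WeightMatrix,
    spec: LanguageSpec,
    alternatives: Alternatives = "model",
) -> float:
    """Mean correct-object probability, premarking minus postmarking."""
    pre = eval_sim2(pre_models, spec, "pre", alternatives)["probability"].mean()
    post = eval_sim2(post_model, spec, "post")["probability"].mean()
    return float(pre - post)
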