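"""The two marking-order simulations.

Simulation 1 (category structure): premarking and postmarking learners are
trained on role-swapped encodings of the *same* noun-token stream -- the
premarker predicts the noun's feature bundle, or the feature bundle
predicts the postmarker -- and compared on how well they categorize along
the distinct meaning dimension and the partly overlapping form dimension.

Simulation 2 (levels of abstraction): both learners map noun form cues to
object meanings.  The postmarking learner solves the discrimination among
all 32 objects for the whole budget; the premarking learner shares that
full-set training for the first quarter (premarker-class associations must
first be acquired) and then continues as four class-restricted learners
whose negative evidence is confined to the outcomes their reduced stream
contains.  The premarking advantage, if any, therefore comes purely from
set-size reduction: token order, encodings and learning rate are identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._kernel import run_training
from .choice import (
    Alternatives,
    eval_sim1,
    eval_sim2,
    sim1_mean_difference,
    sim2_mean_difference,
)
from .delta import (
    LearnerConfig,
    NumericFailure,
    WeightMatrix,
    compile_events,
    _index_events,
)
from .language import (
    Event,
    LanguageSpec,
    NounEntry,
    build_language_spec,
    events_from_tokens,
    noun_token_stream,
)

__all__ = [
    "CompiledStream",
    "Sim1Result",
    "Sim2Result",
    "run_sim1",
    "run_sim2",
    "train_compiled",
]

BEHAVIORAL_TRIALS = 412


@dataclass
class CompiledStream:
    """An event stream flattened to index arrays for the training kernel."""

    cue_index: list[str]
    outcome_index: list[str]
    cue_flat: np.ndarray
    cue_off: np.ndarray
    out_flat: np.ndarray
    out_off: np.ndarray

    @classmethod
    def from_events(cls, events: Sequence[Event],
                    cue_index: Sequence[str] | None = None,
                    outcome_index: Sequence[str] | None = None) -> "CompiledStream":
        auto_c, auto_o = _index_events(events)
        cue_index = list(cue_index) if cue_index is not None else auto_c
        outcome_index = list(outcome_index) if outcome_index is not None else auto_o
        cue_pos = {c: i for i, c in enumerate(cue_index)}
        out_pos = {o: j for j, o in enumerate(outcome_index)}
        return cls(cue_index, outcome_index, *compile_events(events, cue_pos, out_pos))

    @property
    def n_trials(self) -> int:
        return self.cue_off.shape[0] - 1

    def permuted_outcomes(self, perm: np.ndarray) -> "CompiledStream":
        """Reorder the per-trial outcome *sets* by ``perm``; cues untouched."""
        lengths = np.diff(self.out_off)
        if (lengths == 1).all():  # singleton outcomes permute directly
            return CompiledStream(self.cue_index, self.outcome_index,
                                  self.cue_flat, self.cue_off,
                                  self.out_flat[perm], self.out_off)
        new_off = np.zeros_like(self.out_off)
        new_off[1:] = np.cumsum(lengths[perm])
        new_flat = np.empty_like(self.out_flat)
        for t, src in enumerate(perm):
            new_flat[new_off[t]:new_off[t + 1]] = self.out_flat[self.out_off[src]:self.out_off[src + 1]]
        return CompiledStream(self.cue_index, self.outcome_index,
                              self.cue_flat, self.cue_off, new_flat, new_off)

    def subset(self, trials: np.ndarray) -> "CompiledStream":
        """Keep only the given trial positions (order preserved)."""
        cue_segs = [self.cue_flat[self.cue_off[t]:self.cue_off[t + 1]] for t in trials]
        out_segs = [self.out_flat[self.out_off[t]:self.out_off[t + 1]] for t in trials]
        cue_off = np.zeros(len(trials) + 1, dtype=np.int64)
        out_off = np.zeros(len(trials) + 1, dtype=np.int64)
        cue_off[1:] = np.cumsum([len(s) for s in cue_segs])
        out_off[1:] = np.cumsum([len(s) for s in out_segs])
        return CompiledStream(
            self.cue_index, self.outcome_index,
            np.concatenate(cue_segs) if cue_segs else np.empty(0, dtype=np.int64),
            cue_off,
            np.concatenate(out_segs) if out_segs else np.empty(0, dtype=np.int64),
            out_off,
        )


def train_compiled(
    cs: CompiledStream,
    eta: float = 0.01,
    init: np.ndarray | None = None,
    active_cols: np.ndarray | None = None,
    snapshots_at: Sequence[int] = (),
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Kernel-level training; returns (final weights, snapshots by trial).

    ``active_cols`` freezes all other outcome columns (reduced-set
    training); outcome ids in the stream must then fall inside it.
    """
    n_cues, n_out = len(cs.cue_index), len(cs.outcome_index)
    W_full = np.zeros((n_cues, n_out)) if init is None else init.copy()
    if active_cols is None:
        W = np.ascontiguousarray(W_full)
        out_flat = cs.out_flat
    else:
        remap = -np.ones(n_out, dtype=np.int64)
        remap[active_cols] = np.arange(active_cols.size)
        out_flat = remap[cs.out_flat]
        if (out_flat < 0).any():
            raise ValueError("stream contains outcomes outside the active set")
        W = np.ascontiguousarray(W_full[:, active_cols])
    snap_at = np.asarray(sorted({int(s) for s in snapshots_at if 1 <= s <= cs.n_trials}),
                         dtype=np.int64)
    snaps = np.zeros((snap_at.size, W.shape[0], W.shape[1]))
    max_delta = np.zeros(cs.n_trials)
    bad = run_training(W, cs.cue_flat, cs.cue_off, out_flat, cs.out_off, eta,
                       snap_at, snaps, max_delta, np.zeros((1, 1)), False)
    if bad:
        raise NumericFailure(f"non-finite weights at trial {bad}")

    def scatter(sub):
        if active_cols is None:
            return sub.copy()
        full = W_full.copy()
        full[:, active_cols] = sub
        return full

    return scatter(W), {int(s): scatter(snaps[i]) for i, s in enumerate(snap_at)}


# ---------------------------------------------------------------------------
# Simulation 1


@dataclass
class Sim1Result:
    """Per-class choice probabilities and headline mean differences.

    ``differences[(dimension, checkpoint)]`` is the postmarking-minus-
    premarking mean over the four classes; checkpoints are the behavioral
    trial count (412) and the full budget ("asymptote").
    """

    table: pd.DataFrame
    differences: dict[tuple[str, str], float]
    n_trials: int
    seed: int | None = None

    def difference(self, dimension: str, checkpoint: str = "asymptote") -> float:
        return self.differences[(dimension, checkpoint)]


def _sim1_streams(
    spec: LanguageSpec, tokens: Sequence[NounEntry]
) -> tuple[CompiledStream, CompiledStream]:
    pre = CompiledStream.from_events(events_from_tokens(spec, tokens, "pre", "sim1"))
    post = CompiledStream.from_events(events_from_tokens(spec, tokens, "post", "sim1"))
    return pre, post


def _sim1_matrices(
    pre_cs: CompiledStream, post_cs: CompiledStream, eta: float,
    snapshots_at: Sequence[int] = (),
) -> tuple[WeightMatrix, WeightMatrix, dict[int, WeightMatrix], dict[int, WeightMatrix]]:
    w_pre, s_pre = train_compiled(pre_cs, eta, snapshots_at=snapshots_at)
    w_post, s_post = train_compiled(post_cs, eta, snapshots_at=snapshots_at)
    wrap_pre = lambda v: WeightMatrix(pre_cs.cue_index, pre_cs.outcome_index, v)
    wrap_post = lambda v: WeightMatrix(post_cs.cue_index, post_cs.outcome_index, v)
    return (wrap_pre(w_pre), wrap_post(w_post),
            {t: wrap_pre(v) for t, v in s_pre.items()},
            {t: wrap_post(v) for t, v in s_post.items()})


def run_sim1(
    seed: int = 0,
    n_trials: int = 1600,
    eta: float = 0.01,
    spec: LanguageSpec | None = None,
    sampler: Literal["multiset", "iid"] = "multiset",
) -> Sim1Result:
    """Train the two marking models on a matched stream and evaluate both
    dimensions at the behavioral checkpoint (412 trials) and at the end of
    the budget (1,600 trials, the asymptote regime)."""
    spec = spec or build_language_spec()
    rng = np.random.default_rng(seed)
    tokens = noun_token_stream(spec, n_trials, rng, sampler=sampler)
    pre_cs, post_cs = _sim1_streams(spec, tokens)
    checkpoints = {"behavioral": BEHAVIORAL_TRIALS, "asymptote": n_trials}
    W_pre, W_post, snaps_pre, snaps_post = _sim1_matrices(
        pre_cs, post_cs, eta, snapshots_at=[BEHAVIORAL_TRIALS]
    )
    at = {
        "behavioral": (snaps_pre.get(BEHAVIORAL_TRIALS, W_pre),
                       snaps_post.get(BEHAVIORAL_TRIALS, W_post)),
        "asymptote": (W_pre, W_post),
    }
    tables, diffs = [], {}
    for label, (wp, wq) in at.items():
        for dim in ("meaning", "form"):
            tables.append(eval_sim1(wp, spec, "pre", dim).assign(checkpoint=label))
            tables.append(eval_sim1(wq, spec, "post", dim).assign(checkpoint=label))
            diffs[(dim, label)] = sim1_mean_difference(wp, wq, spec, dim)
    return Sim1Result(pd.concat(tables, ignore_index=True), diffs, n_trials, seed)


def sim1_statistics(
    spec: LanguageSpec,
    pre_cs: CompiledStream,
    post_cs: CompiledStream,
    eta: float = 0.01,
    outcome_perms: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """(form, meaning) mean differences at the end of a compiled stream pair.

    ``outcome_perms`` applies an outcome-set permutation to each stream --
    the shuffled-outcome null in which markers and noun bundles are paired
    at random while marginals and cue structure are preserved.
    """
    if outcome_perms is not None:
        pre_cs = pre_cs.permuted_outcomes(outcome_perms[0])
        post_cs = post_cs.permuted_outcomes(outcome_perms[1])
    W_pre, W_post, *_ = _sim1_matrices(pre_cs, post_cs, eta)
    return (
        sim1_mean_difference(W_pre, W_post, spec, "form"),
        sim1_mean_difference(W_pre, W_post, spec, "meaning"),
    )


# ---------------------------------------------------------------------------
# Simulation 2


@dataclass
class Sim2Result:
    """Per-noun correct-object probabilities and premarking-minus-postmarking
    differences at the behavioral checkpoint and at the end of training."""

    table: pd.DataFrame
    differences: dict[str, float]
    median_differences: dict[str, float]
    n_trials: int
    quarter: int
    alternatives: str
    asymptote_trial: int | None = None
    seed: int | None = None

    def difference(self, checkpoint: str = "asymptote") -> float:
        return self.differences[checkpoint]


@dataclass
class _Sim2Setup:
    """Compiled full stream plus the class split of the continuation phase.

    The cue side of each class's continuation stream never changes between
    baselines (only outcomes are shuffled), so it is compiled once.
    """

    spec: LanguageSpec
    cs: CompiledStream
    quarter: int
    class_trials: dict[int, np.ndarray] = field(default_factory=dict)
    class_cues: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def build(cls, spec: LanguageSpec, tokens: Sequence[NounEntry], quarter: int) -> "_Sim2Setup":
        events = events_from_tokens(spec, tokens, "pre", "sim2")
        cs = CompiledStream.from_events(events)
        classes = np.array([n.noun_class for n in tokens])
        split = {k: np.nonzero(classes[quarter:] == k)[0] + quarter for k in (1, 2, 3, 4)}
        cues = {}
        for k, idx in split.items():
            segs = [cs.cue_flat[cs.cue_off[t]:cs.cue_off[t + 1]] for t in idx]
            off = np.zeros(len(idx) + 1, dtype=np.int64)
            off[1:] = np.cumsum([len(s) for s in segs])
            cues[k] = (np.concatenate(segs), off)
        return cls(spec, cs, quarter, split, cues)

    def models(
        self, eta: float, outcome_perm: np.ndarray | None = None,
        snapshots_at: Sequence[int] = (), fresh_learners: bool = False,
    ) -> tuple[dict[int, WeightMatrix], WeightMatrix, dict[int, np.ndarray]]:
        """Train both conditions; returns (pre class models, post model, post snaps).

        Each premarking class model is a *reduced network*: its outcome
        index is exactly the set of objects its continuation stream
        delivered (the 8 within-class objects in veridical training),
        initialized from the shared quarter-point weights of those columns.
        Negative evidence therefore applies only inside the reduced set.
        """
        cs = self.cs if outcome_perm is None else self.cs.permuted_outcomes(outcome_perm)
        snaps_wanted = sorted(set(snapshots_at) | {self.quarter})
        w_post, snaps = train_compiled(cs, eta, snapshots_at=snaps_wanted)
        w_quarter = snaps[self.quarter]
        pre_models = {}
        for k in (1, 2, 3, 4):
            idx = self.class_trials[k]
            out_k = cs.out_flat[idx]  # sim2 outcome sets are singletons
            active = np.unique(out_k)
            remap = -np.ones(len(cs.outcome_index), dtype=np.int64)
            remap[active] = np.arange(active.size)
            cue_flat, cue_off = self.class_cues[k]
            reduced = CompiledStream(
                cs.cue_index, [cs.outcome_index[j] for j in active],
                cue_flat, cue_off, remap[out_k],
                np.arange(len(idx) + 1, dtype=np.int64),
            )
            init = None if fresh_learners else np.ascontiguousarray(w_quarter[:, active])
            w_k, _ = train_compiled(reduced, eta, init=init)
            pre_models[k] = WeightMatrix(reduced.cue_index, reduced.outcome_index, w_k)
        post = WeightMatrix(cs.cue_index, cs.outcome_index, w_post)
        return pre_models, post, snaps


def run_sim2(
    seed: int = 0,
    n_epochs: int = 73,
    eta: float = 0.01,
    spec: LanguageSpec | None = None,
    alternatives: Alternatives = "model",
    fresh_learners: bool = False,
    sampler: Literal["multiset", "iid"] = "multiset",
    check_asymptote: bool = False,
) -> Sim2Result:
    """Noun-to-object learning under full-set vs. class-reduced training.

    The default budget of 73 epochs (30,076 trials) is where the weights of
    the most frequent nouns reach their asymptotic regime: the per-trial
    prediction error on their object columns stays within 5% of the unit
    activation ceiling across a full trailing epoch (detectable with
    :func:`marklearn.delta.detect_asymptote` and ``check_asymptote=True``).
    The first quarter of the budget is shared full-set training for the
    premarking condition.
    """
    spec = spec or build_language_spec()
    n_trials = n_epochs * spec.trials_per_epoch
    if n_trials < spec.trials_per_epoch:
        raise ValueError("schedule must cover at least one epoch")
    rng = np.random.default_rng(seed)
    tokens = noun_token_stream(spec, n_trials, rng, sampler=sampler)
    quarter = n_trials // 4
    setup = _Sim2Setup.build(spec, tokens, quarter)
    pre_models, post, snaps = setup.models(
        eta, snapshots_at=[BEHAVIORAL_TRIALS], fresh_learners=fresh_learners
    )
    w412 = WeightMatrix(setup.cs.cue_index, setup.cs.outcome_index, snaps[BEHAVIORAL_TRIALS])
    # During the shared first quarter the premarking condition *is* the
    # full-set learner, so its 412-trial checkpoint uses the same weights.
    pre412 = {k: w412 for k in (1, 2, 3, 4)}

    tables, diffs, med = [], {}, {}
    for label, (pre_m, post_m) in {
        "behavioral": (pre412, w412),
        "asymptote": (pre_models, post),
    }.items():
        t_pre = eval_sim2(pre_m, spec, "pre", alternatives).assign(checkpoint=label)
        t_post = eval_sim2(post_m, spec, "post").assign(checkpoint=label)
        tables.extend([t_pre, t_post])
        diffs[label] = float(t_pre["probability"].mean() - t_post["probability"].mean())
        med[label] = float(t_pre["probability"].median() - t_post["probability"].median())
    asymptote_trial = _sim2_asymptote_trial(setup, eta, spec) if check_asymptote else None
    return Sim2Result(
        pd.concat(tables, ignore_index=True), diffs, med,
        n_trials, quarter, alternatives, asymptote_trial, seed,
    )


def _sim2_asymptote_trial(setup: _Sim2Setup, eta: float, spec: LanguageSpec) -> int | None:
    """Asymptote of the frequent-noun object weights in the full-set model."""
    from .delta import detect_asymptote, train  # local import to avoid cycle at module load

    hi_objects = [n.object_meaning for n in spec.nouns if n.frequency == max(
        m.frequency for m in spec.nouns)]
    events = _events_of_stream(setup.cs)
    traj = train(
        events,
        LearnerConfig(eta=eta, record_deltas=True),
        cue_labels=setup.cs.cue_index,
        outcome_labels=setup.cs.outcome_index,
    )
    try:
        return detect_asymptote(traj, tol=eta * 0.05, window=spec.trials_per_epoch,
                                outcomes=hi_objects)
    except ValueError:
        return None


def _events_of_stream(cs: CompiledStream) -> list[Event]:
    events = []
    for t in range(cs.n_trials):
        cues = frozenset(cs.cue_index[i] for i in cs.cue_flat[cs.cue_off[t]:cs.cue_off[t + 1]])
        outs = frozenset(cs.outcome_index[j] for j in cs.out_flat[cs.out_off[t]:cs.out_off[t + 1]])
        events.append(Event(cues, outs, t + 1))
    return events


def sim2_statistic(
    setup: _Sim2Setup,
    eta: float = 0.01,
    alternatives: Alternatives = "model",
    outcome_perm: np.ndarray | None = None,
) -> float:
    """End-of-training premarking-minus-postmarking mean, for one stream."""
    pre_models, post, _ = setup.models(eta, outcome_perm=outcome_perm)
    return sim2_mean_difference(pre_models, post, setup.spec, alternatives)
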