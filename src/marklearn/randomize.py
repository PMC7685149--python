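"""Shuffled-outcome randomization tests for the marking-order effects.

The null hypothesis is that the observed premarking/postmarking difference
could arise from random cue-outcome pairings.  Each baseline permutes the
multiset of per-trial outcome *sets* across trials (cue sets and trial
order untouched), retrains the relevant models identically, and recomputes
the same mean-difference statistic.  The Monte-Carlo p-value uses the
add-one permutation estimator ``(b + 1) / (n + 1)``, so with 1,000
baselines the smallest attainable one-sided p is 1/1001.

Direction conventions: the form-dimension and noun-learning tests are
one-sided in the hypothesized direction (postmarking advantage for the
overlapping form dimension; premarking advantage for noun learning); the
meaning-dimension test is two-sided, since it checks the *absence* of an
order effect on distinct categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .language import Event, LanguageSpec, build_language_spec, noun_token_stream
from .sims import _Sim2Setup, _sim1_streams, sim1_statistics, sim2_statistic

__all__ = [
    "RandomizationResult",
    "monte_carlo_p",
    "run_randomization_test",
    "run_sim1_randomization",
    "run_sim2_randomization",
    "shuffle_outcomes",
]

SimId = Literal["sim1_form", "sim1_meaning", "sim2"]

ALTERNATIVE = {"sim1_form": "greater", "sim1_meaning": "two-sided", "sim2": "greater"}


@dataclass
class RandomizationResult:
    observed_stat: float
    baseline_stats: np.ndarray
    alternative: str
    sim_id: str

    @property
    def n_baselines(self) -> int:
        return int(self.baseline_stats.size)

    @property
    def baseline_mean(self) -> float:
        return float(self.baseline_stats.mean())

    @property
    def p_value(self) -> float:
        return monte_carlo_p(self.observed_stat, self.baseline_stats, self.alternative)

    def to_dict(self) -> dict:
        return {
            "sim": self.sim_id,
            "observed": self.observed_stat,
            "baseline_mean": self.baseline_mean,
            "p_value": self.p_value,
            "n_baselines": self.n_baselines,
            "alternative": self.alternative,
        }


def monte_carlo_p(observed: float, baselines: np.ndarray, alternative: str = "greater") -> float:
    """Add-one permutation p-value; ``two-sided`` compares magnitudes."""
    b = np.asarray(baselines, dtype=float)
    if alternative == "greater":
        count = int((b >= observed).sum())
    elif alternative == "less":
        count = int((b <= observed).sum())
    elif alternative == "two-sided":
        count = int((np.abs(b) >= abs(observed)).sum())
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return (count + 1) / (b.size + 1)


def shuffle_outcomes(events: Sequence[Event], seed: int | np.random.Generator) -> list[Event]:
    """Permute outcome sets across trials, keeping cue sets in place."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(events))
    return [
        Event(ev.cues, events[src].outcomes, ev.trial_index)
        for ev, src in zip(events, perm)
    ]


def shuffle_outcome_labels(events: Sequence[Event], seed: int | np.random.Generator) -> list[Event]:
    """Label-level variant: shuffle the flattened outcome tokens, keeping the
    per-trial outcome-set sizes.  Provided for sensitivity analysis; the
    default tests permute whole outcome sets."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [o for ev in events for o in sorted(ev.outcomes)]
    perm = rng.permutation(len(labels))
    shuffled = [labels[i] for i in perm]
    out, k = [], 0
    for ev in events:
        size = len(ev.outcomes)
        chunk = shuffled[k:k + size]
        k += size
        out.append(Event(ev.cues, frozenset(chunk), ev.trial_index))
    return out


def run_sim1_randomization(
    seed: int = 0,
    n_baselines: int = 1000,
    n_trials: int = 1600,
    eta: float = 0.01,
    spec: LanguageSpec | None = None,
) -> dict[str, RandomizationResult]:
    """Both Simulation-1 tests (overlapping form, distinct meaning).

    The baseline protocol is identical for the two statistics, so each of
    the ``n_baselines`` retrained model pairs yields both.
    """
    spec = spec or build_language_spec()
    rng = np.random.default_rng(seed)
    tokens = noun_token_stream(spec, n_trials, rng)
    pre_cs, post_cs = _sim1_streams(spec, tokens)
    obs_form, obs_meaning = sim1_statistics(spec, pre_cs, post_cs, eta)
    stats = np.zeros((n_baselines, 2))
    for b in range(n_baselines):
        perms = (rng.permutation(n_trials), rng.permutation(n_trials))
        stats[b] = sim1_statistics(spec, pre_cs, post_cs, eta, outcome_perms=perms)
    return {
        "sim1_form": RandomizationResult(obs_form, stats[:, 0], ALTERNATIVE["sim1_form"], "sim1_form"),
        "sim1_meaning": RandomizationResult(
            obs_meaning, stats[:, 1], ALTERNATIVE["sim1_meaning"], "sim1_meaning"
        ),
    }


def run_sim2_randomization(
    seed: int = 0,
    n_baselines: int = 1000,
    n_epochs: int = 73,
    eta: float = 0.01,
    spec: LanguageSpec | None = None,
    alternatives: str = "model",
) -> RandomizationResult:
    spec = spec or build_language_spec()
    rng = np.random.default_rng(seed)
    n_trials = n_epochs * spec.trials_per_epoch
    tokens = noun_token_stream(spec, n_trials, rng)
    setup = _Sim2Setup.build(spec, tokens, n_trials // 4)
    observed = sim2_statistic(setup, eta, alternatives)
    stats = np.zeros(n_baselines)
    for b in range(n_baselines):
        stats[b] = sim2_statistic(setup, eta, alternatives,
                                  outcome_perm=rng.permutation(n_trials))
    return RandomizationResult(observed, stats, ALTERNATIVE["sim2"], "sim2")


def run_randomization_test(
    sim_id: SimId,
    seed: int = 0,
    n_baselines: int = 1000,
    spec: LanguageSpec | None = None,
    **kwargs,
) -> RandomizationResult:
    """One of the three randomization tests by name."""
    if sim_id in ("sim1_form", "sim1_meaning"):
        return run_sim1_randomization(seed, n_baselines, spec=spec, **kwargs)[sim_id]
    if sim_id == "sim2":
        return run_sim2_randomization(seed, n_baselines, spec=spec, **kwargs)
    raise ValueError(f"unknown test: {sim_id!r}")
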