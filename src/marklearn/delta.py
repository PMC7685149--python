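"""Incremental error-driven (delta-rule / Widrow-Hoff) learning.

A fully connected two-layer network stores an association weight
``V[i, j]`` from every cue ``i`` to every outcome ``j``.  On each trial the
outcome activation is the summed weight of the present cues,

    act(j) = sum_{x in cues(t)} V[x, j],

and each present cue's weight to outcome ``j`` moves by
``eta * (1 - act(j))`` if ``j`` occurred and ``eta * (0 - act(j))``
otherwise; absent cues are untouched.  All deltas of one trial are computed
from the pre-trial matrix and applied at once (the standard simultaneous
Rescorla-Wagner convention).  With a small learning rate this is the LMS
rule, whose long-run fixed point from a zero start is the minimum-norm
least-squares regression of outcome indicators on cue indicators under the
empirical event frequencies -- which :func:`asymptote_oracle` computes in
closed form as an independent check on the trained weights.

Cues and outcomes are indexed up front from the full event stream, so
negative evidence applies to every outcome the stream will ever contain
(removing order-of-first-appearance artifacts and matching batch-style
asymptotes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._kernel import run_training
from .language import Event

__all__ = [
    "LearnerConfig",
    "NumericFailure",
    "WeightMatrix",
    "WeightTrajectory",
    "asymptote_oracle",
    "detect_asymptote",
    "train",
    "update_weights",
]


class NumericFailure(FloatingPointError):
    """Weights became non-finite during training."""


@dataclass(frozen=True)
class LearnerConfig:
    """Learning-rate and trajectory-recording settings.

    eta is the single learning-rate parameter of the rule (default 0.01).
    """

    eta: float = 0.01
    record_every: int | None = None
    record_deltas: bool = False
    asymptote_tol: float = 1e-4
    asymptote_window: int = 412

    def __post_init__(self) -> None:
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")


class WeightMatrix:
    """Labeled cue x outcome weight matrix."""

    def __init__(
        self,
        cue_index: Sequence[str],
        outcome_index: Sequence[str],
        values: np.ndarray | None = None,
    ) -> None:
        self.cue_index = list(cue_index)
        self.outcome_index = list(outcome_index)
        if values is None:
            values = np.zeros((len(self.cue_index), len(self.outcome_index)))
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.cue_index), len(self.outcome_index)):
            raise ValueError("values shape does not match index lengths")
        self.values = values
        self._cue_pos = {c: i for i, c in enumerate(self.cue_index)}
        self._out_pos = {o: j for j, o in enumerate(self.outcome_index)}

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.cue_index, self.outcome_index, self.values.copy())

    def __getitem__(self, key: tuple[str, str]) -> float:
        cue, outcome = key
        return float(self.values[self._cue_pos[cue], self._out_pos[outcome]])

    def activations(self, cues: Iterable[str], strict: bool = False) -> np.ndarray:
        """Summed present-cue weights for every outcome (zero for unknown cues)."""
        rows = []
        for c in cues:
            if c in self._cue_pos:
                rows.append(self._cue_pos[c])
            elif strict:
                raise KeyError(f"unknown cue: {c!r}")
        if not rows:
            return np.zeros(len(self.outcome_index))
        return self.values[rows].sum(axis=0)

    def activation_of(self, cues: Iterable[str], outcome: str) -> float:
        return float(self.activations(cues)[self._out_pos[outcome]])

    def activation_map(self, cues: Iterable[str]) -> dict[str, float]:
        acts = self.activations(cues)
        return {o: float(a) for o, a in zip(self.outcome_index, acts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cue_index, columns=self.outcome_index)

    def to_long(self) -> pd.DataFrame:
        df = self.to_frame().stack().rename("weight").reset_index()
        df.columns = ["cue", "outcome", "weight"]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class WeightTrajectory:
    """Weights over training: final matrix, snapshots, per-trial update sizes.

    ``max_delta[t]`` is the largest absolute per-weight change on trial
    ``t + 1``; ``deltas`` (optional) stores it per outcome column.  A
    snapshot at trial ``t`` equals replaying events ``1..t`` from zeros.
    """

    final: WeightMatrix
    snapshots: dict[int, WeightMatrix] = field(default_factory=dict)
    max_delta: np.ndarray | None = None
    deltas: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return 0 if self.max_delta is None else int(self.max_delta.shape[0])

    def at(self, trial: int) -> WeightMatrix:
        if trial == self.n_trials:
            return self.final
        return self.snapshots[trial]


def update_weights(W: WeightMatrix, event: Event, eta: float = 0.01) -> WeightMatrix:
    """Apply one delta-rule trial, returning a new matrix.

    Unknown cue/outcome labels auto-grow the matrix with zero rows/columns.
    Activations are taken from the pre-trial matrix for every cell of the
    trial; rows of absent cues are unchanged.
    """
    cue_index = W.cue_index + [c for c in sorted(event.cues) if c not in W._cue_pos]
    out_index = W.outcome_index + [o for o in sorted(event.outcomes) if o not in W._out_pos]
    values = np.zeros((len(cue_index), len(out_index)))
    values[: len(W.cue_index), : len(W.outcome_index)] = W.values
    new = WeightMatrix(cue_index, out_index, values)
    rows = [new._cue_pos[c] for c in event.cues]
    target = np.zeros(len(out_index))
    target[[new._out_pos[o] for o in event.outcomes]] = 1.0
    delta = eta * (target - new.values[rows].sum(axis=0))
    if not np.all(np.isfinite(delta)):
        raise NumericFailure("non-finite weight update")
    new.values[rows] += delta
    return new


def _index_events(events: Sequence[Event]) -> tuple[list[str], list[str]]:
    cues: dict[str, None] = {}
    outs: dict[str, None] = {}
    for ev in events:
        for c in sorted(ev.cues):
            cues.setdefault(c)
        for o in sorted(ev.outcomes):
            outs.setdefault(o)
    return list(cues), list(outs)


def compile_events(
    events: Sequence[Event],
    cue_pos: Mapping[str, int],
    out_pos: Mapping[str, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten events into index arrays consumable by the training kernel."""
    cue_flat, out_flat = [], []
    cue_off = np.zeros(len(events) + 1, dtype=np.int64)
    out_off = np.zeros(len(events) + 1, dtype=np.int64)
    for t, ev in enumerate(events):
        cue_flat.extend(cue_pos[c] for c in ev.cues)
        out_flat.extend(out_pos[o] for o in ev.outcomes)
        cue_off[t + 1] = len(cue_flat)
        out_off[t + 1] = len(out_flat)
    return (
        np.asarray(cue_flat, dtype=np.int64),
        cue_off,
        np.asarray(out_flat, dtype=np.int64),
        out_off,
    )


def train(
    events: Sequence[Event],
    config: LearnerConfig | None = None,
    cue_labels: Sequence[str] | None = None,
    outcome_labels: Sequence[str] | None = None,
    init: WeightMatrix | None = None,
    active_outcomes: Sequence[str] | None = None,
    snapshots_at: Sequence[int] = (),
) -> WeightTrajectory:
    """Train a delta-rule network over an ordered event stream.

    Parameters
    ----------
    events:
        Ordered learning trials.
    config:
        Learning settings; default ``LearnerConfig()`` (eta = 0.01).
    cue_labels, outcome_labels:
        Optional pre-specified indices; by default both are collected from
        the full stream before training starts.
    init:
        Starting weights (copied); used for continuation training.  Must
        cover all labels of the stream.
    active_outcomes:
        If given, only these outcome columns receive updates; all other
        columns stay frozen.  This implements training inside a reduced
        outcome set, where negative evidence applies only within the set.
    snapshots_at:
        1-based trial indices at which full weight copies are kept.
    """
    if len(events) == 0:
        raise ValueError("event stream must be non-empty")
    config = config or LearnerConfig()
    if init is not None:
        cue_index = list(init.cue_index)
        out_index = list(init.outcome_index)
        auto_c, auto_o = _index_events(events)
        missing = [c for c in auto_c if c not in init._cue_pos] + [
            o for o in auto_o if o not in init._out_pos
        ]
        if missing:
            raise ValueError(f"init matrix lacks labels: {missing[:5]}")
        W_full = init.values.copy()
    else:
        auto_c, auto_o = _index_events(events)
        cue_index = list(cue_labels) if cue_labels is not None else auto_c
        out_index = list(outcome_labels) if outcome_labels is not None else auto_o
        W_full = np.zeros((len(cue_index), len(out_index)))
    cue_pos = {c: i for i, c in enumerate(cue_index)}
    out_pos = {o: j for j, o in enumerate(out_index)}

    if active_outcomes is not None:
        active = sorted({out_pos[o] for o in active_outcomes})
    else:
        active = list(range(len(out_index)))
    active_arr = np.asarray(active, dtype=np.int64)
    sub_pos = {out_index[j]: a for a, j in enumerate(active)}
    cue_flat, cue_off, out_flat, out_off = compile_events(events, cue_pos, sub_pos)

    snap_list = sorted(set(int(s) for s in snapshots_at))
    if config.record_every:
        snap_list = sorted(
            set(snap_list) | set(range(config.record_every, len(events) + 1, config.record_every))
        )
    snap_at = np.asarray([s for s in snap_list if 1 <= s <= len(events)], dtype=np.int64)

    W = np.ascontiguousarray(W_full[:, active_arr])
    snaps = np.zeros((len(snap_at), W.shape[0], W.shape[1]))
    max_delta = np.zeros(len(events))
    deltas = (
        np.zeros((len(events), W.shape[1])) if config.record_deltas else np.zeros((1, 1))
    )
    bad = run_training(
        W, cue_flat, cue_off, out_flat, out_off, config.eta,
        snap_at, snaps, max_delta, deltas, config.record_deltas,
    )
    if bad:
        raise NumericFailure(f"non-finite weights at trial {bad}")

    def scatter(sub: np.ndarray) -> WeightMatrix:
        full = W_full.copy()
        full[:, active_arr] = sub
        return WeightMatrix(cue_index, out_index, full)

    traj = WeightTrajectory(
        final=scatter(W),
        snapshots={int(s): scatter(snaps[i]) for i, s in enumerate(snap_at)},
        max_delta=max_delta,
        deltas=deltas if config.record_deltas else None,
    )
    return traj


def asymptote_oracle(
    events: Sequence[Event] | Sequence[tuple[Event, float]],
    cue_labels: Sequence[str] | None = None,
    outcome_labels: Sequence[str] | None = None,
) -> WeightMatrix:
    """Closed-form long-run weights: frequency-weighted least squares.

    Collapses the stream to distinct (cue set, outcome set) types with
    multiplicities and returns the minimum-norm solution of the weighted
    regression of outcome indicators on cue indicators -- the small-eta
    fixed point of the LMS recursion started from zero.  Rank deficiency is
    handled by the pseudoinverse (minimum-norm) solution.
    """
    pairs: list[tuple[Event, float]] = []
    for item in events:
        if isinstance(item, Event):
            pairs.append((item, 1.0))
        else:
            ev, w = item
            pairs.append((ev, float(w)))
    agg: dict[tuple[frozenset, frozenset], float] = {}
    for ev, w in pairs:
        agg[(ev.cues, ev.outcomes)] = agg.get((ev.cues, ev.outcomes), 0.0) + w
    if cue_labels is None or outcome_labels is None:
        auto_c, auto_o = _index_events([ev for ev, _ in pairs])
        cue_labels = cue_labels or auto_c
        outcome_labels = outcome_labels or auto_o
    cue_pos = {c: i for i, c in enumerate(cue_labels)}
    out_pos = {o: j for j, o in enumerate(outcome_labels)}
    X = np.zeros((len(agg), len(cue_labels)))
    Y = np.zeros((len(agg), len(outcome_labels)))
    w = np.zeros(len(agg))
    for r, ((cues, outs), weight) in enumerate(agg.items()):
        X[r, [cue_pos[c] for c in cues]] = 1.0
        Y[r, [out_pos[o] for o in outs]] = 1.0
        w[r] = weight
    sw = np.sqrt(w / w.sum())[:, None]
    sol, *_ = np.linalg.lstsq(X * sw, Y * sw, rcond=None)
    return WeightMatrix(list(cue_labels), list(outcome_labels), sol)


def detect_asymptote(
    traj: WeightTrajectory,
    tol: float | None = None,
    window: int | None = None,
    outcomes: Sequence[str] | None = None,
) -> int | None:
    """First trial after which weights have effectively stopped changing.

    Returns the smallest 1-based trial index ``t >= window`` such that the
    largest absolute per-weight change over trials ``t - window + 1 .. t``
    is below ``tol`` (monotone in ``tol``), or ``None`` if never reached.
    ``outcomes`` restricts the check to specific outcome columns (requires
    ``record_deltas=True`` during training); the default window is one
    412-trial epoch.
    """
    tol = 1e-4 if tol is None else tol
    window = 412 if window is None else int(window)
    if traj.max_delta is None or traj.n_trials < window:
        raise ValueError("trajectory must hold at least `window` recorded trials")
    if outcomes is not None:
        if traj.deltas is None:
            raise ValueError("per-outcome deltas were not recorded")
        pos = {o: j for j, o in enumerate(traj.final.outcome_index)}
        series = traj.deltas[:, [pos[o] for o in outcomes]].max(axis=1)
    else:
        series = traj.max_delta
    running = pd.Series(series).rolling(window).max().to_numpy()
    hits = np.nonzero(running[window - 1:] < tol)[0]
    if hits.size == 0:
        return None
    return int(hits[0] + window)
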