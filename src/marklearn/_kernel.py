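"""Inner training loop of the delta-rule learner.

The update for one trial is rank-deficient but dense in the outcome
dimension: every present cue row receives the same delta vector
``eta * (target_indicator - activation)``, computed from the pre-trial
weights.  The loop is sequential (each trial depends on the previous
weights), so it is compiled with numba when available and falls back to an
equivalent pure-numpy implementation otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _train_loop(W, cue_flat, cue_off, out_flat, out_off, eta,
                snap_at, snaps, max_delta, deltas, record_deltas):
    """Run all trials in place on W (cues x outcomes).

    snap_at: sorted 1-based trial indices at which to copy W into snaps.
    Returns the 1-based index of the first trial producing non-finite
    weights, or 0 on success.
    """
    n_trials = cue_off.shape[0] - 1
    n_out = W.shape[1]
    d = np.empty(n_out)
    snap_ptr = 0
    for t in range(n_trials):
        for j in range(n_out):
            d[j] = 0.0
        for ci in range(cue_off[t], cue_off[t + 1]):
            c = cue_flat[ci]
            for j in range(n_out):
                d[j] -= W[c, j]
        for j in range(n_out):
            d[j] *= eta
        for oi in range(out_off[t], out_off[t + 1]):
            d[out_flat[oi]] += eta
        m = 0.0
        for j in range(n_out):
            a = abs(d[j])
            if a > m:
                m = a
        if not np.isfinite(m):
            return t + 1
        max_delta[t] = m
        if record_deltas:
            for j in range(n_out):
                deltas[t, j] = abs(d[j])
        for ci in range(cue_off[t], cue_off[t + 1]):
            c = cue_flat[ci]
            for j in range(n_out):
                W[c, j] += d[j]
        if snap_ptr < snap_at.shape[0] and snap_at[snap_ptr] == t + 1:
            for i in range(W.shape[0]):
                for j in range(n_out):
                    snaps[snap_ptr, i, j] = W[i, j]
            snap_ptr += 1
    return 0


def _train_loop_numpy(W, cue_flat, cue_off, out_flat, out_off, eta,
                      snap_at, snaps, max_delta, deltas, record_deltas):
    n_trials = cue_off.shape[0] - 1
    snap_ptr = 0
    for t in range(n_trials):
        cues = cue_flat[cue_off[t]:cue_off[t + 1]]
        d = -eta * W[cues].sum(axis=0)
        d[out_flat[out_off[t]:out_off[t + 1]]] += eta
        m = np.abs(d).max()
        if not np.isfinite(m):
            return t + 1
        max_delta[t] = m
        if record_deltas:
            deltas[t] = np.abs(d)
        W[cues] += d
        if snap_ptr < snap_at.shape[0] and snap_at[snap_ptr] == t + 1:
            snaps[snap_ptr] = W
            snap_ptr += 1
    return 0


def run_training(W, cue_flat, cue_off, out_flat, out_off, eta,
                 snap_at, snaps, max_delta, deltas, record_deltas):
    loop = _train_loop if _HAVE_NUMBA else _train_loop_numpy
    return loop(W, cue_flat, cue_off, out_flat, out_off, float(eta),
                snap_at, snaps, max_delta, deltas, record_deltas)
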