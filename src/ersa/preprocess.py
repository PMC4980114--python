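"""Epoch-level preprocessing: automated artifact rejection and response locking.

The rejection rule is fully automated: pooling all time points of all
trials of one phase, a trial is discarded when at least one of its time
points exceeds three interquartile ranges above the median in *both*
absolute amplitude and absolute gradient (first difference) at the same
time point.  Requiring the joint exceedance means large slow drifts (high
amplitude, low gradient) and brief low-amplitude glitches survive, while
high-amplitude fast transients are removed.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import EpochSet
from .spectral import TimeFrequencyRepresentation

logger = logging.getLogger(__name__)

IQR_FACTOR = 3.0
RESPONSE_WINDOW = (-1.0, 0.1)


def artifact_thresholds(epochs: EpochSet, factor: float = IQR_FACTOR) -> tuple[float, float]:
    """(amplitude, gradient) thresholds: pooled median + ``factor`` * IQR.

    Both statistics are computed on absolute values pooled over every time
    point of every trial, so the thresholds are invariant to trial order.
    """
    amp = np.abs(epochs.data).ravel()
    grad = np.abs(np.diff(epochs.data, axis=1)).ravel()
    thr = []
    for v in (amp, grad):
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        thr.append(med + factor * (q3 - q1))
    return thr[0], thr[1]


def reject_artifacts(
    epochs: EpochSet, factor: float = IQR_FACTOR
) -> tuple[EpochSet, np.ndarray]:
    """Drop trials with a joint amplitude+gradient threshold exceedance.

    Returns the cleaned :class:`EpochSet` and the boolean rejection mask
    (True = rejected) for audit.  The gradient at sample ``t`` is
    ``x[t+1] - x[t]``; the joint test uses the amplitude at either endpoint
    of the offending step, so a transient is caught on its rising or
    falling flank.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials to estimate rejection thresholds")
    thr_amp, thr_grad = artifact_thresholds(epochs, factor)
    amp = np.abs(epochs.data)
    grad = np.abs(np.diff(epochs.data, axis=1))
    amp_hit = amp > thr_amp
    joint = (grad > thr_grad) & (amp_hit[:, :-1] | amp_hit[:, 1:])
    rejected = joint.any(axis=1)
    n = int(rejected.sum())
    if n:
        logger.info("rejected %d/%d trials (%.1f%%)", n, epochs.n_trials,
                    100.0 * n / epochs.n_trials)
    return epochs.select(~rejected), rejected


def response_lock(
    epochs: EpochSet,
    latencies: np.ndarray | None = None,
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> tuple[EpochSet, np.ndarray]:
    """Realign stimulus-locked traces to the button press.

    The output covers ``window`` (default -1.0..+0.1 s) around each trial's
    response: the sample at output time ``t`` equals the input sample at
    ``rt + t``.  Trials whose realigned window falls outside the source
    epoch, or whose latency is missing, are dropped with a warning; the
    boolean mask of kept trials is returned alongside.
    """
    if epochs.lock != "stimulus":
        raise ValueError("response_lock expects stimulus-locked epochs")
    if latencies is None:
        if "rt_s" not in getattr(epochs.events, "columns", ()):
            raise ValueError("no latencies given and events lack an rt_s column")
        latencies = epochs.events["rt_s"].to_numpy(dtype=float)
    latencies = np.asarray(latencies, dtype=float)
    if latencies.size != epochs.n_trials:
        raise ValueError("one latency per trial required")

    sfreq = epochs.sfreq
    n_out = int(round((window[1] - window[0]) * sfreq)) + 1
    out_times = window[0] + np.arange(n_out) / sfreq
    t0 = epochs.times[0]

    finite = np.isfinite(latencies)
    start = np.zeros(latencies.size, dtype=int)
    start[finite] = np.round((latencies[finite] + window[0] - t0) * sfreq).astype(int)
    ok = finite & (start >= 0) & (start + n_out <= epochs.n_samples)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("response_lock dropped %d/%d trials (latency missing or "
                       "window outside epoch)", dropped, epochs.n_trials)
    idx = np.flatnonzero(ok)
    data = np.empty((idx.size, n_out), dtype=epochs.data.dtype)
    for row, i in enumerate(idx):
        data[row] = epochs.data[i, start[i]:start[i] + n_out]
    ev = epochs.events.iloc[idx].reset_index(drop=True) if len(epochs.events) else epochs.events
    out = EpochSet(data=data, times=out_times, sfreq=sfreq, lock="response", events=ev)
    return out, ok


def response_lock_tfr(
    tfr: TimeFrequencyRepresentation,
    latencies: np.ndarray | None = None,
    window: tuple[float, float] = RESPONSE_WINDOW,
) -> tuple[TimeFrequencyRepresentation, np.ndarray]:
    """Realign a stimulus-locked TFR to the response by shifting the 10-ms grid.

    The decomposition stays as computed on the full stimulus-locked epoch
    (avoiding edge artifacts from re-windowing raw data); each trial's time
    axis is resampled at the nearest 10-ms bin of ``rt + t``.  Trials whose
    shifted window leaves the grid, or would include edge-padded estimates
    at frequencies above ``STRICT_VALID_FMIN``, are dropped (mask returned).
    """
    from .spectral import STRICT_VALID_FMIN
    if tfr.lock != "stimulus":
        raise ValueError("expected a stimulus-locked TFR")
    if latencies is None:
        if tfr.events is None or "rt_s" not in tfr.events.columns:
            raise ValueError("no latencies given and events lack an rt_s column")
        latencies = tfr.events["rt_s"].to_numpy(dtype=float)
    latencies = np.asarray(latencies, dtype=float)
    step = float(np.round(np.median(np.diff(tfr.times)), 6))
    n_out = int(round((window[1] - window[0]) / step)) + 1
    out_times = window[0] + np.arange(n_out) * step

    finite = np.isfinite(latencies)
    rt_bins = np.zeros(latencies.size, dtype=int)
    rt_bins[finite] = np.round(latencies[finite] / step).astype(int)
    first_bin = int(round(tfr.times[0] / step))
    start = rt_bins + int(round(window[0] / step)) - first_bin
    ok = finite & (start >= 0) & (start + n_out <= tfr.times.size)
    strict_rows = tfr.frequencies >= STRICT_VALID_FMIN
    vrow = tfr.valid[strict_rows].all(axis=0) if strict_rows.any() \
        else np.ones(tfr.times.size, bool)
    for i in np.flatnonzero(ok):
        if not vrow[start[i]:start[i] + n_out].all():
            ok[i] = False
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("response_lock_tfr dropped %d/%d trials", dropped, tfr.n_trials)
    idx = np.flatnonzero(ok)
    power = np.empty((idx.size, tfr.power.shape[1], n_out), dtype=tfr.power.dtype)
    valid = np.ones((tfr.power.shape[1], n_out), dtype=bool)
    for row, i in enumerate(idx):
        sl = slice(start[i], start[i] + n_out)
        power[row] = tfr.power[i, :, sl]
        valid &= tfr.valid[:, sl]
    ev = None if tfr.events is None else tfr.events.iloc[idx].reset_index(drop=True)
    from dataclasses import replace
    out = replace(tfr, power=power, times=out_times, valid=valid, lock="response",
                  events=ev)
    return out, ok
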