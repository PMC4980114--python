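"""Encoding x retrieval reinstatement maps from sliding Spearman correlations.

A *pattern* is the relative-power matrix (43 frequencies x a short time
window) centred on one 10-ms bin.  Sliding the centre over encoding and
retrieval time and Spearman-correlating every encoding pattern with every
retrieval pattern of the same trial yields that trial's reinstatement map.
Surrogate maps repeat the construction between a trial's retrieval
patterns and the encoding patterns of *other* trials sharing the same
target association, controlling for category-level similarity.

Pattern variants
----------------
``tf_400ms``   43 x 41 values over a 400-ms window (reference analysis)
``freqs_only`` 43 values at the centre bin alone
``tf_500ms``   43 x 51 values over a 500-ms window
``avg_500ms``  43 values, the 500-ms window averaged over time

Spearman correlations use average ranks for ties.  Constant patterns have
no defined rank correlation; the affected bins are set to NaN and excluded
from all averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .spectral import TIME_STEP, TimeFrequencyRepresentation

logger = logging.getLogger(__name__)

__all__ = [
    "VARIANTS", "BANDS", "Pattern", "ReinstatementMap",
    "extract_pattern", "pattern_centers", "rank_pattern_matrix",
    "reinstatement_map", "maps_from_rank_matrices", "condition_average",
    "surrogate_maps", "band_restricted_map", "correlation_weights", "fisher_z",
]

#: variant -> (window length s, average over time?)
VARIANTS = {
    "tf_400ms": (0.400, False),
    "freqs_only": (0.0, False),
    "tf_500ms": (0.500, False),
    "avg_500ms": (0.500, True),
}

#: frequency-band boundaries (Hz, inclusive on the analysis grid) used by
#: the band exclusion/inclusion analysis
BANDS = {
    "delta": (2, 3), "theta": (4, 7), "alpha": (8, 12),
    "beta": (13, 29), "gamma1": (30, 50), "gamma2": (55, 100),
}

from .spectral import STRICT_VALID_FMIN


@dataclass
class Pattern:
    """One trial's frequency x time relative-power pattern."""

    values: np.ndarray            # (43, n_window_bins)
    variant: str
    center: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pattern contains non-finite values")


@dataclass
class ReinstatementMap:
    """Correlations on an encoding-time x retrieval-time grid."""

    values: np.ndarray            # (n_enc, n_ret)
    enc_times: np.ndarray
    ret_times: np.ndarray
    scale: str = "rho"            # rho | fisher_z
    lock: str = "stimulus"
    provenance: str = "own"       # own | surrogate

    def window_mean(self, enc_window: tuple[float, float],
                    ret_window: tuple[float, float]) -> float:
        ei = _range_idx(self.enc_times, enc_window)
        ri = _range_idx(self.ret_times, ret_window)
        block = self.values[np.ix_(ei, ri)]
        return float(np.nanmean(block))

    def fisher(self) -> "ReinstatementMap":
        if self.scale != "rho":
            return self
        return replace(self, values=fisher_z(self.values), scale="fisher_z")


def _range_idx(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    eps = 1e-9
    idx = np.flatnonzero((times >= window[0] - eps) & (times <= window[1] + eps))
    if idx.size == 0:
        raise ValueError(f"window {window} contains no map bins")
    return idx


def _variant_bins(variant: str, step: float = TIME_STEP) -> tuple[int, int]:
    """(n_window_bins, half) for a variant; bins are odd-counted, centred."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown pattern variant {variant!r}")
    length, _ = VARIANTS[variant]
    n = int(round(length / step)) + 1
    return n, n // 2


def pattern_centers(
    tfr: TimeFrequencyRepresentation,
    variant: str = "tf_400ms",
    time_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Indices of grid bins usable as pattern centres.

    A centre is kept when its pattern window fits inside the time grid and
    every bin of frequencies >= :data:`STRICT_VALID_FMIN` within the window
    is strictly valid (full taper window inside the epoch) according to the
    TFR's validity mask; an optional *time_range* (seconds) restricts the
    result further.  For a stimulus-locked -1..+3 s epoch and the 400-ms
    variant this yields centres spanning about -0.49..2.49 s; for
    response-locked grids (already realigned from mid-epoch bins) it spans
    every centre whose window fits.
    """
    _, half = _variant_bins(variant)
    rows = tfr.frequencies >= STRICT_VALID_FMIN
    vrow = tfr.valid[rows].all(axis=0) if rows.any() else np.ones(tfr.times.size, bool)
    n_bins = 2 * half + 1
    csum = np.concatenate([[0], np.cumsum(vrow)])
    ok = np.zeros(tfr.times.size, dtype=bool)
    lo = np.arange(tfr.times.size) - half
    hi = np.arange(tfr.times.size) + half
    inside = (lo >= 0) & (hi < tfr.times.size)
    ok[inside] = (csum[hi[inside] + 1] - csum[lo[inside]]) == n_bins
    if time_range is not None:
        ok &= (tfr.times >= time_range[0] - 1e-9) & (tfr.times <= time_range[1] + 1e-9)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no valid pattern centres for this epoch/variant")
    return idx


def extract_pattern(
    tfr: TimeFrequencyRepresentation,
    trial: int,
    center: float,
    variant: str = "tf_400ms",
) -> Pattern:
    """The frequency x time pattern of one trial centred at *center* seconds."""
    if tfr.normalization == "raw":
        raise ValueError("patterns are defined on normalized (relative/log) power")
    n_bins, half = _variant_bins(variant)
    ci = int(np.argmin(np.abs(tfr.times - center)))
    if abs(tfr.times[ci] - center) > TIME_STEP / 2 + 1e-9:
        raise ValueError(f"center {center} s is not on the 10-ms grid")
    lo, hi = ci - half, ci + half
    if lo < 0 or hi >= tfr.times.size:
        raise ValueError("pattern window out of range")
    vals = tfr.power[trial, :, lo:hi + 1]
    if VARIANTS[variant][1]:
        vals = vals.mean(axis=1, keepdims=True)
    return Pattern(values=np.array(vals), variant=variant, center=float(tfr.times[ci]))


def _windowed_features(power: np.ndarray, centers: np.ndarray,
                       variant: str, freq_rows: np.ndarray | None) -> np.ndarray:
    """(n_centers, n_features) matrix of vectorized patterns for one trial."""
    n_bins, half = _variant_bins(variant)
    if freq_rows is not None:
        power = power[freq_rows]
    sw = np.lib.stride_tricks.sliding_window_view(power, n_bins, axis=1)
    starts = centers - half
    if starts.min() < 0 or starts.max() >= sw.shape[1]:
        raise ValueError("pattern window out of range")
    feats = sw[:, starts, :]                      # (F, n_centers, n_bins)
    if VARIANTS[variant][1]:
        feats = feats.mean(axis=2, keepdims=True)
    return np.ascontiguousarray(feats.transpose(1, 0, 2).reshape(centers.size, -1))


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (1..n); fast argsort path, scipy fallback on ties."""
    order = np.argsort(x, axis=1)
    sorted_x = np.take_along_axis(x, order, axis=1)
    tie_rows = np.flatnonzero((sorted_x[:, 1:] == sorted_x[:, :-1]).any(axis=1))
    ranks = np.empty(x.shape, dtype=np.float64)
    np.put_along_axis(ranks, order, np.arange(1.0, x.shape[1] + 1)[None, :], axis=1)
    if tie_rows.size:
        ranks[tie_rows] = rankdata(x[tie_rows], axis=1)
    return ranks


def rank_pattern_matrix(
    tfr: TimeFrequencyRepresentation,
    trial: int,
    centers: np.ndarray,
    variant: str = "tf_400ms",
    freq_rows: np.ndarray | None = None,
    dtype=np.float32,
) -> np.ndarray:
    """Centred, unit-norm rank matrix of a trial's sliding patterns.

    Row ``i`` holds the average-tie ranks of the pattern at ``centers[i]``,
    centred and scaled to unit norm, so Spearman correlations between any
    two patterns reduce to a dot product (NaN rows mark constant patterns).
    """
    feats = _windowed_features(tfr.power[trial], centers, variant, freq_rows)
    ranks = _average_ranks(feats).astype(dtype)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = ranks / norms
    z[norms[:, 0] == 0] = np.nan
    return z


def maps_from_rank_matrices(z_enc: np.ndarray, z_ret: np.ndarray) -> np.ndarray:
    """Spearman map (n_enc_centers x n_ret_centers) from two rank matrices."""
    return z_enc @ z_ret.T


def reinstatement_map(
    tfr_enc: TimeFrequencyRepresentation,
    tfr_ret: TimeFrequencyRepresentation,
    trial_enc: int,
    trial_ret: int,
    variant: str = "tf_400ms",
    enc_range: tuple[float, float] | None = None,
    ret_range: tuple[float, float] | None = None,
    dtype=np.float64,
) -> ReinstatementMap:
    """Sliding Spearman correlation map between one encoding and one
    retrieval trial (10-ms steps over all valid centres)."""
    eci = pattern_centers(tfr_enc, variant, enc_range)
    rci = pattern_centers(tfr_ret, variant, ret_range)
    ze = rank_pattern_matrix(tfr_enc, trial_enc, eci, variant, dtype=dtype)
    zr = rank_pattern_matrix(tfr_ret, trial_ret, rci, variant, dtype=dtype)
    vals = maps_from_rank_matrices(ze, zr)
    return ReinstatementMap(values=vals, enc_times=tfr_enc.times[eci],
                            ret_times=tfr_ret.times[rci], lock=tfr_ret.lock)


def condition_average(maps) -> ReinstatementMap:
    """Elementwise mean of trial maps (NaN bins excluded pairwise)."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    stack = np.stack([m.values for m in maps])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return replace(maps[0], values=mean)


def surrogate_maps(
    tfr_enc: TimeFrequencyRepresentation,
    tfr_ret: TimeFrequencyRepresentation,
    associations,
    variant: str = "tf_400ms",
    enc_range: tuple[float, float] | None = None,
    ret_range: tuple[float, float] | None = None,
    dtype=np.float32,
    return_trial_maps: bool = False,
):
    """Association-matched surrogate reinstatement for one participant's AR trials.

    Both TFRs must hold the same AR trials in the same order.  For trial
    ``i`` the surrogate is the mean map between its retrieval patterns and
    the encoding patterns of every *other* same-association trial; the
    participant-level surrogate map averages over trials.  Trials whose
    association has no partner are skipped (logged).
    """
    associations = np.asarray(associations)
    n = associations.size
    if tfr_enc.n_trials != n or tfr_ret.n_trials != n:
        raise ValueError("one association label per trial required")
    eci = pattern_centers(tfr_enc, variant, enc_range)
    rci = pattern_centers(tfr_ret, variant, ret_range)
    z_enc = [rank_pattern_matrix(tfr_enc, i, eci, variant, dtype=dtype)
             for i in range(n)]
    # mean over partner maps == map of the partners' mean rank matrix
    sums = {a: np.sum([z_enc[i] for i in np.flatnonzero(associations == a)], axis=0)
            for a in np.unique(associations)}
    counts = {a: int((associations == a).sum()) for a in np.unique(associations)}

    trial_maps, used = [], []
    for i in range(n):
        a = associations[i]
        if counts[a] < 2:
            logger.warning("trial %d skipped: association %r has no AR partner", i, a)
            continue
        partner_mean = (sums[a] - z_enc[i]) / (counts[a] - 1)
        zr = rank_pattern_matrix(tfr_ret, i, rci, variant, dtype=dtype)
        trial_maps.append(maps_from_rank_matrices(partner_mean, zr))
        used.append(i)
    if not trial_maps:
        raise ValueError("no AR trial has a same-association partner")
    mean_map = ReinstatementMap(
        values=np.mean(trial_maps, axis=0), enc_times=tfr_enc.times[eci],
        ret_times=tfr_ret.times[rci], lock=tfr_ret.lock, provenance="surrogate")
    if return_trial_maps:
        per_trial = [ReinstatementMap(values=v, enc_times=tfr_enc.times[eci],
                                      ret_times=tfr_ret.times[rci],
                                      lock=tfr_ret.lock, provenance="surrogate")
                     for v in trial_maps]
        return mean_map, per_trial, np.asarray(used)
    return mean_map


def band_restricted_map(
    tfr_enc: TimeFrequencyRepresentation,
    tfr_ret: TimeFrequencyRepresentation,
    trial_enc: int,
    trial_ret: int,
    band: str | None,
    mode: str = "exclude",
    variant: str = "tf_400ms",
    enc_range=None,
    ret_range=None,
) -> ReinstatementMap:
    """Reinstatement map computed on a subset of frequency rows.

    ``mode="exclude"`` drops the named band, ``mode="only"`` keeps just it;
    ``band=None`` with mode="exclude" (or a band covering the whole grid
    with mode="only") reproduces the reference map.
    """
    if mode not in ("exclude", "only"):
        raise ValueError("mode must be 'exclude' or 'only'")
    freqs = tfr_enc.frequencies
    if band is None:
        keep = np.ones(freqs.size, dtype=bool)
        if mode == "only":
            raise ValueError("mode='only' requires a band")
    else:
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}; choose from {sorted(BANDS)}")
        lo, hi = BANDS[band]
        inside = (freqs >= lo) & (freqs <= hi)
        keep = inside if mode == "only" else ~inside
    rows = np.flatnonzero(keep)
    if rows.size == 0:
        raise ValueError("no frequency rows retained")
    eci = pattern_centers(tfr_enc, variant, enc_range)
    rci = pattern_centers(tfr_ret, variant, ret_range)
    ze = rank_pattern_matrix(tfr_enc, trial_enc, eci, variant, freq_rows=rows,
                             dtype=np.float64)
    zr = rank_pattern_matrix(tfr_ret, trial_ret, rci, variant, freq_rows=rows,
                             dtype=np.float64)
    return ReinstatementMap(values=maps_from_rank_matrices(ze, zr),
                            enc_times=tfr_enc.times[eci], ret_times=tfr_ret.times[rci],
                            lock=tfr_ret.lock)


def correlation_weights(enc: Pattern | np.ndarray, ret: Pattern | np.ndarray) -> np.ndarray:
    """Per-frequency contributions to the Spearman correlation of two patterns.

    Both patterns are vectorized, rank-transformed and standardized with
    the normalization that makes the mean of elementwise products equal
    the correlation coefficient; the products are then summed across the
    time bins of each frequency row.  The 43 weights therefore sum to the
    Spearman correlation of the full patterns (to numerical precision).
    """
    a = enc.values if isinstance(enc, Pattern) else np.asarray(enc)
    b = ret.values if isinstance(ret, Pattern) else np.asarray(ret)
    if a.shape != b.shape:
        raise ValueError("patterns must share a shape")
    n_freq, n_time = a.shape
    n = a.size
    out = []
    for v in (a, b):
        r = rankdata(v.ravel())
        r = r - r.mean()
        s = r.std()
        if s == 0:
            raise ValueError("constant pattern: correlation undefined")
        out.append(r / s)
    prod = out[0] * out[1] / n
    return prod.reshape(n_freq, n_time).sum(axis=1)


def fisher_z(rho: np.ndarray | float):
    """Fisher z (atanh) transform; |rho| >= 1 is clipped with a warning."""
    arr = np.asarray(rho, dtype=float)
    limit = 1.0 - 1e-6
    if np.any(np.abs(arr[np.isfinite(arr)]) >= 1.0):
        warnings.warn("correlation(s) at or beyond +/-1 clipped before atanh",
                      RuntimeWarning, stacklevel=2)
    z = np.arctanh(np.clip(arr, -limit, limit))
    return float(z) if np.isscalar(rho) else z
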