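"""Group-level inference: cluster-based permutation tests and RM-ANOVA helpers.

All map-level tests are second-level random-effects analyses over
participants.  Suprathreshold bins (paired/one-sample t at a two-tailed
forming threshold, or one-way repeated-measures F at a one-tailed one)
are grouped into 4-connected clusters; each cluster's mass (the sum of
its statistic values) is compared against the permutation distribution of
the maximum cluster mass, giving family-wise corrected p-values.  The
paired/one-sample null flips the sign of whole participant difference
maps; the F null permutes condition labels within participant.  p-values
use the (b + 1) / (m + 1) estimator and are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "Cluster", "ClusterResult",
    "cluster_permutation_paired", "cluster_permutation_one_sample",
    "cluster_permutation_F", "conjunction_min_t", "median_split_linkage",
    "rm_anova_2x2", "rm_anova_oneway", "trialwise_crossband_correlation",
    "across_participant_correlation",
]

#: 4-neighbour connectivity on a 2-D grid
CONNECTIVITY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Cluster:
    sign: int
    mask: np.ndarray
    mass: float
    p: float = 1.0


@dataclass
class ClusterResult:
    """Thresholded statistic map with permutation-corrected clusters."""

    stat_map: np.ndarray
    threshold: float
    clusters: list[Cluster] = field(default_factory=list)
    stat: str = "t"
    alpha_cf: float = 0.05
    n_permutations: int = 0
    seed: int | None = None

    def significant_mask(self, alpha: float = 0.05, sign: int | None = None) -> np.ndarray:
        """Union of clusters with permutation p < *alpha* (optionally one sign)."""
        mask = np.zeros(self.stat_map.shape, dtype=bool)
        for c in self.clusters:
            if c.p < alpha and (sign is None or c.sign == sign):
                mask |= c.mask
        return mask

    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _as_maps(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3:
        raise ValueError("expected (n_participants, height, width) maps")
    return x


def _label(mask: np.ndarray):
    return ndimage.label(mask, structure=CONNECTIVITY)


def _signed_clusters(stat: np.ndarray, thr: float) -> list[Cluster]:
    clusters = []
    with np.errstate(invalid="ignore"):
        pos, neg = stat > thr, stat < -thr
    for sign, mask in ((1, pos), (-1, neg)):
        labels, n = _label(mask)
        for li in range(1, n + 1):
            m = labels == li
            clusters.append(Cluster(sign=sign, mask=m, mass=float(stat[m].sum())))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return clusters


def _max_mass(stat: np.ndarray, thr: float, two_sided: bool) -> float:
    best = 0.0
    with np.errstate(invalid="ignore"):
        masks = [stat > thr]
        if two_sided:
            masks.append(stat < -thr)
    for mask in masks:
        labels, n = _label(mask)
        if n:
            masses = ndimage.sum_labels(np.abs(stat), labels, np.arange(1, n + 1))
            best = max(best, float(masses.max()))
    return best


def _finalize(stat_map, thr, clusters, null_max, stat, alpha_cf, n_perm, seed):
    null_max = np.asarray(null_max)
    for c in clusters:
        b = int((null_max >= abs(c.mass)).sum())
        c.p = (b + 1) / (null_max.size + 1)
    return ClusterResult(stat_map=stat_map, threshold=thr, clusters=clusters,
                         stat=stat, alpha_cf=alpha_cf, n_permutations=null_max.size,
                         seed=seed)


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Sign-flip design: exhaustive when 2^n <= n_perm, else random draws."""
    if n <= 30 and 2 ** n <= n_perm:
        bits = np.arange(2 ** n, dtype=np.int64)
        return 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
    return rng.choice([-1.0, 1.0], size=(n_perm, n))


def cluster_permutation_one_sample(
    diffs: np.ndarray,
    alpha_cf: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster permutation test of participant maps against zero.

    Degenerate bins (non-finite or zero variance across participants) are
    excluded from the statistic map and from clustering.
    """
    d = _as_maps(diffs)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = rng or np.random.default_rng(seed)
    shape = d.shape[1:]
    flat = d.reshape(n, -1)

    good = np.isfinite(flat).all(axis=0)
    var = np.zeros(flat.shape[1])
    var[good] = flat[:, good].var(axis=0, ddof=1)
    good &= var > 0
    flat = np.where(good, flat, 0.0)

    sumsq = (flat ** 2).sum(axis=0)
    thr = float(sps.t.ppf(1 - alpha_cf / 2, n - 1))

    def t_of(signed_sum):
        mean = signed_sum / n
        v = (sumsq - n * mean ** 2) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / np.sqrt(v / n)
        t[~good] = np.nan
        return t.reshape(shape)

    t_obs = t_of(flat.sum(axis=0))
    clusters = _signed_clusters(t_obs, thr)

    signs = _sign_matrix(n, n_perm, rng)
    null_max = np.empty(signs.shape[0])
    chunk = max(1, int(2e8 // max(flat.shape[1], 1) // 8))
    for s0 in range(0, signs.shape[0], chunk):
        block = signs[s0:s0 + chunk] @ flat
        for j, row in enumerate(block):
            null_max[s0 + j] = _max_mass(t_of(row), thr, two_sided=True)

    stat_map = t_obs.copy()
    return _finalize(stat_map, thr, clusters, null_max, "t", alpha_cf,
                     signs.shape[0], seed)


def cluster_permutation_paired(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    alpha_cf: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Paired (A - B) cluster permutation test across participants."""
    a, b = _as_maps(cond_a), _as_maps(cond_b)
    if a.shape != b.shape:
        raise ValueError("condition maps must share a shape")
    return cluster_permutation_one_sample(a - b, alpha_cf=alpha_cf,
                                          n_perm=n_perm, seed=seed)


def _rm_f_from_cond_means(cond_sums, n, k, ss_resid_part, df1, df2):
    """F map given per-condition sums over participants (vectorized)."""
    grand = cond_sums.sum(axis=0) / (n * k)
    m = cond_sums / n
    ss_cond = n * ((m - grand) ** 2).sum(axis=0)
    ss_err = ss_resid_part - ss_cond
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_cond / df1) / (ss_err / df2)
    return f


def cluster_permutation_F(
    conditions,
    alpha_cf: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Omnibus one-way repeated-measures ANOVA cluster test over k conditions.

    *conditions* is a sequence of k congruent (n, H, W) arrays with
    complete pairing.  The null permutes condition labels independently
    within each participant.
    """
    X = np.stack([_as_maps(c) for c in conditions])  # (k, n, H, W)
    k, n = X.shape[:2]
    if k < 3:
        raise ValueError("omnibus F test needs k >= 3 conditions")
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    shape = X.shape[2:]
    flat = X.reshape(k, n, -1)
    P = flat.shape[2]

    good = np.isfinite(flat).all(axis=(0, 1))
    flat = np.where(good, flat, 0.0)

    df1, df2 = k - 1, (k - 1) * (n - 1)
    grand = flat.mean(axis=(0, 1))
    subj = flat.mean(axis=0)                       # (n, P)
    ss_total = ((flat - grand) ** 2).sum(axis=(0, 1))
    ss_subj = k * ((subj - grand) ** 2).sum(axis=0)
    ss_resid_part = ss_total - ss_subj             # = SS_cond + SS_err; invariant

    thr = float(sps.f.ppf(1 - alpha_cf, df1, df2))

    def f_map(cond_sums):
        f = _rm_f_from_cond_means(cond_sums, n, k, ss_resid_part, df1, df2)
        f[~good] = np.nan
        return f.reshape(shape)

    f_obs = f_map(flat.sum(axis=1))
    clusters = [c for c in _signed_clusters(f_obs, thr) if c.sign == 1]

    null_max = np.empty(n_perm)
    rows = np.arange(n)
    for pi in range(n_perm):
        perm = np.argsort(rng.random((n, k)), axis=1).T      # (k, n) labels per subject
        permuted_sums = flat[perm, rows[None, :], :].sum(axis=1)
        null_max[pi] = _max_mass(f_map(permuted_sums), thr, two_sided=False)

    return _finalize(f_obs, thr, clusters, null_max, "F", alpha_cf, n_perm, seed)


def conjunction_min_t(
    res_a: ClusterResult,
    res_b: ClusterResult,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-t conjunction of two independently corrected contrasts.

    Returns the intersection of the two results' significant *positive*
    cluster masks and the elementwise minimum of the t maps inside it
    (NaN outside).
    """
    if res_a.stat_map.shape != res_b.stat_map.shape:
        raise ValueError("statistic maps must share a grid")
    mask = res_a.significant_mask(alpha, sign=1) & res_b.significant_mask(alpha, sign=1)
    min_t = np.where(mask, np.fmin(res_a.stat_map, res_b.stat_map), np.nan)
    return mask, min_t


def median_split_linkage(
    power: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Mean of *values* in the high- vs. low-power half of the trials.

    Trials are split at the median of *power*; with an odd trial count the
    median trial is excluded.  Returns ``(mean_high, mean_low)``.
    """
    power = np.asarray(power, dtype=float)
    values = np.asarray(values, dtype=float)
    if power.size != values.size:
        raise ValueError("power and values must align")
    if power.size < 4:
        raise ValueError("need at least 4 trials for a median split")
    if np.ptp(power) == 0:
        raise ValueError("all power values equal: split undefined")
    order = np.argsort(power, kind="stable")
    n = power.size
    half = n // 2
    low = order[:half]
    high = order[half:] if n % 2 == 0 else order[half + 1:]
    return float(values[high].mean()), float(values[low].mean())


def _one_df_f(contrast: np.ndarray) -> tuple[float, float]:
    n = contrast.size
    mean = contrast.mean()
    se2 = contrast.var(ddof=1) / n
    if se2 == 0:
        return (0.0, 1.0) if mean == 0 else (np.inf, 0.0)
    f = mean ** 2 / se2
    return float(f), float(sps.f.sf(f, 1, n - 1))


def rm_anova_2x2(cells: np.ndarray) -> dict:
    """Within-subject 2x2 ANOVA from per-participant cell means.

    *cells* has shape (n, 2, 2) ordered [factor A level, factor B level].
    Each effect has df = (1, n-1); a noiseless non-zero contrast yields
    ``F = inf`` (flagged via p = 0).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 3 or cells.shape[1:] != (2, 2):
        raise ValueError("cells must be (n, 2, 2)")
    if not np.isfinite(cells).all():
        raise ValueError("missing cells")
    n = cells.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    c_a = cells[:, 0, :].mean(axis=1) - cells[:, 1, :].mean(axis=1)
    c_b = cells[:, :, 0].mean(axis=1) - cells[:, :, 1].mean(axis=1)
    c_i = cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]
    out = {}
    for name, c in (("A", c_a), ("B", c_b), ("interaction", c_i)):
        f, p = _one_df_f(c)
        out[name] = {"F": f, "p": p, "df": (1, n - 1)}
    return out


def rm_anova_oneway(data: np.ndarray, gg_correction: bool = True) -> dict:
    """One-way repeated-measures ANOVA on (n, k) condition means.

    With *gg_correction* the p-value uses Greenhouse-Geisser adjusted
    degrees of freedom (epsilon from the double-centred covariance).
    """
    X = np.asarray(data, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 participants and k >= 2 conditions")
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((X - grand) ** 2).sum() - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_err == 0:
        return {"F": np.inf if ss_cond > 0 else 0.0, "p": 0.0 if ss_cond > 0 else 1.0,
                "df": (df1, df2), "epsilon": 1.0}
    f = (ss_cond / df1) / (ss_err / df2)
    eps = 1.0
    if gg_correction and k > 2:
        S = np.cov(X, rowvar=False)
        C = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
        eps = float(np.trace(C) ** 2 / ((k - 1) * (C ** 2).sum()))
        eps = min(max(eps, 1.0 / (k - 1)), 1.0)
    p = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return {"F": float(f), "p": p, "df": (df1, df2), "epsilon": eps}


def trialwise_crossband_correlation(
    band_a_by_participant,
    band_b_by_participant,
    alpha_cf: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
    min_trials: int = 10,
) -> tuple[np.ndarray, np.ndarray, ClusterResult]:
    """Trial-by-trial cross-band power correlation maps, tested at group level.

    For each participant, Pearson r between band-A power at time ``t1``
    and band-B power at ``t2`` across trials, for every (t1, t2) pair; the
    Fisher-z maps are then tested against zero with a sign-flip cluster
    permutation.  Inputs are per-participant ``(n_trials, n_times)``
    arrays (already restricted to the time range of interest).

    Returns ``(mean r map, group t map, ClusterResult)``.
    """
    from .reinstatement import fisher_z

    z_maps, r_maps = [], []
    for A, B in zip(band_a_by_participant, band_b_by_participant):
        A, B = np.asarray(A, float), np.asarray(B, float)
        if A.shape != B.shape:
            raise ValueError("band arrays must align per participant")
        if A.shape[0] < min_trials:
            raise ValueError(f"need >= {min_trials} trials per participant")
        za = (A - A.mean(0)) / A.std(0, ddof=1)
        zb = (B - B.mean(0)) / B.std(0, ddof=1)
        r = za.T @ zb / (A.shape[0] - 1)
        r_maps.append(r)
        z_maps.append(fisher_z(np.clip(r, -0.999999, 0.999999)))
    res = cluster_permutation_one_sample(np.stack(z_maps), alpha_cf=alpha_cf,
                                         n_perm=n_perm, seed=seed)
    return np.mean(r_maps, axis=0), res.stat_map, res


def across_participant_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two per-participant scalar vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    return float(sps.pearsonr(x, y)[0])
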