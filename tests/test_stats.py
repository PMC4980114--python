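"""Cluster permutation tests, conjunctions, RM-ANOVA helpers, linkage analyses."""

import numpy as np
import pytest
from scipy import stats as sps

from ersa.stats import (
    across_participant_correlation,
    cluster_permutation_F,
    cluster_permutation_one_sample,
    cluster_permutation_paired,
    conjunction_min_t,
    median_split_linkage,
    rm_anova_2x2,
    rm_anova_oneway,
    trialwise_crossband_correlation,
)


def _null_maps(rng, n=11, h=20, w=20):
    return rng.standard_normal((n, h, w))


def test_identical_conditions_give_empty_result(rng):
    a = _null_maps(rng)
    res = cluster_permutation_paired(a, a.copy(), n_perm=100, seed=0)
    assert res.clusters == []
    assert np.all(np.isnan(res.stat_map))  # zero-variance differences excluded


def test_planted_block_recovered(rng):
    """A broad 5-pooled-sd offset in a 20x20 sub-block is detected at p <= 0.002."""
    maps = rng.standard_normal((11, 40, 40))
    maps[:, 10:30, 5:25] += 5.0
    res = cluster_permutation_paired(maps, np.zeros_like(maps), n_perm=1000, seed=1)
    assert res.clusters[0].p <= 0.002
    block = np.zeros((40, 40), dtype=bool)
    block[10:30, 5:25] = True
    sig = res.significant_mask(0.05, sign=1)
    assert (sig & block).sum() / block.sum() > 0.9


def test_cluster_mass_bookkeeping(rng):
    maps = rng.standard_normal((8, 30, 30))
    maps[:, 5:12, 5:12] += 2.0
    res = cluster_permutation_one_sample(maps, n_perm=200, seed=3)
    n = maps.shape[0]
    d = maps.reshape(n, -1)
    t = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(n))
    t = t.reshape(30, 30)
    for c in res.clusters:
        assert c.mass == pytest.approx(t[c.mask].sum(), rel=1e-10)
        assert np.all(np.abs(res.stat_map[c.mask]) > res.threshold)


def test_permutation_p_sign_symmetric(rng):
    a, b = _null_maps(rng), _null_maps(rng)
    a[:, 3:8, 3:8] += 1.0
    r1 = cluster_permutation_paired(a, b, n_perm=400, seed=5)
    r2 = cluster_permutation_paired(-a, -b, n_perm=400, seed=5)
    p1 = sorted(c.p for c in r1.clusters)
    p2 = sorted(c.p for c in r2.clusters)
    assert p1 == p2


def test_seeded_reproducibility(rng):
    a, b = _null_maps(rng), _null_maps(rng)
    a[:, 2:9, 2:9] += 0.8
    r1 = cluster_permutation_paired(a, b, n_perm=300, seed=42)
    r2 = cluster_permutation_paired(a, b, n_perm=300, seed=42)
    assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]


def test_exhaustive_sign_flips_small_n(rng):
    a = rng.standard_normal((5, 1, 12)) + 1.5
    res = cluster_permutation_one_sample(a, n_perm=1000, seed=0)
    assert res.n_permutations == 2 ** 5  # exhaustive when 2^n <= n_perm


def test_conjunction_properties(rng):
    a = _null_maps(rng, h=30, w=30)
    a[:, 2:10, 2:10] += 3.0
    b = _null_maps(rng, h=30, w=30)
    b[:, 18:28, 18:28] += 3.0
    ra = cluster_permutation_one_sample(a, n_perm=300, seed=1)
    rb = cluster_permutation_one_sample(b, n_perm=300, seed=2)
    mask, min_t = conjunction_min_t(ra, rb)
    assert not mask.any()  # disjoint significant clusters -> empty conjunction
    mask_aa, min_t_aa = conjunction_min_t(ra, ra)
    assert np.array_equal(mask_aa, ra.significant_mask(0.05, sign=1))
    assert np.allclose(min_t_aa[mask_aa], ra.stat_map[mask_aa])
    # conjunction mask is contained in each parent's significant mask
    c = a + 0.3 * rng.standard_normal(a.shape)
    rc = cluster_permutation_one_sample(c, n_perm=300, seed=3)
    m, _ = conjunction_min_t(ra, rc)
    assert np.all(~m | ra.significant_mask(0.05, 1))
    assert np.all(~m | rc.significant_mask(0.05, 1))


def test_f_cluster_all_equal_empty(rng):
    base = _null_maps(rng, n=6, h=10, w=10)
    res = cluster_permutation_F([base, base.copy(), base.copy(), base.copy()],
                                n_perm=100, seed=0)
    assert res.clusters == []


def test_f_cluster_detects_single_deviant_condition(rng):
    conds = [_null_maps(rng, n=8, h=20, w=20) for _ in range(4)]
    conds[2][:, 5:15, 5:15] += 3.0
    res = cluster_permutation_F(conds, n_perm=300, seed=1)
    assert res.min_p() < 0.05
    sig = res.significant_mask(0.05)
    block = np.zeros((20, 20), dtype=bool)
    block[5:15, 5:15] = True
    assert (sig & block).any()
    means = [c[:, sig].mean() for c in conds]
    assert np.argmax(means) == 2  # post-hoc ordering matches the planted effect


def test_f_map_matches_anova_oracle(rng):
    """Bin-wise F equals statsmodels AnovaRM on a 5-participant toy (<= 1e-10)."""
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    data = rng.standard_normal((4, 5, 1, 1))
    res = cluster_permutation_F(list(data), n_perm=20, seed=0)
    df = pd.DataFrame({
        "subject": np.repeat(np.arange(5), 4),
        "cond": np.tile(np.arange(4), 5),
        "y": data[:, :, 0, 0].T.ravel(),
    })
    ref = AnovaRM(df, "y", "subject", within=["cond"]).fit()
    f_ref = float(ref.anova_table["F Value"].iloc[0])
    assert res.stat_map[0, 0] == pytest.approx(f_ref, abs=1e-10)


def test_rm_anova_2x2_against_oracle(rng):
    """All three effects match statsmodels AnovaRM on a noisy 2x2 design."""
    import pandas as pd
    from statsmodels.stats.anova import AnovaRM

    cells = rng.standard_normal((6, 2, 2))
    cells[:, 0, 0] += 1.0  # some structure
    out = rm_anova_2x2(cells)
    rows = []
    for s in range(6):
        for a in range(2):
            for b in range(2):
                rows.append({"s": s, "A": a, "B": b, "y": cells[s, a, b]})
    ref = AnovaRM(pd.DataFrame(rows), "y", "s", within=["A", "B"]).fit().anova_table
    assert out["A"]["F"] == pytest.approx(float(ref.loc["A", "F Value"]), abs=1e-10)
    assert out["B"]["F"] == pytest.approx(float(ref.loc["B", "F Value"]), abs=1e-10)
    assert out["interaction"]["F"] == pytest.approx(float(ref.loc["A:B", "F Value"]),
                                                    abs=1e-10)
    assert out["interaction"]["df"] == (1, 5)


def test_rm_anova_2x2_degenerate_patterns(rng):
    n = 5
    flat = np.ones((n, 2, 2))
    out = rm_anova_2x2(flat)
    assert out["interaction"]["F"] == 0.0
    crossed = np.array([[[1.0, -1.0], [-1.0, 1.0]]] * n)  # pure noiseless interaction
    out = rm_anova_2x2(crossed)
    assert np.isinf(out["interaction"]["F"]) and out["interaction"]["p"] == 0.0
    main_only = np.zeros((n, 2, 2))
    main_only[:, 0, :] = 1.0
    main_only += 0.01 * rng.standard_normal((n, 2, 2))
    out = rm_anova_2x2(main_only)
    assert out["A"]["F"] > 100
    assert out["interaction"]["F"] < 10


def test_rm_anova_oneway_gg_against_pingouin(rng):
    import pandas as pd
    import pingouin as pg

    data = rng.standard_normal((8, 4)) + np.array([0.0, 0.2, 0.5, 0.1])
    out = rm_anova_oneway(data)
    df = pd.DataFrame({"s": np.repeat(np.arange(8), 4),
                       "cond": np.tile(np.arange(4), 8),
                       "y": data.ravel()})
    ref = pg.rm_anova(data=df, dv="y", within="cond", subject="s", correction=True)
    assert out["F"] == pytest.approx(float(ref["F"].iloc[0]), abs=1e-8)
    assert out["epsilon"] == pytest.approx(float(ref["eps"].iloc[0]), abs=1e-8)
    assert out["p"] == pytest.approx(float(ref["p_GG_corr"].iloc[0]), abs=1e-8)


def test_median_split_examples():
    high, low = median_split_linkage([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert (high, low) == (3.5, 1.5)
    # odd n: the median trial is excluded
    high, low = median_split_linkage([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert (high, low) == (45.0, 15.0)
    with pytest.raises(ValueError):
        median_split_linkage([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
    with pytest.raises(ValueError):
        median_split_linkage([1, 2, 3], [1, 2, 3])


def test_median_split_recovers_planted_coupling(rng):
    hits = 0
    for _ in range(50):
        g = rng.lognormal(0, 0.5, 40)
        reinst = 0.05 * g + 0.01 * rng.standard_normal(40)
        hi, lo = median_split_linkage(g, reinst)
        hits += hi > lo
    assert hits >= 45  # >= 90% of runs
    # no coupling: difference centred at zero
    diffs = []
    for _ in range(200):
        g = rng.lognormal(0, 0.5, 40)
        reinst = rng.standard_normal(40)
        hi, lo = median_split_linkage(g, reinst)
        diffs.append(hi - lo)
    assert abs(np.mean(diffs)) < 3 * np.std(diffs, ddof=1) / np.sqrt(len(diffs))


def test_crossband_correlation_diagonal_and_null(rng):
    # band A == band B: unit diagonal
    A = [rng.standard_normal((30, 15)) for _ in range(5)]
    r_map, t_map, res = trialwise_crossband_correlation(A, A, n_perm=100, seed=0)
    assert np.allclose(np.diag(r_map), 1.0, atol=1e-10)
    # independent bands: group map centred on zero
    B = [rng.standard_normal((30, 15)) for _ in range(5)]
    r_map, t_map, res = trialwise_crossband_correlation(A, B, n_perm=200, seed=1)
    assert abs(r_map.mean()) < 0.05


def test_crossband_correlation_recovers_anticoupling(rng):
    """Early band-A power anti-correlated with later band-B power appears as a
    negative cluster."""
    a_maps, b_maps = [], []
    for _ in range(8):
        drive = rng.standard_normal((40, 1))
        A = np.tile(drive, (1, 12)) + 0.4 * rng.standard_normal((40, 12))
        B = np.tile(-drive, (1, 12)) + 0.4 * rng.standard_normal((40, 12))
        a_maps.append(A)
        b_maps.append(B)
    r_map, t_map, res = trialwise_crossband_correlation(a_maps, b_maps,
                                                        n_perm=300, seed=2)
    assert res.significant_mask(0.05, sign=-1).any()
    assert r_map.mean() < -0.5


def test_across_participant_correlation():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert across_participant_correlation(x, 2 * x) == pytest.approx(1.0)
    assert across_participant_correlation(x, -x) == pytest.approx(-1.0)
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
    assert across_participant_correlation(x, y) == pytest.approx(
        float(sps.pearsonr(x, y)[0]), abs=1e-12)
    with pytest.raises(ValueError):
        across_participant_correlation(x, np.ones(5))
    with pytest.raises(ValueError):
        across_participant_correlation(x[:2], x[:2])
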