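"""Reinstatement maps: Spearman oracle equivalence, surrogates, decompositions."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from ersa.reinstatement import (
    BANDS,
    band_restricted_map,
    condition_average,
    correlation_weights,
    extract_pattern,
    fisher_z,
    pattern_centers,
    rank_pattern_matrix,
    maps_from_rank_matrices,
    reinstatement_map,
    surrogate_maps,
)

from conftest import synthetic_tfr


def _random_tfr(rng, n_trials=1, n_times=401):
    return synthetic_tfr(rng.lognormal(0.0, 0.3, (n_trials, 43, n_times)))


@pytest.mark.parametrize("variant, shape", [("tf_400ms", (43, 41)),
                                            ("tf_500ms", (43, 51)),
                                            ("freqs_only", (43, 1))])
def test_pattern_variant_shapes(rng, variant, shape):
    tfr = _random_tfr(rng)
    pat = extract_pattern(tfr, 0, 1.0, variant)
    assert pat.values.shape == shape


def test_avg_500ms_pattern_of_constant(rng):
    tfr = synthetic_tfr(np.full((1, 43, 401), 4.2))
    pat = extract_pattern(tfr, 0, 1.0, "avg_500ms")
    assert pat.values.shape == (43, 1)
    assert np.allclose(pat.values, 4.2)


def test_self_correlation_diagonal_is_one(rng):
    tfr = _random_tfr(rng)
    m = reinstatement_map(tfr, tfr, 0, 0, enc_range=(0.5, 0.9), ret_range=(0.5, 0.9))
    assert np.allclose(np.diag(m.values), 1.0, atol=1e-12)


def test_swap_transposes_map(rng):
    enc, ret = _random_tfr(rng), _random_tfr(rng)
    a = reinstatement_map(enc, ret, 0, 0, enc_range=(0.4, 0.8), ret_range=(1.0, 1.4))
    b = reinstatement_map(ret, enc, 0, 0, enc_range=(1.0, 1.4), ret_range=(0.4, 0.8))
    assert np.allclose(a.values, b.values.T, atol=1e-12)


def test_spearman_matches_scipy_oracle(rng):
    """Map bins equal rank-then-Pearson with average ranks (brute force)."""
    enc, ret = _random_tfr(rng), _random_tfr(rng)
    m = reinstatement_map(enc, ret, 0, 0, enc_range=(0.5, 0.7), ret_range=(1.0, 1.2))
    for i, te in enumerate(m.enc_times[::7]):
        for j, tr in enumerate(m.ret_times[::7]):
            pe = extract_pattern(enc, 0, te).values.ravel()
            pr = extract_pattern(ret, 0, tr).values.ravel()
            ref = spearmanr(pe, pr).statistic
            assert m.values[7 * i, 7 * j] == pytest.approx(ref, abs=1e-12)


def test_tied_patterns_use_average_ranks(rng):
    """Duplicated power values (common after multitaper smoothing) still give
    the exact average-rank Spearman value."""
    power = np.round(rng.lognormal(0, 0.3, (1, 43, 401)), 1) + 0.05
    tfr = synthetic_tfr(power)
    other = _random_tfr(rng)
    m = reinstatement_map(tfr, other, 0, 0, enc_range=(0.5, 0.52), ret_range=(1.0, 1.02))
    pe = extract_pattern(tfr, 0, float(m.enc_times[0])).values.ravel()
    pr = extract_pattern(other, 0, float(m.ret_times[0])).values.ravel()
    assert m.values[0, 0] == pytest.approx(spearmanr(pe, pr).statistic, abs=1e-12)


def test_white_noise_maps_average_to_zero(rng):
    """Independent patterns: mean map over 200 trials is 0 within 2 SEM."""
    n = 200
    enc = synthetic_tfr(rng.lognormal(0, 0.3, (n, 43, 101)), t0=0.0)
    ret = synthetic_tfr(rng.lognormal(0, 0.3, (n, 43, 101)), t0=0.0)
    eci = pattern_centers(enc, time_range=(0.5, 0.52))
    rci = pattern_centers(ret, time_range=(0.5, 0.52))
    vals = [maps_from_rank_matrices(
        rank_pattern_matrix(enc, i, eci, dtype=np.float64),
        rank_pattern_matrix(ret, i, rci, dtype=np.float64)).mean()
        for i in range(n)]
    sem = np.std(vals, ddof=1) / np.sqrt(n)
    assert abs(np.mean(vals)) < 2 * sem + 1e-3


def test_constant_pattern_flagged_missing(rng):
    power = rng.lognormal(0, 0.3, (1, 43, 401))
    power[0, :, 95:160] = 1.0  # constant stretch -> constant patterns
    tfr = synthetic_tfr(power)
    other = _random_tfr(rng)
    m = reinstatement_map(tfr, other, 0, 0, enc_range=(0.2, 0.4), ret_range=(1.0, 1.1))
    assert np.isnan(m.values[0, 0])  # centre 0.2: window 0-0.4 fully constant
    avg = condition_average([m, m])
    assert np.isnan(avg.values[0, 0])


def test_condition_average_properties(rng):
    enc, ret = _random_tfr(rng), _random_tfr(rng)
    m = reinstatement_map(enc, ret, 0, 0, enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    single = condition_average([m])
    assert np.allclose(single.values, m.values, equal_nan=True)
    neg = type(m)(values=-m.values, enc_times=m.enc_times, ret_times=m.ret_times)
    assert np.allclose(condition_average([m, neg]).values, 0.0, atol=1e-12)
    a, b, c = (reinstatement_map(enc, ret, 0, 0, enc_range=(0.5, 0.6),
                                 ret_range=(1.0, 1.1)) for _ in range(3))
    perm = condition_average([c, a, b])
    assert np.allclose(perm.values, condition_average([a, b, c]).values)


def test_surrogate_identical_trials_equals_own(rng):
    """When all AR trials share one TFR, surrogate and own maps coincide."""
    base = rng.lognormal(0, 0.3, (1, 43, 401))
    tfr = synthetic_tfr(np.repeat(base, 4, axis=0))
    assoc = np.array(["blue", "blue", "red", "red"])
    sur = surrogate_maps(tfr, tfr, assoc, enc_range=(0.5, 0.6), ret_range=(1.0, 1.1),
                         dtype=np.float64)
    own = reinstatement_map(tfr, tfr, 0, 0, enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    assert np.allclose(sur.values, own.values, atol=1e-6)
    assert sur.provenance == "surrogate"


def test_surrogate_excludes_own_trial(rng):
    """With two trials per association the surrogate is exactly the partner map."""
    tfr = _random_tfr(rng, n_trials=4)
    assoc = np.array(["blue", "blue", "red", "red"])
    _, per_trial, used = surrogate_maps(tfr, tfr, assoc, enc_range=(0.5, 0.6),
                                        ret_range=(1.0, 1.1), dtype=np.float64,
                                        return_trial_maps=True)
    partner = reinstatement_map(tfr, tfr, 1, 0, enc_range=(0.5, 0.6),
                                ret_range=(1.0, 1.1))
    assert np.allclose(per_trial[0].values, partner.values, atol=1e-12)
    assert list(used) == [0, 1, 2, 3]


def test_surrogate_skips_singleton_association(rng, caplog):
    tfr = _random_tfr(rng, n_trials=3)
    assoc = np.array(["blue", "blue", "red"])
    _, per_trial, used = surrogate_maps(tfr, tfr, assoc, enc_range=(0.5, 0.6),
                                        ret_range=(1.0, 1.1),
                                        return_trial_maps=True)
    assert list(used) == [0, 1]


def test_band_restricted_map_modes(rng):
    enc, ret = _random_tfr(rng), _random_tfr(rng)
    ref = reinstatement_map(enc, ret, 0, 0, enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    none_excluded = band_restricted_map(enc, ret, 0, 0, band=None, mode="exclude",
                                        enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    assert np.allclose(none_excluded.values, ref.values, atol=1e-12)
    # exclude + only partition the grid rows
    only = band_restricted_map(enc, ret, 0, 0, band="alpha", mode="only",
                               enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    excl = band_restricted_map(enc, ret, 0, 0, band="alpha", mode="exclude",
                               enc_range=(0.5, 0.6), ret_range=(1.0, 1.1))
    assert only.values.shape == excl.values.shape == ref.values.shape
    assert not np.allclose(only.values, ref.values)
    with pytest.raises(ValueError):
        band_restricted_map(enc, ret, 0, 0, band="sigma", mode="only")
    assert set(BANDS) == {"delta", "theta", "alpha", "beta", "gamma1", "gamma2"}


def test_correlation_weights_sum_identity(rng):
    a = rng.lognormal(0, 0.3, (43, 41))
    w = correlation_weights(a, a)
    assert w.shape == (43,)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    # rank-reversed partner -> -1
    order = np.argsort(a.ravel())
    b = np.empty_like(a.ravel())
    b[order] = np.sort(a.ravel())[::-1]
    assert correlation_weights(a, b.reshape(43, 41)).sum() == pytest.approx(-1.0,
                                                                            abs=1e-12)
    for _ in range(20):
        x, y = rng.random((43, 41)), rng.random((43, 41))
        assert correlation_weights(x, y).sum() == pytest.approx(
            spearmanr(x.ravel(), y.ravel()).statistic, abs=1e-10)
    with pytest.raises(ValueError):
        correlation_weights(np.ones((43, 41)), a)


def test_fisher_z_values_and_symmetry():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
    assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
    r = np.linspace(-0.9, 0.9, 7)
    assert np.allclose(fisher_z(-r), -fisher_z(r))
    assert np.all(np.diff(fisher_z(r)) > 0)  # strictly increasing
    with pytest.warns(RuntimeWarning):
        z = fisher_z(np.array([1.0, -1.0]))
    assert np.all(np.isfinite(z))


def test_z_then_mean_close_to_mean_then_z(rng):
    rho = rng.uniform(-0.2, 0.2, 500)
    diff = abs(np.tanh(fisher_z(rho).mean()) - rho.mean())
    assert diff < 0.01


def test_pattern_center_bounds(rng):
    """On a real -1..+3 s decomposition the usable centres keep the pattern
    window plus the strict-validity taper margin inside the epoch."""
    from ersa.containers import EpochSet
    from ersa.spectral import tfr_transform

    times = np.arange(4001) / 1000.0 - 1.0
    tfr = tfr_transform(EpochSet(rng.standard_normal((1, 4001)), times, 1000.0),
                        dtype=np.float32)
    idx = pattern_centers(tfr, "tf_400ms")
    assert tfr.times[idx[0]] >= tfr.times[0] + 0.5 - 0.03
    assert tfr.times[idx[-1]] <= tfr.times[-1] - 0.5 + 0.03
    with pytest.raises(ValueError):
        extract_pattern(tfr, 0, tfr.times[0], "tf_400ms")  # window out of range


def test_response_locked_map_geometry(tiny_dataset):
    """Retrieval axis realigned to the response; planted reinstatement shows
    up in the pre-response window (encoding axis stays stimulus-locked)."""
    from ersa.preprocess import reject_artifacts, response_lock_tfr
    from ersa.spectral import baseline_normalize, tfr_transform

    enc, ret, _, gt = tiny_dataset
    enc0 = enc.select((enc.events.participant == 0).to_numpy())
    ret0 = ret.select((ret.events.participant == 0).to_numpy())
    enc0, _ = reject_artifacts(enc0)
    ret0, _ = reject_artifacts(ret0)
    tfr_enc = baseline_normalize(tfr_transform(enc0, dtype=np.float32))
    tfr_ret = baseline_normalize(tfr_transform(ret0, dtype=np.float32))
    tfr_rl, ok = response_lock_tfr(tfr_ret)
    assert tfr_rl.lock == "response"
    rci = pattern_centers(tfr_rl)
    assert tfr_rl.times[rci[0]] >= -0.81 and tfr_rl.times[rci[-1]] <= -0.09

    vals = []
    ev_r, ev_e = tfr_rl.events, tfr_enc.events
    for j in range(tfr_rl.n_trials):
        if ev_r["condition"].iat[j] != "AR":
            continue
        tid = ev_r["trial"].iat[j]
        hit = np.flatnonzero((ev_e["condition"] == "AR").to_numpy()
                             & (ev_e["trial"] == tid).to_numpy())
        if hit.size == 0:
            continue
        m = reinstatement_map(tfr_enc, tfr_rl, int(hit[0]), j,
                              enc_range=(0.4, 1.1), dtype=np.float32)
        assert m.lock == "response"
        # realignment is a pure grid shift: the response-locked value in a
        # latency-aligned window equals the stimulus-locked value in the
        # corresponding post-stimulus window (same underlying bins)
        rt_bin = round(float(ev_r["rt_s"].iat[j]) / 0.01) * 0.01
        k = int(np.flatnonzero((tfr_ret.events["trial"] == tid).to_numpy()
                               & (tfr_ret.events["condition"] == "AR").to_numpy())[0])
        ms = reinstatement_map(tfr_enc, tfr_ret, int(hit[0]), k,
                               enc_range=(0.4, 1.1),
                               ret_range=(rt_bin - 0.8, rt_bin - 0.2),
                               dtype=np.float32)
        a = m.window_mean((0.5, 1.0), (-0.8, -0.2))
        b = ms.window_mean((0.5, 1.0), (rt_bin - 0.8, rt_bin - 0.2))
        assert a == pytest.approx(b, abs=1e-5)
        vals.append(a)
    assert len(vals) >= 3
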