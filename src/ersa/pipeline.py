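"""End-to-end orchestration: simulate -> preprocess -> decompose -> maps -> stats.

``run_pipeline`` executes the full analysis on a simulated study and
returns a report bundle: participant-level reinstatement maps (AR, IR,
association-matched surrogate), the cluster-corrected AR>IR and
AR>surrogate contrasts and their min-t conjunction, the AR vs IR
time-frequency power contrast with gamma/alpha cluster detection, band
time courses, the power/reinstatement median-split linkage, and a
ground-truth recovery summary.  Every random draw flows from the seeds
recorded in the config, so identical configs reproduce identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import reinstatement as ri
from . import stats as st
from .config import PipelineConfig
from .containers import EpochSet
from .preprocess import reject_artifacts
from .spectral import baseline_normalize, cluster_mean_power, tfr_transform
from .synth import generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["ParticipantResult", "PipelineResult", "run_pipeline", "analyze_dataset"]


@dataclass
class ParticipantResult:
    participant: int
    enc_times: np.ndarray
    ret_times: np.ndarray
    #: fisher-z participant-average reinstatement maps: AR, IR, surrogate
    maps: dict = field(default_factory=dict)
    #: mean relative-power maps (43 x n_times) per condition at retrieval
    tf_power: dict = field(default_factory=dict)
    tf_times: np.ndarray | None = None
    tf_valid: np.ndarray | None = None
    #: per-AR-trial windowed reinstatement / gamma / alpha cluster power
    trial_reinstatement: np.ndarray | None = None
    trial_gamma: np.ndarray | None = None
    trial_alpha: np.ndarray | None = None
    gamma_power: float = np.nan
    alpha_power: float = np.nan
    n_rejected: dict = field(default_factory=dict)
    n_trials: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: PipelineConfig
    participants: list
    group: dict
    report: dict


def _dtype(cfg: PipelineConfig):
    return np.float32 if cfg.analysis.precision == "float32" else np.float64


def _participant_analysis(
    p: int,
    enc: EpochSet,
    ret: EpochSet,
    cfg: PipelineConfig,
) -> ParticipantResult:
    a = cfg.analysis
    dtype = _dtype(cfg)

    enc_clean, enc_rej = reject_artifacts(enc)
    ret_clean, ret_rej = reject_artifacts(ret)

    sel_enc = enc_clean.select(enc_clean.events["condition"].isin(["AR", "IR"]).to_numpy())
    sel_ret = ret_clean.select(ret_clean.events["condition"].isin(["AR", "IR"]).to_numpy())

    tfr_enc = baseline_normalize(tfr_transform(sel_enc, dtype=dtype), a.baseline)
    tfr_ret = baseline_normalize(tfr_transform(sel_ret, dtype=dtype), a.baseline)

    eci = ri.pattern_centers(tfr_enc, a.variant, a.map_enc_range)
    rci = ri.pattern_centers(tfr_ret, a.variant, a.map_ret_range)
    enc_times, ret_times = tfr_enc.times[eci], tfr_ret.times[rci]

    enc_ev, ret_ev = tfr_enc.events, tfr_ret.events
    z_enc = {}
    for i in range(tfr_enc.n_trials):
        z_enc[(enc_ev["condition"].iat[i], int(enc_ev["trial"].iat[i]))] = (
            ri.rank_pattern_matrix(tfr_enc, i, eci, a.variant, dtype=dtype))

    # association -> summed AR encoding rank matrices, for surrogate partners
    ar_assoc_sums, ar_assoc_counts, ar_assoc_of = {}, {}, {}
    for (cond, tid), z in z_enc.items():
        if cond != "AR":
            continue
        row = enc_ev[(enc_ev["condition"] == "AR") & (enc_ev["trial"] == tid)]
        assoc = row["association"].iat[0]
        ar_assoc_of[tid] = assoc
        if assoc not in ar_assoc_sums:
            ar_assoc_sums[assoc] = np.zeros_like(z)
            ar_assoc_counts[assoc] = 0
        ar_assoc_sums[assoc] += z
        ar_assoc_counts[assoc] += 1

    own_maps = {"AR": [], "IR": []}
    surrogate_trial_maps = []
    trial_rho, trial_idx = [], []
    ei = ri._range_idx(enc_times, a.reinstatement_enc_window)
    riw = ri._range_idx(ret_times, a.reinstatement_ret_window)

    for j in range(tfr_ret.n_trials):
        cond = ret_ev["condition"].iat[j]
        tid = int(ret_ev["trial"].iat[j])
        zr = None
        if (cond, tid) in z_enc:  # own map needs the matching clean encoding trial
            zr = ri.rank_pattern_matrix(tfr_ret, j, rci, a.variant, dtype=dtype)
            m = ri.maps_from_rank_matrices(z_enc[(cond, tid)], zr)
            own_maps[cond].append(m)
            if cond == "AR":
                trial_rho.append(float(np.nanmean(m[np.ix_(ei, riw)])))
                trial_idx.append(j)
        if cond == "AR":
            assoc = ret_ev["association"].iat[j]
            total = ar_assoc_sums.get(assoc)
            cnt = ar_assoc_counts.get(assoc, 0)
            own_z = z_enc.get(("AR", tid))
            n_partners = cnt - (1 if own_z is not None else 0)
            if total is None or n_partners < 1:
                logger.warning("participant %d trial %d: no same-association "
                               "AR partner, surrogate skipped", p, tid)
                continue
            partner_mean = (total - own_z) / n_partners if own_z is not None \
                else total / n_partners
            if zr is None:
                zr = ri.rank_pattern_matrix(tfr_ret, j, rci, a.variant, dtype=dtype)
            surrogate_trial_maps.append(ri.maps_from_rank_matrices(partner_mean, zr))

    if not own_maps["AR"] or not own_maps["IR"] or not surrogate_trial_maps:
        raise RuntimeError(f"participant {p}: insufficient clean trials for maps")

    res = ParticipantResult(participant=p, enc_times=enc_times, ret_times=ret_times)
    for name, stack in (("AR", own_maps["AR"]), ("IR", own_maps["IR"]),
                        ("surrogate", surrogate_trial_maps)):
        arr = np.stack(stack)
        if a.fisher_level == "trial":
            res.maps[name] = np.nanmean(ri.fisher_z(arr), axis=0)
        else:  # z-scale the participant average, just before group tests
            res.maps[name] = ri.fisher_z(np.nanmean(arr, axis=0))

    # retrieval-power analyses (relative power, 43 x n_times)
    is_ar = (ret_ev["condition"] == "AR").to_numpy()
    res.tf_power["AR"] = tfr_ret.power[is_ar].mean(axis=0)
    res.tf_power["IR"] = tfr_ret.power[~is_ar].mean(axis=0)
    res.tf_times = tfr_ret.times
    res.tf_valid = tfr_ret.valid

    gamma = cluster_mean_power(tfr_ret, band=a.gamma_band, window=a.gamma_window)
    alpha = cluster_mean_power(tfr_ret, band=a.alpha_band, window=a.alpha_window)
    res.trial_reinstatement = np.asarray(trial_rho)
    res.trial_gamma = gamma[np.asarray(trial_idx, dtype=int)]
    res.trial_alpha = alpha[np.asarray(trial_idx, dtype=int)]
    # collapsed (AR+IR) cluster power per participant for the
    # across-participant gamma/alpha correlation
    res.gamma_power = float(gamma.mean())
    res.alpha_power = float(alpha.mean())
    res.n_rejected = {"encoding": int(enc_rej.sum()), "retrieval": int(ret_rej.sum())}
    res.n_trials = {"encoding": int(enc.n_trials), "retrieval": int(ret.n_trials),
                    "AR_maps": len(own_maps["AR"]), "IR_maps": len(own_maps["IR"]),
                    "surrogates": len(surrogate_trial_maps)}
    return res


def _block_mask(shape, rows, cols) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[np.ix_(rows, cols)] = True
    return m


def _cluster_report(res: st.ClusterResult) -> dict:
    return {
        "threshold": res.threshold,
        "n_permutations": res.n_permutations,
        "clusters": [{"sign": c.sign, "mass": c.mass, "p": c.p,
                      "n_bins": int(c.mask.sum())} for c in res.clusters[:10]],
        "min_p": res.min_p(),
    }


def analyze_dataset(
    encoding: EpochSet,
    retrieval: EpochSet,
    cfg: PipelineConfig,
    ground_truth=None,
) -> PipelineResult:
    """Run the group analysis on an existing (simulated or imported) dataset."""
    cfg.validate()
    a, scfg = cfg.analysis, cfg.stats
    participants = np.unique(retrieval.events["participant"])
    per_part = []
    for p in participants:
        enc_p = encoding.select((encoding.events["participant"] == p).to_numpy())
        ret_p = retrieval.select((retrieval.events["participant"] == p).to_numpy())
        per_part.append(_participant_analysis(int(p), enc_p, ret_p, cfg))

    enc_times, ret_times = per_part[0].enc_times, per_part[0].ret_times
    maps = {k: np.stack([r.maps[k] for r in per_part])
            for k in ("AR", "IR", "surrogate")}

    res_ar_ir = st.cluster_permutation_paired(
        maps["AR"], maps["IR"], alpha_cf=scfg.alpha_cf,
        n_perm=scfg.n_permutations, seed=scfg.seed)
    res_ar_sur = st.cluster_permutation_paired(
        maps["AR"], maps["surrogate"], alpha_cf=scfg.alpha_cf,
        n_perm=scfg.n_permutations, seed=scfg.seed + 1)
    conj_mask, conj_t = st.conjunction_min_t(res_ar_ir, res_ar_sur,
                                             alpha=scfg.cluster_alpha)

    # TF power contrast AR vs IR with gamma/alpha cluster detection;
    # post-stimulus bins only, edge-padded (invalid) estimates excluded
    tf_times = per_part[0].tf_times
    post = (tf_times >= 0.0)
    tf_mask = per_part[0].tf_valid[:, post]
    tf = {}
    for k in ("AR", "IR"):
        arr = np.stack([r.tf_power[k] for r in per_part])[:, :, post]
        tf[k] = np.where(tf_mask[None], arr, np.nan)
    res_tf = st.cluster_permutation_paired(
        tf["AR"], tf["IR"], alpha_cf=scfg.alpha_cf,
        n_perm=scfg.n_permutations, seed=scfg.seed + 2)
    tf_test_times = tf_times[post]

    from .spectral import FrequencyGrid
    freqs = FrequencyGrid.default().frequencies

    def _band_window_mask(band, window):
        rows = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
        cols = np.flatnonzero((tf_test_times >= window[0]) & (tf_test_times <= window[1]))
        return _block_mask(res_tf.stat_map.shape, rows, cols)

    gamma_block = _band_window_mask(a.gamma_band, a.gamma_window)
    alpha_block = _band_window_mask(a.alpha_band, a.alpha_window)
    gamma_detected = bool((res_tf.significant_mask(scfg.cluster_alpha, sign=1)
                           & gamma_block).any())
    alpha_detected = bool((res_tf.significant_mask(scfg.cluster_alpha, sign=-1)
                           & alpha_block).any())

    # median-split linkage of band power and reinstatement over AR trials
    cells = np.empty((len(per_part), 2, 2))  # (participant, band, power level)
    for i, r in enumerate(per_part):
        hi_g, lo_g = st.median_split_linkage(r.trial_gamma, r.trial_reinstatement)
        hi_a, lo_a = st.median_split_linkage(r.trial_alpha, r.trial_reinstatement)
        cells[i] = [[hi_g, lo_g], [hi_a, lo_a]]
    anova = st.rm_anova_2x2(cells.transpose(0, 2, 1))  # factors: power x band
    t_gamma = sps.ttest_rel(cells[:, 0, 0], cells[:, 0, 1])
    t_alpha = sps.ttest_rel(cells[:, 1, 0], cells[:, 1, 1])

    group = {
        "maps": maps, "enc_times": enc_times, "ret_times": ret_times,
        "res_ar_ir": res_ar_ir, "res_ar_sur": res_ar_sur,
        "conjunction_mask": conj_mask, "conjunction_min_t": conj_t,
        "res_tf": res_tf, "tf_times": tf_test_times, "tf_maps": tf,
        "median_split_cells": cells,
    }

    enc_w, ret_w = a.reinstatement_enc_window, a.reinstatement_ret_window
    ei = np.flatnonzero((enc_times >= enc_w[0]) & (enc_times <= enc_w[1]))
    riw = np.flatnonzero((ret_times >= ret_w[0]) & (ret_times <= ret_w[1]))
    window_block = _block_mask(conj_mask.shape, ei, riw)

    report = {
        "n_participants": len(per_part),
        "trials": {str(r.participant): r.n_trials for r in per_part},
        "rejected": {str(r.participant): r.n_rejected for r in per_part},
        "reinstatement": {
            "window_mean_rho": {
                k: float(np.nanmean(np.tanh(maps[k])[:, ei][:, :, riw]))
                for k in ("AR", "IR", "surrogate")
            },
            "ar_vs_ir": _cluster_report(res_ar_ir),
            "ar_vs_surrogate": _cluster_report(res_ar_sur),
            "conjunction_bins": int(conj_mask.sum()),
            "conjunction_overlaps_window": bool((conj_mask & window_block).any()),
        },
        "power": {
            "ar_vs_ir": _cluster_report(res_tf),
            "gamma_cluster_detected": gamma_detected,
            "alpha_cluster_detected": alpha_detected,
            "gamma_alpha_across_participant_r": (
                st.across_participant_correlation(
                    [r.gamma_power for r in per_part],
                    [r.alpha_power for r in per_part])
                if len(per_part) >= 3 else None),
        },
        "median_split": {
            "gamma_high": float(cells[:, 0, 0].mean()),
            "gamma_low": float(cells[:, 0, 1].mean()),
            "alpha_high": float(cells[:, 1, 0].mean()),
            "alpha_low": float(cells[:, 1, 1].mean()),
            "t_gamma": float(t_gamma.statistic), "p_gamma": float(t_gamma.pvalue),
            "t_alpha": float(t_alpha.statistic), "p_alpha": float(t_alpha.pvalue),
            "interaction_F": anova["interaction"]["F"],
            "interaction_p": anova["interaction"]["p"],
        },
        "seeds": {"study": cfg.study.seed, "stats": scfg.seed},
    }

    if ground_truth is not None:
        gt_enc = ground_truth.encoding_window
        gt_ret = ground_truth.retrieval_window
        gei = np.flatnonzero((enc_times >= gt_enc[0]) & (enc_times <= gt_enc[1]))
        gri = np.flatnonzero((ret_times >= gt_ret[0]) & (ret_times <= gt_ret[1]))
        gt_block = _block_mask(conj_mask.shape, gei, gri)
        report["recovery"] = {
            "conjunction_overlaps_planted": bool((conj_mask & gt_block).any()),
            "planted_encoding_window": list(gt_enc),
            "planted_retrieval_window": list(gt_ret),
        }

    return PipelineResult(config=cfg, participants=per_part, group=group,
                          report=report)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Simulate a study per ``cfg.study`` and run the full analysis on it."""
    cfg.validate()
    encoding, retrieval, _events, gt = generate_dataset(cfg.study)
    result = analyze_dataset(encoding, retrieval, cfg, ground_truth=gt)
    if cfg.out_dir:
        from .io import save_report_bundle
        save_report_bundle(cfg.out_dir, result)
    return result
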