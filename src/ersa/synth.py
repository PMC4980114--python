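"""Synthetic single-contact iEEG with planted reinstatement and band effects.

The generator emulates the statistical structure the analysis pipeline
assumes, one channel per participant:

* a 1/f^chi background (spectral synthesis) with low-amplitude band-limited
  oscillatory components riding on it;
* a trial-unique time-frequency *fingerprint* -- a smooth envelope over
  log-spaced carrier frequencies x time knots -- planted in every old
  trial's encoding epoch (0.5-1 s by default).  On AR trials, and only on
  AR trials, an amplitude-modulated copy of the same envelope is planted
  in the retrieval epoch (1-1.5 s), which is what the reinstatement
  analysis is built to recover.  Each envelope mixes a per-association
  shared component with a trial-unique component, so same-association
  trials resemble each other more than cross-association ones but less
  than a trial resembles itself;
* condition-specific band power effects at retrieval: a gamma (50-90 Hz,
  0.5-1.3 s) increase on AR trials and an alpha (8-12 Hz, 1-2 s) increase
  on IR trials.  A per-trial lognormal modulator couples the AR gamma
  burst amplitude to the reinstated fingerprint amplitude, giving the
  power/reinstatement linkage probed by the median-split analysis;
* response latencies from a shifted lognormal truncated at the 5-s
  response deadline, shorter for AR than IR;
* occasional high-amplitude transient artifacts.

All randomness flows from ``StudyConfig.seed`` through per-participant
``numpy`` child generators, so identical configs give bit-identical data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal.windows import tukey

from .config import BLOCK_TYPE, OLD_CONDITIONS, StudyConfig
from .containers import EpochSet

__all__ = ["Fingerprint", "GroundTruth", "generate_dataset", "make_fingerprint",
           "inject_artifact"]

#: background standard deviation, microvolts
BACKGROUND_SD = 20.0
ENVELOPE_SMOOTH_SIGMA = 0.8


@dataclass
class Fingerprint:
    """One trial's planted time-frequency signature.

    ``carrier_freqs`` (C,) are the sinusoidal carrier frequencies of the
    fingerprint's channels; ``envelope`` (C, n_knots) is each channel's
    smooth, positive amplitude profile over the planted window.  The
    planted power pattern is therefore the squared envelope laid out at
    the carrier frequencies.
    """

    carrier_freqs: np.ndarray
    envelope: np.ndarray

    def rasterize(self, freqs: np.ndarray, n_time: int = 41,
                  rel_bw: float = 0.12) -> np.ndarray:
        """Expected power-envelope image on an analysis frequency grid.

        Each channel contributes a Gaussian frequency profile of relative
        width *rel_bw* around its carrier, amplitude-modulated by its
        time-interpolated envelope -- useful for recovery checks against
        measured patterns.
        """
        freqs = np.asarray(freqs, dtype=float)
        k = self.envelope.shape[1]
        frac = np.linspace(0.0, 1.0, n_time)
        knots = np.linspace(0.0, 1.0, k)
        env_t = np.stack([np.interp(frac, knots, row) for row in self.envelope])
        sigma = rel_bw * self.carrier_freqs
        prof = np.exp(-0.5 * ((freqs[None, :] - self.carrier_freqs[:, None])
                              / sigma[:, None]) ** 2)
        return prof.T @ env_t ** 2


@dataclass
class GroundTruth:
    """Planted structure emitted alongside the data for recovery tests."""

    knot_fractions: np.ndarray
    encoding_window: tuple[float, float]
    retrieval_window: tuple[float, float]
    #: (participant, trial) -> :class:`Fingerprint`
    fingerprints: dict = field(default_factory=dict)
    #: (participant, trial) -> lognormal gain of the retrieval copy (AR only)
    modulations: dict = field(default_factory=dict)
    #: effect name -> dict(condition, band, window, rel_amplitude)
    effects: dict = field(default_factory=dict)
    #: (participant, trial, phase) tuples flagged as artifact-bearing
    artifact_trials: list = field(default_factory=list)


def _association_seed(association: str) -> int:
    return zlib.crc32(association.encode("utf8"))


def _smooth_rows(rng: np.random.Generator, n_rows: int, n_knots: int) -> np.ndarray:
    g = rng.standard_normal((n_rows, n_knots))
    for i in range(n_rows):
        g[i] = gaussian_filter(g[i], ENVELOPE_SMOOTH_SIGMA)
    return np.exp(g)


def _draw_template(rng: np.random.Generator, n_channels: int, n_knots: int,
                   span: tuple[float, float]) -> Fingerprint:
    freqs = np.exp(rng.uniform(np.log(span[0]), np.log(span[1]), n_channels))
    return Fingerprint(carrier_freqs=np.sort(freqs),
                       envelope=_smooth_rows(rng, n_channels, n_knots))


def make_fingerprint(
    trial_id: int,
    association: str,
    rng: np.random.Generator,
    *,
    n_channels: int = 16,
    n_knots: int = 6,
    association_weight: float = 0.3,
    frequency_span: tuple[float, float] = (3.0, 90.0),
    association_template: Fingerprint | None = None,
) -> Fingerprint:
    """Fingerprint mixing an association-shared and a trial-unique component.

    A fraction ``association_weight`` of the channels (rounded) is copied
    from the association's template (same carriers, same envelope rows);
    the remaining channels get trial-unique carriers (log-uniform over
    *frequency_span*) and envelopes.  ``weight = 0`` makes fingerprints
    independent of association, ``weight = 1`` makes same-association
    fingerprints identical; intermediate weights make same-association
    trials more similar to each other than cross-association ones, yet
    less similar than a trial to itself.

    If no template is supplied it is derived deterministically from the
    association label, so repeated calls agree.
    """
    if not 0.0 <= association_weight <= 1.0:
        raise ValueError("association_weight must lie in [0, 1]")
    if association_template is None:
        arng = np.random.default_rng(_association_seed(association))
        association_template = _draw_template(arng, n_channels, n_knots,
                                              frequency_span)
    n_shared = int(round(association_weight * n_channels))
    freqs = np.empty(n_channels)
    env = np.empty((n_channels, n_knots))
    freqs[:n_shared] = association_template.carrier_freqs[:n_shared]
    env[:n_shared] = association_template.envelope[:n_shared]
    n_uniq = n_channels - n_shared
    if n_uniq:
        freqs[n_shared:] = np.exp(rng.uniform(np.log(frequency_span[0]),
                                              np.log(frequency_span[1]), n_uniq))
        env[n_shared:] = _smooth_rows(rng, n_uniq, n_knots)
    env = env / np.sqrt(np.mean(env ** 2))
    return Fingerprint(carrier_freqs=freqs, envelope=env)


def inject_artifact(
    trace: np.ndarray, position: int, scale: float, sfreq: float = 1000.0
) -> np.ndarray:
    """Return *trace* with a brief high-amplitude biphasic transient added.

    The transient is one cycle of a sine over ~8 ms with peak amplitude
    ``scale`` times the trace standard deviation, so it exceeds both the
    amplitude and the gradient rejection thresholds of a clean ensemble.
    ``scale = 0`` returns the trace unchanged.
    """
    trace = np.asarray(trace, dtype=float).copy()
    if scale == 0:
        return trace
    n = max(int(round(0.008 * sfreq)), 4)
    if not 0 <= position < trace.size:
        raise ValueError("artifact position outside the epoch")
    start = min(position, trace.size - n)
    shape = np.sin(2 * np.pi * np.arange(n) / n)
    trace[start:start + n] += scale * trace.std() * shape
    return trace


# ---------------------------------------------------------------------------
# background synthesis

def _spectral_amplitude(n: int, sfreq: float, config: StudyConfig) -> np.ndarray:
    """rFFT amplitude profile of the background: 1/f floor + oscillatory bumps."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    nz = freqs >= 0.5
    amp[nz] = np.maximum(freqs[nz], 1.0) ** (-config.noise_exponent / 2.0)
    for lo, hi, rel in config.oscillations:
        band = (freqs >= lo) & (freqs <= hi)
        if not band.any():
            continue
        bump = 0.5 * (1 - np.cos(2 * np.pi * (freqs[band] - lo) / (hi - lo)))
        amp[band] += rel * amp[band].mean() * bump
    return amp


def _profile_sd(amp: np.ndarray, n: int) -> float:
    """Expected time-domain sd of irfft(amp * complex standard normal)."""
    a2 = amp ** 2
    total = 2.0 * a2[1:].sum()
    if n % 2 == 0:
        total -= a2[-1]  # Nyquist bin is real-valued, counted once
    return np.sqrt(total) / n


def _band_rms(amp: np.ndarray, n: int, sfreq: float, band: tuple[float, float],
              target_sd: float) -> float:
    """RMS of the background restricted to *band*, on the output scale."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    sub = np.where(sel, amp, 0.0)
    return target_sd * _profile_sd(sub, n) / _profile_sd(amp, n)


def _background(rng: np.random.Generator, n_trials: int, n: int,
                amp: np.ndarray, target_sd: float) -> np.ndarray:
    z = rng.standard_normal((n_trials, amp.size)) + 1j * rng.standard_normal(
        (n_trials, amp.size))
    spectrum = amp * z / np.sqrt(2.0)
    x = np.fft.irfft(spectrum, n=n, axis=1)
    return x * (target_sd / _profile_sd(amp, n))


def _bandlimited_noise(rng: np.random.Generator, n: int, sfreq: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS noise restricted to *band* with raised-cosine spectral edges."""
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    lo, hi = band
    edge = max((hi - lo) * 0.15, 1.0)
    mask = np.clip((freqs - (lo - edge)) / edge, 0, 1) * np.clip(
        ((hi + edge) - freqs) / edge, 0, 1)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    x = np.fft.irfft(mask * z, n=n)
    rms = x.std()
    return x / rms if rms > 0 else x


# ---------------------------------------------------------------------------
# planted components

def _window_profile(times: np.ndarray, window: tuple[float, float]):
    """(index, ramp, local fraction) of epoch samples inside *window*."""
    idx = np.flatnonzero((times >= window[0]) & (times < window[1]))
    ramp = tukey(idx.size, alpha=0.4)
    frac = (times[idx] - window[0]) / (window[1] - window[0])
    return idx, ramp, frac


def _fingerprint_signal(
    fingerprint: Fingerprint,
    knot_fractions: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-RMS fingerprint waveform restricted to *window*.

    Each carrier channel is a fixed-frequency sinusoid with a random phase,
    amplitude-modulated by the channel's interpolated envelope row, so the
    planted time-frequency power pattern is the (squared) envelope at the
    carrier frequencies.  Returns ``(sample_indices, waveform)``.
    """
    idx, ramp, frac = _window_profile(times, window)
    env_t = np.stack([np.interp(frac, knot_fractions, row)
                      for row in fingerprint.envelope])
    t_loc = times[idx] - window[0]
    phases = rng.uniform(0, 2 * np.pi, size=fingerprint.carrier_freqs.size)
    carriers = np.sin(2 * np.pi * fingerprint.carrier_freqs[:, None]
                      * t_loc[None, :] + phases[:, None])
    sig = (env_t * carriers).sum(axis=0) * ramp
    rms = sig.std()
    if rms > 0:
        sig = sig / rms
    return idx, sig


def _burst(rng, times, sfreq, window, band) -> tuple[np.ndarray, np.ndarray]:
    """Unit-RMS band-limited burst with smooth on/off ramps in *window*."""
    idx, ramp, _ = _window_profile(times, window)
    noise = _bandlimited_noise(rng, idx.size, sfreq, band)
    sig = noise * ramp
    rms = sig.std()
    if rms > 0:
        sig = sig / rms
    return idx, sig


def _draw_rts(rng, cond, config: StudyConfig, n: int) -> np.ndarray:
    """Shifted lognormal latencies truncated at the response deadline."""
    mean, sd = config.rt_distributions[cond]
    m = mean - config.rt_shift
    sigma2 = np.log1p((sd / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = config.rt_shift + rng.lognormal(mu, np.sqrt(sigma2), todo.size)
        good = draw <= config.rt_max
        out[todo[good]] = draw[good]
        todo = todo[~good]
    return out


def _balanced_associations(rng, labels, n: int) -> np.ndarray:
    reps = -(-n // len(labels))
    pool = np.tile(np.asarray(labels, dtype=object), reps)[:n]
    return rng.permutation(pool)


# ---------------------------------------------------------------------------
# main entry point

def generate_dataset(
    config: StudyConfig,
) -> tuple[EpochSet, EpochSet, pd.DataFrame, GroundTruth]:
    """Simulate one multi-participant study.

    Returns stimulus-locked encoding and retrieval :class:`EpochSet`\\ s
    (trials pooled over participants, metadata in ``.events``), the full
    event table, and the :class:`GroundTruth` describing every planted
    component.
    """
    config.validate()
    fp = config.fingerprint
    t0, t1 = config.epoch_window
    sfreq = config.sampling_rate
    n_samp = int(round((t1 - t0) * sfreq)) + 1
    times = t0 + np.arange(n_samp) / sfreq

    for w in (fp.encoding_window, fp.retrieval_window,
              config.gamma_effect.window, config.alpha_effect.window):
        if not (t0 <= w[0] and w[1] <= t1):
            raise ValueError(f"planted window {w} does not fit in the epoch")

    amp_profile = _spectral_amplitude(n_samp, sfreq, config)
    gamma_rms = _band_rms(amp_profile, n_samp, sfreq, config.gamma_effect.band,
                          BACKGROUND_SD)
    alpha_rms = _band_rms(amp_profile, n_samp, sfreq, config.alpha_effect.band,
                          BACKGROUND_SD)
    effect_rms = {"gamma": gamma_rms, "alpha": alpha_rms}

    knot_fractions = np.linspace(0.0, 1.0, fp.n_time_knots)

    gt = GroundTruth(
        knot_fractions=knot_fractions,
        encoding_window=tuple(fp.encoding_window),
        retrieval_window=tuple(fp.retrieval_window),
        effects={
            "gamma": {"condition": config.gamma_effect.condition,
                      "band": tuple(config.gamma_effect.band),
                      "window": tuple(config.gamma_effect.window),
                      "rel_amplitude": config.gamma_effect.rel_amplitude},
            "alpha": {"condition": config.alpha_effect.condition,
                      "band": tuple(config.alpha_effect.band),
                      "window": tuple(config.alpha_effect.window),
                      "rel_amplitude": config.alpha_effect.rel_amplitude},
        },
    )

    root = np.random.SeedSequence(config.seed)
    part_seeds = root.spawn(config.n_participants)

    enc_rows, ret_rows = [], []
    enc_traces, ret_traces = [], []

    for p, pseed in enumerate(part_seeds):
        rng = np.random.default_rng(pseed)
        assoc_templates = {
            a: _draw_template(rng, fp.n_channels, fp.n_time_knots, fp.frequency_span)
            for a in config.association_set
        }

        trial_specs = []  # (trial_id, condition, association)
        tid = 0
        for cond in ("AR", "IR", "M", "CR"):
            n_c = config.n_trials_per_condition.get(cond, 0)
            assocs = _balanced_associations(rng, config.association_set, n_c)
            for a in assocs:
                trial_specs.append((tid, cond, str(a)))
                tid += 1

        n_old = sum(1 for _, c, _ in trial_specs if c in OLD_CONDITIONS)
        n_ret = len(trial_specs)
        enc_bg = _background(rng, n_old, n_samp, amp_profile, BACKGROUND_SD)
        ret_bg = _background(rng, n_ret, n_samp, amp_profile, BACKGROUND_SD)

        enc_i = 0
        for ri, (trial, cond, assoc) in enumerate(trial_specs):
            rt = _draw_rts(rng, cond, config, 1)[0]
            is_old = cond in OLD_CONDITIONS

            # per-trial lognormal modulator, shared (to degree `coupling`)
            # between the reinstated fingerprint and the gamma burst
            s = config.modulation_sigma
            z = rng.standard_normal()
            z_ind = rng.standard_normal()
            m_reinst = np.exp(s * z - s * s / 2)
            rho = config.gamma_reinstatement_coupling
            m_gamma = np.exp(s * (rho * z + np.sqrt(1 - rho * rho) * z_ind)
                             - s * s / 2)

            if is_old:
                fprint = make_fingerprint(
                    trial, assoc, rng,
                    n_channels=fp.n_channels, n_knots=fp.n_time_knots,
                    association_weight=fp.association_weight,
                    frequency_span=fp.frequency_span,
                    association_template=assoc_templates[assoc],
                )
                gt.fingerprints[(p, trial)] = fprint
                idx, sig = _fingerprint_signal(fprint, knot_fractions,
                                               times, fp.encoding_window, rng)
                enc_bg[enc_i, idx] += fp.amplitude * BACKGROUND_SD * sig
                if cond == "AR":
                    gain = fp.retrieval_gain * m_reinst
                    idx, sig = _fingerprint_signal(fprint, knot_fractions, times,
                                                   fp.retrieval_window, rng)
                    ret_bg[ri, idx] += fp.amplitude * BACKGROUND_SD * gain * sig
                    gt.modulations[(p, trial)] = float(gain)

            for name, eff in (("gamma", config.gamma_effect),
                              ("alpha", config.alpha_effect)):
                if cond != eff.condition or eff.rel_amplitude == 0:
                    continue
                mod = m_gamma if name == "gamma" else 1.0
                idx, sig = _burst(rng, times, sfreq, eff.window, eff.band)
                ret_bg[ri, idx] += eff.rel_amplitude * effect_rms[name] * mod * sig

            for phase, traces, row in (("encoding", enc_bg, enc_i if is_old else None),
                                       ("retrieval", ret_bg, ri)):
                if row is None:
                    continue
                has_artifact = rng.uniform() < config.artifact_rate
                if has_artifact and config.artifact_scale > 0:
                    pos = rng.integers(n_samp // 20, n_samp - n_samp // 20)
                    traces[row] = inject_artifact(traces[row], int(pos),
                                                  config.artifact_scale, sfreq)
                    gt.artifact_trials.append((p, trial, phase))
                rec = {
                    "participant": p, "trial": trial, "phase": phase,
                    "condition": cond, "association": assoc,
                    "block_type": BLOCK_TYPE.get(assoc, "other"),
                    "rt_s": rt if phase == "retrieval" else np.nan,
                    "is_artifact": bool(has_artifact),
                    "old": is_old,
                }
                (enc_rows if phase == "encoding" else ret_rows).append(rec)
            if is_old:
                enc_i += 1

        enc_traces.append(enc_bg)
        ret_traces.append(ret_bg)

    enc_events = pd.DataFrame(enc_rows).reset_index(drop=True)
    ret_events = pd.DataFrame(ret_rows).reset_index(drop=True)
    encoding = EpochSet(np.concatenate(enc_traces), times, sfreq, "stimulus", enc_events)
    retrieval = EpochSet(np.concatenate(ret_traces), times, sfreq, "stimulus", ret_events)
    events = pd.concat([enc_events, ret_events], ignore_index=True)
    return encoding, retrieval, events, gt
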