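# Methods

`ersa` implements a single-contact hippocampal encoding–retrieval
similarity (ERS) analysis together with a synthetic iEEG generator that
emulates the experiment the analysis is designed for: an associative
recognition paradigm in which old words are retrieved either with their
associative detail (AR, operationalizing recollection) or without it
(IR), alongside misses (M) and correct rejections (CR).

## Time–frequency decomposition

Power is estimated by sliding-window Fourier analysis on a 10-ms grid
over 2–100 Hz in 43 bins (1-Hz steps to 29 Hz, 5-Hz steps from 30 Hz).
Two regimes share the grid:

* **2–29 Hz** — Hanning taper, window length five cycles of the target
  frequency (500 ms at 10 Hz, 250 ms at 20 Hz);
* **30–100 Hz** — multitaper, fixed 400-ms window, seven Slepian tapers.
  With K tapers over T seconds the half-bandwidth is (K+1)/(2T) = ±10 Hz;
  the taper family is generated at time-half-bandwidth NW = 4 and the
  poorly concentrated eighth taper is dropped.

Windows are centred on the output bin (odd sample counts enforced) and
evaluated as tapered DFTs at the exact grid frequency via FFT-based
complex demodulation.  Because power is only needed every 10th sample,
the inverse transform is taken on the spectrum folded to 1/10 length —
an exact identity, verified in tests against a brute-force tapered DFT
to ~1e-12 relative error.  A `float32` mode halves memory and roughly
doubles throughput for simulation batches; the default is `float64`.

**Edge handling.** A five-cycle window at 2 Hz spans 2.5 s, so in a
−1..+3 s epoch strictly valid 2-Hz estimates exist only for centres in
0.25–1.75 s — which would leave the −0.5..0 s baseline undefined at the
lowest frequencies.  The decomposition therefore computes all bins from
reflection-padded traces and records an honest per-frequency validity
mask.  Baseline normalization uses the (possibly padding-assisted)
bins; map centres are those whose pattern window contains only strictly
valid bins for all frequencies ≥ 8 Hz (the lowest bins lean on padding
by design), giving maps spanning about −0.49..2.49 s on both axes for a
stimulus-locked epoch and, for response-locked grids, every centre
whose window fits the realigned axis.  The group-level time–frequency
contrast likewise excludes invalid bins.  Edge-padded low-frequency
bins are mildly biased; everything the group statistics compare is
affected identically across conditions.

**Normalization.** Relative power divides each trial × frequency by its
mean over the −0.5..0 s baseline.  Note that the ratio estimator is
biased upward where spectral estimates have few effective degrees of
freedom (single-taper low frequencies): post-stimulus relative alpha
power sits near ~1.4 rather than 1 even for a stationary process.  The
bias is common to all conditions and cancels in every contrast, but
absolute relative-power values should be read with this in mind.  A
log-power mode (no baseline) supports the pre-/post-stimulus control
analysis.

## Reinstatement maps

A *pattern* is the relative-power matrix of 43 frequencies × a 400-ms
window (41 bins; variants: 43 × 51 for 500 ms, 43 frequencies only, and
the 500-ms time-average).  For each trial, every encoding pattern is
Spearman-correlated (average ranks for ties) with every retrieval
pattern, yielding an encoding-time × retrieval-time map in 10-ms steps.
Rank matrices are computed once per trial and maps reduce to matrix
products of standardized ranks; the identity with rank-then-Pearson is
tested at 1e-12.

**Surrogates.** Each AR trial's retrieval patterns are also correlated
with the encoding patterns of every *other* AR trial sharing the same
target association, then averaged — controlling for perceptual,
attentional and condition-level (e.g. gamma-burst) similarity that all
AR trials share.  The partner average exploits linearity: the mean over
partner maps equals the map of the partners' mean rank matrix.

**Group inference.** Participant condition-average maps are Fisher-z
transformed (at the participant-average level, just before the group
test; trial-level z averaging is available) and contrasted with paired
cluster-based permutation tests: bin-wise paired t, two-tailed forming
threshold p < 0.05, 4-connected clusters, cluster mass = summed t, null
distribution of the maximum |mass| over participant-level sign flips
(exhaustive when 2^n does not exceed the permutation count, else random
draws), p = (b+1)/(m+1).  Pattern completion is declared where AR > IR
and AR > surrogate are *each* cluster-significant — the min-t
conjunction of the two corrected contrasts.

## Power analyses and linkage

The AR-vs-IR time–frequency contrast uses the same cluster machinery on
the 43 × time relative-power maps (post-stimulus bins).  Detected
clusters are summarized per trial (gamma 50–90 Hz, 0.5–1.3 s; alpha
8–12 Hz, 1–2 s), and AR trials are median-split by cluster power; the
windowed reinstatement (encoding 0.5–1 s × retrieval 1–1.5 s) of the
high and low halves is compared by paired t and by a within-subject
2×2 ANOVA (power level × band).  The omnibus comparison across
AR/IR/M/CR uses a one-way repeated-measures F cluster test whose null
permutes condition labels within participant.  Greenhouse–Geisser
correction is applied in the scalar one-way RM-ANOVA helper; the
cluster-forming F threshold uses nominal df since the permutation null
controls the family-wise error regardless of the forming threshold.
Response-locked variants realign the TF grid (nearest 10-ms bin) to the
button press, −1..+0.1 s, rather than re-windowing raw traces —
avoiding edge artifacts at the cost of inheriting the stimulus-locked
baseline, which is in any case undefined after realignment.

## Synthetic data

One channel per participant, 1 kHz, epochs −1..+3 s.  The background is
1/f^χ Gaussian noise (spectral synthesis, χ = 2 by default, slope
verified 2–80 Hz) plus low-amplitude band-limited components (theta,
alpha, beta, gamma) riding on it; total sd 20 µV.

* **Fingerprints.**  Every old trial carries a trial-unique
  time–frequency fingerprint in its encoding epoch (0.5–1 s): 16
  sinusoidal carriers at per-trial log-uniform frequencies (3–90 Hz),
  each amplitude-modulated by a smooth positive envelope over 6 time
  knots.  A fraction of channels (the association weight, default 0.15)
  is copied from a per-association template, making same-association
  trials more similar than cross-association ones yet less similar than
  a trial to itself.  On AR trials only, the same fingerprint is
  replanted in the retrieval epoch (1–1.5 s) with a per-trial lognormal
  gain.
* **Band effects.**  AR retrieval epochs receive a 50–90 Hz burst over
  0.5–1.3 s, IR retrieval epochs an 8–12 Hz burst over 1–2 s, both with
  smooth on/off ramps and amplitudes expressed relative to the
  background RMS in the band (defaults 0.4 and 1.0, chosen so both
  contrasts land at ~+35–40% relative power and produce comparably
  strong clusters).  The AR gamma amplitude shares the fingerprint's
  lognormal modulator to degree 0.9 (σ = 0.6), planting the
  power–reinstatement linkage the median split probes.
* **Behaviour and artifacts.**  Response latencies are shifted
  lognormals truncated at the 5-s deadline (AR 1.91 ± 0.50 s trialwise,
  IR 2.14 ± 0.50 s), and 12% of trials receive a high-amplitude biphasic
  transient that exceeds both rejection thresholds.

**Calibration.**  The fingerprint amplitude (0.25 × background sd) was
fixed so the AR-minus-surrogate window difference (~0.04) matches the
scale separating AR from surrogate values in the reference analysis,
with the AR window mean at ~0.08–0.10.  Two emergent properties of the
generator are worth knowing: (i) the surrogate floor is nonzero
(~0.04–0.05) because the gamma burst and the normalization-bias profile
are shared across AR trials — exactly the non-specific similarity the
surrogate is designed to absorb; (ii) the reinstated fingerprint's own
gamma-range carriers add measured gamma power, so a power–reinstatement
median split shows an intrinsic positive linkage even when the planted
amplitude coupling is switched off.  A clean null for the linkage
therefore also removes the retrieval-phase copy.

**What the generator does not emulate:** volume conduction,
epileptiform discharges beyond simple transients, multi-contact
geometry, non-stationary background statistics, participant
heterogeneity in effect topography, or genuine semantic structure in
the fingerprints.  Passing recovery tests therefore demonstrates that
the pipeline detects effects of the planted kind at realistic SNR and
cohort size — not that the method is robust to every pathology of
patient data.

## Artifact rejection

Pooling all time points of all trials of one channel/phase, thresholds
are median + 3·IQR of absolute amplitude and of absolute first
difference.  A trial is rejected when some time step exceeds the
gradient threshold while an adjacent sample exceeds the amplitude
threshold — high-amplitude fast transients go, slow drifts and brief
low-amplitude glitches stay.  On the clean 1/f background the false
rejection rate is ~1%; planted transients are caught with sensitivity
1.0, and at the default 12% artifact rate the overall rejected fraction
lands at ~9–17% across participants.

## Numerical and design choices

* Spearman uses average ranks; a fast argsort path falls back to exact
  tie handling only for rows that contain ties.
* Constant patterns have undefined correlations; affected bins are NaN
  and excluded pairwise from averages and from cluster statistics
  (together with zero-variance bins).
* Fisher z clips |rho| ≥ 1 to 1 − 1e-6 with a warning.
* Band boundaries for the exclusion/inclusion analysis: δ 2–3, θ 4–7,
  α 8–12, β 13–29, γ1 30–50, γ2 55–100 Hz.
* Surrogate pairing pools trials across blocks/runs.
* All randomness derives from explicit seeds (study seed for
  simulation, stats seed for permutations); identical configs
  reproduce reports bit-for-bit.

## Problem sizes used in tests and in `scripts/acceptance.py`

The recovery batches run the default study conditions — 11 participants,
40 AR / 40 IR (plus 20 M / 20 CR) trials, all planted effects at their
calibrated defaults, 1000 permutations per contrast — with the map
region restricted to encoding 0–1.5 s × retrieval 0–2 s and `float32`
spectral precision.  Permutation counts matter near the significance
boundary: the (b+1)/(m+1) p estimator is deliberately conservative, so
a cluster whose true corrected p is ~0.05 reports ~0.055 at 200
permutations and only ~0.051 at 1000; borderline clusters need the full
default count.  The acceptance script evaluates 5 pipeline seeds,
100 null runs × 500 permutations for the type-I calibration, 1000
random pattern pairs for the correlation-weight identity, and 625
trials for the rejection-rule operating characteristics.  Unit tests
use a reduced two-participant cohort that keeps every structural
feature (four associations, all four conditions, artifacts, coupling).

## Known limitations

* Low-frequency edge bins rely on reflection padding (flagged in the
  validity mask); absolute relative-power levels carry the small-sample
  ratio bias described above.
* The omnibus F cluster test and the response-locked analyses are
  implemented and tested at reduced scale but are not part of the
  default report.
* Trial-level Fisher averaging, the 4-cycle/200-ms decomposition preset
  and band-restricted maps are exposed as options and verified for
  consistency, not exercised by the default pipeline.
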