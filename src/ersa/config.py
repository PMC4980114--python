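"""Study and pipeline configuration objects.

``StudyConfig`` fixes the simulated experiment: cohort size, trial counts
per memory condition, epoch geometry, the 1/f background, the planted
trial-unique fingerprints shared between encoding and retrieval on
associative-recognition (AR) trials, the condition-specific gamma/alpha
band effects, response-latency distributions and the artifact rate.
``PipelineConfig`` adds the analysis settings (pattern variant, band/window
definitions, cluster-permutation parameters) used by :mod:`ersa.pipeline`.

Both serialize to plain YAML so a full run is reproducible from one file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

CONDITIONS = ("AR", "IR", "M", "CR")
#: retrieval conditions referring to previously studied ("old") words
OLD_CONDITIONS = ("AR", "IR", "M")
ASSOCIATIONS = ("blue", "red", "indoor", "outdoor")
#: association label -> block type (colour vs. scene blocks)
BLOCK_TYPE = {"blue": "colour", "red": "colour", "indoor": "scene", "outdoor": "scene"}


@dataclass
class FingerprintSpec:
    """Trial-unique time-frequency fingerprint planted at encoding and,
    for AR trials only, copied into the retrieval epoch.

    The fingerprint is a smooth envelope over ``n_channels`` log-spaced
    carrier frequencies x ``n_time_knots`` time knots spanning a fixed
    window.  ``association_weight`` mixes a shared per-association
    component into each trial's envelope (0 = fully trial-unique,
    1 = identical within association).  ``amplitude`` scales the planted
    signal relative to the background standard deviation.
    """

    encoding_window: tuple[float, float] = (0.5, 1.0)
    retrieval_window: tuple[float, float] = (1.0, 1.5)
    frequency_span: tuple[float, float] = (3.0, 90.0)
    amplitude: float = 0.25
    n_channels: int = 16
    n_time_knots: int = 6
    association_weight: float = 0.15
    retrieval_gain: float = 1.0


@dataclass
class BandEffect:
    """Band-limited power increase planted in one condition's retrieval epochs."""

    condition: str = "AR"
    band: tuple[float, float] = (50.0, 90.0)
    window: tuple[float, float] = (0.5, 1.3)
    #: burst amplitude as a multiple of the background RMS within ``band``
    rel_amplitude: float = 0.4


@dataclass
class StudyConfig:
    """Full description of one simulated study."""

    n_participants: int = 11
    n_trials_per_condition: dict[str, int] = field(
        default_factory=lambda: {"AR": 40, "IR": 40, "M": 20, "CR": 20}
    )
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-1.0, 3.0)
    association_set: tuple[str, ...] = ASSOCIATIONS
    #: 1/f^chi spectral slope of the background
    noise_exponent: float = 2.0
    #: (f_lo, f_hi, relative amplitude) band-limited components added to the 1/f floor
    oscillations: tuple[tuple[float, float, float], ...] = (
        (4.0, 8.0, 0.25),
        (8.0, 12.0, 0.25),
        (15.0, 25.0, 0.15),
        (40.0, 80.0, 0.15),
    )
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    gamma_effect: BandEffect = field(default_factory=BandEffect)
    alpha_effect: BandEffect = field(
        default_factory=lambda: BandEffect(
            condition="IR", band=(8.0, 12.0), window=(1.0, 2.0), rel_amplitude=1.0
        )
    )
    #: fraction of the AR gamma-burst amplitude driven by the same per-trial
    #: lognormal modulator as the reinstated fingerprint (0 = independent)
    gamma_reinstatement_coupling: float = 0.9
    #: sigma of the per-trial lognormal amplitude modulator
    modulation_sigma: float = 0.6
    #: per-condition (mean, sd) of response latencies in seconds
    rt_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "AR": (1.91, 0.50),
            "IR": (2.14, 0.50),
            "M": (2.30, 0.55),
            "CR": (2.00, 0.50),
        }
    )
    rt_shift: float = 0.3
    rt_max: float = 5.0
    artifact_rate: float = 0.12
    #: artifact transient amplitude, multiples of the trace sd
    artifact_scale: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for cond, n in self.n_trials_per_condition.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
            if n <= 0:
                raise ValueError(f"trial count for {cond} must be positive")
        t0, t1 = self.epoch_window
        if not t0 < t1:
            raise ValueError("epoch_window start must precede end")
        if len(set(self.association_set)) != len(self.association_set):
            raise ValueError("association labels must be unique")
        fp = self.fingerprint
        for w in (fp.encoding_window, fp.retrieval_window):
            if not (t0 <= w[0] < w[1] <= t1):
                raise ValueError(f"planted window {w} outside epoch {self.epoch_window}")
        for eff in (self.gamma_effect, self.alpha_effect):
            if not (t0 <= eff.window[0] < eff.window[1] <= t1):
                raise ValueError(f"effect window {eff.window} outside epoch")
            if eff.condition not in CONDITIONS:
                raise ValueError(f"unknown effect condition {eff.condition!r}")
        for cond, (m, s) in self.rt_distributions.items():
            if m <= self.rt_shift or s <= 0:
                raise ValueError(f"invalid rt distribution for {cond}")


@dataclass
class AnalysisConfig:
    """Windows, bands and pattern settings of the group analysis."""

    variant: str = "tf_400ms"
    baseline: tuple[float, float] = (-0.5, 0.0)
    gamma_band: tuple[float, float] = (50.0, 90.0)
    gamma_window: tuple[float, float] = (0.5, 1.3)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    alpha_window: tuple[float, float] = (1.0, 2.0)
    #: reinstatement summary window: encoding 0.5-1 s x retrieval 1-1.5 s
    reinstatement_enc_window: tuple[float, float] = (0.5, 1.0)
    reinstatement_ret_window: tuple[float, float] = (1.0, 1.5)
    #: response-locked summary window on the retrieval axis
    response_ret_window: tuple[float, float] = (-0.8, -0.2)
    #: optional restriction of map centres (seconds); None = all valid centres
    map_enc_range: tuple[float, float] | None = None
    map_ret_range: tuple[float, float] | None = None
    #: numeric precision of the heavy TFR/map stages
    precision: str = "float64"
    #: Fisher-z transform applied to the participant-average map
    #: ("participant", default) or to every trial map first ("trial")
    fisher_level: str = "participant"


@dataclass
class StatsConfig:
    alpha_cf: float = 0.05
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0


@dataclass
class PipelineConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    out_dir: str | None = None

    def validate(self) -> None:
        self.study.validate()
        t0, t1 = self.study.epoch_window
        a = self.analysis
        for w in (a.gamma_window, a.alpha_window, a.reinstatement_enc_window,
                  a.reinstatement_ret_window):
            if not (t0 <= w[0] < w[1] <= t1):
                raise ValueError(f"analysis window {w} outside epoch bounds")
        if a.variant not in ("tf_400ms", "freqs_only", "tf_500ms", "avg_500ms"):
            raise ValueError(f"unknown pattern variant {a.variant!r}")
        if a.fisher_level not in ("participant", "trial"):
            raise ValueError("fisher_level must be 'participant' or 'trial'")
        if not 0 < self.stats.alpha_cf < 1:
            raise ValueError("alpha_cf must be in (0, 1)")


def _asdict(obj):
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, list):
            return [clean(x) for x in v]
        return v

    return clean(d)


def _build(cls, data: Mapping):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in ("fingerprint",):
            v = _build(FingerprintSpec, v)
        elif f.name in ("gamma_effect", "alpha_effect"):
            v = _build(BandEffect, v)
        elif f.name == "study":
            v = _build(StudyConfig, v)
        elif f.name == "analysis":
            v = _build(AnalysisConfig, v)
        elif f.name == "stats":
            v = _build(StatsConfig, v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        elif isinstance(v, dict):
            v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
        kwargs[f.name] = v
    return cls(**kwargs)


def to_yaml(config: StudyConfig | PipelineConfig, path=None) -> str:
    """Serialize a config to YAML (returned; also written if *path* given)."""
    text = yaml.safe_dump(_asdict(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_pipeline_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path, string, or mapping."""
    if isinstance(source, Mapping):
        data = source
    else:
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
    cfg = _build(PipelineConfig, data or {})
    cfg.validate()
    return cfg
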