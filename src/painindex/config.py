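"""Configuration objects for every stage of the pain-index pipeline.

All tunable thresholds of the analysis (plausibility ranges, stability
gates, feature windows, model grids, response windows) live here as plain
dataclasses so that a single YAML file can drive a full reproducible run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Canonical vital-sign channel names, in table column order.
VITALS = ("hr", "sbp", "mbp", "dbp", "rr", "spo2")

#: Vitals that enter the stability gates and the model's explanatory set.
#: SpO2 is generated and filtered but is not an explanatory variable.
MODEL_VITALS = ("hr", "sbp", "mbp", "dbp", "rr")


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config field '{name}': {msg}")


def _vital_dict(values: dict) -> dict:
    out = dict(values)
    missing = [v for v in VITALS if v not in out]
    if missing:
        raise ValueError(f"per-vital mapping missing entries for {missing}")
    return out


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic ICU cohort generator.

    Units: times in minutes, HR in bpm, pressures in mmHg, RR in
    breaths/min, SpO2 in %.  ``pain_effect`` is the additive vital-sign
    shift per unit of latent pain severity; the severity scale itself is
    calibrated internally so that the realized fraction of CPOT >= 3
    assessments matches ``target_positive_rate``.
    """

    n_patients: int = 200
    duration_min: int = 2880
    seed: int = 0

    mean: dict = field(default_factory=lambda: {
        "hr": 80.0, "sbp": 122.0, "mbp": 82.0, "dbp": 62.0,
        "rr": 16.0, "spo2": 97.0})
    pop_sd: dict = field(default_factory=lambda: {
        "hr": 10.0, "sbp": 12.0, "mbp": 8.0, "dbp": 8.0,
        "rr": 2.5, "spo2": 1.0})
    # mbp is a derived channel (DBP + pulse-pressure/3); its entry is the
    # realized minute-scale noise SD implied by the SBP/DBP noise
    noise_sd: dict = field(default_factory=lambda: {
        "hr": 3.0, "sbp": 5.0, "mbp": 2.9, "dbp": 3.5,
        "rr": 1.5, "spo2": 0.6})
    # Admission instability: exponentially decaying drift added on top of
    # the true baseline, largest at minute 0.
    drift_magnitude: dict = field(default_factory=lambda: {
        "hr": 18.0, "sbp": 22.0, "mbp": 14.0, "dbp": 10.0,
        "rr": 5.0, "spo2": -2.0})
    drift_half_life_min: float = 10.0
    ar1_coefficient: float = 0.0

    pain_episode_rate: float = 0.05          # episodes per hour
    episode_duration_min: tuple = (20.0, 45.0)
    episode_ramp_min: float = 3.0
    episode_amplitude_sigma: float = 0.3     # lognormal sigma, median 1
    # pain episodes start only after the initial stabilization phase
    # (admissions arrive under residual anaesthesia/analgo-sedation)
    episode_min_onset_min: int = 120
    pain_effect: dict = field(default_factory=lambda: {
        "hr": 8.0, "sbp": 10.0, "mbp": 6.7, "dbp": 5.0,
        "rr": 3.0, "spo2": 0.0})
    target_positive_rate: float = 0.033

    artifact_rate: float = 0.01
    dropout_rate: float = 0.01

    assessment_interval_min: int = 480
    trigger_delay_range: tuple = (1, 5)
    observer_noise: bool = True

    bolus_at_positive_prob: float = 0.5
    bolus_response_prob: float = 0.3
    bolus_decay_half_life_min: float = 30.0
    bolus_effect_duration_min: int = 180
    bolus_followup_delay_min: int = 60
    bolus_min_gap_min: int = 120
    bolus_doses_ug: tuple = (25.0, 50.0, 75.0, 100.0)

    rass_switch_prob: float = 1.0 / 180.0
    cam_positive_rate: float = 0.216
    male_fraction: float = 0.58

    def __post_init__(self) -> None:
        _require(self.n_patients >= 1, "n_patients", "must be >= 1")
        _require(self.duration_min >= 120, "duration_min", "must be >= 120")
        _require(self.assessment_interval_min >= 1,
                 "assessment_interval_min", "must be >= 1")
        for name in ("target_positive_rate", "artifact_rate", "dropout_rate",
                     "bolus_at_positive_prob", "bolus_response_prob",
                     "rass_switch_prob", "cam_positive_rate", "male_fraction"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be a fraction in [0, 1]")
        _require(0.0 <= self.ar1_coefficient < 1.0, "ar1_coefficient",
                 "must be in [0, 1)")
        _require(self.pain_episode_rate >= 0.0, "pain_episode_rate",
                 "must be >= 0")
        _require(self.drift_half_life_min > 0.0, "drift_half_life_min",
                 "must be > 0")
        self.mean = _vital_dict(self.mean)
        self.pop_sd = _vital_dict(self.pop_sd)
        self.noise_sd = _vital_dict(self.noise_sd)
        self.drift_magnitude = _vital_dict(self.drift_magnitude)
        self.pain_effect = _vital_dict(self.pain_effect)
        for name in ("pop_sd", "noise_sd"):
            for v, sd in getattr(self, name).items():
                _require(sd >= 0.0, f"{name}[{v}]", "SD must be >= 0")
        lo, hi = self.episode_duration_min
        _require(0 < lo <= hi, "episode_duration_min",
                 "must be an increasing positive (lo, hi) pair")


@dataclass
class NoiseRuleSet:
    """Per-vital plausibility ranges for row-wise artifact exclusion.

    A record in which any present vital falls outside its inclusive range,
    or in which the pressure ordering DBP <= MBP <= SBP is violated while
    all three pressures are present, is removed whole.
    """

    ranges: dict = field(default_factory=lambda: {
        "hr": (20.0, 250.0), "sbp": (30.0, 300.0), "mbp": (20.0, 250.0),
        "dbp": (10.0, 200.0), "rr": (2.0, 60.0), "spo2": (50.0, 100.0)})
    enforce_pressure_order: bool = True

    def __post_init__(self) -> None:
        self.ranges = _vital_dict(self.ranges)
        for v, (lo, hi) in self.ranges.items():
            _require(lo < hi, f"ranges[{v}]", "lower bound must be < upper")


@dataclass
class StabilityConfig:
    """Gates of the five-step baseline establishment procedure."""

    window_min: int = 60
    coverage_threshold: float = 0.90
    n_segments: int = 3
    friedman_alpha: float = 0.05
    cv_thresholds: dict = field(default_factory=lambda: {
        "hr": 0.10, "sbp": 0.10, "mbp": 0.10, "dbp": 0.10,
        "rr": 0.20, "spo2": 0.02})
    retry_delay_min: int = 20
    anchor_span_min: int = 5
    vitals: tuple = MODEL_VITALS

    def __post_init__(self) -> None:
        _require(0.0 < self.coverage_threshold <= 1.0, "coverage_threshold",
                 "must be in (0, 1]")
        _require(0.0 < self.friedman_alpha < 1.0, "friedman_alpha",
                 "must be in (0, 1)")
        _require(self.window_min % self.n_segments == 0, "window_min",
                 "must be divisible by n_segments")
        _require(self.retry_delay_min >= 1, "retry_delay_min", "must be >= 1")
        _require(0 < self.anchor_span_min <= self.window_min,
                 "anchor_span_min", "must be in (0, window_min]")
        for v in self.vitals:
            thr = self.cv_thresholds.get(v)
            _require(thr is not None and thr > 0.0, f"cv_thresholds[{v}]",
                     "must be > 0 for every gated vital")


#: Deviation summaries computed per vital over the pre-assessment hour.
FEATURE_KINDS = ("value", "dev", "area_above", "area_below", "mean_dev")


@dataclass
class FeatureConfig:
    """Shape of the per-assessment explanatory feature vectors."""

    window_min: int = 60
    coverage_threshold: float = 0.90   # strictly greater-than gate
    rass_tolerance_min: int = 60
    vitals: tuple = MODEL_VITALS
    kinds: tuple = FEATURE_KINDS

    def __post_init__(self) -> None:
        _require(self.window_min >= 2, "window_min", "must be >= 2")
        _require(0.0 < self.coverage_threshold < 1.0, "coverage_threshold",
                 "must be in (0, 1)")
        bad = [k for k in self.kinds if k not in FEATURE_KINDS]
        _require(not bad, "kinds", f"unknown feature kinds {bad}")


@dataclass
class ModelConfig:
    """Random-forest training configuration (grid, CV, oversampling)."""

    n_estimators_grid: tuple = (5, 10, 17, 25, 50)
    max_depth_grid: tuple = (6, 10, 14, 18)
    cv_folds: int = 10
    cv_repeats: int = 10
    seed: int = 0
    oversample: bool = True
    split_unit: str = "patient"
    adasyn_k: int = 5
    adasyn_beta: float = 1.0

    def __post_init__(self) -> None:
        _require(len(self.n_estimators_grid) > 0, "n_estimators_grid",
                 "must be non-empty")
        _require(len(self.max_depth_grid) > 0, "max_depth_grid",
                 "must be non-empty")
        _require(self.cv_folds >= 2, "cv_folds", "must be >= 2")
        _require(self.cv_repeats >= 1, "cv_repeats", "must be >= 1")
        _require(self.split_unit in ("patient", "assessment"), "split_unit",
                 "must be 'patient' or 'assessment'")
        _require(self.adasyn_k >= 1, "adasyn_k", "must be >= 1")

    @classmethod
    def reference_point(cls, **kw) -> "ModelConfig":
        """Single-cell grid at the reference optimum (17 trees, depth 14)."""
        kw.setdefault("n_estimators_grid", (17,))
        kw.setdefault("max_depth_grid", (14,))
        return cls(**kw)


@dataclass
class ResponseConfig:
    """Windows of the fentanyl bolus treatment-response analysis."""

    window_min: int = 60          # trajectory half-width around the bolus
    cpot_search_min: int = 120    # pre/post CPOT search span
    eval_offset_min: int = 60     # evaluation point after administration
    dose_range_ug: tuple = (25.0, 100.0)

    def __post_init__(self) -> None:
        _require(self.window_min >= 1, "window_min", "must be >= 1")
        _require(self.eval_offset_min <= self.window_min, "eval_offset_min",
                 "must be <= window_min")


@dataclass
class RunConfig:
    """One config to drive simulate -> ... -> response end to end."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    noise_rules: NoiseRuleSet = field(default_factory=NoiseRuleSet)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig.reference_point)
    response: ResponseConfig = field(default_factory=ResponseConfig)
    seed: int = 0
    outdir: str = "painindex_run"
    stages: tuple = ("simulate", "preprocess", "baseline", "features",
                     "train", "predict", "evaluate", "response")

    def __post_init__(self) -> None:
        known = ("simulate", "preprocess", "baseline", "features",
                 "train", "predict", "evaluate", "response")
        bad = [s for s in self.stages if s not in known]
        _require(not bad, "stages", f"unknown stages {bad}")


_SECTION_TYPES = {
    "generator": GeneratorConfig, "noise_rules": NoiseRuleSet,
    "stability": StabilityConfig, "features": FeatureConfig,
    "model": ModelConfig, "response": ResponseConfig,
}


def run_config_from_dict(data: dict) -> RunConfig:
    kw = {}
    for key, val in (data or {}).items():
        if key in _SECTION_TYPES:
            if not isinstance(val, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            val = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in val.items()}
            kw[key] = _SECTION_TYPES[key](**val)
        elif key in ("seed", "outdir"):
            kw[key] = val
        elif key == "stages":
            kw[key] = tuple(val)
        else:
            raise ValueError(f"unknown config section '{key}'")
    return RunConfig(**kw)


def load_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return run_config_from_dict(data or {})


def dump_run_config(cfg: RunConfig, path: str) -> None:
    data = dataclasses.asdict(cfg)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
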