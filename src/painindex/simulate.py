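"""Synthetic ICU cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: each
patient has a stable per-vital baseline that is reached only after an
unstable admission period (exponentially decaying drift), intermittent
pain episodes that jointly elevate HR/BP/RR in proportion to a latent
severity, CPOT assessments on an 8-h schedule plus event-triggered ones,
fentanyl boluses with responder/non-responder dynamics, and artifact/
dropout corruption of the per-minute record.

The severity -> CPOT map is ``CPOT = clamp(round(2*severity + eps), 0, 8)``
with integer observer noise ``eps`` uniform on {-1, 0, 1}.  The overall
severity scale is calibrated by bisection so that the expected fraction of
CPOT >= 3 assessments matches ``target_positive_rate``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import VITALS, GeneratorConfig

__all__ = [
    "PatientProfile", "GroundTruth", "Cohort", "generate_cohort",
    "generate_patient_vitals", "emit_assessments", "inject_artifacts",
]

#: Severity thresholds at which CPOT >= 3 becomes possible for each value
#: of the observer noise eps in {-1, 0, 1}: round(2s + eps) >= 3 requires
#: 2s + eps >= 2.5.
_POS_THRESHOLDS = np.array([1.75, 1.25, 0.75])

_RASS_STATES = np.arange(-5, 5)
# Qualitative marginal occupancy (mass near 0 and negative values).
_RASS_PROBS = np.array(
    [0.038, 0.086, 0.108, 0.098, 0.159, 0.428, 0.057, 0.021, 0.004, 0.001])
_RASS_PROBS = _RASS_PROBS / _RASS_PROBS.sum()


@dataclass
class PatientProfile:
    patient_id: str
    age: int
    sex: str
    baselines: dict  # per-vital true baseline values


@dataclass
class GroundTruth:
    """Latent quantities of a generated cohort, for parameter-recovery tests."""

    baselines: pd.DataFrame          # patient_id + one column per vital
    severity: dict                   # patient_id -> per-minute array (>= 0)
    episodes: pd.DataFrame           # patient_id, onset, end, amplitude
    boluses: pd.DataFrame            # patient_id, t_min, responder
    artifact_minutes: pd.DataFrame   # patient_id, t_min
    severity_scale: float


@dataclass
class Cohort:
    vitals: pd.DataFrame
    assessments: pd.DataFrame
    events: pd.DataFrame
    demographics: pd.DataFrame
    ground_truth: GroundTruth
    config: GeneratorConfig = field(repr=False, default=None)

    def write(self, outdir) -> dict:
        """Write the cohort as CSV tables; returns {name: path}."""
        from . import preprocess  # local import to avoid a cycle
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        writers = {
            "vitals": preprocess.write_vitals,
            "assessments": preprocess.write_assessments,
            "events": preprocess.write_events,
            "demographics": preprocess.write_demographics,
        }
        for name, writer in writers.items():
            path = os.path.join(outdir, f"{name}.csv")
            writer(getattr(self, name), path)
            paths[name] = path
        gt_path = os.path.join(outdir, "ground_truth.csv")
        self.ground_truth.baselines.to_csv(gt_path, index=False)
        paths["ground_truth"] = gt_path
        gb_path = os.path.join(outdir, "ground_truth_boluses.csv")
        self.ground_truth.boluses.to_csv(gb_path, index=False)
        paths["ground_truth_boluses"] = gb_path
        return paths


# ---------------------------------------------------------------------------
# latent severity


def _draw_episodes(rng: np.random.Generator, cfg: GeneratorConfig) -> list:
    """Episode (onset, duration, amplitude) triples for one patient."""
    mean_count = cfg.pain_episode_rate * cfg.duration_min / 60.0
    n_ep = rng.poisson(mean_count)
    episodes = []
    start = min(cfg.episode_min_onset_min, cfg.duration_min - 1)
    for _ in range(n_ep):
        onset = int(rng.integers(start, cfg.duration_min))
        lo, hi = cfg.episode_duration_min
        dur = float(rng.uniform(lo, hi))
        amp = float(np.exp(rng.normal(0.0, cfg.episode_amplitude_sigma)))
        episodes.append((onset, dur, amp))
    episodes.sort()
    return episodes


def _unit_severity(n: int, episodes: list, ramp_min: float) -> np.ndarray:
    """Per-minute latent severity on the generator's unit scale (>= 0).

    Each episode is a trapezoid: linear ramp up over ``ramp_min`` minutes,
    plateau at its amplitude, linear ramp down.  Overlaps take the max.
    """
    sev = np.zeros(n)
    t = np.arange(n, dtype=float)
    for onset, dur, amp in episodes:
        end = onset + dur
        rel = np.minimum((t - onset) / ramp_min, (end - t) / ramp_min)
        shape = np.clip(np.minimum(rel, 1.0), 0.0, 1.0)
        np.maximum(sev, amp * shape, out=sev)
    return sev


def _positive_probability(severity: np.ndarray) -> np.ndarray:
    """P(CPOT >= 3) at given severities, averaging over observer noise."""
    return (severity[:, None] >= _POS_THRESHOLDS[None, :]).mean(axis=1)


def _calibrate_scale(unit_sev_at_assessments: np.ndarray,
                     target: float) -> float:
    """Bisection on the severity scale so E[positive fraction] ~= target."""
    u = np.asarray(unit_sev_at_assessments, dtype=float)
    if u.size == 0 or target <= 0.0 or np.all(u <= 0):
        return 1.0

    def frac(scale: float) -> float:
        return float(_positive_probability(scale * u).mean())

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if frac(hi) >= target:
            break
        hi *= 2.0
    if frac(hi) < target:      # target unreachable (few in-episode minutes)
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def _cpot_from_severity(severity: float, eps: int) -> int:
    return int(np.clip(np.rint(2.0 * severity + eps), 0, 8))


# ---------------------------------------------------------------------------
# per-patient streams


def _rass_series(rng: np.random.Generator, n: int,
                 switch_prob: float) -> np.ndarray:
    """Slowly switching categorical RASS chain with the marginal above."""
    switch = rng.random(n) < switch_prob
    switch[0] = True
    seg = np.cumsum(switch)                      # 1-based segment ids
    draws = rng.choice(_RASS_STATES, size=int(seg[-1]), p=_RASS_PROBS)
    return draws[seg - 1]


def _ar1_noise(rng: np.random.Generator, n: int, sd: float,
               phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    if phi == 0.0:
        return rng.normal(0.0, sd, n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, n)
    e[0] = rng.normal(0.0, sd)                   # stationary start
    return lfilter([1.0], [1.0, -phi], e)


def generate_patient_vitals(profile: PatientProfile, config: GeneratorConfig,
                            seed, severity: np.ndarray | None = None
                            ) -> pd.DataFrame:
    """One patient's uncorrupted per-minute vital stream.

    signal = true baseline + decaying admission drift + AR(1) noise
    + pain_effect x severity.  MBP is derived as DBP + pulse-pressure/3
    (pulse pressure floored at 5 mmHg) so DBP <= MBP <= SBP everywhere.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = config.duration_min
    if severity is None:
        severity = np.zeros(n)
    t = np.arange(n, dtype=float)
    decay = np.power(2.0, -t / config.drift_half_life_min)

    def channel(v: str) -> np.ndarray:
        return (profile.baselines[v]
                + config.drift_magnitude[v] * decay
                + _ar1_noise(rng, n, config.noise_sd[v],
                             config.ar1_coefficient)
                + config.pain_effect[v] * severity)

    hr = channel("hr")
    sbp_raw = channel("sbp")
    dbp = channel("dbp")
    rr = channel("rr")
    spo2 = np.minimum(channel("spo2"), 100.0)

    pulse = np.maximum(sbp_raw - dbp, 5.0)
    sbp = dbp + pulse
    mbp = dbp + pulse / 3.0

    df = pd.DataFrame({
        "patient_id": profile.patient_id,
        "t_min": np.arange(n, dtype=np.int64),
        "hr": hr, "sbp": sbp, "mbp": mbp, "dbp": dbp,
        "rr": rr, "spo2": spo2,
    })
    df[list(VITALS)] = df[list(VITALS)].round(1)
    return df


_ARTIFACT_KINDS = ("hr_spike", "sbp_spike", "dbp_spike", "rr_spike",
                   "spo2_low", "order_violation")


def inject_artifacts(stream: pd.DataFrame, artifact_rate: float,
                     dropout_rate: float, seed) -> tuple:
    """Corrupt and thin one patient's stream.

    Corrupted minutes carry out-of-range spikes or a violated pressure
    ordering (every corruption breaks at least one default plausibility
    rule); dropped minutes are removed entirely.  Returns
    ``(stream, corrupted_t_min_array)``.
    """
    if not 0.0 <= artifact_rate <= 1.0 or not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("artifact_rate and dropout_rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if artifact_rate == 0.0 and dropout_rate == 0.0:
        return stream, np.array([], dtype=np.int64)

    df = stream.copy()
    n = len(df)
    hit = np.flatnonzero(rng.random(n) < artifact_rate)
    kinds = rng.integers(0, len(_ARTIFACT_KINDS), size=hit.size)
    for pos, kind_ix in zip(hit, kinds):
        kind = _ARTIFACT_KINDS[kind_ix]
        row = df.index[pos]
        if kind == "hr_spike":
            df.loc[row, "hr"] = round(300.0 + rng.uniform(0, 100), 1)
        elif kind == "sbp_spike":
            df.loc[row, "sbp"] = round(330.0 + rng.uniform(0, 60), 1)
        elif kind == "dbp_spike":
            df.loc[row, "dbp"] = round(220.0 + rng.uniform(0, 40), 1)
        elif kind == "rr_spike":
            df.loc[row, "rr"] = round(70.0 + rng.uniform(0, 30), 1)
        elif kind == "spo2_low":
            df.loc[row, "spo2"] = round(20.0 + rng.uniform(0, 25), 1)
        else:  # pressure ordering violated, all values still "plausible"
            sbp = df.loc[row, "sbp"]
            df.loc[row, "dbp"] = round(min(float(sbp) + 15.0, 199.0), 1)

    keep = rng.random(n) >= dropout_rate
    corrupted_t = df["t_min"].to_numpy()[hit]
    df = df.loc[keep]
    corrupted_t = corrupted_t[np.isin(corrupted_t, df["t_min"].to_numpy())]
    return df.reset_index(drop=True), corrupted_t.astype(np.int64)


def emit_assessments(severity: np.ndarray, rass: np.ndarray,
                     schedule, scale: float = 1.0, seed=0,
                     observer_noise: bool = True) -> pd.DataFrame:
    """Score CPOT/RASS at the scheduled minutes of one patient.

    ``schedule`` minutes must lie within [0, len(severity)] (the stream's
    end boundary is a valid assessment time; severity is then read at the
    final recorded minute).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = len(severity)
    schedule = np.asarray(list(schedule), dtype=np.int64)
    if schedule.size and (schedule.min() < 0 or schedule.max() > n):
        raise ValueError("schedule outside stream time range")
    rows = []
    for t in schedule:
        ix = min(int(t), n - 1)
        eps = int(rng.integers(-1, 2)) if observer_noise else 0
        rows.append({
            "t_min": int(t),
            "cpot": _cpot_from_severity(scale * severity[ix], eps),
            "rass": int(rass[ix]),
        })
    return pd.DataFrame(rows, columns=["t_min", "cpot", "rass"])


# ---------------------------------------------------------------------------
# cohort assembly


def _draw_profile(rng: np.random.Generator, patient_id: str,
                  cfg: GeneratorConfig) -> PatientProfile:
    group = rng.choice(3, p=[0.18, 0.36, 0.46])
    age = int(rng.integers(*((20, 45), (45, 65), (65, 96))[group]))
    sex = "male" if rng.random() < cfg.male_fraction else "female"

    b = {}
    b["hr"] = float(np.clip(rng.normal(cfg.mean["hr"], cfg.pop_sd["hr"]),
                            45, 130))
    b["sbp"] = float(np.clip(rng.normal(cfg.mean["sbp"], cfg.pop_sd["sbp"]),
                             85, 185))
    b["dbp"] = float(np.clip(rng.normal(cfg.mean["dbp"], cfg.pop_sd["dbp"]),
                             40, 105))
    if b["sbp"] - b["dbp"] < 15:
        b["dbp"] = b["sbp"] - 15
    b["mbp"] = b["dbp"] + (b["sbp"] - b["dbp"]) / 3.0
    b["rr"] = float(np.clip(rng.normal(cfg.mean["rr"], cfg.pop_sd["rr"]),
                            8, 28))
    b["spo2"] = float(np.clip(rng.normal(cfg.mean["spo2"], cfg.pop_sd["spo2"]),
                              90, 100))
    return PatientProfile(patient_id, age, sex, b)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full cohort; deterministic given ``config.seed``."""
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(cfg.n_patients)]
    width = max(4, len(str(cfg.n_patients)))

    profiles, episodes_pp, unit_sev_pp, schedules, rass_pp = [], [], [], [], []
    for i, rng in enumerate(rngs):
        pid = f"P{i:0{width}d}"
        profiles.append(_draw_profile(rng, pid, cfg))
        eps = _draw_episodes(rng, cfg)
        episodes_pp.append(eps)
        unit_sev_pp.append(_unit_severity(cfg.duration_min, eps,
                                          cfg.episode_ramp_min))
        scheduled = list(np.arange(cfg.assessment_interval_min,
                                   cfg.duration_min + 1,
                                   cfg.assessment_interval_min))
        lo, hi = cfg.trigger_delay_range
        triggered = []
        for onset, _, _ in eps:
            t = onset + int(rng.integers(lo, hi + 1))
            if t <= cfg.duration_min:
                triggered.append(t)
        schedules.append((scheduled, triggered))
        rass_pp.append(_rass_series(rng, cfg.duration_min,
                                    cfg.rass_switch_prob))

    # calibrate the cohort-wide severity scale on the pre-bolus severities
    sev_at_assess = []
    for sev, (scheduled, triggered) in zip(unit_sev_pp, schedules):
        for t in scheduled + triggered:
            sev_at_assess.append(sev[min(t, cfg.duration_min - 1)])
    scale = _calibrate_scale(np.array(sev_at_assess), cfg.target_positive_rate)

    vitals_parts, assess_parts, event_rows = [], [], []
    gt_bolus_rows, artifact_rows, episode_rows = [], [], []
    for i, rng in enumerate(rngs):
        profile = profiles[i]
        sev = scale * unit_sev_pp[i]
        rass = rass_pp[i]
        scheduled, triggered = schedules[i]

        # time-ordered assessment walk; boluses modify future severity
        heap = [(t, 0, "scheduled") for t in scheduled]
        heap += [(t, 1, "triggered") for t in triggered]
        heapq.heapify(heap)
        last_bolus_t = -10 ** 9
        counter = 2
        assess_rows = []
        while heap:
            t, _, kind = heapq.heappop(heap)
            ix = min(t, cfg.duration_min - 1)
            eps = int(rng.integers(-1, 2)) if cfg.observer_noise else 0
            cpot = _cpot_from_severity(sev[ix], eps)
            cam = np.nan
            if rng.random() < 0.8:
                cam = ("positive" if rng.random() < cfg.cam_positive_rate
                       else "negative")
            assess_rows.append({
                "patient_id": profile.patient_id, "t_min": int(t),
                "cpot": cpot, "rass": int(rass[ix]), "cam_icu": cam})
            if (kind != "followup" and cpot >= 3
                    and t - last_bolus_t >= cfg.bolus_min_gap_min
                    and t + 1 + cfg.bolus_followup_delay_min <= cfg.duration_min
                    and rng.random() < cfg.bolus_at_positive_prob):
                t0 = int(t) + 1
                last_bolus_t = t0
                dose = float(rng.choice(cfg.bolus_doses_ug))
                responder = bool(rng.random() < cfg.bolus_response_prob)
                event_rows.append({
                    "patient_id": profile.patient_id, "t_min": t0,
                    "drug": "fentanyl", "dose_ug": dose})
                gt_bolus_rows.append({
                    "patient_id": profile.patient_id, "t_min": t0,
                    "responder": responder})
                if responder:
                    m_end = min(t0 + cfg.bolus_effect_duration_min,
                                cfg.duration_min)
                    m = np.arange(t0 + 1, m_end)
                    sev[m] = sev[m] * np.power(
                        0.5, (m - t0) / cfg.bolus_decay_half_life_min)
                heapq.heappush(
                    heap, (t0 + cfg.bolus_followup_delay_min, counter,
                           "followup"))
                counter += 1

        stream = generate_patient_vitals(profile, cfg, rng, severity=sev)
        stream, corrupted_t = inject_artifacts(
            stream, cfg.artifact_rate, cfg.dropout_rate, rng)
        vitals_parts.append(stream)
        assess_parts.append(pd.DataFrame(
            assess_rows, columns=["patient_id", "t_min", "cpot", "rass",
                                  "cam_icu"]))
        artifact_rows += [{"patient_id": profile.patient_id, "t_min": int(t)}
                          for t in corrupted_t]
        episode_rows += [{"patient_id": profile.patient_id, "onset": onset,
                          "end": onset + dur, "amplitude": scale * amp}
                         for onset, dur, amp in episodes_pp[i]]
        unit_sev_pp[i] = sev  # keep the post-bolus severity as ground truth

    vitals = pd.concat(vitals_parts, ignore_index=True)
    assessments = (pd.concat(assess_parts, ignore_index=True)
                   .sort_values(["patient_id", "t_min"], kind="stable")
                   .reset_index(drop=True))
    events = pd.DataFrame(event_rows,
                          columns=["patient_id", "t_min", "drug", "dose_ug"])
    demographics = pd.DataFrame(
        [{"patient_id": p.patient_id, "age": p.age, "sex": p.sex}
         for p in profiles])
    gt = GroundTruth(
        baselines=pd.DataFrame(
            [{"patient_id": p.patient_id, **p.baselines} for p in profiles]),
        severity={p.patient_id: unit_sev_pp[i]
                  for i, p in enumerate(profiles)},
        episodes=pd.DataFrame(
            episode_rows, columns=["patient_id", "onset", "end", "amplitude"]),
        boluses=pd.DataFrame(
            gt_bolus_rows, columns=["patient_id", "t_min", "responder"]),
        artifact_minutes=pd.DataFrame(
            artifact_rows, columns=["patient_id", "t_min"]),
        severity_scale=scale,
    )
    return Cohort(vitals, assessments, events, demographics, gt, cfg)
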