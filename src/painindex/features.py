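"""Per-assessment explanatory features: deviations from baseline.

For each CPOT assessment at minute t, the vitals of the half-open window
[t-60, t) are extracted; when strictly more than 90% of the window is
present, gaps are completed by two-tailed linear interpolation and, per
vital v with baseline b_v, the deviation d(t) = v(t) - b_v is summarised
as the trapezoidal area above the baseline, the area below it, the mean
deviation, the deviation at the assessment minute and the raw value.
Sex, stratified age and the nearest RASS score are attached, and the
binary pain label is CPOT >= 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import VITALS, FeatureConfig

__all__ = ["extract_window", "deviation_areas", "stratify_age",
           "label_assessment", "build_feature_table", "minute_feature_table",
           "feature_columns"]

AGE_GROUPS = ("20-44", "45-64", "65+")


def feature_columns(cfg: FeatureConfig | None = None) -> list:
    cfg = cfg or FeatureConfig()
    cols = [f"{v}_{k}" for v in cfg.vitals for k in cfg.kinds]
    return cols + ["sex", "age_group", "rass"]


def extract_window(stream: pd.DataFrame, t: int, vitals=None,
                   width_min: int = 60,
                   coverage_threshold: float = 0.90) -> dict | None:
    """Completed per-vital series over [t - width, t), or None.

    The coverage gate here is strict (> threshold), matching the pain-
    index calculation; the baseline module's gate is inclusive.
    """
    from .baseline import interpolate_gaps

    vitals = tuple(vitals) if vitals is not None else VITALS
    if t - width_min < 0:
        return None
    sel = stream[(stream["t_min"] >= t - width_min) & (stream["t_min"] < t)]
    pos = sel["t_min"].to_numpy() - (t - width_min)
    out = {}
    for v in vitals:
        window = np.full(width_min, np.nan)
        window[pos] = sel[v].to_numpy(dtype=float)
        filled = interpolate_gaps(window, coverage_threshold, strict=True)
        if filled is None:
            return None
        out[v] = filled
    return out


def deviation_areas(series: np.ndarray, baseline_value: float) -> tuple:
    """(area_above, area_below, mean_dev, dev_at_t) for one vital window.

    Areas are trapezoidal integrals (unit*min) of the positive and
    negative parts of the deviation; ``dev_at_t`` is the deviation at the
    final minute of the window.
    """
    d = np.asarray(series, dtype=float) - baseline_value
    area_above = float(np.trapezoid(np.maximum(d, 0.0)))
    area_below = float(np.trapezoid(np.maximum(-d, 0.0)))
    return area_above, area_below, float(d.mean()), float(d[-1])


def stratify_age(age_years) -> str:
    """Study age strata: 20-44, 45-64, 65+ (inclusive bounds)."""
    age = float(age_years)
    if age < 20:
        raise ValueError(f"age {age_years} outside the study population "
                         "(inclusion requires age >= 20)")
    if age <= 44:
        return AGE_GROUPS[0]
    if age <= 64:
        return AGE_GROUPS[1]
    return AGE_GROUPS[2]


def label_assessment(cpot) -> int:
    """Binary pain label: CPOT >= 3 positive (1), <= 2 negative (0)."""
    cpot = int(cpot)
    if not 0 <= cpot <= 8:
        raise ValueError(f"cpot {cpot} outside [0, 8]")
    return int(cpot >= 3)


def _vital_features(windows: dict, base_row: pd.Series, kinds) -> dict:
    feats = {}
    for v, series in windows.items():
        b = float(base_row[f"{v}_base"])
        above, below, mean_dev, dev_at = deviation_areas(series, b)
        all_kinds = {"value": float(series[-1]), "dev": dev_at,
                     "area_above": above, "area_below": below,
                     "mean_dev": mean_dev}
        feats.update({f"{v}_{k}": all_kinds[k] for k in kinds})
    return feats


def build_feature_table(vitals: pd.DataFrame, baselines: pd.DataFrame,
                        assessments: pd.DataFrame,
                        demographics: pd.DataFrame,
                        cfg: FeatureConfig | None = None) -> tuple:
    """One feature row per assessment that passes all gates.

    Returns ``(features_df, drops_df)``; every dropped assessment is
    logged with a reason (no_baseline, before_baseline, coverage,
    no_rass, no_cpot).
    """
    cfg = cfg or FeatureConfig()
    known = set(demographics["patient_id"])
    unknown = set(assessments["patient_id"]) - known
    if unknown:
        raise ValueError(
            f"assessments reference unknown patient_id(s): {sorted(unknown)[:5]}")
    demo = demographics.set_index("patient_id")
    base = baselines.set_index("patient_id")
    streams = dict(tuple(vitals.groupby("patient_id", sort=True)))

    rows, drops = [], []
    for pid, group in assessments.groupby("patient_id", sort=True):
        rass_avail = group.dropna(subset=["rass"])
        rass_t = rass_avail["t_min"].to_numpy()
        rass_v = rass_avail["rass"].to_numpy(dtype=float)
        stream = streams.get(pid)
        for _, a in group.iterrows():
            t = int(a["t_min"])

            def drop(reason):
                drops.append({"patient_id": pid, "t_min": t,
                              "reason": reason})

            if pd.isna(a["cpot"]):
                drop("no_cpot")
                continue
            if pid not in base.index:
                drop("no_baseline")
                continue
            brow = base.loc[pid]
            if t < int(brow["established_at"]):
                drop("before_baseline")
                continue
            windows = (extract_window(stream, t, cfg.vitals, cfg.window_min,
                                      cfg.coverage_threshold)
                       if stream is not None else None)
            if windows is None:
                drop("coverage")
                continue
            if len(rass_t):
                dist = np.abs(rass_t - t)
                j = int(dist.argmin())
            if not len(rass_t) or dist[j] > cfg.rass_tolerance_min:
                drop("no_rass")
                continue
            row = {"patient_id": pid, "t_min": t}
            row.update(_vital_features(windows, brow, cfg.kinds))
            row["sex"] = demo.loc[pid, "sex"]
            row["age_group"] = stratify_age(demo.loc[pid, "age"])
            row["rass"] = int(rass_v[j])
            row["label"] = label_assessment(a["cpot"])
            rows.append(row)

    cols = ["patient_id", "t_min"] + feature_columns(cfg) + ["label"]
    features = pd.DataFrame(rows, columns=cols)
    drops_df = pd.DataFrame(drops, columns=["patient_id", "t_min", "reason"])
    return features, drops_df


# ---------------------------------------------------------------------------
# per-minute features (for continuous pain-index display)


def _rolling_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sum over [i-w, i) for each i >= w, aligned to index i."""
    c = np.concatenate([[0.0], np.cumsum(x)])
    return c[w:] - c[:-w]


def minute_feature_table(vitals: pd.DataFrame, baselines: pd.DataFrame,
                         assessments: pd.DataFrame,
                         demographics: pd.DataFrame,
                         minutes: dict | None = None,
                         cfg: FeatureConfig | None = None) -> pd.DataFrame:
    """Feature rows for arbitrary display minutes, vectorized per patient.

    ``minutes`` maps patient_id -> iterable of minutes (default: every
    minute from baseline establishment to the end of the stream).  Gaps
    are linearly completed over the whole stream before windowing; rows
    are emitted only at minutes where the 1-h window passes the coverage
    gate and the baseline is established, so no pain index exists before
    ``established_at``.
    """
    cfg = cfg or FeatureConfig()
    w = cfg.window_min
    demo = demographics.set_index("patient_id")
    base = baselines.set_index("patient_id")
    parts = []
    for pid, stream in vitals.groupby("patient_id", sort=True):
        if pid not in base.index:
            continue
        brow = base.loc[pid]
        est = int(brow["established_at"])
        t = stream["t_min"].to_numpy()
        n = int(t.max()) + 1
        want = (np.arange(est, n + 1) if minutes is None
                else np.asarray(sorted(minutes.get(pid, [])), dtype=np.int64))
        want = want[(want >= max(est, w)) & (want <= n)]
        if want.size == 0:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[t] = True
        coverage = _rolling_sum(mask.astype(float), w)  # index = window end
        ok = coverage[want - w] > cfg.coverage_threshold * w
        want = want[ok]
        if want.size == 0:
            continue
        cols = {"patient_id": pid, "t_min": want}
        idx = np.arange(n)
        for v in cfg.vitals:
            g = np.full(n, np.nan)
            g[t] = stream[v].to_numpy(dtype=float)
            filled = np.interp(idx, idx[mask], g[mask])
            b = float(brow[f"{v}_base"])
            d = filled - b
            pos, neg = np.maximum(d, 0.0), np.maximum(-d, 0.0)
            for kind, arr in (("area_above", pos), ("area_below", neg)):
                if kind in cfg.kinds:
                    s = _rolling_sum(arr, w)
                    trap = s - 0.5 * (arr[:n - w + 1] + arr[w - 1:])
                    cols[f"{v}_{kind}"] = trap[want - w]
            if "mean_dev" in cfg.kinds:
                cols[f"{v}_mean_dev"] = _rolling_sum(d, w)[want - w] / w
            if "dev" in cfg.kinds:
                cols[f"{v}_dev"] = d[want - 1]
            if "value" in cfg.kinds:
                cols[f"{v}_value"] = filled[want - 1]
        df = pd.DataFrame(cols)
        df["sex"] = demo.loc[pid, "sex"]
        df["age_group"] = stratify_age(demo.loc[pid, "age"])
        a = assessments[(assessments["patient_id"] == pid)
                        & assessments["rass"].notna()]
        if len(a) == 0:
            continue
        at = a["t_min"].to_numpy()
        av = a["rass"].to_numpy(dtype=float)
        j = np.searchsorted(at, want)
        j_lo = np.clip(j - 1, 0, len(at) - 1)
        j_hi = np.clip(j, 0, len(at) - 1)
        nearest = np.where(np.abs(at[j_hi] - want) < np.abs(want - at[j_lo]),
                           j_hi, j_lo)
        df["rass"] = av[nearest].astype(np.int64)
        parts.append(df)
    cols = ["patient_id", "t_min"] + feature_columns(cfg)
    if not parts:
        return pd.DataFrame(columns=cols)
    return pd.concat(parts, ignore_index=True)[cols]
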