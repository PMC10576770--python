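"""Per-patient baseline establishment from the first stable hour.

The procedure scans candidate one-hour windows from ICU admission.  For
each window and each gated vital it applies, in order: a data-coverage
gate (>= 90% of minutes present, interior gaps linearly interpolated and
edges extended with the nearest value), a Friedman rank test across three
chronological 20-min segments (significant difference = unstable), and a
coefficient-of-variation gate (SD/mean above a per-vital threshold =
unstable).  On any failure the window start advances by 20 min.  The
baseline of each vital is the mean of the final five minutes of the first
window at which every vital passes all three gates, used thereafter as a
constant reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .config import VITALS, StabilityConfig

__all__ = ["PatientBaseline", "FriedmanResult", "interpolate_gaps",
           "friedman_stability", "cv_stability", "establish_baseline",
           "establish_baselines"]


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    stable: bool


@dataclass
class PatientBaseline:
    """Per-vital baseline values plus the stability-search audit trail."""

    patient_id: str
    values: dict = field(default_factory=dict)
    established_at: int | None = None
    attempts: list = field(default_factory=list)  # (window_start, reason)

    @property
    def established(self) -> bool:
        return self.established_at is not None


def interpolate_gaps(window: np.ndarray, coverage_threshold: float = 0.90,
                     strict: bool = False) -> np.ndarray | None:
    """Two-tailed linear completion of a fixed-length per-minute window.

    Interior gaps are linearly interpolated between the nearest present
    neighbours; leading/trailing gaps are filled by nearest-value
    extension.  Returns ``None`` when the present fraction fails the
    coverage gate (``>=`` threshold by default, ``>`` when ``strict``).
    """
    window = np.asarray(window, dtype=float)
    present = ~np.isnan(window)
    frac = present.mean() if window.size else 0.0
    ok = frac > coverage_threshold if strict else frac >= coverage_threshold
    if not ok or not present.any():
        return None
    if present.all():
        return window
    idx = np.arange(window.size)
    # np.interp extends edges with the nearest value by construction
    return np.interp(idx, idx[present], window[present])


def friedman_stability(series: np.ndarray, n_segments: int = 3,
                       alpha: float = 0.05) -> FriedmanResult:
    """Friedman rank test over contiguous chronological segments.

    The segments are the treatments and the within-segment minute
    positions are the blocks.  Tie-corrected chi-square statistic; a
    window with no rank variation at all (e.g. a constant series) has
    statistic 0 and p = 1.  ``stable`` is ``p >= alpha``.
    """
    series = np.asarray(series, dtype=float)
    if series.size % n_segments != 0:
        raise ValueError(
            f"series length {series.size} not divisible into "
            f"{n_segments} equal segments")
    m = series.size // n_segments
    k = n_segments
    # block i holds the i-th minute of every segment
    data = series.reshape(k, m).T               # shape (blocks, treatments)
    ranks = np.apply_along_axis(rankdata, 1, data)
    rank_sums = ranks.sum(axis=0)
    ssbn = float((rank_sums ** 2).sum())
    # tie correction identical to the standard (scipy) formulation
    ties = 0.0
    for row in data:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (m * k * (k * k - 1))
    if c <= 0.0:                                 # every block fully tied
        return FriedmanResult(0.0, 1.0, True)
    stat = (12.0 / (k * m * (k + 1)) * ssbn - 3.0 * m * (k + 1)) / c
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, k - 1))
    return FriedmanResult(float(stat), p, p >= alpha)


def cv_stability(series: np.ndarray, threshold: float) -> tuple:
    """Coefficient of variation (sample SD / mean); stable iff cv <= threshold."""
    series = np.asarray(series, dtype=float)
    mean = series.mean()
    if mean <= 0:
        raise ValueError("cv_stability requires a positive series mean")
    sd = series.std(ddof=1) if series.size > 1 else 0.0
    cv = float(sd / mean)
    return cv, cv <= threshold


def _full_grid(stream: pd.DataFrame) -> tuple:
    """(t0-aligned per-vital arrays with NaN gaps, last minute)."""
    t = stream["t_min"].to_numpy()
    n = int(t.max()) + 1 if len(t) else 0
    grids = {}
    for v in VITALS:
        g = np.full(n, np.nan)
        g[t] = stream[v].to_numpy(dtype=float)
        grids[v] = g
    return grids, n


def establish_baseline(stream: pd.DataFrame,
                       cfg: StabilityConfig | None = None) -> PatientBaseline:
    """Scan one (filtered) patient stream for its first stable hour.

    Returns a :class:`PatientBaseline`; ``established_at`` is ``None``
    when no window is accepted before the stream ends (including streams
    shorter than one window, for which the pain index is never defined).
    """
    cfg = cfg or StabilityConfig()
    pid = str(stream["patient_id"].iloc[0]) if len(stream) else "?"
    result = PatientBaseline(patient_id=pid)
    grids, n = _full_grid(stream)
    if n < cfg.window_min:
        result.attempts.append((0, "coverage"))
        return result

    s = 0
    while s + cfg.window_min <= n:
        reason = None
        completed = {}
        for v in cfg.vitals:
            window = grids[v][s:s + cfg.window_min]
            filled = interpolate_gaps(window, cfg.coverage_threshold)
            if filled is None:
                reason = "coverage"
                break
            fr = friedman_stability(filled, cfg.n_segments,
                                    cfg.friedman_alpha)
            if not fr.stable:
                reason = "friedman"
                break
            _, ok = cv_stability(filled, cfg.cv_thresholds[v])
            if not ok:
                reason = "cv"
                break
            completed[v] = filled
        if reason is None:
            anchor = cfg.anchor_span_min
            result.values = {v: float(completed[v][-anchor:].mean())
                             for v in cfg.vitals}
            for v in VITALS:       # ungated vitals anchored without gates
                if v not in result.values:
                    filled = interpolate_gaps(grids[v][s:s + cfg.window_min],
                                              cfg.coverage_threshold)
                    result.values[v] = (float(filled[-anchor:].mean())
                                        if filled is not None else np.nan)
            result.established_at = s + cfg.window_min
            result.attempts.append((s, "none"))
            return result
        result.attempts.append((s, reason))
        s += cfg.retry_delay_min
    return result


def establish_baselines(vitals: pd.DataFrame,
                        cfg: StabilityConfig | None = None) -> tuple:
    """Cohort-level baselines; returns ``(baselines_df, attempts_df)``.

    ``baselines_df`` has one row per patient with an established baseline
    (columns patient_id, established_at, <vital>_base ...); the attempts
    log covers every patient, established or not.
    """
    cfg = cfg or StabilityConfig()
    rows, attempts = [], []
    for pid, stream in vitals.groupby("patient_id", sort=True):
        pb = establish_baseline(stream, cfg)
        attempts += [{"patient_id": pid, "window_start": s, "reason": r}
                     for s, r in pb.attempts]
        if pb.established:
            row = {"patient_id": pid, "established_at": pb.established_at}
            row.update({f"{v}_base": pb.values.get(v, np.nan)
                        for v in VITALS})
            rows.append(row)
    cols = ["patient_id", "established_at"] + [f"{v}_base" for v in VITALS]
    baselines = pd.DataFrame(rows, columns=cols)
    attempts_df = pd.DataFrame(
        attempts, columns=["patient_id", "window_start", "reason"])
    return baselines, attempts_df
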