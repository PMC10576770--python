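"""Discrimination metrics and the fentanyl bolus treatment-response analysis.

AUROC here is the probability that a randomly chosen pain-positive
assessment outscores a randomly chosen negative one (ties counted 1/2),
computed by trapezoidal ROC integration.  The treatment-response analysis
aligns the per-minute pain index around each qualifying fentanyl bolus
(t0 = administration minute), splits boluses by observed CPOT improvement
(pre - post >= 1) and compares the pain index at t0 + 60 min within and
between groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["roc_auc", "youden_threshold", "confusion_at_threshold",
           "harmonic_mean_metrics", "classify_auroc",
           "group_by_cpot_improvement", "fentanyl_response_analysis",
           "ResponseResult", "plot_response"]


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (pairwise concordance with ties at 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def youden_threshold(scores, labels) -> float:
    """ROC threshold maximizing sensitivity + specificity - 1."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    finite = np.isfinite(thr)
    j = np.argmax(tpr[finite] - fpr[finite])
    return float(thr[finite][j])


def confusion_at_threshold(scores, labels, threshold: float | None = None
                           ) -> dict:
    """Sensitivity/specificity/PPV/NPV classifying score >= threshold.

    With no threshold given the Youden-optimal point is used.  PPV or NPV
    with an empty denominator is reported as NaN (absent).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if threshold is None:
        threshold = youden_threshold(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))

    def rate(a, b):
        return a / (a + b) if (a + b) > 0 else float("nan")

    return {"threshold": float(threshold),
            "sensitivity": rate(tp, fn), "specificity": rate(tn, fp),
            "ppv": rate(tp, fp), "npv": rate(tn, fn),
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def harmonic_mean_metrics(sensitivity: float, specificity: float) -> float:
    """Harmonic mean 2ab/(a+b) of two rates in (0, 1]."""
    a, b = float(sensitivity), float(specificity)
    if a <= 0 or b <= 0:
        raise ValueError("harmonic mean requires inputs in (0, 1]")
    if a > 1 or b > 1:
        raise ValueError("rates must be <= 1")
    return 2 * a * b / (a + b)


def classify_auroc(auroc: float) -> str:
    """Accuracy band: low (0.5-0.7), moderate (0.7-0.8), high (>= 0.8)."""
    a = float(auroc)
    if not 0.0 <= a <= 1.0:
        raise ValueError("auroc must be in [0, 1]")
    if a < 0.7:
        return "low"
    if a < 0.8:
        return "moderate"
    return "high"


def group_by_cpot_improvement(cpot_pre, cpot_post) -> str:
    """'improvement' iff the CPOT score decreased by at least 1."""
    pre, post = int(cpot_pre), int(cpot_post)
    for v in (pre, post):
        if not 0 <= v <= 8:
            raise ValueError(f"cpot {v} outside [0, 8]")
    return "improvement" if pre - post >= 1 else "non-improvement"


# ---------------------------------------------------------------------------
# treatment response


@dataclass
class ResponseResult:
    records: pd.DataFrame
    trajectories: pd.DataFrame
    stats: dict
    exclusions: pd.DataFrame = field(repr=False, default=None)


def _paired_tests(pre: np.ndarray, post: np.ndarray) -> dict:
    out = {"n": int(len(pre)), "mean_t0": float(np.mean(pre)) if len(pre)
           else float("nan"),
           "mean_t60": float(np.mean(post)) if len(post) else float("nan")}
    if len(pre) >= 2 and np.ptp(pre - post) > 0:
        out["t_p"] = float(stats.ttest_rel(pre, post).pvalue)
        # directional test of an analgesic response (index drops after bolus)
        out["t_p_drop"] = float(
            stats.ttest_rel(pre, post, alternative="greater").pvalue)
        try:
            w = stats.wilcoxon(pre, post)
            out["wilcoxon_p"] = float(w.pvalue)
        except ValueError:
            out["wilcoxon_p"] = float("nan")
    else:
        out["t_p"] = float("nan")
        out["t_p_drop"] = float("nan")
        out["wilcoxon_p"] = float("nan")
    return out


def fentanyl_response_analysis(painindex: pd.DataFrame, events: pd.DataFrame,
                               assessments: pd.DataFrame,
                               window_min: int = 60,
                               cpot_search_min: int = 120,
                               eval_offset_min: int = 60,
                               dose_range_ug=(25.0, 100.0)) -> ResponseResult:
    """Group bolus responses by CPOT improvement and compare pain indices.

    ``painindex`` holds per-minute scores (patient_id, t_min, pain_index
    in [0, 1]).  A bolus qualifies when its dose lies in the inclusion
    range, no other analgesic is charted within the trajectory window,
    a pre CPOT exists in [t0-search, t0], a post CPOT in (t0, t0+search],
    and the pain index is defined at t0 and t0+offset.  Excluded boluses
    are logged with reasons.
    """
    pi = {pid: grp.set_index("t_min")["pain_index"]
          for pid, grp in painindex.groupby("patient_id")}
    assess = {pid: grp for pid, grp in assessments.groupby("patient_id")}
    lo, hi = dose_range_ug

    records, excl, traj_rows = [], [], []
    for _, ev in events.iterrows():
        pid, t0 = ev["patient_id"], int(ev["t_min"])

        def drop(reason):
            excl.append({"patient_id": pid, "t_min": t0, "reason": reason})

        if ev["drug"] != "fentanyl":
            continue
        if not lo <= float(ev["dose_ug"]) <= hi:
            drop("dose_out_of_range")
            continue
        other = events[(events["patient_id"] == pid)
                       & (events["drug"] != "fentanyl")
                       & (events["t_min"] >= t0 - window_min)
                       & (events["t_min"] <= t0 + window_min)]
        if len(other):
            drop("other_analgesic")
            continue
        a = assess.get(pid)
        if a is None:
            drop("no_cpot_pre")
            continue
        a_cpot = a.dropna(subset=["cpot"])
        pre = a_cpot[(a_cpot["t_min"] >= t0 - cpot_search_min)
                     & (a_cpot["t_min"] <= t0)]
        post = a_cpot[(a_cpot["t_min"] > t0)
                      & (a_cpot["t_min"] <= t0 + cpot_search_min)]
        if len(pre) == 0:
            drop("no_cpot_pre")
            continue
        if len(post) == 0:
            drop("no_cpot_post")
            continue
        series = pi.get(pid)
        if series is None or t0 not in series.index \
                or t0 + eval_offset_min not in series.index:
            drop("pain_index_undefined")
            continue
        cpot_pre = int(pre.iloc[-1]["cpot"])
        cpot_post = int(post.iloc[0]["cpot"])
        group = group_by_cpot_improvement(cpot_pre, cpot_post)
        rec = {"patient_id": pid, "t_min": t0, "cpot_pre": cpot_pre,
               "cpot_post": cpot_post, "group": group,
               "pi_t0": float(series.loc[t0]),
               "pi_t60": float(series.loc[t0 + eval_offset_min])}
        records.append(rec)
        rel = np.arange(-window_min, window_min + 1)
        vals = series.reindex(t0 + rel)
        traj_rows.append(pd.DataFrame({
            "patient_id": pid, "t_min": t0, "group": group,
            "minute_rel": rel, "pain_index": vals.to_numpy()}))

    rec_cols = ["patient_id", "t_min", "cpot_pre", "cpot_post", "group",
                "pi_t0", "pi_t60"]
    records_df = pd.DataFrame(records, columns=rec_cols)
    excl_df = pd.DataFrame(excl, columns=["patient_id", "t_min", "reason"])

    if traj_rows:
        traj_long = pd.concat(traj_rows, ignore_index=True)
        trajectories = (traj_long.groupby(["group", "minute_rel"])
                        ["pain_index"]
                        .agg(median="median",
                             q25=lambda s: s.quantile(0.25),
                             q75=lambda s: s.quantile(0.75),
                             n="count")
                        .reset_index())
    else:
        trajectories = pd.DataFrame(
            columns=["group", "minute_rel", "median", "q25", "q75", "n"])

    st: dict = {"within": {}, "n_total": len(records_df)}
    for group in ("improvement", "non-improvement"):
        sub = records_df[records_df["group"] == group]
        st["within"][group] = _paired_tests(sub["pi_t0"].to_numpy(),
                                            sub["pi_t60"].to_numpy())
    gi = records_df[records_df["group"] == "improvement"]["pi_t60"]
    gn = records_df[records_df["group"] == "non-improvement"]["pi_t60"]
    if len(gi) >= 2 and len(gn) >= 2:
        st["between"] = {
            "welch_p": float(stats.ttest_ind(gi, gn, equal_var=False).pvalue),
            "mannwhitney_p": float(stats.mannwhitneyu(gi, gn).pvalue)}
    else:
        st["between"] = {"welch_p": float("nan"),
                         "mannwhitney_p": float("nan")}
    return ResponseResult(records_df, trajectories, st, excl_df)


def plot_response(trajectories: pd.DataFrame, path) -> None:
    """Median pain-index trajectories around the bolus, per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {"improvement": "--", "non-improvement": "-"}
    for group, sub in trajectories.groupby("group"):
        sub = sub.sort_values("minute_rel")
        ax.plot(sub["minute_rel"], 100 * sub["median"], styles.get(group, "-"),
                label=group)
        ax.fill_between(sub["minute_rel"], 100 * sub["q25"],
                        100 * sub["q75"], alpha=0.2)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("minutes from fentanyl bolus")
    ax.set_ylabel("pain index (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
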