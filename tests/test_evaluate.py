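"""ROC metrics, AUROC banding and the bolus-response analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from painindex.evaluate import (classify_auroc, confusion_at_threshold,
                                fentanyl_response_analysis,
                                group_by_cpot_improvement,
                                harmonic_mean_metrics, roc_auc,
                                youden_threshold)


def concordance_auroc(scores, labels):
    """Brute-force pairwise concordance with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum())
                 / (pos.size * neg.size / 1))


def test_perfect_separation_gives_unit_auroc():
    assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0


def test_four_point_hand_example():
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_random_scores_are_chance_level():
    rng = np.random.default_rng(0)
    scores = rng.random(10_000)
    labels = rng.integers(0, 2, 10_000)
    assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)


def test_auroc_matches_concordance_oracle_with_ties():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = int(rng.integers(10, 400))
        scores = np.round(rng.random(n), 2)     # rounding induces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            concordance_auroc(scores, labels), abs=1e-12)


def test_one_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.2], [1, 1])


@given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=50),
       st.lists(st.integers(0, 1), min_size=4, max_size=50))
def test_complement_symmetry_without_ties(scores, labels):
    n = min(len(scores), len(labels))
    scores, labels = np.array(scores[:n]), np.array(labels[:n])
    assume(len(np.unique(scores)) == n)
    assume(0 < labels.sum() < n)
    assert roc_auc(-scores, labels) == pytest.approx(
        1 - roc_auc(scores, labels), abs=1e-9)


def test_confusion_rates_from_constructed_table():
    # TP=3 FN=1 TN=8 FP=2
    scores = [0.9] * 3 + [0.1] + [0.2] * 8 + [0.8] * 2
    labels = [1] * 4 + [0] * 10
    m = confusion_at_threshold(scores, labels, threshold=0.5)
    assert m["sensitivity"] == pytest.approx(0.75)
    assert m["specificity"] == pytest.approx(0.8)
    assert m["ppv"] == pytest.approx(0.6)
    assert m["npv"] == pytest.approx(8 / 9)


def test_threshold_extremes():
    scores = [0.2, 0.4, 0.6, 0.8]
    labels = [0, 0, 1, 1]
    lo = confusion_at_threshold(scores, labels, threshold=0.0)
    assert lo["sensitivity"] == 1.0 and lo["specificity"] == 0.0
    hi = confusion_at_threshold(scores, labels, threshold=1.0 + 1e-9)
    assert hi["sensitivity"] == 0.0 and hi["specificity"] == 1.0


def test_youden_threshold_maximizes_j():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 500)
    scores = labels * 0.5 + rng.random(500) * 0.6
    thr = youden_threshold(scores, labels)
    m = confusion_at_threshold(scores, labels, thr)
    j_best = m["sensitivity"] + m["specificity"] - 1
    for t in np.linspace(0.01, 0.99, 50):
        mt = confusion_at_threshold(scores, labels, t)
        assert mt["sensitivity"] + mt["specificity"] - 1 <= j_best + 1e-9


def test_harmonic_mean_examples():
    assert harmonic_mean_metrics(0.8, 0.8) == pytest.approx(0.8)
    # reference operating point: sens 73.0%, spec 94.5%
    assert harmonic_mean_metrics(0.730, 0.945) == pytest.approx(
        2 * 0.730 * 0.945 / (0.730 + 0.945))
    with pytest.raises(ValueError):
        harmonic_mean_metrics(0.0, 0.5)


@given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
def test_harmonic_mean_below_arithmetic(a, b):
    h = harmonic_mean_metrics(a, b)
    assert h <= np.sqrt(a * b) + 1e-12 <= (a + b) / 2 + 1e-12


@pytest.mark.parametrize("auroc,band", [
    (0.5, "low"), (0.65, "low"), (0.7, "moderate"), (0.75, "moderate"),
    (0.8, "high"), (0.903, "high"), (1.0, "high")])
def test_auroc_banding(auroc, band):
    assert classify_auroc(auroc) == band


@pytest.mark.parametrize("pre,post,group", [
    (4, 2, "improvement"), (3, 2, "improvement"), (2, 2, "non-improvement"),
    (2, 3, "non-improvement"), (8, 0, "improvement")])
def test_cpot_improvement_grouping(pre, post, group):
    assert group_by_cpot_improvement(pre, post) == group


# ---------------------------------------------------------------------------
# response analysis plumbing


def _painindex(pid, t0, values):
    rel = np.arange(-60, 61)
    return pd.DataFrame({"patient_id": pid, "t_min": t0 + rel,
                         "pain_index": values})


def test_single_bolus_without_improvement():
    t0 = 500
    pi = _painindex("P1", t0, np.full(121, 0.5))
    events = pd.DataFrame([{"patient_id": "P1", "t_min": t0,
                            "drug": "fentanyl", "dose_ug": 50.0}])
    assessments = pd.DataFrame([
        {"patient_id": "P1", "t_min": t0 - 10, "cpot": 5, "rass": 0,
         "cam_icu": np.nan},
        {"patient_id": "P1", "t_min": t0 + 60, "cpot": 5, "rass": 0,
         "cam_icu": np.nan}])
    res = fentanyl_response_analysis(pi, events, assessments)
    assert len(res.records) == 1
    assert res.records.iloc[0]["group"] == "non-improvement"
    assert res.records.iloc[0]["pi_t60"] == pytest.approx(0.5)


def test_bolus_exclusion_reasons_logged():
    t0 = 500
    pi = _painindex("P1", t0, np.full(121, 0.4))
    events = pd.DataFrame([
        {"patient_id": "P1", "t_min": t0, "drug": "fentanyl",
         "dose_ug": 500.0},                              # dose out of range
        {"patient_id": "P2", "t_min": t0, "drug": "fentanyl",
         "dose_ug": 50.0}])                              # no pain index
    assessments = pd.DataFrame([
        {"patient_id": "P2", "t_min": t0 - 5, "cpot": 4, "rass": 0,
         "cam_icu": np.nan},
        {"patient_id": "P2", "t_min": t0 + 30, "cpot": 4, "rass": 0,
         "cam_icu": np.nan}])
    res = fentanyl_response_analysis(pi, events, assessments)
    assert len(res.records) == 0
    assert set(res.exclusions["reason"]) == {"dose_out_of_range",
                                             "pain_index_undefined"}


def test_other_analgesic_period_excluded():
    t0 = 500
    pi = _painindex("P1", t0, np.full(121, 0.4))
    events = pd.DataFrame([
        {"patient_id": "P1", "t_min": t0, "drug": "fentanyl",
         "dose_ug": 50.0},
        {"patient_id": "P1", "t_min": t0 + 20, "drug": "ketamine",
         "dose_ug": 30.0}])
    assessments = pd.DataFrame([
        {"patient_id": "P1", "t_min": t0 - 5, "cpot": 4, "rass": 0,
         "cam_icu": np.nan},
        {"patient_id": "P1", "t_min": t0 + 60, "cpot": 2, "rass": 0,
         "cam_icu": np.nan}])
    res = fentanyl_response_analysis(pi, events, assessments)
    assert len(res.records) == 0
    assert "other_analgesic" in set(res.exclusions["reason"])


def test_trajectories_invariant_to_patient_order():
    rng = np.random.default_rng(3)
    parts, events, assess = [], [], []
    for i, pid in enumerate(["P1", "P2", "P3"]):
        t0 = 300 + 40 * i
        parts.append(_painindex(pid, t0, rng.random(121)))
        events.append({"patient_id": pid, "t_min": t0, "drug": "fentanyl",
                       "dose_ug": 50.0})
        assess += [{"patient_id": pid, "t_min": t0 - 1, "cpot": 4,
                    "rass": 0, "cam_icu": np.nan},
                   {"patient_id": pid, "t_min": t0 + 60, "cpot": 2,
                    "rass": 0, "cam_icu": np.nan}]
    pi = pd.concat(parts, ignore_index=True)
    ev = pd.DataFrame(events)
    aa = pd.DataFrame(assess)
    fwd = fentanyl_response_analysis(pi, ev, aa)
    rev = fentanyl_response_analysis(
        pi.iloc[::-1].reset_index(drop=True),
        ev.iloc[::-1].reset_index(drop=True), aa)
    pd.testing.assert_frame_equal(
        fwd.trajectories.reset_index(drop=True),
        rev.trajectories.reset_index(drop=True))
    # grouping exhaustive and exclusive
    assert (fwd.records["group"].isin(["improvement", "non-improvement"])
            .all())
    assert len(fwd.records) == len(ev)
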