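"""Baseline establishment: interpolation, Friedman and CV gates, retry scan."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, friedmanchisquare

from painindex.baseline import (cv_stability, establish_baseline,
                                friedman_stability, interpolate_gaps)
from painindex.config import StabilityConfig


def brute_force_friedman(data):
    """Independent route: explicit ranks, tie-corrected chi-square.

    ``data`` is (blocks, treatments); ranks computed per block by direct
    pairwise counting rather than a library call.
    """
    n, k = data.shape
    ranks = np.empty_like(data, dtype=float)
    for i in range(n):
        row = data[i]
        for j in range(k):
            less = np.sum(row < row[j])
            equal = np.sum(row == row[j])
            ranks[i, j] = less + (equal + 1) / 2.0
    rank_sums = ranks.sum(axis=0)
    ties = 0.0
    for i in range(n):
        _, counts = np.unique(data[i], return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return (12.0 / (k * n * (k + 1)) * (rank_sums ** 2).sum()
            - 3.0 * n * (k + 1)) / c


# ---------------------------------------------------------------------------
# interpolation


def test_sparse_window_fails_coverage_gate():
    w = np.full(60, np.nan)
    w[0], w[59] = 100.0, 160.0
    assert interpolate_gaps(w, 0.90) is None


def test_interior_gap_filled_linearly():
    w = np.full(60, np.nan)
    w[:10] = 80.0
    w[9] = 80.0
    w[12:] = 86.0
    w[9], w[12] = 80.0, 86.0
    w[:9] = 80.0
    filled = interpolate_gaps(w, 0.90)
    assert filled[10] == pytest.approx(82.0)
    assert filled[11] == pytest.approx(84.0)


def test_fully_present_window_returned_unchanged():
    w = np.linspace(60, 90, 60)
    assert np.array_equal(interpolate_gaps(w, 0.90), w)


def test_edge_gaps_filled_by_nearest_value():
    w = np.full(60, np.nan)
    w[2:58] = 100.0
    filled = interpolate_gaps(w, 0.90)
    assert filled[0] == filled[1] == 100.0
    assert filled[58] == filled[59] == 100.0


def test_coverage_boundary_inclusive_vs_strict():
    w = np.full(60, np.nan)
    w[:54] = 100.0                      # exactly 0.90 present
    assert interpolate_gaps(w, 0.90) is not None
    assert interpolate_gaps(w, 0.90, strict=True) is None
    w[54] = 100.0                       # 55/60 > 0.90
    assert interpolate_gaps(w, 0.90, strict=True) is not None


# ---------------------------------------------------------------------------
# stability gates


def test_identical_segments_are_stable_with_zero_statistic():
    series = np.tile(np.arange(20.0), 3)
    r = friedman_stability(series)
    assert r.statistic == 0.0 and r.p_value == 1.0 and r.stable


def test_hand_computed_friedman_statistic():
    # 5 blocks x 3 ordered treatments: rank sums 5, 10, 15 -> statistic 10
    series = np.array([1, 2, 3, 4, 5, 2, 3, 4, 5, 6, 3, 4, 5, 6, 7],
                      dtype=float)
    r = friedman_stability(series, n_segments=3, alpha=0.05)
    assert r.statistic == pytest.approx(10.0)
    assert r.p_value == pytest.approx(chi2.sf(10.0, 2))
    assert not r.stable


def test_length_not_divisible_raises():
    with pytest.raises(ValueError, match="divisible"):
        friedman_stability(np.arange(61.0))


def test_friedman_matches_bruteforce_and_scipy_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(200):
        series = rng.standard_normal(60)
        mine = friedman_stability(series).statistic
        data = series.reshape(3, 20).T
        assert mine == pytest.approx(brute_force_friedman(data), abs=1e-10)
        ref = friedmanchisquare(*[data[:, j] for j in range(3)]).statistic
        assert mine == pytest.approx(ref, abs=1e-10)


def test_friedman_bruteforce_agrees_on_tied_integer_matrices():
    rng = np.random.default_rng(1)
    for _ in range(100):
        series = rng.integers(0, 4, 60).astype(float)
        mine = friedman_stability(series).statistic
        data = series.reshape(3, 20).T
        assert mine == pytest.approx(brute_force_friedman(data), abs=1e-10)


def test_cv_examples_and_inclusive_boundary():
    assert cv_stability(np.full(30, 80.0), 0.1) == (0.0, True)
    cv, stable = cv_stability(np.array([90.0, 100.0, 110.0]), 0.1)
    assert cv == pytest.approx(0.1)
    assert stable                       # boundary counts as stable
    with pytest.raises(ValueError, match="positive"):
        cv_stability(np.array([-1.0, 1.0]), 0.1)


# ---------------------------------------------------------------------------
# establishment scan


def _stream(values_by_vital, pid="P1", n=140):
    if values_by_vital:
        n = len(next(iter(values_by_vital.values())))
    df = pd.DataFrame({"patient_id": pid, "t_min": np.arange(n)})
    base = {"hr": 80.0, "sbp": 120.0, "mbp": 80.0, "dbp": 60.0,
            "rr": 16.0, "spo2": 97.0}
    for v, b in base.items():
        df[v] = values_by_vital.get(v, np.full(n, b))
    return df


def test_constant_stream_establishes_immediately():
    pb = establish_baseline(_stream({}, "P1"),
                            StabilityConfig())
    assert pb.established_at == 60
    assert pb.values["hr"] == pytest.approx(80.0)
    assert pb.attempts == [(0, "none")]


def test_short_stream_never_establishes():
    df = _stream({}).iloc[:59]
    pb = establish_baseline(df)
    assert not pb.established
    assert pb.attempts[0][1] == "coverage"


def test_retry_after_cv_failure_advances_20_minutes():
    # minutes 0-19 alternate +/-40 around 100 (block-symmetric, so the
    # Friedman ranks cancel and only the CV gate trips); stable afterwards
    hr = np.full(140, 100.0)
    hr[:20] += 40.0 * np.where(np.arange(20) % 2 == 0, 1.0, -1.0)
    pb = establish_baseline(_stream({"hr": hr}))
    assert pb.attempts[0] == (0, "cv")
    assert pb.established_at == 80
    assert pb.values["hr"] == pytest.approx(100.0)


def test_coverage_failure_reason_logged_then_recovers():
    df = _stream({})
    df = df[(df["t_min"] >= 40) | (df["t_min"] % 3 == 0)]  # thin first 40
    pb = establish_baseline(df.reset_index(drop=True))
    assert pb.established
    assert any(r == "coverage" for _, r in pb.attempts)


def test_drifty_admission_recovers_true_baselines(medium_cohort):
    """Parameter recovery at cohort level (loose 3-sigma screen)."""
    from painindex.baseline import establish_baselines
    from painindex.preprocess import apply_noise_filter

    kept, _ = apply_noise_filter(medium_cohort.vitals)
    bl, attempts = establish_baselines(kept)
    assert len(bl) >= 190                    # nearly all patients establish
    gt = medium_cohort.ground_truth.baselines.set_index("patient_id")
    m = bl.set_index("patient_id")
    cfg = medium_cohort.config
    for v in ("hr", "sbp", "dbp", "rr"):
        err = m[f"{v}_base"] - gt.loc[m.index, v]
        tol3 = 3 * cfg.noise_sd[v] / np.sqrt(5)
        assert (err.abs() <= tol3).mean() >= 0.95
    assert (m["established_at"] >= 60).all()
    assert set(attempts["reason"]) <= {"coverage", "friedman", "cv", "none"}


def test_establishment_deterministic(medium_cohort):
    from painindex.baseline import establish_baselines
    from painindex.preprocess import apply_noise_filter

    kept, _ = apply_noise_filter(medium_cohort.vitals)
    one = establish_baselines(kept)[0]
    two = establish_baselines(kept)[0]
    pd.testing.assert_frame_equal(one, two)
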