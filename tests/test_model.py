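"""ADASYN oversampling and the random-forest model/results objects."""

import numpy as np
import pandas as pd
import pytest

from painindex.config import ModelConfig
from painindex.features import feature_columns
from painindex.model import (PainIndexModel, grid_search_train,
                             oversample_positives, repeated_cv_auroc)

CONT = [c for c in feature_columns() if c not in ("sex", "age_group", "rass")]


def test_adasyn_balances_rare_positive_class(feature_factory):
    rng = np.random.default_rng(0)
    df = feature_factory(3000, 0.033, rng)
    f2, y2, synth = oversample_positives(df, df["label"].to_numpy(), seed=0)
    assert 0.4 <= y2.mean() <= 0.6
    # originals preserved verbatim, synthetic rows appended after them
    pd.testing.assert_frame_equal(f2.iloc[:len(df)].reset_index(drop=True),
                                  df.reset_index(drop=True))
    assert synth[:len(df)].sum() == 0 and synth[len(df):].all()


def test_adasyn_balanced_input_nearly_unchanged(feature_factory):
    rng = np.random.default_rng(1)
    df = feature_factory(1000, 0.5, rng)
    f2, _, _ = oversample_positives(df, df["label"].to_numpy(), seed=0)
    assert len(f2) <= 1.05 * len(df)


def test_adasyn_synthetic_points_lie_between_real_positives(feature_factory):
    rng = np.random.default_rng(2)
    df = feature_factory(800, 0.05, rng)
    y = df["label"].to_numpy()
    f2, y2, synth = oversample_positives(df, y, seed=0)
    pos = df.loc[y == 1, CONT].to_numpy()

    def on_some_segment(x):
        for i in range(len(pos)):
            rel = x - pos[i]
            if np.allclose(rel, 0, atol=1e-8):
                return True          # degenerate lambda = 0
            for j in range(len(pos)):
                d = pos[j] - pos[i]
                nz = np.abs(d) > 1e-12
                if not nz.any():
                    continue
                lam = rel[nz][0] / d[nz][0]
                if 0 <= lam <= 1 and np.allclose(rel, lam * d, atol=1e-8):
                    return True
        return False

    for x in f2.loc[synth, CONT].head(30).to_numpy(dtype=float):
        assert on_some_segment(x)
    # categorical fields of synthetic rows are copied, not interpolated
    assert set(f2.loc[synth, "sex"]) <= {"male", "female"}
    assert set(f2.loc[synth, "age_group"]) <= {"20-44", "45-64", "65+"}


def test_adasyn_one_class_set_rejected(feature_factory):
    rng = np.random.default_rng(3)
    df = feature_factory(100, 0.0, rng)
    with pytest.raises(ValueError, match="one-class"):
        oversample_positives(df, df["label"].to_numpy(), seed=0)


def test_single_cell_grid_selects_reference_hyperparameters(feature_factory):
    rng = np.random.default_rng(4)
    df = feature_factory(400, 0.2, rng)
    res = grid_search_train(df, ModelConfig.reference_point(seed=0))
    assert res.params == {"n_estimators": 17, "max_depth": 14}


def test_grid_search_prefers_separating_depth(feature_factory):
    rng = np.random.default_rng(5)
    df = feature_factory(600, 0.25, rng, shift=3.0)
    cfg = ModelConfig(n_estimators_grid=(17,), max_depth_grid=(2, 14),
                      cv_folds=4, seed=0)
    res = PainIndexModel(df, cfg).fit()
    assert res.params["max_depth"] in (2, 14)
    assert len(res.grid_table) == 2
    assert res.grid_table["cv_auroc"].notna().all()


def test_separable_training_data_reaches_perfect_training_auroc(
        feature_factory):
    from painindex.evaluate import roc_auc
    rng = np.random.default_rng(6)
    df = feature_factory(500, 0.3, rng, shift=30.0)
    res = grid_search_train(df, ModelConfig.reference_point(seed=0))
    assert roc_auc(res.predict(df), df["label"]) == 1.0


def test_permuted_labels_give_chance_level_auroc(feature_factory):
    rng = np.random.default_rng(7)
    df = feature_factory(2500, 0.1, rng)
    df["label"] = rng.permutation(df["label"].to_numpy())
    cv = repeated_cv_auroc(df, ModelConfig.reference_point(seed=0, cv_folds=5),
                           repeats=2)
    assert 0.45 <= cv.mean <= 0.55


def test_cross_validation_deterministic_and_probability_bounded(
        feature_factory):
    rng = np.random.default_rng(8)
    df = feature_factory(800, 0.15, rng)
    cfg = ModelConfig.reference_point(seed=11, cv_folds=5)
    cv1 = repeated_cv_auroc(df, cfg, repeats=3)
    cv2 = repeated_cv_auroc(df, cfg, repeats=3)
    assert cv1.per_repeat == cv2.per_repeat
    assert cv1.sd is not None
    res = PainIndexModel(df, cfg).fit()
    p = res.predict(df)
    assert ((0 <= p) & (p <= 1)).all()


def test_single_repeat_reports_absent_sd(feature_factory):
    rng = np.random.default_rng(9)
    df = feature_factory(500, 0.2, rng)
    cv = repeated_cv_auroc(df, ModelConfig.reference_point(seed=0, cv_folds=4),
                           repeats=1)
    assert cv.sd is None and len(cv.per_repeat) == 1


def test_no_synthetic_row_reaches_validation_folds(feature_factory):
    rng = np.random.default_rng(10)
    df = feature_factory(1200, 0.08, rng)
    cv = repeated_cv_auroc(df, ModelConfig.reference_point(seed=0, cv_folds=5),
                           repeats=2)
    audits = [a for repeat in cv.audits for a in repeat]
    assert audits, "cross-validation produced no fold audits"
    for a in audits:
        assert a.validation_all_original
        assert a.n_train_synthetic > 0      # oversampling did happen
        assert a.n_validation > 0


def test_patient_level_split_keeps_patients_whole(feature_factory):
    from painindex.model import _fold_assignment
    rng = np.random.default_rng(11)
    groups = np.repeat([f"P{i}" for i in range(40)], 5)
    folds = _fold_assignment(groups, 10, rng)
    df = pd.DataFrame({"g": groups, "f": folds})
    assert (df.groupby("g")["f"].nunique() == 1).all()
    assert len(np.unique(folds)) == 10


def test_schema_mismatch_rejected(feature_factory):
    rng = np.random.default_rng(12)
    df = feature_factory(300, 0.3, rng)
    res = grid_search_train(df, ModelConfig.reference_point(seed=0))
    bad = df[["patient_id", "t_min"]
             + [c for c in df.columns if c.startswith(("hr_", "sbp_"))]
             + ["sex", "age_group", "rass"]]
    with pytest.raises(ValueError, match="missing columns|schema"):
        res.predict(bad)


def test_one_class_training_rejected(feature_factory):
    rng = np.random.default_rng(13)
    df = feature_factory(200, 0.0, rng)
    with pytest.raises(ValueError, match="single class"):
        PainIndexModel(df, ModelConfig.reference_point()).fit()


def test_results_summary_and_round_trip(tmp_path, feature_factory):
    from painindex.model import PainIndexResults
    rng = np.random.default_rng(14)
    df = feature_factory(400, 0.25, rng)
    res = grid_search_train(df, ModelConfig.reference_point(seed=0))
    text = res.summary()
    assert "n_estimators:        17" in text and "max_depth:           14" in text
    path = tmp_path / "model.joblib"
    res.save(path)
    back = PainIndexResults.load(path)
    x = df.drop(columns=["label"])
    assert np.allclose(back.predict(x), res.predict(x))
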