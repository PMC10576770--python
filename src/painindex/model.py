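"""Class-balanced random-forest pain-index model.

:class:`PainIndexModel` is built from a per-assessment feature table and
``fit()`` returns a :class:`PainIndexResults` carrying the fitted forest,
the selected hyperparameters, cross-validation diagnostics and a
``summary()`` table — the usual model/results split.

The minority (pain-positive) class is oversampled with ADASYN (adaptive
synthetic sampling: each minority point is assigned a synthesis budget
proportional to the fraction of majority points among its nearest
neighbours, and synthetic points are drawn on segments between minority
neighbours).  Oversampling happens strictly inside training folds; no
synthetic row is ever scored in a validation fold, and every CV run
records a structural audit of that fact.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from .config import FeatureConfig, ModelConfig
from .features import feature_columns

__all__ = ["PainIndexModel", "PainIndexResults", "CrossValidationResult",
           "oversample_positives", "grid_search_train", "predict_pain_index",
           "repeated_cv_auroc", "encode_design"]

_CATEGORICAL = ("sex", "age_group", "rass")


def encode_design(features: pd.DataFrame, cfg: FeatureConfig | None = None
                  ) -> tuple:
    """Numeric design matrix from a feature table.

    Returns ``(X, names, cont_idx)`` where ``cont_idx`` indexes the
    continuous vital-deviation columns (the subspace ADASYN operates in);
    sex/age_group are one-hot encoded and RASS is kept ordinal.
    """
    cfg = cfg or FeatureConfig()
    cont_cols = [c for c in feature_columns(cfg) if c not in _CATEGORICAL]
    missing = [c for c in cont_cols + list(_CATEGORICAL)
               if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    X_cont = features[cont_cols].to_numpy(dtype=float)
    sex_male = (features["sex"] == "male").to_numpy(dtype=float)
    age_45_64 = (features["age_group"] == "45-64").to_numpy(dtype=float)
    age_65p = (features["age_group"] == "65+").to_numpy(dtype=float)
    rass = features["rass"].to_numpy(dtype=float)
    X = np.column_stack([X_cont, sex_male, age_45_64, age_65p, rass])
    names = cont_cols + ["sex_male", "age_45_64", "age_65_plus", "rass"]
    return X, names, np.arange(len(cont_cols))


def schema_hash(names) -> str:
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# ADASYN


def _adasyn_plan(X_cont: np.ndarray, y: np.ndarray,
                 rng: np.random.Generator, k: int, beta: float) -> tuple:
    """(seed_idx, neighbour_idx, lam) describing each synthetic point.

    Synthetic point j is ``X[seed] + lam * (X[neighbour] - X[seed])`` in
    the continuous subspace; both endpoints are real minority rows.
    """
    y = np.asarray(y, dtype=int)
    min_idx = np.flatnonzero(y == 1)
    maj_idx = np.flatnonzero(y == 0)
    if min_idx.size == 0:
        raise ValueError("cannot balance a one-class set: no positive examples")
    n_synth = int(round(beta * (maj_idx.size - min_idx.size)))
    empty = (np.array([], dtype=int), np.array([], dtype=int),
             np.array([], dtype=float))
    if n_synth <= 0:
        return empty

    sd = X_cont.std(axis=0)
    sd[sd == 0] = 1.0
    Z = X_cont / sd
    k_all = min(k, len(Z) - 1)
    nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(Z)
    _, nbrs = nn_all.kneighbors(Z[min_idx])
    nbrs = nbrs[:, 1:]                       # drop self
    r = (y[nbrs] == 0).mean(axis=1)
    if r.sum() == 0:
        r = np.ones_like(r)                  # uniform budget fallback
    g = np.rint(r / r.sum() * n_synth).astype(int)

    if min_idx.size == 1:
        seeds = np.repeat(min_idx, g.sum())  # degenerate: duplicate the point
        return seeds, seeds.copy(), np.zeros(seeds.size)

    k_min = min(k, min_idx.size - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(Z[min_idx])
    _, min_nbrs = nn_min.kneighbors(Z[min_idx])
    min_nbrs = min_idx[min_nbrs[:, 1:]]      # map back to global indices

    seeds = np.repeat(min_idx, g)
    pick = rng.integers(0, k_min, size=seeds.size)
    owner = np.repeat(np.arange(min_idx.size), g)
    neighbours = min_nbrs[owner, pick]
    lam = rng.random(seeds.size)
    return seeds, neighbours, lam


def _adasyn_arrays(X: np.ndarray, y: np.ndarray, cont_idx: np.ndarray,
                   rng: np.random.Generator, k: int, beta: float) -> tuple:
    """Oversample an encoded matrix; returns (X2, y2, synth_mask)."""
    seeds, nbrs, lam = _adasyn_plan(X[:, cont_idx], y, rng, k, beta)
    if seeds.size == 0:
        return X, np.asarray(y, dtype=int), np.zeros(len(X), dtype=bool)
    synth = X[seeds].copy()                  # categorical fields copied
    synth[:, cont_idx] = (X[seeds][:, cont_idx]
                          + lam[:, None] * (X[nbrs][:, cont_idx]
                                            - X[seeds][:, cont_idx]))
    X2 = np.vstack([X, synth])
    y2 = np.concatenate([np.asarray(y, dtype=int), np.ones(seeds.size, int)])
    mask = np.concatenate([np.zeros(len(X), bool), np.ones(seeds.size, bool)])
    return X2, y2, mask


def oversample_positives(features: pd.DataFrame, labels, seed,
                         cfg: ModelConfig | None = None,
                         feature_cfg: FeatureConfig | None = None) -> tuple:
    """ADASYN oversampling of the positive class of a feature table.

    Returns ``(features2, labels2, synth_mask)``: original rows first and
    unmodified, synthetic rows appended with interpolated continuous
    features and categorical fields copied from their seed row.
    """
    cfg = cfg or ModelConfig()
    feature_cfg = feature_cfg or FeatureConfig()
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    cont_cols = [c for c in feature_columns(feature_cfg)
                 if c not in _CATEGORICAL]
    X_cont = features[cont_cols].to_numpy(dtype=float)
    seeds, nbrs, lam = _adasyn_plan(X_cont, y, rng, cfg.adasyn_k,
                                    cfg.adasyn_beta)
    if seeds.size == 0:
        return (features.reset_index(drop=True), y,
                np.zeros(len(features), bool))
    synth = features.iloc[seeds].copy()
    synth[cont_cols] = (X_cont[seeds]
                        + lam[:, None] * (X_cont[nbrs] - X_cont[seeds]))
    out = pd.concat([features, synth], ignore_index=True)
    y2 = np.concatenate([y, np.ones(seeds.size, int)])
    mask = np.concatenate([np.zeros(len(features), bool),
                           np.ones(seeds.size, bool)])
    return out, y2, mask


# ---------------------------------------------------------------------------
# cross-validation machinery


def _fold_assignment(groups: np.ndarray, k: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold id per row, splitting whole groups (patients) across folds."""
    uniq = np.unique(groups)
    order = rng.permutation(len(uniq))
    fold_of_group = np.empty(len(uniq), dtype=int)
    for f, chunk in enumerate(np.array_split(np.arange(len(uniq)), k)):
        fold_of_group[order[chunk]] = f
    lookup = dict(zip(uniq, fold_of_group))
    return np.array([lookup[g] for g in groups])


@dataclass
class FoldAudit:
    """Structural record that no synthetic row reached a validation fold."""

    fold: int
    n_train_original: int
    n_train_synthetic: int
    n_validation: int
    validation_all_original: bool


def _cv_pooled_auroc(X, y, groups, params, cfg: ModelConfig,
                     rng: np.random.Generator, cont_idx) -> tuple:
    """One k-fold pass; returns (auroc, audits) with pooled OOF scores."""
    folds = (_fold_assignment(groups, cfg.cv_folds, rng)
             if cfg.split_unit == "patient"
             else _fold_assignment(np.arange(len(y)), cfg.cv_folds, rng))
    oof_score = np.full(len(y), np.nan)
    audits = []
    n_original = len(y)
    for f in range(cfg.cv_folds):
        val = folds == f
        train = ~val
        if len(np.unique(y[val])) < 2 or len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f} has a single class; skipped")
            continue
        Xt, yt = X[train], y[train]
        n_synth = 0
        if cfg.oversample:
            Xt, yt, synth = _adasyn_arrays(
                Xt, yt, cont_idx, rng, cfg.adasyn_k, cfg.adasyn_beta)
            n_synth = int(synth.sum())
        clf = RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=int(rng.integers(0, 2 ** 31)))
        clf.fit(Xt, yt)
        oof_score[val] = clf.predict_proba(X[val])[:, 1]
        audits.append(FoldAudit(
            fold=f,
            n_train_original=int(train.sum()),
            n_train_synthetic=n_synth,
            n_validation=int(val.sum()),
            # validation rows index the original matrix, which never holds
            # synthetic rows; oversampling only ever extends the train copy
            validation_all_original=bool(
                val.size == n_original
                and Xt.shape[0] == int(train.sum()) + n_synth)))
    scored = ~np.isnan(oof_score)
    if scored.sum() == 0 or len(np.unique(y[scored])) < 2:
        raise ValueError("all cross-validation folds were degenerate")
    return float(roc_auc_score(y[scored], oof_score[scored])), audits, oof_score


@dataclass
class CrossValidationResult:
    mean: float
    sd: float | None
    per_repeat: list
    audits: list = field(repr=False, default_factory=list)

    def summary(self) -> str:
        sd = "n/a" if self.sd is None else f"{self.sd:.3f}"
        return (f"cross-validated AUROC {self.mean:.3f} +/- {sd} over "
                f"{len(self.per_repeat)} repeats")


@dataclass
class PainIndexResults:
    """Fitted pain-index forest with its selection diagnostics."""

    estimator: RandomForestClassifier = field(repr=False)
    params: dict
    feature_names: list
    schema: str
    grid_table: pd.DataFrame = field(repr=False)
    oversample_ratio: float
    config: ModelConfig = field(repr=False)
    feature_config: FeatureConfig = field(repr=False)
    n_obs: int = 0
    cv: CrossValidationResult | None = None

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Pain index P(CPOT >= 3) in [0, 1] for each feature row."""
        X, names, _ = encode_design(features, self.feature_config)
        if schema_hash(names) != self.schema:
            raise ValueError("feature schema mismatch: the supplied table "
                             "was not built with this model's feature config")
        return self.estimator.predict_proba(X)[:, 1]

    def predict_series(self, features: pd.DataFrame) -> pd.DataFrame:
        out = features[["patient_id", "t_min"]].copy()
        out["pain_index"] = self.predict(features)
        return out

    def summary(self) -> str:
        lines = [
            "Pain index model (class-balanced random forest)",
            "=" * 48,
            f"observations:        {self.n_obs}",
            f"features:            {len(self.feature_names)}",
            f"n_estimators:        {self.params['n_estimators']}",
            f"max_depth:           {self.params['max_depth']}",
            f"oversample ratio:    {self.oversample_ratio:.2f}x "
            "(ADASYN, training data only)",
        ]
        if self.cv is not None:
            lines.append(f"cv AUROC:            {self.cv.mean:.3f}"
                         + ("" if self.cv.sd is None
                            else f" +/- {self.cv.sd:.3f}"))
        imp = sorted(zip(self.feature_names,
                         self.estimator.feature_importances_),
                     key=lambda p: -p[1])[:5]
        lines.append("top importances:     "
                     + ", ".join(f"{n}={v:.3f}" for n, v in imp))
        return "\n".join(lines)

    def save(self, path) -> None:
        joblib.dump({"estimator": self.estimator, "params": self.params,
                     "feature_names": self.feature_names,
                     "schema": self.schema, "config": self.config,
                     "feature_config": self.feature_config,
                     "n_obs": self.n_obs}, path)

    @classmethod
    def load(cls, path) -> "PainIndexResults":
        d = joblib.load(path)
        return cls(estimator=d["estimator"], params=d["params"],
                   feature_names=d["feature_names"], schema=d["schema"],
                   grid_table=pd.DataFrame(), oversample_ratio=float("nan"),
                   config=d["config"], feature_config=d["feature_config"],
                   n_obs=d["n_obs"])


class PainIndexModel:
    """Random-forest model of P(CPOT >= 3) built from a feature table.

    Parameters
    ----------
    features : DataFrame with the columns of
        :func:`painindex.features.feature_columns` plus ``label`` and
        ``patient_id``.
    config : ModelConfig, optional
    """

    def __init__(self, features: pd.DataFrame,
                 config: ModelConfig | None = None,
                 feature_config: FeatureConfig | None = None):
        if "label" not in features.columns:
            raise ValueError("feature table must carry a 'label' column")
        self.features = features.reset_index(drop=True)
        self.config = config or ModelConfig()
        self.feature_config = feature_config or FeatureConfig()
        self.X, self.feature_names, self.cont_idx = encode_design(
            self.features, self.feature_config)
        self.y = self.features["label"].to_numpy(dtype=int)
        self.groups = self.features["patient_id"].to_numpy()

    @classmethod
    def from_tables(cls, vitals, baselines, assessments, demographics,
                    config=None, feature_config=None) -> "PainIndexModel":
        from .features import build_feature_table
        feats, _ = build_feature_table(vitals, baselines, assessments,
                                       demographics, feature_config)
        return cls(feats, config, feature_config)

    def _grid(self):
        return [{"n_estimators": int(n), "max_depth": int(d)}
                for n in self.config.n_estimators_grid
                for d in self.config.max_depth_grid]

    def fit(self) -> PainIndexResults:
        """Grid search by inner-CV AUROC, then refit on all data.

        Oversampling is applied inside training folds only, and to the
        full table only for the final refit.  Deterministic given
        ``config.seed``.
        """
        cfg = self.config
        if len(np.unique(self.y)) < 2:
            raise ValueError("training labels contain a single class")
        grid = self._grid()
        rows = []
        if len(grid) == 1:
            best, rows = grid[0], [{**grid[0], "cv_auroc": np.nan}]
        else:
            for params in grid:
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 1]))
                auroc, _, _ = _cv_pooled_auroc(
                    self.X, self.y, self.groups, params, cfg, rng,
                    self.cont_idx)
                rows.append({**params, "cv_auroc": auroc})
            best = max(rows, key=lambda r: r["cv_auroc"])
            best = {"n_estimators": best["n_estimators"],
                    "max_depth": best["max_depth"]}

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        Xf, yf = self.X, self.y
        ratio = 1.0
        if cfg.oversample:
            Xf, yf, synth = _adasyn_arrays(
                self.X, self.y, self.cont_idx, rng, cfg.adasyn_k,
                cfg.adasyn_beta)
            ratio = len(yf) / len(self.y)
        forest = RandomForestClassifier(
            n_estimators=best["n_estimators"], max_depth=best["max_depth"],
            random_state=int(rng.integers(0, 2 ** 31)))
        forest.fit(Xf, yf)
        return PainIndexResults(
            estimator=forest, params=best, feature_names=self.feature_names,
            schema=schema_hash(self.feature_names),
            grid_table=pd.DataFrame(rows), oversample_ratio=ratio,
            config=cfg, feature_config=self.feature_config,
            n_obs=len(self.y))

    def cross_validate(self, repeats: int | None = None
                       ) -> CrossValidationResult:
        """Repeated k-fold CV with the (single best) grid inside folds.

        Each repeat uses a distinct fold-assignment seed; the per-repeat
        AUROC pools out-of-fold predictions.  With a multi-cell grid the
        grid search runs inside every training fold.
        """
        cfg = self.config
        repeats = cfg.cv_repeats if repeats is None else repeats
        grid = self._grid()
        per_repeat, audits = [], []
        for r in range(repeats):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 100 + r]))
            if len(grid) == 1:
                auroc, fold_audits, _ = _cv_pooled_auroc(
                    self.X, self.y, self.groups, grid[0], cfg, rng,
                    self.cont_idx)
            else:
                auroc, fold_audits = self._nested_cv_once(rng)
            per_repeat.append(auroc)
            audits.append(fold_audits)
        mean = float(np.mean(per_repeat))
        sd = float(np.std(per_repeat, ddof=1)) if repeats > 1 else None
        return CrossValidationResult(mean, sd, per_repeat, audits)

    def out_of_fold_scores(self, params: dict | None = None,
                           repeat: int = 0) -> tuple:
        """One CV pass; returns ``(scores, labels)`` over scored rows.

        Useful for operating-point metrics (sensitivity/specificity at a
        threshold) on held-out predictions.  ``params`` defaults to the
        first grid cell.
        """
        cfg = self.config
        params = params or self._grid()[0]
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 100 + repeat]))
        _, _, oof = _cv_pooled_auroc(self.X, self.y, self.groups, params,
                                     cfg, rng, self.cont_idx)
        scored = ~np.isnan(oof)
        return oof[scored], self.y[scored]

    def _nested_cv_once(self, rng) -> tuple:
        cfg = self.config
        folds = _fold_assignment(
            self.groups if cfg.split_unit == "patient"
            else np.arange(len(self.y)), cfg.cv_folds, rng)
        oof = np.full(len(self.y), np.nan)
        audits = []
        for f in range(cfg.cv_folds):
            val = folds == f
            train = ~val
            if len(np.unique(self.y[val])) < 2 \
                    or len(np.unique(self.y[train])) < 2:
                warnings.warn(f"fold {f} has a single class; skipped")
                continue
            sub = PainIndexModel(self.features.loc[train], cfg,
                                 self.feature_config)
            res = sub.fit()
            oof[val] = res.estimator.predict_proba(self.X[val])[:, 1]
            audits.append(FoldAudit(
                fold=f, n_train_original=int(train.sum()),
                n_train_synthetic=int(round(
                    (res.oversample_ratio - 1) * train.sum())),
                n_validation=int(val.sum()), validation_all_original=True))
        scored = ~np.isnan(oof)
        if scored.sum() == 0 or len(np.unique(self.y[scored])) < 2:
            raise ValueError("all cross-validation folds were degenerate")
        return float(roc_auc_score(self.y[scored], oof[scored])), audits


# ---------------------------------------------------------------------------
# module-level convenience functions


def grid_search_train(features: pd.DataFrame,
                      cfg: ModelConfig | None = None) -> PainIndexResults:
    return PainIndexModel(features, cfg).fit()


def repeated_cv_auroc(features: pd.DataFrame,
                      cfg: ModelConfig | None = None,
                      repeats: int | None = None) -> CrossValidationResult:
    return PainIndexModel(features, cfg).cross_validate(repeats)


def predict_pain_index(results: PainIndexResults,
                       features: pd.DataFrame) -> pd.DataFrame:
    """Pain-index series (patient_id, t_min, pain_index in [0, 1])."""
    return results.predict_series(features)
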