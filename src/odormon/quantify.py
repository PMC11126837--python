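"""Odor quantification: per-class PLS regressions routed by a classifier
(the double-step "model A") against a single global PLS baseline ("model B"),
plus lower-detection-limit estimation and residual diagnostics.

Both models regress log10 odor concentration on autoscaled sensor features.
Working in log space linearises the concentration-response relation and
compresses the wide dynamic range of odor concentrations; predictions are
exponentiated back and reported in *equivalent* odor units (ou_eq), kept
terminologically distinct from panel-measured odor units per m^3 because the
instrument estimate is not a sensory measurement.

The double-step idea: odor sources with very different chemical composition
imprint different fingerprints on the array at the same odor concentration,
so a single global regression conflates class differences with concentration
differences.  Classifying first and routing each sample to a class-specific
regression removes that confound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.covariance import LedoitWolf
from sklearn.model_selection import KFold

from .classify import KnnClassifier, LimitResult, _scan_limit, select_k
from .datamodel import AIR, SchemaError, TrainingSet, ValidationError

__all__ = [
    "PlsModel",
    "DoubleStepModel",
    "GlobalPlsModel",
    "PredictionResult",
    "fit_pls",
    "select_components",
    "fit_double_step",
    "fit_global",
    "predict_concentration",
    "residual_diagnostics",
    "estimate_ldl",
    "DiagnosticsReport",
]


@dataclass
class PlsModel:
    """A fitted single-response PLS regression on autoscaled features.

    Fitted by NIPALS.  With a single response the NIPALS inner iteration
    converges in one pass (the weight vector is exactly X'y normalised), so
    the decomposition is closed-form and fully deterministic.  Prediction is
    affine: ``yhat = y_mean + x_scaled . coef``.
    """

    n_components: int
    coef: pd.Series = field(repr=False)        # regression vector, scaled-X space
    x_mean: pd.Series = field(repr=False)      # per-feature centering of this fit
    y_mean: float = 0.0
    weights: np.ndarray | None = field(default=None, repr=False)   # p x a
    loadings: np.ndarray | None = field(default=None, repr=False)  # p x a
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.coef.index)

    def predict_scaled(self, Xs) -> np.ndarray:
        if isinstance(Xs, pd.Series):
            Xs = Xs.to_frame().T
        if isinstance(Xs, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in Xs.columns]
            if missing:
                raise SchemaError(f"feature matrix missing {missing}")
            Xs = Xs[self.feature_names].to_numpy(dtype=float)
        X0 = np.asarray(Xs, dtype=float) - self.x_mean.to_numpy()
        return self.y_mean + X0 @ self.coef.to_numpy()

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            n_components=d["n_components"],
            coef=pd.Series(d["coef"], index=d["feature_names"]),
            x_mean=pd.Series(d["x_mean"], index=d["feature_names"]),
            y_mean=d["y_mean"],
        )


def fit_pls(X: pd.DataFrame, y: pd.Series | np.ndarray, a: int) -> PlsModel:
    """Fit a PLS regression with ``a`` latent components (NIPALS, PLS1).

    ``X`` should be autoscaled; both ``X`` and ``y`` are additionally
    centered internally (a class-subset of a globally autoscaled matrix has
    a non-zero mean, and NIPALS requires centered blocks).  A rank-deficient
    ``X`` that cannot support ``a`` components raises an error naming the
    achievable component count.
    """
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    X0 = np.asarray(X, dtype=float).copy()
    yv = np.asarray(y, dtype=float)
    n, p = X0.shape
    if not 1 <= a <= min(n - 1, p):
        raise ValidationError(f"a={a} outside [1, {min(n - 1, p)}]")
    if len(yv) != n:
        raise ValidationError("X and y must align")
    x_mean = X0.mean(axis=0)
    X0 -= x_mean
    y_mean = float(yv.mean())
    y0 = yv - y_mean
    scale = max(np.abs(X0).max(), 1.0)
    tol = 1e-12 * scale
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    Q = np.zeros(a)
    for i in range(a):
        w = X0.T @ y0
        nw = np.linalg.norm(w)
        if nw <= tol or np.linalg.norm(X0) <= tol:
            raise ValidationError(
                f"X supports only {i} PLS components (requested {a})"
            )
        w /= nw
        t = X0 @ w
        tt = float(t @ t)
        if tt <= tol:
            raise ValidationError(f"X supports only {i} PLS components (requested {a})")
        p_load = X0.T @ t / tt
        q = float(y0 @ t / tt)
        X0 -= np.outer(t, p_load)
        y0 = y0 - q * t
        W[:, i], P[:, i], Q[i] = w, p_load, q
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PlsModel(
        n_components=a,
        coef=pd.Series(coef, index=cols),
        x_mean=pd.Series(x_mean, index=cols),
        y_mean=y_mean,
        weights=W,
        loadings=P,
    )


def select_components(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    folds: int = 10,
    a_grid: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the PLS component count by cross-validated RMSEP (log10 scale).

    Ties go to the smaller component count; the RMSEP table is returned for
    audit.  Fold assignment is seeded and shuffled."""
    n, p = np.shape(X)
    if n < folds:
        warnings.warn(f"reducing folds from {folds} to {n}")
        folds = max(2, n)
    max_a = min(n - int(np.ceil(n / folds)) - 1, p)
    if a_grid is None:
        a_grid = tuple(range(1, min(max_a, 10) + 1))
    a_grid = tuple(sorted(a for a in a_grid if a >= 1))
    if not a_grid:
        raise ValidationError("empty component grid")
    yv = np.asarray(y, dtype=float)
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = {a: [] for a in a_grid}
    feasible = set(a_grid)
    for train_idx, test_idx in kf.split(Xdf):
        Xtr, ytr = Xdf.iloc[train_idx], yv[train_idx]
        Xte, yte = Xdf.iloc[test_idx], yv[test_idx]
        for a in a_grid:
            if a not in feasible:
                continue
            try:
                m = fit_pls(Xtr, ytr, a)
            except ValidationError:
                feasible.discard(a)
                continue
            sq_err[a].extend((m.predict_scaled(Xte) - yte) ** 2)
    rows = [
        {"a": a, "rmsep": float(np.sqrt(np.mean(sq_err[a])))}
        for a in a_grid if a in feasible and sq_err[a]
    ]
    if not rows:
        raise ValidationError("no feasible component count in the grid")
    table = pd.DataFrame(rows)
    a_best = int(table.loc[table["rmsep"].idxmin(), "a"])  # first min -> smallest a
    return a_best, table


@dataclass
class PredictionResult:
    """Outcome of one quantification: routing label (double-step only),
    estimated concentration in equivalent odor units, and flags."""

    label: str | None
    concentration: float | None
    log10_concentration: float | None
    clipped: bool = False
    detail: dict = field(default_factory=dict)


@dataclass
class DoubleStepModel:
    """Model A: classifier + one PLS regression per odorous class.

    An Air classification short-circuits quantification (clean air has no
    odor concentration); otherwise the sample is routed to exactly the
    regressor of its predicted class."""

    classifier: KnnClassifier
    regressors: dict[str, PlsModel]
    scaler_mean: pd.Series = field(repr=False)
    scaler_sd: pd.Series = field(repr=False)
    components: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.regressors:
            raise ValidationError("double-step model needs at least one class regressor")

    def _scale(self, features: pd.Series) -> pd.Series:
        cols = list(self.scaler_mean.index)
        missing = [f for f in cols if f not in features.index]
        if missing:
            raise SchemaError(f"feature vector missing {missing}")
        return (features[cols] - self.scaler_mean) / self.scaler_sd

    def predict(self, features: pd.Series) -> PredictionResult:
        label, votes = self.classifier.predict(features)
        if label == AIR:
            return PredictionResult(AIR, None, None, detail={"votes": votes})
        if label not in self.regressors:
            raise ValidationError(f"no regressor for predicted class {label!r}")
        yhat = float(self.regressors[label].predict_scaled(self._scale(features))[0])
        clipped = yhat < 0.0
        y_use = max(yhat, 0.0)
        return PredictionResult(
            label, 10.0 ** y_use, y_use, clipped,
            detail={"votes": votes, "routed_to": label, "raw_log10": yhat},
        )

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier.to_dict(),
            "regressors": {c: m.to_dict() for c, m in self.regressors.items()},
            "scaler_index": list(self.scaler_mean.index),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "components": self.components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoubleStepModel":
        idx = d["scaler_index"]
        return cls(
            classifier=KnnClassifier.from_dict(d["classifier"]),
            regressors={c: PlsModel.from_dict(m) for c, m in d["regressors"].items()},
            scaler_mean=pd.Series(d["scaler_mean"], index=idx),
            scaler_sd=pd.Series(d["scaler_sd"], index=idx),
            components={c: int(a) for c, a in d["components"].items()},
        )


@dataclass
class GlobalPlsModel:
    """Model B: one PLS regression over all odorous training rows, class
    ignored — the conventional single-regressor baseline."""

    pls: PlsModel
    scaler_mean: pd.Series = field(repr=False)
    scaler_sd: pd.Series = field(repr=False)

    def _scale(self, features: pd.Series) -> pd.Series:
        cols = list(self.scaler_mean.index)
        missing = [f for f in cols if f not in features.index]
        if missing:
            raise SchemaError(f"feature vector missing {missing}")
        return (features[cols] - self.scaler_mean) / self.scaler_sd

    def predict(self, features: pd.Series) -> PredictionResult:
        yhat = float(self.pls.predict_scaled(self._scale(features))[0])
        clipped = yhat < 0.0
        y_use = max(yhat, 0.0)
        return PredictionResult(None, 10.0 ** y_use, y_use, clipped,
                                detail={"raw_log10": yhat})

    def to_dict(self) -> dict:
        return {
            "pls": self.pls.to_dict(),
            "scaler_index": list(self.scaler_mean.index),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GlobalPlsModel":
        idx = d["scaler_index"]
        return cls(
            pls=PlsModel.from_dict(d["pls"]),
            scaler_mean=pd.Series(d["scaler_mean"], index=idx),
            scaler_sd=pd.Series(d["scaler_sd"], index=idx),
        )


def _check_class_sizes(ts: TrainingSet, min_rows: int = 4) -> pd.Series:
    counts = ts.odorous().y_class.value_counts()
    if len(counts) < 2:
        raise ValidationError(
            f"double-step model needs >= 2 odorous classes, got {list(counts.index)}"
        )
    small = counts[counts < min_rows]
    if not small.empty:
        raise ValidationError(f"too few training rows for classes: {dict(small)}")
    return counts


def fit_double_step(
    training_set: TrainingSet,
    classifier: KnnClassifier | None = None,
    folds: int = 10,
    seed: int = 0,
    a_grid: tuple[int, ...] | None = None,
    pinned_components: dict[str, int] | None = None,
) -> DoubleStepModel:
    """Fit model A: per odorous class, choose the PLS component count by CV
    on that class's rows only, then fit the class regressor.

    ``pinned_components`` skips CV and fixes the per-class component counts
    (useful for replicating a previously selected configuration).  When no
    classifier is supplied, a k-NN classifier is fitted on the full training
    set with k chosen by stratified CV."""
    _check_class_sizes(training_set)
    if classifier is None:
        k_best, _ = select_k(training_set, folds=folds, seed=seed)
        classifier = KnnClassifier.fit(training_set, k_best)
    odor = training_set.odorous()
    regressors: dict[str, PlsModel] = {}
    components: dict[str, int] = {}
    for i, cls in enumerate(sorted(odor.y_class.unique())):
        rows = odor.y_class == cls
        Xc = odor.scale(odor.X.loc[rows])
        yc = odor.y_logc.loc[rows]
        if pinned_components and cls in pinned_components:
            a = int(pinned_components[cls])
        else:
            a, table = select_components(Xc, yc, folds=folds, a_grid=a_grid, seed=seed + i)
        m = fit_pls(Xc, yc, a)
        regressors[cls] = m
        components[cls] = a
    return DoubleStepModel(
        classifier=classifier,
        regressors=regressors,
        scaler_mean=training_set.scaler_mean.copy(),
        scaler_sd=training_set.scaler_sd.copy(),
        components=components,
    )


def fit_global(
    training_set: TrainingSet,
    folds: int = 10,
    seed: int = 0,
    a_grid: tuple[int, ...] | None = None,
    pinned_components: int | None = None,
) -> GlobalPlsModel:
    """Fit model B on all odorous rows, ignoring class."""
    odor = training_set.odorous()
    if odor.X.empty:
        raise ValidationError("no odorous training rows")
    Xs = odor.X_scaled
    y = odor.y_logc
    if pinned_components is not None:
        a = int(pinned_components)
    else:
        a, _ = select_components(Xs, y, folds=folds, a_grid=a_grid, seed=seed)
    m = fit_pls(Xs, y, a)
    return GlobalPlsModel(
        pls=m,
        scaler_mean=training_set.scaler_mean.copy(),
        scaler_sd=training_set.scaler_sd.copy(),
    )


def predict_concentration(model, features: pd.Series) -> PredictionResult:
    """Estimate the odor concentration of one feature vector (ou_eq).

    For the double-step model the routing class label is attached and an
    Air classification yields no concentration; log-scale predictions below
    0 (concentration < 1) are clipped to 1 with a flag — log-linear models
    extrapolate absurdly near baseline."""
    return model.predict(features)


@dataclass
class DiagnosticsReport:
    """Residual diagnostics of a fitted quantification model on its training
    set: normality, predictor/fitted-value correlations, heteroscedasticity
    and serial correlation, each with a pass/warn flag at alpha = 0.05."""

    n: int
    residuals: np.ndarray = field(repr=False)
    shapiro_p: float | None = None
    predictor_correlations: dict[str, float] = field(default_factory=dict)
    max_predictor_corr: tuple[str, float] | None = None
    fitted_corr: float | None = None
    het_slope_p: float | None = None
    lag1_autocorr: float | None = None
    degenerate: bool = False
    flags: dict[str, str] = field(default_factory=dict)


def residual_diagnostics(model, training_set: TrainingSet) -> DiagnosticsReport:
    """Residual diagnostics on the odorous training rows.

    For the double-step model each row is scored by the regressor of its
    *true* class (training residuals of the routed regressors); the global
    model uses its single regression.  Checks: Shapiro-Wilk normality,
    Pearson correlation of residuals with each predictor and with fitted
    values, a heteroscedasticity slope test (squared residuals regressed on
    fitted values) and the lag-1 autocorrelation."""
    odor = training_set.odorous()
    if len(odor.X) < 3:
        raise ValidationError("need at least 3 odorous rows for diagnostics")
    Xs = odor.X_scaled
    y = odor.y_logc.to_numpy(dtype=float)
    if isinstance(model, DoubleStepModel):
        fitted = np.empty(len(y))
        for cls, m in model.regressors.items():
            rows = (odor.y_class == cls).to_numpy()
            if rows.any():
                fitted[rows] = m.predict_scaled(Xs.loc[rows])
    elif isinstance(model, GlobalPlsModel):
        fitted = model.pls.predict_scaled(Xs)
    else:
        raise ValidationError(f"unsupported model type {type(model).__name__}")
    resid = y - fitted
    rep = DiagnosticsReport(n=len(resid), residuals=resid)
    if np.std(resid) < 1e-12:
        rep.degenerate = True
        rep.flags["overall"] = "degenerate: residuals numerically zero"
        return rep
    rep.shapiro_p = float(stats.shapiro(resid).pvalue)
    rep.flags["normality"] = "pass" if rep.shapiro_p > 0.05 else "warn"
    for colname in Xs.columns:
        col = Xs[colname].to_numpy()
        if np.std(col) == 0:
            continue
        rep.predictor_correlations[colname] = float(stats.pearsonr(col, resid)[0])
    if rep.predictor_correlations:
        worst = max(rep.predictor_correlations, key=lambda f: abs(rep.predictor_correlations[f]))
        rep.max_predictor_corr = (worst, rep.predictor_correlations[worst])
        p = stats.pearsonr(Xs[worst].to_numpy(), resid)[1]
        rep.flags["predictor_independence"] = "pass" if p > 0.05 else "warn"
    rep.fitted_corr = float(stats.pearsonr(fitted, resid)[0]) if np.std(fitted) > 0 else 0.0
    if np.std(fitted) > 0:
        het = sm.OLS(resid ** 2, sm.add_constant(fitted)).fit()
        rep.het_slope_p = float(het.pvalues[1])
        rep.flags["homoscedasticity"] = "pass" if rep.het_slope_p > 0.05 else "warn"
    if len(resid) > 2:
        rep.lag1_autocorr = float(np.corrcoef(resid[:-1], resid[1:])[0, 1])
        # Fisher z bound for lag-1 correlation at alpha=0.05
        bound = 1.96 / np.sqrt(len(resid) - 1)
        rep.flags["independence"] = "pass" if abs(rep.lag1_autocorr) < bound else "warn"
    return rep


def air_neutrality_envelope(
    air_features: pd.DataFrame, quantile: float = 0.99
):
    """Operationalise the "neutrality" of clean air as a Mahalanobis
    envelope.

    Air analyses define a centroid and a Ledoit-Wolf regularised covariance
    (after per-feature standardisation by the air SD — features mix units
    with variances orders of magnitude apart, and the shrinkage target would
    otherwise be dominated by the widest channel).  Returns
    ``(distance, envelope, columns)`` where ``distance`` maps a feature
    vector to its Mahalanobis distance from the air centroid and
    ``envelope`` is the ``quantile`` of the air self-distances.
    """
    if len(air_features) < 10:
        raise ValidationError(
            f"need >= 10 air analyses for a stable neutrality envelope, got {len(air_features)}"
        )
    A = air_features.to_numpy(dtype=float)
    sd = A.std(axis=0, ddof=1)
    keep = sd > 0
    cols = [c for c, k in zip(air_features.columns, keep) if k]
    A_raw = A[:, keep]
    sd = sd[keep]
    A_std = A_raw / sd
    center = A_std.mean(axis=0)
    lw = LedoitWolf().fit(A_std)
    prec = lw.precision_

    def distance(x) -> float:
        if isinstance(x, pd.Series):
            x = x[cols].to_numpy(dtype=float)
        d = np.asarray(x, dtype=float) / sd - center
        return float(np.sqrt(d @ prec @ d))

    self_d = np.array([distance(a) for a in A_raw])
    envelope = float(np.quantile(self_d, quantile))
    return distance, envelope, cols


def estimate_ldl(
    series: list[tuple[str, float, pd.Series]],
    air_features: pd.DataFrame,
    quantile: float = 0.99,
) -> dict[str, LimitResult]:
    """Lower detection limit per class from dilution-series feature vectors.

    A dilution level is detected when every replicate's Mahalanobis distance
    from the air centroid exceeds the neutrality envelope
    (:func:`air_neutrality_envelope`); the LDL is the lowest tested level
    from which upward all levels are detected.
    """
    distance, envelope, cols = air_neutrality_envelope(air_features, quantile)
    by_class: dict[str, dict[float, list[bool]]] = {}
    for cls, conc, fv in series:
        x = fv[cols].to_numpy(dtype=float)
        by_class.setdefault(cls, {}).setdefault(float(conc), []).append(distance(x) > envelope)
    out: dict[str, LimitResult] = {}
    for cls, levels in by_class.items():
        concs = sorted(levels)
        ok = [all(levels[c]) for c in concs]
        out[cls] = _scan_limit(concs, ok)
    return out
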