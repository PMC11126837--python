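"""Odor-class recognition and its performance metrics.

Two classifier families mirror the two instruments: k-nearest-neighbours
(fenceline unit) with the neighbour count chosen by stratified 10-fold
cross-validation, and a stepwise-linear one-vs-rest classifier (receptor
unit) that selects features by entry/removal p-values.  Performance is
summarised by accuracy indexes with Wilson 95% confidence intervals and by
the lower classification limit (LCL): the lowest odor concentration from
which upward every dilution replicate is assigned its true class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .datamodel import AIR, TrainingSet, SchemaError, ValidationError

__all__ = [
    "KnnClassifier",
    "SwLinearClassifier",
    "select_k",
    "predict_class",
    "fit_stepwise_linear",
    "accuracy_index",
    "estimate_lcl",
    "LimitResult",
    "wilson_interval",
]


def _knn_vote(labels: np.ndarray, dists: np.ndarray) -> tuple[str, dict[str, float]]:
    """Plurality vote over the k neighbours; residual ties broken toward the
    class with the smallest mean neighbour distance."""
    k = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    votes = {c: n / k for c, n in zip(classes, counts)}
    best = counts.max()
    tied = [c for c, n in zip(classes, counts) if n == best]
    if len(tied) == 1:
        return tied[0], votes
    mean_d = {c: float(dists[labels == c].mean()) for c in tied}
    return min(tied, key=lambda c: (mean_d[c], c)), votes


@dataclass
class KnnClassifier:
    """k-NN on autoscaled features (Euclidean distance).

    Stores its own autoscaling parameters so that ``predict`` accepts raw
    feature vectors; ``k`` must be odd to mitigate two-class vote ties.
    """

    k: int
    X_ref: pd.DataFrame = field(repr=False)
    labels: pd.Series = field(repr=False)
    scaler_mean: pd.Series = field(repr=False)
    scaler_sd: pd.Series = field(repr=False)
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if not 1 <= self.k <= len(self.X_ref):
            raise ValidationError(f"k={self.k} outside [1, {len(self.X_ref)}]")
        if self.k % 2 == 0:
            raise ValidationError("k must be odd")

    @classmethod
    def fit(cls, training_set: TrainingSet, k: int) -> "KnnClassifier":
        return cls(
            k=k,
            X_ref=training_set.X_scaled.copy(),
            labels=training_set.y_class.copy(),
            scaler_mean=training_set.scaler_mean.copy(),
            scaler_sd=training_set.scaler_sd.copy(),
        )

    @property
    def feature_names(self) -> list[str]:
        return list(self.X_ref.columns)

    def _scale(self, features: pd.Series) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.index]
        if missing:
            raise SchemaError(f"feature vector missing {missing}")
        x = features[self.feature_names].astype(float)
        return ((x - self.scaler_mean[self.feature_names]) / self.scaler_sd[self.feature_names]).to_numpy()

    def predict(self, features: pd.Series) -> tuple[str, dict[str, float]]:
        x = self._scale(features)[None, :]
        d = cdist(x, self.X_ref.to_numpy(), metric=self.metric)[0]
        order = np.argsort(d, kind="stable")[: self.k]
        return _knn_vote(self.labels.to_numpy()[order], d[order])

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "metric": self.metric,
            "feature_names": self.feature_names,
            "X_ref": self.X_ref.to_numpy().tolist(),
            "index": list(map(str, self.X_ref.index)),
            "labels": list(self.labels),
            "scaler_mean": self.scaler_mean[self.feature_names].tolist(),
            "scaler_sd": self.scaler_sd[self.feature_names].tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnnClassifier":
        cols = d["feature_names"]
        idx = pd.Index(d["index"], name="sample_id")
        return cls(
            k=d["k"],
            X_ref=pd.DataFrame(d["X_ref"], index=idx, columns=cols),
            labels=pd.Series(d["labels"], index=idx),
            scaler_mean=pd.Series(d["scaler_mean"], index=cols),
            scaler_sd=pd.Series(d["scaler_sd"], index=cols),
            metric=d["metric"],
        )


def _cv_accuracy(Xs: np.ndarray, y: np.ndarray, k: int, folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(Xs, y):
        d = cdist(Xs[test_idx], Xs[train_idx])
        for row, ti in enumerate(test_idx):
            kk = min(k, len(train_idx))
            order = np.argsort(d[row], kind="stable")[:kk]
            label, _ = _knn_vote(y[train_idx][order], d[row][order])
            correct += label == y[ti]
    return correct / len(y)


def select_k(
    training_set: TrainingSet,
    folds: int = 10,
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9),
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the neighbour count by stratified cross-validated accuracy.

    Ties go to the smallest k; the full accuracy table is returned for
    audit.  If the rarest class has fewer members than ``folds``, the fold
    count is reduced with a warning."""
    if any(k % 2 == 0 for k in k_grid):
        raise ValidationError("k_grid must contain odd values only")
    y = training_set.y_class.to_numpy()
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < folds:
        warnings.warn(f"reducing folds from {folds} to {min_class} (smallest class size)")
        folds = max(2, min_class)
    Xs = training_set.X_scaled.to_numpy()
    rows = [
        {"k": k, "cv_accuracy": _cv_accuracy(Xs, y, k, folds, seed)}
        for k in sorted(k_grid)
    ]
    table = pd.DataFrame(rows)
    k_best = int(table.loc[table["cv_accuracy"].idxmax(), "k"])  # idxmax -> first max
    return k_best, table


@dataclass
class SwLinearClassifier:
    """Stepwise-linear one-vs-rest classifier.

    Per class, a linear indicator regression is built by bidirectional
    stepwise selection (add the candidate with the smallest entry p-value
    below ``p_enter``, drop fitted features whose p-value exceeds
    ``p_remove``); prediction is the argmax of the per-class linear scores.
    """

    models: dict[str, dict]          # class -> {intercept, coef: {feature: value}}
    scaler_mean: pd.Series = field(repr=False)
    scaler_sd: pd.Series = field(repr=False)
    p_enter: float = 0.05
    p_remove: float = 0.10
    trace: dict[str, list[str]] = field(default_factory=dict, repr=False)

    @property
    def feature_names(self) -> list[str]:
        return list(self.scaler_mean.index)

    def scores(self, features: pd.Series) -> dict[str, float]:
        missing = [f for f in self.feature_names if f not in features.index]
        if missing:
            raise SchemaError(f"feature vector missing {missing}")
        xs = (features[self.feature_names] - self.scaler_mean) / self.scaler_sd
        out = {}
        for cls, m in self.models.items():
            out[cls] = m["intercept"] + sum(
                m["coef"].get(f, 0.0) * xs[f] for f in m["coef"]
            )
        return out

    def predict(self, features: pd.Series) -> tuple[str, dict[str, float]]:
        sc = self.scores(features)
        best = max(sorted(sc), key=lambda c: sc[c])
        return best, sc

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "feature_names": self.feature_names,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SwLinearClassifier":
        cols = d["feature_names"]
        return cls(
            models=d["models"],
            scaler_mean=pd.Series(d["scaler_mean"], index=cols),
            scaler_sd=pd.Series(d["scaler_sd"], index=cols),
            p_enter=d["p_enter"],
            p_remove=d["p_remove"],
        )


def _stepwise_select(Xs: pd.DataFrame, y: np.ndarray, p_enter: float,
                     p_remove: float) -> tuple[list[str], list[str]]:
    """Bidirectional stepwise selection on p-values.  Returns (selected,
    selection trace)."""
    selected: list[str] = []
    trace: list[str] = []
    candidates = list(Xs.columns)
    while True:
        # backward pass
        while selected:
            fit = sm.OLS(y, sm.add_constant(Xs[selected], has_constant="add")).fit()
            pv = fit.pvalues.drop("const", errors="ignore").fillna(1.0)
            worst = pv.idxmax()
            if pv[worst] > p_remove:
                selected.remove(worst)
                trace.append(f"-{worst} (p={pv[worst]:.3g})")
            else:
                break
        # forward pass
        best_f, best_p = None, 1.0
        base_rank = np.linalg.matrix_rank(Xs[selected].to_numpy()) if selected else 0
        for f in candidates:
            if f in selected:
                continue
            # collinearity guard: statsmodels' pinv would otherwise split a
            # coefficient across exact duplicates with deceptive p-values
            if np.linalg.matrix_rank(Xs[selected + [f]].to_numpy()) <= base_rank:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.OLS(y, sm.add_constant(Xs[selected + [f]], has_constant="add")).fit()
            p = float(fit.pvalues.get(f, 1.0))
            if not np.isfinite(p):
                p = 1.0
            if p < best_p:
                best_f, best_p = f, p
        if best_f is not None and best_p < p_enter:
            selected.append(best_f)
            trace.append(f"+{best_f} (p={best_p:.3g})")
        else:
            break
    return selected, trace


def fit_stepwise_linear(
    training_set: TrainingSet, p_enter: float = 0.05, p_remove: float = 0.10
) -> SwLinearClassifier:
    """Fit the stepwise-linear one-vs-rest classifier on autoscaled features."""
    if not p_enter < p_remove:
        raise ValidationError("p_enter must be below p_remove")
    Xs = training_set.X_scaled
    models: dict[str, dict] = {}
    traces: dict[str, list[str]] = {}
    for cls in sorted(training_set.y_class.unique()):
        y = (training_set.y_class == cls).astype(float).to_numpy()
        selected, trace = _stepwise_select(Xs, y, p_enter, p_remove)
        if not selected:
            warnings.warn(f"class {cls!r}: no feature passed entry; intercept-only model")
            models[cls] = {"intercept": float(y.mean()), "coef": {}}
        else:
            fit = sm.OLS(y, sm.add_constant(Xs[selected], has_constant="add")).fit()
            models[cls] = {
                "intercept": float(fit.params.get("const", 0.0)),
                "coef": {f: float(fit.params[f]) for f in selected},
            }
        traces[cls] = trace
    return SwLinearClassifier(
        models=models,
        scaler_mean=training_set.scaler_mean.copy(),
        scaler_sd=training_set.scaler_sd.copy(),
        p_enter=p_enter,
        p_remove=p_remove,
        trace=traces,
    )


def predict_class(classifier, features: pd.Series) -> tuple[str, dict[str, float]]:
    """Predict the odor class of one feature vector.

    k-NN returns (label, vote fractions); the stepwise-linear classifier
    returns (label, per-class linear scores)."""
    return classifier.predict(features)


def wilson_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (good small-n
    behaviour), on the 0-1 scale."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)
    hi = 1.0 if k == n else min(1.0, center + half)  # exact at the extremes
    return lo, hi


def accuracy_index(
    predictions: list[str], truth: list[str], task: str = "classification"
) -> tuple[float, float, float]:
    """Accuracy index in percent with its Wilson 95% CI.

    ``task='detection'`` collapses labels to odorous / non-odorous before
    scoring (a confusion between two odorous classes still counts as a
    correct detection); ``task='classification'`` scores the full labels."""
    if task not in ("detection", "classification"):
        raise ValidationError(f"unknown task {task!r}")
    if len(predictions) != len(truth) or not truth:
        raise ValidationError("predictions and truth must be equal-length and non-empty")
    if task == "detection":
        predictions = [p != AIR for p in predictions]
        truth = [t != AIR for t in truth]
    n = len(truth)
    k = sum(p == t for p, t in zip(predictions, truth))
    lo, hi = wilson_interval(k, n)
    return 100.0 * k / n, 100.0 * lo, 100.0 * hi


@dataclass(frozen=True)
class LimitResult:
    """A detection/classification limit on a tested dilution grid.

    ``censored`` marks a limit at the lowest tested level (the true limit
    may lie below); ``non_monotone`` marks series that succeeded at a low
    concentration but failed higher up."""

    value: float | None
    censored: bool = False
    non_monotone: bool = False


def estimate_lcl(
    results: list[tuple[str, float, str]]
) -> dict[str, LimitResult]:
    """Lower classification limit per class from dilution-series predictions.

    ``results`` holds (true class, tested concentration, predicted label)
    per replicate.  The LCL is the lowest tested concentration at and above
    which every replicate is correctly classified; series that are never
    all-correct from some level upward yield ``value=None``."""
    by_class: dict[str, dict[float, list[bool]]] = {}
    for true_cls, conc, pred in results:
        by_class.setdefault(true_cls, {}).setdefault(float(conc), []).append(pred == true_cls)
    out: dict[str, LimitResult] = {}
    for cls, levels in by_class.items():
        concs = sorted(levels)
        ok = [all(levels[c]) for c in concs]
        out[cls] = _scan_limit(concs, ok)
    return out


def _scan_limit(concs: list[float], ok: list[bool]) -> LimitResult:
    """Shared scan for LCL/LDL: lowest level from which upward all levels
    pass."""
    if not any(ok):
        return LimitResult(None)
    # lowest index i such that ok[i:] all True
    idx = len(ok)
    for i in range(len(ok) - 1, -1, -1):
        if ok[i]:
            idx = i
        else:
            break
    if idx == len(ok):
        return LimitResult(None)
    non_mono = any(ok[:idx])
    return LimitResult(concs[idx], censored=(idx == 0), non_monotone=non_mono)
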