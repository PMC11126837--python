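"""PCA-based exploratory analysis of a training set and score-space outlier
flagging.

The decomposition is made deterministic across runs and platforms by a fixed
sign convention: within each component, the loading element of largest
magnitude is made positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datamodel import TrainingSet, ValidationError

__all__ = ["PcaModel", "fit_pca", "flag_outliers", "OutlierFlag"]


@dataclass
class PcaModel:
    """Fitted PCA on the autoscaled feature matrix."""

    loadings: pd.DataFrame          # p x k, columns PC1..PCk
    scores: pd.DataFrame            # n x k
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1.0 + 1e-9:
            raise ValidationError("explained-variance fractions must be non-increasing, sum <= 1")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def components_covering(self, fraction: float = 0.95) -> int:
        """Smallest number of leading components whose cumulative explained
        variance reaches ``fraction`` (all retained components if never)."""
        cum = np.cumsum(self.explained_variance_ratio)
        hit = np.flatnonzero(cum >= fraction)
        return int(hit[0]) + 1 if hit.size else self.n_components


def fit_pca(training_set: TrainingSet, k: int) -> PcaModel:
    """Deterministic PCA of the autoscaled training matrix with ``k``
    retained components."""
    Xs = training_set.X_scaled
    n, p = Xs.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValidationError(f"k={k} outside [1, {min(n - 1, p)}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs.to_numpy())
    load = pca.components_.T  # p x k
    # sign convention: largest-|loading| element positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1.0
            scores[:, j] *= -1.0
    cols = [f"PC{j + 1}" for j in range(k)]
    return PcaModel(
        loadings=pd.DataFrame(load, index=Xs.columns, columns=cols),
        scores=pd.DataFrame(scores, index=Xs.index, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass(frozen=True)
class OutlierFlag:
    sample_id: object
    component: str
    score: float
    threshold: float


def flag_outliers(
    pca_model: PcaModel, k_sd: float = 3.0, n_components: int | None = None
) -> list[OutlierFlag]:
    """Flag samples whose score on any retained component lies more than
    ``k_sd`` standard deviations from that component's mean score.

    By default the components covering 95% of the variance are screened.
    Flags are returned with the offending component; removing the samples is
    the caller's explicit action, so the audit trail stays visible.
    """
    if not k_sd > 0:
        raise ValidationError("k_sd must be positive")
    if n_components is None:
        n_components = pca_model.components_covering(0.95)
    n_components = min(n_components, pca_model.n_components)
    flags: list[OutlierFlag] = []
    for col in pca_model.scores.columns[:n_components]:
        s = pca_model.scores[col]
        mu, sd = float(s.mean()), float(s.std(ddof=1))
        if sd == 0:
            continue
        thr = k_sd * sd
        for sid, val in s.items():
            if abs(val - mu) > thr:
                flags.append(OutlierFlag(sid, col, float(val), thr))
    return flags
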