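"""PC1 composite performance index.

BA, MCC and F1 are strongly collinear across benchmark models, so the first
principal component of their correlation matrix summarizes them in a single
score.  PCA is performed on the correlation matrix (metrics standardized to
zero mean and unit n-1 variance), which makes the composite invariant to
the mixed units of the inputs (percent for BA/F1, raw for MCC).  Principal
axes are sign-indeterminate; PC1 is oriented so that all its loadings are
positive, i.e. a higher PC1 always means a better model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .table import ModelTable

__all__ = ["PCAResult", "pc1_index", "metric_correlations", "attach_pc1"]

DEFAULT_METRICS = ("ba", "mcc", "f1")


@dataclass(frozen=True)
class PCAResult:
    """Loadings, per-model scores and variance fractions of a metric PCA."""

    metrics: tuple[str, ...]
    loadings: np.ndarray            # (k, k); row i = loading vector of PC(i+1)
    scores: pd.DataFrame            # indexed by model_uid, columns PC1..PCk
    variance_fraction: np.ndarray   # (k,)
    means: np.ndarray               # standardization means, metric order
    sds: np.ndarray                 # standardization SDs (ddof=1)

    @property
    def pc1_loadings(self) -> np.ndarray:
        return self.loadings[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project metric vectors (rows, metric order) onto the components."""
        z = (np.asarray(values, dtype=float) - self.means) / self.sds
        return z @ self.loadings.T

    def to_json(self) -> str:
        return json.dumps(
            {
                "metrics": list(self.metrics),
                "loadings": self.loadings.tolist(),
                "variance_fraction": self.variance_fraction.tolist(),
                "means": self.means.tolist(),
                "sds": self.sds.tolist(),
                "scores": {str(uid): row.tolist() for uid, row in zip(self.scores.index, self.scores.values)},
            },
            indent=2,
        )


def _metric_matrix(table: ModelTable, metrics: tuple[str, ...]) -> tuple[np.ndarray, list[int]]:
    missing = [r.model_uid for r in table if any(r.metric(m) is None for m in metrics)]
    if missing:
        raise ValidationError(f"records missing a requested metric: model_uid(s) {missing}")
    uids = [r.model_uid for r in table]
    X = np.array([[r.metric(m) for m in metrics] for r in table], dtype=float)
    return X, uids


def pc1_index(table: ModelTable, metrics: tuple[str, ...] = DEFAULT_METRICS) -> PCAResult:
    """PCA of the requested metrics on the correlation matrix.

    Requires at least 3 records, every metric present on every record, and
    nonzero variance in each metric column.  Components are ordered by
    decreasing explained variance; every component is flipped, if needed,
    so its loading sum is positive, which for the positively-correlated
    performance metrics makes all PC1 loadings positive.
    """
    if len(table) < 3:
        raise InsufficientDataError(f"PCA needs >= 3 records, got {len(table)}")
    X, uids = _metric_matrix(table, metrics)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        const = [m for m, s in zip(metrics, sds) if s == 0]
        raise DegenerateDataError(f"constant metric column(s): {const}")
    Z = (X - means) / sds

    pca = PCA(n_components=len(metrics), svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()

    # resolve the sign indeterminacy: orient each axis by its loading sum
    for i in range(loadings.shape[0]):
        if loadings[i].sum() < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]

    score_df = pd.DataFrame(
        scores, index=pd.Index(uids, name="model_uid"),
        columns=[f"PC{i + 1}" for i in range(len(metrics))],
    )
    return PCAResult(
        metrics=tuple(metrics),
        loadings=loadings,
        scores=score_df,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        means=means,
        sds=sds,
    )


def metric_correlations(table: ModelTable, metrics: tuple[str, ...] = DEFAULT_METRICS) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of the requested metrics."""
    if len(table) < 3:
        raise InsufficientDataError(f"correlation needs >= 3 records, got {len(table)}")
    X, _ = _metric_matrix(table, metrics)
    if np.any(X.std(axis=0, ddof=1) == 0):
        const = [m for m, s in zip(metrics, X.std(axis=0, ddof=1)) if s == 0]
        raise DegenerateDataError(f"constant metric column(s): {const}")
    R = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(R, index=list(metrics), columns=list(metrics))


def attach_pc1(table: ModelTable, pca: PCAResult) -> ModelTable:
    """Return a new table whose records carry their PC1 score.

    PC1 then participates in the coverage analysis exactly like the raw
    performance metrics.
    """
    pc1 = pca.scores["PC1"]
    records = [replace(r, pc1=float(pc1.loc[r.model_uid])) for r in table]
    return table.with_records(records, note="attached PC1 scores")
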