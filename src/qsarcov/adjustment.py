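"""Coverage-performance inference and projection to a common coverage.

Benchmark rules that let a model abstain outside its applicability domain
confound reported performance with the chosen coverage rate (COV): shrink
the domain and the measured metrics improve.  This module quantifies that
association and removes it.  For each metric y:

1.  Pearson-correlate y with the Johnson-normalized coverage z = Sb(COV)
    over the models with COV < 100 (the full-coverage point mass carries no
    information about the trade-off), with a two-sided t test on n-2 df.
2.  Fit the ordinary least-squares line y = a + b z on the same subset;
    every model in the table - including the COV = 100 ones - gets a
    residual against that line.
3.  Project each model along the common slope to any target coverage while
    preserving its residual:  y*(c) = a + b Sb(c) + resid.  At the model's
    own observed coverage this returns the observed value exactly, and at
    100% it yields the coverage-fair estimate used for ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .composite import PCAResult
from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .johnson import JohnsonSbParams, sb_transform
from .table import ModelTable

__all__ = [
    "CorrelationResult",
    "CovRegressionFit",
    "AdjustedEstimate",
    "correlate_cov",
    "fit_cov_line",
    "project_to_cov",
    "rank_at_full_coverage",
    "cov_sweep",
]

DEFAULT_RANK_METRICS = ("ba", "mcc", "f1", "pc1")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one metric with normalized coverage."""

    metric: str
    r: float
    n: int
    t_stat: float
    p_value: float

    def as_dict(self) -> dict:
        return {"metric": self.metric, "r": self.r, "n": self.n, "t_stat": self.t_stat, "p_value": self.p_value}


@dataclass(frozen=True)
class CovRegressionFit:
    """OLS line of one metric on normalized coverage, with per-model residuals.

    The line is fitted on the COV < 100 subset only; ``residuals`` covers
    every model in the table that has the metric, keyed by model_uid.
    ``used_uids`` identifies the fitting subset.
    """

    metric: str
    slope: float
    intercept: float
    residuals: dict[int, float]
    used_uids: tuple[int, ...]
    n_used: int
    residuals_normal: bool | None = None

    def predict(self, z: float) -> float:
        return self.intercept + self.slope * z

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "slope": self.slope,
            "intercept": self.intercept,
            "n_used": self.n_used,
            "residuals_normal": self.residuals_normal,
            "residuals": {str(k): v for k, v in self.residuals.items()},
        }


@dataclass(frozen=True)
class AdjustedEstimate:
    """One model's metric projected to a target coverage."""

    model_uid: int
    metric: str
    target_cov: float
    estimate: float


def _cov_subset(table: ModelTable, metric: str) -> tuple[list[int], np.ndarray, np.ndarray]:
    """(uids, cov, y) over models with COV strictly below 100 and the metric present."""
    uids, cov, y = [], [], []
    for r in table:
        v = r.metric(metric)
        if r.cov < 100 and v is not None:
            uids.append(r.model_uid)
            cov.append(r.cov)
            y.append(v)
    return uids, np.asarray(cov, dtype=float), np.asarray(y, dtype=float)


def pearson_p_value(r: float, n: int) -> tuple[float, float]:
    """Two-sided p for a Pearson r at sample size n via t with n-2 df."""
    if n < 3:
        raise InsufficientDataError(f"need n >= 3 for a correlation test, got {n}")
    if not -1 <= r <= 1:
        raise ValidationError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1:
        return np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(t), float(2 * stats.t.sf(abs(t), df=n - 2))


def correlate_cov(table: ModelTable, params: JohnsonSbParams, metric: str) -> CorrelationResult:
    """Pearson correlation of a metric with Sb-normalized COV (< 100% models only)."""
    uids, cov, y = _cov_subset(table, metric)
    if len(uids) < 3:
        raise InsufficientDataError(
            f"metric {metric!r}: need >= 3 models with cov < 100, got {len(uids)}"
        )
    z = sb_transform(cov, params)
    if np.std(z) == 0 or np.std(y) == 0:
        raise DegenerateDataError(f"metric {metric!r}: zero variance in regressor or response")
    r = float(np.corrcoef(z, y)[0, 1])
    t, p = pearson_p_value(r, len(uids))
    return CorrelationResult(metric=metric, r=r, n=len(uids), t_stat=t, p_value=p)


def fit_cov_line(
    table: ModelTable,
    params: JohnsonSbParams,
    metric: str,
    *,
    check_residual_normality: bool = True,
) -> CovRegressionFit:
    """OLS of a metric on normalized COV over the sub-100%-coverage models.

    Residuals are computed for every model in the table carrying the metric,
    including the full-coverage ones excluded from fitting (Sb(100) is finite
    because the fitted upper bound exceeds 100).
    """
    uids, cov, y = _cov_subset(table, metric)
    if len(uids) < 3:
        raise InsufficientDataError(
            f"metric {metric!r}: need >= 3 models with cov < 100, got {len(uids)}"
        )
    z = sb_transform(cov, params)
    if np.allclose(np.std(z), 0):
        raise DegenerateDataError(f"metric {metric!r}: zero variance in transformed coverage")

    ols = sm.OLS(y, sm.add_constant(z)).fit()
    intercept, slope = float(ols.params[0]), float(ols.params[1])

    residuals: dict[int, float] = {}
    for rec in table:
        v = rec.metric(metric)
        if v is None:
            continue
        residuals[rec.model_uid] = float(v - (intercept + slope * sb_transform(rec.cov, params)))

    normal_flag: bool | None = None
    if check_residual_normality and len(uids) >= 5:
        from .diagnostics import qq_diagnostic  # deferred: diagnostics is a leaf module

        fit_resid = np.array([residuals[u] for u in uids])
        normal_flag = qq_diagnostic(fit_resid).in_band

    return CovRegressionFit(
        metric=metric,
        slope=slope,
        intercept=intercept,
        residuals=residuals,
        used_uids=tuple(uids),
        n_used=len(uids),
        residuals_normal=normal_flag,
    )


def project_to_cov(
    fit: CovRegressionFit,
    model_uid: int,
    target_cov: float,
    params: JohnsonSbParams,
) -> AdjustedEstimate:
    """Slide one model along the fitted line to a target coverage.

    The model's residual is preserved, so projecting to its own observed
    coverage reproduces the observed metric exactly.
    """
    if model_uid not in fit.residuals:
        raise LookupError(
            f"model_uid={model_uid} has no residual for metric {fit.metric!r}; "
            f"available: {sorted(fit.residuals)[:10]}..."
        )
    z = sb_transform(target_cov, params)  # raises DomainError outside (lower, upper)
    estimate = fit.predict(z) + fit.residuals[model_uid]
    return AdjustedEstimate(model_uid=model_uid, metric=fit.metric, target_cov=float(target_cov), estimate=float(estimate))


def rank_at_full_coverage(
    table: ModelTable,
    params: JohnsonSbParams,
    metrics: tuple[str, ...] = DEFAULT_RANK_METRICS,
    *,
    fits: dict[str, CovRegressionFit] | None = None,
    target_cov: float = 100.0,
    top_k: int | None = None,
    pc1_mode: str = "direct",
    pca: PCAResult | None = None,
) -> pd.DataFrame:
    """Estimate every model's metrics at a common coverage and rank them.

    Each metric is fitted on its own complete-case sub-100%-COV subset and
    every model carrying the metric is projected to ``target_cov``.  The
    ranking is by estimated PC1 descending (when present, else the first
    metric), ties broken by estimated BA then model_uid.

    ``pc1_mode='direct'`` projects the observed PC1 scores like any metric;
    ``pc1_mode='recompute'`` instead recomputes PC1 from the projected
    BA/MCC/F1 using the observed-data standardization and loadings (requires
    ``pca``); the two agree when the PCA metrics are all projected with
    their own lines.
    """
    if pc1_mode not in ("direct", "recompute"):
        raise ValidationError(f"pc1_mode must be 'direct' or 'recompute', got {pc1_mode!r}")
    if fits is None:
        fit_metrics = tuple(m for m in metrics if not (m == "pc1" and pc1_mode == "recompute"))
        fits = {m: fit_cov_line(table, params, m, check_residual_normality=False) for m in fit_metrics}

    rows = []
    for rec in table:
        row: dict = {
            "model_uid": rec.model_uid,
            "project": rec.project,
            "phase": rec.phase,
            "team": rec.team,
            "tool_name": rec.tool_name,
            "cov": rec.cov,
        }
        for m in metrics:
            if m == "pc1" and pc1_mode == "recompute":
                continue
            if rec.metric(m) is None:
                row[f"estimated_{m}"] = np.nan
            else:
                row[f"estimated_{m}"] = project_to_cov(fits[m], rec.model_uid, target_cov, params).estimate
        rows.append(row)
    out = pd.DataFrame(rows)

    if "pc1" in metrics and pc1_mode == "recompute":
        if pca is None:
            raise ValidationError("pc1_mode='recompute' requires the fitted PCAResult")
        proj = out[[f"estimated_{m}" for m in pca.metrics]].to_numpy(dtype=float)
        out["estimated_pc1"] = pca.transform(proj)[:, 0]

    sort_cols, ascending = [], []
    for col in ("estimated_pc1", "estimated_ba"):
        if col in out.columns:
            sort_cols.append(col)
            ascending.append(False)
    if not sort_cols:  # rank by the first requested metric
        sort_cols.append(f"estimated_{metrics[0]}")
        ascending.append(False)
    sort_cols.append("model_uid")
    ascending.append(True)
    out = out.sort_values(sort_cols, ascending=ascending, kind="mergesort").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.head(top_k) if top_k is not None else out


def cov_sweep(
    fits: dict[str, CovRegressionFit],
    model_uid: int,
    cov_grid,
    params: JohnsonSbParams,
) -> pd.DataFrame:
    """Projected metric curves for one model over a grid of coverages.

    Returns a long-format frame (cov, metric, estimate); each curve is
    linear in transformed-coverage space by construction.
    """
    grid = np.asarray(list(cov_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("cov_grid must contain at least one coverage value")
    rows = []
    for m, fit in fits.items():
        for c in grid:
            est = project_to_cov(fit, model_uid, float(c), params)
            rows.append({"cov": float(c), "metric": m, "estimate": est.estimate})
    return pd.DataFrame(rows)


def correlations_to_json(results: dict[str, CorrelationResult]) -> str:
    return json.dumps({m: r.as_dict() for m, r in results.items()}, indent=2)
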