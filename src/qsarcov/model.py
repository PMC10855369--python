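"""Model/Results interface for the coverage-standardized reanalysis.

:class:`CoverageStandardizer` is constructed from a benchmark table (a
:class:`~qsarcov.table.ModelTable`, a DataFrame, or a CSV on disk) and its
:meth:`~CoverageStandardizer.fit` runs the whole analysis:

1.  backfill F1 from PPV/sensitivity where missing;
2.  normal quantile diagnostics of each evaluation index and of raw and
    normalized coverage;
3.  PCA of BA/MCC/F1 on the correlation matrix, PC1 attached as the
    composite index;
4.  Johnson Sb normalization of coverage (fitted, or the fixed printed
    transform);
5.  Pearson correlation of each index with normalized coverage (sub-100%
    models), two-sided t test;
6.  per-index least-squares lines and residuals;
7.  projection of every model to 100% (or any) coverage and ranking.

The returned :class:`CoverageStandardizationResults` carries the fitted
pieces and exposes ``estimates_at``, ``rank``, ``sweep`` and ``summary``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjustment, composite, diagnostics
from .errors import InsufficientDataError, ValidationError
from .johnson import PRINTED_COV_PARAMS, JohnsonSbParams, fit_sb, sb_transform
from .table import ModelTable, backfill_f1, read_model_table

__all__ = ["CoverageStandardizer", "CoverageStandardizationResults"]


class CoverageStandardizer:
    """Coverage-standardization model for a benchmark results table.

    Parameters
    ----------
    table : ModelTable
        Per-model records with metrics and coverage.
    metrics : tuple of str
        Performance metrics entering the PCA and the adjustment
        (default BA, MCC, F1).
    include_pc1 : bool
        Add the PC1 composite to the adjusted/ranked indices.
    johnson : "printed", "fit", or JohnsonSbParams
        Coverage normalization: the fixed published transform, a
        quantile-method fit to the observed coverages, or explicit
        parameters.
    sb_fit_excludes_full_cov : bool
        When fitting, drop the COV = 100 point mass from the Sb fit
        (default False: the point mass is part of the distribution and the
        fitted upper bound lands above 100).
    alpha : float
        Level for the quantile-plot confidence bands.
    """

    def __init__(
        self,
        table: ModelTable,
        *,
        metrics: tuple[str, ...] = ("ba", "mcc", "f1"),
        include_pc1: bool = True,
        johnson: str | JohnsonSbParams = "printed",
        sb_fit_excludes_full_cov: bool = False,
        alpha: float = 0.05,
    ) -> None:
        if len(table) == 0:
            raise ValidationError("cannot analyze an empty table")
        self.table = table
        self.metrics = tuple(metrics)
        self.include_pc1 = include_pc1
        self.johnson = johnson
        self.sb_fit_excludes_full_cov = sb_fit_excludes_full_cov
        self.alpha = alpha

    @classmethod
    def from_csv(cls, path: str | Path, schema_config=None, **kwargs) -> "CoverageStandardizer":
        return cls(read_model_table(path, schema_config), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CoverageStandardizer":
        import tempfile

        # reuse the CSV reader's scale detection and validation
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh, index=False)
            tmp = fh.name
        try:
            table = read_model_table(tmp)
        finally:
            Path(tmp).unlink(missing_ok=True)
        table.provenance["source"] = "<dataframe>"
        return cls(table, **kwargs)

    def _resolve_johnson(self, covs: np.ndarray) -> JohnsonSbParams:
        if isinstance(self.johnson, JohnsonSbParams):
            return self.johnson
        if self.johnson == "printed":
            return PRINTED_COV_PARAMS
        if self.johnson == "fit":
            sample = covs[covs < 100] if self.sb_fit_excludes_full_cov else covs
            return fit_sb(sample)
        raise ValidationError(f"johnson must be 'printed', 'fit' or JohnsonSbParams, got {self.johnson!r}")

    def fit(self, pc1_mode: str = "direct") -> "CoverageStandardizationResults":
        table = backfill_f1(self.table)
        covs = np.array([r.cov for r in table])

        diags: dict[str, diagnostics.QQDiagnostic] = {}
        for m in self.metrics + ("cov",):
            vals = [r.metric(m) for r in table if r.metric(m) is not None]
            if len(vals) >= 5:
                diags[m] = diagnostics.qq_diagnostic(vals, alpha=self.alpha)

        pca = composite.pc1_index(table, self.metrics)
        if self.include_pc1:
            table = composite.attach_pc1(table, pca)
        indices = self.metrics + (("pc1",) if self.include_pc1 else ())

        sb_params = self._resolve_johnson(covs)
        sub = covs[covs < 100]
        if sub.size >= 5:
            diags["sb_cov_sub100"] = diagnostics.qq_diagnostic(
                sb_transform(sub, sb_params), alpha=self.alpha
            )

        n_sub = int((covs < 100).sum())
        correlations: dict[str, adjustment.CorrelationResult] = {}
        fits: dict[str, adjustment.CovRegressionFit] = {}
        skipped_reason = None
        if n_sub >= 3:
            for m in indices:
                correlations[m] = adjustment.correlate_cov(table, sb_params, m)
                fits[m] = adjustment.fit_cov_line(table, sb_params, m)
        else:
            skipped_reason = (
                f"coverage analysis skipped: only {n_sub} model(s) with cov < 100 "
                "(need >= 3); estimates equal observed values"
            )

        return CoverageStandardizationResults(
            model=self,
            table=table,
            pca=pca,
            sb_params=sb_params,
            correlations=correlations,
            fits=fits,
            diagnostics=diags,
            indices=indices,
            pc1_mode=pc1_mode,
            skipped_reason=skipped_reason,
        )


@dataclass
class CoverageStandardizationResults:
    """Fitted artifacts of the coverage-standardized reanalysis."""

    model: CoverageStandardizer
    table: ModelTable
    pca: composite.PCAResult
    sb_params: JohnsonSbParams
    correlations: dict[str, adjustment.CorrelationResult]
    fits: dict[str, adjustment.CovRegressionFit]
    diagnostics: dict[str, diagnostics.QQDiagnostic]
    indices: tuple[str, ...]
    pc1_mode: str = "direct"
    skipped_reason: str | None = None

    # -- estimates ---------------------------------------------------------
    def estimates_at(self, target_cov: float = 100.0) -> pd.DataFrame:
        """Every model's indices projected to a common coverage."""
        if not self.fits:
            return self._observed_frame()
        return adjustment.rank_at_full_coverage(
            self.table, self.sb_params, self.indices,
            fits=self.fits if self.pc1_mode == "direct" else None,
            target_cov=target_cov, pc1_mode=self.pc1_mode, pca=self.pca,
        )

    def rank(self, top_k: int | None = None, target_cov: float = 100.0) -> pd.DataFrame:
        """Coverage-fair ranking (estimated PC1 descending) at target coverage."""
        return self.estimates_at(target_cov).head(top_k) if top_k else self.estimates_at(target_cov)

    def _observed_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.table:
            row = {
                "model_uid": r.model_uid, "project": r.project, "phase": r.phase,
                "team": r.team, "tool_name": r.tool_name, "cov": r.cov,
            }
            for m in self.indices:
                row[f"estimated_{m}"] = r.metric(m)
            rows.append(row)
        out = pd.DataFrame(rows)
        sort_cols = [c for c in ("estimated_pc1", "estimated_ba") if c in out.columns] or [
            f"estimated_{self.indices[0]}"
        ]
        out = out.sort_values(sort_cols + ["model_uid"], ascending=[False] * len(sort_cols) + [True],
                              kind="mergesort").reset_index(drop=True)
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        return out

    def sweep(self, model_uid: int | None = None, cov_grid=(100.0, 90.0, 60.0, 30.0)) -> pd.DataFrame:
        """Projected index curves over a coverage grid (default: the top model)."""
        if not self.fits:
            raise InsufficientDataError("no coverage fits available (all models at full coverage)")
        if model_uid is None:
            model_uid = int(self.rank(top_k=1)["model_uid"].iloc[0])
        return adjustment.cov_sweep(self.fits, model_uid, cov_grid, self.sb_params)

    # -- presentation ------------------------------------------------------
    def summary(self, top_k: int = 10) -> str:
        """Human-readable summary in the spirit of a statsmodels results table."""
        lines = [
            "Coverage-standardized benchmark reanalysis",
            "=" * 58,
            f"models: {len(self.table)}   "
            f"full-coverage: {sum(1 for r in self.table if r.cov == 100)}   "
            f"indices: {', '.join(self.indices)}",
            f"Johnson Sb[COV]: lower={self.sb_params.lower:.4g}, upper={self.sb_params.upper:.4g}, "
            f"scale={self.sb_params.scale:.4g}, location={self.sb_params.location:.4g}",
            f"PC1 variance fraction: {self.pca.variance_fraction[0]:.3f}   "
            f"loadings: "
            + ", ".join(f"{m}={l:.3f}" for m, l in zip(self.pca.metrics, self.pca.pc1_loadings)),
            "",
        ]
        if self.correlations:
            lines.append("Correlation with normalized COV (models below 100% coverage)")
            lines.append(f"{'index':>6} {'r':>8} {'n':>5} {'t':>8} {'p (2-sided)':>12}")
            for m, c in self.correlations.items():
                lines.append(f"{m:>6} {c.r:>8.3f} {c.n:>5d} {c.t_stat:>8.3f} {c.p_value:>12.4f}")
            lines.append("")
            lines.append("Least-squares lines  (index = intercept + slope * Sb[COV])")
            for m, f in self.fits.items():
                lines.append(
                    f"{m:>6}: slope={f.slope:>9.3f}  intercept={f.intercept:>9.3f}  "
                    f"n={f.n_used}  residuals normal: {f.residuals_normal}"
                )
        else:
            lines.append(self.skipped_reason or "coverage analysis skipped")
        lines.append("")
        lines.append(f"Top {top_k} models at 100% coverage (by estimated PC1)")
        ranked = self.rank(top_k=top_k)
        display = ranked[["rank", "team", "tool_name"]].copy()
        for m in self.indices:
            col = f"estimated_{m}"
            if col in ranked:
                decimals = 2 if m in ("mcc", "pc1") else 1
                display[col] = ranked[col].round(decimals)
        lines.append(display.to_string(index=False))
        return "\n".join(lines)

    def plot_fit(self, metric: str, ax=None):
        """Scatter of a metric against normalized COV with the fitted line."""
        import matplotlib.pyplot as plt

        if metric not in self.fits:
            raise KeyError(f"no fit for metric {metric!r}")
        fit = self.fits[metric]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        z, y, full = [], [], []
        for r in self.table:
            v = r.metric(metric)
            if v is None:
                continue
            z.append(sb_transform(r.cov, self.sb_params))
            y.append(v)
            full.append(r.cov == 100)
        z, y, full = np.asarray(z), np.asarray(y), np.asarray(full)
        ax.plot(z[~full], y[~full], "ko", ms=4, label="COV < 100%")
        ax.plot(z[full], y[full], "o", color="0.6", ms=4, label="COV = 100%")
        grid = np.linspace(z.min(), z.max(), 50)
        ax.plot(grid, fit.intercept + fit.slope * grid, "r-", lw=1.2, label="least squares")
        ax.set_xlabel("Johnson Sb[COV]")
        ax.set_ylabel(metric)
        ax.legend(fontsize=8)
        return ax

    def plot_qq(self, key: str, ax=None):
        if key not in self.diagnostics:
            raise KeyError(f"no diagnostic {key!r}; available: {sorted(self.diagnostics)}")
        return diagnostics.plot_qq(self.diagnostics[key], ax=ax, title=key)
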