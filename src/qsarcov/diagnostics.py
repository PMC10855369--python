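"""Normal quantile-plot diagnostics with 95% confidence bands.

The analysis screens each evaluation index (and the regression residuals)
for approximate normality by eye: sorted sample values are plotted against
normal quantiles at Blom plotting positions, together with a confidence
band around the fitted normal line; the sample "passes" when every point
stays inside the band.  Two band constructions are available:

``lilliefors`` (default)
    A simultaneous band derived from the 5% Lilliefors critical value for
    the Kolmogorov-Smirnov distance with estimated mean and SD
    (Dallal-Wilkinson approximation).  Its joint coverage for truly normal
    samples is close to the nominal 1 - alpha, so the all-points-inside
    verdict is calibrated.
``pointwise``
    Classical per-point band from the beta distribution of uniform order
    statistics.  Each point has 1 - alpha coverage, but the probability
    that *all* n points stay inside is noticeably below 1 - alpha, so this
    band is stricter than its nominal level as a joint test.

The verdict is advisory: callers get the flag and the per-point violations,
nothing halts on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .adjustment import CovRegressionFit

__all__ = ["QQDiagnostic", "qq_diagnostic", "residual_normality"]


@dataclass(frozen=True)
class QQDiagnostic:
    """Coordinates and verdict of one normal quantile plot."""

    sample: np.ndarray        # sorted ascending
    theoretical: np.ndarray   # fitted-normal quantiles at plotting positions
    lower: np.ndarray         # band lower edge per point
    upper: np.ndarray         # band upper edge per point
    in_band: bool
    violations: tuple[int, ...]   # indices (into the sorted sample) outside the band
    alpha: float
    band: str
    degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample": self.sample,
                "theoretical": self.theoretical,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def blom_positions(n: int) -> np.ndarray:
    """Blom plotting positions (i - 3/8) / (n + 1/4)."""
    i = np.arange(1, n + 1)
    return (i - 0.375) / (n + 0.25)


def lilliefors_critical_value(n: int, alpha: float = 0.05) -> float:
    """Critical KS distance for normality with estimated parameters.

    Dallal-Wilkinson approximation at the 5% level; other levels use the
    asymptotic Kolmogorov scaling relative to 5% and are approximate.
    """
    if n < 5:
        raise InsufficientDataError("critical value defined for n >= 5")
    c05 = 0.895 / (np.sqrt(n) * (1 - 0.01 / np.sqrt(n) + 0.85 / n))
    if alpha == 0.05:
        return float(c05)
    return float(c05 * np.sqrt(np.log(2 / alpha) / np.log(2 / 0.05)))


def _band(n: int, alpha: float, band: str, m: float, s: float) -> tuple[np.ndarray, np.ndarray]:
    p = blom_positions(n)
    if band == "lilliefors":
        c = lilliefors_critical_value(n, alpha)
        lo_p, hi_p = p - c, p + c
        lower = np.where(lo_p > 0, stats.norm.ppf(np.clip(lo_p, 1e-15, 1)), -np.inf)
        upper = np.where(hi_p < 1, stats.norm.ppf(np.clip(hi_p, 0, 1 - 1e-15)), np.inf)
    elif band == "pointwise":
        i = np.arange(1, n + 1)
        lower = stats.norm.ppf(stats.beta.ppf(alpha / 2, i, n - i + 1))
        upper = stats.norm.ppf(stats.beta.ppf(1 - alpha / 2, i, n - i + 1))
    else:
        raise ValidationError(f"unknown band method {band!r}; use 'lilliefors' or 'pointwise'")
    return m + s * lower, m + s * upper


def qq_diagnostic(samples, alpha: float = 0.05, band: str = "lilliefors") -> QQDiagnostic:
    """Normal quantile plot of a sample with a 1 - alpha confidence band.

    The normal line is fitted by the sample mean and SD (ddof = 1), which
    makes the verdict invariant to positive affine transforms of the data.
    A constant sample is flagged degenerate with a vacuously true verdict.
    """
    x = np.sort(np.asarray(list(samples), dtype=float))
    if x.size < 5:
        raise InsufficientDataError(f"need >= 5 samples, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise ValidationError("samples must be finite")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    n = x.size
    m, s = float(x.mean()), float(x.std(ddof=1))
    p = blom_positions(n)
    if s == 0:
        theo = np.full(n, m)
        band_half = np.full(n, np.inf)
        return QQDiagnostic(
            sample=x, theoretical=theo, lower=theo - band_half, upper=theo + band_half,
            in_band=True, violations=(), alpha=alpha, band=band, degenerate=True,
        )
    theoretical = m + s * stats.norm.ppf(p)
    lower, upper = _band(n, alpha, band, m, s)
    outside = np.nonzero((x < lower) | (x > upper))[0]
    return QQDiagnostic(
        sample=x, theoretical=theoretical, lower=lower, upper=upper,
        in_band=outside.size == 0, violations=tuple(int(i) for i in outside),
        alpha=alpha, band=band,
    )


def residual_normality(fit: "CovRegressionFit", alpha: float = 0.05, band: str = "lilliefors") -> QQDiagnostic:
    """QQ diagnostic of a coverage-line fit's residuals (fitting subset only)."""
    resid = [fit.residuals[u] for u in fit.used_uids]
    return qq_diagnostic(resid, alpha=alpha, band=band)


def plot_qq(diag: QQDiagnostic, ax=None, title: str | None = None):
    """Render a QQDiagnostic with matplotlib; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(diag.theoretical, diag.sample, "ko", ms=4)
    ax.plot(diag.theoretical, diag.theoretical, "r-", lw=1)
    finite_lo = np.where(np.isfinite(diag.lower), diag.lower, np.nan)
    finite_hi = np.where(np.isfinite(diag.upper), diag.upper, np.nan)
    ax.plot(diag.theoretical, finite_lo, "r--", lw=0.8)
    ax.plot(diag.theoretical, finite_hi, "r--", lw=0.8)
    ax.set_xlabel("normal quantile")
    ax.set_ylabel("sample quantile")
    if title:
        ax.set_title(title)
    return ax
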