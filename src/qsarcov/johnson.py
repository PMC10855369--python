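"""Johnson Sb normalization of the coverage-rate distribution.

Coverage rates (COV, percent of target compounds a model predicts) are
bounded and heavily left-skewed, with a point mass at 100%.  Pearson
correlation and least-squares machinery downstream assume roughly normal
regressors, so COV is mapped to an unbounded, approximately normal scale
with the Johnson Sb transform

    z = location + scale * ln((x - lower) / (upper - x)),

the four-parameter bounded member of the Johnson system (lower = epsilon,
upper = epsilon + lambda, scale = delta, location = gamma in the classical
notation).  The transform is a strictly increasing bijection from
(lower, upper) onto the real line, so sample ranks are preserved.

Two modes are supported: a *reproduction* transform with fixed published
constants (``PRINTED_COV_PARAMS``), and fitting from data via the
Slifker-Shapiro quantile-matching method (optionally refined by maximum
likelihood when the bounds are user-fixed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "JohnsonSbParams",
    "PRINTED_COV_PARAMS",
    "sb_transform",
    "sb_inverse",
    "fit_sb",
]

# Values within this distance of a bound are rejected rather than clamped:
# silent clamping would distort the downstream regression.
_BOUND_GUARD = 1e-9


@dataclass(frozen=True)
class JohnsonSbParams:
    """Parameters of one Sb transform.

    Attributes
    ----------
    lower, upper : float
        Support bounds (epsilon and epsilon + lambda), in the units of the
        raw variable.
    scale : float
        Multiplier delta applied to the log term; must be positive.
    location : float
        Additive constant gamma.
    """

    lower: float
    upper: float
    scale: float
    location: float

    def __post_init__(self) -> None:
        if not (self.upper > self.lower):
            raise DomainError(f"upper bound ({self.upper}) must exceed lower bound ({self.lower})")
        if not (self.scale > 0):
            raise DomainError(f"scale must be positive, got {self.scale}")

    def to_json(self) -> str:
        return json.dumps(
            {"lower": self.lower, "upper": self.upper, "scale": self.scale, "location": self.location}
        )

    @classmethod
    def from_json(cls, s: str) -> "JohnsonSbParams":
        d = json.loads(s)
        return cls(lower=d["lower"], upper=d["upper"], scale=d["scale"], location=d["location"])


#: Fixed reproduction transform for the benchmark coverage distribution:
#: z = ln((COV - 4.9) / (100.063 - COV)) * 0.111 - 0.655.
PRINTED_COV_PARAMS = JohnsonSbParams(lower=4.9, upper=100.063, scale=0.111, location=-0.655)


def sb_transform(x, params: JohnsonSbParams = PRINTED_COV_PARAMS):
    """Map bounded values to the normalized scale.

    Accepts a scalar or array; strictly increasing on (lower, upper).
    Values at or beyond a bound (within 1e-9) raise :class:`DomainError`.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise DomainError("sb_transform requires finite input")
    if np.any(arr <= params.lower + _BOUND_GUARD):
        bad = np.atleast_1d(arr)[np.atleast_1d(arr) <= params.lower + _BOUND_GUARD][0]
        raise DomainError(f"value {bad} at or below the lower bound {params.lower}")
    if np.any(arr >= params.upper - _BOUND_GUARD):
        bad = np.atleast_1d(arr)[np.atleast_1d(arr) >= params.upper - _BOUND_GUARD][0]
        raise DomainError(f"value {bad} at or above the upper bound {params.upper}")
    z = params.scale * np.log((arr - params.lower) / (params.upper - arr)) + params.location
    return float(z) if np.isscalar(x) or arr.ndim == 0 else z


def sb_inverse(z, params: JohnsonSbParams = PRINTED_COV_PARAMS):
    """Inverse transform: normalized value back to the bounded scale.

    Defined for all finite z; the image is strictly inside (lower, upper).
    """
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise DomainError("sb_inverse requires finite input")
    # logistic form: x = lower + (upper - lower) / (1 + exp(-(z - location)/scale))
    x = params.lower + (params.upper - params.lower) * stats.logistic.cdf(
        (arr - params.location) / params.scale
    )
    # extreme z saturate in floating point; keep the image transformable by
    # holding it strictly clear of the rejection guard around each bound
    x = np.clip(x, params.lower + 2 * _BOUND_GUARD, params.upper - 2 * _BOUND_GUARD)
    return float(x) if np.isscalar(z) or arr.ndim == 0 else x


def _slifker_shapiro(samples: np.ndarray, z_select: float) -> JohnsonSbParams:
    """Quantile-matching Sb fit using four symmetric normal quantiles.

    Matches the sample quantiles at Phi(+-z), Phi(+-3z) to the Johnson Sb
    quantile function (Slifker & Shapiro's percentile method).
    """
    z = z_select
    probs = stats.norm.cdf([-3 * z, -z, z, 3 * z])
    x_m3, x_m1, x_p1, x_p3 = np.quantile(samples, probs)
    m = x_p3 - x_p1
    n = x_m1 - x_m3
    p = x_p1 - x_m1
    if p <= 0 or m <= 0 or n <= 0:
        raise DegenerateDataError("sample quantiles are not strictly increasing; cannot fit Sb")
    pm, pn = p / m, p / n
    ratio = p * p / (m * n)
    if ratio <= 1:
        # The quantile geometry points to an unbounded (Su/Sl) family; for a
        # genuinely bounded variable this happens only for pathological samples.
        raise DegenerateDataError(
            "quantile spacing inconsistent with a bounded (Sb) distribution; "
            f"p^2/(m n) = {ratio:.4f} <= 1"
        )
    half = 0.5 * math.sqrt((1 + pm) * (1 + pn))
    delta = z / math.acosh(half)
    gamma = delta * math.asinh((pn - pm) * math.sqrt((1 + pm) * (1 + pn) - 4) / (2 * (ratio - 1)))
    lam = p * math.sqrt(((1 + pm) * (1 + pn) - 2) ** 2 - 4) / (ratio - 1)
    eps = 0.5 * (x_p1 + x_m1) - lam / 2 + p * (pn - pm) / (2 * (ratio - 1))
    return JohnsonSbParams(lower=eps, upper=eps + lam, scale=delta, location=gamma)


def _fixed_bounds_mle(x: np.ndarray, lower: float, upper: float) -> JohnsonSbParams:
    """MLE of scale/location with the bounds held fixed.

    For a normal target the MLE is the moment match on the logits
    y = ln((x - lower)/(upper - x)): scale = 1/sd(y), location = -mean(y)/sd(y).
    """
    y = np.log((x - lower) / (upper - x))
    sd = y.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("logit-transformed samples are constant")
    return JohnsonSbParams(lower=lower, upper=upper, scale=1.0 / sd, location=-y.mean() / sd)


def fit_sb(
    samples: Iterable[float],
    *,
    z_select: float = 0.524,
    bounds: tuple[float, float] | None = None,
    method: str = "quantile+mle",
    bound_margin: float = 1e-3,
) -> JohnsonSbParams:
    """Fit Sb parameters so the transformed sample is approximately N(0, 1).

    Parameters
    ----------
    samples : iterable of float
        At least 10 distinct finite values.
    z_select : float
        Normal quantile used to pick the four matching percentiles
        (default 0.524, the customary choice for the percentile method).
    bounds : (lower, upper), optional
        Fix the support bounds and estimate only scale/location by maximum
        likelihood on the logit-transformed sample.
    method : {"quantile+mle", "quantile"}
        ``"quantile"`` is the pure Slifker-Shapiro percentile match;
        the default additionally polishes all four parameters by maximum
        likelihood (the percentile match alone can place a bound inside the
        data range and fits the tails poorly).
    bound_margin : float
        Minimum clearance of each fitted bound from the data extremes,
        relative to the sample range.  A bound fitted closer than this
        (e.g. when the sample has a point mass at its maximum) is pushed
        out to the margin and scale/location are re-estimated with the
        bounds fixed; without the margin the transform would be unusable
        at the extreme data values.

    Raises
    ------
    InsufficientDataError
        Fewer than 10 distinct samples.
    DegenerateDataError
        All samples identical (or quantile spacing unusable).
    DomainError
        A sample falls outside user-fixed bounds.
    """
    x = np.asarray(list(samples), dtype=float)
    if np.any(~np.isfinite(x)):
        raise DomainError("samples must be finite")
    if np.unique(x).size < 2 and x.size >= 1:
        raise DegenerateDataError("all samples identical; cannot fit a distribution")
    if np.unique(x).size < 10:
        raise InsufficientDataError(f"need >= 10 distinct samples, got {np.unique(x).size}")
    if method not in ("quantile", "quantile+mle"):
        raise DomainError(f"unknown fitting method {method!r}")

    if bounds is not None:
        lower, upper = bounds
        if not upper > lower:
            raise DomainError("bounds must satisfy upper > lower")
        if np.any(x <= lower) or np.any(x >= upper):
            raise DomainError("samples outside the user-fixed bounds")
        return _fixed_bounds_mle(x, lower, upper)

    params = _slifker_shapiro(x, z_select)
    if method == "quantile+mle":
        with np.errstate(all="ignore"):
            a, b, loc, lam = stats.johnsonsb.fit(
                x, params.location, params.scale, loc=params.lower, scale=params.upper - params.lower
            )
        if lam > 0 and b > 0:
            params = JohnsonSbParams(lower=float(loc), upper=float(loc + lam), scale=float(b), location=float(a))

    # a bound sitting on the data (ties or a point mass at an extreme) makes
    # the transform unusable there; push it out by the margin and refit
    margin = bound_margin * (x.max() - x.min())
    lower, upper = params.lower, params.upper
    adjust = False
    if lower >= x.min() - 10 * _BOUND_GUARD:
        lower, adjust = x.min() - margin, True
    if upper <= x.max() + 10 * _BOUND_GUARD:
        upper, adjust = x.max() + margin, True
    if adjust:
        params = _fixed_bounds_mle(x, lower, upper)
    return params
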