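"""Gaussianity assessment and Box-Cox transformation.

The normality check is the Anderson-Darling test in its
estimated-parameters (composite) form: the statistic is computed against a
normal with sample mean and sample SD, corrected for small samples with
the factor (1 + 0.75/n + 2.25/n^2), and converted to a p-value with the
published piecewise exponential approximation for that case. When the raw
data fail the test, a Box-Cox transform (profile-likelihood lambda on
[-3, 3], with a positivity shift when needed) is attempted and the test is
repeated on the transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

VERDICT_GAUSSIAN_RAW = "gaussian_raw"
VERDICT_GAUSSIAN_BOXCOX = "gaussian_after_boxcox"
VERDICT_NON_GAUSSIAN = "non_gaussian"

LAMBDA_BOUNDS = (-3.0, 3.0)


@dataclass(frozen=True)
class BoxCoxTransform:
    """A Box-Cox map y = ((x + shift)^lambda - 1)/lambda (log at lambda=0).

    ``shift`` repairs non-positive inputs; it is 0 when the data are
    already strictly positive. The map is strictly increasing for every
    lambda, so it preserves order and hence percentile identity.
    """

    lmbda: float
    shift: float = 0.0

    def forward(self, x) -> np.ndarray:
        z = np.asarray(x, dtype=float) + self.shift
        if np.any(z <= 0):
            raise ValueError("shifted values must be > 0 for Box-Cox")
        if self.lmbda == 0:
            return np.log(z)
        return (z**self.lmbda - 1.0) / self.lmbda

    def inverse(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.lmbda == 0:
            return np.exp(y) - self.shift
        base = np.maximum(self.lmbda * y + 1.0, 0.0)  # clamp at support edge
        return base ** (1.0 / self.lmbda) - self.shift


@dataclass(frozen=True)
class GaussianityVerdict:
    a_squared: float
    p_value: float
    alpha: float
    verdict: str
    transform: BoxCoxTransform | None = None
    a_squared_transformed: float | None = None
    p_value_transformed: float | None = None

    @property
    def lmbda(self) -> float | None:
        return None if self.transform is None else self.transform.lmbda

    @property
    def shift(self) -> float | None:
        return None if self.transform is None else self.transform.shift

    def to_record(self) -> dict:
        """JSON-ready record of the assessment."""
        return {
            "a_squared": self.a_squared,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "lambda": self.lmbda,
            "shift": self.shift,
            "a_squared_transformed": self.a_squared_transformed,
            "p_value_transformed": self.p_value_transformed,
        }


def _check(values, min_n: int = 8) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


def anderson_darling_normal(values) -> tuple[float, float]:
    """Anderson-Darling A^2 against a normal with estimated mean/SD, plus
    the composite-case p-value. Returns (a_squared, p_value); a_squared is
    the small-sample corrected statistic A^2*."""
    x = np.sort(_check(values))
    n = x.size
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: Anderson-Darling undefined")
    w = (x - x.mean()) / sd
    logcdf = stats.norm.logcdf(w)
    logsf = stats.norm.logsf(w)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (logcdf + logsf[::-1]))
    a2_star = a2 * (1.0 + 0.75 / n + 2.25 / n**2)
    # D'Agostino-Stephens piecewise p-value approximation (composite case)
    a = a2_star
    if a < 0.2:
        p = 1.0 - math.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    elif a < 0.34:
        p = 1.0 - math.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    elif a < 0.6:
        p = math.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a < 153.467:
        p = math.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    else:
        p = 0.0
    return float(a2_star), float(min(max(p, 0.0), 1.0))


def boxcox_mle(
    values, shift_unit: float = 0.01
) -> tuple[float, float, np.ndarray]:
    """Profile-likelihood Box-Cox fit on lambda in [-3, 3].

    When the sample contains values <= 0, a shift of -min(x) + shift_unit
    (one display-decimal unit of the analyte by convention) is applied
    first. Returns (lambda, shift, transformed values).
    """
    x = _check(values)
    shift = 0.0
    if x.min() <= 0:
        shift = -float(x.min()) + float(shift_unit)
    z = x + shift
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, z),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    t = BoxCoxTransform(lmbda=lam, shift=shift)
    return lam, shift, t.forward(x)


def boxcox_profile_loglik(values, lambdas, shift_unit: float = 0.01):
    """Profile log-likelihood over a lambda grid (diagnostic export)."""
    x = _check(values)
    shift = -float(x.min()) + float(shift_unit) if x.min() <= 0 else 0.0
    z = x + shift
    lambdas = np.asarray(lambdas, dtype=float)
    return np.array([stats.boxcox_llf(l, z) for l in lambdas])


def assess_gaussianity(
    values, alpha: float = 0.05, shift_unit: float = 0.01
) -> GaussianityVerdict:
    """Decide whether RI estimation may treat the data as Gaussian, raw or
    after Box-Cox. Transformation is attempted only when the raw test fails."""
    x = _check(values)
    a2, p = anderson_darling_normal(x)
    if p >= alpha:
        return GaussianityVerdict(a2, p, alpha, VERDICT_GAUSSIAN_RAW)
    lam, shift, z = boxcox_mle(x, shift_unit=shift_unit)
    transform = BoxCoxTransform(lmbda=lam, shift=shift)
    if np.std(z, ddof=1) == 0:
        return GaussianityVerdict(a2, p, alpha, VERDICT_NON_GAUSSIAN, transform)
    a2_t, p_t = anderson_darling_normal(z)
    verdict = VERDICT_GAUSSIAN_BOXCOX if p_t >= alpha else VERDICT_NON_GAUSSIAN
    return GaussianityVerdict(
        a2, p, alpha, verdict, transform,
        a_squared_transformed=a2_t, p_value_transformed=p_t,
    )


def qq_pairs(values) -> tuple[np.ndarray, np.ndarray]:
    """Numeric Q-Q diagnostic: (standard-normal theoretical quantiles at
    (i - 0.5)/n, ordered sample values). Plot-ready, not rendered."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return theo, x
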