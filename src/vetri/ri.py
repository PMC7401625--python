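"""Reference-interval estimation: nonparametric, parametric, and robust
limits with percentile-bootstrap confidence intervals.

A reference interval (RI) is the central ``coverage`` fraction (default
95%) of a healthy reference population, bounded by the lower and upper
reference limits (LRL, URL). Three estimators are provided:

* nonparametric - interpolated order statistics at ranks p(n+1);
* parametric ("standard") - mean +/- z * SD on a working scale that is
  either raw or Box-Cox transformed, back-transformed to analyte units;
* robust - iterated biweight location with biweight-midvariance scale,
  resistant to tail contamination, for moderate n.

Method selection follows sample size and distribution shape: n >= 120
takes the nonparametric route on raw data; 40 <= n < 120 the robust route
(raw scale if Gaussian, Box-Cox scale otherwise); 20 <= n < 40 the robust
route with a small-sample warning; below 20 no RI is computed.

``ReferenceIntervalEstimator`` packages the whole pipeline (Tukey outlier
removal -> gaussianity assessment -> method selection -> limit estimation
-> bootstrap CIs) as a scikit-learn estimator: ``fit`` ingests reference
values, fitted attributes carry the limits, and ``predict`` labels new
observations +1 (inside the interval) / -1 (outside).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .distributions import (
    VERDICT_GAUSSIAN_RAW,
    BoxCoxTransform,
    GaussianityVerdict,
    assess_gaussianity,
)
from .outliers import OutlierReport, remove_far_outliers

METHOD_NONPARAMETRIC = "nonparametric"
METHOD_PARAMETRIC = "parametric"
METHOD_ROBUST = "robust"

#: sample-size floors of the selection rule
N_NONPARAMETRIC = 120
N_ROBUST = 40
N_MIN = 20


@dataclass(frozen=True)
class DescriptiveSummary:
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float
    n: int


@dataclass
class ReferenceIntervalEstimate:
    """A computed RI with its provenance: method, transformation, bootstrap
    CIs on both limits, and the outlier screen's removal count."""

    analyte: str
    n_used: int
    method: str
    transformation: BoxCoxTransform | None
    lrl: float
    url: float
    lrl_ci: tuple[float, float] | None
    url_ci: tuple[float, float] | None
    coverage: float = 0.95
    removed_outliers: int = 0
    verdict: GaussianityVerdict | None = None
    outlier_report: OutlierReport | None = None
    small_sample_warning: bool = False
    descriptives: DescriptiveSummary | None = None
    metadata: dict = field(default_factory=dict)

    def to_record(self) -> dict:
        return {
            "analyte": self.analyte,
            "n": self.n_used,
            "method": self.method,
            "transformation": (
                None
                if self.transformation is None
                else {"lambda": self.transformation.lmbda, "shift": self.transformation.shift}
            ),
            "lrl": self.lrl,
            "url": self.url,
            "lrl_ci": list(self.lrl_ci) if self.lrl_ci else None,
            "url_ci": list(self.url_ci) if self.url_ci else None,
            "coverage": self.coverage,
            "removed_outliers": self.removed_outliers,
            "small_sample_warning": self.small_sample_warning,
        }


def _check(values, min_n: int = 1) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


def describe(values) -> DescriptiveSummary:
    """Sample mean, SD (n-1 denominator), median, min, max."""
    x = _check(values, 1)
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    return DescriptiveSummary(
        mean=float(x.mean()),
        sd=sd,
        median=float(np.median(x)),
        minimum=float(x.min()),
        maximum=float(x.max()),
        n=int(x.size),
    )


def nonparametric_ri(values, coverage: float = 0.95) -> tuple[float, float]:
    """Interpolated order statistics at ranks p(n+1), p = (1 -/+ coverage)/2.

    Ranks are clamped to [1, n], so at the minimal usable n the limits are
    the sample extremes. Requires n >= 2/(1 - coverage) - 1 (39 for 95%).
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    n_floor = int(np.ceil(2.0 / (1.0 - coverage))) - 1
    x = np.sort(_check(values, max(n_floor, 2)))
    n = x.size

    def at_rank(r: float) -> float:
        # ranks that are integers up to float noise are used as-is, so an
        # exact rank (e.g. 3.0 at n = 119) returns the pure order statistic
        if abs(r - round(r)) < 1e-9:
            r = float(round(r))
        r = min(max(r, 1.0), float(n))
        lo = int(np.floor(r))
        frac = r - lo
        if lo >= n:
            return float(x[-1])
        return float(x[lo - 1] + frac * (x[lo] - x[lo - 1]))

    p_low = round((1.0 - coverage) / 2.0, 12)
    return at_rank(p_low * (n + 1)), at_rank((1.0 - p_low) * (n + 1))


def parametric_ri(
    values,
    transformation: BoxCoxTransform | None = None,
    coverage: float = 0.95,
) -> tuple[float, float]:
    """Gaussian limits mean +/- z * SD on the working scale, back-transformed."""
    x = _check(values, 8)
    z = stats.norm.ppf((1.0 + coverage) / 2.0)
    w = transformation.forward(x) if transformation else x
    mu, sd = w.mean(), w.std(ddof=1)
    lo, hi = mu - z * sd, mu + z * sd
    if transformation:
        lo, hi = float(transformation.inverse(lo)), float(transformation.inverse(hi))
    return float(lo), float(hi)


def biweight_location_scale(
    values,
    c_location: float = 3.7,
    c_scale: float = 9.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, float]:
    """Iterated Tukey-biweight location and biweight-midvariance scale.

    The location starts at the median with a scaled-MAD spread and is
    iterated to a fixed point; the scale is the biweight midvariance
    (approximately consistent for sigma at the normal). A zero MAD
    degenerates to (median, 0).
    """
    x = _check(values, 2)
    t = float(np.median(x))
    mad = float(np.median(np.abs(x - t))) / 0.6745
    if mad == 0:
        return t, 0.0
    for _ in range(max_iter):
        u = (x - t) / (c_location * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        t_new = float(np.sum(w * x) / np.sum(w))
        if abs(t_new - t) <= tol * max(mad, 1e-12):
            t = t_new
            break
        t = t_new
    else:
        raise RuntimeError("biweight location did not converge")
    u = (x - t) / (c_scale * mad)
    inside = np.abs(u) < 1
    num = np.sum(((x - t) ** 2 * (1 - u**2) ** 4)[inside])
    den = np.sum(((1 - u**2) * (1 - 5 * u**2))[inside])
    n = x.size
    s = float(np.sqrt(n * num) / abs(den)) if den != 0 else 0.0
    return t, s


def robust_ri(
    values,
    transformation: BoxCoxTransform | None = None,
    coverage: float = 0.95,
    c_location: float = 3.7,
    c_scale: float = 9.0,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Robust limits: biweight location +/- z * biweight scale on the
    working scale, back-transformed. Degenerate (constant) input yields
    (value, value)."""
    x = _check(values, 2)
    z = stats.norm.ppf((1.0 + coverage) / 2.0)
    w = transformation.forward(x) if transformation else x
    t, s = biweight_location_scale(w, c_location=c_location, c_scale=c_scale, tol=tol)
    lo, hi = t - z * s, t + z * s
    if transformation:
        lo, hi = float(transformation.inverse(lo)), float(transformation.inverse(hi))
    return float(lo), float(hi)


def bootstrap_limit_ci(
    values,
    estimator,
    level: float = 0.90,
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Percentile-bootstrap CIs for the two limits of any RI estimator.

    ``estimator`` is a callable mapping a value array to (lrl, url).
    Returns ((lrl_lo, lrl_hi), (url_lo, url_hi)).
    """
    if reps < 200:
        raise ValueError("reps must be >= 200 for stable percentile CIs")
    x = _check(values, 2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lows = np.empty(reps)
    highs = np.empty(reps)
    n = x.size
    for i in range(reps):
        resample = x[rng.integers(0, n, n)]
        try:
            lows[i], highs[i] = estimator(resample)
        except (ValueError, RuntimeError):
            lows[i], highs[i] = np.nan, np.nan
    lows = lows[np.isfinite(lows)]
    highs = highs[np.isfinite(highs)]
    q = [(1 - level) / 2 * 100, (1 + level) / 2 * 100]
    lrl_ci = tuple(np.percentile(lows, q)) if lows.size else (np.nan, np.nan)
    url_ci = tuple(np.percentile(highs, q)) if highs.size else (np.nan, np.nan)
    return (float(lrl_ci[0]), float(lrl_ci[1])), (float(url_ci[0]), float(url_ci[1]))


@dataclass(frozen=True)
class MethodChoice:
    method: str
    use_transform: bool
    small_sample_warning: bool = False


def select_method(n: int, verdict: GaussianityVerdict) -> MethodChoice:
    """Sample-size- and distribution-driven method selection (see module
    docstring for the thresholds)."""
    if n < N_MIN:
        raise ValueError(f"n = {n} is below the floor of {N_MIN} for RI estimation")
    if n >= N_NONPARAMETRIC:
        return MethodChoice(METHOD_NONPARAMETRIC, use_transform=False)
    use_transform = verdict.verdict != VERDICT_GAUSSIAN_RAW
    if n >= N_ROBUST:
        return MethodChoice(METHOD_ROBUST, use_transform=use_transform)
    return MethodChoice(METHOD_ROBUST, use_transform=use_transform, small_sample_warning=True)


class ReferenceIntervalEstimator(BaseEstimator):
    """Full RI pipeline as a scikit-learn estimator.

    Parameters
    ----------
    coverage : float, default 0.95
        Central fraction of the reference population the interval covers.
    method : {"auto", "nonparametric", "parametric", "robust"}
        "auto" applies the n- and distribution-driven selection rule.
    alpha : float, default 0.05
        Significance level of the Anderson-Darling gaussianity test.
    remove_outliers : bool, default True
        Single-pass Tukey far-outlier removal before estimation.
    bootstrap_reps : int, default 1000
        Percentile-bootstrap replicates for the limit CIs (0 disables).
    ci_level : float, default 0.90
        Level of the bootstrap CIs on each limit.
    shift_unit : float, default 0.01
        Positivity shift granularity for Box-Cox (one display-decimal unit).
    random_state : int or None
        Seed for the bootstrap.

    Attributes (after ``fit``)
    --------------------------
    lrl_, url_ : float
        Lower and upper reference limits in analyte units.
    lrl_ci_, url_ci_ : tuple of float
        90% bootstrap CIs of the limits.
    method_ : str
        Estimation method actually used.
    transformation_ : BoxCoxTransform or None
    n_used_ : int
        Sample size after outlier removal.
    removed_outliers_ : int
    verdict_ : GaussianityVerdict
    estimate_ : ReferenceIntervalEstimate
        The full structured result.
    """

    def __init__(
        self,
        coverage: float = 0.95,
        method: str = "auto",
        alpha: float = 0.05,
        remove_outliers: bool = True,
        bootstrap_reps: int = 1000,
        ci_level: float = 0.90,
        shift_unit: float = 0.01,
        c_location: float = 3.7,
        c_scale: float = 9.0,
        random_state: int | None = None,
    ) -> None:
        self.coverage = coverage
        self.method = method
        self.alpha = alpha
        self.remove_outliers = remove_outliers
        self.bootstrap_reps = bootstrap_reps
        self.ci_level = ci_level
        self.shift_unit = shift_unit
        self.c_location = c_location
        self.c_scale = c_scale
        self.random_state = random_state

    def fit(self, X, y=None, analyte: str = ""):
        x = _check(X, N_MIN)

        report = None
        removed = 0
        if self.remove_outliers:
            report = remove_far_outliers(x)
            removed = int(report.removed.size)
            x = report.retained
        if x.size < N_MIN:
            raise ValueError(
                f"only {x.size} values remain after outlier removal (floor {N_MIN})"
            )

        verdict = assess_gaussianity(x, alpha=self.alpha, shift_unit=self.shift_unit)

        if self.method == "auto":
            choice = select_method(x.size, verdict)
        elif self.method in (METHOD_NONPARAMETRIC, METHOD_PARAMETRIC, METHOD_ROBUST):
            choice = MethodChoice(
                self.method,
                use_transform=verdict.verdict != VERDICT_GAUSSIAN_RAW
                and self.method != METHOD_NONPARAMETRIC,
            )
        else:
            raise ValueError(f"unknown method {self.method!r}")
        if choice.small_sample_warning:
            warnings.warn(
                f"n = {x.size} < {N_ROBUST}: robust RI computed on a small sample; "
                "interpret limits with caution",
                UserWarning,
                stacklevel=2,
            )

        transform = verdict.transform if choice.use_transform else None
        point = self._make_estimator(choice.method, transform)
        lrl, url = point(x)

        lrl_ci = url_ci = None
        if self.bootstrap_reps:
            lrl_ci, url_ci = bootstrap_limit_ci(
                x, point, level=self.ci_level, reps=self.bootstrap_reps,
                seed=self.random_state,
            )

        self.lrl_, self.url_ = lrl, url
        self.lrl_ci_, self.url_ci_ = lrl_ci, url_ci
        self.method_ = choice.method
        self.transformation_ = transform
        self.n_used_ = int(x.size)
        self.removed_outliers_ = removed
        self.verdict_ = verdict
        self.estimate_ = ReferenceIntervalEstimate(
            analyte=analyte,
            n_used=int(x.size),
            method=choice.method,
            transformation=transform,
            lrl=lrl,
            url=url,
            lrl_ci=lrl_ci,
            url_ci=url_ci,
            coverage=self.coverage,
            removed_outliers=removed,
            verdict=verdict,
            outlier_report=report,
            small_sample_warning=choice.small_sample_warning,
            descriptives=describe(x),
            metadata={
                "c_location": self.c_location,
                "c_scale": self.c_scale,
                "alpha": self.alpha,
            },
        )
        return self

    def _make_estimator(self, method: str, transform: BoxCoxTransform | None):
        if method == METHOD_NONPARAMETRIC:
            return lambda v: nonparametric_ri(v, coverage=self.coverage)
        if method == METHOD_PARAMETRIC:
            return lambda v: parametric_ri(v, transform, coverage=self.coverage)
        return lambda v: robust_ri(
            v, transform, coverage=self.coverage,
            c_location=self.c_location, c_scale=self.c_scale,
        )

    def predict(self, X) -> np.ndarray:
        """+1 for values inside [lrl_, url_] (limits inclusive), -1 outside."""
        if not hasattr(self, "lrl_"):
            raise AttributeError("estimator is not fitted")
        x = np.asarray(X, dtype=float).ravel()
        return np.where((x >= self.lrl_) & (x <= self.url_), 1, -1)


def estimate_reference_interval(
    values,
    coverage: float = 0.95,
    seed: int | None = None,
    analyte: str = "",
    **kwargs,
) -> ReferenceIntervalEstimate:
    """One-call pipeline: outlier screen, gaussianity, method selection,
    limit estimation, bootstrap CIs. Thin wrapper over
    :class:`ReferenceIntervalEstimator`."""
    est = ReferenceIntervalEstimator(coverage=coverage, random_state=seed, **kwargs)
    est.fit(values, analyte=analyte)
    return est.estimate_
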