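"""Variance machinery: delta method, test-based CIs, design-aware bootstrap.

The delta method propagates a working-model covariance through the smooth
contrast that defines the summary measure (difference, log ratio, or log
odds ratio of averaged predictions).  Test-based intervals rescale the point
estimate by the model-scale z statistic so that the p-value and interval
agree across scales.  The bootstrap resamples the way the trial sampled:
within strata for stratified-block designs, simple resampling otherwise,
and it refuses minimisation designs by default because no resampling scheme
mimics that assignment process.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .data import TrialDataset
from .results import (
    AdjustmentResult,
    ConvergenceError,
    InferenceRefusedError,
    TrialAdjustError,
)


@dataclass(frozen=True)
class InferenceSettings:
    level: float = 0.95
    ci_method: str = "delta"  # {"delta", "test_based", "bootstrap"}
    bootstrap_reps: int = 1000
    bootstrap_resampling: str = "auto"  # {"auto", "simple", "within_strata"}
    bootstrap_failure_cap: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not (0 < self.level < 1):
            raise ValueError("confidence level must lie in (0, 1)")
        if self.ci_method not in {"delta", "test_based", "bootstrap"}:
            raise ValueError(f"unknown ci_method {self.ci_method!r}")


# ---------------------------------------------------------------------------
# Delta method
# ---------------------------------------------------------------------------

_SCALAR_TRANSFORMS = {"identity", "log"}
_CONTRAST_TRANSFORMS = {"difference", "log_ratio", "log_odds_ratio"}


def contrast_value(mu1: float, mu0: float, transform: str) -> float:
    """The summary-measure contrast of two averaged predictions, on the
    estimation scale (log for ratios)."""
    if transform == "difference":
        return mu1 - mu0
    if transform == "log_ratio":
        return float(np.log(mu1 / mu0))
    if transform == "log_odds_ratio":
        return float(np.log(mu1 / (1 - mu1)) - np.log(mu0 / (1 - mu0)))
    raise ValueError(f"unknown contrast {transform!r}")


def contrast_gradient(mu1: float, mu0: float, transform: str) -> np.ndarray:
    if transform == "difference":
        return np.array([1.0, -1.0])
    if transform == "log_ratio":
        return np.array([1.0 / mu1, -1.0 / mu0])
    if transform == "log_odds_ratio":
        return np.array([1.0 / (mu1 * (1 - mu1)), -1.0 / (mu0 * (1 - mu0))])
    raise ValueError(f"unknown contrast {transform!r}")


def delta_method_se(
    estimates: np.ndarray | float,
    vcov: np.ndarray | float,
    transform: str,
    check_gradient: bool = False,
) -> float:
    """SE of a transformed estimate via first-order propagation.

    ``transform`` is either a scalar rule ("identity", "log") applied to a
    single estimate, or a two-argument contrast ("difference", "log_ratio",
    "log_odds_ratio") applied to ``estimates = (mu1, mu0)``.  With
    ``check_gradient=True`` the analytic gradient is verified against a
    central finite difference to 1e-6 relative accuracy.
    """
    if transform in _SCALAR_TRANSFORMS:
        est = float(np.asarray(estimates).reshape(()))
        se_in = float(np.sqrt(np.asarray(vcov).reshape(())))
        if transform == "identity":
            return se_in
        return se_in / abs(est)  # d log(mu) / d mu = 1 / mu

    if transform not in _CONTRAST_TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    mu = np.asarray(estimates, dtype=float)
    V = np.atleast_2d(np.asarray(vcov, dtype=float))
    grad = contrast_gradient(mu[0], mu[1], transform)
    if check_gradient:
        fd = _finite_difference(lambda m: contrast_value(m[0], m[1], transform), mu)
        denom = max(np.max(np.abs(grad)), 1.0)
        if np.max(np.abs(fd - grad)) / denom > 1e-6:
            raise TrialAdjustError(
                "analytic and finite-difference gradients disagree"
            )
    var = float(grad @ V @ grad)
    if var < 0:
        warnings.warn(
            "covariance not positive semi-definite; variance clipped at 0",
            stacklevel=2,
        )
        var = 0.0
    return float(np.sqrt(var))


def _finite_difference(f: Callable, x: np.ndarray, h: float = 1e-7) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        e = np.zeros_like(x)
        e[i] = h * max(abs(x[i]), 1.0)
        g[i] = (f(x + e) - f(x - e)) / (2 * e[i])
    return g


# ---------------------------------------------------------------------------
# Test-based confidence interval
# ---------------------------------------------------------------------------

def test_based_ci(
    estimate_summary_scale: float, z_statistic: float, level: float = 0.95
) -> tuple[float, float]:
    """Interval from the point estimate and a z statistic sharing its null.

    The half-width is (q / |z|) times the distance of the estimate from 0,
    where q is the level quantile of the standard normal; the p-value
    recomputed from the interval equals the model-scale p-value.  Only
    meaningful for difference-scale measures whose null is 0.
    """
    if z_statistic == 0:
        raise TrialAdjustError("test-based interval undefined at z = 0")
    q = stats.norm.ppf(0.5 + level / 2)
    half = (q / abs(z_statistic)) * abs(estimate_summary_scale)
    return (estimate_summary_scale - half, estimate_summary_scale + half)


# ---------------------------------------------------------------------------
# Design-respecting bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    se: float
    ci: tuple[float, float]
    estimates: np.ndarray
    n_failed: int
    reps: int
    resampling: str

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / self.reps


def design_bootstrap(
    data: TrialDataset,
    estimator: Callable[[TrialDataset], AdjustmentResult],
    settings: InferenceSettings,
    allow_minimisation: bool = False,
) -> BootstrapResult:
    """Nonparametric bootstrap whose resampling mimics the trial's sampling.

    Stratified-block designs are resampled within the cross-classification
    of the stratification covariates (simple resampling would treat the
    designed balance as chance and inflate the SE).  Replicates on which the
    estimator fails to converge are counted; if their fraction exceeds
    ``settings.bootstrap_failure_cap`` inference is refused.
    """
    scheme = data.design.scheme
    resampling = settings.bootstrap_resampling
    if scheme == "minimisation" and not allow_minimisation:
        raise InferenceRefusedError(
            "bootstrap under a minimisation design is refused: resampling "
            "cannot mimic the sequential assignment; pass "
            "allow_minimisation=True to accept simple resampling as an "
            "approximation"
        )
    if resampling == "auto":
        resampling = (
            "within_strata" if scheme == "stratified_block" else "simple"
        )
    if scheme == "stratified_block" and resampling == "simple":
        warnings.warn(
            "simple resampling under a stratified-block design targets the "
            "wrong sampling distribution (upwardly biased SE)",
            stacklevel=2,
        )

    rng = np.random.default_rng(settings.seed)
    n = data.n
    if resampling == "within_strata" and data.design.strata_covariates:
        # resample within stratum-by-arm cells: the designed balance of the
        # stratifiers across arms is a fixed feature of the sampling process
        # and must be preserved in every replicate
        cols = list(data.design.strata_covariates) + ["arm"]
        keys = data.frame[cols].astype(str).agg("|".join, axis=1)
        groups = [np.flatnonzero(keys == k) for k in keys.unique()]
    else:
        groups = [np.arange(n)]

    estimates = []
    n_failed = 0
    for _ in range(settings.bootstrap_reps):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        try:
            res = estimator(data.subset(np.sort(idx)))
        except ConvergenceError:
            n_failed += 1
            continue
        estimates.append(res.estimate_estimation_scale)
    frac = n_failed / settings.bootstrap_reps
    if frac > settings.bootstrap_failure_cap:
        raise InferenceRefusedError(
            f"{n_failed}/{settings.bootstrap_reps} bootstrap replicates failed "
            f"to converge (cap {settings.bootstrap_failure_cap:.0%}); the "
            "chosen estimator is not a safe analysis plan for this design"
        )
    arr = np.asarray(estimates)
    alpha = 1 - settings.level
    lo, hi = np.quantile(arr, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(
        se=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        ci=(float(lo), float(hi)),
        estimates=arr,
        n_failed=n_failed,
        reps=settings.bootstrap_reps,
        resampling=resampling,
    )
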