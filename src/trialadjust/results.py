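"""Result containers and typed failures shared across estimators."""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class TrialAdjustError(Exception):
    """Base class for all package errors."""


class PreflightError(TrialAdjustError):
    """Configuration rejected before any model fitting (e.g. an estimand a
    method cannot target)."""


class UnsupportedEstimandError(PreflightError):
    """Requested measure is incompatible with the chosen method: direct
    adjustment always targets a conditional summary; IPTW always targets a
    marginal one."""


class PredictionFailure(TrialAdjustError):
    """Standardisation could not predict for some participants because their
    covariate level was absent from the fitting set."""

    def __init__(self, covariate: str, levels, n_affected: int):
        self.covariate = covariate
        self.levels = tuple(levels)
        self.n_affected = n_affected
        super().__init__(
            f"no predictions for {n_affected} participant(s): level(s) "
            f"{self.levels!r} of covariate {covariate!r} not present in the "
            "model-fitting set; pass drop_unpredictable=True to omit them "
            "(count is logged)"
        )


class InferenceRefusedError(TrialAdjustError):
    """Variance estimation declined (e.g. bootstrap under minimisation, or
    too many non-converging bootstrap replicates)."""


@dataclass
class ConvergenceFailure:
    """A model fit that did not reach a trustworthy optimum.

    reason is one of {"max_iterations", "invalid_fitted_values",
    "separation", "collinearity"}.
    """

    model: str
    reason: str
    detail: str = ""
    advice: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        msg = f"{self.model}: {self.reason}"
        if self.detail:
            msg += f" ({self.detail})"
        if self.advice:
            msg += f"; {self.advice}"
        return msg


class ConvergenceError(TrialAdjustError):
    """Raised instead of returning a silently wrong estimate."""

    def __init__(self, failure: ConvergenceFailure):
        self.failure = failure
        super().__init__(str(failure))


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


@dataclass
class AdjustmentResult:
    """Point estimate with inference, on both scales.

    ``estimate_estimation_scale`` is the scale the model works on (log for
    ratio measures, identity for differences); ``estimate_summary_scale`` is
    what a reader of a trial report expects (exp of the former for ratios).
    """

    estimate_summary_scale: float
    estimate_estimation_scale: float
    se_estimation_scale: float
    ci: tuple[float, float]
    z_statistic: float
    p_value: float
    method: str  # {"direct", "standardisation", "iptw", "unadjusted"}
    estimand: "EstimandSpec"
    n_used: int
    level: float = 0.95
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.estimate_estimation_scale <= hi) and not any(
            math.isnan(v) for v in (lo, hi, self.estimate_estimation_scale)
        ):
            raise ValueError("confidence interval does not bracket the estimate")
        if self.se_estimation_scale < 0:
            raise ValueError("standard error must be non-negative")

    @property
    def ci_summary_scale(self) -> tuple[float, float]:
        from .data import RATIO_MEASURES

        if self.estimand.measure in RATIO_MEASURES:
            return (math.exp(self.ci[0]), math.exp(self.ci[1]))
        return self.ci

    def to_dict(self) -> dict:
        lo, hi = self.ci
        slo, shi = self.ci_summary_scale
        return {
            "method": self.method,
            "measure": self.estimand.measure,
            "population": self.estimand.population,
            "estimate": self.estimate_summary_scale,
            "estimate_estimation_scale": self.estimate_estimation_scale,
            "se_estimation_scale": self.se_estimation_scale,
            "ci_lower": lo,
            "ci_upper": hi,
            "ci_lower_summary_scale": slo,
            "ci_upper_summary_scale": shi,
            "z": self.z_statistic,
            "p_value": self.p_value,
            "level": self.level,
            "n_used": self.n_used,
            "notes": list(self.notes),
        }
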