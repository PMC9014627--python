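"""Direct adjustment: the treatment effect as a regression coefficient.

The outcome is regressed on the randomised arm and covariate main effects
(no arm x covariate interaction) using a GLM whose link puts the treatment
coefficient on the scale of the requested summary measure:

====================  =============================================
measure               model
====================  =============================================
mean_difference       gaussian, identity link
risk_difference       binomial, identity link
risk_ratio            binomial, log link (or Poisson + robust SE)
conditional_odds_ratio  binomial, logit link (logistic regression)
====================  =============================================

Direct adjustment always targets a *conditional* summary: asking it for a
marginal odds ratio is a pre-flight error, not an approximation.  The
identity- and log-link binomial models are exactly the fits that are prone
to non-convergence; failures surface as typed :class:`ConvergenceFailure`
records rather than clamped estimates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._glm import build_design, fit_glm, FittedOutcomeModel
from .data import ARM, OUTCOME, EstimandSpec, TrialDataset
from .results import AdjustmentResult, UnsupportedEstimandError

_MEASURE_MODEL = {
    "mean_difference": ("gaussian", "identity"),
    "risk_difference": ("binomial", "identity"),
    "risk_ratio": ("binomial", "log"),
    "conditional_odds_ratio": ("binomial", "logit"),
}


def fit_outcome_glm(
    data: TrialDataset,
    family: str,
    link: str,
    covariate_names: list[str] | None = None,
    arm_interactions: bool = False,
    freq_weights: np.ndarray | None = None,
    robust: str | None = None,
) -> FittedOutcomeModel:
    """Fit the outcome regression on rows with an observed outcome."""
    mask = data.outcome_observed() & data.covariates_observed()
    sub = data.frame.loc[mask]
    X, names = build_design(
        data, covariate_names=covariate_names,
        arm_interactions=arm_interactions, frame=sub,
    )
    w = None if freq_weights is None else np.asarray(freq_weights)[mask]
    return fit_glm(
        sub[OUTCOME].to_numpy(dtype=float), X, names,
        family=family, link=link, freq_weights=w, robust=robust,
        model_label=f"{family}({link}) outcome model",
    )


def direct_estimate(
    data: TrialDataset,
    estimand: EstimandSpec,
    robust: bool = False,
    robust_variant: str = "HC0",
    covariate_names: list[str] | None = None,
    level: float = 0.95,
    freq_weights: np.ndarray | None = None,
) -> AdjustmentResult:
    """Treatment coefficient and its (model-based or sandwich) SE.

    With ``robust=True`` and measure ``risk_ratio`` the model switches to
    Poisson regression with HC standard errors, the usual convergence-safe
    route to a covariate-adjusted risk ratio.
    """
    if estimand.measure == "marginal_odds_ratio":
        raise UnsupportedEstimandError(
            "direct adjustment always targets a conditional summary measure; "
            "use standardisation or IPTW for the marginal odds ratio"
        )
    family, link = _MEASURE_MODEL[estimand.measure]
    if robust and estimand.measure == "risk_ratio":
        family = "poisson"
    model = fit_outcome_glm(
        data, family, link, covariate_names=covariate_names,
        freq_weights=freq_weights,
        robust=robust_variant if robust else None,
    )
    j = model.names.index(ARM)
    est = float(model.params[j])
    se = float(np.sqrt(model.vcov[j, j]))
    q = stats.norm.ppf(0.5 + level / 2)
    z = est / se if se > 0 else np.inf
    notes = []
    if robust:
        notes.append(f"{robust_variant} robust standard errors")
    summary = float(np.exp(est)) if estimand.estimation_scale == "log" else est
    return AdjustmentResult(
        estimate_summary_scale=summary,
        estimate_estimation_scale=est,
        se_estimation_scale=se,
        ci=(est - q * se, est + q * se),
        z_statistic=z,
        p_value=float(2 * stats.norm.sf(abs(z))),
        method="direct",
        estimand=estimand,
        n_used=model.n_obs,
        level=level,
        notes=notes,
    )


def unadjusted_estimate(
    data: TrialDataset,
    estimand: EstimandSpec,
    level: float = 0.95,
    freq_weights: np.ndarray | None = None,
) -> AdjustmentResult:
    """Arm-only contrast (no covariates); conditional and marginal coincide.

    For a 2x2 table this reproduces the closed-form contrast of arm-level
    summaries with the standard large-sample variance.
    """
    measure = estimand.measure
    if measure == "conditional_odds_ratio":
        measure = "marginal_odds_ratio"  # identical without covariates
    mask = data.outcome_observed()
    y = data.outcome[mask]
    z = data.arm[mask]
    w = (np.ones(mask.sum()) if freq_weights is None
         else np.asarray(freq_weights, dtype=float)[mask])
    n1, n0 = w[z == 1].sum(), w[z == 0].sum()
    m1 = float(np.sum(w[z == 1] * y[z == 1]) / n1)
    m0 = float(np.sum(w[z == 0] * y[z == 0]) / n0)
    if measure == "mean_difference":
        v1 = np.sum(w[z == 1] * (y[z == 1] - m1) ** 2) / n1
        v0 = np.sum(w[z == 0] * (y[z == 0] - m0) ** 2) / n0
        est, var = m1 - m0, v1 / n1 + v0 / n0
    elif measure == "risk_difference":
        est = m1 - m0
        var = m1 * (1 - m1) / n1 + m0 * (1 - m0) / n0
    elif measure == "risk_ratio":
        est = np.log(m1 / m0)
        var = (1 - m1) / (m1 * n1) + (1 - m0) / (m0 * n0)
    else:  # marginal odds ratio
        est = np.log(m1 / (1 - m1)) - np.log(m0 / (1 - m0))
        var = 1 / (m1 * (1 - m1) * n1) + 1 / (m0 * (1 - m0) * n0)
    se = float(np.sqrt(var))
    q = stats.norm.ppf(0.5 + level / 2)
    z_stat = est / se if se > 0 else np.inf
    summary = float(np.exp(est)) if estimand.estimation_scale == "log" else float(est)
    return AdjustmentResult(
        estimate_summary_scale=summary,
        estimate_estimation_scale=float(est),
        se_estimation_scale=se,
        ci=(float(est - q * se), float(est + q * se)),
        z_statistic=float(z_stat),
        p_value=float(2 * stats.norm.sf(abs(z_stat))),
        method="unadjusted",
        estimand=estimand,
        n_used=int(mask.sum()),
        level=level,
    )
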