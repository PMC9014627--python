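"""Standardisation (G-computation / marginalisation).

Fit a working outcome regression on the complete cases, predict every
participant's outcome as if assigned to intervention and then as if assigned
to control, and contrast the two averaged predictions on the requested
summary scale.  The working model fixes *how* the effect is estimated
(logistic regression by default for binary outcomes, which always converges)
while the contrast fixes *what* is estimated — so a risk difference or risk
ratio can be estimated without ever fitting the fragile identity- or
log-link binomial models.

Because predictions need covariates but not outcomes, the averaging set can
be the all-randomised sample even when outcomes are partly missing; that is
the three-step route to the all-randomised estimand under covariate-
dependent missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from ._glm import build_design, fit_glm, FittedOutcomeModel
from .data import ARM, OUTCOME, EstimandSpec, TrialDataset
from .inference import contrast_gradient, contrast_value, delta_method_se, test_based_ci
from .results import (
    AdjustmentResult,
    PredictionFailure,
    TrialAdjustError,
    UnsupportedEstimandError,
)

_CONTRAST = {
    "mean_difference": "difference",
    "risk_difference": "difference",
    "risk_ratio": "log_ratio",
    "marginal_odds_ratio": "log_odds_ratio",
}


@dataclass(frozen=True)
class StandardisationSpec:
    """Working model and target of a standardisation analysis."""

    measure: str
    population: str = "all_randomised"  # averaging set for the predictions
    arm_interactions: bool = False
    ci_method: str = "delta"  # or "test_based"
    covariate_names: tuple[str, ...] | None = None

    def estimand(self) -> EstimandSpec:
        return EstimandSpec(self.measure, self.population)


def standardise(
    data: TrialDataset,
    spec: StandardisationSpec,
    level: float = 0.95,
    drop_unpredictable: bool = False,
    freq_weights: np.ndarray | None = None,
) -> AdjustmentResult:
    """G-computation estimate with a delta-method (or test-based) interval."""
    if spec.measure not in _CONTRAST:
        raise UnsupportedEstimandError(
            "standardisation targets marginal summaries; for the conditional "
            "odds ratio use direct adjustment"
        )
    family = "gaussian" if data.outcome_type == "continuous" else "binomial"
    link = "identity" if family == "gaussian" else "logit"

    fit_mask = data.outcome_observed() & data.covariates_observed()
    if spec.population == "all_randomised":
        pred_mask = data.covariates_observed()
    else:
        pred_mask = fit_mask.copy()

    pred_mask, note_dropped = _check_unseen_levels(
        data, fit_mask, pred_mask, drop_unpredictable
    )

    covs = list(spec.covariate_names) if spec.covariate_names is not None else None
    w_fit = None if freq_weights is None else np.asarray(freq_weights)[fit_mask]
    sub = data.frame.loc[fit_mask]
    X_fit, names = build_design(
        data, covariate_names=covs, arm_interactions=spec.arm_interactions,
        frame=sub,
    )
    # dummy columns for levels absent from the fit set are identically zero;
    # the unseen-level check above has already dealt with the affected rows,
    # so such columns are pruned from both the fit and prediction designs
    keep = [j for j in range(X_fit.shape[1]) if np.any(X_fit[:, j] != 0)]
    model = fit_glm(
        sub[OUTCOME].to_numpy(dtype=float), X_fit[:, keep],
        [names[j] for j in keep], family=family, link=link,
        freq_weights=w_fit, model_label=f"{family}({link}) working model",
    )

    pred_frame = data.frame.loc[pred_mask]
    w_pred = (
        np.ones(len(pred_frame))
        if freq_weights is None
        else np.asarray(freq_weights, dtype=float)[pred_mask]
    )
    mus = []
    grads = []
    for z in (1, 0):
        cf = pred_frame.copy()
        cf[ARM] = z
        Xz_full, _ = build_design(
            data, covariate_names=covs,
            arm_interactions=spec.arm_interactions, frame=cf,
        )
        Xz = Xz_full[:, keep]
        p = model.predict(Xz)
        mus.append(float(np.average(p, weights=w_pred)))
        dmu = model.link_derivative(Xz)
        grads.append((Xz * (dmu * w_pred)[:, None]).sum(axis=0) / w_pred.sum())
    mu1, mu0 = mus

    transform = _CONTRAST[spec.measure]
    if transform != "difference" and (
        min(mu1, mu0) <= 0 or (transform == "log_odds_ratio" and max(mu1, mu0) >= 1)
    ):
        raise TrialAdjustError(
            "degenerate standardised mean (0 or 1): the ratio/odds contrast "
            "is infinite; report the risk difference instead"
        )
    est = contrast_value(mu1, mu0, transform)
    g = contrast_gradient(mu1, mu0, transform)
    grad_beta = g[0] * grads[0] + g[1] * grads[1]
    se = float(np.sqrt(max(grad_beta @ model.vcov @ grad_beta, 0.0)))

    q = stats.norm.ppf(0.5 + level / 2)
    notes = list(note_dropped)
    if spec.ci_method == "test_based":
        if transform != "difference":
            raise TrialAdjustError(
                "test-based intervals require a difference-scale measure "
                "with null at 0"
            )
        j = model.names.index(ARM)
        z_stat = float(model.params[j] / np.sqrt(model.vcov[j, j]))
        ci = test_based_ci(est, z_stat, level)
        notes.append("test-based interval from the working-model z statistic")
    else:
        z_stat = est / se if se > 0 else np.inf
        ci = (est - q * se, est + q * se)

    summary = float(np.exp(est)) if transform != "difference" else est
    return AdjustmentResult(
        estimate_summary_scale=summary,
        estimate_estimation_scale=est,
        se_estimation_scale=se,
        ci=ci,
        z_statistic=float(z_stat),
        p_value=float(2 * stats.norm.sf(abs(z_stat))),
        method="standardisation",
        estimand=spec.estimand(),
        n_used=int(pred_mask.sum()),
        level=level,
        notes=notes,
    )


def standardise_all_randomised(
    data: TrialDataset,
    spec: StandardisationSpec,
    level: float = 0.95,
    drop_unpredictable: bool = False,
) -> AdjustmentResult:
    """Three-step all-randomised standardisation: fit on complete cases,
    average the predictions over every randomised participant.  Identical to
    :func:`standardise` when no outcomes are missing."""
    return standardise(
        data,
        replace(spec, population="all_randomised"),
        level=level,
        drop_unpredictable=drop_unpredictable,
    )


def _check_unseen_levels(data, fit_mask, pred_mask, drop_unpredictable):
    """Levels present in the prediction set but absent at fit time cannot be
    predicted for; fail loudly or (opt-in) drop those rows with a logged
    count."""
    notes: list[str] = []
    pred_mask = pred_mask.copy()
    for name, spec in data.covariates.items():
        if spec.kind != "categorical":
            continue
        fit_levels = set(data.frame.loc[fit_mask, name].dropna().unique())
        pred_levels = set(data.frame.loc[pred_mask, name].dropna().unique())
        unseen = pred_levels - fit_levels
        if not unseen:
            continue
        affected = pred_mask & data.frame[name].isin(unseen).to_numpy()
        if not drop_unpredictable:
            raise PredictionFailure(name, sorted(map(str, unseen)), int(affected.sum()))
        pred_mask &= ~affected
        notes.append(
            f"dropped {int(affected.sum())} participant(s) with unpredictable "
            f"level(s) {sorted(map(str, unseen))} of {name!r}"
        )
    return pred_mask, notes
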