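"""Missing-data handling aimed at the all-randomised estimand.

With outcomes missing at random given covariates, a complete-case analysis
is valid for a *complete-case population* — which is not the population that
was randomised whenever there is effect modification on the summary scale.
Three routes recover the all-randomised estimand: multiple imputation with a
separate imputation model per randomised arm (Rubin's rules on the
estimation scale), standardisation over the all-randomised covariate
distribution (see :mod:`trialadjust.standardise`), and inverse-probability-
of-missingness weighting combined with IPTW.  Missing *covariates* are
handled by across-arm mean imputation or the missing-indicator method,
appropriate for marginal/collapsible measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import build_design, fit_glm
from .data import ARM, OUTCOME, CovariateSpec, EstimandSpec, TrialDataset
from .iptw import WeightSet, _WeightModel
from .results import (
    AdjustmentResult,
    ConvergenceError,
    ConvergenceFailure,
    TrialAdjustError,
)


@dataclass(frozen=True)
class MNARShift:
    """Log-odds shift added to imputed draws, per arm; (0, 0) is MAR."""

    delta_control: float = 0.0
    delta_intervention: float = 0.0

    def for_arm(self, z: int) -> float:
        return self.delta_intervention if z == 1 else self.delta_control


@dataclass
class ImputationSet:
    m: int
    datasets: list[TrialDataset]
    seed: int
    shift: MNARShift = field(default_factory=MNARShift)
    arm_models: dict = field(default_factory=dict)


def mi_by_arm(
    data: TrialDataset,
    m: int = 10,
    seed: int | None = None,
    shift: MNARShift = MNARShift(),
    covariate_names: list[str] | None = None,
    augment_scale: float = 1.0,
) -> ImputationSet:
    """Proper multiple imputation of a binary outcome, separately by arm.

    Each arm's observed outcomes are modelled by logistic regression on
    covariate main effects.  The model is augmented against perfect
    prediction with two pseudo-observations (outcome 0 and 1) at the
    covariate means, carrying total frequency weight
    ``augment_scale * n_parameters``.  Each imputation draws parameters from
    the approximate posterior and then outcomes from the implied Bernoulli;
    an MNAR sensitivity shift adds its per-arm delta to the linear predictor
    of the imputed draws only.

    Fitting separately by arm (rather than pooling with an arm covariate) is
    what makes the downstream analysis target the all-randomised population
    in the presence of treatment-covariate interactions.
    """
    if data.outcome_type != "binary":
        raise TrialAdjustError("mi_by_arm imputes binary outcomes only")
    if not data.covariates_observed().all():
        raise TrialAdjustError("mi_by_arm requires complete covariates")
    rng = np.random.default_rng(seed)
    observed = data.outcome_observed()
    z = data.arm
    fits = {}
    designs = {}
    for arm in (0, 1):
        sel = observed & (z == arm)
        if not sel.any():
            raise TrialAdjustError(f"arm {arm} has no observed outcomes")
        sub = data.frame.loc[sel]
        X, names = build_design(
            data, include_arm=False, covariate_names=covariate_names, frame=sub
        )
        y = sub[OUTCOME].to_numpy(dtype=float)
        Xa, ya, wa = _augment(X, y, augment_scale)
        fits[arm] = fit_glm(
            ya, Xa, names, family="binomial", link="logit", freq_weights=wa,
            model_label=f"arm-{arm} imputation model (augmented)",
        )
        designs[arm] = (sel, names)

    completed = []
    for _ in range(m):
        frame = data.frame.copy()
        for arm in (0, 1):
            miss = (~observed) & (z == arm)
            if not miss.any():
                continue
            model = fits[arm]
            beta = _posterior_draw(rng, model.params, model.vcov)
            Xmiss, _ = build_design(
                data, include_arm=False, covariate_names=covariate_names,
                frame=data.frame.loc[miss],
            )
            eta = Xmiss @ beta + shift.for_arm(arm)
            p = 1.0 / (1.0 + np.exp(-eta))
            frame.loc[miss, OUTCOME] = rng.binomial(1, p).astype(float)
        completed.append(replace(data, frame=frame))
    return ImputationSet(m=m, datasets=completed, seed=seed or 0, shift=shift,
                         arm_models=fits)


def _augment(X, y, scale):
    p = X.shape[1]
    mean_row = X.mean(axis=0)
    Xa = np.vstack([X, mean_row, mean_row])
    ya = np.concatenate([y, [0.0, 1.0]])
    w = np.concatenate([np.ones(len(y)), [scale * p / 2, scale * p / 2]])
    return Xa, ya, w


def _posterior_draw(rng, mean, vcov):
    # cholesky with a tiny jitter for numerically semi-definite vcov
    d = len(mean)
    L = np.linalg.cholesky(vcov + 1e-12 * np.eye(d))
    return mean + L @ rng.standard_normal(d)


def rubin_combine(
    results: list[AdjustmentResult], scale: str = "estimation"
) -> AdjustmentResult:
    """Rubin's rules across completed-data analyses.

    Combination is on the estimation scale by default (log-odds/log-ratio),
    where approximate normality is more plausible than on the summary scale;
    combining on the summary scale is allowed but flagged.  Total variance is
    within + (1 + 1/m) x between, with the standard small-sample df.
    """
    if not results:
        raise TrialAdjustError("nothing to combine")
    est0 = results[0].estimand
    if any(r.estimand != est0 or r.method != results[0].method for r in results):
        raise TrialAdjustError("cannot combine results with mixed estimands/methods")
    m = len(results)
    if scale == "estimation":
        q = np.array([r.estimate_estimation_scale for r in results])
        u = np.array([r.se_estimation_scale**2 for r in results])
    elif scale == "summary":
        q = np.array([r.estimate_summary_scale for r in results])
        # delta-method SE on the summary scale for ratio measures
        u = np.array(
            [
                (r.se_estimation_scale * r.estimate_summary_scale) ** 2
                if r.estimand.estimation_scale == "log"
                else r.se_estimation_scale**2
                for r in results
            ]
        )
    else:
        raise ValueError("scale must be 'estimation' or 'summary'")
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1)) if m > 1 else 0.0
    total = within + (1 + 1 / m) * between
    se = float(np.sqrt(total))
    if between > 0 and m > 1:
        df = (m - 1) * (1 + within / ((1 + 1 / m) * between)) ** 2
        tq = stats.t.ppf(0.5 + results[0].level / 2, df)
    else:
        df = np.inf
        tq = stats.norm.ppf(0.5 + results[0].level / 2)
    z_stat = point / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(z_stat), df)) if np.isfinite(df) else float(
        2 * stats.norm.sf(abs(z_stat))
    )
    notes = [f"Rubin's rules on the {scale} scale, m={m}, df={df:.1f}"]
    if scale == "summary" and est0.estimation_scale == "log":
        notes.append(
            "combined on the summary scale of a ratio measure; intervals "
            "differ from estimation-scale combination"
        )
    is_log = est0.estimation_scale == "log"
    if scale == "estimation":
        summary = float(np.exp(point)) if is_log else point
    else:
        summary = point
    return AdjustmentResult(
        estimate_summary_scale=summary,
        estimate_estimation_scale=point,
        se_estimation_scale=se,
        ci=(point - tq * se, point + tq * se),
        z_statistic=float(z_stat),
        p_value=p,
        method=results[0].method,
        estimand=est0,
        n_used=results[0].n_used,
        level=results[0].level,
        notes=notes,
    )


def ipmw_weights(
    data: TrialDataset, covariate_names: list[str] | None = None
) -> WeightSet:
    """Inverse-probability-of-missingness weights.

    Missingness of the outcome is modelled by logistic regression on the
    analysis covariates *with arm interactions* (equivalently, separately by
    arm); observed rows are weighted by 1 / P(observed | X, Z).  Monotone
    missingness (covariates complete) makes this a single-model affair.
    """
    if not data.covariates_observed().all():
        raise TrialAdjustError("ipmw requires complete covariates")
    r = data.outcome_observed().astype(float)
    X, names = build_design(data, covariate_names=covariate_names,
                            arm_interactions=True)
    # A covariate pattern that is *fully observed* drives its fitted
    # probability to 1 and a coefficient to +inf; that is benign (weight 1),
    # so the generic coefficient-magnitude separation guard is replaced by a
    # check on the quantity that matters: no observed row may have fitted
    # P(observed) near 0, which would mean an unbounded weight.
    model = fit_glm(
        r, X, names, family="binomial", link="logit",
        model_label="missingness model", separation_check=False,
    )
    p = model.predict(X)
    if np.any(p[r == 1] < 1e-6):
        raise ConvergenceError(
            ConvergenceFailure(
                model="missingness model",
                reason="separation",
                detail="fitted probability of being observed is ~0 for some "
                "observed rows (perfect prediction of missingness)",
                advice="simplify the missingness model",
            )
        )
    w = np.where(r == 1, 1.0 / p, np.nan)
    return WeightSet(
        weights=w,
        weight_type="missingness",
        models=[_WeightModel(X=X, prob=p, response=r, names=names)],
    )


def covariate_mean_impute(data: TrialDataset) -> TrialDataset:
    """Replace missing covariate values by the across-arm observed mean
    (continuous) or an explicit extra level (categorical).  Appropriate for
    marginal/collapsible estimands; the outcome is untouched."""
    frame = data.frame.copy()
    covs = dict(data.covariates)
    for name, spec in data.covariates.items():
        col = frame[name]
        if not col.isna().any():
            continue
        if col.notna().sum() == 0:
            raise TrialAdjustError(f"covariate {name!r} is entirely missing")
        if spec.kind == "continuous":
            frame[name] = col.fillna(col.mean())
        else:
            extra = "missing"
            if extra in spec.levels:
                raise TrialAdjustError(
                    f"covariate {name!r} already has a {extra!r} level"
                )
            frame[name] = col.astype(object).where(col.notna(), extra)
            covs[name] = CovariateSpec("categorical", tuple(spec.levels) + (extra,))
    return replace(data, frame=frame, covariates=covs)


def covariate_missing_indicator(
    data: TrialDataset, fill_value: float = 0.0
) -> TrialDataset:
    """Missing-indicator method: set missing covariate values to a constant
    and add a companion binary indicator covariate."""
    frame = data.frame.copy()
    covs = dict(data.covariates)
    for name, spec in list(data.covariates.items()):
        col = frame[name]
        if not col.isna().any():
            continue
        ind_name = f"{name}_missing"
        if ind_name in frame.columns:
            raise TrialAdjustError(f"indicator column {ind_name!r} already exists")
        frame[ind_name] = col.isna().astype(float)
        if spec.kind == "continuous":
            frame[name] = col.fillna(fill_value)
        else:
            frame[name] = col.astype(object).where(col.notna(), spec.levels[0])
        covs[ind_name] = CovariateSpec("continuous")
    return replace(data, frame=frame, covariates=covs)


def missing_indicator_warning(estimand: EstimandSpec) -> str | None:
    """Mean imputation and the missing-indicator method are not suitable
    for conditional non-collapsible summaries."""
    if estimand.measure == "conditional_odds_ratio":
        return (
            "missing-indicator/mean imputation with a conditional "
            "non-collapsible summary measure does not target a well-defined "
            "all-randomised estimand"
        )
    return None


def complete_cases(data: TrialDataset) -> TrialDataset:
    """Rows with observed outcome and covariates; downstream results target
    the complete-case population."""
    mask = data.outcome_observed() & data.covariates_observed()
    if not mask.any():
        raise TrialAdjustError("no complete cases")
    return data.subset(mask)
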