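"""Inverse-probability-of-treatment weighting.

A logistic model predicts each participant's probability of the arm they
were actually randomised to; weighting by its inverse creates a
pseudo-population in which the two arms share the covariate distribution.
The treatment contrast in the weighted sample is then an *unadjusted* one
(weighted arm means), so the outcome step is certain to converge whatever
the summary measure.

Standard errors come from the full stacked M-estimation system — the
weight-model score equations joined with the weighted outcome estimating
equations — so the variance acknowledges that the weights were estimated.
Ignoring that step (the "weights known" shortcut, available as
``se_method="naive"``) is conservative in trials: estimating the weights is
exactly what lets the variance "see" covariate balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glm import build_design, fit_glm
from .data import EstimandSpec, TrialDataset
from .inference import contrast_gradient, contrast_value
from .results import AdjustmentResult, TrialAdjustError, UnsupportedEstimandError

_CONTRAST = {
    "mean_difference": "difference",
    "risk_difference": "difference",
    "risk_ratio": "log_ratio",
    "marginal_odds_ratio": "log_odds_ratio",
}


@dataclass
class _WeightModel:
    """One fitted logistic weight model, kept for the stacked sandwich."""

    X: np.ndarray          # design rows aligned with the dataset
    prob: np.ndarray       # fitted P(response = 1 | X)
    response: np.ndarray   # modelled binary response (arm, or observed flag)
    names: list[str]


@dataclass
class WeightSet:
    """Per-participant inverse-probability weights with their provenance.

    ``weights`` is aligned with the dataset rows; NaN marks rows for which
    the weight is undefined (e.g. missingness weights on unobserved rows).
    """

    weights: np.ndarray
    weight_type: str  # {"treatment", "missingness", "product"}
    models: list[_WeightModel] = field(default_factory=list)
    normalisation: str = "none"  # or "mean_one_per_arm"

    def __post_init__(self):
        w = self.weights
        defined = ~np.isnan(w)
        if not np.all(np.isfinite(w[defined])) or np.any(w[defined] <= 0):
            raise TrialAdjustError("weights must be finite and positive")

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.weights)


def fit_treatment_weights(
    data: TrialDataset,
    covariate_names: list[str] | None = None,
    stabilised: bool = False,
    normalisation: str = "none",
) -> WeightSet:
    """Logistic model of arm on covariate main effects; weight = 1 / fitted
    probability of the arm actually received.

    With no covariates this reduces to the reciprocal allocation
    proportions.  ``stabilised=True`` multiplies by the marginal arm
    proportion (same point estimates, smaller weight magnitudes)."""
    if not data.covariates_observed().all():
        raise TrialAdjustError(
            "treatment weights need complete covariates; impute or transform "
            "first (see the missing-data utilities)"
        )
    z = data.arm.astype(float)
    X, names = build_design(data, include_arm=False, covariate_names=covariate_names)
    model = fit_glm(
        z, X, names, family="binomial", link="logit",
        model_label="treatment (propensity) model",
    )
    e = model.predict(X)
    p_received = np.where(z == 1, e, 1 - e)
    w = 1.0 / p_received
    if stabilised:
        pz = z.mean()
        w *= np.where(z == 1, pz, 1 - pz)
    if normalisation == "mean_one_per_arm":
        for arm in (0, 1):
            w[z == arm] /= w[z == arm].mean()
    return WeightSet(
        weights=w,
        weight_type="treatment",
        models=[_WeightModel(X=X, prob=e, response=z, names=names)],
        normalisation=normalisation,
    )


def combine_weights(treatment: WeightSet, missingness: WeightSet) -> WeightSet:
    """Product of treatment and missingness weights on the rows where the
    missingness weight is defined (outcome-observed rows)."""
    if len(treatment.weights) != len(missingness.weights):
        raise TrialAdjustError("weight sets are not aligned to the same rows")
    return WeightSet(
        weights=treatment.weights * missingness.weights,
        weight_type="product",
        models=treatment.models + missingness.models,
        normalisation="none",
    )


def iptw_estimate(
    data: TrialDataset,
    weights: WeightSet,
    estimand: EstimandSpec,
    se_method: str = "stacked",  # {"stacked", "naive"}
    level: float = 0.95,
    small_sample_threshold: int = 100,
) -> AdjustmentResult:
    """Weighted arm contrast with a sandwich variance.

    The point estimate is the contrast of weighted arm means, identical to a
    weighted arm-only GLM with the link implied by the measure.  The
    ``stacked`` SE solves the joint estimating equations for the weight
    model(s) and the weighted means; ``naive`` treats the weights as known.
    """
    if estimand.measure not in _CONTRAST:
        raise UnsupportedEstimandError(
            "IPTW always targets a marginal summary measure; for the "
            "conditional odds ratio use direct adjustment"
        )
    mask = data.outcome_observed() & weights.defined()
    if not mask.any():
        raise TrialAdjustError("no usable rows (observed outcome with weights)")
    y = data.outcome
    z = data.arm.astype(float)
    w = weights.weights
    m1 = mask & (z == 1)
    m0 = mask & (z == 0)
    mu1 = float(np.sum(w[m1] * y[m1]) / np.sum(w[m1]))
    mu0 = float(np.sum(w[m0] * y[m0]) / np.sum(w[m0]))

    transform = _CONTRAST[estimand.measure]
    if transform != "difference" and (
        min(mu1, mu0) <= 0 or (transform == "log_odds_ratio" and max(mu1, mu0) >= 1)
    ):
        raise TrialAdjustError("degenerate weighted mean (0 or 1) for a ratio measure")
    est = contrast_value(mu1, mu0, transform)

    V = _sandwich_mu_vcov(y, z, w, mask, weights.models if se_method == "stacked" else [],
                          mu1, mu0)
    g = contrast_gradient(mu1, mu0, transform)
    se = float(np.sqrt(max(g @ V @ g, 0.0)))

    q = stats.norm.ppf(0.5 + level / 2)
    z_stat = est / se if se > 0 else np.inf
    notes = []
    if se_method == "naive":
        notes.append("weights treated as known in the variance (shortcut)")
    n_used = int(mask.sum())
    if n_used < small_sample_threshold:
        notes.append(
            f"n = {n_used} < {small_sample_threshold}: sandwich standard "
            "errors can be anti-conservative in small samples; consider a "
            "design-respecting bootstrap"
        )
    summary = float(np.exp(est)) if transform != "difference" else est
    return AdjustmentResult(
        estimate_summary_scale=summary,
        estimate_estimation_scale=float(est),
        se_estimation_scale=se,
        ci=(est - q * se, est + q * se),
        z_statistic=float(z_stat),
        p_value=float(2 * stats.norm.sf(abs(z_stat))),
        method="iptw",
        estimand=estimand,
        n_used=n_used,
        level=level,
        notes=notes,
    )


def _sandwich_mu_vcov(y, z, w, mask, models, mu1, mu0) -> np.ndarray:
    """Covariance of the weighted arm means (mu1, mu0) by M-estimation.

    Estimating equations per participant i:
      weight model k:  x_ki (r_ki - p_ki)            (logistic score)
      mu1:             1{i used, z=1} W_i (y_i - mu1)
      mu0:             1{i used, z=0} W_i (y_i - mu0)
    where W_i is the product of the component weights and, for each
    component, d log W_i / d alpha_k = (p_ki - r_ki) x_ki.
    """
    n = len(y)
    dims = [m.X.shape[1] for m in models]
    p_alpha = sum(dims)
    dim = p_alpha + 2
    A = np.zeros((dim, dim))
    psi = np.zeros((n, dim))

    u1 = mask & (z == 1)
    u0 = mask & (z == 0)
    yc = np.where(mask, np.nan_to_num(y), 0.0)
    r1 = np.where(u1, w * (yc - mu1), 0.0)
    r0 = np.where(u0, w * (yc - mu0), 0.0)
    psi[:, p_alpha] = r1
    psi[:, p_alpha + 1] = r0
    A[p_alpha, p_alpha] = np.sum(w[u1]) / n
    A[p_alpha + 1, p_alpha + 1] = np.sum(w[u0]) / n

    offset = 0
    for m, d in zip(models, dims):
        sl = slice(offset, offset + d)
        score = m.X * (m.response - m.prob)[:, None]
        psi[:, sl] = score
        A[sl, sl] = (m.X * (m.prob * (1 - m.prob))[:, None]).T @ m.X / n
        # - d psi_mu / d alpha = - (residual) * dW/dalpha = -(residual)*(p - r) x
        dlogw = m.X * (m.prob - m.response)[:, None]
        A[p_alpha, sl] = -(r1[:, None] * dlogw).sum(axis=0) / n
        A[p_alpha + 1, sl] = -(r0[:, None] * dlogw).sum(axis=0) / n
        offset += d

    B = psi.T @ psi / n
    Ainv = np.linalg.pinv(A)
    V = Ainv @ B @ Ainv.T / n
    return V[p_alpha:, p_alpha:]
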