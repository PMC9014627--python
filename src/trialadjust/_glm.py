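"""Internal GLM layer: design-matrix construction and guarded fitting.

Model fitting is delegated to statsmodels; this layer pins the covariate
coding (reference-cell dummies against the first declared level), applies the
package-wide convergence criteria, and converts the various ways a fit can go
wrong into a typed :class:`ConvergenceFailure` instead of a silently wrong
estimate.  Identity- and log-link binomial fits additionally require the
fitted probabilities to lie strictly inside (0, 1) at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .data import ARM, TrialDataset
from .results import ConvergenceError, ConvergenceFailure

# Package-wide convergence grid: deviance tolerance and iteration cap for
# IRLS, and the |coefficient| bound on log/logit scales beyond which a fit is
# declared separated.
DEVIANCE_TOL = 1e-10
MAX_ITER = 100
SEPARATION_BOUND = 15.0

_FAMILIES = {
    ("binomial", "logit"): lambda: sm.families.Binomial(),
    ("binomial", "log"): lambda: sm.families.Binomial(link=sm.families.links.Log()),
    ("binomial", "identity"): lambda: sm.families.Binomial(
        link=sm.families.links.Identity()
    ),
    ("poisson", "log"): lambda: sm.families.Poisson(),
    ("gaussian", "identity"): lambda: sm.families.Gaussian(),
}


def build_design(
    data: TrialDataset,
    include_arm: bool = True,
    covariate_names: list[str] | None = None,
    arm_interactions: bool = False,
    frame=None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept, arm, covariate main effects and
    (optionally) arm x covariate interactions.

    Categorical covariates are dummy-coded against their first declared
    level, so coefficient values are pinned by the declaration order.
    ``frame`` overrides the rows used (for predictions on counterfactual
    arms) while the coding still comes from ``data``'s declarations.
    """
    df = data.frame if frame is None else frame
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if include_arm:
        cols.append(df[ARM].to_numpy(dtype=float))
        names.append(ARM)
    main_cols: list[tuple[str, np.ndarray]] = []
    for name in covariate_names if covariate_names is not None else data.covariates:
        spec = data.covariates[name]
        if spec.kind == "continuous":
            main_cols.append((name, df[name].to_numpy(dtype=float)))
        else:
            for level in spec.levels[1:]:
                main_cols.append(
                    (f"{name}[{level}]", (df[name] == level).to_numpy(dtype=float))
                )
    for label, col in main_cols:
        cols.append(col)
        names.append(label)
    if arm_interactions and include_arm:
        z = df[ARM].to_numpy(dtype=float)
        for label, col in main_cols:
            cols.append(z * col)
            names.append(f"{ARM}:{label}")
    return np.column_stack(cols), names


@dataclass
class FittedOutcomeModel:
    """A converged GLM fit with its covariance and diagnostics."""

    family: str
    link: str
    coefficients: dict[str, float]
    params: np.ndarray
    vcov: np.ndarray
    names: list[str]
    converged: bool
    n_iter: int
    n_obs: int
    fitted: np.ndarray
    separation_flag: bool = False
    dropped_terms: list[str] = field(default_factory=list)
    _sm_result: object = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = X @ self.params
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        if self.link == "log":
            return np.exp(eta)
        return eta

    def link_derivative(self, X: np.ndarray) -> np.ndarray:
        """d mu / d eta evaluated row-wise (for delta-method gradients)."""
        mu = self.predict(X)
        if self.link == "logit":
            return mu * (1.0 - mu)
        if self.link == "log":
            return mu
        return np.ones(len(X))


def fit_glm(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str],
    family: str = "binomial",
    link: str = "logit",
    freq_weights: np.ndarray | None = None,
    robust: str | None = None,
    model_label: str | None = None,
    separation_check: bool = True,
) -> FittedOutcomeModel:
    """Guarded maximum-likelihood fit.

    ``robust`` selects a heteroskedasticity-consistent covariance ("HC0" or
    "HC1") in place of the model-based one.  Raises
    :class:`ConvergenceError` on non-convergence, separation, collinearity,
    or fitted probabilities escaping (0, 1) under a non-canonical binomial
    link.
    """
    key = (family, link)
    if key not in _FAMILIES:
        raise ValueError(f"unsupported family/link {key}")
    label = model_label or f"{family}({link}) model"
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the terms whose removal restores full rank
        dropped = _collinear_terms(X, names)
        raise ConvergenceError(
            ConvergenceFailure(
                model=label,
                reason="collinearity",
                detail=f"rank {rank} < {X.shape[1]} columns; implicated terms: {dropped}",
                advice="remove or merge the implicated terms",
            )
        )

    kwargs = {}
    if freq_weights is not None:
        kwargs["freq_weights"] = np.asarray(freq_weights, dtype=float)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # DomainWarning for identity binomial
        model = sm.GLM(y, X, family=_FAMILIES[key](), **kwargs)
    try:
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # typed failures replace warnings
            if robust:
                res = model.fit(maxiter=MAX_ITER, tol=DEVIANCE_TOL, cov_type=robust)
            else:
                res = model.fit(maxiter=MAX_ITER, tol=DEVIANCE_TOL)
    except PerfectSeparationError as exc:
        raise ConvergenceError(
            ConvergenceFailure(
                model=label,
                reason="separation",
                detail=str(exc),
                advice="remove the perfectly predictive term or use augmentation",
            )
        ) from exc
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise ConvergenceError(
            ConvergenceFailure(
                model=label,
                reason="invalid_fitted_values",
                detail=f"iteration left the valid mean space: {exc}",
                advice="switch to a canonical-link model (e.g. logistic) and "
                "standardise to the target measure",
            )
        ) from exc

    params = np.asarray(res.params, dtype=float)
    mu = np.asarray(res.fittedvalues, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ConvergenceError(
            ConvergenceFailure(model=label, reason="max_iterations",
                               detail="non-finite coefficients")
        )
    n_iter = getattr(res, "fit_history", {}).get("iteration", MAX_ITER)
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            ConvergenceFailure(model=label, reason="max_iterations",
                               detail=f"no convergence in {MAX_ITER} iterations")
        )

    if family == "binomial" and link in {"log", "identity"}:
        eps = 1e-10
        if np.any(mu <= eps) or np.any(mu >= 1 - eps):
            raise ConvergenceError(
                ConvergenceFailure(
                    model=label,
                    reason="invalid_fitted_values",
                    detail="fitted probabilities on the boundary of (0, 1)",
                    advice="the constraint binds at the optimum; use "
                    "standardisation after a logistic fit instead",
                )
            )

    if separation_check and link in {"logit", "log"}:
        worst = int(np.argmax(np.abs(params)))
        if abs(params[worst]) > SEPARATION_BOUND:
            raise ConvergenceError(
                ConvergenceFailure(
                    model=label,
                    reason="separation",
                    detail=f"|coefficient| of {names[worst]!r} exceeds "
                    f"{SEPARATION_BOUND} on the {link} scale "
                    f"({params[worst]:.1f})",
                    advice="the term perfectly predicts the outcome",
                )
            )

    return FittedOutcomeModel(
        family=family,
        link=link,
        coefficients=dict(zip(names, params)),
        params=params,
        vcov=np.asarray(res.cov_params(), dtype=float),
        names=list(names),
        converged=True,
        n_iter=int(n_iter) if np.isscalar(n_iter) else MAX_ITER,
        n_obs=int(res.nobs),
        fitted=mu,
        _sm_result=res,
    )


def _collinear_terms(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    dropped = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            dropped.append(names[j])
    return dropped
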