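"""Synthetic trials with known truth, plus the bundled worked examples.

The generator composes a randomisation scheme (simple, stratified permuted
blocks, or minimisation), an outcome model on the logit or identity scale,
and a missingness mechanism.  True marginal and conditional estimand values
are computed analytically from the specification — by exact enumeration for
finite-support covariates and Gauss-Hermite quadrature for a normal
covariate — so parameter-recovery and coverage tests compare against truth,
not against another estimator.

Two fixed worked examples are bundled: the 40-participant two-stratum table
illustrating non-collapsibility of the odds ratio, and the 2000-participant
notional trial with covariate-dependent missingness and effect modification.
The latter's cell counts are cross-validated at load time against the
linear system implied by its published summary values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    ARM,
    OUTCOME,
    CovariateSpec,
    RandomisationDesign,
    StratifiedCounts,
    TrialDataset,
)
from .results import TrialAdjustError


class FixtureError(TrialAdjustError):
    """Bundled worked-example counts inconsistent with their oracle."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateDist:
    """Marginal distribution of one independent baseline covariate."""

    name: str
    kind: str = "categorical"  # or "continuous" (normal)
    levels: tuple = (0, 1)
    probs: tuple = (0.5, 0.5)
    mean: float = 0.0
    sd: float = 1.0

    def support(self) -> tuple[np.ndarray, np.ndarray]:
        """(values, probabilities) for enumeration/quadrature."""
        if self.kind == "categorical":
            return np.asarray(self.levels, dtype=float), np.asarray(self.probs)
        nodes, weights = np.polynomial.hermite_e.hermegauss(64)
        return self.mean + self.sd * nodes, weights / weights.sum()


@dataclass(frozen=True)
class OutcomeModelSpec:
    """True outcome-generating model.

    ``covariate_effects`` maps term strings to coefficients; a term is a
    covariate name, ``name^2`` for its square, or ``name[level]`` for a
    level indicator.  ``effect_modification`` holds arm x term coefficients.
    """

    family: str  # {"binomial", "gaussian"}
    link: str  # {"logit", "identity"}
    intercept: float
    treatment_effect: float
    covariate_effects: dict = field(default_factory=dict)
    effect_modification: dict = field(default_factory=dict)
    residual_sd: float = 0.0


@dataclass(frozen=True)
class MissingnessSpec:
    """Outcome-missingness mechanism.

    mechanism in {"none", "arm_dependent", "covariate_dependent",
    "outcome_dependent"}; ``probabilities`` maps the conditioning value
    (arm, covariate level, or outcome value) to P(missing)."""

    mechanism: str = "none"
    covariate: str | None = None
    probabilities: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(not (0 <= p <= 1) for p in self.probabilities.values()):
            raise ValueError("missingness probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class TrueEstimands:
    """Analytic estimand values implied by a generating specification."""

    mean1: float
    mean0: float
    conditional_scale_effect: float  # treatment coefficient on the link scale
    has_effect_modification: bool
    family: str

    @property
    def mean_difference(self) -> float:
        return self.mean1 - self.mean0

    @property
    def risk_difference(self) -> float:
        return self.mean1 - self.mean0

    @property
    def log_risk_ratio(self) -> float:
        return float(np.log(self.mean1 / self.mean0))

    @property
    def marginal_log_odds_ratio(self) -> float:
        return float(
            np.log(self.mean1 / (1 - self.mean1)) - np.log(self.mean0 / (1 - self.mean0))
        )

    @property
    def conditional_log_odds_ratio(self) -> float:
        if self.has_effect_modification:
            raise TrialAdjustError(
                "no common conditional effect under effect modification"
            )
        return self.conditional_scale_effect


# ---------------------------------------------------------------------------
# Randomisation schemes
# ---------------------------------------------------------------------------

def assign_simple(n: int, allocation_ratio=(1, 1), rng=None) -> np.ndarray:
    rng = np.random.default_rng(rng)
    r1, r0 = allocation_ratio
    return rng.binomial(1, r1 / (r1 + r0), size=n)


def assign_stratified_blocks(
    strata_labels, block_size: int, allocation_ratio=(1, 1), rng=None
) -> np.ndarray:
    """Permuted blocks within each stratum, in participant order.

    ``allocation_ratio`` is (intervention, control); ``block_size`` must be
    divisible by its sum.  With every block completed the within-stratum
    arm split is exact."""
    r1, r0 = allocation_ratio
    if block_size % (r1 + r0):
        raise TrialAdjustError(
            f"block size {block_size} not divisible by allocation total {r1 + r0}"
        )
    rng = np.random.default_rng(rng)
    labels = np.asarray(strata_labels)
    arms = np.zeros(len(labels), dtype=int)
    unit = block_size // (r1 + r0)
    template = np.array([1] * (unit * r1) + [0] * (unit * r0))
    for stratum in pd.unique(labels):
        idx = np.flatnonzero(labels == stratum)
        assigned = []
        while len(assigned) < len(idx):
            assigned.extend(rng.permutation(template))
        arms[idx] = assigned[: len(idx)]
    return arms


def assign_minimisation(
    records: pd.DataFrame, prob_favoured: float = 0.8, rng=None
) -> np.ndarray:
    """Sequential minimisation over equally weighted categorical covariates.

    For each arriving participant, the marginal imbalance (sum over
    balancing covariates of |arm-count difference| within the participant's
    level) is computed under each hypothetical assignment; the minimising
    arm is chosen with probability ``prob_favoured``, ties by fair coin."""
    for col in records.columns:
        if records[col].dtype.kind == "f":
            raise TrialAdjustError(
                f"balancing covariate {col!r} is continuous; minimisation "
                "requires categorical covariates"
            )
    rng = np.random.default_rng(rng)
    counts: dict[tuple, np.ndarray] = {}
    arms = np.zeros(len(records), dtype=int)
    values = records.to_numpy()
    cols = list(records.columns)
    for i, row in enumerate(values):
        keys = [(c, v) for c, v in zip(cols, row)]
        imbalance = []
        for candidate in (0, 1):
            total = 0.0
            for key in keys:
                n = counts.get(key, np.zeros(2)).copy()
                n[candidate] += 1
                total += abs(n[1] - n[0])
            imbalance.append(total)
        if imbalance[0] == imbalance[1]:
            arm = int(rng.integers(2))
        else:
            favoured = int(imbalance[1] < imbalance[0])
            arm = favoured if rng.random() < prob_favoured else 1 - favoured
        arms[i] = arm
        for key in keys:
            counts.setdefault(key, np.zeros(2))[arm] += 1
    return arms


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

def _evaluate_term(term: str, values: dict) -> float:
    if term.endswith("^2"):
        return float(values[term[:-2]]) ** 2
    if term.endswith("]"):
        name, level = term[:-1].split("[", 1)
        v = values[name]
        return float(str(v) == level)
    return float(values[term])


def _linear_predictor(spec: OutcomeModelSpec, values: dict, z: float) -> float:
    eta = spec.intercept + spec.treatment_effect * z
    for term, coef in spec.covariate_effects.items():
        eta += coef * _evaluate_term(term, values)
    for term, coef in spec.effect_modification.items():
        eta += coef * z * _evaluate_term(term, values)
    return eta


def _mean_from_eta(spec: OutcomeModelSpec, eta):
    if spec.link == "logit":
        return 1.0 / (1.0 + np.exp(-np.asarray(eta)))
    return np.asarray(eta)


def true_estimands(
    covariates: list[CovariateDist], outcome: OutcomeModelSpec
) -> TrueEstimands:
    """Exact marginal means under each arm by integrating the outcome model
    over the covariate distribution."""
    supports = [c.support() for c in covariates]
    names = [c.name for c in covariates]
    means = {}
    for z in (0, 1):
        total = 0.0
        for combo in itertools.product(*[range(len(v)) for v, _ in supports]):
            values = {n: supports[j][0][combo[j]] for j, n in enumerate(names)}
            prob = float(np.prod([supports[j][1][combo[j]] for j in range(len(names))]))
            mu = float(_mean_from_eta(outcome, _linear_predictor(outcome, values, z)))
            if outcome.family == "binomial" and not (0 <= mu <= 1):
                raise TrialAdjustError(
                    "outcome specification yields a probability outside [0, 1]"
                )
            total += prob * mu
        means[z] = total
    return TrueEstimands(
        mean1=means[1],
        mean0=means[0],
        conditional_scale_effect=outcome.treatment_effect,
        has_effect_modification=bool(outcome.effect_modification),
        family=outcome.family,
    )


def generate_trial(
    n: int,
    design: RandomisationDesign,
    covariates: list[CovariateDist],
    outcome: OutcomeModelSpec,
    missing: MissingnessSpec = MissingnessSpec(),
    seed: int | None = None,
) -> tuple[TrialDataset, TrueEstimands]:
    """Simulate one trial; bitwise reproducible given (specs, seed)."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(index=range(n))
    for c in covariates:
        if c.kind == "categorical":
            frame[c.name] = rng.choice(np.asarray(c.levels), size=n, p=np.asarray(c.probs))
        else:
            frame[c.name] = rng.normal(c.mean, c.sd, size=n)

    if design.scheme == "simple":
        z = assign_simple(n, design.allocation_ratio, rng)
    elif design.scheme == "stratified_block":
        labels = frame[list(design.strata_covariates)].astype(str).agg("|".join, axis=1)
        z = assign_stratified_blocks(labels, design.block_size,
                                     design.allocation_ratio, rng)
    else:
        z = assign_minimisation(
            frame[list(design.strata_covariates)], design.prob_favoured, rng
        )
    frame[ARM] = z

    eta = _eta_vector(outcome, frame, z)
    mu = _mean_from_eta(outcome, eta)
    if outcome.family == "binomial":
        if np.any(mu < 0) or np.any(mu > 1):
            raise TrialAdjustError("linear predictor gives invalid probability")
        y = rng.binomial(1, mu).astype(float)
        outcome_type = "binary"
    else:
        y = mu + outcome.residual_sd * rng.standard_normal(n)
        outcome_type = "continuous"
    frame[OUTCOME] = y

    miss = _missingness_mask(missing, frame, rng)
    frame.loc[miss, OUTCOME] = np.nan

    covs = {
        c.name: (
            CovariateSpec("categorical", tuple(c.levels))
            if c.kind == "categorical"
            else CovariateSpec("continuous")
        )
        for c in covariates
    }
    data = TrialDataset(frame=frame, covariates=covs, design=design,
                        outcome_type=outcome_type)
    return data, true_estimands(covariates, outcome)


def _eta_vector(spec, frame, z):
    eta = np.full(len(frame), spec.intercept, dtype=float) + spec.treatment_effect * z
    for term, coef in spec.covariate_effects.items():
        eta += coef * _term_column(term, frame)
    for term, coef in spec.effect_modification.items():
        eta += coef * z * _term_column(term, frame)
    return eta


def _term_column(term: str, frame: pd.DataFrame) -> np.ndarray:
    if term.endswith("^2"):
        return frame[term[:-2]].to_numpy(dtype=float) ** 2
    if term.endswith("]"):
        name, level = term[:-1].split("[", 1)
        return (frame[name].astype(str) == level).to_numpy(dtype=float)
    return frame[term].to_numpy(dtype=float)


def _missingness_mask(missing: MissingnessSpec, frame: pd.DataFrame, rng) -> np.ndarray:
    n = len(frame)
    if missing.mechanism == "none":
        return np.zeros(n, dtype=bool)
    if missing.mechanism == "arm_dependent":
        p = np.array([missing.probabilities.get(int(z), 0.0) for z in frame[ARM]])
    elif missing.mechanism == "covariate_dependent":
        col = frame[missing.covariate]
        p = np.array([missing.probabilities.get(v, 0.0) for v in col])
    elif missing.mechanism == "outcome_dependent":
        p = np.array([missing.probabilities.get(int(y), 0.0) for y in frame[OUTCOME]])
    else:
        raise ValueError(f"unknown mechanism {missing.mechanism!r}")
    return rng.random(n) < p


# ---------------------------------------------------------------------------
# Covariate-model misspecification experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MisspecificationScenario:
    interval: tuple[float, float]
    lambda_hat: float
    theta_hat: float
    se_adjusted: float
    se_unadjusted: float


def figure1_experiment(
    intervals=((-0.5, 0.5), (0.0, 1.0), (0.5, 1.5)),
    n_grid: int = 201,
    alpha: float = 0.0,
    theta: float = 1.0,
    gamma: float = 1.0,
    stochastic: bool = False,
    seed: int | None = None,
) -> list[MisspecificationScenario]:
    """Fit a linear covariate model to outcomes generated by a quadratic one.

    The true model is Y = alpha + theta Z + gamma X^2 with no residual
    error; the analyst fits y = a + t z + l x.  The covariate values are a
    deterministic uniform grid on each interval (each grid point appears in
    both arms, so x and z are exactly orthogonal); a stochastic variant
    draws X uniformly instead.  With X centred at 0 the sample correlation
    of x with x^2 vanishes and lambda_hat = 0; on shifted intervals the
    linear term partially adjusts for the quadratic and lambda_hat > 0.
    Standard errors are asymptotic (residual variance RSS / n), under which
    linear adjustment is never less efficient than no adjustment.
    """
    rng = np.random.default_rng(seed)
    out = []
    for lo, hi in intervals:
        if stochastic:
            x = rng.uniform(lo, hi, size=n_grid)
        else:
            x = np.linspace(lo, hi, n_grid)
        x = np.concatenate([x, x])
        z = np.concatenate([np.ones(n_grid), np.zeros(n_grid)])
        y = alpha + theta * z + gamma * x**2
        n = len(y)

        def ols(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = resid @ resid / n
            cov = sigma2 * np.linalg.inv(X.T @ X)
            return beta, cov

        Xa = np.column_stack([np.ones(n), z, x])
        beta_a, cov_a = ols(Xa)
        Xu = np.column_stack([np.ones(n), z])
        _, cov_u = ols(Xu)
        out.append(
            MisspecificationScenario(
                interval=(lo, hi),
                lambda_hat=float(beta_a[2]),
                theta_hat=float(beta_a[1]),
                se_adjusted=float(np.sqrt(cov_a[1, 1])),
                se_unadjusted=float(np.sqrt(cov_u[1, 1])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bundled worked examples
# ---------------------------------------------------------------------------

def fixture_table2() -> StratifiedCounts:
    """Two strata, 40 participants, a common within-stratum odds ratio of 9
    and a marginal odds ratio of 5.4: the non-collapsibility illustration.

    Columns are (control, intervention)."""
    return StratifiedCounts(
        strata=["A", "B"],
        events=np.array([[5, 9], [1, 5]]),
        nonevents=np.array([[5, 1], [9, 5]]),
    )


# Published summary values of the notional-trial example, used as the
# calibration inputs of the reconstruction oracle (3 dp as printed).
_NOTIONAL_SUMMARIES = {
    "rd_all": -0.056,
    "rr_all": 0.748,
    "rd_cc": -0.064,
    "rr_cc": 0.761,
}


def _oracle_cell_risks() -> np.ndarray:
    """Solve the four linear equations linking the published risk
    differences/ratios (all-randomised and complete-case) to the four cell
    risks p[z, x]; complete cases keep all of X=1 but only half of X=0."""
    t = _NOTIONAL_SUMMARIES
    # s_z = p[z,0] + p[z,1] (all-randomised, equal stratum weights x 2)
    s0 = 2 * t["rd_all"] / (t["rr_all"] - 1)
    s1 = t["rr_all"] * s0
    # u_z = p[z,0] + 2 p[z,1] (complete cases, weights 1:2, x 3)
    u0 = 3 * t["rd_cc"] / (t["rr_cc"] - 1)
    u1 = t["rr_cc"] * u0
    p = np.empty((2, 2))
    p[0, 1] = u0 - s0
    p[0, 0] = 2 * s0 - u0
    p[1, 1] = u1 - s1
    p[1, 0] = 2 * s1 - u1
    return p


@dataclass(frozen=True)
class AppendixFixture:
    """The 2x2x2 notional trial: full data and its complete-case view.

    ``full`` holds 2000 participants (500 per covariate-by-arm cell).
    ``complete_case`` is expressed at doubled scale (1000 per X=1 cell, 500
    per X=0 cell) so that halving the X=0 cells stays integral; every
    summary measure is invariant to that scaling."""

    full: StratifiedCounts
    complete_case: StratifiedCounts
    cell_risks: np.ndarray  # [z, x]


def fixture_appendix_table5(tolerance: float = 0.01) -> AppendixFixture:
    # events per 500 by (x, arm): columns (control, intervention)
    events = np.array([[43, 27], [179, 139]])
    full = StratifiedCounts(
        strata=[0, 1], events=events, nonevents=500 - events
    )
    cc_events = np.array([[43, 27], [358, 278]])
    cc_totals = np.array([[500, 500], [1000, 1000]])
    cc = StratifiedCounts(
        strata=[0, 1], events=cc_events, nonevents=cc_totals - cc_events
    )
    risks = np.stack([events[:, 0] / 500, events[:, 1] / 500], axis=0)  # [z, x]
    oracle = _oracle_cell_risks()
    if np.max(np.abs(risks - oracle)) > tolerance:
        raise FixtureError(
            f"bundled cell risks deviate from the reconstruction oracle by "
            f"{np.max(np.abs(risks - oracle)):.4f} (> {tolerance})"
        )
    return AppendixFixture(full=full, complete_case=cc, cell_risks=risks)


def appendix_missingness_dataset() -> TrialDataset:
    """Record-level version of the notional trial with its deterministic
    covariate-dependent outcome missingness applied.

    Built at doubled scale (4000 records, 1000 per cell): within each
    X=0-by-arm cell exactly half of the events and half of the non-events
    have a missing outcome, so the complete-case cell risks equal the true
    ones exactly."""
    fx = fixture_appendix_table5()
    rows = []
    for x in (0, 1):
        for z in (0, 1):
            e = int(fx.full.events[x, z]) * 2
            ne = int(fx.full.nonevents[x, z]) * 2
            if x == 0:
                rows.append((x, z, 1.0, e // 2))
                rows.append((x, z, np.nan, e - e // 2))
                rows.append((x, z, 0.0, ne // 2))
                rows.append((x, z, np.nan, ne - ne // 2))
            else:
                rows.append((x, z, 1.0, e))
                rows.append((x, z, 0.0, ne))
    frame = pd.DataFrame(
        {
            "x": np.repeat([r[0] for r in rows], [r[3] for r in rows]),
            ARM: np.repeat([r[1] for r in rows], [r[3] for r in rows]),
            OUTCOME: np.repeat([r[2] for r in rows], [r[3] for r in rows]),
        }
    )
    design = RandomisationDesign(
        scheme="stratified_block", strata_covariates=("x",), block_size=2
    )
    return TrialDataset(
        frame=frame,
        covariates={"x": CovariateSpec("categorical", (0, 1))},
        design=design,
        outcome_type="binary",
    )
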