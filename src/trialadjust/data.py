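"""Participant-level trial data model and 2x2xK count-table conversions.

A :class:`TrialDataset` wraps a pandas DataFrame with a fixed column layout:
``arm`` (0/1, 1 = intervention), ``outcome`` (binary 0/1 or continuous, NaN
when missing), and one column per declared baseline covariate.  Categorical
covariates carry an explicit ordered level list; the first declared level is
the reference for model coding.  :class:`StratifiedCounts` is the compact
2 (arm) x 2 (event) x K (stratum) representation used by the worked examples
and by exact small-table oracles; ``expand_counts``/``collapse`` convert
between the two losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .results import TrialAdjustError, ValidationReport

ARM = "arm"
OUTCOME = "outcome"

MEASURES = (
    "mean_difference",
    "risk_difference",
    "risk_ratio",
    "marginal_odds_ratio",
    "conditional_odds_ratio",
)
COLLAPSIBLE_MEASURES = frozenset(
    {"mean_difference", "risk_difference", "risk_ratio"}
)
RATIO_MEASURES = frozenset(
    {"risk_ratio", "marginal_odds_ratio", "conditional_odds_ratio"}
)
MARGINAL_MEASURES = frozenset(
    {"mean_difference", "risk_difference", "risk_ratio", "marginal_odds_ratio"}
)


@dataclass(frozen=True)
class RandomisationDesign:
    """How arms were assigned; drives design-respecting inference.

    ``prob_favoured`` (minimisation only) is the probability of assigning the
    marginal-imbalance-minimising arm; the conventional default is 0.8.
    """

    scheme: str = "simple"  # {"simple", "stratified_block", "minimisation"}
    allocation_ratio: tuple[int, int] = (1, 1)
    strata_covariates: tuple[str, ...] = ()
    block_size: int | None = None
    prob_favoured: float = 0.8

    def __post_init__(self):
        if self.scheme not in {"simple", "stratified_block", "minimisation"}:
            raise ValueError(f"unknown randomisation scheme {self.scheme!r}")
        a, b = self.allocation_ratio
        if a <= 0 or b <= 0:
            raise ValueError("allocation ratio must be positive")
        if self.scheme == "stratified_block":
            if self.block_size is None or self.block_size % (a + b):
                raise ValueError(
                    "block_size must be a positive multiple of the summed "
                    "allocation ratio"
                )
        if not (0.5 <= self.prob_favoured <= 1.0):
            raise ValueError("prob_favoured must lie in [0.5, 1]")


@dataclass(frozen=True)
class CovariateSpec:
    """Declared role of one baseline covariate."""

    kind: str  # {"categorical", "continuous"}
    levels: tuple = ()  # categorical only; first level is the reference

    def __post_init__(self):
        if self.kind not in {"categorical", "continuous"}:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 1:
            raise ValueError("categorical covariates need declared levels")


@dataclass(frozen=True)
class EstimandSpec:
    """Summary measure + target population.

    The estimation scale is derived from the measure: ratio measures are
    estimated on the log scale, differences on the identity scale.  The
    ``collapsible`` flag records whether marginal and conditional versions of
    the measure coincide (true for differences and the risk ratio, false for
    both odds ratios).
    """

    measure: str
    population: str = "all_randomised"  # or "complete_case"

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.population not in {"all_randomised", "complete_case"}:
            raise ValueError(f"unknown population {self.population!r}")

    @property
    def collapsible(self) -> bool:
        return self.measure in COLLAPSIBLE_MEASURES

    @property
    def estimation_scale(self) -> str:
        return "log" if self.measure in RATIO_MEASURES else "identity"


@dataclass
class TrialDataset:
    """Participant-level records plus covariate declarations and design."""

    frame: pd.DataFrame
    covariates: dict[str, CovariateSpec] = field(default_factory=dict)
    design: RandomisationDesign = field(default_factory=RandomisationDesign)
    outcome_type: str = "binary"  # or "continuous"

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        missing_cols = {ARM, OUTCOME} - set(self.frame.columns)
        if missing_cols:
            raise TrialAdjustError(f"dataset lacks column(s) {sorted(missing_cols)}")
        for name in self.covariates:
            if name not in self.frame.columns:
                raise TrialAdjustError(f"declared covariate {name!r} not in data")

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def arm(self) -> np.ndarray:
        return self.frame[ARM].to_numpy()

    @property
    def outcome(self) -> np.ndarray:
        return self.frame[OUTCOME].to_numpy(dtype=float)

    def outcome_observed(self) -> np.ndarray:
        return ~pd.isna(self.frame[OUTCOME]).to_numpy()

    def covariates_observed(self) -> np.ndarray:
        if not self.covariates:
            return np.ones(self.n, dtype=bool)
        return ~self.frame[list(self.covariates)].isna().any(axis=1).to_numpy()

    def subset(self, mask: np.ndarray) -> "TrialDataset":
        return replace(self, frame=self.frame.loc[mask].reset_index(drop=True))


@dataclass
class StratifiedCounts:
    """2x2xK event/non-event counts: Table-2-style worked-example input.

    ``events``/``nonevents`` have shape (K, 2) with column 0 = control and
    column 1 = intervention.
    """

    strata: list
    events: np.ndarray
    nonevents: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=int)
        self.nonevents = np.asarray(self.nonevents, dtype=int)
        k = len(self.strata)
        if self.events.shape != (k, 2) or self.nonevents.shape != (k, 2):
            raise TrialAdjustError("count arrays must have shape (K, 2)")
        if (self.events < 0).any() or (self.nonevents < 0).any():
            raise TrialAdjustError("negative count")
        if ((self.events + self.nonevents) == 0).any():
            raise TrialAdjustError("empty stratum-by-arm cell")

    @property
    def totals(self) -> np.ndarray:
        return self.events + self.nonevents

    @property
    def risks(self) -> np.ndarray:
        return self.events / self.totals

    def marginal(self) -> "StratifiedCounts":
        """Collapse all strata into a single 2x2 table."""
        return StratifiedCounts(
            ["all"],
            self.events.sum(axis=0, keepdims=True),
            self.nonevents.sum(axis=0, keepdims=True),
        )

    def scaled(self, factor: int) -> "StratifiedCounts":
        return StratifiedCounts(
            list(self.strata), self.events * factor, self.nonevents * factor
        )

    # -- closed-form 2x2 contrasts (exact oracles for the estimators) ----
    def marginal_risks(self) -> tuple[float, float]:
        m = self.marginal()
        return float(m.risks[0, 0]), float(m.risks[0, 1])

    def marginal_measure(self, measure: str) -> float:
        r0, r1 = self.marginal_risks()
        if measure == "risk_difference":
            return r1 - r0
        if measure == "risk_ratio":
            return r1 / r0
        if measure == "marginal_odds_ratio":
            return (r1 / (1 - r1)) / (r0 / (1 - r0))
        raise TrialAdjustError(f"no closed 2x2 form for measure {measure!r}")


def validate_dataset(data: TrialDataset) -> ValidationReport:
    """Check the dataset invariants; never mutates the data."""
    v: list[str] = []
    arm = data.frame[ARM]
    if arm.isna().any():
        v.append("arm missing")
    observed_arms = set(arm.dropna().unique())
    if not observed_arms <= {0, 1}:
        v.append(f"arm values outside {{0,1}}: {sorted(observed_arms - {0, 1})}")
    if len(observed_arms & {0, 1}) < 2:
        v.append("single arm")
    if len(set(data.covariates)) != len(data.covariates):  # pragma: no cover
        v.append("duplicate covariate names")
    for name, spec in data.covariates.items():
        if spec.kind == "categorical":
            seen = set(data.frame[name].dropna().unique())
            undeclared = seen - set(spec.levels)
            if undeclared:
                v.append(
                    f"covariate {name!r}: undeclared level(s) {sorted(map(str, undeclared))}"
                )
    if data.outcome_type == "binary":
        values = set(data.frame[OUTCOME].dropna().unique())
        if not values <= {0, 1, 0.0, 1.0}:
            v.append("binary outcome with values outside {0,1}")
    return ValidationReport(violations=v)


def expand_counts(
    counts: StratifiedCounts,
    stratum_covariate: str = "stratum",
    design: RandomisationDesign | None = None,
) -> TrialDataset:
    """One record per counted individual; the stratum label becomes a
    categorical covariate.  ``collapse(expand_counts(c)) == c`` exactly."""
    rows = []
    for k, label in enumerate(counts.strata):
        for z in (0, 1):
            rows.append((label, z, 1, counts.events[k, z]))
            rows.append((label, z, 0, counts.nonevents[k, z]))
    frame = pd.DataFrame(
        {
            stratum_covariate: np.repeat([r[0] for r in rows], [r[3] for r in rows]),
            ARM: np.repeat([r[1] for r in rows], [r[3] for r in rows]),
            OUTCOME: np.repeat([r[2] for r in rows], [r[3] for r in rows]).astype(float),
        }
    )
    covs = {
        stratum_covariate: CovariateSpec("categorical", tuple(counts.strata))
    }
    return TrialDataset(
        frame=frame,
        covariates=covs,
        design=design or RandomisationDesign(),
        outcome_type="binary",
    )


def collapse(data: TrialDataset, stratum_covariate: str) -> StratifiedCounts:
    """Aggregate records into stratum x arm x outcome counts."""
    if data.outcome_type != "binary":
        raise TrialAdjustError("collapse requires a binary outcome")
    if pd.isna(data.frame[OUTCOME]).any():
        raise TrialAdjustError("collapse requires fully observed outcomes")
    spec = data.covariates.get(stratum_covariate)
    if spec is None or spec.kind != "categorical":
        raise TrialAdjustError(
            f"{stratum_covariate!r} is not a declared categorical covariate"
        )
    strata = list(spec.levels)
    events = np.zeros((len(strata), 2), dtype=int)
    nonevents = np.zeros((len(strata), 2), dtype=int)
    g = data.frame.groupby([stratum_covariate, ARM])[OUTCOME]
    for (label, z), series in g:
        k = strata.index(label)
        events[k, int(z)] = int(series.sum())
        nonevents[k, int(z)] = int((1 - series).sum())
    return StratifiedCounts(strata, events, nonevents)
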