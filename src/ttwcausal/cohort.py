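"""Synthetic beneficiary cohorts with known causal ground truth.

The real study population — SSI/SSDI disability beneficiaries allowed at
step 5 of the sequential determination process, followed for benefit
suspension or termination due to work — lives in confidential SSA
administrative files. This module generates cohorts that emulate the
published *marginal* structure of that population (program and RFC-
assessment mixture, ~5% treatment prevalence, ~11% outcome prevalence,
covariate-driven confounding, heavy missingness in mental-function
domains) while exposing the true propensity and potential-outcome
probabilities of every record, so that both downstream analysis arms can
be validated against a known estimand.

The generative model is a pair of logistic regressions sharing covariates:

    A_i ~ Bernoulli( expit(alpha_t + x_i' beta_t + u_t[g_i]) )
    Y_i ~ Bernoulli( expit(alpha_y + x_i' beta_y + u_y[g_i] + psi * A_i) )

where ``g_i`` is the (program, RFC) stratum and ``psi`` the true
conditional log odds ratio of treatment on outcome. Confounding arises
from covariates appearing in both coefficient vectors. Missingness is
completely at random, applied after outcome generation, and never touches
treatment or outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "PROGRAMS",
    "RFC_LEVELS",
    "Covariate",
    "LinearModel",
    "SimulationScenario",
    "GroundTruth",
    "OracleEffects",
    "generate_cohort",
    "oracle_effects",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "default_scenario",
    "covariate_names",
    "CohortError",
    "MalformedHeaderError",
    "MissingColumnError",
    "UnknownLevelError",
    "DomainValueError",
]

PROGRAMS = ("SSI", "SSDI", "Concurrent")
RFC_LEVELS = ("PRFC-only", "MRFC-only", "both")
MANDATORY_COLUMNS = ("record_id", "treatment", "outcome", "program", "rfc")


class CohortError(ValueError):
    """Base class for cohort schema violations."""


class MalformedHeaderError(CohortError):
    """The file header could not be parsed as a cohort table."""


class MissingColumnError(CohortError):
    """A mandatory column is absent."""


class UnknownLevelError(CohortError):
    """A categorical column contains a level outside its declared domain."""


class DomainValueError(CohortError):
    """A value violates its column's domain; names the row and column."""


# ---------------------------------------------------------------------------
# Scenario definition


@dataclass(frozen=True)
class Covariate:
    """One covariate of the generative model.

    kind:
        ``binary``      — Bernoulli(p); ``probs`` is a single probability.
        ``categorical`` — one of ``levels`` with probabilities ``probs``.
        ``ordinal``     — like categorical but the *numeric code* (the index
                          into ``levels``) enters the linear predictors.
        ``count``       — Poisson with rate ``probs`` (a scalar).
    rfc_domain:
        None, "PRFC" or "MRFC": a covariate tied to an assessment type is
        structurally missing for records lacking that assessment.
    """

    name: str
    kind: str
    probs: object
    levels: tuple[str, ...] | None = None
    rfc_domain: str | None = None

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "ordinal", "count"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind in ("categorical", "ordinal"):
            if self.levels is None:
                raise ValueError(f"{self.name}: levels required for {self.kind}")
            p = np.asarray(self.probs, float)
            if len(p) != len(self.levels):
                raise ValueError(f"{self.name}: probs/levels length mismatch")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: level probabilities must sum to 1")


@dataclass(frozen=True)
class LinearModel:
    """Intercept plus per-covariate log-odds contributions.

    Coefficient values are floats for binary/ordinal/count covariates and
    ``{level: float}`` dicts for categorical ones.
    """

    intercept: float
    coefs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationScenario:
    n_records: int
    seed: int
    program_mix: tuple[float, float, float]
    rfc_mix: tuple[float, float, float]
    covariate_spec: tuple[Covariate, ...]
    propensity: LinearModel
    outcome: LinearModel
    true_treatment_logor: float
    subgroup_shifts: dict = field(default_factory=dict)  # (program, rfc) -> (t_shift, y_shift)
    missingness: dict = field(default_factory=dict)  # covariate name -> prob in [0, 1)
    misspec: str = "none"
    misspec_confounder: str | None = None
    rfc_structural_missingness: bool = True

    def __post_init__(self):
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        for label, mix in (("program_mix", self.program_mix), ("rfc_mix", self.rfc_mix)):
            mix = np.asarray(mix, float)
            if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-12 or (mix < 0).any():
                raise ValueError(f"{label} must be a probability triple summing to 1")
        names = [c.name for c in self.covariate_spec]
        if len(set(names)) != len(names):
            raise ValueError("duplicate covariate names")
        for model in (self.propensity, self.outcome):
            for name in model.coefs:
                if name not in names:
                    raise ValueError(f"coefficient for unknown covariate {name!r}")
        for name, p in self.missingness.items():
            if name not in names:
                raise ValueError(f"missingness for unknown covariate {name!r}")
            if not (0.0 <= p < 1.0):
                raise ValueError(f"missing probability for {name!r} not in [0, 1)")
        if self.misspec not in (
            "none",
            "omit_confounder_from_propensity",
            "omit_confounder_from_outcome",
            "nonlinear_truth",
        ):
            raise ValueError(f"unknown misspec switch {self.misspec!r}")

    def covariate(self, name: str) -> Covariate:
        for c in self.covariate_spec:
            if c.name == name:
                return c
        raise KeyError(name)

    def dropped_predictors(self, block: str) -> list[str]:
        """Predictors an intentionally misspecified *analysis* model omits.

        The generator always simulates from the full truth; these switches
        describe the analyst's model, for double-robustness experiments.
        """
        if block not in ("propensity", "outcome"):
            raise ValueError("block must be 'propensity' or 'outcome'")
        if self.misspec == f"omit_confounder_from_{block}":
            name = self.misspec_confounder
            if name is None:
                raise ValueError("misspec set but misspec_confounder is None")
            return [name]
        return []


@dataclass(frozen=True)
class GroundTruth:
    """Per-record true probabilities and cohort-level causal contrasts."""

    per_record: pd.DataFrame  # true_propensity, true_outcome_prob_treated/_control
    true_att: float
    true_ate: float
    true_conditional_or: float


@dataclass(frozen=True)
class OracleEffects:
    """Monte-Carlo estimates of the scenario's marginal causal effects."""

    true_att: float
    true_att_se: float
    true_ate: float
    true_ate_se: float
    true_conditional_or: float
    subgroup_ates: dict | None = None


# ---------------------------------------------------------------------------
# Generation


def _draw_covariates(scenario: SimulationScenario, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for cov in scenario.covariate_spec:
        if cov.kind == "binary":
            cols[cov.name] = rng.binomial(1, float(cov.probs), size=n)
        elif cov.kind in ("categorical", "ordinal"):
            codes = rng.choice(len(cov.levels), size=n, p=np.asarray(cov.probs, float))
            if cov.kind == "ordinal":
                cols[cov.name] = codes
            else:
                cols[cov.name] = np.asarray(cov.levels, object)[codes]
        else:  # count
            cols[cov.name] = rng.poisson(float(cov.probs), size=n)
    return pd.DataFrame(cols)


def _numeric_contribution(cov: Covariate, values: np.ndarray, coef) -> np.ndarray:
    if cov.kind == "categorical":
        lut = {lvl: float(coef.get(lvl, 0.0)) for lvl in cov.levels}
        return np.vectorize(lut.__getitem__, otypes=[float])(values)
    return float(coef) * np.asarray(values, float)


def _linear_predictor(
    scenario: SimulationScenario, model: LinearModel, covs: pd.DataFrame
) -> np.ndarray:
    lp = np.full(len(covs), model.intercept, float)
    for name, coef in model.coefs.items():
        cov = scenario.covariate(name)
        lp += _numeric_contribution(cov, covs[name].to_numpy(), coef)
    if scenario.misspec == "nonlinear_truth" and len(scenario.covariate_spec) >= 2:
        c1, c2 = scenario.covariate_spec[:2]
        x1 = _numeric_contribution(c1, covs[c1.name].to_numpy(), 1.0 if c1.kind != "categorical" else {l: float(i) for i, l in enumerate(c1.levels)})
        x2 = _numeric_contribution(c2, covs[c2.name].to_numpy(), 1.0 if c2.kind != "categorical" else {l: float(i) for i, l in enumerate(c2.levels)})
        lp += 0.8 * x1 * x2
    return lp


def _subgroup_shift(scenario: SimulationScenario, program, rfc, which: int) -> np.ndarray:
    out = np.zeros(len(program))
    for (p, r), shifts in scenario.subgroup_shifts.items():
        out[(program == p) & (rfc == r)] += shifts[which]
    return out


def generate_cohort(scenario: SimulationScenario) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a cohort table plus its causal ground truth.

    Four independent pseudo-random streams (covariates, treatment, outcome,
    missingness) are derived from the scenario seed, so changing e.g. the
    missingness configuration leaves treatment and outcome draws untouched.
    Ground truth is computed from the pre-missingness covariates.
    """
    n = scenario.n_records
    ss = np.random.SeedSequence(scenario.seed)
    rng_cov, rng_trt, rng_out, rng_mis = (np.random.Generator(np.random.PCG64(s)) for s in ss.spawn(4))

    program = rng_cov.choice(PROGRAMS, size=n, p=np.asarray(scenario.program_mix, float))
    rfc = rng_cov.choice(RFC_LEVELS, size=n, p=np.asarray(scenario.rfc_mix, float))
    covs = _draw_covariates(scenario, n, rng_cov)

    lp_t = _linear_predictor(scenario, scenario.propensity, covs)
    lp_t += _subgroup_shift(scenario, program, rfc, 0)
    e = expit(lp_t)
    treatment = rng_trt.binomial(1, e)

    lp_y0 = _linear_predictor(scenario, scenario.outcome, covs)
    lp_y0 += _subgroup_shift(scenario, program, rfc, 1)
    p0 = expit(lp_y0)
    p1 = expit(lp_y0 + scenario.true_treatment_logor)
    outcome = rng_out.binomial(1, np.where(treatment == 1, p1, p0))

    observed = covs.copy()
    for cov in scenario.covariate_spec:
        col = observed[cov.name]
        if col.dtype != object:
            col = col.astype("Int64")
        mask = np.zeros(n, bool)
        if scenario.rfc_structural_missingness and cov.rfc_domain == "PRFC":
            mask |= rfc == "MRFC-only"
        if scenario.rfc_structural_missingness and cov.rfc_domain == "MRFC":
            mask |= rfc == "PRFC-only"
        # one uniform draw per covariate regardless of its rate keeps the
        # missingness stream aligned when individual rates change
        p_miss = scenario.missingness.get(cov.name, 0.0)
        mask |= rng_mis.random(n) < p_miss
        col = col.astype(object) if cov.kind == "categorical" else col
        col = col.mask(mask)
        observed[cov.name] = col

    width = max(7, len(str(n)))
    cohort = pd.DataFrame(
        {
            "record_id": [f"R{i:0{width}d}" for i in range(n)],
            "treatment": treatment.astype(np.int64),
            "outcome": outcome.astype(np.int64),
            "program": program,
            "rfc": rfc,
        }
    )
    cohort = pd.concat([cohort, observed], axis=1)

    contrasts = p1 - p0
    truth = GroundTruth(
        per_record=pd.DataFrame(
            {
                "record_id": cohort["record_id"],
                "true_propensity": e,
                "true_outcome_prob_treated": p1,
                "true_outcome_prob_control": p0,
            }
        ),
        true_att=float(contrasts[treatment == 1].mean()) if treatment.any() else float("nan"),
        true_ate=float(contrasts.mean()),
        true_conditional_or=float(math.exp(scenario.true_treatment_logor)),
    )
    return cohort, truth


def oracle_effects(
    scenario: SimulationScenario, n_mc: int = 200_000, by_subgroup: bool = False
) -> OracleEffects:
    """Monte-Carlo oracle for the scenario's marginal ATT and ATE.

    Averages the expit contrast p1(x) - p0(x) over fresh covariate draws;
    the ATT weights the contrast by the true propensity (the conditional
    probability of treatment), which is exact without simulating treatment.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10,000")
    big = replace(scenario, n_records=n_mc, seed=scenario.seed + 982_451_653 % 2**31)
    ss = np.random.SeedSequence(big.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    program = rng.choice(PROGRAMS, size=n_mc, p=np.asarray(scenario.program_mix, float))
    rfc = rng.choice(RFC_LEVELS, size=n_mc, p=np.asarray(scenario.rfc_mix, float))
    covs = _draw_covariates(scenario, n_mc, rng)
    e = expit(_linear_predictor(scenario, scenario.propensity, covs) + _subgroup_shift(scenario, program, rfc, 0))
    lp0 = _linear_predictor(scenario, scenario.outcome, covs) + _subgroup_shift(scenario, program, rfc, 1)
    d = expit(lp0 + scenario.true_treatment_logor) - expit(lp0)

    ate = float(d.mean())
    ate_se = float(d.std(ddof=1) / math.sqrt(n_mc))
    w = e / e.mean()
    att = float((w * d).mean())
    att_se = float((w * (d - att)).std(ddof=1) / math.sqrt(n_mc))

    sub = None
    if by_subgroup:
        sub = {}
        for p in PROGRAMS:
            for r in RFC_LEVELS:
                m = (program == p) & (rfc == r)
                if m.any():
                    sub[(p, r)] = float(d[m].mean())
    return OracleEffects(
        true_att=att,
        true_att_se=att_se,
        true_ate=ate,
        true_ate_se=ate_se,
        true_conditional_or=float(math.exp(scenario.true_treatment_logor)),
        subgroup_ates=sub,
    )


# ---------------------------------------------------------------------------
# I/O


def covariate_names(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in MANDATORY_COLUMNS]


def validate_cohort(cohort: pd.DataFrame) -> None:
    for col in MANDATORY_COLUMNS:
        if col not in cohort.columns:
            raise MissingColumnError(f"mandatory column {col!r} is missing")
    for col in ("treatment", "outcome"):
        vals = cohort[col]
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise DomainValueError(f"column {col!r}, row {row}: value may not be missing")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DomainValueError(
                f"column {col!r}, row {row}: value {vals.iloc[row]!r} not in {{0, 1}}"
            )
    for col, levels in (("program", PROGRAMS), ("rfc", RFC_LEVELS)):
        vals = cohort[col]
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise DomainValueError(f"column {col!r}, row {row}: value may not be missing")
        bad = ~vals.isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise UnknownLevelError(
                f"column {col!r}, row {row}: unknown level {vals.iloc[row]!r}"
            )
    if cohort["record_id"].duplicated().any():
        raise DomainValueError("column 'record_id': duplicate identifiers")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 delimited text; missing fields are empty."""
    validate_cohort(cohort)
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort` (lossless)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MalformedHeaderError(f"cannot parse cohort file: {exc}") from exc
    if df.columns.size == 0 or any(c.strip() == "" or c.startswith("Unnamed") for c in df.columns):
        raise MalformedHeaderError("cohort file header is malformed")
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(f"mandatory column {col!r} is missing")
    for col in ("treatment", "outcome"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise DomainValueError(f"column {col!r}: non-integer value ({exc})") from exc
    for col in covariate_names(df):
        numeric = pd.to_numeric(df[col], errors="coerce")
        observed = df[col].notna()
        if observed.any() and numeric[observed].notna().all():
            if (numeric.dropna() == numeric.dropna().round()).all():
                df[col] = numeric.round().astype("Int64")
            else:
                df[col] = numeric
    validate_cohort(df)
    return df


# ---------------------------------------------------------------------------
# Default scenario (emulates the published cohort marginals)


def _default_covariates() -> tuple[Covariate, ...]:
    return (
        Covariate("male", "binary", 0.5271),
        Covariate("age55_at_award", "binary", 0.6138),
        Covariate(
            "education",
            "categorical",
            (0.6716, 0.0401, 0.2883),
            levels=("hs_grad", "lt_hs", "some_college"),
        ),
        Covariate(
            "diagnosis",
            "categorical",
            (0.0398, 0.0356, 0.2910, 0.4504, 0.0982, 0.0850),
            levels=("cardiovascular", "immune", "mental", "musculoskeletal", "neurological", "other"),
        ),
        Covariate(
            "bmi_class",
            "categorical",
            (0.2327, 0.2233, 0.1150, 0.1018, 0.3066, 0.0206),
            levels=("healthy", "obese1", "obese2", "obese3", "overweight", "underweight"),
        ),
        Covariate(
            "region",
            "categorical",
            (0.2133, 0.2054, 0.3741, 0.2072),
            levels=("midwest", "northeast", "south", "west"),
        ),
        Covariate("stopped_work_health", "binary", 0.6946),
        Covariate("pain_symptoms", "binary", 0.9185),
        Covariate("prfc_push_pull_limited", "binary", 0.5214, rfc_domain="PRFC"),
        Covariate("prfc_sit_alternate", "binary", 0.0426, rfc_domain="PRFC"),
        Covariate("mrfc_understanding_memory", "binary", 0.1989, rfc_domain="MRFC"),
        Covariate("mrfc_concentration", "binary", 0.4554, rfc_domain="MRFC"),
        Covariate("mrfc_social_interaction", "binary", 0.1887, rfc_domain="MRFC"),
        Covariate("mrfc_adaptation", "binary", 0.2038, rfc_domain="MRFC"),
    )


_DEFAULT_PROPENSITY_COEFS = {
    "male": 0.25,
    "age55_at_award": -0.6,
    "education": {"lt_hs": -0.3, "hs_grad": 0.0, "some_college": 0.45},
    "diagnosis": {
        "mental": 0.2,
        "neurological": -0.1,
        "cardiovascular": -0.2,
        "immune": 0.1,
        "musculoskeletal": 0.0,
        "other": 0.0,
    },
    "bmi_class": {
        "underweight": -0.2,
        "overweight": 0.1,
        "obese1": 0.25,
        "obese2": 0.3,
        "obese3": 0.35,
        "healthy": 0.0,
    },
    "region": {"northeast": 0.1, "south": -0.35, "west": 0.05, "midwest": 0.0},
    "stopped_work_health": -0.5,
    "pain_symptoms": -0.2,
}

_DEFAULT_OUTCOME_COEFS = {
    "male": 0.2,
    "age55_at_award": -0.7,
    "education": {"lt_hs": -0.4, "hs_grad": 0.0, "some_college": 0.5},
    "diagnosis": {
        "mental": 0.25,
        "neurological": -0.15,
        "cardiovascular": -0.25,
        "immune": 0.0,
        "musculoskeletal": 0.0,
        "other": 0.0,
    },
    "bmi_class": {
        "underweight": -0.1,
        "overweight": 0.0,
        "obese1": -0.05,
        "obese2": -0.15,
        "obese3": -0.3,
        "healthy": 0.0,
    },
    "region": {"northeast": 0.05, "south": -0.25, "west": 0.1, "midwest": 0.0},
    "stopped_work_health": -0.55,
    "pain_symptoms": -0.15,
}

_DEFAULT_SHIFTS = {
    ("SSI", "PRFC-only"): (0.10, 0.05),
    ("SSI", "MRFC-only"): (0.15, 0.10),
    ("SSI", "both"): (0.20, 0.12),
    ("SSDI", "PRFC-only"): (-0.05, -0.05),
    ("SSDI", "MRFC-only"): (0.00, 0.00),
    ("SSDI", "both"): (0.05, 0.02),
    ("Concurrent", "PRFC-only"): (0.05, 0.00),
    ("Concurrent", "MRFC-only"): (0.10, 0.05),
    ("Concurrent", "both"): (0.12, 0.06),
}

# Three of the four mental-function domains carry heavy (>25%) missingness
# on top of the structural absence for records without an MRFC assessment.
_DEFAULT_MISSINGNESS = {
    "mrfc_understanding_memory": 0.30,
    "mrfc_concentration": 0.10,
    "mrfc_social_interaction": 0.28,
    "mrfc_adaptation": 0.27,
}


def _calibrate_intercepts(
    scenario: SimulationScenario, treatment_target: float, outcome_target: float
) -> SimulationScenario:
    """Bisect both intercepts so the implied marginal prevalences match.

    The outcome marginal accounts for the treatment-effect contribution:
    E[Y] = E[(1-e) p0 + e p1] with e the calibrated propensity.
    """
    n_mc = 200_000
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(714_025)))
    program = rng.choice(PROGRAMS, size=n_mc, p=np.asarray(scenario.program_mix, float))
    rfc = rng.choice(RFC_LEVELS, size=n_mc, p=np.asarray(scenario.rfc_mix, float))
    covs = _draw_covariates(scenario, n_mc, rng)

    lp_t = _linear_predictor(scenario, replace(scenario.propensity, intercept=0.0), covs)
    lp_t += _subgroup_shift(scenario, program, rfc, 0)
    lo, hi = -15.0, 5.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + lp_t).mean() < treatment_target:
            lo = mid
        else:
            hi = mid
    alpha_t = 0.5 * (lo + hi)
    e = expit(alpha_t + lp_t)

    lp_y = _linear_predictor(scenario, replace(scenario.outcome, intercept=0.0), covs)
    lp_y += _subgroup_shift(scenario, program, rfc, 1)
    lo, hi = -15.0, 5.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        marg = ((1 - e) * expit(mid + lp_y) + e * expit(mid + lp_y + scenario.true_treatment_logor)).mean()
        if marg < outcome_target:
            lo = mid
        else:
            hi = mid
    alpha_y = 0.5 * (lo + hi)
    return replace(
        scenario,
        propensity=replace(scenario.propensity, intercept=alpha_t),
        outcome=replace(scenario.outcome, intercept=alpha_y),
    )


def confounded_scenario(
    n_records: int = 5_000,
    seed: int = 0,
    true_treatment_logor: float = math.log(2.0),
    treatment_prevalence: float = 0.15,
    outcome_prevalence: float = 0.25,
    misspec: str = "none",
    misspec_confounder: str = "severity",
    n_null: int = 0,
) -> SimulationScenario:
    """A compact single-stratum scenario with strong shared confounding.

    Six binary covariates; "severity", "work_history" and "urban" load on
    both the treatment and the outcome model (positive confounding), so
    crude contrasts are visibly biased while adjusted ones are not.
    Prevalences are calibrated by the same Monte-Carlo bisection as the
    default scenario. ``n_null`` appends pure-noise binary covariates
    (for shrinkage experiments). Single stratum: the entire cohort is
    SSI / PRFC-only, so hierarchical pooling is not in play.
    """
    covs = [
        Covariate("severity", "binary", 0.40),
        Covariate("work_history", "binary", 0.55),
        Covariate("urban", "binary", 0.60),
        Covariate("male", "binary", 0.53),
        Covariate("support_services", "binary", 0.30),
        Covariate("chronic_pain", "binary", 0.45),
    ]
    covs += [Covariate(f"noise{j:02d}", "binary", 0.5) for j in range(n_null)]
    prop = {
        "severity": -0.8,
        "work_history": 0.7,
        "urban": 0.5,
        "male": 0.25,
        "support_services": 0.6,
    }
    outc = {
        "severity": -0.9,
        "work_history": 0.8,
        "urban": 0.45,
        "chronic_pain": -0.35,
        "male": 0.2,
    }
    scenario = SimulationScenario(
        n_records=n_records,
        seed=seed,
        program_mix=(1.0, 0.0, 0.0),
        rfc_mix=(1.0, 0.0, 0.0),
        covariate_spec=tuple(covs),
        propensity=LinearModel(logit(treatment_prevalence), prop),
        outcome=LinearModel(logit(outcome_prevalence), outc),
        true_treatment_logor=true_treatment_logor,
        misspec=misspec,
        misspec_confounder=misspec_confounder,
        rfc_structural_missingness=False,
    )
    return _calibrate_intercepts(scenario, treatment_prevalence, outcome_prevalence)


def default_scenario(
    n_records: int = 20_000,
    seed: int = 0,
    true_treatment_logor: float = math.log(4.0),
    misspec: str = "none",
    misspec_confounder: str | None = None,
    missingness: dict | None = None,
    treatment_prevalence: float = 0.0512,
    outcome_prevalence: float = 0.1120,
) -> SimulationScenario:
    """The study-condition scenario.

    Marginals follow the published cohort: 52.71% male, 5.12% treatment
    ("Ticket ever in use"), 11.20% outcome (benefits forgone for work),
    RFC mixture 47.12 / 42.78 / 10.10 (%), >25% missingness in three of
    four mental-function domains, and roughly a half-dozen confounders
    shared between the treatment and outcome models with log odds in
    [-0.7, 0.7]. Intercepts are calibrated by Monte-Carlo bisection so the
    implied marginal prevalences hit the targets.
    """
    scenario = SimulationScenario(
        n_records=n_records,
        seed=seed,
        program_mix=(0.249, 0.504, 0.247),
        rfc_mix=(0.4712, 0.4278, 0.1010),
        covariate_spec=_default_covariates(),
        propensity=LinearModel(logit(treatment_prevalence), dict(_DEFAULT_PROPENSITY_COEFS)),
        outcome=LinearModel(logit(outcome_prevalence), dict(_DEFAULT_OUTCOME_COEFS)),
        true_treatment_logor=true_treatment_logor,
        subgroup_shifts=dict(_DEFAULT_SHIFTS),
        missingness=dict(_DEFAULT_MISSINGNESS if missingness is None else missingness),
        misspec=misspec,
        misspec_confounder=misspec_confounder,
    )
    return _calibrate_intercepts(scenario, treatment_prevalence, outcome_prevalence)
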