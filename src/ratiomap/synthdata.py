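"""Synthetic cohort generator with known ground truth.

Generates genotypes (Hardy-Weinberg binomial dosages), lognormal trait
panels with pathway-structured genetic effects and a shared non-genetic
confounder, covariates, missingness, and fixed-horizon outcome tables.
Two planted mechanisms can produce large ratio p-gains:

* ``opposed``   - the variant moves numerator and denominator of its
  target pair in opposite directions, so the log-ratio effect is the sum
  ``theta_num + theta_den``;
* ``confounded`` - the variant moves only the numerator, while both pair
  members load on a shared confounder that the ratio cancels.

Every nonzero generative coefficient is recorded in a :class:`TruthTable`
for parameter-recovery testing.
"""
from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import STAGE_RAW, GenotypeMatrix, TraitMatrix
from .errors import ValidationError

# Aggregate missingness defaults chosen to emulate the reference cohort's
# reported counts: 20,856 NA and 5,940 zero cells out of 274,359 x 168.
_REF_CELLS = 274_359 * 168
DEFAULT_NA_RATE = 20_856 / _REF_CELLS  # ~0.045%
DEFAULT_ZERO_RATE = 5_940 / _REF_CELLS  # ~0.013%

SCENARIOS = ("opposed", "confounded", "null")


@dataclass(frozen=True)
class VariantSpec:
    """Generative description of one variant."""

    id: str
    maf: float
    scenario: str = "null"
    theta_num: float = 0.0
    theta_den: float = 0.0
    target_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf} for {self.id!r}")
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r} for {self.id!r}")
        if self.scenario == "null" and (self.theta_num != 0.0 or self.theta_den != 0.0):
            raise ValidationError(f"null scenario requires zero effects ({self.id!r})")
        if self.scenario == "confounded" and self.theta_den != 0.0:
            raise ValidationError(f"confounded scenario requires theta_den = 0 ({self.id!r})")
        if self.scenario != "null" and self.target_pair is None:
            raise ValidationError(f"scenario {self.scenario!r} requires a target_pair ({self.id!r})")


@dataclass
class CohortConfig:
    """Parameters of the generative model.

    ``lam`` (confounder loading) and ``sigma_trait`` may be scalars or
    per-trait vectors.  Covariate effects are small log-scale shifts; the
    defaults are tuning choices, not estimates from any dataset.
    """

    n_samples: int
    n_traits: int
    lam: float | np.ndarray = 0.0
    sigma_trait: float | np.ndarray = 0.2
    sigma_confounder: float = 0.5
    mu: float | np.ndarray = 0.0
    na_rate: float = DEFAULT_NA_RATE
    zero_rate: float = DEFAULT_ZERO_RATE
    seed: int = 0
    trait_names: list[str] | None = None
    age_range: tuple[float, float] = (40.0, 70.0)
    medication_rate: float = 0.15
    beta_age: float = 0.002
    beta_sex: float = 0.05
    beta_medication: float = -0.10

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.n_traits < 1:
            raise ValidationError(f"n_traits must be >= 1, got {self.n_traits}")
        for name, rate in (("na_rate", self.na_rate), ("zero_rate", self.zero_rate)):
            if not (0.0 <= rate < 1.0):
                raise ValidationError(f"{name} must be in [0, 1), got {rate}")
        if self.na_rate + self.zero_rate >= 1.0:
            raise ValidationError("na_rate + zero_rate must be < 1")
        if not (self.sigma_confounder > 0):
            raise ValidationError("sigma_confounder must be > 0")
        if np.any(np.asarray(self.sigma_trait) <= 0):
            raise ValidationError("sigma_trait must be > 0")
        if not (0.0 <= self.medication_rate < 1.0):
            raise ValidationError("medication_rate must be in [0, 1)")

    @property
    def traits(self) -> list[str]:
        if self.trait_names is not None:
            if len(self.trait_names) != self.n_traits:
                raise ValidationError("trait_names length does not match n_traits")
            return list(self.trait_names)
        return [f"T{i + 1}" for i in range(self.n_traits)]


@dataclass
class TruthTable:
    """Every nonzero generative coefficient, for recovery tests.

    ``effects`` is a long table (variant, trait, effect on the log scale);
    ``lambdas`` holds per-trait confounder loadings; ``variants`` holds
    per-variant maf/scenario metadata; ``confounder`` is the latent
    per-sample log confounder actually drawn; ``covariate_betas`` are the
    log-scale covariate effects applied to every trait.
    """

    effects: pd.DataFrame
    lambdas: pd.Series
    variants: pd.DataFrame
    confounder: np.ndarray
    covariate_betas: dict = field(default_factory=dict)

    def effect(self, variant: str, trait: str) -> float:
        hit = self.effects[(self.effects["variant"] == variant) & (self.effects["trait"] == trait)]
        return float(hit["effect"].iloc[0]) if len(hit) else 0.0


def simulate_genotypes(n_samples: int, specs: list[VariantSpec], seed: int) -> GenotypeMatrix:
    """Hardy-Weinberg dosages: Binomial(2, maf) per variant, iid across samples."""
    if n_samples < 2:
        raise ValidationError(f"n_samples must be >= 2, got {n_samples}")
    ids = [s.id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate variant ids in specs")
    rng = np.random.default_rng(seed)
    data = {s.id: rng.binomial(2, s.maf, size=n_samples).astype(float) for s in specs}
    df = pd.DataFrame(data, index=pd.RangeIndex(n_samples, name="sample"))
    return GenotypeMatrix(df)


def _effect_matrix(specs: list[VariantSpec], traits: list[str]) -> pd.DataFrame:
    E = pd.DataFrame(0.0, index=[s.id for s in specs], columns=traits)
    for s in specs:
        if s.scenario == "null":
            continue
        num, den = s.target_pair  # type: ignore[misc]
        for t in (num, den):
            if t not in traits:
                raise ValidationError(f"target_pair trait {t!r} of {s.id!r} not in panel")
        E.loc[s.id, num] += s.theta_num
        if s.scenario == "opposed":
            E.loc[s.id, den] -= s.theta_den
    return E


def simulate_cohort(
    geno: GenotypeMatrix,
    specs: list[VariantSpec],
    config: CohortConfig,
) -> tuple[TraitMatrix, pd.DataFrame, TruthTable]:
    """Generate a raw trait panel, covariate table and truth table.

    Per sample ``i``:  ``log x_it = mu_t + lam_t * c_i + sum_v E[v,t] g_iv
    + covariate terms + Normal(0, sigma_t^2)`` with log confounder
    ``c_i ~ Normal(0, sigma_c^2)``; traits are exponentiated so all raw
    values are strictly positive before missingness injection.
    """
    n = geno.n_samples
    if n != config.n_samples:
        raise ValidationError("genotype matrix and config disagree on n_samples")
    traits = config.traits
    E = _effect_matrix(specs, traits)
    rng = np.random.default_rng(config.seed)

    c = rng.normal(0.0, config.sigma_confounder, size=n)
    lam = np.broadcast_to(np.asarray(config.lam, dtype=float), (len(traits),)).copy()
    sig = np.broadcast_to(np.asarray(config.sigma_trait, dtype=float), (len(traits),)).copy()
    mu = np.broadcast_to(np.asarray(config.mu, dtype=float), (len(traits),)).copy()

    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    medication = rng.binomial(1, config.medication_rate, size=n).astype(float)

    G = geno.data[E.index].to_numpy()
    age_c = age - age.mean()
    log_x = (
        mu[None, :]
        + np.outer(c, lam)
        + G @ E.to_numpy()
        + np.outer(age_c * config.beta_age + sex * config.beta_sex + medication * config.beta_medication,
                   np.ones(len(traits)))
        + rng.normal(0.0, 1.0, size=(n, len(traits))) * sig[None, :]
    )
    panel = TraitMatrix(
        pd.DataFrame(np.exp(log_x), index=geno.data.index, columns=traits), STAGE_RAW
    )
    covariates = pd.DataFrame(
        {"age": age, "age2": age**2, "sex": sex, "medication": medication},
        index=geno.data.index,
    )
    long = E.stack()
    long = long[long != 0.0]
    effects = (
        long.rename("effect").reset_index().rename(columns={"level_0": "variant", "level_1": "trait"})
    )
    truth = TruthTable(
        effects=effects,
        lambdas=pd.Series(lam, index=traits, name="lambda"),
        variants=pd.DataFrame(
            {"maf": [s.maf for s in specs], "scenario": [s.scenario for s in specs]},
            index=[s.id for s in specs],
        ),
        confounder=c,
        covariate_betas={
            "age": config.beta_age,
            "sex": config.beta_sex,
            "medication": config.beta_medication,
        },
    )
    return panel, covariates, truth


def inject_missingness(
    traits: TraitMatrix,
    na_rate: float = DEFAULT_NA_RATE,
    zero_rate: float = DEFAULT_ZERO_RATE,
    seed: int = 0,
    return_masks: bool = False,
):
    """Set cells missing / to exact zero uniformly at random, disjointly."""
    if traits.stage != STAGE_RAW:
        raise ValidationError("inject_missingness expects a raw panel")
    for name, rate in (("na_rate", na_rate), ("zero_rate", zero_rate)):
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"{name} must be in [0, 1), got {rate}")
    if na_rate + zero_rate >= 1.0:
        raise ValidationError("na_rate + zero_rate must be < 1")
    rng = np.random.default_rng(seed)
    u = rng.random(traits.data.shape)
    na_mask = u < na_rate
    zero_mask = (u >= na_rate) & (u < na_rate + zero_rate)
    values = traits.data.to_numpy().copy()
    values[na_mask] = np.nan
    values[zero_mask] = 0.0
    out = TraitMatrix(
        pd.DataFrame(values, index=traits.data.index, columns=traits.data.columns), STAGE_RAW
    )
    if return_masks:
        return out, na_mask, zero_mask
    return out


DEFAULT_ASSESSMENT_DATE = datetime.date(2010, 1, 1)
DAYS_PER_YEAR = 365.25


def simulate_outcomes(
    n_samples: int,
    risk_covariate,
    effect: float,
    baseline_rate: float,
    horizon_years: float,
    prevalent_fraction: float = 0.0,
    seed: int = 0,
    medication=None,
    assessment_date: datetime.date = DEFAULT_ASSESSMENT_DATE,
) -> pd.DataFrame:
    """Exponential event times with rate ``baseline_rate * exp(effect * covariate)``.

    Events beyond the horizon are censored (no event date).  A
    ``prevalent_fraction`` of samples instead receive an event date before
    the assessment date.  Returns a table with ISO-8601 date strings plus
    exact float event times (``time_years``) for survival analysis.
    """
    if baseline_rate <= 0 or horizon_years <= 0:
        raise ValidationError("baseline_rate and horizon_years must be positive")
    if not (0.0 <= prevalent_fraction <= 1.0):
        raise ValidationError("prevalent_fraction must be in [0, 1]")
    cov = np.asarray(risk_covariate, dtype=float)
    if cov.shape[0] != n_samples:
        raise ValidationError("risk_covariate length must equal n_samples")
    rng = np.random.default_rng(seed)
    rates = baseline_rate * np.exp(effect * cov)
    times = rng.exponential(1.0 / rates)
    n_prev = int(round(prevalent_fraction * n_samples))
    prev_idx = rng.choice(n_samples, size=n_prev, replace=False) if n_prev else np.array([], dtype=int)
    prevalent = np.zeros(n_samples, dtype=bool)
    prevalent[prev_idx] = True

    med = np.zeros(n_samples) if medication is None else np.asarray(medication, dtype=float)
    event_dates = []
    time_years = np.full(n_samples, np.nan)
    status = []
    days_back = rng.uniform(30.0, 3650.0, size=n_samples)
    for i in range(n_samples):
        if prevalent[i]:
            d = assessment_date - datetime.timedelta(days=float(days_back[i]))
            event_dates.append(d.isoformat())
            status.append("prevalent")
        elif times[i] <= horizon_years:
            d = assessment_date + datetime.timedelta(days=times[i] * DAYS_PER_YEAR)
            event_dates.append(d.isoformat())
            time_years[i] = times[i]
            status.append("incident")
        else:
            event_dates.append("")
            status.append("none")
    return pd.DataFrame(
        {
            "sample": np.arange(n_samples),
            "assessment_date": assessment_date.isoformat(),
            "event_date": event_dates,
            "medication": med,
            "time_years": time_years,
            "status": status,
        }
    ).set_index("sample")


def default_variant_specs(
    n_variants: int,
    traits: list[str],
    seed: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    theta: float = 0.1,
    scenario_mix: tuple[float, float, float] = (0.3, 0.3, 0.4),
) -> list[VariantSpec]:
    """Convenience mix of opposed / confounded / null variants for demos.

    Effect magnitudes are tuning choices (the generative scale is not
    pinned down by any external estimate).
    """
    if len(traits) < 2:
        raise ValidationError("need at least 2 traits for ratio scenarios")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(SCENARIOS, size=n_variants, p=scenario_mix)
    specs = []
    for i, kind in enumerate(kinds):
        maf = float(rng.uniform(*maf_range))
        if kind == "null":
            specs.append(VariantSpec(f"v{i + 1}", maf))
            continue
        a, b = rng.choice(len(traits), size=2, replace=False)
        pair = (traits[a], traits[b])
        if kind == "opposed":
            specs.append(VariantSpec(f"v{i + 1}", maf, "opposed", theta, theta, pair))
        else:
            specs.append(VariantSpec(f"v{i + 1}", maf, "confounded", theta, 0.0, pair))
    return specs
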