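"""Scenario data model: development-phase plan, commercial assumptions, correlations.

A *scenario* bundles everything needed to value one rare-disease compound:

* a :class:`PhasePlan` — an ordered list of development phases, each with a
  probability of success (PoS) and three-point (min, mode, max) estimates for
  its out-of-pocket cost (in $M) and duration (in years);
* a :class:`CommercialModel` — the post-approval market: an age-stratified
  patient population, an adoption ramp, an annual list price, operating-margin
  fractions, tax, exclusivity and discounting assumptions, plus optional
  add-on benefits (R&D tax credit, priority review voucher);
* :class:`CorrelationSettings` — the dependence assumptions used by the
  Monte Carlo layers.

Scenario files are flat, versioned YAML (or JSON) documents with explicit
units: costs in millions of dollars, durations in years, price in dollars per
patient-year. Unknown keys are rejected so that typos fail loudly.

The shipped fixtures (``rett_base``, ``rett_lower``, ``rett_upper``,
``me_too``) transcribe the published base-case, bound, and follow-on ("me-too")
assumption sets for a repurposed Rett-syndrome compound developed through a
consolidated four-phase 505(b)(2) plan.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

SCHEMA_VERSION = 1

FIXTURE_NAMES = ("rett_base", "rett_lower", "rett_upper", "me_too")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PhaseSpec(_Model):
    """One development phase.

    ``pos`` is the probability the phase succeeds given that it is attempted.
    ``cost_*`` are $M (out-of-pocket), ``dur_*`` are years; each triple is a
    (min, mode, max) three-point estimate. Degenerate triples (min = mode =
    max) model a deterministic quantity.
    """

    name: str
    pos: float = Field(ge=0.0, le=1.0)
    cost_min: float = Field(gt=0.0)
    cost_mode: float
    cost_max: float
    dur_min: float = Field(gt=0.0)
    dur_mode: float
    dur_max: float

    @model_validator(mode="after")
    def _ordered(self) -> "PhaseSpec":
        if not self.cost_min <= self.cost_mode <= self.cost_max:
            raise ValueError(
                f"phase {self.name!r}: cost triple must satisfy "
                f"cost_min <= cost_mode <= cost_max, got "
                f"({self.cost_min}, {self.cost_mode}, {self.cost_max})"
            )
        if not self.dur_min <= self.dur_mode <= self.dur_max:
            raise ValueError(
                f"phase {self.name!r}: duration triple must satisfy "
                f"dur_min <= dur_mode <= dur_max, got "
                f"({self.dur_min}, {self.dur_mode}, {self.dur_max})"
            )
        return self


class PhasePlan(_Model):
    """Ordered development phases, first to last (launch follows the last)."""

    phases: List[PhaseSpec] = Field(min_length=1)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def pos_vector(self) -> np.ndarray:
        return np.array([p.pos for p in self.phases])

    def modal_durations(self) -> np.ndarray:
        return np.array([p.dur_mode for p in self.phases])

    def modal_costs(self) -> np.ndarray:
        return np.array([p.cost_mode for p in self.phases])


class AgeGroup(_Model):
    """A population stratum: size (thousands of persons), disease prevalence
    (cases per 1,000), and its peak adoption rate as a fraction of the
    reference group's."""

    label: str
    population_thousands: float = Field(ge=0.0)
    prevalence_per_1000: float = Field(ge=0.0)
    peak_adoption_multiplier: float = Field(ge=0.0, le=1.0)

    @property
    def patients(self) -> float:
        """Prevalent patient count (persons), carried unrounded."""
        return self.population_thousands * self.prevalence_per_1000


class AdoptionModel(_Model):
    """Adoption of the therapy after launch.

    ``peak_rate`` is the peak fraction of prevalent patients treated in the
    reference age group (the youngest, multiplier 1.0); other groups peak at
    ``peak_rate * peak_adoption_multiplier``. ``ramp`` gives the fraction of
    peak reached in each year after launch; it holds at its final value
    through the end of exclusivity. ``peak_rate_lo``/``peak_rate_hi`` are the
    95% CI bounds used to calibrate the stochastic adoption draw.
    """

    peak_rate: float = Field(gt=0.0, le=1.0)
    peak_rate_lo: float = Field(gt=0.0, le=1.0)
    peak_rate_hi: float = Field(gt=0.0, le=1.0)
    ramp: List[float] = Field(min_length=1)
    groups: List[AgeGroup] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "AdoptionModel":
        if not self.peak_rate_lo <= self.peak_rate <= self.peak_rate_hi:
            raise ValueError(
                "adoption: require peak_rate_lo <= peak_rate <= peak_rate_hi"
            )
        for v in self.ramp:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"adoption: ramp value {v} outside [0, 1]")
        return self

    def ramp_fraction(self, year: int) -> float:
        """Fraction of peak adoption in ``year`` (1-based) after launch."""
        if year < 1:
            raise ValueError("year is 1-based and must be >= 1")
        return self.ramp[min(year, len(self.ramp)) - 1]


class CommercialModel(_Model):
    """Commercial-stage and financial assumptions.

    Monetary units: ``price`` in $ per patient per year; ``prv_value`` and
    ``pdufa_waiver`` in $M. Fractions are of net sales except
    ``prerevenue_sga_of_rnd`` (SG&A during development, as a fraction of each
    phase's development cost) and ``tax_credit_rate`` (fraction of development
    cost through phase 3 credited back). ``exclusivity_years`` is the revenue
    window implied by the modal timeline; the engine recomputes the window as
    ``max(patent_term_years - launch_time, orphan_exclusivity_years)`` when
    sampled development times shift the launch date.
    """

    price: float = Field(gt=0.0)
    price_lo: float = Field(gt=0.0)
    price_hi: float = Field(gt=0.0)
    adoption: AdoptionModel
    cogs_frac: float = Field(ge=0.0, le=1.0)
    sga_frac: float = Field(ge=0.0, le=1.0)
    rnd_frac: float = Field(ge=0.0, le=1.0)
    prerevenue_sga_of_rnd: float = Field(ge=0.0, le=1.0)
    tax_rate: float = Field(ge=0.0, le=1.0)
    exclusivity_years: float = Field(gt=0.0)
    patent_term_years: float = Field(gt=0.0)
    orphan_exclusivity_years: float = Field(ge=0.0, default=7.0)
    discount_rate: float = Field(gt=0.0)
    tax_credit_rate: float = Field(ge=0.0, le=1.0, default=0.0)
    prv_value: float = Field(ge=0.0, default=0.0)
    prv_year: float = Field(gt=0.0, default=3.0)
    pdufa_waiver: float = Field(ge=0.0, default=0.0)

    @model_validator(mode="after")
    def _check(self) -> "CommercialModel":
        if not self.price_lo <= self.price <= self.price_hi:
            raise ValueError("commercial: require price_lo <= price <= price_hi")
        if self.cogs_frac + self.sga_frac + self.rnd_frac > 1.0:
            raise ValueError(
                "commercial: cogs_frac + sga_frac + rnd_frac exceeds 1"
            )
        return self

    @property
    def operating_margin(self) -> float:
        return 1.0 - self.cogs_frac - self.sga_frac - self.rnd_frac


class CorrelationSettings(_Model):
    """Dependence assumptions for the simulation layers.

    ``phase23_time_cost_rho`` couples the durations and costs of the two
    pivotal clinical phases (phase 2 and phase 3) through a Gaussian copula.
    ``cross_drug_rho`` is the pairwise correlation of phase-success latents
    across drugs in a portfolio; its value is an assumption that every
    portfolio output reports.
    """

    phase23_time_cost_rho: float = Field(ge=-1.0, le=1.0, default=0.5)
    cross_drug_rho: float = Field(ge=0.0, lt=1.0, default=0.2)


class ScenarioFlags(_Model):
    include_tax_credit: bool = False
    include_prv: bool = False


class Scenario(_Model):
    """A full single-compound valuation case."""

    schema_version: int = SCHEMA_VERSION
    name: str = "scenario"
    plan: PhasePlan
    commercial: CommercialModel
    correlations: CorrelationSettings = CorrelationSettings()
    flags: ScenarioFlags = ScenarioFlags()


# ---------------------------------------------------------------------------
# Load / save
# ---------------------------------------------------------------------------


def load_scenario(path: str | Path) -> Scenario:
    """Load and validate a scenario file (YAML or JSON).

    Raises ``FileNotFoundError`` for a missing file and a pydantic
    ``ValidationError`` naming the offending field for schema violations.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return Scenario.model_validate(data)


def save_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario as YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    data = scenario.model_dump(mode="json")
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped fixture scenario (without extension)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return Path(str(resources.files("orphanval").joinpath(f"fixtures/{name}.yaml")))


def load_fixture(name: str) -> Scenario:
    """Load one of the shipped fixture scenarios by name."""
    return load_scenario(fixture_path(name))


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def cumulative_pos(plan: PhasePlan) -> float:
    """Total probability of reaching launch: the product of per-phase PoS."""
    return float(np.prod(plan.pos_vector()))


def arrival_probabilities(plan: PhasePlan) -> np.ndarray:
    """Probability of arriving at each phase (first element is 1)."""
    pos = plan.pos_vector()
    return np.concatenate([[1.0], np.cumprod(pos)[:-1]])


def pos_table(plan: PhasePlan) -> pd.DataFrame:
    """Per-phase PoS and arrival probabilities as a tidy table."""
    return pd.DataFrame(
        {
            "phase": [p.name for p in plan.phases],
            "pos": plan.pos_vector(),
            "prob_arrival": arrival_probabilities(plan),
        }
    )


def write_pos_table(plan: PhasePlan, path: str | Path) -> None:
    pos_table(plan).to_csv(path, index=False)
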