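"""Multi-stage Monte Carlo simulation of a single compound.

Each path draws, with one root seed deterministically split per stream:

* sequential Bernoulli phase outcomes at the plan's PoS values (independent
  of the cost/duration draws);
* per-phase durations and costs from PERT three-point distributions, with
  the phase-2/phase-3 duration-cost block coupled through a Gaussian copula
  at the scenario's ``phase23_time_cost_rho``;
* an annual price and a peak adoption rate from normals calibrated to their
  95% CIs, truncated by rejection at 0 (and 1 for adoption), drawn once per
  path.

The sampled durations re-time all subsequent cash flows: the launch date
shifts and the exclusivity window is recomputed. Per path the module
evaluates

* ``rnpv_path`` — the deterministic engine on the sampled inputs (PoS-
  weighted, Bernoullis not resolved);
* ``value_after_phase[k]`` — the remaining-project value at the end of each
  phase under the sampled inputs (defined for every path; the summary
  conditions on the completion event, which is independent of the inputs);
* ``sale_npv_year0[k]`` — the time-0 NPV of "develop to the end of phase k,
  then sell at its then-current value": failures before k carry their sunk
  costs with zero proceeds, successes net the discounted sale price against
  incurred costs (discounted, or nominal under the alternative convention);
* ``overall_npv`` — the realized NPV with all Bernoullis resolved: revenue
  only on full approval, costs for every attempted phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kernels
from .engine import (
    Conventions,
    DEFAULT_CONVENTIONS,
    exclusivity_window,
    pv_stream,
    revenue_pv0,
)
from .kernels import PertParams, pert_ppf, phase_chain_from_uniforms
from .market import patient_counts
from .scenario import Scenario

#: 0-based indices of the phases whose durations and costs are coupled
#: (phase 2 and phase 3 of the four-phase consolidated plan)
PIVOTAL_PHASES = (1, 2)


def within_drug_corr(
    n_phases: int,
    rho: float,
    pivotal: Sequence[int] = PIVOTAL_PHASES,
) -> np.ndarray:
    """Correlation matrix over the 2k (duration, cost) margins.

    Margins are ordered (dur_0..dur_{k-1}, cost_0..cost_{k-1}). The pivotal
    phases' four margins form an equicorrelated block at ``rho`` — duration
    with duration, cost with cost, and duration with cost — which is the
    positive semi-definite completion of "a pairwise correlation of rho for
    the time and cost of development between the two clinical phases". Users
    may pass any alternative matrix to the simulator.
    """
    m = np.eye(2 * n_phases)
    idx = [i for i in pivotal if i < n_phases]
    block = [*idx, *[n_phases + i for i in idx]]
    for a in block:
        for b in block:
            if a != b:
                m[a, b] = rho
    return m


@dataclass
class SimPaths:
    """Array-of-paths container for one compound (all money in $M)."""

    scenario_name: str
    seed: Optional[int]
    discount_rate: float
    conventions: Conventions
    attempted: np.ndarray
    succeeded: np.ndarray
    durations: np.ndarray
    costs: np.ndarray
    price: np.ndarray
    peak_rate: np.ndarray
    launch: np.ndarray
    exclusivity: np.ndarray
    value_after_phase: np.ndarray
    sale_npv_year0: np.ndarray
    rnpv_path: np.ndarray
    overall_npv: np.ndarray
    phase_names: list[str] = field(default_factory=list)

    @property
    def n_paths(self) -> int:
        return len(self.overall_npv)

    @property
    def n_phases(self) -> int:
        return self.attempted.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        k = self.n_phases
        data = {}
        for j in range(k):
            nm = self.phase_names[j] if self.phase_names else f"phase{j+1}"
            data[f"attempted_{nm}"] = self.attempted[:, j]
            data[f"succeeded_{nm}"] = self.succeeded[:, j]
            data[f"duration_{nm}"] = self.durations[:, j]
            data[f"cost_{nm}"] = self.costs[:, j]
            data[f"value_after_{nm}"] = self.value_after_phase[:, j]
            data[f"sale_npv0_{nm}"] = self.sale_npv_year0[:, j]
        data["price"] = self.price
        data["peak_rate"] = self.peak_rate
        data["launch"] = self.launch
        data["exclusivity"] = self.exclusivity
        data["rnpv_path"] = self.rnpv_path
        data["overall_npv"] = self.overall_npv
        return pd.DataFrame(data)


def _simulate_drug(
    scenario: Scenario,
    n_paths: int,
    rng: np.random.Generator,
    *,
    discount_rate: Optional[float] = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
    success_factor: Optional[np.ndarray] = None,
    cross_rho: float = 0.0,
    corr_matrix: Optional[np.ndarray] = None,
) -> SimPaths:
    """Simulation kernel for one drug.

    ``success_factor`` (n, k) is an optional per-phase common standard-normal
    factor; the drug's phase-success latents become
    ``sqrt(cross_rho) * factor + sqrt(1 - cross_rho) * idiosyncratic``,
    giving pairwise cross-drug correlation ``cross_rho`` in a portfolio.
    The draw order is fixed so that runs are seed-reproducible.
    """
    cm = scenario.commercial
    plan = scenario.plan
    r = cm.discount_rate if discount_rate is None else discount_rate
    conv = conventions.discounting
    k = plan.n_phases
    pos = plan.pos_vector()

    # 1) phase-success latents
    z = rng.standard_normal((n_paths, k))
    if success_factor is not None and cross_rho > 0.0:
        z = np.sqrt(cross_rho) * success_factor + np.sqrt(1.0 - cross_rho) * z
    attempted, succeeded = phase_chain_from_uniforms(stats.norm.cdf(z), pos)

    # 2) duration/cost copula
    corr = (
        within_drug_corr(k, scenario.correlations.phase23_time_cost_rho)
        if corr_matrix is None
        else np.asarray(corr_matrix, dtype=float)
    )
    u = kernels.copula_uniforms(corr, n_paths, rng)
    durations = np.empty((n_paths, k))
    costs = np.empty((n_paths, k))
    for j, ph in enumerate(plan.phases):
        durations[:, j] = pert_ppf(
            u[:, j], PertParams(ph.dur_min, ph.dur_mode, ph.dur_max)
        )
        costs[:, j] = pert_ppf(
            u[:, k + j], PertParams(ph.cost_min, ph.cost_mode, ph.cost_max)
        )

    # 3) price and peak adoption, once per path
    _, price_sd = kernels.normal_from_ci(cm.price, cm.price_lo, cm.price_hi)
    price = kernels.sample_truncated_normal(cm.price, price_sd, n_paths, rng)
    ad = cm.adoption
    _, peak_sd = kernels.normal_from_ci(
        ad.peak_rate, ad.peak_rate_lo, ad.peak_rate_hi
    )
    peak_rate = kernels.sample_truncated_normal(
        ad.peak_rate, peak_sd, n_paths, rng, upper=1.0
    )

    # timing and discounted pieces
    ends = np.cumsum(durations, axis=1)
    starts = ends - durations
    launch = ends[:, -1]
    excl = np.asarray(exclusivity_window(scenario, launch), dtype=float)
    uplift = 1.0 + cm.prerevenue_sga_of_rnd
    counts = patient_counts(ad.groups)
    mult = np.array([g.peak_adoption_multiplier for g in ad.groups])
    patients_per_rate = float((counts * mult).sum())
    peak_cf = (
        patients_per_rate * peak_rate * price * cm.operating_margin
        * (1.0 - cm.tax_rate) / 1e6
    )
    rev0 = revenue_pv0(launch, excl, peak_cf, ad.ramp, r, conv)
    cost_pv = np.column_stack(
        [
            pv_stream(costs[:, j] * uplift, starts[:, j], ends[:, j], r, conv)
            for j in range(k)
        ]
    )

    arrival = np.concatenate([[1.0], np.cumprod(pos)[:-1]])
    p_approval = float(np.prod(pos))
    rnpv_path = -(arrival * cost_pv).sum(axis=1) + p_approval * rev0

    comp = (1.0 + r) ** ends
    value_after = np.empty((n_paths, k))
    for i in range(k):
        fut = np.zeros(n_paths)
        for j in range(i + 1, k):
            fut += float(np.prod(pos[i + 1 : j])) * cost_pv[:, j]
        value_after[:, i] = (
            -fut + float(np.prod(pos[i + 1 :])) * rev0
        ) * comp[:, i]

    # sunk costs under the loss-metric convention
    if conventions.sunk_costs == "nominal":
        sunk = np.where(attempted, costs * uplift, 0.0)
    else:
        sunk = np.where(attempted, cost_pv, 0.0)
    sunk_cum = np.cumsum(sunk, axis=1)

    sale = np.empty((n_paths, k))
    for i in range(k):
        proceeds = np.where(succeeded[:, i], value_after[:, i] / comp[:, i], 0.0)
        sale[:, i] = proceeds - sunk_cum[:, i]

    approved = succeeded[:, -1]
    overall = np.where(approved, rev0, 0.0) - sunk_cum[:, -1]

    return SimPaths(
        scenario_name=scenario.name,
        seed=None,
        discount_rate=r,
        conventions=conventions,
        attempted=attempted,
        succeeded=succeeded,
        durations=durations,
        costs=costs,
        price=price,
        peak_rate=peak_rate,
        launch=launch,
        exclusivity=excl,
        value_after_phase=value_after,
        sale_npv_year0=sale,
        rnpv_path=rnpv_path,
        overall_npv=overall,
        phase_names=[p.name for p in plan.phases],
    )


def drug_streams(seed: int, n_drugs: int) -> tuple[np.random.Generator, list]:
    """Split a root seed into a common-factor stream plus one per drug.

    The layout is stable in ``n_drugs`` up to the drugs drawn, so a one-drug
    portfolio consumes exactly the streams a single-compound run does.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_drugs + 1)
    return np.random.default_rng(children[0]), [
        np.random.default_rng(c) for c in children[1:]
    ]


def simulate_compound(
    scenario: Scenario,
    n_paths: int = 10_000,
    seed: int = 0,
    *,
    discount_rate: Optional[float] = None,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> SimPaths:
    """Simulate ``n_paths`` development paths of a single compound."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    _, (drug_rng,) = drug_streams(seed, 1)
    paths = _simulate_drug(
        scenario,
        n_paths,
        drug_rng,
        discount_rate=discount_rate,
        conventions=conventions,
    )
    paths.seed = seed
    return paths


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class RiskSummary:
    """Distributional statistics for a compound or portfolio ($M).

    ``value_*`` describe the per-phase value distribution conditional on the
    completion event (for a portfolio: the combined value of completing
    drugs, unconditional); ``value_mean_attempted`` conditions on attempt
    instead. The "upper bound" is the configurable percentile
    (default 95th); the sample maximum is reported alongside.
    """

    phase_names: list[str]
    n_paths: int
    seed: Optional[int]
    discount_rate: float
    conventions: dict
    value_mean: np.ndarray
    value_sd: np.ndarray
    value_upper: np.ndarray
    value_max: np.ndarray
    n_completed: np.ndarray
    value_mean_attempted: np.ndarray
    overall_rnpv_mean: float
    overall_rnpv_sd: float
    overall_rnpv_upper: float
    prob_negative_overall: float
    prob_sale_loss: np.ndarray
    cross_drug_rho: Optional[float] = None
    n_drugs: int = 1

    def to_dict(self) -> dict:
        d = {
            "phase_names": self.phase_names,
            "n_paths": self.n_paths,
            "seed": self.seed,
            "n_drugs": self.n_drugs,
            "cross_drug_rho": self.cross_drug_rho,
            "discount_rate": self.discount_rate,
            "conventions": self.conventions,
            "overall_rnpv_mean": self.overall_rnpv_mean,
            "overall_rnpv_sd": self.overall_rnpv_sd,
            "overall_rnpv_upper": self.overall_rnpv_upper,
            "prob_negative_overall": self.prob_negative_overall,
        }
        for key in (
            "value_mean",
            "value_sd",
            "value_upper",
            "value_max",
            "n_completed",
            "value_mean_attempted",
            "prob_sale_loss",
        ):
            arr = getattr(self, key)
            d[key] = [None if np.isnan(v) else float(v) for v in np.asarray(arr, float)]
        return d

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phase": self.phase_names,
                "value_mean": self.value_mean,
                "value_sd": self.value_sd,
                "value_upper": self.value_upper,
                "value_max": self.value_max,
                "n_completed": self.n_completed,
                "prob_sale_loss": self.prob_sale_loss,
            }
        )


def _cond_stats(values: np.ndarray, mask: np.ndarray, pct: float):
    if mask.sum() == 0:
        return np.nan, np.nan, np.nan, np.nan
    v = values[mask]
    return (
        float(v.mean()),
        float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        float(np.percentile(v, pct)),
        float(v.max()),
    )


def summarize(paths: SimPaths) -> RiskSummary:
    """Reduce simulated paths to the risk report.

    Per-phase value statistics condition on successful completion of the
    phase (an empty conditional set reports NaN, never zero); loss
    probabilities are simple fractions over all paths.
    """
    if paths.n_paths == 0:
        raise ValueError("no paths to summarize")
    k = paths.n_phases
    pct = paths.conventions.upper_bound_percentile
    mean = np.empty(k)
    sd = np.empty(k)
    upper = np.empty(k)
    vmax = np.empty(k)
    ncomp = np.empty(k, dtype=int)
    mean_att = np.empty(k)
    for j in range(k):
        mean[j], sd[j], upper[j], vmax[j] = _cond_stats(
            paths.value_after_phase[:, j], paths.succeeded[:, j], pct
        )
        ncomp[j] = int(paths.succeeded[:, j].sum())
        m, _, _, _ = _cond_stats(
            paths.value_after_phase[:, j], paths.attempted[:, j], pct
        )
        mean_att[j] = m
    return RiskSummary(
        phase_names=list(paths.phase_names),
        n_paths=paths.n_paths,
        seed=paths.seed,
        discount_rate=paths.discount_rate,
        conventions=paths.conventions.as_dict(),
        value_mean=mean,
        value_sd=sd,
        value_upper=upper,
        value_max=vmax,
        n_completed=ncomp,
        value_mean_attempted=mean_att,
        overall_rnpv_mean=float(paths.rnpv_path.mean()),
        overall_rnpv_sd=float(paths.rnpv_path.std(ddof=1)),
        overall_rnpv_upper=float(np.percentile(paths.rnpv_path, pct)),
        prob_negative_overall=float((paths.overall_npv < 0).mean()),
        prob_sale_loss=(paths.sale_npv_year0 < 0).mean(axis=0),
    )


# ---------------------------------------------------------------------------
# Sensitivity grid
# ---------------------------------------------------------------------------


def _set_price(s: Scenario, v: float) -> None:
    s.commercial.price_lo = min(s.commercial.price_lo, v)
    s.commercial.price_hi = max(s.commercial.price_hi, v)
    s.commercial.price = v


def _set_peak(s: Scenario, v: float) -> None:
    ad = s.commercial.adoption
    ad.peak_rate_lo = min(ad.peak_rate_lo, v)
    ad.peak_rate_hi = max(ad.peak_rate_hi, v)
    ad.peak_rate = v


def _set_pos(i: int):
    def setter(s: Scenario, v: float) -> None:
        s.plan.phases[i].pos = v

    return setter


def _set_cost(i: int):
    def setter(s: Scenario, v: float) -> None:
        ph = s.plan.phases[i]
        ph.cost_min = min(ph.cost_min, v)
        ph.cost_max = max(ph.cost_max, v)
        ph.cost_mode = v

    return setter


def _set_duration(i: int):
    def setter(s: Scenario, v: float) -> None:
        ph = s.plan.phases[i]
        ph.dur_min = min(ph.dur_min, v)
        ph.dur_max = max(ph.dur_max, v)
        ph.dur_mode = v

    return setter


def _set_discount(s: Scenario, v: float) -> None:
    s.commercial.discount_rate = v


def _set_patent_term(s: Scenario, v: float) -> None:
    s.commercial.patent_term_years = v


def _registry(scenario: Scenario) -> dict:
    reg = {
        "price": _set_price,
        "peak_adoption": _set_peak,
        "discount_rate": _set_discount,
        "patent_term": _set_patent_term,
    }
    for i, ph in enumerate(scenario.plan.phases):
        reg[f"pos:{i}"] = _set_pos(i)
        reg[f"pos:{ph.name}"] = _set_pos(i)
        reg[f"cost:{i}"] = _set_cost(i)
        reg[f"cost:{ph.name}"] = _set_cost(i)
        reg[f"duration:{i}"] = _set_duration(i)
        reg[f"duration:{ph.name}"] = _set_duration(i)
    return reg


def sensitivity_grid(
    scenario: Scenario,
    param: str,
    values: Sequence[float],
    *,
    conventions: Conventions = DEFAULT_CONVENTIONS,
) -> list[tuple[float, float]]:
    """Deterministic rNPV recomputed across a one-parameter sweep.

    ``param`` is one of the registered tunables: ``price``, ``peak_adoption``,
    ``discount_rate``, ``patent_term``, or per-phase ``pos:<i|name>``,
    ``cost:<i|name>``, ``duration:<i|name>``.
    """
    from .engine import rnpv  # local import avoids a cycle

    reg = _registry(scenario)
    if param not in reg:
        raise KeyError(
            f"unknown parameter {param!r}; registered: {sorted(reg)}"
        )
    out = []
    for v in values:
        s2 = scenario.model_copy(deep=True)
        reg[param](s2, float(v))
        out.append((float(v), rnpv(s2, conventions=conventions).rnpv_overall))
    return out
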