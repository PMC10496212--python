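"""Commercial model: patient population, adoption ramp, and per-year cash flow.

Patient counts are carried unrounded throughout (the published peak of 4237
treated patients arises from unrounded intermediates); rounding is applied
only when tables are rendered.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .scenario import AdoptionModel, AgeGroup, CommercialModel


def patient_counts(groups: Sequence[AgeGroup]) -> np.ndarray:
    """Prevalent patients per group: population (thousands) x prevalence
    (per 1,000); the thousands cancel, leaving persons."""
    return np.array([g.patients for g in groups])


def treated_patients(
    adoption: AdoptionModel,
    groups: Sequence[AgeGroup] | None = None,
    year: int = 1,
    *,
    peak_rate: float | None = None,
) -> np.ndarray:
    """Patients treated per group in ``year`` (1-based) after launch.

    ``treated_g = patients_g * peak_rate * multiplier_g * ramp(year)``; the
    ramp holds at its final value from the peak year onward. ``peak_rate``
    overrides the model's base rate (used when the rate is a sampled draw).
    """
    if groups is None:
        groups = adoption.groups
    rate = adoption.peak_rate if peak_rate is None else peak_rate
    frac = adoption.ramp_fraction(year)
    counts = patient_counts(groups)
    mult = np.array([g.peak_adoption_multiplier for g in groups])
    return counts * rate * mult * frac


def peak_treated_patients(
    adoption: AdoptionModel, *, peak_rate: float | None = None
) -> float:
    """Total treated patients at full ramp (the plateau level)."""
    rate = adoption.peak_rate if peak_rate is None else peak_rate
    counts = patient_counts(adoption.groups)
    mult = np.array([g.peak_adoption_multiplier for g in adoption.groups])
    return float((counts * mult).sum() * rate)


def after_tax_cashflow(
    treated_total: float, price: float, cm: CommercialModel
) -> float:
    """Annual after-tax operating cash flow in dollars.

    revenue = patients x price; operating = revenue x (1 - COGS - SG&A - R&D);
    tax applies only when operating income is positive (no loss credit).
    """
    if treated_total < 0:
        raise ValueError("treated_total must be >= 0")
    if cm.cogs_frac + cm.sga_frac + cm.rnd_frac > 1.0:
        raise ValueError("sales fractions sum above 1")
    revenue = treated_total * price
    operating = revenue * cm.operating_margin
    if operating > 0:
        operating *= 1.0 - cm.tax_rate
    return operating


def revenue_schedule(
    cm: CommercialModel,
    n_years: int | None = None,
    *,
    price: float | None = None,
    peak_rate: float | None = None,
) -> pd.DataFrame:
    """Per-year commercial schedule over the exclusivity window.

    Columns: year since launch, per-group treated counts, total, gross
    revenue and after-tax cash flow (both in $). Values are unrounded.
    """
    if n_years is None:
        n_years = int(np.ceil(cm.exclusivity_years))
    price = cm.price if price is None else price
    rows = []
    for year in range(1, n_years + 1):
        per_group = treated_patients(cm.adoption, year=year, peak_rate=peak_rate)
        total = float(per_group.sum())
        row = {"year": year}
        for g, t in zip(cm.adoption.groups, per_group):
            row[f"treated_{g.label}"] = t
        row["treated_total"] = total
        row["gross_revenue"] = total * price
        row["after_tax_cashflow"] = after_tax_cashflow(total, price, cm)
        rows.append(row)
    return pd.DataFrame(rows)


def write_revenue_schedule(cm: CommercialModel, path: str | Path, **kw) -> None:
    revenue_schedule(cm, **kw).to_csv(path, index=False)
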