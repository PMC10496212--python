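"""Diversification across a portfolio of correlated rare-disease compounds.

Simulates 100,000 joint paths of eight compounds sharing the base-case
assumptions, with phase-success latents pairwise correlated across drugs,
and compares the aggregate risk profile with the single-compound one. The
cross-drug correlation is an assumption and is reported with every result.
"""

from orphanval import (
    CROSS_DRUG_RHO_FITTED,
    PortfolioSpec,
    diversification_report,
    load_fixture,
    simulate_compound,
    simulate_portfolio,
    summarize,
)

base = load_fixture("rett_base")
single = summarize(simulate_compound(base, 10_000, seed=2024))

spec = PortfolioSpec(
    scenarios=base, n_drugs=8, cross_drug_rho=CROSS_DRUG_RHO_FITTED
)
_, portfolio = simulate_portfolio(spec, n_paths=100_000, seed=2024)

print(
    f"assumption: cross_drug_rho = {portfolio.cross_drug_rho} "
    f"({portfolio.n_drugs} drugs)"
)
print(diversification_report(single, portfolio).round(3).to_string(index=False))
print(
    "\nPooling eight imperfectly correlated compounds cuts the chance that "
    "the whole program loses money and softens every phase-level loss "
    "probability; lower cross-drug correlation would shrink them further."
)
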