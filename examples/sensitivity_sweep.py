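"""One-parameter sensitivity of the deterministic rNPV.

Sweeps the annual price and the discount rate around the base case, holding
everything else fixed — the tornado-style view of which assumptions move
the valuation most.
"""

from orphanval import load_fixture, sensitivity_grid

base = load_fixture("rett_base")

print("price sweep ($/patient/year -> rNPV $M):")
for v, r in sensitivity_grid(base, "price", [30_000, 40_000, 50_000]):
    print(f"  {v:>8,.0f} -> {r:7.2f}")

print("discount-rate sweep:")
for v, r in sensitivity_grid(base, "discount_rate", [0.15, 0.13, 0.11]):
    print(f"  {v:>8.2f} -> {r:7.2f}")

print("phase-2 success-probability sweep:")
for v, r in sensitivity_grid(base, "pos:phase2", [0.43, 0.53, 0.63]):
    print(f"  {v:>8.2f} -> {r:7.2f}")

print(
    "\nThe valuation is linear in price, roughly linear in each phase PoS, "
    "and sharply convex in the discount rate because revenue sits 6-20 "
    "years out while costs are near-term."
)
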