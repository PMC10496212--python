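"""Deterministic risk-adjusted NPV of a single rare-disease compound.

Loads the shipped base-case scenario (a repurposed Rett-syndrome compound:
four consolidated development phases, a 14-year exclusivity window, a
$40,000 annual price), values it at the 13% discount rate, and adds the two
orphan-drug benefits on top.
"""

from orphanval import apply_prv, apply_tax_credit, load_fixture, rnpv
from orphanval.engine import SPREADSHEET_CONVENTIONS

base = load_fixture("rett_base")
res = rnpv(base, conventions=SPREADSHEET_CONVENTIONS)

print(f"overall rNPV at project start: {res.rnpv_overall:6.2f} $M")
for name, v in zip([p.name for p in base.plan.phases], res.value_after_phase):
    print(f"  value after {name:32s} {v:7.2f} $M")

with_credit = apply_tax_credit(res, base)
with_prv = apply_prv(with_credit, base)
print(f"with 25% R&D tax credit:       {with_credit.rnpv_overall:6.2f} $M")
print(f"plus priority review voucher:  {with_prv.rnpv_overall:6.2f} $M")

print(
    "\nThe overall figure risk-weights every cash flow by the probability "
    "the project survives to it; the per-phase values are what the project "
    "is worth at each phase end, conditional on just having completed it "
    "(they grow as development risk burns off)."
)
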