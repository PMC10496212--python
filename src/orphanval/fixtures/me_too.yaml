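# Follow-on ("me-too") compound: elevated PoS after another compound has shown
# phase-2 efficacy in the indication; all other assumptions as in the base case.
schema_version: 1
name: me_too
plan:
  phases:
  - name: discovery_preclinical_phase1
    pos: 0.72
    cost_min: 1.0
    cost_mode: 4.0
    cost_max: 7.0
    dur_min: 1.0
    dur_mode: 1.0
    dur_max: 1.0
  - name: phase2
    pos: 0.63
    cost_min: 9.0
    cost_mode: 14.0
    cost_max: 40.0
    dur_min: 1.0
    dur_mode: 2.0
    dur_max: 3.0
  - name: phase3
    pos: 0.79
    cost_min: 22.0
    cost_mode: 35.0
    cost_max: 99.0
    dur_min: 1.0
    dur_mode: 2.0
    dur_max: 3.0
  - name: fda_submission_to_launch
    pos: 0.94
    cost_min: 37.0
    cost_mode: 37.0
    cost_max: 37.0
    dur_min: 1.0
    dur_mode: 1.0
    dur_max: 1.0
commercial:
  price: 40000.0
  price_lo: 30000.0
  price_hi: 50000.0
  adoption:
    peak_rate: 0.5
    peak_rate_lo: 0.35
    peak_rate_hi: 0.65
    ramp:
    - 0.3333333333333333
    - 0.6666666666666666
    - 1.0
    groups:
    - label: 0-12
      population_thousands: 25770.0
      prevalence_per_1000: 0.125
      peak_adoption_multiplier: 1.0
    - label: 12-24
      population_thousands: 25313.0
      prevalence_per_1000: 0.12
      peak_adoption_multiplier: 0.75
    - label: 24-48
      population_thousands: 51749.0
      prevalence_per_1000: 0.115
      peak_adoption_multiplier: 0.5
    - label: 48-85
      population_thousands: 64090.0
      prevalence_per_1000: 0.06
      peak_adoption_multiplier: 0.0
  cogs_frac: 0.1
  sga_frac: 0.3
  rnd_frac: 0.05
  prerevenue_sga_of_rnd: 0.4
  tax_rate: 0.2
  exclusivity_years: 14.0
  patent_term_years: 20.0
  orphan_exclusivity_years: 7.0
  discount_rate: 0.13
  tax_credit_rate: 0.25
  prv_value: 100.0
  prv_year: 3.0
  pdufa_waiver: 2.9
correlations:
  phase23_time_cost_rho: 0.5
  cross_drug_rho: 0.2
flags:
  include_tax_credit: false
  include_prv: false
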