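# Three treatments whose baseline uptakes are positively dependent (patients
# who take one treatment are likelier to take the others), supplied as
# ordinary joint moments: singletons are the marginal uptakes, higher-order
# moments exceed the independence products.  The target scenario raises all
# marginals and assumes independent receipt.  Synthetic demonstration data.
schema_version: 1
name: dependent-uptake-demo
treatments:
  - id: ace_inhibitor
    rr: 0.80
  - id: beta_blocker
    rr: 0.85
  - id: statin
    rr: 0.78
baseline_uptake:
  form: moments
  k: 3
  moments:
    "1": 0.60
    "2": 0.50
    "3": 0.40
    "1,2": 0.35
    "1,3": 0.28
    "2,3": 0.25
    "1,2,3": 0.20
target_uptake:
  form: independent
  marginals: [0.90, 0.85, 0.80]
strata:
  - label: under-65
    N: 4000
    deaths: 520
  - label: 65-plus
    N: 2600
    deaths: 610
options:
  cf_interpretation: biased
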