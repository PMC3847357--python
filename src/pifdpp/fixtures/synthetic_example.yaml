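# Two-treatment worked example: N=2500 eligible patients, 750 observed
# deaths under baseline uptakes (50%, 60%), target uptakes (80%, 80%),
# relative risk reductions 0.07 and 0.10, independent uptakes.  The classic
# method estimates cf = 750/2500 = 0.3 and uses it as-is ("biased"
# interpretation); the PIF method uses the 750 deaths directly.
schema_version: 1
name: synthetic-example
treatments:
  - id: treatment1
    rrr: 0.07
  - id: treatment2
    rrr: 0.10
baseline_uptake:
  form: independent
  marginals: [0.5, 0.6]
target_uptake:
  form: independent
  marginals: [0.8, 0.8]
strata:
  - label: all
    N: 2500
    deaths: 750
options:
  cf_interpretation: biased
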