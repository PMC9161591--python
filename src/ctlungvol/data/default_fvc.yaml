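# Placeholder linear spirometry reference set for FVC (litres).
# Coefficients are of the typical magnitude of published adult equations
# (FVC rises ~0.05-0.06 L per cm of height, falls ~0.02-0.03 L per year of
# age); they are NOT a published standard.  Replace with the equation set
# appropriate to your cohort's population before clinical use.
name: placeholder-linear
male:
  alpha: 0.0600   # L per cm height
  beta: -0.0214   # L per year age
  gamma: -4.650
female:
  alpha: 0.0491
  beta: -0.0216
  gamma: -3.590
valid_age: [18, 95]
valid_height: [120, 200]
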