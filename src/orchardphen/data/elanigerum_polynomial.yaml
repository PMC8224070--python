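# Eriosoma lanigerum (apterous virginoparae) development rate, degree-6
# polynomial (coefficients constant-first, units day^-1). Lower threshold
# 5.2 degC; upper cutoff "auto" (~35.0 degC with these coefficients).
# Overwinters as first instars: no head start, first crawler migration
# after one full generation.
species_label: Eriosoma lanigerum (apterous virginoparae)
family: polynomial
coefficients:
  - 1.013e-3
  - -9.014e-4
  - -2.011e-4
  - 1.044e-4
  - -8.425e-6
  - 2.731e-7
  - -3.209e-9
lower_threshold: 5.2
upper_cutoff: auto
start_fraction: 0.0
events:
  - name: first migration
    threshold: 1.0
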