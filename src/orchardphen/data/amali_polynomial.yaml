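# Aphelinus mali egg-to-adult development rate, degree-5 polynomial
# (coefficients constant-first, units day^-1). Lower threshold 8.3 degC;
# upper cutoff "auto" resolves the polynomial's own zero-crossing
# (~35.0 degC with these rounded coefficients); set 32.7 to force the
# reported cutoff instead. Overwintering head start: half a generation.
species_label: Aphelinus mali (egg-to-adult)
family: polynomial
coefficients:
  - -2.940e-3
  - -1.716e-4
  - 4.895e-4
  - -5.389e-5
  - 2.653e-6
  - -4.303e-8
lower_threshold: 8.3
upper_cutoff: auto
start_fraction: 0.5
events:
  - name: G1 adults
    threshold: 1.0
  - name: G2 adults
    threshold: 2.0
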