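# Published mouse CD4+ T-cell recirculation rates with the C1 pair kept
# split: C1a = Peyer's patches (no direct exit to blood; direct edge to
# C1b), C1b = mesenteric lymph nodes.  Remaining compartments as in
# table1.yaml.  All rates in min^-1.
units: per_minute
blood:
  mu: 1.478e-5
  lambda: 1.458e-5
split_compartment:
  xi_B_C1a: 0.53e-2
  xi_B_C1b: 1.06e-2
  xi_C1a_C1b: 0.34e-2
  xi_C1b_B: 0.34e-2
  mu: 1.478e-5
  lambda: 1.458e-5
compartments:
  - {label: C2, xi_in: 1.83,    xi_out: 2.17,    mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C3, xi_in: 0.41,    xi_out: 1.14,    mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C4, xi_in: 5.6e-2,  xi_out: 7.0e-3,  mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C5, xi_in: 2.6e-2,  xi_out: 3.4e-3,  mu: 1.478e-5, lambda: 1.458e-5}
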