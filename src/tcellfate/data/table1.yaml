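# Published mouse CD4+ T-cell recirculation rates, merged star model.
# C1 = mesenteric lymph nodes + Peyer's patches (effective rates),
# C2 = lung, C3 = liver, C4 = spleen, C5 = subcutaneous lymph nodes.
# All rates in min^-1; death 1.478e-5 (~1/47 day^-1), division 1.458e-5
# (~1/48 day^-1) are uniform across compartments.
units: per_minute
blood:
  mu: 1.478e-5
  lambda: 1.458e-5
compartments:
  - {label: C1, xi_in: 1.59e-2, xi_out: 2.60e-3, mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C2, xi_in: 1.83,    xi_out: 2.17,    mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C3, xi_in: 0.41,    xi_out: 1.14,    mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C4, xi_in: 5.6e-2,  xi_out: 7.0e-3,  mu: 1.478e-5, lambda: 1.458e-5}
  - {label: C5, xi_in: 2.6e-2,  xi_out: 3.4e-3,  mu: 1.478e-5, lambda: 1.458e-5}
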