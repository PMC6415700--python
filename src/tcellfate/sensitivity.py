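"""Exact sensitivity of the stationary fractions to migration parameters.

The fractions of the star model depend on the migration rates only
through the immigration/emigration ratios ``K_i = xi_in[i] / xi_out[i]``,
so two matrices are reported:

* ``S_tilde[state, j] = d f_state / d K_j`` -- with ``s = 1 + sum K``::

      d f_B / d K_j  = -1 / s**2                     (same for every j)
      d f_Ci / d K_j = (delta_ij * s - K_i) / s**2

* ``S[state, col]`` -- derivatives with respect to the raw rates in
  compartment-major order ``(xi_B_C1, xi_C1_B, xi_B_C2, xi_C2_B, ...)``,
  obtained from ``S_tilde`` by the chain rule::

      d f / d xi_B_Ci = (d f / d K_i) / xi_out[i]
      d f / d xi_Ci_B = -(d f / d K_i) * K_i / xi_out[i]

Each ``S_tilde`` column sums to zero (the fractions always sum to 1), the
diagonal compartment entries are positive (raising ``K_i`` shifts time
into ``Ci``) and the blood row is uniformly negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fast_migration import immigration_emigration_ratios, stationary_fractions
from .models import StarModel, validate

__all__ = [
    "SensitivityReport",
    "sensitivity_wrt_ratios",
    "sensitivity_wrt_rates",
    "finite_difference_sensitivity",
    "compute_sensitivity",
]


def sensitivity_wrt_ratios(model: StarModel) -> np.ndarray:
    """Matrix ``d f_state / d K_j``, shape ``(M+1, M)``, blood row first."""
    K = immigration_emigration_ratios(model)
    M = model.M
    s = 1.0 + np.sum(K)
    S = np.empty((M + 1, M))
    S[0, :] = -1.0 / s**2
    S[1:, :] = (s * np.eye(M) - K[:, None]) / s**2
    return S


def sensitivity_wrt_rates(model: StarModel) -> np.ndarray:
    """Matrix ``d f_state / d xi``, columns ``(xi_B_C1, xi_C1_B, ...)``."""
    validate(model)
    if np.any(model.xi_out == 0):
        i = int(np.argmax(model.xi_out == 0))
        raise ValueError(
            f"xi_out[{model.labels[i]}] == 0: rate sensitivities undefined"
        )
    K = immigration_emigration_ratios(model)
    St = sensitivity_wrt_ratios(model)
    M = model.M
    S = np.empty((M + 1, 2 * M))
    S[:, 0::2] = St / model.xi_out[None, :]
    S[:, 1::2] = -St * (K / model.xi_out)[None, :]
    return S


def finite_difference_sensitivity(
    model: StarModel, rel_step: float = 1e-6
) -> np.ndarray:
    """Central-difference estimate of ``sensitivity_wrt_rates``.

    Each migration rate is perturbed symmetrically by ``rel_step`` times
    its value and the stationary fractions recomputed; serves as the
    independent numerical oracle for the closed forms.
    """
    validate(model)
    M = model.M
    S = np.empty((M + 1, 2 * M))
    for i in range(M):
        for k, vec_name in ((0, "xi_in"), (1, "xi_out")):
            base = getattr(model, vec_name).copy()
            h = rel_step * base[i]
            if h == 0:
                raise ValueError(
                    f"{vec_name}[{i}] == 0: relative step degenerates"
                )
            for sign, store in ((+1, "hi"), (-1, "lo")):
                vec = base.copy()
                vec[i] = base[i] + sign * h
                kwargs = {vec_name: vec}
                perturbed = StarModel(
                    xi_in=kwargs.get("xi_in", model.xi_in),
                    xi_out=kwargs.get("xi_out", model.xi_out),
                    mu=model.mu, lam=model.lam,
                    mu_B=model.mu_B, lam_B=model.lam_B,
                    labels=model.labels,
                )
                f = stationary_fractions(perturbed)
                if store == "hi":
                    f_hi = f
                else:
                    f_lo = f
            S[:, 2 * i + k] = (f_hi - f_lo) / (2.0 * h)
    return S


@dataclass
class SensitivityReport:
    """Both sensitivity matrices at a given evaluation point."""

    row_labels: tuple[str, ...]
    ratio_labels: tuple[str, ...]
    rate_labels: tuple[str, ...]
    S: np.ndarray
    S_tilde: np.ndarray

    def rates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=list(self.row_labels),
                            columns=list(self.rate_labels))

    def ratios_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S_tilde, index=list(self.row_labels),
                            columns=list(self.ratio_labels))

    def to_csv(self, path_rates: str | Path, path_ratios: str | Path) -> None:
        self.rates_frame().to_csv(path_rates, index_label="fraction")
        self.ratios_frame().to_csv(path_ratios, index_label="fraction")


def compute_sensitivity(model: StarModel) -> SensitivityReport:
    """Evaluate both matrices with labelled rows/columns."""
    rate_labels = []
    for lab in model.labels:
        rate_labels += [f"xi_B_{lab}", f"xi_{lab}_B"]
    return SensitivityReport(
        row_labels=tuple(f"f_{s}" for s in model.state_labels),
        ratio_labels=tuple(f"K_{lab}" for lab in model.labels),
        rate_labels=tuple(rate_labels),
        S=sensitivity_wrt_rates(model),
        S_tilde=sensitivity_wrt_ratios(model),
    )
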