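"""Fast-migration (quasi-steady-state) approximation.

Migration rates are orders of magnitude faster than division and death
(minutes vs. weeks), so the cell's location equilibrates before any
division or death event.  The spatial model then collapses to a single
birth-and-death process with effective rates averaged over the
migration-only stationary distribution ``f``:

    lam_bar = sum_j f_j * lam_j,    mu_bar = sum_j f_j * mu_j.

In the star model the stationary fractions depend on the migration rates
only through the immigration/emigration ratios ``K_i = xi_in[i] / xi_out[i]``:

    f_B = 1 / (1 + sum K),    f_Ci = K_i * f_B.

The extended model (split compartment with a direct C1a -> C1b edge) has
the analogous closed form in terms of ``K_1a = xi_B_C1a / xi_C1a_C1b``,
``K_1b = xi_B_C1b / xi_C1b_B`` and ``K_1a1b = xi_C1a_C1b / xi_C1b_B``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import ExtendedModel, StarModel, validate

__all__ = [
    "SinkError",
    "FMApproximation",
    "immigration_emigration_ratios",
    "stationary_fractions",
    "stationary_fractions_extended",
    "effective_rates",
    "mean_extinction_time",
    "fm_descriptors",
]


class SinkError(ValueError):
    """A compartment receives cells but has no exit: no stationary law exists."""


def immigration_emigration_ratios(model: StarModel) -> np.ndarray:
    """Ratios ``K_i = xi_in[i] / xi_out[i]``, the sole determinants of f."""
    validate(model)
    sink = (model.xi_out == 0) & (model.xi_in > 0)
    if np.any(sink):
        i = int(np.argmax(sink))
        raise SinkError(
            f"compartment {model.labels[i]} has xi_in > 0 but xi_out == 0"
        )
    return np.where(model.xi_in > 0, model.xi_in / np.where(
        model.xi_out > 0, model.xi_out, 1.0), 0.0)


def stationary_fractions(model: StarModel) -> np.ndarray:
    """Migration-only stationary fractions, order ``(B, C1..CM)``."""
    K = immigration_emigration_ratios(model)
    f_B = 1.0 / (1.0 + np.sum(K))
    return np.concatenate([[f_B], K * f_B])


def stationary_fractions_extended(model: ExtendedModel) -> np.ndarray:
    """Stationary fractions of the split model, order ``(B, C1a, C1b, C2..CM)``."""
    validate(model)
    if model.xi_C1b_B <= 0:
        raise SinkError("compartment C1b has xi_C1b_B == 0 but receives cells")
    sink = (model.xi_out == 0) & (model.xi_in > 0)
    if np.any(sink):
        i = int(np.argmax(sink))
        raise SinkError(
            f"compartment {model.labels[i]} has xi_in > 0 but xi_out == 0"
        )
    K_1a = model.xi_B_C1a / model.xi_C1a_C1b
    K_1b = model.xi_B_C1b / model.xi_C1b_B
    K_1a1b = model.xi_C1a_C1b / model.xi_C1b_B
    K_rest = np.where(model.xi_in > 0, model.xi_in / np.where(
        model.xi_out > 0, model.xi_out, 1.0), 0.0)
    K_tot = K_1a * K_1a1b + K_1a + K_1b + np.sum(K_rest)
    f_B = 1.0 / (K_tot + 1.0)
    f_C1a = K_1a * f_B
    f_C1b = (K_1a * K_1a1b + K_1b) * f_B
    return np.concatenate([[f_B, f_C1a, f_C1b], K_rest * f_B])


def _living_rates(model: StarModel | ExtendedModel) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(model, StarModel):
        lam = np.concatenate([[model.lam_B], model.lam])
        mu = np.concatenate([[model.mu_B], model.mu])
    else:
        lam = np.concatenate(
            [[model.lam_B, model.lam_C1a, model.lam_C1b], model.lam])
        mu = np.concatenate(
            [[model.mu_B, model.mu_C1a, model.mu_C1b], model.mu])
    return lam, mu


def effective_rates(
    model: StarModel | ExtendedModel,
    fractions: np.ndarray | None = None,
) -> tuple[float, float]:
    """Effective birth/death rates ``(lam_bar, mu_bar)``, min^-1."""
    if fractions is None:
        fractions = (
            stationary_fractions(model)
            if isinstance(model, StarModel)
            else stationary_fractions_extended(model)
        )
    fractions = np.asarray(fractions, dtype=float)
    if not np.isclose(np.sum(fractions), 1.0, atol=1e-9):
        raise ValueError("fractions must sum to 1")
    lam, mu = _living_rates(model)
    return float(fractions @ lam), float(fractions @ mu)


def mean_extinction_time(lam_bar: float, mu_bar: float) -> float:
    """Mean time for the progeny of one cell to die out, minutes.

    For a linear birth-death process with one founder this is
    ``-log(1 - lam_bar/mu_bar) / lam_bar`` when ``0 < lam_bar < mu_bar``;
    the limit ``1/mu_bar`` is taken as ``lam_bar -> 0``.  A series
    expansion guards against catastrophic cancellation for tiny ratios.
    Returns ``+inf`` when ``lam_bar >= mu_bar`` or ``mu_bar == 0``.
    """
    if mu_bar <= 0 or lam_bar >= mu_bar:
        return np.inf
    rho = lam_bar / mu_bar
    if rho < 1e-8:
        # -log(1-rho)/lam = (1/mu) * (1 + rho/2 + rho^2/3 + ...)
        return (1.0 + rho / 2.0 + rho**2 / 3.0) / mu_bar
    return float(-np.log1p(-rho) / lam_bar)


@dataclass
class FMApproximation:
    """Fast-migration approximations to the single-cell descriptors.

    Location-resolved arrays are ordered like the model's living states.
    The approximation forgets the starting compartment, so every field is
    a scalar or a per-location vector.  ``subcritical`` is ``False`` when
    ``lam_bar >= mu_bar``, in which case extinction time and genealogy
    mean are ``+inf`` (flagged, never raised).
    """

    labels: tuple[str, ...]
    fractions: np.ndarray
    lam_bar: float
    mu_bar: float
    mean_lifetime: float
    mean_divisions: float
    divisions_by_location: np.ndarray
    divisions_by_location_local_rates: np.ndarray
    death_probabilities: np.ndarray
    mean_extinction_time: float
    mean_genealogy_size: float
    subcritical: bool

    def to_frame(self) -> pd.DataFrame:
        """Tidy table in the same schema as ``DescriptorSet.to_frame``."""
        rows = [
            ("any", "mean_lifetime", "", self.mean_lifetime, "min", "fm"),
            ("any", "mean_divisions", "", self.mean_divisions, "", "fm"),
            ("any", "mean_genealogy_size", "", self.mean_genealogy_size,
             "cells", "fm"),
            ("any", "mean_extinction_time", "", self.mean_extinction_time,
             "min", "fm"),
        ]
        for j, loc in enumerate(self.labels):
            rows.append(("any", "stationary_fraction", loc,
                         self.fractions[j], "", "fm"))
            rows.append(("any", "mean_divisions_by_location", loc,
                         self.divisions_by_location[j], "", "fm"))
            rows.append(("any", "death_location_probability", loc,
                         self.death_probabilities[j], "", "fm"))
        return pd.DataFrame(
            rows, columns=["start", "statistic", "location", "value",
                           "units", "method"]
        )


def fm_descriptors(model: StarModel | ExtendedModel) -> FMApproximation:
    """Evaluate the fast-migration approximation for either model variant.

    The printed location split of the division count is
    ``E(N(j)) ~= (lam_bar/mu_bar) * f_j``; the variant weighting by the
    local division rate, ``f_j * lam_j / mu_bar`` (identical when the
    division rate is uniform), is exposed as
    ``divisions_by_location_local_rates`` and is experimental.
    """
    if isinstance(model, StarModel):
        f = stationary_fractions(model)
        labels = model.state_labels
    else:
        f = stationary_fractions_extended(model)
        labels = model.state_labels
    lam, mu = _living_rates(model)
    lam_bar = float(f @ lam)
    mu_bar = float(f @ mu)
    if mu_bar > 0:
        lifetime = 1.0 / mu_bar
        divisions = lam_bar / mu_bar
        death_probs = mu * f / mu_bar
    else:
        lifetime = np.inf
        divisions = np.inf if lam_bar > 0 else 0.0
        death_probs = np.full_like(f, np.nan)
    subcritical = lam_bar < mu_bar
    if subcritical:
        # includes the founder: equals 1 when lam_bar == 0.  The exact
        # descriptors exclude the founder, so the two differ by one cell.
        genealogy = (mu_bar + lam_bar) / (mu_bar - lam_bar)
    else:
        genealogy = np.inf
    return FMApproximation(
        labels=labels,
        fractions=f,
        lam_bar=lam_bar,
        mu_bar=mu_bar,
        mean_lifetime=lifetime,
        mean_divisions=divisions,
        divisions_by_location=divisions * f if np.isfinite(divisions) else f * np.inf,
        divisions_by_location_local_rates=(
            f * lam / mu_bar if mu_bar > 0 else f * np.nan
        ),
        death_probabilities=death_probs,
        mean_extinction_time=mean_extinction_time(lam_bar, mu_bar),
        mean_genealogy_size=genealogy,
        subcritical=subcritical,
    )
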