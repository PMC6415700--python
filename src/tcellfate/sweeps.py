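"""Parameter sweeps reproducing the published numerical experiments.

Three sweeps are provided, each returning a tidy table (one row per grid
point x statistic x location x method):

* :func:`sweep_R` -- the asymmetry sweep: with baseline rates
  ``(mu, lam)``, set ``mu_B = R mu``, ``mu_Ci = R mu``, ``lam_B = lam``,
  ``lam_Ci = R lam`` and scan ``R``.  ``R = 1`` is the fully symmetric
  scenario; growing ``R`` makes division in the blood relatively rarer
  while division/death rates approach the migration timescale, degrading
  the fast-migration approximation.
* :func:`sweep_death_rate` -- scan the death rate of one named
  compartment, tracking death-location probabilities, mean lifetime and
  mean genealogy size; the genealogy mean diverges (infinity flag) when
  the non-explosion conditions are crossed.
* :func:`sweep_direct_migration` -- scan the direct C1a -> C1b rate of
  the extended model, tracking the stationary fractions; as the rate
  tends to zero C1a becomes a sink (``f_C1a -> 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .descriptors import compute_descriptors
from .fast_migration import fm_descriptors, stationary_fractions_extended
from .gillespie import estimate_descriptors
from .models import ExtendedModel, StarModel, validate

__all__ = [
    "SweepConfig",
    "apply_R_scaling",
    "sweep_R",
    "sweep_death_rate",
    "sweep_direct_migration",
]


@dataclass
class SweepConfig:
    """Declarative description of a sweep (used by the CLI).

    ``variable`` is one of ``"R"``, ``"mu_<label>"`` (e.g. ``mu_C1``) or
    ``"xi_C1a_C1b"``; ``grid`` must be non-empty and strictly increasing.
    """

    variable: str
    grid: list[float]
    methods: tuple[str, ...] = ("exact", "fm")
    reps: int = 0
    genealogy_reps: int = 0
    seed: int = 0
    mu_baseline: float | None = None
    lam_baseline: float | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        for m in self.methods:
            if m not in ("exact", "fm", "simulated"):
                raise ValueError(f"unknown method {m!r}")


def apply_R_scaling(
    model: StarModel, R: float, mu: float, lam: float
) -> StarModel:
    """Asymmetry scaling: ``mu_B = mu_Ci = R mu``, ``lam_B = lam``, ``lam_Ci = R lam``."""
    validate(model)
    return replace(
        model,
        mu=np.full(model.M, R * mu),
        lam=np.full(model.M, R * lam),
        mu_B=R * mu,
        lam_B=lam,
    )


def _exact_rows(model: StarModel, point: dict) -> list[dict]:
    ds = compute_descriptors(model)
    labels = ds.labels
    rows = []

    def add(stat, loc, value, start="B"):
        rows.append({**point, "start": start, "statistic": stat,
                     "location": loc, "method": "exact", "value": value})

    add("mean_lifetime", "", ds.m[0])
    add("mean_divisions", "", ds.m_hat[0])
    add("mean_genealogy_size", "", ds.m_tilde[0])
    for j, loc in enumerate(labels):
        add("mean_divisions_by_location", loc, ds.m_hat_by_loc[0, j])
        add("death_location_probability", loc, ds.beta[0, j])
    return rows


def _fm_rows(model: StarModel, point: dict) -> list[dict]:
    fm = fm_descriptors(model)
    rows = []

    def add(stat, loc, value):
        rows.append({**point, "start": "any", "statistic": stat,
                     "location": loc, "method": "fm", "value": value})

    add("mean_lifetime", "", fm.mean_lifetime)
    add("mean_divisions", "", fm.mean_divisions)
    add("mean_genealogy_size", "", fm.mean_genealogy_size)
    for j, loc in enumerate(fm.labels):
        add("mean_divisions_by_location", loc, fm.divisions_by_location[j])
        add("death_location_probability", loc, fm.death_probabilities[j])
    return rows


def _sim_rows(model: StarModel, point: dict, reps: int,
              genealogy_reps: int, seed: int) -> list[dict]:
    summary = estimate_descriptors(
        model, start=0, n_reps=reps, seed=seed,
        genealogy_reps=genealogy_reps,
    )
    rows = []
    for key, (mean, se) in summary.estimates.items():
        stat, loc = (key[:-1].split("[") + [""])[:2] if "[" in key else (key, "")
        rows.append({**point, "start": "B", "statistic": stat,
                     "location": loc, "method": "simulated", "value": mean,
                     "se": se})
    return rows


def sweep_R(
    model: StarModel,
    config: SweepConfig,
) -> pd.DataFrame:
    """Scan the asymmetry factor R on a star model.

    Baselines ``(mu, lam)`` default to the model's blood rates.  Grid
    points where the genealogy turns infinite propagate ``inf`` values;
    the sweep continues.
    """
    mu = config.mu_baseline if config.mu_baseline is not None else model.mu_B
    lam = config.lam_baseline if config.lam_baseline is not None else model.lam_B
    rows: list[dict] = []
    for k, R in enumerate(config.grid):
        scaled = apply_R_scaling(model, float(R), mu, lam)
        point = {"R": float(R), "ln_R": float(np.log(R))}
        if "exact" in config.methods:
            rows += _exact_rows(scaled, point)
        if "fm" in config.methods:
            rows += _fm_rows(scaled, point)
        if "simulated" in config.methods:
            rows += _sim_rows(scaled, point, config.reps,
                              config.genealogy_reps, config.seed + k)
    return pd.DataFrame(rows)


def sweep_death_rate(
    model: StarModel,
    compartment: str,
    config: SweepConfig,
) -> pd.DataFrame:
    """Scan the death rate of one compartment on a star model."""
    validate(model)
    i = model.labels.index(compartment)
    rows: list[dict] = []
    for k, value in enumerate(config.grid):
        mu = model.mu.copy()
        mu[i] = value
        varied = replace(model, mu=mu)
        point = {"swept_parameter": f"mu_{compartment}",
                 "value_min^-1": float(value)}
        if "exact" in config.methods:
            rows += _exact_rows(varied, point)
        if "fm" in config.methods:
            rows += _fm_rows(varied, point)
        if "simulated" in config.methods:
            rows += _sim_rows(varied, point, config.reps,
                              config.genealogy_reps, config.seed + k)
    return pd.DataFrame(rows)


def sweep_direct_migration(
    model: ExtendedModel,
    config: SweepConfig,
) -> pd.DataFrame:
    """Scan the direct C1a -> C1b rate; report stationary fractions."""
    validate(model)
    rows: list[dict] = []
    for value in config.grid:
        varied = replace(model, xi_C1a_C1b=float(value))
        fractions = stationary_fractions_extended(varied)
        for lab, f in zip(varied.state_labels, fractions):
            rows.append({
                "xi_C1a_C1b": float(value),
                "statistic": "stationary_fraction",
                "location": lab,
                "method": "fm",
                "value": float(f),
            })
    return pd.DataFrame(rows)
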