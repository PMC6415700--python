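"""Exact single-cell summary statistics by first-step analysis.

For the absorbing chain of :mod:`tcellfate.models` every quantity below
has a closed form obtained by conditioning on the first event out of each
state.  With ``D = mu_B + sum(xi_in) - sum(xi_in * xi_out / (mu + xi_out))``
(the net drain rate seen from the blood once excursions are folded in):

* mean lifetime ``m_i = E(T_i)``:
  ``m_B = (sum(xi_in / (mu + xi_out)) + 1) / D`` and
  ``m_Ci = (xi_out[i] * m_B + 1) / (mu[i] + xi_out[i])``;
* mean number of divisions ``m_hat_i = E(N_i)`` and its split by the
  compartment where each division happens, ``m_hat_i(j)``;
* death-location probabilities ``beta_i(j) = P(cell dies in j | starts in i)``;
* mean genealogy size ``m_tilde_i = E(G_i)`` (2 cells per division event,
  founder excluded), finite only under the non-explosion conditions;
* the Laplace-Stieltjes transform of the lifetime and the full
  probability mass function of the division count.

Every closed form is cross-checked in the test-suite against
:func:`solve_first_step`, a generic dense linear solve on the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    ExtendedModel,
    GeneratorView,
    StarModel,
    build_generator,
    check_finiteness,
    validate,
)

__all__ = [
    "AbsorptionError",
    "DescriptorSet",
    "DivisionPMF",
    "mean_lifetime",
    "mean_divisions",
    "mean_divisions_by_location",
    "death_location_probabilities",
    "mean_genealogy_size",
    "lifetime_lst",
    "division_count_pmf",
    "solve_first_step",
    "compute_descriptors",
]


class AbsorptionError(ValueError):
    """Raised when death is not certain (e.g. all death rates zero)."""


def _check_absorption(model: StarModel) -> None:
    if model.mu_B + float(np.sum(model.mu)) <= 0.0:
        raise AbsorptionError(
            "all death rates are zero: the lifetime is infinite"
        )


def _blood_drain(model: StarModel) -> float:
    """Net absorption rate D seen from the blood after folding excursions."""
    ret = model.mu + model.xi_out
    D = model.mu_B + np.sum(model.xi_in) - np.sum(
        model.xi_in * model.xi_out / ret
    )
    if D <= 0.0:
        raise AbsorptionError(
            "death is not certain from the blood (net drain rate <= 0)"
        )
    return float(D)


def mean_lifetime(model: StarModel) -> np.ndarray:
    """Mean lifetime per starting state, minutes, order ``(B, C1..CM)``."""
    validate(model)
    _check_absorption(model)
    D = _blood_drain(model)
    ret = model.mu + model.xi_out
    m_B = (np.sum(model.xi_in / ret) + 1.0) / D
    m_C = (model.xi_out * m_B + 1.0) / ret
    return np.concatenate([[m_B], m_C])


def mean_divisions(model: StarModel) -> np.ndarray:
    """Mean number of division events before death, per starting state."""
    validate(model)
    _check_absorption(model)
    D = _blood_drain(model)
    ret = model.mu + model.xi_out
    mhat_B = (np.sum(model.xi_in * model.lam / ret) + model.lam_B) / D
    mhat_C = (model.xi_out * mhat_B + model.lam) / ret
    return np.concatenate([[mhat_B], mhat_C])


def mean_divisions_by_location(model: StarModel) -> np.ndarray:
    """Matrix ``m_hat[start, loc]``: mean divisions performed in ``loc``.

    Rows sum to :func:`mean_divisions`.
    """
    validate(model)
    _check_absorption(model)
    D = _blood_drain(model)
    ret = model.mu + model.xi_out
    M = model.M
    out = np.zeros((M + 1, M + 1))
    # divisions in the blood
    out[0, 0] = model.lam_B / D
    out[1:, 0] = model.xi_out / ret * out[0, 0]
    # divisions in compartment Cj
    mhatB_C = model.xi_in * model.lam / ret / D  # m_hat_B(Cj)
    out[0, 1:] = mhatB_C
    for i in range(M):
        out[1 + i, 1:] = model.xi_out[i] * mhatB_C / ret[i]
        out[1 + i, 1 + i] += model.lam[i] / ret[i]
    return out


def death_location_probabilities(model: StarModel) -> np.ndarray:
    """Matrix ``beta[start, loc] = P(die in loc | start)``; rows sum to 1."""
    validate(model)
    _check_absorption(model)
    D = _blood_drain(model)
    ret = model.mu + model.xi_out
    M = model.M
    beta = np.zeros((M + 1, M + 1))
    beta[0, 0] = model.mu_B / D
    beta[1:, 0] = model.xi_out / ret * beta[0, 0]
    betaB_C = model.xi_in * model.mu / ret / D
    beta[0, 1:] = betaB_C
    for i in range(M):
        beta[1 + i, 1:] = model.xi_out[i] * betaB_C / ret[i]
        beta[1 + i, 1 + i] += model.mu[i] / ret[i]
    return beta


def mean_genealogy_size(model: StarModel) -> tuple[np.ndarray, bool]:
    """Mean total progeny of the founder (2 cells per division event).

    Returns ``(m_tilde, finite)``.  When the non-explosion conditions
    fail the means are ``+inf`` and ``finite`` is ``False``; no exception
    is raised in normal flow.  The founder itself is not counted, so the
    mean is 0 when no division can occur.
    """
    validate(model)
    rep = check_finiteness(model)
    M = model.M
    if not rep.ok:
        return np.full(M + 1, np.inf), False
    ret = model.mu + model.xi_out - model.lam
    D = model.mu_B + np.sum(model.xi_in) - model.lam_B - np.sum(
        model.xi_in * model.xi_out / ret
    )
    mt_B = (np.sum(model.xi_in * 2.0 * model.lam / ret) + 2.0 * model.lam_B) / D
    mt_C = (model.xi_out * mt_B + 2.0 * model.lam) / ret
    return np.concatenate([[mt_B], mt_C]), True


def lifetime_lst(model: StarModel | ExtendedModel, s: float) -> np.ndarray:
    """Laplace-Stieltjes transform ``E(exp(-s T_i))`` per starting state.

    Solves ``(s I - A) L = d`` on the living sub-generator ``A`` with
    death-rate vector ``d``; division self-loops do not enter (they do
    not change the state and cannot affect the absorption time).
    ``L_i(0) = 1`` whenever absorption is certain.
    """
    if s < 0:
        raise ValueError(f"transform argument s must be >= 0, got {s}")
    gen = build_generator(model)
    A = gen.sub_generator
    d = gen.death_rates
    n = gen.n_living
    mat = s * np.eye(n) - A
    try:
        L = np.linalg.solve(mat, d)
    except np.linalg.LinAlgError as exc:
        raise AbsorptionError(f"lifetime transform system is singular: {exc}")
    return L


@dataclass
class DivisionPMF:
    """Truncated distribution of the lifetime division count.

    ``p[n]`` is ``P(N = n | start)``; ``tail`` is the exact mass beyond
    the truncation point (absorption is certain, so total mass is 1).
    """

    start: str
    p: np.ndarray
    tail: float

    def mean(self) -> float:
        """Mean of the truncated PMF (no tail correction)."""
        return float(np.sum(np.arange(self.p.size) * self.p))


def division_count_pmf(
    model: StarModel | ExtendedModel,
    start: int | str = 0,
    n_max: int = 10_000,
    tail_tol: float = 1e-12,
) -> DivisionPMF:
    """Exact PMF of the division count by a matrix-geometric recursion.

    Splitting the first-step probabilities of the embedded jump chain into
    migration (``P_mig``), division (``P_div``, diagonal) and death
    (``p_dead``) gives::

        p_0 = (I - P_mig)^-1 p_dead
        p_n = [(I - P_mig)^-1 P_div] p_{n-1}

    i.e. the chance of observing ``n`` divisions is the chance of
    surviving ``n`` division "stages", each stage wandering freely through
    migration.  Truncated at ``n_max`` or when the remaining mass drops
    below ``tail_tol``.

    Raises
    ------
    AbsorptionError
        If the recursion matrix has spectral radius >= 1 (death is not
        certain and the division count may be infinite).
    """
    gen = build_generator(model)
    n = gen.n_living
    idx = gen.states.index(start) if isinstance(start, str) else int(start)
    if not 0 <= idx < n:
        raise ValueError(f"start state {start!r} is not a living state")
    exit_rates = -np.diag(gen.sub_generator) + gen.division
    if np.any(exit_rates <= 0):
        raise AbsorptionError("a living state has zero total event rate")
    P_mig = gen.sub_generator / exit_rates[:, None]
    np.fill_diagonal(P_mig, 0.0)
    P_div = np.diag(gen.division / exit_rates)
    p_dead = gen.death_rates / exit_rates
    I = np.eye(n)
    p0 = np.linalg.solve(I - P_mig, p_dead)
    R = np.linalg.solve(I - P_mig, P_div)
    rho = float(np.max(np.abs(np.linalg.eigvals(R))))
    if rho >= 1.0 - 1e-10:
        raise AbsorptionError(
            f"division-count recursion has spectral radius {rho:.6g} >= 1; "
            "the division count is not almost-surely finite"
        )
    probs = [p0[idx]]
    vec = p0
    cum = p0[idx]
    while len(probs) <= n_max and 1.0 - cum > tail_tol:
        vec = R @ vec
        probs.append(vec[idx])
        cum += vec[idx]
    return DivisionPMF(
        start=gen.states[idx], p=np.array(probs), tail=max(1.0 - cum, 0.0)
    )


def solve_first_step(
    gen: GeneratorView,
    reward: np.ndarray,
    division_feedback: float = 0.0,
) -> np.ndarray:
    """Generic first-step solver: ``(-A - feedback * diag(division)) x = reward``.

    ``A`` is the living sub-generator.  Expected additive rewards
    accumulated until absorption satisfy this linear system:

    * ``reward = 1`` per unit time -> mean lifetime;
    * ``reward = division`` rates -> mean division count;
    * ``reward = mu_j e_j`` -> probability of dying in ``j``;
    * ``reward = 2 * division`` with ``division_feedback = 1`` -> mean
      genealogy size (each daughter contributes an independent copy of
      the expectation from the division location).

    Used throughout the tests as the independent oracle for the closed
    forms.
    """
    n = gen.n_living
    reward = np.asarray(reward, dtype=float)
    if reward.shape != (n,):
        raise ValueError(f"reward must have shape ({n},), got {reward.shape}")
    mat = -gen.sub_generator - division_feedback * np.diag(gen.division)
    try:
        x = np.linalg.solve(mat, reward)
    except np.linalg.LinAlgError as exc:
        raise AbsorptionError(
            "first-step system is singular: some state cannot reach the "
            f"absorbing state (or the process is critical): {exc}"
        )
    return x


@dataclass
class DescriptorSet:
    """All exact single-cell descriptors of a star model.

    Arrays are ordered ``(B, C1..CM)``; matrices are ``[start, location]``.
    ``m_tilde`` entries are ``+inf`` (with ``genealogy_finite=False``)
    when the non-explosion conditions fail.
    """

    labels: tuple[str, ...]
    m: np.ndarray
    m_hat: np.ndarray
    m_hat_by_loc: np.ndarray
    beta: np.ndarray
    m_tilde: np.ndarray
    genealogy_finite: bool

    def to_frame(self, method: str = "exact") -> pd.DataFrame:
        """Tidy table: one row per (start, statistic, location)."""
        rows = []
        for i, start in enumerate(self.labels):
            rows.append((start, "mean_lifetime", "", self.m[i], "min", method))
            rows.append((start, "mean_divisions", "", self.m_hat[i], "", method))
            rows.append((start, "mean_genealogy_size", "", self.m_tilde[i],
                         "cells", method))
            for j, loc in enumerate(self.labels):
                rows.append((start, "mean_divisions_by_location", loc,
                             self.m_hat_by_loc[i, j], "", method))
                rows.append((start, "death_location_probability", loc,
                             self.beta[i, j], "", method))
        return pd.DataFrame(
            rows, columns=["start", "statistic", "location", "value",
                           "units", "method"]
        )

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "mean_lifetime_min": self.m.tolist(),
            "mean_divisions": self.m_hat.tolist(),
            "mean_divisions_by_location": self.m_hat_by_loc.tolist(),
            "death_location_probabilities": self.beta.tolist(),
            "mean_genealogy_size": [
                None if not np.isfinite(v) else v for v in self.m_tilde
            ],
            "genealogy_finite": self.genealogy_finite,
        }


def compute_descriptors(model: StarModel) -> DescriptorSet:
    """Evaluate every exact descriptor of a validated star model."""
    m_tilde, finite = mean_genealogy_size(model)
    return DescriptorSet(
        labels=model.state_labels,
        m=mean_lifetime(model),
        m_hat=mean_divisions(model),
        m_hat_by_loc=mean_divisions_by_location(model),
        beta=death_location_probabilities(model),
        m_tilde=m_tilde,
        genealogy_finite=finite,
    )
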