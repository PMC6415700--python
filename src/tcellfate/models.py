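"""Model definitions for the single-cell migration/division/death process.

A naive T cell is tracked as an absorbing continuous-time Markov chain on
the states ``{B, C1, ..., CM, dead}``: ``B`` is the blood, each ``Ci`` is a
tissue compartment (lymph nodes, lung, liver, spleen, ...), and the
absorbing state represents cell death.  Migration follows a star topology
around the blood hub with rates ``xi_in[i]`` (blood -> Ci) and
``xi_out[i]`` (Ci -> blood).  Division is a marked self-loop: it spawns a
daughter but leaves the tracked cell where it is.  All rates are in
min^-1.

Two variants are provided:

* :class:`StarModel` -- the pure star topology.
* :class:`ExtendedModel` -- compartment 1 split into a pair
  ``(C1a, C1b)`` with a direct ``C1a -> C1b`` edge and no ``C1a -> blood``
  edge (cells entering C1a can only leave through C1b).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "StarModel",
    "ExtendedModel",
    "GeneratorView",
    "FinitenessReport",
    "ModelValidationError",
    "validate",
    "check_finiteness",
    "critical_death_rate",
    "merge_split_compartment",
    "build_generator",
    "per_day",
    "MINUTES_PER_DAY",
    "TISSUE_NAMES",
]

MINUTES_PER_DAY = 1440.0

#: Biological reading of the default compartment labels (mouse CD4+ T cells,
#: star topology around the blood).
TISSUE_NAMES = {
    "B": "blood",
    "C1": "mesenteric lymph nodes + Peyer's patches",
    "C1a": "Peyer's patches",
    "C1b": "mesenteric lymph nodes",
    "C2": "lung",
    "C3": "liver",
    "C4": "spleen",
    "C5": "subcutaneous lymph nodes",
}


class ModelValidationError(ValueError):
    """Raised when a model's rates or structure are invalid."""


def per_day(rate_per_min: float | np.ndarray) -> float | np.ndarray:
    """Convert a rate from min^-1 to day^-1 (1 day = 1440 min)."""
    return np.asarray(rate_per_min, dtype=float) * MINUTES_PER_DAY


def _as_rate_vector(x, M: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (M,):
        raise ModelValidationError(
            f"{name} must have length {M}, got shape {arr.shape}"
        )
    return arr


@dataclass
class StarModel:
    """Star-topology model: blood hub plus ``M`` tissue compartments.

    Parameters
    ----------
    xi_in
        Migration rates blood -> Ci, min^-1, length ``M``.
    xi_out
        Migration rates Ci -> blood, min^-1, length ``M``.
    mu, lam
        Per-compartment death and division rates, min^-1, length ``M``.
    mu_B, lam_B
        Death and division rate in the blood, min^-1.
    labels
        Compartment names (default ``C1..CM``); the blood is always ``B``.
    """

    xi_in: np.ndarray
    xi_out: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    mu_B: float
    lam_B: float
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        M = np.atleast_1d(np.asarray(self.xi_in, dtype=float)).shape[0]
        self.xi_in = _as_rate_vector(self.xi_in, M, "xi_in")
        self.xi_out = _as_rate_vector(self.xi_out, M, "xi_out")
        self.mu = _as_rate_vector(self.mu, M, "mu")
        self.lam = _as_rate_vector(self.lam, M, "lam")
        self.mu_B = float(self.mu_B)
        self.lam_B = float(self.lam_B)
        if not self.labels:
            self.labels = tuple(f"C{i + 1}" for i in range(M))
        else:
            self.labels = tuple(self.labels)

    @property
    def M(self) -> int:
        """Number of non-blood compartments."""
        return self.xi_in.shape[0]

    @property
    def state_labels(self) -> tuple[str, ...]:
        """Living-state labels, blood first."""
        return ("B",) + self.labels

    def scaled_migration(self, c: float) -> "StarModel":
        """Return a copy with all migration rates multiplied by ``c``."""
        return replace(self, xi_in=self.xi_in * c, xi_out=self.xi_out * c)


@dataclass
class ExtendedModel:
    """Star model with compartment 1 split into the pair ``(C1a, C1b)``.

    Cells reach C1a or C1b directly from the blood; from C1a the only exit
    is the direct edge to C1b (no C1a -> blood edge exists), and from C1b
    cells return to the blood.  The remaining compartments ``C2..CM``
    behave exactly as in :class:`StarModel`.

    ``M`` counts compartments after pooling the pair, so the chain has
    ``M + 2`` living states.
    """

    xi_B_C1a: float
    xi_B_C1b: float
    xi_C1a_C1b: float
    xi_C1b_B: float
    mu_C1a: float
    lam_C1a: float
    mu_C1b: float
    lam_C1b: float
    # compartments C2..CM
    xi_in: np.ndarray
    xi_out: np.ndarray
    mu: np.ndarray
    lam: np.ndarray
    mu_B: float
    lam_B: float
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.atleast_1d(np.asarray(self.xi_in, dtype=float)).shape[0]
        self.xi_in = _as_rate_vector(self.xi_in, m, "xi_in")
        self.xi_out = _as_rate_vector(self.xi_out, m, "xi_out")
        self.mu = _as_rate_vector(self.mu, m, "mu")
        self.lam = _as_rate_vector(self.lam, m, "lam")
        for name in ("xi_B_C1a", "xi_B_C1b", "xi_C1a_C1b", "xi_C1b_B",
                     "mu_C1a", "lam_C1a", "mu_C1b", "lam_C1b",
                     "mu_B", "lam_B"):
            setattr(self, name, float(getattr(self, name)))
        if not self.labels:
            self.labels = tuple(f"C{i + 2}" for i in range(m))
        else:
            self.labels = tuple(self.labels)

    @property
    def M(self) -> int:
        """Number of compartments after pooling C1a/C1b into C1."""
        return self.xi_in.shape[0] + 1

    @property
    def state_labels(self) -> tuple[str, ...]:
        return ("B", "C1a", "C1b") + self.labels


@dataclass
class GeneratorView:
    """Transition-rate view of a validated model.

    ``Q`` is the ``(n+1) x (n+1)`` generator over the ordered states
    (living states then the dead state): off-diagonal entries hold
    migration and death rates, the diagonal the negated exit rates, and
    the dead row is zero.  Division rates are carried separately in
    ``division`` because a division is a marked self-loop, not a change
    of state.
    """

    states: tuple[str, ...]
    Q: np.ndarray
    division: np.ndarray

    @property
    def n_living(self) -> int:
        return len(self.states) - 1

    @property
    def sub_generator(self) -> np.ndarray:
        """Generator restricted to living states (death drain on diagonal)."""
        n = self.n_living
        return self.Q[:n, :n]

    @property
    def death_rates(self) -> np.ndarray:
        """Per-living-state rate into the dead state."""
        return self.Q[: self.n_living, -1]


@dataclass
class FinitenessReport:
    """Verdict of the sufficient non-explosion conditions.

    ``per_compartment[i]`` holds iff ``xi_out[i] + mu[i] > lam[i]``
    (strictly): cells cannot pile up in compartment i.  ``global_ok``
    additionally requires the blood-hub balance
    ``sum(xi_in) + mu_B > lam_B + sum(xi_in * xi_out / (xi_out + mu - lam))``.
    Margins are the left-hand side minus the right-hand side, so a small
    positive margin flags near-criticality.
    """

    per_compartment: np.ndarray
    compartment_margins: np.ndarray
    global_ok: bool
    global_margin: float

    @property
    def ok(self) -> bool:
        return bool(self.global_ok and np.all(self.per_compartment))


def validate(model: StarModel | ExtendedModel) -> StarModel | ExtendedModel:
    """Check model invariants; return the model unchanged if they hold.

    Raises
    ------
    ModelValidationError
        Naming the offending field: negative or non-finite rate, length
        mismatch, duplicate label, an absorbing-in-life compartment
        (``xi_out + mu == 0``), or ``xi_C1a_C1b <= 0`` in the extended
        model (C1a would be a sink).
    """
    if isinstance(model, StarModel):
        scalars = {"mu_B": model.mu_B, "lam_B": model.lam_B}
        vectors = {"xi_in": model.xi_in, "xi_out": model.xi_out,
                   "mu": model.mu, "lam": model.lam}
        labels = model.labels
    elif isinstance(model, ExtendedModel):
        scalars = {
            "mu_B": model.mu_B, "lam_B": model.lam_B,
            "xi_B_C1a": model.xi_B_C1a, "xi_B_C1b": model.xi_B_C1b,
            "xi_C1a_C1b": model.xi_C1a_C1b, "xi_C1b_B": model.xi_C1b_B,
            "mu_C1a": model.mu_C1a, "lam_C1a": model.lam_C1a,
            "mu_C1b": model.mu_C1b, "lam_C1b": model.lam_C1b,
        }
        vectors = {"xi_in": model.xi_in, "xi_out": model.xi_out,
                   "mu": model.mu, "lam": model.lam}
        labels = ("C1a", "C1b") + model.labels
    else:  # pragma: no cover - defensive
        raise TypeError(f"unsupported model type {type(model)!r}")

    for name, value in scalars.items():
        if not np.isfinite(value) or value < 0:
            raise ModelValidationError(f"{name} must be a finite rate >= 0, got {value}")
    for name, vec in vectors.items():
        if not np.all(np.isfinite(vec)) or np.any(vec < 0):
            raise ModelValidationError(f"{name} must contain finite rates >= 0, got {vec}")
    if len(set(labels)) != len(labels) or "B" in labels:
        raise ModelValidationError(f"labels must be unique and distinct from 'B': {labels}")

    if isinstance(model, StarModel):
        dead_end = model.xi_out + model.mu <= 0
        if np.any(dead_end):
            i = int(np.argmax(dead_end))
            raise ModelValidationError(
                f"compartment {model.labels[i]} has xi_out + mu == 0 "
                "(absorbing-in-life compartment)"
            )
    else:
        if model.xi_C1a_C1b <= 0:
            raise ModelValidationError(
                "xi_C1a_C1b must be > 0 (C1a has no edge to blood and would be a sink)"
            )
        if model.xi_C1b_B + model.mu_C1b <= 0:
            raise ModelValidationError("compartment C1b has xi_C1b_B + mu == 0")
        dead_end = model.xi_out + model.mu <= 0
        if np.any(dead_end):
            i = int(np.argmax(dead_end))
            raise ModelValidationError(
                f"compartment {model.labels[i]} has xi_out + mu == 0"
            )
    return model


def check_finiteness(model: StarModel) -> FinitenessReport:
    """Evaluate the sufficient conditions for an almost-surely finite genealogy.

    The inequalities are evaluated strictly, exactly as floating-point
    comparisons; the returned margins let callers detect near-critical
    parameter sets.  When some compartment fails its local condition the
    blood-hub balance involves a non-positive denominator and the global
    condition is reported as failed with margin ``-inf``.
    """
    validate(model)
    denom = model.xi_out + model.mu - model.lam
    margins = denom.copy()
    per_comp = denom > 0.0
    if np.all(per_comp):
        with np.errstate(divide="ignore"):
            drain = np.where(
                model.xi_in > 0, model.xi_in * model.xi_out / denom, 0.0
            )
        lhs = float(np.sum(model.xi_in) + model.mu_B)
        rhs = float(model.lam_B + np.sum(drain))
        global_margin = lhs - rhs
        global_ok = lhs > rhs
    else:
        global_margin = -np.inf
        global_ok = False
    return FinitenessReport(per_comp, margins, global_ok, global_margin)


def critical_death_rate(model: StarModel, i: int) -> float:
    """Death rate in compartment ``i`` at which the genealogy turns infinite.

    Holding every other rate fixed, returns the value of ``mu[i]`` at
    which the non-explosion conditions become equalities; below it the
    mean genealogy size diverges.  Returns 0.0 when the conditions hold
    for every ``mu[i] >= 0`` (the boundary is at a negative rate).
    """
    validate(model)
    denom = model.xi_out + model.mu - model.lam
    others = [k for k in range(model.M) if k != i]
    crit1 = model.lam[i] - model.xi_out[i]
    for k in others:
        if denom[k] <= 0:
            # another compartment already violates its local condition;
            # no choice of mu[i] can restore finiteness
            return np.inf
    # blood-hub balance solved for mu[i]
    C = model.mu_B + np.sum(model.xi_in) - model.lam_B - sum(
        model.xi_in[k] * model.xi_out[k] / denom[k] for k in others
    )
    if C <= 0:
        return np.inf
    if model.xi_in[i] > 0:
        crit2 = model.lam[i] - model.xi_out[i] + model.xi_in[i] * model.xi_out[i] / C
    else:
        crit2 = crit1
    return float(max(crit1, crit2, 0.0))


def merge_split_compartment(model: ExtendedModel) -> StarModel:
    """Pool the split pair ``(C1a, C1b)`` into an effective compartment C1.

    The effective entry rate is the total rate of leaving the blood for
    either sub-compartment, ``xi_B_C1 = xi_B_C1a + xi_B_C1b``.  The
    effective return rate is the reciprocal of the mean time for a cell in
    C1 to reach the blood, averaged over where it entered::

        1/xi_C1_B = P(entered C1a) * (1/xi_C1a_C1b + 1/xi_C1b_B)
                  + P(entered C1b) * (1/xi_C1b_B)

    with ``P(entered C1a) = xi_B_C1a / (xi_B_C1a + xi_B_C1b)``.  Only
    migration is merged: the pooled C1 death/division rates are copied
    from the pair when C1a and C1b share them, otherwise this raises.
    """
    validate(model)
    if model.mu_C1a != model.mu_C1b or model.lam_C1a != model.lam_C1b:
        raise ModelValidationError(
            "cannot merge split compartment: C1a and C1b have different "
            "death/division rates (only migration is merged)"
        )
    xi_B_C1 = model.xi_B_C1a + model.xi_B_C1b
    if xi_B_C1 > 0:
        w_a = model.xi_B_C1a / xi_B_C1
        w_b = model.xi_B_C1b / xi_B_C1
        mean_return = (
            w_a * (1.0 / model.xi_C1a_C1b + 1.0 / model.xi_C1b_B)
            + w_b * (1.0 / model.xi_C1b_B)
        )
        xi_C1_B = 1.0 / mean_return
    else:
        # nothing ever enters the pair; any entrant through C1b leaves at
        # the C1b -> B rate
        xi_C1_B = model.xi_C1b_B
    merged = StarModel(
        xi_in=np.concatenate([[xi_B_C1], model.xi_in]),
        xi_out=np.concatenate([[xi_C1_B], model.xi_out]),
        mu=np.concatenate([[model.mu_C1a], model.mu]),
        lam=np.concatenate([[model.lam_C1a], model.lam]),
        mu_B=model.mu_B,
        lam_B=model.lam_B,
        labels=("C1",) + model.labels,
    )
    return validate(merged)


def build_generator(model: StarModel | ExtendedModel) -> GeneratorView:
    """Assemble the transition-rate table used by solvers and the simulator."""
    validate(model)
    if isinstance(model, StarModel):
        M = model.M
        n = M + 1
        Q = np.zeros((n + 1, n + 1))
        Q[0, 1 : n] = model.xi_in
        Q[1 : n, 0] = model.xi_out
        Q[0, -1] = model.mu_B
        Q[1 : n, -1] = model.mu
        division = np.concatenate([[model.lam_B], model.lam])
    else:
        m = model.xi_in.shape[0]  # compartments C2..CM
        n = m + 3  # B, C1a, C1b, C2..CM
        Q = np.zeros((n + 1, n + 1))
        Q[0, 1] = model.xi_B_C1a
        Q[0, 2] = model.xi_B_C1b
        Q[1, 2] = model.xi_C1a_C1b
        Q[2, 0] = model.xi_C1b_B
        Q[0, 3 : n] = model.xi_in
        Q[3 : n, 0] = model.xi_out
        Q[0, -1] = model.mu_B
        Q[1, -1] = model.mu_C1a
        Q[2, -1] = model.mu_C1b
        Q[3 : n, -1] = model.mu
        division = np.concatenate(
            [[model.lam_B, model.lam_C1a, model.lam_C1b], model.lam]
        )
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q[:n].sum(axis=1)
    states = model.state_labels + ("dead",)
    return GeneratorView(states=states, Q=Q, division=division)
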