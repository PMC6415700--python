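"""Exact stochastic simulation of the single-cell process and its genealogy.

Two exact single-cell samplers are provided:

* ``naive`` -- the textbook Gillespie loop: exponential waiting time at
  the state's total event rate, event chosen proportionally to rates,
  every migration recorded.
* ``skip`` -- an exact jump-skipping sampler for the star topology.
  Migration is minutes-scale while division/death are weeks-scale, so a
  naive loop spends almost all its work on migration events.  Because
  every excursion from the blood visits exactly one compartment and
  returns, the number of completed excursions between two *marked*
  events (division or death) is geometric, the excursion destinations
  are multinomial, and the total elapsed time is a sum of per-state
  gamma variables.  Sampling those sufficient statistics directly is
  distributionally identical to the naive loop but costs O(1) random
  draws per marked event instead of O(thousands).

Randomness: one master integer seed per estimator call; replicate ``k``
uses the ``k``-th child of ``numpy.random.SeedSequence(seed)``, so any
replicate can be reproduced in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import AbsorptionError
from .models import ExtendedModel, StarModel, build_generator, validate

__all__ = [
    "CellPath",
    "Cell",
    "GenealogyRecord",
    "SimulationSummary",
    "simulate_cell",
    "simulate_genealogy",
    "estimate_descriptors",
    "write_event_log",
]


@dataclass
class CellPath:
    """Ordered event log of one tracked cell.

    ``events[k]`` is one of ``{"migrate", "divide", "die"}`` and
    ``locations[k]`` the compartment where the event happens (for a
    migration, the destination).  In ``skip`` mode migration events are
    aggregated away and only marked events appear.  ``terminal`` is False
    when the event cap was hit before death (``censored``).
    """

    start: str
    birth_time: float
    times: np.ndarray
    events: list[str]
    locations: list[str]
    terminal: bool

    @property
    def censored(self) -> bool:
        return not self.terminal

    @property
    def lifetime(self) -> float:
        """Time from birth to death, minutes (nan when censored)."""
        if not self.terminal:
            return np.nan
        return float(self.times[-1] - self.birth_time)

    @property
    def n_divisions(self) -> int:
        return sum(1 for e in self.events if e == "divide")

    @property
    def death_location(self) -> str | None:
        return self.locations[-1] if self.terminal else None

    def divisions_by_location(self, labels: tuple[str, ...]) -> np.ndarray:
        counts = np.zeros(len(labels))
        index = {lab: i for i, lab in enumerate(labels)}
        for e, loc in zip(self.events, self.locations):
            if e == "divide":
                counts[index[loc]] += 1
        return counts

    def division_records(self) -> list[tuple[float, str]]:
        """(time, location) of each division event."""
        return [
            (float(t), loc)
            for t, e, loc in zip(self.times, self.events, self.locations)
            if e == "divide"
        ]


@dataclass
class Cell:
    cell_id: int
    parent_id: int
    birth_time: float
    path: CellPath


@dataclass
class GenealogyRecord:
    """One simulated branching realization rooted at a founder cell."""

    cells: list[Cell]
    censored: bool

    @property
    def n_divisions(self) -> int:
        return sum(c.path.n_divisions for c in self.cells)

    @property
    def genealogy_count(self) -> int:
        """Progeny count: 2 cells per division event, founder excluded."""
        return 2 * self.n_divisions

    @property
    def extinction_time(self) -> float:
        """Time of the last death (nan when censored)."""
        if self.censored:
            return np.nan
        return max(float(c.path.times[-1]) for c in self.cells)


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _SkipTables:
    """Precomputed quantities for the star-topology jump-skipping sampler."""

    def __init__(self, model: StarModel):
        self.labels = model.state_labels
        M = model.M
        self.lam = np.concatenate([[model.lam_B], model.lam])
        self.mu = np.concatenate([[model.mu_B], model.mu])
        self.r_B = float(np.sum(model.xi_in) + model.mu_B + model.lam_B)
        self.r_C = model.xi_out + model.mu + model.lam
        if self.r_B <= 0:
            raise AbsorptionError("blood state has zero total event rate")
        self.q_C = (model.mu + model.lam) / self.r_C
        q_B = (model.mu_B + model.lam_B) / self.r_B
        mig = model.xi_in / self.r_B
        absorb_C = mig * self.q_C           # next marked event is in Ci
        self.a = mig * (1.0 - self.q_C)     # completed excursion to Ci
        self.p_abs = float(q_B + np.sum(absorb_C))
        if self.p_abs <= 0:
            raise AbsorptionError(
                "no division or death rate is positive: no marked event "
                "can ever occur"
            )
        self.abs_cum = np.cumsum(np.concatenate([[q_B], absorb_C]))
        a_sum = float(np.sum(self.a))
        self.a_norm = self.a / a_sum if a_sum > 0 else self.a
        self.scales = np.concatenate([[1.0 / self.r_B], 1.0 / self.r_C])
        self.M = M

    def marked_from_blood(self, rng: np.random.Generator) -> tuple[float, int]:
        """Sample (elapsed time, state of next marked event) from B."""
        N = int(rng.geometric(self.p_abs)) - 1  # completed excursions
        shapes = np.zeros(self.M + 1)
        shapes[0] = N + 1  # blood sojourns
        if N > 0:
            shapes[1:] = rng.multinomial(N, self.a_norm)
        u = rng.random() * self.p_abs
        j = int(np.searchsorted(self.abs_cum, u, side="right"))
        j = min(j, self.M)
        if j > 0:
            shapes[j] += 1  # final sojourn in the marked compartment
        elapsed = float(np.sum(rng.gamma(shapes) * self.scales))
        return elapsed, j

    def next_marked(
        self, state: int, rng: np.random.Generator
    ) -> tuple[float, int]:
        if state == 0:
            return self.marked_from_blood(rng)
        i = state - 1
        dt = rng.exponential(1.0 / self.r_C[i])
        if rng.random() < self.q_C[i]:
            return float(dt), state
        elapsed, j = self.marked_from_blood(rng)
        return float(dt + elapsed), j

    def marked_is_division(self, j: int, rng: np.random.Generator) -> bool:
        tot = self.lam[j] + self.mu[j]
        return rng.random() < self.lam[j] / tot


def _resolve_start(labels: tuple[str, ...], start) -> int:
    if isinstance(start, str):
        return labels.index(start)
    return int(start)


def _simulate_skip(
    model: StarModel,
    start: int,
    rng: np.random.Generator,
    max_events: int,
    birth_time: float = 0.0,
    tables: _SkipTables | None = None,
) -> CellPath:
    tab = tables if tables is not None else _SkipTables(model)
    state = start
    t = birth_time
    times: list[float] = []
    events: list[str] = []
    locations: list[str] = []
    terminal = False
    for _ in range(max_events):
        dt, j = tab.next_marked(state, rng)
        t += dt
        times.append(t)
        locations.append(tab.labels[j])
        if tab.marked_is_division(j, rng):
            events.append("divide")
            state = j
        else:
            events.append("die")
            terminal = True
            break
    return CellPath(
        start=tab.labels[start],
        birth_time=birth_time,
        times=np.array(times),
        events=events,
        locations=locations,
        terminal=terminal,
    )


class _NaiveTables:
    """Per-state event menu for the naive Gillespie loop (any topology)."""

    def __init__(self, model: StarModel | ExtendedModel):
        gen = build_generator(model)
        self.labels = gen.states[:-1]
        n = gen.n_living
        self.menu = []
        for i in range(n):
            rates, kinds, targets = [], [], []
            for j in range(n):
                if j != i and gen.Q[i, j] > 0:
                    rates.append(gen.Q[i, j])
                    kinds.append("migrate")
                    targets.append(j)
            if gen.division[i] > 0:
                rates.append(gen.division[i])
                kinds.append("divide")
                targets.append(i)
            if gen.death_rates[i] > 0:
                rates.append(gen.death_rates[i])
                kinds.append("die")
                targets.append(i)
            rates = np.array(rates)
            self.menu.append(
                (np.cumsum(rates), float(np.sum(rates)), kinds, targets)
            )


def _simulate_naive(
    model: StarModel | ExtendedModel,
    start: int,
    rng: np.random.Generator,
    max_events: int,
    birth_time: float = 0.0,
    tables: _NaiveTables | None = None,
) -> CellPath:
    tab = tables if tables is not None else _NaiveTables(model)
    state = start
    t = birth_time
    times: list[float] = []
    events: list[str] = []
    locations: list[str] = []
    terminal = False
    for _ in range(max_events):
        cum, total, kinds, targets = tab.menu[state]
        if total <= 0:
            raise AbsorptionError(
                f"state {tab.labels[state]} has zero total event rate"
            )
        t += rng.exponential(1.0 / total)
        k = int(np.searchsorted(cum, rng.random() * total, side="right"))
        k = min(k, len(kinds) - 1)
        kind, target = kinds[k], targets[k]
        times.append(t)
        events.append(kind)
        locations.append(tab.labels[target])
        if kind == "migrate":
            state = target
        elif kind == "die":
            terminal = True
            break
    return CellPath(
        start=tab.labels[start],
        birth_time=birth_time,
        times=np.array(times),
        events=events,
        locations=locations,
        terminal=terminal,
    )


def simulate_cell(
    model: StarModel | ExtendedModel,
    start: int | str = 0,
    seed=None,
    mode: str = "auto",
    max_events: int = 1_000_000,
) -> CellPath:
    """Simulate one tracked cell from birth to death.

    ``mode`` is ``"naive"`` (every migration recorded; works for both
    topologies), ``"skip"`` (marked events only; star topology), or
    ``"auto"`` (skip for :class:`StarModel`, naive otherwise).  The event
    cap counts recorded events; a capped path is returned censored, not
    raised.  Division leaves the tracked cell in place (mother identity
    persists).
    """
    validate(model)
    rng = _coerce_rng(seed)
    labels = model.state_labels
    idx = _resolve_start(labels, start)
    if mode == "auto":
        mode = "skip" if isinstance(model, StarModel) else "naive"
    if mode == "skip":
        if not isinstance(model, StarModel):
            raise ValueError("jump-skipping mode requires the star topology")
        return _simulate_skip(model, idx, rng, max_events)
    if mode == "naive":
        return _simulate_naive(model, idx, rng, max_events)
    raise ValueError(f"unknown mode {mode!r}")


def simulate_genealogy(
    model: StarModel | ExtendedModel,
    start: int | str = 0,
    seed=None,
    mode: str = "auto",
    max_events: int = 1_000_000,
    max_cells: int = 100_000,
) -> GenealogyRecord:
    """Simulate the full branching genealogy founded by one cell.

    Daughters spawn at the mother's division location and time and evolve
    independently under identical rules.  The realization is censored
    (partial record, ``censored=True``) when the total number of recorded
    events exceeds ``max_events`` or the tree exceeds ``max_cells`` cells;
    supercritical models therefore cannot hang.
    """
    validate(model)
    rng = _coerce_rng(seed)
    labels = model.state_labels
    idx = _resolve_start(labels, start)
    if mode == "auto":
        mode = "skip" if isinstance(model, StarModel) else "naive"
    if mode == "skip":
        if not isinstance(model, StarModel):
            raise ValueError("jump-skipping mode requires the star topology")
        tables = _SkipTables(model)
        sim = lambda s, bt, budget: _simulate_skip(
            model, s, rng, budget, bt, tables)
    else:
        tables = _NaiveTables(model)
        sim = lambda s, bt, budget: _simulate_naive(
            model, s, rng, budget, bt, tables)

    cells: list[Cell] = []
    censored = False
    events_left = max_events
    # FIFO over (parent_id, birth_time, state); founder has parent -1
    queue: list[tuple[int, float, int]] = [(-1, 0.0, idx)]
    while queue:
        if len(cells) >= max_cells:
            censored = True
            break
        parent_id, birth_time, state = queue.pop(0)
        if events_left <= 0:
            censored = True
            break
        path = sim(state, birth_time, events_left)
        events_left -= len(path.events)
        if path.censored:
            censored = True
        cell_id = len(cells)
        cells.append(Cell(cell_id, parent_id, birth_time, path))
        for t_div, loc in path.division_records():
            queue.append((cell_id, t_div, labels.index(loc)))
    if queue:
        censored = True
    return GenealogyRecord(cells=cells, censored=censored)


@dataclass
class SimulationSummary:
    """Monte-Carlo estimates with standard errors (sample SD / sqrt(n))."""

    labels: tuple[str, ...]
    start: str
    master_seed: int | None
    n_reps: int
    n_censored: int
    genealogy_reps: int
    genealogy_censored: int
    estimates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def mean(self, key: str) -> float:
        return self.estimates[key][0]

    def se(self, key: str) -> float:
        return self.estimates[key][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, v[0], v[1]) for k, v in self.estimates.items()
        ]
        df = pd.DataFrame(rows, columns=["statistic", "mean", "se"])
        df["start"] = self.start
        df["method"] = "simulated"
        return df

    def to_json_dict(self) -> dict:
        return {
            "start": self.start,
            "master_seed": self.master_seed,
            "n_reps": self.n_reps,
            "n_censored": self.n_censored,
            "genealogy_reps": self.genealogy_reps,
            "genealogy_censored": self.genealogy_censored,
            "estimates": {
                k: {"mean": v[0], "se": v[1]}
                for k, v in self.estimates.items()
            },
        }


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    n = x.size
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return m, se


def estimate_descriptors(
    model: StarModel | ExtendedModel,
    start: int | str = 0,
    n_reps: int = 10_000,
    seed: int = 0,
    genealogy_reps: int = 0,
    mode: str = "auto",
    max_events: int = 1_000_000,
    max_cells: int = 100_000,
) -> SimulationSummary:
    """Monte-Carlo estimates of the single-cell descriptors.

    Runs ``n_reps`` single-cell replicates (lifetime, division counts by
    location, death location) and optionally ``genealogy_reps`` branching
    replicates (progeny count).  Censored replicates are excluded from the
    means and reported in the counts.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    validate(model)
    labels = model.state_labels
    idx = _resolve_start(labels, start)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_reps + genealogy_reps)

    lifetimes, divisions = [], []
    div_by_loc, death_loc = [], []
    n_censored = 0
    for k in range(n_reps):
        rng = np.random.default_rng(children[k])
        path = simulate_cell(model, idx, rng, mode=mode, max_events=max_events)
        if path.censored:
            n_censored += 1
            continue
        lifetimes.append(path.lifetime)
        divisions.append(path.n_divisions)
        div_by_loc.append(path.divisions_by_location(labels))
        onehot = np.zeros(len(labels))
        onehot[labels.index(path.death_location)] = 1.0
        death_loc.append(onehot)
    if not lifetimes:
        raise RuntimeError(
            f"all {n_reps} replicates were censored at max_events={max_events}"
        )

    est: dict[str, tuple[float, float]] = {}
    est["mean_lifetime"] = _mean_se(np.array(lifetimes))
    est["mean_divisions"] = _mean_se(np.array(divisions, dtype=float))
    div_by_loc = np.array(div_by_loc)
    death_loc = np.array(death_loc)
    for j, lab in enumerate(labels):
        est[f"mean_divisions[{lab}]"] = _mean_se(div_by_loc[:, j])
        est[f"death_probability[{lab}]"] = _mean_se(death_loc[:, j])

    gen_censored = 0
    if genealogy_reps:
        counts = []
        for k in range(genealogy_reps):
            rng = np.random.default_rng(children[n_reps + k])
            rec = simulate_genealogy(
                model, idx, rng, mode=mode,
                max_events=max_events, max_cells=max_cells,
            )
            if rec.censored:
                gen_censored += 1
                continue
            counts.append(rec.genealogy_count)
        if counts:
            est["mean_genealogy_size"] = _mean_se(
                np.array(counts, dtype=float))
        else:
            raise RuntimeError(
                f"all {genealogy_reps} genealogy replicates were censored "
                f"(max_events={max_events}, max_cells={max_cells})"
            )

    return SimulationSummary(
        labels=labels,
        start=labels[idx],
        master_seed=seed,
        n_reps=n_reps,
        n_censored=n_censored,
        genealogy_reps=genealogy_reps,
        genealogy_censored=gen_censored,
        estimates=est,
    )


def write_event_log(record: GenealogyRecord, path: str | Path) -> None:
    """Write a genealogy's event log as tidy CSV."""
    rows = []
    for cell in record.cells:
        for t, e, loc in zip(cell.path.times, cell.path.events,
                             cell.path.locations):
            rows.append((cell.cell_id, cell.parent_id, t, e, loc))
    pd.DataFrame(
        rows, columns=["cell_id", "parent_id", "time_min", "event",
                       "location"]
    ).to_csv(path, index=False)
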