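"""Multi-population demographic models: definition, validation, canonical form.

A :class:`DemographicModel` describes, backwards in time, the sizes, exponential
growth rates and migration rates of a set of populations, together with a list
of timed events (size/growth changes, migration-rate changes, and instantaneous
lineage moves encoding population splits and admixture pulses).

Conventions, fixed once and used everywhere:

* Time is measured in generations before present; ``t = 0`` is sampling time
  and time increases into the past.
* Sizes are diploid effective sizes; the pairwise coalescence rate within a
  deme of size ``N`` is ``1 / (2 N)`` per generation.
* ``migration_matrix[i][j]`` is the backwards-time rate at which a lineage
  currently in population ``i`` traces its ancestry to population ``j``
  (equivalently, the forwards-time fraction of ``i`` replaced each generation
  by migrants from ``j``).  Diagonal entries are zero.
* Growth rate ``alpha`` is the backwards decay exponent: within an epoch that
  starts at ``t0`` with size ``N0``, the size at time ``t >= t0`` is
  ``N0 * exp(-alpha * (t - t0))`` (a population with ``alpha > 0`` is smaller
  in the past).
* Events listed at identical times are applied in listed order.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "PopulationDef",
    "Citation",
    "SizeGrowthChange",
    "MigrationChange",
    "LineageMove",
    "DemographicEvent",
    "EpochState",
    "CanonicalForm",
    "EqualityReport",
    "DemographicModel",
    "validate_model",
    "canonicalize",
    "models_equal",
    "generic_piecewise_constant",
    "generic_im",
    "state_at_time",
    "ModelValidationError",
]

ALL = None  # sentinel: event applies to all populations

DEFAULT_REL_TOL = 1e-6


class ModelValidationError(ValueError):
    """Raised when an operation requires a valid model and validation fails."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid demographic model:\n" + "\n".join(self.violations))


@dataclass
class PopulationDef:
    """A named population.

    Parameters
    ----------
    id:
        Short unique label (e.g. ``"pop0"``, ``"YRI"``).
    description:
        Free-text description.
    sampling_time:
        Default sampling time for this population, in generations before
        present (0 for contemporary samples).
    """

    id: str
    description: str = ""
    sampling_time: float = 0.0


@dataclass
class Citation:
    """A citation attached to a model, map or engine (DOI or free string)."""

    doi: str
    role: str = "model"  # model | genetic-map | engine


@dataclass
class SizeGrowthChange:
    """At ``time``, set size and/or growth rate of one population (or all).

    ``population=None`` applies to every population.  An unset field retains
    the value in force; a set ``new_size`` is the size at exactly ``time``.
    """

    time: float
    population: Optional[int] = ALL
    new_size: Optional[float] = None
    new_growth_rate: Optional[float] = None


@dataclass
class MigrationChange:
    """At ``time``, set ``m[source][dest]`` (``None`` = all in that slot)."""

    time: float
    source: Optional[int] = ALL
    dest: Optional[int] = ALL
    new_rate: float = 0.0


@dataclass
class LineageMove:
    """At ``time``, each lineage in ``source`` moves to ``dest`` with
    probability ``proportion`` (backwards-time mass migration).

    ``proportion = 1`` encodes a population split (looking forwards: ``source``
    was founded from ``dest``); smaller proportions encode admixture pulses.
    """

    time: float
    source: int = 0
    dest: int = 0
    proportion: float = 1.0


DemographicEvent = Union[SizeGrowthChange, MigrationChange, LineageMove]


@dataclass
class EpochState:
    """Dynamics in force over ``[t_start, t_end)`` (canonical decomposition).

    ``start_sizes`` are the per-population sizes at ``t_start``; within the
    epoch sizes follow ``N_i(t) = start_sizes[i] * exp(-growth_rates[i] *
    (t - t_start))``.  ``t_end`` is ``inf`` for the terminal epoch.
    """

    t_start: float
    t_end: float
    start_sizes: np.ndarray
    growth_rates: np.ndarray
    migration_matrix: np.ndarray

    def size_at(self, t: float) -> np.ndarray:
        """Per-population sizes at time ``t`` (must satisfy t_start <= t)."""
        dt = t - self.t_start
        return self.start_sizes * np.exp(-self.growth_rates * dt)


@dataclass
class CanonicalForm:
    """Epochs tiling ``[0, inf)`` plus the instantaneous lineage-move schedule."""

    num_populations: int
    epochs: List[EpochState]
    lineage_moves: List[LineageMove]

    def epoch_at(self, t: float) -> EpochState:
        for ep in self.epochs:
            if ep.t_start <= t < ep.t_end:
                return ep
        return self.epochs[-1]


@dataclass
class EqualityReport:
    """Result of :func:`models_equal`; ``equal`` iff ``differences`` empty."""

    equal: bool
    differences: List[Tuple[Tuple[float, float], str, object, object]] = field(
        default_factory=list
    )


@dataclass
class DemographicModel:
    """A complete multi-population demographic model."""

    id: str
    description: str = ""
    populations: List[PopulationDef] = field(default_factory=list)
    initial_sizes: List[float] = field(default_factory=list)
    initial_growth_rates: List[float] = field(default_factory=list)
    migration_matrix: List[List[float]] = field(default_factory=list)
    events: List[DemographicEvent] = field(default_factory=list)
    generation_time: float = 1.0
    citations: List[Citation] = field(default_factory=list)

    @property
    def num_populations(self) -> int:
        return len(self.populations)

    def validate(self) -> List[str]:
        return validate_model(self)

    def copy(self) -> "DemographicModel":
        return copy.deepcopy(self)


def _check_pop_index(idx, P, allow_all, where, violations):
    if idx is ALL:
        if not allow_all:
            violations.append(f"{where}: population index may not be 'all'")
        return
    if not isinstance(idx, (int, np.integer)) or isinstance(idx, bool):
        violations.append(f"{where}: population index {idx!r} is not an integer")
    elif not (0 <= idx < P):
        violations.append(f"{where}: population index {idx} out of range [0, {P})")


def validate_model(model: DemographicModel) -> List[str]:
    """Check every structural invariant; return a list of violation strings.

    An empty list means the model is well formed.  Violations are returned,
    never raised, so callers can collect them for user-facing reports.
    """
    v: List[str] = []
    P = model.num_populations
    if P == 0:
        v.append("model has no populations")
    ids = [p.id for p in model.populations]
    if len(set(ids)) != len(ids):
        v.append(f"population ids not unique: {ids}")
    for k, p in enumerate(model.populations):
        if not p.id:
            v.append(f"populations[{k}].id is empty")
        if p.sampling_time < 0:
            v.append(f"populations[{k}].sampling_time is negative")
    if len(model.initial_sizes) != P:
        v.append(f"initial_sizes has length {len(model.initial_sizes)}, expected {P}")
    for k, s in enumerate(model.initial_sizes):
        if not (s > 0) or not math.isfinite(s):
            v.append(f"initial_sizes[{k}] = {s} must be positive and finite")
    if len(model.initial_growth_rates) != P:
        v.append(
            f"initial_growth_rates has length {len(model.initial_growth_rates)}, "
            f"expected {P}"
        )
    M = model.migration_matrix
    if len(M) != P or any(len(row) != P for row in M):
        v.append(f"migration_matrix is not {P}x{P}")
    else:
        for i in range(P):
            for j in range(P):
                if i == j and M[i][j] != 0:
                    v.append(f"migration_matrix[{i}][{i}] = {M[i][j]} must be 0")
                if M[i][j] < 0:
                    v.append(f"migration_matrix[{i}][{j}] = {M[i][j]} is negative")
    for k, ev in enumerate(model.events):
        where = f"events[{k}]"
        if not (ev.time >= 0 and math.isfinite(ev.time)):
            v.append(f"{where}.time = {ev.time} must be finite and >= 0")
        if isinstance(ev, SizeGrowthChange):
            _check_pop_index(ev.population, P, True, where, v)
            if ev.new_size is None and ev.new_growth_rate is None:
                v.append(f"{where}: neither new_size nor new_growth_rate set")
            if ev.new_size is not None and not ev.new_size > 0:
                v.append(f"{where}.new_size = {ev.new_size} must be positive")
        elif isinstance(ev, MigrationChange):
            _check_pop_index(ev.source, P, True, where + ".source", v)
            _check_pop_index(ev.dest, P, True, where + ".dest", v)
            if ev.new_rate < 0:
                v.append(f"{where}.new_rate = {ev.new_rate} is negative")
        elif isinstance(ev, LineageMove):
            _check_pop_index(ev.source, P, False, where + ".source", v)
            _check_pop_index(ev.dest, P, False, where + ".dest", v)
            if isinstance(ev.source, int) and isinstance(ev.dest, int):
                if 0 <= ev.source < P and ev.source == ev.dest:
                    v.append(f"{where}: source and dest are both {ev.source}")
            if not (0.0 <= ev.proportion <= 1.0):
                v.append(f"{where}.proportion = {ev.proportion} not in [0, 1]")
        else:
            v.append(f"{where}: unknown event type {type(ev).__name__}")
    return v


def _require_valid(model: DemographicModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)


def _pop_indices(idx, P):
    return range(P) if idx is ALL else [idx]


def canonicalize(model: Union[DemographicModel, CanonicalForm]) -> CanonicalForm:
    """Decompose a model into epochs of constant dynamics plus lineage moves.

    Epochs tile ``[0, inf)``.  A new epoch starts only where the dynamics
    actually change, so syntactically different event lists with the same
    semantics yield identical canonical forms (redundant or no-op events
    collapse).  Events at equal times are applied in listed order.  A
    ``CanonicalForm`` input is returned as a deep copy (idempotence).
    """
    if isinstance(model, CanonicalForm):
        return copy.deepcopy(model)
    _require_valid(model)
    P = model.num_populations
    events = sorted(enumerate(model.events), key=lambda kv: kv[1].time)
    sizes = np.asarray(model.initial_sizes, dtype=float).copy()
    growth = np.asarray(model.initial_growth_rates, dtype=float).copy()
    mig = np.asarray(model.migration_matrix, dtype=float).copy()
    epochs: List[EpochState] = []
    moves: List[LineageMove] = []
    cur = EpochState(0.0, math.inf, sizes, growth, mig)

    i = 0
    n = len(events)
    while i < n:
        t = events[i][1].time
        group = []
        while i < n and events[i][1].time == t:
            group.append(events[i][1])
            i += 1
        evolved = cur.size_at(t)
        new_sizes = evolved.copy()
        new_growth = cur.growth_rates.copy()
        new_mig = cur.migration_matrix.copy()
        for ev in group:
            if isinstance(ev, SizeGrowthChange):
                for p in _pop_indices(ev.population, P):
                    if ev.new_size is not None:
                        new_sizes[p] = ev.new_size
                    if ev.new_growth_rate is not None:
                        new_growth[p] = ev.new_growth_rate
            elif isinstance(ev, MigrationChange):
                for s in _pop_indices(ev.source, P):
                    for d in _pop_indices(ev.dest, P):
                        if s != d:
                            new_mig[s, d] = ev.new_rate
            elif isinstance(ev, LineageMove):
                if ev.proportion > 0:
                    moves.append(
                        LineageMove(t, int(ev.source), int(ev.dest), float(ev.proportion))
                    )
        changed = (
            not np.array_equal(new_sizes, evolved)
            or not np.array_equal(new_growth, cur.growth_rates)
            or not np.array_equal(new_mig, cur.migration_matrix)
        )
        if changed and t > cur.t_start:
            epochs.append(
                EpochState(
                    cur.t_start, t, cur.start_sizes, cur.growth_rates, cur.migration_matrix
                )
            )
            cur = EpochState(t, math.inf, new_sizes, new_growth, new_mig)
        elif changed:  # change exactly at the current epoch's start (incl. t=0)
            cur = EpochState(cur.t_start, math.inf, new_sizes, new_growth, new_mig)
    epochs.append(cur)
    return CanonicalForm(P, epochs, moves)


def _close(a: float, b: float, rel_tol: float) -> bool:
    if a == b:
        return True
    if math.isinf(a) or math.isinf(b):
        return a == b
    return abs(a - b) <= rel_tol * max(abs(a), abs(b))


def models_equal(
    a: DemographicModel,
    b: DemographicModel,
    rel_tol: float = DEFAULT_REL_TOL,
) -> EqualityReport:
    """Semantic model equality via canonical forms.

    Sizes, growth rates, migration rates and epoch boundaries are compared at
    relative tolerance ``rel_tol`` (default ``1e-6``, tighter than any
    published parameter precision); the population count and the lineage-move
    schedule must match structurally.  Differences are reported as
    ``(epoch interval, field path, value_a, value_b)`` tuples, the report the
    independent-reimplementation QC workflow consumes.
    """
    diffs: List[Tuple[Tuple[float, float], str, object, object]] = []
    if a.num_populations != b.num_populations:
        diffs.append(
            (
                (0.0, math.inf),
                "num_populations",
                a.num_populations,
                b.num_populations,
            )
        )
        return EqualityReport(False, diffs)
    ca, cb = canonicalize(a), canonicalize(b)
    P = ca.num_populations
    if len(ca.epochs) != len(cb.epochs):
        diffs.append(
            ((0.0, math.inf), "num_epochs", len(ca.epochs), len(cb.epochs))
        )
    for ea, eb in zip(ca.epochs, cb.epochs):
        interval = (ea.t_start, ea.t_end)
        if not _close(ea.t_start, eb.t_start, rel_tol):
            diffs.append((interval, "epoch.t_start", ea.t_start, eb.t_start))
        if not _close(ea.t_end, eb.t_end, rel_tol):
            diffs.append((interval, "epoch.t_end", ea.t_end, eb.t_end))
        for p in range(P):
            if not _close(ea.start_sizes[p], eb.start_sizes[p], rel_tol):
                diffs.append(
                    (interval, f"sizes[{p}]", ea.start_sizes[p], eb.start_sizes[p])
                )
            if not _close(ea.growth_rates[p], eb.growth_rates[p], rel_tol):
                diffs.append(
                    (
                        interval,
                        f"growth_rates[{p}]",
                        ea.growth_rates[p],
                        eb.growth_rates[p],
                    )
                )
        for i in range(P):
            for j in range(P):
                if not _close(
                    ea.migration_matrix[i, j], eb.migration_matrix[i, j], rel_tol
                ):
                    diffs.append(
                        (
                            interval,
                            f"migration_matrix[{i}][{j}]",
                            ea.migration_matrix[i, j],
                            eb.migration_matrix[i, j],
                        )
                    )
    if len(ca.lineage_moves) != len(cb.lineage_moves):
        diffs.append(
            (
                (0.0, math.inf),
                "num_lineage_moves",
                len(ca.lineage_moves),
                len(cb.lineage_moves),
            )
        )
    else:
        for k, (ma, mb) in enumerate(zip(ca.lineage_moves, cb.lineage_moves)):
            interval = (ma.time, ma.time)
            if not _close(ma.time, mb.time, rel_tol):
                diffs.append((interval, f"lineage_moves[{k}].time", ma.time, mb.time))
            if ma.source != mb.source:
                diffs.append(
                    (interval, f"lineage_moves[{k}].source", ma.source, mb.source)
                )
            if ma.dest != mb.dest:
                diffs.append((interval, f"lineage_moves[{k}].dest", ma.dest, mb.dest))
            if not _close(ma.proportion, mb.proportion, rel_tol):
                diffs.append(
                    (
                        interval,
                        f"lineage_moves[{k}].proportion",
                        ma.proportion,
                        mb.proportion,
                    )
                )
    return EqualityReport(len(diffs) == 0, diffs)


def generic_piecewise_constant(
    sizes: Sequence[float],
    change_times: Sequence[float] = (),
    *,
    id: str = "GenericPiecewiseConstant",
    generation_time: float = 1.0,
) -> DemographicModel:
    """Single-population piecewise-constant size model.

    Size is ``sizes[0]`` on ``[0, change_times[0])``, ``sizes[k]`` on the
    k-th interval thereafter.  ``len(sizes)`` must equal
    ``len(change_times) + 1`` and change times must be strictly increasing
    and positive.
    """
    sizes = list(sizes)
    change_times = list(change_times)
    if len(sizes) != len(change_times) + 1:
        raise ValueError(
            f"need len(sizes) == len(change_times)+1, got {len(sizes)} and "
            f"{len(change_times)}"
        )
    if any(t2 <= t1 for t1, t2 in zip(change_times, change_times[1:])):
        raise ValueError(f"change_times must be strictly increasing: {change_times}")
    if change_times and change_times[0] <= 0:
        raise ValueError("change_times must be > 0")
    if any(not s > 0 for s in sizes):
        raise ValueError(f"sizes must be positive: {sizes}")
    events: List[DemographicEvent] = [
        SizeGrowthChange(time=t, population=0, new_size=s, new_growth_rate=0.0)
        for t, s in zip(change_times, sizes[1:])
    ]
    return DemographicModel(
        id=id,
        description=(
            "Generic single-population piecewise-constant size model "
            f"({len(sizes)} epoch(s))"
        ),
        populations=[PopulationDef("pop0", "single focal population")],
        initial_sizes=[float(sizes[0])],
        initial_growth_rates=[0.0],
        migration_matrix=[[0.0]],
        events=events,
        generation_time=generation_time,
    )


def generic_im(
    N_anc: float,
    N1: float,
    N2: float,
    T_div: float,
    m12: float,
    m21: float,
    *,
    id: str = "GenericIM",
    generation_time: float = 1.0,
) -> DemographicModel:
    """Generic two-population isolation-with-migration model.

    Six parameters: ancestral size ``N_anc``, post-split sizes ``N1``/``N2``,
    divergence time ``T_div`` (generations), and backwards migration rates
    ``m12`` (lineages in pop0 tracing to pop1) and ``m21``.  At ``T_div``
    all pop1 lineages move to pop0, migration is switched off and pop0 takes
    the ancestral size.
    """
    for name, val in (("N_anc", N_anc), ("N1", N1), ("N2", N2), ("T_div", T_div)):
        if not val > 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    if m12 < 0 or m21 < 0:
        raise ValueError(f"migration rates must be >= 0, got {m12}, {m21}")
    events: List[DemographicEvent] = [
        LineageMove(time=T_div, source=1, dest=0, proportion=1.0),
        SizeGrowthChange(time=T_div, population=0, new_size=N_anc, new_growth_rate=0.0),
        MigrationChange(time=T_div, source=ALL, dest=ALL, new_rate=0.0),
    ]
    return DemographicModel(
        id=id,
        description="Generic two-population isolation-with-migration model",
        populations=[
            PopulationDef("pop0", "first descendant population"),
            PopulationDef("pop1", "second descendant population"),
        ],
        initial_sizes=[float(N1), float(N2)],
        initial_growth_rates=[0.0, 0.0],
        migration_matrix=[[0.0, float(m12)], [float(m21), 0.0]],
        events=events,
        generation_time=generation_time,
    )


def state_at_time(model: Union[DemographicModel, CanonicalForm], t: float) -> EpochState:
    """Epoch containing ``t``, with sizes evolved to exactly ``t``.

    The returned :class:`EpochState` has ``t_start = t`` and the per-population
    sizes ``N_i(t)`` under the containing epoch's growth rates.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    canon = canonicalize(model)
    ep = canon.epoch_at(t)
    return EpochState(
        t_start=float(t),
        t_end=ep.t_end,
        start_sizes=ep.size_at(t),
        growth_rates=ep.growth_rates.copy(),
        migration_matrix=ep.migration_matrix.copy(),
    )


def model_from_canonical(
    canon: CanonicalForm,
    *,
    id: str = "FromCanonical",
    generation_time: float = 1.0,
) -> DemographicModel:
    """Reconstruct a plain model whose canonical form equals ``canon``."""
    first = canon.epochs[0]
    events: List[DemographicEvent] = []
    boundary_events = {}
    for ep in canon.epochs[1:]:
        boundary_events[ep.t_start] = ep
    all_times = sorted(
        set(boundary_events) | {m.time for m in canon.lineage_moves}
    )
    moves_by_time: dict = {}
    for m in canon.lineage_moves:
        moves_by_time.setdefault(m.time, []).append(m)
    for t in all_times:
        for m in moves_by_time.get(t, []):
            events.append(LineageMove(t, m.source, m.dest, m.proportion))
        if t in boundary_events:
            ep = boundary_events[t]
            for p in range(canon.num_populations):
                events.append(
                    SizeGrowthChange(
                        time=t,
                        population=p,
                        new_size=float(ep.start_sizes[p]),
                        new_growth_rate=float(ep.growth_rates[p]),
                    )
                )
            for i in range(canon.num_populations):
                for j in range(canon.num_populations):
                    if i != j:
                        events.append(
                            MigrationChange(t, i, j, float(ep.migration_matrix[i, j]))
                        )
    P = canon.num_populations
    return DemographicModel(
        id=id,
        populations=[PopulationDef(f"pop{i}") for i in range(P)],
        initial_sizes=[float(s) for s in first.start_sizes],
        initial_growth_rates=[float(g) for g in first.growth_rates],
        migration_matrix=[[float(x) for x in row] for row in first.migration_matrix],
        events=events,
        generation_time=generation_time,
    )
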