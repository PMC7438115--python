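"""Analytic pairwise coalescence-rate curves and their empirical counterpart.

For two lineages sampled from given populations, the instantaneous pairwise
coalescence rate is

    lambda(t) = [ sum_i p_ii(t) / (2 N_i(t)) ] / P(T > t),

where ``p_ij(t)`` is the probability that the two (not yet coalesced)
lineages sit in populations ``i`` and ``j`` at time ``t``.  The pair-state
master equation is integrated through the model's canonical epochs: migration
moves one lineage at a time between pair states, coalescence drains the
same-deme states, and lineage-move events apply their relocation to each
lineage independently.  The inverse rate ``1 / (2 lambda(t))`` is the
effective-population-size proxy commonly read off from sequence-based
size-history inference, and serves as the benchmark "truth" curve when
judging such inference against simulations.

Curves are left-continuous step evaluations on the user's time grid, matching
the hazard-estimate binning of :func:`empirical_rate_from_tmrcas`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm
from scipy.stats import binom

from .demography import CanonicalForm, DemographicModel, canonicalize, state_at_time

__all__ = [
    "CoalRateCurve",
    "pairwise_coalescence_rate",
    "empirical_rate_from_tmrcas",
    "true_size_curve",
    "hazard_band_check",
]

_ODE_TOL = 1e-10


@dataclass
class CoalRateCurve:
    """Coalescence-rate curve on a time grid.

    ``survival[k] = P(T > times[k])``; ``rate`` is the instantaneous pairwise
    coalescence hazard; ``inverse_size = 1/(2*rate)`` (infinite where the
    rate is zero, NaN where undefined).
    """

    times: np.ndarray
    survival: np.ndarray
    rate: np.ndarray
    inverse_size: np.ndarray

    def to_tsv(self) -> str:
        lines = ["time\tsurvival\trate\tinverse_size"]
        for k in range(len(self.times)):
            lines.append(
                f"{self.times[k]:.10g}\t{self.survival[k]:.10g}\t"
                f"{self.rate[k]:.10g}\t{self.inverse_size[k]:.10g}"
            )
        return "\n".join(lines) + "\n"


def _pair_states(P: int) -> List[Tuple[int, int]]:
    return [(i, j) for i in range(P) for j in range(i, P)]


def _state_index(P: int):
    states = _pair_states(P)
    idx = {s: k for k, s in enumerate(states)}

    def at(i, j):
        return idx[(min(i, j), max(i, j))]

    return states, at


def _migration_generator(P: int, mig: np.ndarray) -> np.ndarray:
    """Generator (rows = from-state) of the migration part of the pair chain."""
    states, at = _state_index(P)
    S = len(states)
    A = np.zeros((S, S))
    for k, (i, j) in enumerate(states):
        if i == j:
            for d in range(P):
                if d != i and mig[i, d] > 0:
                    A[k, at(i, d)] += 2.0 * mig[i, d]
        else:
            for d in range(P):
                if d != i and mig[i, d] > 0:
                    A[k, at(d, j)] += mig[i, d]
                if d != j and mig[j, d] > 0:
                    A[k, at(i, d)] += mig[j, d]
    A -= np.diag(A.sum(axis=1))
    return A


def _coal_rates_vec(P: int, sizes: np.ndarray) -> np.ndarray:
    """Per-state coalescence rate: 1/(2 N_i) in state {i,i}, else 0."""
    states, _ = _state_index(P)
    out = np.zeros(len(states))
    for k, (i, j) in enumerate(states):
        if i == j:
            out[k] = 1.0 / (2.0 * sizes[i])
    return out


def _apply_lineage_move(P: int, p: np.ndarray, source: int, dest: int, prop: float) -> np.ndarray:
    """Each lineage in ``source`` relocates to ``dest`` independently w.p. prop."""
    states, at = _state_index(P)
    out = np.zeros_like(p)

    def dist(pop):  # distribution of one lineage's location after the move
        if pop == source:
            return [(dest, prop), (source, 1.0 - prop)]
        return [(pop, 1.0)]

    for k, (i, j) in enumerate(states):
        if p[k] == 0:
            continue
        for (ni, wi) in dist(i):
            for (nj, wj) in dist(j):
                w = wi * wj
                if w > 0:
                    out[at(ni, nj)] += p[k] * w
    return out


def pairwise_coalescence_rate(
    model: Union[DemographicModel, CanonicalForm],
    popA: int,
    popB: int,
    time_grid: np.ndarray,
) -> CoalRateCurve:
    """Analytic coalescence-rate curve for one lineage from each population.

    ``time_grid`` must be increasing and start at (or after) the lineages'
    sampling time (contemporary samples: 0).  Zero-growth epochs are advanced
    by matrix exponentials (exact); growth epochs by adaptive ODE stepping at
    tolerance 1e-10.
    """
    canon = canonicalize(model)
    P = canon.num_populations
    for p in (popA, popB):
        if not (0 <= p < P):
            raise ValueError(f"population index {p} out of range")
    grid = np.asarray(time_grid, dtype=float)
    if len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("time_grid must be non-empty and strictly increasing")
    if grid[0] < 0:
        raise ValueError("time_grid starts before the sampling time")

    states, at = _state_index(P)
    S = len(states)
    p_vec = np.zeros(S)
    p_vec[at(popA, popB)] = 1.0

    surv_out = np.empty(len(grid))
    rate_out = np.empty(len(grid))

    t = grid[0]
    gi = 0
    epoch_iter = [ep for ep in canon.epochs if ep.t_end > t]
    moves = [m for m in canon.lineage_moves if m.time >= t]

    def record_until(t_stop, advance):
        """Record grid points in [t, t_stop) using ``advance(dt) -> p_vec``."""
        nonlocal gi, p_vec, t
        while gi < len(grid) and grid[gi] < t_stop:
            tg = grid[gi]
            if tg > t:
                p_vec = advance(tg - t)
                t = tg
            ep = canon.epoch_at(t)
            sizes = ep.size_at(t)
            crate = _coal_rates_vec(P, sizes)
            surv = float(p_vec.sum())
            surv_out[gi] = surv
            rate_out[gi] = float(crate @ p_vec) / surv if surv > 0 else math.nan
            gi += 1
        if t < t_stop and not math.isinf(t_stop):
            p_vec = advance(t_stop - t)
            t = t_stop

    mi = 0
    for ep in epoch_iter:
        if gi >= len(grid):
            break
        # break the epoch at lineage-move times inside it
        stops = []
        while mi < len(moves) and moves[mi].time < ep.t_end:
            stops.append(moves[mi])
            mi += 1
        boundaries = [m.time for m in stops] + [ep.t_end]
        si = 0
        growth = np.asarray(ep.growth_rates, dtype=float)
        zero_growth = np.all(growth == 0.0)
        Amig = _migration_generator(P, np.asarray(ep.migration_matrix, dtype=float))

        for si, stop_t in enumerate(boundaries):
            if zero_growth:
                Q = Amig - np.diag(_coal_rates_vec(P, ep.start_sizes))

                def advance(dt, Q=Q):
                    return expm(Q.T * dt) @ p_vec

            else:

                def advance(dt, ep=ep, Amig=Amig):
                    t0 = t

                    def rhs(tt, y):
                        sizes = ep.size_at(tt)
                        c = _coal_rates_vec(P, sizes)
                        return Amig.T @ y - c * y

                    sol = solve_ivp(
                        rhs,
                        (t0, t0 + dt),
                        p_vec,
                        rtol=_ODE_TOL,
                        atol=_ODE_TOL,
                        method="DOP853",
                    )
                    return sol.y[:, -1]

            record_until(stop_t, advance)
            if si < len(stops):
                mv = stops[si]
                p_vec = _apply_lineage_move(P, p_vec, mv.source, mv.dest, mv.proportion)
        if gi >= len(grid) and ep.t_end > grid[-1]:
            break

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(rate_out > 0, 1.0 / (2.0 * rate_out), math.inf)
    inv = np.where(np.isnan(rate_out), math.nan, inv)
    return CoalRateCurve(grid, surv_out, rate_out, inv)


def empirical_rate_from_tmrcas(
    tmrcas: np.ndarray, time_grid: np.ndarray
) -> CoalRateCurve:
    """Nelson-Aalen-style hazard estimate from Monte-Carlo TMRCA draws.

    For each grid interval ``[t_k, t_{k+1})``, the rate is ``events /
    (at-risk x width)`` with the at-risk count taken at ``t_k``; the curve is
    reported at the interval left edges.  Bins with zero at-risk mass are
    reported as NaN.  Requires at least 100 draws.
    """
    tmrcas = np.sort(np.asarray(tmrcas, dtype=float))
    if len(tmrcas) < 100:
        raise ValueError("need at least 100 TMRCA draws")
    grid = np.asarray(time_grid, dtype=float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("time_grid must have >= 2 strictly increasing points")
    n = len(tmrcas)
    times = grid[:-1]
    surv = np.empty(len(times))
    rate = np.empty(len(times))
    for k in range(len(times)):
        lo, hi = grid[k], grid[k + 1]
        at_risk = n - np.searchsorted(tmrcas, lo, side="left")
        events = np.searchsorted(tmrcas, hi, side="left") - np.searchsorted(
            tmrcas, lo, side="left"
        )
        surv[k] = at_risk / n
        if at_risk == 0:
            rate[k] = math.nan
        else:
            rate[k] = events / (at_risk * (hi - lo))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(rate > 0, 1.0 / (2.0 * rate), math.inf)
    inv = np.where(np.isnan(rate), math.nan, inv)
    return CoalRateCurve(times, surv, rate, inv)


def true_size_curve(
    model: Union[DemographicModel, CanonicalForm], time_grid: np.ndarray
) -> np.ndarray:
    """Per-population census sizes ``N_i(t)`` on the grid (no coalescent
    semantics) — the alternative truth used for multi-population fits.

    Returns an array of shape ``(len(grid), num_populations)``.
    """
    canon = canonicalize(model)
    grid = np.asarray(time_grid, dtype=float)
    out = np.empty((len(grid), canon.num_populations))
    for k, t in enumerate(grid):
        out[k] = state_at_time(canon, float(t)).start_sizes
    return out


def hazard_band_check(
    tmrcas: np.ndarray,
    model: Union[DemographicModel, CanonicalForm],
    popA: int,
    popB: int,
    time_grid: np.ndarray,
    conf: float = 0.99,
    min_survival: float = 0.05,
) -> dict:
    """Pointwise consistency of Monte-Carlo TMRCAs with the analytic curve.

    For each grid bin where the analytic survival exceeds ``min_survival``,
    the observed event count is compared with its exact binomial ``conf``
    band given the bin's at-risk count and the analytic conditional
    coalescence probability.  Returns a dict with the per-bin z-like scores,
    the bins checked, and the number outside the band.
    """
    tmrcas = np.sort(np.asarray(tmrcas, dtype=float))
    grid = np.asarray(time_grid, dtype=float)
    fine = pairwise_coalescence_rate(model, popA, popB, grid)
    n = len(tmrcas)
    checked, failures, details = 0, 0, []
    for k in range(len(grid) - 1):
        lo, hi = grid[k], grid[k + 1]
        s_lo, s_hi = fine.survival[k], fine.survival[k + 1]
        if s_lo <= min_survival or s_lo <= 0:
            continue
        q = 1.0 - s_hi / s_lo  # analytic P(coalesce in bin | alive at lo)
        at_risk = n - np.searchsorted(tmrcas, lo, side="left")
        events = int(
            np.searchsorted(tmrcas, hi, side="left")
            - np.searchsorted(tmrcas, lo, side="left")
        )
        if at_risk == 0:
            continue
        lo_b, hi_b = binom.interval(conf, at_risk, q)
        ok = lo_b <= events <= hi_b
        checked += 1
        failures += 0 if ok else 1
        details.append(
            {
                "t": float(lo),
                "at_risk": int(at_risk),
                "events": events,
                "expected": float(at_risk * q),
                "band": (float(lo_b), float(hi_b)),
                "ok": bool(ok),
            }
        )
    return {"checked": checked, "failures": failures, "bins": details}
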