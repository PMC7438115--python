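"""Backwards-time structured coalescent simulator with recombination.

The engine implements Hudson-style ancestry tracking: each extant lineage
carries a sorted list of disjoint ancestral-material segments, each mapped to
a node in the output tables and annotated with the number of sample genomes
that descend from it.  Event rates per generation:

* pairwise coalescence within population ``i`` at rate ``1 / (2 N_i(t))``
  per pair,
* lineage migration ``i -> j`` at rate ``m[i][j]`` per lineage,
* recombination per lineage at rate equal to the genetic length (expected
  crossovers per generation) of the span between its first and last carried
  material.

Within growth epochs the coalescence waiting time is drawn exactly by
inverting the integrated hazard (no time discretization).  Lineage-move
events relocate each lineage in the source population independently with the
event's proportion.  Coalescing lineages whose material does not overlap
merge without creating a node; segments whose descendant count reaches the
full sample size are fully coalesced and dropped.  All randomness flows from
one seeded generator, so output tables are reproducible byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .demography import CanonicalForm, DemographicModel, canonicalize
from .genmap import RecombinationMap, flat_map
from .tables import Tables

__all__ = [
    "SampleSpec",
    "Contig",
    "simulate_ancestry",
    "drop_mutations",
    "genotype_matrix",
    "export_vcf",
    "pairwise_tmrca_replicates",
    "NonTerminationError",
]

DEFAULT_MAX_EVENTS = 10_000_000


class NonTerminationError(RuntimeError):
    """The simulation cannot (or is suspected not to) reach a common ancestor."""


@dataclass
class SampleSpec:
    """Haploid sample counts per population.

    ``entries`` is a list of ``(population index, haploid count, sampling
    time in generations)`` tuples.
    """

    entries: List[Tuple[int, int, float]]

    @classmethod
    def simple(cls, counts: Sequence[int]) -> "SampleSpec":
        """Contemporary samples: ``counts[i]`` haploids from population ``i``."""
        return cls([(i, int(n), 0.0) for i, n in enumerate(counts) if n > 0])

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.entries)

    def validate(self, num_populations: int) -> None:
        for pop, n, time in self.entries:
            if not (0 <= pop < num_populations):
                raise ValueError(f"sample population {pop} out of range")
            if n < 0:
                raise ValueError("sample counts must be >= 0")
            if time < 0:
                raise ValueError("sampling times must be >= 0")
        if self.total < 2:
            raise ValueError("need at least 2 haploid samples in total")


@dataclass
class Contig:
    """A simulated chromosome: length, recombination map, mutation rate."""

    length: float
    recombination_map: Optional[RecombinationMap] = None
    mutation_rate: float = 0.0

    def __post_init__(self):
        if self.recombination_map is None:
            self.recombination_map = flat_map(self.length, 0.0)
        if self.recombination_map.sequence_length != self.length:
            raise ValueError("recombination map does not span the contig")
        if self.mutation_rate < 0:
            raise ValueError("mutation_rate must be >= 0")


# A segment: (left, right, node, n_descendant_samples)
Seg = Tuple[float, float, int, int]


@dataclass
class _Lineage:
    population: int
    segments: List[Seg]


def _merge_lineages(
    a: _Lineage, b: _Lineage, t: float, pop: int, tables: Tables, n_total: int
) -> _Lineage:
    """Coalesce two lineages at time ``t``; returns the merged lineage."""
    pts = sorted({p for s in a.segments for p in (s[0], s[1])}
                 | {p for s in b.segments for p in (s[0], s[1])})
    out: List[Seg] = []
    new_node = -1
    ia = ib = 0

    def covering(segs, idx, l):
        while idx < len(segs) and segs[idx][1] <= l:
            idx += 1
        if idx < len(segs) and segs[idx][0] <= l:
            return segs[idx], idx
        return None, idx

    for l, r in zip(pts, pts[1:]):
        sa, ia = covering(a.segments, ia, l)
        sb, ib = covering(b.segments, ib, l)
        if sa is not None and sb is not None:
            if new_node < 0:
                new_node = tables.add_node(t, pop)
            tables.add_edge(l, r, new_node, sa[2])
            tables.add_edge(l, r, new_node, sb[2])
            ns = sa[3] + sb[3]
            if ns < n_total:
                out.append((l, r, new_node, ns))
        elif sa is not None:
            out.append((l, r, sa[2], sa[3]))
        elif sb is not None:
            out.append((l, r, sb[2], sb[3]))
    # squash contiguous pieces of the same node/count
    squashed: List[Seg] = []
    for seg in out:
        if (
            squashed
            and squashed[-1][2] == seg[2]
            and squashed[-1][3] == seg[3]
            and squashed[-1][1] == seg[0]
        ):
            prev = squashed[-1]
            squashed[-1] = (prev[0], seg[1], prev[2], prev[3])
        else:
            squashed.append(seg)
    return _Lineage(pop, squashed)


def _draw_coal_time(rng, rate0: float, alpha: float) -> float:
    """Waiting time for hazard ``rate0 * exp(alpha * tau)`` via inversion."""
    if rate0 <= 0:
        return math.inf
    e = rng.exponential()
    if alpha == 0.0:
        return e / rate0
    arg = 1.0 + alpha * e / rate0
    if arg <= 0:
        return math.inf  # hazard decays too fast: no event in this epoch
    return math.log(arg) / alpha


def simulate_ancestry(
    model: DemographicModel,
    samples: SampleSpec,
    contig: Contig,
    seed: int,
    max_events: int = DEFAULT_MAX_EVENTS,
) -> Tables:
    """Simulate the ancestry of ``samples`` on ``contig`` under ``model``.

    Returns fully coalesced node/edge :class:`Tables` (no sites/mutations;
    see :func:`drop_mutations`).  Node times are in generations; sample nodes
    come first, in sample-spec order.  Deterministic given
    ``(model, samples, contig, seed)``.
    """
    canon = canonicalize(model)
    samples.validate(canon.num_populations)
    rng = np.random.default_rng(seed)
    L = contig.length
    gmap = contig.recombination_map
    tables = Tables(sequence_length=L)
    n_total = samples.total

    active: List[_Lineage] = []
    pending: List[Tuple[float, _Lineage]] = []
    for pop, count, s_time in samples.entries:
        for _ in range(count):
            node = tables.add_node(s_time, pop, is_sample=True)
            lin = _Lineage(pop, [(0.0, L, node, 1)])
            if s_time == 0.0:
                active.append(lin)
            else:
                pending.append((s_time, lin))
    pending.sort(key=lambda kv: kv[0])

    moves = canon.lineage_moves  # time-sorted in application order
    move_idx = 0
    epoch_idx = 0
    t = 0.0
    n_events = 0
    P = canon.num_populations

    def gspan(lin: _Lineage) -> float:
        if len(lin.segments) == 0:
            return 0.0
        lo = lin.segments[0][0]
        hi = lin.segments[-1][1]
        return float(gmap.genetic_position(hi) - gmap.genetic_position(lo))

    while active or pending:
        if not active or (len(active) == 1 and not pending):
            # lone lineage: jump to the next sample activation, if any
            if pending:
                t = pending[0][0]
                while pending and pending[0][0] <= t:
                    active.append(pending.pop(0)[1])
                continue
            break
        ep = canon.epochs[epoch_idx]
        while not (ep.t_start <= t < ep.t_end):
            epoch_idx += 1
            ep = canon.epochs[epoch_idx]
        # rates
        counts = [0] * P
        for lin in active:
            counts[lin.population] += 1
        mig_rate_pop = [counts[i] * float(ep.migration_matrix[i].sum()) for i in range(P)]
        mig_total = sum(mig_rate_pop)
        spans = [gspan(lin) for lin in active]
        rec_total = sum(spans)

        tau = math.inf
        kind = None
        which = -1
        if rec_total > 0:
            tau_r = rng.exponential() / rec_total
            if tau_r < tau:
                tau, kind = tau_r, "rec"
        if mig_total > 0:
            tau_m = rng.exponential() / mig_total
            if tau_m < tau:
                tau, kind = tau_m, "mig"
        for i in range(P):
            k = counts[i]
            if k >= 2:
                n_now = float(ep.start_sizes[i]) * math.exp(
                    -float(ep.growth_rates[i]) * (t - ep.t_start)
                )
                rate0 = k * (k - 1) / 2.0 / (2.0 * n_now)
                tau_c = _draw_coal_time(rng, rate0, float(ep.growth_rates[i]))
                if tau_c < tau:
                    tau, kind, which = tau_c, "coal", i

        t_block = ep.t_end
        if move_idx < len(moves):
            t_block = min(t_block, moves[move_idx].time)
        if pending:
            t_block = min(t_block, pending[0][0])

        if t + tau >= t_block:
            if math.isinf(t_block):
                raise NonTerminationError(
                    "lineages can never coalesce (disconnected populations "
                    "with no migration or merging event)"
                )
            t = t_block
            while move_idx < len(moves) and moves[move_idx].time <= t:
                mv = moves[move_idx]
                if mv.time == t:
                    for lin in active:
                        if lin.population == mv.source and (
                            mv.proportion >= 1.0 or rng.random() < mv.proportion
                        ):
                            lin.population = mv.dest
                move_idx += 1
            while pending and pending[0][0] <= t:
                active.append(pending.pop(0)[1])
            continue

        t += tau
        n_events += 1
        if n_events > max_events:
            raise NonTerminationError(
                f"event ceiling of {max_events} exceeded; the model may not "
                "allow all lineages to reach a common ancestor"
            )
        if kind == "rec":
            u = rng.random() * rec_total
            idx = 0
            acc = 0.0
            for idx, sp in enumerate(spans):
                acc += sp
                if u < acc:
                    break
            lin = active[idx]
            lo = lin.segments[0][0]
            hi = lin.segments[-1][1]
            g_lo = float(gmap.genetic_position(lo))
            g_hi = float(gmap.genetic_position(hi))
            g_break = g_lo + rng.random() * (g_hi - g_lo)
            x = float(gmap.physical_position(g_break))
            left_segs: List[Seg] = []
            right_segs: List[Seg] = []
            for seg in lin.segments:
                if seg[1] <= x:
                    left_segs.append(seg)
                elif seg[0] >= x:
                    right_segs.append(seg)
                else:
                    left_segs.append((seg[0], x, seg[2], seg[3]))
                    right_segs.append((x, seg[1], seg[2], seg[3]))
            if left_segs and right_segs:
                lin.segments = left_segs
                active.append(_Lineage(lin.population, right_segs))
            # else: breakpoint outside carried material (zero-rate flank) -> no-op
        elif kind == "mig":
            u = rng.random() * mig_total
            acc = 0.0
            src = 0
            for src in range(P):
                acc += mig_rate_pop[src]
                if u < acc:
                    break
            members = [lin for lin in active if lin.population == src]
            lin = members[int(rng.random() * len(members)) % len(members)]
            row = ep.migration_matrix[src]
            u2 = rng.random() * float(row.sum())
            acc2 = 0.0
            dest = 0
            for dest in range(P):
                acc2 += float(row[dest])
                if u2 < acc2:
                    break
            lin.population = dest
        else:  # coalescence in population `which`
            members = [j for j, lin in enumerate(active) if lin.population == which]
            i1 = members[int(rng.random() * len(members)) % len(members)]
            members.remove(i1)
            i2 = members[int(rng.random() * len(members)) % len(members)]
            a, b = active[i1], active[i2]
            merged = _merge_lineages(a, b, t, which, tables, n_total)
            for j in sorted((i1, i2), reverse=True):
                active.pop(j)
            if merged.segments:
                active.append(merged)

    tables.sort_and_squash_edges()
    return tables


def drop_mutations(tables: Tables, mutation_rate: float, seed: int) -> Tables:
    """Superimpose neutral infinite-sites mutations on an ancestry.

    On each edge, mutations arise as a Poisson process with intensity
    ``mutation_rate x bp span x branch length``; positions are uniform on the
    edge's interval, rounded to integer bp, with collisions redrawn.  Returns
    ``tables`` with its site/mutation columns replaced.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    used = set()
    muts: List[Tuple[int, int]] = []
    for k in range(tables.num_edges):
        l, r = tables.edge_left[k], tables.edge_right[k]
        branch = tables.node_time[tables.edge_parent[k]] - tables.node_time[
            tables.edge_child[k]
        ]
        n_mut = rng.poisson(mutation_rate * (r - l) * branch)
        for _ in range(n_mut):
            for _attempt in range(100):
                pos = int(l + rng.random() * (r - l))
                if pos not in used and pos < tables.sequence_length:
                    used.add(pos)
                    muts.append((pos, tables.edge_child[k]))
                    break
    muts.sort()
    tables.site_position = [p for p, _ in muts]
    tables.site_ancestral = ["A"] * len(muts)
    tables.mutation_site = list(range(len(muts)))
    tables.mutation_node = [n for _, n in muts]
    tables.mutation_derived = ["T"] * len(muts)
    return tables


def _parent_maps(tables: Tables):
    """Per-tree child->parent maps keyed by breakpoint interval."""
    bps = sorted({0.0, tables.sequence_length}
                 | set(tables.edge_left) | set(tables.edge_right))
    maps = []
    for l, r in zip(bps, bps[1:]):
        mid = 0.5 * (l + r)
        pm = {}
        for k in range(tables.num_edges):
            if tables.edge_left[k] <= mid < tables.edge_right[k]:
                pm[tables.edge_child[k]] = tables.edge_parent[k]
        maps.append((l, r, pm))
    return maps


def genotype_matrix(
    tables: Tables, sample_order: Optional[Sequence[int]] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Biallelic 0/1 matrix (sites x samples) plus integer positions.

    Entry ``[s, j]`` is 1 iff sample ``sample_order[j]`` descends from the
    mutation's node in the marginal tree at site ``s``.
    """
    if sample_order is None:
        sample_order = tables.samples()
    S = tables.num_sites
    G = np.zeros((S, len(sample_order)), dtype=np.int8)
    if S == 0:
        return G, np.array([], dtype=int)
    pmaps = _parent_maps(tables)
    lefts = [pm[0] for pm in pmaps]
    positions = np.asarray(tables.site_position, dtype=float)
    idx = np.clip(np.searchsorted(lefts, positions, side="right") - 1, 0, len(pmaps) - 1)
    for s in range(S):
        pm = pmaps[idx[s]][2]
        mut_node = tables.mutation_node[s]
        for j, samp in enumerate(sample_order):
            cur = samp
            while cur is not None:
                if cur == mut_node:
                    G[s, j] = 1
                    break
                cur = pm.get(cur)
    return G, np.asarray(tables.site_position, dtype=int)


def marginal_tree_count(tables: Tables) -> int:
    """Number of distinct marginal parent maps along the sequence."""
    pmaps = _parent_maps(tables)
    count = 1
    for (_, _, a), (_, _, b) in zip(pmaps, pmaps[1:]):
        if a != b:
            count += 1
    return count


def export_vcf(
    tables: Tables,
    sample_names: Optional[Sequence[str]] = None,
    ploidy: int = 2,
    contig_id: str = "1",
) -> str:
    """Render sites as minimal VCF 4.2 text (phased GT, 1-based positions)."""
    samples = tables.samples()
    if len(samples) % ploidy != 0:
        raise ValueError(
            f"{len(samples)} haploid samples cannot be grouped into "
            f"individuals of ploidy {ploidy}"
        )
    n_ind = len(samples) // ploidy
    if sample_names is None:
        sample_names = [f"ind{k}" for k in range(n_ind)]
    if len(sample_names) != n_ind:
        raise ValueError("sample_names length must equal individual count")
    G, positions = genotype_matrix(tables, samples)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=demesim",
        f"##contig=<ID={contig_id},length={int(tables.sequence_length)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_names),
    ]
    for s in range(tables.num_sites):
        gts = []
        for k in range(n_ind):
            alleles = G[s, k * ploidy : (k + 1) * ploidy]
            gts.append("|".join(str(int(a)) for a in alleles))
        ac = int(G[s].sum())
        lines.append(
            f"{contig_id}\t{int(positions[s]) + 1}\t.\t{tables.site_ancestral[s]}\t"
            f"{tables.mutation_derived[s]}\t.\tPASS\tAC={ac}\tGT\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


def pairwise_tmrca_replicates(
    model: DemographicModel,
    popA: int,
    popB: int,
    n_reps: int,
    seed: int,
    max_events_per_rep: int = 1_000_000,
) -> np.ndarray:
    """Monte-Carlo TMRCA draws for one lineage from ``popA`` and one from
    ``popB`` (both from ``popA`` if equal), at a single non-recombining locus.

    A specialized two-lineage walk over the canonical epochs — orders of
    magnitude faster than the full engine, used as the empirical counterpart
    of the analytic coalescence-rate curves.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    canon = canonicalize(model)
    P = canon.num_populations
    for p in (popA, popB):
        if not (0 <= p < P):
            raise ValueError(f"population index {p} out of range")
    rng = np.random.default_rng(seed)
    epochs = canon.epochs
    moves = canon.lineage_moves
    rowsums = [np.asarray(ep.migration_matrix, dtype=float).sum(axis=1) for ep in epochs]
    out = np.empty(n_reps)
    log = math.log
    for rep in range(n_reps):
        pa, pb = popA, popB
        t = 0.0
        ei = 0
        mi = 0
        n_ev = 0
        while True:
            ep = epochs[ei]
            while not (ep.t_start <= t < ep.t_end):
                ei += 1
                ep = epochs[ei]
            rs = rowsums[ei]
            mig_total = float(rs[pa] + rs[pb])
            tau = math.inf
            kind = 0  # 1 = coal, 2 = mig
            if pa == pb:
                alpha = float(ep.growth_rates[pa])
                n_now = float(ep.start_sizes[pa]) * math.exp(-alpha * (t - ep.t_start))
                rate0 = 1.0 / (2.0 * n_now)
                e = -log(1.0 - rng.random())
                if alpha == 0.0:
                    tau_c = e / rate0
                else:
                    arg = 1.0 + alpha * e / rate0
                    tau_c = log(arg) / alpha if arg > 0 else math.inf
                if tau_c < tau:
                    tau, kind = tau_c, 1
            if mig_total > 0:
                tau_m = -log(1.0 - rng.random()) / mig_total
                if tau_m < tau:
                    tau, kind = tau_m, 2
            t_block = ep.t_end
            if mi < len(moves):
                t_block = min(t_block, moves[mi].time)
            if t + tau >= t_block:
                if math.isinf(t_block):
                    raise NonTerminationError(
                        "pair of lineages can never coalesce under this model"
                    )
                t = t_block
                while mi < len(moves) and moves[mi].time <= t:
                    mv = moves[mi]
                    if mv.time == t:
                        if pa == mv.source and (
                            mv.proportion >= 1.0 or rng.random() < mv.proportion
                        ):
                            pa = mv.dest
                        if pb == mv.source and (
                            mv.proportion >= 1.0 or rng.random() < mv.proportion
                        ):
                            pb = mv.dest
                    mi += 1
                continue
            t += tau
            n_ev += 1
            if n_ev > max_events_per_rep:
                raise NonTerminationError("per-replicate event ceiling exceeded")
            if kind == 1:
                out[rep] = t
                break
            # migration: pick which lineage, then destination
            if rng.random() * mig_total < rs[pa]:
                row = np.asarray(epochs[ei].migration_matrix[pa], dtype=float)
                u = rng.random() * rs[pa]
                acc = 0.0
                for d in range(P):
                    acc += row[d]
                    if u < acc:
                        pa = d
                        break
            else:
                row = np.asarray(epochs[ei].migration_matrix[pb], dtype=float)
                u = rng.random() * rs[pb]
                acc = 0.0
                for d in range(P):
                    acc += row[d]
                    if u < acc:
                        pb = d
                        break
    return out
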