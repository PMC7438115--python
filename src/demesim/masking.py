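"""Low-recombination masking and BED-style interval handling.

Empirical size-history analyses routinely drop large genomic blocks where
recombination is so low that a single marginal genealogy dominates; the rule
implemented here masks maximal runs of map intervals whose rate falls in the
lowest tail (default: 5th percentile, length-weighted over bp) of the map's
rate distribution, keeping only runs that are "large" in the sense of
spanning at least ``min_cM`` centimorgans *at the chromosome's mean rate*
(a literal genetic-length criterion would never fire inside a
low-recombination run, so the size cut-off is expressed in physical length
converted at the mean rate; the rule is isolated here and configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np

from .genmap import RecombinationMap
from .tables import Tables

__all__ = ["MaskIntervals", "low_recombination_mask", "apply_mask"]


@dataclass
class MaskIntervals:
    """Sorted, disjoint, 0-based half-open bp intervals to exclude."""

    intervals: List[Tuple[float, float]]

    def __post_init__(self):
        self.intervals = _merge(self.intervals)

    @property
    def total_bp(self) -> float:
        return sum(r - l for l, r in self.intervals)

    def contains(self, pos: float) -> bool:
        for l, r in self.intervals:
            if l <= pos < r:
                return True
        return False

    def to_bed(self, chrom: str = "chr1") -> str:
        return "".join(f"{chrom}\t{int(l)}\t{int(r)}\n" for l, r in self.intervals)

    @classmethod
    def from_bed(cls, text: str) -> "MaskIntervals":
        ivals = []
        for ln in text.splitlines():
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split()
            ivals.append((float(parts[1]), float(parts[2])))
        return cls(ivals)


def _merge(intervals) -> List[Tuple[float, float]]:
    ivals = sorted((float(l), float(r)) for l, r in intervals if r > l)
    out: List[Tuple[float, float]] = []
    for l, r in ivals:
        if out and l <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], r))
        else:
            out.append((l, r))
    return out


def weighted_rate_percentile(gmap: RecombinationMap, percentile: float) -> float:
    """Length-weighted percentile of the map's per-bp rate distribution."""
    lengths = np.diff(gmap.positions)
    order = np.argsort(gmap.rates, kind="stable")
    rates = gmap.rates[order]
    w = lengths[order]
    cum = np.cumsum(w) / w.sum()
    idx = int(np.searchsorted(cum, percentile / 100.0, side="left"))
    idx = min(idx, len(rates) - 1)
    return float(rates[idx])


def low_recombination_mask(
    gmap: RecombinationMap,
    percentile: float = 5.0,
    min_cM: float = 1.0,
) -> MaskIntervals:
    """Mask large low-recombination blocks of a genetic map.

    The threshold is the length-weighted ``percentile`` of the map's
    interval rates; maximal runs of intervals with rate *strictly below* the
    threshold are merged, and a run is kept iff its physical length converted
    at the chromosome's mean rate reaches ``min_cM`` centimorgans.  A uniform
    map therefore masks nothing, and ``percentile=0`` masks nothing.
    """
    if len(gmap.rates) == 0:
        return MaskIntervals([])
    threshold = weighted_rate_percentile(gmap, percentile)
    mean_rate = gmap.mean_rate()
    min_bp = (min_cM / 100.0) / mean_rate if mean_rate > 0 else np.inf
    out = []
    run_start = None
    for k in range(len(gmap.rates)):
        low = gmap.rates[k] < threshold
        if low and run_start is None:
            run_start = gmap.positions[k]
        if (not low or k == len(gmap.rates) - 1) and run_start is not None:
            run_end = gmap.positions[k] if not low else gmap.positions[k + 1]
            if run_end - run_start >= min_bp:
                out.append((run_start, run_end))
            run_start = None
    return MaskIntervals(out)


def apply_mask(
    obj: Union[Tables, Tuple[np.ndarray, np.ndarray]],
    mask: MaskIntervals,
    sequence_length: float = None,
):
    """Remove sites inside ``mask``; return the filtered object and the
    retained (accessible) span in bp.

    ``obj`` may be :class:`Tables` (filtered copy of the site/mutation
    columns, in place) or a ``(genotype matrix, positions)`` pair.
    Overlapping mask intervals are normalized by merging; applying a mask
    twice is a no-op.
    """
    if isinstance(obj, Tables):
        L = obj.sequence_length
        keep = [
            i for i, pos in enumerate(obj.site_position) if not mask.contains(pos)
        ]
        remap = {old: new for new, old in enumerate(keep)}
        obj.site_position = [obj.site_position[i] for i in keep]
        obj.site_ancestral = [obj.site_ancestral[i] for i in keep]
        mut_keep = [k for k, s in enumerate(obj.mutation_site) if s in remap]
        obj.mutation_site = [remap[obj.mutation_site[k]] for k in mut_keep]
        obj.mutation_node = [obj.mutation_node[k] for k in mut_keep]
        obj.mutation_derived = [obj.mutation_derived[k] for k in mut_keep]
        retained = L - min(mask.total_bp, L)
        return obj, retained
    G, positions = obj
    if sequence_length is None:
        raise ValueError("sequence_length required when masking a matrix")
    positions = np.asarray(positions)
    keep = np.array([not mask.contains(p) for p in positions], dtype=bool)
    retained = sequence_length - min(mask.total_bp, sequence_length)
    return (G[keep], positions[keep]), retained
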