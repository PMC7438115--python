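"""Site-based summary statistics: SFS, joint SFS, diversity, LD decay."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["sfs", "joint_sfs", "fold_sfs", "nucleotide_diversity", "ld_decay"]


def _check_binary(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional (sites x samples)")
    if G.size and not np.isin(G, (0, 1)).all():
        raise ValueError("genotype matrix must contain only 0/1 entries")
    return G


def sfs(G: np.ndarray) -> np.ndarray:
    """Unfolded site frequency spectrum ``xi_1 .. xi_{n-1}``.

    ``G`` is a biallelic 0/1 matrix (sites x n haploid samples).  Entry
    ``i-1`` counts sites whose derived allele is carried by exactly ``i``
    samples; fixed and absent classes are excluded, so the vector sums to the
    number of segregating sites.
    """
    G = _check_binary(G)
    n = G.shape[1]
    counts = G.sum(axis=1)
    out = np.zeros(n - 1, dtype=int)
    for i in range(1, n):
        out[i - 1] = int((counts == i).sum())
    return out


def fold_sfs(xi: np.ndarray) -> np.ndarray:
    """Fold an unfolded SFS: minor-allele classes ``eta_i = xi_i + xi_{n-i}``."""
    xi = np.asarray(xi)
    n = len(xi) + 1
    out = np.zeros(n // 2, dtype=xi.dtype)
    for i in range(1, n // 2 + 1):
        if i == n - i:
            out[i - 1] = xi[i - 1]
        else:
            out[i - 1] = xi[i - 1] + xi[n - i - 1]
    return out


def joint_sfs(G: np.ndarray, partition: Sequence[int]) -> np.ndarray:
    """Two-population joint SFS: ``(n1+1) x (n2+1)`` matrix of site counts.

    ``partition[j]`` is 0 or 1, assigning sample column ``j`` to a
    population.  Cell ``(d1, d2)`` counts sites with derived count ``d1`` in
    population 0 and ``d2`` in population 1; the monomorphic corners remain
    in the matrix but are excluded from segregating-site totals by
    construction of the input (every site in ``G`` is segregating overall).
    """
    G = _check_binary(G)
    partition = np.asarray(partition)
    if len(partition) != G.shape[1]:
        raise ValueError("partition length must equal the sample count")
    cols0 = partition == 0
    cols1 = partition == 1
    n1, n2 = int(cols0.sum()), int(cols1.sum())
    out = np.zeros((n1 + 1, n2 + 1), dtype=int)
    d1 = G[:, cols0].sum(axis=1)
    d2 = G[:, cols1].sum(axis=1)
    for a, b in zip(d1, d2):
        out[a, b] += 1
    return out


def nucleotide_diversity(G: np.ndarray, span: float) -> float:
    """Per-site nucleotide diversity pi over an accessible span of ``span`` bp.

    Average number of pairwise differences per accessible base:
    ``pi = sum_s 2 d_s (n - d_s) / (n (n-1)) / span``.
    """
    if not span > 0:
        raise ValueError(f"accessible span must be > 0, got {span}")
    G = _check_binary(G)
    if G.shape[0] == 0:
        return 0.0
    n = G.shape[1]
    d = G.sum(axis=1).astype(float)
    return float((2.0 * d * (n - d) / (n * (n - 1))).sum() / span)


def ld_decay(
    G: np.ndarray,
    positions: np.ndarray,
    bins: Sequence[float],
    min_minor_count: int = 2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean r-squared between site pairs, binned by physical distance.

    ``bins`` are distance-bin edges in bp.  Sites whose minor-allele count is
    below ``min_minor_count`` (default: singletons) are excluded, the
    field-standard filter; monomorphic pairs are skipped.  Returns
    ``(mean r2 per bin, pair count per bin)``.
    """
    G = _check_binary(G).astype(float)
    positions = np.asarray(positions, dtype=float)
    bins = np.asarray(bins, dtype=float)
    if G.shape[0] != len(positions):
        raise ValueError("positions length must equal the site count")
    n = G.shape[1]
    d = G.sum(axis=1)
    keep = (np.minimum(d, n - d) >= min_minor_count) & (d > 0) & (d < n)
    G = G[keep]
    positions = positions[keep]
    S = G.shape[0]
    sums = np.zeros(len(bins) - 1)
    counts = np.zeros(len(bins) - 1, dtype=int)
    if S < 2:
        return np.full(len(bins) - 1, np.nan), counts
    Gc = G - G.mean(axis=1, keepdims=True)
    norms = np.sqrt((Gc ** 2).sum(axis=1))
    for a in range(S - 1):
        dist = positions[a + 1 :] - positions[a]
        which = np.searchsorted(bins, dist, side="right") - 1
        valid = (which >= 0) & (which < len(bins) - 1)
        if not valid.any():
            continue
        denom = norms[a] * norms[a + 1 :]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Gc[a + 1 :] @ Gc[a]) / denom
        r2 = r ** 2
        for b, v, ok in zip(which, r2, valid & (denom > 0)):
            if ok:
                sums[b] += v
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts
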