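"""Recombination maps: piecewise-constant per-bp crossover rates.

Coordinates are 0-based half-open base pairs.  Rates are expected crossovers
per bp per generation (Morgans/bp); the field's conventional unit conversion
``1 cM/Mb == 1e-8 per bp per generation`` is applied when reading HapMap-style
files.  Regions a map does not cover (before its first / after its last
position) get rate 0, matching maps that omit telomeres and centromeres.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RecombinationMap",
    "parse_hapmap_map",
    "dump_hapmap_map",
    "flat_map",
    "synthesize_map",
    "MapFormatError",
]

CM_PER_MORGAN = 100.0


class MapFormatError(ValueError):
    """Malformed genetic-map text; message names the offending row."""


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates over ``[0, sequence_length)``.

    ``positions`` has length ``len(rates) + 1``, is strictly increasing,
    starts at 0 and ends at ``sequence_length``; interval ``k`` is
    ``[positions[k], positions[k+1])`` with rate ``rates[k]`` per bp per
    generation.
    """

    positions: np.ndarray
    rates: np.ndarray
    sequence_length: float
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.positions) != len(self.rates) + 1:
            raise ValueError("need len(positions) == len(rates) + 1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        if self.positions[0] != 0 or self.positions[-1] != self.sequence_length:
            raise ValueError("positions must span [0, sequence_length]")
        # cumulative genetic position (Morgans) at each breakpoint
        self._cum = np.concatenate(
            [[0.0], np.cumsum(self.rates * np.diff(self.positions))]
        )

    @property
    def total_morgans(self) -> float:
        return float(self._cum[-1])

    @property
    def total_cM(self) -> float:
        return self.total_morgans * CM_PER_MORGAN

    def genetic_position(self, bp) -> np.ndarray:
        """Cumulative genetic position (Morgans) at physical coordinate(s)."""
        bp = np.asarray(bp, dtype=float)
        if np.any(bp < 0) or np.any(bp > self.sequence_length):
            raise ValueError("coordinate outside [0, sequence_length]")
        idx = np.clip(np.searchsorted(self.positions, bp, side="right") - 1, 0, len(self.rates) - 1)
        return self._cum[idx] + (bp - self.positions[idx]) * self.rates[idx]

    def physical_position(self, morgans) -> np.ndarray:
        """Leftmost physical coordinate at a cumulative genetic position."""
        g = np.asarray(morgans, dtype=float)
        idx = np.clip(np.searchsorted(self._cum, g, side="right") - 1, 0, len(self.rates) - 1)
        rate = self.rates[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            off = np.where(rate > 0, (g - self._cum[idx]) / rate, 0.0)
        return np.minimum(self.positions[idx] + off, self.sequence_length)

    def genetic_distance(self, a_bp: float, b_bp: float) -> float:
        """Genetic distance between two coordinates, in centimorgans."""
        if not (0 <= a_bp <= b_bp <= self.sequence_length):
            raise ValueError(
                f"need 0 <= a <= b <= L, got a={a_bp}, b={b_bp}, L={self.sequence_length}"
            )
        return float(
            (self.genetic_position(b_bp) - self.genetic_position(a_bp)) * CM_PER_MORGAN
        )

    def mean_rate(self) -> float:
        """Length-weighted mean rate per bp per generation over the chromosome."""
        return self.total_morgans / self.sequence_length


def mean_recombination_rate(gmap: RecombinationMap) -> float:
    """Length-weighted mean per-bp rate (module-level alias of ``mean_rate``)."""
    return gmap.mean_rate()


def genetic_distance(gmap: RecombinationMap, a_bp: float, b_bp: float) -> float:
    """Genetic distance in cM between two coordinates (function form)."""
    return gmap.genetic_distance(a_bp, b_bp)


def flat_map(length: float, rate: float) -> RecombinationMap:
    """Uniform map: one interval covering ``[0, length)`` at ``rate``."""
    if not length > 0:
        raise ValueError(f"length must be > 0, got {length}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return RecombinationMap(np.array([0.0, float(length)]), np.array([float(rate)]), float(length))


def parse_hapmap_map(text: str, sequence_length: float) -> RecombinationMap:
    """Parse a HapMap-format genetic map (header + 4 columns).

    Columns are ``Chromosome  Position(bp)  Rate(cM/Mb)  Map(cM)``.  The Rate
    column governs: interval ``[pos_k, pos_{k+1})`` gets ``rate_k`` converted
    at 1 cM/Mb = 1e-8 /bp/generation; the last row's rate is unused and the
    uncovered flanks get rate 0.  The cumulative Map(cM) column is recomputed
    from the rates and a warning is emitted if it disagrees.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MapFormatError("empty genetic map file")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):  # line 1 is the header
        parts = ln.split()
        if len(parts) != 4:
            raise MapFormatError(f"row {lineno}: expected 4 columns, got {len(parts)}")
        try:
            pos, rate, cum = float(parts[1]), float(parts[2]), float(parts[3])
        except ValueError as exc:
            raise MapFormatError(f"row {lineno}: non-numeric field: {ln!r}") from exc
        if rate < 0:
            raise MapFormatError(f"row {lineno}: negative rate {rate}")
        if rows and pos <= rows[-1][0]:
            raise MapFormatError(
                f"row {lineno}: position {pos} not greater than previous {rows[-1][0]}"
            )
        rows.append((pos, rate, cum))
    if rows and rows[-1][0] > sequence_length:
        raise MapFormatError(
            f"map position {rows[-1][0]} exceeds sequence length {sequence_length}"
        )

    pos = np.array([r[0] for r in rows])
    rate_cm_mb = np.array([r[1] for r in rows])
    cum_cm = np.array([r[2] for r in rows])
    if len(rows) >= 2:
        recomputed = np.concatenate(
            [[cum_cm[0]], cum_cm[0] + np.cumsum(rate_cm_mb[:-1] * np.diff(pos) / 1e6)]
        )
        if not np.allclose(recomputed, cum_cm, rtol=1e-6, atol=1e-6):
            warnings.warn(
                "Map(cM) column inconsistent with Rate(cM/Mb) column; "
                "the rate column governs",
                stacklevel=2,
            )

    positions = [0.0]
    rates = []
    if len(rows) == 0 or pos[0] > 0:
        if len(rows) and pos[0] > 0:
            positions.append(float(pos[0]))
            rates.append(0.0)
    for k in range(len(rows) - 1):
        positions.append(float(pos[k + 1]))
        rates.append(float(rate_cm_mb[k]) * 1e-8)
    if not positions or positions[-1] < sequence_length:
        positions.append(float(sequence_length))
        rates.append(0.0)
    if len(rates) == 0:  # degenerate: single row at position == L
        positions = [0.0, float(sequence_length)]
        rates = [0.0]
    return RecombinationMap(np.array(positions), np.array(rates), float(sequence_length))


def dump_hapmap_map(gmap: RecombinationMap, chrom: str = "chr1") -> str:
    """Serialize a map to HapMap 4-column text (rate column authoritative)."""
    out = io.StringIO()
    out.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
    cum_cm = gmap._cum * CM_PER_MORGAN
    for k in range(len(gmap.rates)):
        out.write(
            f"{chrom}\t{gmap.positions[k]:.0f}\t{gmap.rates[k] / 1e-8:.17g}\t{cum_cm[k]:.17g}\n"
        )
    out.write(
        f"{chrom}\t{gmap.positions[-1]:.0f}\t0\t{cum_cm[-1]:.17g}\n"
    )
    return out.getvalue()


def synthesize_map(
    length: float,
    n_windows: int,
    log_rate_mean: float = np.log(1e-8),
    log_rate_sd: float = 1.0,
    seed: int = 0,
) -> RecombinationMap:
    """Synthetic heterogeneous map: equal-width windows, i.i.d. log-normal rates.

    Stands in for empirically inferred maps in tests and examples; the
    defaults give a mean rate near the human-typical 1e-8 /bp/generation with
    realistic order-of-magnitude heterogeneity.  Deterministic given ``seed``.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    rates = np.exp(rng.normal(log_rate_mean, log_rate_sd, size=n_windows))
    positions = np.linspace(0.0, float(length), n_windows + 1)
    return RecombinationMap(positions, rates, float(length))
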