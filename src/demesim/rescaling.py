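"""Population-size rescaling for tractable forward-style simulation.

Dividing all population sizes by a scaling factor ``Q`` while multiplying all
per-generation rates (mutation, recombination, migration, growth) by ``Q``
and dividing event times by ``Q`` leaves every population-scaled parameter
invariant: ``theta = 4 N mu`` and ``rho = 4 N r`` per bp, and ``4 N m`` per
migration edge.  Under neutrality the distribution of sequence statistics is
unchanged up to the time relabeling ``t -> t/Q``; this module performs the
transform and carries a selection-coefficient slot in the signature for
interface completeness (selection itself is out of scope).
"""

from __future__ import annotations

import copy
from typing import Optional, Tuple

import numpy as np

from .demography import (
    DemographicModel,
    LineageMove,
    MigrationChange,
    SizeGrowthChange,
)
from .genmap import RecombinationMap

__all__ = ["rescale"]


def rescale(
    model: DemographicModel,
    mutation_rate: float,
    recombination_map: Optional[RecombinationMap],
    Q: float,
    selection_coefficient: Optional[float] = None,
) -> Tuple[DemographicModel, float, Optional[RecombinationMap], Optional[float]]:
    """Rescale a model by factor ``Q``.

    Returns ``(model', mutation_rate', map', selection')`` with sizes divided
    by ``Q``, times divided by ``Q``, and growth/migration/mutation/
    recombination (and selection, if given) rates multiplied by ``Q``.
    ``Q = 1`` is the identity on canonical form.
    """
    if not Q > 0:
        raise ValueError(f"scaling factor Q must be > 0, got {Q}")
    m = copy.deepcopy(model)
    m.id = model.id
    m.description = (model.description + f" [rescaled by Q={Q}]").strip()
    m.initial_sizes = [s / Q for s in m.initial_sizes]
    m.initial_growth_rates = [g * Q for g in m.initial_growth_rates]
    m.migration_matrix = [[r * Q for r in row] for row in m.migration_matrix]
    for ev in m.events:
        ev.time = ev.time / Q
        if isinstance(ev, SizeGrowthChange):
            if ev.new_size is not None:
                ev.new_size = ev.new_size / Q
            if ev.new_growth_rate is not None:
                ev.new_growth_rate = ev.new_growth_rate * Q
        elif isinstance(ev, MigrationChange):
            ev.new_rate = ev.new_rate * Q
        # LineageMove proportions are probabilities: unchanged
    mu = mutation_rate * Q
    gmap = None
    if recombination_map is not None:
        gmap = RecombinationMap(
            recombination_map.positions.copy(),
            recombination_map.rates * Q,
            recombination_map.sequence_length,
        )
    sel = None if selection_coefficient is None else selection_coefficient * Q
    return m, mu, gmap, sel
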