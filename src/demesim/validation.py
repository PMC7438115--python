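"""Reference validation scenarios for the engine and the analytic curves.

Four small models with known or analytically computable pairwise coalescence
behaviour — constant size, two-epoch bottleneck, symmetric two-island, and a
clean-split isolation-with-migration model — together with the time grids on
which their truth curves are compared against Monte-Carlo hazards.  These are
the toolkit's own correctness surface: the analytic inverse-coalescence-rate
curve must agree with the empirical hazard of single-locus pairwise TMRCA
simulations on every one of them.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .demography import DemographicModel, PopulationDef, generic_im, generic_piecewise_constant

__all__ = ["two_island_model", "reference_scenarios"]


def two_island_model(N: float = 5000.0, m: float = 5e-5) -> DemographicModel:
    """Symmetric two-island model: equal sizes, symmetric migration."""
    return DemographicModel(
        id="SymmetricTwoIsland",
        description=f"two islands of size {N} with symmetric migration {m}",
        populations=[PopulationDef("island0"), PopulationDef("island1")],
        initial_sizes=[float(N), float(N)],
        initial_growth_rates=[0.0, 0.0],
        migration_matrix=[[0.0, float(m)], [float(m), 0.0]],
    )


def reference_scenarios() -> Dict[str, Tuple[DemographicModel, int, int, np.ndarray]]:
    """The four benchmark scenarios: name -> (model, popA, popB, time grid).

    Grids span the region where pair survival stays above a few percent, with
    about ten bins each; parameter scales are human-like (sizes 10^3-10^4
    diploids, divergence a few thousand generations).
    """
    return {
        "constant": (
            generic_piecewise_constant([10000.0]),
            0,
            0,
            np.linspace(0.0, 60000.0, 11),
        ),
        "two_epoch": (
            generic_piecewise_constant([10000.0, 1000.0], [1000.0]),
            0,
            0,
            np.array([0, 250, 500, 750, 1000, 1500, 2000, 3000, 4500, 6000, 8000.0]),
        ),
        "two_island": (
            two_island_model(5000.0, 5e-5),
            0,
            0,
            np.linspace(0.0, 80000.0, 11),
        ),
        "im_split": (
            generic_im(7300.0, 10000.0, 10000.0, 4000.0, 5e-5, 5e-5),
            0,
            1,
            np.array(
                [0, 500, 1000, 2000, 3000, 4000, 8000, 16000, 24000, 36000, 48000.0]
            ),
        ),
    }
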