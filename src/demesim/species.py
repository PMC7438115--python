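"""Species and chromosome descriptors, naming conventions, and the registry.

A species is identified by a six-character code built from the first three
letters of the genus and species names, each capitalized (``HomSap``,
``DroMel``, ``AraTha``).  Registered demographic-model ids follow the grammar
``<CamelCaseDescription>_<integer><AuthorInitial><2-digit year>``
(e.g. ``OutOfAfrica_3G09``); generic built-in models are exempt.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .demography import Citation, DemographicModel, generic_im, generic_piecewise_constant
from .genmap import RecombinationMap, flat_map, synthesize_map

__all__ = [
    "ChromosomeDef",
    "SpeciesRecord",
    "Registry",
    "validate_species_id",
    "validate_model_id",
    "default_registry",
]

_SPECIES_ID_RE = re.compile(r"^[A-Z][a-z]{2}[A-Z][a-z]{2}$")
_MODEL_ID_RE = re.compile(r"^[A-Z][A-Za-z0-9]*_[0-9]+[A-Z][0-9]{2}$")


def validate_species_id(species_id: str) -> bool:
    """True iff ``species_id`` is two concatenated capitalized 3-letter blocks."""
    return bool(_SPECIES_ID_RE.match(species_id))


def validate_model_id(model_id: str) -> bool:
    """True iff ``model_id`` follows the catalog naming grammar.

    Grammar: CamelCase description, underscore, number of populations,
    first-author initial, two-digit publication year — or a ``Generic*``
    built-in family name, which is exempt.
    """
    if model_id.startswith("Generic"):
        return True
    return bool(_MODEL_ID_RE.match(model_id))


@dataclass
class ChromosomeDef:
    """Physical description of one chromosome."""

    id: str
    length: float  # bp
    mean_mutation_rate: float  # per bp per generation
    mean_recombination_rate: float  # per bp per generation

    def __post_init__(self):
        if not self.length > 0:
            raise ValueError(f"chromosome {self.id}: length must be > 0")
        if self.mean_mutation_rate < 0 or self.mean_recombination_rate < 0:
            raise ValueError(f"chromosome {self.id}: rates must be >= 0")


@dataclass
class SpeciesRecord:
    """Everything the simulator needs to know about one species."""

    id: str
    name: str
    generation_time: float
    chromosomes: List[ChromosomeDef] = field(default_factory=list)
    genetic_maps: Dict[str, RecombinationMap] = field(default_factory=dict)
    models: Dict[str, DemographicModel] = field(default_factory=dict)
    citations: List[Citation] = field(default_factory=list)

    def __post_init__(self):
        if not validate_species_id(self.id):
            raise ValueError(
                f"species id {self.id!r} does not match the six-character "
                "GenSpe naming convention"
            )
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chromosome ids: {ids}")

    def chromosome(self, chrom_id: str) -> ChromosomeDef:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(
            f"unknown chromosome {chrom_id!r} for {self.id}; "
            f"known: {[c.id for c in self.chromosomes]}"
        )


class Registry:
    """An in-memory catalog of species, their maps and demographic models."""

    def __init__(self):
        self._species: Dict[str, SpeciesRecord] = {}

    def add_species(self, record: SpeciesRecord) -> None:
        if record.id in self._species:
            raise ValueError(f"species {record.id!r} already registered")
        self._species[record.id] = record

    def add_model(self, species_id: str, model: DemographicModel) -> None:
        import warnings

        if not validate_model_id(model.id):
            warnings.warn(
                f"model id {model.id!r} does not follow the catalog naming "
                "grammar (Description_<n><Initial><yy>)",
                stacklevel=2,
            )
        self.species(species_id).models[model.id] = model

    def species(self, species_id: str) -> SpeciesRecord:
        try:
            return self._species[species_id]
        except KeyError:
            raise KeyError(
                f"unknown species {species_id!r}; known: {sorted(self._species)}"
            ) from None

    def species_ids(self) -> List[str]:
        return sorted(self._species)

    def resolve_model(self, species_id: str, model_id: str) -> DemographicModel:
        sp = self.species(species_id)
        try:
            return sp.models[model_id]
        except KeyError:
            raise KeyError(
                f"unknown model {model_id!r} for species {species_id}; "
                f"known: {sorted(sp.models)}"
            ) from None


def default_registry() -> Registry:
    """The built-in demo catalog: one synthetic species with generic models.

    ``GenSpe`` ("Genericus speciens") carries two small synthetic chromosomes
    with human-like per-bp rates, a flat and a heterogeneous genetic map, and
    the two generic model families.  Catalog entries for real species are
    registered by the user from model-definition files.
    """
    reg = Registry()
    sp = SpeciesRecord(
        id="GenSpe",
        name="Genericus speciens",
        generation_time=1.0,
        chromosomes=[
            ChromosomeDef("chr1", 2e6, 1e-8, 1e-8),
            ChromosomeDef("chr2", 1e6, 1e-8, 1.2e-8),
        ],
        citations=[Citation("demesim-engine", role="engine")],
    )
    sp.genetic_maps["flat_chr1"] = flat_map(2e6, 1e-8)
    sp.genetic_maps["synthetic_chr1"] = synthesize_map(2e6, 40, seed=17)
    reg.add_species(sp)
    reg.add_model("GenSpe", generic_piecewise_constant([10000], id="GenericConstant"))
    reg.add_model(
        "GenSpe",
        generic_piecewise_constant([10000, 1000], [1000], id="GenericTwoEpoch"),
    )
    reg.add_model("GenSpe", generic_im(7300, 10000, 10000, 4000, 0.0, 0.0))
    return reg
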