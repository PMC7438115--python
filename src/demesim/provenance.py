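"""Run configuration, provenance records, sub-seed derivation, citations.

Every simulation output carries a provenance sidecar from which the run can
be re-executed exactly: the resolved arguments, package version, master seed
and the derived per-output sub-seed.  Citation emission groups the sources a
run depends on (engine, model, genetic map) so they can be acknowledged.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .demography import DemographicModel
from .engine import Contig, SampleSpec, drop_mutations, export_vcf, simulate_ancestry
from .genmap import RecombinationMap, flat_map, parse_hapmap_map
from .modelfile import load_model_file
from .species import Registry, default_registry
from .tables import Tables

__all__ = [
    "RunConfig",
    "derive_subseed",
    "run_simulate_command",
    "emit_citations",
    "list_catalog",
    "rerun_from_provenance",
]

ENGINE_CITATION = "demesim coalescent engine (this package)"


@dataclass
class RunConfig:
    """Everything needed to resolve and execute a simulation run.

    ``R`` replicates of ``C`` chromosomes are simulated, giving ``R x C``
    output bundles with per-output sub-seeds derived from ``seed``.
    """

    species: Optional[str] = None
    model: Optional[str] = None  # catalog model id
    model_file: Optional[str] = None  # path to a model-definition file
    chromosome: Optional[str] = None
    length: Optional[float] = None
    map_file: Optional[str] = None
    map_name: Optional[str] = None  # named catalog map
    samples: List[int] = field(default_factory=list)  # haploids per population
    mutation_rate: Optional[float] = None
    recombination_rate: Optional[float] = None
    replicates: int = 1
    chroms_per_replicate: int = 1
    seed: int = 1
    output_prefix: str = "demesim_run"
    scaling_factor: float = 1.0
    vcf: bool = False

    def validate(self) -> None:
        if sum(self.samples) < 2:
            raise ValueError("need at least 2 haploid samples in total")
        if self.replicates < 1 or self.chroms_per_replicate < 1:
            raise ValueError("replicates and chromosomes per replicate must be >= 1")
        if self.model is None and self.model_file is None:
            raise ValueError("one of model id or model file is required")


def derive_subseed(master_seed: int, replicate: int, chromosome: int) -> int:
    """Deterministic, injective sub-seed for output (replicate, chromosome).

    Counter-based: SHA-256 of the decimal triple, reduced mod 2^31.  Recorded
    in each output's provenance so any single bundle can be reproduced.
    """
    if replicate < 0 or chromosome < 0:
        raise ValueError("indices must be >= 0")
    key = f"{master_seed}:{replicate}:{chromosome}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:8], "big") % (2**31)


def _resolve(config: RunConfig, registry: Optional[Registry] = None):
    """Resolve a config to (model, contig pieces, citations)."""
    registry = registry or default_registry()
    config.validate()
    if config.model_file is not None:
        model = load_model_file(Path(config.model_file).read_text())
    else:
        if config.species is None:
            raise KeyError("a species id is required to resolve a catalog model")
        model = registry.resolve_model(config.species, config.model)

    length = config.length
    mu = config.mutation_rate
    rec = config.recombination_rate
    if config.species is not None and config.chromosome is not None:
        chrom = registry.species(config.species).chromosome(config.chromosome)
        length = length or chrom.length
        mu = mu if mu is not None else chrom.mean_mutation_rate
        rec = rec if rec is not None else chrom.mean_recombination_rate
    if length is None:
        raise ValueError("contig length unresolved: give a chromosome id or length")
    if mu is None:
        mu = 0.0

    if config.map_file is not None:
        gmap = parse_hapmap_map(Path(config.map_file).read_text(), length)
    elif config.map_name is not None and config.species is not None:
        gmap = registry.species(config.species).genetic_maps[config.map_name]
    else:
        gmap = flat_map(length, rec if rec is not None else 0.0)
    return model, length, mu, gmap


def emit_citations(config: RunConfig, registry: Optional[Registry] = None) -> str:
    """Deterministic citation block for a resolved run, grouped by role."""
    model, _, _, _ = _resolve(config, registry)
    lines = ["# Citations", "engine:", f"  - {ENGINE_CITATION}"]
    model_cites = [c.doi for c in model.citations if c.role == "model"]
    lines.append("model:")
    if model_cites:
        lines.extend(f"  - {c}" for c in sorted(model_cites))
    else:
        lines.append(f"  - (generic model family: {model.id}; no primary source)")
    map_cites = [c.doi for c in model.citations if c.role == "genetic-map"]
    if config.map_file is not None:
        map_cites.append(f"user-supplied map file: {config.map_file}")
    elif config.map_name is not None:
        map_cites.append(f"catalog map: {config.map_name}")
    if map_cites:
        lines.append("genetic-map:")
        lines.extend(f"  - {c}" for c in sorted(map_cites))
    return "\n".join(lines) + "\n"


def list_catalog(registry: Optional[Registry] = None) -> str:
    """Stable text listing of registered species, models and maps."""
    registry = registry or default_registry()
    lines = ["# Catalog"]
    for sid in registry.species_ids():
        sp = registry.species(sid)
        lines.append(f"{sid}  ({sp.name}, generation time {sp.generation_time} y)")
        lines.append("  chromosomes:")
        for c in sp.chromosomes:
            lines.append(
                f"    {c.id}  length={c.length:.0f}bp  mu={c.mean_mutation_rate:g}"
                f"  r={c.mean_recombination_rate:g}"
            )
        if sp.genetic_maps:
            lines.append("  genetic maps:")
            for name in sorted(sp.genetic_maps):
                lines.append(f"    {name}")
        if sp.models:
            lines.append("  models:")
            for name in sorted(sp.models):
                lines.append(f"    {name}")
    return "\n".join(lines) + "\n"


def _digest(path: Optional[str]) -> Optional[str]:
    if path is None:
        return None
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_simulate_command(
    config: RunConfig,
    registry: Optional[Registry] = None,
    stderr=None,
) -> List[str]:
    """Execute a run: R x C simulations, each written as a TSV bundle.

    Returns the list of output prefixes.  Each bundle embeds a provenance
    record sufficient to re-execute it; the citation block is printed to
    ``stderr``.
    """
    stderr = stderr if stderr is not None else sys.stderr
    model, length, mu, gmap = _resolve(config, registry)
    if config.scaling_factor != 1.0:
        from .rescaling import rescale

        model, mu, gmap, _ = rescale(model, mu, gmap, config.scaling_factor)
    samples = SampleSpec.simple(config.samples)
    contig = Contig(length=gmap.sequence_length, recombination_map=gmap, mutation_rate=mu)
    prefixes = []
    for r in range(config.replicates):
        for c in range(config.chroms_per_replicate):
            sub = derive_subseed(config.seed, r, c)
            tables = simulate_ancestry(model, samples, contig, seed=sub)
            if mu > 0:
                drop_mutations(tables, mu, seed=derive_subseed(sub, 0, 1))
            prefix = f"{config.output_prefix}_r{r}_c{c}"
            tables.provenance = {
                "tool": "demesim",
                "version": __version__,
                "config": {
                    k: v for k, v in vars(config).items() if not k.startswith("_")
                },
                "replicate": r,
                "chromosome_index": c,
                "master_seed": config.seed,
                "sub_seed": sub,
                "sequence_length": length,
                "mutation_rate": mu,
                "engine": {"name": "demesim-hudson", "max_events": None},
                "input_digests": {
                    "model_file": _digest(config.model_file),
                    "map_file": _digest(config.map_file),
                },
                "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
            tables.write(prefix)
            if config.vcf:
                Path(f"{prefix}.vcf").write_text(export_vcf(tables))
            prefixes.append(prefix)
    print(emit_citations(config, registry), file=stderr)
    return prefixes


def rerun_from_provenance(provenance_path: str, output_prefix: str) -> str:
    """Re-execute the single bundle described by a provenance sidecar.

    Reconstructs the run configuration, re-runs only the recorded
    (replicate, chromosome) cell, and writes it under ``output_prefix``;
    the node/edge/site/mutation tables are byte-identical to the originals.
    """
    prov = json.loads(Path(provenance_path).read_text())
    cfg = RunConfig(**prov["config"])
    cfg.replicates = prov["replicate"] + 1
    cfg.chroms_per_replicate = prov["chromosome_index"] + 1
    model, length, mu, gmap = _resolve(cfg)
    if cfg.scaling_factor != 1.0:
        from .rescaling import rescale

        model, mu, gmap, _ = rescale(model, mu, gmap, cfg.scaling_factor)
    samples = SampleSpec.simple(cfg.samples)
    contig = Contig(length=gmap.sequence_length, recombination_map=gmap, mutation_rate=mu)
    sub = prov["sub_seed"]
    tables = simulate_ancestry(model, samples, contig, seed=sub)
    if mu > 0:
        drop_mutations(tables, mu, seed=derive_subseed(sub, 0, 1))
    tables.write(output_prefix)
    return output_prefix
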