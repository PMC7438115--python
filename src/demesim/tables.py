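"""Tabular genealogy encoding: node/edge/site/mutation tables.

A simulated ancestry is stored as four flat tables, the text counterpart of
the succinct tree-sequence encoding: nodes (time, population, sample flag),
edges (left, right, parent, child over 0-based half-open bp intervals), sites
(position, ancestral state) and mutations (site, node, derived state).  The
tables serialize to four TSV files plus a provenance sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

__all__ = ["Tables", "TableValidationError", "validate_tables"]


class TableValidationError(ValueError):
    """A structural invariant of the tables is violated."""


@dataclass
class Tables:
    """Node/edge/site/mutation tables for one simulated contig."""

    sequence_length: float
    node_time: List[float] = field(default_factory=list)
    node_population: List[int] = field(default_factory=list)
    node_is_sample: List[bool] = field(default_factory=list)
    edge_left: List[float] = field(default_factory=list)
    edge_right: List[float] = field(default_factory=list)
    edge_parent: List[int] = field(default_factory=list)
    edge_child: List[int] = field(default_factory=list)
    site_position: List[int] = field(default_factory=list)
    site_ancestral: List[str] = field(default_factory=list)
    mutation_site: List[int] = field(default_factory=list)
    mutation_node: List[int] = field(default_factory=list)
    mutation_derived: List[str] = field(default_factory=list)
    provenance: Optional[Dict] = None

    # -- construction -----------------------------------------------------
    def add_node(self, time: float, population: int, is_sample: bool = False) -> int:
        self.node_time.append(float(time))
        self.node_population.append(int(population))
        self.node_is_sample.append(bool(is_sample))
        return len(self.node_time) - 1

    def add_edge(self, left: float, right: float, parent: int, child: int) -> None:
        self.edge_left.append(float(left))
        self.edge_right.append(float(right))
        self.edge_parent.append(int(parent))
        self.edge_child.append(int(child))

    @property
    def num_nodes(self) -> int:
        return len(self.node_time)

    @property
    def num_edges(self) -> int:
        return len(self.edge_left)

    @property
    def num_sites(self) -> int:
        return len(self.site_position)

    def samples(self) -> List[int]:
        return [i for i, s in enumerate(self.node_is_sample) if s]

    # -- maintenance ------------------------------------------------------
    def sort_and_squash_edges(self) -> None:
        """Sort edges by (parent time, parent, child, left) and merge
        contiguous intervals of the same parent/child pair."""
        order = sorted(
            range(self.num_edges),
            key=lambda k: (
                self.node_time[self.edge_parent[k]],
                self.edge_parent[k],
                self.edge_child[k],
                self.edge_left[k],
            ),
        )
        L, R, P, C = [], [], [], []
        for k in order:
            l, r = self.edge_left[k], self.edge_right[k]
            p, c = self.edge_parent[k], self.edge_child[k]
            if L and P[-1] == p and C[-1] == c and R[-1] == l:
                R[-1] = r
            else:
                L.append(l)
                R.append(r)
                P.append(p)
                C.append(c)
        self.edge_left, self.edge_right = L, R
        self.edge_parent, self.edge_child = P, C

    # -- serialization ----------------------------------------------------
    def write(self, prefix: str) -> List[Path]:
        """Write nodes/edges/sites/mutations TSVs plus provenance sidecar.

        Files are ``<prefix>.nodes.tsv`` etc.; returns the written paths.
        """
        prefix = str(prefix)
        paths = []

        def w(name: str, header: str, rows) -> None:
            p = Path(f"{prefix}.{name}.tsv")
            with open(p, "w") as fh:
                fh.write(header + "\n")
                for row in rows:
                    fh.write("\t".join(row) + "\n")
            paths.append(p)

        w(
            "nodes",
            "id\ttime\tpopulation\tis_sample",
            (
                (str(i), repr(self.node_time[i]), str(self.node_population[i]), str(int(self.node_is_sample[i])))
                for i in range(self.num_nodes)
            ),
        )
        w(
            "edges",
            "left\tright\tparent\tchild",
            (
                (repr(self.edge_left[k]), repr(self.edge_right[k]), str(self.edge_parent[k]), str(self.edge_child[k]))
                for k in range(self.num_edges)
            ),
        )
        w(
            "sites",
            "id\tposition\tancestral_state",
            (
                (str(i), str(self.site_position[i]), self.site_ancestral[i])
                for i in range(self.num_sites)
            ),
        )
        w(
            "mutations",
            "site\tnode\tderived_state",
            (
                (str(self.mutation_site[k]), str(self.mutation_node[k]), self.mutation_derived[k])
                for k in range(len(self.mutation_site))
            ),
        )
        if self.provenance is not None:
            p = Path(f"{prefix}.provenance.json")
            with open(p, "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)
                fh.write("\n")
            paths.append(p)
        return paths

    @classmethod
    def read(cls, prefix: str) -> "Tables":
        """Read a TSV bundle written by :meth:`write`."""
        prefix = str(prefix)

        def rows(name):
            with open(f"{prefix}.{name}.tsv") as fh:
                next(fh)  # header
                for ln in fh:
                    yield ln.rstrip("\n").split("\t")

        t = cls(sequence_length=0.0)
        for r in rows("nodes"):
            t.node_time.append(float(r[1]))
            t.node_population.append(int(r[2]))
            t.node_is_sample.append(bool(int(r[3])))
        for r in rows("edges"):
            t.edge_left.append(float(r[0]))
            t.edge_right.append(float(r[1]))
            t.edge_parent.append(int(r[2]))
            t.edge_child.append(int(r[3]))
        for r in rows("sites"):
            t.site_position.append(int(r[1]))
            t.site_ancestral.append(r[2])
        for r in rows("mutations"):
            t.mutation_site.append(int(r[0]))
            t.mutation_node.append(int(r[1]))
            t.mutation_derived.append(r[2])
        prov_path = Path(f"{prefix}.provenance.json")
        if prov_path.exists():
            t.provenance = json.loads(prov_path.read_text())
            t.sequence_length = float(t.provenance.get("sequence_length", 0.0))
        if t.sequence_length == 0.0 and t.edge_right:
            t.sequence_length = max(t.edge_right)
        return t


def validate_tables(tables: Tables) -> None:
    """Check structural invariants; raise :class:`TableValidationError`.

    Invariants: every edge's parent is strictly older than its child; the
    intervals of the edges above each child are non-overlapping; every sample
    node's material is covered by parent edges over ``[0, L)``; site positions
    are unique and in range; mutations reference valid sites and nodes.
    """
    t = tables
    L = t.sequence_length
    for k in range(t.num_edges):
        p, c = t.edge_parent[k], t.edge_child[k]
        if not (0 <= p < t.num_nodes and 0 <= c < t.num_nodes):
            raise TableValidationError(f"edge {k}: node index out of range")
        if not t.node_time[p] > t.node_time[c]:
            raise TableValidationError(
                f"edge {k}: parent time {t.node_time[p]} not greater than "
                f"child time {t.node_time[c]}"
            )
        if not (0 <= t.edge_left[k] < t.edge_right[k] <= L):
            raise TableValidationError(f"edge {k}: bad interval")
    by_child: Dict[int, List] = {}
    for k in range(t.num_edges):
        by_child.setdefault(t.edge_child[k], []).append(
            (t.edge_left[k], t.edge_right[k])
        )
    for c, ivals in by_child.items():
        ivals.sort()
        for (l1, r1), (l2, r2) in zip(ivals, ivals[1:]):
            if l2 < r1:
                raise TableValidationError(
                    f"child {c}: overlapping parent edges ({l1},{r1}) and ({l2},{r2})"
                )
    for s in t.samples():
        ivals = sorted(by_child.get(s, []))
        covered = 0.0
        for l, r in ivals:
            if l > covered:
                raise TableValidationError(
                    f"sample {s}: uncovered gap [{covered}, {l})"
                )
            covered = max(covered, r)
        if covered < L:
            raise TableValidationError(f"sample {s}: uncovered tail [{covered}, {L})")
    if len(set(t.site_position)) != t.num_sites:
        raise TableValidationError("duplicate site positions")
    for i, pos in enumerate(t.site_position):
        if not (0 <= pos < L):
            raise TableValidationError(f"site {i}: position {pos} out of range")
    for k in range(len(t.mutation_site)):
        if not (0 <= t.mutation_site[k] < t.num_sites):
            raise TableValidationError(f"mutation {k}: bad site index")
        if not (0 <= t.mutation_node[k] < t.num_nodes):
            raise TableValidationError(f"mutation {k}: bad node index")
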