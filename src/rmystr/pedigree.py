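"""Paternal pedigree graphs: validation, IO, subtree and path utilities.

A pedigree is a forest of father-to-son edges over male individuals, a
subset of whom ("sampled") have genotyped haplotypes; the rest are
unsampled ancestors known only from genealogical records.  Mutations are
observable only on the minimal subtree connecting the sampled men, so the
meiosis denominator of a pedigree is the edge count of that (Steiner)
subtree, not of the full genealogy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "PedigreeGraph",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "steiner_subtree",
    "meioses_between",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class PedigreeGraph:
    """A paternal genealogy.

    ``father_of`` maps child -> father (at most one father per child);
    ``sampled`` is the subset of individuals with haplotypes.
    """

    pedigree_id: str
    father_of: dict[str, str]
    sampled: set[str] = field(default_factory=set)
    extra_individuals: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sampled = set(self.sampled)
        self.extra_individuals = set(self.extra_individuals)
        self.validate()

    @property
    def individuals(self) -> set[str]:
        ids = set(self.father_of) | set(self.father_of.values())
        return ids | self.extra_individuals

    @property
    def n_edges(self) -> int:
        return len(self.father_of)

    def to_undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.individuals)
        g.add_edges_from(self.father_of.items())
        return g

    def to_directed(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        g.add_edges_from(self.father_of.items())  # child -> father
        return g

    def validate(self) -> None:
        """Check acyclicity, single fatherhood, and sampled connectivity."""
        dg = self.to_directed()
        if not nx.is_directed_acyclic_graph(dg):
            cycle = nx.find_cycle(dg)
            raise PedigreeError(
                f"pedigree {self.pedigree_id}: individual is its own ancestor "
                f"(cycle through {cycle[0][0]})"
            )
        missing = self.sampled - self.individuals
        if missing:
            raise PedigreeError(
                f"pedigree {self.pedigree_id}: sampled ID(s) absent from "
                f"graph: {sorted(missing)}"
            )
        if len(self.sampled) >= 2:
            und = self.to_undirected()
            comp = nx.node_connected_component(und, next(iter(self.sampled)))
            stray = self.sampled - comp
            if stray:
                raise PedigreeError(
                    f"pedigree {self.pedigree_id}: sampled individuals not "
                    f"connected: {sorted(stray)}"
                )

    def describe(self) -> dict[str, int]:
        sub = steiner_subtree(self)
        return {
            "individuals": len(self.individuals),
            "sampled": len(self.sampled),
            "edges": self.n_edges,
            "subtree_meioses": sub.number_of_edges(),
        }


def steiner_subtree(pedigree: PedigreeGraph, terminals=None) -> nx.Graph:
    """Minimal subtree of the genealogy connecting *terminals*
    (default: the sampled individuals).

    Because each individual has at most one father the genealogy is a
    forest, so the Steiner tree is exact: take the component containing
    the terminals and iteratively prune non-terminal leaves.
    """
    terminals = set(pedigree.sampled if terminals is None else terminals)
    g = pedigree.to_undirected()
    if not terminals:
        return nx.Graph()
    keep = g.subgraph(
        nx.node_connected_component(g, next(iter(terminals)))
    ).copy()
    if not terminals <= set(keep.nodes):
        raise PedigreeError(
            f"pedigree {pedigree.pedigree_id}: terminals not connected"
        )
    pruned = True
    while pruned:
        pruned = False
        for node in [n for n in keep.nodes if keep.degree(n) <= 1 and n not in terminals]:
            keep.remove_node(node)
            pruned = True
    return keep


def meioses_between(pedigree: PedigreeGraph, a: str, b: str) -> int:
    """Number of parent-child transmissions on the genealogical path
    a -> common ancestor -> b."""
    g = pedigree.to_undirected()
    try:
        return nx.shortest_path_length(g, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        raise PedigreeError(
            f"pedigree {pedigree.pedigree_id}: {a} and {b} are not connected"
        ) from None


def read_pedigree(path: str | Path, sep: str = "\t") -> PedigreeGraph:
    """Read a pedigree edge list.

    Columns: ``child``, ``father``, ``sampled`` (0/1 flag on the child
    row).  A row with an empty ``father`` declares an individual without
    an edge (e.g. a sampled founder).  ``pedigree_id`` is taken from the
    file name stem.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    required = {"child", "father"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'child' and 'father'")
    father_of: dict[str, str] = {}
    sampled: set[str] = set()
    extra: set[str] = set()
    for _, row in df.iterrows():
        child = str(row["child"]).strip()
        father_cell = row["father"]
        father = (
            ""
            if father_cell is None or pd.isna(father_cell)
            else str(father_cell).strip()
        )
        if father:
            if child in father_of and father_of[child] != father:
                raise PedigreeError(
                    f"{path}: individual {child} has two fathers "
                    f"({father_of[child]}, {father})"
                )
            father_of[child] = father
        else:
            extra.add(child)
        flag = row.get("sampled")
        if flag is not None and not pd.isna(flag) and str(flag).strip() in {"1", "true", "True"}:
            sampled.add(child)
    g = PedigreeGraph(path.stem, father_of, sampled, extra)
    log.info(
        "%s: %d individuals, %d sampled, %d subtree meioses",
        path.name,
        len(g.individuals),
        len(g.sampled),
        steiner_subtree(g).number_of_edges() if g.sampled else 0,
    )
    return g


def write_pedigree(path: str | Path, pedigree: PedigreeGraph, sep: str = "\t") -> None:
    rows = [
        {"child": c, "father": f, "sampled": int(c in pedigree.sampled)}
        for c, f in sorted(pedigree.father_of.items())
    ]
    for node in sorted(pedigree.individuals - set(pedigree.father_of)):
        if node in pedigree.sampled:
            rows.append({"child": node, "father": "", "sampled": 1})
    pd.DataFrame(rows, columns=["child", "father", "sampled"]).to_csv(
        path, sep=sep, index=False
    )
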