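"""Mutation-event counting by maximum parsimony and by pairwise comparison.

Within pedigrees, the number of mutation events at a locus is the minimum
number of subtree edges on which the allele changes, over all assignments
of alleles to unsampled ancestors.  Any change counts as a single event
regardless of its size in repeat units (a 36 vs 34 difference is one
multi-step event), which makes this unordered-state parsimony: multiple
independent hits at the same locus within the short time frame of a
pedigree are far less likely than a single multi-step event.

Between unrelated individuals the same difference is counted as |delta|
independent single-step events (36 vs 34 = two events), since no recent
shared ancestry constrains the history.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .haplotypes import Haplotype
from .panels import Panel
from .pedigree import PedigreeGraph, steiner_subtree

log = logging.getLogger(__name__)

__all__ = [
    "MutationCount",
    "Convention",
    "parsimony_event_count",
    "count_pedigree_mutations",
    "pair_mutation_count",
]

Convention = Literal["related", "unrelated"]

_INF = float("inf")


@dataclass
class MutationCount:
    """Per-column mutation events for one pedigree or couple."""

    unit_id: str
    per_locus_events: dict[str, int] = field(default_factory=dict)
    total_meioses: int = 0
    convention: Convention = "related"

    @property
    def total_events(self) -> int:
        return sum(self.per_locus_events.values())


def parsimony_event_count(
    pedigree: PedigreeGraph, leaf_alleles: Mapping[str, float | None]
) -> int:
    """Minimum number of allele-change events explaining the observed
    alleles of sampled individuals on the pedigree subtree.

    *leaf_alleles* maps sampled IDs to one numeric allele value; ``None``
    marks a missing call, and the corresponding individual is pruned from
    the subtree for this locus.  Any-size change costs one event
    (unordered states), so this is Fitch-style parsimony generalised to
    observed individuals sitting anywhere in the tree, solved by Sankoff
    dynamic programming over the distinct observed alleles.
    """
    informative = {
        i: v for i, v in leaf_alleles.items() if v is not None and i in pedigree.sampled
    }
    if len(informative) < 2:
        log.info(
            "pedigree %s: fewer than 2 informative individuals, count 0",
            pedigree.pedigree_id,
        )
        return 0
    states = sorted(set(informative.values()))
    if len(states) == 1:
        return 0

    sub = steiner_subtree(pedigree, informative.keys())
    state_idx = {s: k for k, s in enumerate(states)}
    n_states = len(states)

    # Root anywhere; iterative post-order Sankoff with unit change cost.
    root = next(iter(informative))
    parent: dict[str, str | None] = {root: None}
    order: list[str] = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in sub.neighbors(node):
            if nb != parent[node]:
                parent[nb] = node
                order.append(nb)
                stack.append(nb)

    cost: dict[str, list[float]] = {}
    for node in reversed(order):
        if node in informative:
            c = [_INF] * n_states
            c[state_idx[informative[node]]] = 0.0
        else:
            c = [0.0] * n_states
        for child in sub.neighbors(node):
            if parent.get(child) != node:
                continue
            cc = cost[child]
            best = min(cc)
            for s in range(n_states):
                # staying in state s is cc[s]; switching costs best + 1
                c[s] += min(cc[s], best + 1.0)
        cost[node] = c
    return int(min(cost[root]))


def count_pedigree_mutations(
    pedigree: PedigreeGraph, haplotypes: Mapping[str, Haplotype], panel: Panel
) -> MutationCount:
    """Parsimony event counts per scored column plus the meiosis count.

    The meiosis denominator (NGEN) is the number of edges of the minimal
    subtree connecting all sampled individuals; multi-copy loci are scored
    per sorted copy column.  Loci with missing calls contribute their
    informative individuals only; the meiosis count is not down-weighted.
    """
    missing_ids = pedigree.sampled - set(haplotypes)
    if missing_ids:
        raise ValueError(
            f"pedigree {pedigree.pedigree_id}: no haplotype for sampled "
            f"individual(s) {sorted(missing_ids)}"
        )
    ngen = steiner_subtree(pedigree).number_of_edges()
    per_locus: dict[str, int] = {}
    for locus in panel.loci:
        for i, col in enumerate(locus.columns):
            leaf_alleles = {
                sid: (
                    haplotypes[sid].alleles[locus.name][i]
                    if locus.name in haplotypes[sid].alleles
                    else None
                )
                for sid in pedigree.sampled
            }
            per_locus[col] = parsimony_event_count(pedigree, leaf_alleles)
    return MutationCount(
        unit_id=pedigree.pedigree_id,
        per_locus_events=per_locus,
        total_meioses=ngen,
        convention="related",
    )


def pair_mutation_count(
    a: Haplotype,
    b: Haplotype,
    panel: Panel,
    convention: Convention,
    meioses: int = 0,
) -> MutationCount:
    """Mutation events separating two haplotypes.

    ``related``: one event per differing column (multi-step changes are
    single events).  ``unrelated``: |allele difference| events per column
    in step units.  Multi-copy loci are compared copy-wise after sorting,
    which is the minimal-total-difference matching for equal-size tuples.
    A locus missing in either haplotype is skipped symmetrically.
    """
    if convention not in ("related", "unrelated"):
        raise ValueError(f"unknown convention {convention!r}")
    per_locus: dict[str, int] = {}
    for locus in panel.loci:
        va = a.alleles.get(locus.name)
        vb = b.alleles.get(locus.name)
        if va is None or vb is None:
            log.info(
                "pair (%s,%s): locus %s missing, skipped",
                a.sample_id,
                b.sample_id,
                locus.name,
            )
            continue
        if len(va) != len(vb):
            raise ValueError(
                f"pair ({a.sample_id},{b.sample_id}): copy count mismatch at "
                f"{locus.name} ({len(va)} vs {len(vb)})"
            )
        for i, col in enumerate(locus.columns):
            step = locus.step_unit
            diff = abs(va[i] - vb[i]) / step
            if convention == "related":
                per_locus[col] = int(diff > 0)
            else:
                per_locus[col] = int(round(diff))
    return MutationCount(
        unit_id=f"{a.sample_id}|{b.sample_id}",
        per_locus_events=per_locus,
        total_meioses=meioses,
        convention=convention,
    )
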