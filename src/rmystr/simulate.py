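"""Forward simulation of Y-STR haplotypes down paternal pedigrees.

Alleles evolve under a symmetric stepwise mutation model: per meiosis each
scored copy of each locus mutates independently with probability mu; a
mutation moves the allele by one repeat unit with probability
1 - p_multistep, otherwise by 1 + Geometric(step_tail) units, with the
direction chosen +/- equiprobably.  Back mutation and homoplasy arise
naturally from this model, which is what makes parsimony counts a (slight)
undercount of the true event number.

The module also builds the three study designs the estimators are tested
on: a deep-rooted pedigree set (26 pedigrees, ~470 meioses connecting
distantly related men), a close-relative couple set (27 couples, 45
meioses: father-son, brothers, uncle-nephew, cousins), and a clustered
"sub-lineage" set (star-of-stars genealogy, nine groups by default)
mimicking unrelated men within a young haplogroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .counting import pair_mutation_count
from .haplotypes import CoupleRecord, Haplotype
from .panels import Panel, load_panel
from .pedigree import PedigreeGraph, meioses_between
from .reference import FOUNDER_ALLELES, default_locus_rates

log = logging.getLogger(__name__)

__all__ = [
    "MutationModel",
    "TruthLogEvent",
    "default_model",
    "default_founder",
    "generate_pedigree",
    "build_star_pedigree",
    "simulate_haplotypes",
    "generate_study_pedigrees",
    "generate_close_couples",
    "generate_lineage_dataset",
    "make_couples",
    "couples_from_pedigree",
    "write_truth_log",
]

#: Nine sub-lineage labels used for the default clustered dataset.
R_M269_SUBLINEAGES = (
    "R-M269*",
    "R-U106",
    "R-L48",
    "R-P312",
    "R-SRY2627",
    "R-U152",
    "R-L2",
    "R-L20",
    "R-L21",
)


@dataclass(frozen=True)
class MutationModel:
    """Stepwise mutation model parameters.

    ``rates`` maps scored column name -> per-meiosis mutation probability.
    ``p_multistep`` is the chance an event exceeds one repeat unit;
    ``step_tail`` the geometric parameter of the extra step count.
    """

    rates: dict[str, float]
    p_multistep: float = 0.04
    step_tail: float = 0.5

    def __post_init__(self) -> None:
        for col, mu in self.rates.items():
            if not 0.0 <= mu <= 1.0:
                raise ValueError(f"rate for {col} out of [0,1]: {mu}")
        if not 0.0 <= self.p_multistep < 1.0:
            raise ValueError(f"p_multistep out of [0,1): {self.p_multistep}")
        if not 0.0 < self.step_tail <= 1.0:
            raise ValueError(f"step_tail out of (0,1]: {self.step_tail}")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rates": {k: float(v) for k, v in self.rates.items()},
            "p_multistep": self.p_multistep,
            "step_tail": self.step_tail,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MutationModel":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(
            rates=dict(payload["rates"]),
            p_multistep=float(payload.get("p_multistep", 0.04)),
            step_tail=float(payload.get("step_tail", 0.5)),
        )

    def scaled(self, factor: float) -> "MutationModel":
        """Model with every per-column rate multiplied by *factor*."""
        return MutationModel(
            {k: min(1.0, v * factor) for k, v in self.rates.items()},
            self.p_multistep,
            self.step_tail,
        )


class TruthLogEvent(NamedTuple):
    """One recorded mutation: which edge (by child), column, and alleles."""

    pedigree_id: str
    child: str
    locus: str
    copy: int
    from_allele: float
    to_allele: float


def default_model(panels: Iterable[Panel] | Panel | None = None) -> MutationModel:
    """Model with published direct-count per-column rates as defaults."""
    if panels is None:
        panels = [load_panel("YFILER"), load_panel("RM13")]
    if isinstance(panels, Panel):
        panels = [panels]
    cols: list[str] = []
    for p in panels:
        cols.extend(c for c in p.columns if c not in cols)
    return MutationModel(default_locus_rates(cols))


def uniform_model(
    panel: Panel, mu: float, p_multistep: float = 0.04, step_tail: float = 0.5
) -> MutationModel:
    """Model with one shared per-column rate (used for calibration runs)."""
    return MutationModel(
        {c: mu for c in panel.columns}, p_multistep, step_tail
    )


def default_founder(panels: Iterable[Panel] | Panel | None = None) -> Haplotype:
    """Founder haplotype at locus-specific modal allele values."""
    if panels is None:
        panels = [load_panel("YFILER"), load_panel("RM13")]
    if isinstance(panels, Panel):
        panels = [panels]
    alleles: dict[str, tuple[float, ...]] = {}
    for p in panels:
        for locus in p.loci:
            alleles[locus.name] = FOUNDER_ALLELES[locus.name]
    return Haplotype("FOUNDER", alleles)


# ---------------------------------------------------------------------------
# pedigree generation


def generate_pedigree(
    n_sampled: int,
    max_depth: int,
    branching: float = 1.2,
    seed: int | np.random.Generator = 0,
    pedigree_id: str = "SIM",
    _max_attempts: int = 200,
) -> PedigreeGraph:
    """Random paternal pedigree with *n_sampled* sampled leaves.

    Grows a sons-tree from a single founder: each man above *max_depth*
    generations fathers Poisson(*branching*) sons.  Sampled individuals
    are drawn among the leaves.  Raises if the requested sample count is
    infeasible for the growth parameters.
    """
    if n_sampled < 2:
        raise ValueError("n_sampled must be >= 2")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(_max_attempts):
        father_of: dict[str, str] = {}
        counter = 0
        frontier = [("I0", 0)]
        leaves: list[str] = []
        while frontier:
            node, depth = frontier.pop(0)
            if depth >= max_depth:
                leaves.append(node)
                continue
            k = int(rng.poisson(branching))
            if k == 0:
                leaves.append(node)
                continue
            for _ in range(k):
                counter += 1
                child = f"I{counter}"
                father_of[child] = node
                frontier.append((child, depth + 1))
        if len(leaves) >= n_sampled and father_of:
            sampled = set(
                rng.choice(sorted(leaves), size=n_sampled, replace=False)
            )
            return PedigreeGraph(pedigree_id, father_of, sampled)
    raise ValueError(
        f"could not grow a pedigree with {n_sampled} sampled leaves "
        f"(max_depth={max_depth}, branching={branching})"
    )


def build_star_pedigree(
    pedigree_id: str, branch_depths: Sequence[int]
) -> PedigreeGraph:
    """Deterministic pedigree: one founder with one descending chain per
    branch; the chain ends are the sampled men.  The subtree meiosis count
    equals the sum of branch depths."""
    if len(branch_depths) < 2 or any(d < 1 for d in branch_depths):
        raise ValueError("need >= 2 branches of depth >= 1")
    father_of: dict[str, str] = {}
    sampled: set[str] = set()
    for b, depth in enumerate(branch_depths):
        parent = "R"
        for g in range(depth):
            node = f"B{b}G{g + 1}"
            father_of[node] = parent
            parent = node
        sampled.add(parent)
    return PedigreeGraph(pedigree_id, father_of, sampled)


# ---------------------------------------------------------------------------
# haplotype evolution


def _model_columns(panel: Panel, model: MutationModel) -> list[tuple[str, int, str, float]]:
    """(locus, copy index, column name, mu) in deterministic panel order."""
    out = []
    for locus in panel.loci:
        for i, col in enumerate(locus.columns):
            if col not in model.rates:
                raise ValueError(f"model missing rate for column {col}")
            out.append((locus.name, i, col, model.rates[col]))
    return out


def _mutate_vector(
    values: np.ndarray,
    mus: np.ndarray,
    model: MutationModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, float, float]]]:
    """One meiosis over all columns; returns new values and
    (column index, from, to) for each event."""
    hits = np.flatnonzero(rng.random(len(values)) < mus)
    if len(hits) == 0:
        return values, []
    out = values.copy()
    events = []
    for j in hits:
        step = 1
        if rng.random() < model.p_multistep:
            step += int(rng.geometric(model.step_tail))
        if rng.random() < 0.5:
            step = -step
        new = out[j] + step
        if new < 0:
            log.warning("allele driven below zero at column %d; reflected", j)
            new = out[j] + abs(step)
        events.append((int(j), float(out[j]), float(new)))
        out[j] = new
    return out, events


def simulate_haplotypes(
    pedigree: PedigreeGraph,
    founder: Haplotype,
    model: MutationModel,
    seed: int | np.random.Generator = 0,
    panel: Panel | Sequence[Panel] | None = None,
) -> tuple[dict[str, Haplotype], list[TruthLogEvent]]:
    """Evolve the founder haplotype down every edge of *pedigree*.

    Returns haplotypes for the sampled individuals and the full truth log
    of mutation events (on all edges, sampled lineages or not).  One
    pseudo-random stream is consumed in deterministic node/column order,
    so identical seeds give identical outputs.
    """
    if panel is None:
        panels = [load_panel("YFILER"), load_panel("RM13")]
    elif isinstance(panel, Panel):
        panels = [panel]
    else:
        panels = list(panel)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    cols: list[tuple[str, int, str, float]] = []
    seen: set[str] = set()
    for p in panels:
        for item in _model_columns(p, model):
            if item[2] not in seen:
                seen.add(item[2])
                cols.append(item)
    for locus, i, col, _ in cols:
        if locus not in founder.alleles or i >= len(founder.alleles[locus]):
            raise ValueError(f"founder missing allele for column {col}")
    mus = np.array([mu for *_, mu in cols])
    founder_vec = np.array(
        [founder.alleles[locus][i] for locus, i, _, _ in cols], dtype=float
    )

    children: dict[str, list[str]] = {}
    roots = []
    for child, father in pedigree.father_of.items():
        children.setdefault(father, []).append(child)
    all_children = set(pedigree.father_of)
    roots = sorted(n for n in pedigree.individuals if n not in all_children)
    if len(roots) != 1:
        raise ValueError(
            f"pedigree {pedigree.pedigree_id}: need exactly one founder to "
            f"simulate from, found {roots}"
        )

    values: dict[str, np.ndarray] = {roots[0]: founder_vec}
    truth: list[TruthLogEvent] = []
    queue = [roots[0]]
    while queue:
        node = queue.pop(0)
        for child in sorted(children.get(node, [])):
            vec, events = _mutate_vector(values[node], mus, model, rng)
            values[child] = vec
            for j, frm, to in events:
                locus, copy_i, _, _ = cols[j]
                truth.append(
                    TruthLogEvent(pedigree.pedigree_id, child, locus, copy_i, frm, to)
                )
            queue.append(child)

    haplotypes: dict[str, Haplotype] = {}
    for sid in sorted(pedigree.sampled):
        alleles: dict[str, list[float]] = {}
        for j, (locus, copy_i, _, _) in enumerate(cols):
            alleles.setdefault(locus, []).append(float(values[sid][j]))
        haplotypes[sid] = Haplotype(sid, {k: tuple(v) for k, v in alleles.items()})
    return haplotypes, truth


def write_truth_log(path: str | Path, events: Sequence[TruthLogEvent]) -> None:
    pd.DataFrame(
        events,
        columns=["pedigree_id", "child", "locus", "copy", "from", "to"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# study designs


def generate_study_pedigrees(
    seed: int | np.random.Generator = 0,
    n_pedigrees: int = 26,
    min_branch_depth: int = 1,
    max_branch_depth: int = 13,
    n_three_branch: int = 14,
) -> list[PedigreeGraph]:
    """Deep-rooted pedigree set emulating the distantly-related design.

    Default scale: 26 pedigrees connecting 66 sampled men (twelve
    pedigrees with two sampled, fourteen with three), branch depths
    uniform on 1-13 generations — pairwise separations up to 26 meioses
    and ~470 subtree meioses in total, the scale and separation profile
    of the published pedigree set.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pedigrees = []
    for k in range(n_pedigrees):
        n_branches = 3 if k < n_three_branch else 2
        depths = [
            int(rng.integers(min_branch_depth, max_branch_depth + 1))
            for _ in range(n_branches)
        ]
        pedigrees.append(build_star_pedigree(f"G{k + 1:02d}", depths))
    return pedigrees


_CLOSE_TOPOLOGIES = {
    # relationship -> branch depths from the shared ancestor
    "father-son": (1,),  # special-cased: ancestor himself is sampled
    "brothers": (1, 1),
    "uncle-nephew": (1, 2),
    "cousins": (2, 2),
}

#: Couple mixture matching the published close-relative set:
#: 27 couples spanning 45 meioses in total.
CLOSE_COUPLE_MIX = (
    ("father-son", 15),
    ("brothers", 8),
    ("uncle-nephew", 2),
    ("cousins", 2),
)


def _close_pedigree(pedigree_id: str, relationship: str) -> PedigreeGraph:
    if relationship == "father-son":
        g = PedigreeGraph(pedigree_id, {"S": "R"}, {"R", "S"})
        return g
    depths = _CLOSE_TOPOLOGIES[relationship]
    return build_star_pedigree(pedigree_id, depths)


def generate_close_couples(
    model: MutationModel,
    seed: int | np.random.Generator = 0,
    mix: Sequence[tuple[str, int]] = CLOSE_COUPLE_MIX,
    panel: Panel | Sequence[Panel] | None = None,
    founder: Haplotype | None = None,
) -> tuple[dict[str, Haplotype], list[CoupleRecord], list[PedigreeGraph]]:
    """Close-relative couple set (father-son, brothers, uncle-nephew,
    cousins).  Default mixture: 27 couples over 45 meioses."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    founder = founder or default_founder(panel)
    haplotypes: dict[str, Haplotype] = {}
    couples: list[CoupleRecord] = []
    pedigrees: list[PedigreeGraph] = []
    idx = 0
    for relationship, count in mix:
        for _ in range(count):
            idx += 1
            pid = f"C{idx:02d}"
            ped = _close_pedigree(pid, relationship)
            haps, _ = simulate_haplotypes(ped, founder, model, rng, panel)
            a, b = sorted(ped.sampled)
            ha = Haplotype(f"{pid}_{a}", dict(haps[a].alleles))
            hb = Haplotype(f"{pid}_{b}", dict(haps[b].alleles))
            haplotypes[ha.sample_id] = ha
            haplotypes[hb.sample_id] = hb
            couples.append(
                CoupleRecord(
                    ha.sample_id,
                    hb.sample_id,
                    meioses=meioses_between(ped, a, b),
                    relationship=relationship,
                    dataset_tag="B",
                )
            )
            pedigrees.append(ped)
    return haplotypes, couples, pedigrees


def _evolve(
    vec: np.ndarray,
    n_meioses: int,
    mus: np.ndarray,
    model: MutationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    for _ in range(n_meioses):
        vec, _ = _mutate_vector(vec, mus, model, rng)
    return vec


def generate_lineage_dataset(
    n_groups: int,
    samples_per_group: int,
    divergence_meioses: int,
    within_meioses: int,
    model: MutationModel,
    seed: int | np.random.Generator = 0,
    panel: Panel | Sequence[Panel] | None = None,
    group_names: Sequence[str] | None = None,
    founder: Haplotype | None = None,
) -> tuple[dict[str, Haplotype], dict[str, str]]:
    """Clustered haplotype set on a star-of-stars genealogy.

    Group founders diverge from a common root by *divergence_meioses*;
    each sample diverges from its group founder by *within_meioses*.
    Returns haplotypes and a sample -> group label mapping.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    if samples_per_group < 1 or divergence_meioses < 0 or within_meioses < 0:
        raise ValueError("invalid lineage dataset parameters")
    if group_names is None:
        group_names = (
            R_M269_SUBLINEAGES
            if n_groups == len(R_M269_SUBLINEAGES)
            else tuple(f"G{g + 1}" for g in range(n_groups))
        )
    if len(group_names) != n_groups:
        raise ValueError("group_names length must equal n_groups")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if panel is None:
        panels = [load_panel("YFILER"), load_panel("RM13")]
    elif isinstance(panel, Panel):
        panels = [panel]
    else:
        panels = list(panel)
    founder = founder or default_founder(panels)
    cols: list[tuple[str, int, str, float]] = []
    seen: set[str] = set()
    for p in panels:
        for item in _model_columns(p, model):
            if item[2] not in seen:
                seen.add(item[2])
                cols.append(item)
    mus = np.array([mu for *_, mu in cols])
    root = np.array([founder.alleles[locus][i] for locus, i, _, _ in cols], dtype=float)

    haplotypes: dict[str, Haplotype] = {}
    labels: dict[str, str] = {}
    for g, name in enumerate(group_names):
        gf = _evolve(root.copy(), divergence_meioses, mus, model, rng)
        for s in range(samples_per_group):
            vec = _evolve(gf.copy(), within_meioses, mus, model, rng)
            sid = f"S{g + 1:02d}_{s + 1:02d}"
            alleles: dict[str, list[float]] = {}
            for j, (locus, _, _, _) in enumerate(cols):
                alleles.setdefault(locus, []).append(float(vec[j]))
            haplotypes[sid] = Haplotype(sid, {k: tuple(v) for k, v in alleles.items()})
            labels[sid] = name
    return haplotypes, labels


def unrelated_haplotype(
    model: MutationModel,
    meioses: int,
    seed: int | np.random.Generator = 0,
    panel: Panel | Sequence[Panel] | None = None,
    founder: Haplotype | None = None,
    sample_id: str = "UNREL",
) -> Haplotype:
    """A haplotype evolved independently from the founder for *meioses*
    transmissions — e.g. the true profile behind a non-paternity event."""
    if panel is None:
        panels = [load_panel("YFILER"), load_panel("RM13")]
    elif isinstance(panel, Panel):
        panels = [panel]
    else:
        panels = list(panel)
    founder = founder or default_founder(panels)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cols: list[tuple[str, int, str, float]] = []
    seen: set[str] = set()
    for p in panels:
        for item in _model_columns(p, model):
            if item[2] not in seen:
                seen.add(item[2])
                cols.append(item)
    mus = np.array([mu for *_, mu in cols])
    vec = np.array([founder.alleles[locus][i] for locus, i, _, _ in cols], dtype=float)
    vec = _evolve(vec, meioses, mus, model, rng)
    alleles: dict[str, list[float]] = {}
    for j, (locus, _, _, _) in enumerate(cols):
        alleles.setdefault(locus, []).append(float(vec[j]))
    return Haplotype(sample_id, {k: tuple(v) for k, v in alleles.items()})


def make_couples(
    haplotypes: dict[str, Haplotype],
    panel: Panel,
    max_step_distance: int,
    labels: dict[str, str] | None = None,
) -> list[CoupleRecord]:
    """All unordered sample pairs whose step distance over *panel* (sum of
    copy-matched absolute allele differences) is <= *max_step_distance*.

    With group *labels*, same-group couples are tagged C1 and cross-group
    couples C2.  A sample may appear in any number of couples.
    """
    if max_step_distance < 0:
        raise ValueError("max_step_distance must be >= 0")
    ids = sorted(haplotypes)
    out: list[CoupleRecord] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = pair_mutation_count(
                haplotypes[a], haplotypes[b], panel, "unrelated"
            ).total_events
            if d > max_step_distance:
                continue
            ga = labels.get(a) if labels else None
            gb = labels.get(b) if labels else None
            tag = "" if ga is None or gb is None else ("C1" if ga == gb else "C2")
            out.append(
                CoupleRecord(
                    a, b, meioses=None, relationship="unrelated",
                    dataset_tag=tag, group_a=ga, group_b=gb,
                )
            )
    return out


def couples_from_pedigree(
    pedigree: PedigreeGraph, dataset_tag: str = "A"
) -> list[CoupleRecord]:
    """All within-pedigree pairs of sampled men with their meiosis
    separations (the pairwise comparisons used for diachronic binning)."""
    ids = sorted(pedigree.sampled)
    return [
        CoupleRecord(
            a,
            b,
            meioses=meioses_between(pedigree, a, b),
            relationship="pedigree-pair",
            dataset_tag=dataset_tag,
        )
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    ]
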