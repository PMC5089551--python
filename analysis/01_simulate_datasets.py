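#!/usr/bin/env python
"""Simulate the three study datasets and write them as plain tables.

Dataset A: 29 deep-rooted paternal pedigrees (26 regular plus 3 carrying
an undetected non-paternity event), ~470 subtree meioses among the
regular ones.  Dataset B: 27 close-relative
couples spanning 45 meioses.  Dataset C: 90 haplotypes clustered into 9
sub-lineage groups.  Everything downstream (02-05) reads these files.
"""

import argparse
from pathlib import Path

import pandas as pd

from rmystr.haplotypes import write_couples, write_haplotype_table
from rmystr.panels import load_panel
from rmystr.pedigree import PedigreeGraph, steiner_subtree, write_pedigree
from rmystr.simulate import (
    build_star_pedigree,
    default_founder,
    default_model,
    generate_close_couples,
    generate_lineage_dataset,
    generate_study_pedigrees,
    simulate_haplotypes,
    unrelated_haplotype,
    write_truth_log,
)

#: Non-paternity pedigrees: (id, branch depths, meioses separating the
#: spurious lineage from the shared founder).  A false paternal link makes
#: one sampled man effectively unrelated, so his haplotype is replaced by
#: an independently evolved one; shallow pedigrees then show the most
#: extreme mutations/meioses ratios, deep ones milder ones.
NON_PATERNITY = (
    ("G27", (2, 2), 150),
    ("G28", (5, 6), 150),
    ("G29", (8, 9), 150),
)


def prefixed(ped: PedigreeGraph) -> PedigreeGraph:
    p = ped.pedigree_id
    return PedigreeGraph(
        p,
        {f"{p}_{c}": f"{p}_{f}" for c, f in ped.father_of.items()},
        {f"{p}_{s}" for s in ped.sampled},
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.out
    (out / "pedigrees").mkdir(parents=True, exist_ok=True)

    panels = [load_panel("YFILER"), load_panel("RM13")]
    model = default_model(panels)
    founder = default_founder(panels)

    # --- Dataset A: deep pedigrees, plus three non-paternity outliers
    pedigrees = [prefixed(p) for p in generate_study_pedigrees(args.seed)]
    spurious: dict[str, int] = {}
    for pid, depths, split in NON_PATERNITY:
        ped = prefixed(build_star_pedigree(pid, list(depths)))
        pedigrees.append(ped)
        spurious[pid] = split

    haplotypes, truth = [], []
    for k, ped in enumerate(pedigrees):
        haps, events = simulate_haplotypes(ped, founder, model, args.seed + 100 + k, panels)
        if ped.pedigree_id in spurious:
            victim = sorted(ped.sampled)[-1]
            swap = unrelated_haplotype(
                model, spurious[ped.pedigree_id], args.seed + 700 + k,
                panels, founder, sample_id=victim,
            )
            haps[victim] = swap
        write_pedigree(out / "pedigrees" / f"{ped.pedigree_id}.tsv", ped)
        haplotypes.extend(haps.values())
        truth.extend(events)
    for panel in panels:
        write_haplotype_table(out / f"haplotypes_A_{panel.name}.tsv", haplotypes, panel)
    write_truth_log(out / "truth_log_A.tsv", truth)
    regular = [p for p in pedigrees if int(p.pedigree_id[1:]) <= 26]
    total = sum(steiner_subtree(p).number_of_edges() for p in regular)
    print(f"dataset A: {len(pedigrees)} pedigrees "
          f"({len(regular)} regular spanning {total} meioses, "
          f"{len(NON_PATERNITY)} with a non-paternity event)")

    # --- Dataset B: close-relative couples
    b_haps, b_couples, _ = generate_close_couples(
        model, args.seed + 500, panel=panels, founder=founder
    )
    for panel in panels:
        write_haplotype_table(out / f"haplotypes_B_{panel.name}.tsv",
                              list(b_haps.values()), panel)
    write_couples(out / "couples_B.tsv", b_couples)
    print(f"dataset B: {len(b_couples)} couples, "
          f"{sum(c.meioses for c in b_couples)} meioses")

    # --- Dataset C: nine clustered sub-lineages
    c_haps, labels = generate_lineage_dataset(
        9, 10, divergence_meioses=22, within_meioses=35,
        model=model, seed=args.seed + 900, panel=panels,
    )
    for panel in panels:
        write_haplotype_table(out / f"haplotypes_C_{panel.name}.tsv",
                              list(c_haps.values()), panel)
    pd.DataFrame(sorted(labels.items()), columns=["sample_id", "group"]).to_csv(
        out / "labels_C.tsv", sep="\t", index=False
    )
    print(f"dataset C: {len(c_haps)} haplotypes in "
          f"{len(set(labels.values()))} groups -> {out}")


if __name__ == "__main__":
    main()
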