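#!/usr/bin/env python
"""Discriminating power between couples, by panel and relatedness class.

Close relatives (Dataset B): fraction of couples differing per panel and
mean mutations per couple (multi-step as single events).  Unrelated men
(Dataset C): mean independent-event mutation counts for same-lineage (C1)
and cross-lineage (C2) couples, with percentile-bootstrap CIs — the
relatedness gradient B < C1 < C2 is the phylogenetic-signal readout.
"""

import argparse
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from rmystr.counting import pair_mutation_count
from rmystr.discrimination import bootstrap_ci, per_couple_counts, summarize
from rmystr.haplotypes import Haplotype, read_couples, read_haplotype_table
from rmystr.panels import load_panel

PANEL_NAMES = ("YFILER", "RM11", "RM13")


def read_merged_haplotypes(sim: Path, tag: str) -> dict[str, Haplotype]:
    merged: dict[str, dict] = {}
    for panel in (load_panel("YFILER"), load_panel("RM13")):
        for h in read_haplotype_table(sim / f"haplotypes_{tag}_{panel.name}.tsv", panel):
            merged.setdefault(h.sample_id, {}).update(h.alleles)
    return {sid: Haplotype(sid, alleles) for sid, alleles in merged.items()}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    # --- Dataset B
    b_haps = read_merged_haplotypes(args.sim, "B")
    b_couples = read_couples(args.sim / "couples_B.tsv")
    rows = []
    for name in PANEL_NAMES:
        s = summarize(b_couples, b_haps, load_panel(name), "related",
                      B=args.bootstrap, seed=args.seed)
        rows.append(
            {
                "panel": s.panel, "dataset_tag": "B", "n_couples": s.n_couples,
                "n_differing": s.n_differing, "power_pct": s.power_pct,
                "mean_mutations": round(s.mean_mutations, 2),
                "ci_low": round(s.boot_ci[0], 2), "ci_high": round(s.boot_ci[1], 2),
                "B": s.B, "seed": s.seed,
            }
        )
    power = pd.DataFrame(rows)
    power.to_csv(args.out / "discrimination_B.tsv", sep="\t", index=False)
    print("close-relative discrimination (related-event convention):")
    print(power.to_string(index=False))

    # --- Dataset C: same- vs cross-lineage couples, study-sized sets
    c_haps = read_merged_haplotypes(args.sim, "C")
    labels = dict(
        pd.read_csv(args.sim / "labels_C.tsv", sep="\t").values
    )
    rng = np.random.default_rng(args.seed)
    ids = sorted(c_haps)
    pair_pool = {"C1": [], "C2": []}
    for a, b in itertools.combinations(ids, 2):
        pair_pool["C1" if labels[a] == labels[b] else "C2"].append((a, b))
    chosen = {
        "C1": [pair_pool["C1"][i] for i in rng.choice(len(pair_pool["C1"]), 30, replace=False)],
        "C2": [pair_pool["C2"][i] for i in rng.choice(len(pair_pool["C2"]), 37, replace=False)],
    }
    fig3_rows = []
    for name in ("RM11", "RM13"):
        panel = load_panel(name)
        b_counts = per_couple_counts(b_couples, b_haps, panel, "unrelated")
        series = {"B": b_counts}
        for tag, pairs in chosen.items():
            series[tag] = [
                pair_mutation_count(c_haps[a], c_haps[b], panel, "unrelated").total_events
                for a, b in pairs
            ]
        for tag, cnt in series.items():
            lo, hi = bootstrap_ci(cnt, B=args.bootstrap, seed=args.seed)
            fig3_rows.append(
                {
                    "panel": name, "dataset_tag": tag, "n_couples": len(cnt),
                    "mean_mutations": round(float(np.mean(cnt)), 2),
                    "ci_low": round(lo, 2), "ci_high": round(hi, 2),
                }
            )
    fig3 = pd.DataFrame(fig3_rows)
    fig3.to_csv(args.out / "mean_mutations_by_class.tsv", sep="\t", index=False)
    print("\nmean independent-event mutations per couple (B vs C1 vs C2):")
    print(fig3.to_string(index=False))


if __name__ == "__main__":
    main()
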