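#!/usr/bin/env python
"""Estimate mutation rates: Grubbs screen, pooled/per-locus/binned tables.

Stage 1 screens the simulated pedigrees' mutations/meioses ratios with
iterated Grubbs tests, which should recover the three injected
non-paternity pedigrees.  Stage 2 pools the surviving counts into pooled
(per panel), per-locus (L=1) and diachronically binned rate tables with
binomial-quantile CIs.  Stage 3 recomputes the published rate tables from
the published direct counts as a cross-check of the estimators.
"""

import argparse
from pathlib import Path

import pandas as pd

from rmystr.counting import MutationCount, pair_mutation_count
from rmystr.haplotypes import Haplotype, read_haplotype_table
from rmystr.panels import load_panel
from rmystr.pedigree import read_pedigree
from rmystr.rates import bin_rates, estimate_rate, grubbs_screen, locus_rates, panel_rate, round_rate
from rmystr.reference import BINNED_COUNTS, LOCUS_NMUT, PEDIGREE_NGEN, POOLED_COUNTS
from rmystr.simulate import couples_from_pedigree

BINS = [(1, 10), (11, 20), (21, 26)]
PANEL_NAMES = ("YFILER", "RM13", "RM11")


def est_row(tag, est):
    return {
        "DATASET": tag, "NGEN": est.NGEN, "NMUT": est.NMUT, "STR_SET": est.panel,
        "MUT_RATE": round_rate(est.rate), "CI_2.5%": round_rate(est.ci_low),
        "CI_97.5%": round_rate(est.ci_high),
    }


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--counts", type=Path, default=Path("results/counts_long.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    long_df = pd.read_csv(args.counts, sep="\t")
    counts: dict[str, dict[str, MutationCount]] = {}
    for (pid, panel), grp in long_df.groupby(["unit_id", "panel"]):
        counts.setdefault(pid, {})[panel] = MutationCount(
            pid,
            dict(zip(grp["locus"], grp["events"])),
            int(grp["meioses"].iloc[0]),
            "related",
        )

    # --- Grubbs screen on combined-panel mutations/meioses ratios
    ratios = {
        pid: sum(mc.total_events for mc in by_panel.values()) / by_panel["RM13"].total_meioses
        for pid, by_panel in counts.items()
    }
    screen = grubbs_screen(ratios, args.alpha)
    pd.DataFrame(
        [{"pedigree_id": pid, "p_value": p} for pid, p in screen.excluded]
    ).to_csv(args.out / "grubbs_excluded.tsv", sep="\t", index=False)
    print(f"Grubbs screen: excluded {[pid for pid, _ in screen.excluded]} "
          f"(final p = {screen.final_p:.2f})")
    retained = screen.retained

    # --- pooled and per-locus rates on the survivors
    pooled_rows, locus_rows = [], []
    for name in PANEL_NAMES:
        panel = load_panel(name)
        source = "RM13" if name == "RM11" else name
        kept = [counts[pid][source] for pid in retained]
        pooled_rows.append(est_row("A", panel_rate(kept, panel, args.alpha)))
        for col, lr in locus_rates(kept, panel, args.alpha).items():
            locus_rows.append(
                {
                    "STR_SET": name, "LOCUS": col, "NMUT": lr.NMUT,
                    "MUT_RATE": round_rate(lr.rate),
                    "CI_2.5%": round_rate(lr.ci_low),
                    "CI_97.5%": round_rate(lr.ci_high),
                }
            )

    # --- diachronic bins over within-pedigree pairwise comparisons
    panels = [load_panel("YFILER"), load_panel("RM13")]
    haps: dict[str, dict] = {}
    for panel in panels:
        for h in read_haplotype_table(args.sim / f"haplotypes_A_{panel.name}.tsv", panel):
            haps.setdefault(h.sample_id, {}).update(h.alleles)
    haplotypes = {sid: Haplotype(sid, alleles) for sid, alleles in haps.items()}
    pair_counts: dict[str, list[MutationCount]] = {"YFILER": [], "RM13": []}
    for pid in retained:
        ped = read_pedigree(args.sim / "pedigrees" / f"{pid}.tsv")
        for c in couples_from_pedigree(ped):
            for panel in panels:
                pair_counts[panel.name].append(
                    pair_mutation_count(
                        haplotypes[c.sample_a], haplotypes[c.sample_b],
                        panel, "related", c.meioses or 0,
                    )
                )
    binned_rows = []
    for name in PANEL_NAMES:
        panel = load_panel(name)
        source = "RM13" if name == "RM11" else name
        for (lo, hi), est in bin_rates(pair_counts[source], panel, BINS, args.alpha).items():
            binned_rows.append(est_row(f"A ({lo}-{hi})", est))

    pd.DataFrame(pooled_rows).to_csv(args.out / "pooled_rates_sim.tsv", sep="\t", index=False)
    pd.DataFrame(locus_rows).to_csv(args.out / "locus_rates_sim.tsv", sep="\t", index=False)
    pd.DataFrame(binned_rows).to_csv(args.out / "binned_rates_sim.tsv", sep="\t", index=False)
    print("simulated pooled rates:")
    print(pd.DataFrame(pooled_rows).to_string(index=False))

    # --- published counts re-run through the same estimators
    ref_rows = []
    for ds, by_panel in POOLED_COUNTS.items():
        for name, (ngen, nmut) in by_panel.items():
            L = load_panel(name).scored_locus_count
            ref_rows.append(est_row(ds, estimate_rate(nmut, ngen, L, name)))
    for (lo, hi), by_panel in BINNED_COUNTS.items():
        for name, (ngen, nmut) in by_panel.items():
            L = load_panel(name).scored_locus_count
            ref_rows.append(est_row(f"A + B ({lo}-{hi})", estimate_rate(nmut, ngen, L, name)))
    pd.DataFrame(ref_rows).to_csv(args.out / "pooled_rates_published_counts.tsv",
                                  sep="\t", index=False)
    ref_locus = [
        {
            "LOCUS": col, "NMUT": nmut,
            **{k: v for k, v in est_row("", estimate_rate(nmut, PEDIGREE_NGEN, 1, "locus")).items()
               if k in ("MUT_RATE", "CI_2.5%", "CI_97.5%")},
        }
        for col, nmut in LOCUS_NMUT.items()
    ]
    pd.DataFrame(ref_locus).to_csv(args.out / "locus_rates_published_counts.tsv",
                                   sep="\t", index=False)
    print(f"reference tables recomputed from published counts -> {args.out}")


if __name__ == "__main__":
    main()
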