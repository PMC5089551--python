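#!/usr/bin/env python
"""DAPC classification of the clustered haplotypes into sub-lineages.

Fits PCA + LDA on single-copy loci for three feature sets (Yfiler, RM11,
Yfiler + RM11), writes admixture-plot-ready membership tables and the
per-group average membership probabilities (amp).  The comparison of amp
across feature sets measures how much phylogenetic signal each panel
retains within a young, homoplasy-prone haplogroup.
"""

import argparse
from pathlib import Path

import pandas as pd

from rmystr.dapc import encode, export_membership_table, fit_dapc, membership
from rmystr.haplotypes import Haplotype, read_haplotype_table
from rmystr.panels import load_panel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    merged: dict[str, dict] = {}
    for panel in (load_panel("YFILER"), load_panel("RM13")):
        for h in read_haplotype_table(args.sim / f"haplotypes_C_{panel.name}.tsv", panel):
            merged.setdefault(h.sample_id, {}).update(h.alleles)
    haps = {sid: Haplotype(sid, alleles) for sid, alleles in merged.items()}
    labels = dict(pd.read_csv(args.sim / "labels_C.tsv", sep="\t").values)

    feature_sets = {
        "YFILER": list(load_panel("YFILER").single_copy_loci),
        "RM11": list(load_panel("RM11").single_copy_loci),
        "YFILER+RM11": list(load_panel("YFILER").single_copy_loci)
        + list(load_panel("RM11").single_copy_loci),
    }
    amp_rows = []
    for name, loci in feature_sets.items():
        enc = encode(haps, loci)
        model = fit_dapc(enc, labels)
        mm = membership(model, enc, labels)
        export_membership_table(mm, labels).to_csv(
            args.out / f"membership_{name.replace('+', '_')}.tsv",
            sep="\t", index=False,
        )
        for group, value in sorted(mm.amp.items()):
            amp_rows.append(
                {"feature_set": name, "n_pc": model.n_pc,
                 "group": group, "amp": round(value, 2)}
            )
    amp = pd.DataFrame(amp_rows)
    amp.to_csv(args.out / "amp_by_feature_set.tsv", sep="\t", index=False)
    print("average membership probability (amp) per group:")
    print(amp.pivot(index="group", columns="feature_set", values="amp").to_string())
    means = amp.groupby("feature_set")["amp"].mean().round(3)
    print("\nmean amp per feature set:")
    print(means.to_string())


if __name__ == "__main__":
    main()
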