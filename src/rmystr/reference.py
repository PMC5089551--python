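"""Published direct-count reference data for Yfiler and RM Y-STR panels.

These counts come from a deep-rooted paternal pedigree study of two
Northern-Italian populations: 26 retained pedigrees spanning 470
father-to-son transmissions (meioses) for the distantly-related set, a
close-relative set of 27 couples spanning 45 meioses, and 97 merged
within-pedigree pairwise comparisons binned by separation (1-10, 11-20,
21-26 meioses).  They serve two purposes here: as inputs for recomputing
the published rate tables with this package's estimators, and as default
per-column mutation probabilities for the stepwise simulator.
"""

from __future__ import annotations

__all__ = [
    "PEDIGREE_NGEN",
    "N_PEDIGREES",
    "CLOSE_NGEN",
    "N_CLOSE_COUPLES",
    "LOCUS_NMUT",
    "POOLED_COUNTS",
    "BINNED_COUNTS",
    "CLOSE_RELATIVE_DIFFERING",
    "default_locus_rates",
]

#: Total meioses observed across the 26 retained deep-rooted pedigrees.
PEDIGREE_NGEN = 470
N_PEDIGREES = 26

#: Close-relative couple set: 27 couples, 45 meioses in total.
CLOSE_NGEN = 45
N_CLOSE_COUPLES = 27

#: Observed mutation events per scored column over the 470 pedigree meioses.
#: Yfiler columns first (17), then RM columns (14).
LOCUS_NMUT: dict[str, int] = {
    # Yfiler
    "DYS393": 2,
    "DYS390": 3,
    "DYS19": 2,
    "DYS391": 1,
    "DYS385a": 2,
    "DYS385b": 0,
    "DYS439": 1,
    "DYS389I": 1,
    "DYS392": 1,
    "DYS389II": 2,
    "DYS458": 6,
    "DYS437": 1,
    "DYS448": 0,
    "YGATAH4": 1,
    "DYS456": 1,
    "DYS438": 0,
    "DYS635": 2,
    # RM Y-STRs
    "DYS576": 5,
    "DYF399S1": 30,
    "DYF387S1": 6,
    "DYS570": 2,
    "DYS526A+B": 3,
    "DYS626": 3,
    "DYS627": 9,
    "DYS518": 6,
    "DYS612": 5,
    "DYS449": 2,
    "DYS547": 7,
    "DYF404S1": 4,
    "DYF403S1a": 12,
    "DYF403S1b": 2,
}

#: Pooled (NGEN, NMUT) per dataset and panel: dataset -> panel -> (ngen, nmut).
POOLED_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "A": {"YFILER": (470, 26), "RM13": (470, 96), "RM11": (470, 54)},
    "B": {"YFILER": (45, 3), "RM13": (45, 10), "RM11": (45, 4)},
}

#: Diachronic bins over the merged pairwise comparisons:
#: (lo, hi) meioses -> panel -> (ngen, nmut).
BINNED_COUNTS: dict[tuple[int, int], dict[str, tuple[int, int]]] = {
    (1, 10): {"YFILER": (168, 8), "RM13": (168, 34), "RM11": (168, 17)},
    (11, 20): {"YFILER": (447, 23), "RM13": (447, 87), "RM11": (447, 58)},
    (21, 26): {"YFILER": (630, 34), "RM13": (630, 109), "RM11": (630, 76)},
}

#: Of the 27 close-relative couples, how many show differing haplotypes.
CLOSE_RELATIVE_DIFFERING: dict[str, int] = {"YFILER": 2, "RM11": 4, "RM13": 9}

#: Typical modal allele values used as the default simulator founder.
#: Absolute values are irrelevant to mutation counting (only differences
#: matter); these keep simulated tables in a realistic allele range.
FOUNDER_ALLELES: dict[str, tuple[float, ...]] = {
    "DYS393": (13,),
    "DYS390": (24,),
    "DYS19": (14,),
    "DYS391": (11,),
    "DYS385": (11, 14),
    "DYS439": (12,),
    "DYS389I": (13,),
    "DYS392": (13,),
    "DYS389II": (29,),
    "DYS458": (17,),
    "DYS437": (15,),
    "DYS448": (19,),
    "YGATAH4": (12,),
    "DYS456": (15,),
    "DYS438": (12,),
    "DYS635": (23,),
    "DYS576": (18,),
    "DYF399S1": (23,),
    "DYF387S1": (37,),
    "DYS570": (17,),
    "DYS526A+B": (49,),
    "DYS626": (31,),
    "DYS627": (21,),
    "DYS518": (38,),
    "DYS612": (28,),
    "DYS449": (30,),
    "DYS547": (45,),
    "DYF404S1": (17,),
    "DYF403S1a": (42,),
    "DYF403S1b": (49,),
}


def default_locus_rates(columns) -> dict[str, float]:
    """Per-column mutation probabilities from the published direct counts.

    Each column's rate is its observed event count divided by the 470
    pedigree meioses.  Columns with zero observed events get rate 0.
    """
    try:
        return {c: LOCUS_NMUT[c] / PEDIGREE_NGEN for c in columns}
    except KeyError as exc:
        raise KeyError(f"no published count for column {exc.args[0]!r}") from None
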