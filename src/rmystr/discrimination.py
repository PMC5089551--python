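"""Discriminating power of a panel between couples of individuals.

Discriminatory power is the fraction of compared couples whose haplotypes
differ at one or more scored columns of the panel.  The complementary
summary is the mean number of mutations separating a couple, with a 95%
bootstrap interval obtained by resampling couples (their mutation counts)
with replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .counting import Convention, pair_mutation_count
from .haplotypes import CoupleRecord, Haplotype
from .panels import Panel, load_panel

__all__ = [
    "DiscriminationSummary",
    "per_couple_counts",
    "discriminating_power",
    "mean_pair_mutations",
    "bootstrap_ci",
    "yfiler_step_distance",
    "summarize",
    "format_pct",
]


@dataclass(frozen=True)
class DiscriminationSummary:
    panel: str
    n_couples: int
    n_differing: int
    power: float
    mean_mutations: float
    boot_ci: tuple[float, float]
    B: int
    seed: int

    @property
    def power_pct(self) -> float:
        return format_pct(self.power)


def format_pct(fraction: float) -> float:
    """Percentage to two decimals, rounding half-up through a 3-decimal
    intermediate (the convention that prints 4/27 as 14.82)."""
    pct = Decimal(repr(fraction)) * 100
    three = pct.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    return float(three.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def per_couple_counts(
    couples: Sequence[CoupleRecord],
    haplotypes: Mapping[str, Haplotype],
    panel: Panel,
    convention: Convention,
) -> list[int]:
    """Total mutation events per couple under the given convention."""
    if not couples:
        raise ValueError("empty couple list")
    counts = []
    for c in couples:
        for sid in (c.sample_a, c.sample_b):
            if sid not in haplotypes:
                raise KeyError(f"no haplotype for couple member {sid}")
        counts.append(
            pair_mutation_count(
                haplotypes[c.sample_a], haplotypes[c.sample_b], panel, convention
            ).total_events
        )
    return counts


def discriminating_power(
    couples: Sequence[CoupleRecord],
    haplotypes: Mapping[str, Haplotype],
    panel: Panel,
    convention: Convention = "related",
) -> tuple[int, int, float]:
    """(n_couples, n_differing, power fraction)."""
    counts = per_couple_counts(couples, haplotypes, panel, convention)
    n_diff = sum(1 for c in counts if c > 0)
    return len(counts), n_diff, n_diff / len(counts)


def mean_pair_mutations(
    couples: Sequence[CoupleRecord],
    haplotypes: Mapping[str, Haplotype],
    panel: Panel,
    convention: Convention,
) -> float:
    counts = per_couple_counts(couples, haplotypes, panel, convention)
    return float(np.mean(counts))


def bootstrap_ci(
    per_couple: Sequence[float],
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the mean per-couple mutation count:
    resample couples with replacement *B* times."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if not len(per_couple):
        raise ValueError("empty count list")
    rng = np.random.default_rng(seed)
    arr = np.asarray(per_couple, dtype=float)
    idx = rng.integers(0, len(arr), size=(B, len(arr)))
    means = arr[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def yfiler_step_distance(a: Haplotype, b: Haplotype) -> int:
    """Sum of copy-matched absolute allele differences over the Yfiler
    panel (the unrelated-convention count restricted to Yfiler)."""
    panel = load_panel("YFILER")
    for h in (a, b):
        missing = [l.name for l in panel.loci if l.name not in h.alleles]
        if missing:
            raise ValueError(
                f"sample {h.sample_id} missing Yfiler loci: {missing}"
            )
    return pair_mutation_count(a, b, panel, "unrelated").total_events


def summarize(
    couples: Sequence[CoupleRecord],
    haplotypes: Mapping[str, Haplotype],
    panel: Panel,
    convention: Convention,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DiscriminationSummary:
    """Full per-panel discrimination summary for one couple set."""
    counts = per_couple_counts(couples, haplotypes, panel, convention)
    n_diff = sum(1 for c in counts if c > 0)
    return DiscriminationSummary(
        panel=panel.name,
        n_couples=len(counts),
        n_differing=n_diff,
        power=n_diff / len(counts),
        mean_mutations=float(np.mean(counts)),
        boot_ci=bootstrap_ci(counts, B=B, alpha=alpha, seed=seed),
        B=B,
        seed=seed,
    )
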