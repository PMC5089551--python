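"""Mutation-rate estimation with binomial-quantile confidence intervals.

The direct-count estimator divides total observed mutation events (NMUT)
by total meioses (NGEN) and by the number of scored columns (L).  The 95%
interval follows the quantile construction: take the 2.5% and 97.5%
quantiles of Binomial(n=NGEN, p=NMUT/NGEN) — the smallest k whose CDF
reaches the requested probability — and divide by NGEN x L.  Note the
binomial size is the meiosis count, not NGEN x L; this is the construction
that reproduces published pedigree-study interval endpoints exactly.

Outlier pedigrees (candidate non-paternity events) are screened by
iterating two-sided Grubbs tests on the per-pedigree mutations/meioses
ratios until the extreme ratio is no longer significant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .counting import MutationCount
from .panels import Panel

log = logging.getLogger(__name__)

__all__ = [
    "RateEstimate",
    "GrubbsResult",
    "pooled_rate",
    "binomial_ci",
    "estimate_rate",
    "locus_rates",
    "grubbs_screen",
    "bin_rates",
    "round_rate",
]


def round_rate(x: float, ndigits: int = 5) -> float:
    """Round half-up to *ndigits* decimals (tabular reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEstimate:
    """A pooled or per-locus mutation rate with its binomial-quantile CI."""

    panel: str
    NGEN: int
    NMUT: int
    L: int
    rate: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def rounded(self, ndigits: int = 5) -> tuple[float, float, float]:
        return (
            round_rate(self.rate, ndigits),
            round_rate(self.ci_low, ndigits),
            round_rate(self.ci_high, ndigits),
        )


def pooled_rate(NMUT: int, NGEN: int, L: int) -> float:
    """Direct-count mutation rate NMUT / (NGEN x L), per locus per meiosis."""
    if NGEN <= 0 or L <= 0:
        raise ValueError(f"NGEN and L must be positive (got {NGEN}, {L})")
    if NMUT < 0:
        raise ValueError(f"NMUT must be >= 0 (got {NMUT})")
    return NMUT / (NGEN * L)


def binomial_ci(
    NMUT: int, NGEN: int, L: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Quantile-based CI: q(alpha/2) and q(1 - alpha/2) of
    Binomial(NGEN, NMUT/NGEN), each divided by NGEN x L.

    q(u) is the smallest integer k with CDF(k) >= u.  For NMUT = 0 the
    distribution is degenerate and both endpoints are 0.
    """
    if NGEN <= 0 or L <= 0:
        raise ValueError(f"NGEN and L must be positive (got {NGEN}, {L})")
    if not 0 <= NMUT <= NGEN:
        raise ValueError(f"NMUT must be in [0, NGEN] (got {NMUT}, NGEN={NGEN})")
    if NMUT == 0:
        return 0.0, 0.0
    p = NMUT / NGEN
    lo = float(stats.binom.ppf(alpha / 2, NGEN, p))
    hi = float(stats.binom.ppf(1 - alpha / 2, NGEN, p))
    return lo / (NGEN * L), hi / (NGEN * L)


def estimate_rate(
    NMUT: int, NGEN: int, L: int, panel: str = "", alpha: float = 0.05
) -> RateEstimate:
    """Convenience wrapper combining :func:`pooled_rate` and
    :func:`binomial_ci`."""
    lo, hi = binomial_ci(NMUT, NGEN, L, alpha)
    return RateEstimate(
        panel=panel,
        NGEN=NGEN,
        NMUT=NMUT,
        L=L,
        rate=pooled_rate(NMUT, NGEN, L),
        ci_low=lo,
        ci_high=hi,
        alpha=alpha,
    )


def pool_counts(
    counts: Iterable[MutationCount], panel: Panel
) -> tuple[int, int]:
    """Total (NGEN, NMUT) over pedigree/couple counts, restricted to the
    panel's scored columns."""
    cols = set(panel.columns)
    ngen = nmut = 0
    for c in counts:
        ngen += c.total_meioses
        nmut += sum(v for k, v in c.per_locus_events.items() if k in cols)
    return ngen, nmut


def panel_rate(
    counts: Iterable[MutationCount], panel: Panel, alpha: float = 0.05
) -> RateEstimate:
    """Pooled rate over a panel from per-unit mutation counts."""
    ngen, nmut = pool_counts(list(counts), panel)
    return estimate_rate(nmut, ngen, panel.scored_locus_count, panel.name, alpha)


def locus_rates(
    counts: Sequence[MutationCount], panel: Panel, alpha: float = 0.05
) -> dict[str, RateEstimate]:
    """Per-column rates (L = 1): events and meioses summed over units."""
    if not counts:
        raise ValueError("locus_rates: empty input")
    if any(c.convention != "related" for c in counts):
        raise ValueError("locus_rates expects related-convention counts")
    out: dict[str, RateEstimate] = {}
    ngen = sum(c.total_meioses for c in counts)
    for col in panel.columns:
        nmut = sum(c.per_locus_events.get(col, 0) for c in counts)
        out[col] = estimate_rate(nmut, ngen, 1, panel.name, alpha)
    return out


@dataclass
class GrubbsResult:
    """Outcome of the iterative Grubbs outlier screen."""

    ratios: dict[str, float]
    excluded: list[tuple[str, float]] = field(default_factory=list)
    final_p: float = 1.0

    @property
    def retained(self) -> list[str]:
        dropped = {k for k, _ in self.excluded}
        return [k for k in self.ratios if k not in dropped]


def _grubbs_p(values: Sequence[float]) -> tuple[int, float, float]:
    """Two-sided single-outlier Grubbs test.

    Returns (index of extreme value, G statistic, p-value), with
    p = min(1, 2N * P(T_{N-2} > t)) where
    t^2 = N (N-2) G^2 / ((N-1)^2 - N G^2).
    """
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0:
        return 0, 0.0, 1.0
    devs = [abs(v - mean) for v in values]
    idx = max(range(n), key=devs.__getitem__)
    g = devs[idx] / sd
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        return idx, g, 0.0
    t = math.sqrt(n * (n - 2) * g * g / denom)
    p = 2 * n * stats.t.sf(t, n - 2)
    return idx, g, min(1.0, p)


def grubbs_screen(
    ratios: Mapping[str, float], alpha: float = 0.05
) -> GrubbsResult:
    """Iteratively remove the most extreme mutations/meioses ratio while
    the two-sided Grubbs test is significant at *alpha*."""
    if len(ratios) < 3:
        raise ValueError("grubbs_screen needs at least 3 ratios")
    remaining = dict(ratios)
    result = GrubbsResult(ratios=dict(ratios))
    while len(remaining) >= 3:
        # sort for input-order invariance
        keys = sorted(remaining)
        idx, g, p = _grubbs_p([remaining[k] for k in keys])
        if p > alpha:
            result.final_p = p
            return result
        outlier = keys[idx]
        log.info("Grubbs: excluding %s (G=%.3f, p=%.3g)", outlier, g, p)
        result.excluded.append((outlier, p))
        del remaining[outlier]
    result.final_p = 1.0
    return result


def bin_rates(
    couple_counts: Sequence[MutationCount],
    panel: Panel,
    bins: Sequence[tuple[int, int]],
    alpha: float = 0.05,
) -> dict[tuple[int, int], RateEstimate]:
    """Diachronic rates: pool related-convention couple counts into
    disjoint meiosis-separation bins and estimate each bin's rate.

    Couples falling outside every bin are logged and skipped.
    """
    for i, (lo1, hi1) in enumerate(bins):
        for lo2, hi2 in bins[i + 1 :]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValueError(f"overlapping bins ({lo1},{hi1}) and ({lo2},{hi2})")
    cols = set(panel.columns)
    totals = {b: [0, 0] for b in bins}  # [NGEN, NMUT]
    for c in couple_counts:
        hit = next(
            (b for b in bins if b[0] <= c.total_meioses <= b[1]), None
        )
        if hit is None:
            log.info("couple %s (%d meioses) outside all bins", c.unit_id, c.total_meioses)
            continue
        totals[hit][0] += c.total_meioses
        totals[hit][1] += sum(
            v for k, v in c.per_locus_events.items() if k in cols
        )
    out: dict[tuple[int, int], RateEstimate] = {}
    for b, (ngen, nmut) in totals.items():
        if ngen == 0:
            log.info("bin %s empty, no estimate", b)
            continue
        out[b] = estimate_rate(nmut, ngen, panel.scored_locus_count, panel.name, alpha)
    return out
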