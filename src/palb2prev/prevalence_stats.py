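"""Hardy-Weinberg carrier-prevalence estimation from qualifying allele counts.

For an autosomal-dominant gene, a cohort of ``n`` individuals contributes
``2n`` alleles.  With ``total_ac`` qualifying (pathogenic / likely
pathogenic) alleles, the minor-allele frequency is ``q = total_ac / 2n``
and the heterozygous-carrier prevalence under Hardy-Weinberg equilibrium is
``2pq = 2q(1-q)`` (homozygotes, q**2, are excluded).  Confidence intervals
are computed for q on the allele scale — exact (Clopper-Pearson) binomial
by default, Wilson score or Poisson-exact as alternatives — and mapped to
the carrier scale through the monotone transform ``f(q) = 2q(1-q)``
(monotone for q <= 1/2).

The denominator is always twice the cohort's individual count, not the
per-variant allele number; per-variant AN is retained upstream only for QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Tuple

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .variant_model import CohortSpec, VariantRecord

__all__ = [
    "PrevalenceEstimate",
    "aggregate_qualifying_ac",
    "carrier_prevalence",
    "one_in_n",
    "prevalence_ci",
    "estimate_prevalence",
    "pool_cohorts",
    "project_carriers",
    "format_pct",
]

CI_METHODS = ("exact_binomial", "wilson", "poisson_exact")


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Carrier-prevalence point estimate with carrier-scale CI for one cell."""

    total_ac: int
    n_individuals: int
    q: float
    p: float
    prevalence: float  # 2pq carrier frequency
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    one_in_n: Optional[int] = None
    alpha: float = 0.05
    ci_method: str = "exact_binomial"
    cohort: Optional[CohortSpec] = None
    source: Optional[str] = None


def aggregate_qualifying_ac(
    records: Sequence[VariantRecord],
    qualifying_keys,
    population_label: str,
) -> int:
    """Sum of allele counts over qualifying variants in one population.

    A record without counts for the population contributes 0; an empty
    qualifying set yields 0.
    """
    qualifying_keys = set(qualifying_keys)
    return sum(r.ac(population_label) for r in records if r.key in qualifying_keys)


def _check_counts(total_ac: int, n_individuals: int) -> None:
    if n_individuals < 1:
        raise ValueError(f"n_individuals must be >= 1, got {n_individuals}")
    if not (0 <= total_ac <= 2 * n_individuals):
        raise ValueError(
            f"total_ac {total_ac} outside [0, {2 * n_individuals}] "
            f"for {n_individuals} individuals"
        )


def carrier_prevalence(total_ac: int, n_individuals: int) -> PrevalenceEstimate:
    """Point estimate: q = total_ac / 2n, prevalence = 2q(1-q)."""
    _check_counts(total_ac, n_individuals)
    q = total_ac / (2 * n_individuals)
    prevalence = 2.0 * q * (1.0 - q)
    return PrevalenceEstimate(
        total_ac=total_ac,
        n_individuals=n_individuals,
        q=q,
        p=1.0 - q,
        prevalence=prevalence,
        one_in_n=one_in_n(prevalence) if prevalence > 0 else None,
    )


def one_in_n(prevalence: float) -> int:
    """'One carrier in every N' = floor(1 / prevalence); requires prevalence > 0."""
    if prevalence <= 0:
        raise ValueError("one_in_n is undefined for prevalence <= 0 (render as NA)")
    return math.floor(1.0 / prevalence)


def _carrier_scale(q: float) -> float:
    # 2q(1-q) is monotone up to q = 1/2; clamp so CI mapping stays ordered
    q = min(q, 0.5)
    return 2.0 * q * (1.0 - q)


def prevalence_ci(
    total_ac: int,
    n_individuals: int,
    alpha: float = 0.05,
    method: str = "exact_binomial",
) -> Tuple[float, float]:
    """Carrier-scale confidence interval for the 2pq prevalence.

    A (1-alpha) CI for q is computed from ``total_ac`` successes in ``2n``
    trials, then both bounds are mapped through ``2q(1-q)``.  With zero
    successes the lower bound is exactly 0.
    """
    _check_counts(total_ac, n_individuals)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    trials = 2 * n_individuals
    if method == "exact_binomial":
        q_lo, q_hi = proportion_confint(total_ac, trials, alpha=alpha, method="beta")
        if total_ac == 0:
            q_lo = 0.0
    elif method == "wilson":
        q_lo, q_hi = proportion_confint(total_ac, trials, alpha=alpha, method="wilson")
    elif method == "poisson_exact":
        # Garwood interval for the count, scaled to a frequency
        q_lo = 0.0 if total_ac == 0 else stats.chi2.ppf(alpha / 2, 2 * total_ac) / 2 / trials
        q_hi = stats.chi2.ppf(1 - alpha / 2, 2 * total_ac + 2) / 2 / trials
    else:
        raise ValueError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")
    q_lo = 0.0 if math.isnan(q_lo) else float(q_lo)
    return _carrier_scale(q_lo), _carrier_scale(float(q_hi))


def estimate_prevalence(
    total_ac: int,
    cohort: CohortSpec,
    source: Optional[str] = None,
    alpha: float = 0.05,
    method: str = "exact_binomial",
) -> PrevalenceEstimate:
    """Full estimate (point + CI + one-in-N) for one cohort x source cell."""
    point = carrier_prevalence(total_ac, cohort.n_individuals)
    lo, hi = prevalence_ci(total_ac, cohort.n_individuals, alpha=alpha, method=method)
    return PrevalenceEstimate(
        total_ac=total_ac,
        n_individuals=cohort.n_individuals,
        q=point.q,
        p=point.p,
        prevalence=point.prevalence,
        ci_low=lo,
        ci_high=hi,
        one_in_n=point.one_in_n,
        alpha=alpha,
        ci_method=method,
        cohort=cohort,
        source=source,
    )


def pool_cohorts(
    components: Sequence[Tuple[int, int]],
) -> Tuple[int, int]:
    """Element-wise sum of (total_ac, n_individuals) pairs across databases."""
    if not components:
        raise ValueError("pool_cohorts requires at least one component")
    acs, ns = zip(*components)
    return int(sum(acs)), int(sum(ns))


def project_carriers(prevalence_rounded_pct: float, population_size: int) -> int:
    """Expected carriers in a census population, rounded to the nearest thousand.

    Takes the prevalence already rounded to 0.01 percentage points (as
    reported) — e.g. 0.13% of 51.8 million is ~67,000 carriers.
    """
    carriers = population_size * prevalence_rounded_pct / 100.0
    thousands = int(
        Decimal(str(carriers / 1000.0)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
    return 1000 * thousands


def format_pct(value: float, decimals: int = 2) -> str:
    """Render a proportion as a percentage, half-away-from-zero (0.0018036 -> '0.18')."""
    pct = Decimal(str(value)) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return str(pct.quantize(quantum, rounding=ROUND_HALF_UP))
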