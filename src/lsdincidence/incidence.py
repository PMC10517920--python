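"""Carrier-based incidence estimation under Hardy-Weinberg equilibrium.

For each gene the risk allele frequency ``q`` is the sum of the cohort
allele frequencies of its qualifying variants: pathogenic + likely
pathogenic under the *conservative* mode, additionally VUS under the
*extended* mode.  With ``Q = 1 - q``, the carrier rate is ``2 Q q`` and the
disease incidence ``q**2``; multi-gene diseases pool ``q`` across their
genes before squaring, and the combined incidence across diseases is the
sum of per-disease ``q**2`` (loci treated as independent; in-cis variant
pairs are not merged, which can overestimate incidence).

Uncertainty on an incidence expressed as a count per denominator uses the
exact (Garwood) Poisson interval from gamma quantiles, which generalizes
smoothly to non-integer counts; two incidence rates are compared with the
exact conditional binomial test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .acmg import AcmgClass
from .cohort import CohortVariant


class RiskMode(str, Enum):
    CONSERVATIVE = "conservative"  # P + LP
    EXTENDED = "extended"  # P + LP + VUS


_QUALIFYING = {
    RiskMode.CONSERVATIVE: frozenset(
        {AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC}
    ),
    RiskMode.EXTENDED: frozenset(
        {AcmgClass.PATHOGENIC, AcmgClass.LIKELY_PATHOGENIC, AcmgClass.VUS}
    ),
}


class AggregationError(ValueError):
    """Raised when allele-frequency sums are inconsistent (e.g. q > 1)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 4.225 -> 4.23 at 2 dp)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RiskAlleleSet:
    """Qualifying variants of one gene under one risk mode."""

    gene_symbol: str
    mode: RiskMode
    variant_keys: frozenset[str]
    q: float

    @property
    def Q(self) -> float:
        return 1.0 - self.q


@dataclass(frozen=True)
class GeneIncidence:
    """Per-disease carrier rate and incidence with its exact Poisson CI."""

    disease_name: str
    gene_symbols: frozenset[str]
    mode: RiskMode
    q: float
    carrier_rate: float
    incidence: float
    incidence_per_100k: float  # rounded, 2 dp half-up
    ci95_per_100k: tuple[float, float]


@dataclass(frozen=True)
class RateComparison:
    rate_a: float
    rate_b: float
    denom_a: float
    denom_b: float
    p_value: float
    method: str
    degenerate: bool = False


def risk_allele_set(
    gene: str,
    classifications: Mapping[str, AcmgClass],
    variants: Mapping[str, CohortVariant] | Iterable[CohortVariant],
    mode: RiskMode | str,
) -> RiskAlleleSet:
    """Sum allele frequencies of a gene's qualifying classified variants.

    Benign and likely benign variants never qualify; the conservative set
    is a subset of the extended set by construction.
    """
    mode = RiskMode(mode)
    if not isinstance(variants, Mapping):
        variants = {v.variant_key: v for v in variants}
    qualifying = _QUALIFYING[mode]
    keys = set()
    q_exact = Fraction(0)
    for key, acmg_class in classifications.items():
        if acmg_class not in qualifying:
            continue
        variant = variants.get(key)
        if variant is None or variant.gene_symbol != gene:
            continue
        keys.add(key)
        q_exact += variant.allele_frequency
    if q_exact > 1:
        raise AggregationError(
            f"{gene}: summed risk allele frequency {float(q_exact):.4g} > 1"
        )
    return RiskAlleleSet(
        gene_symbol=gene, mode=mode, variant_keys=frozenset(keys), q=float(q_exact)
    )


def carrier_and_incidence(q: float) -> tuple[float, float]:
    """Hardy-Weinberg carrier rate ``2(1-q)q`` and incidence ``q**2``."""
    if not 0 <= q <= 1:
        raise ValueError(f"risk allele frequency must be in [0, 1], got {q}")
    return 2.0 * (1.0 - q) * q, q * q


def poisson_exact_ci(
    count: float, denominator: float = 1.0, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a count.

    The lower bound is half the ``alpha/2`` chi-square quantile at
    ``2*count`` degrees of freedom (0 at zero counts) and the upper bound
    half the ``1 - alpha/2`` quantile at ``2*count + 2`` df — equivalently
    gamma quantiles with shapes ``count`` and ``count + 1``, which extends
    the interval to non-integer counts.  Bounds are returned on the
    per-``denominator`` scale of the input count (pass the count already
    expressed per 100,000 and a denominator of 1 to get bounds per
    100,000).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.gamma.ppf(alpha / 2, count))
    upper = float(stats.gamma.ppf(1 - alpha / 2, count + 1))
    return lower / denominator, upper / denominator


def compare_rates(
    count_a: float,
    denom_a: float,
    count_b: float,
    denom_b: float,
    method: str = "exact",
) -> RateComparison:
    """Two-sided comparison of two event rates.

    The default exact conditional test conditions on the total count
    ``K = k_a + k_b``: under equal rates, ``k_a`` is binomial with success
    probability ``denom_a / (denom_a + denom_b)``, and the two-sided
    p-value is the minimum-likelihood binomial tail.  A normal
    approximation on the rate difference is selectable for large counts.
    The p-value is invariant under swapping the two rates.
    """
    if min(count_a, count_b) < 0 or min(denom_a, denom_b) <= 0:
        raise ValueError("counts must be >= 0 and denominators > 0")
    rate_a, rate_b = count_a / denom_a, count_b / denom_b
    total = count_a + count_b
    if total == 0:
        return RateComparison(
            rate_a, rate_b, denom_a, denom_b, 1.0, method, degenerate=True
        )
    if method == "exact":
        k_a = int(round(count_a))
        k = int(round(total))
        if not math.isclose(k_a, count_a) or not math.isclose(k, total):
            warnings.warn(
                "exact rate comparison rounds non-integer counts",
                stacklevel=2,
            )
        p0 = denom_a / (denom_a + denom_b)
        p_value = float(stats.binomtest(k_a, k, p0).pvalue)
    elif method == "normal":
        pooled = total / (denom_a + denom_b)
        se = math.sqrt(pooled * (1 / denom_a + 1 / denom_b))
        z = (rate_a - rate_b) / se if se > 0 else 0.0
        p_value = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return RateComparison(rate_a, rate_b, denom_a, denom_b, min(p_value, 1.0), method)


def disease_incidence(
    disease_name: str,
    gene_sets: Sequence[RiskAlleleSet],
    denominator: float = 100_000,
    ci_level: float = 0.95,
) -> GeneIncidence:
    """Pool risk alleles of a disease's gene(s) and derive its incidence.

    ``q`` sums over genes (no cross-gene compound-heterozygote correction),
    the CI treats the incidence expressed per ``denominator`` as a Poisson
    count over that denominator.
    """
    modes = {gs.mode for gs in gene_sets}
    if len(modes) > 1:
        raise AggregationError(f"{disease_name}: mixed risk modes {modes}")
    mode = modes.pop() if modes else RiskMode.CONSERVATIVE
    q = sum(gs.q for gs in gene_sets)
    if q > 1:
        raise AggregationError(f"{disease_name}: pooled q {q:.4g} > 1")
    carrier, incidence = carrier_and_incidence(q)
    count = incidence * denominator
    ci = poisson_exact_ci(count, denominator=1.0, level=ci_level)
    return GeneIncidence(
        disease_name=disease_name,
        gene_symbols=frozenset(gs.gene_symbol for gs in gene_sets),
        mode=mode,
        q=q,
        carrier_rate=carrier,
        incidence=incidence,
        incidence_per_100k=round_half_up(count, 2),
        ci95_per_100k=(round_half_up(ci[0], 2), round_half_up(ci[1], 2)),
    )


def combined_incidence(
    reports: Sequence[GeneIncidence], denominator: float = 100_000
) -> float:
    """Total incidence across diseases: sum of per-disease ``q**2``.

    Reported per ``denominator``, rounded to 2 dp half-up.  Each disease
    must appear once (multi-gene diseases are pooled upstream).
    """
    names = [r.disease_name for r in reports]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise AggregationError(f"duplicate disease entries: {dupes}")
    total = sum(r.incidence for r in reports)
    return round_half_up(total * denominator, 2)


def carrier_one_in_n(carrier_rate: float) -> float | None:
    """Express a carrier rate as '1 in N' (None at a zero rate)."""
    return None if carrier_rate == 0 else 1.0 / carrier_rate
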