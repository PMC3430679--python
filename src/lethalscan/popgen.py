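"""Population-genetic bookkeeping for a recessive lethal allele.

Given genotype counts from a random sample of unaffected animals, this module
estimates the carrier (heterozygote) frequency c, back-calculates the allele
frequency q under Hardy-Weinberg equilibrium (2q(1-q) = c), predicts the
expected incidence of affected births, and quantifies the homozygote deficit:
the probability of observing zero D/D animals in a sample of size N if
homozygotes were fully viable.

The expected incidence uses the carrier-pairing approximation c^2/4 (the
probability that both parents are carriers times the 1/4 transmission
probability). The exact HWE value q^2 differs by ~8% at c = 0.074; both are
exposed, the approximation is the default because the headline "1 in 730"
style numbers are computed that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .errors import DataError

__all__ = [
    "GenotypeCounts",
    "CarrierEstimate",
    "carrier_frequency",
    "allele_freq_from_carrier",
    "expected_incidence",
    "prob_zero_homozygotes",
    "survival_adjusted_incidence",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at a biallelic deletion locus in a diploid sample."""

    n_wildtype: int
    n_carrier: int
    n_homozygous: int

    def __post_init__(self) -> None:
        if min(self.n_wildtype, self.n_carrier, self.n_homozygous) < 0:
            raise DataError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_wildtype + self.n_carrier + self.n_homozygous


@dataclass(frozen=True)
class CarrierEstimate:
    """Point estimate and Wilson 95% CI of the carrier frequency."""

    estimate: float
    ci_low: float
    ci_high: float
    n_carrier: int
    n_total: int


def carrier_frequency(counts: GenotypeCounts, alpha: float = 0.05) -> CarrierEstimate:
    """Estimate the carrier frequency c = n_carrier / N with a Wilson score CI.

    The Wilson interval is used instead of the Wald interval because c is a
    small proportion and the Wald interval degenerates near 0.
    """
    n = counts.total
    if n == 0:
        raise DataError("cannot estimate a carrier frequency from an empty sample")
    low, high = proportion_confint(counts.n_carrier, n, alpha=alpha, method="wilson")
    return CarrierEstimate(
        estimate=counts.n_carrier / n,
        ci_low=float(low),
        ci_high=float(high),
        n_carrier=counts.n_carrier,
        n_total=n,
    )


def allele_freq_from_carrier(c: float) -> float:
    """Smaller root q of 2q(1-q) = c, the HWE allele frequency of the deletion.

    Only defined for c <= 0.5 (the heterozygote frequency 2q(1-q) is maximal
    at q = 1/2 where it equals 1/2).
    """
    if not 0.0 <= c <= 0.5:
        raise DataError(f"carrier frequency {c} outside [0, 0.5]: no HWE root q <= 0.5")
    # 2q^2 - 2q + c = 0  ->  q = (1 - sqrt(1 - 2c)) / 2
    return (1.0 - math.sqrt(1.0 - 2.0 * c)) / 2.0


def expected_incidence(c: float, exact: bool = False) -> tuple[float, int]:
    """Expected incidence of affected (D/D) births from carrier frequency c.

    By default uses the carrier-pairing approximation c^2 / 4 (both parents
    carriers, each transmits with probability 1/2). With ``exact=True`` uses
    the HWE homozygote frequency q^2. Returns ``(incidence, reciprocal)``
    with the reciprocal rounded to the nearest 10 (0 when the incidence is 0).
    """
    if not 0.0 <= c <= 1.0:
        raise DataError(f"carrier frequency {c} outside [0, 1]")
    if exact:
        q = allele_freq_from_carrier(c)
        incidence = q * q
    else:
        incidence = c * c / 4.0
    if incidence == 0.0:
        return 0.0, 0
    reciprocal = int(round(1.0 / incidence / 10.0) * 10)
    return incidence, reciprocal


def prob_zero_homozygotes(q: float, n: int) -> float:
    """Probability that a HWE sample of n diploids contains no homozygote.

    Exact binomial zero-class probability (1 - q^2)^n. Monotonically
    decreasing in both q and n.
    """
    if not 0.0 <= q <= 1.0:
        raise DataError(f"allele frequency {q} outside [0, 1]")
    if n < 1:
        raise DataError("sample size must be >= 1")
    return (1.0 - q * q) ** n


def survival_adjusted_incidence(
    c: float, survival_fraction: float
) -> tuple[float | None, int | None]:
    """Reciprocal incidence of affected *births* given in-utero survival.

    One affected birth is expected every 1 / ((c^2/4) * survival) calvings.
    Returns ``(raw_reciprocal, rounded_reciprocal)`` where the rounded value
    is to the nearest 100 when above 1,000 (nearest 10 otherwise), and
    ``(None, None)`` when survival is 0 (no homozygote is ever born).
    """
    if not 0.0 <= survival_fraction <= 1.0:
        raise DataError(f"survival fraction {survival_fraction} outside [0, 1]")
    incidence, _ = expected_incidence(c)
    born = incidence * survival_fraction
    if born == 0.0:
        return None, None
    raw = 1.0 / born
    if raw > 1000.0:
        rounded = int(round(raw / 100.0) * 100)
    else:
        rounded = int(round(raw / 10.0) * 10)
    return raw, rounded
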