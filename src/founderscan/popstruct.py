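"""Population substructure and homozygote-deficit screening.

Three questions about departures from Hardy-Weinberg proportions:

* per site, is the genotype configuration compatible with random mating?
  (exact conditional HWE test, enumerating heterozygote configurations);
* cohort-wide, how much substructure is there? Under the standard
  decomposition P(hom-alt) = q^2 + F q(1-q), the per-site excess
  homozygosity regressed on q(1-q) through the origin has slope F, the
  proportion of allelic variance explained by structure (F_ST);
* per variant, are homozygotes missing outright -- the signature of a
  recessive-lethal allele whose homozygotes never enter a population
  survey?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCounts",
    "FstFit",
    "DeficitFlag",
    "hwe_exact_test",
    "estimate_fst",
    "homozygote_deficit_screen",
    "fold_excess_homozygotes",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts at one biallelic site."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self):
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("at least one called genotype required")

    @property
    def n_total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def allele_count(self) -> int:
        return 2 * self.n_hom_alt + self.n_het

    @property
    def allele_freq(self) -> float:
        return self.allele_count / (2 * self.n_total)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.n_hom_ref + other.n_hom_ref,
            self.n_het + other.n_het,
            self.n_hom_alt + other.n_hom_alt,
        )


def _log_het_probs(n: int, ac: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every feasible heterozygote count.

    Conditional on n diploids and alternate-allele count ac, the number of
    heterozygotes x has the same parity as ac and satisfies
    x <= min(ac, 2n - ac). The conditional probability is

        P(x) = n! / (a! b! c!) * 2^x / C(2n, ac)

    with a = (ac - x)/2 hom-alt, b = x het, c = n - a - b hom-ref; the
    normalizing constant cancels when we normalize over the support.
    """
    m = min(ac, 2 * n - ac)
    xs = np.arange(m % 2, m + 1, 2)
    a = (ac - xs) // 2
    c = n - a - xs
    logp = (
        gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(xs + 1)
        - gammaln(c + 1)
        + xs * np.log(2.0)
    )
    logp -= logp.max()
    logp -= np.log(np.exp(logp).sum())
    return xs, logp


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the sample size and allele count and sums the
    probabilities of all heterozygote configurations no more probable than
    the observed one (ties included in the tail, the standard convention).
    Monomorphic sites return p = 1.
    """
    n, ac = counts.n_total, counts.allele_count
    ac = min(ac, 2 * n - ac)  # test is symmetric in allele labelling
    if ac == 0:
        return 1.0
    obs = counts.n_het
    xs, logp = _log_het_probs(n, counts.allele_count)
    p_obs = logp[xs == obs]
    if p_obs.size == 0:
        raise ValueError(f"heterozygote count {obs} infeasible for n={n}, ac={ac}")
    tail = np.exp(logp[logp <= p_obs[0] + 1e-12]).sum()
    return float(min(tail, 1.0))


@dataclass
class FstFit:
    """Zero-intercept regression estimate of substructure F."""

    estimate: float
    se: float
    n_sites: int
    out_of_range: bool = False

    def __post_init__(self):
        # estimates slightly outside [0,1] are reported, not clipped
        self.out_of_range = not (0.0 <= self.estimate <= 1.0)


def _hw_expected_hom_frac(q: np.ndarray, n: np.ndarray, corrected: bool) -> np.ndarray:
    """Hardy-Weinberg expected hom-alt fraction from the estimated frequency.

    The naive q_hat^2 is biased upward (E[q_hat^2] = q^2 + q(1-q)/2n),
    which matters when rare sites dominate; the corrected form
    q_hat^2 - q_hat(1-q_hat)/(2n-1) is unbiased for q^2 under binomial
    allele sampling.
    """
    e = q * q
    if corrected:
        e = e - q * (1.0 - q) / (2.0 * n - 1.0)
    return e


def estimate_fst(
    counts: list[GenotypeCounts], weighted: bool = False, corrected: bool = True
) -> FstFit:
    """Estimate F from excess homozygosity across sites.

    Per polymorphic site, the response is (observed hom-alt fraction -
    expected under Hardy-Weinberg) and the regressor q(1-q), with q the
    observed alternate frequency; the zero-intercept least-squares slope
    is the F estimate. ``corrected`` (default) uses the unbiased
    finite-sample Hardy-Weinberg expectation so a panmictic cohort
    centers on F=0 even when rare sites dominate; ``weighted=True``
    applies inverse-variance weights proportional to n / (q(1-q)),
    down-weighting sites where the excess is noisiest.
    """
    rows = [(c.n_hom_alt / c.n_total, c.allele_freq, c.n_total) for c in counts if 0 < c.allele_count < 2 * c.n_total]
    if len(rows) < 2:
        raise ValueError("need at least 2 polymorphic sites to estimate F")
    hom, q, n = map(np.asarray, zip(*rows))
    x = q * (1.0 - q)
    y = hom - _hw_expected_hom_frac(q, n, corrected)
    w = n / np.maximum(x, 1e-12) if weighted else np.ones_like(x)
    sxx = float(np.sum(w * x * x))
    slope = float(np.sum(w * x * y) / sxx)
    resid = y - slope * x
    dof = len(x) - 1
    se = float(np.sqrt(np.sum(w * resid**2) / dof / sxx))
    return FstFit(estimate=slope, se=se, n_sites=len(x))


@dataclass
class DeficitFlag:
    """Screen result for one variant's homozygote deficit."""

    variant_id: str
    expected: float
    observed: int
    hwe_p: float
    deficit_p: float
    flagged: bool


def homozygote_deficit_screen(
    variants: dict[str, list[GenotypeCounts]],
    min_expected: float = 3.0,
    p_threshold: float = 0.05,
) -> list[DeficitFlag]:
    """Screen pooled cohorts for variants with too few homozygotes.

    Per variant the cohorts' genotype counts are pooled (the test of the
    pooled counts equals the test of the summed GenotypeCounts); expected
    homozygotes are n * q_hat^2 from the pooled frequency. Variants with
    expectation >= ``min_expected`` and observed < expected get an exact
    HWE p and a Poisson lower-tail p on the observed count; the flag fires
    when the Poisson tail drops below ``p_threshold``. Below
    ``min_expected`` the absence of homozygotes is uninformative and the
    variant is reported unflagged.
    """
    out = []
    for vid, cohort_counts in variants.items():
        pooled = cohort_counts[0]
        for c in cohort_counts[1:]:
            pooled = pooled + c
        q = pooled.allele_freq
        expected = pooled.n_total * q * q
        observed = pooled.n_hom_alt
        hwe_p = hwe_exact_test(pooled)
        deficit_p = float(stats.poisson.cdf(observed, expected)) if expected > 0 else 1.0
        flagged = (
            expected >= min_expected and observed < expected and deficit_p < p_threshold
        )
        out.append(DeficitFlag(vid, expected, observed, hwe_p, deficit_p, flagged))
    return out


def fold_excess_homozygotes(counts: list[GenotypeCounts], corrected: bool = True) -> float:
    """Aggregate observed/expected homozygote ratio across variants.

    Sums observed hom-alt counts and Hardy-Weinberg expectations over all
    variants; a ratio above 1 indicates study-wide homozygote excess
    (e.g. from within-population substructure). ``corrected`` (default)
    uses the unbiased expectation n*(q_hat^2 - q_hat(1-q_hat)/(2n-1)), so
    a panmictic cohort centers on 1 even when the variants are rare.
    """
    obs = sum(c.n_hom_alt for c in counts)
    exp = sum(
        c.n_total
        * _hw_expected_hom_frac(np.float64(c.allele_freq), np.float64(c.n_total), corrected)
        for c in counts
    )
    if exp == 0:
        raise ValueError("total Hardy-Weinberg expectation is zero; ratio undefined")
    return float(obs / exp)


def screen_report(flags: list[DeficitFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": f.variant_id,
                "expected_hom": f.expected,
                "observed_hom": f.observed,
                "hwe_p": f.hwe_p,
                "deficit_p": f.deficit_p,
                "flagged": f.flagged,
            }
            for f in flags
        ]
    )
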