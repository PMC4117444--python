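"""Site-frequency-spectrum comparison between populations, by functional class.

The central object is an SFSTable: segregating-site counts cross-classified
by population x functional class x allele-frequency bin, with a dedicated
singleton bin (alternate-allele count exactly 1, regardless of the
denominator). Two test statistics accompany it: a one-sided binomial test
for an excess of variable sites in one population over the other, and a
one-sided hypergeometric test for over-representation of the LoF class
relative to the synonymous class. Per-individual burden summaries (mean
sites carried, mean homozygous-alternate sites) complete the picture of
what a bottleneck does to an average genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = [
    "SFSTable",
    "BurdenSummary",
    "DEFAULT_BIN_EDGES",
    "build_sfs",
    "excess_binomial_test",
    "class_enrichment_test",
    "per_individual_burden",
]

#: interior bin edges; bins are [edge_i, edge_{i+1}) and the last is [0.10, 1]
DEFAULT_BIN_EDGES = (0.005, 0.01, 0.02, 0.05, 0.10)

SINGLETON = "singleton"


def _bin_labels(edges) -> list[str]:
    labels = [SINGLETON, f"(0,{edges[0]:g})"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g},{hi:g})")
    labels.append(f"[{edges[-1]:g},1]")
    return labels


def assign_bin(ac: int, an: int, edges=DEFAULT_BIN_EDGES) -> str | None:
    """Bin label for one site in one population; None if not segregating.

    Singletons are defined by allele count 1. Other sites fall into
    half-open frequency bins [lo, hi), except the top bin which is closed
    at 1.
    """
    if ac <= 0 or an <= 0:
        return None
    if ac == 1:
        return SINGLETON
    q = ac / an
    labels = _bin_labels(edges)
    if q < edges[0]:
        return labels[1]
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if lo <= q < hi:
            return labels[2 + k]
    return labels[-1]


@dataclass
class SFSTable:
    """Counts of segregating sites by population x class x frequency bin."""

    bin_edges: tuple
    counts: pd.DataFrame  # index (population, var_class), columns = bin labels
    sample_sizes: dict = field(default_factory=dict)

    @property
    def bin_labels(self) -> list[str]:
        return list(self.counts.columns)

    def segregating(self, population: str, var_class: str) -> int:
        return int(self.counts.loc[(population, var_class)].sum())

    def ratio(self, pop_a: str, pop_b: str, var_class: str) -> pd.Series:
        """Per-bin count ratio pop_a / pop_b for one class (NaN where B empty)."""
        a = self.counts.loc[(pop_a, var_class)].astype(float)
        b = self.counts.loc[(pop_b, var_class)].astype(float)
        return a / b.replace(0, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return self.counts.reset_index()


def build_sfs(variants: pd.DataFrame, bin_edges=DEFAULT_BIN_EDGES, populations=None) -> SFSTable:
    """Build an SFSTable from a variant table with per-population counts.

    ``variants`` needs columns ``var_class`` plus ``ac_<pop>`` / ``an_<pop>``
    for each population (alternate-allele count; called-allele denominator,
    i.e. 2 x called genotypes). Each site contributes to exactly one bin in
    each population in which it segregates.
    """
    edges = tuple(bin_edges)
    if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    if edges[0] <= 0 or edges[-1] >= 1:
        raise ValueError("interior bin edges must lie in (0, 1)")
    if populations is None:
        populations = sorted(c[3:] for c in variants.columns if c.startswith("ac_"))
    if not populations:
        raise ValueError("no ac_<pop> columns found")
    labels = _bin_labels(edges)
    classes = sorted(variants["var_class"].unique())
    idx = pd.MultiIndex.from_product([populations, classes], names=["population", "var_class"])
    counts = pd.DataFrame(0, index=idx, columns=labels)
    for pop in populations:
        ac = variants[f"ac_{pop}"].to_numpy()
        an = variants[f"an_{pop}"].to_numpy()
        for vc, a, n in zip(variants["var_class"], ac, an):
            lab = assign_bin(int(a), int(n), edges)
            if lab is not None:
                counts.loc[(pop, vc), lab] += 1
    return SFSTable(bin_edges=edges, counts=counts)


def cohort_variant_counts(cohorts: dict[str, SyntheticCohort]) -> pd.DataFrame:
    """Merge per-population allele counts from cohorts into one variant table."""
    pops = list(cohorts)
    base = next(iter(cohorts.values())).variants[["variant_id", "var_class"]].copy()
    for pop, cohort in cohorts.items():
        base[f"ac_{pop}"] = cohort.allele_counts()
        base[f"an_{pop}"] = 2 * cohort.called_genotypes()
    return base


def excess_binomial_test(n_pop_a: int, n_pop_b: int) -> float:
    """One-sided binomial p for an excess of sites in population A.

    Under the null each variable site is equally likely to be counted in
    either population, so p = P(X >= n_A) with X ~ Bin(n_A + n_B, 1/2).
    """
    if n_pop_a < 0 or n_pop_b < 0:
        raise ValueError("counts must be non-negative")
    if n_pop_a == 0 and n_pop_b == 0:
        raise ValueError("excess test undefined when both counts are zero")
    return float(stats.binom.sf(n_pop_a - 1, n_pop_a + n_pop_b, 0.5))


def class_enrichment_test(lof_a: int, syn_a: int, lof_b: int, syn_b: int) -> float:
    """One-sided hypergeometric p for LoF over-representation in population A.

    Conditions on the margins of the 2x2 (class x population) table of
    variant counts and asks whether population A holds more of the LoF
    class than expected: p = P(X >= lof_a) with
    X ~ Hypergeom(N=total, K=lof_a+lof_b, n=lof_a+syn_a).
    """
    for v in (lof_a, syn_a, lof_b, syn_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    total = lof_a + syn_a + lof_b + syn_b
    n_lof = lof_a + lof_b
    n_a = lof_a + syn_a
    if n_lof == 0 or n_lof == total or n_a == 0 or n_a == total:
        logger.warning("degenerate 2x2 margin; enrichment test returns p=1")
        return 1.0
    return float(stats.hypergeom.sf(lof_a - 1, total, n_lof, n_a))


@dataclass
class BurdenSummary:
    """Mean per-individual variant burdens, by class x frequency bin.

    ``table`` columns: var_class, bin, mean_sites (sites with >= 1
    alternate allele per individual), mean_hom_alt (homozygous-alternate
    sites per individual).
    """

    population: str
    n_samples: int
    table: pd.DataFrame

    def total(self, mode: str = "mean_sites", var_class: str | None = None) -> float:
        t = self.table if var_class is None else self.table[self.table["var_class"] == var_class]
        return float(t[mode].sum())


def per_individual_burden(
    cohort: SyntheticCohort, bin_edges=DEFAULT_BIN_EDGES, population: str | None = None
) -> BurdenSummary:
    """Average per-individual counts of carried and homozygous-alternate sites.

    Bins use the cohort's own allele counts and called-genotype
    denominators. Variants with no called genotypes are excluded (logged).
    Missing genotypes contribute nothing for that individual at that site.
    """
    edges = tuple(bin_edges)
    ac = cohort.allele_counts()
    an = 2 * cohort.called_genotypes()
    n = cohort.n_samples
    dropped = int((an == 0).sum())
    if dropped:
        logger.info("excluding %d all-missing variants from burden", dropped)
    carried = cohort.dosages >= 1
    hom_alt = cohort.dosages == 2
    rows = []
    labels = _bin_labels(edges)
    classes = cohort.variants["var_class"].to_numpy()
    bins = np.array([assign_bin(int(a), int(d), edges) or "" for a, d in zip(ac, an)])
    for vc in sorted(set(classes)):
        for lab in labels:
            sel = (classes == vc) & (bins == lab)
            rows.append(
                {
                    "var_class": vc,
                    "bin": lab,
                    "n_sites": int(sel.sum()),
                    "mean_sites": float(carried[:, sel].sum() / n),
                    "mean_hom_alt": float(hom_alt[:, sel].sum() / n),
                }
            )
    return BurdenSummary(
        population=population or cohort.population, n_samples=n, table=pd.DataFrame(rows)
    )
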