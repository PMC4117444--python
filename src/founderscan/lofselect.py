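"""Genotype QC, LoF confidence calling, and enrichment-based variant selection.

Implements the filters used to pick founder-enriched loss-of-function
variants for follow-up genotyping:

* per-genotype QC -- genotype quality >= 30, depth >= 10, heterozygote
  allele balance in [0.3, 0.7], homozygote off-genotype read fraction
  < 0.1; failing calls are set to missing;
* per-variant LoF confidence -- high iff at least one transcript passes
  every annotation filter;
* allele-frequency concordance between two independent reference subsets
  (two-sided Fisher exact test; discordant variants are sequencing/alignment
  artifact candidates and are dropped at p <= 1e-5);
* the selection window itself -- founder allele frequency 0.5-5% and at
  least 2-fold enrichment over the reference population (absent from the
  reference counts as infinitely enriched);
* composite two-variant knockouts for genes carrying two LoF alleles
  (homozygous or compound heterozygous carriers count as knockouts;
  unphased compound heterozygotes are assumed to be in trans and flagged
  as such).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "SelectionDecision",
    "LOF_CONSEQUENCES",
    "genotype_qc",
    "qc_matrix",
    "lof_confidence",
    "nfe_concordance_test",
    "select_enriched",
    "make_composite",
]

MISSING = -1

LOF_CONSEQUENCES = frozenset({"stop_gained", "splice_donor", "splice_acceptor", "frameshift", "lof"})


@dataclass(frozen=True)
class GenotypeCall:
    """One genotype call with its quality metrics.

    ``ad`` is (reference reads, alternate reads); allele balance is the
    alternate fraction of the total.
    """

    dosage: int  # 0/1/2 or MISSING
    gq: int | None
    dp: int | None
    ad: tuple[int, int] | None

    @property
    def allele_balance(self) -> float | None:
        if self.ad is None:
            return None
        total = self.ad[0] + self.ad[1]
        return self.ad[1] / total if total > 0 else None


def genotype_qc(
    call: GenotypeCall,
    min_gq: int = 30,
    min_dp: int = 10,
    het_ab: tuple[float, float] = (0.3, 0.7),
    hom_off_frac: float = 0.1,
) -> int:
    """Return the retained dosage, or MISSING if the call fails QC.

    Missing FORMAT fields are treated as failing (logged at debug level).
    For homozygous calls the *off-genotype* read fraction (reference reads
    for hom-alt, alternate reads for hom-ref) must be below
    ``hom_off_frac``.
    """
    if call.dosage == MISSING:
        return MISSING
    if call.gq is None or call.dp is None:
        logger.debug("call lacks GQ/DP; treated as failing")
        return MISSING
    if call.gq < min_gq or call.dp < min_dp:
        return MISSING
    ab = call.allele_balance
    if call.dosage == 1:
        if ab is None or not (het_ab[0] <= ab <= het_ab[1]):
            return MISSING
    else:
        if ab is None:
            logger.debug("homozygous call lacks AD; treated as failing")
            return MISSING
        off = ab if call.dosage == 0 else 1.0 - ab
        if off >= hom_off_frac:
            return MISSING
    return call.dosage


def qc_matrix(
    dosages: np.ndarray,
    gq: np.ndarray,
    dp: np.ndarray,
    ad_ref: np.ndarray,
    ad_alt: np.ndarray,
    min_gq: int = 30,
    min_dp: int = 10,
    het_ab: tuple[float, float] = (0.3, 0.7),
    hom_off_frac: float = 0.1,
) -> np.ndarray:
    """Vectorized genotype QC over (n_samples x n_variants) arrays."""
    out = dosages.copy()
    total = ad_ref + ad_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(total > 0, ad_alt / total, np.nan)
    fail = (gq < min_gq) | (dp < min_dp)
    het = dosages == 1
    fail |= het & (~((ab >= het_ab[0]) & (ab <= het_ab[1])) | np.isnan(ab))
    off = np.where(dosages == 0, ab, 1.0 - ab)
    fail |= (dosages != 1) & (dosages != MISSING) & (np.isnan(off) | (off >= hom_off_frac))
    out[fail & (dosages != MISSING)] = MISSING
    return out


def lof_confidence(consequence: str, transcript_filter_pass: list[list[bool]] | list[bool]) -> str:
    """High/low confidence call for an annotated LoF variant.

    ``transcript_filter_pass`` is, per transcript, either a single boolean
    (passed all filters) or a list of per-filter booleans. A variant is
    ``high`` confidence iff at least one transcript passes every filter.
    Non-LoF consequences are outside the rule's domain and return
    ``not_applicable``.
    """
    if consequence not in LOF_CONSEQUENCES:
        logger.info("lof_confidence not applicable to consequence %r", consequence)
        return "not_applicable"
    if not transcript_filter_pass:
        return "low"
    for t in transcript_filter_pass:
        ok = all(t) if isinstance(t, (list, tuple)) else bool(t)
        if ok:
            return "high"
    return "low"


def nfe_concordance_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int], threshold: float = 1e-5
) -> tuple[float, bool]:
    """Fisher exact concordance of allele frequencies in two reference subsets.

    ``counts_a``/``counts_b`` are (alt, ref) allele counts. Returns the
    two-sided p and keep = (p > threshold). With no observed alleles in
    either subset there is no evidence of discordance; the variant is kept
    with a warning.
    """
    if sum(counts_a) == 0 or sum(counts_b) == 0:
        logger.warning("empty allele-count subset; keeping variant (no evidence of discordance)")
        return 1.0, True
    table = [[counts_a[0], counts_a[1]], [counts_b[0], counts_b[1]]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), bool(p > threshold)


@dataclass
class SelectionDecision:
    """Outcome of the enrichment filter for one variant."""

    variant_id: str
    founder_af: float
    reference_af: float
    fold: float  # math.inf when the reference frequency is 0
    concordance_p: float | None
    accepted: bool
    rejection_reason: str | None = None

    @property
    def fold_category(self) -> str | None:
        if not self.accepted:
            return None
        return ">10" if self.fold > 10 else ">2"


def select_enriched(
    variant_id: str,
    founder_af: float,
    reference_af: float,
    confidence: str = "high",
    concordance: tuple[float, bool] | None = None,
    freq_window: tuple[float, float] = (0.005, 0.05),
    min_fold: float = 2.0,
) -> SelectionDecision:
    """Apply the founder-enrichment selection rule to one variant.

    Accept iff the variant is high-confidence LoF, its founder allele
    frequency lies in ``freq_window`` (inclusive), its fold enrichment over
    the reference is >= ``min_fold`` (reference frequency 0 counts as
    infinite fold), and its reference subsets were concordant. Frequencies
    are expected to come from QC-passing genotypes only.
    """
    fold = math.inf if reference_af == 0 else founder_af / reference_af
    conc_p, conc_keep = concordance if concordance is not None else (None, True)

    reason = None
    if confidence != "high":
        reason = "not high-confidence LoF"
    elif not (freq_window[0] <= founder_af <= freq_window[1]):
        reason = "below frequency window" if founder_af < freq_window[0] else "above frequency window"
    elif fold < min_fold:
        reason = f"fold {fold:.3g} < {min_fold:g}"
    elif not conc_keep:
        reason = "reference subsets discordant"
    return SelectionDecision(
        variant_id=variant_id,
        founder_af=founder_af,
        reference_af=reference_af,
        fold=fold,
        concordance_p=conc_p,
        accepted=reason is None,
        rejection_reason=reason,
    )


def make_composite(dosage_1, dosage_2) -> np.ndarray:
    """Combine two same-gene LoF variants into one composite dosage.

    Per sample: missing if either constituent is missing, else
    min(2, d1 + d2). Samples reaching dosage 2 are complete knockouts --
    homozygous for either variant or compound heterozygous (assumed in
    trans when unphased). Symmetric in its arguments and capped at 2.
    """
    d1 = np.asarray(dosage_1, dtype=np.int8)
    d2 = np.asarray(dosage_2, dtype=np.int8)
    comp = np.minimum(d1 + d2, 2).astype(np.int8)
    comp[(d1 == MISSING) | (d2 == MISSING)] = MISSING
    return comp
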