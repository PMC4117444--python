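# Methods

`founderscan` implements the statistical machinery of a founder-population
loss-of-function (LoF) study: a forward simulation of allele frequencies
through a founding bottleneck, comparison of site-frequency spectra by
functional class, Hardy–Weinberg-based substructure and lethality screens,
enrichment-based variant selection with genotype-level QC, a
rank-inverse-normal association scan, and fixed-effects meta-analysis with
a Mendelian-randomization reading of mediated disease effects. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic data can and cannot show.

## Demographic and selection model

Two populations share a common ancestral allele frequency per site. The
founder population passes through a single instantaneous bottleneck of
`bottleneck_size` diploids (default 1,000) `bottleneck_start` generations
before present (default 100) and regrows exponentially to `present_size`;
the outbred population keeps a constant size. There is no migration,
recombination or new mutation: the model tracks standing variants, which is
sufficient for every site-level statistic downstream.

Selection is by viability on genotype fitnesses 1, 1−hs, 1−s (reference
homozygote, heterozygote, alternate homozygote). The deterministic
recursion

    q' = [q²(1−s) + q(1−q)(1−hs)] / [1 − sq² − 2hs·q(1−q)]

reduces for a complete recessive lethal (s=1, h=0) to q' = q/(1+q) with
closed form q_t = q₀/(1+t·q₀). The hyperbolic decay is the quantitative
reason recessive lethals entering a bottleneck at 1–5% are still at 0.1–1%
a hundred generations later yet below 0.1% after a thousand — selection
only sees the rare homozygotes. Stochastic mode applies the same recursion
and then resamples 2N gametes binomially each generation (Wright–Fisher),
so 0 and 1 are absorbing; the stochastic mean tracks the deterministic
curve up to a small Jensen-type bias of order q/2N per generation (the
recursion is concave), which at N = 10⁵ is within Monte-Carlo noise of a
few thousand replicate sites.

### Initial frequency spectra

Each variant class draws its initial frequency from a point mass or an
interval with one of three shapes: `uniform`, `log` (density ∝ 1/q, the
constant-size neutral spectrum) or `growth` (density ∝ q^{−3/2}, the
steeper spectrum of a recently expanded population). The default is
`growth` on (10⁻⁶, 0.05) for synonymous and (10⁻⁶, 0.01) for LoF sites
(LoF capped lower and given s = 0.01, h = 0.5, reflecting weak persistent
selection). The steep shape matters: the founder excess of low-frequency
variants is fed by promotion of ultra-rare alleles through the bottleneck,
and exists only when the sub-window reservoir is much larger than the
window occupancy — which is exactly the situation in real exome data,
where singletons dominate. With a uniform or even 1/q spectrum, or with a
small outbred population that drifts and loses its own rare variation, the
founder window count never exceeds the outbred one; we therefore set the
outbred (and ancestral) effective size to 500,000 so the comparison
population holds its expansion-shaped spectrum essentially frozen over the
100 simulated generations. Under these defaults the four directional
hallmarks — fewer singletons per founder individual, more 0.5–5% variants
in the founder cohort, a higher LoF share in that window, and a
significant class-ratio test — each held in 12/12 seeded replicates when
the defaults were frozen.

The default cohort sizes (3,000 + 3,000 samples, 8,000 sites per class)
mirror the scale of exome comparisons between a founder population and a
reference panel while keeping a full pipeline run around 20 s on one CPU.

### Genotypes, substructure, phenotypes

Genotypes are sampled per site from the Balding–Nichols genotype
probabilities (q² + Fq(1−q), 2q(1−q)(1−F), (1−q)² + Fq(1−q)), so the
substructure parameter F estimated downstream has a known generating
truth. Missing genotypes are injected at a configurable rate (default 0).

Quantitative traits are built as Σβ_v·dosage + 0.01·age + 0.1·female +
N(0,1), so per-allele effects β are in units of the residual SD. Disease
is an exponential time-to-event whose log-hazard is (standardized trait) ×
`trait_loghr` plus optional direct per-allele effects; the baseline hazard
is calibrated by root-finding so the marginal event fraction within the
follow-up window (default 10 years) equals the configured event rate, and
censoring is administrative at the end of follow-up. Setting the direct
effect to zero makes the exclusion-restriction condition of Mendelian
randomization true by construction, giving the identity (genotype→disease
log-HR) = (genotype→biomarker in SD) × (biomarker→disease log-HR per SD)
that the tests verify.

Randomness follows one named stream per stage (trajectories, genotypes,
samples, phenotypes, splits), each derived from the master seed and a
stable stage label, so identical configurations are byte-identical and any
stage can be re-run independently.

## Site-frequency spectrum and burdens

Sites are cross-classified by population × class × frequency bin.
Singletons are defined by alternate-allele count exactly 1; other bins are
half-open [lo, hi) on the frequency computed over called genotypes only,
with default interior edges 0.005, 0.01, 0.02, 0.05, 0.10 (the printed
figure this layout follows does not state its edges; these are configurable).
Alleles are taken as written in the VCF — no minor-allele folding, since
the 0.5–5% selection window refers to the alternate (LoF) allele. The
excess test is a one-sided binomial P(X ≥ n_A), X ~ Bin(n_A+n_B, ½); the
class test is a one-sided hypergeometric on the 2×2 class × population
table. One-sidedness is our documented reading of "excess in the founder
population"; the underlying report does not state sidedness. Per-individual
burdens are reported in two modes — sites carried and homozygous-alternate
sites — averaged over individuals.

## Hardy–Weinberg, F and the deficit screen

The exact HWE test conditions on sample size and allele count and sums the
probabilities of all heterozygote configurations no more probable than the
observed one (ties included — the standard convention); it is computed in
log-space and validated against exhaustive rational-arithmetic enumeration
for every configuration with n ≤ 50.

Substructure is estimated from the decomposition P(hom-alt) = q² +
Fq(1−q): per polymorphic site the excess homozygosity (observed hom-alt
fraction minus the HWE expectation) is regressed through the origin on
q(1−q); the slope is F̂. Because E[q̂²] = q² + q(1−q)/2n, the naive
expectation is biased exactly where founder data live (rare variants);
the default uses the unbiased form q̂² − q̂(1−q̂)/(2n−1), under which a
panmictic cohort centers on F̂ = 0 and the study-wide homozygote
observed/expected ratio centers on 1. The uncorrected expectation is
available by flag (`corrected=False`) for textbook arithmetic on exact
Hardy–Weinberg proportions. Unweighted least squares is the default;
inverse-variance weighting is a flag. Estimates slightly outside [0,1] are
reported and flagged, never clipped.

The homozygote-deficit screen pools genotype counts across cohorts (testing
pooled counts equals testing the summed counts), computes expected
homozygotes n·q̂², and for variants with expectation ≥ 3 (below that,
absence is uninformative) and observed < expected reports the exact HWE p
and a Poisson lower tail on the observed count; the flag fires on the
Poisson tail below 0.05. Combining cohorts by pooling counts and re-testing
is our documented choice where a combined p had no stated method.

## Variant QC and selection

Genotype-level QC sets a call to missing when GQ < 30, DP < 10, a
heterozygote's alternate-read fraction lies outside [0.3, 0.7], or a
homozygote's off-genotype read fraction (reference reads for hom-alt,
alternate for hom-ref — our reading of an undefined orientation) is ≥ 0.1.
QC is idempotent and has an exact vectorized equivalent.

A LoF variant is high-confidence iff at least one transcript passes every
annotation filter; the filters themselves are consumed as boolean flags,
never re-derived from sequence. Selection accepts high-confidence variants
with founder frequency in [0.005, 0.05] (post-QC frequencies; window
applied after QC by choice), fold enrichment ≥ 2 over the reference
(reference frequency 0 → fold ∞, sorted into the >10 category), and
concordant allele frequencies between two independent reference subsets
(two-sided Fisher exact, drop at p ≤ 10⁻⁵). Two same-gene LoF variants
combine into a composite dosage min(2, d₁+d₂); composite-2 carriers are
knockouts, with unphased compound heterozygotes assumed in trans.

## Association

Traits are residualized on age + age² within each sex stratum, then ranks
(ties averaged) map to normal quantiles with the Blom offset
(r − 3/8)/(n + 1/4); strata are recombined afterwards. Residualize-then-
transform ordering and the Blom constant are our documented choices where
the procedure's description is ambiguous; the transform depends only on
ranks, so it is invariant to monotone re-expression of the raw trait.

Per variant: OLS (closed form, t-based p) for quantitative traits;
maximum-likelihood logistic regression for prevalent disease (separation
signalled); Cox partial likelihood for incident disease with Breslow ties
by default and Efron by flag. Dosage coding is additive 0/1/2 (composite
dosages allowed); medications enter as binary covariates; a Fisher exact
test on the knockout × case table is available as the secondary
homozygote test. The screen reports all results below 2×10⁻⁴ together with
the expected chance count (tests × threshold) and the study-wide
Bonferroni line. Biomarker–disease direction uses two one-sided Welch
t-tests (higher-in-cases, lower-in-cases).

## Meta-analysis

Fixed effects only: β_c = Σ(β_i/SE_i²)/Σ(1/SE_i²), SE_c = (Σ1/SE_i²)^{−½},
two-sided normal p; Cochran's Q is emitted as a diagnostic, never a gate.
The combination is exactly associative. Fisher's method refers −2Σln p to
χ² with 2k df, computed in log space; since a published combined p for the
cardioprotective endpoint is only recoverable if one-sided (halved)
p-values were combined, both conventions are implemented and neither is
asserted as ground truth. The packaged summary table of discovery /
replication / combined columns is verified by recomputation: 30 of its 34
dual-entry rows reproduce (β, SE) within ±0.002 and 31 reproduce β; the
exceptions carry internally inconsistent printed values (one combined
column duplicated from an adjacent row, one replication effect
contradicting its own p-value, one SE apparently typoed).

## What the synthetic data does not show

The generator reproduces the *structure* the analyses assume — bottleneck
site-frequency distortion, Balding–Nichols substructure, mediated disease
risk — not the magnitudes of any real cohort. In particular: the default
singleton depletion is far stronger than the ~4-fold seen in real
founder-vs-reference comparisons (the simulated outbred population keeps
its full ultra-rare reservoir, real panels do not sequence deeply enough
to); linkage, relatedness, genotyping error and phenotype curation are
absent; and the zero-homozygote screen can only be checked at the printed
scale (n = 36,262, allele frequency 1.2%, zero homozygotes), where the
exact counts behind the published p = 0.0077 are unavailable — our
two-sided exact test gives 0.012 and the one-sided deficit tail 0.005,
bracketing it. Passing tests therefore demonstrate correctness of the
estimators and the direction and order of magnitude of the population
genetic effects, not numerical agreement with any cohort-specific value.

## Problem sizes

Defaults were chosen so the full default pipeline runs in ~20 s and the
complete test suite in a few minutes on one CPU: 8,000 sites per class and
3,000 samples per cohort for spectrum contrasts; 5,000 sites × 3,000
samples for F̂ recovery; n = 9,000–25,000 single-variant cohorts for
effect-size recovery (matching the reported study scales); 2,000
replicates for the null calibration of the INT + OLS scan; 2,000 replicate
sites for stochastic-vs-deterministic trajectory comparisons.
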