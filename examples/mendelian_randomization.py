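"""Mendelian randomization on simulated genotype -> biomarker -> disease data.

A variant that lowers a biomarker, where the biomarker drives disease
hazard and the variant has no direct disease effect, acts as a natural
experiment: the genotype-disease log-hazard should equal the product of
the genotype-biomarker effect (in SD) and the biomarker-disease
log-hazard per SD. The simulation makes that mediation structure true by
construction and the analysis recovers it.
"""

import numpy as np

import founderscan as fs

cfg = fs.SimConfig(
    mode="deterministic", n_sites_per_class=1,
    sample_sizes={"founder": 15_000, "outbred": 1},
    class_specs=(fs.VariantClassSpec("lof", s=0.0, h=0.5, q0=0.1),), seed=10,
)
cohort = fs.simulate_cohorts(cfg)["founder"]
vid = cohort.variants["variant_id"][0]
spec = fs.EffectSpec(variant=vid, trait="biomarker", beta=-0.5, trait_loghr=0.4)
pheno = fs.simulate_phenotypes(cohort, [spec], seed=10)

z = fs.int_transform(pheno["biomarker"], pheno["sex"], pheno["age"])
geno_bio = fs.linear_assoc(cohort.dosages[:, 0], z)
geno_dis = fs.cox_assoc(cohort.dosages[:, 0], pheno["event"], pheno["time"])

product = geno_bio.effect * spec.trait_loghr
print(f"genotype -> biomarker:  {geno_bio.effect:+.3f} SD per allele (SE {geno_bio.se:.3f})")
print(f"biomarker -> disease:   {spec.trait_loghr:+.3f} log-hazard per SD (simulation truth)")
print(f"predicted genotype -> disease log-hazard: {product:+.3f}")
print(f"observed Cox genotype -> disease log-hazard: {geno_dis.effect:+.3f} (SE {geno_dis.se:.3f})")
print(f"per-allele hazard ratio: {np.exp(geno_dis.effect):.3f}")
print("-> the Cox effect matches the mediation product within sampling error, the "
      "identity a Mendelian-randomization reading of a protective variant relies on.")
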