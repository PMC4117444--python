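"""Variant-trait association with the rank-inverse-normal pipeline.

Simulates a cohort in which one low-frequency LoF variant lowers a
biomarker by 0.6 SD per allele, transforms the trait (sex-stratified
age + age^2 residualization, then Blom rank-normal scores), scans every
variant, and prints the screen report with its chance-expectation
arithmetic.
"""

import founderscan as fs

cfg = fs.SimConfig(
    mode="deterministic",
    n_sites_per_class=40,
    sample_sizes={"founder": 4000, "outbred": 1},
    class_specs=(fs.VariantClassSpec("lof", s=0.0, h=0.5, q0=(0.02, 0.08), q0_shape="uniform"),),
    seed=5,
)
cohort = fs.simulate_cohorts(cfg)["founder"]
causal = cohort.variants["variant_id"].iloc[7]
pheno = fs.simulate_phenotypes(
    cohort, [fs.EffectSpec(variant=causal, trait="biomarker", beta=-0.6)], seed=5
)

z = fs.int_transform(pheno["biomarker"], pheno["sex"], pheno["age"])
results = []
for j, vid in enumerate(cohort.variants["variant_id"]):
    results.append(fs.linear_assoc(cohort.dosages[:, j], z, variant_id=vid, trait_id="biomarker"))

report = fs.screen_all(results, n_variants=len(results), n_traits=1)
print(f"scan of {report['n_tests']} variant x trait tests at p < {report['screen_p']:g}")
print(f"expected chance hits: {report['expected_chance_hits']:.3f}; "
      f"study-wide Bonferroni threshold: {report['bonferroni_threshold']:.2g}")
for hit in report["hits"]:
    star = "*" if hit["study_wide_significant"] else ""
    print(f"  {hit['variant_id']:8s} beta={hit['effect']:+.3f} SD/allele "
          f"se={hit['se']:.3f} p={hit['p']:.2g} {star}")
print(f"-> the causal variant ({causal}) is recovered with an effect near -0.6 SD; "
      "everything else stays at chance level.")
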