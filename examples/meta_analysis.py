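"""Combine discovery and replication results by fixed-effects meta-analysis.

Loads the packaged summary-statistics table from a published screen of
Finnish-enriched LoF variants (discovery, replication and combined
columns), recomputes every combined column by inverse-variance weighting,
and shows Fisher's combined probability and a forest table for a
cardioprotective endpoint.
"""

from founderscan import fisher_combined, forest_summary, ivw_meta
from founderscan.metastats import load_screen_summary, verify_combined_columns

m = ivw_meta([(-0.608, 0.031), (-0.729, 0.055)])
print("lipoprotein(a)-lowering variant, discovery + replication:")
print(f"  combined beta = {m.effect:.3f} SD/allele, SE = {m.se:.3f}, p = {m.p:.2e}")

check = verify_combined_columns(tol=0.002)
print(f"\nIVW reproduces {int(check['match'].sum())} of {len(check)} printed combined "
      "(beta, SE) columns within +/-0.002")
print("rows that do not reproduce (internally inconsistent printed values):")
for _, row in check[~check["match"]].iterrows():
    print(f"  {row['trait']:12s} {row['gene']:8s} "
          f"ivw=({row['ivw_beta']:+.3f}, {row['ivw_se']:.3f}) "
          f"printed=({row['printed_beta']:+.3f}, {row['printed_se']:.3f})")

p_two = fisher_combined([0.0067, 0.016])
p_one = fisher_combined([0.0067, 0.016], one_sided=True)
print(f"\nFisher's combined probability for two cardioprotective results "
      f"(p = 0.0067, 0.016):\n  two-sided inputs: {p_two:.2e}; one-sided inputs: {p_one:.2e}")

forest = forest_summary({"population cohort": (-0.236, 0.087), "case-control replication": (-0.139, 0.058)})
print("\nforest table (log-HR scale, hazard-ratio columns exponentiated):")
print(forest.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("-> each study's 95% CI and the IVW-combined row, ready for a forest plot.")
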