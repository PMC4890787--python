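"""Candidate-gene triage by 2^-ddCt relative expression.

Simulates the seven-gene qPCR panel (facial and dorsal skin, four
embryonic stages, two-week-old and adult birds, sextuplicate wells),
quantifies relative expression against GAPDH, and classifies each gene:
a causal candidate must be differential in facial skin at every embryonic
stage AND in the adult, with the wild type essentially silent (ectopic
activation, not modulation).
"""

from mbsv.exprq import classify_candidate, compare_groups, delta_delta_ct
from mbsv.syndata import mb_expression_panel, simulate_ct_table

panel = mb_expression_panel()
ct = simulate_ct_table(panel, seed=71)

rel = delta_delta_ct(
    ct, calibrator_group={"genotype": "mb/mb", "tissue": "dorsal", "stage": "adult"}
)
hox = rel[(rel["gene"] == "HOXB8") & (rel["tissue"] == "facial")
          & (rel["stage"] == "adult")]
print("HOXB8 adult facial skin fold change vs calibrator:")
print(hox[["genotype", "fold"]].to_string(index=False))

cmp = compare_groups(
    ct, "HOXB8",
    {"genotype": "mb/mb", "tissue": "facial", "stage": "adult"},
    {"genotype": "Mb/Mb", "tissue": "facial", "stage": "adult"},
)
print(f"\ncarrier vs wild type: p = {cmp.p_value:.2e} {cmp.tier} "
      f"(log2 fold {cmp.estimate_log2_fold:+.1f})")

print("\npattern classification across the panel:")
for gene in panel["gene"].unique():
    call = classify_candidate(ct, gene)
    tag = "Mb-consistent" if call.mb_consistent else "rejected"
    stages = call.evidence
    n_sig = int(stages["significant"].sum())
    print(f"  {gene:<8} {tag:<14} ({n_sig}/{len(stages)} stages differential)")

print("\nOnly the gene ectopically active in carrier facial skin through "
      "the whole feather-development window survives; genes differential "
      "only postnatally are excluded as consequences rather than causes.")
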