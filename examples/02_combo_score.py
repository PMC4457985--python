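"""The combined two-locus protective-allele score.

Enumerates the nine genotype combinations at rs480902 (EGLN1) / rs1063856
(VWF) with protective allele T at both, scores a small synthetic cohort,
and tabulates the score distribution per subgroup.
"""

import numpy as np

import clinescreen as cs

# 1. The score mapping itself: CC/CC -> 0 ... TT/TT -> 4
table = cs.enumerate_combo_table()
print("genotype combination -> protective-allele count")
for combo, score in sorted(table.items(), key=lambda kv: kv[1]):
    print(f"  {combo}: {score}")
print(f"{len(table)} combinations; 0 = double risk homozygote (CC/CC), "
      f"4 = all alleles protective (TT/TT)\n")

# 2. Score a simulated two-group cohort with contrasting protective frequencies
loci = (
    cs.LocusInfo("rs480902", "C", "T", effect_allele="T", protective_flag=True),
    cs.LocusInfo("rs1063856", "C", "T", effect_allele="T", protective_flag=True),
)
spec = cs.CohortSpec(
    groups=(
        cs.GroupSpec("P", 29, {"rs480902": 0.75, "rs1063856": 0.95}),
        cs.GroupSpec("K", 28, {"rs480902": 0.40, "rs1063856": 0.63}),
    ),
    loci=loci,
    seed=7,
)
gm, samples = cs.gen_cohort(spec)
scores = cs.score_samples(gm)
dist = cs.score_distribution(scores, samples, by="group_label", max_score=4)
print(dist.pivot(index="score", columns="stratum", values="count").to_string())
mean = {g: np.mean([c.score for c in scores if c.sample_id.startswith(g)])
        for g in ("P", "K")}
print(f"\nmean score P = {mean['P']:.2f}, K = {mean['K']:.2f}: the group with "
      "higher protective-allele frequencies concentrates at high scores.")
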