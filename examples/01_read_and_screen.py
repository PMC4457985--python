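"""Read a small genotype table and Fisher-screen two subgroups.

Builds a 10-sample genotype TSV at two SNPs, reads it into a dosage matrix,
and tests for an allele-frequency difference between groups A and B with
per-comparison FDR control.
"""

import tempfile
from pathlib import Path

import pandas as pd

import clinescreen as cs

loci = [
    cs.LocusInfo("rs480902", "C", "T", effect_allele="T", gene_label="EGLN1"),
    cs.LocusInfo("rs1063856", "C", "T", effect_allele="C", gene_label="VWF"),
]

# group A is T-rich at rs480902; the second SNP is similar in both groups
rows = [
    ("A1", "TT", "CT"), ("A2", "TT", "CC"), ("A3", "CT", "CT"),
    ("A4", "TT", "CT"), ("A5", "TT", "CC"),
    ("B1", "CC", "CT"), ("B2", "CT", "CC"), ("B3", "CC", "CT"),
    ("B4", "CC", "CC"), ("B5", "CT", "NN"),  # one missing call
]

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "genotypes.tsv"
    path.write_text(
        "sample_id\trs480902\trs1063856\n"
        + "\n".join("\t".join(r) for r in rows) + "\n"
    )
    gm = cs.read_genotype_tsv(path, loci)

samples = cs.SampleTable(pd.DataFrame({
    "sample_id": [r[0] for r in rows],
    "group_label": ["A"] * 5 + ["B"] * 5,
    "population_id": ["demo"] * 10,
    "altitude_m": [float("nan")] * 10,
}))

records = cs.screen(gm, samples, comparisons=[("A", "B")], alpha_fdr=0.05)
print(cs.records_to_frame(records).round(4).to_string(index=False))
print()
print("freq_1/freq_2 are effect-allele frequencies in groups A and B;")
print("p_allelic is the two-sided Fisher p on the 2x2 allele table and")
print("q_allelic its BH-adjusted value within this comparison. The planted")
print("rs480902 contrast (T: 0.9 vs 0.2) stands out; rs1063856 does not.")
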