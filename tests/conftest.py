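import numpy as np
import pandas as pd
import pytest

from clinescreen import GenotypeMatrix, LocusInfo, SampleTable


@pytest.fixture
def score_loci() -> list[LocusInfo]:
    """The two default score loci: EGLN1 rs480902 (effect = protective T)
    and VWF rs1063856 (effect = risk C, so protective dosage is 2 - d)."""
    return [
        LocusInfo("rs480902", "C", "T", effect_allele="T", protective_flag=True,
                  gene_label="EGLN1"),
        LocusInfo("rs1063856", "C", "T", effect_allele="C", gene_label="VWF"),
    ]


@pytest.fixture
def small_matrix(score_loci) -> GenotypeMatrix:
    # rs480902 T-dosage, rs1063856 C-dosage
    dosage = np.array(
        [
            [0.0, 2.0],  # CC / CC  -> score 0
            [2.0, 0.0],  # TT / TT  -> score 4
            [1.0, 0.0],  # CT / TT  -> score 3
            [2.0, np.nan],  # missing at rs1063856
        ]
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], score_loci, dosage)


@pytest.fixture
def small_samples() -> SampleTable:
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group_label": ["K", "P", "P", "K"],
                "population_id": ["pop1", "pop1", "pop2", "pop2"],
                "altitude_m": [100.0, 100.0, 3500.0, 3500.0],
            }
        )
    )


def write_genotype_file(path, header, rows):
    lines = ["\t".join(["sample_id"] + header)]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
)


def write_vcf(path, sample_ids, variants):
    """variants: list of (pos, vid, ref, alt, [gt strings])."""
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids))
    for pos, vid, ref, alt, gts in variants:
        lines.append(f"1\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
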