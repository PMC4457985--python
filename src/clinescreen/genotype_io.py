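"""Genotype and metadata I/O.

Reads genotype tables (two-letter genotype TSV or VCF) and sample metadata
into an effect-allele dosage matrix. Dosage is the per-sample count of a
user-designated *effect allele* (0, 1, 2, or missing), stored as float with
NaN for missing calls so that whole-matrix operations vectorise.

Genotype strings are unphased and strand-naive: allele letters in the data
must match the locus annotation exactly; no strand flipping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NN"

__all__ = [
    "MISSING_TOKEN",
    "LocusInfo",
    "GenotypeMatrix",
    "SampleTable",
    "read_locus_annotations",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_genotype_vcf",
    "allele_counts",
]


@dataclass(frozen=True)
class LocusInfo:
    """Annotation for one biallelic SNP.

    ``effect_allele`` is the allele counted by the dosage coding; whether it
    is the designated protective allele is carried as annotation
    (``protective_flag``), never inferred — ancestral/derived status is an
    input of the analysis, not something this package computes.
    """

    locus_id: str
    allele_a: str
    allele_b: str
    effect_allele: str
    protective_flag: bool = False
    gene_label: str = ""

    def __post_init__(self) -> None:
        for name in ("allele_a", "allele_b", "effect_allele"):
            a = getattr(self, name)
            if not (isinstance(a, str) and len(a) == 1):
                raise ValueError(f"{self.locus_id}: {name} must be a single character, got {a!r}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.locus_id}: alleles must differ")
        if self.effect_allele not in (self.allele_a, self.allele_b):
            raise ValueError(
                f"{self.locus_id}: effect allele {self.effect_allele!r} not in "
                f"({self.allele_a!r}, {self.allele_b!r})"
            )

    @property
    def other_allele(self) -> str:
        return self.allele_b if self.effect_allele == self.allele_a else self.allele_a


class GenotypeMatrix:
    """Samples x loci effect-allele dosage matrix.

    ``dosage`` is a float array of shape (n_samples, n_loci) whose non-missing
    entries are in {0, 1, 2}; missing calls are NaN.
    """

    def __init__(self, sample_ids: Sequence[str], loci: Sequence[LocusInfo], dosage: np.ndarray):
        sample_ids = list(sample_ids)
        loci = list(loci)
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(sample_ids), len(loci)):
            raise ValueError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(loci)} loci"
            )
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        ids = [l.locus_id for l in loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus ids")
        finite = dosage[np.isfinite(dosage)]
        if not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosage values must be 0, 1 or 2")
        self.sample_ids = sample_ids
        self.loci = loci
        self.dosage = dosage
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}
        self._locus_index = {l.locus_id: j for j, l in enumerate(loci)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def locus(self, locus_id: str) -> LocusInfo:
        try:
            return self.loci[self._locus_index[locus_id]]
        except KeyError:
            raise KeyError(f"locus {locus_id!r} not in matrix") from None

    def locus_column(self, locus_id: str) -> int:
        if locus_id not in self._locus_index:
            raise KeyError(f"locus {locus_id!r} not in matrix")
        return self._locus_index[locus_id]

    def dosage_vector(self, locus_id: str) -> np.ndarray:
        return self.dosage[:, self.locus_column(locus_id)]

    def sample_rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_loci} loci)"


@dataclass
class SampleTable:
    """Per-sample metadata: subgroup label, population, altitude (metres)."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "group_label", "population_id", "altitude_m")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("sample_id", "group_label", "population_id"):
            if col not in df.columns:
                raise ValueError(f"sample table missing column {col!r}")
            df[col] = df[col].astype(str)
        if "altitude_m" not in df.columns:
            df["altitude_m"] = np.nan
        df["altitude_m"] = pd.to_numeric(df["altitude_m"], errors="raise")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in sample table: {dups[:5]}")
        if (df["altitude_m"].dropna() < 0).any():
            raise ValueError("altitude_m must be >= 0 where present")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def samples_in_group(self, group: str | Sequence[str]) -> list[str]:
        """Sample ids whose group_label equals ``group`` (or is in it, when a
        sequence of labels is given — used for pooled-group comparisons)."""
        labels = [group] if isinstance(group, str) else list(group)
        mask = self.df["group_label"].isin(labels)
        return self.df.loc[mask, "sample_id"].tolist()

    def samples_in_population(self, population_id: str) -> list[str]:
        mask = self.df["population_id"] == str(population_id)
        return self.df.loc[mask, "sample_id"].tolist()

    @property
    def group_labels(self) -> list[str]:
        return sorted(self.df["group_label"].unique())

    def __len__(self) -> int:
        return len(self.df)


def read_locus_annotations(path) -> list[LocusInfo]:
    """Read a locus annotation TSV: locus_id, allele_a, allele_b,
    effect_allele, protective_flag, gene_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "allele_a", "allele_b", "effect_allele"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table missing columns {sorted(required - set(df.columns))}")
    out = []
    for row in df.itertuples(index=False):
        flag = str(getattr(row, "protective_flag", "false")).strip().lower() in ("1", "true", "yes")
        out.append(
            LocusInfo(
                locus_id=row.locus_id,
                allele_a=row.allele_a,
                allele_b=row.allele_b,
                effect_allele=row.effect_allele,
                protective_flag=flag,
                gene_label=str(getattr(row, "gene_label", "") or ""),
            )
        )
    if len({l.locus_id for l in out}) != len(out):
        raise ValueError("duplicate locus ids in annotation table")
    return out


def _dosage_from_genotype(cell: str, locus: LocusInfo, sample_id: str, missing_token: str) -> float:
    if cell == missing_token:
        return np.nan
    if len(cell) != 2:
        raise ValueError(
            f"sample {sample_id!r}, locus {locus.locus_id!r}: malformed genotype {cell!r}"
        )
    valid = {locus.allele_a, locus.allele_b}
    for ch in cell:
        if ch not in valid:
            raise ValueError(
                f"sample {sample_id!r}, locus {locus.locus_id!r}: unknown allele "
                f"{ch!r} in genotype {cell!r} (expected {sorted(valid)})"
            )
    return float(cell.count(locus.effect_allele))


def read_genotype_tsv(
    path, locus_annotations: Sequence[LocusInfo], missing_token: str = MISSING_TOKEN
) -> GenotypeMatrix:
    """Read a genotype TSV (header of locus ids, one row per sample, cells are
    two-letter genotype strings like ``CT`` or the missing token).

    Heterozygotes are unordered: ``CT`` and ``TC`` code the same dosage.
    Column order in the file defines locus order in the matrix; every column
    must have an annotation.
    """
    ann = {l.locus_id: l for l in locus_annotations}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"first column must be 'sample_id', got {df.columns[0]!r}")
    locus_ids = list(df.columns[1:])
    unknown = [lid for lid in locus_ids if lid not in ann]
    if unknown:
        raise ValueError(f"loci in file without annotation: {unknown[:5]}")
    sample_ids = df["sample_id"].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample id(s) in genotype file: {dups[:5]}")
    loci = [ann[lid] for lid in locus_ids]
    dosage = np.empty((len(sample_ids), len(loci)))
    for j, locus in enumerate(loci):
        col = df[locus.locus_id].tolist()
        for i, cell in enumerate(col):
            dosage[i, j] = _dosage_from_genotype(str(cell), locus, sample_ids[i], missing_token)
    return GenotypeMatrix(sample_ids, loci, dosage)


def write_genotype_tsv(gm: GenotypeMatrix, path, missing_token: str = MISSING_TOKEN) -> None:
    """Write a GenotypeMatrix back to the two-letter genotype TSV dialect.

    Heterozygotes are written with alleles in lexicographic order; a re-read
    yields identical dosage values.
    """
    cols = {"sample_id": gm.sample_ids}
    for j, locus in enumerate(gm.loci):
        eff, oth = locus.effect_allele, locus.other_allele
        geno = {2.0: eff + eff, 1.0: "".join(sorted((eff, oth))), 0.0: oth + oth}
        col = [missing_token if not np.isfinite(d) else geno[d] for d in gm.dosage[:, j]]
        cols[locus.locus_id] = col
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_genotype_vcf(path, locus_annotations: Sequence[LocusInfo]) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT subfield only), matching loci by ID.

    GT allele indices are mapped through REF/ALT to allele letters and then to
    effect-allele dosage. Half-missing genotypes (``./1``) are coded missing.
    An annotated locus absent from the VCF yields a warning and a column of
    missing calls; REF/ALT letters inconsistent with the annotation are a hard
    error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    found: dict[str, np.ndarray] = {}
    wanted = {l.locus_id: l for l in locus_annotations}
    for variant in vcf:
        vid = variant.ID
        if vid not in wanted:
            continue
        locus = wanted[vid]
        letters = [variant.REF] + list(variant.ALT)
        valid = {locus.allele_a, locus.allele_b}
        if not set(letters).issubset(valid):
            raise ValueError(
                f"locus {vid!r}: VCF alleles {letters} inconsistent with "
                f"annotation {sorted(valid)}"
            )
        col = np.empty(len(sample_ids))
        for i, g in enumerate(variant.genotypes):
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:  # fully or half missing
                col[i] = np.nan
            else:
                col[i] = float(
                    (letters[a1] == locus.effect_allele) + (letters[a2] == locus.effect_allele)
                )
        found[vid] = col
    dosage = np.empty((len(sample_ids), len(locus_annotations)))
    for j, locus in enumerate(locus_annotations):
        if locus.locus_id in found:
            dosage[:, j] = found[locus.locus_id]
        else:
            warnings.warn(f"locus {locus.locus_id!r} absent from VCF; coding column as missing")
            dosage[:, j] = np.nan
    return GenotypeMatrix(sample_ids, list(locus_annotations), dosage)


def allele_counts(
    gm: GenotypeMatrix, samples: Sequence[str], locus: str
) -> tuple[int, int]:
    """Effect-allele and other-allele counts for a sample subset at one locus.

    Missing calls are excluded per SNP (complete-case within the comparison);
    counts sum to twice the number of non-missing samples.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("sample subset must be non-empty")
    d = gm.dosage[gm.sample_rows(samples), gm.locus_column(locus)]
    called = np.isfinite(d)
    effect = int(np.nansum(d))
    total = 2 * int(called.sum())
    return effect, total - effect
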