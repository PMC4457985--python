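"""Per-SNP Fisher exact association between cohort subgroups, with FDR control.

The screen compares the effect-allele frequency of every locus between two
groups of samples — pairwise subgroups, one subgroup against a pooled rest, or
pooled subgroups against a background panel — using a two-sided Fisher exact
test on the 2x2 allele-count table (allelic arm) and on the 2x3 table of
genotype classes (genotypic arm). P-values are adjusted per comparison across
all loci by the Benjamini-Hochberg step-up procedure.

Two-sided exact p-values follow the point-probability (minimum-likelihood)
rule used by mainstream statistics packages: the sum of the probabilities of
all tables with the observed margins whose probability does not exceed that of
the observed table (within a small relative tolerance to absorb floating-point
ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype_io import GenotypeMatrix, SampleTable

__all__ = [
    "FisherResult",
    "fisher_2x2",
    "fisher_rxc",
    "bh_fdr",
    "AssociationRecord",
    "screen",
    "records_to_frame",
    "write_records_tsv",
]

_TIE_TOL = 1e-7

# log-factorial lookup, grown on demand; exact table enumeration needs
# log C(n, k) for n up to the total count of the largest table seen.
_LOGF = np.array([0.0])


def _log_factorials(n: int) -> np.ndarray:
    global _LOGF
    if len(_LOGF) <= n:
        start = len(_LOGF)
        ext = np.log(np.arange(start, n + 1, dtype=float))
        _LOGF = np.concatenate([_LOGF, _LOGF[-1] + np.cumsum(ext)])
    return _LOGF


class FisherResult(NamedTuple):
    """Two-sided exact p-value plus a flag for uninformative margins."""

    p: float
    degenerate: bool


def _validate_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.number):
        raise ValueError("counts must be numeric")
    if np.any(t < 0):
        raise ValueError("negative count in contingency table")
    if np.any(t != np.floor(t)):
        raise ValueError("non-integer count in contingency table")
    return t.astype(np.int64)


def fisher_2x2(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table of non-negative counts.

    Sums hypergeometric point probabilities over the support of the first
    cell. A table with a zero row margin, or with all counts in one column,
    carries no association information and is flagged degenerate (p = 1).
    """
    t = _validate_counts(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    return fisher_rxc(t)


def fisher_rxc(table: Sequence[Sequence[int]]) -> FisherResult:
    """Two-sided Fisher exact test on a 2xC table by full enumeration.

    Enumerates every table with the observed margins (feasible at cohort
    scale); the probability of a table given margins is
    ``prod_j C(c_j, a_j) / C(N, r_1)`` where ``a_j`` is the first-row entry in
    column ``j``. Zero columns force zero cells and drop out of the
    enumeration, so a 2x3 table with an empty column equals the 2x2 test on
    the remaining columns.
    """
    t = _validate_counts(table)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError(f"expected a 2xC table, got shape {t.shape}")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = int(t.sum())
    degenerate = bool((row == 0).any() or (col > 0).sum() <= 1)
    if n == 0:
        return FisherResult(1.0, True)
    logf = _log_factorials(n)
    r1 = int(row[0])
    denom = logf[n] - logf[r1] - logf[n - r1]  # log C(N, r1)

    # Enumerate first-row compositions column by column.
    cols = col.astype(int)
    k = len(cols)
    logps: list[float] = []

    def recurse(j: int, remaining: int, acc: float) -> None:
        if j == k - 1:
            a = remaining
            if 0 <= a <= cols[j]:
                c = cols[j]
                logps.append(acc + logf[c] - logf[a] - logf[c - a])
            return
        tail_cap = int(cols[j + 1 :].sum())
        lo = max(0, remaining - tail_cap)
        hi = min(cols[j], remaining)
        c = cols[j]
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, acc + logf[c] - logf[a] - logf[c - a])

    recurse(0, r1, -denom)
    logp_all = np.array(logps)

    # log-probability of the observed table
    obs = 0.0 - denom
    for j in range(k):
        c, a = int(cols[j]), int(t[0, j])
        obs += logf[c] - logf[a] - logf[c - a]

    keep = logp_all <= obs + np.log1p(_TIE_TOL)
    if keep.all():  # every table ties or falls below the observed one
        return FisherResult(1.0, degenerate)
    p = float(np.exp(logp_all[keep]).sum())
    return FisherResult(min(max(p, np.finfo(float).tiny), 1.0), degenerate)


def bh_fdr(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (Benjamini-Yekutieli with
    ``method='by'``), returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(p, method=sm_method)[1]


@dataclass
class AssociationRecord:
    """One SNP x one subgroup comparison.

    Frequencies are effect-allele frequencies held at full precision; rounding
    to the two decimals conventional in association tables happens only when
    writing output.
    """

    locus_id: str
    gene_label: str
    comparison: tuple[str, str]
    freq_1: float
    freq_2: float
    n1_alleles: int
    n2_alleles: int
    p_allelic: float
    p_genotypic: float
    q_allelic: float = np.nan
    q_genotypic: float = np.nan
    degenerate: bool = False
    significant: bool = False


def _group_name(group: str | Sequence[str]) -> str:
    return group if isinstance(group, str) else "+".join(group)


def screen(
    gm: GenotypeMatrix,
    st: SampleTable,
    comparisons: Sequence[tuple[str | Sequence[str], str | Sequence[str]]],
    alpha_fdr: float = 0.05,
    genotypic: bool = True,
    fdr_method: str = "bh",
    joint_fdr: bool = False,
) -> list[AssociationRecord]:
    """Fisher-screen every locus for each comparison, with per-comparison FDR.

    Each comparison is a pair of group specifications: a group label, or a
    sequence of labels to pool (e.g. ``(("V", "P", "K"), "IE_POOL")`` for
    pooled subgroups against the background panel). The FDR family is all
    loci within one comparison, allelic and genotypic arms adjusted
    separately; ``joint_fdr=True`` adjusts each arm across all comparisons
    jointly instead. Records are flagged significant when the allelic
    q-value is at most ``alpha_fdr``.

    ``genotypic=False`` skips the 2x3 genotype-class test (its p/q emitted as
    NaN), which is useful in large simulation sweeps of the allelic arm.
    """
    if not (0 < alpha_fdr < 1):
        raise ValueError("alpha_fdr must be in (0, 1)")
    records: list[AssociationRecord] = []
    per_comparison: list[list[AssociationRecord]] = []
    for g1, g2 in comparisons:
        ids1, ids2 = st.samples_in_group(g1), st.samples_in_group(g2)
        for label, ids in ((g1, ids1), (g2, ids2)):
            if not ids:
                raise ValueError(f"group {label!r} has no samples")
        rows1, rows2 = gm.sample_rows(ids1), gm.sample_rows(ids2)
        d1, d2 = gm.dosage[rows1], gm.dosage[rows2]
        eff1 = np.nansum(d1, axis=0)
        eff2 = np.nansum(d2, axis=0)
        tot1 = 2 * np.isfinite(d1).sum(axis=0)
        tot2 = 2 * np.isfinite(d2).sum(axis=0)
        comp_records = []
        name = (_group_name(g1), _group_name(g2))
        for j, locus in enumerate(gm.loci):
            a, b = int(eff1[j]), int(tot1[j] - eff1[j])
            c, d = int(eff2[j]), int(tot2[j] - eff2[j])
            allelic = fisher_2x2([[a, b], [c, d]])
            if genotypic:
                g1_counts = [(d1[:, j] == k).sum() for k in (0, 1, 2)]
                g2_counts = [(d2[:, j] == k).sum() for k in (0, 1, 2)]
                geno = fisher_rxc([g1_counts, g2_counts])
                p_geno = geno.p
            else:
                p_geno = np.nan
            comp_records.append(
                AssociationRecord(
                    locus_id=locus.locus_id,
                    gene_label=locus.gene_label,
                    comparison=name,
                    freq_1=a / tot1[j] if tot1[j] else np.nan,
                    freq_2=c / tot2[j] if tot2[j] else np.nan,
                    n1_alleles=int(tot1[j]),
                    n2_alleles=int(tot2[j]),
                    p_allelic=allelic.p,
                    p_genotypic=p_geno,
                    degenerate=allelic.degenerate,
                )
            )
        per_comparison.append(comp_records)
        records.extend(comp_records)

    families = [records] if joint_fdr else per_comparison
    for family in families:
        q_a = bh_fdr([r.p_allelic for r in family], method=fdr_method)
        for r, q in zip(family, q_a):
            r.q_allelic = float(q)
            r.significant = bool(q <= alpha_fdr)
        if genotypic:
            q_g = bh_fdr([r.p_genotypic for r in family], method=fdr_method)
            for r, q in zip(family, q_g):
                r.q_genotypic = float(q)
    return records


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Association records as a DataFrame (full precision)."""
    return pd.DataFrame(
        {
            "gene": [r.gene_label for r in records],
            "locus_id": [r.locus_id for r in records],
            "comparison": ["{}vs{}".format(*r.comparison) for r in records],
            "freq_1": [r.freq_1 for r in records],
            "freq_2": [r.freq_2 for r in records],
            "n1_alleles": [r.n1_alleles for r in records],
            "n2_alleles": [r.n2_alleles for r in records],
            "p_allelic": [r.p_allelic for r in records],
            "q_allelic": [r.q_allelic for r in records],
            "p_genotypic": [r.p_genotypic for r in records],
            "q_genotypic": [r.q_genotypic for r in records],
            "degenerate": [r.degenerate for r in records],
            "significant": [r.significant for r in records],
        }
    )


def write_records_tsv(records: Sequence[AssociationRecord], path) -> None:
    """Write records as TSV, frequencies rounded to two decimals for display."""
    df = records_to_frame(records)
    df["freq_1"] = df["freq_1"].round(2)
    df["freq_2"] = df["freq_2"].round(2)
    df.to_csv(path, sep="\t", index=False)
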