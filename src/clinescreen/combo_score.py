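"""Combined multi-locus protective-allele score.

An individual's score is the unweighted count of designated protective
alleles over k loci, so it ranges 0..2k. With the default two-locus
configuration — protective allele T at rs480902 (EGLN1, the
high-altitude-adaptation-associated allele) and at rs1063856 (VWF, the
derived non-thrombotic allele) — score 0 is the CC/CC double risk homozygote
and score 4 the TT/TT double protective homozygote, and the nine two-locus
genotype combinations map onto scores 0..4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleTable

__all__ = [
    "ScoreLocus",
    "ScoreConfig",
    "DEFAULT_SCORE_CONFIG",
    "ComboScore",
    "score_samples",
    "enumerate_combo_table",
    "score_distribution",
]


@dataclass(frozen=True)
class ScoreLocus:
    """One scored locus: which allele counts as protective, and its partner."""

    locus_id: str
    protective_allele: str
    risk_allele: str

    def __post_init__(self) -> None:
        if self.protective_allele == self.risk_allele:
            raise ValueError(f"{self.locus_id}: protective and risk alleles must differ")


@dataclass(frozen=True)
class ScoreConfig:
    loci: tuple[ScoreLocus, ...]
    missing_policy: Literal["exclude_sample", "not_applicable"] = "exclude_sample"

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValueError("at least one locus required")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate locus in score configuration")

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def max_score(self) -> int:
        return 2 * self.k


DEFAULT_SCORE_CONFIG = ScoreConfig(
    loci=(
        ScoreLocus("rs480902", protective_allele="T", risk_allele="C"),
        ScoreLocus("rs1063856", protective_allele="T", risk_allele="C"),
    )
)


@dataclass(frozen=True)
class ComboScore:
    """Per-sample protective-allele count; ``score`` is None when any scored
    locus is missing under the ``not_applicable`` policy."""

    sample_id: str
    score: int | None


def score_samples(gm: GenotypeMatrix, cfg: ScoreConfig = DEFAULT_SCORE_CONFIG) -> list[ComboScore]:
    """Score every sample as the sum of protective-allele dosages.

    The dosage matrix counts the annotated effect allele; when the protective
    allele is the other one the contribution is ``2 - dosage``. Samples with
    a missing call at any configured locus are dropped (``exclude_sample``,
    the default) or emitted with ``score=None`` (``not_applicable``).
    """
    contributions = np.zeros((gm.n_samples, cfg.k))
    for j, sl in enumerate(cfg.loci):
        locus = gm.locus(sl.locus_id)  # raises KeyError if absent
        pair = {locus.allele_a, locus.allele_b}
        if {sl.protective_allele, sl.risk_allele} != pair:
            raise ValueError(
                f"{sl.locus_id}: score alleles {sl.protective_allele}/{sl.risk_allele} "
                f"do not match annotated pair {sorted(pair)}"
            )
        d = gm.dosage_vector(sl.locus_id)
        contributions[:, j] = d if sl.protective_allele == locus.effect_allele else 2.0 - d
    total = contributions.sum(axis=1)
    out: list[ComboScore] = []
    for sid, s in zip(gm.sample_ids, total):
        if np.isfinite(s):
            out.append(ComboScore(sid, int(round(s))))
        elif cfg.missing_policy == "not_applicable":
            out.append(ComboScore(sid, None))
    return out


def enumerate_combo_table(cfg: ScoreConfig = DEFAULT_SCORE_CONFIG) -> dict[str, int]:
    """Map each two-locus genotype combination to its score (k = 2 only).

    Returns exactly nine entries (3 x 3 genotype classes), keyed
    ``"<geno1>/<geno2>"`` with each genotype's alleles in lexicographic
    order, e.g. ``"CC/CC" -> 0`` and ``"TT/TT" -> 4`` under the default
    configuration.
    """
    if cfg.k != 2:
        raise ValueError("genotype-combination enumeration is defined for exactly two loci")
    per_locus: list[list[tuple[str, int]]] = []
    for sl in cfg.loci:
        genos = []
        for n_prot in (0, 1, 2):
            alleles = [sl.risk_allele] * (2 - n_prot) + [sl.protective_allele] * n_prot
            genos.append(("".join(sorted(alleles)), n_prot))
        per_locus.append(genos)
    return {
        f"{g1}/{g2}": s1 + s2
        for g1, s1 in per_locus[0]
        for g2, s2 in per_locus[1]
    }


def score_distribution(
    scores: Sequence[ComboScore],
    st: SampleTable,
    by: Literal["group_label", "population_id"] = "group_label",
    max_score: int | None = None,
) -> pd.DataFrame:
    """Counts and frequencies of each score value per stratum.

    Emits one row per (stratum, score) over the full score range 0..2k, so
    the frequency of the top score (all alleles protective) is always
    present. Strata with no scored samples appear with count 0 and NaN
    frequencies.
    """
    scored = {cs.sample_id: cs.score for cs in scores if cs.score is not None}
    if max_score is None:
        max_score = max(scored.values()) if scored else 0
    strata = sorted(st.df[by].unique())
    sample_stratum = dict(zip(st.df["sample_id"], st.df[by]))
    rows = []
    for stratum in strata:
        vals = [s for sid, s in scored.items() if sample_stratum.get(sid) == stratum]
        n = len(vals)
        for score in range(max_score + 1):
            count = sum(v == score for v in vals)
            rows.append(
                {
                    "stratum": stratum,
                    "score": score,
                    "count": count,
                    "frequency": count / n if n else np.nan,
                    "n_scored": n,
                }
            )
    return pd.DataFrame(rows)
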