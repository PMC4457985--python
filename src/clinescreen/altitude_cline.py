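"""Population-level score summaries and altitude-cline correlation.

Summarises combined genotype scores per population (mean score and the
frequency of the maximal, all-protective score) and tests for a cline —
a monotone relationship between a population summary and altitude — with
Spearman's rank correlation. Ties take mid-ranks; the two-sided p-value is
an exact permutation enumeration for small panels (n <= 8) and the usual
t-approximation with n - 2 degrees of freedom otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Sequence

import numpy as np
from scipy import stats

from .combo_score import ComboScore
from .genotype_io import SampleTable

__all__ = [
    "PopulationScoreSummary",
    "CorrelationResult",
    "summarize_populations",
    "spearman",
    "cline_test",
]

_EXACT_N_MAX = 8


@dataclass(frozen=True)
class PopulationScoreSummary:
    population_id: str
    n_scored: int
    mean_score: float
    freq_score_max: float
    altitude_m: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str  # "exact_permutation" | "t_approximation" | "undefined"
    zero_variance: bool = False


def summarize_populations(
    scores: Sequence[ComboScore], st: SampleTable, max_score: int = 4
) -> list[PopulationScoreSummary]:
    """One summary per population with at least one scored sample.

    ``max_score`` is 2k for the k-locus score (4 for the default two-locus
    configuration); ``freq_score_max`` is the fraction of scored samples
    carrying only protective alleles. Populations whose samples were all
    excluded (missing genotypes) are omitted with a warning. Altitude must be
    single-valued within a population.
    """
    scored = {cs.sample_id: cs.score for cs in scores if cs.score is not None}
    out: list[PopulationScoreSummary] = []
    for pop, sub in st.df.groupby("population_id", sort=True):
        vals = [scored[s] for s in sub["sample_id"] if s in scored]
        if not vals:
            warnings.warn(f"population {pop!r} has no scored samples; omitted")
            continue
        alts = sub["altitude_m"].dropna().unique()
        if len(alts) > 1:
            raise ValueError(f"population {pop!r} has conflicting altitudes {alts}")
        out.append(
            PopulationScoreSummary(
                population_id=str(pop),
                n_scored=len(vals),
                mean_score=float(np.mean(vals)),
                freq_score_max=float(np.mean([v == max_score for v in vals])),
                altitude_m=float(alts[0]) if len(alts) else np.nan,
            )
        )
    return out


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of mid-ranks. For n <= 8 the two-sided
    p-value enumerates all n! permutations of one rank vector (the exact
    null distribution of rho given the observed tie pattern); for larger n
    the t-approximation with n - 2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(np.nan, n, 1.0, "undefined", zero_variance=True)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= _EXACT_N_MAX:
        obs = abs(rho)
        hits = 0
        for perm in permutations(ry):
            if abs(_rank_rho(rx, np.array(perm))) >= obs - 1e-12:
                hits += 1
        p = hits / factorial(n)
        return CorrelationResult(rho, n, p, "exact_permutation")
    res = stats.spearmanr(x, y)
    p = min(max(float(res.pvalue), np.finfo(float).tiny), 1.0)
    return CorrelationResult(rho, n, p, "t_approximation")


def cline_test(summaries: Sequence[PopulationScoreSummary]) -> dict[str, CorrelationResult]:
    """Rank-correlate population score summaries with altitude.

    Returns Spearman results for the mean score and for the frequency of the
    maximal (all-protective) score against altitude, over populations with a
    known altitude. Requires at least 3 such populations.
    """
    usable = [s for s in summaries if np.isfinite(s.altitude_m)]
    if len(usable) < 3:
        raise ValueError("need at least 3 populations with altitude")
    alt = [s.altitude_m for s in usable]
    return {
        "mean_score": spearman([s.mean_score for s in usable], alt),
        "freq_score_max": spearman([s.freq_score_max for s in usable], alt),
    }
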