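"""Synthetic genotype cohorts and population panels.

Generates data with the statistical structure the analysis assumes —
Hardy-Weinberg genotype sampling at specified per-group effect-allele
frequencies, independent loci, optional missingness — so every pipeline
stage is testable without any genotype download.

`reference_cohort` builds the package's standard test cohort: three
constitution-type subgroups Vata/Pitta/Kapha of sizes 39/29/28 plus a
92-sample heterogeneous-phenotype background pool (IE pool), genotyped at
2,800 loci of which nine carry planted between-group allele-frequency
contrasts (the association-table effect sizes this package's screen is sized
for, plus a synthetic two-locus protective-allele contrast at
rs480902/rs1063856) and 2,791 are null.

Randomness: one `numpy` SeedSequence per run, spawn-keyed per group /
population, so regenerating a subset reproduces it bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, LocusInfo, SampleTable

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "PopulationSpec",
    "PanelSpec",
    "gen_cohort",
    "gen_panel",
    "logistic_cline",
    "PLANTED_CONTRASTS",
    "SCORE_LOCUS_FREQUENCIES",
    "reference_cohort",
    "reference_panel_spec",
]


@dataclass(frozen=True)
class GroupSpec:
    """One cohort subgroup: label, size and per-locus effect-allele frequency.

    A frequency entry may instead be a length-3 tuple of genotype-class
    probabilities (dosage 0/1/2) for non-HWE sampling.
    """

    label: str
    size: int
    freqs: Mapping[str, float | tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"group {self.label!r}: size must be >= 1")
        for lid, f in self.freqs.items():
            if isinstance(f, tuple):
                if len(f) != 3 or any(p < 0 for p in f) or abs(sum(f) - 1.0) > 1e-9:
                    raise ValueError(f"{self.label}/{lid}: genotype probs must sum to 1")
            elif not (0.0 <= f <= 1.0):
                raise ValueError(f"{self.label}/{lid}: frequency {f} outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    loci: tuple[LocusInfo, ...]
    hwe: bool = True
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        ids = {l.locus_id for l in self.loci}
        for g in self.groups:
            missing = ids - set(g.freqs)
            if missing:
                raise ValueError(f"group {g.label!r}: no frequency for loci {sorted(missing)[:5]}")


def _draw_group(g: GroupSpec, loci: Sequence[LocusInfo], hwe: bool, missing_rate: float,
                rng: np.random.Generator) -> np.ndarray:
    m = len(loci)
    dosage = np.empty((g.size, m))
    for j, locus in enumerate(loci):
        f = g.freqs[locus.locus_id]
        if isinstance(f, tuple):
            dosage[:, j] = rng.choice(3, size=g.size, p=f)
        elif hwe:
            dosage[:, j] = rng.binomial(2, f, size=g.size)
        else:
            raise ValueError(
                f"group {g.label!r}: hwe=False requires genotype-class probabilities"
            )
    if missing_rate > 0:
        mask = rng.random((g.size, m)) < missing_rate
        dosage[mask] = np.nan
    return dosage


def gen_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, SampleTable]:
    """Sample a cohort: per sample per locus, dosage ~ Binomial(2, group
    frequency) under HWE; loci independent; calls masked missing at
    ``missing_rate``. Fully reproducible from ``spec.seed``."""
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.groups))
    blocks, ids, labels = [], [], []
    for g, ss in zip(spec.groups, children):
        rng = np.random.default_rng(ss)
        blocks.append(_draw_group(g, spec.loci, spec.hwe, spec.missing_rate, rng))
        ids.extend(f"{g.label}_{i:04d}" for i in range(g.size))
        labels.extend([g.label] * g.size)
    gm = GenotypeMatrix(ids, list(spec.loci), np.vstack(blocks))
    st = SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "group_label": labels,
                "population_id": labels,
                "altitude_m": np.nan,
            }
        )
    )
    return gm, st


def logistic_cline(intercept: float, slope: float) -> Callable[[float], float]:
    """Logistic-in-altitude allele-frequency cline: f(alt) = expit(intercept +
    slope * alt). Bounded in (0, 1) for any altitude by construction."""
    def f(altitude_m: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(intercept + slope * altitude_m))))
    return f


@dataclass(frozen=True)
class PopulationSpec:
    population_id: str
    size: int
    altitude_m: float

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"population {self.population_id!r}: size must be >= 1")
        if self.altitude_m < 0:
            raise ValueError(f"population {self.population_id!r}: altitude must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    """Population panel with altitude-dependent allele frequencies.

    ``cline`` maps each locus id to either a constant frequency or a
    callable of altitude (see :func:`logistic_cline`)."""

    populations: tuple[PopulationSpec, ...]
    loci: tuple[LocusInfo, ...]
    cline: Mapping[str, float | Callable[[float], float]]
    missing_rate: float = 0.0
    seed: int = 0

    def frequency(self, locus_id: str, altitude_m: float) -> float:
        c = self.cline[locus_id]
        f = c(altitude_m) if callable(c) else float(c)
        if not (0.0 <= f <= 1.0):
            raise ValueError(
                f"cline for {locus_id!r} gives frequency {f} outside [0, 1] "
                f"at altitude {altitude_m}"
            )
        return f


def gen_panel(spec: PanelSpec) -> tuple[GenotypeMatrix, SampleTable]:
    """Sample a population panel: per-population frequencies from the cline
    function, then HWE genotype sampling as in :func:`gen_cohort`. The sample
    table carries population_id and altitude_m; group_label marks panel
    membership."""
    for pop in spec.populations:  # validate the whole cline up front
        for locus in spec.loci:
            spec.frequency(locus.locus_id, pop.altitude_m)
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.populations))
    blocks, rows = [], []
    for pop, ss in zip(spec.populations, children):
        rng = np.random.default_rng(ss)
        g = GroupSpec(
            label=pop.population_id,
            size=pop.size,
            freqs={l.locus_id: spec.frequency(l.locus_id, pop.altitude_m) for l in spec.loci},
        )
        blocks.append(_draw_group(g, spec.loci, True, spec.missing_rate, rng))
        for i in range(pop.size):
            rows.append(
                {
                    "sample_id": f"{pop.population_id}_{i:04d}",
                    "group_label": "PANEL",
                    "population_id": pop.population_id,
                    "altitude_m": pop.altitude_m,
                }
            )
    st = SampleTable(pd.DataFrame(rows))
    gm = GenotypeMatrix(st.df["sample_id"].tolist(), list(spec.loci), np.vstack(blocks))
    return gm, st


# ---------------------------------------------------------------------------
# Reference cohort: the planted association structure
# ---------------------------------------------------------------------------

#: Planted between-group effect-allele frequency contrasts: nine
#: (locus, comparison) pairs over eight distinct SNPs (rs3741860 is planted
#: in two comparisons). Frequencies are the generating values for the named
#: groups; groups not named here default to the unweighted mean of the named
#: ones (see _reference_frequencies).
PLANTED_CONTRASTS: tuple[dict, ...] = (
    dict(gene="LEPR", locus="rs1171271", alleles=("C", "T"), effect="C",
         comparison=("P", "K"), freqs=(0.46, 0.13)),
    dict(gene="OR6K3", locus="rs857703", alleles=("A", "G"), effect="A",
         comparison=("K", "V"), freqs=(0.11, 0.43)),
    dict(gene="UCP2", locus="rs660339", alleles=("A", "G"), effect="A",
         comparison=("K", "V"), freqs=(0.15, 0.49)),
    dict(gene="OLR1", locus="rs3741860", alleles=("A", "G"), effect="G",
         comparison=("V", "P"), freqs=(0.49, 0.14)),
    dict(gene="OLR1", locus="rs3741860", alleles=("A", "G"), effect="G",
         comparison=("P", "K"), freqs=(0.14, 0.53)),
    dict(gene="SPTA1", locus="rs857691", alleles=("C", "T"), effect="T",
         comparison=("P", "K"), freqs=(0.40, 0.06)),
    dict(gene="SPTA1", locus="rs857721", alleles=("A", "T"), effect="A",
         comparison=("P", "K"), freqs=(0.43, 0.05)),
    dict(gene="VWF", locus="rs1063856", alleles=("C", "T"), effect="C",
         comparison=("P", "K"), freqs=(0.05, 0.37)),
    dict(gene="OR10Z1", locus="rs857685", alleles=("A", "C"), effect="C",
         comparison=("P", "K"), freqs=(0.41, 0.05)),
)

#: SYNTHETIC defaults for the EGLN1 score locus: per-group frequency of the
#: protective T allele at rs480902. This cohort's true rs480902 frequencies
#: were never published; these values merely give the two-locus score a
#: group contrast to exercise (Pitta enriched, Kapha depleted, pool
#: intermediate).
SCORE_LOCUS_FREQUENCIES: dict[str, float] = {"V": 0.55, "P": 0.75, "K": 0.40, "IE_POOL": 0.57}

GROUP_SIZES: dict[str, int] = {"V": 39, "P": 29, "K": 28, "IE_POOL": 92}

N_TOTAL_LOCI = 2800


def _reference_frequencies() -> tuple[list[LocusInfo], dict[str, dict[str, float]]]:
    """Planted loci and their per-group generating frequencies.

    Groups without a planted value for a locus — and the IE background
    pool — receive the unweighted mean of that locus's planted group
    frequencies, so the pooled cohort does not contrast with the background.
    """
    per_locus: dict[str, dict[str, float]] = {}
    loci: dict[str, LocusInfo] = {}
    for row in PLANTED_CONTRASTS:
        lid = row["locus"]
        a, b = row["alleles"]
        loci.setdefault(
            lid,
            LocusInfo(lid, a, b, effect_allele=row["effect"], gene_label=row["gene"]),
        )
        d = per_locus.setdefault(lid, {})
        for grp, f in zip(row["comparison"], row["freqs"]):
            d[grp] = f
    for lid, d in per_locus.items():
        fill = float(np.mean(list(d.values())))
        for grp in GROUP_SIZES:
            d.setdefault(grp, fill)
    # EGLN1 score locus: effect allele = protective T (synthetic frequencies)
    egln1 = LocusInfo("rs480902", "C", "T", effect_allele="T",
                      protective_flag=True, gene_label="EGLN1")
    loci[egln1.locus_id] = egln1
    per_locus[egln1.locus_id] = dict(SCORE_LOCUS_FREQUENCIES)
    return list(loci.values()), per_locus


def reference_cohort(seed: int = 17) -> tuple[GenotypeMatrix, SampleTable]:
    """Deterministic standard cohort: V/P/K at 39/29/28 plus a 92-sample IE
    background pool, 188 samples x 2,800 loci.

    Nine loci are informative — the eight planted-contrast SNPs of
    :data:`PLANTED_CONTRASTS` plus rs480902 with synthetic score-locus
    frequencies — and 2,791 null loci share across all groups a frequency
    drawn once from Uniform(0.05, 0.95). Identical seeds give bitwise-
    identical cohorts.
    """
    planted_loci, per_locus = _reference_frequencies()
    n_null = N_TOTAL_LOCI - len(planted_loci)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    null_freqs = rng.uniform(0.05, 0.95, size=n_null)
    null_loci = [
        LocusInfo(f"rsNULL{i:04d}", "A", "G", effect_allele="A", gene_label="NULL")
        for i in range(n_null)
    ]
    loci = tuple(planted_loci + null_loci)
    groups = []
    for label, size in GROUP_SIZES.items():
        freqs: dict[str, float] = {l.locus_id: per_locus[l.locus_id][label] for l in planted_loci}
        freqs.update({l.locus_id: float(f) for l, f in zip(null_loci, null_freqs)})
        groups.append(GroupSpec(label=label, size=size, freqs=freqs))
    spec = CohortSpec(groups=tuple(groups), loci=loci, seed=seed)
    return gen_cohort(spec)


def reference_panel_spec(
    n_populations: int = 20,
    samples_per_population: int = 30,
    max_altitude_m: float = 4000.0,
    intercept: float = -0.85,
    slope_per_m: float = 5e-4,
    seed: int = 17,
) -> PanelSpec:
    """Panel of populations spanning sea level to high altitude with a
    logistic protective-allele cline at both score loci.

    Defaults give protective-T frequency ~0.30 at sea level rising to ~0.76
    at 4,000 m, emulating a worldwide panel in which high-altitude
    populations selectively retain the protective two-locus combination.
    ``slope_per_m=0`` yields a flat (null) panel.
    """
    altitudes = np.linspace(0.0, max_altitude_m, n_populations)
    pops = tuple(
        PopulationSpec(f"POP{i:02d}", samples_per_population, float(a))
        for i, a in enumerate(altitudes)
    )
    loci = (
        LocusInfo("rs480902", "C", "T", effect_allele="T", protective_flag=True,
                  gene_label="EGLN1"),
        LocusInfo("rs1063856", "C", "T", effect_allele="T", protective_flag=True,
                  gene_label="VWF"),
    )
    cline = {l.locus_id: logistic_cline(intercept, slope_per_m) for l in loci}
    return PanelSpec(populations=pops, loci=loci, cline=cline, seed=seed)
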