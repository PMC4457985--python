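"""Fisher exact kernels, BH adjustment, and the subgroup screen."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import clinescreen as cs
from clinescreen.synthetic_data import CohortSpec, GroupSpec, gen_cohort
from oracles import bh_oracle, fisher_2x2_oracle, fisher_2x3_oracle

counts = st.integers(min_value=0, max_value=25)


class TestFisher2x2:
    def test_equal_proportions_give_one(self):
        assert cs.fisher_2x2([[5, 5], [5, 5]]).p == 1.0

    def test_diagonal_table_enumeration(self):
        # margins (2,2)/(2,2): three tables with point probs 1/6, 4/6, 1/6
        assert cs.fisher_2x2([[2, 0], [0, 2]]).p == pytest.approx(1 / 3, rel=1e-12)

    def test_zero_row_margin_degenerate(self):
        r = cs.fisher_2x2([[0, 0], [3, 4]])
        assert r.p == 1.0 and r.degenerate

    def test_single_nonzero_column_degenerate(self):
        r = cs.fisher_2x2([[4, 0], [7, 0]])
        assert r.p == 1.0 and r.degenerate

    def test_negative_count_raises(self):
        with pytest.raises(ValueError, match="negative"):
            cs.fisher_2x2([[1, -1], [0, 2]])

    def test_reconstructed_association_table_magnitude(self):
        """Allele counts reconstructed from rounded frequencies 0.43 vs 0.05
        at 58/56 alleles give a p-value of the same order as the published
        6e-07 (rounding and unknown missingness preclude an exact match)."""
        p = cs.fisher_2x2([[25, 33], [3, 53]]).p
        assert 1e-8 < p < 1e-5

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(counts, counts, counts, counts)
    def test_row_and_column_swap_invariance(self, a, b, c, d):
        p0 = cs.fisher_2x2([[a, b], [c, d]]).p
        assert cs.fisher_2x2([[c, d], [a, b]]).p == pytest.approx(p0, rel=1e-10)
        assert cs.fisher_2x2([[b, a], [d, c]]).p == pytest.approx(p0, rel=1e-10)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(counts, counts, counts, counts)
    def test_matches_exact_rational_oracle(self, a, b, c, d):
        p = cs.fisher_2x2([[a, b], [c, d]]).p
        assert p == pytest.approx(fisher_2x2_oracle([[a, b], [c, d]]), rel=1e-9)

    def test_matches_scipy_on_random_tables(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(7)
        for _ in range(200):
            t = rng.integers(0, 40, size=(2, 2))
            if t.sum(axis=1).min() == 0 or (t.sum(axis=0) > 0).sum() <= 1:
                continue
            assert cs.fisher_2x2(t).p == pytest.approx(
                fisher_exact(t)[1], rel=1e-9
            ), t


class TestFisherRxc:
    def test_uniform_table_gives_one(self):
        assert cs.fisher_rxc([[10, 10, 10], [10, 10, 10]]).p == 1.0

    def test_zero_column_equals_reduced_2x2(self):
        full = cs.fisher_rxc([[4, 2, 0], [1, 5, 0]])
        reduced = cs.fisher_2x2([[4, 2], [1, 5]])
        assert full.p == pytest.approx(reduced.p, rel=1e-12)

    def test_derived_2x3_example_against_oracle(self):
        p = cs.fisher_rxc([[4, 2, 0], [0, 2, 4]]).p
        assert p == pytest.approx(fisher_2x3_oracle([[4, 2, 0], [0, 2, 4]]), rel=1e-9)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(st.lists(st.integers(0, 12), min_size=6, max_size=6))
    def test_matches_exact_rational_oracle(self, cells):
        t = [cells[:3], cells[3:]]
        assert cs.fisher_rxc(t).p == pytest.approx(fisher_2x3_oracle(t), rel=1e-9)


class TestBhFdr:
    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(cs.bh_fdr([0.01] * 10), [0.01] * 10)

    def test_single_pvalue_identity(self):
        assert cs.bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_step_up_worked_example(self):
        got = cs.bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2])
        np.testing.assert_allclose(got, [0.005, 0.025, 1 / 30, 0.05, 0.2], rtol=1e-9)

    def test_empty_input(self):
        assert len(cs.bh_fdr([])) == 0

    def test_out_of_range_raises(self):
        for bad in ([0.0], [1.5], [np.nan]):
            with pytest.raises(ValueError):
                cs.bh_fdr(bad)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, 100)
        q = cs.bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            p = rng.uniform(1e-8, 1, rng.integers(1, 40))
            np.testing.assert_allclose(cs.bh_fdr(p), bh_oracle(p), rtol=1e-12)


def _two_group_cohort(freq1, freq2, n1, n2, m, seed, planted_freqs=None):
    """Cohort of two groups; locus 0 optionally planted, the rest null."""
    rng = np.random.default_rng(seed)
    null = rng.uniform(0.1, 0.9, m)
    loci = tuple(
        cs.LocusInfo(f"rs{j}", "A", "G", effect_allele="A") for j in range(m)
    )
    f1 = {f"rs{j}": float(null[j]) for j in range(m)}
    f2 = dict(f1)
    if planted_freqs:
        f1["rs0"], f2["rs0"] = planted_freqs
    spec = CohortSpec(
        groups=(GroupSpec("g1", n1, f1), GroupSpec("g2", n2, f2)),
        loci=loci,
        seed=seed,
    )
    return gen_cohort(spec)


class TestScreen:
    def test_identical_groups_not_significant(self, score_loci):
        d = np.array([[1.0, 0.0], [2.0, 1.0], [1.0, 0.0], [2.0, 1.0]])
        gm = cs.GenotypeMatrix(["a1", "a2", "b1", "b2"], score_loci, d)
        st_ = cs.SampleTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"],
                 "group_label": ["X", "X", "Y", "Y"],
                 "population_id": ["p"] * 4, "altitude_m": [0.0] * 4}
            )
        )
        recs = cs.screen(gm, st_, [("X", "Y")])
        assert all(r.p_allelic == 1.0 and not r.significant for r in recs)

    def test_missing_group_raises(self, small_matrix, small_samples):
        with pytest.raises(ValueError, match="no samples"):
            cs.screen(small_matrix, small_samples, [("K", "ABSENT")])

    def test_record_fields_and_q_dominates_p(self, small_matrix, small_samples):
        recs = cs.screen(small_matrix, small_samples, [("K", "P")])
        for r in recs:
            assert 0 < r.p_allelic <= 1 and r.q_allelic >= r.p_allelic - 1e-15
            assert r.n1_alleles % 2 == 0 and r.n2_alleles % 2 == 0

    def test_all_missing_group_flagged_degenerate(self, score_loci):
        d = np.array([[np.nan, 1.0], [np.nan, 0.0], [1.0, 1.0], [0.0, 2.0]])
        gm = cs.GenotypeMatrix(["a1", "a2", "b1", "b2"], score_loci, d)
        st_ = cs.SampleTable(
            pd.DataFrame(
                {"sample_id": ["a1", "a2", "b1", "b2"],
                 "group_label": ["X", "X", "Y", "Y"],
                 "population_id": ["p"] * 4, "altitude_m": [0.0] * 4}
            )
        )
        recs = cs.screen(gm, st_, [("X", "Y")])
        by_locus = {r.locus_id: r for r in recs}
        assert by_locus["rs480902"].degenerate and by_locus["rs480902"].p_allelic == 1.0

    def test_planted_snp_attains_smallest_q_in_majority_of_replicates(self):
        """One strong planted frequency difference among null SNPs should rank
        first by q in most replicates."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            gm, st_ = _two_group_cohort(0.1, 0.6, 30, 30, 40, seed, planted_freqs=(0.1, 0.6))
            recs = cs.screen(gm, st_, [("g1", "g2")], genotypic=False)
            best = min(recs, key=lambda r: (r.q_allelic, r.p_allelic))
            wins += best.locus_id == "rs0"
        assert wins > n_rep / 2

    def test_global_null_false_discovery_proportion_controlled(self):
        """With no true frequency differences, the mean realized FDP at
        q <= 0.05 over many simulated screens stays below 0.075."""
        fdps = []
        for seed in range(100):
            gm, st_ = _two_group_cohort(None, None, 30, 30, 250, seed)
            recs = cs.screen(gm, st_, [("g1", "g2")], genotypic=False)
            n_sig = sum(r.significant for r in recs)
            fdps.append(n_sig / max(n_sig, 1) if n_sig else 0.0)
        assert np.mean(fdps) <= 0.075

    def test_output_frame_rounds_frequencies_only_on_write(self, tmp_path,
                                                           small_matrix, small_samples):
        recs = cs.screen(small_matrix, small_samples, [("K", "P")])
        full = cs.records_to_frame(recs)
        out = tmp_path / "recs.tsv"
        cs.write_records_tsv(recs, out)
        written = pd.read_csv(out, sep="\t")
        assert np.allclose(written["freq_1"], full["freq_1"].round(2), equal_nan=True)
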