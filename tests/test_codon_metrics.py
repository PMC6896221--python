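import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cubkit import (
    CodingGene,
    SimulationConfig,
    aggregate_indices,
    count_codons,
    enc,
    fop,
    gc3s,
    pooled_counts,
    rscu,
    simulate_gene_set,
    wright_f_hat,
)
from cubkit.genetic_code import CODON_INDEX
from cubkit.optimal_codons import from_preferred_map
from cubkit.sequence_io import GeneSet, expression_extremes


class TestCountCodons:
    def test_simple_gene(self, code):
        g = CodingGene("g", ("ATG", "AAA", "AAG"))
        counts = count_codons(g, code)
        assert counts[CODON_INDEX["ATG"]] == 1
        assert counts[CODON_INDEX["AAA"]] == 1
        assert counts.sum() == 3

    def test_ambiguous_codons_skipped_gene_retained(self, code):
        g = CodingGene("g", ("AAA",) * 200 + ("AAN",))
        counts = count_codons(g, code)
        assert counts.sum() == 200

    def test_terminal_stop_excluded(self, code):
        g = CodingGene("g", ("ATG", "AAA", "TAA"))
        counts = count_codons(g, code)
        assert counts[CODON_INDEX["TAA"]] == 0
        assert counts.sum() == 2

    def test_all_ambiguous_gives_zero_vector(self, code):
        g = CodingGene("g", ("NNN", "ANA"))
        assert count_codons(g, code).sum() == 0


class TestRscu:
    def test_two_fold_family_hand_value(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAA"]] = 6  # Lys
        counts[CODON_INDEX["AAG"]] = 2
        r = rscu(counts, code)
        assert r[CODON_INDEX["AAA"]] == pytest.approx(1.5)
        assert r[CODON_INDEX["AAG"]] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self, code, uniform_counts):
        r = rscu(uniform_counts, code)
        for fam in code.families.values():
            if len(fam) >= 2:
                for c in fam:
                    assert r[CODON_INDEX[c]] == pytest.approx(1.0)

    def test_zero_total_family_is_masked_not_zero(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAA"]] = 3
        r = rscu(counts, code)
        assert np.isnan(r[CODON_INDEX["GGG"]])  # empty Gly family

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4))
    def test_family_mean_is_one_whenever_total_positive(self, code, fam_counts):
        counts = np.zeros(64, dtype=np.int64)
        gly = code.families["G"]
        for c, n in zip(gly, fam_counts):
            counts[CODON_INDEX[c]] = n
        r = rscu(counts, code)
        vals = [r[CODON_INDEX[c]] for c in gly]
        if sum(fam_counts) > 0:
            assert np.mean(vals) == pytest.approx(1.0)
        else:
            assert all(np.isnan(v) for v in vals)


class TestEnc:
    def test_uniform_usage_is_61(self, uniform_counts, code):
        assert enc(uniform_counts, code) == 61.0

    def test_one_codon_per_amino_acid_is_20(self, single_codon_counts, code):
        assert enc(single_codon_counts, code) == pytest.approx(20.0)

    def test_f_hat_hand_value(self):
        # counts (3,1): F = (4 * 0.625 - 1)/3 = 0.5
        assert wright_f_hat(np.array([3, 1])) == pytest.approx(0.5)

    def test_f_hat_undefined_below_two_counts(self):
        assert np.isnan(wright_f_hat(np.array([1, 0])))

    def test_bounds_on_random_counts(self, code):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(0, 40, size=64)
            e = enc(counts, code)
            if not np.isnan(e):
                assert 20.0 <= e <= 61.0

    def test_scale_invariance_in_large_count_limit(self, code):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 20, size=64)
        e10 = enc(base * 10, code)
        e1000 = enc(base * 1000, code)
        assert abs(e10 - e1000) < 0.5

    def test_no_computable_family_is_nan(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["ATG"]] = 100  # Met only: nothing estimable
        assert np.isnan(enc(counts, code))


class TestGc3s:
    def test_all_gc_ending(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAG"]] = 10
        counts[CODON_INDEX["GGC"]] = 5
        assert gc3s(counts, code) == 1.0

    def test_all_at_ending(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAA"]] = 10
        counts[CODON_INDEX["GGT"]] = 5
        assert gc3s(counts, code) == 0.0

    def test_met_trp_only_is_undefined(self, code):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["ATG"]] = 10
        counts[CODON_INDEX["TGG"]] = 10
        assert np.isnan(gc3s(counts, code))


class TestFop:
    @pytest.fixture
    def lys_pref(self, code):
        return from_preferred_map({"K": "AAG"}, code)

    def test_every_codon_optimal(self, code, lys_pref):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAG"]] = 30
        assert fop(counts, lys_pref, code) == 1.0

    def test_no_optimal_codon_used(self, code, lys_pref):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAA"]] = 30
        assert fop(counts, lys_pref, code) == 0.0

    def test_half_optimal(self, code, lys_pref):
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAG"]] = 30
        counts[CODON_INDEX["AAA"]] = 30
        # Gly codons are ineligible (no optimal codon for Gly in the set)
        counts[CODON_INDEX["GGG"]] = 100
        assert fop(counts, lys_pref, code) == pytest.approx(0.5)

    def test_empty_set_undefined(self, code):
        from cubkit.optimal_codons import OptimalCodonSet

        empty = OptimalCodonSet(preferred={}, unpreferred={})
        counts = np.zeros(64, dtype=np.int64)
        counts[CODON_INDEX["AAG"]] = 30
        assert np.isnan(fop(counts, empty, code))


class TestAggregateIndices:
    def test_single_gene_pooled_equals_gene_row(self, code):
        g = CodingGene(
            "g",
            ("AAA", "AAG", "ATT", "ATC", "GGG", "GGC", "CTA", "CTG") * 30,
        )
        per_gene, summary = aggregate_indices(GeneSet("x", [g]))
        assert summary.loc["pooled", "enc"] == pytest.approx(
            per_gene.loc["g", "enc"]
        )
        assert summary.loc["pooled", "gc3s"] == pytest.approx(
            per_gene.loc["g", "gc3s"]
        )

    def test_strong_selection_lowers_mean_enc(self):
        base = dict(n_genes=120, codons_per_gene=250, seed=5)
        gs_hi, _ = simulate_gene_set(
            SimulationConfig(s_profile=((1.0, 2.0),), **base)
        )
        gs_0, _ = simulate_gene_set(
            SimulationConfig(s_profile=((1.0, 0.0),), **base)
        )
        _, sum_hi = aggregate_indices(gs_hi)
        _, sum_0 = aggregate_indices(gs_0)
        assert sum_hi.loc["mean", "enc"] < sum_0.loc["mean", "enc"]

    def test_highly_expressed_genes_have_lower_enc(self):
        gs, _ = simulate_gene_set(
            SimulationConfig(n_genes=400, codons_per_gene=250, seed=6)
        )
        high, low = expression_extremes(gs, n=100)
        _, s_high = aggregate_indices(high)
        _, s_low = aggregate_indices(low)
        assert s_high.loc["mean", "enc"] < s_low.loc["mean", "enc"]


class TestMonotonicityInS:
    def test_fop_increases_and_enc_decreases_with_s(self):
        s_grid = [0.0, 0.5, 1.0, 1.5, 2.0]
        mean_fop, mean_enc = [], []
        for i, s in enumerate(s_grid):
            gs, truth = simulate_gene_set(
                SimulationConfig(
                    n_genes=80, codons_per_gene=250,
                    s_profile=((1.0, s),), seed=40 + i,
                )
            )
            per_gene, _ = aggregate_indices(gs, truth.optimal_codon_set)
            mean_fop.append(per_gene["fop"].mean())
            mean_enc.append(per_gene["enc"].mean())
        assert spearmanr(s_grid, mean_fop).statistic > 0
        assert spearmanr(s_grid, mean_enc).statistic < 0
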