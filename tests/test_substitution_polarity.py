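import math
from collections import Counter

import numpy as np
import pytest

from cubkit import (
    AlignedCodonPair,
    SimulationConfig,
    branch_report,
    gc_shift_test,
    polarize_branch,
    simulate_branch,
)
from cubkit.optimal_codons import from_preferred_map
from cubkit.substitution_polarity import BranchSubstitutionSummary
from cubkit.synthetic_data import at_preferred_map, gc_preferred_map


@pytest.fixture(scope="module")
def lys_ocs(code):
    return from_preferred_map({"K": "AAG"}, code)


class TestPolarizeBranch:
    def test_identical_sequences_all_masked(self, lys_ocs):
        p = AlignedCodonPair("anc", "des", ("AAA", "GGG"), ("AAA", "GGG"))
        s = polarize_branch(p, lys_ocs)
        assert s.total_synonymous == 0
        assert math.isnan(s.gc_ancestral) and math.isnan(s.gc_current)

    def test_single_to_preferred_column(self, lys_ocs):
        p = AlignedCodonPair("anc", "des", ("AAA",), ("AAG",))
        s = polarize_branch(p, lys_ocs)
        assert (s.to_preferred, s.to_unpreferred) == (1, 0)
        assert s.gc_ancestral == 0.0
        assert s.gc_current == 100.0

    def test_amino_acid_change_and_multiposition_columns_excluded(
        self, lys_ocs
    ):
        p = AlignedCodonPair(
            "anc", "des",
            ("AAA", "CTA", "AAA"),
            ("AAC", "TTG", "AAG"),  # K->N change; Leu 2-position; K->K syn
        )
        s = polarize_branch(p, lys_ocs)
        assert s.total_synonymous == 1
        assert s.to_preferred == 1

    def test_conservation_on_simulated_branches(self):
        for seed in range(3):
            sim = simulate_branch(
                SimulationConfig(n_genes=10, codons_per_gene=200,
                                 branch_length=0.3, seed=600 + seed)
            )
            for p in sim.pairs:
                s = polarize_branch(p, sim.initial_ocs, run_test=False)
                assert s.to_preferred + s.to_unpreferred == s.total_synonymous

    def test_swap_symmetry_for_two_fold_families(self, code, lys_ocs):
        rng = np.random.default_rng(30)
        fam = ("AAA", "AAG")
        anc = tuple(fam[i] for i in rng.integers(0, 2, 200))
        des = tuple(fam[i] for i in rng.integers(0, 2, 200))
        p = AlignedCodonPair("anc", "des", anc, des)
        fwd = polarize_branch(p, lys_ocs, run_test=False)
        rev = polarize_branch(p.swapped(), lys_ocs, run_test=False)
        assert (fwd.to_preferred, fwd.to_unpreferred) == (
            rev.to_unpreferred, rev.to_preferred
        )
        assert fwd.gc_ancestral == rev.gc_current
        assert fwd.gc_current == rev.gc_ancestral

    def test_counts_match_simulator_event_log_exactly(self):
        sim = simulate_branch(
            SimulationConfig(n_genes=30, codons_per_gene=200,
                             s_profile=((1.0, 0.5),), branch_length=0.1,
                             seed=9)
        )
        ev = sim.events
        hits = Counter(zip(ev.gene_id, ev.codon_index))
        multi = {key for key, n in hits.items() if n > 1}
        single = ev[
            [(g, c) not in multi for g, c in zip(ev.gene_id, ev.codon_index)]
        ]
        tp_log = int(single.to_preferred.sum())
        tu_log = len(single) - tp_log
        tp = tu = 0
        for p in sim.pairs:
            keep = [i for i in range(len(p)) if (p.label_b, i) not in multi]
            sub = AlignedCodonPair(
                p.label_a, p.label_b,
                tuple(p.codons_a[i] for i in keep),
                tuple(p.codons_b[i] for i in keep),
            )
            s = polarize_branch(sub, sim.initial_ocs, run_test=False)
            tp += s.to_preferred
            tu += s.to_unpreferred
        assert (tp, tu) == (tp_log, tu_log)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            AlignedCodonPair("a", "b", ("AAA",), ("AAA", "AAG"))


class TestGcShiftTest:
    def test_observed_proportional_to_opportunity_gives_p_one(self):
        s = BranchSubstitutionSummary(
            "b", to_preferred=30, to_unpreferred=60,
            gc_ancestral=40.0, gc_current=50.0,
            opportunity_to_preferred=100, opportunity_to_unpreferred=200,
        )
        assert gc_shift_test(s) == pytest.approx(1.0)

    def test_strong_excess_is_highly_significant(self):
        # 4000 substitutions, heavily to-preferred against a balanced
        # opportunity
        s = BranchSubstitutionSummary(
            "b", to_preferred=3000, to_unpreferred=1000,
            gc_ancestral=30.0, gc_current=80.0,
            opportunity_to_preferred=5000, opportunity_to_unpreferred=5000,
        )
        assert gc_shift_test(s) < 1e-4

    def test_zero_total_is_masked(self):
        s = BranchSubstitutionSummary(
            "b", to_preferred=0, to_unpreferred=0,
            gc_ancestral=float("nan"), gc_current=float("nan"),
            opportunity_to_preferred=10, opportunity_to_unpreferred=10,
        )
        assert math.isnan(gc_shift_test(s))

    def test_fifty_fifty_mode(self):
        s = BranchSubstitutionSummary(
            "b", to_preferred=50, to_unpreferred=50,
            gc_ancestral=50.0, gc_current=50.0,
        )
        assert gc_shift_test(s, fifty_fifty=True) == pytest.approx(1.0)


class TestBranchReport:
    def test_gc_selection_raises_gc(self, code):
        # GC-ending preferred set under selection: GC3 climbs along the branch
        cfg = SimulationConfig(
            n_genes=40, codons_per_gene=300, k=1.0,
            s_profile=((1.0, 1.0),), ancestor_s=0.0,
            branch_length=0.6, seed=31,
        )
        sim = simulate_branch(cfg)
        report = branch_report(sim.pairs, ocs=sim.initial_ocs)
        pooled_anc = np.average(
            report["gc_ancestral"], weights=report["total_substitutions"]
        )
        pooled_cur = np.average(
            report["gc_current"], weights=report["total_substitutions"]
        )
        assert pooled_cur > pooled_anc

    def test_neutral_at_biased_mutation_lowers_gc(self, code):
        # start at a GC-selected equilibrium, evolve neutrally under the
        # AT-biased spectrum: GC decays
        cfg = SimulationConfig(
            n_genes=40, codons_per_gene=300, k=2.21,
            s_profile=((1.0, 0.0),), ancestor_s=1.5,
            branch_length=0.6, seed=32,
        )
        sim = simulate_branch(cfg)
        report = branch_report(sim.pairs, ocs=sim.initial_ocs)
        pooled_anc = np.average(
            report["gc_ancestral"], weights=report["total_substitutions"]
        )
        pooled_cur = np.average(
            report["gc_current"], weights=report["total_substitutions"]
        )
        assert pooled_cur < pooled_anc

    def test_empty_branch_list_gives_empty_report(self):
        report = branch_report([])
        assert len(report) == 0
        assert "to_preferred" in report.columns

    def test_report_rows_satisfy_count_conservation(self):
        sim = simulate_branch(
            SimulationConfig(n_genes=15, codons_per_gene=250,
                             branch_length=0.4, seed=33)
        )
        report = branch_report(sim.pairs, ocs=sim.initial_ocs)
        assert (
            report["to_preferred"] + report["to_unpreferred"]
            == report["total_substitutions"]
        ).all()
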