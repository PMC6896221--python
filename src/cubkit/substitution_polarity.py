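"""Polarized synonymous-substitution counting on ancestor -> descendant
branches.

Given an aligned ancestor/descendant codon pair and a species' optimal-codon
set, a codon column counts as one synonymous substitution when the two
codons differ only at the third position and encode the same amino acid.
Each counted substitution is binary-classified: "to preferred" when the
descendant codon is in the preferred set, otherwise "to unpreferred" — so
the two classes always sum to the total.  Columns with an amino-acid change
or changes at several positions are excluded (single-event parsimony;
pathway ambiguity cannot be resolved from pair data).

GC content at the third position is tallied over substituted sites only,
before (ancestral) and after (current) the substitutions, and the excess of
to-preferred over to-unpreferred changes is tested with a Pearson 2x2
chi-square against the mutational opportunity (how many ancestral codons
could move toward vs away from the preferred set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .divergence_popgen import AlignedCodonPair
from .genetic_code import GeneticCode, get_code
from .optimal_codons import OptimalCodonSet

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class BranchSubstitutionSummary:
    """Counts and GC shift for one species branch (one report row).

    ``opportunity_to_preferred`` / ``opportunity_to_unpreferred`` are the
    numbers of analysable ancestral codons that are currently unpreferred
    (can still move toward the preferred set) vs preferred (can move away);
    they normalize the chi-square test.  GC percentages are NaN when no
    substitution was counted.
    """

    branch_label: str
    to_preferred: int
    to_unpreferred: int
    gc_ancestral: float  # percent GC at substituted third positions, before
    gc_current: float  # same, after
    opportunity_to_preferred: int = 0
    opportunity_to_unpreferred: int = 0
    chi2_p: float = float("nan")

    @property
    def total_synonymous(self) -> int:
        return self.to_preferred + self.to_unpreferred


def polarize_branch(
    pair: AlignedCodonPair,
    ocs: OptimalCodonSet,
    genetic_code: int = 1,
    run_test: bool = True,
) -> BranchSubstitutionSummary:
    """Count synonymous third-position substitutions toward/away from the
    preferred set on one ancestor (``codons_a``) -> descendant (``codons_b``)
    branch."""
    code = get_code(genetic_code)
    preferred = ocs.preferred_codons()
    to_pref = to_unpref = 0
    gc_anc = gc_cur = 0
    opp_pref = opp_unpref = 0
    label = f"{pair.label_a}->{pair.label_b}"
    for anc, cur in zip(pair.codons_a, pair.codons_b):
        if not (set(anc) <= _ACGT and set(cur) <= _ACGT):
            continue
        aa_anc = code.codon_to_aa.get(anc)
        if aa_anc is None:
            continue
        # Opportunity: ancestral codons of families with a preferred codon.
        if any(c in preferred for c in code.families[aa_anc]):
            if anc in preferred:
                opp_unpref += 1
            else:
                opp_pref += 1
        if anc == cur:
            continue
        if code.codon_to_aa.get(cur) != aa_anc:
            continue
        if anc[:2] != cur[:2]:
            continue  # multi-position change (third-position rule)
        if cur in preferred:
            to_pref += 1
        else:
            to_unpref += 1
        gc_anc += anc[2] in "GC"
        gc_cur += cur[2] in "GC"
    total = to_pref + to_unpref
    summary = BranchSubstitutionSummary(
        branch_label=label,
        to_preferred=to_pref,
        to_unpreferred=to_unpref,
        gc_ancestral=100.0 * gc_anc / total if total else float("nan"),
        gc_current=100.0 * gc_cur / total if total else float("nan"),
        opportunity_to_preferred=opp_pref,
        opportunity_to_unpreferred=opp_unpref,
    )
    if run_test:
        p = gc_shift_test(summary)
        summary = BranchSubstitutionSummary(
            **{**summary.__dict__, "chi2_p": p}
        )
    return summary


def gc_shift_test(
    s: BranchSubstitutionSummary,
    ancestral_site_composition: tuple[int, int] | None = None,
    fifty_fifty: bool = False,
) -> float:
    """Pearson chi-square for excess of to-preferred over to-unpreferred
    substitutions relative to opportunity.

    The 2x2 table crosses observed substitution counts (to-preferred,
    to-unpreferred) with the mutational opportunity (ancestral codons
    currently unpreferred vs currently preferred), taken from the summary
    unless ``ancestral_site_composition`` overrides it.  With
    ``fifty_fifty`` the observed counts are instead tested against an equal
    split (goodness of fit).  Returns NaN when the test is undefined (zero
    total or a zero margin).
    """
    if s.total_synonymous == 0:
        return float("nan")
    observed = np.array([s.to_preferred, s.to_unpreferred], dtype=float)
    if fifty_fifty:
        chi2, p = stats.chisquare(observed)
        return float(p)
    if ancestral_site_composition is not None:
        opp = np.array(ancestral_site_composition, dtype=float)
    else:
        opp = np.array(
            [s.opportunity_to_preferred, s.opportunity_to_unpreferred],
            dtype=float,
        )
    table = np.stack([observed, opp])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return float("nan")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def branch_report(
    branches: list[tuple[AlignedCodonPair, OptimalCodonSet]] | list,
    ocs=None,
    genetic_code: int = 1,
) -> pd.DataFrame:
    """Report with one row per species branch.

    ``branches`` is either a list of (pair, optimal_codon_set) tuples or a
    list of pairs with a shared ``ocs``.  Columns mirror the usual published
    layout: GC3 of the preferred codons, to-preferred / to-unpreferred /
    total substitution counts, ancestral and current GC at the substituted
    sites, and the chi-square p-value.
    """
    rows = []
    for item in branches:
        if isinstance(item, tuple):
            pair, pair_ocs = item
        else:
            pair, pair_ocs = item, ocs
        if pair_ocs is None:
            raise ValueError("no optimal-codon set supplied for a branch")
        s = polarize_branch(pair, pair_ocs, genetic_code=genetic_code)
        rows.append(
            {
                "branch": s.branch_label,
                "gc3_preferred": pair_ocs.gc3_of_preferred,
                "to_preferred": s.to_preferred,
                "to_unpreferred": s.to_unpreferred,
                "total_substitutions": s.total_synonymous,
                "gc_ancestral": s.gc_ancestral,
                "gc_current": s.gc_current,
                "chi2_p": s.chi2_p,
            }
        )
    columns = [
        "branch",
        "gc3_preferred",
        "to_preferred",
        "to_unpreferred",
        "total_substitutions",
        "gc_ancestral",
        "gc_current",
        "chi2_p",
    ]
    return pd.DataFrame(rows, columns=columns)
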