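"""Population-scaled selection on codon usage under mutation-selection-drift
equilibrium.

The model (Bulmer; Sharp and colleagues) considers a preferred codon C1 and
an unpreferred synonym C2, with mutation rates u (C1 -> C2) and v (C2 -> C1)
and fitness difference s.  With population-scaled quantities S = 2*Ne*s,
U = 2*Ne*u, V = 2*Ne*v, the equilibrium frequency of the preferred codon is

    P = e^S * V / (e^S * V + U)  =  e^S / (e^S + k),     k = U/V = u/v

which inverts to S = ln[P * k / (1 - P)].  Only the ratio k ever enters the
computation.  When the mutation spectrum has not been measured, k is
inferred from weakly expressed genes, where selection on codon usage is
taken to be negligible, so P_low = 1/(1 + k), i.e. k = (1 - P_low)/P_low.

Significance of S for the highly expressed gene class is assessed by
resampling: S is recomputed on random gene sets of the same size (sharing
the low-expression k) and the observed S is compared with the upper tail of
that null distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .codon_metrics import count_codons
from .genetic_code import CODON_INDEX, GeneticCode, get_code
from .optimal_codons import OptimalCodonSet
from .sequence_io import GeneSet, expression_extremes

MEASURED = "measured"
INFERRED = "inferred-from-low-expression"


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class MutationSpectrum:
    """Mutation rates between preferred and unpreferred codons.

    ``u`` is the rate preferred -> unpreferred and ``v`` the reverse, in
    arbitrary (relative) units; only k = u/v matters downstream.  The
    directly measured diatom spectrum (P. tricornutum) has u = 2.21, v = 1.0
    (k = 2.21) when the preferred codon is GC-ending, and u = 1.0, v = 2.21
    (k = 0.45) when it is AT-ending.
    """

    u: float
    v: float
    source: str = MEASURED

    def __post_init__(self) -> None:
        if self.u <= 0 or self.v <= 0:
            raise SelectionError("mutation rates must be positive")

    @property
    def k(self) -> float:
        return self.u / self.v


@dataclass(frozen=True)
class PSummary:
    """Pooled optimal-codon frequency over an amino-acid subset."""

    per_aa: dict[str, tuple[int, int]]  # aa -> (optimal count, total count)

    @property
    def n_optimal(self) -> int:
        return sum(o for o, _ in self.per_aa.values())

    @property
    def n_total(self) -> int:
        return sum(t for _, t in self.per_aa.values())

    @property
    def pooled_p(self) -> float:
        t = self.n_total
        return self.n_optimal / t if t else float("nan")


@dataclass(frozen=True)
class SelectionEstimate:
    """S for a gene subset, with the resampling significance test."""

    P: float
    k: float
    S: float
    p_value: float
    n_genes: int
    n_codon_observations: int
    amino_acid_subset: tuple[str, ...]
    null_S: np.ndarray = field(default=None, repr=False)

    @property
    def significance(self) -> str:
        if self.p_value < 0.01:
            return "***"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def equilibrium_P(S: float, k: float) -> float:
    """Equilibrium preferred-codon frequency P = e^S / (e^S + k)."""
    if k <= 0:
        raise SelectionError("k must be positive")
    return math.exp(S) / (math.exp(S) + k)


def estimate_S(P: float, k: float) -> float:
    """S = ln[P * k / (1 - P)] — the exact inverse of :func:`equilibrium_P`."""
    if k <= 0:
        raise SelectionError("k must be positive")
    if not 0.0 < P < 1.0:
        raise SelectionError(f"P must lie strictly in (0, 1); got {P}")
    return math.log(P * k / (1.0 - P))


def default_aa_subset(
    ocs: OptimalCodonSet, code: GeneticCode | None = None
) -> tuple[str, ...]:
    """Two-fold degenerate amino acids with exactly one preferred codon —
    the subset matching the two-state model."""
    code = code or get_code(1)
    return tuple(
        aa
        for aa in code.two_fold_aas
        if len(ocs.preferred.get(aa, ())) == 1
    )


def p_summary(
    gs: GeneSet,
    ocs: OptimalCodonSet,
    aa_subset=None,
    code: GeneticCode | None = None,
) -> PSummary:
    """Pooled preferred vs total synonymous counts over ``aa_subset``."""
    code = code or get_code(1)
    subset = tuple(aa_subset) if aa_subset is not None else default_aa_subset(ocs, code)
    per_gene = _per_gene_counts(gs, ocs, subset, code)
    per_aa: dict[str, tuple[int, int]] = {}
    for i, aa in enumerate(subset):
        per_aa[aa] = (
            int(per_gene["optimal"][:, i].sum()),
            int(per_gene["total"][:, i].sum()),
        )
    return PSummary(per_aa=per_aa)


def _per_gene_counts(gs, ocs, subset, code):
    """Per-gene optimal/total count arrays over the amino-acid subset."""
    fam_idx = []
    opt_idx = []
    for aa in subset:
        fam = code.families[aa]
        fam_idx.append([CODON_INDEX[c] for c in fam])
        opt_idx.append(
            [CODON_INDEX[c] for c in fam if c in ocs.preferred.get(aa, ())]
        )
    n = len(gs)
    optimal = np.zeros((n, len(subset)), dtype=np.int64)
    total = np.zeros((n, len(subset)), dtype=np.int64)
    for gi, gene in enumerate(gs):
        counts = count_codons(gene, code)
        for ai in range(len(subset)):
            total[gi, ai] = counts[fam_idx[ai]].sum()
            optimal[gi, ai] = counts[opt_idx[ai]].sum()
    return {"optimal": optimal, "total": total}


def estimate_k_from_low_expression(
    low: GeneSet,
    ocs: OptimalCodonSet,
    aa_subset=None,
    code: GeneticCode | None = None,
) -> MutationSpectrum:
    """Infer k from weakly expressed genes via k = (1 - P)/P.

    Selection on codon usage is assumed negligible in the low-expression
    class, so its preferred-codon frequency reflects mutation alone.
    """
    code = code or get_code(1)
    ps = p_summary(low, ocs, aa_subset, code)
    P = ps.pooled_p
    if not 0.0 < P < 1.0:
        raise SelectionError(
            f"low-expression P = {P}: cannot infer k (need 0 < P < 1)"
        )
    k = (1.0 - P) / P
    return MutationSpectrum(u=k, v=1.0, source=INFERRED)


def restrict_to_stable_codons(
    ocs_list, code: GeneticCode | None = None
) -> tuple[str, ...]:
    """Amino acids whose (single) preferred codon is identical in every
    supplied species — the clade-stable subset for S estimation.

    Two-fold families are listed first.  Empty when no amino acid is stable
    across the clade (a warning is emitted).
    """
    import warnings

    code = code or get_code(1)
    if len(ocs_list) < 2:
        raise SelectionError("need optimal-codon sets from >= 2 species")
    stable: list[str] = []
    for aa in sorted(code.families):
        if len(code.families[aa]) < 2:
            continue
        prefs = [ocs.preferred.get(aa, ()) for ocs in ocs_list]
        if all(len(p) == 1 for p in prefs) and len({p[0] for p in prefs}) == 1:
            stable.append(aa)
    stable.sort(key=lambda aa: (len(code.families[aa]) != 2, aa))
    if not stable:
        warnings.warn("no amino acid has a stable preferred codon in this clade")
    return tuple(stable)


def selection_analysis(
    gs: GeneSet,
    ocs: OptimalCodonSet,
    spectrum: MutationSpectrum | None = None,
    n: int = 500,
    reps: int = 1000,
    seed: int | None = None,
    aa_subset=None,
    exclude_extremes_from_null: bool = False,
    genetic_code: int = 1,
) -> SelectionEstimate:
    """Estimate S for the ``n`` most-expressed genes and test it by resampling.

    k comes from ``spectrum`` when supplied, else from the ``n`` least
    expressed genes via k = (1 - P)/P.  The null distribution is built from
    ``reps`` random n-gene sets drawn without replacement from the full
    filtered set (extremes included unless ``exclude_extremes_from_null``),
    all sharing the same k.  The p-value is (r + 1)/(reps + 1) with r the
    number of null S values strictly greater than the observed S.
    """
    code = get_code(genetic_code)
    if len(gs) < 2 * n:
        raise SelectionError(f"need >= {2 * n} genes; have {len(gs)}")
    high, low = expression_extremes(gs, n=n)
    if spectrum is None:
        spectrum = estimate_k_from_low_expression(low, ocs, aa_subset, code)
    k = spectrum.k
    subset = tuple(aa_subset) if aa_subset is not None else default_aa_subset(ocs, code)
    if not subset:
        raise SelectionError("empty amino-acid subset: no testable families")

    # Precompute per-gene counts once over a canonical gene order so the
    # result is invariant to input order and fully determined by the seed.
    genes_sorted = sorted(gs.genes, key=lambda g: g.gene_id)
    pool = GeneSet(gs.species_label, genes_sorted)
    per_gene = _per_gene_counts(pool, ocs, subset, code)
    opt = per_gene["optimal"].sum(axis=1)
    tot = per_gene["total"].sum(axis=1)

    high_ids = {g.gene_id for g in high}
    high_mask = np.array([g.gene_id in high_ids for g in genes_sorted])
    P_obs = opt[high_mask].sum() / tot[high_mask].sum()
    S_obs = estimate_S(P_obs, k)

    if exclude_extremes_from_null:
        low_ids = {g.gene_id for g in low}
        candidates = np.array(
            [
                i
                for i, g in enumerate(genes_sorted)
                if g.gene_id not in high_ids and g.gene_id not in low_ids
            ]
        )
    else:
        candidates = np.arange(len(genes_sorted))
    if len(candidates) < n:
        raise SelectionError("too few genes left for null resampling")
    rng = np.random.default_rng(seed)
    null_S = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(candidates, size=n, replace=False)
        P_r = opt[pick].sum() / tot[pick].sum()
        null_S[r] = estimate_S(P_r, k)
    r_greater = int(np.sum(null_S > S_obs))
    p_value = (r_greater + 1) / (reps + 1)
    return SelectionEstimate(
        P=float(P_obs),
        k=float(k),
        S=float(S_obs),
        p_value=float(p_value),
        n_genes=n,
        n_codon_observations=int(tot[high_mask].sum()),
        amino_acid_subset=subset,
        null_S=null_S,
    )
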