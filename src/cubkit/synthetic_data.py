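"""Synthetic gene sets and ancestor -> descendant branches with known truth.

Two generators:

``simulate_gene_set``
    Draws codons directly from the mutation-selection-drift stationary law:
    within each synonymous family the (single) preferred codon appears with
    probability P = e^S / (e^S + k), where S is the gene's selection
    strength and k the mutation-bias ratio (preferred -> unpreferred over
    the reverse); the remaining probability is spread uniformly over the
    unpreferred synonyms.  Sampling the equilibrium directly is exact and
    fast — no forward simulation is needed for stationary data.  Expression
    values are a rank-deterministic lognormal transform of the gene's
    expression quantile plus a small noise term, so expression extremes
    recover the intended selection classes with high probability.

``simulate_branch``
    Evolves each codon site forward in continuous time along a branch,
    restricted to synonymous third-position changes within the codon's
    "box" (synonyms sharing the first two nucleotides).  The substitution
    rate from codon x to y is

        rate(x -> y) = [k if x is GC-ending and y is AT-ending else 1]
                       * [e^S if y is preferred else 1]

    i.e. an AT-biased mutation process with an e^S fixation acceptance
    toward the currently preferred codon.  This chain is reversible with
    stationary weights k^[AT-ending] * e^(S*[preferred]), which reduces to
    the same P = e^S/(e^S + k) equilibrium in every 2-codon box.  The
    ancestor is drawn from the stationary law of the initial preferred set;
    optionally the preferred set flips (GC <-> AT) at ``shift_time`` along
    the branch — the moving-target scenario.  Every substitution is
    recorded in an event log with its polarity, giving exact ground truth
    for the polarization analysis.

Branch length is expressed as expected synonymous substitutions per NG86
synonymous site (so at low density dS recovers it, and branch_length plays
the role of 2*t*mu).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .divergence_popgen import AlignedCodonPair, synonymous_site_fraction
from .genetic_code import GeneticCode, get_code, is_gc_ending
from .optimal_codons import OptimalCodonSet, from_preferred_map
from .sequence_io import CodingGene, GeneSet


def gc_preferred_map(code: GeneticCode | None = None) -> dict[str, str]:
    """One GC-ending preferred codon per degenerate family (C before G)."""
    code = code or get_code(1)
    out = {}
    for aa in code.degenerate_aas:
        fam = code.families[aa]
        for end in "CG":
            ending = [c for c in fam if c[2] == end]
            if ending:
                out[aa] = ending[0]
                break
    return out


def at_preferred_map(code: GeneticCode | None = None) -> dict[str, str]:
    """One AT-ending preferred codon per degenerate family (T before A)."""
    code = code or get_code(1)
    out = {}
    for aa in code.degenerate_aas:
        fam = code.families[aa]
        for end in "TA":
            ending = [c for c in fam if c[2] == end]
            if ending:
                out[aa] = ending[0]
                break
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for both generators.

    ``s_profile`` maps expression-rank quantiles to S as a sorted tuple of
    (upper_quantile, S) segments: a gene at quantile q gets the S of the
    first segment with q <= upper_quantile.  The default — S = 0.5 for the
    top expression quartile, S = 0 elsewhere, k = 2.21, 2000 genes of 300
    codons with a GC-ending preferred set — matches the measured diatom
    mutation spectrum and the magnitude of selection reported for highly
    expressed genes.
    """

    n_genes: int = 2000
    codons_per_gene: int = 300
    k: float = 2.21
    s_profile: tuple[tuple[float, float], ...] = ((0.75, 0.0), (1.0, 0.5))
    preferred: dict[str, str] | None = None  # aa -> codon; None = GC set
    branch_length: float = 0.5
    shift_time: float | None = None
    shift_preferred: dict[str, str] | None = None  # None = AT flip
    branch_s: float | None = None  # selection along the branch; None = max profile S
    ancestor_s: float | None = None  # shapes the ancestral equilibrium
    amino_acid_frequencies: dict[str, float] | None = None  # None = uniform
    expression_log_sd: float = 2.0
    expression_noise_sd: float = 0.01
    seed: int = 0
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.codons_per_gene <= 0:
            raise ValueError("counts must be positive")
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.branch_length < 0:
            raise ValueError("branch_length must be non-negative")
        if self.shift_time is not None and not 0 <= self.shift_time <= 1:
            raise ValueError("shift_time must lie in [0, 1]")
        qs = [q for q, _ in self.s_profile]
        if qs != sorted(qs) or not math.isclose(qs[-1], 1.0):
            raise ValueError("s_profile quantiles must be sorted and end at 1")

    def s_for_quantile(self, q: float) -> float:
        for upper, s in self.s_profile:
            if q <= upper:
                return s
        return self.s_profile[-1][1]

    @property
    def max_s(self) -> float:
        return max(s for _, s in self.s_profile)

    def preferred_map(self, code: GeneticCode) -> dict[str, str]:
        return dict(self.preferred) if self.preferred else gc_preferred_map(code)

    def shift_map(self, code: GeneticCode) -> dict[str, str]:
        if self.shift_preferred:
            return dict(self.shift_preferred)
        base = self.preferred_map(code)
        flipped = at_preferred_map(code)
        gc_frac = sum(is_gc_ending(c) for c in base.values()) / len(base)
        return flipped if gc_frac >= 0.5 else gc_preferred_map(code)


@dataclass
class GeneSetTruth:
    """Ground truth attached to a simulated gene set."""

    per_gene_s: dict[str, float]
    preferred: dict[str, str]
    k: float
    optimal_codon_set: OptimalCodonSet


def simulate_gene_set(cfg: SimulationConfig) -> tuple[GeneSet, GeneSetTruth]:
    """Equilibrium-sampled gene set with expression and truth record."""
    code = get_code(cfg.genetic_code)
    rng = np.random.default_rng(cfg.seed)
    pref = cfg.preferred_map(code)
    aas = sorted(code.families)
    if cfg.amino_acid_frequencies:
        w = np.array([cfg.amino_acid_frequencies.get(a, 0.0) for a in aas])
    else:
        w = np.ones(len(aas))
    w = w / w.sum()

    n, m = cfg.n_genes, cfg.codons_per_gene
    q = (np.arange(n) + 0.5) / n
    s = np.array([cfg.s_for_quantile(qi) for qi in q])
    p = np.exp(s) / (np.exp(s) + cfg.k)

    aa_idx = rng.choice(len(aas), size=(n, m), p=w)
    take_pref = rng.random((n, m)) < p[:, None]
    alt_draw = rng.integers(0, 1 << 30, size=(n, m))

    codon_grid = np.empty((n, m), dtype="<U3")
    for ai, aa in enumerate(aas):
        mask = aa_idx == ai
        if not mask.any():
            continue
        fam = code.families[aa]
        if len(fam) == 1:
            codon_grid[mask] = fam[0]
            continue
        if aa not in pref:
            # No preferred codon in this family: uniform usage.
            alt = np.asarray(fam, dtype="<U3")[alt_draw[mask] % len(fam)]
            codon_grid[mask] = alt
            continue
        unpref = [c for c in fam if c != pref[aa]]
        pm = mask & take_pref
        codon_grid[pm] = pref[aa]
        um = mask & ~take_pref
        alt = np.asarray(unpref, dtype="<U3")[alt_draw[um] % len(unpref)]
        codon_grid[um] = alt

    noise = rng.normal(0.0, cfg.expression_noise_sd, size=n)
    expression = np.exp(cfg.expression_log_sd * ndtri(q) + noise)

    width = len(str(n - 1))
    genes = [
        CodingGene(
            gene_id=f"g{i:0{width}d}",
            codons=tuple(codon_grid[i]),
            expression=float(expression[i]),
        )
        for i in range(n)
    ]
    gs = GeneSet(species_label=f"sim_seed{cfg.seed}", genes=genes)
    truth = GeneSetTruth(
        per_gene_s={g.gene_id: float(s[i]) for i, g in enumerate(genes)},
        preferred=pref,
        k=cfg.k,
        optimal_codon_set=from_preferred_map(pref, code),
    )
    return gs, truth


# ---------------------------------------------------------------------------
# Branch simulation


def _box_rates(
    box: tuple[str, ...], preferred: set[str], k: float, s: float
) -> dict[str, tuple[list[str], np.ndarray, float]]:
    out = {}
    for x in box:
        targets, rates = [], []
        for y in box:
            if y == x:
                continue
            m = k if (is_gc_ending(x) and not is_gc_ending(y)) else 1.0
            w = math.exp(s) if y in preferred else 1.0
            targets.append(y)
            rates.append(m * w)
        r = np.asarray(rates, dtype=float)
        out[x] = (targets, r, float(r.sum()))
    return out


def _stationary_weights(
    fam: tuple[str, ...], preferred: set[str], k: float, s: float
) -> np.ndarray:
    w = np.array(
        [
            (1.0 if is_gc_ending(c) else k)
            * (math.exp(s) if c in preferred else 1.0)
            for c in fam
        ]
    )
    return w / w.sum()


@dataclass
class BranchSimulation:
    """Aligned ancestor/descendant pairs plus the exact event log."""

    pairs: list[AlignedCodonPair]
    events: pd.DataFrame
    initial_ocs: OptimalCodonSet
    final_ocs: OptimalCodonSet
    config: SimulationConfig = field(repr=False, default=None)

    def ancestor_gene_set(self) -> GeneSet:
        return GeneSet(
            "ancestor",
            [
                CodingGene(gene_id=p.label_b, codons=p.codons_a)
                for p in self.pairs
            ],
        )

    def descendant_gene_set(self) -> GeneSet:
        return GeneSet(
            "descendant",
            [
                CodingGene(gene_id=p.label_b, codons=p.codons_b)
                for p in self.pairs
            ],
        )


def simulate_branch(cfg: SimulationConfig) -> BranchSimulation:
    """Evolve ``n_genes`` ancestral genes along one branch.

    Returns aligned (ancestor, descendant) pairs and an event log with one
    row per substitution: gene_id, codon_index, time, from_codon, to_codon
    and to_preferred (judged by the preferred set active at event time).
    """
    code = get_code(cfg.genetic_code)
    rng = np.random.default_rng(cfg.seed)
    branch_s = cfg.branch_s if cfg.branch_s is not None else cfg.max_s
    anc_s = cfg.ancestor_s if cfg.ancestor_s is not None else branch_s
    pref1_map = cfg.preferred_map(code)
    pref1 = set(pref1_map.values())
    if cfg.shift_time is not None:
        pref2_map = cfg.shift_map(code)
        pref2 = set(pref2_map.values())
    else:
        pref2_map, pref2 = pref1_map, pref1

    aas = sorted(code.families)
    if cfg.amino_acid_frequencies:
        w = np.array([cfg.amino_acid_frequencies.get(a, 0.0) for a in aas])
    else:
        w = np.ones(len(aas))
    w = w / w.sum()

    n, m = cfg.n_genes, cfg.codons_per_gene
    aa_idx = rng.choice(len(aas), size=(n, m), p=w)

    # Ancestor from the stationary law of the initial preferred set.
    ancestor = np.empty((n, m), dtype="<U3")
    for ai, aa in enumerate(aas):
        mask = aa_idx == ai
        if not mask.any():
            continue
        fam = code.families[aa]
        if len(fam) == 1:
            ancestor[mask] = fam[0]
            continue
        probs = _stationary_weights(fam, pref1, cfg.k, anc_s)
        draw = rng.choice(len(fam), size=int(mask.sum()), p=probs)
        ancestor[mask] = np.asarray(fam, dtype="<U3")[draw]

    # Rate scale: expected substitutions per NG86 synonymous site equals
    # branch_length when evaluated at the ancestral state.
    syn_sites = sum(
        synonymous_site_fraction(c, code) for c in ancestor.ravel()
    )
    rates1 = {}
    rates2 = {}
    for codon, box in code.boxes.items():
        if len(box) < 2:
            continue
        rates1.update(_box_rates(box, pref1, cfg.k, branch_s))
        rates2.update(_box_rates(box, pref2, cfg.k, branch_s))
    base_rate = sum(
        rates1[c][2] for c in ancestor.ravel() if c in rates1
    )
    scale = (
        cfg.branch_length * syn_sites / base_rate if base_rate > 0 else 0.0
    )

    t_shift = cfg.shift_time if cfg.shift_time is not None else 1.0
    phases = [(0.0, t_shift, rates1, pref1), (t_shift, 1.0, rates2, pref2)]

    descendant = ancestor.copy()
    log_rows = []
    if scale > 0:
        for gi in range(n):
            for ci in range(m):
                x = descendant[gi, ci]
                if x not in rates1:
                    continue
                t = 0.0
                for start, end, rates, pref in phases:
                    if end <= start:
                        continue
                    t = max(t, start)
                    while True:
                        targets, r, total = rates[x]
                        lam = scale * total
                        if lam <= 0:
                            t = end
                            break
                        t_next = t + rng.exponential(1.0 / lam)
                        if t_next > end:
                            t = end
                            break
                        t = t_next
                        y = targets[
                            int(rng.choice(len(targets), p=r / total))
                        ]
                        log_rows.append(
                            {
                                "gene_id": gi,
                                "codon_index": ci,
                                "time": t,
                                "from_codon": x,
                                "to_codon": y,
                                "to_preferred": y in pref,
                            }
                        )
                        x = y
                descendant[gi, ci] = x

    width = len(str(n - 1))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    pairs = [
        AlignedCodonPair(
            label_a=f"anc|{gene_ids[i]}",
            label_b=gene_ids[i],
            codons_a=tuple(ancestor[i]),
            codons_b=tuple(descendant[i]),
        )
        for i in range(n)
    ]
    events = pd.DataFrame(
        log_rows,
        columns=[
            "gene_id",
            "codon_index",
            "time",
            "from_codon",
            "to_codon",
            "to_preferred",
        ],
    )
    if len(events):
        events["gene_id"] = [gene_ids[i] for i in events["gene_id"]]
    return BranchSimulation(
        pairs=pairs,
        events=events,
        initial_ocs=from_preferred_map(pref1_map, code),
        final_ocs=from_preferred_map(pref2_map, code),
        config=cfg,
    )
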