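"""Synonymous divergence (NG86 dS), silent-site diversity and the
population-genetic calculators built on them.

dS between two aligned coding sequences follows Nei & Gojobori (1986):
each codon's synonymous site count is the expected fraction of single-
nucleotide changes that are synonymous (changes creating a stop codon count
as non-synonymous); differences between codons differing at several
positions are averaged over all mutational pathways, excluding pathways
passing through stop codons; the proportion pS = syn_diffs/syn_sites is
corrected for multiple hits with the Jukes-Cantor formula
dS = -(3/4) ln(1 - (4/3) pS).  All pathways receive equal weight — no
transition/transversion weighting.

Silent-site diversity pi is the mean over all sequence pairs of the
*uncorrected* synonymous difference proportion (intra-species distances are
small, so no saturation correction is applied).  From these, the neutral
equilibrium relations give the effective population size Ne = pi/(4 mu) and
the divergence time t = dS/(2 mu) in generations, converted to years via a
generations-per-year factor (default 100, a plausible rate for wild diatom
populations).  The default mutation rate mu = 4.77e-10 per site per
generation is the directly measured P. tricornutum rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .genetic_code import GeneticCode, get_code

#: Measured P. tricornutum per-site per-generation mutation rate.
DEFAULT_MU = 4.77e-10
DEFAULT_GENERATIONS_PER_YEAR = 100.0

_ACGT = frozenset("ACGT")


class SaturationError(ValueError):
    """pS >= 3/4: beyond the Jukes-Cantor correctable range."""


@dataclass(frozen=True)
class AlignedCodonPair:
    """Two aligned, gapless codon sequences of equal length.

    Use :meth:`from_strings` to build one from raw aligned nucleotide
    strings: codon columns containing gaps or ambiguity characters in
    either sequence are dropped pairwise before analysis.
    """

    label_a: str
    label_b: str
    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(
                f"codon sequences differ in length: {len(self.codons_a)} "
                f"vs {len(self.codons_b)}"
            )

    def __len__(self) -> int:
        return len(self.codons_a)

    @classmethod
    def from_strings(
        cls, a: str, b: str, label_a: str = "a", label_b: str = "b"
    ) -> "AlignedCodonPair":
        a = a.upper().replace("U", "T")
        b = b.upper().replace("U", "T")
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        ca, cb = [], []
        for i in range(0, len(a), 3):
            x, y = a[i : i + 3], b[i : i + 3]
            if set(x) <= _ACGT and set(y) <= _ACGT:
                ca.append(x)
                cb.append(y)
        return cls(label_a, label_b, tuple(ca), tuple(cb))

    def swapped(self) -> "AlignedCodonPair":
        return AlignedCodonPair(
            self.label_b, self.label_a, self.codons_b, self.codons_a
        )


@dataclass(frozen=True)
class DivergenceEstimate:
    ds: float
    syn_sites: float
    syn_diffs: float
    ps: float
    t_generations: float | None = None
    t_years: float | None = None


@dataclass(frozen=True)
class DiversityEstimate:
    pi_silent: float
    n_sequences: int
    ne: float | None = None


# ---------------------------------------------------------------------------
# NG86 machinery


def synonymous_site_fraction(codon: str, code: GeneticCode) -> float:
    """NG86 synonymous site count of one codon (0 to 3).

    Sum over the three positions of (synonymous single-nucleotide changes)/3.
    Changes producing a stop codon are non-synonymous; stop codons
    themselves have zero synonymous sites.
    """
    aa = code.codon_to_aa.get(codon)
    if aa is None:
        return 0.0
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if code.codon_to_aa.get(mut) == aa:
                s += 1.0 / 3.0
    return s


def pathway_differences(
    c1: str, c2: str, code: GeneticCode
) -> tuple[float, float]:
    """(synonymous, non-synonymous) difference counts between two codons,
    averaged with equal weight over all mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    does, all pathways are used (standard NG86 fallback).  Steps between a
    sense codon and a stop codon count as non-synonymous.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                through_stop = True
            if (
                code.codon_to_aa.get(cur) is not None
                and code.codon_to_aa.get(cur) == code.codon_to_aa.get(nxt)
            ):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((syn, nonsyn, through_stop))
    valid = [p for p in paths if not p[2]]
    if not valid:
        valid = paths
    syn = sum(p[0] for p in valid) / len(valid)
    nonsyn = sum(p[1] for p in valid) / len(valid)
    return syn, nonsyn


def _pair_syn_stats(
    pair: AlignedCodonPair, code: GeneticCode
) -> tuple[float, float]:
    """(synonymous sites, synonymous differences) over analysable columns.

    Columns where either codon is a stop are skipped (no sensible NG86
    site count).
    """
    sites_a = sites_b = diffs = 0.0
    used = 0
    for ca, cb in zip(pair.codons_a, pair.codons_b):
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        if ca not in code.codon_to_aa or cb not in code.codon_to_aa:
            continue
        sites_a += synonymous_site_fraction(ca, code)
        sites_b += synonymous_site_fraction(cb, code)
        diffs += pathway_differences(ca, cb, code)[0]
        used += 1
    if used == 0:
        raise ValueError("no analysable codon columns in the pair")
    return (sites_a + sites_b) / 2.0, diffs


def ng86_ds(
    pair: AlignedCodonPair,
    mu: float | None = None,
    generations_per_year: float = DEFAULT_GENERATIONS_PER_YEAR,
    genetic_code: int = 1,
) -> DivergenceEstimate:
    """NG86 synonymous divergence with Jukes-Cantor correction.

    When ``mu`` is given the divergence time is filled in via dS = 2 t mu.
    Raises :class:`SaturationError` when pS >= 3/4.
    """
    code = get_code(genetic_code)
    syn_sites, syn_diffs = _pair_syn_stats(pair, code)
    if syn_sites == 0:
        raise ValueError("zero synonymous sites: dS undefined")
    ps = syn_diffs / syn_sites
    if ps >= 0.75:
        raise SaturationError(
            f"pS = {ps:.3f} >= 0.75: synonymous sites saturated"
        )
    ds = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    t_gen = t_yr = None
    if mu is not None:
        t_gen, t_yr = time_from_ds(ds, mu, generations_per_year)
    return DivergenceEstimate(
        ds=ds,
        syn_sites=syn_sites,
        syn_diffs=syn_diffs,
        ps=ps,
        t_generations=t_gen,
        t_years=t_yr,
    )


def silent_pi(
    seqs: dict[str, str] | list[tuple[str, str]],
    mu: float | None = None,
    genetic_code: int = 1,
) -> DiversityEstimate:
    """Average pairwise synonymous-site diversity (uncorrected pS).

    ``seqs`` maps labels to aligned nucleotide strings (or a list of
    (label, seq) tuples).  Gap/ambiguity columns are dropped pairwise.  With
    ``mu`` supplied, Ne = pi/(4 mu) is filled in.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise ValueError("need >= 2 sequences for pi")
    code = get_code(genetic_code)
    ps_values = []
    for (la, sa), (lb, sb) in itertools.combinations(items, 2):
        pair = AlignedCodonPair.from_strings(sa, sb, la, lb)
        sites, diffs = _pair_syn_stats(pair, code)
        if sites == 0:
            continue
        ps_values.append(diffs / sites)
    if not ps_values:
        raise ValueError("no pair had synonymous sites")
    pi = float(np.mean(ps_values))
    ne = ne_from_pi(pi, mu) if mu is not None else None
    return DiversityEstimate(pi_silent=pi, n_sequences=len(items), ne=ne)


def ne_from_pi(pi: float, mu: float) -> float:
    """Effective population size from neutral diversity: Ne = pi/(4 mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (4.0 * mu)


def time_from_ds(
    ds: float,
    mu: float,
    generations_per_year: float = DEFAULT_GENERATIONS_PER_YEAR,
) -> tuple[float, float]:
    """(t_generations, t_years) from dS = 2 t mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if ds < 0:
        raise ValueError("ds must be non-negative")
    t_gen = ds / (2.0 * mu)
    return t_gen, t_gen / generations_per_year


def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    """Aligned codon FASTA -> {label: sequence} (order preserved)."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def pairwise_ds_matrix(
    seqs: dict[str, str],
    mu: float | None = None,
    generations_per_year: float = DEFAULT_GENERATIONS_PER_YEAR,
    genetic_code: int = 1,
):
    """Symmetric pairwise dS DataFrame over a set of aligned sequences."""
    import pandas as pd

    labels = list(seqs)
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for la, lb in itertools.combinations(labels, 2):
        pair = AlignedCodonPair.from_strings(seqs[la], seqs[lb], la, lb)
        d = ng86_ds(pair, mu=mu, generations_per_year=generations_per_year,
                    genetic_code=genetic_code).ds
        mat.loc[la, lb] = d
        mat.loc[lb, la] = d
    return mat
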