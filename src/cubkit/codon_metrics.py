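"""Per-gene and aggregate codon-usage statistics.

Implements the classical index set: codon counts, relative synonymous codon
usage (RSCU), Wright's effective number of codons (ENC, CodonW-compatible
variant), GC and GC3s content, and the frequency of optimal codons (FOP)
given an optimal-codon set.

ENC follows Wright (1990) as implemented in CodonW: for each amino acid with
n >= 2 counted codons and within-family frequencies p_i, the codon
homozygosity is F = (n * sum p_i^2 - 1) / (n - 1).  F values are averaged
within each degeneracy class and combined as

    ENC = n1 + n2/F2 + n3/F3 + n4/F4 + n6/F6

(n_k = number of amino acids with k synonyms; 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6
for the standard code), capped at 61.  A missing 3-fold class is
interpolated as (F2 + F4)/2; families with fewer than 2 counts, or F <= 0,
are treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import (
    CODON_INDEX,
    CODONS,
    GeneticCode,
    get_code,
    is_gc_ending,
)
from .sequence_io import CodingGene, GeneSet

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class UsageIndices:
    """One row of per-gene (or pooled) codon-usage indices.

    ``enc`` lies in [20, 61]; ``fop`` is NaN when no optimal set was
    supplied; ``gc3s`` and ``gc`` are fractions in [0, 1].  Undefined
    quantities (e.g. GC3s of a gene with no synonymously variable codons)
    are NaN.
    """

    gene_id: str
    enc: float
    gc3s: float
    gc: float
    fop: float = float("nan")
    n_codons: int = 0


def count_codons(
    gene: CodingGene, code: GeneticCode | None = None
) -> np.ndarray:
    """64-slot codon count vector (order: :data:`cubkit.genetic_code.CODONS`).

    The terminal stop codon and any codon containing a non-ACGT character
    are skipped; internal stops (should not survive filtering) are counted
    in the vector but ignored by every downstream index.
    """
    code = code or get_code(1)
    counts = np.zeros(64, dtype=np.int64)
    for codon in gene.coding_codons(code):
        idx = CODON_INDEX.get(codon)
        if idx is not None and set(codon) <= _ACGT:
            counts[idx] += 1
    return counts


def pooled_counts(gs: GeneSet, code: GeneticCode | None = None) -> np.ndarray:
    code = code or get_code(1)
    total = np.zeros(64, dtype=np.int64)
    for g in gs:
        total += count_codons(g, code)
    return total


def counts_matrix(gs: GeneSet, code: GeneticCode | None = None) -> pd.DataFrame:
    """genes x 64 codon count matrix as a DataFrame."""
    code = code or get_code(1)
    data = np.stack([count_codons(g, code) for g in gs])
    return pd.DataFrame(data, index=[g.gene_id for g in gs], columns=list(CODONS))


def rscu(counts: np.ndarray, code: GeneticCode | None = None) -> np.ndarray:
    """Relative synonymous codon usage per codon.

    RSCU_i = count_i / mean(count over the synonymous family).  Families
    with zero total — and stop codons — are NaN (masked), not zero.
    """
    code = code or get_code(1)
    out = np.full(64, np.nan)
    for aa, family in code.families.items():
        idx = [CODON_INDEX[c] for c in family]
        total = counts[idx].sum()
        if total > 0:
            out[idx] = counts[idx] * len(family) / total
    return out


def wright_f_hat(family_counts: np.ndarray) -> float:
    """Codon homozygosity F for one synonymous family.

    F = (n * sum p_i^2 - 1) / (n - 1) with n the family total.  NaN when
    n < 2 (not estimable from fewer than two counted codons).
    """
    n = int(np.sum(family_counts))
    if n < 2:
        return float("nan")
    p = np.asarray(family_counts, dtype=float) / n
    return (n * float(np.sum(p**2)) - 1.0) / (n - 1)


def enc(counts: np.ndarray, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons; 61 = no bias, 20 = maximal bias.

    Returns NaN when a required degeneracy class has no computable family
    (beyond the 3-fold class, which is interpolated).
    """
    code = code or get_code(1)
    f_by_class: dict[int, list[float]] = {}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        fam_counts = counts[[CODON_INDEX[c] for c in family]]
        f = wright_f_hat(fam_counts)
        if not math.isnan(f) and f > 0:
            f_by_class.setdefault(k, []).append(f)
    n_by_class = {
        k: len(aas) for k, aas in code.fold_classes.items() if k >= 2
    }
    f_mean = {k: float(np.mean(v)) for k, v in f_by_class.items()}
    # CodonW convention: a missing 3-fold class (Ile absent) is interpolated.
    if 3 in n_by_class and 3 not in f_mean:
        if 2 in f_mean and 4 in f_mean:
            f_mean[3] = (f_mean[2] + f_mean[4]) / 2.0
    value = float(len(code.fold_classes.get(1, ())))
    for k, n_k in sorted(n_by_class.items()):
        if k not in f_mean:
            return float("nan")
        value += n_k / f_mean[k]
    return min(value, 61.0)


def gc3s(counts: np.ndarray, code: GeneticCode | None = None) -> float:
    """GC fraction at third positions of synonymously variable codons.

    Codons of non-degenerate amino acids (Met, Trp) and stops are excluded
    — the "s" in GC3s.  NaN when no eligible codons were counted.
    """
    code = code or get_code(1)
    gc_n = 0
    total = 0
    for codon, aa in code.codon_to_aa.items():
        if code.degeneracy[codon] < 2:
            continue
        c = int(counts[CODON_INDEX[codon]])
        total += c
        if is_gc_ending(codon):
            gc_n += c
    return gc_n / total if total else float("nan")


def gc_content(counts: np.ndarray, code: GeneticCode | None = None) -> float:
    """Overall GC fraction of counted (sense) codons."""
    code = code or get_code(1)
    gc_n = 0
    total = 0
    for codon in code.codon_to_aa:
        c = int(counts[CODON_INDEX[codon]])
        total += 3 * c
        gc_n += c * sum(1 for b in codon if b in "GC")
    return gc_n / total if total else float("nan")


def fop(counts: np.ndarray, ocs, code: GeneticCode | None = None) -> float:
    """Frequency of optimal codons.

    Numerator: counts of codons flagged preferred.  Denominator: counts of
    all codons of amino acids that have at least one preferred codon
    (Ikemura convention — keeps FOP = 1 attainable).  NaN when the optimal
    set is empty or no eligible codons were counted.
    """
    code = code or get_code(1)
    preferred = ocs.preferred_codons()
    if not preferred:
        return float("nan")
    eligible_aas = {code.codon_to_aa[c] for c in preferred}
    num = 0
    den = 0
    for codon, aa in code.codon_to_aa.items():
        if aa not in eligible_aas:
            continue
        c = int(counts[CODON_INDEX[codon]])
        den += c
        if codon in preferred:
            num += c
    return num / den if den else float("nan")


def indices_for_counts(
    gene_id: str,
    counts: np.ndarray,
    ocs=None,
    code: GeneticCode | None = None,
) -> UsageIndices:
    code = code or get_code(1)
    return UsageIndices(
        gene_id=gene_id,
        enc=enc(counts, code),
        gc3s=gc3s(counts, code),
        gc=gc_content(counts, code),
        fop=fop(counts, ocs, code) if ocs is not None else float("nan"),
        n_codons=int(counts[[CODON_INDEX[c] for c in code.codon_to_aa]].sum()),
    )


def aggregate_indices(
    gs: GeneSet, ocs=None, code: GeneticCode | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene indices plus species-level summary.

    Returns ``(per_gene, summary)``.  ``per_gene`` has one row per gene
    (enc, fop, gc3s, gc, n_codons, expression).  ``summary`` has a
    ``pooled`` row (indices on summed counts over all genes — the "total
    transcriptome" view) and a ``mean`` row (per-gene means); both are
    reported because either convention is used for transcriptome-wide
    tables.
    """
    code = code or get_code(1)
    rows = []
    pooled = np.zeros(64, dtype=np.int64)
    for g in gs:
        counts = count_codons(g, code)
        pooled += counts
        u = indices_for_counts(g.gene_id, counts, ocs, code)
        rows.append(
            {
                "gene_id": u.gene_id,
                "enc": u.enc,
                "fop": u.fop,
                "gc3s": u.gc3s,
                "gc": u.gc,
                "n_codons": u.n_codons,
                "expression": g.expression,
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene_id")
    pooled_u = indices_for_counts("pooled", pooled, ocs, code)
    summary = pd.DataFrame(
        [
            {
                "row": "pooled",
                "enc": pooled_u.enc,
                "fop": pooled_u.fop,
                "gc3s": pooled_u.gc3s,
                "gc": pooled_u.gc,
                "n_codons": pooled_u.n_codons,
            },
            {
                "row": "mean",
                "enc": per_gene["enc"].mean(),
                "fop": per_gene["fop"].mean(),
                "gc3s": per_gene["gc3s"].mean(),
                "gc": per_gene["gc"].mean(),
                "n_codons": per_gene["n_codons"].mean(),
            },
        ]
    ).set_index("row")
    return per_gene, summary
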