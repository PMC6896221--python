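"""Data-driven identification of preferred (optimal) codons.

The procedure mirrors the classical CodonW workflow: run a correspondence
analysis (CA) of the gene x codon usage matrix (RSCU by default), rank genes
along axis 1 (which tracks bias strength), take the top and bottom few
percent of genes as the high- and low-bias groups, and for every codon test
a 2x2 contingency table {high-bias, low-bias} x {this codon, other synonyms}
with a Pearson chi-square test.  Codons significantly enriched in the
high-bias group are flagged preferred; significantly depleted ones
unpreferred.

The GC3 content of the preferred set is classified into the three empirical
bands seen across diatom strains — AT-rich, moderate-GC and GC-rich — using
band edges at 0.40 and 0.75 (midpoints of the observed gaps, 29-46% and
72-79%).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .codon_metrics import counts_matrix, enc, rscu
from .genetic_code import CODON_INDEX, CODONS, GeneticCode, get_code, is_gc_ending
from .sequence_io import GeneSet

AT_RICH = "AT-rich"
MODERATE_GC = "moderate-GC"
GC_RICH = "GC-rich"

#: Band edges on GC3-of-preferred separating AT-rich / moderate-GC / GC-rich.
GC_CLASS_EDGES = (0.40, 0.75)


class DegenerateMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class CAResult:
    """Correspondence-analysis ordination of genes in codon-usage space."""

    gene_ids: tuple[str, ...]
    codon_ids: tuple[str, ...]
    row_coordinates: np.ndarray  # genes x axes, principal coordinates
    inertias: np.ndarray  # descending, one per axis
    axis1_flipped: bool = False

    @property
    def axis1(self) -> np.ndarray:
        if self.row_coordinates.shape[1] == 0:
            return np.zeros(len(self.gene_ids))
        return self.row_coordinates[:, 0]


@dataclass(frozen=True)
class OptimalCodonSet:
    """Preferred / unpreferred codon flags per amino acid.

    Only synonymously variable amino acids appear; a codon is never in both
    lists.  ``skipped`` records codons that could not be tested (family
    absent from an extreme group).
    """

    preferred: dict[str, tuple[str, ...]]
    unpreferred: dict[str, tuple[str, ...]]
    alpha: float = 0.01
    extremes_fraction: float = 0.05
    p_values: dict[str, float] = field(default_factory=dict)
    skipped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for aa in self.preferred:
            overlap = set(self.preferred[aa]) & set(self.unpreferred.get(aa, ()))
            if overlap:
                raise ValueError(f"codons both preferred and unpreferred: {overlap}")

    def preferred_codons(self) -> frozenset[str]:
        return frozenset(c for cods in self.preferred.values() for c in cods)

    def unpreferred_codons(self) -> frozenset[str]:
        return frozenset(c for cods in self.unpreferred.values() for c in cods)

    def is_preferred(self, codon: str) -> bool:
        return codon in self.preferred_codons()

    @property
    def gc3_of_preferred(self) -> float:
        cods = self.preferred_codons()
        if not cods:
            return float("nan")
        return sum(is_gc_ending(c) for c in cods) / len(cods)

    @property
    def gc_class(self) -> str | None:
        return classify_preferred_gc(self)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "preferred": {aa: list(c) for aa, c in sorted(self.preferred.items())},
            "unpreferred": {aa: list(c) for aa, c in sorted(self.unpreferred.items())},
            "alpha": self.alpha,
            "extremes_fraction": self.extremes_fraction,
            "gc3_of_preferred": None
            if np.isnan(self.gc3_of_preferred)
            else self.gc3_of_preferred,
            "gc_class": self.gc_class,
            "skipped": list(self.skipped),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "OptimalCodonSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            preferred={aa: tuple(c) for aa, c in d["preferred"].items()},
            unpreferred={aa: tuple(c) for aa, c in d["unpreferred"].items()},
            alpha=d.get("alpha", 0.01),
            extremes_fraction=d.get("extremes_fraction", 0.05),
            skipped=tuple(d.get("skipped", ())),
        )

    def to_flag_table(self, code: GeneticCode | None = None) -> str:
        """CodonW-style 64-entry flag table: codon<TAB>flag per line,
        flag in {preferred, unpreferred, no_signal, nondegenerate, stop}."""
        code = code or get_code(1)
        pref = self.preferred_codons()
        unpref = self.unpreferred_codons()
        lines = []
        for codon in CODONS:
            if codon in code.stop_codons:
                flag = "stop"
            elif code.degeneracy.get(codon, 1) < 2:
                flag = "nondegenerate"
            elif codon in pref:
                flag = "preferred"
            elif codon in unpref:
                flag = "unpreferred"
            else:
                flag = "no_signal"
            lines.append(f"{codon}\t{flag}")
        return "\n".join(lines) + "\n"


def from_preferred_map(
    preferred: dict[str, str | tuple[str, ...]],
    code: GeneticCode | None = None,
) -> OptimalCodonSet:
    """Build an OptimalCodonSet from an amino-acid -> preferred-codon map,
    flagging every other synonym unpreferred (handy for simulations)."""
    code = code or get_code(1)
    pref: dict[str, tuple[str, ...]] = {}
    unpref: dict[str, tuple[str, ...]] = {}
    for aa, cods in preferred.items():
        chosen = (cods,) if isinstance(cods, str) else tuple(cods)
        pref[aa] = chosen
        unpref[aa] = tuple(c for c in code.families[aa] if c not in chosen)
    return OptimalCodonSet(preferred=pref, unpreferred=unpref)


def classify_preferred_gc(ocs: OptimalCodonSet) -> str | None:
    """AT-rich (< 0.40), moderate-GC (0.40-0.75) or GC-rich (> 0.75) by the
    GC3 fraction of the preferred set; None when the set is empty."""
    g = ocs.gc3_of_preferred
    if np.isnan(g):
        return None
    lo, hi = GC_CLASS_EDGES
    if g < lo:
        return AT_RICH
    if g <= hi:
        return MODERATE_GC
    return GC_RICH


def correspondence_analysis(
    matrix: np.ndarray,
    gene_ids=None,
    codon_ids=None,
    gene_enc: np.ndarray | None = None,
) -> CAResult:
    """Chi-square-distance correspondence analysis of a genes x codons matrix.

    Standard row-profile decomposition: with N = X / grand_total, row masses
    r and column masses c, the standardized residual matrix
    S = D_r^{-1/2} (N - r c^T) D_c^{-1/2} is SVD'd; principal row
    coordinates are D_r^{-1/2} U Sigma and inertias the squared singular
    values.  Axis 1 is oriented so that larger coordinates mean stronger
    codon bias (negative correlation with per-gene ENC when ``gene_enc`` is
    given; otherwise the sign is fixed deterministically by the largest
    column loading).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise DegenerateMatrixError("expected a 2-D genes x codons matrix")
    n, p = X.shape
    gene_ids = tuple(gene_ids) if gene_ids is not None else tuple(
        f"g{i}" for i in range(n)
    )
    codon_ids = tuple(codon_ids) if codon_ids is not None else tuple(
        f"c{j}" for j in range(p)
    )
    if np.any(X < 0) or np.any(~np.isfinite(X)):
        raise DegenerateMatrixError("matrix must be finite and non-negative")
    col_keep = X.sum(axis=0) > 0
    X = X[:, col_keep]
    codon_ids = tuple(c for c, k in zip(codon_ids, col_keep) if k)
    if X.shape[1] < 2 or np.any(X.sum(axis=1) == 0):
        raise DegenerateMatrixError(
            "need >= 2 non-empty codon columns and no all-zero gene rows"
        )
    total = X.sum()
    N = X / total
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (sig[0] if sig.size else 0.0)
    keep = sig > tol
    U, sig, Vt = U[:, keep], sig[keep], Vt[keep]
    rows = (U * sig) / np.sqrt(r)[:, None]
    flipped = False
    if rows.shape[1] > 0:
        if gene_enc is not None:
            e = np.asarray(gene_enc, dtype=float)
            ok = np.isfinite(e) & np.isfinite(rows[:, 0])
            corr = np.corrcoef(rows[ok, 0], e[ok])[0, 1] if ok.sum() > 2 else 0.0
            if np.isfinite(corr) and corr > 0:
                flipped = True
        else:
            # Deterministic fallback: largest-|loading| column made positive.
            load = Vt[0] / np.sqrt(c)
            j = int(np.argmax(np.abs(load)))
            if load[j] < 0:
                flipped = True
        if flipped:
            rows = rows.copy()
            rows[:, 0] = -rows[:, 0]
    return CAResult(
        gene_ids=gene_ids,
        codon_ids=codon_ids,
        row_coordinates=rows,
        inertias=sig**2,
        axis1_flipped=flipped,
    )


def _rscu_matrix(counts: np.ndarray, code: GeneticCode) -> tuple[np.ndarray, list[str]]:
    """RSCU matrix restricted to degenerate sense codons; NaN (zero-total
    family) filled with 0 so CA sees a plain non-negative matrix."""
    cols = [
        c
        for c in CODONS
        if c in code.codon_to_aa and code.degeneracy[c] >= 2
    ]
    idx = [CODON_INDEX[c] for c in cols]
    R = np.stack([rscu(row, code)[idx] for row in counts])
    return np.nan_to_num(R, nan=0.0), cols


def identify_optimal_codons(
    gs: GeneSet,
    extremes_fraction: float = 0.05,
    alpha: float = 0.01,
    use_rscu: bool = True,
    bonferroni: bool = False,
    genetic_code: int = 1,
) -> OptimalCodonSet:
    """CA + per-codon 2x2 chi-square identification of preferred codons.

    Genes are ranked by CA axis 1; the top/bottom ``extremes_fraction`` form
    the high-/low-bias groups.  For each degenerate codon, a Pearson
    chi-square (no Yates correction) on {high, low} x {codon, other
    synonyms} flags it preferred (p < alpha and relatively more used in the
    high-bias group) or unpreferred (p < alpha, less used).  Cells with
    expected count < 5 raise a warning but the codon is kept.
    """
    code = get_code(genetic_code)
    if len(gs) < 40:
        raise ValueError("need >= 40 genes for meaningful extreme groups")
    cm = counts_matrix(gs, code)
    # Input-order invariance: fix a canonical gene order up front.
    cm = cm.sort_index()
    counts = cm.to_numpy()
    mat, cols = (
        _rscu_matrix(counts, code) if use_rscu else (
            counts[:, [CODON_INDEX[c] for c in CODONS
                       if c in code.codon_to_aa and code.degeneracy[c] >= 2]],
            [c for c in CODONS if c in code.codon_to_aa and code.degeneracy[c] >= 2],
        )
    )
    gene_enc = np.array([enc(row, code) for row in counts])
    try:
        ca = correspondence_analysis(
            mat, gene_ids=cm.index, codon_ids=cols, gene_enc=gene_enc
        )
        axis1 = ca.axis1
    except DegenerateMatrixError:
        raise
    if ca.inertias.size == 0 or ca.inertias[0] <= 1e-12:
        # No usage variation among genes: no signal, empty set.
        return OptimalCodonSet(
            preferred={}, unpreferred={}, alpha=alpha,
            extremes_fraction=extremes_fraction,
        )
    m = max(2, int(round(extremes_fraction * len(gs))))
    order = np.lexsort((np.array(cm.index), -axis1))
    high_idx = order[:m]
    low_idx = order[-m:]
    high = counts[high_idx].sum(axis=0)
    low = counts[low_idx].sum(axis=0)

    preferred: dict[str, list[str]] = {}
    unpreferred: dict[str, list[str]] = {}
    p_values: dict[str, float] = {}
    skipped: list[str] = []
    for aa in code.degenerate_aas:
        fam = code.families[aa]
        fam_idx = [CODON_INDEX[c] for c in fam]
        h_tot = high[fam_idx].sum()
        l_tot = low[fam_idx].sum()
        if h_tot == 0 or l_tot == 0:
            skipped.extend(fam)
            continue
        for codon in fam:
            ci = CODON_INDEX[codon]
            table = np.array(
                [
                    [high[ci], h_tot - high[ci]],
                    [low[ci], l_tot - low[ci]],
                ],
                dtype=float,
            )
            if table.sum(axis=0).min() == 0:
                # Codon unused in both groups (or family fixed): untestable.
                skipped.append(codon)
                continue
            expected = stats.contingency.expected_freq(table)
            if expected.min() < 5:
                warnings.warn(
                    f"expected count < 5 for codon {codon}; chi-square "
                    "approximation may be poor",
                    stacklevel=2,
                )
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            if bonferroni:
                p = min(1.0, p * sum(len(code.families[a]) for a in code.degenerate_aas))
            p_values[codon] = float(p)
            if p < alpha:
                rel_high = high[ci] / h_tot
                rel_low = low[ci] / l_tot
                if rel_high > rel_low:
                    preferred.setdefault(aa, []).append(codon)
                elif rel_high < rel_low:
                    unpreferred.setdefault(aa, []).append(codon)
    return OptimalCodonSet(
        preferred={aa: tuple(v) for aa, v in preferred.items()},
        unpreferred={aa: tuple(v) for aa, v in unpreferred.items()},
        alpha=alpha,
        extremes_fraction=extremes_fraction,
        p_values=p_values,
        skipped=tuple(skipped),
    )
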