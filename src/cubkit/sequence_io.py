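"""Reading, filtering and stratifying coding sequences and expression data.

The unit of analysis is a :class:`CodingGene`: one in-frame CDS held as a
list of codons, with an optional expression value (FPKM).  Gene sets are
filtered the way transcriptome codon-usage studies filter them: drop genes
whose length is not a multiple of three, genes with internal stop codons,
and genes shorter than a minimum codon count (default 200 codons, chosen to
keep per-gene index variance manageable).  Expression extremes (the 500
most- and least-expressed genes by default) drive the downstream
optimal-codon and selection analyses.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, get_code

_ACGT = frozenset("ACGT")


class SequenceIOError(ValueError):
    pass


@dataclass(frozen=True)
class CodingGene:
    """One in-frame coding sequence.

    ``codons`` is the raw codon list as parsed (upper-case, may contain
    ambiguity characters such as N; a terminal stop codon is retained here).
    Counting routines use :meth:`coding_codons`, which strips a terminal
    stop; codons containing non-ACGT characters are skipped at counting
    time rather than dropping the gene.
    """

    gene_id: str
    codons: tuple[str, ...]
    expression: float | None = None

    def coding_codons(self, code: GeneticCode) -> tuple[str, ...]:
        """Codons with a terminal stop (if any) removed."""
        if self.codons and self.codons[-1] in code.stop_codons:
            return self.codons[:-1]
        return self.codons

    def n_codons(self, code: GeneticCode) -> int:
        return len(self.coding_codons(code))

    def has_internal_stop(self, code: GeneticCode) -> bool:
        return any(c in code.stop_codons for c in self.coding_codons(code))

    def with_expression(self, value: float) -> "CodingGene":
        return replace(self, expression=float(value))


@dataclass
class GeneSet:
    """A collection of genes from one species/strain plus a filter log."""

    species_label: str
    genes: list[CodingGene]
    filter_log: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = [i for i, n in Counter(ids).items() if n > 1]
            raise SequenceIOError(f"duplicate gene ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> CodingGene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class ExpressionTable:
    """gene_id -> FPKM, optionally derived from read counts + lengths."""

    fpkm: dict[str, float]
    counts: dict[str, int] | None = None
    lengths_bp: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for g, v in self.fpkm.items():
            if v < 0 or math.isnan(v):
                raise SequenceIOError(f"negative/NaN FPKM for {g}")
        if self.lengths_bp is not None:
            bad = [g for g, L in self.lengths_bp.items() if L < 3]
            if bad:
                raise SequenceIOError(f"lengths < 3 bp: {bad[:5]}")


def read_cds_fasta(
    path: str | Path,
    species_label: str | None = None,
    genetic_code: int = 1,
) -> GeneSet:
    """Parse a CDS FASTA file into a :class:`GeneSet`.

    Records whose length is not a multiple of three are excluded and logged
    under ``filter_log["frame"]``.  Parsing is case-insensitive.  An empty
    file yields an empty set.
    """
    path = Path(path)
    genes: list[CodingGene] = []
    log: Counter = Counter()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            log["frame"] += 1
            continue
        if not seq:
            log["empty"] += 1
            continue
        codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
        genes.append(CodingGene(gene_id=record.id, codons=codons))
    label = species_label if species_label is not None else path.stem
    get_code(genetic_code)  # validate the table id early
    return GeneSet(species_label=label, genes=genes, filter_log=log)


def write_cds_fasta(gs: GeneSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq("".join(g.codons)), id=g.gene_id, description="")
        for g in gs.genes
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_genes(
    gs: GeneSet, min_codons: int = 200, genetic_code: int = 1
) -> GeneSet:
    """Apply the length and internal-stop filters.

    Keeps genes with at least ``min_codons`` codons (terminal stop not
    counted) and no internal stop codon.  Removal counts are accumulated in
    the returned set's ``filter_log`` (idempotent: filtering an already
    filtered set changes nothing).
    """
    code = get_code(genetic_code)
    kept: list[CodingGene] = []
    log = Counter(gs.filter_log)
    for g in gs.genes:
        if g.has_internal_stop(code):
            log["internal_stop"] += 1
        elif g.n_codons(code) < min_codons:
            log["short"] += 1
        else:
            kept.append(g)
    return GeneSet(species_label=gs.species_label, genes=kept, filter_log=log)


def compute_fpkm(table: ExpressionTable) -> ExpressionTable:
    """FPKM from read counts: count * 1e9 / (length_bp * library_total).

    The library total is the sum of counts over the supplied table.
    """
    if table.counts is None or table.lengths_bp is None:
        raise SequenceIOError("table holds no counts/lengths to convert")
    total = sum(table.counts.values())
    if total == 0:
        raise SequenceIOError("empty library: total mapped count is zero")
    fpkm = {
        g: table.counts[g] * 1e9 / (table.lengths_bp[g] * total)
        for g in table.counts
    }
    return ExpressionTable(
        fpkm=fpkm, counts=table.counts, lengths_bp=table.lengths_bp
    )


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with header (gene_id, count, length_bp) or (gene_id, fpkm).

    Count tables are converted to FPKM via :func:`compute_fpkm`.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "fpkm" in cols:
        return ExpressionTable(
            fpkm=dict(zip(df["gene_id"].astype(str), df["fpkm"].astype(float)))
        )
    if "count" in cols and "length_bp" in cols:
        raw = ExpressionTable(
            fpkm={},
            counts=dict(
                zip(df["gene_id"].astype(str), df["count"].astype(int))
            ),
            lengths_bp=dict(
                zip(df["gene_id"].astype(str), df["length_bp"].astype(int))
            ),
        )
        return compute_fpkm(raw)
    raise SequenceIOError(
        "expression table needs columns (gene_id, fpkm) or "
        "(gene_id, count, length_bp)"
    )


def attach_expression(gs: GeneSet, table: ExpressionTable) -> GeneSet:
    """Return a GeneSet with FPKM attached; genes absent from the table are
    dropped and logged under ``no_expression``."""
    kept = []
    log = Counter(gs.filter_log)
    for g in gs.genes:
        if g.gene_id in table.fpkm:
            kept.append(g.with_expression(table.fpkm[g.gene_id]))
        else:
            log["no_expression"] += 1
    return GeneSet(species_label=gs.species_label, genes=kept, filter_log=log)


def expression_extremes(
    gs: GeneSet, n: int = 500
) -> tuple[GeneSet, GeneSet]:
    """The ``n`` most- and ``n`` least-expressed genes, as two disjoint sets.

    Ties are broken lexicographically by gene_id so the split is
    deterministic.  Zero-FPKM genes are eligible for the low set (their
    count is recorded in the low set's filter log).
    """
    missing = [g.gene_id for g in gs.genes if g.expression is None]
    if missing:
        raise SequenceIOError(
            f"{len(missing)} genes lack expression values (e.g. {missing[0]})"
        )
    if len(gs) < 2 * n:
        raise SequenceIOError(
            f"need at least {2 * n} genes for n={n} extremes; "
            f"have {len(gs)} — lower n"
        )
    # One sort keeps the two sets disjoint even under fully tied expression.
    ranked = sorted(gs.genes, key=lambda g: (g.expression, g.gene_id))
    low = ranked[:n]
    high = list(reversed(ranked[-n:]))
    low_log = Counter({"zero_fpkm_in_low": sum(1 for g in low if g.expression == 0)})
    return (
        GeneSet(f"{gs.species_label}|high", high),
        GeneSet(f"{gs.species_label}|low", low, low_log),
    )


def write_filter_report(gs: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rule\tn_removed\n")
        for rule in sorted(gs.filter_log):
            fh.write(f"{rule}\t{gs.filter_log[rule]}\n")
        fh.write(f"kept\t{len(gs)}\n")
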