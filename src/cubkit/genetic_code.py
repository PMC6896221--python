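"""Genetic code tables and synonymous-family bookkeeping.

Everything downstream (codon counting, ENC, optimal-codon identification,
NG86 site counting, the simulators) needs the same handful of views of a
genetic code: codon -> amino acid, synonymous families, degeneracy classes,
and the third-position "box" of a codon (synonymous codons sharing the first
two nucleotides).  This module derives all of them once from an NCBI
translation table via Biopython and caches the result.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

BASES = "TCAG"
#: The 64 codons in TCAG order (the conventional codon-table layout).
CODONS: tuple[str, ...] = tuple(
    a + b + c for a in BASES for b in BASES for c in BASES
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

GC_BASES = frozenset("GC")


def is_gc_ending(codon: str) -> bool:
    """True if the third position of ``codon`` is G or C."""
    return codon[2] in GC_BASES


@dataclass(frozen=True)
class GeneticCode:
    """Derived views of one NCBI translation table.

    Attributes
    ----------
    table_id : NCBI translation-table identifier (1 = standard nuclear code,
        appropriate for diatom nuclear CDS).
    codon_to_aa : sense codon -> one-letter amino acid.
    stop_codons : the stop codons of the table.
    families : amino acid -> tuple of synonymous codons (sorted).
    degeneracy : sense codon -> size of its synonymous family.
    boxes : sense codon -> tuple of synonymous codons sharing its first two
        nucleotides (including itself); the reachable set under
        third-position synonymous change.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]]
    degeneracy: dict[str, int]
    boxes: dict[str, tuple[str, ...]]
    fold_classes: dict[int, tuple[str, ...]] = field(default_factory=dict)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if c in self.codon_to_aa)

    @property
    def degenerate_aas(self) -> tuple[str, ...]:
        """Amino acids with >= 2 synonymous codons, sorted."""
        return tuple(
            aa for aa in sorted(self.families) if len(self.families[aa]) > 1
        )

    @property
    def two_fold_aas(self) -> tuple[str, ...]:
        return tuple(
            aa for aa in sorted(self.families) if len(self.families[aa]) == 2
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, codon: str) -> str | None:
        return self.codon_to_aa.get(codon)

    def synonymous(self, a: str, b: str) -> bool:
        """True if ``a`` and ``b`` are distinct sense codons for one amino acid."""
        aa = self.codon_to_aa.get(a)
        return aa is not None and aa == self.codon_to_aa.get(b) and a != b


@functools.lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    """Build (and cache) the :class:`GeneticCode` for an NCBI table id."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    stops = frozenset(table.stop_codons)

    families: dict[str, list[str]] = {}
    for codon in CODONS:
        aa = codon_to_aa.get(codon)
        if aa is not None:
            families.setdefault(aa, []).append(codon)
    families_t = {aa: tuple(sorted(cods)) for aa, cods in families.items()}
    degeneracy = {
        codon: len(families_t[aa]) for codon, aa in codon_to_aa.items()
    }
    boxes = {}
    for codon, aa in codon_to_aa.items():
        boxes[codon] = tuple(
            c for c in families_t[aa] if c[:2] == codon[:2]
        )
    fold_classes: dict[int, list[str]] = {}
    for aa, cods in families_t.items():
        fold_classes.setdefault(len(cods), []).append(aa)
    fold_classes_t = {
        k: tuple(sorted(v)) for k, v in fold_classes.items()
    }
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stop_codons=stops,
        families=families_t,
        degeneracy=degeneracy,
        boxes=boxes,
        fold_classes=fold_classes_t,
    )


STANDARD_CODE = get_code(1)
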