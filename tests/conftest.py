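import numpy as np
import pytest

from cubkit.genetic_code import CODON_INDEX, get_code


@pytest.fixture(scope="session")
def code():
    return get_code(1)


@pytest.fixture
def uniform_counts(code):
    """Equal counts (600) for every synonymous codon of degenerate families."""
    counts = np.zeros(64, dtype=np.int64)
    for fam in code.families.values():
        if len(fam) >= 2:
            for c in fam:
                counts[CODON_INDEX[c]] = 600
    return counts


@pytest.fixture
def single_codon_counts(code):
    """One codon used (600) per amino acid, zero for all its synonyms."""
    counts = np.zeros(64, dtype=np.int64)
    for fam in code.families.values():
        counts[CODON_INDEX[fam[0]]] = 600
    return counts


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


@pytest.fixture
def fasta_writer(tmp_path):
    def _write(records, name="test.fasta"):
        return write_fasta(tmp_path / name, records)

    return _write
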