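"""Independent brute-force oracles used by the test suite.

Deliberately written with different machinery from the package (Biopython
translation, recursive pathway enumeration, elementwise eigendecomposition)
so they constitute genuinely separate computations of the same quantities.
"""

import math

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon via Biopython translation."""
    if codon in STOPS:
        return 0.0
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and _aa(mut) == _aa(codon):
                s += 1.0 / 3.0
    return s


def _paths(c1: str, c2: str):
    """All mutational pathways c1 -> c2 as (syn, nonsyn, through_stop)."""
    if c1 == c2:
        return [(0, 0, False)]
    out = []
    for pos in range(3):
        if c1[pos] != c2[pos]:
            nxt = c1[:pos] + c2[pos] + c1[pos + 1 :]
            syn_step = (
                c1 not in STOPS and nxt not in STOPS and _aa(c1) == _aa(nxt)
            )
            through = nxt in STOPS and nxt != c2
            for s, n, t in _paths(nxt, c2):
                out.append(
                    (s + (1 if syn_step else 0), n + (0 if syn_step else 1),
                     t or through)
                )
    return out


def oracle_syn_diffs(c1: str, c2: str) -> float:
    """Pathway-averaged synonymous difference count between two codons."""
    paths = _paths(c1, c2)
    valid = [p for p in paths if not p[2]] or paths
    return sum(p[0] for p in valid) / len(valid)


def oracle_ds(codons_a, codons_b) -> float:
    """Full NG86 dS with Jukes-Cantor correction, from scratch."""
    sites_a = sites_b = diffs = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if ca in STOPS or cb in STOPS:
            continue
        sites_a += oracle_syn_sites(ca)
        sites_b += oracle_syn_sites(cb)
        diffs += oracle_syn_diffs(ca, cb)
    sites = (sites_a + sites_b) / 2.0
    ps = diffs / sites
    return -0.75 * math.log(1.0 - 4.0 * ps / 3.0)


def oracle_ca_row_coordinates(X):
    """CA principal row coordinates by explicit elementwise residuals and
    eigendecomposition of S S^T (up to per-axis sign)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    total = X.sum()
    N = X / total
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    S = np.zeros_like(N)
    for i in range(n):
        for j in range(p):
            S[i, j] = (N[i, j] - r[i] * c[j]) / math.sqrt(r[i] * c[j])
    vals, vecs = np.linalg.eigh(S @ S.T)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > 1e-12
    coords = (vecs[:, keep] * np.sqrt(vals[keep])) / np.sqrt(r)[:, None]
    return coords, vals[keep]
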