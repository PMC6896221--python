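# cubkit

Codon usage bias (CUB) analysis for phytoplankton transcriptomes — built
around the question of why organisms with astronomically large populations,
such as marine diatoms, often show only modest codon bias.

Synonymous codons are not used at random: weak selection for translational
accuracy and efficiency favours one "optimal" codon per amino acid, and the
strength of the resulting bias depends on the balance between selection,
mutation bias and genetic drift. `cubkit` implements the full analysis
chain used to characterize this balance from coding-sequence data:

- **Per-gene indices** — Wright's effective number of codons (ENC, 61 = no
  bias, 20 = one codon per amino acid, CodonW-compatible), frequency of
  optimal codons (FOP), RSCU, GC and GC3s.
- **Optimal-codon identification** — correspondence analysis of the
  gene × codon usage matrix, extreme high-/low-bias gene groups, and a
  per-codon 2×2 Pearson χ² test; the preferred set's third-position GC is
  classified as AT-rich, moderate-GC or GC-rich.
- **Selection strength** — the mutation–selection–drift equilibrium model
  for a preferred codon C1 vs an unpreferred synonym C2. With *S* = 2*N*ₑ*s*
  and mutation-bias ratio *k* = *u*/*v* (C1→C2 over C2→C1), the equilibrium
  frequency of the preferred codon is

  *P* = e^*S* / (e^*S* + *k*),  inverted as  *S* = ln[*P·k* / (1 − *P*)].

  *k* is taken from a measured mutation spectrum or inferred from weakly
  expressed genes (*k* = (1 − *P*)/*P*, selection assumed negligible
  there), and the *S* of the 500 most-expressed genes is tested against a
  resampling null of 1000 random 500-gene sets.
- **Divergence and population genetics** — Nei–Gojobori (1986) synonymous
  divergence dS with Jukes–Cantor correction, silent-site diversity π, and
  the calculators *N*ₑ = π/(4μ) and *t* = dS/(2μ) with a
  generations-per-year conversion (default μ = 4.77×10⁻¹⁰, the measured
  *Phaeodactylum tricornutum* rate).
- **Substitution polarity** — on ancestor → descendant aligned pairs,
  counts of synonymous third-position substitutions toward vs away from the
  preferred set, with ancestral/current GC3 at substituted sites and an
  opportunity-normalized χ² test.
- **Synthetic data** — an equilibrium gene-set sampler and a forward branch
  simulator (with an optional mid-branch flip of the preferred set, the
  "moving target" scenario) that give every stage known ground truth.

## Worked example

Simulate a 2000-gene species at mutation–selection–drift equilibrium
(mutation bias k = 2.21 toward AT, selection S = 0.5 on the top expression
quartile), identify its preferred codons from the data alone, and estimate
the selection strength:

```python
from cubkit import (SimulationConfig, simulate_gene_set,
                    identify_optimal_codons, selection_analysis)

cfg = SimulationConfig(n_genes=2000, codons_per_gene=300, seed=11)
genes, truth = simulate_gene_set(cfg)

ocs = identify_optimal_codons(genes)
print(ocs.gc3_of_preferred, ocs.gc_class)

est = selection_analysis(genes, ocs, n=500, reps=1000, seed=11)
print(f"P = {est.P:.4f}  k = {est.k:.3f}  S = {est.S:.3f}  "
      f"p = {est.p_value:.4g}  {est.significance}")
```

This prints:

```
1.0 GC-rich
P = 0.4273  k = 2.206  S = 0.498  p = 0.000999  ***
```

The identified preferred set is fully GC-ending (as simulated); the
inferred mutation bias (k = 2.206) and selection strength (S = 0.498)
recover the simulated k = 2.21 and S = 0.5, and the resampling test flags
the highly expressed genes as significantly more biased than random gene
sets (p < 0.01, the `***` mark). The same gene set shows the expected
expression effect — mean ENC 52.72 in the 500 most-expressed genes vs
56.54 in the 500 least-expressed — and the calculators give, e.g.,
Ne = 1.05×10⁷ for π = 0.02 and 1.57×10⁸ generations (1.57 My at 100
generations/year) for dS = 0.15.

The same stages are available from the shell via the `cub` command
(`simulate`, `metrics`, `optimal`, `selection`, `divergence`, `polarity`,
`run-species`, `run-clade`); every subcommand takes `--seed` and `--out`.

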