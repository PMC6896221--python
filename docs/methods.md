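# Methods

This note documents the models implemented in `cubkit`, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
data can and cannot show about real transcriptomes.

## Gene filtering and expression

A coding gene is a list of codons parsed from an in-frame CDS FASTA record.
Records whose length is not a multiple of three are excluded at parse time;
a terminal stop codon is kept in the raw record but never counted. The
analysis filter removes genes with an internal stop codon and genes shorter
than 200 codons (terminal stop excluded) — short genes make per-gene
indices such as ENC very noisy. Codons containing ambiguity characters
(N etc.) are skipped at counting time rather than dropping the gene:
transcriptome assemblies routinely contain Ns, and discarding those genes
would bias the length filter. Internal-stop detection uses the standard
nuclear genetic code (NCBI table 1, appropriate for diatom nuclear CDS) and
is configurable by table id.

Expression is FPKM, either supplied directly or computed from read counts
as `count × 10⁹ / (length_bp × library_total)`, with the library total
taken as the sum of counts in the supplied table. The "high" and "low"
expression classes are the n = 500 most- and least-expressed genes; ties
are broken lexicographically by gene id through a single sort, which keeps
the two sets deterministic and disjoint. Zero-FPKM genes are eligible for
the low class (their number is recorded in the low set's filter log);
whether to exclude them is a judgement call, and keeping them matches the
view that the low class should represent minimal selection on codon usage.

## Codon-usage indices

**ENC.** Wright's effective number of codons in the CodonW-compatible
variant. For each amino acid with n ≥ 2 counted codons and within-family
frequencies pᵢ, the codon homozygosity is F = (n Σpᵢ² − 1)/(n − 1). F
values are averaged within each degeneracy class and combined as
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ (the class constants are derived
from the genetic-code table, so non-standard codes work too), capped at 61.
Families with fewer than two counts, or F ≤ 0, are treated as missing; a
missing 3-fold class (isoleucine) is interpolated as (F̄₂ + F̄₄)/2; any
other missing class makes ENC undefined (NaN) rather than silently wrong.
The six-fold amino acids (Leu, Ser, Arg) are treated as single six-fold
families.

**GC3s** is the GC fraction at third positions of synonymously variable
codons only — Met, Trp and stops excluded. **RSCU** is the codon count
divided by its family mean; zero-total families are masked (NaN), not
zero. **FOP** divides the count of preferred codons by the count of all
codons belonging to amino acids that have at least one preferred codon, so
FOP = 1 is attainable. Species-level tables report both the pooled-count
("total transcriptome") row and per-gene means, since both conventions are
in circulation.

## Optimal-codon identification

Correspondence analysis is the standard chi-square-distance row-profile
decomposition (SVD of the standardized residual matrix), run by default on
the per-gene RSCU matrix with masked entries set to zero — RSCU removes
amino-acid-composition differences between genes, which would otherwise
dominate the ordination; a raw-count mode is available. Axis 1 is oriented
so that larger coordinates mean stronger bias: the sign is flipped if the
axis correlates positively with per-gene ENC (when an ENC vector is
available), otherwise a deterministic convention (largest-magnitude column
loading positive) fixes it. Zero-variation input (all genes with identical
usage) has zero inertia and yields an empty optimal set — no signal, no
preferred codons.

Genes are ranked along axis 1 and the top and bottom 5% (per tail,
configurable) form the high- and low-bias groups — the conventional
CodonW fraction. For each codon of a degenerate family the 2×2 table
{high, low} × {this codon, other synonyms} is tested by Pearson χ² without
Yates correction (determinism and parity with the classical tool chain);
expected counts below 5 trigger a warning but the codon is retained. A
codon is preferred when p < α (default 0.01, per codon, no multiple-testing
correction; a Bonferroni mode exists) and its relative usage is higher in
the high-bias group; unpreferred when lower. Families absent from either
extreme group are skipped and reported.

The preferred set's third-position GC classifies the species into the three
empirically observed bands — AT-rich (< 0.40), moderate-GC (0.40–0.75),
GC-rich (> 0.75). Observed distributions are strongly trimodal with gaps at
roughly 29–46% and 72–79%; the band edges are the midpoints of those gaps.

## Selection strength

The two-state mutation–selection–drift model: preferred codon C1,
unpreferred C2, mutation rates u (C1→C2) and v (C2→C1), fitness difference
s. With S = 2Nₑs and k = u/v, the equilibrium preferred-codon frequency is
P = e^S/(e^S + k), inverted as S = ln[Pk/(1 − P)]. Only the ratio k enters
any computation; s and Nₑ are never separated. P is pooled across amino
acids (total preferred / total synonymous counts) rather than averaged per
family — pooling is variance-minimizing and matches the classical
treatment. The default amino-acid subset is the two-fold degenerate
families with exactly one preferred codon, the case the two-state model
describes exactly.

When no measured mutation spectrum is supplied, k is inferred from the
500 least-expressed genes via k = (1 − P_low)/P_low, on the assumption that
selection on codon usage is negligible there. When selection is *not*
negligible in the low class this k is inflated toward the selected
equilibrium and S is systematically underestimated — a directional bias
the test suite demonstrates on simulated data, and the reason estimates
from measured spectra can be roughly twice the inferred-spectrum ones.

Significance: S of the high class is compared with S recomputed on 1000
random 500-gene sets (drawn without replacement from all filtered genes,
extremes included by default; an exclusion option exists), all sharing the
same k. The p-value is (r + 1)/(reps + 1) with r the number of null values
strictly greater than the observed S — the unbiased resampling convention.
Marks: `***` for p < 0.01, `*` for p < 0.05, `ns` otherwise. Because k
enters observed and null S identically (an additive ln k), the test is
insensitive to k error. Gene order never matters: genes are canonically
sorted before resampling, so the result is a function of (data, seed) only.
For cross-species clade analyses, `restrict_to_stable_codons` returns the
amino acids whose single preferred codon is identical in every species —
restricting S estimation to families whose selective target has not moved
within the clade. Reported S values are raw: negative estimates (P below
the mutational equilibrium 1/(1+k)) are meaningful signals of
disequilibrium and are not clipped.

## Divergence and diversity

dS follows Nei & Gojobori (1986) with equal-pathway weighting and no
transition/transversion weighting (the behaviour of the classical
silent-site tools): per-codon synonymous site fractions (mutations to stop
codons count as non-synonymous) averaged over the two sequences;
differences between codons differing at several positions averaged over
all mutational pathways, excluding pathways through stop codons (falling
back to all pathways if none avoids a stop); Jukes–Cantor correction
dS = −¾ ln(1 − 4pS/3), with pS ≥ ¾ raising a saturation error. Columns
containing gaps or ambiguity are dropped pairwise, not listwise, to
maximize usable sites per pair. π is the mean pairwise pS, left
uncorrected — it is an intra-species quantity where multiple hits are
negligible. The calculators are the neutral equilibrium identities
Nₑ = π/(4μ) and t = dS/(2μ); μ defaults to 4.77×10⁻¹⁰ per site per
generation (the directly measured *P. tricornutum* rate) and the
year conversion to 100 generations/year (a plausible figure for wild
diatom populations, which likely undergo at least several dozen
generations per year) — both always overridable.

## Substitution polarity

Ancestral sequences are *inputs* (reconstructed upstream by ML tools);
this module only consumes aligned ancestor/descendant pairs. A codon
column counts as one synonymous substitution when the codons differ only
at the third position and encode the same amino acid; every counted
substitution is binary-classified — descendant codon preferred → "to
preferred", anything else → "to unpreferred" — so the two columns always
sum to the total, matching the row-sum identity of published substitution
tables. Columns with amino-acid changes or multi-position changes are
excluded (single-event parsimony; pathway ambiguity is unresolvable from
pair data). GC percentages are tallied over the substituted third
positions only, before and after.

The χ² test asks whether the to-preferred/to-unpreferred split deviates
from mutational opportunity: the 2×2 table crosses the observed counts
with the numbers of analysable ancestral codons currently unpreferred
(able to move toward the preferred set) vs preferred (able to move away),
Pearson χ² without continuity correction. A simple 50:50 goodness-of-fit
mode is available. The test is masked (NaN) for zero totals or margins.

## Synthetic data

The gene-set generator samples the equilibrium law directly: the model's
stationary distribution is known in closed form, so forward simulation
would add nothing but noise and cost. Each gene receives S from a
quantile→S profile; within each synonymous family the preferred codon is
drawn with probability e^S/(e^S + k) and the remainder spread uniformly
over the unpreferred synonyms (families above two-fold use this two-state
preferred-vs-rest reduction, consistent with the two-codon model; families
without a preferred codon are uniform). Expression is
exp(σ·Φ⁻¹(q) + ε) with σ = 2 (a realistic lognormal FPKM spread) and
ε ~ N(0, 0.01) — rank-deterministic up to small noise, so the expression
extremes select the intended selection classes with high probability.

The branch simulator is a continuous-time Markov chain per codon site,
restricted to third-position synonymous moves within the codon's "box"
(synonyms sharing the first two nucleotides): rate(x→y) = [k if GC-ending →
AT-ending else 1] × [e^S if y preferred else 1]. The chain is reversible
with stationary weights k^[AT-ending]·e^(S·[preferred]), which reduces to
the same P = e^S/(e^S + k) equilibrium in every two-codon box (and to an
effective ratio 1/k when the preferred codon is AT-ending). The ancestor
is drawn from the stationary law of the initial preferred set (its own S
configurable); branch length is calibrated so that the expected number of
substitutions per NG86 synonymous site at the ancestral state equals
`branch_length`, making it directly comparable to dS (= 2tμ) at low
density. With `shift_time` set, the preferred set flips (GC ↔ AT by
default) partway along the branch — the moving-target scenario in which
codon usage chases a relocated optimum and ends less biased than either
equilibrium. Every substitution is logged with its time and polarity,
giving exact ground truth for the polarity counting (recovered exactly on
columns hit once).

Defaults are fixed at the study conditions: 2000 genes × 300 codons,
k = 2.21 (the measured diatom spectrum, AT-biased), S = 0.5 for the top
expression quartile and 0 elsewhere, a GC-ending preferred set, uniform
amino-acid composition, branch length 0.5 (a typical within-genus silent
divergence).

**The moving-target comparison is run at k = 1.** With the AT-biased
spectrum, a GC→AT flip of the preferred set is *assisted* by mutation
bias: the post-shift equilibrium is more biased than the pre-shift one and
descendant ENC can decrease, confounding the effect the comparison is
about. Symmetric mutation isolates the selection-target shift; the paired
(same-seed) effect is then large and stable (≈ +6 ENC points at S = 1,
flip at mid-branch).

**What the simulations do not emulate:** real amino-acid composition and
gene-length variation, expression measurement error, demographic change,
linked selection and recombination, between-site rate variation,
transition/transversion bias, and alignment or ancestral-reconstruction
error. Passing tests therefore demonstrate the correctness and statistical
calibration of the estimators under the model's own assumptions, not the
robustness of those assumptions on real transcriptomes.

## Numerical and testing conventions

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs and seed reproduce output
  byte for byte, and reports carry the config hash and seed.
- Undefined quantities are NaN (masked), never silently zero; impossible
  requests (P at 0 or 1, saturated pS, empty libraries) raise typed errors.
- The resampling test's type-I calibration is checked at a reduced size
  (400 genes × 200 codons, 100-gene extremes, 200 resamples, 200 null
  replicates) and parameter recovery at the full default size over 20
  seeds — sizes chosen to keep the suite fast while leaving Monte Carlo
  error well below the asserted bands. Seeded stochastic checks assert
  within 3 SE (false-alarm ≈ 0.3%).
- Implementation-vs-oracle tests back the two nontrivial numerics:
  correspondence analysis against an elementwise eigendecomposition, and
  NG86 dS against a recursive pathway-enumeration oracle built on
  Biopython translation.

## Known limitations

- The equilibrium S estimator is biased wherever the preferred set changed
  recently (the very signal the polarity module detects); the stable-codon
  restriction mitigates but cannot eliminate this.
- ENC is undefined for genes missing whole degeneracy classes (rare above
  the 200-codon filter); no small-sample ENC correction is applied.
- The branch simulator's third-position restriction means first-position
  synonymous changes (Leu, Arg) never occur, so simulated dS slightly
  underuses those sites; the site calibration absorbs the effect at the
  aggregate level.
- π and dS assume selective neutrality of synonymous sites — the analysis
  itself quantifies how weakly that holds (|S| up to ~1), which inflates
  neither by much at these magnitudes but is not corrected for.
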