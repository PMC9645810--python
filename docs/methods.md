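# Methods

This note documents the models implemented in `evoexpr`, the assumptions
behind them, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Study design being modeled

The package targets the analysis layer of a multi-line evolution
experiment: L evolved bacterial lines (default 11), each sequenced in
replicate (default 2 RNA-seq + 2 Ribo-seq libraries) and compared against
ancestor samples (default 4), over a shared complement of G transcripts
(default 4131). Differential-expression model fitting itself (DESeq2-style
shrinkage, translation-efficiency models) is out of scope: the pipeline
consumes per-(gene, line) fold-change/q-value tables and count matrices as
inputs, and the generators emit tables of the same shape.

## Expression containers and DEG calling

`CountMatrix` enforces an identical gene complement across samples; genes
missing from a line's transcriptome (deleted) are zero-padded rows. TPM is
the standard length-normalized rate scaled to 10⁶ per sample; the
normalization identity (column sums = 10⁶) is enforced by the
`AbundanceMatrix` container itself.

A gene is a DEG in line *i* iff it is measured there with q ≤ 0.01
(inclusive) and a nonzero signed log2 fold-change. Rows with status
`deleted` or `indel` carry no fold-change or q-value and can never be
DEGs; for analyses needing a dense matrix they are encoded as log2FC = −10
(configurable), a value chosen to represent severe downregulation — a
deleted gene produces no functional transcript, and the encoding lets a
deletion dominate pathway scores. Significant rows with log2FC exactly 0
join neither direction set; they are counted and logged.

Correlation profiles compare all column pairs (Pearson or Spearman),
partition pairs into evolved–evolved vs ancestor–evolved classes, and
report a two-sample KS test between the two correlation distributions.
Log-scale inputs may contain −inf from zero-TPM genes; these are treated
as missing and dropped pairwise, with the per-pair gene count reported.
When correlating TPM across lines we use log10 of the replicate-mean TPM;
using individual replicates instead is a caller-side choice, since the
function takes an arbitrary gene × column matrix.

## The parallelism null

For each gene define S_up = number of lines where it is up-significant,
S_down analogously, and x = max(S_up, S_down) — the number of lines
supporting its most-repeated direction. A gene up in some lines and down
in others therefore scores the larger of the two run counts rather than
being forced into a single direction; an alternative `unanimous` mode,
which zeroes genes with conflicting calls, is available behind a flag.

Under the null, line *i* distributes its u_i up- and d_i down-calls over
random genes, so a fixed gene is up in line *i* with probability u_i/G.
Two constructions of the null pmf of x are provided:

* `sinib_independent` (default): X_up ~ PoissonBinomial(u_1/G, …, u_L/G)
  and X_down ~ PoissonBinomial(d_1/G, …, d_L/G) treated as independent;
  P(max ≤ k) = F_up(k)·F_down(k). This mirrors the classical
  SINIB-package construction but allows a gene to be simultaneously up and
  down in one line — an approximation that is excellent when
  (u_i + d_i) ≪ G.
* `trinomial_exact`: a dynamic program over lines on the joint
  (n_up, n_down) state with per-line cell probabilities
  (u_i/G, d_i/G, 1 − u_i/G − d_i/G), which enforces within-line mutual
  exclusivity. The two constructions converge as the per-line densities
  shrink (tested at u_i = d_i = G/1000).

`sinib_pmf` computes the exact pmf of any sum of Binomial(n_i, p_i)
variables by iterated convolution of the component pmfs (O(L·ΣN) work);
it is verified against exhaustive enumeration to 10⁻¹² and a 10⁶-draw
Monte-Carlo sample.

### KS test on discrete support

The observed sample is the per-gene x restricted to x ≥ 1; the reference
is the null pmf conditioned on x ≥ 1. On support {1…L} the KS statistic is
the maximum CDF discrepancy over the support points (both CDFs step at
the same locations, so this is the exact supremum). The asymptotic
Kolmogorov p-value is markedly conservative on such coarse discrete
support — under the null it would reject far less often than α — so the
default p-value is obtained by parametric Monte Carlo: multinomial
samples of the observed size are drawn from the conditioned null pmf, the
statistic is recomputed for each (vectorized, 2000 draws by default), and
p = (1 + #{D_sim ≥ D_obs}) / (1 + n_sim). This keeps the test calibrated
(rejection ≈ α under the null, verified over 200 simulated datasets at
study scale). The classical asymptotic formula remains available via
`p_method="asymptotic"` for comparability, with its conservativeness
logged rather than corrected.

Expected gene counts per x are reported both raw (G × pmf) and rounded to
the nearest integer.

## Absolute quantification

Cell volume assumes the rod-shaped spherocylinder:
V = π(w/2)²(l − w) + (4/3)π(w/2)³, degenerating to a sphere at l = w;
l < w is rejected.

The spike-in calibration regresses log10(TPM) on log10(molecules added)
per sample by OLS. The log–log scale is chosen because spike-in inputs
span about six orders of magnitude and a linear-scale fit would be
dominated by the few largest spike-ins; zero-TPM spike-ins have no
log-scale image and are excluded (and counted) rather than pseudo-counted.
At least 3 usable spike-ins are required, and a non-positive fitted slope
is treated as a non-physical calibration.

Gene TPM inverts through molecules = 10^((log10 TPM − intercept)/slope);
TPM = 0 maps to 0 molecules and is flagged. Molecules per CFU divides by
an effective cell count = CFU × Π(sampling fractions), where each
library-preparation step's fraction lies in (0, 1] and an empty list means
the whole culture was used. Sampling fractions are free user inputs
(default: none) since step-level accounting is experiment-specific. CFU
counts are used as given, without correction for undercounting.

Absolute fold-changes are mean(evolved replicates)/mean(ancestor
samples) per gene; genes with zero ancestor mean are excluded and counted.
The replicate null is the per-gene ratio replicate1/replicate2 within a
line, in the replicate order given by the caller (documented, fixed);
under exchangeable replicates its log is symmetric about 0, so the
distribution centers at ratio 1. A two-sample KS test on |log2| of the two
distributions quantifies whether between-line changes exceed
between-replicate variation. Per-line totals (Σ over genes of
replicate-mean molecules per CFU) are related to median cell volume by
Pearson correlation and OLS slope, requiring ≥ 3 lines.

## Codon-level ribosome density

Coordinates: each CDS is padded with 25 nt on both ends; positions are
1-based on the padded transcript. Bacterial footprints are mapped by their
3′ ends, and the A-site nucleotide is 3′-end − 37 (12 nt ribosome
geometry + 25 nt padding), equivalently 3′-end − 12 in CDS coordinates.
The codon containing that nucleotide (index ⌈pos/3⌉) receives the count —
the within-codon convention is ours, since only the offset itself is
standard. Reads shorter than 24 nt and A-sites outside [1, CDS length]
are discarded and counted. Frame periodicity is the distribution of
(A-site − 1) mod 3; QC passes when the dominant frame holds ≥ 0.4 of
reads (default).

Per-gene codon counts are normalized to the gene total (each gene
contributes unit mass), and only genes with ≥ 100 reads in that sample
qualify — the filter is applied per sample/replicate. The genome-wide
density of codon type c averages normalized densities over all
*occurrences* of c across qualifying genes; a gene-weighted alternative
(mean over genes of each gene's mean at c) is available via
`average="gene"`. First/last codons are not masked. Per-codon log2
fold-changes compare mean evolved density to mean ancestor density; codon
types with zero density on either side are flagged missing.

### Stop-vs-sense mixed model

Response: per-(codon, line) log2 density fold-change. Fixed effects:
intercept β0 (mean sense-codon shift) and a stop-codon indicator β1
(additional stop shift; stops are TAA, TAG, TGA). Random effects: per-line
intercept and per-line stop slope, uncorrelated — implemented in
statsmodels MixedLM as a random intercept plus a variance component on the
stop indicator. All candidates (ordinary regression, random intercept
only, uncorrelated intercept+slope, correlated intercept+slope) are fit by
maximum likelihood rather than REML so their AICs are comparable across
random-effect structures sharing fixed effects. The uncorrelated structure
is the primary fit; if it fails or does not converge the best-AIC
converged candidate is used and the downgrade logged. Rows are sorted into
a canonical (line, codon) order before fitting so the optimizer path — and
hence the fit — is invariant to input row order; the optimizer tries
L-BFGS, then CG, then Powell. Per-line predicted stop effects are
β1 + b1_line from the random-effect BLUPs.

## Pathway perturbation

RPS(reaction) = max over the reaction's enzymes of |log2FC|, read as
"magnitude of the most-changed enzyme": a −10 deletion dominates a +2
upregulation, which is the intended behavior for deletion-driven
pathways. Enzymes absent from the fold-change vector are skipped and
logged; a reaction with no scorable enzyme is excluded from the pathway's
reaction count N rather than scored 0 (scoring 0 would dilute PPS with
missingness). PPS = √(ΣRPS²/N), the root mean square, so
min RPS ≤ PPS ≤ max RPS and PPS is monotone in every enzyme magnitude.

The permutation null shuffles gene labels of each line's fold-change
vector independently (1000 permutations by default): this preserves every
line's marginal fold-change distribution while destroying both pathway
membership and cross-line gene identity. Shuffling within lines rather
than globally was chosen because lines can differ systematically in
fold-change scale (e.g. mutators), and a global shuffle would mix those
scales into the null. Observed cross-line Spearman correlations of the
pathway-indexed PPS vectors are compared to the pooled null correlations
with a two-sample KS test. The hot inner loop (per-reaction maxima over a
permuted matrix) is vectorized over lines via a precomputed gene-position
index; the scalar RPS/PPS functions remain the reference implementation
and the two paths are tested against each other.

## Synthetic-data generators

All generators are pure functions of (config, seed) and their ground
truth is returned alongside the data.

* **Fold-change tables**: a fixed shared pool of
  round(shared_fraction × deg_per_line) genes is a DEG in every line
  (keeping its pool direction with probability `direction_concordance`);
  the remaining DEGs are line-private draws. With this mechanism the
  shared fraction of any line's DEG set equals `shared_fraction` exactly,
  and `shared_fraction = 0` makes lines fully independent (pairwise
  overlap is hypergeometric). True DEG magnitudes are Gamma(2,
  effect/2)-distributed (mean = `effect_size_log2`, default 1.0 — a
  typical DEG effect in bulk RNA-seq) with q-values drawn below 0.009;
  non-DEGs get N(0, 0.05) fold-changes and Uniform(0,1) q-values, so ~1%
  of them are sporadic false positives, as in real q-value tables.
  Deleted genes (status `deleted`, no fold-change) are drawn outside the
  shared pool.
* **Counts**: gene baselines are lognormal around `nb_mean` (default 500
  reads, matching hundreds-of-reads-per-transcript bulk libraries);
  negative-binomial sampling uses the RNA-seq convention
  var = μ + μ²·dispersion with dispersion 0.05. Evolved means scale by
  2^log2FC; deleted genes are all-zero in their line; Ribo counts share
  the RNA means but are drawn independently (no translational changes by
  default).
* **Spike-ins**: log10(observed) = intercept + slope·log10(molecules) +
  N(0, noise_sd) per spike-in per sample; the default design has 92
  spike-ins log-spaced over six decades, one mix for all samples.
* **Footprints**: the generator is the exact inverse of A-site
  assignment — the A-site codon is drawn proportional to dwell weights
  over the gene's codons, the 3′ end is placed at the codon's first
  nucleotide + 37, and off-frame jitter moves it ±1 nt with probability
  1 − frame0_fraction. Placements outside the padded transcript are
  re-placed at the un-jittered position.
* **Codon fold-change tables**: the mixed model itself, simulated forward
  with uncorrelated per-line N(0, sd²) intercept/slope deviations.
* **Pathway maps, cell geometry, CFU metadata**: structural toys with the
  documented invariants (≥ 1 reaction per pathway, ≥ 1 enzyme per
  reaction; length ≥ width per cell).

What the generators do *not* emulate: sequencing error, adapters, UMIs,
positional coverage bias, gene–gene correlation of expression changes,
batch effects, or mutational mechanisms behind sharing. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated models, not robustness to real-data artifacts
upstream of the input tables.

## Problem sizes and numerical choices

Simulation-based tests run at the emulated study scale — 11 lines, 4131
genes, ~270 DEGs/line — with 200 seeds for null calibration and 50 for
power/recovery checks; footprint round trips use 10⁵ reads; the
pathway-score brute-force comparison covers 1000 random maps. Convolution
round-off in `sinib_pmf` is renormalized (it is ≤ 10⁻¹²); pmf mass is
clipped at 0 before the Σ = 1 invariant is enforced. Degenerate inputs
(all-zero samples, constant calibration designs, constant correlation
columns, lines with zero DEGs, unscorable pathways) raise or are flagged
and logged as documented per function rather than silently propagating
NaN.

## Known limitations

* The independent-SINIB null slightly overstates P(x ≥ 1) relative to the
  exact trinomial when per-line DEG densities are large; both are exposed.
* The Monte-Carlo KS p-value has resolution 1/(n_sim + 1); raise `n_sim`
  for very small p-values.
* MixedLM variance components can sit on the boundary (zero variance) for
  small L; the AIC table then effectively compares against the simpler
  structure, and genuinely singular candidates are dropped with a logged
  downgrade.
* PPS treats all reactions equally regardless of pathway topology, and
  the permutation null ignores gene–gene correlation, so its p-values are
  anti-conservative if fold-changes are strongly co-regulated within
  operons sharing pathways.
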