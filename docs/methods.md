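# Methods

This note documents the statistical models, the parameters that matter,
the synthetic-data generator, and the numerical choices made where the
design was genuinely open.

## Differential expression

**Normalization.** `normalize_quantile` maps every sample to the common
distribution of across-sample mean order statistics, assigned back by
within-column rank (ties broken by stable sort order). This is the
quantile-normalization step of RMA-style preprocessing; probe-level
background correction and median polish are out of scope because the
package consumes gene-level matrices. Quantile normalization assumes the
bulk of the transcriptome is unchanged between samples; the synthetic
generator honors this with a dominant null template (see below).

**Moderated t.** The variance model is the standard empirical-Bayes
hierarchy: gene-wise residual variances s²_g (pooled within-group, d_g =
N − 3 df for the three-group design) are draws from a scaled
inverse-chi-square prior with hyperparameters (d₀, s₀²). The prior is
fitted by method-of-moments on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the excess of var(e) over the chi-square sampling variance ψ′(d_g/2)
estimates ψ′(d₀/2), inverted by Newton iteration; the mean of e gives
s₀². When the observed spread does not exceed the sampling spread, d₀ =
+∞ and every gene uses s₀² (the fully shared-variance limit); at d₀ = 0
the statistic reduces to the ordinary pooled-variance t. Residual
variances are floored at 1e-8 before taking logs. p-values are two-sided
from a t distribution on d₀ + d_g df (normal when d₀ = ∞). The chain is
verified in the test suite against the limma reference implementation on
identical input (agreement to ~1e-14 in d₀, s₀², t and p).

**Selection.** The differentially expressed universe is the union of the
three pairwise contrasts at BH-adjusted p < α (default 0.05). Whether the
motivating analyses used raw or adjusted p at this step is ambiguous, so
a raw-p mode (`de_use_adjusted: false`) and a moderated-F alternative
(`expression.moderated_f`) are exposed; neither is asserted as ground
truth.

## Reversal clusters

Group-mean triples over (control, MCAO, MCAO_NRG1) are standardized per
gene to mean 0, population sd 1 — clustering is shape-based; constant
rows cannot be standardized and are excluded with a warning. k-means
(k = 10 by default, "user defined" in the motivating analyses) uses
Lloyd's algorithm with k-means++ seeding and 25 restarts behind a fixed
seed, via scikit-learn; the returned objective is the best over restarts
and the assignment is bitwise reproducible given the seed.

A centroid (c, m, n) is classified from two parameters: δ (minimum
injury shift |m − c|, default 0.5 on the standardized scale) and ρ
(minimum recovery fraction r = (n − m)/(c − m), default 0.5, i.e. the
treatment must undo at least half the injury shift). r is a ratio of
differences and therefore invariant to shifting or rescaling the whole
triple; values above 1 (overshoot past baseline) still count as
recovery. Reversal clusters must have size strictly greater than
`min_cluster_size` (default 10) — a 10-gene reversal cluster is excluded,
mirroring the exclusion of the 10-gene cluster in the motivating study —
and are processed in order of decreasing |injury shift|.

## Conserved-promoter TFBS scanning

**Conservation model.** Conservation between a 3 kb reference promoter
and its ortholog is modelled as ungapped local alignment under +5/−4
match/mismatch scores. Significance uses Karlin–Altschul statistics,
E = K·m·n·e^(−λS): λ is the unique positive root of
Σ p_i p_j e^(λ·s_ij) = 1, solved by Brent bracketing to |residual| <
1e-10 (for uniform bases with ±1 scores the root is ln 3, a closed-form
test anchor); K is a configured constant, default 0.173, the standard
ungapped value for +5/−4 nucleotide scoring. The default acceptance
threshold is E < 0.001.

Maximal segments are located by exact-word seeding (default word size 9)
followed by ungapped X-drop extension (default drop-off 50) and trimming
to the maximal-scoring sub-segment, with greedy non-overlapping selection
on the reference by score. This finds the same segments as a full
dynamic program whenever a segment contains one exact 9-mer — which a
segment strong enough to reach E < 0.001 (score ≥ ~110, i.e. ≥ 73%
identity over ≥ 30 bp) essentially always does — at a small fraction of
the O(mn) cost. The null calibration (100 independent random 3 kb pairs)
shows a false-positive region rate of 0 at the default threshold.

**MATCH scoring.** A TRANSFAC count matrix is converted to frequencies
f(i,b); each position carries information I(i) = Σ_b f·ln(4f) ∈ [0, ln 4]
(0·ln 0 := 0). A window b₁…b_L scores

    Current = Σ_i I(i)·f(i, b_i),
    MSS = (Current − Min) / (Max − Min),

with Max and Min the information-weighted per-position maxima and
minima, so the consensus scores exactly 1 and the anti-consensus 0. The
core similarity CSS is the same quantity over the matrix's core — the 5
consecutive positions with the largest total information, leftmost on
ties (whole matrix if shorter than 5). Windows on both strands that lie
fully inside a conserved region and reach MSS ≥ 0.85 and CSS ≥ 0.95 are
hits; minus-strand hits are reported by their reference-strand start
(0-based half-open coordinates, position 0 = most upstream base).
Overlapping hits of one matrix all count — site totals require it — and
windows containing N are skipped. Whether scanning should cover the
whole promoter rather than only conserved segments is not settled in the
motivating description; region-restricted is the default and
`restrict_to_conserved: false` scans everything. A matrix whose
positions carry no information at all (Max = Min) cannot discriminate
and scores 0.

**Gene attrition.** Cluster genes partition into `no_ortholog` (no
ortholog in the table), `no_tfbs` (ortholog but zero hits over all
matrices) and `analysis_ready`; only the last group enters the count
table, with explicit zeros.

## Over-representation

Seventeen control gene sets are drawn uniformly without replacement from
the ortholog-bearing DE universe excluding the cluster, size-matched to
the analysis-ready cluster gene count. The provenance of the original
tool's 17 fixed control sets is not described in the motivating study;
size-matching from the same DE universe preserves the exchangeability
logic of the statistic and is this package's documented choice (the
count of 17 and p ≤ 0.05 are kept as stated).

For each matrix, the cluster's per-gene counts are tested against each
control set with a one-sided Mann–Whitney U (alternative: cluster counts
stochastically greater), U counting strict wins plus half-ties. With
pooled n ≤ 12 the p-value is exact by enumeration of all labelings
(valid under ties — count data are tie-heavy); otherwise a normal
approximation with tie-corrected variance and 0.5 continuity correction
is used, accurate to within 0.02 of exact enumeration for tie-free
samples at n = 4–6 and increasingly accurate as n grows. A matrix is
flagged only when p ≤ α against **all** sets — a conjunction over 17
tests, which is conservative by construction (the synthetic null shows a
per-matrix false-flag rate of 0 across 20 studies). Summary rows report
total sites, genes with ≥ 1 site, and the percentage rounded half-up to
an integer (35/39 → 90, 15/39 → 38).

## Synthetic-data generator

The generator emulates the three-group stroke design: 4 sham controls, 3
MCAO, 3 MCAO+NRG1 arrays; log2 intensities are template group-means plus
i.i.d. N(0, noise_sd²) noise, noise_sd = 0.25 log2 units (the motivating
data's within-group variance is unpublished; 0.25 is a realistic
microarray replicate sd and is a free parameter).

**Templates.** Standardized 3-profiles lie on a circle (mean 0, sd 1
leaves one degree of freedom), so the ten differentially expressed
templates are chosen as a wheel of angles spread around that circle —
the geometry that maximizes k-means separability at fixed noise. Exactly
one angle lies in the reversal-down zone (injury shift ≥ δ with recovery
≥ ρ; the chosen angle gives r = 0.90) and its mirror in the reversal-up
zone; the others realize sustained, treatment-dominant and
partial-recovery (r = 0.33) shapes. An eleventh null template (all
zeros) holds 79% of genes so that normalization sees a mostly unchanged
transcriptome. Default weights put 3% of genes on the down-reversal and
1.2% on the up-reversal template: at the default 3000 genes the reversal
clusters land near the 92- and 30-gene scale of the motivating study and
the DE universe near 600 genes.

**Promoters.** 3000 bp, i.i.d. bases at GC 0.5. Conserved blocks
(default 400/250/150 bp) are placed uniformly without overlap at
identical coordinates in reference and ortholog (no indel evolution);
inside blocks the ortholog differs by i.i.d. substitutions at rate 0.02,
outside the sequences are independent. 15% of genes have no ortholog.
Planted sites are exact consensus occurrences (random strand), Poisson
counts at 3 sites/promoter for the enriched matrix in target-template
genes versus 0.3 elsewhere, placed fully inside conserved blocks without
mutual overlap (rejection sampling) and written identically into both
sequences, so every planted site re-scores at MSS = CSS = 1. All
quantities are recorded in a truth table; `simulate_study` writes the
complete file bundle and everything round-trips through the package
parsers.

**What the generator does not emulate** — probe-level effects, indels,
correlated noise across genes, GC- or position-biased promoter
composition, motif self-similarity within real TFBS families, and real
TRANSFAC matrices (the bundled matrices are synthetic, sharply peaked at
a random consensus). Passing the planted-truth tests therefore
demonstrates that the chain's logic and statistics are correct under the
stated model, not that the thresholds are optimal for any particular
real dataset.

## Problem sizes and determinism

The default study is 3000 genes × 10 samples with 3 kb promoters; the
test suite uses a scaled study (1200 genes, 1.5 kb promoters, blocks
scaled proportionally) that preserves every structural feature, and the
20-study recovery benchmark runs at that scale. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); reruns with
identical configuration produce bitwise-identical reports, and the run
manifest records the configuration digest and seeds.

## Known limitations

- The conservation seed-and-extend search can in principle miss a
  significant segment with no exact 9-mer (< ~73% identity); such
  segments are also at the edge of detectability for the E-value model.
- K is configured, not estimated from the score distribution; since E
  depends on K only linearly and on S exponentially, threshold behavior
  is dominated by λ and S.
- Control sets are resampled per run from the study's own DE universe;
  results are conditional on that universe, unlike the original tool's
  fixed external control sets.
- The qPCR helper (`expression.delta_ct`) implements ΔCt =
  Ct(target) − Ct(reference) only; it is a convenience for validation
  workflows, not a calibrated quantification model.
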