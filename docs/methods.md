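# Methods

## Problem setting

We infer directed TF→target edges for a small set of master regulators
from (i) one expression profile per gene over an ordered developmental
series (k timepoints; the motivating system is embryo maturation sampled
at 7, 8, 10, 12, 13, 15 and 17 days after pollination, three replicates)
and (ii) regulons of experimentally confirmed targets that serve as
positive training examples.  Negative examples are unknown in principle;
we sample them uniformly from expressed genes outside the regulon, the
standard positive–unlabelled compromise, at a 1:1 ratio with the
positives.

## Differential expression

Counts are converted to log2-CPM, `log2((c + 0.5)/(N + 1)·1e6)`, and each
observation receives a precision weight from a lowess-smoothed (span 0.5)
trend of the quarter-root residual variance against mean log2-CPM,
evaluated at the observation's fitted (group-mean) value and inverted to
the fourth power.  For each consecutive timepoint pair we compute weighted
group means, a pooled weighted residual variance s² on d = n₁+n₂−2 df,
and moderate it with an inverse-chi-square prior: s̃² = (d₀s₀² + ds²)/(d₀+d).
The hyperparameters (d₀, s₀²) are fitted per contrast by the method of
moments on log s² (the mean and variance of log s² under the scaled-F
model identify both, via digamma/trigamma terms; the trigamma inverse is
solved by Newton iteration).  The moderated t = Δmean / (s̃·SE factor) is
referred to a t distribution on d₀+d df, two-sided.  p-values are
Benjamini–Hochberg adjusted **per contrast** (a pooled option exists), and
a gene is declared DE when any consecutive contrast has adjusted p < 0.05.
Setting `prior_df=0` recovers the ordinary two-sample t exactly, which is
the identity our tests pin.  Genes with all-zero counts are removed before
modelling (their variance is undefined) and reported.

This is a desk-scale implementation of the voom/eBayes idea, not a
bit-exact port of any existing package; its own contracts (formula values,
null calibration, monotone shrinkage) are what the test suite asserts.

## Supervised models

Pair features: *global* concatenates the regulator and target profiles
(length 2k); *local* uses the target's consecutive log2 fold changes
(length k−1) with pseudocount ε = 1 FPKM guarding zeros (configurable).
The classifier is a soft-margin SVM, C = 1000 (a high misclassification
cost, appropriate for small curated positive sets), with linear or RBF
kernels; the RBF width defaults to γ = 1/n_features.  The quadratic
program is delegated to scikit-learn's SVC; the model surface we rely on —
box constraints 0 ≤ α_i ≤ C, Σα_i y_i = 0, and scoring by the dual
expansion f(x) = Σ y_i α_i k(x_i, x) + b — is verified against an
explicit kernel-expansion evaluation.  Decision ties (f = 0) classify
negative (conservative prediction).

Evaluation uses three-fold cross-validation: DE positives and the sampled
negatives are partitioned into three seeded folds (sizes differing by at
most one); each training set is two folds of each class **plus all
non-DE ("stable") positives**, which never appear in a test fold.  AUC is
computed from the ROC curve by trapezoid; with ties this equals the
Mann–Whitney probability with 0.5 credit, and the equality is enforced
against an independent pairwise-comparison oracle.  The negative set is
drawn once before splitting (a single seeded draw), not re-drawn per fold.

For the global model the per-regulator training sets are pooled into one
problem per fold; evaluation remains per regulator so the comparison table
has one row per (method, kernel, regulator, fold).

## CLR baseline

Profiles are discretised into equal-width bins over each gene's range;
mutual information is the plug-in estimate in nats.  The bin count
defaults to ⌈√n⌉ for n samples: a plug-in MI estimate with nearly as many
bins as samples saturates (every joint cell is unique and MI → log n for
all pairs), which destroys the contrast between coupled and independent
pairs that CLR's background z-scores depend on.  At n = 100 conditions the
rule reproduces the conventional 10-bin default; at n = 7 it gives 3.  An
explicit `n_bins` overrides the rule.  Row backgrounds (mean and sample
sd, excluding the diagonal self-MI) yield z_ij = max(0, (M_ij − μ_i)/σ_i);
rows with zero background sd contribute z = 0; w_ij = √(z_ij² + z_ji²).
Edges from declared regulators are ranked by decreasing w with
lexicographic tie-breaks.  A brute-force recomputation from the
definitions serves as the oracle on small instances (agreement 1e-12).

## Post-processing

Pearson correlation between each (known ∪ predicted) target and its
regulator is computed on replicate-averaged profiles (no log transform by
default); zero-variance profiles are flagged undefined and excluded.  The
"strongly positively correlated" rule keeps r ≥ 0.6 (boundary inclusive);
the anti-correlation report uses r ≤ −0.6.  K-means is Lloyd's algorithm
with seeded random-sample initialisation, best of 20 restarts by
within-cluster sum of squares; an empty cluster arising mid-iteration is
re-seeded with the point farthest from its centre so the returned solution
always has k nonempty clusters.  k is user-supplied per regulator (a
typical choice is 3–4); returned cluster ids are renumbered so cluster 1
peaks earliest in the series.  On 1-D instances with ≤ 8 points the
solver provably attains the enumerated global optimum with ≥ 20 restarts,
which is the oracle test.

## Motif analysis

Promoters are the strand-oriented upstream regions of length ≤ 3000 bp,
truncated at the nearest annotated gene boundary on either strand and at
chromosome ends; genes with an empty region are reported unscanned.
Coordinates are 1-based inclusive on input (GFF3), 0-based half-open
internally, and hit starts are 1-based within the promoter.  PWMs are read
from MEME-minimal files with strict validation (probability rows must sum
to 1 within 1e-6); the background defaults to uniform 0.25 unless the file
declares one.  Log2-odds use a pseudocount of 0.01·bg per cell.  Scores
live on a 1/1000 integer grid; the exact null distribution of the window
score under the background model is built once by dynamic programming over
positions, so every reported p-value P(score ≥ s) is exact for the grid
the scanner produces (verified against full 4^L enumeration for L ≤ 6).
Both strands are scanned (the reverse strand via the window's reverse
complement); windows containing N are skipped.  A target is **direct**
when at least one hit has p < 10⁻⁴ (strict), **indirect** when scanned
without such a hit, **unscanned** without a promoter or motif — the three
statuses partition the targets.  No multiple-testing correction is applied
to hits; the threshold is a raw per-window p-value.  Direct targets that
are TFs with a known motif become *secondary TFs* and are scanned against
the primary regulator's indirect targets, one cascade level deep;
secondary TFs without a motif are listed but not scanned.

## Synthetic data

The generator emulates the *shape* of the motivating data, not its
values: regulator profiles are cubic-smoothed random curves over k = 7
points scaled into a 1–10 FPKM-like range; each of the 100 true targets is
`coupling × regulator + N(0, (0.25·signal sd)²)` clipped at zero (a
configurable fraction couples negatively, mirrored about the profile
midline); the other 399 genes are independent smooth curves.  Counts are
negative-binomial with variance μ + φμ² (φ = 0.1; φ → 0 recovers Poisson),
mean proportional to expression at 50 counts per FPKM unit, three
replicates per timepoint.  For DE power studies a separate generator
plants mean shifts of a stated size (in per-observation log2 sd units) at
one random consecutive boundary in a subset of genes.  Promoters are
i.i.d. uniform ACGT with the motif consensus (optionally mutated
per-position) planted at a random offset in a configurable fraction of
targets, laid out head-to-tail on one forward-strand chromosome so the
upstream-extraction rule recovers each promoter exactly.  Everything is
bit-reproducible from (config, seed).

What passing these conditions does *not* show: real regulons are noisy and
incomplete, real coupling is non-linear and lagged, real promoters have
composition bias and repeats, and real negative examples are unlabelled
positives at an unknown rate.  The synthetic results certify the
machinery — feature construction, the CV protocol, the estimators, the
scanner — not biological performance.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 500-gene / 100-target
fixture for model recovery, 1000–2000 genes for DE power and null
calibration, ≤ 5×6 matrices for the CLR oracle, L ≤ 6 motifs for the
p-value oracle, and ≤ 8-point 1-D instances for the k-means oracle —
sizes at which the independent oracles are exactly computable while the
code paths are identical to full-scale use.  Tolerances: 1e-12 for
algebraic identities (AUC, CLR), 1e-6 for the discretised motif p-values,
1e-9 for QP-dependent quantities.  Seeds are mandatory everywhere
randomness enters (negative sampling, CV folds, k-means restarts, all
generators); identical configuration and seeds give byte-identical
pipeline outputs.

## Known limitations

- The moderated-t implementation supports only consecutive-timepoint
  contrasts and no replicate-correlation or array-weight extensions.
- CLR is the plain plug-in estimator; no B-spline MI, no DPI/ARACNE
  pruning.
- The scanner's exact p-values assume a 0-order background; no q-values.
- One cascade level for secondary TFs, mirroring the intended analysis
  depth.
- The per-gene expression model uses replicate-averaged profiles; replicate
  variability enters only through the DE stage.
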