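# Methods

`nestmorph` implements an objective species-delimitation workflow for
continuous morphometric data with nest structure, of the kind used in
quantitative ant taxonomy: exploratory clustering proposes species
hypotheses, cross-validated discriminant analysis confirms or lumps
them, and ratio analysis distills the result into a usable
identification key. This note records the models, the numerical
choices, and what the synthetic tests do and do not demonstrate.

## Data model

A specimen is a worker ant with 22 linear measurements in μm (head,
mesosoma, petiole, postpetiole and spine dimensions). Absolute cephalic
size CS = (CL + CWb)/2 is derived, never measured, and is the
denominator of most diagnostic ratios. Specimens nest inside *nest
samples* (shared collection code): nestmates are assumed close kin, so
within-nest variation approximates measurement error plus within-colony
plasticity, and between-nest variation carries the taxonomic signal.

Data quality is screened two ways. Repeatability of a trait is the
average-measure intraclass correlation of a double-measurement trial,
computed from the two-way ANOVA mean squares
(ICC = (MSR − MSE)/(MSR + (MSC − MSE)/n), negative estimates clamped to
0). The error-variance screen flags any trait whose maximum absolute
Pearson correlation with all other traits falls below a threshold
(default 0.5): in size-dominated morphometrics every honest trait
correlates strongly with the rest, so an uncorrelated column suggests
measurement trouble. The screen is advisory; nothing is dropped
automatically.

## Nest-centroid clustering

Raw μm traits (no standardization — the discriminant solution absorbs
linear reparameterizations) enter an LDA with nest samples as groups:
the generalized eigenproblem Sb·a = λ·Sw·a on between-nest and pooled
within-nest scatter. All axes with eigenvalue above 1e-10 of the
leading one are retained (at most min(22, nests − 1)), because
downstream distances should use the full morphospace, not only the two
plotting axes. Axis signs follow a canonical rule (largest-magnitude
loading positive) so runs are comparable across platforms.

With many singleton nests the pooled within-nest scatter can be
rank-deficient. The default conditioning shrinks the within-nest
*correlation* matrix toward the identity with a Ledoit–Wolf intensity
estimated from the standardized within-nest residuals — equivalently,
the covariance is shrunk toward its own diagonal, which preserves the
scale-invariance of the scores (multiplying a trait column by a
constant changes nothing). Shrinkage is applied only when needed
(rank deficiency or condition failure) and is recorded in the model's
`regularization` field.

Specimen scores are averaged per nest (the nest centroid); pairwise
Euclidean distances between centroids feed Ward agglomeration (complete
/ average / UPGMA available) and the dendrogram is exported as an
ultrametric Newick plus a merge table. The dendrogram is a phenetic
display, not a phylogeny. Specimen-level clustering is available by
flag; nest centroids are the default unit.

## Cluster number: the Gap statistic and PART

The within-cluster dispersion is W = Σ_r D_r/(2 n_r) (D_r the sum of
squared pairwise distances in cluster r), compared on the log scale with
its mean under B reference datasets drawn uniformly over the data range
in the principal-component frame. The selection rule is the classic
one: the smallest k with gap(k) ≥ gap(k+1) − s(k+1), where s carries
the √(1 + 1/B) factor; a first-local-maximum variant is available by
flag. B defaults to 500; tests use smaller B, which only widens the
simulation error.

PART applies this recursively: a cluster found at one level is re-tested
on its own subset, until a subset has fewer than 2·min_size cases
(min_size defaults to 3, k_max to 10 per split). When a subset is judged
homogeneous (k = 1) a tentative binary split is attempted: if one side
has fewer than min_size members those cases are set aside as outliers,
the remainder is re-tested, and the outliers are finally attached to the
nearest resulting cluster centroid. This exact tentative-split variant
is this package's documented interpretation of the idea of isolating
outliers that would otherwise halt the recursion.

Two base engines mirror common practice: Ward agglomeration cut at k,
and k-means with 25 seeded restarts (reference draws inside the gap
computation use 5 restarts; the reference dispersion is an average over
B draws and is insensitive to the per-draw restart count, which keeps
the cost of B = 500 manageable). All randomness flows from one integer
seed.

A structural property worth knowing: when k well-separated clusters are
arranged near-symmetrically (no macro-structure), the gap gain from
k = 1 to k = 2 is small — the binary split helps the observed data and
the uniform reference about equally — and the stepwise rule can stop at
k = 1 even though the gap curve peaks sharply at the true k. Real
morphometric data are usually hierarchical (species complexes first,
species within them), which is exactly the regime where the recursion
shines; the synthetic end-to-end checks therefore use the
study-emulating geometry rather than idealized point clusters.

## Confirmation: wildcards, LOOCV-LDA, lumping

The two engine partitions are matched by solving the assignment problem
on their contingency table; specimens classified congruently become
prior classes, the rest become *wildcards* with no prior imposed.
Leave-one-out cross-validated LDA (proportional class priors; equal
priors by option) predicts every non-wildcard specimen from all the
others. Wildcards are excluded from all training and assigned the
highest-posterior class of the full model in a single pass (no
iterative re-training — the simplest reading of "no prior imposed").
Classification success is reported per class (diagonal over row sum)
and overall (trace over total) across non-wildcard specimens;
misclassified specimens keep their prior label, with the prediction
recorded in the provenance notes.

Lumping operationalizes "separation not convincingly confirmed": while
any class scores below a threshold (default 0.90) and the majority of
its errors land in one partner class, the pair is merged and the LOOCV
re-run, until stable. The threshold is exposed and every merge is
logged in the per-specimen notes.

## Multivariate ratio analysis

On the log scale, isometric size is the projection onto the unit
diagonal (implemented as the mean of log traits, the same up to the
1/√p factor), and shape is the orthogonal complement of that axis after
column centering, summarized by its principal components. Isometric
inflation of a specimen moves its size and leaves every shape score
unchanged — that is the construction guarantee. Note that the *sample
correlation* between shape scores and isosize is not forced to zero:
that correlation is precisely the allometric signal the decomposition
exposes, so it is not asserted as an invariant.

The ratio extractor scans all ordered trait pairs. For two groups each
log-ratio is scored by the standardized group-mean difference in
pooled-SD units; for more groups by the one-dimensional between/within
criterion. Errors come from the optimal single-threshold rule on the
ratio (resubstitution, with a leave-one-out error alongside); only one
orientation per pair is reported (first group high), ties in the
ranking break lexicographically, and zero-variance ratios are excluded
with a warning. Scores are invariant to per-trait rescaling, so whether
the raw table was standardized is irrelevant to the ranking.

## The identification key

The published seven-couplet key is hard-coded with its printed ratio
thresholds (SL/CS 0.73, NOL/CS 0.3, SPST/CS 0.36, PoOC/CL 0.455, CW/ML
0.73, CL/CW 1.09, PSTI/SPTI 2.5, PSTI/PPW 1.84, elevation 500 m). The
decisive predicate of each couplet is quantitative; sculpture, color
and elevation are advisory — a disagreement produces a warning, never
an override, because only ratios are machine-checkable from a
measurement table. Ties at a printed threshold follow the non-strict
arm where the published wording is non-strict (PSTI/SPTI ≤ 2.5 keys to
*sikorai*); where both arms are printed strict or ambiguous (0.73,
1.84) ties route to the second arm. In the final couplet the published
arm ranges and the species' summary statistics show *excelsior* on the
low side of PSTI/PPW ≈ 1.84 and *rugosus* on the high side, and the
implementation follows the ranges. The key is serializable as
structured text so other keys can be loaded.

## Synthetic data generator

The generator draws log-trait vectors as species mean + per-nest effect
(shared by nestmates) + per-individual isometric size factor (equal
loading on all traits) + independent residual, then exponentiates to
μm — log-normal, hence strictly positive, with the size factor creating
the all-traits-correlate structure real ants show. Defaults emulate the
study design: 8 species parameterized by the published per-species mean
morphologies (reconstructed from CS and the ratio table), published
nest counts (58, 18, 7, 9, 23, 28, 9, 32) and worker totals (227 in
all, 1–3 workers per nest), and typical per-species elevations as the
advisory covariate.

Noise defaults (log-scale SDs ≈ coefficients of variation):
`size_sd = 0.045` reproduces the ≈4–5% CS variation of the summary
table, `nest_sd = 0.015` and `individual_sd = 0.012` give ratio CVs of
≈2–3%, matching the published ratio SDs. The near-noise-free variant
(`tight_study_config`) sets worker-level log-ratio scatter to 0.002 so
the narrowest species-to-threshold margin in the key (≈0.016 in log
units, *modestus* CW/ML) stays ≥ 8 SDs away — the construction under
which full key agreement is guaranteed rather than merely likely.

What passing synthetic tests do *not* show: the generator's residuals
are independent across traits given size, so particular ratios are less
dispersed than in real specimens (the *excelsior*/*rugosus* PSTI/PPW
contrast separates perfectly here, whereas real material overlaps), and
no qualitative characters, measurement blunders, geographic clines or
missing data are simulated. Conclusions about real material require the
real specimen table.

## Problem sizes and determinism

The shipped checks run the full pipeline at 227 specimens / 184 nests
with B = 50 reference draws in the test suite and B = 500 in the
acceptance script (about two minutes on one core; the Ward engine is
essentially free, k-means dominates). Every stochastic component —
generator, reference draws, k-means restarts, recursion seeds — derives
from a single integer seed, and identical configurations produce
byte-identical outputs.

## Known limitations

- The tentative-split rule is one documented interpretation; the
  historical implementation it echoes is not fully specified in print.
- The merge ("lumping") criterion quantifies an inherently editorial
  judgment; different thresholds can lump or keep borderline clusters.
- LDA assumes a shared within-class covariance; strongly heteroscedastic
  clusters would call for quadratic or regularized alternatives.
- The elevation predicate of the final couplet is advisory only, so
  populations at atypical elevations produce warnings, not different
  identifications.
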