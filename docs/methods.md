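# Methods

This note documents the models and procedures implemented in `omicslink`,
the parameters that matter, the numerical choices, and what the synthetic
data used by the tests does and does not establish about real data.

## Inputs and assumptions

Both omics matrices are samples × features, tab-delimited, complete
(missing values are rejected at parse time: every downstream statistic —
correlation matrices, CCA, PLS — assumes complete data, and no principled
imputation rule exists at this stage of the pipeline). Values are assumed
pre-normalized; the statistics further assume approximate multivariate
normality, which the user must judge. ChEBI identifiers are normalized to
bare integers ("CHEBI:" prefix stripped on input, re-added in reports);
gene symbols are compared case-insensitively after uppercasing, since
mouse-derived files frequently mix case while interaction snapshots use
uppercase symbols.

## Functional grouping

The knowledge base is four offline snapshot files: metabolite→pathway
(ChEBI2Reactome dialect), pathway→gene, ChEBI ontology child→parent edges,
and a scored gene–gene interaction list (STRING dialect, integer combined
score in [0, 1000]). Resolution of a ChEBI query prefers, in order: the
query itself; the nearest pathway-annotated *descendant* (the full subtree
is searched breadth-first, not only direct children — "children direction"
is a preference of direction, not of depth); the nearest annotated
ancestor. "Nearest" is BFS depth (fewest ontology edges); the ontology
defines no edge lengths, so hop count is the only defensible metric. Ties
at equal depth are broken by the smallest numeric ChEBI id, which makes
resolution deterministic. Unresolvable ids are reported as UNMAPPED and
contribute nothing downstream; a fully unmapped metabolite list yields an
empty group with a warning rather than an error, so a pipeline over many
subsets degrades gracefully.

Gene-set expansion is exactly one interaction hop: "closest neighbors" is
read as direct interactors, matching the neighborhood semantics of scored
interaction databases. The score threshold defaults to 400 — the
conventional "medium confidence" cutoff — and is an explicit, logged
parameter (0–1000) because no single value suits every snapshot. Expansion
is monotone in the threshold and deliberately applied once; iterating it
would grow the set without bound. The knowledge base carries a free-text
species label that is logged, never enforced: cross-species snapshots are
scientifically questionable but sometimes the only option, and that
judgment belongs to the analyst.

## Decorrelation

Within-set pruning uses a greedy first-come-first-kept scan in input column
order: the first column is kept; each later column is dropped when its
absolute correlation with any kept column reaches the threshold, recording
the kept column with the largest |r| as its representative. Alternatives
(clustering the correlation graph, keeping the most-connected member) are
defensible but unanchored; the greedy rule is deterministic given the
file's column order, trivially reportable, and self-checkable (recomputing
the kept-set correlation matrix must show all off-diagonal |r| below the
threshold — the suite asserts this on random inputs). Absolute correlation
is compared, since strong negative correlation is redundancy too. Pearson
is the default (the downstream engines are linear); Spearman is available
for monotone-but-nonlinear redundancy. Zero-variance columns have no
defined correlation; they are dropped with a warning and no representative.
Typical operating thresholds in this domain are r = 0.6 for gene sets and
r = 0.7 for metabolite sets; both are plain CLI parameters.

## Canonical correlation analysis

Inputs are always standardized (mean 0, sd 1, ddof = 1), so weights are
comparable across variables. Computation is the SVD of
R_xx^(−1/2) R_xy R_yy^(−1/2): singular values are the canonical
correlations, and back-transformed singular vectors the weights. The
inverse square roots come from symmetric eigendecompositions; a minimum
eigenvalue below 1e−10 raises an error that points at the pruning step,
since a singular within-set correlation matrix means collinear columns
survived. Preconditions: n > max(p, q) + 1 is a hard error; the classical
guideline of 20 samples per variable is only a warning, because real
studies of this shape (e.g. n = 40 with a dozen representatives per block)
routinely violate it and remain interpretable alongside the significance
tests.

Diagnostics follow the classical definitions: loadings are correlations of
variables with variates (computed as R·weights, exact on standardized
data); adequacy is the mean squared loading of a set on its own variate;
communality the per-variable sum of squared loadings; redundancy of set Y
for pair i is r_i² times Y's adequacy on v_i (and symmetrically for X).
Bartlett's sequential test uses the classic multiplier
−[n − 1 − (p + q + 1)/2] without the Lawley correction; the variant choice
is recorded here because published tables rarely state it. Signs of
canonical pairs are arbitrary; the convention adopted is that the
largest-magnitude loading across both blocks of each pair is positive
(flipping a_i and b_i together, which preserves cor(u_i, v_i)). A
numerically perfect correlation (r = 1, e.g. Y an invertible linear image
of X) drives Bartlett's Λ to zero; the result table then reports the
correct limit χ² = ∞, p = 0 instead of failing. The standalone
`bartlett_test` operation remains strict (r must lie in [0, 1)).

Helio-plot data is emitted as a table (variable, set, loading, angle) for
one chosen variate rather than as a rendered figure, keeping plotting
backends out of the pipeline.

## Partial least squares

The engine is NIPALS with X-deflation and regression of both blocks on the
X-scores (the orthogonal-scores PLS2 family), chosen because its named
matrices — T = XW-type scores, weights W, X-loadings P, Y-loadings Q, and
coefficients — are the ones conventionally reported for this workflow.
With deflation the naive product B = WQ' is not the regression matrix; the
corrected form B = W(P'W)⁻¹Q' is used, and the result object notes this.
Centering is always on; unit-variance scaling is on by default because
omics blocks live on heterogeneous scales, and switchable (fitting
pre-standardized data with scaling off is equivalent, which the suite
asserts). The inner loop converges when the score vector changes by a
relative 1e−12 or after 500 iterations; iteration counts are stored on the
result. Cumulative explained variance is reported for *both* blocks —
reporting conventions differ on which block a single "% explained" series
refers to, so the ambiguity is surfaced instead of hidden. Zero-variance
response columns are a hard error naming the column.

Cross-validation refits the entire model (including centering/scaling) on
every training fold. Leave-one-out is the default scheme — deterministic
and appropriate at the small n this pipeline targets — with seeded k-fold
as the alternative. Curves are reported per response for 0…A components;
the 0-component model predicts the training-fold response means, so its
RMSEP is the cross-validated sd of the centered response and serves as the
skill baseline. R² is defined as 1 − PRESS_a/PRESS_0 against that
baseline.

## Synthetic data

`generate_paired_omics` plants canonical structure directly: for each
requested ρ_i, a shared latent z_i ~ N(0,1) is drawn, the Y-side latent is
ρ_i z_i + √(1 − ρ_i²) ε_i, and the latent blocks are embedded through
random orthonormal loading matrices with isotropic N(0, noise_sd²) noise
added. The noiseless construction has population canonical correlations
exactly ρ; isotropic noise attenuates them by 1/(1 + noise_sd²), i.e. ≈1%
at the default noise_sd = 0.1, chosen so that estimator-recovery tests
measure the estimator rather than the noise model. The latent-factor
construction (rather than specifying a joint covariance directly) also
fixes a ground-truth latent count, which the PLS component-selection tests
use. One integer seed drives a single `numpy.random.Generator`; identical
spec and seed reproduce output files bit-for-bit.

The generator emulates exactly the multivariate-normal world the statistics
assume. It does **not** emulate heteroscedastic platform noise, batch
effects, outliers, or skewed metabolite distributions — so passing tests
certify the mathematics and the plumbing, not robustness to real-data
pathologies. Outlier handling in particular is intentionally out of scope:
CCA is known to be sensitive to outliers, and rejecting them is a judgment
left upstream of this toolkit.

`generate_fixture_knowledgebase` writes a miniature snapshot in which, by
construction, the metabolite queries cover all four resolution branches
(the VIA_CHILD query also has a mapped parent at distance 1, so the
child-over-parent preference is genuinely exercised, not vacuously true).

## Problem sizes in the test suite and acceptance script

The suite verifies the CCA solver against a direct numerical maximization
of cor(a'X, b'Y) (BFGS, multi-restart, residualization-based deflation) on
instances with n = 200 and p = q ∈ {2, 3, 4}; Bartlett calibration uses
2000 null replicates at n = 100, p = q = 3; planted-correlation recovery
uses n = 1000 over 10 seeds (the per-component estimates are averaged over
seeds before comparison, since a single estimate at n = 1000 carries
sampling noise of the same order as the tolerance); PLS component
selection uses 20 seeds of a 2-latent model at n = 100 with leave-one-out
validation. The acceptance script runs the full pipeline at the
study-shaped size n = 40, p = 20, q = 12 with planted ρ = (0.9, 0.6, 0.3),
thresholds 0.6/0.7 and a 3-component PLS. These sizes were chosen as the
smallest at which each property is statistically meaningful.

## Known limitations

- No cross-namespace identifier translation (Ensembl/UniProt columns are
  accepted as labels but not mapped to HGNC).
- Pairwise-correlation pruning only; no multivariate collinearity
  diagnostics (VIF, condition numbers).
- No regularized or generalized CCA, no sparse PLS or PLS-DA.
- The pathway granularity of the snapshot is taken as given; no
  reaction-level reconstruction.
- Knowledge-base completeness bounds the biology: genes absent from the
  snapshot can never enter a functional group, and cross-species snapshots
  are accepted but only logged.
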