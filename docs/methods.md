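# Methods

## Connectome construction

A subject's parcellated time series (node × timepoint) is reduced to a
vector of Fisher z-transformed Pearson correlations over the
*n(n−1)/2* unordered node pairs.  The canonical edge order everywhere in the
package is the row-major upper triangle, 0-based; one unambiguous index
convention prevents silent misalignment between weight maps computed in
different stages.  Correlations are clipped to |r| ≤ 1 − 10⁻⁷ before
arctanh so that degenerate pairs stay finite while the ordering of edges is
preserved; real data cannot reach |r| = 1, so the clip only matters for
synthetic and pathological inputs.  A zero-variance node is an error naming
the node, not a silent NaN.

The shipped default atlas (`data/atlas246_8net_synthetic.tsv`) has 246 nodes
in 8 networks — 36 subcortical nodes plus 210 cortical nodes split across
VIS, SMN, DAN, VAN, LIM, FPN and DMN with realistic proportions.  It is a
synthetic stand-in that fixes the edge space and the 36 network pairs; it
carries no real anatomical node labels, and users supply their own atlas TSV
for real parcellations.  Network order is the order of first appearance in
the file; network pairs are ordered row-major over the upper triangle of the
network grid including its diagonal.

## Prediction

PLSR is solved with SIMPLS (de Jong 1993, *Chemometrics Intell. Lab. Syst.*
18:251).  Preprocessing is mean-centering of features and target only, using
training statistics folded into the intercept — edges share units, so no
variance scaling is applied by default.  For a single response SIMPLS and
NIPALS PLS1 yield identical coefficients; the test suite uses scikit-learn's
NIPALS implementation as an independent cross-check of the hand-written
core, and the univariate case collapses to the OLS slope exactly.

The number of components is a genuinely open choice in this workflow.  The
default selects it per training fold by inner 5-fold cross-validation over
1..20 components, minimizing held-out RMSE; the SIMPLS decomposition yields
the whole component path at the cost of one fit, so selection is cheap.  A
fixed-component mode exists for reproducibility experiments, and several
desk-scale defaults in the pipeline use 1 component, which is where the
inner-CV rule typically lands on the default synthetic conditions.

Repeated k-fold CV (10 folds × 200 repetitions by default) redraws a random
partition each repetition from a single seeded generator; fold sizes differ
by at most one subject.  Nothing computed on a held-out fold — centering,
screening, component selection — ever enters training; the leakage guard is
asserted in the tests by shuffling held-out targets and checking training
coefficients are bit-identical.  Each repetition's held-out predictions are
concatenated before scoring, giving one (r, R², RMSE) triple per repetition;
summaries are mean ± SD over repetitions.  All reps × folds fold-level
coefficient vectors are retained for interpretation.

Permutation tests shuffle the target, re-run the full CV pipeline, and use
the add-one estimator p = (1 + exceedances)/(1 + n_perm), which never
returns zero and floors at 1/5001 ≤ 2.0 × 10⁻⁴ for 5000 iterations.  The
null statistic is the mean r over a reduced number of repetitions (1
repetition of 10-fold CV per permutation by default, recorded in the
result); running the full 200 repetitions inside every permutation would
change nothing statistically at great cost.

Covariate control of accuracy is a partial correlation: both actual and
predicted scores are residualized on the covariates and correlated, with a
t-distributed p on n − 2 − k degrees of freedom.  An alternative reading —
residualizing the target *before* fitting — exists in the literature; this
package implements the partial-correlation reading, which leaves the fitted
models untouched.  Covariate-independent feature screening (used for
age-excluded cognition models) retains, per training fold, only edges whose
partial correlation with the target given the covariate reaches α = 0.05;
fold weight maps keep full length with zeros on screened-out edges.

The CPM family is the standard correlation-screen protocol: edges related to
the training target at p < 0.01 are split by sign, summed into per-subject
positive and negative strengths, and a linear model on the two strengths is
fitted on training data.  It serves as a multicollinearity cross-check on
the PLSR weight maps, not as the primary engine.

## Interpretation

The connection-level representation is the arithmetic mean of all fold-level
coefficient vectors (2000 for the default 200 × 10 design).  The node level
sums each node's incident edge weights — signed sums, so the node total
equals twice the edge total (handshake identity); an absolute-value variant
is available behind a flag for users who want contribution magnitude.  The
network level aggregates each of the K(K+1)/2 network-pair cells: mean
weight, and positive and negative sums each normalized by the pair's edge
count so large networks do not dominate.  Mean cells are linear in the
underlying map, which the tests exploit.

Overlap between two same-level maps is Pearson's r with a permutation null
built by shuffling the entries of one map; p is two-sided,
(1 + #{|null| ≥ |r|})/(1 + n_perm), since inverse relationships between age
and cognition maps are the expected signal.

## Stability battery

Fold-map inter-correlation uses all distinct map pairs when there are at
most `max_pairs` (default 10 000) and otherwise a seeded sample of that many
distinct pairs — an unbiased estimator of the same mean and SD at a fraction
of the ~2 × 10⁶ pairs a 2000-map run implies.  The subject-level bootstrap
refits the full-data model per resample (with replacement, same component
rule re-applied); degenerate resamples with a constant target are redrawn
and counted.  Network-restricted models re-run the repeated-CV engine on
each pair's edges alone; the report includes each pair's accuracy, the
whole-brain accuracy, and the Spearman correlation between pair size and
pair accuracy.  Whether a restricted model "beats" the whole brain is left
as reported means with SDs; no formal test is imposed.

## Mediation

Per edge, the three-regression decomposition with age as exposure, the edge
as mediator, a cognitive score as outcome, and optional covariates (gender,
mean FD): a from m ~ x + C, b and c′ from y ~ x + m + C, c from y ~ x + C.
The OLS identity a·b + c′ = c holds exactly with identical covariate sets
and is asserted to 10⁻⁸.  Inference on a·b resamples subjects jointly
(percentile CI, default 10 000 iterations; two-sided add-one p from the
resampled distribution).  The proportion mediated is a·b/c, the dominant
convention of the R `mediation` workflow; when |c| < 10⁻¹⁰ it is flagged
undefined and reported as NaN rather than a spurious ratio.  Top-k families
(k = 100 and k = 300 in the reference workflow) are each corrected with
BH-FDR across exactly k tests; ties in the weight ranking break by edge
index.

## Transfer

The frozen model for external validation is refit once on the full
discovery cohort — not the average of CV fold models — and serialized as
JSON (coefficients, intercept, component count, atlas hash, training
metadata).  Application to an external cohort is `intercept + X @ coef` with
no refitting; the training-cohort centering lives inside the intercept and
no external statistic is used.  An atlas content hash guards against
applying a model to an incompatible edge ordering.  Validation correlates
predicted scores with external age partialling out mean FD; the Bonferroni
family is all models applied to that cohort (9 by default: age plus eight
cognitive metrics).  Sign conventions are preserved: age models should
transfer positively, cognition models negatively.

## Synthetic cohorts

The generator emulates an adult-lifespan cohort with the statistical
structure the analysis assumes, at sizes a desk can afford:

- **Age** uniform over 19–89 years — the simplest stand-in for an
  approximately uniform lifespan cohort.
- **Cognition**: one shared factor g = s·z(age) + √(1−s²)·ε with
  standardized slope s = −0.6 by default; the primary metric (gF) is the
  factor itself and the other seven battery metrics mix it with private
  noise (loading √0.75), keeping all metrics intercorrelated and negatively
  age-coupled without modelling each task.  An optional per-metric missing
  rate emulates incomplete batteries; default complete.
- **Motion**: mean framewise displacement is lognormal (median ≈ 0.12 mm,
  log-SD 0.35) and mildly correlated with age (r ≈ 0.3), so FD-control
  analyses have something real to remove.
- **Connectome edges**: z = baseline + β_age·z(age) + β_cog·z(ε) +
  γ·FD + N(0, σ), where ε is the cognition component independent of age,
  γ = −0.3 z-units/mm, σ = 0.5 by default, and baseline is 0.3 within /
  0.1 between networks.
- **Effect map**: within-network edges of DMN, VAN, SMN and SUB load
  negatively on age and positively on cognition; LIM within-network and
  SMN-to-associative (plus DMN–VAN) between-network edges do the opposite;
  all other edges carry no effect.  Magnitudes are U(0.1, 0.3) per edge.
  The age and cognition loadings are anti-mirrored edge by edge
  (β_cog = −β_age × U(0.9, 1.1)): the same connections carry opposite
  effects for the two constructs.  The ±10 % jitter is deliberate — exact
  mirroring would collapse the edge signal to a single latent direction and
  make age unrecoverable beyond that combination, while fully independent
  magnitudes would let a multivariate fit cancel the anti-aligned latent
  and scramble per-edge coefficient signs.  The jitter keeps the age and
  cognition latents separately identifiable (noise-free CV accuracy reaches
  r = 1) while preserving per-edge sign structure in fitted maps.
- **Time series**: given a target connectome, the implied correlation
  matrix is repaired to the nearest valid (PSD, unit-diagonal) matrix by
  eigenvalue clipping — rejected if any correlation must move more than
  0.1 — and i.i.d. Gaussian timepoints are drawn from it.  Sample
  correlations converge to the target at the usual 1/√(T−3) rate.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, scanner/site effects, nonlinear age trajectories,
heavy-tailed motion artefacts, or realistic effect sparsity (the planted
effects are dense within their network classes and far stronger than
plausible single-edge effects in real data).  Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, under its
own assumptions — not that real cohorts would yield comparable accuracies.
Synthetic accuracies are not calibrated to any empirical cohort's numbers.

## Numerical choices and degenerate inputs

- SIMPLS stops early if the predictor space is exhausted (rank deficiency)
  and records the effective component count.
- Constant prediction targets, zero-variance nodes, empty screens/feature
  sets, rank-deficient covariates, and level-mismatched maps raise typed
  exceptions rather than producing silent numbers.
- A vector fully explained by covariates (residual sum of squares below
  10⁻¹² of its raw sum of squares) has partial correlation defined as 0.
- Ties in fold sizes differ by at most one; ties in top-k weight selection
  break by edge index.
- On-disk tables are UTF-8 TSV with repr-precision floats and are read back
  with round-trip parsing, so write→read is bitwise exact and full-pipeline
  reruns from one config are byte-identical (checksummed manifest).

## Desk-scale problem sizes

The test suite and the acceptance script run the full designs where counts
matter (200 × 10 CV, 5000-iteration permutation floor, 199-iteration
permutation nulls over 200 datasets) but at reduced feature and cohort sizes
(20–60 nodes, 80–500 subjects, reduced bootstrap iteration counts).  These
sizes are the package's own defaults for simulation studies; the estimators
are identical to the full-scale ones, only the problem sizes differ.

## Known limitations

- Single-output PLSR only; multi-output prediction of all phenotypes at
  once is out of scope.
- No site harmonization, no brain-age bias correction, no nonlinear models.
- CPM internals follow the standard published protocol (p-threshold screen,
  sum strengths, bivariate linear model); variants (robust correlation,
  partial-correlation screens) are not implemented.
- The mediation analysis is associational; no sensitivity analysis for
  sequential ignorability is provided.
- Plotting is limited to network-cell heatmaps.
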