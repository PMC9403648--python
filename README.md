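# connpredict

Connectome-based predictive modelling of age and cognition from whole-brain
functional connectivity.

Healthy aging is accompanied by cognitive decline, and both constructs leave
distributed fingerprints in the brain's functional connectome — the matrix of
pairwise temporal correlations between parcellated regions' activity.
`connpredict` implements the full analysis stack used to ask how far those
fingerprints overlap: it predicts age and cognitive scores from connectome
edges, interprets the resulting model weights at three spatial levels,
quantifies their similarity and stability, tests whether predictive
connections mediate the age–cognition association, and transfers frozen
models across cohorts.  A synthetic-cohort generator with planted,
network-structured effects makes every stage testable without any imaging
data.

The package is aimed at network-neuroscience and biostatistics researchers
who want a tested, scriptable reference implementation of this workflow — or
a simulation test bed for methodological work on connectome-based prediction.

## The model

Each subject's connectome is built from a node × time series matrix: pairwise
Pearson correlations, Fisher z-transform (arctanh, with |r| clipped to
1 − 10⁻⁷), and vectorization of the upper triangle — *n(n−1)/2* edges in
row-major order (30 135 edges for the default 246-node parcellation whose
nodes are grouped into 8 canonical networks: VIS, SMN, DAN, VAN, LIM, FPN,
DMN, SUB).

Prediction uses partial least squares regression solved with the SIMPLS
algorithm: for target *y* and edge matrix *X*, a small number of latent
components maximizing predictor–target covariance yields a per-edge
coefficient vector **β** (the weight map) and intercept, with prediction
*ŷ = β₀ + Xβ*.  Models are evaluated in repeated 10-fold cross-validation
(200 repetitions by default): per repetition the held-out predictions are
scored as Pearson *r*, cross-validated *R²* = 1 − SS_res/SS_tot, and RMSE,
reported as mean ± SD over repetitions.  Significance comes from permutation
tests — the target is shuffled, the full CV pipeline re-run, and
*p* = (1 + #{null ≥ observed}) / (1 + n_perm), which floors at 1/5001 ≤
2.0 × 10⁻⁴ for 5000 iterations.

Weight maps are interpreted at the connection level (the mean of all
reps × folds fold-level coefficient vectors), the node level (sum of each
node's incident edge weights), and the network level (per network pair, the
mean weight plus sign-split sums normalized by the pair's edge count).
Overlap between two models is the Pearson correlation of their maps with a
permutation null.  The robustness battery covers bootstrap weight maps,
fold-map inter-correlations, an independent CPM (correlation-screen)
model family, and the 36 network-restricted prediction runs.  Mediation
follows the standard three-regression decomposition per edge (*a·b*
indirect effect, bootstrap percentile CI, BH-FDR over the top-k weighted
edges), and transfer applies a frozen model to an external cohort as a pure
dot product, validated by partial correlation with age controlling head
motion under Bonferroni correction.

## Worked example

```python
import connpredict as cp

atlas = cp.scaled_canonical_atlas(60)                 # 8 networks, 60 nodes
spec = cp.default_spec(atlas, n_subjects=300, noise_sd=0.5, seed=7)
phenotypes, edges = cp.simulate_cohort(spec)

model = cp.ConnectomePLS.from_dataframe(phenotypes, edges, "age", atlas=atlas)
cv = model.fit_repeated_cv(folds=10, reps=20, n_components=1, seed=0)
print(cv.summary())

age_map = cp.average_maps(cv.fold_weight_maps)
cv_gf = cp.ConnectomePLS.from_dataframe(phenotypes, edges, "gF").fit_repeated_cv(
    folds=10, reps=20, n_components=1, seed=0)
gf_map = cp.average_maps(cv_gf.fold_weight_maps)
res = cp.overlap(age_map, gf_map, n_perm=9999, seed=0)
print(f"age-gF weight-map overlap: r = {res.r:.3f}, p = {res.p:.2g}")
```

prints

```
  metric       mean        sd
0      r   0.725464  0.001097
1     R2   0.526293  0.001588
2   RMSE  13.975498  0.023423
age-gF weight-map overlap: r = -0.978, p = 0.0001
```

Age is predicted from held-out connectomes at r ≈ 0.73 (RMSE in years), and
the age and fluid-intelligence weight maps are strongly inversely
correlated — the connections that strengthen with age are those that predict
lower cognition, exactly the structure the generator plants.  Network-level
cells come from `cp.network_summary(age_map, atlas)`, e.g.:

```
net_a net_b  mean_weight  positive_sum_normalized  negative_sum_normalized  edge_count
  VIS   VIS    -0.001654                 0.005754                -0.007407          21
  VIS   SMN    -0.002669                 0.004750                -0.007419          63
```

A command-line interface mirrors the library (`connpredict synth / predict /
interpret / overlap / stability / mediate / transfer / full-run`); `full-run`
chains every stage from one config and writes a checksummed manifest.

## Layout

- `src/connpredict/connectome.py` — atlas, edge indexing, Fisher-z connectomes
- `src/connpredict/synthetic.py` — cohort and time-series generators
- `src/connpredict/prediction.py` — SIMPLS, `ConnectomePLS` model/results, CV,
  permutation tests, covariate screening, CPM, motion filtering
- `src/connpredict/interpretation.py` — weight maps, summaries, overlap
- `src/connpredict/stability.py` — bootstrap, inter-correlation,
  network-restricted models
- `src/connpredict/mediation.py` — per-edge mediation with bootstrap and FDR
- `src/connpredict/transfer.py` — frozen-model application and validation
- `src/connpredict/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, formats
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
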