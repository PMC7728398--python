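# Methods

This note describes the models and procedures implemented in `wirespace`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology left the design open.

## The wiring model

Cortical wiring is summarised by three complementary node-by-node features
on a common parcellation:

* **Geodesic distance (GD).** Each parcel is represented by an exemplar
  vertex — the mesh vertex closest (Euclidean) to the parcel's vertex
  centroid, ties broken by lowest vertex index. GD(i, j) is the shortest
  path between exemplars over the mesh edge graph, with edges weighted by
  Euclidean length (Dijkstra). We deliberately use graph shortest paths
  rather than exact polyhedral geodesics or fast marching: the downstream
  normalisation is rank-based, so the few-percent metric discrepancy cannot
  change the manifold, and graph paths are deterministic and directly
  checkable against a brute-force all-pairs oracle. Consequences worth
  knowing: on a dense planar triangulation, graph paths overshoot the
  straight-line distance by ~4% on average (the Delaunay-graph "spanner
  stretch"), and distances between co-circular point sets depend on the
  (non-unique) triangulation. When a mesh has disconnected hemispheres,
  cross-hemisphere entries can be filled by mirroring homologous
  within-hemisphere distances (`GD(i,j) = (GD(h(i),j) + GD(i,h(j)))/2`
  with `h` the homologue map supplied by the parcellation).

* **Microstructure profile covariance (MPC).** Depth-wise intensity
  profiles are sampled on equivolumetric surfaces. Under a linear-frustum
  model where cross-sectional area varies as
  `((1-x)·√A_inner + x·√A_outer)²`, cumulative volume is cubic in depth, so
  the equal-volume depth fractions have a closed-form inverse (equal areas
  degenerate to equidistant fractions). Within a parcel, vertices whose
  across-depth median intensity deviates from the parcel median by more
  than 3 scaled median absolute deviations (scale 1.4826) are excluded; a
  zero MAD excludes nothing, which protects constant parcels. MPC(i, j) is
  the partial Pearson correlation of node profiles controlling for the
  cortex-mean profile, thresholded at 0, and the surviving entries are
  natural-log transformed. The log of r ∈ (0, 1] is ≤ 0; since fusion is
  rank-based, the base and sign convention of the log are immaterial (any
  strictly monotone transform yields an identical manifold), and we pick
  the natural log for definiteness. An exact r = 1 would collide with the
  0 sparsity sentinel after the log; it is nudged to the nearest negative
  representable value.

* **Tractography strength (TS).** Per-subject streamline-weight matrices
  are combined by distance-dependent consensus: edges are pooled into
  equal-count GD bins (each subject-edge occurrence contributes one sample,
  preserving the pooled edge-length distribution), and each bin retains the
  K most consistent edges, K = round(mean per-subject edge count in the
  bin), ties broken by higher mean nonzero weight. Retained weights are the
  mean of the nonzero subject weights. Default 10 bins; hemispheres are
  pooled. One bin reduces to plain consistency thresholding at matched
  global density.

## Building the wiring space

1. **Normalisation.** Nonzero entries of each matrix are rank-normalised
   (average ranks on ties); GD is negated first so larger values mean
   closer. Each matrix's ranks are min–max rescaled to the range of the
   ranked entries of the sparsest matrix (typically TS), balancing the
   contribution of the three modalities. Zeros (absent edges) are
   preserved, not ranked.
2. **Fusion.** The three normalised rows per node are concatenated and
   converted to a row-wise normalised-angle affinity,
   `a(i,j) = 1 − arccos(cos_sim)/π` (identical rows → 1, orthogonal → 0.5,
   antiparallel → 0). Negative cosine similarities are allowed (affinity
   < 0.5) rather than clipped; the arccos map keeps them valid.
3. **Diffusion-map embedding.** With degrees `d_i = Σ_j a_ij`, the
   anisotropic kernel `W = a / (d^α d^α)` (α = 0.5 by default: balanced
   influence of sampling density; the embedding is empirically insensitive
   to α — axes at α ∈ {0, 0.5, 1} correlate > 0.95) is row-normalised to a
   Markov matrix and eigendecomposed through its symmetric conjugate with a
   deterministic dense solver. The trivial constant eigenvector (λ = 1) is
   dropped; coordinates use the diffusion-time-0 convention, scaling
   eigenvector k by `λ_k/(1−λ_k)`, with eigenvectors normalised to unit
   norm under the stationary distribution and a fixed sign convention
   (each column's largest-magnitude entry positive) so runs are
   bit-reproducible. Variance explained is `λ_k / Σλ` over nontrivial
   eigenvalues.
4. **Dimensionality.** The scree elbow is the eigenvalue point with
   maximum perpendicular distance to the line joining the first and last
   scree points; the retained count is that point's 0-based index. A
   degenerate scree (no curvature) retains 1 with a warning. On the
   planted synthetic sheet this selects 2.
5. **Alignment.** Spaces are compared after orthogonal Procrustes
   (rotation + reflection, no scaling) following centring.

## Manifold analytics

**Wiring distance** triangulates the 2-D space (Delaunay) and measures
exact shortest paths over the triangulation edges — a deterministic
stand-in for front propagation on the same graph, identical to a
brute-force graph oracle by construction. Collinear embeddings fall back
to 1-D distances with a warning. **Centrality** is the mean distance of a
node to all others; high values mark distinctive, specialised wiring.

**Axis fans** probe map-to-axis association: 32 intercardinal lines in
5.625° steps through the coordinate centroid, each sampled at 100 equally
spaced points over the coordinate range; nodes take the integer index of
their nearest sample point, Spearman correlations are computed per axis and
Benjamini–Hochberg adjusted over the 32 tests. The anchor point (centroid)
is our choice; positions use the sampled points, not the infinite line.

**Consensus k-means** runs seeded k-means 100 times per candidate k
(default 10–20), accumulates a co-assignment consensus matrix, cuts
`1 − consensus` by average-linkage at each k, and scores stability as mean
within-cluster minus mean between-cluster consensus; the chosen k maximises
stability. The stability formula is our choice where the methodology
delegates to a citation.

## Microscale association

**Externopyramidisation** per node is
`rescale01(max/mean intensity) × rescale01(1 − supra/total thickness)`;
both quotients are rescaled independently across nodes, a degenerate
(constant) quotient rescales to 0. Higher values mean sharper, shallower
peak layers — a feedforward-dominated laminar profile. **Cell-type maps**
average log2 expression over marker gene sets (set semantics, missing genes
logged, empty intersections are errors); co-expression similarity is the
inverse Euclidean distance with a machine-scale ε guard for identical
regions.

**Spatial association** regresses a node map on (E1, E2) by OLS and reports
the multiple correlation R with a permutation p-value,
`p = (1 + #{R_null ≥ R_obs}) / (1 + n_surrogates)`, against one of two
spatial-autocorrelation-preserving nulls:

* *Spin*: a uniformly random 3-D rotation of the node coordinate cloud,
  mapped back to nodes one-to-one by Hungarian assignment — an exact
  permutation, so the value multiset is preserved exactly.
* *Moran spectral randomisation*: sign-randomisation of the map's
  coefficients in the Moran eigenvector basis of the double-centred weight
  matrix (inverse-GD by default), which preserves the map's variance and
  Moran's I exactly.

Both yield uniform p-values on isotropic noise (checked by KS test in the
acceptance suite).

## Predicting functional connectivity

For each seed node, the z-scored FC row is predicted from three
z-standardised features per target: wiring distance and the signed
differences along E1 and E2 (signed, because the electrophysiological mixed
model uses the same quantities additively). The learner is AdaBoost.R2
over depth-4 regression trees; the number of estimators (6, 8, …, 20) and
learning rate (0.01, 0.05, 0.1, 0.3, 1) are selected by 5-fold
cross-validation (contiguous random partitions under the run seed) and the
winner refit on all targets. Because boosting is sequential, the CV grid
over estimator counts is evaluated exactly from staged predictions of a
single largest fit per fold and rate. Accuracy is reported as MSE and R²;
held-out evaluation fits on one FC matrix and scores against another.

## Directed coherence

Welch auto- and cross-spectra use 2-s Hamming windows advanced in 1-s
steps (an optional white-matter average reference is subtracted upstream);
coherency is `C_xy = P_xy/√(P_xx P_yy)` and msc its squared magnitude. The
cross-spectrum convention is `S_xy = E[X conj(Y)]`, so a signal that leads
another produces a positive phase slope. The frequency grid follows from
the window and an explicit `nfft`, making the grid reproducible. The phase
slope index per band is `Ψ_xy = Im Σ_{f∈F} conj(C_xy(f))·C_xy(f+δf)`,
unstandardised (no jackknife normaliser), over sliding 4-Hz bands with 2-Hz
overlap from 1–100 Hz; bands overlapping 55–65 Hz (power-line range) are
dropped entirely rather than truncated. Ψ is exactly antisymmetric because
`C_yx = conj(C_xy)`; complex coherency (not msc) is required or the
imaginary part would vanish.

Channel-pair Ψ values are modelled per band as
`Ψ ~ 0 + EdgeType + wd + ΔE1 + ΔE2` with random intercepts for subject,
seed channel and target channel — crossed effects expressed as variance
components within a single encompassing group (REML). Components estimated
at the zero boundary (< 1e-7) are dropped and the model refit; with all
components at zero the fit reduces exactly to OLS, which is also the
fallback for singular fits and the single-subject case. p-values use the
t-distribution with residual degrees of freedom. Cluster similarity
correlates the per-cluster in/out t-profiles across bands after removing
the two clusters' direct entries; the first principal component gives a
loading per cluster. Lasso profiling regresses that loading on
standardised microscale predictors over a shared λ path, with
leave-one-observation-out refits for coefficient spread and a post-hoc OLS
(adjusted R²) on the sparsest nonempty support. Hierarchy placement
thresholds the signed t-matrix at p < 0.05: level 1 holds pure drivers
(significant outgoing, no incoming), each next level holds clusters whose
significant inputs are all placed; the network is hierarchical iff all
clusters place and every edge runs strictly downward. Non-hierarchy is a
result (offending edges listed), not an error.

## Synthetic fixtures: what they emulate, and what they do not

`make_planted_dataset` builds a gently domed rectangular patch mesh
(aspect ≈ 4:3, k-means parcellation, ~6 vertices per parcel) with planted
2-D latent coordinates (the flat parcel-centroid frame, rescaled to
[0, 1]²). GD is the true mesh geodesic; MPC comes from synthetic laminar
profiles whose Gaussian peak depth drifts linearly with latent axis 2
(bump width 0.25 in depth units — wide enough that the profile-similarity
kernel is broad and the planted sheet carries exactly two dominant
diffusion modes; profile noise sd 0.1 of the unit bump amplitude); TS is a
sparse graph whose connection probability decays exponentially in latent
distance, with the length scale calibrated by bisection to hit the
requested density (default 15%) and lognormal weight scatter (sd 0.25).

`make_profiles` generates unimodal Gaussian depth bumps on a unit
baseline. `make_recordings` propagates band-limited (default 20–30 Hz)
unit-variance sources along a directed acyclic cluster graph with known
millisecond lags and unit coupling, adds channel noise at a given SNR
(default 2), and varies subjects by seed and per-channel gains.
`make_fc` produces `exp(−wd/τ) + N(0, σ)` (τ defaults to half the mean
off-diagonal wiring distance; σ defaults to 0.2), row-z-scored and
symmetrised; `expected_holdout_r2` gives the closed-form signal-to-noise
ceiling on held-out R² that any learner can at best approach.

These fixtures plant the *structure* the pipeline must recover; they do
not emulate tractography biases, partial-volume or registration error,
inhomogeneous parcel sizes across lobes, volume conduction beyond a common
reference, or 1/f spectra. Passing tests therefore demonstrate the
correctness and statistical calibration of the machinery, not performance
on empirical neuroimaging data.

## Problem sizes and numerical choices

The test and acceptance runs use 300-node planted datasets (the package's
reference size, solved densely in under a second), 10-subject / 60-s /
512-Hz recordings for the directionality stack, 5-subject simulated Ψ
tables for mixed-model calibration (100 seeds), 1,000 surrogates per null
with ~100–150 repetitions for KS uniformity, and seed-node subsamples
(25–100 of 300) for the boosted FC evaluations; subsampling seeds is
unbiased for the mean per-node metrics. Dense eigensolves are used up to a
few thousand nodes; all stochastic steps take explicit seeds and all
reported runs are bit-reproducible under a fixed seed. Degenerate inputs
follow documented conventions: constant min–max rescales map to 0,
zero-MAD parcels keep all vertices, collinear embeddings fall back to 1-D,
empty consensus bins reduce the bin count with a warning.

## Known limitations

* Surface mode only for GD; no volumetric (grey/white-matter propagation)
  variant, and the homologue map for mirroring must be supplied.
* The cross-hemisphere mirroring rule is a symmetric average of the two
  homologous distances; other conventions exist.
* Mixed-model inference uses residual-df t-statistics, not Satterthwaite
  or Kenward–Roger corrections; with few subjects its p-values are
  approximate (the calibration test bounds the practical error).
* `similarity_pca` concatenates both in- and out-profiles per cluster;
  vectorising only one direction would give slightly different loadings.
* The boosted FC model shares its random seed across nodes; node-level
  fits are independent and embarrassingly parallel but run serially here.
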