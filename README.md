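# wirespace

A toolkit for building and interrogating a **multi-scale cortical wiring
space**: a compact coordinate system of the cortex derived from three
complementary structural features rather than tractography alone.

Systems neuroscientists studying how cortical structure constrains function
face a gap between diffusion tractography (which misses the short
cortico-cortical fibres that make up most connections) and postmortem
descriptions of microstructure. `wirespace` closes that gap in software: it
constructs three node-by-node wiring features —

* **GD**, geodesic distance between region exemplars along the cortical
  mid-thickness mesh (spatial proximity),
* **MPC**, microstructure profile covariance — the partial correlation of
  depth-wise intracortical intensity profiles between regions, controlling
  for the cortex-mean profile (architectonic similarity),
* **TS**, group-consensus tractography strength via distance-dependent
  consensus thresholding,

— rank-normalises and fuses them into a normalised-angle affinity matrix,
and embeds that with **diffusion maps** (anisotropic kernel, α = 0.5;
coordinates scaled by λ/(1−λ)). The two dominant eigenvectors (E1, E2) span
the *wiring space*; distances within it (wd, over a Delaunay triangulation)
and signed axis differences (ΔE1, ΔE2) drive the downstream analytics:

* manifold centrality and 32-axis intercardinal fans with BH-FDR,
* cytoarchitectural association (externopyramidisation =
  rescaled max/mean intensity × rescaled relative supragranular thinness),
  cell-type expression maps, and spin / Moran spectral-randomisation
  spatial nulls,
* per-node AdaBoost regression-tree prediction of functional connectivity
  from (wd, ΔE1, ΔE2) with the 5-fold CV hyperparameter grid,
* a directed-coherence stack: Welch cross-spectra → complex coherency →
  phase slope index per sliding 4-Hz band (55–65 Hz excluded) → linear
  mixed model of cluster-pair effects (`Ψ ~ EdgeType + wd + ΔE1 + ΔE2` with
  subject/channel random intercepts) → hierarchy placement,
* consensus k-means discretisation of the space with stability-based
  choice of k,
* a first-class synthetic-data module that plants ground truth (latent 2-D
  coordinates, laminar peak depths, directed lags, FC signal-to-noise) so
  the entire pipeline is testable end-to-end without any imaging data.

## Worked example

```python
import numpy as np
import wirespace as ws

# a planted dataset: patch mesh, latent 2-D coordinates, GD/MPC/TS triplet
ds = ws.make_planted_dataset(n_nodes=300, noise_sd=0.1, ts_density=0.15, seed=11)

# fuse and embed; scree test retains the dimensionality
space = ws.build_wiring_space(ds.gd, ds.mpc, ds.ts, alpha=0.5,
                              n_components="auto", seed=11)
print(space.n_components)                      # 2
print(space.variance_explained.round(3))       # [0.276 0.133]

# the embedding recovers the planted coordinates up to rotation
from wirespace.manifold import WiringSpace, align_procrustes
template = WiringSpace(ds.latent, np.array([.5, .4]), np.array([.3, .2]),
                       0.5, space.node_ids)
aligned = align_procrustes(space, template)
for k in range(2):
    r = np.corrcoef(aligned.coordinates[:, k], ds.latent[:, k])[0, 1]
    print(f"axis {k + 1}: r = {abs(r):.3f}")   # axis 1: r = 0.964
                                               # axis 2: r = 0.966
```

The printed numbers mean: the scree elbow keeps exactly the two planted
dimensions, they carry ~41% of the wiring-affinity variance, and after
Procrustes alignment each embedding axis correlates with its planted latent
axis at |r| ≈ 0.96 despite 10% feature noise.

The same pipeline is scriptable from the shell:

```bash
wirespace synth --nodes 300 --seed 11 --out data/
wirespace embed --features data/gd.csv,data/mpc.csv,data/ts.csv \
    --alpha 0.5 --dims auto --out data/space.csv
wirespace distances --space data/space.csv --out data/dist/
wirespace run --config pipeline.yaml    # full pipeline + JSON manifest
```

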