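"""Construction of the three cortical wiring feature matrices.

The wiring model rests on three node-by-node features:

* **GD** — geodesic distance between region exemplars along the cortical
  mid-thickness mesh (spatial proximity, a proxy for short cortico-cortical
  fibres).
* **MPC** — microstructure profile covariance: partial correlation of
  depth-wise intracortical intensity profiles between regions, controlling
  for the cortex-mean profile (architectonic similarity).
* **TS** — tractography strength: a group-consensus streamline-weight
  matrix obtained by distance-dependent consensus thresholding of
  per-subject connectomes.

All three are represented as :class:`FeatureMatrix` objects with an explicit
"absent edge" sentinel (0), a symmetric value matrix, and a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "SurfaceMesh",
    "IntensityProfileSet",
    "FeatureMatrix",
    "SubjectConnectome",
    "equivolumetric_fractions",
    "build_profiles",
    "compute_mpc",
    "geodesic_matrix",
    "consensus_ts",
]

MAD_SCALE = 1.4826  # consistency constant for a normal distribution


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated cortical surface with a per-vertex parcellation.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Coordinates in mm.
    faces : (n_faces, 3) int array
        Triangles as vertex index triplets.
    parcel_labels : (n_vertices,) int array
        Per-vertex parcel id; 0 means unassigned.
    vertex_data : dict of str -> array
        Optional per-vertex scalar layers (e.g. a (n_vertices, n_depths)
        intensity array under the key ``"intensity"``).
    """

    vertices: np.ndarray
    faces: np.ndarray
    parcel_labels: np.ndarray
    vertex_data: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.parcel_labels = np.asarray(self.parcel_labels, dtype=int)
        if not np.isfinite(self.vertices).all():
            raise ValueError("mesh vertices contain non-finite coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("faces reference invalid vertex indices")
        if self.parcel_labels.shape != (len(self.vertices),):
            raise ValueError("parcel_labels must be one label per vertex")

    @property
    def parcel_ids(self) -> np.ndarray:
        """Sorted ids of non-empty parcels (0 = unassigned is excluded)."""
        ids = np.unique(self.parcel_labels)
        return ids[ids != 0]

    def edge_graph(self) -> sparse.csr_matrix:
        """Sparse symmetric graph of mesh edges weighted by Euclidean length."""
        f = self.faces
        ii = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        jj = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        w = np.linalg.norm(self.vertices[ii] - self.vertices[jj], axis=1)
        n = len(self.vertices)
        g = sparse.coo_matrix((w, (ii, jj)), shape=(n, n)).tocsr()
        g = g.maximum(g.T)
        return g

    def parcel_centroids(self) -> np.ndarray:
        """Arithmetic mean of vertex coordinates per parcel (parcel-id order)."""
        return np.vstack([
            self.vertices[self.parcel_labels == pid].mean(axis=0)
            for pid in self.parcel_ids
        ])


@dataclass
class IntensityProfileSet:
    """Node-by-depth intracortical intensity profiles."""

    profiles: np.ndarray            # (n_nodes, n_depths)
    depth_fractions: np.ndarray     # (n_depths,), 0 = outer boundary
    node_ids: np.ndarray
    band_labels: np.ndarray | None = None  # per-depth "supragranular"/"infragranular"

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        self.depth_fractions = np.asarray(self.depth_fractions, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if np.any(np.diff(self.depth_fractions) <= 0):
            raise ValueError("depth_fractions must be strictly increasing")
        if self.profiles.shape != (len(self.node_ids), len(self.depth_fractions)):
            raise ValueError("profiles shape must be (n_nodes, n_depths)")


@dataclass
class FeatureMatrix:
    """Symmetric node-by-node wiring feature with an absent-edge sentinel."""

    values: np.ndarray
    modality: str                   # "GD" | "MPC" | "TS"
    node_ids: np.ndarray
    sparsity_value: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match node_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError(f"{self.modality} matrix is not symmetric")
        if self.modality in ("GD", "TS") and np.any(self.values < -1e-12):
            raise ValueError(f"{self.modality} entries must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def nonzero_mask(self) -> np.ndarray:
        return self.values != self.sparsity_value


@dataclass
class SubjectConnectome:
    """Per-subject non-negative streamline-weight matrix."""

    values: np.ndarray
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("subject connectome must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("subject connectome weights must be non-negative")
        np.fill_diagonal(self.values, 0.0)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def equivolumetric_fractions(area_outer: float, area_inner: float,
                             n_surfaces: int) -> np.ndarray:
    """Depth fractions of surfaces bounding equal tissue volume.

    Under a linear-frustum model the cross-sectional area at relative
    position ``x`` in [0, 1] varies as ``((1-x)*sqrt(area_inner) +
    x*sqrt(area_outer))**2``, so cumulative volume is a cubic in ``x`` and
    the equal-volume positions have a closed-form inverse.

    Returns ``n_surfaces`` strictly increasing fractions in [0, 1] with the
    endpoints included.  When the two areas are equal the fractions are
    equidistant.
    """
    if area_outer <= 0 or area_inner <= 0:
        raise ValueError("surface areas must be positive")
    if n_surfaces < 2:
        raise ValueError("need at least 2 surfaces")
    a = np.sqrt(area_inner)
    b = np.sqrt(area_outer)
    k = np.arange(n_surfaces) / (n_surfaces - 1)
    if np.isclose(a, b):
        return k
    # V(x) = (c(x)^3 - a^3) / (3(b-a)), c(x) = a + (b-a)x; solve V(x_k) = k*V(1)
    c = np.cbrt(a ** 3 + k * (b ** 3 - a ** 3))
    return (c - a) / (b - a)


def _median_profiles_mask(intensity: np.ndarray) -> np.ndarray:
    """Vertices to keep under the 3-scaled-MAD outlier rule."""
    med_per_vertex = np.median(intensity, axis=1)
    centre = np.median(med_per_vertex)
    mad = MAD_SCALE * np.median(np.abs(med_per_vertex - centre))
    if mad == 0:
        return np.ones(len(med_per_vertex), dtype=bool)
    return np.abs(med_per_vertex - centre) <= 3 * mad


def build_profiles(mesh: SurfaceMesh, depth_fractions=None,
                   intensity_key: str = "intensity") -> IntensityProfileSet:
    """Average vertex intensity profiles into node profiles.

    Within each parcel, vertices whose across-depth median intensity lies
    more than 3 scaled median absolute deviations (scale 1.4826) from the
    parcel median are excluded; the remaining vertices are averaged per
    depth.  A zero MAD (constant parcel) excludes nothing.
    """
    intensity = np.asarray(mesh.vertex_data[intensity_key], dtype=float)
    if intensity.ndim != 2 or intensity.shape[1] < 2:
        raise ValueError("mesh must carry at least 2 intensity depth layers")
    if depth_fractions is None:
        depth_fractions = np.linspace(0, 1, intensity.shape[1])
    node_ids = mesh.parcel_ids
    profiles = np.empty((len(node_ids), intensity.shape[1]))
    for i, pid in enumerate(node_ids):
        vi = intensity[mesh.parcel_labels == pid]
        if len(vi) == 0:
            raise ValueError(f"parcel {pid} has no vertices")
        keep = _median_profiles_mask(vi)
        if not keep.any():
            raise ValueError(f"parcel {pid} lost all vertices to the outlier filter")
        profiles[i] = vi[keep].mean(axis=0)
    return IntensityProfileSet(profiles, np.asarray(depth_fractions), node_ids)


def compute_mpc(profiles: IntensityProfileSet,
                log_transform: bool = True) -> FeatureMatrix:
    """Microstructure profile covariance matrix.

    Pairwise partial Pearson correlation of node profiles controlling for the
    across-node mean profile::

        r_ij.c = (r_ij - r_ic * r_jc) / sqrt((1 - r_ic^2)(1 - r_jc^2))

    Entries <= 0 are set to the sparsity sentinel; positive entries are
    natural-log transformed (rank order preserved, which is all the
    downstream rank-based fusion consumes).  Diagonal set to the sentinel.
    """
    x = profiles.profiles
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = profiles.node_ids[sd == 0]
        raise ValueError(f"zero-variance profile for node(s) {bad.tolist()}")
    mean_profile = x.mean(axis=0)
    stack = np.vstack([x, mean_profile])
    r = np.corrcoef(stack)
    r_ij = r[:n, :n]
    r_c = r[:n, n]
    if np.any(np.abs(r_c) >= 1 - 1e-12):
        bad = profiles.node_ids[np.abs(r_c) >= 1 - 1e-12]
        raise ValueError(
            f"profile identical (up to sign) to the mean profile for node(s) "
            f"{bad.tolist()}: partial correlation is degenerate")
    denom = np.sqrt(np.outer(1 - r_c ** 2, 1 - r_c ** 2))
    partial = (r_ij - np.outer(r_c, r_c)) / denom
    vals = np.where(partial > 0, partial, 0.0)
    if log_transform:
        pos = vals > 0
        vals[pos] = np.log(vals[pos])
        # log(r)=0 at r==1 would collide with the sentinel; nudge inside
        vals[pos & (vals == 0)] = -1e-300
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2
    return FeatureMatrix(vals, "MPC", profiles.node_ids)


def geodesic_matrix(mesh: SurfaceMesh, mirror: bool = False,
                    hemispheres: np.ndarray | None = None,
                    homologues: dict | None = None) -> FeatureMatrix:
    """Geodesic distance between parcel exemplars along mesh edges.

    The exemplar of a parcel is the vertex minimising Euclidean distance to
    the parcel's vertex centroid (ties broken by lowest vertex index).
    GD(i, j) is the shortest-path distance between exemplars over the mesh
    edge graph with Euclidean edge lengths (Dijkstra).

    When ``mirror`` is set, unreachable cross-hemisphere entries are filled
    by mirroring homologous within-hemisphere distances:
    ``GD(i, j) = (GD(h(i), j) + GD(i, h(j))) / 2`` where ``h`` maps each
    parcel to its homologue in the other hemisphere (``homologues``), and
    ``hemispheres`` gives a per-parcel hemisphere id.
    """
    node_ids = mesh.parcel_ids
    centroids = mesh.parcel_centroids()
    exemplars = np.empty(len(node_ids), dtype=int)
    for i, pid in enumerate(node_ids):
        vids = np.flatnonzero(mesh.parcel_labels == pid)
        d = np.linalg.norm(mesh.vertices[vids] - centroids[i], axis=1)
        exemplars[i] = vids[np.argmin(d)]  # argmin takes the lowest index on ties
    graph = mesh.edge_graph()
    dist = dijkstra(graph, directed=False, indices=exemplars)[:, exemplars]
    dist = (dist + dist.T) / 2
    if np.isinf(dist).any():
        if not mirror:
            bad = node_ids[np.isinf(dist).any(axis=1)]
            raise ValueError(
                f"unreachable exemplars for node(s) {bad.tolist()}; "
                "mesh is disconnected (set mirror=True with homologues to fill)")
        if hemispheres is None or homologues is None:
            raise ValueError("mirror=True requires hemispheres and homologues")
        idx = {pid: i for i, pid in enumerate(node_ids)}
        for i, pi in enumerate(node_ids):
            for j, pj in enumerate(node_ids):
                if np.isinf(dist[i, j]):
                    d1 = dist[idx[homologues[pi]], j]
                    d2 = dist[i, idx[homologues[pj]]]
                    dist[i, j] = (d1 + d2) / 2
        if np.isinf(dist).any():
            raise ValueError("mirroring left unreachable node pairs")
    np.fill_diagonal(dist, 0.0)
    return FeatureMatrix(dist, "GD", node_ids)


def consensus_ts(subject_connectomes: list[SubjectConnectome],
                 gd: FeatureMatrix, n_bins: int = 10) -> FeatureMatrix:
    """Distance-dependent consensus thresholding of subject connectomes.

    Edges (pairs with a nonzero weight in at least one subject) are pooled
    into ``n_bins`` equal-count geodesic-distance bins, where each
    subject-edge occurrence contributes one sample so the pooled edge length
    distribution is preserved.  Per bin, the K most consistent edges are
    retained, K = round(mean per-subject edge count in the bin); consistency
    is the fraction of subjects with a nonzero weight, ties broken by higher
    mean nonzero weight.  Retained edge weight = mean of nonzero subject
    weights.
    """
    if len(subject_connectomes) < 2:
        raise ValueError("need at least 2 subjects")
    n = gd.n_nodes
    stack = np.stack([s.values for s in subject_connectomes])
    if stack.shape[1:] != (n, n):
        raise ValueError("subject connectomes do not match the GD matrix")
    iu = np.triu_indices(n, k=1)
    w = stack[:, iu[0], iu[1]]                      # (n_subj, n_pairs)
    present = w > 0
    any_present = present.any(axis=0)
    consistency = present.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_w = np.where(any_present, w.sum(axis=0) / np.maximum(present.sum(axis=0), 1), 0.0)
    d = gd.values[iu]

    # pooled (subject-weighted) edge length distribution defines the bins
    pooled = np.repeat(d, present.sum(axis=0))
    while n_bins > 1:
        edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
        if len(np.unique(edges)) == n_bins + 1:
            break
        warnings.warn(f"empty/degenerate bin at n_bins={n_bins}; reducing")
        n_bins -= 1
    if n_bins == 1:
        edges = np.array([pooled.min(), pooled.max()])
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = np.digitize(d, edges[1:-1])

    keep = np.zeros(len(d), dtype=bool)
    out_w = np.zeros(len(d))
    for b in range(n_bins):
        cand = np.flatnonzero((bin_of == b) & any_present)
        if len(cand) == 0:
            continue
        k_bin = int(round(present[:, bin_of == b].sum(axis=1).mean()))
        k_bin = min(k_bin, len(cand))
        order = np.lexsort((-mean_w[cand], -consistency[cand]))
        sel = cand[order[:k_bin]]
        keep[sel] = True
        out_w[sel] = mean_w[sel]
    vals = np.zeros((n, n))
    vals[iu[0][keep], iu[1][keep]] = out_w[keep]
    vals = vals + vals.T
    return FeatureMatrix(vals, "TS", gd.node_ids)
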