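"""Analytics within the wiring space.

Distances between nodes in the embedded space ("wiring distance"), nodal
centrality, intercardinal axis fans for map-to-axis association, community
assignment from vertex overlays, and consensus k-means discretisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import Delaunay, QhullError
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from statsmodels.stats.multitest import multipletests

from .manifold import WiringSpace

logger = logging.getLogger(__name__)

__all__ = [
    "WiringDistanceMatrix",
    "AxisFan",
    "wiring_distance",
    "centrality",
    "axis_fan",
    "assign_communities",
    "ConsensusKMeans",
    "consensus_kmeans",
]

AXIS_STEP_DEG = 5.625
N_AXES = 32
N_AXIS_SAMPLES = 100


@dataclass
class WiringDistanceMatrix:
    """Manifold geodesic distances plus per-axis signed differences.

    ``values[i, j]`` is the shortest-path distance between nodes i and j
    over the Delaunay triangulation of the 2-D embedding; ``delta_e[k]``
    holds the antisymmetric differences ``E_k(i) - E_k(j)``.
    """

    values: np.ndarray              # (n, n) wiring distances
    delta_e: np.ndarray             # (d, n, n) signed eigenvector differences
    node_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.delta_e = np.asarray(self.delta_e, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("wiring distance must be symmetric")
        if np.any(self.values < 0) or np.any(np.diag(self.values) != 0):
            raise ValueError("wiring distance must be non-negative with zero diagonal")
        if not np.allclose(self.delta_e, -np.transpose(self.delta_e, (0, 2, 1)),
                           atol=1e-9):
            raise ValueError("delta_e must be antisymmetric")


@dataclass
class AxisFan:
    """Intercardinal axis fan: node positions and per-axis correlations."""

    angles: np.ndarray              # (32,) degrees in [0, 174.375]
    node_positions: np.ndarray      # (n_nodes, 32) integers in [1, 100]
    correlations: np.ndarray        # (32,) Spearman rho with the feature
    p_values: np.ndarray            # (32,) raw p-values
    q_values: np.ndarray            # (32,) BH-FDR adjusted

    @property
    def dominant_axis(self) -> int:
        return int(np.argmax(np.abs(self.correlations)))


def wiring_distance(space: WiringSpace) -> WiringDistanceMatrix:
    """Geodesic distances over the Delaunay triangulation of (E1, E2).

    The 2-D wiring space is triangulated and distances are exact shortest
    paths over the triangulation edges weighted by Euclidean length (a
    deterministic stand-in for front-propagation distance on the same
    graph).  Collinear embeddings fall back to 1-D path distances along the
    first axis with a warning.
    """
    coords = space.coordinates
    if coords.shape[1] < 2:
        coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
    else:
        coords = coords[:, :2]
    n = len(coords)
    try:
        tri = Delaunay(coords)
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                e = (simplex[a], simplex[(a + 1) % 3])
                edges.add((min(e), max(e)))
        ii, jj = np.array(sorted(edges)).T
        w = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        g = sparse.coo_matrix((w, (ii, jj)), shape=(n, n))
        wd = dijkstra(g, directed=False)
    except QhullError:
        warnings.warn("collinear embedding; falling back to 1-D path distances")
        wd = np.abs(coords[:, 0][:, None] - coords[:, 0][None, :])
    wd = (wd + wd.T) / 2
    d = space.coordinates.shape[1]
    delta = np.stack([space.coordinates[:, k][:, None] -
                      space.coordinates[:, k][None, :] for k in range(d)])
    return WiringDistanceMatrix(wd, delta, space.node_ids)


def centrality(wd: WiringDistanceMatrix) -> np.ndarray:
    """Mean wiring distance of each node to all others (diagonal excluded).

    Higher values mark nodes with more distinctive, specialised wiring;
    low values mark integrative zones close to everything.
    """
    n = wd.values.shape[0]
    return wd.values.sum(axis=1) / (n - 1)


def axis_fan(space: WiringSpace, feature: np.ndarray) -> AxisFan:
    """Correlate a per-node map with 32 intercardinal axes of the space.

    Lines at angles k*5.625 deg (k = 0..31) through the coordinate centroid
    are each sampled at 100 equally spaced points spanning the coordinate
    range; every node is assigned the (1-based) index of its nearest sample
    point per axis.  Spearman correlation of the feature with the position
    is computed per axis and Benjamini-Hochberg adjusted across the 32
    tests.  The dominant axis is the one with maximum |rho|.
    """
    feature = np.asarray(feature, dtype=float)
    if np.all(feature == feature[0]):
        raise ValueError("constant feature map: correlation undefined")
    coords = space.coordinates[:, :2]
    if len(feature) != len(coords):
        raise ValueError("feature must cover all nodes")
    centroid = coords.mean(axis=0)
    rel = coords - centroid
    angles = np.arange(N_AXES) * AXIS_STEP_DEG
    positions = np.empty((len(coords), N_AXES), dtype=int)
    rhos = np.empty(N_AXES)
    pvals = np.empty(N_AXES)
    for k, ang in enumerate(angles):
        u = np.array([np.cos(np.deg2rad(ang)), np.sin(np.deg2rad(ang))])
        proj = rel @ u
        t = np.linspace(proj.min(), proj.max(), N_AXIS_SAMPLES)
        pts = t[:, None] * u[None, :]           # sample points relative to centroid
        d2 = ((rel[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        positions[:, k] = np.argmin(d2, axis=1) + 1
        rhos[k], pvals[k] = spearmanr(feature, positions[:, k])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return AxisFan(angles, positions, rhos, pvals, qvals)


def assign_communities(parcel_labels: np.ndarray,
                       community_map: np.ndarray) -> dict:
    """Modal community per parcel from a per-vertex community overlay.

    Ties are broken by the lowest community id (logged).
    """
    parcel_labels = np.asarray(parcel_labels)
    community_map = np.asarray(community_map)
    out = {}
    for pid in np.unique(parcel_labels):
        if pid == 0:
            continue
        comms = community_map[parcel_labels == pid]
        vals, counts = np.unique(comms, return_counts=True)
        winners = vals[counts == counts.max()]
        if len(winners) > 1:
            logger.info("parcel %s: community tie %s broken by lowest id",
                        pid, winners.tolist())
        out[pid] = winners.min()
    return out


class ConsensusKMeans(BaseEstimator, ClusterMixin):
    """Consensus-based k-means with stability-driven choice of k.

    For each candidate k, k-means is run ``n_reps`` times from seeded random
    initialisations and the consensus matrix (co-assignment fraction over
    runs) is accumulated.  Final labels at each k come from an
    average-linkage agglomerative cut of ``1 - consensus``; the stability of
    k is the mean within-cluster consensus minus the mean between-cluster
    consensus under those labels.  The chosen k maximises stability.

    Attributes
    ----------
    k_ : chosen number of clusters
    labels_ : (n_nodes,) final labels, ids in 1..k
    consensus_ : (n, n) co-assignment fractions at the chosen k
    stability_ : dict of candidate k -> stability score
    """

    def __init__(self, k_range=range(10, 21), n_reps: int = 100,
                 random_state: int = 0):
        self.k_range = k_range
        self.n_reps = n_reps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = X.coordinates if isinstance(X, WiringSpace) else np.asarray(X, dtype=float)
        n = len(X)
        ks = list(self.k_range)
        if max(ks) > n:
            raise ValueError("k_range exceeds the number of nodes")
        rng = np.random.default_rng(self.random_state)
        stability, results = {}, {}
        for k in ks:
            consensus = np.zeros((n, n))
            for _ in range(self.n_reps):
                seed = int(rng.integers(0, 2 ** 31 - 1))
                lab = KMeans(n_clusters=k, n_init=1, random_state=seed).fit_predict(X)
                consensus += lab[:, None] == lab[None, :]
            consensus /= self.n_reps
            final = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage="average"
            ).fit_predict(1.0 - consensus)
            same = final[:, None] == final[None, :]
            off = ~np.eye(n, dtype=bool)
            within = consensus[same & off]
            between = consensus[~same]
            stability[k] = within.mean() - (between.mean() if between.size else 0.0)
            results[k] = (consensus, final + 1)
        self.stability_ = stability
        self.k_ = max(ks, key=lambda k: stability[k])
        self.consensus_, self.labels_ = results[self.k_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_kmeans(space: WiringSpace, k_range=range(10, 21),
                     reps: int = 100, seed: int = 0) -> ConsensusKMeans:
    """Functional wrapper over :class:`ConsensusKMeans`."""
    return ConsensusKMeans(k_range=k_range, n_reps=reps, random_state=seed).fit(space)
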