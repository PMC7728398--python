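"""Cytoarchitectural and transcriptomic association analytics.

Links the wiring space to microscale substrates: an externopyramidisation
score from laminar staining profiles, cell-type-specific expression maps
averaged over marker gene sets, interregional co-expression similarity, and
multiple-regression association with spatial-autocorrelation-preserving
null models (spin test, Moran spectral randomisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist
from scipy.stats import special_ortho_group

from .features import IntensityProfileSet
from .manifold import WiringSpace

logger = logging.getLogger(__name__)

__all__ = [
    "CellTypeExpression",
    "SpatialNullSpec",
    "externopyramidisation",
    "celltype_maps",
    "coexpression_similarity",
    "spatial_association",
    "spin_surrogates",
    "moran_surrogates",
]

CANONICAL_CELL_TYPES = (
    "astrocyte", "endothelial", "microglia", "inhibitory neuron",
    "excitatory neuron", "oligodendrocyte", "OPC", "pericyte",
)


@dataclass
class CellTypeExpression:
    """Node-by-cell-type mean log2 expression plus the defining gene sets."""

    values: pd.DataFrame            # nodes x cell types
    gene_sets: dict = field(default_factory=dict)


@dataclass
class SpatialNullSpec:
    """Specification of a spatial null model.

    ``method="spin"`` needs per-node ``sphere_coords`` (3-D positions used
    for the random-rotation permutations); ``method="moran"`` needs a
    symmetric spatial ``weight_matrix`` (e.g. inverse geodesic distance).
    """

    method: str                     # "spin" | "moran"
    n_surrogates: int = 1000
    seed: int = 0
    sphere_coords: np.ndarray | None = None
    weight_matrix: np.ndarray | None = None

    def __post_init__(self):
        if self.method not in ("spin", "moran"):
            raise ValueError("method must be 'spin' or 'moran'")
        if self.n_surrogates < 100:
            raise ValueError("need at least 100 surrogates")
        if self.method == "spin" and self.sphere_coords is None:
            raise ValueError("spin null requires sphere_coords")
        if self.method == "moran" and self.weight_matrix is None:
            raise ValueError("moran null requires weight_matrix")


def _minmax01(v: np.ndarray) -> np.ndarray:
    rng = v.max() - v.min()
    if rng == 0:
        logger.info("degenerate min-max rescale of a constant vector; mapping to 0")
        return np.zeros_like(v)
    return (v - v.min()) / rng


def externopyramidisation(profiles: IntensityProfileSet,
                          supra_thickness: np.ndarray,
                          total_thickness: np.ndarray) -> np.ndarray:
    """Externopyramidisation score per node.

    Indexes the shift of pyramidal-neuron weight towards superficial layers:
    ``q1 = max(intensity) / mean(intensity)`` (peak sharpness) and
    ``q2 = 1 - supra_thickness / total_thickness`` (relative supragranular
    thinness) are min-max rescaled independently across nodes to [0, 1] and
    multiplied.  Constant quotients rescale to 0.
    """
    supra = np.asarray(supra_thickness, dtype=float)
    total = np.asarray(total_thickness, dtype=float)
    if np.any(total <= 0) or np.any(supra <= 0):
        raise ValueError("thicknesses must be positive")
    if np.any(supra > total):
        raise ValueError("supragranular thickness cannot exceed total")
    x = profiles.profiles
    means = x.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("zero mean intensity profile")
    q1 = x.max(axis=1) / means
    q2 = 1.0 - supra / total
    return _minmax01(q1) * _minmax01(q2)


def celltype_maps(expression: pd.DataFrame, gene_sets: dict) -> CellTypeExpression:
    """Mean log2 expression per cell type and node.

    ``expression`` is a gene-by-node table; each cell type's map is the mean
    over its marker genes present in the table (duplicates counted once,
    missing genes logged).
    """
    maps = {}
    for cell_type, genes in gene_sets.items():
        genes = sorted(set(genes))
        present = [g for g in genes if g in expression.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.info("cell type %s: %d gene(s) missing from the table: %s",
                        cell_type, len(missing), missing)
        if not present:
            raise ValueError(f"no genes of cell type '{cell_type}' found in "
                             "the expression table")
        maps[cell_type] = expression.loc[present].mean(axis=0)
    values = pd.DataFrame(maps)
    return CellTypeExpression(values, {k: sorted(set(v)) for k, v in gene_sets.items()})


def coexpression_similarity(celltypes: CellTypeExpression,
                            eps: float = 1e-12) -> np.ndarray:
    """Inverse Euclidean distance between node cell-type expression vectors.

    ``similarity(i, j) = 1 / (eps + ||v_i - v_j||)``; the machine-scale
    guard keeps identical regions finite.  The diagonal is excluded from
    downstream analyses by convention.
    """
    x = celltypes.values.to_numpy()
    d = squareform(pdist(x))
    return 1.0 / (eps + d)


# ---------------------------------------------------------------------------
# spatial null models
# ---------------------------------------------------------------------------

def spin_surrogates(coords: np.ndarray, n_surrogates: int,
                    seed: int) -> np.ndarray:
    """Spatial-rotation permutations of node positions.

    Each surrogate applies a uniformly random 3-D rotation to the node
    coordinate cloud and matches rotated positions back to original nodes
    one-to-one (Hungarian assignment on Euclidean distance), yielding an
    exact permutation that preserves the value multiset while respecting
    spatial contiguity.
    Returns an (n_surrogates, n_nodes) array of permutation indices.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_surrogates, n), dtype=int)
    for s in range(n_surrogates):
        rot = special_ortho_group.rvs(3, random_state=rng)
        rotated = coords @ rot.T
        cost = ((rotated[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        _, perm = linear_sum_assignment(cost)
        perms[s] = perm
    return perms


def moran_surrogates(target: np.ndarray, weight_matrix: np.ndarray,
                     n_surrogates: int, seed: int) -> np.ndarray:
    """Moran spectral randomisation surrogates of a spatial map.

    The target is expanded in the Moran eigenvector basis of the
    double-centred spatial weight matrix; surrogates randomise the signs of
    the spectral coefficients, which preserves the map's variance and its
    Moran's I (spatial autocorrelation) exactly.
    Returns an (n_surrogates, n_nodes) array of surrogate maps.
    """
    w = np.asarray(weight_matrix, dtype=float)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    n = len(w)
    h = np.eye(n) - np.ones((n, n)) / n
    _, vecs = np.linalg.eigh(h @ w @ h)
    y = np.asarray(target, dtype=float)
    mean = y.mean()
    coef = vecs.T @ (y - mean)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_surrogates, n))
    return (signs * coef) @ vecs.T + mean


def _multiple_r(coords: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Multiple correlation of each target column with (E1, E2) via OLS."""
    n = len(coords)
    design = np.column_stack([np.ones(n), coords])
    q, _ = np.linalg.qr(design)
    yc = targets - targets.mean(axis=0)
    ss_tot = (yc ** 2).sum(axis=0)
    proj = q.T @ targets
    fitted_ss = (proj[1:] ** 2).sum(axis=0)  # drop the intercept direction
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = fitted_ss / ss_tot
    return np.sqrt(np.clip(r2, 0.0, 1.0))


def spatial_association(space: WiringSpace, target: np.ndarray,
                        null: SpatialNullSpec) -> dict:
    """Variance in a node map explained by (E1, E2) with a spatial null.

    Fits ``target ~ E1 + E2`` by OLS and reports the multiple correlation R.
    The null distribution recomputes R on surrogate targets (spin rotations
    or Moran spectral randomisation); ``p = (1 + #{R_null >= R_obs}) /
    (1 + n_surrogates)``.
    """
    target = np.asarray(target, dtype=float)
    if np.all(target == target[0]):
        raise ValueError("constant target map")
    coords = space.coordinates[:, :2]
    r_obs = float(_multiple_r(coords, target[:, None])[0])
    if null.method == "spin":
        perms = spin_surrogates(null.sphere_coords, null.n_surrogates, null.seed)
        surrogates = target[perms].T              # (n_nodes, n_surrogates)
    else:
        surrogates = moran_surrogates(target, null.weight_matrix,
                                      null.n_surrogates, null.seed).T
    r_null = _multiple_r(coords, surrogates)
    p = (1.0 + np.sum(r_null >= r_obs)) / (1.0 + null.n_surrogates)
    return {"r": r_obs, "p": float(p), "r_null": r_null}
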