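"""Fusing the wiring features into a low-dimensional wiring space.

The pipeline is: rank-normalise the three feature matrices (inverting GD so
larger means closer, and rescaling every matrix to the numerical range of
the sparsest one), horizontally concatenate them, turn row profiles into a
normalised-angle affinity matrix, and embed with diffusion maps.  The first
two eigenvectors (E1, E2) span the "wiring space".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .features import FeatureMatrix

__all__ = [
    "AffinityMatrix",
    "WiringSpace",
    "rank_normalise_rescale",
    "fuse_affinity",
    "DiffusionMapEmbedding",
    "diffusion_embed",
    "select_dims",
    "align_procrustes",
    "build_wiring_space",
]


@dataclass
class AffinityMatrix:
    """Symmetric node-by-node wiring affinity in [0, 1] with unit diagonal."""

    values: np.ndarray
    node_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("affinity diagonal must be 1")


@dataclass
class WiringSpace:
    """Node coordinates on the retained diffusion eigenvectors.

    ``coordinates[:, 0]`` is E1, ``coordinates[:, 1]`` is E2, columns
    ordered by decreasing eigenvalue.  ``variance_explained`` fractions are
    relative to the sum of all nontrivial eigenvalues.
    """

    coordinates: np.ndarray         # (n_nodes, d)
    eigenvalues: np.ndarray         # (d,)
    variance_explained: np.ndarray  # (d,)
    alpha: float
    node_ids: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        self.node_ids = np.asarray(self.node_ids)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 1:
            raise ValueError("coordinates must be (n_nodes, d) with d >= 1")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be in decreasing order")
        if self.variance_explained.sum() > 1 + 1e-9:
            raise ValueError("variance_explained must sum to <= 1")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def rank_normalise_rescale(matrices: list[FeatureMatrix]) -> list[np.ndarray]:
    """Rank-normalise feature matrices and rescale to a shared range.

    GD entries are negated before ranking so that larger normalised values
    mean closer regions.  Only nonzero (non-sentinel) entries are ranked
    (average ranks on ties); zeros are left untouched.  Each matrix's ranks
    are then min-max rescaled to the [min, max] of the ranked entries of the
    sparsest matrix so the modalities contribute on a balanced numerical
    range.
    """
    masks, ranked = [], []
    for m in matrices:
        mask = m.nonzero_mask()
        if not mask.any():
            raise ValueError(f"matrix {m.modality} has no nonzero entries")
        vals = m.values[mask]
        if m.modality == "GD":
            vals = -vals
        r = rankdata(vals)
        out = np.zeros_like(m.values)
        out[mask] = r
        masks.append(mask)
        ranked.append(out)
    sparsest = int(np.argmin([mask.sum() for mask in masks]))
    lo = ranked[sparsest][masks[sparsest]].min()
    hi = ranked[sparsest][masks[sparsest]].max()
    out_list = []
    for mask, rk in zip(masks, ranked):
        v = rk[mask]
        vmin, vmax = v.min(), v.max()
        if vmax > vmin:
            v = lo + (v - vmin) * (hi - lo) / (vmax - vmin)
        else:
            v = np.full_like(v, (lo + hi) / 2)
        out = np.zeros_like(rk)
        out[mask] = v
        out_list.append(out)
    return out_list


def fuse_affinity(normalised: list[np.ndarray],
                  node_ids=None) -> AffinityMatrix:
    """Normalised-angle affinity of horizontally concatenated feature rows.

    ``affinity(i, j) = 1 - arccos(cos_sim(row_i, row_j)) / pi`` where rows
    are the concatenation of node i's rows across modalities.  Identical
    rows give 1, orthogonal rows 0.5, antiparallel rows 0.  Diagonal forced
    to 1.
    """
    feat = np.hstack(normalised)
    norms = np.linalg.norm(feat, axis=1)
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero feature row for node index(es) {bad.tolist()}; "
                         "angle similarity undefined")
    unit = feat / norms[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = (aff + aff.T) / 2
    np.fill_diagonal(aff, 1.0)
    if node_ids is None:
        node_ids = np.arange(len(aff))
    return AffinityMatrix(aff, node_ids)


class DiffusionMapEmbedding(BaseEstimator, TransformerMixin):
    """Diffusion-map embedding of a symmetric affinity matrix.

    With degrees ``d_i = sum_j a_ij`` the anisotropic kernel is
    ``W_ij = a_ij / (d_i^alpha d_j^alpha)``; row-normalising W gives a
    Markov matrix whose right eigenvectors (the trivial constant one
    dropped) are the embedding axes.  Coordinates use the diffusion-time-0
    convention, scaling eigenvector k by ``lambda_k / (1 - lambda_k)``.

    Parameters
    ----------
    alpha : float, default 0.5
        Density-influence parameter (0 = maximal influence, 1 = none).
    n_components : int, default 10
        Number of nontrivial eigenvectors to retain.
    random_state : int or None
        Unused by the deterministic dense solver; accepted for pipeline
        compatibility.

    Attributes
    ----------
    embedding_ : (n_nodes, n_components) array
    eigenvalues_ : (n_components,) retained nontrivial eigenvalues
    variance_explained_ : eigenvalue fractions over all nontrivial ones
    """

    def __init__(self, alpha: float = 0.5, n_components: int = 10,
                 random_state: int | None = None):
        self.alpha = alpha
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, X, y=None):
        a = X.values if isinstance(X, AffinityMatrix) else np.asarray(X, dtype=float)
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("affinity must be symmetric")
        if a.min() < 0:
            raise ValueError("affinity must be non-negative")
        n = a.shape[0]
        deg = a.sum(axis=1)
        if np.any(deg == 0):
            raise ValueError("affinity graph has isolated nodes")
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(a > 0, directed=False)
        if n_comp > 1:
            raise ValueError("affinity graph is disconnected")
        w = a / np.outer(deg ** self.alpha, deg ** self.alpha)
        d2 = w.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(d2)
        s = w * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of the Markov matrix
        evals, evecs = eigh(s)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if abs(evals[0] - 1.0) > 1e-8:
            raise ValueError("leading eigenvalue differs from 1; affinity graph "
                             "may be disconnected")
        psi = evecs * inv_sqrt[:, None]       # right eigenvectors of the Markov matrix
        psi = psi / psi[:, [0]]               # trivial eigenvector becomes constant 1
        lam = evals[1:]
        nontrivial = lam[lam > 1e-12]
        k = min(self.n_components, len(nontrivial))
        lam_k = lam[:k]
        coords = psi[:, 1:k + 1] * (lam_k / (1 - lam_k))
        # deterministic sign: each column's largest-magnitude entry is positive
        flip = np.sign(coords[np.argmax(np.abs(coords), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        coords = coords * flip
        self.embedding_ = coords
        self.eigenvalues_ = lam_k
        self.variance_explained_ = lam_k / nontrivial.sum()
        self.n_features_in_ = n
        return self

    def transform(self, X=None):
        return self.embedding_

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def diffusion_embed(affinity: AffinityMatrix, alpha: float = 0.5,
                    n_components: int = 10,
                    seed: int | None = None) -> WiringSpace:
    """Functional wrapper over :class:`DiffusionMapEmbedding`."""
    est = DiffusionMapEmbedding(alpha=alpha, n_components=n_components,
                                random_state=seed).fit(affinity)
    return WiringSpace(est.embedding_, est.eigenvalues_,
                       est.variance_explained_, alpha, affinity.node_ids)


def select_dims(eigenvalues) -> int:
    """Cattell scree elbow on an ordered eigenvalue sequence.

    The elbow is the scree point with maximum perpendicular distance to the
    straight line joining the first and last points; the retained count is
    that point's 0-based index.  A degenerate scree (no curvature, or elbow
    at the first point) returns 1 with a warning.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if len(lam) < 3:
        raise ValueError("need at least 3 eigenvalues for the scree test")
    x = np.arange(len(lam), dtype=float)
    p0 = np.array([x[0], lam[0]])
    p1 = np.array([x[-1], lam[-1]])
    d = p1 - p0
    d /= np.linalg.norm(d)
    rel = np.column_stack([x, lam]) - p0
    perp = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
    elbow = int(np.argmax(perp))
    if elbow < 1 or perp[elbow] < 1e-12:
        warnings.warn("degenerate scree (no elbow); retaining 1 component")
        return 1
    return elbow


def align_procrustes(space: WiringSpace, template: WiringSpace) -> WiringSpace:
    """Orthogonally align a wiring space to a template (no scaling).

    Both coordinate sets are centred; the rotation/reflection minimising the
    Frobenius distance to the template is applied to ``space``.
    """
    if not np.array_equal(space.node_ids, template.node_ids):
        raise ValueError("node sets differ between space and template")
    if space.n_components != template.n_components:
        raise ValueError("dimensionality differs between space and template")
    a = space.coordinates - space.coordinates.mean(axis=0)
    b = template.coordinates - template.coordinates.mean(axis=0)
    rot, _ = orthogonal_procrustes(a, b)
    aligned = a @ rot + template.coordinates.mean(axis=0)
    return WiringSpace(aligned, space.eigenvalues, space.variance_explained,
                       space.alpha, space.node_ids)


def build_wiring_space(gd: FeatureMatrix, mpc: FeatureMatrix,
                       ts: FeatureMatrix, alpha: float = 0.5,
                       n_components: int | str = "auto",
                       seed: int | None = None) -> WiringSpace:
    """End-to-end: normalise, fuse, embed, and (optionally) scree-select.

    ``n_components="auto"`` embeds with 10 components and truncates at the
    Cattell scree elbow of the eigenvalue sequence.
    """
    normalised = rank_normalise_rescale([gd, mpc, ts])
    aff = fuse_affinity(normalised, node_ids=gd.node_ids)
    space = diffusion_embed(aff, alpha=alpha, n_components=10, seed=seed)
    if n_components == "auto":
        k = select_dims(space.eigenvalues)
    else:
        k = int(n_components)
    return WiringSpace(space.coordinates[:, :k], space.eigenvalues[:k],
                       space.variance_explained[:k], alpha, space.node_ids)
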