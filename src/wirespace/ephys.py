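"""Directed-coherence analysis of multichannel intracranial recordings.

Welch cross-spectra give complex coherency per channel pair; the phase
slope index (PSI) summed over sliding frequency bands gives a signed,
antisymmetric estimate of temporal precedence.  Channel-pair PSI values are
aggregated to cluster-to-cluster effects with a linear mixed model
(EdgeType fixed effects plus wiring-geometry covariates and crossed random
intercepts for subject and channels), and the signed, thresholded t-statistic
network is tested for a Felleman-van-Essen-style hierarchy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import signal
from sklearn.decomposition import PCA
from sklearn.linear_model import lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralSet",
    "PSIMatrix",
    "EdgeTypeStats",
    "HierarchyResult",
    "LassoProfile",
    "welch_csd",
    "phase_slope_index",
    "edgetype_lmm",
    "similarity_pca",
    "lasso_profile",
    "hierarchy_placement",
]

EXCLUDED_BAND = (55.0, 65.0)  # power-line noise range


@dataclass
class SpectralSet:
    """Cross-spectral description of a multichannel recording."""

    freqs: np.ndarray               # (n_freqs,) Hz
    auto_spectra: np.ndarray        # (n_ch, n_freqs) P_xx, real >= 0
    cross_spectra: np.ndarray       # (n_ch, n_ch, n_freqs) complex P_xy
    coherency: np.ndarray           # (n_ch, n_ch, n_freqs) complex C_xy
    msc: np.ndarray                 # magnitude-squared coherence |C_xy|^2
    df: float                       # frequency resolution (Hz)

    def __post_init__(self):
        if np.any(self.auto_spectra < -1e-12):
            raise ValueError("auto spectra must be non-negative")
        if np.any(self.msc < -1e-9) or np.any(self.msc > 1 + 1e-9):
            raise ValueError("magnitude-squared coherence must lie in [0, 1]")


@dataclass
class PSIMatrix:
    """Per-band antisymmetric phase slope index matrices."""

    values: np.ndarray              # (n_bands, n_ch, n_ch)
    bands: np.ndarray               # (n_bands, 2) [lo, hi) Hz

    def __post_init__(self):
        if not np.allclose(self.values, -np.transpose(self.values, (0, 2, 1)),
                           atol=1e-10):
            raise ValueError("PSI must be antisymmetric per band")


@dataclass
class EdgeTypeStats:
    """Cluster-pair fixed effects from the mixed model of PSI."""

    t_stats: np.ndarray             # (k, k), NaN diagonal
    p_values: np.ndarray            # (k, k), NaN diagonal
    estimates: np.ndarray           # (k, k) fixed-effect coefficients
    random_variances: dict          # term -> estimated variance
    fallback: str | None = None     # set when random terms were dropped


@dataclass
class HierarchyResult:
    """Level placement of clusters under the directed-coherence network."""

    hierarchical: bool
    levels: dict                    # cluster -> level (1 = top); empty if not
    edges: list                     # significant signed edges (src, dst, t)
    offending_edges: list = field(default_factory=list)


@dataclass
class LassoProfile:
    """Lasso regularisation path with leave-one-out coefficient spread."""

    lambdas: np.ndarray             # shared lambda grid (descending)
    coefs: np.ndarray               # (n_predictors, n_lambdas) full-model path
    coef_sd: np.ndarray             # (n_predictors, n_lambdas) LOO sd
    predictor_names: list
    sparse_support: list            # predictors of the sparsest nonempty model
    adjusted_r2: float              # post hoc OLS on that support


# ---------------------------------------------------------------------------
# spectra and PSI
# ---------------------------------------------------------------------------

def welch_csd(signals: np.ndarray, fs: float, window_s: float = 2.0,
              step_s: float = 1.0, nfft: int | None = None,
              wm_reference: np.ndarray | None = None) -> SpectralSet:
    """Welch auto- and cross-spectra of a channel-by-time recording.

    Hamming-tapered blocks of ``window_s`` seconds advanced in ``step_s``
    steps are averaged into auto spectra P_xx and cross spectra P_xy;
    coherency is ``C_xy = P_xy / sqrt(P_xx P_yy)`` and the magnitude-squared
    coherence its squared modulus.  ``wm_reference`` (e.g. the average
    signal of white-matter channels) is subtracted from every channel
    before spectral estimation — the documented re-referencing hook.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n_channels >= 2, n_samples) array")
    nperseg = int(round(window_s * fs))
    if nperseg > x.shape[1]:
        raise ValueError("window longer than the record")
    if wm_reference is not None:
        x = x - np.asarray(wm_reference, dtype=float)[None, :]
    noverlap = nperseg - int(round(step_s * fs))
    freqs, pxy = signal.csd(x[:, None, :], x[None, :, :], fs=fs,
                            window="hamming", nperseg=nperseg,
                            noverlap=noverlap, nfft=nfft, axis=-1)
    # S_xy = E[X conj(Y)] so that a positive phase slope means x leads y
    pxy = np.conj(pxy)
    pxx = np.real(np.einsum("iif->if", pxy))
    denom = np.sqrt(pxx[:, None, :] * pxx[None, :, :])
    coherency = pxy / denom
    msc = np.clip(np.abs(coherency) ** 2, 0.0, 1.0)
    return SpectralSet(freqs, pxx, pxy, coherency, msc,
                       df=float(freqs[1] - freqs[0]))


def _band_index_sets(freqs: np.ndarray, fmin: float, fmax: float,
                     width: float, overlap: float,
                     excluded=EXCLUDED_BAND):
    starts = np.arange(fmin, fmax - width + 1e-9, width - overlap)
    bands, idx_sets = [], []
    for lo in starts:
        hi = lo + width
        if lo < excluded[1] and hi > excluded[0]:
            continue  # bands straddling the exclusion range are dropped
        full = np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))
        if len(full) < 2:
            raise ValueError(f"band [{lo}, {hi}] Hz has fewer than 2 grid points")
        bands.append((lo, hi))
        idx_sets.append(full[:-1])  # f and f+df both inside the band
    return np.array(bands), idx_sets


def phase_slope_index(spectra: SpectralSet, fmin: float = 1.0,
                      fmax: float = 100.0, width: float = 4.0,
                      overlap: float = 2.0,
                      excluded=EXCLUDED_BAND) -> PSIMatrix:
    """Phase slope index per sliding frequency band.

    ``psi_xy = Im( sum_{f in F} conj(C_xy(f)) * C_xy(f + df) )`` with F the
    band's frequency set and df the grid resolution; unstandardised.  Bands
    are ``width`` Hz wide with ``overlap`` Hz overlap from ``fmin`` to
    ``fmax``; bands overlapping the excluded range (power-line noise) are
    dropped entirely.  The result is exactly antisymmetric in channel order
    because ``C_yx = conj(C_xy)``.
    """
    bands, idx_sets = _band_index_sets(spectra.freqs, fmin, fmax, width,
                                       overlap, excluded)
    c = spectra.coherency
    psi = np.empty((len(bands), c.shape[0], c.shape[1]))
    for b, idx in enumerate(idx_sets):
        prod = np.conj(c[:, :, idx]) * c[:, :, idx + 1]
        psi[b] = np.imag(prod.sum(axis=2))
    psi = (psi - np.transpose(psi, (0, 2, 1))) / 2  # enforce exact antisymmetry
    for b in range(len(bands)):
        np.fill_diagonal(psi[b], 0.0)
    return PSIMatrix(psi, bands)


# ---------------------------------------------------------------------------
# cluster-level mixed model
# ---------------------------------------------------------------------------

def _pair_table(psi_band: np.ndarray, channel_cluster: np.ndarray,
                subject: str, covariates: dict | None) -> pd.DataFrame:
    n_ch = psi_band.shape[0]
    rows = []
    for i in range(n_ch):
        for j in range(n_ch):
            if i == j:
                continue
            row = {
                "psi": psi_band[i, j],
                "edge_type": f"{channel_cluster[i]}_{channel_cluster[j]}",
                "src_cluster": channel_cluster[i],
                "dst_cluster": channel_cluster[j],
                "ch_seed": f"{subject}:{i}",
                "ch_target": f"{subject}:{j}",
                "subject": subject,
            }
            if covariates is not None:
                row["wd"] = covariates["wd"][i, j]
                row["dE1"] = covariates["dE1"][i, j]
                row["dE2"] = covariates["dE2"][i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def edgetype_lmm(psi_per_subject: list[np.ndarray],
                 cluster_per_subject: list[np.ndarray],
                 covariates_per_subject: list[dict] | None = None,
                 subject_ids: list[str] | None = None,
                 clusters: np.ndarray | None = None,
                 reml: bool = True) -> EdgeTypeStats:
    """Mixed model of channel-pair PSI with cluster-pair fixed effects.

    Fits ``psi ~ 0 + EdgeType + wd + dE1 + dE2`` with random intercepts for
    subject, seed channel, and target channel (crossed, expressed as
    variance components within one encompassing group).  Different-cluster
    EdgeType coefficients are returned as a k-by-k t-statistic / p-value
    matrix (t[i, j] refers to the directed pair i -> j).

    Variance components estimated at the zero boundary are dropped and the
    model refit; with all components at zero the fit reduces exactly to
    ordinary least squares (the documented singular-fit fallback).  Cluster
    pairs never observed are reported as NaN.
    """
    n_subj = len(psi_per_subject)
    if subject_ids is None:
        subject_ids = [f"s{i}" for i in range(n_subj)]
    tables = []
    for s in range(n_subj):
        cov = None if covariates_per_subject is None else covariates_per_subject[s]
        tables.append(_pair_table(psi_per_subject[s], cluster_per_subject[s],
                                  subject_ids[s], cov))
    data = pd.concat(tables, ignore_index=True)
    data = data[data.src_cluster != data.dst_cluster].reset_index(drop=True)
    if clusters is None:
        clusters = np.unique(np.concatenate(cluster_per_subject))
    has_cov = covariates_per_subject is not None
    fixed = "psi ~ 0 + C(edge_type)" + (" + wd + dE1 + dE2" if has_cov else "")

    vc = {"subject": "0 + C(subject)", "ch_seed": "0 + C(ch_seed)",
          "ch_target": "0 + C(ch_target)"}
    if n_subj < 2:
        vc.pop("subject")
        fallback = "single subject: subject intercept inestimable, dropped"
        logger.warning(fallback)
    else:
        fallback = None

    def _fit_mixed(vc_terms):
        groups = np.ones(len(data))
        model = smf.mixedlm(fixed, data, groups=groups, vc_formula=vc_terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=["lbfgs", "powell"])

    random_variances = {}
    result = None
    vc_terms = dict(vc)
    while vc_terms:
        try:
            res = _fit_mixed(vc_terms)
        except np.linalg.LinAlgError:
            dropped = list(vc_terms)[-1]
            vc_terms.pop(dropped)
            fallback = (fallback or "") + f" singular fit: dropped {dropped};"
            logger.warning("singular mixed-model fit; dropping %s", dropped)
            continue
        vc_names = res.model.exog_vc.names
        vcomp = dict(zip(vc_names, np.asarray(res.vcomp)))
        dead = [k for k, v in vcomp.items() if v < 1e-7]
        if not dead:
            random_variances = vcomp
            result = res
            break
        for k in dead:
            vc_terms.pop(k)
        fallback = (fallback or "") + f" dropped zero-variance terms {dead};"
        logger.info("dropping zero-variance random terms %s", dead)
    if result is None:  # all components at the boundary -> exact OLS limit
        result = smf.ols(fixed, data).fit()
        fallback = (fallback or "") + " all random terms zero: OLS fit"

    k = len(clusters)
    cidx = {c: i for i, c in enumerate(clusters)}
    t = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    est = np.full((k, k), np.nan)
    for name in result.params.index:
        if not name.startswith("C(edge_type)"):
            continue
        label = name.split("[")[1].rstrip("]")
        src, dst = label.split("_")
        try:
            src = type(clusters[0])(src)
            dst = type(clusters[0])(dst)
        except (TypeError, ValueError):
            pass
        i, j = cidx[src], cidx[dst]
        est[i, j] = result.params[name]
        t[i, j] = result.tvalues[name]
        p[i, j] = result.pvalues[name]
    return EdgeTypeStats(t, p, est, random_variances, fallback)


# ---------------------------------------------------------------------------
# similarity, lasso profiling, hierarchy
# ---------------------------------------------------------------------------

def similarity_pca(edge_stats_per_band: list[EdgeTypeStats]) -> dict:
    """First principal component of cluster directed-coherence similarity.

    Each cluster's profile is the concatenation across bands of its outgoing
    and incoming t-statistics to every other cluster.  Pairwise Pearson
    correlations are computed after removing the entries of the two
    clusters' direct relationship, then the first principal component of
    the similarity matrix gives a loading per cluster plus the variance
    fraction it accounts for.
    """
    k = edge_stats_per_band[0].t_stats.shape[0]
    if k < 3:
        raise ValueError("need at least 3 clusters")
    n_bands = len(edge_stats_per_band)
    # profiles[i] has, per band, out-stats t[i, :] then in-stats t[:, i]
    # indexed by counterpart cluster so direct entries can be masked.
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            vi, vj = [], []
            for st in edge_stats_per_band:
                for c in range(k):
                    if c in (i, j):
                        continue  # remove the direct relationship and self
                    vi.extend([st.t_stats[i, c], st.t_stats[c, i]])
                    vj.extend([st.t_stats[j, c], st.t_stats[c, j]])
            vi, vj = np.array(vi), np.array(vj)
            ok = np.isfinite(vi) & np.isfinite(vj)
            if ok.sum() < 3 or vi[ok].std() == 0 or vj[ok].std() == 0:
                raise ValueError("constant or empty t-statistic profile")
            sim[i, j] = sim[j, i] = np.corrcoef(vi[ok], vj[ok])[0, 1]
    pca = PCA(n_components=min(k, 3)).fit(sim)
    loading = pca.transform(sim)[:, 0]
    if np.abs(loading).max() > 0 and loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    return {"loading": loading, "similarity": sim,
            "variance_fraction": float(pca.explained_variance_ratio_[0])}


def lasso_profile(loadings: np.ndarray, predictors: pd.DataFrame,
                  n_lambdas: int = 100, lambdas=None) -> LassoProfile:
    """Lasso path of the PC loading on cluster-level microscale predictors.

    The path is computed on standardised predictors over a shared descending
    lambda grid; leave-one-observation-out refits at the same lambdas give
    per-coefficient standard deviations.  The sparsest nonempty support is
    refit post hoc by OLS and its adjusted R-squared reported.
    """
    y = np.asarray(loadings, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations")
    x = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    grid = n_lambdas if lambdas is None else np.asarray(lambdas, dtype=float)
    lambdas, coefs, _ = lasso_path(xs, y - y.mean(), alphas=grid)
    n = len(y)
    loo = np.empty((n, xs.shape[1], len(lambdas)))
    for i in range(n):
        mask = np.arange(n) != i
        _, c, _ = lasso_path(xs[mask], y[mask] - y[mask].mean(), alphas=lambdas)
        loo[i] = c
    coef_sd = loo.std(axis=0)
    nnz = (np.abs(coefs) > 1e-12).sum(axis=0)
    nonempty = np.flatnonzero(nnz > 0)
    if len(nonempty) == 0:
        raise ValueError("lasso path is empty at every lambda")
    sparse_idx = nonempty[np.argmin(nnz[nonempty])]
    support = [names[i] for i in np.flatnonzero(np.abs(coefs[:, sparse_idx]) > 1e-12)]
    xsup = xs[:, [names.index(s) for s in support]]
    if len(y) <= len(support) + 1:
        raise ValueError("too few observations for the sparse-model refit")
    ols = sm.OLS(y, sm.add_constant(xsup)).fit()
    return LassoProfile(lambdas, coefs, coef_sd, names, support,
                        float(ols.rsquared_adj))


def hierarchy_placement(t_stats: np.ndarray, p_values: np.ndarray,
                        alpha: float = 0.05,
                        cluster_ids=None) -> HierarchyResult:
    """Place clusters into hierarchy levels from signed, thresholded PSI.

    Significant positive t-statistics define directed "drives" edges.
    Level 1 holds clusters with at least one significant outgoing edge and
    no significant incoming edge; each next level holds the unplaced
    clusters whose significant incoming edges all originate from already
    placed clusters.  The network is hierarchical iff every cluster is
    placed and every significant edge runs from a strictly higher level to
    a lower one; otherwise the offending (e.g. cyclic) edges are reported.
    """
    t = np.asarray(t_stats, dtype=float)
    p = np.asarray(p_values, dtype=float)
    k = t.shape[0]
    if cluster_ids is None:
        cluster_ids = list(range(k))
    edges = []
    for i in range(k):
        for j in range(k):
            if i != j and np.isfinite(t[i, j]) and p[i, j] < alpha and t[i, j] > 0:
                edges.append((cluster_ids[i], cluster_ids[j], float(t[i, j])))
    incoming = {c: set() for c in cluster_ids}
    outgoing = {c: set() for c in cluster_ids}
    for src, dst, _ in edges:
        incoming[dst].add(src)
        outgoing[src].add(dst)
    levels = {}
    level = 1
    top = [c for c in cluster_ids if not incoming[c] and outgoing[c]]
    isolated = [c for c in cluster_ids if not incoming[c] and not outgoing[c]]
    placed = set()
    for c in top:
        levels[c] = 1
    placed.update(top)
    # isolated clusters join immediately below the top level
    for c in isolated:
        levels[c] = 2 if top else 1
    placed.update(isolated)
    while True:
        level += 1
        ready = [c for c in cluster_ids if c not in placed
                 and incoming[c] and incoming[c] <= placed]
        if not ready:
            break
        for c in ready:
            levels[c] = level
        placed.update(ready)
    if len(placed) < k:
        stuck = [c for c in cluster_ids if c not in placed]
        offending = [e for e in edges if e[0] in stuck or e[1] in stuck]
        return HierarchyResult(False, {}, edges, offending)
    offending = [(s, d, tv) for s, d, tv in edges if levels[s] >= levels[d]]
    if offending:
        return HierarchyResult(False, {}, edges, offending)
    return HierarchyResult(True, levels, edges)
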