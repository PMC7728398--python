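"""Synthetic fixtures with planted ground truth.

Every pipeline stage can be exercised without any neuroimaging downloads:

* :func:`make_planted_dataset` builds a curved triangulated patch mesh,
  plants smooth 2-D latent coordinates on it, and derives a GD / MPC / TS
  feature triplet whose structure is governed by those coordinates — the
  embedding pipeline should recover them up to rotation.
* :func:`make_profiles` emulates laminar staining profiles as unimodal
  depth bumps with controllable peak depth.
* :func:`make_recordings` emulates multichannel oscillatory recordings in
  which directed cluster-to-cluster couplings have known lags.
* :func:`make_fc` generates functional connectivity as a monotone function
  of wiring distance plus noise, with a closed-form expected held-out
  R-squared for the prediction stage.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from sklearn.cluster import KMeans

from .features import (FeatureMatrix, IntensityProfileSet, SurfaceMesh,
                       compute_mpc, geodesic_matrix)
from .manifold import WiringSpace
from .metrics import wiring_distance

__all__ = [
    "PlantedDataset",
    "make_patch_mesh",
    "make_planted_dataset",
    "make_profiles",
    "make_recordings",
    "make_fc",
    "expected_holdout_r2",
]


@dataclass
class PlantedDataset:
    mesh: SurfaceMesh
    latent: np.ndarray              # (n_nodes, 2) planted coordinates
    gd: FeatureMatrix
    mpc: FeatureMatrix
    ts: FeatureMatrix
    params: dict = field(default_factory=dict)


def make_patch_mesh(n_nodes: int, vertices_per_node: int = 6,
                    seed: int = 0) -> tuple[SurfaceMesh, np.ndarray]:
    """Curved rectangular patch mesh with a k-means parcellation.

    A regular grid (aspect ~4:3) is lifted onto a gentle dome so geodesics
    differ from straight lines, triangulated, and divided into ``n_nodes``
    spatially compact parcels by k-means on the 2-D vertex positions.
    Returns the mesh and the (n_nodes, 2) parcel-centroid positions in the
    flat coordinates, scaled to [0, 1] per axis (the planted latent frame).
    """
    n_vert = n_nodes * vertices_per_node
    gx = int(np.ceil(np.sqrt(n_vert * 4 / 3)))
    gy = int(np.ceil(n_vert / gx))
    xx, yy = np.meshgrid(np.arange(gx, dtype=float), np.arange(gy, dtype=float))
    x, y = xx.ravel(), yy.ravel()
    # gentle dome: curvature without folding
    z = 0.15 * gx * np.sin(np.pi * x / gx) * np.sin(np.pi * y / gy)
    verts = np.column_stack([x, y, z])
    faces = []
    for j in range(gy - 1):
        for i in range(gx - 1):
            v0 = j * gx + i
            faces.append([v0, v0 + 1, v0 + gx])
            faces.append([v0 + 1, v0 + gx + 1, v0 + gx])
    faces = np.asarray(faces)
    km = KMeans(n_clusters=n_nodes, n_init=1, random_state=seed).fit(
        np.column_stack([x, y]))
    labels = km.labels_ + 1
    mesh = SurfaceMesh(verts, faces, labels)
    cent = np.vstack([np.column_stack([x, y])[labels == pid].mean(axis=0)
                      for pid in mesh.parcel_ids])
    latent = (cent - cent.min(axis=0)) / (cent.max(axis=0) - cent.min(axis=0))
    return mesh, latent


def make_profiles(n_nodes: int, n_depths: int, peak_depths,
                  noise_sd: float = 0.0, seed: int = 0,
                  peak_width: float = 0.15,
                  node_ids=None) -> IntensityProfileSet:
    """Unimodal laminar intensity profiles with planted peak depths.

    Each node's profile is a Gaussian bump over cortical depth centred on
    its ``peak_depths`` entry (0 = outer boundary) on a constant baseline,
    plus independent Gaussian noise of sd ``noise_sd``.
    """
    peak_depths = np.atleast_1d(np.asarray(peak_depths, dtype=float))
    if np.any((peak_depths < 0) | (peak_depths > 1)):
        raise ValueError("peak_depths must lie in [0, 1]")
    if len(peak_depths) == 1:
        peak_depths = np.full(n_nodes, peak_depths[0])
    depths = np.linspace(0.0, 1.0, n_depths)
    rng = np.random.default_rng(seed)
    profiles = 1.0 + np.exp(-((depths[None, :] - peak_depths[:, None]) ** 2)
                            / (2 * peak_width ** 2))
    profiles = profiles + rng.normal(0.0, noise_sd, profiles.shape)
    if node_ids is None:
        node_ids = np.arange(1, n_nodes + 1)
    return IntensityProfileSet(profiles, depths, node_ids)


def _calibrate_decay(dist: np.ndarray, density: float) -> float:
    """Bisection for the length scale giving the requested mean probability."""
    lo, hi = 1e-6, 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        mean_p = np.exp(-dist / mid).mean()
        if mean_p < density:
            lo = mid
        else:
            hi = mid
    return np.sqrt(lo * hi)


def make_planted_dataset(n_nodes: int = 300, noise_sd: float = 0.1,
                         ts_density: float = 0.15,
                         seed: int = 0) -> PlantedDataset:
    """Feature triplet governed by planted 2-D latent coordinates.

    * GD — mesh geodesics between parcel exemplars (a monotone function of
      latent distance by construction of the patch).
    * MPC — covariance of synthetic laminar profiles whose peak depth
      drifts monotonically with latent axis 2 (plus ``noise_sd`` profile
      noise).
    * TS — sparse symmetric graph with connection probability decaying
      exponentially in latent distance, calibrated to ``ts_density``;
      retained weights decay with distance with multiplicative lognormal
      scatter.
    """
    if n_nodes < 20:
        raise ValueError("need at least 20 nodes")
    if not 0 < ts_density <= 1:
        raise ValueError(f"infeasible TS density {ts_density}")
    rng = np.random.default_rng(seed)
    mesh, latent = make_patch_mesh(n_nodes, seed=seed)
    gd = geodesic_matrix(mesh)

    # broad bumps keep the profile-similarity kernel wide so the planted
    # sheet has exactly two dominant diffusion modes
    peaks = 0.15 + 0.7 * latent[:, 1]
    profiles = make_profiles(n_nodes, n_depths=12, peak_depths=peaks,
                             noise_sd=noise_sd,
                             seed=int(rng.integers(2 ** 31 - 1)),
                             peak_width=0.25, node_ids=gd.node_ids)
    mpc = compute_mpc(profiles)

    dlat = np.linalg.norm(latent[:, None, :] - latent[None, :, :], axis=2)
    iu = np.triu_indices(n_nodes, k=1)
    scale = _calibrate_decay(dlat[iu], ts_density)
    p = np.exp(-dlat / scale)
    adj = rng.random(dlat.shape) < p
    weights = np.exp(-dlat / scale) * rng.lognormal(0.0, 0.25, dlat.shape)
    vals = np.zeros_like(dlat)
    vals[iu] = np.where(adj[iu], weights[iu], 0.0)
    vals = vals + vals.T
    ts = FeatureMatrix(vals, "TS", gd.node_ids)
    return PlantedDataset(mesh, latent, gd, mpc, ts,
                          params={"noise_sd": noise_sd,
                                  "ts_density": ts_density, "seed": seed})


def _bandlimited_noise(rng, n_samples: int, fs: float, band) -> np.ndarray:
    sos = sp_signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    return x / x.std()


def make_recordings(cluster_graph: list[tuple], n_subjects: int = 10,
                    channels_per_cluster: int = 3, fs: float = 512.0,
                    duration_s: float = 60.0, snr: float = 2.0,
                    band=(20.0, 30.0), coupling: float = 1.0,
                    seed: int = 0) -> list[dict]:
    """Multichannel recordings with known directed lagged couplings.

    ``cluster_graph`` lists directed edges ``(src, dst, lag_ms)``; clusters
    are propagated in topological order, each receiving an attenuated,
    lagged copy of its parents' full signals on top of its own band-limited
    source.  Channels are the cluster signal plus independent channel noise
    (``snr`` = signal sd / noise sd); subjects differ by seed and by random
    per-channel gains.  Returns one dict per subject with ``signals``
    (channels x samples), ``fs``, ``channel_cluster`` and ``subject_id``.
    """
    clusters = sorted({c for e in cluster_graph for c in e[:2]})
    n_samples = int(duration_s * fs)
    max_lag = max((e[2] for e in cluster_graph), default=0.0)
    if max_lag / 1000.0 >= duration_s:
        raise ValueError("lag exceeds the recording duration")
    if fs < 4 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    # topological order (cluster_graph must be acyclic)
    order, pending = [], {c: set() for c in clusters}
    for src, dst, _ in cluster_graph:
        pending[dst].add(src)
    while len(order) < len(clusters):
        ready = [c for c in clusters if c not in order and pending[c] <= set(order)]
        if not ready:
            raise ValueError("cluster_graph contains a cycle")
        order.extend(ready)
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_subjects):
        srng = np.random.default_rng(rng.integers(2 ** 31 - 1))
        sigs = {c: _bandlimited_noise(srng, n_samples, fs, band) for c in clusters}
        for c in order:
            for src, dst, lag_ms in cluster_graph:
                if dst != c:
                    continue
                shift = int(round(lag_ms * fs / 1000.0))
                lagged = np.roll(sigs[src], shift)
                sigs[c] = sigs[c] + coupling * lagged
        channels, channel_cluster = [], []
        for c in clusters:
            for _ in range(channels_per_cluster):
                gain = srng.uniform(0.8, 1.2)
                noise = srng.standard_normal(n_samples) * (sigs[c].std() / snr)
                channels.append(gain * sigs[c] + noise)
                channel_cluster.append(c)
        out.append({"signals": np.vstack(channels), "fs": fs,
                    "channel_cluster": np.array(channel_cluster),
                    "subject_id": f"sub-{s:02d}"})
    return out


def make_fc(space: WiringSpace, tau: float | None = None,
            noise_sd: float = 0.2, seed: int = 0) -> np.ndarray:
    """Functional connectivity decaying in wiring distance, plus noise.

    ``FC_ij = exp(-wd_ij / tau) + N(0, noise_sd)``, row-wise z-scored, then
    symmetrised by averaging with the transpose.  ``tau`` defaults to half
    the mean off-diagonal wiring distance.
    """
    wd = wiring_distance(space).values
    if tau is None:
        tau = _default_tau(wd)
    rng = np.random.default_rng(seed)
    raw = np.exp(-wd / tau) + rng.normal(0.0, noise_sd, wd.shape)
    z = (raw - raw.mean(axis=1, keepdims=True)) / raw.std(axis=1, keepdims=True)
    return (z + z.T) / 2


def _default_tau(wd: np.ndarray) -> float:
    n = wd.shape[0]
    off = wd[~np.eye(n, dtype=bool)]
    return float(off.mean() / 2)


def expected_holdout_r2(space: WiringSpace, tau: float | None = None,
                        noise_sd: float = 0.2) -> float:
    """Closed-form expected held-out R-squared of the FC generator.

    A model that recovers the noiseless signal exactly attains, per seed
    row, ``R^2 = 1 - Var(noise) / Var(target)`` under the generator's
    z-scoring and symmetrisation; this returns the mean over rows.  Actual
    learners fall at or below this signal-to-noise ceiling.
    """
    wd = wiring_distance(space).values
    if tau is None:
        tau = _default_tau(wd)
    s = np.exp(-wd / tau)
    n = s.shape[0]
    mu = s.mean(axis=1)
    sig2 = s.var(axis=1) + noise_sd ** 2       # population row variance of raw FC
    sig = np.sqrt(sig2)
    # symmetrised z-score: T_ij = ((raw_i(j)-mu_i)/sig_i + (raw_j(i)-mu_j)/sig_j)/2
    s_sym = ((s - mu[:, None]) / sig[:, None] + (s.T - mu[None, :]) / sig[None, :]) / 2
    var_noise = (noise_sd ** 2) * (1.0 / sig2[:, None] + 1.0 / sig2[None, :]) / 4
    r2 = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        sig_var = s_sym[i, mask[i]].var()
        noi_var = var_noise[i, mask[i]].mean()
        r2[i] = sig_var / (sig_var + noi_var)
    return float(r2.mean())
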