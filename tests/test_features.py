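"""Unit tests for the wiring feature constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wirespace.features import (FeatureMatrix, SubjectConnectome, SurfaceMesh,
                                build_profiles, compute_mpc, consensus_ts,
                                equivolumetric_fractions, geodesic_matrix)
from wirespace.synthetic import make_profiles


# ---------------------------------------------------------------------------
# equivolumetric fractions
# ---------------------------------------------------------------------------

def _frustum_volume(a_inner, a_outer, x0, x1, n_grid=20001):
    """Numeric-integration oracle for the cumulative frustum volume."""
    x = np.linspace(x0, x1, n_grid)
    area = ((1 - x) * np.sqrt(a_inner) + x * np.sqrt(a_outer)) ** 2
    return np.trapezoid(area, x)


def test_equal_areas_give_equidistant_fractions():
    assert np.allclose(equivolumetric_fractions(2.0, 2.0, 5),
                       [0, 0.25, 0.5, 0.75, 1.0])


def test_two_surfaces_are_endpoints():
    assert np.allclose(equivolumetric_fractions(7.3, 0.4, 2), [0.0, 1.0])


@pytest.mark.parametrize("a_out,a_in,n", [(4.0, 1.0, 12), (9.0, 2.0, 7)])
def test_fractions_bound_equal_volumes(a_out, a_in, n):
    fr = equivolumetric_fractions(a_out, a_in, n)
    assert fr[0] == 0 and fr[-1] == 1 and np.all(np.diff(fr) > 0)
    vols = [_frustum_volume(a_in, a_out, fr[i], fr[i + 1]) for i in range(n - 1)]
    assert np.allclose(vols, vols[0], atol=1e-6)


@given(st.floats(0.1, 50), st.floats(0.1, 50), st.integers(2, 20))
@settings(max_examples=50, deadline=None)
def test_fractions_always_increasing_in_unit_interval(a_out, a_in, n):
    fr = equivolumetric_fractions(a_out, a_in, n)
    assert len(fr) == n
    assert fr[0] == pytest.approx(0) and fr[-1] == pytest.approx(1)
    assert np.all(np.diff(fr) > 0)


def test_nonpositive_area_rejected():
    with pytest.raises(ValueError):
        equivolumetric_fractions(0.0, 1.0, 5)


# ---------------------------------------------------------------------------
# profile building and the MAD outlier rule
# ---------------------------------------------------------------------------

def _flat_strip_mesh(n_cols, rows=2, labels=None):
    """Flat triangulated strip: n_cols columns of `rows` stacked vertices."""
    xs, ys = np.meshgrid(np.arange(n_cols, dtype=float), np.arange(rows, dtype=float))
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(xs.size)])
    faces = []
    for j in range(rows - 1):
        for i in range(n_cols - 1):
            v0 = j * n_cols + i
            faces.append([v0, v0 + 1, v0 + n_cols])
            faces.append([v0 + 1, v0 + n_cols + 1, v0 + n_cols])
    if labels is None:
        labels = np.tile(np.arange(1, n_cols + 1), rows)
    return SurfaceMesh(verts, np.array(faces), np.asarray(labels))


def test_identical_vertices_average_to_themselves():
    mesh = _flat_strip_mesh(4)
    prof = np.tile(np.array([1.0, 2.0, 3.0]), (len(mesh.vertices), 1))
    mesh.vertex_data["intensity"] = prof
    out = build_profiles(mesh)
    assert np.allclose(out.profiles, [1.0, 2.0, 3.0])


def test_outlier_vertex_excluded_by_mad_rule():
    # one parcel of 50 vertices in two rows of 25
    mesh = _flat_strip_mesh(25, rows=2, labels=np.ones(50, dtype=int))
    rng = np.random.default_rng(3)
    prof = 10.0 + rng.normal(0, 0.5, (50, 6))
    med = np.median(prof, axis=1)
    centre = np.median(med)
    mad = 1.4826 * np.median(np.abs(med - centre))
    prof[13] += 10 * mad  # shift one vertex far beyond the 3-MAD fence
    mesh.vertex_data["intensity"] = prof
    out = build_profiles(mesh)
    keep = np.ones(50, dtype=bool)
    keep[13] = False
    assert np.allclose(out.profiles[0], prof[keep].mean(axis=0))


def test_single_vertex_parcel_passes_through():
    mesh = _flat_strip_mesh(3, rows=1)
    # a 1-row strip has no faces; give it a degenerate face over its vertices
    mesh = SurfaceMesh(mesh.vertices, np.array([[0, 1, 2]]), np.array([1, 2, 3]))
    prof = np.array([[1.0, 2.0], [5.0, 6.0], [9.0, 8.0]])
    mesh.vertex_data["intensity"] = prof
    out = build_profiles(mesh)
    assert np.allclose(out.profiles, prof)  # MAD = 0 excludes nothing


def test_constant_parcel_not_wiped_by_zero_mad():
    mesh = _flat_strip_mesh(2, rows=2, labels=np.array([1, 1, 1, 1]))
    prof = np.ones((4, 5))
    prof[0] += 0.0
    mesh.vertex_data["intensity"] = prof
    out = build_profiles(mesh)
    assert np.allclose(out.profiles, 1.0)


# ---------------------------------------------------------------------------
# microstructure profile covariance
# ---------------------------------------------------------------------------

def _partial_corr_oracle(profiles):
    """Residualisation oracle: regress out the mean profile, correlate residuals."""
    x = profiles - profiles.mean(axis=1, keepdims=True)
    c = profiles.mean(axis=0)
    c = c - c.mean()
    resid = np.empty_like(x)
    for i in range(x.shape[0]):
        beta = (x[i] @ c) / (c @ c)
        resid[i] = x[i] - beta * c
    return np.corrcoef(resid)


def test_mpc_matches_residualisation_oracle(rng):
    profiles = make_profiles(20, 12, rng.uniform(0.1, 0.9, 20), noise_sd=0.1,
                             seed=11)
    mpc = compute_mpc(profiles, log_transform=False)
    oracle = _partial_corr_oracle(profiles.profiles)
    mask = (mpc.values != 0) & ~np.eye(20, dtype=bool)
    assert np.allclose(mpc.values[mask], oracle[mask], atol=1e-10)
    # thresholded entries were non-positive in the oracle
    assert np.all(oracle[~mask & ~np.eye(20, dtype=bool)] <= 1e-10)


def test_mean_plus_noise_profiles_decorrelate(rng):
    base = np.sin(np.linspace(0, np.pi, 400))
    profiles = base + rng.normal(0, 1.0, (15, 400))
    from wirespace.features import IntensityProfileSet
    ps = IntensityProfileSet(profiles, np.linspace(0, 1, 400), np.arange(15))
    mpc = compute_mpc(ps, log_transform=False)
    off = mpc.values[~np.eye(15, dtype=bool)]
    # partial correlations near zero: most entries fall below the 0 threshold
    assert np.abs(off[off != 0]).max() < 0.35
    assert (off == 0).mean() > 0.3


def test_identical_profiles_have_unit_partial_correlation():
    prof = np.vstack([np.array([1.0, 3.0, 2.0, 5.0]),
                      np.array([1.0, 3.0, 2.0, 5.0]),
                      np.array([4.0, 1.0, 3.0, 2.0])])
    from wirespace.features import IntensityProfileSet
    ps = IntensityProfileSet(prof, np.linspace(0, 1, 4), np.arange(3))
    mpc = compute_mpc(ps, log_transform=False)
    assert mpc.values[0, 1] == pytest.approx(1.0, abs=1e-12)


def test_zero_variance_profile_rejected():
    from wirespace.features import IntensityProfileSet
    prof = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
    ps = IntensityProfileSet(prof, np.linspace(0, 1, 3), np.array([7, 8, 9]))
    with pytest.raises(ValueError, match="7"):
        compute_mpc(ps)


# ---------------------------------------------------------------------------
# geodesic distance
# ---------------------------------------------------------------------------

def _floyd_warshall_oracle(n, edges):
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i, j, w in edges:
        d[i, j] = min(d[i, j], w)
        d[j, i] = d[i, j]
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def test_adjacent_exemplars_distance_is_edge_length():
    mesh = _flat_strip_mesh(2, rows=2, labels=np.array([1, 2, 1, 2]))
    gd = geodesic_matrix(mesh)
    # exemplars are the vertices nearest each parcel centroid, one column apart
    assert gd.values[0, 1] == pytest.approx(1.0)


def test_collinear_strip_accumulates_euclidean_distance():
    mesh = _flat_strip_mesh(6, rows=2)
    gd = geodesic_matrix(mesh)
    ids = np.arange(6)
    assert np.allclose(gd.values, np.abs(ids[:, None] - ids[None, :]))


def test_geodesics_match_brute_force_oracle(rng):
    from wirespace.synthetic import make_patch_mesh
    mesh, _ = make_patch_mesh(30, vertices_per_node=6, seed=5)
    gd = geodesic_matrix(mesh)
    graph = mesh.edge_graph().tocoo()
    edges = [(i, j, w) for i, j, w in zip(graph.row, graph.col, graph.data)]
    full = _floyd_warshall_oracle(len(mesh.vertices), edges)
    centroids = mesh.parcel_centroids()
    exemplars = []
    for k, pid in enumerate(mesh.parcel_ids):
        vids = np.flatnonzero(mesh.parcel_labels == pid)
        exemplars.append(vids[np.argmin(np.linalg.norm(
            mesh.vertices[vids] - centroids[k], axis=1))])
    oracle = full[np.ix_(exemplars, exemplars)]
    assert np.allclose(gd.values, oracle)


def test_geodesic_triangle_inequality_and_symmetry(small_planted):
    g = small_planted.gd.values
    assert np.array_equal(g, g.T)
    n = g.shape[0]
    i, j, k = np.meshgrid(range(n), range(n), range(0, n, 7), indexing="ij")
    assert np.all(g[i, j] <= g[i, k.squeeze()] + g[k.squeeze(), j] + 1e-9)


def test_disconnected_mesh_without_mirror_errors():
    m1 = _flat_strip_mesh(3, rows=2)
    verts = np.vstack([m1.vertices, m1.vertices + [100.0, 0, 0]])
    faces = np.vstack([m1.faces, m1.faces + len(m1.vertices)])
    labels = np.concatenate([m1.parcel_labels, m1.parcel_labels + 3])
    mesh = SurfaceMesh(verts, faces, labels)
    with pytest.raises(ValueError, match="unreachable"):
        geodesic_matrix(mesh)
    # mirroring homologous parcels fills the cross-hemisphere block
    homol = {1: 4, 2: 5, 3: 6, 4: 1, 5: 2, 6: 3}
    gd = geodesic_matrix(mesh, mirror=True,
                         hemispheres=np.array([0, 0, 0, 1, 1, 1]),
                         homologues=homol)
    assert np.isfinite(gd.values).all()
    assert gd.values[0, 3] == pytest.approx((gd.values[0, 0] + gd.values[3, 3]) / 2)


# ---------------------------------------------------------------------------
# distance-dependent consensus thresholding
# ---------------------------------------------------------------------------

def _random_connectomes(gd, n_subjects, seed, decay=0.5):
    rng = np.random.default_rng(seed)
    n = gd.values.shape[0]
    scale = np.median(gd.values[gd.values > 0])
    p = np.exp(-gd.values / (decay * scale))
    subs = []
    for s in range(n_subjects):
        iu = np.triu_indices(n, 1)
        w = np.zeros((n, n))
        mask = rng.random(len(iu[0])) < p[iu]
        w[iu[0][mask], iu[1][mask]] = rng.lognormal(0, 0.5, mask.sum())
        subs.append(SubjectConnectome(w + w.T, f"s{s}"))
    return subs


def test_unanimous_graph_is_returned_verbatim(small_planted):
    gd = small_planted.gd
    n = gd.values.shape[0]
    rng = np.random.default_rng(0)
    iu = np.triu_indices(n, 1)
    base = np.zeros((n, n))
    mask = rng.random(len(iu[0])) < 0.2
    base[iu[0][mask], iu[1][mask]] = 1.0
    base = base + base.T
    subs = [SubjectConnectome(base.copy(), f"s{i}") for i in range(4)]
    ts = consensus_ts(subs, gd, n_bins=10)
    assert np.array_equal(ts.values != 0, base != 0)
    assert np.allclose(ts.values[ts.values != 0], 1.0)


def test_per_bin_retained_count_matches_rule(small_planted):
    gd = small_planted.gd
    subs = _random_connectomes(gd, 6, seed=2)
    n_bins = 8
    ts = consensus_ts(subs, gd, n_bins=n_bins)
    n = gd.values.shape[0]
    iu = np.triu_indices(n, 1)
    stack = np.stack([s.values[iu] for s in subs])
    present = stack > 0
    d = gd.values[iu]
    pooled = np.repeat(d, present.sum(axis=0))
    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = np.digitize(d, edges[1:-1])
    kept = ts.values[iu] != 0
    for b in range(n_bins):
        in_bin = bin_of == b
        expected = int(round(present[:, in_bin].sum(axis=1).mean()))
        expected = min(expected, int((present.any(axis=0) & in_bin).sum()))
        assert kept[in_bin].sum() == expected


def test_single_bin_reduces_to_global_consistency_threshold(small_planted):
    gd = small_planted.gd
    subs = _random_connectomes(gd, 5, seed=4)
    ts = consensus_ts(subs, gd, n_bins=1)
    n = gd.values.shape[0]
    iu = np.triu_indices(n, 1)
    stack = np.stack([s.values[iu] for s in subs])
    present = stack > 0
    k = int(round(present.sum(axis=1).mean()))
    assert (ts.values[iu] != 0).sum() == k
    # retained edges are the k most consistent ones
    consistency = present.mean(axis=0)
    kept = ts.values[iu] != 0
    assert consistency[kept].min() >= np.sort(consistency)[::-1][k - 1] - 1e-12


def test_retained_weight_is_mean_of_nonzero_weights(small_planted):
    gd = small_planted.gd
    subs = _random_connectomes(gd, 5, seed=9)
    ts = consensus_ts(subs, gd, n_bins=6)
    n = gd.values.shape[0]
    iu = np.triu_indices(n, 1)
    stack = np.stack([s.values[iu] for s in subs])
    kept = ts.values[iu] != 0
    w = stack[:, kept]
    means = np.where(w > 0, w, np.nan)
    assert np.allclose(ts.values[iu][kept], np.nanmean(means, axis=0))
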