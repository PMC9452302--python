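"""LSI, clustering, UMAP, markers and pseudotime on controlled synthetic
structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score, silhouette_score

from spatac import analysis as an
from spatac.matrices import FeatureMatrix


def _block_matrix(n_per=60, n_feat=120, depth=200, seed=0, n_blocks=2):
    """Pixels in disjoint blocks use disjoint feature subsets."""
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    per_block = n_feat // n_blocks
    for b in range(n_blocks):
        lam = np.full(n_feat, 0.05)
        lam[b * per_block:(b + 1) * per_block] = depth / per_block
        for _ in range(n_per):
            rows.append(rng.poisson(lam))
            labels.append(b)
    X = sparse.csr_matrix(np.vstack(rows))
    barcodes = [f"px{i:04d}" for i in range(X.shape[0])]
    feats = pd.DataFrame({"name": [f"f{j}" for j in range(n_feat)]})
    return FeatureMatrix(X, barcodes, feats), np.array(labels)


def test_leading_contrast_component_separates_disjoint_blocks():
    """Two pixel blocks with disjoint accessible features split perfectly.

    The top SVD component of the uncentred TF-IDF matrix is the shared
    global-scale direction; the block contrast is the leading component with
    between-pixel structure, and it separates the blocks exactly
    (sign-invariantly).
    """
    mat, truth = _block_matrix()
    emb = an.iterative_lsi(mat, var_features=mat.shape[1], dims=10, seed=0)
    diffs = [abs(emb.coords[truth == 0, i].mean()
                 - emb.coords[truth == 1, i].mean())
             for i in range(emb.coords.shape[1])]
    best = int(np.argmax(diffs))
    assert best <= 1  # contrast lives in the top two retained components
    c = emb.coords[:, best]
    side = c > np.median(c)
    agreement = max((side == truth).mean(), (side == (1 - truth)).mean())
    assert agreement == 1.0


def test_identical_rows_are_degenerate():
    X = sparse.csr_matrix(np.tile(np.arange(1, 21), (30, 1)))
    mat = FeatureMatrix(X, [f"p{i}" for i in range(30)],
                        pd.DataFrame({"name": [f"f{j}" for j in range(20)]}))
    with pytest.warns(UserWarning):
        emb = an.iterative_lsi(mat, iterations=1, var_features=20, dims=5, seed=0)
    assert emb.degenerate


def test_lsi_is_deterministic_under_seed():
    mat, _ = _block_matrix(seed=3)
    e1 = an.iterative_lsi(mat, var_features=mat.shape[1], dims=8, seed=42)
    e2 = an.iterative_lsi(mat, var_features=mat.shape[1], dims=8, seed=42)
    np.testing.assert_array_equal(e1.coords, e2.coords)
    np.testing.assert_array_equal(e1.selected_features, e2.selected_features)


def test_lsi_depth_robustness():
    """Doubling one pixel's counts barely moves it in retained components."""
    mat, _ = _block_matrix(seed=5)
    X2 = mat.X.tolil()
    X2[0] = (mat.X[0] * 2).todense()
    boosted = FeatureMatrix(X2.tocsr(), mat.barcodes, mat.features)
    e1 = an.iterative_lsi(mat, iterations=1, var_features=mat.shape[1],
                          dims=6, seed=0)
    e2 = an.iterative_lsi(boosted, iterations=1, var_features=mat.shape[1],
                          dims=6, seed=0)
    k = min(e1.coords.shape[1], e2.coords.shape[1])
    scale = np.linalg.norm(e1.coords[:, :k], axis=1).mean()
    shift = np.linalg.norm(e1.coords[0, :k] - e2.coords[0, :k])
    assert shift < 0.15 * scale


def test_clustering_recovers_blocks_and_is_permutation_invariant():
    mat, truth = _block_matrix(n_blocks=3, n_per=50, seed=7)
    emb = an.iterative_lsi(mat, var_features=mat.shape[1], dims=10, seed=7)
    labels = an.cluster_graph(emb, resolution=0.5, seed=7)
    assert adjusted_rand_score(truth, labels) >= 0.9
    perm = np.random.default_rng(0).permutation(len(truth))
    labels_p = an.cluster_graph(emb.coords[perm], resolution=0.5, seed=7)
    assert adjusted_rand_score(labels[perm], labels_p) == pytest.approx(1.0)


def test_tiny_resolution_gives_one_cluster():
    # connected data (single block): resolution -> 0 merges everything
    mat, _ = _block_matrix(seed=9, n_blocks=1)
    emb = an.iterative_lsi(mat, var_features=mat.shape[1], dims=6, seed=9)
    labels = an.cluster_graph(emb, resolution=1e-4, seed=9)
    assert len(np.unique(labels)) == 1
    assert labels.min() == 0


def test_umap_is_seeded_and_separates_blocks():
    mat, truth = _block_matrix(n_per=40, seed=11)
    emb = an.iterative_lsi(mat, var_features=mat.shape[1], dims=8, seed=11)
    c1 = an.umap_embed(emb, n_neighbors=15, seed=11)
    c2 = an.umap_embed(emb, n_neighbors=15, seed=11)
    np.testing.assert_array_equal(c1, c2)
    assert silhouette_score(c1, truth) > 0.5


def test_umap_shrinks_neighbors_with_warning():
    mat, _ = _block_matrix(n_per=8, n_feat=30, seed=13)
    emb = an.iterative_lsi(mat, var_features=30, dims=5, seed=13)
    with pytest.warns(UserWarning, match="shrinking"):
        an.umap_embed(emb, n_neighbors=30, seed=13)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def test_planted_marker_is_recovered():
    rng = np.random.default_rng(17)
    n = 80
    X = rng.poisson(1.0, size=(n, 30)).astype(float)
    labels = np.repeat([0, 1], n // 2)
    X[labels == 0, 3] += rng.poisson(8.0, size=n // 2)  # planted marker
    mat = FeatureMatrix(sparse.csr_matrix(X), [f"p{i}" for i in range(n)],
                        pd.DataFrame({"name": [f"f{j}" for j in range(30)]}))
    table = an.marker_features(mat, labels, fdr_max=0.05, log2fc_min=0.25)
    hit = table[(table["cluster"] == 0) & (table["feature"] == "f3")]
    assert len(hit) == 1 and hit["log2fc"].iloc[0] > 2
    assert (table["fdr"] >= table["p"] - 1e-12).all()


def test_permuted_labels_yield_no_markers():
    rng = np.random.default_rng(19)
    X = rng.poisson(2.0, size=(120, 40)).astype(float)
    mat = FeatureMatrix(sparse.csr_matrix(X), [f"p{i}" for i in range(120)],
                        pd.DataFrame({"name": [f"f{j}" for j in range(40)]}))
    hits = 0
    for s in range(5):
        labels = np.random.default_rng(s).permutation(np.repeat([0, 1], 60))
        hits += len(an.marker_features(mat, labels, fdr_max=0.05, log2fc_min=0.0))
    assert hits <= 2  # null calibration: ~0 FDR-passing markers


def test_identical_clusters_give_empty_table():
    X = np.tile(np.arange(20.0), (40, 1))
    mat = FeatureMatrix(sparse.csr_matrix(X), [f"p{i}" for i in range(40)],
                        pd.DataFrame({"name": [f"f{j}" for j in range(20)]}))
    table = an.marker_features(mat, np.repeat([0, 1], 20))
    assert table.empty


def test_small_cluster_skipped():
    mat, _ = _block_matrix(n_per=20, seed=23)
    labels = np.zeros(40, dtype=int)
    labels[:2] = 1
    with pytest.warns(UserWarning, match="too small"):
        an.marker_features(mat, labels)


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

def test_midpoint_pixel_gets_pseudotime_50():
    coords = np.array([[0.0, 0.0]] * 10 + [[10.0, 0.0]] * 10 + [[5.0, 0.0]])
    labels = np.array([0] * 10 + [1] * 10 + [0])
    traj = an.backbone_pseudotime(coords, labels, [0, 1])
    assert traj.pseudotime[-1] == pytest.approx(50.0, abs=3.0)
    assert traj.pseudotime[0] == pytest.approx(0.0, abs=3.0)


def test_pixels_outside_backbone_are_excluded():
    coords = np.vstack([np.zeros((5, 2)), np.ones((5, 2)), 5 * np.ones((5, 2))])
    labels = np.repeat([0, 1, 2], 5)
    traj = an.backbone_pseudotime(coords, labels, [0, 1])
    assert np.isnan(traj.pseudotime[labels == 2]).all()
    assert (~traj.in_backbone[labels == 2]).all()
    with pytest.raises(ValueError):
        an.backbone_pseudotime(coords, labels, [0, 9])


def test_cluster_means_increase_along_backbone():
    rng = np.random.default_rng(29)
    coords = np.vstack([rng.normal(loc=[k * 4.0, 0], scale=0.5, size=(30, 2))
                        for k in range(4)])
    labels = np.repeat(np.arange(4), 30)
    traj = an.backbone_pseudotime(coords, labels, [0, 1, 2, 3])
    means = [np.nanmean(traj.pseudotime[labels == k]) for k in range(4)]
    assert all(a < b for a, b in zip(means, means[1:]))
    assert np.nanmin(traj.pseudotime) >= 0 and np.nanmax(traj.pseudotime) <= 100


def test_feature_along_pseudotime_bins():
    rng = np.random.default_rng(31)
    coords = np.linspace([0, 0], [10, 0], 100) + rng.normal(0, 0.1, (100, 2))
    labels = (coords[:, 0] > 5).astype(int)
    traj = an.backbone_pseudotime(coords, labels, [0, 1])
    linear = coords[:, 0]
    curve = an.feature_along_pseudotime(linear, traj, n_bins=10)
    assert curve["n"].sum() == 100
    assert (curve["mean"].diff().dropna() > -0.5).all()  # near-monotone
    flat = an.feature_along_pseudotime(np.ones(100), traj, n_bins=10)
    assert np.allclose(flat["smoothed"], 1.0)
    with pytest.raises(ValueError):
        an.feature_along_pseudotime(linear, traj, n_bins=1000)
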