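"""Dimensionality reduction, clustering, embedding, markers and pseudotime.

The reduction is iterative latent semantic indexing (LSI): a pinned TF-IDF
transform (tf = count / pixel total; idf = log(1 + N / (1 + df));
x = log1p(tf * idf * 1e4)) followed by truncated SVD.  Components whose
scores correlate with log sequencing depth (|r| > 0.75) are dropped.  The
second iteration re-selects features by cross-cluster pseudo-bulk
variability after an interim graph clustering, then repeats the reduction.

Clustering is Leiden community detection on a shared-nearest-neighbour
(cosine) graph; markers are two-sided Wilcoxon rank-sum tests per cluster
with Benjamini-Hochberg adjustment; pseudotime projects pixels onto the
piecewise-linear path through ordered backbone-cluster centroids, scaled to
[0, 100].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .matrices import FeatureMatrix


# ---------------------------------------------------------------------------
# LSI
# ---------------------------------------------------------------------------

@dataclass
class Embedding:
    coords: np.ndarray                  # (pixels, kept dims)
    barcodes: list[str]
    depth_corr: np.ndarray              # |r| vs log depth, all computed dims
    kept: np.ndarray                    # indices of retained dims
    selected_features: np.ndarray       # feature indices used in final pass
    method: str = "iterative_lsi"
    degenerate: bool = False
    seed: int = 0


def tfidf_log(X: sparse.csr_matrix, scale: float = 1e4) -> sparse.csr_matrix:
    """Pinned TF-IDF: log1p(tf * idf * scale)."""
    X = X.tocsr().astype(float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    tf = sparse.diags(1.0 / depth) @ X
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + X.shape[0] / (1.0 + df))
    out = (tf @ sparse.diags(idf)).tocsr()
    out.data = np.log1p(out.data * scale)
    return out


def _svd_embed(Z: sparse.csr_matrix, dims: int, seed: int) -> np.ndarray:
    k = int(min(dims, min(Z.shape) - 1))
    if k < 1:
        raise ValueError("matrix too small for SVD")
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min(Z.shape))
    U, S, Vt = svds(Z, k=k, v0=v0)
    order = np.argsort(S)[::-1]
    U, S, Vt = U[:, order], S[order], Vt[order]
    # deterministic sign convention: largest-magnitude loading positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    return U * S


def _lsi_pass(X: sparse.csr_matrix, feature_idx: np.ndarray, dims: int,
              seed: int, depth_corr_max: float,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    Z = tfidf_log(X[:, feature_idx])
    emb = _svd_embed(Z, dims, seed)
    log_depth = np.log1p(np.asarray(X.sum(axis=1)).ravel())
    corr = np.zeros(emb.shape[1])
    for i in range(emb.shape[1]):
        sd = emb[:, i].std()
        corr[i] = 0.0 if sd == 0 or log_depth.std() == 0 else abs(
            np.corrcoef(emb[:, i], log_depth)[0, 1])
    kept = np.flatnonzero(corr <= depth_corr_max)
    return emb, corr, kept


def iterative_lsi(matrix: FeatureMatrix, iterations: int = 2,
                  var_features: int = 25_000, dims: int = 30,
                  cluster_resolution: float = 0.2, seed: int = 0,
                  depth_corr_max: float = 0.75, n_neighbors: int = 30,
                  ) -> Embedding:
    """Iterative LSI over an insertion-count matrix.

    Pass 1 reduces the ``var_features`` most accessible features; an interim
    Leiden clustering then defines pseudo-bulk profiles whose cross-cluster
    variability selects the features for the final pass.
    """
    X = matrix.X.tocsr()
    n_feat = X.shape[1]
    if var_features > n_feat:
        warnings.warn(f"var_features {var_features} > {n_feat} features; using all")
        var_features = n_feat
    totals = np.asarray(X.sum(axis=0)).ravel()
    feature_idx = np.argsort(totals, kind="stable")[::-1][:var_features]
    emb = corr = kept = None
    for it in range(iterations):
        emb, corr, kept = _lsi_pass(X, feature_idx, dims, seed, depth_corr_max)
        if it == iterations - 1:
            break
        labels = cluster_graph(emb[:, kept] if kept.size else emb,
                               resolution=cluster_resolution,
                               n_neighbors=n_neighbors, seed=seed)
        feature_idx = _variable_by_pseudobulk(X, labels, var_features)
    degenerate = kept.size == 0 or emb[:, kept].std() < 1e-12 or all(
        emb[:, i].std() < 1e-9 * max(1.0, abs(emb[:, i]).max())
        for i in kept)
    if degenerate and kept.size:
        warnings.warn("embedding degenerate: retained components carry no "
                      "pixel-to-pixel variation")
    if kept.size == 0:
        warnings.warn("all components depth-correlated; embedding degenerate")
        coords = emb
        kept = np.arange(emb.shape[1])
    else:
        coords = emb[:, kept]
    return Embedding(coords=coords, barcodes=list(matrix.barcodes),
                     depth_corr=corr, kept=kept,
                     selected_features=feature_idx, degenerate=degenerate,
                     seed=seed)


def _variable_by_pseudobulk(X: sparse.csr_matrix, labels: np.ndarray,
                            var_features: int) -> np.ndarray:
    profiles = []
    for lab in np.unique(labels):
        rows = np.flatnonzero(labels == lab)
        total = np.asarray(X[rows].sum(axis=0)).ravel().astype(float)
        s = total.sum()
        profiles.append(np.log1p(total / s * 1e4 if s else total))
    V = np.vstack(profiles).var(axis=0)
    return np.argsort(V, kind="stable")[::-1][:var_features]


# ---------------------------------------------------------------------------
# graph clustering
# ---------------------------------------------------------------------------

def snn_graph(coords: np.ndarray, n_neighbors: int = 30,
              metric: str = "cosine") -> ig.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = coords.shape[0]
    k = min(n_neighbors, n - 1)
    if k < n_neighbors:
        warnings.warn(f"only {n} pixels; shrinking n_neighbors to {k}")
    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    A = sparse.coo_matrix((np.ones(idx.size), (rows, idx.ravel())),
                          shape=(n, n)).tocsr()
    A.data[:] = 1
    shared = (A @ A.T).tocoo()  # counts of shared neighbours
    deg = k + 1
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * deg - s)
    keep = jac > 1.0 / 15.0  # prune weak SNN edges (Seurat-style cutoff)
    g = ig.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())),
                 edge_attrs={"weight": jac[keep].tolist()})
    return g


def cluster_graph(coords_or_embedding, resolution: float = 1.0,
                  n_neighbors: int = 30, seed: int = 0) -> np.ndarray:
    """Leiden clustering on the SNN graph; labels contiguous from 0.

    Labels are deterministically relabelled by decreasing cluster size (ties
    by smallest member index), so permutation of the input only permutes the
    per-pixel labels, not the partition.
    """
    coords = (coords_or_embedding.coords
              if isinstance(coords_or_embedding, Embedding)
              else np.asarray(coords_or_embedding))
    g = snn_graph(coords, n_neighbors=n_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=int(seed),
        n_iterations=2)
    raw = np.asarray(part.membership)
    order = sorted(np.unique(raw),
                   key=lambda l: (-(raw == l).sum(), int(np.argmax(raw == l))))
    remap = {l: i for i, l in enumerate(order)}
    return np.array([remap[l] for l in raw])


def umap_embed(coords_or_embedding, n_neighbors: int = 30,
               metric: str = "cosine", min_dist: float = 0.5,
               seed: int = 0) -> np.ndarray:
    """Seeded 2-D UMAP of the LSI space."""
    import umap  # deferred: heavy import

    coords = (coords_or_embedding.coords
              if isinstance(coords_or_embedding, Embedding)
              else np.asarray(coords_or_embedding))
    if coords.shape[1] < 2:
        raise ValueError("need an embedding with >= 2 dims")
    if np.allclose(coords, coords[0]):
        raise ValueError("degenerate embedding: all points identical")
    k = min(n_neighbors, coords.shape[0] - 1)
    if k < n_neighbors:
        warnings.warn(f"only {coords.shape[0]} pixels; shrinking n_neighbors to {k}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = umap.UMAP(n_neighbors=k, metric=metric, min_dist=min_dist,
                          random_state=int(seed), n_components=2)
        return model.fit_transform(coords)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def marker_features(matrix: FeatureMatrix, labels: np.ndarray,
                    fdr_max: float = 0.05, log2fc_min: float = 0.25,
                    pseudo: float = 1.0, min_cluster_size: int = 3,
                    ) -> pd.DataFrame:
    """Per-cluster two-sided Wilcoxon rank-sum markers, BH-adjusted per cluster.

    log2FC = log2((mean_in + pseudo) / (mean_out + pseudo)).  Rows are
    filtered at FDR <= fdr_max and log2FC >= log2fc_min.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need >= 2 clusters for marker detection")
    X = matrix.X.toarray() if sparse.issparse(matrix.X) else np.asarray(matrix.X)
    names = (matrix.features["name"].tolist()
             if "name" in matrix.features else
             [f"f{i}" for i in range(X.shape[1])])
    out = []
    for lab in np.unique(labels):
        inside = labels == lab
        if inside.sum() < min_cluster_size or (~inside).sum() < min_cluster_size:
            warnings.warn(f"cluster {lab} too small; skipped")
            continue
        xin, xout = X[inside], X[~inside]
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(xin, xout, alternative="two-sided", axis=0)
        p = np.nan_to_num(res.pvalue, nan=1.0)
        lfc = np.log2((xin.mean(axis=0) + pseudo) / (xout.mean(axis=0) + pseudo))
        fdr = multipletests(p, method="fdr_bh")[1]
        sel = (fdr <= fdr_max) & (lfc >= log2fc_min)
        for j in np.flatnonzero(sel):
            out.append((int(lab), names[j], float(lfc[j]), float(p[j]),
                        float(fdr[j])))
    return (pd.DataFrame(out, columns=["cluster", "feature", "log2fc", "p", "fdr"])
            .sort_values(["cluster", "fdr", "feature"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# pseudotime
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    pseudotime: np.ndarray        # NaN outside backbone clusters
    in_backbone: np.ndarray       # bool per pixel
    backbone: list[int]
    barcodes: list[str] = field(default_factory=list)


def backbone_pseudotime(embedding: Embedding | np.ndarray, labels: np.ndarray,
                        backbone: list[int], seed: int = 0) -> Trajectory:
    """Project pixels onto the ordered backbone-cluster centroid path.

    Each pixel of backbone cluster k is projected onto the segment from
    centroid k to centroid k+1 (the last cluster projects onto the previous
    segment); pseudotime is the clamped arc position rescaled to [0, 100].
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else np.asarray(embedding)
    barcodes = embedding.barcodes if isinstance(embedding, Embedding) else []
    labels = np.asarray(labels)
    if len(backbone) < 2:
        raise ValueError("backbone needs >= 2 clusters")
    for lab in backbone:
        if (labels == lab).sum() == 0:
            raise ValueError(f"backbone cluster {lab} is empty or unknown")
    K = len(backbone)
    centroids = np.vstack([coords[labels == lab].mean(axis=0) for lab in backbone])
    pt = np.full(len(labels), np.nan)
    member = np.isin(labels, backbone)
    pos_of = {lab: i for i, lab in enumerate(backbone)}
    for lab in backbone:
        k = pos_of[lab]
        seg = (k, k + 1) if k < K - 1 else (K - 2, K - 1)
        a, b = centroids[seg[0]], centroids[seg[1]]
        v = b - a
        denom = float(v @ v) or 1.0
        rows = np.flatnonzero(labels == lab)
        t = np.clip((coords[rows] - a) @ v / denom, 0.0, 1.0)
        pt[rows] = seg[0] + t
    pt = pt / (K - 1) * 100.0
    return Trajectory(pseudotime=pt, in_backbone=member, backbone=list(backbone),
                      barcodes=list(barcodes))


def feature_along_pseudotime(values: np.ndarray, trajectory: Trajectory,
                             n_bins: int = 20, smooth_window: int = 3
                             ) -> pd.DataFrame:
    """Equal-occupancy pseudotime bins with rolling-mean-smoothed feature means."""
    values = np.asarray(values, dtype=float)
    sel = np.flatnonzero(trajectory.in_backbone)
    if n_bins > sel.size:
        raise ValueError(f"n_bins {n_bins} > {sel.size} backbone pixels")
    order = sel[np.argsort(trajectory.pseudotime[sel], kind="stable")]
    chunks = np.array_split(order, n_bins)
    rows = [(i, trajectory.pseudotime[c].mean(), values[c].mean(), len(c))
            for i, c in enumerate(chunks)]
    df = pd.DataFrame(rows, columns=["bin", "pseudotime", "mean", "n"])
    df["smoothed"] = df["mean"].rolling(smooth_window, center=True,
                                       min_periods=1).mean()
    return df
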