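"""Morphometric pseudotime: single-structure trajectory analysis.

Borrowing the analysis vocabulary of single-cell transcriptomics, each
segmented structure (e.g. a glomerulus) is treated as a sample and its
morphometric features as the measured variables. The pipeline is

1. relative-counts (RC) normalisation of each structure's feature row,
2. Pearson-residual correspondence analysis for dimension reduction,
3. a diffusion map with locally scaled Gaussian kernel and density
   normalisation,
4. Louvain clustering on the first two diffusion components,
5. a backbone pseudotime: an ordered list of clusters from healthy to
   diseased defines a piecewise-linear path through cluster centroids;
   instances are projected onto the path and their arc-length position is
   scaled to [0, 100],
6. bucketing of instances into 20 pseudotime buckets with per-condition
   fractions and loess-smoothed curves,
7. a patient-level trajectory: each patient's cluster-membership
   histograms (glomeruli and tubules) are compared by the exact
   1-Wasserstein distance with the Euclidean centroid distance as ground
   metric; the two matrices are combined (element-wise mean after max-
   normalisation) and re-embedded like instance-level data.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import cdist, pdist, squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "TrajectoryResult",
    "rc_normalize",
    "ca_pearson_residuals",
    "diffusion_map",
    "louvain_clusters",
    "backbone_pseudotime",
    "bucket_fractions",
    "wasserstein_histogram_distance",
    "wasserstein_patient_distances",
    "fit_trajectory",
]


# ---------------------------------------------------------------------------
# normalisation and correspondence analysis
# ---------------------------------------------------------------------------

def rc_normalize(M, scale: float = 1e4, shift: bool = True) -> np.ndarray:
    """Relative-counts normalisation: each row divided by its sum, times scale.

    Signed or unbounded features are min-shifted per column to zero first
    (``shift=True``), since relative counts presume non-negative entries.
    Rows with zero sum raise.
    """
    X = np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("feature matrix must be 2-D with >= 2 features")
    if shift:
        X = X - np.minimum(X.min(axis=0), 0.0)
    if (X < 0).any():
        raise ValueError("negative entries after shift; cannot RC-normalise")
    rs = X.sum(axis=1)
    if np.any(rs == 0):
        raise ValueError("zero-sum rows cannot be RC-normalised")
    return X / rs[:, None] * scale


def ca_pearson_residuals(M, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Pearson-residual correspondence analysis of a non-negative matrix.

    The matrix is treated as a contingency table; residuals
    (observed - expected) / sqrt(expected) under the row-by-column
    independence model are decomposed by truncated SVD, and the row
    coordinates (U * singular values) are returned together with the
    singular values. Deterministic up to column sign, fixed by making the
    largest-magnitude column loading positive.
    """
    X = np.asarray(M, dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis requires non-negative entries")
    total = X.sum()
    r = X.sum(axis=1, keepdims=True)
    c = X.sum(axis=0, keepdims=True)
    E = r @ c / total
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(E > 0, (X - E) / np.sqrt(E), 0.0)
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    tol = max(S.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank == 0:
        warnings.warn(
            "matrix matches the independence model exactly (rank-1 input); "
            "embedding is degenerate", stacklevel=2,
        )
        return np.zeros((X.shape[0], 0)), np.zeros(0)
    if rank < n_components:
        warnings.warn(
            f"requested {n_components} components but residual rank is {rank}; "
            "returning fewer", stacklevel=2,
        )
        n_components = rank
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # sign convention
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U * s, s


# ---------------------------------------------------------------------------
# diffusion map
# ---------------------------------------------------------------------------

def _local_sigmas(D: np.ndarray, k: int) -> np.ndarray:
    """Per-point bandwidth: distance to the k-th nearest distinct neighbour.

    Zero distances (exact duplicates) are ignored when ranking, so
    duplicating the dataset leaves the bandwidths unchanged.
    """
    sig = np.empty(D.shape[0])
    for i in range(D.shape[0]):
        pos = np.unique(D[i][D[i] > 0])  # duplicates collapse to one entry
        if pos.size == 0:
            sig[i] = 1.0
            continue
        sig[i] = pos[min(k, pos.size) - 1]
    return sig


def diffusion_map(
    X,
    n_components: int = 10,
    k_nn: int | None = None,
    local_k: int = 5,
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion-map embedding with local scaling and density normalisation.

    A Gaussian kernel with per-point bandwidth (distance to the
    ``local_k``-th nearest distinct neighbour) is density-normalised
    (anticipated-density correction, alpha = 1) and converted to a Markov
    transition operator whose leading non-trivial eigenvectors give the
    diffusion components, ordered by eigenvalue magnitude and scaled by
    their eigenvalue. Eigenvectors are scaled to unit degree-weighted RMS,
    which makes the per-point values invariant to duplicating the dataset.

    ``k_nn`` sparsifies the kernel to a (symmetrised) k-nearest-neighbour
    graph; a disconnected graph is reconnected by minimum-spanning-tree
    augmentation with a warning. ``metric='precomputed'`` takes X as a
    distance matrix.
    """
    X = np.asarray(X, dtype=float)
    if metric == "precomputed":
        D = X.copy()
        n = D.shape[0]
    else:
        n = X.shape[0]
        D = squareform(pdist(X))
    if n < n_components + 2:
        raise ValueError("need at least n_components + 2 points")
    sig = _local_sigmas(D, local_k)
    W = np.exp(-(D**2) / (sig[:, None] * sig[None, :]))
    if k_nn is not None:
        keep = np.zeros_like(W, dtype=bool)
        order = np.argsort(D, axis=1)
        for i in range(n):
            keep[i, order[i, : k_nn + 1]] = True
        keep |= keep.T
        Wk = np.where(keep, W, 0.0)
        ncomp, comp_labels = connected_components(Wk > 0, directed=False)
        if ncomp > 1:
            warnings.warn(
                f"kNN graph has {ncomp} components; reconnecting via "
                "minimum-spanning-tree augmentation", stacklevel=2,
            )
            mst = minimum_spanning_tree(D).toarray()
            bridge = (mst > 0) & (comp_labels[:, None] != comp_labels[None, :])
            Wk[bridge] = W[bridge]
            Wk = np.maximum(Wk, Wk.T)
        W = Wk
    # density normalisation (alpha = 1)
    q = W.sum(axis=1)
    W = W / (q[:, None] * q[None, :])
    d = W.sum(axis=1)
    inv_sqrt_d = 1.0 / np.sqrt(d)
    A = W * inv_sqrt_d[:, None] * inv_sqrt_d[None, :]
    A = (A + A.T) / 2.0
    vals, vecs = np.linalg.eigh(A)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    # drop the trivial constant eigenvector (eigenvalue 1)
    psi = vecs * inv_sqrt_d[:, None]
    lam = vals[1 : n_components + 1]
    coords = psi[:, 1 : n_components + 1]
    # degree-weighted unit RMS + sign convention
    wts = d / d.sum()
    for j in range(coords.shape[1]):
        nrm = np.sqrt(np.sum(wts * coords[:, j] ** 2))
        if nrm > 0:
            coords[:, j] /= nrm
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1.0
    return coords * lam[None, :], lam


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def louvain_clusters(
    coords: np.ndarray,
    k_nn: int = 20,
    seed: int = 0,
    prune: float = 1.0 / 15.0,
    resolution: float = 0.1,
) -> np.ndarray:
    """Louvain community detection on a shared-nearest-neighbour graph.

    Uses exactly the supplied coordinates (callers pass the first two
    diffusion components); edges are weighted by the Jaccard overlap of
    k-nearest-neighbour sets and pruned below ``prune``. The default
    modularity resolution is deliberately low so that a homogeneous point
    cloud stays in one or two communities instead of fragmenting; raise it
    for finer partitions. The random number generator is seeded for a
    reproducible partition. Labels are 0..K-1.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k_nn:
        raise ValueError(f"need more than k_nn={k_nn} points, got {n}")
    D = squareform(pdist(coords))
    order = np.argsort(D, axis=1)
    neigh = [set(order[i, : k_nn + 1].tolist()) for i in range(n)]
    edges, weights = [], []
    for i in range(n):
        for j in order[i, 1 : k_nn + 1]:
            j = int(j)
            if j <= i:
                continue
            jac = len(neigh[i] & neigh[j]) / len(neigh[i] | neigh[j])
            if jac >= prune:
                edges.append((i, j))
                weights.append(jac)
    g = ig.Graph(n=n, edges=edges)
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights=weights, resolution=resolution)
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# backbone pseudotime
# ---------------------------------------------------------------------------

def backbone_pseudotime(
    coords: np.ndarray,
    labels: np.ndarray,
    backbone: list[int],
) -> np.ndarray:
    """Pseudotime along an ordered cluster backbone, scaled to [0, 100].

    A piecewise-linear path is drawn through the centroids of the backbone
    clusters (in the given healthy-to-diseased order); every instance of a
    backbone cluster is projected to its nearest point on the path and its
    arc-length position is min-max scaled to [0, 100]. Instances outside
    the backbone receive NaN.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    backbone = list(backbone)
    if len(backbone) < 2:
        raise ValueError("backbone must contain at least two clusters")
    for b in backbone:
        if not np.any(labels == b):
            raise ValueError(f"backbone cluster {b} is empty")
    centroids = np.stack([coords[labels == b].mean(axis=0) for b in backbone])
    seg = np.diff(centroids, axis=0)
    seg_len = np.sqrt((seg**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    pt = np.full(len(labels), np.nan)
    on_path = np.isin(labels, backbone)
    P = coords[on_path]
    best_d = np.full(len(P), np.inf)
    best_s = np.zeros(len(P))
    for k in range(len(seg)):
        v = seg[k]
        L2 = float(v @ v)
        if L2 == 0:
            t = np.zeros(len(P))
        else:
            t = np.clip((P - centroids[k]) @ v / L2, 0.0, 1.0)
        proj = centroids[k] + t[:, None] * v
        dist = np.sqrt(((P - proj) ** 2).sum(axis=1))
        better = dist < best_d
        best_d[better] = dist[better]
        best_s[better] = cum[k] + t[better] * seg_len[k]
    smin, smax = best_s.min(), best_s.max()
    if smax > smin:
        best_s = (best_s - smin) / (smax - smin) * 100.0
    else:
        best_s = np.zeros_like(best_s)
    pt[on_path] = best_s
    return pt


def bucket_fractions(
    pseudotime: np.ndarray,
    condition,
    n_buckets: int = 20,
    loess_frac: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-bucket condition fractions along the pseudotime, with loess curves.

    Instances are distributed over ``n_buckets`` equal-width buckets on
    [0, 100]; in each non-empty bucket the fraction of every condition is
    computed (fractions sum to 1 per bucket). Empty buckets are emitted as
    missing and excluded from the loess smoothing.
    """
    pt = np.asarray(pseudotime, dtype=float)
    cond = pd.Categorical(np.asarray(condition))
    ok = np.isfinite(pt)
    edges = np.linspace(0.0, 100.0, n_buckets + 1)
    which = np.clip(np.digitize(pt[ok], edges[1:-1]), 0, n_buckets - 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    table = pd.DataFrame(
        index=pd.Index(centers, name="bucket_center"),
        columns=list(cond.categories), dtype=float,
    )
    codes = cond.codes[ok]
    for b in range(n_buckets):
        in_b = which == b
        if not in_b.any():
            continue
        counts = np.bincount(codes[in_b], minlength=len(cond.categories))
        table.iloc[b] = counts / counts.sum()
    curves: dict[str, np.ndarray] = {}
    nonempty = table.notna().all(axis=1).to_numpy()
    xs = centers[nonempty]
    for name in cond.categories:
        ys = table.loc[nonempty, name].to_numpy(float)
        if len(xs) >= 3:
            curves[str(name)] = lowess(ys, xs, frac=loess_frac,
                                       return_sorted=False)
        else:
            curves[str(name)] = ys
    return table, curves


# ---------------------------------------------------------------------------
# Wasserstein patient-level trajectory
# ---------------------------------------------------------------------------

def wasserstein_histogram_distance(
    p: np.ndarray, q: np.ndarray, cost: np.ndarray
) -> float:
    """Exact 1-Wasserstein distance between histograms under a cost matrix.

    Solves the optimal-transport linear programme to optimality; the cost
    matrix is typically the Euclidean distance between cluster centroids.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    cost = np.asarray(cost, dtype=float)
    K = len(p)
    if q.shape != (K,) or cost.shape != (K, K):
        raise ValueError("incompatible histogram / cost shapes")
    p = p / p.sum()
    q = q / q.sum()
    # marginal constraints; the last column constraint is redundant
    A_eq = np.zeros((2 * K - 1, K * K))
    b_eq = np.zeros(2 * K - 1)
    for i in range(K):
        A_eq[i, i * K : (i + 1) * K] = 1.0
        b_eq[i] = p[i]
    for j in range(K - 1):
        A_eq[K + j, j::K] = 1.0
        b_eq[K + j] = q[j]
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"OT solve failed: {res.message}")
    return float(res.fun)


def _cluster_histogram(labels: np.ndarray, n_clusters: int) -> np.ndarray:
    h = np.bincount(np.asarray(labels, dtype=int), minlength=n_clusters).astype(float)
    return h / h.sum()


def wasserstein_patient_distances(
    labels_by_patient: dict[str, np.ndarray],
    centroids: np.ndarray,
) -> pd.DataFrame:
    """Pairwise 1-Wasserstein distances between patients' cluster histograms.

    Each patient's structure clustering is encoded as a probability
    distribution over clusters; the ground metric is the Euclidean distance
    between cluster centroids in diffusion space.
    """
    patients = sorted(labels_by_patient)
    K = centroids.shape[0]
    cost = cdist(centroids, centroids)
    hists = {p: _cluster_histogram(labels_by_patient[p], K) for p in patients}
    D = np.zeros((len(patients), len(patients)))
    for a in range(len(patients)):
        for b in range(a + 1, len(patients)):
            d = wasserstein_histogram_distance(
                hists[patients[a]], hists[patients[b]], cost
            )
            D[a, b] = D[b, a] = d
    return pd.DataFrame(D, index=patients, columns=patients)


def combine_distance_matrices(
    glom: pd.DataFrame, tubule: pd.DataFrame | None
) -> pd.DataFrame:
    """Element-wise mean of max-normalised structure-wise distance matrices.

    A patient missing one structure type has that entry imputed from the
    available type (logged by the caller).
    """
    if tubule is None:
        return glom.copy()
    common = sorted(set(glom.index) | set(tubule.index))
    mats = []
    for M in (glom, tubule):
        full = pd.DataFrame(np.nan, index=common, columns=common)
        sub = M / M.to_numpy().max() if M.to_numpy().max() > 0 else M
        full.loc[sub.index, sub.columns] = sub
        mats.append(full.to_numpy())
    stack = np.array(mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        comb = np.nanmean(stack, axis=0)
    np.fill_diagonal(comb, 0.0)
    return pd.DataFrame(comb, index=common, columns=common)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryResult:
    """Everything the single-structure trajectory pipeline produces."""

    diffusion_coords: np.ndarray
    eigenvalues: np.ndarray
    cluster_labels: np.ndarray
    backbone: list[int]
    pseudotime: np.ndarray  # [0, 100], NaN off the backbone
    bucket_table: pd.DataFrame | None = None
    curves: dict[str, np.ndarray] = field(default_factory=dict)


def _auto_backbone(
    coords: np.ndarray, labels: np.ndarray, condition, severity_order
) -> list[int]:
    """Advisory backbone: clusters ordered healthy to diseased.

    Uses the mean condition-severity rank per cluster when a condition is
    given (orientation by severity), otherwise the mean of the first
    diffusion component.
    """
    clusters = np.unique(labels)
    if condition is not None and severity_order is not None:
        sev = {c: i for i, c in enumerate(severity_order)}
        score = np.array([np.mean([sev[c] for c in np.asarray(condition)[labels == k]])
                          for k in clusters])
    else:
        score = np.array([coords[labels == k, 0].mean() for k in clusters])
    return [int(k) for k in clusters[np.argsort(score)]]


def fit_trajectory(
    features,
    condition=None,
    severity_order: list | None = None,
    backbone: list[int] | None = None,
    n_ca_components: int = 10,
    n_diffusion_components: int = 10,
    k_nn: int = 20,
    n_buckets: int = 20,
    seed: int = 0,
) -> TrajectoryResult:
    """Run the full RC -> CA -> diffusion -> Louvain -> backbone pipeline.

    ``backbone`` is the user-supplied ordered cluster list (healthy to
    diseased); when omitted an advisory ordering is derived from the
    condition severity (or the first diffusion component) — inspect the
    clusters before trusting it.
    """
    norm = rc_normalize(features)
    emb, _ = ca_pearson_residuals(norm, n_components=n_ca_components)
    coords, lam = diffusion_map(emb, n_components=n_diffusion_components)
    labels = louvain_clusters(coords[:, :2], k_nn=k_nn, seed=seed)
    if backbone is None:
        backbone = _auto_backbone(coords[:, :2], labels, condition, severity_order)
    pt = backbone_pseudotime(coords[:, :2], labels, backbone)
    table, curves = (None, {})
    if condition is not None:
        table, curves = bucket_fractions(pt, condition, n_buckets=n_buckets)
    return TrajectoryResult(
        diffusion_coords=coords,
        eigenvalues=lam,
        cluster_labels=labels,
        backbone=backbone,
        pseudotime=pt,
        bucket_table=table,
        curves=curves,
    )
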