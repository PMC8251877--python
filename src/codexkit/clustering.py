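"""Unsupervised cell-type discovery by kNN-density mode seeking.

This is an X-shift-style procedure: each cell's local density is the
inverse of the mean distance to its K nearest neighbors (in arcsinh +
z-scored marker space); every cell links to the densest of its K neighbors
that is denser than itself; cells with no denser neighbor are density modes
and the trees rooted at modes are the clusters.  Basins that are fragments
of one population are then merged by structural-contact, resolution-floor
and density-saddle tests (see :func:`xshift_cluster`), preserving modes
separated by genuine density dips.  K is chosen by an elbow on the
cluster-count-versus-K curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .stack_io import marker_columns

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "prepare_features",
    "knn_density",
    "xshift_cluster",
    "cluster_cells",
    "select_elbow",
    "profile_clusters",
]


@dataclass
class ClusterParams:
    K: int = 30
    K_sweep: tuple[int, ...] = (10, 20, 30, 60)
    cofactor: float = 5.0  # arcsinh cofactor, cytometry convention
    excluded_markers: tuple[str, ...] = ()
    saddle_fraction: float = 0.6  # dimension-normalized mode-merge threshold
    seed: int = 0  # used only if subsampling is requested
    subsample: int | None = None

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.cofactor <= 0:
            raise ValueError("cofactor must be positive")


@dataclass
class ClusterResult:
    labels: np.ndarray  # dense 0..n_clusters-1, one per cell
    K: int
    profiles: pd.DataFrame = field(default_factory=pd.DataFrame)  # mean transformed profile
    sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def prepare_features(
    table: pd.DataFrame,
    params: ClusterParams | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Marker matrix for clustering: arcsinh(x / cofactor), per-marker z-score.

    Excluded markers are dropped before the transform; markers with zero
    variance carry no information and are dropped with a warning.
    """
    params = params or ClusterParams()
    params.validate()
    if len(table) == 0:
        raise ValueError("empty cell table")
    markers = [m for m in marker_columns(table) if m not in params.excluded_markers]
    unknown = set(params.excluded_markers) - set(marker_columns(table))
    if unknown:
        raise ValueError(f"excluded markers not in table: {sorted(unknown)}")
    X = np.arcsinh(table[markers].to_numpy(dtype=float) / params.cofactor)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(markers, keep) if not k]
        warnings.warn(f"dropping zero-variance markers: {dropped}")
        markers = [m for m, k in zip(markers, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    X = (X - X.mean(axis=0)) / sd
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")
    return X, markers


def knn_density(features: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Density = 1 / mean distance to the K nearest neighbors (self excluded).

    Returns (density, neighbor index matrix of shape (n, K)).
    """
    n = len(features)
    if K >= n:
        raise ValueError(f"K={K} must be below the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=K + 1).fit(features)
    dist, idx = nn.kneighbors(features)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    mean_d = dist.mean(axis=1)
    density = np.where(mean_d > 0, 1.0 / np.maximum(mean_d, 1e-300), np.inf)
    return density, idx


def xshift_cluster(features: np.ndarray, K: int,
                   saddle_fraction: float = 0.6,
                   min_contact: float = 0.3,
                   absorb_factor: float = 6.0,
                   absorb_floor: float = 0.1,
                   smooth_passes: int = 1) -> ClusterResult:
    """Mode-seeking clustering on the kNN density field.

    The climb partitions cells into density basins.  Basins are then
    merged by three complementary rules, each targeting a different way
    the finite-K density estimate fragments one true population:

    1. *Structural contact*: the fraction of the smaller basin's kNN
       links that cross the pair's boundary, normalized by the share
       expected when a single dense region is cut in two
       (``(K / size) ** (1/d)``, the relative thickness of the kNN
       boundary shell in ``d`` dimensions).  Normalized contact of at
       least ``min_contact`` means the basins are two halves of one
       region and they merge.
    2. *Resolution floor*: a basin with fewer than ``absorb_factor x K``
       members is below the smoothing scale of the density estimate and
       cannot witness a separate mode; it joins its strongest-contact
       neighbor (requiring raw contact of at least ``absorb_floor`` so
       truly isolated small clusters survive).
    3. *Density saddle*: remaining adjacent groups merge, best pair
       first, while ``(saddle / weaker group peak) ** d >=
       saddle_fraction``.  The saddle is a noise-resistant order
       statistic of the boundary edges, the peak is the mean of the
       basin's top densities, and the ``d``-th power converts the kNN
       density ratio to a probability-density ratio, making the
       threshold dimension-free.

    A final single-pass kNN-majority vote smooths boundary assignments.
    Deterministic for a given input order; ties between equally dense
    neighbors break toward the lowest index.
    """
    n, d_dim = features.shape
    density, idx = knn_density(features, K)

    # link each point to the densest of its neighbors that is denser than itself
    neigh_density = density[idx]  # (n, K)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        denser = neigh_density[i] > density[i]
        if not denser.any():
            continue
        cand = idx[i][denser]
        cd = neigh_density[i][denser]
        parent[i] = cand[np.lexsort((cand, -cd))][0]  # densest, lowest index on ties

    # path-compress to the mode at the root of each tree
    root = parent.copy()
    is_mode = root == -1
    root[is_mode] = np.flatnonzero(is_mode)
    for _ in range(n):
        nxt = np.where(parent[root] == -1, root, parent[root])
        if np.array_equal(nxt, root):
            break
        root = nxt

    mode_idx, basin = np.unique(root, return_inverse=True)
    n_modes = len(mode_idx)
    sizes = np.bincount(basin)
    # robust peak: mean of the basin's top densities (the single maximum is
    # upward-biased for small basins at small K)
    peaks = np.array([
        np.sort(density[basin == b])[-min(5, sizes[b]):].mean()
        for b in range(n_modes)
    ])

    # kNN-graph edges crossing basin boundaries
    src = np.repeat(np.arange(n), idx.shape[1])
    dst = idx.ravel()
    cross = basin[src] != basin[dst]
    pair_edges: dict[tuple[int, int], list[float]] = {}
    for a, b, s in zip(basin[src[cross]], basin[dst[cross]],
                       np.minimum(density[src[cross]], density[dst[cross]])):
        key = (a, b) if a < b else (b, a)
        pair_edges.setdefault(key, []).append(s)
    pair_saddle: dict[tuple[int, int], float] = {}
    pair_contact: dict[tuple[int, int], float] = {}
    pair_norm_contact: dict[tuple[int, int], float] = {}
    for (a, b), es in pair_edges.items():
        es_sorted = sorted(es, reverse=True)
        ki = min(5, max(1, len(es_sorted) // 3)) - 1  # order statistic, not max
        pair_saddle[(a, b)] = es_sorted[ki]
        smaller = min(sizes[a], sizes[b])
        contact = len(es) / (K * smaller)
        pair_contact[(a, b)] = contact
        # expected boundary share for a bisected region; clamped so basins
        # smaller than K are not merged unconditionally
        shell = min(1.0, (K / smaller) ** (1.0 / d_dim))
        pair_norm_contact[(a, b)] = contact / shell

    uf = np.arange(n_modes)

    def find(a: int) -> int:
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            uf[max(ra, rb)] = min(ra, rb)

    # rule 1: structural contact
    for (a, b), c in sorted(pair_norm_contact.items()):
        if c >= min_contact:
            union(a, b)
    # rule 2: sub-resolution groups join their strongest-contact neighbor,
    # iterated so coalescing fragments keep absorbing until they reach the
    # resolution scale or run out of contact
    pair_n_edges = {k: len(es) for k, es in pair_edges.items()}
    for _ in range(n_modes):
        group_size: dict[int, int] = {}
        for m in range(n_modes):
            g = find(m)
            group_size[g] = group_size.get(g, 0) + int(sizes[m])
        group_edges: dict[tuple[int, int], int] = {}
        for (a, b), ne in pair_n_edges.items():
            ga, gb = find(a), find(b)
            if ga == gb:
                continue
            gkey = (ga, gb) if ga < gb else (gb, ga)
            group_edges[gkey] = group_edges.get(gkey, 0) + ne
        best = None
        for (ga, gb), ne in sorted(group_edges.items()):
            if min(group_size[ga], group_size[gb]) >= absorb_factor * K:
                continue
            c = ne / (K * min(group_size[ga], group_size[gb]))
            if c >= absorb_floor and (best is None or c > best[0]):
                best = (c, ga, gb)
        if best is None:
            break
        union(best[1], best[2])
    # rule 3: greedy saddle merges against current group peaks
    for _ in range(max(1, n_modes)):
        group_peak: dict[int, float] = {}
        for m in range(n_modes):
            g = find(m)
            group_peak[g] = max(group_peak.get(g, 0.0), peaks[m])
        best = None
        for (a, b), s in pair_saddle.items():
            ga, gb = find(a), find(b)
            if ga == gb:
                continue
            ratio = (s / min(group_peak[ga], group_peak[gb])) ** d_dim
            if ratio >= saddle_fraction and (best is None or ratio > best[0]):
                best = (ratio, ga, gb)
        if best is None:
            break
        _, ga, gb = best
        union(ga, gb)

    group = np.array([find(m) for m in range(n_modes)])
    # dense labels ordered by the lowest original mode index in each group
    uniq = sorted(set(group.tolist()), key=lambda g: mode_idx[group == g].min())
    remap = {g: i for i, g in enumerate(uniq)}
    labels = np.array([remap[group[b]] for b in basin], dtype=np.int64)

    # kNN-majority smoothing of boundary assignments (own label kept on ties)
    for _ in range(smooth_passes):
        new = labels.copy()
        for i in range(n):
            votes = np.bincount(labels[idx[i]])
            top = np.flatnonzero(votes == votes.max())
            new[i] = labels[i] if labels[i] in top else top[0]
        if np.array_equal(new, labels):
            break
        labels = new
    _, labels = np.unique(labels, return_inverse=True)

    return ClusterResult(labels=labels, K=K, sizes=np.bincount(labels))


def cluster_cells(features: np.ndarray, params: ClusterParams) -> ClusterResult:
    """Cluster a feature matrix, subsampling first when configured.

    With ``params.subsample`` set and fewer rows than cells, a seeded
    uniform subsample is clustered and the held-out cells take the label
    of their nearest clustered neighbor.  Keeps very large tables
    desk-scale without changing the algorithm.
    """
    params.validate()
    n = len(features)
    if params.subsample is None or n <= params.subsample:
        return xshift_cluster(features, params.K, params.saddle_fraction)
    rng = np.random.default_rng(params.seed)
    pick = np.sort(rng.choice(n, params.subsample, replace=False))
    sub = xshift_cluster(features[pick], params.K, params.saddle_fraction)
    nn = NearestNeighbors(n_neighbors=1).fit(features[pick])
    nearest = nn.kneighbors(features, return_distance=False)[:, 0]
    labels = sub.labels[nearest]
    labels[pick] = sub.labels
    return ClusterResult(labels=labels, K=params.K, sizes=np.bincount(labels))


def select_elbow(
    features: np.ndarray,
    K_sweep,
    saddle_fraction: float = 0.6,
) -> tuple[int, pd.DataFrame]:
    """Pick K where the cluster-count-vs-K curve flattens.

    The count falls steeply while K under-smooths the density, then
    plateaus at the resolved structure; the chosen K is the first sweep
    point whose count matches the next one (the start of the plateau).
    If no two consecutive counts agree, the point of maximum second
    difference of log counts is used.  A completely flat curve has no
    elbow: the smallest K is returned with a warning.  The full curve is
    returned for logging.
    """
    K_sweep = list(K_sweep)
    if len(K_sweep) < 3:
        raise ValueError("K sweep needs at least 3 values")
    if sorted(K_sweep) != K_sweep:
        raise ValueError("K sweep must be sorted ascending")
    counts = [xshift_cluster(features, K, saddle_fraction).n_clusters for K in K_sweep]
    curve = pd.DataFrame({"K": K_sweep, "n_clusters": counts})
    if all(c == counts[0] for c in counts):
        warnings.warn("cluster count constant across sweep; no elbow, returning smallest K")
        return K_sweep[0], curve
    for i in range(len(counts) - 1):
        if counts[i] == counts[i + 1]:
            return K_sweep[i], curve
    logc = np.log(np.maximum(counts, 1))
    d2 = [logc[i - 1] - 2 * logc[i] + logc[i + 1] for i in range(1, len(counts) - 1)]
    if max(d2) <= 0:
        warnings.warn("no convex elbow in cluster-count curve; returning smallest K")
        return K_sweep[0], curve
    best = max(range(len(d2)), key=lambda i: (d2[i], i))  # ties -> larger K
    return K_sweep[best + 1], curve


def profile_clusters(result: ClusterResult, table: pd.DataFrame,
                     params: ClusterParams | None = None) -> pd.DataFrame:
    """Per-cluster mean raw and transformed intensity for every marker.

    All markers are reported (including any excluded from clustering), with
    rows ordered by cluster size descending.  Every cluster is non-empty by
    construction; this is asserted.
    """
    params = params or ClusterParams()
    markers = marker_columns(table)
    labels = result.labels
    assert len(labels) == len(table)
    sizes = np.bincount(labels)
    assert (sizes > 0).all(), "empty cluster encountered"
    rows = []
    for lab in np.argsort(sizes)[::-1]:
        sub = table.iloc[labels == lab]
        row = {"cluster": int(lab), "size": int(sizes[lab])}
        for m in markers:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_arcsinh_mean"] = float(np.arcsinh(sub[m] / params.cofactor).mean())
        rows.append(row)
    return pd.DataFrame(rows)
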