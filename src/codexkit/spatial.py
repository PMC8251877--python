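"""Spatial analyses: follicle composition and windowed density correlation.

Follicles (B-cell-rich regions) arrive as labeled masks; for each one a
surrounding ring is derived by dilating the mask so the region's outer
extent scales to ``factor`` times the maximum pairwise distance D between
the cells inside (dilation radius ``(factor - 1) * D / 2``).  Cell-type
composition is tallied inside the mask and in the ring, and averaged per
tissue.  Local structure is probed by counting cell types inside randomly
placed square windows and correlating the per-window counts between every
pair of types (Spearman), ordered for display by hierarchical clustering.

Cells are points: a cell belongs to a region iff its centroid pixel does.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

__all__ = [
    "CompositionResult",
    "DensityCorrelation",
    "follicle_ring",
    "auto_follicle_mask",
    "composition",
    "sample_density",
    "density_correlation",
]


@dataclass
class CompositionResult:
    """Cell-type frequencies per follicle (inner and ring) plus tissue mean.

    ``per_follicle`` has one row per (follicle, zone) with count columns and
    frequency columns per cell type; ``tissue_mean`` is the unweighted mean
    of per-follicle frequency vectors per zone.
    """

    per_follicle: pd.DataFrame
    tissue_mean: pd.DataFrame
    cell_types: list[str]


@dataclass
class DensityCorrelation:
    counts: pd.DataFrame  # windows x cell types
    rho: pd.DataFrame  # cell types x cell types, Spearman
    order: list[str]  # dendrogram display order
    undefined: list[str] = field(default_factory=list)  # zero-variance types


def _cells_in_region(table: pd.DataFrame, region: np.ndarray) -> np.ndarray:
    """Boolean mask of cells whose centroid pixel lies inside a boolean region."""
    ys = np.clip(np.rint(table["y_px"].to_numpy()).astype(int), 0, region.shape[0] - 1)
    xs = np.clip(np.rint(table["x_px"].to_numpy()).astype(int), 0, region.shape[1] - 1)
    return region[ys, xs]


def follicle_ring(
    mask: np.ndarray,
    table: pd.DataFrame,
    factor: float = 1.2,
) -> dict[int, np.ndarray]:
    """Surrounding ring per follicle, scaled to the follicle's cell spread.

    For follicle k: D = maximum pairwise centroid distance among its cells;
    ring = pixels outside every follicle but within a dilation of mask k by
    ``(factor - 1) * D / 2``.  ``factor=1`` gives empty rings.  Follicles
    holding fewer than two cells are skipped with a warning.
    """
    if factor < 1.0:
        raise ValueError("ring factor must be >= 1")
    mask = np.asarray(mask)
    labels = [int(k) for k in np.unique(mask) if k != 0]
    any_follicle = mask > 0
    rings: dict[int, np.ndarray] = {}
    for k in labels:
        region = mask == k
        inside = _cells_in_region(table, region)
        pts = table.loc[inside, ["y_px", "x_px"]].to_numpy(dtype=float)
        if len(pts) < 2:
            warnings.warn(f"follicle {k} holds {len(pts)} cells; ring skipped")
            continue
        D = float(pdist(pts).max())
        radius = (factor - 1.0) * D / 2.0
        if radius <= 0:
            rings[k] = np.zeros_like(region)
            continue
        dist_out = ndi.distance_transform_edt(~region)
        rings[k] = (dist_out <= radius) & ~any_follicle
    return rings


def auto_follicle_mask(
    plane: np.ndarray,
    threshold: float | None = None,
    closing_radius: int = 5,
    min_area: int = 500,
) -> np.ndarray:
    """Convenience follicle mask from one marker plane (e.g. CD19).

    Threshold (Otsu by default), morphological closing, small-object
    removal, connected-component labeling.  Hand-drawn masks remain the
    primary input; this is only a starting point.
    """
    from skimage.filters import threshold_otsu
    from skimage.morphology import binary_closing, disk, remove_small_objects

    if threshold is None:
        threshold = threshold_otsu(plane)
    fg = binary_closing(plane > threshold, disk(closing_radius))
    fg = remove_small_objects(fg, min_size=min_area)
    labeled, _ = ndi.label(fg)
    return labeled.astype(np.int32)


def composition(
    table: pd.DataFrame,
    mask: np.ndarray,
    rings: dict[int, np.ndarray] | None = None,
    label_column: str = "cluster",
) -> CompositionResult:
    """Cell-type composition inside each follicle and its surrounding ring.

    Frequencies are counts / total within the zone; the tissue average is
    the unweighted mean of per-follicle frequency vectors.  An empty zone
    reports zero frequencies with count 0 and a warning.
    """
    if label_column not in table.columns:
        raise ValueError(f"cell table lacks a {label_column!r} column")
    mask = np.asarray(mask)
    types = sorted(pd.unique(table[label_column]).tolist())
    rows = []
    for k in (int(v) for v in np.unique(mask) if v != 0):
        zones = {"inner": mask == k}
        if rings is not None and k in rings:
            zones["ring"] = rings[k]
        for zone, region in zones.items():
            sub = table[_cells_in_region(table, region)]
            total = len(sub)
            if total == 0:
                warnings.warn(f"follicle {k} zone {zone!r} holds no cells")
            row = {"follicle": k, "zone": zone, "total": total}
            vc = sub[label_column].value_counts()
            for t in types:
                c = int(vc.get(t, 0))
                row[f"count_{t}"] = c
                row[f"freq_{t}"] = c / total if total else 0.0
            rows.append(row)
    per_follicle = pd.DataFrame(rows)
    means = []
    if len(per_follicle):
        for zone, grp in per_follicle.groupby("zone"):
            nonempty = grp[grp["total"] > 0]
            src = nonempty if len(nonempty) else grp
            mean_row = {"zone": zone, "n_follicles": len(src)}
            for t in types:
                mean_row[f"freq_{t}"] = float(src[f"freq_{t}"].mean())
            means.append(mean_row)
    return CompositionResult(
        per_follicle=per_follicle,
        tissue_mean=pd.DataFrame(means),
        cell_types=[str(t) for t in types],
    )


def sample_density(
    table: pd.DataFrame,
    shape: tuple[int, int],
    window: int = 100,
    n_windows: int = 500,
    domain: np.ndarray | None = None,
    seed: int = 0,
    label_column: str = "cluster",
) -> pd.DataFrame:
    """Cell-type counts inside randomly placed square windows.

    Window origins are drawn uniformly (seeded) with the whole square
    inside the domain — the full image, or the True region of ``domain``.
    Windows may overlap.  Returns a (windows x cell types) count frame with
    window origin columns ``y0``/``x0`` attached as metadata columns.
    """
    if window < 10:
        raise ValueError("window must be at least 10 px")
    if n_windows < 10:
        raise ValueError("need at least 10 windows")
    h, w = shape
    if h < window or w < window:
        raise ValueError("domain smaller than the window")
    rng = np.random.default_rng(seed)

    if domain is not None:
        domain = np.asarray(domain, dtype=bool)
        # integral image: a window is valid iff fully inside the domain
        ii = np.pad(np.cumsum(np.cumsum(domain, 0), 1), ((1, 0), (1, 0)))
        full = window * window
        valid = (
            ii[window:, window:] - ii[:-window, window:]
            - ii[window:, :-window] + ii[:-window, :-window]
        ) == full
        ys, xs = np.nonzero(valid)
        if len(ys) == 0:
            raise ValueError("domain holds no full window; domain smaller than window")
        pick = rng.integers(0, len(ys), n_windows)
        origins = np.column_stack([ys[pick], xs[pick]])
    else:
        origins = np.column_stack([
            rng.integers(0, h - window + 1, n_windows),
            rng.integers(0, w - window + 1, n_windows),
        ])

    types = sorted(pd.unique(table[label_column]).tolist()) if len(table) else []
    cy = table["y_px"].to_numpy(dtype=float) if len(table) else np.array([])
    cx = table["x_px"].to_numpy(dtype=float) if len(table) else np.array([])
    labels = table[label_column].to_numpy() if len(table) else np.array([])
    out = {"y0": origins[:, 0], "x0": origins[:, 1]}
    for t in types:
        sel = labels == t
        ty, tx = cy[sel], cx[sel]
        counts = np.empty(n_windows, dtype=int)
        for i, (y0, x0) in enumerate(origins):
            counts[i] = int(np.sum(
                (ty >= y0) & (ty < y0 + window) & (tx >= x0) & (tx < x0 + window)
            ))
        out[str(t)] = counts
    frame = pd.DataFrame(out)
    if not types:
        # keep an all-zero column-free frame but remember the window count
        frame.attrs["empty_table"] = True
    frame.attrs["window"] = window
    return frame


def density_correlation(counts: pd.DataFrame) -> DensityCorrelation:
    """Pairwise Spearman correlation of per-window cell-type counts.

    Average-rank tie handling (scipy).  Types with zero variance across
    windows have undefined rank correlation; they are reported as 0 and
    flagged.  Display order comes from average-linkage clustering of
    ``1 - rho``.
    """
    type_cols = [c for c in counts.columns if c not in ("y0", "x0")]
    if len(counts) < 10:
        raise ValueError("need at least 10 windows")
    if len(type_cols) < 2:
        raise ValueError("need at least 2 cell types")
    X = counts[type_cols].to_numpy(dtype=float)
    undefined = [t for t, sd in zip(type_cols, X.std(axis=0)) if sd == 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(X).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(rho, 1.0)
    rho_df = pd.DataFrame(rho, index=type_cols, columns=type_cols)

    if len(type_cols) > 2:
        dist = squareform(np.clip(1.0 - rho, 0.0, 2.0), checks=False)
        order = [type_cols[i] for i in leaves_list(average(dist))]
    else:
        order = list(type_cols)
    return DensityCorrelation(counts=counts, rho=rho_df, order=order,
                              undefined=undefined)


def plot_density_heatmap(result: DensityCorrelation, path) -> None:
    """Red (anticorrelated) to green (correlated) heatmap in dendrogram order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = result.rho.loc[result.order, result.order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.to_numpy(), cmap="RdYlGn", vmin=-1, vmax=1)
    ax.set_xticks(range(len(result.order)), result.order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(result.order)), result.order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
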