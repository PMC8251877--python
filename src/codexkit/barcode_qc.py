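"""Barcode orthogonality and cycle-chemistry quality control.

Three views of how cleanly a barcode/reporter library behaves:

* a rank image — per pixel, the top three intensities across all reporter
  planes rendered blue/green/red; a field dominated by blue means one
  barcode per pixel, i.e. minimal cross-reactivity;
* an intersection-over-union matrix over the per-barcode positive cell
  sets — off-diagonal mass flags cross-hybridizing pairs;
* an on/off cycle trace — reveal a marker in some cycles and not others,
  and measure how reproducible the on-signal is and how much carries over
  into off cycles (stripping efficiency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

__all__ = [
    "RankImage",
    "CycleTrace",
    "rank_image",
    "gate_barcode_positive",
    "iou_matrix",
    "cycle_reproducibility",
]


@dataclass
class RankImage:
    """Top-3 intensity planes (blue >= green >= red) plus argmax channel map."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    argmax_channel: np.ndarray
    dominance_fraction: float

    def rgb(self) -> np.ndarray:
        """(h, w, 3) float RGB composite for display, scaled to [0, 1]."""
        scale = max(float(self.blue.max()), 1e-12)
        return np.clip(
            np.dstack([self.red, self.green, self.blue]) / scale, 0.0, 1.0
        )


@dataclass
class CycleTrace:
    """Per-marker on/off cycle statistics.

    ``per_cycle`` columns: marker, cycle, intensity, on.  ``summary``
    columns: marker, on_mean, deviation (max relative deviation of later
    on-cycles from the first), carryover (mean off-cycle signal immediately
    after an on-cycle, as a fraction of on_mean), passed.
    """

    per_cycle: pd.DataFrame
    summary: pd.DataFrame
    bound: float = 0.20


def rank_image(
    planes: np.ndarray,
    dominance_ratio: float = 2.0,
    mask: np.ndarray | None = None,
) -> RankImage:
    """Rank reporter planes per pixel and composite the top three.

    ``planes`` is (n_planes, h, w) over every reporter channel of every
    cycle (n_planes >= 3).  Ties keep plane order (lowest plane wins the
    higher rank).  ``dominance_fraction`` is the fraction of (masked)
    pixels whose rank-1 intensity exceeds ``dominance_ratio`` times the
    rank-2 intensity — the quantitative version of "most pixels are blue".
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim != 3 or planes.shape[0] < 3:
        raise ValueError("need at least 3 reporter planes")
    # sort ascending then take the last three: argmax below handles tie order
    srt = np.sort(planes, axis=0)
    blue, green, red = srt[-1], srt[-2], srt[-3]
    argmax = np.argmax(planes, axis=0)  # first plane wins ties
    sel = np.ones(blue.shape, dtype=bool) if mask is None else mask.astype(bool)
    denom = np.maximum(green[sel], 1e-12)
    dominance = float(np.mean(blue[sel] >= dominance_ratio * denom)) if sel.any() else 0.0
    return RankImage(blue=blue, green=green, red=red, argmax_channel=argmax,
                     dominance_fraction=dominance)


def gate_barcode_positive(
    table: pd.DataFrame,
    channel: str,
    method: str = "gmm",
    threshold: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Cells positive for one barcode channel.

    Default: two-component Gaussian mixture on log1p intensity; positive =
    upper component at posterior > 0.5.  Falls back to Otsu with a warning
    when the distribution is degenerate (components collapse).  A fixed
    threshold is supported for exact reproducibility.
    """
    if channel not in table.columns:
        raise KeyError(f"unknown channel {channel!r}")
    if len(table) < 10:
        raise ValueError("need at least 10 cells to gate")
    x = table[channel].to_numpy(dtype=float)

    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed gating requires a threshold")
        return table[x > threshold].copy()

    lx = np.log1p(np.clip(x, 0, None))
    if np.ptp(lx) == 0:
        warnings.warn(f"{channel}: all intensities identical; gate is all-or-none")
        return table.iloc[0:0].copy()

    if method == "gmm":
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
        gm.fit(lx[:, None])
        means = gm.means_.ravel()
        if abs(means[0] - means[1]) < 0.25 * np.sqrt(gm.covariances_.ravel().mean()):
            warnings.warn(f"{channel}: unimodal distribution, falling back to Otsu")
            method = "otsu"
        else:
            upper = int(np.argmax(means))
            post = gm.predict_proba(lx[:, None])[:, upper]
            return table[post > 0.5].copy()
    if method == "otsu":
        thr = threshold_otsu(lx)
        return table[lx > thr].copy()
    raise ValueError(f"unknown gating method {method!r}")


def iou_matrix(cell_sets: dict[int, set] | dict[str, set]) -> pd.DataFrame:
    """Intersection-over-union between every pair of positive cell sets.

    Symmetric with unit diagonal; an empty union is defined as IoU 0 (with
    a warning) so heatmaps stay renderable.
    """
    keys = list(cell_sets)
    if len(keys) < 2:
        raise ValueError("need at least 2 cell sets")
    n = len(keys)
    mat = np.eye(n)
    warned = False
    for i in range(n):
        a = set(cell_sets[keys[i]])
        for j in range(i + 1, n):
            b = set(cell_sets[keys[j]])
            union = len(a | b)
            if union == 0:
                if not warned:
                    warnings.warn("empty union; IoU defined as 0")
                    warned = True
                v = 0.0
            else:
                v = len(a & b) / union
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=keys, columns=keys)


def cycle_reproducibility(
    traces: pd.DataFrame,
    schedule: pd.DataFrame,
    bound: float = 0.20,
) -> CycleTrace:
    """Quantify on/off cycle behavior of each marker against its schedule.

    ``traces``: one column per marker, one row per cycle (mean on-target
    intensity); ``schedule``: boolean frame of the same shape (True = the
    marker's reporter was added that cycle).

    For each marker: on_mean over on-cycles; deviation = the largest
    relative difference of later on-cycles from the first on-cycle (the
    signal of additional cycles relative to the initial one); carryover =
    mean intensity of off-cycles immediately following an on-cycle, as a
    fraction of on_mean (stripping efficiency).  ``passed`` is
    deviation <= bound.
    """
    if not traces.index.equals(schedule.index):
        raise ValueError("trace and schedule cycles differ")
    rows, summary = [], []
    for marker in traces.columns:
        if marker not in schedule.columns:
            raise ValueError(f"schedule does not cover marker {marker!r}")
        vals = traces[marker].to_numpy(dtype=float)
        on = schedule[marker].to_numpy(dtype=bool)
        if not on.any():
            raise ValueError(f"marker {marker!r} has no on-cycles")
        on_vals = vals[on]
        on_mean = float(on_vals.mean())
        first = on_vals[0]
        if first <= 0:
            raise ValueError(f"marker {marker!r}: first on-cycle signal is not positive")
        deviation = float(np.max(np.abs(on_vals - first)) / first)
        # off-cycles immediately following an on-cycle measure stripping
        after_on = np.zeros_like(on)
        after_on[1:] = on[:-1]
        strip_off = (~on) & after_on
        carryover = float(vals[strip_off].mean() / on_mean) if strip_off.any() else 0.0
        for cyc, v, flag in zip(traces.index, vals, on):
            rows.append({"marker": marker, "cycle": int(cyc),
                         "intensity": float(v), "on": bool(flag)})
        summary.append({
            "marker": marker, "on_mean": on_mean, "deviation": deviation,
            "carryover": carryover, "passed": deviation <= bound,
        })
    return CycleTrace(per_cycle=pd.DataFrame(rows),
                      summary=pd.DataFrame(summary), bound=bound)
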