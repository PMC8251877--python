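"""Multicycle image preprocessing: registration, background, stitching.

The stage drift between imaging cycles is modelled as a pure translation,
estimated on the nuclear channel (imaged every cycle) by windowed phase
cross-correlation with sub-pixel upsampling.  Background is removed by
subtracting registered blank-cycle images of the same fluor.  Overlapping
tiles are stitched with linear seam blending, optionally refining nominal
stage positions by pairwise phase correlation plus spanning-tree
accumulation.  Finally all cycles are concatenated into a single mosaic
with one plane per marker (nuclear plane kept once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.registration import phase_cross_correlation

from .stack_io import ChannelMap, TileGrid, TileStack

__all__ = [
    "DriftTable",
    "Mosaic",
    "estimate_drift",
    "apply_drift",
    "subtract_background",
    "deconvolve",
    "stitch",
    "concatenate",
    "process",
]


@dataclass
class DriftTable:
    """Per (cycle, tile) translation applied by the stage, in pixels.

    ``per_tile`` columns: cycle, tile, dy, dx, score.  ``per_cycle`` holds
    the median across tiles (robust to single-tile failures), used when a
    cycle is shifted jointly.
    """

    per_tile: pd.DataFrame
    reference_cycle: int = 1

    @property
    def per_cycle(self) -> dict[int, tuple[float, float]]:
        out = {}
        for cyc, grp in self.per_tile.groupby("cycle"):
            out[int(cyc)] = (float(grp["dy"].median()), float(grp["dx"].median()))
        return out

    def drift_for(self, cycle: int, tile: int) -> tuple[float, float]:
        row = self.per_tile[
            (self.per_tile["cycle"] == cycle) & (self.per_tile["tile"] == tile)
        ]
        if len(row) == 0:
            raise KeyError(f"no drift estimate for cycle {cycle}, tile {tile}")
        return float(row["dy"].iloc[0]), float(row["dx"].iloc[0])


@dataclass
class Mosaic:
    """Registered, concatenated field: ``data[plane, y, x]`` with names."""

    data: np.ndarray
    plane_names: list[str]
    channel_map: ChannelMap | None = None
    log: list[str] = field(default_factory=list)

    def plane(self, name: str) -> np.ndarray:
        try:
            return self.data[self.plane_names.index(name)]
        except ValueError:
            raise KeyError(f"no plane named {name!r}") from None

    def validate(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError("mosaic contains NaNs")
        if len(self.plane_names) != self.data.shape[0]:
            raise ValueError("plane name count != plane count")


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _phase_shift(reference: np.ndarray, moving: np.ndarray,
                 upsample: int = 20, window: bool = True):
    """Translation applied to produce `moving` from `reference`, plus a score.

    phase_cross_correlation returns the shift registering `moving` onto
    `reference`, i.e. the negative of the applied translation.
    """
    if window:
        w = _hann2d(reference.shape)
        ref, mov = reference * w, moving * w
    else:
        ref, mov = reference, moving
    shift, error, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample)
    score = float(np.clip(1.0 - error, 0.0, 1.0))
    return -shift[0], -shift[1], score


def estimate_drift(
    stack: TileStack,
    reference_cycle: int = 1,
    upsample: int = 20,
) -> DriftTable:
    """Estimate per-cycle stage drift from the nuclear channel of each tile.

    The estimate is per tile; downstream joint correction uses the per-cycle
    median across tiles.  Raises if the registration channel is empty.
    """
    rows = []
    for (cycle, tile) in sorted(stack.images):
        ref = stack.nuclear(reference_cycle, tile)
        mov = stack.nuclear(cycle, tile)
        if np.ptp(ref) == 0 or np.ptp(mov) == 0:
            raise ValueError(
                f"registration channel empty (cycle {cycle}, tile {tile})"
            )
        if cycle == reference_cycle:
            rows.append((cycle, tile, 0.0, 0.0, 1.0))
            continue
        dy, dx, score = _phase_shift(ref, mov, upsample=upsample)
        h, w = ref.shape
        if abs(dy) >= h / 4 or abs(dx) >= w / 4:
            warnings.warn(
                f"implausible drift ({dy:.1f}, {dx:.1f}) at cycle {cycle}, "
                f"tile {tile}; score {score:.2f}"
            )
        rows.append((cycle, tile, dy, dx, score))
    table = pd.DataFrame(rows, columns=["cycle", "tile", "dy", "dx", "score"])
    return DriftTable(per_tile=table, reference_cycle=reference_cycle)


def _translate(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    if dy == 0.0 and dx == 0.0:
        return img
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.zeros_like(img)
        iy, ix = int(dy), int(dx)
        h, w = img.shape
        ys0, ys1 = max(0, iy), min(h, h + iy)
        xs0, xs1 = max(0, ix), min(w, w + ix)
        out[ys0:ys1, xs0:xs1] = img[ys0 - iy : ys1 - iy, xs0 - ix : xs1 - ix]
        return out
    return ndi.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)


def apply_drift(stack: TileStack, drift: DriftTable, per_tile: bool = False) -> TileStack:
    """Undo the estimated drift; all channels of a cycle move jointly.

    Out-of-field pixels are filled with 0.  Zero drift is the identity
    (bit-equal).  ``per_tile=True`` uses each tile's own estimate instead of
    the per-cycle median.
    """
    out = stack.copy()
    per_cycle = drift.per_cycle
    for (cycle, tile), img in out.images.items():
        dy, dx = drift.drift_for(cycle, tile) if per_tile else per_cycle[cycle]
        if dy == 0.0 and dx == 0.0:
            continue
        for p in range(img.shape[0]):
            img[p] = _translate(img[p], -dy, -dx)
    out.log.append(f"apply_drift(reference_cycle={drift.reference_cycle}, per_tile={per_tile})")
    return out


def subtract_background(stack: TileStack, channel_map: ChannelMap | None = None) -> TileStack:
    """Subtract blank-cycle images from reporter channels of the same fluor.

    With blanks flanking a cycle, the per-pixel background is linearly
    interpolated by cycle index; otherwise the nearest blank is used.
    Results are clamped at zero.  Requires registration first.
    """
    cmap = channel_map or stack.channel_map
    out = stack.copy()
    blanks: dict[str, list[int]] = {f: cmap.blank_cycles_for_fluor(f) for f in cmap.fluors}
    for e in cmap.reporter_entries():
        bcyc = blanks[e.fluor]
        if not bcyc:
            raise ValueError(
                f"no blank cycle for fluor {e.fluor!r}; disable background "
                "subtraction explicitly if none was acquired"
            )
        p = cmap.plane_index(e.fluor)
        lower = [c for c in bcyc if c <= e.cycle]
        upper = [c for c in bcyc if c >= e.cycle]
        for tile in stack.tile_ids:
            if lower and upper:
                lo, hi = lower[-1], upper[0]
                if lo == hi:
                    bg = stack.plane(lo, tile, p)
                else:
                    t = (e.cycle - lo) / (hi - lo)
                    bg = (1 - t) * stack.plane(lo, tile, p) + t * stack.plane(hi, tile, p)
            else:
                near = min(bcyc, key=lambda c: abs(c - e.cycle))
                bg = stack.plane(near, tile, p)
            out.images[(e.cycle, tile)][p] = np.clip(
                stack.plane(e.cycle, tile, p) - bg, 0.0, None
            )
    out.log.append("subtract_background")
    return out


def deconvolve(image: np.ndarray, psf_sigma: float, iterations: int = 30) -> np.ndarray:
    """Richardson–Lucy deconvolution with an isotropic Gaussian PSF.

    Off by default in the pipeline.  Convolutions use reflective boundaries
    so a flat image is an exact fixed point and flux is conserved to within
    ~1%; the output is non-negative by construction.
    """
    if psf_sigma <= 0:
        raise ValueError("psf sigma must be positive")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    img = np.clip(image.astype(float), 0.0, None)
    if img.max() == 0:
        return img

    def blur(a: np.ndarray) -> np.ndarray:
        return ndi.gaussian_filter(a, psf_sigma, mode="reflect", truncate=4.0)

    eps = 1e-12
    est = img.copy()
    for _ in range(iterations):
        ratio = img / np.maximum(blur(est), eps)
        est = est * blur(ratio)  # Gaussian PSF is symmetric: mirror = itself
    return np.clip(est, 0.0, None)


def _ramp_weight(shape: tuple[int, int], margins: tuple[int, int, int, int]) -> np.ndarray:
    """Separable blend weight: linear 0->1 over each overlapped margin."""
    h, w = shape
    top, bottom, left, right = margins
    wy = np.ones(h)
    if top > 0:
        wy[:top] = (np.arange(top) + 1) / (top + 1)
    if bottom > 0:
        wy[h - bottom :] = ((np.arange(bottom) + 1) / (bottom + 1))[::-1]
    wx = np.ones(w)
    if left > 0:
        wx[:left] = (np.arange(left) + 1) / (left + 1)
    if right > 0:
        wx[w - right :] = ((np.arange(right) + 1) / (right + 1))[::-1]
    return np.outer(wy, wx)


def stitch(
    tiles: dict[int, np.ndarray],
    grid: TileGrid,
    refine: bool = False,
    register_plane: int = 0,
    upsample: int = 20,
) -> tuple[np.ndarray, dict[int, tuple[float, float]]]:
    """Assemble overlapping tiles into one mosaic with seam blending.

    ``tiles[t]`` is ``(c, h, w)`` (or ``(h, w)``).  Placement starts from
    nominal grid geometry; with ``refine`` the offsets are adjusted by phase
    correlation on neighbor overlaps (bounded by half the overlap) and made
    globally consistent by accumulating corrections over a spanning tree
    rooted at tile 0.  Returns the mosaic and the tile origins used.
    """
    tiles = {t: (img[None] if img.ndim == 2 else img) for t, img in tiles.items()}
    shapes = {img.shape for img in tiles.values()}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent tile shapes: {sorted(shapes)}")
    n_ch, th, tw = next(iter(shapes))
    if (th, tw) != grid.tile_shape:
        raise ValueError("tile shape does not match grid")
    oy, ox = grid.overlap_px()
    if refine and oy == 0 and ox == 0:
        raise ValueError("refinement requires overlapping tiles")

    origins = {t: tuple(map(float, grid.tile_origin(t))) for t in tiles}

    if refine and grid.n_tiles > 1:
        corrections = {0: (0.0, 0.0)}
        pending = [0]
        bound_y, bound_x = max(1.0, oy / 2), max(1.0, ox / 2)
        while pending:
            t = pending.pop(0)
            r, c = divmod(t, grid.cols)
            for (nr, nc) in ((r, c + 1), (r + 1, c), (r, c - 1), (r - 1, c)):
                if not (0 <= nr < grid.rows and 0 <= nc < grid.cols):
                    continue
                n = nr * grid.cols + nc
                if n in corrections:
                    continue
                delta = _pair_offset(tiles[t][register_plane], tiles[n][register_plane],
                                     origins[t], origins[n], (th, tw), upsample)
                if delta is None:
                    continue
                dy = float(np.clip(delta[0], -bound_y, bound_y))
                dx = float(np.clip(delta[1], -bound_x, bound_x))
                corrections[n] = (corrections[t][0] + dy, corrections[t][1] + dx)
                pending.append(n)
        for t in tiles:
            cy, cx = corrections.get(t, (0.0, 0.0))
            origins[t] = (origins[t][0] + cy, origins[t][1] + cx)

    H = int(np.ceil(max(o[0] for o in origins.values()) + th))
    W = int(np.ceil(max(o[1] for o in origins.values()) + tw))
    acc = np.zeros((n_ch, H, W))
    wacc = np.zeros((H, W))
    for t, img in tiles.items():
        r, c = divmod(t, grid.cols)
        margins = (oy if r > 0 else 0, oy if r < grid.rows - 1 else 0,
                   ox if c > 0 else 0, ox if c < grid.cols - 1 else 0)
        weight = _ramp_weight((th, tw), margins)
        yo, xo = origins[t]
        iy, ix = int(np.floor(yo)), int(np.floor(xo))
        fy, fx = yo - iy, xo - ix
        if fy or fx:
            img = np.stack([ndi.shift(img[p], (fy, fx), order=1, mode="nearest")
                            for p in range(n_ch)])
        y0, x0 = max(0, iy), max(0, ix)
        y1, x1 = min(H, iy + th), min(W, ix + tw)
        sy, sx = y0 - iy, x0 - ix
        acc[:, y0:y1, x0:x1] += img[:, sy : sy + (y1 - y0), sx : sx + (x1 - x0)] * \
            weight[sy : sy + (y1 - y0), sx : sx + (x1 - x0)]
        wacc[y0:y1, x0:x1] += weight[sy : sy + (y1 - y0), sx : sx + (x1 - x0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        mosaic = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0)
    return mosaic, origins


def _pair_offset(tile_a, tile_b, origin_a, origin_b, shape, upsample):
    """Correction (dy, dx) to add to tile_b's origin so it matches tile_a."""
    th, tw = shape
    ay, ax = origin_a
    by, bx = origin_b
    y0, y1 = int(max(ay, by)), int(min(ay + th, by + th))
    x0, x1 = int(max(ax, bx)), int(min(ax + tw, bx + tw))
    if y1 - y0 < 8 or x1 - x0 < 8:
        return None
    sub_a = tile_a[int(y0 - ay) : int(y1 - ay), int(x0 - ax) : int(x1 - ax)]
    sub_b = tile_b[int(y0 - by) : int(y1 - by), int(x0 - bx) : int(x1 - bx)]
    if np.ptp(sub_a) == 0 or np.ptp(sub_b) == 0:
        return None
    dy, dx, _ = _phase_shift(sub_a, sub_b, upsample=upsample)
    # content of b appears shifted by (dy, dx) relative to a: move b back
    return (-dy, -dx)


def concatenate(
    cycle_mosaics: dict[int, np.ndarray],
    channel_map: ChannelMap,
    reference_cycle: int = 1,
) -> Mosaic:
    """Concatenate registered cycles into one plane-per-marker mosaic.

    Plane order: nuclear (taken once, from the reference cycle) then the
    non-blank markers in channel-map order; blank planes are dropped.
    """
    markers = channel_map.markers()
    if len(markers) != len(set(markers)):
        raise ValueError("duplicate marker names in channel map")
    planes = [cycle_mosaics[reference_cycle][0]]
    names = [channel_map.nuclear_channel]
    for cyc in range(1, channel_map.n_cycles + 1):
        for e in channel_map.entries_for_cycle(cyc):
            if e.blank:
                continue
            planes.append(cycle_mosaics[cyc][channel_map.plane_index(e.fluor)])
            names.append(e.marker)
    data = np.stack(planes)
    m = Mosaic(data=data, plane_names=names, channel_map=channel_map,
               log=[f"concatenate(reference_cycle={reference_cycle})"])
    m.validate()
    return m


def process(
    stack: TileStack,
    refine_stitch: bool = False,
    background: bool = True,
    deconvolve_sigma: float = 0.0,
    deconvolve_iterations: int = 30,
    reference_cycle: int = 1,
) -> tuple[Mosaic, DriftTable]:
    """Full preprocessing chain: register -> subtract -> stitch -> concatenate."""
    drift = estimate_drift(stack, reference_cycle=reference_cycle)
    registered = apply_drift(stack, drift)
    if background:
        registered = subtract_background(registered)
    if deconvolve_sigma > 0:
        for key, img in registered.images.items():
            for p in range(img.shape[0]):
                img[p] = deconvolve(img[p], deconvolve_sigma, deconvolve_iterations)
        registered.log.append(f"deconvolve(sigma={deconvolve_sigma})")
    cycle_mosaics = {}
    for cyc in range(1, stack.n_cycles + 1):
        tiles = {t: registered.images[(cyc, t)] for t in registered.tile_ids}
        cycle_mosaics[cyc], _ = stitch(tiles, stack.grid, refine=refine_stitch)
    mosaic = concatenate(cycle_mosaics, stack.channel_map, reference_cycle)
    mosaic.log = registered.log + mosaic.log
    return mosaic, drift
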