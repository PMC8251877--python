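"""Synthetic multicycle imaging phantoms with complete ground truth.

The phantom emulates what a cyclic DNA-barcoded immunofluorescence run
produces: per cycle one nuclear plane (the registration channel, present in
every cycle) plus up to three reporter planes, tiled with overlap, with
inter-cycle stage drift, additive background, optical blur, sensor noise,
blank (no-reporter) slots, and optional barcode cross-talk.

Cells are rendered as disks (nucleus) with an annular membrane; a cell's
reporter intensity is its type's expected expression for the marker carried
by that (cycle, fluor) slot.  Sub-pixel drift is applied in the Fourier
domain so the ground-truth drift table is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .stack_io import (
    ChannelEntry,
    ChannelMap,
    TileGrid,
    TileStack,
    DEFAULT_FLUORS,
    MAX_REPORTERS_PER_CYCLE,
)

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_tissue_phantom",
    "generate_singlet_spread",
    "generate_on_off_schedule",
    "generate_colocalization_points",
    "singlet_channel_map",
    "default_cell_types",
    "write_phantom",
]


def default_cell_types() -> dict[str, dict[str, float]]:
    """Expected marker expression (arbitrary units) for five lymphoid types.

    CD45 is a pan-immune membrane marker; each type additionally carries one
    defining lineage marker, mirroring a minimal tonsil-like panel.
    """
    return {
        "Tcell": {"CD3": 100.0, "CD45": 80.0},
        "Bcell": {"CD19": 100.0, "CD45": 80.0},
        "Macrophage": {"CD68": 100.0, "CD45": 80.0},
        "Epithelial": {"Cytokeratin": 100.0},
        "Stromal": {"CD90": 100.0},
    }


@dataclass
class PhantomConfig:
    """Generator settings; the defaults are the standard small phantom.

    ``drift`` is the per-cycle translation (dy, dx) of the stage relative to
    cycle 1; sub-pixel values allowed.  ``crosstalk`` maps
    ``(source barcode, destination barcode) -> leaked fraction``: cells
    carrying the source barcode light up in the destination's channel at
    that fraction of their source signal.
    """

    tile_shape: tuple[int, int] = (200, 200)
    grid: tuple[int, int] = (2, 2)  # rows, cols
    overlap: float = 0.1
    pixel_size_um: float = 0.5
    n_cycles: int = 3
    n_cells: int = 150
    cell_types: dict[str, dict[str, float]] = field(default_factory=default_cell_types)
    type_frequencies: dict[str, float] | None = None
    positions: np.ndarray | None = None  # fixed (n, 2) (y, x); else random
    min_spacing: float = 15.0
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 0.8
    membrane_width: float = 2.0
    membrane_markers: frozenset = frozenset({"CD45"})
    nuclear_intensity: float = 150.0
    drift: list[tuple[float, float]] | None = None  # per cycle, cycle 1 first
    background: float | dict[str, float] = 8.0
    blur_sigma: float = 1.0
    noise: str = "gaussian"  # or "poisson"
    noise_sd: float = 3.0
    crosstalk: dict[tuple[int, int], float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("cell count must be >= 0")
        if not (0.0 <= self.overlap < 0.5):
            raise ValueError("overlap fraction must be in [0, 0.5)")
        for t, profile in self.cell_types.items():
            for m, v in profile.items():
                if v < 0:
                    raise ValueError(f"negative intensity for {t}/{m}")
        for (i, j), frac in self.crosstalk.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"cross-talk fraction {frac} for {(i, j)} not in [0, 1]")
        h, w = self.mosaic_shape()
        if self.drift is not None:
            for dy, dx in self.drift:
                if abs(dy) >= h / 4 or abs(dx) >= w / 4:
                    raise ValueError("drift magnitude must stay below field size / 4")
        if self.noise not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    def tile_grid(self) -> TileGrid:
        return TileGrid(
            rows=self.grid[0],
            cols=self.grid[1],
            overlap=self.overlap,
            tile_shape=self.tile_shape,
        )

    def mosaic_shape(self) -> tuple[int, int]:
        return self.tile_grid().mosaic_shape()

    def background_for(self, fluor: str) -> float:
        if isinstance(self.background, dict):
            return float(self.background.get(fluor, 0.0))
        return float(self.background)


@dataclass
class PhantomTruth:
    """Ground truth: one row per cell plus the applied per-cycle drift.

    ``cells`` columns: id (dense from 1), y, x (mosaic px), radius (nucleus,
    px), type, and one column per marker with the cell's true mean reporter
    intensity.  ``drift`` columns: cycle, dy, dx.  ``background`` maps
    channel name -> additive level.
    """

    cells: pd.DataFrame
    drift: pd.DataFrame
    background: dict[str, float]
    mosaic_shape: tuple[int, int]

    def validate(self) -> None:
        if len(self.cells):
            ids = self.cells["id"].to_numpy()
            if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
                raise ValueError("truth cell ids must be dense from 1")
            h, w = self.mosaic_shape
            if ((self.cells["y"] < 0) | (self.cells["y"] >= h)).any() or (
                (self.cells["x"] < 0) | (self.cells["x"] >= w)
            ).any():
                raise ValueError("truth cell outside the mosaic")


# ---------------------------------------------------------------------------
# channel-map construction
# ---------------------------------------------------------------------------

def _tissue_channel_map(config: PhantomConfig) -> ChannelMap:
    """Markers row-major over (cycle, fluor) slots; trailing slots blank.

    The last cycle is kept reporter-free when the marker count allows, so
    every fluor has a blank cycle for background subtraction.
    """
    markers = sorted({m for prof in config.cell_types.values() for m in prof})
    fluors = DEFAULT_FLUORS
    n_slots = config.n_cycles * len(fluors)
    if len(markers) > n_slots - len(fluors):
        # no room for a blank cycle; fill what we can
        if len(markers) > n_slots:
            raise ValueError(
                f"{len(markers)} markers need more than {config.n_cycles} cycles"
            )
    entries = []
    mi = 0
    barcode = 1
    for cyc in range(1, config.n_cycles + 1):
        for fluor in fluors:
            last_cycle_blank = cyc == config.n_cycles and len(markers) <= n_slots - len(fluors)
            if mi < len(markers) and not last_cycle_blank:
                entries.append(
                    ChannelEntry(cycle=cyc, fluor=fluor, marker=markers[mi],
                                 barcode=barcode, exposure=0.1)
                )
                mi += 1
                barcode += 1
            else:
                entries.append(ChannelEntry(cycle=cyc, fluor=fluor, blank=True))
    return ChannelMap(entries=entries, pixel_size_um=config.pixel_size_um)


def singlet_channel_map(n_barcodes: int, pixel_size_um: float = 0.5) -> ChannelMap:
    """One barcode per (cycle, fluor) slot, <=3 per cycle, plus a blank cycle."""
    fluors = list(DEFAULT_FLUORS)
    n_cycles = math.ceil(n_barcodes / MAX_REPORTERS_PER_CYCLE)
    entries = []
    bc = 1
    for cyc in range(1, n_cycles + 1):
        for fluor in fluors:
            if bc <= n_barcodes:
                entries.append(
                    ChannelEntry(cycle=cyc, fluor=fluor, marker=f"BC{bc:02d}",
                                 barcode=bc, exposure=0.1)
                )
                bc += 1
            else:
                entries.append(ChannelEntry(cycle=cyc, fluor=fluor, blank=True))
    # trailing blank cycle so background subtraction has a reference
    final = n_cycles + 1
    for fluor in fluors:
        entries.append(ChannelEntry(cycle=final, fluor=fluor, blank=True))
    return ChannelMap(entries=entries, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _place_cells(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Random centers with minimum spacing; bounded rejection sampling."""
    if config.positions is not None:
        pos = np.asarray(config.positions, dtype=float)
        if pos.shape != (config.n_cells, 2):
            raise ValueError("positions must be (n_cells, 2)")
        return pos
    h, w = config.mosaic_shape()
    margin = config.nucleus_radius_mean + config.membrane_width + 2
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("field too small for the configured cell size")
    if config.n_cells == 0:
        return np.empty((0, 2), dtype=float)
    placed: list[tuple[float, float]] = []
    max_attempts = max(1000, 300 * config.n_cells)
    attempts = 0
    d2min = config.min_spacing**2
    while len(placed) < config.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_cells} cells with minimum spacing "
                f"{config.min_spacing} px in a {h}x{w} field after "
                f"{max_attempts} attempts; requested density is infeasible"
            )
        attempts += 1
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        if all((y - py) ** 2 + (x - px) ** 2 >= d2min for py, px in placed):
            placed.append((y, x))
    return np.asarray(placed, dtype=float)


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, r: float) -> tuple:
    """Slices + boolean disk for a circle, clipped to the image."""
    h, w = shape
    y0, y1 = max(0, int(np.floor(cy - r - 1))), min(h, int(np.ceil(cy + r + 2)))
    x0, x1 = max(0, int(np.floor(cx - r - 1))), min(w, int(np.ceil(cx + r + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return (slice(y0, y1), slice(x0, x1)), mask


def _paint(plane: np.ndarray, cy: float, cx: float, r: float, value: float,
           inner_r: float | None = None) -> None:
    h, w = plane.shape
    y0, y1 = max(0, int(np.floor(cy - r - 1))), min(h, int(np.ceil(cy + r + 2)))
    x0, x1 = max(0, int(np.floor(cx - r - 1))), min(w, int(np.ceil(cx + r + 2)))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    mask = d2 <= r**2
    if inner_r is not None:
        mask &= d2 > inner_r**2
    plane[y0:y1, x0:x1][mask] += value


def _fourier_translate(plane: np.ndarray, dy: float, dx: float) -> np.ndarray:
    if dy == 0 and dx == 0:
        return plane
    out = np.fft.ifft2(ndi.fourier_shift(np.fft.fft2(plane), (dy, dx))).real
    return np.clip(out, 0, None)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render(
    config: PhantomConfig,
    cmap: ChannelMap,
    cells: pd.DataFrame,
    rng: np.random.Generator,
) -> TileStack:
    """Render per-cycle mosaics from the truth table, then cut tiles."""
    grid = config.tile_grid()
    H, W = grid.mosaic_shape()
    drift = config.drift or [(0.0, 0.0)] * cmap.n_cycles
    marker_cols = [c for c in cells.columns if c not in ("id", "y", "x", "radius", "type", "barcode")]

    # ideal (pre-background) image per marker, painted once and reused
    ideal: dict[str, np.ndarray] = {}
    for m in marker_cols:
        plane = np.zeros((H, W))
        vals = cells[m].to_numpy()
        for i in range(len(cells)):
            if vals[i] <= 0:
                continue
            cy, cx, r = cells["y"].iat[i], cells["x"].iat[i], cells["radius"].iat[i]
            if m in config.membrane_markers:
                _paint(plane, cy, cx, r + config.membrane_width, vals[i], inner_r=r)
            else:
                _paint(plane, cy, cx, r + config.membrane_width, vals[i])
        ideal[m] = plane

    nuclear_ideal = np.zeros((H, W))
    for i in range(len(cells)):
        _paint(nuclear_ideal, cells["y"].iat[i], cells["x"].iat[i],
               cells["radius"].iat[i], config.nuclear_intensity)

    bc_to_marker = {e.barcode: e.marker for e in cmap.reporter_entries()}

    images: dict[tuple[int, int], np.ndarray] = {}
    n_planes = cmap.n_planes_per_cycle
    for cyc in range(1, cmap.n_cycles + 1):
        mosaic = np.zeros((n_planes, H, W))
        mosaic[0] = nuclear_ideal
        for e in cmap.entries_for_cycle(cyc):
            p = cmap.plane_index(e.fluor)
            if not e.blank:
                mosaic[p] = ideal[e.marker].copy()
                for (src, dst), frac in config.crosstalk.items():
                    if dst == e.barcode and src in bc_to_marker:
                        mosaic[p] += frac * ideal[bc_to_marker[src]]
        if config.blur_sigma > 0:
            for p in range(n_planes):
                mosaic[p] = ndi.gaussian_filter(mosaic[p], config.blur_sigma)
        mosaic[0] += config.background_for(cmap.nuclear_channel)
        for fluor in cmap.fluors:
            mosaic[cmap.plane_index(fluor)] += config.background_for(fluor)
        dy, dx = drift[cyc - 1]
        if dy or dx:
            for p in range(n_planes):
                mosaic[p] = _fourier_translate(mosaic[p], dy, dx)
        if config.noise == "gaussian" and config.noise_sd > 0:
            mosaic += rng.normal(0.0, config.noise_sd, mosaic.shape)
        elif config.noise == "poisson":
            mosaic = rng.poisson(np.clip(mosaic, 0, None)).astype(float)
        mosaic = np.clip(mosaic, 0.0, 65535.0)

        th, tw = grid.tile_shape
        for t in range(grid.n_tiles):
            oy, ox = grid.tile_origin(t)
            images[(cyc, t)] = mosaic[:, oy : oy + th, ox : ox + tw].copy()

    return TileStack(images=images, channel_map=cmap, grid=grid)


def _truth_frame(
    config: PhantomConfig,
    cmap: ChannelMap,
    positions: np.ndarray,
    radii: np.ndarray,
    types: list[str],
    profiles: list[dict[str, float]],
    barcodes: np.ndarray | None = None,
) -> PhantomTruth:
    markers = cmap.markers()
    rows = {
        "id": np.arange(1, len(positions) + 1),
        "y": positions[:, 0],
        "x": positions[:, 1],
        "radius": radii,
        "type": types,
    }
    for m in markers:
        rows[m] = np.array([p.get(m, 0.0) for p in profiles])
    cells = pd.DataFrame(rows)
    if barcodes is not None:
        cells["barcode"] = barcodes
    drift = config.drift or [(0.0, 0.0)] * cmap.n_cycles
    drift_df = pd.DataFrame(
        {"cycle": np.arange(1, cmap.n_cycles + 1),
         "dy": [d[0] for d in drift[: cmap.n_cycles]],
         "dx": [d[1] for d in drift[: cmap.n_cycles]]}
    )
    background = {cmap.nuclear_channel: config.background_for(cmap.nuclear_channel)}
    for f in cmap.fluors:
        background[f] = config.background_for(f)
    truth = PhantomTruth(
        cells=cells, drift=drift_df, background=background,
        mosaic_shape=config.mosaic_shape(),
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_tissue_phantom(
    config: PhantomConfig | None = None,
    channel_map: ChannelMap | None = None,
) -> tuple[TileStack, PhantomTruth]:
    """Tissue-like phantom: mixed cell types at random positions.

    Deterministic for a fixed ``config.seed``.  Returns the tiled multicycle
    stack (float arrays, 16-bit range) and the ground truth.
    """
    config = config or PhantomConfig()
    config.validate()
    cmap = channel_map or _tissue_channel_map(config)
    rng = np.random.default_rng(config.seed)

    positions = _place_cells(config, rng)
    radii = np.clip(
        rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, config.n_cells),
        1.5, None,
    )
    type_names = list(config.cell_types)
    if config.type_frequencies:
        p = np.array([config.type_frequencies.get(t, 0.0) for t in type_names])
        p = p / p.sum()
    else:
        p = np.full(len(type_names), 1.0 / len(type_names))
    types = [type_names[i] for i in rng.choice(len(type_names), config.n_cells, p=p)]
    profiles = [config.cell_types[t] for t in types]

    truth = _truth_frame(config, cmap, positions, radii, types, profiles)
    stack = _render(config, cmap, truth.cells, rng)
    return stack, truth


def generate_singlet_spread(
    config: PhantomConfig | None = None,
    n_barcodes: int = 59,
) -> tuple[TileStack, PhantomTruth]:
    """Pooled singlet spread: every cell carries exactly one barcode.

    Emulates pooling aliquots of cells each stained with the same antibody
    carrying a different barcode; each cell is positive in exactly one
    reporter channel (before cross-talk).  Barcodes are revealed at most
    three per cycle over ``ceil(n_barcodes / 3)`` reporter-bearing cycles.
    """
    if n_barcodes <= 0:
        raise ValueError("n_barcodes must be positive")
    config = config or PhantomConfig()
    config.validate()
    cmap = singlet_channel_map(n_barcodes, config.pixel_size_um)
    rng = np.random.default_rng(config.seed)

    positions = _place_cells(config, rng)
    radii = np.clip(
        rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd, config.n_cells),
        1.5, None,
    )
    barcodes = rng.integers(1, n_barcodes + 1, config.n_cells)
    intensity = 100.0
    types = [f"BC{b:02d}" for b in barcodes]
    profiles = [{f"BC{b:02d}": intensity} for b in barcodes]

    # singlet cells are stained on the membrane-bound CD45; paint whole cell
    cfg = replace(config, membrane_markers=frozenset(),
                  drift=config.drift or [(0.0, 0.0)] * cmap.n_cycles)
    truth = _truth_frame(cfg, cmap, positions, radii, types, profiles,
                         barcodes=barcodes)
    stack = _render(cfg, cmap, truth.cells, rng)
    return stack, truth


def generate_colocalization_points(
    shape: tuple[int, int] = (1000, 1000),
    n_per_type: int = 900,
    n_hotspots: int = 8,
    hotspot_sd: float = 60.0,
    exclusion_radius: float = 150.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Point pattern with a co-localized module and a spatially excluded type.

    Types ``A`` and ``B`` are planted in the same randomly placed hotspots
    (sharing local density gradients, like cell types of one
    micro-anatomical module); type ``C`` fills the complementary area,
    kept away from every hotspot.  Returns a centroid cell table with a
    ``cluster`` column, ready for windowed density analysis.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = min(h, w) * 0.1
    hot = np.column_stack([
        rng.uniform(margin, h - margin, n_hotspots),
        rng.uniform(margin, w - margin, n_hotspots),
    ])

    def around(n: int) -> np.ndarray:
        c = hot[rng.integers(0, n_hotspots, n)]
        return np.clip(c + rng.normal(0, hotspot_sd, (n, 2)),
                       0, [h - 1, w - 1])

    a, b = around(n_per_type), around(n_per_type)
    c_pts: list[list[float]] = []
    while len(c_pts) < n_per_type:
        cand = np.column_stack([rng.uniform(0, h, 4 * n_per_type),
                                rng.uniform(0, w, 4 * n_per_type)])
        d = np.min(np.linalg.norm(cand[:, None, :] - hot[None], axis=2), axis=1)
        c_pts.extend(cand[d > exclusion_radius].tolist())
    c = np.array(c_pts[:n_per_type])

    pts = np.vstack([a, b, c])
    labels = ["A"] * n_per_type + ["B"] * n_per_type + ["C"] * n_per_type
    return pd.DataFrame({
        "id": np.arange(1, len(pts) + 1),
        "y_px": pts[:, 0],
        "x_px": pts[:, 1],
        "cluster": labels,
    })


def generate_on_off_schedule(n_cycles: int, markers: list[str]) -> pd.DataFrame:
    """Repeating 4-cycle reveal pattern {A, B, A+B, none} for two markers.

    Returns a boolean frame indexed by cycle (1-based) with one column per
    marker; e.g. 16 cycles = 4 blocks, each marker on in 8 cycles.
    """
    if len(markers) != 2:
        raise ValueError("the on/off pattern is defined for exactly 2 markers")
    if n_cycles <= 0 or n_cycles % 4 != 0:
        raise ValueError("n_cycles must be a positive multiple of 4")
    a, b = markers
    block = [(True, False), (False, True), (True, True), (False, False)]
    flags = [block[(c - 1) % 4] for c in range(1, n_cycles + 1)]
    return pd.DataFrame(flags, columns=[a, b], index=pd.RangeIndex(1, n_cycles + 1, name="cycle"))


def write_phantom(directory, stack: TileStack, truth: PhantomTruth) -> None:
    """Write tiles + experiment YAML + truth/drift CSVs."""
    from .stack_io import write_experiment
    from pathlib import Path

    directory = Path(directory)
    write_experiment(directory, stack)
    truth.cells.to_csv(directory / "truth_cells.csv", index=False)
    truth.drift.to_csv(directory / "truth_drift.csv", index=False)
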