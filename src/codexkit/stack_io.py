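"""On-disk formats for multicycle imaging experiments.

A multicycle experiment is a directory of multichannel TIFF tiles named
``cyc{CC}_tile{TTT}.tif`` (channel order: nuclear first, then the reporter
fluors in a fixed order), plus an experiment YAML describing the channel map
and the tile grid.  Segmented cells are exchanged as CSV or FCS 3.1 tables.

Pixel conventions: 0-based, half-open indexing, origin top-left, ``y`` down
and ``x`` right.  Millimetre coordinates appear only in exported cell tables
(``mm = px * pixel_size_um / 1000``).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelEntry",
    "ChannelMap",
    "TileGrid",
    "TileStack",
    "CELLTABLE_BASE_COLUMNS",
    "marker_columns",
    "make_cell_table",
    "read_experiment",
    "write_experiment",
    "write_cell_table",
    "read_cell_table",
    "read_fcs",
    "tile_filename",
]

#: Fluor channels a reporter oligonucleotide can carry, in plane order.
DEFAULT_FLUORS = ("FAM", "Cy3", "Cy5")

#: Maximum number of reporter-bearing channels per imaging cycle.
MAX_REPORTERS_PER_CYCLE = 3

#: Calibrated per-antibody exposure range, seconds.
EXPOSURE_RANGE = (0.01, 10.0)

CELLTABLE_BASE_COLUMNS = ["id", "tile", "x_px", "y_px", "x_mm", "y_mm", "area_px"]


def tile_filename(cycle: int, tile: int) -> str:
    return f"cyc{cycle:02d}_tile{tile:03d}.tif"


@dataclass(frozen=True)
class ChannelEntry:
    """One (cycle, fluor) slot: either a reporter for a marker or a blank."""

    cycle: int  # 1-based
    fluor: str
    marker: str = ""
    barcode: int | None = None
    exposure: float = 0.1
    blank: bool = False


@dataclass
class ChannelMap:
    """Assignment of (cycle, fluor) slots to markers/barcodes.

    The nuclear channel is imaged in every cycle and is always plane 0 of a
    cycle's TIFF; reporter fluors follow in ``fluors`` order.  Every
    (cycle, fluor) slot must be listed, either as a reporter entry or as an
    explicit blank.
    """

    entries: list[ChannelEntry]
    pixel_size_um: float = 0.5
    nuclear_channel: str = "Hoechst"
    fluors: tuple[str, ...] = DEFAULT_FLUORS

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.entries:
            raise ValueError("channel map has no entries")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        seen_slots: set[tuple[int, str]] = set()
        seen_markers: set[str] = set()
        per_cycle_reporters: dict[int, int] = {}
        for e in self.entries:
            if e.fluor not in self.fluors:
                raise ValueError(f"unknown fluor {e.fluor!r}")
            if e.fluor == self.nuclear_channel:
                raise ValueError("nuclear channel cannot carry a reporter")
            slot = (e.cycle, e.fluor)
            if slot in seen_slots:
                raise ValueError(f"duplicate (cycle, fluor) slot {slot}")
            seen_slots.add(slot)
            if not e.blank:
                per_cycle_reporters[e.cycle] = per_cycle_reporters.get(e.cycle, 0) + 1
                if e.marker in seen_markers:
                    raise ValueError(f"marker {e.marker!r} listed twice")
                seen_markers.add(e.marker)
                lo, hi = EXPOSURE_RANGE
                if not (lo <= e.exposure <= hi):
                    raise ValueError(
                        f"exposure {e.exposure} s for {e.marker!r} outside [{lo}, {hi}]"
                    )
        for cyc, n in per_cycle_reporters.items():
            if n > MAX_REPORTERS_PER_CYCLE:
                raise ValueError(
                    f"cycle {cyc} carries {n} reporters; at most "
                    f"{MAX_REPORTERS_PER_CYCLE} fluorescent reporters per cycle"
                )

    # -- accessors --------------------------------------------------------
    @property
    def n_cycles(self) -> int:
        return max(e.cycle for e in self.entries)

    @property
    def n_planes_per_cycle(self) -> int:
        return 1 + len(self.fluors)

    def entries_for_cycle(self, cycle: int) -> list[ChannelEntry]:
        ents = [e for e in self.entries if e.cycle == cycle]
        return sorted(ents, key=lambda e: self.fluors.index(e.fluor))

    def plane_index(self, fluor: str) -> int:
        """Plane index of a fluor within one cycle's image (0 = nuclear)."""
        return 1 + self.fluors.index(fluor)

    def markers(self) -> list[str]:
        """Non-blank marker names, cycle order then fluor order."""
        out = []
        for c in range(1, self.n_cycles + 1):
            for e in self.entries_for_cycle(c):
                if not e.blank:
                    out.append(e.marker)
        return out

    def reporter_entries(self) -> list[ChannelEntry]:
        return [e for e in self.entries if not e.blank]

    def blank_cycles_for_fluor(self, fluor: str) -> list[int]:
        return sorted(e.cycle for e in self.entries if e.blank and e.fluor == fluor)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pixel_size_um": float(self.pixel_size_um),
            "nuclear_channel": self.nuclear_channel,
            "fluors": list(self.fluors),
            "channels": [
                {
                    "cycle": e.cycle,
                    "fluor": e.fluor,
                    "marker": e.marker,
                    "barcode": e.barcode,
                    "exposure": float(e.exposure),
                    "blank": bool(e.blank),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMap":
        entries = [
            ChannelEntry(
                cycle=int(c["cycle"]),
                fluor=str(c["fluor"]),
                marker=str(c.get("marker", "")),
                barcode=c.get("barcode"),
                exposure=float(c.get("exposure", 0.1)),
                blank=bool(c.get("blank", False)),
            )
            for c in d["channels"]
        ]
        return cls(
            entries=entries,
            pixel_size_um=float(d.get("pixel_size_um", 0.5)),
            nuclear_channel=str(d.get("nuclear_channel", "Hoechst")),
            fluors=tuple(d.get("fluors", DEFAULT_FLUORS)),
        )


@dataclass(frozen=True)
class TileGrid:
    rows: int = 1
    cols: int = 1
    overlap: float = 0.0  # fraction of tile size shared with each neighbor
    order: str = "row-major"  # or "serpentine"
    tile_shape: tuple[int, int] = (200, 200)  # (h, w) px

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not (0.0 <= self.overlap < 0.5):
            raise ValueError("overlap fraction must be in [0, 0.5)")
        if self.order not in ("row-major", "serpentine"):
            raise ValueError(f"unknown acquisition order {self.order!r}")

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def overlap_px(self) -> tuple[int, int]:
        h, w = self.tile_shape
        return int(round(self.overlap * h)), int(round(self.overlap * w))

    def mosaic_shape(self) -> tuple[int, int]:
        h, w = self.tile_shape
        oy, ox = self.overlap_px()
        return (self.rows * h - (self.rows - 1) * oy,
                self.cols * w - (self.cols - 1) * ox)

    def tile_origin(self, tile: int) -> tuple[int, int]:
        """Nominal top-left mosaic pixel of a tile (0-based tile index)."""
        r, c = divmod(tile, self.cols)
        if self.order == "serpentine" and r % 2 == 1:
            c = self.cols - 1 - c
        h, w = self.tile_shape
        oy, ox = self.overlap_px()
        return r * (h - oy), c * (w - ox)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "overlap": float(self.overlap),
            "order": self.order,
            "tile_shape": list(self.tile_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TileGrid":
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            overlap=float(d.get("overlap", 0.0)),
            order=str(d.get("order", "row-major")),
            tile_shape=tuple(d.get("tile_shape", (200, 200))),
        )


@dataclass
class TileStack:
    """All images of one experiment: ``images[(cycle, tile)] -> (c, h, w)``.

    Cycle indices are 1-based; tile indices 0-based row-major.  Arrays are
    float internally; integer TIFFs are promoted on read.
    """

    images: dict[tuple[int, int], np.ndarray]
    channel_map: ChannelMap
    grid: TileGrid
    log: list[str] = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.channel_map.n_cycles

    @property
    def tile_ids(self) -> list[int]:
        return sorted({t for (_, t) in self.images})

    def plane(self, cycle: int, tile: int, plane: int) -> np.ndarray:
        return self.images[(cycle, tile)][plane]

    def nuclear(self, cycle: int, tile: int) -> np.ndarray:
        return self.plane(cycle, tile, 0)

    def copy(self) -> "TileStack":
        return TileStack(
            images={k: v.copy() for k, v in self.images.items()},
            channel_map=self.channel_map,
            grid=self.grid,
            log=list(self.log),
        )


# ---------------------------------------------------------------------------
# experiment directory I/O
# ---------------------------------------------------------------------------

def write_experiment(
    directory: str | Path,
    stack: TileStack,
    dtype=np.uint16,
) -> None:
    """Write a TileStack as 16-bit TIFF tiles plus an experiment YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    info = np.iinfo(dtype)
    for (cycle, tile), img in stack.images.items():
        arr = np.clip(np.rint(img), info.min, info.max).astype(dtype)
        tifffile.imwrite(directory / tile_filename(cycle, tile), arr,
                         photometric="minisblack")
    meta = {"channel_map": stack.channel_map.to_dict(), "grid": stack.grid.to_dict()}
    with open(directory / "experiment.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_experiment(
    directory: str | Path,
    channel_map_path: str | Path | None = None,
) -> TileStack:
    """Load a tiled multicycle experiment, checking layout completeness.

    Every (cycle, tile) file implied by the channel map and the grid must be
    present with a consistent shape; a gap raises naming the missing file.
    """
    directory = Path(directory)
    if channel_map_path is None:
        channel_map_path = directory / "experiment.yaml"
    with open(channel_map_path) as fh:
        meta = yaml.safe_load(fh)
    cmap = ChannelMap.from_dict(meta["channel_map"] if "channel_map" in meta else meta)
    grid = TileGrid.from_dict(meta["grid"]) if "grid" in meta else TileGrid()

    images: dict[tuple[int, int], np.ndarray] = {}
    expected_planes = cmap.n_planes_per_cycle
    shape: tuple[int, ...] | None = None
    missing = []
    for cycle in range(1, cmap.n_cycles + 1):
        for tile in range(grid.n_tiles):
            path = directory / tile_filename(cycle, tile)
            if not path.exists():
                missing.append(path.name)
                continue
            arr = tifffile.imread(path)
            if arr.ndim == 2:
                arr = arr[None]
            if arr.shape[0] != expected_planes:
                raise ValueError(
                    f"{path.name}: {arr.shape[0]} channels, channel map "
                    f"implies {expected_planes}"
                )
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(f"{path.name}: shape {arr.shape} != {shape}")
            images[(cycle, tile)] = arr.astype(np.float64)
    if missing:
        raise FileNotFoundError(
            "experiment directory has gaps: missing " + ", ".join(missing)
        )
    return TileStack(images=images, channel_map=cmap, grid=grid)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker intensity columns of a cell table (everything non-structural)."""
    skip = set(CELLTABLE_BASE_COLUMNS) | {"cluster", "region", "type", "barcode"}
    return [c for c in table.columns if c not in skip]


def make_cell_table(
    ids: np.ndarray,
    y_px: np.ndarray,
    x_px: np.ndarray,
    area_px: np.ndarray,
    intensities: dict[str, np.ndarray],
    pixel_size_um: float,
    tile: np.ndarray | int = 0,
) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=int),
            "tile": tile,
            "x_px": np.asarray(x_px, dtype=float),
            "y_px": np.asarray(y_px, dtype=float),
            "x_mm": np.asarray(x_px, dtype=float) * pixel_size_um / 1000.0,
            "y_mm": np.asarray(y_px, dtype=float) * pixel_size_um / 1000.0,
            "area_px": np.asarray(area_px, dtype=int),
        }
    )
    for m, v in intensities.items():
        table[m] = np.asarray(v, dtype=float)
    return table


def write_cell_table(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a cell table as CSV (lossless round-trip) or FCS 3.1.

    FCS carries one parameter per marker plus x, y (px) and area; values are
    stored linearly as float32 list mode.
    """
    path = Path(path)
    if len(table) == 0:
        warnings.warn("writing empty cell table (header only)")
    if format == "csv":
        table.to_csv(path, index=False)
    elif format == "fcs":
        cols = ["x_px", "y_px", "area_px"] + marker_columns(table)
        data = table[cols].to_numpy(dtype=np.float32) if len(table) else \
            np.zeros((0, len(cols)), dtype=np.float32)
        _write_fcs(path, cols, data)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# minimal FCS 3.1 (float32 list mode, little-endian)
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"


def _write_fcs(path: Path, names: list[str], data: np.ndarray) -> None:
    n_events, n_par = data.shape
    keywords = {
        "$DATATYPE": "F",
        "$MODE": "L",
        "$BYTEORD": "1,2,3,4",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(names, start=1):
        rng = float(data[:, i - 1].max()) if n_events else 1.0
        keywords[f"$P{i}N"] = name.replace(_FCS_DELIM, "_")
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(np.ceil(rng)) + 1)

    header_len = 58
    # iterate because $BEGINDATA/$ENDDATA lengths depend on the text length
    begin_data = 0
    for _ in range(8):
        kw = dict(keywords)
        kw["$BEGINDATA"] = str(begin_data)
        kw["$ENDDATA"] = str(begin_data + data.nbytes - 1 if data.nbytes else begin_data)
        kw["$BEGINANALYSIS"] = "0"
        kw["$ENDANALYSIS"] = "0"
        text = _FCS_DELIM + _FCS_DELIM.join(
            f"{k}{_FCS_DELIM}{v}" for k, v in kw.items()
        ) + _FCS_DELIM
        text_bytes = text.encode("ascii")
        new_begin = header_len + len(text_bytes)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    end_data = begin_data + data.nbytes - 1 if data.nbytes else begin_data

    def _off(v: int) -> bytes:
        s = str(v)
        if len(s) > 8:
            s = "0"  # too large for the header slot; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _off(header_len) + _off(header_len + len(text_bytes) - 1)
    header += _off(begin_data if data.nbytes else 0)
    header += _off(end_data if data.nbytes else 0)
    header += _off(0) + _off(0)
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text_bytes)
        fh.write(data.astype("<f4").tobytes())


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read a float list-mode FCS file written by :func:`write_cell_table`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3"):
        raise ValueError("not an FCS 3.x file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kw = dict(zip(parts[::2], parts[1::2]))
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    begin = int(kw.get("$BEGINDATA") or raw[26:34])
    if kw["$DATATYPE"] != "F":
        raise ValueError("only $DATATYPE F supported")
    little = kw["$BYTEORD"].startswith("1")
    dtype = "<f4" if little else ">f4"
    data = np.frombuffer(raw, dtype=dtype, count=n_par * n_tot, offset=begin)
    data = data.reshape(n_tot, n_par)
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    return pd.DataFrame(data, columns=names)


def _fcs_param_count(path: str | Path) -> int:
    with open(path, "rb") as fh:
        raw = fh.read()
    text = raw[int(raw[10:18]) : int(raw[18:26]) + 1].decode("ascii")
    parts = text.strip(text[0]).split(text[0])
    return int(dict(zip(parts[::2], parts[1::2]))["$PAR"])
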