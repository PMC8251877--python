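"""Registration, background subtraction, deconvolution, stitching."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from codexkit.phantom import PhantomConfig, generate_tissue_phantom
from codexkit.preprocess import (
    apply_drift,
    concatenate,
    deconvolve,
    estimate_drift,
    process,
    stitch,
    subtract_background,
)
from codexkit.stack_io import ChannelEntry, ChannelMap, TileGrid, TileStack


def _texture(shape=(160, 160), seed=0, n_dots=None):
    """Nuclei-like field: bright blurred disks on a dark background.

    Featureful at all spatial frequencies, like a real registration channel.
    """
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    h, w = shape
    n_dots = n_dots or (h * w) // 600
    yy, xx = np.mgrid[:h, :w]
    for _ in range(n_dots):
        y, x = rng.integers(10, h - 10), rng.integers(10, w - 10)
        img[(yy - y) ** 2 + (xx - x) ** 2 <= 25] = rng.uniform(100, 160)
    return ndi.gaussian_filter(img, 1.0)


def _integer_shift_ncc_oracle(ref, mov, max_shift=10):
    """Exhaustive integer-shift normalized cross-correlation over +-max_shift."""
    best, best_score = (0, 0), -np.inf
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            shifted = np.roll(np.roll(mov, -dy, axis=0), -dx, axis=1)
            m = np.s_[max_shift:-max_shift, max_shift:-max_shift]
            a, b = ref[m].ravel(), shifted[m].ravel()
            score = np.corrcoef(a, b)[0, 1]
            if score > best_score:
                best, best_score = (dy, dx), score
    return best


def _stack_from_planes(planes_by_cycle, cmap=None):
    """Single-tile stack whose cycle c image is [nuclear] (1, h, w)."""
    n_cycles = len(planes_by_cycle)
    if cmap is None:
        entries = []
        for c in range(1, n_cycles + 1):
            entries.append(ChannelEntry(cycle=c, fluor="FAM", blank=True))
            entries.append(ChannelEntry(cycle=c, fluor="Cy3", blank=True))
            entries.append(ChannelEntry(cycle=c, fluor="Cy5", blank=True))
        cmap = ChannelMap(entries=entries)
    h, w = planes_by_cycle[0].shape
    images = {}
    for c, nuc in enumerate(planes_by_cycle, start=1):
        img = np.zeros((4, h, w))
        img[0] = nuc
        images[(c, 0)] = img
    grid = TileGrid(rows=1, cols=1, tile_shape=(h, w))
    return TileStack(images=images, channel_map=cmap, grid=grid)


class TestEstimateDrift:
    def test_identical_images_give_zero(self):
        base = _texture()
        stack = _stack_from_planes([base, base.copy()])
        dt = estimate_drift(stack)
        assert dt.per_cycle[2] == (0.0, 0.0)

    def test_integer_shift_matches_exhaustive_ncc_oracle(self):
        base = _texture(seed=1)
        moved = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        assert _integer_shift_ncc_oracle(base, moved) == (3, -2)
        stack = _stack_from_planes([base, moved])
        dy, dx = estimate_drift(stack).per_cycle[2]
        assert (round(dy), round(dx)) == (3, -2)
        assert abs(dy - 3) < 0.05 and abs(dx + 2) < 0.05

    def test_subpixel_shift_recovered_within_quarter_pixel(self):
        cfg = PhantomConfig(drift=[(0, 0), (0.5, -1.25), (3.0, -2.0)],
                            noise_sd=3.0, seed=4)
        stack, truth = generate_tissue_phantom(cfg)
        dt = estimate_drift(stack)
        for _, row in truth.drift.iterrows():
            dy, dx = dt.per_cycle[int(row.cycle)]
            assert abs(dy - row.dy) <= 0.25
            assert abs(dx - row.dx) <= 0.25

    def test_blank_registration_channel_raises(self):
        stack = _stack_from_planes([np.zeros((64, 64)), np.zeros((64, 64))])
        with pytest.raises(ValueError, match="registration channel empty"):
            estimate_drift(stack)


class TestApplyDrift:
    def test_zero_drift_is_bit_identity(self):
        base = _texture()
        stack = _stack_from_planes([base, base.copy()])
        dt = estimate_drift(stack)
        out = apply_drift(stack, dt)
        for k in stack.images:
            assert np.array_equal(out.images[k], stack.images[k])

    def test_integer_shift_then_unshift_restores_interior(self):
        base = _texture(seed=2)
        moved = np.zeros_like(base)
        moved[4:, :-3] = base[:-4, 3:]  # shift by (+4, -3), zero-filled
        stack = _stack_from_planes([base, moved])
        dt = estimate_drift(stack)
        out = apply_drift(stack, dt)
        interior = np.s_[6:-6, 6:-6]
        np.testing.assert_allclose(out.images[(2, 0)][0][interior],
                                   base[interior], atol=1e-6)

    def test_registration_restores_cross_cycle_correlation(self):
        cfg = PhantomConfig(drift=[(0, 0), (4.5, -3.25), (-2.0, 5.5)],
                            noise_sd=0.0, seed=6)
        stack, _ = generate_tissue_phantom(cfg)
        out = apply_drift(stack, estimate_drift(stack))
        for cyc in (2, 3):
            for t in out.tile_ids:
                a = out.nuclear(1, t)[8:-8, 8:-8].ravel()
                b = out.nuclear(cyc, t)[8:-8, 8:-8].ravel()
                assert np.corrcoef(a, b)[0, 1] > 0.99


class TestSubtractBackground:
    def _map_with_blank(self, n_cycles=2, blank_cycle=2):
        entries = []
        for c in range(1, n_cycles + 1):
            if c == blank_cycle:
                entries.append(ChannelEntry(cycle=c, fluor="FAM", blank=True))
            else:
                entries.append(ChannelEntry(cycle=c, fluor="FAM", marker=f"M{c}", barcode=c))
            entries.append(ChannelEntry(cycle=c, fluor="Cy3", blank=True))
            entries.append(ChannelEntry(cycle=c, fluor="Cy5", blank=True))
        return ChannelMap(entries=entries)

    def _stack(self, signal, blank, cmap):
        h, w = signal.shape
        images = {}
        for c, plane in ((1, signal), (2, blank)):
            img = np.zeros((4, h, w))
            img[0] = 1.0  # non-empty nuclear
            img[1] = plane
            images[(c, 0)] = img
        grid = TileGrid(tile_shape=(h, w))
        return TileStack(images=images, channel_map=cmap, grid=grid)

    def test_signal_equal_to_blank_zeroes_out(self):
        cmap = self._map_with_blank()
        plane = _texture((64, 64))
        out = subtract_background(self._stack(plane, plane.copy(), cmap))
        assert np.all(out.images[(1, 0)][1] == 0)

    def test_object_over_background_recovered_exactly(self):
        cmap = self._map_with_blank()
        signal = np.full((64, 64), 20.0)
        signal[20:30, 20:30] += 100.0
        blank = np.full((64, 64), 20.0)
        out = subtract_background(self._stack(signal, blank, cmap))
        res = out.images[(1, 0)][1]
        assert np.all(res[20:30, 20:30] == 100.0)
        res[20:30, 20:30] = 0
        assert np.all(res == 0)

    def test_missing_blank_raises_with_instruction(self):
        entries = [
            ChannelEntry(cycle=1, fluor="FAM", marker="M1", barcode=1),
            ChannelEntry(cycle=1, fluor="Cy3", blank=True),
            ChannelEntry(cycle=1, fluor="Cy5", blank=True),
        ]
        cmap = ChannelMap(entries=entries)
        img = np.ones((4, 32, 32))
        stack = TileStack(images={(1, 0): img}, channel_map=cmap,
                          grid=TileGrid(tile_shape=(32, 32)))
        with pytest.raises(ValueError, match="blank"):
            subtract_background(stack)

    def test_phantom_residual_below_twice_noise_sd(self):
        """Blank-subtracted reporter residual in cell-free areas is noise-level."""
        cfg = PhantomConfig(grid=(1, 1), tile_shape=(200, 200), n_cells=20,
                            background=20.0, noise_sd=3.0, seed=8)
        stack, truth = generate_tissue_phantom(cfg)
        out = subtract_background(stack)
        cmap = stack.channel_map
        # cell-free = far from every truth cell
        h, w = cfg.tile_shape
        yy, xx = np.mgrid[:h, :w]
        free = np.ones((h, w), bool)
        for _, cell in truth.cells.iterrows():
            free &= (yy - cell.y) ** 2 + (xx - cell.x) ** 2 > (cell.radius + 8) ** 2
        e = cmap.reporter_entries()[0]
        res = out.images[(e.cycle, 0)][cmap.plane_index(e.fluor)]
        assert abs(res[free].mean()) <= 2 * cfg.noise_sd


class TestDeconvolve:
    def test_impulse_peak_sharpens(self):
        img = np.zeros((65, 65))
        img[32, 32] = 100.0
        blurred = ndi.gaussian_filter(img, 2.0)
        out = deconvolve(blurred, psf_sigma=2.0, iterations=30)
        assert out.max() > blurred.max()
        assert out.sum() == pytest.approx(blurred.sum(), rel=0.01)  # flux conserved

    def test_flat_image_is_fixed_point(self):
        img = np.full((40, 40), 13.0)
        out = deconvolve(img, psf_sigma=1.5, iterations=10)
        np.testing.assert_allclose(out, img, rtol=1e-6)

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            deconvolve(np.ones((8, 8)), psf_sigma=1.0, iterations=0)


class TestStitch:
    def test_single_tile_unchanged(self):
        img = _texture((100, 100))
        grid = TileGrid(rows=1, cols=1, tile_shape=(100, 100))
        mosaic, _ = stitch({0: img[None]}, grid)
        np.testing.assert_array_equal(mosaic[0], img)

    # 2x2 tiles of 211 px with 22 px (~10%) overlap span exactly 400 px
    _GRID_400 = TileGrid(rows=2, cols=2, overlap=22 / 211, tile_shape=(211, 211))

    def test_2x2_cut_reconstructs_source_exactly(self):
        """Tiles cut from one 400x400 image with ~10% overlap: identical data
        in the overlaps, so blending reproduces the source everywhere."""
        src = _texture((400, 400), seed=7)
        grid = self._GRID_400
        tiles = {}
        for t in range(4):
            oy, ox = grid.tile_origin(t)
            tiles[t] = src[None, oy : oy + 211, ox : ox + 211]
        mosaic, _ = stitch(tiles, grid, refine=False)
        np.testing.assert_allclose(mosaic[0], src, atol=1e-9)

    def test_planted_stage_error_recovered_by_refinement(self):
        """Tiles cut at +-2 px jittered positions, stitched with the nominal
        grid + refinement: recovered origins within 0.5 px of the true cut."""
        src = _texture((420, 420), seed=8)
        grid = self._GRID_400
        jitter = {0: (0, 0), 1: (2, -1), 2: (-2, 2), 3: (1, 2)}
        tiles, true_origin = {}, {}
        for t in range(4):
            oy, ox = grid.tile_origin(t)
            jy, jx = jitter[t]
            tiles[t] = src[None, 8 + oy + jy : 8 + oy + jy + 211,
                           8 + ox + jx : 8 + ox + jx + 211]
            true_origin[t] = (oy + jy, ox + jx)
        _, origins = stitch(tiles, grid, refine=True)
        for t in range(4):
            # anchored on tile 0 (its jitter is 0)
            err_y = abs(origins[t][0] - true_origin[t][0])
            err_x = abs(origins[t][1] - true_origin[t][1])
            assert err_y <= 0.5 and err_x <= 0.5, (t, origins[t], true_origin[t])

    def test_inconsistent_tile_shapes_rejected(self):
        grid = TileGrid(rows=1, cols=2, overlap=0.1, tile_shape=(64, 64))
        with pytest.raises(ValueError, match="shape"):
            stitch({0: np.zeros((1, 64, 64)), 1: np.zeros((1, 64, 32))}, grid)


class TestConcatenate:
    def _cmap(self, markers_per_cycle, n_cycles):
        entries = []
        fluors = ["FAM", "Cy3", "Cy5"]
        bc = 1
        for c in range(1, n_cycles + 1):
            for i, f in enumerate(fluors):
                if i < markers_per_cycle:
                    entries.append(ChannelEntry(cycle=c, fluor=f, marker=f"M{bc}", barcode=bc))
                    bc += 1
                else:
                    entries.append(ChannelEntry(cycle=c, fluor=f, blank=True))
        return ChannelMap(entries=entries)

    def test_single_cycle_three_markers_gives_four_planes(self):
        cmap = self._cmap(3, 1)
        mos = concatenate({1: np.random.default_rng(0).random((4, 16, 16))}, cmap)
        assert mos.data.shape[0] == 4
        assert mos.plane_names[0] == "Hoechst"

    def test_blank_planes_dropped_and_order_follows_map(self):
        cmap = self._cmap(2, 3)  # 6 markers over 3 cycles, 1 blank fluor each
        rng = np.random.default_rng(1)
        cycle_mosaics = {c: rng.random((4, 8, 8)) for c in (1, 2, 3)}
        mos = concatenate(cycle_mosaics, cmap)
        assert mos.plane_names == ["Hoechst", "M1", "M2", "M3", "M4", "M5", "M6"]
        np.testing.assert_array_equal(mos.data[0], cycle_mosaics[1][0])
        np.testing.assert_array_equal(mos.data[1], cycle_mosaics[1][1])
        np.testing.assert_array_equal(mos.data[3], cycle_mosaics[2][1])


def test_full_process_is_reproducible(standard_phantom):
    """Same stack processed twice gives bit-identical mosaics."""
    _, stack, _ = standard_phantom
    m1, d1 = process(stack)
    m2, d2 = process(stack)
    assert np.array_equal(m1.data, m2.data)
    assert d1.per_tile.equals(d2.per_tile)
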