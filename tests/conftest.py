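"""Shared fixtures: all test data is generated, nothing is loaded from disk."""

import numpy as np
import pytest

from codexkit.phantom import PhantomConfig, generate_tissue_phantom
from codexkit.preprocess import process
from codexkit.segmentation import SegmentationParams, quantify_cells, segment_cells


@pytest.fixture(scope="session")
def standard_phantom():
    """100 cells, SNR ~10, spacing >= 3 nuclear radii, 2x2 tiles."""
    cfg = PhantomConfig(
        tile_shape=(220, 220), grid=(2, 2), overlap=0.1,
        n_cells=100, min_spacing=15.0, noise_sd=10.0, seed=11,
    )
    stack, truth = generate_tissue_phantom(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def processed(standard_phantom):
    """Mosaic + label image + quantified cell table for the standard phantom."""
    _, stack, truth = standard_phantom
    mosaic, drift = process(stack)
    labels = segment_cells(
        mosaic.plane("Hoechst"), mosaic.plane("CD45"), SegmentationParams()
    )
    cells = quantify_cells(labels, mosaic)
    return mosaic, labels, cells


@pytest.fixture(scope="session")
def gaussian_mixture_5x8():
    """5 components in 8 marker dimensions, minimum center separation 4 sd."""
    rng = np.random.default_rng(42)
    centers = rng.normal(0, 1, (5, 8))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    from scipy.spatial.distance import pdist

    centers *= 4.0 / pdist(centers).min()
    labels = rng.integers(0, 5, 5000)
    X = centers[labels] + rng.normal(0, 1, (5000, 8))
    return X, labels
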