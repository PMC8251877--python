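"""Spatial statistics: rings, composition, windowed density correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from codexkit.phantom import generate_colocalization_points
from codexkit.spatial import (
    composition,
    density_correlation,
    follicle_ring,
    sample_density,
)


def brute_force_spearman(x, y):
    """Rank-correlation oracle with average ranks for ties."""

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v), float)
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _follicle_fixture(seed=0, n=500, frac_b=0.7, radius=100, center=(200, 200)):
    rng = np.random.default_rng(seed)
    mask = np.zeros((600, 600), np.int32)
    mask[_disk_mask((600, 600), *center, radius)] = 1
    ang = rng.uniform(0, 2 * np.pi, n)
    rad = (radius - 1) * np.sqrt(rng.uniform(0, 1, n))
    ys = center[0] + rad * np.sin(ang)
    xs = center[1] + rad * np.cos(ang)
    n_b = int(round(frac_b * n))  # exact planted composition
    types = rng.permutation(np.array(["B"] * n_b + ["T"] * (n - n_b)))
    table = pd.DataFrame({"id": np.arange(1, n + 1), "y_px": ys, "x_px": xs,
                          "cluster": types})
    return mask, table


class TestFollicleRing:
    def test_factor_one_ring_is_empty(self):
        mask, table = _follicle_fixture()
        rings = follicle_ring(mask, table, factor=1.0)
        assert rings[1].sum() == 0

    def test_ring_area_matches_analytic_annulus(self):
        """Circular follicle of radius r: ring area ~ pi((r + 0.1 D)^2 - r^2)."""
        mask, table = _follicle_fixture(seed=1)
        rings = follicle_ring(mask, table, factor=1.2)
        D = pdist(table[["y_px", "x_px"]].to_numpy()).max()
        analytic = np.pi * ((100 + 0.1 * D) ** 2 - 100**2)
        assert rings[1].sum() == pytest.approx(analytic, rel=0.05)

    def test_sparse_follicle_skipped_with_warning(self):
        mask = np.zeros((50, 50), np.int32)
        mask[10:20, 10:20] = 1
        table = pd.DataFrame({"id": [1], "y_px": [15.0], "x_px": [15.0],
                              "cluster": ["B"]})
        with pytest.warns(UserWarning, match="ring skipped"):
            rings = follicle_ring(mask, table)
        assert 1 not in rings

    def test_rings_clipped_at_other_follicles(self):
        mask, table = _follicle_fixture()
        mask2 = mask.copy()
        mask2[_disk_mask(mask.shape, 200, 420, 60)] = 2
        extra = pd.DataFrame({"id": [9991, 9992], "y_px": [200.0, 210.0],
                              "x_px": [400.0, 440.0], "cluster": ["B", "B"]})
        rings = follicle_ring(mask2, pd.concat([table, extra]), factor=1.2)
        assert not (rings[1] & (mask2 > 0)).any()


class TestComposition:
    def test_pure_region_frequency_is_one(self):
        mask, table = _follicle_fixture(frac_b=1.0)
        result = composition(table, mask)
        inner = result.per_follicle.query("zone == 'inner'").iloc[0]
        assert inner["freq_B"] == 1.0

    def test_planted_70_30_recovered_within_3_points(self):
        mask, table = _follicle_fixture(seed=2, frac_b=0.7, n=500)
        result = composition(table, mask)
        inner = result.per_follicle.query("zone == 'inner'").iloc[0]
        assert inner["freq_B"] == pytest.approx(0.7, abs=0.03)
        assert inner["freq_B"] + inner["freq_T"] == pytest.approx(1.0)

    def test_tissue_average_is_unweighted_mean(self):
        mask = np.zeros((100, 200), np.int32)
        mask[20:40, 20:40] = 1
        mask[20:40, 120:140] = 2
        table = pd.DataFrame({
            "id": [1, 2, 3], "y_px": [30.0, 30.0, 35.0],
            "x_px": [30.0, 130.0, 135.0], "cluster": ["A", "B", "B"],
        })
        result = composition(table, mask)
        mean = result.tissue_mean.query("zone == 'inner'").iloc[0]
        # follicle 1 is pure A; follicle 2 pure B -> average (0.5, 0.5)
        assert mean["freq_A"] == pytest.approx(0.5)
        assert mean["freq_B"] == pytest.approx(0.5)

    def test_empty_region_reports_zero_with_warning(self):
        mask = np.zeros((50, 50), np.int32)
        mask[40:49, 40:49] = 1
        table = pd.DataFrame({"id": [1], "y_px": [5.0], "x_px": [5.0],
                              "cluster": ["A"]})
        with pytest.warns(UserWarning, match="no cells"):
            result = composition(table, mask)
        row = result.per_follicle.iloc[0]
        assert row["total"] == 0 and row["freq_A"] == 0.0


class TestSampleDensity:
    def test_poisson_field_mean_count_matches_intensity(self):
        """Uniform field at density rho: window mean ~ rho * window^2."""
        rng = np.random.default_rng(3)
        H = W = 1000
        n = 4000  # rho = 0.004 /px^2 -> lambda = 40 per 100x100 window
        table = pd.DataFrame({
            "id": np.arange(n), "y_px": rng.uniform(0, H, n),
            "x_px": rng.uniform(0, W, n), "cluster": "A",
        })
        counts = sample_density(table, (H, W), window=100, n_windows=500, seed=4)
        lam = 40.0
        sem = np.sqrt(lam / 500)
        assert counts["A"].mean() == pytest.approx(lam, abs=3 * sem + 1.0)

    def test_empty_table_gives_no_type_columns(self):
        table = pd.DataFrame({"id": [], "y_px": [], "x_px": [], "cluster": []})
        counts = sample_density(table, (300, 300), window=50, n_windows=20, seed=0)
        assert len(counts) == 20

    def test_reproducible_under_seed(self):
        _, table = _follicle_fixture()
        c1 = sample_density(table, (600, 600), window=50, n_windows=50, seed=9)
        c2 = sample_density(table, (600, 600), window=50, n_windows=50, seed=9)
        pd.testing.assert_frame_equal(c1, c2)

    def test_domain_mask_constrains_windows(self):
        _, table = _follicle_fixture()
        domain = np.zeros((600, 600), bool)
        domain[100:300, 100:300] = True
        counts = sample_density(table, (600, 600), window=50, n_windows=30,
                                domain=domain, seed=5)
        assert (counts["y0"] >= 100).all() and (counts["y0"] <= 250).all()
        assert (counts["x0"] >= 100).all() and (counts["x0"] <= 250).all()

    def test_domain_smaller_than_window_rejected(self):
        _, table = _follicle_fixture()
        with pytest.raises(ValueError):
            sample_density(table, (60, 60), window=100, n_windows=10)

    def test_doubling_windows_shrinks_standard_error(self):
        """SEM of the mean count scales ~ 1/sqrt(n_windows)."""
        rng = np.random.default_rng(6)
        n = 3000
        table = pd.DataFrame({
            "id": np.arange(n), "y_px": rng.uniform(0, 800, n),
            "x_px": rng.uniform(0, 800, n), "cluster": "A",
        })
        sems = []
        for n_win in (250, 1000):  # 4x windows -> SEM halves
            means = []
            for rep in range(30):
                c = sample_density(table, (800, 800), window=80,
                                   n_windows=n_win, seed=100 + rep)
                means.append(c["A"].mean())
            sems.append(np.std(means))
        assert sems[1] == pytest.approx(sems[0] / 2, rel=0.3)


class TestDensityCorrelation:
    def _counts(self, cols):
        df = pd.DataFrame(cols)
        df["y0"] = 0
        df["x0"] = 0
        return df

    def test_identical_counts_give_rho_one(self):
        v = np.arange(12)
        dc = density_correlation(self._counts({"A": v, "B": v.copy()}))
        assert dc.rho.loc["A", "B"] == 1.0

    def test_reversed_counts_give_rho_minus_one(self):
        v = np.arange(12)
        dc = density_correlation(self._counts({"A": v, "B": v[::-1].copy()}))
        assert dc.rho.loc["A", "B"] == -1.0

    def test_small_vectors_match_rank_oracle(self):
        x = [1, 2, 3, 4, 5] * 2
        y = [2, 1, 4, 3, 5] * 2
        want = brute_force_spearman(x, y)
        dc = density_correlation(self._counts({"A": x, "B": y}))
        assert dc.rho.loc["A", "B"] == pytest.approx(want)
        # forced by the rank arithmetic on (1,2,3,4,5) vs (2,1,4,3,5)
        assert want == pytest.approx(0.8)

    def test_matrix_matches_oracle_on_random_counts(self):
        rng = np.random.default_rng(7)
        cols = {t: rng.poisson(5, 20) for t in "ABCD"}
        dc = density_correlation(self._counts(cols))
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    want = brute_force_spearman(cols[a], cols[b])
                    assert dc.rho.loc[a, b] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_type_flagged_as_zero(self):
        dc = density_correlation(self._counts({"A": np.arange(15),
                                               "B": np.full(15, 3)}))
        assert dc.rho.loc["A", "B"] == 0.0
        assert "B" in dc.undefined

    def test_colocalized_module_recovered(self):
        """Co-planted pair correlates (rho >= 0.5); the spatially excluded
        type anticorrelates (rho <= -0.3) over 500 windows of 100 px."""
        table = generate_colocalization_points(seed=10)
        counts = sample_density(table, (1000, 1000), window=100,
                                n_windows=500, seed=11)
        dc = density_correlation(counts)
        assert dc.rho.loc["A", "B"] >= 0.5
        assert dc.rho.loc["A", "C"] <= -0.3
        # after ordering, A and B are adjacent (a positive block)
        ia, ib = dc.order.index("A"), dc.order.index("B")
        assert abs(ia - ib) == 1
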