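import numpy as np
import pytest

from canopyagb.geo import Affine, RasterGrid
from canopyagb.texture import (
    DIRECTION_OFFSETS,
    TextureConfig,
    glcm,
    quantize,
    texture_map,
    texture_metric,
    tf_table,
)


def glcm_oracle(win, direction_deg, levels):
    """Brute-force pair enumeration, written independently of the library."""
    dr, dc = DIRECTION_OFFSETS[direction_deg]
    P = np.zeros((levels, levels))
    h, w = win.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[win[r, c], win[r2, c2]] += 1
                P[win[r2, c2], win[r, c]] += 1
    return P / P.sum()


def var_oracle(P):
    i = np.arange(P.shape[0])[:, None]
    mu = (P * i).sum()
    return ((i - mu) ** 2 * P).sum()


def ent_oracle(P):
    nz = P[P > 0]
    return -(nz * np.log(nz)).sum()


class TestQuantize:
    def test_endpoints(self):
        q = quantize(np.array([[0.0, 255.0]]), 32)
        assert q.tolist() == [[0, 31]]

    def test_constant_band(self):
        assert (quantize(np.full((4, 4), 7.0), 32) == 0).all()

    def test_uniform_binning_boundaries(self):
        vals = np.arange(256.0).reshape(16, 16)
        q = quantize(vals, 4)
        flat = q.ravel()
        assert (flat[:64] == 0).all()
        assert (flat[64:128] == 1).all()
        assert (flat[128:192] == 2).all()
        assert (flat[192:] == 3).all()


class TestGLCM:
    def test_constant_window_single_cell(self):
        P = glcm(np.full((3, 3), 2, dtype=int), 0, 4)
        assert P[2, 2] == 1.0
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_horizontal(self):
        P = glcm(np.array([[0, 1], [1, 0]]), 0, 2)
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)

    def test_sum_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            win = rng.integers(0, 4, size=(3, 3))
            for d in DIRECTION_OFFSETS:
                P = glcm(win, d, 4)
                assert P.sum() == pytest.approx(1.0)
                assert np.allclose(P, P.T)

    def test_too_small_window(self):
        with pytest.raises(ValueError, match="pairs"):
            glcm(np.array([[1]]), 0, 2)

    def test_exhaustive_binary_3x3_vs_oracle(self):
        """All 512 binary 3x3 windows, four directions, exact agreement."""
        for code in range(512):
            win = np.array([(code >> k) & 1 for k in range(9)]).reshape(3, 3)
            for d in DIRECTION_OFFSETS:
                assert np.allclose(glcm(win, d, 2), glcm_oracle(win, d, 2))

    def test_sampled_4level_windows_vs_oracle(self):
        rng = np.random.default_rng(1)
        wins = rng.integers(0, 4, size=(300, 3, 3))
        for win in wins:
            for d in DIRECTION_OFFSETS:
                P, Po = glcm(win, d, 4), glcm_oracle(win, d, 4)
                assert np.allclose(P, Po)
                assert texture_metric(win, "VAR", d, 4) == pytest.approx(
                    var_oracle(Po), abs=1e-12)
                assert texture_metric(win, "ENT", d, 4) == pytest.approx(
                    ent_oracle(Po), abs=1e-12)


class TestTextureMetric:
    def test_constant_window_all_zero(self):
        win = np.full((5, 5), 3, dtype=int)
        for m in ("DR", "VAR", "ENT"):
            assert texture_metric(win, m, 0, 32) == 0.0

    def test_checkerboard_entropy_ln2(self):
        # odd-sized checkerboard: every direction yields two equally likely
        # co-occurrence cells, so ENT = -2 * 0.5 ln 0.5 = ln 2
        win = np.indices((5, 5)).sum(axis=0) % 2
        for d in DIRECTION_OFFSETS:
            assert texture_metric(win, "ENT", d, 2) == pytest.approx(np.log(2))

    def test_data_range_endpoints(self):
        win = np.arange(32).reshape(4, 8)
        assert texture_metric(win, "DR", 0, 32) == 31.0

    def test_entropy_bounded_by_log_levels_squared(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            win = rng.integers(0, 8, size=(5, 5))
            ent = texture_metric(win, "ENT", 45, 8)
            assert 0.0 <= ent <= 2 * np.log(8) + 1e-12

    def test_var_direction_invariant_on_isotropic_pattern(self):
        win = np.indices((5, 5)).sum(axis=0) % 2  # balanced checkerboard
        vals = {d: texture_metric(win, "VAR", d, 2) for d in DIRECTION_OFFSETS}
        assert len({round(v, 12) for v in vals.values()}) == 1


class TestTextureMap:
    CFG = TextureConfig()

    def test_constant_band_zero_map(self):
        out = texture_map(np.full((8, 8), 5.0), self.CFG, "ENT")
        assert np.allclose(out.values, 0.0)

    def test_shape_preserved(self):
        rng = np.random.default_rng(3)
        band = rng.random((11, 13))
        for m in ("DR", "VAR", "ENT"):
            assert texture_map(band, self.CFG, m).values.shape == (11, 13)

    @pytest.mark.parametrize("metric", ["DR", "VAR", "ENT"])
    def test_center_pixel_matches_brute_force_average(self, metric):
        """Map value = plain mean of per-(window, direction) metrics."""
        rng = np.random.default_rng(4)
        band = rng.integers(0, 256, size=(9, 9)).astype(float)
        q = quantize(band, self.CFG.gray_levels)
        out = texture_map(band, self.CFG, metric).values[4, 4]
        vals = []
        for w in self.CFG.window_sizes:
            h = w // 2
            win = q[4 - h:5 + h, 4 - h:5 + h]
            if metric == "DR":
                vals.append(texture_metric(win, "DR"))
            else:
                for d in self.CFG.directions_deg:
                    P = glcm_oracle(win, d, self.CFG.gray_levels)
                    vals.append(var_oracle(P) if metric == "VAR" else ent_oracle(P))
        assert out == pytest.approx(np.mean(vals), abs=1e-10)

    def test_translation_equivariance_away_from_borders(self):
        rng = np.random.default_rng(5)
        tile = rng.integers(0, 32, size=(14, 14)).astype(float)
        shifted = np.roll(tile, 3, axis=1)
        a = texture_map(tile, self.CFG, "ENT").values
        b = texture_map(shifted, self.CFG, "ENT").values
        assert np.allclose(a[3:-3, 3:-6], b[3:-3, 6:-3])

    def test_band_smaller_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            texture_map(np.zeros((4, 4)), self.CFG, "VAR")


class TestTFTable:
    def test_shape_nine_columns(self, small_scene):
        df = tf_table(small_scene.rgb, small_scene.plots)
        metric_cols = [c for c in df.columns if c not in ("plot_id", "stage")]
        assert sorted(metric_cols) == sorted(
            [f"{b}{m}" for b in "RGB" for m in ("DR", "VAR", "ENT")])
        assert len(df) == len(small_scene.plots)

    def test_uniform_image_all_zero(self, small_scene):
        rgb = RasterGrid(values=np.full((3, *small_scene.rgb.shape), 100, np.uint8),
                         transform=small_scene.rgb.transform,
                         crs_id=small_scene.rgb.crs_id)
        df = tf_table(rgb, small_scene.plots[:3])
        assert np.allclose(df[[c for c in df.columns
                               if c not in ("plot_id", "stage")]].to_numpy(), 0.0)

    def test_textured_plot_has_higher_entropy_than_smooth(self):
        """A half-covered (blobby) plot shows more green-band entropy than a
        fully closed canopy."""
        rng = np.random.default_rng(6)
        img = np.full((3, 20, 40), 60, dtype=np.uint8)
        img[1, :, :20] = 120  # smooth closed canopy, constant green
        img[1, :, 20:] = rng.choice([60, 120], size=(20, 20))  # patchy
        rgb = RasterGrid(values=img, transform=Affine(1, 0, 0, 0, -1, 20))
        from shapely.geometry import box
        from canopyagb.geo import PlotROI
        smooth = PlotROI("smooth", box(2, 2, 18, 18), "C1", "N0", 1)
        patchy = PlotROI("patchy", box(22, 2, 38, 18), "C1", "N0", 1)
        df = tf_table(rgb, [smooth, patchy]).set_index("plot_id")
        assert df.loc["patchy", "GENT"] > df.loc["smooth", "GENT"]
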