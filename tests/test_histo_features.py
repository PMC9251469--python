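import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from mfhcc import cohort_stats as cs
from mfhcc import histo_features as hf
from mfhcc import synthetic_data as sd


def blank_image(h, w, rgb=(233, 195, 208)):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = rgb
    return img


class TestTiling:
    def test_grid_arithmetic(self):
        tiles = hf.tile_image(blank_image(512, 512), side=256)
        assert len(tiles) == 4
        assert all(t.side == 256 for t in tiles)
        assert len(hf.tile_image(blank_image(256, 256), side=256)) == 1

    def test_partial_edge_tiles_discarded(self):
        tiles = hf.tile_image(blank_image(300, 550), side=256)
        assert len(tiles) == 2  # 1 row x 2 cols fit fully

    def test_too_small_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="smaller"):
            assert hf.tile_image(blank_image(100, 100), side=256) == []

    def test_mask_fraction_rule(self):
        img = blank_image(512, 512)
        mask = np.zeros((512, 512), dtype=bool)
        mask[:256, :256] = True  # one quadrant fully masked
        tiles = hf.tile_image(img, mask=mask, side=256)
        assert len(tiles) == 1 and tiles[0].tile_id == "r0c0"
        # brute-force pixel count confirms the other quadrants are below 50%
        for r0, c0 in [(0, 256), (256, 0), (256, 256)]:
            frac = mask[r0 : r0 + 256, c0 : c0 + 256].mean()
            assert frac < 0.5


class TestMacenko:
    def test_self_normalization_is_near_identity(self):
        r = sd.render_nucleus_tile(
            sd.ImagePairParams(side_px=256), np.random.default_rng(9), n_nuclei=8
        )
        out = hf.macenko_normalize(r.tile, r.tile)
        diff = np.abs(out.pixels.astype(int) - r.tile.pixels.astype(int)).max(axis=2)
        assert (diff <= 2).mean() >= 0.99

    def test_known_stain_vectors_recovered_within_5_degrees(self):
        rng = np.random.default_rng(21)
        h_true = np.array([0.65, 0.70, 0.29])
        e_true = np.array([0.07, 0.99, 0.11])
        h_true, e_true = h_true / np.linalg.norm(h_true), e_true / np.linalg.norm(e_true)
        stains = np.stack([h_true, e_true], axis=1)
        # independent concentrations reaching 0 give near-pure-stain pixels,
        # as nuclei (pure hematoxylin) and stroma (pure eosin) do in tissue
        conc = rng.uniform(0.0, 1.2, size=(2, 8192))
        od = (stains @ conc).T
        od = od[(od >= hf.OD_BACKGROUND_THRESHOLD).all(axis=1)]
        est = hf.estimate_stain_matrix(od)
        for truth, col in zip((h_true, e_true), est.T):
            angle = np.degrees(np.arccos(np.clip(np.dot(truth, col), -1, 1)))
            assert angle < 5.0

    def test_all_white_tile_passthrough_with_warning(self):
        tile = hf.Tile(pixels=np.full((64, 64, 3), 255, dtype=np.uint8), tile_id="w")
        ref = hf.Tile(pixels=blank_image(64, 64, rgb=(120, 90, 150)))
        with pytest.warns(UserWarning, match="no stained pixels"):
            out = hf.macenko_normalize(tile, ref)
        np.testing.assert_array_equal(out.pixels, tile.pixels)

    def test_background_preserved(self):
        params = sd.ImagePairParams(side_px=256)
        rng = np.random.default_rng(30)
        src = sd.render_nucleus_tile(params, rng, n_nuclei=6)
        ref = sd.render_nucleus_tile(params, rng, n_nuclei=6)
        out = hf.macenko_normalize(src.tile, ref.tile)
        od = hf.rgb_to_od(src.tile.pixels).reshape(-1, 3)
        bg = ~(od >= hf.OD_BACKGROUND_THRESHOLD).all(axis=1)
        np.testing.assert_array_equal(
            out.pixels.reshape(-1, 3)[bg], src.tile.pixels.reshape(-1, 3)[bg]
        )


class TestSegmentation:
    def test_well_separated_nuclei_counted(self):
        r = sd.render_nucleus_tile(
            sd.ImagePairParams(side_px=384), np.random.default_rng(14), n_nuclei=10
        )
        seg = hf.segment_nuclei(r.tile)
        assert seg.max() == 10

    def test_blank_tile_gives_zero_labels(self):
        tile = hf.Tile(pixels=blank_image(128, 128))
        assert hf.segment_nuclei(tile).max() == 0

    def test_size_filter_removes_tiny_component(self):
        img = blank_image(256, 256)
        rr, cc = disk((64, 64), 2)  # ~12 px = 3 um^2 at mpp 0.5
        img[rr, cc] = (70, 50, 130)
        rr, cc = disk((180, 180), 12)  # ~452 px = 113 um^2
        img[rr, cc] = (70, 50, 130)
        seg = hf.segment_nuclei(hf.Tile(pixels=img))
        assert seg.max() == 1
        assert seg[64, 64] == 0 and seg[180, 180] == 1

    def test_count_recovery_over_seeded_tiles(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            n = int(rng.integers(5, 51))
            r = sd.render_nucleus_tile(sd.ImagePairParams(), rng, n_nuclei=n)
            assert abs(hf.segment_nuclei(r.tile).max() - n) <= 1


class TestNucleusFeatures:
    def test_circle_area_close_to_analytic(self):
        # radius 10 um = 20 px at 0.5 um/px
        img = blank_image(256, 256)
        mask = np.zeros((256, 256), dtype=np.int32)
        rr, cc = disk((128, 128), 20)
        mask[rr, cc] = 1
        img[rr, cc] = (70, 50, 130)
        feats = hf.nucleus_features(mask, hf.Tile(pixels=img))
        assert feats.loc[0, "area"] == pytest.approx(np.pi * 100, rel=0.05)
        assert 0.9 <= feats.loc[0, "circularity"] <= 1.15
        assert feats.loc[0, "solidity"] > 0.95

    def test_pure_color_channel_means(self):
        img = blank_image(64, 64)
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 10)
        mask[rr, cc] = 1
        img[rr, cc] = (255, 0, 0)
        feats = hf.nucleus_features(mask, hf.Tile(pixels=img))
        assert feats.loc[0, "rmean"] == 255.0
        assert feats.loc[0, "gmean"] == 0.0
        assert feats.loc[0, "bmean"] == 0.0
        assert feats.loc[0, "intensity_std"] == 0.0

    def test_two_nuclei_distance_features(self):
        # centroids 100 px apart = 50 um at mpp 0.5
        img = blank_image(256, 256)
        mask = np.zeros((256, 256), dtype=np.int32)
        for label, center in ((1, (78, 128)), (2, (178, 128))):
            rr, cc = disk(center, 8)
            mask[rr, cc] = label
            img[rr, cc] = (70, 50, 130)
        feats = hf.nucleus_features(mask, hf.Tile(pixels=img))
        for col in ("dist_mean", "dist_max", "dist_min"):
            assert feats[col].tolist() == pytest.approx([50.0, 50.0], abs=0.1)

    def test_single_nucleus_distances_zero(self):
        img = blank_image(64, 64)
        mask = np.zeros((64, 64), dtype=np.int32)
        rr, cc = disk((32, 32), 8)
        mask[rr, cc] = 1
        feats = hf.nucleus_features(mask, hf.Tile(pixels=img))
        assert feats.loc[0, "dist_mean"] == 0.0 == feats.loc[0, "dist_max"]


class TestImageLevelFeatures:
    @staticmethod
    def records(values, feature="area"):
        df = pd.DataFrame({f: [50.0] * len(values) for f in hf.NUCLEUS_FEATURES})
        df[feature] = values
        return df

    def test_degenerate_distribution_conventions(self):
        vec = hf.image_level_features(self.records([60.0] * 5))
        assert vec["area_std"] == 0.0
        assert vec["area_skewness"] == 0.0 and vec["area_kurtosis"] == 0.0
        assert vec["area_entropy"] == 0.0
        bins = [vec[f"area_bin{k}"] for k in range(1, 11)]
        assert sum(bins) == pytest.approx(1.0) and max(bins) == 1.0

    def test_uniform_bins_maximal_entropy(self):
        # area bin centers for range (0, 300): 15, 45, ..., 285
        vec = hf.image_level_features(self.records([15.0 + 30 * k for k in range(10)]))
        assert vec["area_entropy"] == pytest.approx(np.log2(10))

    def test_moments_match_independent_computation(self):
        rng = np.random.default_rng(77)
        values = rng.lognormal(mean=3.5, sigma=0.4, size=500)
        vec = hf.image_level_features(self.records(values))
        m = values.mean()
        s = np.sqrt(((values - m) ** 2).mean())
        skew = ((values - m) ** 3).mean() / s**3
        kurt = ((values - m) ** 4).mean() / s**4 - 3
        assert vec["area_mean"] == pytest.approx(m, rel=1e-9)
        assert vec["area_std"] == pytest.approx(s, rel=1e-9)
        assert vec["area_skewness"] == pytest.approx(skew, rel=1e-6)
        assert vec["area_kurtosis"] == pytest.approx(kurt, rel=1e-6)

    def test_vector_shape_and_finiteness(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {f: rng.uniform(1, 40, size=7) for f in hf.NUCLEUS_FEATURES}
        )
        vec = hf.image_level_features(df)
        assert len(vec) == 150
        assert np.isfinite(vec.to_numpy()).all()
        for feat in hf.NUCLEUS_FEATURES:
            bins = sum(vec[f"{feat}_bin{k}"] for k in range(1, 11))
            assert bins == pytest.approx(1.0)

    def test_histogram_subset_has_100_names(self):
        names = hf.histogram_feature_names()
        assert len(names) == 100
        assert all(name.split("_bin")[0] in hf.NUCLEUS_FEATURES for name in names)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            hf.image_level_features(pd.DataFrame(columns=list(hf.NUCLEUS_FEATURES)))


class TestFocusPairCorrelation:
    def test_identity_and_inversion(self, rng):
        v = pd.Series(rng.normal(size=50))
        assert hf.focus_pair_correlation(v, v) == pytest.approx(1.0)
        zero = pd.Series(0.0, index=v.index)
        one = pd.Series(1.0, index=v.index)
        assert hf.focus_pair_correlation(
            v, -v, cohort_mean=zero, cohort_std=one
        ) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        v = pd.Series([1.0] * 10)
        with pytest.raises(ValueError, match="zero-variance"):
            hf.focus_pair_correlation(v, v)

    def test_im_pairs_more_correlated_than_mo(self):
        """Shared-morphology (IM) foci correlate more than independent (MO) foci."""
        rng = np.random.default_rng(7)
        params = sd.ImagePairParams()
        vecs, pairs = [], []
        for pattern in ["IM"] * 12 + ["MO"] * 12:
            ra, rb = sd.simulate_focus_pair_images(pattern, params, rng)
            va = hf.image_level_features(hf.nucleus_features(ra.mask, ra.tile))
            vb = hf.image_level_features(hf.nucleus_features(rb.mask, rb.tile))
            vecs += [va, vb]
            pairs.append((pattern, va, vb))
        cohort = pd.DataFrame(vecs)
        mu, sdv = cohort.mean(), cohort.std(ddof=0)
        corrs = {"IM": [], "MO": []}
        for pattern, va, vb in pairs:
            corrs[pattern].append(hf.focus_pair_correlation(va, vb, mu, sdv))
        _, p = cs.mann_whitney(corrs["IM"], corrs["MO"])
        assert np.mean(corrs["IM"]) > np.mean(corrs["MO"])
        assert p < 0.05
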