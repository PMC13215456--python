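"""Tiling, masking, Macenko normalization, pooled deep features, objects."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from ptmls import pathomics as pm
from ptmls import synthetic as syn


class TestTiling:
    def test_exact_division(self):
        tiles = pm.tile_slide(np.zeros((1024, 1024, 3), np.uint8), 512)
        assert len(tiles) == 4
        assert [(t.row, t.col) for t in tiles] == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_remainders_are_dropped(self):
        tiles = pm.tile_slide(np.zeros((700, 1030, 3), np.uint8), 512)
        assert len(tiles) == 2

    def test_too_small_image_is_an_error(self):
        with pytest.raises(ValueError):
            pm.tile_slide(np.zeros((300, 600, 3), np.uint8), 512)

    def test_tiling_is_a_partition(self):
        img = np.arange(1024 * 1024 * 3, dtype=np.int64).reshape(1024, 1024, 3)
        tiles = pm.tile_slide(img, 512)
        seen = np.concatenate([t.pixels.ravel() for t in tiles])
        assert len(seen) == len(np.unique(seen))  # disjoint
        assert set(seen).issubset(set(range(img.size)))


class TestTissueMask:
    def test_bimodal_image_is_split_exactly(self):
        img = np.full((100, 100, 3), 255, np.uint8)
        img[:, :50] = 0
        m = pm.tissue_mask(img)
        assert m[:, :50].all() and not m[:, 50:].any()

    def test_constant_image_has_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            m = pm.tissue_mask(np.full((50, 50, 3), 255, np.uint8))
        assert not m.any()

    def test_synthetic_slide_mask_recovered(self):
        s = syn.make_slide(256, 256, 0, 0.5, seed=3)
        m = pm.tissue_mask(s.image)
        assert abs(m.mean() - s.tissue_mask.mean()) < 0.05


class TestFilterTiles:
    def _tiles_with_fraction(self, fracs, ts=10):
        # one tile row; mask designed so tile i has tissue fraction fracs[i]
        mask = np.zeros((ts, ts * len(fracs)), bool)
        for i, f in enumerate(fracs):
            block = np.zeros(ts * ts, bool)
            block[:int(round(f * ts * ts))] = True
            mask[:, i * ts:(i + 1) * ts] = block.reshape(ts, ts)
        img = np.zeros((ts, ts * len(fracs), 3), np.uint8)
        return pm.filter_tiles(pm.tile_slide(img, ts), mask)

    def test_full_tile_is_retained_and_boundary_rejected(self):
        got = self._tiles_with_fraction([1.0, 0.80])
        assert got[0].retained
        assert not got[1].retained  # strict inequality at 0.80

    def test_sweep_recovers_the_cutoff(self):
        fracs = np.round(np.arange(0.0, 1.01, 0.01), 2)
        got = self._tiles_with_fraction(list(fracs))
        rejected = [f for f, t in zip(fracs, got) if not t.retained]
        assert max(rejected) == 0.80


class TestStains:
    def test_recovery_within_two_degrees_on_synthetic_mixture(self):
        img, S = syn.make_stain_mixture(seed=4)
        model = pm.estimate_stains(img)
        for j in range(2):
            cosang = abs(model.stain_matrix[:, j] @ S[:, j])
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 2.0

    def test_pure_white_image_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient"):
            pm.estimate_stains(np.full((64, 64, 3), 255, np.uint8))

    def test_normalize_against_self_is_identity(self):
        img, _ = syn.make_stain_mixture(shape=(80, 80), seed=5)
        model = pm.estimate_stains(img)
        out = pm.normalize_tile(img, model, model)
        assert np.abs(out.astype(float) - img.astype(float)).mean() <= 2.0

    def test_normalization_is_idempotent(self):
        img, _ = syn.make_stain_mixture(shape=(80, 80), seed=6)
        ref_img, _ = syn.make_stain_mixture(shape=(80, 80), seed=7,
                                            stain_matrix=_ALT_STAINS)
        ref = pm.estimate_stains(ref_img)
        once = pm.normalize_tile(img, pm.estimate_stains(img), ref)
        twice = pm.normalize_tile(once, pm.estimate_stains(once), ref)
        assert np.abs(once.astype(float) - twice.astype(float)).mean() <= 2.0

    def test_cross_stain_difference_is_reduced(self):
        # same concentration scene rendered under two stain matrices
        rng = np.random.default_rng(8)
        n = 90 * 90
        frac = rng.beta(0.3, 0.3, n)
        mag = rng.uniform(0.4, 2.5, n)
        conc = np.column_stack([mag * frac, mag * (1 - frac)])
        S1 = syn.DEFAULT_STAIN_MATRIX
        S2 = _ALT_STAINS
        imgs = []
        for S in (S1, S2):
            od = conc @ S.T
            imgs.append(np.clip(np.rint(256 * 10 ** (-od) - 1), 0,
                                255).astype(np.uint8).reshape(90, 90, 3))
        m1, m2 = (pm.estimate_stains(i) for i in imgs)
        pre = np.abs(imgs[0].astype(float) - imgs[1].astype(float)).mean()
        n1 = pm.normalize_tile(imgs[0], m1, m1)
        n2 = pm.normalize_tile(imgs[1], m2, m1)
        post = np.abs(n1.astype(float) - n2.astype(float)).mean()
        assert post * 5 <= pre

    def test_unmix_reconstruction_matches_od(self):
        img, S = syn.make_stain_mixture(shape=(60, 60), seed=9)
        model = pm.estimate_stains(img)
        od = -np.log10((img.astype(float) + 1) / 256)
        rec = pm.stain_concentrations(img, model) @ model.stain_matrix.T
        assert np.linalg.norm(rec - od) / np.linalg.norm(od) < 0.05


# a second physically valid H&E basis (alternative dye lot / scanner)
_ALT_STAINS = np.array([[0.644, 0.093],
                        [0.717, 0.954],
                        [0.267, 0.283]])
_ALT_STAINS = _ALT_STAINS / np.linalg.norm(_ALT_STAINS, axis=0, keepdims=True)


class TestDeepFeatures:
    def test_pooling_equals_per_channel_maxima(self):
        rng = np.random.default_rng(0)
        act = rng.standard_normal((5, 7, 7))

        class Fake:
            out_channels = 5

            def __call__(self, x):
                return act

        v = pm.deep_features(np.zeros((32, 32, 3), np.uint8), Fake())
        assert np.array_equal(v, act.reshape(5, -1).max(axis=1))

    def test_wrong_grid_is_an_error(self):
        class Bad:
            def __call__(self, x):
                return np.zeros((4, 6, 6))

        with pytest.raises(ValueError, match="7, 7"):
            pm.deep_features(np.zeros((32, 32, 3), np.uint8), Bad())

    def test_backbone_is_deterministic(self):
        bb = pm.TinyResNet(out_channels=16, seed=3)
        tile = np.full((64, 64, 3), 128, np.uint8)
        v1 = pm.deep_features(tile, bb)
        v2 = pm.deep_features(tile, pm.TinyResNet(out_channels=16, seed=3))
        assert v1.shape == (16,)
        assert np.array_equal(v1, v2)
        assert np.all(np.isfinite(v1))

    def test_aggregate_identity_mean_and_symmetry(self):
        v = np.arange(4.0)
        w = np.ones(4)
        assert np.array_equal(pm.aggregate_slide([v]), v)
        assert np.allclose(pm.aggregate_slide([v, w]), (v + w) / 2)
        assert np.allclose(pm.aggregate_slide([v, w]),
                           pm.aggregate_slide([w, v]))
        assert np.allclose(pm.aggregate_slide([v, v]), v)

    def test_empty_aggregate_is_an_error(self):
        with pytest.raises(ValueError, match="no informative tissue"):
            pm.aggregate_slide([])


def _disk_channel(centers, radius, shape=(200, 200)):
    ch = np.zeros(shape)
    for cy, cx in centers:
        rr, cc = disk((cy, cx), radius, shape=shape)
        ch[rr, cc] = 1.0
    return ch


class TestSegmentation:
    def test_five_disks_give_five_objects(self):
        ch = _disk_channel([(40, 40), (40, 150), (100, 100), (160, 40),
                            (160, 150)], 10)
        lab = pm.segment_nuclei(ch, d_min=10, d_max=50)
        assert lab.max() == 5

    def test_small_disks_are_rejected(self):
        ch = _disk_channel([(100, 100)], 3)
        assert pm.segment_nuclei(ch, d_min=10, d_max=50).max() == 0

    def test_blank_channel_gives_no_objects(self):
        assert pm.segment_nuclei(np.zeros((64, 64)), 10, 50).max() == 0

    def test_expand_zero_is_identity(self):
        ch = _disk_channel([(100, 100)], 10)
        lab = pm.segment_nuclei(ch, 10, 50)
        assert np.array_equal(pm.expand_cells(lab, 0), lab)

    def test_expansion_matches_brute_force_nearest_seed(self):
        lab = np.zeros((40, 40), np.int32)
        lab[18:22, 10:14] = 1
        lab[18:22, 22:26] = 2
        got = pm.expand_cells(lab, 10)
        # brute-force: each pixel joins the nearest labeled pixel <= 10 px
        ys, xs = np.nonzero(lab)
        want = np.zeros_like(lab)
        for i in range(40):
            for j in range(40):
                d2 = (ys - i) ** 2 + (xs - j) ** 2
                k = np.argmin(d2)
                if d2[k] <= 100:
                    want[i, j] = lab[ys[k], xs[k]]
        # ties on the equidistant ridge may break either way
        assert (got == want).mean() > 0.97
        assert (got[lab > 0] == lab[lab > 0]).all()

    def test_expanded_cells_contain_their_nuclei(self):
        ch = _disk_channel([(50, 50), (50, 120)], 10)
        lab = pm.segment_nuclei(ch, 10, 50)
        cells = pm.expand_cells(lab, 8)
        assert ((cells == lab) | (lab == 0)).all()


class TestMorphometrics:
    def test_disk_area_within_five_percent(self):
        lab = np.zeros((100, 100), np.int32)
        rr, cc = disk((50, 50), 10)
        lab[rr, cc] = 1
        m = pm.morphometrics(lab, lab, lab.astype(float), lab.astype(float))
        assert abs(m["mean_nucleus_area"] - np.pi * 100) / (np.pi * 100) < 0.05

    def test_blank_image_yields_count_zero_vector(self):
        z = np.zeros((50, 50))
        m = pm.morphometrics(z.astype(np.int32), z.astype(np.int32), z, z)
        assert len(m) == 11
        assert m["nuclei_count"] == 0
        assert m["nuclear_density"] == 0
        assert np.isnan(m["mean_nucleus_area"])

    def test_eccentricity_of_circle_and_elongated_ellipse(self):
        lab = np.zeros((120, 120), np.int32)
        rr, cc = disk((60, 60), 20)
        lab[rr, cc] = 1
        m = pm.morphometrics(lab, lab, lab.astype(float), lab.astype(float))
        assert m["mean_nucleus_eccentricity"] <= 0.2
        lab2 = np.zeros((120, 120), np.int32)
        rr, cc = ellipse(60, 60, 10, 40)
        lab2[rr, cc] = 1
        m2 = pm.morphometrics(lab2, lab2, lab2.astype(float), lab2.astype(float))
        assert m2["mean_nucleus_eccentricity"] >= 0.9

    def test_segmentation_on_synthetic_slide_hematoxylin(self, slide):
        model = pm.estimate_stains(slide.image)
        h, _ = pm.unmix_channels(slide.image, model)
        lab = pm.segment_nuclei(h)
        assert abs(lab.max() - len(slide.nuclei)) <= 2
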