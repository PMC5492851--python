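import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from cstquant.calibration import BleedThroughParams
from cstquant.images import ImageSet
from cstquant.nfret import (
    compute_fret_index,
    compute_nfret,
    extract_line_profile,
    filament_mask,
    fire_lut,
    nfret_timecourse,
    pearson_colocalization,
    region_nfret_stats,
    render_false_color,
)
from cstquant.pipeline import preprocess_image_set
from cstquant.simulate import generate_filament_scene, generate_nocodazole_timecourse


def _imgset(d, a, f):
    return ImageSet(donor=np.asarray(d, float), acceptor=np.asarray(a, float), fret=np.asarray(f, float))


class TestFretIndex:
    def test_printed_formula_values(self, typical_bleed):
        images = _imgset([[100.0]], [[100.0]], [[50.0]])
        assert compute_fret_index(images, typical_bleed).values[0, 0] == pytest.approx(15.0)

    def test_zero_bleed_is_identity(self):
        images = _imgset([[3.0, 4.0]], [[5.0, 6.0]], [[7.0, 8.0]])
        out = compute_fret_index(images, BleedThroughParams(0, 0)).values
        assert np.array_equal(out, images.fret)

    def test_pure_crosstalk_cancels(self, typical_bleed):
        d = np.array([[100.0, 200.0]])
        a = np.array([[40.0, 80.0]])
        images = _imgset(d, a, typical_bleed.A * d + typical_bleed.B * a)
        assert np.allclose(compute_fret_index(images, typical_bleed).values, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _imgset(np.ones((4, 4)), np.ones((4, 4)), np.ones((5, 5)))


class TestNfret:
    def test_printed_formula_values(self, typical_bleed):
        # F_index 15 over sqrt(100*100) -> 15 on the x100 scale
        images = _imgset([[100.0]], [[100.0]], [[50.0]])
        nmap = compute_nfret(images, typical_bleed)
        assert nmap.values[0, 0] == pytest.approx(15.0)

    def test_gain_invariance(self, typical_bleed):
        images = _imgset([[100.0, 50.0]], [[80.0, 60.0]], [[60.0, 40.0]])
        n1 = compute_nfret(images, typical_bleed).values
        scaled = _imgset(4 * images.donor, 4 * images.acceptor, 4 * images.fret)
        n4 = compute_nfret(scaled, typical_bleed).values
        assert np.allclose(n1, n4)

    def test_negative_pixels_clamped_to_zero(self, typical_bleed):
        images = _imgset([[100.0]], [[100.0]], [[10.0]])  # F_index = -25
        nmap = compute_nfret(images, typical_bleed)
        assert nmap.values[0, 0] == 0.0
        assert nmap.raw[0, 0] < 0
        assert nmap.valid_mask[0, 0]

    def test_low_signal_pixels_invalid_not_zero(self, typical_bleed):
        images = _imgset([[100.0, 1.0]], [[100.0, 1.0]], [[50.0, 0.5]])
        nmap = compute_nfret(images, typical_bleed, signal_floor=6.0)
        assert not nmap.valid_mask[0, 1]
        assert np.isnan(nmap.values[0, 1])

    def test_all_invalid_warns(self, typical_bleed):
        images = _imgset([[1.0]], [[1.0]], [[1.0]])
        with pytest.warns(UserWarning, match="signal floor"):
            compute_nfret(images, typical_bleed)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        arr=hnp.arrays(
            float,
            (3, 3),
            elements=st.floats(min_value=10.0, max_value=1e4),
        ),
        gain=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_index_linear_and_nfret_gain_invariant(self, arr, gain):
        bleed = BleedThroughParams(0.1, 0.25)
        images = _imgset(arr, arr[::-1], 0.5 * arr)
        scaled = _imgset(gain * images.donor, gain * images.acceptor, gain * images.fret)
        f1 = compute_fret_index(images, bleed).values
        fg = compute_fret_index(scaled, bleed).values
        assert np.allclose(fg, gain * f1, rtol=1e-9)
        n1 = compute_nfret(images, bleed, signal_floor=0.0).values
        ng = compute_nfret(scaled, bleed, signal_floor=0.0).values
        assert np.allclose(ng, n1, rtol=1e-7)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        fret=hnp.arrays(float, (4, 4), elements=st.floats(min_value=0.0, max_value=100.0)),
    )
    def test_clamping_only_raises_values(self, fret):
        bleed = BleedThroughParams(0.1, 0.25)
        images = _imgset(np.full((4, 4), 50.0), np.full((4, 4), 50.0), fret)
        nmap = compute_nfret(images, bleed)
        assert np.all(nmap.values >= nmap.raw)
        nonneg = nmap.raw >= 0
        assert np.array_equal(nmap.values[nonneg], nmap.raw[nonneg])


class TestFilamentMask:
    def test_recovers_generator_filaments(self, small_untreated):
        images, truth = generate_filament_scene(small_untreated, seed=1)
        pre = preprocess_image_set(images)
        mask = filament_mask(pre.acceptor)
        inter = (mask & truth.filament_mask).sum()
        union = (mask | truth.filament_mask).sum()
        assert inter / union > 0.5

    def test_blank_image_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="blank"):
            mask = filament_mask(np.zeros((64, 64)))
        assert not mask.any()


class TestLineProfile:
    def test_constant_image_constant_profile(self):
        prof = extract_line_profile(np.full((20, 20), 7.0), np.array([[2.0, 2.0], [2.0, 17.0]]))
        assert np.allclose(prof.values, 7.0)
        assert np.all(np.diff(prof.positions) > 0)

    def test_peak_at_filament_crossing(self):
        img = np.zeros((32, 32))
        img[:, 15] = 10.0  # vertical filament at col 15
        prof = extract_line_profile(img, np.array([[16.0, 2.0], [16.0, 29.0]]))
        assert prof.positions[np.argmax(prof.values)] == pytest.approx(13.0, abs=1.0)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_line_profile(np.zeros((10, 10)), np.array([[0.0, 0.0], [0.0, 20.0]]))


class TestRegionStats:
    def test_uniform_region(self, typical_bleed):
        images = _imgset(np.full((8, 8), 100.0), np.full((8, 8), 100.0), np.full((8, 8), 45.0))
        nmap = compute_nfret(images, typical_bleed)
        stats = region_nfret_stats(nmap, np.ones((8, 8), bool))
        assert stats.mean == pytest.approx(10.0)
        assert stats.sd == 0.0
        assert stats.n == 64

    def test_per_cell_averaging(self, typical_bleed):
        fret = np.full((4, 4), 45.0)
        fret[:, 2:] = 80.0  # second cell has F_index 45 -> NFRET 45
        images = _imgset(np.full((4, 4), 100.0), np.full((4, 4), 100.0), fret)
        nmap = compute_nfret(images, typical_bleed)
        labels = np.ones((4, 4), int)
        labels[:, 2:] = 2
        stats = region_nfret_stats(nmap, np.ones((4, 4), bool), cell_labels=labels)
        assert stats.n == 2
        assert stats.mean == pytest.approx((10.0 + 45.0) / 2)
        assert stats.per_cell

    def test_empty_mask_rejected(self, typical_bleed):
        images = _imgset(np.full((4, 4), 100.0), np.full((4, 4), 100.0), np.full((4, 4), 45.0))
        nmap = compute_nfret(images, typical_bleed)
        with pytest.raises(ValueError):
            region_nfret_stats(nmap, np.zeros((4, 4), bool))


class TestPearson:
    def test_identity_and_inversion(self, rng):
        x = rng.normal(size=(50, 50))
        assert pearson_colocalization(x, x) == pytest.approx(1.0)
        assert pearson_colocalization(x, -x + 3) == pytest.approx(-1.0)

    def test_known_population_correlation(self, rng):
        n = 10_000
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=n)
        r = pearson_colocalization(z[:, 0], z[:, 1], np.ones(n, bool))
        assert r == pytest.approx(0.8, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_colocalization(np.ones((5, 5)), np.arange(25.0).reshape(5, 5))


class TestRendering:
    def test_lut_shape_and_extremes(self):
        lut = fire_lut()
        assert lut.shape == (256, 3)
        assert np.array_equal(lut[0], [0, 0, 0])
        assert np.array_equal(lut[255], [255, 255, 255])

    def test_display_range_mapping(self, typical_bleed):
        vals = np.array([[0.0, 30.0, 60.0, 90.0]])
        nmap = type(compute_nfret(_imgset([[1.0]], [[1.0]], [[1.0]]), typical_bleed, 0.0))(
            values=vals, valid_mask=np.ones_like(vals, bool), raw=vals
        )
        rgb = render_false_color(nmap, (0.0, 60.0))
        lut = fire_lut()
        assert np.array_equal(rgb[0, 0], lut[0])
        assert np.array_equal(rgb[0, 1], lut[128])  # mid-scale, round-half-even
        assert np.array_equal(rgb[0, 2], lut[255])
        assert np.array_equal(rgb[0, 3], lut[255])  # clipped to top colour

    def test_invalid_pixels_black(self):
        vals = np.array([[50.0, np.nan]])
        from cstquant.nfret import NFRETMap

        nmap = NFRETMap(values=vals, valid_mask=np.array([[True, False]]), raw=vals)
        rgb = render_false_color(nmap)
        assert np.array_equal(rgb[0, 1], [0, 0, 0])


class TestTimecourse:
    def test_static_scene_gives_flat_series(self, small_untreated, typical_bleed):
        images, _ = generate_filament_scene(small_untreated.with_(noise_scale=0.0), seed=2)
        pre = preprocess_image_set(images)
        df = nfret_timecourse([(0.0, pre), (60.0, pre), (120.0, pre)], typical_bleed)
        assert df["mean_nfret"].nunique() == 1

    def test_nocodazole_series_nonincreasing(self, small_untreated, typical_bleed):
        series = generate_nocodazole_timecourse(
            small_untreated.with_(noise_scale=0.0), seed=3, timepoints=[0.0, 600.0, 1200.0, 1800.0]
        )
        pre = [(t, preprocess_image_set(img)) for t, img, _ in series]
        df = nfret_timecourse(pre, typical_bleed, mask_policy="per-frame")
        means = df["mean_nfret"].to_numpy()
        assert np.all(np.diff(means) <= 1e-9)
        # ten minutes of depolymerization roughly halves the signal
        assert means[1] / means[0] == pytest.approx(0.5, abs=0.15)
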