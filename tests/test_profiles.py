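import numpy as np
import pytest
from scipy.special import erfinv

from mrgating import (
    DeliverySegments,
    DoseDistribution2D,
    FieldSpec,
    Profile1D,
    ScanImage,
    convolve_reference,
    duty_cycle_signal,
    extract_profile,
    preprocess_scan,
    profile_constancy,
    profile_metrics,
    register_points,
    synthetic_static_field,
)
from mrgating.dose import build_segments
from mrgating.traces import MotionTrace
from oracles import brute_force_median, brute_force_rigid_residual


@pytest.fixture
def field_20cm():
    """20 cm x 20 cm field on a 1 mm grid (output-constancy geometry)."""
    spec = FieldSpec(field_size=(200.0, 200.0), penumbra_sigma=3.0)
    ax = np.arange(-130.0, 130.01, 1.0)
    return synthetic_static_field(spec, ax, ax)


class TestPreprocessScan:
    def test_window_one_is_identity_on_channel(self):
        rng = np.random.default_rng(0)
        img = ScanImage(pixels=rng.integers(0, 255, (12, 14, 3)).astype(np.uint8), pixel_spacing=0.5)
        dose = preprocess_scan(img, channel="red", median_window=1)
        assert np.array_equal(dose.dose, img.pixels[:, :, 0].T.astype(float))
        assert dose.spacing == (0.5, 0.5)

    def test_single_impulse_removed(self):
        px = np.full((11, 11), 100.0)
        px[5, 5] = 10_000.0
        dose = preprocess_scan(ScanImage(pixels=px, pixel_spacing=1.0), median_window=3)
        assert np.all(dose.dose == 100.0)

    def test_matches_brute_force_median(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 1, (15, 12))
        dose = preprocess_scan(ScanImage(pixels=px, pixel_spacing=1.0), median_window=3)
        assert np.allclose(dose.dose, brute_force_median(px, 3).T, atol=1e-12)

    def test_even_window_rejected(self):
        img = ScanImage(pixels=np.zeros((5, 5)), pixel_spacing=1.0)
        with pytest.raises(ValueError):
            preprocess_scan(img, median_window=4)


class TestRegisterPoints:
    def test_identity(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [7.0, 3.0]])
        tf = register_points(pts, pts)
        assert tf.rotation_rad == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.translation, 0.0, atol=1e-12)
        assert tf.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_rigid_transform(self):
        rng = np.random.default_rng(4)
        src = rng.uniform(-20, 20, (6, 2))
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        dst = src @ R.T + [3.0, -2.0]
        tf = register_points(src, dst)
        assert tf.rotation_rad == pytest.approx(th, abs=1e-9)
        assert np.allclose(tf.translation, [3.0, -2.0], atol=1e-9)
        assert np.allclose(tf.apply(src), dst, atol=1e-9)

    def test_noisy_residual_matches_numeric_optimizer(self):
        rng = np.random.default_rng(8)
        src = rng.uniform(-20, 20, (8, 2))
        th = np.deg2rad(-7.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        dst = src @ R.T + [1.0, 4.0] + rng.normal(0, 0.3, (8, 2))
        tf = register_points(src, dst)
        assert tf.residual_rms == pytest.approx(brute_force_rigid_residual(src, dst), abs=1e-6)

    def test_residual_invariant_under_common_transform(self):
        rng = np.random.default_rng(9)
        src = rng.uniform(-10, 10, (5, 2))
        dst = src + rng.normal(0, 0.5, (5, 2))
        r0 = register_points(src, dst).residual_rms
        th = np.deg2rad(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        r1 = register_points(src @ R.T + [5, -1], dst @ R.T + [5, -1]).residual_rms
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_coincident_points_rejected(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            register_points(pts, pts)


class TestExtractProfile:
    def test_single_row_band(self, small_field):
        p = extract_profile(small_field, "in-plane", band_center=0.0, band_width=0.5)
        i = np.argmin(np.abs(small_field.x_axis))
        assert np.array_equal(p.value, small_field.dose[i, :])

    def test_separable_field_band_mean_equals_row(self, small_field):
        wide = extract_profile(small_field, "cross-plane", band_center=7.5, band_width=5.0)
        narrow = extract_profile(small_field, "cross-plane", band_center=7.5, band_width=0.5)
        assert np.allclose(wide.value / wide.value.max(), narrow.value / narrow.value.max(), atol=1e-6)

    def test_matches_row_averaging_oracle(self):
        rng = np.random.default_rng(2)
        x = np.arange(10.0)
        z = np.arange(12.0)
        dose = DoseDistribution2D(x, z, rng.uniform(0, 1, (10, 12)))
        p = extract_profile(dose, "cross-plane", band_center=5.0, band_width=4.0)
        sel = (z >= 3.0) & (z <= 7.0)
        assert np.allclose(p.value, dose.dose[:, sel].mean(axis=1), atol=1e-12)

    def test_band_outside_grid_rejected(self, small_field):
        with pytest.raises(ValueError):
            extract_profile(small_field, "cross-plane", band_center=500.0)


class TestProfileMetrics:
    def test_flat_top_has_zero_flatness_and_symmetry(self):
        pos = np.linspace(-150, 150, 601)
        val = np.where(np.abs(pos) <= 100, 1.0, 0.0)
        # soften the step over one sample so crossings interpolate
        m = profile_metrics(Profile1D(pos, val, "cross-plane"))
        assert m.flatness == pytest.approx(0.0, abs=1e-9)
        assert m.symmetry == pytest.approx(0.0, abs=1e-9)
        assert m.field_size == pytest.approx(200.0, abs=1.0)

    def test_field_size_matches_nominal_20cm(self, field_20cm):
        p = extract_profile(field_20cm, "cross-plane", band_center=0.0, band_width=5.0)
        m = profile_metrics(p)
        assert m.field_size == pytest.approx(200.0, abs=1.0)
        assert m.cax == pytest.approx(1.0, abs=1e-6)

    def test_penumbra_matches_erf_closed_form(self):
        # fine grid so linear interpolation of the erf edge is negligible
        spec = FieldSpec(field_size=(200.0, 200.0), penumbra_sigma=3.0)
        ax = np.arange(-130.0, 130.01, 0.25)
        field = synthetic_static_field(spec, ax, ax)
        p = extract_profile(field, "cross-plane", band_center=0.0, band_width=0.5)
        m = profile_metrics(p)
        expected = 2.0 * np.sqrt(2.0) * erfinv(0.6) * 3.0
        assert m.penumbra_left == pytest.approx(expected, rel=0.01)
        assert m.penumbra_right == pytest.approx(expected, rel=0.01)

    def test_metrics_invariant_to_uniform_scaling_except_cax(self, field_20cm):
        p = extract_profile(field_20cm, "in-plane", band_center=0.0, band_width=5.0)
        m1 = profile_metrics(p)
        m2 = profile_metrics(Profile1D(p.position, 0.37 * p.value, "in-plane"))
        assert m2.cax == pytest.approx(0.37 * m1.cax, rel=1e-9)
        for attr in ("field_size", "penumbra_left", "penumbra_right", "flatness", "symmetry"):
            assert getattr(m2, attr) == pytest.approx(getattr(m1, attr), abs=1e-9)

    def test_profile_without_crossings_rejected(self):
        pos = np.linspace(-10, 10, 21)
        with pytest.raises(ValueError):
            profile_metrics(Profile1D(pos, np.full(21, 5.0), "cross-plane"))


class TestProfileConstancy:
    def test_identical_inputs_zero_deltas(self, field_20cm):
        m = profile_metrics(extract_profile(field_20cm, "cross-plane", 0.0, 5.0))
        deltas = profile_constancy(m, m)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in deltas.values())

    def test_small_output_drop_in_cax(self, field_20cm):
        p = extract_profile(field_20cm, "cross-plane", 0.0, 5.0)
        m_ref = profile_metrics(p)
        m_gated = profile_metrics(Profile1D(p.position, 0.999 * p.value, p.axis))
        deltas = profile_constancy(m_ref, m_gated)
        assert deltas["cax_pct"] == pytest.approx(-0.1, abs=1e-6)

    def test_duty_cycle_delivery_with_ideal_servo_is_constant(self, field_20cm):
        # static target, applet gating: the time-weighted delivery collapses
        # to the static field itself, so all constancy deltas vanish
        t = np.arange(0, 3001) / 100.0
        motion = MotionTrace(t=t, z=np.zeros_like(t), fs=100.0)
        m_ref = profile_metrics(extract_profile(field_20cm, "cross-plane", 0.0, 5.0))
        for on_s, off_s in ((2.0, 1.0), (0.5, 1.0), (0.05, 0.05)):
            beam = duty_cycle_signal(on_s, off_s, motion.duration, 2000.0)
            gated = convolve_reference(field_20cm, build_segments(motion, beam), window=(0.0, 15.0))
            m_gated = profile_metrics(extract_profile(gated, "cross-plane", 0.0, 5.0))
            deltas = profile_constancy(m_ref, m_gated)
            assert all(abs(v) < 1e-9 for v in deltas.values())
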