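"""Sample-builder operations: SG envelope, LAI fit, envelope synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from viseam import synthetic
from viseam.samples import (
    FitError,
    LaiViFit,
    SGConfig,
    apply_fit,
    build_target,
    fit_lai_vi,
    flag_outliers,
    read_sample_store,
    read_sg_config,
    sg_envelope_filter,
    sg_smooth,
    snow_blend,
    synthesize,
    upper_envelope_interpolate,
    write_sample_store,
    write_sg_config,
)
from viseam.series import (
    EVI,
    NDVI,
    SENTINEL,
    LAISeries,
    QASeries,
    SeriesError,
    UnusableSeriesError,
    VISeries,
)

from conftest import make_vi


def poly_ls_oracle(values, center, half_width, order):
    """Dense normal-equations least squares on one window.

    The abscissa is scaled to [-1, 1] to keep the normal equations well
    conditioned; the fitted value at the window centre is unchanged.
    """
    t = np.arange(-half_width, half_width + 1, dtype=float) / half_width
    y = values[center - half_width : center + half_width + 1]
    A = np.vander(t, order + 1, increasing=True)
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    return coef[0]  # value at window centre


class TestSGEnvelope:
    def test_constant_series_unchanged(self):
        vi = VISeries(values=np.full(92, 0.5))
        out = sg_envelope_filter(vi, SGConfig())
        np.testing.assert_allclose(out.values, 0.5, atol=1e-12)

    def test_defaults_match_standard_configuration(self):
        cfg = SGConfig()
        assert cfg.half_width == 12 and cfg.iterations == 2

    def test_matches_window_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0.0, 1.0, 92)
        for hw, order in ((12, 2), (12, 6), (5, 3)):
            s = sg_smooth(y, hw, order)
            for center in (hw, 40, 91 - hw):
                assert abs(s[center] - poly_ls_oracle(y, center, hw, order)) < 1e-10

    def test_agrees_with_scipy_savgol_at_low_order(self):
        # independent route: scipy's convolution-based filter is accurate
        # at low polynomial order and must agree with the direct LS fit
        from scipy.signal import savgol_filter

        rng = np.random.default_rng(8)
        y = rng.uniform(0, 1, 92)
        ours = sg_smooth(y, 12, 2)
        scipys = savgol_filter(y, 25, 2, mode="interp")
        np.testing.assert_allclose(ours, scipys, atol=1e-9)

    def test_fills_sentinels_before_fitting(self):
        v = np.full(92, 0.5)
        v[10:20] = SENTINEL
        out = sg_envelope_filter(VISeries(values=v), SGConfig())
        np.testing.assert_allclose(out.values, 0.5, atol=1e-9)

    def test_all_sentinel_raises(self):
        with pytest.raises(UnusableSeriesError):
            sg_envelope_filter(VISeries(values=np.full(92, SENTINEL)), SGConfig())

    def test_idempotent_in_polynomial_passband(self):
        # SG reproduces polynomials up to its order exactly, so a second
        # application of a single-iteration envelope pass is a fixed point
        t = np.linspace(-1, 1, 92)
        vi = VISeries(values=0.5 + 0.3 * t - 0.2 * t * t)
        cfg = SGConfig(iterations=1)
        once = sg_envelope_filter(vi, cfg)
        twice = sg_envelope_filter(once, cfg)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-6)

    def test_config_invariants(self):
        with pytest.raises(SeriesError):
            SGConfig(half_width=2, poly_order=2)
        with pytest.raises(SeriesError):
            SGConfig(iterations=0)


class TestFlagOutliers:
    def test_identity_when_equal(self):
        vi = VISeries(values=np.full(46, 0.4))
        out = flag_outliers(vi, vi, 0.4)
        assert np.array_equal(out.values, vi.values)

    def test_flags_beyond_threshold(self):
        vi = make_vi([0.1])
        smooth = make_vi([0.6])
        out = flag_outliers(vi, smooth, 0.4)
        assert out.values[0] == SENTINEL

    def test_boundary_equality_keeps_point(self):
        vi = make_vi([0.2])
        smooth = make_vi([0.6])
        out = flag_outliers(vi, smooth, 0.4)  # deviation exactly 0.4
        assert out.values[0] == 0.2

    @given(st.floats(0.05, 0.6), st.floats(0.05, 0.6))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        rng = np.random.default_rng(0)
        vi = VISeries(values=rng.uniform(0, 1, 46))
        smooth = VISeries(values=rng.uniform(0, 1, 46))
        n_lo = np.sum(flag_outliers(vi, smooth, lo).values == SENTINEL)
        n_hi = np.sum(flag_outliers(vi, smooth, hi).values == SENTINEL)
        assert n_hi <= n_lo


class TestLaiViFit:
    def test_noiseless_recovery(self):
        a, b, c = -0.8, 0.2, 0.9
        lai = np.tile(np.linspace(0, 6, 46), 2)
        vi = np.clip(c - np.exp(a * lai + b), -0.2, 1.0)
        fit = fit_lai_vi(VISeries(values=vi), LAISeries(values=lai))
        assert fit.a == pytest.approx(a, abs=1e-4)
        assert fit.b == pytest.approx(b, abs=1e-4)
        assert fit.c == pytest.approx(c, abs=1e-4)

    def test_constant_lai_unidentifiable(self):
        with pytest.raises(FitError):
            fit_lai_vi(VISeries(values=np.full(46, 0.5)),
                       LAISeries(values=np.full(46, 3.0)))

    def test_too_few_pairs(self):
        v = np.full(46, SENTINEL)
        v[:2] = 0.5
        with pytest.raises(FitError):
            fit_lai_vi(VISeries(values=v),
                       LAISeries(values=np.linspace(0, 5, 46)))

    def test_constrained_branch_bounds_sign(self):
        rng = np.random.default_rng(5)
        lai = np.clip(rng.uniform(5.2, 9.5, 92), 0, 10)
        vi = np.clip(0.95 - np.exp(-0.35 * lai + 0.1)
                     + rng.normal(0, 0.01, 92), -0.2, 1.0)
        fit = fit_lai_vi(VISeries(values=vi), LAISeries(values=lai),
                         constrain=True, constrain_sign=1.0)
        assert fit.constrained and fit.a >= 0

    def test_apply_fit_limits(self):
        fit = LaiViFit(a=-1.0, b=0.0, c=1.0, rss=0.0, n_used=10)
        lai = LAISeries(values=np.concatenate([[0.0], np.full(45, 10.0)]))
        out = apply_fit(fit, lai)
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[1] == pytest.approx(1.0, abs=1e-4)  # saturation

    def test_round_trip_through_apply(self):
        a, b, c = -0.5, -0.1, 0.92
        lai = np.tile(np.linspace(0.2, 5.5, 46), 2)
        vi = c - np.exp(a * lai + b)
        fit = fit_lai_vi(VISeries(values=vi), LAISeries(values=lai))
        back = apply_fit(fit, LAISeries(values=lai))
        np.testing.assert_allclose(back.values, vi, atol=1e-4)


class TestUpperEnvelope:
    def test_hand_worked_example(self):
        vi = make_vi([0.1, 0.5, 0.2, 0.6, 0.1])
        out = upper_envelope_interpolate(vi)
        assert out.values[2] == pytest.approx(0.55)
        np.testing.assert_allclose(out.values[[0, 1, 3, 4]],
                                   [0.1, 0.5, 0.6, 0.1])

    def test_constant_series_identity(self):
        vi = VISeries(values=np.full(46, 0.4))
        np.testing.assert_allclose(upper_envelope_interpolate(vi).values, 0.4)

    def test_strictly_increasing_identity(self):
        v = np.linspace(0.1, 0.9, 46)
        out = upper_envelope_interpolate(VISeries(values=v))
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_sentinels_are_never_envelope_points(self):
        v = np.full(46, 0.5)
        v[10] = SENTINEL
        out = upper_envelope_interpolate(VISeries(values=v))
        assert out.values[10] == pytest.approx(0.5)

    def test_too_few_valid_points(self):
        v = np.full(46, SENTINEL)
        v[3] = 0.5
        with pytest.raises(UnusableSeriesError):
            upper_envelope_interpolate(VISeries(values=v))


class TestSynthesizeAndSnowBlend:
    def test_elementwise_max(self):
        f = make_vi([0.2, 0.8])
        e = make_vi([0.5, 0.4])
        out = synthesize(f, e)
        assert out.values[0] == 0.5 and out.values[1] == 0.8
        assert np.all(out.values >= f.values) and np.all(out.values >= e.values)

    def test_sentinel_input_rejected(self):
        f = make_vi([SENTINEL, 0.8])
        with pytest.raises(SeriesError):
            synthesize(f, make_vi([0.5, 0.4]))

    def test_blend_endpoints_exact(self):
        n = 46
        syn = VISeries(values=np.full(n, 0.6))
        trigger = VISeries(values=np.full(n, 0.1))  # below 0.2 everywhere
        at_02 = snow_blend(VISeries(values=np.full(n, 0.2)), syn, trigger)
        assert np.all(at_02.values == 0.6)
        at_m02 = snow_blend(VISeries(values=np.full(n, -0.2)), syn, trigger)
        assert np.all(at_m02.values == -0.2)

    def test_blend_midpoint(self):
        n = 46
        out = snow_blend(VISeries(values=np.full(n, 0.0)),
                         VISeries(values=np.full(n, 0.6)),
                         VISeries(values=np.full(n, 0.1)))
        np.testing.assert_allclose(out.values, 0.3)

    def test_blend_is_convex_combination(self):
        rng = np.random.default_rng(2)
        ori = VISeries(values=rng.uniform(-0.19, 0.4, 46))
        syn = VISeries(values=rng.uniform(0.0, 0.9, 46))
        sg = VISeries(values=rng.uniform(0.0, 0.4, 46))
        out = snow_blend(ori, syn, sg)
        lo = np.minimum(ori.values, syn.values) - 1e-12
        hi = np.maximum(ori.values, syn.values) + 1e-12
        blended = sg.values < 0.2
        assert np.all(out.values[blended] >= lo[blended])
        assert np.all(out.values[blended] <= hi[blended])
        np.testing.assert_allclose(out.values[~blended], syn.values[~blended])


class TestBuildTarget:
    def test_clean_pixel_near_idempotent(self, clean_pixel):
        truth, lai = clean_pixel
        rec = build_target(truth, lai)
        rmse = np.sqrt(np.mean((rec.target_vi.values - truth.values) ** 2))
        assert rmse < 0.02
        assert rec.provenance in ("standard", "snow-blend")

    def test_cloud_gap_filled_within_plausible_range(self, clean_pixel):
        truth, lai = clean_pixel
        v = truth.values.copy()
        v[30:35] = SENTINEL  # five-step gap near peak growth
        rec = build_target(truth.with_values(v), lai)
        assert np.all(rec.target_vi.values != SENTINEL)
        cfg = SGConfig.for_kind(NDVI)
        assert rec.target_vi.values.min() >= truth.values.min() - cfg.deviation_threshold
        assert rec.target_vi.values.max() <= truth.values.max() + cfg.deviation_threshold

    def test_saturation_branch_provenance(self):
        phen = synthetic.PhenologyParams(
            base_vi=0.8, peak_vi=0.9, transition_steepness=0.03,
            inter_annual_jitter=0.0)
        truth, lai = synthetic.generate_truth(
            phen, seed=3, lai_coeffs=synthetic.LAI_VI_SATURATED)
        assert lai.values.min() > 5.0
        rec = build_target(truth, lai)
        assert rec.provenance == "saturation-refit"

    def test_output_always_in_range_without_sentinels(self, contaminated_pixel):
        truth, observed, lai, qa = contaminated_pixel
        rec = build_target(observed, lai, qa=qa)
        assert np.all(rec.target_vi.values > SENTINEL)
        assert np.all(rec.target_vi.values <= 1.0)

    def test_target_dominates_lai_fit_before_smoothing(self, contaminated_pixel):
        # the synthesis step guarantees target >= LAI-fit curve pre-smoothing
        truth, observed, lai, qa = contaminated_pixel
        cfg = SGConfig.for_kind(NDVI)
        smooth = sg_envelope_filter(observed, cfg)
        flagged = flag_outliers(observed, smooth, cfg.deviation_threshold)
        fit = fit_lai_vi(flagged, lai)
        fitting = apply_fit(fit, lai)
        env = upper_envelope_interpolate(flagged)
        syn = synthesize(fitting, env)
        assert np.all(syn.values >= fitting.values - 1e-9)


def test_sample_store_round_trip(tmp_path, clean_pixel):
    truth, lai = clean_pixel
    rec = build_target(truth, lai)
    path = tmp_path / "samples.csv"
    write_sample_store(path, [rec, rec])
    back = read_sample_store(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].target_vi.values, rec.target_vi.values)
    assert back[0].provenance == rec.provenance


def test_sg_config_file_round_trip(tmp_path):
    cfgs = {"NDVI": SGConfig(), "EVI": SGConfig.for_kind(EVI)}
    path = tmp_path / "sg.cfg"
    write_sg_config(path, cfgs)
    back = read_sg_config(path)
    assert back["NDVI"] == cfgs["NDVI"]
    assert back["EVI"] == cfgs["EVI"]
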