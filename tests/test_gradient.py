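"""Gaussian fitting, the three-layer normalization, averaging, controls."""

import numpy as np
import pandas as pd
import pytest

from embryograd import gradient
from embryograd.errors import AlignmentError, FitError
from embryograd.gradient import (
    EmbryoGradientData,
    NormalizationContext,
    average_embryos,
    control_background,
    correlate_channels,
    dv_norm_curve,
    fit_gaussian,
    low_pass,
    mesh_edges,
    normalize_fixed,
    session_factor,
    smooth_params,
    time_course_at_dv,
    timecourse_factor,
)
from embryograd.synth import gaussian_gradient


class TestFitGaussian:
    def test_noiseless_recovery_to_machine_precision(self):
        x = np.linspace(-1, 1, 100)
        y = gaussian_gradient(x, 10.0, 2.0, 0.0, 0.15)
        fit = fit_gaussian(x, y)
        assert fit.A == pytest.approx(10.0, rel=1e-6)
        assert fit.B == pytest.approx(2.0, rel=1e-6)
        assert fit.mu == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma == pytest.approx(0.15, rel=1e-6)
        assert fit.residual_norm < 1e-9

    @pytest.mark.parametrize(
        "params", [(5.0, 1.0, 0.3, 0.08), (3.0, 0.5, -0.4, 0.3), (20.0, 4.0, 0.0, 0.5)]
    )
    def test_recovery_across_parameter_space(self, params):
        x = np.linspace(-1, 1, 200)
        y = gaussian_gradient(x, *params)
        fit = fit_gaussian(x, y)
        assert np.allclose([fit.A, fit.B, fit.mu, fit.sigma], params, rtol=1e-6,
                           atol=1e-8)

    def test_flat_data_yields_zero_amplitude(self):
        x = np.linspace(-1, 1, 50)
        fit = fit_gaussian(x, np.full(50, 7.3))
        assert fit.A == pytest.approx(0.0, abs=1e-6)
        assert fit.B == pytest.approx(7.3, rel=1e-6)

    def test_model_closed_form_at_peak_and_width(self):
        fit = gradient.GradientFit(A=10, B=2, mu=0.1, sigma=0.2,
                                   residual_norm=0, n_nuclei=50)
        assert fit(0.1) == pytest.approx(12.0)
        assert fit(0.1 + 0.2) == pytest.approx(2 + 10 * np.exp(-0.5))
        assert fit(0.1 - 0.2) == pytest.approx(2 + 10 * np.exp(-0.5))

    def test_too_few_nuclei_rejected(self):
        with pytest.raises(FitError):
            fit_gaussian(np.linspace(0, 1, 5), np.ones(5))


class TestNormalizationFactors:
    def test_session_factor_identity_and_scaling(self):
        assert session_factor(1.74e4, 0.1) == pytest.approx(1.0)
        assert session_factor(2 * 1.74e4, 0.1) == pytest.approx(2.0)
        assert session_factor(1.74e4, 0.2) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            session_factor(-1.0, 0.1)

    def test_timecourse_factor_identity_and_scaling(self):
        assert timecourse_factor(100.0, 1.0) == pytest.approx(1.0)
        assert timecourse_factor(200.0, 1.0) == pytest.approx(2.0)
        assert timecourse_factor(100.0, 2.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            timecourse_factor(100.0, 0.0)

    def test_context_multiplicative_composition_order_free(self):
        ctx = NormalizationContext(calib_mean=2e4, calib_lp=0.12, nuc_mean=130.0,
                                   nuc_lp=1.1)
        ctx.curve_norm = 1.0 + 0.2 * np.sin(np.linspace(0, 3, 151))
        ctx.curve_norm /= ctx.curve_norm.mean()
        dv = np.linspace(-1, 1, 40)
        raw = np.full(40, 500.0)
        joint = ctx.normalize(raw, dv)
        stepwise = raw / ctx.calib_norm
        stepwise = stepwise / ctx.timecourse_norm
        stepwise = stepwise / gradient.apply_dv_curve(dv, ctx.x_grid, ctx.curve_norm)
        assert np.allclose(joint, stepwise, rtol=1e-12)
        # the 151-point grid is enforced
        with pytest.raises(ValueError):
            NormalizationContext(curve_norm=np.ones(150))

    def test_global_brightness_cancels_between_embryos(self):
        dv = np.linspace(-1, 1, 60)
        base = gaussian_gradient(dv, 8.0, 2.0, 0.0, 0.2) * 100
        ctx_a = NormalizationContext(nuc_mean=100.0, nuc_lp=1.0)
        ctx_b = NormalizationContext(nuc_mean=130.0, nuc_lp=1.0)
        a = ctx_a.normalize(base, dv)
        b = ctx_b.normalize(1.3 * base, dv)  # 1.3x brighter embryo
        assert np.allclose(a, b, rtol=0.02)


class TestNormalizeFixed:
    def _records(self, n=80, ch2=None, ch1=None):
        dv = np.linspace(-1, 1, n)
        nuc = np.full(n, 50.0)
        if ch1 is None:
            ch1 = 50.0 * gaussian_gradient(dv, 6.0, 1.0, 0.0, 0.18)
        if ch2 is None:
            ch2 = ch1.copy()
        return pd.DataFrame(
            {"dv": dv, "mean_nuclear": nuc, "mean_signal": ch1, "mean_signal2": ch2}
        )

    def test_gaussian_channel_normalizes_to_unit_range(self):
        rec = self._records()
        out, fits = normalize_fixed(rec, channels=("mean_signal",))
        prof = out["norm_mean_signal"]
        assert prof.min() == pytest.approx(0.0, abs=0.02)
        assert prof.max() == pytest.approx(1.0, abs=0.02)
        assert fits["mean_signal"].sigma == pytest.approx(0.18, rel=1e-3)

    def test_flat_channel_handled_without_blowup(self):
        rec = self._records(ch1=np.full(80, 50.0))
        out, fits = normalize_fixed(rec, channels=("mean_signal",))
        assert np.isfinite(out["norm_mean_signal"]).all()
        assert fits["mean_signal"].A == pytest.approx(0.0, abs=1e-6)

    def test_shared_field_channels_normalize_identically(self):
        rec = self._records()
        out, _ = normalize_fixed(rec)
        assert np.allclose(
            out["norm_mean_signal"], out["norm_mean_signal2"], atol=1e-6
        )

    def test_low_nuclear_nuclei_dropped(self):
        rec = self._records()
        rec.loc[3, "mean_nuclear"] = 0.0
        out, _ = normalize_fixed(rec, channels=("mean_signal",))
        assert len(out) == len(rec) - 1


class TestDvNormCurve:
    def _frames(self, nuclear_fn, n=60, n_frames=3):
        rows = []
        rng = np.random.default_rng(0)
        for f in range(n_frames):
            dv = rng.uniform(-1, 1, n)
            rows.append(
                pd.DataFrame(
                    {"frame": f, "dv": dv, "mean_nuclear": nuclear_fn(np.abs(dv))}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_uniform_nuclear_channel_gives_unit_curve(self):
        rec = self._frames(lambda x: np.full_like(x, 3000.0))
        grid, curve = dv_norm_curve(rec)
        assert len(grid) == 151 and len(curve) == 151
        assert np.all(np.abs(curve - 1.0) < 0.01)

    def test_ramp_on_both_channels_is_removed(self):
        ramp = lambda x: 1.0 + 1.0 * x  # 2x brighter ventrally
        rec = self._frames(lambda x: 3000.0 * ramp(x), n=400)
        grid, curve = dv_norm_curve(rec)
        dv = np.linspace(-1, 1, 300)
        signal = gaussian_gradient(dv, 10.0, 2.0, 0.0, 0.15) * ramp(np.abs(dv))
        corrected = signal / gradient.apply_dv_curve(dv, grid, curve)
        fit = fit_gaussian(dv, corrected)
        # the multiplicative ramp distorts the profile; after curve_norm the
        # generating parameters come back (up to the curve's unit-mean scale)
        assert fit.sigma == pytest.approx(0.15, rel=0.03)
        assert fit.mu == pytest.approx(0.0, abs=0.02)
        assert fit.A / fit.B == pytest.approx(5.0, rel=0.03)

    def test_single_frame_equals_its_own_curve(self):
        rec = self._frames(lambda x: 3000.0 * (1 + 0.3 * x), n_frames=1)
        _, curve1 = dv_norm_curve(rec)
        _, curve2 = dv_norm_curve(pd.concat([rec, rec.assign(frame=1)]))
        assert np.allclose(curve1, curve2)

    def test_small_frames_excluded(self):
        rec = self._frames(lambda x: np.full_like(x, 1.0), n=10)
        with pytest.raises(ValueError):
            dv_norm_curve(rec)


class TestSmoothParams:
    def _fits(self, values):
        return pd.DataFrame(
            {"frame": np.arange(len(values)), "A": values, "B": values,
             "sigma": values}
        )

    def test_constant_sequence_unchanged(self):
        out = smooth_params(self._fits(np.full(20, 3.0)))
        assert np.allclose(out.A, 3.0)

    def test_outlier_attenuated_tenfold(self):
        vals = np.zeros(20)
        vals[10] = 5.0
        out = smooth_params(self._fits(vals), window=10)
        assert out.A[10] == pytest.approx(5.0 / 10.0)

    def test_linear_trend_unchanged_in_interior(self):
        vals = np.arange(20, dtype=float)
        out = smooth_params(self._fits(vals), window=10)
        # centered even window averages t-5..t+4 -> constant -0.5 shift
        assert np.allclose(np.diff(out.A[6:14]), 1.0)


def _analytic_embryo(A, B, sigma, n_frames=10, n_nuclei=400, noise=0.0, seed=0,
                     name=""):
    rng = np.random.default_rng(seed)
    rows = []
    fits = []
    for f in range(n_frames):
        dv = np.linspace(-1, 1, n_nuclei)
        y = gaussian_gradient(dv, A, B, 0.0, sigma)
        if noise:
            y = y + rng.normal(0, noise, n_nuclei)
        rows.append(pd.DataFrame({"frame": f, "dv": dv, "intensity": y}))
        fits.append({"frame": f, "A": A, "B": B, "mu": 0.0, "sigma": sigma})
    return EmbryoGradientData(
        nuclei=pd.concat(rows, ignore_index=True), fits=pd.DataFrame(fits), name=name
    )


class TestAverageEmbryos:
    def test_mesh_spacing(self):
        mesh, edges = mesh_edges()
        assert len(mesh) == 36
        assert mesh[1] - mesh[0] == pytest.approx(1.0 / 35.0)
        assert round(mesh[1] - mesh[0], 4) == 0.0286
        assert edges[0] == 0.0 and edges[-1] == 1.0

    def test_single_embryo_self_average(self):
        e = _analytic_embryo(10.0, 2.0, 0.15)
        avg = average_embryos([e])
        assert np.allclose(avg.chi.chi, 1.0)
        expected = gaussian_gradient(avg.mesh, 10.0, 2.0, 0.0, 0.15)
        assert np.allclose(avg.mean[0], expected, rtol=0.02)

    def test_two_widths_average_to_intermediate_gaussian(self):
        e1 = _analytic_embryo(10.0, 2.0, 0.10, name="narrow")
        e2 = _analytic_embryo(10.0, 2.0, 0.20, name="wide")
        avg = average_embryos([e1, e2])
        expected = gaussian_gradient(avg.mesh, 10.0, 2.0, 0.0, 0.15)
        assert np.all(np.abs(avg.mean - expected[None, :]) / expected[None, :] < 0.02)
        chi = avg.chi.set_index("embryo").chi
        assert np.allclose(chi.loc["narrow"], 1.5)
        assert np.allclose(chi.loc["wide"], 0.75)

    def test_symmetric_embryo_fold_consistency(self):
        # a perfectly left/right symmetric embryo averages to either half
        x_half = np.linspace(0.001, 1, 300)
        dv = np.concatenate([x_half, -x_half])
        y = gaussian_gradient(np.abs(dv), 10.0, 2.0, 0.0, 0.15)
        nuclei = pd.DataFrame({"frame": 0, "dv": dv, "intensity": y})
        fits = pd.DataFrame(
            [{"frame": 0, "A": 10.0, "B": 2.0, "mu": 0.0, "sigma": 0.15}]
        )
        both = average_embryos([EmbryoGradientData(nuclei, fits)])
        half = average_embryos(
            [EmbryoGradientData(nuclei[nuclei.dv > 0], fits)]
        )
        assert np.allclose(both.mean, half.mean, atol=1e-9)

    def test_no_common_frames_raises(self):
        e1 = _analytic_embryo(10, 2, 0.15, n_frames=3)
        e2 = _analytic_embryo(10, 2, 0.15, n_frames=3)
        e2.nuclei["frame"] += 10
        e2.fits["frame"] += 10
        with pytest.raises(AlignmentError):
            average_embryos([e1, e2])
        with pytest.raises(AlignmentError):
            average_embryos([])

    def test_averaging_reduces_sem(self):
        singles = [
            _analytic_embryo(10, 2, 0.15, n_frames=1, noise=0.5, seed=k, name=str(k))
            for k in range(5)
        ]
        avg5 = average_embryos(singles)
        avg1 = average_embryos(singles[:1])
        better = (avg5.sem[0] < avg1.sem[0]) | avg1.interpolated[0]
        assert better.sum() >= 30

    def test_empty_bins_interpolated_and_flagged(self):
        # nuclei only on [0, 0.5]: ventral bins are empty -> interpolated
        dv = np.linspace(0, 0.5, 200)
        nuclei = pd.DataFrame(
            {"frame": 0, "dv": dv,
             "intensity": gaussian_gradient(dv, 10, 2, 0, 0.15)}
        )
        fits = pd.DataFrame([{"frame": 0, "A": 10.0, "B": 2.0, "mu": 0, "sigma": 0.15}])
        avg = average_embryos([EmbryoGradientData(nuclei, fits)])
        assert avg.interpolated[0, -1]
        assert np.isfinite(avg.mean).all()


class TestControlBackground:
    def test_constant_background(self):
        curves = [np.full(40, 7.0), np.full(40, 7.0)]
        filtered, beta, normalized = control_background(curves, 18)
        assert np.allclose(filtered[0], 7.0)
        assert beta == pytest.approx(7.0)
        assert np.allclose(normalized[0], 1.0)

    def test_nine_minute_sine_attenuated(self):
        t = np.arange(80)
        c, a, period = 10.0, 2.0, 18  # 9 min at 30 s/frame
        curve = c + a * np.sin(2 * np.pi * t / period)
        filtered, _, _ = control_background([curve], period)
        interior = filtered[0][period // 2 : -period // 2]
        # boxcar of one period nulls the oscillation (<5% of c residual)
        assert np.all(np.abs(interior - c) / c < 0.05)
        assert np.max(np.abs(interior - c)) < 0.10 * a

    def test_per_set_beta_normalization_equalizes_microscopes(self):
        set1 = [np.full(30, 5.0)]
        set2 = [np.full(30, 15.0)]  # 3x brighter microscope
        _, b1, n1 = control_background(set1, None)
        _, b2, n2 = control_background(set2, None)
        assert b2 == pytest.approx(3 * b1)
        assert np.allclose(n1[0], n2[0])

    def test_low_pass_window_one_is_identity(self):
        x = np.arange(10.0)
        assert np.allclose(low_pass(x, 1), x)


class TestCorrelateChannels:
    def _embryo(self, rho_perfect=True, n=60, seed=0):
        rng = np.random.default_rng(seed)
        dv = np.linspace(-1, 1, n)
        base = gaussian_gradient(dv, 6, 1, 0, 0.2)
        ch1 = 50.0 * base
        ch2 = ch1.copy() if rho_perfect else (2 * ch1.mean() - ch1)
        return pd.DataFrame(
            {"dv": dv, "mean_nuclear": np.full(n, 50.0),
             "mean_signal": ch1, "mean_signal2": ch2}
        )

    def test_identical_channels_give_unit_correlation(self):
        rhos, mean, sd = correlate_channels([self._embryo() for _ in range(3)])
        assert np.allclose(rhos, 1.0)
        assert mean == pytest.approx(1.0)

    def test_negated_channel_gives_minus_one(self):
        rhos, _, _ = correlate_channels([self._embryo(rho_perfect=False)])
        assert rhos[0] == pytest.approx(-1.0)

    def test_too_few_nuclei_excluded(self):
        rhos, mean, _ = correlate_channels([self._embryo(n=10)])
        assert rhos == [] and np.isnan(mean)


class TestTimeCourseAtDv:
    def _nuclei(self, n_frames=6):
        rows = []
        for f in range(n_frames):
            dv = np.linspace(-1, 1, 101)
            A, B, sigma = 2.0 + f, 2.0, 0.3 - 0.02 * f
            rows.append(pd.DataFrame(
                {"frame": f, "dv": dv,
                 "intensity": gaussian_gradient(dv, A, B, 0, sigma)}))
        return pd.concat(rows, ignore_index=True)

    def test_peak_follows_refining_amplitude(self):
        tc = time_course_at_dv(self._nuclei(), x0=0.0, band=0.05)
        assert tc["mean"].is_monotonic_increasing
        assert np.allclose(tc["mean"], 2.0 + tc.frame + 2.0, rtol=0.02)

    def test_far_tail_stays_at_basal(self):
        nuclei = self._nuclei()
        nuclei["intensity"] = gaussian_gradient(nuclei.dv, 10.0, 2.0, 0.0, 0.15)
        tc = time_course_at_dv(nuclei, x0=0.7, band=0.05)
        assert np.allclose(tc["mean"], 2.0, rtol=0.01)

    def test_zero_band_returns_single_nucleus_trace(self):
        nuclei = self._nuclei()
        tc = time_course_at_dv(nuclei, x0=1.0, band=0.0)
        assert (tc.n == 2).all()  # dv = +1 and -1 fold onto x0 = 1

    def test_missing_frames_are_nan_not_zero(self):
        nuclei = self._nuclei()
        nuclei = nuclei[(nuclei.frame != 2) | (np.abs(nuclei.dv) > 0.5)]
        tc = time_course_at_dv(nuclei, x0=0.0, band=0.05)
        assert np.isnan(tc.loc[tc.frame == 2, "mean"]).all()
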