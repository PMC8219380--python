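"""SPR affinity fitting: free/constrained Langmuir, standard curve, CV."""

import numpy as np
import pytest

from tcrpower import spr
from tcrpower.spr import (BindingCurve, FitError, StandardCurve,
                          build_standard_curve, double_reference,
                          fit_langmuir_constrained, fit_langmuir_free,
                          fit_w632_rmax, replicate_cv, select_reported_kd)

T_SERIES = np.array([1.25, 2.5, 5.0, 10.0, 20.0, 40.0, 80.0])


def langmuir(T, kd, bmax):
    return bmax * T / (kd + T)


def grid_sse(curve, kds, bmaxes):
    """Brute-force SSE surface oracle over a (KD, Bmax) grid."""
    out = np.empty((len(kds), len(bmaxes)))
    for i, kd in enumerate(kds):
        for j, bm in enumerate(bmaxes):
            out[i, j] = np.sum((curve.B - langmuir(curve.T, kd, bm)) ** 2)
    return out


class TestDoubleReference:
    def test_signal_equal_reference_zeroes_out(self):
        s = np.array([5.0, 6.0, 7.0])
        assert np.allclose(double_reference(s, s, np.zeros(3), np.zeros(3)), 0)

    def test_constant_buffer_drift_is_subtracted(self, rng):
        sig = rng.uniform(0, 100, 10)
        ref = rng.uniform(0, 10, 10)
        drift = np.full(10, 3.5)
        out = double_reference(sig, ref, drift, drift)
        assert np.allclose(out, sig - ref - 3.5)

    def test_removes_simulated_drift_to_noise_floor(self):
        rng = np.random.RandomState(3)
        n, sigma = 200, 1.0
        true = np.zeros(n)
        drift = 12.0
        sig = true + drift + rng.normal(0, sigma, n)
        ref = rng.normal(0, sigma, n) * 0  # reference channel idealised
        buf = np.full(n, drift) + rng.normal(0, sigma, n)
        out = double_reference(sig, ref, buf, buf)
        assert abs(out.mean()) < sigma / np.sqrt(n) * 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            double_reference([1, 2], [1, 2, 3], [0, 0], [0, 0])


class TestFreeFit:
    def test_noiseless_exact_recovery(self):
        curve = BindingCurve("x", T_SERIES, langmuir(T_SERIES, 10.0, 100.0))
        fit = fit_langmuir_free(curve)
        assert fit.kd == pytest.approx(10.0, rel=1e-6)
        assert fit.bmax == pytest.approx(100.0, rel=1e-6)
        assert fit.saturation_ratio == pytest.approx(8.0, rel=1e-6)

    def test_flat_curve_rejected(self):
        with pytest.raises(FitError):
            fit_langmuir_free(BindingCurve("x", T_SERIES, np.full(7, 42.0)))

    def test_nonsaturating_sse_ridge_is_flat(self):
        """With max(T) = KD/5 the SSE barely changes along Bmax/KD ~ const
        over a 10-fold KD span: the free fit is ridge-unidentifiable."""
        kd_true, bmax_true = 400.0, 1000.0
        curve = BindingCurve("x", T_SERIES,
                             langmuir(T_SERIES, kd_true, bmax_true))
        kds = np.geomspace(kd_true, 10 * kd_true, 25)
        # profile SSE: best Bmax for each KD (closed-form linear LS)
        profile = []
        for kd in kds:
            f = curve.T / (kd + curve.T)
            bmax_star = float(curve.B @ f / (f @ f))
            profile.append(float(np.sum((curve.B - bmax_star * f) ** 2)))
        scale = np.sum(curve.B ** 2)
        assert max(profile) / scale < 0.01

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            BindingCurve("x", [1, 2, 3], [1, 2, 3])  # < 4 points
        with pytest.raises(ValueError):
            BindingCurve("x", [3, 2, 4, 5], [1, 2, 3, 4])  # not increasing


class TestW632:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(5, 600, 20)
        fit = fit_w632_rmax("x", t, 50.0 * t / (20.0 + t))
        assert fit.rmax == pytest.approx(50.0, rel=1e-6)
        assert fit.kt == pytest.approx(20.0, rel=1e-6)

    def test_constant_trace_limit(self):
        t = np.linspace(5, 600, 20)
        fit = fit_w632_rmax("x", t, np.full(20, 7.0))
        assert fit.rmax == pytest.approx(7.0, rel=1e-3)
        assert fit.kt == pytest.approx(0.0, abs=1e-2)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.RandomState(11)
        t = np.linspace(5, 600, 30)
        r = 50.0 * t / (20.0 + t) + rng.normal(0, 1.0, 30)
        fit = fit_w632_rmax("x", t, r)
        assert fit.rmax == pytest.approx(50.0, rel=0.05)


class TestStandardCurve:
    def _fit(self, kd, bmax, sat):
        return spr.LangmuirFit("x", kd, bmax, "free", 0.0, sat)

    def test_exact_line(self):
        pairs = [(r, self._fit(5.0, 2.0 * r, 10.0)) for r in (10, 20, 30, 40, 50)]
        std = build_standard_curve(pairs)
        assert std.slope == pytest.approx(2.0)
        assert std.intercept == pytest.approx(0.0, abs=1e-9)
        assert std.n_points == 5

    def test_saturation_filter(self):
        pairs = [(r, self._fit(5.0, 2.0 * r, 10.0)) for r in (10, 20, 30)]
        pairs += [(r, self._fit(5.0, 2.0 * r, 1.0)) for r in (40, 50)]
        assert build_standard_curve(pairs).n_points == 3

    def test_too_few_retained(self):
        pairs = [(r, self._fit(5.0, 2.0 * r, 1.0)) for r in (10, 20, 30, 40)]
        with pytest.raises(FitError):
            build_standard_curve(pairs)

    def test_requires_free_fits(self):
        pairs = [(10.0, spr.LangmuirFit("x", 5, 20, "constrained", 0, 10))] * 3
        with pytest.raises(ValueError):
            build_standard_curve(pairs)


class TestConstrainedFit:
    STD = StandardCurve(slope=2.0, intercept=0.0, n_points=5,
                        rmax_min=10.0, rmax_max=1000.0)

    def test_consistent_with_free_fit_when_saturating(self):
        curve = BindingCurve("x", T_SERIES, langmuir(T_SERIES, 10.0, 100.0))
        free = fit_langmuir_free(curve)
        con = fit_langmuir_constrained(curve, self.STD, rmax=50.0)
        assert con.bmax == pytest.approx(100.0)
        assert con.kd == pytest.approx(free.kd, rel=1e-6)

    def test_recovers_nonsaturating_kd_with_exact_bmax(self):
        """max(T) = KD/10: the free fit is on a ridge, but the constrained
        fit with the true Bmax recovers KD to 1e-6 (grid oracle confirms a
        unique 1-D minimum)."""
        kd_true, bmax_true = 800.0, 1000.0
        curve = BindingCurve("x", T_SERIES,
                             langmuir(T_SERIES, kd_true, bmax_true))
        con = fit_langmuir_constrained(curve, self.STD, rmax=500.0)
        assert con.kd == pytest.approx(kd_true, rel=1e-6)
        kds = np.geomspace(80, 8000, 41)
        sse_1d = grid_sse(curve, kds, [bmax_true])[:, 0]
        assert kds[np.argmin(sse_1d)] == pytest.approx(kd_true, rel=0.15)

    def test_extrapolation_refused(self):
        curve = BindingCurve("x", T_SERIES, langmuir(T_SERIES, 10.0, 100.0))
        with pytest.raises(ValueError, match="outside standard curve"):
            fit_langmuir_constrained(curve, self.STD, rmax=1100.0)

    def test_scale_invariance_of_constrained_kd(self):
        curve = BindingCurve("x", T_SERIES, langmuir(T_SERIES, 300.0, 1000.0))
        con1 = fit_langmuir_constrained(curve, self.STD, rmax=500.0)
        curve2 = BindingCurve("x", T_SERIES, curve.B * 0.37)
        std2 = StandardCurve(2.0 * 0.37, 0.0, 5, 10.0, 1000.0)
        con2 = fit_langmuir_constrained(curve2, std2, rmax=500.0)
        assert con1.kd == pytest.approx(con2.kd, rel=1e-9)


class TestReportingRule:
    def _fit(self, kd, method):
        return spr.LangmuirFit("x", kd, 100.0, method, 0.0, 1.0)

    @pytest.mark.parametrize("kd_con, kd_free, expected_kd, expected_method", [
        (50.0, 30.0, 50.0, "constrained"),
        (5.0, 7.0, 7.0, "free"),
        (20.0, 7.0, 7.0, "free"),  # boundary reads "above" strictly
    ])
    def test_switch(self, kd_con, kd_free, expected_kd, expected_method):
        kd, method = select_reported_kd(self._fit(kd_free, "free"),
                                        self._fit(kd_con, "constrained"))
        assert (kd, method) == (expected_kd, expected_method)


class TestReplicateCV:
    def test_identical_replicates(self):
        assert replicate_cv([10.0, 10.0, 10.0]) == 0.0

    def test_two_replicates_value(self):
        # mean 15, sample SD sqrt(50) -> CV = 0.4714...
        assert replicate_cv([10.0, 20.0]) == pytest.approx(0.4714, abs=1e-4)

    def test_errors(self):
        with pytest.raises(ValueError):
            replicate_cv([10.0])
        with pytest.raises(ValueError):
            replicate_cv([-10.0, 10.0])
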