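"""Window-of-linearity fitting, duplicate QC, construct calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsinchoice import synthetic
from opsinchoice.qpcr import (GENES, AmplificationCurve, AmplificationFit,
                              StandardCurve, WindowConfig, fit_amplification,
                              fit_standard_curve, qc_duplicates, quantify,
                              relative_expression)

NO_BASELINE = WindowConfig(baseline_cycles=None, threshold=1e4)


def exponential_curve(n0=10.0, e=2.0, n_cycles=30, gene="LWS", rep=1):
    c = np.arange(1, n_cycles + 1, dtype=float)
    return AmplificationCurve("P1", "W1", "S1", gene, rep, c, n0 * e ** c)


class TestFitAmplification:
    def test_exact_exponential(self):
        """F(c) = 10 * 2^c inverts exactly: E = 2, N0 = 10, Ct = log2(1e3)."""
        fit = fit_amplification(exponential_curve(), NO_BASELINE)
        assert fit.efficiency_E == pytest.approx(2.0, abs=1e-9)
        assert fit.N0 == pytest.approx(10.0, rel=1e-9)
        assert fit.Ct == pytest.approx(math.log2(1e3), abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_deterministic(self):
        a = fit_amplification(exponential_curve(), NO_BASELINE)
        b = fit_amplification(exponential_curve(), NO_BASELINE)
        assert (a.window, a.efficiency_E, a.N0, a.Ct) == \
               (b.window, b.efficiency_E, b.N0, b.Ct)

    def test_flat_curve_fails(self):
        c = np.arange(1, 31, dtype=float)
        curve = AmplificationCurve("P", "W", "S", "LWS", 1, c,
                                   np.full(30, 100.0))
        fit = fit_amplification(curve, WindowConfig())
        assert not fit.ok and "no_amplification" in fit.qc_flags

    def test_decreasing_curve_fails(self):
        c = np.arange(1, 31, dtype=float)
        curve = AmplificationCurve("P", "W", "S", "LWS", 1, c,
                                   1e4 * 0.8 ** c)
        fit = fit_amplification(curve, WindowConfig(baseline_cycles=None))
        assert not fit.ok

    def test_noisy_efficiency_recovery(self):
        """Mean estimated E over replicate noisy curves stays within
        +/-0.05 of the generating E = 1.90 (2% multiplicative noise,
        logistic plateau)."""
        q = synthetic.QpcrTruth()
        cfg = WindowConfig()
        cycles = np.arange(1, q.n_cycles + 1, dtype=float)
        est = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            f = synthetic._signal(0.005, 1.90, cycles, q, rng)
            curve = AmplificationCurve("P", "W", "S", "LWS", 1, cycles, f)
            fit = fit_amplification(curve, cfg)
            assert fit.ok
            est.append(fit.efficiency_E)
        assert abs(np.mean(est) - 1.90) < 0.05

    def test_curve_invariants(self):
        with pytest.raises(ValueError):
            AmplificationCurve("P", "W", "S", "LWS", 1,
                               np.array([1, 2, 2, 3]), np.ones(4))
        with pytest.raises(ValueError):
            AmplificationCurve("P", "W", "S", "LWS", 1,
                               np.arange(1, 11), np.ones(10))  # < 15 cycles


class TestDuplicateQC:
    def _fit(self, ct, eff_pct):
        e = 1.0 + eff_pct / 100.0
        fit = AmplificationFit(None, (10, 15), math.log10(e), 1.0, e, 10.0,
                               ct, 0.999, 0.0)
        return fit

    @pytest.mark.parametrize("cts,effs,expect_pass,reason", [
        ((20.0, 20.0), (100, 100), True, None),
        ((20.0, 21.0), (100, 100), False, "ct_sd"),       # sd ~ 0.707
        ((20.0, 20.0), (70, 100), False, "efficiency_range"),
        # boundary cases: the printed thresholds pass exactly
        ((20.0, 20.0), (75.0, 125.0), True, None),
        ((20.0, 20.0 + 0.5 * math.sqrt(2)), (100, 100), True, None),  # sd = 0.5
        ((20.0, 20.0), (74.9, 100), False, "efficiency_range"),
        ((20.0, 20.0), (125.1, 100), False, "efficiency_range"),
        ((20.0, 20.0 + 0.51 * math.sqrt(2)), (100, 100), False, "ct_sd"),
    ])
    def test_qc_rule(self, cts, effs, expect_pass, reason):
        qc = qc_duplicates(self._fit(cts[0], effs[0]),
                           self._fit(cts[1], effs[1]))
        assert qc.passed is expect_pass
        if reason:
            assert reason in qc.reasons
        assert qc.mean_Ct == pytest.approx(np.mean(cts))

    def test_failed_fit_fails_qc(self):
        bad = AmplificationFit(None, None, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, 0.0, {"no_amplification"})
        qc = qc_duplicates(self._fit(20, 100), bad)
        assert not qc.passed and qc.reasons == ["fit_failure"]


class TestStandardCurve:
    @pytest.mark.parametrize("e", [1.8, 1.9, 2.0])
    def test_closed_form_slope(self, e):
        """A perfect dilution series has slope m = -1/log10(E)."""
        logc = np.array([0.0, -1.0, -2.0, -3.0, -4.0])
        # Ct at threshold T: N0 * E^Ct = T  =>  Ct = (log10 T - log10 N0)/log10 E
        ct = (4.0 - logc) / math.log10(e)
        curve = fit_standard_curve(list(zip(logc, ct)), gene="LWS")
        assert curve.slope_m == pytest.approx(-1.0 / math.log10(e), abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_refused(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0.0, 20.0), (-1.0, 23.3)])

    def test_inverted_series_flagged(self):
        pts = [(0.0, 20.0), (-1.0, 18.0), (-2.0, 16.0)]
        assert "inverted_series" in fit_standard_curve(pts).flags


def _uniform_curves(m=-1.0 / math.log10(2.0), b=40.0):
    return {g: StandardCurve(g, m, b, 1.0, 5) for g in GENES}


class TestRelativeExpression:
    def test_symmetry(self):
        prof = relative_expression({g: 20.0 for g in GENES},
                                  _uniform_curves())
        for g in GENES:
            assert prof.proportions[g] == pytest.approx(0.25, abs=1e-12)

    def test_one_gene_shifted_by_slope(self):
        """Lowering one Ct by |m| log-units multiplies its N0 by 10."""
        m = -1.0 / math.log10(2.0)
        cts = {g: 20.0 for g in GENES}
        cts["LWS"] = 20.0 + m  # lower Ct by |m|
        prof = relative_expression(cts, _uniform_curves(m))
        assert prof.proportions["LWS"] == pytest.approx(10.0 / 13.0, abs=1e-9)
        for g in ("SWS2b", "SWS2a", "RH2A"):
            assert prof.proportions[g] == pytest.approx(1.0 / 13.0, abs=1e-9)

    def test_missing_gene_incomplete(self):
        cts = {g: 20.0 for g in GENES if g != "RH2A"}
        prof = relative_expression(cts, _uniform_curves())
        assert not prof.complete and "RH2A" in prof.missing

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(10.0, 35.0), min_size=4, max_size=4),
           st.floats(1.5, 2.2), st.floats(30.0, 45.0))
    def test_normalization_property(self, cts, e, b):
        """Proportions sum to one for arbitrary valid Cts and curves."""
        m = -1.0 / math.log10(e)
        prof = relative_expression(dict(zip(GENES, cts)),
                                   _uniform_curves(m, b))
        assert sum(prof.proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= p <= 1.0 for p in prof.proportions.values())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 3.0))
    def test_monotonicity(self, delta):
        """Lowering one gene's Ct raises its share, lowers all others."""
        base = {"SWS2b": 28.0, "SWS2a": 22.0, "RH2A": 20.0, "LWS": 21.0}
        lowered = dict(base, LWS=base["LWS"] - delta)
        curves = _uniform_curves()
        p0 = relative_expression(base, curves).proportions
        p1 = relative_expression(lowered, curves).proportions
        assert p1["LWS"] > p0["LWS"]
        for g in ("SWS2b", "SWS2a", "RH2A"):
            assert p1[g] < p0[g]


class TestQuantifyRoundTrip:
    def test_noise_free_recovery(self, plan):
        """The ideal generator mode inverts to the planted proportions."""
        ideal = plan.ideal()
        cohort = synthetic.make_cohort(ideal).head(8)
        curves, truth = synthetic.gen_qpcr(ideal, cohort)
        profiles, _, _ = quantify(
            curves, cohort.rename(columns={"female_id": "sample"}))
        assert profiles["complete"].all()
        merged = profiles.merge(truth, on="sample")
        for g in GENES:
            err = (merged[f"prop_{g}"] - merged[f"true_prop_{g}"]).abs()
            assert err.max() < 1e-6
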