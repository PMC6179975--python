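"""Landmark extraction from generated instrument traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ricotype as rt
from ricotype.curves import (CurveConfig, NoCompressionPeaksError,
                             NoGelPointError, RheoCurve, TPACurve)

NOISELESS = CurveConfig(smoothing_window=1)


class TestRheometry:
    def test_planted_landmarks_recovered(self, noiseless_config):
        """Noiseless planted gel point, extrema and slopes are recovered
        within one sampling interval (time landmarks) and its value change."""
        spec = rt.RheoCurveSpec(gel_temp=75.0, Gmax=40.0, temp_at_Gmax=90.0,
                                Gtrough=15.0, dt_min=0.05)
        curve, truth = rt.gen_rheometry_curve(spec, 0)
        f = rt.extract_rheometry_features(curve, noiseless_config)
        dtemp = spec.ramp_rate * spec.dt_min  # temperature step per sample
        assert abs(f.gel_temp - 75.0) <= dtemp
        assert abs(f.temp_at_Gmax - 90.0) <= dtemp
        assert f.Gmax == pytest.approx(40.0, abs=0.05)
        assert f.Gtrough == pytest.approx(15.0, abs=0.05)
        assert f.S1 == pytest.approx(truth["S1"], rel=0.02)
        assert f.S2 == pytest.approx(truth["S2"], rel=0.02)
        assert f.S3 == pytest.approx(truth["S3"], rel=0.02)
        assert f.S4 is not None and f.S4 < 0

    def test_tand_identity_and_ratio_arithmetic(self, noiseless_config):
        """tan(delta) at G'max times G'max equals G'' at G'max exactly; the
        study-scale example 40.64 kPa x 0.11 gives ~4.47 kPa."""
        curve, _ = rt.gen_rheometry_curve(rt.RheoCurveSpec(), 0)
        f = rt.extract_rheometry_features(curve, noiseless_config)
        assert f.tand_at_Gmax * f.Gmax == pytest.approx(f.Gpp_at_Gmax, abs=1e-12)
        assert 40.64 * 0.11 == pytest.approx(4.47, abs=0.005)

    def test_identical_moduli_have_no_gel_point(self, noiseless_config):
        """G' == G'' keeps tan(delta) pinned at 1: no crossing exists."""
        t = np.linspace(0.0, 30.0, 200)
        temp = np.where(t <= 15, 35 + 4 * t, 95 - 4 * (t - 15))
        g = 1.0 + np.linspace(0, 10, 200)
        curve = RheoCurve(t, temp, g, g.copy())
        with pytest.raises(NoGelPointError):
            rt.extract_rheometry_features(curve, noiseless_config)

    def test_resampling_invariance(self, noiseless_config):
        """Doubling the sampling density moves landmarks by less than one
        original sampling interval."""
        spec = rt.RheoCurveSpec(dt_min=0.1)
        dense = rt.RheoCurveSpec(dt_min=0.05)
        f1 = rt.extract_rheometry_features(rt.gen_rheometry_curve(spec, 0)[0], noiseless_config)
        f2 = rt.extract_rheometry_features(rt.gen_rheometry_curve(dense, 0)[0], noiseless_config)
        assert abs(f1.gel_time - f2.gel_time) < 0.1
        assert abs(f1.Gmax - f2.Gmax) < 0.05

    def test_noisy_recovery_with_smoothing(self):
        """Under noise, the default smoothing window keeps gel temperature
        within a degree of the planted value."""
        spec = rt.RheoCurveSpec(noise_sd=0.1, dt_min=0.02)
        curve, _ = rt.gen_rheometry_curve(spec, 3)
        f = rt.extract_rheometry_features(curve, CurveConfig(smoothing_window=9))
        assert abs(f.gel_temp - spec.gel_temp) < 1.0
        assert f.Gmax == pytest.approx(spec.Gmax, rel=0.05)


class TestPasting:
    def test_planted_landmarks_and_identities(self, noiseless_config):
        """Planted PV/TV/FV reproduce the study cluster-3-scale BD/SB/LO."""
        spec = rt.RVACurveSpec(PV=2.49, TV=1.39, FV=2.64, PT=5.89)
        curve, _ = rt.gen_pasting_curve(spec, 0)
        f = rt.extract_pasting_features(curve, noiseless_config)
        assert f.PV == pytest.approx(2.49, abs=0.01)
        assert f.PT == pytest.approx(5.89, abs=spec.dt_min)
        assert f.BD == pytest.approx(1.10, abs=0.01)
        assert f.SB == pytest.approx(0.15, abs=0.01)
        assert f.LO == pytest.approx(1.25, abs=0.01)
        assert f.PTemp is not None

    @given(pv=st.floats(1.0, 6.0), drop=st.floats(0.0, 0.9),
           rise=st.floats(0.0, 2.0))
    @settings(max_examples=25, deadline=None)
    def test_identities_hold_exactly(self, pv, drop, rise):
        """BD = PV - TV, SB = FV - PV, LO = FV - TV = BD + SB for any curve."""
        tv = pv * (1 - drop)
        spec = rt.RVACurveSpec(PV=pv, TV=tv, FV=tv + rise, dt_min=0.05)
        curve, _ = rt.gen_pasting_curve(spec, 0)
        f = rt.extract_pasting_features(curve, NOISELESS)
        assert f.BD == pytest.approx(f.PV - f.TV, abs=1e-12)
        assert f.SB == pytest.approx(f.FV - f.PV, abs=1e-12)
        assert f.LO == pytest.approx(f.BD + f.SB, abs=1e-12)
        assert f.TV <= f.PV + 1e-12

    def test_flat_curve(self, noiseless_config):
        """Constant viscosity: all landmarks equal, differences zero, no
        pasting temperature."""
        t = np.arange(0, 12.5, 0.05)
        from ricotype.synth import _rva_temperature
        curve = rt.synth.RVACurve(t, _rva_temperature(t, 12.5), np.ones_like(t))
        f = rt.extract_pasting_features(curve, noiseless_config)
        assert f.PV == f.TV == f.FV == 1.0
        assert f.BD == f.SB == f.LO == 0.0
        assert f.PTemp is None

    def test_table3_identity_arithmetic(self):
        """The study's cluster-3 means obey LO = BD + SB within rounding."""
        assert abs((1.10 + 0.15) - 1.24) <= 0.011


class TestTPA:
    def test_planted_areas_and_peaks(self, noiseless_config):
        """Study-scale lobes: areas 2.00/0.88 and peak 1.96 kg give
        HRD 1.96, COH 0.44, ADH 0.02."""
        spec = rt.TPACurveSpec(area1=2.00, area2=0.88, peak1=1.96, neg_area=0.02)
        curve, _ = rt.gen_tpa_curve(spec, 0)
        f = rt.extract_tpa_features(curve, noiseless_config)
        assert f.HRD == pytest.approx(1.96, abs=0.01)
        assert f.COH == pytest.approx(0.44, abs=0.005)
        assert f.ADH == pytest.approx(0.02, abs=0.002)
        assert f.SPR == pytest.approx(spec.T2 / spec.T1, abs=0.02)

    def test_identical_lobes(self, noiseless_config):
        """Two identical triangles, no pull-off: COH = 1, ADH = 0."""
        t = np.arange(0, 10, 0.005)
        f = np.zeros_like(t)
        for t0 in (1.0, 6.0):
            up = (t >= t0) & (t <= t0 + 1)
            down = (t > t0 + 1) & (t <= t0 + 2)
            f[up] = 2.0 * (t[up] - t0)
            f[down] = 2.0 * (t0 + 2 - t[down])
        feats = rt.extract_tpa_features(TPACurve(t, f), noiseless_config)
        assert feats.COH == pytest.approx(1.0, abs=1e-6)
        assert feats.ADH == 0.0
        assert feats.HRD == pytest.approx(2.0, abs=0.02)
        assert feats.SPR == pytest.approx(1.0, abs=1e-6)

    def test_zero_trace_rejected(self, noiseless_config):
        with pytest.raises(NoCompressionPeaksError):
            rt.extract_tpa_features(
                TPACurve(np.arange(0, 5, 0.01), np.zeros(500)), noiseless_config)


def test_generator_determinism():
    """Same spec and seed yield bit-identical curves."""
    a, _ = rt.gen_rheometry_curve(rt.RheoCurveSpec(noise_sd=0.2), 5)
    b, _ = rt.gen_rheometry_curve(rt.RheoCurveSpec(noise_sd=0.2), 5)
    assert np.array_equal(a.g_prime_kPa, b.g_prime_kPa)
    assert np.array_equal(a.g_double_prime_kPa, b.g_double_prime_kPa)


def test_inconsistent_spec_rejected():
    """Planted trough equal to the peak is not a valid curve."""
    with pytest.raises(rt.synth.SpecError):
        rt.RheoCurveSpec(Gmax=20.0, Gtrough=20.0)
    with pytest.raises(rt.synth.SpecError):
        rt.RVACurveSpec(PV=1.0, TV=1.5)
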