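"""Equilibrium and transition-state thermodynamics, signatures, Tm."""

import numpy as np
import pytest

from fabthermo import (
    ActivationParams,
    R,
    T_REF,
    ThermoParams,
    classify_signature,
    eyring_fit,
    eyring_kon,
    fold_change,
    gibbs_from_kd,
    kd_from_gibbs,
    predict_gibbs,
    tm_from_thermogram,
    vant_hoff_fit,
)
from fabthermo.synthetic import generate_dsc_thermogram
from conftest import TEMPS


class TestGibbsFromKd:
    def test_molar_kd_gives_zero(self):
        assert gibbs_from_kd(1.0, 298.15) == 0.0

    @pytest.mark.parametrize(
        "kd,temp,expected_kj",
        [
            # direct evaluation of R*T*ln(Kd) at panel affinities
            (2.22e-10, 298.15, -55.1),
            (2.03e-12, 293.15, -65.6),
        ],
    )
    def test_panel_affinity_energies(self, kd, temp, expected_kj):
        assert gibbs_from_kd(kd, temp) / 1e3 == pytest.approx(expected_kj, abs=0.05)

    def test_monotone_increasing_in_kd(self):
        kds = np.logspace(-12, -6, 30)
        dg = gibbs_from_kd(kds, 298.15)
        assert np.all(np.diff(dg) > 0)

    def test_non_positive_kd_rejected(self):
        with pytest.raises(ValueError):
            gibbs_from_kd(0.0, 298.15)

    def test_kd_round_trip(self):
        assert kd_from_gibbs(gibbs_from_kd(3.3e-9, 290.0), 290.0) == pytest.approx(3.3e-9, rel=1e-12)


class TestPredictGibbs:
    def test_reduces_to_dh_minus_tds_at_reference(self):
        p = ThermoParams(dH=-30e3, dS=80.0, dCp=-1.5e3)
        assert predict_gibbs(p, T_REF) == pytest.approx(p.dH - T_REF * p.dS, rel=1e-12)

    def test_linear_in_t_without_heat_capacity(self):
        p = ThermoParams(dH=-40e3, dS=50.0, dCp=0.0)
        dg = predict_gibbs(p, TEMPS)
        assert np.allclose(np.diff(dg, 2), 0.0, atol=1e-9)

    def test_hand_evaluated_curvature_case(self):
        # independent arithmetic: dH - T*dS + dCp*(T-T0) - dCp*T*ln(T/T0)
        dH, dS, dCp, t = -30e3, 80.0, -1.5e3, 303.15
        expected = dH - t * dS + dCp * (t - 293.15) - dCp * t * np.log(t / 293.15)
        assert predict_gibbs(ThermoParams(dH=dH, dS=dS, dCp=dCp), t) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-53999.4, abs=1.0)

    def test_reference_temperature_not_configurable(self):
        with pytest.raises(ValueError):
            ThermoParams(dH=0.0, dS=0.0, dCp=0.0, t_ref=298.15)


class TestVantHoffFit:
    def test_exact_recovery_linear_case(self):
        p = ThermoParams(dH=-40e3, dS=50.0, dCp=0.0)
        fit = vant_hoff_fit(TEMPS, predict_gibbs(p, TEMPS))
        assert fit.dH == pytest.approx(p.dH, rel=1e-8)
        assert fit.dS == pytest.approx(p.dS, rel=1e-8)
        assert abs(fit.dCp) < 1e-6

    def test_recovery_with_curvature(self):
        p = ThermoParams(dH=-30e3, dS=80.0, dCp=-1.5e3)
        fit = vant_hoff_fit(TEMPS, predict_gibbs(p, TEMPS))
        for name in ("dH", "dS", "dCp"):
            assert getattr(fit, name) == pytest.approx(getattr(p, name), rel=1e-6)

    def test_three_points_interpolate_exactly(self):
        p = ThermoParams(dH=-25e3, dS=60.0, dCp=-900.0)
        t = TEMPS[:3]
        fit = vant_hoff_fit(t, predict_gibbs(p, t))
        residuals = predict_gibbs(fit, t) - predict_gibbs(p, t)
        assert np.max(np.abs(residuals)) < 1e-6

    def test_under_determined_rejected(self):
        with pytest.raises(ValueError):
            vant_hoff_fit(TEMPS[:2], np.array([-55e3, -54e3]))

    def test_round_trip_random_draws(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            p = ThermoParams(
                dH=rng.uniform(-80e3, 40e3), dS=rng.uniform(-100, 300), dCp=rng.uniform(-3e3, 1e3)
            )
            fit = vant_hoff_fit(TEMPS, predict_gibbs(p, TEMPS))
            assert fit.dH == pytest.approx(p.dH, rel=1e-6, abs=1e-3)
            assert fit.dS == pytest.approx(p.dS, rel=1e-6, abs=1e-6)
            assert fit.dCp == pytest.approx(p.dCp, rel=1e-6, abs=1e-6)


class TestEyringFit:
    def test_zero_activation_enthalpy_gives_zero_slope(self):
        a = ActivationParams(dH_act=0.0, dS_act=-60.0)
        kon = eyring_kon(a, TEMPS)
        slope = np.polyfit(1.0 / TEMPS, np.log(kon / TEMPS), 1)[0]
        assert abs(slope) < 1e-9
        fit = eyring_fit(TEMPS, kon)
        assert abs(fit.dH_act) < 1e-6

    def test_exact_recovery(self):
        a = ActivationParams(dH_act=40e3, dS_act=-60.0)
        fit = eyring_fit(TEMPS, eyring_kon(a, TEMPS))
        assert fit.dH_act == pytest.approx(a.dH_act, rel=1e-9)
        assert fit.dS_act == pytest.approx(a.dS_act, rel=1e-9)

    def test_kon_doubling_implies_22_kj(self):
        """Hand solution of ln(k2/k1) = ln(T2/T1) - dH_act/R*(1/T2 - 1/T1)."""
        t1, t2 = 283.15, 303.15
        dh_hand = (np.log(2.0) - np.log(t2 / t1)) * R / (1 / t1 - 1 / t2)
        assert dh_hand == pytest.approx(22.3e3, abs=50.0)
        kon = np.array([1e6, 2e6])
        fit = eyring_fit(np.array([t1, t2]), kon)
        assert fit.dH_act == pytest.approx(dh_hand, rel=1e-9)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            eyring_fit(np.array([298.15]), np.array([1e6]))

    def test_round_trip_random_draws(self):
        rng = np.random.default_rng(88)
        for _ in range(20):
            a = ActivationParams(dH_act=rng.uniform(5e3, 80e3), dS_act=rng.uniform(-150, 100))
            fit = eyring_fit(TEMPS, eyring_kon(a, TEMPS))
            assert fit.dH_act == pytest.approx(a.dH_act, rel=1e-6)
            assert fit.dS_act == pytest.approx(a.dS_act, rel=1e-6, abs=1e-6)


class TestFoldChange:
    @pytest.mark.parametrize(
        "mutant,wildtype,printed",
        [
            (5.44e7, 2.48e6, "22"),     # fastest-association mutant
            (7.19e6, 2.48e6, "2.9"),
            (7.64e5, 2.48e6, "0.31"),
            (2.79e5, 2.48e6, "0.11"),
        ],
    )
    def test_kon_ratios_at_printed_precision(self, mutant, wildtype, printed):
        assert f"{fold_change(mutant, wildtype):.2g}" == printed

    def test_off_rate_ratio(self):
        ratio = fold_change(1.46e-5, 5.49e-4)
        assert ratio == pytest.approx(0.0266, abs=5e-4)
        assert f"{ratio:.1g}" == "0.03"

    def test_self_ratio_is_one(self):
        assert fold_change(3.3, 3.3) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestClassifySignature:
    def test_both_favorable(self):
        labels = classify_signature(-20e3, 100.0)
        assert labels == {"enthalpy": "favorable", "entropy": "favorable"}

    def test_entropy_driven(self):
        labels = classify_signature(15e3, 200.0)
        assert labels == {"enthalpy": "unfavorable", "entropy": "favorable"}

    def test_neutral_boundary(self):
        labels = classify_signature(0.0, 50.0)
        assert labels["enthalpy"] == "neutral"
        assert classify_signature(-20e3, 0.0)["entropy"] == "neutral"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_signature(np.nan, 0.0)


class TestTmExtraction:
    def test_recovers_wildtype_like_tm(self):
        tg = generate_dsc_thermogram(76.8)
        result = tm_from_thermogram(tg.temps_c, tg.excess_cp)
        assert result.tm_c == pytest.approx(76.8, abs=0.1)
        assert not result.at_edge

    @pytest.mark.parametrize("tm", [66.9, 69.5, 71.1, 74.4])
    def test_recovers_panel_tms(self, tm):
        tg = generate_dsc_thermogram(tm)
        assert tm_from_thermogram(tg.temps_c, tg.excess_cp).tm_c == pytest.approx(tm, abs=0.1)

    def test_flat_baseline_is_no_peak(self):
        t = np.linspace(30.0, 90.0, 121)
        with pytest.raises(ValueError, match="no transition peak"):
            tm_from_thermogram(t, np.full_like(t, 5.0))

    def test_edge_peak_warns(self):
        t = np.linspace(30.0, 90.0, 121)
        rising = np.exp((t - 30.0) / 10.0)
        with pytest.warns(RuntimeWarning, match="edge"):
            result = tm_from_thermogram(t, rising)
        assert result.at_edge
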