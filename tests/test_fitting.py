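"""Blank subtraction and global 1:1 fitting: recovery, SEs, reporting."""

import numpy as np
import pytest

from fabthermo import (
    FitResult,
    InjectionProtocol,
    KineticParams,
    NonIdentifiableError,
    SensorgramTrace,
    blank_subtract,
    fit_report,
    global_fit,
    simulate_sensorgram,
)
from conftest import WT_KOFF, WT_KON, concentration_series


class TestBlankSubtract:
    def test_trace_minus_itself_is_zero(self, wt_params, protocol):
        tr = simulate_sensorgram(wt_params, protocol)
        out = blank_subtract(tr, tr)
        assert np.all(out.responses == 0.0)

    def test_zero_blank_is_identity(self, wt_params, protocol):
        tr = simulate_sensorgram(wt_params, protocol)
        blank = SensorgramTrace(tr.times, np.zeros_like(tr.responses), 0.0, tr.temperature)
        out = blank_subtract(tr, blank)
        assert np.array_equal(out.responses, tr.responses)
        assert out.concentration == tr.concentration

    def test_constant_offset_recovered_exactly(self, wt_params, protocol):
        tr = simulate_sensorgram(wt_params, protocol)
        offset = 17.5
        shifted = SensorgramTrace(
            tr.times, tr.responses + offset, tr.concentration, tr.temperature,
            tr.t_assoc_start, tr.t_assoc_end,
        )
        blank = SensorgramTrace(tr.times, np.full_like(tr.responses, offset), 0.0, tr.temperature)
        out = blank_subtract(shifted, blank)
        np.testing.assert_allclose(out.responses, tr.responses, rtol=0, atol=1e-12)

    def test_mismatched_grids_rejected(self, wt_params, protocol):
        tr = simulate_sensorgram(wt_params, protocol)
        blank = SensorgramTrace(tr.times + 0.5, np.zeros_like(tr.responses), 0.0, tr.temperature)
        with pytest.raises(ValueError, match="grid"):
            blank_subtract(tr, blank)


class TestGlobalFit:
    def test_noiseless_recovery_wildtype(self, wt_params):
        traces = concentration_series(wt_params)
        res = global_fit(traces)
        assert res.converged
        assert res.params.kon == pytest.approx(WT_KON, rel=1e-6)
        assert res.params.koff == pytest.approx(WT_KOFF, rel=1e-6)
        assert res.params.rmax == pytest.approx(100.0, rel=1e-6)
        assert res.residual_sum_of_squares < 1e-12

    def test_noiseless_recovery_random_draws(self):
        """Ground truth is recovered to 1e-6 across the plausible rate space."""
        rng = np.random.default_rng(202)
        for _ in range(20):
            kon = 10 ** rng.uniform(5, 8)
            koff = 10 ** rng.uniform(-5, -2)
            params = KineticParams(kon=kon, koff=koff, rmax=100.0, temperature=298.15)
            traces = concentration_series(params)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = global_fit(traces)
            assert res.converged
            assert res.params.kon == pytest.approx(kon, rel=1e-6)
            assert res.params.koff == pytest.approx(koff, rel=1e-6)
            assert res.params.rmax == pytest.approx(100.0, rel=1e-6)

    def test_fit_invariant_to_trace_order(self, wt_params):
        traces = concentration_series(wt_params, noise_sd=1.0, seed=5)
        a = global_fit(traces)
        b = global_fit(traces[::-1])
        assert a.params.kon == pytest.approx(b.params.kon, rel=1e-9)
        assert a.params.koff == pytest.approx(b.params.koff, rel=1e-9)

    def test_noisy_recovery_median_error(self, wt_params):
        errs_kon, errs_koff = [], []
        for seed in range(20):
            traces = concentration_series(wt_params, noise_sd=1.0, seed=seed)
            res = global_fit(traces)
            errs_kon.append(abs(res.params.kon - WT_KON) / WT_KON)
            errs_koff.append(abs(res.params.koff - WT_KOFF) / WT_KOFF)
        assert np.median(errs_kon) < 0.05
        assert np.median(errs_koff) < 0.05

    def test_se_shrinks_with_replicates(self, wt_params):
        medians = []
        for n_rep in (1, 2):
            ses = []
            for seed in range(10):
                traces = []
                for rep in range(n_rep):
                    traces += concentration_series(wt_params, noise_sd=1.0, seed=1000 * n_rep + 10 * seed + rep)
                ses.append(global_fit(traces).standard_errors["kon"])
            medians.append(np.median(ses))
        assert medians[1] < medians[0]

    def test_blank_only_not_identifiable(self, wt_params):
        protocol = InjectionProtocol(0.0, 120.0, 720.0, 0.0)
        blank = simulate_sensorgram(wt_params, protocol, noise_sd=1.0, seed=0)
        with pytest.raises(NonIdentifiableError):
            global_fit([blank])

    def test_all_zero_responses_not_identifiable(self, wt_params):
        t = np.arange(0.0, 721.0)
        tr = SensorgramTrace(t, np.zeros_like(t), 5e-9, 298.15, 0.0, 120.0)
        with pytest.raises(NonIdentifiableError):
            global_fit([tr])

    def test_short_dissociation_flags_koff(self):
        params = KineticParams(kon=7.19e6, koff=1e-7, rmax=100.0)
        traces = concentration_series(params)
        with pytest.warns(RuntimeWarning, match="koff poorly determined"):
            res = global_fit(traces)
        assert res.warnings


class TestFitReport:
    def _result(self, kon, koff):
        params = KineticParams(kon=kon, koff=koff, rmax=100.0)
        return FitResult(
            params=params,
            standard_errors={"kon": 0.01e6, "koff": 0.01e-4, "rmax": 1.0},
            residual_sum_of_squares=0.0,
            n_points=100,
            converged=True,
        )

    def test_kd_is_ratio_of_rounded_rates(self):
        row = fit_report(self._result(2.48e6, 5.49e-4), variant="wild-type")
        assert row["kd_M"] == pytest.approx(2.21e-10, rel=1e-3)

    def test_tightest_variant_row(self):
        row = fit_report(self._result(7.19e6, 1.46e-5), variant="R5")
        assert row["kd_M"] == pytest.approx(2.03e-12, rel=1e-3)

    def test_rmax_not_in_row(self):
        row = fit_report(self._result(1e6, 1e-3))
        assert all("rmax" not in key for key in row)

    def test_unconverged_result_rejected(self):
        res = self._result(1e6, 1e-3)
        res.converged = False
        with pytest.raises(ValueError):
            fit_report(res)
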