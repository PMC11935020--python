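"""Decay-model evaluation, log-slope fitting, and rate-constant regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from juxtacell import kinetics as kin
from juxtacell import synthdata as sd

NLUC_K = 38207.0  # M^-1 s^-1
E_SERIES = [1e-9, 2e-9, 5e-9, 10e-9, 20e-9]


def _params(K=NLUC_K, E=5e-9, S0=20e-6, alpha=1e15):
    return kin.KineticParams(K=K, E=E, S0=S0, alpha=alpha)


class TestModelFlux:
    def test_no_enzyme_means_no_light(self, minute_grid):
        tr = kin.model_flux(_params(E=0.0), minute_grid)
        assert np.all(tr.flux == 0.0)

    def test_initial_flux_is_alpha_K_E_S0(self):
        p = _params()
        tr = kin.model_flux(p, [0.0, 1.0, 2.0])
        assert tr.flux[0] == pytest.approx(p.alpha * p.K * p.E * p.S0, rel=1e-12)

    def test_half_life_matches_closed_form(self):
        # K = 38207 M^-1 s^-1 at 5 nM enzyme: flux halves every ln2/(K E) ~ 3.63e3 s
        p = _params(K=NLUC_K, E=5e-9)
        t_half = np.log(2) / (p.K * p.E)
        assert t_half == pytest.approx(3.63e3, rel=0.01)
        tr = kin.model_flux(p, [0.0, t_half, 2 * t_half])
        assert tr.flux[1] == pytest.approx(tr.flux[0] / 2, rel=1e-12)
        assert tr.flux[2] == pytest.approx(tr.flux[0] / 4, rel=1e-12)

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            kin.model_flux(_params(), [0.0, 10.0, 10.0])

    def test_rejects_invalid_params(self):
        with pytest.raises(ValueError):
            kin.KineticParams(K=-1.0, E=1e-9, S0=1e-6)
        with pytest.raises(ValueError):
            kin.KineticParams(K=1.0, E=1e-9, S0=0.0)


class TestFitLogSlope:
    def test_noiseless_model_is_log_linear(self, minute_grid):
        # generating lambda = K E = 1e-3 /s recovered exactly, r^2 = 1
        p = _params(K=1e5, E=1e-8)  # K E = 1e-3
        fit = kin.fit_log_slope(kin.model_flux(p, minute_grid))
        assert fit.slope_magnitude == pytest.approx(1e-3, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_flux_has_zero_slope(self, minute_grid):
        tr = kin.LuminescenceTrace(minute_grid, np.full_like(minute_grid, 500.0), 1e-9)
        fit = kin.fit_log_slope(tr)
        assert fit.slope_magnitude == pytest.approx(0.0, abs=1e-15)
        assert 0.0 <= fit.r_squared <= 1.0

    def test_noisy_slope_close_to_generating_rate(self, minute_grid):
        # 1 % multiplicative log-normal noise, fixed seed -> slope within 2 %
        p = _params(K=1e5, E=1e-8)
        (tr,) = sd.make_trace_set(
            K=p.K, E_list=[p.E], S0=p.S0, alpha=p.alpha,
            noise_cv=0.01, seed=42, t_grid=minute_grid,
        )
        fit = kin.fit_log_slope(tr)
        assert fit.slope_magnitude == pytest.approx(1e-3, rel=0.02)

    def test_scale_invariance_of_slope(self, minute_grid):
        p = _params()
        tr = kin.model_flux(p, minute_grid)
        base = kin.fit_log_slope(tr).slope_magnitude
        for c in (0.5, 3.0, 1e4):
            scaled = kin.LuminescenceTrace(
                tr.times, tr.flux * c, tr.enzyme_concentration
            )
            assert kin.fit_log_slope(scaled).slope_magnitude == pytest.approx(
                base, rel=1e-9
            )

    def test_min_flux_exclusion_and_insufficient_data(self, minute_grid):
        tr = kin.LuminescenceTrace(
            minute_grid, np.full_like(minute_grid, 5.0), 1e-9
        )
        with pytest.raises(kin.InsufficientDataError):
            kin.fit_log_slope(tr, min_flux=10.0)

    def test_window_restricts_samples(self, minute_grid):
        p = _params(K=1e5, E=1e-8)
        tr = kin.model_flux(p, minute_grid)
        fit = kin.fit_log_slope(tr, window=(300.0, 900.0))
        assert fit.n_points_used == 11
        assert fit.window == (300.0, 900.0)


class TestEstimateRateConstant:
    def test_exact_line_through_origin(self):
        pts = [(E * 1e-9, 1e4 * E * 1e-9) for E in (1, 2, 5, 10)]
        fit = kin.estimate_rate_constant(pts)
        assert fit.K_hat == pytest.approx(1e4, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-15)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_ols_on_three_points(self):
        # brute-force closed-form OLS oracle on an arbitrary 3-point design
        pts = [(1e-9, 2.1e-5), (4e-9, 7.9e-5), (9e-9, 19.5e-5)]
        E = np.array([p[0] for p in pts])
        lam = np.array([p[1] for p in pts])
        slope_oracle = np.sum((E - E.mean()) * (lam - lam.mean())) / np.sum(
            (E - E.mean()) ** 2
        )
        fit = kin.estimate_rate_constant(pts)
        assert fit.K_hat == pytest.approx(slope_oracle, rel=1e-12)
        assert fit.ci95[0] <= fit.K_hat <= fit.ci95[1]

    @pytest.mark.parametrize("K_true", [NLUC_K, 10644.0])
    def test_recovers_generating_constant_end_to_end(self, K_true, minute_grid):
        traces = sd.make_trace_set(K=K_true, E_list=E_SERIES, t_grid=minute_grid)
        pts = [
            (tr.enzyme_concentration, kin.fit_log_slope(tr).slope_magnitude)
            for tr in traces
        ]
        fit = kin.estimate_rate_constant(pts)
        assert fit.K_hat == pytest.approx(K_true, rel=1e-3)

    def test_degenerate_design_rejected(self):
        with pytest.raises(kin.DegenerateDesignError):
            kin.estimate_rate_constant([(1e-9, 1.0), (1e-9, 2.0), (1e-9, 3.0)])
        with pytest.raises(kin.InsufficientDataError):
            kin.estimate_rate_constant([(1e-9, 1.0), (2e-9, 2.0)])

    def test_bias_shrinks_with_replicates(self, minute_grid):
        # with noise, pooling slopes from more replicates tightens recovery;
        # K E is kept well above the slope noise floor so |slope| folding
        # cannot pin a residual bias
        K_true = 1e5
        errs = []
        for n_rep, seed in ((2, 1), (40, 2)):
            pts = []
            for rep in range(n_rep):
                traces = sd.make_trace_set(
                    K=K_true, E_list=E_SERIES, noise_cv=0.05,
                    seed=seed * 1000 + rep, t_grid=minute_grid,
                )
                pts += [
                    (
                        tr.enzyme_concentration,
                        kin.fit_log_slope(tr, window=(0.0, 1800.0)).slope_magnitude,
                    )
                    for tr in traces
                ]
            errs.append(abs(kin.estimate_rate_constant(pts).K_hat - K_true) / K_true)
        assert errs[1] < 0.01
        assert errs[1] < max(errs[0], 0.02)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(logK=st.floats(min_value=3.0, max_value=6.0))
def test_noiseless_recovery_across_rate_constant_range(logK):
    """Two-stage estimation inverts the generator for any K in [1e3, 1e6]."""
    K = 10.0**logK
    # sample within ~2 decay half-lives so the log fit sees real curvature
    t_end = min(1800.0, 2 * np.log(2) / (K * 20e-9))
    t_grid = np.linspace(0.0, t_end, 31)
    traces = sd.make_trace_set(K=K, E_list=E_SERIES, t_grid=t_grid, alpha=1e18)
    pts = [
        (tr.enzyme_concentration, kin.fit_log_slope(tr, min_flux=0.0).slope_magnitude)
        for tr in traces
    ]
    assert kin.estimate_rate_constant(pts).K_hat == pytest.approx(K, rel=1e-3)


class TestTraceSummaries:
    def test_max_flux_of_decaying_trace_is_first_sample(self, minute_grid):
        tr = kin.model_flux(_params(), minute_grid)
        assert kin.max_photon_flux(tr) == tr.flux[0]

    def test_max_flux_ordering_follows_KE(self, minute_grid):
        a = kin.model_flux(_params(K=2e4, E=10e-9), minute_grid)
        b = kin.model_flux(_params(K=1e4, E=10e-9), minute_grid)
        assert kin.max_photon_flux(a) > kin.max_photon_flux(b)

    def test_time_above_zero_threshold_is_span(self, minute_grid):
        tr = kin.model_flux(_params(), minute_grid)
        assert kin.time_above_threshold(tr, 0.0) == pytest.approx(1800.0)

    def test_threshold_above_max_gives_zero(self, minute_grid):
        tr = kin.model_flux(_params(), minute_grid)
        assert kin.time_above_threshold(tr, 2 * kin.max_photon_flux(tr)) == 0.0

    def test_half_maximum_crossing_near_half_life(self):
        p = _params(K=1e5, E=1e-8)  # lambda = 1e-3 -> t_half ~ 693 s
        t_grid = np.arange(0.0, 3001.0, 30.0)
        tr = kin.model_flux(p, t_grid)
        t = kin.time_above_threshold(tr, tr.flux[0] / 2)
        assert abs(t - np.log(2) / 1e-3) <= 30.0


class TestTraceIO:
    def test_csv_round_trip_multi_label(self, tmp_path, minute_grid):
        traces = sd.make_trace_set(K=1e4, E_list=E_SERIES, noise_cv=0.02, seed=3)
        path = tmp_path / "traces.csv"
        kin.write_traces_csv(traces, path)
        back = kin.read_traces_csv(path)
        assert [t.label for t in back] == [t.label for t in traces]
        for a, b in zip(traces, back):
            np.testing.assert_allclose(b.times, a.times)
            np.testing.assert_allclose(b.flux, a.flux)
            assert b.enzyme_concentration == a.enzyme_concentration
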