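import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crabtree as ct
from crabtree.kinetics import EndpointRule

from conftest import make_timeseries


def _growth_series():
    """Exact doubling every hour on ample glucose."""
    return make_timeseries(
        [0.0, 1.0, 2.0, 3.0],
        dw_gL=[0.1, 0.2, 0.4, 0.8],
        od600=[0.2, 0.4, 0.8, 1.6],
        glucose_gL=[18.0, 16.0, 12.0, 8.0],
    )


class TestExponentialWindow:
    def test_exact_doubling(self):
        window = ct.detect_exponential_window(_growth_series(), min_points=4)
        assert window.mu_per_h == pytest.approx(math.log(2.0), abs=1e-12)
        assert window.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert (window.t_start_h, window.t_end_h) == (0.0, 3.0)

    def test_flat_biomass_has_no_window(self):
        ts = make_timeseries(
            [0, 1, 2, 3, 4],
            dw_gL=[0.5] * 5,
            glucose_gL=[18] * 5,
        )
        with pytest.raises(ValueError, match="manual window"):
            ct.detect_exponential_window(ts)

    def test_window_stops_before_ethanol_decline(self, noiseless_runs):
        _, ts, _ = noiseless_runs["strong_positive"]
        window = ct.detect_exponential_window(ts)
        eth = ts.samples["ethanol_gL"]
        t_peak = ts.samples["time_h"].iloc[int(np.argmax(eth))]
        assert window.t_end_h <= t_peak

    def test_simulated_mu_recovery(self, noiseless_runs):
        for preset, (params, ts, _) in noiseless_runs.items():
            window = ct.detect_exponential_window(ts)
            assert window.mu_per_h == pytest.approx(
                ct.glucose_phase_mu(params), rel=0.02), preset


class TestFitGrowthRate:
    def test_exact_exponential(self):
        t = np.arange(0.0, 11.0)
        ts = make_timeseries(
            t, dw_gL=0.05 * np.exp(0.3 * t), od600=0.1 * np.exp(0.3 * t),
            glucose_gL=np.linspace(20, 10, len(t)),
        )
        assert ct.fit_growth_rate(ts, (0, 10)) == pytest.approx(0.300,
                                                                abs=1e-12)

    def test_od_basis_gives_identical_slope(self):
        """OD600 is a constant multiple of DW, which only shifts the
        log intercept."""
        t = np.arange(0.0, 11.0)
        ts = make_timeseries(
            t, dw_gL=0.05 * np.exp(0.3 * t), od600=0.1 * np.exp(0.3 * t),
            glucose_gL=np.linspace(20, 10, len(t)),
        )
        mu_dw = ct.fit_growth_rate(ts, (0, 10), basis="DW")
        mu_od = ct.fit_growth_rate(ts, (0, 10), basis="OD600")
        assert mu_od == pytest.approx(mu_dw, abs=1e-12)

    def test_diauxic_phase_matches_ethanol_growth_rate(self, noiseless_runs):
        """A window placed on the ethanol-consumption phase recovers the
        analytic mu = Yxe * qe_max."""
        params, ts, _ = noiseless_runs["strong_positive"]
        s = ts.samples
        eth = s["ethanol_gL"].to_numpy()
        peak = int(np.argmax(eth))
        # early diauxic phase: ethanol still >> Ke, so the Monod factor
        # E/(Ke+E) stays within ~1% of saturation
        high = np.flatnonzero(eth > 5.0)
        t0 = s["time_h"].iloc[peak + 1]
        t1 = s["time_h"].iloc[high[-1]]
        mu = ct.fit_growth_rate(ts, (t0, t1))
        assert mu == pytest.approx(ct.ethanol_phase_mu(params), rel=0.02)

    def test_nonpositive_biomass_rejected(self):
        ts = make_timeseries([0, 1, 2, 3], dw_gL=[0.0, 0.1, 0.2, 0.4])
        with pytest.raises(ValueError, match="nonpositive"):
            ct.fit_growth_rate(ts, (0, 3))


class TestEndpoint:
    def test_ethanol_maximum(self):
        ts = make_timeseries(
            [0, 6, 12, 18],
            dw_gL=[0.1, 1.0, 3.0, 3.5],
            glucose_gL=[20, 10, 0.0, 0.0],
            ethanol_gL=[0.0, 4.0, 7.8, 5.0],
        )
        endpoint = ct.determine_endpoint(ts)
        assert endpoint.rule is EndpointRule.ETHANOL_MAX
        assert endpoint.crabtree_positive
        assert endpoint.t_end_h == 12.0
        assert not endpoint.mixed_metabolism

    def test_glucose_depletion_interpolated(self):
        ts = make_timeseries(
            [19, 20, 21],
            dw_gL=[8, 9, 10],
            glucose_gL=[1.0, 0.4, 0.0],
        )
        endpoint = ct.determine_endpoint(ts)
        assert endpoint.rule is EndpointRule.GLUCOSE_DEPLETED
        # crossing 0.1 g/L between 0.4 and 0.0: 20 + 0.3/0.4
        assert endpoint.t_end_h == pytest.approx(20.75)

    def test_mixed_metabolism_flagged(self):
        ts = make_timeseries(
            [0, 6, 12, 18],
            dw_gL=[0.1, 1.0, 3.0, 3.5],
            glucose_gL=[20, 10, 2.0, 0.0],
            ethanol_gL=[0.0, 4.0, 7.8, 5.0],
        )
        with pytest.warns(UserWarning, match="mixed"):
            endpoint = ct.determine_endpoint(ts)
        assert endpoint.rule is EndpointRule.ETHANOL_MAX
        assert endpoint.mixed_metabolism

    def test_unfinished_culture_rejected(self):
        ts = make_timeseries([0, 1, 2], dw_gL=[0.1, 0.2, 0.4],
                             glucose_gL=[20, 18, 16])
        with pytest.raises(ValueError, match="not finished"):
            ct.determine_endpoint(ts)


class TestYieldsAndRates:
    def test_fermentative_yields_hand_arithmetic(self):
        ts = make_timeseries(
            [0, 10, 20],
            dw_gL=[0.05, 1.0, 3.25],
            glucose_gL=[20.0, 10.0, 0.0],
            ethanol_gL=[0.0, 4.0, 7.8],
        )
        endpoint = ct.Endpoint(20.0, EndpointRule.ETHANOL_MAX, True)
        yields = ct.compute_yields(ts, endpoint)
        assert yields["ethanol"] == pytest.approx(7.8 / 20.0)
        assert yields["biomass"] == pytest.approx(3.2 / 20.0)

    def test_respiratory_yields_hand_arithmetic(self):
        ts = make_timeseries(
            [0, 10, 20],
            dw_gL=[0.0, 4.0, 11.4],
            glucose_gL=[20.0, 12.0, 0.0],
        )
        endpoint = ct.Endpoint(20.0, EndpointRule.GLUCOSE_DEPLETED, False)
        yields = ct.compute_yields(ts, endpoint)
        assert yields["biomass"] == pytest.approx(0.57)
        assert all(yields[p] == 0.0 for p in yields if p != "biomass")

    def test_zero_consumption_rejected(self):
        ts = make_timeseries([0, 1, 2], dw_gL=[1, 1, 1],
                             glucose_gL=[20, 20, 20],
                             ethanol_gL=[9.9, 9.9, 9.9])
        endpoint = ct.Endpoint(0.0, EndpointRule.ETHANOL_MAX, True)
        with pytest.raises(ValueError, match="consumed"):
            ct.compute_yields(ts, endpoint)

    def test_specific_rates_hand_arithmetic(self):
        ts = make_timeseries(
            [0, 2, 4],
            dw_gL=[0.4, 0.9, 2.0],
            glucose_gL=[18.0, 14.0, 8.0],
            ethanol_gL=[0.0, 1.0, 4.0],
        )
        window = ct.ExponentialWindow(0.0, 4.0, 0.28, 1.0, 3)
        rates = ct.compute_specific_rates(ts, window)
        assert rates["glucose"] == pytest.approx(10.0 / 1.6 * 0.28)  # 1.75
        assert rates["ethanol"] == pytest.approx(4.0 / 1.6 * 0.28)
        assert rates["glycerol"] == 0.0

    def test_rate_yield_consistency(self, noiseless_runs):
        """q_E / q_S equals the exponential-phase ethanol-per-glucose
        yield (the two rate formulations agree)."""
        _, ts, metrics = noiseless_runs["strong_positive"]
        s = ts.samples
        mask = (s["time_h"] >= metrics.window.t_start_h) & (
            s["time_h"] <= metrics.window.t_end_h)
        sub = s.loc[mask]
        de = sub["ethanol_gL"].iloc[-1] - sub["ethanol_gL"].iloc[0]
        ds = sub["glucose_gL"].iloc[0] - sub["glucose_gL"].iloc[-1]
        assert metrics.rates["ethanol"] / metrics.rates["glucose"] == (
            pytest.approx(de / ds, rel=1e-9))

    def test_flat_biomass_rejected(self):
        ts = make_timeseries([0, 1, 2], dw_gL=[1, 1, 1],
                             glucose_gL=[20, 15, 10])
        window = ct.ExponentialWindow(0.0, 2.0, 0.2, 1.0, 3)
        with pytest.raises(ValueError, match="biomass not increasing"):
            ct.compute_specific_rates(ts, window)


class TestGasMetrics:
    def test_respiratory_rq_is_one(self, noiseless_runs):
        _, ts, metrics = noiseless_runs["negative"]
        assert metrics.respiration_ratio == pytest.approx(1.00, abs=0.02)

    def test_fermenting_rq_far_above_one(self, noiseless_runs):
        _, _, metrics = noiseless_runs["strong_positive"]
        assert metrics.respiration_ratio > 1.5

    def test_zero_o2_flagged_infinite(self):
        ts = make_timeseries(
            [0, 5, 10],
            dw_gL=[0.1, 0.5, 1.0],
            glucose_gL=[20, 10, 0.05],
            ethanol_gL=[0, 5, 9.5],
            co2_cum_mol_per_L=[0.0, 0.1, 0.2],
        )
        assert math.isinf(ct.respiration_ratio(ts))

    def test_missing_gas_columns_rejected(self):
        ts = make_timeseries([0, 1, 2], dw_gL=[1, 2, 4],
                             glucose_gL=[20, 10, 0])
        ts.samples = ts.samples.drop(columns=["o2_cum_mol_per_L"])
        with pytest.raises(ValueError, match="o2_cum_mol_per_L"):
            ct.respiration_ratio(ts)

    def test_pure_fermentation_stoichiometry_closes(self):
        """C6H12O6 -> 2 EtOH + 2 CO2: 20 g/L glucose gives 10.22 g/L
        ethanol and 0.222 mol/L CO2, closing the carbon balance."""
        ts = make_timeseries(
            [0, 5, 10],
            dw_gL=[0.1, 0.1, 0.1],
            glucose_gL=[20.0, 10.0, 0.0],
            ethanol_gL=[0.0, 5.11, 10.22],
            co2_cum_mol_per_L=[0.0, 0.111, 0.222],
        )
        endpoint = ct.Endpoint(10.0, EndpointRule.ETHANOL_MAX, True)
        assert ct.carbon_balance(ts, endpoint) == pytest.approx(1.00,
                                                                abs=0.01)

    def test_dropping_biomass_lowers_balance(self, noiseless_runs):
        _, ts, metrics = noiseless_runs["negative"]
        clipped = ts.copy()
        clipped.samples["dw_gL"] = clipped.samples["dw_gL"].iloc[0]
        partial = ct.carbon_balance(clipped, metrics.endpoint)
        assert partial < metrics.carbon_balance
        assert partial < 1.0

    @pytest.mark.parametrize("preset",
                             ["strong_positive", "intermediate", "negative"])
    def test_simulations_are_carbon_closed(self, noiseless_runs, preset):
        _, _, metrics = noiseless_runs[preset]
        assert metrics.carbon_balance == pytest.approx(1.00, abs=0.01)


class TestInvariances:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(0.2, 5.0))
    def test_scale_invariance(self, noiseless_runs, scale):
        """Rescaling every concentration and the dry weight (with the
        g/L extraction thresholds rescaled alongside, since they are
        absolute concentrations) leaves all extracted metrics
        unchanged."""
        _, ts, metrics = noiseless_runs["strong_positive"]
        scaled = ts.copy()
        for col in scaled.samples.columns:
            if col != "time_h":
                scaled.samples[col] = scaled.samples[col] * scale
        cfg = ct.ExtractionConfig(
            window_glucose_min_gL=1.0 * scale,
            ethanol_detect_gL=0.5 * scale,
            glucose_depleted_gL=0.1 * scale,
        )
        m2 = ct.extract_metrics(scaled, cfg)
        assert m2.mu_per_h == pytest.approx(metrics.mu_per_h, rel=1e-9)
        assert m2.yields["ethanol"] == pytest.approx(
            metrics.yields["ethanol"], rel=1e-9)
        assert m2.yields["biomass"] == pytest.approx(
            metrics.yields["biomass"], rel=1e-9)
        assert m2.rates["glucose"] == pytest.approx(
            metrics.rates["glucose"], rel=1e-9)
        assert m2.respiration_ratio == pytest.approx(
            metrics.respiration_ratio, rel=1e-9)
        assert m2.carbon_balance == pytest.approx(
            metrics.carbon_balance, rel=1e-9)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(shift=st.floats(-5.0, 50.0))
    def test_time_shift_invariance(self, noiseless_runs, shift):
        _, ts, metrics = noiseless_runs["intermediate"]
        shifted = ts.copy()
        shifted.samples["time_h"] = shifted.samples["time_h"] + shift
        m2 = ct.extract_metrics(shifted)
        assert m2.mu_per_h == pytest.approx(metrics.mu_per_h, rel=1e-9)
        assert m2.yields["ethanol"] == pytest.approx(
            metrics.yields["ethanol"], rel=1e-9)
        assert m2.endpoint.t_end_h - metrics.endpoint.t_end_h == (
            pytest.approx(shift, abs=1e-6))


class TestExtractMetrics:
    def test_negative_run_has_no_fermentation(self, noiseless_runs):
        _, _, metrics = noiseless_runs["negative"]
        assert metrics.rates["ethanol"] == 0.0
        assert metrics.yields["ethanol"] == 0.0
        assert not metrics.endpoint.crabtree_positive

    def test_strong_positive_yield_matches_preset(self, noiseless_runs):
        params, _, metrics = noiseless_runs["strong_positive"]
        analytic = ct.glucose_phase_yields(params)["ethanol"]
        assert metrics.endpoint.crabtree_positive
        assert metrics.yields["ethanol"] == pytest.approx(analytic, rel=0.03)

    def test_manual_window_override(self, noiseless_runs):
        params, ts, _ = noiseless_runs["strong_positive"]
        cfg = ct.ExtractionConfig(manual_window=(2.0, 10.0))
        metrics = ct.extract_metrics(ts, cfg)
        assert metrics.window.t_start_h == 2.0
        assert metrics.mu_per_h == pytest.approx(
            ct.glucose_phase_mu(params), rel=0.02)

    def test_errors_carry_stage_names(self):
        ts = make_timeseries([0, 1, 2, 3], dw_gL=[0.5] * 4,
                             glucose_gL=[18] * 4)
        with pytest.raises(ValueError, match="window detection"):
            ct.extract_metrics(ts)
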