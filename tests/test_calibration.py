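"""Sequential calibration: arithmetic steps, scans, fits, and round trips."""

import numpy as np
import pytest

from eve2sim import (
    DataFeatures,
    constrain_unbinding,
    estimate_high_rate,
    extract_minute_series,
    fit_repressor_binding,
    occupancy_to_binding,
    run_full_estimation,
    simulate_nucleus,
    solve_activation_rates,
    solve_nucleus_ode,
    spatial_profile,
    termination_rate,
)
from eve2sim.stats import per_minute_change, regularize


class TestArithmeticSteps:
    def test_occupancy_inversion_basics(self):
        assert occupancy_to_binding(0.5, 1.0, 1.0) == pytest.approx(1.0)
        assert occupancy_to_binding(0.0, 0.5, 1e-9) == 0.0

    def test_occupancy_inversion_recovers_printed_bcd_constant(self):
        conc_b = 0.033 * (0.55 / 0.45) / 2.6e6  # the calibrated fixture [B]
        assert occupancy_to_binding(0.55, 0.033, conc_b) == pytest.approx(2.6e6)

    def test_saturated_occupancy_rejected(self):
        with pytest.raises(ValueError):
            occupancy_to_binding(1.0, 0.033, 1e-8)
        with pytest.raises(ValueError):
            occupancy_to_binding(0.5, 0.033, 0.0)

    @pytest.mark.parametrize("gain, sig_figs, expected",
                             [(33.5, 2, 0.56), (60.0, 2, 1.0), (22.0, None, 22 / 60)])
    def test_high_rate_from_max_gain(self, gain, sig_figs, expected):
        assert estimate_high_rate(gain, sig_figs=sig_figs) == pytest.approx(expected)

    def test_high_rate_requires_positive_gain(self):
        with pytest.raises(ValueError):
            estimate_high_rate(0.0)

    def test_termination_rate_and_round_trip(self):
        k = termination_rate(4.2)
        assert k == pytest.approx(3.97e-3, abs=5e-6)
        assert termination_rate(1.0) == pytest.approx(1 / 60)
        assert 1.0 / (60.0 * k) == pytest.approx(4.2)
        with pytest.raises(ValueError):
            termination_rate(-1.0)


class TestActivationSolve:
    def test_default_features_reproduce_printed_rates(self):
        act = solve_activation_rates(DataFeatures(), k_1100=0.56, p_B=0.55,
                                     k_unbind=0.033, conc_h=2.9421e-8)
        assert act.p_H == pytest.approx(0.138, abs=0.001)
        assert act.k_1000 == pytest.approx(0.09, abs=0.001)
        assert act.k_bind_h == pytest.approx(1.8e5, rel=0.01)

    def test_equal_split_balances_the_two_pathways(self):
        feats = DataFeatures(mean_total_transcripts=200.0,
                             mean_low_pathway_transcripts=100.0)
        act = solve_activation_rates(feats, k_1100=0.4, p_B=0.5, k_unbind=0.033,
                                     conc_h=1e-8)
        # LOW and HIGH pathway fluxes are equal by construction
        assert act.k_1000 * (1 - act.p_H) == pytest.approx(0.4 * act.p_H)

    def test_infeasible_targets_rejected(self):
        feats = DataFeatures(mean_total_transcripts=2000.0,
                             mean_low_pathway_transcripts=115.0)
        with pytest.raises(ValueError):
            solve_activation_rates(feats, k_1100=0.56, p_B=0.55, k_unbind=0.033,
                                   conc_h=1e-8)


class TestFullEstimation:
    def test_reproduces_all_printed_constants(self, calibration):
        r = calibration.rates
        assert r.k_bind_b == pytest.approx(2.6e6, rel=1e-6)
        assert r.k_bind_h == pytest.approx(1.8e5, rel=1e-6)
        assert r.k_bind_k == pytest.approx(9.9e6)
        assert r.k_bind_g == pytest.approx(1.98e7)
        assert r.k_unbind_b == 0.033
        assert r.k_1000 == pytest.approx(0.09, abs=5e-4)
        assert r.k_1100 == 0.56
        assert r.k_T == pytest.approx(3.97e-3, abs=5e-6)

    def test_calibrated_set_reproduces_mean_total_within_one_percent(
            self, calibration, center_conc):
        traj = solve_nucleus_ode(center_conc, calibration.rates, duration=2700,
                                 step=0.1, record_every=2700.0)
        assert traj.final["m_prod"] == pytest.approx(230.0, rel=0.01)

    def test_variation_features_recalibrate_consistently(self, profiles):
        feats = DataFeatures(mean_total_transcripts=245.0,
                             mean_low_pathway_transcripts=122.5)
        rep = run_full_estimation(feats, profiles)
        conc = profiles.conc_at(42, time_varying=False)
        traj = solve_nucleus_ode(conc, rep.rates, duration=2700, step=0.1,
                                 record_every=2700.0)
        assert traj.final["m_prod"] == pytest.approx(245.0, rel=0.01)

    def test_report_serializes(self, calibration, tmp_path):
        calibration.to_json(tmp_path / "report.json")
        text = calibration.render()
        assert "k_bind_b" in text and "step 6" in text


class TestUnbindingScan:
    def test_printed_value_feasible_and_frozen_switching_rejected(
            self, profiles, rates):
        conc = profiles.conc_at(42, time_varying=False)
        scan = constrain_unbinding([1e-4, 0.033], DataFeatures(), conc, rates,
                                   n_replicates=10, base_seed=3)
        feas = dict(zip(scan.candidates, scan.feasible))
        assert feas[0.033]
        assert not feas[1e-4]  # near-frozen states: persistent, often silent
        assert scan.selected == pytest.approx(0.033)
        # the slow candidate fails the change-autocorrelation condition
        assert scan.frac_pass_change[0] < 0.5

    def test_empty_feasible_set_reported_not_raised(self, profiles, rates):
        conc = profiles.conc_at(42, time_varying=False)
        scan = constrain_unbinding([1e-5], DataFeatures(), conc, rates,
                                   n_replicates=4, base_seed=1)
        assert scan.selected is None
        assert not scan.feasible.any()


class TestRepressorFit:
    def test_recovers_constants_from_self_consistent_target(self, profiles, rates):
        target = spatial_profile(profiles, rates, times=(300.0, 1200.0, 2700.0),
                                 step=1.0, positions=range(35, 48))
        fit = fit_repressor_binding(target[["position_el", "time_s", "m_prod"]],
                                    profiles, rates.replace(k_bind_k=1e6,
                                                            k_bind_g=1e6))
        assert fit.identifiable
        assert fit.k_bind_k == pytest.approx(9.9e6, rel=0.05)
        assert fit.k_bind_g == pytest.approx(1.98e7, rel=0.05)

    def test_flat_target_reported_unidentifiable(self, profiles, rates):
        import pandas as pd

        target = pd.DataFrame({
            "position_el": list(range(35, 48)) * 2,
            "time_s": [1200.0] * 13 + [2700.0] * 13,
            "m_prod": [100.0] * 26,
        })
        fit = fit_repressor_binding(target, profiles, rates)
        assert not fit.identifiable

    def test_only_the_product_of_binding_and_concentration_is_identifiable(
            self, profiles, rates):
        """Doubling repressor concentrations with halved constants: same profile."""
        import dataclasses

        doubled = dataclasses.replace(
            profiles,
            conc0={k: (2 * v if k in ("kr", "gt") else v.copy())
                   for k, v in profiles.conc0.items()})
        halved = rates.replace(k_bind_k=rates.k_bind_k / 2,
                               k_bind_g=rates.k_bind_g / 2)
        a = spatial_profile(profiles, rates, times=(2700.0,), step=1.0)
        b = spatial_profile(doubled, halved, times=(2700.0,), step=1.0)
        np.testing.assert_allclose(a.m_prod, b.m_prod, rtol=1e-12)


class TestRoundTrips:
    def test_concentration_scale_invariance_is_exact(self, rates, center_conc):
        """Scaling all concentrations and inversely scaling binding constants
        leaves seed-matched trajectories bit-identical."""
        import dataclasses

        c = 3.7
        scaled_conc = dataclasses.replace(center_conc, bcd=center_conc.bcd * c,
                                          hb=center_conc.hb * c)
        scaled_rates = rates.replace(k_bind_b=rates.k_bind_b / c,
                                     k_bind_h=rates.k_bind_h / c,
                                     k_bind_k=rates.k_bind_k / c,
                                     k_bind_g=rates.k_bind_g / c)
        a = simulate_nucleus(center_conc, rates, duration=2700, seed=99)
        b = simulate_nucleus(scaled_conc, scaled_rates, duration=2700, seed=99)
        np.testing.assert_array_equal(a.event_times, b.event_times)
        np.testing.assert_array_equal(a.state_index, b.state_index)

    def test_recalibration_on_simulated_features_recovers_rates(
            self, profiles, calibration, center_conc):
        """Simulate -> extract features -> re-estimate -> recover the rates.

        Occupancy is read as the Bcd-bound dwell fraction and the HIGH rate
        from the pooled maximum per-minute gain; tolerances reflect the
        sampling spread of those estimators at 60 replicates.
        """
        rates = calibration.rates
        trajs = [simulate_nucleus(center_conc, rates, duration=2700,
                                  seed=(31, "rt", r)) for r in range(60)]
        total = np.mean([t.total_initiations for t in trajs])
        low = np.mean([np.sum((t.event_labels == "initiate") & (t.state_index == 8))
                       for t in trajs])
        p_b = np.mean([t.bcd_bound_fraction() for t in trajs])
        max_gain = max(
            per_minute_change(regularize(*extract_minute_series(t))).rate.max()
            for t in trajs)
        feats = DataFeatures(positive_change_fraction=float(p_b),
                             max_gain_per_minute=float(max_gain),
                             mean_total_transcripts=float(total),
                             mean_low_pathway_transcripts=float(low))
        rec = run_full_estimation(feats, profiles, high_rate_sig_figs=None)
        assert rec.rates.k_1000 == pytest.approx(rates.k_1000, rel=0.10)
        assert rec.rates.k_1100 == pytest.approx(rates.k_1100, rel=0.30)
        assert rec.p_H == pytest.approx(calibration.p_H, rel=0.30)
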