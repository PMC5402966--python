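"""Stochastic simulator: exactness against analytic oracles, reproducibility."""

import numpy as np
import pytest
from scipy import stats as sps

from eve2sim import (
    RateSet,
    TFConcentration,
    extract_minute_series,
    simulate_nucleus,
    simulate_stripe,
    solve_nucleus_ode,
    stationary_occupancy,
)


class TestDeterminism:
    def test_same_seed_is_bit_identical(self, rates, center_conc):
        a = simulate_nucleus(center_conc, rates, duration=1800, seed=42)
        b = simulate_nucleus(center_conc, rates, duration=1800, seed=42)
        np.testing.assert_array_equal(a.event_times, b.event_times)
        np.testing.assert_array_equal(a.nascent, b.nascent)

    def test_different_replicate_keys_differ(self, rates, center_conc):
        a = simulate_nucleus(center_conc, rates, duration=1800, seed=(1, 42, 0))
        b = simulate_nucleus(center_conc, rates, duration=1800, seed=(1, 42, 1))
        assert a.n_events != b.n_events or not np.array_equal(a.event_times,
                                                              b.event_times)

    def test_stripe_ensemble_reproducible(self, profiles, rates):
        kw = dict(duration=600, n_replicates=2, base_seed=7, positions=[40, 42])
        e1 = simulate_stripe(profiles, rates, **kw)
        e2 = simulate_stripe(profiles, rates, **kw)
        for key in e1.trajectories:
            np.testing.assert_array_equal(e1.trajectories[key].event_times,
                                          e2.trajectories[key].event_times)


class TestTrajectoryInvariants:
    def test_zero_rates_give_empty_event_log(self):
        zero = RateSet(**{f: 0.0 for f in (
            "k_bind_b", "k_bind_h", "k_bind_k", "k_bind_g",
            "k_unbind_b", "k_unbind_h", "k_unbind_k", "k_unbind_g",
            "k_1000", "k_1100", "k_T")})
        traj = simulate_nucleus(TFConcentration(), zero, duration=600, seed=0)
        assert traj.n_events == 0

    def test_nascent_equals_initiations_minus_terminations(self, rates, center_conc):
        traj = simulate_nucleus(center_conc, rates, duration=2700, seed=3)
        np.testing.assert_array_equal(traj.nascent, traj.cum_init - traj.cum_term)
        assert np.all(traj.nascent >= 0)
        assert np.all(np.diff(traj.event_times) >= 0)

    def test_dwell_times_sum_to_duration(self, rates, center_conc):
        traj = simulate_nucleus(center_conc, rates, duration=2700, seed=4)
        assert traj.dwell_seconds().sum() == pytest.approx(2700.0)


class TestAgreementWithAnalyticOracles:
    def test_replicate_mean_matches_ode_within_three_se(self, rates, center_conc):
        n = 200
        totals = [simulate_nucleus(center_conc, rates, duration=2700,
                                   seed=(11, "mean", r)).total_initiations
                  for r in range(n)]
        ode = solve_nucleus_ode(center_conc, rates, duration=2700, step=0.5,
                                record_every=2700.0).final["m_prod"]
        se = np.std(totals, ddof=1) / np.sqrt(n)
        assert abs(np.mean(totals) - ode) < 3 * se

    def test_output_is_super_poissonian_from_slow_switching(self, rates, center_conc):
        totals = [simulate_nucleus(center_conc, rates, duration=2700,
                                   seed=(11, "mean", r)).total_initiations
                  for r in range(200)]
        assert np.var(totals, ddof=1) > np.mean(totals)

    def test_bcd_bound_dwell_matches_stationary_occupancy(self, rates, center_conc):
        fracs = [simulate_nucleus(center_conc, rates, duration=2700,
                                  seed=(5, "dwell", r)).bcd_bound_fraction()
                 for r in range(10)]
        assert np.mean(fracs) == pytest.approx(0.55, abs=0.03)

    def test_long_run_state_distribution_not_rejected(self, rates, center_conc):
        """Chi-squared GOF of sampled states against the product-form law."""
        traj = simulate_nucleus(center_conc, rates, duration=2e5, seed=11)
        occ = stationary_occupancy(center_conc, rates)
        # sample every 5 minutes (>> mixing time ~30 s) for near-independence
        states = traj.state_at(np.arange(300.0, 2e5, 300.0))
        expected = occ.probabilities * len(states)
        keep = expected > 5
        observed = np.bincount(states, minlength=16)
        res = sps.chisquare(observed[keep],
                            expected[keep] / expected[keep].sum() * observed[keep].sum())
        assert res.pvalue > 0.01


@pytest.fixture(scope="module")
def halved(rates):
    return rates.replace(n_copies=2, k_1000=rates.k_1000 / 2, k_1100=rates.k_1100 / 2)


class TestTwoCopyTranscription:
    def test_summed_mean_output_matches_single_copy(self, rates, halved, center_conc):
        n = 100
        one = [simulate_nucleus(center_conc, rates, duration=2700,
                                seed=(21, "1c", r)).total_initiations for r in range(n)]
        two = [simulate_nucleus(center_conc, halved, duration=2700,
                                seed=(21, "2c", r)).total_initiations for r in range(n)]
        se = np.sqrt(np.var(one, ddof=1) / n + np.var(two, ddof=1) / n)
        assert abs(np.mean(one) - np.mean(two)) < 3 * se

    def test_two_copies_narrow_the_change_distribution(self, rates, halved,
                                                       center_conc):
        from eve2sim.stats import per_minute_change, regularize

        def pooled_change_var(rr, tag):
            chunks = []
            for r in range(10):
                traj = simulate_nucleus(center_conc, rr, duration=2700,
                                        seed=(22, tag, r))
                t, c = extract_minute_series(traj)
                chunks.append(per_minute_change(regularize(t, c)).rate)
            return np.var(np.concatenate(chunks))

        assert pooled_change_var(halved, "2c") < pooled_change_var(rates, "1c")

    def test_merged_log_sums_copies(self, rates, halved, center_conc):
        traj = simulate_nucleus(center_conc, halved, duration=900, seed=8)
        assert len(traj.copies) == 2
        t = np.linspace(0, 900, 30)
        np.testing.assert_array_equal(
            traj.nascent_at(t),
            traj.copies[0].nascent_at(t) + traj.copies[1].nascent_at(t))


class TestStripeSimulation:
    def test_anterior_extends_further_than_posterior(self, profiles, rates):
        ens = simulate_stripe(profiles, rates, duration=2700, n_replicates=5,
                              base_seed=9, positions=[37, 47])
        wins = sum(ens.trajectories[(37, r)].total_initiations
                   > ens.trajectories[(47, r)].total_initiations for r in range(5))
        assert wins > 2.5  # majority of replicates

    def test_replicate_count_validated(self, profiles, rates):
        with pytest.raises(ValueError):
            simulate_stripe(profiles, rates, n_replicates=0)

    def test_unevenness_across_positions(self, profiles, rates):
        ens = simulate_stripe(profiles, rates, duration=2700, n_replicates=1,
                              base_seed=2, positions=[40, 41, 42, 43, 44])
        prof = ens.accumulated_profile().set_index("position_el").m_prod
        assert prof.std() > 0


class TestMinuteSampling:
    def test_regular_sampling_of_45_minutes_gives_46_points(self, rates, center_conc):
        traj = simulate_nucleus(center_conc, rates, duration=2700, seed=1)
        times, counts = extract_minute_series(traj)
        assert len(times) == 46
        assert times[0] == 0.0 and times[-1] == 2700.0

    def test_constant_trajectory_samples_constant(self):
        zero = RateSet(**{f: 0.0 for f in (
            "k_bind_b", "k_bind_h", "k_bind_k", "k_bind_g",
            "k_unbind_b", "k_unbind_h", "k_unbind_k", "k_unbind_g",
            "k_1000", "k_1100", "k_T")})
        traj = simulate_nucleus(TFConcentration(), zero, duration=600, seed=0)
        _, counts = extract_minute_series(traj)
        assert np.all(counts == 0)

    def test_irregular_scheme_is_seeded_and_roughly_per_minute(self, rates,
                                                               center_conc):
        traj = simulate_nucleus(center_conc, rates, duration=2700, seed=1)
        t1, c1 = extract_minute_series(traj, scheme="irregular", seed=5)
        t2, c2 = extract_minute_series(traj, scheme="irregular", seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(c1, c2)
        gaps = np.diff(t1)
        assert gaps.min() >= 20.0
        assert 30 <= len(t1) <= 70  # ~1-minute cadence over 45 minutes

    def test_irregular_then_regularize_round_trip(self, rates, center_conc):
        from eve2sim.stats import regularize

        traj = simulate_nucleus(center_conc, rates, duration=2700, seed=1)
        t, c = extract_minute_series(traj, scheme="irregular", seed=5)
        ms = regularize(t, c)
        assert len(ms.minute) <= 46

    def test_unknown_scheme_rejected(self, rates, center_conc):
        traj = simulate_nucleus(center_conc, rates, duration=600, seed=1)
        with pytest.raises(ValueError):
            extract_minute_series(traj, scheme="hourly")
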