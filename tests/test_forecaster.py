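"""Rejection-sampling trajectory reconstruction under empirical constraints."""

import numpy as np
import pytest

from poolsel import forecaster as fc, hw, synthetic_data as sd
from poolsel.forecaster import (
    EmpiricalConstraints,
    check_constraints,
    constraints_from_tables,
    forecast_locus,
    n_simulation_records,
    summarize_ensemble,
    verify_ensemble,
)

DAYS = (2, 6, 10, 14, 22)


def truth_constraints(truth, locus, tolerance=0.10):
    idx = [list(truth.days).index(d) for d in DAYS]
    return EmpiricalConstraints(
        days=DAYS, maf=truth.maf[locus, idx], survival=truth.survival[locus, idx],
        tolerance=tolerance,
    ), idx


class TestCheckConstraints:
    def _cons(self, maf, surv, tol=0.10):
        return EmpiricalConstraints(days=(2, 6), maf=[maf, maf], survival=[surv, surv / 2], tolerance=tol)

    def test_maf_deviation_beyond_tolerance_rejected(self):
        ok, reason = check_constraints(0.30, 0.50, self._cons(0.45, 0.50), 0)
        assert not ok and reason == "maf"

    def test_survival_checked_on_relative_scale(self):
        # |0.50 - 0.52| / 0.52 = 0.038 < 0.10: passes
        ok, _ = check_constraints(0.45, 0.50, self._cons(0.45, 0.52), 0)
        assert ok
        ok, reason = check_constraints(0.45, 0.40, self._cons(0.45, 0.52), 0)
        assert not ok and reason == "survival"

    def test_vacuous_tolerance_accepts_everything(self):
        cons = self._cons(0.45, 0.5, tol=1.0)
        assert check_constraints(0.99, 0.01, cons, 0)[0]

    def test_zero_survival_constraint_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            EmpiricalConstraints(days=(2, 6), maf=[0.3, 0.3], survival=[0.5, 0.0])

    def test_increasing_survival_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            EmpiricalConstraints(days=(2, 6), maf=[0.3, 0.3], survival=[0.4, 0.5])


class TestForecastLocus:
    def test_vacuous_tolerance_accepts_first_draw_every_interval(self):
        cons = EmpiricalConstraints(days=DAYS, maf=[0.3] * 5, survival=[0.5, 0.4, 0.3, 0.2, 0.04],
                                    tolerance=1.0, survival_mode="absolute")
        ens = forecast_locus(hw.hwe_expected(0.3), cons, n_accept=10, seed=0)
        assert ens.n_accepted == 10
        assert ens.attempts == 10 * len(DAYS)  # one draw per interval per trajectory
        assert ens.restarts == 0

    def test_accepted_trajectories_satisfy_constraints_posthoc(self):
        truth = sd.simulate_truth(sd.make_scenario("balanced", n_loci=5, seed=21))
        for i in range(5):
            cons, _ = truth_constraints(truth, i)
            ens = forecast_locus(truth.states[i, 0], cons, n_accept=20, seed=100 + i)
            assert ens.n_accepted == 20
            assert verify_ensemble(ens, cons)

    def test_states_on_simplex_and_maf_consistent_throughout(self):
        truth = sd.simulate_truth(sd.make_scenario("directional", n_loci=3, seed=22))
        cons, _ = truth_constraints(truth, 0)
        ens = forecast_locus(truth.states[0, 0], cons, n_accept=15, seed=7)
        np.testing.assert_allclose(ens.states.sum(axis=2), 1.0, atol=1e-9)
        assert np.all(ens.states >= 0)
        implied = ens.states[:, :, 1] / 2 + ens.states[:, :, 2]
        np.testing.assert_allclose(ens.maf(), implied, atol=1e-9)

    def test_deterministic_given_seed(self):
        truth = sd.simulate_truth(sd.make_scenario("neutral", n_loci=2, seed=23))
        cons, _ = truth_constraints(truth, 0)
        e1 = forecast_locus(truth.states[0, 0], cons, n_accept=8, seed=99)
        e2 = forecast_locus(truth.states[0, 0], cons, n_accept=8, seed=99)
        np.testing.assert_array_equal(e1.states, e2.states)
        np.testing.assert_array_equal(e1.fitness, e2.fitness)

    def test_infeasible_constraints_return_partial_ensemble_not_hang(self):
        # MAF leaps 0.05 -> 0.95 in one interval: unreachable under any viabilities
        # from a state with f_BB tiny relative to the required jump at this tolerance
        cons = EmpiricalConstraints(days=(2, 6), maf=[0.05, 0.95], survival=[0.5, 0.25],
                                    tolerance=0.01)
        ens = forecast_locus(hw.hwe_expected(0.05), cons, n_accept=5,
                             max_attempts_per_interval=200, max_restarts=10, seed=1)
        assert ens.infeasible
        assert ens.n_accepted < 5
        assert ens.diagnostics["restarts"] >= 10

    def test_shrinking_tolerance_with_unit_survival_approaches_neutral_fitness(self):
        # survival consistent with w_bar = 1: viabilities are capped at 1, so a
        # mean fitness within tol of 1 bounds every genotype's viability below
        # by 1 - tol/f_g; as the tolerance shrinks the accepted vectors are
        # squeezed toward equal (neutral) components
        spreads = {}
        for tol in (0.4, 0.2):
            cons = EmpiricalConstraints(days=(2, 6), maf=[0.5, 0.5], survival=[1.0, 1.0],
                                        tolerance=tol)
            ens = forecast_locus(hw.hwe_expected(0.5), cons, n_accept=10, seed=3,
                                 max_attempts_per_interval=200_000)
            assert ens.n_accepted == 10
            # hard bound: total survival deficit <= tol caps each 1 - w_g at tol/f_g
            assert ens.fitness[:, :, 1].min() >= 1 - tol / 0.4 - 1e-9
            np.testing.assert_allclose(ens.maf()[:, 1:], 0.5, atol=tol + 1e-12)
            spreads[tol] = float((ens.fitness.max(axis=2) - ens.fitness.min(axis=2)).mean())
        assert spreads[0.2] < spreads[0.4]


class TestSummaries:
    def test_bookkeeping_of_simulation_records(self):
        assert n_simulation_records(473, 50, 6) == 141_900

    def test_identical_trajectories_have_zero_width_intervals(self):
        cons = EmpiricalConstraints(days=(2, 6), maf=[0.3, 0.3], survival=[0.5, 0.25], tolerance=1.0)
        ens = forecast_locus(hw.hwe_expected(0.3), cons, n_accept=4, seed=5)
        ens.states[:] = ens.states[0]
        ens.fitness[:] = ens.fitness[0]
        ens.survival[:] = ens.survival[0]
        summary = summarize_ensemble(ens)
        for g in ("AA", "AB", "BB"):
            np.testing.assert_allclose(summary[f"f_{g}_lo"], summary[f"f_{g}_hi"], atol=1e-12)

    def test_mean_of_two_trajectories(self):
        cons = EmpiricalConstraints(days=(2, 6), maf=[0.3, 0.3], survival=[0.5, 0.25], tolerance=1.0)
        ens = forecast_locus(hw.hwe_expected(0.3), cons, n_accept=2, seed=6)
        ens.states[0, 1, 1], ens.states[1, 1, 1] = 0.4, 0.6
        summary = summarize_ensemble(ens)
        assert summary.loc[summary["day"] == 2, "f_AB"].iloc[0] == pytest.approx(0.5)

    def test_singleton_ensemble_rejected(self):
        cons = EmpiricalConstraints(days=(2, 6), maf=[0.3, 0.3], survival=[0.5, 0.25], tolerance=1.0)
        ens = forecast_locus(hw.hwe_expected(0.3), cons, n_accept=1, seed=7)
        with pytest.raises(ValueError):
            summarize_ensemble(ens)


class TestRecoveryProperties:
    def test_directional_truth_recovers_fitness_ordering(self):
        """With w_AA >> w_BB at every interval, the reconstruction should rank
        the homozygote viabilities correctly for nearly all loci."""
        sc = sd.make_scenario("directional", n_loci=20, seed=31, effect_range=(0.25, 0.3),
                              maf_range=(0.35, 0.5))
        truth = sd.simulate_truth(sc)
        good_early, good_overall = 0, 0
        for i in range(20):
            cons, _ = truth_constraints(truth, i)
            ens = forecast_locus(truth.states[i, 0], cons, n_accept=30, seed=500 + i)
            w_mean = ens.fitness.mean(axis=0)  # (n_intervals, 3)
            diff = w_mean[:, 0] - w_mean[:, 2]
            # the homozygote ordering is identifiable while the minor allele is
            # still common; by the last interval selection has made it rare and
            # w_BB reverts toward the proposal prior, so that interval is excluded
            good_early += bool(np.all(diff[:-1] > 0))
            good_overall += bool(diff.mean() > 0)
        assert good_early >= 18  # >= 90% of loci
        assert good_overall >= 18

    def test_neutral_truth_gives_no_homozygote_asymmetry(self):
        """Under neutrality at q = 0.5 the problem is symmetric in the two
        homozygotes, so their reconstructed mean viabilities must agree.
        (The heterozygote viability is NOT recovered as equal: the accepted
        set's geometry under uniform proposals inflates weakly-constrained
        components; see the methods note.)"""
        sc = sd.make_scenario("neutral", n_loci=50, seed=32, maf_range=(0.5, 0.5))
        truth = sd.simulate_truth(sc)
        means = []
        for i in range(50):
            cons, _ = truth_constraints(truth, i)
            ens = forecast_locus(truth.states[i, 0], cons, n_accept=20, seed=700 + i)
            means.append(ens.fitness.mean(axis=0))
        w_bar = np.mean(means, axis=0)  # (n_intervals, 3)
        assert np.all(np.abs(w_bar[:, 0] - w_bar[:, 2]) < 0.05)

    def test_constraints_from_tables_roundtrip(self):
        import pandas as pd

        maf = pd.Series({0: 0.3, 2: 0.31, 6: 0.29, 10: 0.30, 14: 0.32, 22: 0.28})
        surv = pd.Series({0: 1.0, 2: 0.5, 6: 0.4, 10: 0.3, 14: 0.2, 22: 0.04})
        cons = constraints_from_tables(maf, surv, days=DAYS, tolerance=0.1)
        assert cons.days == DAYS
        np.testing.assert_allclose(cons.maf, [0.31, 0.29, 0.30, 0.32, 0.28])
        np.testing.assert_allclose(cons.survival, [0.5, 0.4, 0.3, 0.2, 0.04])
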