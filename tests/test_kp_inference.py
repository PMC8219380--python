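"""Annealed Metropolis-Hastings fitting of the KP potency model."""

import math

import numpy as np
import pytest
from scipy import stats

from tcrpower import kp_inference as ki, synthetic
from tcrpower.kp_inference import (AnnealSchedule, distance, fit_ensemble,
                                   make_priors, mh_step, perturb,
                                   potency_data_from_table, run_chain,
                                   synthetic_schedule)


def truth_vector(truth):
    """Ground truth on the fitting scale (linear N, log10 elsewhere)."""
    return np.concatenate([
        [truth.N, math.log10(truth.gamma), math.log10(truth.delta_hat)],
        np.log10(truth.kp), np.log10(truth.lambda_hat)])


class TestPriors:
    @pytest.mark.parametrize("n_exp, expected", [(12, 27), (17, 37), (1, 5)])
    def test_parameter_counts(self, n_exp, expected):
        assert make_priors(n_exp).n_params == expected

    def test_sample_within_bounds(self, rng):
        priors = make_priors(3, "cell")
        for _ in range(100):
            th = priors.sample(rng)
            assert np.all(th >= priors.lo) and np.all(th <= priors.hi)

    def test_cell_lambda_hat_prior_differs(self):
        plate, cell = make_priors(2, "plate"), make_priors(2, "cell")
        assert plate.lo[-1] == -4.0 and plate.hi[-1] == 1.0
        assert cell.lo[-1] == -6.0 and cell.hi[-1] == -3.0


class TestDistance:
    def test_zero_at_truth_for_noiseless_data(self):
        truth = synthetic.default_kp_truth(3, seed=8, sigma_log=0.0)
        table, _ = synthetic.generate_kp_potency_dataset(truth, seed=9)
        data = potency_data_from_table(table)
        assert distance(truth_vector(truth), data) == pytest.approx(0.0, abs=1e-18)

    def test_single_point_residual(self):
        truth = synthetic.KPGroundTruth(kd_panels=((10.0,),), sigma_log=0.0)
        table, _ = synthetic.generate_kp_potency_dataset(truth, seed=0)
        table["potency"] *= 10.0 ** 0.5  # shift by 0.5 log10 units
        data = potency_data_from_table(table)
        assert distance(truth_vector(truth), data) == pytest.approx(0.25, rel=1e-9)

    def test_manual_two_experiment_oracle(self):
        """Hand-computed distance for a 2-experiment, 2-point table."""
        n, gamma, delta_hat = 2.0, 1e-5, 1e-6
        kps, lams = [1.0, 2.0], [0.1, 0.05]
        kon = 0.0447
        kds = [10.0, 100.0]
        pots = [1.0, 30.0]  # same observed potencies in both experiments
        expected = 0.0
        for kp, lam in zip(kps, lams):
            for kd, pot in zip(kds, pots):
                b = (1 + kon * kd / kp) ** n
                rho = (math.log10(lam) + n * math.log10(1 + kon * kd / kp)
                       + math.log10(1 - delta_hat * kd / (lam * b - 1 / gamma)))
                expected += (rho - math.log10(pot)) ** 2
        rows = []
        for i in range(2):
            for kd, pot in zip(kds, pots):
                rows.append({"study_id": "s", "experiment_id": f"E{i}",
                             "ligand_id": "x", "kd_uM": kd, "potency": pot,
                             "readout": "r", "flag": ""})
        import pandas as pd
        data = potency_data_from_table(pd.DataFrame(rows))
        theta = np.array([n, math.log10(gamma), math.log10(delta_hat),
                          math.log10(kps[0]), math.log10(kps[1]),
                          math.log10(lams[0]), math.log10(lams[1])])
        assert distance(theta, data) == pytest.approx(expected, rel=1e-12)

    def test_unreachable_point_gives_infinite_distance(self):
        truth = synthetic.KPGroundTruth(kd_panels=((1500.0,),), sigma_log=0.0)
        table, _ = synthetic.generate_kp_potency_dataset(truth, seed=0)
        data = potency_data_from_table(table)
        theta = truth_vector(truth)
        theta[0] = 4.0       # many steps
        theta[1] = -4.0      # large gamma
        theta[3] = -1.0      # slow kp
        theta[4] = 1.0       # huge lambda_hat -> threshold unreachable
        assert np.isinf(distance(theta, data))


class TestPerturb:
    def test_shift_range_and_reflection_at_bound(self):
        priors = make_priors(1)
        seed = 42
        theta = priors.hi.copy()  # start exactly at the upper bounds
        cand = perturb(theta, priors, np.random.RandomState(seed))
        rs = np.random.RandomState(seed)
        for k in range(priors.n_params):
            shift = rs.uniform(-0.005, 0.005) * (priors.hi[k] - priors.lo[k])
            expected = priors.hi[k] - shift if shift > 0 else priors.hi[k] + shift
            assert cand[k] == pytest.approx(expected, abs=1e-15)

    def test_n_shift_is_half_percent_of_prior_width(self):
        # N prior (0, 4): shift range +/- 0.02
        priors = make_priors(1)
        rng = np.random.RandomState(0)
        theta = 0.5 * (priors.lo + priors.hi)
        shifts = np.array([perturb(theta, priors, rng)[0] - theta[0]
                           for _ in range(20_000)])
        assert np.abs(shifts).max() <= 0.02
        assert np.abs(shifts).max() > 0.0195  # range is actually reached
        ks = stats.kstest(shifts, stats.uniform(-0.02, 0.04).cdf)
        assert ks.pvalue > 0.01

    def test_stays_within_bounds(self, rng):
        priors = make_priors(2)
        theta = priors.lo + 1e-6
        for _ in range(500):
            theta = perturb(theta, priors, rng)
            assert np.all(theta >= priors.lo) and np.all(theta <= priors.hi)


class TestMHStep:
    def test_improvement_always_accepted(self, rng):
        assert mh_step(5.0, 4.0, 0.001, rng)

    def test_acceptance_probability_at_delta_equal_xi(self):
        rng = np.random.RandomState(77)
        n, trials = 0, 100_000
        for _ in range(trials):
            n += mh_step(1.0, 1.0 + 0.3, 0.3, rng)
        p_hat = n / trials
        p_true = math.exp(-1.0)
        assert abs(p_hat - p_true) < 3 * math.sqrt(p_true * (1 - p_true) / trials)

    def test_greedy_limit_never_accepts(self, rng):
        assert not any(mh_step(1.0, 1.5, 1e-12, rng) for _ in range(1000))


class TestSchedules:
    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            AnnealSchedule(10.0, np.array([50.0, 60.0]), np.array([1.0, 0.1]), 1.0)
        with pytest.raises(ValueError):
            AnnealSchedule(10.0, np.array([50.0, 30.0]), np.array([0.1, 1.0]), 1.0)

    def test_synthetic_schedule_scales_with_noise(self):
        s = synthetic_schedule(n_points=96, sigma_log=0.1)
        assert s.termination == pytest.approx(96 * 0.01 * 1.2)
        assert np.all(np.diff(s.thresholds) < 0)
        assert s.thresholds[0] / s.termination == pytest.approx(50.0 / 11.08)


class TestRunChain:
    def test_same_seed_identical_trajectory(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = synthetic_schedule(data.n_points, 0.1, max_steps=2000)
        a = run_chain(data, priors, sched, seed=5)
        b = run_chain(data, priors, sched, seed=5)
        assert np.array_equal(a.theta, b.theta) and a.steps == b.steps

    def test_python_and_numba_engines_agree_exactly(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = synthetic_schedule(data.n_points, 0.1, max_steps=1500)
        a = run_chain(data, priors, sched, seed=11, engine="numba")
        b = run_chain(data, priors, sched, seed=11, engine="python")
        assert np.array_equal(a.theta, b.theta)
        assert a.distance == b.distance and a.steps == b.steps

    def test_loose_termination_returns_immediately(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = AnnealSchedule(10.0, np.array([50.0]), np.array([1.0]),
                               termination=1e9)
        res = run_chain(data, priors, sched, seed=1)
        assert res.converged and res.steps == 0

    def test_converges_on_noiseless_data(self):
        truth = synthetic.default_kp_truth(2, seed=5, sigma_log=0.0)
        table, _ = synthetic.generate_kp_potency_dataset(truth, seed=6)
        data = potency_data_from_table(table)
        priors = make_priors(2)
        sched = synthetic_schedule(data.n_points, 0.02, max_steps=2_000_000)
        res = run_chain(data, priors, sched, seed=2)
        assert res.converged
        assert res.distance < sched.termination


class TestFitEnsemble:
    def test_determinism_and_summary_shape(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = synthetic_schedule(data.n_points, 0.1, max_steps=500_000)
        e1 = fit_ensemble(data, priors, sched, n_chains=4, seed=9)
        e2 = fit_ensemble(data, priors, sched, n_chains=4, seed=9)
        assert e1.table.equals(e2.table)
        s = e1.summary()
        assert s["n_chains"] + s["n_failed"] == 4
        assert set(s) >= {"N", "kp", "tau_kp", "distance"}
        assert len(s["kp"]["per_experiment_median"]) == 2
        # tau_KP = N / kp per chain and experiment
        row = e1.table.iloc[0]
        assert s["tau_kp"]["per_experiment_median"][0] > 0
        assert row["N"] / row["kp_1"] == pytest.approx(
            (e1.table["N"] / e1.table["kp_1"]).iloc[0])

    def test_all_chains_failing_raises(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = AnnealSchedule(10.0, np.array([50.0]), np.array([1.0]),
                               termination=1e-12, max_steps=50)
        with pytest.raises(RuntimeError, match="all chains failed"):
            fit_ensemble(data, priors, sched, n_chains=3, seed=0)

    def test_ensemble_members_satisfy_invariants(self, small_kp_dataset):
        _, _, data = small_kp_dataset
        priors = make_priors(data.n_experiments)
        sched = synthetic_schedule(data.n_points, 0.1, max_steps=500_000)
        ens = fit_ensemble(data, priors, sched, n_chains=4, seed=9)
        assert (ens.table["D"] < sched.termination).all()
        assert ens.table["N"].between(priors.lo[0], priors.hi[0]).all()
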