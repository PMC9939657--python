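import numpy as np
import pytest

import hergfit as hf
from hergfit.errors import SamplerError
from hergfit.inference import INFEASIBLE_OBJECTIVE


@pytest.fixture(scope="module")
def cell(staircase):
    """One physiological synthetic cell: (truth, clean trace, noisy trace)."""
    theta = hf.sample_cell_params(1, seed=21)[0]
    clean = hf.simulate_current(theta, staircase, 100.0)
    noisy = hf.add_noise(clean, hf.NoiseModel(), seed=4)
    return theta, clean, noisy


class TestObjective:
    def test_zero_at_truth_noiseless(self, cell, staircase):
        theta, clean, _ = cell
        assert hf.objective_rmse(theta, clean, staircase) < 1e-3

    def test_noise_floor_at_truth(self, cell, staircase):
        theta, _, noisy = cell
        assert hf.objective_rmse(theta, noisy, staircase) == pytest.approx(10.84, rel=0.05)

    def test_tiny_conductance_gives_target_rms(self, cell, staircase):
        theta, clean, _ = cell
        off = theta.as_array().copy()
        off[0] = 1e-9  # essentially closed channel
        rmse = hf.objective_rmse(hf.ChannelParams.from_array(off), clean, staircase)
        assert rmse == pytest.approx(np.sqrt(np.mean(clean.values ** 2)), rel=1e-4)

    def test_factor_decimation_consistent(self, cell, staircase):
        theta, clean, _ = cell
        fine = hf.simulate_current(theta, staircase, 500.0)
        assert hf.objective_rmse(theta, hf.downsample(fine, 5), staircase, factor=1) < 1e-9


class TestClassifyFit:
    def test_threshold_boundary_converges(self):
        assert hf.classify_fit(10.84, 10.84, True) == "converged"

    def test_far_above_floor_is_local_minimum(self):
        assert hf.classify_fit(108.4, 10.84, True) == "local_minimum"

    def test_solver_breakdown_is_failure(self):
        assert hf.classify_fit(0.1, 10.84, False) == "failed"

    def test_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            hf.classify_fit(1.0, 0.0, True)


class TestFitCmaes:
    def test_start_at_optimum_converges_fast(self, cell, staircase):
        # noiseless target, start at the generating theta: nothing to improve
        theta, clean, _ = cell
        res = hf.fit_cmaes(clean, staircase, theta,
                           config=hf.CmaesConfig(seed=1, max_iter=200))
        assert res.status == "converged"
        assert res.rmse < 1e-3
        assert res.iterations <= 150  # long-patience stop, well below the cap

    def test_perturbed_start_recovers_parameters(self, cell, staircase):
        theta, _, noisy = cell
        fac = np.array([1.5 if i % 2 else 1 / 1.5 for i in range(9)])
        init = hf.ChannelParams.from_array(theta.as_array() * fac)
        res = hf.fit_cmaes(noisy, staircase, init, config=hf.RECOVERY_CONFIG)
        rel = np.abs(res.theta_hat.as_array() / theta.as_array() - 1)
        assert res.status == "converged"
        assert rel[1:].max() < 0.10

    def test_constraint_violating_start_proceeds(self, cell, staircase):
        _, _, noisy = cell
        bad = hf.ChannelParams(g_kr=1000.0, p1=10.0, p2=400.0, p3=1.0, p4=1.0,
                               p5=1.0, p6=1.0, p7=1.0, p8=1.0)
        assert not hf.check_constraints(bad)
        res = hf.fit_cmaes(noisy, staircase, bad,
                           config=hf.CmaesConfig(seed=2, max_iter=30))
        assert any("constraint" in m for m in res.messages)
        assert res.iterations >= 1

    def test_incumbent_objective_nonincreasing(self, cell, staircase):
        _, _, noisy = cell
        init = hf.sample_params(n=1, seed=55)[0]
        res = hf.fit_cmaes(noisy, staircase, init,
                           config=hf.CmaesConfig(seed=3, max_iter=60))
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_deterministic_given_seed(self, cell, staircase):
        _, _, noisy = cell
        init = hf.sample_params(n=1, seed=56)[0]
        cfg = hf.CmaesConfig(seed=7, max_iter=25)
        a = hf.fit_cmaes(noisy, staircase, init, config=cfg)
        b = hf.fit_cmaes(noisy, staircase, init, config=cfg)
        np.testing.assert_array_equal(a.theta_hat.as_array(), b.theta_hat.as_array())
        assert a.iterations == b.iterations


@pytest.fixture(scope="module")
def chain(cell, staircase):
    theta, _, noisy = cell
    return theta, hf.adaptive_metropolis(noisy, staircase, theta,
                                         n_samples=20_000, seed=9)


class TestAdaptiveMetropolis:
    def test_acceptance_rate_in_tuning_band(self, chain):
        _, ch = chain
        assert 0.05 < ch.acceptance_rate < 0.6

    def test_posterior_mean_covers_truth(self, chain):
        theta, ch = chain
        post = ch.samples[5000:]
        z = (post.mean(0) - hf.to_normalized(theta)) / post.std(0)
        assert np.all(np.abs(z) < 3.0)

    def test_chain_stays_in_unit_box(self, chain):
        _, ch = chain
        assert ch.samples.min() >= 0.0 and ch.samples.max() <= 1.0

    def test_infeasible_start_rejected(self, cell, staircase):
        _, _, noisy = cell
        bad = hf.ChannelParams(g_kr=1000.0, p1=10.0, p2=400.0, p3=1.0, p4=1.0,
                               p5=1.0, p6=1.0, p7=1.0, p8=1.0)
        with pytest.raises(SamplerError):
            hf.adaptive_metropolis(noisy, staircase, bad, n_samples=10, seed=1)


class TestBenchmark:
    def test_report_structure(self, staircase, trained_model):
        cells_ds = hf.generate_dataset(3, seed=4321)
        cells = [(cells_ds.example(i).trace, cells_ds.example(i).theta_raw)
                 for i in range(3)]
        rep = hf.benchmark_inits(cells, trained_model, staircase,
                                 config=hf.CmaesConfig(max_iter=15), seed=2)
        summary = rep.summary()
        assert set(summary) == {"predicted", "prior", "random"}
        for row in summary.values():
            assert row["n_cells"] == 3
            assert row["n_converged"] + row["n_local_minima"] + row["n_failures"] == 3

    def test_empty_cells_rejected(self, staircase, trained_model):
        with pytest.raises(ValueError):
            hf.benchmark_inits([], trained_model, staircase)
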