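"""Scoring against arbitrary-unit data and the Metropolis machinery."""

import numpy as np
import pytest

from kinens.estimate import (
    ChainConfig,
    DatasetProtocol,
    Observation,
    TrainingSet,
    accept,
    autocorrelation_interval,
    default_stds,
    ensemble_stats,
    propose,
    run_chain,
    scale_factor,
    simulation_error,
    thin_by_autocorrelation,
)
from kinens.network import ParameterSet
from kinens.simulate import Event, SimulationProtocol

from conftest import make_network


def grid_search_beta(M, x, s, lo=0.0, hi=20.0, n=2_000_001):
    """Independent 1-D oracle for the optimal scale factor."""
    betas = np.linspace(lo, hi, n)
    cost = ((np.asarray(M)[:, None] - betas[None, :] * np.asarray(x)[:, None])
            / np.asarray(s)[:, None]) ** 2
    return betas[np.argmin(cost.sum(axis=0))]


class TestScaleFactor:
    def test_exact_proportionality(self):
        assert scale_factor([2, 4], [1, 2], [1, 1]) == pytest.approx(2.0)

    def test_half_signal(self):
        assert scale_factor([2, 0], [1, 1], [1, 1]) == pytest.approx(1.0)

    def test_unequal_sigma_reweights(self):
        beta = scale_factor([2, 0], [1, 1], [1, 10])
        assert beta == pytest.approx(grid_search_beta([2, 0], [1, 1], [1, 10]), abs=1e-3)
        assert beta == pytest.approx(2 * 100 / 101, rel=1e-9)  # closed form by hand

    def test_matches_grid_search_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0.1, 2.0, 6)
            M = rng.uniform(0.0, 5.0, 6)
            s = rng.uniform(0.2, 3.0, 6)
            beta = scale_factor(M, x, s)
            oracle = grid_search_beta(M, x, s)
            assert beta == pytest.approx(oracle, rel=5e-4, abs=1e-4)

    def test_all_zero_simulated_returns_none(self):
        assert scale_factor([1, 2], [0, 0], [1, 1]) is None

    def test_negative_optimum_clamped(self):
        assert scale_factor([-3, -1], [1, 1], [1, 1]) == 0.0


class TestDefaultStds:
    def test_ten_percent_rule(self):
        np.testing.assert_allclose(default_stds([5.0]), [0.5])

    def test_zero_value_floored(self):
        assert default_stds([0.0])[0] > 0

    def test_flagged_augmented(self):
        np.testing.assert_allclose(default_stds([5.0], flagged=[True], augment=0.5), [2.5])

    def test_augment_outside_range_rejected(self):
        with pytest.raises(ValueError):
            default_stds([1.0], augment=0.1)


@pytest.fixture
def tiny_training():
    """Production/degradation network with a hormone-like timecourse."""
    net, params = make_network(
        [("A", 1.0), ("B", 0.0)],
        [("", "A", 2e-4), ("A", "", 1e-4), ("A", "B", 5e-5), ("B", "", 2e-4)],
    )
    proto = DatasetProtocol(
        clone="base",
        protocol=SimulationProtocol(events=[Event(1.0, "add_species", "A", 1.0)], t_end=24.0),
    )
    return net, params, proto


def _observe(net, params, proto, times, species, beta=1.0, sigma=0.1):
    from kinens.estimate import _simulate_dataset

    obs = [Observation("d", sp, t, 1.0, 1.0) for sp in species for t in times]
    sim = _simulate_dataset(net, params, proto, obs, clones=None)
    return [
        Observation("d", o.species_id, o.condition, beta * v, sigma)
        for o, v in zip(obs, sim)
    ]


class TestSimulationError:
    def test_zero_error_up_to_scale(self, tiny_training):
        net, params, proto = tiny_training
        obs = _observe(net, params, proto, [0.5, 2, 4, 8], ["A", "B"], beta=7.3)
        ts = TrainingSet(obs, {"d": proto})
        assert simulation_error(params, ts, net) == pytest.approx(0.0, abs=1e-12)

    def test_one_sigma_residuals_give_unit_error(self, tiny_training):
        # two equal simulated values, residuals +sigma/-sigma: the fitted
        # beta stays at the true scale and every residual is exactly 1 sigma
        net, params, proto = tiny_training
        base = _observe(net, params, proto, [16.0, 24.0], ["A"], sigma=0.05)
        v1, v2 = base[0].value, base[1].value
        assert v1 == pytest.approx(v2, rel=5e-3)  # near steady state
        mean = 0.5 * (v1 + v2)
        obs = [
            Observation("d", "A", 16.0, mean + 0.05, 0.05),
            Observation("d", "A", 24.0, mean - 0.05, 0.05),
        ]
        ts = TrainingSet(obs, {"d": proto})
        assert simulation_error(params, ts, net) == pytest.approx(1.0, abs=2e-2)

    def test_unit_rescaling_invariance(self, tiny_training):
        net, params, proto = tiny_training
        ppert = ParameterSet(params.rate_constants * 1.3, params.nonzero_initial_conditions)
        obs = _observe(net, params, proto, [0.5, 2, 4, 8], ["A", "B"], beta=2.0)
        ts1 = TrainingSet(obs, {"d": proto})
        scaled = [
            Observation(o.dataset_id, o.species_id, o.condition,
                        10 * o.value if o.species_id == "A" else o.value,
                        10 * o.std if o.species_id == "A" else o.std)
            for o in obs
        ]
        ts2 = TrainingSet(scaled, {"d": proto})
        e1, e2 = simulation_error(ppert, ts1, net), simulation_error(ppert, ts2, net)
        assert e1 > 0.1  # perturbed parameters leave real misfit
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_failed_simulation_gives_infinite_error(self, tiny_training):
        net, params, proto = tiny_training
        obs = [Observation("d", "A", "no_such_condition", 1.0, 0.1)]
        bad = DatasetProtocol(clone="base", mode="steady", conditions={})
        ts = TrainingSet(obs, {"d": bad})
        assert simulation_error(params, ts, net) == np.inf


class TestProposal:
    def test_tiny_sigma_is_near_identity(self):
        p = ParameterSet(np.array([1.0, 2.0, 3.0]))
        cfg = ChainConfig(sigma=1e-12, E0=1.0)
        q = propose(p, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(q.rate_constants, p.rate_constants, rtol=1e-10)

    def test_positivity_and_log_std(self):
        p = ParameterSet(np.array([0.5]))
        cfg = ChainConfig(sigma=0.2, E0=1.0)
        rng = np.random.default_rng(1)
        draws = np.array([propose(p, cfg, rng).rate_constants[0] for _ in range(10_000)])
        assert np.all(draws > 0)
        assert np.std(np.log(draws / 0.5)) == pytest.approx(0.2, rel=0.05)

    def test_block_proposal_touches_subset(self):
        p = ParameterSet(np.ones(10))
        cfg = ChainConfig(sigma=0.3, E0=1.0, block_size=3)
        q = propose(p, cfg, np.random.default_rng(2))
        assert np.sum(q.rate_constants != 1.0) == 3


class TestAccept:
    def test_improvement_always_accepted(self):
        cfg = ChainConfig(sigma=0.1, E0=1.0)
        rng = np.random.default_rng(0)
        assert all(accept(5.0, 4.0, cfg, rng) for _ in range(100))

    def test_half_life_point(self):
        cfg = ChainConfig(sigma=0.1, E0=0.7)
        rng = np.random.default_rng(3)
        dE = 0.7 * np.log(2.0)
        hits = sum(accept(1.0, 1.0 + dE, cfg, rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.5, abs=0.02)

    def test_infinite_error_never_accepted(self):
        cfg = ChainConfig(sigma=0.1, E0=1.0)
        rng = np.random.default_rng(0)
        assert not any(accept(1.0, np.inf, cfg, rng) for _ in range(100))


def quadratic_error(params):
    logk = np.log(params.rate_constants)
    return float(np.sum(logk**2))


class TestChain:
    def test_bitwise_deterministic_under_seed(self):
        start = ParameterSet(np.array([1.5, 0.5]))
        cfg = ChainConfig(sigma=0.3, E0=1.0, n_steps=200, seed=9)
        a = run_chain(start, quadratic_error, cfg)
        b = run_chain(start, quadratic_error, cfg)
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.errors, b.errors)
        np.testing.assert_array_equal(a.accepted, b.accepted)

    def test_zero_temperature_limit_is_greedy(self):
        start = ParameterSet(np.array([3.0, 0.2]))
        cfg = ChainConfig(sigma=0.2, E0=1e-12, n_steps=300, seed=4)
        ch = run_chain(start, quadratic_error, cfg)
        assert np.all(np.diff(ch.errors) <= 1e-12)

    def test_stationary_density_matches_boltzmann_1d(self):
        # E = (log k)^2, E0 = 1  =>  log k ~ N(0, 1/2)
        from scipy.stats import kstest

        start = ParameterSet(np.array([1.0]))
        cfg = ChainConfig(sigma=0.8, E0=1.0, n_steps=20_000, seed=11)
        ch = run_chain(start, quadratic_error, cfg)
        samples = np.log(ch.params[2000::40, 0])
        stat, p = kstest(samples, "norm", args=(0.0, np.sqrt(0.5)))
        assert p > 0.01


class TestThinning:
    def test_white_noise_interval_is_one(self):
        rng = np.random.default_rng(0)
        assert autocorrelation_interval(rng.normal(size=5000)) == 1

    def test_ar1_interval_matches_theory(self):
        rng = np.random.default_rng(5)
        rho, n = 0.9, 40_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        interval = autocorrelation_interval(x)
        expected = np.log(20) / np.log(1 / rho)  # ~28.4
        assert abs(interval - expected) / expected < 0.20

    def test_thinning_keeps_every_interval_th_state(self):
        start = ParameterSet(np.array([1.0, 1.0]))
        cfg = ChainConfig(sigma=0.5, E0=1.0, n_steps=500, seed=2)
        ch = run_chain(start, quadratic_error, cfg)
        ens = thin_by_autocorrelation(ch, burn_in=0.1)
        assert len(ens.members) >= 3
        steps = np.diff(ens.provenance)
        assert np.all(steps == ens.thinning_interval)


class TestEnsembleStats:
    def test_identical_members_zero_cv(self):
        from kinens.estimate import Ensemble

        members = [ParameterSet(np.array([1.0, 2.0])) for _ in range(5)]
        ens = Ensemble(members, np.zeros(5))
        stats = ensemble_stats(ens)
        np.testing.assert_allclose(stats["cv"], 0.0)
        assert stats["frac_cv_gt_1"] == 0.0

    def test_two_member_cv_hand_computed(self):
        from kinens.estimate import Ensemble

        k = 0.4
        members = [ParameterSet(np.array([k])), ParameterSet(np.array([3 * k]))]
        ens = Ensemble(members, np.zeros(2))
        stats = ensemble_stats(ens)
        # mean 2k, sample std sqrt(2) k  =>  CV = sqrt(2)/2
        assert stats["cv"][0] == pytest.approx(np.sqrt(2) / 2)
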