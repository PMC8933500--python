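"""Compartmentalized serial-transfer simulator: seeding, growth, dilution, fusion."""

import math

import numpy as np
import pytest

from replinet import simulator as sim


def _config(**kwargs):
    defaults = dict(
        species=("H",),
        rates=np.array([[1.0]]),
        n_compartments=200,
        rounds=3,
        seed=0,
    )
    defaults.update(kwargs)
    return sim.SimConfig(**defaults)


class TestConfig:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("capacity", 0.0),
            ("dilution", 0.5),
            ("n_compartments", 1),
            ("fusion_number", -1.0),
            ("reaction_time", 0.0),
            ("init_mean", -1.0),
        ],
    )
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            _config(**{field: value})

    def test_rate_matrix_shape_checked(self):
        with pytest.raises(ValueError):
            _config(species=("A", "B"), rates=np.ones((3, 3)))

    def test_yaml_round_trip(self, tmp_path):
        config = _config(init_mean=(10.0,))
        config.to_yaml(tmp_path / "c.yaml")
        assert sim.SimConfig.from_yaml(tmp_path / "c.yaml") == config


class TestPoissonSeeding:
    def test_zero_mean_empty(self):
        state = sim.initialize_poisson(_config(init_mean=0.0))
        assert state.counts.sum() == 0

    def test_sample_mean_within_three_se(self):
        config = _config(n_compartments=10_000)
        state = sim.initialize_poisson(config)
        mean = state.counts[:, 0].mean()
        assert abs(mean - 10.0) <= 3 * math.sqrt(10.0 / 10_000)

    def test_variance_matches_mean(self):
        config = _config(n_compartments=10_000)
        state = sim.initialize_poisson(config)
        var = state.counts[:, 0].var(ddof=1)
        assert abs(var / 10.0 - 1.0) < 0.05  # Poisson: var == mean

    def test_per_species_means(self):
        config = _config(
            species=("A", "B"), rates=np.zeros((2, 2)), init_mean=(10.0, 0.0),
            n_compartments=2000,
        )
        state = sim.initialize_poisson(config)
        assert state.counts[:, 1].sum() == 0
        assert state.counts[:, 0].sum() > 0


class TestReplication:
    def test_zero_rates_unchanged(self):
        x = np.array([3.0, 7.0])
        out = sim.replicate_compartment(x, np.zeros((2, 2)), 300.0, 1.0)
        np.testing.assert_allclose(out, x)

    def test_at_capacity_unchanged(self):
        out = sim.replicate_compartment(
            np.array([300.0]), np.array([[1.0]]), 300.0, 1.0
        )
        assert out[0] == pytest.approx(300.0, rel=1e-6)

    def test_parasite_alone_no_growth(self):
        # parasite row sources only the (absent) host column
        k = np.array([[0.0, 0.0], [2.0, 0.0]])  # species (host, parasite)
        out = sim.replicate_compartment(np.array([0.0, 10.0]), k, 300.0, 5.0)
        np.testing.assert_allclose(out, [0.0, 10.0])

    def test_single_replicator_approaches_capacity(self):
        out = sim.replicate_compartment(
            np.array([10.0]), np.array([[1.0]]), 300.0, 10.0, rtol=1e-10, atol=1e-12
        )
        assert out[0] == pytest.approx(300.0, rel=1e-3)

    def test_matches_fine_step_rk4_oracle(self):
        # independent fixed-step RK4 integration of the same field
        k = np.array([[0.8, 0.3], [0.0, 0.5]])
        c = 300.0

        def f(x):
            return x * (k @ x) * (1 - x.sum() / c)

        x = np.array([5.0, 8.0])
        h = 1e-4
        for _ in range(int(2.0 / h)):
            k1 = f(x)
            k2 = f(x + h / 2 * k1)
            k3 = f(x + h / 2 * k2)
            k4 = f(x + h * k3)
            x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out = sim.replicate_compartment(
            np.array([5.0, 8.0]), k, c, 2.0, rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_batch_matches_per_compartment(self):
        rng = np.random.default_rng(0)
        k = np.array([[1.0, 0.2], [0.5, 0.0]])
        batch = rng.poisson(10, size=(20, 2)).astype(float)
        joint = sim.replicate_compartment(batch, k, 300.0, 1.0, rtol=1e-10, atol=1e-12)
        for i in range(20):
            single = sim.replicate_compartment(batch[i], k, 300.0, 1.0, rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(joint[i], single, atol=1e-5)

    def test_total_capped_at_capacity(self):
        out = sim.replicate_compartment(
            np.array([100.0, 100.0]), np.ones((2, 2)), 300.0, 50.0
        )
        assert out.sum() <= 300.0 * (1 + 1e-6)


class TestDilution:
    def test_identity_at_d1(self, rng):
        state = sim.CompartmentState(("H",), rng.poisson(10, (50, 1)).astype(float))
        out = sim.dilute(state, 1.0, rng)
        np.testing.assert_array_equal(out.counts, state.counts)

    def test_empty_stays_empty(self, rng):
        state = sim.CompartmentState(("H",), np.zeros((10, 1)))
        assert sim.dilute(state, 5.0, rng).counts.sum() == 0

    def test_fivefold_expected_loss(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(10, (10_000, 1)).astype(float)
        state = sim.CompartmentState(("H",), counts)
        out = sim.dilute(state, 5.0, rng)
        total = counts.sum()
        # retained total = sum of per-compartment totals kept w.p. 1/5
        expected = total / 5
        var = (counts[:, 0] ** 2).sum() * (1 / 5) * (4 / 5)
        assert abs(out.counts.sum() - expected) <= 3 * math.sqrt(var)
        assert out.counts.sum() <= total


class TestFusionDivision:
    def test_totals_conserved_exactly(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(7, (500, 3)).astype(float)
        state = sim.CompartmentState(("A", "B", "C"), counts)
        out = sim.fuse_divide(state, 1.3, rng)
        np.testing.assert_array_equal(
            out.counts.sum(axis=0), counts.sum(axis=0)
        )

    def test_f_zero_identity(self, rng):
        counts = rng.poisson(5, (20, 2)).astype(float)
        state = sim.CompartmentState(("A", "B"), counts)
        out = sim.fuse_divide(state, 0.0, rng)
        np.testing.assert_array_equal(out.counts, counts)

    def test_pooled_pair_redistributes_binomially(self):
        # compartments (6, 4): after one event each holds Binomial(10, 1/2)
        outcomes = []
        for seed in range(400):
            rng = np.random.default_rng(seed)
            state = sim.CompartmentState(("A",), np.array([[6.0], [4.0]]))
            out = sim.fuse_divide(state, 0.5, rng)  # round(2*0.5) = 1 event
            assert out.counts.sum() == 10
            outcomes.append(out.counts[0, 0])
        mean = np.mean(outcomes)
        assert abs(mean - 5.0) <= 3 * math.sqrt(10 * 0.25 / 400)

    def test_single_compartment_rejected(self, rng):
        state = sim.CompartmentState(("A",), np.array([[5.0]]))
        with pytest.raises(ValueError):
            sim.fuse_divide(state, 1.0, rng)


class TestRunExperiment:
    def test_identical_seeds_identical_trajectories(self):
        config = _config(rounds=4, n_compartments=100)
        a = sim.summaries_to_frame(sim.run_experiment(config))
        b = sim.summaries_to_frame(sim.run_experiment(config))
        assert a.equals(b)

    def test_zero_rates_decay_to_extinction(self):
        # with no replication, totals shrink ~D-fold per round
        config = _config(
            species=("A", "B"), rates=np.zeros((2, 2)), n_compartments=500, rounds=12,
        )
        summaries = sim.run_experiment(config)
        # ceil(log_D(initial/threshold)) bounds the *expected* decay; actual
        # extinction is a stochastic tail event, so allow one extra round
        bound = math.ceil(math.log(10 * 500 / 1.0, 5))
        extinct_round = next(
            s.round for s in summaries if len(s.extinct) == 2
        )
        assert extinct_round <= bound + 1

    def test_persistent_self_replicator(self):
        config = _config(
            rates=np.array([[3.0]]), n_compartments=1000, rounds=22,
        )
        summaries = sim.run_experiment(config)
        assert summaries[-1].round == 22
        assert not summaries[-1].extinct
        assert summaries[-1].totals["H"] > 1000  # far above threshold

    def test_round_summaries_structure(self):
        config = _config(rounds=2, n_compartments=50)
        summaries = sim.run_experiment(config)
        assert [s.round for s in summaries] == [0, 1, 2]
        state_total = summaries[0].totals["H"]
        assert summaries[0].mean_per_compartment["H"] == pytest.approx(state_total / 50)


class TestKnockout:
    def test_remove_nothing_identical_to_baseline(self):
        config = _config(
            species=("A", "B"), rates=np.eye(2) * 2.0, n_compartments=200, rounds=3,
        )
        base = sim.summaries_to_frame(sim.run_experiment(config))
        ko = sim.summaries_to_frame(sim.knockout_experiment(config, []))
        assert base.equals(ko)

    def test_remove_zero_initialized_species_identical(self):
        config = _config(
            species=("A", "B"), rates=np.eye(2) * 2.0, init_mean=(10.0, 0.0),
            n_compartments=200, rounds=3,
        )
        base = sim.summaries_to_frame(sim.run_experiment(config))
        ko = sim.summaries_to_frame(sim.knockout_experiment(config, ["B"]))
        assert base.equals(ko)

    def test_sole_source_removal_forces_parasite_extinction(self):
        # parasite P replicates only via host H; removing H dooms P
        k = np.array([[2.0, 0.0], [2.4, 0.0]])  # rows (H, P), col H is sole source
        config = _config(
            species=("H", "P"), rates=k, n_compartments=1000, rounds=10,
        )
        summaries = sim.knockout_experiment(config, ["H"])
        assert any("P" in s.extinct for s in summaries)

    def test_remove_all_rejected(self):
        with pytest.raises(ValueError):
            sim.knockout_experiment(_config(), ["H"])

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            sim.knockout_experiment(_config(), ["X"])


class TestStochasticRound:
    def test_integers_unchanged(self, rng):
        x = np.array([[1.0, 5.0], [0.0, 300.0]])
        np.testing.assert_array_equal(sim.stochastic_round(x, rng), x)

    def test_unbiased_on_fractions(self):
        rng = np.random.default_rng(0)
        draws = [sim.stochastic_round(np.array([2.3]), rng)[0] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(2.3, abs=0.05)
        assert set(draws) == {2.0, 3.0}
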