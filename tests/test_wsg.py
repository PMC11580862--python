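import numpy as np
import pytest

from abmkf.wsg import (
    AgentArray,
    WSGMicrostate,
    WSGParams,
    init_wsg,
    step_wsg,
    summarize_wsg,
    synthesize_wsg,
)


def _single_agent_state(params, energy, species="sheep", position=(0.5, 0.5)):
    agent = AgentArray(np.array([position]), np.array([0.0]), np.array([float(energy)]))
    empty = AgentArray.empty()
    alive = np.zeros((params.world_width, params.world_height), dtype=bool)
    counter = np.full(alive.shape, params.grass_regrowth_time, dtype=int)
    wolves, sheep = (agent, empty) if species == "wolf" else (empty, agent)
    return WSGMicrostate(wolves, sheep, alive, counter)


class TestInit:
    def test_full_density(self, rng):
        params = WSGParams(init_grass_density=1.0, world_width=10, world_height=10)
        micro = init_wsg(params, rng)
        assert micro.grass_alive.all()
        assert (micro.grass_counter == 0).all()

    def test_no_wolves(self, rng):
        micro = init_wsg(WSGParams(init_wolves=0), rng)
        assert len(micro.wolves) == 0

    def test_density_matches_binomial(self, rng):
        params = WSGParams(init_grass_density=0.5, world_width=255, world_height=255)
        micro = init_wsg(params, rng)
        n = params.n_patches
        sigma = np.sqrt(n * 0.25)
        assert abs(micro.grass_alive.sum() - 0.5 * n) < 3 * sigma

    def test_energy_positive_and_bounded(self, rng):
        params = WSGParams(init_wolves=500, init_sheep=500)
        micro = init_wsg(params, rng)
        assert (micro.wolves.energies > 0).all()
        assert (micro.wolves.energies <= 2 * params.wolf_gain_from_food).all()
        assert (micro.sheep.energies <= 2 * params.sheep_gain_from_food).all()


class TestStep:
    def test_grass_regrowth(self, rng):
        params = WSGParams(world_width=2, world_height=2, init_wolves=0, init_sheep=0)
        micro = init_wsg(params, rng)
        micro.grass_alive[:] = False
        micro.grass_counter[:] = 1
        out = step_wsg(micro, params, rng)
        assert out.grass_alive.all()
        assert (out.grass_counter == 0).all()

    def test_reproduction_conserves_energy(self, rng):
        # no grass, no predators: only move cost and reproduction touch energy
        params = WSGParams(
            world_width=5, world_height=5, sheep_reproduce_prob=1.0, init_wolves=0
        )
        micro = _single_agent_state(params, energy=10.0)
        out = step_wsg(micro, params, rng)
        assert len(out.sheep) == 2
        # parent+child energy sums to post-move energy
        assert out.sheep.energies.sum() == pytest.approx(9.0)

    def test_wolf_eats_colocated_sheep(self, rng):
        # a 1x1 torus keeps predator and prey on the same patch
        params = WSGParams(
            world_width=1,
            world_height=1,
            wolf_reproduce_prob=0.0,
            sheep_reproduce_prob=0.0,
        )
        wolves = AgentArray(np.array([[0.5, 0.5]]), np.array([0.0]), np.array([5.0]))
        sheep = AgentArray(np.array([[0.5, 0.5]]), np.array([1.0]), np.array([3.0]))
        alive = np.zeros((1, 1), dtype=bool)
        counter = np.full((1, 1), params.grass_regrowth_time)
        micro = WSGMicrostate(wolves, sheep, alive, counter)
        out = step_wsg(micro, params, rng)
        assert len(out.sheep) == 0
        assert out.wolves.energies[0] == pytest.approx(5.0 - 1.0 + params.wolf_gain_from_food)

    def test_sheep_nonincreasing_without_food(self, rng):
        params = WSGParams(
            world_width=8, world_height=8, init_wolves=0, init_sheep=30,
            sheep_reproduce_prob=0.0, init_grass_density=0.0,
        )
        micro = init_wsg(params, rng)
        counts = [len(micro.sheep)]
        for _ in range(30):
            micro = step_wsg(micro, params, rng)
            counts.append(len(micro.sheep))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_grass_state_partition_invariant(self, wsg_params, rng):
        micro = init_wsg(wsg_params, rng)
        for _ in range(20):
            micro = step_wsg(micro, wsg_params, rng)
            alive = int(micro.grass_alive.sum())
            regrowing = int((micro.grass_counter > 0).sum())
            assert alive + regrowing == wsg_params.n_patches
            assert (micro.grass_counter[micro.grass_alive] == 0).all()
            assert (micro.grass_counter <= wsg_params.grass_regrowth_time).all()

    def test_reproducible_under_fixed_seed(self, wsg_params):
        outs = []
        for _ in range(2):
            r = np.random.default_rng(99)
            micro = init_wsg(wsg_params, r)
            for _ in range(10):
                micro = step_wsg(micro, wsg_params, r)
            outs.append(micro)
        a, b = outs
        assert np.array_equal(a.wolves.positions, b.wolves.positions)
        assert np.array_equal(a.sheep.energies, b.sheep.energies)
        assert np.array_equal(a.grass_counter, b.grass_counter)

    def test_positions_stay_on_torus(self, wsg_params, rng):
        micro = init_wsg(wsg_params, rng)
        for _ in range(5):
            micro = step_wsg(micro, wsg_params, rng)
        for ag in (micro.wolves, micro.sheep):
            assert (ag.positions[:, 0] >= 0).all()
            assert (ag.positions[:, 0] < wsg_params.world_width).all()
            assert (ag.positions[:, 1] < wsg_params.world_height).all()


class TestSummarize:
    def test_empty_world(self, rng):
        params = WSGParams(init_wolves=0, init_sheep=0, init_grass_density=0.0)
        mv = summarize_wsg(init_wsg(params, rng))
        assert np.array_equal(mv.values, [0.0, 0.0, 0.0])

    def test_counts(self, rng):
        params = WSGParams(world_width=4, world_height=4, init_wolves=3, init_sheep=5)
        micro = init_wsg(params, rng)
        micro.grass_alive[:] = False
        micro.grass_counter[:] = 1
        micro.grass_alive.ravel()[:7] = True
        micro.grass_counter.ravel()[:7] = 0
        assert np.array_equal(summarize_wsg(micro).values, [3.0, 5.0, 7.0])

    def test_permutation_invariance(self, wsg_params, rng):
        micro = init_wsg(wsg_params, rng)
        perm = rng.permutation(len(micro.sheep))
        shuffled = micro.copy()
        shuffled.sheep = shuffled.sheep.take(perm)
        assert np.array_equal(summarize_wsg(micro).values, summarize_wsg(shuffled).values)


class TestSynthesize:
    def test_fixed_point(self, wsg_params, rng):
        seed = init_wsg(wsg_params, rng)
        target = summarize_wsg(seed)
        out = synthesize_wsg(target, seed, wsg_params, rng)
        assert np.array_equal(summarize_wsg(out).values, target.values)
        assert len(out.wolves) == len(seed.wolves)

    def test_remove_all_wolves(self, wsg_params, rng):
        seed = init_wsg(wsg_params, rng)
        target = summarize_wsg(seed).values.copy()
        target[0] = 0
        out = synthesize_wsg(target, seed, wsg_params, rng)
        assert len(out.wolves) == 0

    def test_random_targets_exact(self, wsg_params, rng):
        seed = init_wsg(wsg_params, rng)
        for _ in range(100):
            target = np.array(
                [
                    rng.integers(0, 60),
                    rng.integers(0, 120),
                    rng.integers(0, wsg_params.n_patches + 1),
                ],
                dtype=float,
            )
            out = synthesize_wsg(target, seed, wsg_params, rng)
            assert np.array_equal(summarize_wsg(out).values, target)
            assert (out.grass_counter[out.grass_alive] == 0).all()

    def test_added_agents_resample_survivor_energy(self, wsg_params, rng):
        seed = init_wsg(wsg_params, rng)
        seed.sheep.energies[:] = 3.25  # sentinel value
        target = summarize_wsg(seed).values + np.array([0.0, 10.0, 0.0])
        out = synthesize_wsg(target, seed, wsg_params, rng)
        assert (out.sheep.energies == 3.25).all()

    def test_grass_overflow_rejected(self, wsg_params, rng):
        seed = init_wsg(wsg_params, rng)
        bad = np.array([1.0, 1.0, wsg_params.n_patches + 1.0])
        with pytest.raises(ValueError):
            synthesize_wsg(bad, seed, wsg_params, rng)
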