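"""GA model-predictive controller: fitness shape, evolution operators,
elitism, box closure and closed-loop convergence on exact toy plants."""

import numpy as np
import pytest

from triscale.dataset import roll_window
from triscale.gacontrol import (
    GAConfig,
    ReferenceOutput,
    control_loop,
    evolve,
    fitness,
)
from triscale.network import build_toy_network


@pytest.fixture(scope="module")
def toy():
    spec = build_toy_network(2, 2, 3, 1, seed=3)
    p, s, m, c = spec.dims
    return spec, p + s + m + c, p + s + m


def _window(n_in, n_out, tau=3, fill=0.5):
    inst = np.full(n_in, fill)
    out = inst[:n_out]
    ws = roll_window(np.tile(inst, (tau + 1, 1)), np.tile(out, (tau + 1, 1)),
                     theta=tau, tau=tau)
    return ws.v, inst


def _exact_surrogate(n_in, n_out):
    """Output equals the x,y,z block of the current input (identity map)."""
    return lambda V: V[:, -n_in:][:, :n_out]


class _IdentityPlant:
    def __init__(self, spec):
        self.spec = spec
        n = spec.p + spec.s + spec.m

        self._n_out = n

    def step(self, inst):
        return np.asarray(inst[: self._n_out], dtype=float).copy()


class TestFitness:
    def test_exact_match_gives_one(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = inst[:n_out].copy()
        f = fitness(inst, _exact_surrogate(n_in, n_out), v, ref)
        assert f == pytest.approx(1.0)

    def test_unit_l1_error_gives_half(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = inst[:n_out].copy()
        ref[0] += 1.0  # total L1 error exactly 1 (prediction unclamped at 0.5)
        f = fitness(inst, _exact_surrogate(n_in, n_out), v, ref)
        assert f == pytest.approx(0.5)

    def test_strictly_decreasing_in_l1_error(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = inst[:n_out].copy()
        rng = np.random.default_rng(0)
        sur = _exact_surrogate(n_in, n_out)
        for _ in range(50):
            g1, g2 = inst.copy(), inst.copy()
            e1, e2 = rng.uniform(0, 0.4, 2)
            g1[0] = 0.5 + min(e1, e2)
            g2[0] = 0.5 + max(e1, e2)
            if e1 != e2:
                assert fitness(g1, sur, v, ref) > fitness(g2, sur, v, ref)


class TestEvolve:
    def test_optimal_incumbent_returned_unchanged(self, toy):
        """If the current input already matches the reference, elitism
        returns it without any generation."""
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = inst[:n_out].copy()
        best, fit, info = evolve(inst, v, ref, _exact_surrogate(n_in, n_out),
                                 GAConfig(seed=0))
        np.testing.assert_array_equal(best, inst)
        assert info["generations"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_quadratic_toy_finds_root(self, toy, seed):
        """Surrogate gamma_1 = input_1^2 with reference 0.25: the GA must
        locate input_1 ~ 0.5 (grid-search oracle value)."""
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)

        def surrogate(V):
            out = V[:, -n_in:][:, :n_out].copy()
            out[:, 0] = V[:, -n_in] ** 2
            return out

        ref = inst[:n_out].copy()
        ref[0] = 0.25
        grid = np.linspace(0, 1, 10001)
        oracle = grid[np.argmin(np.abs(grid ** 2 - 0.25))]
        cfg = GAConfig(seed=seed, max_generations=30, fitness_threshold=0.999)
        best, _, _ = evolve(inst, v, ref, surrogate, cfg)
        assert abs(best[0] - oracle) <= 0.05

    def test_best_fitness_history_is_nondecreasing(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = np.clip(inst[:n_out] + 0.3, 0, 0.99)
        for seed in range(5):
            _, _, info = evolve(inst, v, ref, _exact_surrogate(n_in, n_out),
                                GAConfig(seed=seed, fitness_threshold=0.9999,
                                         max_generations=15))
            hist = info["best_fitness_history"]
            assert all(b >= a for a, b in zip(hist, hist[1:]))

    def test_genomes_stay_in_unit_box(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out, fill=0.02)  # near the boundary
        ref = np.full(n_out, 0.99)
        for seed in range(5):
            best, _, _ = evolve(inst, v, ref, _exact_surrogate(n_in, n_out),
                                GAConfig(seed=seed, chromosome_jitter=0.5))
            assert np.all(best >= 0.0) and np.all(best <= 1.0)

    def test_single_point_crossover_mode_runs(self, toy):
        spec, n_in, n_out = toy
        v, inst = _window(n_in, n_out)
        ref = np.clip(inst[:n_out] + 0.2, 0, 0.99)
        cfg = GAConfig(seed=1, crossover_mode="single_point", crossover_index=3)
        best, fit, _ = evolve(inst, v, ref, _exact_surrogate(n_in, n_out), cfg)
        assert 0.0 < fit <= 1.0


class TestControlLoop:
    def test_identity_plant_convergence_rate(self, toy):
        """>= 95% of 20 seeded runs reach L1 < 0.02 within 30 iterations
        (exact surrogate, identity plant)."""
        spec, n_in, n_out = toy
        v, _ = _window(n_in, n_out)
        plant = _IdentityPlant(spec)
        ref = ReferenceOutput({spec.species_names()[0]: 0.8})
        sur = _exact_surrogate(n_in, n_out)
        converged = 0
        for seed in range(20):
            res = control_loop(plant, sur, v, ref, l1_threshold=0.02,
                               max_iter=30, cfg=GAConfig(seed=seed))
            converged += res.converged
        assert converged >= 19

    def test_huge_threshold_returns_first_iteration(self, toy):
        spec, n_in, n_out = toy
        v, _ = _window(n_in, n_out)
        plant = _IdentityPlant(spec)
        ref = ReferenceOutput({spec.species_names()[0]: 0.8})
        res = control_loop(plant, _exact_surrogate(n_in, n_out), v, ref,
                           l1_threshold=float(n_out), max_iter=30,
                           cfg=GAConfig(seed=0))
        assert res.converged and res.iterations == 1

    def test_seed_determinism_of_full_loop(self, toy):
        spec, n_in, n_out = toy
        v, _ = _window(n_in, n_out)
        plant = _IdentityPlant(spec)
        ref = ReferenceOutput({spec.species_names()[1]: 0.3})
        a = control_loop(plant, _exact_surrogate(n_in, n_out), v, ref,
                         cfg=GAConfig(seed=7))
        b = control_loop(plant, _exact_surrogate(n_in, n_out), v, ref,
                         cfg=GAConfig(seed=7))
        np.testing.assert_array_equal(a.final_input, b.final_input)
        assert a.iterations == b.iterations

    def test_nonconvergence_is_structured_failure(self, toy):
        spec, n_in, n_out = toy
        v, _ = _window(n_in, n_out)
        plant = _IdentityPlant(spec)
        ref = ReferenceOutput({spec.species_names()[0]: 0.8})

        def hopeless_surrogate(V):  # constant wrong prediction
            return np.zeros((len(V), n_out))

        res = control_loop(plant, hopeless_surrogate, v, ref,
                           l1_threshold=1e-9, max_iter=3, cfg=GAConfig(seed=0))
        assert not res.converged
        assert len(res.trace) == 3


class TestReferenceOutput:
    def test_vector_holds_free_outputs_at_current(self, toy):
        spec, n_in, n_out = toy
        ref = ReferenceOutput({spec.species_names()[2]: 0.9})
        cur = np.full(n_out, 0.4)
        vec = ref.vector(spec, cur)
        assert vec[2] == 0.9
        assert np.all(np.delete(vec, 2) == 0.4)

    def test_out_of_range_setpoint_rejected(self):
        with pytest.raises(ValueError):
            ReferenceOutput({"a": 1.5})

    def test_unknown_species_rejected(self, toy):
        spec, _, n_out = toy
        with pytest.raises(KeyError):
            ReferenceOutput({"nonexistent": 0.5}).indices(spec)
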