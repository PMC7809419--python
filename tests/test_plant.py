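"""MIMO plant: reproducibility, step purity, perturbations, enzyme-signal
overrides and checklist-driven parameter tuning."""

import numpy as np
import pytest

from triscale.kinetics import StateVectors
from triscale.network import (
    GeneRule,
    NetworkSpec,
    ReactionRule,
    build_toy_network,
)
from triscale.plant import (
    DirectionalAssertion,
    Perturbation,
    Plant,
    PlantConfig,
    apply_perturbation,
    build_plant,
    evaluate_assertion,
    spec_with_parameter_table,
    tune_parameters,
)


class TestReproducibility:
    def test_same_seeds_give_identical_parameters_and_trajectories(self, toy_spec):
        a = Plant(PlantConfig(spec=toy_spec, init_seed=5))
        b = Plant(PlantConfig(spec=toy_spec, init_seed=5))
        for k, v in a.parameter_table().items():
            np.testing.assert_array_equal(v, b.parameter_table()[k])
        np.testing.assert_array_equal(a.initial_instance(), b.initial_instance())
        ta = a.simulate(horizon=2.0, n_points=5)
        tb = b.simulate(horizon=2.0, n_points=5)
        np.testing.assert_array_equal(ta.species_matrix(), tb.species_matrix())

    def test_different_init_seed_changes_initial_state(self, toy_spec):
        a = Plant(PlantConfig(spec=toy_spec, init_seed=5))
        b = Plant(PlantConfig(spec=toy_spec, init_seed=6))
        assert not np.array_equal(a.initial_instance(), b.initial_instance())


class TestStep:
    def test_step_is_pure(self, toy_plant):
        inst = toy_plant.initial_instance()
        np.testing.assert_array_equal(toy_plant.step(inst), toy_plant.step(inst))

    def test_step_output_dimensions(self, ccm_plant, ccm_init):
        out = ccm_plant.step(ccm_init.concat())
        assert out.shape == (107,)
        assert np.all((out >= 0) & (out <= 1))

    def test_fixed_point_input_returns_itself(self):
        """A state with every layer at rest maps to itself: gene with its
        transcription factor absent and basal = decay, signaling with only
        degradation at level zero, metabolite at zero."""
        spec = NetworkSpec(
            gene_names=["g0"],
            signaling_names=["y0"],
            metabolite_names=["z0"],
            input_names=["u0"],
            gene_rules=[GeneRule(0, 0.1, 0.1, tf_activators={0: 0.5})],
            interaction_rules=[],
            reaction_rules=[ReactionRule(0, (0,), (), 0, 0.5, 0.5)],
        )
        plant = Plant(PlantConfig(spec=spec))
        inst = np.array([0.6, 0.0, 0.0, 0.3])  # x, y, z, u
        np.testing.assert_allclose(plant.step(inst), inst[:3], atol=1e-7)

    def test_wrong_length_rejected(self, toy_plant):
        with pytest.raises(ValueError):
            toy_plant.step(np.zeros(3))


class TestPerturbation:
    def test_knockouts_zero_every_flux(self, toy_plant):
        spec = toy_plant.spec
        pert = Perturbation(knockouts=tuple(range(spec.n)))
        ko = apply_perturbation(toy_plant, pert)
        rng = np.random.default_rng(0)
        for _ in range(50):
            r = ko.compiled.metabolic_rates(
                rng.uniform(0, 1, spec.p), rng.uniform(0, 1, spec.s),
                rng.uniform(0, 1, spec.m), rng.uniform(0, 1, spec.c))
            assert np.all(r == 0.0)
        # original plant untouched
        assert np.all(toy_plant.compiled.rate_constants > 0)

    def test_knockout_by_enzyme_name(self, ccm_plant):
        ko = apply_perturbation(ccm_plant, Perturbation(knockouts=("pdh",)))
        spec = ccm_plant.spec
        g = spec.gene_index("pdh")
        for r in spec.reaction_rules:
            if r.catalyzing_gene == g:
                assert ko.compiled.rate_constants[r.reaction_index] == 0.0

    def test_empty_perturbation_preserves_behavior(self, toy_plant):
        same = apply_perturbation(toy_plant, Perturbation())
        t0 = toy_plant.simulate(horizon=2.0, n_points=5)
        t1 = same.simulate(horizon=2.0, n_points=5)
        np.testing.assert_array_equal(t0.species_matrix(), t1.species_matrix())

    def test_enzyme_signal_pins_state_component(self, toy_plant):
        name = toy_plant.spec.gene_names[0]
        pinned = apply_perturbation(
            toy_plant, Perturbation(enzyme_signals={name: 0.77}))
        traj = pinned.simulate(horizon=2.0, n_points=5)
        np.testing.assert_allclose(traj.X[:, 0], 0.77, atol=1e-12)
        out = pinned.step(pinned.initial_instance())
        assert out[0] == pytest.approx(0.77)

    def test_unknown_names_rejected(self, toy_plant):
        with pytest.raises(KeyError):
            apply_perturbation(toy_plant, Perturbation(knockouts=("nope",)))
        with pytest.raises(KeyError):
            apply_perturbation(toy_plant,
                               Perturbation(enzyme_signals={"nope": 0.5}))
        with pytest.raises(ValueError):
            Perturbation(enzyme_signals={"x": 1.5})


class TestTuneParameters:
    def test_empty_checklist_returns_table_unchanged(self, toy_plant):
        before = toy_plant.parameter_table()
        table, report = tune_parameters(toy_plant, [], budget=50, seed=0)
        assert report["evaluations"] == 0
        for k in before:
            np.testing.assert_array_equal(before[k], table[k])

    def test_satisfied_checklist_applies_no_perturbations(self, toy_plant):
        traj = toy_plant.simulate()
        # pick a species trend that already holds
        names = toy_plant.spec.species_names()
        mat = traj.species_matrix()
        deltas = mat[-1] - mat[len(mat) // 10]
        idx = int(np.argmax(np.abs(deltas)))
        direction = "up" if deltas[idx] > 0 else "down"
        before = toy_plant.parameter_table()
        _, report = tune_parameters(
            toy_plant, [DirectionalAssertion(names[idx], direction)],
            budget=50, seed=0)
        assert report["evaluations"] == 0
        for k, v in toy_plant.parameter_table().items():
            np.testing.assert_array_equal(v, before[k])

    def test_search_satisfies_reachable_objective(self):
        """A metabolite pushed down by an overstrong sink can be rescued
        by local parameter moves within the budget."""
        spec = build_toy_network(2, 2, 3, 1, seed=12)
        plant = Plant(PlantConfig(spec=spec))
        # make the terminal sink overwhelming so z2 collapses
        plant.compiled.rate_constants[-1] = 1.0
        plant.compiled.rate_constants[0] = 0.05
        item = DirectionalAssertion(spec.metabolite_names[-1], "up", level=0.2)
        assert not evaluate_assertion(item, {"main": plant.simulate()}, spec)
        _, report = tune_parameters(plant, [item], budget=200, seed=1)
        assert report["satisfied"] == 1

    def test_budget_exhaustion_reports_partial_satisfaction(self, toy_plant):
        impossible = DirectionalAssertion(toy_plant.spec.metabolite_names[0],
                                          "up", level=2.0)  # unreachable
        table, report = tune_parameters(toy_plant, [impossible], budget=5, seed=0)
        assert report["satisfied"] == 0
        assert report["evaluations"] == 5

    def test_knockouts_never_resurrected(self, toy_plant):
        ko = apply_perturbation(toy_plant, Perturbation(knockouts=(0,)))
        item = DirectionalAssertion(ko.spec.metabolite_names[0], "up", level=2.0)
        tune_parameters(ko, [item], budget=20, seed=0)
        assert ko.compiled.rate_constants[0] == 0.0


class TestParameterTableSpecRoundTrip:
    def test_table_written_back_into_spec(self, toy_spec):
        plant = Plant(PlantConfig(spec=toy_spec))
        table = plant.parameter_table()
        rng = np.random.default_rng(1)
        table["rate_constants"] = np.clip(
            table["rate_constants"] + rng.uniform(-0.04, 0.04, toy_spec.n),
            0.02, 1.0)
        spec2 = spec_with_parameter_table(toy_spec, table)
        plant2 = Plant(PlantConfig(spec=spec2))
        np.testing.assert_allclose(
            plant2.parameter_table()["rate_constants"], table["rate_constants"])


def test_build_plant_attaches_checklist_report(toy_spec):
    cfg = PlantConfig(spec=toy_spec, behavior_checklist=[
        DirectionalAssertion(toy_spec.metabolite_names[0], "up", level=-1.0),
    ])
    plant = build_plant(cfg)
    assert plant.checklist_report
    assert all(isinstance(v, (bool, np.bool_)) for v in plant.checklist_report.values())
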