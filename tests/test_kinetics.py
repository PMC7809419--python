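"""Rate laws: hand-computed oracles, nonnegativity/monotonicity/knockout
properties, and scalar-vs-compiled equivalence."""

import numpy as np
import pytest

from triscale.kinetics import (
    CompiledNetwork,
    KineticsConstraintError,
    StateVectors,
    full_derivative,
    gene_rate,
    metabolic_rates,
    signaling_rates,
)
from triscale.network import (
    GeneRule,
    InteractionRule,
    NetworkSpec,
    ReactionRule,
    build_toy_network,
)


def _state(y=None, z=None, u=None, x=None):
    return StateVectors(
        x=np.atleast_1d(x if x is not None else [1.0]),
        y=np.atleast_1d(y if y is not None else [0.0]),
        z=np.atleast_1d(z if z is not None else [0.0]),
        u=np.atleast_1d(u if u is not None else [0.0]),
    )


class TestGeneRate:
    def test_absent_transcription_factor_gives_basal_minus_decay(self):
        rule = GeneRule(0, basal_rate=0.1, decay_rate=0.05,
                        tf_activators={0: 0.5, 1: 0.7})
        st = _state(y=[0.8, 0.0])
        assert gene_rate(rule, st) == pytest.approx(0.1 - 0.05)

    def test_activated_mode_multiplies_expression_rate(self):
        # e = 0.5*0.8 = 0.4; cofactor (1 + 0.5*0.4) = 1.2 -> 1.2*0.4 + 0.1 - 0.05
        rule = GeneRule(0, basal_rate=0.1, decay_rate=0.05,
                        tf_activators={0: 0.5}, act_met={0: 0.5})
        st = _state(y=[0.8], z=[0.4])
        assert gene_rate(rule, st) == pytest.approx(0.53)

    def test_inhibited_mode_divides_numerator(self):
        # (K*y + b) / (1 + F*z) - d = (0.4 + 0.1)/1.25 - 0.05 = 0.35
        rule = GeneRule(0, basal_rate=0.1, decay_rate=0.05,
                        tf_activators={0: 0.5}, inh_met={0: 0.625})
        st = _state(y=[0.8], z=[0.4])
        assert gene_rate(rule, st) == pytest.approx(0.35)

    def test_plain_mode_is_first_branch(self):
        rule = GeneRule(0, basal_rate=0.1, decay_rate=0.05, tf_activators={0: 0.5})
        st = _state(y=[0.8])
        assert gene_rate(rule, st) == pytest.approx(0.5 * 0.8 + 0.1 - 0.05)

    def test_strict_mode_rejects_modifier_product_at_one(self):
        rule = GeneRule(0, basal_rate=0.1, decay_rate=0.05,
                        tf_activators={0: 0.5}, inh_met={0: 0.9})
        st = _state(y=[0.8], z=[1.5])  # out-of-box transient: F*z = 1.35
        with pytest.raises(KineticsConstraintError, match="gene 0"):
            gene_rate(rule, st, strict=True)
        # non-strict evaluation proceeds
        gene_rate(rule, st, strict=False)


def _one_interaction_spec(**kw):
    return NetworkSpec(
        gene_names=["g0"],
        signaling_names=["y0", "y1"],
        metabolite_names=["z0"],
        input_names=["u0"],
        gene_rules=[GeneRule(0, 0.1, 0.2, tf_activators={0: 0.5})],
        interaction_rules=[InteractionRule(0, target=0, **kw)],
        reaction_rules=[],
    )


class TestSignalingRates:
    def test_bare_activator_product(self):
        spec = _one_interaction_spec(activators={1: 0.5})
        st = StateVectors([1.0], [0.0, 0.6], [0.0], [0.0])
        assert signaling_rates(spec, st)[0] == pytest.approx(0.30)

    def test_enhancer_multiplies(self):
        spec = _one_interaction_spec(activators={1: 0.5}, enh_met={0: 0.5})
        st = StateVectors([1.0], [0.0, 0.6], [0.4], [0.0])
        assert signaling_rates(spec, st)[0] == pytest.approx(0.36)

    def test_inhibitor_divides(self):
        spec = _one_interaction_spec(activators={1: 0.5}, inh_met={0: 0.5})
        st = StateVectors([1.0], [0.0, 0.6], [0.4], [0.0])
        assert signaling_rates(spec, st)[0] == pytest.approx(0.25)

    def test_zero_activator_level_gives_zero_rate(self):
        spec = _one_interaction_spec(activators={1: 0.9})
        st = StateVectors([1.0], [0.5, 0.0], [0.9], [0.9])
        assert signaling_rates(spec, st)[0] == 0.0


def _one_reaction_spec(K=1.0, K_M=1.0, **kw):
    return NetworkSpec(
        gene_names=["g0"],
        signaling_names=["y0"],
        metabolite_names=["z0", "z1"],
        input_names=["u0"],
        gene_rules=[GeneRule(0, 0.1, 0.2, tf_activators={0: 0.5})],
        interaction_rules=[],
        reaction_rules=[ReactionRule(0, (0,), (1,), 0, K, K_M, **kw)],
    )


class TestMetabolicRates:
    def test_half_saturation(self):
        spec = _one_reaction_spec()
        st = StateVectors([1.0], [0.0], [1.0, 0.0], [0.0])
        assert metabolic_rates(spec, st)[0] == pytest.approx(0.5)

    def test_enhancer_multiplies(self):
        spec = _one_reaction_spec(enh_met={1: 0.5})
        st = StateVectors([1.0], [0.0], [1.0, 0.4], [0.0])
        assert metabolic_rates(spec, st)[0] == pytest.approx(0.6)

    def test_knockout_rate_constant_gives_exact_zero(self):
        spec = _one_reaction_spec().with_knockouts([0])
        rng = np.random.default_rng(0)
        for _ in range(20):
            st = StateVectors(rng.uniform(0, 1, 1), rng.uniform(0, 1, 1),
                              rng.uniform(0, 1, 2), rng.uniform(0, 1, 1))
            assert metabolic_rates(spec, st)[0] == 0.0

    def test_zero_substrate_gives_zero_flux(self):
        spec = _one_reaction_spec()
        st = StateVectors([1.0], [0.0], [0.0, 0.5], [0.0])
        assert metabolic_rates(spec, st)[0] == 0.0


class TestFullDerivative:
    def test_matrix_scaling_oracle(self):
        """One interaction produced at rate 0.2 feeding species 0 and
        consuming species 1: with w1 = 1/60 the fast derivative is
        (12, -12)."""
        spec = NetworkSpec(
            gene_names=["g0"],
            signaling_names=["y0", "y1"],
            metabolite_names=["z0"],
            input_names=["u0"],
            gene_rules=[GeneRule(0, 0.1, 0.2, tf_activators={0: 0.5})],
            interaction_rules=[InteractionRule(0, target=0, consumed=(1,),
                                               activators={1: 0.25})],
            reaction_rules=[],
        )
        st = StateVectors([0.0], [0.0, 0.8], [0.5], [0.5])
        _, dy, _ = full_derivative(spec, st, w1=1 / 60, w2=1.0)
        assert dy == pytest.approx([12.0, -12.0])

    def test_all_rates_zero_leaves_basal_decay_only(self, toy_spec):
        st = StateVectors(
            np.zeros(toy_spec.p), np.zeros(toy_spec.s),
            np.zeros(toy_spec.m), np.zeros(toy_spec.c),
        )
        dx, dy, dz = full_derivative(toy_spec, st, 1 / 60, 1 / 60)
        expected_dx = [r.basal_rate - r.decay_rate
                       for r in sorted(toy_spec.gene_rules, key=lambda r: r.gene_index)]
        assert dx == pytest.approx(expected_dx)
        # sources with basal rates may still fire; every rate involving a
        # zero activator/substrate is zero
        st2 = StateVectors(np.zeros(toy_spec.p), np.zeros(toy_spec.s),
                           np.zeros(toy_spec.m), np.zeros(toy_spec.c))
        r_m = metabolic_rates(toy_spec, st2)
        assert np.all(r_m == 0.0)  # enzymes at zero kill all fluxes

    def test_unit_ratios_are_identity_scaling(self, toy_spec):
        rng = np.random.default_rng(1)
        st = StateVectors(rng.uniform(0, 1, toy_spec.p), rng.uniform(0, 1, toy_spec.s),
                          rng.uniform(0, 1, toy_spec.m), rng.uniform(0, 1, toy_spec.c))
        _, dy1, dz1 = full_derivative(toy_spec, st, 1.0, 1.0)
        assert dy1 == pytest.approx(toy_spec.interaction_matrix @ signaling_rates(toy_spec, st))
        assert dz1 == pytest.approx(toy_spec.stoich_matrix @ metabolic_rates(toy_spec, st))

    def test_invalid_ratios_rejected(self, toy_spec):
        st = StateVectors(np.zeros(toy_spec.p), np.zeros(toy_spec.s),
                          np.zeros(toy_spec.m), np.zeros(toy_spec.c))
        with pytest.raises(ValueError):
            full_derivative(toy_spec, st, 0.0, 1.0)


class TestProperties:
    N_RANDOM = 10_000

    @pytest.fixture(scope="class")
    def toys(self):
        return [build_toy_network(3, 3, 4, 2, seed=s, extra_reactions=3) for s in range(3)]

    def test_rate_nonnegativity_over_random_states(self, toys):
        """r_sigma >= 0 and r_rho >= 0 for states in the unit box."""
        rng = np.random.default_rng(42)
        per_toy = self.N_RANDOM // len(toys)
        for spec in toys:
            comp = CompiledNetwork(spec)
            for _ in range(per_toy):
                x = rng.uniform(0, 1, spec.p)
                y = rng.uniform(0, 1, spec.s)
                z = rng.uniform(0, 1, spec.m)
                u = rng.uniform(0, 1, spec.c)
                assert np.all(comp.signaling_rates(x, y, z, u) >= 0)
                assert np.all(comp.metabolic_rates(x, y, z, u) >= 0)

    def test_flux_monotone_in_substrate_and_enzyme(self, toys):
        spec = toys[0]
        comp = CompiledNetwork(spec)
        rng = np.random.default_rng(7)
        x = rng.uniform(0.2, 0.8, spec.p)
        y = rng.uniform(0, 1, spec.s)
        z = rng.uniform(0.2, 0.8, spec.m)
        u = rng.uniform(0, 1, spec.c)
        for rule in spec.reaction_rules:
            rho = rule.reaction_index
            for sub in rule.substrates:
                vals = []
                for level in np.linspace(0, 1, 9):
                    z2 = z.copy()
                    z2[sub] = level
                    vals.append(comp.metabolic_rates(x, y, z2, u)[rho])
                assert np.all(np.diff(vals) >= -1e-12)
            vals = []
            for level in np.linspace(0, 1, 9):
                x2 = x.copy()
                x2[rule.catalyzing_gene] = level
                vals.append(comp.metabolic_rates(x2, y, z, u)[rho])
            assert np.all(np.diff(vals) >= -1e-12)

    def test_flux_saturates_below_kinetic_ceiling(self, toys):
        """r_rho <= K * E * (enhancer product) as substrates -> 1."""
        spec = toys[1]
        comp = CompiledNetwork(spec)
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 1, spec.p)
        y = rng.uniform(0, 1, spec.s)
        u = rng.uniform(0, 1, spec.c)
        z = np.ones(spec.m)
        rates = comp.metabolic_rates(x, y, z, u)
        for rule in spec.reaction_rules:
            enh = np.prod([1 + f for f in rule.enh_met.values()]) * np.prod(
                [1 + f for f in rule.enh_inp.values()])
            ceiling = rule.rate_constant * x[rule.catalyzing_gene] * enh
            assert rates[rule.reaction_index] <= ceiling + 1e-12

    def test_knockout_nullity_for_all_states(self, toys):
        spec = toys[2].with_knockouts(range(toys[2].n))
        comp = CompiledNetwork(spec)
        rng = np.random.default_rng(13)
        for _ in range(200):
            r = comp.metabolic_rates(
                rng.uniform(0, 1, spec.p), rng.uniform(0, 1, spec.s),
                rng.uniform(0, 1, spec.m), rng.uniform(0, 1, spec.c))
            assert np.all(r == 0.0)

    def test_plain_gene_rule_matches_first_branch(self):
        """With all modifier sets empty the gene rate is exactly
        e + b - d when the transcription-factor product is positive."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            K = rng.uniform(0.01, 0.99)
            rule = GeneRule(0, basal_rate=rng.uniform(0.01, 0.5),
                            decay_rate=rng.uniform(0.01, 0.5),
                            tf_activators={0: K})
            yv = rng.uniform(0.01, 1.0)
            st = _state(y=[yv])
            assert gene_rate(rule, st) == pytest.approx(
                K * yv + rule.basal_rate - rule.decay_rate)

    def test_compiled_matches_scalar_reference(self, toys):
        rng = np.random.default_rng(3)
        for spec in toys:
            comp = CompiledNetwork(spec)
            for _ in range(50):
                st = StateVectors(
                    rng.uniform(0, 1, spec.p), rng.uniform(0, 1, spec.s),
                    rng.uniform(0, 1, spec.m), rng.uniform(0, 1, spec.c))
                ref = full_derivative(spec, st, 1 / 60, 1 / 60)
                got = comp.derivative(st.x, st.y, st.z, st.u, 1 / 60, 1 / 60)
                for a, b in zip(ref, got):
                    np.testing.assert_allclose(a, b, atol=1e-12)
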