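# triscale

Simulation and surrogate-based control of integrated biochemical pathways
that run on three timescales: a slow gene-regulatory network, a fast
signaling network and an ultrafast metabolic network.  The package is
aimed at systems biologists who want to study how a regulated metabolic
system responds to knockouts, environmental signals and setpoint control —
the shipped application is central carbon metabolism (CCM) of a mammalian
cell and the Warburg effect in cancer cells.

## The model

States are normalized to [0, 1]: gene expressions `x ∈ R^p`, signaling
levels `y ∈ R^s`, metabolite concentrations `z ∈ R^m` and external inputs
`u ∈ R^c`.  With timescale ratios `ω₁ = ω₂ = 1/60`,

    ẋ = f(x, y, z, u)                      (transcription: slow)
    ẏ = (1/ω₁) N⁽ˢ⁾ r⁽ˢ⁾(y, z, u)          (signaling: fast)
    ż = (1/(ω₁ω₂)) N⁽ᵐ⁾ r⁽ᵐ⁾(x, z, u)      (metabolism: ultrafast)

where `N⁽ˢ⁾` and `N⁽ᵐ⁾` are ±1/0 incidence matrices, signaling rates are
products of binding-constant-weighted activator levels with
enhancer/inhibitor factors `(1 + F·level)`, gene expression rates are
`eᵢ = ∏ K yⱼ` with basal and decay terms, and metabolic fluxes follow
modified Michaelis–Menten kinetics `r = K E Z/(K_M + Z)` with `E` the
catalyzing gene's expression level and `Z` the product of substrate
concentrations.

On top of the simulator the package builds:

* a **MIMO plant** interface (`step: ⟨x,y,z,u⟩ → ⟨x,y,z⟩` over one slow
  time unit) with knockout and enzyme-signal perturbations,
* a **sliding-window dataset** (τ = 19 past input/output pairs + the
  current input; 4713 regressor elements for the packaged network),
* an **ε-insensitive SVR surrogate** (one regressor per output on a shared
  RBF Gram matrix; kernel coefficient 10, C = 100, ε = 0.0025),
* a **GA model-predictive controller** (selection above the median,
  uniform crossover, single-locus mutation with probability 0.7, elitism)
  that drives chosen plant outputs to reference values, with optional
  online surrogate adaptation,
* a **scenario registry**: normal, hypoxia, insulin deprivation, the
  six-enzyme Warburg knockout, the controlled cancer state
  (ATP → 0.95, ribose 5P → 0.70) and six drug-target cases.

See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

Simulate the packaged CCM network under normal and Warburg-knockout
conditions and compare end-of-run lactate and ATP:

```python
import numpy as np
from triscale import Plant, PlantConfig, Perturbation, apply_perturbation
from triscale.ccm import build_ccm_network, nominal_inputs, WARBURG_KNOCKOUT_ENZYMES
from triscale.kinetics import StateVectors

spec = build_ccm_network()
plant = Plant(PlantConfig(spec=spec, u_default=nominal_inputs(spec)))
init = StateVectors(np.full(spec.p, 0.5), np.full(spec.s, 0.4),
                    np.full(spec.m, 0.4), nominal_inputs(spec))
warburg = apply_perturbation(plant, Perturbation(knockouts=tuple(WARBURG_KNOCKOUT_ENZYMES)))

for label, pl in [("normal", plant), ("warburg", warburg)]:
    traj = pl.simulate(init=init.copy(), horizon=10.0, n_points=41)
    z = traj.Z[-4:].mean(axis=0)
    zi = spec.metabolite_index
    print(f"{label}: lactate={z[zi('lactate')]:.3f} atp={z[zi('atp')]:.3f} "
          f"nadph={z[zi('nadph')]:.3f}")
```

prints

```
normal: lactate=0.327 atp=0.596 nadph=0.498
warburg: lactate=0.890 atp=0.104 nadph=0.107
```

i.e. knocking out pyruvate dehydrogenase, pyruvate carboxylase, acyl-CoA
synthetase, fatty-acid synthase, PEPCK1 and succinyl-CoA synthetase shifts
the plant into fermentation: lactate roughly triples while ATP and NADPH
collapse — the Warburg phenotype.

The same experiments are available from the shell:

```
triscale simulate --network ccm --scenario warburg --out warburg.csv
triscale train-surrogate --scenario warburg --phi 800 --out model.npz
triscale control --model model.npz --reference atp=0.95 --reference r5p=0.70
triscale drug-target --case tkt_deact
```

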