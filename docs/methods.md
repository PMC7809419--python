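# Methods

`triscale` simulates an integrated biochemical system — a gene-regulatory
network, a signaling network and a metabolic network coupled across three
timescales — approximates the resulting multiple-input/multiple-output
(MIMO) plant with an ensemble of support vector regressors, and drives
selected plant outputs to reference values with a genetic-algorithm (GA)
model-predictive controller.  The shipped application is central carbon
metabolism (CCM) of a mammalian cell: the Warburg fermentation phenotype,
a setpoint-controlled "cancer" state, and six candidate drug targets.

## The three-timescale model

States are normalized to [0, 1]: gene expressions `x` (length p), signaling
levels `y` (length s), metabolite concentrations `z` (length m), external
inputs `u` (length c).  Gene-regulatory events are the slow layer; the
signaling layer runs a factor `1/w1` faster and the metabolic layer a
further `1/w2` faster (defaults w1 = w2 = 1/60, so metabolism is 3600×
faster than transcription):

    dx/dt = f(x, y, z, u)
    dy/dt = (1/w1) N_s r_s(y, z, u)
    dz/dt = (1/(w1 w2)) N_m r_m(x, z, u)

* Gene rates: `dx_i/dt = e_i·A_i + b_i − d_i` with expression rate
  `e_i = ∏ K_ij' y_j'` (product over required transcription factors),
  cofactor multiplier `A_i = ∏(1 + F z)(1 + F u)` and inhibitor divisor
  applied to `(e_i·A_i + b_i)`; if any required factor is absent the gene
  falls back to `b_i − d_i`.  Basal/decay rates are constants (not
  proportional to x), so expression levels ramp and saturate at the box
  bounds unless production and decay balance.
* Signaling rates: `r_σ = basal_σ ∏ K_jj' y_j'` with metabolite/input
  enhancer multipliers and inhibitor divisors; the interaction matrix N_s
  (entries ±1/0) routes production and degradation.
* Metabolic fluxes: `r_ρ = K_ρ E_ρ Z/(K_ρM + Z)` with `Z` the product of
  substrate concentrations (one lumped Michaelis term also for
  multi-substrate reactions) and `E_ρ` the expression level of the
  catalyzing gene; noncompetitive/allosteric modifiers multiply or divide
  the rate.  Setting `K_ρ = 0` knocks the reaction out exactly.

All binding/feedback constants live in [0, 1); kinetic and Michaelis
constants in (0, 1].

**Integration.** The coupled system is stiff (`1/(w1 w2)` = 3600).  The
default mode integrates the packed state with an implicit BDF method and a
precomputed Jacobian sparsity pattern derived from the network wiring; the
right-hand side is JIT-compiled.  States are clamped to [0, 1] at each
sample point (clamp counts are recorded).  A `nested_multirate` mode
sub-steps the fast/ultrafast layers explicitly with an RK4 cascade at
`dt·w1` and `dt·w1·w2` resolution; it mirrors the stretched-timescale
construction and is intended for small test systems.  Default tolerances
are rtol 1e-6/atol 1e-8 for analysis runs and rtol 1e-4/atol 1e-6 for
plant steps inside the data-generation and control loops.

**Quasi-steady state.** Letting the fast ratios tend to zero gives the
ultrafast equilibrium `z* = H'(x, y, u)` (root of the unscaled metabolic
derivative inside the unit box) and the fast equilibrium `y* = G(x, u)`
(solved jointly with the slaved ultrafast layer), and a reduced slow model
`dx/dt = f(x, G(x,u), H(x,u), u)`.  Roots are found by a bounded
trust-region least-squares solve with a Newton polish; ties are broken by
the solver's descent path from the box midpoint.  Conserved cofactor pools
(NAD(H), NADP(H), adenine nucleotides) make the equilibrium set a
manifold; the integrator, not the root solver, is authoritative for
pool-constrained long-run behaviour.

**Equilibrium-tracking inputs.** The external input that best
equilibrates a given state minimizes the 2-norm of the *unscaled* layer
residuals over the input box (the timescale prefactors would weight the
metabolic block 3600:1 without changing the root set).  Because many
inputs equilibrate a state almost equally well, the solve is damped with a
Tikhonov proximity term toward the previous input; without damping
successive inputs jump across the under-determined solution set and the
windowed regressors (below) become pairwise distant, which destroys the
surrogate's kernel geometry.

## The packaged CCM network

Dimensions 37 genes, 29 signaling species, 41 metabolites, 27 external
inputs (107 outputs); 62 signaling interactions, 53 reactions.  The wiring
covers glycolysis with gluconeogenic branches, the TCA cycle, the oxidative
and non-oxidative pentose phosphate pathway, fatty-acid
synthesis/consumption, oxidative phosphorylation, and lumped housekeeping
fluxes (ATP demand, NADPH-dependent ROS clearance and biosynthesis,
nucleotide synthesis, lactate/CO2 efflux); signaling covers the
growth-factor/PI3K/AKT/mTOR, RAS/ERK, JAK/STAT3, NF-κB, HIF-1α/PHD/VHL,
p53/MDM2 and LKB1/AMPK axes; glycolytic genes sit under HIF-1α/MYC,
pentose-phosphate genes under MYC (G6PD repressed by p53), gluconeogenic
genes under FOXO with insulin/AKT repression, lipogenic genes under
SREBP-1.

Deliberate lumping choices (the model is phenomenological, in normalized
units):

* The ATP-investment coupling of upper glycolysis (hexokinase, PFK) is not
  carried as an explicit ATP substrate: with it, every parameterization we
  tried collapsed into a self-amplifying ATP crash (low ATP throttles
  glycolysis which starves ATP production).  ATP homeostasis is instead
  carried by phosphoglycerate kinase/pyruvate kinase/succinyl-CoA
  synthetase/oxidative phosphorylation against a saturating lumped demand
  flux.
* The oxidative PPP senses energy charge (ATP-enhanced, ADP-inhibited) and
  glucose-6-phosphate isomerase senses it inversely (Pasteur effect);
  these couplings produce the fermentation phenotype's NADPH drop.
* Housekeeping fluxes reuse existing gene slots (ATP demand and AMP
  degradation under `atp5`, ROS clearance under `g6pd`, the
  nucleotide-synthesis drain under `idh`, NADPH-consuming biosynthesis
  under `acon`, lactate efflux under `glut1`, β-oxidation under `acsl`):
  the curated gene list has no dedicated genes for them.
* Receptor-level signaling interactions carry a `basal` rate constant
  (a pure product of upstream activators has no constant when there are
  none), and every signaling species has a first-order degradation
  interaction; both extend the ±1 interaction-matrix bookkeeping.

Kinetic constants were calibrated by the package's own
`tune_parameters` hill climb (random local perturbations ≤ 0.05,
lexicographic acceptance on the number of satisfied checklist assertions
then on signed margins) against a checklist encoding the qualitative
behaviour of the pathway: rising ribose 5P, NADPH, PEP, oxaloacetate,
citrate, FFA and G6P under fed normoxic conditions; operating-range
anchors (ATP and NADPH interior, external glucose not saturated); and the
fermentation contrasts of the six-enzyme knockout (lactate/pyruvate up;
FFA, citrate, succinate, ATP, NADPH, glucose production down; p53 up),
each with a minimum separation of 0.02.  The calibrated table ships both
inside `ccm.py` (`TUNED_PARAMETERS`) and as `data/ccm.net.yaml`.  It is a
reconstruction tuned for qualitative fidelity, not a fit to measurements.

## Plant, dataset and surrogate

The **plant** freezes a parameter table and exposes
`step(<x,y,z,u>) -> <x,y,z>`: integrate one `step_horizon` (default 1 slow
unit) under constant `u` and return the clamped state; `step` is a pure
function of its input instance.  Perturbations: knockouts (zeroed rate
constants), pinned enzyme signals (hard state overrides), reference
overrides for controller scenarios.

The **dataset** is NARX-style: the regressor stacks τ = 19 past
(input, output) pairs plus the current input (d = 4713 for the packaged
sizes; 107-dimensional target).  Generation drives the plant closed-loop —
step, solve the damped equilibrium-tracking input, add uniform excitation
jitter (amplitude 0.02) — in segments (default 50 samples) restarted from
fresh seeded random states in (0, 1), because a single settled trajectory
leaves the slow and pool coordinates unexplored; windows never straddle a
restart.  The split into train/test is seeded i.i.d. (default 65:35).

The **surrogate** is one ε-insensitive SVR per output on a shared
precomputed RBF Gram matrix (kernel coefficient 10, C = 100, ε = 0.0025,
by the reference setting).  Constant target columns short-circuit to a
bias-only model.  *Accuracy* is the percentage of test samples whose mean
squared error across all outputs is below 0.05.  Note this threshold is
lenient — most outputs move little over one step, so even coarse models
score high; the high-90s accuracies this package reproduces should be read
accordingly.

## GA model-predictive control

One GA optimization (Algorithm `evolve`): the first population is drawn
uniformly over the box; subsequent populations are seeded around the
current input (jitter radius 0.1 by default).  Selection keeps chromosomes
above the population-median fitness, recombination is uniform crossover
(single-point at index 53 — half the output length — as an alternative),
mutation rewrites one random locus of a chromosome with probability 0.7,
and elitism preserves the best.  Fitness is `1/(1 + weighted L1 error)` of
the surrogate prediction against the reference; the free (non-setpoint)
components are down-weighted (default 0.05) and take their reference
values from the surrogate's own prediction at the incumbent window.  Both
choices are load-bearing: equally weighted free components penalize every
state excursion a distant setpoint requires, and plant-side free
references make the incumbent (whose window the model knows exactly)
unbeatable against candidates that carry regression-to-the-data model
bias.

The closed loop: optimize, step the true plant with the winner, slide the
window, stop when the L1 norm of (reference − plant output) falls below
the threshold (free reference components equal the current output, so
this measures setpoint error).  The loop keeps the best state found and
reverts to it after 8 non-improving iterations (re-exploring globally),
and — when the training dataset is supplied — adapts the surrogate online:
each executed (window, output) pair is appended and the ensemble refitted
every 2 iterations on an incrementally grown Gram matrix.  Adaptation is
essential at scaled dataset sizes: the offline surrogate is accurate on
its training trajectories but nearly flat elsewhere (we measured true
single-coordinate responses of ~0.9 predicted as ~0.002), so ±0.02
setpoint precision is only available where the loop has sampled.

For the packaged cancer scenario the scaled control surrogate uses a wider
kernel (bandwidth γ = 0.5) with lag-weighted features (past blocks
weighted 0.05): at d = 4713 the γ = 10 kernel is numerically zero beyond
squared distance ~1, which makes the controller blind off-manifold; the
plant's response is Markov in the current input instance, so
de-emphasizing the history lags concentrates the kernel metric on the
coordinates that drive the response.  This is a system-identification
choice for the control task; the plain γ = 10 setting remains the default
for the surrogate-accuracy experiments.

## Shipped scenarios and problem sizes

* `normal`, `hypoxia`, `insulin_deprivation`, `warburg`: simulation
  scenarios (horizon 10 slow units, 41 samples) with directional
  assertions evaluated on means over the final 10% of samples,
  comparator-matched by seed; "no significant change" rows use a ±0.10
  flat band.
* `cancer`: six-enzyme knockout plant + GA control to ATP = 0.95 and
  ribose 5P = 0.70 (L1 threshold 0.02, up to 150 iterations; the
  20-seed robustness experiment uses 60-iteration runs and reports the
  best state per run).  The scaled control surrogate is built from
  φ = 500 window samples (65% trained on, segments of 50); GA settings:
  jitter 0.08, free-component weight 0.05, three plant-arbitrated
  candidates per iteration, refit every 2 iterations.  The
  mutated-regulation table (metabolic, signaling, gene-regulatory
  directions vs the normal run) is asserted on the controlled trajectory.
* drug-target cases: the case's reference expression level joins the
  cancer reference from the scenario midpoint (continuation of the
  converged loop, up to 60 iterations), and the outcome directions are
  asserted against the cancer baseline tails.

## What the tests do and do not show

The synthetic toy networks and the packaged CCM network exercise every
operation end to end, and the directional scenario suite checks that the
curated model reproduces the qualitative biology it was calibrated for.
Passing tests therefore demonstrate internal consistency and qualitative
fidelity, not quantitative agreement with any measured cell: the kinetic
constants are normalized reconstructions, the sliding-window surrogate is
validated against this simulator only, and the lenient MSE-threshold
accuracy metric would also admit much coarser models.

## Known limitations

The controlled experiments reproduce the setpoints reliably but the
*emergent* directional knock-ons only partially.  The controller chooses
the full input instance, so it can reach ATP = 0.95 / ribose 5P = 0.70
through routes the reconstructed network permits but a cancer cell would
not use (e.g. loading the adenine pool rather than sustaining maximal
glycolytic flux); about a third of the mutated-regulation rows and some
drug-case outcomes therefore depend on which route a seed finds.
Likewise, deactivating transketolase does not starve ribose 5P here
because the oxidative pentose-phosphate branch alone can supply it in
this wiring.  Reproducing every reported direction would require the
original (unpublished) constants or a wiring in which those routes are
essential.

Other limitations:

* Gene expression uses constant basal/decay terms, so expressions pin to
  the box bounds under sustained regulatory imbalance; directional claims
  are therefore evaluated on tail means, not absolute levels.
* The equilibrium-input problem is under-determined; the damped solution
  is one representative of a solution manifold.
* GA control of the scaled surrogate is stochastic: a minority of seeds
  stall in partial-tracking states; the scenario reports the best state
  reached per run.
* The nested multirate integrator is explicit and intended for toy
  systems; the stiff path is the production integrator.
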