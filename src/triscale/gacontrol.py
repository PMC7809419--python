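"""Genetic-algorithm model-predictive controller.

The controller drives selected plant outputs to reference values by
optimizing, at each sampling instant, the next full input instance
``<x, y, z, u>`` over the SVR surrogate:

* one GA optimization (:func:`evolve`) seeds a population around the
  current input, scores each chromosome by the surrogate-predicted output
  error against the reference, and applies selection, crossover (uniform
  by default; single-point at a fixed crossover index as an alternative),
  per-locus mutation and elitism until the fitness threshold or the
  generation budget is reached;
* the closed loop (:func:`control_loop`) alternates GA optimization,
  window update, surrogate prediction and a true plant step, retrying the
  GA when its solution's fitness regresses, and stops when the L1 norm of
  the reference error falls below a threshold.

The reference holds target values for the controlled outputs only; all
free outputs track their current values, so the L1 stopping criterion
effectively measures the setpoint error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import roll_window, window_dimension
from .network import NetworkSpec
from .plant import Plant
from .surrogate import SurrogateModel, predict

__all__ = [
    "GAConfig",
    "ReferenceOutput",
    "ControlResult",
    "fitness",
    "evolve",
    "control_loop",
]

CROSSOVER_INDEX_DEFAULT = 53  # ~half the packaged network's 107 outputs


@dataclass(frozen=True)
class GAConfig:
    """GA controller settings.

    The population size, selection weight (``None`` = population median
    fitness), fitness threshold, jitter radius used to seed chromosomes
    around the current input, and the L1 stopping threshold of the outer
    loop are free parameters of the method; the defaults are documented
    design choices.  ``mutation_prob`` is the probability that a
    chromosome is mutated (or, with ``mutation_scope='locus'``, the
    per-locus redraw probability); ``crossover_index`` applies in
    ``single_point`` mode and is placed near half the output-vector
    length.
    """

    population_size: int = 60
    max_generations: int = 10
    mutation_prob: float = 0.7
    crossover_mode: str = "uniform"
    crossover_index: int = CROSSOVER_INDEX_DEFAULT
    mutation_scope: str = "chromosome"
    selection_weight: float | None = None
    fitness_threshold: float = 0.98
    chromosome_jitter: float = 0.1
    free_weight: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation_prob must be in [0, 1]")
        if self.crossover_mode not in ("uniform", "single_point"):
            raise ValueError(f"unknown crossover_mode {self.crossover_mode!r}")
        if self.mutation_scope not in ("chromosome", "locus"):
            raise ValueError(f"unknown mutation_scope {self.mutation_scope!r}")


@dataclass(frozen=True)
class ReferenceOutput:
    """Setpoints for selected output species; all other outputs are free
    and tracked at their current values."""

    setpoints: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, val in self.setpoints.items():
            if not (0.0 < float(val) < 1.0):
                raise ValueError(f"setpoint {name!r} must be in (0, 1), got {val}")

    def indices(self, spec: NetworkSpec) -> dict[int, float]:
        names = spec.species_names()
        out = {}
        for name, val in self.setpoints.items():
            try:
                out[names.index(name)] = float(val)
            except ValueError:
                raise KeyError(f"unknown output species {name!r}") from None
        return out

    def vector(self, spec: NetworkSpec, current_output: np.ndarray) -> np.ndarray:
        """Full reference vector: setpoints where specified, the current
        output elsewhere."""
        ref = np.asarray(current_output, dtype=float).copy()
        for idx, val in self.indices(spec).items():
            ref[idx] = val
        return ref


def _predict(surrogate, V: np.ndarray) -> np.ndarray:
    """Evaluate the surrogate on a regressor batch.

    Accepts a fitted :class:`SurrogateModel` or any callable ``V -> G``
    (e.g. an exact plant map in tests)."""
    if callable(surrogate) and not isinstance(surrogate, SurrogateModel):
        return np.asarray(surrogate(V), dtype=float)
    return predict(surrogate, V)


def _updated_regressors(v_context: np.ndarray, genomes: np.ndarray) -> np.ndarray:
    """Replace the trailing current-input block of the window regressor
    with each genome; returns a (n_genomes, d) batch."""
    n_in = genomes.shape[-1]
    base = np.repeat(v_context[None, :], len(genomes), axis=0)
    base[:, -n_in:] = genomes
    return base


def fitness(
    genomes: np.ndarray,
    surrogate: SurrogateModel,
    v_context: np.ndarray,
    reference: np.ndarray,
    target_mask: np.ndarray | None = None,
    free_weight: float = 1.0,
) -> np.ndarray:
    """Fitness ``1 / (1 + ||gamma_hat - reference||_1)`` in (0, 1].

    ``genomes`` may be one chromosome (1-D) or a population batch (2-D);
    the surrogate is evaluated on the window regressor with its
    current-input block replaced by each genome.

    With a ``target_mask``, the L1 error of the non-target (free)
    components is down-weighted by ``free_weight``: the free components
    merely track their current values, and weighting them like the
    setpoints would penalize every state excursion the controller needs
    to make to reach a distant reference.
    """
    genomes = np.asarray(genomes, dtype=float)
    single = genomes.ndim == 1
    if single:
        genomes = genomes[None, :]
    if isinstance(surrogate, SurrogateModel):
        from .surrogate import predict_with_context

        pred = predict_with_context(surrogate, np.asarray(v_context, dtype=float),
                                    genomes)
    else:
        V = _updated_regressors(np.asarray(v_context, dtype=float), genomes)
        pred = _predict(surrogate, V)
    abs_err = np.abs(pred - reference[None, :])
    if target_mask is not None:
        weights = np.where(target_mask, 1.0, free_weight)
        err = (abs_err * weights[None, :]).sum(axis=1)
    else:
        err = abs_err.sum(axis=1)
    fit = 1.0 / (1.0 + err)
    return float(fit[0]) if single else fit


def _crossover(pool: np.ndarray, n_children: int, cfg: GAConfig, rng) -> np.ndarray:
    idx_a = rng.integers(len(pool), size=n_children)
    idx_b = rng.integers(len(pool), size=n_children)
    a, b = pool[idx_a].copy(), pool[idx_b]
    n_loci = pool.shape[1]
    if cfg.crossover_mode == "uniform":
        swap = rng.random((n_children, n_loci)) < 0.5
    else:
        cut = min(cfg.crossover_index, n_loci)
        swap = np.zeros((n_children, n_loci), dtype=bool)
        swap[:, cut:] = True
    a[swap] = b[swap]
    return a


def evolve(
    current_input: np.ndarray,
    v_context: np.ndarray,
    reference: np.ndarray,
    surrogate: SurrogateModel,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
    target_mask: np.ndarray | None = None,
    global_init: bool = False,
) -> tuple[np.ndarray, float, dict]:
    """One GA optimization: return the fittest input instance.

    With ``global_init`` the population is drawn uniformly over the whole
    unit box (the first optimization of a control run, before any optimal
    solution exists); otherwise it is seeded with uniform jitter around
    the current input (the incumbent itself is always included, so an
    already-optimal input is returned unchanged by elitism).
    fitness above the selection weight (population median by default,
    with a top-half fallback when the pool empties) are recombined by
    crossover and mutated (by default one random locus per mutated
    chromosome is redrawn uniformly in [0, 1]; ``mutation_scope='locus'``
    redraws each locus independently), and the best chromosome is
    preserved unchanged.  Stops once the best fitness exceeds
    ``cfg.fitness_threshold`` or after ``max_generations``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    cur = np.asarray(current_input, dtype=float)
    n_loci = len(cur)
    if global_init:
        pop = rng.uniform(0.0, 1.0, (cfg.population_size, n_loci))
    else:
        pop = np.clip(
            cur[None, :] + rng.uniform(-cfg.chromosome_jitter, cfg.chromosome_jitter,
                                       (cfg.population_size, n_loci)),
            0.0, 1.0,
        )
    pop[0] = cur

    def _fit(batch):
        return fitness(batch, surrogate, v_context, reference,
                       target_mask=target_mask, free_weight=cfg.free_weight)

    fits = _fit(pop)
    best_idx = int(np.argmax(fits))
    best, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    history = [best_fit]
    generations = 0
    while best_fit <= cfg.fitness_threshold and generations < cfg.max_generations:
        generations += 1
        cut = float(np.median(fits)) if cfg.selection_weight is None else cfg.selection_weight
        pool = pop[fits > cut]
        if len(pool) == 0:  # fallback: top half by fitness
            pool = pop[np.argsort(fits)[-max(2, len(pop) // 2):]]
        children = _crossover(pool, cfg.population_size - 1, cfg, rng)
        if cfg.mutation_scope == "locus":
            mutate = rng.random(children.shape) < cfg.mutation_prob
        else:
            # a chromosome is mutated with prob mutation_prob; a mutated
            # chromosome has one random locus redrawn uniformly in [0, 1]
            hit = rng.random(len(children)) < cfg.mutation_prob
            loci = rng.integers(children.shape[1], size=len(children))
            mutate = np.zeros(children.shape, dtype=bool)
            mutate[np.flatnonzero(hit), loci[hit]] = True
        redraw = rng.uniform(0.0, 1.0, children.shape)
        children[mutate] = redraw[mutate]
        pop = np.vstack([best[None, :], children])  # elitism
        fits = _fit(pop)
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)
    return best, best_fit, {"generations": generations, "best_fitness_history": history}


@dataclass
class ControlResult:
    """Closed-loop outcome: final input instance, convergence flag and a
    per-iteration trace (L1 error, fitness, controlled outputs)."""

    final_input: np.ndarray
    converged: bool
    iterations: int
    trace: pd.DataFrame
    final_output: np.ndarray = field(default=None)


def control_loop(
    plant: Plant,
    surrogate: SurrogateModel,
    v_init: np.ndarray,
    reference: ReferenceOutput,
    l1_threshold: float = 0.02,
    max_iter: int = 30,
    cfg: GAConfig | None = None,
    train_data=None,
    refit_every: int = 1,
    revert_after: int = 8,
    arbitrate: int = 1,
) -> ControlResult:
    """Closed-loop setpoint control of the plant through the surrogate.

    Per iteration: run one GA optimization from the current input, slide
    the window forward with the optimized input and the true plant
    output, and evaluate the L1 norm of (reference - plant output) —
    free reference components equal the current output, so the criterion
    measures the setpoint error.  If the GA solution's fitness regresses
    relative to the previous iteration, the GA is retried once with fresh
    randomness.  The loop keeps the best state found; after
    ``revert_after`` iterations without improvement it reverts to it
    (restart from the incumbent optimum).  Non-convergence returns a
    structured failure (converged = False) with the full trace.

    With ``train_data`` (the dataset the surrogate was fitted on) the
    surrogate is adapted online: every executed (window, plant output)
    pair is appended and the ensemble refitted every ``refit_every``
    iterations, so the model sharpens along the loop's own path — the
    fixed offline surrogate only carries coarse information away from its
    training trajectories.

    With ``arbitrate > 1``, each iteration additionally evaluates that
    many close variants of the GA winner on the true plant and commits
    the one with the lowest true setpoint error (the plant is stepped
    every iteration anyway; arbitration spends a couple of extra steps to
    let the plant, not the model, resolve near-ties).
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    spec = plant.spec
    p, s, m, c = spec.dims
    n_in, n_out = p + s + m + c, p + s + m
    tau = (len(v_init) - n_in) // (n_in + n_out)
    if window_dimension(tau, p, s, m, c) != len(v_init):
        raise ValueError("v_init length inconsistent with plant dimensions")

    # reconstruct the rolling history from the initial window
    from .dataset import WindowSample, unroll_window

    inputs, outputs = unroll_window(WindowSample(np.asarray(v_init, float), np.zeros(n_out), tau),
                                    tau, spec.dims)
    hist_in = [inputs[k] for k in range(tau)] + [inputs[tau]]
    hist_out = [outputs[k] for k in range(tau)]

    current_input = hist_in[-1].copy()
    current_output = plant.step(current_input)
    hist_out.append(current_output)

    target_mask = np.zeros(n_out, dtype=bool)
    for idx in reference.indices(spec):
        target_mask[idx] = True

    from .dataset import Dataset as _Dataset
    from .surrogate import fit as _fit_surrogate

    adapt = train_data is not None and isinstance(surrogate, SurrogateModel)
    if adapt:
        from .surrogate import gram_matrix

        V_base = np.asarray(train_data.V, dtype=float)
        G_base = np.asarray(train_data.G, dtype=float)
        V_aug = [V_base]
        G_aug = [G_base]
        hp0 = surrogate.hyperparams
        K_aug = gram_matrix(V_base, hp0, p + s + m + c)
        hw_sqrt = np.sqrt(hp0.history_weight) if hp0.history_weight < 1.0 else 1.0
        w_feat = np.full(V_base.shape[1], hw_sqrt)
        w_feat[-(p + s + m + c):] = 1.0

    rows = []
    prev_fit = -np.inf
    converged = False
    v_current = np.asarray(v_init, dtype=float).copy()
    best_l1 = np.inf
    best_pack = None
    since_best = 0
    just_reverted = False
    for it in range(1, max_iter + 1):
        # free reference components track the surrogate's own prediction at
        # the incumbent window, so candidate fitness measures predicted
        # *change*: the model's regression-to-the-data bias is shared by
        # incumbent and candidates and cancels instead of freezing the
        # loop on the incumbent.
        predicted_current = _predict(surrogate, v_current[None, :])[0]
        ref_vec = reference.vector(spec, predicted_current)
        best, best_fit, info = evolve(current_input, v_current, ref_vec, surrogate,
                                      cfg, rng, target_mask=target_mask,
                                      global_init=(it == 1 or just_reverted))
        just_reverted = False
        if it > 1 and best_fit < prev_fit:
            # fitness regressed: try again, re-exploring the whole box
            best2, fit2, info2 = evolve(current_input, v_current, ref_vec, surrogate,
                                        cfg, rng, target_mask=target_mask,
                                        global_init=True)
            if fit2 > best_fit:
                best, best_fit, info = best2, fit2, info2
        prev_fit = best_fit

        # candidate set: the GA winner plus close variants; the true plant
        # arbitrates by setpoint error
        n_in = p + s + m + c
        cands = [best]
        for _ in range(max(0, arbitrate - 1)):
            cands.append(np.clip(best + rng.uniform(-0.04, 0.04, n_in), 0.0, 1.0))
        new_input = None
        plant_out = None
        cand_l1 = np.inf
        for cand in cands:
            out_c = plant.step(cand)
            ref_c = reference.vector(spec, out_c)
            l1_c = float(np.abs(ref_c - out_c).sum())
            if adapt:
                v_c = v_current.copy()
                v_c[-n_in:] = cand
                V_all = np.vstack(V_aug)
                new_row = np.exp(-hp0.kernel_coef * (
                    ((V_all - v_c[None, :]) * w_feat[None, :]) ** 2).sum(axis=1))
                K_aug = np.block([
                    [K_aug, new_row[:, None]],
                    [new_row[None, :], np.ones((1, 1))],
                ])
                V_aug.append(v_c[None, :])
                G_aug.append(out_c[None, :])
            if l1_c < cand_l1:
                new_input, plant_out, cand_l1 = cand, out_c, l1_c
        hist_in.append(new_input)
        hist_out.append(plant_out)
        ins = np.asarray(hist_in[-(tau + 1):])
        outs = np.asarray(hist_out[-(tau + 1):])
        ws = roll_window(ins, outs, theta=tau, tau=tau)
        v_current = ws.v
        current_input = new_input
        current_output = plant_out

        ref_now = reference.vector(spec, plant_out)
        l1 = float(np.abs(ref_now - plant_out).sum())
        row = {"iteration": it, "l1": l1, "fitness": best_fit,
               "generations": info["generations"]}
        names = spec.species_names()
        for name in reference.setpoints:
            row[name] = float(plant_out[names.index(name)])
        rows.append(row)
        if l1 < best_l1 - 1e-12:
            best_l1 = l1
            best_pack = (current_input.copy(), current_output.copy(), v_current.copy())
            since_best = 0
        else:
            since_best += 1
        if l1 < l1_threshold:
            converged = True
            break
        if adapt and it % refit_every == 0:
            aug = _Dataset(V=np.vstack(V_aug), G=np.vstack(G_aug),
                           meta=dict(getattr(train_data, "meta", {})))
            surrogate = _fit_surrogate(aug, hp0, gram=K_aug)
        if since_best >= revert_after and best_pack is not None:
            current_input, current_output, v_current = (
                best_pack[0].copy(), best_pack[1].copy(), best_pack[2].copy())
            since_best = 0
            just_reverted = True

    if not converged and best_pack is not None:
        # report the best state found rather than the last explored one
        current_input, current_output, _ = best_pack

    return ControlResult(
        final_input=current_input,
        converged=converged,
        iterations=len(rows),
        trace=pd.DataFrame(rows),
        final_output=current_output,
    )
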