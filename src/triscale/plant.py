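"""MIMO plant: the integrated-pathway simulator behind a step interface.

The plant wraps a compiled network with frozen kinetic parameters and
exposes the input/output contract used by dataset generation and control:
one *input instance* is the concatenation ``<x, y, z, u>`` of length
``p + s + m + c``; one *output instance* is the state ``<x, y, z>`` of
length ``p + s + m`` reached after integrating one ``step_horizon`` of
slow time under the constant input ``u``.  ``step`` is a pure function of
its input instance.

Perturbations modify a plant without touching the base network definition:

* knockouts zero the kinetic rate constant of the targeted reactions (all
  reactions catalyzed by a named enzyme gene), so the knocked fluxes are
  identically zero;
* enzyme signals pin named gene/protein state components to externally
  imposed levels in (0, 1) for the whole step (hard overrides);
* reference overrides are carried along for controller scenarios.

``tune_parameters`` implements the calibration protocol used to build the
shipped parameter set: random local perturbations of the kinetic constants
(step <= 0.05), hill-climbing on the number of satisfied directional
checklist assertions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .kinetics import CompiledNetwork, StateVectors
from .network import NetworkSpec
from .simulate import TimescaleConfig, Trajectory, integrate

__all__ = [
    "PlantConfig",
    "Perturbation",
    "DirectionalAssertion",
    "Plant",
    "build_plant",
    "apply_perturbation",
    "evaluate_assertion",
    "assertion_margin",
    "tune_parameters",
]


@dataclass
class PlantConfig:
    """Plant construction parameters.

    ``init_seed`` draws the initial concentrations/expressions uniformly in
    (0, 1); with fixed seeds the plant is fully reproducible.
    ``step_horizon`` is the slow-time length of one plant step (the
    sampling period of the input/output interface).
    """

    spec: NetworkSpec
    init_seed: int = 0
    param_seed: int = 0
    step_horizon: float = 1.0
    w1: float = 1.0 / 60.0
    w2: float = 1.0 / 60.0
    rel_tol: float = 1e-4
    abs_tol: float = 1e-6
    clamp: bool = True
    u_default: np.ndarray | None = None
    behavior_checklist: list = field(default_factory=list)


@dataclass(frozen=True)
class Perturbation:
    """Knockouts (enzyme gene names or reaction indices), pinned enzyme
    signals (species name -> level in (0, 1)) and reference overrides for
    controller scenarios."""

    knockouts: tuple = ()
    enzyme_signals: Mapping[str, float] = field(default_factory=dict)
    reference_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, level in self.enzyme_signals.items():
            if not (0.0 < float(level) < 1.0):
                raise ValueError(f"enzyme signal {name!r} must be in (0, 1), got {level}")


@dataclass(frozen=True)
class DirectionalAssertion:
    """One machine-checkable qualitative claim about simulated behaviour.

    With ``baseline=None`` the claim is a trend within the run named
    ``run``: the mean over the final ``tail`` fraction of samples is
    compared against the value at the ``start`` fraction of the horizon
    (the earliest samples are excluded because the fast layers relax from
    arbitrary initial conditions).  With a ``baseline`` run name, the
    claim compares tail means across two runs (comparator matched by
    seed).
    """

    species: str
    direction: str  # "up" | "down"
    run: str = "main"
    baseline: str | None = None
    tail: float = 0.1
    start: float = 0.1
    min_delta: float = 0.0
    level: float | None = None  # absolute reference level instead of a run

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")


def _species_column(spec: NetworkSpec, traj: Trajectory, name: str) -> np.ndarray:
    names = spec.species_names()
    try:
        idx = names.index(name)
    except ValueError:
        raise KeyError(f"unknown species {name!r}") from None
    return traj.species_matrix()[:, idx]


def _tail_mean(col: np.ndarray, frac: float) -> float:
    k = max(1, int(np.ceil(frac * len(col))))
    return float(col[-k:].mean())


def evaluate_assertion(
    item: DirectionalAssertion,
    trajs: Mapping[str, Trajectory],
    spec: NetworkSpec,
) -> bool:
    delta = assertion_margin(item, trajs, spec)
    return delta > 0


def assertion_margin(
    item: DirectionalAssertion,
    trajs: Mapping[str, Trajectory],
    spec: NetworkSpec,
) -> float:
    """Signed margin of an assertion: positive iff it passes, and how far
    past its minimum separation the comparison lies."""
    col = _species_column(spec, trajs[item.run], item.species)
    end = _tail_mean(col, item.tail)
    if item.level is not None:
        ref = item.level
    elif item.baseline is None:
        i0 = min(len(col) - 1, int(np.floor(item.start * len(col))))
        ref = float(col[i0])
    else:
        ref = _tail_mean(_species_column(spec, trajs[item.baseline], item.species), item.tail)
    delta = end - ref
    return (delta - item.min_delta) if item.direction == "up" else (-delta - item.min_delta)


class Plant:
    """The simulated MIMO system with frozen parameters.

    Parameters (kinetic rate and Michaelis constants, modifier strengths)
    live in the compiled network's mutable arrays; the underlying
    :class:`NetworkSpec` is never modified.
    """

    def __init__(self, cfg: PlantConfig):
        self.cfg = cfg
        self.spec = cfg.spec
        self.compiled = CompiledNetwork(cfg.spec)
        self.pinned: dict[int, float] = {}  # packed-state index -> level
        self.perturbation: Perturbation | None = None
        p, s, m, c = self.spec.dims
        self.in_dim = p + s + m + c
        self.out_dim = p + s + m
        if cfg.u_default is None:
            self.u_default = np.full(c, 0.5)
        else:
            self.u_default = np.asarray(cfg.u_default, dtype=float)

    # -- construction helpers -------------------------------------------
    def initial_state(self) -> StateVectors:
        """Random initial concentrations/expressions in (0, 1), seeded."""
        rng = np.random.default_rng(self.cfg.init_seed)
        p, s, m, c = self.spec.dims
        sv = StateVectors(
            x=rng.uniform(0.0, 1.0, p),
            y=rng.uniform(0.0, 1.0, s),
            z=rng.uniform(0.0, 1.0, m),
            u=self.u_default.copy(),
        )
        self._apply_pins_state(sv)
        return sv

    def initial_instance(self) -> np.ndarray:
        return self.initial_state().concat()

    def parameter_table(self) -> dict[str, np.ndarray]:
        comp = self.compiled
        return {
            "rate_constants": comp.rate_constants.copy(),
            "michaelis_constants": comp.michaelis_constants.copy(),
            "reaction_enh": comp._m_enh.const.copy(),
            "reaction_inh": comp._m_inh.const.copy(),
        }

    def set_parameter_table(self, table: Mapping[str, np.ndarray]) -> None:
        comp = self.compiled
        comp.rate_constants[:] = table["rate_constants"]
        comp.michaelis_constants[:] = table["michaelis_constants"]
        comp._m_enh.const[:] = table["reaction_enh"]
        comp._m_inh.const[:] = table["reaction_inh"]

    # -- perturbations ---------------------------------------------------
    def _resolve_knockouts(self, knockouts: Sequence) -> list[int]:
        out: list[int] = []
        for item in knockouts:
            if isinstance(item, str):
                try:
                    g = self.spec.gene_index(item)
                except ValueError:
                    raise KeyError(f"unknown enzyme gene {item!r}") from None
                out.extend(
                    r.reaction_index
                    for r in self.spec.reaction_rules
                    if r.catalyzing_gene == g
                )
            else:
                idx = int(item)
                if not (0 <= idx < self.spec.n):
                    raise KeyError(f"unknown reaction index {idx}")
                out.append(idx)
        return out

    def _packed_index(self, name: str) -> int:
        p, s = self.spec.p, self.spec.s
        if name in self.spec.gene_names:
            return self.spec.gene_index(name)
        if name in self.spec.signaling_names:
            return p + self.spec.signal_index(name)
        if name in self.spec.metabolite_names:
            return p + s + self.spec.metabolite_index(name)
        raise KeyError(f"unknown species {name!r}")

    def _apply_pins_state(self, sv: StateVectors) -> None:
        p, s = self.spec.p, self.spec.s
        for idx, level in self.pinned.items():
            if idx < p:
                sv.x[idx] = level
            elif idx < p + s:
                sv.y[idx - p] = level
            else:
                sv.z[idx - p - s] = level

    # -- dynamics --------------------------------------------------------
    def _system(self):
        if not self.pinned:
            return self.compiled
        return _PinnedSystem(self.compiled, self.pinned)

    def _tsc(self, t_grid: np.ndarray) -> TimescaleConfig:
        cfg = self.cfg
        return TimescaleConfig(
            w1=cfg.w1,
            w2=cfg.w2,
            t_grid=t_grid,
            abs_tol=cfg.abs_tol,
            rel_tol=cfg.rel_tol,
            clamp=cfg.clamp,
        )

    def step(self, input_instance: np.ndarray) -> np.ndarray:
        """One plant step: integrate ``step_horizon`` from the given
        ``<x, y, z, u>`` and return the clamped ``<x, y, z>`` reached."""
        vec = np.asarray(input_instance, dtype=float)
        if vec.shape != (self.in_dim,):
            raise ValueError(f"input instance must have length {self.in_dim}, got {vec.shape}")
        sv = StateVectors.from_concat(vec, self.spec.dims)
        self._apply_pins_state(sv)
        t_grid = np.array([0.0, self.cfg.step_horizon])
        traj = integrate(self._system(), sv, sv.u, self._tsc(t_grid))
        out = np.concatenate([traj.X[-1], traj.Y[-1], traj.Z[-1]])
        for idx, level in self.pinned.items():
            out[idx] = level
        return np.clip(out, 0.0, 1.0)

    def simulate(
        self,
        init: StateVectors | None = None,
        u_policy=None,
        horizon: float = 10.0,
        n_points: int = 51,
    ) -> Trajectory:
        init = init or self.initial_state()
        init = init.copy()
        self._apply_pins_state(init)
        if u_policy is None:
            u_policy = self.u_default
        t_grid = np.linspace(0.0, horizon, n_points)
        return integrate(self._system(), init, u_policy, self._tsc(t_grid))


class _PinnedSystem:
    """Compiled-network wrapper that pins selected packed-state components
    (enzyme-signal overrides): level forced, derivative zeroed."""

    def __init__(self, comp: CompiledNetwork, pinned: Mapping[int, float]):
        self._comp = comp
        self.p, self.s, self.m, self.c = comp.p, comp.s, comp.m, comp.c
        self.idx = np.array(sorted(pinned), dtype=np.int64)
        self.levels = np.array([pinned[i] for i in sorted(pinned)])

    def rhs(self, w1, w2, u_of_t, clip=True):
        inner = self._comp.rhs(w1, w2, u_of_t, clip=clip)

        def fun(t, v):
            v = v.copy()
            v[self.idx] = self.levels
            dv = inner(t, v)
            dv[self.idx] = 0.0
            return dv

        return fun

    def derivative(self, x, y, z, u, w1, w2):
        return self._comp.derivative(x, y, z, u, w1, w2)

    def jac_sparsity(self):
        return self._comp.jac_sparsity()


def build_plant(cfg: PlantConfig) -> Plant:
    """Build a plant with frozen parameters; if the config carries a
    behaviour checklist, verify it on the nominal simulation and attach
    the report (``plant.checklist_report``)."""
    plant = Plant(cfg)
    if cfg.behavior_checklist:
        traj = plant.simulate()
        results = {
            (i.species, i.direction): evaluate_assertion(i, {"main": traj}, cfg.spec)
            for i in cfg.behavior_checklist
        }
        plant.checklist_report = results
    else:
        plant.checklist_report = {}
    return plant


def apply_perturbation(plant: Plant, pert: Perturbation) -> Plant:
    """Return a new plant with the perturbation applied; the original is
    untouched."""
    new = Plant(plant.cfg)
    new.set_parameter_table(plant.parameter_table())
    new.pinned = dict(plant.pinned)
    ko = new._resolve_knockouts(pert.knockouts)
    new.compiled.set_knockouts(ko)
    for name, level in pert.enzyme_signals.items():
        new.pinned[new._packed_index(name)] = float(level)
    for name in pert.reference_overrides:
        new._packed_index(name)  # existence check
    new.perturbation = pert
    new.checklist_report = getattr(plant, "checklist_report", {})
    return new


def tune_parameters(
    plant: Plant,
    checklist: Sequence[DirectionalAssertion],
    budget: int = 200,
    seed: int = 0,
    make_runs: Callable[[Plant], Mapping[str, Trajectory]] | None = None,
    step: float = 0.05,
) -> tuple[dict[str, np.ndarray], dict]:
    """Hill-climb the plant's kinetic parameter table against a checklist.

    Random local perturbations (uniform, magnitude <= ``step``) are applied
    to a random subset of the kinetic rate constants, Michaelis constants
    and reaction-modifier strengths; a candidate is kept when it satisfies
    at least as many checklist items as the incumbent and strictly more on
    improvement steps.  Returns the best parameter table (also installed
    into the plant) and a report; exhausting the budget yields the
    best-found table with a partial-satisfaction report rather than an
    exception.
    """
    if make_runs is None:
        make_runs = lambda pl: {"main": pl.simulate()}

    def score(pl):
        trajs = make_runs(pl)
        margins = [assertion_margin(item, trajs, pl.spec) for item in checklist]
        results = [mg > 0 for mg in margins]
        # lexicographic: satisfied count first, then clipped margin mass so
        # the climb is guided toward (and not away from) failing items
        margin_mass = float(np.sum(np.clip(margins, -0.5, 0.05)))
        return (sum(results), margin_mass), results

    rng = np.random.default_rng(seed)
    best_table = plant.parameter_table()
    best_score, best_results = score(plant)
    n_items = len(checklist)
    evals = 0
    while best_score[0] < n_items and evals < budget:
        cand = {k: v.copy() for k, v in best_table.items()}
        for key, lo, hi in [
            ("rate_constants", 0.02, 1.0),
            ("michaelis_constants", 0.05, 1.0),
            ("reaction_enh", 0.0, 0.95),
            ("reaction_inh", 0.0, 0.95),
        ]:
            arr = cand[key]
            if arr.size == 0:
                continue
            mask = rng.random(arr.size) < 0.15
            if key == "rate_constants":
                mask &= best_table[key] > 0.0  # never resurrect knockouts
            arr[mask] = np.clip(arr[mask] + rng.uniform(-step, step, mask.sum()), lo, hi)
        plant.set_parameter_table(cand)
        s, results = score(plant)
        evals += 1
        if s >= best_score:
            best_score, best_results, best_table = s, results, cand
    plant.set_parameter_table(best_table)
    report = {
        "satisfied": best_score[0],
        "margin_mass": best_score[1],
        "total": n_items,
        "evaluations": evals,
        "results": {
            (item.species, item.direction, item.baseline): ok
            for item, ok in zip(checklist, best_results)
        },
    }
    return best_table, report


def spec_with_parameter_table(spec: NetworkSpec, table: Mapping[str, np.ndarray]) -> NetworkSpec:
    """Write a plant parameter table back into a new :class:`NetworkSpec`.

    Reaction rate/Michaelis constants and modifier strengths are replaced
    by the table's values (modifier values map back in rule declaration
    order, mirroring the compiled layout).
    """
    K = np.asarray(table["rate_constants"], dtype=float)
    KM = np.asarray(table["michaelis_constants"], dtype=float)
    enh = list(np.asarray(table["reaction_enh"], dtype=float))
    inh = list(np.asarray(table["reaction_inh"], dtype=float))
    enh_pos = inh_pos = 0
    rules = []
    for i, rule in enumerate(spec.reaction_rules):
        n_enh = len(rule.enh_met) + len(rule.enh_inp)
        n_inh = len(rule.inh_met) + len(rule.inh_inp)
        e_vals = enh[enh_pos:enh_pos + max(n_enh, 1)][:n_enh] if n_enh else []
        i_vals = inh[inh_pos:inh_pos + max(n_inh, 1)][:n_inh] if n_inh else []
        enh_pos += max(n_enh, 1)  # empty rows carry one padding slot
        inh_pos += max(n_inh, 1)
        e_it = iter(e_vals)
        i_it = iter(i_vals)
        rules.append(replace(
            rule,
            rate_constant=float(K[i]),
            michaelis_constant=float(KM[i]),
            enh_met={k: float(next(e_it)) for k in rule.enh_met},
            enh_inp={k: float(next(e_it)) for k in rule.enh_inp},
            inh_met={k: float(next(i_it)) for k in rule.inh_met},
            inh_inp={k: float(next(i_it)) for k in rule.inh_inp},
        ))
    return NetworkSpec(
        gene_names=list(spec.gene_names),
        signaling_names=list(spec.signaling_names),
        metabolite_names=list(spec.metabolite_names),
        input_names=list(spec.input_names),
        gene_rules=list(spec.gene_rules),
        interaction_rules=list(spec.interaction_rules),
        reaction_rules=rules,
        display_names=dict(spec.display_names),
    )
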