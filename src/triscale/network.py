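"""Network specifications for integrated pathway models.

A :class:`NetworkSpec` describes one integrated system of three coupled
layers:

* a gene-regulatory layer of ``p`` genes whose expression levels feed the
  metabolic layer as enzyme levels,
* a signaling layer of ``s`` proteins/transcription factors wired through an
  s x q interaction matrix ``N_s`` (entries in {-1, 0, +1}),
* a metabolic layer of ``m`` metabolites wired through an m x n
  stoichiometric matrix ``N_m`` (entries in {-1, 0, +1}),

plus ``c`` external inputs representing the environment (nutrient supply,
oxygen, hormones, growth factors, ...).

All species levels and all binding/kinetic constants live in normalized
units: levels in [0, 1], binding and feedback constants in [0, 1), kinetic
rate and Michaelis constants in (0, 1].

Specs are serialized to a human-readable YAML dialect (extension
``.net.yaml``) in which species are referenced by name; in memory the rules
use integer indices for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GeneRule",
    "InteractionRule",
    "ReactionRule",
    "NetworkSpec",
    "NetworkValidationError",
    "validate_network",
    "load_network",
    "save_network",
    "build_toy_network",
]

FORMAT_TAG = "triscale-network/1"


class NetworkValidationError(ValueError):
    """A network specification violates one of its structural invariants."""


def _as_fmap(d: Mapping[int, float] | None) -> dict[int, float]:
    return {int(k): float(v) for k, v in (d or {}).items()}


@dataclass(frozen=True)
class GeneRule:
    """Transcription rule for one gene.

    The expression rate is the product of binding-constant-weighted
    transcription-factor levels, ``e_i = prod_j' K_ij' * y_j'``.  Metabolite
    and external-input cofactors multiply ``e_i`` by ``(1 + F*level)``
    factors; inhibitors (metabolites, inputs or other signaling molecules)
    divide ``e_i + b_i`` by the analogous factors.  If any required
    transcription factor is absent (level 0) the gene falls back to basal
    production minus decay.
    """

    gene_index: int
    basal_rate: float
    decay_rate: float
    tf_activators: dict[int, float] = field(default_factory=dict)
    act_met: dict[int, float] = field(default_factory=dict)
    act_inp: dict[int, float] = field(default_factory=dict)
    inh_met: dict[int, float] = field(default_factory=dict)
    inh_inp: dict[int, float] = field(default_factory=dict)
    inh_sig: dict[int, float] = field(default_factory=dict)

    @property
    def mode(self) -> str:
        has_act = bool(self.act_met or self.act_inp)
        has_inh = bool(self.inh_met or self.inh_inp or self.inh_sig)
        if has_act and has_inh:
            return "mixed"
        if has_act:
            return "activated"
        if has_inh:
            return "inhibited"
        return "plain"


@dataclass(frozen=True)
class InteractionRule:
    """One signaling interaction (column of ``N_s``).

    ``target`` is the species produced/activated (the +1 entry of the
    column); ``consumed`` are species consumed by the interaction (the -1
    entries).  Pure consumption (degradation) interactions have
    ``target=None``.  The initial rate is ``basal * prod_j' K_jj' * y_j'``;
    ``basal`` exists so that receptor-level source interactions with no
    upstream activator still carry a rate constant.  Metabolite and input
    enhancers multiply the rate; metabolite, input and signaling inhibitors
    divide it.
    """

    interaction_index: int
    target: int | None
    activators: dict[int, float] = field(default_factory=dict)
    consumed: tuple[int, ...] = ()
    basal: float = 1.0
    enh_met: dict[int, float] = field(default_factory=dict)
    enh_inp: dict[int, float] = field(default_factory=dict)
    inh_met: dict[int, float] = field(default_factory=dict)
    inh_inp: dict[int, float] = field(default_factory=dict)
    inh_sig: dict[int, float] = field(default_factory=dict)

    @property
    def mode(self) -> str:
        has_enh = bool(self.enh_met or self.enh_inp)
        has_inh = bool(self.inh_met or self.inh_inp or self.inh_sig)
        if has_enh and has_inh:
            return "mixed"
        if has_enh:
            return "enhanced"
        if has_inh:
            return "inhibited"
        return "plain"


@dataclass(frozen=True)
class ReactionRule:
    """One enzymatic reaction (column of ``N_m``).

    Saturating kinetics ``K * E * Z / (K_M + Z)`` with ``Z`` the product of
    substrate concentrations and ``E`` the expression level of the
    catalyzing gene.  Metabolite/input enhancers multiply the rate,
    inhibitors divide it (noncompetitive/allosteric modulation).  Setting
    ``rate_constant`` to zero knocks the reaction out.
    """

    reaction_index: int
    substrates: tuple[int, ...]
    products: tuple[int, ...]
    catalyzing_gene: int
    rate_constant: float
    michaelis_constant: float
    enh_met: dict[int, float] = field(default_factory=dict)
    enh_inp: dict[int, float] = field(default_factory=dict)
    inh_met: dict[int, float] = field(default_factory=dict)
    inh_inp: dict[int, float] = field(default_factory=dict)

    @property
    def mode(self) -> str:
        has_enh = bool(self.enh_met or self.enh_inp)
        has_inh = bool(self.inh_met or self.inh_inp)
        if has_enh and has_inh:
            return "mixed"
        if has_enh:
            return "enhanced"
        if has_inh:
            return "inhibited"
        return "plain"


def _matrix_from_rules(n_rows: int, rules: Sequence, plus, minus) -> np.ndarray:
    mat = np.zeros((n_rows, len(rules)), dtype=np.int8)
    for col, rule in enumerate(rules):
        for r in plus(rule):
            mat[r, col] = 1
        for r in minus(rule):
            mat[r, col] = -1
    return mat


@dataclass
class NetworkSpec:
    """Full integrated-pathway definition.

    Dimensions are conventionally named ``p`` (genes), ``s`` (signaling
    species), ``m`` (metabolites), ``c`` (external inputs), ``q``
    (signaling interactions) and ``n`` (metabolic reactions).
    """

    gene_names: list[str]
    signaling_names: list[str]
    metabolite_names: list[str]
    input_names: list[str]
    gene_rules: list[GeneRule]
    interaction_rules: list[InteractionRule]
    reaction_rules: list[ReactionRule]
    display_names: dict[str, str] = field(default_factory=dict)
    interaction_matrix: np.ndarray | None = None
    stoich_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.interaction_matrix is None:
            self.interaction_matrix = _matrix_from_rules(
                self.s,
                self.interaction_rules,
                plus=lambda r: [] if r.target is None else [r.target],
                minus=lambda r: r.consumed,
            )
        else:
            self.interaction_matrix = np.asarray(self.interaction_matrix, dtype=np.int8)
        if self.stoich_matrix is None:
            self.stoich_matrix = _matrix_from_rules(
                self.m,
                self.reaction_rules,
                plus=lambda r: r.products,
                minus=lambda r: r.substrates,
            )
        else:
            self.stoich_matrix = np.asarray(self.stoich_matrix, dtype=np.int8)

    # -- dimensions -----------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.gene_names)

    @property
    def s(self) -> int:
        return len(self.signaling_names)

    @property
    def m(self) -> int:
        return len(self.metabolite_names)

    @property
    def c(self) -> int:
        return len(self.input_names)

    @property
    def q(self) -> int:
        return len(self.interaction_rules)

    @property
    def n(self) -> int:
        return len(self.reaction_rules)

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (self.p, self.s, self.m, self.c)

    # -- lookups --------------------------------------------------------
    def gene_index(self, name: str) -> int:
        return self.gene_names.index(name)

    def signal_index(self, name: str) -> int:
        return self.signaling_names.index(name)

    def metabolite_index(self, name: str) -> int:
        return self.metabolite_names.index(name)

    def input_index(self, name: str) -> int:
        return self.input_names.index(name)

    def species_names(self) -> list[str]:
        """Canonical output ordering: genes, then signaling, then metabolites."""
        return list(self.gene_names) + list(self.signaling_names) + list(self.metabolite_names)

    def with_knockouts(self, reaction_indices: Sequence[int]) -> "NetworkSpec":
        """Copy of the spec with the given reactions' rate constants zeroed."""
        ko = set(int(i) for i in reaction_indices)
        bad = ko - set(range(self.n))
        if bad:
            raise KeyError(f"unknown reaction indices: {sorted(bad)}")
        rules = [
            replace(r, rate_constant=0.0) if r.reaction_index in ko else r
            for r in self.reaction_rules
        ]
        return NetworkSpec(
            gene_names=list(self.gene_names),
            signaling_names=list(self.signaling_names),
            metabolite_names=list(self.metabolite_names),
            input_names=list(self.input_names),
            gene_rules=list(self.gene_rules),
            interaction_rules=list(self.interaction_rules),
            reaction_rules=rules,
            display_names=dict(self.display_names),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkSpec):
            return NotImplemented
        return (
            self.gene_names == other.gene_names
            and self.signaling_names == other.signaling_names
            and self.metabolite_names == other.metabolite_names
            and self.input_names == other.input_names
            and self.gene_rules == other.gene_rules
            and self.interaction_rules == other.interaction_rules
            and self.reaction_rules == other.reaction_rules
            and np.array_equal(self.interaction_matrix, other.interaction_matrix)
            and np.array_equal(self.stoich_matrix, other.stoich_matrix)
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_range(d: Mapping[int, float], limit: int, field_name: str, what: str) -> None:
    for idx, val in d.items():
        if not (0 <= idx < limit):
            raise NetworkValidationError(f"{field_name}: {what} index {idx} out of range [0, {limit})")
        if not (0.0 <= val < 1.0):
            raise NetworkValidationError(f"{field_name}: constant {val!r} for index {idx} outside [0, 1)")


def validate_network(spec: NetworkSpec) -> NetworkSpec:
    """Check every structural invariant; return the spec if all hold.

    Raises :class:`NetworkValidationError` naming the offending field.
    """
    p, s, m, c = spec.dims
    for names, label in [
        (spec.gene_names, "gene_names"),
        (spec.signaling_names, "signaling_names"),
        (spec.metabolite_names, "metabolite_names"),
        (spec.input_names, "input_names"),
    ]:
        if len(set(names)) != len(names):
            raise NetworkValidationError(f"{label}: duplicate species names")

    Ns = spec.interaction_matrix
    Nm = spec.stoich_matrix
    if Ns.shape != (s, spec.q):
        raise NetworkValidationError(
            f"interaction_matrix: expected shape {(s, spec.q)}, got {Ns.shape}"
        )
    if Nm.shape != (m, spec.n):
        raise NetworkValidationError(
            f"stoich_matrix: expected shape {(m, spec.n)}, got {Nm.shape}"
        )
    if Ns.size and not np.isin(Ns, (-1, 0, 1)).all():
        raise NetworkValidationError("interaction_matrix: entries must be in {-1, 0, +1}")
    if Nm.size and not np.isin(Nm, (-1, 0, 1)).all():
        raise NetworkValidationError("stoich_matrix: entries must be in {-1, 0, +1}")

    if len(spec.gene_rules) != p:
        raise NetworkValidationError(
            f"gene_rules: expected {p} rules (one per gene), got {len(spec.gene_rules)}"
        )
    seen_genes = set()
    for rule in spec.gene_rules:
        fn = f"gene_rules[{rule.gene_index}]"
        if not (0 <= rule.gene_index < p):
            raise NetworkValidationError(f"{fn}: gene_index out of range")
        if rule.gene_index in seen_genes:
            raise NetworkValidationError(f"{fn}: duplicate gene_index")
        seen_genes.add(rule.gene_index)
        if not (0.0 < rule.basal_rate < 1.0):
            raise NetworkValidationError(f"{fn}: basal_rate must be in (0, 1)")
        if not (0.0 < rule.decay_rate < 1.0):
            raise NetworkValidationError(f"{fn}: decay_rate must be in (0, 1)")
        _check_range(rule.tf_activators, s, fn + ".tf_activators", "signaling")
        _check_range(rule.act_met, m, fn + ".act_met", "metabolite")
        _check_range(rule.act_inp, c, fn + ".act_inp", "input")
        _check_range(rule.inh_met, m, fn + ".inh_met", "metabolite")
        _check_range(rule.inh_inp, c, fn + ".inh_inp", "input")
        _check_range(rule.inh_sig, s, fn + ".inh_sig", "signaling")
        if set(rule.act_met) & set(rule.inh_met) or set(rule.act_inp) & set(rule.inh_inp):
            raise NetworkValidationError(f"{fn}: activator and inhibitor sets overlap")

    seen_sigma = set()
    for col, rule in enumerate(spec.interaction_rules):
        fn = f"interaction_rules[{col}]"
        if rule.interaction_index != col:
            raise NetworkValidationError(f"{fn}: interaction_index {rule.interaction_index} != column {col}")
        if rule.interaction_index in seen_sigma:
            raise NetworkValidationError(f"{fn}: duplicate interaction_index")
        seen_sigma.add(rule.interaction_index)
        if rule.target is not None and not (0 <= rule.target < s):
            raise NetworkValidationError(f"{fn}: target out of range")
        if not (0.0 < rule.basal <= 1.0):
            raise NetworkValidationError(f"{fn}: basal must be in (0, 1]")
        _check_range(rule.activators, s, fn + ".activators", "signaling")
        _check_range(rule.enh_met, m, fn + ".enh_met", "metabolite")
        _check_range(rule.enh_inp, c, fn + ".enh_inp", "input")
        _check_range(rule.inh_met, m, fn + ".inh_met", "metabolite")
        _check_range(rule.inh_inp, c, fn + ".inh_inp", "input")
        _check_range(rule.inh_sig, s, fn + ".inh_sig", "signaling")
        plus = set(np.flatnonzero(Ns[:, col] == 1).tolist())
        minus = set(np.flatnonzero(Ns[:, col] == -1).tolist())
        want_plus = set() if rule.target is None else {rule.target}
        if plus != want_plus:
            raise NetworkValidationError(
                f"interaction_matrix column {col}: +1 entries {sorted(plus)} do not match target {rule.target}"
            )
        if minus != set(rule.consumed):
            raise NetworkValidationError(
                f"interaction_matrix column {col}: -1 entries {sorted(minus)} do not match consumed {sorted(rule.consumed)}"
            )

    for col, rule in enumerate(spec.reaction_rules):
        fn = f"reaction_rules[{col}]"
        if rule.reaction_index != col:
            raise NetworkValidationError(f"{fn}: reaction_index {rule.reaction_index} != column {col}")
        if not (0 <= rule.catalyzing_gene < p):
            raise NetworkValidationError(f"{fn}: catalyzing_gene out of range")
        if not (0.0 <= rule.rate_constant <= 1.0):
            raise NetworkValidationError(f"{fn}: rate_constant must be in [0, 1] (0 = knockout)")
        if not (0.0 < rule.michaelis_constant <= 1.0):
            raise NetworkValidationError(f"{fn}: michaelis_constant must be in (0, 1]")
        for idx in rule.substrates + rule.products:
            if not (0 <= idx < m):
                raise NetworkValidationError(f"{fn}: metabolite index {idx} out of range")
        _check_range(rule.enh_met, m, fn + ".enh_met", "metabolite")
        _check_range(rule.enh_inp, c, fn + ".enh_inp", "input")
        _check_range(rule.inh_met, m, fn + ".inh_met", "metabolite")
        _check_range(rule.inh_inp, c, fn + ".inh_inp", "input")
        minus = set(np.flatnonzero(Nm[:, col] == -1).tolist())
        plus = set(np.flatnonzero(Nm[:, col] == 1).tolist())
        if minus != set(rule.substrates):
            raise NetworkValidationError(
                f"stoich_matrix column {col}: -1 entries {sorted(minus)} do not match substrates {sorted(rule.substrates)}"
            )
        if plus != set(rule.products):
            raise NetworkValidationError(
                f"stoich_matrix column {col}: +1 entries {sorted(plus)} do not match products {sorted(rule.products)}"
            )
    return spec


# ---------------------------------------------------------------------------
# serialization (.net.yaml)
# ---------------------------------------------------------------------------

def _names_of(indices, names) -> list[str]:
    return [names[i] for i in indices]


def _named(d: Mapping[int, float], names: Sequence[str]) -> dict[str, float]:
    return {names[i]: float(v) for i, v in sorted(d.items())}


def _unnamed(d: Mapping[str, float] | None, names: Sequence[str], field_name: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for name, val in (d or {}).items():
        try:
            out[names.index(name)] = float(val)
        except ValueError:
            raise NetworkValidationError(f"{field_name}: unknown species name {name!r}") from None
    return out


def _spec_to_doc(spec: NetworkSpec) -> dict:
    g, sg, mt, inp = (
        spec.gene_names,
        spec.signaling_names,
        spec.metabolite_names,
        spec.input_names,
    )

    def drop_empty(d: dict) -> dict:
        return {k: v for k, v in d.items() if v not in ({}, (), [], None)}

    gene_rules = []
    for r in sorted(spec.gene_rules, key=lambda r: r.gene_index):
        gene_rules.append(drop_empty({
            "gene": g[r.gene_index],
            "basal": float(r.basal_rate),
            "decay": float(r.decay_rate),
            "tf": _named(r.tf_activators, sg),
            "act_met": _named(r.act_met, mt),
            "act_inp": _named(r.act_inp, inp),
            "inh_met": _named(r.inh_met, mt),
            "inh_inp": _named(r.inh_inp, inp),
            "inh_sig": _named(r.inh_sig, sg),
        }))
    interactions = []
    for r in spec.interaction_rules:
        interactions.append(drop_empty({
            "target": None if r.target is None else sg[r.target],
            "basal": float(r.basal),
            "activators": _named(r.activators, sg),
            "consumed": _names_of(r.consumed, sg),
            "enh_met": _named(r.enh_met, mt),
            "enh_inp": _named(r.enh_inp, inp),
            "inh_met": _named(r.inh_met, mt),
            "inh_inp": _named(r.inh_inp, inp),
            "inh_sig": _named(r.inh_sig, sg),
        }))
    reactions = []
    for r in spec.reaction_rules:
        reactions.append(drop_empty({
            "gene": g[r.catalyzing_gene],
            "substrates": _names_of(r.substrates, mt),
            "products": _names_of(r.products, mt),
            "K": float(r.rate_constant),
            "K_M": float(r.michaelis_constant),
            "enh_met": _named(r.enh_met, mt),
            "enh_inp": _named(r.enh_inp, inp),
            "inh_met": _named(r.inh_met, mt),
            "inh_inp": _named(r.inh_inp, inp),
        }))
    return {
        "format": FORMAT_TAG,
        "genes": list(g),
        "signals": list(sg),
        "metabolites": list(mt),
        "inputs": list(inp),
        "display_names": dict(spec.display_names),
        "gene_rules": gene_rules,
        "interactions": interactions,
        "reactions": reactions,
        "interaction_matrix": {
            "rows": spec.s,
            "cols": spec.q,
            "data": spec.interaction_matrix.astype(int).tolist(),
        },
        "stoich_matrix": {
            "rows": spec.m,
            "cols": spec.n,
            "data": spec.stoich_matrix.astype(int).tolist(),
        },
    }


def _doc_to_spec(doc: dict) -> NetworkSpec:
    if doc.get("format") != FORMAT_TAG:
        raise NetworkValidationError(
            f"format: expected {FORMAT_TAG!r}, got {doc.get('format')!r}"
        )
    g = list(doc["genes"])
    sg = list(doc["signals"])
    mt = list(doc["metabolites"])
    inp = list(doc["inputs"])

    gene_rules = []
    for i, r in enumerate(doc.get("gene_rules", [])):
        fn = f"gene_rules[{i}]"
        gene_rules.append(GeneRule(
            gene_index=g.index(r["gene"]),
            basal_rate=float(r["basal"]),
            decay_rate=float(r["decay"]),
            tf_activators=_unnamed(r.get("tf"), sg, fn + ".tf"),
            act_met=_unnamed(r.get("act_met"), mt, fn + ".act_met"),
            act_inp=_unnamed(r.get("act_inp"), inp, fn + ".act_inp"),
            inh_met=_unnamed(r.get("inh_met"), mt, fn + ".inh_met"),
            inh_inp=_unnamed(r.get("inh_inp"), inp, fn + ".inh_inp"),
            inh_sig=_unnamed(r.get("inh_sig"), sg, fn + ".inh_sig"),
        ))
    interactions = []
    for i, r in enumerate(doc.get("interactions", [])):
        fn = f"interactions[{i}]"
        tgt = r.get("target")
        interactions.append(InteractionRule(
            interaction_index=i,
            target=None if tgt is None else sg.index(tgt),
            basal=float(r.get("basal", 1.0)),
            activators=_unnamed(r.get("activators"), sg, fn + ".activators"),
            consumed=tuple(sg.index(nm) for nm in r.get("consumed", [])),
            enh_met=_unnamed(r.get("enh_met"), mt, fn + ".enh_met"),
            enh_inp=_unnamed(r.get("enh_inp"), inp, fn + ".enh_inp"),
            inh_met=_unnamed(r.get("inh_met"), mt, fn + ".inh_met"),
            inh_inp=_unnamed(r.get("inh_inp"), inp, fn + ".inh_inp"),
            inh_sig=_unnamed(r.get("inh_sig"), sg, fn + ".inh_sig"),
        ))
    reactions = []
    for i, r in enumerate(doc.get("reactions", [])):
        fn = f"reactions[{i}]"
        reactions.append(ReactionRule(
            reaction_index=i,
            substrates=tuple(mt.index(nm) for nm in r.get("substrates", [])),
            products=tuple(mt.index(nm) for nm in r.get("products", [])),
            catalyzing_gene=g.index(r["gene"]),
            rate_constant=float(r["K"]),
            michaelis_constant=float(r["K_M"]),
            enh_met=_unnamed(r.get("enh_met"), mt, fn + ".enh_met"),
            enh_inp=_unnamed(r.get("enh_inp"), inp, fn + ".enh_inp"),
            inh_met=_unnamed(r.get("inh_met"), mt, fn + ".inh_met"),
            inh_inp=_unnamed(r.get("inh_inp"), inp, fn + ".inh_inp"),
        ))

    kwargs = {}
    for key, attr in [("interaction_matrix", "interaction_matrix"), ("stoich_matrix", "stoich_matrix")]:
        block = doc.get(key)
        if block is not None:
            data = np.asarray(block["data"], dtype=float)
            if data.size == 0:
                data = data.reshape(int(block["rows"]), int(block["cols"]))
            if data.shape != (int(block["rows"]), int(block["cols"])):
                raise NetworkValidationError(
                    f"{key}: declared shape ({block['rows']}, {block['cols']}) does not match data {data.shape}"
                )
            if data.size and not np.isin(data, (-1, 0, 1)).all():
                raise NetworkValidationError(f"{key}: entries must be in {{-1, 0, +1}}")
            kwargs[attr] = data.astype(np.int8)

    spec = NetworkSpec(
        gene_names=g,
        signaling_names=sg,
        metabolite_names=mt,
        input_names=inp,
        gene_rules=gene_rules,
        interaction_rules=interactions,
        reaction_rules=reactions,
        display_names=dict(doc.get("display_names", {})),
        **kwargs,
    )
    return validate_network(spec)


def load_network(path: str | Path) -> NetworkSpec:
    """Read and validate a ``.net.yaml`` network specification."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise NetworkValidationError(f"{path}: not a mapping document")
    return _doc_to_spec(doc)


def save_network(spec: NetworkSpec, path: str | Path) -> Path:
    """Write a validated spec; ``load_network`` round-trips it exactly."""
    validate_network(spec)
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_doc(spec), fh, sort_keys=False, default_flow_style=None, width=100)
    return path


# ---------------------------------------------------------------------------
# toy fixture generator
# ---------------------------------------------------------------------------

def build_toy_network(
    n_genes: int,
    n_signals: int,
    n_metabolites: int,
    n_inputs: int,
    seed: int,
    extra_reactions: int = 0,
) -> NetworkSpec:
    """Generate a small random, connected, valid network for testing.

    Every signaling species gets one production interaction (activated by a
    random upstream species, or basal for species 0) and one first-order
    degradation interaction.  Every metabolite takes part in at least one
    reaction; reaction chains are wired so the metabolic layer is connected.
    All constants are drawn uniformly from their admissible ranges.
    Deterministic for a fixed seed.
    """
    for label, val in [
        ("n_genes", n_genes),
        ("n_signals", n_signals),
        ("n_metabolites", n_metabolites),
        ("n_inputs", n_inputs),
    ]:
        if val < 1:
            raise ValueError(f"{label} must be >= 1, got {val}")
    rng = np.random.default_rng(seed)

    def const() -> float:
        return float(rng.uniform(0.05, 0.95))

    g = [f"g{i}" for i in range(n_genes)]
    sg = [f"y{j}" for j in range(n_signals)]
    mt = [f"z{k}" for k in range(n_metabolites)]
    inp = [f"u{l}" for l in range(n_inputs)]

    interactions: list[InteractionRule] = []
    for j in range(n_signals):
        idx = len(interactions)
        if j == 0:
            rule = InteractionRule(
                interaction_index=idx,
                target=j,
                basal=const(),
                enh_inp={int(rng.integers(n_inputs)): const()},
            )
        else:
            upstream = int(rng.integers(j))
            rule = InteractionRule(
                interaction_index=idx,
                target=j,
                activators={upstream: const()},
            )
        interactions.append(rule)
        interactions.append(InteractionRule(
            interaction_index=len(interactions),
            target=None,
            activators={j: const()},
            consumed=(j,),
        ))

    reactions: list[ReactionRule] = []
    # source reaction feeding metabolite 0 from outside, then a chain
    reactions.append(ReactionRule(
        reaction_index=0,
        substrates=(),
        products=(0,),
        catalyzing_gene=int(rng.integers(n_genes)),
        rate_constant=const(),
        michaelis_constant=const(),
        enh_inp={int(rng.integers(n_inputs)): const()},
    ))
    for k in range(1, n_metabolites):
        reactions.append(ReactionRule(
            reaction_index=len(reactions),
            substrates=(k - 1,),
            products=(k,),
            catalyzing_gene=int(rng.integers(n_genes)),
            rate_constant=const(),
            michaelis_constant=const(),
        ))
    # sink so the chain does not saturate
    reactions.append(ReactionRule(
        reaction_index=len(reactions),
        substrates=(n_metabolites - 1,),
        products=(),
        catalyzing_gene=int(rng.integers(n_genes)),
        rate_constant=const(),
        michaelis_constant=const(),
    ))
    for _ in range(extra_reactions):
        k_from = int(rng.integers(n_metabolites))
        k_to = int(rng.integers(n_metabolites))
        if k_to == k_from:
            k_to = (k_from + 1) % n_metabolites
        reactions.append(ReactionRule(
            reaction_index=len(reactions),
            substrates=(k_from,),
            products=(k_to,),
            catalyzing_gene=int(rng.integers(n_genes)),
            rate_constant=const(),
            michaelis_constant=const(),
            enh_met={int(rng.integers(n_metabolites)): const()} if rng.random() < 0.5 else {},
        ))

    gene_rules = []
    for i in range(n_genes):
        tf = {int(rng.integers(n_signals)): const()}
        rule = GeneRule(
            gene_index=i,
            basal_rate=float(rng.uniform(0.02, 0.2)),
            decay_rate=float(rng.uniform(0.1, 0.4)),
            tf_activators=tf,
        )
        draw = rng.random()
        if draw < 0.3:
            rule = replace(rule, act_met={int(rng.integers(n_metabolites)): const()})
        elif draw < 0.6:
            rule = replace(rule, inh_met={int(rng.integers(n_metabolites)): const()})
        gene_rules.append(rule)

    spec = NetworkSpec(
        gene_names=g,
        signaling_names=sg,
        metabolite_names=mt,
        input_names=inp,
        gene_rules=gene_rules,
        interaction_rules=interactions,
        reaction_rules=reactions,
    )
    return validate_network(spec)
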