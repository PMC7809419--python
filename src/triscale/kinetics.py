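"""Rate laws and state derivatives for the three-layer pathway model.

Three families of rates drive the coupled system:

* gene expression rates ``e_i = prod K_ij' y_j'`` with cofactor
  multipliers and inhibitor divisors (modified mass-action transcription),
* signaling interaction rates ``r_sigma = basal * prod K_jj' y_j'`` with
  metabolite/input enhancer multipliers and inhibitor divisors,
* metabolic fluxes ``r_rho = K E Z / (K_M + Z)`` with ``Z`` the product of
  substrate concentrations (a single lumped Michaelis term for
  multi-substrate reactions) and noncompetitive/allosteric modulation.

The full state derivative couples the layers through the timescale ratios
``w1`` (slow:fast) and ``w2`` (fast:ultrafast):

    dx/dt = f(x, y, z, u)                (genes, slow)
    dy/dt = (1/w1) * N_s r_s             (signaling, fast)
    dz/dt = (1/(w1*w2)) * N_m r_m        (metabolites, ultrafast)

Scalar, per-rule evaluators are provided for clarity and testing;
:class:`CompiledNetwork` evaluates everything with flat index arrays and
``reduceat`` segment products, which is what the integrator uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import GeneRule, InteractionRule, NetworkSpec, ReactionRule

try:  # optional JIT acceleration; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "StateVectors",
    "RateVectors",
    "KineticsConstraintError",
    "gene_rate",
    "signaling_rates",
    "metabolic_rates",
    "full_derivative",
    "CompiledNetwork",
]


class KineticsConstraintError(ValueError):
    """An inhibitor factor ``F * level`` reached or exceeded 1 in strict mode."""


@dataclass
class StateVectors:
    """System state: gene expressions x, signaling levels y, metabolite
    concentrations z and external inputs u, all in normalized [0, 1] units."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.u = np.asarray(self.u, dtype=float)

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (len(self.x), len(self.y), len(self.z), len(self.u))

    def concat(self) -> np.ndarray:
        """Flatten to one input instance ``<x, y, z, u>``."""
        return np.concatenate([self.x, self.y, self.z, self.u])

    @classmethod
    def from_concat(cls, vec: np.ndarray, dims: tuple[int, int, int, int]) -> "StateVectors":
        p, s, m, c = dims
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (p + s + m + c,):
            raise ValueError(f"expected length {p + s + m + c}, got {vec.shape}")
        return cls(
            x=vec[:p].copy(),
            y=vec[p:p + s].copy(),
            z=vec[p + s:p + s + m].copy(),
            u=vec[p + s + m:].copy(),
        )

    def copy(self) -> "StateVectors":
        return StateVectors(self.x.copy(), self.y.copy(), self.z.copy(), self.u.copy())


@dataclass
class RateVectors:
    """Instantaneous rates: signaling interaction rates ``r_s`` (length q),
    metabolic fluxes ``r_m`` (length n) and gene expression rates ``e``
    (length p)."""

    r_s: np.ndarray
    r_m: np.ndarray
    e: np.ndarray


def _prod_K(d: Mapping[int, float], vec: np.ndarray) -> float:
    out = 1.0
    for idx, k in d.items():
        out *= k * vec[idx]
    return out


def _prod_1pF(d: Mapping[int, float], vec: np.ndarray, strict: bool, label: str) -> float:
    out = 1.0
    for idx, f in d.items():
        fv = f * vec[idx]
        if strict and fv >= 1.0:
            raise KineticsConstraintError(
                f"{label}: modifier product F*level = {fv:.4g} >= 1 for index {idx}"
            )
        out *= 1.0 + fv
    return out


# ---------------------------------------------------------------------------
# scalar reference evaluators
# ---------------------------------------------------------------------------

def gene_rate(rule: GeneRule, state: StateVectors, strict: bool = False) -> float:
    """Time derivative of one gene's expression level.

    If the product of required transcription-factor levels is zero the gene
    reduces to basal production minus decay.  Otherwise activating
    cofactors multiply the expression rate, and inhibitors divide the
    (expression + basal) numerator, composing the activated and inhibited
    forms when a rule carries both.
    """
    label = f"gene {rule.gene_index}"
    e = _prod_K(rule.tf_activators, state.y)
    if e == 0.0:
        return rule.basal_rate - rule.decay_rate
    act = _prod_1pF(rule.act_met, state.z, strict, label) * _prod_1pF(
        rule.act_inp, state.u, strict, label
    )
    inh = (
        _prod_1pF(rule.inh_met, state.z, strict, label)
        * _prod_1pF(rule.inh_inp, state.u, strict, label)
        * _prod_1pF(rule.inh_sig, state.y, strict, label)
    )
    return (e * act + rule.basal_rate) / inh - rule.decay_rate


def _signaling_rate(rule: InteractionRule, state: StateVectors, strict: bool = False) -> float:
    label = f"interaction {rule.interaction_index}"
    r = rule.basal * _prod_K(rule.activators, state.y)
    r *= _prod_1pF(rule.enh_met, state.z, strict, label)
    r *= _prod_1pF(rule.enh_inp, state.u, strict, label)
    r /= _prod_1pF(rule.inh_met, state.z, strict, label)
    r /= _prod_1pF(rule.inh_inp, state.u, strict, label)
    r /= _prod_1pF(rule.inh_sig, state.y, strict, label)
    return r


def signaling_rates(spec: NetworkSpec, state: StateVectors, strict: bool = False) -> np.ndarray:
    """Length-q vector of signaling interaction rates."""
    return np.array([_signaling_rate(r, state, strict) for r in spec.interaction_rules])


def _metabolic_rate(rule: ReactionRule, state: StateVectors, strict: bool = False) -> float:
    label = f"reaction {rule.reaction_index}"
    if rule.rate_constant == 0.0:
        return 0.0
    Z = 1.0
    for k in rule.substrates:
        Z *= state.z[k]
    E = state.x[rule.catalyzing_gene]
    r = rule.rate_constant * E * Z / (rule.michaelis_constant + Z)
    r *= _prod_1pF(rule.enh_met, state.z, strict, label)
    r *= _prod_1pF(rule.enh_inp, state.u, strict, label)
    r /= _prod_1pF(rule.inh_met, state.z, strict, label)
    r /= _prod_1pF(rule.inh_inp, state.u, strict, label)
    return r


def metabolic_rates(spec: NetworkSpec, state: StateVectors, strict: bool = False) -> np.ndarray:
    """Length-n vector of metabolic fluxes."""
    return np.array([_metabolic_rate(r, state, strict) for r in spec.reaction_rules])


def full_derivative(
    spec: NetworkSpec,
    state: StateVectors,
    w1: float,
    w2: float,
    strict: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scalar-path state derivative ``(dx, dy, dz)``.

    ``dy = (1/w1) N_s r_s`` and ``dz = (1/(w1 w2)) N_m r_m``; setting
    ``w1 = w2 = 1`` recovers the unscaled single-timescale system.
    """
    if not (0.0 < w1 <= 1.0 and 0.0 < w2 <= 1.0):
        raise ValueError(f"timescale ratios must be in (0, 1], got w1={w1}, w2={w2}")
    dx = np.array([gene_rate(r, state, strict) for r in spec.gene_rules])
    r_s = signaling_rates(spec, state, strict)
    r_m = metabolic_rates(spec, state, strict)
    dy = (spec.interaction_matrix @ r_s) / w1
    dz = (spec.stoich_matrix @ r_m) / (w1 * w2)
    return dx, dy, dz


# ---------------------------------------------------------------------------
# compiled vectorized evaluator
# ---------------------------------------------------------------------------

_XOFF, _YOFF, _ZOFF, _UOFF = 0, 1, 2, 3  # segment id of each factor's source vector


class _SegProd:
    """Segment products over a flat factor array.

    Each row is a list of ``(which_vector, index, constant)`` triples; empty
    rows are padded so ``reduceat`` yields 1 for them.  ``finalize`` turns
    the (which, index) pairs into one gather index over the packed vector
    ``w = [x, y, z, u]`` so evaluation is a single fancy-index plus
    ``reduceat``.
    """

    def __init__(self, rows: Sequence[Sequence[tuple[int, int, float]]]):
        which: list[int] = []
        idx: list[int] = []
        const: list[float] = []
        offsets: list[int] = []
        for row in rows:
            offsets.append(len(idx))
            if not row:
                which.append(-1)
                idx.append(0)
                const.append(0.0)
            else:
                for w, i, k in row:
                    which.append(w)
                    idx.append(i)
                    const.append(k)
        self.nrows = len(rows)
        self.which = np.asarray(which, dtype=np.int64)
        self.idx = np.asarray(idx, dtype=np.int64)
        self.const = np.asarray(const, dtype=float)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.pad = self.which < 0
        self.gidx: np.ndarray | None = None

    def finalize(self, p: int, s: int, m: int) -> None:
        base = np.array([0, 0, p, p + s, p + s + m], dtype=np.int64)
        self.gidx = self.idx + base[self.which + 1]
        self.gidx[self.pad] = 0

    def prod_K(self, w: np.ndarray) -> np.ndarray:
        """Row-wise product of ``constant * level``; empty rows give 1."""
        if self.nrows == 0:
            return np.ones(0)
        vals = self.const * w[self.gidx]
        if self.pad.any():
            vals[self.pad] = 1.0
        return np.multiply.reduceat(vals, self.offsets)

    def prod_1pF(self, w: np.ndarray) -> np.ndarray:
        """Row-wise product of ``1 + constant * level``; empty rows give 1."""
        if self.nrows == 0:
            return np.ones(0)
        vals = 1.0 + self.const * w[self.gidx]
        if self.pad.any():
            vals[self.pad] = 1.0
        return np.multiply.reduceat(vals, self.offsets)

    def touched(self, which: int) -> np.ndarray:
        """Boolean (nrows,) mask of rows that read from vector ``which``."""
        out = np.zeros(self.nrows, dtype=bool)
        sel = self.which == which
        if sel.any():
            rows = np.searchsorted(self.offsets, np.flatnonzero(sel), side="right") - 1
            out[rows] = True
        return out

    def row_indices(self, which: int):
        """Yield ``(row, species_index)`` pairs for factors drawn from ``which``."""
        sel = np.flatnonzero(self.which == which)
        rows = np.searchsorted(self.offsets, sel, side="right") - 1
        return list(zip(rows.tolist(), self.idx[sel].tolist()))


@dataclass
class CompiledNetwork:
    """Vectorized rate evaluator built once per :class:`NetworkSpec`.

    ``rate_constants`` and ``michaelis_constants`` are held as mutable
    arrays so that knockouts and parameter tuning can act on the compiled
    object without recompiling the index structure.
    """

    spec: NetworkSpec
    rate_constants: np.ndarray = field(init=False)
    michaelis_constants: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        spec = self.spec
        self.p, self.s, self.m, self.c = spec.dims
        self.N_s = spec.interaction_matrix.astype(float)
        self.N_m = spec.stoich_matrix.astype(float)

        gr = sorted(spec.gene_rules, key=lambda r: r.gene_index)
        self.basal = np.array([r.basal_rate for r in gr])
        self.decay = np.array([r.decay_rate for r in gr])
        self._g_tf = _SegProd([[(_YOFF, j, k) for j, k in r.tf_activators.items()] for r in gr])
        self._g_act = _SegProd([
            [(_ZOFF, j, k) for j, k in r.act_met.items()]
            + [(_UOFF, j, k) for j, k in r.act_inp.items()]
            for r in gr
        ])
        self._g_inh = _SegProd([
            [(_ZOFF, j, k) for j, k in r.inh_met.items()]
            + [(_UOFF, j, k) for j, k in r.inh_inp.items()]
            + [(_YOFF, j, k) for j, k in r.inh_sig.items()]
            for r in gr
        ])

        ir = spec.interaction_rules
        self.sig_basal = np.array([r.basal for r in ir])
        self._s_act = _SegProd([[(_YOFF, j, k) for j, k in r.activators.items()] for r in ir])
        self._s_enh = _SegProd([
            [(_ZOFF, j, k) for j, k in r.enh_met.items()]
            + [(_UOFF, j, k) for j, k in r.enh_inp.items()]
            for r in ir
        ])
        self._s_inh = _SegProd([
            [(_ZOFF, j, k) for j, k in r.inh_met.items()]
            + [(_UOFF, j, k) for j, k in r.inh_inp.items()]
            + [(_YOFF, j, k) for j, k in r.inh_sig.items()]
            for r in ir
        ])

        rr = spec.reaction_rules
        self.rate_constants = np.array([r.rate_constant for r in rr])
        self.michaelis_constants = np.array([r.michaelis_constant for r in rr])
        self.enzyme_gene = np.array([r.catalyzing_gene for r in rr], dtype=np.int64)
        self._m_sub = _SegProd([[(_ZOFF, j, 1.0) for j in r.substrates] for r in rr])
        self._m_enh = _SegProd([
            [(_ZOFF, j, k) for j, k in r.enh_met.items()]
            + [(_UOFF, j, k) for j, k in r.enh_inp.items()]
            for r in rr
        ])
        self._m_inh = _SegProd([
            [(_ZOFF, j, k) for j, k in r.inh_met.items()]
            + [(_UOFF, j, k) for j, k in r.inh_inp.items()]
            for r in rr
        ])

        for seg in (self._g_tf, self._g_act, self._g_inh, self._s_act,
                    self._s_enh, self._s_inh, self._m_sub, self._m_enh,
                    self._m_inh):
            seg.finalize(self.p, self.s, self.m)

    # -- rate families --------------------------------------------------
    def _pack(self, x, y, z, u) -> np.ndarray:
        return np.concatenate([x, y, z, u])

    def _gene_rates_w(self, w) -> np.ndarray:
        e = self._g_tf.prod_K(w)
        act = self._g_act.prod_1pF(w)
        inh = self._g_inh.prod_1pF(w)
        dx = (e * act + self.basal) / inh - self.decay
        absent = e <= 0.0
        if absent.any():
            dx = np.where(absent, self.basal - self.decay, dx)
        return dx

    def _signaling_rates_w(self, w) -> np.ndarray:
        r = self.sig_basal * self._s_act.prod_K(w)
        r *= self._s_enh.prod_1pF(w)
        r /= self._s_inh.prod_1pF(w)
        return r

    def _metabolic_rates_w(self, w) -> np.ndarray:
        Z = self._m_sub.prod_K(w)
        E = w[self.enzyme_gene]
        r = self.rate_constants * E * Z / (self.michaelis_constants + Z)
        r *= self._m_enh.prod_1pF(w)
        r /= self._m_inh.prod_1pF(w)
        return r

    def gene_rates(self, x, y, z, u) -> np.ndarray:
        return self._gene_rates_w(self._pack(x, y, z, u))

    def expression_rates(self, x, y, z, u) -> np.ndarray:
        return self._g_tf.prod_K(self._pack(x, y, z, u))

    def signaling_rates(self, x, y, z, u) -> np.ndarray:
        return self._signaling_rates_w(self._pack(x, y, z, u))

    def metabolic_rates(self, x, y, z, u) -> np.ndarray:
        return self._metabolic_rates_w(self._pack(x, y, z, u))

    def derivative(self, x, y, z, u, w1: float, w2: float):
        """``(dx, dy, dz)`` with timescale scaling applied."""
        w = self._pack(x, y, z, u)
        dx = self._gene_rates_w(w)
        dy = (self.N_s @ self._signaling_rates_w(w)) / w1
        dz = (self.N_m @ self._metabolic_rates_w(w)) / (w1 * w2)
        return dx, dy, dz

    def _fast_args(self):
        """Argument tuple for the module-level JIT kernel (built once)."""
        if getattr(self, "_fast_args_cache", None) is None:
            segs = (self._g_tf, self._g_act, self._g_inh, self._s_act,
                    self._s_enh, self._s_inh, self._m_sub, self._m_enh, self._m_inh)
            seg_args = []
            for g in segs:
                seg_args.extend([
                    np.ascontiguousarray(g.gidx),
                    np.ascontiguousarray(g.const),
                    np.ascontiguousarray(np.append(g.offsets, len(g.idx))),
                    np.ascontiguousarray(g.pad),
                ])
            self._fast_args_cache = (
                self.p, self.s, self.m,
                np.ascontiguousarray(self.basal), np.ascontiguousarray(self.decay),
                np.ascontiguousarray(self.sig_basal),
                np.ascontiguousarray(self.enzyme_gene),
                np.ascontiguousarray(self.N_s), np.ascontiguousarray(self.N_m),
                tuple(seg_args),
            )
        return self._fast_args_cache

    def rhs(self, w1: float, w2: float, u_of_t, clip: bool = True):
        """Right-hand side ``f(t, state)`` over the packed state [x, y, z].

        States are clipped to [0, 1] before rate evaluation so that solver
        excursions outside the box cannot produce unphysical rates.
        """
        p, s, m = self.p, self.s, self.m
        n_state = p + s + m
        iw1 = 1.0 / w1
        iw12 = 1.0 / (w1 * w2)
        u_const = None
        try:
            u_const = np.asarray(u_of_t(0.0), dtype=float)
        except Exception:
            pass
        w_buf = np.empty(n_state + self.c)
        K, KM = self.rate_constants, self.michaelis_constants

        if _HAVE_NUMBA:
            (pp, ss, mm, basal, decay, sig_basal, enzyme_gene,
             Ns, Nm, seg_args) = self._fast_args()

            def fun(t, v):
                if clip:
                    v = np.clip(v, 0.0, 1.0)
                w_buf[:n_state] = v
                w_buf[n_state:] = u_of_t(t) if u_const is None or callable(u_of_t) else u_const
                return _rhs_core(w_buf, pp, ss, mm, basal, decay, sig_basal,
                                 enzyme_gene, K, KM, Ns, Nm, iw1, iw12, *seg_args)

            return fun

        def fun(t, v):
            if clip:
                v = np.clip(v, 0.0, 1.0)
            w_buf[:n_state] = v
            w_buf[n_state:] = u_of_t(t) if u_const is None or callable(u_of_t) else u_const
            dx = self._gene_rates_w(w_buf)
            dy = (self.N_s @ self._signaling_rates_w(w_buf)) * iw1
            dz = (self.N_m @ self._metabolic_rates_w(w_buf)) * iw12
            return np.concatenate([dx, dy, dz])

        return fun

    def jac_sparsity(self) -> np.ndarray:
        """Dependency pattern of the packed derivative, for implicit solvers."""
        if getattr(self, "_jac_sparsity", None) is not None:
            return self._jac_sparsity
        p, s, m = self.p, self.s, self.m
        n_state = p + s + m
        S = np.zeros((n_state, n_state), dtype=bool)

        def mark(rows_cols, row_off, col_off):
            for r, cidx in rows_cols:
                S[row_off + r, col_off + cidx] = True

        # genes depend on y (TFs, inhibitors) and z (cofactors)
        for seg in (self._g_tf, self._g_act, self._g_inh):
            mark(seg.row_indices(_YOFF), 0, p)
            mark(seg.row_indices(_ZOFF), 0, p + s)
        # signaling rows depend on the y/z factors of every interaction they touch
        rows_y = np.abs(self.N_s) > 0  # (s, q)
        for seg in (self._s_act, self._s_enh, self._s_inh):
            for col, cidx in seg.row_indices(_YOFF):
                S[p:p + s, p + cidx] |= rows_y[:, col]
            for col, cidx in seg.row_indices(_ZOFF):
                S[p:p + s, p + s + cidx] |= rows_y[:, col]
        # metabolite rows depend on substrates/modifiers and the enzyme gene
        rows_z = np.abs(self.N_m) > 0  # (m, n)
        for seg in (self._m_sub, self._m_enh, self._m_inh):
            for col, cidx in seg.row_indices(_ZOFF):
                S[p + s:, p + s + cidx] |= rows_z[:, col]
        for col in range(self.N_m.shape[1]):
            S[p + s:, self.enzyme_gene[col]] |= rows_z[:, col]
        np.fill_diagonal(S, True)
        self._jac_sparsity = S
        return S

    # -- parameter table ------------------------------------------------
    def set_knockouts(self, reaction_indices: Sequence[int]) -> None:
        for idx in reaction_indices:
            self.rate_constants[int(idx)] = 0.0


# ---------------------------------------------------------------------------
# JIT kernels (module level so they compile once per process)
# ---------------------------------------------------------------------------

if _HAVE_NUMBA:

    @_njit(cache=True)
    def _seg_eval(w, gidx, const, offs, pad, one_plus):
        nrows = len(offs) - 1
        out = np.empty(nrows)
        for r in range(nrows):
            prod = 1.0
            for k in range(offs[r], offs[r + 1]):
                if pad[k]:
                    continue
                if one_plus:
                    prod *= 1.0 + const[k] * w[gidx[k]]
                else:
                    prod *= const[k] * w[gidx[k]]
            out[r] = prod
        return out

    @_njit(cache=True)
    def _rhs_core(w, p, s, m, basal, decay, sig_basal, enzyme_gene, K, KM,
                  Ns, Nm, iw1, iw12,
                  gtf_i, gtf_c, gtf_o, gtf_p,
                  gact_i, gact_c, gact_o, gact_p,
                  ginh_i, ginh_c, ginh_o, ginh_p,
                  sact_i, sact_c, sact_o, sact_p,
                  senh_i, senh_c, senh_o, senh_p,
                  sinh_i, sinh_c, sinh_o, sinh_p,
                  msub_i, msub_c, msub_o, msub_p,
                  menh_i, menh_c, menh_o, menh_p,
                  minh_i, minh_c, minh_o, minh_p):
        e = _seg_eval(w, gtf_i, gtf_c, gtf_o, gtf_p, False)
        act = _seg_eval(w, gact_i, gact_c, gact_o, gact_p, True)
        inh = _seg_eval(w, ginh_i, ginh_c, ginh_o, ginh_p, True)
        dv = np.empty(p + s + m)
        for i in range(p):
            if e[i] <= 0.0:
                dv[i] = basal[i] - decay[i]
            else:
                dv[i] = (e[i] * act[i] + basal[i]) / inh[i] - decay[i]
        rs = sig_basal * _seg_eval(w, sact_i, sact_c, sact_o, sact_p, False)
        rs *= _seg_eval(w, senh_i, senh_c, senh_o, senh_p, True)
        rs /= _seg_eval(w, sinh_i, sinh_c, sinh_o, sinh_p, True)
        Z = _seg_eval(w, msub_i, msub_c, msub_o, msub_p, False)
        rm = np.empty(len(K))
        for r in range(len(K)):
            rm[r] = K[r] * w[enzyme_gene[r]] * Z[r] / (KM[r] + Z[r])
        rm *= _seg_eval(w, menh_i, menh_c, menh_o, menh_p, True)
        rm /= _seg_eval(w, minh_i, minh_c, minh_o, minh_p, True)
        dv[p:p + s] = (Ns @ rs) * iw1
        dv[p + s:] = (Nm @ rm) * iw12
        return dv
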