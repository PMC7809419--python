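"""Three-timescale integration and quasi-steady-state (QSS) reduction.

The coupled system

    dx/dt = f(x, y, z, u)
    dy/dt = (1/w1)   g^(x, y, z, u)
    dz/dt = (1/(w1 w2)) h^^(x, y, z, u)

is stiff for small timescale ratios (the defaults w1 = w2 = 1/60 give a
1:3600 separation between the gene-regulatory and metabolic layers), so the
default integration mode uses an implicit adaptive solver over the packed
state with a precomputed Jacobian sparsity pattern.  A ``nested_multirate``
mode sub-steps the fast and ultrafast layers explicitly at dt*w1 and
dt*w1*w2 resolution; it mirrors the stretched-timescale construction and is
intended for small test systems.

Letting the fast timescales collapse (w -> 0) gives the QSS maps
``z = H'(x, y, u)`` (ultrafast layer at equilibrium) and ``y = G(x, u)``
(fast layer at equilibrium with the ultrafast layer slaved to it), and the
reduced slow system ``dx/dt = f(x, G(x,u), H(x,u), u)``.  Roots are found
inside the unit box by a bounded trust-region least-squares solve.

States are clamped to [0, 1] after each accepted sample (all quantities are
normalized); clamp events are counted in the trajectory metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.optimize import root as scipy_root

from .kinetics import CompiledNetwork, StateVectors
from .network import NetworkSpec

__all__ = [
    "TimescaleConfig",
    "Trajectory",
    "CustomSystem",
    "QSSInfeasibleError",
    "IntegrationError",
    "as_system",
    "integrate",
    "qss_ultrafast",
    "qss_fast",
    "reduced_slow_derivative",
    "solve_equilibrium_input",
    "write_trajectory_csv",
]

OMEGA_DEFAULT = 1.0 / 60.0


class QSSInfeasibleError(RuntimeError):
    """No quasi-steady-state root found inside the unit box."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class TimescaleConfig:
    """Integration configuration.

    ``w1`` is the slow:fast and ``w2`` the fast:ultrafast timescale ratio
    (dimensionless, both 1/60 by default).  ``t_grid`` is expressed on the
    slow timescale; one slow unit is the natural gene-regulatory time unit.
    """

    w1: float = OMEGA_DEFAULT
    w2: float = OMEGA_DEFAULT
    t_grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 10.0, 101))
    integration_mode: str = "direct_stiff"
    abs_tol: float = 1e-8
    rel_tol: float = 1e-6
    clamp: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.w1 <= 1.0 and 0.0 < self.w2 <= 1.0):
            raise ValueError(f"timescale ratios must be in (0, 1]: w1={self.w1}, w2={self.w2}")
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.t_grid.ndim != 1 or len(self.t_grid) < 2 or np.any(np.diff(self.t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing with >= 2 points")
        if self.integration_mode not in ("direct_stiff", "nested_multirate"):
            raise ValueError(f"unknown integration_mode {self.integration_mode!r}")


@dataclass
class Trajectory:
    """Time-indexed states on the slow-time grid.

    ``X``, ``Y``, ``Z`` and ``U`` are (T, p/s/m/c) arrays aligned with
    ``times``; ``meta`` records configuration and clamp statistics.
    """

    times: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    U: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, idx: int) -> StateVectors:
        return StateVectors(self.X[idx], self.Y[idx], self.Z[idx], self.U[idx])

    def species_matrix(self) -> np.ndarray:
        """(T, p+s+m) output matrix in canonical species order."""
        return np.hstack([self.X, self.Y, self.Z])


@dataclass
class CustomSystem:
    """Adapter exposing arbitrary ``f, g, h`` callables (unscaled) through
    the same interface as :class:`~triscale.kinetics.CompiledNetwork`.

    Used for closed-form test systems where no network spec exists.
    """

    p: int
    s: int
    m: int
    c: int
    f: Callable
    g: Callable
    h: Callable

    def derivative(self, x, y, z, u, w1: float, w2: float):
        return (
            np.atleast_1d(self.f(x, y, z, u)),
            np.atleast_1d(self.g(x, y, z, u)) / w1,
            np.atleast_1d(self.h(x, y, z, u)) / (w1 * w2),
        )

    def rhs(self, w1, w2, u_of_t, clip=True):
        def fun(t, v):
            x, y, z = v[:self.p], v[self.p:self.p + self.s], v[self.p + self.s:]
            dx, dy, dz = self.derivative(x, y, z, u_of_t(t), w1, w2)
            return np.concatenate([dx, dy, dz])
        return fun


def as_system(obj) -> CompiledNetwork | CustomSystem:
    """Accept a NetworkSpec, CompiledNetwork or CustomSystem."""
    if isinstance(obj, NetworkSpec):
        return CompiledNetwork(obj)
    return obj


def _u_policy(u_policy, c: int) -> Callable[[float], np.ndarray]:
    if callable(u_policy):
        return u_policy
    u_const = np.asarray(u_policy, dtype=float)
    if u_const.shape != (c,):
        raise ValueError(f"constant input must have length {c}")
    return lambda t: u_const


def integrate(
    system,
    init: StateVectors,
    u_policy,
    cfg: TimescaleConfig | None = None,
) -> Trajectory:
    """Integrate the coupled three-timescale system on ``cfg.t_grid``.

    ``u_policy`` is either a constant length-c vector or a callable
    ``t -> u``.  Integration proceeds segment by segment between grid
    points; with ``cfg.clamp`` the state is clamped to [0, 1] after each
    segment (clamp magnitudes accumulate in ``meta['clamp_events']``).
    """
    cfg = cfg or TimescaleConfig()
    sysm = as_system(system)
    u_of_t = _u_policy(u_policy, sysm.c)
    p, s, m = sysm.p, sysm.s, sysm.m
    rhs = sysm.rhs(cfg.w1, cfg.w2, u_of_t, clip=cfg.clamp)

    t_grid = cfg.t_grid
    v = np.concatenate([init.x, init.y, init.z]).astype(float)
    out = np.empty((len(t_grid), p + s + m))
    out[0] = v
    clamp_events = 0

    if cfg.integration_mode == "direct_stiff":
        kwargs: dict = {}
        if hasattr(sysm, "jac_sparsity"):
            kwargs["jac_sparsity"] = sysm.jac_sparsity()
            method = "BDF"
        else:
            method = "LSODA"
        for i in range(1, len(t_grid)):
            sol = solve_ivp(
                rhs,
                (t_grid[i - 1], t_grid[i]),
                v,
                method=method,
                rtol=cfg.rel_tol,
                atol=cfg.abs_tol,
                **kwargs,
            )
            if not sol.success:
                raise IntegrationError(
                    f"solver failed between t={t_grid[i - 1]} and t={t_grid[i]}: {sol.message}",
                    last_time=float(t_grid[i - 1]),
                )
            v = sol.y[:, -1]
            if cfg.clamp:
                clipped = np.clip(v, 0.0, 1.0)
                clamp_events += int(np.sum(np.abs(clipped - v) > 0))
                v = clipped
            elif np.any(v < -1e-6) or np.any(v > 1 + 1e-6):
                raise IntegrationError(
                    f"state left [0, 1] at t={t_grid[i]} with clamping disabled",
                    last_time=float(t_grid[i - 1]),
                )
            out[i] = v
    else:  # nested_multirate: explicit RK4 cascade at dt*w1 / dt*w1*w2
        for i in range(1, len(t_grid)):
            h = t_grid[i] - t_grid[i - 1]
            n1 = max(1, int(np.ceil(1.0 / cfg.w1)))
            n2 = max(1, int(np.ceil(1.0 / cfg.w2)))
            v = _rk4_steps(rhs, t_grid[i - 1], v, h, 4 * n1 * n2)
            if cfg.clamp:
                clipped = np.clip(v, 0.0, 1.0)
                clamp_events += int(np.sum(np.abs(clipped - v) > 0))
                v = clipped
            out[i] = v

    U = np.array([u_of_t(t) for t in t_grid])
    return Trajectory(
        times=t_grid.copy(),
        X=out[:, :p],
        Y=out[:, p:p + s],
        Z=out[:, p + s:],
        U=U,
        meta={
            "w1": cfg.w1,
            "w2": cfg.w2,
            "mode": cfg.integration_mode,
            "clamp_events": clamp_events,
        },
    )


def _rk4_steps(rhs, t0: float, v: np.ndarray, h: float, n: int) -> np.ndarray:
    dt = h / n
    t = t0
    for _ in range(n):
        k1 = rhs(t, v)
        k2 = rhs(t + dt / 2, v + dt / 2 * k1)
        k3 = rhs(t + dt / 2, v + dt / 2 * k2)
        k4 = rhs(t + dt, v + dt * k3)
        v = v + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return v


# ---------------------------------------------------------------------------
# quasi-steady-state maps
# ---------------------------------------------------------------------------

def _box_root(residual, v0: np.ndarray, abs_tol: float):
    sol = least_squares(
        residual,
        np.clip(v0, 1e-9, 1 - 1e-9),
        bounds=(0.0, 1.0),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    v = sol.x
    res = np.max(np.abs(sol.fun)) if sol.fun.size else 0.0
    if res > 0.0:
        # Newton polish: the bounded trust-region solve can stall slightly
        # above machine-level residuals near the interior; accept the
        # polished root only if it stays inside the box.
        polished = scipy_root(residual, v, method="hybr")
        vp = np.asarray(polished.x, dtype=float)
        if np.all(vp >= -1e-10) and np.all(vp <= 1 + 1e-10):
            vp = np.clip(vp, 0.0, 1.0)
            resp = np.max(np.abs(np.atleast_1d(residual(vp))))
            if resp < res:
                v, res = vp, resp
    return v, res


def qss_ultrafast(
    system,
    x: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    z0: np.ndarray | None = None,
    abs_tol: float = 1e-8,
) -> np.ndarray:
    """Ultrafast-layer equilibrium ``z* = H'(x, y, u)``: root of the
    unscaled metabolic derivative inside the unit box."""
    sysm = as_system(system)

    def residual(z):
        return np.atleast_1d(sysm.derivative(x, y, z, u, 1.0, 1.0)[2])

    z0 = np.full(sysm.m, 0.5) if z0 is None else np.asarray(z0, dtype=float)
    z, res = _box_root(residual, z0, abs_tol)
    if res > abs_tol:
        raise QSSInfeasibleError(
            f"no ultrafast QSS root in the box: residual inf-norm {res:.3g} > {abs_tol:g}"
        )
    return z


def qss_fast(
    system,
    x: np.ndarray,
    u: np.ndarray,
    y0: np.ndarray | None = None,
    z0: np.ndarray | None = None,
    abs_tol: float = 1e-8,
    return_z: bool = False,
):
    """Fast-layer equilibrium ``y* = G(x, u)``.

    Solved jointly with the slaved ultrafast layer: find (y, z) in the box
    with both the signaling and metabolic unscaled derivatives zero.  Set
    ``return_z=True`` to also receive the consistent ``z* = H(x, u)``.
    """
    sysm = as_system(system)
    s, m = sysm.s, sysm.m

    def residual(v):
        y, z = v[:s], v[s:]
        _, dy, dz = sysm.derivative(x, y, z, u, 1.0, 1.0)
        return np.concatenate([np.atleast_1d(dy), np.atleast_1d(dz)])

    v0 = np.concatenate([
        np.full(s, 0.5) if y0 is None else np.asarray(y0, dtype=float),
        np.full(m, 0.5) if z0 is None else np.asarray(z0, dtype=float),
    ])
    v, res = _box_root(residual, v0, abs_tol)
    if res > abs_tol:
        raise QSSInfeasibleError(
            f"no fast QSS root in the box: residual inf-norm {res:.3g} > {abs_tol:g}"
        )
    return (v[:s], v[s:]) if return_z else v[:s]


def reduced_slow_derivative(system, x: np.ndarray, u: np.ndarray, **kw) -> np.ndarray:
    """Slow derivative with the fast layers at quasi-steady state:
    ``dx/dt = f(x, G(x,u), H(x,u), u)``."""
    sysm = as_system(system)
    y, z = qss_fast(sysm, x, u, return_z=True, **kw)
    return np.atleast_1d(sysm.derivative(x, y, z, u, 1.0, 1.0)[0])


def solve_equilibrium_input(
    system,
    state: StateVectors,
    u0: np.ndarray | None = None,
    max_nfev: int | None = 25,
    proximity: float = 0.0,
) -> tuple[np.ndarray, bool]:
    """Input ``u`` in [0,1]^c that best equilibrates the given state.

    Minimizes the 2-norm of the unscaled layer derivatives ``(f, g^, h^^)``
    over the input box (the timescale prefactors only rescale each layer's
    residual block, and the unscaled problem weights the layers equally;
    any exact equilibrium is a root of both).  Returns ``(u, exact)``
    where ``exact`` reports whether a root was found to solver precision.
    Never raises inside data-generation loops: on solver failure the
    starting input is returned with ``exact=False``.

    The inverse problem is typically under-determined (many inputs
    equilibrate a given state almost equally well); a positive
    ``proximity`` adds Tikhonov damping ``sqrt(proximity) * (u - u0)`` to
    the residual so successive solves along a trajectory vary smoothly
    instead of wandering across the solution set.
    """
    sysm = as_system(system)
    x, y, z = state.x, state.y, state.z
    u_start = state.u if u0 is None else np.asarray(u0, dtype=float)

    if isinstance(sysm, CompiledNetwork):
        n_state = sysm.p + sysm.s + sysm.m
        w_buf = np.empty(n_state + sysm.c)
        w_buf[:n_state] = np.concatenate([x, y, z])
        rhs = sysm.rhs(1.0, 1.0, lambda t: w_buf[n_state:], clip=False)
        v_state = w_buf[:n_state].copy()

        def residual_raw(u):
            w_buf[n_state:] = u
            return rhs(0.0, v_state)
    else:

        def residual_raw(u):
            dx, dy, dz = sysm.derivative(x, y, z, u, 1.0, 1.0)
            return np.concatenate([np.atleast_1d(dx), np.atleast_1d(dy), np.atleast_1d(dz)])

    if proximity > 0.0:
        w_prox = np.sqrt(proximity)
        u_ref = u_start.copy()

        def residual(u):
            return np.concatenate([residual_raw(u), w_prox * (u - u_ref)])
    else:
        residual = residual_raw

    try:
        sol = least_squares(
            residual,
            np.clip(u_start, 1e-9, 1 - 1e-9),
            bounds=(0.0, 1.0),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            max_nfev=max_nfev,
        )
    except Exception:
        return u_start.copy(), False
    raw = residual_raw(sol.x)
    exact = bool(np.max(np.abs(raw)) <= 1e-8) if np.size(raw) else True
    return sol.x, exact


def write_trajectory_csv(traj: Trajectory, spec: NetworkSpec, path: str | Path) -> Path:
    """Write a trajectory as CSV with header ``time,<species...>`` in
    canonical species order (genes, signaling, metabolites), then inputs."""
    cols = spec.species_names() + [f"u:{n}" for n in spec.input_names]
    df = pd.DataFrame(
        np.hstack([traj.X, traj.Y, traj.Z, traj.U]),
        columns=cols,
    )
    df.insert(0, "time", traj.times)
    path = Path(path)
    df.to_csv(path, index=False)
    return path
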