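"""Sliding-window supervised dataset for surrogate training.

The surrogate is a NARX-style regressor: each sample's regressor vector
``v`` stacks ``tau`` past (input instance, output instance) pairs, oldest
first, followed by the current input instance; the supervised target is
the current output instance.  With ``p + s + m`` outputs and ``c``
external inputs the regressor dimension is

    d = tau * (2*(p+s+m) + c) + (p+s+m+c)

(for the packaged network sizes and tau = 19 this is 4713, with a
107-dimensional target).

During generation the plant is driven in closed form: each output is fed
to the equilibrium-input solver to produce the next external input, to
which a small seeded uniform excitation jitter is added so that the
regressor matrix keeps full numerical rank instead of settling onto an
equilibrium orbit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .kinetics import StateVectors
from .plant import Plant
from .simulate import solve_equilibrium_input

__all__ = [
    "WindowSample",
    "Dataset",
    "window_dimension",
    "roll_window",
    "unroll_window",
    "generate_dataset",
    "split",
]

DEFAULT_TAU = 19
DEFAULT_JITTER = 0.02
DEFAULT_SEGMENT = None  # single closed-loop trajectory by default
DEFAULT_STATE_JITTER = 0.0  # optional single-coordinate pulse excitation
U_PROXIMITY = 1.0  # damping of the equilibrium-input solve along trajectories


@dataclass(frozen=True)
class WindowSample:
    """One supervised sample: regressor ``v`` (length d), target ``gamma``
    (length p+s+m) and its time index ``theta``."""

    v: np.ndarray
    gamma: np.ndarray
    theta: int


@dataclass
class Dataset:
    """Column-stacked window samples: ``V`` is (phi, d), ``G`` is
    (phi, p+s+m); ``meta`` records tau, dims and seeds."""

    V: np.ndarray
    G: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.V)

    def sample(self, i: int) -> WindowSample:
        return WindowSample(self.V[i], self.G[i], int(self.meta.get("theta0", 0)) + i)

    def save(self, path: str | Path) -> Path:
        """Persist as a two-array columnar archive with a manifest."""
        path = Path(path)
        np.savez_compressed(path, V=self.V, G=self.G,
                            meta=np.array(repr(self.meta), dtype=object))
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Dataset":
        import ast

        with np.load(path, allow_pickle=True) as archive:
            meta = ast.literal_eval(str(archive["meta"][()]))
            return cls(V=archive["V"], G=archive["G"], meta=meta)


def window_dimension(tau: int, p: int, s: int, m: int, c: int) -> int:
    """Regressor length ``tau*(2*(p+s+m)+c) + (p+s+m+c)``."""
    for label, v in [("tau", tau), ("p", p), ("s", s), ("m", m), ("c", c)]:
        if v < 0:
            raise ValueError(f"{label} must be >= 0, got {v}")
    out = p + s + m
    return tau * (2 * out + c) + (out + c)


def roll_window(
    inputs: np.ndarray,
    outputs: np.ndarray,
    theta: int,
    tau: int,
) -> WindowSample:
    """Build the window sample at time index ``theta``.

    ``inputs`` is a (T, p+s+m+c) array of input instances and ``outputs``
    the matching (T, p+s+m) array of output instances.  The regressor
    concatenates the (input, output) pairs at ages tau..1 (oldest first)
    and then the current input; the target is the current output.
    """
    if theta < tau:
        raise ValueError(f"insufficient history: theta={theta} < tau={tau}")
    if theta >= len(inputs):
        raise ValueError(f"theta={theta} beyond trajectory length {len(inputs)}")
    blocks = []
    for age in range(tau, 0, -1):
        t = theta - age
        blocks.append(inputs[t])
        blocks.append(outputs[t])
    blocks.append(inputs[theta])
    return WindowSample(
        v=np.concatenate(blocks),
        gamma=outputs[theta].copy(),
        theta=theta,
    )


def unroll_window(
    sample: WindowSample,
    tau: int,
    dims: tuple[int, int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Slice a regressor back into its (inputs, outputs) blocks.

    Returns (tau+1, p+s+m+c) inputs and (tau, p+s+m) past outputs; exact
    inverse of :func:`roll_window` on the stored trajectory rows.
    """
    p, s, m, c = dims
    n_in, n_out = p + s + m + c, p + s + m
    v = sample.v
    if v.shape != (window_dimension(tau, p, s, m, c),):
        raise ValueError("regressor length inconsistent with tau and dims")
    inputs = np.empty((tau + 1, n_in))
    outputs = np.empty((tau, n_out))
    off = 0
    for k in range(tau):
        inputs[k] = v[off:off + n_in]
        off += n_in
        outputs[k] = v[off:off + n_out]
        off += n_out
    inputs[tau] = v[off:off + n_in]
    return inputs, outputs


def _drive_plant(plant, state, u, n_steps, rng, jitter, u_solver,
                 state_jitter=0.0):
    """Closed-loop excitation: step, solve the equilibrium-tracking input,
    jitter it, and form the next input instance from the (optionally
    jittered) output.  State jitter perturbs every component of the next
    input instance so the regressors carry coordinate-wise variation
    around the trajectory, not just input variation."""
    p, s, m, c = plant.spec.dims
    n_in, n_out = p + s + m + c, p + s + m
    inputs = np.empty((n_steps, n_in))
    outputs = np.empty((n_steps, n_out))
    for t in range(n_steps):
        inst = np.concatenate([state.x, state.y, state.z, u])
        inputs[t] = inst
        try:
            out = plant.step(inst)
        except Exception:  # plant step failure -> truncate
            return inputs[:t], outputs[:t], t
        outputs[t] = out
        nxt = out.copy()
        if state_jitter > 0.0:
            # single-coordinate pulse: redraw one random state component so
            # consecutive samples isolate per-coordinate plant responses
            k = rng.integers(n_out)
            nxt[k] = rng.uniform(0.0, 1.0)
        state = StateVectors(nxt[:p], nxt[p:p + s], nxt[p + s:], u)
        if u_solver is not None:
            u_next, _ = u_solver(plant.compiled, state)
        else:
            u_next, _ = solve_equilibrium_input(plant.compiled, state,
                                                proximity=U_PROXIMITY)
        u = np.clip(u_next + rng.uniform(-jitter, jitter, c), 0.0, 1.0)
    return inputs, outputs, None


def generate_dataset(
    plant: Plant,
    phi: int,
    tau: int = DEFAULT_TAU,
    seed: int = 0,
    jitter: float = DEFAULT_JITTER,
    init: StateVectors | None = None,
    u_solver: Callable | None = None,
    segment_length: int | None = DEFAULT_SEGMENT,
    state_jitter: float = DEFAULT_STATE_JITTER,
) -> Dataset:
    """Drive the plant and collect ``phi`` window samples.

    Each cycle applies the current input instance to the plant, records
    the output, solves for the next equilibrium-tracking input, jitters it
    uniformly within ``±jitter`` (seeded) and forms the next input
    instance from the current output.

    By default the whole dataset comes from one closed-loop trajectory.
    With ``segment_length`` set, generation proceeds in segments of that
    many samples, each restarted from a fresh seeded random initial state
    in (0, 1) (the first segment uses ``init``/the plant's initial
    state): a single settled trajectory leaves the slow and pool
    coordinates unexplored, which matters when the dataset must support
    control rather than one-step prediction.
    With ``state_jitter`` nonzero, one random component of each next input
    instance is additionally redrawn uniformly (a single-coordinate pulse),
    so the dataset carries clean per-coordinate response information.
    Windows never straddle a restart.  A failed plant step truncates the
    dataset with a warning recorded in ``meta``.
    """
    if phi < 1:
        raise ValueError("phi must be >= 1")
    rng = np.random.default_rng(seed)
    p, s, m, c = plant.spec.dims
    n_out = p + s + m
    d = window_dimension(tau, p, s, m, c)
    seg = phi if segment_length is None else min(segment_length, phi)

    V_parts, G_parts = [], []
    truncated_at = None
    remaining = phi
    first = True
    while remaining > 0 and truncated_at is None:
        n_here = min(seg, remaining)
        if first:
            state = (init or plant.initial_state()).copy()
            first = False
        else:
            state = StateVectors(
                rng.uniform(0, 1, p), rng.uniform(0, 1, s),
                rng.uniform(0, 1, m), plant.u_default.copy(),
            )
            plant._apply_pins_state(state)
        u = state.u.copy()
        inputs, outputs, trunc = _drive_plant(
            plant, state, u, n_here + tau, rng, jitter, u_solver,
            state_jitter=state_jitter)
        if trunc is not None:
            truncated_at = phi - remaining + max(0, trunc - tau)
        n_avail = max(0, len(inputs) - tau)
        for i in range(min(n_here, n_avail)):
            ws = roll_window(inputs, outputs, theta=tau + i, tau=tau)
            V_parts.append(ws.v)
            G_parts.append(ws.gamma)
        remaining -= n_here

    V = np.asarray(V_parts) if V_parts else np.empty((0, d))
    G = np.asarray(G_parts) if G_parts else np.empty((0, n_out))
    meta = {
        "tau": tau,
        "dims": (p, s, m, c),
        "seed": seed,
        "jitter": jitter,
        "theta0": tau,
        "phi": len(V),
        "segment_length": seg,
        "state_jitter": state_jitter,
    }
    if truncated_at is not None:
        meta["truncated_at_step"] = truncated_at
    return Dataset(V=V, G=G, meta=meta)


def split(dataset: Dataset, train_fraction: float = 0.65, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded i.i.d. random split into (train, test) of sizes
    ``floor(phi * f)`` and the remainder; the two parts partition the
    dataset."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    order = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    tr, te = np.sort(order[:n_train]), np.sort(order[n_train:])
    meta = dict(dataset.meta)
    return (
        Dataset(V=dataset.V[tr], G=dataset.G[tr], meta={**meta, "part": "train"}),
        Dataset(V=dataset.V[te], G=dataset.G[te], meta={**meta, "part": "test"}),
    )
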