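"""MISO-ensemble epsilon-insensitive SVR surrogate of the plant.

One support vector regressor per output component mu = 1..(p+s+m), all
sharing a radial-basis kernel kappa(v, v') = exp(-g ||v - v'||^2).  Each
MISO model solves the standard epsilon-SVR dual

    min_{zeta, zeta*} 1/2 (zeta - zeta*)^T K (zeta - zeta*)
                      + eps * sum(zeta + zeta*) - gamma^T (zeta - zeta*)
    s.t. 0 <= zeta, zeta* <= C,  sum(zeta - zeta*) = 0,

and predicts gamma_hat = sum_b alpha_b kappa(v, v_b) + beta with
alpha_b = zeta_b - zeta_b*.  Defaults follow the plant-surrogate setting:
kernel coefficient 10, box constant C = 100, tube eps = 0.0025.

The Gram matrix is computed once and shared by all outputs (the per-output
solver runs on a precomputed kernel), which makes fitting an ensemble of
~100 outputs on a few thousand samples tractable.  Constant target columns
short-circuit to a bias-only model.  A small reference QP solver
(:func:`svr_dual_qp`) is provided for cross-checking the dual solution on
tiny problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVR

from .dataset import Dataset

__all__ = [
    "SVRHyperparams",
    "MISOModel",
    "SurrogateModel",
    "fit",
    "gram_matrix",
    "predict_with_context",
    "predict",
    "accuracy",
    "kkt_report",
    "svr_dual_qp",
]

MSE_THRESHOLD_DEFAULT = 0.05


@dataclass(frozen=True)
class SVRHyperparams:
    """Kernel coefficient (radial-basis gamma), box constant C and tube
    half-width epsilon."""

    kernel_coef: float = 10.0
    C: float = 100.0
    epsilon: float = 0.0025
    tol: float = 1e-4  # SMO stopping tolerance of the per-output solver
    history_weight: float = 1.0  # kernel feature weight of the past-lag blocks

    def __post_init__(self) -> None:
        if self.kernel_coef <= 0 or self.C <= 0 or self.epsilon < 0:
            raise ValueError(f"invalid hyperparameters: {self}")


@dataclass
class MISOModel:
    """One fitted single-output model: indices of its support vectors into
    the shared support-vector matrix, dual coefficients alpha = zeta -
    zeta*, and bias beta."""

    sv_indices: np.ndarray
    alpha: np.ndarray
    beta: float


@dataclass
class SurrogateModel:
    """Ensemble of MISO models sharing one support-vector matrix.

    With ``history_weight < 1`` the kernel acts on lag-weighted features:
    the trailing current-input block keeps unit weight while the past
    input/output blocks are scaled down.  The plant output is determined
    by the current input instance (the window is informationally
    redundant), so de-emphasizing the past lags concentrates the kernel
    metric on the coordinates that drive the response.
    """

    support_vectors: np.ndarray  # (n_train, d): full training inputs
    models: list[MISOModel]
    hyperparams: SVRHyperparams
    meta: dict = field(default_factory=dict)
    _weighted_sv: np.ndarray | None = None

    def stacked_coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_train, n_outputs) dual-coefficient matrix and bias
        vector, so batch prediction is a single matrix product."""
        if getattr(self, "_stacked", None) is None:
            n = len(self.support_vectors)
            A = np.zeros((n, self.n_outputs))
            beta = np.empty(self.n_outputs)
            for mu, mdl in enumerate(self.models):
                beta[mu] = mdl.beta
                if len(mdl.sv_indices):
                    A[mdl.sv_indices, mu] = mdl.alpha
            self._stacked = (A, beta)
        return self._stacked

    def _feature_weights(self, d: int) -> np.ndarray | None:
        hw = self.hyperparams.history_weight
        if hw >= 1.0:
            return None
        n_in = self.meta.get("n_in")
        w = np.full(d, np.sqrt(hw))
        if n_in:
            w[-int(n_in):] = 1.0
        return w

    @property
    def n_outputs(self) -> int:
        return len(self.models)

    @property
    def d(self) -> int:
        return self.support_vectors.shape[1]

    def kernel(self, V: np.ndarray) -> np.ndarray:
        w = self._feature_weights(self.support_vectors.shape[1])
        if w is None:
            return rbf_kernel(V, self.support_vectors, gamma=self.hyperparams.kernel_coef)
        if self._weighted_sv is None:
            self._weighted_sv = self.support_vectors * w[None, :]
        return rbf_kernel(V * w[None, :], self._weighted_sv,
                          gamma=self.hyperparams.kernel_coef)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {
            "support_vectors": self.support_vectors,
            "hyper": np.array([
                self.hyperparams.kernel_coef,
                self.hyperparams.C,
                self.hyperparams.epsilon,
                self.hyperparams.tol,
                self.hyperparams.history_weight,
            ]),
            "meta": np.array(repr(self.meta), dtype=object),
        }
        for i, m in enumerate(self.models):
            arrays[f"sv_{i}"] = m.sv_indices
            arrays[f"alpha_{i}"] = m.alpha
            arrays[f"beta_{i}"] = np.array([m.beta])
        np.savez_compressed(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SurrogateModel":
        import ast

        with np.load(path, allow_pickle=True) as arc:
            hyper = SVRHyperparams(*arc["hyper"].tolist())
            n_out = sum(1 for k in arc.files if k.startswith("beta_"))
            models = [
                MISOModel(
                    sv_indices=arc[f"sv_{i}"],
                    alpha=arc[f"alpha_{i}"],
                    beta=float(arc[f"beta_{i}"][0]),
                )
                for i in range(n_out)
            ]
            return cls(
                support_vectors=arc["support_vectors"],
                models=models,
                hyperparams=hyper,
                meta=ast.literal_eval(str(arc["meta"][()])),
            )


def gram_matrix(V: np.ndarray, hp: SVRHyperparams, n_in: int | None) -> np.ndarray:
    """Training Gram matrix under the (possibly lag-weighted) kernel."""
    if hp.history_weight < 1.0 and n_in:
        w = np.full(V.shape[1], np.sqrt(hp.history_weight))
        w[-int(n_in):] = 1.0
        Vw = V * w[None, :]
        return rbf_kernel(Vw, Vw, gamma=hp.kernel_coef)
    return rbf_kernel(V, V, gamma=hp.kernel_coef)


def fit(train: Dataset, hyperparams: SVRHyperparams | None = None,
        gram: np.ndarray | None = None) -> SurrogateModel:
    """Fit one epsilon-SVR per output on a shared precomputed Gram matrix.

    Target columns that are numerically constant get an empty support set
    with the constant as bias (the flat function lies inside the tube).
    ``gram`` short-circuits the Gram computation (e.g. when it is grown
    incrementally during online adaptation).
    """
    hp = hyperparams or SVRHyperparams()
    V, G = np.asarray(train.V, dtype=float), np.asarray(train.G, dtype=float)
    if len(V) == 0:
        raise ValueError("empty training set")
    if train.meta.get("dims"):
        p_, s_, m_, c_ = train.meta["dims"]
        n_in = p_ + s_ + m_ + c_
    else:
        n_in = None
    K = gram if gram is not None else gram_matrix(V, hp, n_in)
    models: list[MISOModel] = []
    for mu in range(G.shape[1]):
        g = G[:, mu]
        if np.ptp(g) <= hp.epsilon * 1e-3:
            models.append(MISOModel(
                sv_indices=np.empty(0, dtype=np.int64),
                alpha=np.empty(0),
                beta=float(g.mean()),
            ))
            continue
        est = SVR(kernel="precomputed", C=hp.C, epsilon=hp.epsilon, tol=hp.tol)
        est.fit(K, g)
        models.append(MISOModel(
            sv_indices=est.support_.astype(np.int64),
            alpha=est.dual_coef_.ravel().copy(),
            beta=float(est.intercept_[0]),
        ))
    return SurrogateModel(
        support_vectors=V,
        models=models,
        hyperparams=hp,
        meta={"n_train": len(V), "n_in": n_in,
              **{k: train.meta.get(k) for k in ("tau", "dims", "seed")}},
    )


def predict(model: SurrogateModel, V: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Kernel-expansion prediction for one regressor or a batch.

    Outputs are clamped to [0, 1] by default so predictions remain valid
    plant states for the controller loop.
    """
    V = np.asarray(V, dtype=float)
    single = V.ndim == 1
    if single:
        V = V[None, :]
    if V.shape[1] != model.d:
        raise ValueError(f"regressor length {V.shape[1]} != model dimension {model.d}")
    Kx = model.kernel(V)  # (n, n_train)
    out = np.empty((len(V), model.n_outputs))
    for mu, m in enumerate(model.models):
        if len(m.sv_indices) == 0:
            out[:, mu] = m.beta
        else:
            out[:, mu] = Kx[:, m.sv_indices] @ m.alpha + m.beta
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return out[0] if single else out


def predict_with_context(
    model: SurrogateModel,
    v_context: np.ndarray,
    genomes: np.ndarray,
    clamp: bool = True,
) -> np.ndarray:
    """Batch prediction for regressors that share every block of
    ``v_context`` except the trailing current-input block, which is
    replaced by each genome.

    The kernel distance splits into a per-support-vector constant (the
    shared history blocks) plus the current-block distance, so the
    expensive part is one small matrix product per call instead of a full
    d-dimensional kernel per candidate.
    """
    genomes = np.atleast_2d(np.asarray(genomes, dtype=float))
    n_in = genomes.shape[1]
    hp = model.hyperparams
    sv = model.support_vectors
    hw = hp.history_weight if hp.history_weight < 1.0 else 1.0
    hist_v = v_context[:-n_in]
    hist_sv = sv[:, :-n_in]
    cur_sv = sv[:, -n_in:]
    hist_d2 = hw * ((hist_sv - hist_v[None, :]) ** 2).sum(axis=1)  # (n_sv,)
    cur_d2 = (
        (genomes ** 2).sum(axis=1)[:, None]
        + (cur_sv ** 2).sum(axis=1)[None, :]
        - 2.0 * genomes @ cur_sv.T
    )
    K = np.exp(-hp.kernel_coef * (cur_d2 + hist_d2[None, :]))
    A, beta = model.stacked_coefficients()
    out = K @ A + beta[None, :]
    if clamp:
        out = np.clip(out, 0.0, 1.0)
    return out


def accuracy(
    model: SurrogateModel,
    test: Dataset,
    mse_threshold: float = MSE_THRESHOLD_DEFAULT,
) -> float:
    """Percentage of test samples whose mean squared error across all
    outputs is below the threshold."""
    if mse_threshold <= 0:
        raise ValueError("mse_threshold must be > 0")
    if len(test) == 0:
        raise ValueError("empty test set: accuracy undefined")
    pred = predict(model, test.V, clamp=False)
    mse = np.mean((pred - test.G) ** 2, axis=1)
    return 100.0 * float(np.mean(mse < mse_threshold))


def kkt_report(model: SurrogateModel, train: Dataset, tol: float = 1e-3) -> dict:
    """Karush-Kuhn-Tucker diagnostics for every fitted output.

    Checks the box constraint |alpha| <= C, the dual equality sum(alpha)
    = 0, and the tube condition: non-bound support vectors must sit on the
    epsilon-tube boundary, and every training residual must satisfy
    |r| <= eps + slack with slack only on bound vectors.
    """
    hp = model.hyperparams
    pred = predict(model, train.V, clamp=False)
    box_ok, dual_sums, tube_violations = [], [], []
    for mu, m in enumerate(model.models):
        box_ok.append(bool(np.all(np.abs(m.alpha) <= hp.C * (1 + 1e-9))))
        dual_sums.append(float(np.sum(m.alpha)))
        resid = train.G[:, mu] - pred[:, mu]
        free = np.zeros(len(train.V), dtype=bool)
        if len(m.sv_indices):
            free[m.sv_indices] = np.abs(m.alpha) < hp.C * (1 - 1e-6)
        inside = np.ones(len(train.V), dtype=bool)
        if len(m.sv_indices):
            bound_sv = m.sv_indices[np.abs(m.alpha) >= hp.C * (1 - 1e-6)]
            inside[bound_sv] = False  # bound SVs may lie outside the tube
        viol = np.abs(resid[inside]) - hp.epsilon
        tube_violations.append(float(viol.max()) if viol.size else 0.0)
    return {
        "box_ok": box_ok,
        "dual_sums": dual_sums,
        "max_abs_dual_sum": float(np.max(np.abs(dual_sums))) if dual_sums else 0.0,
        "tube_violations": tube_violations,
        "max_tube_violation": float(np.max(tube_violations)) if tube_violations else 0.0,
        "tol": tol,
    }


def svr_dual_qp(
    K: np.ndarray,
    g: np.ndarray,
    C: float,
    epsilon: float,
) -> tuple[np.ndarray, float]:
    """Reference epsilon-SVR dual solver for tiny problems (n <= ~60).

    Solves the standard 2n-variable dual QP in (zeta, zeta*) with exact
    gradients under the box constraints [0, C] and the equality
    ``sum(zeta - zeta*) = 0`` (sequential quadratic programming), then
    recovers the bias from the free (non-bound) support vectors.
    Intended as an independent oracle, not for production fitting.
    """
    from scipy.optimize import minimize

    n = len(g)

    def objective(v):
        zeta, zeta_s = v[:n], v[n:]
        a = zeta - zeta_s
        Ka = K @ a
        val = 0.5 * a @ Ka + epsilon * np.sum(zeta + zeta_s) - g @ a
        grad = np.concatenate([Ka + epsilon - g, -Ka + epsilon + g])
        return val, grad

    res = minimize(
        objective,
        np.zeros(2 * n),
        jac=True,
        method="SLSQP",
        bounds=[(0.0, C)] * (2 * n),
        constraints=[{"type": "eq",
                      "fun": lambda v: np.sum(v[:n] - v[n:]),
                      "jac": lambda v: np.concatenate([np.ones(n), -np.ones(n)])}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    alpha = res.x[:n] - res.x[n:]

    free = (np.abs(alpha) > 1e-7) & (np.abs(alpha) < C * (1 - 1e-6))
    pred_nob = K @ alpha
    if free.any():
        # on free SVs: g - pred = beta + eps*sign(alpha)
        betas = g[free] - pred_nob[free] - epsilon * np.sign(alpha[free])
        beta = float(np.median(betas))
    else:
        beta = float(np.median(g - pred_nob))
    return alpha, beta
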