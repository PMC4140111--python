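"""Elman recurrent network with sigmoid hidden / linear output layers,
batch Levenberg–Marquardt training, gradient-descent-with-momentum
training, and a feedforward (context-free) baseline.

The network computes

    x(k) = f(w1 u(k-1) + w2 x_c(k) + b_h),   f(z) = 1/(1 + e^{-z})
    y(k) = w3 x(k) + b_o                      (linear output)
    x_c(k) = x(k-1)                           (undertake/context layer)

The undertake layer always has the same neuron count as the hidden layer.
Because the classifier applies the net to non-sequential tabular samples,
the default context handling is reset-per-sample with two forward passes:
pass 1 (zero context) seeds x_c from the sample itself, pass 2 produces
the output.  This exercises the w2 recurrence while keeping predictions
independent of sample order; carry-over mode is available for genuinely
sequential data.  Biases are included so the sigmoid can shift.

Training follows the truncated-gradient convention for recurrent nets:
the context activations are treated as constants while differentiating,
which makes batch Levenberg–Marquardt well defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElmanNet",
    "TrainConfig",
    "TrainReport",
    "hidden_size",
    "sse",
    "train_lm",
    "train_gdm",
    "predict_labels",
    "decode_labels",
    "make_elman_net",
    "make_bp_net",
]


def hidden_size(n: int, m: int) -> int:
    """Empirical hidden-neuron count from the input/output layer sizes:
    s = round(sqrt(0.43 n m + 0.12 m² + 2.54 n + 0.77 m + 0.35) + 0.51)."""
    if n < 1 or m < 1:
        raise ValueError("layer sizes must be positive")
    s = math.sqrt(0.43 * n * m + 0.12 * m * m + 2.54 * n + 0.77 * m + 0.35) + 0.51
    return max(int(math.floor(s + 0.5)), 1)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sse(targets: np.ndarray, outputs: np.ndarray) -> float:
    """Sum of squared errors Σ (t - y)² over all outputs and samples."""
    targets = np.asarray(targets, dtype=float)
    outputs = np.asarray(outputs, dtype=float)
    if targets.shape != outputs.shape:
        raise ValueError("targets and outputs must have equal shapes")
    return float(np.sum((targets - outputs) ** 2))


class ElmanNet:
    """Weights, biases and context state of one network.

    ``recurrent=False`` freezes w2 at zero and trains it never — the plain
    feedforward (BP-style) baseline with an otherwise identical surface.
    The same seed yields identical w1/w3/bias initializations for the
    recurrent and feedforward nets.
    """

    def __init__(
        self,
        n_inputs: int,
        n_hidden: int,
        n_outputs: int,
        seed: int | None = None,
        recurrent: bool = True,
    ):
        if min(n_inputs, n_hidden, n_outputs) < 1:
            raise ValueError("layer sizes must be positive")
        self.n = n_inputs
        self.r = n_hidden
        self.m = n_outputs
        self.recurrent = recurrent
        rng = np.random.default_rng(seed)
        # fixed draw order keeps w1/w3/biases seed-identical across variants
        self.w1 = rng.uniform(-0.5, 0.5, size=(self.r, self.n))
        self.w2 = rng.uniform(-0.5, 0.5, size=(self.r, self.r))
        self.w3 = rng.uniform(-0.5, 0.5, size=(self.m, self.r))
        self.b_hidden = rng.uniform(-0.5, 0.5, size=self.r)
        self.b_output = rng.uniform(-0.5, 0.5, size=self.m)
        if not recurrent:
            self.w2 = np.zeros((self.r, self.r))
        self.context = np.zeros(self.r)

    # -- stateful single-step interface -------------------------------

    def reset_context(self) -> None:
        self.context = np.zeros(self.r)

    def forward(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One time step: returns (y, x) and stores x as the new context."""
        u = np.asarray(u, dtype=float).ravel()
        if u.shape[0] != self.n:
            raise ValueError(f"input length {u.shape[0]} != n_inputs {self.n}")
        x = _sigmoid(self.w1 @ u + self.w2 @ self.context + self.b_hidden)
        y = self.w3 @ x + self.b_output
        if not np.all(np.isfinite(x)):
            raise FloatingPointError("non-finite hidden activation")
        self.context = x
        return y, x

    # -- batch interface ----------------------------------------------

    def _batch_contexts(self, X: np.ndarray, context_mode: str) -> np.ndarray:
        """Per-sample frozen context vectors.

        reset-per-sample: pass-1 activation from zero context;
        carry-over: sequential pass through the rows.
        """
        if not self.recurrent or context_mode == "none":
            return np.zeros((X.shape[0], self.r))
        if context_mode == "reset":
            return _sigmoid(X @ self.w1.T + self.b_hidden)
        if context_mode == "carry":
            C = np.zeros((X.shape[0], self.r))
            ctx = np.zeros(self.r)
            for i, u in enumerate(X):
                C[i] = ctx
                ctx = _sigmoid(self.w1 @ u + self.w2 @ ctx + self.b_hidden)
            return C
        raise ValueError(f"unknown context_mode {context_mode!r}")

    def predict(self, X: np.ndarray, context_mode: str = "reset") -> np.ndarray:
        """Batch outputs, (n_samples, m)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        C = self._batch_contexts(X, context_mode)
        H = _sigmoid(X @ self.w1.T + C @ self.w2.T + self.b_hidden)
        return H @ self.w3.T + self.b_output

    # -- parameter vector ---------------------------------------------

    @property
    def n_params(self) -> int:
        base = self.r * self.n + self.m * self.r + self.r + self.m
        return base + (self.r * self.r if self.recurrent else 0)

    def get_params(self) -> np.ndarray:
        parts = [self.w1.ravel()]
        if self.recurrent:
            parts.append(self.w2.ravel())
        parts += [self.w3.ravel(), self.b_hidden, self.b_output]
        return np.concatenate(parts)

    def set_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[0] != self.n_params:
            raise ValueError("parameter vector length mismatch")
        i = 0

        def take(shape):
            nonlocal i
            size = int(np.prod(shape))
            out = theta[i : i + size].reshape(shape)
            i += size
            return out.copy()

        self.w1 = take((self.r, self.n))
        if self.recurrent:
            self.w2 = take((self.r, self.r))
        self.w3 = take((self.m, self.r))
        self.b_hidden = take((self.r,))
        self.b_output = take((self.m,))

    def jacobian(self, X: np.ndarray, contexts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """∂y/∂θ of the truncated model (contexts constant).

        Returns (J, Y): J has shape (n_samples·m, n_params) with rows in
        sample-major order, Y the (n_samples, m) outputs at the frozen
        contexts.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        N = X.shape[0]
        Z = X @ self.w1.T + contexts @ self.w2.T + self.b_hidden
        H = _sigmoid(Z)
        Y = H @ self.w3.T + self.b_output
        dH = H * (1.0 - H)  # σ'(z)

        P = self.n_params
        J = np.zeros((N * self.m, P))
        for k in range(self.m):
            # d y_k / d z_j = w3[k, j] * σ'(z_j)
            g = dH * self.w3[k]  # (N, r)
            col = 0
            # w1 (r, n): dy/dw1[j, a] = g[:, j] * X[:, a]
            block = (g[:, :, None] * X[:, None, :]).reshape(N, -1)
            J[k :: self.m, col : col + self.r * self.n] = block
            col += self.r * self.n
            if self.recurrent:
                block = (g[:, :, None] * contexts[:, None, :]).reshape(N, -1)
                J[k :: self.m, col : col + self.r * self.r] = block
                col += self.r * self.r
            # w3 (m, r): dy_k/dw3[k, j] = H[:, j]
            w3block = np.zeros((N, self.m * self.r))
            w3block[:, k * self.r : (k + 1) * self.r] = H
            J[k :: self.m, col : col + self.m * self.r] = w3block
            col += self.m * self.r
            J[k :: self.m, col : col + self.r] = g
            col += self.r
            bo = np.zeros((N, self.m))
            bo[:, k] = 1.0
            J[k :: self.m, col : col + self.m] = bo
        return J, Y

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r": self.r,
            "m": self.m,
            "recurrent": self.recurrent,
            "w1": self.w1.tolist(),
            "w2": self.w2.tolist(),
            "w3": self.w3.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "b_output": self.b_output.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElmanNet":
        net = cls(d["n"], d["r"], d["m"], seed=0, recurrent=d["recurrent"])
        net.w1 = np.asarray(d["w1"], dtype=float)
        net.w2 = np.asarray(d["w2"], dtype=float)
        net.w3 = np.asarray(d["w3"], dtype=float)
        net.b_hidden = np.asarray(d["b_hidden"], dtype=float)
        net.b_output = np.asarray(d["b_output"], dtype=float)
        net.reset_context()
        return net

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "ElmanNet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_elman_net(n: int, r: int, m: int, seed: int | None = None) -> ElmanNet:
    return ElmanNet(n, r, m, seed=seed, recurrent=True)


def make_bp_net(n: int, r: int, m: int, seed: int | None = None) -> ElmanNet:
    """Feedforward baseline: w2 frozen at zero, context never used."""
    return ElmanNet(n, r, m, seed=seed, recurrent=False)


@dataclass
class TrainConfig:
    max_epochs: int = 2000
    goal_sse: float = 1e-3
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    seed: int | None = None
    context_mode: str = "reset"  # reset-per-sample | carry-over
    forward_passes_per_sample: int = 2

    def __post_init__(self) -> None:
        if self.mu_init <= 0 or self.mu_inc <= 1 or not 0 < self.mu_dec < 1:
            raise ValueError("require mu_init > 0, mu_inc > 1, 0 < mu_dec < 1")
        if self.forward_passes_per_sample < 1:
            raise ValueError("forward_passes_per_sample must be ≥ 1")


@dataclass
class TrainReport:
    epochs_run: int
    final_sse: float
    sse_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _batch_sse(net: ElmanNet, X: np.ndarray, T: np.ndarray, context_mode: str) -> float:
    return sse(T, net.predict(X, context_mode=context_mode))


def train_lm(net: ElmanNet, X: np.ndarray, T: np.ndarray, cfg: TrainConfig) -> TrainReport:
    """Batch Levenberg–Marquardt.

    Each epoch: freeze per-sample contexts, build the Jacobian of the
    residuals w.r.t. all trainable parameters, solve (J'J + μI)Δ = J'e,
    and accept the step only if the full-network SSE decreases (then
    μ ← μ·mu_dec); otherwise μ ← μ·mu_inc and retry.  Stops at goal_sse,
    max_epochs, or μ overflow.  The accepted-step SSE trace is therefore
    non-increasing by construction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if T.shape != (X.shape[0], net.m):
        raise ValueError("target shape mismatch")

    mode = "reset" if cfg.context_mode.startswith("reset") else "carry"
    s = _batch_sse(net, X, T, mode)
    trace = [s]
    if s <= cfg.goal_sse:
        return TrainReport(epochs_run=0, final_sse=s, sse_trace=np.asarray(trace))

    mu = cfg.mu_init
    epochs = 0
    eye = np.eye(net.n_params)
    for _ in range(cfg.max_epochs):
        contexts = net._batch_contexts(X, mode)
        J, Y = net.jacobian(X, contexts)
        e = (T - Y).ravel()
        g = J.T @ e
        A = J.T @ J
        theta = net.get_params()
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(A + mu * eye, g)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_inc
                continue
            net.set_params(theta + delta)
            trial = _batch_sse(net, X, T, mode)
            if np.isfinite(trial) and trial < s:
                s = trial
                mu = max(mu * cfg.mu_dec, 1e-20)
                accepted = True
                break
            net.set_params(theta)
            mu *= cfg.mu_inc
        if not accepted:
            break  # μ overflow: no decreasing step exists at this damping range
        epochs += 1
        trace.append(s)
        if s <= cfg.goal_sse:
            break
    return TrainReport(epochs_run=epochs, final_sse=s, sse_trace=np.asarray(trace))


def train_gdm(
    net: ElmanNet,
    X: np.ndarray,
    T: np.ndarray,
    lr: float = 0.01,
    momentum: float = 0.9,
    epochs: int = 1000,
    context_mode: str = "reset",
    goal_sse: float = 0.0,
) -> TrainReport:
    """Batch gradient descent with momentum on the truncated gradient:
    v ← momentum·v − lr·∇SSE, θ ← θ + v.  Raises if the SSE diverges to
    a non-finite value."""
    if lr < 0 or not 0 <= momentum < 1:
        raise ValueError("require lr ≥ 0 and 0 ≤ momentum < 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    mode = "reset" if context_mode.startswith("reset") else "carry"
    v = np.zeros(net.n_params)
    trace = []
    s = _batch_sse(net, X, T, mode)
    trace.append(s)
    run = 0
    for _ in range(epochs):
        contexts = net._batch_contexts(X, mode)
        J, Y = net.jacobian(X, contexts)
        e = (T - Y).ravel()
        grad = -2.0 * (J.T @ e)  # ∇ SSE
        v = momentum * v - lr * grad
        net.set_params(net.get_params() + v)
        s = _batch_sse(net, X, T, mode)
        run += 1
        trace.append(s)
        if not np.isfinite(s):
            raise FloatingPointError(f"gradient-descent training diverged at epoch {run}")
        if s <= goal_sse:
            break
    return TrainReport(epochs_run=run, final_sse=s, sse_trace=np.asarray(trace))


def decode_labels(outputs: np.ndarray, class_values: np.ndarray) -> np.ndarray:
    """Map continuous outputs to the nearest class value; ties go to the
    lower class."""
    class_values = np.asarray(class_values, dtype=float).ravel()
    if class_values.size == 0:
        raise ValueError("class_values must be nonempty")
    outputs = np.asarray(outputs, dtype=float).reshape(-1)
    # searchsorted on midpoints: value exactly at a midpoint joins the lower class
    mids = (class_values[:-1] + class_values[1:]) / 2.0
    idx = np.searchsorted(mids, outputs, side="left")
    return class_values[idx]


def predict_labels(
    net: ElmanNet, X: np.ndarray, class_values: np.ndarray, context_mode: str = "reset"
) -> np.ndarray:
    out = net.predict(X, context_mode=context_mode)
    if net.m != 1:
        raise ValueError("nearest-class decoding applies to single-output nets")
    return decode_labels(out[:, 0], class_values)
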