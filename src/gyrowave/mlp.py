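"""Three-layer feed-forward network trained with Levenberg–Marquardt.

The classifier is a single-hidden-layer perceptron with logistic (log-
sigmoid) hidden units and linear outputs.  Targets are one-hot coded —
output i is 1 for class i, 0 otherwise — and predictions use the
max-selection rule with ties broken toward the lowest class index.

Training minimizes the sum of squared errors over all outputs with the
damped Gauss–Newton (Levenberg–Marquardt) update

    dw = (J'J + lambda I)^{-1} J' e,

where J is the Jacobian of the per-pattern, per-output residuals with
respect to every weight and bias.  A step is accepted only if it lowers
the SSE; otherwise the damping lambda is raised, interpolating toward
(scaled) gradient descent.  Hidden-layer sizing uses "enlarging": train at
increasing hidden sizes and keep the smallest that fully learns the
training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkConfig",
    "MLPNetwork",
    "TrainingOptions",
    "one_hot",
    "init_network",
    "forward",
    "predict",
    "jacobian",
    "lm_train",
    "TrainingResult",
    "enlarge_hidden",
    "EnlargeResult",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Layer sizes in n1:n2:n3 form (input, hidden, output)."""

    n_in: int
    n_hidden: int
    n_out: int

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be positive")

    @property
    def n_params(self) -> int:
        return (self.n_in + 1) * self.n_hidden + (self.n_hidden + 1) * self.n_out

    def __str__(self) -> str:
        return f"{self.n_in}:{self.n_hidden}:{self.n_out}"


@dataclass
class MLPNetwork:
    W1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    W2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)

    @property
    def config(self) -> NetworkConfig:
        return NetworkConfig(self.W1.shape[1], self.W1.shape[0], self.W2.shape[0])

    def copy(self) -> "MLPNetwork":
        return MLPNetwork(self.W1.copy(), self.b1.copy(),
                          self.W2.copy(), self.b2.copy())


@dataclass(frozen=True)
class TrainingOptions:
    """Levenberg–Marquardt schedule and stopping rules.

    Training stops at ``goal_mse`` (mean squared error over all outputs),
    after ``max_epochs`` accepted/attempted epochs, when the damping
    exceeds ``max_lambda`` without an acceptable step, or — if
    ``goal_accuracy`` is set — once training-set classification accuracy
    (percent) reaches it.
    """

    lambda_init: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    max_lambda: float = 1e10
    max_epochs: int = 200
    goal_mse: float = 1e-4
    goal_accuracy: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lambda_up > 1.0 > self.lambda_down > 0.0):
            raise ValueError("require lambda_up > 1 > lambda_down > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def one_hot(labels, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """One-hot target matrix and the class-id vector indexing its columns."""
    labels = np.asarray(labels)
    classes = np.unique(labels) if classes is None else np.asarray(classes)
    T = (labels[:, None] == classes[None, :]).astype(float)
    if not np.all(T.sum(axis=1) == 1):
        raise ValueError("every label must match exactly one class id")
    return T, classes


def init_network(config: NetworkConfig, seed: int = 0) -> MLPNetwork:
    """Uniform fan-in/fan-out initialization; biases start at zero."""
    rng = np.random.default_rng(seed)
    a1 = np.sqrt(6.0 / (config.n_in + config.n_hidden))
    a2 = np.sqrt(6.0 / (config.n_hidden + config.n_out))
    return MLPNetwork(
        W1=rng.uniform(-a1, a1, size=(config.n_hidden, config.n_in)),
        b1=np.zeros(config.n_hidden),
        W2=rng.uniform(-a2, a2, size=(config.n_out, config.n_hidden)),
        b2=np.zeros(config.n_out),
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def forward(net: MLPNetwork, x) -> tuple[np.ndarray, np.ndarray]:
    """Outputs and hidden activations; accepts one vector or a matrix."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != net.W1.shape[1]:
        raise ValueError(f"input dimension {X.shape[1]} does not match "
                         f"network n_in {net.W1.shape[1]}")
    H = _sigmoid(X @ net.W1.T + net.b1)
    Y = H @ net.W2.T + net.b2
    if single:
        return Y[0], H[0]
    return Y, H


def predict(net: MLPNetwork, x, classes=None) -> np.ndarray | int:
    """Max-selection rule; ties go to the lowest class index.

    Without an explicit ``classes`` vector, classes are numbered 1..n_out.
    """
    Y, _ = forward(net, np.atleast_2d(np.asarray(x, dtype=float)))
    idx = np.argmax(Y, axis=1)  # argmax returns the first (lowest) maximum
    if classes is None:
        out = idx + 1
    else:
        out = np.asarray(classes)[idx]
    if np.asarray(x).ndim == 1:
        return out[0]
    return out


# --------------------------------------------------------------------------
# Levenberg–Marquardt
# --------------------------------------------------------------------------

def _pack(net: MLPNetwork) -> np.ndarray:
    return np.concatenate([net.W1.ravel(), net.b1, net.W2.ravel(), net.b2])


def _unpack(theta: np.ndarray, config: NetworkConfig) -> MLPNetwork:
    i, h, o = config.n_in, config.n_hidden, config.n_out
    parts = np.split(theta, np.cumsum([h * i, h, o * h])[:3])
    return MLPNetwork(parts[0].reshape(h, i), parts[1],
                      parts[2].reshape(o, h), parts[3])


def _residuals(net: MLPNetwork, X: np.ndarray, T: np.ndarray) -> np.ndarray:
    Y, _ = forward(net, X)
    return (Y - T).ravel()


def jacobian(net: MLPNetwork, X: np.ndarray) -> np.ndarray:
    """Jacobian of all per-pattern, per-output residuals w.r.t. all params.

    Rows are ordered (pattern, output) C-style, columns follow the packing
    (W1, b1, W2, b2).  Residuals are y − t, so dr/dtheta = dy/dtheta.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    P = X.shape[0]
    cfg = net.config
    _, H = forward(net, X)          # (P, h)
    S = H * (1.0 - H)               # sigmoid derivative at hidden pre-acts
    K, h = cfg.n_out, cfg.n_hidden

    J_W1 = np.einsum("kj,pj,pi->pkji", net.W2, S, X).reshape(P, K, h * cfg.n_in)
    J_b1 = np.einsum("kj,pj->pkj", net.W2, S)
    J_W2 = np.zeros((P, K, K, h))
    for k in range(K):
        J_W2[:, k, k, :] = H
    J_W2 = J_W2.reshape(P, K, K * h)
    J_b2 = np.broadcast_to(np.eye(K), (P, K, K))
    J = np.concatenate([J_W1, J_b1, J_W2, J_b2], axis=2)
    return J.reshape(P * K, cfg.n_params)


@dataclass
class TrainingResult:
    network: MLPNetwork
    loss_history: list[float]  # SSE after each accepted step (index 0: initial)
    n_epochs: int
    stop_reason: str
    final_mse: float


def lm_train(net: MLPNetwork, X, T, opts: TrainingOptions = TrainingOptions()
             ) -> TrainingResult:
    """Levenberg–Marquardt training on one-hot targets ``T``.

    Returns a new network (the input is not modified) together with the
    SSE history over accepted steps, which is non-increasing by
    construction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] != T.shape[0]:
        raise ValueError("X and T must have the same number of patterns")
    if X.shape[0] < 1:
        raise ValueError("at least one training pattern is required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("training data must be finite")

    cfg = net.config
    theta = _pack(net)
    n_outputs_total = T.size
    labels_idx = np.argmax(T, axis=1)

    r = _residuals(_unpack(theta, cfg), X, T)
    sse = float(r @ r)
    if not np.isfinite(sse):
        raise FloatingPointError("non-finite initial loss")
    history = [sse]
    lam = opts.lambda_init
    eye = np.eye(cfg.n_params)
    stop_reason = "max_epochs"
    epoch = 0

    def _train_accuracy(th: np.ndarray) -> float:
        Y, _ = forward(_unpack(th, cfg), X)
        return 100.0 * float(np.mean(np.argmax(Y, axis=1) == labels_idx))

    while epoch < opts.max_epochs:
        if sse / n_outputs_total <= opts.goal_mse:
            stop_reason = "goal_mse"
            break
        if (opts.goal_accuracy is not None
                and _train_accuracy(theta) >= opts.goal_accuracy):
            stop_reason = "goal_accuracy"
            break
        epoch += 1
        net_cur = _unpack(theta, cfg)
        J = jacobian(net_cur, X)
        g = J.T @ r
        JtJ = J.T @ J
        accepted = False
        while lam <= opts.max_lambda:
            try:
                step = np.linalg.solve(JtJ + lam * eye, g)
            except np.linalg.LinAlgError:
                lam *= opts.lambda_up
                continue
            theta_new = theta - step
            r_new = _residuals(_unpack(theta_new, cfg), X, T)
            sse_new = float(r_new @ r_new)
            if np.isfinite(sse_new) and sse_new < sse:
                theta, r, sse = theta_new, r_new, sse_new
                history.append(sse)
                lam = max(lam * opts.lambda_down, np.finfo(float).tiny)
                accepted = True
                break
            lam *= opts.lambda_up
        if not accepted:
            stop_reason = "max_lambda"
            break

    return TrainingResult(
        network=_unpack(theta, cfg),
        loss_history=history,
        n_epochs=epoch,
        stop_reason=stop_reason,
        final_mse=sse / n_outputs_total,
    )


# --------------------------------------------------------------------------
# hidden-layer sizing
# --------------------------------------------------------------------------

@dataclass
class EnlargeResult:
    n_hidden: int
    network: MLPNetwork
    trace: list[dict]  # one row per tried size: n_hidden, train_accuracy, sse
    config: NetworkConfig


def enlarge_hidden(n_in: int, n_out: int, X, T,
                   opts: TrainingOptions = TrainingOptions(), *,
                   h_min: int = 2, h_step: int = 2, h_max: int = 32,
                   seed: int = 0) -> EnlargeResult:
    """Grow the hidden layer until the training set is fully learned.

    Trains at h = h_min, h_min + h_step, ... and returns the smallest
    hidden size that reaches 100% training-set classification accuracy;
    if none does, the best-performing size is returned.  The full trace of
    tried sizes is reported.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if X.shape[0] < 1:
        raise ValueError("enlarging requires a non-empty training set")
    if h_min > h_max:
        raise ValueError("h_min must not exceed h_max")
    labels_idx = np.argmax(T, axis=1)

    trace: list[dict] = []
    best = None  # (accuracy, -h, network, h)
    for h in range(h_min, h_max + 1, h_step):
        cfg = NetworkConfig(n_in, h, n_out)
        result = lm_train(init_network(cfg, seed), X, T, opts)
        Y, _ = forward(result.network, X)
        acc = 100.0 * float(np.mean(np.argmax(Y, axis=1) == labels_idx))
        trace.append({"n_hidden": h, "train_accuracy": acc,
                      "sse": result.loss_history[-1],
                      "stop_reason": result.stop_reason})
        if best is None or acc > best[0]:
            best = (acc, result.network, h)
        if acc >= 100.0:
            break
    acc, network, h = best
    return EnlargeResult(n_hidden=h, network=network, trace=trace,
                         config=NetworkConfig(n_in, h, n_out))


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def save_network(net: MLPNetwork, path: str | Path, *,
                 opts: TrainingOptions | None = None,
                 final_mse: float | None = None,
                 classes=None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = net.config
    doc = {
        "config": {"n_in": cfg.n_in, "n_hidden": cfg.n_hidden, "n_out": cfg.n_out},
        "W1": net.W1.ravel().tolist(),
        "b1": net.b1.tolist(),
        "W2": net.W2.ravel().tolist(),
        "b2": net.b2.tolist(),
        "training_options": None if opts is None else {
            k: getattr(opts, k) for k in (
                "lambda_init", "lambda_up", "lambda_down", "max_lambda",
                "max_epochs", "goal_mse", "goal_accuracy", "seed")},
        "final_mse": final_mse,
        "classes": None if classes is None else np.asarray(classes).tolist(),
    }
    path.write_text(json.dumps(doc))
    return path


def load_network(path: str | Path) -> tuple[MLPNetwork, dict]:
    doc = json.loads(Path(path).read_text())
    c = doc["config"]
    net = MLPNetwork(
        W1=np.asarray(doc["W1"]).reshape(c["n_hidden"], c["n_in"]),
        b1=np.asarray(doc["b1"]),
        W2=np.asarray(doc["W2"]).reshape(c["n_out"], c["n_hidden"]),
        b2=np.asarray(doc["b2"]),
    )
    return net, doc
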