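"""Feedforward network trained by backpropagation with momentum.

An 8-input, single-hidden-layer, 1-output network with logistic sigmoid
activations throughout, written directly against numpy.  Training is
full-batch gradient descent on the mean squared error with a momentum
term,

    dW <- momentum * dW - lr * dE/dW,    W <- W + dW,

stopping when the epoch MSE reaches the learning goal or the epoch
budget is spent.  Alongside the MSE, each epoch logs the normalized
absolute deviation

    d = ( sum_i |Y_i - P_i| / Y_max ) / m,

the target-value statistic used to judge how far the network's
predictions P sit from the desired outputs Y (m samples, Y_max the
largest desired output).

Defaults: learning rate 0.01, momentum 0.2, learning goal 2e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_INPUTS = 8


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class NetworkModel:
    """Weights of an ``n_inputs -> hidden -> 1`` sigmoid network."""

    w_hidden: np.ndarray   # (H, n_inputs)
    b_hidden: np.ndarray   # (H,)
    w_out: np.ndarray      # (H,)
    b_out: float
    trained: bool = False

    def __post_init__(self):
        self.w_hidden = np.asarray(self.w_hidden, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        H, n_in = self.w_hidden.shape
        if H < 1:
            raise ValueError("need at least one hidden unit")
        if self.b_hidden.shape != (H,) or self.w_out.shape != (H,):
            raise ValueError("inconsistent layer shapes")
        for arr in (self.w_hidden, self.b_hidden, self.w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def hidden_size(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.w_hidden.shape[1]

    def to_dict(self) -> dict:
        return {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": float(self.b_out),
            "trained": bool(self.trained),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(w_hidden=np.asarray(d["w_hidden"]),
                   b_hidden=np.asarray(d["b_hidden"]),
                   w_out=np.asarray(d["w_out"]),
                   b_out=float(d["b_out"]), trained=bool(d["trained"]))


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.2
    learning_goal: float = 0.0002
    max_epochs: int = 20000
    hidden_size: int = 8

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.learning_goal <= 0:
            raise ValueError("learning_goal must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be non-negative")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")


def init_network(hidden_size: int = 8, seed=None, n_inputs: int = N_INPUTS) -> NetworkModel:
    """Fresh network with weights uniform on [-0.5, 0.5], seeded."""
    if hidden_size < 1:
        raise ValueError("hidden_size must be >= 1")
    rng = np.random.default_rng(seed)
    return NetworkModel(
        w_hidden=rng.uniform(-0.5, 0.5, size=(hidden_size, n_inputs)),
        b_hidden=rng.uniform(-0.5, 0.5, size=hidden_size),
        w_out=rng.uniform(-0.5, 0.5, size=hidden_size),
        b_out=float(rng.uniform(-0.5, 0.5)),
    )


def forward(net: NetworkModel, x) -> float:
    """Sigmoid feedforward pass for one input vector; output in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_inputs,):
        raise ValueError(f"input must be a length-{net.n_inputs} vector")
    hidden = _sigmoid(net.w_hidden @ x + net.b_hidden)
    return float(_sigmoid(net.w_out @ hidden + net.b_out))


def forward_batch(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    hidden = _sigmoid(X @ net.w_hidden.T + net.b_hidden)
    return _sigmoid(hidden @ net.w_out + net.b_out)


def target_value(Y, P) -> float:
    """Normalized mean absolute deviation d = (sum |Y_i - P_i| / Y_max) / m."""
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y.shape != P.shape or Y.ndim != 1 or Y.size == 0:
        raise ValueError("Y and P must be equal-length non-empty vectors")
    y_max = float(np.max(Y))
    if y_max == 0:
        raise ValueError("max(Y) must be nonzero to normalize the deviation")
    return float(np.sum(np.abs(Y - P) / y_max) / Y.size)


def _loss_and_grads(net: NetworkModel, X: np.ndarray, y: np.ndarray):
    """Batch MSE and its gradients w.r.t. every parameter (backprop)."""
    m = X.shape[0]
    hidden = _sigmoid(X @ net.w_hidden.T + net.b_hidden)        # (m, H)
    out = _sigmoid(hidden @ net.w_out + net.b_out)              # (m,)
    err = out - y
    mse = float(np.mean(err ** 2))
    delta_out = (2.0 / m) * err * out * (1.0 - out)             # (m,)
    g_w_out = hidden.T @ delta_out                              # (H,)
    g_b_out = float(delta_out.sum())
    delta_h = np.outer(delta_out, net.w_out) * hidden * (1.0 - hidden)  # (m, H)
    g_w_hidden = delta_h.T @ X                                  # (H, n_in)
    g_b_hidden = delta_h.sum(axis=0)
    return mse, out, (g_w_hidden, g_b_hidden, g_w_out, g_b_out)


@dataclass
class TrainResult:
    net: NetworkModel
    history: list = field(default_factory=list)  # (epoch, mse, d)
    epochs: int = 0
    converged: bool = False

    @property
    def final_mse(self) -> float:
        return self.history[-1][1]


def train(net: NetworkModel, X, y, config: TrainConfig | None = None) -> TrainResult:
    """Full-batch backpropagation with momentum until the learning goal.

    ``X`` is (m, n_inputs); ``y`` holds targets strictly inside (0, 1)
    so the sigmoid output can reach them.  The epoch error is evaluated
    before each update, so a dataset the network already fits stops at
    epoch 0 without touching the weights.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("training dataset must be non-empty")
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of samples")
    if X.shape[1] != net.n_inputs:
        raise ValueError(f"inputs must have {net.n_inputs} features")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("targets must lie strictly inside (0, 1)")

    velocity = [np.zeros_like(net.w_hidden), np.zeros_like(net.b_hidden),
                np.zeros_like(net.w_out), 0.0]
    history = []
    epoch = 0
    converged = False
    while True:
        mse, out, grads = _loss_and_grads(net, X, y)
        history.append((epoch, mse, target_value(y, out)))
        if mse <= config.learning_goal:
            converged = True
            break
        if epoch >= config.max_epochs:
            break
        velocity[0] = config.momentum * velocity[0] - config.learning_rate * grads[0]
        velocity[1] = config.momentum * velocity[1] - config.learning_rate * grads[1]
        velocity[2] = config.momentum * velocity[2] - config.learning_rate * grads[2]
        velocity[3] = config.momentum * velocity[3] - config.learning_rate * grads[3]
        net.w_hidden = net.w_hidden + velocity[0]
        net.b_hidden = net.b_hidden + velocity[1]
        net.w_out = net.w_out + velocity[2]
        net.b_out = net.b_out + velocity[3]
        epoch += 1
    net.trained = True
    return TrainResult(net=net, history=history, epochs=epoch, converged=converged)


@dataclass
class StageDecision:
    score: float
    threshold: float

    @property
    def proceed(self) -> bool:
        return self.score >= self.threshold

    @property
    def retrain(self) -> bool:
        return not self.proceed


def ann_stage(elite_features, net: NetworkModel, threshold: float = 0.5) -> StageDecision:
    """Score the GA-denoised feature vector and gate on the output threshold.

    A score at or above the threshold means the event proceeds to the
    database-matching evaluation; below it the network is flagged for
    retraining.
    """
    if not net.trained:
        raise ValueError("network has not been trained")
    return StageDecision(score=forward(net, elite_features), threshold=float(threshold))
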