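"""Small feedforward regression networks for brain-age prediction.

The brain-age predictor is deliberately tiny: 5-25 inputs (top-ranked
graph metrics), one or two tanh hidden layers with 2-10 units, and a
single linear output unit.  Training minimizes mean squared error plus a
fixed weight-decay penalty ``lambda * sum(W**2)`` (biases excluded) — the
shrinkage role of Bayesian-regularized backpropagation with a
deterministic, seedable optimizer.  Optimization runs L-BFGS with
analytic gradients to convergence (projected-gradient norm below 1e-6) or
2000 iterations, from a seeded Glorot-uniform initialization, so a given
(data, architecture, seed) triple always yields bit-identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["NetArchitecture", "BrainAgeNet", "train_network", "evaluate",
           "default_architectures"]

HIDDEN_UNIT_CHOICES = (2, 5, 7, 10)
DEFAULT_DECAY = 0.01


@dataclass(frozen=True)
class NetArchitecture:
    """Input width plus hidden-layer unit counts (1 or 2 layers).

    For two-layer nets the second layer never has more units than the
    first.
    """

    n_inputs: int
    hidden_layers: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.hidden_layers) <= 2):
            raise ValueError("1 or 2 hidden layers supported")
        if len(self.hidden_layers) == 2 and self.hidden_layers[1] > self.hidden_layers[0]:
            raise ValueError("second hidden layer must not exceed the first")
        if self.n_inputs < 1:
            raise ValueError("need at least one input")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_layers, 1)

    @property
    def n_parameters(self) -> int:
        sizes = self.layer_sizes
        return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))

    def label(self) -> str:
        return f"{self.n_inputs}in-" + "x".join(map(str, self.hidden_layers))


def default_architectures(
    units: tuple[int, ...] = HIDDEN_UNIT_CHOICES,
) -> list[tuple[int, ...]]:
    """All 1-layer sizes plus 2-layer pairs with second <= first (14 total)."""
    archs: list[tuple[int, ...]] = [(u,) for u in units]
    archs += [(a, b) for a in units for b in units if b <= a]
    return archs


def _unpack(theta: np.ndarray, sizes: tuple[int, ...]):
    weights, biases, off = [], [], 0
    for i in range(len(sizes) - 1):
        n_in, n_out = sizes[i], sizes[i + 1]
        weights.append(theta[off : off + n_in * n_out].reshape(n_in, n_out))
        off += n_in * n_out
        biases.append(theta[off : off + n_out])
        off += n_out
    return weights, biases


def _forward(X: np.ndarray, weights, biases):
    acts = [X]
    h = X
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.tanh(h @ W + b)
        acts.append(h)
    out = h @ weights[-1] + biases[-1]
    return out.ravel(), acts


def _loss_grad(theta: np.ndarray, sizes, X, y, decay):
    weights, biases = _unpack(theta, sizes)
    pred, acts = _forward(X, weights, biases)
    n = len(y)
    err = pred - y
    loss = float(err @ err) / n + decay * sum(float((W**2).sum()) for W in weights)

    g_w = [np.zeros_like(W) for W in weights]
    g_b = [np.zeros_like(b) for b in biases]
    delta = (2.0 / n) * err[:, None]  # d loss / d output
    for layer in range(len(weights) - 1, -1, -1):
        g_w[layer] = acts[layer].T @ delta + 2.0 * decay * weights[layer]
        g_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
    grad = np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(g_w, g_b)])
    return loss, grad


def _glorot_init(sizes: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    parts = []
    for i in range(len(sizes) - 1):
        n_in, n_out = sizes[i], sizes[i + 1]
        limit = np.sqrt(6.0 / (n_in + n_out))
        parts.append(rng.uniform(-limit, limit, size=n_in * n_out))
        parts.append(np.zeros(n_out))
    return np.concatenate(parts)


@dataclass
class BrainAgeNet:
    """A frozen trained network: architecture, weights, seed, decay.

    Targets are standardized internally during training (``target_mean``,
    ``target_sd``); predictions are returned on the original years scale.
    """

    architecture: NetArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_seed: int
    decay_coefficient: float
    target_mean: float = 0.0
    target_sd: float = 1.0
    training_rmse: float = field(default=np.nan)

    def predict(self, X_std: np.ndarray) -> np.ndarray:
        X_std = np.asarray(X_std, dtype=float)
        if X_std.shape[1] != self.architecture.n_inputs:
            raise ValueError(
                f"expected {self.architecture.n_inputs} inputs, got {X_std.shape[1]}"
            )
        pred, _ = _forward(X_std, self.weights, self.biases)
        return pred * self.target_sd + self.target_mean

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for W, b in zip(self.weights, self.biases):
            h.update(np.ascontiguousarray(W).tobytes())
            h.update(np.ascontiguousarray(b).tobytes())
        return h.hexdigest()


def train_network(
    X_std: np.ndarray,
    age: np.ndarray,
    arch: NetArchitecture,
    seed: int = 0,
    decay: float = DEFAULT_DECAY,
    max_iter: int = 2000,
    gtol: float = 1e-6,
) -> BrainAgeNet:
    """Train one network to convergence; deterministic given the seed."""
    X_std = np.asarray(X_std, dtype=float)
    age = np.asarray(age, dtype=float)
    if X_std.shape[1] != arch.n_inputs:
        raise ValueError("feature matrix width must equal n_inputs")
    sizes = arch.layer_sizes
    rng = np.random.default_rng(seed)
    theta0 = _glorot_init(sizes, rng)
    y_mean = float(age.mean())
    y_sd = float(age.std())
    if y_sd == 0:
        raise ValueError("constant target ages")
    y_scaled = (age - y_mean) / y_sd
    res = minimize(
        _loss_grad,
        theta0,
        args=(sizes, X_std, y_scaled, decay),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(
            "training diverged; try a smaller decay coefficient or rescale targets"
        )
    weights, biases = _unpack(res.x, sizes)
    net = BrainAgeNet(
        architecture=arch,
        weights=[w.copy() for w in weights],
        biases=[b.copy() for b in biases],
        training_seed=seed,
        decay_coefficient=decay,
        target_mean=y_mean,
        target_sd=y_sd,
    )
    net.training_rmse = evaluate(net, X_std, age)[0]
    return net


def evaluate(net: BrainAgeNet, X_std: np.ndarray, age: np.ndarray):
    """(rmse, mae, predictions) of a frozen network on standardized data."""
    pred = net.predict(X_std)
    age = np.asarray(age, dtype=float)
    resid = pred - age
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return rmse, mae, pred
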