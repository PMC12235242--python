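"""Node-wise multiplicative correction network (operator NN).

A small fully connected network is evaluated independently at every mesh
node. Its inputs are the normalized local state (modifier plus scaled
mobile/stationary adsorbate concentrations, 2n+1 features; 7 for the
standard ternary); its outputs are n strictly positive multipliers (one
per adsorbate adsorption rate; 3 for the ternary). ReLU activates the
hidden layers; Softplus on the output keeps every correction positive, so
the sign of the rates stays controlled by the mechanistic operator.

The final layer is initialized at the identity-correction point (zero
weights, bias softplus^-1(1) = ln(e-1)) so that a freshly initialized
hybrid model is *exactly* the calibrated mechanistic model; the hidden
layers use Kaiming initialization. Forward, input-Jacobian and
parameter-VJP passes are written out explicitly (Y_l = W_l X_{l-1} + b_l
with the chain rule run backwards), which is all the autodiff this small
architecture needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

SOFTPLUS_ONE_BIAS = float(np.log(np.e - 1.0))  # softplus(ln(e-1)) == 1


def softplus(x: np.ndarray) -> np.ndarray:
    """Numerically safe log(1 + exp(x))."""
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def softplus_prime(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softplus_inv(y):
    """Inverse of softplus for y > 0."""
    y = np.asarray(y, dtype=float)
    return np.where(y > 30, y, np.log(np.expm1(np.maximum(y, 1e-300))))


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and initialization of the correction network."""

    n_hidden_layers: int = 2
    nodes_per_layer: int = 14
    n_components: int = 3
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.nodes_per_layer < self.output_width:
            raise ValueError("hidden width must be >= output width")

    @property
    def input_width(self) -> int:
        return 2 * self.n_components + 1

    @property
    def output_width(self) -> int:
        return self.n_components


class CorrectionNetwork:
    """Feed-forward ReLU network with Softplus output, shared across nodes.

    Parameters are a flat list of (W, b) pairs; rows of the input batch are
    mesh nodes, so permutation of nodes permutes outputs identically.
    """

    def __init__(self, config: NetworkConfig, params):
        self.config = config
        self.params = [(np.array(W, dtype=float), np.array(b, dtype=float))
                       for W, b in params]

    # -- parameter bookkeeping ------------------------------------------------

    def copy(self) -> "CorrectionNetwork":
        return CorrectionNetwork(self.config,
                                 [(W.copy(), b.copy()) for W, b in self.params])

    def flat_parameters(self) -> np.ndarray:
        return np.concatenate([np.concatenate([W.ravel(), b])
                               for W, b in self.params])

    def set_flat_parameters(self, vec: np.ndarray) -> None:
        k = 0
        for li, (W, b) in enumerate(self.params):
            nW, nb = W.size, b.size
            self.params[li] = (vec[k:k + nW].reshape(W.shape).copy(),
                               vec[k + nW:k + nW + nb].copy())
            k += nW + nb
        if k != vec.size:
            raise ValueError("parameter vector length mismatch")

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in self.params)

    # -- forward / backward ---------------------------------------------------

    def forward(self, X: np.ndarray, return_cache: bool = False):
        """Batch forward pass: X (N, input_width) -> (N, output_width)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_width:
            raise ValueError(
                f"expected feature width {self.config.input_width}, got {X.shape}")
        acts = [X]
        pre = []
        h = X
        last = len(self.params) - 1
        for li, (W, b) in enumerate(self.params):
            y = h @ W.T + b
            pre.append(y)
            h = softplus(y) if li == last else np.maximum(y, 0.0)
            acts.append(h)
        if return_cache:
            return h, (acts, pre)
        return h

    def input_jacobian(self, X: np.ndarray) -> np.ndarray:
        """d(output)/d(input) per node: (N, output_width, input_width)."""
        _, (acts, pre) = self.forward(X, return_cache=True)
        N = X.shape[0]
        J = np.broadcast_to(np.eye(self.config.input_width),
                            (N, self.config.input_width, self.config.input_width))
        last = len(self.params) - 1
        for li, (W, b) in enumerate(self.params):
            J = np.einsum("oi,nij->noj", W, J)
            dact = softplus_prime(pre[li]) if li == last \
                else (pre[li] > 0).astype(float)
            J = dact[:, :, None] * J
        return J

    def param_vjp(self, X: np.ndarray, cotangent: np.ndarray):
        """Gradients of sum(cotangent * output) w.r.t. every (W, b).

        Implements the standard backward recursion: delta_l on the layer
        pre-activations, dW = delta^T X_{l-1}, db = sum(delta).
        """
        _, (acts, pre) = self.forward(X, return_cache=True)
        last = len(self.params) - 1
        delta = cotangent * softplus_prime(pre[last])
        grads = [None] * len(self.params)
        for li in range(last, -1, -1):
            W, b = self.params[li]
            grads[li] = (delta.T @ acts[li], delta.sum(axis=0))
            if li > 0:
                delta = (delta @ W) * (pre[li - 1] > 0)
        return grads

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Flat named-parameter archive (JSON) with the config echoed."""
        payload = {
            "config": {
                "n_hidden_layers": self.config.n_hidden_layers,
                "nodes_per_layer": self.config.nodes_per_layer,
                "n_components": self.config.n_components,
                "init_seed": self.config.init_seed,
            },
            "parameters": {},
        }
        for li, (W, b) in enumerate(self.params):
            payload["parameters"][f"W{li}"] = W.tolist()
            payload["parameters"][f"b{li}"] = b.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "CorrectionNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        config = NetworkConfig(**payload["config"])
        params = []
        li = 0
        while f"W{li}" in payload["parameters"]:
            params.append((np.array(payload["parameters"][f"W{li}"]),
                           np.array(payload["parameters"][f"b{li}"])))
            li += 1
        return cls(config, params)


def init_network(config: NetworkConfig) -> CorrectionNetwork:
    """Kaiming-initialized hidden layers; output layer at the identity
    correction (W=0, b=softplus^-1(1)) so the fresh hybrid model equals the
    mechanistic one exactly."""
    rng = np.random.default_rng(config.init_seed)
    widths = ([config.input_width]
              + [config.nodes_per_layer] * config.n_hidden_layers
              + [config.output_width])
    params = []
    for li in range(len(widths) - 1):
        fan_in, fan_out = widths[li], widths[li + 1]
        if li == len(widths) - 2:
            W = np.zeros((fan_out, fan_in))
            b = np.full(fan_out, SOFTPLUS_ONE_BIAS)
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_out, fan_in))
            b = np.zeros(fan_out)
        params.append((W, b))
    return CorrectionNetwork(config, params)


def normalize_features(state_row, injection_concentrations) -> np.ndarray:
    """Normalize one state row [cm, c_1..c_n, qm, q_1..q_n] into network
    features [cm, c~_1..c~_n, q~_1..q~_n] (qm dropped, modifier unscaled)."""
    row = np.asarray(state_row, dtype=float)
    cinj = np.asarray(injection_concentrations, dtype=float)
    if np.any(cinj <= 0):
        raise ValueError("injection concentrations must be positive")
    n = cinj.size
    if row.size != 2 * n + 2:
        raise ValueError("state row width does not match component count")
    return np.concatenate([[row[0]], row[1:1 + n] / cinj,
                           row[2 + n:] / cinj])


class NetworkCorrection:
    """Adapter applying a CorrectionNetwork to full column states.

    Satisfies the correction protocol used by ColumnModel: `values`,
    `state_jacobian` (w.r.t. the state columns [cm, c_i, q_i]) and
    `param_vjp`.
    """

    def __init__(self, net: CorrectionNetwork):
        self.net = net

    def values(self, state, model) -> np.ndarray:
        return self.net.forward(model.features(state))

    def state_jacobian(self, state, model) -> np.ndarray:
        J = self.net.input_jacobian(model.features(state))
        return J * model.feature_scales()[None, None, :]

    def param_vjp(self, state, model, cotangent):
        return self.net.param_vjp(model.features(state), cotangent)


class IdentityCorrection:
    """Correction identically equal to one (pure mechanistic model)."""

    def values(self, state, model):
        return np.ones((state.shape[0], model.n_comp))

    def state_jacobian(self, state, model):
        return np.zeros((state.shape[0], model.n_comp, 2 * model.n_comp + 1))

    def param_vjp(self, state, model, cotangent):
        return None
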