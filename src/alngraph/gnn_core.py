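"""Dense, from-scratch graph neural network cores.

Three message-passing families for binary node classification on small
patient graphs, implemented directly in numpy with hand-derived
backward passes:

* GCN — symmetric-renormalized neighbourhood averaging,
  ``H' = act(D^-1/2 (A+I) D^-1/2 H W + b)``;
* GAT — single-head attention over each node's closed neighbourhood,
  ``e_ij = LeakyReLU(a^T [W h_i || W h_j])``, softmax-normalized;
* GIN — injective sum aggregation ``(1+eps) h_i + sum_j h_j`` fed
  through a two-affine MLP, followed by a linear readout.

Cohort graphs have at most a few hundred nodes, so everything is dense
float64; there is no sparse machinery and no GPU path.  Analytic
gradients for every parameter are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np


class ModelError(ValueError):
    """Raised for invalid model configuration or shapes."""


# ---------------------------------------------------------------------------
# activations

def _relu(z):
    return np.maximum(z, 0.0)


def _relu_grad(z):
    return (z > 0.0).astype(float)


def _tanh_grad(z):
    return 1.0 - np.tanh(z) ** 2


ACTIVATIONS = {"relu": (_relu, _relu_grad), "tanh": (np.tanh, _tanh_grad)}


def _leaky(z, slope):
    return np.where(z > 0.0, z, slope * z)


def _leaky_grad(z, slope):
    return np.where(z > 0.0, 1.0, slope)


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    Depth 2, width 16, single-head attention, ReLU and no dropout are
    small-cohort defaults; all are configurable.
    """

    architecture: str = "gcn"
    n_layers: int = 2
    hidden_dim: int = 16
    activation: str = "relu"
    dropout: float = 0.0
    leaky_slope: float = 0.2
    init_seed: int = 0
    n_classes: int = 2

    def validate(self) -> None:
        if self.architecture not in ("gcn", "gat", "gin"):
            raise ModelError(f"unknown architecture {self.architecture!r}")
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ModelError("n_layers and hidden_dim must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ModelError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ModelError("dropout must lie in [0, 1)")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ModelError("leaky_slope must lie in (0, 1)")


def _layer_dims(config: ModelConfig, d_in: int) -> list:
    return [d_in] + [config.hidden_dim] * (config.n_layers - 1) + [config.n_classes]


# ---------------------------------------------------------------------------
# initialisation

def _glorot(rng, fan_in, fan_out, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def init_params(config: ModelConfig, d_in: int) -> dict:
    """Glorot-uniform weights, zero biases, zero GIN epsilons; seeded."""
    config.validate()
    if d_in < 1:
        raise ModelError("d_in must be >= 1")
    rng = np.random.default_rng(config.init_seed)
    params: dict = {}
    if config.architecture in ("gcn", "gat"):
        dims = _layer_dims(config, d_in)
        for l, (di, do) in enumerate(zip(dims[:-1], dims[1:])):
            params[f"W{l}"] = _glorot(rng, di, do)
            if config.architecture == "gcn":
                params[f"b{l}"] = np.zeros(do)
            else:
                params[f"a{l}"] = _glorot(rng, 2 * do, 1, shape=(2 * do,))
    else:  # gin: n_layers aggregation blocks, then a linear readout
        h = config.hidden_dim
        for l in range(config.n_layers):
            di = d_in if l == 0 else h
            params[f"eps{l}"] = np.zeros(())
            params[f"Wa{l}"] = _glorot(rng, di, h)
            params[f"ba{l}"] = np.zeros(h)
            params[f"Wb{l}"] = _glorot(rng, h, h)
            params[f"bb{l}"] = np.zeros(h)
        params["W_out"] = _glorot(rng, h, config.n_classes)
        params["b_out"] = np.zeros(config.n_classes)
    return params


# ---------------------------------------------------------------------------
# graph operators

def normalize_adjacency(A) -> np.ndarray:
    """Symmetric renormalization ``D^-1/2 (A + I) D^-1/2``."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ModelError("adjacency must be square and symmetric")
    if np.any(np.diag(A) != 0.0):
        raise ModelError("adjacency must have zero diagonal")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _check_input(X, params, config):
    d_in = params["W0" if config.architecture != "gin" else "Wa0"].shape[0]
    if X.shape[1] != d_in:
        raise ModelError(f"feature width {X.shape[1]} does not match "
                         f"parameters initialised for d_in={d_in}")


def _dropout_mask(rng, shape, rate):
    if rng is None or rate == 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


# ---------------------------------------------------------------------------
# GCN

def _gcn_forward(A_hat, X, params, config, rng=None):
    act, _ = ACTIVATIONS[config.activation]
    H = np.asarray(X, dtype=float)
    caches = []
    L = config.n_layers
    for l in range(L):
        M = A_hat @ H
        Z = M @ params[f"W{l}"] + params[f"b{l}"]
        if l < L - 1:
            H_out = act(Z)
            mask = _dropout_mask(rng, H_out.shape, config.dropout)
            if mask is not None:
                H_out = H_out * mask
        else:
            H_out, mask = Z, None
        caches.append({"M": M, "Z": Z, "mask": mask})
        H = H_out
    return H, caches


def _gcn_backward(A_hat, dlogits, params, config, caches):
    _, actg = ACTIVATIONS[config.activation]
    grads = {}
    dZ = dlogits
    for l in range(config.n_layers - 1, -1, -1):
        c = caches[l]
        grads[f"W{l}"] = c["M"].T @ dZ
        grads[f"b{l}"] = dZ.sum(axis=0)
        if l > 0:
            dM = dZ @ params[f"W{l}"].T
            dH = A_hat.T @ dM
            prev = caches[l - 1]
            if prev["mask"] is not None:
                dH = dH * prev["mask"]
            dZ = dH * actg(prev["Z"])
    return grads


def gcn_forward(A_hat, X, params, config: ModelConfig) -> np.ndarray:
    """Logits (n x 2) of the GCN stack on a renormalized adjacency."""
    _check_input(np.asarray(X), params, config)
    logits, _ = _gcn_forward(np.asarray(A_hat, float), X, params, config)
    return logits


# ---------------------------------------------------------------------------
# GAT

def _gat_forward(A, X, params, config, rng=None):
    act, _ = ACTIVATIONS[config.activation]
    n = A.shape[0]
    neigh = (A + np.eye(n)) > 0.0  # closed neighbourhood
    H = np.asarray(X, dtype=float)
    caches = []
    L = config.n_layers
    for l in range(L):
        W, a = params[f"W{l}"], params[f"a{l}"]
        do = W.shape[1]
        Z = H @ W
        s1, s2 = Z @ a[:do], Z @ a[do:]
        E = s1[:, None] + s2[None, :]
        Eact = _leaky(E, config.leaky_slope)
        scores = np.where(neigh, Eact, -np.inf)
        scores = scores - scores.max(axis=1, keepdims=True)
        exps = np.exp(scores)
        alpha = exps / exps.sum(axis=1, keepdims=True)
        Hagg = alpha @ Z
        if l < L - 1:
            H_out = act(Hagg)
            mask = _dropout_mask(rng, H_out.shape, config.dropout)
            if mask is not None:
                H_out = H_out * mask
        else:
            H_out, mask = Hagg, None
        caches.append({"H": H, "Z": Z, "E": E, "alpha": alpha, "Hagg": Hagg,
                       "mask": mask})
        H = H_out
    return H, caches


def _gat_backward(A, dlogits, params, config, caches):
    _, actg = ACTIVATIONS[config.activation]
    grads = {}
    dout = dlogits
    for l in range(config.n_layers - 1, -1, -1):
        c = caches[l]
        W, a = params[f"W{l}"], params[f"a{l}"]
        do = W.shape[1]
        if l < config.n_layers - 1:
            if c["mask"] is not None:
                dout = dout * c["mask"]
            dHagg = dout * actg(c["Hagg"])
        else:
            dHagg = dout
        Z, alpha = c["Z"], c["alpha"]
        dalpha = dHagg @ Z.T
        dZ = alpha.T @ dHagg
        row_dot = (dalpha * alpha).sum(axis=1, keepdims=True)
        dscore = alpha * (dalpha - row_dot)          # masked entries have alpha=0
        dE = dscore * _leaky_grad(c["E"], config.leaky_slope)
        ds1 = dE.sum(axis=1)
        ds2 = dE.sum(axis=0)
        dZ = dZ + np.outer(ds1, a[:do]) + np.outer(ds2, a[do:])
        grads[f"a{l}"] = np.concatenate([Z.T @ ds1, Z.T @ ds2])
        grads[f"W{l}"] = c["H"].T @ dZ
        dout = dZ @ W.T
    return grads


def gat_forward(A, X, params, config: ModelConfig) -> np.ndarray:
    """Logits of the attention stack; attention rows sum to one over
    each node's closed neighbourhood."""
    _check_input(np.asarray(X), params, config)
    logits, _ = _gat_forward(np.asarray(A, float), X, params, config)
    return logits


def gat_attention(A, X, params, config: ModelConfig, layer: int = 0) -> np.ndarray:
    """Attention matrix alpha of one layer (diagnostic)."""
    _, caches = _gat_forward(np.asarray(A, float), X, params, config)
    return caches[layer]["alpha"]


# ---------------------------------------------------------------------------
# GIN

def _gin_forward(A, X, params, config, rng=None):
    act, _ = ACTIVATIONS[config.activation]
    H = np.asarray(X, dtype=float)
    caches = []
    for l in range(config.n_layers):
        eps = params[f"eps{l}"]
        P = (1.0 + eps) * H + A @ H
        U = P @ params[f"Wa{l}"] + params[f"ba{l}"]
        V = act(U)
        H_out = V @ params[f"Wb{l}"] + params[f"bb{l}"]
        mask = _dropout_mask(rng, H_out.shape, config.dropout)
        if mask is not None:
            H_out = H_out * mask
        caches.append({"H": H, "P": P, "U": U, "V": V, "mask": mask})
        H = H_out
    logits = H @ params["W_out"] + params["b_out"]
    caches.append({"H_final": H})
    return logits, caches


def _gin_backward(A, dlogits, params, config, caches):
    _, actg = ACTIVATIONS[config.activation]
    grads = {
        "W_out": caches[-1]["H_final"].T @ dlogits,
        "b_out": dlogits.sum(axis=0),
    }
    dH = dlogits @ params["W_out"].T
    for l in range(config.n_layers - 1, -1, -1):
        c = caches[l]
        if c["mask"] is not None:
            dH = dH * c["mask"]
        grads[f"Wb{l}"] = c["V"].T @ dH
        grads[f"bb{l}"] = dH.sum(axis=0)
        dV = dH @ params[f"Wb{l}"].T
        dU = dV * actg(c["U"])
        grads[f"Wa{l}"] = c["P"].T @ dU
        grads[f"ba{l}"] = dU.sum(axis=0)
        dP = dU @ params[f"Wa{l}"].T
        grads[f"eps{l}"] = np.asarray((dP * c["H"]).sum())
        dH = (1.0 + params[f"eps{l}"]) * dP + A.T @ dP
    return grads


def gin_forward(A, X, params, config: ModelConfig) -> np.ndarray:
    """Logits of the sum-aggregation stack with MLP transforms."""
    _check_input(np.asarray(X), params, config)
    logits, _ = _gin_forward(np.asarray(A, float), X, params, config)
    return logits


# ---------------------------------------------------------------------------
# loss, unified dispatch, optimiser

def softmax_cross_entropy(logits, Y):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    `Y` is one-hot (n x 2).  Stabilized by row-max subtraction; the
    gradient is ``(softmax - Y) / n``.
    """
    logits = np.asarray(logits, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if logits.shape != Y.shape:
        raise ModelError(f"shape mismatch: logits {logits.shape}, labels {Y.shape}")
    if not np.allclose(Y.sum(axis=1), 1.0):
        raise ModelError("label rows must be one-hot")
    shifted = logits - logits.max(axis=1, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    log_probs = shifted - log_z
    n = logits.shape[0]
    loss = float(-(Y * log_probs).sum() / n)
    grad = (np.exp(log_probs) - Y) / n
    return loss, grad


_FORWARD = {"gcn": _gcn_forward, "gat": _gat_forward, "gin": _gin_forward}
_BACKWARD = {"gcn": _gcn_backward, "gat": _gat_backward, "gin": _gin_backward}


def propagation_matrix(A, config: ModelConfig) -> np.ndarray:
    """The operator each architecture consumes: renormalized adjacency
    for GCN, the raw 0/1 adjacency for GAT and GIN."""
    A = np.asarray(A, dtype=float)
    return normalize_adjacency(A) if config.architecture == "gcn" else A


def model_forward(mat, X, params, config: ModelConfig) -> np.ndarray:
    _check_input(np.asarray(X), params, config)
    logits, _ = _FORWARD[config.architecture](np.asarray(mat, float), X, params, config)
    return logits


def loss_and_grads(mat, X, Y, params, config: ModelConfig,
                   node_idx=None, rng=None):
    """Full forward/backward pass.

    `node_idx` restricts the loss to a subset of nodes (the full graph
    still participates in message passing); used by the optional
    minibatch training mode.
    """
    _check_input(np.asarray(X), params, config)
    mat = np.asarray(mat, dtype=float)
    logits, caches = _FORWARD[config.architecture](mat, X, params, config, rng=rng)
    if node_idx is None:
        loss, dlogits = softmax_cross_entropy(logits, Y)
    else:
        node_idx = np.asarray(node_idx)
        loss, dsub = softmax_cross_entropy(logits[node_idx], np.asarray(Y)[node_idx])
        dlogits = np.zeros_like(logits)
        dlogits[node_idx] = dsub
    grads = _BACKWARD[config.architecture](mat, dlogits, params, config, caches)
    return loss, grads, logits


@dataclass
class AdamState:
    """Bias-corrected Adam accumulators, one slot per parameter."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps_hat: float = 1e-8
    step: int = 0
    m: dict = None
    v: dict = None


def init_adam_state(params: dict, lr: float = 1e-4) -> AdamState:
    return AdamState(lr=lr,
                     m={k: np.zeros_like(p) for k, p in params.items()},
                     v={k: np.zeros_like(p) for k, p in params.items()})


def adam_step(params: dict, grads: dict, state: AdamState):
    """One bias-corrected Adam update; returns (params', state')."""
    state.step += 1
    t = state.step
    c1 = 1.0 - state.beta1 ** t
    c2 = 1.0 - state.beta2 ** t
    new_params = {}
    for k, p in params.items():
        g = grads[k]
        if g.shape != np.shape(p):
            raise ModelError(f"gradient shape mismatch for {k}")
        state.m[k] = state.beta1 * state.m[k] + (1.0 - state.beta1) * g
        state.v[k] = state.beta2 * state.v[k] + (1.0 - state.beta2) * g ** 2
        m_hat = state.m[k] / c1
        v_hat = state.v[k] / c2
        new_params[k] = p - state.lr * m_hat / (np.sqrt(v_hat) + state.eps_hat)
    return new_params, state


# ---------------------------------------------------------------------------
# checkpoints

CHECKPOINT_VERSION = 1


def save_checkpoint(path, params: dict, config: ModelConfig) -> None:
    payload = {
        "format_version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(config),
        "params": {k: np.asarray(v).tolist() for k, v in params.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path):
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != CHECKPOINT_VERSION:
        raise ModelError(f"unsupported checkpoint version {payload.get('format_version')}")
    config = ModelConfig(**payload["config"])
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    return params, config
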