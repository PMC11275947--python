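"""Per-view graph convolutional network emitting soft class labels.

Each view (TF binding, H3K27ac) gets its own two-layer GCN over the
normalized sample-similarity adjacency A-hat:

    H1 = dropout(ReLU(A-hat X W0 + b0))
    P  = softmax(A-hat H1 W1 + b1)

trained transductively with cross-entropy on the training mask.  The
continuous expression target is discretized into ``c`` quantile bins
(edges from the training set only) to define the classification task; the
resulting soft labels feed the fusion stage.

Everything is plain numpy (float64) with hand-written backprop and
full-batch Adam updates; all randomness (Glorot init, dropout masks) comes
from one seeded generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig

__all__ = [
    "GCNParams",
    "discretize_expression",
    "gcn_forward",
    "train_view_gcn",
    "AdamState",
    "adam_step",
    "glorot",
    "softmax",
    "cross_entropy",
]


# ---------------------------------------------------------------- numerics

def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    probs: np.ndarray, labels: np.ndarray, mask: np.ndarray, smoothing: float = 0.0
) -> float:
    """Masked mean cross-entropy against (optionally smoothed) targets.

    With ``smoothing`` = eps the target for a sample in class k is
    ``(1-eps)·onehot(k) + eps/c`` — softened labels keep the view
    classifiers from saturating, which preserves within-class magnitude
    information in the soft predictions the fusion stage consumes.
    """
    logp = np.log(np.clip(probs[mask], 1e-12, None))
    if smoothing == 0.0:
        return float(-np.mean(logp[np.arange(logp.shape[0]), labels[mask]]))
    c = probs.shape[1]
    q = np.full(logp.shape, smoothing / c)
    q[np.arange(logp.shape[0]), labels[mask]] += 1.0 - smoothing
    return float(-np.mean(np.sum(q * logp, axis=1)))


@dataclass
class AdamState:
    """First/second-moment accumulators for one parameter dict."""

    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0


def adam_step(
    params: dict[str, np.ndarray],
    grads: dict[str, np.ndarray],
    state: AdamState,
    lr: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> None:
    """In-place full-batch Adam update."""
    state.t += 1
    for k, g in grads.items():
        if k not in state.m:
            state.m[k] = np.zeros_like(g)
            state.v[k] = np.zeros_like(g)
        state.m[k] = beta1 * state.m[k] + (1 - beta1) * g
        state.v[k] = beta2 * state.v[k] + (1 - beta2) * g * g
        m_hat = state.m[k] / (1 - beta1 ** state.t)
        v_hat = state.v[k] / (1 - beta2 ** state.t)
        params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)


# ---------------------------------------------------------------- labels

def discretize_expression(
    y: np.ndarray, c: int, train_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-bin a continuous target into integer labels in [0, c).

    Bin edges are the interior ``c``-quantiles of the *training* values
    only; validation/test samples are mapped with those same edges.  A
    value equal to an edge goes to the lower bin.

    Returns (labels, edges).
    """
    y = np.asarray(y, float)
    train_mask = np.asarray(train_mask, bool)
    if c < 1:
        raise ValueError("c must be >= 1")
    if not train_mask.any():
        raise ValueError("empty training mask")
    y_train = y[train_mask]
    if c > np.unique(y_train).size:
        raise ValueError(
            f"c={c} exceeds the {np.unique(y_train).size} distinct training "
            "values; use a smaller number of classes"
        )
    if c == 1:
        return np.zeros(y.shape, dtype=int), np.array([])
    edges = np.quantile(y_train, np.arange(1, c) / c)
    # side='left': y == edge counts as the lower bin
    labels = np.searchsorted(edges, y, side="left")
    return labels.astype(int), edges


# ---------------------------------------------------------------- model

@dataclass
class GCNParams:
    """Weights of a two-layer GCN: n_features -> hidden_size -> c."""

    weights: dict[str, np.ndarray]
    hidden_size: int
    n_classes: int

    @classmethod
    def init(
        cls, rng: np.random.Generator, n_features: int, hidden_size: int, n_classes: int
    ) -> "GCNParams":
        return cls(
            weights={
                "W0": glorot(rng, n_features, hidden_size),
                "b0": np.zeros(hidden_size),
                "W1": glorot(rng, hidden_size, n_classes),
                "b1": np.zeros(n_classes),
            },
            hidden_size=hidden_size,
            n_classes=n_classes,
        )

    def copy(self) -> "GCNParams":
        return GCNParams(
            {k: v.copy() for k, v in self.weights.items()},
            self.hidden_size,
            self.n_classes,
        )


def gcn_forward(
    H0: np.ndarray,
    A_hat: np.ndarray,
    params: GCNParams,
    *,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Two graph-conv layers with ReLU then softmax.

    Returns (hidden, probs) — or (hidden, probs, cache) with
    ``return_cache=True`` for backprop.  Dropout (inverted scaling) is
    applied to the hidden layer only when ``dropout > 0`` and an ``rng``
    is supplied (training mode).
    """
    H0 = np.asarray(H0, float)
    if A_hat.shape[0] != A_hat.shape[1] or A_hat.shape[0] != H0.shape[0]:
        raise ValueError(
            f"adjacency {A_hat.shape} incompatible with features {H0.shape}"
        )
    W = params.weights
    if H0.shape[1] != W["W0"].shape[0]:
        raise ValueError(
            f"feature dim {H0.shape[1]} != W0 input dim {W['W0'].shape[0]}"
        )
    AH0 = A_hat @ H0
    Z1 = AH0 @ W["W0"] + W["b0"]
    H1 = relu(Z1)
    if dropout > 0 and rng is not None:
        keep = (rng.random(H1.shape) >= dropout) / (1.0 - dropout)
        H1d = H1 * keep
    else:
        keep = None
        H1d = H1
    AH1 = A_hat @ H1d
    Z2 = AH1 @ W["W1"] + W["b1"]
    P = softmax(Z2)
    if return_cache:
        cache = {"AH0": AH0, "Z1": Z1, "H1d": H1d, "AH1": AH1, "keep": keep, "P": P}
        return H1, P, cache
    return H1, P


def gcn_backward(
    A_hat: np.ndarray,
    params: GCNParams,
    cache: dict,
    dZ2: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss given d(loss)/d(logits) = dZ2."""
    W = params.weights
    grads = {
        "W1": cache["AH1"].T @ dZ2,
        "b1": dZ2.sum(axis=0),
    }
    dH1d = (A_hat.T @ dZ2) @ W["W1"].T
    if cache["keep"] is not None:
        dH1d = dH1d * cache["keep"]
    dZ1 = dH1d * (cache["Z1"] > 0)
    grads["W0"] = cache["AH0"].T @ dZ1
    grads["b0"] = dZ1.sum(axis=0)
    return grads


def ce_logit_grad(
    P: np.ndarray, labels: np.ndarray, mask: np.ndarray, smoothing: float = 0.0
) -> np.ndarray:
    """d(mean masked cross-entropy)/d(logits): (P - q)/|mask| on the mask."""
    dZ = np.zeros_like(P)
    idx = np.flatnonzero(mask)
    c = P.shape[1]
    q = np.full((idx.size, c), smoothing / c)
    q[np.arange(idx.size), labels[idx]] += 1.0 - smoothing
    dZ[idx] = P[idx] - q
    return dZ / idx.size


def add_weight_decay(
    grads: dict[str, np.ndarray], params: GCNParams | dict, wd: float
) -> None:
    """L2 penalty gradient on weight matrices (biases exempt)."""
    weights = params.weights if hasattr(params, "weights") else params
    for k in grads:
        if k.split(".")[-1].startswith("W"):
            grads[k] = grads[k] + wd * weights[k]


def train_view_gcn(
    X: np.ndarray,
    A_hat: np.ndarray,
    labels: np.ndarray,
    masks: dict[str, np.ndarray],
    config: RunConfig,
    *,
    epochs: int | None = None,
    rng: np.random.Generator | None = None,
    params: GCNParams | None = None,
) -> tuple[GCNParams, np.ndarray, list[float]]:
    """Train one view's GCN with cross-entropy on the train mask.

    Transductive: the forward pass always covers the whole graph; masks
    only gate the loss.  Returns (params, full-graph soft predictions in
    eval mode, per-epoch training losses).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if params is None:
        params = GCNParams.init(rng, X.shape[1], config.hidden_size, config.n_classes)
    n_epochs = config.epochs if epochs is None else epochs
    state = AdamState()
    losses: list[float] = []
    for _ in range(n_epochs):
        _, P, cache = gcn_forward(
            X, A_hat, params, dropout=config.dropout, rng=rng, return_cache=True
        )
        loss = cross_entropy(P, labels, masks["train"], config.label_smoothing)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"cross-entropy diverged (loss={loss}); lower the learning rate"
            )
        losses.append(loss)
        dZ2 = ce_logit_grad(P, labels, masks["train"], config.label_smoothing)
        grads = gcn_backward(A_hat, params, cache, dZ2)
        add_weight_decay(grads, params, config.weight_decay)
        adam_step(params.weights, grads, state, config.lr)
    _, P_eval = gcn_forward(X, A_hat, params)
    return params, P_eval, losses
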