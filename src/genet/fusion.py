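"""Cross-feature fusion of the two views' soft labels into an expression value.

Each sample's per-view class-probability vectors are combined into a
cross-feature discovery tensor — the outer product p_tf (x) p_hm, a c x c
matrix whose entry (i, j) is the joint weight the two views place on label
pair (i, j).  The tensor is flattened row-major and fed to a small
regression head (one hidden ReLU layer, linear output) that predicts the
continuous expression value.

Training runs in two stages: each view GCN is pretrained on its
classification loss, then training alternates between per-view
cross-entropy steps (anchoring the tensor's label semantics) and
end-to-end mean-squared-error steps that flow through the tensor into both
GCNs and the head.  Early stopping monitors validation MSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .gcn_view import (
    AdamState,
    GCNParams,
    adam_step,
    add_weight_decay,
    ce_logit_grad,
    cross_entropy,
    discretize_expression,
    gcn_backward,
    gcn_forward,
    glorot,
    relu,
    train_view_gcn,
)

__all__ = [
    "RegressorParams",
    "GenetModel",
    "build_cross_feature_tensor",
    "flatten_tensor",
    "unflatten_tensor",
    "fusion_forward",
    "fusion_loss_and_grads",
    "train_genet",
]


def build_cross_feature_tensor(p_tf: np.ndarray, p_hm: np.ndarray) -> np.ndarray:
    """Outer product of the two views' soft labels, per sample.

    Accepts single length-c vectors or (n, c) batches; returns c x c or
    (n, c, c).  For simplex inputs the entries of each sample's tensor sum
    to exactly 1 (product of the two sums).
    """
    p_tf = np.asarray(p_tf, float)
    p_hm = np.asarray(p_hm, float)
    if p_tf.shape != p_hm.shape:
        raise ValueError(f"view shapes differ: {p_tf.shape} vs {p_hm.shape}")
    if p_tf.ndim == 1:
        return np.outer(p_tf, p_hm)
    return p_tf[:, :, None] * p_hm[:, None, :]


def flatten_tensor(t: np.ndarray) -> np.ndarray:
    """Row-major flattening of a c x c tensor (batched or single)."""
    t = np.asarray(t, float)
    if t.ndim == 2:
        return t.reshape(-1)
    return t.reshape(t.shape[0], -1)


def unflatten_tensor(v: np.ndarray, c: int) -> np.ndarray:
    v = np.asarray(v, float)
    if v.ndim == 1:
        return v.reshape(c, c)
    return v.reshape(v.shape[0], c, c)


@dataclass
class RegressorParams:
    """Fusion head: c^2 -> fusion_hidden (ReLU) -> 1 linear output."""

    weights: dict[str, np.ndarray]

    @classmethod
    def init(
        cls, rng: np.random.Generator, c: int, fusion_hidden: int
    ) -> "RegressorParams":
        return cls(
            weights={
                "Wf0": glorot(rng, c * c, fusion_hidden),
                "bf0": np.zeros(fusion_hidden),
                "Wf1": glorot(rng, fusion_hidden, 1),
                "bf1": np.zeros(1),
            }
        )

    def copy(self) -> "RegressorParams":
        return RegressorParams({k: v.copy() for k, v in self.weights.items()})


def fusion_forward(v: np.ndarray, params: RegressorParams) -> np.ndarray | float:
    """Regression head on a flattened tensor: W2 ReLU(W1 v + b1) + b2."""
    W = params.weights
    v = np.asarray(v, float)
    single = v.ndim == 1
    V = v[None, :] if single else v
    if V.shape[1] != W["Wf0"].shape[0]:
        raise ValueError(
            f"input dim {V.shape[1]} != head input dim {W['Wf0'].shape[0]}"
        )
    out = relu(V @ W["Wf0"] + W["bf0"]) @ W["Wf1"] + W["bf1"]
    return float(out[0, 0]) if single else out[:, 0]


@dataclass
class Scaler:
    """Affine standardization, stored so predictions leave model space."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, axis: int | None = 0) -> "Scaler":
        mean = np.mean(x, axis=axis)
        sd = np.std(x, axis=axis)
        return cls(np.asarray(mean, float), np.where(sd > 0, sd, 1.0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return x * self.sd + self.mean

    def copy(self) -> "Scaler":
        return Scaler(np.array(self.mean, copy=True), np.array(self.sd, copy=True))


@dataclass
class GenetModel:
    """Trained two-view model: per-view GCNs plus the fusion head.

    Feature columns and the regression target are standardized during
    training; the fitted scalers are part of the model so ``predict``
    consumes raw bin features and returns expression on its original scale.
    """

    params_tf: GCNParams
    params_hm: GCNParams
    head: RegressorParams
    edges: np.ndarray  # expression quantile edges used for the class labels
    config: RunConfig
    x_scaler_tf: Scaler | None = None
    x_scaler_hm: Scaler | None = None
    y_scaler: Scaler | None = None

    def predict(
        self, X_tf: np.ndarray, X_hm: np.ndarray, A_tf: np.ndarray, A_hm: np.ndarray
    ) -> np.ndarray:
        """Deterministic (eval-mode) expression predictions for all samples."""
        if self.x_scaler_tf is not None:
            X_tf = self.x_scaler_tf.transform(X_tf)
            X_hm = self.x_scaler_hm.transform(X_hm)
        _, p_tf = gcn_forward(X_tf, A_tf, self.params_tf)
        _, p_hm = gcn_forward(X_hm, A_hm, self.params_hm)
        V = flatten_tensor(build_cross_feature_tensor(p_tf, p_hm))
        yhat = fusion_forward(V, self.head)
        return self.y_scaler.inverse(yhat) if self.y_scaler is not None else yhat

    def copy(self) -> "GenetModel":
        return GenetModel(
            self.params_tf.copy(), self.params_hm.copy(), self.head.copy(),
            self.edges.copy(), self.config,
            None if self.x_scaler_tf is None else self.x_scaler_tf.copy(),
            None if self.x_scaler_hm is None else self.x_scaler_hm.copy(),
            None if self.y_scaler is None else self.y_scaler.copy(),
        )

    def save(self, path: str) -> None:
        """Checkpoint: one npz archive plus a JSON manifest (``path + '.json'``).

        The archive holds every weight matrix and scaler under prefixed
        keys; the manifest records layer shapes and the full config so a
        checkpoint is reproducible and self-describing.
        """
        import json

        arrays: dict[str, np.ndarray] = {"edges": self.edges}
        for prefix, weights in (
            ("tf", self.params_tf.weights), ("hm", self.params_hm.weights),
            ("head", self.head.weights),
        ):
            arrays.update({f"{prefix}.{k}": v for k, v in weights.items()})
        for name, scaler in (
            ("x_tf", self.x_scaler_tf), ("x_hm", self.x_scaler_hm),
            ("y", self.y_scaler),
        ):
            if scaler is not None:
                arrays[f"scaler.{name}.mean"] = np.atleast_1d(scaler.mean)
                arrays[f"scaler.{name}.sd"] = np.atleast_1d(scaler.sd)
        np.savez(path, **arrays)
        manifest = {
            "config": self.config.to_dict(),
            "shapes": {k: list(v.shape) for k, v in arrays.items()},
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "GenetModel":
        import json

        from .config import RunConfig

        with open(str(path) + ".json") as fh:
            manifest = json.load(fh)
        config = RunConfig.from_dict(manifest["config"])
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            arrays = {k: z[k] for k in z.files}

        def group(prefix):
            return {k.split(".", 1)[1]: arrays[k] for k in arrays
                    if k.startswith(prefix + ".") and not k.startswith("scaler.")}

        def scaler(name):
            key = f"scaler.{name}.mean"
            if key not in arrays:
                return None
            return Scaler(arrays[key], arrays[f"scaler.{name}.sd"])

        tf_w, hm_w, head_w = group("tf"), group("hm"), group("head")
        return cls(
            GCNParams(tf_w, config.hidden_size, config.n_classes),
            GCNParams(hm_w, config.hidden_size, config.n_classes),
            RegressorParams(head_w),
            arrays["edges"],
            config,
            scaler("x_tf"), scaler("x_hm"), scaler("y"),
        )


def fusion_loss_and_grads(
    X_tf: np.ndarray,
    X_hm: np.ndarray,
    A_tf: np.ndarray,
    A_hm: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    params_tf: GCNParams,
    params_hm: GCNParams,
    head: RegressorParams,
    *,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, dict[str, np.ndarray]]]:
    """Masked MSE of the end-to-end model and its gradients.

    Gradients flow from the regression loss through the head, the flattened
    tensor, the outer product, each softmax, and both GCNs.  Returns
    (loss, {"tf": ..., "hm": ..., "head": ...}).
    """
    mask = np.asarray(mask, bool)
    _, p_tf, cache_tf = gcn_forward(
        X_tf, A_tf, params_tf, dropout=dropout, rng=rng, return_cache=True
    )
    _, p_hm, cache_hm = gcn_forward(
        X_hm, A_hm, params_hm, dropout=dropout, rng=rng, return_cache=True
    )
    T = build_cross_feature_tensor(p_tf, p_hm)
    V = flatten_tensor(T)
    W = head.weights
    Zh = V @ W["Wf0"] + W["bf0"]
    Hf = relu(Zh)
    yhat = (Hf @ W["Wf1"] + W["bf1"])[:, 0]

    n_mask = int(mask.sum())
    resid = np.zeros_like(yhat)
    resid[mask] = yhat[mask] - y[mask]
    loss = float(np.sum(resid[mask] ** 2) / n_mask)

    # ---- backward
    dyhat = (2.0 / n_mask) * resid  # zero off-mask
    dHf = dyhat[:, None] @ W["Wf1"].T
    dZh = dHf * (Zh > 0)
    g_head = {
        "Wf1": Hf.T @ dyhat[:, None],
        "bf1": np.array([dyhat.sum()]),
        "Wf0": V.T @ dZh,
        "bf0": dZh.sum(axis=0),
    }
    c = p_tf.shape[1]
    dT = dZh @ W["Wf0"].T
    dT = dT.reshape(-1, c, c)
    dp_tf = np.einsum("nij,nj->ni", dT, p_hm)
    dp_hm = np.einsum("nij,ni->nj", dT, p_tf)

    def softmax_backprop(P: np.ndarray, dP: np.ndarray) -> np.ndarray:
        return P * (dP - np.sum(dP * P, axis=1, keepdims=True))

    g_tf = gcn_backward(A_tf, params_tf, cache_tf, softmax_backprop(p_tf, dp_tf))
    g_hm = gcn_backward(A_hm, params_hm, cache_hm, softmax_backprop(p_hm, dp_hm))
    return loss, {"tf": g_tf, "hm": g_hm, "head": g_head}


def train_genet(
    X_tf: np.ndarray,
    X_hm: np.ndarray,
    A_tf: np.ndarray,
    A_hm: np.ndarray,
    y: np.ndarray,
    masks: dict[str, np.ndarray],
    config: RunConfig,
) -> tuple[GenetModel, np.ndarray, dict[str, list[float]]]:
    """Two-stage training of the full two-view model.

    Stage 1 pretrains each view GCN on quantile-binned labels
    (``config.pretrain_epochs`` cross-entropy epochs).  Stage 2 runs
    ``config.epochs`` rounds alternating a cross-entropy step per view with
    an end-to-end MSE step through the fusion tensor, early-stopping on
    validation MSE with ``config.patience``.  Returns the best model (by
    validation MSE), eval-mode predictions for every sample, and the loss
    history.
    """
    y = np.asarray(y, float)
    rng = np.random.default_rng(config.seed)
    labels, edges = discretize_expression(y, config.n_classes, masks["train"])

    # column-standardized features (transductive: all samples, no labels)
    # and train-standardized target; scalers travel with the model
    X_tf_raw, X_hm_raw = np.asarray(X_tf, float), np.asarray(X_hm, float)
    xs_tf = Scaler.fit(X_tf)
    xs_hm = Scaler.fit(X_hm)
    X_tf = xs_tf.transform(np.asarray(X_tf, float))
    X_hm = xs_hm.transform(np.asarray(X_hm, float))
    ys = Scaler.fit(y[np.asarray(masks["train"], bool)], axis=None)
    y = ys.transform(y)

    params_tf, _, _ = train_view_gcn(
        X_tf, A_tf, labels, masks, config, epochs=config.pretrain_epochs, rng=rng
    )
    params_hm, _, _ = train_view_gcn(
        X_hm, A_hm, labels, masks, config, epochs=config.pretrain_epochs, rng=rng
    )
    head = RegressorParams.init(rng, config.n_classes, config.fusion_hidden)
    model = GenetModel(params_tf, params_hm, head, np.asarray(edges), config)

    ce_state_tf, ce_state_hm = AdamState(), AdamState()
    e2e_state = AdamState()
    e2e_params = {
        **{f"tf.{k}": v for k, v in params_tf.weights.items()},
        **{f"hm.{k}": v for k, v in params_hm.weights.items()},
        **{f"head.{k}": v for k, v in head.weights.items()},
    }
    history: dict[str, list[float]] = {"ce_tf": [], "ce_hm": [], "mse": [], "val_mse": []}
    best: GenetModel | None = None
    best_val = np.inf
    stale = 0

    for epoch in range(config.epochs):
        # per-view classification steps (label anchoring, dropout active)
        for params, state, X, A, key in (
            (params_tf, ce_state_tf, X_tf, A_tf, "ce_tf"),
            (params_hm, ce_state_hm, X_hm, A_hm, "ce_hm"),
        ):
            _, P, cache = gcn_forward(
                X, A, params, dropout=config.dropout, rng=rng, return_cache=True
            )
            loss = cross_entropy(P, labels, masks["train"], config.label_smoothing)
            if not np.isfinite(loss):
                raise FloatingPointError("view classification loss diverged")
            history[key].append(loss)
            grads = gcn_backward(
                A, params, cache,
                ce_logit_grad(P, labels, masks["train"], config.label_smoothing),
            )
            add_weight_decay(grads, params, config.weight_decay)
            adam_step(params.weights, grads, state, config.lr)

        # end-to-end regression updates through the tensor; deterministic
        # forward — gradient noise here would swamp the small tensor signal
        for _ in range(config.fusion_steps):
            mse, grads = fusion_loss_and_grads(
                X_tf, X_hm, A_tf, A_hm, y, masks["train"],
                params_tf, params_hm, head,
            )
            if not np.isfinite(mse):
                raise FloatingPointError("fusion regression loss diverged")
            flat = {
                **{f"tf.{k}": v for k, v in grads["tf"].items()},
                **{f"hm.{k}": v for k, v in grads["hm"].items()},
                **{f"head.{k}": v for k, v in grads["head"].items()},
            }
            add_weight_decay(flat, e2e_params, config.weight_decay)
            adam_step(e2e_params, flat, e2e_state, config.lr)
        history["mse"].append(mse)

        # early stopping on validation MSE (eval mode, standardized space)
        yhat = model.predict(X_tf, X_hm, A_tf, A_hm)
        vmask = masks["val"]
        val_mse = float(np.mean((yhat[vmask] - y[vmask]) ** 2)) if vmask.any() else mse
        history["val_mse"].append(val_mse)
        if val_mse < best_val - 1e-12:
            best_val = val_mse
            best = model.copy()
            stale = 0
        elif stale + 1 >= config.patience and epoch + 1 >= config.min_epochs:
            break
        else:
            stale += 1

    final = best if best is not None else model
    final.x_scaler_tf, final.x_scaler_hm, final.y_scaler = xs_tf, xs_hm, ys
    yhat = final.predict(X_tf_raw, X_hm_raw, A_tf, A_hm)
    return final, yhat, history
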