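"""Graph neural network that predicts functional from structural connectivity.

Architecture: a two-layer graph convolutional encoder over the SC
adjacency with self-loops and symmetric degree normalization,

    H^{l+1} = PReLU( D^{-1/2} (A + I) D^{-1/2} H^l W^l ),

starting from one-hot node features (H^0 = I_K), followed by a
two-layer perceptron edge decoder that maps the concatenated pair of
node embeddings to a scalar predicted FC value,

    pFC_ij = W2 . ReLU(W1 . [h_i ; h_j] + b1) + b2,

trained with mean squared error over ordered off-diagonal edges plus
an L2 penalty on the MLP weight matrices, using Adam.  The final
prediction is symmetrized, (pFC_ij + pFC_ji) / 2, with zero diagonal.

The forward and backward passes are written directly in NumPy: the
model is small (K <= a few hundred nodes, tens of thousands of
parameters), every step is exactly reproducible from the seed, and the
analytic gradients are validated against finite differences in the
test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidInputError, TrainingError

__all__ = [
    "GnnConfig",
    "GnnModel",
    "init_model",
    "save_model",
    "load_model",
    "normalized_adjacency",
    "gcn_layer",
    "encode",
    "decode_edge",
    "predict_fc",
    "mse_l2_loss",
    "split_cohort",
    "train_model",
    "group_level_predict",
]


@dataclass(frozen=True)
class GnnConfig:
    """Architecture and optimization settings.

    ``gcn_dims`` runs input->...->embedding (input dim must equal the
    number of nodes K because node features are one-hot); ``mlp_hidden``
    is the single hidden width of the edge decoder, whose input width
    is twice the final embedding dim and whose output is a scalar.
    Defaults are the desk-scale settings (K=60 cohorts); for an
    empirical 400-node parcellation the natural settings would be
    gcn_dims=(400, 256, 256), mlp_hidden=64, epochs=400.
    """

    gcn_dims: tuple[int, ...] = (60, 64, 64)
    mlp_hidden: int = 64
    batch_size: int = 2
    learning_rate: float = 0.007
    l2_lambda: float = 0.0001
    epochs: int = 250
    prelu_init: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if len(self.gcn_dims) < 2 or any(d < 1 for d in self.gcn_dims):
            raise ConfigError("gcn_dims must list >= 2 positive dims")
        if self.mlp_hidden < 1:
            raise ConfigError("mlp_hidden must be >= 1")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.l2_lambda < 0:
            raise ConfigError("l2_lambda must be >= 0")

    @property
    def n_layers(self) -> int:
        return len(self.gcn_dims) - 1

    def replace(self, **kwargs) -> "GnnConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gcn_dims"] = list(self.gcn_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GnnConfig":
        d = dict(d)
        d["gcn_dims"] = tuple(d["gcn_dims"])
        return cls(**d)


@dataclass
class GnnModel:
    """All trainable parameters plus the architecture config."""

    gcn_weights: list[np.ndarray]
    prelu_slopes: np.ndarray          # one trainable scalar per GCN layer
    w1: np.ndarray                    # (2*C_L, mlp_hidden)
    b1: np.ndarray                    # (mlp_hidden,)
    w2: np.ndarray                    # (mlp_hidden,)
    b2: float
    config: GnnConfig

    def mlp_weight_sq_norm(self) -> float:
        """Sum of squares of the MLP weight matrices (biases excluded)."""
        return float(np.sum(self.w1**2) + np.sum(self.w2**2))

    def copy(self) -> "GnnModel":
        return GnnModel(
            gcn_weights=[w.copy() for w in self.gcn_weights],
            prelu_slopes=self.prelu_slopes.copy(),
            w1=self.w1.copy(), b1=self.b1.copy(),
            w2=self.w2.copy(), b2=self.b2, config=self.config)


def init_model(config: GnnConfig, rng: np.random.Generator | None = None) -> GnnModel:
    """Scaled-uniform fan-in initialization from the seeded stream."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gcn_weights = []
    for fan_in, fan_out in zip(config.gcn_dims[:-1], config.gcn_dims[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        gcn_weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
    c_l = config.gcn_dims[-1]
    bound = 1.0 / np.sqrt(2 * c_l)
    w1 = rng.uniform(-bound, bound, size=(2 * c_l, config.mlp_hidden))
    b1 = rng.uniform(-bound, bound, size=config.mlp_hidden)
    bound = 1.0 / np.sqrt(config.mlp_hidden)
    w2 = rng.uniform(-bound, bound, size=config.mlp_hidden)
    b2 = float(rng.uniform(-bound, bound))
    slopes = np.full(config.n_layers, config.prelu_init)
    return GnnModel(gcn_weights=gcn_weights, prelu_slopes=slopes,
                    w1=w1, b1=b1, w2=w2, b2=b2, config=config)


def normalized_adjacency(a: np.ndarray) -> np.ndarray:
    """S = D^{-1/2} (A + I) D^{-1/2}; self-loop weight 1 on the input scale."""
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("adjacency contains non-finite values")
    a_hat = a + np.eye(a.shape[0])
    d = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _prelu(x: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(x >= 0, x, alpha * x)


def gcn_layer(h: np.ndarray, a: np.ndarray, w: np.ndarray,
              alpha: float) -> np.ndarray:
    """One graph convolution: PReLU(D^{-1/2}(A+I)D^{-1/2} H W)."""
    s = normalized_adjacency(a)
    return _prelu(s @ h @ w, alpha)


def encode(sc: np.ndarray, model: GnnModel) -> list[np.ndarray]:
    """All node-embedding layers H^0..H^L; H^0 is the identity (one-hot)."""
    k = sc.shape[0]
    if model.gcn_weights[0].shape[0] != k:
        raise ConfigError(
            f"gcn input dim {model.gcn_weights[0].shape[0]} != K={k}")
    s = normalized_adjacency(sc)
    hs = [np.eye(k)]
    h = hs[0]
    for w, alpha in zip(model.gcn_weights, model.prelu_slopes):
        h = _prelu(s @ h @ w, float(alpha))
        hs.append(h)
    return hs


def decode_edge(h_i: np.ndarray, h_j: np.ndarray, model: GnnModel) -> float:
    """Scalar edge prediction from one ordered pair of embeddings."""
    if h_i.size != model.config.gcn_dims[-1] or h_j.size != h_i.size:
        raise ConfigError("embedding length does not match the MLP input")
    x = np.concatenate([h_i, h_j])
    a1 = np.maximum(0.0, x @ model.w1 + model.b1)
    return float(a1 @ model.w2 + model.b2)


def _pairwise_predictions(h: np.ndarray, model: GnnModel) -> np.ndarray:
    """Raw (asymmetric) K x K prediction matrix over all ordered pairs."""
    c = h.shape[1]
    u = h @ model.w1[:c]            # source-side term
    v = h @ model.w1[c:]            # target-side term
    pre = u[:, None, :] + v[None, :, :] + model.b1
    a1 = np.maximum(0.0, pre)
    return a1 @ model.w2 + model.b2


def predict_fc(sc: np.ndarray, model: GnnModel) -> np.ndarray:
    """Symmetrized predicted FC, (pFC_ij + pFC_ji)/2, zero diagonal."""
    h = encode(sc, model)[-1]
    p = _pairwise_predictions(h, model)
    p = 0.5 * (p + p.T)
    np.fill_diagonal(p, 0.0)
    return p


def mse_l2_loss(pfc_batch: list[np.ndarray], efc_batch: list[np.ndarray],
                model: GnnModel, l2_lambda: float) -> float:
    """Batch loss: mean over subjects of the ordered-pair MSE, plus
    ``l2_lambda * ||W_MLP||^2`` (MLP weight matrices only, no biases)."""
    if l2_lambda < 0:
        raise ConfigError("l2_lambda must be >= 0")
    if len(pfc_batch) != len(efc_batch) or not pfc_batch:
        raise InvalidInputError("batches must be non-empty and equal-length")
    total = 0.0
    for p, e in zip(pfc_batch, efc_batch):
        k = p.shape[0]
        diff = p - e
        off = ~np.eye(k, dtype=bool)
        total += float(np.sum(diff[off] ** 2)) / (k * (k - 1))
    return total / len(pfc_batch) + l2_lambda * model.mlp_weight_sq_norm()


def split_cohort(subject_ids: list, fraction: float = 0.5,
                 seed: int | np.random.Generator = 0) -> tuple[list, list]:
    """Random disjoint, exhaustive train/test split; sizes differ by <= 1."""
    n = len(subject_ids)
    if n < 4:
        raise InvalidInputError(f"need at least 4 subjects to split, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * fraction))
    train = sorted(perm[:n_train].tolist())
    test = sorted(perm[n_train:].tolist())
    return ([subject_ids[i] for i in train], [subject_ids[i] for i in test])


def _forward_backward(s: np.ndarray, efc: np.ndarray, model: GnnModel):
    """Loss and analytic gradients for one subject (data term only).

    Returns (loss, grads) where grads mirrors the parameter layout.
    The loss is the ordered-pair MSE, (1/(K(K-1))) sum_{i != j}
    (pFC_ij - eFC_ij)^2, on the raw (unsymmetrized) predictions, as in
    training; symmetrization is applied only at prediction time.
    """
    k = s.shape[0]
    c = model.config.gcn_dims[-1]

    # ---- forward ----
    hs = [np.eye(k)]
    zs = []
    h = hs[0]
    for w, alpha in zip(model.gcn_weights, model.prelu_slopes):
        z = s @ h @ w
        zs.append(z)
        h = _prelu(z, float(alpha))
        hs.append(h)
    u = h @ model.w1[:c]
    v = h @ model.w1[c:]
    pre = u[:, None, :] + v[None, :, :] + model.b1
    a1 = np.maximum(0.0, pre)
    p = a1 @ model.w2 + model.b2

    off = ~np.eye(k, dtype=bool)
    diff = np.where(off, p - efc, 0.0)
    denom = k * (k - 1)
    loss = float(np.sum(diff**2)) / denom

    # ---- backward ----
    dp = 2.0 * diff / denom
    da1 = dp[:, :, None] * model.w2[None, None, :]
    dpre = np.where(pre > 0, da1, 0.0)
    g_w2 = np.einsum("ijm,ij->m", a1, dp)
    g_b2 = float(dp.sum())
    g_b1 = dpre.sum(axis=(0, 1))
    du = dpre.sum(axis=1)
    dv = dpre.sum(axis=0)
    g_w1 = np.vstack([h.T @ du, h.T @ dv])
    dh = du @ model.w1[:c].T + dv @ model.w1[c:].T

    g_gcn = [None] * len(model.gcn_weights)
    g_alpha = np.zeros_like(model.prelu_slopes)
    for l in range(len(model.gcn_weights) - 1, -1, -1):
        z = zs[l]
        alpha = float(model.prelu_slopes[l])
        dz = np.where(z >= 0, dh, alpha * dh)
        g_alpha[l] = float(np.sum(dh * np.where(z < 0, z, 0.0)))
        m = s @ hs[l]
        g_gcn[l] = m.T @ dz
        if l > 0:
            dh = s @ (dz @ model.gcn_weights[l].T)   # s is symmetric
    return loss, {"gcn": g_gcn, "alpha": g_alpha, "w1": g_w1, "b1": g_b1,
                  "w2": g_w2, "b2": g_b2}


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


def _params_to_list(model: GnnModel) -> list[np.ndarray]:
    return (list(model.gcn_weights)
            + [model.prelu_slopes, model.w1, model.b1, model.w2,
               np.array([model.b2])])


def _list_to_params(model: GnnModel, params: list[np.ndarray]) -> None:
    n = len(model.gcn_weights)
    model.gcn_weights = params[:n]
    model.prelu_slopes = params[n]
    model.w1, model.b1, model.w2 = params[n + 1], params[n + 2], params[n + 3]
    model.b2 = float(params[n + 4][0])


def train_model(train_scs: list[np.ndarray], train_fcs: list[np.ndarray],
                config: GnnConfig) -> tuple[GnnModel, np.ndarray]:
    """Train on a cohort of node-aligned (SC, FC) pairs.

    Batched Adam on the MSE + L2 objective; parameters are initialized
    from the seeded stream and subject order is reshuffled per epoch
    from the same stream, so the run is fully reproducible.  Returns
    the final model and the per-epoch mean training loss.
    """
    config.validate()
    if len(train_scs) != len(train_fcs) or not train_scs:
        raise InvalidInputError("need equal-length, non-empty SC/FC lists")
    k = train_scs[0].shape[0]
    if config.gcn_dims[0] != k:
        raise ConfigError(f"gcn_dims[0]={config.gcn_dims[0]} must equal K={k}")
    rng = np.random.default_rng(config.seed)
    model = init_model(config, rng)
    s_mats = [normalized_adjacency(a) for a in train_scs]

    opt = _Adam([p.shape for p in _params_to_list(model)], config.learning_rate)
    n = len(train_scs)
    lam = config.l2_lambda
    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            grads_sum = None
            batch_loss = 0.0
            for idx in batch:
                loss, g = _forward_backward(s_mats[idx], train_fcs[idx], model)
                batch_loss += loss
                glist = (g["gcn"] + [g["alpha"], g["w1"], g["b1"], g["w2"],
                                     np.array([g["b2"]])])
                if grads_sum is None:
                    grads_sum = glist
                else:
                    grads_sum = [a + b for a, b in zip(grads_sum, glist)]
            nb = len(batch)
            grads = [g / nb for g in grads_sum]
            # L2 penalty on MLP weight matrices only.
            n_gcn = len(model.gcn_weights)
            grads[n_gcn + 1] = grads[n_gcn + 1] + 2 * lam * model.w1
            grads[n_gcn + 3] = grads[n_gcn + 3] + 2 * lam * model.w2
            batch_loss = batch_loss / nb + lam * model.mlp_weight_sq_norm()
            if not np.isfinite(batch_loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            params = opt.step(_params_to_list(model), grads)
            _list_to_params(model, params)
            epoch_loss += batch_loss
            n_batches += 1
        losses[epoch] = epoch_loss / n_batches
    return model, losses


def group_level_predict(model: GnnModel, test_scs: list[np.ndarray],
                        test_fcs: list[np.ndarray]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Predict the group-mean FC from the elementwise-mean test SC.

    Returns (predicted mean FC, empirical mean FC).
    """
    if not test_scs:
        raise InvalidInputError("test set is empty")
    mean_sc = np.mean(np.stack(test_scs), axis=0)
    mean_fc = np.mean(np.stack(test_fcs), axis=0)
    return predict_fc(mean_sc, model), mean_fc


def save_model(model: GnnModel, path) -> None:
    """Checkpoint all parameter matrices plus the config as JSON text."""
    import json
    from pathlib import Path
    payload = {
        "config": model.config.to_dict(),
        "gcn_weights": [w.tolist() for w in model.gcn_weights],
        "prelu_slopes": model.prelu_slopes.tolist(),
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> GnnModel:
    """Restore a checkpoint written by :func:`save_model`."""
    import json
    from pathlib import Path
    payload = json.loads(Path(path).read_text())
    return GnnModel(
        gcn_weights=[np.array(w) for w in payload["gcn_weights"]],
        prelu_slopes=np.array(payload["prelu_slopes"]),
        w1=np.array(payload["w1"]), b1=np.array(payload["b1"]),
        w2=np.array(payload["w2"]), b2=float(payload["b2"]),
        config=GnnConfig.from_dict(payload["config"]))
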