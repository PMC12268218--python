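"""Classifiers for per-frame facial-feature sequences.

Two model families are provided:

* an SVM baseline (RBF kernel, C=1, gamma='scale', standard-scaled inputs)
  operating on time-averaged video-level features, via scikit-learn;
* recurrent sequence classifiers: a 1-directional stacked GRU (3 layers,
  hidden size 35) whose per-frame outputs are reduced to a video-level vector
  by one of three heads — uniform averaging, learned-context attention
  (hierarchical contextual attention over frames), or a depthwise 1-D
  convolution (kernel 3, stride 1, same padding) followed by temporal
  averaging — and then classified by an MLP (two hidden layers of 24 ReLU
  units) with a softmax output.

The recurrent models, Adam optimizer and backpropagation are implemented
directly in NumPy.  Training minimizes cross-entropy with Adam (learning rate
0.001, batch size 64) and early stopping on validation UAR with a patience of
30 epochs, restoring the best-epoch weights.  Sequences within a batch are
zero-padded to the batch maximum and padded frames are masked in the GRU
recursion and in all three heads.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import EmotionLabel, FeatureSequence, VideoRecord, concat_features
from .evaluation import contingency, uar

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "SVMBaseline",
    "LeakageError",
    "DegenerateTrainingError",
    "fit_svm_baseline",
    "average_pool",
    "attention_pool",
    "conv_pool",
    "forward",
    "train_model",
    "predict_records",
    "map_to_valence",
    "run_early_stopping",
    "BINARY_CLASSES",
    "MULTICLASS_CLASSES",
]

BINARY_CLASSES = ("negative", "positive")
MULTICLASS_CLASSES = tuple(sorted(l.value for l in EmotionLabel))


class LeakageError(ValueError):
    """A subject appears in more than one data split."""


class DegenerateTrainingError(ValueError):
    """Training data does not contain at least two classes."""


def map_to_valence(label: EmotionLabel) -> str:
    """'negative' for anger/anxiety/disgust/sadness, 'positive' otherwise."""
    return label.valence


@dataclass
class ModelConfig:
    """Hyperparameters of a recurrent sequence classifier."""

    task: str = "multiclass"  # 'binary' or 'multiclass'
    head: str = "attention"  # 'average', 'attention' or 'convolution'
    feature_kind: str = "appearance"
    gru_layers: int = 3
    gru_hidden: int = 35
    mlp_hidden: tuple = (24, 24)
    learning_rate: float = 0.001
    batch_size: int = 64
    patience: int = 30
    max_epochs: int = 500
    conv_depthwise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.head not in ("average", "attention", "convolution"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.feature_kind not in ("appearance", "deep", "concatenated"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.gru_hidden < 1 or self.gru_layers < 1:
            raise ValueError("gru_hidden and gru_layers must be >= 1")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")

    @property
    def n_classes(self) -> int:
        return 2 if self.task == "binary" else 16

    @property
    def class_names(self) -> tuple:
        return BINARY_CLASSES if self.task == "binary" else MULTICLASS_CLASSES


@dataclass
class TrainedModel:
    """A fitted sequence classifier: config, weights, input standardizer,
    per-epoch validation history, and the index (1-based) of the best epoch."""

    config: ModelConfig
    params: dict
    standardizer: tuple  # (mean, sd) per feature; sd==0 columns pass through
    history: list = field(default_factory=list)
    best_epoch: int = 0
    loss_history: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Single-file .npz archive: config + standardizer + weights + history."""
        meta = json.dumps(
            {
                "config": {**self.config.__dict__, "mlp_hidden": list(self.config.mlp_hidden)},
                "history": self.history,
                "best_epoch": self.best_epoch,
                "loss_history": self.loss_history,
            }
        )
        np.savez(
            path,
            __meta__=np.array(meta),
            __mean__=self.standardizer[0],
            __sd__=self.standardizer[1],
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            cfg_d = meta["config"]
            cfg_d["mlp_hidden"] = tuple(cfg_d["mlp_hidden"])
            cfg = ModelConfig(**cfg_d)
            params = {k: z[k] for k in z.files if not k.startswith("__")}
            model = cls(cfg, params, (z["__mean__"], z["__sd__"]))
        model.history = meta["history"]
        model.best_epoch = meta["best_epoch"]
        model.loss_history = meta.get("loss_history", [])
        return model


# ---------------------------------------------------------------------------
# SVM baseline
# ---------------------------------------------------------------------------

@dataclass
class SVMBaseline:
    """Standard-scaled RBF-kernel SVM over video-level feature vectors."""

    pipeline: Pipeline

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))

    @property
    def classes_(self) -> np.ndarray:
        return self.pipeline.named_steps["svc"].classes_


def fit_svm_baseline(X: np.ndarray, y: Sequence) -> SVMBaseline:
    """Fit the baseline SVM: StandardScaler + SVC(kernel='rbf', C=1,
    gamma='scale'), hard-label prediction."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", C=1.0, gamma="scale"))]
    )
    pipe.fit(X, y)
    return SVMBaseline(pipe)


# ---------------------------------------------------------------------------
# Pooling heads (stateless functional forms with explicit parameters)
# ---------------------------------------------------------------------------

def _masked_weighted_sum(H: np.ndarray, w: np.ndarray) -> np.ndarray:
    """sum_t w[...,t] * H[...,t,:] — shared by the average and attention heads
    so that zero attention parameters reproduce averaging bit-for-bit."""
    return np.einsum("...t,...th->...h", w, H)


def average_pool(H: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Uniform (masked) mean over time of a (T, h) or (B, T, h) array."""
    H = np.asarray(H, dtype=float)
    single = H.ndim == 2
    if single:
        H = H[None]
    B, T, _ = H.shape
    m = np.ones((B, T)) if mask is None else np.asarray(mask, dtype=float)
    w = m / m.sum(axis=1, keepdims=True)
    out = _masked_weighted_sum(H, w)
    return out[0] if single else out


def attention_pool(
    H: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Learned-context attention over frames.

    u_t = tanh(W h_t + b); alpha = softmax_t(u_t . c) over unmasked frames;
    output = sum_t alpha_t h_t.  Returns (pooled, alpha); alpha sums to 1.
    With W = b = c = 0 the weights are uniform and the output equals
    ``average_pool`` exactly.
    """
    H = np.asarray(H, dtype=float)
    single = H.ndim == 2
    if single:
        H = H[None]
    B, T, h = H.shape
    m = np.ones((B, T)) if mask is None else np.asarray(mask, dtype=float)
    u = np.tanh(H @ W.T + b)  # (B, T, h)
    s = u @ c  # (B, T)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s) * m
    alpha = e / e.sum(axis=1, keepdims=True)
    out = _masked_weighted_sum(H, alpha)
    return (out[0], alpha[0]) if single else (out, alpha)


def conv_pool(
    H: np.ndarray,
    kernel: np.ndarray,
    bias: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Depthwise temporal convolution (kernel 3, stride 1, zero 'same'
    padding) followed by a masked average over time.

    ``kernel`` has shape (3, h): the same 3-tap filter per feature channel.
    """
    H = np.asarray(H, dtype=float)
    single = H.ndim == 2
    if single:
        H = H[None]
    B, T, h = H.shape
    m = np.ones((B, T)) if mask is None else np.asarray(mask, dtype=float)
    Hm = H * m[:, :, None]
    pad = np.zeros((B, 1, h))
    prev = np.concatenate([pad, Hm[:, :-1]], axis=1)
    nxt = np.concatenate([Hm[:, 1:], pad], axis=1)
    y = prev * kernel[0] + Hm * kernel[1] + nxt * kernel[2]
    if bias is not None:
        y = y + bias
    w = m / m.sum(axis=1, keepdims=True)
    out = _masked_weighted_sum(y, w)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# GRU forward / backward
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _init_params(cfg: ModelConfig, input_dim: int, rng: np.random.Generator) -> dict:
    """Uniform(-1/sqrt(fan), 1/sqrt(fan)) initialisation; attention starts at
    zero so it begins as plain averaging."""
    p: dict[str, np.ndarray] = {}
    h = cfg.gru_hidden
    k = 1.0 / np.sqrt(h)
    d = input_dim
    for l in range(cfg.gru_layers):
        p[f"gru{l}_W_ih"] = rng.uniform(-k, k, size=(3 * h, d))
        p[f"gru{l}_W_hh"] = rng.uniform(-k, k, size=(3 * h, h))
        p[f"gru{l}_b_ih"] = rng.uniform(-k, k, size=3 * h)
        p[f"gru{l}_b_hh"] = rng.uniform(-k, k, size=3 * h)
        d = h
    if cfg.head == "attention":
        p["att_W"] = np.zeros((h, h))
        p["att_b"] = np.zeros(h)
        p["att_c"] = np.zeros(h)
    elif cfg.head == "convolution":
        kc = 1.0 / np.sqrt(3.0)
        p["conv_kernel"] = rng.uniform(-kc, kc, size=(3, h))
        p["conv_bias"] = np.zeros(h)
    d = h
    for i, width in enumerate(cfg.mlp_hidden):
        km = 1.0 / np.sqrt(d)
        p[f"mlp{i}_W"] = rng.uniform(-km, km, size=(width, d))
        p[f"mlp{i}_b"] = np.zeros(width)
        d = width
    ko = 1.0 / np.sqrt(d)
    p["out_W"] = rng.uniform(-ko, ko, size=(cfg.n_classes, d))
    p["out_b"] = np.zeros(cfg.n_classes)
    return p


def _gru_layer_forward(
    X: np.ndarray, mask: np.ndarray, W_ih, W_hh, b_ih, b_hh
) -> tuple[np.ndarray, dict]:
    """One GRU layer over a padded batch.  Masked steps carry the hidden
    state through unchanged.  Returns (H, cache)."""
    B, T, _ = X.shape
    h = W_hh.shape[1]
    H = np.zeros((B, T, h))
    cache = {"r": [], "z": [], "n": [], "ghn": [], "hprev": [], "X": X, "mask": mask}
    h_t = np.zeros((B, h))
    for t in range(T):
        x_t = X[:, t]
        gi = x_t @ W_ih.T + b_ih
        gh = h_t @ W_hh.T + b_hh
        gi_r, gi_z, gi_n = np.split(gi, 3, axis=1)
        gh_r, gh_z, gh_n = np.split(gh, 3, axis=1)
        r = _sigmoid(gi_r + gh_r)
        z = _sigmoid(gi_z + gh_z)
        n = np.tanh(gi_n + r * gh_n)
        h_new = (1 - z) * n + z * h_t
        m = mask[:, t][:, None]
        cache["r"].append(r)
        cache["z"].append(z)
        cache["n"].append(n)
        cache["ghn"].append(gh_n)
        cache["hprev"].append(h_t)
        h_t = m * h_new + (1 - m) * h_t
        H[:, t] = h_t
    return H, cache


def _gru_layer_backward(dH: np.ndarray, cache: dict, W_ih, W_hh) -> tuple[np.ndarray, dict]:
    """Backprop one GRU layer.  Returns (dX, grads)."""
    X, mask = cache["X"], cache["mask"]
    B, T, _ = X.shape
    h = W_hh.shape[1]
    dW_ih = np.zeros_like(W_ih)
    dW_hh = np.zeros_like(W_hh)
    db_ih = np.zeros(3 * h)
    db_hh = np.zeros(3 * h)
    dX = np.zeros_like(X)
    dh_next = np.zeros((B, h))
    for t in range(T - 1, -1, -1):
        r, z, n = cache["r"][t], cache["z"][t], cache["n"][t]
        gh_n, h_prev = cache["ghn"][t], cache["hprev"][t]
        m = mask[:, t][:, None]
        dh = dH[:, t] + dh_next
        dh_new = m * dh
        dh_carry = (1 - m) * dh  # flows straight to h_{t-1} on padded steps
        dn = dh_new * (1 - z)
        dz = dh_new * (h_prev - n)
        dh_prev = dh_new * z
        dn_pre = dn * (1 - n**2)
        dgh_n = dn_pre * r
        dr = dn_pre * gh_n
        dr_pre = dr * r * (1 - r)
        dz_pre = dz * z * (1 - z)
        dgi = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
        dgh = np.concatenate([dr_pre, dz_pre, dgh_n], axis=1)
        x_t = X[:, t]
        dW_ih += dgi.T @ x_t
        dW_hh += dgh.T @ h_prev
        db_ih += dgi.sum(axis=0)
        db_hh += dgh.sum(axis=0)
        dX[:, t] = dgi @ W_ih
        dh_next = dgh @ W_hh + dh_prev + dh_carry
    return dX, {"W_ih": dW_ih, "W_hh": dW_hh, "b_ih": db_ih, "b_hh": db_hh}


def _net_forward(
    params: dict, cfg: ModelConfig, X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Full forward pass on a padded batch: GRU stack -> head -> MLP -> softmax.

    Returns (probabilities (B, K), cache)."""
    caches = []
    H = X
    for l in range(cfg.gru_layers):
        H, c = _gru_layer_forward(
            H, mask,
            params[f"gru{l}_W_ih"], params[f"gru{l}_W_hh"],
            params[f"gru{l}_b_ih"], params[f"gru{l}_b_hh"],
        )
        caches.append(c)
    head_cache: dict = {"H": H, "mask": mask}
    if cfg.head == "average":
        pooled = average_pool(H, mask)
    elif cfg.head == "attention":
        pooled, alpha = attention_pool(H, params["att_W"], params["att_b"], params["att_c"], mask)
        head_cache["alpha"] = alpha
        head_cache["u"] = np.tanh(H @ params["att_W"].T + params["att_b"])
    else:
        pooled = conv_pool(H, params["conv_kernel"], params["conv_bias"], mask)
    # MLP
    a = pooled
    acts = [a]
    for i in range(len(cfg.mlp_hidden)):
        zi = a @ params[f"mlp{i}_W"].T + params[f"mlp{i}_b"]
        a = np.maximum(zi, 0.0)
        acts.append(a)
    logits = a @ params["out_W"].T + params["out_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    cache = {"gru": caches, "head": head_cache, "acts": acts, "probs": probs, "pooled": pooled}
    return probs, cache


def _net_backward(
    params: dict, cfg: ModelConfig, cache: dict, y_idx: np.ndarray
) -> dict:
    """Gradients of mean cross-entropy w.r.t. every parameter."""
    probs = cache["probs"]
    B = probs.shape[0]
    grads: dict[str, np.ndarray] = {}
    dlogits = probs.copy()
    dlogits[np.arange(B), y_idx] -= 1.0
    dlogits /= B
    acts = cache["acts"]
    grads["out_W"] = dlogits.T @ acts[-1]
    grads["out_b"] = dlogits.sum(axis=0)
    da = dlogits @ params["out_W"]
    for i in range(len(cfg.mlp_hidden) - 1, -1, -1):
        dz = da * (acts[i + 1] > 0)
        grads[f"mlp{i}_W"] = dz.T @ acts[i]
        grads[f"mlp{i}_b"] = dz.sum(axis=0)
        da = dz @ params[f"mlp{i}_W"]
    dpooled = da  # (B, h)

    H = cache["head"]["H"]
    mask = cache["head"]["mask"]
    m = mask.astype(float)
    Bn, T, h = H.shape
    if cfg.head == "average":
        w = m / m.sum(axis=1, keepdims=True)
        dH = w[:, :, None] * dpooled[:, None, :]
    elif cfg.head == "attention":
        alpha = cache["head"]["alpha"]
        u = cache["head"]["u"]
        dH = alpha[:, :, None] * dpooled[:, None, :]
        dalpha = np.einsum("bh,bth->bt", dpooled, H)
        ds = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        grads["att_c"] = np.einsum("bt,bth->h", ds, u)
        du = ds[:, :, None] * params["att_c"]
        du_pre = du * (1 - u**2)
        grads["att_W"] = np.einsum("bti,btj->ij", du_pre, H)
        grads["att_b"] = du_pre.sum(axis=(0, 1))
        dH += du_pre @ params["att_W"]
    else:
        kernel = params["conv_kernel"]
        w = m / m.sum(axis=1, keepdims=True)
        dy = w[:, :, None] * dpooled[:, None, :]  # (B, T, h)
        Hm = H * m[:, :, None]
        pad = np.zeros((Bn, 1, h))
        prev = np.concatenate([pad, Hm[:, :-1]], axis=1)
        nxt = np.concatenate([Hm[:, 1:], pad], axis=1)
        grads["conv_kernel"] = np.stack(
            [
                np.einsum("bth,bth->h", dy, prev),
                np.einsum("bth,bth->h", dy, Hm),
                np.einsum("bth,bth->h", dy, nxt),
            ]
        )
        grads["conv_bias"] = dy.sum(axis=(0, 1))
        dHm = (
            dy * kernel[1]
            + np.concatenate([dy[:, 1:], pad], axis=1) * kernel[0]
            + np.concatenate([pad, dy[:, :-1]], axis=1) * kernel[2]
        )
        dH = dHm * m[:, :, None]

    for l in range(cfg.gru_layers - 1, -1, -1):
        dH, g = _gru_layer_backward(
            dH, cache["gru"][l], params[f"gru{l}_W_ih"], params[f"gru{l}_W_hh"]
        )
        for k, v in g.items():
            grads[f"gru{l}_{k}"] = v
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def run_early_stopping(history: Sequence[float], patience: int) -> tuple[int, int]:
    """Apply the early-stopping rule to a validation-metric history.

    Epochs are 1-based.  An epoch improves only if its metric is strictly
    greater than the best so far; training stops after ``patience``
    consecutive non-improving epochs.  Returns (stop_epoch, best_epoch) —
    stop_epoch == len(history) means the rule never fired.
    """
    best, best_epoch, since = -np.inf, 0, 0
    for epoch, value in enumerate(history, start=1):
        if value > best:
            best, best_epoch, since = value, epoch, 0
        else:
            since += 1
        if since >= patience:
            return epoch, best_epoch
    return len(history), best_epoch


def _record_matrix(rec: VideoRecord, kind: str) -> np.ndarray:
    if kind == "appearance":
        return rec.features.values
    if rec.deep_features is None:
        raise ValueError(f"record {rec.video_id!r} has no deep features")
    if kind == "deep":
        return rec.deep_features.values
    return concat_features(rec.features, rec.deep_features).values


def _targets(records: Sequence[VideoRecord], cfg: ModelConfig) -> np.ndarray:
    names = cfg.class_names
    if cfg.task == "binary":
        return np.array([names.index(r.label.valence) for r in records])
    return np.array([names.index(r.label.value) for r in records])


def _standardize(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe


def _batch_forward(
    params: dict, cfg: ModelConfig, mats: list[np.ndarray]
) -> np.ndarray:
    """Forward a list of (already standardized) T_i x D matrices; returns probs."""
    probs = np.empty((len(mats), cfg.n_classes))
    bs = cfg.batch_size
    for i in range(0, len(mats), bs):
        chunk = mats[i: i + bs]
        T = max(m.shape[0] for m in chunk)
        X = np.zeros((len(chunk), T, chunk[0].shape[1]))
        mask = np.zeros((len(chunk), T))
        for j, mat in enumerate(chunk):
            X[j, : mat.shape[0]] = mat
            mask[j, : mat.shape[0]] = 1.0
        p, _ = _net_forward(params, cfg, X, mask)
        probs[i: i + len(chunk)] = p
    return probs


def forward(model: TrainedModel, seq: FeatureSequence) -> np.ndarray:
    """Class-probability vector for one sequence (softmax output)."""
    cfg = model.config
    if seq.feature_kind != cfg.feature_kind:
        raise ValueError(
            f"model expects {cfg.feature_kind} features, got {seq.feature_kind}"
        )
    mean, sd = model.standardizer
    if seq.dim != mean.shape[0]:
        raise ValueError(f"input dimension {seq.dim} != standardizer {mean.shape[0]}")
    mat = _standardize(seq.values, mean, sd)
    return _batch_forward(model.params, cfg, [mat])[0]


def predict_records(model: TrainedModel, records: Sequence[VideoRecord]) -> list[str]:
    """Hard class-name predictions for a list of records."""
    cfg = model.config
    mean, sd = model.standardizer
    mats = [_standardize(_record_matrix(r, cfg.feature_kind), mean, sd) for r in records]
    probs = _batch_forward(model.params, cfg, mats)
    names = cfg.class_names
    return [names[i] for i in probs.argmax(axis=1)]


def _val_uar(params, cfg, mats, y_idx) -> float:
    probs = _batch_forward(params, cfg, mats)
    pred = probs.argmax(axis=1)
    names = list(range(cfg.n_classes))
    return uar(contingency(list(y_idx), list(pred), names))


def train_model(
    train: Sequence[VideoRecord],
    val: Sequence[VideoRecord],
    cfg: ModelConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Train a GRU sequence classifier with Adam, cross-entropy loss and
    early stopping on validation UAR (best-epoch weights restored).

    Train and validation splits must be subject-disjoint.
    """
    if not train or not val:
        raise ValueError("train and validation splits must both be nonempty")
    overlap = {r.subject_id for r in train} & {r.subject_id for r in val}
    if overlap:
        raise LeakageError(f"subjects in both train and validation: {sorted(overlap)}")

    y_train = _targets(train, cfg)
    y_val = _targets(val, cfg)
    if len(np.unique(y_train)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")

    raw_train = [_record_matrix(r, cfg.feature_kind) for r in train]
    all_frames = np.vstack(raw_train)
    mean = all_frames.mean(axis=0)
    sd = all_frames.std(axis=0)
    mats_train = [_standardize(m, mean, sd) for m in raw_train]
    mats_val = [
        _standardize(_record_matrix(r, cfg.feature_kind), mean, sd) for r in val
    ]

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, mats_train[0].shape[1], rng)
    opt = _Adam(params, cfg.learning_rate)

    history: list[float] = []
    loss_history: list[float] = []
    best_uar, best_epoch, since = -np.inf, 0, 0
    best_params = copy.deepcopy(params)
    n = len(mats_train)
    for epoch in range(1, cfg.max_epochs + 1):
        losses: list[float] = []
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i: i + cfg.batch_size]
            chunk = [mats_train[j] for j in idx]
            T = max(m.shape[0] for m in chunk)
            X = np.zeros((len(chunk), T, chunk[0].shape[1]))
            mask = np.zeros((len(chunk), T))
            for j, mat in enumerate(chunk):
                X[j, : mat.shape[0]] = mat
                mask[j, : mat.shape[0]] = 1.0
            probs, cache = _net_forward(params, cfg, X, mask)
            losses.append(
                -np.mean(np.log(probs[np.arange(len(idx)), y_train[idx]] + 1e-300))
            )
            grads = _net_backward(params, cfg, cache, y_train[idx])
            opt.step(params, grads)
        loss_history.append(float(np.mean(losses)))
        v = _val_uar(params, cfg, mats_val, y_val)
        history.append(v)
        if verbose:
            print(f"epoch {epoch}: val UAR {v:.4f}")
        if v > best_uar:
            best_uar, best_epoch, since = v, epoch, 0
            best_params = copy.deepcopy(params)
        else:
            since += 1
        if since >= cfg.patience:
            break
    return TrainedModel(cfg, best_params, (mean, sd), history, best_epoch, loss_history)
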