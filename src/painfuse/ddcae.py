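"""Multi-modal deep denoising convolutional auto-encoder with gated fusion.

One encoder/decoder pair per physiological channel plus a trainable fusion
gate and a joint inference head, trained end-to-end:

* encoder: three blocks of (2 same-padded Conv1D + max-pool 2) with
  8/16/32 kernels, ELU activations, optional per-position attention after
  every convolution, then a fully connected layer to the latent width eta;
* decoder: fully connected to (m/8)*4 units, reshape, three blocks of
  (2 Conv1D + 2x upsampling) with 32/16/8 kernels, and a final linear
  1-channel convolution back to the window length m;
* fusion: each latent h_i is passed through a tanh normalization layer,
  the normalized latents are concatenated and fed to a softmax layer over
  all n*eta features; the fused representation is the eta-wise sum of each
  weight slice multiplied element-wise with the raw latent h_i;
* head: dense 128 (ELU) -> dropout -> dense c (softmax) or dense 1 (linear).

The training objective combines per-modality denoising reconstruction
errors (mean squared error against the clean signal, plus an L2 penalty on
that auto-encoder's parameters) with the task loss, weighted by per-model
regularization weights alpha_i / alpha_psi.

Convolution kernels are modality-specific: 3 for the slowly varying EDA
channel, 11 for ECG/EMG/RSP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, maxpool1d, upsample1d
from .nn import Adam, Conv1D, Dense, SpatialAttention, dropout_mask, softmax
from .preprocess import SegmentDataset

__all__ = [
    "ModelConfig", "preset", "elu", "MultimodalDDCAE", "Encoder", "Decoder",
    "GateFusion", "InferenceHead", "reconstruction_loss", "task_loss",
    "total_loss", "train_supervised", "stratified_batches",
]


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha*(exp(x)-1) below."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, alpha * np.expm1(x))


@dataclass(frozen=True)
class ModelConfig:
    modalities: tuple
    m: int
    eta: int = 256
    task: str = "classification"  # or "regression"
    n_classes: int = 2
    attention: bool = True
    attention_kernel: int = 3
    channels: tuple = (8, 16, 32)
    dropout: float = 0.5
    l2: float = 1e-3
    alphas: tuple = None
    alpha_psi: float = 0.4
    noise_sd: float = 0.1
    lr: float = 1e-5
    epochs: int = 100
    batch_size: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.m % 8 != 0:
            raise ValueError("window length m must be divisible by 8 "
                             "(three 2x poolings)")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.alphas is None:
            object.__setattr__(
                self, "alphas", tuple([0.2] * len(self.modalities))
            )
        if len(self.alphas) != len(self.modalities):
            raise ValueError("need one alpha per modality")

    def kernel_for(self, modality: str) -> int:
        return 3 if modality == "EDA" else 11

    @property
    def n(self) -> int:
        return len(self.modalities)


_PRESETS = {
    "biovid": dict(
        modalities=("EDA", "ECG", "EMG"), m=1152,
        alphas=(0.2, 0.2, 0.2), alpha_psi=0.4,
        batch={"binary": 40, "multiclass": 100, "regression": 100},
        n_classes={"binary": 2, "multiclass": 5},
    ),
    "senseemotion": dict(
        modalities=("EDA", "ECG", "EMG", "RSP"), m=1664,
        alphas=(0.15, 0.15, 0.15, 0.15), alpha_psi=0.4,
        batch={"binary": 120, "multiclass": 480, "regression": 480},
        n_classes={"binary": 2, "multiclass": 4},
    ),
}


def preset(dataset: str, task: str = "binary", **overrides) -> ModelConfig:
    """Dataset presets with the full-scale architecture and optimizer settings."""
    if dataset not in _PRESETS:
        raise ValueError(f"unknown dataset preset {dataset!r}")
    if task not in ("binary", "multiclass", "regression"):
        raise ValueError(f"unknown task {task!r}")
    p = _PRESETS[dataset]
    cfg = dict(
        modalities=p["modalities"], m=p["m"], alphas=p["alphas"],
        alpha_psi=p["alpha_psi"], batch_size=p["batch"][task],
        task="regression" if task == "regression" else "classification",
        n_classes=p["n_classes"].get(task, 1),
    )
    cfg.update(overrides)
    if "modalities" in overrides and "alphas" not in overrides:
        cfg["alphas"] = (p["alphas"][0],) * len(cfg["modalities"])
    return ModelConfig(**cfg)


# ---------------------------------------------------------------------------
# Network components
# ---------------------------------------------------------------------------

class Encoder:
    """Corrupted window (N, m) -> latent (N, out_dim)."""

    def __init__(self, rng, cfg: ModelConfig, modality: str,
                 out_dim: int | None = None, dense_activation: str = "elu"):
        k = cfg.kernel_for(modality)
        c1, c2, c3 = cfg.channels
        chain = [(1, c1), (c1, c1), (c1, c2), (c2, c2), (c2, c3), (c3, c3)]
        self.convs = [Conv1D(rng, ci, co, k) for ci, co in chain]
        self.atts = (
            [SpatialAttention(rng, cfg.attention_kernel) for _ in chain]
            if cfg.attention else None
        )
        self.flat = (cfg.m // 8) * c3
        self.dense = Dense(rng, self.flat, out_dim or cfg.eta,
                           activation=dense_activation)
        self.m = cfg.m

    def __call__(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        f = x.reshape(n, self.m, 1)
        for i, conv in enumerate(self.convs):
            f = conv(f)
            if self.atts is not None:
                f = self.atts[i](f)
            if i % 2 == 1:
                f = maxpool1d(f, 2)
        return self.dense(f.reshape(n, self.flat))

    @property
    def params(self):
        out = [p for c in self.convs for p in c.params]
        if self.atts is not None:
            out += [p for a in self.atts for p in a.params]
        return out + self.dense.params


class Decoder:
    """Latent (N, eta) -> reconstruction (N, m).

    The dense layer has (m/8)*4 units reshaped to (m/8, 4), which recovers
    a 576-unit layer at m = 1152 and scales consistently with the window.
    """

    def __init__(self, rng, cfg: ModelConfig, modality: str):
        k = cfg.kernel_for(modality)
        c1, c2, c3 = cfg.channels
        self.m = cfg.m
        self.dense = Dense(rng, cfg.eta, (cfg.m // 8) * 4, activation="elu")
        chain = [(4, c3), (c3, c3), (c3, c2), (c2, c2), (c2, c1), (c1, c1)]
        self.convs = [Conv1D(rng, ci, co, k) for ci, co in chain]
        self.out_conv = Conv1D(rng, c1, 1, k, activation=None)

    def __call__(self, h: Tensor) -> Tensor:
        n = h.shape[0]
        f = self.dense(h).reshape(n, self.m // 8, 4)
        for i, conv in enumerate(self.convs):
            f = conv(f)
            if i % 2 == 1:
                f = upsample1d(f, 2)
        return self.out_conv(f).reshape(n, self.m)

    @property
    def params(self):
        return (self.dense.params
                + [p for c in self.convs for p in c.params]
                + self.out_conv.params)


class GateFusion:
    """Softmax gate over all n*eta normalized latent features.

    Each latent goes through its own tanh normalization layer; the
    concatenated normalized latents feed the softmax logits, and the fused
    representation is the element-wise weighted sum of the *raw* latents.
    """

    def __init__(self, rng, n: int, eta: int):
        self.n, self.eta = n, eta
        self.norms = [Dense(rng, eta, eta, activation="tanh") for _ in range(n)]
        self.gate = Dense(rng, n * eta, n * eta)

    def __call__(self, latents: list):
        assert len(latents) == self.n
        batch = latents[0].shape[0]
        normalized = [norm(h) for norm, h in zip(self.norms, latents)]
        w = softmax(self.gate(concat(normalized, axis=1)), axis=1)
        hstack = concat(latents, axis=1).reshape(batch, self.n, self.eta)
        fused = (w.reshape(batch, self.n, self.eta) * hstack).sum(axis=1)
        return w, fused

    @property
    def params(self):
        return [p for d in self.norms for p in d.params] + self.gate.params


class InferenceHead:
    def __init__(self, rng, cfg: ModelConfig):
        self.cfg = cfg
        out = cfg.n_classes if cfg.task == "classification" else 1
        self.fc1 = Dense(rng, cfg.eta, 128, activation="elu")
        self.fc2 = Dense(rng, 128, out)

    def __call__(self, fused: Tensor, train: bool = False, rng=None) -> Tensor:
        z = self.fc1(fused)
        if train and self.cfg.dropout > 0:
            z = z * dropout_mask(rng, z.shape, self.cfg.dropout)
        out = self.fc2(z)
        if self.cfg.task == "classification":
            return softmax(out, axis=1)
        return out.reshape(out.shape[0])

    @property
    def params(self):
        return self.fc1.params + self.fc2.params


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def reconstruction_loss(clean: np.ndarray, recon: Tensor,
                        weights=(), lam: float = 0.0) -> Tensor:
    """Batch-mean squared L2 reconstruction error + lam * ||W||^2."""
    d = recon - Tensor(clean, requires_grad=False)
    loss = (d * d).sum(axis=1).mean()
    if lam:
        for w in weights:
            loss = loss + lam * (w * w).sum()
    return loss


def task_loss(pred: Tensor, y: np.ndarray, task: str = "classification",
              eps: float = 1e-7) -> Tensor:
    """Categorical cross-entropy (one-hot y) or mean squared error."""
    if task == "classification":
        p = pred.clip_min(eps)
        yt = Tensor(y, requires_grad=False)
        return -(yt * p.log()).sum(axis=1).mean()
    d = pred - Tensor(y, requires_grad=False)
    return (d * d).mean()


def total_loss(recon_losses, task_loss_value, alphas, alpha_psi):
    if len(recon_losses) != len(alphas):
        raise ValueError("need exactly one alpha per reconstruction loss")
    out = alpha_psi * task_loss_value
    for a, e in zip(alphas, recon_losses):
        out = out + a * e
    return out


def one_hot(idx: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros((len(idx), c))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def stratified_batches(rng: np.random.Generator, y: np.ndarray,
                       batch_size: int) -> list:
    """Label-stratified shuffled batches (regression: plain shuffle)."""
    n = len(y)
    classes, inv = np.unique(y, return_inverse=True)
    if len(classes) > max(20, int(np.sqrt(n))):  # treat as continuous targets
        order = rng.permutation(n)
    else:
        keys = np.empty(n)
        for ci in range(len(classes)):
            idx = np.flatnonzero(inv == ci)
            keys[idx] = (rng.permutation(len(idx)) + rng.random(len(idx))) / len(idx)
        order = np.argsort(keys)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


# ---------------------------------------------------------------------------
# The full model
# ---------------------------------------------------------------------------

class MultimodalDDCAE:
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoders = {mod: Encoder(rng, cfg, mod) for mod in cfg.modalities}
        self.decoders = {mod: Decoder(rng, cfg, mod) for mod in cfg.modalities}
        self.gate = GateFusion(rng, cfg.n, cfg.eta)
        self.head = InferenceHead(rng, cfg)
        self._rng = rng
        self.classes_ = None

    # -- parameter bookkeeping -------------------------------------------
    def modality_weights(self, mod: str) -> list:
        return self.encoders[mod].params + self.decoders[mod].params

    def parameters(self) -> list:
        out = []
        for mod in self.cfg.modalities:
            out += self.modality_weights(mod)
        return out + self.gate.params + self.head.params

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[f"p{i}"]

    # -- forward paths -----------------------------------------------------
    def forward(self, X: dict, train: bool = False) -> dict:
        latents, recons = {}, {}
        for mod in self.cfg.modalities:
            h = self.encoders[mod](Tensor(X[mod], requires_grad=False))
            latents[mod] = h
            recons[mod] = self.decoders[mod](h)
        w, fused = self.gate([latents[mod] for mod in self.cfg.modalities])
        out = self.head(fused, train=train, rng=self._rng)
        return {"latents": latents, "recons": recons, "gate_weights": w,
                "fused": fused, "output": out}

    def loss_on_batch(self, X_clean: dict, y: np.ndarray) -> tuple:
        cfg = self.cfg
        X_noisy = {
            mod: x + self._rng.normal(0.0, cfg.noise_sd, x.shape)
            for mod, x in X_clean.items()
        }
        out = self.forward(X_noisy, train=True)
        recon_losses = [
            reconstruction_loss(X_clean[mod], out["recons"][mod],
                                self.modality_weights(mod), cfg.l2)
            for mod in cfg.modalities
        ]
        lt = task_loss(out["output"], y, cfg.task)
        return total_loss(recon_losses, lt, cfg.alphas, cfg.alpha_psi), {
            "recon": [float(e.data) for e in recon_losses],
            "task": float(lt.data),
        }

    def predict_proba(self, X: dict) -> np.ndarray:
        return self.forward(X, train=False)["output"].data

    def predict(self, X: dict) -> np.ndarray:
        out = self.predict_proba(X)
        if self.cfg.task == "classification":
            idx = out.argmax(axis=1)  # ties resolve to the lowest class index
            return self.classes_[idx] if self.classes_ is not None else idx
        return out

    # -- training ----------------------------------------------------------
    def encode_targets(self, y: np.ndarray) -> np.ndarray:
        if self.cfg.task == "regression":
            return np.asarray(y, dtype=float)
        if self.classes_ is None:
            self.classes_ = np.unique(y)
        idx = np.searchsorted(self.classes_, y)
        return one_hot(idx, self.cfg.n_classes)

    def fit(self, ds: SegmentDataset, epochs: int | None = None) -> list:
        cfg = self.cfg
        if cfg.task == "classification" and len(np.unique(ds.y)) < 2:
            raise ValueError("classification needs training data from "
                             ">= 2 classes")
        targets = self.encode_targets(ds.y)
        opt = Adam(self.parameters(), cfg.lr)
        history = []
        for epoch in range(epochs if epochs is not None else cfg.epochs):
            batch_losses = []
            for idx in stratified_batches(self._rng, ds.y, cfg.batch_size):
                Xb = {mod: x[idx] for mod, x in ds.X.items()}
                loss, parts = self.loss_on_batch(Xb, targets[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                batch_losses.append(float(loss.data))
            history.append({"epoch": epoch, "loss": float(np.mean(batch_losses))})
        return history


def train_supervised(ds: SegmentDataset, cfg: ModelConfig,
                     epochs: int | None = None):
    """End-to-end supervised training; returns (model, per-epoch history)."""
    model = MultimodalDDCAE(cfg)
    history = model.fit(ds, epochs=epochs)
    return model, history
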