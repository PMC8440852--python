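"""Adaptive-prior variational auto-encoders and self-supervised fine-tuning.

Each modality gets a stochastic convolutional encoder producing a diagonal
Gaussian posterior p(h|x) (mean plus soft-plus standard deviation, 2*eta
output units) and a decoder p(x|h). Instead of a fixed standard-normal
prior, the latent prior of each modality tracks the marginal posterior by
an exponential running mean with retention factor (1 - 1/tau).

Information-processing constraints penalize, with weights 1/beta, the KL
divergence between each posterior and its running marginal: the latent
posteriors (1/beta1), the fusion-gate weight distribution against its
running marginal p(w) (1/beta2), and the classifier output distribution
against the running label marginal p(y) (1/beta3). The gate and classifier
outputs are softmax vectors and are treated directly as categorical
distributions; for regression the output is a scalar and the p(y)
constraint is omitted.

The self-supervised procedure runs per leave-one-subject-out fold:
(i) train the system on the held-in, non-augmented data; (ii) draw latents
from the learned priors, decode them into synthetic multi-channel windows
and pseudo-label them with the model's own prediction; (iii) fine-tune on
only the generated set; (iv) evaluate on the held-out subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from ._autodiff import Tensor
from .nn import Adam
from .ddcae import (
    Decoder, Encoder, GateFusion, InferenceHead, ModelConfig, one_hot,
    reconstruction_loss, stratified_batches, task_loss,
)
from .evaluation import FoldResult, loso_folds
from .preprocess import SegmentDataset, apply_scaling, normalize

log = logging.getLogger(__name__)

__all__ = [
    "SSLConfig", "LatentPosterior", "RunningPrior", "gaussian_kl",
    "categorical_kl", "avae_loss", "info_constrained_loss",
    "AdaptiveVAESystem", "pseudo_label", "ssl_run",
]


@dataclass(frozen=True)
class SSLConfig:
    beta1: float = 0.001
    beta2: float = 0.001
    beta3: float = 0.001
    ema_decay: float = 0.9995  # retention factor (1 - 1/tau) => tau = 2000
    gen_fraction: float = 0.25
    pretrain_epochs: int = 100
    finetune_epochs: int = 100
    fixed_prior: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.beta1, self.beta2, self.beta3) <= 0:
            raise ValueError("beta weights must be > 0")
        if not 0 < self.ema_decay < 1:
            raise ValueError("ema_decay must lie in (0, 1)")

    @property
    def tau(self) -> float:
        return 1.0 / (1.0 - self.ema_decay)


@dataclass
class LatentPosterior:
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.sd) <= 0):
            raise ValueError("posterior sd must be positive")


@dataclass
class RunningPrior:
    """Exponentially smoothed marginal: Gaussian per latent dimension, or
    categorical for the gate/label marginals."""

    kind: str  # "gaussian" | "categorical"
    mean: np.ndarray = None
    sd: np.ndarray = None
    probs: np.ndarray = None
    tau: float = 2000.0

    @staticmethod
    def gaussian(dim: int, tau: float) -> "RunningPrior":
        return RunningPrior("gaussian", mean=np.zeros(dim), sd=np.ones(dim),
                            tau=tau)

    @staticmethod
    def categorical(dim: int, tau: float) -> "RunningPrior":
        return RunningPrior("categorical", probs=np.full(dim, 1.0 / dim),
                            tau=tau)

    def update(self, observation):
        """new = (1 - 1/tau) * old + (1/tau) * observed."""
        a = 1.0 / self.tau
        if self.kind == "gaussian":
            obs_mean, obs_sd = observation
            self.mean = (1 - a) * self.mean + a * np.asarray(obs_mean)
            self.sd = (1 - a) * self.sd + a * np.asarray(obs_sd)
        else:
            p = (1 - a) * self.probs + a * np.asarray(observation)
            self.probs = p / p.sum()
        return self


def gaussian_kl(post: LatentPosterior, prior: RunningPrior) -> float:
    """Closed-form KL between diagonal Gaussians, summed over dimensions
    (averaged over a batch of posteriors when `post` is batched)."""
    if prior.kind != "gaussian":
        raise ValueError("prior must be Gaussian")
    if np.any(prior.sd <= 0):
        raise ValueError("prior sd must be positive")
    m1, s1 = np.atleast_2d(post.mean), np.atleast_2d(post.sd)
    m2, s2 = prior.mean, prior.sd
    kl = (np.log(s2 / s1) + (s1**2 + (m1 - m2) ** 2) / (2 * s2**2) - 0.5)
    return float(kl.sum(axis=-1).mean())


def categorical_kl(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> float:
    """KL(p || q) for probability vectors (batched p averaged)."""
    p = np.atleast_2d(p)
    val = np.where(p > 0, p * (np.log(p + eps) - np.log(q + eps)), 0.0)
    return float(val.sum(axis=-1).mean())


def avae_loss(x: np.ndarray, reconstruction: np.ndarray,
              post: LatentPosterior, prior: RunningPrior,
              beta1: float) -> float:
    """Variational objective for one modality (minimized form).

    Gaussian reconstruction negative log-likelihood up to constants
    (0.5 * squared error, batch-averaged) plus the KL of the posterior
    from the prior weighted by 1/beta1.
    """
    if beta1 <= 0:
        raise ValueError("beta1 must be > 0")
    x, rec = np.atleast_2d(x), np.atleast_2d(reconstruction)
    nll = 0.5 * float(((x - rec) ** 2).sum(axis=-1).mean())
    return nll + (1.0 / beta1) * gaussian_kl(post, prior)


def info_constrained_loss(task_loss_value: float,
                          gate_probs: np.ndarray, gate_marginal: np.ndarray,
                          label_probs: np.ndarray, label_marginal: np.ndarray,
                          beta2: float, beta3: float) -> float:
    """Task loss plus the gate/label information-processing penalties.

    Each penalty is the categorical KL of the network's output
    distribution against its running marginal, weighted by 1/beta.
    """
    if min(beta2, beta3) <= 0:
        raise ValueError("beta weights must be > 0")
    out = float(task_loss_value)
    out += (1.0 / beta2) * categorical_kl(gate_probs, gate_marginal)
    if label_probs is not None:
        out += (1.0 / beta3) * categorical_kl(label_probs, label_marginal)
    return out


# -- Tensor-valued penalty terms (training path) ----------------------------

def _kl_gauss_t(mean: Tensor, sd: Tensor, prior: RunningPrior) -> Tensor:
    pm = Tensor(prior.mean, requires_grad=False)
    ps = Tensor(prior.sd, requires_grad=False)
    kl = (ps.log() - sd.log()
          + (sd * sd + (mean - pm) * (mean - pm)) / (2.0 * ps * ps)
          - 0.5)
    return kl.sum(axis=1).mean()


def _kl_cat_t(p: Tensor, q: np.ndarray, eps: float = 1e-12) -> Tensor:
    logq = Tensor(np.log(q + eps), requires_grad=False)
    pc = p.clip_min(eps)
    return (p * (pc.log() - logq)).sum(axis=1).mean()


class AdaptiveVAESystem:
    """Per-modality adaptive-prior VAEs + fusion gate + inference head."""

    def __init__(self, cfg: ModelConfig, ssl: SSLConfig):
        self.cfg, self.ssl = cfg, ssl
        rng = np.random.default_rng(ssl.seed if ssl.seed else cfg.seed)
        self.encoders = {
            mod: Encoder(rng, cfg, mod, out_dim=2 * cfg.eta,
                         dense_activation=None)
            for mod in cfg.modalities
        }
        for enc in self.encoders.values():
            # start near-deterministic: softplus(-3) ~ 0.05 keeps early
            # latent sampling noise well below the latent means, avoiding
            # the noisy-gradient phase before the posterior widens
            enc.dense.b.data[cfg.eta:] = -3.0
        self.decoders = {mod: Decoder(rng, cfg, mod) for mod in cfg.modalities}
        self.gate = GateFusion(rng, cfg.n, cfg.eta)
        self.head = InferenceHead(rng, cfg)
        self.priors = {
            mod: RunningPrior.gaussian(cfg.eta, ssl.tau)
            for mod in cfg.modalities
        }
        self.gate_prior = RunningPrior.categorical(cfg.n * cfg.eta, ssl.tau)
        self.label_prior = (
            RunningPrior.categorical(cfg.n_classes, ssl.tau)
            if cfg.task == "classification" else None
        )
        self._rng = rng
        self.classes_ = None
        self.trained_ = False

    # -- plumbing ----------------------------------------------------------
    def modality_weights(self, mod):
        return self.encoders[mod].params + self.decoders[mod].params

    def parameters(self):
        out = []
        for mod in self.cfg.modalities:
            out += self.modality_weights(mod)
        return out + self.gate.params + self.head.params

    # -- stochastic encoding ----------------------------------------------
    def encode_stochastic(self, x, modality: str, sample: bool = True,
                          rng=None):
        """Posterior (mean, soft-plus sd) and a reparameterized sample."""
        xt = x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)
        raw = self.encoders[modality](xt)
        eta = self.cfg.eta
        mean, sd = raw[:, :eta], raw[:, eta:].softplus()
        if sample:
            eps = (rng or self._rng).standard_normal(mean.shape)
            h = mean + sd * Tensor(eps, requires_grad=False)
        else:
            h = mean
        return LatentPosterior(mean.data, sd.data), (mean, sd, h)

    # -- training objective ------------------------------------------------
    def _batch_loss(self, X_clean: dict, y: np.ndarray, corrupt: bool = True):
        cfg, ssl = self.cfg, self.ssl
        latents, terms = [], []
        post_stats = {}
        for mod in cfg.modalities:
            x = X_clean[mod]
            xin = (x + self._rng.normal(0.0, cfg.noise_sd, x.shape)
                   if corrupt else x)
            _, (mean, sd, h) = self.encode_stochastic(xin, mod)
            recon = self.decoders[mod](h)
            nll = 0.5 * reconstruction_loss(x, recon)
            kl = _kl_gauss_t(mean, sd, self.priors[mod])
            terms.append(nll + (1.0 / ssl.beta1) * kl)
            latents.append(h)
            # marginal observation: moment-match the batch mixture of
            # posteriors — its variance is E[sd^2] + Var(means)
            # (law of total variance), not the average posterior sd
            mu = mean.data.mean(axis=0)
            var = (sd.data**2).mean(axis=0) + mean.data.var(axis=0)
            post_stats[mod] = (mu, np.sqrt(var))
        w, fused = self.gate(latents)
        out = self.head(fused, train=True, rng=self._rng)
        loss = task_loss(out, y, cfg.task)
        for t in terms:
            loss = loss + t
        loss = loss + (1.0 / ssl.beta2) * _kl_cat_t(w, self.gate_prior.probs)
        if self.label_prior is not None:
            loss = loss + (1.0 / ssl.beta3) * _kl_cat_t(
                out, self.label_prior.probs
            )
        obs = {
            "posteriors": post_stats,
            "gate": w.data.mean(axis=0),
            "label": out.data.mean(axis=0) if self.label_prior is not None else None,
        }
        return loss, obs

    def _update_priors(self, obs):
        if not self.ssl.fixed_prior:
            for mod, stats in obs["posteriors"].items():
                self.priors[mod].update(stats)
        self.gate_prior.update(obs["gate"])
        if self.label_prior is not None:
            self.label_prior.update(obs["label"])

    def encode_targets(self, y):
        if self.cfg.task == "regression":
            return np.asarray(y, dtype=float)
        if self.classes_ is None:
            self.classes_ = np.unique(y)
        return one_hot(np.searchsorted(self.classes_, y), self.cfg.n_classes)

    def fit(self, ds: SegmentDataset, epochs: int | None = None,
            corrupt: bool = True, lr: float | None = None) -> list:
        cfg = self.cfg
        targets = self.encode_targets(ds.y)
        opt = Adam(self.parameters(), lr if lr is not None else cfg.lr)
        history = []
        for epoch in range(epochs if epochs is not None else
                           self.ssl.pretrain_epochs):
            losses = []
            for idx in stratified_batches(self._rng, ds.y, cfg.batch_size):
                Xb = {mod: x[idx] for mod, x in ds.X.items()}
                loss, obs = self._batch_loss(Xb, targets[idx], corrupt)
                opt.zero_grad()
                loss.backward()
                opt.step()
                self._update_priors(obs)
                losses.append(float(loss.data))
            history.append({"epoch": epoch, "loss": float(np.mean(losses))})
        self.trained_ = True
        return history

    # -- prediction --------------------------------------------------------
    def forward_deterministic(self, X: dict):
        latents = []
        for mod in self.cfg.modalities:
            _, (_, _, h) = self.encode_stochastic(X[mod], mod, sample=False)
            latents.append(h)
        w, fused = self.gate(latents)
        return self.head(fused, train=False), w

    def predict(self, X: dict) -> np.ndarray:
        out, _ = self.forward_deterministic(X)
        if self.cfg.task == "classification":
            idx = out.data.argmax(axis=1)
            return self.classes_[idx] if self.classes_ is not None else idx
        return out.data

    # -- generation and fine-tuning -----------------------------------------
    def generate(self, K: int, rng=None) -> SegmentDataset:
        """Draw K latents per modality from the priors, decode, pseudo-label.

        The pseudo-label comes from the inference head applied to the fused
        drawn latents (hard argmax for classification, raw scalar for
        regression). Samples are tagged provenance="generated".
        """
        if not self.trained_:
            raise RuntimeError("generate() requires a trained model")
        rng = rng or self._rng
        cfg = self.cfg
        latents, X = [], {}
        for mod in cfg.modalities:
            prior = self.priors[mod]
            h = rng.normal(prior.mean, prior.sd, (K, cfg.eta))
            ht = Tensor(h, requires_grad=False)
            X[mod] = self.decoders[mod](ht).data
            latents.append(ht)
        w, fused = self.gate(latents)
        out = self.head(fused, train=False)
        if cfg.task == "classification":
            idx = out.data.argmax(axis=1)
            y = (self.classes_[idx] if self.classes_ is not None else idx)
        else:
            y = out.data
        return SegmentDataset(
            X=X, y=np.asarray(y),
            subject=np.full(K, "<generated>", dtype=object),
            shift=np.zeros(K, dtype=int),
            provenance=np.full(K, "generated", dtype=object),
        )

    #: fine-tuning learning-rate factor: pseudo-labeled prior draws are a
    #: noisier supervision signal than real data, so the fine-tuning phase
    #: runs an order of magnitude gentler than the pretext phase
    FINETUNE_LR_FACTOR = 0.1

    def fine_tune(self, generated: SegmentDataset,
                  epochs: int | None = None) -> list:
        """Phase (iii): continue training on ONLY self-generated samples."""
        if not np.all(generated.provenance == "generated"):
            raise ValueError("fine-tuning set must contain only "
                             "self-generated samples")
        return self.fit(generated,
                        epochs=(epochs if epochs is not None
                                else self.ssl.finetune_epochs),
                        lr=self.cfg.lr * self.FINETUNE_LR_FACTOR)


def pseudo_label(model, X: dict) -> np.ndarray:
    """Hard model-assigned labels for a batch of multi-channel windows."""
    out, _ = model.forward_deterministic(X)
    if model.cfg.task == "classification":
        idx = out.data.argmax(axis=1)  # ties resolve to the lowest index
        return model.classes_[idx] if model.classes_ is not None else idx
    return out.data


def ssl_run(ds: SegmentDataset, cfg: ModelConfig, ssl: SSLConfig,
            folds=None, scale: bool = True) -> list:
    """Three-phase self-supervised procedure under LOSO cross-validation.

    `ds` must be the non-augmented cohort. Returns one FoldResult per fold;
    `folds` restricts evaluation to a subset of the LOSO folds (by test
    subject id) for scaled experiments.
    """
    all_folds = loso_folds(ds)
    if folds is not None:
        keep = set(folds)
        all_folds = [f for f in all_folds if f[1] in keep]
    results = []
    for k, (train_subjects, test_subject) in enumerate(all_folds):
        train = ds.select(ds.subject != test_subject)
        test = ds.select(ds.subject == test_subject)
        if scale:
            train, stats = normalize(train)
            test = apply_scaling(test, stats)
        fold_seed = (ssl.seed * 100003 + k * 1009 + 1) % (2**31)
        model = AdaptiveVAESystem(cfg, replace(ssl, seed=fold_seed))
        model.fit(train)
        K = math.ceil(ssl.gen_fraction * len(train))
        if K == 0:
            log.warning("fold %s: K = 0 generated samples; fine-tuning skipped",
                        test_subject)
        else:
            generated = model.generate(K)
            model.fine_tune(generated)
        preds = model.predict(test.X)
        results.append(FoldResult(
            test_subject, test.y, preds, task=cfg.task,
            classes=model.classes_,
        ))
    return results
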