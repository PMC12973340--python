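"""β-normalized variational autoencoder on concatenated zFC‖zSC vectors.

A fully-connected VAE implemented in NumPy: linear layers with leaky-ReLU
activations, a Gaussian latent space with closed-form KL divergence, the
reparameterization trick during training, and Adam optimization with
hand-derived backpropagation (verified against finite differences in the test
suite).  The KL weight is β normalized by latent size M over input size N
(β_norm = β·M/N), so the per-feature reconstruction error and the KL term are
on comparable scales across input sizes.

Loss reduction is the mean over batch and features for the reconstruction
term and the mean over batch of the per-sample KL summed over latent
dimensions; the total is ``mse + beta_norm * kl``.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .io import ConnectivityMatrix
from .preprocess import ModelVector, NormalizationParams, devectorize_upper, tanh_denormalize


class VAETrainingError(RuntimeError):
    pass


@dataclass
class VAEConfig:
    encoder_widths: tuple[int, ...] = (512, 256, 128)
    decoder_widths: tuple[int, ...] = (128, 256, 512)
    latent_dim: int = 8
    beta: float = 1.0
    leaky_slope: float = 0.01
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 2000
    patience: int = 750
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.encoder_widths + self.decoder_widths):
            raise ValueError("layer widths must be strictly positive")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")

    def beta_norm(self, input_length: int) -> float:
        """β·M/N — recomputed whenever the input length changes."""
        return self.beta * self.latent_dim / float(input_length)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["encoder_widths"] = list(self.encoder_widths)
        d["decoder_widths"] = list(self.decoder_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VAEConfig":
        d = dict(d)
        d["encoder_widths"] = tuple(d["encoder_widths"])
        d["decoder_widths"] = tuple(d["decoder_widths"])
        return cls(**d)


def _leaky(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, a, slope * a)


def _leaky_grad(a: np.ndarray, slope: float) -> np.ndarray:
    return np.where(a > 0, 1.0, slope)


@dataclass
class TrainedVAE:
    """Weights, the configuration used, and the training history."""

    config: VAEConfig
    input_length: int
    params: dict[str, np.ndarray]
    history: list[dict] = field(default_factory=list)
    provenance: str = "healthy_trained"

    @property
    def beta_norm(self) -> float:
        return self.config.beta_norm(self.input_length)

    def copy(self) -> "TrainedVAE":
        return TrainedVAE(
            config=replace(self.config),
            input_length=self.input_length,
            params={k: v.copy() for k, v in self.params.items()},
            history=copy.deepcopy(self.history),
            provenance=self.provenance,
        )

    def save(self, path) -> None:
        path = Path(path)
        meta = {"config": self.config.to_dict(), "input_length": self.input_length,
                "provenance": self.provenance, "history": self.history}
        np.savez(path.with_suffix(".npz"), **self.params)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, path) -> "TrainedVAE":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        with np.load(path.with_suffix(".npz")) as data:
            params = {k: data[k] for k in data.files}
        return cls(config=VAEConfig.from_dict(meta["config"]),
                   input_length=meta["input_length"], params=params,
                   history=meta["history"], provenance=meta["provenance"])


def build_vae(config: VAEConfig, input_length: int) -> TrainedVAE:
    """Untrained model with deterministic He-normal initialization."""
    if input_length <= 0:
        raise ValueError("input_length must be positive")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 97])))
    params: dict[str, np.ndarray] = {}

    def init(name: str, fan_in: int, fan_out: int) -> None:
        params[f"{name}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out))
        params[f"{name}_b"] = np.zeros(fan_out)

    widths = (input_length,) + tuple(config.encoder_widths)
    for i in range(len(config.encoder_widths)):
        init(f"enc{i}", widths[i], widths[i + 1])
    init("mu", widths[-1], config.latent_dim)
    init("logvar", widths[-1], config.latent_dim)
    dwidths = (config.latent_dim,) + tuple(config.decoder_widths) + (input_length,)
    for i in range(len(dwidths) - 1):
        init(f"dec{i}", dwidths[i], dwidths[i + 1])
    return TrainedVAE(config=replace(config), input_length=input_length, params=params)


def _encode(model: TrainedVAE, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    cfg = model.config
    cache = []
    h = x
    for i in range(len(cfg.encoder_widths)):
        a = h @ model.params[f"enc{i}_W"] + model.params[f"enc{i}_b"]
        cache.append((h, a))
        h = _leaky(a, cfg.leaky_slope)
    mu = h @ model.params["mu_W"] + model.params["mu_b"]
    logvar = h @ model.params["logvar_W"] + model.params["logvar_b"]
    cache.append((h, None))
    return mu, logvar, cache


def _decode(model: TrainedVAE, z: np.ndarray) -> tuple[np.ndarray, list]:
    cfg = model.config
    cache = []
    h = z
    n_dec = len(cfg.decoder_widths) + 1
    for i in range(n_dec):
        a = h @ model.params[f"dec{i}_W"] + model.params[f"dec{i}_b"]
        cache.append((h, a))
        h = _leaky(a, cfg.leaky_slope) if i < n_dec - 1 else a  # final layer linear
    return h, cache


def encode_mean(model: TrainedVAE, x: np.ndarray) -> np.ndarray:
    """Latent means (no sampling) for one vector or a batch."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu, _, _ = _encode(model, x)
    return mu


def forward(model: TrainedVAE, x: np.ndarray, eps: np.ndarray | None = None):
    """Full pass; ``eps=None`` means deterministic (z = latent mean)."""
    mu, logvar, enc_cache = _encode(model, x)
    z = mu if eps is None else mu + eps * np.exp(0.5 * logvar)
    xhat, dec_cache = _decode(model, z)
    return xhat, mu, logvar, z, enc_cache, dec_cache


def vae_loss(x: np.ndarray, xhat: np.ndarray, mu: np.ndarray, logvar: np.ndarray,
             beta_norm: float) -> tuple[float, float, float]:
    """(total, reconstruction MSE, KL) with KL in closed form per sample."""
    recon = float(np.mean((xhat - x) ** 2))
    kl = float(np.mean(0.5 * np.sum(np.exp(logvar) + mu ** 2 - 1.0 - logvar, axis=1)))
    total = recon + beta_norm * kl
    if not np.isfinite(total):
        raise VAETrainingError("non-finite loss")
    return total, recon, kl


def _backward(model: TrainedVAE, x, xhat, mu, logvar, z, eps, enc_cache, dec_cache
              ) -> dict[str, np.ndarray]:
    cfg = model.config
    b, n = x.shape
    beta_norm = model.beta_norm
    grads: dict[str, np.ndarray] = {}

    # decoder
    delta = 2.0 * (xhat - x) / (b * n)
    n_dec = len(cfg.decoder_widths) + 1
    for i in reversed(range(n_dec)):
        h_in, a = dec_cache[i]
        if i < n_dec - 1:
            delta = delta * _leaky_grad(a, cfg.leaky_slope)
        grads[f"dec{i}_W"] = h_in.T @ delta
        grads[f"dec{i}_b"] = delta.sum(axis=0)
        delta = delta @ model.params[f"dec{i}_W"].T
    dz = delta

    # latent heads: reparameterized sample + KL term
    std = np.exp(0.5 * logvar)
    dmu = dz + beta_norm * mu / b
    dlogvar = (0.0 if eps is None else dz * eps * 0.5 * std) \
        + beta_norm * 0.5 * (np.exp(logvar) - 1.0) / b
    h_top = enc_cache[-1][0]
    grads["mu_W"] = h_top.T @ dmu
    grads["mu_b"] = dmu.sum(axis=0)
    grads["logvar_W"] = h_top.T @ dlogvar
    grads["logvar_b"] = dlogvar.sum(axis=0)
    delta = dmu @ model.params["mu_W"].T + dlogvar @ model.params["logvar_W"].T

    # encoder
    for i in reversed(range(len(cfg.encoder_widths))):
        h_in, a = enc_cache[i]
        delta = delta * _leaky_grad(a, cfg.leaky_slope)
        grads[f"enc{i}_W"] = h_in.T @ delta
        grads[f"enc{i}_b"] = delta.sum(axis=0)
        delta = delta @ model.params[f"enc{i}_W"].T
    return grads


def loss_and_grads(model: TrainedVAE, x: np.ndarray, eps: np.ndarray | None):
    """One forward/backward pass; used by training and by gradient checks."""
    xhat, mu, logvar, z, enc_cache, dec_cache = forward(model, x, eps)
    losses = vae_loss(x, xhat, mu, logvar, model.beta_norm)
    grads = _backward(model, x, xhat, mu, logvar, z, eps, enc_cache, dec_cache)
    return losses, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _eval_loss(model: TrainedVAE, x: np.ndarray) -> tuple[float, float, float]:
    xhat, mu, logvar, *_ = forward(model, x, eps=None)
    return vae_loss(x, xhat, mu, logvar, model.beta_norm)


def train_vae(train_x: np.ndarray, val_x: np.ndarray, config: VAEConfig,
              model: TrainedVAE | None = None, provenance: str = "healthy_trained",
              ) -> TrainedVAE:
    """Mini-batch Adam training with early stopping on total validation loss.

    Validation uses the latent mean (deterministic); training samples one
    reparameterized latent per input.  The returned model carries the weights
    of the best validation epoch and the full loss history.
    """
    train_x = np.asarray(train_x, dtype=float)
    val_x = np.asarray(val_x, dtype=float)
    if train_x.ndim != 2 or val_x.ndim != 2 or not len(train_x) or not len(val_x):
        raise VAETrainingError("train and validation splits must be non-empty 2-D arrays")
    if train_x.shape[1] != val_x.shape[1]:
        raise VAETrainingError("train/validation input lengths differ")
    n = train_x.shape[1]
    if model is None:
        model = build_vae(config, n)
    else:
        model = model.copy()
        model.config = replace(config)
        if model.input_length != n:
            raise VAETrainingError("model input length does not match data")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, 11])))
    opt = _Adam(model.params, config.learning_rate)
    # the untrained/incoming weights count as the epoch -1 baseline, so the
    # returned model is never worse on validation than its starting point
    best_val = _eval_loss(model, val_x)[0]
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = -1
    history: list[dict] = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_x))
        tot = rec = kl = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = train_x[idx]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            try:
                (t, r, k), grads = loss_and_grads(model, xb, eps)
            except VAETrainingError as err:
                raise VAETrainingError(f"divergence at epoch {epoch}: {err}") from err
            opt.step(model.params, grads)
            tot += t * len(idx)
            rec += r * len(idx)
            kl += k * len(idx)
        m = len(train_x)
        val_tot, val_rec, val_kl = _eval_loss(model, val_x)
        history.append({
            "epoch": epoch, "train_total": tot / m, "train_recon": rec / m,
            "train_kl": kl / m, "val_total": val_tot, "val_recon": val_rec,
            "val_kl": val_kl,
        })
        if val_tot < best_val:
            best_val = val_tot
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.params = best_params
    model.history = model.history + history
    model.provenance = provenance
    return model


def fine_tune(model: TrainedVAE, patient_train: np.ndarray, patient_val: np.ndarray,
              config_override: dict | None = None) -> TrainedVAE:
    """Transfer learning: continue optimization from the healthy weights on a
    small patient split at a reduced learning rate (default 1e-4)."""
    if model.provenance != "healthy_trained":
        raise VAETrainingError("fine_tune expects a healthy-trained model")
    patient_train = np.asarray(patient_train, dtype=float)
    patient_val = np.asarray(patient_val, dtype=float)
    if patient_train.size == 0 or patient_val.size == 0:
        raise VAETrainingError("empty patient split")
    overrides = {"learning_rate": 1e-4}
    overrides.update(config_override or {})
    cfg = replace(model.config, **overrides)
    if cfg.max_epochs == 0:
        tuned = model.copy()
        tuned.provenance = "fine_tuned"
        return tuned
    return train_vae(patient_train, patient_val, cfg, model=model,
                     provenance="fine_tuned")


def reconstruct_subject(model: TrainedVAE, vector: ModelVector,
                        params: NormalizationParams | None = None,
                        ) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Deterministic reconstruction (latent mean, no sampling).

    The decoder output is split into its FC and SC halves, devectorized,
    mapped back through tanh, and post-processed: reconstructed SC values
    below zero are set to 0.  SC stays in the power-law-transformed domain.
    """
    if vector.values.size != model.input_length:
        raise VAETrainingError("model vector length does not match model input")
    x = vector.values[None, :]
    xhat, *_ = forward(model, x, eps=None)
    half = model.input_length // 2
    p = vector.n_parcels
    fc = tanh_denormalize(devectorize_upper(xhat[0, :half], p))
    sc = tanh_denormalize(devectorize_upper(xhat[0, half:], p))
    sc[sc < 0] = 0.0
    return (
        ConnectivityMatrix(vector.subject_id, "FC_recon", fc),
        ConnectivityMatrix(vector.subject_id, "SC_recon", sc),
    )


def reconstruction_quality(orig: np.ndarray, recon: np.ndarray
                           ) -> tuple[float, float]:
    """(MSE, Spearman rank correlation) over the strict upper triangle."""
    orig = np.asarray(orig, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if orig.shape != recon.shape:
        raise ValueError("shape mismatch")
    iu = np.triu_indices(orig.shape[0], k=1)
    a, b = orig[iu], recon[iu]
    mse = float(np.mean((a - b) ** 2))
    if np.all(a == a[0]) or np.all(b == b[0]):
        return mse, float("nan")
    rho = float(stats.spearmanr(a, b).statistic)
    return mse, rho
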