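"""Scale-Invariant Residuals Transform (SIRT).

An autoencoder is trained to reconstruct non-negative spectral features under
the Itakura-Saito (IS) divergence

    D_IS(x || x_hat) = sum_i  x_i / x_hat_i  -  ln(x_i / x_hat_i)  -  1 ,

a scale-invariant Bregman divergence matched to non-negative spectral data
with multiplicative, gamma-distributed residuals.  Because the IS noise model
is multiplicative (x = x_hat o eps), the elementwise reconstruction residual

    x_tilde = x / x_hat

is itself a non-negative feature vector: the SIRT-transformed features.  With
a small latent dimension the autoencoder captures only the principal sources
of spectral variance (e.g. broadband subject-specific gains), so dividing by
the reconstruction removes those nuisance directions while leaving the bulk
of the variance — including any group-contrast signal — in the residuals.

Architecture: a fully connected encoder (hidden dims 128/64/32 by default,
each followed by batch normalization and dropout), a softplus non-negativity
activation on the latent code, and a non-negative matrix-factorization
decoder (a k x p component matrix, kept non-negative by a softplus
parameterization).  Both halves are trained jointly by decoupled-weight-decay
Adam on the IS objective; the parameterization from the epoch with the lowest
training loss is checkpointed.  The network and its gradients are implemented
directly in NumPy.

Training batches are drawn by age inverse-propensity weighting so the sampled
(age-bin x class) distribution is approximately independent, preventing the
model from absorbing age-class confounding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

__all__ = [
    "SIRTConfig",
    "SIRTModel",
    "is_divergence",
    "train_sirt",
    "sirt_transform",
    "age_propensity_weights",
    "age_propensity_batches",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    """Inverse of softplus for y > 0."""
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-np.maximum(y, 1e-12)))


@dataclass
class SIRTConfig:
    """Hyperparameters of the SIRT autoencoder.

    Defaults: latent dimension 15, encoder hidden layers (128, 64, 32) with
    dropout probability 0.7, 10 training epochs, encoder weight decay 0.1,
    and Adam with learning rate 1e-3.  ``reconstruction_floor`` keeps the
    reconstruction strictly positive so the residual ratio is always defined.
    """

    latent_dim: int = 15
    encoder_hidden_dims: tuple = (128, 64, 32)
    dropout_p: float = 0.7
    epochs: int = 10
    encoder_weight_decay: float = 0.1
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    reconstruction_floor: float = 1e-6
    input_floor: float = 1e-12
    decoder_prefit: bool = False
    age_propensity_batching: bool = True
    n_age_bins: int = 10

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.reconstruction_floor <= 0:
            raise ValueError("reconstruction_floor must be positive")


def is_divergence(x: np.ndarray, xhat: np.ndarray,
                  eps_floor: float = 1e-12) -> float:
    """Itakura-Saito divergence, summed over coordinates.

    Non-negative, zero iff x == xhat, and exactly scale invariant:
    D(c*x || c*xhat) = D(x || xhat) for any c > 0.  Zero coordinates of x are
    floored at ``eps_floor`` so the log term stays finite.
    """
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError("x and xhat must have the same shape")
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    if np.any(xhat <= 0):
        raise ValueError("xhat must be strictly positive")
    r = np.maximum(x, eps_floor) / xhat
    return float(np.sum(r - np.log(r) - 1.0))


# ---------------------------------------------------------------------------
# network parameters and forward/backward passes


def _init_params(input_dim: int, config: SIRTConfig, x_scale: np.ndarray,
                 rng: np.random.Generator) -> tuple:
    """Initialize parameters and batch-norm buffers.

    The decoder component matrix is scaled so the initial reconstruction is on
    the order of the per-feature data mean, which keeps the first IS-gradient
    steps well conditioned.
    """
    params: dict = {}
    dims = [input_dim, *config.encoder_hidden_dims]
    for i in range(len(config.encoder_hidden_dims)):
        fan_in = dims[i]
        bound = 1.0 / np.sqrt(fan_in)
        params[f"W{i}"] = rng.uniform(-bound, bound, (dims[i], dims[i + 1]))
        params[f"b{i}"] = rng.uniform(-bound, bound, dims[i + 1])
        params[f"gamma{i}"] = np.ones(dims[i + 1])
        params[f"beta{i}"] = np.zeros(dims[i + 1])
    bound = 1.0 / np.sqrt(dims[-1])
    params["Wz"] = rng.uniform(-bound, bound, (dims[-1], config.latent_dim))
    params["bz"] = rng.uniform(-bound, bound, config.latent_dim)
    # softplus(0) = ln 2, so the fresh latent code is ~ln 2 per component
    target = np.maximum(x_scale, config.input_floor) / (
        np.log(2.0) * config.latent_dim)
    params["V"] = _softplus_inv(
        target[None, :] * rng.uniform(0.5, 1.5, (config.latent_dim,
                                                 input_dim)))
    buffers = {}
    for i, d in enumerate(config.encoder_hidden_dims):
        buffers[f"rm{i}"] = np.zeros(d)
        buffers[f"rv{i}"] = np.ones(d)
    return params, buffers


def _encode(X: np.ndarray, params: dict, buffers: dict, config: SIRTConfig,
            train: bool, rng: np.random.Generator | None = None):
    """Forward pass through the encoder; returns (H, cache)."""
    cache = {"inputs": [], "z": [], "xn": [], "bn_out": [], "masks": [],
             "mu": [], "var": []}
    H = X
    n_hidden = len(config.encoder_hidden_dims)
    for i in range(n_hidden):
        cache["inputs"].append(H)
        Z = H @ params[f"W{i}"] + params[f"b{i}"]
        cache["z"].append(Z)
        if train:
            mu = Z.mean(axis=0)
            var = Z.var(axis=0)
            buffers[f"rm{i}"] = ((1 - _BN_MOMENTUM) * buffers[f"rm{i}"]
                                 + _BN_MOMENTUM * mu)
            m = max(Z.shape[0], 2)
            buffers[f"rv{i}"] = ((1 - _BN_MOMENTUM) * buffers[f"rv{i}"]
                                 + _BN_MOMENTUM * var * m / (m - 1))
        else:
            mu = buffers[f"rm{i}"]
            var = buffers[f"rv{i}"]
        xn = (Z - mu) / np.sqrt(var + _BN_EPS)
        out = params[f"gamma{i}"] * xn + params[f"beta{i}"]
        cache["mu"].append(mu)
        cache["var"].append(var)
        cache["xn"].append(xn)
        cache["bn_out"].append(out)
        R = np.maximum(out, 0.0)
        if train and config.dropout_p > 0:
            mask = (rng.random(R.shape) >= config.dropout_p) / (
                1.0 - config.dropout_p)
        else:
            mask = None
        cache["masks"].append(mask)
        H = R * mask if mask is not None else R
    cache["latent_in"] = H
    Zz = H @ params["Wz"] + params["bz"]
    cache["zz"] = Zz
    Hcode = _softplus(Zz)
    return Hcode, cache


def _forward(X: np.ndarray, params: dict, buffers: dict, config: SIRTConfig,
             train: bool, rng: np.random.Generator | None = None):
    H, cache = _encode(X, params, buffers, config, train, rng)
    Wdec = _softplus(params["V"])
    Xhat = H @ Wdec + config.reconstruction_floor
    cache["H"] = H
    cache["Wdec"] = Wdec
    return Xhat, cache


def _backward(X: np.ndarray, Xhat: np.ndarray, params: dict, cache: dict,
              config: SIRTConfig) -> dict:
    """Gradients of the mean elementwise IS divergence w.r.t. all parameters."""
    n_el = X.size
    Xs = np.maximum(X, config.input_floor)
    dXhat = (1.0 / Xhat - Xs / Xhat ** 2) / n_el

    grads: dict = {}
    H = cache["H"]
    grads["V"] = (H.T @ dXhat) * expit(params["V"])
    dH = dXhat @ cache["Wdec"].T
    dZz = dH * expit(cache["zz"])
    grads["Wz"] = cache["latent_in"].T @ dZz
    grads["bz"] = dZz.sum(axis=0)
    dOut = dZz @ params["Wz"].T

    for i in reversed(range(len(config.encoder_hidden_dims))):
        mask = cache["masks"][i]
        if mask is not None:
            dOut = dOut * mask
        dBN = dOut * (cache["bn_out"][i] > 0)
        xn = cache["xn"][i]
        grads[f"gamma{i}"] = (dBN * xn).sum(axis=0)
        grads[f"beta{i}"] = dBN.sum(axis=0)
        m = X.shape[0]
        var = cache["var"][i]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        dxn = dBN * params[f"gamma{i}"]
        # standard batch-norm backward (batch statistics are functions of Z)
        Zc = cache["z"][i] - cache["mu"][i]
        dvar = np.sum(dxn * Zc, axis=0) * (-0.5) * inv_std ** 3
        dmu = (np.sum(dxn, axis=0) * (-inv_std)
               + dvar * np.mean(-2.0 * Zc, axis=0))
        dZ = dxn * inv_std + dvar * 2.0 * Zc / m + dmu / m
        grads[f"W{i}"] = cache["inputs"][i].T @ dZ
        grads[f"b{i}"] = dZ.sum(axis=0)
        dOut = dZ @ params[f"W{i}"].T
    return grads


class _AdamW:
    """Adam with decoupled weight decay on the encoder weight matrices."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 decayed_keys: set, frozen_keys: set = frozenset(),
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.decayed = decayed_keys
        self.frozen = frozen_keys
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            if k in self.frozen:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k in self.decayed and self.wd > 0:
                params[k] -= self.lr * self.wd * params[k]


# ---------------------------------------------------------------------------
# age inverse-propensity batching


def age_propensity_weights(ages: np.ndarray, labels: np.ndarray,
                           n_bins: int = 10) -> np.ndarray:
    """Sampling weights inversely proportional to P(class | age bin).

    Bins are deciles of the pooled age distribution.  Under these weights the
    sampled joint (age-bin x class) distribution is approximately independent.
    Bins containing a single class fall back to unweighted sampling (with a
    warning), since the propensity of the missing class is zero there.
    """
    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    edges = np.unique(np.quantile(ages, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.digitize(ages, edges[1:-1]), 0, len(edges) - 2)
    w = np.ones(len(ages))
    for b in np.unique(bins):
        in_bin = bins == b
        for cls in np.unique(labels):
            sel = in_bin & (labels == cls)
            if not sel.any():
                warnings.warn(
                    f"age bin {b} contains a single class; falling back to "
                    "unweighted sampling within that bin", stacklevel=2)
                break
            w[sel] = in_bin.sum() / sel.sum()  # 1 / P(class | bin)
        else:
            continue
        w[in_bin] = 1.0
    return w / w.sum()


def age_propensity_batches(sample_ages, labels, batch_size: int, seed: int,
                           n_batches: int | None = None,
                           n_bins: int = 10) -> list:
    """Deterministic sequence of weighted-with-replacement index batches."""
    ages = np.asarray(sample_ages, dtype=float)
    labels = np.asarray(labels)
    n = len(ages)
    if n_batches is None:
        n_batches = max(1, int(np.ceil(n / batch_size)))
    w = age_propensity_weights(ages, labels, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=(n_batches, batch_size), p=w)
    return [idx[i] for i in range(n_batches)]


# ---------------------------------------------------------------------------
# model object and training


@dataclass
class SIRTModel:
    """A trained SIRT autoencoder: encoder + non-negative NMF decoder."""

    params: dict
    buffers: dict
    config: SIRTConfig
    input_dim: int
    training_log: list
    best_epoch: int

    @property
    def decoder_components(self) -> np.ndarray:
        """The non-negative k x p component matrix W."""
        return _softplus(self.params["V"])

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Non-negative latent codes (inference mode)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self._check_dim(X)
        H, _ = _encode(X, self.params, self.buffers, self.config, train=False)
        return H

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Strictly positive reconstruction x_hat = code @ W + floor."""
        H = self.encode(X)
        return H @ self.decoder_components + self.config.reconstruction_floor

    def _check_dim(self, X: np.ndarray) -> None:
        if X.shape[-1] != self.input_dim:
            raise ValueError(
                f"input dimension {X.shape[-1]} does not match the model's "
                f"{self.input_dim}")

    def save(self, path) -> None:
        """Checkpoint to ``<path>`` (.npz) with a JSON sidecar ``<path>.json``."""
        arrays = {f"p_{k}": v for k, v in self.params.items()}
        arrays.update({f"b_{k}": v for k, v in self.buffers.items()})
        np.savez(path, **arrays)
        sidecar = {
            "config": asdict(self.config),
            "input_dim": self.input_dim,
            "training_log": self.training_log,
            "best_epoch": self.best_epoch,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SIRTModel":
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        cfg_dict = sidecar["config"]
        cfg_dict["encoder_hidden_dims"] = tuple(cfg_dict["encoder_hidden_dims"])
        config = SIRTConfig(**cfg_dict)
        data = np.load(str(path) if str(path).endswith(".npz")
                       else str(path) + ".npz")
        params = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
        buffers = {k[2:]: data[k] for k in data.files if k.startswith("b_")}
        return cls(params=params, buffers=buffers, config=config,
                   input_dim=sidecar["input_dim"],
                   training_log=sidecar["training_log"],
                   best_epoch=sidecar["best_epoch"])


def _as_arrays(samples, ages, labels):
    """Accept a feature matrix or a list of SpectralSample objects."""
    if hasattr(samples, "ndim"):
        X = np.asarray(samples, dtype=float)
        y = None if labels is None else np.asarray(labels)
    else:
        X = np.stack([s.x for s in samples]).astype(float)
        y = np.array([s.label for s in samples])
        if labels is not None:
            y = np.asarray(labels)
    a = None if ages is None else np.asarray(ages, dtype=float)
    return X, a, y


def train_sirt(samples, ages=None, labels=None,
               config: SIRTConfig | None = None) -> SIRTModel:
    """Train the SIRT autoencoder on non-negative feature vectors.

    Parameters
    ----------
    samples : (n, p) array or list of SpectralSample
        Non-negative spectral features.
    ages, labels : arrays, optional
        Per-sample ages (months) and binary labels.  When both are given and
        ``config.age_propensity_batching`` is on, batches are drawn by age
        inverse-propensity weighting; otherwise plain shuffled batches.
    config : SIRTConfig

    Returns
    -------
    SIRTModel
        The parameterization from the epoch with minimum training loss
        (checkpointing never sees anything but the training data).
        ``training_log`` holds the per-epoch mean elementwise IS divergence.
    """
    config = config or SIRTConfig()
    X, a, y = _as_arrays(samples, ages, labels)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("no training samples provided")
    if np.any(X < 0):
        raise ValueError("SIRT input features must be non-negative")
    n, p = X.shape

    rng = np.random.default_rng(config.seed)
    params, buffers = _init_params(p, config, X.mean(axis=0), rng)

    if config.decoder_prefit:
        params["V"] = _softplus_inv(_prefit_nmf_components(X, config))
    decayed = ({f"W{i}" for i in range(len(config.encoder_hidden_dims))}
               | {"Wz"})
    frozen = {"V"} if config.decoder_prefit else set()
    opt = _AdamW(params, config.learning_rate, config.encoder_weight_decay,
                 decayed_keys=decayed, frozen_keys=frozen)

    use_propensity = (config.age_propensity_batching and a is not None
                      and y is not None and len(np.unique(y)) == 2)
    batch_size = min(config.batch_size, n)
    n_batches = max(1, int(np.ceil(n / batch_size)))

    training_log: list = []
    best_loss = np.inf
    best_epoch = -1
    best_params = None
    best_buffers = None
    for epoch in range(config.epochs):
        if use_propensity:
            batches = age_propensity_batches(
                a, y, batch_size, seed=int(rng.integers(2 ** 31)),
                n_batches=n_batches, n_bins=config.n_age_bins)
        else:
            perm = rng.permutation(n)
            batches = [perm[i * batch_size:(i + 1) * batch_size]
                       for i in range(n_batches)]
            if len(batches) > 1 and len(batches[-1]) < 2:
                batches[-2] = np.concatenate(batches[-2:])
                batches.pop()
        total = 0.0
        count = 0
        for idx in batches:
            xb = X[idx]
            Xhat, cache = _forward(xb, params, buffers, config, train=True,
                                   rng=rng)
            r = np.maximum(xb, config.input_floor) / Xhat
            loss = float(np.mean(r - np.log(r) - 1.0))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite SIRT training loss at epoch {epoch}; "
                    "consider lowering the learning rate or rescaling inputs")
            grads = _backward(xb, Xhat, params, cache, config)
            opt.step(params, grads)
            total += loss * xb.shape[0]
            count += xb.shape[0]
        epoch_loss = total / count
        training_log.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_epoch = epoch
            best_params = {k: v.copy() for k, v in params.items()}
            best_buffers = {k: v.copy() for k, v in buffers.items()}

    return SIRTModel(params=best_params, buffers=best_buffers, config=config,
                     input_dim=p, training_log=training_log,
                     best_epoch=best_epoch)


def _prefit_nmf_components(X: np.ndarray, config: SIRTConfig) -> np.ndarray:
    """Component matrix from a multiplicative-update IS-divergence NMF fit."""
    from sklearn.decomposition import NMF

    nmf = NMF(n_components=config.latent_dim, beta_loss="itakura-saito",
              solver="mu", init="random", max_iter=200,
              random_state=config.seed)
    nmf.fit(np.maximum(X, config.input_floor))
    return np.maximum(nmf.components_, config.input_floor)


def sirt_transform(model: SIRTModel, x: np.ndarray) -> np.ndarray:
    """SIRT-transformed features x_tilde = x / x_hat (elementwise).

    The reconstruction runs in inference mode (dropout off, batch norm on
    running statistics) and is floored strictly above zero, so the ratio is
    always finite and non-negative.  The identity x_tilde * x_hat = x holds
    exactly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    model._check_dim(X)
    if np.any(X < 0):
        raise ValueError("SIRT input features must be non-negative")
    Xhat = model.reconstruct(X)
    out = X / Xhat
    return out[0] if single else out
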