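"""Variational autoencoder for CNV overlap features.

Model
-----
The encoder maps an overlap-feature vector x (scaled to [0, 1]) through up
to three ReLU hidden layers to the mean and log-variance of a diagonal
Gaussian approximate posterior Q(z|x); the decoder mirrors the encoder and
ends in a sigmoid.  Layer widths follow the square-root rule: each hidden
layer has ceil(sqrt(previous width)) units, and the latent dimension is
ceil(sqrt(last hidden width)), never below 2.

Training minimizes the negative evidence lower bound

    L = E_q[recon(x, x̂)] + KL( N(mu, diag(exp(logvar))) || N(0, I) )

with the reparameterization z = mu + exp(logvar/2) ⊙ ε, ε ~ N(0, I), using
Adam.  The reconstruction term is per-sample summed squared error averaged
over the batch (binary cross-entropy is available for binarized features).
Everything — train/validation split, weight init, ε draws, dropout — flows
from a single seed, so runs are bit-reproducible.
"""

from __future__ import annotations

import io as _io
import json
import math
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "VAEParams",
    "plan_architecture",
    "kl_divergence",
    "elbo_loss",
    "train_vae",
    "save_checkpoint",
    "load_checkpoint",
]

LATENT_FLOOR = 2


@dataclass(frozen=True)
class ArchitectureSpec:
    input_dim: int
    hidden_sizes: tuple[int, ...]
    latent_dim: int
    activation: str = "relu"  # "relu" | "linear"
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the method's stated choices
    (Adam, learning rate 1e-3, multiplicative decay 1 = constant rate,
    at most 10,000 epochs, 80/20 train/validation split)."""

    learning_rate: float = 1e-3
    lr_decay: float = 1.0
    max_epochs: int = 10_000
    batch_size: int = 128
    train_fraction: float = 0.8
    seed: int = 0
    early_stop_patience: int = 50
    kl_warmup_epochs: int = 50  # KL weight anneals 0 -> 1 to avoid posterior collapse
    free_bits: float = 0.25  # per-dim KL floor (nats); no KL gradient below it
    recon_loss: str = "mse"  # "mse" | "bce"
    sparsity: float = 0.0  # fraction of encoder weights masked to zero (0 = off)
    weight_decay: float = 0.0  # decoupled (AdamW-style) decay on weight matrices
    l1_penalty: float = 0.0  # proximal L1 on the input->hidden weights (feature selection)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class VAEParams:
    """All weight arrays; encoder weights are (in, out) so x @ W + b."""

    arch: ArchitectureSpec
    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    W_mu: np.ndarray
    b_mu: np.ndarray
    W_lv: np.ndarray
    b_lv: np.ndarray
    dec_W: list[np.ndarray]
    dec_b: list[np.ndarray]
    enc_mask: Optional[list[np.ndarray]] = None  # static sparsity masks

    def copy(self) -> "VAEParams":
        return VAEParams(
            arch=self.arch,
            enc_W=[w.copy() for w in self.enc_W],
            enc_b=[b.copy() for b in self.enc_b],
            W_mu=self.W_mu.copy(),
            b_mu=self.b_mu.copy(),
            W_lv=self.W_lv.copy(),
            b_lv=self.b_lv.copy(),
            dec_W=[w.copy() for w in self.dec_W],
            dec_b=[b.copy() for b in self.dec_b],
            enc_mask=None if self.enc_mask is None else [m.copy() for m in self.enc_mask],
        )


def plan_architecture(
    input_dim: int, max_hidden: int = 3, dropout_rate: float = 0.1
) -> ArchitectureSpec:
    """Derive layer widths from the input size by the square-root rule.

    Repeatedly applies ceil(sqrt(.)) for up to ``max_hidden`` hidden
    layers, stopping early once a width would stop strictly decreasing or
    fall below the latent floor of 2; the latent dimension is
    ceil(sqrt(last hidden width)), floored at 2.
    """
    if input_dim < 4:
        raise ValueError("input_dim must be at least 4")
    sizes: list[int] = []
    prev = input_dim
    for _ in range(max_hidden):
        nxt = math.isqrt(prev - 1) + 1  # ceil(sqrt(prev)) for prev >= 2
        if nxt >= prev or nxt < LATENT_FLOOR:
            break
        sizes.append(nxt)
        prev = nxt
    latent = max(LATENT_FLOOR, math.isqrt(prev - 1) + 1)
    return ArchitectureSpec(
        input_dim=input_dim,
        hidden_sizes=tuple(sizes),
        latent_dim=latent,
        dropout_rate=dropout_rate,
    )


LOGVAR_BIAS_INIT = -3.0


def init_params(
    arch: ArchitectureSpec, rng: np.random.Generator, sparsity: float = 0.0
) -> VAEParams:
    """He-normal initialization; decoder mirrors the encoder widths.

    The log-variance head bias starts at -3 (posterior sigma ~ 0.22) so the
    reparameterization noise does not drown the latent mean at the start of
    training — with a unit-variance initial posterior the decoder learns to
    ignore z and the encoder never receives gradient (posterior collapse).
    """
    dims = [arch.input_dim, *arch.hidden_sizes]
    enc_W, enc_b = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        enc_W.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        enc_b.append(np.zeros(fan_out))
    last = dims[-1]
    W_mu = rng.normal(0.0, math.sqrt(1.0 / last), size=(last, arch.latent_dim))
    W_lv = rng.normal(0.0, math.sqrt(1.0 / last), size=(last, arch.latent_dim))
    dec_dims = [arch.latent_dim, *reversed(arch.hidden_sizes), arch.input_dim]
    dec_W, dec_b = [], []
    for fan_in, fan_out in zip(dec_dims[:-1], dec_dims[1:]):
        dec_W.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        dec_b.append(np.zeros(fan_out))
    mask = None
    if sparsity > 0:
        mask = [(rng.random(w.shape) >= sparsity).astype(float) for w in enc_W]
        enc_W = [w * m for w, m in zip(enc_W, mask)]
    return VAEParams(
        arch=arch,
        enc_W=enc_W,
        enc_b=[b for b in enc_b],
        W_mu=W_mu,
        b_mu=np.zeros(arch.latent_dim),
        W_lv=W_lv,
        b_lv=np.full(arch.latent_dim, LOGVAR_BIAS_INIT),
        dec_W=dec_W,
        dec_b=dec_b,
        enc_mask=mask,
    )


def _act(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(a, 0.0)
    if kind == "linear":
        return a
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (a > 0).astype(a.dtype)
    return np.ones_like(a)


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def encode(
    params: VAEParams,
    X: np.ndarray,
    dropout_masks: Optional[list[np.ndarray]] = None,
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray, np.ndarray]:
    """Forward pass of the encoder.

    Returns (pre-activations, activations, mu, logvar); ``activations[0]``
    is the input.  ``dropout_masks`` are inverted-dropout multipliers for
    each hidden layer (training only).
    """
    act = params.arch.activation
    hs = [X]
    pre = []
    h = X
    for li, (W, b) in enumerate(zip(params.enc_W, params.enc_b)):
        a = h @ W + b
        pre.append(a)
        h = _act(a, act)
        if dropout_masks is not None:
            h = h * dropout_masks[li]
        hs.append(h)
    mu = h @ params.W_mu + params.b_mu
    logvar = h @ params.W_lv + params.b_lv
    return pre, hs, mu, logvar


def decode(
    params: VAEParams, z: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Forward pass of the decoder: hidden ReLUs, sigmoid output."""
    act = params.arch.activation
    ds = [z]
    pre = []
    h = z
    n = len(params.dec_W)
    for li, (W, b) in enumerate(zip(params.dec_W, params.dec_b)):
        a = h @ W + b
        pre.append(a)
        h = _act(a, act) if li < n - 1 else _sigmoid(a)
        ds.append(h)
    return pre, ds, h


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag(exp(logvar))) || N(0, I) ).

    For a batch (2-D inputs) the mean over rows is returned.  Closed form
    per dimension: (mu² + exp(logvar) − 1 − logvar) / 2; always ≥ 0.
    """
    mu = np.asarray(mu, dtype=float)
    logvar = np.asarray(logvar, dtype=float)
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise ValueError("non-finite mu/logvar")
    per = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=-1)
    return float(np.mean(per))


def elbo_loss(
    X: np.ndarray,
    params: VAEParams,
    eps: Optional[np.ndarray] = None,
    recon_loss: str = "mse",
) -> tuple[float, float, float]:
    """(total, reconstruction, kl) for a batch.

    ``eps`` supplies the reparameterization noise; ``None`` means the
    deterministic mode z = mu.  Reconstruction is summed over features and
    averaged over the batch; total = reconstruction + kl, the negative of
    the variational lower bound up to the data-likelihood constant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.arch.input_dim:
        raise ValueError("batch width does not match the architecture input size")
    _, _, mu, logvar = encode(params, X)
    z = mu if eps is None else mu + np.exp(0.5 * logvar) * eps
    _, _, xhat = decode(params, z)
    if recon_loss == "mse":
        recon = float(np.mean(np.sum((xhat - X) ** 2, axis=1)))
    elif recon_loss == "bce":
        p = np.clip(xhat, 1e-12, 1 - 1e-12)
        recon = float(np.mean(np.sum(-(X * np.log(p) + (1 - X) * np.log1p(-p)), axis=1)))
    else:
        raise ValueError(f"unknown recon_loss {recon_loss!r}")
    kl = kl_divergence(mu, logvar)
    return recon + kl, recon, kl


def _elbo_grads(
    params: VAEParams,
    X: np.ndarray,
    eps: np.ndarray,
    dropout_masks: Optional[list[np.ndarray]],
    recon_loss: str,
    beta: float = 1.0,
    free_bits: float = 0.0,
) -> tuple[float, dict]:
    """One forward/backward pass on recon + beta·KL; returns (loss, grads).

    ``beta`` < 1 implements KL warm-up.  ``free_bits`` masks the KL
    gradient for latent dimensions whose batch-mean KL is below the floor,
    preventing posterior collapse; the reported loss uses the same
    weighting as the gradients.
    """
    act = params.arch.activation
    B = X.shape[0]
    enc_pre, hs, mu, logvar = encode(params, X, dropout_masks)
    sig = np.exp(0.5 * logvar)
    z = mu + sig * eps
    dec_pre, ds, xhat = decode(params, z)

    if recon_loss == "mse":
        recon = float(np.mean(np.sum((xhat - X) ** 2, axis=1)))
        dxhat = 2.0 * (xhat - X) / B
        da_out = dxhat * xhat * (1.0 - xhat)
    else:  # bce with sigmoid output: d/da = (xhat - X)/B
        p = np.clip(xhat, 1e-12, 1 - 1e-12)
        recon = float(np.mean(np.sum(-(X * np.log(p) + (1 - X) * np.log1p(-p)), axis=1)))
        da_out = (xhat - X) / B
    kl = kl_divergence(mu, logvar)
    total = recon + beta * kl

    g_dec_W = [np.zeros_like(w) for w in params.dec_W]
    g_dec_b = [np.zeros_like(b) for b in params.dec_b]
    da = da_out
    for li in range(len(params.dec_W) - 1, -1, -1):
        h_in = ds[li]
        g_dec_W[li] = h_in.T @ da
        g_dec_b[li] = da.sum(axis=0)
        if li > 0:
            dh = da @ params.dec_W[li].T
            da = dh * _act_grad(dec_pre[li - 1], act)
    # after the loop `da` holds the gradient w.r.t. dec_pre[0]
    dz = da @ params.dec_W[0].T

    # KL gradients (mean over batch), masked per dim by the free-bits floor
    kl_per_dim = 0.5 * np.mean(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=0)
    active = (kl_per_dim >= free_bits).astype(float)
    dmu = beta * active * mu / B
    dlv = beta * active * 0.5 * (np.exp(logvar) - 1.0) / B
    # reparameterization path
    dmu = dmu + dz
    dlv = dlv + dz * eps * 0.5 * sig

    h_last = hs[-1]
    g_W_mu = h_last.T @ dmu
    g_b_mu = dmu.sum(axis=0)
    g_W_lv = h_last.T @ dlv
    g_b_lv = dlv.sum(axis=0)

    dh = dmu @ params.W_mu.T + dlv @ params.W_lv.T
    g_enc_W = [np.zeros_like(w) for w in params.enc_W]
    g_enc_b = [np.zeros_like(b) for b in params.enc_b]
    for li in range(len(params.enc_W) - 1, -1, -1):
        if dropout_masks is not None:
            dh = dh * dropout_masks[li]
        da_e = dh * _act_grad(enc_pre[li], act)
        g_enc_W[li] = hs[li].T @ da_e
        g_enc_b[li] = da_e.sum(axis=0)
        if li > 0:
            dh = da_e @ params.enc_W[li].T
    if params.enc_mask is not None:
        g_enc_W = [g * m for g, m in zip(g_enc_W, params.enc_mask)]
    grads = {
        "enc_W": g_enc_W,
        "enc_b": g_enc_b,
        "W_mu": g_W_mu,
        "b_mu": g_b_mu,
        "W_lv": g_W_lv,
        "b_lv": g_b_lv,
        "dec_W": g_dec_W,
        "dec_b": g_dec_b,
    }
    return total, grads


class AdamState:
    """Adam moments for an arbitrary nested list-of-arrays parameter set."""

    def __init__(
        self,
        arrays: list[np.ndarray],
        lr: float,
        beta1=0.9,
        beta2=0.999,
        eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        # decoupled decay applies to matrices only, never to bias vectors
        self.decay_mask = [a.ndim > 1 for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for a, g, m, v, dec in zip(arrays, grads, self.m, self.v, self.decay_mask):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            a -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if dec and self.weight_decay > 0:
                a *= 1.0 - self.lr * self.weight_decay


def _flatten(params: VAEParams) -> list[np.ndarray]:
    return [
        *params.enc_W,
        *params.enc_b,
        params.W_mu,
        params.b_mu,
        params.W_lv,
        params.b_lv,
        *params.dec_W,
        *params.dec_b,
    ]


def _flatten_grads(g: dict) -> list[np.ndarray]:
    return [
        *g["enc_W"],
        *g["enc_b"],
        g["W_mu"],
        g["b_mu"],
        g["W_lv"],
        g["b_lv"],
        *g["dec_W"],
        *g["dec_b"],
    ]


def train_val_split(
    n: int,
    train_fraction: float,
    rng: np.random.Generator,
    y: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled train/validation index split, stratified by y when given."""
    if y is None:
        order = rng.permutation(n)
        n_train = max(1, int(round(train_fraction * n)))
        n_train = min(n_train, n - 1)
        return order[:n_train], order[n_train:]
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(train_fraction * len(idx))))
        k = min(k, len(idx) - 1) if len(idx) > 1 else 1
        train_idx.append(idx[:k])
        val_idx.append(idx[k:])
    tr = np.concatenate(train_idx)
    va = np.concatenate(val_idx)
    return tr[rng.permutation(len(tr))], va[rng.permutation(len(va))]


def train_vae(
    X: np.ndarray,
    config: TrainConfig,
    arch: Optional[ArchitectureSpec] = None,
    y: Optional[np.ndarray] = None,
) -> tuple[VAEParams, dict]:
    """Fit the VAE by reparameterized Adam descent on the negative ELBO.

    Labels ``y`` are *not* used in the loss; when given they only stratify
    the 80/20 train/validation split.  Early stopping watches the
    validation total loss with ``early_stop_patience``; the parameters
    achieving the best validation loss are returned along with a trace
    ``{"train": [...], "val": [...], "recon": [...], "kl": [...]}``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(config.seed)
    if arch is None:
        arch = plan_architecture(X.shape[1])
    params = init_params(arch, rng, sparsity=config.sparsity)
    tr_idx, va_idx = train_val_split(X.shape[0], config.train_fraction, rng, y=y)
    Xtr, Xva = X[tr_idx], X[va_idx]
    opt = AdamState(_flatten(params), lr=config.learning_rate, weight_decay=config.weight_decay)
    best = params.copy()
    best_val = math.inf
    wait = 0
    trace = {"train": [], "val": [], "recon": [], "kl": []}
    n_tr = Xtr.shape[0]
    p_drop = arch.dropout_rate
    for epoch in range(config.max_epochs):
        opt.lr = config.learning_rate * (config.lr_decay**epoch)
        beta = (
            min(1.0, (epoch + 1) / config.kl_warmup_epochs)
            if config.kl_warmup_epochs > 0
            else 1.0
        )
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        for lo in range(0, n_tr, config.batch_size):
            batch = Xtr[order[lo : lo + config.batch_size]]
            eps = rng.standard_normal((batch.shape[0], arch.latent_dim))
            masks = None
            if p_drop > 0 and arch.hidden_sizes:
                masks = [
                    (rng.random((batch.shape[0], h)) >= p_drop) / (1 - p_drop)
                    for h in arch.hidden_sizes
                ]
            loss, grads = _elbo_grads(
                params,
                batch,
                eps,
                masks,
                config.recon_loss,
                beta=beta,
                free_bits=config.free_bits,
            )
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})"
                )
            opt.step(_flatten(params), _flatten_grads(grads))
            ep_loss += loss * batch.shape[0]
        val_total, val_recon, val_kl = elbo_loss(Xva, params, eps=None, recon_loss=config.recon_loss)
        trace["train"].append(ep_loss / n_tr)
        trace["val"].append(val_total)
        trace["recon"].append(val_recon)
        trace["kl"].append(val_kl)
        if val_total < best_val - 1e-9:
            best_val = val_total
            best = params.copy()
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    return best, trace


# ---------------------------------------------------------------------------
# Checkpoint format: a zip archive containing `meta.json` (architecture,
# training config, array manifest) and one little-endian .npy per array.
# Any language with JSON + npy readers can reload it.
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def _collect_arrays(params: VAEParams, extra: Optional[dict] = None) -> dict[str, np.ndarray]:
    arrays: dict[str, np.ndarray] = {}
    for i, (w, b) in enumerate(zip(params.enc_W, params.enc_b)):
        arrays[f"enc_W_{i}"] = w
        arrays[f"enc_b_{i}"] = b
    arrays["W_mu"] = params.W_mu
    arrays["b_mu"] = params.b_mu
    arrays["W_lv"] = params.W_lv
    arrays["b_lv"] = params.b_lv
    for i, (w, b) in enumerate(zip(params.dec_W, params.dec_b)):
        arrays[f"dec_W_{i}"] = w
        arrays[f"dec_b_{i}"] = b
    if params.enc_mask is not None:
        for i, m in enumerate(params.enc_mask):
            arrays[f"enc_mask_{i}"] = m
    if extra:
        arrays.update(extra)
    return arrays


def save_checkpoint(
    path: str | Path,
    params: VAEParams,
    config: Optional[TrainConfig] = None,
    head: Optional[dict] = None,
) -> None:
    """Write a versioned single-file checkpoint (zip of npy + meta.json).

    ``head`` may carry classifier-head arrays, e.g. ``{"head_w": ...,
    "head_b": ...}``.
    """
    extra = {k: np.asarray(v) for k, v in (head or {}).items()}
    arrays = _collect_arrays(params, extra)
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "arch": asdict(params.arch),
        "config": asdict(config) if config is not None else None,
        "n_enc_layers": len(params.enc_W),
        "n_dec_layers": len(params.dec_W),
        "has_mask": params.enc_mask is not None,
        "arrays": sorted(arrays),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for name, arr in arrays.items():
            buf = _io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            zf.writestr(f"{name}.npy", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[VAEParams, Optional[TrainConfig], dict]:
    """Reload a checkpoint; returns (params, train config, head arrays)."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta["format_version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
        arrays = {
            name: np.load(_io.BytesIO(zf.read(f"{name}.npy")))
            for name in meta["arrays"]
        }
    arch_d = dict(meta["arch"])
    arch_d["hidden_sizes"] = tuple(arch_d["hidden_sizes"])
    arch = ArchitectureSpec(**arch_d)
    n_enc, n_dec = meta["n_enc_layers"], meta["n_dec_layers"]
    params = VAEParams(
        arch=arch,
        enc_W=[arrays[f"enc_W_{i}"] for i in range(n_enc)],
        enc_b=[arrays[f"enc_b_{i}"] for i in range(n_enc)],
        W_mu=arrays["W_mu"],
        b_mu=arrays["b_mu"],
        W_lv=arrays["W_lv"],
        b_lv=arrays["b_lv"],
        dec_W=[arrays[f"dec_W_{i}"] for i in range(n_dec)],
        dec_b=[arrays[f"dec_b_{i}"] for i in range(n_dec)],
        enc_mask=(
            [arrays[f"enc_mask_{i}"] for i in range(n_enc)] if meta["has_mask"] else None
        ),
    )
    config = TrainConfig(**meta["config"]) if meta["config"] else None
    head = {
        k: arrays[k]
        for k in meta["arrays"]
        if not (
            k.startswith(("enc_W_", "enc_b_", "dec_W_", "dec_b_", "enc_mask_"))
            or k in ("W_mu", "b_mu", "W_lv", "b_lv")
        )
    }
    return params, config, head
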