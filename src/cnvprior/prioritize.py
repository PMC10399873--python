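"""Semi-supervised training and the weight-product gene score.

Phase 1 (``pretrain``) fits the VAE without labels on the pooled CNV
features of every available disorder.  Phase 2 (``finetune``) discards the
decoder, attaches a sigmoid classifier head to the latent mean and trains
with binary cross-entropy against the case/control labels — either jointly
with the encoder (default) or with the encoder frozen, which reduces to
logistic regression on the latent codes.

The per-feature score is the product of all encoder-path weight matrices
with the classifier head,

    w_final = W_1 · W_2 · … · W_mu · w_head   (I × 1),

with biases and activations omitted: a first-order linear attribution of
the pre-sigmoid case logit to each input feature.  Positive entries mark
case-associated gene × dosage features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import FeatureKey, FeatureMatrix
from .vae import (
    AdamState,
    TrainConfig,
    VAEParams,
    _act_grad,
    _sigmoid,
    encode,
    train_val_split,
    train_vae,
)

logger = logging.getLogger(__name__)


@dataclass
class ClassifierHead:
    """Sigmoid readout on the latent mean: p(case) = σ(mu · w + b)."""

    weights: np.ndarray  # (latent_dim,)
    bias: float

    def predict_proba(self, mu: np.ndarray) -> np.ndarray:
        return _sigmoid(mu @ self.weights + self.bias)


@dataclass
class GeneResult:
    key: FeatureKey
    score: float
    rank: Optional[int]  # 1..n over non-excluded results, None if excluded
    case_ov: int
    control_ov: int
    fisher_p: float
    perm_p: Optional[float] = None
    q_value: Optional[float] = None
    excluded: bool = False
    reason: str = ""


def pretrain(
    matrix: FeatureMatrix | np.ndarray, config: TrainConfig
) -> tuple[VAEParams, dict]:
    """Unsupervised VAE fit on pooled (unlabeled) disorder features."""
    X = matrix.X if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    return train_vae(X, config)


def auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC: P(score_case > score_control) + ½·P(equal)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


FINETUNE_L1_DEFAULT = 1.0


def finetune(
    pretrained: VAEParams,
    matrix: FeatureMatrix,
    config: TrainConfig,
    mode: str = "joint",
    l1_penalty: Optional[float] = None,
) -> tuple[VAEParams, ClassifierHead, dict]:
    """Supervised fine-tuning of the encoder + classifier head.

    ``mode="joint"`` (default) updates encoder weights, mu head and
    classifier head; ``mode="frozen"`` updates the head only (a logistic
    model on the fixed latent means).  The latent code is the mean —
    deterministic, no sampling.  Returns the updated parameters, the head,
    and metrics: per-epoch losses plus held-out (20%) ``accuracy`` and
    rank ``auc``.

    ``l1_penalty`` applies a proximal soft-threshold to the input→hidden
    weight matrix after each Adam step (joint mode): connections to
    features without consistent gradient support across batches are driven
    to exactly zero, restricting the effective number of parameters.  The
    strength is relative to the Adam step size.  ``None`` takes
    ``config.l1_penalty`` if set, else the fine-tuning default of 1.0; pass
    0 to disable.
    """
    if mode not in ("joint", "frozen"):
        raise ValueError(f"unknown finetune mode {mode!r}")
    if l1_penalty is None:
        l1_penalty = config.l1_penalty if config.l1_penalty > 0 else FINETUNE_L1_DEFAULT
    X, y = matrix.X, matrix.y.astype(float)
    if X.shape[1] != pretrained.arch.input_dim:
        raise ValueError(
            f"feature count {X.shape[1]} does not match pretrained input "
            f"size {pretrained.arch.input_dim}"
        )
    if len(np.unique(matrix.y)) < 2:
        raise ValueError("fine-tuning needs both cases and controls")
    rng = np.random.default_rng(config.seed)
    params = pretrained.copy()
    tr, va = train_val_split(X.shape[0], config.train_fraction, rng, y=matrix.y)
    Xtr, ytr, Xva, yva = X[tr], y[tr], X[va], y[va]
    head = ClassifierHead(
        weights=rng.normal(0.0, 1.0 / math.sqrt(params.arch.latent_dim), params.arch.latent_dim),
        bias=0.0,
    )
    # frozen mode: the latent means are fixed, so standardize them for the
    # head fit (their scale can be arbitrarily small) and fold the affine
    # transform back into the returned head afterwards — exact for a
    # linear readout.
    mu_shift = np.zeros(params.arch.latent_dim)
    mu_scale = np.ones(params.arch.latent_dim)
    if mode == "frozen":
        _, _, mu_all, _ = encode(params, Xtr)
        mu_shift = mu_all.mean(axis=0)
        sd = mu_all.std(axis=0)
        mu_scale = np.where(sd > 1e-12, sd, 1.0)

    def pack() -> list[np.ndarray]:
        head_b = np.array([head.bias])
        if mode == "frozen":
            return [head.weights, head_b]
        return [*params.enc_W, *params.enc_b, params.W_mu, params.b_mu, head.weights, head_b]

    arrays = pack()
    opt = AdamState(arrays, lr=config.learning_rate, weight_decay=config.weight_decay)
    act = params.arch.activation
    p_drop = params.arch.dropout_rate if mode == "joint" else 0.0

    def bce(Xb: np.ndarray, yb: np.ndarray) -> float:
        _, _, mu, _ = encode(params, Xb)
        mu = (mu - mu_shift) / mu_scale
        p = np.clip(head.predict_proba(mu), 1e-12, 1 - 1e-12)
        return float(np.mean(-(yb * np.log(p) + (1 - yb) * np.log1p(-p))))

    best_state = [a.copy() for a in arrays]
    best_val = math.inf
    wait = 0
    trace = {"train": [], "val": []}
    n_tr = Xtr.shape[0]
    for epoch in range(config.max_epochs):
        opt.lr = config.learning_rate * (config.lr_decay**epoch)
        order = rng.permutation(n_tr)
        ep = 0.0
        for lo in range(0, n_tr, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            Xb, yb = Xtr[idx], ytr[idx]
            B = Xb.shape[0]
            masks = None
            if p_drop > 0 and params.arch.hidden_sizes:
                masks = [
                    (rng.random((B, h)) >= p_drop) / (1 - p_drop)
                    for h in params.arch.hidden_sizes
                ]
            pre, hs, mu, _ = encode(params, Xb, masks)
            mu = (mu - mu_shift) / mu_scale
            p = np.clip(_sigmoid(mu @ head.weights + head.bias), 1e-12, 1 - 1e-12)
            loss = float(np.mean(-(yb * np.log(p) + (1 - yb) * np.log1p(-p))))
            if not math.isfinite(loss):
                raise FloatingPointError(f"fine-tuning diverged at epoch {epoch}")
            dlogit = (p - yb) / B
            g_head_w = mu.T @ dlogit
            g_head_b = np.array([dlogit.sum()])
            if mode == "frozen":
                opt.step(arrays, [g_head_w, g_head_b])
            else:
                dmu = np.outer(dlogit, head.weights)
                g_W_mu = hs[-1].T @ dmu
                g_b_mu = dmu.sum(axis=0)
                dh = dmu @ params.W_mu.T
                g_enc_W = [np.zeros_like(w) for w in params.enc_W]
                g_enc_b = [np.zeros_like(b) for b in params.enc_b]
                for li in range(len(params.enc_W) - 1, -1, -1):
                    if masks is not None:
                        dh = dh * masks[li]
                    da = dh * _act_grad(pre[li], act)
                    g_enc_W[li] = hs[li].T @ da
                    g_enc_b[li] = da.sum(axis=0)
                    if li > 0:
                        dh = da @ params.enc_W[li].T
                if params.enc_mask is not None:
                    g_enc_W = [g * m for g, m in zip(g_enc_W, params.enc_mask)]
                opt.step(
                    arrays,
                    [*g_enc_W, *g_enc_b, g_W_mu, g_b_mu, g_head_w, g_head_b],
                )
                if l1_penalty > 0:
                    W0 = params.enc_W[0]
                    np.multiply(
                        np.sign(W0),
                        np.maximum(np.abs(W0) - opt.lr * l1_penalty, 0.0),
                        out=W0,
                    )
            head.bias = float(arrays[-1][0])
            ep += loss * B
        val = bce(Xva, yva)
        trace["train"].append(ep / n_tr)
        trace["val"].append(val)
        if val < best_val - 1e-9:
            best_val = val
            best_state = [a.copy() for a in arrays]
            wait = 0
        else:
            wait += 1
            if wait >= config.early_stop_patience:
                break
    for a, b in zip(arrays, best_state):
        a[...] = b
    head.bias = float(arrays[-1][0])
    if mode == "frozen":
        # fold the standardization into the head: w·(mu-m)/s + b = (w/s)·mu + (b - w·m/s)
        folded_w = head.weights / mu_scale
        head.bias = float(head.bias - np.sum(head.weights * mu_shift / mu_scale))
        head.weights[...] = folded_w

    _, _, mu_va, _ = encode(params, Xva)
    p_va = head.predict_proba(mu_va)
    metrics = {
        "train_loss": trace["train"],
        "val_loss": trace["val"],
        "accuracy": float(np.mean((p_va >= 0.5) == (yva == 1))),
        "auc": auc_rank(p_va, yva.astype(int)),
        "n_val": int(len(va)),
    }
    return params, head, metrics


def gene_scores(params: VAEParams, head: ClassifierHead) -> np.ndarray:
    """Weight-product attribution: one signed score per input feature.

    Multiplies encoder weight matrices, the mu head and the classifier
    head into an I×1 column; the shape chain must be compatible.
    """
    chain = [*params.enc_W, params.W_mu]
    w = np.asarray(head.weights, dtype=float).reshape(-1)
    if chain[-1].shape[1] != w.shape[0]:
        raise ValueError("classifier head does not match the latent dimension")
    out = w
    for W in reversed(chain):
        out = W @ out
    return out


def rank_genes(
    scores: np.ndarray,
    counts: pd.DataFrame,
    fisher_p: np.ndarray,
    perm_p: Optional[np.ndarray] = None,
    q_values: Optional[np.ndarray] = None,
    ranking_excluded: Optional[np.ndarray] = None,
    by: str = "score",
    use_abs: bool = False,
) -> list[GeneResult]:
    """Assemble and sort per-feature results.

    Exclusions (never ranked, carried with a reason): zero overlap in both
    arms, and control-dominated features (ControlOV > CaseOV).  The
    remaining features are ordered by signed score descending (``by =
    "score"``, default; ``use_abs`` ranks by magnitude) or by Fisher p
    ascending (``by="fisher"``); ties break by the other key, then
    lexicographically by gene id and dosage so the ordering is total.
    """
    n = len(counts)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != n or len(fisher_p) != n:
        raise ValueError("scores, counts and tests must share the feature axis")
    results: list[GeneResult] = []
    for j in range(n):
        case_ov = int(counts["case_ov"].iloc[j])
        control_ov = int(counts["control_ov"].iloc[j])
        excluded, reason = False, ""
        if case_ov + control_ov == 0:
            excluded, reason = True, "no overlapping CNVs"
        elif control_ov > case_ov:
            excluded, reason = True, "overlaps more controls than cases"
        elif ranking_excluded is not None and bool(ranking_excluded[j]):
            excluded, reason = True, "flagged by prefilter"
        results.append(
            GeneResult(
                key=FeatureKey(str(counts["gene_id"].iloc[j]), str(counts["dosage"].iloc[j])),
                score=float(scores[j]),
                rank=None,
                case_ov=case_ov,
                control_ov=control_ov,
                fisher_p=float(fisher_p[j]),
                perm_p=None if perm_p is None else float(perm_p[j]),
                q_value=None if q_values is None else float(q_values[j]),
                excluded=excluded,
                reason=reason,
            )
        )
    rankable = [r for r in results if not r.excluded]

    def sort_key(r: GeneResult):
        s = abs(r.score) if use_abs else r.score
        if by == "score":
            return (-s, r.fisher_p, r.key.gene_id, r.key.dosage)
        if by == "fisher":
            return (r.fisher_p, -s, r.key.gene_id, r.key.dosage)
        raise ValueError(f"unknown ranking key {by!r}")

    rankable.sort(key=sort_key)
    for i, r in enumerate(rankable, start=1):
        r.rank = i
    ranked = rankable + [r for r in results if r.excluded]
    return ranked


def results_to_frame(results: Sequence[GeneResult]) -> pd.DataFrame:
    """Ranked-results table with the columns of the output TSV."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "gene": [r.key.gene_id for r in results],
            "status": [r.key.dosage for r in results],
            "score": [r.score for r in results],
            "caseOV": [r.case_ov for r in results],
            "controlOV": [r.control_ov for r in results],
            "fisher_p": [r.fisher_p for r in results],
            "perm_p": [r.perm_p for r in results],
            "q_value": [r.q_value for r in results],
            "excluded": [r.excluded for r in results],
            "reason": [r.reason for r in results],
        }
    )
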