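"""Training objectives and the training loop.

The primary objective is binary cross-entropy with logits: per-solver
composite scores in [0, 1] are soft multi-label targets, each solver getting
an independent sigmoid output (several solvers can legitimately score high on
the same complex, so softmax competition would be wrong).  Mean-squared
error, pairwise logistic ranking and a smooth NDCG@3 surrogate are available
as alternatives / auxiliaries via a weighted loss mix.

Every loss returns its value and, on request, the analytic gradient with
respect to the logits; the training loop backpropagates that gradient through
the selector network, updating with Adam under a cosine learning-rate
schedule and early-stopping on held-out relaxed-criterion selection success.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import binomtest

from .data import FoldSplit, Instance, PerformanceTable
from .selector import (
    SelectorConfig,
    SelectorParams,
    backward_batch,
    forward_batch,
    init_params,
)

__all__ = [
    "TrainConfig",
    "TrainReport",
    "bce_loss",
    "mse_loss",
    "pairwise_logistic_loss",
    "ndcg3_loss",
    "exact_ndcg3",
    "mixed_loss",
    "train",
    "paired_test",
]

TAU_TIE = 1e-6


# ---------------------------------------------------------------------------
# losses (vector in, scalar out; optional gradient w.r.t. logits)
# ---------------------------------------------------------------------------

def bce_loss(logits, targets, return_grad: bool = False):
    """Sum over solvers of binary cross-entropy with logits (soft labels ok).

    Computed in the standard overflow-free form
    ``max(z,0) - z*t + log(1 + exp(-|z|))``.
    """
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    if z.shape != t.shape:
        raise ValueError("logits and targets must have the same shape")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("targets must lie in [0, 1]")
    loss = float(np.sum(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    if not return_grad:
        return loss
    return loss, expit(z) - t


def mse_loss(probs, targets, return_grad: bool = False):
    """Mean squared difference; gradient is w.r.t. the first argument."""
    p = np.asarray(probs, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    diff = p - t
    loss = float(np.mean(diff ** 2))
    if not return_grad:
        return loss
    return loss, 2.0 * diff / diff.size


def _mse_on_logits(logits, targets, return_grad: bool = False):
    """MSE between sigmoid(logits) and targets, with gradient w.r.t. logits."""
    z = np.asarray(logits, dtype=float)
    p = expit(z)
    if not return_grad:
        return mse_loss(p, targets)
    loss, dp = mse_loss(p, targets, return_grad=True)
    return loss, dp * p * (1.0 - p)


def pairwise_logistic_loss(logits, targets, tau_tie: float = TAU_TIE,
                           return_grad: bool = False):
    """Mean logistic loss over ordered pairs with a clear target gap.

    Pairs (a, b) with ``targets[a] > targets[b] + tau_tie`` contribute
    ``log(1 + exp(-(logits[a] - logits[b])))``; near-ties are excluded.  With
    no valid pairs the loss is 0 (warning-free degenerate case).
    """
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    if z.size < 2:
        raise ValueError("pairwise loss needs at least 2 solvers")
    grad = np.zeros_like(z)
    total, n_pairs = 0.0, 0
    for a in range(z.size):
        for b in range(z.size):
            if t[a] > t[b] + tau_tie:
                diff = z[a] - z[b]
                total += np.logaddexp(0.0, -diff)
                g = -expit(-diff)
                grad[a] += g
                grad[b] -= g
                n_pairs += 1
    if n_pairs == 0:
        return (0.0, grad) if return_grad else 0.0
    loss = float(total / n_pairs)
    if not return_grad:
        return loss
    return loss, grad / n_pairs


def exact_ndcg3(scores_pred, targets) -> float:
    """Exact NDCG@3 with linear gains; 1.0 when targets are uniform."""
    s = np.asarray(scores_pred, dtype=float)
    t = np.asarray(targets, dtype=float)
    order = np.argsort(-s, kind="stable")
    discounts = 1.0 / np.log2(np.arange(2, min(3, t.size) + 2))
    dcg = float(np.sum(t[order[:3]] * discounts))
    ideal = np.sort(t)[::-1]
    idcg = float(np.sum(ideal[:3] * discounts))
    if idcg == 0.0:
        return 1.0
    return dcg / idcg


def ndcg3_loss(logits, targets, temperature: float = 1.0,
               return_grad: bool = False):
    """1 - smooth NDCG@3 with a sigmoid rank surrogate.

    The approximate rank of solver a is ``1 + sum_b sigmoid((z_b - z_a)/T)``;
    each solver's discounted gain is weighted by a smooth top-3 membership
    indicator ``sigmoid((3.5 - rank)/T)``.  As T -> 0 this recovers exact
    NDCG@3.  Uniform targets give loss 0 (any ordering is ideal).
    """
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    m = z.size
    if m < 3:
        raise ValueError("NDCG@3 needs at least 3 solvers")
    if np.ptp(t) < TAU_TIE:
        return (0.0, np.zeros_like(z)) if return_grad else 0.0
    ideal = np.sort(t)[::-1]
    idcg = float(np.sum(ideal[:3] / np.log2(np.arange(2, 5))))

    T = temperature
    diff = (z[None, :] - z[:, None]) / T        # diff[a, b] = (z_b - z_a)/T
    sig = expit(diff)
    np.fill_diagonal(sig, 0.0)
    rank = 1.0 + sig.sum(axis=1)                # approximate ranks
    memb = expit((3.5 - rank) / T)              # smooth top-3 indicator
    log_term = np.log2(1.0 + rank)
    dcg = float(np.sum(t * memb / log_term))
    raw = 1.0 - dcg / idcg
    loss = float(np.clip(raw, 0.0, 1.0))
    if not return_grad:
        return loss
    if raw < 0.0 or raw > 1.0:                  # clipped: flat region
        return loss, np.zeros_like(z)

    # d(dcg)/d(rank_a)
    dmemb = -memb * (1 - memb) / T
    dwa = t * (dmemb * log_term - memb / ((1.0 + rank) * math.log(2))) / log_term ** 2
    # d(rank_a)/d(z_c): sig' terms; rank_a depends on z_a and all z_b
    sig_prime = sig * (1.0 - sig) / T           # d sig[a,b] / d z_b ; -d/d z_a
    np.fill_diagonal(sig_prime, 0.0)
    # dz[c] = sum_a dwa[a] * d rank_a / d z_c
    dz = sig_prime.T @ dwa - dwa * sig_prime.sum(axis=1)
    return loss, -dz / idcg


def mixed_loss(logits, targets, weights: dict, return_grad: bool = False):
    """Weighted combination of the four objectives on one logit vector."""
    total, grad = 0.0, np.zeros(np.asarray(logits).shape)
    parts = {
        "bce": bce_loss,
        "mse": _mse_on_logits,
        "pairwise": pairwise_logistic_loss,
        "ndcg3": ndcg3_loss,
    }
    for name, fn in parts.items():
        w = weights.get(name, 0.0)
        if w == 0.0:
            continue
        if return_grad:
            val, g = fn(logits, targets, return_grad=True)
            grad += w * g
        else:
            val = fn(logits, targets)
        total += w * val
    return (total, grad) if return_grad else total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimiser and loop settings.

    ``loss_mix`` weights the four objectives; pure BCE is the default.  The
    cosine schedule spans ``max_epochs`` with no restarts; early stopping
    monitors relaxed-criterion selection success on the held-out fold.
    """

    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 20
    loss_mix: dict = field(default_factory=lambda: {"bce": 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        weights = list(self.loss_mix.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("loss_mix needs non-negative weights, at least one positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")


@dataclass
class TrainReport:
    epoch_losses: list[float]
    val_metrics: list[float]
    best_epoch: int
    params: SelectorParams
    config: SelectorConfig
    train_config: TrainConfig


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, arrays, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for arr, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _cosine_lr(base_lr: float, epoch: int, max_epochs: int) -> float:
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max_epochs))


def _selection_success(logits: np.ndarray, success: np.ndarray) -> float:
    """Fraction of instances whose argmax-selected solver succeeded."""
    picks = np.argmax(logits, axis=1)
    return float(np.mean(success[np.arange(len(picks)), picks]))


def train(
    table: PerformanceTable,
    embeddings: dict[str, Instance],
    split: FoldSplit,
    fold: int,
    sel_cfg: SelectorConfig,
    train_cfg: TrainConfig = TrainConfig(),
) -> TrainReport:
    """Fit the selector on one fold's training split.

    Targets are the composite-score rows of ``table``; the held-out fold
    provides the early-stopping validation metric (relaxed-criterion top-1
    selection success).  Best-epoch parameters are restored.  Fully seeded:
    identical inputs and seeds give identical loss trajectories.
    """
    if fold not in range(split.k):
        raise ValueError(f"fold {fold} out of range for k={split.k}")
    row_of = {iid: i for i, iid in enumerate(table.instance_ids)}
    train_idx = np.array([row_of[i] for i in split.train_ids(fold) if i in row_of])
    val_idx = np.array([row_of[i] for i in split.test_ids(fold) if i in row_of])
    if len(train_idx) < train_cfg.batch_size:
        raise ValueError("training split smaller than batch size")

    def gather(idx):
        ids = [table.instance_ids[i] for i in idx]
        prot = [embeddings[i].protein_embedding for i in ids]
        lig = np.stack([embeddings[i].ligand_embedding for i in ids])
        return prot, lig

    prot_tr, lig_tr = gather(train_idx)
    prot_va, lig_va = gather(val_idx)
    targets_tr = table.scores[train_idx]
    val_success = table.success_relaxed[val_idx]

    params = init_params(sel_cfg)
    opt = _Adam([a.shape for a in params.trainable()])
    rng = np.random.default_rng(train_cfg.seed)

    epoch_losses: list[float] = []
    val_metrics: list[float] = []
    best_metric, best_epoch, best_params = -np.inf, -1, params.copy()
    stall = 0

    for epoch in range(train_cfg.max_epochs):
        lr = _cosine_lr(train_cfg.lr, epoch, train_cfg.max_epochs)
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), train_cfg.batch_size):
            batch = order[start:start + train_cfg.batch_size]
            cache: dict = {}
            logits = forward_batch(
                [prot_tr[i] for i in batch], lig_tr[batch],
                params, sel_cfg, training=True, cache=cache,
            )
            if not np.all(np.isfinite(logits)):
                raise FloatingPointError("non-finite logits during training")
            tb = targets_tr[batch]
            dlogits = np.zeros_like(logits)
            batch_loss = 0.0
            for r in range(logits.shape[0]):
                val, g = mixed_loss(logits[r], tb[r], train_cfg.loss_mix, return_grad=True)
                batch_loss += val
                dlogits[r] = g
            if not math.isfinite(batch_loss):
                raise FloatingPointError("non-finite loss during training")
            dlogits /= logits.shape[0]          # mean loss over the mini-batch
            grads = backward_batch(dlogits, params, sel_cfg, cache)
            opt.step(params.trainable(), grads, lr)
            epoch_loss += batch_loss
        epoch_losses.append(epoch_loss / len(order))

        val_logits = forward_batch(prot_va, lig_va, params, sel_cfg, training=False)
        metric = _selection_success(val_logits, val_success)
        val_metrics.append(metric)
        if metric > best_metric:
            best_metric, best_epoch = metric, epoch
            best_params = params.copy()
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.patience:
                break

    return TrainReport(
        epoch_losses=epoch_losses,
        val_metrics=val_metrics,
        best_epoch=best_epoch,
        params=best_params,
        config=sel_cfg,
        train_config=train_cfg,
    )


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def paired_test(success_selected, success_sbs) -> float:
    """Two-sided exact sign test on discordant per-instance success pairs.

    Returns 1.0 when no pair is discordant (no evidence either way).
    """
    a = np.asarray(success_selected, dtype=int)
    b = np.asarray(success_sbs, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 1")
    wins = int(np.sum((a == 1) & (b == 0)))
    losses = int(np.sum((a == 0) & (b == 1)))
    n_disc = wins + losses
    if n_disc == 0:
        return 1.0
    return float(binomtest(wins, n_disc, 0.5, alternative="two-sided").pvalue)
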