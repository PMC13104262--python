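"""The embedding-based solver selector.

Architecture
------------
Instances arrive as a variable-length residue embedding matrix ``x_P``
(n_residues x d_protein, from a protein language model) plus a fixed ligand
vector ``x_L`` (d_ligand, from a chemical language model).  The selector is
the composition ``argmax . g . f``:

* an *attentional pooler* compresses ``x_P`` into one protein vector: each
  head owns a learned query and a linear key projection into a small
  attention space; attention weights are a scaled-dot-product softmax over
  residues, and the head's output is the attention-weighted sum of that
  head's slice of the raw residue vectors (heads concatenate back to
  d_protein).  There is no positional encoding, so pooling is invariant to
  residue order;
* a *fusion* layer concatenates the pooled protein vector with ``x_L`` and
  projects linearly into a joint space;
* a *residual MLP decoder*: a stack of residual blocks (linear -> batch norm
  -> ReLU -> linear, plus skip), whose outputs are all concatenated and
  mapped by a final linear head to one logit per portfolio solver.

Outputs are per-solver sigmoid probabilities (multi-label, no softmax
competition across solvers); selection is the argmax logit with ties broken
to the earliest portfolio index.

Everything is plain numpy with hand-derived gradients (see
:mod:`dockselect.objectives` for the training loop); batch normalisation
uses batch statistics during training and running averages at inference, so
batch-size-1 inference is exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .data import Instance

__all__ = [
    "SelectorConfig",
    "SelectorParams",
    "PredictionVector",
    "init_params",
    "pool_protein",
    "fuse",
    "decode",
    "forward",
    "modality_dropout_forward",
    "forward_batch",
    "describe",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class SelectorConfig:
    """Hyperparameters of the selector.

    Defaults mirror the reference setting: single attention head, joint
    dimension 128, four residual blocks of width 256.  ``d_protein`` must be
    divisible by ``n_heads`` (heads pool disjoint slices of the residue
    vector).
    """

    d_protein: int = 1152
    d_ligand: int = 384
    n_heads: int = 1
    attn_dim: int = 128
    joint_dim: int = 128
    n_resblocks: int = 4
    resblock_width: int = 256
    m_out: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_protein", "d_ligand", "n_heads", "attn_dim", "joint_dim",
                     "n_resblocks", "resblock_width", "m_out"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.d_protein % self.n_heads != 0:
            raise ValueError("d_protein must be divisible by n_heads")

    @property
    def d_head(self) -> int:
        return self.d_protein // self.n_heads


@dataclass
class SelectorParams:
    """All learnable arrays plus batch-norm running statistics."""

    queries: list[np.ndarray]        # per head: (attn_dim,)
    key_proj: list[np.ndarray]       # per head: (attn_dim, d_protein)
    w_fuse: np.ndarray               # (joint_dim, d_protein + d_ligand)
    b_fuse: np.ndarray               # (joint_dim,)
    blocks: list[dict]               # w1, b1, gamma, beta, w2, b2, run_mean, run_var
    w_head: np.ndarray               # (m_out, n_resblocks * joint_dim)
    b_head: np.ndarray               # (m_out,)

    def trainable(self) -> list[np.ndarray]:
        """Flat list of trainable arrays (excludes running statistics)."""
        arrs = list(self.queries) + list(self.key_proj) + [self.w_fuse, self.b_fuse]
        for blk in self.blocks:
            arrs += [blk["w1"], blk["b1"], blk["gamma"], blk["beta"], blk["w2"], blk["b2"]]
        arrs += [self.w_head, self.b_head]
        return arrs

    def copy(self) -> "SelectorParams":
        return SelectorParams(
            queries=[q.copy() for q in self.queries],
            key_proj=[k.copy() for k in self.key_proj],
            w_fuse=self.w_fuse.copy(),
            b_fuse=self.b_fuse.copy(),
            blocks=[{k: v.copy() for k, v in blk.items()} for blk in self.blocks],
            w_head=self.w_head.copy(),
            b_head=self.b_head.copy(),
        )


@dataclass
class PredictionVector:
    """Per-solver prediction for one instance."""

    logits: np.ndarray
    probs: np.ndarray = field(init=False)
    selected: int = field(init=False)
    margin: float = field(init=False)

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=float)
        self.probs = expit(self.logits)
        self.selected = int(np.argmax(self.logits))  # argmax -> earliest tie-break
        top2 = np.sort(self.probs)[::-1][:2]
        self.margin = float(top2[0] - top2[1]) if self.probs.size > 1 else 0.0


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: SelectorConfig) -> SelectorParams:
    """Seeded fan-in-uniform initialisation; biases zero, BN at identity."""
    rng = np.random.default_rng(config.seed)
    queries = [_fan_in_uniform(rng, (config.attn_dim,), config.attn_dim)
               for _ in range(config.n_heads)]
    key_proj = [_fan_in_uniform(rng, (config.attn_dim, config.d_protein), config.d_protein)
                for _ in range(config.n_heads)]
    d_in = config.d_protein + config.d_ligand
    w_fuse = _fan_in_uniform(rng, (config.joint_dim, d_in), d_in)
    b_fuse = np.zeros(config.joint_dim)
    blocks = []
    for _ in range(config.n_resblocks):
        blocks.append({
            "w1": _fan_in_uniform(rng, (config.resblock_width, config.joint_dim), config.joint_dim),
            "b1": np.zeros(config.resblock_width),
            "gamma": np.ones(config.resblock_width),
            "beta": np.zeros(config.resblock_width),
            "w2": _fan_in_uniform(rng, (config.joint_dim, config.resblock_width), config.resblock_width),
            "b2": np.zeros(config.joint_dim),
            "run_mean": np.zeros(config.resblock_width),
            "run_var": np.ones(config.resblock_width),
        })
    d_cat = config.n_resblocks * config.joint_dim
    w_head = _fan_in_uniform(rng, (config.m_out, d_cat), d_cat)
    b_head = np.zeros(config.m_out)
    return SelectorParams(queries, key_proj, w_fuse, b_fuse, blocks, w_head, b_head)


def describe(config: SelectorConfig) -> dict:
    """Parameter count breakdown (trainable arrays only)."""
    params = init_params(config)
    groups = {
        "pooler": sum(a.size for a in params.queries) + sum(a.size for a in params.key_proj),
        "fusion": params.w_fuse.size + params.b_fuse.size,
        "decoder_blocks": sum(
            blk["w1"].size + blk["b1"].size + blk["gamma"].size + blk["beta"].size
            + blk["w2"].size + blk["b2"].size
            for blk in params.blocks
        ),
        "head": params.w_head.size + params.b_head.size,
    }
    groups["total"] = sum(groups.values())
    return groups


# ---------------------------------------------------------------------------
# batched forward / backward (training engine)
# ---------------------------------------------------------------------------

def _pad_batch(protein_mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length residue matrices into (B, L_max, d) plus a mask."""
    lengths = [m.shape[0] for m in protein_mats]
    L = max(lengths)
    d = protein_mats[0].shape[1]
    X = np.zeros((len(protein_mats), L, d))
    mask = np.zeros((len(protein_mats), L), dtype=bool)
    for i, m in enumerate(protein_mats):
        X[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = True
    return X, mask


def forward_batch(
    protein_mats: list[np.ndarray],
    ligand_vecs: np.ndarray,
    params: SelectorParams,
    config: SelectorConfig,
    training: bool = False,
    cache: dict | None = None,
) -> np.ndarray:
    """Batched forward pass; returns (B, m_out) logits.

    With ``training=True`` batch statistics drive the BN layers and running
    averages are updated in place; pass a dict as ``cache`` to retain the
    intermediates needed by :func:`backward_batch`.
    """
    X, mask = _pad_batch([np.asarray(p, dtype=float) for p in protein_mats])
    xL = np.asarray(ligand_vecs, dtype=float)
    B = X.shape[0]
    if X.shape[2] != config.d_protein or xL.shape != (B, config.d_ligand):
        raise ValueError(
            f"embedding dims {X.shape[2]}/{xL.shape[-1]} do not match config "
            f"{config.d_protein}/{config.d_ligand}"
        )
    c = cache if cache is not None else {}
    c["X"], c["mask"] = X, mask

    # attention pooling
    scale = 1.0 / np.sqrt(config.attn_dim)
    pooled_heads, alphas, keys_list = [], [], []
    for h in range(config.n_heads):
        keys = X @ params.key_proj[h].T                     # (B, L, attn)
        att = (keys @ params.queries[h]) * scale            # (B, L)
        att = np.where(mask, att, -np.inf)
        att = att - att.max(axis=1, keepdims=True)
        w = np.exp(att) * mask
        alpha = w / w.sum(axis=1, keepdims=True)            # (B, L)
        sl = slice(h * config.d_head, (h + 1) * config.d_head)
        pooled_heads.append(np.einsum("bl,bld->bd", alpha, X[:, :, sl]))
        alphas.append(alpha)
        keys_list.append(keys)
    pooled = np.concatenate(pooled_heads, axis=1)           # (B, d_protein)
    c["alphas"], c["keys"], c["pooled"] = alphas, keys_list, pooled

    # fusion
    u = np.concatenate([pooled, xL], axis=1)
    z = u @ params.w_fuse.T + params.b_fuse                 # (B, joint)
    c["u"], c["z0"] = u, z

    # residual decoder
    block_caches, block_outs = [], []
    for blk in params.blocks:
        a = z @ blk["w1"].T + blk["b1"]                     # (B, width)
        if training and B > 1:
            mu = a.mean(axis=0)
            var = a.var(axis=0)
            blk["run_mean"] = (1 - _BN_MOMENTUM) * blk["run_mean"] + _BN_MOMENTUM * mu
            unbiased = var * B / (B - 1)
            blk["run_var"] = (1 - _BN_MOMENTUM) * blk["run_var"] + _BN_MOMENTUM * unbiased
        else:
            mu, var = blk["run_mean"], blk["run_var"]
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (a - mu) * inv_std
        y = blk["gamma"] * xhat + blk["beta"]
        r = np.maximum(y, 0.0)
        z_next = z + r @ blk["w2"].T + blk["b2"]
        block_caches.append({
            "z_in": z, "a": a, "xhat": xhat, "inv_std": inv_std, "y": y, "r": r,
            "batch_stats": training and B > 1,
        })
        block_outs.append(z_next)
        z = z_next
    c["block_caches"], c["block_outs"] = block_caches, block_outs

    cat = np.concatenate(block_outs, axis=1)                # (B, K*joint)
    logits = cat @ params.w_head.T + params.b_head
    c["cat"] = cat
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in forward pass")
    return logits


def backward_batch(
    dlogits: np.ndarray,
    params: SelectorParams,
    config: SelectorConfig,
    cache: dict,
) -> list[np.ndarray]:
    """Gradients w.r.t. every trainable array, ordered as ``params.trainable()``."""
    X, mask = cache["X"], cache["mask"]
    B = X.shape[0]
    J = config.joint_dim

    d_w_head = dlogits.T @ cache["cat"]
    d_b_head = dlogits.sum(axis=0)
    dcat = dlogits @ params.w_head                          # (B, K*joint)

    grads_blocks = []
    dz = np.zeros((B, J))
    for k in range(config.n_resblocks - 1, -1, -1):
        blk, bc = params.blocks[k], cache["block_caches"][k]
        dz_out = dz + dcat[:, k * J:(k + 1) * J]
        # linear w2
        d_w2 = dz_out.T @ bc["r"]
        d_b2 = dz_out.sum(axis=0)
        dr = dz_out @ blk["w2"]
        dy = dr * (bc["y"] > 0)
        d_gamma = (dy * bc["xhat"]).sum(axis=0)
        d_beta = dy.sum(axis=0)
        dxhat = dy * blk["gamma"]
        if bc["batch_stats"]:
            da = (bc["inv_std"] / B) * (
                B * dxhat
                - dxhat.sum(axis=0)
                - bc["xhat"] * (dxhat * bc["xhat"]).sum(axis=0)
            )
        else:
            da = dxhat * bc["inv_std"]
        d_w1 = da.T @ bc["z_in"]
        d_b1 = da.sum(axis=0)
        dz = dz_out + da @ blk["w1"]                        # skip + through-block path
        grads_blocks.insert(0, [d_w1, d_b1, d_gamma, d_beta, d_w2, d_b2])

    # fusion
    d_w_fuse = dz.T @ cache["u"]
    d_b_fuse = dz.sum(axis=0)
    du = dz @ params.w_fuse
    dpooled = du[:, : config.d_protein]

    # pooling
    scale = 1.0 / np.sqrt(config.attn_dim)
    d_queries, d_keyproj = [], []
    for h in range(config.n_heads):
        sl = slice(h * config.d_head, (h + 1) * config.d_head)
        alpha, keys = cache["alphas"][h], cache["keys"][h]
        dph = dpooled[:, sl]                                # (B, d_head)
        dalpha = np.einsum("bd,bld->bl", dph, X[:, :, sl])
        datt = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        datt = datt * mask
        d_q = scale * np.einsum("bl,bla->a", datt, keys)
        dkeys = scale * datt[:, :, None] * params.queries[h][None, None, :]
        d_k = np.einsum("bla,blp->ap", dkeys, X)
        d_queries.append(d_q)
        d_keyproj.append(d_k)

    grads = d_queries + d_keyproj + [d_w_fuse, d_b_fuse]
    for g in grads_blocks:
        grads += g
    grads += [d_w_head, d_b_head]
    return grads


# ---------------------------------------------------------------------------
# single-instance operations (inference mode)
# ---------------------------------------------------------------------------

def pool_protein(x_P: np.ndarray, params: SelectorParams, config: SelectorConfig) -> np.ndarray:
    """Attention-pool a residue matrix into one d_protein vector."""
    x_P = np.asarray(x_P, dtype=float)
    if x_P.ndim != 2 or x_P.shape[1] != config.d_protein:
        raise ValueError(f"x_P must be (n_residues, {config.d_protein})")
    scale = 1.0 / np.sqrt(config.attn_dim)
    out = []
    for h in range(config.n_heads):
        keys = x_P @ params.key_proj[h].T
        att = (keys @ params.queries[h]) * scale
        att = att - att.max()
        alpha = np.exp(att)
        alpha /= alpha.sum()
        sl = slice(h * config.d_head, (h + 1) * config.d_head)
        out.append(alpha @ x_P[:, sl])
    return np.concatenate(out)


def fuse(pooled: np.ndarray, x_L: np.ndarray, params: SelectorParams,
         config: SelectorConfig) -> np.ndarray:
    """Linear projection of [pooled protein; ligand] into the joint space."""
    pooled = np.asarray(pooled, dtype=float)
    x_L = np.asarray(x_L, dtype=float)
    if pooled.shape != (config.d_protein,) or x_L.shape != (config.d_ligand,):
        raise ValueError("fuse: dimension mismatch with config")
    return params.w_fuse @ np.concatenate([pooled, x_L]) + params.b_fuse


def decode(z: np.ndarray, params: SelectorParams, config: SelectorConfig) -> np.ndarray:
    """Residual decoder on one joint vector (inference BN); returns m logits."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite decoder input")
    outs = []
    for blk in params.blocks:
        a = blk["w1"] @ z + blk["b1"]
        xhat = (a - blk["run_mean"]) / np.sqrt(blk["run_var"] + _BN_EPS)
        r = np.maximum(blk["gamma"] * xhat + blk["beta"], 0.0)
        z = z + blk["w2"] @ r + blk["b2"]
        outs.append(z)
    cat = np.concatenate(outs)
    logits = params.w_head @ cat + params.b_head
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits")
    return logits


def forward(instance: Instance, params: SelectorParams,
            config: SelectorConfig) -> PredictionVector:
    """Full inference pipeline: pool -> fuse -> decode -> sigmoid/argmax."""
    pooled = pool_protein(instance.protein_embedding, params, config)
    z = fuse(pooled, instance.ligand_embedding, params, config)
    return PredictionVector(logits=decode(z, params, config))


def modality_dropout_forward(instance: Instance, params: SelectorParams,
                             config: SelectorConfig, mode: str = "both") -> PredictionVector:
    """Forward pass with one input modality zeroed out (ablation control)."""
    if mode not in ("both", "protein_only", "ligand_only"):
        raise ValueError(f"unknown modality-dropout mode {mode!r}")
    x_P = np.asarray(instance.protein_embedding, dtype=float)
    x_L = np.asarray(instance.ligand_embedding, dtype=float)
    if mode == "protein_only":
        x_L = np.zeros_like(x_L)
    elif mode == "ligand_only":
        x_P = np.zeros_like(x_P)
    pooled = pool_protein(x_P, params, config)
    z = fuse(pooled, x_L, params, config)
    return PredictionVector(logits=decode(z, params, config))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: SelectorParams, config: SelectorConfig,
                    extra: dict | None = None) -> None:
    """Single-archive checkpoint: arrays plus JSON metadata with a version field."""
    arrays: dict[str, np.ndarray] = {}
    for h, (q, k) in enumerate(zip(params.queries, params.key_proj)):
        arrays[f"query_{h}"] = q
        arrays[f"key_{h}"] = k
    arrays["w_fuse"], arrays["b_fuse"] = params.w_fuse, params.b_fuse
    for i, blk in enumerate(params.blocks):
        for key, val in blk.items():
            arrays[f"block{i}_{key}"] = val
    arrays["w_head"], arrays["b_head"] = params.w_head, params.b_head
    meta = {"version": CHECKPOINT_VERSION, "config": asdict(config)}
    if extra:
        meta["extra"] = extra
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SelectorParams, SelectorConfig, dict]:
    """Load a checkpoint; returns (params, config, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if "version" not in meta:
            raise ValueError("checkpoint missing version field")
        config = SelectorConfig(**meta["config"])
        queries = [data[f"query_{h}"] for h in range(config.n_heads)]
        key_proj = [data[f"key_{h}"] for h in range(config.n_heads)]
        blocks = []
        for i in range(config.n_resblocks):
            blocks.append({
                key: data[f"block{i}_{key}"]
                for key in ("w1", "b1", "gamma", "beta", "w2", "b2", "run_mean", "run_var")
            })
        params = SelectorParams(
            queries=queries, key_proj=key_proj,
            w_fuse=data["w_fuse"], b_fuse=data["b_fuse"],
            blocks=blocks, w_head=data["w_head"], b_head=data["b_head"],
        )
    return params, config, meta
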