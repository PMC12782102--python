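"""Attention-based fusion model for per-residue SLiM classification.

Architecture
------------
Two *enhanced attention* blocks — single-head attention with an output
projection, residual connection and layer normalization — are applied
separately to the physicochemical (L x 108) and evolutionary (L x 20)
blocks. Their outputs are concatenated with the 128-d semantic block into an
L x 256 fused matrix, passed through a four-head scaled-dot-product
attention layer (residual + layer norm), and classified per residue by an
MLP (256 -> 64 -> 2) with GELU activation, dropout 0.3 on the hidden layer,
and a softmax output. Training minimizes the two-class cross-entropy (the
softmax form of binary cross-entropy) with Adam at learning rate 0.001.

The enhanced-attention block has two variants behind ``variant``:

* ``matmul`` (default): scores = Q K^T / sqrt(D), row softmax over key
  positions, output = weights @ V — the canonical reading of the scaled
  dot-product equations;
* ``elementwise``: scores = (Q * K) / sqrt(D), softmax over the sequence
  axis per channel, output = weights * V — honouring a literal element-wise
  product of weights and values.

Everything is plain numpy with hand-written backprop; gradients are verified
against finite differences in the test suite. All randomness (weight
initialization, batch order, negative sampling, dropout) is seeded, so a
fixed seed reproduces a training run bit-for-bit on one thread.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf

from .evaluation import ScoreSet, roc_auc
from .features import FeatureMatrix

LN_EPS = 1e-5

# block order in the fused matrix: semantic | evolutionary | physicochemical
BLOCK_ORDER = ("seqfea", "pssm", "phy")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact Gaussian-error GELU: x * Phi(x)."""
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    phi = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    return 0.5 * (1.0 + erf(x / np.sqrt(2.0))) + x * phi


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(A: np.ndarray, dA: np.ndarray, axis: int) -> np.ndarray:
    return A * (dA - np.sum(dA * A, axis=axis, keepdims=True))


def _ln_forward(R: np.ndarray, gain: np.ndarray, bias: np.ndarray):
    mu = R.mean(axis=-1, keepdims=True)
    var = R.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (R - mu) * inv
    return gain * xhat + bias, (xhat, inv, gain)


def _ln_backward(dY: np.ndarray, cache):
    xhat, inv, gain = cache
    dgain = np.sum(dY * xhat, axis=tuple(range(dY.ndim - 1)))
    dbias = np.sum(dY, axis=tuple(range(dY.ndim - 1)))
    dxhat = dY * gain
    dR = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * np.mean(dxhat * xhat, axis=-1, keepdims=True)
    )
    return dR, dgain, dbias


def _init_weight(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EnhancedAttentionParams:
    """Single-head attention block with projection, residual and layer norm."""

    WQ: np.ndarray
    WK: np.ndarray
    WV: np.ndarray
    WO: np.ndarray
    ln_gain: np.ndarray
    ln_bias: np.ndarray
    variant: str = "matmul"

    def __post_init__(self) -> None:
        D = self.WQ.shape[0]
        for name in ("WQ", "WK", "WV", "WO"):
            if getattr(self, name).shape != (D, D):
                raise ValueError(f"{name} must be {D}x{D}")
        if self.variant not in ("matmul", "elementwise"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def D(self) -> int:
        return self.WQ.shape[0]

    @classmethod
    def init(cls, D: int, seed: int, variant: str = "matmul") -> "EnhancedAttentionParams":
        rng = np.random.default_rng(seed)
        return cls(
            WQ=_init_weight(rng, D, (D, D)),
            WK=_init_weight(rng, D, (D, D)),
            WV=_init_weight(rng, D, (D, D)),
            WO=_init_weight(rng, D, (D, D)),
            ln_gain=np.ones(D),
            ln_bias=np.zeros(D),
            variant=variant,
        )

    def tensors(self) -> dict[str, np.ndarray]:
        return {
            "WQ": self.WQ, "WK": self.WK, "WV": self.WV, "WO": self.WO,
            "ln_gain": self.ln_gain, "ln_bias": self.ln_bias,
        }


@dataclass
class FusionParams:
    """Multi-head attention over the fused feature matrix (residual + LN)."""

    WQ: np.ndarray
    WK: np.ndarray
    WV: np.ndarray
    WO: np.ndarray
    ln_gain: np.ndarray
    ln_bias: np.ndarray
    heads: int = 4

    def __post_init__(self) -> None:
        D = self.WQ.shape[0]
        if D % self.heads != 0:
            raise ValueError(f"model dim {D} not divisible by {self.heads} heads")

    @property
    def D(self) -> int:
        return self.WQ.shape[0]

    @property
    def head_dim(self) -> int:
        return self.D // self.heads

    @classmethod
    def init(cls, D: int, heads: int, seed: int) -> "FusionParams":
        rng = np.random.default_rng(seed)
        return cls(
            WQ=_init_weight(rng, D, (D, D)),
            WK=_init_weight(rng, D, (D, D)),
            WV=_init_weight(rng, D, (D, D)),
            WO=_init_weight(rng, D, (D, D)),
            ln_gain=np.ones(D),
            ln_bias=np.zeros(D),
            heads=heads,
        )

    def tensors(self) -> dict[str, np.ndarray]:
        return {
            "WQ": self.WQ, "WK": self.WK, "WV": self.WV, "WO": self.WO,
            "ln_gain": self.ln_gain, "ln_bias": self.ln_bias,
        }


@dataclass
class MLPParams:
    """Two-layer classification head with GELU hidden activation."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, in_dim: int, hidden: int, out_dim: int, seed: int) -> "MLPParams":
        rng = np.random.default_rng(seed)
        return cls(
            W1=_init_weight(rng, in_dim, (in_dim, hidden)),
            b1=np.zeros(hidden),
            W2=_init_weight(rng, hidden, (hidden, out_dim)),
            b2=np.zeros(out_dim),
        )

    def tensors(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2}


@dataclass
class TrainConfig:
    lr: float = 0.001
    dropout: float = 0.3
    epochs: int = 100
    batch_sequences: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class ModelBundle:
    """All trainable parameters plus the configuration that produced them."""

    enh_phy: EnhancedAttentionParams | None
    enh_pssm: EnhancedAttentionParams | None
    fusion: FusionParams
    mlp: MLPParams
    config: TrainConfig
    meta: dict = field(default_factory=dict)

    @property
    def blocks(self) -> tuple[str, ...]:
        return tuple(self.meta.get("blocks", BLOCK_ORDER))

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        if self.enh_phy is not None:
            params.update({f"enh_phy.{k}": v for k, v in self.enh_phy.tensors().items()})
        if self.enh_pssm is not None:
            params.update({f"enh_pssm.{k}": v for k, v in self.enh_pssm.tensors().items()})
        params.update({f"fusion.{k}": v for k, v in self.fusion.tensors().items()})
        params.update({f"mlp.{k}": v for k, v in self.mlp.tensors().items()})
        return params

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        params = self.parameters()
        np.savez(out / "weights.npz", **params)
        manifest = {
            "blocks": list(self.blocks),
            "heads": self.fusion.heads,
            "variant": None if self.enh_phy is None and self.enh_pssm is None
            else (self.enh_phy or self.enh_pssm).variant,
            "shapes": {k: list(v.shape) for k, v in params.items()},
            "config": {
                "lr": self.config.lr, "dropout": self.config.dropout,
                "epochs": self.config.epochs,
                "batch_sequences": self.config.batch_sequences,
                "seed": self.config.seed,
            },
            "meta": {k: v for k, v in self.meta.items() if k != "blocks"},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        in_dir = Path(in_dir)
        manifest = json.loads((in_dir / "manifest.json").read_text())
        data = dict(np.load(in_dir / "weights.npz"))
        variant = manifest.get("variant") or "matmul"

        def ea(prefix: str) -> EnhancedAttentionParams | None:
            if f"{prefix}.WQ" not in data:
                return None
            return EnhancedAttentionParams(
                WQ=data[f"{prefix}.WQ"], WK=data[f"{prefix}.WK"],
                WV=data[f"{prefix}.WV"], WO=data[f"{prefix}.WO"],
                ln_gain=data[f"{prefix}.ln_gain"], ln_bias=data[f"{prefix}.ln_bias"],
                variant=variant,
            )

        fusion = FusionParams(
            WQ=data["fusion.WQ"], WK=data["fusion.WK"], WV=data["fusion.WV"],
            WO=data["fusion.WO"], ln_gain=data["fusion.ln_gain"],
            ln_bias=data["fusion.ln_bias"], heads=manifest["heads"],
        )
        mlp = MLPParams(
            W1=data["mlp.W1"], b1=data["mlp.b1"], W2=data["mlp.W2"], b2=data["mlp.b2"]
        )
        cfgd = manifest["config"]
        config = TrainConfig(
            lr=cfgd["lr"], dropout=cfgd["dropout"], epochs=cfgd["epochs"],
            batch_sequences=cfgd["batch_sequences"], seed=cfgd["seed"],
        )
        meta = dict(manifest.get("meta", {}))
        meta["blocks"] = tuple(manifest["blocks"])
        return cls(ea("enh_phy"), ea("enh_pssm"), fusion, mlp, config, meta)


def init_bundle(
    seqfea_dim: int = 128,
    phy_dim: int = 108,
    pssm_dim: int = 20,
    heads: int = 4,
    hidden: int = 64,
    variant: str = "matmul",
    config: TrainConfig | None = None,
    blocks: tuple[str, ...] = BLOCK_ORDER,
) -> ModelBundle:
    """Seeded bundle with consistent dimensions (256 fused under defaults)."""
    if config is None:
        config = TrainConfig()
    dims = {"seqfea": seqfea_dim, "pssm": pssm_dim, "phy": phy_dim}
    blocks = tuple(b for b in BLOCK_ORDER if b in blocks)
    if not blocks:
        raise ValueError("at least one feature block required")
    fused = sum(dims[b] for b in blocks)
    if fused % heads != 0:
        raise ValueError(f"fused dim {fused} not divisible by {heads} heads")
    seed = config.seed
    return ModelBundle(
        enh_phy=EnhancedAttentionParams.init(phy_dim, seed + 1, variant)
        if "phy" in blocks else None,
        enh_pssm=EnhancedAttentionParams.init(pssm_dim, seed + 2, variant)
        if "pssm" in blocks else None,
        fusion=FusionParams.init(fused, heads, seed + 3),
        mlp=MLPParams.init(fused, hidden, 2, seed + 4),
        config=config,
        meta={"blocks": blocks, "dims": dims},
    )


# ---------------------------------------------------------------------------
# enhanced attention (single head, two variants)
# ---------------------------------------------------------------------------


def _ea_forward(X: np.ndarray, p: EnhancedAttentionParams):
    D = p.D
    Q, K, V = X @ p.WQ, X @ p.WK, X @ p.WV
    scale = 1.0 / np.sqrt(D)
    if p.variant == "matmul":
        S = (Q @ K.T) * scale
        A = softmax(S, axis=-1)
        O = A @ V
    else:  # elementwise
        S = (Q * K) * scale
        A = softmax(S, axis=0)  # over sequence positions, per channel
        O = A * V
    P = O @ p.WO
    Y, ln_cache = _ln_forward(X + P, p.ln_gain, p.ln_bias)
    return Y, (X, Q, K, V, A, O, ln_cache)


def _ea_backward(dY: np.ndarray, cache, p: EnhancedAttentionParams):
    X, Q, K, V, A, O, ln_cache = cache
    scale = 1.0 / np.sqrt(p.D)
    dR, dgain, dbias = _ln_backward(dY, ln_cache)
    dX = dR.copy()
    dP = dR
    dWO = O.T @ dP
    dO = dP @ p.WO.T
    if p.variant == "matmul":
        dV = A.T @ dO
        dA = dO @ V.T
        dS = _softmax_backward(A, dA, axis=-1)
        dQ = dS @ K * scale
        dK = dS.T @ Q * scale
    else:
        dV = dO * A
        dA = dO * V
        dS = _softmax_backward(A, dA, axis=0)
        dQ = dS * K * scale
        dK = dS * Q * scale
    grads = {
        "WQ": X.T @ dQ, "WK": X.T @ dK, "WV": X.T @ dV, "WO": dWO,
        "ln_gain": dgain, "ln_bias": dbias,
    }
    dX += dQ @ p.WQ.T + dK @ p.WK.T + dV @ p.WV.T
    return dX, grads


def enhanced_attention_forward(X: np.ndarray, params: EnhancedAttentionParams) -> np.ndarray:
    """Enhanced single-head attention block; output shape equals input shape."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.D:
        raise ValueError(f"input must be L x {params.D}")
    Y, _ = _ea_forward(X, params)
    return Y


# ---------------------------------------------------------------------------
# feature fusion
# ---------------------------------------------------------------------------


def fuse_concat(
    seqfea: FeatureMatrix | None,
    pssm_enh: FeatureMatrix | None,
    phy_enh: FeatureMatrix | None,
) -> FeatureMatrix:
    """Concatenate the feature blocks channel-wise.

    Channel order is semantic | evolutionary | physicochemical; with the
    default widths (128, 20, 108) the fused matrix has 256 channels.
    """
    blocks = [
        (name, fm)
        for name, fm in (("seqfea", seqfea), ("pssm", pssm_enh), ("phy", phy_enh))
        if fm is not None
    ]
    if not blocks:
        raise ValueError("no blocks to fuse")
    L = blocks[0][1].values.shape[0]
    for name, fm in blocks:
        if fm.values.shape[0] != L:
            raise ValueError(
                f"block {name!r} has {fm.values.shape[0]} rows, expected {L}"
            )
    values = np.hstack([fm.values for _, fm in blocks])
    names = [f"{name}:{ch}" for name, fm in blocks for ch in fm.channel_names]
    return FeatureMatrix(
        seq_id=blocks[0][1].seq_id, source="fused", values=values, channel_names=names
    )


# ---------------------------------------------------------------------------
# multi-head fusion attention
# ---------------------------------------------------------------------------


def _mha_forward(X: np.ndarray, p: FusionParams, mask: np.ndarray | None = None):
    L, D = X.shape
    h, hd = p.heads, p.head_dim
    Q = (X @ p.WQ).reshape(L, h, hd)
    K = (X @ p.WK).reshape(L, h, hd)
    V = (X @ p.WV).reshape(L, h, hd)
    S = np.einsum("qhd,khd->hqk", Q, K) / np.sqrt(hd)
    if mask is not None:
        S = np.where(mask[None, None, :], S, -1e30)
    A = softmax(S, axis=-1)  # h x L x L over key positions
    O = np.einsum("hqk,khd->qhd", A, V).reshape(L, D)
    P = O @ p.WO
    Y, ln_cache = _ln_forward(X + P, p.ln_gain, p.ln_bias)
    return Y, (X, Q, K, V, A, O, ln_cache)


def _mha_backward(dY: np.ndarray, cache, p: FusionParams):
    X, Q, K, V, A, O, ln_cache = cache
    L, D = X.shape
    h, hd = p.heads, p.head_dim
    dR, dgain, dbias = _ln_backward(dY, ln_cache)
    dX = dR.copy()
    dP = dR
    dWO = O.T @ dP
    dO = (dP @ p.WO.T).reshape(L, h, hd)
    dA = np.einsum("qhd,khd->hqk", dO, V)
    dV = np.einsum("hqk,qhd->khd", A, dO)
    dS = _softmax_backward(A, dA, axis=-1) / np.sqrt(hd)
    dQ = np.einsum("hqk,khd->qhd", dS, K)
    dK = np.einsum("hqk,qhd->khd", dS, Q)
    grads = {
        "WQ": X.T @ dQ.reshape(L, D),
        "WK": X.T @ dK.reshape(L, D),
        "WV": X.T @ dV.reshape(L, D),
        "WO": dWO,
        "ln_gain": dgain,
        "ln_bias": dbias,
    }
    dX += (
        dQ.reshape(L, D) @ p.WQ.T
        + dK.reshape(L, D) @ p.WK.T
        + dV.reshape(L, D) @ p.WV.T
    )
    return dX, grads


def multihead_forward(
    X: np.ndarray, params: FusionParams, mask: np.ndarray | None = None
) -> np.ndarray:
    """Multi-head scaled dot-product attention with residual + layer norm.

    ``mask`` flags valid positions (True = real residue); padded positions
    are excluded from the softmax normalization.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.D:
        raise ValueError(f"input must be L x {params.D}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (X.shape[0],):
            raise ValueError("mask length must equal sequence length")
    Y, _ = _mha_forward(X, params, mask)
    return Y


# ---------------------------------------------------------------------------
# MLP head
# ---------------------------------------------------------------------------


def _mlp_forward(
    X: np.ndarray,
    p: MLPParams,
    dropout_mask: np.ndarray | None = None,
):
    A1 = X @ p.W1 + p.b1
    H = gelu(A1)
    if dropout_mask is not None:
        H = H * dropout_mask
    Z = H @ p.W2 + p.b2
    return Z, (X, A1, H, dropout_mask)


def _mlp_backward(dZ: np.ndarray, cache, p: MLPParams):
    X, A1, H, dropout_mask = cache
    dW2 = H.T @ dZ
    db2 = dZ.sum(axis=0)
    dH = dZ @ p.W2.T
    if dropout_mask is not None:
        dH = dH * dropout_mask
    dA1 = dH * _gelu_grad(A1)
    dW1 = X.T @ dA1
    db1 = dA1.sum(axis=0)
    dX = dA1 @ p.W1.T
    return dX, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def mlp_forward(
    x: np.ndarray,
    params: MLPParams,
    dropout_active: bool = False,
    dropout: float = 0.3,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-residue class probabilities ``softmax(W2 GELU(W1 x + b1) + b2)``.

    With ``dropout_active`` an inverted-dropout mask (rate ``dropout``) is
    applied to the hidden layer; inference is deterministic.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.W1.shape[0]:
        raise ValueError(f"input dim {X.shape[1]} != {params.W1.shape[0]}")
    mask = None
    if dropout_active and dropout > 0:
        if rng is None:
            rng = np.random.default_rng()
        mask = (rng.random((X.shape[0], params.W1.shape[1])) >= dropout) / (1 - dropout)
    Z, _ = _mlp_forward(X, params, mask)
    P = softmax(Z, axis=-1)
    return P[0] if single else P


# ---------------------------------------------------------------------------
# full forward / backward over one sequence
# ---------------------------------------------------------------------------


@dataclass
class SequenceFeatures:
    """Precomputed per-sequence feature blocks plus labels and the loss mask."""

    seq_id: str
    blocks: dict[str, np.ndarray]  # keys among seqfea/phy/pssm
    labels: np.ndarray | None = None
    loss_idx: np.ndarray | None = None  # residue indices contributing to loss


def _forward_seq(bundle: ModelBundle, feats: SequenceFeatures, dropout_mask=None):
    caches: dict[str, object] = {}
    parts = []
    for name in bundle.blocks:
        X = feats.blocks[name]
        if name == "phy" and bundle.enh_phy is not None:
            Y, caches["enh_phy"] = _ea_forward(X, bundle.enh_phy)
        elif name == "pssm" and bundle.enh_pssm is not None:
            Y, caches["enh_pssm"] = _ea_forward(X, bundle.enh_pssm)
        else:
            Y = X
        parts.append(Y)
    F = np.hstack(parts)
    H, caches["fusion"] = _mha_forward(F, bundle.fusion)
    Z, caches["mlp"] = _mlp_forward(H, bundle.mlp, dropout_mask)
    return Z, caches


def _backward_seq(bundle: ModelBundle, feats: SequenceFeatures, dZ, caches):
    grads: dict[str, np.ndarray] = {}
    dH, mlp_g = _mlp_backward(dZ, caches["mlp"], bundle.mlp)
    grads.update({f"mlp.{k}": v for k, v in mlp_g.items()})
    dF, fus_g = _mha_backward(dH, caches["fusion"], bundle.fusion)
    grads.update({f"fusion.{k}": v for k, v in fus_g.items()})
    offset = 0
    for name in bundle.blocks:
        width = feats.blocks[name].shape[1]
        dPart = dF[:, offset : offset + width]
        offset += width
        if name == "phy" and bundle.enh_phy is not None:
            _, ea_g = _ea_backward(dPart, caches["enh_phy"], bundle.enh_phy)
            grads.update({f"enh_phy.{k}": v for k, v in ea_g.items()})
        elif name == "pssm" and bundle.enh_pssm is not None:
            _, ea_g = _ea_backward(dPart, caches["enh_pssm"], bundle.enh_pssm)
            grads.update({f"enh_pssm.{k}": v for k, v in ea_g.items()})
    return grads


def _loss_and_grad_logits(Z: np.ndarray, labels: np.ndarray, loss_idx: np.ndarray):
    """Summed two-class cross-entropy over the selected residues.

    Returns (summed loss, dLoss/dZ for a *sum* over selected rows); the
    caller divides by the total residue count to form the mean.
    """
    zsel = Z[loss_idx]
    y = labels[loss_idx].astype(int)
    zmax = zsel.max(axis=1, keepdims=True)
    logsumexp = zmax[:, 0] + np.log(np.exp(zsel - zmax).sum(axis=1))
    loss = float(np.sum(logsumexp - zsel[np.arange(len(y)), y]))
    P = softmax(zsel, axis=-1)
    P[np.arange(len(y)), y] -= 1.0
    dZ = np.zeros_like(Z)
    dZ[loss_idx] = P
    return loss, dZ


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def predict(bundle: ModelBundle, feats: SequenceFeatures) -> np.ndarray:
    """Per-residue probability of the SLiM class (dropout inactive)."""
    missing = [b for b in bundle.blocks if b not in feats.blocks]
    if missing:
        raise ValueError(f"features for {feats.seq_id!r} lack blocks {missing}")
    for name in bundle.blocks:
        want = bundle.meta.get("dims", {}).get(name)
        if want is not None and feats.blocks[name].shape[1] != want:
            raise ValueError(
                f"block {name!r} of {feats.seq_id!r} has width "
                f"{feats.blocks[name].shape[1]}, bundle expects {want}"
            )
    Z, _ = _forward_seq(bundle, feats)
    return softmax(Z, axis=-1)[:, 1]


def _validation_auc(bundle: ModelBundle, val_seqs: list[SequenceFeatures]) -> float:
    scores = np.concatenate([predict(bundle, f) for f in val_seqs])
    labels = np.concatenate([f.labels for f in val_seqs])
    if labels.min() == labels.max():
        return float("nan")
    _, auc = roc_auc(ScoreSet(scores, labels))
    return auc


def train(
    bundle: ModelBundle,
    train_seqs: list[SequenceFeatures],
    val_seqs: list[SequenceFeatures] | None,
    config: TrainConfig | None = None,
):
    """Train the full model with Adam; returns (best bundle, history rows).

    Batches are whole sequences; the cross-entropy is averaged over the
    class-balanced loss-residue coordinates only, while attention always
    sees the complete sequence. The epoch with the best validation AUC is
    checkpointed and returned (final epoch if no validation set). History
    rows carry epoch, mean train loss and validation AUC.
    """
    if config is None:
        config = bundle.config
    if any(f.loss_idx is None or len(f.loss_idx) == 0 for f in train_seqs):
        train_seqs = [f for f in train_seqs if f.loss_idx is not None and len(f.loss_idx)]
    if not train_seqs:
        raise ValueError("no training sequences with loss residues")

    bundle = copy.deepcopy(bundle)
    if config.epochs == 0:
        return bundle, []

    params = bundle.parameters()
    opt = _Adam(params, config.lr)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_auc, best_params = -np.inf, None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_seqs))
        epoch_loss, epoch_count = 0.0, 0
        for start in range(0, len(order), config.batch_sequences):
            batch = [train_seqs[i] for i in order[start : start + config.batch_sequences]]
            n_total = sum(len(f.loss_idx) for f in batch)
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for f in batch:
                L = f.blocks[bundle.blocks[0]].shape[0]
                mask = None
                if config.dropout > 0:
                    mask = (
                        rng.random((L, bundle.mlp.W1.shape[1])) >= config.dropout
                    ) / (1 - config.dropout)
                Z, caches = _forward_seq(bundle, f, dropout_mask=mask)
                loss, dZ = _loss_and_grad_logits(Z, f.labels, f.loss_idx)
                epoch_loss += loss
                epoch_count += len(f.loss_idx)
                for k, g in _backward_seq(bundle, f, dZ / n_total, caches).items():
                    grads[k] += g
            opt.step(params, grads)
        val_auc = _validation_auc(bundle, val_seqs) if val_seqs else float("nan")
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / epoch_count, "val_auc": val_auc}
        )
        if val_seqs and not np.isnan(val_auc) and val_auc > best_auc:
            best_auc = val_auc
            best_params = {k: v.copy() for k, v in params.items()}

    if best_params is not None:
        for k, v in best_params.items():
            params[k][...] = v
    return bundle, history
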