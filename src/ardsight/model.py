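"""Attention-GRU sequence classifier.

Architecture: a learned elementwise normalization layer feeds a 2-layer
GRU (64 hidden units by default).  A soft-attention scorer assigns each
time step a score from the concatenation of the final deepest hidden
state ``l`` with that step's deepest hidden state ``h``:

    score(l, h) = K . tanh(A . prelu(B . n([l, h])))

where ``n`` is a second, independent learned normalization layer.  The
softmax of the scores weights the deepest hidden states into a context
vector; ``[l, context]`` (128-d for hidden size 64) passes through a
2-layer feed-forward head whose 64-d intermediate activation is the
penultimate embedding and whose 7 logits are the outcome predictions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional, Union

import numpy as np

from ardsight import autodiff as ad
from ardsight.autodiff import Tensor, affine_norm, concat, softmax, stack
from ardsight.features import N_ROWS, N_STEPS

__all__ = [
    "ModelConfig",
    "ModelParams",
    "normalize",
    "attention_score",
    "forward",
    "forward_batch",
    "multitask_loss",
    "save_checkpoint",
    "load_checkpoint",
]

NORM_EPS = 1e-7
PRELU_INIT_SLOPE = 0.25
ARDS_OUTPUT_INDEX = 0  # primary outcome is the first logit


@dataclass
class ModelConfig:
    n_features: int = N_ROWS
    n_steps: int = N_STEPS
    hidden_size: int = 64
    n_layers: int = 2
    attn_dim: int = 64
    penultimate_dim: int = 64
    n_outputs: int = 7
    eps: float = NORM_EPS
    seed: int = 0

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class ModelParams:
    """All learnable tensors, keyed by name."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        F, H, D = config.n_features, config.hidden_size, config.attn_dim
        P, O = config.penultimate_dim, config.n_outputs
        self.tensors: dict[str, Tensor] = {}

        def param(name: str, shape: tuple[int, ...], fan_in: int) -> None:
            bound = 1.0 / np.sqrt(fan_in)
            self.tensors[name] = Tensor(
                rng.uniform(-bound, bound, size=shape), requires_grad=True
            )

        def norm_layer(prefix: str, dim: int) -> None:
            # starts as a plain z-score: mu=0, sigma=1, a=1, b=0
            self.tensors[f"{prefix}_mu"] = Tensor(np.zeros(dim), requires_grad=True)
            self.tensors[f"{prefix}_sigma"] = Tensor(np.ones(dim), requires_grad=True)
            self.tensors[f"{prefix}_a"] = Tensor(np.ones(dim), requires_grad=True)
            self.tensors[f"{prefix}_b"] = Tensor(np.zeros(dim), requires_grad=True)

        norm_layer("norm_in", F)
        for layer in range(config.n_layers):
            in_dim = F if layer == 0 else H
            for gate in ("z", "r", "n"):
                param(f"gru{layer}_Wx{gate}", (in_dim, H), in_dim)
                param(f"gru{layer}_Wh{gate}", (H, H), H)
                param(f"gru{layer}_bx{gate}", (H,), H)
                param(f"gru{layer}_bh{gate}", (H,), H)
        norm_layer("norm_attn", 2 * H)
        param("attn_B", (2 * H, D), 2 * H)
        param("attn_A", (D, D), D)
        param("attn_K", (D, 1), D)
        self.tensors["attn_slope"] = Tensor(
            np.array(PRELU_INIT_SLOPE), requires_grad=True
        )
        param("cls_W1", (2 * H, P), 2 * H)
        param("cls_b1", (P,), P)
        self.tensors["cls_slope"] = Tensor(
            np.array(PRELU_INIT_SLOPE), requires_grad=True
        )
        param("cls_W2", (P, O), P)
        param("cls_b2", (O,), O)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def parameters(self) -> list[Tensor]:
        return list(self.tensors.values())

    def copy(self) -> "ModelParams":
        new = ModelParams.__new__(ModelParams)
        new.config = self.config
        new.tensors = {
            k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.tensors.items()
        }
        return new

    def set_input_norm(self, mu: np.ndarray, sigma: np.ndarray) -> None:
        """Optionally seed the input normalization layer from data stats."""
        self.tensors["norm_in_mu"].data[:] = mu
        self.tensors["norm_in_sigma"].data[:] = sigma


def normalize(
    v: Union[np.ndarray, Tensor],
    mu: Union[np.ndarray, Tensor],
    sigma: Union[np.ndarray, Tensor],
    a: Union[np.ndarray, Tensor],
    b: Union[np.ndarray, Tensor],
    eps: float = NORM_EPS,
) -> Tensor:
    """Learned normalization: ``a * (v - mu) / (sigma + eps) + b`` elementwise."""
    v, mu, sigma, a, b = (Tensor._lift(x) for x in (v, mu, sigma, a, b))
    if not (mu.shape[-1] == sigma.shape[-1] == a.shape[-1] == b.shape[-1] == v.shape[-1]):
        raise ValueError("normalization parameter lengths must match input")
    return affine_norm(v, mu, sigma, a, b, eps)


def _apply_norm(params: ModelParams, prefix: str, x: Tensor) -> Tensor:
    return normalize(
        x,
        params[f"{prefix}_mu"],
        params[f"{prefix}_sigma"],
        params[f"{prefix}_a"],
        params[f"{prefix}_b"],
        eps=params.config.eps,
    )


def attention_score(
    l: Union[np.ndarray, Tensor], h: Union[np.ndarray, Tensor], params: ModelParams
) -> Tensor:
    """Score a single (l, h) pair; returns a scalar tensor."""
    l, h = Tensor._lift(l), Tensor._lift(h)
    H = params.config.hidden_size
    if l.shape != (H,) or h.shape != (H,):
        raise ValueError(f"l and h must each have length {H}")
    lh = concat([l.reshape(1, H), h.reshape(1, H)], axis=1)
    return _score(params, lh).reshape(())


def _score(params: ModelParams, lh: Tensor) -> Tensor:
    """Batched attention scores for rows of ``lh`` (n, 2H) -> (n, 1)."""
    n = _apply_norm(params, "norm_attn", lh)
    u = (n @ params["attn_B"]).prelu(params["attn_slope"])
    return (u @ params["attn_A"]).tanh() @ params["attn_K"]


def _gru_cell(
    pre: Tensor,
    t: int,
    h: Tensor,
    Whz: Tensor,
    Whr: Tensor,
    Whn: Tensor,
    bhz: Tensor,
    bhr: Tensor,
    bhn: Tensor,
) -> Tensor:
    """One fused GRU step with a hand-derived backward pass.

    ``pre`` is the precomputed input projection (T, N, 3H) holding the
    x-side of the z, r, n gates for every step; ``t`` selects the step.
    Fusing the cell into a single graph node keeps the per-batch node
    count (and python overhead) low.
    """
    H = h.data.shape[-1]
    xp = pre.data[t]
    hd = h.data
    z = 1.0 / (1.0 + np.exp(-(xp[:, :H] + hd @ Whz.data + bhz.data)))
    r = 1.0 / (1.0 + np.exp(-(xp[:, H : 2 * H] + hd @ Whr.data + bhr.data)))
    c = hd @ Whn.data + bhn.data
    n = np.tanh(xp[:, 2 * H :] + r * c)
    out_data = (1.0 - z) * n + z * hd
    parents = (pre, h, Whz, Whr, Whn, bhz, bhr, bhn)
    out = Tensor(out_data, requires_grad=any(p.requires_grad for p in parents), _prev=parents)
    if out.requires_grad:
        def _bw(g):
            dn = g * (1.0 - z)
            dz = g * (hd - n)
            dan = dn * (1.0 - n * n)
            dr = dan * c
            dc = dan * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            if pre.requires_grad:
                if pre.grad is None:
                    pre.grad = np.zeros_like(pre.data)
                pg = pre.grad[t]
                pg[:, :H] += daz
                pg[:, H : 2 * H] += dar
                pg[:, 2 * H :] += dan
            if h.requires_grad:
                h._accum(g * z + daz @ Whz.data.T + dar @ Whr.data.T + dc @ Whn.data.T)
            if Whz.requires_grad:
                Whz._accum(hd.T @ daz)
                Whr._accum(hd.T @ dar)
                Whn._accum(hd.T @ dc)
                bhz._accum(daz.sum(axis=0))
                bhr._accum(dar.sum(axis=0))
                bhn._accum(dc.sum(axis=0))
        out._backward = _bw
    return out


def _gru_layer(
    params: ModelParams, layer: int, x_seq: Tensor, T: int, N: int
) -> list[Tensor]:
    """Run one GRU layer over a (T, N, in_dim) sequence; returns h per step."""
    H = params.config.hidden_size
    flat = x_seq.reshape(T * N, x_seq.shape[-1])
    Wx = concat(
        [params[f"gru{layer}_Wx{g}"] for g in ("z", "r", "n")], axis=1
    )  # (in_dim, 3H)
    bx = concat([params[f"gru{layer}_bx{g}"] for g in ("z", "r", "n")], axis=0)
    pre = (flat @ Wx + bx).reshape(T, N, 3 * H)
    h = Tensor(np.zeros((N, H)))
    gate_params = tuple(
        params[f"gru{layer}_{name}"]
        for name in ("Whz", "Whr", "Whn", "bhz", "bhr", "bhn")
    )
    states: list[Tensor] = []
    for t in range(T):
        h = _gru_cell(pre, t, h, *gate_params)
        states.append(h)
    return states


def forward_batch(matrices: np.ndarray, params: ModelParams) -> dict[str, Tensor]:
    """Forward pass over a batch of feature matrices (N, rows, steps).

    Returns logits (N, 7), attention weights (N, steps), context (N, H)
    and the penultimate embedding (N, penultimate_dim).
    """
    cfg = params.config
    if matrices.ndim == 2:
        matrices = matrices[None]
    N, R, T = matrices.shape
    if R != cfg.n_features or T != cfg.n_steps:
        raise ValueError(
            f"expected matrices of shape (n, {cfg.n_features}, {cfg.n_steps}), got {matrices.shape}"
        )

    X = Tensor(matrices.transpose(2, 0, 1))  # (T, N, F)
    Xn = _apply_norm(params, "norm_in", X)

    states = _gru_layer(params, 0, Xn, T, N)
    for layer in range(1, cfg.n_layers):
        states = _gru_layer(params, layer, stack(states), T, N)

    l = states[-1]  # final deepest hidden state (N, H)
    Hs = stack(states)  # (T, N, H)
    lh = concat([stack([l] * T), Hs], axis=2)  # (T, N, 2H)
    scores = _score(params, lh.reshape(T * N, 2 * cfg.hidden_size)).reshape(T, N)
    weights = softmax(scores, axis=0)  # (T, N)
    context = (Hs * weights.reshape(T, N, 1)).sum(axis=0)  # (N, H)

    cat = concat([l, context], axis=1)  # (N, 2H)
    penult = (cat @ params["cls_W1"] + params["cls_b1"]).prelu(params["cls_slope"])
    logits = penult @ params["cls_W2"] + params["cls_b2"]
    return {
        "logits": logits,
        "attention_weights": weights,  # (T, N) tensor
        "context": context,
        "penultimate": penult,
        "final_hidden": l,
    }


def forward(
    matrix: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single-encounter forward pass without gradient tracking.

    Returns (logits(7), attention_weights(steps), penultimate, context).
    """
    with ad.no_grad():
        out = forward_batch(matrix[None] if matrix.ndim == 2 else matrix, params)
    return (
        out["logits"].data[0],
        out["attention_weights"].data[:, 0],
        out["penultimate"].data[0],
        out["context"].data[0],
    )


def multitask_loss(
    logits: Union[np.ndarray, Tensor],
    labels: np.ndarray,
    loss_mask: Optional[np.ndarray] = None,
) -> Tensor:
    """Masked mean binary cross-entropy over the outcome dimensions.

    ``logits`` may be (7,) or (n, 7); ``loss_mask`` selects which outcomes
    contribute (1 = contribute).  Raises on an all-masked input.
    """
    logits = Tensor._lift(logits)
    labels = np.asarray(labels, dtype=float)
    if loss_mask is None:
        loss_mask = np.ones_like(labels)
    mask = np.asarray(loss_mask, dtype=float)
    if mask.sum() == 0:
        raise ValueError("all outcomes masked; loss undefined")
    # stable BCE-with-logits: softplus(x) - x*y
    elem = logits.softplus() - logits * labels
    return (elem * mask).sum() * (1.0 / mask.sum())


def save_checkpoint(path: str, params: ModelParams) -> None:
    """Single-file checkpoint: npz of arrays plus embedded config and hash."""
    arrays = {k: v.data for k, v in params.tensors.items()}
    meta = json.dumps({"config": asdict(params.config), "hash": params.config.hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> ModelParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        if config.hash() != meta["hash"]:
            raise ValueError("checkpoint config hash mismatch")
        params = ModelParams(config)
        for k in params.tensors:
            params.tensors[k] = Tensor(np.asarray(data[k]), requires_grad=True)
    return params
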