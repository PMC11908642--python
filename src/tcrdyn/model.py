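"""A small configurable BERT-style transformer encoder for amino-acid pairs.

The encoder follows the post-layer-norm BERT layout: summed token, absolute
position, and segment embeddings -> layer norm -> N blocks of multi-head
self-attention and a GELU feed-forward, each with residual + layer norm.
Two interchangeable heads sit on top:

* a token-prediction (MLM) head — dense + GELU + layer norm + decoder to the
  25-token vocabulary — used during pretraining;
* a binding-classification head — a single output neuron with sigmoid on the
  START-position hidden state — used during finetuning.

All reported losses are mean cross-entropies in nats, so loss thresholds
(e.g. the 1.0 heuristic) are well-defined.  Presets mirror the published
model dimensions (layers, hidden units, attention heads): bertrand (8, 512,
8), tcrbert (12, 768, 12), stapler (8, 512, 8), plus a tiny (2, 64, 2)
preset for desk-scale studies.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .masking import IGNORE_INDEX, MaskedBatch

PRESETS = {
    "bertrand": dict(n_layers=8, hidden=512, n_heads=8),
    "tcrbert": dict(n_layers=12, hidden=768, n_heads=12),
    "stapler": dict(n_layers=8, hidden=512, n_heads=8),
    "tiny": dict(n_layers=2, hidden=64, n_heads=2),
}

N_SEGMENTS = 3
VOCAB_SIZE = 25


class ModelConfigError(ValueError):
    pass


class ShapeMismatchError(ValueError):
    """Encoder transfer between incompatible configurations."""


@dataclass(frozen=True)
class ModelConfig:
    n_layers: int = 2
    hidden: int = 64
    n_heads: int = 2
    ff_dim: Optional[int] = None
    max_len: int = 64
    vocab_size: int = VOCAB_SIZE
    dropout: float = 0.1
    preset: str = "custom"

    def __post_init__(self):
        if self.hidden % self.n_heads != 0:
            raise ModelConfigError(
                f"hidden ({self.hidden}) must be divisible by n_heads ({self.n_heads})"
            )
        if self.ff_dim is None:
            object.__setattr__(self, "ff_dim", 4 * self.hidden)
        if not 0.0 <= self.dropout < 1.0:
            raise ModelConfigError(f"dropout must be in [0, 1), got {self.dropout}")

    @classmethod
    def from_preset(cls, name: str, max_len: int = 64, dropout: float = 0.1) -> "ModelConfig":
        if name not in PRESETS:
            raise ModelConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        return cls(max_len=max_len, dropout=dropout, preset=name, **PRESETS[name])

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "hidden": self.hidden,
            "n_heads": self.n_heads,
            "ff_dim": self.ff_dim,
            "max_len": self.max_len,
            "vocab_size": self.vocab_size,
            "dropout": self.dropout,
            "preset": self.preset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class EncoderState:
    """Named parameter arrays of the encoder (and heads) plus their config."""

    config: ModelConfig
    params: dict[str, np.ndarray]
    init_seed: int

    def copy(self) -> "EncoderState":
        return EncoderState(self.config, {k: v.copy() for k, v in self.params.items()}, self.init_seed)

    def encoder_param_names(self) -> list[str]:
        return [k for k in self.params if not k.startswith(("mlm.", "cls."))]

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


@dataclass
class Checkpoint:
    epoch: int
    encoder: EncoderState
    train_loss: float
    eval_loss: Optional[float] = None

    def __post_init__(self):
        if self.epoch < 0:
            raise ModelConfigError(f"checkpoint epoch must be >= 0, got {self.epoch}")
        if self.train_loss < 0 or (self.eval_loss is not None and self.eval_loss < 0):
            raise ModelConfigError("losses must be nonnegative")


def _param_shapes(config: ModelConfig) -> dict[str, tuple]:
    h, f = config.hidden, config.ff_dim
    shapes: dict[str, tuple] = {
        "emb.tok": (config.vocab_size, h),
        "emb.pos": (config.max_len, h),
        "emb.seg": (N_SEGMENTS, h),
        "emb.ln.gamma": (h,),
        "emb.ln.beta": (h,),
    }
    for i in range(config.n_layers):
        p = f"layer{i}."
        shapes.update(
            {
                p + "attn.wq": (h, h), p + "attn.bq": (h,),
                p + "attn.wk": (h, h), p + "attn.bk": (h,),
                p + "attn.wv": (h, h), p + "attn.bv": (h,),
                p + "attn.wo": (h, h), p + "attn.bo": (h,),
                p + "ln1.gamma": (h,), p + "ln1.beta": (h,),
                p + "ff.w1": (h, f), p + "ff.b1": (f,),
                p + "ff.w2": (f, h), p + "ff.b2": (h,),
                p + "ln2.gamma": (h,), p + "ln2.beta": (h,),
            }
        )
    shapes.update(
        {
            "mlm.dense.w": (h, h), "mlm.dense.b": (h,),
            "mlm.ln.gamma": (h,), "mlm.ln.beta": (h,),
            "mlm.dec.w": (h, config.vocab_size), "mlm.dec.b": (config.vocab_size,),
            "cls.w": (h, 1), "cls.b": (1,),
        }
    )
    return shapes


INIT_STD = 0.02


def _init_params(config: ModelConfig, seed: int, only: Optional[set] = None) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    params = {}
    for name, shape in _param_shapes(config).items():
        if only is not None and name not in only:
            continue
        if name.endswith((".gamma",)):
            params[name] = np.ones(shape, dtype=ag.DTYPE)
        elif name.endswith((".beta", ".b", ".bq", ".bk", ".bv", ".bo", ".b1", ".b2")):
            params[name] = np.zeros(shape, dtype=ag.DTYPE)
        else:
            params[name] = rng.normal(0.0, INIT_STD, size=shape).astype(ag.DTYPE)
    return params


def init_model(config: ModelConfig, seed: int) -> EncoderState:
    """Deterministically initialize all encoder and head parameters."""
    return EncoderState(config=config, params=_init_params(config, seed), init_seed=seed)


class TransformerModel:
    """Trainable view of an :class:`EncoderState`: parameters as autodiff tensors.

    ``frozen`` parameter names are excluded from gradient updates (their
    tensors still participate in the forward pass).
    """

    def __init__(self, state: EncoderState, frozen: Optional[set] = None):
        self.config = state.config
        self.frozen = frozen or set()
        self.params: dict[str, Tensor] = {
            name: Tensor(arr.copy(), requires_grad=name not in self.frozen)
            for name, arr in state.params.items()
        }

    def trainable(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k not in self.frozen}

    def to_state(self, init_seed: int = 0) -> EncoderState:
        return EncoderState(
            config=self.config,
            params={k: v.data.copy() for k, v in self.params.items()},
            init_seed=init_seed,
        )

    # -- forward passes -----------------------------------------------------

    def _encode(
        self,
        token_ids: np.ndarray,
        segment_ids: np.ndarray,
        position_ids: np.ndarray,
        attention_mask: np.ndarray,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Hidden states (B, L, H); ``rng`` enables dropout (training mode)."""
        cfg, P = self.config, self.params
        x = ag.add(
            ag.add(ag.embedding(P["emb.tok"], token_ids), ag.embedding(P["emb.pos"], position_ids)),
            ag.embedding(P["emb.seg"], segment_ids),
        )
        x = ag.layer_norm(x, P["emb.ln.gamma"], P["emb.ln.beta"])
        x = ag.dropout(x, cfg.dropout, rng)

        B, L = token_ids.shape
        nh, dh = cfg.n_heads, cfg.hidden // cfg.n_heads
        # additive attention bias: large negative at padded key positions
        bias = ((1.0 - attention_mask[:, None, None, :]) * -1e9).astype(ag.DTYPE)

        for i in range(cfg.n_layers):
            p = f"layer{i}."

            def proj(name, h):
                w = ag.matmul(h, P[p + name[0]])
                w = ag.add(w, P[p + name[1]])
                w = ag.reshape(w, (B, L, nh, dh))
                return ag.transpose(w, (0, 2, 1, 3))  # (B, nh, L, dh)

            q = proj(("attn.wq", "attn.bq"), x)
            k = proj(("attn.wk", "attn.bk"), x)
            v = proj(("attn.wv", "attn.bv"), x)
            scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
            scores = ag.add_const(scores, bias)
            probs = ag.softmax_last(scores)
            probs = ag.dropout(probs, cfg.dropout, rng)
            ctx = ag.matmul(probs, v)  # (B, nh, L, dh)
            ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (B, L, cfg.hidden))
            attn_out = ag.add(ag.matmul(ctx, P[p + "attn.wo"]), P[p + "attn.bo"])
            attn_out = ag.dropout(attn_out, cfg.dropout, rng)
            x = ag.layer_norm(ag.add(x, attn_out), P[p + "ln1.gamma"], P[p + "ln1.beta"])

            ff = ag.gelu(ag.add(ag.matmul(x, P[p + "ff.w1"]), P[p + "ff.b1"]))
            ff = ag.add(ag.matmul(ff, P[p + "ff.w2"]), P[p + "ff.b2"])
            ff = ag.dropout(ff, cfg.dropout, rng)
            x = ag.layer_norm(ag.add(x, ff), P[p + "ln2.gamma"], P[p + "ln2.beta"])
        return x

    def mlm_logits(self, batch: MaskedBatch, rng: Optional[np.random.Generator] = None) -> Tensor:
        h = self._encode(batch.corrupted_ids, batch.segment_ids, batch.position_ids,
                         batch.attention_mask, rng)
        P = self.params
        h = ag.gelu(ag.add(ag.matmul(h, P["mlm.dense.w"]), P["mlm.dense.b"]))
        h = ag.layer_norm(h, P["mlm.ln.gamma"], P["mlm.ln.beta"])
        return ag.add(ag.matmul(h, P["mlm.dec.w"]), P["mlm.dec.b"])

    def mlm_loss(self, batch: MaskedBatch, rng: Optional[np.random.Generator] = None) -> Tensor:
        return ag.token_cross_entropy(self.mlm_logits(batch, rng), batch.targets, IGNORE_INDEX)

    def cls_logits(
        self,
        token_ids: np.ndarray,
        segment_ids: np.ndarray,
        position_ids: np.ndarray,
        attention_mask: np.ndarray,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        h = self._encode(token_ids, segment_ids, position_ids, attention_mask, rng)
        start = Tensor(h.data[:, 0, :], parents=(h,), backward=_start_slice_backward(h))
        P = self.params
        return ag.add(ag.matmul(start, P["cls.w"]), P["cls.b"])  # (B, 1)


def _start_slice_backward(h: Tensor):
    def backward(grad):
        if h.requires_grad:
            g = np.zeros_like(h.data)
            g[:, 0, :] = grad
            h._accumulate(g)

    return backward


# -- functional, evaluation-mode entry points -------------------------------


def mlm_forward(state: EncoderState, batch: MaskedBatch) -> tuple[np.ndarray, float, bool]:
    """Per-position vocabulary distributions and the mean masked cross-entropy.

    Returns ``(probs, loss_nats, no_selection_flag)``; when the batch contains
    zero selected positions the loss is defined as 0 and the flag is raised.
    """
    model = TransformerModel(state)
    logits = model.mlm_logits(batch, rng=None)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    no_selection = batch.n_selected == 0
    loss = 0.0 if no_selection else float(
        ag.token_cross_entropy(logits, batch.targets, IGNORE_INDEX).data
    )
    return probs, loss, no_selection


def cls_forward(
    state: EncoderState,
    token_ids: np.ndarray,
    segment_ids: np.ndarray,
    position_ids: np.ndarray,
    attention_mask: np.ndarray,
    labels: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, Optional[float]]:
    """Binding probabilities in (0, 1) and, if labels are given, the mean BCE."""
    model = TransformerModel(state)
    logits = model.cls_logits(token_ids, segment_ids, position_ids, attention_mask, rng=None)
    probs = ag.sigmoid(logits.data[:, 0])
    if labels is None:
        return probs, None
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    loss = float(ag.binary_cross_entropy_with_logits(logits, labels[:, None]).data)
    return probs, loss


def transfer_encoder(
    checkpoint: Checkpoint,
    config: Optional[ModelConfig] = None,
    head_seed: int = 0,
    freeze: bool = False,
) -> TransformerModel:
    """Build a finetuning model whose encoder equals the checkpoint bitwise.

    The classification head is freshly initialized from ``head_seed``.  With
    ``freeze=True`` the encoder parameters are excluded from updates; the
    default (False) lets finetuning update every layer.
    """
    src = checkpoint.encoder
    if config is not None:
        src_shapes = {k: v.shape for k, v in src.params.items()}
        for name, shape in _param_shapes(config).items():
            if name.startswith("cls."):
                continue
            if src_shapes.get(name) != shape:
                raise ShapeMismatchError(
                    f"parameter {name!r}: checkpoint has {src_shapes.get(name)}, "
                    f"target config needs {shape}"
                )
    state = src.copy()
    fresh_head = _init_params(src.config, head_seed, only={"cls.w", "cls.b"})
    state.params.update(fresh_head)
    frozen = set(state.encoder_param_names()) if freeze else set()
    return TransformerModel(state, frozen=frozen)


# -- checkpoint persistence -------------------------------------------------
#
# weights.bin is a deterministic named-array container: a JSON header listing
# (name, dtype, shape, byte offset) followed by the concatenated raw little-
# endian array bytes.  Writing is bit-faithful and timestamp-free, so saved
# checkpoints round-trip bitwise and identical runs produce identical files.

_MAGIC = b"TCRDYN01"


def _write_arrays(path: Path, arrays: dict[str, np.ndarray]) -> None:
    header = {}
    offset = 0
    blobs = []
    for name in sorted(arrays):
        arr = np.ascontiguousarray(arrays[name])
        raw = arr.astype(arr.dtype.newbyteorder("<"), copy=False).tobytes()
        header[name] = {"dtype": str(arr.dtype), "shape": list(arr.shape), "offset": offset,
                        "nbytes": len(raw)}
        blobs.append(raw)
        offset += len(raw)
    head = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(head).to_bytes(8, "little"))
        fh.write(head)
        for raw in blobs:
            fh.write(raw)


def _read_arrays(path: Path) -> dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a tcrdyn weight container")
        head_len = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(head_len).decode())
        body = fh.read()
    arrays = {}
    for name, meta in header.items():
        raw = body[meta["offset"] : meta["offset"] + meta["nbytes"]]
        arrays[name] = np.frombuffer(raw, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"]).copy()
    return arrays


def save_checkpoint(checkpoint: Checkpoint, directory: str | Path) -> Path:
    d = Path(directory) / f"epoch_{checkpoint.epoch}"
    d.mkdir(parents=True, exist_ok=True)
    _write_arrays(d / "weights.bin", checkpoint.encoder.params)
    meta = {
        "epoch": checkpoint.epoch,
        "train_loss": checkpoint.train_loss,
        "eval_loss": checkpoint.eval_loss,
        "config": checkpoint.encoder.config.to_dict(),
        "init_seed": checkpoint.encoder.init_seed,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return d


def load_checkpoint(directory: str | Path) -> Checkpoint:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    params = _read_arrays(d / "weights.bin")
    state = EncoderState(
        config=ModelConfig.from_dict(meta["config"]), params=params, init_seed=meta["init_seed"]
    )
    return Checkpoint(
        epoch=meta["epoch"], encoder=state,
        train_loss=meta["train_loss"], eval_loss=meta["eval_loss"],
    )
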