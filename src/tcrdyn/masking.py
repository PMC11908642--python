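"""BERT-style corruption of encoded examples for masked-language-model training.

Each residue position (never a special token or padding) is independently
selected with probability ``p_select`` (default 0.15).  A selected position is
replaced by MASK with probability 0.80, by a uniformly random residue token
with probability 0.10, and left unchanged with probability 0.10; the original
token id is recorded as the prediction target.  Corruption is re-drawn on
every call (dynamic masking), so successive epochs see different corruptions
of the same corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import EncodedExample, Vocabulary

#: Sentinel target at positions that are not selected for prediction.
IGNORE_INDEX = -100


class MaskingError(ValueError):
    pass


@dataclass(frozen=True)
class MaskingPolicy:
    """Selection and replacement probabilities for MLM corruption."""

    p_select: float = 0.15
    p_mask: float = 0.80
    p_random: float = 0.10
    p_keep: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.p_select < 1.0:
            raise MaskingError(f"p_select must be in (0, 1), got {self.p_select}")
        total = self.p_mask + self.p_random + self.p_keep
        if abs(total - 1.0) > 1e-12:
            raise MaskingError(f"p_mask + p_random + p_keep must sum to 1, got {total}")


@dataclass
class MaskedBatch:
    """Corrupted token ids with per-position MLM targets.

    ``targets`` holds the original token id exactly where ``selection_mask``
    is 1 and :data:`IGNORE_INDEX` elsewhere; ``corrupted_ids`` equals the
    input ids wherever ``selection_mask`` is 0.
    """

    corrupted_ids: np.ndarray   # (n, max_len) int64
    targets: np.ndarray         # (n, max_len) int64, IGNORE_INDEX off-selection
    selection_mask: np.ndarray  # (n, max_len) {0,1}
    segment_ids: np.ndarray
    position_ids: np.ndarray
    attention_mask: np.ndarray

    @property
    def n_selected(self) -> int:
        return int(self.selection_mask.sum())


def corrupt(
    examples: list[EncodedExample],
    policy: MaskingPolicy,
    seed: int,
    vocab: Vocabulary | None = None,
) -> MaskedBatch:
    """Corrupt a batch of encoded examples for MLM, deterministically given ``seed``."""
    if vocab is None:
        vocab = Vocabulary()
    token_ids = np.stack([ex.token_ids for ex in examples])
    segment_ids = np.stack([ex.segment_ids for ex in examples])
    position_ids = np.stack([ex.position_ids for ex in examples])
    attention_mask = np.stack([ex.attention_mask for ex in examples])

    if np.any(token_ids == vocab.mask_id):
        raise MaskingError("input already contains MASK tokens; corrupt clean examples only")

    rng = np.random.default_rng(seed)
    residue_lo, residue_hi = vocab.residue_ids.start, vocab.residue_ids.stop
    eligible = (token_ids >= residue_lo) & (token_ids < residue_hi)

    selected = eligible & (rng.random(token_ids.shape) < policy.p_select)

    # Replacement branch per selected position: 0 = MASK, 1 = random residue, 2 = keep.
    u = rng.random(token_ids.shape)
    branch = np.where(u < policy.p_mask, 0, np.where(u < policy.p_mask + policy.p_random, 1, 2))
    random_residues = rng.integers(residue_lo, residue_hi, size=token_ids.shape)

    corrupted = token_ids.copy()
    corrupted[selected & (branch == 0)] = vocab.mask_id
    repl = selected & (branch == 1)
    corrupted[repl] = random_residues[repl]

    targets = np.where(selected, token_ids, IGNORE_INDEX).astype(np.int64)
    return MaskedBatch(
        corrupted_ids=corrupted,
        targets=targets,
        selection_mask=selected.astype(np.int64),
        segment_ids=segment_ids,
        position_ids=position_ids,
        attention_mask=attention_mask,
    )


def restore(batch: MaskedBatch) -> np.ndarray:
    """Recover the original token ids from a corrupted batch."""
    sel = batch.selection_mask.astype(bool)
    return np.where(sel, batch.targets, batch.corrupted_ids)
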