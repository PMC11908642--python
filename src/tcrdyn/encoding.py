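"""Token vocabulary and fixed-length encoding of antigen/CDR3 pairs.

A classification or MLM sample is the concatenation

    START  <antigen residues>  END  <cdr3 residues>  END  PAD ...

with the antigen portion optional (single-sequence repertoire models take the
CDR3 alone).  Segment ids distinguish the antigen portion (0) from the CDR3
portion (1); special tokens and padding carry segment 2.  Position ids are
absolute 0-based indices over the padded sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The 20 proteinogenic amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SEG_ANTIGEN = 0
SEG_CDR3 = 1
SEG_SPECIAL = 2


class EncodingError(ValueError):
    """Raised for invalid residues, over-length inputs, or malformed layouts."""


@dataclass(frozen=True)
class Vocabulary:
    """Fixed 25-token vocabulary: 5 special tokens + 20 residues.

    Ids are contiguous from 0 with the special tokens first (PAD=0 so that
    zero-padding arrays is equivalent to PAD-filling them).
    """

    pad: str = "[PAD]"
    start: str = "[START]"
    end: str = "[END]"
    mask: str = "[MASK]"
    unk: str = "[UNK]"
    _id_of: dict = field(default_factory=dict, repr=False)
    _symbol_of: tuple = field(default=(), repr=False)

    def __post_init__(self):
        symbols = [self.pad, self.start, self.end, self.mask, self.unk]
        symbols += list(AMINO_ACIDS)
        object.__setattr__(self, "_symbol_of", tuple(symbols))
        object.__setattr__(self, "_id_of", {s: i for i, s in enumerate(symbols)})

    def __len__(self) -> int:
        return len(self._symbol_of)

    @property
    def pad_id(self) -> int:
        return self._id_of[self.pad]

    @property
    def start_id(self) -> int:
        return self._id_of[self.start]

    @property
    def end_id(self) -> int:
        return self._id_of[self.end]

    @property
    def mask_id(self) -> int:
        return self._id_of[self.mask]

    @property
    def unk_id(self) -> int:
        return self._id_of[self.unk]

    @property
    def special_ids(self) -> frozenset:
        return frozenset(range(5))

    @property
    def residue_ids(self) -> range:
        """Contiguous id range of the 20 residue tokens."""
        return range(5, 25)

    @property
    def residue_tokens(self) -> str:
        return AMINO_ACIDS

    def id_of(self, symbol: str) -> int:
        try:
            return self._id_of[symbol]
        except KeyError:
            raise EncodingError(f"symbol {symbol!r} is not in the vocabulary") from None

    def symbol_of(self, token_id: int) -> str:
        if not 0 <= token_id < len(self._symbol_of):
            raise EncodingError(f"token id {token_id} out of range [0, {len(self)})")
        return self._symbol_of[token_id]

    def encode_residues(self, residues: str) -> list[int]:
        return [self.id_of(r) for r in residues]

    def to_json(self) -> str:
        """Serialize the id assignment for checkpoint provenance."""
        return json.dumps({"symbols": list(self._symbol_of)})


def build_vocabulary() -> Vocabulary:
    """Return the fixed amino-acid vocabulary (stable ids across runs)."""
    return Vocabulary()


@dataclass
class EncodedExample:
    """A tokenized (antigen, CDR3) pair padded to ``max_len``.

    All four arrays have identical length; ``attention_mask`` is 1 exactly on
    non-PAD positions.
    """

    token_ids: np.ndarray
    segment_ids: np.ndarray
    position_ids: np.ndarray
    attention_mask: np.ndarray
    label: Optional[int] = None

    def __post_init__(self):
        n = len(self.token_ids)
        if not (len(self.segment_ids) == len(self.position_ids) == len(self.attention_mask) == n):
            raise EncodingError("token/segment/position/attention arrays must share one length")

    @property
    def max_len(self) -> int:
        return len(self.token_ids)


def encode_pair(
    antigen: Optional[str],
    cdr3: str,
    vocab: Vocabulary,
    max_len: int = 64,
    label: Optional[int] = None,
) -> EncodedExample:
    """Encode an (optional antigen, CDR3) residue pair into a fixed-length example.

    Raises
    ------
    EncodingError
        If a residue is outside the 20-letter alphabet or the encoded layout
        would exceed ``max_len`` (inputs are never silently truncated).
    """
    if not cdr3:
        raise EncodingError("cdr3 residue string must be non-empty")
    parts: list[tuple[int, int]] = [(vocab.start_id, SEG_SPECIAL)]
    if antigen is not None:
        if not antigen:
            raise EncodingError("antigen residue string must be non-empty (or None)")
        parts += [(vocab.id_of(r), SEG_ANTIGEN) for r in antigen]
        parts.append((vocab.end_id, SEG_SPECIAL))
    parts += [(vocab.id_of(r), SEG_CDR3) for r in cdr3]
    parts.append((vocab.end_id, SEG_SPECIAL))

    if len(parts) > max_len:
        raise EncodingError(
            f"encoded length {len(parts)} exceeds max_len={max_len} "
            f"(antigen {0 if antigen is None else len(antigen)}, cdr3 {len(cdr3)})"
        )

    token_ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    segment_ids = np.full(max_len, SEG_SPECIAL, dtype=np.int64)
    attention_mask = np.zeros(max_len, dtype=np.int64)
    for i, (tid, seg) in enumerate(parts):
        token_ids[i] = tid
        segment_ids[i] = seg
        attention_mask[i] = 1
    position_ids = np.arange(max_len, dtype=np.int64)
    if label is not None and label not in (0, 1):
        raise EncodingError(f"label must be 0 or 1, got {label!r}")
    return EncodedExample(token_ids, segment_ids, position_ids, attention_mask, label)


def decode(example: EncodedExample, vocab: Vocabulary) -> tuple[Optional[str], str]:
    """Invert :func:`encode_pair`: recover (antigen or None, cdr3) residue strings."""
    ids = [int(t) for t in example.token_ids]
    n_real = int(example.attention_mask.sum())
    if n_real == 0:
        raise EncodingError("example is all padding; nothing to decode")
    if ids[0] != vocab.start_id:
        raise EncodingError("malformed layout: first token is not START")
    body = ids[1:n_real]
    segments: list[str] = []
    current: list[str] = []
    for tid in body:
        if tid == vocab.end_id:
            segments.append("".join(current))
            current = []
        elif tid in (vocab.mask_id, vocab.unk_id, vocab.pad_id, vocab.start_id):
            raise EncodingError(f"malformed layout: unexpected token {vocab.symbol_of(tid)!r}")
        else:
            current.append(vocab.symbol_of(tid))
    if current:
        raise EncodingError("malformed layout: sequence does not terminate with END")
    if len(segments) == 1:
        return None, segments[0]
    if len(segments) == 2:
        return segments[0], segments[1]
    raise EncodingError(f"malformed layout: found {len(segments)} END-delimited portions")
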