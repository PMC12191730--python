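"""Fixed 26-token vocabulary and the paired-chain encoding.

Vocabulary: 20 canonical amino acids, "X" for unnatural residues, and the
five special tokens <pad>, <mask>, <unk>, <cls>, <eos>. Inputs are the heavy
and light chains joined by a double-<cls> separator and padded to a fixed
length (default 320) with no truncation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .annotate import RegionMask, build_region_mask
from .layout import EncodingLayout, LayoutOverflowError
from .records import AMINO_ACIDS, AnnotatedChain, PairedRecord

__all__ = [
    "Vocabulary",
    "EncodedPair",
    "build_vocab",
    "encode_pair",
    "decode",
    "MalformedInputError",
]

# ESM-style ordering: specials, canonical residues, X, then <mask> last.
_RESIDUE_ORDER = "LAGVSERTIDPKQNFYMHWC"
assert sorted(_RESIDUE_ORDER) == sorted(AMINO_ACIDS)
_TOKENS = ("<cls>", "<pad>", "<eos>", "<unk>") + tuple(_RESIDUE_ORDER) + ("X", "<mask>")


class MalformedInputError(ValueError):
    """Token ids do not form a valid encoded pair."""


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple = _TOKENS
    index: dict = field(default_factory=lambda: {t: i for i, t in enumerate(_TOKENS)})

    def __len__(self) -> int:
        return len(self.tokens)

    def id(self, token: str) -> int:
        return self.index[token]

    def token(self, idx: int) -> str:
        return self.tokens[idx]

    @property
    def pad_id(self) -> int:
        return self.index["<pad>"]

    @property
    def mask_id(self) -> int:
        return self.index["<mask>"]

    @property
    def cls_id(self) -> int:
        return self.index["<cls>"]

    @property
    def eos_id(self) -> int:
        return self.index["<eos>"]

    @property
    def unk_id(self) -> int:
        return self.index["<unk>"]

    @property
    def residue_ids(self) -> np.ndarray:
        """Ids of the 21 residue tokens (20 amino acids + X)."""
        return np.array([self.index[t] for t in _RESIDUE_ORDER + "X"], dtype=np.int64)

    @property
    def special_ids(self) -> frozenset:
        return frozenset(
            self.index[t] for t in ("<cls>", "<pad>", "<eos>", "<unk>", "<mask>")
        )

    def encode_residue(self, ch: str) -> int:
        """Residue character to id; unknown characters map to "X"."""
        return self.index.get(ch, self.index["X"])

    def to_json(self) -> str:
        return json.dumps(list(self.tokens))

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        tokens = tuple(json.loads(text))
        return cls(tokens=tokens, index={t: i for i, t in enumerate(tokens)})


def build_vocab() -> Vocabulary:
    """The fixed 26-token vocabulary, stable across runs."""
    return Vocabulary()


@dataclass
class EncodedPair:
    """One tokenized paired input of fixed length with its region mask."""

    token_ids: np.ndarray  # int64, length max_len
    attention_flags: np.ndarray  # uint8, 1 = real token, 0 = pad
    region_mask: RegionMask
    pair_id: str

    @property
    def layout(self) -> EncodingLayout:
        return self.region_mask.layout

    @property
    def n_real(self) -> int:
        return int(self.attention_flags.sum())


def encode_pair(
    heavy: AnnotatedChain,
    light: AnnotatedChain,
    vocab: Vocabulary,
    max_len: int = 320,
    pair_id: str = "",
) -> EncodedPair:
    """Encode <cls> H <cls><cls> L <eos> <pad>* and its region mask in one pass."""
    if not heavy.sequence or not light.sequence:
        raise ValueError("both chains must be non-empty")
    layout = EncodingLayout(len(heavy.sequence), len(light.sequence), max_len)
    ids = np.full(max_len, vocab.pad_id, dtype=np.int64)
    ids[0] = vocab.cls_id
    h0, h1 = layout.heavy_span
    ids[h0:h1] = [vocab.index.get(c, vocab.index["X"]) for c in heavy.sequence]
    s0, s1 = layout.separator_span
    ids[s0:s1] = vocab.cls_id
    l0, l1 = layout.light_span
    ids[l0:l1] = [vocab.index.get(c, vocab.index["X"]) for c in light.sequence]
    ids[layout.eos_index] = vocab.eos_id
    flags = np.zeros(max_len, dtype=np.uint8)
    flags[: layout.total_real] = 1
    mask = build_region_mask(
        PairedRecord(pair_id=pair_id or "pair", heavy=heavy, light=light,
                     cell_type="memory"),  # encoding imposes no cell-type rule
        layout,
    )
    return EncodedPair(ids, flags, mask, pair_id or "pair")


def encode_record(record: PairedRecord, vocab: Vocabulary, max_len: int = 320) -> EncodedPair:
    return encode_pair(record.heavy, record.light, vocab, max_len, record.pair_id)


def decode(token_ids, vocab: Vocabulary) -> tuple[str, str]:
    """Inverse of ``encode_pair`` on its image: recover (heavy, light) strings."""
    ids = np.asarray(token_ids)
    if ids.ndim != 1 or len(ids) == 0:
        raise MalformedInputError("expected a 1-D id vector")
    real = ids[ids != vocab.pad_id]
    if len(real) < 5 or real[0] != vocab.cls_id or real[-1] != vocab.eos_id:
        raise MalformedInputError("missing <cls> ... <eos> frame")
    body = real[1:-1]
    # locate the double-<cls> separator
    is_cls = body == vocab.cls_id
    sep = np.flatnonzero(is_cls[:-1] & is_cls[1:])
    if len(sep) != 1:
        raise MalformedInputError("separator <cls><cls> not found exactly once")
    s = int(sep[0])
    heavy_ids, light_ids = body[:s], body[s + 2 :]
    if len(heavy_ids) == 0 or len(light_ids) == 0:
        raise MalformedInputError("empty chain segment")
    specials = vocab.special_ids
    for seg in (heavy_ids, light_ids):
        if any(int(i) in specials for i in seg):
            raise MalformedInputError("special token inside a chain segment")
    to_str = lambda seg: "".join(vocab.token(int(i)) for i in seg)
    return to_str(heavy_ids), to_str(light_ids)


# re-exported for callers that catch the overflow condition by name
OverflowEncodingError = LayoutOverflowError
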