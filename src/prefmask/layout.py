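"""Token layout of a paired-chain input.

The encoded layout is::

    <cls>  heavy residues  <cls> <cls>  light residues  <eos>  <pad>...

i.e. the two chains are joined by a double-<cls> separator, with one leading
<cls> and one trailing <eos>, then padded to a fixed length.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import REGION_ORDER

#: chain-qualified region labels, in the order used by region-mask codes 1..14
CHAIN_REGION_LABELS = tuple(f"H-{r}" for r in REGION_ORDER) + tuple(
    f"L-{r}" for r in REGION_ORDER
)
SPECIAL_LABEL = 0  # region-mask code for any non-residue position (incl. pad)

#: chain-agnostic bucket for each chain-qualified label (frameworks pooled)
AGNOSTIC_BUCKET = {
    lab: ("FR" if lab.endswith(("FR1", "FR2", "FR3", "FR4")) else lab.split("-")[1])
    for lab in CHAIN_REGION_LABELS
}

N_EXTRA_TOKENS = 4  # lead <cls>, two separator <cls>, trailing <eos>


class LayoutOverflowError(ValueError):
    """The pair does not fit in the configured maximum length."""


@dataclass(frozen=True)
class EncodingLayout:
    """Positions of every structural element for one heavy/light pair."""

    heavy_len: int
    light_len: int
    max_len: int = 320

    def __post_init__(self):
        if self.heavy_len < 1 or self.light_len < 1:
            raise ValueError("both chains must be non-empty")
        if self.total_real > self.max_len:
            raise LayoutOverflowError(
                f"pair needs {self.total_real} tokens but max_len={self.max_len} "
                "(no truncation is performed)"
            )

    @property
    def total_real(self) -> int:
        return self.heavy_len + self.light_len + N_EXTRA_TOKENS

    @property
    def heavy_span(self) -> tuple[int, int]:
        return 1, 1 + self.heavy_len

    @property
    def separator_span(self) -> tuple[int, int]:
        s = 1 + self.heavy_len
        return s, s + 2

    @property
    def light_span(self) -> tuple[int, int]:
        s = 3 + self.heavy_len
        return s, s + self.light_len

    @property
    def eos_index(self) -> int:
        return self.light_span[1]

    def chain_position(self, index: int) -> tuple[str, int] | None:
        """Map a token index to ("H"|"L", residue offset), or None for specials."""
        h0, h1 = self.heavy_span
        if h0 <= index < h1:
            return "H", index - h0
        l0, l1 = self.light_span
        if l0 <= index < l1:
            return "L", index - l0
        return None
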