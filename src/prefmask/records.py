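"""Core containers for annotated antibody chains and paired records.

Coordinates are 0-based, half-open throughout. A chain's regions must tile
the sequence in the canonical order FR1, CDR1, FR2, CDR2, FR3, CDR3, FR4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
LOCI = ("heavy", "kappa", "lambda")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class RecordError(ValueError):
    """A chain or pair violates its structural invariants."""


class MaskAlignmentError(RecordError):
    """Region annotations do not tile the sequence (e.g. adjacent CDRs)."""


class UnsupportedRecordError(RecordError):
    """A record lacks the information an operation requires (e.g. germline)."""


@dataclass
class AnnotatedChain:
    """One variable-domain amino-acid sequence with region boundaries.

    ``germline_v`` is the germline-encoded FR1..FR3 span (the V segment
    exclusive of its CDR3 tail); ``germline_full`` is the complete
    pre-mutation sequence as assembled at recombination, used for mutation
    bookkeeping. ``templated_mask[i]`` is False at non-templated (inserted)
    CDR3 positions.
    """

    sequence: str
    regions: list  # [(label, start, end)] in REGION_ORDER
    locus: str
    germline_v: str | None = None
    germline_full: str | None = None
    templated_mask: list | None = None
    v_mutation_count: int = 0

    def validate(self) -> None:
        if self.locus not in LOCI:
            raise RecordError(f"unknown locus {self.locus!r}")
        if not self.sequence:
            raise RecordError("empty sequence")
        labels = tuple(r[0] for r in self.regions)
        if labels != REGION_ORDER:
            raise MaskAlignmentError(
                f"regions must be exactly {REGION_ORDER}, got {labels}"
            )
        cursor = 0
        for label, start, end in self.regions:
            if start != cursor:
                raise MaskAlignmentError(
                    f"{label} starts at {start}, expected {cursor} (gap/overlap)"
                )
            if end < start:
                raise MaskAlignmentError(f"{label} has negative length")
            if end == start:
                # An empty region means two neighbours touch, i.e. the
                # annotation placed regions adjacently that should be apart.
                raise MaskAlignmentError(f"{label} is empty (adjacent regions)")
            cursor = end
        if cursor != len(self.sequence):
            raise MaskAlignmentError(
                f"regions cover [0,{cursor}) but sequence has length {len(self.sequence)}"
            )
        cdr3 = self.region_bounds("CDR3")
        if cdr3[1] - cdr3[0] < 1:
            raise MaskAlignmentError("CDR3 must have length >= 1")

    def region_bounds(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.regions:
            if lab == label:
                return start, end
        raise KeyError(label)

    def region_seq(self, label: str) -> str:
        start, end = self.region_bounds(label)
        return self.sequence[start:end]

    @property
    def v_span(self) -> tuple[int, int]:
        """FR1..FR3 span: the portion compared against ``germline_v``."""
        return self.region_bounds("FR1")[0], self.region_bounds("FR3")[1]

    def copy(self) -> "AnnotatedChain":
        return replace(
            self,
            regions=list(self.regions),
            templated_mask=None if self.templated_mask is None else list(self.templated_mask),
        )


@dataclass
class PairedRecord:
    """A natively (or artificially) paired heavy/light chain observation."""

    pair_id: str
    heavy: AnnotatedChain
    light: AnnotatedChain
    donor_id: str = "d0"
    cell_type: str = "naive"  # naive | memory
    pairing_label: str = "native"  # native | shuffled
    specificity_label: str = "unlabeled"  # positive | negative | unlabeled
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.heavy is None or self.light is None:
            raise RecordError("both chains must be present")
        if self.heavy.locus != "heavy":
            raise RecordError("heavy slot must hold a heavy-locus chain")
        if self.light.locus == "heavy":
            raise RecordError("light slot must hold a kappa/lambda chain")
        self.heavy.validate()
        self.light.validate()
        if self.cell_type == "naive" and (
            self.heavy.v_mutation_count or self.light.v_mutation_count
        ):
            raise RecordError("naive cells must carry zero V mutations")

    @property
    def concat_sequence(self) -> str:
        return self.heavy.sequence + self.light.sequence

    def copy(self) -> "PairedRecord":
        return PairedRecord(
            pair_id=self.pair_id,
            heavy=self.heavy.copy(),
            light=self.light.copy(),
            donor_id=self.donor_id,
            cell_type=self.cell_type,
            pairing_label=self.pairing_label,
            specificity_label=self.specificity_label,
            meta=dict(self.meta),
        )


def regions_from_lengths(lengths: dict[str, int]) -> list:
    """Build a tiling region list from per-region lengths in canonical order."""
    out, cursor = [], 0
    for label in REGION_ORDER:
        n = lengths[label]
        out.append((label, cursor, cursor + n))
        cursor += n
    return out
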