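"""Region-mask construction, QC filtering, mutation counting, identity clustering.

These are the dataset-preparation steps that sit between raw annotated
repertoires and model training: build per-token region masks aligned to the
paired-chain encoding, drop duplicate and mis-annotated pairs, count V-gene
amino-acid mutations against the germline, and collapse near-identical pairs
by greedy identity clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .layout import (
    AGNOSTIC_BUCKET,
    CHAIN_REGION_LABELS,
    SPECIAL_LABEL,
    EncodingLayout,
)
from .records import (
    AnnotatedChain,
    MaskAlignmentError,
    PairedRecord,
    UnsupportedRecordError,
)

__all__ = [
    "RegionMask",
    "build_region_mask",
    "filter_dataset",
    "count_v_mutations",
    "cluster_identity",
    "MaskAlignmentError",
    "UnsupportedRecordError",
]

# region-mask codes: 0 = special/pad, 1..7 = heavy FR1..FR4, 8..14 = light
LABEL_CODES = {lab: i + 1 for i, lab in enumerate(CHAIN_REGION_LABELS)}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}


@dataclass
class RegionMask:
    """Per-position region labels over one encoded paired input.

    ``labels[i]`` is 0 at special/pad positions and one of the 14
    chain-qualified region codes at residue positions.
    """

    labels: np.ndarray  # int8, length = layout.max_len
    layout: EncodingLayout

    @property
    def residue_positions(self) -> np.ndarray:
        return np.flatnonzero(self.labels != SPECIAL_LABEL)

    @property
    def n_residues(self) -> int:
        return int(np.count_nonzero(self.labels != SPECIAL_LABEL))

    def positions_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == LABEL_CODES[label])

    @property
    def cdr3_positions(self) -> np.ndarray:
        return np.flatnonzero(
            (self.labels == LABEL_CODES["H-CDR3"]) | (self.labels == LABEL_CODES["L-CDR3"])
        )

    @property
    def p_hat_cdr3(self) -> float:
        """Fraction of residue positions that lie in either chain's CDR3."""
        return len(self.cdr3_positions) / self.n_residues

    def agnostic_bucket(self, index: int) -> str | None:
        code = int(self.labels[index])
        if code == SPECIAL_LABEL:
            return None
        return AGNOSTIC_BUCKET[CODE_LABELS[code]]

    def label_counts(self) -> dict:
        return {
            lab: int(np.count_nonzero(self.labels == code))
            for lab, code in LABEL_CODES.items()
        }


def build_region_mask(pair: PairedRecord, layout: EncodingLayout | None = None,
                      max_len: int = 320) -> RegionMask:
    """Region labels aligned to the token layout of ``encode_pair``.

    Raises :class:`MaskAlignmentError` when a chain's annotations do not
    tile its sequence (the QC condition that ``filter_dataset`` screens).
    """
    pair.validate()  # raises MaskAlignmentError on tiling violations
    if layout is None:
        layout = EncodingLayout(len(pair.heavy.sequence), len(pair.light.sequence), max_len)
    labels = np.zeros(layout.max_len, dtype=np.int8)
    for chain, prefix, (start, _) in (
        (pair.heavy, "H", layout.heavy_span),
        (pair.light, "L", layout.light_span),
    ):
        for region, r0, r1 in chain.regions:
            labels[start + r0 : start + r1] = LABEL_CODES[f"{prefix}-{region}"]
    return RegionMask(labels=labels, layout=layout)


def filter_dataset(records, max_len: int = 320):
    """Remove exact duplicate pairs and mask-alignment failures.

    Returns ``(kept, rejected)`` where ``rejected`` is a list of
    ``(pair_id, reason)`` tuples. First occurrence of a duplicate is kept.
    Idempotent: filtering the kept set again rejects nothing.
    """
    kept, rejected = [], []
    seen = set()
    for rec in records:
        key = (rec.heavy.sequence, rec.light.sequence)
        if key in seen:
            rejected.append((rec.pair_id, "duplicate"))
            continue
        try:
            build_region_mask(rec, max_len=max_len)
        except (MaskAlignmentError, ValueError) as exc:
            rejected.append((rec.pair_id, f"mask_alignment: {exc}"))
            continue
        seen.add(key)
        kept.append(rec)
    return kept, rejected


def count_v_mutations(chain: AnnotatedChain) -> int:
    """Number of V-region (FR1..FR3) positions differing from germline.

    CDR3 lies outside the V span compared here, so non-templated junction
    residues never count as V mutations.
    """
    if chain.germline_v is None:
        raise UnsupportedRecordError(f"chain has no germline_v ({chain.locus})")
    v0, v1 = chain.v_span
    observed = chain.sequence[v0:v1]
    if len(observed) != len(chain.germline_v):
        raise UnsupportedRecordError(
            "V span and germline_v lengths differ; indel-bearing records are unsupported"
        )
    count = sum(1 for a, b in zip(observed, chain.germline_v) if a != b)
    chain.v_mutation_count = count
    return count


def _identity(a: str, b: str) -> float:
    """Fraction of matching columns in a global (NW) alignment of a and b."""
    if a == b:
        return 1.0
    res = edlib.align(a, b, mode="NW", task="path")
    align_len = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            align_len += int(num)
            num = ""
    return 1.0 - res["editDistance"] / align_len


def cluster_identity(records, threshold: float = 0.96):
    """Greedy incremental identity clustering of concatenated H+L sequences.

    Records are processed in descending concatenated length (ties broken by
    pair_id); each record joins the first existing cluster whose
    representative it matches at >= ``threshold`` identity, else founds a new
    cluster. Returns the representatives (cluster founders, i.e. longest
    members) in founding order. At threshold 1.0 this is exact deduplication.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r.concat_sequence), r.pair_id))
    reps = []
    for rec in ordered:
        seq = rec.concat_sequence
        for rep in reps:
            if _identity(seq, rep.concat_sequence) >= threshold:
                break
        else:
            reps.append(rec)
    return reps
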