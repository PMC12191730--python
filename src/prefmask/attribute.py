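"""Gradient-based attribution of classifier decisions (AttCAT-style).

For a target class y, each layer l contributes a class-activation term per
token i: the inner product of the layer's hidden state h_i^l with the
gradient of the target logit with respect to it, weighted by the attention
that token receives in that layer (averaged over heads and query positions).
The per-token impact is the sum over layers. Scores follow the display
convention that negative values indicate impact toward the target class;
standard scaling (per sequence, population sd) makes scores comparable
across models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotate import CODE_LABELS, RegionMask
from .nn import ClassifierHead, Encoder, Tensor

__all__ = [
    "AttributionResult",
    "attcat_scores",
    "standardize",
    "region_enrichment",
    "select_explanation_cohort",
    "ENRICHMENT_CAP",
]

ENRICHMENT_CAP = 1e6  # sentinel for an infinite enrichment ratio


@dataclass
class AttributionResult:
    """Per-token impact scores for one input and one target class.

    ``scores[i]`` covers the i-th non-pad token; negative means impact
    toward ``target_class``. ``layer_components`` holds the raw (toward-
    class) per-layer terms before sign flip and weighting summation.
    """

    scores: np.ndarray  # float64, length = n non-pad tokens
    layer_components: list  # per layer: toward-class attention-weighted terms
    target_class: int
    token_positions: np.ndarray  # indices into the encoded input
    sign_convention: str = "negative_toward_target"
    normalization: str = "raw"  # raw | standard-scaled
    meta: dict = field(default_factory=dict)


def attcat_scores(
    model: Encoder,
    head: ClassifierHead,
    encoded,
    target_class: int,
    pooling: str = "cls",
) -> AttributionResult:
    """Impact scores for a single encoded input.

    impact_i = sum over layers of abar_i^l * <h_i^l, d y_target / d h_i^l>,
    where abar_i^l is the mean attention received by token i over heads and
    non-pad query positions; pad positions are excluded throughout, and the
    returned scores are negated so negative = toward the target class.
    """
    length = encoded.layout.total_real
    ids = encoded.token_ids[None, :length]
    flags = encoded.attention_flags[None, :length]
    hidden, captured = model.forward(ids, flags, capture=True)
    if pooling == "cls":
        pooled = hidden.take_position(0, axis=1)
    elif pooling in ("mean", "cdrh3_mean"):
        pos = (encoded.region_mask.residue_positions if pooling == "mean"
               else encoded.region_mask.positions_of("H-CDR3"))
        acc = hidden.take_position(int(pos[0]), axis=1)
        for p in pos[1:]:
            acc = acc + hidden.take_position(int(p), axis=1)
        pooled = acc * (1.0 / len(pos))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    logits = head.logits(pooled)  # (1, n_classes)
    target = logits.take_position(int(target_class), axis=1)
    target.backward()
    positions = np.arange(length)
    impact = np.zeros(length, dtype=np.float64)
    components = []
    for h_l, attn in zip(captured["hidden"], captured["attention"]):
        if h_l.grad is None:
            raise RuntimeError("model did not expose hidden-state gradients")
        # attn: (1, heads, query, key); rows are distributions over keys
        assert attn.min() >= 0.0
        assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-4)
        cat = (h_l.data[0].astype(np.float64) * h_l.grad[0].astype(np.float64)).sum(-1)
        a_bar = attn[0].mean(axis=0).mean(axis=0)  # mean over heads and queries
        components.append(a_bar * cat)
        impact += a_bar * cat
    return AttributionResult(
        scores=-impact,  # negative = toward the target class
        layer_components=components,
        target_class=int(target_class),
        token_positions=positions,
        meta={"pooling": pooling, "pair_id": encoded.pair_id},
    )


def standardize(result: AttributionResult) -> AttributionResult:
    """Standard-scale scores per sequence: (x - mean) / population sd."""
    if result.normalization == "standard-scaled":
        return result  # flag prevents double application
    if len(result.scores) < 2:
        raise ValueError("standard scaling needs at least 2 tokens")
    sd = result.scores.std()
    if sd == 0.0:
        warnings.warn("zero-variance attribution scores; standardized to zeros")
        scaled = np.zeros_like(result.scores)
    else:
        scaled = (result.scores - result.scores.mean()) / sd
    return replace(result, scores=scaled, normalization="standard-scaled")


def region_enrichment(result: AttributionResult, region_mask: RegionMask) -> dict:
    """Mean |impact| per chain-qualified region, CDR-vs-FR and heavy-vs-light
    enrichment ratios (infinite ratios are capped at ``ENRICHMENT_CAP``)."""
    labels = region_mask.labels[result.token_positions]
    magnitude = np.abs(result.scores)
    per_region = {}
    for code in np.unique(labels):
        if code == 0:
            continue
        name = CODE_LABELS[int(code)]
        per_region[name] = float(magnitude[labels == code].mean())

    def _mean(names):
        vals = [per_region[n] for n in names if n in per_region]
        return float(np.mean(vals)) if vals else np.nan

    def _ratio(num, den):
        if np.isnan(num) or np.isnan(den):
            return np.nan
        if den == 0.0:
            return ENRICHMENT_CAP if num > 0 else 1.0
        return min(num / den, ENRICHMENT_CAP)

    cdr = _mean([n for n in per_region if "CDR" in n])
    fr = _mean([n for n in per_region if "FR" in n])
    heavy = _mean([n for n in per_region if n.startswith("H-")])
    light = _mean([n for n in per_region if n.startswith("L-")])
    return {
        "per_region": per_region,
        "cdr_mean": cdr,
        "fr_mean": fr,
        "cdr_fr_ratio": _ratio(cdr, fr),
        "heavy_mean": heavy,
        "light_mean": light,
        "heavy_light_ratio": _ratio(heavy, light),
    }


def select_explanation_cohort(records, probabilities, k: int = 50):
    """Pick ``k`` records spread evenly over the rank range of the mean
    predicted probability, returned in ascending mean-probability order.

    ``probabilities`` maps each record to one probability per classifier
    (array of shape (n_records,) or (n_records, n_models)); ties in the mean
    are broken by pair_id for determinism.
    """
    probs = np.asarray(probabilities, dtype=float)
    mean_prob = probs if probs.ndim == 1 else probs.mean(axis=1)
    if len(mean_prob) != len(records):
        raise ValueError("one probability row per record required")
    order = sorted(range(len(records)),
                   key=lambda i: (mean_prob[i], records[i].pair_id))
    if k >= len(records):
        if k > len(records):
            warnings.warn(f"k={k} exceeds {len(records)} records; returning all")
        return [records[i] for i in order]
    ranks = np.unique(np.round(np.linspace(0, len(records) - 1, k)).astype(int))
    return [records[order[r]] for r in ranks]


def attribution_table(
    result: AttributionResult, encoded, vocab
) -> pd.DataFrame:
    """Long-format table (token, residue, chain, region, scores) for export."""
    labels = encoded.region_mask.labels
    rows = []
    for j, i in enumerate(result.token_positions):
        code = int(labels[i])
        name = CODE_LABELS[code] if code else "special"
        rows.append({
            "token_index": int(i),
            "residue": vocab.token(int(encoded.token_ids[i])),
            "chain": name.split("-")[0] if code else "",
            "region": name.split("-")[1] if code else "special",
            "score": float(result.scores[j]),
        })
    return pd.DataFrame(rows)
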