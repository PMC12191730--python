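"""Preferential and uniform masking probabilities, plan caching, and the
dynamic 80/10/10 corruption collator.

The preferential scheme raises the masking probability of CDR3 residues to
``r_cdr3`` (default 25%) and rescales the probability of every other residue
position so the average over the whole (residue) sequence stays at ``r_avg``
(default 15%)::

    P(x) = r_cdr3                                   if x in CDR3
    P(x) = (r_avg - r_cdr3 * p_hat) / (1 - p_hat)   otherwise

where ``p_hat`` is the fraction of residue positions lying in either chain's
CDR3. For long CDR3s the second branch can go negative; it is then clamped
to zero and the plan flagged, leaving those records slightly above the
target average. Probability construction is a single pass over the dataset;
the resulting plans are cached and reused every epoch, while the Bernoulli
selection itself is re-drawn dynamically each time a batch is collated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotate import RegionMask
from .tokenizer import EncodedPair, Vocabulary

__all__ = [
    "MaskingPlan",
    "CorruptedBatch",
    "preferential_probs",
    "uniform_probs",
    "PlanCache",
    "precompute_plan_cache",
    "collate",
    "DegenerateInputError",
    "StaleCacheError",
    "IGNORE_INDEX",
]

IGNORE_INDEX = -100  # sentinel for positions that do not contribute to the loss

STRATEGIES = ("uniform", "preferential")


class DegenerateInputError(ValueError):
    """The sequence has no non-CDR3 residue positions."""


class StaleCacheError(RuntimeError):
    """A plan cache was built under a different configuration or dataset."""


@dataclass
class MaskingPlan:
    """Per-position masking probabilities for one encoded pair."""

    probs: np.ndarray  # float64, length max_len; 0 at special/pad positions
    r_cdr3: float
    r_avg: float
    p_hat_cdr3: float
    clamped: bool = False

    def mean_residue_prob(self, region_mask: RegionMask) -> float:
        pos = region_mask.residue_positions
        return float(self.probs[pos].mean())


def preferential_probs(
    region_mask: RegionMask, r_cdr3: float = 0.25, r_avg: float = 0.15
) -> MaskingPlan:
    """CDR3 residues at ``r_cdr3``; everything else rescaled to hold ``r_avg``."""
    if not 0.0 < r_avg <= r_cdr3 <= 1.0:
        raise ValueError("need 0 < r_avg <= r_cdr3 <= 1")
    residues = region_mask.residue_positions
    cdr3 = region_mask.cdr3_positions
    n_res, n_cdr3 = len(residues), len(cdr3)
    if n_res == 0:
        raise DegenerateInputError("no residue positions")
    if n_cdr3 == n_res:
        raise DegenerateInputError("no non-CDR3 residue positions (p_hat = 1)")
    p_hat = n_cdr3 / n_res
    non_cdr3_p = (r_avg - r_cdr3 * p_hat) / (1.0 - p_hat)
    clamped = non_cdr3_p <= 0.0 and p_hat > 0.0  # boundary counts as clamped
    non_cdr3_p = max(non_cdr3_p, 0.0)
    probs = np.zeros(len(region_mask.labels), dtype=np.float64)
    probs[residues] = non_cdr3_p
    probs[cdr3] = r_cdr3
    return MaskingPlan(probs, r_cdr3, r_avg, p_hat, clamped)


def uniform_probs(region_mask: RegionMask, r_avg: float = 0.15) -> MaskingPlan:
    """The conventional scheme: every residue position at ``r_avg``."""
    probs = np.zeros(len(region_mask.labels), dtype=np.float64)
    probs[region_mask.residue_positions] = r_avg
    return MaskingPlan(probs, r_avg, r_avg, region_mask.p_hat_cdr3, clamped=False)


def plan_for(encoded: EncodedPair, strategy: str, r_cdr3: float = 0.25,
             r_avg: float = 0.15) -> MaskingPlan:
    if strategy == "uniform":
        return uniform_probs(encoded.region_mask, r_avg)
    if strategy == "preferential":
        return preferential_probs(encoded.region_mask, r_cdr3, r_avg)
    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass
class PlanCache:
    """One masking plan per record, computed once and reused every epoch.

    Keyed by (pair_id, strategy, r_cdr3, r_avg) plus a checksum of the
    dataset's pair-id manifest; any mismatch raises :class:`StaleCacheError`
    rather than silently reusing stale probabilities. ``recompute_count``
    counts probability-vector constructions, so reuse is observable.
    """

    strategy: str
    r_cdr3: float
    r_avg: float
    dataset_checksum: str
    plans: dict = field(default_factory=dict)  # pair_id -> MaskingPlan
    recompute_count: int = 0
    n_clamped: int = 0

    def key(self) -> tuple:
        return (self.strategy, round(self.r_cdr3, 12), round(self.r_avg, 12))

    def get(self, encoded: EncodedPair) -> MaskingPlan:
        plan = self.plans.get(encoded.pair_id)
        if plan is None:
            raise StaleCacheError(f"no cached plan for {encoded.pair_id!r}")
        return plan

    def validate_against(self, dataset) -> None:
        if _dataset_checksum(dataset) != self.dataset_checksum:
            raise StaleCacheError("cache was built for a different dataset")

    # --- persistence: binary probability matrix + JSON manifest -------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pair_ids = list(self.plans)
        mat = np.stack([self.plans[p].probs for p in pair_ids])
        np.save(directory / "plans.npy", mat)
        manifest = {
            "strategy": self.strategy,
            "r_cdr3": self.r_cdr3,
            "r_avg": self.r_avg,
            "dataset_checksum": self.dataset_checksum,
            "pair_ids": pair_ids,
            "p_hat": [self.plans[p].p_hat_cdr3 for p in pair_ids],
            "clamped": [self.plans[p].clamped for p in pair_ids],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, directory, expected_strategy=None, expected_r_cdr3=None,
             expected_r_avg=None) -> "PlanCache":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        for name, expected, got in (
            ("strategy", expected_strategy, manifest["strategy"]),
            ("r_cdr3", expected_r_cdr3, manifest["r_cdr3"]),
            ("r_avg", expected_r_avg, manifest["r_avg"]),
        ):
            if expected is not None and expected != got:
                raise StaleCacheError(f"cache {name}={got!r}, requested {expected!r}")
        mat = np.load(directory / "plans.npy")
        cache = cls(manifest["strategy"], manifest["r_cdr3"], manifest["r_avg"],
                    manifest["dataset_checksum"])
        for i, pid in enumerate(manifest["pair_ids"]):
            cache.plans[pid] = MaskingPlan(
                mat[i], manifest["r_cdr3"], manifest["r_avg"],
                manifest["p_hat"][i], manifest["clamped"][i],
            )
        cache.n_clamped = int(sum(manifest["clamped"]))
        return cache


def _dataset_checksum(dataset) -> str:
    h = hashlib.sha256()
    for enc in dataset:
        h.update(enc.pair_id.encode())
        h.update(bytes([0]))
    return h.hexdigest()


def precompute_plan_cache(dataset, strategy: str, r_cdr3: float = 0.25,
                          r_avg: float = 0.15) -> PlanCache:
    """Single initial pass over ``dataset`` building every record's plan."""
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    cache = PlanCache(strategy, r_cdr3, r_avg, _dataset_checksum(dataset))
    for enc in dataset:
        plan = plan_for(enc, strategy, r_cdr3, r_avg)
        cache.recompute_count += 1
        cache.n_clamped += int(plan.clamped)
        cache.plans[enc.pair_id] = plan
    return cache


@dataclass
class CorruptedBatch:
    """A batch after dynamic corruption.

    ``corruption_kind`` records which branch each selected position took:
    0 = replaced by <mask>, 1 = replaced by a random residue token,
    2 = left unchanged, -1 = not selected.
    """

    input_ids: np.ndarray  # int64 (B, L)
    target_ids: np.ndarray  # int64 (B, L); IGNORE_INDEX off-target
    selection_mask: np.ndarray  # bool (B, L)
    corruption_kind: np.ndarray  # int8 (B, L)
    rng_state: dict | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selection_mask.sum())


def collate(batch, plans, vocab: Vocabulary, rng: np.random.Generator) -> CorruptedBatch:
    """Dynamically corrupt a batch of encoded pairs.

    Each residue position is selected independently with its plan
    probability; of the selected positions, 80% become <mask>, 10% a random
    residue token (never a special), and 10% stay unchanged. Targets hold
    the original token at selected positions and the ignore sentinel
    elsewhere. Fresh randomness every call gives dynamic masking.
    """
    if isinstance(plans, PlanCache):
        plans = [plans.get(enc) for enc in batch]
    if len(plans) != len(batch):
        raise ValueError("plans must correspond 1:1 with batch members")
    ids = np.stack([enc.token_ids for enc in batch]).astype(np.int64)
    probs = np.stack([plan.probs for plan in plans])
    if probs.shape != ids.shape:
        raise ValueError(
            f"plan/encoding length mismatch: {probs.shape} vs {ids.shape}"
        )
    state = rng.bit_generator.state
    selected = rng.random(ids.shape) < probs
    u = rng.random(ids.shape)
    kind = np.full(ids.shape, -1, dtype=np.int8)
    kind[selected & (u < 0.8)] = 0
    kind[selected & (u >= 0.8) & (u < 0.9)] = 1
    kind[selected & (u >= 0.9)] = 2
    targets = np.where(selected, ids, IGNORE_INDEX)
    corrupted = ids.copy()
    corrupted[kind == 0] = vocab.mask_id
    n_random = int((kind == 1).sum())
    if n_random:
        corrupted[kind == 1] = rng.choice(vocab.residue_ids, size=n_random)
    return CorruptedBatch(corrupted, targets, selected, kind, rng_state=state)
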