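"""MLM pre-training harness with region-partitioned, uniform-masked validation.

Two strategies are trained from the same code path: conventional uniform
masking and preferential CDR3 masking. Validation always uses the uniform
strategy with a fixed masking seed, so both models are scored on the very
same corrupted positions, and each masked position's cross-entropy is
assigned to its chain-agnostic region bucket (FR pools all eight framework
regions of both chains; CDR1/CDR2/CDR3 pool the two chains' loops).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .masking import IGNORE_INDEX, PlanCache, collate, precompute_plan_cache
from .nn import AdamW, Encoder, ModelConfig, cross_entropy_logits, linear_warmup_decay
from .tokenizer import Vocabulary, build_vocab

__all__ = [
    "ModelConfig",
    "TrainSchedule",
    "LossTrace",
    "count_parameters",
    "train_mlm",
    "validate",
    "select_checkpoint",
    "DivergenceError",
]

REGION_BUCKETS = ("FR", "CDR1", "CDR2", "CDR3")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class TrainSchedule:
    total_steps: int
    batch_size: int
    peak_lr: float
    warmup_steps: int
    decay: str = "linear"
    checkpoint_interval: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.warmup_steps >= self.total_steps:
            raise ValueError("warmup_steps must be < total_steps")

    @classmethod
    def paper(cls, seed: int = 0) -> "TrainSchedule":
        return cls(500_000, 256, 1e-4, 30_000, "linear", 50_000, seed)

    @classmethod
    def tiny(cls, seed: int = 0) -> "TrainSchedule":
        return cls(2000, 32, 1e-3, 100, "linear", 500, seed)


def count_parameters(config: ModelConfig) -> int:
    """Exact trainable parameter count from the architecture's tensor census."""
    from .nn.transformer import parameter_shapes

    return int(sum(math.prod(shape) for _, shape in parameter_shapes(config)))


@dataclass
class LossTrace:
    """Per-step training loss and per-eval region-partitioned validation loss."""

    train_steps: list = field(default_factory=list)
    train_losses: list = field(default_factory=list)
    evals: list = field(default_factory=list)  # {step, overall, FR..., counts}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": s, "split": "train", "region": "all", "loss": l}
            for s, l in zip(self.train_steps, self.train_losses)
        ]
        for ev in self.evals:
            rows.append({"step": ev["step"], "split": "val", "region": "all",
                         "loss": ev["overall"]})
            for region in REGION_BUCKETS:
                if region in ev:
                    rows.append({"step": ev["step"], "split": "val",
                                 "region": region, "loss": ev[region]})
        return pd.DataFrame(rows, columns=["step", "split", "region", "loss"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _crop(batch_arrays, length: int):
    return [a[:, :length] for a in batch_arrays]


def _mlm_loss(model: Encoder, corrupted, flags) -> tuple:
    """Cross-entropy over the selected positions of a corrupted batch."""
    B, L = corrupted.input_ids.shape
    hidden = model.forward(corrupted.input_ids, flags)
    flat_targets = corrupted.target_ids.reshape(-1)
    rows = np.flatnonzero(flat_targets != IGNORE_INDEX)
    picked = hidden.reshape(B * L, model.config.hidden_size).gather_rows(rows)
    logits = model.mlm_logits(picked)
    return cross_entropy_logits(logits, flat_targets[rows]), len(rows)


def validate(
    model: Encoder,
    val_dataset,
    vocab: Vocabulary | None = None,
    mask_seed: int = 1234,
    batch_size: int = 64,
    r_avg: float = 0.15,
) -> dict:
    """Uniform-masked validation, partitioned by chain-agnostic region.

    The masking RNG is re-seeded with ``mask_seed`` on every call, so any two
    models evaluated with the same seed see bit-identical masked positions.
    Returns {"overall", "n", and one entry per non-empty region bucket plus
    "<region>_n" counts}; empty buckets are absent, never reported as 0.
    """
    vocab = vocab or build_vocab()
    plans = precompute_plan_cache(val_dataset, "uniform", r_avg=r_avg)
    rng = np.random.default_rng(mask_seed)
    sums = {b: 0.0 for b in REGION_BUCKETS}
    counts = {b: 0 for b in REGION_BUCKETS}
    for start in range(0, len(val_dataset), batch_size):
        chunk = val_dataset[start : start + batch_size]
        corrupted = collate(chunk, plans, vocab, rng)
        length = max(enc.layout.total_real for enc in chunk)
        ids, targets, flags = _crop(
            [corrupted.input_ids, corrupted.target_ids,
             np.stack([e.attention_flags for e in chunk])], length)
        hidden = model.forward(ids, flags)
        logits = model.mlm_logits(hidden).data  # (B, L, V)
        z = logits - logits.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        for b, enc in enumerate(chunk):
            sel = np.flatnonzero(targets[b] != IGNORE_INDEX)
            for pos in sel:
                bucket = enc.region_mask.agnostic_bucket(int(pos))
                if bucket is None:
                    continue
                sums[bucket] += -float(logp[b, pos, targets[b, pos]])
                counts[bucket] += 1
    total_n = sum(counts.values())
    out = {"n": total_n}
    if total_n:
        out["overall"] = sum(sums.values()) / total_n
    for bucket in REGION_BUCKETS:
        if counts[bucket]:
            out[bucket] = sums[bucket] / counts[bucket]
            out[f"{bucket}_n"] = counts[bucket]
    return out


def train_mlm(
    dataset,
    strategy: str,
    model_config: ModelConfig,
    schedule: TrainSchedule,
    val_dataset=None,
    plan_cache: PlanCache | None = None,
    vocab: Vocabulary | None = None,
    out_dir=None,
    r_cdr3: float = 0.25,
    r_avg: float = 0.15,
    val_mask_seed: int = 1234,
    log_every: int = 10,
) -> tuple:
    """Train one MLM model; returns (model, LossTrace).

    Loss is cross-entropy over the collator-selected positions only.
    Checkpoints (weights + config + eval) are written every
    ``checkpoint_interval`` steps when ``out_dir`` is given, and an eval is
    always recorded at those steps and at the final step.
    """
    vocab = vocab or build_vocab()
    if plan_cache is None:
        plan_cache = precompute_plan_cache(dataset, strategy, r_cdr3, r_avg)
    else:
        if plan_cache.strategy != strategy:
            raise ValueError("plan cache strategy mismatch")
        plan_cache.validate_against(dataset)
    model = Encoder(model_config, seed=schedule.seed)
    opt = AdamW(model.params, lr=schedule.peak_lr)
    rng = np.random.default_rng(schedule.seed + 7919)
    trace = LossTrace()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "run_manifest.json").write_text(json.dumps({
            "strategy": strategy, "r_cdr3": r_cdr3, "r_avg": r_avg,
            "seed": schedule.seed, "val_mask_seed": val_mask_seed,
            "model": model_config.__dict__, "schedule": schedule.__dict__,
        }, default=str))
    flags_all = np.stack([e.attention_flags for e in dataset])

    def _eval(step: int) -> None:
        if val_dataset:
            ev = validate(model, val_dataset, vocab, mask_seed=val_mask_seed, r_avg=r_avg)
            ev["step"] = step
            trace.evals.append(ev)
        if out_dir is not None:
            model.save(out_dir / f"checkpoint_{step:07d}.npz")

    for step in range(1, schedule.total_steps + 1):
        idx = rng.choice(len(dataset), size=schedule.batch_size,
                         replace=len(dataset) < schedule.batch_size)
        chunk = [dataset[i] for i in idx]
        corrupted = collate(chunk, plan_cache, vocab, rng)
        length = max(enc.layout.total_real for enc in chunk)
        corrupted.input_ids, corrupted.target_ids = _crop(
            [corrupted.input_ids, corrupted.target_ids], length)
        flags = flags_all[idx][:, :length]
        model.zero_grad()
        loss, n_sel = _mlm_loss(model, corrupted, flags)
        value = float(loss.data)
        if not np.isfinite(value):
            if out_dir is not None:
                model.save(out_dir / "diverged_snapshot.npz")
            raise DivergenceError(f"non-finite loss at step {step}")
        loss.backward()
        opt.step(lr=linear_warmup_decay(step - 1, schedule.total_steps,
                                        schedule.warmup_steps, schedule.peak_lr))
        if step == 1 or step % log_every == 0 or step == schedule.total_steps:
            trace.train_steps.append(step)
            trace.train_losses.append(value)
        if step % schedule.checkpoint_interval == 0 or step == schedule.total_steps:
            _eval(step)
    if out_dir is not None:
        trace.to_csv(out_dir / "loss_trace.csv")
    return model, trace


def select_checkpoint(trace: LossTrace) -> int:
    """Checkpointed step with the minimum overall validation loss (ties: earliest)."""
    if not trace.evals:
        raise ValueError("no evaluated checkpoints in trace")
    best = min(trace.evals, key=lambda ev: (ev["overall"], ev["step"]))
    return int(best["step"])
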