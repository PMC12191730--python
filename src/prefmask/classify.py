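"""Native-vs-shuffled pairing and binding-specificity classification.

Dataset construction (donor-wise light-chain shuffling with collision
filtering and exact class balance), stratified 5-fold cross-validation, and
frozen-base classifier-head training: the encoder's weights are untouched
(verified by checksum) and only a single affine head on a pooled
representation is optimized, so the task scores reflect the quality of the
pre-trained embeddings. Also provides the mutation-count grid analyses that
explain what drives native-pair classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .nn import AdamW, ClassifierHead, Encoder, Tensor, cross_entropy_logits
from .nn.optim import linear_warmup_decay
from .records import PairedRecord
from .tokenizer import Vocabulary, build_vocab, encode_record

__all__ = [
    "ClassifierDataset",
    "MetricReport",
    "MutationGrid",
    "HeadConfig",
    "make_shuffled_pairs",
    "stratified_kfold",
    "train_head",
    "compute_metrics",
    "mutation_grid",
    "split_by_pairing_type",
    "embed_records",
]

POSITIVE_LABEL = {"pairing": "shuffled", "specificity": "positive"}


@dataclass
class ClassifierDataset:
    """Labeled paired records plus their cross-validation fold assignment."""

    records: list
    task: str  # pairing | specificity
    folds: list | None = None  # [(train_idx, test_idx)] after stratified_kfold
    provenance: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        positive = POSITIVE_LABEL[self.task]
        attr = "pairing_label" if self.task == "pairing" else "specificity_label"
        return np.array(
            [1 if getattr(r, attr) == positive else 0 for r in self.records]
        )

    def class_counts(self) -> tuple[int, int]:
        y = self.labels
        return int((y == 0).sum()), int((y == 1).sum())


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A permutation of range(n) with no fixed points (n >= 2)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_shuffled_pairs(
    records, shuffle_fraction: float = 0.5, rng: np.random.Generator | None = None
) -> ClassifierDataset:
    """Build a class-balanced native-vs-shuffled pairing dataset.

    Per donor, ``shuffle_fraction`` of the pairs are sampled and their light
    chains permuted by a derangement; the rest stay native. Shuffled pairs
    whose heavy+light sequences coincide with any native pair (light-chain
    redundancy) are filtered out and counted, and the larger class is then
    trimmed at random so the final classes balance exactly.
    """
    rng = rng or np.random.default_rng(0)
    native, shuffled = [], []
    n_singleton = 0
    by_donor: dict[str, list] = {}
    for rec in records:
        by_donor.setdefault(rec.donor_id, []).append(rec)
    for donor in sorted(by_donor):
        group = by_donor[donor]
        n_shuf = int(len(group) * shuffle_fraction)
        chosen = rng.choice(len(group), size=n_shuf, replace=False)
        chosen_set = set(int(i) for i in chosen)
        if len(chosen_set) < 2:
            n_singleton += len(chosen_set)
            chosen_set = set()  # a lone pair cannot be deranged; keep native
        sampled = [group[i] for i in sorted(chosen_set)]
        for i, rec in enumerate(group):
            if i not in chosen_set:
                native.append(rec.copy())
        if sampled:
            perm = _derangement(len(sampled), rng)
            for i, rec in enumerate(sampled):
                partner = sampled[int(perm[i])]
                new = PairedRecord(
                    pair_id=f"{rec.pair_id}x{partner.pair_id}",
                    heavy=rec.heavy.copy(),
                    light=partner.light.copy(),
                    donor_id=donor,
                    cell_type=rec.cell_type if rec.cell_type == partner.cell_type
                    else "mixed",
                    pairing_label="shuffled",
                )
                shuffled.append(new)
    native_keys = {(r.heavy.sequence, r.light.sequence) for r in records}
    kept_shuffled = [
        r for r in shuffled if (r.heavy.sequence, r.light.sequence) not in native_keys
    ]
    n_collisions = len(shuffled) - len(kept_shuffled)
    # exact balance: trim the larger class at random
    n_keep = min(len(native), len(kept_shuffled))
    trimmed = {"native": 0, "shuffled": 0}
    if len(native) > n_keep:
        keep = rng.choice(len(native), size=n_keep, replace=False)
        trimmed["native"] = len(native) - n_keep
        native = [native[i] for i in sorted(keep)]
    if len(kept_shuffled) > n_keep:
        keep = rng.choice(len(kept_shuffled), size=n_keep, replace=False)
        trimmed["shuffled"] = len(kept_shuffled) - n_keep
        kept_shuffled = [kept_shuffled[i] for i in sorted(keep)]
    return ClassifierDataset(
        records=native + kept_shuffled,
        task="pairing",
        provenance={
            "n_input": len(records),
            "n_native": len(native),
            "n_shuffled": len(kept_shuffled),
            "n_collisions_filtered": n_collisions,
            "n_singleton_returned": n_singleton,
            "n_trimmed": trimmed,
        },
    )


def stratified_kfold(dataset: ClassifierDataset, k: int = 5, seed: int = 0) -> list:
    """Deterministic stratified k-fold split; per-fold label ratio within one
    record of the global ratio."""
    y = dataset.labels
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} records")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (train.copy(), test.copy()) for train, test in splitter.split(np.zeros(len(y)), y)
    ]
    dataset.folds = folds
    return folds


@dataclass
class HeadConfig:
    """Classifier-head optimization settings."""

    epochs: int = 50
    batch_size: int = 256
    peak_lr: float = 1e-5
    warmup_ratio: float = 0.1
    pooling: str = "cls"  # cls | mean | cdrh3_mean

    @classmethod
    def paper(cls, pooling: str = "cls") -> "HeadConfig":
        return cls(50, 256, 1e-5, 0.1, pooling)

    @classmethod
    def tiny(cls, pooling: str = "cls") -> "HeadConfig":
        # desk-scale: small feature dim and dataset need a hotter head
        return cls(epochs=120, batch_size=64, peak_lr=0.02, warmup_ratio=0.1,
                   pooling=pooling)


def embed_records(
    model: Encoder,
    records,
    vocab: Vocabulary | None = None,
    pooling: str = "cls",
    batch_size: int = 64,
    max_len: int | None = None,
) -> np.ndarray:
    """Pooled frozen-base representations, one row per record.

    "cls" pools the leading <cls> position's final hidden state; "mean"
    averages the final hidden states over residue positions; "cdrh3_mean"
    averages over heavy-CDR3 positions only (a region-restricted pooling for
    motif-driven tasks at small model scale, where whole-sequence pooling
    dilutes a short CDRH3 signal below germline-choice variance).
    """
    vocab = vocab or build_vocab()
    max_len = max_len or model.config.max_len
    encoded = [encode_record(r, vocab, max_len=max_len) for r in records]
    out = np.zeros((len(records), model.config.hidden_size), dtype=np.float32)
    for start in range(0, len(encoded), batch_size):
        chunk = encoded[start : start + batch_size]
        length = max(e.layout.total_real for e in chunk)
        ids = np.stack([e.token_ids[:length] for e in chunk])
        flags = np.stack([e.attention_flags[:length] for e in chunk])
        hidden = model.forward(ids, flags).data
        for i, enc in enumerate(chunk):
            if pooling == "cls":
                out[start + i] = hidden[i, 0]
            elif pooling == "mean":
                pos = enc.region_mask.residue_positions
                out[start + i] = hidden[i, pos].mean(axis=0)
            elif pooling == "cdrh3_mean":
                pos = enc.region_mask.positions_of("H-CDR3")
                out[start + i] = hidden[i, pos].mean(axis=0)
            else:
                raise ValueError(f"unknown pooling {pooling!r}")
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class MetricReport:
    """Per-fold test metrics with a mean +/- SE summary over the 5 folds."""

    frame: pd.DataFrame  # columns: fold, accuracy, auc, aupr, f1, mcc
    curves: list = field(default_factory=list)  # per-fold per-epoch accuracy

    def summary(self) -> pd.DataFrame:
        metrics = [c for c in self.frame.columns if c != "fold"]
        mean = self.frame[metrics].mean()
        se = self.frame[metrics].std(ddof=1) / np.sqrt(len(self.frame))
        return pd.DataFrame({"mean": mean, "se": se})

    def to_csv(self, path) -> None:
        long = self.frame.melt(id_vars="fold", var_name="metric", value_name="value")
        summ = self.summary().reset_index().rename(columns={"index": "metric"})
        rows = [long]
        for stat in ("mean", "se"):
            rows.append(pd.DataFrame({
                "fold": stat, "metric": summ["metric"], "value": summ[stat]}))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def compute_metrics(scores, labels) -> dict:
    """Threshold-0.5 accuracy/F1/MCC plus threshold-free AUC/AUPR.

    ``scores`` are positive-class probabilities. With single-class labels the
    ranking metrics are undefined and reported as absent (None).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= 0.5).astype(int)
    out = {
        "accuracy": float(accuracy_score(labels, pred)),
        "f1": float(f1_score(labels, pred, zero_division=0)),
        "mcc": float(matthews_corrcoef(labels, pred)),
    }
    if len(np.unique(labels)) < 2:
        out["auc"] = None
        out["aupr"] = None
    else:
        out["auc"] = float(roc_auc_score(labels, scores))
        out["aupr"] = float(average_precision_score(labels, scores))
    return out


def train_head(
    base_model: Encoder,
    dataset: ClassifierDataset,
    config: HeadConfig | None = None,
    vocab: Vocabulary | None = None,
    seed: int = 0,
    max_len: int | None = None,
) -> tuple:
    """Train one affine head per CV fold on frozen-base pooled embeddings.

    Returns ``(heads, report, oof_probs)`` where ``oof_probs[i]`` is the
    positive-class probability for record ``i`` predicted by the single head
    whose held-out fold contains it — no record is ever scored by a head
    that saw it in training. The base model is verified bit-identical before
    and after (frozen-base contract).
    """
    config = config or HeadConfig.tiny()
    if dataset.folds is None:
        stratified_kfold(dataset, k=5, seed=seed)
    checksum_before = base_model.checksum()
    features = embed_records(
        base_model, dataset.records, vocab, pooling=config.pooling, max_len=max_len
    )
    y = dataset.labels
    rng = np.random.default_rng(seed)
    heads, fold_rows, curves = [], [], []
    oof = np.full(len(y), np.nan)
    for fold_i, (train_idx, test_idx) in enumerate(dataset.folds):
        assert len(set(train_idx) & set(test_idx)) == 0, "fold leakage"
        head = ClassifierHead(features.shape[1], 2, seed=seed + fold_i)
        opt = AdamW(head.params, lr=config.peak_lr, weight_decay=0.0)
        n_train = len(train_idx)
        steps_per_epoch = max(1, n_train // config.batch_size)
        total_steps = config.epochs * steps_per_epoch
        warmup = max(1, int(config.warmup_ratio * total_steps))
        step = 0
        curve = []
        for _ in range(config.epochs):
            order = rng.permutation(train_idx)
            for s in range(steps_per_epoch):
                idx = order[s * config.batch_size : (s + 1) * config.batch_size]
                if len(idx) == 0:
                    continue
                opt.zero_grad()
                loss = cross_entropy_logits(
                    head.logits(Tensor(features[idx])), y[idx]
                )
                loss.backward()
                opt.step(lr=linear_warmup_decay(step, total_steps, warmup,
                                                config.peak_lr))
                step += 1
            test_probs = _softmax(head.logits(Tensor(features[test_idx])).data)[:, 1]
            curve.append(float(accuracy_score(y[test_idx],
                                              (test_probs >= 0.5).astype(int))))
        probs = _softmax(head.logits(Tensor(features[test_idx])).data)[:, 1]
        oof[test_idx] = probs
        fold_rows.append({"fold": fold_i, **compute_metrics(probs, y[test_idx])})
        curves.append(curve)
        heads.append(head)
    assert base_model.checksum() == checksum_before, "base model weights changed"
    report = MetricReport(pd.DataFrame(fold_rows), curves=curves)
    return heads, report, oof


@dataclass
class MutationGrid:
    """Counts and mean shuffled-class probability over (m_H, m_L) cells."""

    frame: pd.DataFrame  # columns: m_h, m_l, count, mean_shuffled_prob, truth

    def counts(self, truth: str) -> pd.DataFrame:
        return self.frame[self.frame.truth == truth]

    def total(self, truth: str) -> int:
        return int(self.counts(truth)["count"].sum())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def mutation_grid(predictions, records) -> MutationGrid:
    """Aggregate shuffled-class probabilities by chain-specific mutation counts,
    with separate grids for true-native and true-shuffled pairs."""
    rows = [
        {
            "m_h": r.heavy.v_mutation_count,
            "m_l": r.light.v_mutation_count,
            "truth": r.pairing_label,
            "prob": float(p),
        }
        for p, r in zip(predictions, records)
    ]
    df = pd.DataFrame(rows, columns=["m_h", "m_l", "truth", "prob"])
    if df.empty:
        return MutationGrid(pd.DataFrame(
            columns=["m_h", "m_l", "count", "mean_shuffled_prob", "truth"]))
    grid = (
        df.groupby(["truth", "m_h", "m_l"])
        .agg(count=("prob", "size"), mean_shuffled_prob=("prob", "mean"))
        .reset_index()[["m_h", "m_l", "count", "mean_shuffled_prob", "truth"]]
    )
    return MutationGrid(grid)


def split_by_pairing_type(predictions, records, threshold: float = 0.5) -> dict:
    """Accuracy for "same" (both chains unmutated or both mutated) versus
    "different" (exactly one chain mutated) pairs. Empty groups are absent."""
    groups: dict[str, list] = {"same": [], "different": []}
    for p, r in zip(predictions, records):
        same = (r.heavy.v_mutation_count > 0) == (r.light.v_mutation_count > 0)
        correct = (float(p) >= threshold) == (r.pairing_label == "shuffled")
        groups["same" if same else "different"].append(correct)
    return {
        name: {"accuracy": float(np.mean(vals)), "n": len(vals)}
        for name, vals in groups.items()
        if vals
    }
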