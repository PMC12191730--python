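"""Build a native-vs-shuffled pairing dataset and inspect its mutation grids.

Shuffling light chains across cells of the same donor breaks the shared
maturation history of native pairs: natives concentrate near the
m_H = m_L diagonal while shuffled pairs spread out. The script prints the
grid statistics and trains frozen-base classifier heads with 5-fold CV.
"""

import numpy as np

from prefmask.annotate import filter_dataset
from prefmask.classify import (
    HeadConfig,
    make_shuffled_pairs,
    mutation_grid,
    stratified_kfold,
    train_head,
)
from prefmask.pretrain import ModelConfig, TrainSchedule, train_mlm
from prefmask.sim import SimConfig, simulate_repertoire
from prefmask.tokenizer import build_vocab, encode_record

vocab = build_vocab()
records = simulate_repertoire(SimConfig(n_pairs=400, naive_fraction=0.3, seed=6))
kept, _ = filter_dataset(records)

dataset = make_shuffled_pairs(kept, 0.5, np.random.default_rng(7))
print("dataset:", dataset.provenance)

grid = mutation_grid(np.full(len(dataset.records), 0.5), dataset.records).frame
for truth in ("native", "shuffled"):
    sub = grid[grid.truth == truth]
    diff = np.repeat((sub.m_h - sub.m_l).abs().values, sub["count"].values)
    print(f"{truth:>9}: mean |m_H - m_L| = {diff.mean():.2f}, var = {diff.var():.2f}")
print("-> shuffled pairs adopt the wider mutation distribution.")

encoded = [encode_record(r, vocab) for r in kept]
schedule = TrainSchedule(total_steps=100, batch_size=16, peak_lr=1e-3,
                         warmup_steps=10, checkpoint_interval=100, seed=0)
base, _ = train_mlm(encoded, "preferential", ModelConfig.tiny(), schedule,
                    vocab=vocab)
stratified_kfold(dataset, k=5, seed=0)
_, report, _ = train_head(base, dataset, HeadConfig.tiny(pooling="mean"),
                          vocab=vocab, seed=0)
print("\npairing head metrics (mean +/- SE over 5 folds):")
print(report.summary())
print("-> near-chance at this scale: an affine head on a whole-sequence")
print("   pooled tiny model cannot represent the |m_H - m_L| comparison;")
print("   the mutation grids above carry the signal a deeper base exploits.")
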