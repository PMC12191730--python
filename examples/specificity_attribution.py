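"""Classify implanted-motif binding specificity and attribute the decision.

Positives carry a 5-mer motif in their heavy CDR3. A tiny MLM base is
pre-trained briefly, a single affine head is trained on frozen CDRH3-pooled
embeddings with 5-fold CV, and AttCAT-style impact scores are computed for a
few positives to show where the classifier looks.
"""

import numpy as np

from prefmask.annotate import filter_dataset
from prefmask.attribute import attcat_scores, region_enrichment, standardize
from prefmask.classify import (
    ClassifierDataset,
    HeadConfig,
    stratified_kfold,
    train_head,
)
from prefmask.pretrain import ModelConfig, TrainSchedule, train_mlm
from prefmask.sim import SimConfig, implant_specificity, simulate_repertoire
from prefmask.tokenizer import build_vocab, encode_record

vocab = build_vocab()
config = SimConfig(n_pairs=300, motif_implant_prob=1.0, seed=5)
records = simulate_repertoire(config)
records = implant_specificity(records, config, np.random.default_rng(42))
kept, _ = filter_dataset(records)
encoded = [encode_record(r, vocab) for r in kept]

schedule = TrainSchedule(total_steps=120, batch_size=16, peak_lr=1e-3,
                         warmup_steps=12, checkpoint_interval=120, seed=0)
base, _ = train_mlm(encoded, "preferential", ModelConfig.tiny(), schedule,
                    vocab=vocab)

dataset = ClassifierDataset(records=kept, task="specificity")
stratified_kfold(dataset, k=5, seed=0)
heads, report, oof = train_head(base, dataset,
                                HeadConfig.tiny(pooling="cdrh3_mean"),
                                vocab=vocab, seed=0)
print("specificity head metrics (mean +/- SE over 5 folds):")
print(report.summary())

positives = [r for r in dataset.records if r.specificity_label == "positive"][:4]
print(f"\nAttCAT |impact| by region ({config.motif} implanted in heavy CDR3):")
for rec in positives:
    enc = encode_record(rec, vocab)
    result = standardize(attcat_scores(base, heads[0], enc, 1,
                                       pooling="cdrh3_mean"))
    summary = region_enrichment(result, enc.region_mask)
    print(f"  {rec.pair_id}: H-CDR3 {summary['per_region']['H-CDR3']:.2f} "
          f"vs FR mean {summary['fr_mean']:.2f} "
          f"(CDR/FR ratio {summary['cdr_fr_ratio']:.1f})")
print("-> high-impact residues concentrate where the motif was implanted.")
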