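"""Train one uniform-masked and one preferentially-masked model and compare
their region-partitioned validation losses.

A single-seed, reduced-step version of the comparison in the test suite
(about two minutes on one CPU). Both models are validated under uniform
masking with identical masked positions, so the CDR3 columns are directly
comparable.
"""

from prefmask.annotate import filter_dataset
from prefmask.pretrain import ModelConfig, TrainSchedule, train_mlm
from prefmask.sim import SimConfig, simulate_repertoire
from prefmask.tokenizer import build_vocab, encode_record

vocab = build_vocab()
records = simulate_repertoire(SimConfig(n_pairs=320, seed=11))
kept, _ = filter_dataset(records)
encoded = [encode_record(r, vocab) for r in kept]
val, train = encoded[:64], encoded[64:]

results = {}
for strategy in ("uniform", "preferential"):
    schedule = TrainSchedule(total_steps=200, batch_size=16, peak_lr=1e-3,
                             warmup_steps=20, checkpoint_interval=200, seed=0)
    _, trace = train_mlm(train, strategy, ModelConfig.tiny(), schedule,
                         val_dataset=val, vocab=vocab)
    results[strategy] = trace.evals[-1]
    ev = trace.evals[-1]
    print(f"{strategy:>13}: overall {ev['overall']:.4f}  FR {ev['FR']:.4f}  "
          f"CDR1 {ev['CDR1']:.4f}  CDR2 {ev['CDR2']:.4f}  CDR3 {ev['CDR3']:.4f}")

delta = results["uniform"]["CDR3"] - results["preferential"]["CDR3"]
print(f"\nCDR3 validation loss difference (uniform - preferential): {delta:+.4f}")
print("-> a positive value means the preferential model extracts more from the")
print("   junctional region at the same step count. At this very short run the")
print("   region ordering is still settling; with more steps the templated")
print("   regions drop below the partly non-templated CDR3 for both models.")
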