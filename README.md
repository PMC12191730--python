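# prefmask

Preferential CDR3 masking for antibody language-model pre-training, with the
full surrounding pipeline at desk scale: a seeded paired-repertoire
simulator, region annotation and QC, the 26-token paired-chain tokenizer, an
encoder-only transformer (rotary positions, pre-layer norm) with its MLM
training harness, region-partitioned evaluation, native-pairing and
binding-specificity classification on frozen embeddings, and gradient-based
attribution of classifier decisions.

## The problem

Antibody variable domains are mostly germline-templated; the CDR3 loop spans
the V(D)J junction, carries non-templated residues, and dominates antigen
binding — and it is exactly the region masked-language models learn worst
under conventional uniform masking, because most training signal lands on
easy templated positions. The remedy implemented here raises the masking
probability of CDR3 residues while rescaling the rest of the sequence so the
average stays at the conventional rate:

```
P(x) = r_cdr3                                  x ∈ CDR3      (default 0.25)
P(x) = (r_avg − r_cdr3·p̂) / (1 − p̂)            x ∉ CDR3      (r_avg = 0.15)
```

where `p̂` is the fraction of residue positions in either chain's CDR3. Both
strategies then predict the same expected number of tokens per epoch, while
CDR3 receives ~1.67× the training signal. The library implements this scheme
(with single-pass plan caching and a dynamic 80/10/10 corruption collator),
trains uniform- and preferentially-masked encoders side by side, and
evaluates them on identically-masked validation sets, per antibody region.

## Worked example

```python
import numpy as np
from prefmask.sim import SimConfig, simulate_repertoire
from prefmask.tokenizer import build_vocab, encode_record
from prefmask.masking import preferential_probs, precompute_plan_cache, collate

vocab = build_vocab()
records = simulate_repertoire(SimConfig(n_pairs=64, seed=1))
encoded = [encode_record(r, vocab) for r in records]

plan = preferential_probs(encoded[0].region_mask)
cache = precompute_plan_cache(encoded, "preferential")
batch = collate(encoded, cache, vocab, np.random.default_rng(0))
```

Running `examples/masking_scheme.py` (which does the above and prints the
arithmetic) gives:

```
CDR3 fraction p_hat = 0.0913
CDR3 rate 0.25, non-CDR3 rate 0.1400
mean over residue positions = 0.150000000000
one collated batch: 2269 positions selected
  <mask>: 0.800
  random residue: 0.094
  unchanged: 0.106
```

The first three lines are the masking equation at work: this pair's CDR3s
cover 9.13% of its residues, so non-CDR3 positions drop to 14.0% and the
sequence-wide average is held at exactly 15%. The last block is one dynamic
corruption draw: of the selected positions, ~80% became `<mask>`, ~10% a
random residue token, ~10% were left unchanged.

The other scripts in `examples/` each exercise one capability end to end and
print what the numbers mean: `simulate_repertoire.py` (junction and
co-maturation statistics; e.g. corr(m_H, m_L) = 0.87 at defaults),
`pretrain_directional.py` (uniform vs preferential region losses on shared
validation masks), `pairing_task.py` (shuffled-pair construction and
mutation grids), `specificity_attribution.py` (motif-implant classification
and AttCAT-style region enrichment).

A thin CLI mirrors the pipeline for shell use
(`prefmask simulate|annotate|pretrain|evaluate|pairtask|spectask|explain`,
each with `--config/--seed/--out/--preset`); every run writes a manifest
with the resolved configuration and seeds.

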