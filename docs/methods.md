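# Methods

## The model and the question it serves

Antibody variable domains are assembled by V(D)J recombination and refined by
somatic hypermutation (SHM). Most of the sequence is copied from germline
segments; the third complementarity-determining region (CDR3) spans the
V(D)J junction, carries non-templated insertions, and dominates antigen
contact. Masked language models (MLMs) trained on antibody sequences with the
conventional uniform 15% masking therefore spend most of their training
signal on easily-predicted templated residues.

`prefmask` implements the alternative: **preferential masking**. For a paired
heavy/light input with region annotations, the per-position masking
probability is

```
P(x) = r_cdr3                                  if x lies in either CDR3
P(x) = (r_avg − r_cdr3·p̂) / (1 − p̂)            otherwise
```

with `r_cdr3 = 0.25` (a `0.35` variant is supported), `r_avg = 0.15`, and
`p̂` the fraction of residue positions in CDR3. The second branch is chosen
so the mean over residue positions is exactly `r_avg`; consequently both
strategies predict the same expected number of tokens per epoch and CDR3
positions carry `r_cdr3/r_avg ≈ 1.67×` the training signal. For very long
CDR3s the non-CDR3 branch can reach zero; it is clamped there, the plan is
flagged, and the record's average sits slightly above target (the count of
clamped plans is surfaced by the plan cache and the CLI).

Two numerical choices to note:

* the 15% average is defined over **residue** positions; special and pad
  tokens always have probability 0 (masking them is never meaningful);
* probabilities are computed once per record in a single dataset pass and
  cached (`PlanCache`), keyed by `(pair_id, strategy, r_cdr3, r_avg)` plus a
  dataset checksum; a mismatch raises rather than silently reusing stale
  probabilities. Selection itself is re-drawn at every collation (dynamic
  masking), with the 80/10/10 mask/random/keep corruption applied
  per-position. Random replacements are drawn uniformly from the 21 residue
  tokens — never special tokens, which would corrupt the layout — and may
  coincide with the original token, so the collator records the branch each
  position took (`corruption_kind`) for unbiased measurement of the split.

## Encoding

The 26-token vocabulary holds the 20 amino acids, `X` for unnatural
residues, and `<pad> <mask> <unk> <cls> <eos>`. A pair is encoded as
`<cls> H <cls><cls> L <eos>` padded to length 320 with no truncation
(overflow is an error). The leading `<cls>` and trailing `<eos>` follow the
encoder family's convention; the double-`<cls>` separator is the defining
layout element. Unknown characters map to `X` (not `<unk>`, which is kept
for tokenizer robustness only). The region mask built in the same pass
labels every residue position with one of 14 chain-qualified regions
(FR1–FR4, CDR1–CDR3, per chain); special positions carry label 0.

## The encoder and its training harness

The architecture family is an encoder-only transformer with rotary position
embeddings and pre-layer normalization, an MLM head (dense + GELU + LN +
decoder tied to the embedding), and a 2-logit affine classification head on
a pooled representation. Because the training stack is implemented on numpy
with a small reverse-mode autograd engine (validated against central finite
differences to 1e-4), there is no dropout and no mixed precision; AdamW
(β = 0.9/0.98, ε = 1e-8, weight decay 0.01 excluding norms/biases — config,
not contract) with linear warmup/decay drives the weights. Two presets
exist: `paper_350m` (32 layers, 20 heads, hidden 960, intermediate 3840;
355.2M parameters, i.e. ~350M at nearest-50M granularity — constructible,
counted analytically, never trained here) and `tiny` (2 layers, 4 heads,
hidden 64), the working scale for every experiment in this repository.

Cross-entropy is computed over collator-selected positions only. Validation
always uses the **uniform** strategy for both models — the preferential
pre-training task is harder by construction, so comparing models on their
own training corruptions would be unfair — and additionally fixes the
validation masking seed so both models are scored on bit-identical masked
positions. Each masked position's loss is assigned to a chain-agnostic
bucket (FR pools all eight frameworks; CDR1/CDR2/CDR3 pool both chains);
overall loss is the target-count-weighted mean of the buckets, and an empty
bucket is reported as absent, never as zero. Checkpoint selection takes the
evaluated step with minimum overall validation loss (ties: earliest).

## The synthetic repertoire

The generator stands in for natively-paired human B-cell datasets. Per
locus, a seeded germline library is sampled: V segments with FR1/CDR1/FR2/
CDR2/FR3 (nominal lengths 25/8/17/8/38, jitter ±1) and a 4-residue CDR3
tail, D segments (heavy only, ~6 residues), J segments with a 5-residue
CDR3 head and FR4 (~11). Default library sizes are 8 V / 6 D / 4 J (heavy)
and 6 V / 4 J (kappa). Recombination trims a truncated-geometric number of
residues (`trim_geometric_p = 0.5`) from each junction end and inserts
Poisson-distributed uniform-random residues (`cdr3_insertion_mean = 4`,
split over the two heavy junction gaps); an assembly whose CDR3 would be
empty is resampled. All non-CDR3 residues are verbatim germline, and every
record stores its full pre-mutation sequence and a templated/non-templated
flag per position, so mutation bookkeeping is exact by construction.

Maturation: cells are naive with probability `naive_fraction` (default 0.5)
and naive cells carry zero mutations. For memory cells one latent intensity
per pair, `λ ~ Exponential(mean = 8)`, drives both chains:
`m_H ~ Poisson(λ)`, `m_L ~ Poisson(0.8·λ)`. A fixed λ would make the chains'
counts independent; the across-pair variation of the shared λ is what
produces the co-maturation correlation (≈0.88 at the default mean) that the
pairing analyses rely on, and the 0.8 factor reproduces the observation that
light chains run slightly colder. Mutated positions are drawn with CDR
positions up-weighted 4× (`cdr_hotspot_weight`); substitutions are uniform
over the 19 alternatives. Donors are independent replicate streams of the
same process — no donor-specific germline variation.

Specificity labels: half the records are labeled positive and, with
probability `motif_implant_prob` (default 0.8), receive a fixed 5-mer motif
(`WGDYW`) at a uniform-random offset inside the heavy CDR3, mimicking
convergent epitope-specific motifs; records whose CDRH3 is shorter than the
motif are skipped and counted.

What the generator does **not** emulate: nucleotide-level recombination and
codon-aware SHM targeting, allele/gene usage frequencies, isotypes, clonal
lineage structure, and donor-specific germline variation. Tests passing on
this generator show that the machinery behaves as specified under a
repertoire with the right coarse statistics — not that the biological effect
sizes of real repertoires are reproduced.

## Dataset preparation

`filter_dataset` removes exact duplicate pairs (first kept) and records
whose region annotations fail to tile their sequence (e.g. an empty
framework placing two CDRs adjacent), logging a reason per rejection; it is
idempotent. `count_v_mutations` compares the FR1–FR3 span against the stored
germline V (CDR3 is outside the comparison, so junctional residues never
count). `cluster_identity` greedily clusters concatenated heavy+light
sequences in descending length order; identity is matching columns over the
global (Needleman–Wunsch, unit-cost) alignment length, computed with edlib,
so gaps count as mismatches. Greedy-by-length is deterministic and cheap;
at threshold 1.0 it reduces to exact deduplication. Clustering operates on
concatenated pairs (whether the original preprocessing clustered pairs or
single chains is not derivable; this is the package's choice).

## Classification tasks

`make_shuffled_pairs` samples 50% of each donor's pairs and permutes their
light chains by a derangement (a plain permutation could return a chain to
its own partner); shuffled pairs whose sequences coincide with any native
pair — possible under light-chain redundancy — are filtered and counted, a
donor contributing a single sampled pair is returned to the native side, and
the larger class is trimmed at random so classes balance exactly. Folds come
from stratified 5-fold CV (scikit-learn, seeded); every record is scored
only by the head whose held-out fold contains it, and train/test
intersections are asserted empty on every run.

`train_head` freezes the base (bit-identical checksums before/after are
asserted) and trains one affine 2-logit head per fold on pooled embeddings.
Pooling options: `cls` (the leading `<cls>` state; API default), `mean`
(over residue positions), and `cdrh3_mean` (over heavy-CDR3 positions). The
desk-scale specificity preset uses `cdrh3_mean`: with a tiny base, whole-
sequence pooling dilutes a 5-residue motif below the compositional variance
contributed by germline segment choice (measured AUC ceilings ~0.6–0.75
regardless of head training), while the motif's evidence is by construction
in CDRH3. The head preset at this scale uses a larger learning rate
(2e-2, 120 epochs, batch 64) than the full-scale settings (1e-5, 50 epochs,
batch 256), which are retained as the `paper` preset. Metrics (accuracy,
AUC, AUPR, F1, MCC; threshold 0.5 where applicable) come from scikit-learn
and are reported per fold with mean ± SE over the 5 folds; single-class
folds report ranking metrics as absent.

Known desk-scale limitation: native-vs-shuffled pairing classification stays
near chance here. The discriminative signal is the mutation-count mismatch
between chains, an inherently non-linear (XOR-like) function of the pooled
features that a single affine head cannot represent unless the frozen base
already encodes cross-chain compatibility — which a 2-layer briefly-trained
model does not. The mutation-grid analyses (native pairs concentrated near
the m_H = m_L diagonal, shuffled pairs dispersed) demonstrate that the
simulated data carries the signal, and the grid/"same vs different"
aggregation paths are tested against direct-aggregation oracles with
mutation-informed synthetic scorers.

## Per-position evaluation and model comparison

For each test sequence, every residue position is masked one at a time
(single-position corruption, one forward pass per position — not the
training collator), the argmax over residue tokens (specials can never be
"correct") is compared with the truth, and accuracies are aggregated per
sequence for each of the 14 chain-qualified regions, in unmutated (both
chains V-identical to germline) and mutated (either chain mutated) cohorts.
Two models are compared per region with a two-sided paired t-test on
per-sequence accuracies, Bonferroni-corrected ×14 and capped at 1; regions
with under two paired observations are reported untestable, identical
tables as "no difference". The API default of 1,000 sequences per cohort
matches the full-scale protocol; the test suite uses tens of records
because single-position inference is the dominant cost on this backend.

## Attribution

For a classifier decision toward class y, each layer contributes per token
the inner product of its hidden state with the gradient of the target logit
with respect to that hidden state, weighted by the attention the token
receives in that layer (mean over heads and non-pad query positions —
attention-received aggregation is pluggable; rows are asserted
non-negative and sum to one); the impact is the sum over layers, pads
excluded. Scores are reported with the display convention that negative
means impact toward the target class, and standard scaling ((x − mean)/sd,
population sd, per sequence) makes them comparable across models; a
zero-variance vector standardizes to zeros with a warning, and a flag
prevents double scaling. Region summaries report mean |impact| per
chain-qualified region plus CDR-vs-FR and heavy-vs-light ratios (an
infinite ratio is capped at 1e6). Early-sequence "attention sink" tokens are
not removed, only visible in the per-token tables. Explanation cohorts pick
k records evenly spaced over the rank range of the mean predicted
probability, ascending, with ties broken by pair id.

## Desk-scale study conditions

Chosen once for the test suite (sizes are the package's working defaults at
this scale):

* directional pre-training comparison: 640 simulated pairs (512 train /
  128 validation), tiny model, 400 steps, batch 16, peak lr 1e-3, warmup 40,
  three seeds; both strategies validated on identical uniform masks. The
  preferential model's CDR3 validation loss is required to be ≤ the uniform
  model's at the matched final step in at least 2 of 3 seeds, and every
  trained model must order FR loss < CDR3 loss.
* specificity task: 400 pairs with fully-implanted positives, a 150-step
  preferentially-masked base, CDRH3-mean pooling, 5-fold heads; the
  acceptance bar is AUC > 0.9 with a logistic-regression oracle on the same
  features as cross-check. (At the generator's default implant probability
  of 0.8 the maximum achievable AUC is exactly 0.9 — one fifth of the
  positives are indistinguishable from negatives — so the full-implantation
  condition is the one under which the bar is informative.)
* collator statistics: ≥100,000 selected positions, three binomial standard
  errors.

## Reproducibility

Every stochastic component takes an explicit seed or `numpy` Generator:
the simulator (identical config ⇒ byte-identical repertoire files), the
trainer (identical schedule seed ⇒ identical loss traces on this
single-threaded backend), validation masking, fold splitting, and head
initialization. The CLI fans a single root seed out to named per-stage
streams and writes a manifest (resolved config, its hash, seeds, package
version) next to every artifact.
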