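"""Per-position masked-prediction accuracy by region, and the paired
statistical comparison between two models.

Each residue of each test sequence is masked one at a time (single-position
corruption, not the 80/10/10 training collator), the model predicts it, and
the argmax over residue tokens is scored against the truth. Accuracies are
aggregated per sequence for each of the 14 chain-qualified regions, split
into unmutated and mutated cohorts, and two models are compared region-wise
with a two-sided paired t-test under Bonferroni correction for the 14
region hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CODE_LABELS
from .layout import CHAIN_REGION_LABELS
from .nn import Encoder, Tensor
from .tokenizer import Vocabulary, build_vocab, encode_record

__all__ = [
    "AccuracyTable",
    "per_position_accuracy",
    "compare_models",
    "N_REGION_TESTS",
]

N_REGION_TESTS = 14  # chain-qualified regions: 7 per chain x 2 chains


@dataclass
class AccuracyTable:
    """Per-sequence, per-region prediction accuracy.

    ``frame`` columns: pair_id, cohort, chain, region, correct, total,
    accuracy. ``region`` is chain-qualified ("H-CDR3", "L-FR1", ...).
    """

    frame: pd.DataFrame

    def region_accuracy(self, region: str) -> pd.Series:
        sub = self.frame[self.frame.region == region]
        return sub.set_index("pair_id")["accuracy"]

    def mean_by_region(self) -> pd.Series:
        return self.frame.groupby("region")["accuracy"].mean()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def pair_cohort(record) -> str:
    """"unmutated" iff both chains carry zero V mutations, else "mutated"."""
    mutated = record.heavy.v_mutation_count > 0 or record.light.v_mutation_count > 0
    return "mutated" if mutated else "unmutated"


def per_position_accuracy(
    model: Encoder,
    records,
    vocab: Vocabulary | None = None,
    n_per_cohort: int = 1000,
    max_len: int | None = None,
    batch_positions: int = 128,
) -> AccuracyTable:
    """Iteratively mask and predict every residue of up to ``n_per_cohort``
    records per cohort; aggregate accuracy per chain-qualified region.

    Every inference input carries exactly one corrupted position (asserted).
    The argmax is restricted to residue tokens, so a special token can never
    be counted as a correct prediction.
    """
    vocab = vocab or build_vocab()
    max_len = max_len or model.config.max_len
    residue_ids = vocab.residue_ids
    taken = {"unmutated": 0, "mutated": 0}
    rows = []
    for record in records:
        cohort = pair_cohort(record)
        if taken[cohort] >= n_per_cohort:
            continue
        try:
            enc = encode_record(record, vocab, max_len=max_len)
        except ValueError:
            continue  # skipped and surfaced via the rejected count
        taken[cohort] += 1
        positions = enc.region_mask.residue_positions
        length = enc.layout.total_real
        base = enc.token_ids[:length]
        flags = enc.attention_flags[:length]
        correct = np.zeros(len(positions), dtype=bool)
        for start in range(0, len(positions), batch_positions):
            pos = positions[start : start + batch_positions]
            ids = np.tile(base, (len(pos), 1))
            ids[np.arange(len(pos)), pos] = vocab.mask_id
            assert ((ids != base).sum(axis=1) == 1).all(), "exactly one masked position"
            hidden = model.forward(ids, np.tile(flags, (len(pos), 1)))
            picked = hidden.data[np.arange(len(pos)), pos]  # (n, H)
            logits = model.mlm_logits(Tensor(picked)).data
            pred = residue_ids[np.argmax(logits[:, residue_ids], axis=1)]
            correct[start : start + len(pos)] = pred == base[pos]
        labels = enc.region_mask.labels[positions]
        for code in np.unique(labels):
            region = CODE_LABELS[int(code)]
            sel = labels == code
            rows.append({
                "pair_id": record.pair_id,
                "cohort": cohort,
                "chain": region.split("-")[0],
                "region": region,
                "correct": int(correct[sel].sum()),
                "total": int(sel.sum()),
            })
    frame = pd.DataFrame(
        rows, columns=["pair_id", "cohort", "chain", "region", "correct", "total"]
    )
    frame["accuracy"] = frame["correct"] / frame["total"]
    return AccuracyTable(frame)


def compare_models(table_a: AccuracyTable, table_b: AccuracyTable) -> pd.DataFrame:
    """Region-wise two-sided paired t-test between two accuracy tables.

    Pairs per-sequence accuracies on pair_id; the adjusted p-value is the
    Bonferroni correction min(1, 14 * p) for the 14 region hypotheses.
    Regions with fewer than two paired observations, or with identically
    zero differences, are reported as untestable / no-difference.
    """
    rows = []
    for region in CHAIN_REGION_LABELS:
        a = table_a.region_accuracy(region)
        b = table_b.region_accuracy(region)
        joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner").dropna()
        n = len(joined)
        row = {"region": region, "n": n, "t": np.nan, "df": n - 1,
               "p_raw": np.nan, "p_adj": np.nan, "note": ""}
        if n < 2:
            row["note"] = "untestable: fewer than 2 paired observations"
        else:
            diffs = joined["a"] - joined["b"]
            if np.allclose(diffs, 0.0):
                row["note"] = "no difference"
            else:
                t, p = stats.ttest_rel(joined["a"], joined["b"])
                row.update(t=float(t), p_raw=float(p),
                           p_adj=float(min(1.0, N_REGION_TESTS * p)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["region", "n", "t", "df", "p_raw", "p_adj", "note"])
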