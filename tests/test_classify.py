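"""Shuffled-pair construction, stratified CV, metrics, frozen-head training,
and the mutation-grid analyses."""

import numpy as np
import pytest

from prefmask.classify import (
    ClassifierDataset,
    HeadConfig,
    compute_metrics,
    make_shuffled_pairs,
    mutation_grid,
    split_by_pairing_type,
    stratified_kfold,
    train_head,
)
from prefmask.nn import Encoder, ModelConfig
from prefmask.sim import SimConfig, simulate_repertoire

from conftest import make_pair


def _donor_records(n, donor="d0", seed0=0):
    records = []
    for i in range(n):
        rec = make_pair(f"{donor}p{i}", seed=seed0 + 3 * i)
        rec.donor_id = donor
        rec.cell_type = "memory"
        records.append(rec)
    return records


def test_four_pairs_one_donor_gives_two_plus_two():
    records = _donor_records(4)
    ds = make_shuffled_pairs(records, 0.5, np.random.default_rng(0))
    natives, shuffled = ds.class_counts()
    assert (natives, shuffled) == (2, 2)
    native_keys = {(r.heavy.sequence, r.light.sequence) for r in records}
    for rec in ds.records:
        if rec.pairing_label == "shuffled":
            assert (rec.heavy.sequence, rec.light.sequence) not in native_keys


def test_shared_light_chain_collisions_are_filtered():
    records = _donor_records(6, seed0=100)
    # two pairs share an identical light chain: a derangement that swaps them
    # recreates a native pair, which must be filtered and counted
    records[1].light = records[0].light.copy()
    total_collisions = 0
    for trial in range(6):
        ds = make_shuffled_pairs(records, 1.0, np.random.default_rng(trial))
        total_collisions += ds.provenance["n_collisions_filtered"]
        n0, n1 = ds.class_counts()
        assert n0 == n1  # balance restored by trimming
    assert total_collisions > 0


def test_empty_input_gives_empty_dataset():
    ds = make_shuffled_pairs([], 0.5, np.random.default_rng(0))
    assert ds.records == []
    assert ds.class_counts() == (0, 0)


def test_exact_balance_across_donors():
    records = _donor_records(9, "d0") + _donor_records(7, "d1", 500) \
        + _donor_records(1, "d2", 900)
    ds = make_shuffled_pairs(records, 0.5, np.random.default_rng(2))
    n0, n1 = ds.class_counts()
    assert n0 == n1
    assert ds.provenance["n_singleton_returned"] >= 0


def test_stratified_kfold_contract():
    records = [make_pair(f"p{i}", seed=i) for i in range(100)]
    for i, rec in enumerate(records):
        rec.pairing_label = "shuffled" if i % 2 else "native"
    ds = ClassifierDataset(records=records, task="pairing")
    folds = stratified_kfold(ds, k=5, seed=1)
    labels = ds.labels
    for train_idx, test_idx in folds:
        assert len(test_idx) == 20
        assert labels[test_idx].sum() == 10
        assert set(train_idx).isdisjoint(test_idx)
    again = stratified_kfold(ds, k=5, seed=1)
    assert all((a[1] == b[1]).all() for a, b in zip(folds, again))

    # 103 records (52/51): fold sizes within 1, labels within 1 of proportional
    records = [make_pair(f"q{i}", seed=200 + i) for i in range(103)]
    for i, rec in enumerate(records):
        rec.pairing_label = "shuffled" if i < 51 else "native"
    ds = ClassifierDataset(records=records, task="pairing")
    folds = stratified_kfold(ds, k=5, seed=0)
    sizes = [len(t) for _, t in folds]
    assert max(sizes) - min(sizes) <= 1
    for _, test_idx in folds:
        pos = ds.labels[test_idx].sum()
        expected = 51 * len(test_idx) / 103
        assert abs(pos - expected) <= 1

    small = ClassifierDataset(records=records[:6], task="pairing")
    for i, rec in enumerate(small.records):
        rec.pairing_label = "shuffled" if i < 2 else "native"
    with pytest.raises(ValueError):
        stratified_kfold(small, k=5)


def test_compute_metrics_extremes():
    labels = [0, 1, 0, 1, 1, 0]
    perfect = compute_metrics([0.1, 0.9, 0.2, 0.8, 0.7, 0.3], labels)
    assert all(perfect[m] == 1.0 for m in ("accuracy", "auc", "aupr", "f1", "mcc"))
    inverted = compute_metrics([0.9, 0.1, 0.8, 0.2, 0.3, 0.7], labels)
    assert inverted["mcc"] == -1.0
    single = compute_metrics([0.2, 0.6, 0.7], [1, 1, 1])
    assert single["auc"] is None and single["aupr"] is None


def test_compute_metrics_against_exhaustive_threshold_oracle():
    """Six-item fixture: AUC by pair counting, AUPR by precision steps,
    thresholded metrics by direct tallies."""
    scores = np.array([0.9, 0.8, 0.55, 0.45, 0.3, 0.1])
    labels = np.array([1, 0, 1, 1, 0, 0])
    got = compute_metrics(scores, labels)

    pos, neg = scores[labels == 1], scores[labels == 0]
    pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
    assert got["auc"] == pytest.approx(np.mean(pairs))

    order = np.argsort(-scores)
    tp = fp = 0
    aupr = 0.0
    n_pos = labels.sum()
    for idx in order:  # average precision: sum precision at each recall step
        if labels[idx] == 1:
            tp += 1
            aupr += tp / (tp + fp) / n_pos
        else:
            fp += 1
    assert got["aupr"] == pytest.approx(aupr)

    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    assert got["accuracy"] == pytest.approx((tp + tn) / 6)
    assert got["f1"] == pytest.approx(2 * tp / (2 * tp + fp + fn))
    mcc = (tp * tn - fp * fn) / np.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    assert got["mcc"] == pytest.approx(mcc)


@pytest.fixture(scope="module")
def tiny_base():
    return Encoder(ModelConfig(1, 2, 32, 64, 26, 320), seed=0)


def test_train_head_freezes_base_and_prevents_leakage(tiny_base):
    records = simulate_repertoire(SimConfig(n_pairs=60, seed=3))
    for i, rec in enumerate(records):
        rec.specificity_label = "positive" if i % 2 else "negative"
    ds = ClassifierDataset(records=records, task="specificity")
    before = tiny_base.checksum()
    config = HeadConfig(epochs=10, batch_size=16, peak_lr=0.02,
                        warmup_ratio=0.1, pooling="mean")
    heads, report, oof = train_head(tiny_base, ds, config, seed=0)
    assert tiny_base.checksum() == before
    assert len(heads) == 5
    assert not np.isnan(oof).any()  # every record scored exactly once
    assert set(report.frame.columns) >= {"fold", "accuracy", "auc", "aupr",
                                         "f1", "mcc"}
    summary = report.summary()
    assert {"mean", "se"} <= set(summary.columns)


def test_random_labels_give_chance_accuracy(tiny_base):
    rng = np.random.default_rng(9)
    records = simulate_repertoire(SimConfig(n_pairs=120, seed=4))
    for rec in records:
        rec.specificity_label = "positive" if rng.random() < 0.5 else "negative"
    ds = ClassifierDataset(records=records, task="specificity")
    config = HeadConfig(epochs=10, batch_size=16, peak_lr=0.02,
                        warmup_ratio=0.1, pooling="mean")
    _, report, _ = train_head(tiny_base, ds, config, seed=0)
    acc = report.frame["accuracy"].mean()
    se = np.sqrt(0.25 / len(records))
    assert abs(acc - 0.5) < 3 * se + 0.05


def test_mutation_grid_counts_and_truth_split():
    records = simulate_repertoire(SimConfig(n_pairs=80, naive_fraction=0.3, seed=8))
    grid = mutation_grid(np.full(len(records), 0.4), records)
    assert grid.total("native") == len(records)
    assert grid.counts("shuffled").empty
    assert grid.frame["mean_shuffled_prob"].between(0, 1).all()


def test_mutation_grid_aggregates_scorer_faithfully():
    """A mutation-mismatch scorer must show higher mean shuffled probability
    off the m_H = m_L diagonal (direct-aggregation oracle)."""
    records = simulate_repertoire(SimConfig(n_pairs=400, naive_fraction=0.3, seed=12))
    ds = make_shuffled_pairs(records, 0.5, np.random.default_rng(3))
    diffs = np.array([abs(r.heavy.v_mutation_count - r.light.v_mutation_count)
                      for r in ds.records])
    probs = 1 / (1 + np.exp(-(diffs - 3)))  # mutation-informed synthetic scorer
    grid = mutation_grid(probs, ds.records).frame
    grid["absdiff"] = (grid.m_h - grid.m_l).abs()
    diag = grid[grid.absdiff <= 1]
    off = grid[grid.absdiff >= 5]
    wmean = lambda d: (d.mean_shuffled_prob * d["count"]).sum() / d["count"].sum()
    assert wmean(off) > wmean(diag)
    # oracle: recompute cell means directly from raw predictions
    import pandas as pd
    raw = pd.DataFrame({
        "m_h": [r.heavy.v_mutation_count for r in ds.records],
        "m_l": [r.light.v_mutation_count for r in ds.records],
        "truth": [r.pairing_label for r in ds.records],
        "p": probs,
    })
    direct = raw.groupby(["truth", "m_h", "m_l"])["p"].mean()
    for _, row in grid.sample(20, random_state=0).iterrows():
        assert row["mean_shuffled_prob"] == pytest.approx(
            direct[(row["truth"], row["m_h"], row["m_l"])])


def test_split_by_pairing_type_hand_fixture():
    records = []
    for i, (mh, ml, label) in enumerate([
        (0, 0, "native"), (5, 4, "native"), (0, 6, "shuffled"), (3, 0, "shuffled"),
        (0, 0, "shuffled"), (7, 8, "shuffled"), (0, 5, "native"), (2, 3, "native"),
    ]):
        rec = make_pair(f"h{i}", seed=40 + i)
        rec.heavy.v_mutation_count = mh
        rec.light.v_mutation_count = ml
        rec.pairing_label = label
        records.append(rec)
    # scores: predict shuffled iff mutation status differs
    preds = [0.9 if (r.heavy.v_mutation_count > 0) != (r.light.v_mutation_count > 0)
             else 0.1 for r in records]
    groups = split_by_pairing_type(preds, records)
    # same: records 0,1,4,5,7 -> correct for 0,1,7 (native) wrong for 4,5 -> 3/5
    # different: records 2,3,6 -> correct 2,3 (shuffled) wrong 6 -> 2/3
    assert groups["same"]["n"] == 5
    assert groups["same"]["accuracy"] == pytest.approx(3 / 5)
    assert groups["different"]["n"] == 3
    assert groups["different"]["accuracy"] == pytest.approx(2 / 3)
    only_same = [r for r in records
                 if (r.heavy.v_mutation_count > 0) == (r.light.v_mutation_count > 0)]
    result = split_by_pairing_type([0.1] * len(only_same), only_same)
    assert "different" not in result
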