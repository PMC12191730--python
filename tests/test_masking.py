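"""Masking-probability construction, plan caching, and the dynamic collator."""

import numpy as np
import pytest

from prefmask.annotate import LABEL_CODES, RegionMask, build_region_mask
from prefmask.layout import EncodingLayout
from prefmask.masking import (
    DegenerateInputError,
    StaleCacheError,
    collate,
    precompute_plan_cache,
    preferential_probs,
    uniform_probs,
)

from conftest import make_pair


def _synthetic_mask(n_residues, n_cdr3):
    """A hand-built region mask with an exact CDR3 residue fraction."""
    layout = EncodingLayout(max(1, n_residues - n_cdr3), max(1, n_cdr3), 320)
    labels = np.zeros(320, dtype=np.int8)
    labels[1 : 1 + (n_residues - n_cdr3)] = LABEL_CODES["H-FR1"]
    start = 1 + (n_residues - n_cdr3)
    labels[start + 2 : start + 2 + n_cdr3] = LABEL_CODES["H-CDR3"]
    return RegionMask(labels=labels, layout=layout)


def test_formula_limit_no_cdr3_gives_uniform_rate():
    mask = _synthetic_mask(100, 0)
    plan = preferential_probs(mask)
    assert np.allclose(plan.probs[mask.residue_positions], 0.15)
    assert plan.p_hat_cdr3 == 0.0


def test_formula_at_ten_percent_cdr3():
    """p_hat = 0.10 with default rates: non-CDR3 rate (0.15-0.025)/0.9."""
    mask = _synthetic_mask(100, 10)
    plan = preferential_probs(mask)
    non_cdr3 = sorted(set(mask.residue_positions) - set(mask.cdr3_positions))
    assert np.allclose(plan.probs[non_cdr3], (0.15 - 0.025) / 0.9, atol=1e-15)
    assert np.allclose(plan.probs[mask.cdr3_positions], 0.25)


def test_average_rate_maintained_exactly(encoded):
    """Mean probability over residue positions is 15% for unclamped plans."""
    for enc in encoded[:50]:
        plan = preferential_probs(enc.region_mask)
        assert not plan.clamped
        mean = plan.probs[enc.region_mask.residue_positions].mean()
        assert abs(mean - 0.15) < 1e-12
        # expectation identity: sum of probs = r_avg * n_residues
        assert abs(plan.probs.sum() - 0.15 * enc.region_mask.n_residues) < 1e-9


def test_clamping_at_extreme_cdr3_fraction():
    mask = _synthetic_mask(100, 60)
    plan = preferential_probs(mask)
    assert plan.clamped
    non_cdr3 = sorted(set(mask.residue_positions) - set(mask.cdr3_positions))
    assert np.allclose(plan.probs[non_cdr3], 0.0)
    assert np.allclose(plan.probs[mask.cdr3_positions], 0.25)
    with pytest.raises(DegenerateInputError):
        preferential_probs(_synthetic_mask(60, 60))


def test_uniform_probs(encoded):
    enc = encoded[0]
    plan = uniform_probs(enc.region_mask)
    res = enc.region_mask.residue_positions
    assert np.allclose(plan.probs[res], 0.15)
    special = np.setdiff1d(np.arange(320), res)
    assert np.allclose(plan.probs[special], 0.0)
    assert abs(plan.probs[res].mean() - 0.15) < 1e-15


def test_preferential_at_equal_rates_is_uniform(encoded):
    for enc in encoded[:20]:
        pref = preferential_probs(enc.region_mask, r_cdr3=0.15, r_avg=0.15)
        unif = uniform_probs(enc.region_mask)
        assert (pref.probs == unif.probs).all()


def test_non_cdr3_rate_strictly_decreasing_in_cdr3_fraction():
    rates = []
    for n_cdr3 in range(0, 60, 5):
        plan = preferential_probs(_synthetic_mask(100, n_cdr3))
        if plan.clamped:
            break
        non = (0.15 - 0.25 * plan.p_hat_cdr3) / (1 - plan.p_hat_cdr3)
        rates.append(non)
    assert all(a > b for a, b in zip(rates, rates[1:]))


def test_plan_cache_single_pass_and_reuse(encoded, vocab, tmp_path):
    dataset = encoded[:100]
    cache = precompute_plan_cache(dataset, "preferential")
    assert len(cache.plans) == len(dataset)
    assert cache.recompute_count == len(dataset)
    rng = np.random.default_rng(0)
    for _ in range(3):  # later epochs must not recompute probabilities
        collate(dataset[:16], cache, vocab, rng)
    assert cache.recompute_count == len(dataset)

    cache.save(tmp_path / "cache")
    loaded = type(cache).load(tmp_path / "cache", expected_strategy="preferential",
                              expected_r_cdr3=0.25, expected_r_avg=0.15)
    for enc in dataset:
        assert (loaded.get(enc).probs == cache.get(enc).probs).all()
    loaded.validate_against(dataset)

    with pytest.raises(StaleCacheError):  # changing r_cdr3 invalidates the cache
        type(cache).load(tmp_path / "cache", expected_r_cdr3=0.35)
    with pytest.raises(StaleCacheError):  # different dataset -> stale
        loaded.validate_against(dataset[:10])
    with pytest.raises(StaleCacheError):  # unknown record
        cache.get(encoded[110])


def test_cache_supports_the_35_percent_variant(encoded):
    cache = precompute_plan_cache(encoded[:10], "preferential", r_cdr3=0.35)
    for enc in encoded[:10]:
        plan = cache.get(enc)
        assert np.allclose(plan.probs[enc.region_mask.cdr3_positions], 0.35)
        assert abs(plan.probs[enc.region_mask.residue_positions].mean() - 0.15) < 1e-12


def test_collate_zero_plan_selects_nothing(encoded, vocab):
    dataset = encoded[:4]
    cache = precompute_plan_cache(dataset, "uniform")
    for plan in cache.plans.values():
        plan.probs[:] = 0.0
    batch = collate(dataset, cache, vocab, np.random.default_rng(0))
    assert batch.n_selected == 0
    assert (batch.target_ids == -100).all()
    assert (batch.input_ids == np.stack([e.token_ids for e in dataset])).all()


def test_collate_dynamic_masks_differ_across_epochs(encoded, vocab):
    dataset = encoded[:8]
    cache = precompute_plan_cache(dataset, "uniform")
    rng = np.random.default_rng(3)
    first = collate(dataset, cache, vocab, rng)
    second = collate(dataset, cache, vocab, rng)
    assert (first.selection_mask != second.selection_mask).any()


def test_collate_never_emits_special_replacements(encoded, vocab):
    dataset = encoded[:32]
    cache = precompute_plan_cache(dataset, "preferential")
    rng = np.random.default_rng(5)
    for _ in range(5):
        batch = collate(dataset, cache, vocab, rng)
        random_positions = batch.corruption_kind == 1
        emitted = set(batch.input_ids[random_positions].tolist())
        assert emitted <= set(vocab.residue_ids.tolist())
        # selection only at residue positions; every selected target is real
        assert (batch.target_ids[batch.selection_mask] >= 0).all()
        labels = np.stack([e.region_mask.labels for e in dataset])
        assert (labels[batch.selection_mask] != 0).all()


def test_collate_length_mismatch_raises(encoded, vocab):
    dataset = encoded[:4]
    cache = precompute_plan_cache(dataset, "uniform")
    plans = [cache.get(e) for e in dataset]
    plans[0] = type(plans[0])(plans[0].probs[:100], 0.15, 0.15, 0.1, False)
    with pytest.raises(ValueError):
        collate(dataset, plans, vocab, np.random.default_rng(0))


def test_empirical_selection_frequency_matches_plan(encoded, vocab):
    """Per-position selection frequency converges to the plan probabilities."""
    enc = encoded[0]
    cache = precompute_plan_cache([enc], "preferential")
    plan = cache.get(enc)
    rng = np.random.default_rng(11)
    n_draws = 2000
    freq = np.zeros(320)
    for _ in range(n_draws):
        batch = collate([enc], cache, vocab, rng)
        freq += batch.selection_mask[0]
    freq /= n_draws
    se = np.sqrt(plan.probs * (1 - plan.probs) / n_draws)
    assert (np.abs(freq - plan.probs) <= 4.5 * se + 1e-12).all()


def test_signal_allocation_ratio(encoded, vocab):
    """Preferential masking routes r_cdr3/r_avg (~1.67x) more prediction
    targets into CDR3 than uniform masking, record for record."""
    dataset = encoded[:24]
    pref = precompute_plan_cache(dataset, "preferential")
    unif = precompute_plan_cache(dataset, "uniform")
    labels = np.stack([e.region_mask.labels for e in dataset])
    cdr3 = (labels == LABEL_CODES["H-CDR3"]) | (labels == LABEL_CODES["L-CDR3"])
    counts = {"preferential": [0, 0], "uniform": [0, 0]}
    rng = np.random.default_rng(17)
    for _ in range(400):
        for name, cache in (("preferential", pref), ("uniform", unif)):
            batch = collate(dataset, cache, vocab, rng)
            counts[name][0] += int((batch.selection_mask & cdr3).sum())
            counts[name][1] += int(batch.selection_mask.sum())
    share = {k: c / t for k, (c, t) in counts.items()}
    ratio = share["preferential"] / share["uniform"]
    assert abs(ratio - 0.25 / 0.15) < 0.08
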