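"""Repertoire-simulator behaviour: determinism, junction model, SHM coupling,
motif implantation, and mutation bookkeeping."""

import numpy as np
import pytest

from prefmask.classify import make_shuffled_pairs
from prefmask.sim import (
    SimConfig,
    apply_shm,
    build_germline_library,
    default_libraries,
    implant_specificity,
    recombine_pair,
    simulate_repertoire,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _lib_fingerprint(lib):
    return (
        tuple((v.name, tuple(sorted(v.region_seqs.items())), v.cdr3_tail)
              for v in lib.v_segments),
        tuple(lib.d_segments),
        tuple((j.name, j.cdr3_head, j.fr4) for j in lib.j_segments),
    )


def test_library_determinism_and_structure():
    a = build_germline_library("heavy", 5, 3, 2, seed=7)
    b = build_germline_library("heavy", 5, 3, 2, seed=7)
    assert _lib_fingerprint(a) == _lib_fingerprint(b)
    big = build_germline_library("heavy", 50, 20, 6, seed=3)
    assert len(big.v_segments) == 50
    # every V segment carries exactly the five annotated sub-regions
    assert all(len(v.region_seqs) == 5 for v in big.v_segments)
    assert all(set(c) <= set(AA) for v in big.v_segments
               for c in "".join(v.region_seqs.values()))


def test_light_locus_has_no_d_segments():
    lib = build_germline_library("kappa", 4, 0, 2, seed=1)
    assert lib.d_segments == []
    with pytest.raises(ValueError):
        build_germline_library("kappa", 4, 2, 2, seed=1)


def test_degenerate_junction_is_pure_germline():
    """With no insertions and no trimming, CDR3 is exactly the germline junction."""
    lib_h, lib_l = default_libraries(3)
    config = SimConfig(cdr3_insertion_mean=0.0, trim_geometric_p=1.0, seed=3)
    rng = np.random.default_rng(0)
    for _ in range(5):
        rec = recombine_pair(lib_h, lib_l, config, rng)
        for chain in (rec.heavy, rec.light):
            c0, c1 = chain.region_bounds("CDR3")
            assert all(chain.templated_mask[c0:c1]), "non-templated residue found"
            assert chain.sequence == chain.germline_full
        # heavy junction must be an untouched V-tail + D + J-head
        h_cdr3 = rec.heavy.region_seq("CDR3")
        assert any(h_cdr3.startswith(v.cdr3_tail) for v in lib_h.v_segments)
        assert any(h_cdr3.endswith(j.cdr3_head) for j in lib_h.j_segments)


def _truncated_geom_mean(p, cap):
    # E[min(G, cap)] for G ~ Geometric on {0,1,...}: sum_{k<cap} P(G > k)
    return sum((1 - p) ** (k + 1) for k in range(cap))


def test_cdr3_length_matches_closed_form_expectation():
    """Sample mean CDR3 length agrees with the trim+insertion model's expectation."""
    lib_h, _ = default_libraries(0)
    config = SimConfig(seed=0)
    p = config.trim_geometric_p
    # expectation per segment choice, averaged over the uniform segment draw
    e_v = np.mean([len(v.cdr3_tail) - _truncated_geom_mean(p, len(v.cdr3_tail))
                   for v in lib_h.v_segments])
    e_j = np.mean([len(j.cdr3_head) - _truncated_geom_mean(p, len(j.cdr3_head))
                   for j in lib_h.j_segments])
    # D remnant: len - E[min(G1, L)] - E[min(G2, L - t1)] = E[max(0, L - G1 - G2)]
    def e_d(L):
        pmf = [(1 - p) ** k * p for k in range(200)]
        total = 0.0
        for g1, p1 in enumerate(pmf):
            for g2, p2 in enumerate(pmf[: 200 - g1]):
                total += p1 * p2 * max(0, L - g1 - g2)
        return total
    e_d_mean = np.mean([e_d(len(d)) for _, d in lib_h.d_segments])
    expected = e_v + e_j + e_d_mean + config.cdr3_insertion_mean
    rng = np.random.default_rng(123)
    lib_l = default_libraries(0)[1]
    lengths = []
    for _ in range(4000):
        rec_chain = recombine_pair(lib_h, lib_l, config, rng).heavy
        c0, c1 = rec_chain.region_bounds("CDR3")
        lengths.append(c1 - c0)
    lengths = np.array(lengths)
    se = lengths.std(ddof=1) / np.sqrt(len(lengths))
    assert abs(lengths.mean() - expected) < 3 * se


def _column_entropies(seqs):
    n = min(len(s) for s in seqs)
    ents = []
    for j in range(n):
        _, counts = np.unique([s[j] for s in seqs], return_counts=True)
        freq = counts / counts.sum()
        ents.append(-(freq * np.log(freq)).sum())
    return np.array(ents)


def test_cdr3_columns_more_diverse_than_framework_columns():
    """Positional diversity is highest in CDR3 (junctional + non-templated)."""
    records = simulate_repertoire(SimConfig(n_pairs=800, naive_fraction=1.0, seed=4))
    cdr3 = [r.heavy.region_seq("CDR3") for r in records]
    fr = [r.heavy.region_seq("FR1") + r.heavy.region_seq("FR2") for r in records]
    assert _column_entropies(cdr3).mean() > _column_entropies(fr).mean()


def test_naive_records_are_unmutated():
    records = simulate_repertoire(SimConfig(n_pairs=60, naive_fraction=1.0, seed=2))
    for rec in records:
        assert rec.heavy.v_mutation_count == 0
        assert rec.light.v_mutation_count == 0
        assert rec.meta["m_heavy"] == 0 and rec.meta["m_light"] == 0


def test_shared_intensity_couples_chain_mutation_counts():
    """corr(m_H, m_L) > 0.5 under the shared maturation-intensity model."""
    # Monte-Carlo oracle of the mixed-Poisson model itself
    rng = np.random.default_rng(0)
    lam = rng.exponential(8.0, size=6000)
    oracle = np.corrcoef(rng.poisson(lam), rng.poisson(0.8 * lam))[0, 1]
    assert oracle > 0.5, "model family itself must exceed the bound"
    records = simulate_repertoire(SimConfig(n_pairs=4000, naive_fraction=0.0, seed=9))
    m_h = np.array([r.meta["m_heavy"] for r in records])
    m_l = np.array([r.meta["m_light"] for r in records])
    assert np.corrcoef(m_h, m_l)[0, 1] > 0.5


def test_shuffling_widens_mutation_difference():
    """Shuffled pairs lose the co-maturation coupling of native pairs."""
    records = simulate_repertoire(SimConfig(n_pairs=1200, naive_fraction=0.0, seed=13))
    diff_native = np.array(
        [r.heavy.v_mutation_count - r.light.v_mutation_count for r in records]
    )
    shuffled = make_shuffled_pairs(records, 0.5, np.random.default_rng(1))
    diff_shuffled = np.array(
        [r.heavy.v_mutation_count - r.light.v_mutation_count
         for r in shuffled.records if r.pairing_label == "shuffled"]
    )
    assert diff_shuffled.var() > diff_native.var()


def test_motif_implantation_contract():
    config = SimConfig(n_pairs=300, seed=21)
    records = simulate_repertoire(config)

    # prob=0: sequences untouched
    none = implant_specificity(
        records, SimConfig(n_pairs=300, motif_implant_prob=0.0, seed=21),
        np.random.default_rng(5))
    assert [r.heavy.sequence for r in none] == [r.heavy.sequence for r in records]

    # prob=1: every positive CDRH3 (long enough) carries the motif
    stats: dict = {}
    full = implant_specificity(
        records, SimConfig(n_pairs=300, motif_implant_prob=1.0, seed=21),
        np.random.default_rng(5), stats=stats)
    positives = [r for r in full if r.specificity_label == "positive"]
    with_motif = sum(config.motif in r.heavy.region_seq("CDR3") for r in positives)
    assert with_motif == len(positives) - stats["skipped"]
    assert stats["n_positive"] == len(full) // 2  # exact class counts reported

    # defaults (prob 0.8): positive motif frequency far above background
    stats = {}
    part = implant_specificity(records, config, np.random.default_rng(5), stats=stats)
    pos_freq = np.mean([config.motif in r.heavy.sequence for r in part
                        if r.specificity_label == "positive"])
    neg_freq = np.mean([config.motif in r.heavy.sequence for r in part
                        if r.specificity_label == "negative"])
    assert pos_freq > neg_freq + 0.5


def test_mutation_bookkeeping_hamming_identity():
    """Stored counts equal Hamming distance to germline over templated positions."""
    records = simulate_repertoire(SimConfig(n_pairs=150, seed=31))
    for rec in records:
        for chain, key in ((rec.heavy, "m_heavy"), (rec.light, "m_light")):
            hamming = sum(
                1 for s, g, t in zip(chain.sequence, chain.germline_full,
                                     chain.templated_mask) if t and s != g
            )
            assert rec.meta[key] == hamming
            v0, v1 = chain.v_span
            v_hamming = sum(1 for a, b in zip(chain.sequence[v0:v1], chain.germline_v)
                            if a != b)
            assert chain.v_mutation_count == v_hamming
            if rec.cell_type == "naive":
                # conservation: unmutated chains match germline everywhere
                assert chain.sequence == chain.germline_full


def test_repertoire_determinism():
    a = simulate_repertoire(SimConfig(n_pairs=40, seed=5))
    b = simulate_repertoire(SimConfig(n_pairs=40, seed=5))
    assert [(r.pair_id, r.concat_sequence, r.donor_id, r.cell_type) for r in a] == \
           [(r.pair_id, r.concat_sequence, r.donor_id, r.cell_type) for r in b]
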