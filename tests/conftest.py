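import numpy as np
import pytest

from prefmask.annotate import filter_dataset
from prefmask.records import AnnotatedChain, PairedRecord, regions_from_lengths
from prefmask.sim import SimConfig, simulate_repertoire
from prefmask.tokenizer import build_vocab, encode_record

HEAVY_LENGTHS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 38,
                 "CDR3": 14, "FR4": 11}
LIGHT_LENGTHS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 30,
                 "CDR3": 9, "FR4": 11}


def make_chain(lengths, locus="heavy", seed=0, germline=True):
    """A synthetic annotated chain with the given per-region lengths."""
    rng = np.random.default_rng(seed)
    n = sum(lengths.values())
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
    regions = regions_from_lengths(lengths)
    v_end = dict((r, e) for r, _s, e in regions)["FR3"]
    chain = AnnotatedChain(
        sequence=seq,
        regions=regions,
        locus=locus,
        germline_v=seq[:v_end] if germline else None,
        germline_full=seq,
        templated_mask=[True] * n,
    )
    chain.validate()
    return chain


def make_pair(pair_id="t0", seed=0, heavy_lengths=None, light_lengths=None):
    heavy = make_chain(heavy_lengths or HEAVY_LENGTHS, "heavy", seed)
    light = make_chain(light_lengths or LIGHT_LENGTHS, "kappa", seed + 1)
    return PairedRecord(pair_id=pair_id, heavy=heavy, light=light)


@pytest.fixture(scope="session")
def vocab():
    return build_vocab()


@pytest.fixture(scope="session")
def repertoire():
    """A small mixed naive/memory repertoire shared across tests."""
    records = simulate_repertoire(SimConfig(n_pairs=120, seed=7))
    kept, _ = filter_dataset(records)
    return kept


@pytest.fixture(scope="session")
def encoded(repertoire, vocab):
    return [encode_record(r, vocab) for r in repertoire]
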