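"""Synthetic paired-repertoire generator.

Emulates the statistical structure of natively paired human B-cell
repertoires at desk scale: germline-templated frameworks and CDR1/CDR2,
variable-length partly non-templated CDR3s assembled from trimmed V(-D)-J
junctions plus random insertions, coupled heavy/light somatic hypermutation
loads for native pairs, donor labels, and implantable CDRH3 motifs that give
a learnable binding-specificity signal.

Generative model, per pair:

* recombination — pick V, (D,) J uniformly from the germline library; trim a
  truncated-geometric number of residues from each junction end; insert a
  Poisson-distributed number of uniform-random residues at each junction.
  All non-CDR3 residues are copied verbatim from germline.
* maturation — naive cells carry zero mutations. For memory cells one latent
  intensity per pair, lambda ~ Exponential(mean = mutation_rate_scale),
  drives both chains: m_H ~ Poisson(lambda), m_L ~ Poisson(0.8 * lambda)
  (light chains run a little colder, matching the observed asymmetry).
  The shared lambda is what couples the two chains' mutation counts.
  Mutated positions are drawn with CDR positions up-weighted by
  ``cdr_hotspot_weight``; substitutions are uniform over the 19 alternatives.
* specificity — positives optionally carry a fixed CDRH3 k-mer motif at a
  random offset, mimicking convergent epitope-specific motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import count_v_mutations
from .records import (
    AMINO_ACIDS,
    AnnotatedChain,
    PairedRecord,
    regions_from_lengths,
)

__all__ = [
    "GermlineLibrary",
    "SimConfig",
    "build_germline_library",
    "recombine_pair",
    "apply_shm",
    "implant_specificity",
    "simulate_repertoire",
]

# nominal germline region lengths (residues); individual segments jitter +/-1
REGION_LENGTH_DEFAULTS = {"FR1": 25, "CDR1": 8, "FR2": 17, "CDR2": 8, "FR3": 38, "FR4": 11}
V_CDR3_TAIL_LEN = 4   # germline V residues extending into CDR3
J_CDR3_HEAD_LEN = 5   # germline J residues starting CDR3's tail end
D_LEN = 6             # heavy-chain D segment length (pre-trimming)

_V_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


@dataclass(frozen=True)
class VSegment:
    name: str
    region_seqs: dict          # region -> residue string, FR1..FR3
    cdr3_tail: str

    @property
    def fr1_fr3(self) -> str:
        return "".join(self.region_seqs[r] for r in _V_REGIONS)


@dataclass(frozen=True)
class JSegment:
    name: str
    cdr3_head: str
    fr4: str


@dataclass
class GermlineLibrary:
    locus: str
    v_segments: list
    d_segments: list  # [(name, seq)]; empty for light loci
    j_segments: list
    seed: int


def _rand_aa(rng, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def build_germline_library(
    locus: str, n_v: int, n_d: int, n_j: int, seed: int
) -> GermlineLibrary:
    """Deterministically sample a germline segment library for one locus."""
    if locus not in ("heavy", "kappa", "lambda"):
        raise ValueError(f"unknown locus {locus!r}")
    if locus != "heavy" and n_d > 0:
        raise ValueError("D segments exist only for the heavy locus")
    if n_v < 1 or n_j < 1 or (locus == "heavy" and n_d < 1):
        raise ValueError("segment counts must be >= 1 (n_d >= 1 for heavy)")
    rng = np.random.default_rng(seed)
    prefix = {"heavy": "IGHV", "kappa": "IGKV", "lambda": "IGLV"}[locus]
    vs = []
    for i in range(n_v):
        lengths = {
            r: REGION_LENGTH_DEFAULTS[r] + int(rng.integers(-1, 2))
            for r in _V_REGIONS
        }
        vs.append(
            VSegment(
                name=f"{prefix}{i + 1}-sim",
                region_seqs={r: _rand_aa(rng, lengths[r]) for r in _V_REGIONS},
                cdr3_tail=_rand_aa(rng, V_CDR3_TAIL_LEN),
            )
        )
    ds = [
        (f"IGHD{i + 1}-sim", _rand_aa(rng, D_LEN + int(rng.integers(-1, 2))))
        for i in range(n_d)
    ]
    js = [
        JSegment(
            name=f"{prefix[:3]}J{i + 1}-sim",
            cdr3_head=_rand_aa(rng, J_CDR3_HEAD_LEN),
            fr4=_rand_aa(rng, REGION_LENGTH_DEFAULTS["FR4"] + int(rng.integers(-1, 2))),
        )
        for i in range(n_j)
    ]
    return GermlineLibrary(locus, vs, ds, js, seed)


@dataclass
class SimConfig:
    """Study conditions of the synthetic repertoire."""

    n_pairs: int = 1000
    naive_fraction: float = 0.5
    mutation_rate_scale: float = 8.0   # mean mutations per mutated heavy chain
    cdr_hotspot_weight: float = 4.0    # CDR vs FR mutation weight, >= 1
    cdr3_insertion_mean: float = 4.0   # expected non-templated residues per junction region
    trim_geometric_p: float = 0.5      # per-end junction trimming, Geometric on {0,1,...}
    motif: str = "WGDYW"               # CDRH3 k-mer marking the positive class
    motif_implant_prob: float = 0.8
    n_donors: int = 4
    seed: int = 0

    def __post_init__(self):
        for name in ("naive_fraction", "motif_implant_prob", "trim_geometric_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mutation_rate_scale < 0:
            raise ValueError("mutation_rate_scale must be >= 0")
        if self.cdr_hotspot_weight < 1:
            raise ValueError("cdr_hotspot_weight must be >= 1")
        if self.cdr3_insertion_mean < 0:
            raise ValueError("cdr3_insertion_mean must be >= 0")


def _trim(rng, p: float, cap: int) -> int:
    """Truncated geometric trim on {0, 1, ...}, capped at ``cap``."""
    if p >= 1.0:
        return 0
    return min(int(rng.geometric(p) - 1), cap)


def _junction(lib: GermlineLibrary, config: SimConfig, rng) -> tuple:
    """Assemble one chain's CDR3; returns (cdr3, templated_flags, names)."""
    v = lib.v_segments[int(rng.integers(len(lib.v_segments)))]
    j = lib.j_segments[int(rng.integers(len(lib.j_segments)))]
    p = config.trim_geometric_p
    parts = []  # (residues, templated?)
    v_rem = v.cdr3_tail[: len(v.cdr3_tail) - _trim(rng, p, len(v.cdr3_tail))]
    parts.append((v_rem, True))
    d_name = ""
    if lib.locus == "heavy":
        d_name, d_seq = lib.d_segments[int(rng.integers(len(lib.d_segments)))]
        ins1 = _rand_aa(rng, rng.poisson(config.cdr3_insertion_mean / 2.0))
        t_l = _trim(rng, p, len(d_seq))
        t_r = _trim(rng, p, len(d_seq) - t_l)
        d_rem = d_seq[t_l : len(d_seq) - t_r]
        ins2 = _rand_aa(rng, rng.poisson(config.cdr3_insertion_mean / 2.0))
        parts += [(ins1, False), (d_rem, True), (ins2, False)]
    else:
        ins = _rand_aa(rng, rng.poisson(config.cdr3_insertion_mean))
        parts.append((ins, False))
    j_rem = j.cdr3_head[_trim(rng, p, len(j.cdr3_head)) :]
    parts.append((j_rem, True))
    cdr3 = "".join(s for s, _ in parts)
    flags = [t for s, t in parts for _ in s]
    return cdr3, flags, v, j, d_name


def _recombine_chain(lib: GermlineLibrary, config: SimConfig, rng) -> AnnotatedChain:
    while True:
        cdr3, cdr3_flags, v, j, d_name = _junction(lib, config, rng)
        if len(cdr3) >= 1:
            break  # never emit an empty CDR3; resample exhausted junctions
    lengths = {r: len(v.region_seqs[r]) for r in _V_REGIONS}
    lengths["CDR3"] = len(cdr3)
    lengths["FR4"] = len(j.fr4)
    seq = v.fr1_fr3 + cdr3 + j.fr4
    templated = [True] * len(v.fr1_fr3) + cdr3_flags + [True] * len(j.fr4)
    chain = AnnotatedChain(
        sequence=seq,
        regions=regions_from_lengths(lengths),
        locus=lib.locus,
        germline_v=v.fr1_fr3,
        germline_full=seq,
        templated_mask=templated,
        v_mutation_count=0,
    )
    chain.validate()
    return chain


def recombine_pair(
    library_h: GermlineLibrary,
    library_l: GermlineLibrary,
    config: SimConfig,
    rng: np.random.Generator,
    pair_id: str = "pair",
) -> PairedRecord:
    """One naive pair: independent V(D)J assembly of heavy and light chains."""
    if library_h.locus != "heavy" or library_l.locus == "heavy":
        raise ValueError("need one heavy and one light (kappa/lambda) library")
    heavy = _recombine_chain(library_h, config, rng)
    light = _recombine_chain(library_l, config, rng)
    return PairedRecord(pair_id=pair_id, heavy=heavy, light=light)


def _mutate_chain(chain: AnnotatedChain, m: int, config: SimConfig, rng) -> None:
    n = len(chain.sequence)
    m = min(m, n)
    if m == 0:
        return
    weights = np.ones(n)
    for region, start, end in chain.regions:
        if region.startswith("CDR"):
            weights[start:end] = config.cdr_hotspot_weight
    weights /= weights.sum()
    positions = rng.choice(n, size=m, replace=False, p=weights)
    seq = list(chain.sequence)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(19))]
    chain.sequence = "".join(seq)


def _recount(chain: AnnotatedChain) -> int:
    """Hamming distance to germline over templated positions; updates V count."""
    count_v_mutations(chain)
    return sum(
        1
        for s, g, t in zip(chain.sequence, chain.germline_full, chain.templated_mask)
        if t and s != g
    )


def apply_shm(record: PairedRecord, config: SimConfig, rng: np.random.Generator) -> PairedRecord:
    """Somatic hypermutation with a shared per-pair maturation intensity."""
    out = record.copy()
    if out.cell_type == "naive" or config.mutation_rate_scale == 0:
        out.meta.update(m_heavy=0, m_light=0)
        return out
    lam = rng.exponential(config.mutation_rate_scale)
    _mutate_chain(out.heavy, int(rng.poisson(lam)), config, rng)
    _mutate_chain(out.light, int(rng.poisson(0.8 * lam)), config, rng)
    out.meta.update(m_heavy=_recount(out.heavy), m_light=_recount(out.light))
    return out


def implant_specificity(
    records, config: SimConfig, rng: np.random.Generator, stats: dict | None = None
):
    """Assign balanced specificity labels and implant the positive-class motif.

    Positives receive the motif at a uniform-random in-CDRH3 offset with
    probability ``motif_implant_prob``; negatives are never modified. Records
    whose CDRH3 is shorter than the motif are skipped (label kept, implant
    dropped) and counted in ``stats['skipped']``.
    """
    records = [r.copy() for r in records]
    order = rng.permutation(len(records))
    n_pos = len(records) // 2
    positive_idx = set(int(i) for i in order[:n_pos])
    skipped = implanted = 0
    for i, rec in enumerate(records):
        if i not in positive_idx:
            rec.specificity_label = "negative"
            continue
        rec.specificity_label = "positive"
        if rng.random() >= config.motif_implant_prob:
            continue
        chain = rec.heavy
        c0, c1 = chain.region_bounds("CDR3")
        width = (c1 - c0) - len(config.motif)
        if width < 0:
            skipped += 1
            continue
        offset = c0 + int(rng.integers(width + 1))
        seq = chain.sequence
        chain.sequence = seq[:offset] + config.motif + seq[offset + len(config.motif) :]
        _recount(chain)
        implanted += 1
    if stats is not None:
        stats.update(skipped=skipped, implanted=implanted, n_positive=n_pos,
                     n_negative=len(records) - n_pos)
    return records


def default_libraries(seed: int) -> tuple:
    """The default heavy/kappa germline libraries, derived from one seed."""
    return (
        build_germline_library("heavy", n_v=8, n_d=6, n_j=4, seed=seed * 1000 + 1),
        build_germline_library("kappa", n_v=6, n_d=0, n_j=4, seed=seed * 1000 + 2),
    )


def simulate_repertoire(
    config: SimConfig,
    library_h: GermlineLibrary | None = None,
    library_l: GermlineLibrary | None = None,
):
    """Generate a full repertoire: recombine, assign donors/cell types, mutate.

    Identical config (and libraries) implies a byte-identical repertoire.
    """
    if library_h is None or library_l is None:
        library_h, library_l = default_libraries(config.seed)
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_pairs):
        rec = recombine_pair(library_h, library_l, config, rng, pair_id=f"p{i:06d}")
        rec.donor_id = f"d{int(rng.integers(config.n_donors))}"
        rec.cell_type = "naive" if rng.random() < config.naive_fraction else "memory"
        rec = apply_shm(rec, config, rng)
        records.append(rec)
    return records
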