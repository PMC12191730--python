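"""Flat-file interchange: AIRR-rearrangement-style TSV, pairs CSV, FASTA.

One TSV row per chain; a companion CSV links the two chains of each pair and
carries the pair-level labels. The ``germline_v_aa`` column is non-standard
but required to round-trip mutation bookkeeping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import REGION_ORDER, AnnotatedChain, PairedRecord, regions_from_lengths

_REGION_COLS = {
    "FR1": "fwr1_aa", "CDR1": "cdr1_aa", "FR2": "fwr2_aa", "CDR2": "cdr2_aa",
    "FR3": "fwr3_aa", "CDR3": "cdr3_aa", "FR4": "fwr4_aa",
}

AIRR_COLUMNS = [
    "sequence_id", "cell_id", "locus", "sequence_aa",
    *[_REGION_COLS[r] for r in REGION_ORDER],
    "v_call", "v_mutation_count", "germline_v_aa", "donor_id", "cell_type",
]


def _chain_row(rec: PairedRecord, chain: AnnotatedChain, which: str) -> dict:
    row = {
        "sequence_id": f"{rec.pair_id}_{which}",
        "cell_id": rec.pair_id,
        "locus": chain.locus,
        "sequence_aa": chain.sequence,
        "v_call": rec.meta.get(f"{which}_v_call", ""),
        "v_mutation_count": chain.v_mutation_count,
        "germline_v_aa": chain.germline_v or "",
        "donor_id": rec.donor_id,
        "cell_type": rec.cell_type,
    }
    for region in REGION_ORDER:
        row[_REGION_COLS[region]] = chain.region_seq(region)
    return row


def write_airr_tsv(records, tsv_path, pairs_csv_path=None) -> None:
    rows = []
    for rec in records:
        rows.append(_chain_row(rec, rec.heavy, "heavy"))
        rows.append(_chain_row(rec, rec.light, "light"))
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if pairs_csv_path is not None:
        write_pairs_csv(records, pairs_csv_path)


def write_pairs_csv(records, path) -> None:
    rows = [
        {
            "pair_id": r.pair_id,
            "sequence_id_heavy": f"{r.pair_id}_heavy",
            "sequence_id_light": f"{r.pair_id}_light",
            "pairing_label": r.pairing_label,
            "specificity_label": r.specificity_label,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["pair_id", "sequence_id_heavy", "sequence_id_light",
                 "pairing_label", "specificity_label"],
    ).to_csv(path, index=False)


def _chain_from_row(row) -> AnnotatedChain:
    lengths = {r: len(str(row[_REGION_COLS[r]])) for r in REGION_ORDER}
    chain = AnnotatedChain(
        sequence=str(row["sequence_aa"]),
        regions=regions_from_lengths(lengths),
        locus=str(row["locus"]),
        germline_v=str(row["germline_v_aa"]) or None,
        v_mutation_count=int(row["v_mutation_count"]),
    )
    return chain


def read_airr_tsv(tsv_path, pairs_csv_path) -> list:
    """Reconstruct paired records from the TSV + pairs CSV written above."""
    chains = pd.read_csv(tsv_path, sep="\t", keep_default_na=False)
    pairs = pd.read_csv(pairs_csv_path, keep_default_na=False)
    by_id = {row["sequence_id"]: row for _, row in chains.iterrows()}
    records = []
    for _, prow in pairs.iterrows():
        hrow = by_id[prow["sequence_id_heavy"]]
        lrow = by_id[prow["sequence_id_light"]]
        records.append(
            PairedRecord(
                pair_id=str(prow["pair_id"]),
                heavy=_chain_from_row(hrow),
                light=_chain_from_row(lrow),
                donor_id=str(hrow["donor_id"]),
                cell_type=str(hrow["cell_type"]),
                pairing_label=str(prow["pairing_label"]),
                specificity_label=str(prow["specificity_label"]),
            )
        )
    return records


def write_fasta(records, path) -> None:
    """Concatenated heavy+light residues per pair, for identity clustering."""
    seqs = [
        SeqRecord(Seq(r.concat_sequence), id=r.pair_id, description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def write_rejection_log(rejections, path) -> None:
    pd.DataFrame(rejections, columns=["pair_id", "reason"]).to_csv(path, index=False)
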