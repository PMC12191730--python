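"""Generate a synthetic paired antibody repertoire and inspect its structure.

Builds 500 heavy/kappa pairs (half naive, half affinity-matured), writes the
AIRR-style TSV + pairs CSV + FASTA, and prints the junction and mutation
statistics the generator is designed to reproduce: variable-length CDR3s,
high CDR3 positional diversity, and correlated heavy/light mutation loads.
"""

import numpy as np

from prefmask import io as pio
from prefmask.sim import SimConfig, simulate_repertoire

config = SimConfig(n_pairs=500, seed=0)
records = simulate_repertoire(config)

pio.write_airr_tsv(records, "repertoire_airr.tsv", "repertoire_pairs.csv")
pio.write_fasta(records, "repertoire_pairs.fasta")

cdr3_lengths = [len(r.heavy.region_seq("CDR3")) for r in records]
memory = [r for r in records if r.cell_type == "memory"]
m_h = np.array([r.meta["m_heavy"] for r in memory])
m_l = np.array([r.meta["m_light"] for r in memory])

print(f"pairs: {len(records)}  (memory: {len(memory)})")
print(f"heavy CDR3 length: mean {np.mean(cdr3_lengths):.1f}, "
      f"range {min(cdr3_lengths)}-{max(cdr3_lengths)}")
print(f"memory mutation loads: heavy {m_h.mean():.1f}, light {m_l.mean():.1f}")
print(f"corr(m_H, m_L) = {np.corrcoef(m_h, m_l)[0, 1]:.2f}")
print("-> chains co-mature: a shared per-pair intensity couples their loads,")
print("   which is the signal the native-vs-shuffled pairing task relies on.")
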