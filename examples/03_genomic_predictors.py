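"""Duplicated-gene counting and per-category gene counts (NOGF).

Generates a homology hit table with planted duplicate pairs, boundary
decoys and self hits, applies the strict E-value/coverage filter, and
counts genes per functional category from a flat gene -> category map.
"""

import numpy as np
import pandas as pd

from phyloniche import count_duplicated_genes, count_nogf
from phyloniche.simulate import simulate_hit_table

hits, expected = simulate_hit_table(
    n_genes=40, n_dup_pairs=8, rng=np.random.default_rng(5), species="sp1"
)
n_d = count_duplicated_genes(hits)  # E < 1e-5 and coverage > 30%, strict
print(f"hit table: {len(hits)} rows (pairs, boundary decoys, self hits)")
print(f"duplicated genes N_d = {n_d['sp1']} (planted: {expected})")
# Decoys sitting exactly at E = 1e-5 or coverage = 30% are excluded by the
# strict inequalities, so the planted count is recovered exactly.

gene_map = pd.DataFrame(
    [("sp1", "g1", "Exosome"), ("sp1", "g2", "Exosome"),
     ("sp1", "g2", "Ribosome"), ("sp1", "g3", "Ribosome")],
    columns=["species", "gene", "category"],
)
nogf = count_nogf(gene_map, ["Exosome", "Ribosome", "Spliceosome"])
print("NOGF counts:")
print(nogf.to_string())
# g2 carries two categories and contributes once to each; the category
# absent from the map reports 0.
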