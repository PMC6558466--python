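"""Prune a catalog so every retained SNP pair is effectively independent.

The score model multiplies per-SNP factors as if SNPs were independent, so
catalogs are pruned to pairwise dosage r-squared below 0.2. Pruning is greedy
in catalog order: the earlier-listed SNP of a correlated pair is kept.
"""

import numpy as np

from grskit import GenotypeMatrix, SNPCatalog, SNPRecord, pairwise_r2, prune_by_ld

records = tuple(
    SNPRecord(f"rs{i}", "1", 100 * i, "A", "G", 1.2, 0.4) for i in (1, 2, 3)
)
catalog = SNPCatalog("demo", records)

# rs2 duplicates rs1 (perfect LD); rs3 is independent of both.
rng = np.random.default_rng(42)
g1 = rng.binomial(2, 0.4, 500).astype(float)
g3 = rng.binomial(2, 0.4, 500).astype(float)
matrix = GenotypeMatrix(
    tuple(f"s{i}" for i in range(500)), ("rs1", "rs2", "rs3"),
    np.column_stack([g1, g1, g3]), oriented=True,
)

for a, b in [("rs1", "rs2"), ("rs1", "rs3")]:
    print(f"r2({a}, {b}) = {pairwise_r2(matrix, a, b):.3f}")

result = prune_by_ld(catalog, matrix, r2_threshold=0.2)
print(f"\nretained: {result.catalog.rsids}")
print(f"removed:  {result.removed}")
print("rs2 falls because it is a perfect proxy of the earlier-listed rs1;")
print("keeping both would double-count that locus in the score.")
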