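"""Score one individual against a small risk-SNP panel.

Each SNP contributes OR^g / W, where g counts risk alleles, OR is the
published per-allele odds ratio, and W is the Hardy-Weinberg expectation of
OR^g in the reference population. The product is interpretable as relative
risk: 1.0 means population-average risk.
"""

from grskit import SNPCatalog, SNPRecord, expected_risk_weight, grs_single

catalog = SNPCatalog(
    "demo",
    (
        SNPRecord("rs100", "1", 1000, "A", "G", odds_ratio=1.20, risk_freq=0.30),
        SNPRecord("rs200", "2", 2000, "C", "T", odds_ratio=1.35, risk_freq=0.50),
        SNPRecord("rs300", "3", 3000, "G", "A", odds_ratio=0.90, risk_freq=0.12),
    ),
)

for record in catalog:
    w = expected_risk_weight(record.risk_freq, record.odds_ratio)
    print(f"{record.rsid}: OR={record.odds_ratio:.2f} f={record.risk_freq:.2f} W={w:.4f}")

# This subject carries 2, 1 and 0 risk alleles at the three SNPs.
score = grs_single([2, 1, 0], catalog)
print(f"\nGRS = {score:.4f}")
print("A GRS above 1 reads as that many-fold the population-average risk;")
print("here the subject carries ~%.0f%% elevated risk for this trait." % ((score - 1) * 100))
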