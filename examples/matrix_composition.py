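"""Degree of methylation and phenolic class shares of apple matrices.

Uses the composition of an apple matrix with free (unbound) procyanidins:
methanol 25 mg/g and galacturonic acid 170 mg/g of alcohol-insoluble solids
give the pectin degree of methylation; the per-compound phenolic shares
(% w/w of total phenolics) are grouped into the five phenolic classes.
"""

from fermkin import (
    CompositionRecord,
    degree_of_methylation,
    phenolic_class_shares,
)

dm = degree_of_methylation(methanol=25, galacturonic_acid=170)
print(f"degree of methylation: {dm:.1f}% (rounded: {round(dm)}%)")
print("  = 100 * (25/32.04) / (170/176.13), the molar ratio of methanol to")
print("  anhydrogalacturonic-acid residues in the pectin\n")

record = CompositionRecord(
    "Mno",
    phenolics={
        "CAT": 4.16, "EPI": 8.9, "PCA": 63.9,       # flavan-3-ols
        "PLX": 0.68, "PLZ": 3.17,                   # dihydrochalcones
        "5CQA": 17.39, "pCQA": 1.10,                # hydroxycinnamic acids
        "TotalFl": 0.67,                            # flavonols
    },
    methanol=25.0,
    dpn=6.3,
)
print("phenolic class shares (% w/w of total phenolics):")
for cls, share in sorted(phenolic_class_shares(record).items()):
    print(f"  {cls:22s} {share:5.1f}")
print("\nProcyanidins dominate (flavan-3-ols ~77%), hydroxycinnamic acids "
      "are ~18%.")
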