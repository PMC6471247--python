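"""Two-way (donor, matrix) ANOVA on fitted rate constants, with pooled SD.

Fits the fractional-conversion model per replicate on a synthetic study and
asks whether the acetate production rate differs among donors and among
matrices.  The pooled standard deviation summarises replicate-to-replicate
reproducibility across all arms.
"""

import numpy as np

from fermkin import (
    GroupSummary,
    correct_study,
    fit_study,
    generate_study,
    pooled_sd,
    two_way_anova,
)

fits, _ = fit_study(correct_study(generate_study(seed=42)))
acetate = fits[fits.analyte == "acetate"].dropna(subset=["K_per_h"])

groups = [
    GroupSummary(f"{d}/{m}", len(g), float(np.std(g["K_per_h"], ddof=1)))
    for (d, m), g in acetate.groupby(["donor", "matrix"])
]
print(f"pooled SD of acetate K over {len(groups)} replicate groups: "
      f"{pooled_sd(groups):.4f} h^-1")

res = two_way_anova(acetate["K_per_h"], acetate["donor"], acetate["matrix"])
print("\nfactor    df      SS         F         p       ")
for name, eff in (("donor", res.donor), ("matrix", res.matrix)):
    print(f"{name:8s} {eff.df:3d}  {eff.ss:9.5f}  {eff.F:8.2f}  "
          f"{eff.p:9.2e}  {eff.stars}")
print(f"residual {res.residual_df:3d}  MS={res.residual_ms:.6f}")
print("\nBoth factors are significant: the generator scales rates per donor "
      "(0.65x-1.35x)\nand halves the SCFA edge rates for the Mno matrix.")
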