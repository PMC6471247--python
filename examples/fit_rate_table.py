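"""Full analysis pipeline: background-correct, fit, and tabulate rates.

Simulates a study, subtracts each donor's blank-fermenter arm, fits the
fractional-conversion model C(t) = Cinf + (C0 - Cinf)exp(-Kt) per replicate,
and prints the per-arm acetate and procyanidin rate constants.  The acetate
rates for the Mno matrix (no procyanidin-cell-wall interaction) sit at about
half of the Mnc/Mcov rates — the generator's designed contrast — while
procyanidin degradation is fastest for Mno.
"""

import tempfile
from pathlib import Path

import pandas as pd

from fermkin import PipelineConfig, generate_study, run_pipeline, write_timecourses

workdir = Path(tempfile.mkdtemp())
write_timecourses(generate_study(seed=42), workdir / "timecourses.csv")

paths = run_pipeline(PipelineConfig(input_path=workdir / "timecourses.csv",
                                    out_dir=workdir / "out"))
table = pd.read_csv(paths["rate_table"])

for analyte in ("acetate", "PCA"):
    sub = table[table.analyte == analyte].pivot_table(
        index="donor", columns="matrix", values="K_per_h"
    )[["Mno", "Mnc", "Mcov"]]
    print(f"\n{analyte} rate constants K (h^-1):")
    print(sub.round(3).to_string())

print("\nEach cell is the mean fitted K over three replicates; "
      "Mno < Mnc, Mcov for the\nSCFA and Mno > Mnc > Mcov for procyanidin "
      "degradation, per the designed multipliers.")
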