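# fermkin

Kinetic analysis of in vitro batch fecal fermentations: how fast does the
human gut microbiota ferment a food matrix into short-chain fatty acids
(SCFAs), and how fast does it degrade the matrix's procyanidins into
microbial phenolic metabolites?

`fermkin` is a library for researchers who monitor metabolite concentrations
in batch fermenters over time (typically 0–48 h, a handful of sampling
points, a no-substrate control fermenter per donor) and want reproducible
rate constants, degradation extents and donor/matrix statistics out the
other end. It ships a first-order catabolic-network simulator so the whole
pipeline can be exercised, calibrated and tested without wet-lab data.

## The model

Every background-corrected time course is fitted with the fractional
conversion model associated with a first-order reaction,

```
C(t) = C∞ + (C0 − C∞) · exp(−K·t)
```

where *C0* (mM) is the initial concentration, *C∞* the concentration at
infinite time, and *K* (h⁻¹) the rate constant. The same curve covers SCFA
production (C∞ > C0) and procyanidin degradation (C∞ < C0). Before fitting,
each matrix arm is corrected by subtracting the matching blank-fermenter arm
(the same donor's microbiota incubated without substrate), so the fitted
kinetics describe only substrate-driven chemistry.

Around the fit, the package provides:

- **`fermkin.kinetics`** — model evaluation and bounded nonlinear
  least-squares fitting, background subtraction with zero-clipping,
  observed 48-h degradation extents, and rate-table assembly;
- **`fermkin.network`** — an exact (matrix-exponential) simulator of a
  first-order reaction network encoding procyanidin catabolism: two
  hydrolysis routes from procyanidins to phenylacetic and
  phenylvaleric/valerolactone metabolites, a hydroxycinnamate route into the
  phenylpropionic series, and a carbohydrate pool feeding acetate,
  propionate and butyrate; plus a study generator (donors × matrices ×
  replicates, endogenous baselines, measurement noise);
- **`fermkin.stats`** — pooled standard deviation and a two-way
  fixed-effects ANOVA (donor, matrix; Type II sums of squares) built from
  first principles;
- **`fermkin.composition`** — matrix-composition arithmetic: pectin degree
  of methylation (molar ratio of methanol to anhydrogalacturonic acid) and
  phenolic class shares;
- **`fermkin.pipeline`** — CSV in/out and end-to-end orchestration, also
  exposed as a thin CLI (`fermkin simulate|fit|anova|composition`).

## Worked example

```python
import pandas as pd, tempfile
from pathlib import Path
from fermkin import (PipelineConfig, generate_study, run_pipeline,
                     write_timecourses)

workdir = Path(tempfile.mkdtemp())
write_timecourses(generate_study(seed=42), workdir / "timecourses.csv")
paths = run_pipeline(PipelineConfig(input_path=workdir / "timecourses.csv",
                                    out_dir=workdir / "out"))
table = pd.read_csv(paths["rate_table"])
print(table[table.analyte == "acetate"]
      .pivot_table(index="donor", columns="matrix", values="K_per_h")
      [["Mno", "Mnc", "Mcov"]].round(3))
```

prints

```
matrix    Mno    Mnc   Mcov
donor
O1      0.065  0.135  0.152
O2      0.087  0.179  0.169
O3      0.056  0.097  0.090
O4      0.091  0.203  0.197
```

Each cell is the acetate production rate constant K (h⁻¹), the mean of three
replicate fits after background correction. Mno (procyanidins free in
solution, no cell-wall interaction) ferments at roughly half the rate of Mnc
and Mcov in every donor — the contrast the simulator encodes — while donors
span a ~2–3× range in overall activity. The same run writes the corrected
time courses, per-replicate fits and the donor×matrix ANOVA table alongside
the rate table; see `examples/` for one short script per capability
(simulation, fitting, composition, statistics).

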