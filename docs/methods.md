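# Methods

## Kinetic model and fitting

Concentration time courses from batch fecal fermentations are summarised by
the fractional conversion model associated with a first-order reaction,

    C(t) = C∞ + (C0 − C∞) · exp(−K·t)

with parameters C0 (initial concentration, mM), C∞ (asymptotic
concentration, mM) and K (rate constant, h⁻¹). The model assumes a single
first-order process approaching a plateau; it is exact for a source species
of a linear reaction network and for an end-product fed by a single
first-order step, and an approximation for everything in between.
Production and degradation are distinguished only by the sign of C∞ − C0.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) on per-replicate data:

- **Initialisation** is deterministic: C0 from the first observation, C∞
  from the last, K from the slope of a log-linear regression of
  log|C(t) − C∞_init| on t (falling back to 0.1 h⁻¹ when degenerate).
- **Bounds**: K ∈ [0, 10] h⁻¹. C0 and C∞ are allowed three observed data
  ranges beyond the observed extremes. One range is not enough: a curve
  with K ≈ 0.01 h⁻¹ reveals only ~38 % of its total conversion within 48 h,
  so its true asymptote lies well outside the observed span, and a tighter
  box clips the estimate.
- **Convergence**: relative tolerance 1e-10 on parameters and cost, at most
  10,000 evaluations. Failure sets `converged=False` on the fit rather than
  raising; non-converged arms stay in the rate table, flagged.
- **Degenerate inputs**: a flat series has no identifiable K and raises;
  fewer than four distinct points cannot constrain three parameters and
  raise; duplicated sampling times are averaged with a warning.

On noiseless curves generated on the study grid (0, 2, 4, 6, 8, 10, 24, 30,
48 h) the fit recovers any (C0, C∞, K) with K ∈ [0.01, 0.5] h⁻¹ to 1e-4
relative; with additive noise at 5 % of the dynamic range the median
relative error of K over 200 replicates is about 8 % (< 15 %) for
K ∈ [0.05, 0.25] h⁻¹. Both checks run in the test suite.

Fitting is applied per replicate and the K estimates are then averaged per
(donor, matrix, analyte). Fitting the mean curve instead is equally
defensible on the data the model targets; per-replicate fitting was chosen
because it preserves replicate dispersion for the pooled-SD and ANOVA
summaries. C∞ is left free (not constrained to zero for degraded
substrates): the degradation of a partly inaccessible substrate genuinely
plateaus above zero, and a free asymptote lets the data decide.

## Background correction

Fecal microbiota produce metabolites without any added substrate, so every
matrix arm is corrected by pointwise subtraction of the blank-fermenter arm
of the same donor, replicate and analyte. Negative corrected values cannot
be concentrations; by default they are clipped to zero and the clipped
indices are recorded on the time course and logged. Grids are required to
be identical (both arms of a study are sampled on the same schedule);
linear interpolation of the control onto the sample grid is available
behind an explicit flag for irregular data.

The 48-h degradation extent, 100·(C(0) − C(48))/C(0), uses observed
endpoint values rather than fitted parameters, because "percent degraded
after 48 h" is a statement about the incubation actually performed, not
about the extrapolated asymptote. Extent is reported only for arms whose
fitted direction is degradation; for production analytes the quantity is
meaningless (C(0) is noise around zero after correction) and is left NaN.

## The synthetic-data generator

The generator emulates a 48-h batch study: 4 donors × 3 matrices (Mno,
Mnc, Mcov) × 3 replicates plus a no-matrix control arm per donor, sampled
at 0, 2, 4, 6, 8, 10, 24, 30 and 48 h.

**Reaction network.** Species and edges encode the microbial catabolism of
procyanidins: one route from procyanidins (PCA) via
3,4-dihydroxyphenylacetic acid to the end-product 3-hydroxyphenylacetic
acid; a second via the phenyl-γ-valerolactones to
5-(3-hydroxyphenyl)valeric acid, with a slow additional drain into the
phenylpropionic series; hydroxycinnamates degrading through
3-(3,4-dihydroxyphenyl)propionic and 3-(3-hydroxyphenyl)propionic acids to
3-phenylpropionic acid; and a carbohydrate pool feeding acetate, propionate
and butyrate through parallel edges. An optional low-rate edge from
flavonols into the phenylacetic branch is off by default. Yields default
to 1 (no stoichiometry is imposed); all rates are free parameters of the
generator, calibrated once to reproduce qualitative timing — intermediates
peaking between 2 and 10 h, end-products plateauing by 48 h — not claimed
to be measured values. Default initial pools (procyanidins 0.8 mM,
hydroxycinnamates 0.45 mM, carbohydrates 83 mM hexose-equivalents) put the
simulated SCFA plateaus near 58/12/12 mM (acetate/propionate/butyrate) and
the phenolic metabolites in the 0.05–0.5 mM range.

**Solution.** The system dx/dt = A·x is linear with constant coefficients
and is solved exactly as x(t) = expm(A·t)·x(0); the simulator agrees with
the Bateman closed form on 2- and 3-species chains to 1e-8 relative and
conserves mass under unit yields.

**Donor and matrix effects.** Edge rates are scaled per arm by
multipliers keyed by edge source species (`"*"` = all edges). Defaults:
donors scale all rates by 1.0/1.25/0.65/1.35 (O1–O4), spanning the
few-fold inter-individual spread typical of fecal inocula; the Mno matrix
halves the carbohydrate (SCFA) edge rates and multiplies procyanidin
degradation by 1.4, while Mcov multiplies it by 0.9 — encoding the
qualitative contrast that free procyanidins inhibit carbohydrate
fermentation most and are themselves degraded fastest.

**Baselines and noise.** Endogenous metabolite baselines (0.002–0.2 mM
per species) are added to every arm; control arms contain baselines plus
noise only. Default noise is additive Gaussian with σ = 5 % of each
series' dynamic range (floor 0.001 mM), negative draws clipped to zero; a
multiplicative lognormal option exists. Per-arm random substreams are
derived deterministically from the study seed and a CRC of the arm key, so
a study is bit-reproducible regardless of arm iteration order.

**What the generator does not emulate.** No bacterial growth dynamics,
enzyme inhibition, cell-wall porosity, pH or gas effects; no partly
inaccessible substrate fraction, so simulated procyanidins degrade to
completion whereas real matrices retain 16–42 % at 48 h; noise is
homoscedastic per series, whereas analytical error typically grows with
concentration. Passing recovery tests therefore demonstrates correctness
of the estimation machinery under a known first-order truth, not the
adequacy of first-order kinetics for any particular real fermentation.

## Statistics

**Pooled SD** across replicate groups is
sqrt(Σ(nᵢ−1)·sdᵢ² / Σ(nᵢ−1)); groups with fewer than two observations
contribute no degrees of freedom and are ignored.

**Two-way ANOVA** (donor, matrix) is a fixed-effects main-effects model
with Type II sums of squares computed by explicit design-matrix least
squares: each factor's SS is the increase in residual SS when it is
dropped from the two-factor model. On balanced data this equals the
sequential decomposition; Type II was chosen because a single lost
fermenter is the typical imbalance in such studies and Type II keeps each
main effect adjusted for the other. No interaction term is fitted (one
observation per cell after replicate averaging would leave it
unidentifiable in the rate tables) and no multiple-testing correction is
applied. F = MS_factor/MS_residual with p from the F distribution;
significance stars at p ≤ 0.05/0.01/0.001. The implementation is
cross-checked in the tests against statsmodels' `anova_lm` (Type II) on
unbalanced data and against a brute-force projection oracle on balanced
data, and its type-I error rate is calibration-tested at α = 0.05 over
2000 null simulations.

The per-arm statistic entering the concentration ANOVA is the 48-h value
for end-products (3-phenylpropionic and 3-hydroxyphenylacetic acids,
5-(3-hydroxyphenyl)valeric acid, acetate, propionate, butyrate) and the
per-curve maximum for transient intermediates (the dihydroxy acids and
valerolactones), which peak mid-incubation. Rate constants are analysed
per replicate.

## Composition arithmetic

Degree of methylation = 100 · (methanol/32.04)/(GalA/176.13), i.e. the
molar ratio of methanol to galacturonic acid, with the galacturonic acid
counted as the polymeric anhydro residue (176.13 g/mol). This convention
reproduces a reference apple-pectin cell (25 mg/g methanol, 170 mg/g GalA
→ 80.8 % → 81 %) exactly; the free-acid mass (194.14 g/mol) does not.
Printed compositions of companion matrices deviate by ≤ 2 points under the
same convention, consistent with rounding of the published inputs.
Phenolic class shares are plain sums of per-compound shares within
flavan-3-ols, dihydrochalcones, hydroxycinnamic acids, flavonols and
anthocyanins; unknown compound codes are rejected by name, and DPn (degree
of polymerisation) is carried as data, never computed.

## Problem sizes and determinism

The default synthetic study (192 time courses) fits in ~2 s; the full test
suite, including the 2000-simulation ANOVA calibration and 200-replicate
noisy-recovery checks, runs in well under a minute. All randomness flows
from explicit seeds; identical inputs and seed give byte-identical output
CSVs.

## Known limitations

- The fractional-conversion fit is a three-parameter summary; it cannot
  represent the rise-and-fall of transient intermediates, which are instead
  summarised by their observed maximum.
- Extent and plateau statements depend on the 48-h horizon; slow arms
  (K ≲ 0.02 h⁻¹) are summarised far from their asymptote, where K and C∞
  are strongly correlated and individually imprecise.
- The ANOVA treats donors as fixed effects, matching the tabulated-study
  convention it mirrors; generalisation to a donor population would require
  a mixed model, which is out of scope.
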