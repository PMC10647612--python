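# Methods

`sweetval` implements the computational half of a single-laboratory
validation of a targeted LC-MS/MS assay for nine steviol glycosides
(rebaudiosides A–D and F, rubusoside, dulcoside A, stevioside,
steviolbioside) in three food matrices (non-alcoholic beverage, yogurt,
snack). This note records the model, the statistics, the synthetic-data
generator that stands in for the instrument, and the numerical and
design choices a maintainer would want to know about.

## Identification model

Each analyte is defined by an SRM transition record: a negative-mode
precursor m/z, one quantifier product ion (most intense transition,
used for quantitation) and two qualifier product ions, plus a reference
retention time on a 13-minute C18 gradient. A peak is assigned to an
analyte when precursor and one product m/z both match within `mz_tol`
(default 0.5 m/z, unit resolution on a triple quadrupole) and the
retention time agrees with the reference within an RPD window
(default 5%). Ties break on smallest RT discrepancy, then smallest
precursor error, then analyte name, making assignment deterministic and
independent of input order. Two isobaric pairs (stevioside /
rebaudioside B at precursor 803.458; rubusoside / steviolbioside at
nominal 641) are separated by retention time alone; at the default
tolerances their RT discrepancy (≥ 12% RPD) excludes cross-assignment.
Identity is confirmed by the *presence* of at least one qualifier
transition; quantifier/qualifier area-ratio banding is deliberately not
the default because presence-only confirmation is what the assay design
assumes. Shrinking either tolerance can only remove assignments
(monotonicity), which the property tests exercise.

## Calibration

Response is modelled as linear in concentration, `y = a·x + b`, fit by
unweighted ordinary least squares over 0.2/0.3/0.4/0.5/0.8/1.0 mg/L
with triplicate injections entered as individual points (not level
means), so that per-level response %RSD is preserved for the linearity
check. R² is 1 − SSE/SST with the intercept always included. A fit is
accepted as linear when R² > 0.99 and every level's %RSD is below 15%.
1/x weighting exists behind a config switch but is off by default since
the validation design uses unweighted curves. Back-calculation is
`(y − b)/a`; negative concentrations are passed through flagged, as
they are candidates for censoring, not errors.

## Validation statistics

With sample standard deviations (n−1) throughout:

* retention-time agreement: %RPD = 100·|RT₁−RT₂| / ((RT₁+RT₂)/2),
  accepted below 5%;
* repeatability: %RSD = 100·SD/x̄, accepted below 20% (below 15% for
  the linearity and survey-QC checks);
* reproducibility: HorRat = %RSD / PRSD with the Horwitz function
  PRSD = 2^(1 − 0.5·log₁₀ C), C a dimensionless mass fraction
  (mg/L values are converted as C·10⁻⁶, assuming unit density so
  mg/L ≈ mg/kg); accepted below 2.0. The Thompson low-concentration
  modification is intentionally not applied;
* accuracy: recovery % = 100·(x̄_spiked − x̄_blank)/x_spike, accepted
  in 70–120%; the blank mean defaults to 0 for analyte-free blanks;
* matrix effect: %ME = 100·(signal in spiked matrix)/(signal in
  solvent), computed per replicate pair and summarized per level as
  mean ± SD; 100 means no effect, below 100 ionization suppression,
  above 100 enhancement; accepted in 80–120%;
* detection limits: S₀ = SD of the replicates at the lowest spiked
  level (back-calculated concentrations), S₀′ = S₀/√n with n the
  number of replicates averaged when reporting (default n = 1; a plain
  /n divisor is available behind `sqrt_n=False` for compatibility with
  texts that print that form), LOD = 3·S₀′ and LOQ = 10·S₀′, so
  LOQ/LOD = 10/3 identically before rounding. LOD/LOQ are additionally
  reported in steviol equivalents (below).

Left-censored results are substituted per scenario: lower bound → 0,
middle bound → ½·LOD (or ½·LOQ), upper bound → LOD (or LOQ); totals are
monotone lower ≤ middle ≤ upper by construction.

Steviol equivalents: [SE] = CF·[SG], with default conversion factors
equal to the molecular-weight ratio MW(steviol C₂₀H₃₀O₃)/MW(glycoside)
(the JECFA convention), computed from the glycoside formulas; a CSV
table can override them. The formula used for steviolbioside is
C₃₂H₅₀O₁₃, consistent with its precursor m/z and the literature.

Reported values are rounded half away from zero (2 decimals for
concentrations and percentages, 3 for LOD/LOQ), which reproduces
boundary cases such as a mean of 2.075 printing as 2.08.

## Synthetic-data generator

The generator emulates the full study design so that the pipeline has
known ground truth. Its defaults are the design itself: 9 analytes ×
3 matrices, 6 calibration levels × 3 replicates, 3 spike levels
(0.2/0.5/1.0 mg/L) × 7 replicates, 3 blank injections, matrix-effect
pairs at the spike design, and a 38-specimen survey (20 beverages,
10 yogurts, 8 snacks) measured in triplicate with ~50% of analytes
present per specimen at lognormal concentrations (median ≈ 0.5 mg/L,
inside the calibration range).

The detector model is

    y = me · (a·C_extract + b) · (1 + ε),  ε ~ N(0, noise_cv)

where `C_extract = C·rec` for spikes taken through the whole
preparation, `C_extract = C` for post-extraction standards
(matrix-matched calibration and matrix-effect arms), and `me = rec = 1`
in solvent. The suppression factor multiplies the *whole* detected
signal, background term included: under this form the matrix-effect
ratio estimator and the recovery estimator (quantified against the
matrix-matched curve, which carries slope `a·me` and intercept `b·me`)
are unbiased for `me` and `rec`, which makes the generator's parameters
identifiable by the pipeline — the property the parameter-recovery
tests verify. Noise is multiplicative (proportional CV) because every
acceptance band in the validation is relative; retention times are
jittered N(0, `rt_jitter_sd`) around the reference values. Blank
injections emit zero-mean noise only.

Default noise settings: `noise_cv = 0.03` (giving back-calculated
repeatability %RSDs of roughly 1–8%, the magnitude a well-behaved
electrospray assay shows at these levels) and `rt_jitter_sd = 0.01` min
(RPDs well under the 5% window). Default per-analyte slopes and
intercepts are plausible electrospray magnitudes for these compounds
(tens of thousands of area units per mg/L); default matrix factors are
`me` = 1.02/0.85/1.05 and `rec` = 0.95/0.88/1.00 for
beverage/yogurt/snack — dairy suppresses hardest, snack mildly
enhances. At these settings an occasional matrix-matched R² falls just
below the 0.99 band (e.g. 0.987–0.989 on some seeds); this is the
realistic borderline scatter of the design, and such cells are reported
as failures rather than smoothed away.

What the generator does *not* emulate: chromatographic peak shape and
integration, carryover and drift, inter-day effects, analyte-specific
matrix interactions beyond a single per-matrix factor, and additive
noise floors (an option exists but defaults off). Passing tests
therefore demonstrate that the statistics, censoring and reporting are
correct and that the pipeline recovers known effect sizes from data
with this covariance structure — not that any particular real assay
would meet the bands.

## Parameter-recovery experiment design

Bias of the matrix-effect and recovery estimators is checked on a 3×3
grid of (me, rec) ∈ {0.8, 1.0, 1.2} × {0.85, 0.95, 1.05}, 100 seeds per
grid point, one analyte in one matrix per run to keep the suite fast.
The comparison tolerance is the design's Monte-Carlo tolerance — 2
percentage points for the matrix effect and 3 for recovery, never
tighter than twice the measured MC standard error. A literal 2·SE check
per grid point would false-alarm on ~5% of the 18 point-statistics even
for an exactly unbiased estimator, and the per-replicate ratio
estimator used for reporting carries a small O(cv²) Jensen bias that is
real but an order of magnitude inside these tolerances. LOD scaling is
checked separately: doubling `noise_cv` must double the estimated LOD
(ratio in [1.8, 2.2] over 200 paired seeds).

## Degenerate inputs and tie-breaks

Single-replicate sets report no SD (and no %RSD/HorRat) rather than
erroring; constant replicates give LOD = LOQ = 0; a zero calibration
slope is an error only at back-calculation time; missing input roles
degrade the corresponding criterion to "not evaluated" instead of
aborting the run, and the CLI exits 0 whenever a report was produced
(failed criteria are results, not crashes; only schema/config errors
exit 2).

## Problem sizes

The shipped analysis and the acceptance script run the full design
(3,456 observation rows, 54 peaks) once per invocation — a few seconds
on one CPU. The Monte-Carlo suites (900 grid runs, 400 LOD runs) use
the one-analyte reduction and complete in well under a minute.
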