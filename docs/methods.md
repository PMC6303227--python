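# Methods

`saltphenome` re-implements, as a tested library, the analysis pipeline
of a conveyor-greenhouse salinity screening of wild and cultivated rice:
daily multi-view shoot images and gravimetric watering records in, and
smoothed growth trajectories, water-use indices, tolerance indices,
genotype × salinity inference and the randomisation design out.  A
synthetic-experiment generator with known ground truth stands in for the
(unreleased) greenhouse data, so every stage is checkable by parameter
recovery.

## Projected shoot area and the hybrid trait

Projected shoot area (PSA, kilopixels) is the sum of per-view plant
areas: two side views at 90° plus a top view for the RGB camera, the two
side views for the fluorescence (FLUO) camera.  Because tall plants
eventually outgrow the RGB field of view, the analysed trait is a
*hybrid*: RGB PSA for DAS 4–19 and FLUO PSA from DAS 20 onwards, with
FLUO mapped onto the RGB scale by an ordinary least-squares fit of RGB
on FLUO across all plants on the splice day (day 20), on the raw
observations.  Both the splice day and an intercept-free variant are
configurable (`splice_das`, `through_origin`); the default keeps the
intercept, since the two optical systems need not agree at zero area.

Calibration is a pooled cross-sectional regression, so it inherits the
usual errors-in-variables caveat: with multiplicative measurement noise
on both cameras the slope is attenuated by the (high) reliability of the
splice-day area spread, and the intercept absorbs the complementary
bias.  Accuracy of the fitted *mapping* is therefore assessed over the
central range of the splice-day observations, where the splice actually
operates, rather than coefficient-by-coefficient at the extremes.

## Smoothing splines parameterised by effective df

Each plant's series y_i at days x_i is smoothed by the natural cubic
smoothing spline minimising Σ(y_i − f(x_i))² + λ∫f″², in Reinsch form
with the penalty matrix K = QR⁻¹Qᵀ.  The smoothness control is the
effective degrees of freedom df = tr[(I + λK)⁻¹]; λ is found by Brent
root-finding on log λ to |tr − df| ≤ 10⁻³.  The default df = 5 is the
setting conventional for 30-day shoot-area series.  Two limits anchor
the implementation: df = 2 reproduces the ordinary least-squares line
(the penalty's null space) and df = n the natural-spline interpolant;
both serve as closed-form oracles in the tests.  Between knots the
fitted spline is evaluated exactly via the natural cubic interpolant of
its fitted values, which coincides with the smoothing spline.

Missing days are simply absent from the fit — no imputation — mirroring
the blank-value rule used for corrupted watering records.

## Growth rates, water use, WUI

The absolute growth rate (AGR, kpx day⁻¹) differences the sPSA spline
over consecutive observed days; the relative growth rate (RGR, day⁻¹)
differences a *separate* spline fitted to ln PSA with the same df,
matching the convention of differencing consecutive ln PSA values and
avoiding the bias of logging a raw-scale smooth.  Daily water use is
weight-after-watering(t−1) − weight-before-watering(t), with negative
values (leakage) blanked and logged.  The daily water-use index is
smoothed AGR / water use, missing (never infinite) where water use is
missing or zero.  Interval summaries over the standard endpoints
{4, 9, 14, 19, 23, 28} are endpoint differences divided by interval
length — on the PSA scale for AGR, the ln PSA scale for RGR — so
length-weighted interval AGRs telescope exactly to the total sPSA
change; interval WUI divides the sPSA gain by the summed water loss of
the interval (water on day t belongs to the interval containing t under
the day-ending convention).

## Tolerance indices

ST = 100·(mean SDW under salt)/(mean SDW control), at 80 mM by
convention; Na⁺/K⁺ from the leaf ion assay; chlorophyll and biomass
normalised as ratios of group means (not means of ratios); relative
senescence as a percent increase of the group mean over control.  The
tissue-water re-expression divides a dry-weight concentration by
(FW/DW − 1), the grams of tissue water per gram dry matter; dividing by
FW/DW itself would misattribute the dry mass as water.  Note the two
published worked values for this quantity read in genotype order are
mutually inconsistent with their own inputs (114/2.6 = 43.8 belongs with
the FW/DW = 3.6 accession, 83/2.4 = 34.6 with 3.4); the implementation
follows the arithmetic.

## Inference

The genotype × salinity analysis replaces the original spatial mixed
model (REML, residual variance structures) with a fixed-effects
linear model — genotype*treatment + replicate block, homoscedastic
residuals — which on a balanced design reproduces raw cell means
exactly.  This is a deliberate simplification: the maximal mixed model
is facility-specific and not recoverable from its citation, while the
fixed-effects model preserves the quantities the downstream comparisons
need.  Wald F-tests use type-II sums of squares and the fixed-model
residual df.  Pairs of predicted means are compared by the approximate
t statistic (μ_a − μ_b)/√(se_a² + se_b²) against a standard normal
reference by default (a t reference with user-supplied df is available);
when cell variances are flagged unequal, each prediction's variance is
replaced by half the average variance of the pairwise differences it
participates in before testing.  One-way screening traits use ANOVA
with Tukey HSD (studentized range); interval-wise comparisons are
deliberately unadjusted.  Genotype-level ST-vs-ion relationships use
OLS with R² = squared Pearson correlation.

## Experimental design generation

Lines are assigned to main units by a 7 × 6 Youden square built by
deleting one row of the cyclic Latin square of order 7 and randomising
rows, columns and labels: rows are complete replicates and the seven
columns form a BIBD with v = b = 7, r = k = 6, λ = 5.  Within each main
unit (2 lanes × 2 positions) the four salt treatments are split into two
lane-blocks of two; the three possible pairings are allocated 14 times
each across the 42 main units so all six treatment pairs have equal
block concurrence, then randomised.  A `validate_layout` checker
enforces the invariants (each replicate holds all 28 line × treatment
combinations once; each main unit one line and all four treatments; no
slot reused) and works on externally supplied layouts.

## The synthetic experiment

The generator emulates the screening's structure, not its pixels.  Per
plant and day (DAS 0 at first salt application):

- growth: multiplicative discrete logistic,
  area′ = area·exp[g(1 − area/K)] with
  g = r0·max(0, 1 − β_osm·C(t))·max(0, 1 − β_ion·A(t)) — an immediate
  osmotic penalty in the external concentration C(t) and a cumulative
  ionic penalty in internal shoot Na⁺ A(t);
- salt: C(t) follows the staged ramp (25, then up to 40, 80, 100 mM
  daily increments), then holds the target; EC values are stored as
  metadata only (the source protocol prints one more EC value than salt
  levels in its first screening, so the 40 mM pairing is ambiguous);
- ion accumulation: A′ = A + u·C(t)·(1 − exclusion), u = 0.001
  Na-units/(mM·day); `exclusion` ∈ [0, 1] is the genotype's shoot
  Na⁺-exclusion capacity, the simulator's central tolerance axis;
- senescence: a logistic function of A (half-point 1.5 Na-units, width
  0.4, ceiling 0.6), so a perfect excluder stays at the no-salt
  baseline; chlorophyll declines with senescence; SES (1–9) increases
  with senescence excess over baseline, so unstressed plants score 1;
- transpiration: 1.5 mL per kpx of green (non-senescent) area per day
  with 5 % lognormal genotype noise; watering tables are built by exact
  water balance around the 600 mL target, so gravimetric water use
  recovers transpiration exactly in the noiseless limit;
- observation: per-camera totals get mean-one lognormal noise (CV 3 %
  by default) and are split into fixed view fractions; FLUO sees
  intercept + slope·area; RGB totals after `rgb_last_valid_das`
  (default 20, i.e. trustworthy through the calibration day) are shrunk
  by a fixed factor 0.7 — a deliberately crude stand-in for
  field-of-view loss, since the pipeline only requires RGB to be
  untrustworthy after the splice;
- harvest: SFW allometric in final area (0.12 g/kpx), SDW/SFW = 0.28
  (FW/DW ≈ 3.6), leaf Na⁺ = 20 + 150·A μmol g⁻¹ DW, K⁺ around a
  genotype mean, all with 10 % lognormal noise.

Default panel: seven lines spanning exclusion 0.30–0.90 and r0
0.08–0.14 day⁻¹ (intrinsic RGR of the order observed for rice
seedlings), K 300–550 kpx; four treatments; six replicates; 30 days;
lane effects N(0, 0.05) on the log scale and 5 % initial-size jitter.
Randomness fans out from one seed to per-plant substreams by stable
hashing of plant ids, so subsetting plants does not change their draws.

What the generator does *not* emulate: diurnal physiology, root
compartments, developmental switches (e.g. flowering arrest of vigorous
lines), spatially correlated residuals beyond a lane effect, or
non-multiplicative measurement error.  Passing recovery tests therefore
demonstrates correctness of the *estimators* under the stated generative
assumptions, not robustness to every feature of real greenhouse data.

## Numerical choices and scale of the test problems

Penalty search tolerance 10⁻³ on tr(S); spline systems are dense
(n ≤ ~30 points per plant).  Degenerate inputs: non-positive PSA is
rejected before logs; zero or missing water gives missing WUI; interval
endpoints outside a plant's fitted range raise.  Calibration refuses
fewer than three paired plants or zero FLUO variance.  Monte-Carlo
checks run at sizes chosen to keep the full suite around half a minute
on one CPU: 1000 null pairs for the approximate-t calibration, 500
reduced-size experiments (3 lines × 2 levels × 3 replicates, 20 days)
for the Wald-F null, 150 plants for camera-calibration recovery, 100
seeded runs for interaction power.

## Known limitations

- The fixed-effects model understates SE inflation that a spatial
  residual model would capture; Wald denominators use fixed-model
  residual df because the original mixed-model df are not recoverable.
- The FLUO→RGB calibration is least-squares, not errors-in-variables;
  at 3 % camera noise the induced mapping bias is well under the
  acceptance band, but heavier noise would warrant a measurement-error
  model.
- SES is stored and simulated as an integer 1–9 only; the visual-scoring
  rubric itself is out of scope, as are pixel-level segmentation and
  chlorophyll extraction chemistry.
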