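# saltphenome

Image-based salinity-tolerance analysis for rice screening experiments.

High-throughput phenotyping platforms image each plant daily from
several camera angles and weigh every pot before and after watering.
`saltphenome` turns those records into the quantities a salinity
screening actually reports — smoothed growth trajectories, growth and
water-use rates, scalar tolerance indices, and genotype × salinity
inference — and ships a synthetic-experiment generator with known
ground truth so the entire pipeline can be exercised and validated
without any external data.  It is aimed at plant phenomics analysts and
quantitative geneticists working with conveyor-greenhouse (cart/lane)
salinity trials.

## What it computes

- **PSA** (projected shoot area, kilopixels): per-camera sums of view
  areas; a **hybrid** trait splices RGB (early days) with fluorescence
  (late days) after a linear cross-calibration fitted on the splice day,
  because tall plants outgrow the RGB field of view.
- **sPSA, AGR, RGR**: per-plant natural cubic smoothing splines
  parameterised by effective degrees of freedom (trace of the smoother
  matrix; default df = 5).  AGR = ΔsPSA/Δt; RGR = Δln PSA/Δt from a
  spline fitted to ln PSA.  Interval summaries over DAS
  {4, 9, 14, 19, 23, 28}.
- **Water use and WUI**: daily pot-weight loss (negative values
  blanked), WUI = growth per mL transpired, daily and per interval.
- **Tolerance indices**: ST = 100·SDW(salt)/SDW(control), shoot Na⁺/K⁺,
  chlorophyll/biomass normalised to control, relative senescence,
  tissue-water re-expression c_tw = c_dw/(FW/DW − 1).
- **Statistics**: ANOVA + Tukey HSD; fixed-effects genotype*treatment +
  replicate-block predicted means with Wald F-tests and approximate
  pairwise t-tests (unequal-variance adjustment available); ST-vs-ion
  regressions; squared Pearson correlations.
- **Design**: 7 × 6 Youden square (λ = 5) and resolved treatment
  pair-blocks assembled onto the lane × position cart grid, with a
  layout validator.

See `docs/methods.md` for the model details and assumptions.

## A worked example

```python
from saltphenome import (SimulationConfig, simulate_experiment, compute_psa,
                         calibrate_hybrid, build_hybrid_series,
                         fit_smoothing_spline, derive_rates, interval_summaries)

tables = simulate_experiment(SimulationConfig(seed=1))   # 7 lines x 4 NaCl x 6 reps
rgb  = compute_psa(tables["imaging"], "RGB")
fluo = compute_psa(tables["imaging"], "FLUO")
fit  = calibrate_hybrid(rgb, fluo, splice_das=20)
hybrid = build_hybrid_series(rgb, fluo, fit)
smoothed = {p: derive_rates(fit_smoothing_spline(s, df=5))
            for p, s in hybrid.items()}
print(interval_summaries(smoothed).head())
```

With seed 1 the calibration prints
`rgb = 0.11 + 0.998 * fluo (n = 168, r^2 = 0.985)` — the two cameras are
generated in 1:1 relation, and the fitted map recovers it — and the
interval table gives, e.g., mean control AGR over DAS 4–9 of
1.69 kpx/day for the vigorous salt-tolerant standard versus
0.67 kpx/day for the salt-sensitive one; at 100 mM NaCl those fall to
1.18 and 0.46.  Growth suppression by salt, and its genotype dependence,
is read directly off these interval rates.

The `examples/` directory has one short script per capability
(simulation, growth trajectories, WUI, tolerance indices, inference,
design), each printing the numbers it computes and what they mean.  A
thin CLI mirrors the pipeline
(`saltphenome simulate|design|smooth|traits|indices|stats|run|validate`);
`saltphenome run --out-dir results --seed 1` executes the whole chain
and writes every artifact as CSV with a config-hash header.

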