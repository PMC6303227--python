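"""From raw camera views to smoothed growth trajectories.

Builds per-plant projected shoot area (PSA) from the two cameras,
cross-calibrates fluorescence onto the RGB scale at the day-20 splice,
fits a df = 5 natural cubic smoothing spline per plant, and derives the
absolute and relative growth rates over the standard intervals.
"""

from saltphenome import (
    SimulationConfig,
    build_hybrid_series,
    calibrate_hybrid,
    compute_psa,
    derive_rates,
    fit_smoothing_spline,
    interval_summaries,
    simulate_experiment,
)

tables = simulate_experiment(SimulationConfig(seed=1))
rgb = compute_psa(tables["imaging"], "RGB")
fluo = compute_psa(tables["imaging"], "FLUO")

fit = calibrate_hybrid(rgb, fluo, splice_das=20)
print(f"FLUO -> RGB calibration at DAS {fit.splice_das}: "
      f"rgb = {fit.intercept:.2f} + {fit.slope:.3f} * fluo "
      f"(n = {fit.n_points}, r^2 = {fit.r_squared:.3f})")

hybrid = build_hybrid_series(rgb, fluo, fit)
smoothed = {p: derive_rates(fit_smoothing_spline(s, df=5))
            for p, s in hybrid.items()}

summary = interval_summaries(smoothed).merge(
    tables["metadata"][["plant", "genotype", "treatment"]], on="plant")
mean_agr = (summary[summary.genotype.isin(["Pokkali", "IR29"])]
            .groupby(["genotype", "treatment", "interval"], sort=False)
            ["agr_kpx_day"].mean().round(2).unstack("interval"))
print("\nMean absolute growth rate (kpx/day) per interval of days after salting:")
print(mean_agr.to_string())
print("\nPokkali (salt-tolerant, vigorous) grows several-fold faster than the"
      "\nsalt-sensitive IR29 in every interval, and salt depresses late-interval"
      "\ngrowth in both.")
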