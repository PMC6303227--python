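"""Generate a complete synthetic salinity screening.

Seven rice lines (two O. sativa standards and five wild accessions with
different Na+ exclusion capacities) x four NaCl levels (0/40/80/100 mM,
applied as staged daily increments) x six replicates, imaged daily by
RGB and fluorescence cameras for 30 days after salting and watered to a
600 mL target.
"""

from saltphenome import SimulationConfig, simulate_experiment

config = SimulationConfig(seed=1)
tables = simulate_experiment(config)

for name in ("imaging", "watering", "harvest", "ion", "metadata"):
    print(f"{name:9s} {tables[name].shape[0]:6d} rows x {tables[name].shape[1]} cols")

print("\nFirst imaging rows (one per plant x day x camera x view, kilopixels):")
print(tables["imaging"].head(5).to_string(index=False))

print("\nHarvest of one tolerant and one sensitive line at 100 mM:")
harvest = tables["harvest"].merge(tables["metadata"], on="plant")
sel = harvest[(harvest.treatment == "100mM")
              & harvest.genotype.isin(["Oa-VR", "Oa-D"])]
print(sel.groupby("genotype")[["sdw_g", "chlorophyll_mg_g", "ses"]]
      .mean().round(2).to_string())
print("\nThe excluder (Oa-VR) keeps more biomass and chlorophyll and a lower"
      "\nvisual salt-injury score (SES) than the weak excluder (Oa-D).")
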