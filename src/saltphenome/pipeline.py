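"""End-to-end orchestration: config, table validation, and the full run.

The pipeline consumes five CSV tables (imaging, watering, harvest, ion,
metadata) — either read from disk or produced by the synthetic
experiment generator — and emits tidy per-plant trait tables, interval
summaries, tolerance indices and the inferential tables.  All outputs
are CSV (UTF-8, dot decimal) with units encoded in column names and a
header comment carrying a hash of the configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import growthcurves as gc
from . import indices as idx
from . import stats as st
from .simulate import SimulationConfig, simulate_experiment

__all__ = ["RunConfig", "run_pipeline", "validate_tables", "load_tables"]

log = logging.getLogger(__name__)

TABLE_NAMES = ("imaging", "watering", "harvest", "ion", "metadata")

REQUIRED_COLUMNS = {
    "imaging": {"plant", "das", "camera", "view", "area_kpx"},
    "watering": {"plant", "das", "weight_before_g", "weight_after_g",
                 "water_added_mL"},
    "harvest": {"plant", "sfw_g", "sdw_g", "tillers", "chlorophyll_mg_g",
                "ses", "senescence"},
    "ion": {"plant", "na_umol_gdw", "k_umol_gdw"},
    "metadata": {"plant", "genotype", "treatment", "replicate"},
}


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Either ``input_dir`` points at the five CSV tables, or ``simulate``
    holds a `SimulationConfig` and the tables are generated.  Defaults:
    spline df 5, splice day 20, interval endpoints 4/9/14/19/23/28,
    alpha 0.05, salt level for the tolerance indices 80 mM.
    """

    input_dir: Path | None = None
    simulate: SimulationConfig | None = None
    df: float = 5.0
    splice_das: int = 20
    endpoints: tuple[int, ...] = gc.DEFAULT_ENDPOINTS
    alpha: float = 0.05
    salt_level: str = "80mM"
    control_level: str = "0mM"
    seed: int = 0
    out_dir: Path = Path("results")

    def __post_init__(self) -> None:
        self.endpoints = tuple(int(e) for e in self.endpoints)
        if any(b <= a for a, b in zip(self.endpoints, self.endpoints[1:])):
            raise ValueError("endpoints must be strictly increasing")
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
            if not self.input_dir.is_dir():
                raise FileNotFoundError(f"input_dir {self.input_dir} does not exist")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulationConfig(**sim) if isinstance(sim, dict) \
                else SimulationConfig()
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs are
        written does not change what they contain)."""
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def load_tables(input_dir: Path) -> dict[str, pd.DataFrame]:
    """Read the five pipeline tables from ``<input_dir>/<name>.csv``."""
    tables = {}
    for name in TABLE_NAMES:
        path = Path(input_dir) / f"{name}.csv"
        if not path.is_file():
            if name == "watering":
                log.warning("watering table absent: water traits will be skipped")
                continue
            raise FileNotFoundError(f"missing table: {path}")
        tables[name] = pd.read_csv(path, comment="#")
    return tables


def validate_tables(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Schema and sanity checks; returns a list of problem descriptions.

    Checks required columns, duplicate plant x day x camera x view
    imaging rows, negative areas, and non-integer or out-of-range SES
    scores.  An empty report means the tables are clean.
    """
    report: list[str] = []
    for name, required in REQUIRED_COLUMNS.items():
        if name not in tables:
            if name in ("watering",):
                continue  # optional: pipeline degrades without water traits
            report.append(f"{name}: table missing")
            continue
        cols = set(tables[name].columns)
        missing = required - cols
        if missing:
            report.append(f"{name}: missing columns {sorted(missing)}")
    img = tables.get("imaging")
    if img is not None and not (REQUIRED_COLUMNS["imaging"] - set(img.columns)):
        dup = img.duplicated(subset=["plant", "das", "camera", "view"])
        for _, row in img[dup].iterrows():
            report.append(
                f"imaging: duplicate view row plant={row['plant']!r}"
                f" das={row['das']} camera={row['camera']} view={row['view']}")
        neg = img["area_kpx"] < 0
        if neg.any():
            report.append(f"imaging: {int(neg.sum())} negative area value(s)")
    harv = tables.get("harvest")
    if harv is not None and "ses" in harv.columns:
        ses = harv["ses"]
        bad = ~ses.astype(float).apply(float.is_integer) | (ses < 1) | (ses > 9)
        for _, row in harv[bad].iterrows():
            report.append(f"harvest: plant={row['plant']!r} SES={row['ses']}"
                          " not an integer in 1..9")
    return report


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write every artifact to ``config.out_dir``.

    Stages: (load or simulate tables) -> per-camera PSA -> hybrid
    calibration and splice -> smoothing splines -> AGR/RGR -> water use
    and WUI -> interval summaries -> tolerance indices -> genotype x
    salinity predicted means, Wald F-tests and pairwise comparisons ->
    ST-vs-ion regressions.  Deterministic given config + seed.  All
    outputs are computed before anything is written, so a failure never
    leaves a partial bundle behind.
    """
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        tables = simulate_experiment(sim)
        log.info("simulated experiment: %d plants",
                 tables["metadata"].shape[0])
    elif config.input_dir is not None:
        tables = load_tables(config.input_dir)
    else:
        raise ValueError("config needs either input_dir or a simulate block")

    problems = validate_tables(tables)
    hard = [p for p in problems if "duplicate" in p or "missing columns" in p
            or "table missing" in p]
    if hard:
        raise ValueError("input validation failed: " + "; ".join(hard))
    for p in problems:
        log.warning("validation: %s", p)

    meta = tables["metadata"]
    outputs: dict[str, pd.DataFrame] = {}

    rgb = gc.compute_psa(tables["imaging"], "RGB")
    fluo = gc.compute_psa(tables["imaging"], "FLUO")
    fit = gc.calibrate_hybrid(rgb, fluo, config.splice_das)
    log.info("hybrid calibration at das %d: rgb = %.3f + %.3f * fluo"
             " (n=%d, r2=%.4f)", fit.splice_das, fit.intercept, fit.slope,
             fit.n_points, fit.r_squared)
    hybrid = gc.build_hybrid_series(rgb, fluo, fit)

    smoothed: dict[str, gc.SmoothedSeries] = {}
    for plant, series in hybrid.items():
        sm = gc.fit_smoothing_spline(series, config.df)
        smoothed[plant] = gc.derive_rates(sm)

    have_water = "watering" in tables
    water: dict[str, gc.WaterSeries] = {}
    if have_water:
        water = gc.compute_water_use(tables["watering"], config.df)
        for plant, ws in water.items():
            if plant in smoothed:
                gc.compute_wui(smoothed[plant], ws)
    else:
        log.warning("no watering table: water-use and WUI outputs skipped")

    trait_rows = []
    for plant, sm in sorted(smoothed.items()):
        series = hybrid[plant]
        src = dict(zip(series.das.tolist(), series.source))
        ws = water.get(plant)
        wu = dict(zip(ws.das.tolist(), ws.water_use)) if ws else {}
        wui = dict(zip(ws.das.tolist(), ws.wui)) if ws is not None and \
            ws.wui is not None else {}
        for i, d in enumerate(sm.das.tolist()):
            trait_rows.append({
                "plant": plant, "das": d,
                "psa_kpx": sm.psa[i], "s_psa_kpx": sm.s_psa[i],
                "s_agr_kpx_day": sm.s_agr[i], "s_rgr_day": sm.s_rgr[i],
                "water_use_mL": wu.get(d, np.nan),
                "wui_kpx_mL": wui.get(d, np.nan),
                "source": src.get(d, ""),
            })
    outputs["traits"] = pd.DataFrame(trait_rows)

    intervals = gc.interval_summaries(smoothed, config.endpoints,
                                      water if have_water else None)
    outputs["intervals"] = intervals.merge(
        meta[["plant", "genotype", "treatment", "replicate"]], on="plant")

    outputs["indices"] = idx.tolerance_table(
        tables["harvest"], tables["ion"], meta,
        salt_level=config.salt_level, control_level=config.control_level)

    final_das = int(max(sm.das[-1] for sm in smoothed.values()))
    final_psa = pd.DataFrame({
        "plant": list(smoothed),
        "s_psa_final_kpx": [sm.s_psa[-1] for sm in smoothed.values()]})
    analysis = final_psa.merge(
        tables["harvest"][["plant", "sdw_g"]], on="plant").merge(
        meta[["plant", "genotype", "treatment", "replicate"]], on="plant")
    pm = st.predicted_means(analysis, "s_psa_final_kpx")
    outputs["predicted_means"] = pm.table
    wald = pm.wald.reset_index().rename(columns={"index": "term"})
    outputs["wald_tests"] = wald
    comps = st.pairwise_comparisons(pm.table)
    outputs["pairwise"] = pd.DataFrame([dataclasses.asdict(c) for c in comps])

    r2, pval = st.correlate(analysis["s_psa_final_kpx"], analysis["sdw_g"])
    ion_reg = st.regress_st_on_ion(outputs["indices"]["st_pct"],
                                   outputs["indices"]["na_umol_gdw"])
    outputs["summary_stats"] = pd.DataFrame([
        {"quantity": f"r2_sPSA{final_das}_vs_SDW", "value": r2},
        {"quantity": "p_sPSA_vs_SDW", "value": pval},
        {"quantity": "st_vs_na_slope", "value": ion_reg["slope"]},
        {"quantity": "st_vs_na_r2", "value": ion_reg["r_squared"]},
        {"quantity": "st_vs_na_p", "value": ion_reg["p_value"]},
        {"quantity": "calibration_intercept_kpx", "value": fit.intercept},
        {"quantity": "calibration_slope", "value": fit.slope},
        {"quantity": "calibration_r2", "value": fit.r_squared},
    ])

    # everything computed: now write the bundle atomically-ish
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    for name, df_out in outputs.items():
        _write_csv(df_out, out / f"{name}.csv", cfg_hash)
    if config.simulate is not None:
        for name in TABLE_NAMES:
            _write_csv(tables[name], out / f"{name}.csv", cfg_hash)
    log.info("wrote %d artifact tables to %s (config %s)",
             len(outputs), out, cfg_hash)
    return outputs
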