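"""Synthetic salinity-screening experiments for image-based rice phenotyping.

Generates the five tables the analysis pipeline consumes — imaging,
watering, harvest, ion and design/metadata — from a latent per-plant
growth model with known ground truth, so every downstream estimate can
be checked against the parameters that produced it.

The latent model is a daily discrete-time logistic with two salt
effects: an immediate *osmotic* penalty proportional to the external
NaCl concentration, and a cumulative *ionic* penalty driven by internal
shoot Na+ which accumulates in proportion to external concentration and
the genotype's exclusion capacity.  Senescence and chlorophyll loss are
coupled to internal Na+; transpiration is proportional to green
(non-senescent) shoot area; harvest biomass is allometric in final
shoot area.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeParams",
    "TreatmentSchedule",
    "LatentPlantState",
    "ObservationModel",
    "SimulationConfig",
    "simulate_growth",
    "observe_experiment",
    "simulate_harvest",
    "simulate_experiment",
    "default_genotypes",
    "default_treatments",
]

# fixed uptake constant: internal Na+ units per mM external NaCl per day
NA_UPTAKE_PER_MM_DAY = 0.001
# senescence ~ logistic(internal Na+): half-saturation and width (Na+ units)
SENESCENCE_NA50 = 1.5
SENESCENCE_WIDTH = 0.4
SENESCENCE_MAX = 0.6
# transpiration per unit green shoot area, mL day^-1 kpx^-1
TRANSP_PER_KPX = 1.5
# leaf Na+ (umol g^-1 DW) = base + scale * internal Na+
NA_DW_BASE = 20.0
NA_DW_SCALE = 150.0
# staged application protocol: daily increments up to the target
SALT_RAMP_STAGES = (25.0, 40.0, 80.0, 100.0)
# electrical conductivity by final NaCl level, dS m^-1 (metadata only; the
# source protocol lists one more EC value than salt levels in its first
# screening, so the 40 mM pairing here is the closest unambiguous reading)
EC_BY_MM = {0.0: 0.0, 40.0: 4.5, 80.0: 8.7, 100.0: 10.5}
# empty pot + dry soil weight, g (1 g water == 1 mL)
POT_BASE_WEIGHT_G = 1800.0


def _require_finite(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value}")
    return float(value)


@dataclass(frozen=True)
class GenotypeParams:
    """Generative parameters for one rice line.

    r0 is the intrinsic relative growth rate (day^-1), K the asymptotic
    projected shoot area (kilopixels).  ``exclusion`` in [0, 1] is the
    fraction of the external Na+ flux kept out of the shoot; 1 means a
    perfect excluder.  ``allometry`` is (SFW grams per kilopixel of
    final PSA, SDW/SFW ratio).
    """

    name: str
    r0: float
    K: float
    beta_osm: float = 0.002
    beta_ion: float = 0.12
    exclusion: float = 0.5
    allometry: tuple[float, float] = (0.12, 0.28)
    a0: float = 5.0          # shoot area at salting, kpx
    k_dw: float = 200.0      # mean leaf K+, umol g^-1 DW
    chlorophyll0: float = 3.0  # unstressed chlorophyll, mg g^-1 SDW

    def __post_init__(self) -> None:
        for f in ("r0", "K", "beta_osm", "beta_ion", "exclusion", "a0"):
            _require_finite(f, getattr(self, f))
        if self.r0 <= 0:
            raise ValueError(f"r0 must be > 0, got {self.r0}")
        if self.K <= 0:
            raise ValueError(f"K must be > 0, got {self.K}")
        if not 0.0 <= self.exclusion <= 1.0:
            raise ValueError(f"exclusion must be in [0, 1], got {self.exclusion}")
        if self.beta_osm < 0 or self.beta_ion < 0:
            raise ValueError("salt sensitivities must be >= 0")
        if self.a0 <= 0:
            raise ValueError(f"a0 must be > 0, got {self.a0}")


@dataclass(frozen=True)
class TreatmentSchedule:
    """Staged NaCl application reaching ``target_mM``.

    The ramp holds the external concentration on each day after salting
    starts, following the staged protocol (25, then up to 40, 80 and
    100 mM in daily increments); after the ramp the target is held.
    """

    target_mM: float
    ramp: tuple[float, ...]
    ec_dSm: float = 0.0

    def __post_init__(self) -> None:
        if self.ramp:
            if any(b < a for a, b in zip(self.ramp, self.ramp[1:])):
                raise ValueError("ramp must be non-decreasing")
            if self.ramp[-1] != self.target_mM:
                raise ValueError("ramp must end at target_mM")
        elif self.target_mM != 0:
            raise ValueError("non-zero target requires a ramp")

    @classmethod
    def from_target(cls, target_mM: float) -> "TreatmentSchedule":
        """Build the staged schedule for a final concentration."""
        if target_mM == 0:
            return cls(target_mM=0.0, ramp=(0.0,), ec_dSm=EC_BY_MM.get(0.0, 0.0))
        # stages strictly below the target, then the target itself
        ramp = tuple(s for s in SALT_RAMP_STAGES if s < target_mM) + (float(target_mM),)
        return cls(target_mM=float(target_mM), ramp=ramp,
                   ec_dSm=EC_BY_MM.get(float(target_mM), float("nan")))

    def concentration(self, das: int) -> float:
        """External NaCl (mM) on a given day after salting."""
        if das < 0:
            return 0.0
        if das < len(self.ramp):
            return self.ramp[das]
        return self.target_mM

    @property
    def label(self) -> str:
        return f"{self.target_mM:g}mM"


@dataclass(frozen=True)
class LatentPlantState:
    """Ground truth for one plant on one day after salting."""

    das: int
    true_area: float        # kpx
    internal_na: float      # arbitrary units, non-decreasing
    senescent_frac: float
    transpiration: float    # mL lost between this day and the next


@dataclass(frozen=True)
class ObservationModel:
    """How cameras and the watering system observe the latent state.

    FLUO total area is ``fluo_intercept + fluo_slope * true_area`` before
    multiplicative lognormal noise; RGB observes the area directly.  RGB
    totals after ``rgb_last_valid_das`` are shrunk by
    ``rgb_truncation_factor`` to emulate plants outgrowing the RGB
    camera's field of view.  The default keeps RGB trustworthy through
    day 20 so the day-20 FLUO/RGB cross-calibration, fitted on raw
    observations, is not confounded by the truncation.
    """

    fluo_intercept: float = 0.0
    fluo_slope: float = 1.0
    cv_rgb: float = 0.03
    cv_fluo: float = 0.03
    rgb_last_valid_das: int = 20
    rgb_truncation_factor: float = 0.7
    watering_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fluo_slope <= 0:
            raise ValueError("fluo_slope must be > 0")
        if self.cv_rgb < 0 or self.cv_fluo < 0:
            raise ValueError("noise CVs must be >= 0")


RGB_VIEWS = (("SV0", 0.4), ("SV90", 0.4), ("TV", 0.2))
FLUO_VIEWS = (("SV0", 0.5), ("SV90", 0.5))


def _senescence(internal_na: float) -> float:
    return SENESCENCE_MAX / (1.0 + math.exp(-(internal_na - SENESCENCE_NA50)
                                            / SENESCENCE_WIDTH))


def senescence_baseline() -> float:
    """Senescent fraction of a plant that never saw salt."""
    return _senescence(0.0)


def _plant_rng(seed: int, plant_id: str, stream: str = "") -> np.random.Generator:
    """Per-plant substream from a global seed via stable id hashing."""
    h = zlib.crc32(f"{plant_id}|{stream}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def _lognoise(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal factor(s) with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    z = rng.standard_normal(size)
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def simulate_growth(
    genotype: GenotypeParams,
    schedule: TreatmentSchedule,
    days: int = 30,
    seed: int = 0,
    *,
    plant_id: str = "plant",
    a0_scale: float = 1.0,
    transp_cv: float = 0.05,
) -> list[LatentPlantState]:
    """Daily latent trajectory of one plant from DAS 0 to ``days``.

    The update per day is multiplicative logistic with a salt-dependent
    rate:

        g(t)   = r0 * max(0, 1 - beta_osm*C(t)) * max(0, 1 - beta_ion*A(t))
        area'  = area * exp(g(t) * (1 - area/K))
        A'     = A + u * C(t) * (1 - exclusion)

    where C(t) is the external NaCl concentration and A the internal
    shoot Na+.  Deterministic given ``seed`` (the only randomness is the
    genotype-level transpiration noise).
    """
    if days < 1:
        raise ValueError(f"days must be >= 1, got {days}")
    _require_finite("a0_scale", a0_scale)
    rng = _plant_rng(seed, plant_id, "transp")
    area = genotype.a0 * a0_scale
    internal_na = 0.0
    out: list[LatentPlantState] = []
    for das in range(days + 1):
        sen = _senescence(internal_na)
        green = area * (1.0 - sen)
        transp = TRANSP_PER_KPX * green * float(_lognoise(rng, transp_cv))
        out.append(LatentPlantState(das=das, true_area=area,
                                    internal_na=internal_na,
                                    senescent_frac=sen, transpiration=transp))
        c = schedule.concentration(das)
        g = genotype.r0 * max(0.0, 1.0 - genotype.beta_osm * c) \
            * max(0.0, 1.0 - genotype.beta_ion * internal_na)
        area = area * math.exp(g * (1.0 - area / genotype.K))
        internal_na = internal_na + NA_UPTAKE_PER_MM_DAY * c * (1.0 - genotype.exclusion)
    return out


def observe_experiment(
    latents: dict[str, list[LatentPlantState]],
    model: ObservationModel,
    target_volume_mL: float = 600.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Camera and watering records for a set of latent trajectories.

    Returns (imaging, watering).  Imaging has one row per
    plant x day x camera x view with the view area in kilopixels; the
    per-camera view sums are noisy versions of the latent area (RGB) or
    of ``intercept + slope*area`` (FLUO).  Watering rows carry pot weight
    before and after watering consistent with the latent transpiration
    and the target water volume.
    """
    if not latents:
        raise ValueError("no latent trajectories supplied")
    img_rows = []
    wat_rows = []
    for plant, states in sorted(latents.items()):
        if not states:
            raise ValueError(f"empty latent sequence for plant {plant!r}")
        rng = _plant_rng(model.seed, plant, "camera")
        wrng = _plant_rng(model.seed, plant, "watering")
        weight_before_next = POT_BASE_WEIGHT_G + target_volume_mL
        for st in states:
            rgb_total = st.true_area
            if st.das > model.rgb_last_valid_das:
                rgb_total *= model.rgb_truncation_factor
            rgb_total *= float(_lognoise(rng, model.cv_rgb))
            fluo_total = model.fluo_intercept + model.fluo_slope * st.true_area
            fluo_total *= float(_lognoise(rng, model.cv_fluo))
            for view, frac in RGB_VIEWS:
                img_rows.append((plant, st.das, "RGB", view, rgb_total * frac))
            for view, frac in FLUO_VIEWS:
                img_rows.append((plant, st.das, "FLUO", view, fluo_total * frac))

            weight_before = weight_before_next
            noise = float(_lognoise(wrng, model.watering_cv))
            weight_before_obs = weight_before * noise if model.watering_cv else weight_before
            weight_after = POT_BASE_WEIGHT_G + target_volume_mL
            wat_rows.append((plant, st.das, weight_before_obs, weight_after,
                             weight_after - weight_before_obs))
            weight_before_next = weight_after - st.transpiration
    imaging = pd.DataFrame(img_rows,
                           columns=["plant", "das", "camera", "view", "area_kpx"])
    watering = pd.DataFrame(wat_rows,
                            columns=["plant", "das", "weight_before_g",
                                     "weight_after_g", "water_added_mL"])
    return imaging, watering


def simulate_harvest(
    latents: dict[str, list[LatentPlantState]],
    genotype: GenotypeParams,
    seed: int = 0,
    *,
    noise_cv: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-of-experiment destructive measurements for one genotype's plants.

    Returns (harvest, ion).  SFW/SDW are allometric in final latent PSA
    with shared lognormal noise (so the SDW/SFW ratio is exact);
    chlorophyll declines with the senescent fraction; SES is an integer
    1-9 increasing in senescence excess over the no-salt baseline, so
    unstressed plants score exactly 1.
    """
    if not latents:
        raise ValueError("no latent trajectories supplied")
    sfw_per_kpx, sdw_sfw = genotype.allometry
    base = senescence_baseline()
    h_rows, i_rows = [], []
    for plant, states in sorted(latents.items()):
        if not states:
            raise ValueError(f"empty latent sequence for plant {plant!r}")
        rng = _plant_rng(seed, plant, "harvest")
        final = states[-1]
        sfw = sfw_per_kpx * final.true_area * float(_lognoise(rng, noise_cv))
        sdw = sdw_sfw * sfw
        tillers = max(1, int(round(0.05 * final.true_area
                                   * float(_lognoise(rng, noise_cv)))))
        height = 12.0 * math.sqrt(final.true_area) * float(_lognoise(rng, noise_cv))
        chlorophyll = genotype.chlorophyll0 * (1.0 - final.senescent_frac) \
            * float(_lognoise(rng, noise_cv))
        rel = (final.senescent_frac - base) / (SENESCENCE_MAX - base)
        ses = 1 + int(round(8.0 * min(1.0, max(0.0, rel))))
        h_rows.append((plant, sfw, sdw, tillers, height, chlorophyll, ses,
                       final.senescent_frac))
        na_dw = (NA_DW_BASE + NA_DW_SCALE * final.internal_na) \
            * float(_lognoise(rng, noise_cv))
        k_dw = genotype.k_dw * float(_lognoise(rng, noise_cv))
        i_rows.append((plant, na_dw, k_dw))
    harvest = pd.DataFrame(h_rows, columns=[
        "plant", "sfw_g", "sdw_g", "tillers", "height_cm",
        "chlorophyll_mg_g", "ses", "senescence"])
    ion = pd.DataFrame(i_rows, columns=["plant", "na_umol_gdw", "k_umol_gdw"])
    return harvest, ion


def default_genotypes() -> list[GenotypeParams]:
    """The seven-line panel emulated by default: two O. sativa standards
    (salt-tolerant Pokkali, salt-sensitive IR29) and five wild accessions
    spanning a gradient of Na+ exclusion capacity."""
    return [
        GenotypeParams("Pokkali", r0=0.14, K=550, beta_ion=0.10, exclusion=0.85),
        GenotypeParams("IR29", r0=0.08, K=300, beta_ion=0.18, exclusion=0.35),
        GenotypeParams("Oa-VR", r0=0.12, K=450, beta_ion=0.08, exclusion=0.90),
        GenotypeParams("Oa-D", r0=0.12, K=450, beta_ion=0.15, exclusion=0.30),
        GenotypeParams("Oa-CH", r0=0.11, K=420, beta_ion=0.12, exclusion=0.60),
        GenotypeParams("Oa-KR", r0=0.13, K=500, beta_ion=0.12, exclusion=0.45),
        GenotypeParams("Om-T", r0=0.11, K=400, beta_osm=0.0028, beta_ion=0.13,
                       exclusion=0.40),
    ]


def default_treatments() -> list[TreatmentSchedule]:
    return [TreatmentSchedule.from_target(t) for t in (0.0, 40.0, 80.0, 100.0)]


@dataclass
class SimulationConfig:
    """Full synthetic-experiment specification.

    Defaults mirror the emulated screening: seven lines x four NaCl
    levels (0/40/80/100 mM, staged daily increments) x six replicates,
    imaged daily for 30 days after salting, watered to a 600 mL target.
    """

    genotypes: list[GenotypeParams] = field(default_factory=default_genotypes)
    treatments: list[TreatmentSchedule] = field(default_factory=default_treatments)
    n_reps: int = 6
    days: int = 30
    observation: ObservationModel = field(default_factory=ObservationModel)
    spatial_sd: float = 0.05      # lane effect SD on log area scale
    init_cv: float = 0.05         # per-plant initial-area CV
    transp_cv: float = 0.05
    harvest_cv: float = 0.10
    target_volume_mL: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.days < 1:
            raise ValueError("days must be >= 1")


def _metadata(config: SimulationConfig) -> pd.DataFrame:
    """Plant -> genotype/treatment/replicate/lane/position assignment.

    For the canonical 7-line x 4-treatment x 6-replicate shape the
    randomisation comes from the Youden-square split-unit layout;
    otherwise carts are laid out factorially on consecutive lanes.
    """
    n_g, n_t = len(config.genotypes), len(config.treatments)
    g_names = [g.name for g in config.genotypes]
    t_labels = [t.label for t in config.treatments]
    if (n_g, n_t, config.n_reps) == (7, 4, 6):
        from .design import assemble_layout, resolved_pair_blocks, youden_square
        square = youden_square(lines=g_names, seed=config.seed)
        blocks = resolved_pair_blocks(treatments=t_labels, n_main_units=42,
                                      seed=config.seed)
        layout = assemble_layout(square, blocks)
        meta = layout.rename(columns={"line": "genotype"})
    else:
        rows = []
        cart = 0
        for rep in range(1, config.n_reps + 1):
            for gi, g in enumerate(g_names):
                for ti, t in enumerate(t_labels):
                    lane = 2 * (rep - 1) + 1 + (cart % 2)
                    rows.append((lane, cart % 14 + 1, rep, gi + 1, g, t, cart // 2))
                    cart += 1
        meta = pd.DataFrame(rows, columns=["lane", "position", "replicate",
                                           "main_unit", "genotype", "treatment",
                                           "block"])
    meta = meta.copy()
    meta["plant"] = [
        f"{g}_{t}_r{r}" for g, t, r in
        zip(meta["genotype"], meta["treatment"], meta["replicate"])
    ]
    cols = ["plant", "genotype", "treatment", "replicate", "lane", "position",
            "main_unit", "block"]
    return meta[[c for c in cols if c in meta.columns]]


def simulate_experiment(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run a full synthetic experiment.

    Returns a dict with the five analysis tables (``imaging``,
    ``watering``, ``harvest``, ``ion``, ``metadata``) plus the latent
    ground truth under ``_latents`` for parameter-recovery checks.
    Byte-identical across runs with the same config and seed.
    """
    meta = _metadata(config)
    geno_by_name = {g.name: g for g in config.genotypes}
    sched_by_label = {t.label: t for t in config.treatments}
    lane_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x1A7E]))
    lanes = sorted(meta["lane"].unique()) if "lane" in meta else []
    lane_eff = {ln: float(lane_rng.normal(0.0, config.spatial_sd)) for ln in lanes}

    latents: dict[str, list[LatentPlantState]] = {}
    for row in meta.itertuples(index=False):
        g = geno_by_name[row.genotype]
        sched = sched_by_label[row.treatment]
        rng = _plant_rng(config.seed, row.plant, "init")
        a0_scale = math.exp(lane_eff.get(getattr(row, "lane", None), 0.0)) \
            * float(_lognoise(rng, config.init_cv))
        latents[row.plant] = simulate_growth(
            g, sched, days=config.days, seed=config.seed,
            plant_id=row.plant, a0_scale=a0_scale, transp_cv=config.transp_cv)

    obs = replace(config.observation, seed=config.observation.seed or config.seed)
    imaging, watering = observe_experiment(latents, obs, config.target_volume_mL)

    harvest_parts, ion_parts = [], []
    for g in config.genotypes:
        plants = meta.loc[meta["genotype"] == g.name, "plant"]
        sub = {p: latents[p] for p in plants}
        h, i = simulate_harvest(sub, g, seed=config.seed, noise_cv=config.harvest_cv)
        harvest_parts.append(h)
        ion_parts.append(i)
    harvest = pd.concat(harvest_parts, ignore_index=True).sort_values("plant") \
        .reset_index(drop=True)
    ion = pd.concat(ion_parts, ignore_index=True).sort_values("plant") \
        .reset_index(drop=True)
    return {"imaging": imaging, "watering": watering, "harvest": harvest,
            "ion": ion, "metadata": meta, "_latents": latents}
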