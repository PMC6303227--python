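"""From raw multi-view shoot images and pot weights to smoothed growth traits.

Projected shoot area (PSA, kilopixels) is the sum of per-view plant
areas: three views (two sides at 90 degrees plus top) for the RGB
camera, two side views for the fluorescence (FLUO) camera.  Because
plants eventually outgrow the RGB field of view, a *hybrid* PSA series
uses RGB early and FLUO — rescaled onto the RGB scale by a linear
cross-calibration fitted on the splice day — from the splice day
onwards.

Per plant, the hybrid series is smoothed with a natural cubic smoothing
spline (df = 5 by default) giving sPSA, from which the absolute growth
rate AGR (kpx day^-1, differences of sPSA) and relative growth rate RGR
(day^-1, differences of a spline fitted to ln PSA) are derived.  Daily
water use comes from the gravimetric watering records; the water-use
index WUI is growth per mL transpired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spline import SplineFit, smoothing_spline

__all__ = [
    "PSASeries",
    "CalibrationFit",
    "SmoothedSeries",
    "WaterSeries",
    "compute_psa",
    "calibrate_hybrid",
    "build_hybrid_series",
    "fit_smoothing_spline",
    "derive_rates",
    "compute_water_use",
    "compute_wui",
    "interval_wui",
    "interval_summaries",
    "DEFAULT_ENDPOINTS",
]

log = logging.getLogger(__name__)

#: interval endpoints (days after salting) used for stage-wise summaries
DEFAULT_ENDPOINTS = (4, 9, 14, 19, 23, 28)

EXPECTED_VIEWS = {"RGB": ("SV0", "SV90", "TV"), "FLUO": ("SV0", "SV90")}


@dataclass
class PSASeries:
    """Per-plant projected shoot area by day after salting."""

    plant: str
    das: np.ndarray              # strictly increasing ints
    psa: np.ndarray              # kpx, > 0
    source: list[str] = field(default_factory=list)  # per-day provenance tag

    def __post_init__(self) -> None:
        self.das = np.asarray(self.das, dtype=int)
        self.psa = np.asarray(self.psa, dtype=float)
        if np.any(np.diff(self.das) <= 0):
            raise ValueError(f"plant {self.plant!r}: das must be strictly increasing")
        if not self.source:
            self.source = [""] * self.das.size

    def at(self, das: int) -> float:
        idx = np.nonzero(self.das == das)[0]
        return float(self.psa[idx[0]]) if idx.size else float("nan")


@dataclass(frozen=True)
class CalibrationFit:
    """Linear map from FLUO PSA onto the RGB scale: rgb = intercept + slope*fluo."""

    intercept: float
    slope: float
    splice_das: int
    n_points: int
    r_squared: float

    def __call__(self, fluo_psa):
        return self.intercept + self.slope * np.asarray(fluo_psa, dtype=float)


@dataclass
class SmoothedSeries:
    """Smoothed trajectory and derived rates for one plant.

    ``s_agr``/``s_rgr`` are aligned with ``das`` and refer to the change
    over the day ending at each entry (NaN on the first day).
    """

    plant: str
    das: np.ndarray
    psa: np.ndarray              # raw hybrid PSA the spline was fitted to
    s_psa: np.ndarray
    df: float
    psa_fit: SplineFit = field(repr=False)
    ln_fit: SplineFit | None = field(default=None, repr=False)
    s_agr: np.ndarray | None = None
    s_rgr: np.ndarray | None = None

    def s_psa_at(self, das: float) -> float:
        """sPSA at an arbitrary day inside the fitted range."""
        self._check_range(das)
        return float(self.psa_fit(das))

    def s_lnpsa_at(self, das: float) -> float:
        if self.ln_fit is None:
            raise ValueError("call derive_rates first: ln-spline not fitted")
        self._check_range(das)
        return float(self.ln_fit(das))

    def _check_range(self, das: float) -> None:
        if das < self.das[0] or das > self.das[-1]:
            raise ValueError(
                f"day {das} outside smoothed range [{self.das[0]}, {self.das[-1]}]"
                f" for plant {self.plant!r}")


@dataclass
class WaterSeries:
    """Daily gravimetric water use for one plant.

    ``water_use[i]`` is the loss over the day ending at ``das[i]`` (NaN
    where unavailable or negative); ``wui`` is filled by `compute_wui`.
    """

    plant: str
    das: np.ndarray
    water_use: np.ndarray
    s_water_use: np.ndarray | None = None
    wui: np.ndarray | None = None


def compute_psa(imaging: pd.DataFrame, camera: str) -> dict[str, PSASeries]:
    """Sum per-view areas into one PSA value per plant per day.

    RGB sums three views (SV0, SV90, TV); FLUO sums the two side views.
    A duplicated plant x day x view row is an error; a day missing one
    of its expected views is dropped with a warning.
    """
    if camera not in EXPECTED_VIEWS:
        raise ValueError(f"unknown camera {camera!r}; expected RGB or FLUO")
    expected = set(EXPECTED_VIEWS[camera])
    sub = imaging[imaging["camera"] == camera]
    dup = sub.duplicated(subset=["plant", "das", "view"], keep=False)
    if dup.any():
        first = sub[dup].iloc[0]
        raise ValueError(
            f"duplicate view row: plant={first['plant']!r} das={first['das']}"
            f" view={first['view']!r}")
    out: dict[str, PSASeries] = {}
    for plant, g in sub.groupby("plant", sort=True):
        days, vals = [], []
        for das, gd in g.groupby("das", sort=True):
            views = set(gd["view"])
            if views != expected:
                log.warning("plant %s das %s: %s views %s != expected %s; day dropped",
                            plant, das, camera, sorted(views), sorted(expected))
                continue
            days.append(int(das))
            vals.append(float(gd["area_kpx"].sum()))
        if days:
            out[str(plant)] = PSASeries(plant=str(plant), das=np.array(days),
                                        psa=np.array(vals),
                                        source=[camera] * len(days))
    return out


def calibrate_hybrid(
    rgb: dict[str, PSASeries],
    fluo: dict[str, PSASeries],
    splice_das: int = 20,
    *,
    through_origin: bool = False,
) -> CalibrationFit:
    """Fit the FLUO -> RGB linear map on the splice day, across plants.

    Ordinary least squares of RGB PSA on FLUO PSA using every plant with
    both cameras on ``splice_das`` (raw observations, pooled — a
    per-plant fit on a single day would be underdetermined).
    """
    xs, ys = [], []
    for plant, r in rgb.items():
        f = fluo.get(plant)
        if f is None:
            continue
        rv, fv = r.at(splice_das), f.at(splice_das)
        if np.isfinite(rv) and np.isfinite(fv):
            xs.append(fv)
            ys.append(rv)
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 plants with both cameras on das {splice_das}, got {len(xs)}")
    x = np.array(xs)
    y = np.array(ys)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in FLUO PSA on the splice day")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - slope * x
    else:
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationFit(intercept=float(intercept), slope=float(slope),
                          splice_das=int(splice_das), n_points=len(xs),
                          r_squared=r2)


def build_hybrid_series(
    rgb: dict[str, PSASeries],
    fluo: dict[str, PSASeries],
    fit: CalibrationFit,
) -> dict[str, PSASeries]:
    """Splice RGB (days before the splice day) with calibrated FLUO (from it on).

    Days where the required camera is absent fall back to the other
    camera (calibrated if FLUO); days with neither are left missing.
    """
    out: dict[str, PSASeries] = {}
    for plant in sorted(set(rgb) | set(fluo)):
        r = rgb.get(plant)
        f = fluo.get(plant)
        days: dict[int, tuple[float, str]] = {}
        if f is not None:
            for d, v in zip(f.das, f.psa):
                days[int(d)] = (float(fit(v)), "FLUO-calibrated")
        if r is not None:
            for d, v in zip(r.das, r.psa):
                d = int(d)
                if d < fit.splice_das or d not in days:
                    days[d] = (float(v), "RGB")
        if not days:
            continue
        das = np.array(sorted(days))
        out[plant] = PSASeries(
            plant=plant, das=das,
            psa=np.array([days[d][0] for d in das]),
            source=[days[d][1] for d in das])
    return out


def fit_smoothing_spline(series: PSASeries, df: float = 5.0) -> SmoothedSeries:
    """Smooth a PSA series with a natural cubic smoothing spline.

    The penalty is chosen so the smoother-matrix trace equals ``df``
    (within 1e-3).  Missing days are simply absent from the fit; no
    imputation is performed.  Requires at least ``df`` observed days and
    strictly positive PSA.
    """
    mask = np.isfinite(series.psa)
    das = series.das[mask].astype(float)
    psa = series.psa[mask]
    if np.any(psa <= 0):
        raise ValueError(f"plant {series.plant!r}: non-positive PSA cannot be smoothed")
    if das.size < df:
        raise ValueError(
            f"plant {series.plant!r}: {das.size} days < df={df}")
    fit = smoothing_spline(das, psa, df)
    return SmoothedSeries(plant=series.plant, das=das.astype(int), psa=psa,
                          s_psa=fit.fitted, df=float(df), psa_fit=fit)


def derive_rates(smoothed: SmoothedSeries) -> SmoothedSeries:
    """Fill s_agr and s_rgr by differencing over consecutive observed days.

    AGR differences the sPSA spline; RGR differences a spline fitted to
    ln(PSA) with the same df (not the log of the PSA spline), matching
    the convention of taking differences of consecutive ln PSA values.
    """
    if np.any(smoothed.psa <= 0):
        raise ValueError("non-positive PSA: cannot take logs for RGR")
    ln_fit = smoothing_spline(smoothed.das.astype(float), np.log(smoothed.psa),
                              smoothed.df)
    smoothed.ln_fit = ln_fit
    das = smoothed.das.astype(float)
    dt = np.diff(das)
    agr = np.diff(smoothed.s_psa) / dt
    rgr = np.diff(ln_fit.fitted) / dt
    smoothed.s_agr = np.concatenate([[np.nan], agr])
    smoothed.s_rgr = np.concatenate([[np.nan], rgr])
    return smoothed


def compute_water_use(watering: pd.DataFrame, df: float = 5.0) -> dict[str, WaterSeries]:
    """Daily water loss per pot from the weighing records.

    use(t) = weight after watering on the previous imaging day minus
    weight before watering on day t.  Negative values (leakage) are
    replaced with missing values, logged, and excluded from the
    smoothing fit so they cannot distort the spline.
    """
    out: dict[str, WaterSeries] = {}
    for plant, g in watering.groupby("plant", sort=True):
        g = g.sort_values("das")
        das = g["das"].to_numpy(dtype=int)
        if np.any(np.diff(das) <= 0):
            raise ValueError(f"plant {plant!r}: duplicated or unordered watering days")
        before = g["weight_before_g"].to_numpy(dtype=float)
        after = g["weight_after_g"].to_numpy(dtype=float)
        use = np.full(das.size, np.nan)
        use[1:] = after[:-1] - before[1:]
        neg = use < 0
        if neg.any():
            log.warning("plant %s: %d negative water-use value(s) on das %s set missing",
                        plant, int(neg.sum()), das[np.nonzero(neg)[0]].tolist())
            use[neg] = np.nan
        ws = WaterSeries(plant=str(plant), das=das, water_use=use)
        ok = np.isfinite(use)
        if ok.sum() >= df:
            sfit = smoothing_spline(das[ok].astype(float), use[ok], df)
            s = np.full(das.size, np.nan)
            s[ok] = sfit.fitted
            ws.s_water_use = s
        out[str(plant)] = ws
    return out


def compute_wui(smoothed: SmoothedSeries, water: WaterSeries) -> WaterSeries:
    """Daily water-use index: smoothed AGR divided by daily water use.

    Missing (or zero) water use gives a missing WUI, never an infinity.
    """
    if smoothed.s_agr is None:
        raise ValueError("call derive_rates before compute_wui")
    if not np.isfinite(water.water_use).any():
        raise ValueError(f"plant {water.plant!r}: water series is all missing")
    agr_by_das = dict(zip(smoothed.das.tolist(), smoothed.s_agr))
    wui = np.full(water.das.size, np.nan)
    for i, (d, w) in enumerate(zip(water.das.tolist(), water.water_use)):
        a = agr_by_das.get(d, np.nan)
        if np.isfinite(a) and np.isfinite(w) and w != 0:
            wui[i] = a / w
    water.wui = wui
    return water


def interval_wui(
    smoothed: SmoothedSeries,
    water: WaterSeries,
    start: int,
    end: int,
) -> float:
    """Total sPSA gain over (start, end] divided by total water loss in it.

    Water use on day t covers the day ending at t, so the interval sums
    days start+1 .. end.  Returns NaN if any water value in the interval
    is missing.
    """
    if end <= start:
        raise ValueError("interval end must exceed start")
    d_psa = smoothed.s_psa_at(end) - smoothed.s_psa_at(start)
    mask = (water.das > start) & (water.das <= end)
    if mask.sum() != end - start or not np.all(np.isfinite(water.water_use[mask])):
        return float("nan")
    total = float(np.sum(water.water_use[mask]))
    return d_psa / total if total != 0 else float("nan")


def interval_summaries(
    smoothed: dict[str, SmoothedSeries],
    endpoints: tuple[int, ...] = DEFAULT_ENDPOINTS,
    water: dict[str, WaterSeries] | None = None,
) -> pd.DataFrame:
    """Per-plant, per-interval mean AGR, RGR (and WUI when water given).

    Interval value = (s(end) - s(start)) / (end - start), on the PSA
    scale for AGR and the ln PSA scale for RGR; consecutive endpoints
    define the intervals.  Endpoints outside a plant's smoothed range
    raise.
    """
    endpoints = tuple(int(e) for e in endpoints)
    if any(b <= a for a, b in zip(endpoints, endpoints[1:])):
        raise ValueError("endpoints must be strictly increasing")
    rows = []
    for plant, sm in sorted(smoothed.items()):
        if sm.ln_fit is None:
            derive_rates(sm)
        for a, b in zip(endpoints, endpoints[1:]):
            agr = (sm.s_psa_at(b) - sm.s_psa_at(a)) / (b - a)
            rgr = (sm.s_lnpsa_at(b) - sm.s_lnpsa_at(a)) / (b - a)
            row = {"plant": plant, "interval": f"{a}-{b}", "start": a, "end": b,
                   "agr_kpx_day": agr, "rgr_day": rgr}
            if water is not None and plant in water:
                row["wui_kpx_mL"] = interval_wui(sm, water[plant], a, b)
            rows.append(row)
    return pd.DataFrame(rows)
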