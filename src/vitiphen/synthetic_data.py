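"""Seeded synthetic site-season generator.

Emulates the statistical structure of the satellite/reanalysis inputs the
phenology model consumes: biweekly NDVI in [0.10, 0.85] (population mean ~0.45)
and EVI in [0.08, 0.75] (~0.38), daily weather per agroecological zone
(Mediterranean / subtropical / temperate, with zone-typical annual rainfall),
growing-degree-day stage labels (base 10 degC), cloud-spike contamination
(mean NDVI depression 0.47) and missing-data runs with a configurable
gap-length mix.

Everything is indexed on the season-relative grid of :mod:`vitiphen.stages`:
day 1 is the local season start, so Southern-hemisphere sites differ only in
the absolute calendar phase of their weather, never in array layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vitiphen.stages import (
    DAYS_PER_INTERVAL,
    N_INTERVALS,
    SEASON_DAYS,
    STAGE_INDEX,
    STAGE_ORDER,
    STAGES,
)

__all__ = [
    "ZonePreset",
    "ZONE_PRESETS",
    "GddRule",
    "StageTimeline",
    "SiteSeries",
    "SimulationParams",
    "DEFAULT_GAP_MIX",
    "simulate_weather",
    "compute_gdd_and_stages",
    "simulate_vegetation",
    "corrupt_series",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

# Gap-length classes and the frequency mix of gap *counts* used by default.
GAP_CLASSES = ("1", "2", "3", "4-6", ">6")
#: Default mix of gap counts per length class (proportional to the observed
#: census of 3842 / 894 / 306 / 142 / 53 gaps).
DEFAULT_GAP_MIX = {
    "1": 3842 / 5237,
    "2": 894 / 5237,
    "3": 306 / 5237,
    "4-6": 142 / 5237,
    ">6": 53 / 5237,
}


@dataclass(frozen=True)
class ZonePreset:
    """Climate preset for one agroecological zone.

    ``annual_rainfall_range`` is in mm/year; temperatures in degC.
    ``season_start_doy`` is the absolute calendar day-of-year at which the
    local growing season (and hence the 26-interval grid) begins.
    """

    name: str
    annual_rainfall_range: tuple[float, float]
    temp_mean: float
    temp_amplitude: float
    season_start_doy: int
    noise_sd: float
    hemisphere: str  # "north" | "south"
    wet_peak_doy: int  # calendar day-of-year of maximum rain-day probability
    wet_seasonality: float  # amplitude of the rain-day probability cycle
    anchors: tuple[tuple[float, float], ...]  # (lat, lon) vineyard anchors

    def __post_init__(self) -> None:
        lo, hi = self.annual_rainfall_range
        if not 0 < lo < hi:
            raise ValueError("annual_rainfall_range must be an increasing positive interval")
        if not 1 <= self.season_start_doy <= 365:
            raise ValueError("season_start_doy must be in [1, 365]")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")


ZONE_PRESETS: dict[str, ZonePreset] = {
    "mediterranean": ZonePreset(
        name="mediterranean",
        annual_rainfall_range=(600.0, 800.0),
        temp_mean=15.0,
        temp_amplitude=9.0,
        season_start_doy=91,
        noise_sd=1.5,
        hemisphere="north",
        wet_peak_doy=15,
        wet_seasonality=0.22,
        anchors=((38.5, -122.5), (41.7, -4.7), (43.5, 11.2)),
    ),
    "subtropical": ZonePreset(
        name="subtropical",
        annual_rainfall_range=(400.0, 550.0),
        temp_mean=17.0,
        temp_amplitude=7.0,
        season_start_doy=274,
        noise_sd=1.5,
        hemisphere="south",
        wet_peak_doy=196,
        wet_seasonality=0.15,
        anchors=((-34.5, 138.9), (-34.2, 146.0)),
    ),
    "temperate": ZonePreset(
        name="temperate",
        annual_rainfall_range=(700.0, 900.0),
        temp_mean=13.0,
        temp_amplitude=9.0,
        season_start_doy=105,
        noise_sd=1.5,
        hemisphere="north",
        wet_peak_doy=300,
        wet_seasonality=0.05,
        anchors=((44.8, -0.6), (50.0, 8.0)),
    ),
}


def get_zone(name: str) -> ZonePreset:
    try:
        return ZONE_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown zone {name!r}; expected one of {sorted(ZONE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class GddRule:
    """Thermal-time staging rule.

    A stage's onset is the first day the cumulative GDD (base ``base_temp``)
    reaches its threshold; a stage persists until the next stage's onset so
    that per-interval labels are contiguous. ``band_uppers`` retains the
    published upper band edges as metadata only.
    """

    base_temp: float = 10.0
    onsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "budburst": 50.0,
            "flowering": 400.0,
            "veraison": 1000.0,
            "harvest": 1400.0,
        }
    )
    band_uppers: Mapping[str, float] = field(
        default_factory=lambda: {
            "budburst": 100.0,
            "flowering": 600.0,
            "veraison": 1200.0,
            "harvest": 1800.0,
        }
    )

    def __post_init__(self) -> None:
        vals = [self.onsets[s] for s in STAGES]
        if not all(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("stage onset thresholds must be strictly increasing")


@dataclass
class StageTimeline:
    """Per-interval stage labels plus stage-onset days (season-relative)."""

    stage_per_interval: list[str]
    onset_day: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.stage_per_interval) != N_INTERVALS:
            raise ValueError(f"expected {N_INTERVALS} interval labels")
        idx = [STAGE_INDEX[s] for s in self.stage_per_interval]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("stage sequence must be monotone non-decreasing")


@dataclass
class SiteSeries:
    """One site-season: daily weather, biweekly indices, ground-truth stages."""

    site_id: str
    lat: float
    lon: float
    zone: str
    daily_temp: np.ndarray  # (365,) degC, season-relative
    daily_rain: np.ndarray  # (365,) mm >= 0
    daily_rh: np.ndarray  # (365,) % in [0, 100]
    ndvi: np.ndarray  # (26,) possibly NaN
    evi: np.ndarray  # (26,) possibly NaN
    biweekly_rain: np.ndarray  # (26,) mm
    timeline: StageTimeline
    contaminated_steps: frozenset[int] = frozenset()  # 0-based interval indices


@dataclass(frozen=True)
class SimulationParams:
    """Corruption and noise settings for a generated dataset."""

    cloud_rate: float = 0.002  # per-interval cloud-spike probability
    heavy_rate: float = 0.0178  # fraction of series with pervasive contamination
    gap_series_prob: float = 0.2847  # P(series has >= 1 missing run)
    extra_gaps_mean: float = 0.84  # Poisson mean of additional runs per affected series
    gap_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAP_MIX))
    veg_noise_sd: float = 0.02

    @classmethod
    def clean(cls) -> "SimulationParams":
        """No contamination, no gaps (used for clean-condition experiments)."""
        return cls(
            cloud_rate=0.0,
            heavy_rate=0.0,
            gap_series_prob=0.0,
            extra_gaps_mean=0.0,
            gap_mix={c: 0.0 for c in GAP_CLASSES},
        )


# --------------------------------------------------------------------------
# weather
# --------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_weather(zone: ZonePreset, year_seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one season of daily weather for a zone.

    Temperature is an annual sinusoid (phase set by hemisphere) plus Gaussian
    noise; rainfall is a seasonally modulated intermittent gamma process
    rescaled so the annual total falls inside the zone's range; relative
    humidity is elevated on rain days. Returns season-relative (365,) arrays
    ``(daily_temp, daily_rain, daily_rh)``.
    """
    if isinstance(zone, str):
        zone = get_zone(zone)
    rng = _as_rng(year_seed)

    days = np.arange(SEASON_DAYS)
    doy = (zone.season_start_doy - 1 + days) % 365 + 1  # absolute calendar doy
    peak_doy = 201 if zone.hemisphere == "north" else 19
    temp = (
        zone.temp_mean
        + zone.temp_amplitude * np.cos(2 * np.pi * (doy - peak_doy) / 365.0)
        + rng.normal(0.0, zone.noise_sd, SEASON_DAYS)
    )

    p_wet = np.clip(
        0.28 + zone.wet_seasonality * np.cos(2 * np.pi * (doy - zone.wet_peak_doy) / 365.0),
        0.05,
        0.9,
    )
    wet = rng.random(SEASON_DAYS) < p_wet
    amounts = np.where(wet, rng.gamma(shape=0.8, scale=8.0, size=SEASON_DAYS), 0.0)
    lo, hi = zone.annual_rainfall_range
    target = rng.uniform(lo, hi)
    total = amounts.sum()
    if total <= 0:  # pragma: no cover - p_wet floor makes this unreachable
        amounts[rng.integers(SEASON_DAYS)] = 1.0
        total = 1.0
    rain = amounts * (target / total)

    rh = np.clip(55.0 + 25.0 * wet + rng.normal(0.0, 8.0, SEASON_DAYS), 20.0, 100.0)
    return temp, rain, rh


# --------------------------------------------------------------------------
# thermal-time staging
# --------------------------------------------------------------------------

def compute_gdd_and_stages(
    daily_temp: np.ndarray, rule: GddRule | None = None, season_start_doy: int = 1
) -> StageTimeline:
    """Label a season from cumulative growing degree days.

    ``daily_temp`` is season-relative (index 0 = season start). The stage on a
    day is the highest stage whose onset threshold the cumulative GDD has
    reached; each interval is labeled by its midpoint day. Stages whose
    thresholds are never crossed are simply absent.
    """
    rule = rule or GddRule()
    temp = np.asarray(daily_temp, dtype=float)
    if temp.shape != (SEASON_DAYS,):
        raise ValueError(f"expected {SEASON_DAYS} daily temperatures, got {temp.shape}")
    cum = np.cumsum(np.maximum(0.0, temp - rule.base_temp))

    onset_day: dict[str, int] = {}
    for stage in STAGES:
        crossed = np.nonzero(cum >= rule.onsets[stage])[0]
        if crossed.size:
            onset_day[stage] = int(crossed[0]) + 1  # 1-based season day

    labels = []
    for i in range(N_INTERVALS):
        mid = DAYS_PER_INTERVAL * i + 8  # season-relative midpoint day
        g = cum[mid - 1]
        stage = "pre_season"
        for s in STAGES:
            if g >= rule.onsets[s]:
                stage = s
        labels.append(stage)
    return StageTimeline(stage_per_interval=labels, onset_day=onset_day)


# --------------------------------------------------------------------------
# vegetation indices
# --------------------------------------------------------------------------

# Double-logistic canopy curve constants (clean-trajectory envelope). The
# rise/fall time constants keep the maximum clean biweekly |dNDVI| at
# 0.68 * 14 / (4 * 13) ~= 0.18, so that with +-2 sd observation noise the
# clean step never exceeds 0.28.
_NDVI_BASE = 0.15
_NDVI_PEAK = 0.83
_RISE_LAG_DAYS = 20.0
_RISE_TAU = 13.0
_FALL_LAG_DAYS = 45.0
_FALL_TAU = 16.0
# EVI is an affine companion of the same latent canopy signal, mapping the
# NDVI range [0.10, 0.85] onto the EVI range [0.08, 0.75].
_EVI_SCALE = 0.67 / 0.75
_EVI_OFFSET = 0.08 - 0.10 * _EVI_SCALE


def _latent_canopy(timeline: StageTimeline, days: np.ndarray) -> np.ndarray:
    bud = timeline.onset_day.get("budburst")
    if bud is None:
        return np.full(days.shape, _NDVI_BASE)
    harv = timeline.onset_day.get("harvest")
    d_rise = bud + _RISE_LAG_DAYS
    d_fall = (harv + _FALL_LAG_DAYS) if harv is not None else SEASON_DAYS + 60.0
    rise = 1.0 / (1.0 + np.exp(-(days - d_rise) / _RISE_TAU))
    fall = 1.0 / (1.0 + np.exp(-(days - d_fall) / _FALL_TAU))
    return _NDVI_BASE + (_NDVI_PEAK - _NDVI_BASE) * (rise - fall)


def simulate_vegetation(
    timeline: StageTimeline, seed, noise_sd: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Clean biweekly NDVI and EVI trajectories for a labeled season.

    NDVI follows a double-logistic seasonal curve keyed to the stage onsets
    (green-up after budburst, plateau through veraison, senescence after
    harvest) plus truncated Gaussian noise, clipped to [0.10, 0.85]; EVI is an
    affine transform of the same latent curve with its own noise, clipped to
    [0.08, 0.75].
    """
    rng = _as_rng(seed)
    mids = np.array([DAYS_PER_INTERVAL * i + 8 for i in range(N_INTERVALS)], dtype=float)
    latent = _latent_canopy(timeline, mids)

    def noisy(x: np.ndarray) -> np.ndarray:
        if noise_sd <= 0:
            return x
        eps = np.clip(rng.normal(0.0, noise_sd, x.shape), -2 * noise_sd, 2 * noise_sd)
        return x + eps

    ndvi = np.clip(noisy(latent), 0.10, 0.85)
    evi = np.clip(noisy(_EVI_SCALE * latent + _EVI_OFFSET), 0.08, 0.75)
    return ndvi, evi


# --------------------------------------------------------------------------
# corruption
# --------------------------------------------------------------------------

_CLASS_LENGTHS = {"1": (1, 1), "2": (2, 2), "3": (3, 3), "4-6": (4, 6), ">6": (7, 10)}


def _draw_gap_length(cls: str, rng: np.random.Generator) -> int:
    lo, hi = _CLASS_LENGTHS[cls]
    return int(rng.integers(lo, hi + 1))


def corrupt_series(
    series: SiteSeries,
    cloud_rate: float,
    gap_mix: Mapping[str, float],
    seed,
    gap_series_prob: float = 0.2847,
    extra_gaps_mean: float = 0.84,
    heavy: bool = False,
) -> SiteSeries:
    """Inject cloud spikes and missing runs into a clean series.

    Cloud spikes depress NDVI by an amount drawn from N(0.47, 0.12) truncated
    to [0.31, 0.75] (so the same-step depression always exceeds the 0.3 QC
    threshold); EVI is depressed proportionally. Missing runs follow the
    length-class mix ``gap_mix``. The returned copy records spike indices in
    ``contaminated_steps``; the input is not modified.
    """
    if not 0.0 <= cloud_rate <= 1.0:
        raise ValueError("cloud_rate must be in [0, 1]")
    weights = np.array([float(gap_mix.get(c, 0.0)) for c in GAP_CLASSES])
    if np.any(weights < 0):
        raise ValueError("gap_mix weights must be non-negative")
    total_w = weights.sum()
    want_gaps = total_w > 0
    if want_gaps and abs(total_w - 1.0) > 1e-9:
        raise ValueError("gap_mix weights must sum to 1")

    rng = _as_rng(seed)
    ndvi = series.ndvi.copy()
    evi = series.evi.copy()

    # clouds register as large drops only against a vegetated signal; steps on
    # the low pre/post-season baseline cannot absorb the full depression
    # within the sensor floor of -0.2, so spikes target vegetated steps
    eligible = np.nonzero(~np.isnan(ndvi) & (ndvi > 0.45))[0]
    if heavy and eligible.size:
        n_spikes = min(int(rng.integers(9, 14)), eligible.size)
        spike_idx = rng.choice(eligible, size=n_spikes, replace=False)
    else:
        spike_idx = eligible[rng.random(eligible.size) < cloud_rate]
    for i in spike_idx:
        depth = float(np.clip(rng.normal(0.47, 0.12), 0.31, 0.75))
        # the depression is imposed against the previous step's clean value so
        # the realized step-to-step decrease matches the drawn magnitude even
        # on the steep green-up limb
        ref_n = series.ndvi[i - 1] if i > 0 and np.isfinite(series.ndvi[i - 1]) else series.ndvi[i]
        ref_e = series.evi[i - 1] if i > 0 and np.isfinite(series.evi[i - 1]) else series.evi[i]
        ndvi[i] = max(ref_n - depth, -0.2)
        evi[i] = max(ref_e - _EVI_SCALE * depth, -0.2)

    if want_gaps and rng.random() < gap_series_prob:
        n_gaps = 1 + int(rng.poisson(extra_gaps_mean))
        occupied = np.zeros(N_INTERVALS, dtype=bool)
        for _ in range(n_gaps):
            cls = GAP_CLASSES[int(rng.choice(len(GAP_CLASSES), p=weights / total_w))]
            length = _draw_gap_length(cls, rng)
            for _try in range(30):
                start = int(rng.integers(0, N_INTERVALS - length + 1))
                sl = slice(start, start + length)
                if not occupied[sl].any():
                    occupied[sl] = True
                    ndvi[sl] = np.nan
                    evi[sl] = np.nan
                    break

    return replace(
        series,
        ndvi=ndvi,
        evi=evi,
        contaminated_steps=frozenset(int(i) for i in spike_idx),
    )


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def _zone_counts(n_sites: int, zone_mix: Sequence[float]) -> list[int]:
    mix = np.asarray(zone_mix, dtype=float)
    if mix.shape != (len(ZONE_PRESETS),) or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("zone_mix must be non-negative proportions over the 3 zones summing to 1")
    raw = n_sites * mix
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding keeps the mix exact whenever it divides n
    for i in np.argsort(-(raw - counts))[: n_sites - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _simulate_site(
    site_id: str, zone: ZonePreset, params: SimulationParams, ss: np.random.SeedSequence
) -> SiteSeries:
    rng = np.random.default_rng(ss)
    anchor = zone.anchors[int(rng.integers(len(zone.anchors)))]
    lat = anchor[0] + rng.uniform(-0.5, 0.5)
    lon = anchor[1] + rng.uniform(-0.5, 0.5)

    temp, rain, rh = simulate_weather(zone, rng)
    timeline = compute_gdd_and_stages(temp)
    ndvi, evi = simulate_vegetation(timeline, rng, noise_sd=params.veg_noise_sd)
    biweekly = np.minimum(
        rain[: N_INTERVALS * DAYS_PER_INTERVAL].reshape(N_INTERVALS, DAYS_PER_INTERVAL).sum(axis=1),
        150.0,
    )
    series = SiteSeries(
        site_id=site_id,
        lat=lat,
        lon=lon,
        zone=zone.name,
        daily_temp=temp,
        daily_rain=rain,
        daily_rh=rh,
        ndvi=ndvi,
        evi=evi,
        biweekly_rain=biweekly,
        timeline=timeline,
    )
    heavy = params.heavy_rate > 0 and rng.random() < params.heavy_rate
    if heavy or params.cloud_rate > 0 or params.gap_series_prob > 0:
        series = corrupt_series(
            series,
            params.cloud_rate,
            params.gap_mix,
            rng,
            gap_series_prob=params.gap_series_prob,
            extra_gaps_mean=params.extra_gaps_mean,
            heavy=heavy,
        )
    return series


def simulate_dataset(
    n_sites: int,
    zone_mix: Sequence[float] = (0.4, 0.3, 0.3),
    params: SimulationParams | None = None,
    seed: int = 0,
) -> list[SiteSeries]:
    """Generate a seeded collection of site-seasons.

    ``zone_mix`` gives the (mediterranean, subtropical, temperate) proportions;
    counts are resolved by largest-remainder rounding, so e.g. 3000 sites at
    (0.4, 0.3, 0.3) yield exactly 1200/900/900. Identical seeds produce
    identical collections.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    params = params or SimulationParams()
    counts = _zone_counts(n_sites, zone_mix)
    seeds = np.random.SeedSequence(seed).spawn(n_sites)

    out: list[SiteSeries] = []
    k = 0
    for zone_name, count in zip(ZONE_PRESETS, counts):
        zone = ZONE_PRESETS[zone_name]
        for _ in range(count):
            out.append(_simulate_site(f"site{k:05d}", zone, params, seeds[k]))
            k += 1
    return out


# --------------------------------------------------------------------------
# delimited-text IO
# --------------------------------------------------------------------------

def write_dataset(collection: Sequence[SiteSeries], outdir, seed=None, params=None) -> None:
    """Write a collection as CSV tables plus a JSON manifest.

    Produces ``vegetation.csv`` (site_id, lat, lon, zone, interval, ndvi, evi,
    rain_mm), ``weather.csv`` (site_id, day, temp_c, rain_mm, rh_pct, with
    ``day`` season-relative) and ``labels.csv`` (per-interval stage plus
    stage-onset days).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    veg_rows, weather_rows, label_rows = [], [], []
    for s in collection:
        for i in range(N_INTERVALS):
            veg_rows.append(
                (s.site_id, s.lat, s.lon, s.zone, i + 1, s.ndvi[i], s.evi[i], s.biweekly_rain[i])
            )
            onset = {st: s.timeline.onset_day.get(st, "") for st in STAGES}
            label_rows.append(
                (s.site_id, i + 1, s.timeline.stage_per_interval[i], *onset.values())
            )
        for d in range(SEASON_DAYS):
            weather_rows.append(
                (s.site_id, d + 1, s.daily_temp[d], s.daily_rain[d], s.daily_rh[d])
            )

    pd.DataFrame(
        veg_rows, columns=["site_id", "lat", "lon", "zone", "interval", "ndvi", "evi", "rain_mm"]
    ).to_csv(outdir / "vegetation.csv", index=False, float_format="%.6f")
    pd.DataFrame(
        weather_rows, columns=["site_id", "day", "temp_c", "rain_mm", "rh_pct"]
    ).to_csv(outdir / "weather.csv", index=False, float_format="%.4f")
    pd.DataFrame(
        label_rows,
        columns=["site_id", "interval", "stage"] + [f"onset_{s}" for s in STAGES],
    ).to_csv(outdir / "labels.csv", index=False)

    manifest = {"n_sites": len(collection), "seed": seed}
    if params is not None:
        manifest["params"] = {
            k: (dict(v) if isinstance(v, Mapping) else v) for k, v in vars(params).items()
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(indir) -> list[SiteSeries]:
    """Read a collection written by :func:`write_dataset`."""
    indir = Path(indir)
    veg = pd.read_csv(indir / "vegetation.csv")
    weather = pd.read_csv(indir / "weather.csv")
    labels = pd.read_csv(indir / "labels.csv")

    out = []
    weather_g = {k: g for k, g in weather.groupby("site_id", sort=False)}
    labels_g = {k: g for k, g in labels.groupby("site_id", sort=False)}
    for site_id, g in veg.groupby("site_id", sort=False):
        g = g.sort_values("interval")
        w = weather_g[site_id].sort_values("day")
        lab = labels_g[site_id].sort_values("interval")
        onset = {}
        for st in STAGES:
            v = lab[f"onset_{st}"].iloc[0]
            if pd.notna(v) and v != "":
                onset[st] = int(v)
        timeline = StageTimeline(
            stage_per_interval=lab["stage"].tolist(), onset_day=onset
        )
        out.append(
            SiteSeries(
                site_id=str(site_id),
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                zone=str(g["zone"].iloc[0]),
                daily_temp=w["temp_c"].to_numpy(float),
                daily_rain=w["rain_mm"].to_numpy(float),
                daily_rh=w["rh_pct"].to_numpy(float),
                ndvi=g["ndvi"].to_numpy(float),
                evi=g["evi"].to_numpy(float),
                biweekly_rain=g["rain_mm"].to_numpy(float),
                timeline=timeline,
            )
        )
    return out
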