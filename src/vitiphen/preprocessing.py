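"""QC, imputation, normalization and pseudo-image construction.

The pipeline stages, in order: spike filtering on NDVI (biweekly change above
a 0.3 threshold), dropping series contaminated beyond a 30% fraction,
gap-length-adaptive imputation (linear for single-step gaps, cubic spline for
2-3 steps, windowed LOESS beyond), biweekly rainfall aggregation, dataset-level
min-max normalization, and reshaping each site-season into a 26x3x1
pseudo-image (rows = biweekly steps; columns = NDVI, EVI, rainfall) with an
optional causal row cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from vitiphen.stages import DAYS_PER_INTERVAL, N_INTERVALS
from vitiphen.synthetic_data import SiteSeries

__all__ = [
    "QcConfig",
    "GapSegment",
    "ImputationConfig",
    "NormalizationParams",
    "PseudoImage",
    "QcError",
    "ImputationError",
    "flag_spikes",
    "qc_partition",
    "find_gaps",
    "impute_gaps",
    "impute_series",
    "aggregate_rainfall",
    "normalize_minmax",
    "build_pseudo_image",
    "gap_census",
    "TABLE_GAP_CENSUS",
]


class QcError(ValueError):
    pass


class ImputationError(ValueError):
    pass


@dataclass(frozen=True)
class QcConfig:
    delta_ndvi_threshold: float = 0.3
    drop_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0 < self.delta_ndvi_threshold < 1:
            raise ValueError("delta_ndvi_threshold must be in (0, 1)")
        if not 0 < self.drop_fraction <= 1:
            raise ValueError("drop_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of missing biweekly steps (0-based indices)."""

    start_index: int
    length: int
    left_anchor: int | None  # nearest observed index before the gap
    right_anchor: int | None  # nearest observed index after the gap


@dataclass(frozen=True)
class ImputationConfig:
    linear_max_len: int = 1
    spline_max_len: int = 3
    loess_span: float = 0.2
    loess_half_window: int = 6

    def __post_init__(self) -> None:
        if self.linear_max_len > self.spline_max_len:
            raise ValueError("linear_max_len must be <= spline_max_len")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")


@dataclass
class NormalizationParams:
    """Per-feature min-max bounds; features are (ndvi, evi, rain)."""

    x_min: dict[str, float]
    x_max: dict[str, float]

    def __post_init__(self) -> None:
        for k in self.x_min:
            if not self.x_max[k] > self.x_min[k]:
                raise ValueError(f"degenerate feature {k!r}: x_max must exceed x_min")

    def transform(self, feature: str, x: np.ndarray, clip: bool = True) -> np.ndarray:
        lo, hi = self.x_min[feature], self.x_max[feature]
        out = (np.asarray(x, dtype=float) - lo) / (hi - lo)
        return np.clip(out, 0.0, 1.0) if clip else out

    def inverse(self, feature: str, x: np.ndarray) -> np.ndarray:
        lo, hi = self.x_min[feature], self.x_max[feature]
        return np.asarray(x, dtype=float) * (hi - lo) + lo


@dataclass
class PseudoImage:
    """26x3 normalized matrix; rows beyond ``valid_rows`` are zero (causal mask)."""

    values: np.ndarray  # (26, 3) in [0, 1]
    feature_order: tuple[str, str, str] = ("ndvi", "evi", "rain")
    channels: int = 1
    valid_rows: int = N_INTERVALS

    def __post_init__(self) -> None:
        if self.values.shape != (N_INTERVALS, 3):
            raise ValueError(f"pseudo-image must be {N_INTERVALS}x3, got {self.values.shape}")

    @property
    def tensor(self) -> np.ndarray:
        """(1, 26, 3) single-channel view for the classifier."""
        return self.values[None, :, :]


# --------------------------------------------------------------------------
# spike QC
# --------------------------------------------------------------------------

def flag_spikes(ndvi: np.ndarray, cfg: QcConfig | None = None) -> np.ndarray:
    """Flag steps whose NDVI change from the previous *observed* step exceeds
    the threshold (strict inequality, rises and drops alike).

    Missing steps are never flagged. Raises :class:`QcError` if fewer than two
    steps are observed.
    """
    cfg = cfg or QcConfig()
    x = np.asarray(ndvi, dtype=float)
    obs = np.nonzero(~np.isnan(x))[0]
    if obs.size < 2:
        raise QcError("need at least 2 observed steps to screen for spikes")
    flags = np.zeros(x.shape, dtype=bool)
    for prev, cur in zip(obs, obs[1:]):
        if abs(x[cur] - x[prev]) > cfg.delta_ndvi_threshold:
            flags[cur] = True
    return flags


def qc_partition(
    collection: Sequence[SiteSeries], cfg: QcConfig | None = None
) -> tuple[list[SiteSeries], list[SiteSeries]]:
    """Split a collection into kept and dropped series.

    A series is dropped when flagged plus originally missing steps exceed
    ``drop_fraction`` of the 26 intervals (strict). In kept series, flagged
    steps are censored to NaN in both NDVI and EVI (the contamination is
    atmospheric and affects both indices); rainfall is untouched.
    """
    cfg = cfg or QcConfig()
    kept, dropped = [], []
    for s in collection:
        flags = flag_spikes(s.ndvi, cfg)
        bad = flags | np.isnan(s.ndvi)
        if bad.sum() > cfg.drop_fraction * N_INTERVALS:
            dropped.append(s)
            continue
        if flags.any():
            ndvi = s.ndvi.copy()
            evi = s.evi.copy()
            ndvi[flags] = np.nan
            evi[flags] = np.nan
            s = replace(s, ndvi=ndvi, evi=evi)
        kept.append(s)
    return kept, dropped


# --------------------------------------------------------------------------
# gaps and imputation
# --------------------------------------------------------------------------

def find_gaps(missing_mask: np.ndarray) -> list[GapSegment]:
    """Maximal missing runs with their nearest observed anchors."""
    mask = np.asarray(missing_mask, dtype=bool)
    if mask.shape != (N_INTERVALS,):
        raise ValueError(f"mask must have length {N_INTERVALS}")
    gaps: list[GapSegment] = []
    i = 0
    while i < mask.size:
        if mask[i]:
            j = i
            while j + 1 < mask.size and mask[j + 1]:
                j += 1
            gaps.append(
                GapSegment(
                    start_index=i,
                    length=j - i + 1,
                    left_anchor=i - 1 if i > 0 else None,
                    right_anchor=j + 1 if j + 1 < mask.size else None,
                )
            )
            i = j + 1
        else:
            i += 1
    return gaps


def _loess_at(
    x: np.ndarray, obs_idx: np.ndarray, target: int, cfg: ImputationConfig
) -> float:
    """Local quadratic LOESS (tricube weights) at ``target`` over observed
    points within +-half_window intervals, widening the window if fewer than
    4 observed points fall inside it.

    The local polynomial is degree 2: around a multi-step gap the nearest
    observations sit several steps away, and a local line leaves a curvature
    bias on seasonal trajectories that dominates the observation noise; the
    quadratic term removes it."""
    w = cfg.loess_half_window
    while True:
        local = obs_idx[np.abs(obs_idx - target) <= w]
        if local.size >= 4 or w >= N_INTERVALS:
            break
        w += 1
    if local.size < 3:
        raise ImputationError(f"too few observed points for LOESS near step {target}")
    t = local.astype(float) - target  # center for conditioning
    d = np.abs(t)
    h = max(d.max(), 1.0)
    wts = (1 - (d / (h * 1.0001)) ** 3) ** 3
    X = np.stack([np.ones(local.size), t, t**2], axis=1)
    A = X.T @ (X * wts[:, None])
    b = X.T @ (wts * x[local])
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate geometry
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
    return float(beta[0])


def impute_gaps(
    series: np.ndarray,
    gaps: Sequence[GapSegment] | None = None,
    cfg: ImputationConfig | None = None,
) -> np.ndarray:
    """Fill missing steps with the gap-length-adaptive scheme.

    Length-1 gaps: linear interpolation between anchors; length 2-3: cubic
    spline (not-a-knot) through the observed points; longer gaps: windowed
    LOESS with span ``loess_span``. Edge gaps with one absent anchor use
    nearest-observed extension when short, LOESS otherwise. Observed values
    are never altered; an already-complete series is returned unchanged.
    """
    cfg = cfg or ImputationConfig()
    x = np.asarray(series, dtype=float).copy()
    mask = np.isnan(x)
    if gaps is None:
        gaps = find_gaps(mask)
    if not gaps:
        return x
    obs_idx = np.nonzero(~mask)[0]
    if obs_idx.size == 0:
        raise ImputationError("cannot impute an all-missing series")

    spline = None
    for gap in gaps:
        idx = np.arange(gap.start_index, gap.start_index + gap.length)
        edge = gap.left_anchor is None or gap.right_anchor is None
        if gap.length <= cfg.spline_max_len and edge:
            anchor = gap.right_anchor if gap.left_anchor is None else gap.left_anchor
            x[idx] = x[anchor]
        elif gap.length <= cfg.linear_max_len:
            x[idx] = np.interp(idx, obs_idx, x[obs_idx])
        elif gap.length <= cfg.spline_max_len:
            if obs_idx.size < 4:
                raise ImputationError(
                    f"too few observed points for spline at steps {idx[0]}..{idx[-1]}"
                )
            if spline is None:
                spline = CubicSpline(obs_idx, x[obs_idx])
            x[idx] = spline(idx)
        else:
            if obs_idx.size < 4:
                raise ImputationError(
                    f"too few observed points for LOESS at steps {idx[0]}..{idx[-1]}"
                )
            for t in idx:
                x[t] = _loess_at(x, obs_idx, int(t), cfg)
    return x


def impute_series(s: SiteSeries, cfg: ImputationConfig | None = None) -> SiteSeries:
    """Impute NDVI and EVI of one site-season (convenience wrapper)."""
    ndvi = impute_gaps(s.ndvi, cfg=cfg)
    evi = impute_gaps(s.evi, cfg=cfg)
    return replace(s, ndvi=ndvi, evi=evi)


# --------------------------------------------------------------------------
# rainfall aggregation and normalization
# --------------------------------------------------------------------------

def aggregate_rainfall(daily_rain: np.ndarray, season_start_day: int = 1) -> np.ndarray:
    """Sum daily rainfall into the 26 biweekly intervals.

    Interval ``i`` covers days ``start + 14*(i-1) .. start + 14*i - 1``
    (1-based); the 26 sums conserve the 364-day season total.
    """
    rain = np.asarray(daily_rain, dtype=float)
    start = season_start_day - 1
    need = start + N_INTERVALS * DAYS_PER_INTERVAL
    if rain.ndim != 1 or rain.size < need:
        raise ValueError(f"daily rainfall must cover {need} days from the season start")
    window = rain[start : start + N_INTERVALS * DAYS_PER_INTERVAL]
    return window.reshape(N_INTERVALS, DAYS_PER_INTERVAL).sum(axis=1)


def normalize_minmax(
    collection: Sequence[SiteSeries],
    params: NormalizationParams | str = "fit",
) -> tuple[list[SiteSeries], NormalizationParams]:
    """Min-max normalize (ndvi, evi, rain) across a collection.

    With ``params="fit"`` the per-feature bounds are fitted on this collection
    (a training fold); pass fitted params to transform held-out data, whose
    out-of-range values are clipped to [0, 1].
    """
    if isinstance(params, str):
        if params != "fit":
            raise ValueError("params must be NormalizationParams or 'fit'")
        feats = {
            "ndvi": np.concatenate([s.ndvi for s in collection]),
            "evi": np.concatenate([s.evi for s in collection]),
            "rain": np.concatenate([s.biweekly_rain for s in collection]),
        }
        x_min = {k: float(np.nanmin(v)) for k, v in feats.items()}
        x_max = {k: float(np.nanmax(v)) for k, v in feats.items()}
        params = NormalizationParams(x_min=x_min, x_max=x_max)

    out = [
        replace(
            s,
            ndvi=params.transform("ndvi", s.ndvi),
            evi=params.transform("evi", s.evi),
            biweekly_rain=params.transform("rain", s.biweekly_rain),
        )
        for s in collection
    ]
    return out, params


def build_pseudo_image(
    series: SiteSeries, interval_t: int = N_INTERVALS, params: NormalizationParams | None = None
) -> PseudoImage:
    """Build the causal 26x3x1 pseudo-image up to interval ``interval_t``.

    The series must already be imputed; if ``params`` is given the features
    are normalized here, otherwise they are assumed normalized already.
    Rows beyond ``interval_t`` are zeroed.
    """
    if not 1 <= interval_t <= N_INTERVALS:
        raise ValueError(f"interval_t must be in 1..{N_INTERVALS}")
    cols = (series.ndvi, series.evi, series.biweekly_rain)
    if params is not None:
        cols = (
            params.transform("ndvi", series.ndvi),
            params.transform("evi", series.evi),
            params.transform("rain", series.biweekly_rain),
        )
    values = np.stack(cols, axis=1).astype(float)
    if np.isnan(values[:interval_t]).any():
        raise ValueError("pseudo-image input must be imputed (no NaN in valid rows)")
    values[interval_t:] = 0.0
    return PseudoImage(values=values, valid_rows=interval_t)


# --------------------------------------------------------------------------
# gap census
# --------------------------------------------------------------------------

#: Published gap census used as an arithmetic fixture: per length class,
#: (number of gaps, total missing timesteps).
TABLE_GAP_CENSUS: dict[str, tuple[int, int]] = {
    "1": (3842, 3842),
    "2": (894, 1788),
    "3": (306, 918),
    "4-6": (142, 710),
    ">6": (53, 955),
}


def gap_census(
    counts: Mapping[str, tuple[int, int]],
    total_series: int,
    timesteps_per_series: int = N_INTERVALS,
    affected_series: int | None = None,
) -> dict:
    """Summarize a gap-length census.

    ``counts`` maps each length class to ``(n_gaps, missing_timesteps)``.
    Returns per-class shares of missing timesteps (percent, 1 decimal), the
    overall missing percentage (2 decimals) and, when ``affected_series`` is
    given, the percentage of series affected (2 decimals).
    """
    if total_series <= 0 or timesteps_per_series <= 0:
        raise ValueError("totals must be positive")
    total_missing = sum(m for _, m in counts.values())
    if total_missing <= 0:
        raise ValueError("undefined shares: no missing timesteps")
    out = {
        "class_share_pct": {
            cls: round(100.0 * m / total_missing, 1) for cls, (_, m) in counts.items()
        },
        "total_missing": total_missing,
        "overall_missing_pct": round(
            100.0 * total_missing / (total_series * timesteps_per_series), 2
        ),
    }
    if affected_series is not None:
        out["affected_series_pct"] = round(100.0 * affected_series / total_series, 2)
    return out
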