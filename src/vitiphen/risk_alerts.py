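"""Rule-based rain-stress and pest-risk alerting and event-matching validation.

A post-processing layer over the stage classifier: rain alerts fire when
biweekly rainfall above the collection's 75th percentile coincides with
predicted flowering (fruit set is folded into the flowering window); pest
alerts fire on warm-humid days (temperature > 22 degC and RH > 70%) inside the
30-day window before predicted veraison — conditions favourable to grapevine
moth (Lobesia botrana). Alerts are validated against documented events with a
+-5-day true-positive tolerance and a +-10-day false-positive exclusion band
(alerts 5-10 days from an event count neither way, absorbing reporting lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from vitiphen.stages import N_INTERVALS, interval_midpoint_day
from vitiphen.synthetic_data import SiteSeries

__all__ = [
    "RiskRuleConfig",
    "AlertRecord",
    "EventRecord",
    "MatchConfig",
    "MatchCounts",
    "rain_threshold",
    "detect_rain_risk",
    "detect_pest_risk",
    "recommend",
    "match_events",
    "alert_metrics",
    "events_from_truth",
]


@dataclass(frozen=True)
class RiskRuleConfig:
    rain_percentile: float = 75.0
    pest_temp_c: float = 22.0
    pest_rh_pct: float = 70.0
    pre_veraison_window_days: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.rain_percentile < 100:
            raise ValueError("rain_percentile must be in (0, 100)")
        if self.pre_veraison_window_days <= 0:
            raise ValueError("pre_veraison_window_days must be positive")


@dataclass(frozen=True)
class AlertRecord:
    site_id: str
    alert_type: str  # "rain" | "pest"
    day: int  # season-relative day
    stage_context: str
    trigger: tuple[float, ...]  # (rain_mm,) or (temp_c, rh_pct)


@dataclass(frozen=True)
class EventRecord:
    site_id: str
    event_type: str  # "rain" | "pest"
    day: int
    confidence: int = 1


@dataclass(frozen=True)
class MatchConfig:
    tp_tolerance_days: int = 5
    fp_exclusion_days: int = 10

    def __post_init__(self) -> None:
        if self.fp_exclusion_days < self.tp_tolerance_days:
            raise ValueError("fp_exclusion_days must be >= tp_tolerance_days")


@dataclass
class MatchCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0


# --------------------------------------------------------------------------
# detection rules
# --------------------------------------------------------------------------

def rain_threshold(
    collection: Sequence[SiteSeries], cfg: RiskRuleConfig | None = None
) -> float:
    """75th-percentile biweekly rainfall over the whole collection (population
    percentile; the per-site alternative is a keyword of detect_rain_risk)."""
    cfg = cfg or RiskRuleConfig()
    values = np.concatenate([s.biweekly_rain for s in collection])
    if values.size == 0:
        raise ValueError("empty rainfall collection")
    return float(np.percentile(values, cfg.rain_percentile))


def detect_rain_risk(
    predicted_stages: Sequence[str],
    series: SiteSeries,
    threshold: float | None = None,
    cfg: RiskRuleConfig | None = None,
    per_site: bool = False,
) -> list[AlertRecord]:
    """Rain-stress alerts: intervals with rainfall strictly above the 75th
    percentile whose predicted stage is flowering. Alert date = interval
    midpoint."""
    cfg = cfg or RiskRuleConfig()
    rain = np.asarray(series.biweekly_rain, dtype=float)
    if rain.size == 0 or np.all(np.isnan(rain)):
        raise ValueError("empty rainfall series")
    if threshold is None or per_site:
        threshold = float(np.percentile(rain, cfg.rain_percentile))
    alerts = []
    for i in range(N_INTERVALS):
        if predicted_stages[i] == "flowering" and rain[i] > threshold:
            alerts.append(
                AlertRecord(
                    site_id=series.site_id,
                    alert_type="rain",
                    day=interval_midpoint_day(i + 1),
                    stage_context="flowering",
                    trigger=(float(rain[i]),),
                )
            )
    return alerts


def detect_pest_risk(
    veraison_onset_day: int | None,
    series: SiteSeries,
    cfg: RiskRuleConfig | None = None,
) -> list[AlertRecord]:
    """Pest-risk alerts in the pre-veraison window.

    Scans days ``[onset - 30, onset - 1]`` for temperature > 22 degC together
    with RH > 70%; a run of consecutive qualifying days collapses to a single
    alert dated at the run's first day. No predicted veraison, no alerts.
    """
    cfg = cfg or RiskRuleConfig()
    if veraison_onset_day is None:
        return []
    lo = max(1, veraison_onset_day - cfg.pre_veraison_window_days)
    hi = veraison_onset_day - 1
    if hi < lo:
        return []
    days = np.arange(lo, hi + 1)
    temp = series.daily_temp[days - 1]
    rh = series.daily_rh[days - 1]
    if np.isnan(temp).any() or np.isnan(rh).any():
        bad = days[np.isnan(temp) | np.isnan(rh)]
        raise ValueError(f"missing weather covariates on days {bad.tolist()}")
    hot_humid = (temp > cfg.pest_temp_c) & (rh > cfg.pest_rh_pct)

    alerts = []
    in_run = False
    for d, ok, t, h in zip(days, hot_humid, temp, rh):
        if ok and not in_run:
            alerts.append(
                AlertRecord(
                    site_id=series.site_id,
                    alert_type="pest",
                    day=int(d),
                    stage_context="veraison",
                    trigger=(float(t), float(h)),
                )
            )
            in_run = True
        elif not ok:
            in_run = False
    return alerts


_RECOMMENDATIONS = {
    "budburst": ("Low", "Low", "Monitor soil moisture, prepare irrigation"),
    "flowering": ("High", "Medium", "Deploy rain covers, monitor humidity"),
    "veraison": ("Low", "High", "Apply biopesticides, increase scouting"),
    "harvest": ("Medium", "Low", "Delay harvest if rain expected, prepare storage"),
}


def recommend(stage: str) -> tuple[str, str, str]:
    """Static (rain risk grade, pest risk grade, recommended action) per stage."""
    try:
        return _RECOMMENDATIONS[stage]
    except KeyError:
        raise ValueError(f"unknown stage {stage!r}") from None


# --------------------------------------------------------------------------
# event matching and metrics
# --------------------------------------------------------------------------

def match_events(
    alerts: Sequence[AlertRecord],
    events: Sequence[EventRecord],
    cfg: MatchConfig | None = None,
) -> dict[str, MatchCounts]:
    """Greedy one-to-one alert/event matching per (site, type).

    An event is a true positive when a same-site same-type alert lies within
    the +-5-day tolerance; pairs are consumed greedily by smallest gap (ties
    to the earlier event). Unmatched events are false negatives. An unmatched
    alert is a false positive only when no same-site same-type event exists
    within +-10 days; alerts in the 5-10-day band count neither way.
    """
    cfg = cfg or MatchConfig()
    counts = {"rain": MatchCounts(), "pest": MatchCounts()}
    keys = {(a.site_id, a.alert_type) for a in alerts} | {
        (e.site_id, e.event_type) for e in events
    }
    for site, typ in sorted(keys):
        al = [a for a in alerts if a.site_id == site and a.alert_type == typ]
        ev = [e for e in events if e.site_id == site and e.event_type == typ]
        pairs = sorted(
            (
                (abs(a.day - e.day), e.day, a.day, ai, ei)
                for ai, a in enumerate(al)
                for ei, e in enumerate(ev)
                if abs(a.day - e.day) <= cfg.tp_tolerance_days
            ),
        )
        used_a: set[int] = set()
        used_e: set[int] = set()
        for gap, _, _, ai, ei in pairs:
            if ai in used_a or ei in used_e:
                continue
            used_a.add(ai)
            used_e.add(ei)
            counts[typ].tp += 1
        counts[typ].fn += len(ev) - len(used_e)
        for ai, a in enumerate(al):
            if ai in used_a:
                continue
            near = any(abs(a.day - e.day) <= cfg.fp_exclusion_days for e in ev)
            if not near:
                counts[typ].fp += 1
    return counts


def alert_metrics(tp: int, fn: int, fp: int) -> dict[str, float]:
    """Sensitivity (%, 1 decimal), precision (2 decimals) and F1 from counts."""
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return {
        "sensitivity_pct": round(sens, 1),
        "precision": round(prec, 2),
        "f1": round(f1, 2),
        "tp": tp,
        "fn": fn,
        "fp": fp,
    }


# --------------------------------------------------------------------------
# synthetic documented events
# --------------------------------------------------------------------------

def events_from_truth(
    collection: Sequence[SiteSeries],
    threshold: float,
    cfg: RiskRuleConfig | None = None,
    seed: int = 0,
    report_jitter_days: int = 2,
) -> list[EventRecord]:
    """Documented-event records derived from ground-truth stage timelines.

    Emulates field reports: a rain-damage event wherever true flowering
    coincides with rainfall above the threshold, and a pest-outbreak event at
    the first true warm-humid run in the 30 days before true veraison onset.
    Reported dates carry a small uniform jitter (field reports are accurate to
    a few days).
    """
    cfg = cfg or RiskRuleConfig()
    rng = np.random.default_rng(seed)
    events: list[EventRecord] = []
    for s in collection:
        jit = lambda d: int(np.clip(d + rng.integers(-report_jitter_days, report_jitter_days + 1), 1, 364))
        for i in range(N_INTERVALS):
            if s.timeline.stage_per_interval[i] == "flowering" and s.biweekly_rain[i] > threshold:
                events.append(
                    EventRecord(s.site_id, "rain", jit(interval_midpoint_day(i + 1)))
                )
        onset = s.timeline.onset_day.get("veraison")
        for a in detect_pest_risk(onset, s, cfg):
            events.append(EventRecord(s.site_id, "pest", jit(a.day)))
    return events
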