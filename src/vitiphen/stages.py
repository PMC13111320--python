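"""Shared phenological-stage conventions and the season-relative time grid.

A site-season is indexed in season-relative days 1..365 (day 1 = local season
start); the 26 biweekly intervals tile days 1..364, interval ``i`` covering
days ``14*(i-1)+1 .. 14*i``. All downstream code works on this grid so that
hemisphere and calendar placement are transparent.
"""

from __future__ import annotations

N_INTERVALS = 26
DAYS_PER_INTERVAL = 14
SEASON_DAYS = 365

#: The four classifier stages, in developmental order.
STAGES = ("budburst", "flowering", "veraison", "harvest")

#: Full label order including the internal pre-budburst label.
STAGE_ORDER = ("pre_season",) + STAGES

STAGE_INDEX = {s: i for i, s in enumerate(STAGE_ORDER)}


def interval_midpoint_day(interval: int, season_start_day: int = 1) -> int:
    """Season-relative midpoint day of a biweekly interval (1-based).

    With the default season start of day 1, interval 3 (days 29..42) has
    midpoint day 36.
    """
    if not 1 <= interval <= N_INTERVALS:
        raise ValueError(f"interval must be in 1..{N_INTERVALS}, got {interval}")
    return season_start_day + DAYS_PER_INTERVAL * (interval - 1) + 7


def interval_of_day(day: int) -> int:
    """1-based biweekly interval containing a season-relative day (1..364)."""
    if not 1 <= day <= N_INTERVALS * DAYS_PER_INTERVAL:
        raise ValueError(f"day must be in 1..{N_INTERVALS * DAYS_PER_INTERVAL}, got {day}")
    return (day - 1) // DAYS_PER_INTERVAL + 1
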