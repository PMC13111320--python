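"""Generator invariants: weather ranges, GDD staging, vegetation statistics,
corruption ground truth and dataset determinism."""

import numpy as np
import pytest

from vitiphen.stages import DAYS_PER_INTERVAL, N_INTERVALS, STAGE_INDEX
from vitiphen.synthetic_data import (
    DEFAULT_GAP_MIX,
    GddRule,
    SimulationParams,
    ZONE_PRESETS,
    compute_gdd_and_stages,
    corrupt_series,
    get_zone,
    simulate_dataset,
    simulate_vegetation,
    simulate_weather,
    write_dataset,
)


# ---------------------------------------------------------------- weather

@pytest.mark.parametrize("zone_name", list(ZONE_PRESETS))
@pytest.mark.parametrize("seed", [0, 7, 99])
def test_annual_rainfall_within_zone_range(zone_name, seed):
    zone = ZONE_PRESETS[zone_name]
    _, rain, _ = simulate_weather(zone, seed)
    lo, hi = zone.annual_rainfall_range
    assert lo <= rain.sum() <= hi
    assert np.all(rain >= 0)


def test_weather_determinism_and_rh_range():
    zone = ZONE_PRESETS["mediterranean"]
    t1, r1, h1 = simulate_weather(zone, 5)
    t2, r2, h2 = simulate_weather(zone, 5)
    assert np.array_equal(t1, t2) and np.array_equal(r1, r2) and np.array_equal(h1, h2)
    assert h1.min() >= 20 and h1.max() <= 100


def test_degenerate_sinusoid_constant_temperature():
    from dataclasses import replace

    zone = replace(ZONE_PRESETS["mediterranean"], noise_sd=0.0, temp_amplitude=0.0)
    temp, _, _ = simulate_weather(zone, 0)
    assert np.allclose(temp, zone.temp_mean)


def test_unknown_zone_rejected():
    with pytest.raises(ValueError, match="unknown zone"):
        get_zone("tropical")


# ---------------------------------------------------------------- GDD staging

def test_constant_20c_onsets():
    """At a constant 20 degC the cumulative GDD gains 10/day, so budburst
    (50 GDD) falls on day 5 and flowering (400 GDD) on day 40."""
    temp = np.full(365, 20.0)
    tl = compute_gdd_and_stages(temp)
    assert tl.onset_day["budburst"] == 5
    assert tl.onset_day["flowering"] == 40
    assert tl.onset_day["veraison"] == 100
    assert tl.onset_day["harvest"] == 140


def test_constant_base_temperature_never_stages():
    tl = compute_gdd_and_stages(np.full(365, 10.0))
    assert tl.onset_day == {}
    assert all(s == "pre_season" for s in tl.stage_per_interval)


def test_gdd_oracle_brute_force():
    """Onset days agree with an independent day-by-day accumulation on random
    temperature series."""
    rule = GddRule()
    rng = np.random.default_rng(42)
    for _ in range(50):
        temp = rng.uniform(0.0, 35.0, 365)
        tl = compute_gdd_and_stages(temp, rule)
        # brute force: accumulate day by day, record first crossing
        acc = 0.0
        expected = {}
        for d in range(365):
            acc += max(0.0, temp[d] - rule.base_temp)
            for stage, thr in rule.onsets.items():
                if stage not in expected and acc >= thr:
                    expected[stage] = d + 1
        assert tl.onset_day == expected


def test_stage_sequence_monotone(clean_collection):
    for s in clean_collection:
        idx = [STAGE_INDEX[x] for x in s.timeline.stage_per_interval]
        assert all(b >= a for a, b in zip(idx, idx[1:]))
        onsets = [s.timeline.onset_day.get(k) for k in ("budburst", "flowering", "veraison", "harvest")]
        present = [o for o in onsets if o is not None]
        assert present == sorted(present)


def test_onset_inside_first_carrying_interval(clean_collection):
    for s in clean_collection:
        for stage, day in s.timeline.onset_day.items():
            first = next(
                (i for i, lab in enumerate(s.timeline.stage_per_interval) if lab == stage), None
            )
            if first is None:  # stage crossed after its interval midpoints ended
                continue
            # the onset cannot postdate the midpoint of the first carrying interval
            assert day <= DAYS_PER_INTERVAL * first + 8


# ---------------------------------------------------------------- vegetation

def test_noise_free_curve_is_smooth_rise_plateau_decline():
    temp = np.full(365, 20.0)
    tl = compute_gdd_and_stages(temp)
    ndvi, evi = simulate_vegetation(tl, seed=0, noise_sd=0.0)
    d = np.diff(ndvi)
    peak = int(np.argmax(ndvi))
    assert np.all(d[: max(peak - 1, 1)] >= -1e-9)  # monotone rise to the peak
    assert np.all(d[peak:] <= 1e-9)  # monotone decline after
    assert np.all((evi >= 0.08) & (evi <= 0.75))


def test_clean_delta_ndvi_bounded(clean_collection):
    for s in clean_collection:
        assert np.nanmax(np.abs(np.diff(s.ndvi))) <= 0.28


def test_population_means_match_target_statistics():
    col = simulate_dataset(300, params=SimulationParams.clean(), seed=77)
    ndvi = np.concatenate([s.ndvi for s in col])
    evi = np.concatenate([s.evi for s in col])
    assert abs(ndvi.mean() - 0.45) < 0.05
    assert abs(evi.mean() - 0.38) < 0.05


def test_distribution_conformance_bounds():
    col = simulate_dataset(1000, params=SimulationParams.clean(), seed=11)
    ndvi = np.concatenate([s.ndvi for s in col])
    rain = np.concatenate([s.biweekly_rain for s in col])
    assert 0.10 <= ndvi.min() and ndvi.max() <= 0.85
    assert 0.0 <= rain.min() and rain.max() <= 150.0


# ---------------------------------------------------------------- corruption

def test_corrupt_noop_when_disabled(clean_collection):
    s = clean_collection[0]
    out = corrupt_series(s, 0.0, {c: 0.0 for c in DEFAULT_GAP_MIX}, seed=0)
    assert np.array_equal(out.ndvi, s.ndvi)
    assert out.contaminated_steps == frozenset()


def test_spike_drop_magnitude_mean_near_047(clean_collection):
    """The realized step-to-step NDVI decrease at spiked steps averages ~0.47
    and always exceeds the 0.3 screening threshold."""
    drops = []
    for rep in range(5):
        for k, s in enumerate(clean_collection):
            out = corrupt_series(s, 0.15, {c: 0.0 for c in DEFAULT_GAP_MIX}, seed=rep * 100 + k)
            for i in sorted(out.contaminated_steps):
                if i == 0 or i - 1 in out.contaminated_steps:
                    continue
                drops.append(s.ndvi[i - 1] - out.ndvi[i])
    drops = np.array(drops)
    assert drops.size > 100
    assert abs(drops.mean() - 0.47) < 0.04
    assert drops.min() > 0.3


def test_gap_length_class_frequencies_follow_mix():
    from vitiphen.preprocessing import find_gaps

    params = SimulationParams(cloud_rate=0.0, heavy_rate=0.0, gap_series_prob=1.0)
    col = simulate_dataset(600, params=params, seed=5)
    counts = {"1": 0, "2": 0, "3": 0, "4-6": 0, ">6": 0}
    for s in col:
        for g in find_gaps(np.isnan(s.ndvi)):
            if g.length <= 3:
                counts[str(g.length)] += 1
            elif g.length <= 6:
                counts["4-6"] += 1
            else:
                counts[">6"] += 1
    total = sum(counts.values())
    for cls, want in DEFAULT_GAP_MIX.items():
        got = counts[cls] / total
        # binomial 4-sigma band
        tol = 4 * np.sqrt(want * (1 - want) / total)
        assert abs(got - want) < tol + 0.01, (cls, got, want)


def test_gap_mix_must_sum_to_one(clean_collection):
    with pytest.raises(ValueError, match="sum to 1"):
        corrupt_series(clean_collection[0], 0.0, {"1": 0.5, "2": 0.2}, seed=0)


# ---------------------------------------------------------------- dataset

def test_zone_counts_exact():
    col = simulate_dataset(30, (0.4, 0.3, 0.3), SimulationParams.clean(), seed=0)
    zones = [s.zone for s in col]
    assert zones.count("mediterranean") == 12
    assert zones.count("subtropical") == 9
    assert zones.count("temperate") == 9


def test_single_site_collection():
    col = simulate_dataset(1, (1.0, 0.0, 0.0), SimulationParams.clean(), seed=3)
    assert len(col) == 1 and col[0].zone == "mediterranean"
    assert col[0].ndvi.shape == (N_INTERVALS,)


def test_dataset_serialization_deterministic(tmp_path):
    for sub in ("a", "b"):
        col = simulate_dataset(5, params=SimulationParams(), seed=9)
        write_dataset(col, tmp_path / sub, seed=9)
    for name in ("vegetation.csv", "weather.csv", "labels.csv"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


def test_roundtrip_read_write(tmp_path, clean_collection):
    from vitiphen.synthetic_data import read_dataset

    write_dataset(clean_collection[:4], tmp_path)
    back = read_dataset(tmp_path)
    assert len(back) == 4
    for a, b in zip(clean_collection[:4], back):
        assert a.site_id == b.site_id
        np.testing.assert_allclose(a.ndvi, b.ndvi, atol=1e-6)
        assert a.timeline.stage_per_interval == b.timeline.stage_per_interval
        assert a.timeline.onset_day == b.timeline.onset_day
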