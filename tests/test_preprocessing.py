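"""Spike QC, gap imputation, aggregation, normalization, pseudo-images and the
gap census."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitiphen import preprocessing as pp
from vitiphen.stages import N_INTERVALS
from vitiphen.synthetic_data import DEFAULT_GAP_MIX, SimulationParams, corrupt_series, simulate_dataset


# ---------------------------------------------------------------- spikes

def test_flat_series_no_flags():
    assert not pp.flag_spikes(np.full(26, 0.4)).any()


def test_single_drop_and_recovery_flagged():
    x = np.full(26, 0.65)
    x[10] = 0.20  # drop of 0.45, recovery of 0.45
    flags = pp.flag_spikes(x)
    assert flags[10] and flags[11]
    assert flags.sum() == 2


def test_delta_exactly_threshold_not_flagged():
    x = np.full(26, 0.50)
    x[5] = 0.20  # delta exactly 0.3: strict inequality, no flag
    assert not pp.flag_spikes(x).any()


def test_delta_uses_previous_observed_value():
    x = np.full(26, 0.60)
    x[7] = np.nan
    x[8] = 0.25  # vs last observed 0.60 -> 0.35 > 0.3
    assert pp.flag_spikes(x)[8]


def test_all_missing_raises():
    with pytest.raises(pp.QcError):
        pp.flag_spikes(np.full(26, np.nan))


def test_qc_partition_drop_boundary():
    def series_with_bad(n_bad):
        from vitiphen.synthetic_data import simulate_dataset

        s = simulate_dataset(1, (1, 0, 0), SimulationParams.clean(), seed=1)[0]
        ndvi = s.ndvi.copy()
        ndvi[:n_bad] = np.nan
        from dataclasses import replace

        return replace(s, ndvi=ndvi)

    kept, dropped = pp.qc_partition([series_with_bad(9)])  # 9/26 = 34.6% > 30%
    assert not kept and len(dropped) == 1
    kept, dropped = pp.qc_partition([series_with_bad(7)])  # 7/26 = 26.9% < 30%
    assert len(kept) == 1 and not dropped


def test_spike_filter_transparent_on_clean_data(clean_collection):
    kept, dropped = pp.qc_partition(clean_collection)
    assert not dropped
    for before, after in zip(clean_collection, kept):
        assert not np.isnan(after.ndvi).any()
        np.testing.assert_array_equal(before.ndvi, after.ndvi)


def test_spike_filter_recall_on_injected_spikes(clean_collection):
    injected = flagged = 0
    for rep in range(4):
        for k, s in enumerate(clean_collection):
            out = corrupt_series(s, 0.1, {c: 0.0 for c in DEFAULT_GAP_MIX}, seed=1000 * rep + k)
            flags = pp.flag_spikes(out.ndvi)
            injected += len(out.contaminated_steps)
            flagged += sum(1 for i in out.contaminated_steps if flags[i])
    assert injected > 50
    assert flagged / injected >= 0.90


# ---------------------------------------------------------------- gaps

def test_find_gaps_enumeration():
    mask = np.zeros(26, dtype=bool)
    mask[[5, 6, 12]] = True
    gaps = pp.find_gaps(mask)
    assert [(g.start_index, g.length) for g in gaps] == [(5, 2), (12, 1)]
    assert gaps[0].left_anchor == 4 and gaps[0].right_anchor == 7


def test_find_gaps_empty_and_edges():
    assert pp.find_gaps(np.zeros(26, dtype=bool)) == []
    mask = np.zeros(26, dtype=bool)
    mask[0] = mask[25] = True
    gaps = pp.find_gaps(mask)
    assert gaps[0].left_anchor is None and gaps[0].right_anchor == 1
    assert gaps[1].left_anchor == 24 and gaps[1].right_anchor is None


# ---------------------------------------------------------------- imputation

def test_linear_gap_recovered_exactly():
    t = np.arange(26, dtype=float)
    x = 0.02 * t
    xm = x.copy()
    xm[9] = np.nan
    out = pp.impute_gaps(xm)
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_cubic_gap_recovered_by_spline():
    t = np.arange(26, dtype=float)
    x = 1e-4 * (t - 12.0) ** 3 + 0.4
    xm = x.copy()
    xm[10:12] = np.nan  # interior L=2 gap
    out = pp.impute_gaps(xm)
    np.testing.assert_allclose(out, x, atol=1e-6)


def test_long_gap_uses_loess_branch(monkeypatch):
    called = {}
    orig = pp._loess_at

    def spy(*args, **kwargs):
        called["yes"] = True
        return orig(*args, **kwargs)

    monkeypatch.setattr(pp, "_loess_at", spy)
    x = np.sin(np.linspace(0, np.pi, 26)) * 0.5 + 0.2
    x[8:13] = np.nan  # L = 5
    pp.impute_gaps(x)
    assert called.get("yes")


def test_loess_recovers_smooth_seasonal_signal():
    rng = np.random.default_rng(0)
    t = np.linspace(0, np.pi, 26)
    noise_sd = 0.02
    errs = []
    for k in range(20):
        clean = 0.15 + 0.6 * np.sin(t)
        x = clean + rng.normal(0, noise_sd, 26)
        xm = x.copy()
        start = rng.integers(4, 17)
        xm[start : start + 5] = np.nan
        out = pp.impute_gaps(xm)
        errs.append(out[start : start + 5] - clean[start : start + 5])
    rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
    assert rmse <= 1.5 * noise_sd


def test_imputation_idempotent_on_complete_series():
    x = np.random.default_rng(1).random(26)
    np.testing.assert_array_equal(pp.impute_gaps(x), x)


def test_observed_values_never_altered():
    x = np.sin(np.linspace(0, 2, 26))
    xm = x.copy()
    xm[[3, 9, 10, 15, 16, 17, 18]] = np.nan
    out = pp.impute_gaps(xm)
    obs = ~np.isnan(xm)
    np.testing.assert_array_equal(out[obs], x[obs])


def test_edge_gap_short_uses_nearest_value():
    x = np.linspace(0.2, 0.7, 26)
    xm = x.copy()
    xm[:2] = np.nan
    out = pp.impute_gaps(xm)
    np.testing.assert_allclose(out[:2], x[2])


@given(st.sets(st.integers(0, 25), max_size=10))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_dispatch_exhaustive_over_gap_lengths(missing):
    """Every gap length maps to exactly one imputation branch and the output
    is always complete when >= 4 observations remain."""
    x = 0.3 + 0.4 * np.sin(np.linspace(0, 3, 26))
    xm = x.copy()
    xm[list(missing)] = np.nan
    if 26 - len(missing) < 4:
        return
    out = pp.impute_gaps(xm)
    assert not np.isnan(out).any()


# ---------------------------------------------------------------- aggregation

def test_rainfall_aggregation_conservation():
    rain = np.ones(365)
    agg = pp.aggregate_rainfall(rain)
    np.testing.assert_allclose(agg, 14.0)
    one = np.zeros(365)
    one[100] = 30.0
    agg = pp.aggregate_rainfall(one)
    assert agg.sum() == 30.0 and (agg > 0).sum() == 1
    rng_rain = np.random.default_rng(2).random(365) * 10
    assert np.isclose(pp.aggregate_rainfall(rng_rain).sum(), rng_rain[:364].sum())


def test_rainfall_window_bounds_checked():
    with pytest.raises(ValueError):
        pp.aggregate_rainfall(np.ones(100))


# ---------------------------------------------------------------- normalization

def test_minmax_endpoints_and_table_value():
    params = pp.NormalizationParams(x_min={"ndvi": 0.10}, x_max={"ndvi": 0.85})
    assert params.transform("ndvi", np.array([0.10]))[0] == 0.0
    assert params.transform("ndvi", np.array([0.85]))[0] == 1.0
    assert abs(params.transform("ndvi", np.array([0.45]))[0] - 0.4667) < 5e-5


def test_minmax_roundtrip_and_degenerate():
    params = pp.NormalizationParams(x_min={"f": 2.0}, x_max={"f": 9.0})
    x = np.linspace(2, 9, 11)
    back = params.inverse("f", params.transform("f", x))
    np.testing.assert_allclose(back, x, atol=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        pp.NormalizationParams(x_min={"f": 1.0}, x_max={"f": 1.0})


def test_fit_on_collection_bounds_outputs(clean_collection):
    normed, params = pp.normalize_minmax(clean_collection, "fit")
    for s in normed:
        for arr in (s.ndvi, s.evi, s.biweekly_rain):
            assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0


# ---------------------------------------------------------------- pseudo-image

def test_pseudo_image_shapes_and_causal_mask(clean_collection):
    normed, params = pp.normalize_minmax(clean_collection, "fit")
    s = normed[0]
    full = pp.build_pseudo_image(s, 26)
    assert full.values.shape == (26, 3) and full.valid_rows == 26
    assert not np.any(full.values[-1] == np.nan)
    one = pp.build_pseudo_image(s, 1)
    assert np.all(one.values[1:] == 0.0)
    assert np.any(one.values[0] != 0.0)
    with pytest.raises(ValueError):
        pp.build_pseudo_image(s, 27)


def test_feature_column_order_is_contractual(clean_collection):
    normed, _ = pp.normalize_minmax(clean_collection, "fit")
    s = normed[0]
    img = pp.build_pseudo_image(s, 26)
    np.testing.assert_array_equal(img.values[:, 0], s.ndvi)
    np.testing.assert_array_equal(img.values[:, 2], s.biweekly_rain)


# ---------------------------------------------------------------- census

def test_census_reproduces_published_percentages():
    out = pp.gap_census(pp.TABLE_GAP_CENSUS, total_series=10_000, affected_series=2847)
    assert out["class_share_pct"] == {
        "1": 46.8,
        "2": 21.8,
        "3": 11.2,
        "4-6": 8.6,
        ">6": 11.6,
    }
    assert out["overall_missing_pct"] == 3.16
    assert out["affected_series_pct"] == 28.47


def test_census_single_class_and_zero_errors():
    out = pp.gap_census({"1": (10, 10)}, total_series=100)
    assert out["class_share_pct"]["1"] == 100.0
    with pytest.raises(ValueError):
        pp.gap_census({"1": (0, 0)}, total_series=100)
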