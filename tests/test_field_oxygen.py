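"""Unit tests for in-situ DO logger summarization."""

import numpy as np
import pandas as pd
import pytest

from oxyreg.errors import DataError, MetadataError, ParameterError
from oxyreg.field_oxygen import (
    FieldSeries,
    align_with_tides,
    cumulative_time_histogram,
    interior_exterior_delta,
    read_logger_csv,
    summarize_series,
)


def make_series(do, position="interior", colony_id="c1", cadence_s=60,
                start="2022-02-05 00:00:00", temperature=None):
    do = np.asarray(do, dtype=float)
    ts = pd.date_range(start, periods=do.size, freq=f"{cadence_s}s")
    temp = temperature if temperature is not None else np.full(do.size, 29.0)
    return FieldSeries(timestamps=ts, do_mgL=do, temperature=temp,
                       position=position, colony_id=colony_id)


def sinusoid_series(mean=6.0, amp=2.0, cycles=10, period_h=6.0, **kw):
    n = int(cycles * period_h * 60)  # 60-s cadence
    t_h = np.arange(n) / 60.0
    return make_series(mean + amp * np.sin(2 * np.pi * t_h / period_h), **kw)


# ---------------------------------------------------------------------------
# construction / reading
# ---------------------------------------------------------------------------

def test_series_rejects_bad_position():
    with pytest.raises(MetadataError):
        make_series(np.full(10, 6.0), position="middle")


def test_series_rejects_out_of_range_do():
    with pytest.raises(DataError, match="DO outside"):
        make_series([6.0, 25.0])


def test_read_well_formed(tmp_path):
    p = tmp_path / "log.csv"
    ts = pd.date_range("2022-02-05", periods=200, freq="60s")
    pd.DataFrame({"datetime": ts, "do_mgL": 6.0, "temp_C": 29.0}).to_csv(
        p, index=False)
    s = read_logger_csv(p, "interior", "c1")
    assert s.n == 200
    assert "cadence_warning" not in s.meta


def test_read_cadence_warning(tmp_path):
    p = tmp_path / "log.csv"
    ts = pd.date_range("2022-02-05", periods=150, freq="10min")
    pd.DataFrame({"datetime": ts, "do_mgL": 6.0}).to_csv(p, index=False)
    s = read_logger_csv(p, "exterior", "c1")
    assert "cadence_warning" in s.meta


def test_read_records_gaps(tmp_path):
    p = tmp_path / "log.csv"
    ts = list(pd.date_range("2022-02-05", periods=100, freq="60s"))
    ts += list(pd.date_range(ts[-1] + pd.Timedelta(minutes=20),
                             periods=100, freq="60s"))
    pd.DataFrame({"datetime": ts, "do_mgL": 6.0}).to_csv(p, index=False)
    s = read_logger_csv(p, "interior", "c1")
    assert len(s.meta["gaps"]) == 1


def test_read_empty_file(tmp_path):
    p = tmp_path / "log.csv"
    p.write_text("")
    with pytest.raises(DataError):
        read_logger_csv(p, "interior", "c1")


def test_read_unknown_position(tmp_path):
    p = tmp_path / "log.csv"
    p.write_text("datetime,do_mgL\n2022-02-05,6.0\n")
    with pytest.raises(MetadataError):
        read_logger_csv(p, "inside", "c1")


# ---------------------------------------------------------------------------
# summarize_series
# ---------------------------------------------------------------------------

def test_summary_constant_series():
    s = make_series(np.full(200, 6.0))
    summ = summarize_series(s, thresholds=[5.0])
    assert summ.fraction_below[5.0] == 0.0
    assert summ.do_min == summ.do_max == summ.do_mean == 6.0
    assert summ.do_range == 0.0


def test_summary_two_level_series():
    s = make_series([4.0, 4.0, 6.0, 6.0] * 50)
    summ = summarize_series(s, thresholds=[5.0])
    assert summ.fraction_below[5.0] == pytest.approx(0.5)


def test_summary_sinusoid_arcsine_fraction():
    # DO = 6 + 2 sin: below 5 iff sin < -1/2, a third of each cycle
    s = sinusoid_series()
    summ = summarize_series(s, thresholds=[5.0])
    assert summ.fraction_below[5.0] == pytest.approx(1.0 / 3.0, abs=0.01)


def test_summary_min_samples():
    with pytest.raises(ParameterError):
        summarize_series(make_series(np.full(50, 6.0)))


def test_summary_fraction_monotone_in_threshold():
    s = sinusoid_series()
    summ = summarize_series(s, thresholds=[3.0, 4.0, 5.0, 6.0, 7.0, 9.0])
    fracs = [summ.fraction_below[t] for t in sorted(summ.fraction_below)]
    assert all(a <= b for a, b in zip(fracs, fracs[1:]))
    assert all(0.0 <= f <= 1.0 for f in fracs)
    assert summ.do_min <= summ.do_mean <= summ.do_max


# ---------------------------------------------------------------------------
# cumulative_time_histogram
# ---------------------------------------------------------------------------

def test_histogram_constant_single_bin():
    s = make_series(np.full(150, 6.0))
    h = cumulative_time_histogram(s, bin_width=1.0, origin=5.5)
    assert h.fraction.sum() == pytest.approx(1.0, abs=1e-9)
    i = int(np.argmax(h.fraction))
    assert h.fraction[i] == pytest.approx(1.0)
    assert h.bin_left[i] == pytest.approx(5.5)
    assert h.bin_right[i] == pytest.approx(6.5)


def test_histogram_two_level_counts():
    s = make_series([4.2, 4.2, 4.2, 6.2] * 50)
    h = cumulative_time_histogram(s, bin_width=1.0, origin=0.0)
    frac = dict(zip(h.bin_left, h.fraction))
    assert frac[4.0] == pytest.approx(0.75)
    assert frac[6.0] == pytest.approx(0.25)


def test_histogram_matches_brute_force_tally():
    s = sinusoid_series()
    width = 0.5
    h = cumulative_time_histogram(s, bin_width=width, origin=0.0)
    # independent oracle: per-sample loop into bins
    counts = {}
    for v in s.do_mgL:
        lo = np.floor(v / width) * width
        counts[round(lo, 6)] = counts.get(round(lo, 6), 0) + 1
    total = s.do_mgL.size
    for left, fr in zip(h.bin_left, h.fraction):
        assert fr == pytest.approx(counts.get(round(left, 6), 0) / total,
                                   abs=1e-9)
    assert h.fraction.sum() == pytest.approx(1.0, abs=1e-9)


def test_histogram_bad_width():
    with pytest.raises(ParameterError):
        cumulative_time_histogram(make_series(np.full(150, 6.0)), bin_width=0)


# ---------------------------------------------------------------------------
# interior_exterior_delta
# ---------------------------------------------------------------------------

def test_delta_identical_series_zero():
    i = make_series(np.full(200, 6.0))
    e = make_series(np.full(200, 6.0), position="exterior")
    d = interior_exterior_delta(i, e)
    assert d["delta_mean"] == 0.0
    assert d["delta_range"] == 0.0
    assert d["pct_diff"] == 0.0


def test_delta_constant_offset():
    base = 6.0 + np.sin(np.linspace(0, 20, 300))
    i = make_series(base)
    e = make_series(base + 0.5, position="exterior")
    d = interior_exterior_delta(i, e)
    assert d["delta_mean"] == pytest.approx(0.5)
    assert d["delta_range"] == pytest.approx(0.0, abs=1e-12)


def test_delta_antisymmetric():
    rng = np.random.default_rng(5)
    i = make_series(6.0 + rng.normal(0, 0.3, 300))
    e = make_series(7.0 + rng.normal(0, 0.3, 300), position="exterior")
    d = interior_exterior_delta(i, e)
    i_sw = make_series(e.do_mgL, position="interior")
    e_sw = make_series(i.do_mgL, position="exterior")
    d_sw = interior_exterior_delta(i_sw, e_sw)
    assert d_sw["delta_mean"] == pytest.approx(-d["delta_mean"])
    assert d_sw["delta_range"] == pytest.approx(-d["delta_range"])


def test_delta_requires_same_colony():
    i = make_series(np.full(200, 6.0), colony_id="a")
    e = make_series(np.full(200, 6.0), position="exterior", colony_id="b")
    with pytest.raises(DataError, match="colony"):
        interior_exterior_delta(i, e)


def test_delta_requires_overlap():
    i = make_series(np.full(200, 6.0), start="2022-02-05")
    e = make_series(np.full(200, 6.0), position="exterior",
                    start="2022-02-07")
    with pytest.raises(DataError, match="overlap"):
        interior_exterior_delta(i, e)


def test_delta_uses_overlap_window_only():
    # interior covers two days; exterior only the second, where interior is
    # higher: restricting to the overlap is what makes the delta negative
    do_i = np.concatenate([np.full(1440, 5.0), np.full(1440, 7.0)])
    i = make_series(do_i, start="2022-02-05 00:00:00")
    e = make_series(np.full(1440, 6.5), position="exterior",
                    start="2022-02-06 00:00:00")
    d = interior_exterior_delta(i, e)
    assert d["delta_mean"] == pytest.approx(-0.5, abs=1e-6)


def test_delta_generator_ground_truth():
    from oxyreg.synthetic_data import simulate_field_series
    interior, exterior = simulate_field_series(interior_pct_offset=10.0,
                                               days=2, seed=3)
    d = interior_exterior_delta(interior, exterior)
    assert d["pct_diff"] == pytest.approx(10.0, abs=0.5)


# ---------------------------------------------------------------------------
# align_with_tides
# ---------------------------------------------------------------------------

def _sun_table(dates, sunrise="06:10", sunset="18:50"):
    return pd.DataFrame({"date": dates, "sunrise": sunrise, "sunset": sunset})


def test_align_single_day():
    s = make_series(np.full(24 * 60, 6.0), start="2022-02-05 00:00:00")
    tides = pd.DataFrame({
        "datetime": pd.date_range("2022-02-05", periods=25, freq="1h"),
        "height_m": np.sin(np.linspace(0, 2 * np.pi, 25)) + 1.5,
    })
    joined = align_with_tides(s, tides, _sun_table(["2022-02-05"]))
    assert len(joined) == s.n
    assert joined["height_m"].notna().all()
    # nearest-neighbour offsets never exceed 30 min for hourly tide entries
    sunset = pd.Timestamp("2022-02-05 18:50")
    flips = joined.loc[joined["is_day"].astype(int).diff() == -1, "datetime"]
    assert (flips == sunset).all()


def test_align_day_flag_semantics():
    s = make_series(np.full(24 * 60, 6.0), start="2022-02-05 00:00:00")
    tides = pd.DataFrame({
        "datetime": pd.date_range("2022-02-05", periods=25, freq="1h"),
        "height_m": 1.0,
    })
    joined = align_with_tides(s, tides, _sun_table(["2022-02-05"]))
    at = joined.set_index("datetime")["is_day"]
    assert not at[pd.Timestamp("2022-02-05 06:09:00")]
    assert at[pd.Timestamp("2022-02-05 06:10:00")]
    assert at[pd.Timestamp("2022-02-05 18:49:00")]
    assert not at[pd.Timestamp("2022-02-05 18:50:00")]


def test_align_tide_coverage_gap():
    s = make_series(np.full(240, 6.0), start="2022-02-05 00:00:00")
    tides = pd.DataFrame({
        "datetime": pd.date_range("2022-02-05 02:00", periods=5, freq="1h"),
        "height_m": 1.0,
    })
    with pytest.raises(DataError, match="tide table"):
        align_with_tides(s, tides, _sun_table(["2022-02-05"]))


def test_align_sun_table_missing_date():
    s = make_series(np.full(240, 6.0), start="2022-02-05 23:00:00")
    tides = pd.DataFrame({
        "datetime": pd.date_range("2022-02-05 22:00", periods=8, freq="1h"),
        "height_m": 1.0,
    })
    with pytest.raises(DataError, match="sun table"):
        align_with_tides(s, tides, _sun_table(["2022-02-05"]))
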