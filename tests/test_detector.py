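"""Unit and property tests for the FSM detector."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fincount.detector import (MODES, DetectionEvent, DetectorConfig,
                               FSMDetector, ImpedanceSample, State,
                               combine_modes, detect_events,
                               detection_threshold, events_to_frame,
                               iter_stream, noise_amplitude, read_stream,
                               stability_check, state_history, write_stream)

RNG = np.random.default_rng(12345)


def make_stream(re: np.ndarray, im: np.ndarray | None = None,
                rate: float = 20.0, t0: float = 0.0) -> pd.DataFrame:
    n = re.size
    if im is None:
        im = np.full(n, -0.005)
    return pd.DataFrame({
        "device_id": "0",
        "frequency_hz": 50_000.0,
        "resistance_ohm": re,
        "reactance_ohm": im,
        "timestamp_s": t0 + np.arange(n) / rate,
    })


def baseline_with_dip(n_base: int = 600, dip_depth: float = 0.5,
                      dip_len: int = 40, sd: float = 0.002) -> np.ndarray:
    re = 230.0 + RNG.normal(0, sd, size=n_base)
    i0 = n_base // 2
    re[i0:i0 + dip_len] -= dip_depth
    return re


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def test_noise_amplitude_constant_buffer_is_zero():
    assert noise_amplitude([5.0] * 20) == 0.0


def test_noise_amplitude_known_value():
    # median 2.0, max 7.0 -> amplitude 5.0
    assert noise_amplitude([1.0, 2.0, 3.0, 2.0, 7.0]) == 5.0


def test_noise_amplitude_never_negative():
    # max == median only for constant buffers; skewed-low buffer stays >= 0
    assert noise_amplitude([-3.0, -3.0, -3.0, -9.0, -3.0]) == 0.0


def test_noise_amplitude_empty_raises():
    with pytest.raises(ValueError):
        noise_amplitude([])


def test_detection_threshold_ratio_half_equals_median_minus_amplitude():
    buf = list(RNG.normal(100.0, 1.0, size=200))
    med = float(np.median(buf))
    amp = noise_amplitude(buf)
    assert detection_threshold(buf, 0.5) == pytest.approx(med - amp, abs=0.0)


def test_detection_threshold_noise_floor_applies():
    buf = [10.0] * 50                       # zero noise amplitude
    assert detection_threshold(buf, 3.0, noise_floor=0.01) == pytest.approx(
        10.0 - 3.0 * 2.0 * 0.01)


def test_detection_threshold_negative_ratio_raises():
    with pytest.raises(ValueError):
        detection_threshold([1.0, 2.0], -1.0)


def test_stability_check_flat_is_stable():
    buf = [(t, 5.0) for t in np.arange(10) * 0.05]
    assert stability_check(buf, swing_max=0.1, slope_max=2.5e-3)


def test_stability_check_swing_violation():
    buf = [(0.0, 0.0), (0.05, 0.2), (0.10, 0.0)]
    assert not stability_check(buf, swing_max=0.1, slope_max=1e9)


def test_stability_check_slope_violation():
    t = np.arange(20) * 0.05
    buf = list(zip(t, 0.05 * t))            # slope 50 mOhm/s, swing 47.5 mOhm
    assert not stability_check(buf, swing_max=0.1, slope_max=2.5e-3)


def test_stability_check_requires_two_samples():
    with pytest.raises(ValueError):
        stability_check([(0.0, 1.0)], 0.1, 0.1)


@pytest.mark.parametrize("mode,table", [
    ("re", {(0, 0): 0, (0, 1): 0, (1, 0): 1, (1, 1): 1}),
    ("im", {(0, 0): 0, (0, 1): 1, (1, 0): 0, (1, 1): 1}),
    ("or", {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 1}),
    ("and", {(0, 0): 0, (0, 1): 0, (1, 0): 0, (1, 1): 1}),
])
def test_combine_modes_truth_table(mode, table):
    for (a, b), out in table.items():
        assert combine_modes(bool(a), bool(b), mode) is bool(out)


def test_combine_modes_unknown_mode_raises():
    with pytest.raises(ValueError):
        combine_modes(True, True, "xor")


def test_detector_config_validation():
    with pytest.raises(ValueError):
        DetectorConfig(buffer_len=1)
    with pytest.raises(ValueError):
        DetectorConfig(mode="bogus")
    with pytest.raises(ValueError):
        DetectorConfig(threshold_ratio=-1.0)
    with pytest.raises(ValueError):
        DetectorConfig(gap_reset_s=0.0)


# ---------------------------------------------------------------------------
# FSM behavior
# ---------------------------------------------------------------------------

def test_dip_produces_one_event_and_fish_state():
    stream = make_stream(baseline_with_dip())
    cfg = DetectorConfig()
    events = detect_events(stream, cfg)
    assert len(events) == 1
    states = state_history(stream, cfg)
    assert State.FISH in states
    # the event brackets the injected dip (samples 300..339 at 20 Hz)
    assert events[0].t_start == pytest.approx(15.0, abs=0.2)
    assert events[0].t_end == pytest.approx(17.0, abs=0.3)
    assert events[0].channel_evidence == "re"


def test_positive_spikes_never_reach_fish():
    re = 230.0 + RNG.normal(0, 0.002, size=800)
    re[np.arange(250, 800, 60)] += 5.0      # large positive spikes only
    states = state_history(make_stream(re), DetectorConfig())
    assert State.FISH not in states
    assert detect_events(make_stream(re), DetectorConfig()) == []


def test_gap_triggers_internal_reset():
    re = 230.0 + RNG.normal(0, 0.002, size=500)
    stream = make_stream(re)
    stream.loc[300:, "timestamp_s"] += 5.0  # 5 s pause mid-stream
    states = state_history(stream, DetectorConfig())
    assert states[299] == State.STABLE      # settled before the gap
    assert states[300] == State.INIT        # reset at the gap
    assert states[-1] == State.STABLE       # settles again afterwards


def test_gap_closes_open_event():
    re = baseline_with_dip(n_base=600, dip_len=300)  # dip runs to the end
    stream = make_stream(re)
    stream.loc[320:, "timestamp_s"] += 5.0  # gap while in FISH
    events = detect_events(stream, DetectorConfig())
    assert len(events) >= 1
    assert events[0].t_end <= stream["timestamp_s"].iloc[319] + 1e-9


def test_trailing_open_event_is_closed_by_finish():
    re = baseline_with_dip(n_base=400, dip_len=200)  # still in FISH at EOF
    stream = make_stream(re)
    events = detect_events(stream, DetectorConfig())
    assert len(events) == 1
    assert events[0].t_end == pytest.approx(stream["timestamp_s"].iloc[-1])


def test_thresholds_frozen_during_noisy_and_fish():
    """A deep dip must not inflate the threshold against a second fish."""
    re = 230.0 + RNG.normal(0, 0.002, size=1200)
    re[400:460] -= 1.0                      # first fish
    re[700:760] -= 0.3                      # second, shallower fish
    events = detect_events(make_stream(re), DetectorConfig())
    assert len(events) == 2


def test_online_equals_vectorized_all_modes():
    re = 230.0 + RNG.normal(0, 0.003, size=900)
    re[500:550] -= 0.4
    im = -0.005 + 1e-3 * (re - 230.0) + RNG.normal(0, 5e-6, size=900)
    stream = make_stream(re, im)
    for mode in MODES:
        cfg = DetectorConfig(mode=mode)
        ev_v = detect_events(stream, cfg, engine="vectorized")
        ev_o = detect_events(stream, cfg, engine="online")
        assert [(e.t_start, e.t_end, e.channel_evidence) for e in ev_v] == \
               [(e.t_start, e.t_end, e.channel_evidence) for e in ev_o]


def test_detection_is_deterministic():
    stream = make_stream(baseline_with_dip())
    cfg = DetectorConfig()
    a = detect_events(stream, cfg)
    b = detect_events(stream, cfg)
    assert [(e.t_start, e.t_end) for e in a] == [(e.t_start, e.t_end) for e in b]


def test_malformed_samples_are_skipped():
    re = baseline_with_dip()
    stream = make_stream(re)
    stream.loc[100, "resistance_ohm"] = np.nan
    events = detect_events(stream, DetectorConfig())
    assert len(events) == 1                 # dip still found


def test_empty_stream_gives_no_events():
    stream = make_stream(np.empty(0))
    assert detect_events(stream, DetectorConfig()) == []
    assert state_history(stream, DetectorConfig()).size == 0


def test_unknown_engine_raises():
    with pytest.raises(ValueError):
        detect_events(make_stream(np.zeros(5)), DetectorConfig(), engine="gpu")


def test_event_times_ordered():
    with pytest.raises(ValueError):
        DetectionEvent(2.0, 1.0, "re")


# ---------------------------------------------------------------------------
# stream I/O
# ---------------------------------------------------------------------------

def test_stream_roundtrip(tmp_path):
    stream = make_stream(baseline_with_dip(n_base=250))
    path = tmp_path / "s.csv"
    write_stream(stream, path)
    back = read_stream(path)
    pd.testing.assert_frame_equal(back, stream[back.columns])


def test_read_stream_missing_column_raises(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("timestamp_s,resistance_ohm\n0.0,1.0\n")
    with pytest.raises(ValueError):
        read_stream(path)


def test_iter_stream_skips_malformed_lines(tmp_path):
    stream = make_stream(np.full(5, 230.0))
    path = tmp_path / "s.csv"
    write_stream(stream, path)
    with open(path, "a") as fh:
        fh.write("0,50000,not-a-number,-0.005,99.0\n")
    samples = list(iter_stream(path))
    assert len(samples) == 5
    assert samples[0] == ImpedanceSample(t=0.0, re=230.0, im=-0.005)


def test_events_to_frame_columns():
    frame = events_to_frame([DetectionEvent(1.0, 2.0, "re")], "re", 3.0)
    assert list(frame.columns) == ["t_start", "t_end", "mode",
                                   "threshold_ratio", "channel_evidence"]
    assert len(frame) == 1


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=50),
       st.floats(0, 10), st.floats(0, 10))
def test_threshold_monotone_in_ratio(buf, r1, r2):
    lo, hi = sorted((r1, r2))
    assert detection_threshold(buf, hi) <= detection_threshold(buf, lo) + 1e-12


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
def test_threshold_never_above_median(buf):
    assert detection_threshold(buf, 1.0) <= np.median(buf) + 1e-12


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
def test_noise_amplitude_nonnegative(buf):
    assert noise_amplitude(buf) >= 0.0


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.booleans(), st.booleans())
def test_mode_algebra_property(cre, cim):
    assert combine_modes(cre, cim, "and") <= combine_modes(cre, cim, "re")
    assert combine_modes(cre, cim, "re") <= combine_modes(cre, cim, "or")
    assert combine_modes(cre, cim, "and") <= combine_modes(cre, cim, "im")
    assert combine_modes(cre, cim, "im") <= combine_modes(cre, cim, "or")
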