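"""Real-time fish detection from impedance streams.

A four-state finite-state machine watches a stream of (resistance, reactance)
samples and decides, sample by sample, whether a fish is present between the
electrodes:

* ``INIT`` (0): buffer filling or conditions unstable since start/reset.
* ``STABLE`` (1): no fish, stable baseline; detection thresholds track the
  buffer statistics every sample.
* ``NOISY`` (2): signal statistics exceed the stability criterion but no fish
  condition fired; the detection thresholds are frozen at the values of the
  last stable period so that excess noise cannot inflate them.
* ``FISH`` (3): the newest sample dropped below the detection threshold.

Freshwater fish conduct better than the surrounding water, so a fish shows up
as a *decay* of the measured values; all positive peaks are treated as noise.
The noise amplitude is the maximum positive deviation from the median of a
200-sample buffer, and a sample triggers a detection when it falls below

    median - threshold_ratio * 2 * max(noise_amplitude, noise_floor)

(the factor 2 turns the amplitude into a peak-to-peak level).  A threshold
ratio of 0.5 therefore fires on any drop below the temporal noise level.

The stability criterion bounds the buffer's total swing (max - min) and the
magnitude of its least-squares slope versus time.  Long pauses in the stream
trigger an internal reset back to ``INIT``.

Two execution paths produce identical results: an online :class:`FSMDetector`
consuming one sample at a time (mirroring live operation), and a vectorized
batch replay used for parameter sweeps, where the sliding-window statistics
are precomputed once per stream and reused across (mode, threshold) settings.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

MODES = ("re", "im", "or", "and")

#: CSV column order for stream files (times in seconds, impedances in ohm).
STREAM_COLUMNS = ("device_id", "frequency_hz", "resistance_ohm",
                  "reactance_ohm", "timestamp_s")


class State(IntEnum):
    INIT = 0
    STABLE = 1
    NOISY = 2
    FISH = 3


@dataclass(frozen=True)
class ImpedanceSample:
    """One timestamped impedance reading at a stated excitation frequency."""

    t: float                 # s, strictly increasing within a stream
    re: float                # ohm, resistance Re(Z)
    im: float                # ohm, reactance Im(Z)
    f: float = 50_000.0      # Hz
    device_id: str = "0"


@dataclass(frozen=True)
class DetectorConfig:
    """All numeric criteria of the detector.

    Defaults follow the reference operating point: a 200-sample buffer,
    100 mOhm / 100 uOhm maximum swing and 2.5 mOhm/s / 10 uOhm/s maximum
    slope for the resistance / reactance channels.  ``gap_reset_s`` defaults
    to five nominal sample intervals at 20 Hz.  The noise floors guard the
    degenerate zero-noise buffer (quantization scale).
    """

    buffer_len: int = 200
    swing_max_re: float = 0.100
    swing_max_im: float = 100e-6
    slope_max_re: float = 2.5e-3
    slope_max_im: float = 10e-6
    threshold_ratio: float = 3.0
    mode: str = "re"
    gap_reset_s: float = 0.25
    noise_floor_re: float = 0.010
    noise_floor_im: float = 10e-6

    def __post_init__(self) -> None:
        if self.buffer_len < 2:
            raise ValueError("buffer_len must be at least 2")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for name in ("swing_max_re", "swing_max_im", "slope_max_re",
                     "slope_max_im", "threshold_ratio", "noise_floor_re",
                     "noise_floor_im"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.gap_reset_s <= 0:
            raise ValueError("gap_reset_s must be positive")

    @property
    def uses_re(self) -> bool:
        return self.mode in ("re", "or", "and")

    @property
    def uses_im(self) -> bool:
        return self.mode in ("im", "or", "and")


@dataclass
class DetectionEvent:
    """One maximal run of FISH states."""

    t_start: float
    t_end: float
    channel_evidence: str  # "re", "im" or "re+im": which condition fired

    def __post_init__(self) -> None:
        if self.t_end < self.t_start:
            raise ValueError("t_end must be >= t_start")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def noise_amplitude(buffer_values: Sequence[float]) -> float:
    """Maximum positive deviation from the buffer median (never negative)."""
    v = np.asarray(buffer_values, dtype=float)
    if v.size == 0:
        raise ValueError("noise_amplitude requires a non-empty buffer")
    return float(max(0.0, v.max() - np.median(v)))


def detection_threshold(buffer_values: Sequence[float], threshold_ratio: float,
                        noise_floor: float = 0.0) -> float:
    """median - ratio * peak-to-peak noise (twice the noise amplitude)."""
    v = np.asarray(buffer_values, dtype=float)
    if v.size == 0:
        raise ValueError("detection_threshold requires a non-empty buffer")
    if threshold_ratio < 0:
        raise ValueError("threshold_ratio must be >= 0")
    amp = max(noise_amplitude(v), noise_floor)
    return float(np.median(v) - threshold_ratio * 2.0 * amp)


def stability_check(buffer: Sequence[tuple[float, float]], swing_max: float,
                    slope_max: float) -> bool:
    """Swing (max-min) and |least-squares slope| within their limits."""
    arr = np.asarray(buffer, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("stability_check requires at least two (t, value) samples")
    t, v = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("stability_check requires distinct timestamps")
    if np.ptp(v) > swing_max:
        return False
    tc = t - t.mean()
    slope = float(np.dot(tc, v - v.mean()) / np.dot(tc, tc))
    return abs(slope) <= slope_max


def combine_modes(cond_re: bool, cond_im: bool, mode: str) -> bool:
    """Fuse per-channel condition outcomes according to the operating mode."""
    if mode == "re":
        return cond_re
    if mode == "im":
        return cond_im
    if mode == "or":
        return cond_re or cond_im
    if mode == "and":
        return cond_re and cond_im
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


# ---------------------------------------------------------------------------
# online detector
# ---------------------------------------------------------------------------

class _Channel:
    """Rolling (t, value) buffer with the statistics the FSM needs."""

    __slots__ = ("t", "v", "maxlen")

    def __init__(self, maxlen: int) -> None:
        self.maxlen = maxlen
        self.t: deque[float] = deque(maxlen=maxlen)
        self.v: deque[float] = deque(maxlen=maxlen)

    def push(self, t: float, v: float) -> None:
        self.t.append(t)
        self.v.append(v)

    def clear(self) -> None:
        self.t.clear()
        self.v.clear()

    @property
    def full(self) -> bool:
        return len(self.v) == self.maxlen

    def threshold(self, ratio: float, floor: float) -> float:
        return detection_threshold(list(self.v), ratio, floor)

    def stable(self, swing_max: float, slope_max: float) -> bool:
        if len(self.v) < 2:
            return False
        return stability_check(list(zip(self.t, self.v)), swing_max, slope_max)


class FSMDetector:
    """Online four-state detector; feed samples one at a time via step()."""

    def __init__(self, config: DetectorConfig) -> None:
        self.config = config
        self.reset()

    def reset(self) -> None:
        """Internal reset back to the initial state (e.g. after a pause)."""
        self.state = State.INIT
        self._re = _Channel(self.config.buffer_len)
        self._im = _Channel(self.config.buffer_len)
        self.frozen_threshold: tuple[float, float] | None = None
        self._last_t: float | None = None
        self._open_event: DetectionEvent | None = None
        self.events: list[DetectionEvent] = []
        self.transitions: list[tuple[float, State, State]] = []

    # -- helpers ---------------------------------------------------------
    def _thresholds(self) -> tuple[float, float]:
        cfg = self.config
        thr_re = self._re.threshold(cfg.threshold_ratio, cfg.noise_floor_re)
        thr_im = self._im.threshold(cfg.threshold_ratio, cfg.noise_floor_im)
        return thr_re, thr_im

    def _condition(self, sample: ImpedanceSample,
                   thresholds: tuple[float, float]) -> tuple[bool, bool, bool]:
        cond_re = sample.re < thresholds[0]
        cond_im = sample.im < thresholds[1]
        return cond_re, cond_im, combine_modes(cond_re, cond_im, self.config.mode)

    def _stable(self) -> bool:
        """Mode-relevant stability; in fused modes both channels must be stable."""
        cfg = self.config
        ok = True
        if cfg.uses_re:
            ok = ok and self._re.stable(cfg.swing_max_re, cfg.slope_max_re)
        if cfg.uses_im:
            ok = ok and self._im.stable(cfg.swing_max_im, cfg.slope_max_im)
        return ok

    def _go(self, t: float, new_state: State) -> None:
        if new_state is not self.state:
            self.transitions.append((t, self.state, new_state))
            self.state = new_state

    def _open(self, t: float, cond_re: bool, cond_im: bool) -> None:
        ev = "re+im" if (cond_re and cond_im) else ("re" if cond_re else "im")
        self._open_event = DetectionEvent(t, t, ev)

    def _close(self, t: float) -> None:
        assert self._open_event is not None
        self._open_event.t_end = t
        self.events.append(self._open_event)
        self._open_event = None

    # -- the transition function ----------------------------------------
    def step(self, sample: ImpedanceSample) -> State:
        cfg = self.config
        if not all(math.isfinite(x) for x in (sample.t, sample.re, sample.im)):
            logger.warning("skipping malformed sample at t=%r", sample.t)
            return self.state
        if self._last_t is not None and (
                sample.t - self._last_t > cfg.gap_reset_s or sample.t < self._last_t):
            if self._open_event is not None:
                self._close(self._last_t)
            self._go(sample.t, State.INIT)
            self._re.clear()
            self._im.clear()
            self.frozen_threshold = None

        state = self.state
        if state is State.STABLE:
            thresholds = self._thresholds()
        elif state in (State.NOISY, State.FISH):
            thresholds = self.frozen_threshold
        else:
            thresholds = None

        self._re.push(sample.t, sample.re)
        self._im.push(sample.t, sample.im)

        if state is State.INIT:
            if self._re.full and self._stable():
                self._go(sample.t, State.STABLE)
        elif state is State.STABLE:
            cond_re, cond_im, fire = self._condition(sample, thresholds)
            if fire:
                self.frozen_threshold = thresholds
                self._open(sample.t, cond_re, cond_im)
                self._go(sample.t, State.FISH)
            elif not self._stable():
                self.frozen_threshold = thresholds
                self._go(sample.t, State.NOISY)
        elif state is State.NOISY:
            cond_re, cond_im, fire = self._condition(sample, thresholds)
            if fire:
                self._open(sample.t, cond_re, cond_im)
                self._go(sample.t, State.FISH)
            elif self._stable():
                self.frozen_threshold = None
                self._go(sample.t, State.STABLE)
        else:  # FISH: hold while the frozen-threshold condition persists
            _, _, fire = self._condition(sample, thresholds)
            if not fire:
                self._close(sample.t)
                self._go(sample.t, State.NOISY)

        self._last_t = sample.t
        return self.state

    def finish(self) -> list[DetectionEvent]:
        """Close a trailing open event (stream ended while in FISH)."""
        if self._open_event is not None and self._last_t is not None:
            self._close(self._last_t)
        return self.events


# ---------------------------------------------------------------------------
# vectorized batch replay
# ---------------------------------------------------------------------------

@dataclass
class StreamStats:
    """Per-stream sliding-window statistics shared across detector settings.

    Arrays are indexed by sample; ``med_prev``/``amp_prev`` describe the
    window of the ``buffer_len`` samples *preceding* each sample (the buffer
    the detector holds when the sample arrives; NaN while the buffer is not
    yet full), and ``stable_incl`` describes the window *including* it.
    ``segment`` labels gap-free runs (a long pause starts a new segment and
    resets the windows, mirroring the online detector's internal reset).
    """

    t: np.ndarray
    values: dict[str, np.ndarray]
    med_prev: dict[str, np.ndarray]
    amp_prev: dict[str, np.ndarray]
    stable_incl: dict[str, np.ndarray]
    buffer_full_incl: np.ndarray
    config: DetectorConfig


def _window_stats(t: np.ndarray, v: np.ndarray, L: int, swing_max: float,
                  slope_max: float):
    """Full-window median, amplitude and stability flag for one segment."""
    n = v.size
    med = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    stable = np.zeros(n, dtype=bool)
    if n < L:
        return med, amp, stable, med.copy(), amp.copy()
    W = sliding_window_view(v, L)          # row r = samples [r, r+L)
    TW = sliding_window_view(t, L)
    m = np.median(W, axis=1)
    a = np.maximum(0.0, W.max(axis=1) - m)
    swing = W.max(axis=1) - W.min(axis=1)
    tm = TW.mean(axis=1)
    vm = W.mean(axis=1)
    tc = TW - tm[:, None]
    denom = np.einsum("ij,ij->i", tc, tc)
    slope = np.einsum("ij,ij->i", tc, W - vm[:, None]) / denom
    ok = (swing <= swing_max) & (np.abs(slope) <= slope_max)
    # window including sample k is row k-L+1; window preceding it is row k-L
    med_incl = np.full(n, np.nan)
    amp_incl = np.full(n, np.nan)
    med_incl[L - 1:] = m
    amp_incl[L - 1:] = a
    stable[L - 1:] = ok
    med[L:] = m[:-1]
    amp[L:] = a[:-1]
    return med, amp, stable, med_incl, amp_incl


def precompute_stats(t: np.ndarray, re: np.ndarray, im: np.ndarray,
                     config: DetectorConfig) -> list[StreamStats]:
    """Split a stream at gaps and compute per-segment window statistics.

    The statistics depend only on ``buffer_len`` and the stability limits,
    so one precomputation serves every (mode, threshold_ratio) replay.
    """
    t = np.asarray(t, dtype=float)
    re = np.asarray(re, dtype=float)
    im = np.asarray(im, dtype=float)
    good = np.isfinite(t) & np.isfinite(re) & np.isfinite(im)
    if not good.all():
        logger.warning("dropping %d malformed samples", int((~good).sum()))
        t, re, im = t[good], re[good], im[good]
    if t.size == 0:
        return []
    dt = np.diff(t)
    breaks = np.flatnonzero((dt > config.gap_reset_s) | (dt < 0)) + 1
    segments = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, t.size]):
        ts, rs, ims = t[lo:hi], re[lo:hi], im[lo:hi]
        L = config.buffer_len
        mr, ar, sr, _, _ = _window_stats(ts, rs, L, config.swing_max_re,
                                         config.slope_max_re)
        mi, ai, si, _, _ = _window_stats(ts, ims, L, config.swing_max_im,
                                         config.slope_max_im)
        full = np.arange(ts.size) >= L - 1
        segments.append(StreamStats(
            t=ts, values={"re": rs, "im": ims},
            med_prev={"re": mr, "im": mi}, amp_prev={"re": ar, "im": ai},
            stable_incl={"re": sr, "im": si}, buffer_full_incl=full,
            config=config))
    return segments


def replay(segments: list[StreamStats], mode: str, threshold_ratio: float,
           noise_floor_re: float | None = None,
           noise_floor_im: float | None = None,
           collect_states: bool = False):
    """Run the FSM over precomputed statistics.

    Returns (events, states) where states is a per-sample array of State
    values (concatenated over segments) when ``collect_states`` is true.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if threshold_ratio < 0:
        raise ValueError("threshold_ratio must be >= 0")
    events: list[DetectionEvent] = []
    all_states: list[np.ndarray] = []
    use_re = mode in ("re", "or", "and")
    use_im = mode in ("im", "or", "and")

    for seg in segments:
        cfg = seg.config
        fre = noise_floor_re if noise_floor_re is not None else cfg.noise_floor_re
        fim = noise_floor_im if noise_floor_im is not None else cfg.noise_floor_im
        ratio2 = 2.0 * threshold_ratio
        t = seg.t
        vre, vim = seg.values["re"], seg.values["im"]
        mre, mim = seg.med_prev["re"], seg.med_prev["im"]
        are, aim = seg.amp_prev["re"], seg.amp_prev["im"]
        sre, sim = seg.stable_incl["re"], seg.stable_incl["im"]
        full = seg.buffer_full_incl
        n = t.size
        states = np.empty(n, dtype=np.int8) if collect_states else None

        state = State.INIT
        frozen_re = frozen_im = 0.0
        open_t = -1.0
        open_ev = ""
        for k in range(n):
            if state == State.INIT:
                if full[k] and (not use_re or sre[k]) and (not use_im or sim[k]):
                    state = State.STABLE
            elif state == State.STABLE:
                thr_re = mre[k] - ratio2 * max(are[k], fre)
                thr_im = mim[k] - ratio2 * max(aim[k], fim)
                cre = vre[k] < thr_re
                cim = vim[k] < thr_im
                fire = ((cre or cim) if mode == "or" else
                        (cre and cim) if mode == "and" else
                        cre if mode == "re" else cim)
                if fire:
                    frozen_re, frozen_im = thr_re, thr_im
                    open_t = t[k]
                    open_ev = "re+im" if (cre and cim) else ("re" if cre else "im")
                    state = State.FISH
                elif not ((not use_re or sre[k]) and (not use_im or sim[k])):
                    frozen_re, frozen_im = thr_re, thr_im
                    state = State.NOISY
            elif state == State.NOISY:
                cre = vre[k] < frozen_re
                cim = vim[k] < frozen_im
                fire = ((cre or cim) if mode == "or" else
                        (cre and cim) if mode == "and" else
                        cre if mode == "re" else cim)
                if fire:
                    open_t = t[k]
                    open_ev = "re+im" if (cre and cim) else ("re" if cre else "im")
                    state = State.FISH
                elif (not use_re or sre[k]) and (not use_im or sim[k]):
                    state = State.STABLE
            else:  # FISH
                cre = vre[k] < frozen_re
                cim = vim[k] < frozen_im
                fire = ((cre or cim) if mode == "or" else
                        (cre and cim) if mode == "and" else
                        cre if mode == "re" else cim)
                if not fire:
                    events.append(DetectionEvent(open_t, t[k], open_ev))
                    state = State.NOISY
            if collect_states:
                states[k] = int(state)
        if state == State.FISH:
            events.append(DetectionEvent(open_t, t[n - 1], open_ev))
        if collect_states:
            all_states.append(states)
    states_out = np.concatenate(all_states) if collect_states and all_states else None
    return events, states_out


# ---------------------------------------------------------------------------
# batch drivers and I/O
# ---------------------------------------------------------------------------

def detect_events(stream, config: DetectorConfig,
                  engine: str = "vectorized") -> list[DetectionEvent]:
    """One event per maximal run of FISH states over a timestamp-sorted stream.

    ``stream`` may be a DataFrame with the standard columns or an iterable of
    :class:`ImpedanceSample`.  The default vectorized engine and the online
    engine implement the identical transition function.
    """
    t, re, im = _stream_arrays(stream)
    if t.size == 0:
        return []
    if engine == "vectorized":
        segs = precompute_stats(t, re, im, config)
        events, _ = replay(segs, config.mode, config.threshold_ratio)
        return events
    if engine == "online":
        det = FSMDetector(config)
        for i in range(t.size):
            det.step(ImpedanceSample(t=t[i], re=re[i], im=im[i]))
        return det.finish()
    raise ValueError(f"unknown engine {engine!r}")


def state_history(stream, config: DetectorConfig) -> np.ndarray:
    """Per-sample FSM state array (malformed samples excluded)."""
    t, re, im = _stream_arrays(stream)
    if t.size == 0:
        return np.empty(0, dtype=np.int8)
    segs = precompute_stats(t, re, im, config)
    _, states = replay(segs, config.mode, config.threshold_ratio,
                       collect_states=True)
    return states if states is not None else np.empty(0, dtype=np.int8)


def _stream_arrays(stream) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(stream, pd.DataFrame):
        return (stream["timestamp_s"].to_numpy(float),
                stream["resistance_ohm"].to_numpy(float),
                stream["reactance_ohm"].to_numpy(float))
    samples = list(stream)
    t = np.array([s.t for s in samples], dtype=float)
    re = np.array([s.re for s in samples], dtype=float)
    im = np.array([s.im for s in samples], dtype=float)
    return t, re, im


def read_stream(path) -> pd.DataFrame:
    """Read a delimited stream file (header row required)."""
    df = pd.read_csv(path, dtype={"device_id": str})
    missing = set(STREAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stream file {path} lacks columns {sorted(missing)}")
    return df[list(STREAM_COLUMNS)]


def write_stream(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(STREAM_COLUMNS))


def iter_stream(path) -> Iterator[ImpedanceSample]:
    """Line-streaming reader for live (append-only) operation."""
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        col = {name: header.index(name) for name in STREAM_COLUMNS}
        for line in fh:
            parts = line.strip().split(",")
            if len(parts) < len(header):
                continue
            try:
                yield ImpedanceSample(
                    t=float(parts[col["timestamp_s"]]),
                    re=float(parts[col["resistance_ohm"]]),
                    im=float(parts[col["reactance_ohm"]]),
                    f=float(parts[col["frequency_hz"]]),
                    device_id=parts[col["device_id"]])
            except ValueError:
                logger.warning("skipping malformed stream line: %r", line.strip())


def events_to_frame(events: Iterable[DetectionEvent], mode: str,
                    threshold_ratio: float) -> pd.DataFrame:
    rows = [(e.t_start, e.t_end, mode, threshold_ratio, e.channel_evidence)
            for e in events]
    return pd.DataFrame(rows, columns=["t_start", "t_end", "mode",
                                       "threshold_ratio", "channel_evidence"])
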