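"""Detector scoring against ground-truth track labels.

A pass-labelled track counts as a true positive when the detector's state
history over the track's stream contains at least one fish-detected state
(multi-event passes still yield one TP), and a false negative otherwise.
A dwell-labelled track is a true negative when no fish-detected state occurs,
a false positive otherwise.  Sensitivity and specificity follow the usual
definitions TP/(TP+FN) and TN/(TN+FP); undefined ratios (zero denominator)
are reported as missing, never as 0 or 1.

Sweeps replay the identical set of streams for every (mode, threshold ratio)
cell; the sliding-window statistics are precomputed once per stream and
shared across cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detector import MODES, DetectorConfig, precompute_stats, replay
from .field import TankGeometry
from .synth import Benchmark, BenchmarkItem
from .tracks import Track, min_electrode_distance

OUTCOMES = ("TP", "FN", "TN", "FP")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fn: int = 0
    tn: int = 0
    fp: int = 0

    def add(self, outcome: str) -> None:
        if outcome == "TP":
            self.tp += 1
        elif outcome == "FN":
            self.fn += 1
        elif outcome == "TN":
            self.tn += 1
        elif outcome == "FP":
            self.fp += 1
        else:
            raise ValueError(f"unknown outcome {outcome!r}")


def sensitivity(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positive-class tracks were judged."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def specificity(counts: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when no negative-class tracks were judged."""
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else None


def judge_track(stream, label: str, config: DetectorConfig) -> str | None:
    """Outcome of one labelled stream under one detector setting."""
    from .detector import detect_events
    if label not in ("pass", "dwell"):
        warnings.warn(f"track label {label!r} excluded from scoring",
                      stacklevel=2)
        return None
    detected = len(detect_events(stream, config)) > 0
    if label == "pass":
        return "TP" if detected else "FN"
    return "TN" if detected is False else "FP"


def _item_stats(items: Sequence[BenchmarkItem], config: DetectorConfig):
    out = []
    for item in items:
        t = item.stream["timestamp_s"].to_numpy(float)
        re = item.stream["resistance_ohm"].to_numpy(float)
        im = item.stream["reactance_ohm"].to_numpy(float)
        out.append(precompute_stats(t, re, im, config))
    return out


def sweep(benchmark: Benchmark | Sequence[BenchmarkItem],
          modes: Sequence[str] = MODES,
          ratios: Sequence[float] = (0.5, 1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5, 5.5, 6),
          config: DetectorConfig | None = None,
          return_outcomes: bool = False):
    """Score every (mode, threshold ratio) cell on identical streams.

    Returns a DataFrame with columns mode, threshold_ratio, TP, FN, TN, FP,
    sensitivity, specificity (the last two as NaN when undefined).  With
    ``return_outcomes`` also returns {(mode, ratio): [outcome per item]}.
    """
    items = list(benchmark)
    if not items:
        raise ValueError("sweep requires a non-empty benchmark")
    for m in modes:
        if m not in MODES:
            raise ValueError(f"unknown mode {m!r}")
    if len(list(ratios)) == 0:
        raise ValueError("sweep requires at least one threshold ratio")
    cfg = config or DetectorConfig()
    stats = _item_stats(items, cfg)
    rows = []
    outcomes: dict[tuple[str, float], list[str | None]] = {}
    for mode in modes:
        for ratio in ratios:
            counts = ConfusionCounts()
            cell = []
            for item, segs in zip(items, stats):
                if item.label not in ("pass", "dwell"):
                    cell.append(None)
                    continue
                events, _ = replay(segs, mode, ratio)
                detected = len(events) > 0
                out = ("TP" if detected else "FN") if item.label == "pass" \
                    else ("FP" if detected else "TN")
                counts.add(out)
                cell.append(out)
            outcomes[(mode, float(ratio))] = cell
            se = sensitivity(counts)
            sp = specificity(counts)
            rows.append((mode, float(ratio), counts.tp, counts.fn, counts.tn,
                         counts.fp,
                         np.nan if se is None else se,
                         np.nan if sp is None else sp))
    table = pd.DataFrame(rows, columns=["mode", "threshold_ratio", "TP", "FN",
                                        "TN", "FP", "sensitivity",
                                        "specificity"])
    return (table, outcomes) if return_outcomes else table


def distance_stratified(items: Sequence[BenchmarkItem],
                        outcomes: Sequence[str | None],
                        geometry: TankGeometry) -> pd.DataFrame:
    """Minimum electrode distance summarized per outcome class.

    One row per outcome class with n, median and quartiles (meters); classes
    with no members are flagged empty (n = 0, NaN statistics).
    """
    dists: dict[str, list[float]] = {k: [] for k in OUTCOMES}
    for item, out in zip(items, outcomes):
        if out is None:
            continue
        dists[out].append(min_electrode_distance(item.track, geometry))
    rows = []
    for key in OUTCOMES:
        d = np.asarray(dists[key])
        if d.size:
            rows.append((key, d.size, float(np.median(d)),
                         float(np.percentile(d, 25)),
                         float(np.percentile(d, 75))))
        else:
            rows.append((key, 0, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["outcome", "n", "median_m", "q1_m",
                                       "q3_m"])


def joined_positions(item: BenchmarkItem) -> pd.DataFrame:
    """Track positions joined with the stream's resistance by timestamp.

    The stream leads with a fish-free warm-up; track sample i corresponds to
    stream time warmup_s + track.t[i].
    """
    t_stream = item.stream["timestamp_s"].to_numpy(float)
    re = item.stream["resistance_ohm"].to_numpy(float)
    t_track = item.track.t + item.warmup_s
    idx = np.searchsorted(t_stream, t_track)
    idx = np.clip(idx, 0, t_stream.size - 1)
    return pd.DataFrame({
        "t_s": item.track.t,
        "x_m": item.track.xyz[:, 0],
        "y_m": item.track.xyz[:, 1],
        "z_m": item.track.xyz[:, 2],
        "resistance_ohm": re[idx],
    })


def spatial_median_map(items: Sequence[BenchmarkItem], geometry: TankGeometry,
                       bin_size: float = 0.010):
    """Median joined resistance per xy bin (half-open bin edges).

    Returns (medians, counts, x_edges, y_edges); bins the fish never visited
    hold NaN.  A point at exactly one bin width falls into the second bin.
    """
    nx = int(np.ceil(geometry.length_x / bin_size))
    ny = int(np.ceil(geometry.width_y / bin_size))
    values: dict[tuple[int, int], list[float]] = {}
    for item in items:
        j = joined_positions(item)
        ix = np.floor(j["x_m"].to_numpy() / bin_size).astype(int)
        iy = np.floor(j["y_m"].to_numpy() / bin_size).astype(int)
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        for a, b, v in zip(ix[ok], iy[ok], j["resistance_ohm"].to_numpy()[ok]):
            values.setdefault((a, b), []).append(v)
    med = np.full((nx, ny), np.nan)
    cnt = np.zeros((nx, ny), dtype=int)
    for (a, b), vs in values.items():
        med[a, b] = np.median(vs)
        cnt[a, b] = len(vs)
    x_edges = np.arange(nx + 1) * bin_size
    y_edges = np.arange(ny + 1) * bin_size
    return med, cnt, x_edges, y_edges


def map_to_long_frame(med: np.ndarray, cnt: np.ndarray, x_edges, y_edges
                      ) -> pd.DataFrame:
    """Long-format (x_bin_mm, y_bin_mm, median_ohm, n) for CSV export."""
    rows = []
    for a in range(med.shape[0]):
        for b in range(med.shape[1]):
            if cnt[a, b]:
                rows.append((x_edges[a] * 1e3, y_edges[b] * 1e3,
                             med[a, b], int(cnt[a, b])))
    return pd.DataFrame(rows, columns=["x_bin_mm", "y_bin_mm", "median_ohm", "n"])
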