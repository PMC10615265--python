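"""Seeded synthetic trajectories and impedance streams.

The generator emulates the tank experiment so the detector and the evaluation
pipeline can be exercised without recorded data: smooth spline trajectories of
the two ground-truth classes (passes between the side walls, dwells near one
side wall), and impedance streams built from the field model's fish-induced
resistance change plus a noise model with slow sinusoidal baseline drift,
Gaussian sample noise and sparse positive spikes (positive, because upward
peaks are by construction noise, never fish).

Physics enters through a precomputed surrogate: the fish-free field is solved
once on a coarse grid and the depolarization-corrected linearized resistance
change for the ellipsoidal fish is tabulated over fish-center positions, then
interpolated trilinearly along the trajectory.  A slow mode re-solves the
full field per sample for small cross-check problems.

Everything is reproducible: the scenario seed expands deterministically into
per-item seeds recorded in the benchmark manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, RegularGridInterpolator
from scipy.ndimage import correlate

from . import field as fieldmod
from .detector import STREAM_COLUMNS
from .field import (FishEllipsoid, TankGeometry, build_grid, delta_R_linearized,
                    embed_fish, sensitivity_map, solve_field)
from .tracks import Track, classify_track


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances of the resistance / reactance channels.

    Defaults describe the nominal scenario: sample noise well inside the
    detector's stability envelope (the expected range of 200 Gaussian draws
    is about 5.5 sigma, which must stay below the 100 mOhm swing limit for a
    fish-free stream to register as stable), a slow conductivity drift whose
    maximum slope 2*pi*A/T stays below the 2.5 mOhm/s limit, and occasional
    positive spikes emulating electromagnetic interference.
    """

    gaussian_sd: float = 0.005        # ohm
    spike_rate: float = 0.05          # 1/s
    spike_amplitude: float = 0.15     # ohm, strictly positive (upward)
    drift_amplitude: float = 0.2      # ohm
    drift_period: float = 600.0       # s
    gaussian_sd_im: float = 5e-6      # ohm
    baseline_im: float = -0.005       # ohm, Im(Z) of water is negative

    def __post_init__(self) -> None:
        for name in ("gaussian_sd", "spike_rate", "spike_amplitude",
                     "drift_amplitude", "gaussian_sd_im"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be positive")

    @property
    def max_drift_slope(self) -> float:
        """Largest |d drift/dt| of the sinusoidal baseline (ohm/s)."""
        return 2.0 * np.pi * self.drift_amplitude / self.drift_period


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic benchmark."""

    n_pass: int = 40
    n_dwell: int = 40
    sample_rate: float = 20.0               # Hz
    speed_range: tuple[float, float] = (0.05, 0.15)   # m/s
    depth_range: tuple[float, float] = (0.05, 0.15)   # m
    electrode_width: float = 0.020          # m
    sigma_water: float = 0.05               # S/m
    reactance_scale: float = 1e-3
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    surrogate_h: float = 0.010              # m, surrogate solver grid
    warmup_s: float = 20.0                  # fish-free lead-in per stream
    wall_margin: float = 0.020              # m, waypoint clearance from walls

    def __post_init__(self) -> None:
        if self.n_pass < 0 or self.n_dwell < 0:
            raise ValueError("track counts must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def geometry(self) -> TankGeometry:
        return TankGeometry(electrode_width=self.electrode_width)


class DeltaRMap:
    """Tabulated fish-induced resistance change versus fish-center position.

    Built from one fish-free solve: the depolarization-corrected linearized
    voxel contributions are correlated with the ellipsoid's fractional-
    occupancy footprint (long axis along +x, the dominant pass direction) and
    interpolated trilinearly.  Values are clipped to <= 0: a conductive fish
    can only lower the measured resistance.
    """

    def __init__(self, geometry: TankGeometry, sigma_water: float,
                 h: float = 0.010, fish: FishEllipsoid | None = None,
                 subsamples: int = 4) -> None:
        self.geometry = geometry
        self.sigma_water = float(sigma_water)
        self.fish = fish or FishEllipsoid(center=(0.0, 0.0, 0.0))
        grid = build_grid(geometry, h, sigma_water)
        sol = solve_field(grid)
        self.r_baseline = sol.resistance
        sens = sensitivity_map(sol)

        # per-voxel corrected integrand (heading +x): -S * gfac * dsig/sw^2
        dsig = self.fish.sigma_fish - sigma_water
        L = fieldmod.depolarization_factors(self.fish.semi_axes)
        frame = self.fish.frame()
        e = sens.j_hat @ frame.T
        gfac = np.sum(e ** 2 / (1.0 + L[None, None, None, :] * dsig / sigma_water),
                      axis=-1)
        W = -sens.S * gfac * dsig / sigma_water ** 2

        kernel = _ellipsoid_kernel(self.fish.semi_axes, h, subsamples)
        dr = correlate(W, kernel, mode="constant", cval=0.0) * h ** 3
        self._dr = np.minimum(dr, 0.0)
        axes = [grid.axis_centers(k) for k in range(3)]
        self._interp = RegularGridInterpolator(
            axes, self._dr, bounds_error=False, fill_value=None)

    def delta_r(self, xyz: np.ndarray) -> np.ndarray:
        """Resistance change (ohm, <= 0) at fish-center position(s)."""
        arr = np.atleast_2d(np.asarray(xyz, dtype=float))
        return np.minimum(self._interp(arr), 0.0)


def _ellipsoid_kernel(semi_axes, h: float, subsamples: int) -> np.ndarray:
    """Fractional-occupancy footprint of an axis-aligned ellipsoid.

    Each kernel voxel carries the fraction of its volume inside the
    ellipsoid (estimated on a subsample lattice), so the kernel integrates to
    the ellipsoid volume even on grids coarse relative to the minor axis.
    """
    a, b, c = semi_axes
    half = [int(np.ceil(s / h)) for s in (a, b, c)]
    shape = [2 * m + 1 for m in half]
    sub = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    kern = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                dx = (i - half[0] + sub[:, None, None]) * h
                dy = (j - half[1] + sub[None, :, None]) * h
                dz = (k - half[2] + sub[None, None, :]) * h
                inside = ((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2) <= 1.0
                kern[i, j, k] = inside.mean()
    return kern


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def _thigmotactic_y(rng: np.random.Generator, size: int, geometry: TankGeometry,
                    margin: float) -> np.ndarray:
    """Lateral waypoint positions with wall preference (arcsine law).

    Small fish in open tanks show strong thigmotaxis (wall following), so
    crossing positions concentrate near the long walls - which also carry
    the electrodes.  Beta(1/2, 1/2) over the admissible span captures that
    boundary-affine behavior.
    """
    span = geometry.width_y - 2 * margin
    return margin + span * rng.beta(0.5, 0.5, size=size)


def _spline_track(waypoints: np.ndarray, duration: float, rate: float,
                  geometry: TankGeometry) -> Track:
    """Cubic spline through waypoints, sampled uniformly in time."""
    n = waypoints.shape[0]
    chord = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(waypoints, axis=0), axis=1))]
    if chord[-1] == 0:
        chord = np.arange(n, dtype=float)  # stationary: parametrize by index
    u = chord / chord[-1]
    u = np.maximum.accumulate(u + np.arange(n) * 1e-12)  # strictly increasing
    spl = CubicSpline(u, waypoints, axis=0, bc_type="natural")
    t = np.arange(int(round(duration * rate)) + 1) / rate
    pos = spl(t / duration)
    eps = 2e-3
    hi = np.array([geometry.length_x, geometry.width_y, geometry.water_depth_z])
    pos = np.clip(pos, eps, hi - eps)
    return Track(t, pos)


def generate_pass_track(config: ScenarioConfig, rng: np.random.Generator,
                        geometry: TankGeometry | None = None) -> Track:
    """A smooth crossing from one side wall to the opposite one.

    Starts and ends within 50 mm of the side walls (x = 0 and x = length_x),
    so ``classify_track`` labels it a pass by construction.
    """
    geo = geometry or config.geometry()
    m = config.wall_margin
    n_int = int(rng.integers(2, 5))
    xs = np.r_[rng.uniform(0.010, 0.040),
               np.sort(rng.uniform(0.07, geo.length_x - 0.07, n_int)),
               geo.length_x - rng.uniform(0.010, 0.040)]
    if rng.random() < 0.5:
        xs = xs[::-1]
    n = xs.size
    ys = _thigmotactic_y(rng, n, geo, m)
    zs = rng.uniform(*config.depth_range, size=n)
    wp = np.column_stack([xs, ys, zs])
    speed = rng.uniform(*config.speed_range)
    length = np.sum(np.linalg.norm(np.diff(wp, axis=0), axis=1))
    duration = max(length / speed, 2.0)
    return _spline_track(wp, duration, config.sample_rate, geo)


def generate_dwell_track(config: ScenarioConfig, rng: np.random.Generator,
                         geometry: TankGeometry | None = None) -> Track:
    """A trajectory confined within 50 mm of one side wall for >= 10 s."""
    geo = geometry or config.geometry()
    duration = float(rng.uniform(12.0, 30.0))
    n_wp = max(3, int(duration / 3.0))
    xs = rng.uniform(0.005, 0.045, size=n_wp)
    if rng.random() < 0.5:
        xs = geo.length_x - xs
    ys = rng.uniform(config.wall_margin, geo.width_y - config.wall_margin,
                     size=n_wp)
    zs = rng.uniform(*config.depth_range, size=n_wp)
    wp = np.column_stack([xs, ys, zs])
    track = _spline_track(wp, duration, config.sample_rate, geo)
    # constructive guarantee: never leave the 50 mm side-wall zone
    x = track.xyz[:, 0]
    if xs[0] < geo.length_x / 2:
        track.xyz[:, 0] = np.clip(x, 0.002, 0.0495)
    else:
        track.xyz[:, 0] = np.clip(x, geo.length_x - 0.0495, geo.length_x - 0.002)
    return track


# ---------------------------------------------------------------------------
# stream rendering
# ---------------------------------------------------------------------------

def render_impedance(track: Track, surrogate: DeltaRMap, noise: NoiseModel,
                     rng: np.random.Generator, sample_rate: float = 20.0,
                     reactance_scale: float = 1e-3, warmup_s: float = 20.0,
                     full_solve: bool = False, device_id: str = "0",
                     frequency_hz: float = 50_000.0) -> pd.DataFrame:
    """Impedance stream for one track.

    re(t) = R_baseline + dR(position) + drift + gaussian + positive spikes;
    im(t) = baseline_im + reactance_scale * dR + scaled noise (fish decays
    are negative-going on both channels).  The stream starts with a fish-free
    warm-up of ``warmup_s`` seconds so the detector can establish a baseline,
    mirroring the ambient history of a continuous recording.
    """
    if len(track):
        hi = np.array([surrogate.geometry.length_x, surrogate.geometry.width_y,
                       surrogate.geometry.water_depth_z])
        if (track.xyz < -0.005).any() or (track.xyz > hi + 0.005).any():
            raise ValueError("track leaves the surrogate's tank volume")
    n_warm = int(round(warmup_s * sample_rate))
    n_track = len(track)
    t = np.arange(n_warm + n_track) / sample_rate
    dr = np.zeros(t.size)
    if n_track:
        if full_solve:
            dr[n_warm:] = _full_solve_dr(track, surrogate)
        else:
            dr[n_warm:] = surrogate.delta_r(track.xyz)

    phase = rng.uniform(0, 2 * np.pi)
    drift = noise.drift_amplitude * np.sin(2 * np.pi * t / noise.drift_period + phase)
    gauss = rng.normal(0.0, noise.gaussian_sd, size=t.size)
    spikes = np.zeros(t.size)
    if noise.spike_rate > 0:
        k = rng.binomial(1, min(1.0, noise.spike_rate / sample_rate), size=t.size)
        spikes = k * noise.spike_amplitude
    re = surrogate.r_baseline + dr + drift + gauss + spikes
    gauss_im = rng.normal(0.0, noise.gaussian_sd_im, size=t.size)
    im = (noise.baseline_im
          + reactance_scale * (dr + drift + spikes)
          + gauss_im)
    return pd.DataFrame({
        "device_id": device_id,
        "frequency_hz": frequency_hz,
        "resistance_ohm": re,
        "reactance_ohm": im,
        "timestamp_s": t,
    })[list(STREAM_COLUMNS)]


def _full_solve_dr(track: Track, surrogate: DeltaRMap) -> np.ndarray:
    """Per-sample full field solves (slow; for small cross-checks only)."""
    from .tracks import headings as _headings
    geo = surrogate.geometry
    grid = build_grid(geo, 0.010, surrogate.sigma_water)
    hd = _headings(Track(track.t, track.xyz))
    out = np.empty(len(track))
    for i in range(len(track)):
        fish = replace(surrogate.fish, center=tuple(track.xyz[i]),
                       heading=tuple(hd[i]))
        out[i] = solve_field(embed_fish(grid, fish)).resistance - surrogate.r_baseline
    return out


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkItem:
    item_id: str
    label: str
    seed: int
    track: Track
    stream: pd.DataFrame
    warmup_s: float


@dataclass
class Benchmark:
    config: ScenarioConfig
    geometry: TankGeometry
    surrogate: DeltaRMap
    items: list[BenchmarkItem]

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)


def item_seed(master_seed: int, index: int) -> int:
    """Deterministic per-item seed (recorded in the manifest)."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               & 0x7FFFFFFF)


def _make_item(config: ScenarioConfig, geometry: TankGeometry,
               surrogate: DeltaRMap, label: str, index: int) -> BenchmarkItem:
    seed = item_seed(config.seed, index)
    rng = np.random.default_rng(seed)
    gen = generate_pass_track if label == "pass" else generate_dwell_track
    track = gen(config, rng, geometry)
    stream = render_impedance(track, surrogate, config.noise, rng,
                              sample_rate=config.sample_rate,
                              reactance_scale=config.reactance_scale,
                              warmup_s=config.warmup_s)
    return BenchmarkItem(item_id=f"{label}_{index:03d}", label=label,
                         seed=seed, track=track, stream=stream,
                         warmup_s=config.warmup_s)


def make_benchmark(config: ScenarioConfig,
                   out_dir: str | Path | None = None,
                   force: bool = False) -> Benchmark:
    """Generate the labeled dataset (streams + tracks + manifest).

    With ``out_dir`` the items are also written to disk: a manifest CSV
    (id, label, seed, stream_path, track_path) plus one stream and one track
    CSV per item, byte-identical on regeneration with the same config.
    """
    geometry = config.geometry()
    surrogate = DeltaRMap(geometry, config.sigma_water, h=config.surrogate_h)
    items = []
    idx = 0
    for _ in range(config.n_pass):
        items.append(_make_item(config, geometry, surrogate, "pass", idx))
        idx += 1
    for _ in range(config.n_dwell):
        items.append(_make_item(config, geometry, surrogate, "dwell", idx))
        idx += 1
    bench = Benchmark(config, geometry, surrogate, items)
    if out_dir is not None:
        write_benchmark(bench, out_dir, force=force)
    return bench


def write_benchmark(bench: Benchmark, out_dir: str | Path,
                    force: bool = False) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for item in bench.items:
        spath = out / f"{item.item_id}_stream.csv"
        tpath = out / f"{item.item_id}_track.csv"
        item.stream.to_csv(spath, index=False)
        item.track.to_frame().to_csv(tpath, index=False)
        rows.append((item.item_id, item.label, item.seed, spath.name, tpath.name))
    pd.DataFrame(rows, columns=["id", "label", "seed", "stream_path",
                                "track_path"]).to_csv(out / "manifest.csv",
                                                      index=False)
    return out


def load_benchmark(in_dir: str | Path, config: ScenarioConfig | None = None
                   ) -> list[BenchmarkItem]:
    """Read back the items of a written benchmark (streams and tracks)."""
    from .tracks import read_track
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    items = []
    for row in manifest.itertuples(index=False):
        stream = pd.read_csv(in_dir / row.stream_path)
        track = read_track(in_dir / row.track_path)
        warm = config.warmup_s if config is not None else ScenarioConfig().warmup_s
        items.append(BenchmarkItem(item_id=row.id, label=row.label,
                                   seed=int(row.seed), track=track,
                                   stream=stream, warmup_s=warm))
    return items
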