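"""Trajectory processing: smoothing, headings, labels, distances, triangulation.

Tracks are timestamped 3D positions of the fish inside the tank (meters
internally; track files use millimeters).  The module provides the steps
between raw localization output and the quantities the evaluation needs:
LOWESS smoothing of each coordinate versus time, heading estimation from
successive positions, pass/dwell labelling, distance to the electrode
centers, and the two-camera triangulation geometry that turns pixel
positions into 3D coordinates via per-camera reference-plane homographies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .field import TankGeometry

TRACK_COLUMNS = ("t_s", "x_mm", "y_mm", "z_mm")
LABELS = ("pass", "dwell", "other")


@dataclass
class Track:
    """Timestamps (s) and positions (m) with optional joined resistance."""

    t: np.ndarray
    xyz: np.ndarray                      # (n, 3)
    re_ohm: np.ndarray | None = None     # optional per-sample joined values

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.t.shape[0] != self.xyz.shape[0]:
            raise ValueError("t and xyz lengths differ")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("track timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def validate_bounds(self, geometry: TankGeometry, tol: float = 0.005) -> None:
        hi = np.array([geometry.length_x, geometry.width_y, geometry.water_depth_z])
        if (self.xyz < -tol).any() or (self.xyz > hi + tol).any():
            raise ValueError("track leaves the tank bounds beyond tolerance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t,
            "x_mm": self.xyz[:, 0] * 1e3,
            "y_mm": self.xyz[:, 1] * 1e3,
            "z_mm": self.xyz[:, 2] * 1e3,
        })


def read_track(path) -> Track:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track file {path} lacks columns {sorted(missing)}")
    xyz = df[["x_mm", "y_mm", "z_mm"]].to_numpy(float) * 1e-3
    return Track(df["t_s"].to_numpy(float), xyz)


def write_track(track: Track, path) -> None:
    track.to_frame().to_csv(path, index=False)


def lowess_smooth(track: Track, frac: float = 0.1) -> Track:
    """Locally weighted regression of each coordinate versus time.

    The default window fraction 0.1 corresponds to roughly a two-second
    window on a 20 Hz, 20 s track, matching fish maneuver timescales.
    Timestamps are unchanged; a linear trajectory passes through unchanged.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if len(track) < 10:
        raise ValueError("lowess_smooth requires at least 10 samples")
    sm = np.column_stack([
        _sm_lowess(track.xyz[:, k], track.t, frac=frac, it=1,
                   return_sorted=False)
        for k in range(3)
    ])
    return Track(track.t.copy(), sm, track.re_ohm)


def headings(track: Track, default: tuple[float, float, float] = (1.0, 0.0, 0.0),
             smoothed: bool = True) -> np.ndarray:
    """Unit vectors pointing to the subsequent track point.

    The last sample repeats the previous heading; zero-displacement steps
    inherit the last valid heading (the configured default before any valid
    one exists).  Heading estimation on unsmoothed tracks is noisy, so a
    warning is emitted when ``smoothed`` is false.
    """
    if len(track) < 2:
        raise ValueError("headings require at least two samples")
    if not smoothed:
        warnings.warn("heading estimation on an unsmoothed track is noisy",
                      stacklevel=2)
    d = np.diff(track.xyz, axis=0)
    norms = np.linalg.norm(d, axis=1)
    out = np.empty_like(track.xyz)
    last = np.asarray(default, dtype=float)
    last = last / np.linalg.norm(last)
    any_valid = False
    for i in range(len(track) - 1):
        if norms[i] > 0:
            last = d[i] / norms[i]
            any_valid = True
        out[i] = last
    out[-1] = last
    if not any_valid:
        warnings.warn("stationary track: headings fall back to the default",
                      stacklevel=2)
    return out


def classify_track(track: Track, geometry: TankGeometry, margin: float = 0.05,
                   dwell_min_s: float = 10.0) -> str:
    """Label a track as 'pass', 'dwell' or 'other'.

    A pass crosses from within ``margin`` of one side wall (x = 0 or
    x = length_x) to within ``margin`` of the opposite one, in either
    direction.  A non-pass track dwelling within ``margin`` of a single side
    wall for at least ``dwell_min_s`` contiguous seconds is a dwell.
    The label is invariant under time reversal.
    """
    x = track.xyz[:, 0]
    L = geometry.length_x
    near_lo = x <= margin
    near_hi = x >= L - margin
    if near_lo.any() and near_hi.any():
        first_lo, last_lo = np.flatnonzero(near_lo)[[0, -1]]
        first_hi, last_hi = np.flatnonzero(near_hi)[[0, -1]]
        if first_lo < last_hi or first_hi < last_lo:
            return "pass"
    for near in (near_lo, near_hi):
        if _longest_run_duration(track.t, near) >= dwell_min_s:
            return "dwell"
    return "other"


def _longest_run_duration(t: np.ndarray, flags: np.ndarray) -> float:
    best = 0.0
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            best = max(best, t[i - 1] - t[start])
            start = None
    if start is not None:
        best = max(best, t[-1] - t[start])
    return best


def electrode_distances(xyz: np.ndarray, geometry: TankGeometry) -> np.ndarray:
    """Per-sample distance to the nearer electrode center.

    The reference point is the electrode center (x = electrode_center_x) on
    either wall, taken at the sample's own depth (electrodes span the full
    water column, so z is clamped to the electrode extent).
    """
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    dx = xyz[:, 0] - geometry.electrode_center_x
    dz = xyz[:, 2] - np.clip(xyz[:, 2], 0.0, geometry.water_depth_z)
    d0 = np.sqrt(dx ** 2 + xyz[:, 1] ** 2 + dz ** 2)
    d1 = np.sqrt(dx ** 2 + (geometry.width_y - xyz[:, 1]) ** 2 + dz ** 2)
    return np.minimum(d0, d1)


def min_electrode_distance(track: Track, geometry: TankGeometry) -> float:
    """Minimum over the track of the distance to either electrode center."""
    if len(track) == 0:
        raise ValueError("min_electrode_distance requires a non-empty track")
    return float(electrode_distances(track.xyz, geometry).min())


def within_detection_region(xyz, geometry: TankGeometry,
                            radius: float = 0.05) -> np.ndarray | bool:
    """Whether sample(s) lie within ``radius`` of an electrode center.

    This is the convention used to build video-reference detection intervals.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    arr = np.asarray(xyz, dtype=float)
    res = electrode_distances(arr, geometry) <= radius
    return bool(res[0]) if arr.ndim == 1 else res


# ---------------------------------------------------------------------------
# two-camera triangulation via reference-plane homographies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneCalibration:
    """Four marker pixels and their world coordinates on one reference plane."""

    pixels: np.ndarray        # (4, 2)
    world: np.ndarray         # (4, 3), coplanar

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float))
        object.__setattr__(self, "world", np.asarray(self.world, dtype=float))
        if self.pixels.shape != (4, 2) or self.world.shape != (4, 3):
            raise ValueError("plane calibration needs four pixel and world points")
        o, u, v = self._basis()
        # non-collinearity: both in-plane spans must be non-degenerate
        coords = (self.world - o) @ np.column_stack([u, v])
        if abs(np.linalg.det(np.cov(coords.T))) < 1e-18:
            raise ValueError("reference markers are (nearly) collinear")

    def _basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = self.world[0]
        u = self.world[1] - o
        u = u / np.linalg.norm(u)
        w = self.world[2] - o
        v = w - np.dot(w, u) * u
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError("reference markers are (nearly) collinear")
        v = v / nv
        n = np.cross(u, v)
        if abs(np.dot(self.world[3] - o, n)) > 1e-6:
            raise ValueError("reference markers are not coplanar")
        return o, u, v

    def homography(self) -> np.ndarray:
        """3x3 map from pixel homogeneous coordinates to plane coordinates."""
        o, u, v = self._basis()
        plane = (self.world - o) @ np.column_stack([u, v])   # (4, 2)
        A = []
        for (px, py), (a, b) in zip(self.pixels, plane):
            A.append([px, py, 1, 0, 0, 0, -a * px, -a * py, -a])
            A.append([0, 0, 0, px, py, 1, -b * px, -b * py, -b])
        A = np.asarray(A)
        _, _, vt = np.linalg.svd(A)
        return vt[-1].reshape(3, 3)

    def map_pixel(self, pixel: Sequence[float]) -> np.ndarray:
        """World point where the viewing ray of ``pixel`` meets this plane."""
        H = self.homography()
        q = H @ np.array([pixel[0], pixel[1], 1.0])
        if abs(q[2]) < 1e-15:
            raise ValueError("pixel maps to the plane at infinity")
        a, b = q[0] / q[2], q[1] / q[2]
        o, u, v = self._basis()
        return o + a * u + b * v


@dataclass(frozen=True)
class CameraCalibration:
    """Two parallel reference planes seen by one camera."""

    plane1: PlaneCalibration
    plane2: PlaneCalibration

    def pixel_ray(self, pixel) -> tuple[np.ndarray, np.ndarray]:
        """Viewing ray (origin, unit direction) through the two planes."""
        p1 = self.plane1.map_pixel(pixel)
        p2 = self.plane2.map_pixel(pixel)
        d = p2 - p1
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise ValueError("degenerate ray: plane intersections coincide")
        return p1, d / n


@dataclass(frozen=True)
class StereoCalibration:
    top: CameraCalibration
    side: CameraCalibration


def triangulate(pixel_top, pixel_side, calib: StereoCalibration
                ) -> tuple[np.ndarray, float]:
    """3D position from one pixel per camera.

    Each pixel is mapped through the camera's two reference-plane
    homographies, giving two world points that define the viewing ray.  The
    returned position is the midpoint of the shortest segment connecting the
    two rays; the residual is that segment's length (zero for consistent,
    noiseless projections).
    """
    o1, d1 = calib.top.pixel_ray(pixel_top)
    o2, d2 = calib.side.pixel_ray(pixel_side)
    cross = np.cross(d1, d2)
    denom = np.dot(cross, cross)
    if denom < 1e-12:
        raise ValueError("near-parallel viewing rays: triangulation degenerate")
    w = o2 - o1
    s = np.dot(np.cross(w, d2), cross) / denom
    u = np.dot(np.cross(w, d1), cross) / denom
    p1 = o1 + s * d1
    p2 = o2 + u * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))
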