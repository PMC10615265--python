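"""Shared fixtures: the nominal benchmark, its sweep, and synthetic cameras."""

from __future__ import annotations

import numpy as np
import pytest

from fincount.detector import DetectorConfig
from fincount.evaluate import sweep
from fincount.field import TankGeometry
from fincount.synth import ScenarioConfig, make_benchmark
from fincount.tracks import (CameraCalibration, PlaneCalibration,
                             StereoCalibration)

RATIO_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@pytest.fixture(scope="session")
def geometry() -> TankGeometry:
    return TankGeometry()


@pytest.fixture(scope="session")
def nominal_benchmark():
    """The 40-pass + 40-dwell benchmark at all-default study conditions."""
    return make_benchmark(ScenarioConfig())


@pytest.fixture(scope="session")
def full_sweep(nominal_benchmark):
    """All four modes over the 0.5..6 ratio grid, with per-item outcomes."""
    table, outcomes = sweep(nominal_benchmark, ratios=RATIO_GRID,
                            config=DetectorConfig(), return_outcomes=True)
    return table, outcomes


# ---------------------------------------------------------------------------
# synthetic pinhole cameras for triangulation tests
# ---------------------------------------------------------------------------

class PinholeCamera:
    """Exact perspective projection used as the triangulation oracle."""

    def __init__(self, position, target, up=(0.0, 0.0, 1.0),
                 f: float = 1500.0, pp=(640.0, 480.0)) -> None:
        c = np.asarray(position, dtype=float)
        z = np.asarray(target, dtype=float) - c
        z /= np.linalg.norm(z)
        u = np.asarray(up, dtype=float)
        x = np.cross(z, u)
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        self.c = c
        self.R = np.vstack([x, y, z])   # world -> camera rotation
        self.f = f
        self.pp = np.asarray(pp, dtype=float)

    def project(self, world) -> np.ndarray:
        w = np.atleast_2d(np.asarray(world, dtype=float))
        cam = (w - self.c) @ self.R.T
        pix = self.f * cam[:, :2] / cam[:, 2:3] + self.pp
        return pix[0] if np.asarray(world).ndim == 1 else pix


def _plane_markers(axis: int, level: float) -> np.ndarray:
    """Four non-collinear markers on a tank-aligned plane."""
    if axis == 2:       # horizontal plane z = level
        pts = [(0.05, 0.03), (0.35, 0.03), (0.35, 0.21), (0.05, 0.21)]
        return np.array([(x, y, level) for x, y in pts])
    if axis == 1:       # vertical plane y = level
        pts = [(0.05, 0.02), (0.35, 0.02), (0.35, 0.18), (0.05, 0.18)]
        return np.array([(x, level, z) for x, z in pts])
    raise ValueError(axis)


def _camera_calibration(camera: PinholeCamera, axis: int,
                        levels: tuple[float, float]) -> CameraCalibration:
    planes = []
    for level in levels:
        world = _plane_markers(axis, level)
        planes.append(PlaneCalibration(pixels=camera.project(world),
                                       world=world))
    return CameraCalibration(*planes)


@pytest.fixture(scope="session")
def stereo_rig():
    """(top camera, side camera, StereoCalibration) with exact projections."""
    top = PinholeCamera(position=(0.23, 0.10, 1.2), target=(0.20, 0.12, 0.10))
    side = PinholeCamera(position=(0.17, -1.1, 0.14), target=(0.20, 0.12, 0.10))
    calib = StereoCalibration(
        top=_camera_calibration(top, axis=2, levels=(0.02, 0.18)),
        side=_camera_calibration(side, axis=1, levels=(0.02, 0.22)),
    )
    return top, side, calib
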