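"""Finite-difference forward model of the measurement tank.

The tank is a rectangular water volume with one strip electrode centered on
each of the two long walls (the walls at y = 0 and y = width_y), extending
over the full water depth.  For field modelling the interleaved pick-up /
current-carrying comb pair on each wall is collapsed into a single electrode,
which is valid when electrode-interface (double-layer) effects are ignored.

The electric potential V solves the continuity equation for a purely
conductive medium,

    div( sigma * grad V ) = 0,

with Dirichlet conditions on the electrode footprints (one driven at
``v_drive`` volts, the other grounded) and zero normal current on every other
boundary (glass walls and the free water surface).  Discretization is a
7-point finite-difference scheme on a regular voxel grid, cell-centered, with
harmonic averaging of conductivity across cell faces; Dirichlet electrode
values enter through half-cell fluxes, which makes the scheme exact for the
parallel-plate (full-wall electrode) configuration.

From the solved potential the module derives the total current I, the
resistance R = v_drive / I, the current-density field J = -sigma * grad V and
the impedance-sensitivity field

    S = (J_PU . J_CC) / I^2      [1/m^4]

which quantifies the contribution of each voxel to the measured impedance.
In the collapsed two-electrode approximation the PU and CC fields coincide
and S = |J|^2 / I^2 >= 0.

A fish is represented as a homogeneous conductive ellipsoid (full axes
50 x 20 x 10 mm, 1 S/m by default) whose long axis follows the heading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, cg, splu
from scipy.special import elliprd


class FieldSolverError(RuntimeError):
    """Raised when the linear solve fails to converge."""


@dataclass(frozen=True)
class TankGeometry:
    """Water volume and electrode layout (meters).

    The coordinate origin is at one bottom tank corner: x along the 400 mm
    edge, y along the 240 mm electrode-to-electrode axis, z up.  Electrodes
    are vertical strips on the walls y = 0 and y = width_y, centered at
    ``electrode_center_x`` and spanning the full water depth.
    """

    length_x: float = 0.400
    width_y: float = 0.240
    water_depth_z: float = 0.200
    electrode_width: float = 0.020
    electrode_center_x: float = 0.200

    def __post_init__(self) -> None:
        if min(self.length_x, self.width_y, self.water_depth_z) <= 0:
            raise ValueError("tank dimensions must be positive")
        if self.electrode_width <= 0:
            raise ValueError("electrode_width must be positive")
        if self.electrode_width > self.length_x + 1e-12:
            raise ValueError("electrode_width cannot exceed the wall length")

    @property
    def electrode_spacing(self) -> float:
        """Electrodes face each other across the tank width."""
        return self.width_y


@dataclass
class ConductivityGrid:
    """Voxelized conductivity over the water volume.

    ``sigma`` has shape (nx, ny, nz); voxel centers sit at ((i+0.5)h, ...).
    ``electrode_mask`` is an (nx, nz) boolean footprint shared by both wall
    electrodes (they face each other).
    """

    geometry: TankGeometry
    h: float
    sigma: np.ndarray
    electrode_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sigma.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.sigma.shape[axis]
        return (np.arange(n) + 0.5) * self.h

    def copy(self) -> "ConductivityGrid":
        return ConductivityGrid(self.geometry, self.h, self.sigma.copy(),
                                self.electrode_mask.copy())


@dataclass(frozen=True)
class FishEllipsoid:
    """Homogeneous conductive ellipsoid model of the fish.

    ``semi_axes`` are along (heading, horizontal-cross, vertical-cross);
    defaults correspond to full axes 50 x 20 x 10 mm.
    """

    center: tuple[float, float, float]
    heading: tuple[float, float, float] = (1.0, 0.0, 0.0)
    semi_axes: tuple[float, float, float] = (0.025, 0.010, 0.005)
    sigma_fish: float = 1.0

    def frame(self) -> np.ndarray:
        """Orthonormal body frame (rows: long axis, horizontal, vertical)."""
        e1 = np.asarray(self.heading, dtype=float)
        n = np.linalg.norm(e1)
        if n == 0:
            raise ValueError("heading must be a nonzero vector")
        e1 = e1 / n
        up = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(e1, up)) > 0.99:  # near-vertical heading: fall back
            up = np.array([1.0, 0.0, 0.0])
        e2 = np.cross(up, e1)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        return np.vstack([e1, e2, e3])


@dataclass
class FieldSolution:
    """Solved potential and derived quantities for one electrode drive."""

    grid: ConductivityGrid
    v_drive: float
    potential: np.ndarray          # (nx, ny, nz), volts
    current_density: np.ndarray    # (nx, ny, nz, 3), A/m^2
    current_drive: float           # A, integrated over the driven electrode
    current_ground: float          # A, integrated over the grounded electrode
    drive_side: int = 0            # 0: wall y=0 driven, 1: wall y=width_y

    @property
    def total_current(self) -> float:
        return 0.5 * (self.current_drive + self.current_ground)

    @property
    def resistance(self) -> float:
        return self.v_drive / self.total_current


@dataclass
class SensitivityField:
    """Per-voxel impedance sensitivity S = (J_PU . J_CC) / I^2  [1/m^4].

    ``j_hat`` carries the unit current-density direction of the fish-free
    field, used by the linearized inclusion surrogate.
    """

    grid: ConductivityGrid
    S: np.ndarray
    j_hat: np.ndarray


def build_grid(geometry: TankGeometry, h: float, sigma_water: float) -> ConductivityGrid:
    """Uniform-water grid with electrode footprints recorded.

    ``h`` must divide the tank dimensions to within one voxel.
    """
    if h <= 0:
        raise ValueError("voxel spacing h must be positive")
    if sigma_water <= 0:
        raise ValueError("sigma_water must be positive")
    dims = (geometry.length_x, geometry.width_y, geometry.water_depth_z)
    counts = []
    for d in dims:
        n = int(round(d / h))
        if n < 2 or abs(n * h - d) > h:
            raise ValueError(f"h={h} does not tile tank dimension {d}")
        counts.append(n)
    nx, ny, nz = counts
    sigma = np.full((nx, ny, nz), float(sigma_water))
    x = (np.arange(nx) + 0.5) * h
    half_w = 0.5 * geometry.electrode_width
    col = np.abs(x - geometry.electrode_center_x) <= half_w + 1e-12
    if not col.any():  # never let the electrode vanish on a coarse grid
        col[np.argmin(np.abs(x - geometry.electrode_center_x))] = True
    electrode_mask = np.repeat(col[:, None], nz, axis=1)
    return ConductivityGrid(geometry, h, sigma, electrode_mask)


def embed_fish(grid: ConductivityGrid, fish: FishEllipsoid) -> ConductivityGrid:
    """Return a copy of the grid with fish voxels set to ``sigma_fish``.

    A voxel belongs to the fish when its center lies inside the rotated
    ellipsoid.  A fish entirely outside the water volume leaves the grid
    unchanged (with a warning).
    """
    mask = fish_voxel_mask(grid, fish)
    out = grid.copy()
    if not mask.any():
        warnings.warn("fish ellipsoid does not cover any voxel center; "
                      "grid unchanged", stacklevel=2)
        return out
    out.sigma[mask] = fish.sigma_fish
    return out


def fish_voxel_mask(grid: ConductivityGrid, fish: FishEllipsoid) -> np.ndarray:
    """Boolean mask of voxel centers inside the rotated ellipsoid."""
    frame = fish.frame()
    a, b, c = fish.semi_axes
    cx, cy, cz = fish.center
    X = grid.axis_centers(0)[:, None, None] - cx
    Y = grid.axis_centers(1)[None, :, None] - cy
    Z = grid.axis_centers(2)[None, None, :] - cz
    u1 = X * frame[0, 0] + Y * frame[0, 1] + Z * frame[0, 2]
    u2 = X * frame[1, 0] + Y * frame[1, 1] + Z * frame[1, 2]
    u3 = X * frame[2, 0] + Y * frame[2, 1] + Z * frame[2, 2]
    return (u1 / a) ** 2 + (u2 / b) ** 2 + (u3 / c) ** 2 <= 1.0


def _assemble(grid: ConductivityGrid, v_drive: float, drive_side: int):
    """Sparse SPD system for the cell-centered scheme.

    drive_side 0 drives the electrode on the wall y=0, 1 the wall y=width_y.
    Returns (A, b, boundary couplings) where the couplings are per-electrode
    (cell indices, conductances) used afterwards to integrate currents.
    """
    nx, ny, nz = grid.shape
    h = grid.h
    N = nx * ny * nz
    idx = np.arange(N).reshape(nx, ny, nz)
    sig = grid.sigma

    rows, cols, data = [], [], []
    diag = np.zeros(N)

    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s1 = sig[tuple(sl_lo)]
        s2 = sig[tuple(sl_hi)]
        g = (h * 2.0 * s1 * s2 / (s1 + s2)).ravel()
        i1 = idx[tuple(sl_lo)].ravel()
        i2 = idx[tuple(sl_hi)].ravel()
        rows.append(i1); cols.append(i2); data.append(-g)
        rows.append(i2); cols.append(i1); data.append(-g)
        np.add.at(diag, i1, g)
        np.add.at(diag, i2, g)

    # Electrode Dirichlet faces via half-cell conductance 2*h*sigma.
    mask = grid.electrode_mask
    b = np.zeros(N)
    couplings = []
    for side, j in ((0, 0), (1, ny - 1)):
        cells = idx[:, j, :][mask]
        gb = 2.0 * h * sig[:, j, :][mask]
        np.add.at(diag, cells, gb)
        if side == drive_side:
            np.add.at(b, cells, gb * v_drive)
        couplings.append((cells, gb, v_drive if side == drive_side else 0.0))

    A = sp.coo_matrix(
        (np.concatenate(data + [diag]),
         (np.concatenate(rows + [np.arange(N)]),
          np.concatenate(cols + [np.arange(N)]))),
        shape=(N, N)).tocsr()
    return A, b, couplings


def solve_field(grid: ConductivityGrid, v_drive: float = 1.0,
                drive_side: int = 0, rtol: float = 1e-8,
                maxiter: int = 50000,
                x0: np.ndarray | None = None) -> FieldSolution:
    """Solve the conduction problem and derive J, I and R.

    Small systems are factorized directly; larger ones use Jacobi-
    preconditioned conjugate gradients seeded with the parallel-plate ramp
    (or with ``x0``, e.g. a solution prolongated from a coarser grid).
    """
    if v_drive <= 0:
        raise ValueError("v_drive must be positive")
    if drive_side not in (0, 1):
        raise ValueError("drive_side must be 0 or 1")
    nx, ny, nz = grid.shape
    N = nx * ny * nz
    A, b, couplings = _assemble(grid, v_drive, drive_side)

    if N <= 30000 and x0 is None:
        V = splu(A.tocsc()).solve(b)
    else:
        if x0 is None:
            yfrac = (grid.axis_centers(1) / grid.geometry.width_y)
            ramp = v_drive * (1.0 - yfrac) if drive_side == 0 else v_drive * yfrac
            x0 = np.broadcast_to(ramp[None, :, None], grid.shape).ravel().copy()
        else:
            x0 = np.asarray(x0, dtype=float).ravel()
            if x0.size != N:
                raise ValueError("x0 does not match the grid size")
        Minv = 1.0 / A.diagonal()
        M = LinearOperator((N, N), matvec=lambda r: Minv * r)
        V, info = cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
        if info != 0:
            res = np.linalg.norm(A @ V - b) / np.linalg.norm(b)
            raise FieldSolverError(
                f"CG did not converge (info={info}, rel. residual {res:.2e}, "
                f"N={N}, maxiter={maxiter})")
    V = V.reshape(grid.shape)

    currents = []
    for cells, gb, vd in couplings:
        flat = V.ravel()[cells]
        # positive current = flow out of the driven electrode into the water
        currents.append(float(np.sum(gb * (vd - flat))))
    i_drive = currents[drive_side]
    i_ground = -currents[1 - drive_side]

    J = _current_density(grid, V, couplings, drive_side)
    return FieldSolution(grid=grid, v_drive=v_drive, potential=V,
                         current_density=J, current_drive=i_drive,
                         current_ground=i_ground, drive_side=drive_side)


def _current_density(grid, V, couplings, drive_side) -> np.ndarray:
    """Cell-centered J by averaging the two face-flux densities per axis.

    Insulating boundary faces carry zero flux; electrode boundary faces carry
    the half-cell Dirichlet flux.  The averaging is exact for uniform fields.
    """
    nx, ny, nz = grid.shape
    h = grid.h
    sig = grid.sigma
    J = np.zeros((nx, ny, nz, 3))
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        s1 = sig[tuple(sl_lo)]
        s2 = sig[tuple(sl_hi)]
        gf = 2.0 * s1 * s2 / (s1 + s2)  # face conductivity
        dV = V[tuple(sl_hi)] - V[tuple(sl_lo)]
        f = -gf * dV / h  # flux density along +axis
        face = np.zeros((nx + (axis == 0), ny + (axis == 1), nz + (axis == 2)))
        interior = [slice(None)] * 3
        interior[axis] = slice(1, -1)
        face[tuple(interior)] = f
        if axis == 1:  # electrode faces on the y boundaries
            mask = grid.electrode_mask
            for side, j in ((0, 0), (1, ny - 1)):
                vd = couplings[side][2]
                # half-cell flux density into +y direction
                fb = -2.0 * sig[:, j, :] * (
                    (V[:, j, :] - vd) if side == 0 else (vd - V[:, j, :])
                ) / h
                tgt = face[:, 0, :] if side == 0 else face[:, ny, :]
                tgt[mask] = fb[mask]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        J[..., axis] = 0.5 * (face[tuple(lo)] + face[tuple(hi)])
    return J


def sensitivity_map(solution_pu: FieldSolution,
                    solution_cc: FieldSolution | None = None) -> SensitivityField:
    """Impedance-sensitivity field S = (J_PU . J_CC) / I^2.

    With ``solution_cc`` omitted the collapsed two-electrode approximation is
    used (PU and CC coincide), giving S = |J|^2 / I^2 >= 0.
    """
    if solution_cc is None:
        solution_cc = solution_pu
    ga, gb = solution_pu.grid, solution_cc.grid
    if ga.shape != gb.shape or abs(ga.h - gb.h) > 1e-15:
        raise ValueError("sensitivity requires both solutions on the same grid")
    Jp = solution_pu.current_density
    Jc = solution_cc.current_density
    S = np.einsum("...i,...i->...", Jp, Jc) / (
        solution_pu.total_current * solution_cc.total_current)
    norm = np.linalg.norm(Jp, axis=-1)
    norm[norm == 0] = 1.0
    j_hat = Jp / norm[..., None]
    return SensitivityField(grid=solution_pu.grid, S=S, j_hat=j_hat)


def resistance_with_fish(geometry: TankGeometry, sigma_water: float,
                         fish: FishEllipsoid | None, h: float,
                         v_drive: float = 1.0) -> float:
    """Full-solve tank resistance with an optional embedded fish."""
    grid = build_grid(geometry, h, sigma_water)
    if fish is not None:
        grid = embed_fish(grid, fish)
    return solve_field(grid, v_drive=v_drive).resistance


def calibrate_sigma_water(r_measured: float, geometry: TankGeometry, h: float,
                          tol: float = 0.05, sigma_ref: float = 0.05) -> float:
    """Water conductivity reproducing a fish-free resistance reading.

    For uniform water the discrete operator is linear in sigma, so
    R(sigma) = R(sigma_ref) * sigma_ref / sigma exactly; a single reference
    solve plus scaling meets the +/-50 mOhm contract without iteration.
    """
    if r_measured <= 0:
        raise ValueError("r_measured must be positive")
    grid = build_grid(geometry, h, sigma_ref)
    r_ref = solve_field(grid).resistance
    sigma = sigma_ref * r_ref / r_measured
    # Exact by linearity; guard against pathological inputs anyway.
    if not np.isfinite(sigma) or sigma <= 0:
        raise FieldSolverError("calibration failed: non-physical conductivity")
    return float(sigma)


def depolarization_factors(semi_axes: Sequence[float]) -> np.ndarray:
    """Ellipsoid depolarization factors along the three principal axes.

    Computed from Carlson's degenerate elliptic integral R_D; the three
    factors sum to 1.
    """
    a, b, c = (float(v) for v in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    pref = a * b * c / 3.0
    return np.array([
        pref * elliprd(b * b, c * c, a * a),
        pref * elliprd(c * c, a * a, b * b),
        pref * elliprd(a * a, b * b, c * c),
    ])


def delta_R_linearized(sensitivity: SensitivityField, fish: FishEllipsoid,
                       sigma_water: float, corrected: bool = True) -> float:
    """First-order estimate of the fish-induced resistance change.

    With ``corrected=False`` this is the plain resistivity-linearized
    lead-field estimate

        dR = sum_{fish voxels} (1/sigma_fish - 1/sigma_water) * S * h^3 .

    With ``corrected=True`` (default) each voxel term additionally carries the
    analytic interior-field factor of a conductive ellipsoid in a locally
    uniform field (depolarization factors along the body frame), which is
    substantially more accurate at high conductivity contrast:

        dR = -sum_v S_v h^3 * (dsig/sw^2) * sum_j e_j^2 / (1 + L_j dsig/sw)

    where e_j are the components of the local unit current direction in the
    body frame, L_j the depolarization factors and dsig = sigma_fish -
    sigma_water.  Negative whenever the fish conducts better than the water.
    """
    if sigma_water <= 0:
        raise ValueError("sigma_water must be positive")
    grid = sensitivity.grid
    mask = fish_voxel_mask(grid, fish)
    if not mask.any():
        return 0.0
    dsig = fish.sigma_fish - sigma_water
    if dsig == 0.0:
        return 0.0
    h3 = grid.h ** 3
    Sv = sensitivity.S[mask]
    if not corrected:
        drho = 1.0 / fish.sigma_fish - 1.0 / sigma_water
        return float(drho * np.sum(Sv) * h3)
    L = depolarization_factors(fish.semi_axes)
    frame = fish.frame()  # rows are body axes
    e = sensitivity.j_hat[mask] @ frame.T  # (n, 3) components in body frame
    gfac = np.sum(e ** 2 / (1.0 + L[None, :] * dsig / sigma_water), axis=1)
    return float(-np.sum(Sv * gfac) * h3 * dsig / sigma_water ** 2)


def midline_profiles(width_to_spacing_ratios: Sequence[float],
                     geometry: TankGeometry, h: float,
                     db_floor: float = -60.0) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Sensitivity profiles along the electrode-to-electrode midline.

    For each width/spacing ratio the fish-free field is solved and S is
    sampled along the line through the electrode centers (x = center_x,
    z = mid-depth), from one wall to the other.  Profiles are returned in dB
    relative to the per-ratio profile maximum, as {ratio: (y_m, S_dB)}.
    Ratios whose electrode would exceed the wall are clipped with a warning.
    """
    out: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for ratio in width_to_spacing_ratios:
        if ratio <= 0:
            raise ValueError("width/spacing ratios must be positive")
        width = ratio * geometry.electrode_spacing
        if width > geometry.length_x:
            warnings.warn(f"ratio {ratio} exceeds the wall; clipping electrode "
                          f"width to {geometry.length_x} m", stacklevel=2)
            width = geometry.length_x
        geo = replace(geometry, electrode_width=width)
        grid = build_grid(geo, h, 0.05)
        sens = sensitivity_map(solve_field(grid))
        x = grid.axis_centers(0)
        z = grid.axis_centers(2)
        xi = _nearest_indices(x, geo.electrode_center_x)
        zi = _nearest_indices(z, 0.5 * geo.water_depth_z)
        prof = sens.S[np.ix_(xi, np.arange(grid.shape[1]), zi)].mean(axis=(0, 2))
        db = 10.0 * np.log10(np.maximum(prof / prof.max(), 10 ** (db_floor / 10)))
        out[float(ratio)] = (grid.axis_centers(1), db)
    return out


def prolong_potential(V: np.ndarray) -> np.ndarray:
    """Piecewise-constant prolongation of a potential to a halved-spacing grid.

    Used to warm-start conjugate gradients when refining a grid (each coarse
    voxel maps onto the 2x2x2 fine voxels it contains).
    """
    return np.repeat(np.repeat(np.repeat(V, 2, axis=0), 2, axis=1), 2, axis=2)


def dissipated_power(solution: FieldSolution) -> float:
    """Volume-integrated sigma * |grad V|^2 from the discrete face fluxes.

    For the exact discrete solution this equals v_drive * I (the power
    identity R * I^2); the residual of the iterative solve is the only
    source of disagreement.
    """
    grid = solution.grid
    V = solution.potential
    sig = grid.sigma
    h = grid.h
    total = 0.0
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        g = h * 2.0 * sig[tuple(sl_lo)] * sig[tuple(sl_hi)] / (
            sig[tuple(sl_lo)] + sig[tuple(sl_hi)])
        dV = V[tuple(sl_hi)] - V[tuple(sl_lo)]
        total += float(np.sum(g * dV * dV))
    # electrode half-cell contributions
    ny = grid.shape[1]
    mask = grid.electrode_mask
    for side, j in ((0, 0), (1, ny - 1)):
        vd = solution.v_drive if side == solution.drive_side else 0.0
        gb = 2.0 * h * sig[:, j, :][mask]
        dV = V[:, j, :][mask] - vd
        total += float(np.sum(gb * dV * dV))
    return total


def _nearest_indices(centers: np.ndarray, target: float) -> np.ndarray:
    """Indices of all centers at the minimal distance from target (1 or 2)."""
    d = np.abs(centers - target)
    return np.flatnonzero(d <= d.min() + 1e-12)
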