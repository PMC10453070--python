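"""MAC staggered-grid geometry, discrete operators and ghost-cell boundaries.

Layout (marker-and-cell): the scalars p, psi, q, c live at cell centres,
shape ``(Nx, Ny)``; the horizontal velocity ``v1`` lives at vertical cell
faces, shape ``(Nx+1, Ny)``; the vertical velocity ``v2`` at horizontal
faces, shape ``(Nx, Ny+1)``.  Arrays are indexed ``[i, j]`` with ``i`` along
x.  Cells are indexed ``0..Nx-1 x 0..Ny-1``, v1 faces ``0..Nx``, v2 faces
``0..Ny``.

Boundary conditions (the bioconvection model): the top edge is the fluid-air
interface — oxygen is saturated (c = 1) and the chemotactic cell flux
balances diffusive flux (zero total flux); bottom and sides are zero-gradient
for the scalars; the velocity is no-slip everywhere.  These are encoded as
ghost layers so that interior stencils never special-case the boundary.  An
'mms' mode instead supplies exact manufactured-solution data on every edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np

__all__ = [
    "GridSpec", "build_grid", "BCSpec",
    "center_diff", "face_divergence", "pressure_gradient_to_faces",
    "velocity_derivatives_at_own_points", "velocity_to_centers",
    "cross_velocity_at_points", "apply_scalar_ghosts",
    "pad_scalar", "pad_v1_y", "pad_v2_x", "v1_wall_values", "v2_wall_values",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform Cartesian MAC grid on [xa, xb] x [ya, yb] with Nx x Ny cells."""

    xa: float
    xb: float
    ya: float
    yb: float
    Nx: int
    Ny: int
    hx: float
    hy: float
    x: np.ndarray   # node coordinates, shape (Nx+1,)
    y: np.ndarray   # node coordinates, shape (Ny+1,)
    xc: np.ndarray  # cell-centre coordinates, shape (Nx,)
    yc: np.ndarray  # cell-centre coordinates, shape (Ny,)

    @property
    def center_shape(self) -> tuple[int, int]:
        return (self.Nx, self.Ny)

    @property
    def v1_shape(self) -> tuple[int, int]:
        return (self.Nx + 1, self.Ny)

    @property
    def v2_shape(self) -> tuple[int, int]:
        return (self.Nx, self.Ny + 1)


def build_grid(xa: float, xb: float, ya: float, yb: float,
               Nx: int, Ny: int) -> GridSpec:
    """Build the staggered grid: nodes x_i = xa + i*hx, centres x_i + hx/2."""
    if not (xb > xa and yb > ya):
        raise ValueError("degenerate domain bounds")
    if Nx < 3 or Ny < 3:
        raise ValueError("need at least 3 cells per direction")
    hx = (xb - xa) / Nx
    hy = (yb - ya) / Ny
    x = xa + hx * np.arange(Nx + 1)
    y = ya + hy * np.arange(Ny + 1)
    xc = xa + hx * (np.arange(Nx) + 0.5)
    yc = ya + hy * (np.arange(Ny) + 0.5)
    return GridSpec(xa, xb, ya, yb, Nx, Ny, hx, hy, x, y, xc, yc)


@dataclass
class BCSpec:
    """Boundary-condition bundle.

    ``mode='model'``: the bioconvection conditions — top: c = 1 and zero total
    cell flux (ghost q = q * exp(alpha*(1-c)) at the interface); bottom and
    sides: zero gradient for q and c; no-slip velocity on every edge.

    ``mode='mms'``: manufactured-solution data; ``case`` must expose callables
    ``q_fn(x, y, t)``, ``c_fn``, ``v1_fn``, ``v2_fn`` evaluated at ghost or
    wall coordinates.

    ``ghost_mode`` selects how the Dirichlet oxygen value at the top is
    imposed: 'literal' sets the ghost cell itself to 1 (the validated form);
    'reflected' uses ghost = 2*1 - interior (reflection through the wall
    value).
    """

    mode: Literal["model", "mms"] = "model"
    ghost_mode: Literal["literal", "reflected"] = "literal"
    case: Any = None

    def __post_init__(self):
        if self.mode not in ("model", "mms"):
            raise ValueError(f"unknown bc mode {self.mode!r}")
        if self.ghost_mode not in ("literal", "reflected"):
            raise ValueError(f"unknown ghost mode {self.ghost_mode!r}")
        if self.mode == "mms" and self.case is None:
            raise ValueError("mms boundary mode requires a manufactured case")


# --------------------------------------------------------------------------
# difference operators
# --------------------------------------------------------------------------

def center_diff(field: np.ndarray, h: float, axis: int, order: int) -> np.ndarray:
    """Central difference along ``axis`` at interior points.

    order 1: (U_{k+1} - U_{k-1}) / (2h);  order 2: (U_{k-1} - 2 U_k + U_{k+1}) / h^2.
    The result loses the first and last slice along ``axis`` — pass a
    ghost-padded array to obtain values at every physical point.  The same
    stencils serve cell-centred scalars and each velocity component at its own
    staggered points.
    """
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (x) or 1 (y)")
    F = np.asarray(field, dtype=float)
    lo = [slice(None)] * F.ndim
    mid = [slice(None)] * F.ndim
    hi = [slice(None)] * F.ndim
    lo[axis] = slice(0, -2)
    mid[axis] = slice(1, -1)
    hi[axis] = slice(2, None)
    if order == 1:
        return (F[tuple(hi)] - F[tuple(lo)]) / (2.0 * h)
    if order == 2:
        return (F[tuple(lo)] - 2.0 * F[tuple(mid)] + F[tuple(hi)]) / h**2
    raise ValueError("order must be 1 or 2")


def velocity_derivatives_at_own_points(v: np.ndarray, which: str,
                                       grid: GridSpec) -> np.ndarray:
    """First/second differences of a velocity component at its own staggered
    points (interior along the differencing axis); ``which`` is one of
    'dx', 'dy', 'dxx', 'dyy'."""
    table = {"dx": (0, 1, grid.hx), "dxx": (0, 2, grid.hx),
             "dy": (1, 1, grid.hy), "dyy": (1, 2, grid.hy)}
    if which not in table:
        raise ValueError(f"unknown derivative {which!r}")
    axis, order, h = table[which]
    return center_diff(v, h, axis, order)


def face_divergence(v1: np.ndarray, v2: np.ndarray, grid: GridSpec) -> np.ndarray:
    """MAC divergence at cell centres from face velocities."""
    if v1.shape != grid.v1_shape or v2.shape != grid.v2_shape:
        raise ValueError("staggered field shapes inconsistent with grid")
    return ((v1[1:, :] - v1[:-1, :]) / grid.hx
            + (v2[:, 1:] - v2[:, :-1]) / grid.hy)


def pressure_gradient_to_faces(p: np.ndarray, grid: GridSpec):
    """Pressure gradient at *interior* faces: x-component at vertical faces
    i = 1..Nx-1 (shape (Nx-1, Ny)), y-component at horizontal faces
    j = 1..Ny-1 (shape (Nx, Ny-1)).  Boundary faces are not populated — the
    velocity there is Dirichlet."""
    if p.shape != grid.center_shape:
        raise ValueError("pressure shape inconsistent with grid")
    gx = (p[1:, :] - p[:-1, :]) / grid.hx
    gy = (p[:, 1:] - p[:, :-1]) / grid.hy
    return gx, gy


def velocity_to_centers(v1: np.ndarray, v2: np.ndarray):
    """Arithmetic two-point average of each face component to cell centres."""
    return 0.5 * (v1[:-1, :] + v1[1:, :]), 0.5 * (v2[:, :-1] + v2[:, 1:])


def cross_velocity_at_points(v: np.ndarray, grid: GridSpec,
                             target: str) -> np.ndarray:
    """Four-neighbour average of one velocity component at the *other*
    component's interior staggered points.

    ``target='v1'``: v2 averaged to interior v1 points (i=1..Nx-1, all j),
    shape (Nx-1, Ny).  ``target='v2'``: v1 averaged to interior v2 points
    (all i, j=1..Ny-1), shape (Nx, Ny-1).
    """
    if target == "v1":
        if v.shape != grid.v2_shape:
            raise ValueError("expected a v2 field")
        return 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])
    if target == "v2":
        if v.shape != grid.v1_shape:
            raise ValueError("expected a v1 field")
        return 0.25 * (v[:-1, :-1] + v[1:, :-1] + v[:-1, 1:] + v[1:, 1:])
    raise ValueError("target must be 'v1' or 'v2'")


# --------------------------------------------------------------------------
# ghost layers
# --------------------------------------------------------------------------

def _mms_ghost_coords(grid: GridSpec):
    """Centre-row/column coordinates extended by one ghost on each side."""
    xg = np.concatenate(([grid.xa - grid.hx / 2], grid.xc,
                         [grid.xb + grid.hx / 2]))
    yg = np.concatenate(([grid.ya - grid.hy / 2], grid.yc,
                         [grid.yb + grid.hy / 2]))
    return xg, yg


def pad_scalar(F: np.ndarray, grid: GridSpec, var: str, bc: BCSpec,
               params=None, t: float | None = None,
               c: np.ndarray | None = None) -> np.ndarray:
    """Return ``F`` padded to (Nx+2, Ny+2) with ghost values per the boundary
    conditions.  ``var`` is 'q' or 'c'.  In model mode the q top ghost needs
    the oxygen field ``c`` and ``params.alpha``; in mms mode the exact field
    is evaluated at the ghost coordinates at time ``t``.

    Ghost filling applies the x-edge rule first, then the y-edge rule (the
    y-rule therefore owns the corners); the scheme's stencils never touch
    corners, the order is fixed only for reproducibility.
    """
    if F.shape != grid.center_shape:
        raise ValueError("scalar field shape inconsistent with grid")
    P = np.empty((grid.Nx + 2, grid.Ny + 2), dtype=float)
    P[1:-1, 1:-1] = F
    if bc.mode == "mms":
        if t is None:
            raise ValueError("mms ghosts require the time level t")
        fn = {"q": bc.case.q_fn, "c": bc.case.c_fn}[var]
        xg, yg = _mms_ghost_coords(grid)
        P[0, 1:-1] = fn(xg[0], grid.yc, t)
        P[-1, 1:-1] = fn(xg[-1], grid.yc, t)
        P[:, 0] = fn(xg, yg[0], t)
        P[:, -1] = fn(xg, yg[-1], t)
        return P
    # model mode: zero-gradient copies on left/right/bottom
    P[0, 1:-1] = F[0, :]
    P[-1, 1:-1] = F[-1, :]
    P[:, 0] = P[:, 1]
    if var == "c":
        if bc.ghost_mode == "literal":
            P[:, -1] = 1.0
        else:
            P[:, -1] = 2.0 - P[:, -2]
    elif var == "q":
        if params is None or c is None:
            raise ValueError("q top ghost needs params.alpha and the c field")
        ctop = np.empty(grid.Nx + 2)
        ctop[1:-1] = c[:, -1]
        ctop[0] = c[0, -1]
        ctop[-1] = c[-1, -1]
        P[:, -1] = P[:, -2] * np.exp(params.alpha * (1.0 - ctop))
    else:
        raise ValueError("var must be 'q' or 'c'")
    return P


def apply_scalar_ghosts(q: np.ndarray, c: np.ndarray, grid: GridSpec,
                        params, bc: BCSpec, t: float | None = None):
    """Ghost-padded (q, c) pair, each (Nx+2, Ny+2); see :func:`pad_scalar`."""
    cp = pad_scalar(c, grid, "c", bc, params=params, t=t)
    qp = pad_scalar(q, grid, "q", bc, params=params, t=t, c=c)
    return qp, cp


def v1_wall_values(grid: GridSpec, bc: BCSpec, t: float | None = None):
    """v1 Dirichlet data: (left (Ny,), right (Ny,), bottom (Nx+1,), top (Nx+1,)).
    Left/right are on-grid values at x = xa, xb; bottom/top are wall values
    used for reflected ghosts (v1 points do not lie on the y walls)."""
    if bc.mode == "model":
        z = np.zeros
        return z(grid.Ny), z(grid.Ny), z(grid.Nx + 1), z(grid.Nx + 1)
    f = bc.case.v1_fn
    return (f(grid.xa, grid.yc, t), f(grid.xb, grid.yc, t),
            f(grid.x, grid.ya, t), f(grid.x, grid.yb, t))


def v2_wall_values(grid: GridSpec, bc: BCSpec, t: float | None = None):
    """v2 Dirichlet data: (bottom (Nx,), top (Nx,), left (Ny+1,), right (Ny+1,))."""
    if bc.mode == "model":
        z = np.zeros
        return z(grid.Nx), z(grid.Nx), z(grid.Ny + 1), z(grid.Ny + 1)
    f = bc.case.v2_fn
    return (f(grid.xc, grid.ya, t), f(grid.xc, grid.yb, t),
            f(grid.xa, grid.y, t), f(grid.xb, grid.y, t))


def pad_v1_y(v1: np.ndarray, grid: GridSpec, bc: BCSpec,
             t: float | None = None) -> np.ndarray:
    """Pad v1 with one ghost row below and above: ghost = 2*wall - adjacent
    (second-order Dirichlet reflection; wall value 0 for no-slip)."""
    if v1.shape != grid.v1_shape:
        raise ValueError("v1 shape inconsistent with grid")
    _, _, bot, top = v1_wall_values(grid, bc, t)
    P = np.empty((grid.Nx + 1, grid.Ny + 2), dtype=float)
    P[:, 1:-1] = v1
    P[:, 0] = 2.0 * bot - v1[:, 0]
    P[:, -1] = 2.0 * top - v1[:, -1]
    return P


def pad_v2_x(v2: np.ndarray, grid: GridSpec, bc: BCSpec,
             t: float | None = None) -> np.ndarray:
    """Pad v2 with one ghost column left and right (Dirichlet reflection)."""
    if v2.shape != grid.v2_shape:
        raise ValueError("v2 shape inconsistent with grid")
    _, _, left, right = v2_wall_values(grid, bc, t)
    P = np.empty((grid.Nx + 2, grid.Ny + 1), dtype=float)
    P[1:-1, :] = v2
    P[0, :] = 2.0 * left - v2[0, :]
    P[-1, :] = 2.0 * right - v2[-1, :]
    return P
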