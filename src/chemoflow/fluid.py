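"""One fluid advance of the pressure-stabilized dimension-splitting scheme.

Step 1 — velocity.  An explicit predictor treats convection (with velocity
and convected field extrapolated to the half time level,
u* = 3/2 u^{n-1} - 1/2 u^{n-2}), the lagged pressure p* = p^{n-3/2} +
psi^{n-3/2}, the full 2D Laplacian of u^{n-1} and the cell-buoyancy force
f(q) = (0, Sc*gamma*q); an ADI correction then makes the viscous term
Crank-Nicolson one direction at a time, so every implicit solve is a
tridiagonal line solve.

Step 2 — pressure.  The pressure increment psi solves
(I - dxx)(I - dyy) psi = -div(u^n)/dt via two one-dimensional Helmholtz
sweeps with homogeneous Neumann closures (the factorized operator replaces
the Poisson operator of classical projection), and the pressure is updated
incrementally with the chi*eta divergence correction that restores
second-order accuracy.

The divergence of u^n is not exactly zero (stabilized, not projected); it
vanishes as dt is refined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import (BCSpec, GridSpec, center_diff, cross_velocity_at_points,
                   face_divergence, pad_v1_y, pad_v2_x,
                   pressure_gradient_to_faces, v1_wall_values, v2_wall_values)
from .params import PhysicalParams
from .tridiag import solve_helmholtz_lines

__all__ = ["FluidHistory", "buoyancy_force", "explicit_predictor",
           "adi_viscous_correction", "pressure_update", "fluid_advance"]


@dataclass
class FluidHistory:
    """Velocity/pressure history the two-level scheme needs.

    At startup u^{n-2} duplicates u^{n-1} (the extrapolations degrade to first
    order on the first step only) and p^{-1/2} = psi^{-1/2} = 0.
    """

    v1_nm1: np.ndarray
    v2_nm1: np.ndarray
    v1_nm2: np.ndarray
    v2_nm2: np.ndarray
    p: np.ndarray      # p^{n-3/2}
    psi: np.ndarray    # psi^{n-3/2}
    dt: float


def buoyancy_force(q_star: np.ndarray, params: PhysicalParams) -> np.ndarray:
    """Sc*gamma*q at interior v2 points (vertical two-point average), shape
    (Nx, Ny-1).  The x-momentum contribution is identically zero.  The force
    enters the momentum equation with a minus sign."""
    return params.Sc * params.gamma * 0.5 * (q_star[:, :-1] + q_star[:, 1:])


def explicit_predictor(hist: FluidHistory, q_star: np.ndarray,
                       params: PhysicalParams, grid: GridSpec, bc: BCSpec,
                       t_new: float | None = None, forcing=None):
    """Predicted velocity (v1~, v2~) before the viscous correction.

    Interior points receive u^{n-1} + dt*( -(u*.grad)u* - Sc grad p*
    + Sc lap u^{n-1} - f(q*) [+ forcing] ); boundary faces carry the
    Dirichlet data at t^n.  ``forcing`` (manufactured runs) exposes
    ``f1(x, y, t)`` / ``f2`` evaluated at each component's points at the half
    time level.
    """
    dt = hist.dt
    Sc = params.Sc
    t_old = None if t_new is None else t_new - dt
    t_mid = None if t_new is None else t_new - 0.5 * dt

    v1s = 1.5 * hist.v1_nm1 - 0.5 * hist.v1_nm2
    v2s = 1.5 * hist.v2_nm1 - 0.5 * hist.v2_nm2
    p_star = hist.p + hist.psi
    gx, gy = pressure_gradient_to_faces(p_star, grid)

    # --- v1 at interior vertical faces i=1..Nx-1 ---
    v1s_pad = pad_v1_y(v1s, grid, bc, t_mid)
    d1x = center_diff(v1s, grid.hx, 0, 1)                     # (Nx-1, Ny)
    d1y = center_diff(v1s_pad, grid.hy, 1, 1)[1:-1, :]        # (Nx-1, Ny)
    v2s_at_v1 = cross_velocity_at_points(v2s, grid, "v1")     # (Nx-1, Ny)
    conv1 = v1s[1:-1, :] * d1x + v2s_at_v1 * d1y

    v1o_pad = pad_v1_y(hist.v1_nm1, grid, bc, t_old)
    lap1 = (center_diff(hist.v1_nm1, grid.hx, 0, 2)
            + center_diff(v1o_pad, grid.hy, 1, 2)[1:-1, :])

    rhs1 = -conv1 - Sc * gx + Sc * lap1
    if forcing is not None:
        rhs1 = rhs1 + forcing.f1(grid.x[1:-1, None], grid.yc[None, :], t_mid)
    v1t = np.empty(grid.v1_shape)
    v1t[1:-1, :] = hist.v1_nm1[1:-1, :] + dt * rhs1
    bl, br, _, _ = v1_wall_values(grid, bc, t_new)
    v1t[0, :] = bl
    v1t[-1, :] = br

    # --- v2 at interior horizontal faces j=1..Ny-1 ---
    v2s_pad = pad_v2_x(v2s, grid, bc, t_mid)
    d2x = center_diff(v2s_pad, grid.hx, 0, 1)[:, 1:-1]        # (Nx, Ny-1)
    d2y = center_diff(v2s, grid.hy, 1, 1)
    v1s_at_v2 = cross_velocity_at_points(v1s, grid, "v2")
    conv2 = v1s_at_v2 * d2x + v2s[:, 1:-1] * d2y

    v2o_pad = pad_v2_x(hist.v2_nm1, grid, bc, t_old)
    lap2 = (center_diff(v2o_pad, grid.hx, 0, 2)[:, 1:-1]
            + center_diff(hist.v2_nm1, grid.hy, 1, 2))

    force2 = buoyancy_force(q_star, params)
    rhs2 = -conv2 - Sc * gy + Sc * lap2 - force2
    if forcing is not None:
        rhs2 = rhs2 + forcing.f2(grid.xc[:, None], grid.y[None, 1:-1], t_mid)
    v2t = np.empty(grid.v2_shape)
    v2t[:, 1:-1] = hist.v2_nm1[:, 1:-1] + dt * rhs2
    bb, bt, _, _ = v2_wall_values(grid, bc, t_new)
    v2t[:, 0] = bb
    v2t[:, -1] = bt
    return v1t, v2t


def adi_viscous_correction(v1t: np.ndarray, v2t: np.ndarray,
                           v1_nm1: np.ndarray, v2_nm1: np.ndarray,
                           params: PhysicalParams, grid: GridSpec, bc: BCSpec,
                           dt: float, t_new: float | None = None):
    """Direction-by-direction viscous correction, Eqs. of the ADI step:

    x-sweep:  (I - (Sc dt/2) dxx) u_bar = u~ - (Sc dt/2) dxx u^{n-1}
    y-sweep:  (I - (Sc dt/2) dyy) u^n  = u_bar - (Sc dt/2) dyy u^{n-1}

    Each component is solved at its own staggered points; both intermediate
    and final fields satisfy the Dirichlet data of their sweep direction.
    """
    kappa = 0.5 * params.Sc * dt
    t_old = None if t_new is None else t_new - dt
    v1_bl, v1_br, v1_wb, v1_wt = v1_wall_values(grid, bc, t_new)
    v2_bb, v2_bt, v2_wl, v2_wr = v2_wall_values(grid, bc, t_new)

    # ---- v1: unknowns at interior nodes i=1..Nx-1 ----
    rhs = v1t[1:-1, :] - kappa * center_diff(v1_nm1, grid.hx, 0, 2)
    v1b_int = solve_helmholtz_lines(
        kappa, grid.hx, rhs.T, "dirichlet_node", "dirichlet_node",
        data_left=v1_bl, data_right=v1_br).T          # (Nx-1, Ny)
    v1o_pad = pad_v1_y(v1_nm1, grid, bc, t_old)
    rhs = v1b_int - kappa * center_diff(v1o_pad, grid.hy, 1, 2)[1:-1, :]
    v1n_int = solve_helmholtz_lines(
        kappa, grid.hy, rhs, "dirichlet_ghost", "dirichlet_ghost",
        data_left=v1_wb[1:-1], data_right=v1_wt[1:-1])
    v1n = np.empty(grid.v1_shape)
    v1n[1:-1, :] = v1n_int
    v1n[0, :] = v1_bl
    v1n[-1, :] = v1_br

    # ---- v2: unknowns at interior faces j=1..Ny-1 ----
    v2o_pad = pad_v2_x(v2_nm1, grid, bc, t_old)
    rhs = v2t[:, 1:-1] - kappa * center_diff(v2o_pad, grid.hx, 0, 2)[:, 1:-1]
    v2b_int = solve_helmholtz_lines(
        kappa, grid.hx, rhs.T, "dirichlet_ghost", "dirichlet_ghost",
        data_left=v2_wl[1:-1], data_right=v2_wr[1:-1]).T
    rhs = v2b_int - kappa * center_diff(v2_nm1, grid.hy, 1, 2)
    v2n_int = solve_helmholtz_lines(
        kappa, grid.hy, rhs, "dirichlet_node", "dirichlet_node",
        data_left=v2_bb, data_right=v2_bt)
    v2n = np.empty(grid.v2_shape)
    v2n[:, 1:-1] = v2n_int
    v2n[:, 0] = v2_bb
    v2n[:, -1] = v2_bt
    return v1n, v2n


def pressure_update(v1n, v2n, v1_nm1, v2_nm1, p_old, params: PhysicalParams,
                    grid: GridSpec, dt: float):
    """Dimension-split pressure increment and incremental pressure update.

    (I - dxx) psi_bar = -div(u^n)/(Sc*dt)   (Neumann in x),
    (I - dyy) psi     = psi_bar             (Neumann in y),
    p^{n-1/2} = p^{n-3/2} + psi - (chi*eta/2) div(u^n + u^{n-1}).

    The 1/Sc factor makes the increment equation consistent with the
    Sc*grad(p) momentum term (the pressure-correction feedback then has
    unit gain); without it the update is only meaningful for Sc = 1 and the
    coupled iteration amplifies divergence by O(Sc) per step.
    """
    div_n = face_divergence(v1n, v2n, grid)
    div_o = face_divergence(v1_nm1, v2_nm1, grid)
    psi_bar = solve_helmholtz_lines(1.0, grid.hx,
                                    (-div_n / (params.Sc * dt)).T,
                                    "neumann", "neumann").T
    psi = solve_helmholtz_lines(1.0, grid.hy, psi_bar, "neumann", "neumann")
    p_new = p_old + psi - 0.5 * params.chi * params.eta * (div_n + div_o)
    return psi, p_new


def fluid_advance(hist: FluidHistory, q_star: np.ndarray,
                  params: PhysicalParams, grid: GridSpec, bc: BCSpec,
                  t_new: float | None = None, forcing=None):
    """Steps 1-2 combined: returns (v1^n, v2^n, psi^{n-1/2}, p^{n-1/2})."""
    v1t, v2t = explicit_predictor(hist, q_star, params, grid, bc,
                                  t_new=t_new, forcing=forcing)
    v1n, v2n = adi_viscous_correction(v1t, v2t, hist.v1_nm1, hist.v2_nm1,
                                      params, grid, bc, hist.dt, t_new=t_new)
    psi, p_new = pressure_update(v1n, v2n, hist.v1_nm1, hist.v2_nm1,
                                 hist.p, params, grid, hist.dt)
    return v1n, v2n, psi, p_new
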