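"""Dimension-split oxygen and cell-density updates (chemotaxis half of the
scheme).

Both scalars are advanced by Lie (sequential) splitting: an x-sweep followed
by a y-sweep, each treating only its own second derivative implicitly —
every solve is a batch of tridiagonal systems.  Convection and the
chemotaxis term are explicit; the consumption reaction beta*r(c)*q uses the
cell density extrapolated to the midpoint of the (sub-)interval and is
weighted (1/2, 1/2) between the sweeps so the total reaction per step is
consistent with the PDE (the literal both-sweeps form and a first-sweep-only
form remain switchable for diagnosis).

The oxygen cut-off r(c) = (tanh((c - 0.3)/eps) + 1)/2 switches consumption
and chemotaxis off where oxygen falls below the survival threshold 0.3.

The chemotaxis term defaults to the conservative face-flux discretization of
div(q r(c) grad c) — the divergence of two-point-averaged fluxes — which
telescopes exactly and so preserves total cell mass under no-flux closures;
the derivative-product form (dq/dx * r * dc/dx) is available as a switch.
"""

from __future__ import annotations

import numpy as np

from .grid import BCSpec, GridSpec, pad_scalar
from .params import PhysicalParams
from .tridiag import solve_helmholtz_lines

__all__ = ["r_of_c", "half_time_density", "oxygen_update", "cell_update",
           "REACTION_WEIGHTS"]

#: named reaction-weight modes: fraction of beta*r*q applied in (x, y) sweep
REACTION_WEIGHTS = {
    "consistent": (0.5, 0.5),
    "literal": (1.0, 1.0),
    "first": (1.0, 0.0),
}


def r_of_c(c, eps: float):
    """Smoothed oxygen cut-off r(c) = (tanh((c - 0.3)/eps) + 1)/2 in (0, 1)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return 0.5 * (np.tanh((np.asarray(c, dtype=float) - 0.3) / eps) + 1.0)


def _r(c, params: PhysicalParams):
    if params.r_const is not None:
        return np.full_like(np.asarray(c, dtype=float), params.r_const)
    return r_of_c(c, params.eps)


def half_time_density(q_nm1: np.ndarray, q_nm2: np.ndarray,
                      coeffs=(1.5, -0.5)) -> np.ndarray:
    """Cell density extrapolated from the two history levels.

    The default (3/2, -1/2) targets the midpoint of [t^{n-1}, t^n]; the
    Richardson half-steps use (5/4, -1/4) and (7/4, -3/4) for the midpoints
    of their sub-intervals.  Exact for densities linear in time.
    """
    a, b = coeffs
    return a * q_nm1 + b * q_nm2


def _mms_ghost_line(fn, grid: GridSpec, edge: str, t: float) -> np.ndarray:
    if edge == "left":
        return fn(grid.xa - grid.hx / 2, grid.yc, t)
    if edge == "right":
        return fn(grid.xb + grid.hx / 2, grid.yc, t)
    if edge == "bottom":
        return fn(grid.xc, grid.ya - grid.hy / 2, t)
    if edge == "top":
        return fn(grid.xc, grid.yb + grid.hy / 2, t)
    raise ValueError(edge)


def _pad_mms(F: np.ndarray, grid: GridSpec, fn, t: float) -> np.ndarray:
    """Pad an intermediate split field with ghost values from an evaluator
    (corrected intermediate data in manufactured runs)."""
    P = np.empty((F.shape[0] + 2, F.shape[1] + 2), dtype=float)
    P[1:-1, 1:-1] = F
    P[0, 1:-1] = _mms_ghost_line(fn, grid, "left", t)
    P[-1, 1:-1] = _mms_ghost_line(fn, grid, "right", t)
    xg = np.concatenate(([grid.xa - grid.hx / 2], grid.xc,
                         [grid.xb + grid.hx / 2]))
    P[:, 0] = fn(xg, grid.ya - grid.hy / 2, t)
    P[:, -1] = fn(xg, grid.yb + grid.hy / 2, t)
    return P


def oxygen_update(c_prev: np.ndarray, q_half: np.ndarray,
                  v1c: np.ndarray, v2c: np.ndarray,
                  params: PhysicalParams, grid: GridSpec, bc: BCSpec,
                  tau: float, t_start: float | None = None,
                  weights=(0.5, 0.5), forcing=None) -> np.ndarray:
    """One split advance of the oxygen concentration over a step of size tau.

    x-sweep: (I - tau*zeta*dxx) c_bar = c^{old} - tau*v1*dx c^{old}
             - w_x*tau*beta*r(c^{old})*q_half  [+ w_x*tau*f_c]
    y-sweep: (I - tau*zeta*dyy) c^{new} = c_bar - tau*v2*dy c_bar
             - w_y*tau*beta*r(c_bar)*q_half   [+ w_y*tau*f_c]

    ``v1c, v2c`` are the convecting velocity at cell centres; boundary
    closures come from ``bc`` (model: Neumann sides/bottom, saturated c = 1
    at the top; mms: exact ghost data).
    """
    t_end = None if t_start is None else t_start + tau
    t_mid = None if t_start is None else t_start + 0.5 * tau
    wx, wy = weights
    kx = tau * params.zeta
    fsrc = 0.0
    if forcing is not None:
        fsrc = tau * forcing.fc(grid.xc[:, None], grid.yc[None, :], t_mid)

    cp = pad_scalar(c_prev, grid, "c", bc, params=params, t=t_start)
    dxc = (cp[2:, 1:-1] - cp[:-2, 1:-1]) / (2.0 * grid.hx)
    rhs = (c_prev - tau * v1c * dxc
           - wx * tau * params.beta * _r(c_prev, params) * q_half
           + wx * fsrc)
    if bc.mode == "mms":
        # the intermediate c_bar differs from c(t_end) by O(tau) at the
        # boundary; impose the corrected intermediate data instead
        cbar_bc = bc.case.cbar_fn(tau, wy)
        gl = _mms_ghost_line(cbar_bc, grid, "left", t_end)
        gr = _mms_ghost_line(cbar_bc, grid, "right", t_end)
        c_bar = solve_helmholtz_lines(kx, grid.hx, rhs.T, "ghost_known",
                                      "ghost_known", data_left=gl,
                                      data_right=gr).T
    else:
        c_bar = solve_helmholtz_lines(kx, grid.hx, rhs.T,
                                      "neumann", "neumann").T

    ky = tau * params.zeta
    if bc.mode == "mms":
        cbp = _pad_mms(c_bar, grid, cbar_bc, t_end)
    else:
        cbp = pad_scalar(c_bar, grid, "c", bc, params=params, t=t_end)
    dyc = (cbp[1:-1, 2:] - cbp[1:-1, :-2]) / (2.0 * grid.hy)
    rhs = (c_bar - tau * v2c * dyc
           - wy * tau * params.beta * _r(c_bar, params) * q_half
           + wy * fsrc)
    if bc.mode == "mms":
        gb = _mms_ghost_line(bc.case.c_fn, grid, "bottom", t_end)
        gt = _mms_ghost_line(bc.case.c_fn, grid, "top", t_end)
        c_new = solve_helmholtz_lines(ky, grid.hy, rhs, "ghost_known",
                                      "ghost_known", data_left=gb,
                                      data_right=gt)
    elif bc.ghost_mode == "literal":
        # ghost cell itself saturated: c_ghost = 1
        c_new = solve_helmholtz_lines(ky, grid.hy, rhs, "neumann",
                                      "ghost_known", data_right=1.0)
    else:
        c_new = solve_helmholtz_lines(ky, grid.hy, rhs, "neumann",
                                      "dirichlet_ghost", data_right=1.0)
    return c_new


def _chemo_term(qp: np.ndarray, cp: np.ndarray, params: PhysicalParams,
                grid: GridSpec, axis: int, form: str,
                zero_boundary_flux: bool = False) -> np.ndarray:
    """x- or y-part of the chemotaxis operator from ghost-padded fields.

    ``qp`` is padded along ``axis`` only as sliced below; ``cp`` is the fully
    padded oxygen field.  Conservative form: divergence of face fluxes
    F = avg(q r(c)) * dc/ds; with ``zero_boundary_flux`` the domain-boundary
    face fluxes are set to zero — the integral (finite-volume) form of the
    no-total-flux condition, which conserves cell mass exactly together with
    the Neumann diffusive closure.
    """
    h = grid.hx if axis == 0 else grid.hy
    if axis == 0:
        q_line = qp[:, 1:-1]      # (Nx+2, Ny)
        c_line = cp[:, 1:-1]
    else:
        q_line = qp[1:-1, :]      # (Nx, Ny+2)
        c_line = cp[1:-1, :]
    r_line = _r(c_line, params)
    if form == "conservative":
        qr = q_line * r_line
        if axis == 0:
            flux = 0.5 * (qr[:-1, :] + qr[1:, :]) * (c_line[1:, :]
                                                     - c_line[:-1, :]) / h
            if zero_boundary_flux:
                flux[0, :] = 0.0
                flux[-1, :] = 0.0
            return (flux[1:, :] - flux[:-1, :]) / h
        flux = 0.5 * (qr[:, :-1] + qr[:, 1:]) * (c_line[:, 1:]
                                                 - c_line[:, :-1]) / h
        if zero_boundary_flux:
            flux[:, 0] = 0.0
            flux[:, -1] = 0.0
        return (flux[:, 1:] - flux[:, :-1]) / h
    if form == "literal":
        if axis == 0:
            dq = (q_line[2:, :] - q_line[:-2, :]) / (2.0 * h)
            dc = (c_line[2:, :] - c_line[:-2, :]) / (2.0 * h)
            rmid = r_line[1:-1, :]
        else:
            dq = (q_line[:, 2:] - q_line[:, :-2]) / (2.0 * h)
            dc = (c_line[:, 2:] - c_line[:, :-2]) / (2.0 * h)
            rmid = r_line[:, 1:-1]
        return dq * rmid * dc
    raise ValueError(f"unknown chemotaxis form {form!r}")


def cell_update(q_prev: np.ndarray, c_new: np.ndarray,
                v1c: np.ndarray, v2c: np.ndarray,
                params: PhysicalParams, grid: GridSpec, bc: BCSpec,
                tau: float, t_start: float | None = None,
                chemo_form: str = "conservative",
                q_top_closure: str = "auto",
                forcing=None) -> np.ndarray:
    """One split advance of the cell density over a step of size tau.

    x-sweep: (I - tau*dxx) q_bar = q^{old} - tau*v1*dx q^{old}
             - tau*alpha*Cx(q^{old}, c^{new})  [+ tau/2*f_q]
    y-sweep: (I - tau*dyy) q^{new} = q_bar - tau*v2*dy q_bar
             - tau*alpha*Cy(q_bar, c^{new})    [+ tau/2*f_q]

    ``c_new`` is the freshly updated oxygen field of the same (sub-)step.
    The top closure of the y-sweep uses the chemotactic-flux ghost
    q_ghost = q * exp(alpha*(1 - c)), which is linear in the unknown top
    value and therefore enters the tridiagonal diagonal directly.
    """
    t_end = None if t_start is None else t_start + tau
    t_mid = None if t_start is None else t_start + 0.5 * tau
    fsrc = 0.0
    if forcing is not None:
        fsrc = tau * forcing.fq(grid.xc[:, None], grid.yc[None, :], t_mid)

    if q_top_closure == "auto":
        q_top_closure = "flux" if chemo_form == "conservative" else "exp"
    zero_flux = (bc.mode == "model" and q_top_closure == "flux")
    cp = pad_scalar(c_new, grid, "c", bc, params=params, t=t_end)
    qp = pad_scalar(q_prev, grid, "q", bc, params=params, t=t_start, c=c_new)
    dxq = (qp[2:, 1:-1] - qp[:-2, 1:-1]) / (2.0 * grid.hx)
    Cx = _chemo_term(qp, cp, params, grid, 0, chemo_form,
                     zero_boundary_flux=zero_flux)
    rhs = q_prev - tau * v1c * dxq - tau * params.alpha * Cx + 0.5 * fsrc
    if bc.mode == "mms":
        # corrected intermediate boundary data (see oxygen_update)
        qbar_bc = bc.case.qbar_fn(tau)
        gl = _mms_ghost_line(qbar_bc, grid, "left", t_end)
        gr = _mms_ghost_line(qbar_bc, grid, "right", t_end)
        q_bar = solve_helmholtz_lines(tau, grid.hx, rhs.T, "ghost_known",
                                      "ghost_known", data_left=gl,
                                      data_right=gr).T
    else:
        q_bar = solve_helmholtz_lines(tau, grid.hx, rhs.T,
                                      "neumann", "neumann").T

    if bc.mode == "mms":
        qbp = _pad_mms(q_bar, grid, qbar_bc, t_end)
    else:
        qbp = pad_scalar(q_bar, grid, "q", bc, params=params, t=t_end,
                         c=c_new)
    dyq = (qbp[1:-1, 2:] - qbp[1:-1, :-2]) / (2.0 * grid.hy)
    Cy = _chemo_term(qbp, cp, params, grid, 1, chemo_form,
                     zero_boundary_flux=zero_flux)
    rhs = q_bar - tau * v2c * dyq - tau * params.alpha * Cy + 0.5 * fsrc
    if bc.mode == "mms":
        gb = _mms_ghost_line(bc.case.q_fn, grid, "bottom", t_end)
        gt = _mms_ghost_line(bc.case.q_fn, grid, "top", t_end)
        q_out = solve_helmholtz_lines(tau, grid.hy, rhs, "ghost_known",
                                      "ghost_known", data_left=gb,
                                      data_right=gt)
    elif zero_flux:
        # integral form of the zero-total-flux interface condition: both the
        # diffusive and chemotactic fluxes vanish through every boundary
        # face, so total cell mass is conserved exactly
        q_out = solve_helmholtz_lines(tau, grid.hy, rhs, "neumann", "neumann")
    else:
        lam = np.exp(params.alpha * (1.0 - c_new[:, -1]))
        q_out = solve_helmholtz_lines(tau, grid.hy, rhs, "neumann",
                                      "robin_ghost", lam_right=lam)
    return q_out
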