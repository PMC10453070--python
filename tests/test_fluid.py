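"""Fluid step: predictor, ADI viscous correction, split pressure update."""

import numpy as np
import pytest

from chemoflow.fluid import (FluidHistory, adi_viscous_correction,
                             buoyancy_force, explicit_predictor, fluid_advance,
                             pressure_update)
from chemoflow.grid import BCSpec, build_grid, face_divergence
from chemoflow.params import PhysicalParams
from chemoflow.tridiag import solve_helmholtz_lines


def zero_hist(g, dt=1e-3):
    z = np.zeros
    return FluidHistory(z(g.v1_shape), z(g.v2_shape), z(g.v1_shape),
                        z(g.v2_shape), z(g.center_shape), z(g.center_shape),
                        dt)


def test_buoyancy_force_trivial_cases(unit_grid):
    g = unit_grid
    p = PhysicalParams(Sc=500, gamma=5000)
    assert np.allclose(buoyancy_force(np.zeros(g.center_shape), p), 0.0)
    p0 = PhysicalParams(Sc=500, gamma=0.0)
    assert np.allclose(buoyancy_force(np.ones(g.center_shape), p0), 0.0)
    f = buoyancy_force(np.full(g.center_shape, 0.8), p)
    assert f.shape == (g.Nx, g.Ny - 1)
    assert np.allclose(f, 500 * 5000 * 0.8)


def test_predictor_zero_state_stays_zero(unit_grid, model_bc):
    g = unit_grid
    hist = zero_hist(g)
    v1t, v2t = explicit_predictor(hist, np.zeros(g.center_shape),
                                  PhysicalParams(), g, model_bc)
    assert np.allclose(v1t, 0.0) and np.allclose(v2t, 0.0)


def test_predictor_buoyancy_only(unit_grid, model_bc):
    """With everything zero but a constant q*, only the buoyancy survives:
    v2~ = -dt*Sc*gamma*q0 at interior horizontal faces."""
    g = unit_grid
    dt = 1e-3
    hist = zero_hist(g, dt)
    q0 = 0.7
    p = PhysicalParams(Sc=500, gamma=5000)
    v1t, v2t = explicit_predictor(hist, np.full(g.center_shape, q0), p, g,
                                  model_bc)
    assert np.allclose(v1t, 0.0)
    assert np.allclose(v2t[:, 1:-1], -dt * 500 * 5000 * q0, rtol=1e-13)
    assert np.allclose(v2t[:, 0], 0.0) and np.allclose(v2t[:, -1], 0.0)


def test_predictor_matches_loop_implementation(unit_grid, model_bc, rng):
    """Straight-line nested-loop evaluation of the discrete momentum
    predictor against the vectorized implementation."""
    g = unit_grid
    dt = 2e-3
    p = PhysicalParams(alpha=1, beta=1, gamma=3.0, Sc=2.0, eta=1)
    v1a = rng.standard_normal(g.v1_shape)
    v2a = rng.standard_normal(g.v2_shape)
    v1b = rng.standard_normal(g.v1_shape)
    v2b = rng.standard_normal(g.v2_shape)
    pr = rng.standard_normal(g.center_shape)
    ps = rng.standard_normal(g.center_shape)
    qs = rng.standard_normal(g.center_shape)
    hist = FluidHistory(v1a, v2a, v1b, v2b, pr, ps, dt)
    got1, got2 = explicit_predictor(hist, qs, p, g, model_bc)

    v1s = 1.5 * v1a - 0.5 * v1b
    v2s = 1.5 * v2a - 0.5 * v2b
    pstar = pr + ps
    hx, hy, Sc = g.hx, g.hy, p.Sc

    def gh1(v, i, j):  # v1-type array with reflected no-slip ghosts in y
        if j < 0 or j >= g.Ny:
            return -v[i, min(max(j, 0), g.Ny - 1)]
        return v[i, j]

    def gh2(v, i, j):  # v2-type array with reflected ghosts in x
        if i < 0 or i >= g.Nx:
            return -v[min(max(i, 0), g.Nx - 1), j]
        return v[i, j]

    ref1 = np.zeros(g.v1_shape)
    for i in range(1, g.Nx):
        for j in range(g.Ny):
            conv = (v1s[i, j] * (v1s[i + 1, j] - v1s[i - 1, j]) / (2 * hx)
                    + 0.25 * (v2s[i - 1, j] + v2s[i, j] + v2s[i - 1, j + 1]
                              + v2s[i, j + 1])
                    * (gh1(v1s, i, j + 1) - gh1(v1s, i, j - 1)) / (2 * hy))
            lap = ((v1a[i - 1, j] - 2 * v1a[i, j] + v1a[i + 1, j]) / hx**2
                   + (gh1(v1a, i, j - 1) - 2 * v1a[i, j]
                      + gh1(v1a, i, j + 1)) / hy**2)
            gp = (pstar[i, j] - pstar[i - 1, j]) / hx
            ref1[i, j] = v1a[i, j] + dt * (-conv - Sc * gp + Sc * lap)
    assert np.allclose(got1, ref1, atol=1e-12)

    ref2 = np.zeros(g.v2_shape)
    for i in range(g.Nx):
        for j in range(1, g.Ny):
            conv = (0.25 * (v1s[i, j - 1] + v1s[i + 1, j - 1] + v1s[i, j]
                            + v1s[i + 1, j])
                    * (gh2(v2s, i + 1, j) - gh2(v2s, i - 1, j)) / (2 * hx)
                    + v2s[i, j] * (v2s[i, j + 1] - v2s[i, j - 1]) / (2 * hy))
            lap = ((gh2(v2a, i - 1, j) - 2 * v2a[i, j]
                    + gh2(v2a, i + 1, j)) / hx**2
                   + (v2a[i, j - 1] - 2 * v2a[i, j] + v2a[i, j + 1]) / hy**2)
            gp = (pstar[i, j] - pstar[i, j - 1]) / hy
            force = Sc * p.gamma * 0.5 * (qs[i, j - 1] + qs[i, j])
            ref2[i, j] = v2a[i, j] + dt * (-conv - Sc * gp + Sc * lap - force)
    assert np.allclose(got2, ref2, atol=1e-12)


def test_adi_trivial_and_degenerate(unit_grid, model_bc):
    g = unit_grid
    z1, z2 = np.zeros(g.v1_shape), np.zeros(g.v2_shape)
    v1n, v2n = adi_viscous_correction(z1, z2, z1, z2, PhysicalParams(), g,
                                      model_bc, 1e-3)
    assert np.allclose(v1n, 0.0) and np.allclose(v2n, 0.0)
    # Sc = 0: the implicit operators reduce to the identity
    rng = np.random.default_rng(1)
    v1t = rng.standard_normal(g.v1_shape)
    v2t = rng.standard_normal(g.v2_shape)
    v1t[0] = v1t[-1] = 0.0
    v2t[:, 0] = v2t[:, -1] = 0.0
    p0 = PhysicalParams(Sc=0.0)
    v1n, v2n = adi_viscous_correction(v1t, v2t, z1, z2, p0, g, model_bc, 1e-3)
    assert np.allclose(v1n, v1t, atol=1e-13)
    assert np.allclose(v2n, v2t, atol=1e-13)


def test_pressure_update_zero_velocity(unit_grid):
    g = unit_grid
    z1, z2 = np.zeros(g.v1_shape), np.zeros(g.v2_shape)
    p_old = np.random.default_rng(2).standard_normal(g.center_shape)
    psi, p_new = pressure_update(z1, z2, z1, z2, p_old, PhysicalParams(), g,
                                 1e-3)
    assert np.allclose(psi, 0.0)
    assert np.allclose(p_new, p_old)


def test_pressure_update_constant_divergence(unit_params):
    """Constant divergence d0: constants are Neumann eigenvectors, so
    psi = -d0/dt exactly (unit Schmidt number)."""
    g = build_grid(0, 1, 0, 1, 6, 5)
    dt = 1e-2
    v1 = np.broadcast_to(g.x[:, None], g.v1_shape).copy()  # div = 1
    v2 = np.zeros(g.v2_shape)
    psi, _ = pressure_update(v1, v2, np.zeros_like(v1), np.zeros_like(v2),
                             np.zeros(g.center_shape), unit_params, g, dt)
    assert np.allclose(psi, -1.0 / dt, rtol=1e-11)


def test_pressure_split_matches_dense_factorized_operator(unit_params, rng):
    """The two 1D sweeps solve (I-dxx)(I-dyy) psi = -div/(Sc dt): compare
    with a dense Kronecker solve on a 6x5 grid."""
    g = build_grid(0, 1, 0, 1, 6, 5)
    dt = 1.0  # unit step keeps psi O(1), so 1e-11 agreement is meaningful
    v1 = rng.standard_normal(g.v1_shape)
    v2 = rng.standard_normal(g.v2_shape)
    psi, _ = pressure_update(v1, v2, np.zeros_like(v1), np.zeros_like(v2),
                             np.zeros(g.center_shape), unit_params, g, dt)

    def helm1d(n, h):
        r = 1.0 / h**2
        A = (1 + 2 * r) * np.eye(n)
        A += np.diag(np.full(n - 1, -r), 1) + np.diag(np.full(n - 1, -r), -1)
        A[0, 0] -= r
        A[-1, -1] -= r
        return A

    Ax = helm1d(g.Nx, g.hx)
    Ay = helm1d(g.Ny, g.hy)
    rhs = -face_divergence(v1, v2, g) / (unit_params.Sc * dt)
    dense = np.linalg.solve(np.kron(Ax, Ay), rhs.ravel()).reshape(g.Nx, g.Ny)
    assert np.max(np.abs(psi - dense)) < 1e-11


def test_pressure_sweeps_commute(rng):
    """Factorized operator: x- and y-sweeps commute to machine precision."""
    g = build_grid(0, 1, 0, 1, 9, 7)
    rhs = rng.standard_normal(g.center_shape)
    xy = solve_helmholtz_lines(1.0, g.hy,
                               solve_helmholtz_lines(1.0, g.hx, rhs.T,
                                                     "neumann", "neumann").T,
                               "neumann", "neumann")
    yx = solve_helmholtz_lines(1.0, g.hx,
                               solve_helmholtz_lines(1.0, g.hy, rhs,
                                                     "neumann", "neumann").T,
                               "neumann", "neumann").T
    assert np.max(np.abs(xy - yx)) < 1e-13


def test_unforced_velocity_stays_zero(unit_grid, model_bc):
    """gamma = 0, zero initial velocity, no-slip walls: the velocity remains
    identically zero over many steps."""
    g = unit_grid
    p = PhysicalParams(gamma=0.0, Sc=100.0)
    hist = zero_hist(g, 1e-3)
    q = np.full(g.center_shape, 0.9)
    for _ in range(5):
        v1n, v2n, psi, pn = fluid_advance(hist, q, p, g, model_bc)
        assert np.allclose(v1n, 0.0) and np.allclose(v2n, 0.0)
        hist = FluidHistory(v1n, v2n, hist.v1_nm1, hist.v2_nm1, pn, psi,
                            hist.dt)


def test_divergence_shrinks_with_dt(unit_params):
    """Pressure stabilization: ||div u|| at a fixed time decreases when dt
    is halved (manufactured run on a coarse grid)."""
    from chemoflow.mms import build_mms_case
    from chemoflow.timeloop import RunConfig, Simulation

    case = build_mms_case(unit_params)
    norms = []
    for dt in (0.02, 0.01):
        cfg = RunConfig(xa=-1, xb=1, ya=-1, yb=1, Nx=16, Ny=16, dt=dt, T=0.2,
                        params=unit_params, bc_mode="mms", ic="mms",
                        mms_case=case, cfl_warn=False)
        sim = Simulation(cfg)
        for _ in range(int(round(0.2 / dt))):
            s = sim.advance()
        div = face_divergence(s.v1, s.v2, sim.grid)
        norms.append(np.sqrt(np.mean(div**2)))
    assert norms[1] < norms[0]
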