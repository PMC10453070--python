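"""Staggered-grid geometry, discrete operators and ghost layers."""

import numpy as np
import pytest

from chemoflow.grid import (BCSpec, apply_scalar_ghosts, build_grid,
                            center_diff, cross_velocity_at_points,
                            face_divergence, pad_scalar,
                            pressure_gradient_to_faces,
                            velocity_derivatives_at_own_points,
                            velocity_to_centers)
from chemoflow.params import PhysicalParams


@pytest.mark.parametrize("bounds,N,expect", [
    ((0, 1, 0, 1), (4, 4), {"hx": 0.25, "xc0": 0.125}),
    ((-1, 1, -1, 1), (50, 50), {"hx": 0.04}),
    ((-3, 3, 0, 1), (300, 200), {"hx": 0.02, "hy": 0.005}),
])
def test_build_grid_spacings(bounds, N, expect):
    g = build_grid(*bounds, *N)
    if "hx" in expect:
        assert g.hx == pytest.approx(expect["hx"], abs=1e-15)
    if "hy" in expect:
        assert g.hy == pytest.approx(expect["hy"], abs=1e-15)
    if "xc0" in expect:
        assert g.xc[0] == pytest.approx(expect["xc0"], abs=1e-15)
    # invariants: spacing times count spans the domain; centres offset hx/2
    assert g.hx * g.Nx == pytest.approx(bounds[1] - bounds[0], rel=1e-14)
    assert np.allclose(g.xc - g.x[:-1], g.hx / 2)
    assert g.xc[0] > g.x[0] and g.xc[-1] < g.x[-1]


def test_build_grid_rejects_bad_input():
    with pytest.raises(ValueError):
        build_grid(0, 0, 0, 1, 4, 4)
    with pytest.raises(ValueError):
        build_grid(0, 1, 0, 1, 2, 4)


def test_center_diff_exact_on_polynomials(unit_grid):
    g = unit_grid
    X, Y = np.meshgrid(g.xc, g.yc, indexing="ij")
    assert np.allclose(center_diff(X, g.hx, 0, 1), 1.0, atol=1e-13)
    d1 = center_diff(X**2, g.hx, 0, 1)
    assert np.allclose(d1, 2 * X[1:-1, :], atol=1e-12)
    assert np.allclose(center_diff(X**2, g.hx, 0, 2), 2.0, atol=1e-11)
    assert np.allclose(center_diff(Y**2, g.hy, 1, 2), 2.0, atol=1e-11)


def test_center_diff_matches_dense_stencil(unit_grid, rng):
    g = unit_grid
    F = rng.standard_normal(g.center_shape)
    n = g.Nx
    D1 = (np.diag(np.ones(n - 1), 1) - np.diag(np.ones(n - 1), -1)) / (2 * g.hx)
    dense = (D1 @ F)[1:-1, :]
    assert np.allclose(center_diff(F, g.hx, 0, 1), dense, atol=1e-13)
    D2 = (np.diag(np.ones(n - 1), 1) + np.diag(np.ones(n - 1), -1)
          - 2 * np.eye(n)) / g.hx**2
    assert np.allclose(center_diff(F, g.hx, 0, 2), (D2 @ F)[1:-1, :],
                       atol=1e-13)


def test_center_diff_rejects_bad_axis(unit_grid):
    with pytest.raises(ValueError):
        center_diff(np.zeros(unit_grid.center_shape), unit_grid.hx, 2, 1)
    with pytest.raises(ValueError):
        center_diff(np.zeros(unit_grid.center_shape), unit_grid.hx, 0, 3)


def test_velocity_derivatives_are_the_central_stencils(unit_grid, rng):
    g = unit_grid
    v1 = rng.standard_normal(g.v1_shape)
    assert np.allclose(velocity_derivatives_at_own_points(v1, "dx", g),
                       center_diff(v1, g.hx, 0, 1))
    assert np.allclose(velocity_derivatives_at_own_points(v1, "dyy", g),
                       center_diff(v1, g.hy, 1, 2))
    with pytest.raises(ValueError):
        velocity_derivatives_at_own_points(v1, "dxy", g)


def test_face_divergence_constants_and_linear(unit_grid):
    g = unit_grid
    v1 = np.full(g.v1_shape, 3.0)
    v2 = np.full(g.v2_shape, -1.5)
    assert np.allclose(face_divergence(v1, v2, g), 0.0, atol=1e-14)
    # v1 = x on faces, v2 = -y on faces: exactly divergence-free discretely
    v1 = np.broadcast_to(g.x[:, None], g.v1_shape).copy()
    v2 = np.broadcast_to(-g.y[None, :], g.v2_shape).copy()
    assert np.allclose(face_divergence(v1, v2, g), 0.0, atol=1e-13)


def test_face_divergence_matches_loop(unit_grid, rng):
    g = unit_grid
    v1 = rng.standard_normal(g.v1_shape)
    v2 = rng.standard_normal(g.v2_shape)
    ref = np.zeros(g.center_shape)
    for i in range(g.Nx):
        for j in range(g.Ny):
            ref[i, j] = ((v1[i + 1, j] - v1[i, j]) / g.hx
                         + (v2[i, j + 1] - v2[i, j]) / g.hy)
    assert np.allclose(face_divergence(v1, v2, g), ref, atol=1e-14)


def test_divergence_of_discrete_curl_vanishes(unit_grid, rng):
    """MAC compatibility: the discrete curl of any nodal stream function is
    exactly divergence-free."""
    g = unit_grid
    phi = rng.standard_normal((g.Nx + 1, g.Ny + 1))
    v1 = (phi[:, 1:] - phi[:, :-1]) / g.hy
    v2 = -(phi[1:, :] - phi[:-1, :]) / g.hx
    assert np.abs(face_divergence(v1, v2, g)).max() < 1e-12


def test_pressure_gradient(unit_grid, rng):
    g = unit_grid
    gx, gy = pressure_gradient_to_faces(np.full(g.center_shape, 2.5), g)
    assert np.allclose(gx, 0.0) and np.allclose(gy, 0.0)
    X = np.broadcast_to(g.xc[:, None], g.center_shape).copy()
    gx, gy = pressure_gradient_to_faces(X, g)
    assert np.allclose(gx, 1.0, atol=1e-13)
    assert np.allclose(gy, 0.0, atol=1e-14)
    p = rng.standard_normal(g.center_shape)
    gx, gy = pressure_gradient_to_faces(p, g)
    for i in range(1, g.Nx):
        for j in range(g.Ny):
            assert gx[i - 1, j] == pytest.approx(
                (p[i, j] - p[i - 1, j]) / g.hx, abs=1e-14)


def test_velocity_to_centers(unit_grid, rng):
    g = unit_grid
    v1 = np.full(g.v1_shape, 4.0)
    v2 = np.full(g.v2_shape, -2.0)
    c1, c2 = velocity_to_centers(v1, v2)
    assert np.allclose(c1, 4.0) and np.allclose(c2, -2.0)
    # averaging is exact for fields linear in the averaged coordinate
    v1 = np.broadcast_to(g.x[:, None], g.v1_shape).copy()
    c1, _ = velocity_to_centers(v1, v2)
    assert np.allclose(c1, np.broadcast_to(g.xc[:, None], g.center_shape),
                       atol=1e-14)
    v1 = rng.standard_normal(g.v1_shape)
    c1, _ = velocity_to_centers(v1, v2)
    for i in range(g.Nx):
        for j in range(g.Ny):
            assert c1[i, j] == pytest.approx(
                0.5 * (v1[i, j] + v1[i + 1, j]), abs=1e-14)


def test_cross_velocity_averaging(unit_grid, rng):
    g = unit_grid
    v2 = np.full(g.v2_shape, 7.0)
    assert np.allclose(cross_velocity_at_points(v2, g, "v1"), 7.0)
    # bilinear field: four-point average is exact at the midpoint
    Xf, Yf = np.meshgrid(g.xc, g.y, indexing="ij")
    v2 = 2.0 + 3.0 * Xf + 0.5 * Yf + 1.5 * Xf * Yf
    got = cross_velocity_at_points(v2, g, "v1")
    Xt, Yt = np.meshgrid(g.x[1:-1], g.yc, indexing="ij")
    assert np.allclose(got, 2.0 + 3.0 * Xt + 0.5 * Yt + 1.5 * Xt * Yt,
                       atol=1e-13)
    v1 = rng.standard_normal(g.v1_shape)
    got = cross_velocity_at_points(v1, g, "v2")
    i, j = 3, 2  # interior v2 point
    assert got[i, j - 1] == pytest.approx(
        0.25 * (v1[i, j - 1] + v1[i + 1, j - 1] + v1[i, j] + v1[i + 1, j]),
        abs=1e-14)


class TestScalarGhosts:
    def test_saturated_interface_gives_neutral_q_ghost(self, unit_grid,
                                                       model_bc):
        g = unit_grid
        q = np.random.default_rng(0).uniform(0.5, 2.0, g.center_shape)
        c = np.ones(g.center_shape)
        qp, cp = apply_scalar_ghosts(q, c, g, PhysicalParams(), model_bc)
        assert np.allclose(qp[1:-1, -1], q[:, -1])  # exponent is zero
        assert np.allclose(cp[1:-1, -1], 1.0)       # literal ghost

    def test_alpha_zero_gives_neutral_q_ghost(self, unit_grid, model_bc):
        g = unit_grid
        q = np.full(g.center_shape, 1.3)
        c = np.full(g.center_shape, 0.6)
        p = PhysicalParams(alpha=0.0)
        qp, _ = apply_scalar_ghosts(q, c, g, p, model_bc)
        assert np.allclose(qp[1:-1, -1], 1.3)

    def test_exponential_ghost_value(self, unit_grid, model_bc):
        # q=1, c=0.9 at the interface with alpha=10 -> ghost = e
        g = unit_grid
        q = np.ones(g.center_shape)
        c = np.full(g.center_shape, 0.9)
        p = PhysicalParams(alpha=10.0)
        qp, _ = apply_scalar_ghosts(q, c, g, p, model_bc)
        assert np.allclose(qp[1:-1, -1], np.e, atol=1e-12)

    def test_zero_gradient_sides_and_bottom(self, unit_grid, model_bc, rng):
        g = unit_grid
        q = rng.uniform(0.5, 1.0, g.center_shape)
        c = rng.uniform(0.5, 1.0, g.center_shape)
        qp, cp = apply_scalar_ghosts(q, c, g, PhysicalParams(), model_bc)
        for P, F in ((qp, q), (cp, c)):
            assert np.allclose(P[0, 1:-1], F[0, :])
            assert np.allclose(P[-1, 1:-1], F[-1, :])
            assert np.allclose(P[1:-1, 0], F[:, 0])

    def test_ghost_application_idempotent(self, unit_grid, model_bc, rng):
        g = unit_grid
        q = rng.uniform(0.5, 1.0, g.center_shape)
        c = rng.uniform(0.5, 1.0, g.center_shape)
        p = PhysicalParams()
        a = apply_scalar_ghosts(q, c, g, p, model_bc)
        b = apply_scalar_ghosts(q, c, g, p, model_bc)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_reflected_oxygen_ghost(self, unit_grid, rng):
        g = unit_grid
        bc = BCSpec(mode="model", ghost_mode="reflected")
        c = rng.uniform(0.5, 1.0, g.center_shape)
        cp = pad_scalar(c, g, "c", bc)
        assert np.allclose(cp[1:-1, -1], 2.0 - c[:, -1])
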