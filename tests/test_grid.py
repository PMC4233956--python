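"""Staggered-grid operators and the fast-transform Stokes solver."""

import numpy as np
import pytest

from ibfelv.grid import (MacState, StokesSolver, convective_term, divergence,
                         gradient, laplacian, stokes_solve)

L = 15.0


def _rand_state(N, rng, interior=3):
    st = MacState.zeros(N, L)
    for c in st.u:
        sl = tuple(slice(interior, -interior) for _ in range(3))
        c[sl] = rng.standard_normal(c[sl].shape)
    return st


def test_divergence_of_uniform_and_linear_fields():
    N = 16
    st = MacState.zeros(N, L)
    st.u1[:] = 2.0
    st.u2[:] = -1.0
    st.u3[:] = 0.5
    assert np.abs(divergence(st)).max() == 0.0
    h = st.h
    x_faces = np.arange(N + 1) * h
    st.u1 = np.broadcast_to(x_faces[:, None, None], (N + 1, N, N)).copy()
    st.u2 = np.broadcast_to(-x_faces[None, :, None], (N, N + 1, N)).copy()
    st.u3[:] = 0.0
    assert np.abs(divergence(st)).max() < 1e-13


def test_gradient_of_constant_pressure_interior():
    N = 16
    p = np.full((N, N, N), 7.0)
    g = gradient(p, L / N)
    # interior faces see no gradient; boundary faces feel the p=0 wall value
    assert np.abs(g[0][1:-1]).max() == 0.0
    assert np.abs(g[1][:, 1:-1]).max() == 0.0


def test_discrete_duality_divergence_gradient(rng):
    """<div u, p> = -<u, grad p> for interior-supported fields."""
    N = 16
    u = _rand_state(N, rng)
    p = np.zeros((N, N, N))
    p[2:-2, 2:-2, 2:-2] = rng.standard_normal((N - 4,) * 3)
    g = gradient(p, u.h)
    lhs = np.sum(divergence(u) * p)
    rhs = -(np.sum(u.u1 * g[0]) + np.sum(u.u2 * g[1]) + np.sum(u.u3 * g[2]))
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_div_grad_equals_seven_point_laplacian(rng):
    """Operator identity div(grad p) = cell-centered 7-point Laplacian with
    the p = 0 wall ghosts."""
    N = 12
    h = L / N
    p = rng.standard_normal((N, N, N))
    g = gradient(p, h)
    dg = MacState(u1=g[0], u2=g[1], u3=g[2], p=p, h=h, domain=L)
    lap = divergence(dg)
    # explicit 7-point stencil with odd-reflection ghosts
    pad = np.pad(p, 1, mode="constant")
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = 0
        hi[ax] = -1
        src_lo = [slice(1, -1)] * 3
        src_hi = [slice(1, -1)] * 3
        src_lo[ax] = 1
        src_hi[ax] = -2
        pad[tuple(lo)] = -pad[tuple(src_lo)]
        pad[tuple(hi)] = -pad[tuple(src_hi)]
    ref = -6.0 * p.copy()
    for ax in range(3):
        for s in (-1, 1):
            idx = [slice(1, -1)] * 3
            idx[ax] = slice(1 + s, pad.shape[ax] - 1 + s)
            ref += pad[tuple(idx)]
    np.testing.assert_allclose(lap, ref / h ** 2, atol=1e-12)


def test_laplacian_of_linear_field_interior():
    N = 16
    h = L / N
    x = np.arange(N + 1) * h
    u = np.broadcast_to(x[:, None, None], (N + 1, N, N)).copy()
    lap = laplacian(u, 0, h)
    assert np.abs(lap[2:-2, 2:-2, 2:-2]).max() < 1e-12


def test_convective_term_uniform_flow_vanishes():
    st = MacState.zeros(16, L)
    st.u1[:] = 1.0
    st.u2[:] = 0.5
    st.u3[:] = -0.3
    conv = convective_term(st)
    assert max(np.abs(c).max() for c in conv) < 1e-14


def test_convective_term_second_order_on_smooth_profile():
    errs = []
    for N in (32, 64):
        st = MacState.zeros(N, L)
        h = st.h
        x = np.arange(N + 1) * h
        g = np.sin(2 * np.pi * x / L) ** 2 + 0.5
        st.u1 = np.broadcast_to(g[:, None, None], (N + 1, N, N)).copy()
        conv = convective_term(st)
        gp = 2 * np.sin(2 * np.pi * x / L) * np.cos(2 * np.pi * x / L) * 2 * np.pi / L
        errs.append(np.abs(conv[0][:, N // 2, N // 2] - g * gp).max())
    assert errs[0] / errs[1] > 3.0


def test_convective_term_mirror_antisymmetry(rng):
    """Mirroring the velocity field about the x-midplane flips the sign of
    the x-convective component at mirrored locations."""
    N = 16
    st = _rand_state(N, rng)
    stm = MacState.zeros(N, L)
    stm.u1 = -st.u1[::-1]
    stm.u2 = st.u2[::-1]
    stm.u3 = st.u3[::-1]
    c = convective_term(st)
    cm = convective_term(stm)
    np.testing.assert_allclose(cm[0], -c[0][::-1], atol=1e-12)
    np.testing.assert_allclose(cm[1], c[1][::-1], atol=1e-12)


def test_stokes_zero_input(rng):
    sol = StokesSolver(16, L, 1e-3, 0.04, 1.0)
    u0 = tuple(np.zeros(s) for s in [(17, 16, 16), (16, 17, 16), (16, 16, 17)])
    u1, p = sol.solve(u0, u0)
    assert max(np.abs(c).max() for c in u1) == 0.0
    assert p.std() == 0.0


def test_stokes_solve_is_exact_on_both_blocks(rng):
    """Momentum and continuity residuals of the CN system at round-off."""
    N = 16
    dt, mu, rho = 1e-3, 0.5, 1.0
    sol = StokesSolver(N, L, dt, mu, rho)
    h = sol.h
    f = tuple(rng.standard_normal(s) for s in
              [(N + 1, N, N), (N, N + 1, N), (N, N, N + 1)])
    u0 = tuple(0.01 * rng.standard_normal(c.shape) for c in f)
    u1, p = sol.solve(u0, f)
    st = MacState(u1=u1[0], u2=u1[1], u3=u1[2], p=p, h=h, domain=L)
    scale = max(np.abs(np.concatenate([c.ravel() for c in f])))
    assert np.abs(divergence(st)).max() * h / max(st.max_speed(), 1e-30) < 1e-12
    g = gradient(p, h)
    for d in range(3):
        r = (rho * (u1[d] - u0[d]) / dt + g[d]
             - 0.5 * mu * (laplacian(u1[d], d, h) + laplacian(u0[d], d, h))
             - f[d])
        assert np.abs(r).max() < 1e-10 * scale


def test_stokes_manufactured_solution_second_order():
    """Velocity error vs a smooth exact steady Stokes solution decays at
    second order under grid refinement.

    Exact fields: divergence-free streamfunction velocity
    u = (F(x) F'(y) G(z), -F'(x) F(y) G(z), 0) with F = 1 - cos(2 pi x / L)
    (so tangential components vanish at every wall) and pressure
    p = sin(pi x/L) sin(pi y/L) sin(pi z/L) (zero on the walls).  A huge dt
    makes the single CN step a steady solve, exposing only the spatial
    truncation of the stencils.
    """
    mu, rho, dt = 0.7, 1.0, 1.0e6
    k = 2 * np.pi / L
    q = np.pi / L

    def F(x):
        return 1.0 - np.cos(k * x)

    def Fp(x):
        return k * np.sin(k * x)

    def Fpp(x):
        return k * k * np.cos(k * x)

    def Fppp(x):
        return -k ** 3 * np.sin(k * x)

    errs = []
    for N in (16, 32):
        sol = StokesSolver(N, L, dt, mu, rho)
        h = sol.h
        xf = np.arange(N + 1) * h
        xc = (np.arange(N) + 0.5) * h

        def grid3(a, b, c):
            return a[:, None, None] * b[None, :, None] * c[None, None, :]

        G = lambda z: np.sin(q * z)
        u1_ex = grid3(F(xf), Fp(xc), G(xc))
        u2_ex = grid3(-Fp(xc), F(xf), G(xc))
        u3_ex = np.zeros((N, N, N + 1))
        u_ex = (u1_ex, u2_ex, u3_ex)

        lap1 = grid3(Fpp(xf), Fp(xc), G(xc)) + grid3(F(xf), Fppp(xc), G(xc)) \
            - q * q * u1_ex
        lap2 = grid3(-Fppp(xc), F(xf), G(xc)) + grid3(-Fp(xc), Fpp(xf), G(xc)) \
            - q * q * u2_ex
        gp1 = grid3(q * np.cos(q * xf), np.sin(q * xc), np.sin(q * xc))
        gp2 = grid3(np.sin(q * xc), q * np.cos(q * xf), np.sin(q * xc))
        gp3 = grid3(np.sin(q * xc), np.sin(q * xc), q * np.cos(q * xf))
        f = (gp1 - mu * lap1, gp2 - mu * lap2, gp3)

        u_new, _ = sol.solve(u_ex, f)
        err = max(np.abs(u_new[d] - u_ex[d]).max() for d in range(3))
        errs.append(err)
    assert errs[0] / errs[1] > 3.0


def test_stokes_solve_wrapper_contract(rng):
    N = 16
    f = tuple(np.zeros(s) for s in [(N + 1, N, N), (N, N + 1, N), (N, N, N + 1)])
    for c in f:
        c[4:-4, 4:-4, 4:-4] = rng.standard_normal(c[4:-4, 4:-4, 4:-4].shape)
    u0 = tuple(np.zeros_like(c) for c in f)
    u1, p = stokes_solve(u0, f, dt=1e-3, mu=0.04, rho=1.0, domain=L)
    st = MacState(u1=u1[0], u2=u1[1], u3=u1[2], p=p, h=L / N, domain=L)
    assert np.abs(divergence(st)).max() * st.h <= 1e-10 * st.max_speed()


def test_solver_argument_validation():
    with pytest.raises(ValueError):
        StokesSolver(16, L, dt=-1.0, mu=0.04, rho=1.0)
    with pytest.raises(ValueError):
        StokesSolver(16, L, dt=1e-3, mu=0.04, rho=0.0)
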