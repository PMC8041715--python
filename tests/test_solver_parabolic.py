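"""Discrete operators and IMEX stepping of the diffusion-dominated system."""
import numpy as np
import pytest

from gliomapal import (
    Grid2D,
    MacroParams,
    ParabolicOperators,
    SolverConfig,
    SolverFields,
    State,
    TensorField,
    imex_step,
    laplacian_5pt,
    run_modified_system_5_1,
    run_parabolic,
    upwind_tendency,
    weickert_stencil,
)
from gliomapal.io_experiments import gaussian_sum


def unit_grid(n):
    return Grid2D.square(1.0, n)


class TestWeickertStencil:
    def test_isotropic_reduces_to_five_point(self):
        g = unit_grid(12)
        L = weickert_stencil(TensorField.isotropic(g, 2.5), g.h)
        L5 = laplacian_5pt(g.nx, g.ny, g.h)
        assert abs(L - 2.5 * L5).max() < 1e-12

    def test_quadratic_field_constant_anisotropic(self):
        # for constant diag(a, b) the operator is exact on x^2: gives 2a
        g = unit_grid(16)
        a, c = 0.7, 0.2
        L = weickert_stencil(TensorField(g, a, 0.0, c), g.h)
        X, Y = g.meshgrid()
        res = (L @ (X**2).ravel()).reshape(g.shape)
        assert np.allclose(res[1:-1, 1:-1], 2 * a, rtol=1e-10)
        res = (L @ (Y**2).ravel()).reshape(g.shape)
        assert np.allclose(res[1:-1, 1:-1], 2 * c, rtol=1e-10)

    def test_mixed_term_via_diagonal_stencil(self):
        # constant off-diagonal b: apply to xy gives 2b in the interior
        g = unit_grid(16)
        b = 0.15
        L = weickert_stencil(TensorField(g, 0.5, b, 0.5), g.h)
        X, Y = g.meshgrid()
        res = (L @ (X * Y).ravel()).reshape(g.shape)
        assert np.allclose(res[1:-1, 1:-1], 2 * b, rtol=1e-10)

    def test_checkerboard_free_on_linear_fields(self):
        # constant (possibly mixed) tensor: div(D grad lin) = 0 exactly
        g = unit_grid(14)
        L = weickert_stencil(TensorField(g, 0.6, 0.2, 0.5), g.h)
        X, Y = g.meshgrid()
        lin = 0.3 * X + 0.7 * Y + 1.0
        res = (L @ lin.ravel()).reshape(g.shape)
        assert np.abs(res[1:-1, 1:-1]).max() <= 1e-12 / g.h

    def test_conservation_structure(self, aniso_fields):
        L = weickert_stencil(aniso_fields.DT, aniso_fields.h)
        assert np.abs(L.sum(axis=1)).max() < 1e-12  # constants in the kernel
        assert np.abs(L.sum(axis=0)).max() < 1e-12  # exact mass conservation
        assert abs(L - L.T).max() < 1e-15

    def test_nonnegative_off_diagonals_under_weickert_condition(self):
        g = unit_grid(10)
        L = weickert_stencil(TensorField(g, 0.5, 0.2, 0.4), g.h).tocoo()
        off = L.data[L.row != L.col]
        assert off.min() >= 0.0

    def test_non_psd_rejected(self):
        g = unit_grid(8)
        with pytest.raises(ValueError, match="node"):
            weickert_stencil(TensorField(g, 0.1, 0.5, 0.1), g.h)


class TestLaplacian:
    def test_annihilates_constants(self):
        L = laplacian_5pt(9, 9, 0.1)
        assert np.abs(L @ np.ones(81)).max() < 1e-12

    def test_discrete_neumann_eigenpair(self):
        # cell-centered cosine modes diagonalize the edge-assembled operator:
        # v_i = cos(pi k (i + 1/2)/n), lambda = -(2/h^2)(1 - cos(pi k/n))
        n, h, k = 24, 0.05, 3
        g = Grid2D(nx=n, ny=5, h=h)
        L = laplacian_5pt(n, 5, h)
        i = np.arange(n)
        v = np.cos(np.pi * k * (i + 0.5) / n)
        field = np.repeat(v[:, None], 5, axis=1)
        lam = -(2.0 / h**2) * (1.0 - np.cos(np.pi * k / n))
        assert np.allclose((L @ field.ravel()).reshape(n, 5), lam * field, atol=1e-9)

    def test_zero_total_flux(self, rng):
        L = laplacian_5pt(13, 11, 0.2)
        S = rng.random(13 * 11)
        assert abs((L @ S).sum()) < 1e-12 * np.abs(L @ S).max()


class TestUpwind:
    def test_zero_velocity(self):
        M = np.random.default_rng(0).random((8, 8))
        T = upwind_tendency(M, np.zeros((7, 8)), np.zeros((8, 7)), 0.1)
        assert np.all(T == 0.0)

    def test_step_profile_upwind_from_the_left(self):
        h, v = 0.1, 0.3
        M = np.zeros((10, 5))
        M[:5, :] = 1.0
        T = upwind_tendency(M, np.full((9, 5), v), np.zeros((10, 4)), h)
        # interior rule: -v (M_i - M_{i-1})/h, nonzero only at the jump
        expected = np.zeros((10, 5))
        expected[5, :] = -v * (0.0 - 1.0) / h
        expected[0, :] = -v * M[0, 0] / h  # boundary face carries no influx
        assert np.allclose(T[1:-1, :], expected[1:-1, :], atol=1e-14)

    def test_monotone_no_new_extrema(self, rng):
        # advection alone (uniform velocity) creates no new extrema under CFL
        h, dt = 0.1, 0.02
        M = rng.random((20, 20))
        wx = np.full((19, 20), 0.8)
        wy = np.full((20, 19), -0.6)
        M1 = M + dt * upwind_tendency(M, wx, wy, h)
        # away from the no-flux walls (where inflow legitimately piles up)
        inner = (slice(1, -1), slice(1, -1))
        assert M1[inner].max() <= M.max() + 1e-12
        assert M1[inner].min() >= M.min() - 1e-12

    def test_conservation_on_random_fields(self, rng):
        M = rng.random((17, 13))
        wx = rng.normal(size=(16, 13))
        wy = rng.normal(size=(17, 12))
        T = upwind_tendency(M, wx, wy, 0.05)
        assert abs(T.sum()) < 1e-12 * np.abs(T).max() * T.size


class TestImexStep:
    def test_constant_acidity_decay(self):
        g = unit_grid(8)
        fields = SolverFields.isotropic(g, 1e-3)
        p = MacroParams(alpha=1.0, mu0=0.0)
        ops = ParabolicOperators(fields, p)
        st = imex_step(State(np.zeros(g.shape), np.full(g.shape, 2.0)), ops, p, 0.1)
        assert np.allclose(st.S, 2.0 / 1.1, rtol=1e-12)

    def test_zero_state_is_fixed(self):
        g = unit_grid(8)
        p = MacroParams(alpha=0.5, mu0=1.0)
        ops = ParabolicOperators(SolverFields.isotropic(g, 1e-3), p)
        st = imex_step(State(np.zeros(g.shape), np.zeros(g.shape)), ops, p, 0.2)
        assert np.all(st.M == 0.0) and np.all(st.S == 0.0)

    def test_reaction_matches_scalar_forward_euler(self):
        # spatially constant state: all transport vanishes, M follows the
        # explicit reaction update, S the implicit linear update
        g = unit_grid(8)
        p = MacroParams(alpha=0.8, mu0=0.3)
        ops = ParabolicOperators(SolverFields.isotropic(g, 1e-3), p)
        M0, S0, dt = 0.4, 1.7, 0.05
        st = imex_step(State(np.full(g.shape, M0), np.full(g.shape, S0)), ops, p, dt)
        m_expected = M0 + dt * p.mu0 * M0 * (1 - M0) * (1 - S0)
        s_expected = (S0 + dt * M0) / (1 + dt * p.alpha)
        assert np.allclose(st.M, m_expected, rtol=1e-12)
        assert np.allclose(st.S, s_expected, rtol=1e-12)


class TestRuns:
    def test_mass_conservation_without_source_or_taxis(self, aniso_fields):
        # myopic diffusion + drift only: the nodal sum of M is invariant
        p = MacroParams(alpha=0.01, mu0=0.0, taxis_on=False)
        grid = aniso_fields.grid
        ic = State(
            gaussian_sum(grid, [(0.5, 500.0, 500.0, 120.0)]),
            gaussian_sum(grid, [(1.0, 400.0, 500.0, 150.0)]),
        )
        cfg = SolverConfig(dt=0.5, t_end=500.0, snapshot_every=250)
        res = run_parabolic(aniso_fields, p, ic, cfg)
        masses = res.diagnostics["mass_M"].to_numpy()
        assert len(res.diagnostics) >= 3  # 1000 steps taken
        assert np.abs(masses - masses[0]).max() <= 1e-8 * masses[0]

    def test_zero_tumor_stays_zero_and_acid_decays(self, aniso_fields):
        p = MacroParams(alpha=0.1, mu0=0.5)
        grid = aniso_fields.grid
        ic = State(np.zeros(grid.shape), np.full(grid.shape, 0.7))
        res = run_parabolic(aniso_fields, p, ic, SolverConfig(dt=0.5, t_end=100.0))
        assert np.all(res.final.M == 0.0)
        assert res.final.S.max() < 0.7 * np.exp(-0.1 * 90)

    def test_positivity_in_death_regime(self, aniso_fields, experiment_params):
        grid = aniso_fields.grid
        ic = State(
            gaussian_sum(grid, [(0.9, 500.0, 500.0, 100.0)]),
            gaussian_sum(grid, [(3.0, 500.0, 500.0, 200.0)]),
        )
        res = run_parabolic(
            aniso_fields, experiment_params, ic, SolverConfig(dt=0.25, t_end=200.0)
        )
        assert min(float(s.M.min()) for s in res.snapshots) >= -1e-12
        assert min(float(s.S.min()) for s in res.snapshots) >= -1e-12

    def test_blowup_is_detected_not_raised(self):
        # supercritical reaction state: M > 1 with S > 1 grows superlinearly
        g = unit_grid(16)
        fields = SolverFields.isotropic(g, 1e-4)
        p = MacroParams(alpha=0.01, mu0=5.0, taxis_on=False)
        ic = State(np.full(g.shape, 1.5), np.full(g.shape, 2.0))
        res = run_parabolic(fields, p, ic, SolverConfig(dt=0.5, t_end=200.0))
        assert res.blowup_time is not None
        assert res.final.is_finite()

    def test_grid_convergence_first_order_regime(self):
        # refining the mesh must shrink the change between successive levels
        p = MacroParams(alpha=0.05, mu0=0.1)
        finals = {}
        for n in (25, 49, 97):
            g = unit_grid(n)
            fields = SolverFields.isotropic(g, 2e-3)
            ic = State(
                gaussian_sum(g, [(0.8, 0.5, 0.5, 0.12)]),
                gaussian_sum(g, [(1.5, 0.45, 0.5, 0.15)]),
            )
            res = run_parabolic(fields, p, ic, SolverConfig(dt=0.2, t_end=30.0))
            finals[n] = res.final.M
        coarse_err = np.abs(finals[25] - finals[49][::2, ::2]).mean()
        fine_err = np.abs(finals[49] - finals[97][::2, ::2]).mean()
        assert fine_err < 0.8 * coarse_err


class TestTaxisContribution:
    def test_taxis_matters_most_during_pattern_formation(self):
        # the taxis-on/taxis-off runs drift apart while the pattern forms and
        # reconverge later: the L1 gap peaks before the final time
        from gliomapal import run_preset

        res_taxis, _ = run_preset("experiment2_ic49", nx=41)
        res_plain, _ = run_preset("fig9_no_taxis", nx=41)
        gaps = [
            float(np.abs(a.M - b.M).mean())
            for a, b in zip(res_taxis.snapshots, res_plain.snapshots)
        ]
        peak = int(np.argmax(gaps))
        assert gaps[peak] > 0
        assert peak < len(gaps) - 1
        assert gaps[-1] < gaps[peak]


class TestModifiedSystem:
    def test_steady_state_is_preserved(self):
        g = unit_grid(24)
        fields = SolverFields.isotropic(g, 1e-3)
        p = MacroParams(alpha=1.0, zeta=0.5, mu0=0.05)
        ic = State(np.ones(g.shape), np.full(g.shape, 0.25))
        res = run_modified_system_5_1(fields, p, ic, SolverConfig(dt=1.0, t_end=200.0))
        assert np.abs(res.final.M - 1.0).max() < 1e-10
        assert np.abs(res.final.S - 0.25).max() < 1e-10

    def test_acidity_bound_and_lyapunov_monotone(self):
        g = unit_grid(24)
        fields = SolverFields.isotropic(g, 1e-3)
        p = MacroParams(alpha=1.0, zeta=0.5, mu0=0.05)
        ic = State(
            0.2 + gaussian_sum(g, [(0.5, 0.5, 0.5, 0.15)]),
            np.full(g.shape, 0.2),
        )
        res = run_modified_system_5_1(
            fields, p, ic, SolverConfig(dt=1.0, t_end=2000.0, snapshot_every=100)
        )
        d = res.diagnostics
        bound = max(p.zeta / p.alpha, 0.2)
        assert int(d["S_bound_violated"].sum()) == 0
        assert d["max_S"].max() <= bound + 1e-12
        F = d["lyapunov_F"].to_numpy(dtype=float)
        tail = F[len(F) // 4 :]
        assert np.all(np.diff(tail) <= 1e-10)

    def test_warns_outside_provable_regime(self):
        g = unit_grid(8)
        fields = SolverFields.isotropic(g, 1e-3)
        p = MacroParams(alpha=0.3, zeta=0.5, mu0=0.05)
        ic = State(np.ones(g.shape), np.full(g.shape, 0.2))
        with pytest.warns(UserWarning, match="provable regime"):
            run_modified_system_5_1(fields, p, ic, SolverConfig(dt=1.0, t_end=2.0))


class TestConfigValidation:
    def test_bad_dt(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0, t_end=1.0)

    def test_cfl_warning(self, aniso_fields):
        p = MacroParams(alpha=0.01, mu0=0.0)
        grid = aniso_fields.grid
        u_big = np.zeros(grid.shape + (2,))
        u_big[..., 0] = 50.0
        fields = SolverFields(grid=grid, h=aniso_fields.h, DT=aniso_fields.DT, u=u_big)
        ic = State(np.ones(grid.shape), np.zeros(grid.shape))
        with pytest.warns(UserWarning, match="CFL"):
            run_parabolic(fields, p, ic, SolverConfig(dt=1.0, t_end=2.0))
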