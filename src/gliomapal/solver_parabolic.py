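"""Finite-difference solver for the diffusion-dominated (parabolic-limit) system.

Nondimensional equations on a no-flux rectangle:

    dM/dt = div(D_T grad M) + div(u M) + div(g(S) M D_T grad S) + f(M, S)
    dS/dt = Lap S + P(M) - alpha S

where ``u = div D_T`` (myopic drift), ``g`` is the repellent pH-taxis
sensitivity, ``f`` the acid-modulated logistic source and ``P(M)`` either the
linear production ``M`` (baseline system) or the saturated
``zeta M/(1+M)`` (the modified system whose large-time behavior is known:
``M -> 1``, ``S -> zeta/(2 alpha)`` when ``zeta < alpha``, ``|S0| < 1`` and
the growth rate exceeds a computable threshold).

Discretization: the anisotropic diffusion uses the non-negative 3x3 stencil
of Weickert (directional derivatives along the stencil diagonals replace the
mixed term), assembled edge-by-edge so the operator is symmetric with zero
row and column sums — constants are in its kernel and the plain nodal sum of
M is conserved exactly under no-flux. Acidity diffusion uses the standard
5-point Laplacian. Advection (drift + taxis) is first-order upwind in flux
form; time stepping is IMEX Euler with both diffusion blocks (and the S decay
term) implicit, advection and sources explicit.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .coefficients import MacroParams, growth_source, proton_source, taxis_coefficient_g
from .grid import Grid2D, TensorField
from .tissue import SolverFields

__all__ = [
    "State",
    "SolverConfig",
    "SimulationResult",
    "weickert_stencil",
    "laplacian_5pt",
    "upwind_tendency",
    "ParabolicOperators",
    "imex_step",
    "run_parabolic",
    "run_modified_system_5_1",
]

BLOWUP_THRESHOLD = 1e6


@dataclass
class State:
    """Tumor density M (carrying-capacity units) and acidity S (S_max units)."""

    M: np.ndarray
    S: np.ndarray
    t: float = 0.0

    def copy(self) -> "State":
        return State(self.M.copy(), self.S.copy(), self.t)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.M)) and np.all(np.isfinite(self.S)))


@dataclass
class SolverConfig:
    """Time stepping controls.

    ``dt`` is the nondimensional step (advection and explicit sources impose
    a CFL-type bound which is checked at run time and warned about, not
    silently fixed); diffusion is implicit, so no parabolic restriction
    applies. ``snapshot_every`` counts steps between stored snapshots.
    ``clip_negative='clip_and_log'`` zeroes negative undershoots and logs the
    clipped mass; default is off because the scheme is positivity-preserving
    and clipping would mask genuine defects.
    """

    dt: float
    t_end: float
    snapshot_every: int = 50
    cfl_safety: float = 0.8
    clip_negative: Literal["off", "clip_and_log"] = "off"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if not 0 < self.cfl_safety <= 1:
            raise ValueError("cfl_safety must lie in (0, 1]")


@dataclass
class SimulationResult:
    """Snapshots plus per-snapshot diagnostics of a run."""

    times: np.ndarray
    snapshots: list[State]
    diagnostics: pd.DataFrame
    params: MacroParams
    blowup_time: float | None = None
    clipped_mass: float = 0.0

    @property
    def final(self) -> State:
        return self.snapshots[-1]


def weickert_stencil(DT: TensorField, h: float) -> sparse.csr_matrix:
    """Non-negative 3x3 discretization of ``div(D_T grad M)``.

    Mixed-derivative contributions are carried by directional differences
    along the stencil diagonals: with ``b+ = max(b, 0)`` and ``b- = max(-b,
    0)`` the edge conductivities are

        axial x : (a_P + a_Q - |b|_P - |b|_Q) / (2 h^2)
        axial y : (c_P + c_Q - |b|_P - |b|_Q) / (2 h^2)
        NE/SW   : (b+_P + b+_Q) / (2 h^2)
        NW/SE   : (b-_P + b-_Q) / (2 h^2)

    assembled symmetrically per edge (diagonal = minus the row sum). Interior
    rows reproduce the classical 3x3 stencil; omitting edges through the
    boundary realizes the discrete no-flux condition, and zero column sums
    make the nodal sum of M exactly conserved. Off-diagonal weights are
    non-negative wherever ``|D12| <= min(D11, D22)`` holds nodewise.

    Raises if any nodal tensor fails positive semidefiniteness.
    """
    a, b, c = DT.dxx, DT.dxy, DT.dyy
    l2 = DT.eigenvalues()[1]
    scale = max(float(np.abs(DT.trace()).max()), 1.0)
    if l2.min() < -1e-12 * scale:
        i, j = np.unravel_index(int(np.argmin(l2)), l2.shape)
        raise ValueError(f"tumor diffusion tensor not PSD at node ({i}, {j})")
    nx, ny = a.shape
    idx = np.arange(nx * ny).reshape(nx, ny)
    babs = np.abs(b)
    bp = 0.5 * (babs + b)  # positive part
    bm = 0.5 * (babs - b)  # negative part

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add_edges(P: np.ndarray, Q: np.ndarray, w: np.ndarray) -> None:
        P, Q, w = P.ravel(), Q.ravel(), w.ravel()
        rows.extend([P, Q, P, Q])
        cols.extend([Q, P, P, Q])
        vals.extend([w, w, -w, -w])

    inv2h2 = 1.0 / (2.0 * h * h)
    # axial edges
    add_edges(
        idx[:-1, :], idx[1:, :],
        (a[:-1, :] + a[1:, :] - babs[:-1, :] - babs[1:, :]) * inv2h2,
    )
    add_edges(
        idx[:, :-1], idx[:, 1:],
        (c[:, :-1] + c[:, 1:] - babs[:, :-1] - babs[:, 1:]) * inv2h2,
    )
    # diagonal edges: NE/SW carries the positive part of b, NW/SE the negative
    add_edges(idx[:-1, :-1], idx[1:, 1:], (bp[:-1, :-1] + bp[1:, 1:]) * inv2h2)
    add_edges(idx[1:, :-1], idx[:-1, 1:], (bm[1:, :-1] + bm[:-1, 1:]) * inv2h2)

    L = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    )
    return L.tocsr()


def laplacian_5pt(nx: int, ny: int, h: float) -> sparse.csr_matrix:
    """Standard 5-point Laplacian with homogeneous Neumann boundary.

    Edge-assembled like :func:`weickert_stencil` with unit isotropic
    conductivity: symmetric, zero row/column sums, annihilates constants.
    """
    grid = Grid2D(nx=nx, ny=ny, h=h)
    return weickert_stencil(TensorField.isotropic(grid, 1.0), h)


def upwind_tendency(M: np.ndarray, wx: np.ndarray, wy: np.ndarray, h: float) -> np.ndarray:
    """First-order upwind tendency ``-div(w M)`` for face transport velocity w.

    ``wx`` lives on x-faces (shape (nx-1, ny)), ``wy`` on y-faces
    (nx, ny-1); boundary faces carry zero flux. The telescoping flux form
    conserves the nodal sum of M exactly and creates no new extrema
    (monotone) under the CFL condition.
    """
    Fx = np.where(wx > 0, wx * M[:-1, :], wx * M[1:, :])
    Fy = np.where(wy > 0, wy * M[:, :-1], wy * M[:, 1:])
    T = np.zeros_like(M)
    T[:-1, :] -= Fx
    T[1:, :] += Fx
    T[:, :-1] -= Fy
    T[:, 1:] += Fy
    return T / h


def _face_mean_x(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A[:-1, :] + A[1:, :])


def _face_mean_y(A: np.ndarray) -> np.ndarray:
    return 0.5 * (A[:, :-1] + A[:, 1:])


class ParabolicOperators:
    """Pre-assembled spatial operators for one (tissue, parameter) pair.

    The diffusion operators depend only on the frozen tissue fields, so the
    implicit matrices are factorized once per time-step size and reused.
    """

    def __init__(
        self,
        fields: SolverFields,
        params: MacroParams,
        system: Literal["baseline", "saturated"] = "baseline",
    ):
        self.fields = fields
        self.params = params
        self.system = system
        self.h = fields.h
        self.shape = fields.grid.shape
        self.L_M = weickert_stencil(fields.DT, self.h)
        self.L_S = laplacian_5pt(*self.shape, self.h)
        # face-interpolated tensor components and myopic drift
        self.DTxx_fx = _face_mean_x(fields.DT.dxx)
        self.DTxy_fx = _face_mean_x(fields.DT.dxy)
        self.DTxy_fy = _face_mean_y(fields.DT.dxy)
        self.DTyy_fy = _face_mean_y(fields.DT.dyy)
        self.ux_f = _face_mean_x(fields.u[..., 0])
        self.uy_f = _face_mean_y(fields.u[..., 1])
        self._lu_M = None
        self._lu_S = None
        self._dt = None

    def prepare(self, dt: float, need_M: bool = True) -> None:
        if self._dt == dt and (self._lu_M is not None or not need_M):
            return
        n = self.L_S.shape[0]
        I = sparse.identity(n, format="csc")
        if need_M:
            self._lu_M = splu((I - dt * self.L_M).tocsc())
        self._lu_S = splu(((1.0 + dt * self.params.alpha) * I - dt * self.L_S).tocsc())
        self._dt = dt

    # -- explicit pieces -------------------------------------------------
    def advection_velocity(self, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Transport velocity ``w = -(u + g(S) D_T grad S)`` at faces."""
        h = self.h
        wx = -self.ux_f.copy()
        wy = -self.uy_f.copy()
        if self.params.taxis_on:
            g = taxis_coefficient_g(S, self.params)
            dSdx = np.gradient(S, h, axis=0)
            dSdy = np.gradient(S, h, axis=1)
            # x-faces: normal derivative exact at the face, tangential averaged
            dSdx_fx = (S[1:, :] - S[:-1, :]) / h
            dSdy_fx = _face_mean_x(dSdy)
            g_fx = _face_mean_x(g)
            wx -= g_fx * (self.DTxx_fx * dSdx_fx + self.DTxy_fx * dSdy_fx)
            dSdy_fy = (S[:, 1:] - S[:, :-1]) / h
            dSdx_fy = _face_mean_y(dSdx)
            g_fy = _face_mean_y(g)
            wy -= g_fy * (self.DTxy_fy * dSdx_fy + self.DTyy_fy * dSdy_fy)
        return wx, wy

    def max_face_speed(self, S: np.ndarray) -> float:
        wx, wy = self.advection_velocity(S)
        mx = float(np.abs(wx).max()) if wx.size else 0.0
        my = float(np.abs(wy).max()) if wy.size else 0.0
        return max(mx, my)

    def source_M(self, M: np.ndarray, S: np.ndarray) -> np.ndarray:
        return growth_source(M, S, self.params)

    def source_S(self, M: np.ndarray) -> np.ndarray:
        return proton_source(M, self.params, self.system)

    def explicit_rhs_M(self, M: np.ndarray, S: np.ndarray) -> np.ndarray:
        """Full right-hand side of the M-equation evaluated explicitly.

        Used by tests and as the epsilon-scaled correction block of the
        hyperbolic-limit solver; the IMEX stepper itself treats the
        diffusion part implicitly.
        """
        diff = (self.L_M @ M.ravel()).reshape(self.shape)
        wx, wy = self.advection_velocity(S)
        return diff + upwind_tendency(M, wx, wy, self.h) + self.source_M(M, S)


def imex_step(state: State, ops: ParabolicOperators, params: MacroParams, dt: float) -> State:
    """One IMEX Euler step: explicit advection/sources, implicit diffusion.

    The S decay ``-alpha S`` is folded into the implicit S solve (a constant
    S with M = 0 decays as ``S/(1 + dt*alpha)`` per step); the M source is
    explicit, so a spatially constant state follows the forward-Euler
    reaction update exactly.
    """
    ops.prepare(dt)
    M, S = state.M, state.S
    wx, wy = ops.advection_velocity(S)
    rhs_M = M + dt * (upwind_tendency(M, wx, wy, ops.h) + ops.source_M(M, S))
    M_new = ops._lu_M.solve(rhs_M.ravel()).reshape(ops.shape)
    rhs_S = S + dt * ops.source_S(M)
    S_new = ops._lu_S.solve(rhs_S.ravel()).reshape(ops.shape)
    return State(M_new, S_new, state.t + dt)


def _lyapunov(M: np.ndarray, S: np.ndarray, params: MacroParams, C_M: float, h: float) -> float | None:
    """Energy functional of the modified system; None where ln M is undefined."""
    if np.any(M <= 0):
        return None
    s_star = params.zeta / (2.0 * params.alpha)
    cell = h * h
    return float(
        cell * np.sum(M - 1.0 - np.log(M)) + 0.5 * C_M * cell * np.sum((S - s_star) ** 2)
    )


def _run(
    fields: SolverFields,
    params: MacroParams,
    ic: State,
    config: SolverConfig,
    system: Literal["baseline", "saturated"],
) -> SimulationResult:
    ops = ParabolicOperators(fields, params, system=system)
    ops.prepare(config.dt)
    h = ops.h
    cell = h * h
    n_steps = int(round(config.t_end / config.dt))

    speed = ops.max_face_speed(ic.S)
    if speed > 0 and config.dt > config.cfl_safety * h / speed:
        warnings.warn(
            f"dt={config.dt:g} exceeds the advective CFL bound "
            f"{config.cfl_safety * h / speed:g}; expect loss of monotonicity",
            stacklevel=2,
        )

    # steady state the diagnostics track
    if system == "saturated":
        S_star = params.zeta / (2.0 * params.alpha)
        s_bound = max(params.zeta / params.alpha, float(ic.S.max()))
    else:
        S_star = 1.0 / params.alpha
        s_bound = np.nan
    l1, l2 = fields.DT.eigenvalues()
    theta_ell = float(l2.min())
    D0 = float(l1.max())
    C_M = (
        D0**2 * params.Lambda**2 / (4.0 * theta_ell * params.K**4 * (params.K + params.B) ** 2)
        if theta_ell > 0
        else np.nan
    )

    state = State(np.asarray(ic.M, dtype=float).copy(), np.asarray(ic.S, dtype=float).copy(), ic.t)
    snapshots = [state.copy()]
    rows = []
    clipped = 0.0
    blowup_time = None

    def record(st: State) -> None:
        X, Y = fields.grid.meshgrid()
        mass = float(st.M.sum())
        com_x = float((st.M * X).sum() / mass) if mass > 0 else np.nan
        com_y = float((st.M * Y).sum() / mass) if mass > 0 else np.nan
        rows.append(
            {
                "t": st.t,
                "mass_M": cell * mass,
                "mass_S": cell * float(st.S.sum()),
                "min_M": float(st.M.min()),
                "max_M": float(st.M.max()),
                "min_S": float(st.S.min()),
                "max_S": float(st.S.max()),
                "sup_M_err": float(np.abs(st.M - 1.0).max()),
                "sup_S_err": float(np.abs(st.S - S_star).max()),
                "S_bound": s_bound,
                "S_bound_violated": bool(st.S.max() > s_bound + 1e-12)
                if np.isfinite(s_bound)
                else False,
                "lyapunov_F": _lyapunov(st.M, st.S, params, C_M, h)
                if system == "saturated" and np.isfinite(C_M)
                else None,
                "com_x": com_x,
                "com_y": com_y,
            }
        )

    record(state)
    for step in range(1, n_steps + 1):
        state = imex_step(state, ops, params, config.dt)
        if config.clip_negative == "clip_and_log":
            neg = state.M < 0
            if np.any(neg):
                clipped += -cell * float(state.M[neg].sum())
                state.M[neg] = 0.0
        if not state.is_finite() or max(state.M.max(), state.S.max()) > BLOWUP_THRESHOLD:
            blowup_time = state.t
            break
        if step % config.snapshot_every == 0 or step == n_steps:
            snapshots.append(state.copy())
            record(state)

    return SimulationResult(
        times=np.array([s.t for s in snapshots]),
        snapshots=snapshots,
        diagnostics=pd.DataFrame(rows),
        params=params,
        blowup_time=blowup_time,
        clipped_mass=clipped,
    )


def run_parabolic(
    fields: SolverFields, params: MacroParams, ic: State, config: SolverConfig
) -> SimulationResult:
    """Integrate the baseline nondimensional system (linear proton production).

    On blow-up (non-finite values or fields exceeding 1e6) the run stops and
    reports ``blowup_time`` together with the last finite snapshot instead of
    raising.
    """
    return _run(fields, params, ic, config, system="baseline")


def run_modified_system_5_1(
    fields: SolverFields, params: MacroParams, ic: State, config: SolverConfig
) -> SimulationResult:
    """Integrate the modified system with saturated proton production.

    Diagnostics include the sup-norm distances to the known attractor
    ``(1, zeta/(2 alpha))``, the a-priori acidity bound
    ``max(zeta/alpha, |S0|_inf)`` (flagged per snapshot if exceeded) and the
    Lyapunov functional ``int(M - 1 - ln M) + (C_M/2) int (S -
    zeta/(2 alpha))^2``. Outside the theorem regime (``zeta >= alpha`` or
    ``|S0|_inf >= 1``) a warning is issued and the run proceeds.
    """
    if params.zeta >= params.alpha or float(np.asarray(ic.S).max()) >= 1.0:
        warnings.warn(
            "outside the provable regime (need zeta < alpha and sup S0 < 1); running anyway",
            stacklevel=2,
        )
    return _run(fields, params, ic, config, system="saturated")
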