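"""Steady states, linear stability and pattern quantification.

The pseudopalisade signature is quantified by a radial ring score around the
acidity peak: a hypocellular acidic center surrounded by a hypercellular
garland yields a positive score, a centered or monotonically decaying tumor
a non-positive one. Linear stability of the homogeneous coexistence state is
scanned over wavenumbers to test for Turing (diffusion/taxis-driven)
instability; the repellent taxis enters the dispersion relation as a
cross-diffusion coupling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .coefficients import MacroParams, taxis_coefficient_g
from .grid import Grid2D
from .solver_parabolic import SimulationResult

__all__ = [
    "StabilityReport",
    "RingMetrics",
    "steady_states",
    "mu_star",
    "jacobian_k2",
    "turing_scan",
    "ring_metrics",
    "convergence_report",
]


def steady_states(params: MacroParams, system: str = "baseline") -> list[tuple[float, float]]:
    """Spatially homogeneous steady states (M*, S*).

    Baseline system: the trivial (0, 0) and the coexistence state
    ``(1, 1/alpha)`` (logistic root M = 1 balanced against ``S = M/alpha``).
    Saturated system: (0, 0) and ``(1, zeta/(2 alpha))`` since the proton
    source at carrying capacity is ``zeta/2``.
    """
    if system == "baseline":
        return [(0.0, 0.0), (1.0, 1.0 / params.alpha)]
    if system == "saturated":
        return [(0.0, 0.0), (1.0, params.zeta / (2.0 * params.alpha))]
    raise ValueError(f"unknown system {system!r}")


def mu_star(params: MacroParams, D0: float, theta_ell: float, S0_inf: float) -> float:
    """Growth-rate threshold above which the energy method certifies decay.

    ``mu* = zeta^2 C_M / (4 alpha (1 - max(zeta/alpha, |S0|_inf)))`` with
    ``C_M = D0^2 Lambda^2 / (4 theta K^4 (K + B)^2)``; ``D0`` bounds the
    tumor diffusion tensor, ``theta_ell`` its ellipticity constant.
    Requires the contraction regime ``max(zeta/alpha, |S0|_inf) < 1``.
    """
    cap = max(params.zeta / params.alpha, S0_inf)
    if cap >= 1.0:
        raise ValueError("threshold defined only for max(zeta/alpha, sup S0) < 1")
    C_M = D0**2 * params.Lambda**2 / (
        4.0 * theta_ell * params.K**4 * (params.K + params.B) ** 2
    )
    return params.zeta**2 * C_M / (4.0 * params.alpha * (1.0 - cap))


@dataclass
class StabilityReport:
    steady_state: tuple[float, float]
    jacobian: np.ndarray  # reaction Jacobian at k^2 = 0
    k2_grid: np.ndarray
    growth_rates: np.ndarray  # max Re(eigenvalue) per k^2
    turing_unstable: bool
    background_unstable: bool
    most_unstable_k2: float | None

    @property
    def max_growth_rate(self) -> float:
        return float(self.growth_rates.max())


def jacobian_k2(
    params: MacroParams, dT: float, k2, M_star: float = 1.0, include_taxis: bool = True
) -> np.ndarray:
    """Linearization ``J(k^2)`` of the baseline system about ``(M*, M*/alpha)``.

    Perturbations ``~ exp(lambda t + i k.x)`` obey ``z' = J(k^2) z`` with

        J(k^2) = [[f_M - dT k^2,  f_S - g(S*) dT M* k^2],
                  [1,             -alpha - k^2]]

    for constant scalar tumor diffusivity ``dT``; the off-diagonal k^2 entry
    is the linearized repellent-taxis flux (set ``include_taxis=False`` to
    scan pure diffusion).
    """
    S_star = M_star / params.alpha
    f_M = params.mu0 * (1.0 - 2.0 * M_star) * (1.0 - S_star)
    f_S = -params.mu0 * M_star * (1.0 - M_star)
    taxis = taxis_coefficient_g(S_star, params) * dT * M_star if include_taxis else 0.0
    k2 = np.asarray(k2, dtype=float)
    J = np.zeros(k2.shape + (2, 2))
    J[..., 0, 0] = f_M - dT * k2
    J[..., 0, 1] = f_S - taxis * k2
    J[..., 1, 0] = 1.0
    J[..., 1, 1] = -params.alpha - k2
    return J


def turing_scan(
    params: MacroParams,
    dT: float,
    k2_grid: np.ndarray | None = None,
    include_taxis: bool = True,
) -> StabilityReport:
    """Scan the dispersion relation for diffusion/taxis-driven instability.

    ``turing_unstable`` is True only when the homogeneous state is stable to
    uniform perturbations (k = 0) yet some k^2 > 0 grows. When the
    background itself is unstable (the regime of very weak proton buffering,
    alpha < 1, where S* = 1/alpha exceeds the death threshold), the flag is
    False and ``background_unstable`` is set — whatever patterns emerge there
    are not of Turing type.
    """
    if k2_grid is None:
        k2_grid = np.logspace(-2, 4, 200)
    k2_grid = np.asarray(k2_grid, dtype=float)
    J_all = jacobian_k2(params, dT, k2_grid, include_taxis=include_taxis)
    eigs = np.linalg.eigvals(J_all)
    growth = eigs.real.max(axis=-1)
    J0 = jacobian_k2(params, dT, 0.0, include_taxis=include_taxis)
    rate0 = float(np.linalg.eigvals(J0).real.max())
    background_unstable = rate0 >= 0.0
    unstable_k = growth > max(rate0, 0.0) + 1e-14
    turing = bool((not background_unstable) and np.any(growth > 1e-14))
    most = float(k2_grid[np.argmax(growth)]) if turing else None
    return StabilityReport(
        steady_state=(1.0, 1.0 / params.alpha),
        jacobian=J0,
        k2_grid=k2_grid,
        growth_rates=growth,
        turing_unstable=turing,
        background_unstable=background_unstable,
        most_unstable_k2=most,
    )


@dataclass
class RingMetrics:
    """Radial pseudopalisade metrics around one acidity peak.

    ``ring_score = (rim_value - center_value) / max(rim_value, tiny)`` from
    the azimuthally averaged tumor profile; positive iff the rim (profile
    maximum away from the center) exceeds the central density. ``rim_width``
    is the full width (same length unit as the grid) of the profile around
    the rim above half its prominence.
    """

    center: tuple[float, float]
    radii: np.ndarray
    radial_profile: np.ndarray
    rim_radius: float
    rim_value: float
    center_value: float
    ring_score: float
    rim_width: float
    secondary: list["RingMetrics"] = field(default_factory=list)


def _ring_at(M: np.ndarray, grid: Grid2D, center_idx: tuple[int, int]) -> RingMetrics:
    X, Y = grid.meshgrid()
    cx, cy = grid.x[center_idx[0]], grid.y[center_idx[1]]
    r = np.hypot(X - cx, Y - cy)
    bins = np.floor(r / grid.h + 0.5).astype(int)
    counts = np.bincount(bins.ravel())
    sums = np.bincount(bins.ravel(), weights=M.ravel())
    profile = sums / counts
    radii = grid.h * np.arange(profile.size)
    center_value = float(profile[0])
    rim_idx = int(np.argmax(profile[1:])) + 1 if profile.size > 1 else 0
    rim_value = float(profile[rim_idx])
    score = (rim_value - center_value) / max(rim_value, 1e-30)
    prominence = rim_value - center_value
    level = rim_value - 0.5 * abs(prominence)
    above = profile >= level
    lo = rim_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = rim_idx
    while hi < profile.size - 1 and above[hi + 1]:
        hi += 1
    return RingMetrics(
        center=(float(cx), float(cy)),
        radii=radii,
        radial_profile=profile,
        rim_radius=float(radii[rim_idx]),
        rim_value=rim_value,
        center_value=center_value,
        ring_score=float(score),
        rim_width=float(radii[hi] - radii[lo]),
    )


def ring_metrics(M: np.ndarray, S: np.ndarray, grid: Grid2D) -> RingMetrics:
    """Ring metrics at the global acidity maximum; secondary peaks attached.

    Local acidity maxima above half the global maximum each get their own
    metric (multi-focus initial conditions produce several hypoxic centers);
    the primary one is at the global maximum. Deterministic given the
    fields, and invariant under quarter-turn rotations of both.
    """
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    peak_mask = (ndimage.maximum_filter(S, size=3, mode="nearest") == S) & (
        S >= 0.5 * S.max()
    )
    labels, n_found = ndimage.label(peak_mask)
    centers = []
    for lab in range(1, n_found + 1):
        ii, jj = np.nonzero(labels == lab)
        k = int(np.argmax(S[ii, jj]))
        centers.append((int(ii[k]), int(jj[k])))
    global_idx = tuple(int(v) for v in np.unravel_index(np.argmax(S), S.shape))
    primary = _ring_at(M, grid, global_idx)
    primary.secondary = [
        _ring_at(M, grid, c) for c in centers if c != global_idx
    ]
    return primary


def convergence_report(result: SimulationResult, params: MacroParams) -> pd.DataFrame:
    """Long-time diagnostics table with a fitted decay rate.

    Columns: time, sup-norm errors to the attractor, the acidity bound
    violations. The decay rate ``r`` of ``|M - 1|_inf ~ C exp(-r t)`` is fit
    by log-linear least squares on the second half of the run and attached as
    ``DataFrame.attrs['rate']`` with its R^2; an identically-zero error
    sequence yields rate None (reported as converged).
    """
    d = result.diagnostics
    if len(d) < 10:
        raise ValueError("need at least 10 snapshots for a convergence report")
    out = d[["t", "sup_M_err", "sup_S_err"]].copy()
    if "S_bound_violated" in d:
        out["S_bound_violated"] = d["S_bound_violated"]
        out.attrs["bound_violations"] = int(d["S_bound_violated"].sum())
    tail = out.iloc[len(out) // 2 :]
    err = tail["sup_M_err"].to_numpy()
    t = tail["t"].to_numpy()
    positive = err > 0
    if positive.sum() < 3:
        out.attrs["rate"] = None
        out.attrs["r_squared"] = None
        return out
    logs = np.log(err[positive])
    slope, intercept = np.polyfit(t[positive], logs, 1)
    pred = slope * t[positive] + intercept
    ss_res = float(((logs - pred) ** 2).sum())
    ss_tot = float(((logs - logs.mean()) ** 2).sum())
    out.attrs["rate"] = float(-slope)
    out.attrs["r_squared"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return out
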