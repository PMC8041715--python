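"""Microscale receptor kinetics and the scalar coefficients of the PDEs.

The subcellular model is first-order binding of extracellular protons to
transmembrane units: ``dy/dt = k+ (S/S_max)(1 - y) - k- y`` with equilibrium
``y* = (S/S_max) / (S/S_max + k_D)``, ``k_D = k-/k+``. Deviations from that
equilibrium modulate the cells' turning rate ``lambda(z) = lambda0 -
lambda1 z`` and, after upscaling, survive only through the repellent
pH-taxis sensitivity ``g(S)``.

All solver-facing quantities are nondimensional; :func:`nondimensionalize`
maps a dimensional parameter table onto them.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

__all__ = [
    "MicroParams",
    "MacroParams",
    "DimensionalParams",
    "Scales",
    "receptor_equilibrium",
    "binding_ode_step",
    "taxis_coefficient_g",
    "nondimensionalize",
    "growth_source",
    "proton_source",
]


@dataclass(frozen=True)
class MicroParams:
    """Receptor binding/unbinding rates (1/s) and the acidity death threshold."""

    k_plus: float = 0.004
    k_minus: float = 0.01
    S_max: float = 10.0 ** (-6.4)  # mol/l

    def __post_init__(self) -> None:
        if min(self.k_plus, self.k_minus, self.S_max) <= 0:
            raise ValueError("micro-scale parameters must be positive")

    @property
    def kD(self) -> float:
        return self.k_minus / self.k_plus


@dataclass(frozen=True)
class MacroParams:
    """Nondimensional constants of the macroscopic tumor-acidity system.

    ``lambda0_t = lambda0/k+`` and ``lambda1_t = lambda1/k+`` are the scaled
    turning-rate coefficients; ``kD`` the receptor dissociation constant;
    ``alpha`` the acidity removal-to-production ratio; ``mu0`` the scaled
    growth rate; ``zeta`` the saturated proton-production coefficient of the
    modified system; ``epsilon`` the hyperbolic scaling parameter.

    ``source_variant`` selects the tumor source: ``acid_death`` is
    ``mu0 M (1 - M)(1 - S)`` (negative above the death threshold S = 1,
    required for pseudopalisades), ``acid_saturated`` is
    ``mu0 (1 - M) M / (1 + S)`` (never negative: proliferation merely slows
    with acidity). ``taxis_on = False`` switches the pH-taxis flux off
    (the g = 0 comparison).
    """

    alpha: float = 0.02
    mu0: float = 9.259e-4
    kD: float = 2.5
    lambda0_t: float = 25.0
    lambda1_t: float = 25.0
    zeta: float = 0.5
    epsilon: float = 1e-5
    source_variant: Literal["acid_death", "acid_saturated"] = "acid_death"
    taxis_on: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if min(self.alpha, self.kD, self.lambda0_t) <= 0 or min(self.mu0, self.lambda1_t) < 0:
            raise ValueError("macro parameters must be positive")

    # constants of the qualitative-analysis form g = Lambda/((S+K)^2 (S+K+B))
    @property
    def Lambda(self) -> float:
        return self.lambda1_t * self.kD

    @property
    def K(self) -> float:
        return self.kD

    @property
    def B(self) -> float:
        return self.lambda0_t

    def with_(self, **kwargs) -> "MacroParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional parameter table (point values; ranged entries default to
    documented picks: M_max = 1e7 cells/mm^3, D_s = 1e-6 mm^2/s,
    lambda1 = 0.1 1/s)."""

    M_max: float = 1e7  # cells/mm^3
    S_max: float = 10.0 ** (-6.4)  # mol/l
    s: float = 2.8e-6  # mm/s
    lambda0: float = 0.1  # 1/s
    lambda1: float = 0.1  # 1/s
    k_plus: float = 0.004  # 1/s
    k_minus: float = 0.01  # 1/s
    beta: float = 1e-9  # proton production rate
    alpha: float = 1e-11  # 1/s
    D_s: float = 1e-6  # mm^2/s
    mu0_per_day: float = 0.2  # 1/day

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Scales:
    """Characteristic scales: t_scale = S_max/(beta M_max) seconds,
    x_scale = sqrt(D_s t_scale) mm."""

    t_scale: float
    x_scale: float


SECONDS_PER_DAY = 86400.0


def receptor_equilibrium(S, mp: MicroParams) -> np.ndarray | float:
    """Equilibrium occupancy ``y* = (S/S_max)/(S/S_max + k_D)`` in [0, 1)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("proton concentration must be non-negative")
    r = S / mp.S_max
    out = r / (r + mp.kD)
    return float(out) if out.ndim == 0 else out


def binding_ode_step(y, S, dt: float, mp: MicroParams):
    """One RK4 step of the binding kinetics at frozen acidity ``S``.

    The ODE is linear, so RK4 reproduces the exact exponential relaxation to
    ``y*`` to O(dt^4).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")

    def G(yv):
        return mp.k_plus * (np.asarray(S, float) / mp.S_max) * (1.0 - yv) - mp.k_minus * yv

    k1 = G(y)
    k2 = G(y + 0.5 * dt * k1)
    k3 = G(y + 0.5 * dt * k2)
    k4 = G(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def taxis_coefficient_g(S_t, p: MacroParams) -> np.ndarray | float:
    """Nondimensional repellent-taxis sensitivity.

    ``g(S) = lambda1_t * kD / ((S + kD)^2 (S + kD + lambda0_t))``; positive
    and strictly decreasing on S >= 0 (cells respond less sensitively once
    receptors saturate). Identical to the analysis form
    ``Lambda / ((S + K)^2 (S + K + B))`` with Lambda = lambda1_t*kD, K = kD,
    B = lambda0_t.
    """
    S_t = np.asarray(S_t, dtype=float)
    out = p.lambda1_t * p.kD / ((S_t + p.kD) ** 2 * (S_t + p.kD + p.lambda0_t))
    return float(out) if out.ndim == 0 else out


def nondimensionalize(dp: DimensionalParams) -> tuple[MacroParams, Scales]:
    """Map the dimensional table onto nondimensional constants and scales.

    Formulas: ``t_scale = S_max/(beta M_max)``, ``x_scale = sqrt(D_s
    t_scale)``, ``alpha_t = (alpha/beta)(S_max/M_max)``, ``mu0_t = mu0 *
    t_scale`` (mu0 first converted from 1/day to 1/s), ``lambda_i_t =
    lambda_i / k+``.

    Unit convention: the table's ``beta`` and ``S_max`` must be supplied in a
    matching volume unit and ``M_max`` is treated as a pure count; the
    formulas are applied to the raw numbers. The published table mixes mol/l
    with per-mm^3 quantities, so the absolute magnitude of ``alpha_t`` and
    ``mu0_t`` depends on that convention — the qualitative regimes the model
    explores (orders of magnitude in alpha) do not.
    """
    t_scale = dp.S_max / (dp.beta * dp.M_max)
    x_scale = float(np.sqrt(dp.D_s * t_scale))
    mu0_s = dp.mu0_per_day / SECONDS_PER_DAY
    params = MacroParams(
        alpha=dp.alpha / dp.beta * dp.S_max / dp.M_max,
        mu0=mu0_s * t_scale,
        kD=dp.k_minus / dp.k_plus,
        lambda0_t=dp.lambda0 / dp.k_plus,
        lambda1_t=dp.lambda1 / dp.k_plus,
    )
    return params, Scales(t_scale=t_scale, x_scale=x_scale)


def redimensionalize(p: MacroParams, scales: Scales, dp_ref: DimensionalParams) -> DimensionalParams:
    """Invert :func:`nondimensionalize` given the reference scale anchors.

    The map is not square (several dimensional constants share one
    nondimensional group), so the anchors ``M_max, S_max, beta, D_s, k+``
    are taken from ``dp_ref`` and the remaining entries are reconstructed.
    Round-trips with :func:`nondimensionalize` to machine precision.
    """
    return replace(
        dp_ref,
        alpha=p.alpha * dp_ref.beta * dp_ref.M_max / dp_ref.S_max,
        mu0_per_day=p.mu0 / scales.t_scale * SECONDS_PER_DAY,
        lambda0=p.lambda0_t * dp_ref.k_plus,
        lambda1=p.lambda1_t * dp_ref.k_plus,
        k_minus=p.kD * dp_ref.k_plus,
    )


def growth_source(M, S_t, p: MacroParams) -> np.ndarray:
    """Nondimensional tumor source term f(M, S).

    ``acid_death``: ``mu0 M (1 - M)(1 - S)`` — logistic growth that reverses
    into decay wherever acidity exceeds the death threshold (S > 1), the
    mechanism that hollows out pseudopalisade centers.
    ``acid_saturated``: ``mu0 (1 - M) M / (1 + S)`` — proliferation damped by
    acidity but no acid-induced death (no pseudopalisades).
    """
    M = np.asarray(M, dtype=float)
    S_t = np.asarray(S_t, dtype=float)
    if p.source_variant == "acid_death":
        return p.mu0 * M * (1.0 - M) * (1.0 - S_t)
    if p.source_variant == "acid_saturated":
        return p.mu0 * (1.0 - M) * M / (1.0 + S_t)
    raise ValueError(f"unknown source variant {p.source_variant!r}")


def proton_source(M, p: MacroParams, system: Literal["baseline", "saturated"]) -> np.ndarray:
    """Proton production by tumor cells: ``M`` (baseline nondimensional
    system) or the saturated ``zeta M / (1 + M)`` of the modified system."""
    M = np.asarray(M, dtype=float)
    if system == "baseline":
        return M
    if system == "saturated":
        return p.zeta * M / (1.0 + M)
    raise ValueError(f"unknown system {system!r}")
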