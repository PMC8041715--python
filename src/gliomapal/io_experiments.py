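"""Initial conditions, experiment presets, and result serialization.

The experiment catalogue mirrors the simulation study: isotropic vs
anisotropic undirected tissue (parabolic limit), strong-buffering and
alternative-source variants, a taxis-off comparison, and the
directed-tissue (hyperbolic limit) runs. All presets are pure data and run
end-to-end through :func:`run_preset`.

Scale conventions for the presets (documented in the methods note): the
synthetic tissue lives on [0, 1000] um; the nondimensional system uses
t_scale = 4e4 s (about half a day, putting the scaled growth rate at
mu0_t ~= 0.093 so that proliferation, acidification and acid-induced death
compete on comparable timescales) and the proton diffusivity at the low end
of its published range (D_s = 5e-8 mm^2/s), giving x_scale =
sqrt(D_s t_scale) = 45 um. The turning-rate constants are lambda0_t =
lambda1_t = 25 with kD = 2.5. The buffering ratio alpha is chosen per
preset in the qualitative regime the simulation study reports: alpha = 0.01
(very weak buffering, acidity screening length ~10 length units = 450 um)
for the pseudopalisade experiments, four orders of magnitude more for the
strong-buffering (lower-grade) preset.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .analysis import mu_star, ring_metrics
from .coefficients import MacroParams
from .grid import Grid2D
from .solver_hyperbolic import HyperbolicConfig, run_hyperbolic
from .solver_parabolic import (
    SimulationResult,
    SolverConfig,
    State,
    run_modified_system_5_1,
    run_parabolic,
)
from .tissue import (
    FiberDistributionParams,
    SolverFields,
    build_tissue,
    nondimensional_fields,
)

__all__ = [
    "X_SCALE_MM",
    "T_SCALE_S",
    "DS_MM2_S",
    "S_MAX_MOL_L",
    "gaussian_sum",
    "initial_conditions",
    "ExperimentPreset",
    "preset_registry",
    "run_preset",
    "save_result",
    "load_result",
]

X_SCALE_MM = 0.045
T_SCALE_S = 4e4
DS_MM2_S = 5e-8
S_MAX_MOL_L = 10.0 ** (-6.4)

DOMAIN_UM = 1000.0

EXPERIMENT_PARAMS = MacroParams(alpha=0.01, mu0=0.0926)


def gaussian_sum(grid: Grid2D, bumps: list[tuple[float, float, float, float]]) -> np.ndarray:
    """Sum of isotropic Gaussians ``amp * exp(-((x-cx)^2+(y-cy)^2)/(2 sig^2))``."""
    X, Y = grid.meshgrid()
    out = np.zeros(grid.shape)
    for amp, cx, cy, sig in bumps:
        out += amp * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * sig**2))
    return out


# (amplitude, cx um, cy um, sigma um); S amplitudes in mol/l, scaled by S_max
_IC_M = {
    "4.8": [(0.005, 500.0, 500.0, 25.0), (0.005, 600.0, 500.0, 20.0), (0.005, 300.0, 400.0, 10.0)],
    "4.9": [(0.005, 500.0, 500.0, 25.0), (0.005, 600.0, 500.0, 20.0)],
}
_IC_S = {
    "4.8": [(1e-7, 500.0, 500.0, 15.0), (1e-7, 600.0, 500.0, 10.0), (S_MAX_MOL_L, 300.0, 400.0, 7.5)],
    "4.9": [(S_MAX_MOL_L, 500.0, 500.0, 15.0), (S_MAX_MOL_L, 600.0, 500.0, 10.0)],
}


def initial_conditions(ic_set: Literal["4.8", "4.9"], grid: Grid2D) -> State:
    """Multifocal Gaussian initial data on the [0, 1000] um domain.

    Tumor bumps have amplitude 0.005 of carrying capacity; acidity
    amplitudes are given in mol/l and nondimensionalized by the death
    threshold S_max = 10^-6.4 mol/l (so the strongest foci start exactly at
    the threshold). Set "4.8" has three foci, set "4.9" two.
    """
    if ic_set not in _IC_M:
        raise ValueError(f"unknown initial-condition set {ic_set!r}; choose '4.8' or '4.9'")
    x0, x1, y0, y1 = grid.extent
    centers = [(b[1], b[2]) for b in _IC_M[ic_set]]
    if not all(x0 <= cx <= x1 and y0 <= cy <= y1 for cx, cy in centers):
        raise ValueError("grid does not cover the initial tumor foci")
    M = gaussian_sum(grid, _IC_M[ic_set])
    S = gaussian_sum(grid, [(a / S_MAX_MOL_L, cx, cy, s) for a, cx, cy, s in _IC_S[ic_set]])
    return State(M=M, S=S, t=0.0)


@dataclass(frozen=True)
class ExperimentPreset:
    """A runnable experiment: tissue recipe, parameters, IC and horizon."""

    name: str
    description: str
    solver: Literal["parabolic", "hyperbolic", "saturated"]
    delta: float = 1.0
    kappa: float = 0.0
    variant: str = "symmetric_bimodal"
    params: MacroParams = EXPERIMENT_PARAMS
    ic_set: str = "4.8"
    nx: int = 201
    t_end: float = 900.0
    dt: float = 0.25
    snapshot_every: int = 180
    epsilon: float = 1e-5


def _experiment_presets() -> dict[str, ExperimentPreset]:
    base = ExperimentPreset(
        name="experiment1_ic48",
        description="Isotropic undirected tissue (delta=1), three-focus IC; "
        "pseudopalisade formation under weak buffering",
        solver="parabolic",
    )
    aniso = replace(
        base,
        name="experiment2_ic48",
        description="Anisotropic undirected tissue (delta=0.2, kappa=3, two "
        "crossing fiber bundles), three-focus IC",
        delta=0.2,
        kappa=3.0,
    )
    presets = [
        base,
        replace(base, name="experiment1_ic49", ic_set="4.9",
                description="Isotropic undirected tissue, two-focus IC"),
        aniso,
        replace(aniso, name="experiment2_ic49", ic_set="4.9",
                description="Anisotropic undirected tissue, two-focus IC"),
        replace(
            aniso,
            name="fig7_strong_buffering",
            ic_set="4.9",
            params=EXPERIMENT_PARAMS.with_(alpha=100.0),
            description="Proton buffering four orders of magnitude stronger: "
            "no hypoxic necrosis, lower-grade morphology",
        ),
        replace(
            aniso,
            name="fig8_saturated_growth",
            ic_set="4.9",
            params=EXPERIMENT_PARAMS.with_(source_variant="acid_saturated"),
            description="Acidity-saturated proliferation without acid-induced "
            "death: no pseudopalisades",
        ),
        replace(
            aniso,
            name="fig9_no_taxis",
            ic_set="4.9",
            params=EXPERIMENT_PARAMS.with_(taxis_on=False),
            description="pH-taxis switched off (g=0); pairs with "
            "experiment2_ic49 to isolate the taxis contribution",
        ),
        ExperimentPreset(
            name="hyperbolic_delta02",
            description="Directed tissue, drift-dominated limit, delta=0.2: "
            "cells driven along the positive x/y fiber bundles",
            solver="hyperbolic",
            delta=0.2,
            kappa=3.0,
            variant="unsymmetric_von_mises",
            ic_set="4.9",
            t_end=900.0,
            dt=0.04,
            snapshot_every=1125,
        ),
        ExperimentPreset(
            name="hyperbolic_delta1",
            description="Directed tissue, delta=1: migration along the "
            "diagonal toward the upper-right corner, no ring",
            solver="hyperbolic",
            delta=1.0,
            variant="unsymmetric_von_mises",
            ic_set="4.9",
            t_end=900.0,
            dt=0.4,
            snapshot_every=112,
        ),
        ExperimentPreset(
            name="theorem52_saturated",
            description="Modified system with saturated proton production in "
            "the provable regime: M -> 1, S -> zeta/(2 alpha)",
            solver="saturated",
            nx=64,
            t_end=8e5,
            dt=100.0,
            snapshot_every=100,
            params=MacroParams(alpha=1.0, zeta=0.5, mu0=1.0),  # mu0 replaced at build
        ),
    ]
    return {p.name: p for p in presets}


_PRESETS = _experiment_presets()


def preset_registry() -> dict[str, ExperimentPreset]:
    return dict(_PRESETS)


def theorem_setup(
    nx: int = 64, d: float = 1e-3, zeta: float = 0.5, alpha: float = 1.0,
    mu0_factor: float = 10.0, s0: float = 0.2, bump_amp: float = 0.1,
) -> tuple[SolverFields, MacroParams, State]:
    """Study configuration for the long-time-convergence theorem.

    Unit square, constant isotropic nondimensional tumor diffusion ``d``
    (so ellipticity and norm bounds are both ``d``), saturated proton
    production with ``zeta < alpha``, uniform sub-threshold initial acidity
    and a Gaussian tumor bump; the growth rate is ``mu0_factor`` times the
    certified threshold mu*.
    """
    grid = Grid2D.square(1.0, nx)
    fields = SolverFields.isotropic(grid, d)
    params = MacroParams(alpha=alpha, zeta=zeta, mu0=1.0)
    mu = mu0_factor * mu_star(params, D0=d, theta_ell=d, S0_inf=s0)
    params = params.with_(mu0=mu)
    M0 = gaussian_sum(grid, [(bump_amp, 0.5, 0.5, 0.15)])
    S0 = np.full(grid.shape, s0)
    return fields, params, State(M=M0, S=S0, t=0.0)


def _build_fields(preset: ExperimentPreset, nx: int) -> SolverFields:
    grid = Grid2D.square(DOMAIN_UM, nx)
    qp = FiberDistributionParams(
        delta=preset.delta, kappa=preset.kappa, variant=preset.variant
    )
    tissue = build_tissue(grid, qp)
    return nondimensional_fields(tissue, Ds=DS_MM2_S, x_scale_mm=X_SCALE_MM, t_scale_s=T_SCALE_S)


def run_preset(
    name: str,
    nx: int | None = None,
    t_end: float | None = None,
    dt: float | None = None,
    snapshot_every: int | None = None,
) -> tuple[SimulationResult, dict]:
    """Run a named preset end-to-end; returns (result, analysis reports).

    Overrides allow scaled-down runs on coarser grids or shorter horizons.
    The report dictionary carries ring metrics at the midpoint and final
    snapshots (pattern presets) or the convergence diagnostics (theorem
    preset).
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    preset = _PRESETS[name]
    nx = nx or preset.nx
    config_kwargs = dict(
        dt=dt or preset.dt,
        t_end=t_end or preset.t_end,
        snapshot_every=snapshot_every or preset.snapshot_every,
    )
    reports: dict = {"preset": preset.name}
    if preset.solver == "saturated":
        fields, params, ic = theorem_setup(nx=nx)
        reports["grid"] = fields.grid
        result = run_modified_system_5_1(fields, params, ic, SolverConfig(**config_kwargs))
        from .analysis import convergence_report

        if len(result.diagnostics) >= 10:
            reports["convergence"] = convergence_report(result, params)
    else:
        fields = _build_fields(preset, nx)
        grid = fields.grid
        reports["grid"] = grid
        ic = initial_conditions(preset.ic_set, grid)
        if preset.solver == "parabolic":
            result = run_parabolic(fields, preset.params, ic, SolverConfig(**config_kwargs))
        else:
            result = run_hyperbolic(
                fields, preset.params, ic,
                HyperbolicConfig(epsilon=preset.epsilon, **config_kwargs),
            )
        mid = result.snapshots[len(result.snapshots) // 2]
        last = result.final
        reports["ring_mid"] = ring_metrics(mid.M, mid.S, grid)
        reports["ring_final"] = ring_metrics(last.M, last.S, grid)
    return result, reports


# -- serialization -------------------------------------------------------


def save_result(path: str | Path, result: SimulationResult, grid: Grid2D) -> None:
    """Write a run to ``<path>.npz`` plus a JSON metadata sidecar."""
    path = Path(path)
    M = np.stack([s.M for s in result.snapshots])
    S = np.stack([s.S for s in result.snapshots])
    np.savez_compressed(
        path.with_suffix(".npz"),
        times=result.times,
        M=M,
        S=S,
        grid=np.array([grid.nx, grid.ny, grid.h, grid.x0, grid.y0]),
        diagnostics=result.diagnostics.to_records(index=False),
    )
    meta = {
        "params": asdict(result.params),
        "blowup_time": result.blowup_time,
        "clipped_mass": result.clipped_mass,
        "n_snapshots": len(result.snapshots),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_result(path: str | Path) -> tuple[SimulationResult, Grid2D]:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=True) as data:
        times = data["times"]
        M, S = data["M"], data["S"]
        gnx, gny, gh, gx0, gy0 = data["grid"]
        diagnostics = pd.DataFrame.from_records(data["diagnostics"])
    meta = json.loads(path.with_suffix(".json").read_text())
    params = MacroParams(**meta["params"])
    grid = Grid2D(nx=int(gnx), ny=int(gny), h=float(gh), x0=float(gx0), y0=float(gy0))
    snapshots = [State(M[i], S[i], float(times[i])) for i in range(len(times))]
    result = SimulationResult(
        times=times,
        snapshots=snapshots,
        diagnostics=diagnostics,
        params=params,
        blowup_time=meta["blowup_time"],
        clipped_mass=meta.get("clipped_mass", 0.0),
    )
    return result, grid


def render_fields(result: SimulationResult, grid: Grid2D, path: str | Path) -> None:
    """Quick-look PNG of the final tumor and acidity fields (fixed colormap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    last = result.final
    for ax, field_, label in ((axes[0], last.M, "tumor M"), (axes[1], last.S, "acidity S")):
        im = ax.imshow(
            field_.T, origin="lower", extent=grid.extent, cmap="viridis"
        )
        ax.set_title(f"{label} at t={last.t:g}")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
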