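"""Synthetic brain-tissue construction.

A synthetic water diffusion tensor field stands in for DTI data on the
sub-millimetre scale of a histological sample. From it we derive, per grid
node, a fiber orientation distribution ``q(x, theta)`` on the unit circle
(a uniform/von-Mises mixture for undirected tissue, or a combination of two
unsymmetric von Mises densities for directed tissue), and from ``q`` the
macroscopic tissue quantities that enter the tumor PDEs:

* ``E_q``  — mean fiber orientation, the first angular moment of ``q``;
* ``D_T``  — tumor diffusion tensor, ``(s^2/lambda0) * int q theta x theta``;
* ``u``    — drift ``div D_T`` of the myopic (non-Fickian) diffusion;
* ``FA``   — fractional anisotropy of a tensor;
* ``Q``    — macroscopic tissue area fraction from the water tensor.

Spatial coordinates of the synthetic fields are in micrometres; cell speed
``s`` is in mm/s and the turning rate ``lambda0`` in 1/s, so ``D_T`` carries
mm^2/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .grid import Grid2D, TensorField

__all__ = [
    "FiberDistributionParams",
    "TissueModel",
    "water_diffusion_tensor",
    "water_tensor_field",
    "fractional_anisotropy",
    "leading_eigenvector",
    "q_symmetric",
    "q_unsymmetric",
    "angular_grid",
    "orientation_moments",
    "divergence_tensor",
    "tissue_density_Q",
    "build_tissue",
]

_D_CENTER = 450.0  # um; crossing point of the two synthetic fiber bundles


def _d_profile(x, y):
    """Anisotropy modulation of the synthetic water tensor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return 0.25 * np.exp(-0.005 * (x - _D_CENTER) ** 2) - 0.25 * np.exp(
        -0.005 * (y - _D_CENTER) ** 2
    )


def water_diffusion_tensor(x: float, y: float) -> np.ndarray:
    """Synthetic water diffusion tensor diag(0.5 - d, 0.5 + d) at (x, y) in um.

    The modulation ``d(x, y)`` is a difference of two narrow Gaussian ridges
    along the lines x = 450 and y = 450, mimicking two crossing fiber
    bundles. Both diagonal entries stay within [0.25, 0.75].
    """
    d = _d_profile(x, y)
    return np.array([[0.5 - d, 0.0], [0.0, 0.5 + d]])


def water_tensor_field(grid: Grid2D) -> TensorField:
    X, Y = grid.meshgrid()
    d = _d_profile(X, Y)
    return TensorField(grid, 0.5 - d, np.zeros(grid.shape), 0.5 + d)


def fractional_anisotropy(tensor) -> np.ndarray | float:
    """FA = |l1 - l2| / sqrt(l1^2 + l2^2) of a symmetric PSD 2x2 tensor.

    Accepts a single 2x2 matrix or a :class:`TensorField`. The zero tensor is
    assigned FA = 0 (isotropy limit). Rotation invariant; 1 for a rank-one
    (perfectly aligned) tensor.
    """
    if isinstance(tensor, TensorField):
        l1, l2 = tensor.eigenvalues()
    else:
        t = np.asarray(tensor, dtype=float)
        mean = 0.5 * (t[..., 0, 0] + t[..., 1, 1])
        radius = np.hypot(0.5 * (t[..., 0, 0] - t[..., 1, 1]), t[..., 0, 1])
        l1, l2 = mean + radius, mean - radius
    denom = np.sqrt(l1**2 + l2**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(denom > 0, np.abs(l1 - l2) / np.where(denom > 0, denom, 1.0), 0.0)
    return fa if fa.ndim else float(fa)


def leading_eigenvector(tensor) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue, with a fixed sign.

    Eigenvectors are defined up to sign; we fix the first component to be
    non-negative (ties broken by a non-negative second component) so derived
    fields are deterministic. For degenerate (isotropic) tensors the choice
    (1, 0) is returned; there the concentration k(x) = kappa*FA vanishes and
    the orientation distribution is uniform, so the direction is immaterial.
    """
    if isinstance(tensor, TensorField):
        a, b, c = tensor.dxx, tensor.dxy, tensor.dyy
    else:
        t = np.asarray(tensor, dtype=float)
        a, b, c = t[..., 0, 0], t[..., 0, 1], t[..., 1, 1]
    a, b, c = np.broadcast_arrays(*np.atleast_1d(a, b, c))
    radius = np.hypot(0.5 * (a - c), b)
    # eigenvector of [[a, b], [b, c]] for l1 = mean + radius
    vx = np.where(radius > 0, 0.5 * (a - c) + radius, 1.0)
    vy = np.where(radius > 0, b, 0.0)
    # the formula degenerates when l1 is reached along y (vx = vy = 0)
    degenerate = (np.abs(vx) < 1e-300) & (np.abs(vy) < 1e-300)
    vx = np.where(degenerate, 0.0, vx)
    vy = np.where(degenerate, 1.0, vy)
    norm = np.hypot(vx, vy)
    vx, vy = vx / norm, vy / norm
    flip = (vx < 0) | ((vx == 0) & (vy < 0))
    sign = np.where(flip, -1.0, 1.0)
    out = np.stack([vx * sign, vy * sign], axis=-1)
    return out[0] if out.shape == (1, 2) else out


@dataclass(frozen=True)
class FiberDistributionParams:
    """Parameters of the per-node fiber orientation distribution.

    ``delta`` weights the isotropic/diagonal component, ``kappa`` the
    sensitivity of cells to fiber alignment (concentration k(x) = kappa *
    FA(x)). The ``unsymmetric_von_mises`` variant adds a diagonal bundle of
    strength ``kh_amplitude * exp(-kh_decay * |x - kh_center|^2)`` oriented
    along the unit vector ``gamma``.
    """

    delta: float = 1.0
    kappa: float = 0.0
    variant: Literal["symmetric_bimodal", "unsymmetric_von_mises"] = "symmetric_bimodal"
    kh_center: tuple[float, float] = (450.0, 450.0)
    kh_amplitude: float = 0.05
    kh_decay: float = 1e-6
    gamma: tuple[float, float] = (1.0 / np.sqrt(2.0), 1.0 / np.sqrt(2.0))

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if abs(np.hypot(*self.gamma) - 1.0) > 1e-9:
            raise ValueError("gamma must be a unit vector")

    def k_h(self, x, y) -> np.ndarray:
        cx, cy = self.kh_center
        return self.kh_amplitude * np.exp(
            -self.kh_decay * ((np.asarray(x, float) - cx) ** 2 + (np.asarray(y, float) - cy) ** 2)
        )


def angular_grid(n_theta: int) -> tuple[np.ndarray, float]:
    """Equispaced angles on [0, 2*pi) and the (periodic-trapezoid) weight."""
    if n_theta < 16:
        raise ValueError("angular quadrature needs at least 16 nodes")
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    return theta, 2.0 * np.pi / n_theta


def _von_mises(theta, k, mu_angle):
    from scipy.special import i0

    return np.exp(k * np.cos(theta - mu_angle)) / (2.0 * np.pi * i0(k))


def q_symmetric(theta, delta: float, k, phi1) -> np.ndarray:
    """Uniform / bimodal-von-Mises mixture density on the circle.

    ``q = delta/(2 pi) + (1 - delta) * (vM(k, phi1) + vM(k, -phi1)) / 2``.
    Symmetric under theta -> theta + pi, hence zero mean orientation: the
    undirected-tissue model. ``k`` is the concentration kappa*FA at the node,
    ``phi1`` the leading water-tensor eigenvector (angle or unit vector).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    phi = _as_angle(phi1)
    theta = np.asarray(theta, dtype=float)
    vm = 0.5 * (_von_mises(theta, k, phi) + _von_mises(theta, k, phi + np.pi))
    return delta / (2.0 * np.pi) + (1.0 - delta) * vm


def q_unsymmetric(theta, delta: float, k, phi1, k_h, gamma) -> np.ndarray:
    """Combination of two unsymmetric unimodal von Mises densities.

    ``q_h = delta * vM(k_h, gamma) + (1 - delta) * vM(k, phi1)``: a weak
    bundle oriented along the diagonal ``gamma`` (strength decaying away from
    its center) plus an aligned component along ``phi1``. Its first moment is
    generally nonzero: the directed-tissue model.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    theta = np.asarray(theta, dtype=float)
    return delta * _von_mises(theta, k_h, _as_angle(gamma)) + (1.0 - delta) * _von_mises(
        theta, k, _as_angle(phi1)
    )


def _as_angle(direction) -> float | np.ndarray:
    direction = np.asarray(direction, dtype=float)
    if direction.shape and direction.shape[-1] == 2:
        return np.arctan2(direction[..., 1], direction[..., 0])
    return direction


def orientation_moments(
    q_values: np.ndarray, theta: np.ndarray, s: float, lambda0: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Angular moments of ``q``: (E_q, D_T, V_q).

    ``q_values`` has the angle on its last axis. In 2-D the velocity set is
    ``s * S^1`` with measure weight ``omega = s``, so

    ``E_q = int theta q dtheta``  (unit-circle first moment),
    ``D_T = (s^2/lambda0) int q theta x theta dtheta``,
    ``V_q = int (theta - E_q) x (theta - E_q) q dtheta``.

    The periodic composite trapezoid rule is spectrally accurate for the
    smooth densities used here; ``tr D_T = s^2/lambda0`` up to quadrature
    error since ``q`` integrates to one.
    """
    w = 2.0 * np.pi / theta.size
    ct, st = np.cos(theta), np.sin(theta)
    e1 = q_values @ ct * w
    e2 = q_values @ st * w
    mxx = q_values @ (ct * ct) * w
    mxy = q_values @ (ct * st) * w
    myy = q_values @ (st * st) * w
    Eq = np.stack([e1, e2], axis=-1)
    second = np.stack(
        [np.stack([mxx, mxy], axis=-1), np.stack([mxy, myy], axis=-1)], axis=-2
    )
    DT = (s**2 / lambda0) * second
    Vq = second - Eq[..., :, None] * Eq[..., None, :]
    return Eq, DT, Vq


def divergence_tensor(field: TensorField, h: float | None = None) -> np.ndarray:
    """Row-wise divergence ``u_i = sum_j d_j T_ij`` of a tensor field.

    Central differences in the interior, one-sided at the boundary
    (``np.gradient`` convention). ``h`` defaults to the grid spacing; pass an
    explicit value to work in other length units. Returns shape (nx, ny, 2).
    """
    if h is None:
        h = field.grid.h
    ux = np.gradient(field.dxx, h, axis=0) + np.gradient(field.dxy, h, axis=1)
    uy = np.gradient(field.dxy, h, axis=0) + np.gradient(field.dyy, h, axis=1)
    return np.stack([ux, uy], axis=-1)


def tissue_density_Q(Dw: TensorField) -> np.ndarray:
    """Macroscopic tissue area fraction ``Q = 1 - tr(Dw) / (4 l1)``.

    Derived from the expected Brownian exit time over a grid cell: the
    characteristic diffusion length is ``l_c = sqrt(tr(Dw) h^2 / (4 l1))``
    with ``l1`` the leading eigenvalue, and ``Q = 1 - l_c^2/h^2``; the cell
    size cancels. In 2-D, ``l1 <= tr <= 2 l1`` confines Q to [1/2, 3/4].
    """
    l1, _ = Dw.eigenvalues()
    tr = Dw.trace()
    if np.any(l1 <= 0):
        raise ValueError("tissue density undefined for a non-positive water tensor")
    return 1.0 - tr / (4.0 * l1)


@dataclass
class TissueModel:
    """Grid-sampled tissue: water tensor, q-parameters and derived fields."""

    grid: Grid2D
    Dw: TensorField
    q_params: FiberDistributionParams
    FA: np.ndarray  # of the water tensor, in [0, 1]
    Eq: np.ndarray  # (nx, ny, 2) mean fiber orientation
    DT: TensorField  # tumor diffusion tensor, mm^2/s
    u: np.ndarray  # (nx, ny, 2) div DT, mm/s (gradient taken per mm)
    Q: np.ndarray  # tissue area fraction
    s: float  # cell speed, mm/s
    lambda0: float  # turning rate, 1/s
    n_theta: int = 128

    def q_at(self, i: int, j: int, theta) -> np.ndarray:
        """Orientation density at node (i, j)."""
        p = self.q_params
        k = p.kappa * self.FA[i, j]
        phi1 = leading_eigenvector(
            np.array(
                [
                    [self.Dw.dxx[i, j], self.Dw.dxy[i, j]],
                    [self.Dw.dxy[i, j], self.Dw.dyy[i, j]],
                ]
            )
        )
        if p.variant == "symmetric_bimodal":
            return q_symmetric(theta, p.delta, k, phi1)
        x, y = self.grid.x[i], self.grid.y[j]
        return q_unsymmetric(theta, p.delta, k, phi1, p.k_h(x, y), p.gamma)


def build_tissue(
    grid: Grid2D,
    q_params: FiberDistributionParams,
    s: float = 2.8e-6,
    lambda0: float = 0.1,
    n_theta: int = 128,
    Dw: TensorField | None = None,
) -> TissueModel:
    """Assemble all derived tissue fields on the grid.

    ``Dw`` defaults to the synthetic water tensor; a user-supplied gridded
    tensor field may replace it. The angular quadrature uses ``n_theta``
    equispaced nodes (>= 16; the default 128 resolves concentrations up to
    kappa ~ 5 far beyond quadrature tolerance).
    """
    if Dw is None:
        Dw = water_tensor_field(grid)
    theta, _ = angular_grid(n_theta)
    FA = np.asarray(fractional_anisotropy(Dw))
    k = q_params.kappa * FA
    phi = _as_angle(leading_eigenvector(Dw))
    if q_params.variant == "symmetric_bimodal":
        q = q_symmetric(theta[None, None, :], q_params.delta, k[..., None], phi[..., None])
    else:
        X, Y = grid.meshgrid()
        kh = q_params.k_h(X, Y)
        q = q_unsymmetric(
            theta[None, None, :],
            q_params.delta,
            k[..., None],
            phi[..., None],
            kh[..., None],
            q_params.gamma,
        )
    Eq, DT_mats, _ = orientation_moments(q, theta, s, lambda0)
    DT = TensorField.from_matrices(grid, DT_mats)
    u = divergence_tensor(DT, h=grid.h * 1e-3)  # gradient per mm -> u in mm/s
    Q = tissue_density_Q(Dw)
    return TissueModel(
        grid=grid,
        Dw=Dw,
        q_params=q_params,
        FA=FA,
        Eq=Eq,
        DT=DT,
        u=u,
        Q=Q,
        s=s,
        lambda0=lambda0,
        n_theta=n_theta,
    )


@dataclass
class SolverFields:
    """Nondimensional per-node fields consumed by the PDE solvers.

    ``h`` is the grid spacing in units of the chosen length scale; ``DT`` is
    the tumor diffusion tensor divided by the proton diffusivity ``D_s``;
    ``u = div DT`` in the scaled coordinates; ``Eq`` and the drift speed
    ``s_nd`` feed the hyperbolic-limit solver; ``c2 = s^2/(lambda0 D_s)`` is
    the prefactor of its directional second-drift correction.
    """

    grid: Grid2D
    h: float
    DT: TensorField
    u: np.ndarray
    Eq: np.ndarray | None = None
    s_nd: float = 0.0
    c2: float = 0.0

    @classmethod
    def isotropic(cls, grid: Grid2D, d: float, h: float | None = None) -> "SolverFields":
        """Constant isotropic nondimensional tumor diffusion (u = 0)."""
        return cls(
            grid=grid,
            h=grid.h if h is None else h,
            DT=TensorField.isotropic(grid, d),
            u=np.zeros(grid.shape + (2,)),
        )


def nondimensional_fields(
    tissue: TissueModel,
    Ds: float = 1e-6,
    x_scale_mm: float = 0.02,
    t_scale_s: float = 400.0,
) -> SolverFields:
    """Scale a tissue model into solver units.

    ``Ds`` (mm^2/s) is the proton diffusivity used to nondimensionalize
    tensors; ``x_scale_mm``/``t_scale_s`` are the length/time scales of the
    nondimensional system. Grid coordinates are in micrometres.
    """
    DT_nd = tissue.DT.scaled(1.0 / Ds)
    h_nd = tissue.grid.h * 1e-3 / x_scale_mm
    u_nd = divergence_tensor(DT_nd, h=h_nd)
    s_nd = tissue.s * t_scale_s / x_scale_mm
    c2 = tissue.s**2 / (tissue.lambda0 * Ds)
    return SolverFields(
        grid=tissue.grid, h=h_nd, DT=DT_nd, u=u_nd, Eq=tissue.Eq, s_nd=s_nd, c2=c2
    )
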