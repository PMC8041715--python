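# Methods

This note records the model as implemented, the numerical choices, the
rationale for the default study conditions, and what the shipped tests do
and do not establish.

## Model structure

Two coupled fields on a rectangle with no-flux boundaries: tumor cell
density `M` (fraction of carrying capacity) and extracellular proton
concentration `S` (fraction of the lethal threshold `S_max = 10^-6.4`
mol/l).

**Diffusion-dominated (undirected-tissue) system**

```
M_t = div(D_T grad M) + div(u M) + div(g(S) M D_T grad S) + f(M, S)
S_t = Lap S + P(M) - alpha S
```

with `u = div D_T`. The first two terms together are the myopic diffusion
`nabla nabla : (D_T M)`; myopic diffusion is not Fickian — constants are in
the kernel of `div(D_T grad .)` but not of the full operator when `D_T`
varies in space, so a homogeneous population in heterogeneous tissue still
drifts. The taxis flux `+g(S) M D_T grad S` moves cells *down* acidity
gradients (repellent pH-taxis); its sensitivity

```
g(S) = lambda1 * kD / ((S + kD)^2 * (S + kD + lambda0))
```

is positive and strictly decreasing, the macroscopic residue of the
microscale proton–receptor kinetics `y' = k+ (S/S_max)(1 - y) - k- y`
(`kD = k-/k+`; the receptor ODE and its equilibrium are implemented and
tested in `coefficients`). Here `lambda0, lambda1` denote the turning-rate
coefficients scaled by `k+` (defaults 25 and 25 from the dimensional set
`lambda0 = lambda1 = 0.1/s`, `k+ = 0.004/s`).

Two source variants:

* `acid_death` (default): `f = mu0 M (1 - M)(1 - S)` — logistic growth that
  becomes decay where `S > 1`. Acid-induced death is what carves the
  hypocellular center of a pseudopalisade.
* `acid_saturated`: `f = mu0 (1 - M) M / (1 + S)` — growth merely slowed by
  acidity, never negative; shipped as the `fig8_saturated_growth` preset and
  indeed it produces no hollow centers.

Proton production `P(M)` is `M` in the baseline system and the saturated
`zeta M / (1 + M)` in the modified system used for long-time analysis.

**Drift-dominated (directed-tissue) system.** When the orientation
distribution is unsymmetric, the mean fiber orientation `E_q` is nonzero and

```
M_t + div(s E_q M) = eps * [corrections] ,
```

where the corrections are the myopic diffusion, a directional term
`-div(c2 E_q div(E_q M))` with `c2 = s^2/lambda0` (nondimensionalized), the
taxis flux and the source, all scaled by `eps` (default `1e-5`).

**Tissue.** The synthetic water diffusion tensor is
`diag(0.5 - d, 0.5 + d)` with
`d(x, y) = 0.25 exp(-0.005 (x - 450)^2) - 0.25 exp(-0.005 (y - 450)^2)`
(coordinates in micrometres): two narrow crossing "fiber bundles" along
`x = 450` and `y = 450`. Orientation densities on the circle:

* undirected: `q = delta/(2 pi) + (1 - delta) * (vM(k, phi1) + vM(k, -phi1))/2`,
  a uniform/bimodal–von-Mises mixture with concentration
  `k = kappa * FA(D_w)` and `phi1` the leading water-tensor eigenvector;
  symmetric under `theta -> theta + pi`, hence `E_q = 0`;
* directed: `q_h = delta * vM(k_h, gamma) + (1 - delta) * vM(k, phi1)` with
  `gamma = (1,1)/sqrt(2)` and
  `k_h = 0.05 exp(-1e-6 ((x-450)^2 + (y-450)^2))`.

Derived fields: `E_q` (first angular moment), `D_T = (s^2/lambda0) *
int q theta theta^T` (trace identity `tr D_T = s^2/lambda0`),
`u = div D_T`, fractional anisotropy `FA = |l1 - l2|/sqrt(l1^2 + l2^2)`
(zero tensor mapped to 0), and tissue fraction `Q = 1 - tr(D_w)/(4 l1)`
(grid-size independent; in `[1/2, 3/4]` in 2-D).

## Numerical schemes

* **Angular quadrature**: periodic composite trapezoid with 128 nodes
  (spectrally accurate for the smooth densities used; 256 nodes agree with
  the closed forms to 1e-8 and better). Eigenvectors are sign-fixed
  (non-negative first component) so all derived fields are deterministic.
* **Anisotropic diffusion** `div(D grad M)`: Weickert's non-negative 3x3
  stencil — the mixed derivative is carried by directional differences along
  the stencil diagonals, with edge conductivities
  `(a_P + a_Q - |b|_P - |b|_Q)/2h^2` (axial) and `(b±_P + b±_Q)/2h^2`
  (diagonals). We assemble it edge-by-edge, which makes the matrix exactly
  symmetric with zero row *and* column sums: constants are annihilated and
  the plain nodal sum of `M` is conserved to solver precision. Dropping the
  edges that would cross the boundary realizes the discrete no-flux
  condition. Off-diagonal weights are non-negative wherever
  `|D12| <= min(D11, D22)`, which holds for every shipped tissue (the
  synthetic water tensor is diagonal, so `phi1` is axis-aligned and `D_T`
  nearly diagonal).
* **Acidity diffusion**: the same assembly with the identity tensor (the
  standard 5-point Laplacian). Its Neumann eigenpairs are the cell-centered
  cosines `cos(pi k (i + 1/2)/n)` with eigenvalues
  `-(2/h^2)(1 - cos(pi k/n))`, which the tests use as a closed-form oracle.
* **Advection** (myopic drift `u` plus taxis): conservative flux-form
  first-order upwind; face velocities use arithmetic means of the nodal
  tensors/coefficients, and the acidity gradient normal to a face is the
  exact two-point difference. Boundary faces carry zero flux. In the drift
  solver the leading transport uses MUSCL reconstruction with the Van Leer
  limiter (TVD in 1-D sweeps; reduces to first-order upwind at extrema),
  dimension by dimension.
* **Directional correction term**: the identity
  `nabla nabla:(D_T M) - div(c2 E_q div(E_q M)) =
  div((D_T - c2 E_q E_q^T) grad M) + div((u - c2 (div E_q) E_q) M)` is used,
  whose tensor `D_T - c2 E_q E_q^T = c2 V_q` is the orientation covariance
  and therefore positive semidefinite. Discretizing the combined form with
  the Weickert stencil plus upwind drift keeps the update
  positivity-preserving; the term-by-term form (nested central differences)
  is algebraically equivalent but produced O(1e-11) undershoots at the
  sharp corner pile-up of long drift runs.
* **Time stepping**: IMEX Euler. Both diffusion blocks and the acidity decay
  `-alpha S` are implicit (one sparse LU factorization per operator, reused
  every step since the tissue fields are frozen); advection, the tumor
  source and the proton production are explicit. Consequences used by the
  tests: a constant `S` with `M = 0` decays as `S/(1 + dt alpha)` per step,
  and the discrete acidity bound `max(zeta/alpha, |S0|_inf)` is preserved
  *exactly* by the scheme in the saturated system. The advective CFL bound
  is checked at run time (warning for the parabolic solver, where advection
  is a small correction; an error for the drift solver, where it is the
  leading term). Blow-up (non-finite values or fields above 1e6) stops the
  run and reports the time rather than raising.
* **Negative clipping** is available (`clip_and_log`) but off by default:
  the shipped schemes are positivity-preserving and clipping would mask
  regressions.

## Study conditions (presets) and their rationale

The experiment presets solve the nondimensional system on the
`[0, 1000] um` square (default 201x201, h = 5 um). Choices fixed once:

* `t_scale = 4e4 s` (~0.46 day), so the scaled growth rate is
  `mu0 = 0.2/day * t_scale = 0.0926`. This puts proliferation,
  acidification and acid-induced death on comparable timescales — the
  regime in which the reported pattern phenomenology (rims near carrying
  capacity around freshly necrotic centers) can occur at all. The published
  parameter table does not pin this scale down unambiguously (its volume
  units are mixed), so it is a package-level convention, recorded here.
* `D_s = 5e-8 mm^2/s`, the low end of the published range, giving
  `x_scale = sqrt(D_s t_scale) = 45 um` and a 22-unit-wide domain. With the
  buffering ratio `alpha = 0.01`, the acidity screening length
  `1/sqrt(alpha) = 10` units (450 um) is well inside the domain, so the
  acid field stays spatially structured instead of flooding the box.
* `alpha = 0.01` for the pattern experiments ("very weak buffering");
  `alpha = 100` — four orders of magnitude more — for the strong-buffering
  preset, which indeed produces a homogeneous, dense, non-necrotic tumor
  (lower-grade morphology). Turning-rate constants `lambda0 = lambda1 = 25`,
  `kD = 2.5` throughout.
* Initial conditions: Gaussian sums with the published centers, widths and
  amplitudes (tumor 0.005 of carrying capacity; acidity amplitudes 1e-7 and
  10^-6.4 mol/l, i.e. 0.2512 and exactly 1.0 after scaling by `S_max`).
* Drift presets use the directed orientation distribution `q_h`, drift
  speed `s_nd = s t_scale/x_scale = 2.49`, `eps = 1e-5`, and time steps
  within the drift CFL bound (`dt = 0.04` for `delta = 0.2`, whose mean
  orientation reaches |E_q| ~ 0.5 along the bundles; `dt = 0.4` for
  `delta = 1`, where |E_q| <= I1(0.05)/I0(0.05) ~ 0.025).
* The long-time preset (`theorem52_saturated`) uses the provable regime on
  the unit square: constant isotropic `D_T = 1e-3 I`, `zeta = 0.5 < alpha
  = 1`, uniform `S0 = 0.2 < 1`, growth rate ten times the certified
  threshold `mu* = zeta^2 C_M / (4 alpha (1 - max(zeta/alpha, |S0|_inf)))`
  with `C_M = D0^2 Lambda^2 / (4 theta K^4 (K+B)^2)` — the threshold is
  computed at run time, not hard-coded — `dt = 100`, `t_end = 8e5`, by which
  time successive snapshots differ by far less than the 1e-6 settling
  criterion the tests assert.

Problem sizes used by the test suite (grids of 33–101 nodes per side,
horizons up to t = 900, and the 64x64 long-time run) were chosen as the
smallest sizes at which the qualitative classifications are stable under
refinement; the grid-convergence test checks that refinement shrinks the
solution change between successive levels.

## What the synthetic data does and does not show

The tissue generator emulates the *geometry* of DTI-derived anisotropy at
the histological scale (two crossing bundles, graded alignment, a weak
diagonal bias for the directed case). It does not emulate measurement noise,
partial-volume effects, real fiber-tract curvature, vascularization or
necrosis mechanics. Passing tests therefore establish that the solvers
reproduce the mathematical model's behavior — ring formation under weak
buffering in the diffusive limit, drift without rings in the transport
limit, the proven long-time attractor of the saturated system — not that
the model quantitatively matches patient tissue.

## Pattern metrics

`ring_metrics` bins the tumor field azimuthally around the acidity maximum
(bin width = one grid spacing) and reports
`ring_score = (rim - center)/max(rim, tiny)` with the rim the profile
maximum away from the center; positive iff the center is hypocellular
relative to the rim, 0 for uniform fields, negative for centered blobs. Ring
width is the full width of the profile above half its prominence. Local
acidity maxima above half the global maximum are reported as secondary
centers. The metric is invariant under quarter-turn rotations and is
deliberately azimuthally averaged: a displaced compact tumor (the drift
regime) scores non-positive because the acid peak travels with the cells.

## Linear stability

`turing_scan` linearizes the baseline system about the coexistence state
`(1, 1/alpha)` with a constant scalar tumor diffusivity `dT`:

```
J(k^2) = [ f_M - dT k^2        f_S - g(S*) dT M* k^2 ]
         [ 1                   -alpha - k^2          ]
```

The repellent taxis enters as a cross-diffusion entry with `J12 J21 < 0`,
i.e. it is *stabilizing* — consistent with the absence of any Turing band in
both the taxis-on and taxis-off scans over `k^2 in [1e-2, 1e4]`. In the
weak-buffering regime `alpha < 1` the uniform state itself is a saddle
(`S* = 1/alpha` exceeds the death threshold), so the observed
pseudopalisades are not Turing patterns but transient structures organized
by the acid field. The scan is validated against a matrix-exponential
time-domain oracle and against the measured growth rate of a seeded cosine
mode in the full solver (at the discrete wavenumber of the mode).

## Known limitations

* The dimensional-to-nondimensional map follows the printed formulas on raw
  numbers; because the published table mixes volume units, the absolute
  magnitudes of `alpha` and `mu0` produced by it are convention-dependent.
  The presets therefore fix their nondimensional values directly (above).
* No finite-time blow-up occurs in our scheme for the large-`alpha`
  configurations we probed (implicit diffusion and the saturating sources
  are too forgiving); blow-up *detection* is tested on a genuinely
  supercritical reaction state instead.
* Figure-level reproduction is qualitative: snapshot times and color scales
  of the original simulation study are not published.
* 2-D only; dimension-split limiting (no corner-transport upwinding);
  `S`-dependent turning coefficients are out of scope.
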