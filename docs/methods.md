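# Methods

## The model

`gelfilm` simulates a thin film of two-phase gel — a viscous polymer
network imbibed with inviscid solvent and seeded with cells — floating
freely in a bath of pure solvent.  The film is symmetric about its
mid-plane and mid-line, with free surfaces at `y = ±h(x,t)` and ends at
`x = ±L(t)`, and is characterised by a small height-to-length aspect
ratio.  All quantities are dimensionless: lengths are scaled on the
initial half-length, heights on the mean initial height, cell density on
its mean initial value, and time on the ratio of polymer viscosity to the
thermal free-energy scale.

The depth-averaged (leading-order lubrication) balance laws govern the
polymer volume fraction `θ_p(x,t)`, half-height `h(x,t)`, cell density
`n(x,t)`, axial polymer velocity `v_p(x,t)` and half-length `L(t)`:

- polymer and solvent mass conservation, written in the depth-integrated
  contents `Q = θ_p h` and `W = (1−θ_p) h`;
- a first-order (in space) force balance for `v_p`, integrating the
  divergence of the intra-gel solvent flux `V1` against the
  trans-boundary source `V2`;
- an advection–compression–diffusion equation for `n` (cells ride on the
  polymer and diffuse with coefficient `D`);
- the kinematic end condition `dL/dT = v_p(X=1)`.

Two potentials close the model.  Flory–Huggins mixing gives the solvent
chemical potential

    mu_s(θ_p) = log(1−θ_p) + (1 − 1/N) θ_p + χ θ_p²  (+ mu_s0),

and cells pull on the network through the saturating traction potential
`G(n) = τ₀ n² / (1 + λ n²)`.  The combination

    residual(θ_p, n) = mu_s − mu_s^e + θ_p G(n),

the imbalance of potentials across the free surface, is the single driver
of swelling (`residual < 0`), contraction (`> 0`) and equilibrium (`= 0`).
The external potential `mu_s^e` is that of pure solvent, `f(0) = mu_s0`;
note that `mu_s0` therefore cancels from the residual and plays no
dynamical role.

Steady states require `v_p = 0` and spatially uniform `θ_p` and `n`
satisfying `residual = 0` — but place no restriction on `h`, which may
remain non-uniform.  With zero cell diffusion this rigidity is lost:
frozen states with non-uniform `θ_p` and `n` exist in which the residual
is pointwise non-zero but its flux-balanced integral vanishes (solvent
circulates through a stationary network).

## Parameters

| symbol | meaning | default | notes |
| --- | --- | --- | --- |
| `N` | polymer chain length | 100 | fixed in all scenarios |
| `chi` | Flory interaction parameter | 0.75 | 0.4–1.5 across scenarios; large χ favours demixing/contraction |
| `mu_p0`, `mu_s0` | standard free energies | 0 | `mu_s0` cancels from the dynamics |
| `tau0` | cell traction strength | 1 | 0.1 for the weak-traction scenario |
| `lam` | contact inhibition | 1 | saturates `G` at `tau0/lam` |
| `xi` | polymer–solvent drag | 1 | 0.2–4 in the drag study |
| `R` | interface resistance | 1 | rescales time exactly: `h = F(T/R)` for uniform films |
| `D` | cell diffusion | 1 | `D = 0` exits the asymptotic regime and must be acknowledged explicitly |

Bulk viscosities of both phases cancel from the leading-order system (and
are zero in the baseline parameter set); they are not represented.

## Uniform films: the reduced ODE

If `θ_p`, `n` and `h` start spatially uniform they remain so, and the
model collapses to one stiff scalar ODE,

    dh/dt = −(1/2R) · residual(θ_I/h², n_I/h²),

with `θ_p = θ_I/h²`, `n = n_I/h²`, `L = h` exact in time.  It is
integrated with LSODA at `rtol = 1e-8`, `atol = 1e-10`; equilibrium is
declared when `|dh/dt| < 1e-10` (implemented as a terminal event on the
dense solution, which subsumes the "sustained over consecutive steps"
reading since the rate decays monotonically).  The default horizon is
`t_end = 2000`: the cell-free swelling scenario relaxes with an e-folding
time of ≈18, so reaching the 1e-10 rate threshold takes t ≈ 300.
Equilibria are reported rounded to two decimals, the precision at which
they are usually quoted.

Interior equilibria are found independently of the ODE by a dense sign
scan (10⁴ panels) of `g(θ) = residual(θ, n_I θ/θ_I)` over
`(1e-6, 1−1e-6)` with Brent refinement to `|g| < 1e-13`.  The trivial
fully-dissolved root at `θ → 0` is excluded by the bracket.  Note that
besides the physically attracting root there is generically a second,
dilute interior root (e.g. θ ≈ 0.042 for χ = 0.75): the small-θ expansion
of the residual, `−θ/N + (χ−½)θ² + …`, changes sign for χ > ½.  All
interior roots are returned; callers select.

## Short-time perturbation analysis

Around a uniform equilibrium scaled to `h* = n* = L* = 1`, a cosine
perturbation of wavenumber `γ = Zπ` (forced by the no-flux end
conditions) evolves at short times `T = δ T̂` with closed-form profiles.
The growth or decay of the `θ_p` and `h` modes is governed by the sign of

    z = θ* f''(θ*) − τ₀/(1+λ) − 2 τ₀ N₀₁ θ*/(1+λ)²,

(`z > 0` ⇒ decay), through the common rate factor
`Γ = (1−θ*)γ²/(ξθ*) + 1/R`.  The cell mode carries the additional
diffusive rate `D γ²`, implemented with the damping sign: the short-time
cell balance contains `D ∂²/∂X² [N₀₁ cos(γX)] = −D γ² N₀₁ cos(γX)`, so
its amplitude factor is `1 − δT̂ (D γ² + z Γ/N₀₁)`.  Diffusion therefore
always shrinks the cell mode, consistent with diffusion being stabilising.
These closed forms serve as an independent oracle for the PDE solver in
the tests (observed convergence order in the short-time scale ≥ 2 after
removing the O(ε²) floor of the linearisation).

## The thin-film solver

The moving domain is mapped to `X ∈ [0,1]` via `x = L(T) X`.  The solver
advances the conservative contents `Q`, `W` and the cell density `n` on a
uniform grid (default spacing `dX = 0.025`, 41 nodes) with a
Crank–Nicolson scheme (default `dT = 1e-4`; the reference audits use
`1e-5`, slow cell-free relaxations use up to `1e-3` after a step-halving
check — CN is O(dT²) and the reported quantities are insensitive at these
steps).

Numerical choices that matter:

- **Velocity.** `∂v_p/∂X` follows pointwise from the force balance;
  `v_p` is recovered by cumulative trapezoid from `v_p(0) = 0`, and
  `dL/dT = v_p(1)`.  Spatial derivatives are central, with second-order
  one-sided stencils for `∂V1/∂X` at the ends.
- **No-flux ends.** The composition gradients *inside* `V1` are evaluated
  with their boundary values `∂θ_p/∂X = ∂n/∂X = 0` at `X = 0, 1`, so `V1`
  vanishes identically at the film ends — the leading-order interface
  condition (solvent and polymer velocities agree at the end face).
  Omitting this lets zero-diffusion runs drift into spurious
  boundary-layer quasi-equilibria.
- **Conservative transport.** The moving-grid and advective terms
  combine exactly into a single flux: with `u = X·(dL/dT) − v_p`
  (which vanishes at both ends),
  `U_T = (1/L)(U u)_X − (L̇/L) U` for each transported field.  Central
  differences of the flux in the interior plus half-cell flux balances at
  the boundary nodes make the trapezoid-weighted flux sum telescope to
  zero, so the discrete polymer mass `L ∫Q dX` is conserved to round-off
  by the spatial scheme; the observed worst-case drift over a full
  contraction run (including the cell mass, which is not exactly
  telescoped) is below 1e-5 %.
- **Cell diffusion** uses a conservative face-flux stencil with zero-flux
  boundary faces (equivalently, reflection), keeping the discrete cell
  mass budget closed.
- **Nonlinearity.** Within each CN step the coefficients (`v_p`, `L̇`,
  `h`) are converged by Picard iteration: freeze at the latest iterate,
  solve the three tridiagonal systems (Gauss–Seidel order Q → W → n),
  re-solve the velocity, repeat until the maximum relative update is
  below 1e-10 (cap 50; typically 2–3 sweeps).  This preserves the CN
  structure without a hand-derived Newton Jacobian; transient differences
  against a fully coupled treatment are O(dT²) and long-time equilibria
  are insensitive (checked by dT-halving).
- **Steadiness.** A run is steady when `max|v_p|`, `max|∂v_p/∂X|` and
  (for `D > 0`) the maximal diffusive rate of `n` all fall below 1e-8.
  For `D > 0` this forces the pointwise residual (`V2`) to zero as well;
  for `D = 0` it correctly admits the frozen non-uniform states in which
  `V2 ≠ 0` pointwise.
- **Breakdown.** `Q` or `W` at the positivity floor (1e-10), or `θ_p`
  outside `[1e-3, 1−1e-3]`, halts the run with the offending state
  attached — never clipping.  Parameter regimes with very rapid evolution
  (large `τ₀` or `χ`, especially with `D = 0`) genuinely break down this
  way.
- A spatially uniform state is preserved *exactly* (the combined flux
  velocity `u` vanishes identically), so the PDE inherits the reduced
  ODE's dynamics for uniform data to O(dT²).

## Scenario presets and what they emulate

The preset registry reproduces the published scenario table: uniform
swelling (χ = 0.75) and contracting (χ = 1.5) cell-free films; uniform
cell-seeded films with strong (τ₀ = 1) and weak (τ₀ = 0.1) traction and a
five-fold resistance variant; cosine-perturbed polymer, cells or height
(amplitude 0.02, mode Z = 1); the drag (ξ = 0.2/4) and resistance
(R = 0.4/4) studies; and the zero-diffusion case (χ = 0.4, D = 0).
Initial height and cell density are normalised to unit spatial mean (the
model's scaling); profiles are validated against the symmetry/no-flux end
conditions at construction.  These generators are deterministic
analytical profiles — they contain no measurement noise, parameter
heterogeneity or geometric irregularity, so passing tests demonstrate
fidelity to the continuum model, not robustness to experimental artefacts.

## Reproduction status

All printed equilibrium values and amplitudes of the reference scenarios
reproduce at the quoted precision: (0.45, 1.16, 1.16) and (0.86, 0.84)
for the uniform cell-free films; (0.86, 1.44, 0.83, 0.83) and
(0.54, 0.91, 1.05, 1.05) for the cell-seeded films; height amplitude
0.019 about mean 1.16 for the perturbed cell-free film; mean cell density
1.29 with amplitude 0.033 (and θ amplitude 0.004, h amplitude 0.002) for
the zero-diffusion run; worst-case mass drift below 2.69e-5 %; exact
five-fold time rescaling with R = 5.

One quoted number does not reproduce: the polymer-fraction amplitude of
the high-drag (ξ = 4) study at T = 0.8.  The faithful run of the stated
configuration gives 0.012; an independent method-of-lines discretisation
(non-conservative θ/h/n variables, finer grid, adaptive stiff integrator)
agrees to all printed digits, and the value is insensitive to the time
step and to the boundary-derivative convention.  The model passes an
amplitude of 0.007 near T ≈ 1.0 (and the ξ = 1 variant passes it near
T = 0.6).  The qualitative statement — high drag preserves the initial
spatial structure far longer than low drag — holds robustly.  The
corresponding acceptance test asserts the printed value and is expected
to fail; it is kept red rather than adjusted.

## Known limitations

- Surface tension, substrate attachment, cell proliferation/death and
  end-region boundary layers are outside the model's scope.
- The thin-film reduction needs `D = O(1)` to make the cell density
  depth-independent; `D = 0` runs are formally outside the asymptotic
  regime and require an explicit acknowledgment flag.
- The scheme uses no upwinding; at `dX = 0.025` mild dispersion is
  possible for rapidly evolving profiles, and runs with large `τ₀` or `χ`
  may fail loudly rather than converge.
- The mass audit quotes the trapezoid quadrature of the grid contents;
  the cell mass is conserved by construction only up to the discrete
  product rule (observed ≤ 1e-5 %), not to round-off like the polymer.
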