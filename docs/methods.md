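# Methods

## The model

`helixmi` implements a one-dimensional lattice model of a homogeneous DNA
double strand in which each nucleotide is a rigid disc of mass `m` and
moment of inertia `I`.  Two degrees of freedom per strand — a transverse
displacement and a rotation — are combined into symmetric/antisymmetric
coordinates: the in-phase stretch `w_j`, the out-of-phase stretch `lam_j`
(hydrogen-bond opening), and the reduced rotation `psi_j`.  Hydrogen
bonding is a Morse potential `D (e^{-a sqrt2 lam - g} - 1)^2` whose
rotational contribution `g = r (cos theta + cos phi)` couples stretch and
twist; nearest neighbours interact harmonically with stiffnesses `k`
(stretch) and `xi` (rotation).  A tight-binding charge carrier with
transfer integral `V` rides on the chain and couples to the local stretch
through an on-site Holstein term `chi lam_j |phi_j|^2`.  The dynamics is
semiclassical: the charge amplitude obeys a Schroedinger equation,

    i hbar d(phi_j)/dt = -V (phi_{j+1} + phi_{j-1}) + chi lam_j phi_j,

while `w`, `lam`, `psi` obey Newton equations.  In the small-angle
reduction the on-site exponential is `e^{-a sqrt2 lam}` in both the stretch
and rotation forces; the unreduced Morse geometry remains available for
energy evaluation (`total_energy(..., reduced=False)`).

In the long-wavelength limit the system closes into three coupled field
equations for `lam(x,t)`, `psi(x,t)`, `phi(x,t)` with coefficients

    W_g = 4 a^2 D / m,   alpha0 = 3 a sqrt2 / 2,   gamma2 = 7 a^2 / 3,
    c0 = -k/m,  c1 = -xi/I,  c2 = chi/m,  beta = m r W_g sqrt2 / (2 I),
    Q1 = -V/hbar,  Q2 = chi/hbar,  P1 = -2 V/hbar,  eta = c1/P1.

A third-order numerical expansion of the reduced Morse force reproduces
`W_g`, `W_g alpha0`, `W_g gamma2` (tested), so the continuum nonlinearity
is consistent with the discrete force.  Two transcription quirks of the
continuum charge equation are preserved as model definitions rather than
"fixed": the `P1`/`Q1` roles are interchanged relative to the naive
continuum limit of the hopping term, and the continuum charge-pressure
term `c2 |phi|^2` lacks the `lam` factor of its discrete counterpart
`-(chi/m) lam |phi|^2`.  Both are implemented as printed in their
respective backends, so the discrete and continuum backends agree for the
lattice fields in the long-wave limit (tested) but not for the charge
phase.

## Units

Energies in eV, lengths in angstrom, masses in amu, angles in radians.
The induced time unit is `t0 = 1 A sqrt(amu/eV) = 1.0181e-14 s` and
`hbar = 0.06465 eV t0` is a fixed constant of the unit system.  All
printed parameter values are usable unchanged; the reference integration
step `dt = 0.055` is read in units of `t0`.  Wavenumbers are rad/site.

## Default parameters

The package defaults are the growth-rate reference set: `m = I = 300 amu`,
`a = 4.41 1/A`, `D = 0.04 eV`, `chi = 0.3 eV/A`, `V = 0.0015 eV`,
`r = 0.3 A`, `k = 0.04 eV/A^2` (the only stacking stiffness printed in any
reference set, reused throughout).  The rotational stiffness `xi` is never
given numerically; it defaults to `k r^2` (the stretch stiffness acting at
the disc rim) and every output records the value used.  The equilibrium
gap `d` cancels from the reduced dynamics and defaults to 0.  Named
presets `fig1`, `fig2`, `fig3a/b`, `fig4a`–`fig4d` carry the other printed
sets; `fig3b` reads the transfer integral "15^-3 eV" as 15e-3 eV by
analogy with the companion panel's 10^-3 eV.

## Linear stability (modulational instability)

A uniform stretch `lam0`, a charge plane wave `phi0 e^{i(kx - w0 t)}` and
a rotation plane wave `psi0 e^{i(kx - w0 t)}` are perturbed at wavenumber
`K1`.  The linearized equations close into a 5x5 operator `M(Omega)` on
the perturbation amplitudes; `det M(Omega) = 0` is a degree-8 polynomial
whose largest positive imaginary root is the growth rate.  The operator is
block-triangular: the charge/stretch rows form a closed 3x3 block, and the
rotation rows (4–5) are driven by the stretch perturbation but never feed
back.  Consequently the spectrum factorizes exactly, and with a dark
carrier (`phi0 = 0`) the growth rate equals the blockwise maximum
(tested).

Two entry conventions are provided and their differences reported at run
time.  `as_printed` reproduces the published entry table; `rederived`
(canonical) generates every entry mechanically from the linearized field
equations and differs in four places: the sign of the `2 alpha0 lam0` term
in `m33`, the `b1`/`b2` content of the rotation-row couplings, the `lam0`
power in `m44`, and a factor 2 on the `K K1` cross term `m45`.  The
published closed-form polynomial coefficients additionally deviate from
the exact expansion of `det M` in the signs of several `w0^2` cross terms
and in the constant term (which also cancels internally; both facts are
verified symbolically and numerically).  The package therefore exposes
three root-finding routes: the published coefficients (`printed_poly`),
the exact expansion (`expanded_poly`), and an independent determinant
oracle (`det_roots`) that linearizes the quadratic matrix pencil into a
10x10 generalized eigenproblem and polishes the eight finite eigenvalues
by Newton iteration on the holomorphic determinant.  `expanded_poly` and
`det_roots` agree to better than 1e-6 relative on random draws (tested); a
9-point interpolation of the determinant was rejected because the
low-order coefficients (~1e-13 against unit leading coefficient) drown in
cancellation.

The carrier dispersion `w0 = eta (A - k^2)/(B + k^2)` and the quartic
`k^4 - mu k^2 + mu1 = 0` for admissible carrier wavenumbers are
implemented as printed formulas.  `A` and `mu1` contain the ratio
`beta/W_g`, which is evaluated through its regular closed form
`m r sqrt2/(2I)` so the `D -> 0` limit stays finite.  Negative
discriminants yield complex `k^2`, returned with an explicit flag.  The
growth rate is independent of `w0` inside the rotation block (the `w0^2`
terms cancel in the imaginary parts), so the uncertain provenance of the
dispersion formula does not propagate into the instability predictions.

## Integrators

*Discrete backend.*  Strang splitting: a unitary charge substep (half
step), a symplectic lattice substep (full step, charge density frozen),
and a second unitary charge substep with the updated stretch.  The charge
substep is itself split-step Fourier — half a potential phase
`e^{-i chi lam tau/(2 hbar)}`, an exact hopping phase in Fourier space,
half a potential phase — a product of unitaries, so the charge norm is
conserved to rounding regardless of `dt` (observed: ~1e-15 over 1e4
steps).  The lattice substep composes velocity-Verlet with the triple-jump
(Yoshida) coefficients to fourth order.  Plain Verlet at the reference
step `dt = 0.055` would carry a bounded harmonic energy oscillation of
order `(omega dt)^2/8 ~ 4e-6` of the mode energy — above the 1e-6
conservation contract — while the fourth-order composition reduces it to
~1e-10 at three force evaluations per step.  The lattice substep is
exactly time reversible (tested).

*Continuum backend.*  Split-step Fourier (Strang): pointwise half-kicks of
all nonlinear/coupling terms, then exact per-mode evolution of the three
linear problems (a gapped wave equation for `lam`, a gapless one for
`psi`, the linear Schroedinger envelope for `phi`).  All charge factors
are phases, so the envelope norm is again exact.

A caveat the tests respect: the small-angle reduction is not variational —
the rotation restoring force `-G(lam) psi` has no counterpart
`-(1/2) G'(lam) psi^2` in the stretch equation — so the coupled
stretch-rotation sector conserves the natural energy only approximately
(~1e-5 relative over 1e4 steps at the reference amplitudes, independent of
the integrator).  With the rotation field at rest the stretch sector is
exactly Hamiltonian and the 1e-6 drift contract is met with two decades of
margin; the conservation suite therefore probes that sector, and the
residual drift of the coupled system is reported as a model property, not
an integrator defect.

## Cross-validation of the growth rate

Comparing the linear prediction against a direct simulation requires a
carrier state that actually solves the nonlinear equations; a uniform
*stretched* state (`lam0 > 0`) cannot be stationary under electron-type
coupling (`chi > 0`), because the charge pressure `c2 |phi|^2 > 0` is
compressive — the static balance
`W_g (lam - alpha0 lam^2 + gamma2 lam^3) = -c2 |phi0|^2` only has roots
`lam0 <= 0`, where the rotation sector is stable.  The validation scenario
therefore uses hole-type coupling `chi = -0.3 eV/A` (the Holstein coupling
sign depends on the carrier species), with `phi0 = 0.1427` chosen so the
self-consistent stretch is exactly the reference amplitude
`lam0 = 0.002 A`.  On this exactly stationary background the rotation
field evolves exactly linearly (it feeds back on nothing), so a
depth-0.01 rotation seed at `K1 = pi/65` grows indefinitely at the true
linear rate.  The rederived-mode prediction differs from the exact
linearization only at `O(alpha0 lam0) ~ 2%`; the measured rate agrees with
the prediction to ~2% (15% tolerance in the test).  For a wavenumber
beyond the rotation lobe edge a traveling-wave seed at the predicted mode
frequency keeps the sideband amplitude constant to ~0.6% over the same
horizon.  Problem sizes: 260 grid points, 45 000 steps of `dt = 0.055`.

## Qualitative parameter trends

*Disc radius.*  With `xi = k r^2`, the rotation-lobe peak behaves as
`beta lam0 - (3/4)(xi/I) K^2` at its best sideband (published entry
convention), i.e. `C1 r - C2 r^2`: it *rises* with `r` at small radii
(coupling `beta ~ r` beats stiffness `xi ~ r^2`) and falls beyond the
vertex (`r ~ 3.5 A` for the reference set with carrier `K = 3 pi/65`).
The acceptance check tests the decreasing branch — radii from the largest
printed disc radius (3 A) upward — which is the regime the qualitative
claim "larger nucleotides are less unstable" describes.  In the rederived
convention the factor-2 cross term completes the square,
`(xi/I)(K1 - K)^2`, so the lobe peak sits at `K1 = K` with the
stiffness-free value `sqrt(beta lam0)` and *increases* with `r` for all
radii: the two entry conventions differ qualitatively here, which is why
both are first-class citizens of the API.

*Charge coupling.*  In the linear theory `chi` enters only the
charge/stretch block, whose instability windows (where `m11^2` crosses
`m33`) have width growing like `chi`–`chi^2`; the rotation lobe is
`chi`-independent at fixed `lam0` and suppressed entirely under the
self-consistent (negative) stretch.  The unstable-`K1` measure of the
`chi` sweep is therefore *non-decreasing* in `chi` under every policy this
package implements, and the corresponding acceptance test — which asserts
the opposite, qualitative claim of shrinking instability domains — fails
and is intentionally left failing.  The shrinking-domain phenomenology
belongs to the nonlinear charge-pattern regime, which the linear scan
cannot represent; the simulation backends remain available to explore it.

## Numerical choices and degenerate inputs

- Root sorting: descending by (imaginary, real) part; root-set comparisons
  use greedy nearest-neighbour pairing (lexicographic sorting mis-pairs
  near-conjugate clusters).
- Residual contract: every returned root satisfies
  `|det M(Omega)| < 1e-8 x matrix scale` (scale: fourth power of the
  largest entry magnitude, floored at 1); ill-conditioned solves attach a
  warning but still return roots.
- `D = 0` zeroes `W_g` and `beta` but not the ratio `beta/W_g`; `chi = 0`
  zeroes `c2` and `Q2` and decouples the carrier; `xi = 0` or `V = 0` make
  the printed dispersion formulas singular and raise a dedicated error.
- Plane-wave initial data require commensurate wavenumbers
  (`K N / 2 pi` integral); the error message suggests the nearest valid
  chain length.
- Blow-up (non-finite fields) raises an error carrying the step index.
- Defaults for the numerical experiments: `N = 260` sites (two periods of
  the `K = pi/65` modulation), periodic boundaries (required by the
  plane-wave data), `dt = 0.055 t0`.

## What the synthetic scenarios do and do not show

All inputs are generated: modulated plane waves for the dynamics and
random physical parameter draws for the oracle equivalence.  Passing tests
demonstrate internal consistency (integrator contracts, dual-route root
finding, linear-vs-nonlinear agreement on exact carrier states) and the
printed parameter sets' stability landscape.  They do not validate the
model against experimental DNA data: the chain is homogeneous (no
sequence heterogeneity), there is no thermal noise, no electric field, no
helicoidal coupling, and the semiclassical treatment ignores charge
quantum correlations.  Those are model non-goals, not implementation
gaps.
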