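"""Time integration of the reduced lattice-charge equations.

Two backends integrate the same physics:

* ``discrete`` -- the three site-indexed equations of motion: a Schroedinger
  equation for the charge amplitude ``phi_j`` (tight-binding hopping ``V``
  plus Holstein coupling ``chi lam_j phi_j``), Newton equations for the
  out-of-phase stretch ``lam_j`` (harmonic stacking + reduced Morse force -
  ``chi lam_j |phi_j|^2`` back-reaction) and for the reduced rotation
  ``psi_j``, plus the purely harmonic in-phase stretch ``w_j``.
* ``continuum_spectral`` -- the long-wavelength limit: coupled nonlinear
  wave equations for ``lam(x,t)`` and ``psi(x,t)`` and a linear-Schroedinger
  envelope for ``phi(x,t)``, advanced with a split-step Fourier scheme whose
  linear substeps are exact in spectral space.

The lattice substep is symplectic (velocity-Verlet composed to fourth order
with the triple-jump coefficients) and time reversible; every charge substep
is unitary, so ``sum_j |phi_j|^2`` is conserved to rounding regardless of
step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .model_core import (
    DerivedCoefficients,
    LatticeState,
    ModelParameters,
    derive_coefficients,
    reduced_onsite_force,
    rotation_onsite_factor,
    total_energy,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ContinuumFields",
    "BlowUpError",
    "CommensurabilityError",
    "init_modulated_wave",
    "init_modulated_wave_continuum",
    "accelerations",
    "schrodinger_rhs",
    "step",
    "step_lattice",
    "step_continuum",
    "integrate",
    "continuum_energy",
    "sideband_amplitude",
    "measure_sideband_growth",
    "GrowthMeasurement",
]

# triple-jump (Yoshida) composition weights for the 4th-order lattice step
_Y4_W1 = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
_Y4_W0 = 1.0 - 2.0 * _Y4_W1


class BlowUpError(FloatingPointError):
    """Raised when the integration produces non-finite values."""

    def __init__(self, message: str, step_index: int | None = None):
        super().__init__(message)
        self.step_index = step_index


class CommensurabilityError(ValueError):
    """Raised when a plane-wave wavenumber does not fit the periodic chain."""


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for :func:`integrate`.

    The defaults encode the reference numerical experiment: coherently
    modulated plane waves with perturbation wavenumber ``K = pi/65`` and
    carrier ``K0 = 3 pi/65`` (rad/site), amplitudes ``lam0 = phi0 = 0.002``,
    modulation depth 0.01, integrated with time step ``dt = 0.055`` (t0) on
    a periodic chain of ``N = 260`` sites (two periods of the modulation).
    """

    N: int = 260
    dt: float = 0.055
    n_steps: int = 1000
    backend: str = "discrete"
    bc: str = "periodic"
    K: float = math.pi / 65.0
    K0: float = 3.0 * math.pi / 65.0
    lam0: float = 0.002
    phi0: float = 0.002
    psi0: float | None = None  # None: psi_n mirrors lam_n
    mod_depth: float = 0.01
    seed: int = 0
    output_every: int = 1
    dx: float = 1.0  # continuum grid spacing in site units

    def __post_init__(self) -> None:
        if self.N < 3:
            raise ValueError(f"N must be >= 3, got {self.N}")
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 0:
            raise ValueError(f"n_steps must be >= 0, got {self.n_steps}")
        if self.backend not in ("discrete", "continuum_spectral"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.bc != "periodic":
            raise ValueError(f"only periodic boundary conditions are supported, got {self.bc!r}")
        if self.output_every < 1:
            raise ValueError("output_every must be >= 1")
        for name in ("K", "K0"):
            _check_commensurate(getattr(self, name), self.N, name)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_commensurate(K: float, N: int, name: str) -> None:
    if K == 0.0:
        return
    cycles = K * N / (2.0 * math.pi)
    if abs(cycles - round(cycles)) > 1e-9:
        period = 2.0 * math.pi / abs(K)
        n_near = max(3, int(round(round(N / period) * period)) or int(round(period)))
        raise CommensurabilityError(
            f"{name} = {K:g} rad/site is incommensurate with N = {N}: "
            f"{name}*N/(2*pi) = {cycles:.6f} is not an integer; "
            f"the nearest commensurate chain length is N = {n_near}"
        )


def init_modulated_wave(config: SimulationConfig) -> LatticeState:
    """Coherently modulated plane waves on the discrete chain.

    ``lam_n = psi_n = lam0 (1 + depth cos(K n)) cos(K0 n)`` and
    ``phi_n = phi0 (1 + depth exp(i K n)) exp(i K0 n)``; momenta and the
    in-phase stretch start at zero.
    """
    n = np.arange(config.N, dtype=float)
    depth = config.mod_depth
    lam = config.lam0 * (1.0 + depth * np.cos(config.K * n)) * np.cos(config.K0 * n)
    psi0 = config.lam0 if config.psi0 is None else config.psi0
    psi = psi0 * (1.0 + depth * np.cos(config.K * n)) * np.cos(config.K0 * n)
    phi = config.phi0 * (1.0 + depth * np.exp(1j * config.K * n)) * np.exp(1j * config.K0 * n)
    state = LatticeState.zeros(config.N)
    state.lam = lam
    state.psi = psi
    state.phi = phi.astype(complex)
    return state


def _lap(x: np.ndarray) -> np.ndarray:
    return np.roll(x, -1) + np.roll(x, 1) - 2.0 * x


def accelerations(state: LatticeState, params: ModelParameters,
                  coeffs: DerivedCoefficients | None = None,
                  phi_sq: np.ndarray | None = None):
    """Second time derivatives of ``(w, lam, psi)`` on the periodic chain.

    ``lamdd = (k/m) lap(lam) + F_morse(lam)/m - (chi/m) lam |phi|^2``,
    ``psidd = (xi/I) lap(psi) - G(lam) psi / I`` and
    ``wdd = (k/m) lap(w)``, with ``F_morse`` and ``G`` the reduced Morse
    force factors from :mod:`helixmi.model_core`.
    """
    p = params
    if phi_sq is None:
        phi_sq = np.abs(state.phi) ** 2
    a_w = (p.k / p.m) * _lap(state.w)
    a_lam = ((p.k / p.m) * _lap(state.lam)
             + reduced_onsite_force(state.lam, p) / p.m
             - (p.chi / p.m) * state.lam * phi_sq)
    a_psi = (p.xi / p.I) * _lap(state.psi) - rotation_onsite_factor(state.lam, p) * state.psi / p.I
    return a_w, a_lam, a_psi


def schrodinger_rhs(state: LatticeState, params: ModelParameters) -> np.ndarray:
    """``dphi_j/dt = (i/hbar) [V (phi_{j+1} + phi_{j-1}) - chi lam_j phi_j]``."""
    p = params
    phi = state.phi
    hop = np.roll(phi, -1) + np.roll(phi, 1)
    return (1j / p.hbar) * (p.V * hop - p.chi * state.lam * phi)


def _charge_substep(phi: np.ndarray, lam: np.ndarray, tau: float,
                    params: ModelParameters) -> np.ndarray:
    """Unitary Strang substep of the charge amplitude over ``tau`` (frozen lattice)."""
    p = params
    half_pot = np.exp(-0.5j * p.chi * lam * tau / p.hbar)
    phi = half_pot * phi
    q = 2.0 * np.pi * np.fft.fftfreq(phi.shape[0])
    phi = np.fft.ifft(np.exp(2j * p.V * np.cos(q) * tau / p.hbar) * np.fft.fft(phi))
    return half_pot * phi


def _verlet(state: LatticeState, dt: float, params: ModelParameters,
            phi_sq: np.ndarray) -> None:
    """One velocity-Verlet kick-drift-kick for the lattice fields, in place."""
    p = params
    a_w, a_lam, a_psi = accelerations(state, p, phi_sq=phi_sq)
    state.pw += 0.5 * dt * p.m * a_w
    state.plam += 0.5 * dt * p.m * a_lam
    state.ppsi += 0.5 * dt * p.I * a_psi
    state.w += dt * state.pw / p.m
    state.lam += dt * state.plam / p.m
    state.psi += dt * state.ppsi / p.I
    a_w, a_lam, a_psi = accelerations(state, p, phi_sq=phi_sq)
    state.pw += 0.5 * dt * p.m * a_w
    state.plam += 0.5 * dt * p.m * a_lam
    state.ppsi += 0.5 * dt * p.I * a_psi


def step_lattice(state: LatticeState, dt: float, params: ModelParameters,
                 phi_sq: np.ndarray | None = None, order: int = 4) -> LatticeState:
    """Advance only the lattice fields (charge density frozen); symplectic.

    ``order=2`` is plain velocity-Verlet; ``order=4`` (default) its
    triple-jump composition.  Both are exactly time reversible.
    """
    out = state.copy()
    if phi_sq is None:
        phi_sq = np.abs(state.phi) ** 2
    if order == 2:
        _verlet(out, dt, params, phi_sq)
    elif order == 4:
        _verlet(out, _Y4_W1 * dt, params, phi_sq)
        _verlet(out, _Y4_W0 * dt, params, phi_sq)
        _verlet(out, _Y4_W1 * dt, params, phi_sq)
    else:
        raise ValueError(f"order must be 2 or 4, got {order}")
    out.t = state.t + dt
    return out


def step(state: LatticeState, dt: float, params: ModelParameters,
         coeffs: DerivedCoefficients | None = None, *, order: int = 4) -> LatticeState:
    """One full discrete-backend step (Strang split charge/lattice).

    The charge amplitude is advanced by a unitary split-step over ``dt/2``,
    the lattice by a symplectic step over ``dt`` with ``|phi|^2`` frozen,
    then the charge by another ``dt/2`` with the updated stretch.  The charge
    norm is conserved to rounding; for ``chi = 0`` the lattice energy has no
    secular drift.
    """
    out = state.copy()
    out.phi = _charge_substep(out.phi, out.lam, 0.5 * dt, params)
    out = step_lattice(out, dt, params, phi_sq=np.abs(out.phi) ** 2, order=order)
    out.phi = _charge_substep(out.phi, out.lam, 0.5 * dt, params)
    out.t = state.t + dt
    if not (np.all(np.isfinite(out.lam)) and np.all(np.isfinite(out.psi))
            and np.all(np.isfinite(out.phi))):
        raise BlowUpError("integration blow-up: non-finite field values")
    return out


@dataclass
class ContinuumFields:
    """Fields of the continuum backend on a uniform periodic grid."""

    lam: np.ndarray
    lam_t: np.ndarray
    psi: np.ndarray
    psi_t: np.ndarray
    phi: np.ndarray
    dx: float = 1.0
    t: float = 0.0

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.lam_t = np.asarray(self.lam_t, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.psi_t = np.asarray(self.psi_t, dtype=float)
        self.phi = np.asarray(self.phi, dtype=complex)
        n = self.lam.shape
        for name in ("lam_t", "psi", "psi_t", "phi"):
            if getattr(self, name).shape != n:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {n}")

    @property
    def n_grid(self) -> int:
        return self.lam.shape[0]

    def copy(self) -> "ContinuumFields":
        return ContinuumFields(self.lam.copy(), self.lam_t.copy(), self.psi.copy(),
                               self.psi_t.copy(), self.phi.copy(), self.dx, self.t)

    def norm(self) -> float:
        return float(np.sum(np.abs(self.phi) ** 2) * self.dx)


def init_modulated_wave_continuum(config: SimulationConfig) -> ContinuumFields:
    """Sample the modulated plane waves of :func:`init_modulated_wave` on the grid."""
    n_grid = int(round(config.N / config.dx))
    x = np.arange(n_grid, dtype=float) * config.dx
    depth = config.mod_depth
    lam = config.lam0 * (1.0 + depth * np.cos(config.K * x)) * np.cos(config.K0 * x)
    psi0 = config.lam0 if config.psi0 is None else config.psi0
    psi = psi0 * (1.0 + depth * np.cos(config.K * x)) * np.cos(config.K0 * x)
    phi = config.phi0 * (1.0 + depth * np.exp(1j * config.K * x)) * np.exp(1j * config.K0 * x)
    z = np.zeros(n_grid)
    return ContinuumFields(lam=lam, lam_t=z.copy(), psi=psi, psi_t=z.copy(),
                           phi=phi.astype(complex), dx=config.dx)


def _kappa(n: int, dx: float) -> np.ndarray:
    return 2.0 * np.pi * np.fft.fftfreq(n, d=dx)


def _nonlinear_kick(f: ContinuumFields, tau: float, c: DerivedCoefficients) -> None:
    lam = f.lam
    f.lam_t += tau * (c.W_g * (c.alpha0 * lam**2 - c.gamma2 * lam**3) - c.c2 * np.abs(f.phi) ** 2)
    f.psi_t += tau * c.beta * (f.psi * lam - c.alpha0 * f.psi * lam**2 + c.gamma2 * f.psi * lam**3)
    f.phi *= np.exp(-1j * c.Q2 * lam * tau)


def _oscillator_rotate(u_hat, v_hat, omega, dt):
    """Exact evolution of ``udd = -omega^2 u`` per Fourier mode (omega may be 0)."""
    cw = np.cos(omega * dt)
    sw = np.sin(omega * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        sinc = np.where(omega > 0.0, sw / np.where(omega > 0.0, omega, 1.0), dt)
    u_new = cw * u_hat + sinc * v_hat
    v_new = -omega * sw * u_hat + cw * v_hat
    return u_new, v_new


def _linear_drift(f: ContinuumFields, dt: float, c: DerivedCoefficients) -> None:
    kap = _kappa(f.n_grid, f.dx)
    # lam: lam_tt = -c0 lam_xx - W_g lam  ->  omega^2 = W_g - c0 kap^2  (c0 <= 0)
    om_lam = np.sqrt(np.maximum(c.W_g - c.c0 * kap**2, 0.0))
    lam_hat, lamt_hat = np.fft.fft(f.lam), np.fft.fft(f.lam_t)
    lam_hat, lamt_hat = _oscillator_rotate(lam_hat, lamt_hat, om_lam, dt)
    f.lam, f.lam_t = np.fft.ifft(lam_hat).real, np.fft.ifft(lamt_hat).real
    # psi: psi_tt = -c1 psi_xx  ->  omega^2 = -c1 kap^2  (c1 <= 0)
    om_psi = np.sqrt(np.maximum(-c.c1, 0.0)) * np.abs(kap)
    psi_hat, psit_hat = np.fft.fft(f.psi), np.fft.fft(f.psi_t)
    psi_hat, psit_hat = _oscillator_rotate(psi_hat, psit_hat, om_psi, dt)
    f.psi, f.psi_t = np.fft.ifft(psi_hat).real, np.fft.ifft(psit_hat).real
    # phi: i phi_t = P1 phi_xx + Q1 phi  ->  phase -(Q1 - P1 kap^2) dt
    phi_hat = np.fft.fft(f.phi)
    phi_hat *= np.exp(-1j * (c.Q1 - c.P1 * kap**2) * dt)
    f.phi = np.fft.ifft(phi_hat)


def step_continuum(fields: ContinuumFields, dt: float,
                   coeffs: DerivedCoefficients) -> ContinuumFields:
    """One split-step Fourier advance of the continuum system (Strang order).

    Nonlinear/coupling terms act as pointwise half-kicks; the linear parts of
    all three fields are solved exactly per Fourier mode.  The phi update is
    a product of unitaries, so the envelope norm is conserved to rounding.
    """
    out = fields.copy()
    _nonlinear_kick(out, 0.5 * dt, coeffs)
    _linear_drift(out, dt, coeffs)
    _nonlinear_kick(out, 0.5 * dt, coeffs)
    out.t = fields.t + dt
    if not (np.all(np.isfinite(out.lam)) and np.all(np.isfinite(out.psi))
            and np.all(np.isfinite(out.phi))):
        raise BlowUpError("integration blow-up: non-finite field values")
    return out


def continuum_energy(f: ContinuumFields, coeffs: DerivedCoefficients) -> float:
    """Diagnostic energy functional of the continuum lattice fields (per unit mass).

    ``int dx [ lam_t^2/2 - c0 lam_x^2/2 + W_g(lam^2/2 - alpha0 lam^3/3 +
    gamma2 lam^4/4) + c2 |phi|^2 lam + psi_t^2/2 - c1 psi_x^2/2
    - beta lam (1 - alpha0 lam + gamma2 lam^2) psi^2/2 ]``.
    Conserved up to the charge-envelope exchange and the dropped rotation
    back-reaction.
    """
    c = coeffs
    kap = _kappa(f.n_grid, f.dx)
    lam_x = np.fft.ifft(1j * kap * np.fft.fft(f.lam)).real
    psi_x = np.fft.ifft(1j * kap * np.fft.fft(f.psi)).real
    lam = f.lam
    dens = (0.5 * f.lam_t**2 - 0.5 * c.c0 * lam_x**2
            + c.W_g * (0.5 * lam**2 - c.alpha0 * lam**3 / 3.0 + 0.25 * c.gamma2 * lam**4)
            + c.c2 * np.abs(f.phi) ** 2 * lam
            + 0.5 * f.psi_t**2 - 0.5 * c.c1 * psi_x**2
            - 0.5 * c.beta * lam * (1.0 - c.alpha0 * lam + c.gamma2 * lam**2) * f.psi**2)
    return float(np.sum(dens) * f.dx)


@dataclass
class Trajectory:
    """Snapshots and diagnostics recorded by :func:`integrate`."""

    times: np.ndarray
    states: list
    norm_series: np.ndarray
    energy_series: np.ndarray
    config: SimulationConfig
    backend: str

    def lam_matrix(self) -> np.ndarray:
        """Space-time matrix of the stretch field, shape (n_snapshots, N)."""
        return np.stack([s.lam for s in self.states])

    def phi_matrix(self) -> np.ndarray:
        return np.stack([s.phi for s in self.states])

    @property
    def n_snapshots(self) -> int:
        return len(self.states)


def integrate(config: SimulationConfig, params: ModelParameters,
              initial_state=None) -> Trajectory:
    """Run ``n_steps`` of the configured backend and record snapshots.

    Deterministic given the configuration.  Snapshots (deep copies) are
    stored every ``output_every`` steps together with the charge norm and the
    energy diagnostic.  Integration errors are re-raised with the failing
    step index attached.
    """
    coeffs = derive_coefficients(params)
    discrete = config.backend == "discrete"
    if initial_state is None:
        state = init_modulated_wave(config) if discrete else init_modulated_wave_continuum(config)
    else:
        state = initial_state.copy()

    def diag(s):
        if discrete:
            return s.norm(), total_energy(s, params)
        return s.norm(), continuum_energy(s, coeffs)

    times = [state.t]
    states = [state.copy()]
    n0, e0 = diag(state)
    norms, energies = [n0], [e0]
    for i in range(config.n_steps):
        try:
            if discrete:
                state = step(state, config.dt, params, coeffs)
            else:
                state = step_continuum(state, config.dt, coeffs)
        except BlowUpError as err:
            raise BlowUpError(f"{err} at step {i + 1}", step_index=i + 1) from err
        if (i + 1) % config.output_every == 0 or (i + 1) == config.n_steps:
            times.append(state.t)
            states.append(state.copy())
            n_i, e_i = diag(state)
            norms.append(n_i)
            energies.append(e_i)
    return Trajectory(times=np.asarray(times), states=states,
                      norm_series=np.asarray(norms), energy_series=np.asarray(energies),
                      config=config, backend=config.backend)


def sideband_amplitude(traj: Trajectory, K: float, field: str = "lam") -> np.ndarray:
    """Modulus of the spatial Fourier amplitude at ``K`` per snapshot.

    ``field`` selects the stretch (``"lam"``, default), the rotation
    (``"psi"``) or the charge amplitude (``"phi"``).
    """
    if field == "lam":
        mat = traj.lam_matrix()
    elif field == "psi":
        mat = np.stack([s.psi for s in traj.states])
    elif field == "phi":
        mat = traj.phi_matrix()
    else:
        raise ValueError(f"unknown field {field!r}")
    n = mat.shape[1]
    dx = traj.config.dx if traj.backend == "continuum_spectral" else 1.0
    m = int(round(K * n * dx / (2.0 * math.pi)))
    return np.abs(np.fft.fft(mat, axis=1)[:, m]) / n


@dataclass
class GrowthMeasurement:
    """Fitted sideband growth rate and the window it was fitted on."""

    rate: float
    flag: str  # "unstable" or "stable/indeterminate"
    window: tuple
    relative_change: float
    r_squared: float


def measure_sideband_growth(traj: Trajectory, K: float,
                            growth_factor: float = math.e,
                            field: str = "lam") -> GrowthMeasurement:
    """Fit the exponential growth rate of the sideband at wavenumber ``K``.

    The slope of ``log |field_hat(K, t)|`` is fitted over the initial
    exponential window (from the time the amplitude has doubled until it
    reaches half its maximum).  If the amplitude never grows by the factor
    ``growth_factor`` the result is flagged ``stable/indeterminate`` with
    rate 0 and the relative amplitude change observed.
    """
    if traj.n_snapshots < 2:
        raise ValueError("trajectory must contain at least two snapshots")
    amps = sideband_amplitude(traj, K, field=field)
    t = traj.times
    a0 = amps[0]
    if a0 <= 0.0:
        a0 = np.max(amps) * 1e-12 + np.finfo(float).tiny
    rel_change = float(np.max(np.abs(amps - amps[0])) / max(a0, np.finfo(float).tiny))
    if np.max(amps) < growth_factor * a0:
        return GrowthMeasurement(0.0, "stable/indeterminate", (0, len(amps) - 1),
                                 rel_change, 0.0)
    i_start = int(np.argmax(amps >= 2.0 * a0))
    i_end = int(np.argmax(amps >= 0.5 * np.max(amps)))
    if i_end <= i_start + 1:
        i_start, i_end = 0, int(np.argmax(amps))
    sel = slice(i_start, i_end + 1)
    y = np.log(amps[sel])
    x = t[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return GrowthMeasurement(float(slope), "unstable", (i_start, i_end), rel_change, r2)
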