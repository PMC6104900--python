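"""Physical parameters, unit system, coordinate transforms and energies.

The model describes a homogeneous double strand in which each nucleotide is
a rigid disc of mass ``m`` and moment of inertia ``I``.  Base pairs carry an
in-phase stretch ``w`` and an out-of-phase stretch ``lam`` (hydrogen-bond
opening) coupled harmonically along the strand with stiffness ``k``; discs
rotate with stacking stiffness ``xi``.  Hydrogen bonding is a Morse
potential of depth ``D`` and inverse width ``a``; a tight-binding charge
carrier hops between stacked base pairs with transfer integral ``V`` and
couples to the local stretch with a Holstein constant ``chi``.

Units
-----
Energies are in eV, lengths in angstrom, masses in amu and angles in
radians.  The induced time unit is ``t0 = 1 A * sqrt(amu/eV) ~ 1.018e-14 s``
and the reduced Planck constant is the fixed value ``HBAR = 0.06465 eV*t0``.
All frequencies and rates are in 1/t0, wavenumbers in rad/site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "HBAR_EV_T0",
    "T0_SECONDS",
    "ModelParameters",
    "DerivedCoefficients",
    "LatticeState",
    "FullAngleState",
    "derive_coefficients",
    "morse_potential",
    "reduced_onsite_force",
    "rotation_onsite_factor",
    "total_energy",
    "full_to_reduced",
    "reduced_to_full",
]

#: model time unit in SI seconds, 1 A * sqrt(1 amu / 1 eV)
T0_SECONDS = 1e-10 * math.sqrt(1.66053906660e-27 / 1.602176634e-19)

#: reduced Planck constant in eV * t0 (fixed by the unit system)
HBAR_EV_T0 = 6.582119569e-16 / T0_SECONDS

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class ModelParameters:
    """Physical constants of the lattice + charge system.

    Defaults are the growth-rate reference set (300 amu nucleotides,
    a = 4.41 1/A, D = 0.04 eV, chi = 0.3 eV/A, V = 0.0015 eV); the stacking
    stiffness k = 0.04 eV/A^2 is the only printed value in the source
    parameter sets.  ``xi`` defaults to ``k * r**2`` (dimensional analogy
    with the stretch stiffness acting at the disc rim); pass it explicitly
    to override.

    Parameters
    ----------
    m : float
        Nucleotide mass (amu).
    I : float
        Moment of inertia of a disc (amu * A^2).
    k : float
        Stretch stacking stiffness (eV/A^2).
    xi : float or None
        Rotational stacking stiffness (eV/rad^2); ``None`` selects
        ``k * r**2``.
    D : float
        Morse dissociation energy (eV).
    a : float
        Morse inverse width (1/A).
    r : float
        Disc radius (A).
    d : float
        Equilibrium gap between disc rims (A); cancels from the reduced
        dynamics and only enters the unreduced Morse geometry.
    chi : float
        Holstein charge-lattice coupling (eV/A).
    V : float
        Tight-binding transfer integral (eV).
    hbar : float
        Reduced Planck constant (eV * t0); fixed by the unit system and not
        meant to be tuned.
    """

    m: float = 300.0
    I: float = 300.0
    k: float = 0.04
    xi: float | None = None
    D: float = 0.04
    a: float = 4.41
    r: float = 0.3
    d: float = 0.0
    chi: float = 0.3
    V: float = 0.0015
    hbar: float = HBAR_EV_T0

    def __post_init__(self) -> None:
        if self.xi is None:
            object.__setattr__(self, "xi", self.k * self.r**2)
        for name in ("m", "I", "hbar"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if not self.a > 0.0:
            raise ValueError(f"a must be positive, got {self.a!r}")
        for name in ("D", "r", "k", "xi"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)!r}")

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields changed."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients of the long-wavelength (continuum) equations.

    Each field equals its defining formula evaluated on a
    :class:`ModelParameters`; see :func:`derive_coefficients`.
    ``beta_over_wg`` is the ratio ``beta / W_g = m r sqrt(2) / (2 I)``,
    kept separately because it stays finite when ``D -> 0`` makes both
    ``beta`` and ``W_g`` vanish.
    """

    W_g: float
    alpha0: float
    gamma2: float
    c0: float
    c1: float
    c2: float
    beta: float
    Q1: float
    Q2: float
    P1: float
    eta: float
    beta_over_wg: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def derive_coefficients(params: ModelParameters) -> DerivedCoefficients:
    """Evaluate the continuum-equation coefficients.

    ``W_g = 4 a^2 D / m`` is the squared gap frequency of the stretch field,
    ``alpha0 = 3 a sqrt(2) / 2`` and ``gamma2 = 7 a^2 / 3`` the quadratic and
    cubic Taylor coefficients of the reduced Morse force, ``c0 = -k/m`` and
    ``c1 = -xi/I`` the (negated) squared sound speeds, ``c2 = chi/m`` the
    charge pressure on the stretch, ``beta = m r W_g sqrt(2) / (2 I)`` the
    stretch-rotation coupling, and ``Q1 = -V/hbar``, ``Q2 = chi/hbar``,
    ``P1 = -2V/hbar``, ``eta = c1/P1`` the charge-envelope coefficients.
    """
    if not isinstance(params, ModelParameters):
        params = ModelParameters(**dict(params))
    p = params
    W_g = 4.0 * p.a**2 * p.D / p.m
    beta_over_wg = p.m * p.r * _SQRT2 / (2.0 * p.I)
    P1 = -2.0 * p.V / p.hbar
    return DerivedCoefficients(
        W_g=W_g,
        alpha0=3.0 * p.a * _SQRT2 / 2.0,
        gamma2=7.0 * p.a**2 / 3.0,
        c0=-p.k / p.m,
        c1=-p.xi / p.I,
        c2=p.chi / p.m,
        beta=beta_over_wg * W_g,
        Q1=-p.V / p.hbar,
        Q2=p.chi / p.hbar,
        P1=P1,
        eta=(-p.xi / p.I) / P1 if P1 != 0.0 else math.inf,
        beta_over_wg=beta_over_wg,
    )


def morse_potential(lam, g_val, params: ModelParameters):
    """On-site Morse energy ``D (exp(-a sqrt(2) lam - g) - 1)^2`` in eV.

    ``g`` is the rotational contribution ``r (cos(theta) + cos(phi))`` of the
    disc angles to the hydrogen-bond length; pass ``g_val = 0`` for the
    reduced (small-angle) potential.  Total function: accepts scalars or
    arrays, always returns a non-negative energy.
    """
    z = -params.a * _SQRT2 * np.asarray(lam, dtype=float) - np.asarray(g_val, dtype=float)
    return params.D * np.square(np.expm1(z))


def reduced_onsite_force(lam, params: ModelParameters):
    """Reduced Morse force ``2 sqrt(2) a D (e^{-a sqrt2 lam} - 1) e^{-a sqrt2 lam}``.

    This is minus the gradient of the reduced on-site potential
    ``D (e^{-a sqrt2 lam} - 1)^2`` and the nonlinearity whose third-order
    Taylor expansion generates ``W_g``, ``alpha0`` and ``gamma2``.
    """
    e = np.exp(-params.a * _SQRT2 * np.asarray(lam, dtype=float))
    return 2.0 * _SQRT2 * params.a * params.D * (e - 1.0) * e


def rotation_onsite_factor(lam, params: ModelParameters):
    """Factor ``2 r a D (e^{-a sqrt2 lam} - 1) e^{-a sqrt2 lam}`` of the rotation force.

    The reduced rotation obeys ``I psidd = xi lap(psi) - factor * psi``.
    """
    e = np.exp(-params.a * _SQRT2 * np.asarray(lam, dtype=float))
    return 2.0 * params.r * params.a * params.D * (e - 1.0) * e


@dataclass
class LatticeState:
    """Per-site coordinates, momenta and charge amplitude of the chain.

    Arrays all have the same length ``N >= 3``.  ``w`` and ``lam`` are the
    in-phase and out-of-phase stretches (A), ``psi`` the reduced rotation
    (rad), ``pw``/``plam`` linear momenta (amu*A/t0, i.e. ``m * wdot``),
    ``ppsi`` the angular momentum ``I * psidot`` and ``phi`` the complex
    charge amplitude.
    """

    w: np.ndarray
    lam: np.ndarray
    psi: np.ndarray
    pw: np.ndarray
    plam: np.ndarray
    ppsi: np.ndarray
    phi: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.pw = np.asarray(self.pw, dtype=float)
        self.plam = np.asarray(self.plam, dtype=float)
        self.ppsi = np.asarray(self.ppsi, dtype=float)
        self.phi = np.asarray(self.phi, dtype=complex)
        n = self.w.shape[0] if self.w.ndim == 1 else -1
        for name in ("w", "lam", "psi", "pw", "plam", "ppsi", "phi"):
            arr = getattr(self, name)
            if arr.ndim != 1 or arr.shape[0] != n:
                raise ValueError(f"state arrays must be 1-d with a common length; {name} has shape {arr.shape}")
        if n < 3:
            raise ValueError(f"chain needs at least 3 sites, got {n}")

    @property
    def n_sites(self) -> int:
        return self.w.shape[0]

    @classmethod
    def zeros(cls, n: int) -> "LatticeState":
        z = np.zeros(n)
        return cls(w=z.copy(), lam=z.copy(), psi=z.copy(), pw=z.copy(),
                   plam=z.copy(), ppsi=z.copy(), phi=np.zeros(n, dtype=complex))

    def copy(self) -> "LatticeState":
        return LatticeState(self.w.copy(), self.lam.copy(), self.psi.copy(),
                            self.pw.copy(), self.plam.copy(), self.ppsi.copy(),
                            self.phi.copy(), self.t)

    def norm(self) -> float:
        """Total charge probability ``sum |phi_j|^2``."""
        return float(np.sum(np.abs(self.phi) ** 2))

    def normalized(self, total: float = 1.0) -> "LatticeState":
        out = self.copy()
        n = self.norm()
        if n <= 0.0:
            raise ValueError("cannot normalize a zero charge amplitude")
        out.phi = out.phi * math.sqrt(total / n)
        return out


@dataclass
class FullAngleState:
    """Strand displacements ``u``, ``v`` (A) and disc angles ``theta``, ``phi_ang`` (rad)."""

    u: np.ndarray
    v: np.ndarray
    theta: np.ndarray
    phi_ang: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi_ang = np.asarray(self.phi_ang, dtype=float)
        n = self.u.shape
        for name in ("v", "theta", "phi_ang"):
            if getattr(self, name).shape != n:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {n}")


def full_to_reduced(full: FullAngleState) -> dict:
    """Orthogonal transform to symmetric/antisymmetric coordinates.

    Returns ``w = (u+v)/sqrt2``, ``lam = (u-v)/sqrt2`` and the reduced
    angles ``x = (theta+phi)/2``, ``psi = (theta-phi)/2`` (the intermediate
    ``X``, ``Psi`` combinations divided by a further ``sqrt2``).
    """
    w = (full.u + full.v) / _SQRT2
    lam = (full.u - full.v) / _SQRT2
    X = (full.theta + full.phi_ang) / _SQRT2
    Psi = (full.theta - full.phi_ang) / _SQRT2
    return {"w": w, "lam": lam, "x": X / _SQRT2, "psi": Psi / _SQRT2}

def reduced_to_full(w, lam, x, psi) -> FullAngleState:
    """Inverse of :func:`full_to_reduced`; exact to rounding."""
    w = np.asarray(w, dtype=float)
    lam = np.asarray(lam, dtype=float)
    x = np.asarray(x, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (w.shape == lam.shape == x.shape == psi.shape):
        raise ValueError("coordinate arrays must share one shape")
    u = (w + lam) / _SQRT2
    v = (w - lam) / _SQRT2
    theta = x + psi
    phi_ang = x - psi
    return FullAngleState(u=u, v=v, theta=theta, phi_ang=phi_ang)


def total_energy(state: LatticeState, params: ModelParameters, *,
                 reduced: bool = True) -> float:
    """Total semiclassical energy ``H1 + <H2> + <H3>`` in eV (periodic chain).

    Lattice part: kinetic terms, harmonic stacking in ``w``, ``lam`` and
    ``psi``, and the on-site potential.  With ``reduced=True`` (default) the
    on-site part is the small-angle form
    ``D (e^{-a sqrt2 lam} - 1)^2 + r a D psi^2 (e^{-a sqrt2 lam} - 1) e^{-a sqrt2 lam}``
    whose gradients reproduce the reduced equations of motion (the quadratic
    psi term generates the rotation restoring force; its lam back-reaction
    is dropped by the reduction, so the coupled lam-psi sector conserves
    this energy only approximately).  With ``reduced=False`` the unreduced
    Morse geometry ``D (e^{-a sqrt2 lam - g} - 1)^2`` with
    ``g = 2 r cos(x) cos(psi) - 2 r`` (measured from equilibrium, ``x = 0``)
    is used for energy evaluation only.

    Charge part: ``<H2> = -V sum_j (phi_j^* phi_{j+1} + c.c.)`` and
    ``<H3> = sum_j chi lam_j |phi_j|^2``.
    """
    s = state
    p = params
    kinetic = (np.sum(s.pw**2) + np.sum(s.plam**2)) / (2.0 * p.m) + np.sum(s.ppsi**2) / (2.0 * p.I)
    stack = 0.5 * p.k * (np.sum(np.square(s.w - np.roll(s.w, 1)))
                         + np.sum(np.square(s.lam - np.roll(s.lam, 1))))
    stack += 0.5 * p.xi * np.sum(np.square(s.psi - np.roll(s.psi, 1)))
    if reduced:
        e = np.exp(-p.a * _SQRT2 * s.lam)
        onsite = p.D * np.sum(np.square(e - 1.0))
        onsite += p.r * p.a * p.D * np.sum(s.psi**2 * (e - 1.0) * e)
    else:
        # g measured from the equilibrium value 2r so that the flat chain has
        # zero energy: g_dev = 2 r (cos x cos psi - 1) with x = 0.
        g_dev = 2.0 * p.r * (np.cos(s.psi) - 1.0)
        onsite = float(np.sum(morse_potential(s.lam, g_dev, p)))
    h2 = -2.0 * p.V * float(np.real(np.sum(np.conj(s.phi) * np.roll(s.phi, -1))))
    h3 = p.chi * float(np.sum(s.lam * np.abs(s.phi) ** 2))
    total = float(kinetic + stack + onsite + h2 + h3)
    if not math.isfinite(total):
        raise FloatingPointError("non-finite total energy")
    return total
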