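"""Linear stability (modulational instability) of plane-wave carriers.

A uniform stretch ``lam0``, a charge plane wave ``phi0 exp(i(kx - w0 t))``
and a rotation plane wave ``psi0 exp(i(kx - w0 t))`` are perturbed at
wavenumber ``K1``.  The linearized system closes into a 5x5 operator
``M(Omega)`` acting on the perturbation amplitudes
``(u01, v01, lam01, u10, v20)``; nontrivial solutions require
``det M(Omega) = 0``, an eighth-order polynomial in the perturbation
frequency ``Omega``.  The growth rate at ``K1`` is the largest positive
imaginary part among the eight roots.

Two entry conventions are provided.  ``mode="as_printed"`` reproduces the
published entry table verbatim.  ``mode="rederived"`` (canonical) generates
every entry mechanically from the five linearized field equations via the
plane-wave substitution; it differs from the printed table in the sign of
the ``2 alpha0 lam0`` term of ``m33``, the ``b1/b2`` content of the
``lam -> psi`` coupling rows, the ``lam0`` power in ``m44`` and the factor
on the ``K*K1`` cross term ``m45``.  The entry-by-entry differences are
attached to every rederived matrix.

Similarly, the degree-8 characteristic polynomial is available in the
published coefficient form (``form="as_printed"``) and as the exact
expansion of ``det M`` (``form="expanded"``, verified symbolically); the
two differ in the sign of several ``w0^2`` cross terms and a missing
``m11^2 m33 (m44^2 - m45^2)`` contribution to the constant term.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model_core import DerivedCoefficients, ModelParameters, derive_coefficients

__all__ = [
    "SingularDispersionError",
    "PlaneWaveAnsatz",
    "DispersionAux",
    "CarrierWavenumbers",
    "PerturbationMatrix",
    "PolynomialCoefficients",
    "RootResult",
    "GrowthRateScan",
    "unperturbed_frequency",
    "dispersion_aux",
    "carrier_wavenumbers",
    "self_consistent_lam0",
    "build_perturbation_matrix",
    "det_M",
    "polynomial_coefficients",
    "printed_q_simplified",
    "solve_omega",
    "block_spectrum",
    "growth_rate",
    "scan_instability",
]

ENTRY_NAMES = ("m11", "m13", "m23", "m31", "m32", "m33", "m43", "m43b", "m44", "m45")


class SingularDispersionError(ZeroDivisionError):
    """Raised when a dispersion formula hits a pole (vanishing denominator)."""


@dataclass(frozen=True)
class PlaneWaveAnsatz:
    """Unperturbed carrier state of the linear stability analysis.

    ``k`` is the carrier wavenumber (rad/site), ``lam0`` the uniform stretch,
    ``phi0 = a1 + i a2`` the complex charge amplitude (``a1 = a2`` by
    default, the symmetric split) and ``psi0 = b1 + i b2`` the complex
    rotation amplitude.
    """

    k: float = 0.0
    lam0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    b1: float = 0.0
    b2: float = 0.0

    @classmethod
    def from_amplitudes(cls, k: float = 0.0, lam0: float = 0.0,
                        phi0: float = 0.0, psi0: complex = 0.0) -> "PlaneWaveAnsatz":
        """Build with the symmetric charge split ``a1 = a2 = |phi0|/sqrt(2)``."""
        a = abs(phi0) / math.sqrt(2.0)
        psi0 = complex(psi0)
        return cls(k=k, lam0=lam0, a1=a, a2=a, b1=psi0.real, b2=psi0.imag)

    @property
    def phi0(self) -> complex:
        return complex(self.a1, self.a2)

    @property
    def psi0(self) -> complex:
        return complex(self.b1, self.b2)

    @property
    def phi0_sq(self) -> float:
        return self.a1**2 + self.a2**2

    @property
    def symmetric(self) -> bool:
        return self.a1 == self.a2


def unperturbed_frequency(k: float, coeffs: DerivedCoefficients, lam0: float = 0.0) -> float:
    """Carrier frequency ``w0 = eta (A - k^2) / (B + k^2)``.

    ``A = beta c2 / (W_g c1)`` (evaluated through the regular ratio
    ``beta/W_g`` so the ``D -> 0`` limit is finite), ``B = (Q1 + Q2
    lam0)/P1`` and ``eta = c1/P1``.  Raises
    :class:`SingularDispersionError` at the pole ``B + k^2 = 0`` (and when
    ``c1`` or ``P1`` vanish, where the expression is undefined).
    """
    c = coeffs
    if c.c1 == 0.0 or c.P1 == 0.0:
        raise SingularDispersionError("dispersion undefined: c1 and P1 must be nonzero")
    A = c.beta_over_wg * c.c2 / c.c1
    B = (c.Q1 + c.Q2 * lam0) / c.P1
    den = B + k**2
    if not math.isfinite(den) or abs(den) < 1e-12 * (abs(B) + k**2 + 1e-300):
        raise SingularDispersionError(f"dispersion pole: B + k^2 = {den!r}")
    return c.eta * (A - k**2) / den


@dataclass(frozen=True)
class DispersionAux:
    """Auxiliary quantities of the carrier dispersion relation."""

    A: float
    B: float
    eta: float
    mu: float
    mu1: float


def dispersion_aux(coeffs: DerivedCoefficients, lam0: float = 0.0,
                   phi0_sq: float = 0.0) -> DispersionAux:
    """Evaluate ``A``, ``B``, ``eta`` and the quartic coefficients ``mu``, ``mu1``.

    ``mu = -(2 P1 (Q1 + Q2 lam0) + c1) / P1^2`` and
    ``mu1 = -beta c2 |phi0|^2 / W_g + (Q1 + Q2 lam0)^2``.
    """
    c = coeffs
    if c.c1 == 0.0 or c.P1 == 0.0:
        raise SingularDispersionError("auxiliary dispersion quantities need nonzero c1 and P1")
    q = c.Q1 + c.Q2 * lam0
    return DispersionAux(
        A=c.beta_over_wg * c.c2 / c.c1,
        B=q / c.P1,
        eta=c.eta,
        mu=-(2.0 * c.P1 * q + c.c1) / c.P1**2,
        mu1=-c.beta_over_wg * c.c2 * phi0_sq + q**2,
    )


class CarrierWavenumbers(NamedTuple):
    """Roots ``k+/-^2`` of ``k^4 - mu k^2 + mu1 = 0``; complex when flagged."""

    k_plus_sq: complex
    k_minus_sq: complex
    complex_branch: bool


def carrier_wavenumbers(coeffs: DerivedCoefficients, lam0: float = 0.0,
                        phi0_sq: float = 0.0) -> CarrierWavenumbers:
    """Admissible squared carrier wavenumbers ``k^2 = (mu +/- sqrt(mu^2 - 4 mu1))/2``.

    A negative discriminant yields complex ``k^2``; this is reported through
    the ``complex_branch`` flag rather than rejected.
    """
    aux = dispersion_aux(coeffs, lam0, phi0_sq)
    disc = aux.mu**2 - 4.0 * aux.mu1
    complex_branch = disc < 0.0
    root = cmath.sqrt(disc)
    k_plus = (aux.mu + root) / 2.0
    k_minus = (aux.mu - root) / 2.0
    if not complex_branch:
        k_plus, k_minus = k_plus.real, k_minus.real
    return CarrierWavenumbers(k_plus, k_minus, complex_branch)


def self_consistent_lam0(coeffs: DerivedCoefficients, phi0_sq: float) -> float:
    """Static stretch sustained by a uniform charge density.

    Solves ``W_g (lam - alpha0 lam^2 + gamma2 lam^3) + c2 |phi0|^2 = 0`` and
    returns the real root closest to the linear estimate
    ``-c2 |phi0|^2 / W_g`` (the cubic has a single real root for the model's
    parameter range).  The charge pressure is compressive, so the root is
    non-positive.
    """
    c = coeffs
    if c.W_g == 0.0:
        raise ValueError("self-consistent stretch undefined for W_g = 0")
    source = c.c2 * phi0_sq
    roots = np.roots([c.W_g * c.gamma2, -c.W_g * c.alpha0, c.W_g, source])
    real = roots[np.abs(roots.imag) < 1e-9 * (1.0 + np.abs(roots.real))].real
    if real.size == 0:
        raise ValueError("no real self-consistent stretch root found")
    guess = -source / c.W_g
    return float(real[np.argmin(np.abs(real - guess))])


@dataclass
class PerturbationMatrix:
    """Assembled 5x5 linear-stability operator at one ``(K, K1)``.

    ``entries`` maps entry names to values; ``m43`` feeds row 4 and ``m43b``
    row 5 (the printed table uses one shared ``m43``).  ``discrepancies``
    (rederived mode) lists every entry whose printed form differs, as
    ``name: (printed_value, rederived_value)``.
    """

    K: float
    K1: float
    w0: float
    mode: str
    entries: dict
    discrepancies: dict = field(default_factory=dict)

    def matrix(self, omega: complex) -> np.ndarray:
        """The operator ``M(Omega)`` with the frequency inserted."""
        e = self.entries
        om = complex(omega)
        cross = 1j * (2.0 * self.w0 * om + e["m45"])
        return np.array([
            [e["m11"], 1j * om, e["m13"], 0.0, 0.0],
            [-1j * om, e["m11"], e["m23"], 0.0, 0.0],
            [e["m31"], e["m32"], e["m33"] - om**2, 0.0, 0.0],
            [0.0, 0.0, e["m43"], e["m44"] - om**2, -cross],
            [0.0, 0.0, e["m43b"], cross, e["m44"] - om**2],
        ], dtype=complex)

    def det(self, omega: complex) -> complex:
        return complex(np.linalg.det(self.matrix(omega)))

    @property
    def scale(self) -> float:
        """Magnitude reference for residual tolerances."""
        e = self.entries
        row = max(1.0, max(abs(v) for v in e.values()), self.w0**2)
        return row**4

    @property
    def symmetric(self) -> bool:
        """Whether ``m13 m32 = m23 m31`` (the odd determinant terms cancel).

        Always true for the physical entry structure (``m13, m31`` carry
        ``a1`` and ``m23, m32`` carry ``a2``, so both products equal
        ``2 Q2 c2 a1 a2``); can fail only for hand-built entry sets.
        """
        e = self.entries
        return math.isclose(e["m13"] * e["m32"], e["m23"] * e["m31"],
                            rel_tol=1e-12, abs_tol=1e-300)


def _entries_as_printed(K, K1, w0, ansatz: PlaneWaveAnsatz, c: DerivedCoefficients) -> dict:
    lam0 = ansatz.lam0
    m43 = -c.beta * ansatz.b1 + 2.0 * c.alpha0 * lam0 * ansatz.b2 \
        + 3.0 * lam0**2 * c.gamma2 * ansatz.b2
    return {
        "m11": -c.P1 * K1**2 + c.Q1,
        "m13": c.Q2 * ansatz.a1,
        "m23": c.Q2 * ansatz.a2,
        "m31": 2.0 * c.c2 * ansatz.a1,
        "m32": 2.0 * c.c2 * ansatz.a2,
        "m33": -c.c0 * K1**2 + c.W_g * (1.0 + 2.0 * c.alpha0 * lam0 + 3.0 * lam0**2 * c.gamma2),
        "m43": m43,
        "m43b": m43,
        "m44": -w0**2 - c.c1 * K1**2 - c.c1 * K**2 - c.beta * lam0 + c.beta * lam0**2 * c.gamma2,
        "m45": -c.c1 * K * K1,
    }


def _entries_rederived(K, K1, w0, ansatz: PlaneWaveAnsatz, c: DerivedCoefficients) -> dict:
    lam0 = ansatz.lam0
    shape = 1.0 - 2.0 * c.alpha0 * lam0 - 3.0 * c.gamma2 * lam0**2
    return {
        "m11": -c.P1 * K1**2 + c.Q1,
        "m13": c.Q2 * ansatz.a1,
        "m23": c.Q2 * ansatz.a2,
        "m31": 2.0 * c.c2 * ansatz.a1,
        "m32": 2.0 * c.c2 * ansatz.a2,
        "m33": -c.c0 * K1**2 + c.W_g * (1.0 - 2.0 * c.alpha0 * lam0 + 3.0 * c.gamma2 * lam0**2),
        "m43": -c.beta * ansatz.b1 * shape,
        "m43b": -c.beta * ansatz.b2 * shape,
        "m44": -w0**2 - c.c1 * (K1**2 + K**2) - c.beta * lam0 + c.beta * c.gamma2 * lam0**3,
        "m45": 2.0 * c.c1 * K * K1,
    }


def build_perturbation_matrix(K: float, K1: float, w0: float,
                              ansatz: PlaneWaveAnsatz, coeffs: DerivedCoefficients,
                              mode: str = "rederived") -> PerturbationMatrix:
    """Assemble the 5x5 stability operator in the requested entry convention.

    ``mode="as_printed"`` uses the published entry table; ``mode="rederived"``
    substitutes the plane-wave perturbation directly into the five linearized
    field equations.  In rederived mode the returned matrix carries a
    ``discrepancies`` report with every entry whose printed form differs.
    """
    if mode == "as_printed":
        entries = _entries_as_printed(K, K1, w0, ansatz, coeffs)
        disc = {}
    elif mode == "rederived":
        entries = _entries_rederived(K, K1, w0, ansatz, coeffs)
        printed = _entries_as_printed(K, K1, w0, ansatz, coeffs)
        disc = {name: (printed[name], entries[name]) for name in ENTRY_NAMES
                if not math.isclose(printed[name], entries[name],
                                    rel_tol=1e-12, abs_tol=1e-300)}
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'as_printed' or 'rederived'")
    return PerturbationMatrix(K=K, K1=K1, w0=w0, mode=mode, entries=entries,
                              discrepancies=disc)


def det_M(omega: complex, matrix: PerturbationMatrix) -> complex:
    """Determinant of the stability operator with ``Omega`` inserted."""
    return matrix.det(omega)


class PolynomialCoefficients(NamedTuple):
    """Coefficients of ``Omega^8 - P Omega^6 - T Omega^5 + M Omega^4 + N Omega^3
    + R Omega^2 + Z Omega + Q``."""

    P: float
    T: float
    M: float
    N: float
    R: float
    Z: float
    Q: float

    def monic_coefficients(self) -> np.ndarray:
        """Coefficient vector (highest power first) for :func:`numpy.roots`."""
        return np.array([1.0, 0.0, -self.P, -self.T, self.M, self.N, self.R, self.Z, self.Q])


def printed_q_simplified(entries: dict) -> float:
    """The published constant term after its internal cancellation.

    The second and fourth terms of the printed ``Q`` (``-m11^2 m33 m45^2``
    and ``+m11^2 m33 m45^2``) cancel algebraically, leaving
    ``Q = 2 m11 m13 m31 (m45^2 - m44^2)``.
    """
    e = entries
    return 2.0 * e["m11"] * e["m13"] * e["m31"] * (e["m45"] ** 2 - e["m44"] ** 2)


def polynomial_coefficients(matrix: PerturbationMatrix,
                            form: str = "as_printed") -> PolynomialCoefficients:
    """Coefficients of the degree-8 eigenvalue polynomial.

    ``form="as_printed"`` returns the published closed forms verbatim (note
    the constant term's internal cancellation; see
    :func:`printed_q_simplified`).  ``form="expanded"`` returns the exact
    coefficients of ``det M(Omega)`` (valid whenever ``m13 m32 = m23 m31``,
    which the physical entry structure guarantees; the odd determinant
    cross terms then cancel); the two forms differ in the signs of several
    ``w0^2`` cross terms and in the constant term.
    """
    e = matrix.entries
    w0 = matrix.w0
    m11, m13, m23 = e["m11"], e["m13"], e["m23"]
    m31, m32, m33 = e["m31"], e["m32"], e["m33"]
    m44, m45 = e["m44"], e["m45"]
    if form == "as_printed":
        return PolynomialCoefficients(
            P=m11**2 + m33 + 2.0 * m44 - 4.0 * w0**2,
            T=4.0 * w0 * m45,
            M=(2.0 * m33 * m44 - 2.0 * m31 * m11 * m13
               + m11**2 * (2.0 * m44 + m33 - 4.0 * w0**2)
               + m44**2 + 4.0 * m33 * w0**2 - m45**2),
            N=w0 * (4.0 * m33 * m45 - 4.0 * m11**2 * m45),
            R=(2.0 * m11**2 * m33 * m44 + 4.0 * m23 * m44 * m32 * m11
               - m33 * m44**2 - (m11 * m44) ** 2 + 8.0 * m11 * m31 * m13 * w0**2
               - m33 * m45**2 - (m11 * m45) ** 2 - 4.0 * w0**2 * m11**2 * m33),
            Z=w0 * m45 * (8.0 * m11 * m13 * m31 - 4.0 * m11**2 * m33),
            Q=(2.0 * m45**2 * m11 * m13 * m31 - m11**2 * m33 * m45**2
               - 2.0 * m11 * m13 * m31 * m44**2 + m11**2 * m33 * m45**2),
        )
    if form == "expanded":
        if not matrix.symmetric:
            raise ValueError("expanded coefficients require m13*m32 = m23*m31 "
                             "(odd determinant terms cancel); use det-based roots otherwise")
        b = 2.0 * m44 + 4.0 * w0**2
        s3 = m11**2 + m33
        cc = 4.0 * w0 * m45
        d = m44**2 - m45**2
        ee = m11**2 * m33 - m11 * (m13 * m31 + m23 * m32)
        return PolynomialCoefficients(
            P=b + s3,
            T=cc,
            M=d + b * s3 + ee,
            N=cc * s3,
            R=-d * s3 - b * ee,
            Z=-cc * ee,
            Q=d * ee,
        )
    raise ValueError(f"unknown form {form!r}; expected 'as_printed' or 'expanded'")


@dataclass
class RootResult:
    """Eight frequency roots sorted by descending (imaginary, real) part."""

    roots: np.ndarray
    residuals: np.ndarray
    method: str
    warning: str | None = None

    @property
    def growth(self) -> float:
        return max(0.0, float(np.max(self.roots.imag)))


def _sort_roots(roots: np.ndarray) -> np.ndarray:
    order = np.lexsort((-roots.real, -roots.imag))
    return roots[order]


def _quadratic_pencil(matrix: PerturbationMatrix):
    """Split ``M(Omega) = A0 + A1 Omega + A2 Omega^2`` into its matrix coefficients."""
    e = matrix.entries
    a0 = matrix.matrix(0.0)
    a2 = np.diag([0.0, 0.0, -1.0, -1.0, -1.0]).astype(complex)
    a1 = np.zeros((5, 5), dtype=complex)
    a1[0, 1] = 1j
    a1[1, 0] = -1j
    a1[3, 4] = -2j * matrix.w0
    a1[4, 3] = 2j * matrix.w0
    return a0, a1, a2


def _det_eigen_roots(matrix: PerturbationMatrix) -> np.ndarray:
    """Roots of ``det M(Omega) = 0`` via companion linearization of the quadratic pencil.

    The 10x10 generalized eigenproblem has two infinite eigenvalues (the
    charge rows carry no ``Omega^2``); the eight finite ones are polished by
    a few Newton iterations on the holomorphic determinant.
    """
    from scipy.linalg import eig

    a0, a1, a2 = _quadratic_pencil(matrix)
    eye = np.eye(5, dtype=complex)
    lhs = np.block([[np.zeros((5, 5), dtype=complex), eye], [-a0, -a1]])
    rhs = np.block([[eye, np.zeros((5, 5), dtype=complex)],
                    [np.zeros((5, 5), dtype=complex), a2]])
    w, _ = eig(lhs, rhs, right=True, homogeneous_eigvals=True)
    alpha, beta = np.ravel(w[0]), np.ravel(w[1])
    finite = np.abs(beta) > 1e-10 * np.maximum(np.abs(alpha), 1.0)
    roots = alpha[finite] / beta[finite]
    if roots.size != 8:
        order = np.argsort(-np.abs(beta) / np.maximum(np.abs(alpha), 1e-300))
        roots = (alpha / np.where(beta == 0, 1e-300, beta))[order[:8]]
    # Newton polish on det (central-difference derivative of a holomorphic function)
    scale = 1.0 + np.max(np.abs(roots))
    for _ in range(3):
        h = 1e-7 * scale
        f = np.array([matrix.det(z) for z in roots])
        df = np.array([(matrix.det(z + h) - matrix.det(z - h)) / (2.0 * h) for z in roots])
        ok = np.abs(df) > 0
        step_v = np.zeros_like(roots)
        step_v[ok] = f[ok] / df[ok]
        step_v = np.where(np.abs(step_v) < 0.5 * scale, step_v, 0.0)
        roots = roots - step_v
    return roots


def solve_omega(matrix: PerturbationMatrix, method: str = "det_roots",
                tol: float = 1e-8) -> RootResult:
    """Solve for the eight perturbation frequencies.

    ``method="printed_poly"`` / ``"expanded_poly"`` build the companion
    matrix of the corresponding closed-form coefficients;
    ``method="det_roots"`` solves ``det M(Omega) = 0`` directly through a
    linearization of the quadratic matrix pencil plus Newton polishing (the
    independent oracle, never touching the closed-form coefficients).
    Residuals are reported per root; ill-conditioned solves attach a warning
    but still return the roots.
    """
    if method in ("printed_poly", "expanded_poly"):
        form = "as_printed" if method == "printed_poly" else "expanded"
        pc = polynomial_coefficients(matrix, form=form)
        coeff = pc.monic_coefficients().astype(complex)
        roots = np.roots(coeff)
        powers = np.vander(roots, 9)  # columns: roots**8 ... roots**0
        resid = np.abs(powers @ coeff)
        ref = np.maximum(1.0, np.abs(roots)) ** 8
    elif method == "det_roots":
        roots = _det_eigen_roots(matrix)
        resid = np.abs([matrix.det(z) for z in roots])
        ref = np.full(8, matrix.scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    roots = _sort_roots(roots)
    warning = None
    if np.any(resid > tol * np.maximum(ref, 1.0)):
        warning = (f"ill-conditioned root solve ({method}): max residual "
                   f"{np.max(resid / np.maximum(ref, 1.0)):.3e} exceeds {tol:g}")
    return RootResult(roots=roots, residuals=resid, method=method, warning=warning)


def block_spectrum(matrix: PerturbationMatrix) -> dict:
    """Frequencies of the decoupled blocks (exact when ``phi0 = 0``).

    Charge block: ``Omega = +/- m11``.  Stretch block: ``Omega^2 = m33``.
    Rotation block: ``(m44 - Omega^2)^2 = (2 w0 Omega + m45)^2``, i.e. the
    roots of ``Omega^2 + 2 w0 Omega + m45 - m44`` and
    ``Omega^2 - 2 w0 Omega - m45 - m44``.
    """
    e = matrix.entries
    w0 = matrix.w0
    charge = np.array([e["m11"], -e["m11"]], dtype=complex)
    s = cmath.sqrt(e["m33"])
    stretch = np.array([s, -s], dtype=complex)
    rot = np.concatenate([
        np.roots([1.0, 2.0 * w0, e["m45"] - e["m44"]]),
        np.roots([1.0, -2.0 * w0, -e["m45"] - e["m44"]]),
    ]).astype(complex)
    return {"charge": charge, "stretch": stretch, "rotation": rot}


def growth_rate(K: float, K1: float, ansatz: PlaneWaveAnsatz,
                coeffs: DerivedCoefficients, mode: str = "rederived",
                method: str = "det_roots", w0: float | None = None) -> float:
    """Maximum instability growth rate ``max(0, max Im Omega)`` at ``K1``.

    ``w0`` defaults to the printed carrier dispersion
    (:func:`unperturbed_frequency`) evaluated at ``K`` and ``lam0``.
    """
    if w0 is None:
        w0 = unperturbed_frequency(K, coeffs, ansatz.lam0)
    matrix = build_perturbation_matrix(K, K1, w0, ansatz, coeffs, mode=mode)
    return solve_omega(matrix, method=method).growth


@dataclass
class GrowthRateScan:
    """Growth-rate surface over a ``K1`` grid, optionally swept over a parameter."""

    k1_grid: np.ndarray
    sweep_name: str | None
    sweep_values: np.ndarray
    growth: np.ndarray  # (n_sweep, n_k1)
    roots: np.ndarray  # (n_sweep, n_k1, 8) complex
    coefficients: np.ndarray  # (n_sweep, n_k1, 7): P, T, M, N, R, Z, Q
    mode: str
    metadata: dict = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        """Tidy table: one row per (sweep value, K1)."""
        rows = []
        for i, sv in enumerate(self.sweep_values):
            for j, k1 in enumerate(self.k1_grid):
                row = {"K1": k1, "sweep_value": sv, "growth": self.growth[i, j]}
                for name, val in zip(("P", "T", "M", "N", "R", "Z", "Q"),
                                     self.coefficients[i, j]):
                    row[f"coef_{name}"] = val
                for r_i in range(8):
                    row[f"root{r_i}_re"] = self.roots[i, j, r_i].real
                    row[f"root{r_i}_im"] = self.roots[i, j, r_i].imag
                rows.append(row)
        df = pd.DataFrame(rows)
        if self.sweep_name is not None:
            df = df.rename(columns={"sweep_value": self.sweep_name})
        else:
            df = df.drop(columns="sweep_value")
        return df

    def unstable_measure(self, threshold: float = 1e-12) -> np.ndarray:
        """Total K1-measure of the unstable region per sweep value (grid sum)."""
        if self.k1_grid.size < 2:
            return (self.growth > threshold).sum(axis=1).astype(float)
        dk = float(np.mean(np.diff(self.k1_grid)))
        return (self.growth > threshold).sum(axis=1) * dk

    def boundaries(self, threshold: float = 1e-12) -> list:
        """Zero crossings of the growth rate (instability-domain edges) per sweep value."""
        out = []
        for g in self.growth:
            mask = g > threshold
            edges = np.flatnonzero(np.diff(mask.astype(int)) != 0)
            out.append([0.5 * (self.k1_grid[i] + self.k1_grid[i + 1]) for i in edges])
        return out


def scan_instability(k1_grid, params: ModelParameters | DerivedCoefficients, *,
                     k: float = 0.0, lam0="fixed", lam0_value: float = 0.0,
                     phi0: float = 0.0, psi0: complex = 0.0,
                     sweep: tuple | None = None, mode: str = "rederived",
                     method: str = "det_roots", w0: float | None = None,
                     xi_policy: str = "track") -> GrowthRateScan:
    """Tabulate growth rates over ``k1_grid``, optionally sweeping a model parameter.

    ``sweep=(name, values)`` re-derives the continuum coefficients for each
    value of the named :class:`ModelParameters` field.  ``lam0`` is either
    ``"fixed"`` (use ``lam0_value``) or ``"self_consistent"`` (solve the
    static balance of stretch against the uniform charge pressure
    ``c2 |phi0|^2`` for each sweep value).  When sweeping the disc radius
    ``r``, ``xi_policy="track"`` (default) re-ties the rotational stiffness
    to its ``k r^2`` default, while ``"hold"`` keeps the base value.
    Deterministic.
    """
    k1_grid = np.atleast_1d(np.asarray(k1_grid, dtype=float))
    if k1_grid.size == 0:
        raise ValueError("K1 grid must be nonempty")
    if isinstance(params, DerivedCoefficients):
        if sweep is not None or lam0 == "self_consistent":
            raise ValueError("parameter sweeps need ModelParameters, not coefficients")
        base_params = None
        coeff_list = [params]
        sweep_name, sweep_values = None, np.array([np.nan])
    else:
        base_params = params
        if sweep is None:
            sweep_name, sweep_values = None, np.array([np.nan])
            coeff_list = [derive_coefficients(base_params)]
        else:
            sweep_name, sweep_values = sweep
            sweep_values = np.asarray(sweep_values, dtype=float)
            if xi_policy not in ("track", "hold"):
                raise ValueError("xi_policy must be 'track' or 'hold'")
            changes_extra = {"xi": None} if (sweep_name == "r" and xi_policy == "track") else {}
            coeff_list = [derive_coefficients(base_params.replace(**{sweep_name: v}, **changes_extra))
                          for v in sweep_values]

    growth = np.empty((len(coeff_list), k1_grid.size))
    roots = np.empty((len(coeff_list), k1_grid.size, 8), dtype=complex)
    coefs = np.empty((len(coeff_list), k1_grid.size, 7))
    lam0_used = []
    for i, c in enumerate(coeff_list):
        if lam0 == "self_consistent":
            lam0_i = self_consistent_lam0(c, phi0**2)
        elif lam0 == "fixed":
            lam0_i = lam0_value
        else:
            raise ValueError("lam0 must be 'fixed' or 'self_consistent'")
        lam0_used.append(lam0_i)
        ansatz = PlaneWaveAnsatz.from_amplitudes(k=k, lam0=lam0_i, phi0=phi0, psi0=psi0)
        w0_i = unperturbed_frequency(k, c, lam0_i) if w0 is None else w0
        for j, k1 in enumerate(k1_grid):
            matrix = build_perturbation_matrix(k, k1, w0_i, ansatz, c, mode=mode)
            res = solve_omega(matrix, method=method)
            growth[i, j] = res.growth
            roots[i, j] = res.roots
            form = "expanded" if (mode == "rederived" and matrix.symmetric) else "as_printed"
            coefs[i, j] = polynomial_coefficients(matrix, form=form)
    meta = {"k": k, "lam0_policy": lam0, "lam0_used": lam0_used, "phi0": phi0,
            "psi0": complex(psi0), "mode": mode, "method": method}
    if mode == "rederived":
        mid = k1_grid[k1_grid.size // 2]
        probe_ansatz = PlaneWaveAnsatz.from_amplitudes(k=k, lam0=lam0_used[0],
                                                       phi0=phi0, psi0=psi0)
        w0_probe = unperturbed_frequency(k, coeff_list[0], lam0_used[0]) if w0 is None else w0
        probe = build_perturbation_matrix(k, mid, w0_probe, probe_ansatz,
                                          coeff_list[0], mode="rederived")
        meta["entry_discrepancies"] = {name: {"as_printed": pv, "rederived": rv}
                                       for name, (pv, rv) in probe.discrepancies.items()}
    return GrowthRateScan(k1_grid=k1_grid, sweep_name=sweep_name,
                          sweep_values=sweep_values, growth=growth, roots=roots,
                          coefficients=coefs, mode=mode, metadata=meta)
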