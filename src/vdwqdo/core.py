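"""Quantum-Drude-oscillator pair potential: parameterization and evaluation.

A quantum Drude oscillator (QDO) coarse-grains the valence response of an
atom into a single charged quasi-particle (the "drudon", charge -q, mass mu)
harmonically bound to a pseudo-nucleus with frequency omega.  Two free-atom
properties -- the static dipole polarizability alpha1 and the dipole-dipole
dispersion coefficient C6 -- fully determine the oscillator triple
{q, mu, omega}:

* omega follows from C6 = (3/4) hbar omega alpha1**2,
* the product mu*omega follows from a force balance, at the equilibrium
  distance predicted by the alpha1**(1/7) vdW-radius scaling law, between
  the dipole exchange repulsion and the dipole dispersion attraction,
* q then follows from alpha1 = q**2 / (mu omega**2).

The pair potential combines an exchange-repulsion wall derived from the
overlap of the two drudon ground states with the C6/C8/C10 dispersion
series (optionally damped):

    V(R) = A k_e q^2 S(R)/R - sum_n f_n(R) C_2n / R^(2n),   n = 3, 4, 5

where S(R) = exp(-mu omega R^2 / 2) and the amplitude A is fixed by
requiring dV/dR = 0 at the equilibrium distance.  Everything here is in
Hartree atomic units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammainc

from .constants import COULOMB_KE, VDW_RADIUS_PHI

__all__ = [
    "AtomProperties",
    "QDOParameterization",
    "NoPhysicalSolutionError",
    "MultipleRootsError",
    "drude_frequency",
    "equilibrium_distance",
    "higher_dispersion_coefficients",
    "gaussian_overlap",
    "damping_argument",
    "damping_factor",
    "solve_mu_omega",
    "exchange_amplitude",
    "qdo_parameters",
    "potential",
    "potential_derivative",
    "well_depth_closed_form",
    "well_depth_scaling_law",
]

logger = logging.getLogger(__name__)

_DISPERSION_ORDERS = (3, 4, 5)


class NoPhysicalSolutionError(RuntimeError):
    """The force balance has no physical root in the scanned interval."""


class MultipleRootsError(RuntimeError):
    """The force balance has more than one physical root."""


def _require_positive(**quantities) -> None:
    for name, value in quantities.items():
        if not (np.isfinite(value) and value > 0):
            raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class AtomProperties:
    """Free-atom input data, in atomic units.

    alpha1 : static dipole polarizability (bohr^3)
    c6     : dipole-dipole dispersion coefficient (hartree bohr^6)
    re_ref : optional reference dimer equilibrium distance (bohr)
    de_ref : optional reference dimer well depth (hartree)
    source : free-text provenance tag for the numbers
    """

    label: str
    alpha1: float
    c6: float
    re_ref: Optional[float] = None
    de_ref: Optional[float] = None
    source: str = ""

    def __post_init__(self):
        _require_positive(alpha1=self.alpha1, c6=self.c6)
        for name in ("re_ref", "de_ref"):
            value = getattr(self, name)
            if value is not None and not (np.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be positive and finite if given, got {value!r}")

    def scaled(self, ratio: float) -> "AtomProperties":
        """Tkatchenko-Scheffler atom-in-molecule rescaling by a Hirshfeld
        volume ratio v: alpha1 -> v*alpha1, C6 -> v^2*C6."""
        _require_positive(ratio=ratio)
        return replace(
            self,
            alpha1=ratio * self.alpha1,
            c6=ratio**2 * self.c6,
            re_ref=None,
            de_ref=None,
        )


@dataclass(frozen=True)
class QDOParameterization:
    """The oscillator triple {q, mu, omega} and derived pair quantities."""

    label: str
    alpha1: float
    c6: float
    q: float
    mu: float
    omega: float
    mu_omega: float
    c8: float
    c10: float
    r_e: float
    a_exch: float
    damped: bool

    def dispersion_coefficients(self):
        return (self.c6, self.c8, self.c10)


def drude_frequency(alpha1: float, c6: float) -> float:
    """Drude frequency omega = 4 C6 / (3 alpha1^2), inverting the QDO
    closed form C6 = (3/4) hbar omega alpha1^2 (atomic units)."""
    _require_positive(alpha1=alpha1, c6=c6)
    return 4.0 * c6 / (3.0 * alpha1**2)


def equilibrium_distance(alpha1: float) -> float:
    """Equilibrium distance of the homonuclear dimer from the vdW-radius
    scaling law: R_e = 2 R_vdW = 2 Phi alpha1^(1/7), with Phi evaluated
    from the fine-structure constant (Phi = alpha_fsc^(-4/21))."""
    _require_positive(alpha1=alpha1)
    return 2.0 * VDW_RADIUS_PHI * alpha1 ** (1.0 / 7.0)


def higher_dispersion_coefficients(c6: float, mu_omega: float) -> tuple[float, float]:
    """C8 and C10 from C6 and mu*omega via the QDO closed forms
    C8 = 5 C6 / (mu omega), C10 = (245/8) C6 / (mu omega)^2."""
    _require_positive(c6=c6, mu_omega=mu_omega)
    c8 = 5.0 * c6 / mu_omega
    c10 = (245.0 / 8.0) * c6 / mu_omega**2
    return c8, c10


def gaussian_overlap(mu_omega: float, r) -> float:
    """Overlap S(R) = exp(-mu omega R^2 / 2) of the two drudon ground-state
    densities, normalized so that S(0) = 1.

    The drudon ground state is an isotropic Gaussian of width
    1/sqrt(mu omega); the contact-normalized overlap of two such densities
    separated by R equals the squared wave-function overlap integral.
    """
    _require_positive(mu_omega=mu_omega)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    out = np.exp(-mu_omega * r**2 / 2.0)
    return float(out) if out.ndim == 0 else out


def damping_argument(mu_omega: float, r) -> float:
    """Dimensionless variable z = mu omega R^2 / 2 of the QDO damping
    function -- the same exponent that controls the drudon overlap, so the
    damping switches off each dispersion term on the overlap length scale.
    Isolated in one function on purpose: it is the single site that defines
    the damping variable."""
    _require_positive(mu_omega=mu_omega)
    return mu_omega * np.asarray(r, dtype=float) ** 2 / 2.0


def damping_factor(order_n: int, mu_omega: float, r) -> float:
    """QDO damping function for the C_2n dispersion term,

        f_n(z) = 1 - exp(-z) * sum_{k=0}^{n} z^k / k!,   z = mu omega R^2/2.

    Incomplete-gamma form of Tang-Toennies type, but summed only to n (not
    2n) and with the overlap variable z in place of b*R, so it contains only
    even powers of R up to R^(2n); f_n C_2n/R^(2n) ~ R^2 -> 0 at contact.
    Evaluated as the regularized lower incomplete gamma P(n+1, z), which is
    the same function without the small-z cancellation of the literal sum.
    """
    if order_n not in _DISPERSION_ORDERS:
        raise ValueError(f"order_n must be one of {_DISPERSION_ORDERS}, got {order_n}")
    z = damping_argument(mu_omega, r)
    if np.any(z < 0):
        raise ValueError("separation r must be non-negative")
    out = gammainc(order_n + 1, z)
    return float(out) if np.ndim(out) == 0 else out


def _damping_derivative_factor(order_n: int, z) -> float:
    """d f_n / d z = exp(-z) z^n / n! (telescoping derivative)."""
    return np.exp(-z) * z**order_n / math.factorial(order_n)


def _dipole_force_balance(t: float, alpha1: float, c6: float, r_e: float,
                          omega: float, damped: bool) -> float:
    """Residual of the dipole-approximation force balance at R_e.

    Exchange side: J_ex^(1)(R) = k_e q^2 S(R) / (2R), S = exp(-t R^2/2).
    Dispersion side: -f_3(R) C6/R^6 (f_3 = 1 when undamped).
    Returns d/dR [J_ex + V_disp] evaluated at R_e, with the sign chosen so
    the residual crosses zero from above at the physical root.
    """
    r2 = r_e * r_e
    q2 = alpha1 * t * omega  # q^2 = alpha1 mu omega^2 = alpha1 (mu omega) omega
    z = t * r2 / 2.0
    exchange_force = (COULOMB_KE * q2 / 2.0) * math.exp(-z) * (t + 1.0 / r2)
    if damped:
        # d/dR [f_3(z) C6 / R^6] with dz/dR = t R:
        dispersion_force = (c6 / r_e**7) * (
            6.0 * float(damping_factor(3, t, r_e))
            - 2.0 * z * float(_damping_derivative_factor(3, z))
        )
    else:
        dispersion_force = 6.0 * c6 / r_e**7
    return exchange_force - dispersion_force


def solve_mu_omega(alpha1: float, c6: float, r_e: float, damped: bool = False,
                   scan: tuple[float, float] = (1e-4, 1e2),
                   points_per_decade: int = 64) -> float:
    """Solve the transcendental dipole force balance at R_e for mu*omega.

    Roots are located by sign-change bracketing on a geometric grid over
    ``scan`` and refined with Brent's method to relative 1e-14.  The balance
    can have a second, spurious root at very small mu*omega where the drudon
    is more diffuse than the dimer itself (the residual rises through zero);
    only descending crossings -- the localized, physically decaying exchange
    branch -- are kept.  No descending root raises
    :class:`NoPhysicalSolutionError`; more than one raises
    :class:`MultipleRootsError` listing all of them.
    """
    _require_positive(alpha1=alpha1, c6=c6, r_e=r_e)
    omega = drude_frequency(alpha1, c6)

    def residual(t):
        return _dipole_force_balance(t, alpha1, c6, r_e, omega, damped)

    lo, hi = scan
    n = int(points_per_decade * math.log10(hi / lo)) + 1
    grid = np.geomspace(lo, hi, n)
    values = np.array([residual(t) for t in grid])
    roots, all_roots = [], []
    for i in range(n - 1):
        if values[i] == 0.0:
            values[i] = -values[i + 1] if values[i + 1] != 0 else 1.0
        if values[i] * values[i + 1] < 0:
            root = brentq(residual, grid[i], grid[i + 1], rtol=1e-14, maxiter=200)
            all_roots.append(root)
            if values[i] > 0 > values[i + 1]:  # descending: physical branch
                roots.append(root)
    if not roots:
        raise NoPhysicalSolutionError(
            f"no physical mu*omega solution of the force balance for alpha1={alpha1}, "
            f"c6={c6}, r_e={r_e} in the scanned interval [{lo}, {hi}]"
            + (f"; sign changes found at {all_roots}" if all_roots else "")
        )
    if len(roots) > 1:
        raise MultipleRootsError(
            f"force balance has multiple physical roots {roots}; refusing to pick one"
        )
    return roots[0]


def _dispersion_force_sum(coeffs, t, r, damped):
    """Sum over n of -d/dR [f_n C_2n / R^2n] (a positive, attractive force
    magnitude)."""
    z = t * r * r / 2.0
    total = 0.0
    for n, c2n in zip(_DISPERSION_ORDERS, coeffs):
        if damped:
            total += (c2n / r ** (2 * n + 1)) * (
                2 * n * float(damping_factor(n, t, r))
                - 2.0 * z * float(_damping_derivative_factor(n, z))
            )
        else:
            total += 2 * n * c2n / r ** (2 * n + 1)
    return total


def exchange_amplitude(mu_omega: float, q: float, c6: float, c8: float,
                       c10: float, r_e: float, damped: bool = False) -> float:
    """Dimensionless exchange amplitude A of E_ex = A k_e q^2 S(R)/R, fixed
    by the full force balance dV/dR = 0 at R_e.

    Only the combination A k_e q^2 enters the potential, so A transforms
    contravariantly under any re-split of {q, mu, omega} that preserves
    alpha1 and mu*omega.
    """
    _require_positive(mu_omega=mu_omega, q=q, c6=c6, c8=c8, c10=c10, r_e=r_e)
    z = mu_omega * r_e * r_e / 2.0
    attraction = _dispersion_force_sum((c6, c8, c10), mu_omega, r_e, damped)
    wall_slope = math.exp(-z) * (mu_omega + 1.0 / r_e**2)
    return attraction / (COULOMB_KE * q**2 * wall_slope)


def qdo_parameters(atom: AtomProperties, damped: bool = False,
                   r_e_override: Optional[float] = None) -> QDOParameterization:
    """Full parameterization chain {alpha1, C6} -> {q, mu, omega, C8, C10,
    R_e, A}.

    R_e comes from the alpha1^(1/7) scaling law unless overridden (group II
    dimers use reference distances).  omega inverts the C6 closed form,
    mu*omega solves the dipole force balance at R_e, q restores alpha1, and
    the exchange amplitude A closes the force balance of the full potential.
    """
    if r_e_override is not None:
        _require_positive(r_e_override=r_e_override)
        r_e = float(r_e_override)
    else:
        r_e = equilibrium_distance(atom.alpha1)
    omega = drude_frequency(atom.alpha1, atom.c6)
    mu_omega = solve_mu_omega(atom.alpha1, atom.c6, r_e, damped=damped)
    mu = mu_omega / omega
    q = math.sqrt(atom.alpha1 * mu) * omega
    c8, c10 = higher_dispersion_coefficients(atom.c6, mu_omega)
    a_exch = exchange_amplitude(mu_omega, q, atom.c6, c8, c10, r_e, damped=damped)
    return QDOParameterization(
        label=atom.label, alpha1=atom.alpha1, c6=atom.c6, q=q, mu=mu,
        omega=omega, mu_omega=mu_omega, c8=c8, c10=c10, r_e=r_e,
        a_exch=a_exch, damped=damped,
    )


def _check_r(params: QDOParameterization, r: np.ndarray) -> None:
    if np.any(r <= 0):
        raise ValueError("separation r must be positive")
    if not params.damped and np.any(r < 0.5 * params.r_e):
        logger.warning(
            "undamped potential evaluated below 0.5*R_e (R_e=%.4f bohr); "
            "the dispersion series diverges at short range", params.r_e,
        )


def potential(params: QDOParameterization, r) -> float:
    """Total pair potential V(R) in hartree, R in bohr.

    V(R) = A k_e q^2 S(R)/R - sum_n f_n(R) C_2n/R^(2n), with f_n = 1 for the
    undamped variant.  The undamped form is validated for R >= 0.7 R_e.
    """
    r = np.asarray(r, dtype=float)
    _check_r(params, r)
    t = params.mu_omega
    wall = params.a_exch * COULOMB_KE * params.q**2 * np.exp(-t * r**2 / 2.0) / r
    disp = np.zeros_like(r)
    for n, c2n in zip(_DISPERSION_ORDERS, params.dispersion_coefficients()):
        f = damping_factor(n, t, r) if params.damped else 1.0
        disp = disp + f * c2n / r ** (2 * n)
    out = wall - disp
    return float(out) if out.ndim == 0 else out


def potential_derivative(params: QDOParameterization, r) -> float:
    """Analytic dV/dR in hartree/bohr."""
    r = np.asarray(r, dtype=float)
    _check_r(params, r)
    t = params.mu_omega
    z = t * r**2 / 2.0
    wall = -params.a_exch * COULOMB_KE * params.q**2 * np.exp(-z) * (t + 1.0 / r**2)
    disp = np.zeros_like(r)
    for n, c2n in zip(_DISPERSION_ORDERS, params.dispersion_coefficients()):
        if params.damped:
            disp = disp + (c2n / r ** (2 * n + 1)) * (
                2 * n * damping_factor(n, t, r)
                - 2.0 * z * _damping_derivative_factor(n, z)
            )
        else:
            disp = disp + 2 * n * c2n / r ** (2 * n + 1)
    out = wall + disp
    return float(out) if out.ndim == 0 else out


def exchange_energy(params: QDOParameterization, r) -> float:
    """Exchange-repulsion part A k_e q^2 S(R)/R of the potential (hartree)."""
    r = np.asarray(r, dtype=float)
    _check_r(params, r)
    out = (params.a_exch * COULOMB_KE * params.q**2
           * np.exp(-params.mu_omega * r**2 / 2.0) / r)
    return float(out) if out.ndim == 0 else out


def dispersion_energy(params: QDOParameterization, r) -> float:
    """Dispersion part -sum_n f_n C_2n/R^(2n) of the potential (hartree)."""
    return potential(params, r) - exchange_energy(params, r)


def well_depth_closed_form(params: QDOParameterization) -> float:
    """Well depth D_e = -V(R_e) in closed form, hartree.

    Eliminating the exchange amplitude with the force-balance condition
    turns -V(R_e) into a pure dispersion sum,

        D_e = sum_n C_2n/R_e^2n * [f_n (gamma^2+1-2n) + 2 z e^-z z^n/n!]
              / (gamma^2 + 1),

    with gamma^2 = mu omega R_e^2 and z = gamma^2/2 (f_n = 1 and the second
    bracket term absent when undamped).
    """
    t, r_e = params.mu_omega, params.r_e
    g2 = t * r_e * r_e
    z = g2 / 2.0
    total = 0.0
    for n, c2n in zip(_DISPERSION_ORDERS, params.dispersion_coefficients()):
        if params.damped:
            f = float(damping_factor(n, t, r_e))
            extra = 2.0 * z * float(_damping_derivative_factor(n, z))
        else:
            f, extra = 1.0, 0.0
        total += (c2n / r_e ** (2 * n)) * (f * (g2 + 1 - 2 * n) + extra)
    return total / (g2 + 1.0)


def well_depth_scaling_law(atom: AtomProperties) -> float:
    """Two-term well-depth scaling law for vdW dimers, hartree.

    Truncation of the closed-form well depth keeping the dipole-model depth
    plus the leading C8 correction:

        D_e = (C6/R_e^6) (gamma^2 + 5/gamma^2) / (gamma^2 + 1),

    with R_e from the alpha1^(1/7) law and gamma^2 = mu omega R_e^2 from the
    undamped dipole force balance.  Needs only {alpha1, C6}; used for the
    conformal rescaling of noble-gas dimers.
    """
    r_e = equilibrium_distance(atom.alpha1)
    mu_omega = solve_mu_omega(atom.alpha1, atom.c6, r_e, damped=False)
    g2 = mu_omega * r_e * r_e
    return (atom.c6 / r_e**6) * (g2 + 5.0 / g2) / (g2 + 1.0)
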