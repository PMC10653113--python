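"""Combination rules for heteronuclear pairs, plus the QDO damping function.

A heteronuclear dimer AB is represented by two *identical* effective
oscillators parameterized from mixed free-atom properties
{alpha1^AB, C6^AB}, so the homonuclear exchange formalism carries over
unchanged.  C6 mixes by the London two-parameter rule; alpha1 mixes so
that the alpha^(1/7) radius law applied to alpha1^AB reproduces the
geometric-mean combination of the homonuclear vdW radii.
"""

from __future__ import annotations

import math

from .constants import VDW_RADIUS_PHI
from .core import (
    AtomProperties,
    damping_argument,
    damping_factor,
    _require_positive,
)

__all__ = [
    "mix_c6",
    "mix_alpha",
    "mix_vdw_radius",
    "pair_properties",
    "lorentz_berthelot",
    "damping_argument",
    "damping_factor",
]


def mix_c6(atom_a: AtomProperties, atom_b: AtomProperties) -> float:
    """London-formula combination rule for the C6 coefficient:

        C6^AB = 2 C6^A C6^B / [(alpha_B/alpha_A) C6^A + (alpha_A/alpha_B) C6^B]

    Symmetric, and exact (idempotent) for identical atoms.
    """
    a, b = atom_a, atom_b
    _require_positive(alpha1_a=a.alpha1, c6_a=a.c6, alpha1_b=b.alpha1, c6_b=b.c6)
    return (2.0 * a.c6 * b.c6
            / ((b.alpha1 / a.alpha1) * a.c6 + (a.alpha1 / b.alpha1) * b.c6))


def mix_vdw_radius(alpha1_a: float, alpha1_b: float) -> float:
    """Mixed vdW radius, the heteronuclear form of the alpha^(1/7) law:
    R_vdW^AB = Phi (alpha_A alpha_B)^(1/14), the geometric mean of the two
    homonuclear radii."""
    _require_positive(alpha1_a=alpha1_a, alpha1_b=alpha1_b)
    return VDW_RADIUS_PHI * (alpha1_a * alpha1_b) ** (1.0 / 14.0)


def mix_alpha(atom_a: AtomProperties, atom_b: AtomProperties) -> float:
    """Effective polarizability alpha1^AB = sqrt(alpha_A alpha_B).

    Defined so that ``equilibrium_distance(alpha1^AB)`` equals twice the
    mixed vdW radius of :func:`mix_vdw_radius`; symmetric and idempotent.
    """
    _require_positive(alpha1_a=atom_a.alpha1, alpha1_b=atom_b.alpha1)
    return math.sqrt(atom_a.alpha1 * atom_b.alpha1)


def pair_properties(atom_a: AtomProperties, atom_b: AtomProperties) -> AtomProperties:
    """Effective single-atom properties representing the pair AB, ready to
    feed into the usual homonuclear parameterization chain."""
    return AtomProperties(
        label=f"{atom_a.label}-{atom_b.label}",
        alpha1=mix_alpha(atom_a, atom_b),
        c6=mix_c6(atom_a, atom_b),
        source=f"mixed from {atom_a.label} and {atom_b.label}",
    )


def lorentz_berthelot(re_a: float, re_b: float, de_a: float, de_b: float):
    """Lorentz-Berthelot rules: arithmetic mean of R_e, geometric mean of
    D_e.  Provided for benchmarking only; the vdW-QDO pipeline mixes
    {alpha1, C6} instead."""
    _require_positive(re_a=re_a, re_b=re_b, de_a=de_a, de_b=de_b)
    return 0.5 * (re_a + re_b), math.sqrt(de_a * de_b)


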