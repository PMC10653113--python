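"""Quantitative curve comparison and the 12-6 Lennard-Jones reference.

The normalized area-difference metric compares a tested potential against a
reference over the well region [0.8 R_e, 2.0 R_e]:

    Delta_S = 100% * int |V_test - V_ref| dR / int |V_ref| dR

A single unitless percentage: 0 for coinciding curves, 100% when the test
curve is twice the reference everywhere.  Long-range quality is judged
separately through dispersion coefficients, so the window deliberately
stops at 2 R_e.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

__all__ = ["delta_s", "lj_potential", "as_curve_callable"]

Curve = Union[Callable[[float], float], np.ndarray]

_WINDOW = (0.8, 2.0)


def as_curve_callable(curve: Curve, window: tuple[float, float]) -> Callable:
    """Return a callable for either a callable potential or a tabulated
    two-column (R, V) array (cubic interpolation, inside the window only)."""
    if callable(curve):
        return curve
    table = np.asarray(curve, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 4:
        raise ValueError("tabulated curve must be an (n >= 4, 2) array of (R, V)")
    r, v = table[:, 0], table[:, 1]
    if np.any(np.diff(r) <= 0):
        raise ValueError("tabulated R values must be strictly increasing")
    lo, hi = window
    if r[0] > lo or r[-1] < hi:
        raise ValueError(
            f"tabulated curve covers [{r[0]:.4g}, {r[-1]:.4g}] but the "
            f"comparison window is [{lo:.4g}, {hi:.4g}]"
        )
    spline = CubicSpline(r, v)

    def interpolated(x):
        x = np.asarray(x, dtype=float)
        if np.any(x < lo - 1e-12) or np.any(x > hi + 1e-12):
            raise ValueError("tabulated curve evaluated outside the comparison window")
        return spline(x)

    return interpolated


def delta_s(test: Curve, reference: Curve, r_e: float,
            window: tuple[float, float] = _WINDOW, epsrel: float = 1e-8) -> float:
    """Normalized area difference Delta_S between two potentials, percent.

    ``test`` and ``reference`` are callables V(R) or tabulated (R, V)
    arrays; ``r_e`` is the reference equilibrium distance setting the
    integration window ``window`` (multiples of r_e).  Adaptive quadrature
    to relative ``epsrel``.
    """
    if not (np.isfinite(r_e) and r_e > 0):
        raise ValueError(f"r_e must be positive and finite, got {r_e!r}")
    lo, hi = window[0] * r_e, window[1] * r_e
    f_test = as_curve_callable(test, (lo, hi))
    f_ref = as_curve_callable(reference, (lo, hi))

    def diff(r):
        return abs(float(f_test(r)) - float(f_ref(r)))

    def ref_mag(r):
        return abs(float(f_ref(r)))

    try:
        den, _ = quad(ref_mag, lo, hi, epsrel=epsrel, epsabs=0.0, limit=400)
        # the difference integral may be rounding noise (near-identical
        # curves); give it an absolute floor far below the reference area so
        # the quadrature is not asked to resolve that noise
        num, _ = quad(diff, lo, hi, epsrel=epsrel, epsabs=1e-10 * abs(den), limit=400)
    except Exception as exc:  # re-raise with context
        raise ValueError(f"curve not evaluable over [{lo:.4g}, {hi:.4g}] bohr") from exc
    if den == 0.0:
        raise ValueError("reference potential vanishes identically on the window")
    return 100.0 * num / den


def lj_potential(r_e: float, d_e: float, r):
    """Standard 12-6 Lennard-Jones potential with its minimum -d_e at r_e:

        V(r) = d_e [ (r_e/r)^12 - 2 (r_e/r)^6 ]

    Long range: V -> -2 d_e r_e^6 / r^6, i.e. an effective C6 = 2 d_e r_e^6.
    """
    if not (r_e > 0 and d_e > 0):
        raise ValueError("r_e and d_e must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("separation r must be positive")
    x6 = (r_e / r) ** 6
    out = d_e * (x6**2 - 2.0 * x6)
    return float(out) if out.ndim == 0 else out
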