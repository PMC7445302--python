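"""Kirkwood pair-sum diagrams: an independent numerical route to ρ.

The ensemble-averaged reciprocal distance between two contour points of an
ideal rosette depends only on which arms the points sit on.  After the
Gaussian averages are done analytically, <R_H⁻¹> reduces to five purely
geometric double integrals over contour coordinates (arm length L = 1):

    I1 = ∫₀¹ds₂ ∫₀^{s₂}ds₁ (s₂ − s₁)^{-1/2}             two points, same linear arm
    I2 = ∫₀¹∫₀¹ (s₂ + s₁)^{-1/2}                          two different linear arms
    I3 = ∫₀¹ds₂ ∫₀^{s₂}ds₁ (u − u²)^{-1/2}, u = s₂ − s₁   same ring arm
    I4 = ∫₀¹∫₀¹ (s₂ + s₁ − s₂² − s₁²)^{-1/2}              two different ring arms
    I5 = ∫₀¹∫₀¹ (s₂ + s₁ − s₁²)^{-1/2}                    linear arm vs ring arm

All inverse-square-root singularities are integrable.  I1, I2, I3, I5 have
elementary antiderivatives; I4 reduces to a smooth 1D integral after the inner
variable is integrated in closed form.  Assembling <R_H⁻¹> requires counting
*ordered* point pairs: diagrams 1 and 3 are written on the ordered region
s₁ < s₂ and diagram 5 fixes which arm type carries s₁, so the unrestricted
double sum over arms uses the multiplicities

    2 f_c·I1,  f_c(f_c−1)·I2,  2 f_r·I3,  f_r(f_r−1)·I4,  2 f_c f_r·I5.

This module is deliberately independent of :mod:`rosette.theory`'s ρ closed
form (it shares only the <R_g²> expression), so the two routes cross-check
each other.  The Gaussian mean reciprocal distance √(2/π)/σ used in the
assembly is specific to d = 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.integrate import quad

from .theory import rg2_rosette

__all__ = [
    "DiagramTable",
    "QuadratureError",
    "diagram_integral",
    "assemble_rh_inv",
    "rho_from_oracle",
]

DEFAULT_QUAD_TOL = 1e-8


class QuadratureError(RuntimeError):
    """Raised when adaptive quadrature cannot reach the requested tolerance."""


def _quad(f, a, b, tol):
    value, abserr = quad(f, a, b, epsabs=tol, epsrel=0.0, limit=200)
    if abserr > 10 * tol:
        raise QuadratureError(
            f"quadrature achieved abserr={abserr:.3e}, requested {tol:.3e}"
        )
    return value


def _integrand_1(u: float) -> float:
    # ordered region collapsed to u = s2 - s1 with weight (1 - u)
    return (1.0 - u) * u**-0.5


def _integrand_2(s2: float) -> float:
    # inner integral over s1 in closed form
    return 2.0 * (math.sqrt(s2 + 1.0) - math.sqrt(s2))


def _integrand_3(u: float) -> float:
    # (1 - u) * (u - u^2)^{-1/2} = (1 - u)^{1/2} u^{-1/2}
    return math.sqrt(1.0 - u) * u**-0.5


def _integrand_4(x: float) -> float:
    # inner: ∫₀¹ (c + y - y²)^{-1/2} dy = 2 arcsin(1/√(1+4c)), c = x - x²
    c = x - x * x
    return 2.0 * math.asin((1.0 + 4.0 * c) ** -0.5)


def _integrand_5(s1: float) -> float:
    # inner integral over s2 in closed form; c = s1 - s1² >= 0
    c = s1 - s1 * s1
    return 2.0 * (math.sqrt(1.0 + c) - math.sqrt(c))


_INTEGRANDS = {1: _integrand_1, 2: _integrand_2, 3: _integrand_3,
               4: _integrand_4, 5: _integrand_5}


def diagram_integral(label: int, quad_tol: float = DEFAULT_QUAD_TOL) -> float:
    """Evaluate one of the five geometric double integrals at L = 1.

    The d-dependent prefactor common to all diagrams is factored out here and
    reattached in :func:`assemble_rh_inv`.  Each double integral is reduced to
    a 1D adaptive quadrature (inner variable integrated in closed form, or the
    ordered region collapsed by the substitution u = s₂ − s₁ with weight
    1 − u); the endpoint singularities are integrable and handled by the
    adaptive rule.
    """
    if label not in _INTEGRANDS:
        raise ValueError(f"diagram label must be in 1..5, got {label}")
    if quad_tol <= 0:
        raise ValueError("quad_tol must be positive")
    return _quad(_INTEGRANDS[label], 0.0, 1.0, quad_tol)


@dataclass(frozen=True)
class DiagramTable:
    """The five dimensionless diagram integrals at L = 1."""

    i1: float
    i2: float
    i3: float
    i4: float
    i5: float
    quad_tol: float = DEFAULT_QUAD_TOL

    @classmethod
    def compute(cls, quad_tol: float = DEFAULT_QUAD_TOL) -> "DiagramTable":
        return cls(
            *(diagram_integral(k, quad_tol) for k in range(1, 6)),
            quad_tol=quad_tol,
        )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.i1, self.i2, self.i3, self.i4, self.i5)


def assemble_rh_inv(
    f_c: int,
    f_r: int,
    L: float = 1.0,
    table: DiagramTable | None = None,
) -> float:
    """Assemble <R_H⁻¹> of a rosette from the diagram integrals (d = 3).

    Ordered-pair multiplicities are applied to the diagram values, the sum is
    normalized by (f L)², and the d = 3 Gaussian factor √(2/π) restores the
    physical scale; the result carries units 1/√L.
    """
    if f_c < 0 or f_r < 0 or f_c + f_r < 1:
        raise ValueError("need f_c, f_r >= 0 with f_c + f_r >= 1")
    if L <= 0:
        raise ValueError("contour length L must be positive")
    if table is None:
        table = DiagramTable.compute()
    f = f_c + f_r
    total = (
        2.0 * f_c * table.i1
        + f_c * (f_c - 1) * table.i2
        + 2.0 * f_r * table.i3
        + f_r * (f_r - 1) * table.i4
        + 2.0 * f_c * f_r * table.i5
    )
    return math.sqrt(2.0 / math.pi) * total / (f**2 * math.sqrt(L))


def rho_from_oracle(
    f_c: int,
    f_r: int,
    dim: int = 3,
    table: DiagramTable | None = None,
    quad_tol: float = DEFAULT_QUAD_TOL,
) -> float:
    """Size ratio ρ obtained from the quadrature-assembled Kirkwood sum.

    Serves as the independent numerical cross-check of the closed form in
    :func:`rosette.theory.rho_rosette`.  Only d = 3 is supported here (the
    √(2/π) mean-reciprocal-distance factor is three-dimensional); the closed
    form covers general d.
    """
    if dim != 3:
        raise NotImplementedError("the diagram assembly is specific to d = 3")
    if table is None:
        table = DiagramTable.compute(quad_tol)
    return math.sqrt(rg2_rosette(f_c, f_r, 1.0, 3)) * assemble_rh_inv(
        f_c, f_r, 1.0, table
    )
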