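"""Closed-form size ratios of ideal rosette polymers.

For a Gaussian (ideal) rosette with ``f_c`` linear arms and ``f_r`` ring arms
of common contour length L, both the mean square gyration radius

    <R_g²> = (L d / 12 f²) · [f_r(2f_r − 1) + 2f_c(3f_c − 2) + 8 f_r f_c]

and the universal size ratio ρ = √<R_g²> / R_H are known in closed form; ρ is
dimensionless and depends only on the architecture (f_c, f_r) and the spatial
dimension d.  Classic special cases at d = 3:

    chain       ρ = 8/(3√π)          ≈ 1.5045
    ring        ρ = √(2π)/2          ≈ 1.2533
    double ring ρ = √(3π)(3 − √2)/4  ≈ 1.2171
    tadpole     ρ = √22/(96√π)·[3π + 28 + 30·arcsin(1/√5)] ≈ 1.4151

The hydrodynamic radius reported here is defined through the ratio,
R_H = √<R_g²> / ρ, which is consistent with the Kirkwood diagram assembly
implemented (and cross-checked numerically) in :mod:`rosette.diagrams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "TheoryResult",
    "rho_rosette",
    "rg2_rosette",
    "rho_star",
    "rho_special",
    "hydrodynamic_radius",
    "theory_result",
    "SPECIAL_CASES",
]

_SQRT2 = math.sqrt(2.0)
_ARCSIN_1_SQRT5 = math.asin(1.0 / math.sqrt(5.0))


def _validate(f_c: int, f_r: int, dim: int) -> None:
    if f_c < 0 or f_r < 0:
        raise ValueError("arm counts must be non-negative")
    if f_c + f_r < 1:
        raise ValueError("total functionality f_c + f_r must be >= 1")
    if dim < 2:
        raise ValueError("spatial dimension must be >= 2")


def rho_rosette(f_c: int, f_r: int, dim: int = 3) -> float:
    """Universal size ratio ρ = √<R_g²>/R_H of an ideal rosette polymer.

    General closed form for ``f_c`` linear and ``f_r`` ring arms in ``dim``
    spatial dimensions.  Reduces to the chain, star, ring, double-ring and
    tadpole expressions at the corresponding arm counts.
    """
    _validate(f_c, f_r, dim)
    f = f_c + f_r
    pref = (
        math.sqrt(6.0 * dim)
        * math.gamma((dim - 1) / 2.0)
        / (72.0 * f**3 * math.gamma(dim / 2.0))
    )
    root = math.sqrt(6 * f_c**2 + 8 * f_c * f_r + 2 * f_r**2 - 4 * f_c - f_r)
    bracket = (
        -6.0 * f_r * math.pi * (_SQRT2 * (f_r - 1) - 2 * f_r + 1)
        + 16.0 * (_SQRT2 - 1.0) * f_c * (_SQRT2 + f_c)
        + 3.0 * f_c * f_r * (10.0 * _ARCSIN_1_SQRT5 - math.pi + 4.0)
    )
    return pref * root * bracket


def rg2_rosette(f_c: int, f_r: int, L: float = 1.0, dim: int = 3) -> float:
    """Mean square gyration radius <R_g²> of an ideal rosette of arm length L.

    ``L`` is the contour length per arm in units where one unit of contour
    contributes ``dim`` per-component-1 variance to the end-to-end distance
    (i.e. step_var = 1 in the discrete mapping).
    """
    _validate(f_c, f_r, dim)
    if L <= 0:
        raise ValueError("contour length L must be positive")
    f = f_c + f_r
    bracket = f_r * (2 * f_r - 1) + 2 * f_c * (3 * f_c - 2) + 8 * f_r * f_c
    return L * dim * bracket / (12.0 * f**2)


def rho_star(f_c: int) -> float:
    """Size ratio of an ideal star of ``f_c`` linear arms (d = 3).

    Dedicated closed form; agrees with ``rho_rosette(f_c, 0, 3)`` to machine
    precision and reduces to the linear-chain value at ``f_c = 1``.
    """
    if f_c < 1:
        raise ValueError("a star needs at least one arm")
    return (
        8.0
        * math.sqrt(f_c * (3 * f_c - 2))
        / (3.0 * f_c**2 * math.sqrt(math.pi))
        * (_SQRT2 - 1.0)
        * (_SQRT2 + f_c)
    )


#: name -> ((f_c, f_r), closed-form ρ at d = 3)
SPECIAL_CASES: dict[str, tuple[tuple[int, int], float]] = {
    "chain": ((1, 0), 8.0 / (3.0 * math.sqrt(math.pi))),
    "ring": ((0, 1), math.sqrt(2.0 * math.pi) / 2.0),
    "double_ring": ((0, 2), math.sqrt(3.0 * math.pi) / 4.0 * (3.0 - _SQRT2)),
    "tadpole": (
        (1, 1),
        math.sqrt(22.0)
        / (96.0 * math.sqrt(math.pi))
        * (3.0 * math.pi + 28.0 + 30.0 * _ARCSIN_1_SQRT5),
    ),
}


def rho_special(name: str) -> float:
    """Dedicated closed-form ρ for a named architecture at d = 3.

    ``name`` is one of ``chain``, ``ring``, ``tadpole``, ``double_ring``.
    """
    try:
        return SPECIAL_CASES[name][1]
    except KeyError:
        raise ValueError(
            f"unknown architecture {name!r}; expected one of {sorted(SPECIAL_CASES)}"
        ) from None


def hydrodynamic_radius(f_c: int, f_r: int, L: float = 1.0, dim: int = 3) -> float:
    """Kirkwood hydrodynamic radius R_H = √<R_g²>/ρ of an ideal rosette."""
    return math.sqrt(rg2_rosette(f_c, f_r, L, dim)) / rho_rosette(f_c, f_r, dim)


@dataclass(frozen=True)
class TheoryResult:
    """Closed-form observables for one architecture."""

    f_c: int
    f_r: int
    dim: int
    rho: float
    rg2_per_L: float

    @property
    def rh_per_sqrt_L(self) -> float:
        return math.sqrt(self.rg2_per_L) / self.rho


def theory_result(f_c: int, f_r: int, dim: int = 3) -> TheoryResult:
    """Evaluate the closed forms for one architecture (L = 1 units)."""
    return TheoryResult(
        f_c=f_c,
        f_r=f_r,
        dim=dim,
        rho=rho_rosette(f_c, f_r, dim),
        rg2_per_L=rg2_rosette(f_c, f_r, 1.0, dim),
    )


#: (f_c, f_r) rows of the benchmark architecture set, in presentation order:
#: chains/stars, rings/ring-stars, then mixed rosettes.
BENCHMARK_TOPOLOGIES: tuple[tuple[int, int], ...] = (
    (1, 0),
    (2, 0),
    (3, 0),
    (4, 0),
    (0, 1),
    (0, 2),
    (0, 3),
    (0, 4),
    (1, 1),
    (2, 2),
)
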