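"""Finite-size extrapolation of the size ratio: ρ(N) = ρ∞(1 + a N^(−Δ)).

Simulated ρ at finite beads-per-arm N carries a correction-to-scaling term;
for ideal (θ-solvent) statistics the leading exponent is Δ = 1/2.  The model
is linear in x = N^(−Δ):

    ρ(N) = ρ∞ + (ρ∞ a) · x,

so a weighted linear least-squares fit of ρ against x gives the asymptotic
ratio ρ∞ as the intercept and the correction amplitude a = slope/intercept.
Δ is a fixed input, never fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FiniteSizeFit", "fit_finite_size"]


@dataclass(frozen=True)
class FiniteSizeFit:
    """Result of the correction-to-scaling regression."""

    rho_inf: float
    rho_inf_err: float
    amplitude_a: float
    amplitude_a_err: float
    delta: float
    points: tuple[tuple[float, float, float], ...]  # (N, rho, rho_err)
    chi2: float

    def predict(self, n: float | np.ndarray) -> float | np.ndarray:
        return self.rho_inf * (1.0 + self.amplitude_a * np.asarray(n, float) ** -self.delta)


def fit_finite_size(
    points: Sequence[tuple[float, float, float]],
    delta: float = 0.5,
    weighted: bool = True,
) -> FiniteSizeFit:
    """Weighted least-squares fit of ρ(N) = ρ∞(1 + a N^(−Δ)).

    Parameters
    ----------
    points
        Sequence of (N, rho, rho_err) with distinct positive N and positive
        errors.  At least three points are required.
    delta
        Fixed correction-to-scaling exponent (1/2 for ideal statistics).
    weighted
        Weight points by 1/rho_err²; parameter covariance is taken from the
        weighted normal equations (error bars treated as known).  With
        ``weighted=False`` all points get unit weight and the covariance is
        scaled by the residual variance.
    """
    pts = [(float(n), float(r), float(e)) for n, r, e in points]
    if len(pts) < 3:
        raise ValueError("need at least three (N, rho, rho_err) points")
    n_arr = np.array([p[0] for p in pts])
    rho = np.array([p[1] for p in pts])
    err = np.array([p[2] for p in pts])
    if len(np.unique(n_arr)) < 2:
        raise ValueError("design is degenerate: all N identical")
    if np.any(n_arr <= 0):
        raise ValueError("N must be positive")
    if weighted and np.any(err <= 0):
        raise ValueError("weighted fit requires positive rho_err")
    if delta <= 0:
        raise ValueError("delta must be positive")

    x = n_arr**-delta
    w = 1.0 / err**2 if weighted else np.ones_like(rho)
    design = np.column_stack([np.ones_like(x), x])
    wd = design * w[:, None]
    normal = design.T @ wd
    cov = np.linalg.inv(normal)
    beta = cov @ (wd.T @ rho)
    intercept, slope = beta
    resid = rho - design @ beta
    chi2 = float((w * resid**2).sum())
    if not weighted:
        dof = max(1, len(pts) - 2)
        cov = cov * chi2 / dof

    a = slope / intercept
    var_i, var_s = cov[0, 0], cov[1, 1]
    cov_is = cov[0, 1]
    # first-order propagation for a = slope/intercept
    var_a = (
        var_s / intercept**2
        + slope**2 * var_i / intercept**4
        - 2.0 * slope * cov_is / intercept**3
    )
    return FiniteSizeFit(
        rho_inf=float(intercept),
        rho_inf_err=float(math.sqrt(max(var_i, 0.0))),
        amplitude_a=float(a),
        amplitude_a_err=float(math.sqrt(max(var_a, 0.0))),
        delta=float(delta),
        points=tuple(pts),
        chi2=chi2,
    )
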