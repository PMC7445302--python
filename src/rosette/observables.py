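"""Conformational observables: R_g², Kirkwood R_H⁻¹ and the size ratio ρ.

Single-conformation observables

    R_g²   = (1/2M²) Σ_{n,m} (r_n − r_m)²   (= mean squared deviation from
             the centroid)
    R_H⁻¹  = (1/M²) Σ_{n≠m} 1/|r_n − r_m|   (Kirkwood pair sum; the divergent
             diagonal is excluded, the M² normalization kept — the O(1/M)
             difference is absorbed by finite-size extrapolation)

Ensemble estimator

    ρ = √<R_g²> · <R_H⁻¹>

combining ensemble means before taking root and product (not per-conformation
ratios).  The standard error of ρ is obtained by delete-one jackknife over
conformations, which accounts for the correlation between R_g² and R_H⁻¹
within a conformation.

Exact finite-M references for ideal rosettes are provided as oracles: for
beads with known pairwise Gaussian statistics, <1/r> = √(2/π)/σ in d = 3,
so both sums can be evaluated without any sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist

from .sampler import Conformation
from .topology import RosetteTopology

__all__ = [
    "EnsembleEstimate",
    "ChainReference",
    "radius_of_gyration_sq",
    "radius_of_gyration_sq_pairs",
    "inverse_hydrodynamic_radius",
    "discrete_chain_reference",
    "discrete_reference",
    "ensemble_estimate",
]

_COINCIDENT_TOL = 1e-12

PairMode = Union[str, int]  # "exact" or K (number of subsampled pairs)


def _coords(conf: Conformation | np.ndarray) -> np.ndarray:
    if isinstance(conf, Conformation):
        return conf.coords
    return np.asarray(conf, dtype=float)


def radius_of_gyration_sq(conf: Conformation | np.ndarray) -> float:
    """Squared gyration radius of one conformation (centroid form)."""
    x = _coords(conf)
    if x.shape[0] < 2:
        raise ValueError("need at least two beads")
    return float(((x - x.mean(axis=0)) ** 2).sum(axis=1).mean())


def radius_of_gyration_sq_pairs(conf: Conformation | np.ndarray) -> float:
    """Squared gyration radius via the explicit pair sum (1/2M²)ΣΣ(r_n−r_m)².

    Mathematically identical to :func:`radius_of_gyration_sq`; kept as an
    independent code path for verification.
    """
    x = _coords(conf)
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least two beads")
    return float((pdist(x) ** 2).sum() / m**2)  # pdist covers each pair once


def inverse_hydrodynamic_radius(
    conf: Conformation | np.ndarray,
    pair_mode: PairMode = "exact",
    rng: np.random.Generator | None = None,
) -> float:
    """Kirkwood reciprocal-distance sum (1/M²) Σ_{n≠m} 1/|r_n − r_m|.

    ``pair_mode="exact"`` evaluates all M(M−1)/2 distances.  An integer K
    requests an unbiased Monte-Carlo estimate from K uniformly drawn distinct
    ordered pairs, scaled by (M² − M)/M²; if K covers all ordered pairs the
    exact sum is returned.  Subsampling requires ``rng``.
    """
    x = _coords(conf)
    m = x.shape[0]
    if m < 2:
        raise ValueError("need at least two beads")
    n_ordered = m * (m - 1)
    if pair_mode == "exact" or (
        isinstance(pair_mode, (int, np.integer)) and pair_mode >= n_ordered
    ):
        d = pdist(x)
        if d.min() < _COINCIDENT_TOL:
            i, j = _pair_indices(m, int(np.argmin(d)))
            raise ValueError(
                f"beads {i} and {j} coincide (distance {d.min():.3e}); "
                "exact Kirkwood sum undefined"
            )
        return float(2.0 * (1.0 / d).sum() / m**2)
    if not isinstance(pair_mode, (int, np.integer)) or pair_mode < 1:
        raise ValueError(f"pair_mode must be 'exact' or a positive int, got {pair_mode!r}")
    if rng is None:
        raise ValueError("subsampled pair_mode requires an rng")
    k = int(pair_mode)
    i = rng.integers(0, m, size=k)
    # draw j uniformly among the m-1 indices != i
    j = rng.integers(0, m - 1, size=k)
    j[j >= i] += 1
    d = np.linalg.norm(x[i] - x[j], axis=1)
    d = np.where(d < _COINCIDENT_TOL, np.nan, d)
    mean_inv = np.nanmean(1.0 / d)
    return float(mean_inv * n_ordered / m**2)


def _pair_indices(m: int, flat: int) -> tuple[int, int]:
    """Recover (i, j) bead indices from a condensed pdist position."""
    i = 0
    while flat >= m - i - 1:
        flat -= m - i - 1
        i += 1
    return i, i + 1 + flat


class ChainReference(NamedTuple):
    """Exact finite-M observables of an ideal chain (d = 3, step_var = 1)."""

    rg2: float
    rhinv: float
    rho: float


def discrete_chain_reference(M: int) -> ChainReference:
    """Exact R_g², R_H⁻¹ and ρ of a discrete ideal chain of M beads.

    Closed forms for d = 3, unit per-component step variance:
    R_g² = (M² − 1)/(2M) and
    R_H⁻¹ = (2/M²)·√(2/π)·Σ_{j=1}^{M−1}(M − j)/√j.
    ρ(M) increases with M toward the asymptotic chain value 8/(3√π).
    """
    if M < 2:
        raise ValueError("need at least two beads")
    rg2 = (M**2 - 1) / (2.0 * M)
    j = np.arange(1, M, dtype=float)
    rhinv = 2.0 / M**2 * math.sqrt(2.0 / math.pi) * float(((M - j) / np.sqrt(j)).sum())
    return ChainReference(rg2=rg2, rhinv=rhinv, rho=math.sqrt(rg2) * rhinv)


def _pair_variance_matrix(topology: RosetteTopology) -> np.ndarray:
    """Per-component variance of r_a − r_b for every bead pair (step_var = 1).

    Beads on different arms are independent, so the variance is the sum of
    the two single-bead variances; same-arm blocks use the walk covariance
    (|k₁ − k₂| on a linear arm, s(n − s)/n with s = |k₁ − k₂| on a ring).
    """
    n = topology.n_per_arm
    m = topology.total_beads
    self_var = np.zeros(m)
    slices = topology.arm_slices()
    for kind, sl in slices:
        k = np.arange(1, sl.stop - sl.start + 1, dtype=float)
        self_var[sl] = k if kind == "linear" else k * (n - k) / n
    v = self_var[:, None] + self_var[None, :]
    for kind, sl in slices:
        k = np.arange(1, sl.stop - sl.start + 1, dtype=float)
        s = np.abs(k[:, None] - k[None, :])
        v[sl, sl] = s if kind == "linear" else s * (n - s) / n
    np.fill_diagonal(v, 0.0)
    return v


def discrete_reference(topology: RosetteTopology) -> ChainReference:
    """Exact finite-M observables of any ideal rosette topology (d = 3).

    Evaluates both pair sums from the known pairwise Gaussian statistics of
    the architecture — an exact oracle for the sampler at any bead count.
    """
    if topology.dim != 3:
        raise NotImplementedError("<1/r> = sqrt(2/pi)/sigma holds for d = 3 only")
    if topology.step_var <= 0:
        raise ValueError("step_var must be positive for the reference")
    v = _pair_variance_matrix(topology) * topology.step_var
    m = v.shape[0]
    rg2 = 3.0 * v.sum() / (2.0 * m**2)
    off = v[~np.eye(m, dtype=bool)]
    rhinv = math.sqrt(2.0 / math.pi) * float((1.0 / np.sqrt(off)).sum()) / m**2
    return ChainReference(rg2=rg2, rhinv=rhinv, rho=math.sqrt(rg2) * rhinv)


@dataclass(frozen=True)
class EnsembleEstimate:
    """Monte-Carlo means and errors of R_g², R_H⁻¹ and ρ over an ensemble."""

    rg2_mean: float
    rg2_err: float
    rhinv_mean: float
    rhinv_err: float
    rho: float
    rho_err: float
    n_conformations: int
    pair_mode: PairMode = "exact"


def ensemble_estimate(
    confs: Sequence[Conformation],
    pair_mode: PairMode = "exact",
    rng: np.random.Generator | None = None,
) -> EnsembleEstimate:
    """Estimate <R_g²>, <R_H⁻¹> and ρ = √<R_g²>·<R_H⁻¹> from conformations.

    All conformations must share one topology.  Standard errors of the means
    are the usual √(s²/n); the error of ρ comes from a delete-one jackknife
    over conformations.
    """
    if len(confs) < 2:
        raise ValueError("need at least two conformations")
    topo = confs[0].topology
    if any(c.topology != topo for c in confs[1:]):
        raise ValueError("all conformations must share one topology")
    rg2 = np.array([radius_of_gyration_sq(c) for c in confs])
    rhinv = np.array(
        [inverse_hydrodynamic_radius(c, pair_mode, rng) for c in confs]
    )
    n = len(confs)
    rg2_mean = rg2.mean()
    rhinv_mean = rhinv.mean()
    rho = math.sqrt(rg2_mean) * rhinv_mean

    # delete-one jackknife for rho
    rg2_loo = (rg2.sum() - rg2) / (n - 1)
    rhinv_loo = (rhinv.sum() - rhinv) / (n - 1)
    rho_loo = np.sqrt(rg2_loo) * rhinv_loo
    rho_err = math.sqrt((n - 1) / n * ((rho_loo - rho_loo.mean()) ** 2).sum())

    return EnsembleEstimate(
        rg2_mean=float(rg2_mean),
        rg2_err=float(rg2.std(ddof=1) / math.sqrt(n)),
        rhinv_mean=float(rhinv_mean),
        rhinv_err=float(rhinv.std(ddof=1) / math.sqrt(n)),
        rho=float(rho),
        rho_err=float(rho_err),
        n_conformations=n,
        pair_mode=pair_mode,
    )
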