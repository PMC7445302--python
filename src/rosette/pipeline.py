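"""End-to-end pipeline: sample ensembles over N, estimate ρ(N), extrapolate.

This is the simulation counterpart of the closed-form theory: for one
architecture it draws exact conformational ensembles at a ladder of
beads-per-arm values N, measures ρ(N) = √<R_g²>·<R_H⁻¹> with jackknife
errors, and fits the correction-to-scaling law ρ(N) = ρ∞(1 + aN^(−1/2)) to
recover the asymptotic universal ratio.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .extrapolate import FiniteSizeFit, fit_finite_size
from .observables import EnsembleEstimate, PairMode, ensemble_estimate
from .sampler import sample_ensemble
from .topology import RosetteTopology

__all__ = ["rho_series", "extrapolated_rho", "DEFAULT_N_VALUES"]

#: beads-per-arm ladder used for finite-size extrapolation
DEFAULT_N_VALUES: tuple[int, ...] = (100, 200, 400, 800, 1600)


def _subseed(seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2^31 for one (topology, N) ensemble."""
    return int(np.random.SeedSequence((seed, *key)).generate_state(1)[0] % 2**31)


def rho_series(
    f_c: int,
    f_r: int,
    seed: int,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    n_conformations: int = 400,
    pair_mode: PairMode = "exact",
) -> list[tuple[int, EnsembleEstimate]]:
    """Ensemble estimates of ρ at each beads-per-arm value N.

    Each N gets an independent, deterministically derived sub-seed, so the
    points of the series are statistically independent.
    """
    out: list[tuple[int, EnsembleEstimate]] = []
    for n in n_values:
        topo = RosetteTopology(f_c=f_c, f_r=f_r, n_per_arm=n)
        sub = _subseed(seed, f_c, f_r, n)
        confs = list(sample_ensemble(topo, n_conformations, sub))
        rng = np.random.default_rng(np.random.SeedSequence((sub, 1)))
        out.append((n, ensemble_estimate(confs, pair_mode, rng)))
    return out


def extrapolated_rho(
    f_c: int,
    f_r: int,
    seed: int,
    n_values: Sequence[int] = DEFAULT_N_VALUES,
    n_conformations: int = 400,
    pair_mode: PairMode = "exact",
    delta: float = 0.5,
) -> tuple[FiniteSizeFit, list[tuple[int, EnsembleEstimate]]]:
    """Asymptotic ρ∞ of one architecture from the full sampling pipeline."""
    series = rho_series(f_c, f_r, seed, n_values, n_conformations, pair_mode)
    fit = fit_finite_size(
        [(n, est.rho, est.rho_err) for n, est in series], delta=delta
    )
    return fit, series
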