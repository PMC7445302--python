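"""Exact sampling of ideal rosette conformations.

Because the arms of an ideal (no excluded volume) rosette are statistically
independent given the core position, a conformation can be drawn exactly:

* a linear arm is a free Gaussian random walk started at the core (cumulative
  sum of i.i.d. centered Gaussian steps);
* a ring arm is a Brownian bridge — a free walk W conditioned to return to the
  core, constructed as r_k = W_k − (k/n)·W_n, which closes exactly and gives
  bead k the per-component variance step_var·k(n−k)/n.

Every conformation is independent: no equilibration, no integrator bias.
Reproducibility: ensemble member i uses the RNG stream seeded by the pair
(root seed, i), so ensembles are identical regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .topology import RosetteTopology

__all__ = [
    "Conformation",
    "sample_linear_arm",
    "sample_ring_arm",
    "sample_rosette",
    "sample_ensemble",
    "conformation_rng",
]


@dataclass(frozen=True)
class Conformation:
    """One set of bead coordinates for a rosette topology.

    ``coords`` has shape (M, dim) with the core (bead 0) at the origin for
    sampled conformations; MD frames may have drifted freely.
    """

    coords: np.ndarray
    topology: RosetteTopology

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        expected = (self.topology.total_beads, self.topology.dim)
        if coords.shape != expected:
            raise ValueError(
                f"coords shape {coords.shape} does not match topology {expected}"
            )

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def arm_of_bead(self) -> dict[int, tuple[int, int]]:
        return self.topology.arm_of_bead()


def sample_linear_arm(
    n: int,
    rng: np.random.Generator,
    step_var: float = 1.0,
    dim: int = 3,
) -> np.ndarray:
    """Draw one free Gaussian arm of ``n`` beads rooted at the origin.

    Returns an (n, dim) array; bead k (1-based) is the sum of k independent
    centered Gaussian steps of per-component variance ``step_var``, so
    <r_k²> = dim·k·step_var.
    """
    if n < 1:
        raise ValueError("a linear arm needs at least one bead")
    steps = rng.standard_normal((n, dim)) * np.sqrt(step_var)
    return np.cumsum(steps, axis=0)


def sample_ring_arm(
    n: int,
    rng: np.random.Generator,
    step_var: float = 1.0,
    dim: int = 3,
) -> np.ndarray:
    """Draw the n−1 interior beads of a closed Gaussian loop of ``n`` bonds.

    Brownian-bridge construction: from a free walk W of n steps,
    r_k = W_k − (k/n)·W_n for k = 1..n−1.  The endpoints r_0 = r_n = 0 are the
    core and are not stored.  Bead k has per-component variance
    step_var·k(n−k)/n.
    """
    if n < 2:
        raise ValueError("a ring arm needs at least two bonds")
    walk = sample_linear_arm(n, rng, step_var, dim)
    k = np.arange(1, n, dtype=float)[:, None]
    return walk[:-1] - (k / n) * walk[-1]


def sample_rosette(
    topology: RosetteTopology, rng: np.random.Generator
) -> Conformation:
    """Draw one exact conformation of a rosette from its Gaussian measure.

    Arms are mutually independent and rooted at the core (bead 0, at the
    origin).  Deterministic given the generator state.
    """
    coords = np.zeros((topology.total_beads, topology.dim))
    for kind, sl in topology.arm_slices():
        if kind == "linear":
            coords[sl] = sample_linear_arm(
                topology.n_per_arm, rng, topology.step_var, topology.dim
            )
        else:
            coords[sl] = sample_ring_arm(
                topology.n_per_arm, rng, topology.step_var, topology.dim
            )
    return Conformation(coords=coords, topology=topology)


def conformation_rng(seed: int, index: int) -> np.random.Generator:
    """Independent RNG stream for ensemble member ``index`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def sample_ensemble(
    topology: RosetteTopology, n_conformations: int, seed: int
) -> Iterator[Conformation]:
    """Yield ``n_conformations`` independent exact conformations.

    Member i is drawn from the stream keyed by (seed, i), so any subset of the
    ensemble is reproducible independently of the others.
    """
    if n_conformations < 1:
        raise ValueError("need at least one conformation")
    for i in range(n_conformations):
        yield sample_rosette(topology, conformation_rng(seed, i))
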