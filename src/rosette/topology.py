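"""Rosette architectures: arm bookkeeping, bead indexing and bond connectivity.

A rosette polymer is a branched macromolecule in which ``f_c`` linear arms and
``f_r`` ring (loop) arms radiate from a single branch point, the *core*.  All
arms carry the same number of bonds ``n_per_arm``.  Every other module of this
package (exact Gaussian sampling, observables, Langevin dynamics) works on the
bead indexing defined here:

* bead 0 is the core;
* linear arms come first, stored contiguously in declaration order, each
  contributing ``n_per_arm`` beads;
* ring arms follow, each contributing ``n_per_arm - 1`` beads — the bead that
  closes a ring *is* the core, so it is never duplicated (this avoids a
  zero-length pair in Kirkwood sums).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RosetteTopology", "BondList", "total_beads", "build_bond_list"]


@dataclass(frozen=True)
class RosetteTopology:
    """Architecture descriptor of an ideal rosette polymer.

    Parameters
    ----------
    f_c
        Number of linear (open) arms, >= 0.
    f_r
        Number of ring (closed-loop) arms, >= 0.  ``f_c + f_r >= 1``.
    n_per_arm
        Number of bonds per arm contour, >= 2.  In the continuum mapping the
        contour length per arm is ``L = n_per_arm`` when ``step_var = 1``.
    dim
        Spatial dimension, >= 2 (default 3).
    step_var
        Per-component variance of a single bond step (length², default 1), so
        the mean squared bond length is ``dim * step_var``.
    """

    f_c: int
    f_r: int
    n_per_arm: int
    dim: int = 3
    step_var: float = 1.0

    def __post_init__(self) -> None:
        if self.f_c < 0 or self.f_r < 0:
            raise ValueError("arm counts f_c, f_r must be non-negative")
        if self.f_c + self.f_r < 1:
            raise ValueError("total functionality f_c + f_r must be >= 1")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be >= 2")
        if self.dim < 2:
            raise ValueError("spatial dimension must be >= 2")
        if self.step_var < 0:
            raise ValueError("step_var must be non-negative")

    @property
    def functionality(self) -> int:
        """Total number of grafted arms f = f_c + f_r."""
        return self.f_c + self.f_r

    @property
    def total_beads(self) -> int:
        """Number of distinct beads M = 1 + f_c·n + f_r·(n − 1)."""
        n = self.n_per_arm
        return 1 + self.f_c * n + self.f_r * (n - 1)

    def arm_slices(self) -> list[tuple[str, slice]]:
        """Bead-index slice of each arm (excluding the core), linear arms first.

        Returns a list of ``(kind, slice)`` with ``kind`` one of ``"linear"``
        or ``"ring"``, in storage order.
        """
        out: list[tuple[str, slice]] = []
        start = 1
        for _ in range(self.f_c):
            out.append(("linear", slice(start, start + self.n_per_arm)))
            start += self.n_per_arm
        for _ in range(self.f_r):
            out.append(("ring", slice(start, start + self.n_per_arm - 1)))
            start += self.n_per_arm - 1
        return out

    def arm_of_bead(self) -> dict[int, tuple[int, int]]:
        """Map bead index -> (arm index, 1-based position along the arm contour).

        The core (bead 0) is not in the map: it belongs to every arm.
        """
        mapping: dict[int, tuple[int, int]] = {}
        for arm, (_, sl) in enumerate(self.arm_slices()):
            for pos, bead in enumerate(range(sl.start, sl.stop), start=1):
                mapping[bead] = (arm, pos)
        return mapping

    def to_dict(self) -> dict:
        return {
            "fc": self.f_c,
            "fr": self.f_r,
            "n": self.n_per_arm,
            "dim": self.dim,
            "step_var": self.step_var,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RosetteTopology":
        return cls(
            f_c=int(d["fc"]),
            f_r=int(d["fr"]),
            n_per_arm=int(d["n"]),
            dim=int(d.get("dim", 3)),
            step_var=float(d.get("step_var", 1.0)),
        )


@dataclass(frozen=True)
class BondList:
    """Harmonic-bond edge list over bead indices.

    Each linear arm contributes ``n_per_arm`` edges (including the core
    attachment); each ring contributes ``n_per_arm`` edges and closes on the
    core, so the bond count is ``(f_c + f_r) * n_per_arm`` and the core degree
    is ``f_c + 2 f_r``.
    """

    pairs: tuple[tuple[int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.pairs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)

    def degree(self, n_beads: int) -> np.ndarray:
        deg = np.zeros(n_beads, dtype=np.intp)
        arr = self.as_array()
        np.add.at(deg, arr[:, 0], 1)
        np.add.at(deg, arr[:, 1], 1)
        return deg


def total_beads(topology: RosetteTopology) -> int:
    """Number of distinct beads in the rosette (core counted once)."""
    return topology.total_beads


def build_bond_list(topology: RosetteTopology) -> BondList:
    """Bond connectivity realizing the rosette graph.

    Linear arms are paths rooted at the core; ring arms are cycles through the
    core.  The resulting graph is connected with core degree ``f_c + 2 f_r``.
    """
    pairs: list[tuple[int, int]] = []
    for kind, sl in topology.arm_slices():
        beads = list(range(sl.start, sl.stop))
        prev = 0
        for b in beads:
            pairs.append((prev, b))
            prev = b
        if kind == "ring":
            pairs.append((prev, 0))  # closing bond back onto the core
    return BondList(pairs=tuple(pairs))
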