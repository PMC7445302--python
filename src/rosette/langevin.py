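"""Langevin bead-spring dynamics of rosette polymers.

Mirrors the standard coarse-grained MD protocol for ideal polymers: beads of
mass m connected by stiff harmonic bonds V(r) = (k/2)(r − r0)², no
non-bonded interactions, evolved by the Langevin equation

    m r̈_i = F_i − ζ ṙ_i + F_i^R,
    <F_i^R(t) F_j^R(t')> = k_B T ζ δ_ij δ(t − t'),

in reduced units (k_BT = m = b = 1, τ = √(mb²/k_BT)) with the conventional
parameters k = 200 k_BT/b², r0 = b, ζ = 0.5 m/τ and Δt = 0.0025 τ.

The integrator is velocity Verlet with an analytically exact
Ornstein–Uhlenbeck friction/noise substep (the BAOAB splitting), which
samples the Boltzmann distribution of the bonded potential accurately at the
working timestep; the noise amplitude follows fluctuation–dissipation at
finite Δt, √(k_BT(1 − e^{−2ζΔt/m})/m) per velocity component.

Protocol defaults are scaled by the longest Rouse relaxation time
τ_R = ζ N² b²/(3π² k_BT) of an arm of N bonds: equilibration 2 τ_R from an
exactly-sampled Gaussian conformation, frames every 0.75 τ_R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sampler import Conformation, sample_rosette
from .topology import BondList, RosetteTopology, build_bond_list

__all__ = [
    "MDParams",
    "MDState",
    "MDResult",
    "bonded_forces",
    "langevin_step",
    "run_md",
    "rouse_time",
]


@dataclass(frozen=True)
class MDParams:
    """Langevin-dynamics parameters in reduced units (k_BT, m, b, τ)."""

    k: float = 200.0          # bond strength, k_BT / b^2
    r0: float = 1.0           # equilibrium bond length, b
    zeta: float = 0.5         # friction, m / tau
    dt: float = 0.0025        # timestep, tau
    kT: float = 1.0
    mass: float = 1.0
    n_equil_steps: int | None = None      # None -> 2 Rouse times
    n_sample_steps: int | None = None     # None -> 40 frames
    sample_interval: int | None = None    # None -> 0.75 Rouse times
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k, self.zeta, self.dt, self.kT, self.mass) <= 0 or self.r0 <= 0:
            raise ValueError("k, r0, zeta, dt, kT and mass must all be positive")
        # harmonic-bond stability: many steps per bond vibration period
        if self.dt * math.sqrt(self.k / self.mass) >= 0.2:
            raise ValueError(
                "timestep too large for the bond stiffness: "
                f"dt*sqrt(k/m) = {self.dt * math.sqrt(self.k / self.mass):.3f} >= 0.2"
            )


@dataclass
class MDState:
    """Mutable integrator state: positions, velocities, cached forces."""

    coords: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    bonds: np.ndarray  # (n_bonds, 2) bead indices
    step: int = 0


@dataclass(frozen=True)
class MDResult:
    """Sampled frames plus run diagnostics."""

    frames: list[Conformation]
    frame_steps: list[int]
    rg2_series: np.ndarray          # R_g^2 of each sampled frame
    kinetic_temperature: float      # m <v^2> per component, in k_BT
    bond_msd: float                 # <(l - r0)^2> over frames, expect kT/k
    equil_rg2_halves: tuple[float, float]  # stationarity diagnostic
    params: MDParams = field(repr=False, default=MDParams())


def bonded_forces(
    coords: np.ndarray | Conformation,
    bonds: BondList | np.ndarray,
    params: MDParams,
) -> np.ndarray:
    """Harmonic bond forces; Newton's third law holds pairwise.

    Raises on a zero-length bond (force direction undefined).
    """
    x = coords.coords if isinstance(coords, Conformation) else np.asarray(coords, float)
    b = bonds.as_array() if isinstance(bonds, BondList) else np.asarray(bonds)
    if b.size == 0:
        return np.zeros_like(x)
    d = x[b[:, 1]] - x[b[:, 0]]
    ell = np.sqrt((d * d).sum(axis=1))
    if ell.min() < 1e-12:
        idx = int(np.argmin(ell))
        raise ValueError(f"zero-length bond between beads {tuple(b[idx])}")
    fmag = -params.k * (ell - params.r0) / ell  # per unit displacement vector
    fb = fmag[:, None] * d
    forces = np.zeros_like(x)
    np.add.at(forces, b[:, 1], fb)
    np.add.at(forces, b[:, 0], -fb)
    return forces


def langevin_step(
    state: MDState, params: MDParams, rng: np.random.Generator
) -> MDState:
    """Advance the state by one BAOAB step (in place; returns the state)."""
    m = params.mass
    dt = params.dt
    half = 0.5 * dt / m
    c1 = math.exp(-params.zeta * dt / m)
    c2 = math.sqrt(params.kT / m * (1.0 - c1 * c1))

    v = state.velocities
    v += half * state.forces
    state.coords += 0.5 * dt * v
    v *= c1
    v += c2 * rng.standard_normal(v.shape)
    state.coords += 0.5 * dt * v
    state.forces = bonded_forces(state.coords, state.bonds, params)
    v += half * state.forces
    state.step += 1
    if not np.isfinite(state.coords).all():
        raise FloatingPointError(f"non-finite coordinates at step {state.step}")
    return state


def rouse_time(n_per_arm: int, params: MDParams) -> float:
    """Longest Rouse relaxation time ζN²b²/(3π²k_BT) of an arm, in τ."""
    return params.zeta * n_per_arm**2 * params.r0**2 / (3.0 * math.pi**2 * params.kT)


def _resolve_protocol(topology: RosetteTopology, params: MDParams) -> MDParams:
    tau_r_steps = max(1, int(round(rouse_time(topology.n_per_arm, params) / params.dt)))
    interval = params.sample_interval
    if interval is None:
        interval = max(1, int(round(0.75 * tau_r_steps)))
    equil = params.n_equil_steps
    if equil is None:
        # floor covers dissipation of the initial bond-length mismatch
        # (the Gaussian-sampled start has thermal *shape* but hot bonds),
        # which relaxes on the velocity/bond timescale, not the Rouse time
        equil = max(2 * tau_r_steps, 4000)
    sample = params.n_sample_steps
    if sample is None:
        sample = 40 * interval
    return replace(
        params,
        n_equil_steps=equil,
        n_sample_steps=sample,
        sample_interval=interval,
    )


def run_md(topology: RosetteTopology, params: MDParams) -> MDResult:
    """Equilibrate, then sample frames every ``sample_interval`` steps.

    The run starts from an exactly-sampled ideal conformation with the bond
    variance matched to r0 (step_var = r0²/3) and Maxwell–Boltzmann
    velocities, so equilibration only has to relax bond-length
    microstructure.  Deterministic given ``params.seed``.
    """
    params = _resolve_protocol(topology, params)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    init_topo = replace_step_var(topology, params.r0**2 / 3.0)
    conf = sample_rosette(init_topo, rng)
    bonds = build_bond_list(topology).as_array()
    state = MDState(
        coords=conf.coords.copy(),
        velocities=rng.standard_normal(conf.coords.shape)
        * math.sqrt(params.kT / params.mass),
        forces=np.zeros_like(conf.coords),
        bonds=bonds,
    )
    state.forces = bonded_forces(state.coords, state.bonds, params)

    equil_rg2: list[float] = []
    probe = max(1, params.n_equil_steps // 50)
    for step in range(params.n_equil_steps):
        langevin_step(state, params, rng)
        if step % probe == 0:
            x = state.coords
            equil_rg2.append(float(((x - x.mean(0)) ** 2).sum(1).mean()))
    halves = (
        (float(np.mean(equil_rg2[: len(equil_rg2) // 2])),
         float(np.mean(equil_rg2[len(equil_rg2) // 2:])))
        if len(equil_rg2) >= 2
        else (math.nan, math.nan)
    )

    frames: list[Conformation] = []
    frame_steps: list[int] = []
    rg2_series: list[float] = []
    kin = 0.0
    bond_sq = 0.0
    for step in range(1, params.n_sample_steps + 1):
        langevin_step(state, params, rng)
        if step % params.sample_interval == 0:
            x = state.coords
            frames.append(Conformation(coords=x.copy(), topology=topology))
            frame_steps.append(state.step)
            rg2_series.append(float(((x - x.mean(0)) ** 2).sum(1).mean()))
            kin += float(params.mass * (state.velocities**2).mean())
            d = x[bonds[:, 1]] - x[bonds[:, 0]]
            ell = np.sqrt((d * d).sum(axis=1))
            bond_sq += float(((ell - params.r0) ** 2).mean())
    n_frames = max(1, len(frames))
    return MDResult(
        frames=frames,
        frame_steps=frame_steps,
        rg2_series=np.asarray(rg2_series),
        kinetic_temperature=kin / n_frames,
        bond_msd=bond_sq / n_frames,
        equil_rg2_halves=halves,
        params=params,
    )


def replace_step_var(topology: RosetteTopology, step_var: float) -> RosetteTopology:
    """Copy of a topology with a different per-component step variance."""
    return RosetteTopology(
        f_c=topology.f_c,
        f_r=topology.f_r,
        n_per_arm=topology.n_per_arm,
        dim=topology.dim,
        step_var=step_var,
    )
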