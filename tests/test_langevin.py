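"""Langevin bead-spring dynamics: forces, thermostat and equilibrium statistics."""

import math

import numpy as np
import pytest

from rosette.langevin import (
    MDParams,
    MDState,
    bonded_forces,
    langevin_step,
    run_md,
)
from rosette.observables import discrete_reference, ensemble_estimate
from rosette.sampler import sample_ensemble
from rosette.topology import RosetteTopology, build_bond_list


class TestBondedForces:
    params = MDParams()

    def test_zero_at_equilibrium_length(self):
        x = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        f = bonded_forces(x, np.array([[0, 1]]), self.params)
        assert np.allclose(f, 0.0)

    def test_restoring_force_and_newtons_third_law(self):
        delta = 0.05
        x = np.array([[0.0, 0, 0], [1.0 + delta, 0, 0]])
        f = bonded_forces(x, np.array([[0, 1]]), self.params)
        assert f[1, 0] == pytest.approx(-self.params.k * delta)
        assert np.allclose(f[0], -f[1])

    def test_net_force_vanishes(self, rng):
        topo = RosetteTopology(2, 1, 8)
        bonds = build_bond_list(topo)
        x = rng.standard_normal((topo.total_beads, 3))
        f = bonded_forces(x, bonds, self.params)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_zero_length_bond_rejected(self):
        x = np.zeros((2, 3))
        with pytest.raises(ValueError, match="zero-length"):
            bonded_forces(x, np.array([[0, 1]]), self.params)


class TestIntegrator:
    def test_timestep_stability_contract(self):
        with pytest.raises(ValueError, match="timestep"):
            MDParams(dt=0.02)

    def test_free_particle_equipartition(self):
        """With no bonds the OU thermostat gives <v^2> = kT/m per component."""
        params = MDParams(kT=1.3, mass=2.0)
        rng = np.random.default_rng(4)
        n = 600
        state = MDState(
            coords=np.zeros((n, 3)),
            velocities=np.zeros((n, 3)),
            forces=np.zeros((n, 3)),
            bonds=np.empty((0, 2), dtype=np.intp),
        )
        samples = []
        for step in range(4000):
            langevin_step(state, params, rng)
            if step > 2000 and step % 400 == 0:
                samples.append(state.velocities.copy())
        v = np.concatenate(samples).ravel()
        se = (params.kT / params.mass) * math.sqrt(2.0 / (v.size - 1))
        assert abs(v.var(ddof=1) - params.kT / params.mass) < 3 * se

    def test_bond_length_fluctuation(self):
        """Equilibrium of the harmonic bond: <(l - r0)^2> ~ kT/k.

        Many independent bonded pairs are evolved at once to beat the slow
        (~1600 step) decorrelation of the bond energy.
        """
        params = MDParams()
        rng = np.random.default_rng(9)
        n_pairs = 200
        x = rng.standard_normal((2 * n_pairs, 3))
        x[1::2] = x[0::2] + np.array([1.0, 0, 0])  # start at the rest length
        bonds = np.column_stack(
            [np.arange(0, 2 * n_pairs, 2), np.arange(1, 2 * n_pairs, 2)]
        ).astype(np.intp)
        state = MDState(
            coords=x,
            velocities=rng.standard_normal((2 * n_pairs, 3)),
            forces=np.zeros((2 * n_pairs, 3)),
            bonds=bonds,
        )
        state.forces = bonded_forces(state.coords, state.bonds, params)
        sq = []
        for step in range(50_000):
            langevin_step(state, params, rng)
            if step > 8000 and step % 500 == 0:
                ell = np.linalg.norm(
                    state.coords[1::2] - state.coords[0::2], axis=1
                )
                sq.append(((ell - params.r0) ** 2).mean())
        assert np.mean(sq) == pytest.approx(params.kT / params.k, rel=0.05)

    def test_free_diffusion_matches_einstein_relation(self):
        """Long-time displacement variance is 2(kT/zeta)t per component."""
        params = MDParams(zeta=40.0, dt=0.0025)
        rng = np.random.default_rng(12)
        n = 20_000
        state = MDState(
            coords=np.zeros((n, 3)),
            velocities=np.zeros((n, 3)),
            forces=np.zeros((n, 3)),
            bonds=np.empty((0, 2), dtype=np.intp),
        )
        # thermalize velocities, then accumulate diffusive displacement
        for _ in range(400):
            langevin_step(state, params, rng)
        before = state.coords.copy()
        n_steps = 2000
        for _ in range(n_steps):
            langevin_step(state, params, rng)
        disp = (state.coords - before).ravel()
        t = n_steps * params.dt
        # inertial correction: var = 2D(t - m/zeta) for t >> m/zeta
        expected = 2.0 * params.kT / params.zeta * (t - params.mass / params.zeta)
        assert disp.var(ddof=1) == pytest.approx(expected, rel=0.03)


class TestRunMD:
    def test_seed_determinism(self):
        topo = RosetteTopology(1, 0, 10)
        params = MDParams(seed=21, n_equil_steps=200, n_sample_steps=400,
                          sample_interval=100)
        a = run_md(topo, params)
        b = run_md(topo, params)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.coords, fb.coords)

    def test_chain_rg2_matches_gaussian_reference(self):
        """MD <R_g^2> agrees with the ideal-chain value at the measured bond length."""
        topo = RosetteTopology(1, 0, 20)
        params = MDParams(seed=17, n_sample_steps=None)
        result = run_md(topo, params)
        # effective mean-square bond length of the stiff harmonic chain
        eff = _mean_square_bond(result)
        ref = discrete_reference(
            RosetteTopology(1, 0, 20, step_var=eff / 3.0)
        )
        rg2 = result.rg2_series
        se = rg2.std(ddof=1) / math.sqrt(len(rg2))
        assert abs(rg2.mean() - ref.rg2) < 3.5 * se

    def test_ring_closing_bond_statistics(self):
        """The ring-closing bond fluctuates like any other harmonic bond."""
        topo = RosetteTopology(0, 1, 16)
        params = MDParams(seed=33)
        result = run_md(topo, params)
        closing = []
        for frame in result.frames:
            ell = np.linalg.norm(frame.coords[-1] - frame.coords[0])
            closing.append((ell - params.r0) ** 2)
        # 40 frames: compare at jackknife-free 50% tolerance of kT/k
        assert np.mean(closing) == pytest.approx(params.kT / params.k, rel=0.5)

    def test_kinetic_temperature_and_stationarity(self):
        topo = RosetteTopology(1, 0, 30)
        result = run_md(topo, MDParams(seed=8))
        assert result.kinetic_temperature == pytest.approx(1.0, rel=0.02)
        first, second = result.equil_rg2_halves
        # equilibration started from an exact sample: halves statistically equal
        assert abs(first - second) / second < 0.5

    def test_md_rho_agrees_with_direct_sampler(self):
        """ρ is microstructure-insensitive: MD and exact sampling agree at matched M."""
        n = 50
        topo = RosetteTopology(1, 0, n)
        md = run_md(topo, MDParams(seed=5))
        est_md = ensemble_estimate(md.frames)
        est_exact = ensemble_estimate(list(sample_ensemble(topo, 400, seed=2)))
        combined = math.hypot(est_md.rho_err, est_exact.rho_err)
        assert abs(est_md.rho - est_exact.rho) < 3 * combined


def _mean_square_bond(result):
    from rosette.topology import build_bond_list

    bonds = build_bond_list(result.frames[0].topology).as_array()
    acc = []
    for frame in result.frames:
        d = frame.coords[bonds[:, 1]] - frame.coords[bonds[:, 0]]
        acc.append((d**2).sum(axis=1).mean())
    return float(np.mean(acc))
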