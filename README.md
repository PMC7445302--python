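# rosette

Conformational size measures of ideal **rosette polymers** — branched
macromolecules in which `f_c` linear arms and `f_r` closed loops (rings)
radiate from a single core. The package computes, for any architecture
`(f_c, f_r)`:

* the mean square **gyration radius** ⟨R_g²⟩ = (1/2M²) Σ_{n,m} ⟨(r_n − r_m)²⟩,
* the Kirkwood **hydrodynamic radius** via ⟨R_H⁻¹⟩ = (1/M²) Σ_{n≠m} ⟨1/|r_n − r_m|⟩,
* the **universal size ratio** ρ = √⟨R_g²⟩ / R_H,

which is dimensionless, independent of chemical microstructure, and a
fingerprint of the branching architecture: ρ = 8/(3√π) ≈ 1.5045 for a linear
chain, √(2π)/2 ≈ 1.2533 for a ring, and decreases toward 1 as arms — rings in
particular — are added. Ideal (Gaussian) statistics correspond to flexible
polymers in a θ-solvent. Both R_g and R_H are experimentally accessible
(static and dynamic light scattering), which is what makes ρ useful.

The package is written for polymer/biophysics researchers who want either the
closed-form numbers or a simulation pipeline they can modify. It provides
four independent routes to the same physics, which cross-validate each other:

1. **theory** — exact closed forms for ⟨R_g²⟩ and ρ for arbitrary
   `(f_c, f_r)` and spatial dimension d;
2. **diagram oracle** — adaptive quadrature of the five contour double
   integrals behind the Kirkwood sum, assembled with ordered-pair
   combinatorics (an independent numerical check of the closed form);
3. **exact sampling** — independent Gaussian conformations (free walks for
   linear arms, Brownian bridges for rings), with exact finite-size
   references for validation;
4. **Langevin MD** — bead-spring dynamics with stiff harmonic bonds
   (k = 200 k_BT/b², r0 = b, ζ = 0.5 m/τ, Δt = 0.0025 τ), mirroring the
   standard coarse-grained protocol.

Finite-size estimates ρ(N) at N beads per arm are extrapolated with the
θ-solvent correction-to-scaling law ρ(N) = ρ∞(1 + a·N^(−1/2)).

## Worked example

```python
from rosette import (RosetteTopology, discrete_reference, ensemble_estimate,
                     rho_rosette, sample_ensemble)

print(round(rho_rosette(1, 1), 4))        # tadpole: one chain + one ring

topo = RosetteTopology(f_c=1, f_r=0, n_per_arm=199)   # 200-bead chain
est = ensemble_estimate(list(sample_ensemble(topo, 500, seed=42)))
ref = discrete_reference(topo)                        # exact finite-M values
print(f"{est.rho:.4f} +/- {est.rho_err:.4f}  exact {ref.rho:.4f}")
```

prints

```
1.4151
1.3756 +/- 0.0094  exact 1.3880
```

The first number is the closed-form tadpole ratio. The second line compares
a 500-conformation Monte-Carlo estimate of ρ for a 200-bead chain with the
exact discrete-chain value at the same bead count (agreement within 1.4
standard errors); both sit below the asymptote 1.5045 because of the
N^(−1/2) finite-size correction, which `rosette.fit_finite_size` removes.

The `examples/` directory holds one short script per capability (closed
forms, diagram oracle, sampling, MD diagnostics, extrapolation), each
printing the numbers it computes and what they mean. A thin CLI mirrors the
library:

```bash
rosette theory --fc 2 --fr 2
rosette oracle --fc 1 --fr 1
rosette sample --fc 0 --fr 1 --n 200 --conformations 500 --seed 1 --out ring.csv
rosette md --fc 1 --fr 0 --n 50 --seed 1 --out md.csv
rosette extrapolate --in series.csv --out fit.json
```

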