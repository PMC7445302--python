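# Methods

## Model

A rosette polymer is modelled as `f_c` linear arms and `f_r` ring arms of
equal contour length grafted to one branch point (the core). Statistics are
ideal (Gaussian): no excluded volume, no bending stiffness — the θ-solvent
idealization of a flexible polymer. Every observable here follows from the
Gaussian two-point law ⟨(r(s₂) − r(s₁))²⟩ = d·|s₂ − s₁| (per-arm contour
coordinates, unit Kuhn segment), plus the loop-closure constraint on ring
arms. This model does not describe architectures whose conformations are
dominated by steric repulsion between branches (dense brushes, dendrimers),
nor good-solvent (swollen) chains.

Discrete mapping: bead 0 is the core; a linear arm of `n` bonds contributes
`n` beads; a ring arm contributes `n − 1` beads because the bead closing the
loop *is* the core. This convention avoids coincident bead pairs (which
would make the Kirkwood sum singular) at the cost of an O(1) difference in
bead count between arm types; all such O(1/N) effects are absorbed by the
finite-size extrapolation. `step_var` is the per-component bond variance, so
⟨bond²⟩ = d·step_var; ρ is invariant under rescaling it (asserted by test).

## Observables and estimator

* R_g² per conformation is the mean squared deviation from the centroid
  (identical to the pair-sum definition; both code paths exist and are
  tested against each other).
* R_H⁻¹ per conformation is the Kirkwood sum (1/M²)Σ_{n≠m} 1/r_nm. The
  divergent diagonal is excluded while the 1/M² normalization is kept; the
  resulting O(1/M) bias is a finite-size effect like any other and is
  removed by extrapolation. An unbiased pair-subsampling mode (K uniform
  distinct ordered pairs, scaled by (M² − M)/M²) is available for very large
  M; at the problem sizes used by the shipped pipelines the exact sum is
  affordable and is the default.
* ρ = √(mean R_g²) · (mean R_H⁻¹): ensemble means are combined, matching the
  definitions in which each radius is an ensemble property; per-conformation
  ratios are *not* averaged. The error of ρ uses a delete-one jackknife over
  conformations, which captures the within-conformation correlation between
  R_g² and R_H⁻¹ that naive error propagation would miss.

## Closed forms and the diagram oracle

The general ρ(f_c, f_r, d) closed form and ⟨R_g²⟩ = (Ld/12f²)[f_r(2f_r−1) +
2f_c(3f_c−2) + 8f_c f_r] are implemented directly; the special cases (chain,
star, ring, double ring, tadpole) are separate expressions that must agree
with the general form to ≤1e−12 relative (tested). The theory-layer
hydrodynamic radius is *defined* as √⟨R_g²⟩/ρ: a closed-form R_H expression
that is inconsistent with the chain limit exists in the literature context
this package addresses, so R_H is anchored on the two quantities that are
independently verified.

The independent check of ρ is a quadrature oracle. After the Gaussian
averages, ⟨R_H⁻¹⟩ reduces to five geometric double integrals over contour
coordinates (same-arm chain, cross-chain, same-ring, cross-ring,
chain–ring). Four have elementary antiderivatives; the cross-ring integrand
(s₁ + s₂ − s₁² − s₂²)^(−1/2) is integrated in closed form over the inner
variable — ∫₀¹(c + y − y²)^(−1/2)dy = 2·arcsin((1 + 4c)^(−1/2)) with
c = x − x² — leaving a smooth 1D adaptive quadrature (this replaces 2D
adaptive quadrature of the singular-corner integrand; it is faster and
accurate to the requested 1e−8 by construction). Assembly counts *ordered*
point pairs: the same-arm diagrams are written on s₁ < s₂ and the mixed
diagram fixes which arm type carries s₁, so the unrestricted double sum over
arms requires multiplicities {2f_c, f_c(f_c−1), 2f_r, f_r(f_r−1), 2f_c f_r}.
This convention reproduces every known special-case value to ~1e−14; the
half-counting alternative reproduces none. The √(2/π)/σ mean reciprocal
distance used in assembly is specific to d = 3; the closed form covers
general d.

## Exact sampling

Linear arms are cumulative sums of i.i.d. Gaussian steps; ring arms are
Brownian bridges r_k = W_k − (k/n)W_n, which close exactly and give interior
bead k variance step_var·k(n−k)/n. Arms are independent given the core —
exactly the ideal-polymer measure, so every conformation is an independent
exact draw (no equilibration, no integrator bias). Ensemble member i uses an
RNG stream keyed by (root seed, i), so ensembles are reproducible and
order-independent. For validation, exact finite-M references for *any*
architecture are computed from the known pairwise variance structure
(⟨1/r⟩ = √(2/π)/σ for a 3D Gaussian separation).

## Langevin dynamics

The bead-spring model uses harmonic bonds V = (k/2)(ℓ − r0)² with
k = 200 k_BT/b², r0 = b, friction ζ = 0.5 m/τ and Δt = 0.0025 τ
(τ = √(mb²/k_BT)); no non-bonded interactions, so the chain remains ideal.
The integrator is BAOAB — velocity Verlet with the exact Ornstein–Uhlenbeck
solution for the friction/noise substep; the discrete noise amplitude
√(k_BT(1 − e^(−2ζΔt/m))/m) satisfies fluctuation–dissipation at finite Δt.
The stability contract Δt√(k/m) < 0.2 is enforced (0.035 at the defaults).

Protocol defaults are scaled by the longest Rouse time
τ_R = ζN²b²/(3π²k_BT) of an arm of N bonds: equilibration 2τ_R (with a floor
of 4000 steps — the initial state is an exactly-sampled Gaussian
conformation whose *shape* is already equilibrium but whose bond lengths
carry excess harmonic energy that dissipates on the velocity relaxation
timescale m/ζ, not τ_R), production frames every 0.75τ_R, 40 frames by
default. Diagnostics recorded per run: kinetic temperature (target k_BT,
within 2% in tests), bond-length fluctuation ⟨(ℓ − r0)²⟩ (target k_BT/k),
and first-half/second-half equilibration R_g² means as a stationarity check.

A stiff-bond chain is not literally a Gaussian chain at finite N: absolute
R_g² comparisons against the ideal reference use the *measured* mean-square
bond length; ρ, being dimensionless, needs no calibration and agrees with
the exact sampler at matched bead count within statistical error — the key
evidence that the dynamics samples the ideal conformational measure for the
observables of interest.

## Finite-size extrapolation

ρ(N) = ρ∞(1 + aN^(−Δ)) with Δ = 1/2 fixed (ideal/θ statistics; the
good-solvent exponent ≈ 0.53 is out of scope since the model has no excluded
volume). The fit is linear in x = N^(−1/2): weighted least squares with
weights 1/σ_ρ², intercept ρ∞, amplitude a = slope/intercept with first-order
error propagation including the intercept–slope covariance. With known error
bars the parameter covariance is taken directly from the weighted normal
equations; the unweighted variant scales it by χ²/dof. N is *beads per arm*,
not total beads, and is held to that meaning everywhere. The fit reproduces
noiseless model data to ≤1e−10 and its 1σ interval covers the truth in the
expected fraction of noisy replicates (both tested).

## Problem sizes and what the tests show

The shipped pipeline samples N ∈ {100, 200, 400, 800, 1600} with 400
conformations per N and exact pair sums — a desk-scale choice that
reproduces the asymptotic chain and ring ratios to well within the combined
uncertainties of the reference values (1.499 ± 0.005 and 1.244 ± 0.004);
MD validation runs use N ≤ 100 and a single trajectory. Because generation
is exact, larger N costs only the O(M²) pair sum (or switch to
subsampling). Passing tests demonstrate correctness of the Gaussian model,
its estimators and its extrapolation — they do not probe excluded-volume
effects, hydrodynamic interactions beyond the Kirkwood approximation, or
bond-microstructure effects beyond the stiff harmonic spring.

## Numerical notes and limitations

* Quadrature tolerance defaults to 1e−8 (absolute); non-convergence raises
  with the achieved error estimate rather than returning silently.
* Coincident beads (distance < 1e−12) in the exact Kirkwood sum raise an
  error naming the bead indices; the sampler cannot produce them except at
  step_var = 0.
* The oracle-vs-closed-form agreement is asserted at 1e−4 across the
  f_c, f_r ∈ {0..6} grid (quadrature error accumulates linearly in the
  assembly multiplicities).
* Family orderings of ρ at fixed total functionality are not universal:
  by f = 8 the symmetric rosette (4,4) overtakes the pure-chain star (8,0);
  tests assert the ordering only where it actually holds (f ≤ 6) plus the
  crossover.
* Arms of unequal length, multiple branch points, excluded volume and full
  hydrodynamic tensors are out of scope.
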