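"""Finite-size extrapolation of rho for a ring polymer (reduced sizes).

Simulated rho at finite beads-per-arm N carries a correction-to-scaling term
rho(N) = rho_inf(1 + a N^(-1/2)).  This example samples ring ensembles on a
small N ladder, fits the law, and compares rho_inf with the exact asymptote
sqrt(2*pi)/2 = 1.2533.  (The headline computation in scripts/acceptance.py
uses the full ladder N = 100..1600 with 400 conformations per N.)
"""

from rosette import extrapolated_rho

fit, series = extrapolated_rho(
    f_c=0, f_r=1, seed=3, n_values=(50, 100, 200, 400), n_conformations=200
)

print("  N     rho        err")
for n, est in series:
    print(f"{n:4d}   {est.rho:.4f}   {est.rho_err:.4f}")
print()
print(f"rho_inf = {fit.rho_inf:.4f} +/- {fit.rho_inf_err:.4f}  (exact 1.2533)")
print(f"a       = {fit.amplitude_a:.3f} +/- {fit.amplitude_a_err:.3f}")
print(f"chi^2   = {fit.chi2:.2f} over {len(fit.points) - 2} dof")
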