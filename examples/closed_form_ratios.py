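"""Closed-form universal size ratios for rosette architectures.

Evaluates rho = sqrt(<R_g^2>)/R_H for the ten benchmark architectures and the
named special cases.  rho is dimensionless and depends only on the numbers of
linear arms (f_c) and ring arms (f_r): more arms, and especially more rings,
compactify the molecule, pushing rho down from the linear-chain value 1.5045
toward 1.
"""

from rosette import BENCHMARK_TOPOLOGIES, rho_rosette, rho_special, rg2_rosette

print("fc  fr   rho      Rg^2/L")
for fc, fr in BENCHMARK_TOPOLOGIES:
    print(f"{fc:2d}  {fr:2d}   {rho_rosette(fc, fr):.4f}   {rg2_rosette(fc, fr):.4f}")

print()
for name in ("chain", "ring", "double_ring", "tadpole"):
    print(f"{name:12s} rho = {rho_special(name):.4f}")
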