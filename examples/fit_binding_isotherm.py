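"""One-site metal-binding isotherm: simulate and refit.

The protocol mirrors the magnesium titration: twenty 2.5 uL injections of
400 uM titrant into 40 uM peptide at 298 K.  The forward model is the
standard single-site equilibrium with per-injection displacement mixing;
the fit recovers (n, Kd, dH) by multi-start nonlinear least squares and
derives dG = RT ln Kd and -TdS = dG - dH.
"""

import numpy as np

from coffeetide.itc import TitrationProtocol, fit_one_site
from coffeetide.synthdata import generate_isotherm

proto = TitrationProtocol()  # 20 x 2.5 uL, 40 uM cell, 400 uM syringe, 298 K
iso, truth = generate_isotherm(
    proto, n=1.0, kd=4.19e-6, dh=-0.695, noise_sd=0.01, seed=42
)
print("simulated heats (kcal/mol of injectant), first five injections:")
print(" ", np.round(iso.heats[:5], 3))

fit = fit_one_site(iso, proto)
print(f"\ntruth: n = {truth['n']:.2f}, Kd = {truth['kd'] * 1e6:.2f} uM, dH = {truth['dh']:.3f} kcal/mol")
print(f"fit:   n = {fit.n:.2f}, Kd = {fit.kd_uM:.2f} uM, dH = {fit.dh:.3f} kcal/mol")
print(f"derived: dG = {fit.dg:.2f} kcal/mol, -TdS = {fit.minus_tds:.2f} kcal/mol at {fit.temperature:.0f} K")
print("\nA micromolar Kd with a small exothermic dH means binding is mostly"
      "\nentropy-driven, consistent with carboxylate-cluster metal chelation.")
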