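"""Binding occupancy and isotherm fitting for the monobody panel.

First the exact quadratic fraction-bound used to pick monobody
concentrations for the AFM assay (the target sits at low-nanomolar
concentration, so the excess-ligand approximation is nearly exact but the
quadratic is used anyway).  Then a forward-simulated titration with 2%
heat noise is fitted to recover K_D, dH and n.
"""

import numpy as np

from cartwheel import itc

print("occupancy at the AFM assay concentrations (target at 16 nM):")
for name, conc_uM, kd_nM in (("MB-1", 6.8, 566.0), ("MB-13", 14.5, 134.0),
                             ("MB-15", 12.9, 137.0)):
    frac = itc.fraction_bound(conc_uM, 0.016, kd_nM)
    print(f"  {name:6s} {conc_uM:5.1f} uM, K_D {kd_nM:5.0f} nM "
          f"-> {100 * frac:4.1f} % bound")

clean = itc.simulate_titration(kd=137.0, dh=-10.0)
noisy = itc.simulate_titration(kd=137.0, dh=-10.0,
                               noise_sd=0.02 * abs(clean.heats[0]), seed=8)
fit = itc.fit_titration(noisy)
print("\nfit of one noisy synthetic titration (truth: 137 nM, -10 kcal/mol):")
print(f"  K_D = {fit.kd:6.1f} nM   dH = {fit.dh:6.2f} kcal/mol   "
      f"n = {fit.n_stoich:4.2f}")
print(f"  residual RMS = {fit.residual_rms:.3f} ucal")

# All three assay concentrations clear the 70% occupancy requirement by a
# wide margin, and the fitted K_D lands within a few percent of the
# generative value at this noise level.
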