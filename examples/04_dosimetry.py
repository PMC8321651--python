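"""Erythemal UV dosimetry.

Weights a synthetic broadband-UVB lamp spectrum (Gaussian line at
312 nm, roughly an EB-280C-like narrowband source) by the McKinlay-
Diffey erythema action spectrum, converts the erythemally effective
energy (EEE) to standard erythema doses, and reproduces the
tanning-session UVA equivalence arithmetic.
"""

import numpy as np

from uvsig.dosimetry import (
    Dose,
    SpectralIrradiance,
    eee_to_sed,
    effective_dose,
    erythemal_weight,
    tanning_session_uva_equivalence,
)

for lam in (280, 298, 308, 312, 340, 365):
    print(f"erythemal weight at {lam} nm: {erythemal_weight(float(lam)):.4g}")

# synthetic lamp: Gaussian emission centered at 312 nm, sigma 8 nm
lam = np.arange(280.0, 391.0, 1.0)
intensity = np.exp(-0.5 * ((lam - 312.0) / 8.0) ** 2)
lamp = SpectralIrradiance(lam, intensity)

dose = Dose(4.5, "kJ_per_m2")  # a single neonatal UVB exposure
eee = effective_dose(lamp, dose)
print(f"\nunweighted dose: {dose.value} kJ/m2 = {dose.in_mj_per_cm2():.0f} mJ/cm2")
print(f"erythemally effective energy: {eee.value:.1f} mJ/cm2 "
      f"= {eee_to_sed(eee).value:.2f} SED")
print("(weights < 1 above 298 nm shrink the biologically effective dose)")

out = tanning_session_uva_equivalence(session_sed=4.5, lamp_eee_mj_per_cm2=14.2)
print(f"\naverage tanning session: {out['session_sed']} SED "
      f"= {out['session_eee_mj_per_cm2']:.0f} mJ/cm2 EEE")
print(f"UVA-attributable half: {out['uva_attributable_mj_per_cm2']:.1f} mJ/cm2")
print(f"ratio to a 70 kJ/m2 UVA lamp exposure (14.2 mJ/cm2 EEE): "
      f"{out['ratio_to_lamp']:.2f}")
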