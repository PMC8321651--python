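"""Erythemal UV dosimetry.

Weights lamp spectral output by the McKinlay-Diffey erythema action
spectrum to convert an unweighted radiometric dose into erythemally
effective energy (EEE), converts between mJ/cm^2 and standard erythema
doses (1 SED = 10 mJ/cm^2 erythemally weighted), and reproduces the
tanning-session UVA equivalence arithmetic.

The action spectrum is piecewise exponential in wavelength lambda (nm):
1 for lambda <= 298; 10^(0.094 (298 - lambda)) for 298 < lambda <= 328;
10^(0.015 (C - lambda)) for 328 < lambda <= 400, with C = 140 (the
continuous CIE-1998 form, default) or C = 139 (the original 1987
tabulation, which leaves a ~0.07 log10 step at 328 nm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Unit conversion factors to mJ/cm^2 (erythemally weighted where noted).
KJ_PER_M2_TO_MJ_PER_CM2 = 100.0
MJ_PER_CM2_PER_SED = 10.0


@dataclass(frozen=True)
class Dose:
    """A UV dose with explicit units."""

    value: float
    unit: str  # kJ_per_m2 | mJ_per_cm2 | SED

    _UNITS = ("kJ_per_m2", "mJ_per_cm2", "SED")

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("dose must be non-negative")
        if self.unit not in self._UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    def in_mj_per_cm2(self) -> float:
        if self.unit == "kJ_per_m2":
            return self.value * KJ_PER_M2_TO_MJ_PER_CM2
        if self.unit == "SED":
            return self.value * MJ_PER_CM2_PER_SED
        return self.value

    def to(self, unit: str) -> "Dose":
        mj = self.in_mj_per_cm2()
        if unit == "mJ_per_cm2":
            return Dose(mj, unit)
        if unit == "kJ_per_m2":
            return Dose(mj / KJ_PER_M2_TO_MJ_PER_CM2, unit)
        if unit == "SED":
            return Dose(mj / MJ_PER_CM2_PER_SED, unit)
        raise ValueError(f"unknown unit {unit!r}")


@dataclass
class SpectralIrradiance:
    """Relative spectral output of a lamp on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.size < 2:
            raise ValueError("need at least 2 spectral points for integration")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if (self.intensities < 0).any():
            raise ValueError("intensities must be non-negative")
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if lo < 250 or hi > 400:
            raise ValueError("spectrum must lie within [250, 400] nm")


def erythemal_weight(wavelength_nm, c: float = 140.0):
    """McKinlay-Diffey erythemal weighting at one or more wavelengths.

    Vectorized over the input; raises for wavelengths outside
    [250, 400] nm.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam < 250) or np.any(lam > 400):
        raise ValueError("wavelength outside the [250, 400] nm domain")
    w = np.where(
        lam <= 298,
        1.0,
        np.where(
            lam <= 328,
            10.0 ** (0.094 * (298.0 - lam)),
            10.0 ** (0.015 * (c - lam)),
        ),
    )
    return float(w) if np.isscalar(wavelength_nm) else w


def erythemal_fraction(spectrum: SpectralIrradiance, c: float = 140.0) -> float:
    """Erythemally weighted fraction of a lamp's output.

    integral(w(lambda) S(lambda)) / integral(S(lambda)) by trapezoidal
    quadrature on the native grid; grids coarser than 5 nm are first
    linearly resampled to 1 nm so the rapidly varying weight is sampled
    adequately.
    """
    lam, s = spectrum.wavelengths, spectrum.intensities
    total = np.trapezoid(s, lam)
    if total <= 0:
        raise ValueError("spectrum has zero total intensity")
    if np.max(np.diff(lam)) > 5.0:
        fine = np.arange(lam[0], lam[-1] + 0.5, 1.0)
        fine = np.clip(fine, lam[0], lam[-1])
        s = np.interp(fine, lam, s)
        lam = fine
        total = np.trapezoid(s, lam)
    weighted = np.trapezoid(erythemal_weight(lam, c=c) * s, lam)
    return float(weighted / total)


def effective_dose(
    spectrum: SpectralIrradiance, unweighted_dose: Dose, c: float = 140.0
) -> Dose:
    """Erythemally effective energy (EEE) of an unweighted lamp dose.

    EEE = dose x weighted fraction of the lamp spectrum, returned in
    mJ/cm^2 (erythemally weighted).
    """
    if unweighted_dose.unit == "SED":
        raise ValueError("unweighted dose must be in energy units, not SED")
    frac = erythemal_fraction(spectrum, c=c)
    return Dose(unweighted_dose.in_mj_per_cm2() * frac, "mJ_per_cm2")


def eee_to_sed(eee: Dose) -> Dose:
    """Convert an erythemally weighted dose to standard erythema doses."""
    return eee.to("SED")


def tanning_session_uva_equivalence(
    session_sed: float = 4.5,
    uvb_fraction_of_erythemal: float = 0.5,
    lamp_eee_mj_per_cm2: float = 14.2,
) -> dict[str, float]:
    """Tanning-parlor UVA dose relative to an experimental UVA lamp dose.

    The average tanning session delivers ``session_sed`` standard
    erythema doses; about half of that erythemal energy derives from the
    small UVB component of the lamp, so the UVA-attributable portion is
    the remainder.  The ratio of that portion to the EEE of the
    experimental lamp dose expresses how many lamp-equivalents a session
    represents.
    """
    if session_sed < 0 or lamp_eee_mj_per_cm2 <= 0:
        raise ValueError("doses must be positive")
    session_eee = Dose(session_sed, "SED").in_mj_per_cm2()
    uva_portion = session_eee * (1.0 - uvb_fraction_of_erythemal)
    return {
        "session_sed": session_sed,
        "session_eee_mj_per_cm2": session_eee,
        "uva_attributable_mj_per_cm2": uva_portion,
        "ratio_to_lamp": uva_portion / lamp_eee_mj_per_cm2,
    }


def read_spectrum(path, **read_kwargs) -> SpectralIrradiance:
    """Read a two-column wavelength/intensity CSV or TSV."""
    import pandas as pd

    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=read_kwargs.pop("sep", sep), **read_kwargs)
    return SpectralIrradiance(
        df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
    )
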