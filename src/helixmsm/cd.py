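"""Circular-dichroism helicity quantification.

Observed ellipticities (mdeg) are normalized to mean residue ellipticity

    [theta]_lambda = [theta]_obs / (10 * l * C * n)

with pathlength l in cm, concentration C in mol/L and n residues, giving
deg cm^2 dmol^-1.  Percent alpha-helicity follows from the 222 nm value:

    % helicity = 100 * ([theta]_222 - [theta]_0) / ([theta]_max - [theta]_0)

where [theta]_0 = 2220 - 53 T is the random-coil baseline at temperature T
(deg C) and [theta]_max is the theoretical MRE of a complete helix of n
residues, modelled with the standard finite-length correction
[theta]_max = theta_inf * (1 - x / n); theta_inf = -39500 deg cm^2 dmol^-1
and x = 2.57 are exposed as configuration, not fixed constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CDSpectrum",
    "MRESpectrum",
    "average_and_baseline",
    "mre",
    "coil_baseline",
    "theta_max",
    "percent_helicity",
    "helicity_from_spectrum",
]

THETA_INF_DEFAULT = -39500.0  # deg cm^2 dmol^-1, infinite-helix 222 nm MRE
FINITE_LENGTH_X_DEFAULT = 2.57


@dataclass
class CDSpectrum:
    """Observed CD scans on a common wavelength grid (mdeg)."""

    wavelengths: np.ndarray        # nm, strictly increasing
    scans: np.ndarray              # (n_scans, n_wavelengths) mdeg
    pathlength_cm: float
    concentration_molar: float
    n_residues: int
    temperature_c: float = 25.0
    blank: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.scans = np.atleast_2d(np.asarray(self.scans, dtype=float))
        if (np.diff(self.wavelengths) <= 0).any():
            raise ValueError("wavelengths must be strictly increasing")
        if self.scans.shape[1] != self.wavelengths.shape[0]:
            raise ValueError("scan grid does not match wavelength grid")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be > 0")
        if self.concentration_molar <= 0:
            raise ValueError("concentration must be > 0")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.blank is not None:
            self.blank = np.asarray(self.blank, dtype=float)
            if self.blank.shape != self.wavelengths.shape:
                raise ValueError("blank grid does not match wavelength grid")


@dataclass
class MRESpectrum:
    wavelengths: np.ndarray
    mre: np.ndarray  # deg cm^2 dmol^-1

    def at(self, wavelength: float) -> float:
        """MRE at the grid point nearest the requested wavelength."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.mre[i])


def average_and_baseline(spectrum: CDSpectrum) -> np.ndarray:
    """Pointwise mean over scans, minus the blank when present (mdeg)."""
    avg = spectrum.scans.mean(axis=0)
    if spectrum.blank is not None:
        avg = avg - spectrum.blank
    return avg


def mre(spectrum: CDSpectrum) -> MRESpectrum:
    """Normalize the averaged, baseline-corrected signal to mean residue
    ellipticity."""
    corrected = average_and_baseline(spectrum)
    denom = (10.0 * spectrum.pathlength_cm * spectrum.concentration_molar
             * spectrum.n_residues)
    return MRESpectrum(wavelengths=spectrum.wavelengths,
                       mre=corrected / denom)


def coil_baseline(temperature_c: float) -> float:
    """Random-coil 222 nm MRE baseline: [theta]_0 = 2220 - 53 T."""
    return 2220.0 - 53.0 * temperature_c


def theta_max(
    n_residues: int,
    theta_inf: float = THETA_INF_DEFAULT,
    x: float = FINITE_LENGTH_X_DEFAULT,
) -> float:
    """Theoretical 222 nm MRE of a complete helix of n residues."""
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if n_residues <= x:
        raise ValueError(
            f"finite-length correction undefined for n <= x = {x}"
        )
    return theta_inf * (1.0 - x / n_residues)


def percent_helicity(mre222: float, th_max: float, th_0: float) -> float:
    """Percent helicity from the 222 nm MRE; may fall outside [0, 100] on
    noisy input (returned unclamped)."""
    if th_max == th_0:
        raise ValueError("theta_max equals theta_0; helicity undefined")
    return 100.0 * (mre222 - th_0) / (th_max - th_0)


def helicity_from_spectrum(spectrum: CDSpectrum) -> float:
    """Full chain: average/baseline -> MRE -> %helicity at 222 nm."""
    ms = mre(spectrum)
    th0 = coil_baseline(spectrum.temperature_c)
    thmax = theta_max(spectrum.n_residues)
    return percent_helicity(ms.at(222.0), thmax, th0)


def synthesize_spectrum(
    target_percent_helicity: float,
    n_residues: int,
    wavelengths: Optional[np.ndarray] = None,
    pathlength_cm: float = 0.1,
    concentration_molar: float = 70e-6,
    temperature_c: float = 25.0,
    n_scans: int = 3,
) -> CDSpectrum:
    """Construct an idealized spectrum whose 222 nm MRE is the linear mix of
    the helix and coil basis values at the target helicity (useful as a
    round-trip oracle for the quantification chain)."""
    if wavelengths is None:
        wavelengths = np.arange(200.0, 251.0, 1.0)
    th0 = coil_baseline(temperature_c)
    thmax = theta_max(n_residues)
    frac = target_percent_helicity / 100.0
    mre222 = th0 + frac * (thmax - th0)
    # a smooth band shape anchored exactly at 222 nm
    shape = np.exp(-0.5 * ((wavelengths - 222.0) / 12.0) ** 2)
    mre_curve = mre222 * shape
    obs = mre_curve * (10.0 * pathlength_cm * concentration_molar
                       * n_residues)
    scans = np.tile(obs, (n_scans, 1))
    return CDSpectrum(wavelengths=wavelengths, scans=scans,
                      pathlength_cm=pathlength_cm,
                      concentration_molar=concentration_molar,
                      n_residues=n_residues, temperature_c=temperature_c)
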