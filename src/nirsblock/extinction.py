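"""Hemoglobin extinction coefficients for the modified Beer-Lambert law.

The two-wavelength MBLL relates optical-density changes to concentration
changes of oxygenated and deoxygenated hemoglobin through a 2x2 matrix of
molar extinction coefficients.  The default table below approximates a
standard published compilation of hemoglobin absorption spectra evaluated at
the 695 and 830 nm operating wavelengths of continuous-wave NIRS
instruments; values are in cm^-1 uM^-1 so that, with the source-detector
distance in cm and a partial pathlength factor of 1, recovered
concentrations are in uM-equivalent units.  The absolute scale is a
convention (channel-wise t statistics are scale invariant) and the table is
overridable wherever it is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExtinctionTable", "default_extinction_table"]


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients at the instrument wavelengths.

    Parameters
    ----------
    wavelengths
        The two operating wavelengths in nm, e.g. ``(695.0, 830.0)``.
    eps_oxy, eps_deoxy
        Extinction coefficients of oxy- and deoxy-hemoglobin at each
        wavelength, in cm^-1 uM^-1, ordered like ``wavelengths``.
    """

    wavelengths: tuple[float, float] = (695.0, 830.0)
    eps_oxy: tuple[float, float] = (3.20e-4, 9.74e-4)
    eps_deoxy: tuple[float, float] = (1.90e-3, 6.93e-4)

    def __post_init__(self) -> None:
        if len(set(self.wavelengths)) != 2:
            raise ValueError("wavelengths must be two distinct values")
        if abs(np.linalg.det(self.matrix())) < 1e-300:
            raise ValueError("extinction matrix is singular")

    def matrix(self) -> np.ndarray:
        """Return the 2x2 matrix with rows = wavelengths, cols = (oxy, deoxy)."""
        return np.array(
            [
                [self.eps_oxy[0], self.eps_deoxy[0]],
                [self.eps_oxy[1], self.eps_deoxy[1]],
            ]
        )

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix())


def default_extinction_table() -> ExtinctionTable:
    """The shipped 695/830 nm extinction table (cm^-1 uM^-1)."""
    return ExtinctionTable()
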