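"""Residual-structure metrics: fractional helicity from circular
dichroism and the heteronuclear NOE intensity ratio.

Fractional helicity is the position of the 222 nm mean residue
ellipticity between a random-coil baseline and a chain-length-corrected
full-helix baseline:

    FH = (theta_222 - theta_coil) / (theta_helix - theta_coil)

with the single-wavelength convention

    theta_helix(n, T) = -44000 * (1 - 3/n) + 250 * T[C]
    theta_coil(T)     = 2220 - 53 * T[C]

(deg cm^2 dmol^-1; n = number of residues).  The baseline constants are
configurable — published conventions differ, so FH values are
convention-relative and meaningful mainly as differences within one
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measurement import Measurement, as_measurement, ratio

__all__ = [
    "CDSpectrum",
    "FHResult",
    "HelixBaselines",
    "fractional_helicity",
    "delta_FH",
    "het_noe_ratio",
]


@dataclass(frozen=True)
class HelixBaselines:
    """Coefficients of the 222 nm helix/coil baselines."""

    helix_inf: float = -44000.0   # infinite-chain helix ellipticity
    helix_chain: float = 3.0      # finite-length correction, 1 - chain/n
    helix_T: float = 250.0        # per degree C
    coil_0: float = 2220.0
    coil_T: float = -53.0

    def theta_helix(self, n_residues: int, temperature_C: float) -> float:
        return self.helix_inf * (1.0 - self.helix_chain / n_residues) \
            + self.helix_T * temperature_C

    def theta_coil(self, temperature_C: float) -> float:
        return self.coil_0 + self.coil_T * temperature_C


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum in mean residue ellipticity units.

    wavelength_nm must cover 222 nm (within 1 nm) for the FH estimate;
    n_residues >= 2.
    """

    wavelength_nm: np.ndarray
    mre: np.ndarray               # deg cm^2 dmol^-1
    n_residues: int
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelength_nm.size != self.mre.size:
            raise ValueError("wavelength and mre must have equal length")
        if self.n_residues < 2:
            raise ValueError(f"n_residues must be >= 2, got {self.n_residues}")

    def theta_at(self, wavelength: float, tol: float = 1.0) -> float:
        """MRE at the grid point nearest ``wavelength``; grid points
        farther than ``tol`` nm are not interpolated."""
        i = int(np.argmin(np.abs(self.wavelength_nm - wavelength)))
        if abs(self.wavelength_nm[i] - wavelength) > tol:
            raise ValueError(
                f"no point within {tol} nm of {wavelength} nm "
                f"(nearest: {self.wavelength_nm[i]} nm)"
            )
        return float(self.mre[i])


@dataclass(frozen=True)
class FHResult:
    """Fractional helicity with the inputs that produced it."""

    FH: float
    theta_222: float
    theta_helix: float
    theta_coil: float
    flags: tuple[str, ...] = ()


def fractional_helicity(
    spectrum: CDSpectrum,
    baselines: HelixBaselines = HelixBaselines(),
) -> FHResult:
    """FH from the 222 nm signal between the coil and helix baselines.

    The raw value is soft-clipped to [-0.05, 1.05]; values outside
    [0, 1] are flagged rather than rejected (baseline conventions do
    not perfectly bracket every measured spectrum).
    """
    theta = spectrum.theta_at(222.0)
    th_h = baselines.theta_helix(spectrum.n_residues, spectrum.temperature_C)
    th_c = baselines.theta_coil(spectrum.temperature_C)
    raw = (theta - th_c) / (th_h - th_c)
    flags: tuple[str, ...] = ()
    if not 0.0 <= raw <= 1.0:
        flags = ("outside_unit_interval",)
    return FHResult(
        FH=float(np.clip(raw, -0.05, 1.05)),
        theta_222=theta, theta_helix=th_h, theta_coil=th_c, flags=flags,
    )


def delta_FH(ala: FHResult | float, gly: FHResult | float) -> float:
    """FH_Ala - FH_Gly: helicity lost on glycine substitution."""
    fa = ala.FH if isinstance(ala, FHResult) else float(ala)
    fg = gly.FH if isinstance(gly, FHResult) else float(gly)
    return fa - fg


def het_noe_ratio(I_sat, I_unsat) -> Measurement:
    """{1H}-15N heteronuclear NOE: the ratio of peak intensities with
    and without proton saturation, with propagated error."""
    I_sat, I_unsat = as_measurement(I_sat), as_measurement(I_unsat)
    if I_unsat.value == 0:
        raise ZeroDivisionError("unsaturated intensity is zero")
    if I_sat.value == 0:
        return Measurement(0.0, abs(I_sat.err / I_unsat.value))
    return ratio(I_sat, I_unsat)
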