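"""Analysis-wide configuration and physical constants.

All quantities are SI on disk and in memory (molar, seconds, kelvin,
kcal/mol); display conversions (nM, uM^-1 s^-1) happen only in report
layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 0.0019872

#: Default experiment temperature (25 degrees C) in kelvin.
T_DEFAULT = 298.15


@dataclass(frozen=True)
class AnalysisConfig:
    """Shared settings for fitting and free-energy conversions.

    Parameters
    ----------
    R : float
        Gas constant, kcal mol^-1 K^-1.
    T : float
        Absolute temperature in kelvin used for every RT conversion.
    denaturant_convention : str
        ``"log_linear"`` (default) fits free energies linearly in
        denaturant concentration, the standard m-value convention;
        ``"linear"`` fits the raw equilibrium/rate constants linearly
        against denaturant and reports gradients in native units.
    ftol, xtol : float
        Least-squares convergence tolerances passed to the optimizer.
    ddg_floor : float
        |ddG| (kcal/mol) below which a Phi value is flagged unreliable.
    slope_test_alpha : float
        Two-sided level for the competitor-independence slope test.
    """

    R: float = R_KCAL
    T: float = T_DEFAULT
    denaturant_convention: str = "log_linear"
    ftol: float = 1.49e-8
    xtol: float = 1.49e-8
    ddg_floor: float = 0.3
    slope_test_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.denaturant_convention not in ("log_linear", "linear"):
            raise ValueError(
                "denaturant_convention must be 'log_linear' or 'linear', "
                f"got {self.denaturant_convention!r}"
            )

    @property
    def RT(self) -> float:
        """R*T in kcal/mol."""
        return self.R * self.T

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
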