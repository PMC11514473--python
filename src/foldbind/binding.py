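"""DNA-binding kinetics: pseudo-first-order association and
out-competition dissociation.

Association of the dimeric protein with a labelled DNA target under
pseudo-first-order conditions (protein in >= 10-fold excess over DNA)
relaxes as a single exponential with observed rate

    k_obs = k_on * [dimer] + k_off.

k_on is the gradient of a weighted straight-line fit of k_obs against
dimer concentration.  k_off comes from out-competition: pre-formed
complex mixed with a saturating excess of unlabelled competitor decays
exponentially at a rate independent of competitor concentration, so the
per-concentration rates are averaged (inverse-variance).  The kinetic
dissociation constant is K_D = k_off/k_on with first-order error
propagation.

The module also carries the small utilities used to interpret the
numbers: ionic strength of the assay buffer, the Debye screening length,
and the 280 nm extinction coefficient from amino-acid composition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import lmfit
import statsmodels.api as sm

from .config import AnalysisConfig, DEFAULT_CONFIG
from .measurement import Measurement, as_measurement, ratio, weighted_mean
from .traces import RelaxationTrace

__all__ = [
    "PseudoFirstOrderPoint",
    "RateConstants",
    "SingleExponentialModel",
    "fit_single_exponential",
    "PseudoFirstOrderModel",
    "fit_kobs_line",
    "average_koff",
    "kinetic_KD",
    "BufferComposition",
    "IonSpecies",
    "IonizableSpecies",
    "ionic_strength",
    "debye_length",
    "extinction_coefficient",
    "CompetitorDependenceWarning",
    "MES_PKA_25C",
]


class CompetitorDependenceWarning(UserWarning):
    """Out-competition rates depend on competitor concentration."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PseudoFirstOrderPoint:
    """One observed rate at one dimer concentration."""

    dimer_conc: float            # molar
    k_obs: Measurement           # s^-1
    amplitude: Measurement = Measurement(0.0)
    offset: Measurement = Measurement(0.0)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dimer_conc <= 0:
            raise ValueError(f"dimer_conc must be positive, got {self.dimer_conc}")
        if self.k_obs.value <= 0:
            raise ValueError(f"k_obs must be positive, got {self.k_obs.value}")


@dataclass(frozen=True)
class RateConstants:
    """k_on, k_off and the kinetic K_D for one protein variant."""

    k_on: Measurement            # M^-1 s^-1
    k_off: Measurement           # s^-1
    K_D: Measurement             # molar
    label: str = ""

    @classmethod
    def from_rates(cls, k_on, k_off, label: str = "") -> "RateConstants":
        k_on, k_off = as_measurement(k_on), as_measurement(k_off)
        return cls(k_on=k_on, k_off=k_off, K_D=kinetic_KD(k_on, k_off), label=label)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "k_on_per_M_s": self.k_on.value, "k_on_err": self.k_on.err,
            "k_off_per_s": self.k_off.value, "k_off_err": self.k_off.err,
            "K_D_M": self.K_D.value, "K_D_err_M": self.K_D.err,
        }


# --------------------------------------------------------------------------
# single-exponential trace fit
# --------------------------------------------------------------------------


class SingleExponentialModel:
    """Single-exponential relaxation fit for association/dissociation
    traces: signal = offset + amplitude * (1 - exp(-k_obs * t)).

    A decaying trace is simply a negative fitted amplitude; the rise or
    decay direction is detected from the data for the starting values.
    Warns when the trace has fewer than 10 points or spans fewer than 3
    relaxation times.
    """

    def __init__(self, trace: RelaxationTrace, config: AnalysisConfig = DEFAULT_CONFIG):
        self.trace = trace
        self.config = config

    def fit(self) -> PseudoFirstOrderPoint:
        t, s = self.trace.time, self.trace.signal
        n_tail = max(3, len(s) // 20)
        s_inf = float(np.mean(s[-n_tail:]))
        s_0 = float(s[0])
        amp0 = s_inf - s_0
        if amp0 == 0.0:
            amp0 = 1e-9 * (abs(s_inf) + 1.0)
        resid = np.abs(s - s_inf)
        idx = np.nonzero(resid <= abs(amp0) / math.e)[0]
        t_e = t[idx[0]] if idx.size and idx[0] > 0 else t[max(1, len(t) // 3)]
        k0 = 1.0 / max(t_e, 1e-12)

        def model(p, tt):
            return p["offset"] + p["amplitude"] * (1.0 - np.exp(-p["k_obs"] * tt))

        p = lmfit.Parameters()
        p.add("k_obs", value=k0, min=1e-12)
        p.add("amplitude", value=amp0)
        p.add("offset", value=s_0)
        out = lmfit.minimize(
            lambda p: model(p, t) - s, p, method="leastsq",
            ftol=self.config.ftol, xtol=self.config.xtol,
        )
        if not out.success:
            raise RuntimeError(f"single-exponential fit did not converge: {out.message}")

        flags: list[str] = []
        k = out.params["k_obs"]
        if t[-1] * k.value < 3.0:
            flags.append("short_trace")
            warnings.warn(
                f"trace spans only {t[-1] * k.value:.2f} relaxation times (< 3)",
                UserWarning, stacklevel=2,
            )
        if k.value <= 2e-12:
            flags.append("rate_at_bound")
            warnings.warn("fitted rate at parameter bound", UserWarning, stacklevel=2)

        def m(name):
            par = out.params[name]
            return Measurement(float(par.value), float(par.stderr) if par.stderr else 0.0)

        dimer = self.trace.meta.get("dimer_conc_M")
        if dimer is not None and np.isfinite(dimer):
            return PseudoFirstOrderPoint(
                dimer_conc=float(dimer),
                k_obs=m("k_obs"), amplitude=m("amplitude"), offset=m("offset"),
                flags=tuple(flags),
            )
        return _PointNoConc(
            k_obs=m("k_obs"), amplitude=m("amplitude"), offset=m("offset"),
            flags=tuple(flags),
        )


@dataclass(frozen=True)
class _PointNoConc:
    """Exponential-fit result for a trace with no dimer concentration
    attached (e.g. an out-competition trace)."""

    k_obs: Measurement
    amplitude: Measurement
    offset: Measurement
    flags: tuple[str, ...] = ()


def fit_single_exponential(
    trace: RelaxationTrace, config: AnalysisConfig = DEFAULT_CONFIG
):
    """Fit one trace; returns the observed rate with amplitude/offset.

    If the trace metadata carries ``dimer_conc_M`` the result is a
    :class:`PseudoFirstOrderPoint` ready for the k_obs line.
    """
    if len(trace) < 10:
        warnings.warn("fewer than 10 points in trace", UserWarning, stacklevel=2)
    return SingleExponentialModel(trace, config).fit()


# --------------------------------------------------------------------------
# k_obs line and k_off averaging
# --------------------------------------------------------------------------


class PseudoFirstOrderModel:
    """Weighted straight line of k_obs against dimer concentration.

    The gradient is the association rate constant k_on.  The intercept
    is reported for diagnostics only — the dissociation rate is
    estimated from out-competition, not from this intercept.
    """

    def __init__(self, points: Sequence[PseudoFirstOrderPoint]):
        conc = np.array([p.dimer_conc for p in points], dtype=float)
        if np.unique(conc).size < 3:
            raise ValueError(
                f"need >= 3 distinct dimer concentrations, got {np.unique(conc).size}"
            )
        self.points = list(points)
        self.conc = conc
        self.k_obs = np.array([p.k_obs.value for p in points])
        self.k_err = np.array([p.k_obs.err for p in points])

    def fit(self) -> "PseudoFirstOrderResults":
        X = sm.add_constant(self.conc)
        if np.all(self.k_err > 0):
            res = sm.WLS(self.k_obs, X, weights=1.0 / self.k_err**2).fit()
        else:
            res = sm.OLS(self.k_obs, X).fit()
        return PseudoFirstOrderResults(
            model=self,
            k_on=Measurement(float(res.params[1]), float(res.bse[1])),
            intercept=Measurement(float(res.params[0]), float(res.bse[0])),
            diagnostics={"r_squared": float(res.rsquared), "n": len(self.conc)},
        )


@dataclass
class PseudoFirstOrderResults:
    model: PseudoFirstOrderModel
    k_on: Measurement
    intercept: Measurement
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def plot(self, ax=None):
        """k_obs against dimer concentration with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        ax.errorbar(m.conc * 1e9, m.k_obs, yerr=m.k_err, fmt="o", label="observed")
        xs = np.linspace(0, m.conc.max() * 1.05, 50)
        ax.plot(xs * 1e9, self.intercept.value + self.k_on.value * xs, "-", label="fit")
        ax.set_xlabel("dimer concentration (nM)")
        ax.set_ylabel(r"$k_{obs}$ (s$^{-1}$)")
        ax.legend()
        return ax

    def summary(self) -> str:
        return "\n".join([
            "Pseudo-first-order association analysis",
            "=" * 46,
            f"n concentrations    {self.diagnostics.get('n')}",
            f"k_on (M^-1 s^-1)    {self.k_on:.4g}",
            f"intercept (s^-1)    {self.intercept:.4g}   [diagnostic only]",
            f"R^2                 {self.diagnostics.get('r_squared'):.6f}",
        ])


def fit_kobs_line(points: Sequence[PseudoFirstOrderPoint]) -> PseudoFirstOrderResults:
    """Convenience wrapper: ``PseudoFirstOrderModel(points).fit()``."""
    return PseudoFirstOrderModel(points).fit()


def average_koff(
    points: Sequence[tuple[float, Measurement]],
    alpha: float | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Measurement:
    """Inverse-variance weighted mean of out-competition rates.

    ``points`` are (competitor_conc, k_obs +/- err) pairs from >= 2
    competitor concentrations.  Validity of the averaging rests on the
    rates being independent of competitor concentration: a straight-line
    regression of k_obs on competitor is run and a slope significantly
    different from zero (two-sided, level ``alpha``) raises
    :class:`CompetitorDependenceWarning` — a warning, not a rejection.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 competitor concentrations")
    alpha = config.slope_test_alpha if alpha is None else alpha
    conc = np.array([c for c, _ in points], dtype=float)
    rates = [as_measurement(k) for _, k in points]
    if np.unique(conc).size >= 2:
        y = np.array([m.value for m in rates])
        res = sm.OLS(y, sm.add_constant(conc)).fit()
        p_slope = float(res.pvalues[1])
        if np.isfinite(p_slope) and p_slope < alpha:
            warnings.warn(
                f"observed dissociation rates depend on competitor concentration "
                f"(slope p = {p_slope:.3g} < {alpha}); averaging may be invalid",
                CompetitorDependenceWarning, stacklevel=2,
            )
    return weighted_mean(rates)


def kinetic_KD(k_on, k_off) -> Measurement:
    """K_D = k_off / k_on (molar) with first-order error propagation.

    k_off = 0 is allowed as a boundary (K_D = 0); negative inputs and
    k_on <= 0 are rejected.
    """
    k_on, k_off = as_measurement(k_on), as_measurement(k_off)
    if k_on.value <= 0:
        raise ValueError(f"k_on must be positive, got {k_on.value}")
    if k_off.value < 0:
        raise ValueError(f"k_off must be non-negative, got {k_off.value}")
    if k_off.value == 0:
        warnings.warn("k_off = 0: K_D at boundary", UserWarning, stacklevel=2)
        return Measurement(0.0, k_off.err / k_on.value)
    return ratio(k_off, k_on)


# --------------------------------------------------------------------------
# buffer utilities
# --------------------------------------------------------------------------

#: MES pKa at 25 C assumed for the ionic-strength computation.
MES_PKA_25C = 6.27


@dataclass(frozen=True)
class IonSpecies:
    """A fully dissociating salt: ``ions`` lists (charge, stoichiometry)
    per formula unit, e.g. NaCl -> [(+1, 1), (-1, 1)];
    MgCl2 -> [(+2, 1), (-1, 2)].  Nonionic species use ions=()."""

    name: str
    conc: float                        # molar, formula units
    ions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")


@dataclass(frozen=True)
class IonizableSpecies:
    """A buffer species split between acid and base forms by
    Henderson-Hasselbalch at the buffer pH.

    ``acid_charge``/``base_charge`` are the net charges of the
    protonated and deprotonated forms (MES: 0 / -1).  The counterion
    introduced by titration (e.g. Na+ from NaOH for an anionic base
    form) is included automatically to balance the charge.
    """

    name: str
    conc: float
    pKa: float | None = None
    acid_charge: int = 0
    base_charge: int = -1

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")

    def fractions(self, pH: float) -> tuple[float, float]:
        """(acid, base) fractions at pH."""
        if self.pKa is None:
            raise ValueError(f"{self.name}: pKa required for ionizable species")
        f_base = 1.0 / (1.0 + 10.0 ** (self.pKa - pH))
        return 1.0 - f_base, f_base


@dataclass(frozen=True)
class BufferComposition:
    """Assay buffer: a list of species, pH and temperature (C)."""

    species: tuple
    pH: float
    temperature_C: float = 25.0


def ionic_strength(buffer: BufferComposition) -> float:
    """Ionic strength I = 1/2 * sum(c_i * z_i^2), molar.

    Ionizable buffer species are split by Henderson-Hasselbalch at the
    stated pH; their titration counterions are included.  Nonionic
    species (detergents and the like) contribute zero.  An ionizable
    species without a pKa is an error.
    """
    I = 0.0
    for sp in buffer.species:
        if isinstance(sp, IonizableSpecies):
            f_acid, f_base = sp.fractions(buffer.pH)
            for frac, z in ((f_acid, sp.acid_charge), (f_base, sp.base_charge)):
                c = sp.conc * frac
                I += c * z * z
                I += c * abs(z)  # monovalent counterion balancing this form
        elif isinstance(sp, IonSpecies):
            for z, nu in sp.ions:
                I += sp.conc * nu * z * z
        else:
            raise TypeError(f"unknown species type: {sp!r}")
    return 0.5 * I


def biophysical_buffer() -> BufferComposition:
    """The assay buffer: 10 mM MES pH 6.5, 150 mM NaCl, 10 mM MgCl2,
    0.05% Tween-20 (nonionic)."""
    return BufferComposition(
        species=(
            IonizableSpecies("MES", 0.010, pKa=MES_PKA_25C, acid_charge=0, base_charge=-1),
            IonSpecies("NaCl", 0.150, ions=((1, 1), (-1, 1))),
            IonSpecies("MgCl2", 0.010, ions=((2, 1), (-1, 2))),
            IonSpecies("Tween-20", 0.0005, ions=()),
        ),
        pH=6.5,
        temperature_C=25.0,
    )


def _water_permittivity(T: float) -> float:
    """Relative permittivity of water at temperature T (kelvin);
    CRC polynomial in Celsius, valid 0-100 C."""
    t = T - 273.15
    return 87.740 - 0.40008 * t + 9.398e-4 * t**2 - 1.410e-6 * t**3


def debye_length(I: float, T: float = 298.15) -> float:
    """Debye screening length in nanometres.

    kappa^-1 = sqrt(eps_r*eps0*kB*T / (2*NA*e^2*I')), I' in mol/m^3.
    At 298.15 K this reduces to ~0.304/sqrt(I[M]) nm.
    """
    if I <= 0:
        raise ValueError(f"ionic strength must be positive, got {I}")
    eps0 = 8.8541878128e-12      # F/m
    kB = 1.380649e-23            # J/K
    NA = 6.02214076e23           # 1/mol
    e = 1.602176634e-19          # C
    eps_r = _water_permittivity(T)
    I_m3 = I * 1000.0
    lam = math.sqrt(eps_r * eps0 * kB * T / (2.0 * NA * e * e * I_m3))
    return lam * 1e9


_EXT_TRP = 5500.0   # M^-1 cm^-1 at 280 nm
_EXT_TYR = 1490.0
_EXT_CYSTINE = 125.0
_AA = set("ACDEFGHIKLMNPQRSTVWY")


def extinction_coefficient(sequence: str, oxidized_cys: bool = True) -> float:
    """Composition-based 280 nm molar extinction coefficient,
    eps = 5500*nW + 1490*nY + 125*n_cystine (M^-1 cm^-1).

    ``oxidized_cys=True`` counts cystines as floor(nC/2); reduced
    cysteines contribute nothing.
    """
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    n_cystine = (seq.count("C") // 2) if oxidized_cys else 0
    return _EXT_TRP * seq.count("W") + _EXT_TYR * seq.count("Y") + _EXT_CYSTINE * n_cystine
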