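"""Two-state reversible homodimerization relaxation kinetics.

The scheme is 2P <=> P2 with dissociation equilibrium constant
L = [P]^2/[P2] (molar) and folding rate constant k1 (M^-1 s^-1), where
monomer is consumed at rate k1*[P]^2 and regenerated at rate k1*L*[P2].
Starting from all monomer (refolding by rapid dilution from denaturant,
P0 = P_T) the monomer concentration follows the closed form

    [P](t) = ((L-2z)/4 - ((L+2z)/4) * N * exp(-k1*z*t))
             / (N * exp(-k1*z*t) - 1)

with z = sqrt(L^2/4 + 2*L*P_T) and
N = ((L-2z)/4 + P0) / ((L+2z)/4 + P0).  The observed fluorescence is
linear in monomer, F(t) = F0 + dF*[P](t).  The late-time approach to
equilibrium is exponential with rate k1*z.

Fitting a relaxation trace yields {L, k1, F0, dF} per condition; fitting
the urea dependence of L and k1 (free energies linear in denaturant)
yields the zero-urea constants and the equilibrium and kinetic m-values,
whose ratio places the transition state along the folding reaction
coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import lmfit
import statsmodels.api as sm

from .config import AnalysisConfig, DEFAULT_CONFIG
from .measurement import Measurement, ratio
from .traces import RelaxationTrace

__all__ = [
    "DimerModelParams",
    "monomer_concentration",
    "dimer_concentration",
    "model_fluorescence",
    "relaxation_rate",
    "DimerRelaxationModel",
    "DimerRelaxationResults",
    "fit_refolding_trace",
    "UreaDependenceModel",
    "UreaSeriesResult",
    "fit_urea_dependence",
    "UnidentifiableFitWarning",
]


class UnidentifiableFitWarning(UserWarning):
    """Raised when a relaxation fit cannot constrain its parameters."""


# --------------------------------------------------------------------------
# closed-form model
# --------------------------------------------------------------------------


def _z(L: float, P_T: float) -> float:
    return float(np.sqrt(L * L / 4.0 + 2.0 * L * P_T))


def _N(L: float, P_T: float, P0: float) -> float:
    z = _z(L, P_T)
    return ((L - 2.0 * z) / 4.0 + P0) / ((L + 2.0 * z) / 4.0 + P0)


@dataclass(frozen=True)
class DimerModelParams:
    """Parameters of the two-state dimerization relaxation model.

    L : molar, homodimer dissociation equilibrium constant.
    k1 : M^-1 s^-1, folding (association) rate constant.
    F0 : signal offset; dF : signal change per molar monomer.
    P0 : initial monomer concentration; None means P0 = P_T
         (the refolding initial condition: all monomer).
    Errors (L_err, ...) are standard errors from the fit, 0 if exact.
    """

    L: float
    k1: float
    F0: float = 0.0
    dF: float = 1.0
    P0: float | None = None
    L_err: float = 0.0
    k1_err: float = 0.0
    F0_err: float = 0.0
    dF_err: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError(f"L must be positive, got {self.L}")
        if self.k1 <= 0:
            raise ValueError(f"k1 must be positive, got {self.k1}")

    def z(self, P_T: float) -> float:
        """z = sqrt(L^2/4 + 2*L*P_T); z > L/2 whenever P_T > 0."""
        return _z(self.L, P_T)

    def N(self, P_T: float) -> float:
        """Integration constant; lies in (0, 1) for P0 = P_T > 0."""
        return _N(self.L, P_T, self.P0 if self.P0 is not None else P_T)

    def equilibrium_monomer(self, P_T: float) -> float:
        """[P] at equilibrium, (2z - L)/4; satisfies [P]^2/[P2] = L."""
        return (2.0 * self.z(P_T) - self.L) / 4.0


def monomer_concentration(t, params: DimerModelParams, P_T: float) -> np.ndarray:
    """Monomer concentration [P](t) of the relaxation, molar.

    Decreases monotonically from P0 (= P_T by default) to the
    equilibrium root (2z - L)/4.  ``t`` may be scalar or array; negative
    times are rejected.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if P_T <= 0:
        raise ValueError(f"P_T must be positive, got {P_T}")
    L = params.L
    z = params.z(P_T)
    a = (L - 2.0 * z) / 4.0
    b = (L + 2.0 * z) / 4.0
    N = params.N(P_T)
    E = N * np.exp(-params.k1 * z * t)
    # E < 1 for t >= 0 since 0 < N < 1, so the denominator never vanishes
    return (a - b * E) / (E - 1.0)


def dimer_concentration(t, params: DimerModelParams, P_T: float) -> np.ndarray:
    """[P2](t) = (P_T - [P](t)) / 2 by mass conservation."""
    return (P_T - monomer_concentration(t, params, P_T)) / 2.0


def model_fluorescence(t, params: DimerModelParams, P_T: float) -> np.ndarray:
    """F(t) = F0 + dF * [P](t)."""
    return params.F0 + params.dF * monomer_concentration(t, params, P_T)


def relaxation_rate(params: DimerModelParams, P_T: float) -> float:
    """Late-time exponential relaxation rate k1*z, s^-1."""
    return params.k1 * params.z(P_T)


# --------------------------------------------------------------------------
# per-trace fit
# --------------------------------------------------------------------------


class DimerRelaxationModel:
    """Nonlinear least-squares model for one refolding relaxation trace.

    Fits {L, k1, F0, dF} of the closed-form two-state dimerization
    relaxation to the observed fluorescence.  L and k1 are optimized in
    natural-log space (they span orders of magnitude across denaturant
    conditions); reported errors are delta-method standard errors on the
    natural scale.

    Parameters
    ----------
    trace : RelaxationTrace
        Must carry ``protein_total``.
    config : AnalysisConfig, optional
    """

    def __init__(self, trace: RelaxationTrace, config: AnalysisConfig = DEFAULT_CONFIG):
        if trace.protein_total is None:
            raise ValueError("trace.protein_total is required for a dimerization fit")
        self.trace = trace
        self.config = config

    # -- self-start ---------------------------------------------------------

    def _start_values(self) -> list[dict[str, float]]:
        """Heuristic starts: F0 from the tail, dF from the jump, the rate
        from a single-exponential pre-fit, L from the amplitude-implied
        equilibrium monomer fraction.  Several candidate equilibrium
        fractions are tried and the best fit kept."""
        t, s = self.trace.time, self.trace.signal
        P_T = self.trace.protein_total
        n_tail = max(3, len(s) // 20)
        s_inf = float(np.mean(s[-n_tail:]))
        s_0 = float(np.mean(s[: max(3, len(s) // 100)]))
        amp = s_0 - s_inf
        if amp == 0.0:
            amp = 1e-12 * (abs(s_inf) + 1.0)
        # crude rate: time to decay to 1/e of the amplitude
        resid = np.abs(s - s_inf)
        idx = np.nonzero(resid <= abs(amp) / np.e)[0]
        t_e = t[idx[0]] if idx.size and idx[0] > 0 else t[len(t) // 3]
        rate = 1.0 / max(t_e, t[1] if t[0] == 0 else t[0])
        starts = []
        for f_eq in (0.2, 0.5, 0.8):  # fraction of monomer converted at equilibrium
            dF = amp / (f_eq * P_T)
            P_inf = (1.0 - f_eq) * P_T
            L = 2.0 * P_inf**2 / (P_T - P_inf)
            z = _z(L, P_T)
            starts.append(
                {"L": L, "k1": rate / z, "F0": s_inf - dF * P_inf, "dF": dF}
            )
        return starts

    # -- fit ----------------------------------------------------------------

    def fit(self, init: DimerModelParams | None = None) -> "DimerRelaxationResults":
        """Fit the trace; returns results with standard errors and
        convergence diagnostics.

        Raises ``RuntimeError`` on non-convergence.  Emits
        ``UnidentifiableFitWarning`` (and sets the flag on the results)
        when the covariance cannot constrain L and k1 — e.g. a flat
        trace with no relaxation amplitude.
        """
        t, s = self.trace.time, self.trace.signal
        P_T = float(self.trace.protein_total)

        def residual(p):
            params = DimerModelParams(
                L=np.exp(p["lnL"].value),
                k1=np.exp(p["lnk1"].value),
                F0=p["F0"].value,
                dF=p["dF"].value,
            )
            return model_fluorescence(t, params, P_T) - s

        starts = (
            [{"L": init.L, "k1": init.k1, "F0": init.F0, "dF": init.dF}]
            if init is not None
            else self._start_values()
        )
        best = None
        for s0 in starts:
            p = lmfit.Parameters()
            # log parametrization: positivity is automatic, no bounds needed
            p.add("lnL", value=float(np.log(s0["L"])))
            p.add("lnk1", value=float(np.log(max(s0["k1"], 1e-6))))
            p.add("F0", value=s0["F0"])
            p.add("dF", value=s0["dF"])
            for ftol, xtol in ((self.config.ftol, self.config.xtol), (1e-7, 1e-7)):
                try:
                    out = lmfit.minimize(
                        residual, p, method="leastsq", ftol=ftol, xtol=xtol,
                    )
                except Exception:
                    continue
                if out.success and (best is None or out.chisqr < best.chisqr):
                    best = out
                if out.success:
                    break
        if best is None:
            raise RuntimeError(
                "dimerization relaxation fit did not converge from any start"
            )

        flags: list[str] = []
        pars = best.params
        L = float(np.exp(pars["lnL"].value))
        k1 = float(np.exp(pars["lnk1"].value))
        errs = {}
        for name, scale in (("lnL", L), ("lnk1", k1), ("F0", 1.0), ("dF", 1.0)):
            se = pars[name].stderr
            errs[name] = (se * scale) if se is not None else np.nan
        if best.covar is None or any(not np.isfinite(errs[n]) for n in ("lnL", "lnk1")):
            flags.append("unidentifiable")
        elif pars["lnL"].stderr is not None and pars["lnL"].stderr > np.log(10.0):
            # L constrained to worse than a factor of 10
            flags.append("unidentifiable")
        else:
            # no relaxation amplitude above the residual noise: L and k1
            # ride on nothing (flat trace / dF ~ 0)
            fitted = DimerModelParams(L=L, k1=k1, F0=pars["F0"].value, dF=pars["dF"].value)
            amp = abs(fitted.dF) * (P_T - fitted.equilibrium_monomer(P_T))
            noise_sd = float(np.std(residual(pars))) if len(t) > 4 else 0.0
            if amp < 5.0 * noise_sd or amp == 0.0:
                flags.append("unidentifiable")
        if flags:
            warnings.warn(
                "relaxation fit cannot constrain L and k1 (flat or degenerate trace)",
                UnidentifiableFitWarning,
                stacklevel=2,
            )
        params = DimerModelParams(
            L=L, k1=k1, F0=float(pars["F0"].value), dF=float(pars["dF"].value),
            L_err=float(errs["lnL"]) if np.isfinite(errs["lnL"]) else 0.0,
            k1_err=float(errs["lnk1"]) if np.isfinite(errs["lnk1"]) else 0.0,
            F0_err=float(errs["F0"]) if np.isfinite(errs["F0"]) else 0.0,
            dF_err=float(errs["dF"]) if np.isfinite(errs["dF"]) else 0.0,
        )
        return DimerRelaxationResults(
            model=self, params=params, flags=flags, lmfit_result=best
        )


@dataclass
class DimerRelaxationResults:
    """Estimates from one relaxation-trace fit."""

    model: DimerRelaxationModel
    params: DimerModelParams
    flags: list[str]
    lmfit_result: Any

    @property
    def L(self) -> Measurement:
        return Measurement(self.params.L, self.params.L_err)

    @property
    def k1(self) -> Measurement:
        return Measurement(self.params.k1, self.params.k1_err)

    @property
    def redchi(self) -> float:
        return float(self.lmfit_result.redchi)

    def fittedvalues(self) -> np.ndarray:
        return model_fluorescence(
            self.model.trace.time, self.params, self.model.trace.protein_total
        )

    def resid(self) -> np.ndarray:
        return self.model.trace.signal - self.fittedvalues()

    def plot(self, ax=None):
        """Data, fitted curve and residuals on a log time axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tr = self.model.trace
        ax.plot(tr.time, tr.signal, ".", ms=2, alpha=0.5, label="data")
        ax.plot(tr.time, self.fittedvalues(), "-", lw=1.5, label="fit")
        ax.set_xscale("symlog", linthresh=max(tr.time[1], 1e-6))
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (a.u.)")
        ax.legend()
        return ax

    def summary(self) -> str:
        tr = self.model.trace
        lines = [
            "Two-state dimerization relaxation fit",
            "=" * 46,
            f"n points            {len(tr)}",
            f"P_T (M)             {tr.protein_total:.4g}",
            f"urea (M)            {tr.urea if tr.urea is not None else 'n/a'}",
            f"L  (M)              {self.L:.4g}",
            f"k1 (M^-1 s^-1)      {self.k1:.4g}",
            f"F0                  {Measurement(self.params.F0, self.params.F0_err):.4g}",
            f"dF (per M)          {Measurement(self.params.dF, self.params.dF_err):.4g}",
            f"relaxation k1*z     {relaxation_rate(self.params, tr.protein_total):.4g} s^-1",
            f"reduced chi^2       {self.redchi:.4g}",
        ]
        if self.flags:
            lines.append(f"flags               {', '.join(self.flags)}")
        return "\n".join(lines)


def fit_refolding_trace(
    trace: RelaxationTrace,
    init: DimerModelParams | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> DimerRelaxationResults:
    """Convenience wrapper: ``DimerRelaxationModel(trace, config).fit(init)``."""
    return DimerRelaxationModel(trace, config).fit(init)


# --------------------------------------------------------------------------
# urea dependence
# --------------------------------------------------------------------------


@dataclass
class UreaSeriesResult:
    """Zero-denaturant extrapolation of the dimerization parameters.

    Under the default log-linear convention the free energies
    dG_eq = -RT ln L and dG_kin = RT ln k1 are fitted linearly against
    urea; intercepts give L0 and k1_0, gradient magnitudes give the
    equilibrium and kinetic m-values (kcal mol^-1 M^-1) and
    m_ratio = m_kin/m_eq locates the transition state.  Under the
    ``linear`` convention L and k1 are fitted directly and the gradients
    stay in native units (M per M urea; M^-1 s^-1 per M urea).
    """

    L0: Measurement
    m_eq: Measurement
    k1_0: Measurement
    m_kin: Measurement
    m_ratio: Measurement | None
    convention: str
    n_points: int
    flags: list[str] = field(default_factory=list)
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> str:
        unit_m = "kcal/mol/M" if self.convention == "log_linear" else "native/M"
        lines = [
            "Urea dependence of homodimerization",
            "=" * 46,
            f"convention          {self.convention}",
            f"n points            {self.n_points}",
            f"L0  (M)             {self.L0:.4g}",
            f"m_eq ({unit_m})   {self.m_eq:.4g}",
            f"k1_0 (M^-1 s^-1)    {self.k1_0:.4g}",
            f"m_kin ({unit_m})  {self.m_kin:.4g}",
        ]
        if self.m_ratio is not None:
            lines.append(f"m_kin/m_eq          {self.m_ratio:.4g}")
        if self.flags:
            lines.append(f"flags               {', '.join(self.flags)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "L0_M": self.L0.value, "L0_err_M": self.L0.err,
            "m_eq": self.m_eq.value, "m_eq_err": self.m_eq.err,
            "k1_0_per_M_s": self.k1_0.value, "k1_0_err_per_M_s": self.k1_0.err,
            "m_kin": self.m_kin.value, "m_kin_err": self.m_kin.err,
            "convention": self.convention,
            "n_points": self.n_points,
            "flags": self.flags,
        }
        if self.m_ratio is not None:
            d["m_ratio"] = self.m_ratio.value
            d["m_ratio_err"] = self.m_ratio.err
        return d


class UreaDependenceModel:
    """Weighted straight-line model of the denaturant dependence.

    Built from (urea, per-trace fit) pairs; replicate protein
    concentrations at the same urea are simply pooled as extra points.
    Weights are inverse-variance from the per-trace standard errors,
    with an unweighted fallback when any error is missing or zero.
    """

    def __init__(
        self,
        series: Sequence[tuple[float, DimerRelaxationResults | DimerModelParams]],
        config: AnalysisConfig = DEFAULT_CONFIG,
    ):
        if len(series) < 3:
            raise ValueError(f"need >= 3 urea points, got {len(series)}")
        urea = np.array([u for u, _ in series], dtype=float)
        if np.unique(urea).size < 3:
            raise ValueError("need >= 3 distinct urea concentrations")
        self.urea = urea
        self.L = np.empty(len(series))
        self.L_err = np.empty(len(series))
        self.k1 = np.empty(len(series))
        self.k1_err = np.empty(len(series))
        for i, (_, r) in enumerate(series):
            p = r.params if isinstance(r, DimerRelaxationResults) else r
            self.L[i], self.L_err[i] = p.L, p.L_err
            self.k1[i], self.k1_err[i] = p.k1, p.k1_err
        self.config = config

    @staticmethod
    def _wls(x, y, yerr) -> tuple[Measurement, Measurement, dict]:
        X = sm.add_constant(x)
        if np.all(np.isfinite(yerr)) and np.all(yerr > 0):
            fit = sm.WLS(y, X, weights=1.0 / yerr**2).fit()
        else:
            fit = sm.OLS(y, X).fit()
        (b0, b1), (s0, s1) = fit.params, fit.bse
        diag = {"r_squared": float(fit.rsquared), "df_resid": int(fit.df_resid)}
        return Measurement(float(b0), float(s0)), Measurement(float(b1), float(s1)), diag

    def fit(self) -> UreaSeriesResult:
        cfg = self.config
        flags: list[str] = []
        if cfg.denaturant_convention == "log_linear":
            RT = cfg.RT
            dG = -RT * np.log(self.L)           # dimer stability, kcal/mol
            dG_err = RT * self.L_err / self.L
            icpt, slope, diag_eq = self._wls(self.urea, dG, dG_err)
            # destabilization with urea: dG falls, so the gradient is negative
            if slope.value > 0:
                flags.append("m_eq_direction")
            L0 = Measurement(
                float(np.exp(-icpt.value / RT)),
                float(np.exp(-icpt.value / RT)) * icpt.err / RT,
            )
            m_eq = Measurement(abs(slope.value), slope.err)

            y = RT * np.log(self.k1)
            y_err = RT * self.k1_err / self.k1
            icpt_k, slope_k, diag_kin = self._wls(self.urea, y, y_err)
            if slope_k.value > 0:
                flags.append("m_kin_direction")
            k1_0 = Measurement(
                float(np.exp(icpt_k.value / RT)),
                float(np.exp(icpt_k.value / RT)) * icpt_k.err / RT,
            )
            m_kin = Measurement(abs(slope_k.value), slope_k.err)
        else:
            L0, slope, diag_eq = self._wls(self.urea, self.L, self.L_err)
            m_eq = Measurement(abs(slope.value), slope.err)
            k1_0, slope_k, diag_kin = self._wls(self.urea, self.k1, self.k1_err)
            m_kin = Measurement(abs(slope_k.value), slope_k.err)

        no_spread = (
            float(np.ptp(np.log(self.L))) < 1e-6
            if cfg.denaturant_convention == "log_linear"
            else float(np.ptp(self.L)) == 0.0
        )
        if no_spread or m_eq.value == 0 or (m_eq.err > 0 and m_eq.value < 2 * m_eq.err):
            flags.append("m_eq_consistent_with_zero")
        m_ratio = None
        if m_eq.value > 0:
            m_ratio = ratio(m_kin, m_eq)
            if not (0.0 <= m_ratio.value <= 1.0):
                flags.append("m_ratio_outside_unit_interval")
        else:
            flags.append("m_ratio_undefined")
        return UreaSeriesResult(
            L0=L0, m_eq=m_eq, k1_0=k1_0, m_kin=m_kin, m_ratio=m_ratio,
            convention=cfg.denaturant_convention, n_points=len(self.urea),
            flags=flags, diagnostics={"eq": diag_eq, "kin": diag_kin},
        )


def fit_urea_dependence(
    series: Sequence[tuple[float, DimerRelaxationResults | DimerModelParams]],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> UreaSeriesResult:
    """Convenience wrapper: ``UreaDependenceModel(series, config).fit()``."""
    return UreaDependenceModel(series, config).fit()
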