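"""Transition-state inference over an Ala/Gly mutant panel.

Phi-value analysis compares a mutation's effect on the association
barrier with its effect on overall binding stability.  With the alanine
mutant as pseudo-wild-type and the glycine mutant as the perturbation,

    Phi = ln(kon_Ala / kon_Gly) / ln(KD_Gly / KD_Ala),

Phi ~ 0 meaning the mutated position is unstructured at the transition
state and Phi ~ 1 meaning fully structured.  The panel-level analogue is
the Leffler alpha, the gradient of log10(kon) against log10(KD) across
all mutants; ddG = RT ln(KD_b/KD_a) supports double-mutant additivity
checks, and the koff ratio within each pair is correlated against the
pair's loss of fractional helicity (Pearson, two-tailed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .config import AnalysisConfig, DEFAULT_CONFIG
from .measurement import Measurement, as_measurement, log_ratio, ratio
from .binding import RateConstants

__all__ = [
    "MutantRecord",
    "PhiResult",
    "LFERResult",
    "phi_value",
    "ddG_binding",
    "additivity_check",
    "LefflerModel",
    "leffler_fit",
    "rate_ratio",
    "kon_from_koff_KD",
    "koff_ratio_vs_dFH",
]


@dataclass(frozen=True)
class MutantRecord:
    """One protein variant: kinetics plus fractional helicity.

    ``subst`` is one of Ala, Gly, AlaAla, GlyGly, WT; Ala/Gly records
    that form a comparison pair share ``pair_id``.
    """

    name: str
    subst: str
    pair_id: str
    rates: RateConstants
    position: int | None = None
    FH: Measurement | None = None
    source: str | None = None


@dataclass(frozen=True)
class PhiResult:
    """Phi for one Ala/Gly pair, with the inputs echoed."""

    pair_id: str
    phi: Measurement
    kon_ala: Measurement
    kon_gly: Measurement
    KD_ala: Measurement
    KD_gly: Measurement
    ddG: Measurement              # kcal/mol, Gly vs Ala
    flags: tuple[str, ...] = ()


def phi_value(
    kon_ala, kon_gly, KD_ala, KD_gly,
    pair_id: str = "",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> PhiResult:
    """Phi = ln(kon_Ala/kon_Gly) / ln(KD_Gly/KD_Ala) with first-order
    error propagation over the four inputs.

    KD_Gly = KD_Ala leaves Phi undefined and is an error; |ddG| below
    ``config.ddg_floor`` (kcal/mol) flags the result unreliable (the
    denominator is too small for a stable Phi).
    """
    kon_ala, kon_gly = as_measurement(kon_ala), as_measurement(kon_gly)
    KD_ala, KD_gly = as_measurement(KD_ala), as_measurement(KD_gly)
    for name, m in (("kon_ala", kon_ala), ("kon_gly", kon_gly),
                    ("KD_ala", KD_ala), ("KD_gly", KD_gly)):
        if m.value <= 0:
            raise ValueError(f"{name} must be positive, got {m.value}")
    if KD_gly.value == KD_ala.value:
        raise ValueError("KD_Gly equals KD_Ala: Phi undefined (zero denominator)")
    u = log_ratio(kon_ala, kon_gly)      # ln kon ratio +/- err
    v = log_ratio(KD_gly, KD_ala)        # ln KD ratio +/- err
    phi = u.value / v.value
    err = math.sqrt((u.err / v.value) ** 2 + (u.value * v.err / v.value**2) ** 2)
    ddG = Measurement(config.RT * v.value, config.RT * v.err)
    flags: tuple[str, ...] = ()
    if abs(ddG.value) < config.ddg_floor:
        flags = ("small_ddG_unreliable",)
        warnings.warn(
            f"|ddG| = {abs(ddG.value):.2f} kcal/mol below the reliability "
            f"floor ({config.ddg_floor}); Phi is numerically unstable",
            UserWarning, stacklevel=2,
        )
    return PhiResult(
        pair_id=pair_id, phi=Measurement(phi, err),
        kon_ala=kon_ala, kon_gly=kon_gly, KD_ala=KD_ala, KD_gly=KD_gly,
        ddG=ddG, flags=flags,
    )


def phi_from_records(ala: MutantRecord, gly: MutantRecord,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> PhiResult:
    """Phi for a matched Ala/Gly record pair."""
    if ala.pair_id != gly.pair_id:
        raise ValueError(f"records are not a pair: {ala.pair_id!r} vs {gly.pair_id!r}")
    return phi_value(
        ala.rates.k_on, gly.rates.k_on, ala.rates.K_D, gly.rates.K_D,
        pair_id=ala.pair_id, config=config,
    )


def ddG_binding(KD_a, KD_b, config: AnalysisConfig = DEFAULT_CONFIG) -> Measurement:
    """ddG = RT ln(KD_b / KD_a), kcal/mol, with propagated error.

    Positive when b binds more weakly than a; antisymmetric under
    swapping the arguments.
    """
    KD_a, KD_b = as_measurement(KD_a), as_measurement(KD_b)
    if KD_a.value <= 0 or KD_b.value <= 0:
        raise ValueError("KD values must be positive")
    lr = log_ratio(KD_b, KD_a)
    return Measurement(config.RT * lr.value, config.RT * lr.err)


def additivity_check(single_a, single_b, double, z: float = 2.0) -> dict:
    """Double-mutant additivity: deviation = ddG_double - (ddG_a + ddG_b).

    Returns {'deviation': Measurement, 'additive': bool}; additive when
    |deviation| < z * sigma_deviation.
    """
    a, b, d = map(as_measurement, (single_a, single_b, double))
    dev = d.value - (a.value + b.value)
    err = math.sqrt(a.err**2 + b.err**2 + d.err**2)
    additive = abs(dev) < z * err if err > 0 else dev == 0.0
    return {"deviation": Measurement(dev, err), "additive": bool(additive)}


# --------------------------------------------------------------------------
# Leffler LFER
# --------------------------------------------------------------------------


@dataclass
class LFERResult:
    """Leffler alpha from the panel-wide log-log fit.

    ``alpha`` is reported as the magnitude of the gradient, oriented so
    that alpha and Phi agree (alpha = -d log kon / d log KD); the raw
    signed slope is kept in ``slope_signed``.
    """

    alpha: Measurement
    slope_signed: Measurement
    intercept: Measurement
    n_used: int
    excluded: list[str] = field(default_factory=list)
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join([
            "Leffler linear free-energy relationship",
            "=" * 46,
            f"n mutants           {self.n_used}"
            + (f"   (excluded: {', '.join(self.excluded)})" if self.excluded else ""),
            f"alpha               {self.alpha:.4g}",
            f"signed slope        {self.slope_signed:.4g}",
            f"R^2                 {self.diagnostics.get('r_squared'):.4f}",
        ])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.value, "alpha_err": self.alpha.err,
            "slope_signed": self.slope_signed.value,
            "intercept_log10_kon": self.intercept.value,
            "n_used": self.n_used, "excluded": list(self.excluded),
            **{k: v for k, v in self.diagnostics.items()},
        }


class LefflerModel:
    """Weighted straight-line model of log10(kon) against log10(KD).

    Weights are inverse-variance in log space from the propagated rate
    errors (sigma_log10 = sigma/(k ln 10)); unweighted fallback when any
    error is missing.  Exclusions (e.g. a panel outlier identified by
    inspection) are caller-specified by mutant name, never automatic.
    """

    def __init__(
        self,
        panel: Sequence[MutantRecord],
        exclude: Sequence[str] = (),
    ):
        self.exclude = [str(x) for x in exclude]
        used = [r for r in panel if r.name not in self.exclude]
        if len(used) < 4:
            raise ValueError(f"need >= 4 non-excluded mutants, got {len(used)}")
        for r in used:
            if r.rates.k_on.value <= 0 or r.rates.K_D.value <= 0:
                raise ValueError(f"{r.name}: non-positive rate or KD")
        KD = np.array([r.rates.K_D.value for r in used])
        if np.allclose(KD, KD[0]):
            raise ValueError("all KD values identical: no spread for an LFER fit")
        self.records = used
        self.log_KD = np.log10(KD)
        self.log_kon = np.log10([r.rates.k_on.value for r in used])
        self.log_kon_err = np.array(
            [r.rates.k_on.err / (r.rates.k_on.value * math.log(10.0)) for r in used]
        )

    def fit(self) -> LFERResult:
        X = sm.add_constant(self.log_KD)
        if np.all(self.log_kon_err > 0):
            res = sm.WLS(self.log_kon, X, weights=1.0 / self.log_kon_err**2).fit()
        else:
            res = sm.OLS(self.log_kon, X).fit()
        slope = Measurement(float(res.params[1]), float(res.bse[1]))
        return LFERResult(
            alpha=Measurement(abs(slope.value), slope.err),
            slope_signed=slope,
            intercept=Measurement(float(res.params[0]), float(res.bse[0])),
            n_used=len(self.records),
            excluded=list(self.exclude),
            diagnostics={"r_squared": float(res.rsquared)},
        )


def leffler_fit(panel: Sequence[MutantRecord], exclude: Sequence[str] = ()) -> LFERResult:
    """Convenience wrapper: ``LefflerModel(panel, exclude).fit()``."""
    return LefflerModel(panel, exclude).fit()


# --------------------------------------------------------------------------
# ratios and the helicity correlation
# --------------------------------------------------------------------------


def rate_ratio(k_x, k_y) -> Measurement:
    """r = k_x/k_y with sigma_r = r*sqrt((sx/kx)^2 + (sy/ky)^2);
    inputs must be positive."""
    k_x, k_y = as_measurement(k_x), as_measurement(k_y)
    if k_x.value <= 0 or k_y.value <= 0:
        raise ValueError("rate_ratio requires positive rates")
    return ratio(k_x, k_y)


def kon_from_koff_KD(k_off, K_D) -> Measurement:
    """k_on = k_off / K_D with propagated error (for literature panels
    that report only k_off and K_D)."""
    k_off, K_D = as_measurement(k_off), as_measurement(K_D)
    if k_off.value <= 0 or K_D.value <= 0:
        raise ValueError("kon_from_koff_KD requires positive inputs")
    return ratio(k_off, K_D)


def koff_ratio_vs_dFH(
    panel: Sequence[MutantRecord],
    exclude: Sequence[str] = (),
) -> dict:
    """Pearson correlation of the within-pair koff ratio against the
    helicity difference.

    For every Ala/Gly pair (shared ``pair_id``, both with FH):
    x = FH_Ala - FH_Gly, y = koff_Gly/koff_Ala.  Returns
    {'pearson_r', 'p_two_tailed', 'n'}; the p-value comes from the
    t-distribution with n-2 degrees of freedom.  Excluded mutant names
    drop their pair before the correlation; n < 3 or constant x is an
    error.
    """
    excl = set(exclude)
    pairs: dict[str, dict[str, MutantRecord]] = {}
    for r in panel:
        if r.name in excl or r.subst not in ("Ala", "Gly"):
            continue
        pairs.setdefault(r.pair_id, {})[r.subst] = r
    x, y = [], []
    for pid, members in sorted(pairs.items()):
        if set(members) != {"Ala", "Gly"}:
            continue
        ala, gly = members["Ala"], members["Gly"]
        if ala.FH is None or gly.FH is None:
            continue
        x.append(ala.FH.value - gly.FH.value)
        y.append(gly.rates.k_off.value / ala.rates.k_off.value)
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs with FH, got {n}")
    x, y = np.asarray(x), np.asarray(y)
    if np.allclose(x, x[0]):
        raise ValueError("FH differences are constant: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "p_two_tailed": float(p), "n": n}
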