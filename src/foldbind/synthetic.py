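"""Synthetic stopped-flow data with known ground truth.

Replaces the instrument: generates (a) refolding relaxation traces
obeying the two-state dimerization model across urea and protein
concentrations, (b) pseudo-first-order association traces with
k_obs = k_on*[dimer] + k_off, (c) out-competition dissociation traces
whose rate is independent of competitor concentration, and (d) Ala/Gly
mutant panels with prescribed per-mutant ddG and Phi — all with seeded
Gaussian or lognormal measurement noise, so every downstream fit can be
tested against the generating truth.

Default parameter values are the wild-type study conditions: L0 = 11 nM,
k1_0 = 7.1e6 M^-1 s^-1, m_eq = 1.55 and m_kin = 0.71 kcal mol^-1 M^-1,
k_on = 6.7e9 M^-1 s^-1, k_off = 2.44 s^-1.  Under the log-linear
denaturant convention the condition-level constants are

    L(urea)  = L0  * exp(+m_eq  * urea / RT)     (destabilization)
    k1(urea) = k1_0 * exp(-m_kin * urea / RT)    (slower folding)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .measurement import Measurement
from .traces import RelaxationTrace
from .dimerization import DimerModelParams, model_fluorescence
from .binding import RateConstants
from .phi import MutantRecord

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "MutantPanel",
    "gen_refolding_trace",
    "gen_association_trace",
    "gen_dissociation_trace",
    "gen_refolding_series",
    "gen_association_series",
    "gen_dissociation_series",
    "gen_mutant_panel",
    "write_panel",
    "read_panel",
    "PROTEIN_CONCS",
    "UREA_GRID",
    "DIMER_CONCS",
    "COMPETITOR_CONCS",
]

#: Total-monomer concentrations of the refolding series (molar).
PROTEIN_CONCS: tuple[float, ...] = (2.2e-6, 4.5e-6, 9.1e-6)

#: Final urea concentrations of the refolding series (molar).  Chosen
#: within the denaturant range where the dimer is appreciably populated
#: at micromolar protein under the default ground truth (above ~3.5 M
#: the equilibrium dimerized fraction falls below a few percent and the
#: relaxation has no amplitude).
UREA_GRID: tuple[float, ...] = (1.0, 1.4, 1.8, 2.2, 2.6, 3.0)

#: Dimer concentrations for the association series (molar).
DIMER_CONCS: tuple[float, ...] = (50e-9, 60e-9, 70e-9, 80e-9, 90e-9, 100e-9)

#: Competitor DNA concentrations for the dissociation series (molar).
COMPETITOR_CONCS: tuple[float, ...] = (2e-6, 4e-6, 6e-6, 8e-6)

_TRACE_POINTS = 500
_TRACE_SPAN = 5.0      # relaxation times covered by a trace


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for a generator call.

    kind : ``gaussian_additive`` adds N(0, sigma * amplitude) to every
        point, where *amplitude* is the dynamic range of the noiseless
        trace (set ``relative=False`` for sigma in signal units);
        ``lognormal_multiplicative`` multiplies by exp(N(0, sigma)).
    sigma : noise magnitude (relative by default); sigma = 0 is exact.
    seed : integer; identical seed + parameters give bit-identical output.
    """

    kind: str = "gaussian_additive"
    sigma: float = 0.01
    seed: int = 0
    relative: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.kind not in ("gaussian_additive", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, latent: np.ndarray, amplitude: float, rng=None) -> np.ndarray:
        """Apply noise to a latent signal; ``amplitude`` scales relative
        Gaussian noise."""
        if self.sigma == 0:
            return latent.copy()
        rng = self.rng() if rng is None else rng
        if self.kind == "gaussian_additive":
            sd = self.sigma * abs(amplitude) if self.relative else self.sigma
            return latent + rng.normal(0.0, sd, size=latent.shape)
        return latent * np.exp(rng.normal(0.0, self.sigma, size=latent.shape))

    def with_seed(self, seed: int) -> "NoiseModel":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for the synthetic experiments.

    Defaults are the wild-type study conditions; all rate and affinity
    parameters must be positive.  F0/dF set the fluorescence scale of
    refolding traces (signal units; dF per molar monomer).
    """

    L0: float = 11e-9            # M
    k1_0: float = 7.1e6          # M^-1 s^-1
    m_eq: float = 1.55           # kcal mol^-1 M^-1
    m_kin: float = 0.71          # kcal mol^-1 M^-1
    k_on: float = 6.7e9          # M^-1 s^-1
    k_off: float = 2.44          # s^-1
    F0: float = 0.5
    dF: float = 1.0e6

    def __post_init__(self) -> None:
        for name in ("L0", "k1_0", "k_on", "k_off"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def at_urea(self, urea: float, config: AnalysisConfig = DEFAULT_CONFIG) -> tuple[float, float]:
        """(L, k1) at a urea concentration under the log-linear convention."""
        RT = config.RT
        return (
            self.L0 * float(np.exp(self.m_eq * urea / RT)),
            self.k1_0 * float(np.exp(-self.m_kin * urea / RT)),
        )

    def wt_rates(self, label: str = "WT") -> RateConstants:
        return RateConstants.from_rates(self.k_on, self.k_off, label=label)


def _log_grid(rate: float) -> np.ndarray:
    """t = 0 plus log-spaced points over _TRACE_SPAN relaxation times;
    resolves both the fast phase and the plateau."""
    tau = 1.0 / rate
    return np.concatenate([[0.0], np.geomspace(tau / 200.0, _TRACE_SPAN * tau, _TRACE_POINTS - 1)])


# --------------------------------------------------------------------------
# trace generators
# --------------------------------------------------------------------------


def gen_refolding_trace(
    truth: GroundTruth,
    P_T: float,
    urea: float,
    t_grid: np.ndarray | None = None,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> RelaxationTrace:
    """One refolding relaxation trace at (P_T, urea).

    The latent signal is F0 + dF*[P](t) for the two-state dimerization
    model with condition-level (L, k1) derived from (L0, m_eq) and
    (k1_0, m_kin); noise is added on top.  t_grid defaults to 500
    log-spaced points over 5 relaxation times (rate k1*z).
    """
    if P_T <= 0:
        raise ValueError(f"P_T must be positive, got {P_T}")
    L, k1 = truth.at_urea(urea, config)
    params = DimerModelParams(L=L, k1=k1, F0=truth.F0, dF=truth.dF)
    if t_grid is None:
        t_grid = _log_grid(k1 * params.z(P_T))
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
            raise ValueError("t_grid must be strictly increasing and start at 0")
    latent = model_fluorescence(t_grid, params, P_T)
    amplitude = abs(truth.dF) * (P_T - params.equilibrium_monomer(P_T))
    signal = noise.apply(latent, amplitude)
    return RelaxationTrace(
        time=t_grid, signal=signal, protein_total=P_T, urea=urea,
        meta={
            "kind": "refolding", "seed": noise.seed, "noise": noise.kind,
            "sigma": noise.sigma, "truth": truth, "L_at_urea": L, "k1_at_urea": k1,
        },
    )


def gen_association_trace(
    k_on: float,
    k_off: float,
    dimer_conc: float,
    t_grid: np.ndarray | None = None,
    amplitude: float = 1.0,
    offset: float = 0.0,
    noise: NoiseModel = NoiseModel(sigma=0.0),
    dna_conc: float | None = None,
) -> RelaxationTrace:
    """Pseudo-first-order association trace:
    signal = offset + amplitude*(1 - exp(-k_obs*t)),
    k_obs = k_on*dimer_conc + k_off.

    Warns when the pseudo-first-order regime (dimer >= 10x DNA) is not
    respected; ``dna_conc`` defaults to 5 nM, the labelled-target
    concentration after 1:1 stopped-flow mixing of 10 nM DNA with the
    protein.
    """
    if k_on < 0 or k_off < 0 or dimer_conc < 0:
        raise ValueError("rate constants and dimer_conc must be non-negative")
    dna = 5e-9 if dna_conc is None else dna_conc
    if dna > 0 and dimer_conc < 10.0 * dna:
        warnings.warn(
            f"dimer_conc {dimer_conc:.3g} M is below 10x DNA ({dna:.3g} M); "
            "pseudo-first-order approximation degraded",
            UserWarning, stacklevel=2,
        )
    k_obs = k_on * dimer_conc + k_off
    if t_grid is None:
        t_grid = np.linspace(0.0, _TRACE_SPAN / k_obs, _TRACE_POINTS)
    latent = offset + amplitude * (1.0 - np.exp(-k_obs * np.asarray(t_grid, dtype=float)))
    signal = noise.apply(latent, amplitude)
    return RelaxationTrace(
        time=np.asarray(t_grid, dtype=float), signal=signal,
        meta={
            "kind": "association", "dimer_conc_M": dimer_conc, "dna_M": dna,
            "k_obs_true": k_obs, "seed": noise.seed, "noise": noise.kind,
            "sigma": noise.sigma,
        },
    )


def gen_dissociation_trace(
    k_off: float,
    competitor_conc: float,
    t_grid: np.ndarray | None = None,
    amplitude: float = 1.0,
    offset: float = 0.0,
    noise: NoiseModel = NoiseModel(sigma=0.0),
) -> RelaxationTrace:
    """Out-competition dissociation trace: single-exponential decay at
    rate k_off.  The competitor concentration is recorded as metadata
    but — by construction of the out-competition experiment — does not
    affect the decay rate."""
    if k_off < 0 or competitor_conc < 0:
        raise ValueError("k_off and competitor_conc must be non-negative")
    if t_grid is None:
        rate = k_off if k_off > 0 else 1.0
        t_grid = np.linspace(0.0, _TRACE_SPAN / rate, _TRACE_POINTS)
    t = np.asarray(t_grid, dtype=float)
    latent = offset + amplitude * np.exp(-k_off * t)
    signal = noise.apply(latent, amplitude if amplitude != 0 else 1.0)
    return RelaxationTrace(
        time=t, signal=signal,
        meta={
            "kind": "dissociation", "competitor_M": competitor_conc,
            "seed": noise.seed, "noise": noise.kind, "sigma": noise.sigma,
        },
    )


# --------------------------------------------------------------------------
# series generators (the study designs)
# --------------------------------------------------------------------------


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def gen_refolding_series(
    truth: GroundTruth = GroundTruth(),
    protein_concs: Sequence[float] = PROTEIN_CONCS,
    ureas: Sequence[float] = UREA_GRID,
    sigma: float = 0.01,
    seed: int = 0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[RelaxationTrace]:
    """The full refolding experiment: every (protein, urea) combination,
    each trace with its own sub-seed derived from ``seed``."""
    seeds = iter(_spawn_seeds(seed, len(protein_concs) * len(ureas)))
    return [
        gen_refolding_trace(
            truth, P_T, u, noise=NoiseModel(sigma=sigma, seed=next(seeds)), config=config
        )
        for P_T in protein_concs
        for u in ureas
    ]


def gen_association_series(
    truth: GroundTruth = GroundTruth(),
    dimer_concs: Sequence[float] = DIMER_CONCS,
    sigma: float = 0.01,
    seed: int = 0,
) -> list[RelaxationTrace]:
    seeds = iter(_spawn_seeds(seed, len(dimer_concs)))
    return [
        gen_association_trace(
            truth.k_on, truth.k_off, c, noise=NoiseModel(sigma=sigma, seed=next(seeds))
        )
        for c in dimer_concs
    ]


def gen_dissociation_series(
    truth: GroundTruth = GroundTruth(),
    competitor_concs: Sequence[float] = COMPETITOR_CONCS,
    sigma: float = 0.01,
    seed: int = 0,
) -> list[RelaxationTrace]:
    seeds = iter(_spawn_seeds(seed, len(competitor_concs)))
    return [
        gen_dissociation_trace(
            truth.k_off, c, noise=NoiseModel(sigma=sigma, seed=next(seeds))
        )
        for c in competitor_concs
    ]


# --------------------------------------------------------------------------
# mutant panels
# --------------------------------------------------------------------------


@dataclass
class MutantPanel:
    """Generated Ala/Gly panel plus its generating truth."""

    records: list[MutantRecord]
    truth: pd.DataFrame          # per-mutant noiseless kon/koff/KD and ddG


def gen_mutant_panel(
    wt: RateConstants | None = None,
    n_pairs: int = 7,
    ddG_range: tuple[float, float] = (-1.0, 2.5),
    phi_true: float | Sequence[float] = 0.06,
    noise: NoiseModel = NoiseModel(kind="lognormal_multiplicative", sigma=0.05),
    fh_wt: float = 0.62,
    fh_slope: float = 0.04,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> MutantPanel:
    """Ala/Gly mutant panel with prescribed energetics.

    Every mutant lies on one linear free-energy relationship through the
    wild type: kon = kon_wt * (KD/KD_wt)^(-Phi).  Each pair draws an
    Ala-vs-WT ddG and a shared Ala-to-Gly ddG uniformly from
    ``ddG_range`` (kcal/mol), so KD_Gly/KD_Ala = exp(ddG/RT) and
    kon_Ala/kon_Gly = (KD_Gly/KD_Ala)^Phi hold exactly before noise.
    k_off is set so K_D = k_off/k_on is self-consistent.  Lognormal
    multiplicative noise (sdlog = sigma) perturbs each rate constant and
    the recorded errors are sigma * rate.

    Fractional helicities emulate the helix-propensity readout: the Gly
    member of a pair loses helicity in proportion to ln(koff_Gly/
    koff_Ala) with gradient ``fh_slope``, so the koff-ratio-vs-dFH
    correlation is positive by construction.

    ``phi_true`` may be a scalar or one value per pair; values outside
    [-0.5, 1.5] draw a warning (outside the conventional Phi range) but
    are not rejected.
    """
    wt = GroundTruth().wt_rates() if wt is None else wt
    phis = np.broadcast_to(np.asarray(phi_true, dtype=float), (n_pairs,))
    if np.any((phis < -0.5) | (phis > 1.5)):
        warnings.warn(
            "phi_true outside the conventional range [-0.5, 1.5]",
            UserWarning, stacklevel=2,
        )
    RT = config.RT
    rng = noise.rng()
    phi_panel = float(np.mean(phis))   # places the Ala pseudo-wild-types
    kon_wt, koff_wt = wt.k_on.value, wt.k_off.value
    KD_wt = koff_wt / kon_wt

    records: list[MutantRecord] = []
    truth_rows = []
    lo, hi = ddG_range
    for i in range(n_pairs):
        pair_id = f"p{i + 1:02d}"
        ddG_ala = float(rng.uniform(lo, hi))       # Ala vs WT
        ddG_pair = float(rng.uniform(lo, hi))      # Gly vs Ala (shared within pair)
        specs = [
            (f"M{i + 1:02d}A", "Ala", ddG_ala, phi_panel),
            (f"M{i + 1:02d}G", "Gly", ddG_ala + ddG_pair, None),  # None -> via pair phi
        ]
        kon_ala = None
        fh_prev = None
        for name, subst, ddG_wtref, phi_place in specs:
            KD = KD_wt * float(np.exp(ddG_wtref / RT))
            if phi_place is not None:
                kon = kon_wt * (KD / KD_wt) ** (-phi_place)
                kon_ala, KD_ala = kon, KD
            else:
                # within-pair relation at this pair's Phi, exact before noise
                kon = kon_ala * (KD / KD_ala) ** (-float(phis[i]))
            koff = kon * KD
            truth_rows.append({
                "mutant": name, "pair_id": pair_id, "subst": subst,
                "ddG_vs_wt": ddG_wtref, "phi": float(phis[i]),
                "kon": kon, "koff": koff, "KD": KD,
            })
            kon_noisy = float(kon * np.exp(rng.normal(0.0, noise.sigma))) if noise.sigma else kon
            koff_noisy = float(koff * np.exp(rng.normal(0.0, noise.sigma))) if noise.sigma else koff
            rates = RateConstants.from_rates(
                Measurement(kon_noisy, noise.sigma * kon_noisy),
                Measurement(koff_noisy, noise.sigma * koff_noisy),
                label=name,
            )
            if subst == "Ala":
                fh = float(np.clip(rng.uniform(fh_wt - 0.1, fh_wt + 0.05), 0.0, 1.0))
                fh_prev = (fh, koff)
            else:
                fh = float(np.clip(
                    fh_prev[0] - fh_slope * np.log(koff / fh_prev[1]), 0.0, 1.0
                ))
            records.append(MutantRecord(
                name=name, position=i + 1, subst=subst, pair_id=pair_id,
                rates=rates, FH=Measurement(fh, 0.01),
            ))
    return MutantPanel(records=records, truth=pd.DataFrame(truth_rows))


# --------------------------------------------------------------------------
# panel TSV round trip
# --------------------------------------------------------------------------

_PANEL_COLUMNS = [
    "mutant", "pair_id", "subst",
    "kon_per_M_s", "kon_err", "koff_per_s", "koff_err", "FH",
]


def write_panel(records: Sequence[MutantRecord], path: str | Path) -> Path:
    """Write a mutant panel as TSV (schema: mutant, pair_id, subst,
    kon_per_M_s, kon_err, koff_per_s, koff_err, FH)."""
    rows = [{
        "mutant": r.name, "pair_id": r.pair_id, "subst": r.subst,
        "kon_per_M_s": r.rates.k_on.value, "kon_err": r.rates.k_on.err,
        "koff_per_s": r.rates.k_off.value, "koff_err": r.rates.k_off.err,
        "FH": r.FH.value if r.FH is not None else np.nan,
    } for r in records]
    path = Path(path)
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_panel(path: str | Path) -> list[MutantRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing panel columns {missing}")
    records = []
    for _, row in df.iterrows():
        rates = RateConstants.from_rates(
            Measurement(float(row.kon_per_M_s), float(row.kon_err)),
            Measurement(float(row.koff_per_s), float(row.koff_err)),
            label=str(row.mutant),
        )
        fh = None if pd.isna(row.FH) else Measurement(float(row.FH), 0.0)
        records.append(MutantRecord(
            name=str(row.mutant), position=None, subst=str(row.subst),
            pair_id=str(row.pair_id), rates=rates, FH=fh,
        ))
    return records
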