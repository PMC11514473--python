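"""End-to-end study workflows: simulate the experiment at the wild-type
study conditions, run the full analysis, return the headline estimates.

Each workflow derives every per-trace noise seed from one master seed,
so a run is fully reproducible from that single integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .measurement import Measurement
from . import synthetic, dimerization, binding, phi as phi_mod

__all__ = [
    "refolding_study",
    "association_study",
    "dissociation_study",
    "panel_study",
]


def _subseed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0]) & 0x7FFFFFFF


def refolding_study(
    seed: int = 0,
    sigma: float = 0.01,
    truth: synthetic.GroundTruth | None = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dimerization.UreaSeriesResult:
    """Urea refolding experiment: traces at every protein concentration
    (2.2, 4.5, 9.1 uM) x urea point, fit per trace, pooled weighted
    extrapolation to zero urea."""
    truth = synthetic.GroundTruth() if truth is None else truth
    traces = synthetic.gen_refolding_series(
        truth, sigma=sigma, seed=_subseed(seed, 1), config=config)
    series = [(tr.urea, dimerization.fit_refolding_trace(tr, config=config))
              for tr in traces]
    return dimerization.fit_urea_dependence(series, config)


def association_study(
    seed: int = 0,
    sigma: float = 0.01,
    truth: synthetic.GroundTruth | None = None,
) -> binding.PseudoFirstOrderResults:
    """Association experiment: six dimer concentrations 50-100 nM,
    single-exponential fits, weighted k_obs line."""
    truth = synthetic.GroundTruth() if truth is None else truth
    traces = synthetic.gen_association_series(truth, sigma=sigma, seed=_subseed(seed, 2))
    points = [binding.fit_single_exponential(tr) for tr in traces]
    return binding.fit_kobs_line(points)


def dissociation_study(
    seed: int = 0,
    sigma: float = 0.01,
    truth: synthetic.GroundTruth | None = None,
) -> Measurement:
    """Out-competition experiment: four competitor concentrations
    2-8 uM, single-exponential fits, competitor-independence check,
    inverse-variance weighted k_off."""
    truth = synthetic.GroundTruth() if truth is None else truth
    traces = synthetic.gen_dissociation_series(truth, sigma=sigma, seed=_subseed(seed, 3))
    pairs = [(tr.meta["competitor_M"], binding.fit_single_exponential(tr).k_obs)
             for tr in traces]
    return binding.average_koff(pairs)


def panel_study(
    seed: int = 0,
    sigma: float = 0.05,
    phi_true: float = 0.06,
    n_pairs: int = 7,
) -> phi_mod.LFERResult:
    """Ala/Gly mutant panel (14 mutants) built at a uniform per-mutant
    Phi, lognormal rate noise, weighted Leffler LFER fit."""
    noise = synthetic.NoiseModel(
        kind="lognormal_multiplicative", sigma=sigma, seed=_subseed(seed, 4))
    panel = synthetic.gen_mutant_panel(n_pairs=n_pairs, phi_true=phi_true, noise=noise)
    return phi_mod.leffler_fit(panel.records)
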