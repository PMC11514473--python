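# Methods

## The dimerization relaxation model

The core scheme is a reversible two-state homodimerization, 2P ⇌ P₂,
with no populated intermediates.  We write the dissociation equilibrium
constant as *L* = [P]²/[P₂] (molar) and the folding rate constant as
*k*₁ (M⁻¹s⁻¹), with the mass-action convention that monomer is consumed
at rate *k*₁[P]² and regenerated at rate *k*₁·*L*·[P₂]:

    d[P]/dt = −k₁[P]² + k₁·L·[P₂],    [P₂] = (P_T − [P])/2.

This Riccati equation has the closed-form solution implemented in
`dimerization.monomer_concentration`; its late-time approach to
equilibrium is exponential with rate k₁z, z = √(L²/4 + 2LP_T).  The
factor convention matters: defining monomer loss as 2k₁[P]² instead
doubles the relaxation rate.  We pin the convention by testing the
closed form against an independent adaptive (LSODA) integration of the
ODE above to 10⁻⁸ relative error over a 3×3×3 grid of (L, k₁, P_T)
spanning three orders of magnitude each.

A refolding experiment — rapid dilution out of 8 M urea — starts from
all monomer, P₀ = P_T.  Under that initial condition the integration
constant N = ((L−2z)/4 + P₀)/((L+2z)/4 + P₀) always lies strictly in
(0, 1) (because z < (L+4P_T)/2), which keeps the denominator
N·e^(−k₁zt) − 1 bounded away from zero for all t ≥ 0; no numerical
guard is needed beyond that invariant, which is asserted in tests.

The observed fluorescence is affine in monomer, F(t) = F₀ + ΔF[P](t).
Each trace is fitted by nonlinear least squares (lmfit/MINPACK) for
{L, k₁, F₀, ΔF}, with L and k₁ optimized in natural-log space because
they vary over orders of magnitude across denaturant conditions; the
log parametrization also enforces positivity without bounds.  Standard
errors on L and k₁ are delta-method transforms of the log-space errors.
Starting values are self-generated: F₀ from the trace tail, a
single-exponential pre-fit for the relaxation rate, and three candidate
equilibrium conversion fractions (0.2/0.5/0.8) to seed L and ΔF, with
the lowest-χ² start kept.  Optimizer tolerances default to the standard
MINPACK values (1.49e-8).

A fit is flagged `unidentifiable` when the covariance is singular, when
L is constrained to worse than a factor of ten, or when the implied
relaxation amplitude is under five times the residual noise (a flat
trace: ΔF ≈ 0, or a condition where almost no dimer forms).  Flagged
fits still return values and (large) errors, so downstream
inverse-variance weighting de-emphasizes them naturally.

## Denaturant dependence

m-values are reported in kcal·mol⁻¹·M⁻¹, which presumes the standard
log-linear convention: the free energies ΔG_eq = −RT ln L and
RT ln k₁ are fitted linearly against urea (weighted least squares,
statsmodels WLS, inverse-variance weights from the per-trace errors,
unweighted fallback when errors are absent).  Intercepts give L₀ and
k₁₀; gradient magnitudes give m_eq and m_kin; m_kin/m_eq carries a
propagated error.  A literal linear fit of L and k₁ against urea is
retained behind `AnalysisConfig(denaturant_convention="linear")` for
users who want gradients in native units; the two conventions are never
mixed in one analysis.  Directionality (destabilization with urea) is
asserted and flagged, not enforced.  Replicate protein concentrations
at the same urea enter the line fit as extra points — per-trace fitting
is the default presentation; a global fit sharing {L, k₁} across
concentrations is deliberately not the default.

Gas constant R = 0.0019872 kcal·mol⁻¹·K⁻¹ and T = 298.15 K (25 °C)
everywhere, overridable in `AnalysisConfig`.

## Binding kinetics

Association under pseudo-first-order conditions (dimer ≥ 10× DNA target)
is single-exponential, k_obs = k_on·[dimer] + k_off.  Observed rates
are fitted per trace (rise vs decay auto-detected by the amplitude
sign), then regressed against dimer concentration; the gradient is
k_on.  The intercept is reported for diagnostics only — it is *not*
reinterpreted as k_off, because the out-competition route measures
k_off directly and more reliably.  Out-competition rates at several
competitor concentrations are checked for competitor independence (OLS
slope, two-sided test at α = 0.05; failure warns but does not reject)
and combined by inverse-variance weighted mean.  K_D = k_off/k_on with
first-order propagation; a Monte-Carlo propagation helper provides the
independent cross-check used in tests (agreement within 5% at ≤10%
relative input errors).

Dimer concentration is total monomer / 2 under the saturating-dimer
assumption (total ≫ L); the generator records it directly.

## Φ values and the Leffler LFER

Φ = ln(k_on^Ala/k_on^Gly) / ln(K_D^Gly/K_D^Ala) per pair, errors by the
delta method over all four inputs, Monte-Carlo cross-check available.
Pairs with |ΔΔG| < 0.3 kcal/mol are flagged unreliable rather than
dropped — Φ diverges as its denominator vanishes, and 0.3 kcal/mol is
comfortably below the perturbations a designed Ala/Gly scan produces.

The Leffler α is the gradient of log₁₀ k_on against log₁₀ K_D, fitted
by WLS with log-space inverse-variance weights.  Because Φ is defined
as −d ln k_on/d ln K_D, the signed slope of that plot is −α for a
panel with uniform Φ; α is reported as the magnitude with the
orientation matching Φ, and the raw signed slope is also emitted.
Outlier exclusion is caller-specified by name, never automatic — panel
outliers are identified by inspection, and both including and excluding
fits can be produced.

The helicity correlation takes x = FH_Ala − FH_Gly and
y = k_off,Gly/k_off,Ala per pair and reports the standard unweighted
Pearson r with a two-tailed p from the t-distribution (n−2 dof).

## The synthetic-data generator

The generator emulates the averaged output of a stopped-flow
instrument, not single shots: real measurements average ≥50 traces, so
the default noise — Gaussian, additive, 1% of the trace's dynamic
amplitude — represents post-averaging noise.  Lognormal multiplicative
noise is available for rate-constant panels.  Every generator call is
deterministic in its seed; series generators derive per-trace sub-seeds
from one master seed via `numpy.random.SeedSequence`.

Default study conditions mirror the wild-type experiments: refolding at
2.2/4.5/9.1 μM total protein; association at 50–100 nM dimer against
5 nM labelled target (10 nM before 1:1 mixing); dissociation against
2–8 μM competitor; ground truth L₀ = 11 nM, k₁₀ = 7.1 μM⁻¹s⁻¹,
m_eq = 1.55, m_kin = 0.71 kcal·mol⁻¹·M⁻¹, k_on = 6.7×10⁹ M⁻¹s⁻¹,
k_off = 2.44 s⁻¹.  The refolding urea grid is six points from 1.0 to
3.0 M: under the log-linear convention with this ground truth,
L(urea) exceeds 100 μM above ~3.5 M, the equilibrium dimerized fraction
at micromolar protein drops below a few percent, and a refolding trace
carries no relaxation amplitude — conditions a bench scientist would
not waste protein on.  Traces default to 500 points, log-spaced over
five relaxation times, resolving both the fast phase and the plateau.

Mutant panels place every variant on one LFER through the wild type,
k_on ∝ K_D^(−Φ); each pair draws its Ala-vs-WT and Ala-to-Gly ΔΔG
uniformly from the configured range (default −1 to +2.5 kcal/mol), so
the Φ relation holds exactly before noise.  When per-pair Φ values are
supplied, the within-pair relation uses each pair's Φ and the Ala
placements use the panel mean.  Synthetic fractional helicities give
the Gly member a helicity loss proportional to ln(k_off ratio)
(gradient 0.04 per e-fold), producing ΔFH differences up to ~0.15 —
the scale seen in real Ala/Gly scans — and a positive
k_off-ratio-vs-ΔFH correlation by construction.

What the generator does **not** model: instrument dead time (traces
start at the ideal t = 0 initial condition), photobleaching, mixing
transients, and the extra kinetic phases that unlabelled-identical
out-competition sequences can introduce.  Passing recovery tests
therefore demonstrate estimator correctness under idealized averaged
data, not robustness to instrument artifacts.

## Structure metrics

Fractional helicity uses the single-wavelength 222 nm estimate between
a temperature-dependent coil baseline (2220 − 53·T °C) and a
chain-length-corrected helix baseline (−44000·(1 − 3/n) + 250·T °C).
These constants are one published convention among several and are
fully configurable; FH values are convention-relative, so the package
treats them as comparable within one convention (differences, trends)
rather than as absolute percentages, and no test pins an FH value to a
literature number.  Spectra must actually cover 222 nm — the nearest
grid point within ±1 nm is used, never a longer-range interpolation.
The heteronuclear NOE ratio is a plain intensity ratio with propagated
error, shared with the rate-ratio propagation code path.

## Numerical and design choices

* SI units internally (M, s, K, kcal/mol); nM/μM conversions only at
  display/report layers.
* Weighted mean falls back to the unweighted mean with SEM when any
  error is missing or zero.
* Monte-Carlo propagation discards non-finite draws (e.g. a negative
  rate under a log) and refuses to report if more than half are lost.
* The acceptance/workflow problem sizes — 18 refolding traces, 6
  association + 4 dissociation traces of 500 points, one 14-mutant
  panel — match the simulated study designs above; the whole pipeline
  runs in seconds.
* Repeated-seed calibration of the refolding recovery shows fitted
  standard errors mildly underdispersed (2σ coverage ~85–90%), so
  recovery tests use 3σ bands.  L₀, as an extrapolated intercept, is
  the widest-scattered estimate (seed-to-seed sd ~12%); the rate
  constants and m-values recover to within a few percent.

## Known limitations

* No three-state or intermediate dimerization models, and no
  unfolding-arm (chevron) analysis.
* No reversible-binding biexponential association model; severely
  destabilized variants measured under doubled-concentration protocols
  are carried as metadata only.
* Φ interpretation (how much structure the transition state carries) is
  left to the user; the package computes, it does not interpret.
* The Debye-length helper implements the standard closed form
  κ⁻¹ = √(ε_rε₀k_BT / 2N_Ae²I) (~0.7 nm at 186 mM, 25 °C); screening
  lengths several-fold larger than this are sometimes quoted in the
  literature for comparable buffers and are not reproducible from the
  standard formula.
* MES pKa defaults to 6.27 at 25 °C for the ionic-strength split; the
  value is configurable and the 186 mM headline figure depends on it.
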