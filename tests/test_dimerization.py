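"""Two-state dimerization relaxation model: closed form, ODE oracle,
per-trace fitting and the urea extrapolation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import foldbind as fb
from foldbind.dimerization import (
    DimerModelParams,
    UnidentifiableFitWarning,
    dimer_concentration,
    monomer_concentration,
    relaxation_rate,
)

GRID_L = (1e-9, 1e-7, 1e-5)          # M, spanning 3 orders
GRID_K1 = (1e5, 1e6, 1e7)            # M^-1 s^-1
GRID_PT = (5e-7, 2.2e-6, 9.1e-6)     # M


def ode_monomer(L, k1, P_T, t_eval):
    """Independent oracle: adaptive RK/LSODA integration of the
    mass-action scheme d[P]/dt = -k1*[P]^2 + k1*L*[P2]."""

    def rhs(t, y):
        return [-k1 * y[0] ** 2 + k1 * L * (P_T - y[0]) / 2.0]

    sol = solve_ivp(rhs, [0.0, t_eval[-1]], [P_T], t_eval=t_eval,
                    method="LSODA", rtol=1e-12, atol=1e-22 * P_T)
    return sol.y[0]


@pytest.mark.parametrize("L", GRID_L)
@pytest.mark.parametrize("k1", GRID_K1)
@pytest.mark.parametrize("P_T", GRID_PT)
def test_closed_form_matches_ode_oracle(L, k1, P_T):
    params = DimerModelParams(L=L, k1=k1)
    tau = 1.0 / relaxation_rate(params, P_T)
    t = np.linspace(0.0, 5.0 * tau, 40)
    analytic = monomer_concentration(t, params, P_T)
    numeric = ode_monomer(L, k1, P_T, t)
    np.testing.assert_allclose(analytic, numeric, rtol=1e-8)


def test_initial_condition_is_total_monomer():
    params = DimerModelParams(L=11e-9, k1=7.1e6)
    for P_T in GRID_PT:
        assert monomer_concentration(0.0, params, P_T) == pytest.approx(P_T, rel=1e-12)


def test_equilibrium_limit_satisfies_mass_action():
    params = DimerModelParams(L=11e-9, k1=7.1e6)
    P_T = 2.2e-6
    t_long = 50.0 / relaxation_rate(params, P_T)
    P_inf = float(monomer_concentration(t_long, params, P_T))
    assert P_inf == pytest.approx((2 * params.z(P_T) - params.L) / 4, rel=1e-9)
    P2_inf = (P_T - P_inf) / 2
    assert P_inf**2 / P2_inf == pytest.approx(params.L, rel=1e-6)


def test_monomer_decreases_monotonically():
    params = DimerModelParams(L=1e-7, k1=1e6)
    t = np.linspace(0, 10, 200)
    P = monomer_concentration(t, params, 2.2e-6)
    assert np.all(np.diff(P) < 0)


def test_mass_conservation():
    params = DimerModelParams(L=5e-8, k1=2e6)
    P_T = 4.5e-6
    t = np.geomspace(1e-4, 10, 50)
    total = monomer_concentration(t, params, P_T) + 2 * dimer_concentration(t, params, P_T)
    np.testing.assert_allclose(total, P_T, rtol=1e-12)


def test_integration_constant_in_unit_interval():
    # for the refolding initial condition P0 = P_T the constant N lies
    # strictly in (0, 1), which keeps the denominator away from zero
    for L in GRID_L:
        for P_T in GRID_PT:
            N = DimerModelParams(L=L, k1=1e6).N(P_T)
            assert 0.0 < N < 1.0


def test_weak_dimerization_limit_stays_monomeric():
    params = DimerModelParams(L=1.0, k1=1e6)  # L >> P_T
    t = np.linspace(0, 1e-3, 50)
    P = monomer_concentration(t, params, 1e-6)
    np.testing.assert_allclose(P, 1e-6, rtol=1e-5)


def test_late_time_relaxation_rate_is_k1_z():
    params = DimerModelParams(L=1e-7, k1=1e6)
    P_T = 2.2e-6
    lam = relaxation_rate(params, P_T)
    t = np.linspace(8.0 / lam, 12.0 / lam, 100)
    P_inf = (2 * params.z(P_T) - params.L) / 4
    resid = monomer_concentration(t, params, P_T) - P_inf
    slope = np.polyfit(t, np.log(resid), 1)[0]
    assert -slope == pytest.approx(lam, rel=1e-3)


def test_negative_time_rejected():
    params = DimerModelParams(L=1e-8, k1=1e6)
    with pytest.raises(ValueError, match="non-negative"):
        monomer_concentration(-1.0, params, 1e-6)


def test_invalid_params_rejected():
    with pytest.raises(ValueError, match="L"):
        DimerModelParams(L=0.0, k1=1e6)
    with pytest.raises(ValueError, match="k1"):
        DimerModelParams(L=1e-8, k1=-1.0)


def test_fluorescence_is_affine_in_monomer():
    params = DimerModelParams(L=1e-8, k1=1e6, F0=0.3, dF=2e6)
    P_T = 2.2e-6
    t = np.linspace(0, 1, 20)
    expected = 0.3 + 2e6 * monomer_concentration(t, params, P_T)
    np.testing.assert_allclose(fb.model_fluorescence(t, params, P_T), expected, rtol=1e-14)
    flat = DimerModelParams(L=1e-8, k1=1e6, F0=0.3, dF=0.0)
    np.testing.assert_allclose(fb.model_fluorescence(t, flat, P_T), 0.3)
    assert fb.model_fluorescence(0.0, params, P_T) == pytest.approx(0.3 + 2e6 * P_T)


# ---------------------------------------------------------------- fitting


def test_noise_free_fit_recovers_parameters_exactly(truth, no_noise):
    tr = fb.gen_refolding_trace(truth, 2.2e-6, 2.0, noise=no_noise)
    res = fb.fit_refolding_trace(tr)
    L_true, k1_true = truth.at_urea(2.0)
    assert res.params.L == pytest.approx(L_true, rel=1e-6)
    assert res.params.k1 == pytest.approx(k1_true, rel=1e-6)
    assert np.max(np.abs(res.resid())) < 1e-8 * abs(truth.dF * 2.2e-6)


def test_noisy_fit_recovers_L_within_ten_percent(truth):
    tr = fb.gen_refolding_trace(truth, 2.2e-6, 2.0,
                                noise=fb.NoiseModel(sigma=0.01, seed=11))
    res = fb.fit_refolding_trace(tr)
    L_true, _ = truth.at_urea(2.0)
    assert abs(res.params.L / L_true - 1) < 0.10


def test_flat_trace_flagged_unidentifiable():
    t = np.linspace(0, 1, 100)
    tr = fb.RelaxationTrace(time=t, signal=np.full_like(t, 0.5), protein_total=2.2e-6)
    with pytest.warns(UnidentifiableFitWarning):
        res = fb.fit_refolding_trace(tr)
    assert "unidentifiable" in res.flags


def test_fit_requires_protein_total():
    t = np.linspace(0, 1, 50)
    tr = fb.RelaxationTrace(time=t, signal=np.exp(-t))
    with pytest.raises(ValueError, match="protein_total"):
        fb.DimerRelaxationModel(tr)


# ----------------------------------------------------------- urea series


def _series(truth, sigma, seed, ureas=None):
    traces = fb.gen_refolding_series(truth, sigma=sigma, seed=seed,
                                     **({"ureas": ureas} if ureas else {}))
    return [(tr.urea, fb.fit_refolding_trace(tr)) for tr in traces]


def test_urea_extrapolation_recovers_ground_truth(truth):
    res = fb.fit_urea_dependence(_series(truth, sigma=0.01, seed=21))
    assert abs(res.L0.value - truth.L0) < 2 * res.L0.err + 0.1 * truth.L0
    assert abs(res.k1_0.value - truth.k1_0) < 2 * res.k1_0.err + 0.05 * truth.k1_0
    assert abs(res.m_eq.value - truth.m_eq) < 2 * res.m_eq.err + 0.05 * truth.m_eq
    assert abs(res.m_kin.value - truth.m_kin) < 2 * res.m_kin.err + 0.05 * truth.m_kin
    assert res.m_ratio is not None and 0 < res.m_ratio.value < 1


def test_m_ratio_from_printed_m_values():
    # the transition state lies roughly halfway along folding
    from foldbind.measurement import Measurement, ratio
    r = ratio(Measurement(0.71, 0.03), Measurement(1.55, 0.07))
    assert round(r.value, 2) == 0.46


def test_gradient_free_series_flagged():
    flat_truth = fb.GroundTruth(m_eq=1e-12, m_kin=1e-12)
    res = fb.fit_urea_dependence(_series(flat_truth, sigma=0.0, seed=0,
                                         ureas=(1.0, 2.0, 3.0)))
    assert ("m_eq_consistent_with_zero" in res.flags) or ("m_ratio_undefined" in res.flags)


def test_too_few_urea_points_rejected(truth, no_noise):
    tr = fb.gen_refolding_trace(truth, 2.2e-6, 1.0, noise=no_noise)
    r = fb.fit_refolding_trace(tr)
    with pytest.raises(ValueError, match="urea"):
        fb.fit_urea_dependence([(1.0, r), (1.0, r)])


def test_linear_convention_fits_native_units(truth):
    # under the literal convention the intercept is still ~L at 0 M for
    # data generated with a linear-in-urea L
    cfg = fb.AnalysisConfig(denaturant_convention="linear")
    params = [
        (u, DimerModelParams(L=1e-8 + 2e-9 * u, k1=1e6 - 5e4 * u,
                             L_err=1e-10, k1_err=1e3))
        for u in (1.0, 2.0, 3.0, 4.0)
    ]
    res = fb.fit_urea_dependence(params, cfg)
    assert res.convention == "linear"
    assert res.L0.value == pytest.approx(1e-8, rel=1e-6)
    assert res.m_eq.value == pytest.approx(2e-9, rel=1e-6)
    assert res.k1_0.value == pytest.approx(1e6, rel=1e-6)
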