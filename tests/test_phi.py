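"""Phi values, ddG additivity, the Leffler LFER and the helicity
correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import foldbind as fb
from foldbind.measurement import Measurement, monte_carlo
from foldbind.phi import phi_from_records

RT = fb.DEFAULT_CONFIG.RT


def _m(v, rel=0.0):
    return Measurement(v, rel * v)


def test_phi_zero_when_kon_unchanged():
    res = fb.phi_value(_m(5e9), _m(5e9), _m(0.5e-9), _m(5e-9))
    assert res.phi.value == 0.0


def test_phi_one_when_all_change_in_kon():
    res = fb.phi_value(_m(5e9), _m(5e8), _m(0.5e-9), _m(5e-9))
    assert res.phi.value == pytest.approx(1.0, rel=1e-12)


def test_phi_direct_evaluation():
    res = fb.phi_value(_m(5e9), _m(4e9), _m(0.5e-9), _m(5e-9))
    assert res.phi.value == pytest.approx(math.log(1.25) / math.log(10.0), rel=1e-12)


def test_phi_undefined_for_equal_KD():
    with pytest.raises(ValueError, match="undefined"):
        fb.phi_value(_m(5e9), _m(4e9), _m(1e-9), _m(1e-9))


def test_phi_small_ddG_flagged():
    with pytest.warns(UserWarning, match="floor"):
        res = fb.phi_value(_m(5e9), _m(4.9e9), _m(1e-9), _m(1.1e-9))
    assert "small_ddG_unreliable" in res.flags


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       kr=st.floats(min_value=1.1, max_value=20.0),
       Kr=st.floats(min_value=2.0, max_value=100.0))
def test_phi_scale_invariance(scale, kr, Kr):
    """Multiplying all four inputs by a common factor leaves Phi fixed."""
    base = fb.phi_value(_m(5e9 * kr), _m(5e9), _m(1e-9), _m(1e-9 * Kr))
    scaled = fb.phi_value(_m(5e9 * kr * scale), _m(5e9 * scale),
                          _m(1e-9 * scale), _m(1e-9 * Kr * scale))
    assert scaled.phi.value == pytest.approx(base.phi.value, rel=1e-9)


def test_phi_error_propagation_matches_monte_carlo():
    inputs = [_m(5e9, 0.05), _m(4e9, 0.05), _m(0.5e-9, 0.08), _m(5e-9, 0.08)]
    analytic = fb.phi_value(*inputs)

    def f(ka, kg, Ka, Kg):
        return math.log(ka / kg) / math.log(Kg / Ka)

    mc = monte_carlo(f, inputs, n_draws=100_000, seed=99)
    assert abs(mc.err / analytic.phi.err - 1) < 0.05


# -------------------------------------------------------------------- ddG


def test_ddG_identities():
    assert fb.ddG_binding(_m(1e-9), _m(1e-9)).value == 0.0
    tenfold = fb.ddG_binding(_m(1e-9), _m(1e-8))
    assert tenfold.value == pytest.approx(RT * math.log(10.0), rel=1e-12)
    assert tenfold.value == pytest.approx(1.364, abs=0.002)
    swapped = fb.ddG_binding(_m(1e-8), _m(1e-9))
    assert swapped.value == pytest.approx(-tenfold.value, rel=1e-12)


def test_additivity_check():
    a, b = Measurement(2.0, 0.1), Measurement(2.1, 0.1)
    exact = fb.additivity_check(a, b, Measurement(4.1, 0.1))
    assert exact["additive"] and exact["deviation"].value == pytest.approx(0.0, abs=1e-12)
    broken = fb.additivity_check(a, b, Measurement(5.1, 0.05))
    assert not broken["additive"]


def test_additivity_exact_on_independent_perturbations():
    """ddG values built from independent energetic perturbations add
    exactly through the KD algebra."""
    KD_wt = _m(0.36e-9)
    dg_a, dg_b = 1.3, 0.9
    KD_a = _m(KD_wt.value * math.exp(dg_a / RT))
    KD_b = _m(KD_wt.value * math.exp(dg_b / RT))
    KD_ab = _m(KD_wt.value * math.exp((dg_a + dg_b) / RT))
    out = fb.additivity_check(
        fb.ddG_binding(KD_wt, KD_a), fb.ddG_binding(KD_wt, KD_b),
        fb.ddG_binding(KD_wt, KD_ab))
    assert out["deviation"].value == pytest.approx(0.0, abs=1e-9)


# ------------------------------------------------------------------- LFER


def _record(name, pair, subst, kon, KD, fh=None):
    rates = fb.RateConstants.from_rates(_m(kon, 0.03), _m(kon * KD, 0.03), label=name)
    return fb.MutantRecord(name=name, subst=subst, pair_id=pair, rates=rates,
                           FH=None if fh is None else Measurement(fh, 0.01))


def test_leffler_alpha_zero_for_constant_kon():
    panel = [_record(f"m{i}", f"p{i}", "Ala", 5e9, 10 ** (-10 + i)) for i in range(5)]
    res = fb.leffler_fit(panel)
    assert res.alpha.value == pytest.approx(0.0, abs=1e-10)


def test_leffler_alpha_one_for_phi_one_panel():
    # all binding-energy change in kon: kon ~ 1/KD
    panel = [_record(f"m{i}", f"p{i}", "Ala", 5e9 / (10**i), 1e-10 * 10**i)
             for i in range(5)]
    res = fb.leffler_fit(panel)
    assert res.alpha.value == pytest.approx(1.0, rel=1e-9)
    assert res.slope_signed.value == pytest.approx(-1.0, rel=1e-9)


def test_leffler_roundtrip_through_generator():
    noise = fb.NoiseModel(kind="lognormal_multiplicative", sigma=0.05, seed=14)
    panel = fb.gen_mutant_panel(n_pairs=7, phi_true=0.06, noise=noise)
    res = fb.leffler_fit(panel.records)
    assert abs(res.alpha.value - 0.06) < max(2 * res.alpha.err, 0.02)


def test_leffler_exclusions_recorded():
    panel = [_record(f"m{i}", f"p{i}", "Ala", 5e9, 10 ** (-10 + i)) for i in range(6)]
    res = fb.leffler_fit(panel, exclude=["m0"])
    assert res.n_used == 5 and res.excluded == ["m0"]


def test_leffler_insufficient_or_degenerate_panels_rejected():
    small = [_record(f"m{i}", f"p{i}", "Ala", 5e9, 1e-9 * (i + 1)) for i in range(3)]
    with pytest.raises(ValueError, match=">= 4"):
        fb.leffler_fit(small)
    flat = [_record(f"m{i}", f"p{i}", "Ala", 5e9, 1e-9) for i in range(5)]
    with pytest.raises(ValueError, match="spread"):
        fb.leffler_fit(flat)


# ------------------------------------------------------------------ ratios


def test_rate_ratio_formula():
    r = fb.rate_ratio(Measurement(2.0, 0.2), Measurement(1.0, 0.1))
    assert r.value == 2.0
    assert r.err == pytest.approx(2.0 * math.sqrt(0.01 + 0.01), rel=1e-12)
    assert r.err == pytest.approx(0.283, abs=0.001)


def test_rate_ratio_equal_rates():
    r = fb.rate_ratio(_m(3.0, 0.05), _m(3.0, 0.05))
    assert r.value == 1.0
    assert r.err == pytest.approx(math.sqrt(2) * 0.05, rel=1e-12)


def test_rate_ratio_rejects_nonpositive():
    with pytest.raises(ValueError):
        fb.rate_ratio(Measurement(1.0, 0.0), Measurement(0.0, 0.0))


def test_kon_from_koff_KD_inverts_kinetic_KD():
    kon = fb.kon_from_koff_KD(_m(2.44, 0.0123), _m(0.36e-9, 0.004e-9))
    assert kon.value == pytest.approx(2.44 / 0.36e-9, rel=1e-12)
    assert kon.value == pytest.approx(6.8e9, rel=0.01)
    mc = monte_carlo(lambda a, b: a / b, [_m(2.44, 0.0123), _m(0.36e-9, 0.004e-9)],
                     n_draws=100_000, seed=7)
    assert abs(mc.err / kon.err - 1) < 0.05


# ------------------------------------------------------------ correlation


def _fh_panel(x, y):
    """Pairs with FH difference x[i] and koff ratio y[i]."""
    panel = []
    for i, (xi, yi) in enumerate(zip(x, y)):
        panel.append(_record(f"m{i}A", f"p{i}", "Ala", 5e9, 1e-9, fh=0.6))
        gly = _record(f"m{i}G", f"p{i}", "Gly", 5e9, 1e-9 * yi, fh=0.6 - xi)
        panel.append(gly)
    return panel


def test_perfectly_linear_correlation():
    x = np.array([0.02, 0.04, 0.06, 0.08, 0.10])
    y = 1.0 + 30.0 * x
    out = fb.koff_ratio_vs_dFH(_fh_panel(x, y))
    assert out["pearson_r"] == pytest.approx(1.0, abs=1e-9)
    assert out["n"] == 5


def test_constant_FH_difference_rejected():
    x = np.full(5, 0.05)
    y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError, match="constant"):
        fb.koff_ratio_vs_dFH(_fh_panel(x, y))


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match=">= 3"):
        fb.koff_ratio_vs_dFH(_fh_panel([0.01, 0.02], [1.5, 2.0]))


def test_pearson_matches_definitional_oracle(rng):
    """Brute-force r from the covariance definition, 7 random pairs."""
    x = rng.uniform(0.0, 0.15, 7)
    y = rng.uniform(1.0, 30.0, 7)
    out = fb.koff_ratio_vs_dFH(_fh_panel(x, y))
    r_def = float(np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
    assert out["pearson_r"] == pytest.approx(r_def, abs=1e-12)
    # two-tailed p from the t distribution with n-2 dof
    from scipy import stats
    t = r_def * math.sqrt(5 / (1 - r_def**2))
    assert out["p_two_tailed"] == pytest.approx(2 * stats.t.sf(abs(t), 5), rel=1e-9)


def test_exclusion_drops_pair():
    x = np.array([0.02, 0.04, 0.06, 0.08, 0.10])
    y = 1.0 + 30.0 * x
    out = fb.koff_ratio_vs_dFH(_fh_panel(x, y), exclude=["m0G"])
    assert out["n"] == 4


def test_phi_from_records_requires_matching_pair():
    a = _record("aA", "p1", "Ala", 5e9, 1e-9)
    g = _record("aG", "p2", "Gly", 4e9, 5e-9)
    with pytest.raises(ValueError, match="pair"):
        phi_from_records(a, g)
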