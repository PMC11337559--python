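"""Kinetic model properties: impulse-response identities, ODE/convolution
agreement, nested-model limits, and the perfusion identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caplex.curves import Curve, TimeGrid
from caplex.errors import DomainError, FitError
from caplex.models import (
    ExchangeParameters,
    ToftsParameters,
    UptakeParameters,
    delta_r1_linear,
    e_from_ps_fp,
    exchange_forward,
    exchange_irf,
    fp_from_fb,
    ps_from_e_fp,
    satrec_r1_fit,
    satrec_signal,
    tofts_forward,
    tofts_irf,
    uptake_forward,
    uptake_irf,
)


def rel_l2(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


# ---------------------------------------------------------------------------
# impulse responses

def test_tofts_irf_amplitude_and_area(grid):
    p = ToftsParameters(Ktrans=0.25, ve=20.0)
    irf = tofts_irf(grid, p)
    # at t=0 the IRF equals Ktrans (expressed per second: /60)
    assert irf.values[0] * 60.0 == pytest.approx(p.Ktrans, rel=1e-12)
    # the IRF integrates to ve (expressed as a fraction: /100)
    assert irf.area() * 100.0 == pytest.approx(p.ve, rel=1e-3)


def test_tofts_irf_zero_ktrans_is_zero(grid):
    irf = tofts_irf(grid, ToftsParameters(Ktrans=0.0, ve=20.0))
    assert np.all(irf.values == 0)


def test_uptake_irf_limits(grid):
    p = UptakeParameters(Fp=10.0, vp=5.0, PS=1.0)
    irf = uptake_irf(grid, p)
    assert irf.values[0] == pytest.approx(10.0 / 6000.0, rel=1e-12)  # I(0) = Fp
    # long-time plateau at the net extraction flux E*Fp
    assert irf.values[-1] == pytest.approx(p.E * 10.0 / 6000.0, rel=1e-3)


def test_uptake_irf_ps_zero_is_monoexponential_with_area_vp():
    grid = TimeGrid.uniform(0.5, 2000.0)
    p = UptakeParameters(Fp=30.0, vp=5.0, PS=0.0)
    irf = uptake_irf(grid, p)
    assert irf.area() * 100.0 == pytest.approx(5.0, rel=1e-3)


def test_exchange_irf_matches_uptake_at_ps_zero(grid):
    ex = exchange_irf(grid, ExchangeParameters(Fp=10.0, PS=0.0, vp=5.0, ve=20.0))
    up = uptake_irf(grid, UptakeParameters(Fp=10.0, vp=5.0, PS=0.0))
    assert rel_l2(ex.values, up.values) < 1e-12


# ---------------------------------------------------------------------------
# forward models

def test_tofts_forward_zero_aif_is_zero(grid, aif):
    zero = aif.with_values(np.zeros_like(aif.values))
    ct = tofts_forward(zero, grid, ToftsParameters(0.25, 20.0))
    assert np.all(ct.values == 0)


def test_tofts_ode_and_convolution_agree(grid, aif):
    p = ToftsParameters(Ktrans=0.25, ve=20.0)
    conv = tofts_forward(aif, grid, p, method="conv")
    ode = tofts_forward(aif, grid, p, method="ode")
    assert rel_l2(conv.values, ode.values) < 0.005


def test_tofts_step_aif_steady_state():
    grid = TimeGrid.uniform(2.0, 3600.0)
    c = 2.0
    step = Curve(grid, np.full(grid.n, c), unit="mM")
    p = ToftsParameters(Ktrans=0.5, ve=30.0)
    ct = tofts_forward(step, grid, p, method="ode")
    assert ct.values[-1] == pytest.approx(c * p.ve / 100.0, rel=1e-3)


def test_exchange_ode_and_convolution_agree(grid, aif):
    p = ExchangeParameters(Fp=10.0, PS=2.0, vp=5.0, ve=20.0)
    conv = exchange_forward(aif, grid, p, method="conv")
    ode = exchange_forward(aif, grid, p, method="ode")
    assert rel_l2(conv.values, ode.values) < 0.005


def test_exchange_approaches_uptake_as_ve_grows(grid, aif):
    up = uptake_forward(aif, grid, UptakeParameters(Fp=10.0, vp=5.0, PS=1.0))
    ex = exchange_forward(aif, grid, ExchangeParameters(Fp=10.0, PS=1.0, vp=5.0, ve=1e4))
    assert rel_l2(ex.values, up.values) < 0.01


@pytest.mark.parametrize("model", ["tofts", "uptake", "exchange"])
def test_forward_models_are_linear_in_the_aif(grid, aif, model):
    scaled = aif.with_values(3.0 * aif.values)
    if model == "tofts":
        f = lambda a: tofts_forward(a, grid, ToftsParameters(0.25, 20.0))
    elif model == "uptake":
        f = lambda a: uptake_forward(a, grid, UptakeParameters(10.0, 5.0, 1.0))
    else:
        f = lambda a: exchange_forward(a, grid, ExchangeParameters(10.0, 2.0, 5.0, 20.0))
    assert np.allclose(f(scaled).values, 3.0 * f(aif).values, rtol=1e-10, atol=1e-14)


def test_exchange_degenerate_volumes_rejected():
    with pytest.raises(DomainError):
        ExchangeParameters(Fp=10.0, PS=1.0, vp=0.0, ve=20.0)


# ---------------------------------------------------------------------------
# perfusion identities

def test_ps_from_e_fp_printed_example():
    assert ps_from_e_fp(0.5, 10.0) == pytest.approx(10.0)
    assert ps_from_e_fp(0.0, 10.0) == 0.0
    with pytest.raises(DomainError):
        ps_from_e_fp(1.0, 10.0)


@given(st.floats(0, 0.99), st.floats(0.01, 1000))
@settings(max_examples=200, deadline=None)
def test_extraction_identity_roundtrip(E, Fp):
    ps = ps_from_e_fp(E, Fp)
    assert e_from_ps_fp(ps, Fp) == pytest.approx(E, abs=1e-12)


def test_hematocrit_identity():
    assert fp_from_fb(100.0, 0.45) == pytest.approx(55.0)
    assert fp_from_fb(100.0, 0.0) == 100.0
    assert fp_from_fb(0.0, 0.45) == 0.0
    with pytest.raises(DomainError):
        fp_from_fb(100.0, 1.0)


# ---------------------------------------------------------------------------
# signal <-> relaxation

def test_delta_r1_linear_properties(grid):
    s_bl = 50.0
    S = Curve(grid, np.full(grid.n, s_bl), unit="a.u.")
    assert np.all(delta_r1_linear(S, s_bl, 1.3).values == 0)
    S2 = S.with_values(np.where(grid.times == grid.times[5], 2 * s_bl, s_bl))
    d = delta_r1_linear(S2, s_bl, 1.0)
    assert d.values[5] == pytest.approx(1.0)
    # linearity in the enhancement
    S3 = S.with_values(s_bl + 2 * (S2.values - s_bl))
    assert np.allclose(delta_r1_linear(S3, s_bl, 1.0).values, 2 * d.values)
    with pytest.raises(DomainError):
        delta_r1_linear(S, 0.0, 1.0)


def test_satrec_fit_recovers_noiseless_truth():
    delays = np.linspace(100, 5000, 12)
    signals = satrec_signal(delays / 1000.0, 100.0, 1.0)
    r10, m0 = satrec_r1_fit(delays, signals)
    assert r10 == pytest.approx(1.0, rel=1e-6)
    assert m0 == pytest.approx(100.0, rel=1e-6)


def test_satrec_fit_rejects_constant_signals():
    with pytest.raises(FitError):
        satrec_r1_fit([100, 500, 1000], [0.0, 0.0, 0.0])


def test_satrec_fit_noise_robustness(rng):
    delays = np.linspace(100, 5000, 12)
    clean = satrec_signal(delays / 1000.0, 100.0, 1.0)
    errors = []
    for _ in range(200):
        noisy = clean + rng.normal(0, 1.0, clean.shape)  # 1% of M0
        r10, _ = satrec_r1_fit(delays, noisy)
        errors.append(abs(r10 - 1.0))
    assert np.median(errors) < 0.03
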