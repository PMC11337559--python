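"""Analysis processes: curve statistics, segmentation, deconvolution,
model fitting, AIC selection and pipeline execution."""

import numpy as np
import pytest

from caplex.curves import Curve, TimeGrid
from caplex.errors import DomainError, ExecutionError
from caplex.models import convolve, uptake_forward, UptakeParameters
from caplex.pipeline import read_pipeline, validate_pipeline
from caplex.processes import (
    FitResult,
    ROIMask,
    aic_select,
    auc,
    baseline_mean,
    execute_pipeline,
    fit_model,
    gcv_deconvolve,
    relative_enhancement,
    threshold_mask,
    top_k_by_statistic,
)
from caplex.registry import load_registry
from caplex.synthetic import gen_tissue_curve

REG = load_registry()

_NS = 'xmlns:ex="https://osipi.github.io/OSIPI_CAPLEX/llxml"'


def make_curve(values, dt=1.0):
    values = np.asarray(values, float)
    return Curve(TimeGrid(dt * np.arange(values.size)), values, unit="a.u.")


# ---------------------------------------------------------------------------
# elementary operations

def test_baseline_mean():
    S = make_curve([1, 2, 3, 4])
    assert baseline_mean(S, 2) == 1.5
    assert baseline_mean(S, 4) == 2.5
    with pytest.raises(DomainError):
        baseline_mean(S, 0)
    with pytest.raises(DomainError):
        baseline_mean(S, 5)


def test_relative_enhancement():
    S = make_curve([10, 10, 30, 10])
    enh = relative_enhancement(S, 10.0)
    assert np.allclose(enh.values, [0, 0, 2, 0])
    assert enh.unit == ""
    with pytest.raises(DomainError):
        relative_enhancement(S, 0.0)


def test_auc_constant_and_triangle():
    flat = make_curve(np.ones(421))
    assert auc(flat, 0, 420) == pytest.approx(420.0)
    assert auc(make_curve(np.zeros(421)), 0, 420) == 0.0
    # triangle of height 6, base 20 s centred at t=50
    t = np.arange(0, 101.0)
    tri = np.interp(t, [40, 50, 60], [0, 6, 0], left=0, right=0)
    assert auc(Curve(TimeGrid(t), tri), 0, 100) == pytest.approx(60.0)
    with pytest.raises(DomainError):
        auc(flat, -5, 420)


def test_threshold_mask_extremes_and_fixture():
    img = np.ones((5, 5))
    img[1:3, 1:3] = 10.0
    assert threshold_mask(img, 0.0).n_voxels == 25
    with pytest.warns(UserWarning):
        empty = threshold_mask(img, 100.0)
    assert empty.n_voxels == 0
    mid = threshold_mask(img, 5.0)
    assert mid.n_voxels == 4
    assert mid.mask[1, 1] and not mid.mask[0, 0]


def test_top_k_selection_and_tie_break():
    grid = TimeGrid(np.arange(10.0))
    stack = np.ones((4, 1, 10))
    stack[2, 0] *= 5.0  # unique maximum voxel
    mask = ROIMask(np.ones((4, 1), dtype=bool))
    sel, curve = top_k_by_statistic(stack, grid, mask, 1, (0, 9))
    assert sel.mask[2, 0] and sel.n_voxels == 1
    assert np.allclose(curve.values, 5.0)
    # ties at rank k resolve to ascending flat voxel index
    sel2, _ = top_k_by_statistic(np.ones((4, 1, 10)), grid, mask, 2, (0, 9))
    assert list(np.flatnonzero(sel2.mask.ravel())) == [0, 1]
    # k = mask size -> mean over the whole mask
    _, mean_all = top_k_by_statistic(stack, grid, mask, 4, (0, 9))
    assert np.allclose(mean_all.values, (3 + 5) / 4)
    with pytest.raises(DomainError):
        top_k_by_statistic(stack, grid, mask, 5, (0, 9))


# ---------------------------------------------------------------------------
# deconvolution

def test_gcv_recovers_scale_without_dispersion(grid, aif):
    enh = Curve(grid, aif.values / aif.values.max(), unit="")
    resp = enh.with_values(0.6 * enh.values)
    result = gcv_deconvolve(resp, enh)
    assert 0.57 <= result.PA <= 0.63
    assert result.PA == pytest.approx(result.impulse_response.area())


def test_gcv_identity_input(grid, aif):
    enh = Curve(grid, aif.values / aif.values.max(), unit="")
    result = gcv_deconvolve(enh, enh)
    assert result.PA == pytest.approx(1.0, rel=0.02)


def test_gcv_dispersed_noisy_recovery(grid, aif):
    enh = Curve(grid, aif.values / aif.values.max(), unit="")
    tau = 10.0
    kernel = Curve(grid, np.exp(-grid.times / tau) / tau, unit="1/s")
    clean = 0.8 * convolve(kernel, enh)
    rng = np.random.default_rng(42)
    resp = Curve(grid, clean + rng.normal(0, 0.01 * clean.max(), grid.n), unit="")
    result = gcv_deconvolve(resp, enh)
    assert result.PA == pytest.approx(0.8, rel=0.10)
    # re-convolution reproduces the response within ~noise level
    recon = convolve(result.impulse_response, enh)
    rms = np.sqrt(np.mean((recon - resp.values) ** 2))
    assert rms <= 2 * 0.01 * clean.max()


def test_gcv_rejects_zero_input(grid):
    zero = Curve(grid, np.zeros(grid.n), unit="")
    with pytest.raises(DomainError):
        gcv_deconvolve(zero, zero)


# ---------------------------------------------------------------------------
# model fitting

def test_tofts_fit_recovers_noiseless_truth(grid, aif):
    truth = {"Ktrans": 0.25, "ve": 20.0}
    tissue = gen_tissue_curve(aif, "M.IC1.011", truth)
    fit = fit_model("M.IC1.011", aif, tissue)
    assert fit.success
    assert fit.parameters["Ktrans"] == pytest.approx(0.25, rel=0.01)
    assert fit.parameters["ve"] == pytest.approx(20.0, rel=0.01)
    assert fit.free == ("Ktrans", "ve")
    assert fit.initial == {"Ktrans": 0.1, "ve": 20.0}


def test_tofts_fit_with_fixed_ve(grid, aif):
    tissue = gen_tissue_curve(aif, "M.IC1.011", {"Ktrans": 0.25, "ve": 20.0})
    fit = fit_model("M.IC1.011", aif, tissue, fixed={"ve": 20.0})
    assert fit.free == ("Ktrans",)
    assert fit.fixed == {"ve": 20.0}
    assert fit.parameters["Ktrans"] == pytest.approx(0.25, rel=1e-3)


def test_fit_not_identifiable_on_zero_data(grid):
    zero = Curve(grid, np.zeros(grid.n), unit="mM")
    fit = fit_model("M.IC1.011", zero, zero)
    assert not fit.success
    assert "identifiable" in fit.diagnostics


def test_fit_error_decreases_with_noise(grid, aif):
    truth = {"Ktrans": 0.25, "ve": 20.0}
    clean = gen_tissue_curve(aif, "M.IC1.011", truth)
    peak = clean.values.max()
    errors = []
    for i, frac in enumerate([0.02, 0.01, 0.005, 0.0]):
        noisy = gen_tissue_curve(aif, "M.IC1.011", truth, noise_sigma=frac * peak, seed=100 + i)
        fit = fit_model("M.IC1.011", aif, noisy)
        errors.append(abs(fit.parameters["Ktrans"] - 0.25) / 0.25)
    assert errors[-1] < 1e-6
    assert errors[3] <= errors[0]


def test_fit_rejects_bad_parameter_split(grid, aif):
    tissue = gen_tissue_curve(aif, "M.IC1.011", {"Ktrans": 0.25, "ve": 20.0})
    with pytest.raises(DomainError):
        fit_model("M.IC1.011", aif, tissue, free=("Ktrans",))  # ve unaccounted


# ---------------------------------------------------------------------------
# AIC

def _fit_stub(rss, k, n=60):
    return FitResult(
        model_code="M.IC1.011", parameters={}, units={}, free=tuple(f"p{i}" for i in range(k)),
        fixed={}, initial={}, rss=rss, n_points=n, success=True,
    )


def test_aic_ties_prefer_fewer_parameters():
    winner, aics = aic_select([_fit_stub(1.0, 3), _fit_stub(1.0, 4)])
    assert winner == 0
    assert aics[1] - aics[0] == pytest.approx(2.0)


def test_aic_single_candidate():
    assert aic_select([_fit_stub(1.0, 3)])[0] == 0


def test_aic_zero_rss_does_not_blow_up():
    winner, aics = aic_select([_fit_stub(0.0, 2), _fit_stub(1.0, 2)])
    assert winner == 0
    assert np.isfinite(aics[0])


def test_aic_requires_same_n():
    with pytest.raises(DomainError):
        aic_select([_fit_stub(1.0, 3, n=60), _fit_stub(1.0, 3, n=61)])


def test_aic_prefers_generating_model(grid, aif):
    """Uptake-limit data: AIC should select uptake over exchange usually."""
    truth = UptakeParameters(Fp=10.0, vp=5.0, PS=1.0)
    clean = uptake_forward(aif, grid, truth)
    sigma = clean.values.max() / 50
    rng = np.random.default_rng(7)
    wins = 0
    n_rep = 25
    for _ in range(n_rep):
        noisy = clean.with_values(clean.values + rng.normal(0, sigma, grid.n))
        fits = [fit_model("M.IC1.010", aif, noisy), fit_model("M.IC1.009", aif, noisy)]
        winner, _ = aic_select(fits)
        wins += winner == 0
    assert wins >= 0.8 * n_rep


# ---------------------------------------------------------------------------
# pipeline execution

def _doc(body):
    return read_pipeline(
        f'<?xml version="1.0"?><ex:Pipeline {_NS}>{body}</ex:Pipeline>', lenient=True
    )


def test_execute_matches_manual_composition(grid, aif):
    S = Curve(grid, 100.0 * (1.0 + aif.values / aif.values.max()), unit="a.u.")
    doc = _doc(
        '<ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001">'
        '<ex:InputQuantity value="Signal" code="Q.MS1.001" unit="a.u."/>'
        '<ex:InputQuantity value="Number of baseline time points" code="Q.BL1.001" unit="" numericValue="10"/>'
        '<ex:OutputQuantity value="Baseline signal" code="Q.MS1.002" unit="a.u."/>'
        "</ex:Process>"
        '<ex:Process value="Relative signal enhancement calculation" code="P.SC1.002">'
        '<ex:InputQuantity value="Signal" code="Q.MS1.001" unit="a.u."/>'
        '<ex:InputQuantity value="Baseline signal" code="Q.MS1.002" unit="a.u."/>'
        '<ex:OutputQuantity value="Relative signal enhancement" code="Q.MS1.003" unit=""/>'
        "</ex:Process>"
        '<ex:Process value="Area under the curve calculation" code="G.CD1.001">'
        '<ex:InputQuantity value="Relative signal enhancement" code="Q.MS1.003" unit=""/>'
        '<ex:OutputQuantity value="Area under the curve" code="Q.CD1.001" unit="a.u."/>'
        "</ex:Process>"
    )
    assert validate_pipeline(doc, REG).valid
    out = execute_pipeline(doc, {"Q.MS1.001": S}, REG)
    s_bl = baseline_mean(S, 10)
    enh = relative_enhancement(S, s_bl)
    assert out["Q.MS1.002"] == s_bl
    assert out["Q.CD1.001"] == auc(enh, grid.times[0], grid.times[-1])


def test_execute_set_equal_feeds_hematocrit():
    doc = _doc(
        '<ex:Process value="Plasma flow from blood flow and hematocrit" code="P.PX1.002">'
        "<ex:SetEqual>"
        '<ex:Quantity code="Q.PH1.007.[a]"/>'
        '<ex:Literal numericValue="0.45"/>'
        "</ex:SetEqual>"
        '<ex:InputQuantity value="Blood flow" code="Q.PH1.003" unit="mL/min/100 mL"/>'
        '<ex:InputQuantity value="Hematocrit" code="Q.PH1.007.[a]" unit=""/>'
        '<ex:OutputQuantity value="Blood plasma flow" code="Q.PH1.002" unit="mL/min/100 mL"/>'
        "</ex:Process>"
    )
    assert validate_pipeline(doc, REG).valid
    out = execute_pipeline(doc, {"Q.PH1.003": 100.0}, REG)
    assert out["Q.PH1.002"] == pytest.approx(55.0)


def test_execute_unimplemented_process_is_structured_error():
    doc = _doc('<ex:Process value="Leakage correction" code="P.LC1.001"/>')
    with pytest.raises(ExecutionError) as err:
        execute_pipeline(doc, {}, REG)
    assert err.value.code == "P.LC1.001"


def test_execute_unbound_input_names_the_code():
    doc = _doc(
        '<ex:Process value="Baseline signal estimation by averaging" code="P.BE1.001">'
        '<ex:InputQuantity value="Signal" code="Q.MS1.001" unit="a.u."/>'
        '<ex:InputQuantity value="Number of baseline time points" code="Q.BL1.001" unit="" numericValue="10"/>'
        '<ex:OutputQuantity value="Baseline signal" code="Q.MS1.002" unit="a.u."/>'
        "</ex:Process>"
    )
    with pytest.raises(ExecutionError) as err:
        execute_pipeline(doc, {}, REG)
    assert err.value.code == "Q.MS1.001"
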