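"""Synthetic AIF, tissue curves and the 4D phantom with ground truth."""

import numpy as np
import pytest

from caplex.processes import fit_model, baseline_mean, threshold_mask
from caplex.models import delta_r1_linear
from caplex.synthetic import (
    ARTERY,
    BACKGROUND,
    TISSUE_A,
    AIFSpec,
    PhantomSpec,
    gen_aif,
    gen_phantom,
    gen_tissue_curve,
    region_map,
    region_mean_curve,
)


def test_aif_is_deterministic_and_positive(grid):
    a1 = gen_aif(grid, AIFSpec())
    a2 = gen_aif(grid, AIFSpec())
    assert np.array_equal(a1.values, a2.values)
    assert np.all(a1.values >= 0)
    assert a1.area() > 0


def test_aif_is_zero_before_bolus_arrival(grid):
    spec = AIFSpec(t0=30.0)
    a = gen_aif(grid, spec)
    assert np.all(a.values[grid.times <= 30.0] == 0)
    assert np.any(a.values[grid.times > 30.0] > 0)


def test_tissue_curve_noise_is_seeded(aif):
    truth = {"Ktrans": 0.25, "ve": 20.0}
    clean = gen_tissue_curve(aif, "M.IC1.011", truth)
    n1 = gen_tissue_curve(aif, "M.IC1.011", truth, noise_sigma=0.05, seed=1)
    n1b = gen_tissue_curve(aif, "M.IC1.011", truth, noise_sigma=0.05, seed=1)
    n2 = gen_tissue_curve(aif, "M.IC1.011", truth, noise_sigma=0.05, seed=2)
    assert np.array_equal(n1.values, n1b.values)
    assert not np.array_equal(n1.values, n2.values)
    # noise is zero-mean around the forward model
    reps = np.stack([
        gen_tissue_curve(aif, "M.IC1.011", truth, noise_sigma=0.05, seed=s).values
        for s in range(500)
    ])
    se = 0.05 / np.sqrt(500)
    assert np.max(np.abs(reps.mean(axis=0) - clean.values)) < 3 * se * 4


def test_zero_ktrans_gives_flat_zero(aif):
    flat = gen_tissue_curve(aif, "M.IC1.011", {"Ktrans": 0.0, "ve": 20.0})
    assert np.all(flat.values == 0)


def test_phantom_regions_are_disjoint_and_nonempty():
    spec = PhantomSpec()
    labels = region_map(spec)
    for label in (BACKGROUND, TISSUE_A, ARTERY):
        assert np.any(labels == label)


def test_phantom_threshold_recovers_foreground_exactly():
    spec = PhantomSpec()
    signal, truth = gen_phantom(spec)
    s_bl_map = signal[..., :15].mean(axis=-1)
    mask = threshold_mask(s_bl_map, spec.S_BL / 2)
    assert np.array_equal(mask.mask, truth["labels"] != BACKGROUND)


def test_phantom_ground_truth_independent_of_seed():
    s1, t1 = gen_phantom(PhantomSpec(noise_sigma=1.0, seed=1))
    s2, t2 = gen_phantom(PhantomSpec(noise_sigma=1.0, seed=2))
    assert np.array_equal(t1["labels"], t2["labels"])
    assert t1["tissue_params"] == t2["tissue_params"]
    assert not np.array_equal(s1, s2)
    # identical spec -> bit-identical signal
    s1b, _ = gen_phantom(PhantomSpec(noise_sigma=1.0, seed=1))
    assert np.array_equal(s1, s1b)


def test_noiseless_phantom_end_to_end_recovery():
    """baseline -> dR1 -> Tofts fit on region curves recovers the truth."""
    spec = PhantomSpec()
    signal, truth = gen_phantom(spec)
    grid = truth["grid"]
    art = region_mean_curve(signal, truth["labels"], ARTERY, grid)
    aif_r1 = delta_r1_linear(art, baseline_mean(art, 15), spec.R10)
    for label, params in truth["tissue_params"].items():
        tis = region_mean_curve(signal, truth["labels"], label, grid)
        tis_r1 = delta_r1_linear(tis, baseline_mean(tis, 15), spec.R10)
        fit = fit_model("M.IC1.011", aif_r1, tis_r1)
        assert fit.parameters["Ktrans"] == pytest.approx(params["Ktrans"], rel=0.02)
        assert fit.parameters["ve"] == pytest.approx(params["ve"], rel=0.02)
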