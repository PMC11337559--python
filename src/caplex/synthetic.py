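"""Seeded synthetic DCE data: AIFs, tissue curves and small 4D phantoms.

Every numeric test input in the package is generated here, with known
ground truth, so all stages run without downloads.  The generator emulates
a desk-scale version of a brain DCE acquisition: a dynamic signal series
with arterial voxels and tissue regions, a linear signal-relaxation
response, and optional additive Gaussian noise.  It deliberately omits MR
physics (coil profiles, k-space artifacts, motion, Rician noise floors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import Curve, TimeGrid
from .errors import DomainError
from .processes import model_forward


@dataclass(frozen=True)
class AIFSpec:
    """Population-shaped arterial input: gamma-variate first pass plus an
    exponentially recovering washout tail.

    Defaults give a bolus arriving at 30 s, peaking near 1 min at about
    6 mM, decaying to a slowly washing-out plateau — the shape of a
    standard-dose bolus sampled at a few-second dynamic interval.
    """

    t0: float = 30.0          # bolus arrival [s]
    alpha: float = 3.0        # gamma-variate shape
    tau: float = 8.0          # gamma-variate time scale [s]
    amplitude: float = 6.0    # first-pass peak [mM]
    washout_frac: float = 0.4  # tail plateau as a fraction of the peak
    washout_tau: float = 300.0  # tail decay constant [s]


def gen_aif(grid: TimeGrid, spec: AIFSpec = AIFSpec()) -> Curve:
    """Deterministic smooth positive bolus curve; zero before arrival."""
    t = grid.times - spec.t0
    curve = np.zeros_like(grid.times)
    rising = t > 0
    x = t[rising] / (spec.alpha * spec.tau)
    first_pass = (x * np.exp(1.0 - x)) ** spec.alpha  # peak normalized to 1
    tail = spec.washout_frac * (1.0 - np.exp(-t[rising] / (spec.alpha * spec.tau))) * np.exp(
        -t[rising] / spec.washout_tau
    )
    curve[rising] = spec.amplitude * (first_pass + tail)
    return Curve(grid, curve, unit="mM")


def gen_tissue_curve(
    aif: Curve,
    model_code: str,
    truth: dict[str, float],
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> Curve:
    """Forward-model tissue curve plus seeded additive Gaussian noise.

    ``noise_sigma`` is an absolute standard deviation in the curve's units.
    """
    clean = model_forward(model_code, aif, aif.grid, truth)
    if noise_sigma == 0.0:
        return clean
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = clean.values + rng.normal(0.0, noise_sigma, size=clean.values.shape)
    return clean.with_values(noisy)


# ---------------------------------------------------------------------------
# 4D phantom

#: region labels in the phantom map
BACKGROUND, TISSUE_A, TISSUE_B, ARTERY = 0, 1, 2, 3

_DEFAULT_REGIONS = {
    TISSUE_A: {"Ktrans": 0.25, "ve": 20.0},   # tumor-like enhancing tissue
    TISSUE_B: {"Ktrans": 0.05, "ve": 15.0},   # white-matter-like tissue
}


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic 4D DCE phantom.

    The phantom is a small image volume split into disjoint regions:
    background (zero signal), two Tofts-model tissue regions with stated
    ground truth, and an arterial region carrying the AIF.  The signal
    model is linear in R1: S = S_BL (1 + dR1/R10) with dR1 = r1 C.
    """

    shape: tuple[int, int, int] = (16, 16, 2)
    interval_s: float = 2.0
    duration_s: float = 420.0
    tissue_params: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_REGIONS.items()}
    )
    aif: AIFSpec = AIFSpec()
    S_BL: float = 100.0
    R10: float = 1.0          # 1/s, uniform native relaxation rate
    r1: float = 4.5           # relaxivity [1/s/mM]
    noise_sigma: float = 0.0  # additive Gaussian on signal [a.u.]
    seed: int = 0

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.uniform(self.interval_s, self.duration_s)


def region_map(spec: PhantomSpec) -> np.ndarray:
    """Disjoint label image: quadrant tissue regions, an arterial stripe,
    and a background margin."""
    nx, ny, nz = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[1 : nx // 2, 1 : ny - 1, :] = TISSUE_A
    labels[nx // 2 : nx - 2, 1 : ny - 1, :] = TISSUE_B
    labels[nx - 2, 1 : ny - 1, :] = ARTERY
    return labels


def gen_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict]:
    """Generate the 4D signal image and its ground truth.

    Returns ``(signal, truth)`` where ``signal`` has shape
    ``spec.shape + (n_times,)`` and ``truth`` holds the label map, the
    per-region parameters, the AIF concentration curve and the scalar
    signal-model constants.  The seed determines only the noise; ground
    truth is seed-independent.
    """
    labels = region_map(spec)
    grid = spec.grid
    aif = gen_aif(grid, spec.aif)
    signal = np.zeros(spec.shape + (grid.n,))
    region_conc: dict[int, np.ndarray] = {}
    for label, params in spec.tissue_params.items():
        ct = model_forward("M.IC1.011", aif, grid, params)
        region_conc[label] = ct.values
    region_conc[ARTERY] = aif.values
    for label, conc in region_conc.items():
        if not np.any(labels == label):
            raise DomainError(f"region {label} is empty in this phantom shape")
        d_r1 = spec.r1 * conc
        s = spec.S_BL * (1.0 + d_r1 / spec.R10)
        signal[labels == label] = s
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, size=signal.shape)
        signal[labels == BACKGROUND] = 0.0  # background stays empty air
    truth = {
        "labels": labels,
        "tissue_params": {int(k): dict(v) for k, v in spec.tissue_params.items()},
        "S_BL": spec.S_BL,
        "R10": spec.R10,
        "r1": spec.r1,
        "aif": aif,
        "grid": grid,
    }
    return signal, truth


def region_mean_curve(signal: np.ndarray, labels: np.ndarray, label: int, grid: TimeGrid) -> Curve:
    """Arithmetic-mean signal curve over one labelled region."""
    sel = labels == label
    if not sel.any():
        raise DomainError(f"no voxels carry label {label}")
    return Curve(grid, signal[sel].mean(axis=0), unit="a.u.")


def write_phantom(spec: PhantomSpec, outdir: str | Path) -> dict[str, Path]:
    """Write the phantom as NIfTI + per-region CSV curves + a JSON sidecar.

    Returns the paths written.  The sidecar records the ground truth and
    the generation parameters so downstream runs are self-describing.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signal, truth = gen_phantom(spec)
    grid: TimeGrid = truth["grid"]
    paths: dict[str, Path] = {}

    img = nib.Nifti1Image(signal.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, spec.interval_s))
    paths["signal"] = outdir / "phantom.nii.gz"
    nib.save(img, paths["signal"])

    lab = nib.Nifti1Image(truth["labels"].astype(np.int16), affine=np.eye(4))
    paths["labels"] = outdir / "labels.nii.gz"
    nib.save(lab, paths["labels"])

    curves = {"time_s": grid.times}
    for label in sorted(truth["tissue_params"]):
        curves[f"region{label}"] = region_mean_curve(signal, truth["labels"], label, grid).values
    curves["artery"] = region_mean_curve(signal, truth["labels"], ARTERY, grid).values
    paths["curves"] = outdir / "curves.csv"
    pd.DataFrame(curves).to_csv(paths["curves"], index=False)

    sidecar = {
        "tissue_params": truth["tissue_params"],
        "S_BL": spec.S_BL,
        "R10": spec.R10,
        "r1": spec.r1,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "interval_s": spec.interval_s,
        "duration_s": spec.duration_s,
        "shape": list(spec.shape),
        "region_labels": {"background": BACKGROUND, "tissue_a": TISSUE_A,
                          "tissue_b": TISSUE_B, "artery": ARTERY},
    }
    paths["truth"] = outdir / "ground_truth.json"
    paths["truth"].write_text(json.dumps(sidecar, indent=2))
    return paths
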