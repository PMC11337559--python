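"""Executable analysis processes, keyed by lexicon process codes.

These are the concrete operations behind the worked ROI analysis: baseline
estimation, relative enhancement, AUC, threshold segmentation, maximum-AUC
voxel selection, model-free deconvolution with generalized cross-validation,
nonlinear least-squares kinetic model fitting, and AIC model selection.
:func:`execute_pipeline` binds LL-XML process codes to these operations and
runs an encoded pipeline on data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .codes import LexiconCode, format_code
from .curves import Curve, TimeGrid
from .errors import DomainError, ExecutionError, FitError
from .models import (
    ExchangeParameters,
    ToftsParameters,
    UptakeParameters,
    delta_r1_linear,
    exchange_forward,
    fp_from_fb,
    ps_from_e_fp,
    satrec_r1_fit,
    tofts_forward,
    uptake_forward,
)
from .pipeline import (
    Literal,
    ModelElement,
    PipelineDocument,
    ProcessNode,
    QuantityElement,
    SetEqualStatement,
)
from .registry import LexiconRegistry


# ---------------------------------------------------------------------------
# simple curve/image operations

def baseline_mean(S: Curve, n_baseline: int) -> float:
    """Arithmetic mean of the first ``n_baseline`` samples of a signal."""
    n = int(n_baseline)
    if not (1 <= n <= len(S.values)):
        raise DomainError(f"n_baseline must lie in [1, {len(S.values)}], got {n}")
    return float(np.mean(S.values[:n]))


def relative_enhancement(S: Curve, S_BL: float) -> Curve:
    """Relative enhancement (S - S_BL)/S_BL, unitless."""
    if S_BL <= 0:
        raise DomainError("baseline signal must be positive")
    return Curve(S.grid, (S.values - S_BL) / S_BL, unit="")


def auc(curve: Curve, t_start: float, t_end: float) -> float:
    """Trapezoidal integral of a curve over [t_start, t_end] seconds.

    Window endpoints may fall between samples; values there are obtained
    by linear interpolation.
    """
    t = curve.times
    if not (t[0] <= t_start < t_end <= t[-1]):
        raise DomainError(f"window [{t_start}, {t_end}] outside grid span [{t[0]}, {t[-1]}]")
    inside = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inside], [t_end]))
    vv = np.interp(tt, t, curve.values)
    return float(np.trapezoid(vv, tt))


@dataclass
class ROIMask:
    """Binary voxel mask plus a note on how it was produced."""

    mask: np.ndarray
    provenance: str = "manual"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def threshold_mask(image: np.ndarray, threshold: float) -> ROIMask:
    """Segment out background: mask is true where ``image >= threshold``."""
    if not np.isfinite(threshold):
        raise DomainError("threshold must be finite")
    m = np.asarray(image, dtype=float) >= threshold
    if not m.any():
        warnings.warn("threshold produced an empty mask", stacklevel=2)
    return ROIMask(m, provenance=f"threshold >= {threshold:g}")


def top_k_by_statistic(
    curve_stack: np.ndarray,
    grid: TimeGrid,
    mask: ROIMask,
    k: int,
    window: tuple[float, float],
) -> tuple[ROIMask, Curve]:
    """Select the k masked voxels with largest AUC and average their curves.

    ``curve_stack`` has the time axis last.  Ties at rank k are broken
    deterministically by ascending flat voxel index.  Returns the selection
    mask and the arithmetic-mean signal curve of the selected voxels.
    """
    stack = np.asarray(curve_stack, dtype=float)
    if stack.shape[:-1] != mask.mask.shape:
        raise DomainError("curve stack and mask shapes disagree")
    if not (1 <= k <= mask.n_voxels):
        raise DomainError(f"k must lie in [1, {mask.n_voxels}], got {k}")
    flat = stack.reshape(-1, stack.shape[-1])
    idx = np.flatnonzero(mask.mask.ravel())
    stats = np.array([auc(Curve(grid, flat[i]), window[0], window[1]) for i in idx])
    order = np.argsort(-stats, kind="stable")  # stable: ties keep index order
    chosen = idx[order[:k]]
    sel = np.zeros(flat.shape[0], dtype=bool)
    sel[chosen] = True
    mean_curve = Curve(grid, flat[chosen].mean(axis=0), unit="a.u.")
    return ROIMask(sel.reshape(mask.mask.shape), provenance=f"top-{k} AUC"), mean_curve


# ---------------------------------------------------------------------------
# GCV deconvolution

@dataclass
class DeconvolutionResult:
    impulse_response: Curve
    regularization_parameter: float
    gcv_score: float
    PA: float


def _convolution_matrix(input_values: np.ndarray, dt: float) -> np.ndarray:
    """Lower-triangular discrete convolution operator, trapezoid quadrature.

    Row i approximates integral_0^{t_i} input(t_i - tau) h(tau) dtau with
    half-weights on the end samples, so that the trapezoidal area of the
    recovered response is consistent with the forward operator.
    """
    n = input_values.size
    A = np.zeros((n, n))
    for i in range(1, n):
        A[i, : i + 1] = input_values[i::-1]
        A[i, 0] *= 0.5
        A[i, i] *= 0.5
    return A * dt


def gcv_deconvolve(response: Curve, input_curve: Curve, n_lambda: int = 50) -> DeconvolutionResult:
    """Model-free deconvolution with generalized cross-validation.

    Solves ``response = input (x) h`` for the impulse response h by
    Tikhonov-regularized least squares on the discrete convolution matrix,
    choosing the regularization weight at the minimum of the GCV score over
    a log-spaced grid (1e-6 ... 1e2).  The trapezoidal area of h is the
    arterial partial-volume correction factor PA.
    """
    if response.grid.times.shape != input_curve.grid.times.shape or not np.allclose(
        response.times, input_curve.times
    ):
        raise DomainError("curves must share one time grid")
    if not np.any(input_curve.values):
        raise DomainError("input curve is identically zero")
    grid = response.grid
    if not grid.is_uniform():
        uni = TimeGrid.uniform(grid.dt, grid.times[-1] - grid.times[0], grid.times[0])
        return gcv_deconvolve(response.resample(uni), input_curve.resample(uni), n_lambda)
    A = _convolution_matrix(input_curve.values, grid.dt)
    y = response.values
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    uty = U.T @ y
    n = y.size
    lambdas = np.logspace(-6, 2, n_lambda)
    best = None
    for lam in lambdas:
        f = s**2 / (s**2 + lam)
        resid = np.sum(((1.0 - f) * uty) ** 2) + (y @ y - uty @ uty)
        denom = (n - np.sum(f)) ** 2
        score = n * resid / denom
        if best is None or score < best[0]:
            best = (score, lam)
    score, lam = best
    h = Vt.T @ (s / (s**2 + lam) * uty)
    irf = Curve(grid, h, unit="1/s")
    pa = float(np.trapezoid(h, grid.times))
    return DeconvolutionResult(
        impulse_response=irf, regularization_parameter=float(lam),
        gcv_score=float(score), PA=pa,
    )


# ---------------------------------------------------------------------------
# kinetic model fitting

@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares model fit.

    Records the free/fixed split and the initial values so that rendered
    reports can state the optimizer settings alongside the estimates.
    """

    model_code: str
    parameters: dict[str, float]
    units: dict[str, str]
    free: tuple[str, ...]
    fixed: dict[str, float]
    initial: dict[str, float]
    rss: float
    n_points: int
    success: bool
    diagnostics: str = ""

    @property
    def n_free(self) -> int:
        return len(self.free)


# parameter order, OSIPI units, initial values and box bounds per model
_MODEL_SPECS = {
    "M.IC1.011": {
        "names": ("Ktrans", "ve"),
        "units": {"Ktrans": "1/min", "ve": "mL/100 mL"},
        "initial": {"Ktrans": 0.1, "ve": 20.0},
        "bounds": {"Ktrans": (0.0, 10.0), "ve": (1e-3, 100.0)},
    },
    "M.IC1.010": {
        "names": ("Fp", "vp", "PS"),
        "units": {"Fp": "mL/min/100 mL", "vp": "mL/100 mL", "PS": "mL/min/100 mL"},
        "initial": {"Fp": 2.0, "vp": 10.0, "PS": 0.2},
        "bounds": {"Fp": (0.0, 1e4), "vp": (1e-3, 100.0), "PS": (0.0, 1e4)},
    },
    "M.IC1.009": {
        "names": ("Fp", "PS", "vp", "ve"),
        "units": {
            "Fp": "mL/min/100 mL", "PS": "mL/min/100 mL",
            "vp": "mL/100 mL", "ve": "mL/100 mL",
        },
        "initial": {"Fp": 2.0, "PS": 0.2, "vp": 10.0, "ve": 20.0},
        "bounds": {"Fp": (0.0, 1e4), "PS": (0.0, 1e4), "vp": (1e-3, 100.0), "ve": (1e-3, 100.0)},
    },
}

#: quantity codes <-> kinetic parameter names, for pipeline execution
PARAM_CODES = {
    "Q.PH1.008": "Ktrans",
    "Q.PH1.001.[e]": "ve",
    "Q.PH1.001.[p]": "vp",
    "Q.PH1.002": "Fp",
    "Q.PH1.004": "PS",
}


def model_forward(model_code: str, aif: Curve, grid: TimeGrid, params: dict[str, float]) -> Curve:
    """Evaluate the forward model named by a lexicon model code."""
    if model_code == "M.IC1.011":
        return tofts_forward(aif, grid, ToftsParameters(params["Ktrans"], params["ve"]))
    if model_code == "M.IC1.010":
        return uptake_forward(aif, grid, UptakeParameters(params["Fp"], params["vp"], params["PS"]))
    if model_code == "M.IC1.009":
        return exchange_forward(
            aif, grid, ExchangeParameters(params["Fp"], params["PS"], params["vp"], params["ve"])
        )
    raise ExecutionError(f"no forward model registered for {model_code}", code=model_code)


def fit_model(
    model_code: str | LexiconCode,
    aif: Curve,
    tissue: Curve,
    free: tuple[str, ...] | None = None,
    fixed: dict[str, float] | None = None,
    initial: dict[str, float] | None = None,
) -> FitResult:
    """Nonlinear least-squares fit of a kinetic model to a tissue curve.

    ``free`` names the parameters the optimizer may vary (default: all);
    ``fixed`` holds values for the rest; ``initial`` overrides the default
    starting values.  Bounded trust-region least squares with non-negativity
    bounds is used.  Non-identifiable data yields ``success=False`` with
    diagnostics rather than an exception.
    """
    key = format_code(model_code) if isinstance(model_code, LexiconCode) else str(model_code)
    if key not in _MODEL_SPECS:
        raise ExecutionError(f"unknown or unfittable model code {key}", code=key)
    spec = _MODEL_SPECS[key]
    names = spec["names"]
    fixed = dict(fixed or {})
    free = tuple(free) if free is not None else tuple(n for n in names if n not in fixed)
    declared = set(free) | set(fixed)
    if declared != set(names):
        raise DomainError(
            f"free {sorted(free)} + fixed {sorted(fixed)} must cover exactly "
            f"the parameters of {key}: {names}"
        )
    init = {**spec["initial"], **(initial or {})}
    x0 = np.array([init[n] for n in free])
    lo = np.array([spec["bounds"][n][0] for n in free])
    hi = np.array([spec["bounds"][n][1] for n in free])
    y = tissue.values
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(aif.values))):
        raise FitError("non-finite data")

    def assemble(x):
        p = dict(fixed)
        p.update(zip(free, x))
        return p

    def residual(x):
        return model_forward(key, aif, tissue.grid, assemble(x)).values - y

    base = FitResult(
        model_code=key, parameters={}, units=spec["units"], free=free,
        fixed=fixed, initial={n: init[n] for n in free}, rss=np.inf,
        n_points=y.size, success=False,
    )
    if not np.any(aif.values):
        base.parameters = assemble(x0)
        base.diagnostics = "arterial input is identically zero: model not identifiable"
        return base
    try:
        sol = least_squares(
            residual, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
        )
    except Exception as exc:  # optimizer blow-up is data, not a crash
        base.parameters = assemble(x0)
        base.diagnostics = f"optimizer failure: {exc}"
        return base
    base.parameters = assemble(sol.x)
    base.rss = float(np.sum(sol.fun**2))
    base.success = bool(sol.success)
    base.diagnostics = sol.message
    return base


# ---------------------------------------------------------------------------
# AIC model selection

_RSS_FLOOR = 1e-12  # per-point floor avoids log(0) on perfect fits


def aic_select(fits: list[FitResult]) -> tuple[int, list[float]]:
    """Akaike information criterion over least-squares fits of one dataset.

    AIC = n ln(RSS/n) + 2k with k the number of free parameters.  The
    smallest AIC wins; exact ties go to the candidate with fewer free
    parameters.  All candidates must share the same number of data points.
    """
    if not fits:
        raise DomainError("need at least one candidate fit")
    n = fits[0].n_points
    if any(f.n_points != n for f in fits):
        raise DomainError("candidates must be fits of identical data (same n_points)")
    aics = [
        n * np.log(max(f.rss, n * _RSS_FLOOR) / n) + 2 * f.n_free for f in fits
    ]
    winner = min(range(len(fits)), key=lambda i: (aics[i], fits[i].n_free))
    return winner, [float(a) for a in aics]


# ---------------------------------------------------------------------------
# pipeline execution

def _exec_baseline(inputs, node, env):
    S, n = inputs[0], inputs[1]
    return (baseline_mean(S, int(n)),)


def _exec_relative_enhancement(inputs, node, env):
    return (relative_enhancement(inputs[0], float(inputs[1])),)


def _exec_delta_r1(inputs, node, env):
    S, S_BL, R10 = inputs[0], float(inputs[1]), float(inputs[2])
    return (delta_r1_linear(S, S_BL, R10),)


def _exec_auc(inputs, node, env):
    curve = inputs[0]
    return (auc(curve, curve.times[0], curve.times[-1]),)


def _exec_threshold(inputs, node, env):
    return (threshold_mask(np.asarray(inputs[0]), float(inputs[1])),)


def _exec_satrec(inputs, node, env):
    r10, m0 = satrec_r1_fit(inputs[0], inputs[1])
    return (r10, m0)


def _exec_gcv(inputs, node, env):
    result = gcv_deconvolve(inputs[0], inputs[1])
    return (result.impulse_response, result.PA)


def _exec_ps_from_e(inputs, node, env):
    return (ps_from_e_fp(float(inputs[0]), float(inputs[1])),)


def _exec_fp_from_fb(inputs, node, env):
    return (fp_from_fb(float(inputs[0]), float(inputs[1])),)


def _exec_fit(inputs, node, env):
    """Kinetic model fit: first curve input is the tissue response, second
    the arterial input; the Model child names the model; parameter-coded
    input quantities carry initial (free) or fixed values via their
    ``numericValue`` and ``type`` attributes."""
    models = [c for c in node.children if isinstance(c, ModelElement)]
    if len(models) != 1:
        raise ExecutionError(
            "model fitting needs exactly one Model child",
            code=format_code(node.code) if node.code else None,
        )
    model_key = format_code(models[0].code)
    curves = [v for v in inputs if isinstance(v, Curve)]
    if len(curves) < 2:
        raise ExecutionError("model fitting needs tissue and input curves", code=model_key)
    tissue, aif = curves[0], curves[1]
    fixed: dict[str, float] = {}
    initial: dict[str, float] = {}
    quantities = [c for c in node.children if isinstance(c, QuantityElement) and c.role == "input"]
    for q in quantities:
        if q.code is None:
            continue
        pname = PARAM_CODES.get(format_code(q.code))
        if pname is None or q.numeric_value is None:
            continue
        if q.fit_type == "fixed":
            fixed[pname] = q.numeric_value
        else:
            initial[pname] = q.numeric_value
    result = fit_model(model_key, aif, tissue, fixed=fixed or None, initial=initial or None)
    env["last_fit"] = result
    outputs = []
    for q in node.children:
        if isinstance(q, QuantityElement) and q.role == "output" and q.code is not None:
            key = format_code(q.code)
            if key == "Q.OP1.003":
                outputs.append(result.rss)
            else:
                pname = PARAM_CODES.get(key)
                if pname is None:
                    raise ExecutionError(f"cannot map output {key} to a model parameter", code=key)
                outputs.append(result.parameters[pname])
    return tuple(outputs)


def _exec_aic(inputs, node, env):
    fits = [v for v in inputs if isinstance(v, FitResult)]
    if not fits:
        fits = env.get("fits", [])
    winner, aics = aic_select(list(fits))
    env["aic_winner"] = winner
    return (min(aics),)


IMPLEMENTATIONS = {
    "P.BE1.001": _exec_baseline,
    "P.SC1.002": _exec_relative_enhancement,
    "P.SC1.001": _exec_delta_r1,
    "G.CD1.001": _exec_auc,
    "G.SE1.001": _exec_threshold,
    "P.NR1.001": _exec_satrec,
    "G.DC1.001": _exec_gcv,
    "P.PX1.001": _exec_ps_from_e,
    "P.PX1.002": _exec_fp_from_fb,
    "P.PE1.001": _exec_fit,
    "G.MS1.001": _exec_aic,
}


def _resolve_inputs(node: ProcessNode, env: dict) -> list:
    values = []
    for child in node.children:
        if isinstance(child, QuantityElement) and child.role == "input":
            if child.code is not None and PARAM_CODES.get(format_code(child.code)) and child.fit_type:
                continue  # kinetic fit parameter, consumed by _exec_fit via the node
            if child.numeric_value is not None:
                values.append(child.numeric_value)
                continue
            key = format_code(child.code) if child.code is not None else None
            if key is None or key not in env:
                raise ExecutionError(f"unbound input quantity {key or '<no code>'}", code=key)
            values.append(env[key])
    return values


def _apply_set_equal(node: ProcessNode, env: dict):
    for child in node.children:
        if isinstance(child, SetEqualStatement):
            key = format_code(child.left.code)
            if isinstance(child.right, Literal):
                env[key] = child.right.value
            else:
                rkey = format_code(child.right.code)
                if rkey not in env:
                    raise ExecutionError(f"SetEqual right side unbound: {rkey}", code=rkey)
                env[key] = env[rkey]


def _execute_node(node: ProcessNode, env: dict, outputs: dict):
    _apply_set_equal(node, env)
    subprocs = [c for c in node.children if isinstance(c, ProcessNode)]
    for sub in subprocs:
        _execute_node(sub, env, outputs)
    key = format_code(node.code) if node.code is not None else None
    impl = IMPLEMENTATIONS.get(key)
    if impl is None:
        if subprocs:
            return  # composite (derived) process: children did the work
        raise ExecutionError(f"unimplemented process {key}", code=key)
    values = _resolve_inputs(node, env)
    result = impl(values, node, env)
    out_elems = [
        c for c in node.children if isinstance(c, QuantityElement) and c.role == "output"
    ]
    for q, value in zip(out_elems, result):
        if q.code is not None:
            out_key = format_code(q.code)
            env[out_key] = value
            outputs[out_key] = value


def execute_pipeline(
    doc: PipelineDocument,
    bindings: dict[str, object] | None = None,
    registry: LexiconRegistry | None = None,
) -> dict[str, object]:
    """Execute an LL-XML document top to bottom.

    ``bindings`` seeds the environment (serialized quantity code -> data:
    curves, arrays, numbers).  SetEqual statements are applied before a
    node's children run.  Returns the outputs keyed by OutputQuantity code;
    unbound inputs and unimplemented process codes raise
    :class:`~caplex.errors.ExecutionError` naming the code.
    """
    env: dict[str, object] = dict(bindings or {})
    outputs: dict[str, object] = {}
    for node in doc.processes:
        if isinstance(node, ProcessNode):
            _execute_node(node, env, outputs)
    return outputs
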