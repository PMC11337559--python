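"""Kinetic and signal forward models for DCE-MRI.

Implements the standard indicator-kinetic models used in contrast-agent
perfusion analysis — the Tofts model, the two-compartment uptake model and
the two-compartment exchange model — together with the linear
signal-to-relaxation conversion, the saturation-recovery R1 fit, and the
perfusion identities relating E, PS, Fp, Fb and hematocrit.

Unit convention
---------------
Interface units are the lexicon's endorsed units: Ktrans in min^-1, flows
(Fp, PS, Fb) in mL/min/100 mL, volume fractions (vp, ve) in mL/100 mL,
times in seconds, relaxation rates in s^-1.  All internal computation is
carried out in base SI-like units (per-second rate constants and
dimensionless volume fractions); the conversion happens exactly once, at
the model boundary:

* rate [1/min]            -> /60      [1/s]
* flow [mL/min/100 mL]    -> /6000    [1/s]  (per unit tissue volume)
* volume [mL/100 mL]      -> /100     [dimensionless fraction]

Impulse-response curves are therefore returned in s^-1 on the seconds
grid; their trapezoidal area is the corresponding volume *fraction* (e.g.
the Tofts IRF integrates to ve/100).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .curves import Curve, TimeGrid
from .errors import DomainError, FitError

PER_MIN = 1.0 / 60.0          # min^-1 -> s^-1
FLOW = 1.0 / 6000.0           # mL/min/100 mL -> s^-1
VOL = 1.0 / 100.0             # mL/100 mL -> fraction


@dataclass(frozen=True)
class ToftsParameters:
    """Tofts model parameters: Ktrans [1/min], ve [mL/100 mL]."""

    Ktrans: float
    ve: float

    def __post_init__(self):
        if self.Ktrans < 0:
            raise DomainError("Ktrans must be >= 0")
        if not (0 < self.ve <= 100):
            raise DomainError("ve must lie in (0, 100] mL/100 mL")


@dataclass(frozen=True)
class UptakeParameters:
    """Two-compartment uptake model parameters.

    Fp and PS in mL/min/100 mL, vp in mL/100 mL.  Derived quantities:
    extraction fraction E = PS/(PS + Fp), capillary-plasma mean transit
    time MTTcp = vp/(Fp + PS) in seconds, and whole-blood flow
    Fb = Fp/(1 - Hct) given a hematocrit.
    """

    Fp: float
    vp: float
    PS: float

    def __post_init__(self):
        if min(self.Fp, self.vp, self.PS) < 0:
            raise DomainError("uptake parameters must be non-negative")
        if self.Fp + self.PS == 0:
            raise DomainError("Fp + PS must be positive")

    @property
    def E(self) -> float:
        return self.PS / (self.PS + self.Fp)

    @property
    def MTTcp(self) -> float:
        """Capillary-plasma mean transit time [s]: vp/(Fp + PS)."""
        return (self.vp * VOL) / ((self.Fp + self.PS) * FLOW)

    def Fb(self, Hct: float) -> float:
        if not (0 <= Hct < 1):
            raise DomainError("Hct must lie in [0, 1)")
        return self.Fp / (1.0 - Hct)


@dataclass(frozen=True)
class ExchangeParameters:
    """Two-compartment exchange model parameters (Fp, PS, vp, ve)."""

    Fp: float
    PS: float
    vp: float
    ve: float

    def __post_init__(self):
        if min(self.Fp, self.PS, self.vp, self.ve) < 0:
            raise DomainError("exchange parameters must be non-negative")
        if self.vp <= 0 or self.ve <= 0:
            raise DomainError("vp and ve must be positive (degenerate volumes)")


@dataclass(frozen=True)
class RelaxationState:
    """Relaxation-side quantities of one analysis: native rates, the
    dynamic rate change, hematocrit and the arterial partial-volume
    correction factor."""

    R10: float                  # 1/s, tissue
    R10_blood: float            # 1/s, venous whole blood
    deltaR1: Curve | None = None
    Hct: float = 0.45
    PA: float = 1.0

    def __post_init__(self):
        if self.R10 <= 0 or self.R10_blood <= 0:
            raise DomainError("native relaxation rates must be positive")
        if not (0 <= self.Hct < 1):
            raise DomainError("Hct must lie in [0, 1)")
        if not (0 < self.PA <= 1):
            raise DomainError("PA must lie in (0, 1]")


# ---------------------------------------------------------------------------
# discrete convolution (trapezoid quadrature)

def convolve(irf: Curve, aif: Curve) -> np.ndarray:
    """Causal convolution of an impulse response [1/s] with an input curve.

    Uses trapezoidal quadrature on a uniform grid; non-uniform grids are
    resampled by linear interpolation onto a uniform grid of the same span
    and mean spacing, then interpolated back.
    """
    if irf.grid.times.shape != aif.grid.times.shape or not np.allclose(
        irf.times, aif.times
    ):
        raise DomainError("curves must share one time grid")
    grid = irf.grid
    if not grid.is_uniform():
        uni = TimeGrid.uniform(grid.dt, grid.times[-1] - grid.times[0], grid.times[0])
        out = convolve(irf.resample(uni), aif.resample(uni))
        return np.interp(grid.times, uni.times, out)
    dt = grid.dt
    h, a = irf.values, aif.values
    full = np.convolve(h, a)[: grid.n] * dt
    # trapezoid endpoint correction: half-weight the two end samples
    full -= 0.5 * dt * (h[0] * a + h * a[0])
    return full


# ---------------------------------------------------------------------------
# Tofts model

def tofts_irf(grid: TimeGrid, p: ToftsParameters) -> Curve:
    """Tofts impulse response I(t) = Ktrans exp(-(Ktrans/ve) t).

    Returned in internal units (s^-1 amplitude, seconds grid): the value at
    t = 0 is Ktrans/60 and the trapezoidal area is ve/100.
    """
    k = p.Ktrans * PER_MIN
    ve = p.ve * VOL
    vals = k * np.exp(-(k / ve) * grid.times)
    return Curve(grid, vals, unit="1/s")


def tofts_forward(
    aif: Curve, grid: TimeGrid, p: ToftsParameters, method: str = "conv"
) -> Curve:
    """Tissue curve of the Tofts model, dCt/dt = Ktrans Ca - (Ktrans/ve) Ct.

    ``method='conv'`` evaluates the convolution of the AIF with the Tofts
    IRF; ``method='ode'`` integrates the differential equation directly.
    The two agree on smooth inputs and serve as mutual cross-checks.
    """
    if method == "conv":
        vals = convolve(tofts_irf(grid, p), aif)
        return Curve(grid, vals, unit=aif.unit)
    if method != "ode":
        raise ValueError(f"unknown method {method!r}")
    k = p.Ktrans * PER_MIN
    ve = p.ve * VOL
    t, a = aif.times, aif.values

    def rhs(ti, c):
        return k * np.interp(ti, t, a) - (k / ve) * c

    sol = solve_ivp(
        rhs, (t[0], t[-1]), [0.0], t_eval=t, max_step=grid.dt, rtol=1e-8, atol=1e-12
    )
    if not sol.success:  # pragma: no cover - stiffness never triggers here
        raise FitError(f"ODE integration failed: {sol.message}")
    return Curve(grid, sol.y[0], unit=aif.unit)


# ---------------------------------------------------------------------------
# two-compartment uptake model

def uptake_irf(grid: TimeGrid, p: UptakeParameters) -> Curve:
    """Uptake-model impulse response I(t) = Fp [E + (1-E) exp(-t/Tcp)].

    Internal units: the value at t = 0 is Fp/6000 [1/s]; for PS = 0 the
    area is vp/100 (monoexponential vascular transit).
    """
    fp = p.Fp * FLOW
    ps = p.PS * FLOW
    vp = p.vp * VOL
    e = p.E
    if vp == 0:
        # zero-volume capillary: transit is instantaneous, I collapses to
        # its plateau E*Fp plus an unresolvable delta; reject instead
        raise DomainError("vp must be positive for a resolvable uptake IRF")
    tcp = vp / (fp + ps)
    vals = fp * (e + (1.0 - e) * np.exp(-grid.times / tcp))
    return Curve(grid, vals, unit="1/s")


def uptake_forward(aif: Curve, grid: TimeGrid, p: UptakeParameters) -> Curve:
    """Tissue curve of the uptake model (convolution of AIF with IRF)."""
    return Curve(grid, convolve(uptake_irf(grid, p), aif), unit=aif.unit)


# ---------------------------------------------------------------------------
# two-compartment exchange model

def _exchange_system(p: ExchangeParameters):
    """State matrix A, input vector b and volume weights w (fractions/s)."""
    fp, ps = p.Fp * FLOW, p.PS * FLOW
    vp, ve = p.vp * VOL, p.ve * VOL
    A = np.array([[-(fp + ps) / vp, ps / vp], [ps / ve, -ps / ve]])
    b = np.array([fp / vp, 0.0])
    w = np.array([vp, ve])
    return A, b, w


def exchange_irf(grid: TimeGrid, p: ExchangeParameters) -> Curve:
    """Biexponential impulse response of the two-compartment exchange model.

    Derived from the mass-balance pair
    ``vp dCp/dt = Fp(Ca - Cp) + PS(Ce - Cp)``,
    ``ve dCe/dt = PS(Cp - Ce)``
    with Ct = vp Cp + ve Ce: I(t) = w' exp(A t) b.
    """
    A, b, w = _exchange_system(p)
    lam, V = np.linalg.eig(A)
    coef = V @ (np.linalg.solve(V, b)[:, None] * np.exp(np.outer(lam, grid.times)))
    vals = w @ coef
    return Curve(grid, np.real(vals), unit="1/s")


def exchange_forward(
    aif: Curve, grid: TimeGrid, p: ExchangeParameters, method: str = "conv"
) -> Curve:
    """Tissue curve of the two-compartment exchange model."""
    if method == "conv":
        return Curve(grid, convolve(exchange_irf(grid, p), aif), unit=aif.unit)
    if method != "ode":
        raise ValueError(f"unknown method {method!r}")
    A, b, w = _exchange_system(p)
    t, a = aif.times, aif.values

    def rhs(ti, c):
        return A @ c + b * np.interp(ti, t, a)

    sol = solve_ivp(
        rhs, (t[0], t[-1]), [0.0, 0.0], t_eval=t, max_step=grid.dt, rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover
        raise FitError(f"ODE integration failed: {sol.message}")
    return Curve(grid, w @ sol.y, unit=aif.unit)


# ---------------------------------------------------------------------------
# perfusion identities

def ps_from_e_fp(E: float, Fp: float) -> float:
    """PS = E Fp / (1 - E); inverse of E = PS/(PS + Fp)."""
    if not (0 <= E < 1):
        raise DomainError("E must lie in [0, 1)")
    return E * Fp / (1.0 - E)


def e_from_ps_fp(PS: float, Fp: float) -> float:
    """Extraction fraction E = PS/(PS + Fp)."""
    if PS + Fp <= 0:
        raise DomainError("PS + Fp must be positive")
    return PS / (PS + Fp)


def fp_from_fb(Fb: float, Hct: float) -> float:
    """Plasma flow from whole-blood flow: Fp = (1 - Hct) Fb."""
    if not (0 <= Hct < 1):
        raise DomainError("Hct must lie in [0, 1)")
    return (1.0 - Hct) * Fb


# ---------------------------------------------------------------------------
# signal <-> relaxation

def delta_r1_linear(S: Curve, S_BL: float, R10: float) -> Curve:
    """Linear signal model: dR1(t) = R10 (S(t) - S_BL)/S_BL, in s^-1."""
    if S_BL <= 0:
        raise DomainError("baseline signal must be positive")
    if R10 <= 0:
        raise DomainError("R10 must be positive")
    return Curve(S.grid, R10 * (S.values - S_BL) / S_BL, unit="1/s")


def satrec_signal(TD_s: np.ndarray, M0: float, R1: float) -> np.ndarray:
    """Ideal saturation-recovery signal S(TD) = M0 (1 - exp(-TD R1))."""
    return M0 * (1.0 - np.exp(-np.asarray(TD_s, float) * R1))


def satrec_r1_fit(delays_ms, signals) -> tuple[float, float]:
    """Fit saturation-recovery data to a monoexponential recovery.

    Least-squares fit of S(TD) = M0 (1 - exp(-TD * R10)) with delays given
    in milliseconds.  Returns (R10 [1/s], M0 [a.u.]).
    """
    td = np.asarray(delays_ms, float) / 1000.0
    s = np.asarray(signals, float)
    if td.size < 3 or np.unique(td).size < 3:
        raise FitError("need at least 3 distinct prepulse delays")
    if np.ptp(s) == 0 or not np.all(np.isfinite(s)):
        raise FitError("signals are constant or non-finite; R1 not identifiable")
    smax = float(np.max(np.abs(s)))
    try:
        popt, _ = curve_fit(
            satrec_signal, td, s, p0=(smax, 1.0 / max(np.median(td), 1e-6)),
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"saturation-recovery fit failed: {exc}") from exc
    M0, R10 = float(popt[0]), float(popt[1])
    return R10, M0
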