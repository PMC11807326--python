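"""Parametric map reconstruction: ADC from two-b-value DWI and K^trans
from DCE concentration-time curves via the standard Tofts model.

ADC is the closed-form log-ratio of the b=0 and b=b1 signals.  The Tofts
model describes contrast-agent exchange between blood plasma and the
extravascular extracellular space:

    C_t(t) = K^trans * int_0^t C_p(tau) exp(-k_ep (t - tau)) dtau,

with k_ep = K^trans / v_e.  The arterial input function C_p defaults to the
classic biexponential population curve; inputs are assumed to be tissue
concentrations already (signal-to-concentration conversion is upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

#: Biexponential population AIF parameters (Weinmann): amplitudes in
#: mmol/L per mmol/kg dose, decay rates in 1/min.
AIF_A = (3.99, 4.78)
AIF_M = (0.144, 0.0111)

KTRANS_BOUNDS = (0.0, 5.0)  # min^-1
VE_BOUNDS = (0.001, 1.0)


@dataclass(frozen=True)
class DwiPair:
    """Signal grids at b=0 (``s0``) and b=``b1`` s/mm^2 (``sb``)."""

    s0: np.ndarray
    sb: np.ndarray
    b1: float = 1000.0

    def __post_init__(self) -> None:
        s0 = np.asarray(self.s0, dtype=float)
        sb = np.asarray(self.sb, dtype=float)
        if s0.shape != sb.shape:
            raise ValueError(f"DWI grid shapes differ: {s0.shape} vs {sb.shape}")
        if self.b1 <= 0:
            raise ValueError("b1 must be positive")
        object.__setattr__(self, "s0", s0)
        object.__setattr__(self, "sb", sb)


@dataclass(frozen=True)
class AdcResult:
    """ADC grid in 10^-6 mm^2/s plus per-voxel quality flags."""

    adc: np.ndarray
    invalid: np.ndarray  # non-positive signal, ADC undefined (set to 0)
    clamped: np.ndarray  # negative ADC clamped to 0


@dataclass(frozen=True)
class ToftsParams:
    """Standard-Tofts parameters; ``kep`` = ktrans/ve (1/min)."""

    ktrans: float  # min^-1
    ve: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("ktrans must be non-negative")
        if self.ktrans > 0 and not (0 < self.ve <= 1):
            raise ValueError("ve must lie in (0, 1] when ktrans > 0")

    @property
    def kep(self) -> float:
        return self.ktrans / self.ve if self.ktrans > 0 else 0.0


@dataclass
class ToftsFit:
    params: ToftsParams
    residual_norm: float
    converged: bool = True
    non_identifiable: bool = False
    fallback: bool = False


@dataclass(frozen=True)
class DceSeries:
    """Tissue concentration curves on a shared time grid with an AIF."""

    ct: np.ndarray  # (..., n_phases)
    t_grid: np.ndarray  # minutes, strictly increasing from 0
    cp: np.ndarray  # AIF samples on t_grid

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing and start at 0")
        if np.asarray(self.ct).shape[-1] != t.size or np.asarray(self.cp).size != t.size:
            raise ValueError("ct/cp must be sampled on t_grid")
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "cp", np.asarray(self.cp, dtype=float))
        object.__setattr__(self, "ct", np.asarray(self.ct, dtype=float))


def default_time_grid(n_phases: int = 30, duration_min: float = 4.7) -> np.ndarray:
    """Uniform DCE acquisition grid: 30 phases over 4.7 minutes."""
    return np.linspace(0.0, duration_min, n_phases)


def population_aif(t_grid: np.ndarray, dose_mmol_per_kg: float = 0.1) -> np.ndarray:
    """Biexponential population arterial input function on ``t_grid``."""
    t = np.asarray(t_grid, dtype=float)
    return dose_mmol_per_kg * sum(a * np.exp(-m * t) for a, m in zip(AIF_A, AIF_M))


def compute_adc(dwi: DwiPair) -> AdcResult:
    """Per-voxel ADC = ln(S0/Sb)/b1, reported in 10^-6 mm^2/s.

    Voxels with non-positive signal in either image are flagged invalid
    (ADC set to 0); physically meaningless negative ADC values (signal
    increase with diffusion weighting) are clamped to 0 and flagged.
    """
    valid = (dwi.s0 > 0) & (dwi.sb > 0)
    adc = np.zeros_like(dwi.s0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(dwi.s0[valid] / dwi.sb[valid]) / dwi.b1 * 1e6
    clamped = valid & (adc < 0)
    if clamped.any():
        log.warning("compute_adc: clamped %d negative-ADC voxels to 0", int(clamped.sum()))
    adc[clamped] = 0.0
    return AdcResult(adc=adc, invalid=~valid, clamped=clamped)


def tofts_concentration(params: ToftsParams, t_grid: np.ndarray, cp: np.ndarray) -> np.ndarray:
    """Forward Tofts model by trapezoidal convolution on the grid."""
    t = np.asarray(t_grid, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if params.ktrans == 0:
        return np.zeros_like(t)
    kep = params.kep
    n = t.size
    # row i integrates cp(tau) exp(-kep (t_i - tau)) over tau in [0, t_i]
    # with trapezoid weights; evaluated as one masked matrix product.
    decay = np.exp(-kep * np.clip(t[:, None] - t[None, :], 0.0, None))
    dt = np.diff(t)
    w = np.zeros((n, n))
    # trapezoid coefficients on the sub-grid t[0..i]
    for i in range(1, n):
        w[i, 0] = dt[0] / 2
        w[i, i] = dt[i - 1] / 2
        if i > 1:
            w[i, 1:i] = (dt[:i - 1] + dt[1:i]) / 2
    ct = params.ktrans * ((w * np.tril(decay)) @ cp)
    ct[0] = 0.0
    return ct


def _coarse_grid(ct, t_grid, cp, n=20, top=1):
    """Best `top` (ktrans, ve) pairs on a log-spaced coarse grid."""
    kts = np.geomspace(1e-3, KTRANS_BOUNDS[1], n)
    ves = np.geomspace(VE_BOUNDS[0], VE_BOUNDS[1], n)
    cand = []
    for kt in kts:
        for ve in ves:
            r = tofts_concentration(ToftsParams(kt, ve), t_grid, cp) - ct
            cand.append((float(r @ r), kt, ve))
    cand.sort()
    if top == 1:
        return cand[:1]
    # greedy diverse selection: the residual landscape has flat ridges
    # (e.g. large kep), so starts must be spread out in log-parameter space
    chosen: list[tuple[float, float, float]] = []
    for obj, kt, ve in cand:
        if all(
            abs(np.log(kt) - np.log(k2)) > 0.5 or abs(np.log(ve) - np.log(v2)) > 0.5
            for _, k2, v2 in chosen
        ) or not chosen:
            chosen.append((obj, kt, ve))
        if len(chosen) == top:
            break
    return chosen


def fit_tofts(ct: np.ndarray, t_grid: np.ndarray, cp: np.ndarray) -> ToftsFit:
    """Bounded nonlinear least-squares inversion of the Tofts model.

    Returns ktrans=0 with a non-identifiability flag for an all-zero
    curve (ve has no influence there); falls back to a coarse grid search
    if the local optimizer fails to converge.
    """
    ct = np.asarray(ct, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if t.size < 5:
        raise ValueError("at least 5 time points are required")
    if not np.any(ct):
        return ToftsFit(ToftsParams(0.0, 1.0), 0.0, non_identifiable=True)

    def resid(x):
        return tofts_concentration(ToftsParams(x[0], x[1]), t, cp) - ct

    best_x, best_obj, converged = None, np.inf, False
    for _, kt0, ve0 in _coarse_grid(ct, t, cp, n=15, top=3):
        try:
            sol = least_squares(
                resid,
                x0=[kt0, ve0],
                bounds=([KTRANS_BOUNDS[0], VE_BOUNDS[0]], [KTRANS_BOUNDS[1], VE_BOUNDS[1]]),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        obj = float(sol.fun @ sol.fun)
        if np.isfinite(obj) and obj < best_obj:
            best_x, best_obj, converged = sol.x, obj, bool(sol.success)
    if best_x is None:
        (obj, kt, ve), = _coarse_grid(ct, t, cp, n=50, top=1)
        log.warning("fit_tofts: optimizer did not converge; coarse-grid fallback used")
        return ToftsFit(ToftsParams(kt, ve), float(np.sqrt(obj)), converged=False, fallback=True)
    return ToftsFit(ToftsParams(float(best_x[0]), float(best_x[1])), float(np.sqrt(best_obj)),
                    converged=converged)


def fit_tofts_map(series: DceSeries, mask: np.ndarray | None = None) -> np.ndarray:
    """Fit the Tofts model voxel-wise; returns K^trans in 10^-3 min^-1."""
    ct = series.ct.reshape(-1, series.t_grid.size)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
    else:
        sel = np.ones(ct.shape[0], dtype=bool)
    out = np.zeros(ct.shape[0])
    for i in np.flatnonzero(sel):
        out[i] = fit_tofts(ct[i], series.t_grid, series.cp).params.ktrans * 1e3
    return out.reshape(series.ct.shape[:-1])
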