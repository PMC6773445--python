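"""Kinetic analysis of sampled growth curves.

Derivatives are estimated by local least-squares quadratic fits in a sliding
time window (default half-width 3 h, i.e. 7 points at hourly sampling); at the
series ends the window shrinks one-sidedly so estimates span the full series.
From these we derive the transepithelial fluid flux Ω = (dVl/dt)/Sl, the
tissue-growth and surface-area product-rule decompositions, left/right
asymmetry metrics, and the flux-deficit (catch-up) regression.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .datatypes import MorphoTimeSeries, PairedExperiment, ShellGeometry
from . import units

__all__ = [
    "shell_from_volumes", "quadratic_window_fit", "fit_series",
    "compute_flux", "tissue_growth_decomposition", "surface_decomposition",
    "asymmetry_metrics", "flux_deficit_regression",
    "FluxSeries", "SurfaceDecomposition", "TissueGrowthDecomposition",
]

DEFAULT_HALF_WINDOW = 3.0


def shell_from_volumes(Vl_pl: float, Vo_pl: float) -> ShellGeometry:
    """Sphere-equivalent shell from lumen and total volumes (pl)."""
    if Vo_pl <= Vl_pl:
        raise ValueError("require Vo > Vl")
    if Vl_pl < 0:
        raise ValueError("volumes must be non-negative")
    Rl = (3.0 * units.pl_to_um3(Vl_pl) / (4.0 * math.pi)) ** (1.0 / 3.0)
    Ro = (3.0 * units.pl_to_um3(Vo_pl) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return ShellGeometry(Rl=Rl, Ro=Ro)


def quadratic_window_fit(t: np.ndarray, y: np.ndarray, t_eval: float,
                         half_window: float = DEFAULT_HALF_WINDOW
                         ) -> tuple[float, float]:
    """Local quadratic least squares: (fitted value, first derivative).

    Points within ±half_window of ``t_eval`` are used; if fewer than three
    fall inside (at the series ends), the window grows one-sidedly into the
    interior until three points are available.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    mask = np.abs(t - t_eval) <= half_window + 1e-9
    if mask.sum() < 3:
        order = np.argsort(np.abs(t - t_eval))
        if t.size < 3:
            raise ValueError("need at least 3 points for a quadratic fit")
        mask = np.zeros(t.size, bool)
        mask[order[:3]] = True
    tw = t[mask] - t_eval
    coeffs = np.polyfit(tw, y[mask], 2)
    return float(np.polyval(coeffs, 0.0)), float(coeffs[1])


def fit_series(t: np.ndarray, y: np.ndarray,
               half_window: float = DEFAULT_HALF_WINDOW,
               t_eval: Optional[np.ndarray] = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed quadratic fit at every requested time: (t, value, slope)."""
    te = np.asarray(t if t_eval is None else t_eval, float)
    vals = np.empty(te.size)
    slopes = np.empty(te.size)
    for i, ti in enumerate(te):
        vals[i], slopes[i] = quadratic_window_fit(t, y, ti, half_window)
    return te, vals, slopes


@dataclass
class FluxSeries:
    """Fluid flux Ω(t) (µm/hr) and its ingredients."""

    t: np.ndarray
    Omega: np.ndarray
    dVl_dt: np.ndarray       # pl/hr
    Sl_fit: np.ndarray       # µm²

    def mean_over(self, t0: float, t1: float) -> float:
        m = (self.t >= t0) & (self.t <= t1)
        return float(np.mean(self.Omega[m]))


def compute_flux(t: np.ndarray, Vl_pl: np.ndarray, Sl_um2: np.ndarray,
                 half_window: float = DEFAULT_HALF_WINDOW) -> FluxSeries:
    """Ω(t) = (dVl/dt)/Sl with quadratic-window derivatives.

    Vl in pl, Sl in µm²; Ω returned in µm/hr (= µm³/µm²/hr).
    """
    t = np.asarray(t, float)
    Sl_um2 = np.asarray(Sl_um2, float)
    if np.asarray(Vl_pl).shape != t.shape or Sl_um2.shape != t.shape:
        raise ValueError("Vl and Sl must be aligned with t")
    if np.any(Sl_um2 <= 0):
        raise ValueError("surface area must be positive at evaluated points")
    _, _, dvl = fit_series(t, Vl_pl, half_window)
    _, sl_fit, _ = fit_series(t, Sl_um2, half_window)
    # a local quadratic can undershoot a strongly convex early curve; the
    # datum itself is the better denominator there
    sl_fit = np.where(sl_fit > 0, sl_fit, Sl_um2)
    omega = units.pl_to_um3(dvl) / sl_fit
    return FluxSeries(t=t, Omega=omega, dVl_dt=dvl, Sl_fit=sl_fit)


def flux_from_series(m: MorphoTimeSeries,
                     half_window: float = DEFAULT_HALF_WINDOW) -> FluxSeries:
    return compute_flux(m.t, m.Vl, m.Sl, half_window)


@dataclass
class TissueGrowthDecomposition:
    """j = dVt/dt split into division (s·dN/dt) and resizing (N·ds/dt), pl/hr."""

    t: np.ndarray
    j: np.ndarray
    division_term: np.ndarray
    resizing_term: np.ndarray

    @property
    def offsetting(self) -> np.ndarray:
        """True where the two terms cancel to within their own scale."""
        scale = np.abs(self.division_term) + np.abs(self.resizing_term)
        return np.abs(self.j) < 0.2 * np.maximum(scale, 1e-12)


def tissue_growth_decomposition(t, N, s, half_window=DEFAULT_HALF_WINDOW
                                ) -> TissueGrowthDecomposition:
    """Product rule on Vt = N·s: j = s·dN/dt + N·ds/dt (pl/hr)."""
    t = np.asarray(t, float)
    _, n_fit, dn = fit_series(t, N, half_window)
    _, s_fit, ds = fit_series(t, s, half_window)
    division = s_fit * dn
    resizing = n_fit * ds
    return TissueGrowthDecomposition(
        t=t, j=division + resizing,
        division_term=division, resizing_term=resizing)


@dataclass
class SurfaceDecomposition:
    """dSl/dt split into stretching (N·dψ/dt) and division (ψ·dN/dt), µm²/hr."""

    t: np.ndarray
    total_rate: np.ndarray
    stretch_term: np.ndarray
    division_term: np.ndarray
    break_even_time: Optional[float]


def surface_decomposition(t, Sl, N, half_window=DEFAULT_HALF_WINDOW
                          ) -> SurfaceDecomposition:
    """Decompose lumenal surface-area growth; find the break-even time.

    psi is derived as Sl/N.  The break-even time is the linearly interpolated
    crossing where the division term first exceeds the stretching term and
    stays ahead (a sustained crossing — an isolated noise wiggle across zero
    is not a regime change); if no crossing exists in the span it is None.
    """
    t = np.asarray(t, float)
    psi = np.asarray(Sl, float) / np.maximum(np.asarray(N, float), 1.0)
    _, n_fit, dn = fit_series(t, N, half_window)
    _, psi_fit, dpsi = fit_series(t, psi, half_window)
    stretch = n_fit * dpsi
    division = psi_fit * dn
    diff = division - stretch
    break_even = None
    sign = diff > 0

    def sustained(i: int) -> bool:
        ahead = sign[i:min(i + 4, sign.size)]
        return ahead.sum() >= max(len(ahead) - 1, 1)

    if sign[0] and sustained(0):
        break_even = float(t[0])
    else:
        for i in np.nonzero(sign[1:] & ~sign[:-1])[0]:
            if sustained(i + 1):
                # refine by the root of the locally linearised difference:
                # the point estimate from two noisy samples alone is high
                # variance, while the difference trend is locally linear
                f = -diff[i] / (diff[i + 1] - diff[i])
                t_cross = float(t[i] + f * (t[i + 1] - t[i]))
                w = np.abs(t - t_cross) <= 4.0 + 1e-9
                if w.sum() >= 4:
                    b, a = np.polyfit(t[w], diff[w], 1)
                    if b > 0:
                        t_root = -a / b
                        if t[0] <= t_root <= t[-1]:
                            t_cross = float(t_root)
                break_even = t_cross
                break
    return SurfaceDecomposition(
        t=t, total_rate=stretch + division, stretch_term=stretch,
        division_term=division, break_even_time=break_even)


@dataclass
class AsymmetrySeries:
    t: np.ndarray
    dVl_rel: np.ndarray     # (Vl_control − Vl_punctured)/Vl_control
    dh_rel: np.ndarray      # same for mean (medial+lateral) wall thickness


def asymmetry_metrics(pair: PairedExperiment) -> AsymmetrySeries:
    """Normalized left/right volume and thickness asymmetry."""
    left, right = pair.left, pair.right
    if not np.allclose(left.t, right.t):
        raise ValueError("paired series must share a time grid")
    if np.any(left.Vl <= 0):
        raise ValueError("unpunctured lumen volume must be positive")
    dvl = (left.Vl - right.Vl) / left.Vl
    hl, hr = left.h_mean, right.h_mean
    dh = (hl - hr) / np.maximum(hl, 1e-9)
    return AsymmetrySeries(t=left.t, dVl_rel=dvl, dh_rel=dh)


@dataclass
class FluxDeficitFit:
    kappa_hat: float
    intercept: float
    kappa_se: float
    r_squared: float
    n_points: int
    result: object    # statsmodels fit, for diagnostics


def flux_deficit_regression(pairs: Sequence[PairedExperiment],
                            half_window: float = DEFAULT_HALF_WINDOW,
                            t_min: Optional[float] = None) -> FluxDeficitFit:
    """OLS of excess flux (Ω̃ − Ω) on fractional volume deficit ΔVl/Vl.

    Per-time (deficit, excess-flux) points are averaged across pairs sharing
    a time grid before regressing — each regression point is a cohort mean,
    which suppresses the errors-in-variables attenuation that per-embryo
    deficits would otherwise cause.  The pool starts one full fit window
    after the first puncture event so that no quadratic window straddles the
    volume discontinuity (a window containing the instantaneous loss yields
    a meaningless derivative).  The slope estimates the catch-up gain κ in
    µm/hr per unit fractional deficit.
    """
    t = pairs[0].left.t
    oms, defs = [], []
    for pair in pairs:
        if not np.allclose(pair.left.t, t):
            raise ValueError("pairs must share a time grid for pooling")
        om_l = flux_from_series(pair.left, half_window).Omega
        om_r = flux_from_series(pair.right, half_window).Omega
        oms.append(om_r - om_l)
        defs.append((pair.left.Vl - pair.right.Vl) / pair.left.Vl)
    y_t = np.mean(oms, axis=0)
    x_t = np.mean(defs, axis=0)
    t0 = t_min
    if t0 is None:
        punctures = [e.t for p in pairs for e in p.events
                     if e.kind == "puncture"]
        t0 = (min(punctures) + half_window) if punctures else t[0]
    m = t >= t0 + 1e-9
    x = x_t[m]
    y = y_t[m]
    if x.size < 5:
        raise ValueError("need at least 5 pooled (deficit, flux) points")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate design: all deficits equal")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return FluxDeficitFit(
        kappa_hat=float(res.params[1]), intercept=float(res.params[0]),
        kappa_se=float(res.bse[1]), r_squared=float(res.rsquared),
        n_points=int(x.size), result=res)
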