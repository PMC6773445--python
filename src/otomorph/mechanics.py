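"""Wall mechanics of the pressurised vesicle.

For a thin spherical shell of radius R and thickness h under lumenal pressure
P, force balance (Laplace) gives the in-plane tissue stress sigma = P*R/(2h).
On long timescales the epithelium flows like a viscous fluid, for which the
Stokes relation in spherical geometry reads sigma = 4*mu*(1/R)(dR/dt).
Equating the two yields the effective-viscosity estimator

    mu = P * R**2 / (8 * h * dR/dt),

which converts interval-averaged pressure and morphometric measurements into
a tissue viscosity.  The published uncertainty on mu uses a specific
propagation formula (prefactor 1/8, coefficient 2 on the radius term) that
reproduces the published SD table; the textbook first-order formula is also
provided.  Short-time elasticity is captured by a Maxwell element.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import WallMaterial

__all__ = [
    "laplace_stress", "stokes_stress", "effective_viscosity",
    "ViscosityEstimate", "propagate_viscosity_error", "viscosity_table",
    "maxwell_response", "estimate_material_from_puncture",
]


def laplace_stress(P: float, R: float, h: float) -> float:
    """In-plane wall stress sigma = P*R/(2h), Pa (P in Pa, R and h in µm)."""
    if h <= 0 or R <= 0:
        raise ValueError("require R > 0 and h > 0")
    return P * R / (2.0 * h)


def stokes_stress(mu_pa_s: float, R: float, Rdot_um_s: float) -> float:
    """Viscous wall stress sigma = 4*mu*(dR/dt)/R, Pa.

    mu in Pa·s, R in µm, Rdot in µm/s.
    """
    if R <= 0:
        raise ValueError("require R > 0")
    return 4.0 * mu_pa_s * Rdot_um_s / R


def effective_viscosity(P: float, R: float, h: float,
                        Rdot: float, rdot_unit: str = "um/s") -> float:
    """Effective tissue viscosity mu = P*R^2/(8*h*Rdot), Pa·s.

    ``rdot_unit`` is "um/s" (default, table convention) or "um/hr".
    """
    if h <= 0 or R <= 0:
        raise ValueError("require R > 0 and h > 0")
    if rdot_unit == "um/hr":
        Rdot = Rdot / 3600.0
    elif rdot_unit != "um/s":
        raise ValueError("rdot_unit must be 'um/s' or 'um/hr'")
    if Rdot == 0:
        raise ZeroDivisionError("viscosity undefined at zero growth rate")
    return P * R ** 2 / (8.0 * h * Rdot)


@dataclass
class ViscosityEstimate:
    """Interval-averaged means and SDs entering the viscosity estimate."""

    P_mean: float      # Pa
    P_sd: float
    R_mean: float      # µm
    R_sd: float
    h_mean: float      # µm
    h_sd: float
    Rdot_mean: float   # µm/s
    Rdot_sd: float
    interval: str = ""

    @property
    def mu(self) -> float:
        """Point estimate, Pa·s."""
        return effective_viscosity(self.P_mean, self.R_mean, self.h_mean,
                                   self.Rdot_mean)


def propagate_viscosity_error(est: ViscosityEstimate,
                              mode: str = "published") -> float:
    """Standard deviation of the viscosity estimate, Pa·s.

    mode="published": delta_mu/mu = (1/8)*sqrt[(dP/P)^2 + 2(dR/R)^2 + (dh/h)^2
    + (dR'/R')^2] — the published form, which reproduces the published SD
    table.  mode="standard": first-order propagation for mu ∝ P R^2 / (h R'),
    i.e. sqrt[(dP/P)^2 + 4(dR/R)^2 + (dh/h)^2 + (dR'/R')^2].
    """
    for name in ("P", "R", "h", "Rdot"):
        if getattr(est, f"{name}_mean") <= 0:
            raise ValueError(f"{name} mean must be positive")
        if getattr(est, f"{name}_sd") < 0:
            raise ValueError(f"{name} sd must be non-negative")
    rp = est.P_sd / est.P_mean
    rr = est.R_sd / est.R_mean
    rh = est.h_sd / est.h_mean
    rd = est.Rdot_sd / est.Rdot_mean
    if mode == "published":
        rel = (1.0 / 8.0) * np.sqrt(rp ** 2 + 2.0 * rr ** 2
                                    + rh ** 2 + rd ** 2)
    elif mode == "standard":
        rel = np.sqrt(rp ** 2 + 4.0 * rr ** 2 + rh ** 2 + rd ** 2)
    else:
        raise ValueError("mode must be 'published' or 'standard'")
    return float(est.mu * rel)


def viscosity_table(estimates: Sequence[ViscosityEstimate],
                    mode: str = "published") -> pd.DataFrame:
    """Interval table (P, R, h, R', mu with SDs) mirroring the literature."""
    rows = []
    for est in estimates:
        rows.append({
            "interval": est.interval,
            "P_pa": est.P_mean, "P_sd": est.P_sd,
            "R_um": est.R_mean, "R_sd": est.R_sd,
            "h_um": est.h_mean, "h_sd": est.h_sd,
            "Rdot_um_s": est.Rdot_mean, "Rdot_sd": est.Rdot_sd,
            "mu_1e6_pa_s": est.mu / 1e6,
            "mu_sd_1e6_pa_s": propagate_viscosity_error(est, mode) / 1e6,
        })
    return pd.DataFrame(rows)


def maxwell_response(material: WallMaterial, t: np.ndarray,
                     sigma: np.ndarray) -> np.ndarray:
    """Creep strain of a Maxwell element under a stress history.

    Integrates eps_dot = (sigma_dot + sigma/tau)/G with trapezoidal
    quadrature on a uniform grid:

        eps(t) = sigma(t)/G + (1/(G*tau)) * \\int_0^t sigma dt'

    so a step stress produces the instantaneous elastic jump sigma/G followed
    by creep at rate sigma/(G*tau), and stress release recovers the elastic
    part.  ``G`` is the material's elastic constant (``k``); tau = mu/k.
    Pass ``mu = inf`` (tau -> inf) for a purely elastic response.
    """
    t = np.asarray(t, float)
    sigma = np.asarray(sigma, float)
    if t.size != sigma.size:
        raise ValueError("t and sigma must align")
    dt = np.diff(t)
    if t.size > 2 and not np.allclose(dt, dt[0]):
        raise ValueError("uniform time grid required")
    G = material.k_at(t[0])
    mu = material.mu(t[0]) if callable(material.mu) else float(material.mu)
    if not np.isinf(mu) and mu <= 0:
        raise ValueError("tau must be positive")
    eps = sigma / G
    if not np.isinf(mu):
        tau = mu / G
        integral = np.concatenate(
            [[0.0], np.cumsum(0.5 * (sigma[1:] + sigma[:-1]) * dt)])
        eps = eps + integral / (G * tau)
    return eps


def estimate_material_from_puncture(
        stages: Sequence[float],
        pre_thickness: dict[str, np.ndarray],
        post_thickness: dict[str, np.ndarray]) -> pd.DataFrame:
    """Relative regional softness from puncture recoil.

    For each region, the elastic indicator at each stage is the fractional
    thickening at puncture, (post − pre)/pre, proportional to 1/k (softer
    cells deform more when pressure is released).  The viscous indicator is
    the normalized drift of the post-puncture resting thickness across
    stages, proportional to 1/mu (more fluid-like cells creep more between
    stages).  Indicators are relative — region-vs-region ranking only, no
    absolute calibration.
    """
    stages = np.asarray(stages, float)
    if stages.size < 2:
        raise ValueError("need measurements at >= 2 stages")
    rows = []
    for region in pre_thickness:
        pre = np.asarray(pre_thickness[region], float)
        post = np.asarray(post_thickness[region], float)
        if np.any(pre <= 0):
            raise ValueError("pre-puncture thickness must be positive")
        elastic = (post - pre) / pre
        # drift of the resting (post-puncture) state, normalized per hour
        drift = -np.gradient(post, stages) / post
        for i, st in enumerate(stages):
            rows.append({"region": region, "stage_hpf": st,
                         "elastic_indicator": elastic[i],
                         "viscous_indicator": drift[i]})
    df = pd.DataFrame(rows)
    rank = (df.groupby("region")[["elastic_indicator", "viscous_indicator"]]
            .mean().rank(ascending=False))
    df = df.merge(rank, on="region", suffixes=("", "_rank"))
    return df
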