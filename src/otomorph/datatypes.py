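"""Core containers shared across modules.

The otic vesicle is idealised as a thin spherical shell: a fluid-filled lumen
(volume ``Vl``, surface ``Sl``) wrapped by an epithelium (volume ``Vt``,
thickness ``h``).  Time is measured in hours post-fertilization (hpf).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import units

Quantity = str


@dataclass
class MorphoTimeSeries:
    """Per-embryo sampled growth curves.

    All volumes in pl, areas in µm², lengths in µm, pressure in Pa.  ``P`` may
    be NaN where pressure was not measurable (before ~30 hpf the epithelium is
    too slack to probe).
    """

    t: np.ndarray                    # hpf, strictly increasing
    N: np.ndarray                    # cell count
    s: np.ndarray                    # mean cell volume, pl
    Vt: np.ndarray                   # tissue volume, pl
    Vl: np.ndarray                   # lumen volume, pl
    Vo: np.ndarray                   # total vesicle volume, pl
    Sl: np.ndarray                   # lumenal surface area, µm²
    psi: np.ndarray                  # mean apical cell area, µm²
    h_medial: np.ndarray             # wall thickness, µm
    h_lateral: np.ndarray
    h_poles: np.ndarray
    P: Optional[np.ndarray] = None   # lumenal pressure, Pa (NaN allowed)
    embryo_id: str = "embryo-0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        for name in ("N", "s", "Vt", "Vl", "Vo", "Sl", "psi",
                     "h_medial", "h_lateral", "h_poles"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} shape mismatch")
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if self.P is not None:
            self.P = np.asarray(self.P, dtype=float)

    @property
    def h_mean(self) -> np.ndarray:
        """Mean of the thinning (medial + lateral) wall regions.

        The poles retain their columnar morphology and are excluded, so that
        recovery of thickness symmetry after puncture tracks the regions that
        actually strain.
        """
        return 0.5 * (self.h_medial + self.h_lateral)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: embryo_id, t_hpf, quantity, value, region."""
        rows = []
        regional = {"h_medial": "medial", "h_lateral": "lateral",
                    "h_poles": "poles"}
        for name in ("N", "s", "Vt", "Vl", "Vo", "Sl", "psi"):
            for t, v in zip(self.t, getattr(self, name)):
                rows.append((self.embryo_id, t, name, v, None))
        for name, region in regional.items():
            for t, v in zip(self.t, getattr(self, name)):
                rows.append((self.embryo_id, t, "h", v, region))
        if self.P is not None:
            for t, v in zip(self.t, self.P):
                if np.isfinite(v):
                    rows.append((self.embryo_id, t, "P", v, None))
        return pd.DataFrame(
            rows, columns=["embryo_id", "t_hpf", "quantity", "value", "region"])


@dataclass
class ShellGeometry:
    """Sphere-equivalent shell radii (µm) derived from volumes."""

    Rl: float     # lumen radius
    Ro: float     # outer radius

    def __post_init__(self) -> None:
        if self.Ro <= self.Rl or self.Rl < 0:
            raise ValueError("require Ro > Rl >= 0")

    @property
    def R(self) -> float:
        """Mid-wall average radius (Ro + Rl)/2."""
        return 0.5 * (self.Ro + self.Rl)

    @property
    def h(self) -> float:
        """Wall thickness Ro - Rl."""
        return self.Ro - self.Rl


@dataclass
class Event:
    """Perturbation event applied to a vesicle: puncture, reseal or drug."""

    t: float
    kind: str                 # puncture | reseal | drug
    params: dict = field(default_factory=dict)


@dataclass
class PairedExperiment:
    """Left/right vesicle pair, exactly one side carrying puncture events."""

    left: MorphoTimeSeries      # unperturbed control
    right: MorphoTimeSeries     # punctured side
    events: list[Event] = field(default_factory=list)

    @property
    def V0_series(self) -> np.ndarray:
        """Unperturbed lumen volume, pl."""
        return self.left.Vl

    @property
    def V_series(self) -> np.ndarray:
        """Perturbed lumen volume, pl."""
        return self.right.Vl


@dataclass
class TransportParams:
    """Constants of the pressure-flux feedback law Ω = Ω0 − K·P.

    ``Omega0`` may be a constant or a callable of time (hpf): the osmotic
    pumping capacity rises with developmental stage so that wild-type flux
    stays near 1 µm/hr while homeostatic pressure climbs from 100 to 300 Pa.
    """

    Omega0: float | Callable[[float], float]   # µm/hr
    K: float                                   # µm/(hr·Pa)
    P0: float | Callable[[float], float] = 0.0  # homeostatic pressure, Pa
    c: float = 2.0e-13          # lumenal solute concentration, mol/µm³ (200 mM)
    kappa: float = 4.0          # catch-up gain, µm/hr per unit fractional deficit

    def omega0_at(self, t: float) -> float:
        return self.Omega0(t) if callable(self.Omega0) else float(self.Omega0)

    def p0_at(self, t: float) -> float:
        return self.P0(t) if callable(self.P0) else float(self.P0)

    def solute_rate(self, omega: float) -> float:
        """Isotonic solute transport rate M = Ω·c, mol/(µm²·hr)."""
        return omega * self.c


@dataclass
class WallMaterial:
    """Viscoelastic constants of the epithelium (Maxwell element).

    ``k`` (elasticity, Pa) and ``mu`` (viscosity, Pa·hr internally) may be
    callables of time to represent developmental stiffening.  ``G`` is accepted
    as an alias for ``k`` — the short-time elastic constant.
    """

    k: float | Callable[[float], float]
    mu: float | Callable[[float], float]
    region: str = "bulk"

    @classmethod
    def from_G(cls, G, mu, region="bulk") -> "WallMaterial":
        return cls(k=G, mu=mu, region=region)

    def k_at(self, t: float) -> float:
        val = self.k(t) if callable(self.k) else float(self.k)
        if val <= 0:
            raise ValueError("elasticity must be positive")
        return val

    def mu_at(self, t: float) -> float:
        val = self.mu(t) if callable(self.mu) else float(self.mu)
        if val <= 0:
            raise ValueError("viscosity must be positive")
        return val

    def tau_at(self, t: float) -> float:
        """Relaxation time τ = µ/k, hours."""
        return self.mu_at(t) / self.k_at(t)


@dataclass
class VesicleTrajectory:
    """Simulator output on a uniform time grid."""

    t: np.ndarray          # hpf
    R: np.ndarray          # lumen radius, µm
    h: np.ndarray          # wall thickness, µm
    P: np.ndarray          # lumenal pressure, Pa
    sigma: np.ndarray      # in-plane wall stress, Pa
    Omega: np.ndarray      # fluid flux, µm/hr
    Vl: np.ndarray         # lumen volume, pl
    Vt: np.ndarray         # tissue volume, pl
    strain_elastic: np.ndarray   # stored elastic strain σ/(4k)
    events: list[Event] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "R": self.R, "h": self.h, "P": self.P,
            "sigma": self.sigma, "Omega": self.Omega,
            "Vl": self.Vl, "Vt": self.Vt,
        })


@dataclass
class PressureTrace:
    """Probe pressure trace with ground-truth stage labels when synthetic."""

    t: np.ndarray                       # seconds
    P_raw: np.ndarray                   # Pa
    stages: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P_raw = np.asarray(self.P_raw, dtype=float)
        ends = [s[2] for s in self.stages]
        starts = [s[1] for s in self.stages]
        if any(e > s2 + 1e-9 for e, s2 in zip(ends[:-1], starts[1:])):
            raise ValueError("stages must be non-overlapping and time ordered")


def cohort_mean(cohort: Sequence[MorphoTimeSeries]) -> MorphoTimeSeries:
    """Population-averaged series over a cohort sharing one time grid."""
    t = cohort[0].t
    for m in cohort:
        if not np.allclose(m.t, t):
            raise ValueError("cohort members must share a time grid")
    def avg(name):
        return np.mean([getattr(m, name) for m in cohort], axis=0)
    P = None
    if all(m.P is not None for m in cohort):
        stack = np.array([m.P for m in cohort])
        with np.errstate(invalid="ignore"):
            counts = np.isfinite(stack).sum(axis=0)
            P = np.where(counts > 0,
                         np.nansum(np.where(np.isfinite(stack), stack, 0.0),
                                   axis=0) / np.maximum(counts, 1),
                         np.nan)
    return MorphoTimeSeries(
        t=t, N=avg("N"), s=avg("s"), Vt=avg("Vt"), Vl=avg("Vl"),
        Vo=avg("Vo"), Sl=avg("Sl"), psi=avg("psi"),
        h_medial=avg("h_medial"), h_lateral=avg("h_lateral"),
        h_poles=avg("h_poles"), P=P, embryo_id="cohort-mean")
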