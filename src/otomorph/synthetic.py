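"""Synthetic cohorts emulating wild-type otic-vesicle growth measurements.

The generator reproduces the published wild-type growth curves as smooth
deterministic backbones through anchor values, with Gaussian embryo-to-embryo
and sampling noise scaled to the published standard deviations (n = 10
embryos, hourly sampling 16-45 hpf):

* cell number N: 415 -> 1106 (near-exponential rise),
* mean cell volume s: 0.55 -> 0.34 pl by 28 hpf, constant after,
* lumen volume Vl: 0 -> 440 pl (rapid inflation 16-21 hpf, then a linear
  sphere-equivalent radius, i.e. approximately constant flux ~1 µm/hr),
* total volume Vo = Vl + Vt (235 -> 807 pl),
* wall thickness: medial/lateral 20 -> 4 µm, poles stay columnar,
* pressure P: 100 -> 300 Pa over 30-48 hpf.

Derived quantities honour the bookkeeping identities exactly: Sl is the
sphere-equivalent lumen surface, psi = Sl/N, Vt = N*s, Vo = Vl + Vt.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .datatypes import Event, MorphoTimeSeries, PairedExperiment, PressureTrace

__all__ = [
    "GeneratorSpec", "default_anchors",
    "generate_wildtype_cohort", "generate_puncture_experiment",
    "generate_pressure_trace", "generate_perturbation_cohort",
]

T_MIN, T_MAX = 12.0, 48.0

#: log growth rate of cell number, 1/hr: ln(1106/415)/29
_N_RATE = math.log(1106.0 / 415.0) / 29.0

#: lumen sphere-equivalent radius at 45 hpf (Vl = 440 pl)
_RL45 = (3.0 * 440.0e3 / (4.0 * math.pi)) ** (1.0 / 3.0)

#: linear radius growth rate on 21-45 hpf, chosen so that the surface-area
#: break-even (division term overtakes stretching) falls at 33 hpf given the
#: exponential N(t):  Rl(33) = c/_N_RATE  with  Rl(33) = RL45 - 12 c.
_RL_SLOPE = _RL45 / (12.0 + 1.0 / _N_RATE)


def _n_of(t: np.ndarray) -> np.ndarray:
    return 415.0 * np.exp(_N_RATE * (np.asarray(t, float) - 16.0))


def _rl_anchor_times() -> np.ndarray:
    return np.array([16.0, 18.5, 21.0, 27.0, 33.0, 39.0, 45.0])


def _rl_anchor_values() -> np.ndarray:
    rl21 = _RL45 - 24.0 * _RL_SLOPE
    late = rl21 + _RL_SLOPE * (np.array([27.0, 33.0, 39.0, 45.0]) - 21.0)
    return np.concatenate([[2.0, 12.0, rl21], late])


@dataclass
class GeneratorSpec:
    """Calibration anchors and noise structure for a synthetic cohort.

    ``anchors`` maps a quantity name to a list of (time, mean, sd) points.
    Quantities with ``mean is None`` entries are not allowed; sd is linearly
    interpolated between anchor times (the published SDs exist only at
    selected stages).
    """

    anchors: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: default_anchors())
    noise_sd_scale: float = 1.0
    n_embryos: int = 10
    seed: int = 0
    sampling_interval: float = 1.0
    t_start: float = 16.0
    t_end: float = 45.0
    #: fraction of noise variance shared per embryo (random effect)
    embryo_effect_frac: float = 0.5

    def __post_init__(self) -> None:
        for name, pts in self.anchors.items():
            for (t, m, sd) in pts:
                if not (T_MIN <= t <= T_MAX):
                    raise ValueError(
                        f"anchor for {name} at t={t} outside {T_MIN}-{T_MAX} hpf")
                if sd < 0:
                    raise ValueError(f"negative sd for {name} at t={t}")
        for name in ("N", "Rl"):
            pts = sorted(self.anchors[name])
            vals = [m for (_, m, _) in pts]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} anchors must be nondecreasing")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.sampling_interval))
        return self.t_start + self.sampling_interval * np.arange(n + 1)


def default_anchors() -> dict[str, list[tuple[float, float, float]]]:
    """Anchor set reproducing the published wild-type values."""
    tN = [16.0, 21.0, 27.0, 33.0, 39.0, 45.0]
    n_sd = np.interp(tN, [16.0, 45.0], [26.0, 52.0])
    rl_t = _rl_anchor_times()
    rl_v = _rl_anchor_values()
    # lumen-volume SD 2 -> 18 pl propagated onto the radius: dRl = dVl*Rl/(3Vl)
    vl_sd = np.interp(rl_t, [16.0, 45.0], [2.0, 18.0])
    vl = 4.0 * math.pi / 3.0 * rl_v ** 3 / 1.0e3
    rl_sd = vl_sd * rl_v / (3.0 * np.maximum(vl, 1e-6))
    rl_sd = np.minimum(rl_sd, np.minimum(2.0, 0.35 * rl_v))
    return {
        "N": [(t, m, s) for t, m, s in zip(tN, _n_of(np.array(tN)), n_sd)],
        "s": [(16.0, 0.55, 0.02), (22.0, 0.445, 0.025),
              (28.0, 0.34, 0.03), (45.0, 0.34, 0.03)],
        "Rl": [(t, m, s) for t, m, s in zip(rl_t, rl_v, rl_sd)],
        "h_medial": [(16.0, 20.0, 1.5), (22.0, 12.0, 1.2), (28.0, 7.0, 0.8),
                     (36.0, 5.0, 0.5), (45.0, 4.0, 0.4)],
        "h_lateral": [(16.0, 20.0, 1.5), (22.0, 13.0, 1.2), (28.0, 8.0, 0.8),
                      (36.0, 5.5, 0.5), (45.0, 4.2, 0.4)],
        "h_poles": [(16.0, 20.0, 1.5), (45.0, 19.0, 1.5)],
        "P": [(30.0, 100.0, 25.0), (36.0, 166.0, 23.4), (48.0, 300.0, 40.0)],
    }


def _backbone(pts: Sequence[tuple[float, float, float]], t: np.ndarray):
    """Monotone cubic (PCHIP) backbone through anchors + linear-in-time sd."""
    pts = sorted(pts)
    ta = np.array([p[0] for p in pts])
    ma = np.array([p[1] for p in pts])
    sa = np.array([p[2] for p in pts])
    t = np.asarray(t, float)
    tc = np.clip(t, ta[0], ta[-1])
    if len(ta) >= 2:
        mean = PchipInterpolator(ta, ma)(tc)
    else:
        mean = np.full_like(t, ma[0])
    sd = np.interp(t, ta, sa)
    return mean, sd


def _noise(sd: np.ndarray, scale: float, frac: float,
           z_embryo: float, z_sample: np.ndarray) -> np.ndarray:
    """Shared-embryo-effect plus per-sample Gaussian noise."""
    return sd * scale * (math.sqrt(frac) * z_embryo
                         + math.sqrt(1.0 - frac) * z_sample)


_PRIMARIES = ("N", "s", "Rl", "h_medial", "h_lateral", "h_poles", "P")


def draw_noise_bundle(rng: np.random.Generator, n_t: int) -> dict:
    """Standard-normal draws (embryo effect + per-sample) per primary."""
    return {name: (rng.standard_normal(), rng.standard_normal(n_t))
            for name in _PRIMARIES}


def mix_noise_bundles(a: dict, b: dict, share: float) -> dict:
    """Correlate bundle ``b`` with ``a`` at variance fraction ``share``."""
    w = math.sqrt(share)
    v = math.sqrt(1.0 - share)
    return {name: (w * a[name][0] + v * b[name][0],
                   w * a[name][1] + v * b[name][1]) for name in _PRIMARIES}


def _assemble(spec: GeneratorSpec, t: np.ndarray, rng: np.random.Generator,
              embryo_id: str, rl_override: Optional[np.ndarray] = None,
              flux_gate=None, bundle: Optional[dict] = None
              ) -> MorphoTimeSeries:
    """One embryo: noisy primaries (N, s, Rl, h, P) -> exact derived fields.

    ``flux_gate(t)`` optionally rescales the backbone lumen growth rate after
    a treatment time (drug phenomenology).  ``bundle`` supplies the noise
    draws, allowing correlated left/right sides of one embryo.
    """
    if bundle is None:
        bundle = draw_noise_bundle(rng, t.size)
    out = {}
    for name in _PRIMARIES:
        mean, sd = _backbone(spec.anchors[name], t)
        z_e, z_s = bundle[name]
        noisy = mean + _noise(sd, spec.noise_sd_scale,
                              spec.embryo_effect_frac, z_e, z_s)
        out[name] = np.maximum(noisy, 0.0)
    if rl_override is not None:
        # keep noise structure but replace the deterministic part
        mean, _ = _backbone(spec.anchors["Rl"], t)
        out["Rl"] = rl_override + (out["Rl"] - mean)
    elif flux_gate is not None:
        mean, _ = _backbone(spec.anchors["Rl"], t)
        gated = _gate_radius(t, mean, flux_gate)
        out["Rl"] = gated + (out["Rl"] - mean)
    # a lumen is never measured with a vanishing sphere-equivalent radius
    out["Rl"] = np.maximum(out["Rl"], 0.5)

    N = np.round(out["N"])
    s = out["s"]
    Rl = out["Rl"]
    Vl = 4.0 * math.pi / 3.0 * Rl ** 3 / 1.0e3           # pl
    Sl = 4.0 * math.pi * Rl ** 2                         # µm²
    Vt = N * s
    P = out["P"].copy()
    P[t < 30.0] = np.nan
    return MorphoTimeSeries(
        t=t, N=N, s=s, Vt=Vt, Vl=Vl, Vo=Vl + Vt, Sl=Sl,
        psi=Sl / np.maximum(N, 1.0),
        h_medial=out["h_medial"], h_lateral=out["h_lateral"],
        h_poles=out["h_poles"], P=P, embryo_id=embryo_id)


def _gate_radius(t: np.ndarray, rl_mean: np.ndarray, gate) -> np.ndarray:
    """Re-integrate the backbone radius with dRl/dt scaled by gate(t)."""
    rl = rl_mean.copy()
    for i in range(1, t.size):
        drl = rl_mean[i] - rl_mean[i - 1]
        rl[i] = rl[i - 1] + drl * gate(0.5 * (t[i] + t[i - 1]))
    return rl


def generate_wildtype_cohort(spec: GeneratorSpec) -> list[MorphoTimeSeries]:
    """Cohort of noisy wild-type embryos; identical seed => identical output."""
    rng = np.random.default_rng(spec.seed)
    t = spec.times
    return [_assemble(spec, t, rng, f"wt-{i}") for i in range(spec.n_embryos)]


def generate_puncture_experiment(
        spec: GeneratorSpec, t_puncture: float = 30.0,
        loss_fraction: float = 0.35, kappa: float = 4.0,
        seed: Optional[int] = None,
        reseal_delay_min: float = 5.0) -> PairedExperiment:
    """Paired control/punctured embryo with catch-up recovery.

    At ``t_puncture`` the punctured side loses ``loss_fraction`` of its lumen
    volume instantaneously (the epithelium thickens at conserved tissue
    volume), reseals after ``reseal_delay_min`` minutes, then regenerates with
    excess flux kappa * (ΔVl/Vl) that decays as the deficit closes.
    """
    if not (0.0 < loss_fraction < 1.0):
        if loss_fraction != 0.0:
            raise ValueError("loss_fraction must lie in (0, 1)")
    t = spec.times
    if t_puncture > t[-1] or t_puncture < t[0]:
        raise ValueError("t_puncture outside the series span")
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    rl_mean, _ = _backbone(spec.anchors["Rl"], t)
    backbone = PchipInterpolator(
        np.array(sorted(p[0] for p in spec.anchors["Rl"])),
        np.array([p[1] for p in sorted(spec.anchors["Rl"])]))

    # fine-grained integration of the punctured side's radius
    dt = 1.0 / 60.0
    tf = np.arange(t[0], t[-1] + 0.5 * dt, dt)
    rl_ctrl = backbone(np.clip(tf, 16.0, 45.0))
    drl_ctrl = np.gradient(rl_ctrl, tf)
    rl_p = np.empty_like(tf)
    open_until = t_puncture + reseal_delay_min / 60.0
    # the node at (or just before) t_puncture carries the post-puncture state,
    # so sampling at t_puncture reports t_puncture+
    i0 = int(np.searchsorted(tf, t_puncture - 1e-6))
    rl_p[:i0 + 1] = rl_ctrl[:i0 + 1]
    if loss_fraction == 0.0:
        rl_p = rl_ctrl.copy()       # nothing lost, nothing to regenerate
    else:
        rl_p[i0] = rl_ctrl[i0] * (1.0 - loss_fraction) ** (1.0 / 3.0)
        for i in range(i0, tf.size - 1):
            if tf[i] < open_until:
                drl = 0.0       # barrier open: no net transport
            else:
                deficit = 1.0 - (rl_p[i] / rl_ctrl[i]) ** 3
                drl = drl_ctrl[i] + kappa * max(deficit, 0.0)
            rl_p[i + 1] = rl_p[i] + drl * dt
    rl_p_samples = np.interp(t, tf, rl_p)

    # bilateral measurements of one embryo share most of their variability
    base = draw_noise_bundle(rng, t.size)
    other = draw_noise_bundle(rng, t.size)
    left = _assemble(spec, t, rng, "pair-control", bundle=base)
    right = _assemble(spec, t, rng, "pair-punctured",
                      rl_override=rl_p_samples,
                      bundle=mix_noise_bundles(base, other, share=0.8))
    # wall thickens on the punctured side to conserve tissue volume
    scale = (rl_mean / np.maximum(rl_p_samples, 1e-9)) ** 2
    scale = np.where(t >= t_puncture, np.minimum(scale, 4.0), 1.0)
    for name in ("h_medial", "h_lateral", "h_poles"):
        setattr(right, name, getattr(right, name) * scale)
    events = []
    if loss_fraction > 0.0:
        events = [Event(t_puncture, "puncture",
                        {"loss_fraction": loss_fraction}),
                  Event(open_until, "reseal", {})]
    return PairedExperiment(left=left, right=right, events=events)


def generate_pressure_trace(
        P_baseline: float = 0.0, P_plateau: float = 166.0,
        rise_time_s: float = 30.0, noise_sd: float = 2.0,
        seed: int = 0, baseline_s: float = 30.0, plateau_s: float = 60.0,
        withdrawal_s: float = 2.0, post_s: float = 30.0,
        rate_hz: float = 10.0) -> PressureTrace:
    """Synthetic probe trace: baseline / linear rise / plateau / withdrawal.

    The rise is linear (default 0.5 min, the typical probing-stage rise time)
    and the withdrawal is a fast linear drop back to the bath baseline.
    Ground-truth stage boundaries are attached for segmentation tests.
    """
    if P_plateau < P_baseline or P_baseline < 0:
        raise ValueError("require P_plateau >= P_baseline >= 0")
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    t0, t1 = 0.0, baseline_s
    t2 = t1 + rise_time_s
    t3 = t2 + plateau_s
    t4 = t3 + withdrawal_s
    t5 = t4 + post_s
    t = np.arange(0.0, t5 + 0.5 * dt, dt)
    P = np.full_like(t, float(P_baseline))
    rise = (t >= t1) & (t < t2)
    if rise_time_s > 0:
        P[rise] = P_baseline + (P_plateau - P_baseline) * (t[rise] - t1) / rise_time_s
    P[(t >= t2) & (t < t3)] = P_plateau
    wd = (t >= t3) & (t < t4)
    if withdrawal_s > 0:
        P[wd] = P_plateau - (P_plateau - P_baseline) * (t[wd] - t3) / withdrawal_s
    P = P + noise_sd * rng.standard_normal(t.size)
    stages = [("baseline", t0, t1), ("rise", t1, t2), ("plateau", t2, t3),
              ("withdrawal", t3, t4), ("post", t4, t5)]
    return PressureTrace(t=t, P_raw=P, stages=stages)


def generate_material_assay(stages: Sequence[float] = (25.0, 30.0, 35.0, 40.0),
                            seed: int = 0, noise_sd: float = 0.02
                            ) -> tuple[np.ndarray, dict, dict]:
    """Pre/post-puncture wall thickness per region across developmental stages.

    Emulates the regional viscoelasticity phenomenology: medial and lateral
    cells deform substantially more when pressure is released (softer, larger
    1/k) and their post-puncture resting shapes relax further between stages
    (more fluid, larger 1/mu); pole cells barely respond.  Returns
    (stages, pre_thickness, post_thickness) with per-region arrays in µm.
    """
    stages = np.asarray(stages, float)
    rng = np.random.default_rng(seed)
    t = stages
    pre = {
        "medial": np.interp(t, [16.0, 45.0], [20.0, 4.0]),
        "lateral": np.interp(t, [16.0, 45.0], [20.0, 4.5]),
        "poles": np.full(t.size, 19.5),
    }
    # fractional thickening at puncture (elastic recoil, ∝ 1/k)
    deform = {"medial": 0.40, "lateral": 0.35, "poles": 0.05}
    # resting-shape relaxation across stages (viscous creep, ∝ 1/mu)
    drift = {"medial": 0.012, "lateral": 0.010, "poles": 0.0}
    post = {}
    for region in pre:
        rest = (pre[region] * (1.0 + deform[region])
                * np.exp(-drift[region] * (t - t[0])))
        post[region] = rest * (1.0 + noise_sd * rng.standard_normal(t.size))
    return stages, pre, post


def generate_perturbation_cohort(
        spec: GeneratorSpec, kind: str, dose_scale: float,
        t_treat: float = 25.0) -> list[MorphoTimeSeries]:
    """Drug-treated cohorts.

    ouabain / morpholino scale the lumen influx toward zero with dose (full
    dose arrests growth); cytochalasin softens the wall so realized flux rises
    (2-5x at full dose).
    """
    if not (0.0 <= dose_scale <= 1.0):
        raise ValueError("dose_scale must lie in [0, 1]")
    if kind in ("ouabain", "morpholino"):
        def gate(tm):
            return (1.0 - dose_scale) if tm >= t_treat else 1.0
    elif kind == "cytochalasin":
        def gate(tm):
            return (1.0 + 3.0 * dose_scale) if tm >= t_treat else 1.0
    else:
        raise ValueError(f"unknown perturbation kind: {kind!r}")
    rng = np.random.default_rng(spec.seed)
    t = spec.times
    fg = None if dose_scale == 0.0 else gate
    return [_assemble(spec, t, rng, f"{kind}-{i}", flux_gate=fg)
            for i in range(spec.n_embryos)]
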