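"""Physics of the capillary pressure probe.

Three validation computations for a piezo-resistive sensor coupled to a
water-filled glass capillary:

1. **Membrane compliance.**  The sensing element is a clamped square silicon
   plate (edge L, thickness t) under uniform pressure; Kirchhoff-Love theory
   gives the biharmonic problem ∇⁴w = P/D with built-in edges (w = 0,
   ∂w/∂n = 0).  The classical centre deflection is wc = 1.26e-3·P·L⁴/D.  The
   displaced volume ∬w dx dy must be negligible against the vesicle volume,
   otherwise the act of measuring would deflate the vesicle.
2. **Dilution.**  The endolymph diffuses out through the conical capillary
   toward the water-filled tube; the probe reading is only meaningful while
   the lumenal ion concentration (hence osmotic drive) is nearly unchanged.  The
   vesicle (~100 µm, mixing time < 1 s) is treated as a well-mixed
   compartment coupled to a quasi-1D variable-area diffusion domain along
   the cone.
3. **Plateau extraction.**  The vesicle pressure is the mean of the stable
   plateau after the rise and before leakage, minus the bath baseline.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datatypes import PressureTrace

__all__ = [
    "PlateSpec", "bending_stiffness", "solve_plate", "plate_center_coefficient",
    "sensor_compliance_check", "DiffusionSpec", "dilution_simulation",
    "DilutionResult", "solve_sphere_dirichlet", "extract_plateau_pressure",
    "PlateauResult",
]


# ---------------------------------------------------------------------------
# Clamped-plate deflection
# ---------------------------------------------------------------------------

def bending_stiffness(t_mem_um: float, E_pa: float = 163e9,
                      nu: float = 0.27) -> float:
    """Plate bending stiffness D = E·t³/(12(1−ν²)), N·m.

    Equivalently 2·E·a³/(3(1−ν²)) with a = t/2 the half-thickness; the two
    conventions are algebraically identical.
    """
    if not (0.0 < nu < 0.5):
        raise ValueError("Poisson ratio must lie in (0, 0.5)")
    t_m = t_mem_um * 1e-6
    return E_pa * t_m ** 3 / (12.0 * (1.0 - nu ** 2))


@dataclass
class PlateSpec:
    """Clamped square sensing membrane under uniform transverse load."""

    L: float = 850.0          # edge length, µm
    t_mem: float = 5.0        # membrane thickness, µm
    E: float = 163e9          # Young's modulus, Pa (silicon)
    nu: float = 0.27          # Poisson ratio
    P_load: float = 400.0     # uniform pressure, Pa

    def __post_init__(self) -> None:
        if self.L <= 0 or self.t_mem <= 0:
            raise ValueError("geometry must be positive")
        if not (0.0 < self.nu < 0.5):
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def D_bend(self) -> float:
        """Bending stiffness, N·m."""
        return bending_stiffness(self.t_mem, self.E, self.nu)


def _biharmonic_clamped(n: int) -> sp.csr_matrix:
    """13-point biharmonic operator on an n×n interior grid, clamped edges.

    Boundary values are zero; the zero normal-slope condition enters through
    ghost-point reflection (w_{-1} = w_{1}), which adds +1 to the coefficient
    of the mirrored interior node in rows adjacent to an edge.
    """
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ii = ii.ravel(); jj = jj.ravel()
    row_of = ii * n + jj

    stencil = [(0, 0, 20.0)]
    stencil += [(di, dj, -8.0) for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    stencil += [(di, dj, 2.0) for di, dj in ((1, 1), (1, -1), (-1, 1), (-1, -1))]
    stencil += [(di, dj, 1.0) for di, dj in ((2, 0), (-2, 0), (0, 2), (0, -2))]

    def reflect(k: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map an index beyond the clamped edge back onto the grid.

        k == -1 or n is the boundary node (w = 0, dropped); k == -2 or n+1
        is the ghost node, reflected to the first interior node.
        """
        keep = (k != -1) & (k != n)
        kr = np.where(k == -2, 0, np.where(k == n + 1, n - 1, k))
        return kr, keep

    rows, cols, vals = [], [], []
    for di, dj, c in stencil:
        ir, keep_i = reflect(ii + di)
        jr, keep_j = reflect(jj + dj)
        keep = keep_i & keep_j
        rows.append(row_of[keep])
        cols.append((ir * n + jr)[keep])
        vals.append(np.full(keep.sum(), c))
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n * n, n * n))
    return A.tocsr()


def solve_plate(spec: PlateSpec, grid_n: int = 129) -> tuple[np.ndarray, np.ndarray]:
    """Deflection field w(x, y) (µm grid coordinates, metres deflection).

    ``grid_n`` is the number of nodes per side including the boundary and
    must be odd (>= 33) so a centre node exists.  Returns (x_um, w_m) where
    w has shape (grid_n, grid_n) with zero boundary rows/columns.
    """
    if grid_n < 33:
        raise ValueError("grid_n must be >= 33")
    if grid_n % 2 == 0:
        raise ValueError("grid_n must be odd so the plate centre is a node")
    n = grid_n - 2                      # interior nodes per side
    L_m = spec.L * 1e-6
    d = L_m / (grid_n - 1)
    A = _biharmonic_clamped(n) / d ** 4
    rhs = np.full(n * n, spec.P_load / spec.D_bend)
    w_int = spla.spsolve(A.tocsc(), rhs)
    w = np.zeros((grid_n, grid_n))
    w[1:-1, 1:-1] = w_int.reshape(n, n)
    x_um = np.linspace(0.0, spec.L, grid_n)
    return x_um, w


def plate_center_coefficient(spec: Optional[PlateSpec] = None,
                             grid_n: int = 129) -> float:
    """Dimensionless centre coefficient wc·D/(P·L⁴); ≈ 1.26e-3 classically."""
    spec = spec or PlateSpec()
    _, w = solve_plate(spec, grid_n)
    c = grid_n // 2
    wc = w[c, c]
    L_m = spec.L * 1e-6
    return float(wc * spec.D_bend / (spec.P_load * L_m ** 4))


@dataclass
class ComplianceReport:
    P_pa: np.ndarray
    displaced_volume_um3: np.ndarray
    sphere_volume_um3: float
    margin_orders: float     # log10(sphere / worst displaced volume)


def sensor_compliance_check(spec: PlateSpec,
                            P_range: np.ndarray | list[float] = (100, 200, 300, 400),
                            reference_sphere_diameter: float = 200.0,
                            grid_n: int = 129) -> ComplianceReport:
    """Displaced membrane volume V(P) vs a reference vesicle volume.

    The plate problem is linear, so the field is solved once at the spec's
    load and scaled.  The margin is log10(sphere volume / max displaced
    volume): how many orders of magnitude the measurement-induced volume
    change falls below the vesicle.
    """
    P_range = np.asarray(P_range, float)
    x_um, w = solve_plate(spec, grid_n)
    x_m = x_um * 1e-6
    v_m3 = np.trapezoid(np.trapezoid(w, x_m, axis=1), x_m)   # at spec.P_load
    v_um3 = v_m3 * 1e18
    volumes = v_um3 * P_range / spec.P_load
    r = reference_sphere_diameter / 2.0
    sphere = 4.0 / 3.0 * math.pi * r ** 3
    margin = math.log10(sphere / max(volumes.max(), 1e-300))
    return ComplianceReport(P_pa=P_range, displaced_volume_um3=volumes,
                            sphere_volume_um3=sphere, margin_orders=margin)


# ---------------------------------------------------------------------------
# Capillary diffusion dilution
# ---------------------------------------------------------------------------

@dataclass
class DiffusionSpec:
    """Geometry and transport constants for endolymph dilution."""

    vesicle_diameter: float = 100.0    # µm
    C0: float = 200.0                  # mM
    cone_full_angle: float = 10.5      # degrees
    tube_length: float = 1800.0        # µm (1.8 mm)
    tip_inner_diameter: float = 10.0   # µm
    D_diff: float = 1.61e-9            # m²/s (NaCl in water)

    def __post_init__(self) -> None:
        for name in ("vesicle_diameter", "C0", "cone_full_angle",
                     "tube_length", "tip_inner_diameter", "D_diff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def D_um2_s(self) -> float:
        return self.D_diff * 1e12

    @property
    def vesicle_volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.vesicle_diameter / 2.0) ** 3


@dataclass
class DilutionResult:
    t_s: np.ndarray
    vesicle_fraction: np.ndarray       # C̄_vesicle(t)/C0
    mass_balance_error: float          # max relative drift of total solute

    def fraction_at(self, t_s: float) -> float:
        return float(np.interp(t_s, self.t_s, self.vesicle_fraction))

    def time_to_fraction(self, f: float) -> float:
        """First time (s) the vesicle mean concentration reaches f·C0."""
        if not (0.0 < f <= 1.0):
            raise ValueError("fraction must lie in (0, 1]")
        below = np.nonzero(self.vesicle_fraction <= f)[0]
        if below.size == 0:
            return math.inf
        i = below[0]
        if i == 0:
            return float(self.t_s[0])
        f0, f1 = self.vesicle_fraction[i - 1], self.vesicle_fraction[i]
        t0, t1 = self.t_s[i - 1], self.t_s[i]
        return float(t0 + (f0 - f) / (f0 - f1) * (t1 - t0))


def dilution_simulation(spec: DiffusionSpec, t_end_min: float = 20.0,
                        n_x: int = 360, dt_s: float = 0.25,
                        back_boundary: str = "open",
                        tube_initial_fraction: float = 0.0) -> DilutionResult:
    """Endolymph dilution through the conical capillary.

    Finite-volume, implicit (backward Euler) discretisation of
    ∂C/∂t = (1/A)·∂x(A·D·∂x C) along the cone (tip radius at x = 0 widening
    toward the tube), with the vesicle as a well-mixed end compartment and
    C = 0 held at the tube's back end (``back_boundary="open"``) or a sealed
    zero-flux back end (``"sealed"``, mass conserved — a self-check).
    """
    if dt_s <= 0 or n_x < 10:
        raise ValueError("need dt_s > 0 and n_x >= 10")
    if back_boundary not in ("open", "sealed"):
        raise ValueError("back_boundary must be 'open' or 'sealed'")
    D = spec.D_um2_s
    L = spec.tube_length
    dx = L / n_x
    half_angle = math.radians(spec.cone_full_angle) / 2.0
    r_tip = spec.tip_inner_diameter / 2.0

    x_faces = dx * np.arange(n_x + 1)
    x_cent = 0.5 * (x_faces[:-1] + x_faces[1:])
    r_faces = r_tip + x_faces * math.tan(half_angle)
    r_cent = r_tip + x_cent * math.tan(half_angle)
    A_faces = math.pi * r_faces ** 2
    V_cells = math.pi / 3.0 * (np.diff(x_faces)) * (
        r_faces[:-1] ** 2 + r_faces[:-1] * r_faces[1:] + r_faces[1:] ** 2)
    Vv = spec.vesicle_volume_um3

    # unknowns: [C_vesicle, C_0 ... C_{n_x-1}]
    m = n_x + 1
    vol = np.concatenate([[Vv], V_cells])
    G = np.zeros(m + 1)        # face conductances D*A/dist between unknowns
    G[1] = D * A_faces[0] / (dx / 2.0)              # vesicle <-> cell 0
    G[2:m] = D * A_faces[1:n_x] / dx                # interior faces
    G_back = D * A_faces[n_x] / (dx / 2.0) if back_boundary == "open" else 0.0

    # implicit matrix  (vol/dt + sum G) C^{new} - neighbours = vol/dt C^{old}
    diag = vol / dt_s
    lower = np.zeros(m); upper = np.zeros(m)
    for i in range(m):
        if i >= 1:
            diag[i] += G[i]
            lower[i] = -G[i]
        if i + 1 < m:
            diag[i] += G[i + 1]
            upper[i] = -G[i + 1]
    diag[m - 1] += G_back
    Amat = sp.diags([lower[1:], diag, upper[:-1]], [-1, 0, 1], format="csc")
    solver = spla.factorized(Amat)

    n_steps = int(round(t_end_min * 60.0 / dt_s))
    C = np.full(m, tube_initial_fraction * spec.C0)  # tube solute-free by default
    C[0] = spec.C0
    frac = np.empty(n_steps + 1)
    frac[0] = 1.0
    efflux_cum = 0.0
    total0 = float(np.dot(vol, C))
    max_err = 0.0
    for k in range(1, n_steps + 1):
        C = solver(vol / dt_s * C)
        efflux_cum += G_back * C[-1] * dt_s
        frac[k] = C[0] / spec.C0
        total = float(np.dot(vol, C)) + efflux_cum
        max_err = max(max_err, abs(total - total0) / total0)
    t = dt_s * np.arange(n_steps + 1)
    return DilutionResult(t_s=t, vesicle_fraction=frac,
                          mass_balance_error=max_err)


def solve_sphere_dirichlet(radius_um: float, D_um2_s: float,
                           t_eval_s: np.ndarray, n_r: int = 200
                           ) -> np.ndarray:
    """Mean concentration fraction for diffusion out of a sphere, C(a)=0.

    Radial finite differences on ∂C/∂t = D(1/r²)∂r(r²∂rC) with uniform
    initial concentration and an absorbing surface.  Used to bound the
    well-mixed-vesicle approximation (the mixing time a²/(π²D) is well under
    a second for a 100 µm vesicle) and validated against the classical
    eigenfunction series.
    """
    t_eval_s = np.asarray(t_eval_s, float)
    a = radius_um
    dr = a / n_r
    r_faces = dr * np.arange(n_r + 1)
    r_cent = 0.5 * (r_faces[:-1] + r_faces[1:])
    A_faces = 4.0 * math.pi * r_faces ** 2
    V_cells = 4.0 * math.pi / 3.0 * (r_faces[1:] ** 3 - r_faces[:-1] ** 3)
    dt = min(0.2 * dr ** 2 / D_um2_s, t_eval_s[-1] / 400.0)

    G = D_um2_s * A_faces[1:n_r] / dr
    G_surf = D_um2_s * A_faces[n_r] / (dr / 2.0)
    diag = V_cells / dt
    lower = np.zeros(n_r); upper = np.zeros(n_r)
    for i in range(n_r):
        if i >= 1:
            diag[i] += G[i - 1]; lower[i] = -G[i - 1]
        if i + 1 < n_r:
            diag[i] += G[i]; upper[i] = -G[i]
    diag[n_r - 1] += G_surf
    Amat = sp.diags([lower[1:], diag, upper[:-1]], [-1, 0, 1], format="csc")
    solver = spla.factorized(Amat)

    C = np.ones(n_r)
    t_now = 0.0
    out = np.empty(t_eval_s.size)
    Vtot = V_cells.sum()
    j = 0
    while j < t_eval_s.size:
        if t_now + 1e-12 >= t_eval_s[j]:
            out[j] = float(np.dot(V_cells, C) / Vtot)
            j += 1
            continue
        C = solver(V_cells / dt * C)
        t_now += dt
    return out


# ---------------------------------------------------------------------------
# Plateau extraction
# ---------------------------------------------------------------------------

@dataclass
class PlateauResult:
    P_vesicle: float                     # plateau mean − baseline mean, Pa
    baseline_mean: float
    plateau_mean: float
    segments: dict[str, tuple[float, float]]


def extract_plateau_pressure(trace: PressureTrace,
                             smooth_s: float = 4.0,
                             rate_frac: float = 0.05,
                             min_plateau_s: float = 10.0) -> PlateauResult:
    """Segment a probe trace and report the vesicle pressure.

    Two stages: (i) the derivative of a smoothed trace is thresholded at
    ``rate_frac`` of the peak rise rate to find the rise, the quiet stretch
    after it (sustained >= ``min_plateau_s``, the plateau) and the strong
    negative run after that (the withdrawal); (ii) boundaries are refined to
    the crossings of 50% of each ramp's interior rate — box smoothing smears
    a corner symmetrically, so the half-rate crossing sits on the true
    corner.  The vesicle pressure is plateau mean minus baseline mean.
    """
    t, P = trace.t, trace.P_raw
    if t[-1] - t[0] < 30.0:
        raise ValueError("trace must span at least 30 s")
    dt = float(np.median(np.diff(t)))
    if dt > 1.0 + 1e-9:
        raise ValueError("trace must be sampled at >= 1 Hz")
    win = max(int(round(smooth_s / dt)), 1)
    Ps = _boxsmooth(P, win)
    dP = np.gradient(Ps, t)
    # robust noise level of the derivative (most of a trace is quiet)
    noise = 1.4826 * float(np.median(np.abs(dP - np.median(dP))))
    peak_pos = float(np.max(dP))
    peak_neg = float(-np.min(dP))
    signal_floor = max(1e-9 * max(np.max(np.abs(P)), 1.0), 5.0 * noise)
    if peak_pos <= signal_floor:
        # flat trace (to within noise): plateau equals baseline
        half = t[0] + 0.5 * (t[-1] - t[0])
        base = float(np.mean(P[t < half]))
        return PlateauResult(0.0, base, base,
                             {"baseline": (t[0], half), "plateau": (half, t[-1])})
    thr_pos = max(rate_frac * peak_pos, 4.0 * noise)
    thr_neg = max(rate_frac * peak_neg, 4.0 * noise)

    # a minimally smoothed derivative for boundary refinement: exact corner
    # location when the noise allows, otherwise fall back to the heavily
    # smoothed one (biased by at most half the smoothing window)
    fine_win = 3
    Pf = _boxsmooth(P, fine_win)
    dPf = np.gradient(Pf, t)
    noise_f = 1.4826 * float(np.median(np.abs(dPf - np.median(dPf))))

    def refine(i0: int, i1: int, sign: float) -> tuple[int, int]:
        """Expand/contract a ramp run to the 50%-of-interior-rate crossings."""
        rate_mag = float(np.median(sign * dP[i0:i1]))
        use_fine = 4.0 * noise_f < 0.5 * rate_mag
        d = dPf if use_fine else dP
        # short pulses carry their true rate only at the peak of the fine
        # derivative; long ramps are flat so peak == interior rate
        level = 0.5 * (float(np.max(sign * d[i0:i1])) if use_fine
                       else rate_mag)
        a = (i0 + i1) // 2
        while a > 0 and sign * d[a - 1] >= level:
            a -= 1
        b = (i0 + i1) // 2
        while b < t.size - 1 and sign * d[b + 1] >= level:
            b += 1
        return a, b + 1

    rising = dP > thr_pos
    falling = dP < -thr_neg
    idx_rise = _first_run(rising, max(int(round(2.0 / dt)), 2))
    if idx_rise is None:
        raise ValueError("no detectable pressure rise in trace")
    i_r0, i_r1 = refine(*idx_rise, sign=1.0)
    quiet = ~rising & ~falling
    need = int(round(min_plateau_s / dt))
    idx_plateau = _first_run(quiet & (np.arange(t.size) >= i_r1), need)
    if idx_plateau is None:
        raise ValueError("no detectable plateau after the rise")
    i_p1_coarse = idx_plateau[1]
    idx_wd = _first_run(falling & (np.arange(t.size) >= i_p1_coarse - 1), 2)
    if idx_wd is not None:
        i_w0, i_w1 = refine(*idx_wd, sign=-1.0)
    else:
        i_w0 = i_w1 = min(idx_plateau[1], t.size - 1)
    i_p0, i_p1 = i_r1, i_w0
    segments = {
        "baseline": (t[0], t[i_r0]),
        "rise": (t[i_r0], t[min(i_r1, t.size - 1)]),
        "plateau": (t[i_p0], t[min(i_p1, t.size - 1)]),
    }
    if idx_wd is not None:
        segments["withdrawal"] = (t[i_w0], t[min(i_w1, t.size - 1)])
    # means from the raw (unsmoothed) trace, trimming the smoothing width
    pad = win
    base = P[: max(i_r0 - pad, 1)]
    plat = P[i_p0 + pad: max(i_p1 - pad, i_p0 + pad + 1)]
    baseline_mean = float(np.mean(base))
    plateau_mean = float(np.mean(plat))
    return PlateauResult(P_vesicle=plateau_mean - baseline_mean,
                         baseline_mean=baseline_mean,
                         plateau_mean=plateau_mean, segments=segments)


def _boxsmooth(y: np.ndarray, win: int) -> np.ndarray:
    """Box smoothing with edge-value padding (no zero-pad edge artifacts)."""
    if win <= 1:
        return np.asarray(y, float)
    yp = np.pad(np.asarray(y, float), (win // 2, win - 1 - win // 2),
                mode="edge")
    return np.convolve(yp, np.ones(win) / win, mode="valid")


def _first_run(mask: np.ndarray, min_len: int) -> Optional[tuple[int, int]]:
    """Start/end indices of the first True run of length >= min_len."""
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_len:
                return i, j
            i = j
        else:
            i += 1
    return None
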