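"""Myelinated-axon cable model driven by extracellular potential waveforms.

Single-cable fiber: a string of excitable nodes of Ranvier (fast Na,
persistent Na, slow K and leak channels on a capacitive membrane, mammalian
kinetics at 36 C) connected by passive, perfectly insulated internodal
axoplasm.  Fiber diameter classes use the standard mammalian myelinated-fiber
(MRG) table: diameter sets the node spacing, node diameter and internodal
axon caliber.  The extracellular potential enters the cable equation through
second spatial differences across internodes (the activating function), so a
constant potential or constant gradient cannot excite the fiber; an axon is
"activated" when any node's membrane potential crosses +5 mV (absolute).

Two integration routes:

* :func:`simulate_axon` - adaptive Runge-Kutta (solve_ivp RK45) for a single
  fiber, with an early-stopping +5 mV crossing event.  Reference route.
* :func:`simulate_batch` - a numba-compiled fixed-step RK4 integrator with
  tabulated channel rates that advances thousands of independent fibers at
  once.  This is what grid scans use.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp


class IntegrationError(RuntimeError):
    pass


class DomainError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fiber specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberSpec:
    """One myelinated fiber class.

    ``node_spacing_um`` is the internodal (node-to-node) distance; the three
    default classes are (7.3 um, 750 um), (11.5 um, 1250 um), (15 um,
    1450 um).  Node membrane parameters are per unit nodal area.
    """
    diameter_um: float
    node_spacing_um: float
    node_diameter_um: float
    internode_axon_diameter_um: float
    node_count: int = 21
    node_length_um: float = 1.0
    cm: float = 2.0                  # uF/cm^2
    g_naf: float = 3000.0            # mS/cm^2, fast Na
    g_nap: float = 10.0              # mS/cm^2, persistent Na
    g_ks: float = 80.0               # mS/cm^2, slow K
    g_leak: float = 7.0              # mS/cm^2
    e_na: float = 50.0               # mV
    e_k: float = -90.0               # mV
    v_rest: float = -80.0            # mV
    rho_axial_ohm_cm: float = 70.0

    def __post_init__(self):
        if self.node_count < 3 or self.node_count % 2 == 0:
            raise ValueError("node_count must be odd and >= 3")
        if self.node_spacing_um <= 0 or self.internode_axon_diameter_um <= 0:
            raise ValueError("fiber dimensions must be positive")

    @property
    def axial_conductance_mS(self) -> float:
        """Internodal axoplasmic conductance (mS)."""
        d = self.internode_axon_diameter_um * 1e-4     # cm
        L = self.node_spacing_um * 1e-4
        area = np.pi * d * d / 4.0
        return area / (self.rho_axial_ohm_cm * L) * 1e3

    @property
    def node_area_cm2(self) -> float:
        return np.pi * (self.node_diameter_um * 1e-4) * (self.node_length_um * 1e-4)

    @property
    def coupling_mS_per_cm2(self) -> float:
        """Axial conductance normalized by nodal area."""
        return self.axial_conductance_mS / self.node_area_cm2

    def node_z_positions_mm(self, center_mm: float = 0.0,
                            alignment: float = 0.0) -> np.ndarray:
        """Axial node coordinates; ``alignment`` shifts by a fraction of one
        internode (0 = a node sits exactly at ``center_mm``)."""
        n = self.node_count
        dz = self.node_spacing_um * 1e-3
        return center_mm + (np.arange(n) - (n - 1) / 2 + alignment) * dz


#: default fiber classes, ordered by diameter ascending
DEFAULT_FIBER_CLASSES: tuple[FiberSpec, ...] = (
    FiberSpec(7.3, 750.0, 2.4, 4.6),
    FiberSpec(11.5, 1250.0, 3.7, 8.1),
    FiberSpec(15.0, 1450.0, 5.0, 10.4),
)


# ---------------------------------------------------------------------------
# nodal channel kinetics (mammalian, 36 C); V in mV, rates in 1/ms
# ---------------------------------------------------------------------------

def _vtrap(x, k):
    """x / (1 - exp(-x/k)) with the removable singularity filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / k) < 1e-7
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / k))
    return np.where(small, k * (1.0 + x / (2.0 * k)), out)


def alpha_m(V): return 6.57 * _vtrap(V + 20.4, 10.3)
def beta_m(V): return 0.304 * _vtrap(-(V + 25.7), 9.16)
def alpha_h(V): return 0.34 * _vtrap(-(V + 114.0), 11.0)
def beta_h(V): return 12.6 / (1.0 + np.exp(-(V + 31.8) / 13.4))
def alpha_p(V): return 0.0353 * _vtrap(V + 27.0, 10.2)
def beta_p(V): return 0.000883 * _vtrap(-(V + 34.0), 10.0)
def alpha_s(V): return 0.3 / (1.0 + np.exp(-(V + 53.0) / 5.0))
def beta_s(V): return 0.03 / (1.0 + np.exp(-(V + 90.0)))


def gating_steady_state(V: float) -> tuple[float, float, float, float]:
    m = alpha_m(V) / (alpha_m(V) + beta_m(V))
    h = alpha_h(V) / (alpha_h(V) + beta_h(V))
    p = alpha_p(V) / (alpha_p(V) + beta_p(V))
    s = alpha_s(V) / (alpha_s(V) + beta_s(V))
    return float(m), float(h), float(p), float(s)


def leak_reversal(fiber: FiberSpec) -> float:
    """E_leak that makes v_rest an exact equilibrium of the node membrane."""
    V = fiber.v_rest
    m, h, p, s = gating_steady_state(V)
    i_na = fiber.g_naf * m ** 3 * h * (V - fiber.e_na)
    i_nap = fiber.g_nap * p ** 3 * (V - fiber.e_na)
    i_ks = fiber.g_ks * s * (V - fiber.e_k)
    return V + (i_na + i_nap + i_ks) / fiber.g_leak


# ---------------------------------------------------------------------------
# extracellular drive
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtracellularDrive:
    """External potential at each node (mV) and the pulse time course."""
    node_potentials: np.ndarray      # mV, one entry per node
    stim_duration_ms: float = 0.2    # rectangular cathodic phase

    def __post_init__(self):
        v = np.asarray(self.node_potentials, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("node potentials must be finite")
        object.__setattr__(self, "node_potentials", v)

    def scaled(self, alpha: float) -> "ExtracellularDrive":
        return ExtracellularDrive(self.node_potentials * alpha,
                                  self.stim_duration_ms)


def sample_axial_potential(solution, point_xy: tuple[float, float],
                           extent_mm: float = 40.0,
                           spacing_mm: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Sample the field along the axial test line through ``point_xy``.

    Returns (z, potential_mV), the spatial waveform centered on the array.
    ``point_xy`` must lie inside the cord (white or gray matter).
    """
    geom = solution.mesh.geometry
    if geom is not None:
        import shapely
        if not shapely.contains_xy(geom.white_matter_outline, *point_xy):
            raise DomainError(f"point {point_xy} lies outside the cord "
                              "cross-section")
    half = extent_mm / 2.0
    z = np.arange(-half, half + spacing_mm / 2, spacing_mm)
    return z, solution.sample_line(point_xy, z) * 1e3


def drive_from_field(solution, fiber: FiberSpec,
                     point_xy: tuple[float, float],
                     center_mm: float = 0.0, alignment: float = 0.0,
                     stim_duration_ms: float = 0.2) -> ExtracellularDrive:
    """Resample the axial potential waveform at the fiber's node positions."""
    geom = solution.mesh.geometry
    if geom is not None:
        import shapely
        if not shapely.contains_xy(geom.white_matter_outline, *point_xy):
            raise DomainError(f"point {point_xy} lies outside the cord")
    z = fiber.node_z_positions_mm(center_mm, alignment)
    ve = solution.sample_line(point_xy, z) * 1e3
    return ExtracellularDrive(ve, stim_duration_ms)


def activating_function(node_potentials: np.ndarray,
                        spacing: float | None = None) -> np.ndarray:
    """Discrete second difference of the external node potentials.

    Positive central values predict depolarization sites (diagnostic only;
    the activation decision is always made by the membrane dynamics).  With
    ``spacing`` given the result is scaled by 1/spacing^2.
    """
    v = np.asarray(node_potentials, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 nodes")
    d2 = np.zeros_like(v)
    d2[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
    if spacing is not None:
        d2 = d2 / spacing ** 2
    return d2


# ---------------------------------------------------------------------------
# single-axon adaptive integration (reference route)
# ---------------------------------------------------------------------------

@dataclass
class AxonResponse:
    activated: bool
    first_crossing_node: int | None
    times_ms: np.ndarray
    membrane_traces: np.ndarray       # (n_nodes, n_times), mV
    threshold_mV: float = 5.0


def _second_difference_operator(n: int) -> np.ndarray:
    lap = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            lap[i, i - 1] += 1.0
            lap[i, i] -= 1.0
        if i < n - 1:
            lap[i, i + 1] += 1.0
            lap[i, i] -= 1.0
    return lap


def simulate_axon(fiber: FiberSpec, drive: ExtracellularDrive,
                  t_end_ms: float = 1.0, rtol: float = 1e-6,
                  atol: float = 1e-8, early_stop: bool = True,
                  threshold_mV: float = 5.0) -> AxonResponse:
    """Integrate the node ODE system under ``drive``; adaptive RK45.

    The +5 mV crossing event stops the run early (and flags activation)
    unless ``early_stop`` is disabled, in which case the full traces are
    returned (e.g. to observe bidirectional propagation).
    """
    n = fiber.node_count
    ve = np.asarray(drive.node_potentials, dtype=float)
    if ve.shape != (n,):
        raise ValueError("drive node count does not match fiber node count")
    lap = _second_difference_operator(n)
    d2ve = lap @ ve
    ga = fiber.coupling_mS_per_cm2
    el = leak_reversal(fiber)
    m0, h0, p0, s0 = gating_steady_state(fiber.v_rest)
    y0 = np.concatenate([np.full(n, fiber.v_rest), np.full(n, m0),
                         np.full(n, h0), np.full(n, p0), np.full(n, s0)])

    def rhs(t, y, stim):
        V, m, h, p, s = y.reshape(5, n)
        i_ion = (fiber.g_naf * m ** 3 * h * (V - fiber.e_na)
                 + fiber.g_nap * p ** 3 * (V - fiber.e_na)
                 + fiber.g_ks * s * (V - fiber.e_k)
                 + fiber.g_leak * (V - el))
        dv = (-i_ion + ga * (lap @ V + stim * d2ve)) / fiber.cm
        dm = alpha_m(V) * (1 - m) - beta_m(V) * m
        dh = alpha_h(V) * (1 - h) - beta_h(V) * h
        dp = alpha_p(V) * (1 - p) - beta_p(V) * p
        ds = alpha_s(V) * (1 - s) - beta_s(V) * s
        return np.concatenate([dv, dm, dh, dp, ds])

    def crossing(t, y, stim):
        return np.max(y[:n]) - threshold_mV
    crossing.terminal = early_stop
    crossing.direction = 1.0

    t_on = min(drive.stim_duration_ms, t_end_ms)
    times, traces = [], []
    activated = False
    first_node = None
    segments = [(0.0, t_on, 1.0)]
    if t_end_ms > t_on:
        segments.append((t_on, t_end_ms, 0.0))
    y = y0
    for (a, b, stim) in segments:
        sol = solve_ivp(rhs, (a, b), y, args=(stim,), method="RK45",
                        rtol=rtol, atol=atol, events=crossing, max_step=0.05,
                        dense_output=False)
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}")
        times.append(sol.t)
        traces.append(sol.y[:n])
        if sol.t_events[0].size:
            activated = True
            yev = sol.y_events[0][0][:n]
            first_node = int(np.argmax(yev))
            if early_stop:
                break
        y = sol.y[:, -1]
        if activated and early_stop:
            break
    return AxonResponse(activated=activated, first_crossing_node=first_node,
                        times_ms=np.concatenate(times),
                        membrane_traces=np.concatenate(traces, axis=1),
                        threshold_mV=threshold_mV)


# ---------------------------------------------------------------------------
# batch fixed-step engine (numba)
# ---------------------------------------------------------------------------

_V_TAB_MIN, _V_TAB_MAX, _V_TAB_N = -500.0, 300.0, 8001
_rate_tables = None


def _get_rate_tables():
    global _rate_tables
    if _rate_tables is None:
        v = np.linspace(_V_TAB_MIN, _V_TAB_MAX, _V_TAB_N)
        _rate_tables = np.ascontiguousarray(np.stack([
            alpha_m(v), beta_m(v), alpha_h(v), beta_h(v),
            alpha_p(v), beta_p(v), alpha_s(v), beta_s(v)]))
    return _rate_tables


@njit(cache=True, fastmath=True)
def _rk4_batch(V, m, h, p, s, d2ve, ga, cm, gnaf, gnap, gks, gl,
               ena, ek, el, dt, n_on, n_total, vstop, rates, vmin, dvinv,
               stop_on_first):
    M, N = V.shape
    activated = np.zeros(M, dtype=np.bool_)
    first_node = np.full(M, -1, dtype=np.int64)
    vmax = np.full(M, -1e9)
    nrow = rates.shape[1]

    kV = np.empty((4, N)); km = np.empty((4, N)); kh = np.empty((4, N))
    kp = np.empty((4, N)); ks_ = np.empty((4, N))
    Vt = np.empty(N); mt = np.empty(N); ht = np.empty(N)
    pt = np.empty(N); st = np.empty(N)

    for it in range(n_total):
        stim = 1.0 if it < n_on else 0.0
        for i in range(M):
            if activated[i] and stop_on_first:
                continue
            if activated[i]:
                continue
            for stage in range(4):
                if stage == 0:
                    for nn in range(N):
                        Vt[nn] = V[i, nn]; mt[nn] = m[i, nn]; ht[nn] = h[i, nn]
                        pt[nn] = p[i, nn]; st[nn] = s[i, nn]
                else:
                    c = 0.5 * dt if stage < 3 else dt
                    sm1 = stage - 1
                    for nn in range(N):
                        Vt[nn] = V[i, nn] + c * kV[sm1, nn]
                        mt[nn] = m[i, nn] + c * km[sm1, nn]
                        ht[nn] = h[i, nn] + c * kh[sm1, nn]
                        pt[nn] = p[i, nn] + c * kp[sm1, nn]
                        st[nn] = s[i, nn] + c * ks_[sm1, nn]
                for nn in range(N):
                    v0 = Vt[nn]
                    # axial second difference, sealed ends
                    if nn == 0:
                        d2 = Vt[1] - v0
                    elif nn == N - 1:
                        d2 = Vt[N - 2] - v0
                    else:
                        d2 = Vt[nn - 1] - 2.0 * v0 + Vt[nn + 1]
                    # tabulated rates with linear interpolation
                    x = (v0 - vmin) * dvinv
                    if x < 0.0:
                        x = 0.0
                    elif x > nrow - 1.001:
                        x = nrow - 1.001
                    j = int(x)
                    w = x - j
                    am = rates[0, j] + w * (rates[0, j + 1] - rates[0, j])
                    bm = rates[1, j] + w * (rates[1, j + 1] - rates[1, j])
                    ah = rates[2, j] + w * (rates[2, j + 1] - rates[2, j])
                    bh = rates[3, j] + w * (rates[3, j + 1] - rates[3, j])
                    ap = rates[4, j] + w * (rates[4, j + 1] - rates[4, j])
                    bp = rates[5, j] + w * (rates[5, j + 1] - rates[5, j])
                    as_ = rates[6, j] + w * (rates[6, j + 1] - rates[6, j])
                    bs = rates[7, j] + w * (rates[7, j + 1] - rates[7, j])
                    mm = mt[nn]; hh = ht[nn]; pp = pt[nn]; ss = st[nn]
                    i_ion = (gnaf * mm * mm * mm * hh * (v0 - ena)
                             + gnap * pp * pp * pp * (v0 - ena)
                             + gks * ss * (v0 - ek)
                             + gl * (v0 - el))
                    kV[stage, nn] = (-i_ion + ga * (d2 + stim * d2ve[i, nn])) / cm
                    km[stage, nn] = am * (1.0 - mm) - bm * mm
                    kh[stage, nn] = ah * (1.0 - hh) - bh * hh
                    kp[stage, nn] = ap * (1.0 - pp) - bp * pp
                    ks_[stage, nn] = as_ * (1.0 - ss) - bs * ss
            for nn in range(N):
                V[i, nn] += dt / 6.0 * (kV[0, nn] + 2 * kV[1, nn]
                                        + 2 * kV[2, nn] + kV[3, nn])
                m[i, nn] += dt / 6.0 * (km[0, nn] + 2 * km[1, nn]
                                        + 2 * km[2, nn] + km[3, nn])
                h[i, nn] += dt / 6.0 * (kh[0, nn] + 2 * kh[1, nn]
                                        + 2 * kh[2, nn] + kh[3, nn])
                p[i, nn] += dt / 6.0 * (kp[0, nn] + 2 * kp[1, nn]
                                        + 2 * kp[2, nn] + kp[3, nn])
                s[i, nn] += dt / 6.0 * (ks_[0, nn] + 2 * ks_[1, nn]
                                        + 2 * ks_[2, nn] + ks_[3, nn])
                if V[i, nn] > vmax[i]:
                    vmax[i] = V[i, nn]
                if V[i, nn] >= vstop and not activated[i]:
                    activated[i] = True
                    first_node[i] = nn
        if stop_on_first:
            for i in range(M):
                if activated[i]:
                    return activated, first_node, vmax
    return activated, first_node, vmax


def simulate_batch(fiber: FiberSpec, node_potentials: np.ndarray,
                   stim_duration_ms: float = 0.2, t_end_ms: float = 1.0,
                   dt_ms: float = 1e-3, threshold_mV: float = 5.0,
                   stop_on_first: bool = False
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance many independent fibers of one class simultaneously.

    ``node_potentials``: (M, node_count) external potentials in mV.  Returns
    (activated, first_crossing_node, peak_membrane_potential) arrays.
    """
    ve = np.atleast_2d(np.asarray(node_potentials, dtype=float))
    Mq, N = ve.shape
    if N != fiber.node_count:
        raise ValueError("drive node count does not match fiber node count")
    d2ve = np.zeros_like(ve)
    d2ve[:, 1:-1] = ve[:, :-2] - 2 * ve[:, 1:-1] + ve[:, 2:]
    d2ve[:, 0] = ve[:, 1] - ve[:, 0]
    d2ve[:, -1] = ve[:, -2] - ve[:, -1]
    m0, h0, p0, s0 = gating_steady_state(fiber.v_rest)
    V = np.full((Mq, N), fiber.v_rest)
    m = np.full((Mq, N), m0); h = np.full((Mq, N), h0)
    p = np.full((Mq, N), p0); s = np.full((Mq, N), s0)
    rates = _get_rate_tables()
    dvinv = (_V_TAB_N - 1) / (_V_TAB_MAX - _V_TAB_MIN)
    n_total = int(round(t_end_ms / dt_ms))
    n_on = min(int(round(stim_duration_ms / dt_ms)), n_total)
    act, node, vmax = _rk4_batch(
        V, m, h, p, s, d2ve, fiber.coupling_mS_per_cm2, fiber.cm,
        fiber.g_naf, fiber.g_nap, fiber.g_ks, fiber.g_leak,
        fiber.e_na, fiber.e_k, leak_reversal(fiber), dt_ms,
        n_on, n_total, threshold_mV, rates, _V_TAB_MIN, dvinv,
        stop_on_first)
    return act, node, vmax


# ---------------------------------------------------------------------------
# threshold search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdResult:
    excitable: bool
    threshold_scale: float | None
    bracket: tuple[float, float] | None


def threshold_search(fiber: FiberSpec, unit_drive: ExtracellularDrive,
                     pulse_duration_ms: float | None = None,
                     max_scale: float = 1e3, rel_tol: float = 0.01,
                     engine: str = "batch", t_end_ms: float = 1.0,
                     dt_ms: float = 1e-3) -> ThresholdResult:
    """Minimal drive scale that activates the fiber (bisection, 1% bracket).

    Deterministic; returns a not-excitable result (not an exception) if no
    activation occurs below ``max_scale``.
    """
    dur = (pulse_duration_ms if pulse_duration_ms is not None
           else unit_drive.stim_duration_ms)

    def activates(scale: float) -> bool:
        ve = unit_drive.node_potentials * scale
        if engine == "batch":
            act, _, _ = simulate_batch(fiber, ve[None, :], dur, t_end_ms,
                                       dt_ms, stop_on_first=True)
            return bool(act[0])
        resp = simulate_axon(fiber, ExtracellularDrive(ve, dur),
                             t_end_ms=t_end_ms)
        return resp.activated

    hi = 1.0
    while not activates(hi):
        hi *= 2.0
        if hi > max_scale:
            return ThresholdResult(False, None, None)
    lo = hi / 2.0 if hi > 1.0 else 0.0
    while lo == 0.0 or (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi) if lo > 0 else hi / 2.0
        if activates(mid):
            hi = mid
        else:
            lo = mid
        if lo > 0 and (hi - lo) / hi <= rel_tol:
            break
    return ThresholdResult(True, hi, (lo, hi))
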