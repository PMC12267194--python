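"""Reduced-order aortic hemodynamics with VA-ECMO support.

The 3D flow problem is reduced to a lumped vascular network: Poiseuille
resistances derived from the tract geometry connect the aortic root, the
three supra-aortic ostia and the descending outlet; every outflow boundary
carries a three-element Windkessel (RCR) whose distal pressure obeys

    C dP_d/dt = Q - (P_d - P0)/Rd,     P_outlet = P_d + Rp Q,

equivalent to the convolution form
P(t) = (P0' - Rp Q0) e^(-t/tau) + Rp Q(t) + int_0^t e^(-(t-u)/tau) Q(u)/C du
with tau = Rd C. Node pressures are solved from the (linear) resistive
network coupled to the implicit-Euler Windkessel states at every timestep.

ECMO support injects a constant retrograde flow at the descending aorta. In
that configuration the descending boundary becomes a pure flow source and an
abdominal outlet (with the descending Windkessel) is appended below the
entry point, so distal perfusion is retained. The ECMO-blood fraction
phi(s, t) (0 = native, 1 = ECMO blood) is advected along the aortic axis
with a conservative first-order upwind scheme; the watershed is the most
proximal axial position where the net axial flow changes sign.

Internally SI units; the interface reports pressures in mmHg and flows in
L/min (1 mmHg = 133.322 Pa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .morphometry import BRANCH_NAMES, TractSet

__all__ = [
    "MMHG", "LMIN",
    "FluidProps", "FlowWaveform", "WindkesselParams", "WindkesselState",
    "VesselNetwork", "SimulationConfig", "SimulationResult", "WatershedReport",
    "CalibrationTargets", "CalibrationError",
    "poiseuille_resistance", "build_network", "rcr_outlet_step", "scale_waveform",
    "simulate", "transport_fraction", "watershed_location", "mean_flow",
    "calibrate_rcr", "default_cardiac_waveform",
]

MMHG = 133.322  # Pa per mmHg
LMIN = 1e-3 / 60.0  # m^3/s per L/min

OUTLET_NAMES = (*BRANCH_NAMES, "descending")


@dataclass(frozen=True)
class FluidProps:
    """Blood as an incompressible Newtonian fluid."""

    density: float = 1060.0  # kg/m^3
    viscosity: float = 3.5e-3  # Pa*s (dynamic)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("fluid density and viscosity must be positive")


@dataclass(frozen=True)
class FlowWaveform:
    """Periodic flow waveform over one cardiac cycle (SI: m^3/s)."""

    t: np.ndarray  # (n,), 0 .. period
    q: np.ndarray  # (n,), m^3/s; q[0] == q[-1]
    period: float = 0.8  # s

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if t.shape != q.shape or t.ndim != 1 or t.shape[0] < 3:
            raise ValueError("waveform needs matching 1D t and q arrays")
        if not np.all(np.isfinite(q)):
            raise ValueError("waveform contains non-finite samples")
        if abs(t[0]) > 1e-12 or abs(t[-1] - self.period) > 1e-9:
            raise ValueError("waveform samples must span exactly [0, period]")
        if abs(q[0] - q[-1]) > 1e-12 * max(1.0, np.abs(q).max()):
            raise ValueError("waveform must be periodic (first sample == last sample)")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "q", q)

    @property
    def cycle_mean(self) -> float:
        """Cycle-mean flow, m^3/s (trapezoidal)."""
        return float(np.trapezoid(self.q, self.t) / self.period)

    @property
    def cycle_mean_lmin(self) -> float:
        return self.cycle_mean / LMIN

    def sample(self, t: float | np.ndarray) -> np.ndarray:
        """Periodic interpolation of Q at arbitrary times."""
        return np.interp(np.mod(t, self.period), self.t, self.q)


def default_cardiac_waveform(
    mean_lmin: float = 5.0,
    period: float = 0.8,
    systole_fraction: float = 0.35,
    n_samples: int = 801,
) -> FlowWaveform:
    """Idealized aortic-valve waveform: a rectified two-term sinusoid.

    Forward ejection during the systolic fraction of the cycle (half-sine
    with a second-harmonic skew toward an early peak) and zero diastolic
    inflow; scaled so the cycle mean is exactly ``mean_lmin``.
    """
    t = np.linspace(0.0, period, n_samples)
    theta = t / (systole_fraction * period)
    raw = np.where(theta < 1.0,
                   np.maximum(0.0, np.sin(np.pi * theta) + 0.25 * np.sin(2 * np.pi * theta)),
                   0.0)
    w = FlowWaveform(t=t, q=raw * LMIN, period=period)
    return scale_waveform(w, target_mean_lmin=mean_lmin)


def scale_waveform(
    w: FlowWaveform,
    target_mean_lmin: float | None = None,
    reduction: float | None = None,
) -> FlowWaveform:
    """Uniform multiplicative rescaling of a waveform.

    Exactly one of ``target_mean_lmin`` (desired cycle mean, L/min) or
    ``reduction`` (fractional cardiac-output reduction, e.g. 0.70) must be
    given.
    """
    if (target_mean_lmin is None) == (reduction is None):
        raise ValueError("give exactly one of target_mean_lmin or reduction")
    mean = w.cycle_mean
    if mean <= 0:
        raise ValueError("waveform cycle mean must be positive to rescale")
    if target_mean_lmin is not None:
        if target_mean_lmin <= 0:
            raise ValueError("target mean flow must be positive")
        factor = target_mean_lmin * LMIN / mean
    else:
        if not (0 <= reduction < 1):
            raise ValueError("reduction must lie in [0, 1)")
        factor = 1.0 - reduction
    return FlowWaveform(t=w.t, q=w.q * factor, period=w.period)


# ---------------------------------------------------------------------------
# Windkessel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: proximal R, distal R, compliance."""

    Rp: float  # Pa*s/m^3
    Rd: float  # Pa*s/m^3
    C: float  # m^3/Pa
    P0: float = 0.0  # Pa, distal reference (venous) pressure

    def __post_init__(self) -> None:
        if self.Rp <= 0 or self.Rd <= 0 or self.C <= 0:
            raise ValueError("Windkessel Rp, Rd, C must all be positive")

    @property
    def tau(self) -> float:
        """Time constant Rd*C (s)."""
        return self.Rd * self.C


@dataclass
class WindkesselState:
    """Time-stepped Windkessel with exact exponential integration.

    Over one step with the inflow held constant, the distal-pressure ODE has
    the closed-form update used here, so the stepped pressure matches the
    convolution solution exactly for piecewise-constant Q.
    """

    params: WindkesselParams
    P_d: float = 0.0  # Pa, distal (capacitor) pressure

    def step(self, Q: float, dt: float) -> float:
        """Advance one step at constant inflow Q; returns the outlet pressure."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        p = self.params
        steady = p.P0 + p.Rd * Q
        self.P_d = steady + (self.P_d - steady) * np.exp(-dt / p.tau)
        return self.P_d + p.Rp * Q


def rcr_outlet_step(state: WindkesselState, Q: float, dt: float) -> float:
    """Functional alias for :meth:`WindkesselState.step`."""
    return state.step(Q, dt)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def poiseuille_resistance(viscosity: float, length: float, radius: float) -> float:
    """R = 8 mu L / (pi r^4), SI units."""
    if radius <= 0:
        raise ValueError("non-positive radius in Poiseuille resistance")
    if length < 0:
        raise ValueError("negative segment length")
    return 8.0 * viscosity * length / (np.pi * radius**4)


@dataclass(frozen=True)
class _Segment:
    name: str
    a: int  # upstream junction index
    b: int  # downstream junction index
    R: float  # Pa*s/m^3
    s0: float  # m, axial interval on the aortic axis (nan for branches)
    s1: float


@dataclass(frozen=True)
class _Outlet:
    name: str
    junction: int
    R_access: float  # Pa*s/m^3, branch/cannula resistance in series with Rp


@dataclass
class VesselNetwork:
    """Lumped thoracic-aorta network derived from the seven tracts."""

    junction_names: list[str]
    segments: list[_Segment]
    outlets: dict[str, _Outlet]
    windkessels: dict[str, WindkesselParams]  # populated by calibrate_rcr
    ostia_s: dict[str, float]  # m, branch ostium arc positions on the aorta
    s_ecmo: float  # m, ECMO entry position (thoracic descending end)
    total_length: float  # m, aortic axis incl. abdominal extension if present
    axis_s: np.ndarray  # m, samples along the aortic axis
    axis_r: np.ndarray  # m, inscribed radii at axis_s
    fluid: FluidProps
    with_ecmo_return: bool

    @property
    def root(self) -> int:
        return self.junction_names.index("root")

    def area(self, s: np.ndarray) -> np.ndarray:
        """Lumen cross-sectional area (m^2) along the aortic axis."""
        r = np.interp(s, self.axis_s, self.axis_r)
        return np.pi * r**2


_MM = 1e-3


def build_network(
    tracts: TractSet,
    fluid: FluidProps | None = None,
    with_ecmo_return: bool = False,
    abdominal_length_mm: float = 150.0,
) -> VesselNetwork:
    """Build the lumped network from a tract set.

    Each segment's resistance uses the Poiseuille law with the segment's
    centerline length and mean inscribed radius. ``with_ecmo_return`` appends
    an abdominal segment + outlet below the ECMO entry point (the shock /
    ECMO topology); otherwise the descending outlet sits at the thoracic
    descending end (the healthy topology).
    """
    fluid = fluid or FluidProps()
    total = tracts["total"]
    if total.radii is None:
        raise ValueError("total tract carries no inscribed radii")
    s = total.arclength * _MM
    r = total.radii * _MM
    if np.any(r <= 0):
        raise ValueError("non-positive inscribed radius on the aortic axis")
    ostia_s = {k: v * _MM for k, v in tracts.ostia_s.items()}
    s_end = float(s[-1])

    def _aortic_R(sa: float, sb: float) -> float:
        mask = (s >= sa - 1e-12) & (s <= sb + 1e-12)
        rmean = float(np.mean(r[mask])) if mask.any() else float(np.interp(sa, s, r))
        # a bovine arch collapses the BCA-LCCA interval to a point; keep the
        # junctions distinct with the (short) shared-trunk length floor
        length = max(sb - sa, 0.5 * _MM)
        return poiseuille_resistance(fluid.viscosity, length, rmean)

    junctions = ["root", "bca_j", "lcca_j", "lsa_j", "desc_end"]
    bounds = [0.0, ostia_s["BCA"], ostia_s["LCCA"], ostia_s["LSA"], s_end]
    seg_names = ["ascending", "arch_bca_lcca", "arch_lcca_lsa", "descending"]
    segments = [
        _Segment(name, i, i + 1, _aortic_R(bounds[i], bounds[i + 1]),
                 bounds[i], bounds[i + 1])
        for i, name in enumerate(seg_names)
    ]

    outlets: dict[str, _Outlet] = {}
    for j, name in enumerate(BRANCH_NAMES, start=1):
        br = tracts[name]
        if br.radii is None:
            raise ValueError(f"branch tract {name} carries no inscribed radii")
        rmean = float(np.mean(br.radii[1:])) * _MM  # skip the aortic ostium point
        R_access = poiseuille_resistance(fluid.viscosity, br.length * _MM, rmean)
        outlets[name] = _Outlet(name=name, junction=j, R_access=R_access)

    axis_s, axis_r = s, r
    if with_ecmo_return:
        junctions.append("abd_end")
        L_abd = abdominal_length_mm * _MM
        r_abd = float(r[-1])
        segments.append(_Segment("abdominal", 4, 5,
                                 poiseuille_resistance(fluid.viscosity, L_abd, r_abd),
                                 s_end, s_end + L_abd))
        outlets["descending"] = _Outlet(name="descending", junction=5, R_access=0.0)
        axis_s = np.concatenate([s, [s_end + L_abd]])
        axis_r = np.concatenate([r, [r_abd]])
        total_length = s_end + L_abd
    else:
        outlets["descending"] = _Outlet(name="descending", junction=4, R_access=0.0)
        total_length = s_end

    return VesselNetwork(
        junction_names=junctions, segments=segments, outlets=outlets,
        windkessels={}, ostia_s=ostia_s, s_ecmo=s_end, total_length=total_length,
        axis_s=axis_s, axis_r=axis_r, fluid=fluid, with_ecmo_return=with_ecmo_return,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Run controls: 3 cycles of 0.8 s at 1 ms steps by default."""

    dt: float = 1e-3  # s
    n_cycles: int = 3
    ef_lmin: float = 0.0  # constant ECMO flow, L/min
    mode: str = "healthy"  # healthy | shock

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.ef_lmin < 0:
            raise ValueError("EF must be non-negative")
        if self.mode not in ("healthy", "shock"):
            raise ValueError("mode must be 'healthy' or 'shock'")

    def validate_against(self, period: float) -> None:
        if self.dt > period / 200.0:
            raise ValueError(f"timestep {self.dt} exceeds period/200 = {period / 200.0}")


@dataclass
class SimulationResult:
    """Per-timestep network state plus derived ECMO-fraction diagnostics."""

    t: np.ndarray  # (nt,)
    junction_names: list[str]
    P_junction: np.ndarray  # (nt, nj), Pa
    outlet_flows: dict[str, np.ndarray]  # m^3/s, measured at the outlet boundary
    outlet_pressures: dict[str, np.ndarray]  # Pa
    segment_flows: dict[str, np.ndarray]  # m^3/s, positive downstream
    cardiac_q: np.ndarray  # (nt,), imposed root inflow, m^3/s
    period: float
    config: SimulationConfig
    phi: np.ndarray | None = None  # (nt, n_cells), ECMO fraction
    phi_s: np.ndarray | None = None  # (n_cells,), cell-center arc positions, m

    def final_cycle(self) -> np.ndarray:
        """Boolean mask of the samples in the last simulated cycle."""
        return self.t >= (self.config.n_cycles - 1) * self.period - 1e-12

    def root_pressure_mmhg(self) -> np.ndarray:
        return self.P_junction[:, self.junction_names.index("root")] / MMHG

    def peak_root_pressure_mmhg(self) -> float:
        m = self.final_cycle()
        return float(self.root_pressure_mmhg()[m].max())

    def mean_outlet_flows_lmin(self) -> dict[str, float]:
        return {
            name: mean_flow(q, self.t, self.period)
            for name, q in self.outlet_flows.items()
        }

    def systolic_peak_index(self) -> int:
        m = np.nonzero(self.final_cycle())[0]
        return int(m[np.argmax(self.cardiac_q[m])])

    def diastolic_index(self) -> int:
        m = np.nonzero(self.final_cycle())[0]
        return int(m[np.argmin(self.cardiac_q[m])])


def mean_flow(q: np.ndarray, t: np.ndarray, period: float) -> float:
    """Cycle-mean flow over the final full cycle, in L/min.

    The cycle integral of Q is divided by the period so the result is a flow
    (L/min) rather than a volume.
    """
    t = np.asarray(t, dtype=float)
    q = np.asarray(q, dtype=float)
    if t[-1] - t[0] < period - 1e-9:
        raise ValueError("flow series does not cover a full cycle")
    t0 = t[-1] - period
    mask = t > t0 + 1e-12
    # exact one-period window: interpolate the seam sample at t0
    tw = np.concatenate(([t0], t[mask]))
    qw = np.concatenate(([np.interp(t0, t, q)], q[mask]))
    return float(np.trapezoid(qw, tw) / period / LMIN)


def simulate(
    net: VesselNetwork,
    cardiac: FlowWaveform,
    cfg: SimulationConfig | None = None,
) -> SimulationResult:
    """Run the lumped network for ``n_cycles`` cardiac cycles.

    Per step the cardiac flow is imposed at the root and (in the ECMO
    topology) the constant EF at the descending entry; junction pressures and
    Windkessel distal pressures solve one linear system (implicit Euler on
    the capacitor states). The resistive interior stores no volume, so the
    instantaneous sum of outlet boundary flows equals the total imposed
    inflow to solver precision.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate_against(cardiac.period)
    if cfg.ef_lmin > 0 and not net.with_ecmo_return:
        raise ValueError("EF > 0 requires a network built with with_ecmo_return=True")
    missing = [n for n in net.outlets if n not in net.windkessels]
    if missing:
        raise ValueError(f"outlets without Windkessel parameters: {missing}")

    nj = len(net.junction_names)
    outlet_names = list(net.outlets)
    nk = len(outlet_names)
    dt = cfg.dt
    ef = cfg.ef_lmin * LMIN

    # assemble the constant system matrix over x = [P_junctions, P_d outlets]
    A = np.zeros((nj + nk, nj + nk))
    for seg in net.segments:
        g = 1.0 / seg.R
        A[seg.a, seg.a] += g
        A[seg.a, seg.b] -= g
        A[seg.b, seg.b] += g
        A[seg.b, seg.a] -= g
    R_eff = {}
    for k, name in enumerate(outlet_names):
        o = net.outlets[name]
        wk = net.windkessels[name]
        Re = o.R_access + wk.Rp
        R_eff[name] = Re
        g = 1.0 / Re
        j, d = o.junction, nj + k
        A[j, j] += g
        A[j, d] -= g
        A[d, d] = wk.C / dt + 1.0 / wk.Rd + g
        A[d, j] = -g
    lu = lu_factor(A)

    n_steps = int(round(cfg.n_cycles * cardiac.period / dt))
    t_grid = np.arange(n_steps + 1) * dt
    q_card = cardiac.sample(t_grid)

    # initialize distal pressures near their mean operating point
    q_mean_total = cardiac.cycle_mean + ef
    g_tot = sum(1.0 / (R_eff[n] + net.windkessels[n].Rd) for n in outlet_names)
    P_d = np.array([
        net.windkessels[n].P0
        + net.windkessels[n].Rd * q_mean_total
        * (1.0 / (R_eff[n] + net.windkessels[n].Rd)) / g_tot
        for n in outlet_names
    ])

    P_jun = np.zeros((n_steps + 1, nj))
    Q_out = {n: np.zeros(n_steps + 1) for n in outlet_names}
    P_out = {n: np.zeros(n_steps + 1) for n in outlet_names}
    Q_seg = {s.name: np.zeros(n_steps + 1) for s in net.segments}

    src_root = net.root
    src_ecmo = net.junction_names.index("desc_end") if net.with_ecmo_return else None

    b = np.zeros(nj + nk)
    for i in range(n_steps + 1):
        b[:] = 0.0
        b[src_root] = q_card[i]
        if src_ecmo is not None:
            b[src_ecmo] += ef
        for k, name in enumerate(outlet_names):
            wk = net.windkessels[name]
            b[nj + k] = wk.C / dt * P_d[k] + wk.P0 / wk.Rd
        x = lu_solve(lu, b)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("linear solve diverged (non-finite pressures); "
                               "check network connectivity and Windkessel parameters")
        P = x[:nj]
        P_d = x[nj:]
        P_jun[i] = P
        for seg in net.segments:
            Q_seg[seg.name][i] = (P[seg.a] - P[seg.b]) / seg.R
        for k, name in enumerate(outlet_names):
            o = net.outlets[name]
            q = (P[o.junction] - P_d[k]) / R_eff[name]
            Q_out[name][i] = q
            P_out[name][i] = P_d[k] + net.windkessels[name].Rp * q

    return SimulationResult(
        t=t_grid, junction_names=list(net.junction_names), P_junction=P_jun,
        outlet_flows=Q_out, outlet_pressures=P_out, segment_flows=Q_seg,
        cardiac_q=q_card, period=cardiac.period, config=cfg,
    )


# ---------------------------------------------------------------------------
# ECMO-fraction transport
# ---------------------------------------------------------------------------

def _axial_face_flows(result: SimulationResult, net: VesselNetwork,
                      faces: np.ndarray) -> np.ndarray:
    """Net axial flow (m^3/s, positive downstream) at face positions/time.

    Cumulative balance: the flow just below position s is the cardiac inflow
    minus the branch draws above s, plus EF below the entry point.
    """
    nt = result.t.shape[0]
    Q = np.repeat(result.cardiac_q[:, None], faces.shape[0], axis=1)
    for name in BRANCH_NAMES:
        s_o = net.ostia_s[name]
        Q[:, faces > s_o + 1e-12] -= result.outlet_flows[name][:, None]
    ef = result.config.ef_lmin * LMIN
    if net.with_ecmo_return and ef > 0:
        Q[:, faces > net.s_ecmo + 1e-12] += ef
    return Q


def transport_fraction(
    result: SimulationResult,
    net: VesselNetwork,
    n_cells: int = 240,
) -> np.ndarray:
    """Advect the ECMO-blood fraction phi along the aortic axis.

    Conservative finite-volume first-order upwind transport with velocity
    Q(s,t)/A(s); native blood (phi = 0) enters at the root, ECMO blood
    (phi = 1) at the descending entry; branch uptake removes fluid at the
    ostium cell's fraction. Sub-steps automatically when the CFL number
    exceeds 1 (with a warning). Fills ``result.phi`` / ``result.phi_s`` and
    returns phi with shape (nt, n_cells).
    """
    L = net.total_length
    faces = np.linspace(0.0, L, n_cells + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    ds = faces[1] - faces[0]
    area = net.area(centers)
    vol = area * ds

    Qf = _axial_face_flows(result, net, faces)
    ef = result.config.ef_lmin * LMIN
    ecmo_cell = min(int(net.s_ecmo / ds), n_cells - 1) if net.with_ecmo_return else None
    branch_cells = {name: min(int(net.ostia_s[name] / ds), n_cells - 1)
                    for name in BRANCH_NAMES}

    dt = result.config.dt
    umax = np.abs(Qf).max() / area.min()
    n_sub = max(1, int(np.ceil(umax * dt / ds)))
    if n_sub > 1:
        warnings.warn(f"transport CFL > 1 at dt={dt}; sub-stepping x{n_sub}")
    dts = dt / n_sub

    nt = result.t.shape[0]
    phi = np.zeros((nt, n_cells))
    ph = np.zeros(n_cells)
    for i in range(1, nt):
        qf = Qf[i]
        q_in = {name: result.outlet_flows[name][i] for name in BRANCH_NAMES}
        for _ in range(n_sub):
            # upwind face fluxes of phi
            interior = qf[1:-1]
            up = np.where(interior >= 0, ph[:-1], ph[1:])
            flux = np.empty(n_cells + 1)
            flux[1:-1] = interior * up
            flux[0] = qf[0] * (0.0 if qf[0] >= 0 else ph[0])  # root: native blood in
            flux[-1] = qf[-1] * ph[-1]  # distal boundary carries the end-cell fraction
            dphi = (flux[:-1] - flux[1:]) / vol
            for name, cell in branch_cells.items():
                dphi[cell] -= q_in[name] * ph[cell] / vol[cell]
            if ecmo_cell is not None and ef > 0:
                # injected ECMO blood enters at phi = 1; the matching extra
                # face outflow is already in the face-flux jump at the entry
                dphi[ecmo_cell] += ef / vol[ecmo_cell]
            ph = ph + dts * dphi
        if ph.min() < -1e-9 or ph.max() > 1.0 + 1e-9:
            raise RuntimeError("ECMO fraction left [0, 1] beyond tolerance")
        ph = np.clip(ph, 0.0, 1.0)
        phi[i] = ph
    result.phi = phi
    result.phi_s = centers
    return phi


def branch_fraction(result: SimulationResult, net: VesselNetwork) -> dict[str, float]:
    """Final-cycle mean ECMO fraction taken up by each supra-aortic branch."""
    if result.phi is None:
        raise ValueError("run transport_fraction first")
    m = result.final_cycle()
    ds = result.phi_s[1] - result.phi_s[0]
    out = {}
    for name in BRANCH_NAMES:
        cell = min(int(net.ostia_s[name] / ds), result.phi.shape[1] - 1)
        out[name] = float(result.phi[m, cell].mean())
    return out


# ---------------------------------------------------------------------------
# watershed
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WatershedReport:
    """Watershed (native/ECMO mixing) localization at one cardiac phase."""

    phase: str  # systolic | diastolic
    zone: str  # ascending | BCA-LCCA | LCCA-LSA | at-LSA | descending | none
    s_star: float  # m; most proximal stagnation position (total length if none)
    multiple_sign_changes: bool = False


_SEG_ORDER = ("ascending", "arch_bca_lcca", "arch_lcca_lsa", "descending", "abdominal")
_ZONE_OF_FIRST_NONPOSITIVE = {
    "ascending": "ascending",
    "arch_bca_lcca": "BCA-LCCA",
    "arch_lcca_lsa": "LCCA-LSA",
    "descending": "at-LSA",
    "abdominal": "descending",
}


def watershed_location(
    result: SimulationResult, net: VesselNetwork, phase: str = "systolic"
) -> WatershedReport:
    """Locate the watershed at the systolic peak or in diastole.

    The queried instant is the time of maximum (systolic) or minimum
    (diastolic) cardiac inflow within the final cycle. The watershed arc
    position s* is the upstream boundary of the most proximal aortic segment
    whose net axial flow is non-positive; if every segment is antegrade the
    zone is 'none' (EF insufficient to oppose the cardiac stream) and s* is
    the full axial length. Multiple sign changes are flagged and the most
    proximal one reported.
    """
    if phase == "systolic":
        i = result.systolic_peak_index()
    elif phase == "diastolic":
        i = result.diastolic_index()
    else:
        raise ValueError("phase must be 'systolic' or 'diastolic'")

    seg_names = [s.name for s in net.segments]
    flows = [result.segment_flows[name][i] for name in seg_names]
    bounds = [0.0] + [s.s1 for s in net.segments]
    nonpos = [q <= 0.0 for q in flows]
    sign_changes = sum(
        1 for a, b in zip(nonpos[:-1], nonpos[1:]) if a != b
    )
    if not any(nonpos):
        return WatershedReport(phase=phase, zone="none", s_star=net.total_length,
                               multiple_sign_changes=False)
    k = nonpos.index(True)
    zone = _ZONE_OF_FIRST_NONPOSITIVE[seg_names[k]]
    return WatershedReport(phase=phase, zone=zone, s_star=float(bounds[k]),
                           multiple_sign_changes=sign_changes > 1)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTargets:
    """Calibration conventions for the healthy template run.

    The flow split across the four outlets and the Windkessel time constant
    are package defaults (the underlying physiology offers no unique values);
    the peak-pressure band is the physiological systolic range the healthy
    run must land in.
    """

    peak_pressure_band_mmhg: tuple[float, float] = (120.0, 130.0)
    flow_split: Mapping[str, float] = field(default_factory=lambda: {
        "BCA": 0.15, "LCCA": 0.075, "LSA": 0.075, "descending": 0.70,
    })
    tau: float = 1.5  # s, Rd*C per outlet
    rp_fraction: float = 0.1  # Rp / (Rp + Rd)
    split_tolerance: float = 0.01  # relative, per outlet
    max_iterations: int = 20
    venous_pressure_mmhg: float = 0.0


class CalibrationError(RuntimeError):
    """Raised when the fixed-point calibration fails to reach its targets."""

    def __init__(self, message: str, last_iterate: dict | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate or {}


def calibrate_rcr(
    net: VesselNetwork,
    cardiac: FlowWaveform,
    targets: CalibrationTargets | None = None,
    cfg: SimulationConfig | None = None,
) -> dict[str, WindkesselParams]:
    """Fit per-outlet Windkessel parameters to the target split and band.

    Total peripheral resistance starts at (band-center pressure)/(cardiac
    mean flow) and per-outlet resistances at the target split; then up to
    ``max_iterations`` deterministic fixed-point passes rescale each outlet
    by its measured-vs-target split ratio and the whole set by the measured
    peak-vs-band-center pressure ratio, until every cycle-mean split is
    within tolerance and the peak root pressure lies inside the band. The
    fitted parameters are attached to ``net.windkessels``.
    """
    targets = targets or CalibrationTargets()
    cfg = cfg or SimulationConfig(mode="healthy")
    split = dict(targets.flow_split)
    if set(split) != set(net.outlets):
        raise ValueError(f"flow-split targets {set(split)} do not match outlets "
                         f"{set(net.outlets)}")
    ssum = sum(split.values())
    split = {k: v / ssum for k, v in split.items()}

    q_mean = cardiac.cycle_mean
    if q_mean <= 0:
        raise ValueError("cardiac cycle-mean flow must be positive")
    lo, hi = targets.peak_pressure_band_mmhg
    p_mid = 0.5 * (lo + hi) * MMHG
    p0 = targets.venous_pressure_mmhg * MMHG

    # initial per-outlet total resistance from an Ohmic split of the band center
    R_tot = {name: p_mid / (split[name] * q_mean) for name in split}

    def _params(name: str) -> WindkesselParams:
        R = max(R_tot[name] - net.outlets[name].R_access, 0.05 * R_tot[name])
        Rp = targets.rp_fraction * R
        Rd = R - Rp
        return WindkesselParams(Rp=Rp, Rd=Rd, C=targets.tau / Rd, P0=p0)

    last: dict = {}
    for iteration in range(targets.max_iterations):
        net.windkessels = {name: _params(name) for name in split}
        res = simulate(net, cardiac, cfg)
        means = res.mean_outlet_flows_lmin()
        total = sum(means.values())
        measured_split = {k: v / total for k, v in means.items()}
        peak = res.peak_root_pressure_mmhg()
        split_err = max(abs(measured_split[k] - split[k]) / split[k] for k in split)
        last = {"iteration": iteration, "peak_mmhg": peak,
                "split": measured_split, "split_err": split_err}
        if split_err <= targets.split_tolerance and lo <= peak <= hi:
            return net.windkessels
        for k in split:
            R_tot[k] *= measured_split[k] / split[k]
        scale = peak * MMHG / p_mid
        for k in split:
            R_tot[k] /= scale
    raise CalibrationError(
        f"calibration did not reach the targets in {targets.max_iterations} passes "
        f"(last iterate: {last})", last_iterate=last,
    )
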