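"""Modified Hodgkin-Huxley propagating action potential on a finite cable.

The membrane model is the squid-axon Hodgkin-Huxley system with two
modifications that matter for the physiology simulated here:

* the potassium deactivation rate ``beta_n`` follows the Clay
  parameterization, which increases subthreshold potassium activation and
  gives the axon Type 3 excitability (a single spike in response to a
  sustained depolarizing current) at the normal conductance ratio;
* the membrane capacitance is time varying, ``C_m(t) = C_0 + C_g(t)``, where
  the gating capacitance ``C_g = 0.13 (G_Na/120) (1 - m)`` uF/cm^2 is carried
  by the gating charge of closed sodium channels.  This term is what makes
  conduction velocity saturate and then fall at high sodium conductance.

Temperature enters through a single Q10 factor ``3**((T - 6.3)/10)`` applied
to all six rate constants.  The leak reversal potential is not free: it is
fitted for every ``(G_Na, G_K)`` pair so that -65 mV is a stationary resting
state.

All conductances are peak specific conductances in mS/cm^2, voltages in mV,
time in ms, distances in cm; membrane current densities are then uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from ._kernel import run_cable

__all__ = [
    "CableParams",
    "Conductances",
    "APMetrics",
    "Excitability",
    "SimulationUnstableError",
    "rate_constants",
    "steady_state_gates",
    "solve_leak_potential",
    "gating_capacitance",
    "simulate",
    "analyze_trace",
    "classify_excitability",
    "find_threshold_current",
]

V_REST = -65.0

# Conduction success requires a full-amplitude action potential at the distal
# site, not merely any depolarizing wave: the model sustains marginal
# small-amplitude travelling waves (peaking ~ +5.1 mV) beyond the conduction
# cliffs, while the first fully regenerative wave peaks at >= +5.5 mV.  The
# +5.2 mV level (~70 mV above rest) separates the two branches; success also
# requires the membrane to repolarize after the wave has passed.
FULL_AP_LEVEL_MV = 5.2
REPOL_LEVEL_MV = -50.0


class SimulationUnstableError(RuntimeError):
    """Voltage became non-finite during a cable simulation."""


@dataclass(frozen=True)
class CableParams:
    """Geometry, passive properties, kinetics temperature and protocol.

    Defaults are the squid giant-axon values: a 10 cm cable of radius
    238 um, axial resistivity 0.0354 kOhm cm, leak 0.3 mS/cm^2, intrinsic
    capacitance 0.88 uF/cm^2 and a 20 uA / 0.1 ms stimulus applied to the
    first compartment.
    """

    length_cm: float = 10.0
    radius_cm: float = 238e-4
    axial_resistivity_kohm_cm: float = 0.0354
    g_leak: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    c0: float = 0.88
    cg_max: float = 0.13
    g_na_ref: float = 120.0
    temperature_c: float = 18.5
    dt_ms: float = 1e-3
    dx_cm: float = 1e-2
    stim_amplitude_ua: float = 20.0
    stim_duration_ms: float = 0.1
    stim_extent_cm: float | None = None  # None -> one compartment (dx)
    expand_cm_derivative: bool = False  # include the V dC_m/dt gating term
    t_total_ms: float = 15.0

    def __post_init__(self) -> None:
        for name in (
            "length_cm",
            "radius_cm",
            "axial_resistivity_kohm_cm",
            "g_leak",
            "c0",
            "dt_ms",
            "dx_cm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        n_comp = self.length_cm / self.dx_cm
        if abs(n_comp - round(n_comp)) > 1e-9:
            raise ValueError("dx_cm must divide length_cm")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_cm / self.dx_cm)) + 1

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total_ms / self.dt_ms))

    @property
    def g_axial(self) -> float:
        """Effective axial conductance G_a = r / (2 R_a), in mS."""
        return self.radius_cm / (2.0 * self.axial_resistivity_kohm_cm)

    @property
    def q10(self) -> float:
        return 3.0 ** ((self.temperature_c - 6.3) / 10.0)


@dataclass(frozen=True)
class Conductances:
    """A (G_Na, G_K) phenotype point with its fitted leak reversal V_L."""

    g_na: float
    g_k: float
    v_l: float

    def __post_init__(self) -> None:
        if self.g_na < 0 or self.g_k < 0:
            raise ValueError("conductances must be non-negative")

    @classmethod
    def fitted(cls, g_na: float, g_k: float, params: CableParams) -> "Conductances":
        """Build a phenotype with V_L adjusted so -65 mV is stationary."""
        v_l = solve_leak_potential(g_na, g_k, params.g_leak, e_na=params.e_na, e_k=params.e_k)
        return cls(g_na, g_k, v_l)


class Excitability(Enum):
    TYPE2 = 2  # repetitive firing under sustained current
    TYPE3 = 3  # single spike, then silence


@dataclass(frozen=True)
class APMetrics:
    """Physiological readout of one propagated-action-potential simulation."""

    conducted: bool
    velocity_m_per_s: float  # nan when not conducted
    na_flux_nc_per_cm2: float
    apd50_ms: float
    apd90_ms: float
    spike_count: int


def _safe_expm1_ratio(x: np.ndarray | float) -> np.ndarray:
    """x / (1 - exp(-x/10)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-7
    xs = np.where(small, 1.0, x)
    out = xs / (-np.expm1(-xs / 10.0))
    return np.where(small, 10.0, out)


def rate_constants(v, tc: float):
    """The six gating rate constants (1/ms) at voltage ``v`` and ``tc`` degC.

    Returns ``(alpha_n, beta_n, alpha_m, beta_m, alpha_h, beta_h)``; accepts
    scalars or arrays.  The singular points of alpha_n (V = -55) and alpha_m
    (V = -40) are evaluated by their analytic limits.
    """
    v = np.asarray(v, dtype=float)
    q10 = 3.0 ** ((tc - 6.3) / 10.0)
    a_n = 0.01 * _safe_expm1_ratio(v + 55.0) * q10
    b_n = 0.125 * np.exp(-(v + 65.0) / 19.7) * q10
    a_m = 0.1 * _safe_expm1_ratio(v + 40.0) * q10
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0) * q10
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0) * q10
    b_h = 1.8 / (1.0 + np.exp(-(v + 16.0) / 10.0)) * q10
    return a_n, b_n, a_m, b_m, a_h, b_h


def steady_state_gates(v, tc: float = 6.3):
    """Steady-state gate values (n_inf, m_inf, h_inf); independent of ``tc``."""
    a_n, b_n, a_m, b_m, a_h, b_h = rate_constants(v, tc)
    return a_n / (a_n + b_n), a_m / (a_m + b_m), a_h / (a_h + b_h)


def solve_leak_potential(
    g_na: float,
    g_k: float,
    g_l: float,
    v_rest: float = V_REST,
    e_na: float = 50.0,
    e_k: float = -77.0,
) -> float:
    """Leak reversal V_L that makes ``v_rest`` a stationary point.

    At rest the steady-state ionic currents must balance:
    ``G_K n^4 (V-E_K) + G_Na m^3 h (V-E_Na) + G_L (V-V_L) = 0``
    which is linear in V_L.
    """
    if g_l <= 0:
        raise ValueError("leak conductance must be > 0 to fit V_L")
    n_inf, m_inf, h_inf = steady_state_gates(v_rest)
    i_k = g_k * n_inf**4 * (v_rest - e_k)
    i_na = g_na * m_inf**3 * h_inf * (v_rest - e_na)
    return v_rest + (i_k + i_na) / g_l


def gating_capacitance(m, g_na: float, cg_max: float = 0.13, g_na_ref: float = 120.0):
    """Gating capacitance C_g = cg_max (G_Na/G_ref) (1 - m), uF/cm^2."""
    m = np.asarray(m, dtype=float)
    return cg_max * (g_na / g_na_ref) * (1.0 - m)


def _gate_tables(
    tc: float, dt: float, v_min: float = -150.0, v_max: float = 100.0, dv: float = 0.025
):
    """Exponential-integrator propagator tables for one (temperature, dt).

    Row pairs per gate: ``x_inf (1 - e)`` and ``e = exp(-dt (alpha+beta))``.
    """
    v_grid = np.arange(v_min, v_max + dv / 2, dv)
    a_n, b_n, a_m, b_m, a_h, b_h = rate_constants(v_grid, tc)
    rows = []
    for a, b in ((a_n, b_n), (a_m, b_m), (a_h, b_h)):
        e = np.exp(-dt * (a + b))
        rows.append(a / (a + b) * (1.0 - e))
        rows.append(e)
    return np.ascontiguousarray(np.vstack(rows)), v_min, 1.0 / dv


_TABLE_CACHE: dict[tuple, tuple] = {}


def _tables_for(tc: float, dt: float):
    key = (round(tc, 9), round(dt, 12))
    if key not in _TABLE_CACHE:
        if len(_TABLE_CACHE) > 32:
            _TABLE_CACHE.clear()
        _TABLE_CACHE[key] = _gate_tables(tc, dt)
    return _TABLE_CACHE[key]


@dataclass
class CableTrace:
    """Recorded traces from one simulation."""

    times_ms: np.ndarray
    positions_cm: np.ndarray
    v_mv: np.ndarray  # shape (n_times, n_positions)
    i_na_mid: np.ndarray  # sodium current density at the mid node, uA/cm^2
    mid_position_cm: float
    final_state: dict = field(default_factory=dict)
    params: CableParams | None = None
    cond: Conductances | None = None

    def column(self, position_cm: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.positions_cm - position_cm)))
        if abs(self.positions_cm[j] - position_cm) > 1e-6:
            raise KeyError(f"position {position_cm} cm was not recorded")
        return self.v_mv[:, j]

    def to_frame(self):
        import pandas as pd

        data = {"time_ms": self.times_ms}
        for j, x in enumerate(self.positions_cm):
            data[f"v_{x:g}cm_mv"] = self.v_mv[:, j]
        return pd.DataFrame(data)


DEFAULT_RECORD_FRACTIONS = (0.25, 0.5, 0.75, 0.95)


def simulate(
    params: CableParams,
    cond: Conductances,
    record_positions: Sequence[float] | None = None,
    stim_amplitude_ua: float | None = None,
    stim_duration_ms: float | None = None,
    stim_extent_cm: float | None = None,
) -> CableTrace:
    """Run the cable for ``params.t_total_ms`` and record voltage traces.

    The stimulus current is applied to the first compartment as an areal
    density ``I / (2 pi r dx)``; ends are sealed (zero axial flux).
    """
    if record_positions is None:
        record_positions = [f * params.length_cm for f in DEFAULT_RECORD_FRACTIONS]
    record_positions = np.asarray(sorted(set(float(x) for x in record_positions)))
    if np.any(record_positions < 0) or np.any(record_positions > params.length_cm):
        raise ValueError("record positions must lie on the cable")

    amp = params.stim_amplitude_ua if stim_amplitude_ua is None else stim_amplitude_ua
    dur = params.stim_duration_ms if stim_duration_ms is None else stim_duration_ms

    nx = params.n_nodes
    v = np.full(nx, V_REST)
    n_inf, m_inf, h_inf = steady_state_gates(V_REST)
    n = np.full(nx, n_inf)
    m = np.full(nx, m_inf)
    h = np.full(nx, h_inf)

    tables, v_min, inv_dv = _tables_for(params.temperature_c, params.dt_ms)
    rec_idx = np.array(
        [int(round(x / params.dx_cm)) for x in record_positions], dtype=np.int64
    )
    mid_idx = int(round(0.5 * params.length_cm / params.dx_cm))
    extent = (
        params.stim_extent_cm
        if stim_extent_cm is None and params.stim_extent_cm is not None
        else (stim_extent_cm if stim_extent_cm is not None else params.dx_cm)
    )
    stim_nodes = max(1, int(round(extent / params.dx_cm)))
    stim_density = amp / (2.0 * np.pi * params.radius_cm * stim_nodes * params.dx_cm)
    stim_steps = int(round(dur / params.dt_ms))
    cg_scale = params.cg_max * cond.g_na / params.g_na_ref

    v_rec, i_na_rec, status = run_cable(
        v,
        n,
        m,
        h,
        params.n_steps,
        params.dt_ms,
        params.dx_cm,
        params.g_axial,
        params.c0,
        cg_scale,
        cond.g_na,
        cond.g_k,
        params.g_leak,
        params.e_na,
        params.e_k,
        cond.v_l,
        tables,
        v_min,
        inv_dv,
        stim_density,
        stim_steps,
        stim_nodes,
        rec_idx,
        mid_idx,
        params.expand_cm_derivative,
    )
    if status >= 0:
        raise SimulationUnstableError(
            f"voltage became non-finite at step {status} "
            f"(t = {status * params.dt_ms:.4f} ms); reduce dt or check parameters"
        )
    times = np.arange(params.n_steps + 1) * params.dt_ms
    return CableTrace(
        times_ms=times,
        positions_cm=record_positions,
        v_mv=v_rec,
        i_na_mid=i_na_rec,
        mid_position_cm=mid_idx * params.dx_cm,
        final_state={"v": v, "n": n, "m": m, "h": h},
        params=params,
        cond=cond,
    )


def _peak_time(times: np.ndarray, v: np.ndarray) -> float:
    """Time of the voltage maximum, refined by quadratic interpolation."""
    k = int(np.argmax(v))
    if 0 < k < len(v) - 1:
        y0, y1, y2 = v[k - 1], v[k], v[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            return times[k] + delta * (times[1] - times[0])
    return times[k]


def _upward_crossings(v: np.ndarray, level: float = 0.0) -> np.ndarray:
    above = v >= level
    return np.flatnonzero(~above[:-1] & above[1:]) + 1


def analyze_trace(
    trace: CableTrace,
    params: CableParams | None = None,
    distal_fraction: float = 0.95,
    velocity_fractions: tuple[float, float] = (0.25, 0.75),
) -> APMetrics:
    """Extract conduction and action-potential shape metrics from traces.

    Conduction success is the arrival of a full-amplitude action potential
    at the distal recording site (default 9.5 cm): an upward crossing of
    ``FULL_AP_LEVEL_MV`` followed by repolarization below ``REPOL_LEVEL_MV``
    by the end of the run.  Velocity uses quadratic-interpolated peak times
    at the 25% and 75% positions; flux, APD and spike count are measured at
    the mid-axon node.
    """
    params = params or trace.params
    L = params.length_cm
    v_distal = trace.column(distal_fraction * L)
    conducted = bool(
        len(_upward_crossings(v_distal, FULL_AP_LEVEL_MV)) > 0
        and v_distal[-1] < REPOL_LEVEL_MV
    )

    v_mid = trace.column(0.5 * L)
    spike_idx = _upward_crossings(v_mid)
    spike_count = int(len(spike_idx))

    velocity = float("nan")
    if conducted:
        x1, x2 = (f * L for f in velocity_fractions)
        t1 = _peak_time(trace.times_ms, trace.column(x1))
        t2 = _peak_time(trace.times_ms, trace.column(x2))
        if t2 > t1:
            velocity = 10.0 * (x2 - x1) / (t2 - t1)  # cm/ms -> m/s

    # Sodium charge moved per unit membrane area during the (first) AP at
    # mid-axon; the current is inward (negative), report the magnitude.
    dt = trace.times_ms[1] - trace.times_ms[0]
    na_flux = float(-np.trapezoid(trace.i_na_mid, dx=dt))  # uA/cm^2 * ms = nC/cm^2

    apd50 = apd90 = float("nan")
    if spike_count > 0:
        k_peak = int(np.argmax(v_mid))
        v_peak = v_mid[k_peak]
        amplitude = v_peak - V_REST
        post = v_mid[k_peak:]
        for frac, name in ((0.5, "apd50"), (0.9, "apd90")):
            level = v_peak - frac * amplitude
            below = np.flatnonzero(post <= level)
            if len(below):
                j = below[0]
                if j > 0:  # linear interpolation of the crossing
                    f = (post[j - 1] - level) / (post[j - 1] - post[j])
                    t_cross = (k_peak + j - 1 + f) * dt
                else:
                    t_cross = (k_peak + j) * dt
                value = t_cross - k_peak * dt
                if name == "apd50":
                    apd50 = float(value)
                else:
                    apd90 = float(value)
    return APMetrics(
        conducted=conducted,
        velocity_m_per_s=velocity,
        na_flux_nc_per_cm2=na_flux,
        apd50_ms=apd50,
        apd90_ms=apd90,
        spike_count=spike_count,
    )


def conducts(
    params: CableParams,
    g_na: float,
    g_k: float,
    distal_fraction: float = 0.95,
) -> bool:
    """Does a full-amplitude action potential reach the distal site?"""
    cond = Conductances.fitted(g_na, g_k, params)
    trace = simulate(params, cond, record_positions=[distal_fraction * params.length_cm])
    v = trace.v_mv[:, 0]
    return bool(
        len(_upward_crossings(v, FULL_AP_LEVEL_MV)) > 0 and v[-1] < REPOL_LEVEL_MV
    )


def _spike_count_sustained(
    params: CableParams, cond: Conductances, amplitude_ua: float, position_cm: float
) -> int:
    trace = simulate(
        params,
        cond,
        record_positions=[position_cm],
        stim_amplitude_ua=amplitude_ua,
        stim_duration_ms=params.t_total_ms,
    )
    return int(len(_upward_crossings(trace.v_mv[:, 0])))


def find_threshold_current(
    params: CableParams,
    cond: Conductances,
    position_cm: float,
    rel_tol: float = 0.01,
    start_ua: float = 1.0,
) -> float:
    """Just-threshold sustained current (uA) for a spike at ``position_cm``.

    Doubles from ``start_ua`` to bracket, then bisects to relative tolerance
    ``rel_tol``.
    """
    lo, hi = 0.0, start_ua
    for _ in range(20):
        if _spike_count_sustained(params, cond, hi, position_cm) >= 1:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("no spike elicited up to the bracketing limit")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if _spike_count_sustained(params, cond, mid, position_cm) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def classify_excitability(
    params: CableParams,
    cond: Conductances,
    temperature_c: float = 6.3,
    step_duration_ms: float = 100.0,
    position_fraction: float = 0.5,
    stim_extent_cm: float = 0.5,
) -> Excitability:
    """Type 2 (repetitive) vs Type 3 (single-spike) firing classification.

    A sustained depolarizing current of twice the just-threshold amplitude is
    injected over the first ``stim_extent_cm`` of the cable (a macroscopic
    electrode segment, as in axial-wire current clamp of real axons; a
    point injection produces an unphysically steep sustained gradient);
    spikes are counted mid-axon.  The test runs at low temperature (6.3
    degC) where repetitive firing is physiologically observable; the
    boundary is nearly temperature independent.
    """
    p = replace(
        params,
        temperature_c=temperature_c,
        t_total_ms=step_duration_ms,
        stim_duration_ms=step_duration_ms,
        stim_extent_cm=stim_extent_cm,
    )
    pos = position_fraction * p.length_cm
    i_thresh = find_threshold_current(p, cond, pos)
    n_spikes = _spike_count_sustained(p, cond, 2.0 * i_thresh, pos)
    if n_spikes == 0:
        raise RuntimeError(
            "no spike at twice the just-threshold current; phenotype outside "
            "the excitable region"
        )
    return Excitability.TYPE2 if n_spikes >= 2 else Excitability.TYPE3
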