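"""Deterministic gating kinetics under voltage clamp.

Implements the squid-axon potassium/sodium gating rate functions (classic
depolarization convention: V is the displacement from rest in mV, rest = 0,
time in ms, rates in ms^-1), the n^4 potassium scheme, the full
(n, m, h) membrane model, and a three-state sequential scheme ("p2") whose
open probability is the occupancy of the last state rather than a power of
a gating variable.

The p2 chain  0 <=> 1 <=> 2  has four rate constants tied to the potassium
rates through two free factors A and B:

    k1 = A*alpha_n,  k2 = beta_n,  k3 = alpha_n,  k4 = B*beta_n

With A = B = 2 it reduces exactly to the n^2 scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import _kernels

GATE_IDS = ("n", "m", "h")

#: factors used throughout for the p2 model unless overridden
DEFAULT_FACTOR_A = 0.35
DEFAULT_FACTOR_B = 4.0


@dataclass(frozen=True)
class HHParameters:
    """Membrane parameters (capacitance uF/cm^2, conductances mS/cm^2,
    reversal potentials mV in the depolarization convention)."""

    Cm: float = 1.0
    gL: float = 0.3
    VL: float = 10.6
    gK: float = 36.0
    VK: float = -12.0
    gNa: float = 120.0
    VNa: float = 120.0

    def __post_init__(self):
        if self.Cm <= 0:
            raise ValueError("Cm must be positive")
        for name in ("gL", "gK", "gNa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# rate formulas and their analytic V-derivatives
# ---------------------------------------------------------------------------

def _g(u):
    """u / (e^u - 1), continued through the removable zero of the
    denominator (series 1 - u/2 + u^2/12 for small |u|)."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-5
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 - u / 2.0 + u * u / 12.0,
                   safe / np.expm1(safe))
    return out if out.ndim else float(out)


def _dg(u):
    """d/du of u / (e^u - 1)."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-5
    safe = np.where(small, 1.0, u)
    e = np.expm1(safe)
    out = np.where(small, -0.5 + u / 6.0, (e - safe * (e + 1.0)) / (e * e))
    return out if out.ndim else float(out)


def _alpha_n(V):
    # 10.001 instead of the classic 10 moves the 0/0 point off the integer
    # voltage grid; alpha_n(10) evaluates to the classic limit 0.1.
    return 0.1 * _g((10.001 - V) / 10.0)


def _dalpha_n(V):
    return -0.01 * _dg((10.001 - V) / 10.0)


def _beta_n(V):
    return 0.125 * np.exp(-V / 80.0)


def _dbeta_n(V):
    return -0.125 / 80.0 * np.exp(-V / 80.0)


def _alpha_m(V):
    return _g((25.0 - V) / 10.0)


def _dalpha_m(V):
    return -0.1 * _dg((25.0 - V) / 10.0)


def _beta_m(V):
    return 4.0 * np.exp(-V / 18.0)


def _dbeta_m(V):
    return -4.0 / 18.0 * np.exp(-V / 18.0)


def _alpha_h(V):
    return 0.07 * np.exp(-V / 20.0)


def _dalpha_h(V):
    return -0.07 / 20.0 * np.exp(-V / 20.0)


def _beta_h(V):
    return 1.0 / (np.exp((30.0 - V) / 10.0) + 1.0)


def _dbeta_h(V):
    E = np.exp((30.0 - V) / 10.0)
    return E / 10.0 / (E + 1.0) ** 2


_RATES: dict[str, tuple[Callable, Callable, Callable, Callable]] = {
    "n": (_alpha_n, _beta_n, _dalpha_n, _dbeta_n),
    "m": (_alpha_m, _beta_m, _dalpha_m, _dbeta_m),
    "h": (_alpha_h, _beta_h, _dalpha_h, _dbeta_h),
}


@dataclass(frozen=True)
class GatingRateSet:
    """Rates and derived quantities for one gate at one voltage.

    alpha, beta in ms^-1; dalpha_dV, dbeta_dV in ms^-1 mV^-1; tau in ms.
    """

    gate_id: str
    V: float
    alpha: float
    beta: float
    dalpha_dV: float
    dbeta_dV: float

    @property
    def x_inf(self):
        return self.alpha / (self.alpha + self.beta)

    @property
    def tau(self):
        return 1.0 / (self.alpha + self.beta)


def hh_gate_rates(V, gate_id: str) -> GatingRateSet:
    """Evaluate the rate formulas (and analytic V-derivatives) of one gate."""
    if gate_id not in _RATES:
        raise ValueError(f"unknown gate_id {gate_id!r}; expected one of {GATE_IDS}")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("V must be finite")
    if V.ndim == 0:
        V = float(V)
    a, b, da, db = _RATES[gate_id]
    return GatingRateSet(gate_id, V, a(V), b(V), da(V), db(V))


# ---------------------------------------------------------------------------
# p2 model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class P2Rates:
    """Rate constants and reduced 2x2 generator entries of the p2 chain.

    The two-variable reduction (using p0 = 1 - p1 - p2) reads

        d/dt (p1, p2) = [[a11, a12], [a21, a22]] (p1, p2) + (-a22 - a12, 0)
    """

    V: float
    factor_A: float
    factor_B: float
    k1: float
    k2: float
    k3: float
    k4: float

    @property
    def a11(self):
        return -(self.k1 + self.k2 + self.k3)

    @property
    def a12(self):
        return -self.k1 + self.k4

    @property
    def a21(self):
        return self.k3

    @property
    def a22(self):
        return -self.k4

    def matrix(self) -> np.ndarray:
        return np.array([[self.a11, self.a12], [self.a21, self.a22]])


def p2_rates(V, factor_A: float = DEFAULT_FACTOR_A,
             factor_B: float = DEFAULT_FACTOR_B) -> P2Rates:
    if factor_A <= 0 or factor_B <= 0:
        raise ValueError("factors must be positive")
    rn = hh_gate_rates(V, "n")
    return P2Rates(V, factor_A, factor_B,
                   k1=factor_A * rn.alpha, k2=rn.beta,
                   k3=rn.alpha, k4=factor_B * rn.beta)


def p2_rate_derivatives(V, factor_A: float = DEFAULT_FACTOR_A,
                        factor_B: float = DEFAULT_FACTOR_B) -> dict:
    """Analytic dk_i/dV and d(a_ij)/dV (ms^-1 mV^-1)."""
    rn = hh_gate_rates(V, "n")
    dk1 = factor_A * rn.dalpha_dV
    dk2 = rn.dbeta_dV
    dk3 = rn.dalpha_dV
    dk4 = factor_B * rn.dbeta_dV
    return {
        "dk1": dk1, "dk2": dk2, "dk3": dk3, "dk4": dk4,
        "da11": -(dk1 + dk2 + dk3), "da12": -dk1 + dk4,
        "da21": dk3, "da22": -dk4,
    }


def p2_steady_state(V, factor_A: float = DEFAULT_FACTOR_A,
                    factor_B: float = DEFAULT_FACTOR_B) -> dict:
    """Stationary occupancies of the reduced p2 system.

    Solves the 2x2 linear stationary condition; agrees with the sequential
    closed form p2_inf = k1 k3 / (k2 k4 + k1 k4 + k1 k3).
    """
    r = p2_rates(V, factor_A, factor_B)
    D = r.a11 * r.a22 - r.a12 * r.a21
    if D == 0 or not np.isfinite(D):
        raise ValueError(
            f"singular p2 generator at V={V}: det={D}, rates={r}")
    p1 = r.a22 * (r.a22 + r.a12) / D
    p2 = -r.a21 * (r.a22 + r.a12) / D
    return {"p1_inf": p1, "p2_inf": p2, "p0_inf": 1.0 - p1 - p2}


# ---------------------------------------------------------------------------
# voltage-clamp integration
# ---------------------------------------------------------------------------

MODELS = ("hh_n4", "hh_full", "p2")


@dataclass
class StateTrace:
    """Uniformly sampled voltage-clamp trajectory.

    Gating/probability columns are in [0, 1]; currents in uA/cm^2.
    """

    model: str
    dt_ms: float
    times_ms: np.ndarray
    v_mV: np.ndarray
    states: dict = field(default_factory=dict)   # name -> array
    currents: dict = field(default_factory=dict)  # name -> array (uA/cm^2)
    params: HHParameters = field(default_factory=HHParameters)
    meta: dict = field(default_factory=dict)

    @property
    def i_total(self):
        return self.currents["I_total"]

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.times_ms, "V_mV": self.v_mV}
        cols.update(self.states)
        cols.update(self.currents)
        return pd.DataFrame(cols)


def _as_command(v_command, n_steps):
    """V command sampled at the n_steps+1 grid points."""
    v = np.asarray(v_command, dtype=float)
    if v.ndim == 0:
        return np.full(n_steps + 1, float(v))
    if v.shape[0] != n_steps + 1:
        raise ValueError(
            f"V_command must have {n_steps + 1} samples, got {v.shape[0]}")
    return v


def _check_unit_interval(x, what, tol=1e-6):
    lo, hi = x.min(), x.max()
    if lo < -tol or hi > 1.0 + tol:
        raise ValueError(
            f"{what} left [0,1] (range [{lo:.3g}, {hi:.3g}]); "
            "use a smaller dt")


def integrate_voltage_clamp(model: str, v_command, dt_ms: float,
                            duration_ms: float,
                            params: HHParameters | None = None,
                            factor_A: float = DEFAULT_FACTOR_A,
                            factor_B: float = DEFAULT_FACTOR_B,
                            initial=None) -> StateTrace:
    """Forward-Euler integration of gate/probability ODEs with V forced.

    v_command : scalar (constant clamp) or array on the dt grid
        (duration/dt + 1 samples).
    initial : None (steady state of V at t=0) or explicit array
        (gates (n,) / (n,m,h) or probabilities (p1, p2)).

    The clamp current I = Cm dV/dt + I_L + I_K (+ I_Na) is recorded in
    ``currents``; dV/dt is a centered difference of the command.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    params = params or HHParameters()
    n_steps = int(round(duration_ms / dt_ms))
    if abs(n_steps * dt_ms - duration_ms) > 1e-9 * max(1.0, duration_ms):
        raise ValueError("duration must be a multiple of dt")
    v = _as_command(v_command, n_steps)
    v_mid = v[:-1]  # rate tables frozen at interval start

    if model in ("hh_n4", "hh_full"):
        gates = ("n",) if model == "hh_n4" else ("n", "m", "h")
        alpha = np.column_stack([_RATES[g][0](v_mid) for g in gates])
        beta = np.column_stack([_RATES[g][1](v_mid) for g in gates])
        if initial is None:
            x0 = np.array([hh_gate_rates(v[0], g).x_inf for g in gates])
        else:
            x0 = np.asarray(initial, dtype=float)
            if np.any(x0 < 0) or np.any(x0 > 1):
                raise ValueError("initial gate values must lie in [0,1]")
        traj = _kernels.euler_gates(alpha, beta, x0, dt_ms)
        _check_unit_interval(traj, "gating variables")
        states = {g: traj[:, i] for i, g in enumerate(gates)}
        n = states["n"]
        gk_open = n ** 4
    else:
        r = p2_rates(v_mid, factor_A, factor_B)
        a11, a12 = np.broadcast_to(r.a11, (n_steps,)), np.broadcast_to(r.a12, (n_steps,))
        a21, a22 = np.broadcast_to(r.a21, (n_steps,)), np.broadcast_to(r.a22, (n_steps,))
        c1 = -(a22 + a12)
        c2 = np.zeros(n_steps)
        if initial is None:
            ss = p2_steady_state(v[0], factor_A, factor_B)
            p0 = np.array([ss["p1_inf"], ss["p2_inf"]])
        else:
            p0 = np.asarray(initial, dtype=float)
        traj = _kernels.euler_affine2(
            np.ascontiguousarray(a11, dtype=float),
            np.ascontiguousarray(a12, dtype=float),
            np.ascontiguousarray(a21, dtype=float),
            np.ascontiguousarray(a22, dtype=float),
            np.ascontiguousarray(c1, dtype=float), c2, p0, dt_ms)
        p1, p2 = traj[:, 0], traj[:, 1]
        probs = np.column_stack([1.0 - p1 - p2, p1, p2])
        _check_unit_interval(probs, "state probabilities")
        states = {"p0": probs[:, 0], "p1": p1, "p2": p2}
        gk_open = p2

    times = np.arange(n_steps + 1) * dt_ms
    i_leak = params.gL * (v - params.VL)
    i_k = params.gK * gk_open * (v - params.VK)
    currents = {"I_L": i_leak, "I_K": i_k}
    if model == "hh_full":
        m, h = states["m"], states["h"]
        currents["I_Na"] = params.gNa * m ** 3 * h * (v - params.VNa)
    dvdt = np.gradient(v, dt_ms)
    i_ion = sum(c for k, c in currents.items())
    currents["I_cap"] = params.Cm * dvdt
    currents["I_total"] = currents["I_cap"] + i_ion
    return StateTrace(model=model, dt_ms=dt_ms, times_ms=times, v_mV=v,
                      states=states, currents=currents, params=params,
                      meta={"factor_A": factor_A, "factor_B": factor_B})


# pA per (uA/cm^2 * um^2):  1 uA/cm^2 = 1e-6 A / 1e8 um^2 = 0.01 pA/um^2
_DENSITY_TO_PA_PER_UM2 = 0.01


def deterministic_potassium_current(trace: StateTrace,
                                    params: HHParameters | None = None,
                                    area_um2: float | None = None):
    """Potassium current of a trace: density (uA/cm^2) and, if an area is
    given, the absolute current in pA."""
    params = params or trace.params
    if "n" in trace.states:
        open_frac = trace.states["n"] ** 4
    elif "p2" in trace.states:
        open_frac = trace.states["p2"]
    else:
        raise ValueError("trace has neither n nor p2 states")
    density = params.gK * open_frac * (trace.v_mV - params.VK)
    if area_um2 is None:
        return density
    return density, density * area_um2 * _DENSITY_TO_PA_PER_UM2


def hh_ode_rhs(state, v_clamp, params: HHParameters | None = None):
    """Instantaneous derivatives and clamp current of the full model.

    state : dict with V, n, m, h.  Under voltage clamp the V derivative is
    replaced by the commanded value (0 for a constant hold) and the clamp
    current I = Cm dV/dt + I_L + I_K + I_Na is reported.
    """
    params = params or HHParameters()
    V = state["V"]
    derivs = {}
    for g in ("n", "m", "h"):
        x = state[g]
        if x < -1e-9 or x > 1 + 1e-9:
            raise ValueError(f"gate {g}={x} outside [0,1]")
        r = hh_gate_rates(V, g)
        derivs[f"d{g}_dt"] = r.alpha * (1.0 - x) - r.beta * x
    i_l = params.gL * (V - params.VL)
    i_k = params.gK * state["n"] ** 4 * (V - params.VK)
    i_na = params.gNa * state["m"] ** 3 * state["h"] * (V - params.VNa)
    dv = state.get("dVdt_command", 0.0)
    derivs.update({"dV_dt": dv, "I_L": i_l, "I_K": i_k, "I_Na": i_na,
                   "I_clamp": params.Cm * dv + i_l + i_k + i_na})
    return derivs
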