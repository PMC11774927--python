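"""Small-signal admittance and impedance under voltage clamp.

Linearizing the gating kinetics around a holding potential V0 gives, for
each gate x with rates alpha_x, beta_x, a first-order transfer term

    D_x(w) = [alpha_x' - x0 (alpha_x + beta_x)'] / (iw + alpha_x + beta_x)

(primes are d/dV at V0, x0 = x_inf(V0)).  The membrane admittance density
of the classic model is then

    Y(w) = iw Cm + gL + gK [4 n0^3 (V0-VK) D_n + n0^4]
                 + gNa [3 m0^2 h0 (V0-VNa) D_m + m0^3 (V0-VNa) D_h + m0^3 h0]

and Z = 1/Y.  The p2 chain has the analogous rational transfer
dp2/dV(w) with a second-order denominator (iw - a11)(iw - a22) - a21 a12.

Public interfaces use frequency f in Hz; internally w = 2 pi f rad/s and
rates are converted ms^-1 -> s^-1 at this boundary.  Admittance is a
density in mS/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (HHParameters, hh_gate_rates, p2_rates,
                     p2_rate_derivatives, p2_steady_state,
                     DEFAULT_FACTOR_A, DEFAULT_FACTOR_B)

_MS_TO_S = 1e3  # ms^-1 -> s^-1


@dataclass
class LinearResponse:
    """Complex admittance Y (mS/cm^2) and impedance Z = 1/Y on a grid."""

    model: str
    v0: float
    f_hz: np.ndarray
    Y: np.ndarray
    components: dict = field(default_factory=dict)

    @property
    def Z(self):
        return 1.0 / self.Y

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "f_Hz": self.f_hz,
            "Re_Y": self.Y.real, "Im_Y": self.Y.imag,
            "abs_Z": np.abs(self.Z), "phase_Z": np.angle(self.Z),
        })


def gating_transfer(v0: float, gate_id: str, f_hz):
    """Linearized gate transfer D_x at frequencies f (Hz); units mV^-1."""
    r = hh_gate_rates(v0, gate_id)
    w = 2.0 * np.pi * np.asarray(f_hz, dtype=float)
    num = (r.dalpha_dV - r.x_inf * (r.dalpha_dV + r.dbeta_dV)) * _MS_TO_S
    den = 1j * w + (r.alpha + r.beta) * _MS_TO_S
    return num / den


def _cap_term(f_hz, Cm):
    # uF/cm^2 * rad/s -> mS/cm^2 (factor 1e-3)
    return 1j * 2.0 * np.pi * np.asarray(f_hz, dtype=float) * Cm * 1e-3


def hh_admittance(v0: float, f_hz, params: HHParameters | None = None,
                  include_sodium: bool = True,
                  potassium_exponent: int = 4) -> LinearResponse:
    """Admittance of the classic model at holding potential v0.

    potassium_exponent selects n^4 (default) or the n^2 variant
    (conductance gK n^2, linear term 2 n0 instead of 4 n0^3).
    """
    params = params or HHParameters()
    f = np.asarray(f_hz, dtype=float)
    n0 = hh_gate_rates(v0, "n").x_inf
    Dn = gating_transfer(v0, "n", f)
    q = potassium_exponent
    yk = params.gK * (q * n0 ** (q - 1) * (v0 - params.VK) * Dn + n0 ** q)
    Y = _cap_term(f, params.Cm) + params.gL + yk
    comps = {"D_n": Dn, "Y_K": yk}
    if include_sodium and params.gNa > 0:
        m0 = hh_gate_rates(v0, "m").x_inf
        h0 = hh_gate_rates(v0, "h").x_inf
        Dm = gating_transfer(v0, "m", f)
        Dh = gating_transfer(v0, "h", f)
        yna = params.gNa * (3 * m0 ** 2 * h0 * (v0 - params.VNa) * Dm
                            + m0 ** 3 * (v0 - params.VNa) * Dh
                            + m0 ** 3 * h0)
        Y = Y + yna
        comps.update({"D_m": Dm, "D_h": Dh, "Y_Na": yna})
    if np.any(Y == 0):
        raise ZeroDivisionError("admittance vanished on the grid")
    model = f"hh_n{q}" + ("" if include_sodium and params.gNa > 0 else "_K")
    return LinearResponse(model, v0, f, Y, comps)


def p2_voltage_transfer(v0: float, f_hz,
                        factor_A: float = DEFAULT_FACTOR_A,
                        factor_B: float = DEFAULT_FACTOR_B):
    """dp2/dV transfer of the p2 chain at frequencies f (Hz); mV^-1."""
    r = p2_rates(v0, factor_A, factor_B)
    d = p2_rate_derivatives(v0, factor_A, factor_B)
    ss = p2_steady_state(v0, factor_A, factor_B)
    w = 2.0 * np.pi * np.asarray(f_hz, dtype=float)
    a11, a12 = r.a11 * _MS_TO_S, r.a12 * _MS_TO_S
    a21, a22 = r.a21 * _MS_TO_S, r.a22 * _MS_TO_S
    da11, da12 = d["da11"] * _MS_TO_S, d["da12"] * _MS_TO_S
    da21, da22 = d["da21"] * _MS_TO_S, d["da22"] * _MS_TO_S
    p1, p2 = ss["p1_inf"], ss["p2_inf"]
    num = (a21 * (da11 * p1 + da12 * p2 - (da22 + da12))
           + (1j * w - a11) * (da21 * p1 + da22 * p2))
    den = (1j * w - a11) * (1j * w - a22) - a21 * a12
    return num / den


def p2_admittance(v0: float, f_hz, params: HHParameters | None = None,
                  factor_A: float = DEFAULT_FACTOR_A,
                  factor_B: float = DEFAULT_FACTOR_B) -> LinearResponse:
    """Admittance of the p2 membrane (leak + potassium via p2, no sodium)."""
    params = params or HHParameters()
    f = np.asarray(f_hz, dtype=float)
    dp2 = p2_voltage_transfer(v0, f, factor_A, factor_B)
    p2_inf = p2_steady_state(v0, factor_A, factor_B)["p2_inf"]
    yk = params.gK * (dp2 * (v0 - params.VK) + p2_inf)
    Y = _cap_term(f, params.Cm) + params.gL + yk
    return LinearResponse("p2", v0, f, Y, {"dp2_dV": dp2, "Y_K": yk})


def modified_admittance(v0: float, f_hz, model: str = "n4",
                        params: HHParameters | None = None,
                        factor_A: float = DEFAULT_FACTOR_A,
                        factor_B: float = DEFAULT_FACTOR_B):
    """Voltage-dependent potassium transfer term alone (no capacitance,
    no frequency-independent terms); returns (Ym, |Ym|^2).

    This is the piece of the admittance whose squared magnitude is compared
    with fluctuation spectra in the overlay analyses.
    """
    params = params or HHParameters()
    f = np.asarray(f_hz, dtype=float)
    if model in ("n4", "hh_n4"):
        n0 = hh_gate_rates(v0, "n").x_inf
        ym = params.gK * 4 * n0 ** 3 * (v0 - params.VK) * gating_transfer(v0, "n", f)
    elif model == "p2":
        ym = params.gK * (v0 - params.VK) * p2_voltage_transfer(
            v0, f, factor_A, factor_B)
    else:
        raise ValueError(f"model must be 'n4' or 'p2', got {model!r}")
    return ym, np.abs(ym) ** 2
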