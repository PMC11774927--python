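"""Closed-form autocovariance and fluctuation power spectra.

For a stationary population of N_K identical two-valued (open/closed)
channels with single-channel current i_K, the current autocovariance is
C_IK(t) = N_K i_K^2 [p_inf p(t|0) - p_inf^2] where p(t|0) is the open
probability at lag t conditioned on the channel being open at t = 0.

n^4 scheme: p(t|0) = [n_inf + (1-n_inf) e^(-t/tau_n)]^4 expands into four
exponentials, hence a four-Lorentzian one-sided spectrum

    S_IK(w) = 4 N_K i_K^2 n_inf^4 sum_{q=1..4} C(4,q) n_inf^(4-q)
              (1-n_inf)^q q tau_n / (q^2 + w^2 tau_n^2)

with corner angular frequencies q/tau_n.  p2 scheme: the 2x2 reduced
generator's eigen-decomposition gives two exponentials with weights c1, c2
determined by the open-state initial condition, hence two Lorentzians.

One-sided convention: S(w) = 2 * FT of C over the whole line, reported for
positive frequencies; equivalently S(f) = S(w=2 pi f) in pA^2/Hz satisfies
integral_0^inf S(f) df = Var[I_K].  tau is converted ms -> s here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .models import (hh_gate_rates, p2_rates, p2_steady_state,
                     DEFAULT_FACTOR_A, DEFAULT_FACTOR_B)
from .markov import ChannelPopulation


class DegenerateEigensystemError(ValueError):
    """Raised when the reduced p2 generator has a non-simple real spectrum."""


@dataclass
class LorentzianSpectrum:
    model: str
    v0: float
    f_hz: np.ndarray
    total: np.ndarray              # pA^2/Hz
    components: list = field(default_factory=list)  # (label, weight, tau_s, array)
    prefactor: float = 0.0         # 4 N_K i_K^2 p_inf  (pA^2 s)
    p_inf: float = 0.0

    @property
    def corner_frequencies_hz(self):
        return np.array([1.0 / (2 * np.pi * tau) for _, _, tau, _ in self.components])

    def to_frame(self):
        import pandas as pd
        cols = {"f_Hz": self.f_hz, "S_total": self.total}
        for label, _, _, arr in self.components:
            cols[label] = arr
        return pd.DataFrame(cols)


def n4_autocovariance(lag_s, v0: float,
                      population: ChannelPopulation | None = None):
    """Current autocovariance C_IK(t) of the n^4 scheme, in pA^2."""
    pop = population or ChannelPopulation()
    lag = np.asarray(lag_s, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be nonnegative")
    r = hh_gate_rates(v0, "n")
    n = r.x_inf
    tau_s = r.tau * 1e-3
    i_k = pop.single_channel_current_pA(v0)
    acc = np.zeros_like(lag, dtype=float)
    for q in range(1, 5):
        acc += comb(4, q) * n ** (4 - q) * (1 - n) ** q * np.exp(-q * lag / tau_s)
    return pop.n_channels * i_k ** 2 * n ** 4 * acc


def n4_psd(f_hz, v0: float,
           population: ChannelPopulation | None = None) -> LorentzianSpectrum:
    """Four-Lorentzian fluctuation spectrum of the n^4 scheme (pA^2/Hz)."""
    pop = population or ChannelPopulation()
    f = np.asarray(f_hz, dtype=float)
    w = 2 * np.pi * f
    r = hh_gate_rates(v0, "n")
    n = r.x_inf
    tau = r.tau * 1e-3
    i_k = pop.single_channel_current_pA(v0)
    pref = 4.0 * pop.n_channels * i_k ** 2 * n ** 4
    comps = []
    total = np.zeros_like(f)
    for q in range(1, 5):
        weight = comb(4, q) * n ** (4 - q) * (1 - n) ** q
        s_q = pref * weight * q * tau / (q ** 2 + w ** 2 * tau ** 2)
        comps.append((f"S_{q}", weight, tau / q, s_q))
        total = total + s_q
    return LorentzianSpectrum("n4", v0, f, total, comps, pref, n ** 4)


@dataclass(frozen=True)
class P2Eigensystem:
    """Eigen-decomposition of the reduced p2 generator (rates in ms^-1).

    lam1 is the slow mode (larger, less negative eigenvalue); c1, c2 are the
    expansion weights of p2(t|0) - p2_inf for the open initial condition
    (p0, p1, p2) = (0, 0, 1), satisfying c1 + c2 = 1 - p2_inf.
    """

    v0: float
    trace: float
    det: float
    lam1: float
    lam2: float
    c1: float
    c2: float
    p1_inf: float
    p2_inf: float

    @property
    def tau1_ms(self):
        return -1.0 / self.lam1

    @property
    def tau2_ms(self):
        return -1.0 / self.lam2

    @property
    def v1(self):
        return np.array([(self.lam1 - self._a22) / self._a21, 1.0])

    @property
    def v2(self):
        return np.array([(self.lam2 - self._a22) / self._a21, 1.0])

    # filled by constructor helper
    _a21: float = 0.0
    _a22: float = 0.0


def p2_eigensystem(v0: float, factor_A: float = DEFAULT_FACTOR_A,
                   factor_B: float = DEFAULT_FACTOR_B) -> P2Eigensystem:
    r = p2_rates(v0, factor_A, factor_B)
    T = r.a11 + r.a22
    D = r.a11 * r.a22 - r.a12 * r.a21
    disc = T * T - 4.0 * D
    if disc <= 0:
        raise DegenerateEigensystemError(
            f"reduced generator at V={v0} has non-simple real spectrum: "
            f"trace={T:.6g}, det={D:.6g}, disc={disc:.6g}")
    root = np.sqrt(disc)
    lam1 = (T + root) / 2.0  # slow mode
    lam2 = (T - root) / 2.0
    ss = p2_steady_state(v0, factor_A, factor_B)
    p1, p2 = ss["p1_inf"], ss["p2_inf"]
    c1 = ((lam2 - r.a22) * (1.0 - p2) + r.a21 * p1) / (lam2 - lam1)
    c2 = 1.0 - p2 - c1
    return P2Eigensystem(v0, T, D, lam1, lam2, c1, c2, p1, p2,
                         _a21=r.a21, _a22=r.a22)


def p2_autocovariance(lag_s, v0: float,
                      population: ChannelPopulation | None = None,
                      factor_A: float = DEFAULT_FACTOR_A,
                      factor_B: float = DEFAULT_FACTOR_B):
    pop = population or ChannelPopulation()
    lag = np.asarray(lag_s, dtype=float)
    eig = p2_eigensystem(v0, factor_A, factor_B)
    i_k = pop.single_channel_current_pA(v0)
    t_ms = lag * 1e3
    c = eig.c1 * np.exp(eig.lam1 * t_ms) + eig.c2 * np.exp(eig.lam2 * t_ms)
    return pop.n_channels * i_k ** 2 * eig.p2_inf * c


def p2_psd(f_hz, v0: float, population: ChannelPopulation | None = None,
           factor_A: float = DEFAULT_FACTOR_A,
           factor_B: float = DEFAULT_FACTOR_B) -> LorentzianSpectrum:
    """Two-Lorentzian fluctuation spectrum of the p2 scheme (pA^2/Hz)."""
    pop = population or ChannelPopulation()
    f = np.asarray(f_hz, dtype=float)
    w = 2 * np.pi * f
    eig = p2_eigensystem(v0, factor_A, factor_B)
    i_k = pop.single_channel_current_pA(v0)
    pref = 4.0 * pop.n_channels * i_k ** 2 * eig.p2_inf
    comps = []
    total = np.zeros_like(f)
    for label, c, tau_ms in (("S_1", eig.c1, eig.tau1_ms),
                             ("S_2", eig.c2, eig.tau2_ms)):
        tau = tau_ms * 1e-3
        s = pref * c * tau / (1.0 + w ** 2 * tau ** 2)
        comps.append((label, c, tau, s))
        total = total + s
    return LorentzianSpectrum("p2", v0, f, total, comps, pref, eig.p2_inf)
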