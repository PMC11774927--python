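"""Stochastic channel-population simulation under voltage clamp.

Channel counts of the five-state n^4 chain (states = number of open
subunits, rates (4-k) alpha_n up / k beta_n down) or of the three-state p2
chain are evolved with an exact Gillespie algorithm; for a time-varying
command the rates are frozen on each dt interval (the command is sampled on
the dt grid), which is exact for constant clamps and a negligible
approximation for stimuli far below the gating rates.

Populations are aggregated: transitions move counts between states, never
individual channels, so the cost scales with the number of transition
events, not the number of channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from . import _kernels
from .models import (HHParameters, hh_gate_rates, p2_rates, p2_steady_state,
                     DEFAULT_FACTOR_A, DEFAULT_FACTOR_B, _as_command)

MARKOV_MODELS = ("n4_5state", "p2_3state")


@dataclass(frozen=True)
class ChannelPopulation:
    """Channel density/area bookkeeping.

    Defaults give N_K = 18 um^-2 * 500 um^2 = 9000 channels and a
    single-channel conductance gamma_K = gK/N_K = 20 pS.
    """

    rho_per_um2: float = 18.0
    area_um2: float = 500.0
    gK_mS_cm2: float = 36.0
    VK_mV: float = -12.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("population must contain at least one channel")

    @property
    def n_channels(self) -> int:
        return int(round(self.rho_per_um2 * self.area_um2))

    @property
    def gamma_pS(self) -> float:
        # mS/cm^2 -> pS/um^2 is a factor 10;  gamma = gK * area / N
        return self.gK_mS_cm2 * 10.0 * self.area_um2 / self.n_channels

    def single_channel_current_pA(self, v_mV: float) -> float:
        # pS * mV = 1e-3 pA
        return self.gamma_pS * (v_mV - self.VK_mV) * 1e-3


@dataclass
class MarkovTrace:
    model: str
    dt_ms: float
    times_ms: np.ndarray
    counts: np.ndarray       # (n_samples, S) int64
    v_mV: np.ndarray
    population: ChannelPopulation
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def open_count(self):
        return self.counts[:, -1]

    @property
    def open_fraction(self):
        return self.open_count / self.population.n_channels

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.times_ms}
        for k in range(self.counts.shape[1]):
            cols[f"N{k}"] = self.counts[:, k]
        cols["open"] = self.open_count
        cols["I_pA"] = fluctuating_current(self, self.v_mV, self.population)
        return pd.DataFrame(cols)


def _rate_tables(model, v, factor_A, factor_B):
    """(up, down) per-channel rate tables, shape (n_steps, S-1)."""
    if model == "n4_5state":
        r = hh_gate_rates(v, "n")
        a = np.broadcast_to(np.atleast_1d(r.alpha), v.shape).astype(float)
        b = np.broadcast_to(np.atleast_1d(r.beta), v.shape).astype(float)
        up = np.column_stack([(4 - k) * a for k in range(4)])
        down = np.column_stack([(k + 1) * b for k in range(4)])
    elif model == "p2_3state":
        r = p2_rates(v, factor_A, factor_B)
        k1 = np.broadcast_to(np.atleast_1d(r.k1), v.shape).astype(float)
        k2 = np.broadcast_to(np.atleast_1d(r.k2), v.shape).astype(float)
        k3 = np.broadcast_to(np.atleast_1d(r.k3), v.shape).astype(float)
        k4 = np.broadcast_to(np.atleast_1d(r.k4), v.shape).astype(float)
        up = np.column_stack([k1, k3])
        down = np.column_stack([k2, k4])
    else:
        raise ValueError(
            f"unknown model {model!r}; expected one of {MARKOV_MODELS}")
    return np.ascontiguousarray(up), np.ascontiguousarray(down)


def stationary_distribution(model, v0, factor_A=DEFAULT_FACTOR_A,
                            factor_B=DEFAULT_FACTOR_B):
    """Stationary state-occupancy probabilities at a constant clamp."""
    if model == "n4_5state":
        n = hh_gate_rates(v0, "n").x_inf
        return binom.pmf(np.arange(5), 4, n)
    ss = p2_steady_state(v0, factor_A, factor_B)
    return np.array([ss["p0_inf"], ss["p1_inf"], ss["p2_inf"]])


def simulate_markov(model: str, v_command, population: ChannelPopulation,
                    dt_ms: float, duration_ms: float, rng_seed: int,
                    factor_A: float = DEFAULT_FACTOR_A,
                    factor_B: float = DEFAULT_FACTOR_B,
                    initial_counts=None) -> MarkovTrace:
    """Gillespie simulation of the channel population; deterministic given
    rng_seed.  Initial counts default to a draw from the stationary
    distribution at V(0)."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration_ms / dt_ms))
    v = _as_command(v_command, n_steps)
    up, down = _rate_tables(model, v[:-1], factor_A, factor_B)
    S = up.shape[1] + 1
    # per-channel total exit rate; the dt constraint only matters for the
    # freshness of a time-varying command (SSA is exact within steps)
    exit_rates = np.zeros((up.shape[0], S))
    exit_rates[:, :-1] += up
    exit_rates[:, 1:] += down
    max_rate = exit_rates.max()
    if max_rate * dt_ms >= 0.1:
        raise ValueError(
            f"max exit rate {max_rate:.3g}/ms * dt {dt_ms} too large; "
            "reduce dt")
    if max_rate * duration_ms <= 0:
        raise ValueError("rate overflow or empty duration")
    rng = np.random.default_rng(rng_seed)
    if initial_counts is None:
        p = stationary_distribution(model, v[0], factor_A, factor_B)
        n0 = rng.multinomial(population.n_channels, p / p.sum())
    else:
        n0 = np.asarray(initial_counts, dtype=np.int64)
        if n0.sum() != population.n_channels or n0.min() < 0:
            raise ValueError("initial counts must be nonnegative and sum to N_K")
    kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
    counts = _kernels.ssa_chain(n0.astype(np.int64), up, down,
                                float(dt_ms), kernel_seed)
    if np.any(counts.sum(axis=1) != population.n_channels):
        raise RuntimeError("channel count not conserved (SSA logic error)")
    times = np.arange(n_steps + 1) * dt_ms
    return MarkovTrace(model, dt_ms, times, counts, v, population, rng_seed,
                       meta={"factor_A": factor_A, "factor_B": factor_B})


def fluctuating_current(trace: MarkovTrace, v_command, population=None):
    """Total fluctuating potassium current I(t) = open(t) gamma (V - VK), pA."""
    pop = population or trace.population
    v = np.asarray(v_command, dtype=float)
    if v.ndim and v.shape[0] != trace.open_count.shape[0]:
        raise ValueError("command grid does not match trace grid")
    return trace.open_count * pop.gamma_pS * (v - pop.VK_mV) * 1e-3


def empirical_psd(current_traces, dt_ms: float, transient_skip: int = 0,
                  subtract_ensemble_mean: bool = False):
    """Averaged one-sided periodogram of current traces.

    Each trace is truncated by transient_skip samples, mean-subtracted and
    transformed with a rectangular window; the one-sided density scaling
    (2 |X|^2 dt / N) makes sum(PSD) * df equal the sample variance, matching
    the analytic spectra convention.  Returns (f_Hz, psd pA^2/Hz, n_traces).

    subtract_ensemble_mean removes the across-trace mean trace first, which
    strips any common deterministic (evoked) component so only fluctuations
    remain.
    """
    traces = [np.asarray(t, dtype=float)[transient_skip:] for t in current_traces]
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    n = traces[0].shape[0]
    if any(t.shape[0] != n for t in traces):
        raise ValueError("traces must have equal length")
    dt_s = dt_ms * 1e-3
    if subtract_ensemble_mean:
        mean_trace = np.mean(traces, axis=0)
        traces = [t - mean_trace for t in traces]
    acc = None
    for t in traces:
        x = t - t.mean()
        X = np.fft.rfft(x)
        p = 2.0 * np.abs(X) ** 2 * dt_s / n
        acc = p if acc is None else acc + p
    psd = acc / len(traces)
    f = np.fft.rfftfreq(n, d=dt_s)
    return f[1:], psd[1:], len(traces)


def binned_log_psd(f_hz, psd, fmin=1.0, fmax=1000.0, bins_per_decade=6):
    """Geometric-bin averages of a PSD; returns (bin centers, mean PSD)."""
    edges = np.geomspace(fmin, fmax, int(np.log10(fmax / fmin) * bins_per_decade) + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (f_hz >= lo) & (f_hz < hi)
        if mask.any():
            centers.append(np.sqrt(lo * hi))
            means.append(psd[mask].mean())
    return np.array(centers), np.array(means)
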