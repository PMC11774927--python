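"""Quadratic sinusoidal analysis (QSA).

A real multi-sine stimulus x(t) = sum_{k in Gamma} x_k e^{i w_k t} over the
signed index set Gamma = {-N..-1, 1..N} (x_{-k} = conj x_k, w_k = 2 pi
n_k / T with integer multipliers n_k) probes a weakly nonlinear system.
When no second-order combination frequency (n_i + n_j, |n_i - n_j|, 2 n_k)
collides with a first-order frequency or with another combination, the
periodic response separates exactly into

    y(t) = y0 + sum_k l_k x_k e^{i w_k t}
              + sum_{i,j} b_{i,j} x_i x_j e^{i (w_i + w_j) t}

and every coefficient is read off a distinct Fourier bin.  Only the sum
b_{i,j} + b_{j,i} is identifiable from one bin, so the symmetric convention
b_{i,j} = b_{j,i} splits each measured bin equally; b_{-k,k} = 0 puts all
DC into y0.  The Hermitian QSA matrix is Q_{i,j} = B_{-i,j}.

All frequency bookkeeping uses exact integer multipliers; Hz values appear
only on output boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical 21-component multiplier set (T = 1 s makes these Hz values)
CANONICAL_MULTIPLIERS = (2, 3, 10, 21, 35, 50, 76, 104, 134, 143, 223, 239,
                         285, 388, 405, 515, 564, 636, 815, 892, 982)


# ---------------------------------------------------------------------------
# stimulus design
# ---------------------------------------------------------------------------

def check_overlap(multipliers) -> list:
    """Enumerate all first/second-order frequency collisions.

    Second-order combinations are n_i + n_j (i <= j), |n_i - n_j| (i < j)
    and 2 n_k.  A violation is (a) a combination equal to a first-order
    multiplier, or (b) two distinct unordered source pairs producing the
    same combination frequency.  An empty list means the set is QSA-valid.
    """
    mult = sorted(int(m) for m in multipliers)
    if len(mult) < 2:
        raise ValueError("need at least 2 multipliers")
    if len(set(mult)) != len(mult) or mult[0] <= 0:
        raise ValueError("multipliers must be distinct positive integers")
    first = set(mult)
    violations = []
    sources: dict[int, tuple] = {}

    def add(freq, pair):
        if freq in first:
            violations.append(("first_order", freq, pair))
        if freq in sources and sources[freq] != pair:
            violations.append(("second_order", freq, sources[freq], pair))
        else:
            sources[freq] = pair

    n = len(mult)
    for a in range(n):
        add(2 * mult[a], (mult[a], mult[a]))
    for a in range(n):
        for b in range(a + 1, n):
            add(mult[a] + mult[b], (mult[a], mult[b]))
    for a in range(n):
        for b in range(a + 1, n):
            add(mult[b] - mult[a], (-mult[a], mult[b]))
    return violations


def generate_nonoverlapping_set(n_freq: int, multiplier_range=(1, 1000),
                                rng_seed: int = 0,
                                max_attempts: int = 200000,
                                restart_after: int = 1000) -> np.ndarray:
    """Draw a QSA-valid multiplier set, deterministically for a given seed.

    Candidates are drawn one at a time and kept only if the grown set stays
    overlap-free (incremental rejection; whole-set rejection is hopeless for
    more than a handful of frequencies).  A partial set can paint itself
    into a corner, so after restart_after consecutive rejections the build
    restarts from scratch.
    """
    lo, hi = multiplier_range
    rng = np.random.default_rng(rng_seed)
    chosen: list[int] = []
    attempts = 0
    stuck = 0
    while len(chosen) < n_freq:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_freq} non-overlapping multipliers in "
                f"[{lo}, {hi}] after {max_attempts} attempts; widen the range")
        attempts += 1
        cand = int(rng.integers(lo, hi + 1))
        trial = chosen + [cand]
        if cand not in chosen and (len(trial) == 1 or not check_overlap(trial)):
            chosen.append(cand)
            stuck = 0
        else:
            stuck += 1
            if stuck >= restart_after:
                chosen = []
                stuck = 0
    return np.array(sorted(chosen))


@dataclass(frozen=True)
class StimulusSpec:
    """Non-overlapping multi-sine description.

    amplitudes are per-component cosine amplitudes a_k (mV), so the complex
    coefficients are x_k = (a_k / 2) e^{i theta_k}; the waveform is
    sum_k a_k cos(w_k t + theta_k).
    """

    period_s: float
    multipliers: tuple
    amplitudes_mV: tuple
    phases_rad: tuple

    def __post_init__(self):
        m = np.asarray(self.multipliers, dtype=int)
        if np.any(np.diff(m) <= 0):
            raise ValueError("multipliers must be strictly increasing")
        if len(self.amplitudes_mV) != len(m) or len(self.phases_rad) != len(m):
            raise ValueError("amplitudes/phases must match multipliers")

    @property
    def n_components(self) -> int:
        return len(self.multipliers)

    @property
    def frequencies_hz(self):
        return np.asarray(self.multipliers) / self.period_s

    @property
    def coefficients(self):
        """x_k for k = 1..N."""
        return (np.asarray(self.amplitudes_mV) / 2.0
                * np.exp(1j * np.asarray(self.phases_rad)))

    def violations(self):
        return check_overlap(self.multipliers)


def make_stimulus(period_s: float = 1.0,
                  multipliers=CANONICAL_MULTIPLIERS,
                  amplitude_mV: float = 0.25,
                  phases=None, rng_seed: int = 0,
                  full_circle: bool = False) -> StimulusSpec:
    """Build a StimulusSpec with uniform amplitude and (by default)
    pseudo-random phases in [0, pi] ([0, 2 pi] with full_circle)."""
    mult = tuple(int(m) for m in multipliers)
    if phases is None:
        rng = np.random.default_rng(rng_seed)
        span = 2.0 * np.pi if full_circle else np.pi
        phases = tuple(rng.uniform(0.0, span, len(mult)))
    else:
        phases = tuple(float(p) for p in phases)
    amps = tuple(float(amplitude_mV) for _ in mult)
    return StimulusSpec(period_s, mult, amps, phases)


def synthesize_multisine(spec: StimulusSpec, dt_ms: float,
                         n_periods: int = 1, v0: float = 0.0) -> np.ndarray:
    """Sample the stimulus waveform v0 + x(t) on the dt grid.

    Returns n_periods * Ns + 1 samples (closed grid, for ODE/SSA commands).
    """
    ns = samples_per_period(spec, dt_ms)
    max_second_order = 2 * max(spec.multipliers)
    if max_second_order / spec.period_s >= 0.5 / (dt_ms * 1e-3):
        raise ValueError(
            "Nyquist violation: highest second-order frequency "
            f"{max_second_order / spec.period_s:.0f} Hz >= 1/(2 dt)")
    t_s = np.arange(n_periods * ns + 1) * dt_ms * 1e-3
    x = np.full(t_s.shape, float(v0))
    for a, m, th in zip(spec.amplitudes_mV, spec.multipliers, spec.phases_rad):
        x += a * np.cos(2.0 * np.pi * m / spec.period_s * t_s + th)
    return x


def samples_per_period(spec: StimulusSpec, dt_ms: float) -> int:
    ns = spec.period_s * 1e3 / dt_ms
    if abs(ns - round(ns)) > 1e-9 * ns:
        raise ValueError("dt must divide the stimulus period")
    return int(round(ns))


# ---------------------------------------------------------------------------
# QSA estimation
# ---------------------------------------------------------------------------

@dataclass
class QSAResult:
    """DC term, linear row L over Gamma and Hermitian quadratic matrix Q.

    Gamma ordering is [-N..-1, 1..N]; position p holds signed index
    gamma[p].  Q_{i,j} = B_{-i,j}, so the entry at (i, j) carries output
    frequency w_j - w_i; the doubling (harmonic) coefficients b_{k,k} sit on
    the anti-diagonal positions (-k, k).
    """

    spec: StimulusSpec
    y0: float
    L: np.ndarray          # (2N,) complex
    Q: np.ndarray          # (2N, 2N) complex
    meta: dict = field(default_factory=dict)

    @property
    def gamma(self):
        N = self.spec.n_components
        return np.concatenate([-np.arange(N, 0, -1), np.arange(1, N + 1)])

    @property
    def signed_multipliers(self):
        m = np.asarray(self.spec.multipliers)
        return np.concatenate([-m[::-1], m])

    @property
    def x_gamma(self):
        x = self.spec.coefficients
        return np.concatenate([np.conj(x[::-1]), x])

    def output_multipliers(self):
        """Integer output frequency |n_j - n_i| of each Q entry."""
        sm = self.signed_multipliers
        return np.abs(sm[None, :] - sm[:, None])

    def linear_coefficients(self):
        """l_k for k = 1..N."""
        N = self.spec.n_components
        return self.L[N:]

    def to_frame(self):
        import pandas as pd
        sm = self.signed_multipliers
        ii, jj = np.meshgrid(np.arange(len(sm)), np.arange(len(sm)),
                             indexing="ij")
        return pd.DataFrame({
            "i": sm[ii.ravel()], "j": sm[jj.ravel()],
            "f_out_Hz": (sm[jj.ravel()] - sm[ii.ravel()]) / self.spec.period_s,
            "Re_Q": self.Q.real.ravel(), "Im_Q": self.Q.imag.ravel(),
        })


def _fourier_bins(response, start_index, ns):
    """Complex Fourier coefficients c_m of one period, phase-referenced to
    the stimulus time origin (start_index samples before the window)."""
    y = np.asarray(response, dtype=float)
    if y.shape[0] < ns:
        raise ValueError("response shorter than one period")
    c = np.fft.rfft(y[:ns]) / ns
    m = np.arange(c.shape[0])
    return c * np.exp(-2j * np.pi * m * (start_index % ns) / ns)


def estimate_qsa(spec: StimulusSpec, response, dt_ms: float,
                 start_index: int = 0, baseline: float = 0.0) -> QSAResult:
    """Estimate (y0, L, Q) from one post-transient period of the response.

    response : samples of y(t) for t = (start_index + p) dt, p = 0..Ns-1
        (extra trailing samples are ignored).
    baseline : steady-state response at the holding potential, subtracted so
        y0 captures only the stimulus-induced DC shift.
    """
    if spec.violations():
        raise ValueError("stimulus multipliers overlap; QSA is not identifiable")
    ns = samples_per_period(spec, dt_ms)
    c = _fourier_bins(np.asarray(response, dtype=float) - baseline,
                      start_index, ns)
    mult = np.asarray(spec.multipliers)
    x = spec.coefficients
    N = len(mult)
    y0 = c[0].real

    L = np.empty(2 * N, dtype=complex)
    for k in range(N):
        lk = c[mult[k]] / x[k]
        L[N + k] = lk
        L[N - 1 - k] = np.conj(lk)

    # b over Gamma x Gamma; position of +k is N+k-1... use helpers
    def pos(signed_k):
        return N + signed_k - 1 if signed_k > 0 else N + signed_k

    b = np.zeros((2 * N, 2 * N), dtype=complex)

    def set_pair(i, j, val):
        b[pos(i), pos(j)] = val
        b[pos(j), pos(i)] = val
        b[pos(-i), pos(-j)] = np.conj(val)
        b[pos(-j), pos(-i)] = np.conj(val)

    for k in range(N):
        val = c[2 * mult[k]] / (x[k] * x[k])
        b[pos(k + 1), pos(k + 1)] = val
        b[pos(-(k + 1)), pos(-(k + 1))] = np.conj(val)
    for a in range(N):
        for d in range(a + 1, N):
            i, j = a + 1, d + 1
            set_pair(i, j, c[mult[a] + mult[d]] / (2.0 * x[a] * x[d]))
            set_pair(-i, j, c[mult[d] - mult[a]] / (2.0 * np.conj(x[a]) * x[d]))
    # Q_{i,j} = B_{-i,j}: flipping rows maps position of i to position of -i
    Q = b[::-1, :].copy()
    return QSAResult(spec, y0, L, Q,
                     meta={"dt_ms": dt_ms, "start_index": start_index,
                           "baseline": baseline})


def reconstruct_response(result: QSAResult, dt_ms: float,
                         n_samples: int | None = None,
                         start_index: int = 0) -> np.ndarray:
    """Rebuild y0 + y1(t) + y2(t) from the estimated coefficients."""
    spec = result.spec
    ns = samples_per_period(spec, dt_ms)
    n_samples = n_samples or ns
    t = (start_index + np.arange(n_samples)) * dt_ms * 1e-3
    sm = result.signed_multipliers
    w = 2.0 * np.pi * sm / spec.period_s
    xg = result.x_gamma
    phasors = np.exp(1j * np.outer(t, w))          # (n, 2N)
    y1 = phasors @ (result.L * xg)
    B = result.Q[::-1, :]                           # back to b indexing
    xe = phasors * xg[None, :]
    y2 = np.einsum("ti,ij,tj->t", xe, B, xe)
    return result.y0 + np.real(y1 + y2)


def third_order_diagnostic(spec: StimulusSpec, response, dt_ms: float,
                           start_index: int = 0, baseline: float = 0.0) -> float:
    """Quality metric: response power outside DC/first/second-order bins,
    relative to first-order power (third-order contamination and noise)."""
    ns = samples_per_period(spec, dt_ms)
    c = _fourier_bins(np.asarray(response, dtype=float) - baseline,
                      start_index, ns)
    power = np.abs(c) ** 2
    mult = list(spec.multipliers)
    first = set(mult)
    second = set()
    for a in range(len(mult)):
        second.add(2 * mult[a])
        for d in range(a + 1, len(mult)):
            second.add(mult[a] + mult[d])
            second.add(mult[d] - mult[a])
    used = {0} | first | second
    other = np.array([m for m in range(len(c)) if m not in used])
    p1 = sum(power[m] for m in first)
    return float(power[other].sum() / p1)


# ---------------------------------------------------------------------------
# multi-sinusoidal power spectra
# ---------------------------------------------------------------------------

@dataclass
class SpectrumTable:
    """Frequency -> power mapping with redundancy counts.

    Keys are exact integer multipliers of 1/period_s; power is |y_hat|^2 in
    output units squared (not a density).
    """

    kind: str
    period_s: float
    power: dict = field(default_factory=dict)   # multiplier -> summed power
    counts: dict = field(default_factory=dict)  # multiplier -> N measurements
    n_merged: int = 1

    def frequencies_hz(self):
        return np.array(sorted(self.power)) / self.period_s

    def averaged(self):
        """(f_Hz, mean power, count) sorted by frequency."""
        keys = sorted(self.power)
        f = np.array(keys) / self.period_s
        p = np.array([self.power[k] / self.counts[k] for k in keys])
        n = np.array([self.counts[k] for k in keys])
        return f, p, n

    def to_frame(self):
        import pandas as pd
        f, p, n = self.averaged()
        return pd.DataFrame({"f_Hz": f, "power": p, "count": n,
                             "kind": self.kind})


def _table(kind, period, mapping):
    return SpectrumTable(kind, period, dict(mapping),
                         {k: 1 for k in mapping})


def single_trial_spectra(spec: StimulusSpec, response, dt_ms: float,
                         start_index: int = 0, baseline: float = 0.0) -> dict:
    """S_L, S_D, S_P, S_M of one measurement, keyed by output multiplier."""
    ns = samples_per_period(spec, dt_ms)
    c = _fourier_bins(np.asarray(response, dtype=float) - baseline,
                      start_index, ns)
    power = np.abs(c) ** 2
    mult = list(spec.multipliers)
    s_l = {m: power[m] for m in mult}
    s_d = {2 * m: power[2 * m] for m in mult}
    s_p, s_m = {}, {}
    for a in range(len(mult)):
        for d in range(a + 1, len(mult)):
            s_p[mult[a] + mult[d]] = power[mult[a] + mult[d]]
            s_m[mult[d] - mult[a]] = power[mult[d] - mult[a]]
    return {"S_L": _table("S_L", spec.period_s, s_l),
            "S_D": _table("S_D", spec.period_s, s_d),
            "S_P": _table("S_P", spec.period_s, s_p),
            "S_M": _table("S_M", spec.period_s, s_m)}


def qsa_column_power(result: QSAResult) -> SpectrumTable:
    """Mean squared quadratic output by matrix columns,
    S_R(w_j) = (1/2N) sum_i |Q_{i,j} conj(x_i) x_j|^2, at fundamentals."""
    spec = result.spec
    N = spec.n_components
    xg = result.x_gamma
    contrib = np.abs(result.Q * np.conj(xg)[:, None] * xg[None, :]) ** 2
    col = contrib.sum(axis=0) / (2.0 * N)
    mapping = {}
    for p, m in enumerate(result.signed_multipliers):
        if m > 0:
            mapping[int(m)] = col[p]
    return _table("S_R", spec.period_s, mapping)


def accumulate_spectra(tables: list) -> SpectrumTable:
    """Merge same-kind tables from different trials, tracking redundancy
    counts so shared frequencies are averaged over their measurements."""
    if not tables:
        raise ValueError("no tables to accumulate")
    kind = tables[0].kind
    period = tables[0].period_s
    if any(t.kind != kind or t.period_s != period for t in tables):
        raise ValueError("tables must share kind and period")
    out = SpectrumTable(kind, period, {}, {}, n_merged=len(tables))
    for t in tables:
        for k, p in t.power.items():
            out.power[k] = out.power.get(k, 0.0) + p
            out.counts[k] = out.counts.get(k, 0) + t.counts[k]
    return out


# ---------------------------------------------------------------------------
# QSA on Markov noise
# ---------------------------------------------------------------------------

def qsa_markov_noise_power(spec: StimulusSpec, responses, dt_ms: float,
                           start_index: int = 0, baseline: float = 0.0,
                           remove_harmonics: bool = False) -> np.ndarray:
    """Average |Q_{i,j}|^2 over per-iteration QSA estimates of stochastic
    responses to the SAME stimulus; optionally zero the doubling
    (harmonic-frequency) coefficients."""
    responses = list(responses)
    if len(responses) < 2:
        raise ValueError("need at least 2 iterations")
    acc = None
    for resp in responses:
        r = estimate_qsa(spec, resp, dt_ms, start_index, baseline)
        p = np.abs(r.Q) ** 2
        acc = p if acc is None else acc + p
    avg = acc / len(responses)
    if remove_harmonics:
        avg = remove_harmonic_entries(avg, spec)
    return avg


def remove_harmonic_entries(q_power: np.ndarray, spec: StimulusSpec):
    """Zero entries whose output frequency is a doubling 2|w_k|."""
    N = spec.n_components
    mult = np.asarray(spec.multipliers)
    sm = np.concatenate([-mult[::-1], mult])
    out_mult = np.abs(sm[None, :] - sm[:, None])
    doubled = set(2 * m for m in mult)
    mask = np.isin(out_mult, list(doubled))
    out = q_power.copy()
    out[mask] = 0.0
    return out
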