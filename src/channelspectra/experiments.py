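"""Named end-to-end experiments with seeded reproducibility.

Each experiment mirrors one of the figure-style analyses: impedance sweeps,
Markov fluctuation spectra against their analytic predictions, QSA of the
deterministic models, five-curve normalized overlays, QSA applied to Markov
noise at different stimulus amplitudes, and the membrane-area sweep.  All
outputs are plain CSV tables plus a JSON manifest that allows bit-exact
re-runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import admittance as adm
from . import markov as mk
from . import models as md
from . import qsa
from . import spectra as sp

_FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ExperimentConfig(BaseModel):
    """Validated run configuration; defaults reproduce the reference
    parameter table and figure-caption settings."""

    experiment: str
    model: str = "n4"                       # n4 | p2 (where applicable)
    v0: list[float] = Field(default_factory=lambda: [5.0, 55.0])
    amplitude_mV: float = 0.25
    multipliers: list[int] = Field(
        default_factory=lambda: list(qsa.CANONICAL_MULTIPLIERS))
    period_s: float = 1.0
    iterations: int = 128
    rho_per_um2: float = 18.0
    area_um2: float = 500.0
    dt_ms: float = 0.01
    factor_A: float = md.DEFAULT_FACTOR_A
    factor_B: float = md.DEFAULT_FACTOR_B
    rng_seed: int = 0
    out_dir: str | None = None

    @field_validator("iterations")
    @classmethod
    def _pos_iter(cls, v):
        if v < 1:
            raise ValueError("iterations must be >= 1")
        return v

    @field_validator("dt_ms", "period_s", "amplitude_mV", "area_um2",
                     "rho_per_um2")
    @classmethod
    def _pos(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    def v0_was_set(self) -> bool:
        return "v0" in self.model_fields_set


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------

def transient_skip_ms(model: str, v0: float, factor_A=md.DEFAULT_FACTOR_A,
                      factor_B=md.DEFAULT_FACTOR_B,
                      minimum_ms: float = 50.0) -> float:
    """Settle time excluded from spectral estimation: 10x the slowest
    relaxation time, with a floor."""
    if model in ("n4", "hh_n4", "n4_5state"):
        tau = md.hh_gate_rates(v0, "n").tau
    else:
        tau = sp.p2_eigensystem(v0, factor_A, factor_B).tau1_ms
    return max(10.0 * tau, minimum_ms)


def ode_clamp_response(model: str, v0: float, spec: qsa.StimulusSpec,
                       dt_ms: float = 0.01, observable: str = "I_K_pA",
                       area_um2: float = 500.0,
                       factor_A=md.DEFAULT_FACTOR_A,
                       factor_B=md.DEFAULT_FACTOR_B):
    """Deterministic clamp response to a multi-sine around v0.

    Returns (response window of one period, start_index, baseline) ready for
    QSA estimation.  observable: 'I_K_pA' (absolute potassium current) or
    'I_total' (clamp current density, uA/cm^2).
    """
    ns = qsa.samples_per_period(spec, dt_ms)
    skip = transient_skip_ms(model, v0, factor_A, factor_B)
    start_index = int(np.ceil(skip / dt_ms))
    n_steps = start_index + ns
    t_s = np.arange(n_steps + 1) * dt_ms * 1e-3
    v = np.full(n_steps + 1, float(v0))
    for a, m, th in zip(spec.amplitudes_mV, spec.multipliers, spec.phases_rad):
        v += a * np.cos(2 * np.pi * m / spec.period_s * t_s + th)
    ode_model = "hh_n4" if model in ("n4", "hh_n4") else "p2"
    trace = md.integrate_voltage_clamp(ode_model, v, dt_ms, n_steps * dt_ms,
                                       factor_A=factor_A, factor_B=factor_B)
    if observable == "I_K_pA":
        _, y = md.deterministic_potassium_current(trace, area_um2=area_um2)
        if model in ("n4", "hh_n4"):
            p_inf = md.hh_gate_rates(v0, "n").x_inf ** 4
        else:
            p_inf = md.p2_steady_state(v0, factor_A, factor_B)["p2_inf"]
        baseline = (trace.params.gK * p_inf * (v0 - trace.params.VK)
                    * area_um2 * 0.01)
    elif observable == "I_total":
        y = trace.i_total
        ss = md.integrate_voltage_clamp(ode_model, v0, dt_ms, dt_ms,
                                        factor_A=factor_A, factor_B=factor_B)
        baseline = ss.i_total[0]
    else:
        raise ValueError(f"unknown observable {observable!r}")
    return y[start_index:start_index + ns], start_index, baseline


def markov_clamp_responses(model: str, v0: float, spec: qsa.StimulusSpec,
                           population: mk.ChannelPopulation,
                           iterations: int, rng_seed: int,
                           dt_ms: float = 0.01, burn_in_ms: float = 50.0,
                           factor_A=md.DEFAULT_FACTOR_A,
                           factor_B=md.DEFAULT_FACTOR_B):
    """Per-iteration stochastic current windows (pA) to the SAME stimulus.

    Returns (responses list, start_index).
    """
    ns = qsa.samples_per_period(spec, dt_ms)
    start_index = int(np.ceil(burn_in_ms / dt_ms))
    n_steps = start_index + ns
    t_s = np.arange(n_steps + 1) * dt_ms * 1e-3
    v = np.full(n_steps + 1, float(v0))
    for a, m, th in zip(spec.amplitudes_mV, spec.multipliers, spec.phases_rad):
        v += a * np.cos(2 * np.pi * m / spec.period_s * t_s + th)
    mk_model = "n4_5state" if model in ("n4", "hh_n4") else "p2_3state"
    seeds = np.random.SeedSequence(rng_seed).generate_state(iterations)
    responses = []
    for s in seeds:
        tr = mk.simulate_markov(mk_model, v, population, dt_ms,
                                n_steps * dt_ms, int(s) % (2 ** 31 - 1),
                                factor_A=factor_A, factor_B=factor_B)
        i = mk.fluctuating_current(tr, v)
        responses.append(i[start_index:start_index + ns])
    return responses, start_index


def ode_small_signal_admittance(model: str, v0: float, f_hz: float,
                                amplitude_mV: float = 0.0125,
                                dt_ms: float = 0.01,
                                factor_A=md.DEFAULT_FACTOR_A,
                                factor_B=md.DEFAULT_FACTOR_B) -> complex:
    """Admittance estimated from the time-domain response to one small
    sine: fundamental Fourier coefficient ratio over an integer number of
    post-transient cycles.  Independent of the closed-form linearization."""
    period_ms = 1e3 / f_hz
    ns = int(round(period_ms / dt_ms))
    if abs(ns * dt_ms - period_ms) > 1e-9 * period_ms:
        raise ValueError("dt must divide the stimulus period")
    skip = transient_skip_ms(model, v0, factor_A, factor_B)
    n_skip = int(np.ceil(skip / period_ms)) * ns  # integer periods
    n_steps = n_skip + ns
    t_ms = np.arange(n_steps + 1) * dt_ms
    w = 2 * np.pi * f_hz * 1e-3  # rad/ms
    v = v0 + amplitude_mV * np.cos(w * t_ms)
    ode_model = "hh_n4" if model in ("n4", "hh_n4") else model
    trace = md.integrate_voltage_clamp(ode_model, v, dt_ms, n_steps * dt_ms,
                                       factor_A=factor_A, factor_B=factor_B)
    y = trace.i_total[n_skip:n_skip + ns]
    t = t_ms[n_skip:n_skip + ns]
    c = np.mean(y * np.exp(-1j * w * t))
    return c / (amplitude_mV / 2.0)


def qsa_markov_deviation(model: str, v0: float, amplitude_mV: float,
                         population: mk.ChannelPopulation, iterations: int,
                         rng_seed: int, dt_ms: float = 0.01,
                         multipliers=qsa.CANONICAL_MULTIPLIERS,
                         remove_harmonics: bool = False) -> dict:
    """Relative deviation of the averaged stochastic |Q|^2 from the
    deterministic ODE |Q|^2 (Frobenius norm ratio)."""
    spec = qsa.make_stimulus(1.0, multipliers, amplitude_mV,
                             rng_seed=rng_seed)
    y, si, base = ode_clamp_response(model, v0, spec, dt_ms,
                                     area_um2=population.area_um2)
    q_ode = np.abs(estimate_qsa_window(spec, y, dt_ms, si, base).Q) ** 2
    responses, si_m = markov_clamp_responses(model, v0, spec, population,
                                             iterations, rng_seed + 1, dt_ms)
    q_mk = qsa.qsa_markov_noise_power(spec, responses, dt_ms, si_m,
                                      baseline=base)
    if remove_harmonics:
        q_ode = qsa.remove_harmonic_entries(q_ode, spec)
        q_mk = qsa.remove_harmonic_entries(q_mk, spec)
    dev = np.linalg.norm(q_mk - q_ode) / np.linalg.norm(q_ode)
    return {"deviation": float(dev), "q_markov": q_mk, "q_ode": q_ode,
            "spec": spec}


def estimate_qsa_window(spec, y, dt_ms, start_index, baseline):
    return qsa.estimate_qsa(spec, y, dt_ms, start_index, baseline)


def averaged_random_set_spectra(model: str, v0: float, n_trials: int,
                                rng_seed: int, amplitude_mV: float = 0.25,
                                n_freq: int = 21, dt_ms: float = 0.02,
                                area_um2: float = 500.0) -> dict:
    """S_L, S_D, S_P, S_M, S_R averaged over deterministic trials with
    independent random non-overlapping frequency sets (frequency-merging
    with redundancy counts)."""
    acc: dict[str, list] = {k: [] for k in ("S_L", "S_D", "S_P", "S_M", "S_R")}
    for m in range(n_trials):
        mult = qsa.generate_nonoverlapping_set(n_freq, (1, 1000),
                                               rng_seed + 7919 * m)
        spec = qsa.make_stimulus(1.0, mult, amplitude_mV,
                                 rng_seed=rng_seed + 104729 * m)
        y, si, base = ode_clamp_response(model, v0, spec, dt_ms,
                                         area_um2=area_um2)
        tables = qsa.single_trial_spectra(spec, y, dt_ms, si, base)
        res = qsa.estimate_qsa(spec, y, dt_ms, si, base)
        tables["S_R"] = qsa.qsa_column_power(res)
        for k, t in tables.items():
            acc[k].append(t)
    return {k: qsa.accumulate_spectra(v) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def compare_overlay(curves: dict, normalization: str = "unity_at_lowest",
                    n_grid: int = 50) -> pd.DataFrame:
    """Interpolate (f, power) curves onto a shared geometric grid and
    normalize for shape comparison.

    normalization: 'unity_at_lowest' divides each curve by its value at the
    lowest shared frequency; 'log_offset_fit' removes the least-squares
    vertical offset in log power relative to the first curve.
    """
    fmin = max(np.min(f) for f, _ in curves.values())
    fmax = min(np.max(f) for f, _ in curves.values())
    if fmin >= fmax:
        raise ValueError("curves have disjoint frequency ranges")
    grid = np.geomspace(fmin, fmax, n_grid)
    interp = {}
    for label, (f, p) in curves.items():
        order = np.argsort(f)
        logp = np.interp(np.log(grid), np.log(np.asarray(f)[order]),
                         np.log(np.asarray(p)[order]))
        interp[label] = logp
    out = {"f_Hz": grid}
    labels = list(interp)
    ref = interp[labels[0]]
    for label in labels:
        logp = interp[label]
        if normalization == "unity_at_lowest":
            logp = logp - logp[0]
        elif normalization == "log_offset_fit":
            logp = logp - np.mean(logp - ref)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        out[label] = np.exp(logp)
    return pd.DataFrame(out)


def log_discrepancy(df: pd.DataFrame, a: str, b: str) -> dict:
    d = np.abs(np.log10(df[a].to_numpy()) - np.log10(df[b].to_numpy()))
    return {"max_abs_dlog10": float(d.max()), "mean_abs_dlog10": float(d.mean())}


def five_curve_overlay(model: str, v0: float, n_trials: int, rng_seed: int,
                       dt_ms: float = 0.02) -> pd.DataFrame:
    """Normalized overlay of S_IK, S_L, S_D, S_R and |Ym|^2 (unity at the
    lowest shared frequency)."""
    tabs = averaged_random_set_spectra(model, v0, n_trials, rng_seed,
                                       dt_ms=dt_ms)
    pop = mk.ChannelPopulation()
    fgrid = np.geomspace(1.0, 1000.0, 120)
    s_ik = (sp.n4_psd(fgrid, v0) if model == "n4"
            else sp.p2_psd(fgrid, v0, pop))
    _, ym2 = adm.modified_admittance(v0, fgrid, model=model)
    curves = {"S_IK": (fgrid, s_ik.total), "Ym2": (fgrid, ym2)}
    for k in ("S_L", "S_D", "S_R"):
        f, p, _ = tabs[k].averaged()
        keep = p > 0
        curves[k] = (f[keep], p[keep])
    return compare_overlay(curves)


# ---------------------------------------------------------------------------
# experiment registry
# ---------------------------------------------------------------------------

def _e1_impedance_sweep(cfg: ExperimentConfig) -> dict:
    v0s = cfg.v0 if cfg.v0_was_set() else [-5.0, 0.0, 5.0, 10.2, 15.2, 25.2]
    f = np.geomspace(1.0, 10000.0, 200)
    frames = []
    for with_na in (True, False):
        for v0 in v0s:
            lr = adm.hh_admittance(v0, f, include_sodium=with_na)
            df = lr.to_frame()
            df["V0_mV"] = v0
            df["sodium"] = with_na
            frames.append(df)
    return {"impedance": pd.concat(frames, ignore_index=True)}


def _e2_markov_psd(cfg: ExperimentConfig) -> dict:
    pop = mk.ChannelPopulation(cfg.rho_per_um2, cfg.area_um2)
    frames = []
    mk_model = "n4_5state" if cfg.model == "n4" else "p2_3state"
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(
        len(cfg.v0) * cfg.iterations).reshape(len(cfg.v0), cfg.iterations)
    for vi, v0 in enumerate(cfg.v0):
        traces = []
        for s in seeds[vi]:
            tr = mk.simulate_markov(mk_model, v0, pop, cfg.dt_ms,
                                    cfg.period_s * 1e3,
                                    int(s) % (2 ** 31 - 1),
                                    factor_A=cfg.factor_A,
                                    factor_B=cfg.factor_B)
            traces.append(mk.fluctuating_current(tr, v0))
        skip = int(np.ceil(transient_skip_ms(cfg.model, v0) / cfg.dt_ms))
        f, psd, n = mk.empirical_psd(traces, cfg.dt_ms, transient_skip=skip)
        ana = (sp.n4_psd(f, v0, pop) if cfg.model == "n4"
               else sp.p2_psd(f, v0, pop, cfg.factor_A, cfg.factor_B))
        frames.append(pd.DataFrame({"f_Hz": f, "psd_pA2_per_Hz": psd,
                                    "analytic": ana.total, "V0_mV": v0,
                                    "n_iterations": n}))
    return {"markov_psd": pd.concat(frames, ignore_index=True)}


def _e3_qsa(cfg: ExperimentConfig) -> dict:
    spec = qsa.make_stimulus(cfg.period_s, cfg.multipliers, cfg.amplitude_mV,
                             rng_seed=cfg.rng_seed)
    out = {}
    for v0 in cfg.v0:
        y, si, base = ode_clamp_response(cfg.model, v0, spec, cfg.dt_ms,
                                         observable="I_total")
        res = qsa.estimate_qsa(spec, y, cfg.dt_ms, si, base)
        tabs = qsa.single_trial_spectra(spec, y, cfg.dt_ms, si, base)
        tabs["S_R"] = qsa.qsa_column_power(res)
        out[f"qsa_matrix_v{v0:g}"] = res.to_frame()
        out[f"qsa_linear_v{v0:g}"] = pd.DataFrame({
            "f_Hz": spec.frequencies_hz,
            "Re_l": res.linear_coefficients().real,
            "Im_l": res.linear_coefficients().imag,
        })
        out[f"qsa_spectra_v{v0:g}"] = pd.concat(
            [t.to_frame() for t in tabs.values()], ignore_index=True)
    return out


def _e4_overlay(cfg: ExperimentConfig) -> dict:
    out = {}
    for v0 in cfg.v0:
        df = five_curve_overlay(cfg.model, v0, cfg.iterations, cfg.rng_seed)
        df["V0_mV"] = v0
        out[f"overlay_v{v0:g}"] = df
    return out


def _e5_qsa_markov(cfg: ExperimentConfig) -> dict:
    pop = mk.ChannelPopulation(cfg.rho_per_um2, cfg.area_um2)
    out = {}
    for amp in (1.0, 4.0):
        r = qsa_markov_deviation("p2", 55.0, amp, pop, cfg.iterations,
                                 cfg.rng_seed, cfg.dt_ms)
        spec = r["spec"]
        sm = np.concatenate([-np.asarray(spec.multipliers)[::-1],
                             np.asarray(spec.multipliers)])
        for key, mat in (("markov", r["q_markov"]), ("ode", r["q_ode"])):
            nodiag = qsa.remove_harmonic_entries(mat, spec)
            ii, jj = np.meshgrid(sm, sm, indexing="ij")
            out[f"q2_{key}_amp{amp:g}"] = pd.DataFrame({
                "i": ii.ravel(), "j": jj.ravel(),
                "abs_Q2": mat.ravel(), "abs_Q2_nodiag": nodiag.ravel()})
        out[f"deviation_amp{amp:g}"] = pd.DataFrame(
            {"deviation": [r["deviation"]], "amplitude_mV": [amp]})
    return out


def _e6_area_sweep(cfg: ExperimentConfig) -> dict:
    rows = []
    for area in (50.0, 500.0, 5000.0, 50000.0):
        pop = mk.ChannelPopulation(cfg.rho_per_um2, area)
        r = qsa_markov_deviation("p2", 55.0, 1.0, pop, cfg.iterations,
                                 cfg.rng_seed, cfg.dt_ms)
        rows.append({"area_um2": area, "n_channels": pop.n_channels,
                     "deviation": r["deviation"]})
    return {"area_sweep": pd.DataFrame(rows)}


REGISTRY = {
    "E1": _e1_impedance_sweep,
    "E2": _e2_markov_psd,
    "E3": _e3_qsa,
    "E4": _e4_overlay,
    "E5": _e5_qsa_markov,
    "E6": _e6_area_sweep,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute a registered experiment; write CSVs and a manifest if
    config.out_dir is set.  Returns the result tables."""
    if config.experiment not in REGISTRY:
        raise ValueError(
            f"unknown experiment {config.experiment!r}; "
            f"known: {sorted(REGISTRY)}")
    tables = REGISTRY[config.experiment](config)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_json = config.model_dump_json(exclude={"out_dir"})
        run_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
        for name, df in tables.items():
            df.to_csv(out / f"{config.experiment}_{name}.csv", index=False,
                      float_format=_FLOAT_FMT)
        manifest = {"config": json.loads(cfg_json), "run_hash": run_hash,
                    "tables": sorted(tables)}
        (out / f"{config.experiment}_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
    return tables
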