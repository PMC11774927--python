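# Methods

This note records the models implemented by `channelspectra`, the numerical
and design choices behind them, and what the test conditions do and do not
establish.

## Models and conventions

Voltages use the classic depolarization convention: V is the displacement
from rest (rest = 0), so the potassium reversal potential is V_K = −12 mV.
Time is in ms and rates in ms⁻¹ throughout the kinetics code; conversions
to SI happen only at two declared boundaries — spectra (ms → s, f in Hz,
ω = 2πf rad/s internally) and absolute currents (µA/cm² × µm² → pA,
factor 0.01; pS × mV → pA, factor 10⁻³).  This is because the rate-constant
formulas and membrane parameters (C_m = 1 µF/cm², g_L = 0.3, g_K = 36,
g_Na = 120 mS/cm², V_L = 10.6, V_Na = 120 mV) are tabulated in those units.

The potassium activation rate is implemented as
α_n(V) = 0.01·(10.001 − V)/(e^((10.001−V)/10) − 1): the 10.001 offset
(in both numerator and exponent) moves the removable 0/0 point of the
classic formula off the integer voltage grid, and the implementation
additionally continues u/(e^u − 1) through u = 0 by its series, so the
rates and their analytic V-derivatives are finite and smooth at every
voltage.  This reading — rather than an offset in the exponent only, which
would make α_n vanish at V = 10 and go negative just above it — is the only
one consistent with all four published steady-state values (n∞⁴ = 0.0247 /
0.596 and p₂∞ = 0.0297 / 0.565 at 5 / 55 mV) simultaneously.  α_m gets the
same series continuation at its removable point V = 25.

The p₂ chain 0 ⇌ 1 ⇌ 2 is reduced (p₀ = 1 − p₁ − p₂) to a 2×2 affine
system with generator entries a₁₁ = −(k₁+k₂+k₃), a₁₂ = −k₁+k₄, a₂₁ = k₃,
a₂₂ = −k₄.  Its stationary point is obtained from the 2×2 linear solve and
cross-checked against the sequential closed form
p₂∞ = k₁k₃/(k₂k₄ + k₁k₄ + k₁k₃).  The default factors A = 0.35, B = 4 are
the working values used throughout for the p₂-vs-n⁴ comparisons; A = B = 2
reduces the model exactly to n² (steady state n∞², relaxation times τ_n and
τ_n/2), which the tests exploit as a structural limit.

## Deterministic integration

Forward Euler with default dt = 0.01 ms (the fastest rate at 55 mV times dt
is ≈ 0.02, and the n²-equivalence tests confirm first-order convergence).
Rate tables are precomputed vectorized from the commanded V(t) and frozen on
each dt interval; the jitted inner loops contain no model formulas.  Initial
conditions default to the steady state of V(0).  Integration refuses to
continue if any gate/probability leaves [0,1] by more than 10⁻⁶ (the
symptom of an unstable dt).  The clamp current is
I = C_m dV/dt + I_L + I_K (+ I_Na), with dV/dt a centered difference of the
command.  Sodium is supported in the ODE and admittance paths only; the
stochastic and QSA analyses target the potassium conductance in isolation
(g_Na = 0), which is the regime the comparisons are about.

## Linear admittance

The gating transfer D̂_x(ω) = [α′_x − x₀(α_x+β_x)′]/(iω + α_x + β_x) uses
analytic V-derivatives of the rate formulas (verified against centered
finite differences to < 10⁻⁶ relative).  The membrane admittance densities
(mS/cm²) follow the standard linearization for n⁴/full models and the
second-order rational transfer δp̂₂/δV̂ for p₂, whose denominator is
(iω − a₁₁)(iω − a₂₂) − a₂₁a₁₂.  Public frequency interfaces are in Hz; the
ms⁻¹ → s⁻¹ conversion happens once at this boundary to avoid 2π/unit
mistakes.  The independent check is a small-signal time-domain oracle:
integrate the ODE under a 0.0125 mV single sine and take the ratio of
fundamental Fourier coefficients; closed form and oracle agree to < 1%
across 1–1000 Hz at both operating points, limited by the O(dt) bias of
Euler.

The "modified admittance" Ŷ_m keeps only the voltage-dependent potassium
transfer term (no capacitance, no frequency-independent terms); its squared
magnitude is the linear-kinetics shape that overlay analyses compare with
fluctuation spectra.

## QSA estimation

A multi-sine with integer multipliers n_k of 1/T is QSA-valid when no
second-order combination (n_i+n_j, |n_i−n_j|, 2n_k) collides with a
first-order multiplier or with another combination; the checker enumerates
all combinations exactly in integer arithmetic (frequencies are never
compared as floats).  Random valid sets are built incrementally: candidates
are drawn one at a time and kept only if the grown set stays valid, with a
restart after 1000 consecutive rejections — whole-set rejection sampling
has vanishing acceptance probability at 21 frequencies, and a greedy build
can corner itself, hence the restarts.  Sets are deterministic given the
seed.

Estimation takes exactly one post-transient stimulus period, so every
programmed frequency is an exact FFT bin (no windowing, no zero padding);
an arbitrary window start is handled by an exact phase rotation
e^(−2πi·m·s₀/N_s).  The steady-state response at V₀ is subtracted first, so
y₀ captures only the stimulus-induced DC shift.  Each second-order bin
identifies only the sum b_{i,j}+b_{j,i}; the symmetric convention
b_{i,j} = b_{j,i} splits it equally, b_{−k,k} = 0 assigns all DC to y₀, and
the Hermitian matrix is assembled as Q_{i,j} = B_{−i,j}.  The default
transient excluded before analysis is 10× the slowest relaxation time
(floor 50 ms).  Stimulus phases default to pseudo-random values in [0, π]
(the tabulated convention; a flag allows [0, 2π]).  Default amplitudes:
0.25 mV for deterministic work, 1–4 mV when quadratic responses must
overcome channel noise.  Reconstruction from (y₀, L, Q) reproduces the n⁴
response at 0.25 mV with relative RMS residual < 10⁻³; the remainder is
third-order leakage, which a diagnostic reports as the power in bins
outside DC/first/second order relative to first-order power.

The averaged spectra S_L, S_D, S_P, S_M (raw output-bin powers partitioned
by first/second-order support) and S_R(ω_j) = (1/2N)Σ_i |Q_{i,j}x̄_i x_j|²
merge trials by exact integer frequency with redundancy counts N_Ω, N_Ξ;
measured bins are divided by their counts, never by the trial total.

## Stochastic simulation

Channel populations are simulated as aggregate counts on the 5-state (n⁴)
or 3-state (p₂) chain with an exact Gillespie algorithm; cost scales with
transition events, not channel number.  For time-varying commands the rates
are frozen on each dt interval (0.01 ms default); within an interval the
SSA is exact, and discarding the pending waiting time at each boundary is
valid by memorylessness.  The freshness error of a ≤ 1 kHz stimulus over
0.01 ms is negligible relative to gating rates ≤ 2 ms⁻¹.  Initial counts
are drawn from the stationary law (binomial over subunit states for n⁴, the
stationary occupancies for p₂) and a 50 ms burn-in is discarded regardless.
Defaults: ρ_K = 18 µm⁻², A_K = 500 µm² ⇒ N_K = 9000 and γ_K = g_K/N_K =
20 pS.  Identical seeds give bit-identical traces.

The empirical PSD is the mean-subtracted rectangular-window periodogram per
iteration, averaged arithmetically across iterations, scaled one-sided as
2|X|²dt/N so that Σ PSD·Δf equals the sample variance — the same one-sided
convention as the analytic spectra (S(f) = S_IK(2πf), ∫₀^∞ S df = Var I_K),
verified by the variance integral in both directions.  When a stimulus is
present the evoked deterministic component is removed by subtracting the
across-iteration ensemble-mean trace before the periodogram, which strips
the stimulus response at all orders and leaves the pure fluctuation
spectrum; this is how the stimulus-invariance of the noise spectra is
demonstrated.

## Analytic spectra

For n⁴ the open-state autocovariance expands the conditional open
probability [n∞+(1−n∞)e^(−t/τ_n)]⁴ into four exponentials, giving four
Lorentzians with corner angular frequencies q/τ_n and binomial weights; for
p₂ the reduced generator's eigenvalues λ₁ (slow) and λ₂ give two
Lorentzians with weights c₁, c₂ fixed by the open initial condition
(c₁+c₂ = 1−p₂∞).  Eigenvalues are labeled slow-first so component identity
is stable across voltage sweeps.  A non-simple real spectrum
(T² − 4D ≤ 0) raises a flagged error carrying the trace/determinant
diagnostics rather than silently merging modes; a grid check over
V ∈ [−5, 100] confirms the discriminant stays positive for the working
factor values, so the confluent branch is unreachable there.

One point worth stating precisely: the slow component S₁ dominates the n⁴
spectrum at 55 mV only below the corner region (ratio 0.901 at DC, crossing
0.9 near 20 Hz); every Lorentzian has an ω⁻² tail, so the high-frequency
ratio is exactly w₁/Σq·w_q ≈ 0.68.  The dominance tests therefore assert
the > 0.9 ratio at low frequency plus closeness of the full curves on a log
scale (< 0.2 log₁₀ over 1–1000 Hz), together with the failure of dominance
at 5 mV.

## Experiments and problem sizes

The registry (E1 impedance sweep, E2 Markov-vs-analytic spectra, E3
deterministic QSA, E4 five-curve normalized overlays, E5 QSA-on-Markov
noise at 1 and 4 mV, E6 membrane-area sweep 50–50,000 µm²) writes CSV plus
a JSON manifest (config, seed, hash) enabling bit-exact re-runs; CSV floats
are fixed-format so reruns compare byte-identically.  Overlay normalization
divides each curve by its value at the lowest shared frequency; a
least-squares vertical offset in log power is the alternative for
admittance-vs-PSD overlays, since absolute admittance and noise levels live
in different units.

Problem sizes used by the test suite are chosen to estimate each quantity
well while keeping a full run in minutes: fluctuation spectra use 128
one-second iterations at N_K = 9000 (periodogram scatter ≈ 1/√128,
comfortably inside the 0.15 log₁₀ comparison band after six-per-decade
geometric binning over 1–1000 Hz); QSA-on-Markov comparisons use 16
iterations, the regime in which the stochastic-vs-deterministic contrast is
assessed; deterministic QSA averaging uses 16 random 21-frequency sets at
dt = 0.02–0.05 ms.  The E-registry defaults are configurable upward.

## What the synthetic conditions do not show

All inputs are model-generated; the stimuli are ideal (no electrode
filtering, no recording noise), clamps are perfect, channels are identical
and independent, and rates depend on voltage only.  Passing tests
demonstrate internal consistency of the estimators and closed forms under
these idealizations — they do not establish that a biological membrane
follows either gating scheme, nor calibrate absolute noise levels in a real
recording, where series resistance, leak heterogeneity and other noise
sources enter.  Sodium-channel stochastic spectra (the m³h analogue) are
architecturally straightforward but intentionally not implemented.
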