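"""Multi-sine design and QSA estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import channelspectra as cs
from channelspectra import qsa
import channelspectra.experiments as ex


def brute_force_overlap(mult):
    """Independent re-enumeration of frequency collisions."""
    mult = sorted(mult)
    combos = {}
    for a in range(len(mult)):
        for b in range(a, len(mult)):
            combos.setdefault(mult[a] + mult[b], set()).add((a, b, "+"))
    for a in range(len(mult)):
        for b in range(a + 1, len(mult)):
            combos.setdefault(mult[b] - mult[a], set()).add((a, b, "-"))
    bad = any(freq in mult for freq in combos)
    bad = bad or any(len(src) > 1 for src in combos.values())
    return bad


class TestOverlap:
    def test_consecutive_integers_fail(self):
        v = cs.check_overlap([1, 2, 3, 4])
        # 1 + 2 = 3 collides with a stimulus frequency
        assert any(kind == "first_order" and f == 3 for kind, f, *_ in v)
        # 1 + 4 = 2 + 3
        assert any(kind == "second_order" and f == 5 for kind, f, *_ in v)

    def test_doubling_collision(self):
        v = cs.check_overlap([1, 2])
        assert any(kind == "first_order" and f == 2 for kind, f, *_ in v)

    def test_canonical_set_is_valid(self):
        assert cs.check_overlap(cs.CANONICAL_MULTIPLIERS) == []
        assert not brute_force_overlap(cs.CANONICAL_MULTIPLIERS)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.sets(st.integers(1, 60), min_size=2, max_size=6))
    def test_matches_brute_force(self, mult):
        assert bool(cs.check_overlap(sorted(mult))) == brute_force_overlap(mult)

    def test_too_few(self):
        with pytest.raises(ValueError):
            cs.check_overlap([3])


class TestGenerator:
    def test_deterministic_and_valid(self):
        a = cs.generate_nonoverlapping_set(5, (1, 100), rng_seed=7)
        b = cs.generate_nonoverlapping_set(5, (1, 100), rng_seed=7)
        assert np.array_equal(a, b)
        assert cs.check_overlap(a) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_large_sets_pass_oracle(self, seed):
        m = cs.generate_nonoverlapping_set(21, (1, 1000), rng_seed=seed)
        assert len(m) == 21
        assert cs.check_overlap(m) == []
        assert not brute_force_overlap(list(m))

    def test_impossible_range_raises(self):
        with pytest.raises(RuntimeError):
            cs.generate_nonoverlapping_set(10, (1, 12), rng_seed=0,
                                           max_attempts=200)


class TestSynthesize:
    def test_single_component_cosine(self):
        spec = cs.StimulusSpec(1.0, (3, 5), (1.0, 0.0), (0.0, 0.0))
        x = cs.synthesize_multisine(spec, 0.5)
        t = np.arange(len(x)) * 0.5e-3
        np.testing.assert_allclose(x, np.cos(2 * np.pi * 3 * t), atol=1e-12)
        assert x.max() == pytest.approx(1.0)

    def test_zero_mean_over_period(self, canonical_spec):
        x = cs.synthesize_multisine(canonical_spec, 0.02)
        assert np.mean(x[:-1]) == pytest.approx(0.0, abs=1e-12)

    def test_fft_round_trip(self, canonical_spec):
        dt = 0.02
        x = cs.synthesize_multisine(canonical_spec, dt)
        ns = qsa.samples_per_period(canonical_spec, dt)
        c = np.fft.rfft(x[:ns]) / ns
        xk = canonical_spec.coefficients
        for k, m in enumerate(canonical_spec.multipliers):
            assert abs(c[m] - xk[k]) < 1e-10

    def test_nyquist_guard(self, canonical_spec):
        with pytest.raises(ValueError, match="Nyquist"):
            cs.synthesize_multisine(canonical_spec, 0.5)


class TestEstimator:
    def test_squarer_closed_form(self):
        spec = cs.make_stimulus(1.0, [2, 3], amplitude_mV=1.0,
                                phases=[0.3, 1.1])
        dt = 0.1
        x = cs.synthesize_multisine(spec, dt)
        ns = qsa.samples_per_period(spec, dt)
        res = cs.estimate_qsa(spec, x[:ns] ** 2, dt)
        xk = spec.coefficients
        assert res.y0 == pytest.approx(2 * np.sum(np.abs(xk) ** 2), abs=1e-12)
        assert np.abs(res.L).max() < 1e-12
        b = res.Q[::-1, :]  # back to b indexing
        # all identifiable b-coefficients of a squarer are exactly 1
        vals = np.unique(np.round(np.abs(b), 10))
        np.testing.assert_array_equal(vals, [0.0, 1.0])
        # DC convention
        g = res.gamma
        for k in range(len(g)):
            assert res.Q[len(g) - 1 - k, len(g) - 1 - k] == 0  # b_{-k,k}

    def test_linear_system_gives_zero_q(self, canonical_spec):
        from scipy.signal import lfilter
        dt = 0.02
        x = cs.synthesize_multisine(canonical_spec, dt, n_periods=3)
        y = lfilter([0.2], [1.0, -0.8], x)
        ns = qsa.samples_per_period(canonical_spec, dt)
        res = cs.estimate_qsa(canonical_spec, y[2 * ns:3 * ns], dt,
                              start_index=2 * ns)
        assert np.abs(res.Q).max() < 1e-9
        w = 2 * np.pi * canonical_spec.frequencies_hz * dt * 1e-3
        H = 0.2 / (1 - 0.8 * np.exp(-1j * w))
        np.testing.assert_allclose(res.linear_coefficients(), H, rtol=1e-9)

    def test_hermitian_on_ode_response(self, n4_qsa_run):
        Q = n4_qsa_run["result"].Q
        assert np.abs(Q - Q.conj().T).max() < 1e-10
        assert np.abs(np.linalg.eigvalsh(Q).imag).max() == 0.0

    def test_second_order_frequencies_present(self, n4_qsa_run):
        tabs = cs.single_trial_spectra(
            n4_qsa_run["spec"], n4_qsa_run["y"], n4_qsa_run["dt"],
            n4_qsa_run["start_index"], n4_qsa_run["baseline"])
        _, p_sum, _ = tabs["S_P"].averaged()
        assert np.all(p_sum > 0)

    def test_sl_consistency_with_linear_coefficients(self, n4_qsa_run):
        res = n4_qsa_run["result"]
        tabs = cs.single_trial_spectra(
            n4_qsa_run["spec"], n4_qsa_run["y"], n4_qsa_run["dt"],
            n4_qsa_run["start_index"], n4_qsa_run["baseline"])
        _, s_l, _ = tabs["S_L"].averaged()
        lx = np.abs(res.linear_coefficients()
                    * n4_qsa_run["spec"].coefficients) ** 2
        np.testing.assert_allclose(s_l, lx, rtol=1e-10)

    def test_reconstruction_residual(self, n4_qsa_run):
        rec = cs.reconstruct_response(
            n4_qsa_run["result"], n4_qsa_run["dt"],
            start_index=n4_qsa_run["start_index"]) + n4_qsa_run["baseline"]
        y = n4_qsa_run["y"]
        resid = np.sqrt(np.mean((rec - y) ** 2) / np.mean((y - y.mean()) ** 2))
        assert resid < 1e-3

    def test_overlapping_stimulus_rejected(self):
        spec = cs.StimulusSpec(1.0, (1, 2, 3, 4), (1.0,) * 4, (0.0,) * 4)
        with pytest.raises(ValueError, match="overlap"):
            cs.estimate_qsa(spec, np.zeros(1000), 1.0)


class TestColumnPower:
    def test_zero_matrix(self, canonical_spec):
        res = cs.QSAResult(canonical_spec, 0.0,
                           np.zeros(42, complex), np.zeros((42, 42), complex))
        _, p, _ = cs.qsa_column_power(res).averaged()
        assert np.all(p == 0)

    def test_single_entry(self):
        spec = cs.make_stimulus(1.0, [2, 3], 1.0, phases=[0.0, 0.0])
        Q = np.zeros((4, 4), complex)
        Q[0, 3] = 2.0 + 1.0j     # i = -3, j = +3 slot
        res = cs.QSAResult(spec, 0.0, np.zeros(4, complex), Q)
        x = res.x_gamma
        f, p, _ = cs.qsa_column_power(res).averaged()
        expected = np.abs(Q[0, 3] * np.conj(x[0]) * x[3]) ** 2 / 4.0
        assert p[f == 3.0][0] == pytest.approx(expected, rel=1e-12)
        assert p[f == 2.0][0] == 0.0

    def test_squarer_matches_brute_force(self):
        spec = cs.make_stimulus(1.0, [2, 3], 1.0, phases=[0.4, 2.0])
        dt = 0.1
        x = cs.synthesize_multisine(spec, dt)
        ns = qsa.samples_per_period(spec, dt)
        res = cs.estimate_qsa(spec, x[:ns] ** 2, dt)
        xg = res.x_gamma
        table = cs.qsa_column_power(res)
        f, p, _ = table.averaged()
        for j, m in enumerate(res.signed_multipliers):
            if m <= 0:
                continue
            brute = sum(abs(res.Q[i, j] * np.conj(xg[i]) * xg[j]) ** 2
                        for i in range(4)) / 4.0
            assert p[f == float(m)][0] == pytest.approx(brute, rel=1e-12)


class TestAccumulation:
    def test_idempotent_for_identical_trials(self, n4_qsa_run):
        tabs = cs.single_trial_spectra(
            n4_qsa_run["spec"], n4_qsa_run["y"], n4_qsa_run["dt"],
            n4_qsa_run["start_index"], n4_qsa_run["baseline"])
        merged = cs.accumulate_spectra([tabs["S_L"]] * 5)
        f0, p0, _ = tabs["S_L"].averaged()
        f1, p1, n1 = merged.averaged()
        np.testing.assert_array_equal(f0, f1)
        np.testing.assert_allclose(p0, p1, rtol=1e-14)
        assert np.all(n1 == 5)

    def test_disjoint_union(self):
        a = qsa.SpectrumTable("S_L", 1.0, {2: 1.0}, {2: 1})
        b = qsa.SpectrumTable("S_L", 1.0, {5: 3.0}, {5: 1})
        m = cs.accumulate_spectra([a, b])
        f, p, n = m.averaged()
        np.testing.assert_array_equal(f, [2.0, 5.0])
        np.testing.assert_array_equal(n, [1, 1])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.accumulate_spectra([])

    def test_shared_first_order_values_persist(self):
        # deterministic system: S_L at a frequency present in several random
        # sets averages to the single-trial value
        tabs8 = ex.averaged_random_set_spectra("n4", 5.0, 6, rng_seed=1,
                                               n_freq=6, dt_ms=0.05)
        f, p, n = tabs8["S_L"].averaged()
        shared = n > 1
        if shared.any():
            # re-measure one shared frequency with a fresh 2-tone stimulus
            m = int(f[shared][0])
            other = m + 1 if cs.check_overlap([m, m + 1]) == [] else m + 3
            spec = cs.make_stimulus(1.0, sorted([m, other]), 0.25,
                                    phases=[0.1, 0.2])
            y, si, base = ex.ode_clamp_response("n4", 5.0, spec, 0.05,
                                                observable="I_K_pA")
            t = cs.single_trial_spectra(spec, y, 0.05, si, base)
            fs, ps, _ = t["S_L"].averaged()
            ref = ps[fs == float(m)][0]
            assert p[f == float(m)][0] == pytest.approx(ref, rel=1e-2)


class TestQuadraticSpectraShape:
    def test_sd_decays_while_sr_flattens(self):
        # averaged over random frequency sets: doubling power falls at high
        # frequency, column power reaches a plateau
        tabs = ex.averaged_random_set_spectra("n4", 5.0, 16, rng_seed=5,
                                              dt_ms=0.05)

        def quintile_ratio(kind):
            f, p, _ = tabs[kind].averaged()
            keep = p > 0
            f, p = f[keep], p[keep]
            qlo = np.median(p[f <= np.quantile(f, 0.2)])
            qhi = np.median(p[f >= np.quantile(f, 0.8)])
            return qhi / qlo

        sd, sr = quintile_ratio("S_D"), quintile_ratio("S_R")
        assert sd < 0.05          # doubling power keeps falling
        assert sr > 0.1           # column power levels off
        assert sd < sr / 5        # and the contrast is strong


class TestMarkovNoisePower:
    def test_deterministic_responses_average_trivially(self, n4_qsa_run):
        y = n4_qsa_run["y"]
        q1 = np.abs(n4_qsa_run["result"].Q) ** 2
        avg = cs.qsa_markov_noise_power(
            n4_qsa_run["spec"], [y, y, y], n4_qsa_run["dt"],
            n4_qsa_run["start_index"], n4_qsa_run["baseline"])
        np.testing.assert_allclose(avg, q1, rtol=1e-12)

    def test_harmonic_removal(self, canonical_spec):
        N = canonical_spec.n_components
        q = np.ones((2 * N, 2 * N))
        out = cs.remove_harmonic_entries(q, canonical_spec)
        # exactly the 2N doubling entries vanish
        assert (out == 0).sum() == 2 * N
        for k in range(1, N + 1):
            assert out[N - k, N + k - 1] == 0  # (-k, +k) slot

    def test_needs_two_iterations(self, canonical_spec):
        with pytest.raises(ValueError):
            cs.qsa_markov_noise_power(canonical_spec, [np.zeros(10)], 0.02)
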