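"""Feature extractors against independent oracles and structural invariants."""

import numpy as np
import pytest
from scipy import signal

from pcgkit import PcgRecording, StateSegmentation, extract_all, preprocess
from pcgkit import SynthConfig, generate_recording
from pcgkit import features as F
from pcgkit.segmentation import CardiacCycle, cycles


def seg_from_lengths(n_cycles, lens=(40, 100, 30, 130)):
    ivs, pos = [], 0
    for _ in range(n_cycles):
        for state, ln in zip(("S1", "systole", "S2", "diastole"), lens):
            ivs.append((state, pos, pos + ln))
            pos += ln
    return StateSegmentation(ivs)


# ---------------------------------------------------------------------------
# structure
# ---------------------------------------------------------------------------


def test_canonical_names_and_domain_sizes():
    names = F.feature_names()
    domains = F.feature_domains()
    assert len(names) == 515 == len(domains)
    assert len(set(names)) == 515
    sizes = {d: domains.count(d) for d in F.DOMAINS}
    assert sizes == F.DOMAIN_SIZES
    assert F.feature_names() == names  # stable across calls


def test_band_spec_and_state_grid():
    assert len(F.BAND_SPEC) == 27
    assert F.BAND_SPEC[0] == (10.0, 40.0)
    assert F.BAND_SPEC[-1] == (790.0, 820.0)
    assert all(hi - lo == 30.0 for lo, hi in F.BAND_SPEC)
    assert len(F.STATE_GRID) == 77
    assert F.STATE_GRID[0] == 30.0 and F.STATE_GRID[-1] == 790.0
    assert np.all(np.diff(F.STATE_GRID) == 10.0)


# ---------------------------------------------------------------------------
# time-interval
# ---------------------------------------------------------------------------


class TestTimeInterval:
    def test_periodic_segmentation_has_zero_sds(self):
        out = F.time_interval_features(seg_from_lengths(5), 2000.0)
        names = F.feature_names()[:20]
        sd_idx = [i for i, n in enumerate(names) if n.startswith("sd_")]
        assert np.allclose(out[sd_idx], 0.0)
        assert len(out) == 20

    def test_hand_built_three_cycle_arithmetic(self):
        # cycle lengths 1.0 s / 1.2 s; intervals in samples at fs=1000
        fs = 1000.0
        ivs = [
            ("S1", 0, 100), ("systole", 100, 400), ("S2", 400, 500), ("diastole", 500, 1000),
            ("S1", 1000, 1120), ("systole", 1120, 1480), ("S2", 1480, 1600), ("diastole", 1600, 2200),
            ("S1", 2200, 2300), ("systole", 2300, 2600), ("S2", 2600, 2700), ("diastole", 2700, 3200),
        ]
        out = F.time_interval_features(StateSegmentation(ivs), fs)
        named = dict(zip(F.feature_names()[:20], out))
        # RR intervals: 1.0 and 1.2 s
        assert named["m_RR"] == pytest.approx(1.1)
        assert named["sd_RR"] == pytest.approx(np.std([1.0, 1.2], ddof=1))
        assert named["m_IntS1"] == pytest.approx(np.mean([0.1, 0.12, 0.1]))
        # per-beat systole/RR: 0.3/1.0 and 0.36/1.2 = 0.3 both
        assert named["m_Ratio_SysRR"] == pytest.approx(0.3)
        assert named["sd_Ratio_SysRR"] == pytest.approx(0.0)
        assert named["m_Ratio_SysDia"] == pytest.approx(np.mean([0.6, 0.6, 0.6]))

    def test_single_cycle_all_missing(self):
        out = F.time_interval_features(seg_from_lengths(1), 2000.0)
        assert np.all(np.isnan(out))


# ---------------------------------------------------------------------------
# per-state spectra
# ---------------------------------------------------------------------------


class TestStateSpectrum:
    def test_pure_tone_peaks_at_grid_point(self, rng):
        fs = 2000.0
        t = np.arange(40000) / fs
        x = np.sin(2 * np.pi * 100.0 * t)
        rec = PcgRecording("tone", x, fs)
        seg = seg_from_lengths(10, lens=(400, 400, 400, 400))
        out = F.state_spectrum_features(rec, cycles(seg, rec)).reshape(4, 77)
        for row in out:  # every state slice is the same tone
            assert F.STATE_GRID[int(np.argmax(row))] == 100.0

    def test_zero_state_gives_zeros(self, rng):
        fs = 2000.0
        x = rng.standard_normal(4000)
        seg = seg_from_lengths(2, lens=(100, 400, 100, 400))
        for _, a, b in seg.intervals[::4]:  # zero out every S1
            x[a:b] = 0.0
        rec = PcgRecording("z", x, fs)
        out = F.state_spectrum_features(rec, cycles(seg, rec)).reshape(4, 77)
        assert np.allclose(out[0], 0.0)
        assert not np.allclose(out[1], 0.0)

    def test_count_is_308(self, clean_rec, clean_synth):
        out = F.state_spectrum_features(clean_rec, cycles(clean_synth.truth_segmentation, clean_rec))
        assert len(out) == 308


# ---------------------------------------------------------------------------
# amplitude
# ---------------------------------------------------------------------------


class TestAmplitude:
    def test_identical_s1_s2_envelopes_give_unit_ratio(self):
        burst = np.hanning(60)
        quiet = np.full(200, 1e-3)
        cyc = [CardiacCycle(burst, quiet, burst, quiet) for _ in range(5)]
        out = dict(zip(F.feature_names()[328:340], F.amplitude_features(cyc)))
        assert out["m_Amp_S1S2"] == pytest.approx(1.0, abs=0.05)

    def test_two_cycle_hand_arithmetic(self):
        # constant-amplitude states: |s1|=4, |sys|=1, |s2|=2, |dia|=0.5 then doubled
        def cyc(scale):
            return CardiacCycle(
                np.full(4, 4.0 * scale), np.full(4, 1.0 * scale),
                np.full(4, 2.0 * scale), np.full(4, 0.5 * scale),
            )
        out = dict(zip(F.feature_names()[328:340], F.amplitude_features([cyc(1), cyc(2)])))
        assert out["m_Amp_SysS1"] == pytest.approx(0.25)
        assert out["sd_Amp_SysS1"] == pytest.approx(0.0)
        assert out["m_Amp_DiaS2"] == pytest.approx(0.25)
        assert out["m_Amp_S1S2"] == pytest.approx(2.0)
        assert out["m_Amp_S1Dia"] == pytest.approx(8.0)
        assert out["m_Amp_SysDia"] == pytest.approx(2.0)
        assert out["m_Amp_S2Sys"] == pytest.approx(2.0)

    def test_count_is_12(self, clean_rec, clean_synth):
        assert len(F.amplitude_features(cycles(clean_synth.truth_segmentation, clean_rec))) == 12


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def brute_force_band_energy(x, fs, lo, hi, order=5):
    """Biquad-cascade difference-equation oracle, independent of sosfilt.

    (A single direct-form transfer function would be ill-conditioned for
    the narrow near-Nyquist bands; the cascade is the numerically faithful
    statement of the same filter.)
    """
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = np.asarray(x, dtype=np.float64).copy()
    for b0, b1, b2, _a0, a1, a2 in sos:
        out = np.zeros_like(y)
        for n in range(len(y)):
            acc = b0 * y[n]
            if n >= 1:
                acc += b1 * y[n - 1] - a1 * out[n - 1]
            if n >= 2:
                acc += b2 * y[n - 2] - a2 * out[n - 2]
            out[n] = acc
        y = out
    return np.sum(y**2) / np.sum(x**2)


class TestBandEnergy:
    def test_pure_tone_lands_in_its_band(self):
        fs = 2000.0
        t = np.arange(8000) / fs
        rec = PcgRecording("t55", np.sin(2 * np.pi * 55.0 * t), fs)
        out = F.band_energy_features(rec)
        assert out[1] >= 0.9  # band [40, 70]
        non_adjacent = np.r_[out[3:]]
        assert np.all(non_adjacent < 0.05)

    def test_ratios_bounded(self, clean_rec):
        out = F.band_energy_features(clean_rec)
        assert np.all(out >= 0.0) and np.all(out <= 1.01)
        assert len(out) == 27

    def test_matches_difference_equation_oracle(self, rng):
        fs = 2000.0
        x = rng.standard_normal(64)
        rec = PcgRecording("r", x, fs)
        out = F.band_energy_features(rec)
        for i in (0, 13, 26):
            lo, hi = F.BAND_SPEC[i]
            assert out[i] == pytest.approx(brute_force_band_energy(x, fs, lo, hi), abs=1e-9)

    def test_zero_record_errors(self):
        with pytest.raises(ValueError, match="zero energy"):
            F.band_energy_features(PcgRecording("z", np.zeros(100), 2000))


class TestStateEnergy:
    def test_state_to_cycle_ratios_partition(self, clean_rec, clean_synth):
        ccs = cycles(clean_synth.truth_segmentation, clean_rec)
        for c in ccs:
            total = np.sum(c.cycle**2)
            parts = sum(np.sum(c.slice_of(s) ** 2) for s in ("S1", "systole", "S2", "diastole"))
            assert parts == pytest.approx(total, rel=1e-12)
        out = F.state_energy_features(ccs)
        named = dict(zip([n for n in F.feature_names() if "state_energy" in n], out))
        mean_sum = (
            named["m_Ratio_state_energy_S1_cycle"]
            + named["m_Ratio_state_energy_S2_cycle"]
            + named["m_Ratio_state_energy_sys_cycle"]
            + named["m_Ratio_state_energy_dia_cycle"]
        )
        assert mean_sum == pytest.approx(1.0, abs=1e-9)

    def test_printed_toy_cycle_hand_arithmetic(self):
        # 8-sample cycle, 2 samples per state: energies 8, 2, 18, 0.5
        c = CardiacCycle(
            np.array([2.0, 2.0]), np.array([1.0, 1.0]),
            np.array([3.0, 3.0]), np.array([0.5, 0.5]),
        )
        out = dict(
            zip([n for n in F.feature_names() if "state_energy" in n], F.state_energy_features([c, c]))
        )
        total = 8 + 2 + 18 + 0.5
        assert out["m_Ratio_state_energy_S1_cycle"] == pytest.approx(8 / total)
        assert out["m_Ratio_state_energy_S2_cycle"] == pytest.approx(18 / total)
        assert out["m_Ratio_state_energy_sys_cycle"] == pytest.approx(2 / total)
        assert out["m_Ratio_state_energy_dia_cycle"] == pytest.approx(0.5 / total)
        assert out["m_Ratio_state_energy_S1_S2"] == pytest.approx(8 / 18)
        assert out["m_Ratio_state_energy_S1_sys"] == pytest.approx(4.0)
        assert out["m_Ratio_state_energy_S1_dia"] == pytest.approx(16.0)
        assert out["m_Ratio_state_energy_S2_sys"] == pytest.approx(9.0)
        assert out["m_Ratio_state_energy_S2_dia"] == pytest.approx(36.0)
        assert out["m_Ratio_state_energy_dia_sys"] == pytest.approx(0.25)
        assert out["sd_Ratio_state_energy_S1_cycle"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# record spectrum
# ---------------------------------------------------------------------------


class TestRecordSpectrum:
    def test_ratios_sum_to_one(self, clean_rec):
        out = F.record_spectrum_features(clean_rec)
        assert len(out) == 27
        assert np.sum(out) == pytest.approx(1.0, abs=1e-9)

    def test_tone_mass_in_owning_band(self):
        fs = 2000.0
        t = np.arange(2000) / fs  # 1 Hz bins: 100 Hz hits a bin exactly
        rec = PcgRecording("t", np.sin(2 * np.pi * 100.0 * t), fs)
        out = F.record_spectrum_features(rec)
        # half-open bands: 100 Hz belongs to [100, 130)
        assert out[3] > 0.9


# ---------------------------------------------------------------------------
# cepstrum
# ---------------------------------------------------------------------------


def brute_force_cepstrum(x, n_coeffs=13):
    n = len(x)
    dft = np.array([np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in range(n)])
    logmag = np.log(np.maximum(np.abs(dft), 1e-12 * np.max(np.abs(dft))))
    idft = np.array([np.mean(logmag * np.exp(2j * np.pi * k * np.arange(n) / n)) for k in range(n)])
    return np.real(idft[:n_coeffs])


class TestCepstrum:
    def test_unit_impulse_gives_zeros(self):
        x = np.zeros(64)
        x[0] = 1.0  # white spectrum: log|P| = 0 everywhere
        assert np.allclose(F.cepstrum(x), 0.0, atol=1e-9)

    def test_matches_brute_force_dft_oracle(self, rng):
        x = rng.standard_normal(64)
        np.testing.assert_allclose(F.cepstrum(x), brute_force_cepstrum(x), atol=1e-9)

    def test_coefficient_zero_is_mean_log_magnitude(self, rng):
        x = rng.standard_normal(50)
        expected = np.mean(np.log(np.abs(np.fft.fft(x))))
        assert F.cepstrum(x)[0] == pytest.approx(expected, abs=1e-9)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            F.cepstrum(np.ones(10))

    def test_joined_single_cycle_matches_slice(self, rng):
        fs = 2000.0
        x = rng.standard_normal(670)
        seg = StateSegmentation(
            [("S1", 0, 100), ("systole", 100, 300), ("S2", 300, 400), ("diastole", 400, 670)]
        )
        rec = PcgRecording("one", x, fs)
        out = F.cepstrum_features(rec, seg).reshape(5, 13)
        np.testing.assert_allclose(out[1], F.cepstrum(x[0:100]), atol=1e-12)
        np.testing.assert_allclose(out[4], F.cepstrum(x[400:670]), atol=1e-12)

    def test_joined_states_match_explicit_concatenation(self, clean_rec, clean_synth):
        seg = clean_synth.truth_segmentation
        joined_sys = np.concatenate(
            [clean_rec.samples[a:b] for s, a, b in seg.intervals if s == "systole"]
        )
        out = F.cepstrum_features(clean_rec, seg).reshape(5, 13)
        np.testing.assert_allclose(out[2], F.cepstrum(joined_sys), atol=1e-12)


# ---------------------------------------------------------------------------
# cyclostationarity
# ---------------------------------------------------------------------------


class TestCyclostationarity:
    def test_flat_density_has_unit_sharpness(self):
        alphas = np.linspace(0.1, 10, 100)
        gamma = np.full(100, 3.3)
        d_eta, sharp = F._cyclo_indicators(alphas, gamma)
        assert sharp == pytest.approx(1.0)

    def test_periodic_beats_white_noise(self, rng):
        wins = 0
        for seed in range(10):
            sr = generate_recording(SynthConfig(seed=seed, duration=9.0))
            periodic = F.cyclostationarity_features(sr.recording)
            noise = PcgRecording(
                "n", np.random.default_rng(seed).standard_normal(18000), 2000
            )
            noisy = F.cyclostationarity_features(noise)
            wins += periodic[0] > noisy[0]  # mean degree of cyclostationarity
        assert wins == 10

    def test_count_and_sd_missing_for_single_subsequence(self):
        sr = generate_recording(SynthConfig(seed=1, duration=4.0))
        out = F.cyclostationarity_features(sr.recording)  # one 3 s subsequence
        assert len(out) == 4
        assert np.isfinite(out[0]) and np.isnan(out[1]) and np.isnan(out[3])


# ---------------------------------------------------------------------------
# higher-order statistics
# ---------------------------------------------------------------------------


def moment_skew_kurt(x):
    mu = np.mean(x)
    m2 = np.mean((x - mu) ** 2)
    return np.mean((x - mu) ** 3) / m2**1.5, np.mean((x - mu) ** 4) / m2**2


class TestHos:
    def test_symmetric_slice_zero_skewness(self):
        sym = np.concatenate([np.arange(10.0), -np.arange(10.0)])
        c = CardiacCycle(sym, sym, sym, sym)
        out = F.hos_features([c, c])
        named = dict(zip(F.feature_names()[499 - 16 : 499], out))
        assert named["m_S1_skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_kurtosis_near_three(self, rng):
        g = rng.standard_normal(10_000)
        c = CardiacCycle(g, g, g, g)
        out = F.hos_features([c, c])
        named = dict(zip(F.feature_names()[499 - 16 : 499], out))
        assert abs(named["m_S1_kurtosis"] - 3.0) < 0.2

    def test_matches_moment_oracle(self, rng):
        x = rng.standard_normal(64)
        c = CardiacCycle(x, x, x, x)
        out = F.hos_features([c, c])
        named = dict(zip(F.feature_names()[499 - 16 : 499], out))
        sk, ku = moment_skew_kurt(x)
        assert named["m_sys_skewness"] == pytest.approx(sk, abs=1e-9)
        assert named["m_dia_kurtosis"] == pytest.approx(ku, abs=1e-9)
        assert len(out) == 16


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------


def brute_force_sampen(x, m, r):
    n_t = len(x) - m
    def pairs(length):
        c = 0
        for i in range(n_t):
            for j in range(i + 1, n_t):
                if np.max(np.abs(x[i : i + length] - x[j : j + length])) <= r:
                    c += 1
        return c
    b, a = pairs(m), pairs(m + 1)
    return -np.log(a / b)


class TestEntropy:
    def test_constant_sequence_zero(self):
        assert F.sample_entropy(np.ones(50), m=2, r=0.1) == 0.0

    def test_matches_brute_force(self, rng):
        # a random walk is smooth enough that length-3 template matches exist
        x = np.cumsum(rng.standard_normal(50))
        r = 0.2 * np.std(x)
        assert F.sample_entropy(x, 2, r) == pytest.approx(brute_force_sampen(x, 2, r), abs=1e-9)

    def test_noise_exceeds_sinusoid(self):
        wins = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            noise = g.standard_normal(300)
            t = np.arange(300)
            sine = np.sin(2 * np.pi * 5 * t / 300)
            sine = sine / np.std(sine)
            wins += F.sample_entropy(noise, 2) > F.sample_entropy(sine, 2)
        assert wins == 10

    def test_fuzzy_reference_implementation(self, rng):
        x = rng.standard_normal(40)
        r = 0.2 * np.std(x)
        n_t = len(x) - 2

        def phi(length, local):
            xg = x - np.mean(x)
            seg = np.array([xg[i : i + length] for i in range(n_t)])
            if local:
                seg = seg - seg.mean(axis=1, keepdims=True)
            tot = 0.0
            for i in range(n_t):
                for j in range(n_t):
                    if i != j:
                        tot += np.exp(-((np.max(np.abs(seg[i] - seg[j])) / r) ** 2))
            return tot / (n_t * (n_t - 1))

        expected = np.log(phi(2, True) / phi(3, True)) + np.log(phi(2, False) / phi(3, False))
        assert F.fuzzy_measure_entropy(x, 2, r, r) == pytest.approx(expected, abs=1e-9)

    def test_identical_cycles_zero_sd(self, rng):
        x = rng.standard_normal(120)
        c = CardiacCycle(x, x, x, x)
        out = F.entropy_features([c, c, c], sampling_rate=1000.0)
        named = dict(zip(F.feature_names()[-16:], out))
        for name, v in named.items():
            if name.startswith("sd_"):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_murmur_raises_systolic_sample_entropy(self):
        wins = 0
        for seed in range(10):
            normal = generate_recording(SynthConfig(seed=seed, duration=6.0))
            murmur = generate_recording(SynthConfig(seed=seed, duration=6.0, murmur="systolic"))
            vals = []
            for sr in (normal, murmur):
                rec = preprocess(sr.recording)
                ccs = cycles(sr.truth_segmentation, rec)
                out = F.entropy_features(ccs, 2000.0)
                named = dict(zip(F.feature_names()[-16:], out))
                vals.append(named["m_SampEn_sys"])
            wins += vals[1] > vals[0]
        assert wins >= 9


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


class TestExtractAll:
    def test_length_and_domain_sublengths(self, clean_rec, clean_synth):
        fv = extract_all(clean_rec, clean_synth.truth_segmentation)
        assert len(fv) == 515
        counts = {d: fv.domains.count(d) for d in F.DOMAINS}
        assert [counts[d] for d in F.DOMAINS] == [20, 308, 12, 47, 27, 65, 4, 16, 16]

    def test_deterministic(self, clean_rec, clean_synth):
        a = extract_all(clean_rec, clean_synth.truth_segmentation)
        b = extract_all(clean_rec, clean_synth.truth_segmentation)
        np.testing.assert_array_equal(a.values, b.values)

    def test_ratio_features_scale_invariant(self, clean_rec, clean_synth):
        fv1 = extract_all(clean_rec, clean_synth.truth_segmentation)
        fv2 = extract_all(clean_rec.with_samples(5.0 * clean_rec.samples), clean_synth.truth_segmentation)
        for dom in ("amplitude", "energy", "freq_record", "time_interval"):
            idx = [i for i, d in enumerate(fv1.domains) if d == dom]
            np.testing.assert_allclose(fv1.values[idx], fv2.values[idx], rtol=1e-9)
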