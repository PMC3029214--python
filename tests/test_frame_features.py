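import numpy as np
import pytest
from scipy import signal as sps

from voicelevel.audio_io import Waveform, frame_signal
from voicelevel.frame_features import (
    NASALITY_EPS_DB,
    NasalityComponents,
    approximate_entropy,
    estimate_f0,
    estimate_formants,
    extract_frame_features,
    nasality_score,
    relative_intensity,
)


def hamming_frame(x):
    return x * np.hamming(x.size)


def resonator_chain(excitation, fs, formants):
    x = excitation
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / fs)
        theta = 2 * np.pi * fc / fs
        x = sps.lfilter([1 - r], [1, -2 * r * np.cos(theta), r * r], x)
    return x


def glottal_train(fs, f0, n, tilt=True):
    src = np.zeros(n)
    src[:: int(round(fs / f0))] = 1.0
    if tilt:
        src = sps.lfilter([1], [1, -0.98], src)
    return src


class TestF0:
    def test_pure_sine_recovered_within_1hz(self):
        fs = 44100
        x = np.sin(2 * np.pi * 200 * np.arange(1102) / fs)
        assert estimate_f0(hamming_frame(x), fs) == pytest.approx(200.0, abs=1.0)

    def test_white_noise_is_unvoiced(self, rng):
        assert estimate_f0(hamming_frame(rng.standard_normal(1102)), 44100) == 0.0

    def test_glottal_pulse_train_within_2hz(self):
        fs = 44100
        # 250 Hz needs a non-integer period; use the full-utterance frames
        src = glottal_train(fs, 252.0, 4 * 1102)
        x = resonator_chain(src, fs, [(700, 130), (1220, 70)])
        fm = frame_signal(Waveform(x / np.abs(x).max(), fs))
        f0s = [estimate_f0(fm.frames[t], fs) for t in range(2, fm.n_frames)]
        f0_target = fs / int(round(fs / 252.0))
        assert np.median(f0s) == pytest.approx(f0_target, abs=2.0)

    def test_scale_invariance(self, rng):
        fs = 44100
        x = hamming_frame(np.sin(2 * np.pi * 180 * np.arange(1102) / fs))
        # power-of-two scaling is exact in binary floating point
        assert estimate_f0(4.0 * x, fs) == estimate_f0(x, fs)
        assert estimate_f0(3.7 * x, fs) == pytest.approx(estimate_f0(x, fs), rel=1e-6)

    def test_bad_range_raises(self):
        with pytest.raises(ValueError):
            estimate_f0(np.zeros(100), 44100, fmin=500, fmax=100)


class TestFormants:
    def test_three_resonators_within_5pct(self):
        fs = 44100
        targets = [(700, 130), (1220, 70), (2600, 160)]
        x = resonator_chain(glottal_train(fs, 150.0, fs), fs, targets)
        fm = frame_signal(Waveform(x, fs))
        ests = np.array([estimate_formants(fm.frames[t], fs) for t in range(30, 70)])
        med = np.nanmedian(ests, axis=0)
        for est, (fc, _) in zip(med, targets):
            assert abs(est - fc) / fc < 0.05

    def test_all_zero_frame_returns_nan(self):
        f1, f2, f3 = estimate_formants(np.zeros(1102), 44100)
        assert np.isnan(f1) and np.isnan(f2) and np.isnan(f3)

    def test_single_resonator_gives_f1_only_candidates(self):
        # 130 Hz excitation: harmonics straddle the pole, avoiding the
        # harmonic-snapping bias LPC shows on sparse spectra
        fs = 44100
        x = resonator_chain(glottal_train(fs, 130.0, fs), fs, [(500, 100)])
        fm = frame_signal(Waveform(x, fs))
        ests = np.array([estimate_formants(fm.frames[t], fs) for t in range(30, 60)])
        f1 = np.nanmedian(ests[:, 0])
        assert abs(f1 - 500) / 500 < 0.05

    def test_ordering_when_defined(self):
        fs = 44100
        x = resonator_chain(glottal_train(fs, 150.0, fs), fs, [(700, 130), (1220, 70), (2600, 160)])
        fm = frame_signal(Waveform(x, fs))
        for t in range(30, 50):
            f1, f2, f3 = estimate_formants(fm.frames[t], fs)
            defined = [f for f in (f1, f2, f3) if np.isfinite(f)]
            assert defined == sorted(defined)


class TestRelativeIntensity:
    def test_loudest_frame_is_one_and_ratios(self):
        frames = np.vstack([np.full(100, 0.5), np.full(100, 1.0)])
        ri = relative_intensity(frames)
        assert ri[1] == 1.0
        assert ri[0] == pytest.approx(0.5)

    def test_constant_tone_all_near_one(self):
        fs = 16000
        x = np.sin(2 * np.pi * 220 * np.arange(fs) / fs)
        ri = relative_intensity(frame_signal(Waveform(x, fs)))
        assert ri.min() > 0.99

    def test_all_zero_word_raises(self):
        with pytest.raises(ValueError):
            relative_intensity(np.zeros((5, 100)))


class TestNasality:
    def test_reciprocal_arithmetic(self):
        comp = NasalityComponents(amp_f1_db=60.0, amp_1k_db=50.0)
        assert comp.diff_db == pytest.approx(10.0)
        assert comp.score == pytest.approx(0.1)

    def test_equal_amplitudes_capped(self):
        comp = NasalityComponents(amp_f1_db=55.0, amp_1k_db=55.0)
        assert comp.score == pytest.approx(1.0 / NASALITY_EPS_DB)

    def test_added_1khz_resonance_shrinks_gap(self):
        fs = 44100
        src = glottal_train(fs, 150.0, fs)
        plain = resonator_chain(src, fs, [(600, 110), (1400, 90)])
        nasal = plain + 0.8 * resonator_chain(src, fs, [(1000, 100)])
        gaps = []
        for sig in (plain, nasal):
            fm = frame_signal(Waveform(sig / np.abs(sig).max(), fs))
            ds = [nasality_score(fm.frames[t], fs, 600.0).diff_db for t in range(30, 60)]
            gaps.append(np.median(ds))
        assert gaps[1] < gaps[0]

    def test_undefined_f1_raises(self):
        with pytest.raises(ValueError):
            nasality_score(np.ones(1102), 44100, float("nan"))


def brute_force_apen(x, m=2, r=0.2):
    """O(n^2) reference implementation straight from the definition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = x.std()
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(mm):
        nmm = n - mm + 1
        total = 0.0
        for i in range(nmm):
            count = 0
            for j in range(nmm):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                    count += 1
            total += np.log(count / nmm)
        return total / nmm

    return phi(m) - phi(m + 1)


class TestApproximateEntropy:
    def test_constant_sequence_is_zero(self):
        assert approximate_entropy(np.full(100, 3.3)) == 0.0

    @pytest.mark.parametrize("maker", [
        lambda rng: np.tile([1.0, -1.0], 50),
        lambda rng: rng.standard_normal(100),
        lambda rng: np.sin(np.arange(150) * 0.3) + 0.1 * rng.standard_normal(150),
        lambda rng: rng.standard_normal(200),
    ])
    def test_matches_brute_force_oracle(self, maker, rng):
        x = maker(rng)
        assert approximate_entropy(x) == pytest.approx(brute_force_apen(x), abs=1e-10)

    def test_noise_more_entropic_than_sine(self, rng):
        sine = np.sin(2 * np.pi * 5 * np.linspace(0, 1, 1000))
        for _ in range(3):
            noise = rng.uniform(-1, 1, 1000)
            assert approximate_entropy(noise) > approximate_entropy(sine)

    def test_zero_tolerance_raises(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.ones(50), r=0.0)


class TestExtractFrameFeatures:
    def test_complete_vectors_on_synthetic_word(self, mini_corpus):
        records, _ = mini_corpus
        df = extract_frame_features(records[0].waveform)
        assert list(df.columns) == [
            "f0", "f1", "f2", "f3", "f1f2_ratio", "ri", "nasality", "apen",
        ]
        assert np.isfinite(df.to_numpy()).all()
        assert df["ri"].max() == pytest.approx(1.0)
        voiced = df[df.f0 > 0]
        assert (voiced.f1 < voiced.f2).all()
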