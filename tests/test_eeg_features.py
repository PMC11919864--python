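"""EEG feature families against independent brute-force oracles."""

import numpy as np
import pytest

from emophys.features.eeg import (
    EEG_SELECTED_FAMILIES,
    EEGFeatureSpec,
    band_psd,
    default_dfa_scales,
    dfa_alpha,
    dfa_fluctuations,
    eeg_feature_vector,
    sample_entropy,
    time_stats,
)
from emophys.io import Recording
from emophys.preprocess import segment_recording


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m, r):
    """Exhaustive O(n^2) template counting, written against the definition."""
    n = len(x)
    def count(length):
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + d] - x[j + d]) for d in range(length)) < r:
                    total += 1
        return total
    b = count(m)
    a = count(m + 1)
    return -np.log(a / b), a, b


def dfa_bruteforce(x, scales):
    """Step-by-step DFA with explicit per-window polyfit."""
    y = np.cumsum(x - np.mean(x))
    out = []
    for n in scales:
        residuals = []
        for w in range(len(y) // n):
            seg = y[w * n:(w + 1) * n]
            t = np.arange(n)
            coef = np.polyfit(t, seg, 1)
            residuals.extend(seg - np.polyval(coef, t))
        out.append(np.sqrt(np.mean(np.array(residuals) ** 2)))
    return np.array(out)


# ---------------------------------------------------------------------------
# time-domain statistics
# ---------------------------------------------------------------------------

class TestTimeStats:
    def test_constant_signal(self):
        s = time_stats(np.full(16, 3.25))
        assert s["mean"] == 3.25 and s["variance"] == 0.0 and s["ptp"] == 0.0

    def test_sine_symmetry_zero_skew(self):
        t = np.arange(1280) / 128
        s = time_stats(np.sin(2 * np.pi * 4 * t))  # whole periods
        assert abs(s["skewness"]) < 1e-6

    def test_fixed_vector_matches_moment_formulas(self, rng):
        x = rng.standard_normal(16)
        s = time_stats(x)
        mu = x.sum() / 16
        var = ((x - mu) ** 2).sum() / 16
        m3 = ((x - mu) ** 3).sum() / 16
        m4 = ((x - mu) ** 4).sum() / 16
        assert s["max"] == x.max() and s["min"] == x.min()
        np.testing.assert_allclose(s["mean"], mu, rtol=1e-12)
        np.testing.assert_allclose(s["variance"], var, rtol=1e-12)
        np.testing.assert_allclose(s["ptp"], x.max() - x.min(), rtol=1e-12)
        np.testing.assert_allclose(s["skewness"], m3 / var**1.5, rtol=1e-12)
        np.testing.assert_allclose(s["kurtosis"], m4 / var**2 - 3, rtol=1e-12)

    @pytest.mark.parametrize("a", [2.0, 0.5, 10.0])
    def test_scale_equivariance(self, rng, a):
        x = rng.standard_normal(256)
        s1, s2 = time_stats(x), time_stats(a * x)
        np.testing.assert_allclose(s2["mean"], a * s1["mean"], rtol=1e-9)
        np.testing.assert_allclose(s2["variance"], a**2 * s1["variance"], rtol=1e-9)
        np.testing.assert_allclose(s2["kurtosis"], s1["kurtosis"], rtol=1e-9)
        np.testing.assert_allclose(s2["skewness"], s1["skewness"], rtol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            time_stats(np.array([1.0, np.nan, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# band power
# ---------------------------------------------------------------------------

class TestBandPSD:
    def test_alpha_tone_dominates(self):
        rate = 128.0
        t = np.arange(int(30 * rate)) / rate
        powers = band_psd(np.sin(2 * np.pi * 10 * t), rate)
        total = sum(powers.values())
        assert powers["alpha_psd"] >= 0.95 * total

    def test_zero_signal_zero_power(self):
        powers = band_psd(np.zeros(3840), 128.0)
        assert all(v == 0.0 for v in powers.values())

    def test_white_noise_parseval(self, rng):
        # total band power over 0.5-45 Hz tracks the bandpassed variance
        import scipy.signal as sps
        rate = 128.0
        x = rng.standard_normal(int(120 * rate))
        powers = band_psd(x, rate)
        sos = sps.butter(8, [0.5, 45], btype="bandpass", fs=rate, output="sos")
        var_bp = np.var(sps.sosfiltfilt(sos, x))
        assert abs(sum(powers.values()) - var_bp) / var_bp < 0.10

    def test_additivity_over_adjacent_bands(self, rng):
        # band edges on the Welch grid: power is exactly additive
        rate = 128.0
        x = rng.standard_normal(int(30 * rate))
        split = EEGFeatureSpec(bands={"lo": (8.0, 10.0), "hi": (10.0, 13.0)})
        union = EEGFeatureSpec(bands={"all": (8.0, 13.0)})
        p_split = band_psd(x, rate, split)
        p_union = band_psd(x, rate, union)
        np.testing.assert_allclose(
            p_split["lo_psd"] + p_split["hi_psd"], p_union["all_psd"], rtol=1e-9
        )

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_psd(np.zeros(1000), 128.0, EEGFeatureSpec(bands={"x": (50.0, 70.0)}))


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.full(50, 2.0)) == 0.0

    def test_matches_bruteforce_counting(self):
        rng = np.random.default_rng(1)
        x = np.sin(np.arange(30) * 0.4) + 0.2 * rng.standard_normal(30)
        r = 0.3 * np.std(x)
        expected, a, b = sampen_bruteforce(x, 2, r)
        assert a > 0 and b > 0, "oracle fixture must have matches"
        np.testing.assert_allclose(sample_entropy(x, 2, 0.3), expected, rtol=1e-9)

    @pytest.mark.parametrize("n", [40, 50])
    def test_bruteforce_agreement_various_lengths(self, n):
        rng = np.random.default_rng(n)
        x = np.sin(np.arange(n) * 0.5) + 0.3 * rng.standard_normal(n)
        r = 0.25 * np.std(x)
        expected, a, b = sampen_bruteforce(x, 2, r)
        if a and b:
            np.testing.assert_allclose(sample_entropy(x, 2, 0.25), expected, rtol=1e-9)

    def test_noise_more_irregular_than_sine(self, rng):
        n = 512
        noise = rng.standard_normal(n)
        t = np.arange(n)
        sine = np.sin(2 * np.pi * t / 32)
        sine *= np.std(noise) / np.std(sine)
        assert sample_entropy(noise) > sample_entropy(sine)

    @pytest.mark.parametrize("scale,offset", [(2.0, 0.0), (0.5, 0.0), (4.0, 100.0)])
    def test_affine_invariance(self, rng, scale, offset):
        x = rng.standard_normal(200)
        np.testing.assert_allclose(
            sample_entropy(scale * x + offset), sample_entropy(x), rtol=1e-9
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.zeros(3), m=2)


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

class TestDFA:
    def test_white_noise_alpha_half(self):
        x = np.random.default_rng(7).standard_normal(4096)
        assert abs(dfa_alpha(x) - 0.5) <= 0.1

    def test_brownian_alpha_three_halves(self):
        x = np.cumsum(np.random.default_rng(7).standard_normal(4096))
        assert abs(dfa_alpha(x) - 1.5) <= 0.1

    def test_fluctuations_match_bruteforce(self, rng):
        x = rng.standard_normal(64)
        scales = np.array([4, 8, 16])
        np.testing.assert_allclose(
            dfa_fluctuations(x, scales), dfa_bruteforce(x, scales), rtol=1e-9
        )

    def test_default_scales_span(self):
        scales = default_dfa_scales(3840)
        assert scales.min() >= 4 and scales.max() <= 960 and len(scales) >= 4

    def test_too_few_scales_rejected(self, rng):
        with pytest.raises(ValueError):
            dfa_alpha(rng.standard_normal(100), scales=np.array([4, 8]))


# ---------------------------------------------------------------------------
# per-segment feature vector
# ---------------------------------------------------------------------------

class TestFeatureVector:
    def _segment(self, rng, n_channels, names=None):
        rec = Recording(
            rng.standard_normal((n_channels, 3840)), 128.0,
            names or [f"E{i}" for i in range(n_channels)], "EEG",
        )
        return segment_recording(rec)[0]

    def test_full_family_set_gives_196_features(self, rng):
        seg = self._segment(rng, 14)
        vec = eeg_feature_vector(seg)
        assert len(vec) == 14 * 14 == 196

    def test_selected_family_set_gives_56_features(self, rng):
        seg = self._segment(rng, 14)
        vec = eeg_feature_vector(seg, EEGFeatureSpec(families=EEG_SELECTED_FAMILIES))
        assert len(vec) == 4 * 14 == 56

    def test_single_channel_names(self, rng):
        seg = self._segment(rng, 1, names=["AF3"])
        vec = eeg_feature_vector(seg)
        assert all(name.startswith("AF3.") for name in vec.index)
        assert "AF3.alpha_psd" in vec.index

    def test_channel_major_ordering(self, rng):
        seg = self._segment(rng, 2, names=["A", "B"])
        names = list(eeg_feature_vector(seg).index)
        assert names.index("A.dfa") < names.index("B.max")

    def test_rejects_ecg_segment(self, rng):
        rec = Recording(rng.standard_normal((2, 7680)), 256.0, ["1", "2"], "ECG")
        seg = segment_recording(rec)[0]
        with pytest.raises(ValueError, match="EEG"):
            eeg_feature_vector(seg)
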