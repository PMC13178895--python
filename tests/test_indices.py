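"""Acoustic indices: gini, ACT, AEI, Hf, Sm and the threshold scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nightchorus.audio import AudioClip, Spectrogram, SpectrogramParams, compute_spectrogram
from nightchorus.indices import (
    bin_snr_spread,
    compute_act,
    compute_aei,
    compute_hf,
    compute_index_table,
    compute_sm,
    gini,
    scan_sm_threshold,
    sm_threshold_grid,
)
from tests.conftest import SR, noise_clip, tone_clip


def brute_gini(x):
    x = np.asarray(x, float)
    n = len(x)
    if x.sum() == 0:
        return 0.0
    return sum(abs(a - b) for a in x for b in x) / (2 * n * n * x.mean())


def synthetic_spectrogram(db: np.ndarray, sr: int = SR, wl: int = 484):
    """Build a Spectrogram directly from a dB matrix (full-scale ref)."""
    mag = 10.0 ** (db / 20.0)
    n_bins = db.shape[0]
    return Spectrogram(linear_magnitude=mag, db=db,
                       freq_axis=np.arange(n_bins) * sr / wl,
                       time_axis=np.arange(db.shape[1]) * 48 / sr,
                       sample_rate=sr, params=SpectrogramParams())


class TestGini:
    def test_hand_example(self):
        assert gini([0.1, 0.2, 0.7]) == pytest.approx(0.4, abs=1e-12)

    def test_constant_and_one_hot(self):
        assert gini([3.0] * 7) == pytest.approx(0.0, abs=1e-12)
        for n in (2, 5, 20, 50):
            one_hot = [0.0] * (n - 1) + [1.0]
            assert gini(one_hot) == pytest.approx((n - 1) / n, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.uniform(0, 10, size=rng.integers(2, 51))
            assert gini(x) == pytest.approx(brute_gini(x), abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            gini([1.0])
        with pytest.raises(ValueError):
            gini([1.0, -0.5])

    @given(arrays(np.float64, st.integers(2, 30),
                  elements=st.floats(0, 100)))
    @settings(max_examples=100, deadline=None)
    def test_range_invariant(self, x):
        g = gini(x)
        assert 0.0 <= g < 1.0


class TestACT:
    def test_constant_amplitude_sine_is_zero(self):
        assert compute_act(tone_clip(3000.0, duration=0.5)) == 0.0

    def test_burst_fraction_recovered(self):
        # bursts 20 dB above floor occupying 10 % of blocks -> ACT ~ 0.1
        rng = np.random.default_rng(0)
        n_blocks, w = 1000, 200
        amp = np.full(n_blocks, 0.001)
        burst_at = rng.choice(n_blocks, size=100, replace=False)
        amp[burst_at] = 0.01
        samples = np.repeat(amp, w) * np.sign(rng.standard_normal(n_blocks * w))
        act = compute_act(AudioClip(samples))
        assert 0.08 <= act <= 0.12

    def test_amplitude_scale_invariance(self):
        clip = noise_clip(duration=0.5, rms=0.01, seed=9)
        scaled = AudioClip(clip.samples * 10.0)
        assert compute_act(clip) == pytest.approx(compute_act(scaled), abs=1e-12)

    def test_all_zero_clip_is_zero(self):
        assert compute_act(AudioClip(np.zeros(SR // 2))) == 0.0


class TestAEI:
    def test_equal_band_occupancy_gives_zero(self):
        db = np.full((242, 50), -30.0)  # every cell above -45 in every band
        assert compute_aei(synthetic_spectrogram(db)) == pytest.approx(0.0)

    def test_one_hot_band_gives_closed_form(self):
        db = np.full((242, 50), -80.0)
        freqs = np.arange(242) * SR / 484
        band3 = (freqs >= 3000) & (freqs < 4000)
        db[band3, :] = -20.0
        assert compute_aei(synthetic_spectrogram(db)) == pytest.approx(0.95, abs=1e-9)

    def test_all_below_threshold_gives_zero(self):
        db = np.full((242, 50), -80.0)
        assert compute_aei(synthetic_spectrogram(db)) == 0.0

    def test_not_scale_invariant_near_threshold(self):
        # a -40 dBFS scene drops below the -45 dBFS threshold under -20 dB gain
        clip = tone_clip(5000.0, amp=0.01)
        low = AudioClip(clip.samples * 0.1)
        aei_hi = compute_aei(compute_spectrogram(clip))
        aei_lo = compute_aei(compute_spectrogram(low))
        assert aei_hi != pytest.approx(aei_lo, abs=1e-6)

    def test_requires_full_scale_reference(self):
        clip = tone_clip(5000.0)
        spec = compute_spectrogram(clip, SpectrogramParams(reference="clip_max"))
        with pytest.raises(ValueError, match="full-scale"):
            compute_aei(spec)


class TestHf:
    def test_white_noise_near_one(self):
        spec = compute_spectrogram(noise_clip(duration=5.0, seed=1))
        assert compute_hf(spec) > 0.95

    def test_pure_tone_low(self):
        spec = compute_spectrogram(tone_clip(5000.0, duration=5.0))
        assert compute_hf(spec) < 0.5

    def test_two_tones_exceed_one_tone(self):
        t = np.arange(5 * SR) / SR
        one = AudioClip(0.4 * np.sin(2 * np.pi * 4000 * t))
        two = AudioClip(0.2 * np.sin(2 * np.pi * 4000 * t)
                        + 0.2 * np.sin(2 * np.pi * 9000 * t))
        assert (compute_hf(compute_spectrogram(two))
                > compute_hf(compute_spectrogram(one)))

    def test_silent_clip_rejected(self):
        spec = compute_spectrogram(AudioClip(np.zeros(SR)))
        with pytest.raises(ValueError, match="silent"):
            compute_hf(spec)


def intermittent_tone_clip(freq=6000.0, duration=5.0, amp=0.05,
                           noise_rms=0.005, seed=0):
    """Tone gated on/off at 1 s periods (smooth edges) over noise.

    The gate uses 50 ms raised-cosine ramps so the on/off transitions
    stay narrowband (hard edges are broadband clicks).
    """
    rng = np.random.default_rng(seed)
    n = int(duration * SR)
    t = np.arange(n) / SR
    gate = ((t % 2.0) < 1.0).astype(float)
    ramp = int(0.05 * SR)
    if ramp > 1:
        kernel = np.hanning(2 * ramp + 1)
        gate = np.convolve(gate, kernel / kernel.sum(), mode="same")
    return AudioClip(np.clip(rng.standard_normal(n) * noise_rms
                             + amp * np.sin(2 * np.pi * freq * t) * gate,
                             -1, 1))


class TestSm:
    def test_white_noise_near_zero(self):
        spec = compute_spectrogram(noise_clip(duration=10.0, seed=5))
        assert compute_sm(spec, 6.3) < 5.0

    def test_localised_tone_saturates_few_bins(self):
        # strictly local (unnormalised) SNR: an intermittent loud tone
        # saturates only its own bin(s) plus leakage
        on_bin_freq = 66 * SR / 484  # centred on a frequency bin
        spec = compute_spectrogram(intermittent_tone_clip(freq=on_bin_freq))
        sm = compute_sm(spec, 3.8, segment_duration=0.5, normalize="none")
        assert 100.0 * 1 / 242 <= sm <= 100.0 * 5 / 242 + 1e-9

    def test_monotone_in_threshold_on_random_clips(self):
        rng = np.random.default_rng(7)
        thresholds = np.linspace(3.0, 8.0, 10)
        for i in range(100):
            kind = i % 3
            if kind == 0:
                clip = noise_clip(1.0, rms=rng.uniform(0.001, 0.1), seed=i)
            elif kind == 1:
                clip = intermittent_tone_clip(freq=rng.uniform(500, 18000),
                                              duration=1.0, seed=i)
            else:
                base = noise_clip(1.0, rms=0.005, seed=i).samples
                tone = intermittent_tone_clip(freq=rng.uniform(500, 18000),
                                              duration=1.0, seed=i).samples
                clip = AudioClip(np.clip(base + tone, -1, 1))
            spec = compute_spectrogram(clip)
            sm = [compute_sm(spec, th, segment_duration=0.1) for th in thresholds]
            assert np.all(np.diff(sm) <= 1e-12)

    def test_scale_invariance(self):
        clip = intermittent_tone_clip(duration=2.0)
        spec1 = compute_spectrogram(clip)
        spec2 = compute_spectrogram(AudioClip(clip.samples * 0.1))
        s1 = compute_sm(spec1, 3.8, segment_duration=0.5)
        s2 = compute_sm(spec2, 3.8, segment_duration=0.5)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_invalid_threshold(self):
        spec = compute_spectrogram(noise_clip(1.0))
        with pytest.raises(ValueError):
            compute_sm(spec, 0.0)


class TestScan:
    def test_grid_has_51_values(self):
        assert len(sm_threshold_grid()) == 51
        assert sm_threshold_grid()[0] == 3.0
        assert sm_threshold_grid()[-1] == 8.0

    def test_constructed_saturation_is_ceiling_flagged(self):
        # all bins spread 4 dB at every site: thresholds below 4
        # saturate Sm at 100 with no site variance -> ceiling
        rows = [{"site_id": f"S{i}", "night_id": "N1",
                 "spread": np.full(242, 4.0)} for i in range(12)]
        scan = scan_sm_threshold(pd.DataFrame(rows))
        tab = scan.table
        assert tab[tab.threshold_db <= 4.0]["ceiling"].all()
        assert scan.chosen_threshold > 4.0

    def test_mean_sm_monotone_on_real_spreads(self, gradient_spreads):
        for tag in ("raw", "filtered"):
            scan = scan_sm_threshold(gradient_spreads[tag])
            assert np.all(np.diff(scan.table["mean_sm"]) <= 1e-12)

    def test_all_ceiling_raises(self):
        rows = [{"site_id": f"S{i}", "night_id": "N1",
                 "spread": np.full(242, 20.0)} for i in range(12)]
        with pytest.raises(ValueError, match="widen"):
            scan_sm_threshold(pd.DataFrame(rows))


class TestIndexTable:
    def test_row_counts_and_thresholds(self, gradient_study):
        clip_table, site_means = compute_index_table(
            gradient_study.clips, sm_thresholds={"raw": 6.3, "filtered": 3.8},
            segment_duration=0.5)
        # 12 sites x 5 nights x 2 variants
        assert len(clip_table) == 120
        assert len(site_means) == 24
        raw = clip_table[clip_table.dataset_tag == "raw"]
        filt = clip_table[clip_table.dataset_tag == "filtered"]
        assert (raw.sm_threshold_db == 6.3).all()
        assert (filt.sm_threshold_db == 3.8).all()

    def test_index_ranges(self, gradient_study):
        clip_table, _ = compute_index_table(
            gradient_study.clips[:4], segment_duration=0.5)
        for col, lo, hi in (("act", 0, 1), ("aei", 0, 1), ("hf", 0, 1),
                            ("sm", 0, 100)):
            assert clip_table[col].between(lo, hi).all()

    def test_site_mean_of_identical_nights(self):
        clip = intermittent_tone_clip(duration=2.0)
        clips = [AudioClip(clip.samples, site_id="S1", night_id=f"N{i}")
                 for i in range(3)]
        ct, sm = compute_index_table(clips, segment_duration=0.5,
                                     variants=("raw",))
        assert np.allclose(sm[["act", "aei", "hf", "sm"]].iloc[0],
                           ct[["act", "aei", "hf", "sm"]].iloc[0])
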