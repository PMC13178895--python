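"""Shared fixtures: synthetic clips and a scaled-down gradient study.

Heavy objects are session-scoped so the audio is synthesised once.
Problem sizes are scaled relative to the field design (12 sites x
5 nights x 60 s clips) to keep the suite fast; the scaling choices are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nightchorus import annotations, indices, models, simulate
from nightchorus.audio import AudioClip, SpectrogramParams, compute_spectrogram, high_pass_filter

SR = 44100


def tone_clip(freq: float, duration: float = 1.0, amp: float = 0.5,
              sr: int = SR) -> AudioClip:
    t = np.arange(int(duration * sr)) / sr
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), sample_rate=sr)


def noise_clip(duration: float = 1.0, rms: float = 0.05, seed: int = 0,
               sr: int = SR) -> AudioClip:
    rng = np.random.default_rng(seed)
    return AudioClip(np.clip(rng.standard_normal(int(duration * sr)) * rms,
                             -1, 1), sample_rate=sr)


@pytest.fixture(scope="session")
def gradient_study():
    """12-site insect-richness gradient (5..25), detection prob 1.

    Clip duration scaled to 12 s (field design: 60 s); all randomness
    from one fixed seed.
    """
    plan = simulate.richness_gradient_plan(min_richness=5, max_richness=25,
                                           seed=11, clip_duration=12.0,
                                           detection_prob=1.0)
    return simulate.generate_study(plan)


@pytest.fixture(scope="session")
def gradient_spreads(gradient_study):
    """Per-clip Sm bin-spread vectors for the raw and filtered variants."""
    params = SpectrogramParams()
    out = {"raw": [], "filtered": []}
    for clip in gradient_study.clips:
        for tag in out:
            work = high_pass_filter(clip) if tag == "filtered" else clip
            spec = compute_spectrogram(work, params)
            out[tag].append({
                "site_id": clip.site_id, "night_id": clip.night_id,
                "spread": indices.bin_snr_spread(spec, segment_duration=0.5)})
    return {tag: pd.DataFrame(rows) for tag, rows in out.items()}


@pytest.fixture(scope="session")
def gradient_richness(gradient_study):
    return annotations.richness_table(gradient_study.matrix)


@pytest.fixture(scope="session")
def gradient_scans(gradient_spreads, gradient_richness, gradient_study):
    """Threshold scans (with the Poisson R2 callback) for both variants."""
    reserve = gradient_study.plan.reserve_of_site
    return {tag: indices.scan_sm_threshold(
        gradient_spreads[tag], richness=gradient_richness,
        fit=models.poisson_r2_callback, reserve_of_site=reserve)
        for tag in ("raw", "filtered")}
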