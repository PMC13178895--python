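"""Audio I/O, scheduling, filtering and spectral machinery.

This module holds the shared signal-processing layer of the pipeline:
reading/writing 16-bit PCM WAV clips, the nightly recording schedule
(one clip every ``interval`` seconds inside a fixed evening window),
Butterworth high-pass filtering, the short-time Fourier spectrogram at
the analysis settings (window length 484 samples, 90 % overlap at
44.1 kHz, i.e. ~91 Hz frequency bins and ~11 ms windows), and
power-spectral-density summaries over consecutive 1-kHz bands.

dB values carry an explicit reference convention: ``full_scale`` means
0 dB corresponds to a full-scale sine (amplitude 1.0 after integer
normalisation), ``clip_max`` means 0 dB is the loudest spectrogram cell
of the clip itself.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "AudioClip",
    "SpectrogramParams",
    "Spectrogram",
    "BandPowerSummary",
    "read_wav",
    "write_wav",
    "high_pass_filter",
    "segment_schedule",
    "select_random_clip",
    "compute_spectrogram",
    "band_psd_summary",
    "mean_power_spectrum",
]

_DB_FLOOR = 1e-12  # amplitude floor before log conversion (-240 dB)


@dataclass
class AudioClip:
    """A mono audio clip with site/night provenance.

    ``samples`` are floats normalised to [-1, 1] by the integer full
    scale of the source encoding; ``start_time`` is the offset (s) of
    the clip within its night's recording window.
    """

    samples: np.ndarray
    sample_rate: int = 44100
    site_id: str = ""
    night_id: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError(
                f"AudioClip requires mono samples; got {self.samples.ndim}-d array"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.samples) / self.sample_rate

    def replace_samples(self, samples: np.ndarray) -> "AudioClip":
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


@dataclass(frozen=True)
class SpectrogramParams:
    """STFT settings; defaults follow the study analysis (wl=484, 90 %)."""

    window_length: int = 484
    overlap: float = 0.90
    window_function: str = "hann"
    reference: str = "full_scale"  # or "clip_max"

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")
        if self.reference not in ("full_scale", "clip_max"):
            raise ValueError(f"unknown dB reference {self.reference!r}")

    @property
    def hop(self) -> int:
        return max(1, round(self.window_length * (1.0 - self.overlap)))


@dataclass
class Spectrogram:
    """Linear-magnitude + dB time-frequency matrix (bins x frames).

    ``linear_magnitude`` is scaled so a full-scale on-bin sine has peak
    magnitude 1.0 (amplitude spectrum, Hann coherent gain removed).
    The DC bin is included, the Nyquist bin excluded, so there are
    floor(window_length / 2) frequency bins spaced sample_rate / wl Hz.
    """

    linear_magnitude: np.ndarray  # (n_bins, n_frames)
    db: np.ndarray
    freq_axis: np.ndarray  # Hz, bin centers
    time_axis: np.ndarray  # s, frame centers
    sample_rate: int
    params: SpectrogramParams = field(default_factory=SpectrogramParams)

    @property
    def n_bins(self) -> int:
        return self.linear_magnitude.shape[0]

    @property
    def n_frames(self) -> int:
        return self.linear_magnitude.shape[1]


@dataclass
class BandPowerSummary:
    """Mean PSD per consecutive frequency band plus full-spectrum power.

    ``full_spectrum_power_db`` is the dB of the linear-unit sum of the
    band PSDs (relative to a full-scale sine's band power), i.e. the
    clip-level "full-spectrum power" metric used to screen the candidate
    clip pool.
    """

    band_edges: np.ndarray  # (n_bands + 1,) Hz
    band_psd_db: np.ndarray  # (n_bands,)
    full_spectrum_power_db: float


# ---------------------------------------------------------------------------
# WAV I/O


def read_wav(path: str | Path, site_id: str = "", night_id: str = "",
             start_time: float = 0.0) -> AudioClip:
    """Read a mono PCM WAV file into an :class:`AudioClip`.

    Samples are normalised to [-1, 1] by the integer full scale
    (e.g. 32768 for 16-bit). Multi-channel or non-PCM files raise.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as wf:
            n_channels = wf.getnchannels()
            if n_channels != 1:
                raise ValueError(
                    f"{path}: expected mono audio, got {n_channels} channels"
                )
            sampwidth = wf.getsampwidth()
            rate = wf.getframerate()
            raw = wf.readframes(wf.getnframes())
    except wave.Error as exc:  # compressed / non-PCM encodings
        raise ValueError(f"{path}: unsupported (non-PCM?) WAV encoding: {exc}") from exc

    if sampwidth == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0
    elif sampwidth == 4:
        data = np.frombuffer(raw, dtype="<i4").astype(np.float64) / 2147483648.0
    elif sampwidth == 1:  # 8-bit WAV is unsigned
        data = (np.frombuffer(raw, dtype=np.uint8).astype(np.float64) - 128.0) / 128.0
    else:
        raise ValueError(f"{path}: unsupported PCM sample width {sampwidth} bytes")
    return AudioClip(samples=data, sample_rate=rate, site_id=site_id,
                     night_id=night_id, start_time=start_time)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit mono PCM WAV (values clipped to [-1, 1])."""
    samples = np.clip(clip.samples, -1.0, 1.0)
    ints = np.round(samples * 32767.0).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(clip.sample_rate)
        wf.writeframes(ints.tobytes())


# ---------------------------------------------------------------------------
# Filtering


def high_pass_filter(clip: AudioClip, cutoff: float = 300.0, order: int = 1,
                     zero_phase: bool = False) -> AudioClip:
    """Butterworth high-pass filter (default: order 1, single forward pass).

    ``zero_phase=True`` applies the filter forward and backward
    (doubling the effective magnitude response order, zero phase shift).
    """
    nyquist = clip.sample_rate / 2.0
    if not (0.0 < cutoff < nyquist):
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={nyquist:g}) Hz; got {cutoff:g}"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, cutoff, btype="highpass", fs=clip.sample_rate,
                     output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, clip.samples)
    else:
        filtered = sps.sosfilt(sos, clip.samples)
    return clip.replace_samples(filtered)


# ---------------------------------------------------------------------------
# Recording schedule


def segment_schedule(window_start: float, window_end: float,
                     clip_length: float = 60.0,
                     interval: float = 600.0) -> list[float]:
    """Clip start offsets (s) within a nightly recording window.

    Offsets run 0, interval, 2*interval, ... while the whole clip still
    fits inside the window. Clock times are seconds since the window
    start of the night (e.g. 19:30-22:00 encodes as 0..9000). A window
    shorter than one clip yields an empty list.
    """
    if window_end <= window_start:
        raise ValueError("window_end must be after window_start")
    if clip_length <= 0 or interval <= 0:
        raise ValueError("clip_length and interval must be positive")
    duration = window_end - window_start
    offsets: list[float] = []
    t = 0.0
    while t + clip_length <= duration + 1e-9:
        offsets.append(t)
        t += interval
    return offsets


def select_random_clip(candidates: Sequence, seed: int):
    """Uniformly select one candidate clip, reproducibly for a seed."""
    if len(candidates) == 0:
        raise ValueError("cannot select from an empty candidate list")
    rng = np.random.default_rng(seed)
    return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# Spectrogram and PSD


def _frame(samples: np.ndarray, wl: int, hop: int) -> np.ndarray:
    """(n_frames, wl) view of consecutive overlapping frames."""
    n = len(samples)
    if n < wl:
        raise ValueError(f"clip has {n} samples, shorter than one {wl}-sample window")
    n_frames = (n - wl) // hop + 1
    return np.lib.stride_tricks.sliding_window_view(samples, wl)[::hop][:n_frames]


def compute_spectrogram(clip: AudioClip,
                        params: SpectrogramParams | None = None) -> Spectrogram:
    """Short-time amplitude spectrogram with the analysis conventions.

    hop = round(wl * (1 - overlap)); frames = floor((N - wl)/hop) + 1;
    magnitudes scaled by 2/sum(window) so a full-scale on-bin sine peaks
    at 1.0 (0 dBFS). DC bin kept, Nyquist bin dropped.
    """
    params = params or SpectrogramParams()
    wl = params.window_length
    frames = _frame(clip.samples, wl, params.hop)
    window = sps.get_window(params.window_function, wl, fftbins=True)
    spec = np.fft.rfft(frames * window, axis=1)
    n_bins = wl // 2
    mag = (2.0 / window.sum()) * np.abs(spec[:, :n_bins]).T  # (bins, frames)
    if params.reference == "full_scale":
        ref = 1.0
    else:
        ref = max(mag.max(), _DB_FLOOR)
    db = 20.0 * np.log10(np.maximum(mag, _DB_FLOOR) / ref)
    freq_axis = np.arange(n_bins) * clip.sample_rate / wl
    centers = (np.arange(frames.shape[0]) * params.hop + wl / 2.0) / clip.sample_rate
    return Spectrogram(linear_magnitude=mag, db=db, freq_axis=freq_axis,
                       time_axis=centers, sample_rate=clip.sample_rate,
                       params=params)


def _mean_psd(clip: AudioClip, params: SpectrogramParams | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Mean power spectrum (linear units) over frames; (freqs, psd)."""
    spec = compute_spectrogram(clip, params)
    return spec.freq_axis, np.mean(spec.linear_magnitude ** 2, axis=1)


def band_psd_summary(clip: AudioClip, band_width: float = 1000.0,
                     f_max: float = 20000.0,
                     params: SpectrogramParams | None = None) -> BandPowerSummary:
    """Mean PSD in consecutive bands (default 1-kHz bands, 0-20 kHz).

    Full-spectrum power is the linear-unit sum of band PSDs converted
    to dB relative to full scale.
    """
    if f_max > clip.sample_rate / 2.0:
        raise ValueError("f_max exceeds the Nyquist frequency")
    freqs, psd = _mean_psd(clip, params)
    edges = np.arange(0.0, f_max + band_width / 2, band_width)
    band_psd = np.empty(len(edges) - 1)
    for i in range(len(edges) - 1):
        mask = (freqs >= edges[i]) & (freqs < edges[i + 1])
        band_psd[i] = psd[mask].mean() if mask.any() else 0.0
    total = band_psd.sum()
    total_db = 10.0 * np.log10(max(total, _DB_FLOOR ** 2))
    return BandPowerSummary(band_edges=edges, band_psd_db=10.0 * np.log10(
        np.maximum(band_psd, _DB_FLOOR ** 2)), full_spectrum_power_db=total_db)


def mean_power_spectrum(clips: Sequence[AudioClip],
                        params: SpectrogramParams | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-wise mean PSD of several clips, in dB.

    Averages the per-clip linear-unit power spectra (e.g. all clips of
    one site) and converts to dB. Returns (freqs, mean_psd_db).
    """
    if len(clips) == 0:
        raise ValueError("mean_power_spectrum requires at least one clip")
    rates = {c.sample_rate for c in clips}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates: {sorted(rates)}")
    acc = None
    freqs = None
    for clip in clips:
        freqs, psd = _mean_psd(clip, params)
        acc = psd if acc is None else acc + psd
    mean_psd = acc / len(clips)
    return freqs, 10.0 * np.log10(np.maximum(mean_psd, _DB_FLOOR ** 2))
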