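"""The four acoustic indices (ACT, AEI, Hf, Sm) and the Sm threshold scan.

ACT — acoustic activity: fraction of smoothed-envelope time blocks more
than a fixed margin (default 5 dB) above the envelope's low-percentile
(default 5th) noise floor. Scale-invariant by construction (the dB
envelope is referenced to the clip's own maximum).

AEI — acoustic evenness: Gini coefficient of the per-band proportions
of spectrogram cells exceeding a fixed -45 dBFS threshold, over
consecutive 1-kHz bands spanning 0-20 kHz. 0 means equal energy
distribution; not scale-invariant (the dBFS threshold is absolute).

Hf — spectral entropy: Shannon entropy of the normalised mean amplitude
spectrum, divided by log(number of bins), treating frequency bins as
"species". 1 in the flat-spectrum limit.

Sm — soundscape saturation: percentage of frequency bins whose
within-clip SNR exceeds a dB threshold. SNR is estimated per bin as
the spread between a high and a low quantile (default 95th/5th) of the
bin's level across time segments. Segment spectra are averaged over
``segment_duration`` seconds (raw short-window periodogram frames are
exponentially distributed and would saturate every bin of plain noise)
and normalised to each segment's total power before dB conversion, so
a dominant fluctuating component (e.g. low-frequency traffic noise)
modulates the relative level of every bin — the masking behaviour that
forces higher Sm thresholds on unfiltered recordings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .audio import AudioClip, Spectrogram, SpectrogramParams, compute_spectrogram, high_pass_filter

__all__ = [
    "IndexSet",
    "SmThresholdScan",
    "gini",
    "compute_act",
    "compute_aei",
    "compute_hf",
    "bin_snr_spread",
    "compute_sm",
    "scan_sm_threshold",
    "compute_index_table",
    "sm_threshold_grid",
]

logger = logging.getLogger(__name__)

_DB_FLOOR = 1e-12

INDEX_COLUMNS = ["act", "aei", "hf", "sm"]


@dataclass(frozen=True)
class IndexSet:
    """One clip's index values for one dataset variant (raw or filtered)."""

    act: float
    aei: float
    hf: float
    sm: float
    dataset_tag: str  # "raw" | "filtered"
    sm_threshold_db: float

    def __post_init__(self) -> None:
        if self.dataset_tag not in ("raw", "filtered"):
            raise ValueError(f"dataset_tag must be raw|filtered, got {self.dataset_tag!r}")


@dataclass
class SmThresholdScan:
    """Result of screening Sm SNR thresholds over a dB grid.

    ``table`` has one row per grid value: threshold_db, mean_sm,
    ceiling, r2_biophony, r2_insects, mean_r2. ``chosen_threshold`` is
    the non-ceiling threshold maximising the mean model R² (ties within
    0.01 broken toward the lowest threshold); when no model callback is
    supplied it is the lowest non-ceiling threshold.
    """

    table: pd.DataFrame
    chosen_threshold: float


def sm_threshold_grid(start: float = 3.0, stop: float = 8.0,
                      step: float = 0.1) -> np.ndarray:
    """The screening grid: 3.0-8.0 dB in 0.1 dB increments (51 values)."""
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


# ---------------------------------------------------------------------------
# Primitive statistics


def gini(values: Sequence[float]) -> float:
    """Gini coefficient via the mean-absolute-difference form.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)); an all-zero vector maps
    to 0 by convention (maximally even), negative entries are an error.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("gini requires a 1-d sequence of length >= 2")
    if np.any(x < 0):
        raise ValueError("gini is defined for non-negative values only")
    total = x.sum()
    if total == 0.0:
        return 0.0
    xs = np.sort(x)
    n = len(xs)
    # Equivalent O(n log n) form of the pairwise-difference sum.
    cum = np.cumsum(xs)
    pair_sum = 2.0 * np.sum(np.arange(1, n + 1) * xs) - (n + 1) * total
    return float(max(0.0, pair_sum / (n * total)))


# ---------------------------------------------------------------------------
# ACT


def compute_act(clip: AudioClip, smooth_window: int = 200, margin: float = 5.0,
                floor_percentile: float = 5.0) -> float:
    """Acoustic activity: fraction of envelope blocks above floor + margin.

    The envelope is the mean of |samples| over consecutive
    non-overlapping ``smooth_window``-sample blocks, expressed in dB
    relative to the loudest block; the threshold is the
    ``floor_percentile``-th percentile of that dB envelope plus
    ``margin`` dB; blocks strictly above it count as active.
    """
    if len(clip.samples) == 0:
        raise ValueError("compute_act requires a non-empty clip")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    n_blocks = len(clip.samples) // smooth_window
    if n_blocks < 2:
        raise ValueError("clip too short for the requested smoothing window")
    env = np.abs(clip.samples[: n_blocks * smooth_window]).reshape(
        n_blocks, smooth_window).mean(axis=1)
    peak = env.max()
    if peak == 0.0:
        logger.warning("compute_act: all-zero clip (site=%s night=%s); ACT := 0",
                       clip.site_id, clip.night_id)
        return 0.0
    env_db = 20.0 * np.log10(np.maximum(env, peak * _DB_FLOOR) / peak)
    threshold = np.percentile(env_db, floor_percentile) + margin
    return float(np.mean(env_db > threshold))


# ---------------------------------------------------------------------------
# AEI


def _band_masks(freqs: np.ndarray, band_width: float, f_max: float) -> list[np.ndarray]:
    edges = np.arange(0.0, f_max + band_width / 2, band_width)
    return [(freqs >= edges[i]) & (freqs < edges[i + 1])
            for i in range(len(edges) - 1)]


def compute_aei(spectrogram: Spectrogram, band_width: float = 1000.0,
                db_threshold: float = -45.0, f_max: float = 20000.0) -> float:
    """Acoustic evenness: Gini of band-wise occupancy proportions.

    For each ``band_width`` band up to ``f_max``, the proportion of
    time-frequency cells whose level exceeds ``db_threshold`` (dBFS; the
    spectrogram must use the full-scale reference) is computed; AEI is
    the Gini coefficient of those proportions. All-below-threshold
    clips give 0 (all proportions equal at zero).
    """
    if spectrogram.params.reference != "full_scale":
        raise ValueError("AEI requires a full-scale (dBFS) referenced spectrogram")
    masks = [m for m in _band_masks(spectrogram.freq_axis, band_width, f_max)
             if m.any()]
    if len(masks) < 2:
        raise ValueError("AEI needs at least 2 frequency bands below f_max")
    props = np.array([np.mean(spectrogram.db[m] > db_threshold) for m in masks])
    return gini(props)


# ---------------------------------------------------------------------------
# Hf


def compute_hf(spectrogram: Spectrogram) -> float:
    """Spectral entropy of the mean amplitude spectrum, scaled to [0, 1]."""
    if spectrogram.n_bins < 2:
        raise ValueError("Hf needs at least 2 frequency bins")
    mean_spec = spectrogram.linear_magnitude.mean(axis=1)
    total = mean_spec.sum()
    if total <= 0.0:
        raise ValueError("Hf is undefined for a silent clip")
    p = mean_spec / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(spectrogram.n_bins))


# ---------------------------------------------------------------------------
# Sm


def bin_snr_spread(spectrogram: Spectrogram, noise_quantile: float = 5.0,
                   signal_quantile: float = 95.0,
                   segment_duration: float = 1.0,
                   normalize: str = "segment_total") -> np.ndarray:
    """Per-bin SNR estimate: high-minus-low quantile of segment levels.

    Frames are pooled into consecutive ``segment_duration``-second
    segments and the linear power averaged per bin within each segment
    (raw short-window periodogram values are far too volatile for
    quantile noise floors). With ``normalize="segment_total"`` each
    segment spectrum is divided by its total power before dB
    conversion, so bin levels are *relative*: a dominant fluctuating
    component (low-frequency traffic noise on unfiltered recordings)
    then shifts every bin's relative level and inflates the spreads
    across the whole spectrum — the masking behaviour that pushes the
    usable Sm threshold upward on raw files. ``normalize="none"``
    keeps absolute per-bin levels (strictly local SNR).

    The returned spread (signal_quantile minus noise_quantile of each
    bin's segment levels, in dB) is what :func:`compute_sm`
    thresholds; precomputing it lets the threshold scan reuse one pass
    over the audio.
    """
    if not 0 <= noise_quantile < signal_quantile <= 100:
        raise ValueError("need 0 <= noise_quantile < signal_quantile <= 100")
    if normalize not in ("segment_total", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    power = spectrogram.linear_magnitude ** 2  # (bins, frames)
    n_frames = spectrogram.n_frames
    hop_s = spectrogram.params.hop / spectrogram.sample_rate
    frames_per_seg = max(1, int(round(segment_duration / hop_s)))
    n_segs = n_frames // frames_per_seg
    if n_segs < 2:
        raise ValueError(
            f"clip yields {n_segs} segment(s) of {segment_duration} s; "
            "need >= 2 for quantile spreads (shorten segment_duration)")
    seg_power = power[:, : n_segs * frames_per_seg].reshape(
        spectrogram.n_bins, n_segs, frames_per_seg).mean(axis=2)
    if normalize == "segment_total":
        totals = np.maximum(seg_power.sum(axis=0, keepdims=True), _DB_FLOOR ** 2)
        seg_power = seg_power / totals
    level_db = 10.0 * np.log10(np.maximum(seg_power, _DB_FLOOR ** 2))
    hi = np.percentile(level_db, signal_quantile, axis=1)
    lo = np.percentile(level_db, noise_quantile, axis=1)
    return hi - lo


def compute_sm(spectrogram: Spectrogram, snr_threshold: float,
               noise_quantile: float = 5.0, signal_quantile: float = 95.0,
               segment_duration: float = 1.0,
               normalize: str = "segment_total") -> float:
    """Soundscape saturation: % of bins whose SNR spread >= threshold."""
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    spread = bin_snr_spread(spectrogram, noise_quantile, signal_quantile,
                            segment_duration, normalize)
    return float(100.0 * np.mean(spread >= snr_threshold))


# ---------------------------------------------------------------------------
# Threshold scan


def scan_sm_threshold(
    clip_spreads: pd.DataFrame,
    richness: pd.DataFrame | None = None,
    grid: np.ndarray | None = None,
    fit: Callable[[pd.Series, pd.Series, pd.Series], float] | None = None,
    reserve_of_site: Mapping[str, str] | None = None,
    ceiling_median_sm: float = 99.5,
    ceiling_cv: float = 0.01,
    r2_tie: float = 0.01,
) -> SmThresholdScan:
    """Screen Sm SNR thresholds over a dB grid.

    ``clip_spreads`` holds one row per clip with columns ``site_id``,
    ``night_id`` and ``spread`` (the per-bin dB spread vector from
    :func:`bin_snr_spread`). For each grid threshold the clip-level Sm
    values, their site means, a ceiling flag, and (when ``fit``,
    ``richness`` and ``reserve_of_site`` are supplied) the Efron R² of
    models predicting biophony and insect richness from site-mean Sm
    are tabulated.

    A threshold is ceiling-flagged when the median clip Sm is >=
    ``ceiling_median_sm`` (Sm approaching 100 %) or the coefficient of
    variation of the site means falls below ``ceiling_cv`` (no
    between-site variance left for modelling). The chosen threshold is
    the non-ceiling grid value maximising the mean of the two R²
    (ties within ``r2_tie`` broken toward the lowest threshold); with no
    model callback it is simply the lowest non-ceiling threshold.
    """
    if grid is None:
        grid = sm_threshold_grid()
    spreads = np.stack(clip_spreads["spread"].to_numpy())  # (clips, bins)
    sites = clip_spreads["site_id"].to_numpy()

    rich_by = None
    if richness is not None:
        rich_by = {grp: sub.set_index("site_id")["accumulated_richness"]
                   for grp, sub in richness.groupby("group")}

    rows = []
    for theta in grid:
        sm_clip = 100.0 * np.mean(spreads >= theta, axis=1)
        site_sm = pd.Series(sm_clip).groupby(sites).mean()
        mean_sm = float(sm_clip.mean())
        cv = float(site_sm.std(ddof=1) / site_sm.mean()) if site_sm.mean() > 0 else 0.0
        # a ceiling is saturation at the top: near-100 %% clip values, or
        # high mean Sm with the between-site variance squeezed out
        ceiling = bool(np.median(sm_clip) >= ceiling_median_sm
                       or (mean_sm >= 50.0 and cv < ceiling_cv))
        r2_bio = r2_ins = np.nan
        if fit is not None and rich_by is not None and not ceiling:
            reserve = pd.Series({s: reserve_of_site[s] for s in site_sm.index})
            try:
                r2_bio = fit(site_sm, rich_by["biophony"].loc[site_sm.index], reserve)
                r2_ins = fit(site_sm, rich_by["insects"].loc[site_sm.index], reserve)
            except ValueError:
                pass  # e.g. zero-variance predictor at this threshold
        rows.append((float(theta), mean_sm, ceiling, r2_bio, r2_ins))
    table = pd.DataFrame(rows, columns=["threshold_db", "mean_sm", "ceiling",
                                        "r2_biophony", "r2_insects"])
    table["mean_r2"] = table[["r2_biophony", "r2_insects"]].mean(axis=1)

    usable = table[~table["ceiling"]]
    if usable.empty:
        raise ValueError("every threshold in the grid is ceiling-flagged; "
                         "widen the grid beyond 8.0 dB")
    if fit is None or usable["mean_r2"].isna().all():
        chosen = float(usable["threshold_db"].iloc[0])
    else:
        best = usable["mean_r2"].max()
        near = usable[usable["mean_r2"] >= best - r2_tie]
        chosen = float(near["threshold_db"].iloc[0])
    return SmThresholdScan(table=table, chosen_threshold=chosen)


# ---------------------------------------------------------------------------
# Index table


def compute_index_table(
    clips: Sequence[AudioClip],
    params: SpectrogramParams | None = None,
    sm_thresholds: Mapping[str, float] | None = None,
    filter_cutoff: float = 300.0,
    filter_order: int = 1,
    zero_phase: bool = False,
    segment_duration: float = 1.0,
    sm_normalize: str = "segment_total",
    variants: Sequence[str] = ("raw", "filtered"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clip-level index table plus site means for each dataset variant.

    Returns ``(clip_table, site_means)``. The clip table has one row
    per clip per variant with columns site_id, night_id, dataset_tag,
    act, aei, hf, sm, sm_threshold_db; site means average each index
    over a site's nights within a variant (the site-level predictor
    values paired with accumulated richness).
    """
    params = params or SpectrogramParams()
    sm_thresholds = dict(sm_thresholds or {"raw": 6.3, "filtered": 3.8})
    unknown = set(variants) - {"raw", "filtered"}
    if unknown:
        raise ValueError(f"unknown dataset variants: {sorted(unknown)}")

    rows = []
    skipped = 0
    for clip in clips:
        for tag in variants:
            if tag == "filtered":
                work = high_pass_filter(clip, cutoff=filter_cutoff,
                                        order=filter_order, zero_phase=zero_phase)
            else:
                work = clip
            try:
                spec = compute_spectrogram(work, params)
                act = compute_act(work)
                aei = compute_aei(spec)
                hf = compute_hf(spec)
                sm = compute_sm(spec, sm_thresholds[tag],
                                segment_duration=segment_duration,
                                normalize=sm_normalize)
            except ValueError as exc:
                skipped += 1
                logger.warning("skipping clip site=%s night=%s variant=%s: %s",
                               clip.site_id, clip.night_id, tag, exc)
                continue
            rows.append({"site_id": clip.site_id, "night_id": clip.night_id,
                         "dataset_tag": tag, "act": act, "aei": aei, "hf": hf,
                         "sm": sm, "sm_threshold_db": sm_thresholds[tag]})
    if skipped:
        logger.warning("compute_index_table: %d clip/variant rows excluded", skipped)
    clip_table = pd.DataFrame(rows)
    site_means = (clip_table
                  .groupby(["dataset_tag", "site_id"], as_index=False)[INDEX_COLUMNS]
                  .mean())
    return clip_table, site_means
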