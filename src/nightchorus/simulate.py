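"""Seeded synthetic nocturnal soundscapes with ground-truth annotations.

The generator emulates the statistical structure of a two-reserve
nocturnal recording campaign: a regional pool of sonotype templates
(insect stridulation between 1.4 and 20 kHz with the majority in
3.5-10 kHz; frog/bird/mammal calls below 4 kHz; one bat sonotype above
10 kHz), per-site occupancy subsets (optionally along a richness
gradient), per-night Bernoulli detection, a Gaussian noise floor, and
an optional low-frequency (0-300 Hz) anthropophony layer whose level
fluctuates slowly like passing traffic. Each site-night yields one
mono clip plus the realised event list, from which the binary
presence-absence sonotype matrix is derived — the same object the
annotation stage consumes, so every pipeline stage is testable without
field recordings.

Stridulation is modelled as gated sinusoids (pulse trains with a slow
frequency wobble spanning the template bandwidth); vertebrate calls as
Hann-windowed tones or linear FM sweeps. This is deliberately
parametric: sufficient for acoustic-index responses, not a
psychoacoustic rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .annotations import SonotypeMatrix
from .audio import AudioClip, write_wav

__all__ = [
    "SonotypeTemplate",
    "ScenePlan",
    "StudyData",
    "make_sonotype_pool",
    "synthesize_clip",
    "generate_study",
    "richness_gradient_plan",
    "two_reserve_plan",
]

INSECT_BAND = (1400.0, 20000.0)
INSECT_CORE = (4000.0, 7800.0)
LOWFREQ_BAND = (400.0, 3800.0)
BAT_BAND = (11000.0, 18000.0)

# Annotation taxon labels for template taxa; the single bat sonotype is
# filed with the mammals, as in the field annotation scheme.
_ANNOTATION_TAXON = {"insect": "insect", "frog": "frog", "bird": "bird",
                     "mammal": "mammal", "bat": "mammal"}


@dataclass(frozen=True)
class SonotypeTemplate:
    """One synthetic sonotype: what it sounds like and how often."""

    sonotype_id: str
    taxon: str  # insect | frog | bird | mammal | bat
    carrier_freq: float  # Hz
    bandwidth: float  # Hz
    call_type: str  # pulse_train | tonal | fm_sweep
    duty_cycle: float  # fraction of a pulse period that is "on"
    amplitude_db: float  # dB above the noise-floor RMS
    bout_duration: float  # s
    inter_bout: float  # s
    pulse_rate: float = 0.0  # Hz, pulse_train only

    def __post_init__(self) -> None:
        if self.taxon == "insect" and not (
                INSECT_BAND[0] <= self.carrier_freq <= INSECT_BAND[1]):
            raise ValueError(f"insect carrier {self.carrier_freq} Hz outside "
                             f"{INSECT_BAND}")
        if self.taxon in ("frog", "bird", "mammal") and self.carrier_freq >= 4000:
            raise ValueError(f"{self.taxon} carrier must be below 4000 Hz")
        if self.taxon == "bat" and self.carrier_freq <= 10000:
            raise ValueError("bat carrier must be above 10 kHz")
        if not (0.0 < self.duty_cycle <= 1.0):
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.call_type not in ("pulse_train", "tonal", "fm_sweep"):
            raise ValueError(f"unknown call_type {self.call_type!r}")


@dataclass
class ScenePlan:
    """Full specification of one synthetic study; seeded, reproducible."""

    sites: list[tuple[str, str]]  # (site_id, reserve)
    nights: list[str]
    regional_pool: list[SonotypeTemplate]
    site_occupancy: dict[str, list[str]]  # site -> sonotype ids
    # caller density per site: mean number of simultaneously calling
    # individuals per sonotype (richness gradients covary with
    # abundance; denser choruses fill the spectrum more completely)
    site_density: dict[str, float] | None = None
    nightly_detection_prob: float = 1.0
    anthropophony_db: float | None = 40.0  # dB above floor RMS; None = off
    anthropophony_mod_db: float = 3.5  # sd of the slow level fluctuation
    ambience_db: float | None = None  # optional distant-chorus bed, dB above floor
    noise_floor_db: float = -58.0  # dBFS RMS of the Gaussian floor
    clip_duration: float = 60.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nightly_detection_prob <= 1.0):
            raise ValueError("nightly_detection_prob must be in [0, 1]")
        pool_ids = {t.sonotype_id for t in self.regional_pool}
        for site, occ in self.site_occupancy.items():
            missing = set(occ) - pool_ids
            if missing:
                raise ValueError(f"site {site}: occupancy ids not in pool: "
                                 f"{sorted(missing)}")

    @property
    def reserve_of_site(self) -> dict[str, str]:
        return dict(self.sites)


@dataclass
class StudyData:
    """Generated study: audio, ground truth and schedule."""

    clips: list[AudioClip]
    matrix: SonotypeMatrix
    events: pd.DataFrame  # site_id, night_id, sonotype_id, onset, duration
    schedule: pd.DataFrame
    plan: ScenePlan = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Pool construction


def _spaced_carriers(rng: np.random.Generator, n: int, low: float, high: float,
                     min_sep: float, label: str) -> np.ndarray:
    """n carriers drawn from a shuffled grid of min_sep-spaced slots."""
    slots = np.arange(low, high, min_sep)
    if n > len(slots):
        raise ValueError(
            f"{n} {label} sonotypes exceed the spacing capacity of "
            f"{len(slots)} slots in {low:.0f}-{high:.0f} Hz at {min_sep:.0f} Hz "
            "separation; widen the band or reduce the count")
    chosen = rng.choice(len(slots), size=n, replace=False)
    return slots[chosen] + rng.uniform(0.0, min_sep * 0.5, size=n)


def make_sonotype_pool(n_insect: int, n_lowfreq: int, n_bat: int, seed: int,
                       core_band: tuple[float, float] = INSECT_CORE,
                       core_fraction: float = 0.7,
                       min_sep: float = 135.0,
                       amplitude_db_range: tuple[float, float] = (20.0, 24.0),
                       id_prefix: str = "ST",
                       ) -> list[SonotypeTemplate]:
    """Draw a regional sonotype pool with acoustic-niche spacing.

    At least ``core_fraction`` of insect carriers fall inside
    ``core_band`` (default 4.0-7.8 kHz, within the 3.5-10 kHz range
    where most insect calls sit); carriers keep a minimum
    separation so sonotypes occupy distinguishable spectral niches.
    ``core_band`` can be shifted per community to emulate reserves with
    spectrally distinct assemblages.
    """
    if min(n_insect, n_lowfreq, n_bat) < 0:
        raise ValueError("sonotype counts must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = core_band
    lo = max(lo, INSECT_BAND[0])
    hi = min(hi, INSECT_BAND[1])
    n_core = int(np.ceil(core_fraction * n_insect))
    n_edge = n_insect - n_core
    carriers = list(_spaced_carriers(rng, n_core, lo, hi, min_sep, "core insect"))
    if n_edge > 0:
        # periphery: below and above the core band, inside the insect range
        edge_slots = np.concatenate([
            np.arange(INSECT_BAND[0], lo, min_sep),
            np.arange(hi, INSECT_BAND[1], min_sep)])
        if n_edge > len(edge_slots):
            raise ValueError(
                f"{n_edge} peripheral insect sonotypes exceed the "
                f"{len(edge_slots)}-slot capacity; widen the band")
        idx = rng.choice(len(edge_slots), size=n_edge, replace=False)
        jittered = edge_slots[idx] + rng.uniform(0, min_sep * 0.5, n_edge)
        carriers.extend(np.clip(jittered, INSECT_BAND[0], INSECT_BAND[1] - 1.0))

    templates: list[SonotypeTemplate] = []
    amp_lo, amp_hi = amplitude_db_range
    for i, fc in enumerate(carriers):
        templates.append(SonotypeTemplate(
            sonotype_id=f"{id_prefix}_ins{i:03d}", taxon="insect",
            carrier_freq=float(fc),
            bandwidth=float(rng.uniform(100.0, 400.0)),
            call_type="pulse_train",
            pulse_rate=float(rng.uniform(8.0, 30.0)),
            duty_cycle=float(rng.uniform(0.3, 0.8)),
            amplitude_db=float(rng.uniform(amp_lo, amp_hi)),
            # near-continuous trills: long stridulation bouts broken by
            # short silences keep the chorus bed steady while each
            # caller's band still falls quiet within most clips
            bout_duration=float(rng.uniform(20.0, 60.0)),
            inter_bout=float(rng.uniform(1.0, 3.0))))
    for i in range(n_lowfreq):
        taxon = ("frog", "bird", "mammal")[i % 3]
        templates.append(SonotypeTemplate(
            sonotype_id=f"{id_prefix}_low{i:03d}", taxon=taxon,
            carrier_freq=float(rng.uniform(*LOWFREQ_BAND)),
            bandwidth=float(rng.uniform(200.0, 800.0)),
            call_type=str(rng.choice(["tonal", "fm_sweep"])),
            duty_cycle=1.0,
            # sparse vertebrate calls sit below the insect chorus bed
            amplitude_db=float(rng.uniform(12.0, 18.0)),
            bout_duration=float(rng.uniform(0.5, 2.0)),
            inter_bout=float(rng.uniform(3.0, 10.0))))
    for i in range(n_bat):
        templates.append(SonotypeTemplate(
            sonotype_id=f"{id_prefix}_bat{i:03d}", taxon="bat",
            carrier_freq=float(rng.uniform(*BAT_BAND)),
            bandwidth=float(rng.uniform(500.0, 2000.0)),
            call_type="pulse_train",
            pulse_rate=float(rng.uniform(6.0, 12.0)),
            duty_cycle=float(rng.uniform(0.05, 0.2)),
            amplitude_db=float(rng.uniform(amp_lo, amp_hi)),
            bout_duration=float(rng.uniform(1.0, 4.0)),
            inter_bout=float(rng.uniform(4.0, 12.0))))
    return templates


def pool_metadata(pool: list[SonotypeTemplate]) -> pd.DataFrame:
    """Annotation-schema metadata (sonotype_id, taxon, band) for a pool."""
    rows = [{"sonotype_id": t.sonotype_id,
             "taxon": _ANNOTATION_TAXON[t.taxon],
             "f_low_hz": max(0.0, t.carrier_freq - t.bandwidth / 2),
             "f_high_hz": t.carrier_freq + t.bandwidth / 2}
            for t in pool]
    return pd.DataFrame(rows).set_index("sonotype_id")


# ---------------------------------------------------------------------------
# Clip synthesis


def _bout_intervals(rng: np.random.Generator, duration: float,
                    bout: float, gap: float) -> list[tuple[float, float]]:
    """(onset, length) of bout segments intersecting the clip.

    The bout/silence cycle runs with a random phase (a caller is
    usually mid-bout when a clip starts — choruses are stationary, not
    synchronised to the recorder). If the clip happens to fall entirely
    inside a silence, one bout is placed inside the clip anyway: a
    sonotype assigned to a site-night is audible in that night's clip.
    """
    cycle = bout + gap
    onset = -float(rng.uniform(0.0, cycle))
    intervals = []
    while onset < duration:
        start = max(0.0, onset)
        end = min(onset + bout, duration)
        if end - start > 1e-3:
            intervals.append((start, end - start))
        onset += cycle
    if not intervals:
        start = float(rng.uniform(0.0, max(duration - min(bout, duration), 0.0)
                                  or 0.0))
        intervals.append((start, min(bout, duration - start)))
    return intervals


def _render_template(t: SonotypeTemplate, duration: float, sr: int,
                     amp: float, rng: np.random.Generator,
                     n_voices: int = 1,
                     gap_attenuation_db: float = 60.0,
                     ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render one sonotype's call train (possibly a chorus of voices).

    All voices of a sonotype share the bout/silence timing (individuals
    chorus in synchronised bouts) but have independent pulse phases,
    wobble phases and slight carrier detunes. Between bouts the chorus
    does not fall fully silent: the train continues attenuated by
    ``gap_attenuation_db`` (chorus-bed persistence), so a sonotype's
    frequency band shows a clear but bounded level contrast while the
    clip's total power stays nearly steady.
    """
    n = int(round(duration * sr))
    time = np.arange(n) / sr
    out = np.zeros(n)
    intervals = _bout_intervals(rng, duration, t.bout_duration, t.inter_bout)

    # bout envelope: attenuated baseline, full level inside bouts,
    # with ~50 ms half-cosine ramps at true bout boundaries (a bout
    # running past the clip edge is mid-bout, not a fade)
    gap_gain = 10.0 ** (-gap_attenuation_db / 20.0)
    bout_env = np.full(n, gap_gain)
    r = max(2, int(0.05 * sr))
    rise = gap_gain + (1.0 - gap_gain) * 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
    for onset, length in intervals:
        i0, i1 = int(onset * sr), min(int((onset + length) * sr), n)
        bout_env[i0:i1] = 1.0
        if i0 > 0:
            end = min(i0 + r, i1)
            bout_env[i0:end] = rise[: end - i0]
        if i1 < n:
            start = max(i1 - r, i0)
            bout_env[start:i1] = rise[: i1 - start][::-1]

    for _ in range(max(1, n_voices)):
        # slow frequency wobble spreads energy over the template bandwidth
        wobble_rate = rng.uniform(0.2, 1.0)
        wobble_phase = rng.uniform(0, 2 * np.pi)
        phase0 = rng.uniform(0, 2 * np.pi)
        carrier = t.carrier_freq * (1.0 + rng.normal(0.0, 0.004))
        pulse_shift = rng.uniform(0.0, 1.0)
        if t.call_type == "fm_sweep":
            inst = np.full(n, carrier - t.bandwidth / 2)
            for onset, length in intervals:
                i0, i1 = int(onset * sr), int((onset + length) * sr)
                frac = np.linspace(0.0, 1.0, max(i1 - i0, 1))
                inst[i0:i1] = carrier - t.bandwidth / 2 + t.bandwidth * frac
        else:
            inst = (carrier + (t.bandwidth / 2)
                    * np.sin(2 * np.pi * wobble_rate * time + wobble_phase))
        phase = phase0 + 2 * np.pi * np.cumsum(inst) / sr
        tone = np.sin(phase)
        if t.call_type == "pulse_train":
            pulse_phase = (time * t.pulse_rate + pulse_shift) % 1.0
            gate = (pulse_phase < t.duty_cycle).astype(float)
        else:
            gate = np.ones(n)
        out += amp * tone * gate * bout_env
    return out, intervals


def _anthropophony(rng: np.random.Generator, n: int, sr: int, rms: float,
                   mod_db_sd: float, duration: float) -> np.ndarray:
    """Low-frequency (< ~300 Hz) noise with slow traffic-like level swings."""
    white = rng.standard_normal(n)
    # heavy-vehicle / rail rumble: energy concentrated in the deep bass
    # (below ~25 Hz), the dominant part of the 0-300 Hz traffic band
    sos = sps.butter(4, 25.0, btype="lowpass", fs=sr, output="sos")
    low = sps.sosfilt(sos, white)
    low = low / max(np.sqrt(np.mean(low ** 2)), 1e-12)
    # piecewise-linear dB level curve, ~12 control points per clip
    n_ctrl = 13
    ctrl_t = np.linspace(0.0, duration, n_ctrl)
    # traffic loudness has a bounded peak: clamp rare extreme swings
    ctrl_db = np.clip(rng.standard_normal(n_ctrl) * mod_db_sd, -8.0, 8.0)
    level_db = np.interp(np.arange(n) / sr, ctrl_t, ctrl_db)
    return low * rms * 10.0 ** (level_db / 20.0)


def synthesize_clip(active: list[SonotypeTemplate], duration: float = 60.0,
                    sample_rate: int = 44100, noise_floor_db: float = -58.0,
                    anthropophony_db: float | None = 40.0,
                    anthropophony_mod_db: float = 3.5,
                    ambience_db: float | None = None,
                    seed: int | np.random.SeedSequence = 0,
                    site_id: str = "", night_id: str = "",
                    max_clipped_fraction: float = 0.01,
                    voices: Sequence[int] | None = None,
                    ) -> tuple[AudioClip, pd.DataFrame]:
    """Render one clip from active templates; returns (clip, event list).

    The mix is a Gaussian noise floor (RMS ``noise_floor_db`` dBFS),
    optional fluctuating 0-300 Hz anthropophony, and each template's
    call train at ``amplitude_db`` above the floor RMS. ``voices``
    optionally gives the chorus size per template (default 1 each).
    If more than ``max_clipped_fraction`` of samples would clip, an
    error advises lowering amplitudes.
    """
    rng = np.random.default_rng(seed)
    if voices is None:
        voices = [1] * len(active)
    if len(voices) != len(active):
        raise ValueError("voices must match the active template list")
    n = int(round(duration * sample_rate))
    floor_rms = 10.0 ** (noise_floor_db / 20.0)
    mix = rng.standard_normal(n) * floor_rms
    if ambience_db is not None:
        # steady distant-chorus ambience: band-limited (2-9 kHz) noise at
        # the same level everywhere, the landscape's background biophony
        amb = sps.sosfilt(sps.butter(4, [2000.0, 9000.0], "bandpass",
                                     fs=sample_rate, output="sos"),
                          rng.standard_normal(n))
        amb /= max(np.sqrt(np.mean(amb ** 2)), 1e-12)
        mix += amb * floor_rms * 10.0 ** (ambience_db / 20.0)
    if anthropophony_db is not None:
        mix += _anthropophony(rng, n, sample_rate,
                              floor_rms * 10.0 ** (anthropophony_db / 20.0),
                              anthropophony_mod_db, duration)
    events = []
    for t, n_voices in zip(active, voices):
        amp = floor_rms * 10.0 ** (t.amplitude_db / 20.0)
        wave_part, intervals = _render_template(t, duration, sample_rate, amp,
                                                rng, n_voices=n_voices)
        mix += wave_part
        for onset, length in intervals:
            events.append({"site_id": site_id, "night_id": night_id,
                           "sonotype_id": t.sonotype_id,
                           "onset": onset, "duration": length})
    clipped = np.mean(np.abs(mix) > 1.0)
    if clipped > max_clipped_fraction:
        raise ValueError(
            f"{clipped:.1%} of samples clip (> {max_clipped_fraction:.0%}); "
            "lower template amplitudes or the anthropophony level")
    mix = np.clip(mix, -1.0, 1.0)
    clip = AudioClip(samples=mix, sample_rate=sample_rate, site_id=site_id,
                     night_id=night_id)
    cols = ["site_id", "night_id", "sonotype_id", "onset", "duration"]
    return clip, pd.DataFrame(events, columns=cols)


# ---------------------------------------------------------------------------
# Study generation


def generate_study(plan: ScenePlan, out_dir: str | Path | None = None
                   ) -> StudyData:
    """Render every site-night clip of a plan and derive ground truth.

    All randomness stems from ``plan.seed`` (per-clip streams are
    spawned from (seed, site index, night index), so studies are
    reproducible clip by clip). With ``out_dir`` set, writes 16-bit WAV
    clips, the annotation-schema matrix + metadata CSVs, the schedule
    CSV and a JSON manifest.
    """
    templates = {t.sonotype_id: t for t in plan.regional_pool}
    clips: list[AudioClip] = []
    event_frames: list[pd.DataFrame] = []
    matrix_rows = []
    schedule_rows = []
    for i_site, (site, reserve) in enumerate(plan.sites):
        occ = plan.site_occupancy.get(site, [])
        for i_night, night in enumerate(plan.nights):
            ss = np.random.SeedSequence([int(plan.seed), i_site, i_night])
            rng = np.random.default_rng(ss)
            detected = [sid for sid in occ
                        if rng.random() < plan.nightly_detection_prob]
            density = (plan.site_density or {}).get(site, 1.0)
            # one guaranteed caller per sonotype plus density-driven
            # extra voices (individuals chorusing in synchronised bouts)
            voices = [1 + int(rng.poisson(max(0.0, density - 1.0)))
                      for _ in detected]
            clip, events = synthesize_clip(
                [templates[s] for s in detected],
                duration=plan.clip_duration, sample_rate=plan.sample_rate,
                noise_floor_db=plan.noise_floor_db,
                anthropophony_db=plan.anthropophony_db,
                anthropophony_mod_db=plan.anthropophony_mod_db,
                ambience_db=plan.ambience_db,
                seed=rng, site_id=site, night_id=night, voices=voices)
            clips.append(clip)
            event_frames.append(events)
            present = set(events["sonotype_id"])
            row = {"site_id": site, "night_id": night}
            row.update({sid: int(sid in present) for sid in templates})
            matrix_rows.append(row)
            schedule_rows.append({"site_id": site, "night_id": night,
                                  "reserve": reserve,
                                  "recording_id": f"{site}_{night}",
                                  "duration_s": plan.clip_duration})

    data = pd.DataFrame(matrix_rows)
    data.index = [f"{r.site_id}_{r.night_id}" for r in data.itertuples()]
    matrix = SonotypeMatrix(data=data, meta=pool_metadata(plan.regional_pool))
    events = pd.concat(event_frames, ignore_index=True)
    schedule = pd.DataFrame(schedule_rows)
    study = StudyData(clips=clips, matrix=matrix, events=events,
                      schedule=schedule, plan=plan)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for clip in clips:
            write_wav(out / f"{clip.site_id}_{clip.night_id}.wav", clip)
        cols = [c for c in data.columns if c not in ("site_id", "night_id")]
        data[cols].to_csv(out / "sonotype_matrix.csv",
                          index_label="recording_id")
        matrix.meta.to_csv(out / "sonotype_meta.csv")
        schedule.to_csv(out / "schedule.csv", index=False)
        manifest = {"seed": plan.seed, "n_sites": len(plan.sites),
                    "n_nights": len(plan.nights),
                    "clip_duration": plan.clip_duration,
                    "sample_rate": plan.sample_rate,
                    "files": [f"{c.site_id}_{c.night_id}.wav" for c in clips]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return study


# ---------------------------------------------------------------------------
# Plan builders


def _default_sites(n_sites: int) -> list[tuple[str, str]]:
    """Sites S01..Snn with reserves A/B interleaved along the index."""
    return [(f"S{i + 1:02d}", "A" if i % 2 == 0 else "B")
            for i in range(n_sites)]


def richness_gradient_plan(min_richness: int = 5, max_richness: int = 25,
                           n_sites: int = 12, n_nights: int = 5,
                           seed: int = 0, n_lowfreq: int = 6, n_bat: int = 1,
                           lowfreq_prob: float = 0.5,
                           detection_prob: float = 1.0,
                           clip_duration: float = 60.0,
                           anthropophony_db: float | None = 40.0,
                           ) -> ScenePlan:
    """A study whose sites span an insect-richness gradient.

    Insect occupancy sizes are evenly spaced from ``min_richness`` to
    ``max_richness`` across sites (reserves interleaved so both span
    the gradient); each low-frequency sonotype additionally occupies a
    site with probability ``lowfreq_prob``. Occupancy subsets are drawn
    to hit the insect targets exactly.
    """
    rng = np.random.default_rng(seed)
    pool = make_sonotype_pool(n_insect=max_richness + 1, n_lowfreq=n_lowfreq,
                              n_bat=n_bat, seed=int(rng.integers(2 ** 31)))
    insect_ids = [t.sonotype_id for t in pool if t.taxon == "insect"]
    other_ids = [t.sonotype_id for t in pool if t.taxon != "insect"]
    if max_richness > len(insect_ids):
        raise ValueError("max_richness exceeds the insect pool size")
    targets = np.round(np.linspace(min_richness, max_richness, n_sites)).astype(int)
    sites = _default_sites(n_sites)
    occupancy = {}
    density = {}
    span = max(max_richness - min_richness, 1)
    for (site, _), target in zip(sites, targets):
        chosen = list(rng.choice(insect_ids, size=target, replace=False))
        chosen += [sid for sid in other_ids if rng.random() < lowfreq_prob]
        occupancy[site] = chosen
        # richness covaries with abundance along habitat-quality
        # gradients: richer sites also carry denser choruses
        density[site] = 1.5 + 2.0 * (target - min_richness) / span
    return ScenePlan(sites=sites, nights=[f"N{j + 1}" for j in range(n_nights)],
                     regional_pool=pool, site_occupancy=occupancy,
                     site_density=density,
                     nightly_detection_prob=detection_prob,
                     anthropophony_db=anthropophony_db,
                     clip_duration=clip_duration, seed=seed)


def two_reserve_plan(pool_overlap: float = 1.0, richness: int = 14,
                     pool_size: int = 28, n_sites: int = 12, n_nights: int = 5,
                     seed: int = 0, detection_prob: float = 0.9,
                     clip_duration: float = 60.0,
                     anthropophony_db: float | None = 40.0,
                     ) -> ScenePlan:
    """A two-reserve study with controllable sonotype-pool overlap.

    ``pool_overlap`` = 1 draws every site's occupancy from one shared
    regional pool (the no-reserve-effect scenario); 0 gives each
    reserve its own pool of spectrally distinct insects (separate
    community core bands), emulating disjoint assemblages. Intermediate
    values share that fraction of the pool. All sites have the same
    occupancy size ``richness``.
    """
    if not (0.0 <= pool_overlap <= 1.0):
        raise ValueError("pool_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(round(pool_overlap * pool_size))
    n_own = pool_size - n_shared
    shared = make_sonotype_pool(n_shared, n_lowfreq=4, n_bat=1,
                                seed=int(rng.integers(2 ** 31)),
                                id_prefix="SH") if n_shared else []
    # Distinct assemblages differ along the axes scalar acoustic indices
    # can see: spectral concentration (occupied 1-kHz bands -> AEI/Hf),
    # loudness regime (dBFS threshold visibility -> AEI/Sm) and calling
    # tempo (bout/silence balance -> ACT/Sm). Dominant-frequency
    # placement alone is invisible to band-aggregated indices, so each
    # axis draws the two reserves from opposite halves of its range
    # (randomly swapped) to guarantee genuinely distinct communities.
    def _contrast(lo_range, hi_range):
        vals = [float(rng.uniform(*lo_range)), float(rng.uniform(*hi_range))]
        if rng.random() < 0.5:
            vals.reverse()
        return dict(zip(("A", "B"), vals))

    width_of = _contrast((900.0, 1800.0), (2400.0, 3600.0))
    amp_of = _contrast((12.0, 17.0), (21.0, 26.0))
    tempo_of = _contrast((0.6, 0.9), (1.2, 1.6))
    pools_by_reserve: dict[str, list[SonotypeTemplate]] = {}
    pool_all = list(shared)
    for reserve in ("A", "B"):
        own: list[SonotypeTemplate] = []
        if n_own:
            centre = float(rng.uniform(5500.0, 8000.0))
            half_width = width_of[reserve]
            amp_centre = amp_of[reserve]
            tempo = tempo_of[reserve]
            n_core = int(np.ceil(0.7 * n_own))
            sep = max(60.0, 2.0 * half_width / (n_core + 2))
            own = make_sonotype_pool(
                n_own, n_lowfreq=0, n_bat=0, seed=int(rng.integers(2 ** 31)),
                core_band=(centre - half_width, centre + half_width),
                min_sep=sep,
                amplitude_db_range=(amp_centre - 3.0, amp_centre + 3.0),
                id_prefix=f"R{reserve}")
            own = [replace(t, bout_duration=t.bout_duration * tempo,
                           inter_bout=t.inter_bout / tempo) for t in own]
        pools_by_reserve[reserve] = shared + own
        pool_all.extend(own)
    if richness > pool_size:
        raise ValueError("richness exceeds the per-reserve pool size")
    sites = _default_sites(n_sites)
    occupancy = {}
    for site, reserve in sites:
        ids = [t.sonotype_id for t in pools_by_reserve[reserve]
               if t.taxon == "insect"]
        low = [t.sonotype_id for t in pools_by_reserve[reserve]
               if t.taxon != "insect"]
        occupancy[site] = (list(rng.choice(ids, size=min(richness, len(ids)),
                                           replace=False))
                           + [s for s in low if rng.random() < 0.5])
    return ScenePlan(sites=sites, nights=[f"N{j + 1}" for j in range(n_nights)],
                     regional_pool=pool_all, site_occupancy=occupancy,
                     nightly_detection_prob=detection_prob,
                     anthropophony_db=anthropophony_db,
                     clip_duration=clip_duration, seed=seed)
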