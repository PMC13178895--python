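"""End-to-end orchestration: audio -> indices -> models -> dissimilarity.

A single config (nested dict, YAML/JSON-serialisable) drives the whole
analysis. One master seed fans out to named sub-seeds (simulation,
permutation tests, NMDS restarts) so components re-run in isolation
reproduce the full run's results exactly.

The report bundle mirrors the study's output tables: a clip-level and
site-mean index table per dataset variant (raw / high-pass filtered),
an optional Sm threshold-scan table, the selected-GLM report
(response x predictor grid), a per-reserve summary (accumulated
richness and aggregated indices), and the dissimilarity report
(between/within mean distances, PERMANOVA p and R², PERMDISP p, NMDS
coordinates and stress) for the annotation-based Jaccard view and the
index-profile Ruzicka view.
"""

from __future__ import annotations

import copy
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotations, dissimilarity, indices, models, simulate
from .audio import SpectrogramParams, read_wav

__all__ = ["DEFAULT_CONFIG", "validate_config", "run_analysis", "load_study"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {  # set to None when reading recorded audio
        "kind": "richness_gradient",  # or "two_reserve"
        "min_richness": 5,
        "max_richness": 25,
        "n_sites": 12,
        "n_nights": 5,
        "detection_prob": 1.0,
        "clip_duration": 60.0,
        "anthropophony_db": 40.0,
        "pool_overlap": 1.0,  # two_reserve only
    },
    "audio_dir": None,  # directory with WAVs + schedule.csv + matrix CSVs
    "spectrogram": {"window_length": 484, "overlap": 0.90},
    "filter": {"cutoff_hz": 300.0, "order": 1, "zero_phase": False},
    "sm": {
        "segment_duration": 1.0,
        "normalize": "segment_total",
        "thresholds": {"raw": 6.3, "filtered": 3.8},
        "scan": False,
        "grid": {"start": 3.0, "stop": 8.0, "step": 0.1},
    },
    "families": list(models.FAMILIES),
    "n_permutations": 9999,
    "nmds_restarts": 20,
    "out_dir": None,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults and validate; raises with the *full* error list."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    errors: list[str] = []
    sg = cfg["spectrogram"]
    if not (0 <= sg["overlap"] < 1):
        errors.append(f"spectrogram.overlap must be in [0, 1): {sg['overlap']}")
    if sg["window_length"] < 2:
        errors.append("spectrogram.window_length must be >= 2")
    if cfg["filter"]["cutoff_hz"] <= 0:
        errors.append("filter.cutoff_hz must be positive")
    if cfg["filter"]["order"] < 1:
        errors.append("filter.order must be >= 1")
    if cfg["n_permutations"] < 1:
        errors.append("n_permutations must be positive")
    if cfg["nmds_restarts"] < 1:
        errors.append("nmds_restarts must be positive")
    grid = cfg["sm"]["grid"]
    if not (0 < grid["start"] < grid["stop"]) or grid["step"] <= 0:
        errors.append(f"sm.grid must satisfy 0 < start < stop, step > 0: {grid}")
    for tag, thr in cfg["sm"]["thresholds"].items():
        if tag not in ("raw", "filtered"):
            errors.append(f"unknown sm.thresholds key {tag!r}")
        elif thr <= 0:
            errors.append(f"sm.thresholds[{tag!r}] must be positive")
    if cfg["simulate"] is None and cfg["audio_dir"] is None:
        errors.append("either simulate or audio_dir must be set")
    bad_fams = set(cfg["families"]) - set(models.FAMILIES)
    if bad_fams:
        errors.append(f"unknown GLM families: {sorted(bad_fams)}")
    if errors:
        raise ValueError("invalid config:\n- " + "\n- ".join(errors))
    return cfg


def _sub_seed(master: int, stream: str) -> int:
    """Named, stable sub-seed derived from the master seed (< 2^31).

    Uses a process-independent hash of the stream name (Python's str
    hash is salted per interpreter run and would break cross-run
    reproducibility).
    """
    h = np.random.SeedSequence([master, zlib.crc32(stream.encode())])
    return int(h.generate_state(1)[0] % (2 ** 31))


def load_study(audio_dir: str | Path):
    """Load a recorded/simulated study directory (WAVs + CSV sidecars)."""
    audio_dir = Path(audio_dir)
    schedule = pd.read_csv(audio_dir / "schedule.csv")
    matrix = annotations.load_sonotype_matrix(audio_dir / "sonotype_matrix.csv",
                                              audio_dir / "sonotype_meta.csv")
    clips = []
    missing = []
    for row in schedule.itertuples():
        path = audio_dir / f"{row.recording_id}.wav"
        if not path.exists():
            missing.append(row.recording_id)
            continue
        clips.append(read_wav(path, site_id=str(row.site_id),
                              night_id=str(row.night_id)))
    if missing:
        logger.warning("missing %d scheduled recordings: %s", len(missing),
                       missing)
    reserve_of_site = dict(zip(schedule["site_id"].astype(str),
                               schedule["reserve"].astype(str)))
    return clips, matrix, schedule, reserve_of_site


def _simulated_study(cfg: dict):
    sim = cfg["simulate"]
    seed = _sub_seed(cfg["seed"], "simulation")
    if sim["kind"] == "richness_gradient":
        plan = simulate.richness_gradient_plan(
            min_richness=sim["min_richness"], max_richness=sim["max_richness"],
            n_sites=sim["n_sites"], n_nights=sim["n_nights"], seed=seed,
            detection_prob=sim["detection_prob"],
            clip_duration=sim["clip_duration"],
            anthropophony_db=sim["anthropophony_db"])
    elif sim["kind"] == "two_reserve":
        plan = simulate.two_reserve_plan(
            pool_overlap=sim["pool_overlap"], n_sites=sim["n_sites"],
            n_nights=sim["n_nights"], seed=seed,
            detection_prob=sim["detection_prob"],
            clip_duration=sim["clip_duration"],
            anthropophony_db=sim["anthropophony_db"])
    else:
        raise ValueError(f"unknown simulate.kind {sim['kind']!r}")
    study = simulate.generate_study(plan)
    return (study.clips, study.matrix, study.schedule, plan.reserve_of_site)


def _reserve_summary(matrix, richness: pd.DataFrame, site_means: pd.DataFrame,
                     reserve_of_site: dict) -> pd.DataFrame:
    """Per-reserve accumulated richness and mean index values."""
    rows = []
    rich = richness.copy()
    rich["reserve"] = rich["site_id"].map(reserve_of_site)
    sm = site_means.copy()
    sm["reserve"] = sm["site_id"].map(reserve_of_site)
    for reserve in sorted(set(reserve_of_site.values())):
        row: dict = {"reserve": reserve}
        sub = matrix.data[matrix.data["site_id"].map(reserve_of_site) == reserve]
        for group in annotations.GROUPS:
            cols = [s for s in matrix.sonotype_ids
                    if matrix.meta.loc[s, "taxon"] in annotations.GROUPS[group]]
            row[f"{group}_accumulated"] = int(
                (sub[cols].max(axis=0) > 0).sum()) if cols else 0
        for tag, tag_rows in sm[sm["reserve"] == reserve].groupby("dataset_tag"):
            for col in indices.INDEX_COLUMNS:
                row[f"{col}_{tag}"] = float(tag_rows[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _dissimilarity_report(matrix, site_means: pd.DataFrame,
                          reserve_of_site: dict, n_perm: int, seed: int,
                          nmds_restarts: int) -> dict:
    """Jaccard-on-insects vs Ruzicka-on-indices comparison tables."""
    insect = annotations.group_response(matrix, "insects")
    cols = [c for c in insect.columns if c not in ("site_id", "night_id")]
    presence = (insect.groupby("site_id")[cols].max() > 0).astype(int)
    d_jac = dissimilarity.jaccard_binary(presence)

    filt = site_means[site_means["dataset_tag"] == "filtered"]
    profile_src = filt.set_index("site_id")[list(indices.INDEX_COLUMNS)]
    profile = dissimilarity.prepare_index_profile(profile_src)
    d_ruz = dissimilarity.ruzicka(profile)

    out: dict = {"matrices": {}, "table": [], "nmds": {}}
    for name, dmat in (("insects_jaccard", d_jac), ("indices_ruzicka", d_ruz)):
        groups = {site: reserve_of_site[site] for site in dmat.labels}
        s = _sub_seed(seed, f"perm-{name}")
        pa = dissimilarity.permanova(dmat, groups, n_perm=n_perm, seed=s)
        pdisp = dissimilarity.permdisp(dmat, groups, n_perm=n_perm,
                                       seed=_sub_seed(seed, f"disp-{name}"))
        ord_res = dissimilarity.nmds(dmat, restarts=nmds_restarts,
                                     seed=_sub_seed(seed, f"nmds-{name}"))
        between, within = dissimilarity.mean_pairwise_dissimilarity(dmat, groups)
        row = {"metric": name, "between_dissimilarity": between,
               "permanova_p": pa.p_value, "permanova_r2": pa.r_squared,
               "permdisp_p": pdisp.p_value, "nmds_stress": ord_res.stress}
        row.update({f"within_{g}": w for g, w in within.items()})
        out["matrices"][name] = dmat
        out["table"].append(row)
        out["nmds"][name] = ord_res
    out["table"] = pd.DataFrame(out["table"])
    return out


def run_analysis(config: dict | None = None) -> dict:
    """Run the full pipeline; returns (and optionally writes) the bundle.

    Identical config + seed give identical outputs. The bundle maps
    names to DataFrames / result objects: clip_indices, site_means,
    richness, model_report, reserve_summary, dissimilarity, sm_scan
    (when requested), config.
    """
    cfg = validate_config(config)
    if cfg["audio_dir"] is not None:
        clips, matrix, schedule, reserve_of_site = load_study(cfg["audio_dir"])
    else:
        clips, matrix, schedule, reserve_of_site = _simulated_study(cfg)

    params = SpectrogramParams(window_length=cfg["spectrogram"]["window_length"],
                               overlap=cfg["spectrogram"]["overlap"])
    filt = cfg["filter"]
    richness = annotations.richness_table(matrix)
    seg = cfg["sm"]["segment_duration"]

    bundle: dict = {"config": cfg, "schedule": schedule,
                    "reserve_of_site": reserve_of_site, "richness": richness}

    sm_thresholds = dict(cfg["sm"]["thresholds"])
    if cfg["sm"]["scan"]:
        from .audio import compute_spectrogram, high_pass_filter
        grid_cfg = cfg["sm"]["grid"]
        grid = indices.sm_threshold_grid(grid_cfg["start"], grid_cfg["stop"],
                                         grid_cfg["step"])
        scans = {}
        for tag in ("raw", "filtered"):
            rows = []
            for clip in clips:
                work = (high_pass_filter(clip, cutoff=filt["cutoff_hz"],
                                         order=filt["order"],
                                         zero_phase=filt["zero_phase"])
                        if tag == "filtered" else clip)
                spec = compute_spectrogram(work, params)
                rows.append({"site_id": clip.site_id,
                             "night_id": clip.night_id,
                             "spread": indices.bin_snr_spread(
                                 spec, segment_duration=seg,
                                 normalize=cfg["sm"]["normalize"])})
            scans[tag] = indices.scan_sm_threshold(
                pd.DataFrame(rows), richness=richness, grid=grid,
                fit=models.poisson_r2_callback,
                reserve_of_site=reserve_of_site)
            sm_thresholds[tag] = scans[tag].chosen_threshold
        bundle["sm_scan"] = scans

    clip_table, site_means = indices.compute_index_table(
        clips, params=params, sm_thresholds=sm_thresholds,
        filter_cutoff=filt["cutoff_hz"], filter_order=filt["order"],
        zero_phase=filt["zero_phase"], segment_duration=seg,
        sm_normalize=cfg["sm"]["normalize"])
    bundle["clip_indices"] = clip_table
    bundle["site_means"] = site_means
    bundle["sm_thresholds"] = sm_thresholds

    bundle["model_report"] = models.run_model_grid(
        site_means, richness, reserve_of_site,
        families=tuple(cfg["families"]))
    bundle["reserve_summary"] = _reserve_summary(matrix, richness, site_means,
                                                 reserve_of_site)
    bundle["dissimilarity"] = _dissimilarity_report(
        matrix, site_means, reserve_of_site, cfg["n_permutations"],
        cfg["seed"], cfg["nmds_restarts"])

    if cfg["out_dir"] is not None:
        _write_bundle(bundle, Path(cfg["out_dir"]))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    bundle["clip_indices"].to_csv(out / "clip_indices.csv", index=False)
    bundle["site_means"].to_csv(out / "site_mean_indices.csv", index=False)
    bundle["richness"].to_csv(out / "richness.csv", index=False)
    bundle["model_report"].to_csv(out / "model_report.csv", index=False)
    bundle["reserve_summary"].to_csv(out / "reserve_summary.csv", index=False)
    diss = bundle["dissimilarity"]
    diss["table"].to_csv(out / "dissimilarity_report.csv", index=False)
    for name, dmat in diss["matrices"].items():
        dmat.to_frame().to_csv(out / f"distance_{name}.csv")
    for name, ordn in diss["nmds"].items():
        ordn.coordinates.to_csv(out / f"nmds_{name}.csv")
    if "sm_scan" in bundle:
        for tag, scan in bundle["sm_scan"].items():
            scan.table.to_csv(out / f"sm_scan_{tag}.csv", index=False)
    cfg = copy.deepcopy(bundle["config"])
    (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
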