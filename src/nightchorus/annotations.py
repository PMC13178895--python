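"""Sonotype presence-absence matrices and site-level richness responses.

A sonotype is a distinct, recurrent acoustic signal type used as a
species surrogate. The annotation product is a binary matrix with one
row per recording (site x night) and one column per sonotype, plus
per-sonotype metadata (taxon group and nominal frequency band).

Richness responses are computed per site for three groups:

- ``biophony``: all animal sonotypes (insects + frogs + birds + mammals)
- ``insects``: insect sonotypes only
- ``frogs_birds_mammals``: the low-frequency vertebrate group

``other`` sonotypes (anthropophony/geophony) never count toward
richness. *Accumulated* richness counts sonotypes detected at least
once across a site's nights; *mean* richness averages the per-night
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "TAXA",
    "GROUPS",
    "SonotypeMatrix",
    "load_sonotype_matrix",
    "group_response",
    "accumulate_site_richness",
    "richness_table",
]

logger = logging.getLogger(__name__)

TAXA = ("insect", "bird", "frog", "mammal", "other")

GROUPS = {
    "biophony": ("insect", "bird", "frog", "mammal"),
    "insects": ("insect",),
    "frogs_birds_mammals": ("bird", "frog", "mammal"),
}


@dataclass
class SonotypeMatrix:
    """Binary recordings x sonotypes matrix with per-sonotype metadata.

    ``data`` is indexed by recording id (``site_night``) with columns
    ``site_id``/``night_id`` followed by one 0/1 column per sonotype;
    ``meta`` is indexed by sonotype_id with columns taxon, f_low_hz,
    f_high_hz.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        sonos = self.sonotype_ids
        missing = [s for s in sonos if s not in self.meta.index]
        if missing:
            raise ValueError(f"sonotypes missing taxon metadata: {missing}")
        bad_taxa = set(self.meta["taxon"]) - set(TAXA)
        if bad_taxa:
            raise ValueError(f"unknown taxon labels: {sorted(bad_taxa)}")
        cells = self.data[sonos]
        bad = cells.stack()[~cells.stack().isin((0, 1))]
        if not bad.empty:
            row, col = bad.index[0]
            raise ValueError(
                f"non-binary cell at recording {row!r}, sonotype {col!r}: "
                f"{bad.iloc[0]!r}")

    @property
    def sonotype_ids(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("site_id", "night_id")]

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.data["site_id"].unique())


def _split_recording_id(rec_id: str) -> tuple[str, str]:
    """Split a ``site_night`` recording id at its last underscore."""
    site, sep, night = rec_id.rpartition("_")
    if not sep or not site or not night:
        raise ValueError(f"recording id {rec_id!r} is not of the form site_night")
    return site, night


def load_sonotype_matrix(matrix_path: str | Path,
                         meta_path: str | Path) -> SonotypeMatrix:
    """Load the presence-absence matrix CSV plus its metadata sidecar.

    The matrix CSV's first column is the recording id ``site_night``;
    remaining columns are sonotype ids with 0/1 cells. The metadata CSV
    has columns sonotype_id, taxon, f_low_hz, f_high_hz. Cells other
    than 0/1 and sonotypes without metadata raise.
    """
    raw = pd.read_csv(matrix_path, index_col=0)
    meta = pd.read_csv(meta_path).set_index("sonotype_id")
    parsed = [_split_recording_id(str(r)) for r in raw.index]
    data = raw.copy()
    data.insert(0, "site_id", [p[0] for p in parsed])
    data.insert(1, "night_id", [p[1] for p in parsed])
    return SonotypeMatrix(data=data, meta=meta)


def group_response(matrix: SonotypeMatrix, group: str) -> pd.DataFrame:
    """The binary sub-matrix of sonotypes belonging to a richness group.

    If several rows share a (site, night) pair — e.g. multiple clips
    per night were annotated — they are OR-combined into one row per
    recording, with a warning.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {sorted(GROUPS)}")
    taxa = GROUPS[group]
    cols = [s for s in matrix.sonotype_ids
            if matrix.meta.loc[s, "taxon"] in taxa]
    sub = matrix.data[["site_id", "night_id"] + cols]
    if sub.duplicated(["site_id", "night_id"]).any():
        logger.warning("multiple rows per site-night; OR-combining clips "
                       "into one recording row each")
        sub = sub.groupby(["site_id", "night_id"], as_index=False).max()
    return sub


def accumulate_site_richness(matrix: SonotypeMatrix,
                             group: str) -> pd.DataFrame:
    """Site-level accumulated and mean richness for one group.

    Accumulated richness counts the group's sonotypes present in at
    least one of the site's nights; mean richness is the average over
    nights of the per-night counts. Returns a table with columns
    site_id, group, accumulated_richness, mean_richness.
    """
    sub = group_response(matrix, group)
    cols = [c for c in sub.columns if c not in ("site_id", "night_id")]
    rows = []
    for site, site_rows in sub.groupby("site_id"):
        if cols:
            accumulated = int((site_rows[cols].max(axis=0) > 0).sum())
            mean = float(site_rows[cols].sum(axis=1).mean())
        else:
            accumulated, mean = 0, 0.0
        rows.append({"site_id": site, "group": group,
                     "accumulated_richness": accumulated,
                     "mean_richness": mean})
    return pd.DataFrame(rows)


def richness_table(matrix: SonotypeMatrix) -> pd.DataFrame:
    """Accumulated + mean richness for all three response groups."""
    return pd.concat([accumulate_site_richness(matrix, g) for g in GROUPS],
                     ignore_index=True)
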