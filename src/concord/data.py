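"""Core data containers and CSV ingestion for multi-taxon wetland surveys.

A dataset is a set of site-by-taxon abundance tables ("horizontal communities":
e.g. birds, aquatic macroinvertebrates, vascular plants) observed at the same
wetland sites, plus per-site metadata carrying a ponded-water permanence class
and four hydroperiod indicator variables (days ponded, maximum water depth,
amplitude:maximum-depth ratio, evaporative-loss index).  All downstream
congruence analysis requires the matrices to be row-matched on a common,
deterministically ordered site set, which is what :func:`align_sites` enforces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ponded-water permanence classes, ordered from most ephemeral to most permanent.
PERMANENCE_CLASSES = ("temporary", "seasonal", "semi-permanent", "permanent")

#: Hydroperiod-group membership: short = dries most summers, long = usually ponded.
SHORT_CLASSES = ("temporary", "seasonal")
LONG_CLASSES = ("semi-permanent", "permanent")
GROUP_LABELS = ("short", "long", "all")

#: Canonical column order of a hydroperiod indicator matrix.
HYDRO_VARIABLES = ("days_ponded", "max_depth", "amplitude_ratio", "evap_index")

_METADATA_CSV_COLUMNS = (
    "site_id",
    "permanence_class",
    "days_ponded",
    "max_depth_cm",
    "amplitude_ratio",
    "evap_index",
)


class DataValidationError(ValueError):
    """An input table violates a structural invariant (raised on load/validate)."""


def _check_unique(values: Sequence, what: str) -> None:
    seen: dict = {}
    dups = []
    for v in values:
        if v in seen and v not in dups:
            dups.append(v)
        seen[v] = True
    if dups:
        raise DataValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass(frozen=True)
class CommunityMatrix:
    """Non-negative site x taxon abundance table for one horizontal community.

    ``data`` is indexed by site ID with one column per taxon; values may be
    counts, densities per m**2, or percent cover.  At least 3 sites and 2 taxa
    are required (Procrustes superimposition needs >= 3 rows and >= 2
    dimensions).
    """

    data: pd.DataFrame
    label: str

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index), f"site IDs in community '{self.label}'")
        _check_unique(list(df.columns), f"taxon IDs in community '{self.label}'")
        if df.shape[0] < 3 or df.shape[1] < 2:
            raise DataValidationError(
                f"community '{self.label}' needs >= 3 sites and >= 2 taxa, "
                f"got {df.shape[0]} x {df.shape[1]}"
            )
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = df.index[np.isnan(values).any(axis=1)].tolist()
            raise DataValidationError(
                f"community '{self.label}' has missing abundance cells at sites "
                f"{bad}; blanks are data errors, not zeros"
            )
        if (values < 0).any():
            bad = df.index[(values < 0).any(axis=1)].tolist()
            raise DataValidationError(
                f"community '{self.label}' has negative abundances at sites {bad}"
            )

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, site_ids: Sequence) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[list(site_ids)], self.label)


@dataclass(frozen=True)
class HydroperiodMatrix:
    """Site x 4 table of hydroperiod indicators approximating the latent gradient."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(HYDRO_VARIABLES):
            raise DataValidationError(
                f"hydroperiod matrix columns must be {list(HYDRO_VARIABLES)}, "
                f"got {list(self.data.columns)}"
            )
        _check_unique(list(self.data.index), "site IDs in hydroperiod matrix")
        if self.data.isna().to_numpy().any():
            raise DataValidationError("hydroperiod matrix has missing cells")

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, site_ids: Sequence) -> "HydroperiodMatrix":
        return HydroperiodMatrix(self.data.loc[list(site_ids)])


@dataclass(frozen=True)
class SiteMetadata:
    """Per-site permanence class plus the four hydroperiod indicators.

    ``table`` is indexed by site ID with columns ``permanence_class`` and
    :data:`HYDRO_VARIABLES`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ("permanence_class",) + HYDRO_VARIABLES
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataValidationError(f"metadata missing columns: {missing}")
        _check_unique(list(self.table.index), "site IDs in metadata")
        bad = set(self.table["permanence_class"]) - set(PERMANENCE_CLASSES)
        if bad:
            raise DataValidationError(
                f"unknown permanence class(es) {sorted(bad)}; "
                f"allowed values are {list(PERMANENCE_CLASSES)}"
            )
        days = self.table["days_ponded"].to_numpy(dtype=float)
        if ((days < 0) | (days > 365)).any():
            raise DataValidationError("days_ponded must lie in [0, 365]")
        ratio = self.table["amplitude_ratio"].to_numpy(dtype=float)
        if ((ratio < 0) | (ratio > 1)).any():
            raise DataValidationError("amplitude_ratio must lie in [0, 1]")
        if (self.table["max_depth"].to_numpy(dtype=float) < 0).any():
            raise DataValidationError("max_depth must be >= 0")

    @property
    def site_ids(self) -> list:
        return list(self.table.index)

    def class_counts(self) -> dict:
        counts = self.table["permanence_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in PERMANENCE_CLASSES}

    def hydroperiod_matrix(self) -> HydroperiodMatrix:
        return HydroperiodMatrix(self.table[list(HYDRO_VARIABLES)].astype(float))

    def subset(self, site_ids: Sequence) -> "SiteMetadata":
        return SiteMetadata(self.table.loc[list(site_ids)])


def _read_community_csv(path: Path, label: str, exclude: Sequence[str] | None) -> CommunityMatrix:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected site-ID column plus taxon columns")
    site_col = df.columns[0]
    _check_unique(list(df[site_col]), f"site IDs in {path}")
    df = df.set_index(site_col)
    df.index = df.index.astype(str)
    if exclude:
        present = [c for c in exclude if c in df.columns]
        if present:
            logger.info("community '%s': excluding columns %s", label, present)
        df = df.drop(columns=present)
    return CommunityMatrix(df.astype(float), label)


def load_dataset(
    community_csvs: Mapping[str, Path | str],
    metadata_csv: Path | str,
    exclude_taxa: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[CommunityMatrix], SiteMetadata, HydroperiodMatrix]:
    """Read community abundance CSVs and the site-metadata CSV, validating both.

    Parameters
    ----------
    community_csvs
        Mapping of community label -> CSV path.  Each CSV has taxon codes as
        header, site IDs in the first column.
    metadata_csv
        CSV with columns ``site_id, permanence_class, days_ponded,
        max_depth_cm, amplitude_ratio, evap_index``.
    exclude_taxa
        Optional per-community list of column names to drop before validation
        (e.g. non-vascular cover classes in a plant table).

    Returns the validated community matrices (in the order given), the site
    metadata and the site x 4 hydroperiod indicator matrix.  Matrices are not
    yet row-aligned; call :func:`align_sites` next.
    """
    exclude_taxa = exclude_taxa or {}
    communities = [
        _read_community_csv(Path(p), label, exclude_taxa.get(label))
        for label, p in community_csvs.items()
    ]

    meta_df = pd.read_csv(metadata_csv)
    missing = [c for c in _METADATA_CSV_COLUMNS if c not in meta_df.columns]
    if missing:
        raise DataValidationError(f"{metadata_csv}: missing metadata columns {missing}")
    _check_unique(list(meta_df["site_id"]), f"site IDs in {metadata_csv}")
    meta_df = meta_df.set_index("site_id").rename(columns={"max_depth_cm": "max_depth"})
    meta_df.index = meta_df.index.astype(str)
    meta = SiteMetadata(meta_df[["permanence_class", *HYDRO_VARIABLES]])

    logger.info("loaded %d communities, %d metadata sites", len(communities), len(meta.site_ids))
    logger.info("permanence class counts: %s", meta.class_counts())
    for cm in communities:
        logger.info(
            "community '%s': %d sites x %d taxa", cm.label, len(cm.site_ids), len(cm.taxon_ids)
        )
    return communities, meta, meta.hydroperiod_matrix()


def align_sites(
    matrices: Sequence[CommunityMatrix],
    hydro: HydroperiodMatrix,
    meta: SiteMetadata | None = None,
):
    """Restrict every matrix to the common site set, ordered lexicographically.

    Sites present in some tables but not others are dropped everywhere (and
    logged); Procrustes needs row-matched configurations, so fewer than 3
    shared sites is a hard error.  Returns ``(matrices, hydro)`` or
    ``(matrices, hydro, meta)`` with identical site order in every output.
    """
    sets = [set(m.site_ids) for m in matrices] + [set(hydro.site_ids)]
    if meta is not None:
        sets.append(set(meta.site_ids))
    common = set.intersection(*sets)
    if len(common) < 3:
        raise DataValidationError(
            f"only {len(common)} site(s) shared across all matrices; need >= 3"
        )
    order = sorted(common, key=str)
    for m in matrices:
        dropped = sorted(set(m.site_ids) - common, key=str)
        if dropped:
            logger.warning(
                "community '%s': dropping %d site(s) absent elsewhere: %s",
                m.label, len(dropped), dropped,
            )
    aligned = [m.subset(order) for m in matrices]
    hydro_aligned = hydro.subset(order)
    if meta is None:
        return aligned, hydro_aligned
    return aligned, hydro_aligned, meta.subset(order)


def assign_group(meta: SiteMetadata, label: str) -> list:
    """Return the ordered site IDs whose permanence class belongs to a group.

    ``short`` = temporary + seasonal wetlands, ``long`` = semi-permanent +
    permanent, ``all`` = every class.  Site order follows the metadata table.
    """
    if label not in GROUP_LABELS:
        raise ValueError(f"group label must be one of {list(GROUP_LABELS)}, got {label!r}")
    if label == "all":
        members = set(PERMANENCE_CLASSES)
    elif label == "short":
        members = set(SHORT_CLASSES)
    else:
        members = set(LONG_CLASSES)
    mask = meta.table["permanence_class"].isin(members)
    sites = list(meta.table.index[mask])
    if not sites:
        raise DataValidationError(f"hydroperiod group '{label}' contains no sites")
    logger.info("group '%s': %d sites", label, len(sites))
    return sites
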