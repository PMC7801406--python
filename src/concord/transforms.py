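"""Pre-transformations that make matrices comparable in Euclidean space.

Community tables get the Hellinger transform (row-wise square-rooted relative
abundances), hydroperiod indicators get column z-scores so that days (0-365)
do not dominate a 0-1 ratio under the unit-trace scaling of the Procrustes
fit, and the narrower of two matrices gets zero-filled columns so both share a
dimension.  Also derives the four hydroperiod indicators from raw staff-gauge
readings.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import CommunityMatrix, HydroperiodMatrix, HYDRO_VARIABLES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformedMatrix:
    """A site x variable real matrix with a provenance tag.

    ``kind`` records how the matrix was produced: ``hellinger`` (community
    relative abundances), ``zscore`` (standardized environmental indicators)
    or ``padded`` (zero-columns appended for dimension matching).
    """

    data: pd.DataFrame
    kind: str
    label: str = ""

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def column_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def hellinger(m: CommunityMatrix) -> TransformedMatrix:
    """Hellinger transform: ``out[i, j] = sqrt(x[i, j] / rowsum(i))``.

    Every non-empty row ends up with unit Euclidean norm, making relative
    abundance profiles live on the unit sphere; the transform is invariant to
    multiplying a row by a positive scalar.  All-zero rows (sites where the
    community was not observed at all) are kept as zero rows so that row
    matching across communities is preserved; they are logged as empty sites.
    """
    x = m.values
    rowsum = x.sum(axis=1)
    empty = rowsum == 0
    if empty.any():
        logger.warning(
            "community '%s': %d empty site(s) kept as zero rows: %s",
            m.label, int(empty.sum()), list(np.asarray(m.site_ids)[empty]),
        )
    safe = np.where(empty, 1.0, rowsum)
    out = np.sqrt(x / safe[:, None])
    out[empty] = 0.0
    return TransformedMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        kind="hellinger",
        label=m.label,
    )


def standardize_env(h: HydroperiodMatrix) -> TransformedMatrix:
    """Column z-scores of the hydroperiod indicators (population SD, ddof=0).

    A zero-variance column carries no gradient information and becomes all
    zeros (logged).  The matrix is treated as the full analysis population,
    hence the population rather than sample SD; either choice cancels in the
    Procrustes scaling but must be fixed for reproducibility.
    """
    if len(h.site_ids) < 2:
        raise ValueError("standardization needs at least 2 sites")
    x = h.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    flat = sd == 0
    if flat.any():
        cols = [c for c, f in zip(h.data.columns, flat) if f]
        logger.warning("zero-variance indicator column(s) set to 0: %s", cols)
    out = (x - mean) / np.where(flat, 1.0, sd)
    out[:, flat] = 0.0
    return TransformedMatrix(
        pd.DataFrame(out, index=h.data.index, columns=h.data.columns),
        kind="zscore",
        label="hydroperiod",
    )


def pad_to_common_dimension(
    x: TransformedMatrix, y: TransformedMatrix
) -> tuple[TransformedMatrix, TransformedMatrix]:
    """Append all-zero columns to the narrower matrix so widths match.

    Zero columns contribute nothing to the centered cross-product, so the
    Procrustes statistic is unchanged; they only equalize the embedding
    dimension.  Existing cells are never modified and the wider matrix passes
    through untouched.
    """
    if x.site_ids != y.site_ids:
        raise ValueError("pad_to_common_dimension requires identical site order")

    def _pad(t: TransformedMatrix, width: int) -> TransformedMatrix:
        extra = width - t.data.shape[1]
        if extra <= 0:
            return t
        pad_cols = [f"_pad{k}" for k in range(extra)]
        padded = t.data.copy()
        padded[pad_cols] = 0.0
        return TransformedMatrix(padded, kind="padded", label=t.label)

    width = max(x.data.shape[1], y.data.shape[1])
    return _pad(x, width), _pad(y, width)


@dataclass(frozen=True)
class GaugeSeries:
    """Repeated staff-gauge water-depth readings for one wetland, May-September.

    ``dry_date`` is the date the wetland was first observed dry; if it stayed
    flooded through September the site is credited with ponded water for the
    whole year (365 days) and ``dry_date`` may be absent.
    """

    site_id: str
    dates: Sequence[_dt.date]
    depths_cm: Sequence[float]
    flooded_through_september: bool
    evap_index: float
    dry_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if len(self.dates) != len(self.depths_cm):
            raise ValueError(f"site {self.site_id}: dates/depths length mismatch")
        if len(self.depths_cm) < 2:
            raise ValueError(f"site {self.site_id}: need at least 2 gauge readings")
        if any(d < 0 for d in self.depths_cm):
            raise ValueError(f"site {self.site_id}: negative depth reading")


def derive_hydro_indicators(g: GaugeSeries) -> pd.Series:
    """One hydroperiod-indicator row (days ponded, max depth, amplitude ratio,
    evaporative index) from a season of gauge readings.

    days_ponded is 365 for sites flooded through September, otherwise the
    calendar days from the first (installation) reading to the first observed
    dry date.  The amplitude ratio is (deepest - shallowest) / deepest, 0 for
    a site that never held measurable water.
    """
    if g.flooded_through_september:
        days = 365.0
    else:
        if g.dry_date is None:
            raise ValueError(
                f"site {g.site_id}: hydroperiod undetermined - not flooded through "
                "September but no dry date recorded"
            )
        days = float((g.dry_date - min(g.dates)).days)
        if days < 0:
            raise ValueError(f"site {g.site_id}: dry date precedes first reading")
        days = min(days, 365.0)
    depth_max = float(max(g.depths_cm))
    depth_min = float(min(g.depths_cm))
    ratio = (depth_max - depth_min) / depth_max if depth_max > 0 else 0.0
    return pd.Series(
        {
            "days_ponded": days,
            "max_depth": depth_max,
            "amplitude_ratio": ratio,
            "evap_index": float(g.evap_index),
        },
        name=g.site_id,
    )


def read_gauge_csv(path: Path | str) -> list[GaugeSeries]:
    """Read a long-format gauge CSV: site_id, date, depth_cm, plus per-site
    dry_date (blank if none), flooded_through_september, evap_index."""
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for site_id, grp in df.groupby("site_id", sort=True):
        grp = grp.sort_values("date")
        dry_raw = grp["dry_date"].dropna()
        dry = pd.to_datetime(dry_raw.iloc[0]).date() if len(dry_raw) else None
        out.append(
            GaugeSeries(
                site_id=str(site_id),
                dates=[d.date() for d in grp["date"]],
                depths_cm=list(grp["depth_cm"].astype(float)),
                flooded_through_september=bool(grp["flooded_through_september"].iloc[0]),
                evap_index=float(grp["evap_index"].iloc[0]),
                dry_date=dry,
            )
        )
    return out


def hydro_matrix_from_gauges(gauges: Sequence[GaugeSeries]) -> HydroperiodMatrix:
    """Stack per-site indicator rows into a HydroperiodMatrix."""
    rows = pd.DataFrame([derive_hydro_indicators(g) for g in gauges])
    rows.index.name = "site_id"
    return HydroperiodMatrix(rows[list(HYDRO_VARIABLES)])
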