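"""Comparative logic: cross-community vs community-environment congruence.

The hypothesis framework contrasts two worlds.  If horizontal communities
merely respond in parallel to the hydroperiod gradient, cross-community
congruence should be about as strong as each community's congruence with the
hydroperiod indicators ("environment-consistent").  If biological
interactions couple the communities directly, cross-community congruence
should clearly exceed the community-environment congruence
("interactions-dominant").  The elevation statistic quantifies the excess as
a percentage per community; a second contrast asks whether cross-community
congruence differs between short- and long-hydroperiod wetland groups
(non-stationarity), judged by overlap of the bootstrap confidence intervals.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

INTERACTIONS_DOMINANT = "interactions-dominant"
ENVIRONMENT_CONSISTENT = "environment-consistent"

#: Label under which the hydroperiod indicator matrix enters pair names.
ENV_LABEL = "hydroperiod"


def pair_name(a: str, b: str) -> str:
    """Canonical (order-independent) name for a matrix pair."""
    return "~".join(sorted((a, b)))


@dataclass(frozen=True)
class CongruenceRecord:
    """One bar of the summary figure: a group x matrix-pair congruence."""

    group: str
    pair: str
    mean_r: float
    ci_low: float
    ci_high: float
    median_p: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "pair": self.pair,
            "mean_r": self.mean_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "median_p": self.median_p,
            "significant": bool(self.significant),
        }


@dataclass(frozen=True)
class CongruenceTable:
    """All group x pair congruence records for one analysis.

    With three communities there are six pairs per group (three
    cross-community, three community-hydroperiod) and three groups
    (all / short / long), hence 18 records in a full run.
    """

    records: tuple[CongruenceRecord, ...]
    communities: tuple[str, ...]
    env_label: str = ENV_LABEL

    def get(self, group: str, a: str, b: str) -> CongruenceRecord:
        name = pair_name(a, b)
        for rec in self.records:
            if rec.group == group and rec.pair == name:
                return rec
        raise KeyError(f"no record for group={group!r} pair={name!r}")

    def has_group(self, group: str) -> bool:
        return any(rec.group == group for rec in self.records)

    def cross_pairs(self) -> list[tuple[str, str]]:
        labels = self.communities
        return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([rec.to_dict() for rec in self.records])


@dataclass(frozen=True)
class ElevationSummary:
    """How much cross-community congruence exceeds congruence with hydroperiod.

    ``per_community`` maps each community to its percent elevation; ``mean``
    and ``se`` (sample SD over communities / sqrt(k)) summarize them, and
    ``interpretation`` classifies the outcome against the hypothesis
    framework.
    """

    per_community: dict[str, float]
    mean: float
    se: float
    interpretation: str

    def to_dict(self) -> dict:
        return {
            "per_community_percent": dict(self.per_community),
            "mean_percent": self.mean,
            "se_percent": self.se,
            "interpretation": self.interpretation,
        }


def percent_elevation(r_cross_values: Sequence[float], r_env: float) -> float:
    """Percent by which a community's mean cross-community r exceeds its r
    with the hydroperiod matrix: 100 * (mean(r_cross) - r_env) / r_env."""
    if r_env <= 0:
        raise ValueError(
            "community-environment r must be positive; a zero value suggests a "
            "degenerate environment matrix"
        )
    vals = list(r_cross_values)
    if not vals:
        raise ValueError("need at least one cross-community r value")
    return 100.0 * (statistics.fmean(vals) - r_env) / r_env


def elevation_summary(
    percents: Mapping[str, float] | Sequence[float],
    ci_excludes_env: bool | None = None,
) -> ElevationSummary:
    """Mean and SE of per-community percent elevations, plus interpretation.

    ``percents`` is one percent-elevation value per community (mapping or
    sequence).  The outcome is classified interactions-dominant when the mean
    elevation is positive and, if supplied, ``ci_excludes_env`` is True --
    i.e. every cross-pair confidence interval lies above the corresponding
    community-hydroperiod r (see :func:`classify_congruence`, which derives
    that flag from a CongruenceTable).
    """
    if isinstance(percents, Mapping):
        per = {str(k): float(v) for k, v in percents.items()}
    else:
        per = {f"community_{i + 1}": float(v) for i, v in enumerate(percents)}
    if len(per) < 2:
        raise ValueError("need elevations for at least 2 communities")
    vals = list(per.values())
    mean = statistics.fmean(vals)
    se = statistics.stdev(vals) / len(vals) ** 0.5
    dominant = mean > 0 and (ci_excludes_env is None or ci_excludes_env)
    return ElevationSummary(
        per_community=per,
        mean=mean,
        se=se,
        interpretation=INTERACTIONS_DOMINANT if dominant else ENVIRONMENT_CONSISTENT,
    )


def classify_congruence(table: CongruenceTable, group: str = "all") -> ElevationSummary:
    """Elevation summary for one group of a congruence table.

    A community's cross-community r values are the mean_r of every cross pair
    involving it (two per community with three communities); its environment
    r is the mean_r of its pair with the hydroperiod matrix.  The
    interactions-dominant call additionally requires every cross-pair CI to
    lie entirely above both member communities' environment r values.
    """
    env = {c: table.get(group, c, table.env_label).mean_r for c in table.communities}
    percents = {}
    for c in table.communities:
        cross = [
            table.get(group, a, b).mean_r for a, b in table.cross_pairs() if c in (a, b)
        ]
        percents[c] = percent_elevation(cross, env[c])
    excludes = all(
        table.get(group, a, b).ci_low > max(env[a], env[b])
        for a, b in table.cross_pairs()
    )
    return elevation_summary(percents, ci_excludes_env=excludes)


def stationarity_contrast(table: CongruenceTable) -> pd.DataFrame:
    """Long-minus-short contrast of congruence per matrix pair.

    For every pair, delta_r = mean_r(long) - mean_r(short); the pair is judged
    "stationary" when the two groups' confidence intervals overlap (mirroring
    a visual error-bar comparison; no formal two-sample test is implied).
    """
    for g in ("short", "long"):
        if not table.has_group(g):
            raise ValueError(f"congruence table lacks group '{g}'")
    rows = []
    pairs = table.cross_pairs() + [(c, table.env_label) for c in table.communities]
    for a, b in pairs:
        short = table.get("short", a, b)
        long_ = table.get("long", a, b)
        overlap = short.ci_low <= long_.ci_high and long_.ci_low <= short.ci_high
        rows.append(
            {
                "pair": pair_name(a, b),
                "delta_r": long_.mean_r - short.mean_r,
                "ci_overlap": bool(overlap),
                "verdict": "stationary" if overlap else "non-stationary",
            }
        )
    return pd.DataFrame(rows)
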