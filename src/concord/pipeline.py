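"""End-to-end orchestration: load/simulate -> transform -> rarefy -> bootstrap
-> compare -> report.

A run produces, in order: rarefaction curves with a plateau estimate for all
six matrix pairs; a congruence table (mean r, percentile CI, median PROTEST p)
for the all / short / long site groups at the balanced subsample size; the
elevation summary classifying the outcome against the hypothesis framework;
the long-vs-short stationarity contrast; and a manifest sufficient to re-run
the identical analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .comparison import (
    ENV_LABEL,
    CongruenceRecord,
    CongruenceTable,
    ElevationSummary,
    classify_congruence,
    pair_name,
    stationarity_contrast,
)
from .data import align_sites, assign_group, load_dataset
from .resampling import balanced_bootstrap, detect_plateau, rarefaction_curve
from .synthetic import SyntheticScenario, generate_dataset
from .transforms import hellinger, standardize_env

logger = logging.getLogger(__name__)

GROUPS = ("all", "short", "long")


@dataclass(frozen=True)
class RarefactionSettings:
    n_min: int = 3
    n_max: int = 40
    iterations: int = 100
    plateau_tol: float = 0.01
    plateau_run: int = 3
    enabled: bool = True


@dataclass(frozen=True)
class BootstrapSettings:
    n_target: int | None = None  # None: size of the smaller hydroperiod group
    iterations: int = 1000
    permutations: int = 199
    sig_iterations: int | None = None  # None: every iteration


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, serializable description of one analysis run.

    Exactly one of ``scenario`` (synthetic data) or ``community_csvs`` +
    ``metadata_csv`` (field data) must be provided.  ``alpha`` is the
    significance threshold applied to the median PROTEST p (0.1 by
    convention of the emulated design), ``ci_level`` the bootstrap
    percentile-interval level (0.9).
    """

    scenario: SyntheticScenario | None = None
    community_csvs: Mapping[str, str] | None = None
    metadata_csv: str | None = None
    exclude_taxa: Mapping[str, list] | None = None
    rarefaction: RarefactionSettings = field(default_factory=RarefactionSettings)
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    alpha: float = 0.1
    ci_level: float = 0.9
    seed: int = 0
    output_dir: str | None = None
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        has_files = self.community_csvs is not None and self.metadata_csv is not None
        if self.scenario is None and not has_files:
            raise ValueError("provide either a synthetic scenario or input CSV paths")
        if self.scenario is not None and has_files:
            raise ValueError("provide a scenario or CSV paths, not both")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "scenario" in d and d["scenario"] is not None:
            sc = d["scenario"]
            if "class_thresholds" in sc:
                sc["class_thresholds"] = tuple(sc["class_thresholds"])
            d["scenario"] = SyntheticScenario(**sc)
        if "rarefaction" in d:
            d["rarefaction"] = RarefactionSettings(**d["rarefaction"])
        if "bootstrap" in d:
            d["bootstrap"] = BootstrapSettings(**d["bootstrap"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("scenario") is not None:
            d["scenario"]["taxa_per_community"] = dict(d["scenario"]["taxa_per_community"])
            d["scenario"]["class_thresholds"] = list(d["scenario"]["class_thresholds"])
        return d


@dataclass(frozen=True)
class PipelineReport:
    """Everything a run computed, serializable to JSON/CSV."""

    rarefaction: pd.DataFrame
    plateaus: dict[str, int | None]
    table: CongruenceTable
    elevation: ElevationSummary
    stationarity: pd.DataFrame
    manifest: dict

    def to_json_dict(self) -> dict:
        return {
            "rarefaction": self.rarefaction.to_dict(orient="records"),
            "plateaus": self.plateaus,
            "congruence": [rec.to_dict() for rec in self.table.records],
            "elevation": self.elevation.to_dict(),
            "stationarity": self.stationarity.to_dict(orient="records"),
            "manifest": self.manifest,
        }


def _spawn_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full congruence analysis described by ``cfg``."""
    t0 = time.monotonic()
    if cfg.scenario is not None:
        scenario = dataclasses.replace(cfg.scenario, seed=cfg.seed)
        logger.info("stage 0: generating synthetic dataset (seed %d)", cfg.seed)
        communities, meta, hydro, _ = generate_dataset(scenario)
    else:
        logger.info("stage 0: loading dataset from CSV")
        communities, meta, hydro = load_dataset(
            cfg.community_csvs, cfg.metadata_csv, cfg.exclude_taxa
        )
    communities, hydro, meta = align_sites(communities, hydro, meta)
    labels = tuple(cm.label for cm in communities)

    logger.info("stage 1: transforming matrices (Hellinger + indicator z-scores)")
    transformed = {cm.label: hellinger(cm) for cm in communities}
    transformed[ENV_LABEL] = standardize_env(hydro)

    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    pairs += [(c, ENV_LABEL) for c in labels]

    rng_rare, rng_boot = _spawn_seeds(cfg.seed, 2)

    rare_frames = []
    plateaus: dict[str, int | None] = {}
    if cfg.rarefaction.enabled:
        logger.info("stage 2: rarefaction sweep over %d pairs", len(pairs))
        n_max = min(cfg.rarefaction.n_max, len(meta.site_ids))
        for a, b in pairs:
            curve = rarefaction_curve(
                transformed[a],
                transformed[b],
                n_min=cfg.rarefaction.n_min,
                n_max=n_max,
                iterations=cfg.rarefaction.iterations,
                seed=rng_rare,
                label=pair_name(a, b),
            )
            rare_frames.append(curve.to_frame())
            plateaus[pair_name(a, b)] = detect_plateau(
                curve, tol=cfg.rarefaction.plateau_tol, run=cfg.rarefaction.plateau_run
            )
    rarefaction = (
        pd.concat(rare_frames, ignore_index=True)
        if rare_frames
        else pd.DataFrame(columns=["pair", "n", "mean_r", "se_r", "iterations"])
    )

    logger.info("stage 3: stratified balanced bootstrap (groups %s)", GROUPS)
    records = []
    for group in GROUPS:
        for a, b in pairs:
            summary = balanced_bootstrap(
                transformed[a],
                transformed[b],
                meta,
                group=group,
                n_target=cfg.bootstrap.n_target,
                iterations=cfg.bootstrap.iterations,
                permutations=cfg.bootstrap.permutations,
                sig_iterations=cfg.bootstrap.sig_iterations,
                alpha=cfg.alpha,
                ci_level=cfg.ci_level,
                seed=rng_boot,
                label=pair_name(a, b),
            )
            records.append(
                CongruenceRecord(
                    group=group,
                    pair=pair_name(a, b),
                    mean_r=summary.mean_r,
                    ci_low=summary.ci_low,
                    ci_high=summary.ci_high,
                    median_p=summary.median_p,
                    significant=summary.significant,
                )
            )
    table = CongruenceTable(records=tuple(records), communities=labels, env_label=ENV_LABEL)

    logger.info("stage 4: elevation summary and stationarity contrast")
    elevation = classify_congruence(table, group="all")
    stationarity = stationarity_contrast(table)

    manifest = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "n_sites": len(meta.site_ids),
        "class_counts": meta.class_counts(),
        "group_sizes": {g: len(assign_group(meta, g)) for g in GROUPS},
        "wall_clock_s": round(time.monotonic() - t0, 3),
    }
    report = PipelineReport(
        rarefaction=rarefaction,
        plateaus=plateaus,
        table=table,
        elevation=elevation,
        stationarity=stationarity,
        manifest=manifest,
    )
    if cfg.output_dir is not None:
        write_report(report, cfg.output_dir, make_figures=cfg.make_figures)
    return report


def write_report(report: PipelineReport, out_dir: Path | str, make_figures: bool = False) -> None:
    """Write report.json, congruence_table.csv, rarefaction.csv, manifest.json
    (and optionally a bar-chart figure) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    report.table.to_frame().to_csv(out / "congruence_table.csv", index=False)
    report.rarefaction.to_csv(out / "rarefaction.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))
    if make_figures:
        _figure(report, out / "congruence.png")
    logger.info("report written to %s", out)


def _figure(report: PipelineReport, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.table.to_frame()
    groups = list(dict.fromkeys(df["group"]))
    pairs = list(dict.fromkeys(df["pair"]))
    fig, ax = plt.subplots(figsize=(1.6 * len(pairs) + 2, 4))
    width = 0.8 / len(groups)
    xs = np.arange(len(pairs))
    for gi, g in enumerate(groups):
        sub = df[df["group"] == g].set_index("pair").loc[pairs]
        pos = xs + (gi - (len(groups) - 1) / 2) * width
        err = np.vstack(
            [sub["mean_r"] - sub["ci_low"], sub["ci_high"] - sub["mean_r"]]
        ).clip(min=0)
        ax.bar(pos, sub["mean_r"], width=width, yerr=err, capsize=3, label=g)
        for x, rec in zip(pos, sub.itertuples()):
            if rec.significant:
                ax.text(x, rec.ci_high + 0.02, "*", ha="center")
    ax.set_xticks(xs, pairs, rotation=30, ha="right")
    ax.set_ylabel("Procrustes r")
    ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
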