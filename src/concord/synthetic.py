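"""Gradient-structured synthetic wetlands with tunable cross-community coupling.

The generator realizes the statistical world the analysis assumes: each site
has a latent hydroperiod position h ~ Uniform(0, 1); four noisy indicator
variables (days ponded, max depth, amplitude ratio, evaporative index) are
monotone functions of h; a permanence class follows from fixed thresholds on
h; and each community's taxa have Gaussian niches along h (optima equally
spaced, shared width sigma), with overdispersed counts drawn around the
expected abundances (gamma-mixed Poisson, i.e. negative-binomial-like).

The single interesting knob is the coupling strength kappa in [0, 1]: bird
expected abundances are a (1 - kappa) : kappa blend of their own niche
response and a "habitat" term - a fixed random non-negative mixture of the
site's Hellinger-transformed plant and invertebrate profiles, rescaled to the
same mean abundance.  kappa = 0 gives a world where any cross-community
congruence reflects parallel response to h; kappa near 1 gives a world where
birds track the other communities directly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import (
    HYDRO_VARIABLES,
    PERMANENCE_CLASSES,
    CommunityMatrix,
    HydroperiodMatrix,
    SiteMetadata,
)
from .transforms import hellinger

logger = logging.getLogger(__name__)

#: Indicator model: value = scale * (offset + slope * h) + noise, then clipped.
_INDICATOR_MODEL = {
    #  name:            (offset, slope, scale, clip_lo, clip_hi)
    "days_ponded": (0.0, 1.0, 365.0, 0.0, 365.0),
    "max_depth": (0.0, 1.0, 120.0, 0.0, None),
    "amplitude_ratio": (1.0, -0.8, 1.0, 0.0, 1.0),
    "evap_index": (1.0, -1.0, 1.0, None, None),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic wetland landscape.

    Defaults mirror the emulated study design: 96 sites whose class
    thresholds (cumulative 28/96, 63/96, 80/96 of the latent gradient) give
    the four permanence classes their designed expected frequencies, and
    three communities of 40 / 60 / 80 taxa.  ``niche_width`` (sigma, the SD
    of the Gaussian niche on the unit gradient) is per-community: sharply
    filtered sessile/aquatic communities get narrow niches (0.12 for plants
    and invertebrates) while the mobile, habitat-integrating community gets
    broad ones (0.3 for birds), so that at kappa = 0 the bird configuration
    resembles the near-linear indicator matrix more than the tightly curved
    plant/invertebrate manifolds - two communities with *identical* sharp
    niche structure are otherwise almost perfectly congruent with each other
    regardless of coupling, which would leave nothing for kappa to reveal.
    ``indicator_noise_sd`` is measurement noise as a fraction of each
    indicator's range; ``dispersion`` is the gamma shape of the count mixing
    (Poisson as dispersion -> inf); ``coupling`` is kappa;
    ``coupling_sparsity`` is the expected fraction of plant/invertebrate
    taxa feeding each coupled taxon's habitat term (sparse mixtures keep the
    coupled configuration sharp instead of averaging it away).  With
    ``gradient_free`` the niche structure is replaced by i.i.d. random
    expected abundances (a pure-noise null with no shared gradient).
    """

    n_sites: int = 96
    class_thresholds: tuple[float, float, float] = (0.2917, 0.6563, 0.8333)
    taxa_per_community: Mapping[str, int] = field(
        default_factory=lambda: {"birds": 40, "invertebrates": 60, "plants": 80}
    )
    coupled_community: str = "birds"
    niche_width: float | Mapping[str, float] = field(
        default_factory=lambda: {"birds": 0.3, "invertebrates": 0.12, "plants": 0.12}
    )
    max_abundance: float = 50.0
    coupling: float = 0.6
    indicator_noise_sd: float = 0.05
    dispersion: float = 10.0
    coupling_sparsity: float = 0.03
    gradient_free: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling kappa must lie in [0, 1]")
        th = self.class_thresholds
        if not (0 < th[0] < th[1] < th[2] < 1):
            raise ValueError("class thresholds must be strictly increasing in (0, 1)")
        if self.coupled_community not in self.taxa_per_community:
            raise ValueError(
                f"coupled community {self.coupled_community!r} not among "
                f"{list(self.taxa_per_community)}"
            )
        for label in self.taxa_per_community:
            if self.sigma(label) <= 0:
                raise ValueError(f"niche width for '{label}' must be > 0")

    def sigma(self, label: str) -> float:
        if isinstance(self.niche_width, Mapping):
            return float(self.niche_width[label])
        return float(self.niche_width)

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["taxa_per_community"] = dict(d["taxa_per_community"])
        d["class_thresholds"] = list(d["class_thresholds"])
        if isinstance(self.niche_width, Mapping):
            d["niche_width"] = dict(self.niche_width)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SyntheticScenario":
        d = yaml.safe_load(Path(path).read_text())
        if "class_thresholds" in d:
            d["class_thresholds"] = tuple(d["class_thresholds"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Latent state behind a generated dataset, for recovery tests."""

    h: np.ndarray
    classes: tuple[str, ...]
    kappa: float
    niche_optima: dict[str, np.ndarray]


def _site_ids(n: int) -> list[str]:
    return [f"W{i:03d}" for i in range(1, n + 1)]  # zero-padded: lexicographic == numeric


def generate_landscape(
    s: SyntheticScenario, rng: np.random.Generator | None = None
) -> tuple[SiteMetadata, HydroperiodMatrix, GroundTruth]:
    """Draw the latent gradient, permanence classes and noisy indicators."""
    rng = rng if rng is not None else np.random.default_rng(s.seed)
    h = rng.uniform(0.0, 1.0, size=s.n_sites)
    cls_idx = np.searchsorted(np.asarray(s.class_thresholds), h)
    classes = tuple(PERMANENCE_CLASSES[i] for i in cls_idx)

    cols = {}
    for name, (offset, slope, scale, lo, hi) in _INDICATOR_MODEL.items():
        span = abs(slope) * scale
        noise = rng.normal(0.0, s.indicator_noise_sd * span, size=s.n_sites)
        vals = scale * (offset + slope * h) + noise
        cols[name] = np.clip(vals, lo, hi)
    ids = _site_ids(s.n_sites)
    table = pd.DataFrame({"permanence_class": classes, **cols}, index=pd.Index(ids, name="site_id"))
    meta = SiteMetadata(table[["permanence_class", *HYDRO_VARIABLES]])
    truth = GroundTruth(h=h, classes=classes, kappa=s.coupling, niche_optima={})
    return meta, meta.hydroperiod_matrix(), truth


def _niche_expectation(h: np.ndarray, optima: np.ndarray, sigma: float, a: float) -> np.ndarray:
    return a * np.exp(-((h[:, None] - optima[None, :]) ** 2) / (2.0 * sigma**2))


def _overdispersed_counts(
    expected: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-mixed Poisson draw around the expectation (mean preserved)."""
    lam = np.zeros_like(expected)
    pos = expected > 0
    lam[pos] = rng.gamma(shape=dispersion, scale=expected[pos] / dispersion)
    return rng.poisson(lam).astype(float)


def generate_communities(
    s: SyntheticScenario,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[CommunityMatrix]:
    """Realize the three community matrices from the latent gradient.

    Uncoupled communities (plants, invertebrates) are generated first; the
    coupled community (birds) then blends its own niche response with a fixed
    sparse non-negative mixture of the others' realized Hellinger profiles,
    weighted (1 - kappa) : kappa and drawn with the same count noise.
    """
    rng = rng if rng is not None else np.random.default_rng(s.seed)
    h = truth.h
    ids = _site_ids(len(h))
    a = s.max_abundance

    def niche_term(label: str) -> np.ndarray:
        p = s.taxa_per_community[label]
        if s.gradient_free:
            truth.niche_optima[label] = np.full(p, np.nan)
            return rng.gamma(shape=1.0, scale=a, size=(len(h), p))
        optima = np.linspace(0.0, 1.0, p)
        truth.niche_optima[label] = optima
        return _niche_expectation(h, optima, s.sigma(label), a)

    uncoupled = [lb for lb in s.taxa_per_community if lb != s.coupled_community]
    matrices: dict[str, CommunityMatrix] = {}
    for label in uncoupled:
        counts = _overdispersed_counts(niche_term(label), s.dispersion, rng)
        df = pd.DataFrame(
            counts, index=pd.Index(ids, name="site_id"),
            columns=[f"{label[:3]}_{j:03d}" for j in range(counts.shape[1])],
        )
        matrices[label] = CommunityMatrix(df, label)

    label = s.coupled_community
    p = s.taxa_per_community[label]
    own = niche_term(label)
    profiles = np.hstack([hellinger(matrices[lb]).values for lb in uncoupled])
    weights = rng.exponential(1.0, size=(p, profiles.shape[1]))
    mask = rng.random((p, profiles.shape[1])) < s.coupling_sparsity
    for j in range(p):  # every coupled taxon must depend on something
        if not mask[j].any():
            mask[j, rng.integers(profiles.shape[1])] = True
    weights *= mask
    habitat = profiles @ weights.T
    mean_h = habitat.mean()
    if mean_h > 0:
        habitat *= a / mean_h
    expected = (1.0 - s.coupling) * own + s.coupling * habitat
    counts = _overdispersed_counts(expected, s.dispersion, rng)
    df = pd.DataFrame(
        counts, index=pd.Index(ids, name="site_id"),
        columns=[f"{label[:3]}_{j:03d}" for j in range(p)],
    )
    matrices[label] = CommunityMatrix(df, label)
    return [matrices[lb] for lb in s.taxa_per_community]


def generate_dataset(
    s: SyntheticScenario,
) -> tuple[list[CommunityMatrix], SiteMetadata, HydroperiodMatrix, GroundTruth]:
    """Landscape + communities from a single root generator (seed-reproducible)."""
    rng = np.random.default_rng(s.seed)
    meta, hydro, truth = generate_landscape(s, rng)
    communities = generate_communities(s, truth, rng)
    return communities, meta, hydro, truth


def write_dataset(
    communities: Sequence[CommunityMatrix],
    meta: SiteMetadata,
    out_dir: Path | str,
    scenario: SyntheticScenario | None = None,
) -> dict[str, Path]:
    """Write the CSV formats the loader reads (round-trip compatible)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cm in communities:
        p = out / f"{cm.label}.csv"
        cm.data.rename_axis("site_id").to_csv(p)
        paths[cm.label] = p
    meta_csv = meta.table.rename(columns={"max_depth": "max_depth_cm"}).rename_axis("site_id")
    paths["metadata"] = out / "metadata.csv"
    meta_csv.to_csv(paths["metadata"])
    if scenario is not None:
        paths["scenario"] = out / "scenario.yaml"
        scenario.to_yaml(paths["scenario"])
    return paths
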