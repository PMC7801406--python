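"""Resampling layers around the Procrustes statistic.

Two concerns drive this module.  First, the Procrustes correlation is upward
biased at small n, so a rarefaction sweep (subsampling both matrices at the
same sites for n = 3..40, many times per n) locates the sample size beyond
which the estimate stabilizes.  Second, comparing congruence between
hydroperiod groups of unequal size would confound group with n, so a
stratified balanced bootstrap repeatedly subsamples the larger group down to
the size of the smaller one (proportionally to permanence class, without
replacement) before any contrast is drawn.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import PERMANENCE_CLASSES, SiteMetadata, assign_group
from .procrustes import (
    DegenerateConfigurationError,
    _as_array,
    _configuration,
    _corr_from_configs,
    _pad_arrays,
    protest,
)

logger = logging.getLogger(__name__)


def _subset_r(xa: np.ndarray, ya: np.ndarray, idx: np.ndarray) -> float:
    """Procrustes r of a common row subset; degenerate subsets count as r = 0."""
    try:
        return _corr_from_configs(_configuration(xa[idx]), _configuration(ya[idx]))
    except DegenerateConfigurationError:
        logger.warning("degenerate subsample (no variation); recording r = 0")
        return 0.0


@dataclass(frozen=True)
class RarefactionCurve:
    """Mean +/- SE of the Procrustes r at each subsample size."""

    n_values: np.ndarray
    mean_r: np.ndarray
    se_r: np.ndarray
    iterations: int
    seed: int | None
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair": self.label,
                "n": self.n_values,
                "mean_r": self.mean_r,
                "se_r": self.se_r,
                "iterations": self.iterations,
            }
        )


def rarefaction_curve(
    x,
    y,
    n_min: int = 3,
    n_max: int = 40,
    iterations: int = 100,
    seed: int | np.random.Generator | None = None,
    label: str = "",
) -> RarefactionCurve:
    """Subsample both matrices at the same sites for each n in [n_min, n_max].

    For every subsample size, ``iterations`` site subsets are drawn without
    replacement (one subset applied to both matrices, keeping rows matched)
    and the Procrustes r recorded; the curve reports the mean and standard
    error (SD/sqrt(B)) per n.
    """
    if n_min < 3:
        raise ValueError("n_min must be >= 3 (Procrustes needs >= 3 rows)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xa, ya = _pad_arrays(_as_array(x), _as_array(y))
    n_sites = xa.shape[0]
    if xa.shape[0] != ya.shape[0]:
        raise ValueError("row mismatch between matrices")
    if n_max > n_sites:
        raise ValueError(f"n_max = {n_max} exceeds the {n_sites} available sites")
    ns = np.arange(n_min, n_max + 1)
    means = np.empty(len(ns))
    ses = np.empty(len(ns))
    for k, n in enumerate(ns):
        draws = np.empty(iterations)
        for b in range(iterations):
            idx = rng.choice(n_sites, size=int(n), replace=False)
            draws[b] = _subset_r(xa, ya, idx)
        means[k] = draws.mean()
        ses[k] = draws.std(ddof=1) / math.sqrt(iterations) if iterations > 1 else 0.0
    return RarefactionCurve(
        n_values=ns,
        mean_r=means,
        se_r=ses,
        iterations=iterations,
        seed=seed if isinstance(seed, int) else None,
        label=label,
    )


def detect_plateau(curve: RarefactionCurve, tol: float = 0.01, run: int = 3) -> int | None:
    """Smallest n whose next ``run`` successive mean-r changes are all < tol.

    Returns None when the curve never settles.  The step attributed to n is
    |mean_r(n+1) - mean_r(n)|, so the plateau point is the first n from which
    the curve stays flat for ``run`` consecutive increments.
    """
    steps = np.abs(np.diff(curve.mean_r))
    if len(steps) < run:
        raise ValueError(f"curve needs at least {run + 1} points")
    for k in range(len(steps) - run + 1):
        if np.all(steps[k : k + run] < tol):
            return int(curve.n_values[k])
    return None


def largest_remainder_allocation(counts: Mapping[str, int], n_target: int) -> dict[str, int]:
    """Apportion n_target draws across strata proportionally to their sizes.

    Floor quotas first, then hand out the remaining seats by largest
    fractional remainder (ties broken by stratum size, then by the canonical
    permanence-class order, for determinism).  Every stratum allocation is
    within one of its exact quota and never exceeds the stratum size.
    """
    total = sum(counts.values())
    if n_target > total:
        raise ValueError(f"n_target = {n_target} exceeds the {total} available sites")
    order = {c: i for i, c in enumerate(PERMANENCE_CLASSES)}
    quotas = {c: n_target * k / total for c, k in counts.items()}
    alloc = {c: int(math.floor(q)) for c, q in quotas.items()}
    remaining = n_target - sum(alloc.values())
    by_remainder = sorted(
        counts,
        key=lambda c: (-(quotas[c] - alloc[c]), -counts[c], order.get(c, len(order))),
    )
    for c in by_remainder:
        if remaining == 0:
            break
        if alloc[c] < counts[c]:
            alloc[c] += 1
            remaining -= 1
    if remaining:  # all fractional winners were full; spill to any spare capacity
        for c in by_remainder:
            while remaining and alloc[c] < counts[c]:
                alloc[c] += 1
                remaining -= 1
    return alloc


@dataclass(frozen=True)
class BootstrapSummary:
    """Distribution of the Procrustes r over balanced subsample draws."""

    group: str
    pair: str
    n_sites: int
    iterations: int
    r_draws: np.ndarray = field(repr=False)
    mean_r: float
    ci_low: float
    ci_high: float
    median_p: float
    significant: bool
    alpha: float
    seed: int | None

    def to_record(self) -> dict:
        return {
            "group": self.group,
            "pair": self.pair,
            "n_sites": self.n_sites,
            "iterations": self.iterations,
            "mean_r": self.mean_r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "median_p": self.median_p,
            "significant": bool(self.significant),
        }


def balanced_bootstrap(
    x,
    y,
    meta: SiteMetadata,
    group: str = "all",
    n_target: int | None = None,
    iterations: int = 1000,
    permutations: int = 199,
    sig_iterations: int | None = None,
    alpha: float = 0.1,
    ci_level: float = 0.9,
    seed: int | np.random.Generator | None = None,
    label: str = "",
) -> BootstrapSummary:
    """Stratified balanced bootstrap of the Procrustes r for one site group.

    Each iteration draws ``n_target`` sites without replacement from the
    group, stratified by permanence class with proportional allocation
    (largest-remainder rounding), applies the *same* site subset to both
    matrices, and records r.  A group holding exactly ``n_target`` sites
    (e.g. the long-hydroperiod group at the balancing size) is computed once,
    deterministically.  ``n_target`` defaults to the size of the smaller of
    the short/long groups.  Significance is summarized as the median PROTEST
    p-value over ``sig_iterations`` iterations (default: all of them),
    flagged against ``alpha``; the CI is the percentile interval of the
    draws at ``ci_level``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xa, ya = _pad_arrays(_as_array(x), _as_array(y))
    site_ids = list(getattr(x, "site_ids"))
    if len(site_ids) != xa.shape[0]:  # pragma: no cover - defensive
        raise ValueError("x must carry site_ids matching its rows")
    row_of = {s: i for i, s in enumerate(site_ids)}
    members = [s for s in assign_group(meta, group) if s in row_of]
    if n_target is None:
        n_short = len([s for s in assign_group(meta, "short") if s in row_of])
        n_long = len([s for s in assign_group(meta, "long") if s in row_of])
        n_target = min(n_short, n_long)
    if len(members) < n_target:
        raise ValueError(
            f"group '{group}' has {len(members)} sites, fewer than n_target = {n_target}"
        )

    lo_q = 100 * (1 - ci_level) / 2
    hi_q = 100 - lo_q

    if len(members) == n_target:
        idx = np.sort([row_of[s] for s in members])
        r = _subset_r(xa, ya, idx)
        p = protest(xa[idx], ya[idx], permutations=permutations, seed=rng).p_value
        draws = np.array([r])
        return BootstrapSummary(
            group=group, pair=label, n_sites=n_target, iterations=1,
            r_draws=draws, mean_r=r, ci_low=r, ci_high=r,
            median_p=p, significant=p < alpha, alpha=alpha,
            seed=seed if isinstance(seed, int) else None,
        )

    classes = meta.table.loc[members, "permanence_class"]
    strata = {c: list(classes.index[classes == c]) for c in classes.unique()}
    alloc = largest_remainder_allocation({c: len(s) for c, s in strata.items()}, n_target)
    logger.info("group '%s' stratified allocation at n = %d: %s", group, n_target, alloc)

    if sig_iterations is None:
        sig_iterations = iterations
    draws = np.empty(iterations)
    pvals = []
    for b in range(iterations):
        chosen: list = []
        for c, sites in strata.items():
            take = alloc[c]
            if take:
                chosen.extend(rng.choice(sites, size=take, replace=False))
        idx = np.sort([row_of[s] for s in chosen])
        draws[b] = _subset_r(xa, ya, idx)
        if b < sig_iterations:
            pvals.append(protest(xa[idx], ya[idx], permutations=permutations, seed=rng).p_value)
    median_p = float(np.median(pvals)) if pvals else float("nan")
    return BootstrapSummary(
        group=group, pair=label, n_sites=n_target, iterations=iterations,
        r_draws=draws,
        mean_r=float(draws.mean()),
        ci_low=float(np.percentile(draws, lo_q)),
        ci_high=float(np.percentile(draws, hi_q)),
        median_p=median_p,
        significant=bool(median_p < alpha) if pvals else False,
        alpha=alpha,
        seed=seed if isinstance(seed, int) else None,
    )
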