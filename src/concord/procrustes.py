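"""Symmetric Procrustes superimposition and its permutation test (PROTEST).

Two row-matched configurations X and Y are column-centered and scaled to unit
total sum of squares; the optimal orthogonal rotation (reflections allowed) of
Y onto X is found by SVD of the cross-product Y'X, giving

    r  = sum of singular values of Y'X   (the Procrustes correlation, pseudo-R)
    m2 = 1 - r**2                        (minimized sum of squared residuals)

The symmetric scaling makes r order-invariant: r(X, Y) = r(Y, X).  Statistical
significance is assessed by permuting the rows of Y and recomputing r; the
p-value uses the add-one rule p = (1 + #{r_perm >= r_obs}) / (B + 1), so it is
never exactly zero.  For tiny n an exhaustive n! enumeration provides exact
p-values (used as an oracle in the test-suite).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-12  # float slack when counting permutation ties (>= comparison)


class DegenerateConfigurationError(ValueError):
    """A configuration has no variation left after centering."""


def _as_array(m) -> np.ndarray:
    """Accept TransformedMatrix / CommunityMatrix / HydroperiodMatrix /
    DataFrame / ndarray and return an n x p float array."""
    values = getattr(m, "values", m)
    if callable(values):  # pragma: no cover - defensive
        values = values()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def _pad_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = max(x.shape[1], y.shape[1])
    if x.shape[1] < p:
        x = np.pad(x, ((0, 0), (0, p - x.shape[1])))
    if y.shape[1] < p:
        y = np.pad(y, ((0, 0), (0, p - y.shape[1])))
    return x, y


def _configuration(a: np.ndarray) -> np.ndarray:
    """Center columns and scale to unit total sum of squares."""
    c = a - a.mean(axis=0)
    ss = float((c * c).sum())
    if ss <= 1e-300:
        raise DegenerateConfigurationError(
            "degenerate configuration: matrix has no variation after centering"
        )
    return c / math.sqrt(ss)


def _corr_from_configs(xs: np.ndarray, ys: np.ndarray) -> float:
    """Procrustes correlation of two pre-centered unit-scaled configurations."""
    s = np.linalg.svd(ys.T @ xs, compute_uv=False)
    return min(float(s.sum()), 1.0)


@dataclass(frozen=True)
class ProcrustesResult:
    """Optimal superimposition summary.

    ``rotation`` is the p x p orthogonal matrix Q (reflections allowed) that
    maps the second centered/scaled configuration onto the first:
    ``Y_config @ rotation ~ X_config``.
    """

    r: float
    m2: float
    rotation: np.ndarray
    n_sites: int
    n_dims: int

    def to_json(self) -> dict:
        return {"r": self.r, "m2": self.m2, "n": self.n_sites, "dims": self.n_dims}


@dataclass(frozen=True)
class ProtestResult:
    """Permutation-test summary for a Procrustes fit."""

    observed: ProcrustesResult
    n_permutations: int
    p_value: float
    seed: int | None = None
    permutation_r: np.ndarray | None = field(default=None, repr=False)

    def to_json(self) -> dict:
        return {
            "r": self.observed.r,
            "m2": self.observed.m2,
            "p": self.p_value,
            "B": self.n_permutations,
            "seed": self.seed,
            "n": self.observed.n_sites,
            "dims": self.observed.n_dims,
        }


def procrustes_fit(x, y) -> ProcrustesResult:
    """Symmetric Procrustes fit of two row-matched matrices.

    Widths are equalized with zero columns if needed (which leaves the
    statistic unchanged); both matrices are centered and unit-scaled, and the
    rotation maximizing the cross-configuration inner product is obtained from
    the SVD of the p x p cross-product.
    """
    xa, ya = _pad_arrays(_as_array(x), _as_array(y))
    if xa.shape[0] != ya.shape[0]:
        raise ValueError(f"row mismatch: {xa.shape[0]} vs {ya.shape[0]} sites")
    if xa.shape[0] < 3:
        raise ValueError("Procrustes needs at least 3 sites")
    xs, ys = _configuration(xa), _configuration(ya)
    u, s, vt = np.linalg.svd(ys.T @ xs)
    r = min(float(s.sum()), 1.0)
    return ProcrustesResult(
        r=r,
        m2=max(1.0 - r * r, 0.0),
        rotation=u @ vt,
        n_sites=xa.shape[0],
        n_dims=xa.shape[1],
    )


def protest(
    x,
    y,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
    keep_draws: bool = False,
) -> ProtestResult:
    """Monte-Carlo PROTEST: permute the rows of ``y`` and recompute r.

    Holding ``x`` fixed and permuting ``y`` is an arbitrary but reproducible
    convention; with the symmetric statistic the roles are interchangeable.
    Ties are counted with >= (within 1e-12) and the add-one correction keeps
    the p-value in [1/(B+1), 1].
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xa, ya = _pad_arrays(_as_array(x), _as_array(y))
    if xa.shape[0] != ya.shape[0]:
        raise ValueError(f"row mismatch: {xa.shape[0]} vs {ya.shape[0]} sites")
    observed = procrustes_fit(xa, ya)
    xs, ys = _configuration(xa), _configuration(ya)
    n = xa.shape[0]
    draws = np.empty(permutations)
    for b in range(permutations):
        # centering/scaling are row-permutation invariant, so permute ys directly
        draws[b] = _corr_from_configs(xs, ys[rng.permutation(n)])
    exceed = int(np.sum(draws >= observed.r - _TIE_EPS))
    p = (1 + exceed) / (permutations + 1)
    return ProtestResult(
        observed=observed,
        n_permutations=permutations,
        p_value=p,
        seed=seed if isinstance(seed, int) else None,
        permutation_r=draws if keep_draws else None,
    )


def exhaustive_protest(x, y) -> float:
    """Exact permutation p-value by full n! enumeration (n <= 8).

    The identity permutation is included in the reference set, so the p-value
    is at least 1/n!.  Intended as an oracle for validating the Monte-Carlo
    test on tiny configurations.
    """
    xa, ya = _pad_arrays(_as_array(x), _as_array(y))
    n = xa.shape[0]
    if n > 8:
        raise ValueError(f"exhaustive enumeration refused for n = {n} > 8")
    xs, ys = _configuration(xa), _configuration(ya)
    r_obs = _corr_from_configs(xs, ys)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if _corr_from_configs(xs, ys[list(perm)]) >= r_obs - _TIE_EPS:
            count += 1
    return count / total
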