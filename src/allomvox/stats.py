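"""Exact association statistics for the outlier analysis.

Self-contained implementations of

* Barnard's unconditional exact test for 2x2 tables, using the pooled
  two-proportion score statistic as the ordering criterion and maximizing
  the two-tailed tail probability over a uniform open grid of the nuisance
  success probability; and
* the two-tailed Mann-Whitney U test, with exact enumeration of the null
  distribution for small tie-free samples and a tie- and
  continuity-corrected normal approximation otherwise.

Sign convention for Barnard's z: with row 1 the VPL group and row 2 the
non-VPL group, z is oriented as (non-VPL proportion - VPL proportion), so
an outlier excess among VPL species yields a negative z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["BarnardResult", "MannWhitneyResult", "barnard_exact", "mann_whitney_u"]

_TIE_EPS = 1e-12


@dataclass
class BarnardResult:
    z: float
    p: float
    nuisance_grid_size: int

    def as_dict(self) -> dict:
        return {"z": self.z, "p": self.p,
                "nuisance_grid_size": self.nuisance_grid_size}


@dataclass
class MannWhitneyResult:
    w: float
    p: float
    method: str  # "exact" or "normal_approx"

    def as_dict(self) -> dict:
        return {"w": self.w, "p": self.p, "method": self.method}


def _score_z(x1, n1, x2, n2):
    """Pooled two-proportion score statistic, oriented (p2 - p1).

    Vectorized over ``x1``/``x2``; outcomes with pooled proportion 0 or 1
    score 0 (no evidence in either direction).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x2 / n2 - x1 / n1) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def barnard_exact(table, grid_size: int = 200) -> BarnardResult:
    """Barnard's unconditional exact test for a 2x2 table.

    ``table`` is ``[[a, b], [c, d]]`` with rows = groups (row 1: VPL) and
    columns = (outlier, non-outlier).  The two-tailed p-value is the
    maximum, over a uniform open grid of the common success probability
    pi, of the probability under independent binomials of outcomes at
    least as extreme (``|z| >= |z_obs|``) as the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row sums must be positive")
    z_obs = float(_score_z(a, n1, c, n2))
    if a + c == 0 or b + d == 0:  # no successes (or no failures) at all
        return BarnardResult(z=0.0, p=1.0, nuisance_grid_size=grid_size)

    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    Z = _score_z(x1[:, None], n1, x2[None, :], n2)
    extreme = np.abs(Z) >= np.abs(z_obs) - _TIE_EPS

    grid = (np.arange(1, grid_size + 1)) / (grid_size + 1.0)
    p_max = 0.0
    for pi in grid:
        pmf1 = sps.binom.pmf(x1, n1, pi)
        pmf2 = sps.binom.pmf(x2, n2, pi)
        p_max = max(p_max, float(pmf1 @ extreme @ pmf2))
    return BarnardResult(z=z_obs, p=min(p_max, 1.0),
                         nuisance_grid_size=grid_size)


def _barnard_all_pvalues(n1: int, n2: int, grid_size: int = 200) -> np.ndarray:
    """p-value for every possible outcome ``(x1, x2)`` at fixed margins.

    Returns an ``(n1+1, n2+1)`` array.  Used for exact size calculations
    and simulation studies where calling :func:`barnard_exact` per table
    would repeat the same grid work.
    """
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    Z = _score_z(x1[:, None], n1, x2[None, :], n2)
    absz = np.abs(Z).ravel()
    order = np.argsort(-absz)  # descending |z|
    sorted_absz = absz[order]
    grid = (np.arange(1, grid_size + 1)) / (grid_size + 1.0)
    pmax = np.zeros(absz.size)
    for pi in grid:
        pmf = np.outer(sps.binom.pmf(x1, n1, pi),
                       sps.binom.pmf(x2, n2, pi)).ravel()
        tail = np.cumsum(pmf[order])
        # tail prob of outcomes with |z| >= each cell's own |z| (ties included)
        k = np.searchsorted(-sorted_absz, -(absz - _TIE_EPS), side="right") - 1
        pmax = np.maximum(pmax, tail[k])
    # outcomes with z == 0 (no evidence) always have p = 1
    pmax[absz <= _TIE_EPS] = 1.0
    return np.minimum(pmax, 1.0).reshape(n1 + 1, n2 + 1)


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements yielding each U value, U = 0..n1*n2.

    Dynamic programming over the Gaussian-binomial recursion
    ``N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1, n2 - 1)``.
    """
    max_u = n1 * n2
    prev = np.zeros((n2 + 1, max_u + 1))
    prev[:, 0] = 1.0  # n1 = 0
    for m1 in range(1, n1 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m2 in range(1, n2 + 1):
            cur[m2] = cur[m2 - 1]
            cur[m2, m2:] += prev[m2, :max_u + 1 - m2]
        prev = cur
    return prev[n2]


def mann_whitney_u(x, y, exact_limit: int = 400) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test, first sample as reference.

    ``w`` counts pairs ``(x_i, y_j)`` with ``x_i > y_j`` plus half the
    tied pairs (so ``w(x, y) + w(y, x) = n1 * n2``).  The p-value is exact
    (full enumeration of the null U distribution) when ``n1 * n2 <=
    exact_limit`` and the pooled data are tie-free; otherwise a normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    w = float(gt) + 0.5 * float(eq)

    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and n1 * n2 <= exact_limit:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        u = int(round(w))
        u_low = min(u, n1 * n2 - u)
        p = 2.0 * counts[: u_low + 1].sum() / total
        return MannWhitneyResult(w=w, p=min(p, 1.0), method="exact")

    mean = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return MannWhitneyResult(w=w, p=1.0, method="normal_approx")
    num = max(abs(w - mean) - 0.5, 0.0)  # continuity correction
    z = num / np.sqrt(var)
    p = min(2.0 * sps.norm.sf(z), 1.0)
    return MannWhitneyResult(w=w, p=p, method="normal_approx")
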