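"""Among-species covariance structures for phylogenetic regression.

A phylogeny induces an expected covariance among tip trait values.  Four
structures are supported, matching the candidate evolutionary scenarios of
the allometry analysis:

* Brownian motion (BM): ``V[i, j]`` is the shared root-to-MRCA path length.
* BM + Pagel's lambda: off-diagonal BM covariances scaled by ``lambda`` in
  ``[0, 1]`` (0 = phylogenetic independence, 1 = pure BM).
* BM + Grafen's rho: node heights derived from topology alone
  (``(n_descendant_tips - 1) / (n - 1)``), depths ``1 - h`` raised to the
  power ``rho``; variances are 1 and scale is absorbed by the residual
  variance.  Branch lengths are deliberately ignored — the Grafen structure
  depends only on topology.
* Ornstein-Uhlenbeck with fixed stabilizing-selection strength ``alpha``:
  correlation ``exp(-alpha * d_ij)`` with ``d_ij`` the patristic distance.
  ``alpha`` is interpreted in the tree's own depth units (the tree is not
  rescaled), so fixed values such as 0.1/0.5/1/10 are tree-unit-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import Phylogeny

__all__ = [
    "CovarianceSpec",
    "CovarianceMatrix",
    "bm_vcv",
    "pagel_transform",
    "grafen_vcv",
    "ou_correlation",
    "build_covariance",
]

MODELS = ("BM", "BM_lambda", "BM_grafen", "OU_fixed")

#: fixed-effect-free parameter count each structure adds when profiled
_ESTIMABLE = {"BM": False, "BM_lambda": True, "BM_grafen": True, "OU_fixed": False}


@dataclass(frozen=True)
class CovarianceSpec:
    """Which covariance structure to use, and its parameter.

    ``parameter`` is lambda for ``BM_lambda``, rho for ``BM_grafen`` and
    alpha for ``OU_fixed`` (required); ``estimate_parameter`` defaults to
    True for the lambda/rho structures and must be False for BM/OU_fixed.
    """

    model: str
    parameter: float | None = None
    estimate_parameter: bool | None = None

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        est = self.estimate_parameter
        if est is None:
            est = _ESTIMABLE[self.model]
            object.__setattr__(self, "estimate_parameter", est)
        if self.model in ("BM", "OU_fixed") and est:
            raise ValueError(f"{self.model} has no estimable parameter")
        if self.model == "OU_fixed":
            if self.parameter is None or self.parameter <= 0:
                raise ValueError("OU_fixed requires alpha > 0")
        if self.model == "BM_lambda" and self.parameter is not None:
            if not 0.0 <= self.parameter <= 1.0:
                raise ValueError("lambda must be in [0, 1]")
        if self.model == "BM_grafen" and self.parameter is not None:
            if self.parameter <= 0:
                raise ValueError("rho must be > 0")

    @property
    def label(self) -> str:
        if self.model == "OU_fixed":
            return f"OU(alpha={self.parameter:g})"
        return {"BM": "BM", "BM_lambda": "BM+lambda", "BM_grafen": "BM+rho"}[self.model]


@dataclass
class CovarianceMatrix:
    """A symmetric PSD covariance/correlation matrix over named species."""

    species: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match species list")

    def validate(self, tol: float = 1e-8) -> None:
        V = self.values
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")
        if np.any(np.diag(V) <= 0):
            raise ValueError("covariance matrix has non-positive diagonal")
        w = np.linalg.eigvalsh(V)
        if w.min() < -tol:
            raise ValueError(f"covariance matrix not PSD (min eigenvalue {w.min():g})")

    def reorder(self, order) -> "CovarianceMatrix":
        idx = [self.species.index(s) for s in order]
        return CovarianceMatrix(tuple(order), self.values[np.ix_(idx, idx)])


def bm_vcv(tree: Phylogeny) -> CovarianceMatrix:
    """Brownian-motion variance-covariance matrix.

    ``V[i, j]`` is the root-to-MRCA path length of tips i and j;
    ``V[i, i]`` is the root-to-tip depth.
    """
    names = tree.tips
    _, M = tree._mrca_depths(names)
    return CovarianceMatrix(tuple(names), M)


def pagel_transform(V: CovarianceMatrix, lam: float,
                    bounds: tuple[float, float] = (0.0, 1.0)) -> CovarianceMatrix:
    """Scale off-diagonal entries of a BM matrix by Pagel's lambda."""
    lo, hi = bounds
    if not lo <= lam <= hi:
        raise ValueError(f"lambda={lam} outside [{lo}, {hi}]")
    W = lam * V.values
    np.fill_diagonal(W, np.diag(V.values))
    return CovarianceMatrix(V.species, W)


def grafen_vcv(tree: Phylogeny, rho: float) -> CovarianceMatrix:
    """Grafen's rho correlation structure (topology-only; variances 1)."""
    if rho <= 0:
        raise ValueError("rho must be > 0")
    names = tree.tips
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    if n < 2:
        return CovarianceMatrix(tuple(names), np.ones((1, 1)))
    V = np.zeros((n, n))
    below: dict = {}
    dtree = tree.tree
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [idx[node.taxon.label]]
            continue
        groups = [below.pop(c) for c in node.child_nodes()]
        n_desc = sum(len(g) for g in groups)
        height = (n_desc - 1) / (n - 1)
        cov = (1.0 - height) ** rho
        for gi, g in enumerate(groups):
            for h in groups[gi + 1:]:
                for a in g:
                    for b in h:
                        V[a, b] = V[b, a] = cov
        below[node] = [i for g in groups for i in g]
    np.fill_diagonal(V, 1.0)
    return CovarianceMatrix(tuple(names), V)


def ou_correlation(tree: Phylogeny, alpha: float) -> CovarianceMatrix:
    """Ornstein-Uhlenbeck correlation: ``exp(-alpha * patristic distance)``."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    names = tree.tips
    D = tree.patristic_matrix(names)
    return CovarianceMatrix(tuple(names), np.exp(-alpha * D))


def build_covariance(tree: Phylogeny, spec: CovarianceSpec,
                     parameter: float | None = None) -> CovarianceMatrix:
    """Materialize the covariance matrix for ``spec`` on ``tree``.

    ``parameter`` overrides ``spec.parameter`` (used while profiling).
    """
    p = parameter if parameter is not None else spec.parameter
    if spec.model == "BM":
        return bm_vcv(tree)
    if spec.model == "BM_lambda":
        if p is None:
            raise ValueError("lambda value required")
        return pagel_transform(bm_vcv(tree), p)
    if spec.model == "BM_grafen":
        if p is None:
            raise ValueError("rho value required")
        return grafen_vcv(tree, p)
    if spec.model == "OU_fixed":
        return ou_correlation(tree, p)
    raise ValueError(spec.model)  # pragma: no cover
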