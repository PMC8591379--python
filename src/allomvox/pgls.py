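"""Phylogenetic generalized least squares (PGLS) regression.

The model is ``y ~ N(X beta, sigma2 * V)`` where ``V`` is a phylogenetic
covariance structure (see :mod:`allomvox.covariance`).  Estimation follows
the statsmodels model/results idiom:

>>> model = PGLS(y, X, tree=tree, covariance=CovarianceSpec("BM_lambda"))
>>> res = model.fit()              # REML, profiling lambda if applicable
>>> res.params, res.bse, res.aicc
>>> res.wald_anova()               # chi-square tests on the ML refit

Estimation notes
----------------
* ``beta_hat = (X' V^-1 X)^-1 X' V^-1 y`` via Cholesky whitening; residuals
  are returned on the response scale (``y - X beta_hat``), which is what the
  downstream MAD outlier rule consumes.
* REML log-likelihood includes the ``-1/2 log|X' V^-1 X|`` term; the
  phylogenetic parameter (lambda or rho) is profiled by bounded Brent
  search on the REML criterion, then the model is refit by ML at the
  REML-estimated parameter for Wald testing.
* AICc uses the REML log-likelihood for model selection; all candidate
  structures share the same fixed-effect design, which keeps REML
  likelihoods comparable.
* Parameter count ``k`` = number of regression coefficients + 1 (sigma2)
  + 1 if lambda/rho was estimated (0 for BM and fixed-alpha OU).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

from .covariance import CovarianceMatrix, CovarianceSpec, build_covariance
from .trees import Phylogeny

__all__ = [
    "PGLS",
    "PGLSResults",
    "ModelComparison",
    "GLSCore",
    "gls_fit",
    "profile_fit",
    "aicc",
    "select_model",
    "wald_anova",
    "fit_allometry",
    "DEFAULT_OU_ALPHAS",
]

DEFAULT_OU_ALPHAS = (0.1, 0.5, 1.0, 10.0)

LAMBDA_BOUNDS = (0.0, 1.0)
RHO_BOUNDS = (1e-4, 10.0)
_BRENT_XTOL = 1e-8

#: selection tie-break order among covariance structures (simpler first)
_MODEL_ORDER = {"BM": 0, "BM_lambda": 1, "BM_grafen": 2, "OU_fixed": 3}


@dataclass
class GLSCore:
    """Raw output of a single GLS solve at a fixed covariance matrix."""

    params: np.ndarray
    bse: np.ndarray
    sigma2: float
    llf_ml: float
    llf_reml: float
    resid: np.ndarray
    nobs: int
    df_resid: int
    method: str
    cov_params: np.ndarray


def gls_fit(y: np.ndarray, X: np.ndarray, V: CovarianceMatrix | np.ndarray,
            method: str = "REML", jitter: float | None = None) -> GLSCore:
    """Fit GLS by Cholesky whitening at a fixed covariance matrix.

    Raises ``LinAlgError`` for non-positive-definite ``V`` (optionally add a
    tiny diagonal ``jitter`` to proceed on near-singular input) and
    ``ValueError`` for a singular design.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} rows but X has {n}")
    Vm = V.values if isinstance(V, CovarianceMatrix) else np.asarray(V, float)
    if Vm.shape != (n, n):
        raise ValueError("covariance matrix does not match data dimension")
    if jitter:
        Vm = Vm + jitter * np.eye(n)
    L = linalg.cholesky(Vm, lower=True)  # LinAlgError if not PD
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    cond = np.linalg.cond(XtX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular design matrix X' V^-1 X")
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = y - X @ beta
    rw = yw - Xw @ beta
    rss = float(rw @ rw)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    sigma2_ml = rss / n
    sigma2_reml = rss / (n - p)
    llf_ml = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet_V + n)
    llf_reml = -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma2_reml)
                       + logdet_V + logdet_XtX + (n - p))
    sigma2 = sigma2_reml if method == "REML" else sigma2_ml
    cov_params = sigma2 * linalg.inv(XtX)
    bse = np.sqrt(np.diag(cov_params))
    return GLSCore(params=beta, bse=bse, sigma2=sigma2, llf_ml=llf_ml,
                   llf_reml=llf_reml, resid=resid, nobs=n, df_resid=n - p,
                   method=method, cov_params=cov_params)


def aicc(llf: float, n: int, k: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``AICc = -2 llf + 2k + 2k(k+1)/(n-k-1)``; requires ``n > k + 1``.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class PGLS:
    """Phylogenetic GLS regression model.

    Parameters
    ----------
    endog : (n,) array
        Response values, species-ordered.
    exog : (n, p) array
        Design matrix (include a constant column for the intercept).
    tree : Phylogeny, optional
        Required for tree-derived covariance structures.
    covariance : CovarianceSpec
        Evolutionary covariance structure (default pure BM).
    species : sequence of str, optional
        Species order of the rows; defaults to the tree's tip order (in
        which case rows must already be in that order).
    exog_names : sequence of str, optional
        Column names for the summary (default const/x1/...).
    """

    def __init__(self, endog, exog, tree: Phylogeny | None = None,
                 covariance: CovarianceSpec = CovarianceSpec("BM"),
                 species=None, exog_names=None, endog_name: str = "y"):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        self.covariance = covariance
        self.tree = tree
        self.endog_name = endog_name
        n, p = exog.shape
        if self.endog.shape[0] != n:
            raise ValueError("endog/exog length mismatch")
        if exog_names is None:
            exog_names = ["const"] + [f"x{i}" for i in range(1, p)]
        self.exog_names = list(exog_names)
        if tree is not None:
            tips = tree.tips
            if species is None:
                species = tips
            species = list(species)
            if sorted(species) != sorted(tips):
                missing = sorted(set(species) ^ set(tips))
                raise ValueError(f"species/tree tip mismatch: {missing}")
            if n != len(species):
                raise ValueError("data rows do not match species list")
        self.species = list(species) if species is not None else None

    # ------------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, table, response: str, tree: Phylogeny,
                       covariance: CovarianceSpec = CovarianceSpec("BM"),
                       predictor: str = "log_body_mass"):
        """Build from a trait table whose rows are indexed by species.

        ``table`` must contain ``response`` and ``predictor`` columns and a
        ``species`` column matching the tree tips 1:1.
        """
        import pandas as pd  # local: keep numpy-only paths light

        df = pd.DataFrame(table)
        if "species" not in df.columns:
            raise ValueError("table must have a 'species' column")
        sub = df.set_index("species").loc[tree.tips]  # tree tip order
        y = sub[response].to_numpy(float)
        x = sub[predictor].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        return cls(y, X, tree=tree, covariance=covariance,
                   species=tree.tips, exog_names=["intercept", predictor],
                   endog_name=response)

    def _vcv(self, parameter: float | None = None) -> np.ndarray:
        if self.tree is None:
            raise ValueError("a tree is required for this covariance structure")
        V = build_covariance(self.tree, self.covariance, parameter=parameter)
        if self.species is not None and list(V.species) != list(self.species):
            V = V.reorder(self.species)
        return V.values

    def fit(self, method: str = "REML") -> "PGLSResults":
        """Fit the model; profiles lambda/rho by REML when applicable."""
        spec = self.covariance
        if spec.estimate_parameter:
            return profile_fit(self)
        core_reml = gls_fit(self.endog, self.exog, self._vcv(), method="REML")
        core_ml = gls_fit(self.endog, self.exog, self._vcv(), method="ML")
        core = core_reml if method == "REML" else core_ml
        return PGLSResults(self, core, core_reml.llf_reml, core_ml,
                           phylo_parameter=spec.parameter,
                           parameter_estimated=False)


class PGLSResults:
    """Results of a PGLS fit.

    Attributes mirror statsmodels results objects: ``params``, ``bse``,
    ``tvalues``, ``pvalues`` (t-distribution, residual df), ``resid``
    (response scale), ``sigma2``, ``llf_reml``, ``llf_ml``,
    ``phylo_parameter`` and ``aicc``.
    """

    def __init__(self, model: PGLS, core: GLSCore, llf_reml: float,
                 core_ml: GLSCore, phylo_parameter: float | None,
                 parameter_estimated: bool):
        self.model = model
        self._core = core
        self._core_ml = core_ml
        self.params = core.params
        self.bse = core.bse
        self.resid = core.resid
        self.sigma2 = core.sigma2
        self.nobs = core.nobs
        self.df_resid = core.df_resid
        self.llf_reml = llf_reml
        self.llf_ml = core_ml.llf_ml
        self.phylo_parameter = phylo_parameter
        self.parameter_estimated = parameter_estimated
        self.tvalues = self.params / self.bse
        self.pvalues = 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)
        self.k_params = (len(self.params) + 1
                         + (1 if parameter_estimated else 0))
        self.aicc = aicc(self.llf_reml, self.nobs, self.k_params)

    @property
    def cov_spec(self) -> CovarianceSpec:
        return self.model.covariance

    def wald_anova(self) -> list[tuple[float, float]]:
        """Per-coefficient Wald chi-square (1 df) on the ML refit.

        Mirrors an ANOVA on a single-predictor GLS refit by ML with the
        phylogenetic parameter fixed at its REML estimate.
        """
        return wald_anova(self)

    def summary(self) -> str:
        spec = self.cov_spec
        lines = [
            f"PGLS regression: {self.model.endog_name}",
            f"covariance: {spec.label}"
            + (f", parameter={self.phylo_parameter:.6g}"
               f" ({'estimated' if self.parameter_estimated else 'fixed'})"
               if self.phylo_parameter is not None else ""),
            f"n = {self.nobs}, k = {self.k_params}, sigma2 = {self.sigma2:.6g}",
            f"logLik(REML) = {self.llf_reml:.4f}, logLik(ML) = {self.llf_ml:.4f}, "
            f"AICc = {self.aicc:.4f}",
            "",
            f"{'term':<16}{'estimate':>12}{'s.e.':>10}{'t':>10}{'p':>13}",
        ]
        for name, b, se, t, p in zip(self.model.exog_names, self.params,
                                     self.bse, self.tvalues, self.pvalues):
            lines.append(f"{name:<16}{b:>12.4f}{se:>10.4f}{t:>10.2f}{p:>13.4g}")
        wald = self.wald_anova()
        lines.append("")
        lines.append("Wald ANOVA (ML refit, chi-square, 1 df):")
        for name, (chi2, p) in zip(self.model.exog_names, wald):
            lines.append(f"  {name:<14} chi2 = {chi2:.3f}, p = {p:.4g}")
        return "\n".join(lines)


def wald_anova(fit: PGLSResults) -> list[tuple[float, float]]:
    """Wald chi-square tests per coefficient from the stored ML refit."""
    if fit._core_ml is None:  # pragma: no cover - constructor guarantees it
        raise ValueError("ML refit not available")
    out = []
    for b, se in zip(fit._core_ml.params, fit._core_ml.bse):
        chi2 = (b / se) ** 2
        out.append((float(chi2), float(stats.chi2.sf(chi2, df=1))))
    return out


def profile_fit(model: PGLS) -> PGLSResults:
    """Profile lambda (or rho) by REML, then refit by ML at the optimum.

    Bounded Brent search on the negative REML log-likelihood; deterministic.
    Endpoints are also evaluated so the returned optimum is never worse
    than the boundary values.
    """
    spec = model.covariance
    if not spec.estimate_parameter:
        raise ValueError("profile_fit requires an estimable parameter")
    bounds = LAMBDA_BOUNDS if spec.model == "BM_lambda" else RHO_BOUNDS

    def neg_reml(param: float) -> float:
        core = gls_fit(model.endog, model.exog, model._vcv(param), "REML")
        return -core.llf_reml

    res = optimize.minimize_scalar(
        neg_reml, bounds=bounds, method="bounded",
        options={"xatol": _BRENT_XTOL},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML profiling did not converge: {res.message}")
    candidates = [(res.x, res.fun), (bounds[0], neg_reml(bounds[0])),
                  (bounds[1], neg_reml(bounds[1]))]
    best_param, _ = min(candidates, key=lambda c: c[1])
    V = model._vcv(best_param)
    core_reml = gls_fit(model.endog, model.exog, V, "REML")
    core_ml = gls_fit(model.endog, model.exog, V, "ML")
    return PGLSResults(model, core_reml, core_reml.llf_reml, core_ml,
                       phylo_parameter=float(best_param),
                       parameter_estimated=True)


@dataclass
class ModelComparison:
    """AICc comparison across candidate covariance structures."""

    fits: list[PGLSResults]
    best_index: int

    @property
    def best(self) -> PGLSResults:
        return self.fits[self.best_index]

    def table(self):
        import pandas as pd

        rows = []
        for i, f in enumerate(self.fits):
            rows.append({
                "model": f.cov_spec.label,
                "phylo_parameter": f.phylo_parameter,
                "k": f.k_params,
                "loglik_reml": f.llf_reml,
                "aicc": f.aicc,
                "delta_aicc": f.aicc - self.best.aicc,
                "selected": i == self.best_index,
            })
        return pd.DataFrame(rows)


def select_model(fits: list[PGLSResults]) -> ModelComparison:
    """Pick the minimum-AICc fit.

    Exact AICc ties break toward fewer parameters, then toward the fixed
    structure order BM < BM+lambda < BM+rho < OU.
    """
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    n0, y0 = fits[0].nobs, fits[0].model.endog
    for f in fits[1:]:
        if f.nobs != n0 or not np.array_equal(f.model.endog, y0):
            raise ValueError("candidate fits were computed on different data")
    order = sorted(
        range(len(fits)),
        key=lambda i: (fits[i].aicc, fits[i].k_params,
                       _MODEL_ORDER[fits[i].cov_spec.model], i),
    )
    return ModelComparison(fits=fits, best_index=order[0])


def fit_allometry(table, tree: Phylogeny, response: str,
                  predictor: str = "log_body_mass",
                  ou_alphas=DEFAULT_OU_ALPHAS) -> ModelComparison:
    """Fit the full candidate set for one response and select by AICc.

    Candidates: BM, BM+lambda (profiled), BM+rho (profiled) and one
    fixed-alpha OU model per value in ``ou_alphas``.
    """
    specs = [CovarianceSpec("BM"), CovarianceSpec("BM_lambda"),
             CovarianceSpec("BM_grafen")]
    specs += [CovarianceSpec("OU_fixed", parameter=a) for a in ou_alphas]
    fits = [PGLS.from_dataframe(table, response, tree, covariance=s,
                                predictor=predictor).fit()
            for s in specs]
    return select_model(fits)
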