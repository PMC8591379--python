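"""End-to-end analysis: consensus tree, four allometric PGLS regressions
with AICc model selection, MAD outlier calling, association tests and the
outlier-category tables.

The entry point is :func:`run_analysis`, which consumes a :class:`RunConfig`
and produces an :class:`AnalysisReport`.  For each acoustic response
(MinDF, MaxDF, MeanDF, RangeDF) the candidate covariance structures — BM,
BM+lambda (profiled), BM+rho (profiled) and one fixed-alpha OU model per
configured alpha — are fitted by REML and compared by AICc; residuals of
the selected model feed the MAD outlier rule, the VPL-vs-outlier 2x2
contingency table with Barnard's exact test, and the eight Mann-Whitney
residual comparisons (signed/absolute x full/outliers-only).  Outlier
species are assembled into the VPL and non-VPL direction tables with
category assignments and tally summaries.

Reports are deterministic: species iterate in sorted order and floats are
serialized at 12 significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .outliers import (
    ContingencyTable2x2,
    build_contingency,
    build_outlier_table,
    direction_marks,
    mad_outliers,
    residual_group_comparison,
    size_corrected_raw_comparison,
    tally_outlier_table,
)
from .pgls import DEFAULT_OU_ALPHAS, ModelComparison, fit_allometry
from .traits import LOG_RESPONSE_COLUMNS, RESPONSES, log_features, read_trait_table
from .trees import Phylogeny, consensus_edge_tree, prune_to_taxa, read_newick

__all__ = ["RunConfig", "ResponseResult", "AnalysisReport",
           "run_analysis", "vpl_free_refit", "subset_run"]

log = logging.getLogger("allomvox")

#: clade labels treated as VPL by default (the four mammalian VPL clades)
DEFAULT_VPL_CLADES = ("cetaceans", "bats", "elephants", "non_otariid_pinnipeds")


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Either file paths (``tree_path``, ``traits_path``) or in-memory objects
    (``trees``, ``traits``) may be supplied.  ``subset_mode`` is one of
    ``full``, ``no_odontocetes`` (drops ``exclude_clades``) or
    ``strict_vpl`` (VPL membership restricted to ``strict_vpl_species``).
    """

    tree_path: str | None = None
    traits_path: str | None = None
    trees: list[Phylogeny] | None = None
    traits: pd.DataFrame | None = None
    subset_mode: str = "full"
    vpl_clades: tuple[str, ...] = DEFAULT_VPL_CLADES
    strict_vpl_species: tuple[str, ...] | None = None
    exclude_clades: tuple[str, ...] = ("odontocetes",)
    responses: tuple[str, ...] = RESPONSES
    outlier_threshold: float = 2.5
    mad_scale: float = 1.4826
    ou_alphas: tuple[float, ...] = DEFAULT_OU_ALPHAS
    alpha_level: float = 0.05
    barnard_grid_size: int = 200
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.outlier_threshold <= 0:
            raise ValueError("outlier_threshold must be > 0")
        if not 0.0 < self.alpha_level < 1.0:
            raise ValueError("alpha_level must be in (0, 1)")
        if self.subset_mode not in ("full", "no_odontocetes", "strict_vpl"):
            raise ValueError(f"unknown subset_mode {self.subset_mode!r}")
        bad = [r for r in self.responses if r not in RESPONSES]
        if bad:
            raise ValueError(f"unknown responses {bad}")


@dataclass
class ResponseResult:
    """Everything computed for one acoustic response."""

    response: str
    comparison: ModelComparison
    species: list[str]
    residuals: pd.Series  # response-scale (log10 Hz), indexed by species
    outlier_flags: pd.Series
    marks: pd.Series  # 'U'/'D'/''
    contingency: ContingencyTable2x2
    barnard: object
    residual_tests: list  # GroupComparison x 4
    raw_comparison: object  # GroupComparison in Hz/g

    @property
    def best_fit(self):
        return self.comparison.best


@dataclass
class AnalysisReport:
    """Structured result of :func:`run_analysis`."""

    config: RunConfig
    tree: Phylogeny
    traits: pd.DataFrame
    per_response: dict = field(default_factory=dict)  # response -> ResponseResult
    vpl_table: pd.DataFrame | None = None
    nonvpl_table: pd.DataFrame | None = None
    vpl_tally: object = None
    nonvpl_tally: object = None

    # -- consistency / export ------------------------------------------

    def audit(self) -> None:
        """Internal consistency checks: margins and tallies recompute."""
        n_vpl = int(self.traits["is_vpl"].sum())
        n_nonvpl = int((~self.traits["is_vpl"].astype(bool)).sum())
        for rr in self.per_response.values():
            sub = self.traits.set_index("species").loc[rr.species]
            assert rr.contingency.n_vpl == int(sub["is_vpl"].sum())
            assert rr.contingency.n_nonvpl == int((~sub["is_vpl"].astype(bool)).sum())
            assert rr.contingency.total == len(rr.species)
        for table, tally in ((self.vpl_table, self.vpl_tally),
                             (self.nonvpl_table, self.nonvpl_tally)):
            if table is not None and len(table):
                fresh = tally_outlier_table(table)
                assert fresh.as_dict() == tally.as_dict()
        del n_vpl, n_nonvpl

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for resp, rr in self.per_response.items():
            for f in rr.comparison.fits:
                chi2, p = f.wald_anova()[1]
                rows.append({
                    "response": resp,
                    "model": f.cov_spec.label,
                    "phylo_parameter": f.phylo_parameter,
                    "intercept": f.params[0],
                    "slope": f.params[1],
                    "slope_se": f.bse[1],
                    "slope_t": f.tvalues[1],
                    "wald_chi2": chi2,
                    "wald_p": p,
                    "loglik_reml": f.llf_reml,
                    "loglik_ml": f.llf_ml,
                    "aicc": f.aicc,
                    "selected": f is rr.best_fit,
                })
        return pd.DataFrame(rows)

    def residual_tests_frame(self) -> pd.DataFrame:
        rows = []
        for resp, rr in self.per_response.items():
            for gc in rr.residual_tests:
                rows.append({"response": resp, **gc.as_dict()})
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        out = {
            "provenance": {
                "package_version": __version__,
                "seed": self.config.seed,
                "subset_mode": self.config.subset_mode,
                "n_species": int(len(self.traits)),
                "n_vpl": int(self.traits["is_vpl"].sum()),
                "outlier_threshold": self.config.outlier_threshold,
                "mad_scale": self.config.mad_scale,
            },
            "responses": {},
            "tallies": {
                "vpl": self.vpl_tally.as_dict() if self.vpl_tally else None,
                "non_vpl": self.nonvpl_tally.as_dict() if self.nonvpl_tally else None,
            },
        }
        for resp, rr in self.per_response.items():
            f = rr.best_fit
            out["responses"][resp] = {
                "selected_model": f.cov_spec.label,
                "phylo_parameter": _r12(f.phylo_parameter),
                "slope": _r12(f.params[1]),
                "slope_se": _r12(f.bse[1]),
                "aicc": _r12(f.aicc),
                "n_outliers": int(rr.outlier_flags.sum()),
                "contingency": rr.contingency.as_dict(),
                "barnard": {"z": _r12(rr.barnard.z), "p": _r12(rr.barnard.p)},
            }
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fits_frame().to_csv(out / "fits.csv", index=False,
                                 float_format="%.12g")
        outliers = pd.concat(
            [t for t in (self.vpl_table, self.nonvpl_table)
             if t is not None and len(t)], ignore_index=True,
        ) if (self.vpl_table is not None or self.nonvpl_table is not None) \
            else pd.DataFrame()
        outliers.to_csv(out / "outliers.csv", index=False)
        self.residual_tests_frame().to_csv(out / "residual_tests.csv",
                                           index=False, float_format="%.12g")
        with open(out / "contingency.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _r12(x):
    if x is None:
        return None
    return float(f"{float(x):.12g}")


def _load_inputs(cfg: RunConfig) -> tuple[Phylogeny, pd.DataFrame]:
    if cfg.trees is not None:
        trees = list(cfg.trees)
    elif cfg.tree_path is not None:
        trees = read_newick(cfg.tree_path)
    else:
        raise ValueError("RunConfig needs trees or tree_path")
    if cfg.traits is not None:
        traits = cfg.traits.copy()
    elif cfg.traits_path is not None:
        traits = read_trait_table(cfg.traits_path)
    else:
        raise ValueError("RunConfig needs traits or traits_path")
    tree = trees[0] if len(trees) == 1 else consensus_edge_tree(trees)
    log.info("loaded %d tree(s); analysis tree has %d tips",
             len(trees), tree.n_tips)
    return tree, traits


def _apply_vpl_status(traits: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    traits = traits.copy()
    if cfg.subset_mode == "strict_vpl":
        if not cfg.strict_vpl_species:
            raise ValueError("strict_vpl mode requires strict_vpl_species")
        strict = set(cfg.strict_vpl_species)
        unknown = strict - set(traits["species"])
        if unknown:
            raise ValueError(f"strict VPL species not in dataset: {sorted(unknown)}")
        traits["is_vpl"] = traits["species"].isin(strict)
    elif "is_vpl" not in traits.columns:
        traits["is_vpl"] = traits["clade"].isin(cfg.vpl_clades)
    traits["is_vpl"] = traits["is_vpl"].astype(bool)
    return traits


def _apply_subset(traits: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    if cfg.subset_mode == "no_odontocetes":
        keep = ~traits["clade"].isin(cfg.exclude_clades)
        traits = traits.loc[keep].reset_index(drop=True)
        log.info("subset no_odontocetes: %d species retained", len(traits))
    if len(traits) == 0:
        raise ValueError("subset selection removed every species")
    return traits


def _analyze_response(resp: str, traits_log: pd.DataFrame, tree: Phylogeny,
                      cfg: RunConfig) -> ResponseResult:
    col = LOG_RESPONSE_COLUMNS[resp]
    usable = traits_log.loc[traits_log[col].notna()].reset_index(drop=True)
    dropped = len(traits_log) - len(usable)
    if dropped:
        log.warning("%s: %d species without a defined log feature dropped",
                    resp, dropped)
    sub_tree = (tree if len(usable) == len(traits_log)
                else prune_to_taxa(tree, usable["species"]))
    comparison = fit_allometry(usable, sub_tree, col, ou_alphas=cfg.ou_alphas)
    best = comparison.best
    species = sub_tree.tips  # fit order
    resid = pd.Series(best.resid, index=species).loc[sorted(species)]
    sub = usable.set_index("species").loc[resid.index]
    vpl = sub["is_vpl"].to_numpy(bool)
    flags = mad_outliers(resid.to_numpy(), threshold=cfg.outlier_threshold,
                         scale_b=cfg.mad_scale)
    marks = direction_marks(resid.to_numpy(), flags)
    contingency = build_contingency(flags, vpl)
    barnard = contingency.barnard(grid_size=cfg.barnard_grid_size)
    tests = []
    for scope in ("all", "outliers_only"):
        for form in ("signed", "absolute"):
            try:
                tests.append(residual_group_comparison(
                    resid.to_numpy(), vpl, scope=scope, form=form,
                    outlier_flags=flags))
            except ValueError as exc:  # a group empty after scoping
                log.warning("%s: %s/%s comparison skipped (%s)",
                            resp, scope, form, exc)
    raw = size_corrected_raw_comparison(sub.reset_index(), resp)
    for f in comparison.fits:
        log.info("%s: %-12s AICc=%.3f%s", resp, f.cov_spec.label, f.aicc,
                 "  <- selected" if f is best else "")
    log.info("%s: %d/%d outliers (VPL %d/%d); Barnard z=%.3f p=%.4g",
             resp, int(flags.sum()), len(flags),
             contingency.counts[0, 0], contingency.n_vpl, barnard.z, barnard.p)
    return ResponseResult(
        response=resp, comparison=comparison, species=list(resid.index),
        residuals=resid, outlier_flags=pd.Series(flags, index=resid.index),
        marks=pd.Series(marks, index=resid.index), contingency=contingency,
        barnard=barnard, residual_tests=tests, raw_comparison=raw,
    )


def run_analysis(cfg: RunConfig) -> AnalysisReport:
    """Run the full pipeline under ``cfg`` and return the report."""
    tree, traits = _load_inputs(cfg)
    traits = _apply_vpl_status(traits, cfg)
    traits = _apply_subset(traits, cfg)
    traits = traits.sort_values("species").reset_index(drop=True)
    table_sp, tree_sp = set(traits["species"]), set(tree.tips)
    extra = sorted(table_sp - tree_sp)
    if extra:
        raise ValueError(f"species in traits but not in tree: {extra}")
    if table_sp != tree_sp:
        n_drop = len(tree_sp - table_sp)
        tree = prune_to_taxa(tree, traits["species"])
        log.info("pruned tree to %d trait species (%d tips dropped)",
                 tree.n_tips, n_drop)
    traits_log = log_features(traits)

    report = AnalysisReport(config=cfg, tree=tree, traits=traits)
    for resp in cfg.responses:
        report.per_response[resp] = _analyze_response(resp, traits_log, tree, cfg)

    marks_by_resp = {resp: rr.marks.to_dict()
                     for resp, rr in report.per_response.items()}
    vpl_by_species = dict(zip(traits["species"], traits["is_vpl"]))
    full_table = build_outlier_table(marks_by_resp, vpl_by_species)
    report.vpl_table = full_table.loc[full_table["is_vpl"]].reset_index(drop=True)
    report.nonvpl_table = full_table.loc[~full_table["is_vpl"]].reset_index(drop=True)
    report.vpl_tally = tally_outlier_table(report.vpl_table)
    report.nonvpl_tally = tally_outlier_table(report.nonvpl_table)
    report.audit()
    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report


@dataclass
class RefitComparison:
    """Full-fit vs VPL-free slope comparison for one response."""

    response: str
    slope_full: float
    slope_full_se: float
    slope_vpl_free: float
    slope_vpl_free_se: float
    selected_model: str
    outlier_flags: pd.Series  # non-VPL species against the VPL-free line
    marks: pd.Series

    @property
    def slope_difference(self) -> float:
        return self.slope_vpl_free - self.slope_full


def vpl_free_refit(cfg: RunConfig, report: AnalysisReport) -> dict[str, RefitComparison]:
    """Refit all regressions on non-VPL species only.

    Returns per-response slope comparisons against the full fit, plus
    outlier re-calls of the non-VPL species against the VPL-free line
    (the candidate-species scan).
    """
    traits = report.traits
    if not traits["is_vpl"].any():
        raise ValueError("no VPL species in the dataset")
    nonvpl = traits.loc[~traits["is_vpl"]].reset_index(drop=True)
    sub_tree = prune_to_taxa(report.tree, nonvpl["species"])
    traits_log = log_features(nonvpl)
    out: dict[str, RefitComparison] = {}
    for resp, rr in report.per_response.items():
        col = LOG_RESPONSE_COLUMNS[resp]
        usable = traits_log.loc[traits_log[col].notna()].reset_index(drop=True)
        tree_r = (sub_tree if len(usable) == len(traits_log)
                  else prune_to_taxa(sub_tree, usable["species"]))
        comp = fit_allometry(usable, tree_r, col, ou_alphas=cfg.ou_alphas)
        best = comp.best
        resid = pd.Series(best.resid, index=tree_r.tips).sort_index()
        flags = mad_outliers(resid.to_numpy(), threshold=cfg.outlier_threshold,
                             scale_b=cfg.mad_scale)
        marks = pd.Series(direction_marks(resid.to_numpy(), flags),
                          index=resid.index)
        full_best = rr.best_fit
        out[resp] = RefitComparison(
            response=resp,
            slope_full=float(full_best.params[1]),
            slope_full_se=float(full_best.bse[1]),
            slope_vpl_free=float(best.params[1]),
            slope_vpl_free_se=float(best.bse[1]),
            selected_model=best.cov_spec.label,
            outlier_flags=pd.Series(flags, index=resid.index),
            marks=marks,
        )
    return out


def subset_run(cfg: RunConfig) -> AnalysisReport:
    """Run the pipeline on the configured subset (tagged in the report)."""
    return run_analysis(cfg)
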