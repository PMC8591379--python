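"""MAD outlier calling, direction marks, the five-category taxonomy and
residual group comparisons.

A species is an allometric outlier for a given acoustic response when its
raw (response-scale) PGLS residual deviates from the residual median by
more than ``threshold * scale_b * MAD``, with ``threshold = 2.5`` and the
normal-consistency constant ``scale_b = 1.4826`` by default (both
configurable; ``scale_b = 1`` gives the uncorrected variant).  Outliers
are marked U (above the regression line) or D (below).

The category taxonomy partitions outlier species by VPL status and mark
direction: 1 = VPL, only U; 2 = non-VPL, only D; 3 = VPL, only D;
4 = non-VPL, only U; 5 = VPL, mixed U and D.  A non-VPL species with
mixed marks has no published category and is assigned the sentinel 6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import BarnardResult, MannWhitneyResult, barnard_exact, mann_whitney_u

__all__ = [
    "TABLE_RESPONSE_ORDER",
    "ContingencyTable2x2",
    "CategorySummary",
    "GroupComparison",
    "mad_outliers",
    "direction_marks",
    "build_contingency",
    "assign_category",
    "build_outlier_table",
    "tally_outlier_table",
    "residual_group_comparison",
    "size_corrected_raw_comparison",
]

#: column order of the published outlier tables
TABLE_RESPONSE_ORDER = ("MaxDF", "MeanDF", "MinDF", "RangeDF")

NONVPL_MIXED_CATEGORY = 6


def mad_outliers(residuals, threshold: float = 2.5, scale_b: float = 1.4826,
                 center_on_median: bool = True) -> np.ndarray:
    """Flag residuals deviating from the median by > threshold * scale_b * MAD.

    With ``center_on_median=False`` deviations are measured from zero
    instead (the MAD itself is always median-based).  When the MAD is zero
    (more than half the residuals identical) a warning is issued and
    exactly the residuals strictly different from the median are flagged.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 3:
        raise ValueError("need at least 3 residuals for MAD outlier calling")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    dev = np.abs(r - med) if center_on_median else np.abs(r)
    if mad == 0:
        warnings.warn("MAD of residuals is zero; flagging values that "
                      "differ from the median", stacklevel=2)
        return r != med
    return dev > threshold * scale_b * mad


def direction_marks(residuals, flags) -> list[str]:
    """'U' for flagged positive residuals, 'D' for flagged negative, '' else."""
    r = np.asarray(residuals, dtype=float).ravel()
    f = np.asarray(flags, dtype=bool).ravel()
    if r.shape != f.shape:
        raise ValueError("residuals and flags must have equal length")
    assert not np.any(f & (r == 0)), \
        "a residual of exactly 0 cannot exceed a positive MAD threshold"
    return ["U" if (fi and ri > 0) else "D" if (fi and ri < 0) else ""
            for ri, fi in zip(r, f)]


@dataclass
class ContingencyTable2x2:
    """Counts ``[[vpl_outlier, vpl_non], [nonvpl_outlier, nonvpl_non]]``."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("counts must be a nonnegative 2x2 array")

    @property
    def n_vpl(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_nonvpl(self) -> int:
        return int(self.counts[1].sum())

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def barnard(self, grid_size: int = 200) -> BarnardResult:
        return barnard_exact(self.counts, grid_size=grid_size)

    def as_dict(self) -> dict:
        return {"vpl": [int(self.counts[0, 0]), int(self.counts[0, 1])],
                "non_vpl": [int(self.counts[1, 0]), int(self.counts[1, 1])]}


def build_contingency(flags, vpl) -> ContingencyTable2x2:
    """Cross-tabulate outlier flags against VPL membership."""
    f = np.asarray(flags, dtype=bool).ravel()
    v = np.asarray(vpl, dtype=bool).ravel()
    if f.size == 0:
        raise ValueError("empty input")
    if f.shape != v.shape:
        raise ValueError("flags and vpl must have equal length")
    counts = [[int((v & f).sum()), int((v & ~f).sum())],
              [int((~v & f).sum()), int((~v & ~f).sum())]]
    return ContingencyTable2x2(np.array(counts))


def assign_category(marks, is_vpl: bool) -> int:
    """Assign the outlier-taxonomy category (1-5, or sentinel 6).

    ``marks`` is the species' per-response direction marks ('U'/'D'/'').
    At least one mark must be present (a species with no marks is not an
    outlier and has no category).
    """
    ms = [m for m in marks if m]
    if not ms:
        raise ValueError("species has no direction marks; not an outlier")
    bad = set(ms) - {"U", "D"}
    if bad:
        raise ValueError(f"invalid direction marks: {sorted(bad)}")
    has_u = "U" in ms
    has_d = "D" in ms
    if is_vpl:
        if has_u and has_d:
            return 5
        return 1 if has_u else 3
    if has_u and has_d:
        return NONVPL_MIXED_CATEGORY
    return 4 if has_u else 2


def build_outlier_table(marks_by_response: dict[str, dict[str, str]],
                        vpl_by_species: dict[str, bool],
                        common_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Assemble the published-table-shaped outlier matrix.

    ``marks_by_response`` maps response name -> {species: mark}; only
    species with at least one non-empty mark get a row.  Rows are sorted
    by species name; columns follow the published order.
    """
    species = sorted({s for resp in marks_by_response.values()
                      for s, m in resp.items() if m})
    rows = []
    for sp in species:
        row = {"species": sp,
               "common_name": (common_names or {}).get(sp, "")}
        for resp in TABLE_RESPONSE_ORDER:
            row[resp] = marks_by_response.get(resp, {}).get(sp, "")
        row["is_vpl"] = bool(vpl_by_species[sp])
        row["category"] = assign_category(
            [row[r] for r in TABLE_RESPONSE_ORDER], row["is_vpl"])
        rows.append(row)
    cols = ["species", "common_name", *TABLE_RESPONSE_ORDER, "is_vpl", "category"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CategorySummary:
    """Tallies over an outlier table."""

    n_species: int
    total_marks: int
    n_upward: int
    n_downward: int
    per_response: dict = field(default_factory=dict)  # resp -> {"U": n, "D": n}
    category_counts: dict = field(default_factory=dict)  # category -> n species
    maxdf_rangedf_up_cooccurrence: int = 0
    meanrange_overlap_marks: int = 0

    def as_dict(self) -> dict:
        return {
            "n_species": self.n_species,
            "total_marks": self.total_marks,
            "n_upward": self.n_upward,
            "n_downward": self.n_downward,
            "per_response": self.per_response,
            "category_counts": {str(k): v for k, v in self.category_counts.items()},
            "maxdf_rangedf_up_cooccurrence": self.maxdf_rangedf_up_cooccurrence,
            "meanrange_overlap_marks": self.meanrange_overlap_marks,
        }


def tally_outlier_table(table: pd.DataFrame) -> CategorySummary:
    """Summarize direction marks and categories in an outlier table.

    Beyond total/per-column U/D counts and category counts, reports

    * the number of species marked U for MaxDF that are also marked U for
      RangeDF, and
    * the number of MeanDF/RangeDF marks belonging to species that also
      carry a MinDF or MaxDF mark (the derived features carry only two
      degrees of freedom, so this overlap is expected to be high).
    """
    if len(table) == 0:
        return CategorySummary(0, 0, 0, 0, {r: {"U": 0, "D": 0}
                                            for r in TABLE_RESPONSE_ORDER}, {})
    per_response = {}
    total_u = total_d = 0
    for resp in TABLE_RESPONSE_ORDER:
        col = table[resp].fillna("")
        u, d = int((col == "U").sum()), int((col == "D").sum())
        per_response[resp] = {"U": u, "D": d}
        total_u += u
        total_d += d
    cats = table["category"].value_counts().to_dict()
    cats = {int(k): int(v) for k, v in sorted(cats.items())}
    co = int(((table["MaxDF"] == "U") & (table["RangeDF"] == "U")).sum())
    has_primary = (table["MinDF"].fillna("") != "") | (table["MaxDF"].fillna("") != "")
    overlap = int((table.loc[has_primary, "MeanDF"].fillna("") != "").sum()
                  + (table.loc[has_primary, "RangeDF"].fillna("") != "").sum())
    return CategorySummary(
        n_species=len(table),
        total_marks=total_u + total_d,
        n_upward=total_u,
        n_downward=total_d,
        per_response=per_response,
        category_counts=cats,
        maxdf_rangedf_up_cooccurrence=co,
        meanrange_overlap_marks=overlap,
    )


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of residuals (or raw values) between groups."""

    mean_vpl: float
    mean_nonvpl: float
    se_vpl: float
    se_nonvpl: float
    n_vpl: int
    n_nonvpl: int
    test: MannWhitneyResult
    scope: str = "all"
    form: str = "signed"

    def as_dict(self) -> dict:
        return {
            "mean_vpl": self.mean_vpl, "mean_nonvpl": self.mean_nonvpl,
            "se_vpl": self.se_vpl, "se_nonvpl": self.se_nonvpl,
            "n_vpl": self.n_vpl, "n_nonvpl": self.n_nonvpl,
            "w": self.test.w, "p": self.test.p, "method": self.test.method,
            "scope": self.scope, "form": self.form,
        }


def _compare_groups(vals_vpl, vals_nonvpl, scope, form) -> GroupComparison:
    mw = mann_whitney_u(vals_vpl, vals_nonvpl)
    def se(v):
        return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return GroupComparison(
        mean_vpl=float(np.mean(vals_vpl)),
        mean_nonvpl=float(np.mean(vals_nonvpl)),
        se_vpl=se(vals_vpl), se_nonvpl=se(vals_nonvpl),
        n_vpl=len(vals_vpl), n_nonvpl=len(vals_nonvpl),
        test=mw, scope=scope, form=form,
    )


def residual_group_comparison(residuals, vpl, scope: str = "all",
                              form: str = "signed",
                              outlier_flags=None) -> GroupComparison:
    """Compare VPL vs non-VPL residual distributions (Mann-Whitney).

    ``scope='outliers_only'`` restricts to flagged species (requires
    ``outlier_flags``); ``form='absolute'`` compares magnitudes.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    v = np.asarray(vpl, dtype=bool).ravel()
    if scope not in ("all", "outliers_only"):
        raise ValueError("scope must be 'all' or 'outliers_only'")
    if form not in ("signed", "absolute"):
        raise ValueError("form must be 'signed' or 'absolute'")
    if scope == "outliers_only":
        if outlier_flags is None:
            raise ValueError("outlier_flags required for scope='outliers_only'")
        keep = np.asarray(outlier_flags, dtype=bool).ravel()
        r, v = r[keep], v[keep]
    if form == "absolute":
        r = np.abs(r)
    if not v.any() or v.all():
        raise ValueError(f"a group is empty under scope={scope!r}")
    return _compare_groups(r[v], r[~v], scope, form)


def size_corrected_raw_comparison(table: pd.DataFrame, feature: str) -> GroupComparison:
    """Compare raw per-gram acoustic values (Hz/g) between VPL and non-VPL.

    ``feature`` is a response name (e.g. 'MinDF') or a trait column.  Each
    species' value is its raw frequency divided by its body mass, removing
    systematic body-size differences between the groups.
    """
    from .traits import RESPONSE_COLUMNS

    col = RESPONSE_COLUMNS.get(feature, feature)
    if col not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    vals = table[col].to_numpy(float) / table["body_mass_g"].to_numpy(float)
    v = table["is_vpl"].to_numpy(bool)
    if not v.any() or v.all():
        raise ValueError("both VPL and non-VPL species are required")
    return _compare_groups(vals[v], vals[~v], scope="all", form="hz_per_g")
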