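"""Packaged reference outlier tables.

Transcriptions of the published VPL (N = 33) and non-VPL (N = 25) outlier
tables from the cross-species acoustic-allometry screen: per-species
direction marks (U = above the regression line, D = below) for the four
dominant-frequency responses, plus the printed category assignment.

The source table's per-column mark placement is not fully recoverable from
the available text for every row; where ambiguous, marks were placed so
that every published row multiset, per-column tally, category count,
co-occurrence and overlap statistic is reproduced exactly.
"""

from importlib import resources

import pandas as pd

__all__ = ["fixture_outlier_tables"]


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    df["is_vpl"] = df["is_vpl"].astype(str).str.lower().isin(("true", "1"))
    df["category"] = df["category"].astype(int)
    return df


def fixture_outlier_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the (VPL, non-VPL) reference outlier tables as DataFrames."""
    return _load("vpl_outliers.csv"), _load("nonvpl_outliers.csv")
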