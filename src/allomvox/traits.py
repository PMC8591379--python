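"""Species trait tables: reading, validation and feature transforms.

The canonical on-disk format is a CSV with header
``species,body_mass_g,min_df_hz,max_df_hz,clade,is_vpl`` (``is_vpl`` may be
omitted when VPL status is derived from clade labels downstream).  Reading
derives the mean dominant frequency ``mean_df_hz = (min + max) / 2`` and
the frequency range ``range_df_hz = max - min``, validates positivity and
``max >= min`` per row, and can reconcile species names against a tree.

``log_features`` applies base-10 logarithms to mass and the four frequency
features.  Slopes of log-log regressions are invariant to the common log
base; intercepts are reported base-10.  A frequency range of zero has no
logarithm: such rows get ``NaN`` in ``log_range_df`` (with a warning) and
are excluded from the RangeDF regression, unless a positive ``offset`` is
supplied to shift all range values before the transform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trees import Phylogeny, normalize_name

__all__ = [
    "REQUIRED_COLUMNS",
    "RESPONSES",
    "RESPONSE_COLUMNS",
    "LOG_RESPONSE_COLUMNS",
    "read_trait_table",
    "validate_trait_table",
    "derive_features",
    "log_features",
    "match_species",
]

REQUIRED_COLUMNS = ("species", "body_mass_g", "min_df_hz", "max_df_hz", "clade")

#: the four acoustic responses, in regression order
RESPONSES = ("MinDF", "MaxDF", "MeanDF", "RangeDF")

RESPONSE_COLUMNS = {
    "MinDF": "min_df_hz",
    "MaxDF": "max_df_hz",
    "MeanDF": "mean_df_hz",
    "RangeDF": "range_df_hz",
}

LOG_RESPONSE_COLUMNS = {
    "MinDF": "log_min_df",
    "MaxDF": "log_max_df",
    "MeanDF": "log_mean_df",
    "RangeDF": "log_range_df",
}


def read_trait_table(path, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Read and validate a trait CSV; derive MeanDF and RangeDF columns."""
    df = pd.read_csv(path)
    return validate_trait_table(df, tree=tree)


def validate_trait_table(df: pd.DataFrame, tree: Phylogeny | None = None) -> pd.DataFrame:
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing required columns: {missing}")
    df["species"] = df["species"].astype(str).map(str.strip)
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate species in trait table: {sorted(set(dupes))}")
    for col in ("body_mass_g", "min_df_hz", "max_df_hz"):
        df[col] = pd.to_numeric(df[col])
        bad = df.loc[df[col] <= 0, "species"].tolist()
        if bad:
            raise ValueError(f"non-positive {col} for species: {bad}")
    bad = df.loc[df["max_df_hz"] < df["min_df_hz"], "species"].tolist()
    if bad:
        raise ValueError(f"max_df_hz < min_df_hz for species: {bad}")
    if "is_vpl" in df.columns:
        df["is_vpl"] = df["is_vpl"].map(_parse_bool)
    df = derive_features(df)
    if tree is not None:
        match_species(df, tree)
    return df


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "t", "1", "yes"):
        return True
    if s in ("false", "f", "0", "no"):
        return False
    raise ValueError(f"cannot interpret is_vpl value {v!r}")


def derive_features(df: pd.DataFrame) -> pd.DataFrame:
    """Populate ``mean_df_hz`` and ``range_df_hz`` from min/max."""
    df = df.copy()
    df["mean_df_hz"] = (df["min_df_hz"] + df["max_df_hz"]) / 2.0
    df["range_df_hz"] = df["max_df_hz"] - df["min_df_hz"]
    return df


def match_species(df: pd.DataFrame, tree: Phylogeny) -> dict[str, str]:
    """Match trait-table species 1:1 to tree tips.

    Exact string match after underscore/space normalization.  Raises with
    the full diff when any species is unmatched in either direction.
    """
    table_norm = {normalize_name(s): s for s in df["species"]}
    tree_norm = {normalize_name(t): t for t in tree.tips}
    only_table = sorted(table_norm.keys() - tree_norm.keys())
    only_tree = sorted(tree_norm.keys() - table_norm.keys())
    if only_table or only_tree:
        raise ValueError(
            "species mismatch between trait table and tree; "
            f"in table only: {only_table}; in tree only: {only_tree}"
        )
    return {table_norm[k]: tree_norm[k] for k in table_norm}


def log_features(df: pd.DataFrame, offset: float | None = None) -> pd.DataFrame:
    """Add base-10 log columns for mass and the four frequency features.

    Original columns are retained.  ``offset`` (if given, > 0) is added to
    ``range_df_hz`` before the transform; otherwise zero ranges produce
    ``NaN`` with a warning and are excluded from the RangeDF regression
    downstream.
    """
    df = df.copy()
    for col in ("body_mass_g", "min_df_hz", "max_df_hz", "mean_df_hz"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "species"].tolist()
            raise ValueError(f"cannot log-transform non-positive {col}: {bad}")
    df["log_body_mass"] = np.log10(df["body_mass_g"])
    df["log_min_df"] = np.log10(df["min_df_hz"])
    df["log_max_df"] = np.log10(df["max_df_hz"])
    df["log_mean_df"] = np.log10(df["mean_df_hz"])
    rng = df["range_df_hz"].to_numpy(float)
    if offset is not None:
        if offset <= 0:
            raise ValueError("offset must be > 0")
        df["log_range_df"] = np.log10(rng + offset)
    else:
        if (rng < 0).any():  # impossible after validation; defensive
            raise ValueError("negative range_df_hz")
        zero = rng == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} species have zero frequency range; "
                "their log_range_df is NaN and they are excluded from the "
                "RangeDF regression (pass offset= to keep them)",
                stacklevel=2,
            )
        with np.errstate(divide="ignore"):
            lr = np.log10(rng, where=rng > 0, out=np.full_like(rng, np.nan))
        df["log_range_df"] = lr
    return df
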