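"""Experience-sampling data model, CSV I/O, and deterministic transformations.

The central container is :class:`EsmTable`, a validated long-format table with
one row per subject x assessment ("beep"): continuous time in days since the
subject's first assessment, four emotion sum scores (four 1-4 Likert items
each, hence 4-16), a Bluetooth device count used as a social-presence proxy,
self-reported counts of known/unknown people nearby, and a situational-control
rating in [0, 1].  Item-level responses for reliability analysis live in
:class:`ItemTable`.

All downstream models consume the transformations defined here: the log(x+1)
count transform, complete-case filtering, within-subject (cwc) and
grand-mean (cmc) centering, and lagging of predictors by one assessment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ESM_COLUMNS",
    "ITEM_COLUMNS",
    "CONSTRUCTS",
    "EsmTable",
    "ItemTable",
    "log1p_transform",
    "filter_complete",
    "center_within",
    "center_means",
    "add_centered",
    "lag_predictors",
    "read_esm_csv",
    "write_esm_csv",
    "read_item_csv",
    "write_item_csv",
]

#: canonical ESM CSV column order
ESM_COLUMNS = [
    "subject_id",
    "beep_index",
    "t_days",
    "vigor",
    "fatigue",
    "dejection",
    "anger",
    "bt_count",
    "people_known",
    "people_unknown",
    "control",
]

ITEM_COLUMNS = ["subject_id", "occasion_index", "construct", "item_index", "response"]

#: the four emotion constructs, four items each
CONSTRUCTS = ["vigor", "fatigue", "dejection", "anger"]

_SCORE_BOUNDS = (4, 16)


class EsmDataError(ValueError):
    """Raised for schema or invariant violations in ESM tables."""


@dataclass
class EsmTable:
    """Validated long-format ESM table.

    Wraps a :class:`pandas.DataFrame` with the canonical column schema.  Rows
    are kept stably sorted by ``(subject_id, t_days)``; ``(subject_id,
    beep_index)`` must be unique and time must strictly increase with beep
    index within each subject.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ESM_COLUMNS if c not in df.columns]
        if missing:
            raise EsmDataError(f"missing mandatory columns: {missing}")
        df = df.copy()
        for c in ESM_COLUMNS:
            if c != "subject_id":
                df[c] = pd.to_numeric(df[c], errors="raise")
        df = df.sort_values(["subject_id", "t_days"], kind="stable").reset_index(drop=True)
        dup = df.duplicated(["subject_id", "beep_index"])
        if dup.any():
            row = df.index[dup][0]
            raise EsmDataError(f"duplicate (subject_id, beep_index) at row {row}")
        for sid, g in df.groupby("subject_id", sort=False):
            t = g["t_days"].to_numpy()
            b = g["beep_index"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise EsmDataError(f"non-increasing t_days within subject {sid!r}")
            if np.any(np.diff(b) <= 0):
                raise EsmDataError(f"beep_index not increasing with time for subject {sid!r}")
            if (t < 0).any():
                raise EsmDataError(f"negative t_days for subject {sid!r}")
        lo, hi = _SCORE_BOUNDS
        for c in CONSTRUCTS:
            v = df[c].dropna()
            if ((v < lo) | (v > hi)).any():
                raise EsmDataError(f"{c} sum scores outside [{lo}, {hi}]")
        for c in ("bt_count", "people_known", "people_unknown"):
            v = df[c].dropna()
            if (v < 0).any():
                raise EsmDataError(f"negative values in {c}")
        ctrl = df["control"].dropna()
        if ((ctrl < 0) | (ctrl > 1)).any():
            raise EsmDataError("control outside [0, 1]")
        object.__setattr__(self, "df", df)

    # -- convenience ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def with_derived(self) -> pd.DataFrame:
        """Return a copy of the frame with ``log_bt`` and ``people_total`` added."""
        df = self.df.copy()
        df["log_bt"] = log1p_transform(df["bt_count"])
        df["people_total"] = df["people_known"] + df["people_unknown"]
        return df

    def groupby_subject(self):
        return self.df.groupby("subject_id", sort=False)


@dataclass
class ItemTable:
    """Item-level Likert responses (subject x occasion x construct x item)."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ITEM_COLUMNS if c not in df.columns]
        if missing:
            raise EsmDataError(f"missing mandatory columns: {missing}")
        df = df.copy().reset_index(drop=True)
        bad = ~df["construct"].isin(CONSTRUCTS)
        if bad.any():
            raise EsmDataError(f"unknown construct values: {sorted(df.loc[bad, 'construct'].unique())}")
        resp = pd.to_numeric(df["response"], errors="raise")
        if (~resp.isin([1, 2, 3, 4])).any():
            raise EsmDataError("responses must be in {1, 2, 3, 4}")
        df["response"] = resp.astype(int)
        if df.duplicated(["subject_id", "occasion_index", "construct", "item_index"]).any():
            raise EsmDataError("duplicate (subject, occasion, construct, item) cell")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def log1p_transform(x):
    """Natural log of (x + 1) for non-negative counts.

    Strictly monotone; maps 0 to 0.  Raises on negative input.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("log1p_transform requires non-negative input")
    out = np.log1p(arr)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    if np.isscalar(x):
        return float(out)
    return out


def filter_complete(table: EsmTable, required_columns: list[str]) -> EsmTable:
    """Drop rows with any missing value in ``required_columns`` (complete case).

    Derived columns ``log_bt`` and ``people_total`` may be named; they map to
    their source columns.  Row order is preserved.
    """
    derived = {"log_bt": ["bt_count"], "people_total": ["people_known", "people_unknown"]}
    cols: list[str] = []
    for c in required_columns:
        if c in derived:
            cols.extend(derived[c])
        elif c in table.df.columns:
            cols.append(c)
        else:
            raise EsmDataError(f"unknown column {c!r}")
    kept = table.df.dropna(subset=cols)
    n_removed = len(table.df) - len(kept)
    if n_removed:
        logger.info("filter_complete: removed %d of %d rows with missing %s",
                    n_removed, len(table.df), cols)
    return EsmTable(kept)


def center_within(df: pd.DataFrame, column: str) -> tuple[pd.Series, pd.Series]:
    """Center ``column`` within subject (cwc).

    Returns ``(cwc, subject_mean)`` aligned to the frame's index; the subject
    mean series is broadcast back to the rows so that ``cwc + subject_mean``
    reconstructs the raw column.  Within each subject the cwc values sum to
    zero over the non-missing entries.
    """
    if column not in df.columns:
        raise EsmDataError(f"unknown column {column!r}")
    means = df.groupby("subject_id")[column].transform("mean")
    cwc = df[column] - means
    return cwc.rename(f"{column}_cwc"), means.rename(f"{column}_mean")


def center_means(subject_means: pd.Series) -> pd.Series:
    """Grand-mean center subject means (cmc).

    ``subject_means`` may be per-subject (unique index) or broadcast to rows;
    the grand mean is taken over *subjects*, not rows, so compliance imbalance
    does not tilt it.
    """
    name = subject_means.name or "mean"
    if subject_means.index.has_duplicates:
        # broadcast-to-rows form: one value per subject assumed constant
        per_subj = subject_means.groupby(subject_means.index).first()
    else:
        per_subj = subject_means
    grand = per_subj.mean()
    return (subject_means - grand).rename(str(name).replace("_mean", "") + "_cmc")


def add_centered(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Attach ``<col>_cwc`` and ``<col>_cmc`` for each column (cwc/cmc split).

    The cmc column is the subject's mean centered at the grand mean of subject
    means, constant within subject.
    """
    out = df.copy()
    for col in columns:
        cwc, means = center_within(out, col)
        per_subj = out.groupby("subject_id")[col].mean()
        grand = per_subj.mean()
        out[f"{col}_cwc"] = cwc
        out[f"{col}_cmc"] = means - grand
    return out


def lag_predictors(df: pd.DataFrame, columns: list[str], suffix: str = "_lag1") -> pd.DataFrame:
    """Attach each column shifted by one assessment within subject.

    Lagging is by assessment order (the previous completed beep), not by clock
    time; overnight gaps are lagged like any other.  The first assessment of
    each subject has no predecessor and is dropped, so a subject with a single
    assessment contributes no rows.
    """
    for c in columns:
        if c not in df.columns:
            raise EsmDataError(f"unknown column {c!r}")
    out = df.copy()
    g = out.groupby("subject_id", sort=False)
    for c in columns:
        out[c + suffix] = g[c].shift(1)
    first = g.cumcount() == 0
    return out.loc[~first].reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_esm_csv(path) -> EsmTable:
    """Read the canonical ESM CSV (empty fields and "NA" parse as missing)."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype={"subject_id": str})
    missing = [c for c in ESM_COLUMNS if c not in df.columns]
    if missing:
        raise EsmDataError(f"{path}: missing mandatory columns {missing}")
    try:
        return EsmTable(df)
    except (ValueError, TypeError) as exc:
        raise EsmDataError(f"{path}: {exc}") from exc


def write_esm_csv(table: EsmTable, path) -> None:
    """Write the canonical ESM CSV; write-then-read is the identity."""
    df = table.df[ESM_COLUMNS].copy()
    df.to_csv(path, index=False, na_rep="", float_format="%.10g")


def read_item_csv(path) -> ItemTable:
    df = pd.read_csv(path, na_values=["NA"], dtype={"subject_id": str})
    try:
        return ItemTable(df)
    except (ValueError, TypeError) as exc:
        raise EsmDataError(f"{path}: {exc}") from exc


def write_item_csv(table: ItemTable, path) -> None:
    table.df[ITEM_COLUMNS].to_csv(path, index=False)
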