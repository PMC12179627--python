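"""Generalizability-theory variance decomposition for emotion item responses.

A fully crossed random-effects design person x item x occasion is decomposed
into seven variance components (p, i, o, pi, po, io, residual) with
expected-mean-squares (ANOVA) estimators; the three-way interaction is
confounded with the residual at one observation per cell.  The
generalizability coefficient for the mean over ``n_items`` items and
``n_occasions`` occasions is the relative coefficient

    rho^2 = var_p / (var_p + var_pi/n_i + var_po/n_o + var_res/(n_i n_o)),

the multi-facet analogue of reliability: the share of observed-score variance
attributable to stable between-person differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CONSTRUCTS, ItemTable

__all__ = [
    "VarianceComponents",
    "GStudy",
    "decompose_variance",
    "g_coefficient",
    "percent_components",
    "gtheory_report",
]

COMPONENT_ORDER = ["p", "i", "o", "pi", "po", "io", "res"]


@dataclass
class VarianceComponents:
    """Estimated variance components of the crossed p x i x o design."""

    components: dict          # name -> sigma^2, all >= 0 after truncation
    n_items: int
    n_occasions: int
    n_subjects: int
    truncated: list           # components clipped at zero
    degenerate: bool = False  # constant responses

    def __getitem__(self, key: str) -> float:
        return self.components[key]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def percent(self) -> dict:
        return percent_components(self)


class GStudy:
    """G-study of one construct from item-level responses.

    Accepts an :class:`ItemTable` or any DataFrame with columns
    ``subject_id, occasion_index, construct, item_index, response``.
    """

    def __init__(self, items, construct: str = None):
        df = items.df if isinstance(items, ItemTable) else items
        if construct is not None:
            if construct not in CONSTRUCTS:
                raise ValueError(f"unknown construct {construct!r}")
            df = df[df["construct"] == construct]
        self.df = df
        self.construct = construct

    def fit(self) -> VarianceComponents:
        return decompose_variance(self.df, self.construct)


def decompose_variance(items, construct: str | None = None) -> VarianceComponents:
    """EMS estimates of the seven crossed variance components.

    Balanced data use the classical expected-mean-squares solution exactly;
    cells missing from the crossing are tolerated by computing marginal means
    over available cells and harmonic-mean level counts in the EMS
    coefficients (a moment approximation).  Negative solutions are truncated
    at zero with a warning.
    """
    df = items.df if isinstance(items, ItemTable) else items
    if construct is not None:
        df = df[df["construct"] == construct]
    if df.empty:
        raise ValueError("no responses to decompose")
    for col, lab in (("subject_id", "persons"), ("item_index", "items"),
                     ("occasion_index", "occasions")):
        if df[col].nunique() < 2:
            raise ValueError(f"need at least 2 levels of {lab}")

    cube = df.pivot_table(index="subject_id", columns=["item_index", "occasion_index"],
                          values="response", aggfunc="mean")
    items_lv = cube.columns.get_level_values(0).unique()
    occs_lv = cube.columns.get_level_values(1).unique()
    arr = np.full((cube.shape[0], items_lv.size, occs_lv.size), np.nan)
    for j, it in enumerate(items_lv):
        for k, oc in enumerate(occs_lv):
            if (it, oc) in cube.columns:
                arr[:, j, k] = cube[(it, oc)].to_numpy()
    np_, ni, no = arr.shape

    if np.nanstd(arr) == 0:
        comps = {k: 0.0 for k in COMPONENT_ORDER}
        return VarianceComponents(comps, ni, no, np_, [], degenerate=True)

    present = ~np.isnan(arr)
    if present.all():
        n_p, n_i, n_o = float(np_), float(ni), float(no)
    else:
        # harmonic-mean level counts for the moment equations
        def _hmean(x):
            x = x[x > 0]
            return x.size / np.sum(1.0 / x)
        n_p = _hmean(present.sum(axis=0).ravel().astype(float))
        n_i = _hmean(present.sum(axis=1).ravel().astype(float))
        n_o = _hmean(present.sum(axis=2).ravel().astype(float))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(arr)
        m_p = np.nanmean(arr, axis=(1, 2))
        m_i = np.nanmean(arr, axis=(0, 2))
        m_o = np.nanmean(arr, axis=(0, 1))
        m_pi = np.nanmean(arr, axis=2)
        m_po = np.nanmean(arr, axis=1)
        m_io = np.nanmean(arr, axis=0)

    ss_p = n_i * n_o * np.nansum((m_p - m) ** 2)
    ss_i = n_p * n_o * np.nansum((m_i - m) ** 2)
    ss_o = n_p * n_i * np.nansum((m_o - m) ** 2)
    ss_pi = n_o * np.nansum((m_pi - m_p[:, None] - m_i[None, :] + m) ** 2)
    ss_po = n_i * np.nansum((m_po - m_p[:, None] - m_o[None, :] + m) ** 2)
    ss_io = n_p * np.nansum((m_io - m_i[:, None] - m_o[None, :] + m) ** 2)
    resid = (arr - m_pi[:, :, None] - m_po[:, None, :] - m_io[None, :, :]
             + m_p[:, None, None] + m_i[None, :, None] + m_o[None, None, :] - m)
    ss_res = np.nansum(resid ** 2)

    df_p, df_i, df_o = np_ - 1, ni - 1, no - 1
    df_pi, df_po, df_io = df_p * df_i, df_p * df_o, df_i * df_o
    df_res = df_p * df_i * df_o
    ms = np.array([ss_p / df_p, ss_i / df_i, ss_o / df_o, ss_pi / df_pi,
                   ss_po / df_po, ss_io / df_io, ss_res / df_res])

    # EMS coefficient matrix: rows = MS_p..MS_res, cols = components in order
    C = np.array([
        # p           i           o           pi    po    io    res
        [n_i * n_o,   0,          0,          n_o,  n_i,  0,    1],
        [0,           n_p * n_o,  0,          n_o,  0,    n_p,  1],
        [0,           0,          n_p * n_i,  0,    n_i,  n_p,  1],
        [0,           0,          0,          n_o,  0,    0,    1],
        [0,           0,          0,          0,    n_i,  0,    1],
        [0,           0,          0,          0,    0,    n_p,  1],
        [0,           0,          0,          0,    0,    0,    1],
    ], dtype=float)
    sol = np.linalg.solve(C, ms)
    truncated = [COMPONENT_ORDER[k] for k in range(7) if sol[k] < 0]
    if truncated:
        warnings.warn(f"negative variance estimates truncated to 0: {truncated}",
                      RuntimeWarning)
    comps = {COMPONENT_ORDER[k]: float(max(sol[k], 0.0)) for k in range(7)}
    return VarianceComponents(comps, ni, no, np_, truncated)


def g_coefficient(vc: VarianceComponents, n_items: int | None = None,
                  n_occasions: int | None = None) -> float:
    """Relative generalizability coefficient of the mean score.

    Averages over both items and occasions; only person-crossed error facets
    (pi, po, residual) enter the denominator.
    """
    n_i = vc.n_items if n_items is None else n_items
    n_o = vc.n_occasions if n_occasions is None else n_occasions
    num = vc["p"]
    den = num + vc["pi"] / n_i + vc["po"] / n_o + vc["res"] / (n_i * n_o)
    if den == 0:
        raise ValueError("generalizability coefficient undefined: no variance")
    return float(num / den)


def percent_components(vc: VarianceComponents) -> dict:
    """Each component as a percentage of the total; sums to 100."""
    total = vc.total
    if total == 0:
        return {k: 0.0 for k in COMPONENT_ORDER}
    return {k: 100.0 * v / total for k, v in vc.components.items()}


def gtheory_report(items: ItemTable, n_items: int | None = None,
                   n_occasions: int | None = None) -> pd.DataFrame:
    """Per-construct component shares and rho^2, one row per construct."""
    rows = []
    for c in CONSTRUCTS:
        sub = items.df[items.df["construct"] == c]
        if sub.empty:
            continue
        vc = decompose_variance(sub)
        pct = percent_components(vc)
        rho2 = g_coefficient(vc, n_items, n_occasions)
        rows.append({"construct": c, **{f"pct_{k}": pct[k] for k in COMPONENT_ORDER},
                     "rho2": rho2, "n_items": vc.n_items,
                     "n_occasions": vc.n_occasions})
    return pd.DataFrame(rows)
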