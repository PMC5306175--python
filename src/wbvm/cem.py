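"""Coarsened Exact Matching (CEM) utilities.

Optional pipeline stage for deriving study-population weights when an
external training population must be matched to the study population:
covariates are coarsened into bins, members are exact-matched on the tuple
of bin signatures, and comparison members are weighted to reproduce the
treated arm's stratum distribution.  Weights follow the canonical CEM
definition (Iacus, King & Porro): treated members in matched strata get
weight 1; a comparison member in matched stratum s gets

    w_s = (treated_s / comparison_s) * (matched comparison / matched treated)

and members in unmatched strata get weight 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoarseningSpec",
    "MatchedWeights",
    "coarsen",
    "match",
    "l1_imbalance",
    "auto_spec",
]


@dataclass(frozen=True)
class CoarseningSpec:
    """Per-covariate binning: cut points (continuous) or groupings (discrete).

    ``cuts[c]`` is a strictly increasing sequence of cut points; bins are
    left-closed, right-open except the last.  ``groups[c]`` maps each
    category to a group label; the labels must partition the categories.
    """

    cuts: dict[str, tuple[float, ...]] = field(default_factory=dict)
    groups: dict[str, dict[Hashable, Hashable]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, pts in self.cuts.items():
            arr = np.asarray(pts, float)
            if len(arr) < 2 or not np.all(np.diff(arr) > 0):
                raise ValueError(
                    f"cut points for {c!r} must be strictly increasing "
                    "with at least two values")

    @property
    def covariates(self) -> list[str]:
        return list(self.cuts) + list(self.groups)


def auto_spec(table: pd.DataFrame,
              covariates: Sequence[str] | None = None) -> CoarseningSpec:
    """Sturges-rule binning for continuous covariates (non-canonical default).

    Columns with few distinct values are treated as discrete (identity
    grouping).
    """
    covariates = list(covariates or table.columns)
    cuts: dict[str, tuple[float, ...]] = {}
    groups: dict[str, dict] = {}
    for c in covariates:
        vals = table[c].dropna()
        if vals.nunique() <= 10:
            groups[c] = {v: v for v in vals.unique()}
            continue
        k = int(math.ceil(math.log2(len(vals))) + 1)
        edges = np.linspace(float(vals.min()), float(vals.max()), k + 1)
        cuts[c] = tuple(np.unique(edges))
    return CoarseningSpec(cuts=cuts, groups=groups)


def coarsen(table: pd.DataFrame, spec: CoarseningSpec,
            strict: bool = False) -> pd.Series:
    """Map each member to its tuple of coarsened covariate bins.

    Values outside the outermost cut points are assigned to the boundary
    bin with a warning; ``strict=True`` raises instead.
    """
    missing = [c for c in spec.covariates if c not in table.columns]
    if missing:
        raise KeyError(f"covariates absent from table: {missing}")
    parts: list[pd.Series] = []
    for c, pts in spec.cuts.items():
        v = table[c].astype(float).to_numpy()
        lo, hi = pts[0], pts[-1]
        outside = (v < lo) | (v > hi)
        if outside.any():
            msg = (f"{int(outside.sum())} value(s) of {c!r} outside the cut "
                   f"range [{lo}, {hi}]")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg + "; assigned to the boundary bin")
        # left-closed, right-open except the last bin, which is closed
        idx = np.searchsorted(pts, v, side="right") - 1
        idx = np.clip(idx, 0, len(pts) - 2)
        parts.append(pd.Series(idx, index=table.index, name=c))
    for c, grouping in spec.groups.items():
        parts.append(table[c].map(lambda x: grouping.get(x, x)).rename(c))
    sig = pd.Series(list(zip(*[p.to_numpy() for p in parts])),
                    index=table.index)
    return sig


@dataclass
class MatchedWeights:
    weights: pd.Series
    strata: pd.DataFrame       # per stratum: treated and comparison counts
    matched_treated: int
    matched_comparison: int
    l1_before: float
    l1_after: float


def l1_imbalance(signatures: pd.Series, treated: pd.Series,
                 weights: pd.Series | None = None) -> float:
    """Multivariate L1 distance between arm distributions over strata."""
    treated = treated.astype(bool)
    if weights is None:
        weights = pd.Series(1.0, index=signatures.index)
    df = pd.DataFrame({"sig": signatures, "t": treated, "w": weights})
    tw = df.loc[df["t"]].groupby("sig")["w"].sum()
    cw = df.loc[~df["t"]].groupby("sig")["w"].sum()
    if tw.sum() == 0 or cw.sum() == 0:
        return 1.0
    tw, cw = tw / tw.sum(), cw / cw.sum()
    all_sigs = tw.index.union(cw.index)
    return 0.5 * float(
        (tw.reindex(all_sigs, fill_value=0.0)
         - cw.reindex(all_sigs, fill_value=0.0)).abs().sum())


def match(signatures: pd.Series, treatment_flags: pd.Series
          ) -> MatchedWeights:
    """Exact matching on bin signatures with canonical CEM weights."""
    treated = treatment_flags.astype(bool)
    if treated.all() or not treated.any():
        raise ValueError("both arms must be non-empty")
    df = pd.DataFrame({"sig": signatures, "t": treated})
    counts = df.groupby(["sig", "t"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=[False, True], fill_value=0)
    counts.columns = ["comparison", "treated"]
    matched = counts[(counts["treated"] > 0) & (counts["comparison"] > 0)]
    weights = pd.Series(0.0, index=signatures.index)
    m_t = int(matched["treated"].sum())
    m_c = int(matched["comparison"].sum())
    if m_t == 0:
        warnings.warn("no stratum contains both arms: all weights zero")
    else:
        scale = m_c / m_t
        for sig, row in matched.iterrows():
            in_stratum = signatures == sig
            weights[in_stratum & treated] = 1.0
            weights[in_stratum & ~treated] = (
                row["treated"] / row["comparison"]) * scale
    return MatchedWeights(
        weights=weights,
        strata=counts,
        matched_treated=m_t,
        matched_comparison=m_c,
        l1_before=l1_imbalance(signatures, treated),
        l1_after=l1_imbalance(signatures, treated, weights)
        if m_t else 1.0,
    )
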