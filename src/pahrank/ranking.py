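"""Facility ranking: four methods plus a residual variant.

Method 1   events per resident (optionally per bed).
Method 2   events per person-year of follow-up (exact or approximated
           exposure).
Method 3   model-predicted events per facility — a case-mix risk score.
Method 4   change in ranks, Method 2 minus Method 3: positive change means
           observed use above what resident case-mix predicts.
Residual   observed minus predicted counts (raw or Pearson), the
           model-residual alternative to Method 4.

Rank 1 always marks the lowest PAH use; rank n the highest. Ties are broken
deterministically (stable sort on value then facility id) so every computed
method yields a strict permutation of 1..n over the unflagged facilities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import RankingError
from .exposure import FacilityAggregate
from .nbglmm import FittedNBMM, aggregates_frame, predict_facility_counts

logger = logging.getLogger("pahrank")

METHODS = ("method1", "method2", "method3", "method4", "residual")

TIE_BREAK_RULE = "stable sort on (value, facility_id)"


def rank_values(values: pd.Series, tie_break: str = "facility_id") -> pd.Series:
    """Ascending ranks 1..n with deterministic tie-breaking.

    NaN values (flagged facilities) stay NaN and are excluded from the
    permutation; non-finite non-NaN values are an error naming the
    facility.
    """
    if tie_break != "facility_id":
        raise RankingError(f"unknown tie-break rule {tie_break!r}")
    inf = values.index[np.isinf(values.to_numpy(dtype=float))]
    if len(inf):
        raise RankingError(f"non-finite value for facility {inf[0]!r}")
    valid = values.dropna()
    order = valid.reset_index()
    order.columns = ["facility_id", "value"]
    order = order.sort_values(["value", "facility_id"], kind="stable")
    ranks = pd.Series(np.nan, index=values.index, name="rank")
    ranks.loc[order["facility_id"].to_numpy()] = np.arange(1, len(order) + 1, dtype=float)
    return ranks


def _value_series(aggs: Sequence[FacilityAggregate], num, den_name: str) -> pd.Series:
    vals, flagged = {}, []
    for a in aggs:
        d = num(a)
        if d is None:
            flagged.append(a.facility_id)
            vals[a.facility_id] = np.nan
        else:
            vals[a.facility_id] = d
    if flagged:
        logger.warning("stage=rank flagged_zero_%s=%s", den_name, flagged)
    return pd.Series(vals, name="value").rename_axis("facility_id")


def method1_values(aggs: Sequence[FacilityAggregate], per_bed: bool = False) -> pd.Series:
    """Events per resident; ``per_bed=True`` divides by bed count instead."""
    if per_bed:
        def num(a):
            if not a.n_beds:
                return None
            return a.pah_count / a.n_beds
        return _value_series(aggs, num, "beds")

    def num(a):
        if a.n_residents <= 0:
            return None
        return a.pah_count / a.n_residents
    return _value_series(aggs, num, "residents")


def method2_values(aggs: Sequence[FacilityAggregate]) -> pd.Series:
    """Events per person-year (works with exact or approximate exposure)."""
    def num(a):
        if a.person_years <= 0:
            return None
        return a.pah_count / a.person_years
    return _value_series(aggs, num, "person_years")


def method3_values(model: FittedNBMM, aggs: Sequence[FacilityAggregate]) -> pd.Series:
    """Model-predicted events per facility (the predictive risk score)."""
    return predict_facility_counts(model, list(aggs))


def method4_values(rank2: pd.Series, rank3: pd.Series) -> pd.Series:
    """Rank change, observed (Method 2) minus predicted (Method 3) position.

    Large positive change = observed use well above expectation. Both rank
    series must cover the same facilities.
    """
    s2, s3 = set(rank2.index), set(rank3.index)
    if s2 != s3:
        raise RankingError(f"facility sets differ: {sorted(s2 ^ s3)}")
    return (rank2 - rank3.reindex(rank2.index)).rename("value")


def residual_values(
    observed: pd.Series,
    predicted: pd.Series,
    kind: str = "raw",
    dispersion_k: float = math.inf,
) -> pd.Series:
    """Observed minus predicted counts; ``kind='pearson'`` standardises by
    sqrt(pred + pred^2/k) under the NB2 variance."""
    s1, s2 = set(observed.index), set(predicted.index)
    if s1 != s2:
        raise RankingError(f"facility sets differ: {sorted(s1 ^ s2)}")
    pred = predicted.reindex(observed.index)
    if (pred < 0).any():
        raise RankingError("negative predicted count (internal error)")
    resid = observed - pred
    if kind == "raw":
        return resid.rename("value")
    if kind == "pearson":
        var = pred + pred**2 / dispersion_k
        return (resid / np.sqrt(var)).rename("value")
    raise RankingError(f"unknown residual kind {kind!r}")


@dataclass
class RankTable:
    """Per-facility values and ranks for every computed method.

    ``frame`` has one row per facility with ``value_<method>`` and
    ``rank_<method>`` columns plus ``stratum`` and ``flagged``.
    """

    frame: pd.DataFrame
    tie_break_rule: str = TIE_BREAK_RULE

    @property
    def n_facilities(self) -> int:
        return len(self.frame)

    @property
    def methods(self) -> tuple[str, ...]:
        return tuple(m for m in METHODS if f"rank_{m}" in self.frame.columns)

    def ranks(self, method: str) -> pd.Series:
        col = f"rank_{method}"
        if col not in self.frame.columns:
            raise RankingError(f"method {method!r} not computed; have {self.methods}")
        return self.frame.set_index("facility_id")[col]

    def values(self, method: str) -> pd.Series:
        col = f"value_{method}"
        if col not in self.frame.columns:
            raise RankingError(f"method {method!r} not computed; have {self.methods}")
        return self.frame.set_index("facility_id")[col]


def build_rank_table(
    aggs: Sequence[FacilityAggregate],
    model: FittedNBMM | None = None,
    per_bed: bool = False,
    residual_kind: str = "raw",
    method4_absolute: bool = False,
) -> RankTable:
    """Assemble the rank table for Methods 1–2 and, given a fitted model,
    Methods 3–4 and the residual variant.

    ``method4_absolute=True`` orders Method 4 by |change| instead of signed
    change.
    """
    aggs = list(aggs)
    base = aggregates_frame(aggs)[
        ["facility_id", "n_residents", "pah_count", "person_years", "n_beds",
         "stratum", "flagged"]
    ]
    out = base.set_index("facility_id")

    cols: dict[str, pd.Series] = {
        "method1": method1_values(aggs, per_bed=per_bed),
        "method2": method2_values(aggs),
    }
    if model is not None:
        v3 = method3_values(model, aggs)
        cols["method3"] = v3
        r2 = rank_values(cols["method2"])
        r3 = rank_values(v3)
        both = r2.notna() & r3.notna()
        change = method4_values(r2[both], r3[both]).reindex(r2.index)
        cols["method4"] = change.abs() if method4_absolute else change
        observed = pd.Series(
            {a.facility_id: float(a.pah_count) for a in aggs}
        ).rename_axis("facility_id")
        cols["residual"] = residual_values(
            observed, v3, kind=residual_kind, dispersion_k=model.dispersion_k
        )

    for name, vals in cols.items():
        out[f"value_{name}"] = vals
        out[f"rank_{name}"] = rank_values(vals)

    frame = out.reset_index()
    logger.info("stage=rank facilities=%d methods=%s",
                len(frame), ",".join(cols))
    return RankTable(frame)


def select_top(
    rank_table: RankTable,
    method: str,
    n: int,
    stratified: bool = False,
) -> pd.DataFrame:
    """Select the top-n highest-use facilities by a method's rank.

    Overall selection takes the n largest ranks. Stratified selection takes
    the top n within each stratum and re-ranks within stratum (1 = highest
    use in that stratum). Strata smaller than n are returned whole with a
    warning.
    """
    if n < 1:
        raise RankingError("n must be >= 1")
    ranks = rank_table.ranks(method).dropna()
    df = rank_table.frame.set_index("facility_id").loc[ranks.index].reset_index()
    df = df.sort_values([f"rank_{method}", "facility_id"],
                        ascending=[False, True], kind="stable")
    if not stratified:
        sel = df.head(n).copy()
        sel["selection_rank"] = np.arange(1, len(sel) + 1)
        return sel.reset_index(drop=True)

    parts = []
    for stratum, grp in df.groupby("stratum", sort=True):
        if len(grp) < n:
            logger.warning("stage=select stratum=%s size=%d requested=%d",
                           stratum, len(grp), n)
        top = grp.head(n).copy()
        top["selection_rank"] = np.arange(1, len(top) + 1)
        parts.append(top)
    return pd.concat(parts, ignore_index=True)


def compare_methods(
    rank_table: RankTable,
    method_a: str,
    method_b: str,
    top_n: int = 10,
) -> dict:
    """Top-n overlap, Spearman correlation and per-facility rank shifts."""
    ra = rank_table.ranks(method_a)
    rb = rank_table.ranks(method_b)
    both = ra.notna() & rb.notna()
    ra, rb = ra[both], rb[both]
    n = len(ra)
    top_a = set(ra.nlargest(top_n).index)
    top_b = set(rb.nlargest(top_n).index)
    rho = float(stats.spearmanr(ra, rb).statistic) if n > 1 else float("nan")
    return {
        "method_a": method_a,
        "method_b": method_b,
        "top_n": top_n,
        "overlap": len(top_a & top_b),
        "top_a": sorted(top_a),
        "top_b": sorted(top_b),
        "spearman": rho,
        "rank_shifts": (ra - rb).rename("shift"),
    }


__all__ = [
    "METHODS", "TIE_BREAK_RULE", "RankTable", "rank_values",
    "method1_values", "method2_values", "method3_values", "method4_values",
    "residual_values", "build_rank_table", "select_top", "compare_methods",
]
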