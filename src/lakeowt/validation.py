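"""Satellite vs in-situ match-up construction and performance measures.

A match-up pairs an in-situ sampling (station + date) with a satellite
observation of the same station within a +/- 1 day window; with overpasses
on the day before, of, and after a sampling, a station can contribute up to
three match-ups, each counted independently.  MSI observations are expected
to carry the 3x3-pixel window mean, OLCI the single pixel value (supplied
upstream; recorded on the match-up).

Performance measures follow the conventional definitions:

    R^2  = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2
    RMSE = sqrt( (1/n) sum (y_i - yhat_i)^2 )

with y observed in-situ, yhat the satellite-derived value.  R^2 is kept
literal (it can be negative when the model underperforms the mean) and is
never clamped.  Classification skill is summarised as accuracy (% of equal
labels) plus the distribution over correct / little / large / unclassified
error magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .owt import owt_error_magnitude

__all__ = [
    "build_matchups",
    "r_squared",
    "rmse",
    "owt_accuracy",
    "summarize",
    "GroupingScheme",
]

_WINDOWS = {"MSI": "3x3 mean", "OLCI": "single"}


def build_matchups(insitu: pd.DataFrame, satellite: pd.DataFrame, sensor: str,
                   max_days: int = 1) -> pd.DataFrame:
    """Pair in-situ and satellite rows by station within +/- ``max_days``.

    Both tables need ``station`` and ``date`` columns (date-only matching;
    no time of day).  Duplicate satellite rows (same station and timestamp)
    are dropped with a warning.  Returns one row per pair with in-situ
    columns unprefixed, satellite columns suffixed ``_sat`` on collision,
    plus ``time_delta_days`` and ``window``.
    """
    for name, df in (("insitu", insitu), ("satellite", satellite)):
        if not {"station", "date"}.issubset(df.columns):
            raise ValueError(f"{name} table needs 'station' and 'date' columns")
    sat = satellite.copy()
    sat["date"] = pd.to_datetime(sat["date"]).dt.normalize()
    dup = sat.duplicated(subset=["station", "date"])
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate satellite rows",
                      stacklevel=2)
        sat = sat[~dup]
    ins = insitu.copy()
    ins["date"] = pd.to_datetime(ins["date"]).dt.normalize()
    common = set(ins["station"]) & set(sat["station"])
    if not common:
        warnings.warn("no common stations between in-situ and satellite tables",
                      stacklevel=2)
        return pd.DataFrame()
    merged = ins.merge(sat, on="station", suffixes=("", "_sat"))
    delta = (merged["date_sat"] - merged["date"]).dt.days
    merged = merged[delta.abs() <= max_days].copy()
    merged["time_delta_days"] = (merged["date_sat"] - merged["date"]).dt.days
    merged["window"] = _WINDOWS.get(sensor, "single")
    return merged.reset_index(drop=True)


def r_squared(y, yhat) -> float:
    """Coefficient of determination, 1 - SSres/SStot (literal; can be < 0).

    Undefined (NaN) for constant observations, with a warning.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("r_squared needs two equal-length vectors, n >= 2")
    sstot = np.sum((y - y.mean()) ** 2)
    if sstot == 0:
        warnings.warn("R^2 undefined for constant observations", stacklevel=2)
        return float("nan")
    ssres = np.sum((y - yhat) ** 2)
    return float(1.0 - ssres / sstot)


def rmse(y, yhat) -> float:
    """Root mean squared error in the product's units."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise ValueError("rmse needs two equal-length vectors, n >= 1")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def owt_accuracy(truth: Sequence[str], derived: Sequence[str]) -> dict:
    """Accuracy (%) and the error-magnitude distribution of an OWT comparison.

    Returns ``{"accuracy", "n", "distribution"}`` where the distribution
    maps correct/little/large/unclassified to percentages summing to 100.
    """
    truth = list(truth)
    derived = list(derived)
    if len(truth) != len(derived):
        raise ValueError("label vectors must have equal length")
    if not truth:
        raise ValueError("empty label vectors")
    n = len(truth)
    cats = [owt_error_magnitude(t, d) for t, d in zip(truth, derived)]
    dist = {k: 100.0 * cats.count(k) / n
            for k in ("correct", "little", "large", "unclassified")}
    return {"accuracy": dist["correct"], "n": n, "distribution": dist}


@dataclass(frozen=True)
class GroupingScheme:
    """How match-ups are grouped for per-group validation statistics.

    kind: ``by_lake`` (a lake column), ``by_owt`` (the derived OWT column)
    or ``by_insitu_bins`` (low/medium/high bins of the in-situ values;
    default cutpoints at the terciles of the observed values).
    """

    kind: str
    column: str | None = None
    cutpoints: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("by_lake", "by_owt", "by_insitu_bins"):
            raise ValueError(f"unknown grouping {self.kind!r}")

    def keys(self, df: pd.DataFrame, product: str) -> pd.Series:
        if self.kind == "by_lake":
            return df[self.column or "lake"]
        if self.kind == "by_owt":
            return df[self.column or "owt"]
        y = df[product].astype(float)
        cuts = self.cutpoints or tuple(np.quantile(y.dropna(), [1 / 3, 2 / 3]))
        labels = np.where(y <= cuts[0], "low",
                          np.where(y <= cuts[1], "medium", "high"))
        return pd.Series(labels, index=df.index)


def summarize(matchups: pd.DataFrame, product: str,
              grouping: GroupingScheme | None = None,
              predicted_column: str | None = None) -> pd.DataFrame:
    """Per-group and pooled R^2 / RMSE / n for one product.

    Observations come from the ``product`` column, predictions from
    ``<product>_derived`` (or ``predicted_column``).  Pairs with a missing
    value on either side are dropped and counted in ``n_dropped``.  Groups
    with n < 2 are flagged rather than silently merged; the pooled row
    (group ``"pooled"``) always uses all pairs.
    """
    pred_col = predicted_column or f"{product}_derived"
    for col in (product, pred_col):
        if col not in matchups.columns:
            raise ValueError(f"match-up table lacks column {col!r}")
    y = matchups[product].astype(float)
    yhat = matchups[pred_col].astype(float)
    ok = y.notna() & yhat.notna()
    dropped = int((~ok).sum())
    df = matchups[ok]
    rows = []

    def _stats(name, yy, hh):
        n = len(yy)
        flag = ""
        if n < 2:
            flag = "n < 2"
            r2 = float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r2 = r_squared(yy, hh)
        rows.append({"group": name, "n": n,
                     "r2": r2, "rmse": rmse(yy, hh) if n else float("nan"),
                     "n_dropped": dropped if name == "pooled" else 0,
                     "flag": flag})

    if grouping is not None:
        for key, grp in df.groupby(grouping.keys(df, product), sort=True):
            _stats(key, grp[product].astype(float).to_numpy(),
                   grp[pred_col].astype(float).to_numpy())
    _stats("pooled", df[product].astype(float).to_numpy(),
           df[pred_col].astype(float).to_numpy())
    return pd.DataFrame(rows)
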