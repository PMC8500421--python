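"""Standardization of raw seasonal index values into model-ready z-scores.

Raw seasonal means of NDVI or rainfall differ in level between locations.
Standardized anomalies z_ls = (index_ls - mu_l) / sigma_l remove the
location-specific mean and scale, so one regression can pool locations.
Optionally the raw values are log-transformed first (closer to normal for
rainfall-like quantities); z-scores are then computed on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import KEY_COLUMNS, validate_season_frame

__all__ = ["ZScoreTable", "log_transform", "zscore", "zscore_frame"]


@dataclass
class ZScoreTable:
    """Per-record z-scores plus the location statistics that produced them.

    ``frame`` carries the key columns and a ``z`` column; ``stats`` has one
    row per grouping unit with the mean ``mu`` and standard deviation
    ``sigma`` used, and the window (year span) they were computed over.
    """

    index_name: str
    log: bool
    season_stratified: bool
    frame: pd.DataFrame
    stats: pd.DataFrame


def log_transform(values: np.ndarray | pd.Series, *, keys=None) -> np.ndarray:
    """Natural log, elementwise; all values must be strictly positive.

    NDVI can be zero or negative over non-vegetated surfaces, so a
    non-positive value is reported with its key instead of propagating NaN.
    """
    arr = np.asarray(values, dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        idx = np.nonzero(bad)[0]
        labels = [keys[i] for i in idx] if keys is not None else idx.tolist()
        raise ValueError(
            f"log transform requires positive values; offending entries: "
            f"{labels} (values {arr[idx].tolist()})"
        )
    return np.log(arr)


def zscore(values: np.ndarray | pd.Series, *, ddof: int = 1) -> np.ndarray:
    """Standardize one location's series: (x - mean) / sd.

    Uses the sample (n-1) standard deviation.  Requires at least two
    observations and non-zero spread.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 observations to standardize, got {arr.size}")
    mu = arr.mean()
    sigma = arr.std(ddof=ddof)
    if sigma == 0:
        raise ValueError("constant series: standard deviation is zero")
    return (arr - mu) / sigma


def zscore_frame(
    df: pd.DataFrame,
    index_name: str,
    *,
    log: bool = False,
    season_stratified: bool = False,
    ddof: int = 1,
) -> ZScoreTable:
    """Compute per-location z-scores of one index column of a season table.

    mu_l and sigma_l are computed per location across all years in the
    table, pooling both seasons by default; ``season_stratified=True``
    instead groups by (location, season-of-year).  With ``log=True`` the raw
    values are log-transformed before standardizing.
    """
    df = validate_season_frame(df)
    if index_name not in df.columns:
        raise ValueError(f"index column {index_name!r} not in table")
    vals = pd.to_numeric(df[index_name], errors="coerce")
    if vals.isna().any():
        rows = df.loc[vals.isna(), list(KEY_COLUMNS)].to_dict(orient="records")
        raise ValueError(f"missing {index_name!r} values for keys: {rows}")

    work = df[list(KEY_COLUMNS)].copy()
    if log:
        keys = list(work.itertuples(index=False, name=None))
        work["value"] = log_transform(vals.to_numpy(), keys=keys)
    else:
        work["value"] = vals.to_numpy()

    group_cols = ["location", "season"] if season_stratified else ["location"]
    stats_rows = []
    z = np.empty(len(work))
    for gkey, sub in work.groupby(group_cols, sort=True):
        if len(sub) < 2:
            raise ValueError(
                f"grouping unit {gkey} has {len(sub)} observation(s); "
                "need >= 2 to standardize"
            )
        mu = sub["value"].mean()
        sigma = sub["value"].std(ddof=ddof)
        if sigma == 0:
            raise ValueError(f"grouping unit {gkey} has zero variance")
        z[sub.index.to_numpy()] = (sub["value"] - mu) / sigma
        row = dict(zip(group_cols, gkey if isinstance(gkey, tuple) else (gkey,)))
        row.update(
            mu=mu,
            sigma=sigma,
            n=len(sub),
            year_min=int(df.loc[sub.index, "year"].min()),
            year_max=int(df.loc[sub.index, "year"].max()),
        )
        stats_rows.append(row)

    out = df[list(KEY_COLUMNS)].copy()
    out["z"] = z
    return ZScoreTable(
        index_name=index_name,
        log=log,
        season_stratified=season_stratified,
        frame=out,
        stats=pd.DataFrame(stats_rows),
    )
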