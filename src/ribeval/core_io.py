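"""Domain data model, tabular readers/writers, and herd-to-TLU conversion.

The central in-memory container is a long-format :class:`pandas.DataFrame`
with one row per (location, year, season) and columns for observed livestock
mortality plus one or more raw remote-sensing index values.  Lightweight
dataclasses wrap the few structured objects that move between modules.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "SeasonKey",
    "SeasonObservation",
    "HerdComposition",
    "OutcomeDistribution",
    "KEY_COLUMNS",
    "TLU_PER_ANIMAL",
    "read_season_table",
    "observations_to_frame",
    "frame_to_observations",
    "validate_season_frame",
    "tlu_from_herd",
    "write_report",
    "read_report",
]

#: Canonical column names of a season table.
KEY_COLUMNS = ("location", "year", "season")


class Season(str, enum.Enum):
    """The two herding seasons of the bimodal rainfall calendar.

    LRLD is the long rain / long dry season (March-September); SRSD is the
    short rain / short dry season (October-February).
    """

    LRLD = "LRLD"
    SRSD = "SRSD"


@dataclass(frozen=True, order=True)
class SeasonKey:
    """Unique identifier of one location-season record."""

    location: str
    year: int
    season: Season

    def __post_init__(self) -> None:
        object.__setattr__(self, "season", Season(self.season))


@dataclass
class SeasonObservation:
    """One location-season record: mortality rate and raw index values.

    ``mortality`` is a fraction in [0, 1], or ``None`` for prediction-only
    rows.  ``index_values`` maps index name (e.g. ``"MD"``, ``"LRN"``) to the
    seasonal mean of that index.
    """

    key: SeasonKey
    mortality: float | None
    index_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mortality is not None and not 0.0 <= self.mortality <= 1.0:
            raise ValueError(
                f"mortality {self.mortality!r} outside [0, 1] for {self.key}"
            )


#: TLU value of a single animal of each species: 1 TLU equals 1 cow,
#: 0.7 camels, or 10 goats or sheep, so one camel is 1/0.7 TLU.
TLU_PER_ANIMAL: dict[str, float] = {
    "cattle": 1.0,
    "camels": 1.0 / 0.7,
    "goats": 0.1,
    "sheep": 0.1,
}


@dataclass
class HerdComposition:
    """Per-species animal counts for a household herd."""

    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for species, n in self.counts.items():
            if species not in TLU_PER_ANIMAL:
                raise ValueError(
                    f"unknown species {species!r}; expected one of "
                    f"{sorted(TLU_PER_ANIMAL)}"
                )
            if n < 0:
                raise ValueError(f"negative count for {species!r}: {n}")


def tlu_from_herd(herd: HerdComposition) -> float:
    """Convert a herd to Tropical Livestock Units.

    TLU is the common-currency livestock measure: 1 TLU = 1 cow = 0.7
    camels = 10 goats or sheep.
    """
    return float(sum(TLU_PER_ANIMAL[sp] * n for sp, n in herd.counts.items()))


@dataclass
class OutcomeDistribution:
    """Discrete mortality-outcome distribution: states (M_j, pi_j).

    Mortality values must be strictly increasing and the probabilities must
    sum to one.  Used for binned (probability-weighted) pricing and welfare
    accounting over a stylized risk distribution.
    """

    mortality: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.mortality.shape != self.probability.shape:
            raise ValueError("mortality and probability must have equal length")
        if np.any((self.mortality < 0) | (self.mortality > 1)):
            raise ValueError("mortality states must lie in [0, 1]")
        if np.any(np.diff(self.mortality) <= 0):
            raise ValueError("mortality states must be strictly increasing")
        if np.any(self.probability < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probability.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"probabilities sum to {self.probability.sum()!r}, not 1"
            )


def validate_season_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format season table in canonical column names.

    Checks key uniqueness and the mortality bounds; returns the frame with
    key columns coerced to their canonical dtypes.
    """
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"season table missing key columns: {missing}")
    out = df.copy()
    out["location"] = out["location"].astype(str)
    out["year"] = out["year"].astype(int)
    out["season"] = out["season"].map(lambda s: Season(s).value)

    dup = out.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        keys = out.loc[dup, list(KEY_COLUMNS)].drop_duplicates()
        raise ValueError(
            "duplicate (location, year, season) keys: "
            + ", ".join(
                f"({r.location}, {r.year}, {r.season})" for r in keys.itertuples()
            )
        )
    if "mortality" in out.columns:
        m = pd.to_numeric(out["mortality"], errors="coerce")
        bad = m.notna() & ((m < 0) | (m > 1))
        if bad.any():
            rows = out.index[bad].tolist()
            raise ValueError(
                f"mortality outside [0, 1] in rows {rows}: "
                f"{m[bad].tolist()}"
            )
        out["mortality"] = m
    return out


def read_season_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a long-format CSV of location-season observations.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical names (``location``, ``year``,
        ``season``, ``mortality``, index names) to the column names used in
        the file, so external tables with different headers share this
        reader.

    Returns
    -------
    DataFrame with canonical key columns, a ``mortality`` column (NaN marks
    prediction-only rows) and any index columns.  Raises ``ValueError`` on
    duplicate keys or out-of-range mortality.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {src: canon for canon, src in schema.items() if src in df.columns}
        absent = [src for src in schema.values() if src not in df.columns]
        if absent:
            raise ValueError(f"schema columns not found in {path}: {absent}")
        df = df.rename(columns=rename)
    return validate_season_frame(df)


def observations_to_frame(obs: Sequence[SeasonObservation]) -> pd.DataFrame:
    """Flatten SeasonObservation records into the canonical long table."""
    rows = []
    for o in obs:
        row: dict[str, Any] = {
            "location": o.key.location,
            "year": o.key.year,
            "season": Season(o.key.season).value,
            "mortality": np.nan if o.mortality is None else o.mortality,
        }
        row.update(o.index_values)
        rows.append(row)
    return validate_season_frame(pd.DataFrame(rows))


def frame_to_observations(df: pd.DataFrame) -> list[SeasonObservation]:
    """Inverse of :func:`observations_to_frame`."""
    df = validate_season_frame(df)
    index_cols = [c for c in df.columns if c not in KEY_COLUMNS + ("mortality",)]
    out = []
    for r in df.itertuples():
        m = getattr(r, "mortality", np.nan)
        out.append(
            SeasonObservation(
                key=SeasonKey(r.location, int(r.year), Season(r.season)),
                mortality=None if pd.isna(m) else float(m),
                index_values={c: float(getattr(r, c)) for c in index_cols},
            )
        )
    return out


class _ReportEncoder(json.JSONEncoder):
    def default(self, o: Any) -> Any:
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, enum.Enum):
            return o.value
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        return super().default(o)


def write_report(report: Any, path: str | Path) -> None:
    """Serialize a report (dataclass, mapping, or table) to JSON.

    Dataclasses, enums, numpy scalars/arrays and DataFrames are flattened to
    plain JSON types so the file round-trips through :func:`read_report`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, cls=_ReportEncoder, indent=2, allow_nan=True)
        fh.write("\n")


def read_report(path: str | Path) -> Any:
    """Read a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
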