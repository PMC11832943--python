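"""Reading and writing ring-width series and tabular stand/climate inputs.

Ring-width series travel either in the Tucson decadal format (``.rwl``,
0.01 mm units, ``999``/``-9999`` end-of-series dialects) or in a long CSV
(``series_id, year, width_mm``).  Tree metadata and monthly station climate
come as plain CSV.  All readers return typed records; series are calendar
dated and gap free.

Southern-hemisphere ring years are labeled by the calendar year in which the
growing season ends: the ring spanning October 2020 - March 2021 carries the
label 2021.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "TreeRecord",
    "ClimateTable",
    "RingIOError",
    "read_rwl",
    "write_rwl",
    "read_rings_csv",
    "write_rings_csv",
    "merge_cores_to_tree",
    "read_tree_metadata",
    "read_climate",
]


class RingIOError(ValueError):
    """Malformed or inconsistent ring/metadata input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RingSeries:
    """Dated annual ring widths for one core (or one merged tree).

    Parameters
    ----------
    series_id
        Core identifier (e.g. ``"NP01a"``).
    tree_id
        Tree the core belongs to.
    first_year
        Calendar year of the earliest ring (season-end labeling).
    widths
        Ordered annual ring widths in mm, one per consecutive year.
        Width 0 marks a locally missing ring; it is kept and flagged.
    """

    series_id: str
    tree_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise RingIOError(f"series {self.series_id!r}: needs >= 1 width")
        if np.any(~np.isfinite(self.widths)) or np.any(self.widths < 0):
            raise RingIOError(
                f"series {self.series_id!r}: widths must be finite and >= 0"
            )

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def missing(self) -> np.ndarray:
        """Boolean flags for zero-width (locally absent) rings."""
        return self.widths == 0.0

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class TreeRecord:
    """Field measurements for one target tree."""

    tree_id: str
    dbh: float  # mm
    height: float  # m
    crown_damage: float  # percent, recorded in 5 % classes
    min_age: int | None = None  # ring count at coring height
    neighbors: list[tuple[float, float]] = field(default_factory=list)
    # each neighbor: (dbh_j in mm, distance in m)
    group: str | None = None  # growth-trajectory label, filled downstream

    def __post_init__(self) -> None:
        if self.dbh <= 0:
            raise RingIOError(f"tree {self.tree_id!r}: dbh must be > 0")
        if not 0 <= self.crown_damage <= 100:
            raise RingIOError(
                f"tree {self.tree_id!r}: crown_damage {self.crown_damage} "
                "outside [0, 100]"
            )
        for dbh_j, dist in self.neighbors:
            if dist <= 0:
                raise RingIOError(
                    f"tree {self.tree_id!r}: neighbor distance must be > 0"
                )
            if dbh_j <= 0:
                raise RingIOError(
                    f"tree {self.tree_id!r}: neighbor dbh must be > 0"
                )


@dataclass
class ClimateTable:
    """Monthly values of one variable at one station.

    ``values`` is a pandas Series indexed by (year, month), temperature in
    degC or precipitation in mm.
    """

    station_id: str
    variable: str  # "temperature" | "precipitation"
    values: pd.Series

    def __post_init__(self) -> None:
        if self.variable not in ("temperature", "precipitation"):
            raise RingIOError(f"unknown climate variable {self.variable!r}")
        idx = self.values.index
        if idx.duplicated().any():
            raise RingIOError(
                f"station {self.station_id!r}: duplicate (year, month) rows"
            )
        months = idx.get_level_values(1)
        if ((months < 1) | (months > 12)).any():
            raise RingIOError(f"station {self.station_id!r}: month outside 1..12")
        if self.variable == "precipitation" and (self.values < 0).any():
            raise RingIOError(
                f"station {self.station_id!r}: negative precipitation"
            )


# ---------------------------------------------------------------------------
# Tucson .rwl
# ---------------------------------------------------------------------------

_TERMINATORS = (999, -9999)


def read_rwl(path: str | Path | io.StringIO) -> list[RingSeries]:
    """Parse a Tucson decadal ring-width file into dated series.

    Values are stored in 0.01 mm and converted to mm.  Both the ``999`` and
    ``-9999`` end-of-series markers are accepted.  Decade lines of one series
    must be contiguous and consecutive.
    """
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
        name = "<buffer>"
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(p)
        lines = p.read_text().splitlines()
        name = str(p)

    per_series: dict[str, dict[int, float]] = {}
    finished: dict[str, bool] = {}
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        parts = raw.split()
        if len(parts) < 3:
            raise RingIOError(f"{name}:{lineno}: malformed decade line: {raw!r}")
        sid = parts[0]
        try:
            year0 = int(parts[1])
            vals = [int(v) for v in parts[2:]]
        except ValueError as exc:
            raise RingIOError(
                f"{name}:{lineno}: malformed decade line: {raw!r}"
            ) from exc
        if finished.get(sid):
            raise RingIOError(
                f"{name}:{lineno}: data for series {sid!r} after its terminator "
                "(duplicate series id?)"
            )
        store = per_series.setdefault(sid, {})
        if store:
            expected = max(store) + 1
            if year0 != expected:
                raise RingIOError(
                    f"{name}:{lineno}: series {sid!r} jumps from year "
                    f"{max(store)} to decade {year0} (expected {expected})"
                )
        for i, v in enumerate(vals):
            if v in _TERMINATORS:
                finished[sid] = True
                if i != len(vals) - 1:
                    raise RingIOError(
                        f"{name}:{lineno}: values after terminator for {sid!r}"
                    )
                break
            year = year0 + i
            if year in store:
                raise RingIOError(
                    f"{name}:{lineno}: duplicate year {year} in series {sid!r}"
                )
            if v < 0:
                raise RingIOError(
                    f"{name}:{lineno}: negative ring width {v} in {sid!r}"
                )
            store[year] = v / 100.0

    out: list[RingSeries] = []
    for sid, store in per_series.items():
        if not store:
            continue
        years = sorted(store)
        if years[-1] - years[0] + 1 != len(years):
            missing = sorted(set(range(years[0], years[-1] + 1)) - set(years))
            raise RingIOError(f"{name}: series {sid!r} has year gaps at {missing}")
        widths = np.array([store[y] for y in years])
        out.append(
            RingSeries(series_id=sid, tree_id=_tree_of(sid),
                       first_year=years[0], widths=widths)
        )
    return out


def _tree_of(series_id: str) -> str:
    """Default core -> tree mapping: strip one trailing letter (NP01a -> NP01)."""
    if len(series_id) > 1 and series_id[-1].isalpha() and series_id[-2].isdigit():
        return series_id[:-1]
    return series_id


def write_rwl(series: Iterable[RingSeries], path: str | Path | io.StringIO) -> None:
    """Write series in Tucson decadal layout (0.01 mm units, 999 terminator)."""
    chunks: list[str] = []
    for s in series:
        year = s.first_year
        values = [int(round(w * 100)) for w in s.widths]
        i = 0
        while i < len(values):
            decade_end = (year // 10) * 10 + 9
            n = min(decade_end - year + 1, len(values) - i)
            row = values[i : i + n]
            line = f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6}" for v in row)
            i += n
            year += n
            if i == len(values):
                line += f"{999:>6}"
            chunks.append(line)
    text = "\n".join(chunks) + "\n"
    if isinstance(path, io.StringIO):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_rings_csv(path: str | Path) -> list[RingSeries]:
    """Read the long CSV ring dialect: columns series_id, year, width_mm."""
    df = pd.read_csv(path)
    required = {"series_id", "year", "width_mm"}
    if not required.issubset(df.columns):
        raise RingIOError(
            f"ring CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=int)
        if len(years) and (np.diff(years) != 1).any():
            raise RingIOError(f"series {sid!r}: years not consecutive")
        out.append(
            RingSeries(
                series_id=str(sid),
                tree_id=_tree_of(str(sid)),
                first_year=int(years[0]),
                widths=grp["width_mm"].to_numpy(dtype=float),
            )
        )
    return out


def write_rings_csv(series: Iterable[RingSeries], path: str | Path) -> None:
    rows = [
        {"series_id": s.series_id, "year": y, "width_mm": w}
        for s in series
        for y, w in zip(s.years, s.widths)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def merge_cores_to_tree(series: Sequence[RingSeries]) -> RingSeries:
    """Average the dated cores of one tree into a single mean series.

    The result spans the union of the cores' year ranges; where cores
    overlap the per-year arithmetic mean is taken, on the flanks the single
    available core's value is carried over.
    """
    if not series:
        raise RingIOError("merge_cores_to_tree: empty input")
    tree_ids = {s.tree_id for s in series}
    if len(tree_ids) != 1:
        raise RingIOError(f"cores belong to different trees: {sorted(tree_ids)}")
    if len(series) > 1:
        spans = [set(range(s.first_year, s.last_year + 1)) for s in series]
        if not set.intersection(*spans):
            raise RingIOError("cores share no overlapping years")
    first = min(s.first_year for s in series)
    last = max(s.last_year for s in series)
    n_years = last - first + 1
    total = np.zeros(n_years)
    count = np.zeros(n_years)
    for s in series:
        i0 = s.first_year - first
        total[i0 : i0 + len(s)] += s.widths
        count[i0 : i0 + len(s)] += 1
    if (count == 0).any():
        raise RingIOError("cores leave a year gap in the merged span")
    tid = tree_ids.pop()
    return RingSeries(series_id=tid, tree_id=tid, first_year=first,
                      widths=total / count)


_META_COLUMNS: Mapping[str, str] = {
    "tree_id": "tree_id",
    "dbh_mm": "dbh",
    "height_m": "height",
    "crown_damage_pct": "crown_damage",
    "neighbors": "neighbors",
}


def read_tree_metadata(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[TreeRecord]:
    """Read the tree metadata CSV.

    ``columns`` maps CSV column names to record fields and defaults to
    ``tree_id, dbh_mm, height_m, crown_damage_pct, neighbors``; the deposited
    replication tables can be adapted by passing their own mapping.  The
    neighbor column encodes ``dbh_mm/dist_m`` pairs separated by ``;`` and may
    be empty.
    """
    colmap = dict(columns or _META_COLUMNS)
    df = pd.read_csv(path, dtype={c: str for c in colmap if colmap[c] == "tree_id"})
    missing = set(colmap) - set(df.columns)
    if missing:
        raise RingIOError(f"metadata CSV missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for col, fieldname in colmap.items():
            val = row[col]
            if fieldname == "neighbors":
                kwargs[fieldname] = _parse_neighbors(val)
            elif fieldname == "tree_id":
                kwargs[fieldname] = str(val)
            elif fieldname == "min_age":
                kwargs[fieldname] = None if pd.isna(val) else int(val)
            else:
                kwargs[fieldname] = float(val)
        records.append(TreeRecord(**kwargs))
    return records


def _parse_neighbors(cell) -> list[tuple[float, float]]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    out = []
    for pair in text.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        try:
            dbh_j, dist = pair.split("/")
            out.append((float(dbh_j), float(dist)))
        except ValueError as exc:
            raise RingIOError(f"unparseable neighbor entry {pair!r}") from exc
    return out


def read_climate(path: str | Path) -> list[ClimateTable]:
    """Read monthly station climate CSV: station_id, variable, year, month, value."""
    df = pd.read_csv(path)
    required = {"station_id", "variable", "year", "month", "value"}
    if not required.issubset(df.columns):
        raise RingIOError(
            f"climate CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    tables = []
    for (sid, var), grp in df.groupby(["station_id", "variable"], sort=True):
        values = pd.Series(
            grp["value"].to_numpy(dtype=float),
            index=pd.MultiIndex.from_arrays(
                [grp["year"].to_numpy(dtype=int), grp["month"].to_numpy(dtype=int)],
                names=["year", "month"],
            ),
        ).sort_index()
        tables.append(ClimateTable(station_id=str(sid), variable=str(var),
                                   values=values))
    return tables


def write_climate(tables: Iterable[ClimateTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for (year, month), v in t.values.items():
            rows.append(
                {"station_id": t.station_id, "variable": t.variable,
                 "year": year, "month": month, "value": v}
            )
    pd.DataFrame(rows).to_csv(path, index=False)
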