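"""Station climate departures, regional means, moisture index, season windows.

Monthly station records are converted to z-score departures against a common
reference period, separately per calendar month so that seasonality is
removed.  Station departures are averaged with equal weight into regional
means; a moisture index is the precipitation departure minus the temperature
departure, so strongly negative values flag hot-and-dry years.

A southern-hemisphere ring labeled by its season-end year y integrates
climate over 19 months spanning three calendar years: the previous growing
season's October (year y-2) through the current season's April (year y).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .ringio import ClimateTable

__all__ = [
    "ClimateDeparture",
    "SeasonWindow",
    "ClimateError",
    "standardize_station",
    "regional_mean",
    "moisture_index",
    "season_window",
    "SLOT_LABELS",
]


class ClimateError(ValueError):
    pass


@dataclass
class ClimateDeparture:
    """Monthly z-score departures for one variable (station or regional)."""

    variable: str  # temperature | precipitation | moisture_index
    values: pd.Series  # MultiIndex (year, month), standard-deviation units
    reference_period: tuple[int, int]
    n_stations: pd.Series | None = None  # contributing stations per cell

    def at(self, year: int, month: int) -> float:
        try:
            return float(self.values.loc[(year, month)])
        except KeyError:
            return float("nan")


_MONTH_ABBR = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass
class SeasonWindow:
    """The 19 monthly slots a ring of a given growth year integrates.

    Slots are (year_offset, month) pairs relative to the ring's season-end
    calendar year: previous growing season Oct(-2)..Apr(-1), winter
    May(-1)..Sep(-1), current growing season Oct(-1)..Apr(0).
    """

    growth_year: int
    slots: list[tuple[int, int]]

    def calendar(self) -> list[tuple[int, int]]:
        return [(self.growth_year + off, m) for off, m in self.slots]


_SLOT_OFFSETS: list[tuple[int, int]] = (
    [(-2, m) for m in (10, 11, 12)]
    + [(-1, m) for m in range(1, 13)]
    + [(0, m) for m in (1, 2, 3, 4)]
)

#: labels in slot order: prev-season Oct..Apr, winter May..Sep, current Oct..Apr
SLOT_LABELS: list[str] = (
    [f"prev.{_MONTH_ABBR[m - 1]}" for m in (10, 11, 12, 1, 2, 3, 4)]
    + [f"win.{_MONTH_ABBR[m - 1]}" for m in (5, 6, 7, 8, 9)]
    + [f"cur.{_MONTH_ABBR[m - 1]}" for m in (10, 11, 12, 1, 2, 3, 4)]
)


def season_window(growth_year: int) -> SeasonWindow:
    """The 19-month climate window of the ring labeled ``growth_year``."""
    return SeasonWindow(growth_year=growth_year, slots=list(_SLOT_OFFSETS))


def standardize_station(
    table: ClimateTable,
    reference: tuple[int, int],
    *,
    min_ref_years: int = 20,
) -> ClimateDeparture:
    """Per-calendar-month z-scores against the reference period.

    For each month m, z_{y,m} = (x_{y,m} - mean_m(ref)) / sd_m(ref); by
    construction the reference-period departures of every month have mean 0
    and standard deviation 1.
    """
    lo, hi = reference
    vals = table.values
    years = vals.index.get_level_values("year")
    months = vals.index.get_level_values("month")
    ref = vals[(years >= lo) & (years <= hi)]
    out = pd.Series(np.nan, index=vals.index)
    for m in range(1, 13):
        ref_m = ref[ref.index.get_level_values("month") == m]
        if len(ref_m) == 0:
            continue
        if len(ref_m) < min_ref_years:
            raise ClimateError(
                f"station {table.station_id!r}: only {len(ref_m)} reference "
                f"years for month {m} (< {min_ref_years})"
            )
        mu = ref_m.mean()
        sd = ref_m.std(ddof=1)
        if sd == 0:
            raise ClimateError(
                f"station {table.station_id!r}: zero reference sd in month {m}"
            )
        sel = months == m
        out[sel] = (vals[sel] - mu) / sd
    return ClimateDeparture(
        variable=table.variable,
        values=out.dropna().sort_index(),
        reference_period=reference,
    )


def regional_mean(departures: list[ClimateDeparture]) -> ClimateDeparture:
    """Equal-weight mean of station departures per (year, month).

    Cells missing at some stations are averaged over the stations present;
    the contributing count is recorded per cell.
    """
    if not departures:
        raise ClimateError("regional_mean of no stations")
    variables = {d.variable for d in departures}
    if len(variables) != 1:
        raise ClimateError(f"mixed variables {sorted(variables)}")
    refs = {d.reference_period for d in departures}
    if len(refs) != 1:
        raise ClimateError("stations standardized to different reference periods")
    frame = pd.concat([d.values for d in departures], axis=1)
    return ClimateDeparture(
        variable=variables.pop(),
        values=frame.mean(axis=1).sort_index(),
        reference_period=refs.pop(),
        n_stations=frame.notna().sum(axis=1).sort_index(),
    )


def moisture_index(
    temp: ClimateDeparture, precip: ClimateDeparture
) -> ClimateDeparture:
    """Precipitation departure minus temperature departure, per (year, month)."""
    common = temp.values.index.intersection(precip.values.index)
    if len(common) < len(temp.values.index.union(precip.values.index)):
        warnings.warn(
            "moisture_index: temperature and precipitation coverage differ; "
            "computed on the intersection",
            stacklevel=2,
        )
    mi = (precip.values.loc[common] - temp.values.loc[common]).sort_index()
    return ClimateDeparture(
        variable="moisture_index",
        values=mi,
        reference_period=temp.reference_period,
    )
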