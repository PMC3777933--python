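"""Seasonal calendar: the June-October fishing season in semimonthly halves.

"Two-week intervals" are calendar half-months (1st-15th, 16th-month-end),
ten per season, so a decade spans exactly 100 periods.
"""
from __future__ import annotations

import calendar as _calendar
import datetime as dt
from dataclasses import dataclass

__all__ = [
    "SEASON_MONTHS",
    "SemimonthlyPeriod",
    "semimonthly_periods",
    "assign_period",
    "season_window",
    "day_of_year",
]

SEASON_MONTHS = (6, 7, 8, 9, 10)


@dataclass(frozen=True, order=True)
class SemimonthlyPeriod:
    year: int
    index: int  # 1..10 within the season
    start: dt.date
    end: dt.date

    @property
    def label(self) -> str:
        return f"{self.start:%b} {self.start.day}-{self.end.day} {self.year}"

    @property
    def key(self) -> str:
        return f"{self.year}-{self.index:02d}"

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end


def season_window(year: int) -> tuple[dt.date, dt.date]:
    """Inclusive June 1 - October 31 window for one year."""
    return dt.date(year, 6, 1), dt.date(year, 10, 31)


def day_of_year(d: dt.date) -> int:
    """1-based day of year (Jan 1 = 1)."""
    return d.timetuple().tm_yday


def semimonthly_periods(first_year: int, last_year: int) -> list[SemimonthlyPeriod]:
    """Ordered semimonthly periods covering Jun 1 - Oct 31 of every year."""
    if first_year > last_year:
        raise ValueError("first_year must not exceed last_year")
    out: list[SemimonthlyPeriod] = []
    for year in range(first_year, last_year + 1):
        idx = 0
        for month in SEASON_MONTHS:
            last_day = _calendar.monthrange(year, month)[1]
            for start_day, end_day in ((1, 15), (16, last_day)):
                idx += 1
                out.append(
                    SemimonthlyPeriod(
                        year, idx, dt.date(year, month, start_day), dt.date(year, month, end_day)
                    )
                )
    return out


def assign_period(d: dt.date, periods: list[SemimonthlyPeriod]) -> SemimonthlyPeriod:
    """The unique period containing ``d``; error if outside all periods."""
    if d.month in SEASON_MONTHS:
        idx = 2 * (d.month - SEASON_MONTHS[0]) + (1 if d.day <= 15 else 2)
        for p in periods:
            if p.year == d.year and p.index == idx:
                return p
    raise ValueError(f"date {d.isoformat()} falls outside every supplied period")
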