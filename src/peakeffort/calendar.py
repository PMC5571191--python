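"""Study-period calendar with mast-year flags.

A *mast year* is a year of synchronized superabundant seed production by
white spruce; in the Kluane red squirrel system four such years fall in the
1986-2013 study window (1993, 1998, 2005, 2010). Downstream code only needs
to know which study years are mast years, so the calendar is a small frozen
value object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The Kluane study window and its four mast years.
STUDY_START = 1986
STUDY_END = 2013
STUDY_MAST_YEARS = frozenset({1993, 1998, 2005, 2010})


@dataclass(frozen=True)
class MastCalendar:
    """Ordered study years plus the subset flagged as mast years.

    Parameters
    ----------
    years
        Strictly increasing tuple of calendar years covered by the study.
    mast_years
        Subset of ``years`` in which a mast occurred. At least one year
        must remain non-mast.
    """

    years: tuple[int, ...]
    mast_years: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        mast = frozenset(int(y) for y in self.mast_years)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "mast_years", mast)
        if not years:
            raise ValueError("calendar needs at least one year")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if not mast <= set(years):
            bad = sorted(mast - set(years))
            raise ValueError(f"mast years outside the calendar: {bad}")
        if len(mast) == len(years):
            raise ValueError("at least one year must be non-mast")

    @property
    def start(self) -> int:
        return self.years[0]

    @property
    def end(self) -> int:
        return self.years[-1]

    def is_mast(self, year: int) -> bool:
        return year in self.mast_years

    def __contains__(self, year: object) -> bool:
        return year in self.years


def make_mast_calendar(
    start_year: int,
    end_year: int,
    mast_years: set[int] | frozenset[int] = frozenset(),
) -> MastCalendar:
    """Build a contiguous calendar from ``start_year`` to ``end_year``.

    Raises
    ------
    ValueError
        If the range is inverted or a mast year falls outside it.
    """
    if end_year < start_year:
        raise ValueError(f"inverted year range: {start_year}..{end_year}")
    for y in mast_years:
        if not start_year <= y <= end_year:
            raise ValueError(f"mast year {y} outside [{start_year}, {end_year}]")
    return MastCalendar(tuple(range(start_year, end_year + 1)), frozenset(mast_years))


def study_calendar() -> MastCalendar:
    """The default 1986-2013 calendar with mast years 1993, 1998, 2005, 2010."""
    return make_mast_calendar(STUDY_START, STUDY_END, STUDY_MAST_YEARS)
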