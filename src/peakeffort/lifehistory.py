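"""Derived per-female life-history variables from annual breeding records.

The analysis works from a long-format table of female-years (one row per
female per year of adult life, with the number of pups born that year and
the number of those pups that recruited, i.e. survived their first winter to
sexual maturity). This module turns those records into the per-female
variables the models use:

* **peak effort** — the maximum annual number of pups a female ever produced;
* **peak age** — the age at which that maximum was *first* attained;
* lifetime totals of pups and recruits;
* **primiparity** — whether the first litter came as a yearling (age 1) or
  later;
* mast-exposure variables: whether the female experienced a mast year as an
  adult, her age in the (first) adult mast year, and whether her peak year
  coincided with a mast year ("mast peak");
* pre-peak reproductive rate and post-peak lifespan / pup production.

Records and summaries travel as :class:`pandas.DataFrame` objects with fixed
column names; small frozen dataclasses carry single-female views.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calendar import MastCalendar

RECORD_COLUMNS = ["female_id", "cohort", "year", "age", "pups", "recruits"]

SUMMARY_COLUMNS = [
    "female_id", "cohort", "lifespan", "peak_effort", "peak_age",
    "lifetime_pups", "lifetime_recruits", "n_breeding_years", "primiparity",
    "experienced_mast", "mast_peak", "age_at_mast", "pre_peak_rate",
    "post_peak_lifespan", "post_peak_pups", "prop_recruited", "is_breeder",
]


@dataclass(frozen=True)
class AnnualRecord:
    """One female-year: pups born and recruits from that litter-year."""

    female_id: str
    cohort: int
    year: int
    pups: int
    recruits: int

    @property
    def age(self) -> int:
        return self.year - self.cohort

    def __post_init__(self) -> None:
        if self.pups < 0 or self.recruits < 0:
            raise ValueError("pups and recruits must be non-negative")
        if self.recruits > self.pups:
            raise ValueError(
                f"{self.female_id} year {self.year}: recruits ({self.recruits}) "
                f"exceed pups ({self.pups})"
            )
        if self.age < 1:
            raise ValueError(f"{self.female_id}: breeding record at age {self.age} < 1")


@dataclass(frozen=True)
class FemaleLifeHistory:
    """A female's complete adult record set, sorted by year.

    ``records`` holds one :class:`AnnualRecord` per year of adult life
    (ages 1..lifespan), zero-pup years included.
    """

    female_id: str
    cohort: int
    lifespan: int
    records: tuple[AnnualRecord, ...]

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=lambda r: r.year))
        object.__setattr__(self, "records", recs)
        if not recs:
            raise ValueError(f"{self.female_id}: no annual records")
        years = [r.year for r in recs]
        if len(set(years)) != len(years):
            raise ValueError(f"{self.female_id}: duplicate record years")
        for r in recs:
            if r.female_id != self.female_id or r.cohort != self.cohort:
                raise ValueError(f"{self.female_id}: record identity mismatch")
            if not 1 <= r.age <= self.lifespan:
                raise ValueError(
                    f"{self.female_id}: record age {r.age} outside [1, {self.lifespan}]"
                )


@dataclass(frozen=True)
class FemaleSummary:
    """Per-female derived variables; ``is_breeder`` is False when the female
    never produced a pup (such females are excluded from every analysis set)."""

    female_id: str
    cohort: int
    lifespan: int
    peak_effort: int
    peak_age: int
    lifetime_pups: int
    lifetime_recruits: int
    n_breeding_years: int
    primiparity: int            # 1 = first litter as a yearling, 0 = delayed
    experienced_mast: bool
    mast_peak: bool
    age_at_mast: float          # NaN when no adult mast year was experienced
    pre_peak_rate: float
    post_peak_lifespan: int
    post_peak_pups: int
    prop_recruited: float       # NaN for non-breeders
    is_breeder: bool


def summarize_female(history: FemaleLifeHistory, calendar: MastCalendar) -> FemaleSummary:
    """Compute all derived variables for one female.

    Peak age is the age of *first* attainment of the maximum annual pup
    count; ties at the maximum in later years do not move it. The pre-peak
    rate is total pups at ages below the peak age divided by (peak age - 1),
    defined as 0 for females peaking as yearlings.
    """
    recs = history.records
    pups = np.array([r.pups for r in recs])
    recruits = np.array([r.recruits for r in recs])
    ages = np.array([r.age for r in recs])

    lifetime_pups = int(pups.sum())
    lifetime_recruits = int(recruits.sum())
    is_breeder = lifetime_pups > 0

    peak_effort = int(pups.max())
    peak_age = int(ages[int(np.argmax(pups))])  # argmax -> first attainment
    n_breeding_years = int((pups > 0).sum())

    breeding_ages = ages[pups > 0]
    primiparity = int(is_breeder and breeding_ages.min() == 1)

    adult_masts = [y for y in calendar.mast_years
                   if 1 <= y - history.cohort <= history.lifespan]
    experienced_mast = bool(adult_masts)
    age_at_mast = float(min(adult_masts) - history.cohort) if adult_masts else math.nan
    mast_peak = calendar.is_mast(history.cohort + peak_age)

    pre = pups[ages < peak_age]
    pre_peak_rate = float(pre.sum() / (peak_age - 1)) if peak_age > 1 else 0.0
    post_peak_lifespan = history.lifespan - peak_age
    post_peak_pups = int(pups[ages > peak_age].sum())
    prop_recruited = lifetime_recruits / lifetime_pups if is_breeder else math.nan

    return FemaleSummary(
        female_id=history.female_id, cohort=history.cohort,
        lifespan=history.lifespan, peak_effort=peak_effort, peak_age=peak_age,
        lifetime_pups=lifetime_pups, lifetime_recruits=lifetime_recruits,
        n_breeding_years=n_breeding_years, primiparity=primiparity,
        experienced_mast=experienced_mast, mast_peak=mast_peak,
        age_at_mast=age_at_mast, pre_peak_rate=pre_peak_rate,
        post_peak_lifespan=post_peak_lifespan, post_peak_pups=post_peak_pups,
        prop_recruited=prop_recruited, is_breeder=is_breeder,
    )


def summarize_females(
    histories: Iterable[FemaleLifeHistory], calendar: MastCalendar
) -> pd.DataFrame:
    """One summary row per female (column order :data:`SUMMARY_COLUMNS`)."""
    rows = [summarize_female(h, calendar).__dict__ for h in histories]
    if not rows:
        raise ValueError("no life histories to summarize")
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def build_analysis_sets(summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition breeders into the analysis subsets.

    Returns ``full_set`` (all breeders), ``mast_experienced_set`` (breeders
    that lived through at least one adult mast year), its complement
    ``never_mast_set``, and ``multi_year_set`` (breeders with more than one
    breeding year, used for the single-year-breeder sensitivity rerun).
    """
    full = summaries[summaries["is_breeder"]].reset_index(drop=True)
    mast = full[full["experienced_mast"]].reset_index(drop=True)
    never = full[~full["experienced_mast"]].reset_index(drop=True)
    multi = full[full["n_breeding_years"] > 1].reset_index(drop=True)
    return {
        "full_set": full,
        "mast_experienced_set": mast,
        "never_mast_set": never,
        "multi_year_set": multi,
    }


def annual_table(
    histories: Iterable[FemaleLifeHistory], calendar: MastCalendar
) -> pd.DataFrame:
    """Long-format annual table with mast and peak-year status flags.

    ``is_peak_year`` is 1 in *every* year in which a breeder's pup count
    equals her lifetime maximum (the binary-status construction flags each
    attainment, while peak age records only the first); non-breeders carry
    all-zero flags.
    """
    frames = []
    for h in histories:
        peak = max(r.pups for r in h.records)
        frames.append(pd.DataFrame({
            "female_id": [r.female_id for r in h.records],
            "cohort": [r.cohort for r in h.records],
            "year": [r.year for r in h.records],
            "age": [r.age for r in h.records],
            "pups": [r.pups for r in h.records],
            "recruits": [r.recruits for r in h.records],
            "is_mast": [int(calendar.is_mast(r.year)) for r in h.records],
            "is_peak_year": [int(peak > 0 and r.pups == peak) for r in h.records],
        }))
    if not frames:
        raise ValueError("no life histories given")
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ScalingInfo:
    """Mean/SD used to standardize a predictor; permits exact inversion."""

    mean: float
    sd: float

    def unscale(self, scaled: np.ndarray | float) -> np.ndarray | float:
        return self.mean + self.sd * np.asarray(scaled, dtype=float)


def scale_predictors(values: Sequence[float] | np.ndarray) -> tuple[np.ndarray, ScalingInfo]:
    """Standardize to mean 0 and unit sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values to scale")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot scale a constant column")
    return (x - mean) / sd, ScalingInfo(mean, sd)


# ---------------------------------------------------------------------------
# Records <-> histories and file I/O


def histories_to_frame(histories: Iterable[FemaleLifeHistory]) -> pd.DataFrame:
    rows = [
        (r.female_id, r.cohort, r.year, r.age, r.pups, r.recruits)
        for h in histories for r in h.records
    ]
    if not rows:
        raise ValueError("no life histories given")
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_histories(records: pd.DataFrame) -> list[FemaleLifeHistory]:
    """Group an annual-record table back into per-female histories.

    Lifespan is taken as the oldest recorded age (records cover every year
    of adult life in this data layout).
    """
    missing = [c for c in ["female_id", "cohort", "year", "pups", "recruits"]
               if c not in records.columns]
    if missing:
        raise ValueError(f"records table missing columns: {missing}")
    if len(records) == 0:
        raise ValueError("records table has zero rows")
    histories = []
    for fid, grp in records.groupby("female_id", sort=True):
        cohort = int(grp["cohort"].iloc[0])
        recs = tuple(
            AnnualRecord(str(fid), cohort, int(row.year), int(row.pups), int(row.recruits))
            for row in grp.itertuples()
        )
        lifespan = max(r.age for r in recs)
        histories.append(FemaleLifeHistory(str(fid), cohort, lifespan, recs))
    return histories


def read_records_csv(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    if len(records) == 0:
        raise ValueError(f"records file {path} has zero rows")
    if records[[c for c in RECORD_COLUMNS if c in records.columns]].isna().any().any():
        raise ValueError("missing values are not permitted in the records table")
    return records


def read_records_xlsx(path, column_map: Mapping[str, str], sheet: int | str = 0) -> pd.DataFrame:
    """Read a 1-row-per-female-year spreadsheet, renaming columns via
    ``column_map`` ({source column -> canonical record column})."""
    df = pd.read_excel(path, sheet_name=sheet).rename(columns=dict(column_map))
    missing = [c for c in ["female_id", "cohort", "year", "pups", "recruits"]
               if c not in df.columns]
    if missing:
        raise ValueError(f"column map leaves records without: {missing}")
    if "age" not in df.columns:
        df["age"] = df["year"] - df["cohort"]
    return df[RECORD_COLUMNS]
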