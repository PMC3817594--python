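"""Track-record cleaning, effort standardization and barrier-effect statistics.

The survey protocol: routes are driven/walked at least 12 h after the last
snowfall; each observed track set is one crossing attempt, successful when a
continuing set of tracks is found on the far side of the road.  Counts are
standardized by the number of elapsed 12 h periods, rates by km surveyed, and
the highway's permeability is the ratio of highway to transect crossing rates
(1 = no barrier, 0 = absolute barrier).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CARNIVORE_SPECIES = frozenset(
    {"coyote", "fox", "wolf", "cougar", "bobcat", "lynx", "marten", "wolverine"}
)


@dataclass(frozen=True)
class TrackRecord:
    """One observed track/crossing attempt."""

    species: str
    route: str  # "highway" or a transect id such as "T3"
    position_km: float
    count: int = 1
    success: bool | None = None
    hours_since_snowfall: float = 12.0
    survey_date: date | None = None
    repeat_flag: bool = False

    def __post_init__(self) -> None:
        if self.position_km < 0:
            raise ValueError("position_km must be non-negative")
        if self.count <= 0:
            raise ValueError("count must be a positive integer")
        if self.hours_since_snowfall < 12:
            raise ValueError(
                "hours_since_snowfall < 12 violates the survey protocol"
            )
        if self.success is not None and self.route != "highway":
            raise ValueError("success is defined only for highway records")

    @property
    def on_highway(self) -> bool:
        return self.route == "highway"


@dataclass(frozen=True)
class SurveyEffort:
    """Kilometres surveyed on one route (per survey day)."""

    route: str
    km_surveyed: float
    survey_date: date | None = None

    def __post_init__(self) -> None:
        if self.km_surveyed <= 0:
            raise ValueError("km_surveyed must be positive")


@dataclass(frozen=True)
class PermeabilityResult:
    """Highway-vs-transect crossing-rate ratio for one species or group."""

    group: str
    highway_rate: float
    transect_rate: float
    permeability: float
    basis: str = "all tracks"
    undefined: bool = False


def group_of(species: str) -> str:
    """Map a species label to its modelling group (carnivores are pooled)."""
    return "carnivores" if species in CARNIVORE_SPECIES else species


def deduplicate_tracks(
    records: Sequence[TrackRecord], radius_m: float = 300.0
) -> tuple[list[TrackRecord], list[TrackRecord]]:
    """Flag possible repeat crossings of the same individual.

    Within each species x route, records are walked in (position, date) order;
    a record closer than ``radius_m`` to the last *kept* record of that group
    is flagged as a possible repeat rather than an independent attempt
    (greedy left-to-right chaining).  Returns (kept, flagged).
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    radius_km = radius_m / 1000.0
    kept: list[TrackRecord] = []
    flagged: list[TrackRecord] = []
    key = lambda r: (r.species, r.route)
    groups: dict[tuple[str, str], list[TrackRecord]] = {}
    for rec in records:
        groups.setdefault(key(rec), []).append(rec)
    for recs in groups.values():
        recs = sorted(
            recs, key=lambda r: (r.position_km, r.survey_date or date.min)
        )
        last_kept: float | None = None
        for rec in recs:
            if last_kept is not None and rec.position_km - last_kept < radius_km:
                flagged.append(replace(rec, repeat_flag=True))
            else:
                kept.append(rec)
                last_kept = rec.position_km
    return kept, flagged


def standardize_effort(count: float, hours_since_snowfall: float) -> float:
    """Divide a track count by the number of elapsed 12 h periods.

    Periods are counted with a ceiling so the divisor is at least 1
    (surveys start no earlier than 12 h after snowfall).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if hours_since_snowfall < 12:
        raise ValueError("hours_since_snowfall < 12 violates the survey protocol")
    periods = math.ceil(hours_since_snowfall / 12.0)
    return count / periods


def crossing_rate(total_tracks: float, km_surveyed: float) -> float:
    """Crossings per km = total tracks / total km surveyed."""
    if km_surveyed <= 0:
        raise ValueError("km_surveyed must be positive")
    if total_tracks < 0:
        raise ValueError("total_tracks must be non-negative")
    return total_tracks / km_surveyed


def permeability(
    highway_rate: float,
    transect_rate: float,
    group: str = "",
    basis: str = "all tracks",
) -> PermeabilityResult:
    """Highway crossings per km divided by transect crossings per km.

    Undefined (flagged, NaN) when the transect rate is zero.
    """
    if highway_rate < 0 or transect_rate < 0:
        raise ValueError("rates must be non-negative")
    if transect_rate == 0:
        return PermeabilityResult(
            group=group,
            highway_rate=highway_rate,
            transect_rate=transect_rate,
            permeability=math.nan,
            basis=basis,
            undefined=True,
        )
    return PermeabilityResult(
        group=group,
        highway_rate=highway_rate,
        transect_rate=transect_rate,
        permeability=highway_rate / transect_rate,
        basis=basis,
    )


def _standardized_total(records: Iterable[TrackRecord]) -> float:
    return sum(
        standardize_effort(r.count, r.hours_since_snowfall) for r in records
    )


def estimate_permeability(
    records: Sequence[TrackRecord],
    efforts: Sequence[SurveyEffort],
    group: str | None = None,
    basis: str = "successful crossings",
) -> PermeabilityResult:
    """Estimate permeability for one group (or all species pooled) from raw records.

    Counts are time-standardized per record, summed per route class, then
    divided by the total km surveyed on that class.  With
    ``basis="successful crossings"`` only highway attempts with a continuing
    track on the far side count in the numerator; ``basis="all tracks"``
    counts every highway attempt.
    """
    if basis not in {"all tracks", "successful crossings"}:
        raise ValueError(f"unknown basis {basis!r}")
    if group is not None:
        records = [r for r in records if group_of(r.species) == group]
    hwy_km = sum(e.km_surveyed for e in efforts if e.route == "highway")
    trans_km = sum(e.km_surveyed for e in efforts if e.route != "highway")
    if hwy_km <= 0 or trans_km <= 0:
        raise ValueError("need positive highway and transect effort")
    hwy_records = [r for r in records if r.on_highway]
    if basis == "successful crossings":
        hwy_records = [r for r in hwy_records if r.success]
    trans_records = [r for r in records if not r.on_highway]
    hwy_rate = crossing_rate(_standardized_total(hwy_records), hwy_km)
    trans_rate = crossing_rate(_standardized_total(trans_records), trans_km)
    return permeability(
        hwy_rate, trans_rate, group=group or "all species", basis=basis
    )


@dataclass(frozen=True)
class AccumulationCurve:
    """Cumulative successful-crossing count along the highway."""

    positions_km: np.ndarray  # step locations, sorted
    cumulative: np.ndarray  # counts after each step
    length_km: float

    @property
    def total(self) -> float:
        return float(self.cumulative[-1]) if len(self.cumulative) else 0.0

    def value_at(self, km: float) -> float:
        idx = np.searchsorted(self.positions_km, km, side="right")
        return float(self.cumulative[idx - 1]) if idx else 0.0

    def flat_segments(self, min_km: float = 5.0) -> list[tuple[float, float]]:
        """Stretches of at least ``min_km`` with no crossings (candidate barriers)."""
        edges = np.concatenate([[0.0], self.positions_km, [self.length_km]])
        segments = []
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a >= min_km:
                segments.append((float(a), float(b)))
        return segments

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_km": self.positions_km, "cumulative": self.cumulative}
        )


def accumulation_curve(
    records: Sequence[TrackRecord], length_km: float
) -> AccumulationCurve:
    """Monotone step function of cumulative crossing counts versus km."""
    if length_km <= 0:
        raise ValueError("length_km must be positive")
    for rec in records:
        if not 0 <= rec.position_km <= length_km:
            raise ValueError(
                f"record at km {rec.position_km} lies outside [0, {length_km}]"
            )
    if not records:
        return AccumulationCurve(
            positions_km=np.array([]), cumulative=np.array([]), length_km=length_km
        )
    order = sorted(records, key=lambda r: r.position_km)
    positions = np.array([r.position_km for r in order])
    cumulative = np.cumsum([r.count for r in order]).astype(float)
    # merge coincident positions into single steps
    uniq, last_idx = np.unique(positions, return_index=True)
    take = np.append(last_idx[1:] - 1, len(positions) - 1)
    return AccumulationCurve(
        positions_km=uniq, cumulative=cumulative[take], length_km=length_km
    )


def plot_accumulation_curve(
    curve: AccumulationCurve, path, title: str = "Track accumulation"
) -> None:
    """Render the cumulative-crossings step function to an image file."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    x = np.concatenate([[0.0], curve.positions_km, [curve.length_km]])
    y = np.concatenate([[0.0], curve.cumulative, [curve.total]])
    ax.step(x, y, where="post")
    ax.set_xlabel("km")
    ax.set_ylabel("cumulative crossings")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def permeability_table(
    records: Sequence[TrackRecord], efforts: Sequence[SurveyEffort]
) -> pd.DataFrame:
    """Per-group permeability on both bases, as a tidy table."""
    groups = sorted({group_of(r.species) for r in records})
    rows = []
    for basis in ("all tracks", "successful crossings"):
        for grp in groups + [None]:
            res = estimate_permeability(records, efforts, group=grp, basis=basis)
            rows.append(
                {
                    "group": res.group,
                    "basis": res.basis,
                    "highway_rate": res.highway_rate,
                    "transect_rate": res.transect_rate,
                    "permeability": res.permeability,
                    "undefined": res.undefined,
                }
            )
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[TrackRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "route": [r.route for r in records],
            "position_km": [r.position_km for r in records],
            "count": [r.count for r in records],
            "success": [r.success for r in records],
            "hours_since_snowfall": [r.hours_since_snowfall for r in records],
            "survey_date": [r.survey_date for r in records],
            "repeat_flag": [r.repeat_flag for r in records],
        }
    )


def records_from_frame(table: pd.DataFrame) -> list[TrackRecord]:
    records = []
    for row in table.itertuples(index=False):
        success = row.success
        if pd.isna(success):
            success = None
        else:
            success = bool(success)
        survey_date = getattr(row, "survey_date", None)
        if pd.isna(survey_date):
            survey_date = None
        elif isinstance(survey_date, str):
            survey_date = date.fromisoformat(survey_date)
        elif isinstance(survey_date, pd.Timestamp):
            survey_date = survey_date.date()
        records.append(
            TrackRecord(
                species=row.species,
                route=row.route,
                position_km=float(row.position_km),
                count=int(row.count),
                success=success,
                hours_since_snowfall=float(row.hours_since_snowfall),
                survey_date=survey_date,
                repeat_flag=bool(getattr(row, "repeat_flag", False)),
            )
        )
    return records
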