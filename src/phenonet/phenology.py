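"""Species activity windows (phenophases) from censuses and visitation records.

Start date of activity is the number of days since 1 January until the
first flowering individual (plants) or the first observed flower visit
(visitors). Plants combine two evidence streams — the weekly flowering
census and the daily visitation records — because the census is coarser
than the interaction sampling; by default the earliest evidence of either
kind defines the start, and a provenance flag marks species whose window
was extended by visitation evidence beyond the census evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .records import FloweringCensusRecord, InteractionRecord

__all__ = ["SpeciesPhenology", "PhenologyTable", "build_phenology"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesPhenology:
    species: str
    guild: Literal["plant", "visitor"]
    start_day: int
    end_day: int
    active_days: frozenset[int]
    visit_extended: bool = False  # window widened by visitation evidence

    def __post_init__(self) -> None:
        if not self.active_days:
            raise ValueError(f"{self.species}: no active days")
        if self.start_day != min(self.active_days) or self.end_day != max(self.active_days):
            raise ValueError(f"{self.species}: start/end inconsistent with active days")

    @property
    def window_days(self) -> int:
        """Length of the activity window in days, endpoints inclusive."""
        return self.end_day - self.start_day + 1

    def filled_days(self) -> frozenset[int]:
        """Active days filled to daily resolution between start and end."""
        return frozenset(range(self.start_day, self.end_day + 1))


class PhenologyTable(Mapping[str, SpeciesPhenology]):
    """Per-species activity windows for plants and flower visitors."""

    def __init__(self, entries: Iterable[SpeciesPhenology]):
        self._entries = {e.species: e for e in entries}

    def __getitem__(self, species: str) -> SpeciesPhenology:
        return self._entries[species]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def start_days(self) -> dict[str, int]:
        return {s: e.start_day for s, e in self._entries.items()}

    def guild(self, guild: str) -> list[SpeciesPhenology]:
        return [e for e in self._entries.values() if e.guild == guild]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": e.species,
                    "guild": e.guild,
                    "start_day": e.start_day,
                    "end_day": e.end_day,
                    "duration_days": e.window_days,
                    "visit_extended": e.visit_extended,
                }
                for e in self._entries.values()
            ]
        ).set_index("species")


def build_phenology(
    records: Sequence[InteractionRecord],
    flowering: Sequence[FloweringCensusRecord] = (),
    plant_evidence: Literal["union", "census"] = "union",
) -> PhenologyTable:
    """Derive activity windows from visitation records and flowering censuses.

    Visitor phenology always comes from the visitation records. Plant
    phenology uses flowering censuses with ``n_flowering > 0`` where
    available; with ``plant_evidence="union"`` (default) visitation dates
    widen the window when a plant was visited outside its recorded
    flowering dates, and such species carry ``visit_extended=True``.
    Species with no activity evidence anywhere are excluded with a warning.
    """
    plant_census_days: dict[str, set[int]] = {}
    for rec in flowering:
        if rec.n_flowering > 0:
            plant_census_days.setdefault(rec.plant, set()).add(rec.day_of_year)
        else:
            plant_census_days.setdefault(rec.plant, set())

    plant_visit_days: dict[str, set[int]] = {}
    visitor_days: dict[str, set[int]] = {}
    for rec in records:
        plant_visit_days.setdefault(rec.plant, set()).add(rec.day_of_year)
        visitor_days.setdefault(rec.visitor, set()).add(rec.day_of_year)

    entries: list[SpeciesPhenology] = []
    for plant in sorted(set(plant_census_days) | set(plant_visit_days)):
        census = plant_census_days.get(plant, set())
        visits = plant_visit_days.get(plant, set())
        if plant_evidence == "census":
            days = set(census)
            extended = False
        else:
            days = census | visits
            extended = (not census and bool(visits)) or (
                bool(visits) and bool(census)
                and (min(visits) < min(census) or max(visits) > max(census))
            )
        if not days:
            logger.warning("plant %s has no activity evidence; excluded", plant)
            continue
        entries.append(
            SpeciesPhenology(
                species=plant,
                guild="plant",
                start_day=min(days),
                end_day=max(days),
                active_days=frozenset(days),
                visit_extended=extended,
            )
        )
    for visitor in sorted(visitor_days):
        days = visitor_days[visitor]
        entries.append(
            SpeciesPhenology(
                species=visitor,
                guild="visitor",
                start_day=min(days),
                end_day=max(days),
                active_days=frozenset(days),
            )
        )
    return PhenologyTable(entries)
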