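"""Weighted bipartite networks and temporal aggregation of visitation records.

A :class:`WeightedBipartiteNetwork` holds the plants x visitors count
matrix ``A`` (visitation frequencies), its grand total ``F`` and marginal
totals ``k`` (per plant) and ``d`` (per visitor) — the quantities the
quantitative modularity objective is written in. Aggregation turns dated
records into one sub-network per census day (default), per pair of
consecutive census days, or per ISO calendar week, plus a season-wide
cumulative network.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .records import InteractionRecord

__all__ = [
    "WeightedBipartiteNetwork",
    "aggregate",
    "cumulative",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
]

AggregationWindow = Literal["day", "2day", "week"]


@dataclass(frozen=True)
class WeightedBipartiteNetwork:
    """Plants x visitors non-negative count matrix with labels.

    Every row and column has at least one positive entry: species appear
    in a (sub-)network only if they were active in the covered window.
    """

    plants: tuple[str, ...]
    visitors: tuple[str, ...]
    weights: np.ndarray
    label: str = ""
    date: _dt.date | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.plants), len(self.visitors)):
            raise ValueError("weights shape does not match label counts")
        if np.any(w < 0) or not np.issubdtype(w.dtype, np.integer):
            raise ValueError("weights must be non-negative integers")
        if w.sum() < 1:
            raise ValueError("network must contain at least one visit")
        if np.any(w.sum(axis=1) == 0) or np.any(w.sum(axis=0) == 0):
            raise ValueError("every plant and visitor must have >= 1 visit")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "plants", tuple(self.plants))
        object.__setattr__(self, "visitors", tuple(self.visitors))

    # -- marginal quantities -------------------------------------------------
    @property
    def F(self) -> int:
        """Total number of visits, sum of all A_ij."""
        return int(self.weights.sum())

    @property
    def k(self) -> np.ndarray:
        """Per-plant visit totals (row marginals)."""
        return self.weights.sum(axis=1)

    @property
    def d(self) -> np.ndarray:
        """Per-visitor visit totals (column marginals)."""
        return self.weights.sum(axis=0)

    @property
    def species(self) -> tuple[str, ...]:
        return self.plants + self.visitors

    @property
    def n_interactions(self) -> int:
        """Number of realised (positive-weight) plant-visitor links."""
        return int(np.count_nonzero(self.weights))

    def interaction_set(self) -> set[tuple[str, str]]:
        """Set of realised (plant, visitor) pairs — binary occurrence."""
        rows, cols = np.nonzero(self.weights)
        return {(self.plants[i], self.visitors[j]) for i, j in zip(rows, cols)}

    def species_set(self) -> set[str]:
        return set(self.plants) | set(self.visitors)

    def visitors_of(self, plant: str) -> set[str]:
        """Visitor species with at least one visit to ``plant``."""
        if plant not in self.plants:
            raise KeyError(f"unknown plant {plant!r}")
        i = self.plants.index(plant)
        return {self.visitors[j] for j in np.nonzero(self.weights[i])[0]}

    def weight(self, plant: str, visitor: str) -> int:
        return int(self.weights[self.plants.index(plant), self.visitors.index(visitor)])


def _single_site(records: Sequence[InteractionRecord]) -> str:
    sites = {r.site for r in records}
    if len(sites) != 1:
        raise ValueError(f"records must come from a single site, got {sorted(sites)}")
    return sites.pop()


def _build(records: Sequence[InteractionRecord], label: str, date: _dt.date | None) -> WeightedBipartiteNetwork:
    plants = tuple(sorted({r.plant for r in records}))
    visitors = tuple(sorted({r.visitor for r in records}))
    p_idx = {p: i for i, p in enumerate(plants)}
    v_idx = {v: j for j, v in enumerate(visitors)}
    A = np.zeros((len(plants), len(visitors)), dtype=np.int64)
    for r in records:
        A[p_idx[r.plant], v_idx[r.visitor]] += r.visits
    return WeightedBipartiteNetwork(plants, visitors, A, label=label, date=date)


def aggregate(
    records: Sequence[InteractionRecord], window: AggregationWindow = "day"
) -> list[WeightedBipartiteNetwork]:
    """Break records into time-aggregated sub-networks, ordered by time.

    ``window`` is one of ``"day"`` (one sub-network per census day),
    ``"2day"`` (pairs of consecutive census days, chronological pairing),
    or ``"week"`` (ISO calendar weeks). Windows with no records are
    omitted, so a 10-census-day season yields 10 daily sub-networks.
    """
    if not records:
        raise ValueError("no records to aggregate")
    _single_site(records)
    days = sorted({r.census_date for r in records})
    if window == "day":
        groups = {day: [day] for day in days}
    elif window == "2day":
        groups = {}
        for i in range(0, len(days), 2):
            chunk = days[i : i + 2]
            groups[chunk[0]] = chunk
        # keys are the first census day of each pair
    elif window == "week":
        groups = {}
        for day in days:
            iso = day.isocalendar()
            key = _dt.date.fromisocalendar(iso[0], iso[1], 1)
            groups.setdefault(key, []).append(day)
    else:
        raise ValueError(f"unknown aggregation window {window!r}")

    nets = []
    for start in sorted(groups):
        members = set(groups[start])
        chunk = [r for r in records if r.census_date in members]
        label = start.isoformat() if len(members) == 1 else f"{start.isoformat()}+{len(members) - 1}"
        nets.append(_build(chunk, label=label, date=min(members)))
    return nets


def cumulative(records: Sequence[InteractionRecord]) -> WeightedBipartiteNetwork:
    """Season-wide cumulative quantitative bipartite network of one site."""
    if not records:
        raise ValueError("no records")
    _single_site(records)
    return _build(records, label="cumulative", date=min(r.census_date for r in records))


# -- matrix / edge-list text exports ----------------------------------------

def write_matrix(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    """Rectangular TSV: first row visitor labels, first column plant labels."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(net.visitors) + "\n")
        for i, p in enumerate(net.plants):
            fh.write(p + "\t" + "\t".join(str(int(x)) for x in net.weights[i]) + "\n")


def read_matrix(path: str | Path, label: str = "") -> WeightedBipartiteNetwork:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    visitors = tuple(lines[0].strip("\n").split("\t")[1:])
    plants, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        plants.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    return WeightedBipartiteNetwork(tuple(plants), visitors, np.array(rows, dtype=np.int64), label=label)


def write_edge_list(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("plant,visitor,weight\n")
        for i, p in enumerate(net.plants):
            for j in np.nonzero(net.weights[i])[0]:
                fh.write(f"{p},{net.visitors[j]},{int(net.weights[i, j])}\n")
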