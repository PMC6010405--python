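"""Temporal beta diversity of species assemblages and interactions.

All dissimilarities are computed on binary occurrence (a species or a
(plant, visitor) link is present or absent in a time-aggregated network);
visit counts never enter. Three families are implemented:

* the Whittaker pairwise dissimilarity
  ``beta = (a+b+c) / ((2a+b+c)/2) - 1`` (algebraically ``(b+c)/(2a+b+c)``),
  applied to species sets (``beta_S``), whole interaction sets
  (``beta_WN``) and interactions among shared species (``beta_OS``, the
  rewiring signal);
* the Jaccard dissimilarity ``beta_CC = (b+c)/(a+b+c)`` with its exact
  additive partition into a replacement component
  ``beta_3M = 2 min(b,c)/(a+b+c)`` and a richness-difference component
  ``beta_RICH = |b-c|/(a+b+c)``, in pairwise and pooled multiple-site
  (sum over all pairs of time units) form;
* phenological overlap ``S_ij = a_ij/b_ij`` — shared flowering days over
  union flowering days, a Jaccard similarity on day sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Sequence

import pandas as pd

from .network import WeightedBipartiteNetwork
from .phenology import PhenologyTable

__all__ = [
    "SharedUniqueCounts",
    "BetaPartition",
    "PairwiseNetworkBeta",
    "FloweringOverlap",
    "shared_unique",
    "whittaker_beta",
    "jaccard_partition_pairwise",
    "multisite_jaccard_partition",
    "network_beta",
    "all_pairwise_network_beta",
    "flowering_overlap",
    "overlap_matrix",
    "visitor_assemblage_dissimilarity",
]


@dataclass(frozen=True)
class SharedUniqueCounts:
    """a = shared elements, b = unique to the first set, c = to the second."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c


@dataclass(frozen=True)
class BetaPartition:
    """Jaccard dissimilarity and its replacement/richness decomposition."""

    beta_cc: float
    beta_3m: float
    beta_rich: float
    n_units: int

    def __post_init__(self) -> None:
        if abs(self.beta_cc - (self.beta_3m + self.beta_rich)) > 1e-12:
            raise ValueError("partition is not additive")

    @property
    def replacement_share(self) -> float:
        """beta_3M as a fraction of beta_CC (species turnover share)."""
        return self.beta_3m / self.beta_cc if self.beta_cc > 0 else float("nan")


@dataclass(frozen=True)
class PairwiseNetworkBeta:
    """Whittaker dissimilarities between two time-aggregated networks.

    ``beta_os`` is None when the networks share no species (undefined);
    ``beta_st = beta_wn - beta_os`` is the part of interaction
    dissimilarity attributable to species turnover, reported as-is.
    """

    unit_a: str
    unit_b: str
    time_lag: int
    beta_s: float
    beta_wn: float
    beta_os: float | None

    @property
    def beta_st(self) -> float | None:
        return None if self.beta_os is None else self.beta_wn - self.beta_os


@dataclass(frozen=True)
class FloweringOverlap:
    species_i: str
    species_j: str
    a_ij: int  # days both in flower
    b_ij: int  # days at least one in flower

    @property
    def s_ij(self) -> float:
        return self.a_ij / self.b_ij


def shared_unique(set_a: Iterable[Hashable], set_b: Iterable[Hashable]) -> SharedUniqueCounts:
    sa, sb = set(set_a), set(set_b)
    if not sa and not sb:
        raise ValueError("dissimilarity of two empty sets is undefined")
    return SharedUniqueCounts(a=len(sa & sb), b=len(sa - sb), c=len(sb - sa))


def whittaker_beta(counts: SharedUniqueCounts) -> float:
    """Whittaker dissimilarity: 0 for identical sets, 1 for disjoint sets."""
    a, b, c = counts.a, counts.b, counts.c
    if a + b + c == 0:
        raise ValueError("a + b + c must be positive")
    return (a + b + c) / ((2 * a + b + c) / 2) - 1


def jaccard_partition_pairwise(counts: SharedUniqueCounts) -> tuple[float, float, float]:
    """(beta_CC, beta_3M, beta_RICH) for one pair of assemblages."""
    a, b, c = counts.a, counts.b, counts.c
    n = a + b + c
    if n == 0:
        raise ValueError("a + b + c must be positive")
    return (b + c) / n, 2 * min(b, c) / n, abs(b - c) / n


def multisite_jaccard_partition(assemblages: Sequence[Iterable[Hashable]]) -> BetaPartition:
    """Pooled multiple-site Jaccard partition over >= 2 assemblages.

    Pools numerators and denominators of the pairwise partition over all
    unordered pairs of units, which preserves the additivity
    ``beta_CC = beta_3M + beta_RICH`` exactly.
    """
    sets = [set(s) for s in assemblages]
    if len(sets) < 2:
        raise ValueError("need at least 2 assemblages")
    if any(not s for s in sets):
        raise ValueError("assemblages must be non-empty")
    num_cc = num_3m = num_rich = denom = 0
    for sa, sb in combinations(sets, 2):
        a, b, c = len(sa & sb), len(sa - sb), len(sb - sa)
        num_cc += b + c
        num_3m += 2 * min(b, c)
        num_rich += abs(b - c)
        denom += a + b + c
    return BetaPartition(num_cc / denom, num_3m / denom, num_rich / denom, n_units=len(sets))


def network_beta(
    net_a: WeightedBipartiteNetwork, net_b: WeightedBipartiteNetwork
) -> PairwiseNetworkBeta:
    """beta_S, beta_WN and beta_OS between two time-aggregated networks."""
    beta_s = whittaker_beta(shared_unique(net_a.species_set(), net_b.species_set()))
    ints_a, ints_b = net_a.interaction_set(), net_b.interaction_set()
    beta_wn = whittaker_beta(shared_unique(ints_a, ints_b))
    shared_species = net_a.species_set() & net_b.species_set()
    sub_a = {(p, v) for p, v in ints_a if p in shared_species and v in shared_species}
    sub_b = {(p, v) for p, v in ints_b if p in shared_species and v in shared_species}
    beta_os = whittaker_beta(shared_unique(sub_a, sub_b)) if (sub_a or sub_b) else None
    if net_a.date is not None and net_b.date is not None:
        lag = abs((net_b.date - net_a.date).days)
    else:
        lag = 0
    return PairwiseNetworkBeta(
        unit_a=net_a.label, unit_b=net_b.label, time_lag=lag,
        beta_s=beta_s, beta_wn=beta_wn, beta_os=beta_os,
    )


def all_pairwise_network_beta(nets: Sequence[WeightedBipartiteNetwork]) -> list[PairwiseNetworkBeta]:
    """network_beta for every unordered pair of sub-networks, time ordered."""
    return [network_beta(a, b) for a, b in combinations(nets, 2)]


def pairwise_beta_frame(betas: Sequence[PairwiseNetworkBeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_a": b.unit_a, "unit_b": b.unit_b, "time_lag": b.time_lag,
                "beta_s": b.beta_s, "beta_wn": b.beta_wn,
                "beta_os": b.beta_os, "beta_st": b.beta_st,
            }
            for b in betas
        ]
    )


def flowering_overlap(
    table: PhenologyTable, species_i: str, species_j: str
) -> FloweringOverlap:
    """Phenological overlap S_ij on daily-filled activity windows."""
    di = table[species_i].filled_days()
    dj = table[species_j].filled_days()
    return FloweringOverlap(species_i, species_j, a_ij=len(di & dj), b_ij=len(di | dj))


def overlap_matrix(table: PhenologyTable, guild: str = "plant") -> pd.DataFrame:
    species = sorted(e.species for e in table.guild(guild))
    mat = pd.DataFrame(1.0, index=species, columns=species)
    for i, j in combinations(species, 2):
        s = flowering_overlap(table, i, j).s_ij
        mat.loc[i, j] = mat.loc[j, i] = s
    return mat


def visitor_assemblage_dissimilarity(
    cumulative: WeightedBipartiteNetwork, plant_i: str, plant_j: str
) -> float:
    """Jaccard dissimilarity of two plants' season-wide visitor sets."""
    vi, vj = cumulative.visitors_of(plant_i), cumulative.visitors_of(plant_j)
    if not vi or not vj:
        raise ValueError("plant with no visitors")
    return 1 - len(vi & vj) / len(vi | vj)
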