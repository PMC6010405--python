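"""Linear models relating dissimilarity to time lag and to flowering overlap.

Species-composition dissimilarity (beta_S) is regressed linearly on the
time lag between sub-networks; whole-network interaction dissimilarity
(beta_WN) saturates with lag and is fitted on ln(lag) by default. A third
model regresses the dissimilarity of plants' visitor assemblages on
pairwise flowering overlap — a negative slope means plants flowering in
synchrony share visitors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .beta import PairwiseNetworkBeta, flowering_overlap, visitor_assemblage_dissimilarity
from .network import WeightedBipartiteNetwork
from .phenology import PhenologyTable

__all__ = ["RegressionResult", "ols_fit", "overlap_vs_dissimilarity", "turnover_lag", "TurnoverLag"]

Transform = Literal["none", "log-lag", "log-response"]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    transform: Transform = "none"

    def summary(self) -> str:
        return (
            f"OLS (transform={self.transform}): slope={self.slope:.4g} "
            f"intercept={self.intercept:.4g} R2={self.r_squared:.3f} "
            f"p={self.p_value:.3g} n={self.n}"
        )


def ols_fit(
    x: Sequence[float], y: Sequence[float], transform: Transform = "none"
) -> RegressionResult:
    """Ordinary least squares of y on x with slope t-test.

    ``transform="log-lag"`` replaces x by ln(x) (all x must be positive);
    ``"log-response"`` replaces y by ln(y) (all y positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if transform == "log-lag":
        if np.any(x <= 0):
            raise ValueError("log-lag transform requires positive x")
        x = np.log(x)
    elif transform == "log-response":
        if np.any(y <= 0):
            raise ValueError("log-response transform requires positive y")
        y = np.log(y)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared) if np.var(y) > 0 else 0.0,
        p_value=float(res.pvalues[1]),
        n=int(x.size),
        transform=transform,
    )


def overlap_vs_dissimilarity(
    table: PhenologyTable, cumulative: WeightedBipartiteNetwork
) -> RegressionResult:
    """Visitor-assemblage dissimilarity regressed on flowering overlap.

    One point per unordered pair of plants present both in the phenology
    table and the cumulative network.
    """
    plants = sorted(set(p for p in cumulative.plants if p in table))
    pairs = list(combinations(plants, 2))
    if len(pairs) < 3:
        raise ValueError("need at least 3 plant pairs")
    overlap = [flowering_overlap(table, i, j).s_ij for i, j in pairs]
    dissim = [visitor_assemblage_dissimilarity(cumulative, i, j) for i, j in pairs]
    return ols_fit(overlap, dissim)


@dataclass(frozen=True)
class TurnoverLag:
    """Smallest lag beyond which interaction turnover is complete."""

    lag: int
    n_pairs_at_or_beyond: int


def turnover_lag(betas: Sequence[PairwiseNetworkBeta], tol: float = 1e-12) -> TurnoverLag | None:
    """Smallest lag L with beta_WN = 1 for every pair at lag >= L.

    Returns None when even the maximal-lag pairs retain shared
    interactions (no complete turnover within the season).
    """
    if not betas:
        raise ValueError("no pairwise dissimilarities given")

    def complete_beyond(lag: int) -> bool:
        return all(b.beta_wn >= 1 - tol for b in betas if b.time_lag >= lag)

    lags = sorted({b.time_lag for b in betas})
    if not complete_beyond(lags[-1]):
        return None
    best = min(lag for lag in lags if complete_beyond(lag))
    n = sum(1 for b in betas if b.time_lag >= best)
    return TurnoverLag(lag=best, n_pairs_at_or_beyond=n)
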