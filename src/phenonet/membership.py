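"""Temporal characterization of modules and phenology-based membership.

Three stages: (1) activity profiles — total visits received per census
day by the plants of each module; (2) one-way goodness-of-fit chi-square
tests of those profiles against a uniform-over-days expectation, with
Monte-Carlo p-values and Holm (sequential Bonferroni) correction across
modules; (3) a baseline-category multinomial logistic regression of
module identity on the start day of species activity, with a likelihood
ratio chi-square test against the intercept-only model and predicted
module-membership probability curves over the season.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .modularity import ModularPartition
from .network import WeightedBipartiteNetwork

__all__ = [
    "ModuleActivityProfile",
    "ChiSquareMCResult",
    "module_activity",
    "chi2_mc_test",
    "chi2_mc_table",
    "MultinomialFit",
    "ModuleMembershipModel",
    "fit_multinomial",
    "predict_membership",
]


# ---------------------------------------------------------------------------
# activity profiles

@dataclass(frozen=True)
class ModuleActivityProfile:
    module: int
    visits_per_day: dict  # census date -> visits to the module's plants

    @property
    def total(self) -> int:
        return int(sum(self.visits_per_day.values()))

    def counts(self) -> np.ndarray:
        return np.array([self.visits_per_day[k] for k in sorted(self.visits_per_day)])


def module_activity(
    partition: ModularPartition | Mapping[str, int],
    subnets: Sequence[WeightedBipartiteNetwork],
) -> list[ModuleActivityProfile]:
    """Per-module, per-census-day visits received by the module's plants."""
    assignment = partition.assignment if isinstance(partition, ModularPartition) else dict(partition)
    modules = sorted(set(assignment.values()))
    profiles = {m: {net.date: 0 for net in subnets} for m in modules}
    for net in subnets:
        k = net.k
        for i, plant in enumerate(net.plants):
            if plant not in assignment:
                raise KeyError(f"plant {plant!r} has no module assignment")
            profiles[assignment[plant]][net.date] += int(k[i])
    return [ModuleActivityProfile(m, profiles[m]) for m in modules]


# ---------------------------------------------------------------------------
# Monte-Carlo chi-square

@dataclass(frozen=True)
class ChiSquareMCResult:
    module: int
    chi2: float
    p_mc: float
    n_reps: int
    p_adjusted: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.p_adjusted is None:
            return None
        return self.p_adjusted < 0.05


def chi2_mc_test(
    profile: ModuleActivityProfile,
    n_reps: int = 5000,
    seed: int | None = None,
    expected: Sequence[float] | None = None,
) -> ChiSquareMCResult:
    """One-way chi-square of a module's activity across census days.

    The null expectation is uniform across census days unless ``expected``
    gives per-day weights (e.g. whole-network daily totals). The p-value
    is the add-one Monte-Carlo rank of the observed statistic among
    multinomial replicates drawn under the null, so it is never zero.
    """
    counts = profile.counts().astype(float)
    if counts.size < 2:
        raise ValueError("need at least 2 census days")
    total = counts.sum()
    if total <= 0:
        raise ValueError("profile has no visits")
    if expected is None:
        probs = np.full(counts.size, 1 / counts.size)
    else:
        expected = np.asarray(expected, dtype=float)
        probs = expected / expected.sum()
    exp_counts = total * probs
    chi2 = float(((counts - exp_counts) ** 2 / exp_counts).sum())
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(int(total), probs, size=n_reps)
    rep_chi2 = ((reps - exp_counts) ** 2 / exp_counts).sum(axis=1)
    p_mc = (1 + int((rep_chi2 >= chi2 - 1e-12).sum())) / (n_reps + 1)
    return ChiSquareMCResult(module=profile.module, chi2=chi2, p_mc=p_mc, n_reps=n_reps)


def chi2_mc_table(
    profiles: Sequence[ModuleActivityProfile],
    n_reps: int = 5000,
    seed: int | None = None,
    expected: Sequence[float] | None = None,
) -> pd.DataFrame:
    """chi2_mc_test per module with Holm step-down correction across modules."""
    rng = np.random.default_rng(seed)
    results = [
        chi2_mc_test(p, n_reps=n_reps, seed=int(rng.integers(2**31)), expected=expected)
        for p in profiles
    ]
    raw = [r.p_mc for r in results]
    _, adj, _, _ = multipletests(raw, alpha=0.05, method="holm")
    return pd.DataFrame(
        {
            "module": [r.module for r in results],
            "chi2": [r.chi2 for r in results],
            "p_mc": raw,
            "p_holm": adj,
            "significant": adj < 0.05,
        }
    )


# ---------------------------------------------------------------------------
# multinomial logistic regression of module membership on start day

@dataclass(frozen=True)
class MultinomialFit:
    """Baseline-category logit of module membership on activity start day."""

    modules: tuple  # module labels; first is the reference category
    coefficients: np.ndarray  # (K-1, 2): intercept, start-day slope
    ll_full: float
    ll_null: float
    df: int
    converged: bool
    quasi_separation: bool
    n: int
    x_center: float
    ridge: float

    @property
    def K(self) -> int:
        return len(self.modules)

    @property
    def lr_chi2(self) -> float:
        return max(0.0, 2 * (self.ll_full - self.ll_null))

    @property
    def p_value(self) -> float:
        return float(stats.chi2.sf(self.lr_chi2, self.df))

    def linear_predictors(self, days: np.ndarray) -> np.ndarray:
        x = np.asarray(days, dtype=float) - self.x_center
        eta = np.zeros((x.size, self.K))
        eta[:, 1:] = self.coefficients[:, 0] + np.outer(x, self.coefficients[:, 1])
        return eta

    def predict(self, days: Sequence[float]) -> pd.DataFrame:
        """Predicted module-membership probabilities at the given days."""
        eta = self.linear_predictors(np.asarray(days, dtype=float))
        eta -= eta.max(axis=1, keepdims=True)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
        return pd.DataFrame(probs, index=list(days), columns=list(self.modules))

    def summary(self) -> str:
        lines = [
            "Multinomial logistic regression: module ~ start day of activity",
            f"  n = {self.n}  modules = {self.K} (reference: {self.modules[0]})",
            f"  LR chi2 = {self.lr_chi2:.2f}  df = {self.df}  p = {self.p_value:.3g}",
            f"  converged = {self.converged}  quasi-separation flag = {self.quasi_separation}",
            "  module        intercept     slope/day",
        ]
        for m, (b0, b1) in zip(self.modules[1:], self.coefficients):
            # report intercept on the uncentered day scale
            lines.append(f"  {str(m):<12}  {b0 - b1 * self.x_center:>10.4f}  {b1:>10.4f}")
        return "\n".join(lines)


def _nll_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray, K: int, ridge: float):
    n = x.size
    B = theta.reshape(K - 1, 2)
    eta = np.zeros((n, K))
    eta[:, 1:] = B[:, 0] + np.outer(x, B[:, 1])
    m = eta.max(axis=1, keepdims=True)
    logz = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
    ll = float(eta[np.arange(n), y].sum() - logz.sum())
    probs = np.exp(eta - logz[:, None])
    # gradient of the negative penalized log-likelihood
    resid = probs.copy()
    resid[np.arange(n), y] -= 1.0
    g = np.empty_like(B)
    g[:, 0] = resid[:, 1:].sum(axis=0)
    g[:, 1] = (resid[:, 1:] * x[:, None]).sum(axis=0)
    g[:, 1] += 2 * ridge * B[:, 1]
    pen = ridge * float((B[:, 1] ** 2).sum())
    return -(ll - pen), g.ravel(), ll


class ModuleMembershipModel:
    """Does the start day of species activity predict module membership?

    A baseline-category (multinomial) logit with one numeric predictor,
    fitted by quasi-Newton maximization of a log-likelihood carrying a
    tiny ridge penalty on the slopes (default 1e-6) so that estimates
    stay finite under the (quasi-)separation that phenologically clean
    modules produce. The predictor is centered internally; reported
    intercepts are mapped back to the day-of-year scale.
    """

    def __init__(self, start_days: Sequence[float], modules: Sequence, ridge: float = 1e-6):
        start_days = np.asarray(start_days, dtype=float)
        modules = list(modules)
        if start_days.size != len(modules):
            raise ValueError("start_days and modules must have equal length")
        labels = sorted(set(modules), key=repr)
        if len(labels) < 2:
            raise ValueError("need at least 2 modules")
        counts = {m: modules.count(m) for m in labels}
        empty = [m for m, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"module(s) with zero members: {empty}")
        self.start_days = start_days
        self.module_labels = tuple(labels)
        self.y = np.array([labels.index(m) for m in modules])
        self.ridge = float(ridge)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, start_col: str = "start_day", module_col: str = "module", **kw):
        return cls(df[start_col].to_numpy(), df[module_col].tolist(), **kw)

    def fit(self, maxiter: int = 500) -> MultinomialFit:
        x = self.start_days
        center = float(x.mean())
        xc = x - center
        K = len(self.module_labels)
        n = x.size
        counts = np.bincount(self.y, minlength=K)
        ll_null = float((counts[counts > 0] * np.log(counts[counts > 0] / n)).sum())

        theta0 = np.zeros(2 * (K - 1))
        res = optimize.minimize(
            lambda t: _nll_grad(t, xc, self.y, K, self.ridge)[:2],
            theta0,
            jac=True,
            method="BFGS",
            options={"maxiter": maxiter, "gtol": 1e-8},
        )
        _, grad, ll_full = _nll_grad(res.x, xc, self.y, K, self.ridge)
        # first-order optimality is the convergence criterion; BFGS's own
        # success flag is over-strict near quasi-separation
        converged = bool(np.isfinite(grad).all()) and float(np.abs(grad).max()) < 1e-6
        B = res.x.reshape(K - 1, 2)
        # heuristic separation flag: slopes driven to the ridge-limited scale
        sep = bool((np.abs(B[:, 1]) * (x.std() + 1e-12) > 15).any()) or ll_full > -1e-6 * n
        return MultinomialFit(
            modules=self.module_labels,
            coefficients=B,
            ll_full=ll_full,
            ll_null=ll_null,
            df=K - 1,
            converged=converged,
            quasi_separation=sep,
            n=n,
            x_center=center,
            ridge=self.ridge,
        )


def fit_multinomial(
    start_days: Mapping[str, float] | Sequence[float],
    modules: Mapping[str, int] | Sequence,
    ridge: float = 1e-6,
) -> MultinomialFit:
    """Functional wrapper around :class:`ModuleMembershipModel`.

    When both arguments are mappings keyed by species, they are aligned
    on the species present in both.
    """
    if isinstance(start_days, Mapping) and isinstance(modules, Mapping):
        species = sorted(set(start_days) & set(modules))
        xs = [start_days[s] for s in species]
        ms = [modules[s] for s in species]
    else:
        xs, ms = list(start_days), list(modules)
    return ModuleMembershipModel(xs, ms, ridge=ridge).fit()


def predict_membership(fit: MultinomialFit, day_grid: Sequence[float]) -> pd.DataFrame:
    """Predicted membership probability curves (rows: days, cols: modules)."""
    return fit.predict(day_grid)
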