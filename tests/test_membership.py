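import numpy as np
import pytest
from scipy import stats

from phenonet import (
    ModuleMembershipModel,
    chi2_mc_table,
    chi2_mc_test,
    cumulative,
    aggregate,
    fit_multinomial,
    module_activity,
    predict_membership,
)
from phenonet.membership import ModuleActivityProfile

from conftest import rec


# ---------------------------------------------------------------------------
# activity profiles

def test_single_module_profile_equals_daily_totals(small_records):
    subnets = aggregate(small_records, window="day")
    assignment = {s: 0 for s in cumulative(small_records).species}
    (profile,) = module_activity(assignment, subnets)
    assert profile.total == cumulative(small_records).F
    assert list(profile.counts()) == [n.F for n in subnets]


def test_one_plant_module_profile():
    records = [rec(14, "p1", "v1", 5)]
    subnets = aggregate(records)
    profiles = module_activity({"p1": 3, "v1": 3}, subnets)
    assert profiles[0].visits_per_day == {subnets[0].date: 5}


def test_module_profiles_sum_to_network_totals(small_records):
    subnets = aggregate(small_records, window="day")
    assignment = {}
    for s in cumulative(small_records).species:
        assignment[s] = 0 if s.endswith("1") else 1
    profiles = module_activity(assignment, subnets)
    summed = np.sum([p.counts() for p in profiles], axis=0)
    assert list(summed) == [n.F for n in subnets]


def test_unassigned_plant_is_error(small_records):
    subnets = aggregate(small_records, window="day")
    with pytest.raises(KeyError):
        module_activity({"p1": 0}, subnets)


# ---------------------------------------------------------------------------
# Monte-Carlo chi-square

def prof(counts, module=0):
    return ModuleActivityProfile(module, {i: c for i, c in enumerate(counts)})


def test_uniform_counts_give_chi2_zero_p_one():
    res = chi2_mc_test(prof([10, 10, 10, 10]), n_reps=500, seed=0)
    assert res.chi2 == 0.0
    assert res.p_mc == 1.0


def test_extreme_concentration_is_highly_significant():
    res = chi2_mc_test(prof([40, 0, 0, 0]), n_reps=5000, seed=0)
    assert res.chi2 == pytest.approx(120.0)
    assert res.p_mc <= 1 / 5001 + 1e-12


def test_p_mc_never_zero_and_single_day_error():
    res = chi2_mc_test(prof([100, 0]), n_reps=200, seed=1)
    assert res.p_mc >= 1 / 201
    with pytest.raises(ValueError):
        chi2_mc_test(prof([5]))


def test_holm_step_down_adjustment():
    rng = np.random.default_rng(0)
    # engineered profiles spanning strong / mild / no signal
    profiles = [prof([60, 5, 5], 0), prof([22, 10, 10], 1), prof([15, 12, 15], 2)]
    table = chi2_mc_table(profiles, n_reps=2000, seed=5)
    # Holm: adjusted p >= raw p, monotone in rank order
    assert (table["p_holm"] >= table["p_mc"] - 1e-12).all()
    # hand application on the spec'd raw p pattern
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests([0.001, 0.04, 0.2], method="holm")
    assert adj == pytest.approx([0.003, 0.08, 0.2])


def test_mc_p_matches_exact_enumeration_two_days():
    """2-day profile: the exact multinomial tail is enumerable."""
    counts = [14, 6]
    total = sum(counts)
    probs = np.array([0.5, 0.5])
    exp = total * probs
    chi2_obs = ((np.array(counts) - exp) ** 2 / exp).sum()
    exact = sum(
        stats.binom.pmf(k, total, 0.5)
        for k in range(total + 1)
        if ((k - exp[0]) ** 2 / exp[0] + (total - k - exp[1]) ** 2 / exp[1]) >= chi2_obs - 1e-12
    )
    res = chi2_mc_test(prof(counts), n_reps=5000, seed=7)
    se = np.sqrt(exact * (1 - exact) / 5000)
    assert abs(res.p_mc - exact) <= 3 * se + 1 / 5001


def test_activity_weighted_expectation_option():
    # profile proportional to the community rhythm: no signal under that null
    res = chi2_mc_test(prof([30, 20, 10]), n_reps=500, seed=2, expected=[3, 2, 1])
    assert res.chi2 == 0.0 and res.p_mc == 1.0


# ---------------------------------------------------------------------------
# multinomial membership model

def test_constant_predictor_gives_null_model():
    fit = fit_multinomial([150.0] * 9, [0, 0, 0, 1, 1, 1, 2, 2, 2])
    assert fit.lr_chi2 == pytest.approx(0.0, abs=1e-6)
    assert fit.p_value == pytest.approx(1.0, abs=1e-4)
    assert fit.df == 2


def test_df_follows_modules_minus_one():
    rng = np.random.default_rng(0)
    days = rng.uniform(150, 200, 25)
    modules = rng.integers(0, 5, 25)
    while len(set(modules.tolist())) < 5:
        modules = rng.integers(0, 5, 25)
    fit = fit_multinomial(days, modules.tolist())
    assert fit.K == 5 and fit.df == 4


def test_separated_modules_reject_and_flag():
    days = [160, 162, 164, 190, 192, 194]
    modules = ["early", "early", "early", "late", "late", "late"]
    fit = fit_multinomial(days, modules)
    # null deviance 2 * 6 * ln 2 ~ 8.32; full deviance ~ 0 under separation
    assert fit.ll_null == pytest.approx(-6 * np.log(2))
    assert fit.lr_chi2 > 7.88  # chi2_1 at p = 0.005
    assert fit.quasi_separation
    # early module probability near 1 at day 160
    probs = predict_membership(fit, [160])
    assert probs.loc[160, "early"] > 0.95


def test_probabilities_sum_to_one_everywhere():
    rng = np.random.default_rng(3)
    days = rng.uniform(150, 210, 40)
    modules = (days > 170).astype(int) ^ (rng.random(40) < 0.2).astype(int)
    fit = fit_multinomial(days, modules.tolist())
    grid = np.linspace(140, 220, 33)
    probs = predict_membership(fit, grid)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)


def test_intercept_only_predicts_module_frequencies():
    fit = fit_multinomial([150.0] * 10, [0] * 7 + [1] * 3)
    probs = predict_membership(fit, [150, 160])
    assert np.allclose(probs.iloc[0], [0.7, 0.3], atol=1e-3)


def test_lr_invariant_to_module_relabelling():
    rng = np.random.default_rng(8)
    days = rng.uniform(150, 210, 30)
    modules = np.digitize(days, [170, 190])
    noise = rng.integers(0, 3, 30)
    modules = np.where(rng.random(30) < 0.15, noise, modules)
    base = fit_multinomial(days, modules.tolist())
    relabeled = fit_multinomial(days, [{0: "z", 1: "a", 2: "m"}[m] for m in modules])
    assert base.lr_chi2 == pytest.approx(relabeled.lr_chi2, abs=1e-8)


def test_gradient_small_at_reported_optimum():
    rng = np.random.default_rng(9)
    days = rng.uniform(150, 210, 40)
    modules = np.where(days + rng.normal(0, 12, 40) > 180, "late", "early")
    model = ModuleMembershipModel(days, modules.tolist())
    fit = model.fit()
    assert fit.converged
    from phenonet.membership import _nll_grad

    theta = fit.coefficients.ravel()
    _, grad, _ = _nll_grad(theta, days - fit.x_center, model.y, fit.K, fit.ridge)
    assert np.abs(grad).max() < 1e-6


def test_against_statsmodels_mnlogit():
    """Independent fit of the same likelihood (no separation)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    days = rng.uniform(150, 210, 60)
    latent = days + rng.normal(0, 15, 60)
    modules = np.digitize(latent, [175, 195])
    fit = fit_multinomial(days, modules.tolist())

    X = sm.add_constant(days - days.mean())
    sm_fit = sm.MNLogit(modules, X).fit(disp=False)
    assert fit.ll_full == pytest.approx(sm_fit.llf, abs=1e-4)
    assert fit.lr_chi2 == pytest.approx(sm_fit.llr, abs=1e-3)
    assert np.allclose(fit.coefficients, sm_fit.params.T, atol=1e-3)


def test_model_validation():
    with pytest.raises(ValueError):
        ModuleMembershipModel([1.0, 2.0], [0, 0])  # single module
    with pytest.raises(ValueError):
        ModuleMembershipModel([1.0], [0, 1])  # length mismatch
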