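"""Score tests, covariance estimation and the max-type combination."""
import numpy as np
import pytest
from scipy import stats as sps

import snpsurv as sv
from snpsurv.maxtest import MODELS, _mc_pvalue, ScoreTestResult, SnpTestResult
from conftest import random_genotypes, random_survival


# ---------------------------------------------------------------------------
# genotype scoring
# ---------------------------------------------------------------------------
@pytest.mark.parametrize("g, model, expected", [
    ((0, 1, 2), sv.GeneticModel.DOMINANT, (0, 1, 1)),
    ((0, 1, 2), sv.GeneticModel.RECESSIVE, (0, 0, 1)),
    ((0, 0, 0), sv.GeneticModel.MULTIPLICATIVE, (0, 0, 0)),
    ((2, 1, 0, 1), sv.GeneticModel.MULTIPLICATIVE, (2, 1, 0, 1)),
])
def test_score_genotypes(g, model, expected):
    assert sv.score_genotypes(g, model).tolist() == list(expected)


@pytest.mark.parametrize("bad", [(0, 3), (-1, 1), (0, 1.5), (0, np.nan)])
def test_score_genotypes_rejects_invalid(bad):
    with pytest.raises(ValueError):
        sv.score_genotypes(bad, sv.GeneticModel.DOMINANT)


# ---------------------------------------------------------------------------
# Cox partial score statistic
# ---------------------------------------------------------------------------
def test_score_statistic_hand_worked():
    """Three subjects, all events, z = (1,0,0): only the first risk set
    contributes, giving W = 2/(3*sqrt(3)), var = 2/27, T = sqrt(2)."""
    surv = sv.SurvivalData([1.0, 2.0, 3.0], [1, 1, 1])
    res = sv.cox_score_statistic([1.0, 0.0, 0.0], surv)
    assert res.W == pytest.approx(2 / (3 * np.sqrt(3)), rel=1e-12)
    assert res.variance == pytest.approx(2 / 27, rel=1e-12)
    assert res.T == pytest.approx(np.sqrt(2), rel=1e-12)
    assert res.p_marginal == pytest.approx(2 * sps.norm.sf(np.sqrt(2)), rel=1e-12)


def test_score_equals_numeric_gradient_of_partial_loglik(rng):
    """sqrt(n) W is the score function of the Breslow partial likelihood
    at beta = 0 (checked by central differences)."""
    for _ in range(20):
        n = 30
        z = rng.standard_normal(n)
        surv = random_survival(rng, n)
        res = sv.cox_score_statistic(z, surv)
        h = 1e-5
        num = (sv.partial_loglik([h], z[:, None], surv)
               - sv.partial_loglik([-h], z[:, None], surv)) / (2 * h)
        assert np.sqrt(n) * res.W == pytest.approx(num, rel=1e-6)


def test_score_statistic_matches_statsmodels(rng):
    """W and the score test statistic agree with an independent Cox
    implementation (statsmodels PHReg, Breslow ties)."""
    sm = pytest.importorskip("statsmodels.api")
    for _ in range(5):
        n = 50
        z = rng.standard_normal(n)
        surv = random_survival(rng, n)
        res = sv.cox_score_statistic(z, surv)
        model = sm.PHReg(surv.times, z[:, None], status=surv.events,
                         ties="breslow")
        score = model.score(np.zeros(1))[0]
        info = -model.hessian(np.zeros(1))[0, 0]
        assert np.sqrt(n) * res.W == pytest.approx(score, rel=1e-10)
        assert res.T**2 == pytest.approx(score**2 / info, rel=1e-10)


def test_affine_invariance_of_standardized_statistic(rng):
    """Replacing scores c_g by a + b*c_g (b > 0) leaves T unchanged."""
    n = 80
    g = rng.choice(3, size=n)
    surv = random_survival(rng, n)
    for model in MODELS:
        z = sv.score_genotypes(g, model)
        base = sv.cox_score_statistic(z, surv)
        trans = sv.cox_score_statistic(1.7 + 2.5 * z, surv)
        assert trans.T == pytest.approx(base.T, abs=1e-12)


def test_constant_covariate_is_degenerate(rng):
    surv = random_survival(rng, 20)
    res = sv.cox_score_statistic(np.ones(20), surv)
    assert res.degenerate
    assert res.W == pytest.approx(0.0, abs=1e-12)
    assert res.variance == pytest.approx(0.0, abs=1e-12)
    assert res.p_marginal == 1.0


def test_no_events_raises(rng):
    surv = sv.SurvivalData([1.0, 2.0, 3.0], [0, 0, 0])
    with pytest.raises(ValueError, match="no observed events"):
        sv.cox_score_statistic([0.0, 1.0, 2.0], surv)


# ---------------------------------------------------------------------------
# cross covariance
# ---------------------------------------------------------------------------
def test_cross_covariance_self_and_symmetry(rng):
    n = 60
    surv = random_survival(rng, n)
    za, zb = rng.standard_normal(n), rng.standard_normal(n)
    assert sv.cross_covariance(za, zb, surv) == pytest.approx(
        sv.cross_covariance(zb, za, surv), rel=1e-12)
    self_cov = sv.cross_covariance(za, za, surv)
    assert self_cov == pytest.approx(
        sv.cox_score_statistic(za, surv).variance, rel=1e-12)


def test_estimated_correlations_are_bounded(rng):
    for _ in range(200):
        n = 40
        surv = random_survival(rng, n)
        za, zb = rng.standard_normal(n), rng.standard_normal(n)
        cov = sv.cross_covariance(za, zb, surv)
        va = sv.cross_covariance(za, za, surv)
        vb = sv.cross_covariance(zb, zb, surv)
        assert abs(cov) <= np.sqrt(va * vb) * (1 + 1e-10)


def test_covariance_estimator_matches_monte_carlo(rng):
    """Mean estimated correlation of two scorings agrees with the
    empirical correlation of their score statistics under the null."""
    n, reps = 200, 2000
    surv = random_survival(rng, n)
    G = rng.choice(3, size=(n, reps), p=[0.25, 0.5, 0.25])
    geno = sv.GenotypeMatrix(G.astype(np.int8), [f"S{i}" for i in range(n)],
                             [f"R{j}" for j in range(reps)])
    from snpsurv._cox import RiskSetCache
    cache = RiskSetCache(surv)
    Gs = geno.values[cache.order].astype(int)
    Z = {m: np.asarray(m.scores, float)[Gs] for m in MODELS}
    stats = {m: cache.null_moments(Z[m]) for m in MODELS}
    for a, b in [(MODELS[0], MODELS[1]), (MODELS[0], MODELS[2]),
                 (MODELS[1], MODELS[2])]:
        rho_hat = cache.null_cross(Z[a], Z[b]) / np.sqrt(
            stats[a][1] * stats[b][1])
        emp = np.corrcoef(stats[a][0], stats[b][0])[0, 1]
        assert abs(rho_hat.mean() - emp) < 0.05


def test_marginal_statistics_are_standard_normal_under_null(rng):
    """Kolmogorov-Smirnov on 5000 null replicates per model at the 0.001
    level."""
    n, reps = 150, 5000
    surv = random_survival(rng, n)
    G = rng.choice(3, size=(n, reps), p=[0.25, 0.5, 0.25])
    from snpsurv._cox import RiskSetCache
    cache = RiskSetCache(surv)
    Gs = G[cache.order]
    for model in MODELS:
        W, var = cache.null_moments(np.asarray(model.scores, float)[Gs])
        T = W / np.sqrt(var)
        assert sps.kstest(T, "norm").pvalue > 0.001


# ---------------------------------------------------------------------------
# max-type combination
# ---------------------------------------------------------------------------
def test_mc_pvalue_identity_closed_form():
    """With an identity correlation the max of three independent normals
    has P(Q >= q) = 1 - (2 Phi(q) - 1)^3."""
    B = 200_000
    for q in (1.0, 2.0, 2.5):
        p = _mc_pvalue(q, np.eye(3), B, np.random.default_rng(5))
        exact = 1 - (2 * sps.norm.cdf(q) - 1) ** 3
        assert abs(p - exact) < 4 * np.sqrt(exact * (1 - exact) / B) + 2 / B


def test_mc_pvalue_zero_statistic_is_one():
    assert _mc_pvalue(0.0, np.eye(3), 2000, np.random.default_rng(0)) == 1.0


def test_pmax_monotone_in_observed_statistic():
    corr = np.array([[1, .5, .3], [.5, 1, .6], [.3, .6, 1.0]])
    ps = [_mc_pvalue(q, corr, 5000, np.random.default_rng(11))
          for q in np.linspace(0, 4, 15)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_maxtest_reproducible_and_sandwich_bound(rng):
    """Same seed gives identical results; p_max lies between the smallest
    marginal p-value and three times it, within Monte-Carlo error."""
    config = sv.SimulationConfig(m=60, n=150, beta=0.8, seed=77)
    geno, surv = sv.generate_dataset(config)
    B = 4000
    res1 = sv.maxtest_all(geno, surv, B=B, seed=3)
    res2 = sv.maxtest_all(geno, surv, B=B, seed=3)
    for r1, r2 in zip(res1, res2):
        assert r1.p_max == r2.p_max and r1.Q == r2.Q
    for r in res1:
        if r.degenerate:
            continue
        pmin = min(st.p_marginal for st in r.stats if not st.degenerate)
        eps = 4 * np.sqrt(max(r.p_max, 1 / B) * (1 - min(r.p_max, 1 - 1e-9)) / B)
        assert r.p_max >= pmin - eps - 1 / B
        assert r.p_max <= 3 * pmin + eps + 1 / B


def test_monomorphic_snp_degenerate():
    surv = sv.SurvivalData(np.arange(1.0, 13.0), np.ones(12, int))
    res = sv.maxtest(np.zeros(12, int), surv, B=1500, rng_seed=0)
    assert res.degenerate and res.p_max == 1.0 and res.chosen_model is None


def test_model_without_carriers_is_dropped(rng):
    """No BB carriers make the recessive scoring constant: that model is
    excluded from the max and the correlation matrix shrinks to 2x2."""
    n = 40
    g = rng.choice(2, size=n)  # only AA / AB
    g[:5] = 1
    surv = random_survival(rng, n)
    res = sv.maxtest(g, surv, B=1500, rng_seed=1)
    assert res.stats[0].degenerate
    assert res.kept == (1, 2)
    assert res.correlation.shape == (2, 2)
    assert not res.degenerate
    # dominant and multiplicative scorings coincide without BB carriers
    assert res.stats[1].T == pytest.approx(res.stats[2].T, abs=1e-10)


def _fake_result(t_abs):
    stats = tuple(
        ScoreTestResult(W=t, variance=1.0, T=t,
                        p_marginal=float(2 * sps.norm.sf(abs(t))),
                        degenerate=False)
        for t in t_abs)
    return SnpTestResult(snp_id="x", stats=stats, kept=(0, 1, 2),
                         correlation=np.eye(3), Q=max(map(abs, t_abs)),
                         p_max=0.5, chosen_model=None, degenerate=False)


def test_identify_model_argmax_and_tie_order():
    assert sv.identify_model(_fake_result((3.1, 2.0, 2.9))) \
        is sv.GeneticModel.RECESSIVE
    assert sv.identify_model(_fake_result((2.0, 2.0, 1.0))) \
        is sv.GeneticModel.RECESSIVE
    assert sv.identify_model(_fake_result((-2.0, 1.0, 2.1))) \
        is sv.GeneticModel.MULTIPLICATIVE


def test_identify_model_degenerate_errors():
    res = SnpTestResult(snp_id="x", stats=(), kept=(), correlation=None,
                        Q=np.nan, p_max=1.0, chosen_model=None, degenerate=True)
    with pytest.raises(ValueError):
        sv.identify_model(res)


# ---------------------------------------------------------------------------
# quadratic-form companion test
# ---------------------------------------------------------------------------
def test_quadratic_form_cases(rng):
    res = sv.quadratic_test((0.0, 0.0, 0.0), np.eye(3))
    assert res.W2 == pytest.approx(0.0, abs=1e-12) and res.p_value == 1.0
    res = sv.quadratic_test((1.0, 2.0, 2.0), np.eye(3))
    assert res.W2 == pytest.approx(9.0, rel=1e-12) and res.df == 3
    # the multiplicative scoring is the sum of the other two, so the
    # estimated correlation is always singular with rank 2 and the
    # quadratic form falls back to the generalized inverse
    geno, surv = sv.generate_dataset(
        sv.SimulationConfig(m=5, n=100, n_prognostic=3, seed=9))
    r = sv.maxtest(geno.values[:, 0], surv, B=1200, rng_seed=0)
    assert np.linalg.matrix_rank(r.correlation) == 2
    S = np.array([st.T for st in r.stats])
    expected = S @ np.linalg.pinv(r.correlation, hermitian=True) @ S
    out = sv.quadratic_test(r.stats, r.correlation)
    assert out.df == 2
    assert out.W2 == pytest.approx(expected, rel=1e-8)
    assert out.W2 >= -1e-10


def test_score_statistics_linearly_dependent(rng):
    """W_mult = W_rec + W_dom exactly: the multiplicative score triple is
    the sum of the recessive and dominant triples and W is linear in z."""
    n = 70
    g = rng.choice(3, size=n)
    surv = random_survival(rng, n)
    w = {m: sv.cox_score_statistic(sv.score_genotypes(g, m), surv).W
         for m in MODELS}
    assert w[sv.GeneticModel.MULTIPLICATIVE] == pytest.approx(
        w[sv.GeneticModel.RECESSIVE] + w[sv.GeneticModel.DOMINANT], rel=1e-10)


def test_results_table_columns(rng):
    geno, surv = sv.generate_dataset(sv.SimulationConfig(m=8, n=60, seed=4))
    tab = sv.results_table(sv.maxtest_all(geno, surv, B=1200, seed=0))
    assert list(tab.columns) == [
        "snp_id", "T_rec", "T_dom", "T_mult", "p_rec", "p_dom", "p_mult",
        "Q", "p_max", "chosen_model", "degenerate_flag"]
    assert len(tab) == 8
    assert tab["p_max"].between(0, 1).all()
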