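"""Per-SNP association tests for right-censored traits under genetic-model
uncertainty.

For an SNP with B-allele count g in {0, 1, 2} and a candidate genetic model
with score triple (c0, c1, c2), the covariate z_i = c_{g_i} enters the Cox
partial score test of beta = 0. Three candidate models are considered:
recessive (0,0,1), dominant (0,1,1) and multiplicative (0,1,2). The
max-type statistic Q = max(|T_1|, |T_2|, |T_3|) of the three standardized
score statistics is referred to its simulated null: the three statistics
are jointly asymptotically normal under H0 with a correlation matrix that
is estimated from the risk sets, and the p-value of Q is approximated by
Monte Carlo draws from that trivariate normal. This controls the type-I
error that a naive "take the smallest of three p-values" rule would
inflate, while adapting the test to the unknown true genetic model.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._cox import RiskSetCache
from .data import GenotypeMatrix, SurvivalData

__all__ = [
    "GeneticModel",
    "MODELS",
    "ScoreTestResult",
    "SnpTestResult",
    "QuadraticTestResult",
    "score_genotypes",
    "cox_score_statistic",
    "cross_covariance",
    "maxtest",
    "maxtest_all",
    "model_score_tests",
    "quadratic_test",
    "identify_model",
    "results_table",
]

#: Variance below this is treated as a degenerate (constant) scoring.
_VAR_TOL = 1e-12


class GeneticModel(enum.Enum):
    """Candidate genetic model with its genotype score triple (c0, c1, c2)."""

    RECESSIVE = (0, 0, 1)
    DOMINANT = (0, 1, 1)
    MULTIPLICATIVE = (0, 1, 2)

    @property
    def scores(self) -> tuple:
        return self.value

    @property
    def label(self) -> str:
        return self.name.lower()


#: Fixed model order; also the tie-break order for model identification.
MODELS = (GeneticModel.RECESSIVE, GeneticModel.DOMINANT, GeneticModel.MULTIPLICATIVE)


def score_genotypes(g, model: GeneticModel) -> np.ndarray:
    """Map B-allele counts to the model's genotype scores.

    Entries outside {0, 1, 2} (including missing-data sentinels) are
    rejected; missing genotypes must be handled upstream.
    """
    g = np.asarray(g)
    if g.size and not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must take values in {0, 1, 2}")
    return np.asarray(model.scores, dtype=float)[g.astype(int)]


@dataclass
class ScoreTestResult:
    """Cox partial score test of one scoring of one SNP.

    ``W`` is the normalized partial score statistic, ``variance`` its
    estimated null variance, ``T = W / sqrt(variance)`` the standardized
    statistic and ``p_marginal = 2 (1 - Phi(|T|))`` its two-sided normal
    p-value. A constant scoring (variance 0) is flagged ``degenerate``
    with ``T = nan`` and ``p_marginal = 1``.
    """

    W: float
    variance: float
    T: float
    p_marginal: float
    degenerate: bool


@dataclass
class SnpTestResult:
    """Joint three-model test of one SNP.

    ``stats`` holds the per-model :class:`ScoreTestResult` in the fixed
    order recessive, dominant, multiplicative. ``kept`` lists the indices
    of non-degenerate models; ``correlation`` is the estimated null
    correlation matrix of their standardized statistics, ``Q`` the maximum
    absolute standardized statistic, and ``p_max`` its Monte-Carlo p-value
    (add-one estimator, so ``p_max`` is in ``[1/(B+1), 1]``).
    """

    snp_id: str
    stats: tuple
    kept: tuple
    correlation: Optional[np.ndarray]
    Q: float
    p_max: float
    chosen_model: Optional[GeneticModel]
    degenerate: bool


@dataclass
class QuadraticTestResult:
    """Quadratic-form combination ``W2 = S^T Sigma^{-1} S`` of the three
    standardized statistics; a diagnostic companion to the max statistic."""

    W2: float
    df: int
    p_value: float


def cox_score_statistic(z, surv: SurvivalData) -> ScoreTestResult:
    """Cox partial score test of no association between z and survival.

    ``W`` equals ``n^{-1/2}`` times the gradient of the Breslow partial
    log-likelihood at beta = 0; the variance estimator accumulates the
    risk-set variance of z at each event time.
    """
    z = np.asarray(z, dtype=float)
    cache = RiskSetCache(surv)
    W, var = cache.null_moments(cache.sort_rows(z)[:, None])
    return _score_result(float(W[0]), float(var[0]))


def _score_result(W: float, var: float) -> ScoreTestResult:
    if var <= _VAR_TOL:
        return ScoreTestResult(W=W, variance=max(var, 0.0), T=np.nan,
                               p_marginal=1.0, degenerate=True)
    T = W / np.sqrt(var)
    return ScoreTestResult(W=W, variance=var, T=T,
                           p_marginal=float(2.0 * sps.norm.sf(abs(T))),
                           degenerate=False)


def cross_covariance(z_l, z_lp, surv: SurvivalData) -> float:
    """Estimated null covariance of the score statistics of two scorings."""
    cache = RiskSetCache(surv)
    za = cache.sort_rows(np.asarray(z_l, dtype=float))[:, None]
    zb = cache.sort_rows(np.asarray(z_lp, dtype=float))[:, None]
    return float(cache.null_cross(za, zb)[0])


def _safe_cholesky(corr: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(8):
        try:
            return np.linalg.cholesky(corr + jitter * np.eye(corr.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
    raise np.linalg.LinAlgError("correlation matrix is not positive semidefinite")


def _mc_pvalue(q: float, corr: np.ndarray, B: int, rng: np.random.Generator) -> float:
    """Monte-Carlo p-value of the max statistic under N(0, corr).

    Uses the add-one estimator ``(1 + #{q_b >= q}) / (B + 1)``, which never
    returns 0 and differs from the plain proportion by at most 1/B.
    """
    L = _safe_cholesky(np.asarray(corr, dtype=float))
    draws = rng.standard_normal((B, corr.shape[0])) @ L.T
    q_b = np.abs(draws).max(axis=1)
    return float((1.0 + np.count_nonzero(q_b >= q)) / (B + 1.0))


def _assemble_snp(snp_id, W3, V3, Sigma, B, rng) -> SnpTestResult:
    stats = tuple(_score_result(float(W3[l]), float(V3[l])) for l in range(3))
    kept = tuple(l for l in range(3) if not stats[l].degenerate)
    if not kept:
        return SnpTestResult(snp_id=snp_id, stats=stats, kept=(),
                             correlation=None, Q=np.nan, p_max=1.0,
                             chosen_model=None, degenerate=True)
    sub = Sigma[np.ix_(kept, kept)]
    sd = np.sqrt(np.diag(sub))
    corr = sub / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    T_abs = np.array([abs(stats[l].T) for l in kept])
    Q = float(T_abs.max())
    p_max = _mc_pvalue(Q, corr, B, rng)
    chosen = _argmax_model(stats)
    return SnpTestResult(snp_id=snp_id, stats=stats, kept=kept,
                         correlation=corr, Q=Q, p_max=p_max,
                         chosen_model=chosen, degenerate=False)


def _argmax_model(stats: Sequence[ScoreTestResult]) -> GeneticModel:
    best, best_t = None, -np.inf
    for model, st in zip(MODELS, stats):
        if st.degenerate:
            continue
        if abs(st.T) > best_t:  # strict: ties keep the earlier model
            best, best_t = model, abs(st.T)
    if best is None:
        raise ValueError("all genetic models are degenerate for this SNP")
    return best


def maxtest(genotype, surv: SurvivalData, B: int = 100_000,
            rng_seed: int = 0, snp_id: str = "snp") -> SnpTestResult:
    """Max-type three-model association test for a single SNP.

    A model whose scoring is constant on the sample (e.g. recessive with no
    BB carriers) has an undefined statistic and is dropped from the max and
    from the null correlation matrix; a monomorphic SNP yields a degenerate
    result with ``p_max = 1``.
    """
    if B < 1:
        raise ValueError("B must be a positive number of Monte-Carlo draws")
    g = np.asarray(genotype)
    if g.size and not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must take values in {0, 1, 2}")
    cache = RiskSetCache(surv)
    g_sorted = g[cache.order].astype(int)
    W3, V3, Sigma = _model_moments(cache, g_sorted[:, None])
    rng = np.random.default_rng(rng_seed)
    return _assemble_snp(snp_id, W3[:, 0], V3[:, 0], Sigma[..., 0], B, rng)


def _model_moments(cache: RiskSetCache, G_sorted: np.ndarray):
    """W, variance and 3x3 covariance for every SNP column at once."""
    Zs = [np.asarray(m.scores, dtype=float)[G_sorted] for m in MODELS]
    m = G_sorted.shape[1]
    W = np.empty((3, m))
    V = np.empty((3, m))
    Sigma = np.empty((3, 3, m))
    for l in range(3):
        W[l], V[l] = cache.null_moments(Zs[l])
        Sigma[l, l] = V[l]
    for a, b in ((0, 1), (0, 2), (1, 2)):
        cov = cache.null_cross(Zs[a], Zs[b])
        Sigma[a, b] = Sigma[b, a] = cov
    return W, V, Sigma


def maxtest_all(genotypes: GenotypeMatrix, surv: SurvivalData,
                B: int = 100_000, seed: int = 0) -> list:
    """Run the max-type test on every SNP of a genotype matrix.

    The Monte-Carlo null of SNP ``j`` is seeded with ``seed + j`` so that
    results are reproducible independently of evaluation order.
    """
    if B < 1:
        raise ValueError("B must be a positive number of Monte-Carlo draws")
    cache = RiskSetCache(surv)
    G_sorted = genotypes.values[cache.order].astype(int)
    W, V, Sigma = _model_moments(cache, G_sorted)
    results = []
    for j, snp_id in enumerate(genotypes.snp_ids):
        rng = np.random.default_rng(seed + j)
        results.append(_assemble_snp(snp_id, W[:, j], V[:, j], Sigma[..., j], B, rng))
    return results


def model_score_tests(genotypes: GenotypeMatrix, surv: SurvivalData,
                      model: GeneticModel):
    """Marginal score tests of every SNP under one fixed genetic model.

    Returns arrays (W, variance, T, p) over SNPs; degenerate scorings have
    ``T = nan`` and ``p = 1``. This is the screening statistic of the
    single-model comparison methods.
    """
    cache = RiskSetCache(surv)
    Zs = np.asarray(model.scores, dtype=float)[genotypes.values[cache.order].astype(int)]
    W, var = cache.null_moments(Zs)
    ok = var > _VAR_TOL
    T = np.full(W.shape, np.nan)
    T[ok] = W[ok] / np.sqrt(var[ok])
    p = np.ones(W.shape)
    p[ok] = 2.0 * sps.norm.sf(np.abs(T[ok]))
    return W, var, T, p


def quadratic_test(stats, correlation) -> QuadraticTestResult:
    """Quadratic-form test ``W2 = S^T Sigma^{-1} S`` with S = (T1, T2, T3).

    Referred to a chi-square with df equal to the numerical rank of the
    correlation matrix (generalized inverse when singular). Exposed as a
    diagnostic; the max statistic is the primary test.
    """
    S = np.asarray([st.T if isinstance(st, ScoreTestResult) else st for st in stats],
                   dtype=float)
    Sigma = np.asarray(correlation, dtype=float)
    df = int(np.linalg.matrix_rank(Sigma))
    W2 = float(S @ np.linalg.pinv(Sigma, hermitian=True) @ S)
    return QuadraticTestResult(W2=W2, df=df, p_value=float(sps.chi2.sf(W2, df)))


def identify_model(result: SnpTestResult) -> GeneticModel:
    """Genetic model with the largest |T| (equivalently, lowest marginal
    p-value); ties break by the fixed order recessive < dominant <
    multiplicative."""
    if result.degenerate:
        raise ValueError(f"SNP {result.snp_id}: all models degenerate")
    return _argmax_model(result.stats)


def results_table(results: Sequence[SnpTestResult]) -> pd.DataFrame:
    """Flatten per-SNP results into the standard output table."""
    rows = []
    for r in results:
        rec, dom, mult = r.stats
        rows.append({
            "snp_id": r.snp_id,
            "T_rec": rec.T, "T_dom": dom.T, "T_mult": mult.T,
            "p_rec": rec.p_marginal, "p_dom": dom.p_marginal,
            "p_mult": mult.p_marginal,
            "Q": r.Q, "p_max": r.p_max,
            "chosen_model": r.chosen_model.label if r.chosen_model else "none",
            "degenerate_flag": int(r.degenerate),
        })
    return pd.DataFrame(rows)
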