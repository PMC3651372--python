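"""Synthetic GWAS-survival data generator.

Genotypes are produced by thresholding latent standard normals: for each
sample, x_1, ..., x_m follow an AR(1) process across SNPs (x_1 = eps_1,
x_j = rho x_{j-1} + sqrt(1 - rho^2) eps_j) so that neighboring SNPs are in
linkage disequilibrium while every x_j is marginally N(0, 1). Cutting x_j
at the normal quantiles of the cumulative genotype frequencies yields
B-allele counts with the requested (f1, f2, f3) distribution of AA/AB/BB.

Survival times follow a proportional-hazards model with a unit-exponential
baseline: Lambda(t) = t * exp(sum_j beta_j z_ij) over the D prognostic
SNPs, where z_ij is the score of SNP j's true genetic model (0/1 for
dominant and recessive carriers, allele count for multiplicative),
standardized by its population moments so that beta_j is a per-SD log
hazard ratio comparable across models. Censoring times are Uniform(0, tau)
with tau calibrated by root-finding so the expected censored fraction
matches the target. The default configuration reproduces the canonical
study conditions: m = 1000 SNPs, training sets of n = 200 samples, D = 6
prognostic SNPs with frequencies (.25, .5, .25) and effect size
beta = 0.8 - SNPs 1 and 4 dominant, 2 and 5 recessive, 3 and 6
multiplicative - remaining SNPs at (1/3, 1/3, 1/3), rho in {0, 0.3}, and
15% or 30% censoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .data import GenotypeMatrix, SurvivalData
from .maxtest import GeneticModel

__all__ = ["SimulationConfig", "generate_genotypes", "generate_survival",
           "generate_dataset", "calibrate_censoring"]

#: True-model pattern of the prognostic SNPs, repeated cyclically.
_MODEL_CYCLE = (GeneticModel.DOMINANT, GeneticModel.RECESSIVE,
                GeneticModel.MULTIPLICATIVE)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    ``n_prognostic`` (D) SNPs sit at the first D positions - adjacent, so a
    positive ``rho`` induces LD among them - with genotype frequencies
    ``prognostic_freqs`` and per-SNP log-hazard ratio ``beta``; the
    remaining SNPs carry no effect and use ``null_freqs``.
    """

    m: int = 1000
    n: int = 200
    n_prognostic: int = 6
    rho: float = 0.0
    beta: float = 0.8
    censoring: float = 0.30
    prognostic_freqs: tuple = (0.25, 0.5, 0.25)
    null_freqs: tuple = (1 / 3, 1 / 3, 1 / 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 2:
            raise ValueError("need m >= 1 SNPs and n >= 2 samples")
        if not 0 <= self.n_prognostic <= self.m:
            raise ValueError("n_prognostic must lie in [0, m]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.censoring < 1:
            raise ValueError("the target censoring fraction must lie in [0, 1)")
        for freqs in (self.prognostic_freqs, self.null_freqs):
            f = np.asarray(freqs, dtype=float)
            if f.shape != (3,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-12:
                raise ValueError("genotype frequencies must be 3 non-negative "
                                 "values summing to 1")

    @property
    def true_models(self) -> tuple:
        """Genetic model of each prognostic SNP (dominant, recessive,
        multiplicative, repeating)."""
        return tuple(_MODEL_CYCLE[j % 3] for j in range(self.n_prognostic))

    @property
    def snp_ids(self) -> tuple:
        width = max(4, len(str(self.m)))
        return tuple(f"SNP{j + 1:0{width}d}" for j in range(self.m))

    @property
    def prognostic_ids(self) -> tuple:
        return self.snp_ids[: self.n_prognostic]


def _latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """AR(1)-correlated latent standard normals, samples independent."""
    eps = rng.standard_normal((n, m))
    if rho == 0:
        return eps
    x = eps
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + scale * eps[:, j]
    return x


def _thresholds(config: SimulationConfig):
    D = config.n_prognostic
    f = np.tile(np.asarray(config.null_freqs, dtype=float), (config.m, 1))
    f[:D] = np.asarray(config.prognostic_freqs, dtype=float)
    c1 = sps.norm.ppf(f[:, 0])
    c2 = sps.norm.ppf(f[:, 0] + f[:, 1])
    return c1, c2


def generate_genotypes(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw an n x m genotype matrix under the latent-Gaussian model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = _latent(rng, config.n, config.m, config.rho)
    c1, c2 = _thresholds(config)
    g = (x >= c1).astype(np.int8) + (x >= c2).astype(np.int8)
    sample_ids = tuple(f"S{i + 1:05d}" for i in range(config.n))
    return GenotypeMatrix(g, sample_ids, config.snp_ids)


def _linear_predictor(G_prog: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Log hazard ratio per sample from the standardized true-model scores.

    Scores are centered and scaled by their population moments under the
    prognostic genotype frequencies, so ``beta`` acts per standard
    deviation of the model score regardless of the genetic model.
    """
    eta = np.zeros(G_prog.shape[0])
    f = np.asarray(config.prognostic_freqs, dtype=float)
    for j, model in enumerate(config.true_models):
        scores = np.asarray(model.scores, dtype=float)
        mu = float(f @ scores)
        sd = float(np.sqrt(f @ scores**2 - mu**2))
        if sd == 0:  # degenerate frequencies leave this SNP without effect
            continue
        eta += config.beta * (scores[G_prog[:, j].astype(int)] - mu) / sd
    return eta


def calibrate_censoring(config: SimulationConfig, n_draws: int = 100_000,
                        seed: Optional[int] = None) -> Optional[float]:
    """Upper bound tau of the Uniform(0, tau) censoring distribution.

    Solves ``E[min(T, tau)] / tau = target`` (the censored fraction under
    uniform censoring) by bisection on a Monte-Carlo sample of event
    times. Calibrated once per configuration and then held fixed across
    replicates. Returns None when the target is 0 (no censoring).
    """
    if config.censoring == 0:
        return None
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    D = config.n_prognostic
    if D > 0:
        x = _latent(rng, n_draws, D, config.rho)
        c1, c2 = _thresholds(config)
        g = (x >= c1[:D]).astype(np.int8) + (x >= c2[:D]).astype(np.int8)
        eta = _linear_predictor(g, config)
    else:
        eta = np.zeros(n_draws)
    T = rng.exponential(size=n_draws) * np.exp(-eta)

    def censored_fraction(tau: float) -> float:
        return float(np.minimum(T, tau).mean() / tau)

    hi = float(np.quantile(T, 0.99))
    while censored_fraction(hi) > config.censoring:
        hi *= 2.0
    return float(optimize.brentq(
        lambda tau: censored_fraction(tau) - config.censoring, 1e-9, hi,
        xtol=1e-10, rtol=1e-12))


def generate_survival(genotypes: GenotypeMatrix, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      tau: Optional[float] = None) -> SurvivalData:
    """Draw survival data from the proportional-hazards model.

    Event times use the inverse-CDF of the unit-exponential-baseline PHM;
    censoring times are Uniform(0, tau), with tau calibrated from the
    configuration when not supplied.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    D = config.n_prognostic
    eta = _linear_predictor(genotypes.values[:, :D], config)
    T = rng.exponential(size=config.n) * np.exp(-eta)
    if config.censoring == 0:
        return SurvivalData(T, np.ones(config.n, dtype=np.int8))
    if tau is None:
        tau = calibrate_censoring(config)
    C = rng.uniform(0.0, tau, size=config.n)
    return SurvivalData(np.minimum(T, C), (T <= C).astype(np.int8))


def generate_dataset(config: SimulationConfig, tau: Optional[float] = None):
    """Genotypes plus survival for one replicate; deterministic in
    ``config.seed`` (identical config and seed give bit-identical data)."""
    rng = np.random.default_rng(config.seed)
    genotypes = generate_genotypes(config, rng)
    survival = generate_survival(genotypes, config, rng, tau=tau)
    return genotypes, survival
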