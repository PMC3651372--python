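"""Screen -> identify -> standardize -> fit -> predict, plus evaluation.

The prediction procedure: (1) test every SNP with the max-type three-model
score test, (2) keep SNPs whose Monte-Carlo p-value is below the screening
level alpha, (3) score each kept SNP by the genetic model its largest
standardized statistic identifies, (4) standardize the scores (divisor-n
mean and SD, stored for later prediction), (5) fit the Cox model on the
standardized scores with the gradient lasso, choosing the L1 budget by
cross-validated partial likelihood, and (6) predict with the risk score
r_i = sum_k beta_k z'_ik. Evaluation dichotomizes risk scores at a median
cutoff and compares the high- and low-risk groups with a two-sample
log-rank test: the train/test-split protocol cuts at the test-set median,
the leave-one-out protocol at each fold's training-set median.

For comparison, ``method`` may name a single genetic model instead of
"maxtest": every SNP is then scored under that model and screened by its
marginal score-test p-value, with no model identification.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from lifelines.statistics import logrank_test as _lifelines_logrank

from .data import GenotypeMatrix, SurvivalData
from .gradlasso import DesignMatrix, gradient_lasso_fit, select_budget
from .maxtest import (GeneticModel, identify_model, maxtest_all,
                      model_score_tests, score_genotypes)
from .simulate import SimulationConfig, calibrate_censoring, generate_dataset

__all__ = [
    "PipelineConfig", "FittedModel", "RiskPrediction", "LoocvResult",
    "EmptySelectionError", "screen_snps", "build_design",
    "fit_prediction_model", "evaluate_split", "loocv", "recovery_rate",
    "simulation_study", "StudySummary",
]

#: Default grid of L1 budgets for cross-validation. Spans clearly
#: underfitting to clearly overfitting models for standardized covariates
#: with a handful of moderate effects.
DEFAULT_BUDGET_GRID = (0.25, 0.5, 1.0, 2.0, 3.0, 4.5, 7.0)


class EmptySelectionError(RuntimeError):
    """No SNP passed the screening threshold; the pipeline cannot fit."""


@dataclass
class PipelineConfig:
    """Settings of the prediction pipeline.

    ``method`` is "maxtest" (screen by the max-type test and identify the
    model per SNP) or one of "recessive"/"dominant"/"multiplicative"
    (score every SNP by that fixed model and screen by its marginal test).

    ``budget`` is the L1 budget of the lasso stage. The default of 1.0 -
    one unit of standardized log hazard ratio shared by all coefficients -
    keeps the fitted models parsimonious: because screening admits only
    SNPs that are already marginally significant on the same samples,
    likelihood-based budget selection (cross-validation or information
    criteria on the screened design) is biased toward large budgets that
    retain every screened SNP. Set ``budget=None`` to select the budget by
    cross-validated partial likelihood over ``budget_grid`` instead.
    """

    alpha: float = 0.01
    B: int = 100_000
    method: str = "maxtest"
    budget: Optional[float] = 1.0
    budget_grid: tuple = DEFAULT_BUDGET_GRID
    budget_rule: str = "1se"
    cv_folds: int = 5
    lasso_tol: float = 1e-6
    lasso_max_iter: int = 1000
    cv_tol: float = 1e-5
    cv_max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("the screening level alpha must lie in (0, 1)")
        valid = ("maxtest",) + tuple(m.label for m in GeneticModel)
        if self.method not in valid:
            raise ValueError(f"method must be one of {valid}")


@dataclass
class FittedModel:
    """A trained risk-score model, self-contained for scoring new samples.

    Stores, per design column: the SNP, its genetic-model scoring, the
    training standardization constants (divisor-n mean and SD) and the
    lasso coefficient. ``train_cutoff`` is the median training risk score
    (the LOOCV dichotomization threshold).
    """

    snp_ids: tuple
    model_labels: tuple
    centers: np.ndarray
    scales: np.ndarray
    beta: np.ndarray
    s: float
    loglik: float
    n_screened: int
    train_cutoff: float

    @property
    def active(self) -> np.ndarray:
        return np.nonzero(self.beta)[0]

    @property
    def active_ids(self) -> tuple:
        return tuple(self.snp_ids[j] for j in self.active)

    @property
    def n_selected(self) -> int:
        return int(self.active.size)

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Risk scores from the stored scorings and standardization
        constants; nothing is re-estimated on the new samples."""
        r = np.zeros(genotypes.n_samples)
        for j in self.active:
            model = GeneticModel[self.model_labels[j].upper()]
            z = score_genotypes(genotypes.column(self.snp_ids[j]), model)
            r += self.beta[j] * (z - self.centers[j]) / self.scales[j]
        return r

    def to_json(self) -> str:
        return json.dumps({
            "snps": [
                {"snp_id": sid, "model": lab, "center": c, "scale": sc, "beta": b}
                for sid, lab, c, sc, b in zip(
                    self.snp_ids, self.model_labels,
                    self.centers.tolist(), self.scales.tolist(),
                    self.beta.tolist())
            ],
            "s": self.s,
            "loglik": self.loglik,
            "n_screened": self.n_screened,
            "train_cutoff": self.train_cutoff,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        snps = d["snps"]
        return cls(
            snp_ids=tuple(e["snp_id"] for e in snps),
            model_labels=tuple(e["model"] for e in snps),
            centers=np.array([e["center"] for e in snps], dtype=float),
            scales=np.array([e["scale"] for e in snps], dtype=float),
            beta=np.array([e["beta"] for e in snps], dtype=float),
            s=float(d["s"]), loglik=float(d["loglik"]),
            n_screened=int(d["n_screened"]),
            train_cutoff=float(d["train_cutoff"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class RiskPrediction:
    """Dichotomized risk scores and the two-group log-rank comparison."""

    risk_scores: np.ndarray
    cutoff: float
    groups: np.ndarray  # True = high risk
    logrank_p: float
    degenerate: bool
    model: Optional[FittedModel] = None


@dataclass
class LoocvResult:
    """Leave-one-out evaluation: per-sample assignments and the pooled
    log-rank comparison, plus per-SNP inclusion counts across folds."""

    risk_scores: np.ndarray
    groups: np.ndarray
    logrank_p: float
    inclusion_counts: dict
    n_empty_folds: int
    degenerate: bool


@dataclass
class StudySummary:
    """Replicate-averaged operating characteristics of one scenario."""

    mean_selected: float
    mean_prognostic: float
    recovery: float
    mean_logrank_p: float
    selected_counts: np.ndarray
    prognostic_counts: np.ndarray
    logrank_ps: np.ndarray
    n_replicates: int


def screen_snps(results, alpha: float) -> list:
    """SNP ids with max-test p-value below alpha, in input order."""
    return [r.snp_id for r in results
            if not r.degenerate and r.p_max < alpha]


def build_design(genotypes: GenotypeMatrix, selected_ids: Sequence[str],
                 models: dict):
    """Score the selected SNPs by their identified models and standardize.

    Returns ``(design, centers, scales)``; standardization uses divisor-n
    mean and SD, and the constants are what a fitted model reuses verbatim
    on new samples. Columns that are constant after scoring are dropped
    with a warning.
    """
    cols, centers, scales, kept = [], [], [], []
    for sid in selected_ids:
        z = score_genotypes(genotypes.column(sid), models[sid])
        c = z.mean()
        sd = z.std()  # divisor n
        if sd < 1e-12:
            warnings.warn(f"SNP {sid}: constant scores; column dropped")
            continue
        cols.append((z - c) / sd)
        centers.append(c)
        scales.append(sd)
        kept.append(sid)
    if not cols:
        raise EmptySelectionError("no usable columns after scoring")
    design = DesignMatrix(np.column_stack(cols), tuple(kept))
    return design, np.asarray(centers), np.asarray(scales)


def fit_prediction_model(genotypes: GenotypeMatrix, surv: SurvivalData,
                         config: PipelineConfig) -> FittedModel:
    """Run the screening, model-identification and lasso stages."""
    if config.method == "maxtest":
        results = maxtest_all(genotypes, surv, B=config.B, seed=config.seed)
        selected = screen_snps(results, config.alpha)
        models = {r.snp_id: identify_model(r) for r in results
                  if not r.degenerate and r.p_max < config.alpha}
    else:
        model = GeneticModel[config.method.upper()]
        _, _, _, p = model_score_tests(genotypes, surv, model)
        selected = [sid for sid, pj in zip(genotypes.snp_ids, p)
                    if pj < config.alpha]
        models = {sid: model for sid in selected}
    if not selected:
        raise EmptySelectionError(
            f"no SNP passed screening at alpha={config.alpha}; "
            f"consider raising alpha")
    design, centers, scales = build_design(genotypes, selected, models)
    if config.budget is not None:
        s = float(config.budget)
    else:
        s = select_budget(design, surv, config.budget_grid, k=config.cv_folds,
                          seed=config.seed, rule=config.budget_rule,
                          tol=config.cv_tol, max_iter=config.cv_max_iter)
    fit = gradient_lasso_fit(design, surv, s, tol=config.lasso_tol,
                             max_iter=config.lasso_max_iter)
    risk_train = design.values @ fit.beta
    labels = tuple(models[sid].label for sid in design.column_ids)
    return FittedModel(snp_ids=design.column_ids, model_labels=labels,
                       centers=centers, scales=scales, beta=fit.beta,
                       s=fit.s, loglik=fit.loglik,
                       n_screened=len(selected),
                       train_cutoff=float(np.median(risk_train)))


def _logrank(surv: SurvivalData, high: np.ndarray) -> float:
    """Two-sided two-sample log-rank p-value (hypergeometric variance,
    chi-square(1) reference)."""
    res = _lifelines_logrank(
        surv.times[high], surv.times[~high],
        event_observed_A=surv.events[high],
        event_observed_B=surv.events[~high])
    return float(res.p_value)


def _dichotomize(surv: SurvivalData, r: np.ndarray, cutoff: float):
    """Median split (scores at the cutoff go low-risk) and log-rank test."""
    high = r > cutoff
    if high.all() or not high.any():
        return high, 1.0, True
    return high, _logrank(surv, high), False


def evaluate_split(train_geno: GenotypeMatrix, train_surv: SurvivalData,
                   test_geno: GenotypeMatrix, test_surv: SurvivalData,
                   config: PipelineConfig,
                   cutoff_from: str = "test") -> RiskPrediction:
    """Fit on the training samples, dichotomize the held-out samples.

    ``cutoff_from="test"`` uses the median test-set risk score as the
    cutoff (the simulation-study protocol); ``"train"`` uses the stored
    training median. All estimation happens on the training data only.
    """
    model = fit_prediction_model(train_geno, train_surv, config)
    r = model.predict(test_geno)
    cutoff = float(np.median(r)) if cutoff_from == "test" else model.train_cutoff
    high, p, degenerate = _dichotomize(test_surv, r, cutoff)
    return RiskPrediction(risk_scores=r, cutoff=cutoff, groups=high,
                          logrank_p=p, degenerate=degenerate, model=model)


def loocv(genotypes: GenotypeMatrix, surv: SurvivalData,
          config: PipelineConfig) -> LoocvResult:
    """Leave-one-out evaluation of the whole pipeline.

    Every fold re-runs screening, model identification, budget selection
    and the lasso on the n-1 remaining samples; the held-out sample is
    assigned high/low risk by the fold's training-median cutoff. Folds in
    which no SNP passes screening assign their sample risk score 0 (low
    risk) and are counted in ``n_empty_folds``.
    """
    n = genotypes.n_samples
    if n < 10:
        raise ValueError("leave-one-out evaluation needs at least 10 samples")
    risk = np.zeros(n)
    high = np.zeros(n, dtype=bool)
    inclusion: dict = {}
    n_empty = 0
    all_idx = np.arange(n)
    for i in range(n):
        rest = all_idx[all_idx != i]
        cfg_i = replace(config, seed=config.seed + i * (genotypes.n_snps + 1))
        try:
            model = fit_prediction_model(genotypes.subset_samples(rest),
                                         surv.subset(rest), cfg_i)
        except EmptySelectionError:
            n_empty += 1
            risk[i] = 0.0
            high[i] = False
            continue
        for sid in model.active_ids:
            inclusion[sid] = inclusion.get(sid, 0) + 1
        r_i = model.predict(genotypes.subset_samples([i]))[0]
        risk[i] = r_i
        high[i] = r_i > model.train_cutoff
    if high.all() or not high.any():
        p, degenerate = 1.0, True
    else:
        p, degenerate = _logrank(surv, high), False
    return LoocvResult(risk_scores=risk, groups=high, logrank_p=p,
                       inclusion_counts=inclusion, n_empty_folds=n_empty,
                       degenerate=degenerate)


def recovery_rate(selected_sets: Sequence[Sequence[str]],
                  true_prognostic: Sequence[str]) -> float:
    """Mean number of truly prognostic SNPs in the fitted models divided
    by the mean number of SNPs in the fitted models, across replicates."""
    truth = set(true_prognostic)
    sel = np.array([len(s) for s in selected_sets], dtype=float)
    prog = np.array([len(truth.intersection(s)) for s in selected_sets],
                    dtype=float)
    if sel.sum() == 0:
        raise ValueError("no SNPs selected in any replicate; "
                         "recovery rate undefined")
    return float(prog.mean() / sel.mean())


def simulation_study(sim_config: SimulationConfig, pipe_config: PipelineConfig,
                     n_replicates: int, seed: int = 0) -> StudySummary:
    """Replicate the train/test-split evaluation protocol.

    ``sim_config.n`` is the training-set size: each replicate generates
    ``2 n`` samples, trains the pipeline on the first ``n`` and evaluates
    on the remaining ``n`` (generation order is exchangeable, so the fixed
    split is unbiased). The censoring bound tau is calibrated once and
    shared by all replicates.
    """
    base = np.random.default_rng(seed)
    span = 10 * (sim_config.m + sim_config.n) + 1000
    tau = calibrate_censoring(sim_config, seed=int(base.integers(2**31 - 1)))
    sel_counts, prog_counts, ps, sel_sets = [], [], [], []
    truth = sim_config.prognostic_ids
    for _ in range(n_replicates):
        rep_seed = int(base.integers(2**31 - span))
        pipe_seed = int(base.integers(2**31 - span))
        sim_i = replace(sim_config, n=2 * sim_config.n, seed=rep_seed)
        geno, surv = generate_dataset(sim_i, tau=tau)
        train = np.arange(sim_config.n)
        test = np.arange(sim_config.n, 2 * sim_config.n)
        pred = evaluate_split(geno.subset_samples(train), surv.subset(train),
                              geno.subset_samples(test), surv.subset(test),
                              replace(pipe_config, seed=pipe_seed))
        active = pred.model.active_ids
        sel_sets.append(active)
        sel_counts.append(len(active))
        prog_counts.append(len(set(truth).intersection(active)))
        ps.append(pred.logrank_p)
    sel_counts = np.asarray(sel_counts, dtype=float)
    prog_counts = np.asarray(prog_counts, dtype=float)
    ps = np.asarray(ps, dtype=float)
    return StudySummary(
        mean_selected=float(sel_counts.mean()),
        mean_prognostic=float(prog_counts.mean()),
        recovery=recovery_rate(sel_sets, truth),
        mean_logrank_p=float(ps.mean()),
        selected_counts=sel_counts, prognostic_counts=prog_counts,
        logrank_ps=ps, n_replicates=n_replicates)
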