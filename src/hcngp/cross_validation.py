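"""Repeated k-fold cross-validation of the genomic prediction models.

With k = 5 folds and 5 repeats the harness produces 25 (rep, fold) cells.
Every model in a run is evaluated on the SAME fold plan, so comparisons are
paired. Per cell and model the harness records

* predictive ability r_a — the Pearson correlation between validation-set
  BLUEs and predictions;
* h²_val — narrow-sense heritability estimated on the validation clones
  alone, by MCMC variance partitioning (scaled-inverse-chi-square priors) on
  the VanRaden-G kernel model for ALL models, so accuracies share one
  denominator;
* accuracy = r_a / sqrt(h²_val).

Negative accuracies arise only from negative r_a (sampled variance
components are positive, so h²_val > 0). A fold whose predictions have zero
variance yields an undefined r_a, recorded as missing with a warning; a
fold whose validation h² collapses below 0.01 is flagged unstable and its
accuracy (not its r_a) is recorded as missing, since dividing by a
near-zero square root turns the cell into noise. The run always continues.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .bayes_mcmc import FAMILIES, PriorSpec, fit_bayes, predict_bayes
from .gblup import fit_gblup, predict_gebv
from .grm_kinship import RelationshipMatrix, vanraden_grm
from .io_config import (GenotypeTable, HcngpError, McmcConfig, RkhsConfig,
                        RunConfig, logger)
from .rkhs import KernelSpec, fit_rkhs, gaussian_kernel, predict_rkhs
from .snp_qc import CenteredGenotypes, impute_and_center, match_geno_pheno

ALL_MODELS = ("gblup",) + FAMILIES + ("rkhs",)
MIN_VALIDATION_CLONES = 5
#: validation h2 at or below this is flagged unstable (accuracy undefined)
H2_VAL_FLOOR = 0.01


@dataclass
class FoldPlan:
    """Deterministic repeated partition of n clones into k folds."""
    n: int
    k: int
    reps: int
    seed: int
    assignment: np.ndarray        # (reps, n) fold index per clone

    def fold_members(self, rep: int, fold: int) -> np.ndarray:
        return np.nonzero(self.assignment[rep] == fold)[0]

    def plan_hash(self) -> str:
        return hashlib.sha1(self.assignment.tobytes()).hexdigest()[:12]


def make_folds(n: int, k: int = 5, reps: int = 5, seed: int = 0) -> FoldPlan:
    """Uniform random fold assignment, fresh per repeat; fold sizes differ
    by at most one."""
    if n < k:
        raise HcngpError(f"cannot split {n} clones into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty((reps, n), dtype=np.int64)
    base = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    for r in range(reps):
        assignment[r] = base[rng.permutation(n)]
    return FoldPlan(n=n, k=k, reps=reps, seed=seed, assignment=assignment)


def validation_h2(y_val: pd.Series, K_val: RelationshipMatrix,
                  mcmc: McmcConfig, seed: int = 0) -> float:
    """Validation-set narrow-sense h² by MCMC on the G-kernel model.

    Phenotypic variance is partitioned into a genetic part (covariance K)
    and a residual; the returned value is the posterior mean of
    sigma²_a / (sigma²_a + sigma²_e) after burn-in. Both variances get the
    Jeffreys limit of the scaled-inverse-chi-square prior (df = 0, scale =
    0): a validation fold is small, and any informative scale would pin the
    estimate rather than let the data speak.
    """
    if len(y_val) < MIN_VALIDATION_CLONES:
        raise HcngpError(
            f"need >= {MIN_VALIDATION_CLONES} validation clones, got {len(y_val)}")
    fit = fit_rkhs(y_val, K_val, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                   seed=seed, df0=0.0, s0=0.0, df_u=0.0, s_u=0.0)
    h2 = float(fit.h2)
    if h2 <= 0.01:
        logger.warning("validation-set h2 = %.4f <= 0.01: accuracy unstable", h2)
    return h2


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def _fit_and_predict(model: str, y_train: pd.Series, val_ids: list[str],
                     cg: CenteredGenotypes, G: RelationshipMatrix,
                     Kg: RelationshipMatrix, mcmc: McmcConfig,
                     seed: int) -> pd.Series:
    train_ids = list(y_train.index)
    if model == "gblup":
        fit = fit_gblup(y_train, G)
        return predict_gebv(fit, G, val_ids)
    if model == "rkhs":
        fit = fit_rkhs(y_train, Kg, n_iter=mcmc.n_iter, burn_in=mcmc.burn_in,
                       seed=seed, df0=mcmc.df0, s0=mcmc.s0)
        return predict_rkhs(fit, Kg, val_ids)
    if model in FAMILIES:
        prior = PriorSpec(family=model, df0=mcmc.df0, s0=mcmc.s0)
        fit = fit_bayes(y_train.to_numpy(), cg.rows(train_ids), prior,
                        n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, seed=seed,
                        clone_ids=train_ids, marker_ids=cg.marker_ids)
        return predict_bayes(fit, cg.rows(val_ids), validation_ids=val_ids,
                             marker_ids=cg.marker_ids)
    raise HcngpError(f"unknown model {model!r}; choose from {ALL_MODELS}")


def evaluate_fold(model: str, y_train: pd.Series, y_val: pd.Series,
                  cg: CenteredGenotypes, G: RelationshipMatrix,
                  Kg: RelationshipMatrix, mcmc: McmcConfig, seed: int = 0,
                  h2_val: Optional[float] = None) -> tuple[float, float, float]:
    """Fit on the training clones, predict the validation clones, and return
    (r_a, h2_val, accuracy = r_a / sqrt(h2_val))."""
    if set(y_train.index) & set(y_val.index):
        raise HcngpError("training and validation clone sets overlap")
    val_ids = list(y_val.index)
    if h2_val is None:
        h2_val = validation_h2(y_val, G.restrict(val_ids), mcmc,
                               seed=_derive_seed(seed, 104729))
    pred = _fit_and_predict(model, y_train, val_ids, cg, G, Kg, mcmc, seed)
    if np.std(pred.to_numpy()) == 0 or np.std(y_val.to_numpy()) == 0:
        warnings.warn(f"zero variance in fold predictions ({model}); "
                      "r_a undefined, cell recorded as missing")
        return float("nan"), h2_val, float("nan")
    r_a = float(scipy.stats.pearsonr(y_val.to_numpy(), pred.loc[val_ids].to_numpy())[0])
    if h2_val <= H2_VAL_FLOOR:
        return r_a, h2_val, float("nan")
    return r_a, h2_val, r_a / np.sqrt(h2_val)


@dataclass
class CVResult:
    """Fold-wise cells plus the plan that produced them."""
    cells: pd.DataFrame           # rep, fold, model, n_val, r_a, h2_val, accuracy
    plan: FoldPlan
    models: tuple[str, ...]

    def summary(self) -> pd.DataFrame:
        g = self.cells.groupby("model")
        out = pd.DataFrame({
            "mean_r_a": g["r_a"].mean(),
            "min_r_a": g["r_a"].min(),
            "max_r_a": g["r_a"].max(),
            "mean_accuracy": g["accuracy"].mean(),
            "min_accuracy": g["accuracy"].min(),
            "max_accuracy": g["accuracy"].max(),
            "mean_h2_val": g["h2_val"].mean(),
            "n_cells": g.size(),
            "n_missing": g["r_a"].apply(lambda s: int(s.isna().sum())),
        })
        return out.loc[[m for m in self.models if m in out.index]]

    def to_json_dict(self) -> dict:
        return {
            "plan": {"n": self.plan.n, "k": self.plan.k,
                     "reps": self.plan.reps, "seed": self.plan.seed,
                     "hash": self.plan.plan_hash()},
            "summary": self.summary().round(6).to_dict(orient="index"),
        }


def run_cv(models: Sequence[str], blues, geno: GenotypeTable,
           config: RunConfig) -> CVResult:
    """Repeated k-fold CV of every requested model on one shared fold plan.

    ``blues`` is a BlueSet or clone-indexed Series; ``geno`` the post-QC
    genotype table. Genotypes and BLUEs are intersected, dosages imputed and
    centered once, and the VanRaden G and Gaussian K built once for all
    folds. Any model failure marks that cell missing and the run continues.
    """
    for m in models:
        if m not in ALL_MODELS:
            raise HcngpError(f"unknown model {m!r}; choose from {ALL_MODELS}")
    y_all = blues if isinstance(blues, pd.Series) else blues.series()
    blues_df = pd.DataFrame({"clone_id": y_all.index, "blue": y_all.to_numpy()})
    geno_m, blues_m = match_geno_pheno(geno, blues_df)
    y = pd.Series(blues_m["blue"].to_numpy(), index=geno_m.clone_ids)
    cg = impute_and_center(geno_m)
    G = vanraden_grm(cg.Z, cg.p, cg.clone_ids)
    Kg = gaussian_kernel_from_config(cg, config.rkhs)
    plan = make_folds(len(y), k=config.cv.k, reps=config.cv.reps,
                      seed=config.cv.seed)
    ids = np.asarray(cg.clone_ids)

    rows = []
    for rep in range(plan.reps):
        for fold in range(plan.k):
            val_idx = plan.fold_members(rep, fold)
            val_ids = list(ids[val_idx])
            train_ids = list(ids[plan.assignment[rep] != fold])
            y_train, y_val = y.loc[train_ids], y.loc[val_ids]
            h2v = validation_h2(y_val, G.restrict(val_ids), config.mcmc,
                                seed=_derive_seed(config.cv.seed, rep, fold))
            for mi, model in enumerate(models):
                seed = _derive_seed(config.cv.seed, rep, fold, mi)
                try:
                    r_a, _, acc = evaluate_fold(
                        model, y_train, y_val, cg, G, Kg, config.mcmc,
                        seed=seed, h2_val=h2v)
                except HcngpError as exc:
                    logger.warning("model %s failed in rep %d fold %d: %s",
                                   model, rep, fold, exc)
                    r_a, acc = float("nan"), float("nan")
                rows.append({"rep": rep, "fold": fold, "model": model,
                             "n_val": len(val_ids), "r_a": r_a,
                             "h2_val": h2v, "accuracy": acc})
    cells = pd.DataFrame(rows)
    n_missing = int(cells["r_a"].isna().sum())
    if n_missing:
        logger.warning("CV finished with %d missing cell(s)", n_missing)
    return CVResult(cells=cells, plan=plan, models=tuple(models))


def gaussian_kernel_from_config(cg: CenteredGenotypes,
                                rkhs_cfg: RkhsConfig) -> RelationshipMatrix:
    spec = KernelSpec(theta=rkhs_cfg.theta, distance=rkhs_cfg.distance)
    return gaussian_kernel(cg.dosage_imputed, spec, cg.clone_ids)


def plot_cv_results(cells: pd.DataFrame, path) -> None:
    """Boxplots of r_a and accuracy per model (echoes the usual CV figures)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    models = list(pd.unique(cells["model"]))
    fig, axes = plt.subplots(1, 2, figsize=(3 + 1.2 * len(models), 4))
    for ax, col in zip(axes, ("r_a", "accuracy")):
        data = [cells.loc[cells["model"] == m, col].dropna() for m in models]
        ax.boxplot(data, tick_labels=models)
        ax.set_ylabel(col)
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
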