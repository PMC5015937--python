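"""Cross-validation of prediction accuracy and the accuracy-gain regression.

Predictive ability per fold is the Pearson correlation between predicted
genetic values and the validation BLUPs of grain yield; accuracy divides
the mean ability by the line-mean selection accuracy,
``r_g = mean(r_p) / H_line``.  The standard error uses
``sd(r_p) / (H_line * sqrt(k))`` by default (the SE of a mean of k fold
abilities); the plain ``/ k`` convention is available as a switch.

The gain regression models (multivariate - univariate) accuracy as a
linear function of relationship matrix, environment, the mean square-root
heritability of the secondary traits and their mean absolute genetic
correlation with grain yield, via ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .genetics import TraitBLUEs
from .lmm import LMMError
from .predict import multivariate_predict, univariate_predict
from .relationships import RelationshipMatrix

__all__ = [
    "FoldAssignment",
    "AccuracyResult",
    "PredictionTask",
    "PredictionData",
    "assign_folds",
    "accuracy_from_folds",
    "cross_validate",
    "gain_regression",
]


@dataclass
class FoldAssignment:
    assignment: pd.Series  # line -> fold index in {1..k}
    k: int
    seed: int

    def lines_in_fold(self, fold: int) -> list[str]:
        return list(self.assignment.index[self.assignment == fold])

    def __hash__(self) -> int:
        return hash((self.k, self.seed, tuple(self.assignment.items())))


@dataclass
class AccuracyResult:
    task: str
    fold_abilities: list[float]
    r_p_mean: float
    h_line: float
    r_g: float
    se: float
    excluded_folds: int = 0
    notes: str = ""


@dataclass
class PredictionTask:
    kernel_kind: str  # "A", "G" or "I"
    secondary_mode: str = "none"  # "none", "1rep" or "3rep"
    dthd_corrected: bool = False
    scope: str = "within"  # "within" or "across"

    def label(self) -> str:
        model = "UV" if self.secondary_mode == "none" else f"MV-{self.secondary_mode}"
        corr = "corrected" if self.dthd_corrected else "uncorrected"
        return f"{self.kernel_kind}/{model}/{self.scope}/{corr}"


@dataclass
class PredictionData:
    """Everything one environment's CV needs.

    ``secondary`` holds replicated (3-rep) BLUEs per trait;
    ``secondary_1rep`` single-replicate BLUEs used for test lines in the
    1rep scenario.  ``covariates`` is a per-line frame (lodging, DTHD).
    """

    environment: str
    gy_blues: TraitBLUEs
    secondary: Mapping[str, TraitBLUEs]
    secondary_1rep: Mapping[str, TraitBLUEs]
    validation: pd.Series
    h_line: float
    covariates: pd.DataFrame | None = None


def assign_folds(lines: Sequence[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random partition into k folds with sizes differing by <=1."""
    lines = [str(s) for s in lines]
    if k > len(lines):
        raise ValueError(f"k={k} exceeds {len(lines)} lines")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(lines))
    folds = np.empty(len(lines), dtype=int)
    folds[perm] = np.arange(len(lines)) % k + 1
    return FoldAssignment(pd.Series(folds, index=lines, name="fold"), k, seed)


def accuracy_from_folds(
    abilities: Sequence[float],
    h_line: float,
    *,
    task: str = "",
    se_convention: str = "sqrt_k",
    excluded: int = 0,
) -> AccuracyResult:
    """Aggregate fold abilities into accuracy r_g = mean(r_p) / H_line."""
    vals = [float(v) for v in abilities if np.isfinite(v)]
    if len(vals) < 2:
        raise LMMError("need >=2 finite fold abilities")
    if not h_line > 0.05:
        raise LMMError(f"H_line={h_line} too small to scale accuracy")
    r_p = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    denom = np.sqrt(len(vals)) if se_convention == "sqrt_k" else float(len(vals))
    return AccuracyResult(
        task=task,
        fold_abilities=vals,
        r_p_mean=r_p,
        h_line=float(h_line),
        r_g=r_p / float(h_line),
        se=sd / (float(h_line) * denom),
        excluded_folds=excluded,
    )


def cross_validate(
    task: PredictionTask,
    folds: FoldAssignment,
    data: PredictionData,
    kernels: Mapping[str, RelationshipMatrix],
    *,
    se_convention: str = "sqrt_k",
    max_iter: int = 200,
) -> AccuracyResult:
    """k-fold cross-validation of one prediction task in one environment."""
    kernel = kernels[task.kernel_kind]
    cov_names: list[str] = []
    if data.covariates is not None:
        if "lodging" in data.covariates.columns and (
            data.covariates["lodging"].fillna(0) != 0
        ).any():
            cov_names.append("lodging")
        if task.dthd_corrected:
            if "DTHD" not in data.covariates.columns:
                raise LMMError("DTHD correction requested but covariate absent")
            cov_names.append("DTHD")
    elif task.dthd_corrected:
        raise LMMError("DTHD correction requested but no covariate frame")

    gy_tab = data.gy_blues.table.copy()
    gy_tab["line"] = gy_tab["line"].astype(str)
    cv_lines = [s for s in folds.assignment.index if s in set(gy_tab["line"])]
    abilities: list[float] = []
    excluded = 0
    for fold in range(1, folds.k + 1):
        test = [s for s in folds.lines_in_fold(fold) if s in set(cv_lines)]
        if len(test) < 3:
            continue
        train_tab = gy_tab[~gy_tab["line"].isin(test)]
        gy_train = TraitBLUEs(
            data.gy_blues.trait, data.gy_blues.environment, train_tab
        )
        try:
            if task.secondary_mode == "none":
                pred = univariate_predict(
                    gy_train, kernel, test,
                    covariates=data.covariates, covariate_names=cov_names,
                )
            else:
                sec_test = (
                    data.secondary_1rep if task.secondary_mode == "1rep" else None
                )
                pred = multivariate_predict(
                    gy_train, data.secondary, kernel, test,
                    secondary_test=sec_test,
                    covariates=data.covariates, covariate_names=cov_names,
                    max_iter=max_iter,
                )
        except LMMError:
            excluded += 1
            continue
        obs = data.validation.reindex(pred.index)
        ok = obs.notna()
        abilities.append(float(np.corrcoef(pred[ok], obs[ok])[0, 1]))
    return accuracy_from_folds(
        abilities, data.h_line,
        task=f"{task.label()}@{data.environment}",
        se_convention=se_convention, excluded=excluded,
    )


def gain_regression(gains: pd.DataFrame):
    """OLS of accuracy gain on kernel, environment, H-bar and |r|-bar.

    ``gains`` columns: kernel (reference "A"), environment (reference
    "optimal"), h_bar, r_bar, gain.  Returns the fitted statsmodels
    results (coefficients in ``.params``, ``.pvalues``, ``.rsquared_adj``).
    """
    need = {"kernel", "environment", "h_bar", "r_bar", "gain"} - set(gains.columns)
    if need:
        raise ValueError(f"gain table missing columns: {sorted(need)}")
    if len(gains) < 8:
        raise ValueError("need >=8 rows for the gain regression")
    df = gains.copy()
    env_ref = "optimal" if "optimal" in set(df["environment"]) else sorted(df["environment"])[0]
    ker_ref = "A" if "A" in set(df["kernel"]) else sorted(df["kernel"])[0]
    formula = (
        f"gain ~ C(kernel, Treatment('{ker_ref}')) "
        f"+ C(environment, Treatment('{env_ref}')) + h_bar + r_bar"
    )
    model = smf.ols(formula, data=df)
    res = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        names = np.array(model.exog_names)
        raise ValueError(f"aliased predictors in gain regression: {list(names)}")
    return res
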