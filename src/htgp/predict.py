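"""Pedigree and genomic prediction of grain yield, univariate and
multi-trait.

Two estimators follow scikit-learn conventions (``get_params`` /
``set_params``, fitted attributes with a trailing underscore):

* :class:`GBLUP` — univariate kernel BLUP with REML variance components,
  taking a precomputed relationship kernel like
  :class:`~sklearn.kernel_ridge.KernelRidge` with ``kernel="precomputed"``:
  ``fit(K_train_train, y)`` then ``predict(K_test_train)``.
* :class:`MultiTraitGBLUP` — the multi-trait model with secondary traits
  observed on selection candidates; grain yield is simply absent (masked)
  for test lines and its genetic value is predicted from kernel
  relationships plus the correlated secondary traits.

Module-level functions (``univariate_predict``, ``multivariate_predict``,
``unrelated_predict``) are thin line-ID-aware wrappers used by the
cross-validation driver.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .genetics import TraitBLUEs
from .lmm import LMMError, RandomTerm, fit_lmm
from .multitrait import MultiTraitFit, conditional_predict, fit_multitrait
from .relationships import RelationshipMatrix

__all__ = [
    "GBLUP",
    "MultiTraitGBLUP",
    "univariate_predict",
    "multivariate_predict",
    "unrelated_predict",
]


class GBLUP(BaseEstimator, RegressorMixin):
    """Univariate genomic/pedigree BLUP with a precomputed kernel.

    Model: ``y_i = mu + X_cov b + g_i + e_i`` with ``g ~ N(0, s2_g K)`` and
    ``e_i ~ N(0, s2_e / w_i)``; variance components by REML.  ``predict``
    returns genetic values (centered BLUPs), the quantity selection works
    with, not ``y`` on the original scale.

    Parameters
    ----------
    max_iter : REML iteration cap.

    Attributes (after fit)
    ----------------------
    sigma2_g_, sigma2_e_ : variance components.
    beta_ : fixed effects (intercept first).
    blup_ : genetic values of the training samples.
    py_ : projected residual vector; predictions are ``s2_g K_cross @ py_``.
    """

    def __init__(self, max_iter: int = 200):
        self.max_iter = max_iter

    def fit(self, X, y, sample_weight=None, covariates=None):
        k = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        if k.shape != (n, n):
            raise ValueError(f"X must be the n x n training kernel, got {k.shape}")
        ids = [f"_s{i}" for i in range(n)]
        df = pd.DataFrame({"line": ids, "value": y})
        fixed: list[str] = []
        if covariates is not None:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] != n:
                cov = cov.T
            for j in range(cov.shape[1]):
                df[f"cov{j}"] = cov[:, j]
                fixed.append(f"cov{j}")
        if sample_weight is not None:
            df["w"] = np.asarray(sample_weight, dtype=float)
        kern = RelationshipMatrix(ids, k, kind="G")
        res = fit_lmm(
            df,
            "value",
            fixed=fixed,
            random=[RandomTerm("g", ("line",), kern)],
            weights="w" if sample_weight is not None else None,
            max_iter=self.max_iter,
        )
        self.sigma2_g_ = res.varcomp["g"]
        self.sigma2_e_ = res.varcomp["residual"]
        self.beta_ = res.beta.to_numpy()
        self.blup_ = res.blups["g"].to_numpy()
        w = res.weights
        # P y = W (y - X b - g_hat) / s2_e ; predictions are s2_g K_x @ Py
        self.py_ = w * res.residuals / max(self.sigma2_e_, 1e-300)
        self.loglik_ = res.loglik
        self.n_features_in_ = n
        return self

    def predict(self, X):
        k = np.asarray(X, dtype=float)
        if k.ndim == 1:
            k = k[None, :]
        if k.shape[1] != self.n_features_in_:
            raise ValueError(
                f"cross-kernel has {k.shape[1]} columns, expected {self.n_features_in_}"
            )
        return self.sigma2_g_ * (k @ self.py_)


class MultiTraitGBLUP(BaseEstimator):
    """Multi-trait kernel BLUP; grain yield masked on the test set.

    ``fit`` takes long records (line, trait, value, weight, covariates) and
    a :class:`RelationshipMatrix`; genetic values are predicted for every
    kernel line x trait cell, so test-line predictions are simply read off
    the fitted object.
    """

    def __init__(
        self,
        diagonal: bool = False,
        max_iter: int = 200,
        n_em: int = 20,
    ):
        self.diagonal = diagonal
        self.max_iter = max_iter
        self.n_em = n_em

    def fit(
        self,
        X: pd.DataFrame,
        kernel: RelationshipMatrix,
        *,
        trait_order: Sequence[str] | None = None,
        fixed=None,
        unit: Sequence[str] = ("line",),
        extra_random: Sequence[str] = (),
        H0=None,
        R0=None,
        optimize: bool = True,
    ):
        self.fit_: MultiTraitFit = fit_multitrait(
            X,
            kernel,
            trait_order=trait_order,
            fixed=fixed,
            unit=unit,
            extra_random=extra_random,
            diagonal=self.diagonal,
            H0=H0,
            R0=R0,
            optimize=optimize,
            max_iter=self.max_iter,
            n_em=self.n_em,
        )
        self.H_ = self.fit_.H
        self.R_ = self.fit_.R
        self.genetic_values_ = self.fit_.genetic_values
        self.converged_ = self.fit_.converged
        return self

    def predict(self, lines: Sequence[str], trait: str = "GY") -> np.ndarray:
        return conditional_predict(self.fit_, trait, lines).to_numpy()


def _align_kernel(kernel: RelationshipMatrix, lines: Sequence[str]) -> RelationshipMatrix:
    return kernel.submatrix(sorted(set(map(str, lines))))


def _covariate_frame(
    table: pd.DataFrame,
    covariates: pd.DataFrame | None,
    names: Sequence[str],
) -> pd.DataFrame:
    out = table.copy()
    for c in names:
        out[c] = out["line"].astype(str).map(covariates[c])
        if out[c].isna().any():
            missing = sorted(out.loc[out[c].isna(), "line"].unique())
            raise LMMError(f"covariate '{c}' missing for lines: {missing[:10]}")
    return out


def univariate_predict(
    gy_train: TraitBLUEs,
    kernel: RelationshipMatrix,
    test_lines: Sequence[str],
    *,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
) -> pd.Series:
    """Kernel BLUP of grain yield for test lines from training BLUEs."""
    train_tab = gy_train.table.copy()
    train_tab["line"] = train_tab["line"].astype(str)
    test_lines = [str(s) for s in test_lines]
    overlap = set(test_lines) & set(train_tab["line"])
    if overlap:
        raise LMMError(f"test lines present in training BLUEs: {sorted(overlap)[:10]}")
    all_lines = list(train_tab["line"]) + list(test_lines)
    sub = kernel.submatrix(all_lines)
    n_tr = len(train_tab)
    k_tt = sub.values[:n_tr, :n_tr]
    k_xt = sub.values[n_tr:, :n_tr]
    cov = None
    if covariates is not None and covariate_names:
        tab = _covariate_frame(train_tab, covariates, covariate_names)
        cov = tab[list(covariate_names)].to_numpy(dtype=float)
    model = GBLUP().fit(
        k_tt,
        train_tab["value"].to_numpy(dtype=float),
        sample_weight=train_tab["weight"].to_numpy(dtype=float),
        covariates=cov,
    )
    return pd.Series(model.predict(k_xt), index=test_lines, name="GY_pred")


def _stack_records(
    gy_train: TraitBLUEs,
    secondary: Mapping[str, TraitBLUEs],
    test_lines: Sequence[str],
    secondary_test: Mapping[str, TraitBLUEs] | None = None,
    require_test_secondary: bool = True,
) -> pd.DataFrame:
    """Long records with GY masked on test lines.

    ``secondary_test`` optionally overrides the test-set secondary records
    (e.g. single-replicate BLUEs with weight 1) while training lines keep
    the replicated values.
    """
    test = set(map(str, test_lines))
    parts = [
        gy_train.table.assign(trait="GY")[["line", "trait", "value", "weight"]]
    ]
    for name, b in secondary.items():
        tab = b.table.copy()
        tab["line"] = tab["line"].astype(str)
        if secondary_test is not None:
            t_tab = secondary_test[name].table.copy()
            t_tab["line"] = t_tab["line"].astype(str)
            missing = sorted(test - set(t_tab["line"]))
            if missing:
                raise LMMError(
                    f"secondary trait '{name}' missing for test lines: {missing[:10]}"
                )
            tab = pd.concat(
                [tab[~tab["line"].isin(test)], t_tab[t_tab["line"].isin(test)]]
            )
        missing = sorted(test - set(tab["line"]))
        if missing and require_test_secondary:
            raise LMMError(
                f"secondary trait '{name}' missing for test lines: {missing[:10]}"
            )
        parts.append(tab.assign(trait=name)[["line", "trait", "value", "weight"]])
    return pd.concat(parts, ignore_index=True)


def multivariate_predict(
    gy_train: TraitBLUEs,
    secondary: Mapping[str, TraitBLUEs],
    kernel: RelationshipMatrix,
    test_lines: Sequence[str],
    *,
    secondary_test: Mapping[str, TraitBLUEs] | None = None,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
    diagonal: bool = False,
    max_iter: int = 200,
    require_test_secondary: bool = True,
) -> pd.Series:
    """Multi-trait prediction: secondary traits on all lines, GY on training.

    Record weights (number of plots underlying each BLUE) scale the
    residual variance as ``R_tt / w``.  ``require_test_secondary=False``
    permits secondary traits observed on the training set only — the
    scenario in which multi-trait models gain nothing over univariate.
    """
    test_lines = [str(s) for s in test_lines]
    records = _stack_records(
        gy_train, secondary, test_lines, secondary_test, require_test_secondary
    )
    fixed = None
    if covariates is not None and covariate_names:
        records = _covariate_frame(records, covariates, covariate_names)
        fixed = list(covariate_names)
    lines = sorted(set(records["line"].astype(str)) | set(test_lines))
    sub = kernel.submatrix(lines)
    model = MultiTraitGBLUP(diagonal=diagonal, max_iter=max_iter).fit(
        records,
        sub,
        trait_order=["GY"] + list(secondary),
        fixed=fixed,
    )
    return pd.Series(model.predict(test_lines, "GY"), index=test_lines, name="GY_pred")


def unrelated_predict(
    gy_train_reps: Sequence[TraitBLUEs],
    secondary_reps: Mapping[str, Sequence[TraitBLUEs]],
    test_lines: Sequence[str],
    *,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
    max_iter: int = 200,
) -> pd.Series:
    """Total genetic value prediction assuming unrelated lines (K = I).

    Inputs are per-replicate BLUEs (one :class:`TraitBLUEs` per replicate
    per trait); a random replicate-within-trait effect absorbs replicate
    shifts.  GY records of test lines are excluded (masked).
    """
    test = set(map(str, test_lines))
    parts = []
    n_reps = len(gy_train_reps)
    for b in gy_train_reps:
        tab = b.table.copy()
        tab["line"] = tab["line"].astype(str)
        tab = tab[~tab["line"].isin(test)]
        parts.append(
            tab.assign(trait="GY", replicate=b.replicate_scope)[
                ["line", "trait", "replicate", "value", "weight"]
            ]
        )
    for name, blist in secondary_reps.items():
        for b in blist:
            tab = b.table.copy()
            tab["line"] = tab["line"].astype(str)
            parts.append(
                tab.assign(trait=name, replicate=b.replicate_scope)[
                    ["line", "trait", "replicate", "value", "weight"]
                ]
            )
    records = pd.concat(parts, ignore_index=True)
    fixed = None
    if covariates is not None and covariate_names:
        records = _covariate_frame(records, covariates, covariate_names)
        fixed = list(covariate_names)
    lines = sorted(set(records["line"]) | test)
    ident = RelationshipMatrix.identity(lines)
    extra = ("trait:replicate",) if n_reps > 1 else ()
    model = MultiTraitGBLUP(max_iter=max_iter).fit(
        records,
        ident,
        trait_order=["GY"] + list(secondary_reps),
        fixed=fixed,
        unit=("line", "replicate"),
        extra_random=extra,
    )
    return pd.Series(
        model.predict(sorted(test), "GY"), index=sorted(test), name="GY_pred"
    )
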