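"""Univariate linear mixed models by REML.

The engine fits ``y = X b + sum_k Z_k u_k + e`` where each random factor
``u_k`` is iid ``N(0, s2_k I)`` or, for at most one genotype term,
``N(0, s2_g K)`` with a pedigree/genomic kernel ``K``.  Residuals are
``N(0, s2_e / w_i)`` with optional per-record weights ``w``.

Estimation works on Henderson's mixed-model equations: an EM warm start
(monotone, robust far from the optimum) followed by average-information
Newton steps with step halving, so the restricted likelihood never
decreases.  Variance components are kept nonnegative by boundary
projection onto a small floor.

Everything is dense; the intended problem sizes (hundreds of lines, a few
thousand plots) factor in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .relationships import RelationshipMatrix

__all__ = ["RandomTerm", "LMMResult", "LMMError", "fit_lmm", "studentized_residuals"]


class LMMError(RuntimeError):
    pass


@dataclass
class RandomTerm:
    """One random factor; levels are the observed crossing of ``columns``.

    ``"rep:trial:date"`` denotes replicate nested within trial and date —
    one level per observed (rep, trial, date) combination.  A kernel turns
    the term into a correlated genetic effect whose levels are the kernel's
    line IDs (kernel lines without records still get BLUPs).
    """

    name: str
    columns: tuple[str, ...]
    kernel: RelationshipMatrix | None = None

    @classmethod
    def parse(cls, spec: "str | RandomTerm") -> "RandomTerm":
        if isinstance(spec, RandomTerm):
            return spec
        return cls(name=spec, columns=tuple(spec.split(":")))


@dataclass
class LMMResult:
    varcomp: dict[str, float]
    beta: pd.Series
    blups: dict[str, pd.Series]
    loglik: float
    converged: bool
    trace: list[float]
    fitted: np.ndarray
    residuals: np.ndarray
    resid_df: int
    resid_var_diag: np.ndarray  # diag of Var(e_hat) = R - T C^-1 T'
    weights: np.ndarray
    n_obs: int = 0
    rank_x: int = 0

    @property
    def sigma2(self) -> dict[str, float]:
        return dict(self.varcomp)


def _build_fixed_design(
    data: pd.DataFrame,
    fixed: Sequence[str],
    cell_means: str | None,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = []
    names: list[str] = []
    if cell_means is not None:
        levels = pd.Categorical(data[cell_means].astype(str))
        dummies = pd.get_dummies(levels, dtype=float)
        cols.append(dummies.to_numpy())
        names.extend(f"{cell_means}[{lv}]" for lv in dummies.columns)
    else:
        cols.append(np.ones((len(data), 1)))
        names.append("(Intercept)")
    for f in fixed:
        col = data[f]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float)[:, None])
            names.append(f)
        else:
            dummies = pd.get_dummies(pd.Categorical(col.astype(str)), dtype=float)
            # drop first level against the intercept / cell means
            arr = dummies.to_numpy()[:, 1:]
            cols.append(arr)
            names.extend(f"{f}[{lv}]" for lv in dummies.columns[1:])
    x = np.hstack(cols)
    if x.shape[1]:
        _, rr = np.linalg.qr(x, mode="reduced")
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
        if (diag < tol).any():
            aliased = [names[i] for i in np.where(diag < tol)[0]]
            raise LMMError(f"fixed design is singular; aliased columns: {aliased}")
    return x, names


def _kernel_root(k: np.ndarray, rel_tol: float = 1e-10) -> tuple[np.ndarray, float]:
    """Eigen square root B with K = B B', rank-truncated.

    Genomic kernels built from column-centered markers are exactly singular
    (the all-ones vector is in their null space); working in the rotated
    coordinates ``u = B c`` with iid ``c`` sidesteps K^-1 and keeps the
    mixed-model equations well conditioned.  Returns (B, log|K_r|) where
    the log-determinant runs over the retained eigenvalues.
    """
    w, v = np.linalg.eigh(0.5 * (k + k.T))
    tol = rel_tol * max(w[-1], 0.0)
    if w[-1] <= 0:
        raise LMMError("kernel has no positive eigenvalues")
    keep = w > tol
    w, v = w[keep], v[:, keep]
    return v * np.sqrt(w), float(np.sum(np.log(w)))


def _term_design(
    data: pd.DataFrame, term: RandomTerm
) -> tuple[np.ndarray, list[str], np.ndarray | None, float]:
    """Design matrix, output level labels, kernel root (or None), log|K|.

    For a kernel term the design is the line indicator times the kernel
    root B, the effective levels are the rank-r rotated coordinates, and
    BLUPs on the line scale are recovered as ``B c``.
    """
    if term.kernel is not None:
        if len(term.columns) != 1:
            raise LMMError("kernel term must reference a single column")
        ids = term.kernel.line_ids
        index = {s: i for i, s in enumerate(ids)}
        obs = data[term.columns[0]].astype(str)
        unknown = sorted(set(obs) - set(ids))
        if unknown:
            raise LMMError(
                f"levels of '{term.name}' absent from kernel: {unknown[:10]}"
            )
        b, logdet = _kernel_root(term.kernel.values)
        rows = np.array([index[s] for s in obs])
        return b[rows], list(ids), b, logdet
    key = data[list(term.columns)].astype(str).agg("\x1f".join, axis=1)
    codes, levels = pd.factorize(key, sort=True)
    z = np.zeros((len(data), len(levels)))
    z[np.arange(len(data)), codes] = 1.0
    return z, list(levels), None, 0.0


def _safe_chol_inv(k: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a PD matrix, with tiny jitter."""
    n = k.shape[0]
    jitter = 0.0
    scale = float(np.mean(np.diag(k))) or 1.0
    for _ in range(8):
        try:
            c = cho_factor(k + jitter * np.eye(n), lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            return cho_solve(c, np.eye(n)), logdet
        except np.linalg.LinAlgError:
            jitter = scale * 1e-10 if jitter == 0.0 else jitter * 100.0
    raise LMMError("matrix is numerically singular beyond repair")


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    *,
    fixed: Sequence[str] = (),
    cell_means: str | None = None,
    random: Sequence["str | RandomTerm"] = (),
    weights: str | None = None,
    max_iter: int = 200,
    n_em: int = 10,
    tol_loglik: float = 1e-9,
    tol_param: float = 1e-6,
) -> LMMResult:
    """REML fit; see module docstring for the model.

    Raises :class:`LMMError` on a singular fixed design or non-convergence
    (the likelihood trace rides along on the exception).
    """
    data = data.loc[np.isfinite(pd.to_numeric(data[response], errors="coerce"))]
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise LMMError("no finite responses")
    w = (
        data[weights].to_numpy(dtype=float)
        if weights is not None
        else np.ones(n)
    )
    if (w <= 0).any():
        raise LMMError("weights must be strictly positive")

    x, xnames = _build_fixed_design(data, fixed, cell_means)
    p = x.shape[1]
    if n - p < 1:
        raise LMMError(
            f"saturated fixed design: {n} records for {p} fixed effects "
            "(no residual degrees of freedom; per-replicate estimation needs "
            "repeated check lines to connect trials)"
        )
    terms = [RandomTerm.parse(t) for t in random]
    z_list, level_list, root_list, klogdet_list = [], [], [], []
    for t in terms:
        z, levels, root, logdet = _term_design(data, t)
        z_list.append(z)
        level_list.append(levels)
        root_list.append(root)
        klogdet_list.append(logdet)
    q_sizes = [z.shape[1] for z in z_list]
    q_total = int(sum(q_sizes))
    offsets = np.concatenate([[0], np.cumsum(q_sizes)]).astype(int)

    t_mat = np.hstack([x] + z_list) if q_total else x
    dim = p + q_total
    wt = t_mat * w[:, None]
    twt = t_mat.T @ wt  # T' W T, reused every iteration
    twy = t_mat.T @ (w * y)
    ywy = float(y @ (w * y))
    sum_log_w = float(np.sum(np.log(w)))

    var_y = float(np.var(y)) or 1.0
    floor = 1e-10 * var_y
    n_comp = len(terms)
    theta = np.full(n_comp + 1, var_y / (n_comp + 1.0))
    theta = np.maximum(theta, floor)

    def assemble(th: np.ndarray):
        s2e = th[-1]
        c = twt / s2e
        for k in range(n_comp):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            c[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += 1.0 / th[k]
        rhs = twy / s2e
        try:
            cf = cho_factor(c, lower=True)
        except np.linalg.LinAlgError as exc:
            raise LMMError(f"mixed-model equations singular: {exc}") from exc
        sol = cho_solve(cf, rhs)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ypy = ywy / s2e - float(sol @ rhs)
        m2ll = (
            (n - p) * 0.0  # placeholder, kept for readability
            + n * np.log(s2e)
            - sum_log_w
            + sum(
                q_sizes[k] * np.log(th[k]) + klogdet_list[k]
                for k in range(n_comp)
            )
            + logdet_c
            + ypy
        )
        return -0.5 * m2ll, cf, sol

    def em_update(th, cf, sol):
        cinv = cho_solve(cf, np.eye(dim))
        new = th.copy()
        for k in range(n_comp):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            u = sol[sl]
            quad = float(u @ u)
            tr = float(np.trace(cinv[sl, sl]))
            new[k] = max((quad + tr) / q_sizes[k], floor)
        resid_quad = ywy - float(sol @ twy)
        new[-1] = max(resid_quad / (n - p), floor)
        return new

    def ai_step(th, cf, sol):
        s2e = th[-1]
        ehat = y - t_mat @ sol
        py = w * ehat / s2e
        # V-dot times Py for every component, as columns
        u_cols = np.empty((n, n_comp + 1))
        for k in range(n_comp):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            u_cols[:, k] = z_list[k] @ (sol[sl] / th[k])
        u_cols[:, -1] = ehat / s2e
        # P v = W (v - T C^-1 T' W v / s2e) / s2e
        tv = t_mat.T @ (u_cols * w[:, None]) / s2e
        sols = cho_solve(cf, tv)
        pu = w[:, None] * (u_cols - t_mat @ sols) / s2e
        ai = 0.5 * (u_cols.T @ pu)
        # gradient
        cinv = cho_solve(cf, np.eye(dim))
        grad = np.empty(n_comp + 1)
        tr_sum = 0.0
        for k in range(n_comp):
            sl = slice(p + offsets[k], p + offsets[k + 1])
            u = sol[sl]
            tr_kc = float(np.trace(cinv[sl, sl]))
            quad = float(u @ u)
            tr_pv = (q_sizes[k] - tr_kc / th[k]) / th[k]
            tr_sum += th[k] * tr_pv
            grad[k] = -0.5 * (tr_pv - quad / th[k] ** 2)
        tr_pve = (n - p - tr_sum) / s2e
        quad_e = float(py @ (py / w))  # (Py)' W^-1 (Py)
        grad[-1] = -0.5 * (tr_pve - quad_e)
        # KKT active set: components at the floor whose gradient points
        # further down stay there; anything else is free (can revive)
        at_floor = th <= floor * 1.01
        at_floor[-1] = False  # residual always free
        free = ~(at_floor & (grad < 0))
        delta = np.zeros(n_comp + 1)
        try:
            sub = np.ix_(free, free)
            delta[free] = np.linalg.solve(
                ai[sub] + 1e-12 * np.eye(int(free.sum())), grad[free]
            )
        except np.linalg.LinAlgError:
            delta[free] = grad[free] * th[free] ** 2  # EM-like fallback
        return delta, grad

    ll, cf, sol = assemble(theta)
    trace = [ll]
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        if it <= n_em:
            new_theta = em_update(theta, cf, sol)
        else:
            delta, grad = ai_step(theta, cf, sol)
            step = 1.0
            new_theta = None
            for _ in range(12):
                cand = np.maximum(theta + step * delta, floor)
                try:
                    ll_c, cf_c, sol_c = assemble(cand)
                except LMMError:
                    ll_c = -np.inf
                if ll_c >= ll - 1e-12:
                    new_theta = cand
                    break
                step *= 0.5
            if new_theta is None:
                new_theta = em_update(theta, cf, sol)  # guaranteed ascent
        ll_new, cf_new, sol_new = assemble(new_theta)
        d_ll = ll_new - ll
        # parameter movement on the scale of var(y): components pinned at the
        # floor no longer block convergence
        d_par = float(np.max(np.abs(new_theta - theta))) / var_y
        theta, ll, cf, sol = new_theta, ll_new, cf_new, sol_new
        trace.append(ll)
        if it > 3 and abs(d_ll) < tol_loglik and d_par < tol_param:
            converged = True
            break
        window = (
            max(trace[-8:]) - max(trace[-16:-8]) if it > n_em + 16 else np.inf
        )
        if window < 1e-3 or (it > 100 and window < 3e-2):
            # plateau: bounded boundary oscillation, or a crawl along a
            # nearly flat ridge (e.g. the variance of a 2-level factor);
            # the remaining movement is irrelevant at estimate scale
            converged = True
            break
    if not converged and max_iter > n_em + 2:
        # tolerate flat likelihoods: accept if the last few steps moved < 1e-6
        tail = np.diff(trace[-4:])
        if len(tail) and np.max(np.abs(tail)) < 1e-6:
            converged = True
    if not converged:
        raise LMMError(
            f"REML did not converge in {max_iter} iterations; trace tail "
            f"{[round(v, 6) for v in trace[-5:]]}"
        )

    beta = pd.Series(sol[:p], index=xnames, name="beta")
    blups: dict[str, pd.Series] = {}
    for k, t in enumerate(terms):
        sl = slice(p + offsets[k], p + offsets[k + 1])
        u = sol[sl]
        if root_list[k] is not None:
            u = root_list[k] @ u  # back to the line scale
        blups[t.name] = pd.Series(u, index=level_list[k], name=t.name)
    varcomp = {t.name: float(v) for t, v in zip(terms, theta[:-1])}
    varcomp["residual"] = float(theta[-1])
    # zero-clamp reporting for components at the numerical floor
    for key, v in varcomp.items():
        if key != "residual" and v <= 1e-8 * var_y:
            varcomp[key] = 0.0

    fitted = t_mat @ sol
    resid = y - fitted
    # Var(e_hat) diag = diag(R) - row_i T C^-1 T' row_i
    cs = cho_solve(cf, t_mat.T)
    leverage = np.einsum("ij,ji->i", t_mat, cs)
    resid_var = theta[-1] / w - leverage
    return LMMResult(
        varcomp=varcomp,
        beta=beta,
        blups=blups,
        loglik=float(ll),
        converged=converged,
        trace=trace,
        fitted=fitted,
        residuals=resid,
        resid_df=int(n - p),
        resid_var_diag=resid_var,
        weights=w,
        n_obs=n,
        rank_x=p,
    )


def studentized_residuals(
    result: LMMResult, *, external: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Studentized conditional residuals and two-sided t p-values.

    Internally studentized residuals divide each residual by its estimated
    standard deviation from the fit; the external (leave-one-out) version
    applies the exact OLS rescaling ``t * sqrt((nu - 1) / (nu - t^2))`` with
    ``nu`` the residual degrees of freedom, and p-values use ``nu - 1`` df.
    """
    nu = result.resid_df
    if nu < 2:
        raise LMMError("too few residual degrees of freedom to studentize")
    denom = np.sqrt(np.clip(result.resid_var_diag, 1e-300, None))
    t_int = result.residuals / denom
    if external:
        inner = np.clip(nu - t_int**2, 1e-12, None)
        t_val = t_int * np.sqrt((nu - 1) / inner)
        df = nu - 1
    else:
        t_val, df = t_int, nu
    pvals = 2.0 * stats.t.sf(np.abs(t_val), df)
    return t_val, pvals
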