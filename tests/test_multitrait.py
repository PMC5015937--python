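"""Multi-trait REML engine: prediction oracle, reductions, boundary cases."""

import numpy as np
import pandas as pd
import pytest

from htgp.lmm import LMMError, RandomTerm, fit_lmm
from htgp.multitrait import conditional_predict, fit_multitrait
from htgp.relationships import RelationshipMatrix


def joint_normal_oracle(df, lines, K, H, R):
    """Brute-force conditioning: build the full joint covariance, invert it.

    Fixed effects are per-trait intercepts estimated by GLS; genetic values
    are E[a | y] = Cov(a, y) V^-1 (y - X beta).
    """
    m = len(lines)
    traits = sorted(df["trait"].unique())
    t = len(traits)
    tau = df["trait"].map({s: i for i, s in enumerate(traits)}).to_numpy()
    lin = df["line"].map({s: i for i, s in enumerate(lines)}).to_numpy()
    w = df["weight"].to_numpy(float)
    y = df["value"].to_numpy(float)
    n = len(df)
    Z = np.zeros((n, m * t))
    Z[np.arange(n), tau * m + lin] = 1.0
    X = np.zeros((n, t))
    X[np.arange(n), tau] = 1.0
    G = np.kron(H, K)
    Rs = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if lin[i] == lin[j]:
                Rs[i, j] = R[tau[i], tau[j]] / np.sqrt(w[i] * w[j])
    V = Z @ G @ Z.T + Rs
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    a = G @ Z.T @ Vi @ (y - X @ beta)
    return a.reshape(t, m).T  # lines x traits


def random_instance(rng, m, t, n_masked, with_weights=True):
    lines = [f"L{i}" for i in range(m)]
    M = rng.normal(size=(m, 3 * m))
    K = M @ M.T / (3 * m)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d) + 0.15 * np.eye(m)
    A = rng.normal(size=(t, t))
    H = A @ A.T / t + 0.3 * np.eye(t)
    B = rng.normal(size=(t, t))
    R = 0.5 * (B @ B.T / t + 0.3 * np.eye(t))
    recs = []
    masked = set(rng.choice(m, size=n_masked, replace=False))
    for ti in range(t):
        for i, ln in enumerate(lines):
            if ti == t - 1 and i in masked:
                continue
            recs.append(
                dict(
                    line=ln,
                    trait=f"T{ti}",
                    value=rng.normal(),
                    weight=float(rng.integers(1, 4)) if with_weights else 1.0,
                )
            )
    return pd.DataFrame(recs), lines, K, H, R


class TestPredictionOracle:
    @pytest.mark.parametrize("m,t,n_masked", [(8, 2, 3), (12, 3, 4), (6, 3, 2)])
    def test_mme_equals_joint_conditioning(self, rng, m, t, n_masked):
        """Mixed-model-equation predictions match explicit joint-normal
        conditioning, including masked cells and heterogeneous weights."""
        df, lines, K, H, R = random_instance(rng, m, t, n_masked)
        kern = RelationshipMatrix(lines, K)
        fit = fit_multitrait(
            df, kern, trait_order=sorted(df["trait"].unique()),
            H0=H, R0=R, optimize=False,
        )
        oracle = joint_normal_oracle(df, lines, K, H, R)
        got = fit.genetic_values.to_numpy()
        rel = np.max(np.abs(got - oracle)) / np.max(np.abs(oracle))
        assert rel < 1e-8

    def test_conditional_predict_lookup_and_errors(self, rng):
        df, lines, K, H, R = random_instance(rng, 6, 2, 2)
        fit = fit_multitrait(df, RelationshipMatrix(lines, K),
                             trait_order=["T0", "T1"], H0=H, R0=R, optimize=False)
        s = conditional_predict(fit, "T0", lines[:3])
        assert np.allclose(s.to_numpy(), fit.genetic_values["T0"].iloc[:3])
        with pytest.raises(LMMError, match="unknown trait"):
            conditional_predict(fit, "nope")
        with pytest.raises(LMMError, match="unknown lines"):
            conditional_predict(fit, "T0", ["ghost"])

    def test_identity_kernel_no_information_predicts_zero(self):
        """A masked line with no records and K = I gets the prior mean 0."""
        lines = ["A", "B", "C"]
        df = pd.DataFrame(
            [dict(line=s, trait="T0", value=v, weight=1.0)
             for s, v in zip(["A", "B"], [1.0, -1.0])]
        )
        fit = fit_multitrait(
            df, RelationshipMatrix.identity(lines), trait_order=["T0"],
            H0=np.array([[1.0]]), R0=np.array([[0.5]]), optimize=False,
        )
        assert fit.genetic_values.loc["C", "T0"] == pytest.approx(0.0, abs=1e-12)

    def test_two_trait_closed_form_conditioning(self):
        """K = I, secondary observed, target masked: prediction equals
        cov(a_1, y_2) / var(y_2) * y_2 from the 2x2 normal closed form."""
        H = np.array([[1.0, 0.6], [0.6, 0.8]])
        R = np.array([[0.4, 0.1], [0.1, 0.5]])
        y2 = 1.7
        lines = ["X", "anchor1", "anchor2"]
        # anchors pin the intercepts without informing X (K = I)
        recs = [
            dict(line="X", trait="T1", value=y2, weight=1.0),
            dict(line="anchor1", trait="T0", value=0.3, weight=1.0),
            dict(line="anchor2", trait="T0", value=-0.3, weight=1.0),
            dict(line="anchor1", trait="T1", value=0.1, weight=1.0),
            dict(line="anchor2", trait="T1", value=-0.1, weight=1.0),
        ]
        fit = fit_multitrait(
            pd.DataFrame(recs), RelationshipMatrix.identity(lines),
            trait_order=["T0", "T1"], H0=H, R0=R, optimize=False,
        )
        oracle = joint_normal_oracle(
            pd.DataFrame(recs), lines, np.eye(3), H, R
        )
        assert fit.genetic_values.loc["X", "T0"] == pytest.approx(
            oracle[0, 0], rel=1e-10
        )


class TestREMLEstimation:
    def test_diagonal_constraint_reduces_to_univariate(self, rng, small_kernel):
        """With H and R diagonal the joint model factorizes: predictions
        equal two independent univariate kernel fits."""
        kern = small_kernel
        m = len(kern.line_ids)
        w, v = np.linalg.eigh(kern.values)
        L = v * np.sqrt(np.maximum(w, 0))
        recs = []
        for ti in range(2):
            a = L @ rng.normal(size=m)
            for i, ln in enumerate(kern.line_ids):
                recs.append(dict(line=ln, trait=f"T{ti}",
                                 value=a[i] + rng.normal(0, 1.0), weight=1.0))
        df = pd.DataFrame(recs)
        fit = fit_multitrait(df, kern, trait_order=["T0", "T1"], diagonal=True)
        for ti in range(2):
            sub = df[df["trait"] == f"T{ti}"]
            uni = fit_lmm(sub, "value", random=[RandomTerm("g", ("line",), kern)])
            got = fit.genetic_values[f"T{ti}"].loc[uni.blups["g"].index]
            assert np.max(np.abs(got.to_numpy() - uni.blups["g"].to_numpy())) < 1e-4

    def test_constant_trait_flagged_undefined(self, rng):
        m = 30
        lines = [f"L{i}" for i in range(m)]
        recs = []
        for i, ln in enumerate(lines):
            recs.append(dict(line=ln, trait="T0", value=rng.normal(), weight=1.0))
            recs.append(dict(line=ln, trait="T1", value=5.0, weight=1.0))
        fit = fit_multitrait(
            pd.DataFrame(recs), RelationshipMatrix.identity(lines),
            trait_order=["T0", "T1"],
        )
        corr = fit.genetic_correlations()
        assert fit.H[1, 1] < 1e-3 * fit.H[0, 0]
        assert np.isnan(corr.loc["T0", "T1"])

    def test_em_warmstart_monotone(self, rng):
        """Restricted likelihood never decreases across the EM phase."""
        m = 50
        lines = [f"L{i}" for i in range(m)]
        K = np.eye(m) * 0.8 + 0.2
        L = np.linalg.cholesky(np.kron(np.array([[1, 0.5], [0.5, 1]]), K))
        a = L @ rng.normal(size=2 * m)
        recs = [
            dict(line=ln, trait=f"T{ti}", value=a[ti * m + i] + rng.normal(0, 0.8),
                 weight=1.0)
            for ti in range(2)
            for i, ln in enumerate(lines)
        ]
        fit = fit_multitrait(
            pd.DataFrame(recs), RelationshipMatrix(lines, K),
            trait_order=["T0", "T1"], max_iter=30, n_em=30,
        )
        assert np.all(np.diff(fit.trace) > -1e-7)

    def test_bivariate_recovery(self, rng):
        """Known H with r_g = 0.7: the bivariate fit lands nearby."""
        m = 150
        lines = [f"L{i}" for i in range(m)]
        calls = rng.choice([-1.0, 1.0], size=(m, 500))
        from htgp.relationships import MarkerMatrix, genomic_relationship
        K = genomic_relationship(MarkerMatrix(lines, calls))
        H = np.array([[1.0, 0.7], [0.7, 1.0]])
        R = np.diag([0.4, 0.6])
        L = np.linalg.cholesky(np.kron(H, K.values) + 1e-8 * np.eye(2 * m))
        ests = []
        for _ in range(3):
            a = L @ rng.normal(size=2 * m)
            recs = [
                dict(line=ln, trait=f"T{ti}",
                     value=a[ti * m + i] + rng.normal(0, np.sqrt(R[ti, ti])),
                     weight=1.0)
                for ti in range(2)
                for i, ln in enumerate(lines)
            ]
            fit = fit_multitrait(pd.DataFrame(recs), K, trait_order=["T0", "T1"])
            ests.append(fit.genetic_correlations().iloc[0, 1])
        assert abs(np.mean(ests) - 0.7) < 0.12
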