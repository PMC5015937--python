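"""BLUEs, validation BLUPs, heritabilities, genetic correlations."""

import numpy as np
import pandas as pd
import pytest

from htgp.genetics import (
    across_env_blues,
    environment_blues,
    environment_heritability,
    heritability,
    validation_blups,
)
from htgp.lmm import LMMError


def lattice_plots(genos=36, reps=3, trials=2, env="e", trait="GY", g_sd=1.0,
                  e_sd=0.5, trial_sd=0.7, env_shift=0.0, seed=0, checks=True):
    """Simple trial-series fixture; two check lines repeat in every trial."""
    rng = np.random.default_rng(seed)
    g = rng.normal(0, g_sd, genos)
    chk = (
        {"CHK1": float(rng.normal(0, g_sd)), "CHK2": float(rng.normal(0, g_sd))}
        if checks
        else {}
    )
    per_trial = genos // trials
    rows = []
    for t in range(trials):
        t_eff = rng.normal(0, trial_sd)
        members = [f"L{i:02d}" for i in range(t * per_trial, (t + 1) * per_trial)]
        members += list(chk)
        for r in range(reps):
            for j, ln in enumerate(members):
                gv = chk[ln] if ln in chk else g[int(ln[1:])]
                rows.append(
                    dict(line=ln, environment=env, trial=f"T{t}",
                         replicate=r + 1, block=(j % 6) + 1, date=np.nan,
                         trait=trait,
                         value=env_shift + t_eff + gv + rng.normal(0, e_sd),
                         lodging=0.0)
                )
    return pd.DataFrame(rows), pd.Series(g, index=[f"L{i:02d}" for i in range(genos)])


class TestEnvironmentBlues:
    def test_noiseless_recovers_genotype_deviation(self):
        plots, g = lattice_plots(e_sd=1e-9, trial_sd=0.0, seed=1)
        b = environment_blues(plots, "GY", "e")
        s = b.series().loc[g.index]
        dev_hat = s - s.mean()
        dev = g - g.mean()
        assert np.max(np.abs(dev_hat - dev)) < 1e-5

    def test_per_replicate_mode_record_accounting(self):
        plots, _ = lattice_plots()
        b = environment_blues(plots, "GY", "e", replicate=1)
        assert b.replicate_scope == "rep1"
        tab = b.table.set_index("line")
        entries = [s for s in tab.index if not s.startswith("CHK")]
        assert (tab.loc[entries, "weight"] == 1).all()
        assert (tab.loc[["CHK1", "CHK2"], "weight"] == 2).all()  # in both trials
        b3 = environment_blues(plots, "GY", "e").table.set_index("line")
        assert (b3.loc[entries, "weight"] == 3).all()

    def test_unbalanced_matches_gls_oracle(self):
        """One plot removed: BLUEs equal direct GLS at the REML components."""
        plots, _ = lattice_plots(genos=18, trials=1, seed=2)
        plots = plots.drop(index=4).reset_index(drop=True)
        b = environment_blues(plots, "GY", "e")
        from htgp.lmm import fit_lmm
        res = fit_lmm(plots, "value", cell_means="line",
                      random=["trial", "replicate:trial", "block:replicate:trial"])
        # direct GLS with the same components, built independently
        lines = sorted(plots["line"].unique())
        x = pd.get_dummies(plots["line"], dtype=float)[lines].to_numpy()
        zr = pd.get_dummies(plots["replicate"], dtype=float).to_numpy()
        zb = pd.get_dummies(
            plots["block"].astype(str) + "/" + plots["replicate"].astype(str),
            dtype=float).to_numpy()
        v = (res.varcomp["trial"] * np.ones((len(plots), len(plots)))
             + res.varcomp["replicate:trial"] * zr @ zr.T
             + res.varcomp["block:replicate:trial"] * zb @ zb.T
             + res.varcomp["residual"] * np.eye(len(plots)))
        vi = np.linalg.inv(v)
        beta = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ plots["value"].to_numpy())
        got = b.series().loc[lines].to_numpy()
        assert np.max(np.abs(got - beta)) < 1e-6

    def test_missing_trait_errors(self):
        plots, _ = lattice_plots()
        with pytest.raises(LMMError, match="no records"):
            environment_blues(plots, "CT-GF", "e")


class TestAcrossEnvBlues:
    def _two_env(self, shift=(0.0, 0.0), seed=3, checks=True):
        p1, g = lattice_plots(env="e1", env_shift=shift[0], seed=seed, checks=checks)
        p2, _ = lattice_plots(env="e2", env_shift=shift[1], seed=seed, checks=checks)
        p3, _ = lattice_plots(env="e3", env_shift=0.0, seed=seed + 1, checks=checks)
        return pd.concat([p1, p2, p3], ignore_index=True), g

    def test_environment_shift_invariance(self):
        """With every line equally replicated per environment, adding
        constant environment shifts leaves BLUE deviations untouched
        (checks excluded: their extra replication breaks the symmetry)."""
        plots0, _ = self._two_env(shift=(0.0, 0.0), checks=False)
        plots1, _ = self._two_env(shift=(10.0, -10.0), checks=False)
        b0 = across_env_blues(plots0, "GY", "e3")
        b1 = across_env_blues(plots1, "GY", "e3")
        d0 = b0.series() - b0.series().mean()
        d1 = b1.series() - b1.series().mean()
        assert np.max(np.abs((d1 - d0).to_numpy())) < 1e-6

    def test_exclusion_accounting(self):
        plots, _ = self._two_env()
        b = across_env_blues(plots, "GY", "e1")
        assert b.environment == "except:e1"
        with pytest.raises(LMMError, match="not present"):
            across_env_blues(plots, "GY", "nope")


class TestValidationBlups:
    def test_balanced_shrinkage_closed_form(self):
        plots, g = lattice_plots(trials=1, trial_sd=0.0, seed=5)
        v = validation_blups(plots, "e")
        from htgp.lmm import fit_lmm
        res = fit_lmm(plots, "value",
                      random=["line", "trial", "replicate:trial",
                              "block:replicate:trial"])
        assert abs(v.mean()) < 1e-8  # centered random effects
        assert np.corrcoef(v.loc[g.index], g)[0, 1] > 0.9

    def test_null_lodging_covariate_is_noop(self):
        plots, _ = lattice_plots(seed=6)  # lodging column all zero
        v0 = validation_blups(plots, "e")
        plots2 = plots.drop(columns=["lodging"])
        v1 = validation_blups(plots2, "e")
        assert np.allclose(v0.to_numpy(), v1.loc[v0.index].to_numpy(), atol=1e-9)

    def test_dthd_requires_records(self):
        plots, _ = lattice_plots()
        with pytest.raises(LMMError, match="DTHD"):
            validation_blups(plots, "e", dthd_corrected=True)

    def test_dthd_collinear_with_genotype_shrinks_blups(self):
        plots, g = lattice_plots(trials=1, trial_sd=0.0, e_sd=0.2, seed=7)
        lines = sorted(plots["line"].unique())
        gv = pd.concat([g, pd.Series(0.0, index=["CHK1", "CHK2"])])
        dthd = pd.DataFrame(
            dict(line=lines, environment="e", trial="T0", replicate=1,
                 block=1, date=np.nan, trait="DTHD",
                 value=[60 + 5 * gv[s] for s in lines], lodging=0.0)
        )
        both = pd.concat([plots, dthd], ignore_index=True)
        v_raw = validation_blups(both, "e", dthd_corrected=False)
        v_cor = validation_blups(both, "e", dthd_corrected=True)
        assert v_cor.abs().mean() < 0.2 * v_raw.abs().mean()


class TestHeritability:
    @pytest.mark.parametrize(
        "comp,ndate,nrep,h_plot,h_line",
        [
            (dict(s2_g=1.0, s2_e=1.0), 1, 1, np.sqrt(0.5), np.sqrt(0.5)),
            (dict(s2_g=1.0, s2_gd=1.0, s2_e=1.0), 2, 3, np.sqrt(0.5), np.sqrt(0.6)),
            (dict(s2_g=0.0, s2_e=1.0), 1, 3, 0.0, 0.0),
        ],
    )
    def test_formula_arithmetic(self, comp, ndate, nrep, h_plot, h_line):
        rec = heritability(comp, ndate, nrep)
        assert rec.h_plot == pytest.approx(h_plot, abs=1e-12)
        assert rec.h_line == pytest.approx(h_line, abs=1e-12)

    def test_zero_genetic_variance_flagged(self):
        rec = heritability(dict(s2_g=0.0, s2_e=1.0), 1, 3)
        assert rec.undefined

    def test_line_mean_at_least_plot(self, small_early_heat):
        plots = small_early_heat["plots"]
        for trait in ["GY", "CT-GF", "GNDVI-VEG"]:
            rec = environment_heritability(plots, trait, "early_heat")
            assert rec.h_line >= rec.h_plot - 1e-12
            assert 0 <= rec.h_plot <= 1 and 0 <= rec.h_line <= 1

    def test_round_trip_recovers_targets(self, small_early_heat):
        """Simulated heritability targets are recovered by the estimation
        pipeline (single replicate of the 20-rep acceptance check)."""
        plots = small_early_heat["plots"]
        cfg = small_early_heat["cfg"]
        for trait in ["GY", "CT-GF"]:
            target = cfg.h_targets["early_heat"][trait][0]
            rec = environment_heritability(plots, trait, "early_heat")
            assert rec.h_line == pytest.approx(target, abs=0.12)
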