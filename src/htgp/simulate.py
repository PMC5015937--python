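"""Simulation of a wheat multi-environment yield trial with HTP traits.

The generator emulates the structure of a CIMMYT-style trial series: inbred
lines grouped into trials of 30 entries (28 lines plus 2 repeated checks)
laid out as an alpha lattice with 3 replicates of 6 incomplete blocks,
grown in up to five environments (optimal, drought, severe drought, late
heat, early heat).  Secondary traits — canopy temperature (CT) and two
vegetation indices (GNDVI, RNDVI) — are measured on 1-5 dates per growth
stage (vegetative VEG, grain filling GF); grain yield (GY) is measured
once, and days to heading (DTHD) once on the first replicate only.

True breeding values follow a marker-effect model: biallelic markers are
dropped through a founder/biparental-cross/selfing pedigree, and marker
effects are drawn so the genetic correlation structure per environment
matches the preset targets, with an exchangeable between-environment
correlation.  Nuisance variances (trial, date, replicate, block) are fixed
design noise; genotype-by-date and residual variances are solved per trait
so the realized line-mean and single-plot heritabilities hit their targets
given the date and replicate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relationships import MarkerMatrix, Pedigree

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "scenario_presets",
    "default_config",
    "simulate_population",
    "simulate_trials",
    "simulate_dataset",
    "ENVIRONMENTS",
    "SECONDARY_TRAITS",
]

ENVIRONMENTS = ["optimal", "drought", "severe_drought", "late_heat", "early_heat"]
SECONDARY_TRAITS = [
    "CT-GF", "CT-VEG", "GNDVI-GF", "GNDVI-VEG", "RNDVI-GF", "RNDVI-VEG",
]
ALL_TRAITS = SECONDARY_TRAITS + ["GY", "DTHD"]

# square-root heritabilities (line-mean, single-plot), uncorrected for DTHD
H_TARGETS: dict[str, dict[str, tuple[float, float]]] = {
    "optimal": {
        "CT-GF": (0.93, 0.83), "CT-VEG": (0.88, 0.81), "GNDVI-GF": (0.97, 0.95),
        "GNDVI-VEG": (0.95, 0.93), "GY": (0.83, 0.66), "RNDVI-GF": (0.96, 0.93),
        "RNDVI-VEG": (0.94, 0.92),
    },
    "drought": {
        "CT-GF": (0.77, 0.68), "CT-VEG": (0.93, 0.83), "GNDVI-GF": (0.97, 0.94),
        "GNDVI-VEG": (0.75, 0.71), "GY": (0.92, 0.81), "RNDVI-GF": (0.97, 0.94),
        "RNDVI-VEG": (0.87, 0.85),
    },
    "severe_drought": {
        "CT-GF": (0.95, 0.86), "CT-VEG": (0.79, 0.60), "GNDVI-GF": (0.98, 0.95),
        "GNDVI-VEG": (0.53, 0.48), "GY": (0.97, 0.91), "RNDVI-GF": (0.97, 0.93),
        "RNDVI-VEG": (0.82, 0.79),
    },
    "late_heat": {
        "CT-GF": (0.81, 0.66), "CT-VEG": (0.76, 0.56), "GNDVI-GF": (0.97, 0.93),
        "GNDVI-VEG": (0.89, 0.75), "GY": (0.96, 0.89), "RNDVI-GF": (0.87, 0.82),
        "RNDVI-VEG": (0.95, 0.86),
    },
    "early_heat": {
        "CT-GF": (0.96, 0.88), "CT-VEG": (0.91, 0.85), "GNDVI-GF": (0.99, 0.97),
        "GNDVI-VEG": (0.95, 0.92), "GY": (0.91, 0.78), "RNDVI-GF": (0.98, 0.96),
        "RNDVI-VEG": (0.98, 0.96),
    },
}

# genetic correlations of secondary traits with GY, uncorrected for DTHD
GY_CORRELATIONS: dict[str, dict[str, float]] = {
    "optimal": {
        "CT-GF": -0.65, "CT-VEG": -0.50, "GNDVI-GF": 0.27, "GNDVI-VEG": 0.38,
        "RNDVI-GF": 0.33, "RNDVI-VEG": 0.33,
    },
    "drought": {
        "CT-GF": -0.59, "CT-VEG": -0.53, "GNDVI-GF": -0.29, "GNDVI-VEG": -0.41,
        "RNDVI-GF": -0.12, "RNDVI-VEG": -0.43,
    },
    "severe_drought": {
        "CT-GF": -0.41, "CT-VEG": 0.01, "GNDVI-GF": -0.54, "GNDVI-VEG": -0.62,
        "RNDVI-GF": -0.40, "RNDVI-VEG": -0.77,
    },
    "late_heat": {
        "CT-GF": -0.73, "CT-VEG": -0.66, "GNDVI-GF": 0.44, "GNDVI-VEG": -0.14,
        "RNDVI-GF": 0.34, "RNDVI-VEG": 0.47,
    },
    "early_heat": {
        "CT-GF": -0.70, "CT-VEG": -0.71, "GNDVI-GF": 0.71, "GNDVI-VEG": 0.61,
        "RNDVI-GF": 0.73, "RNDVI-VEG": 0.67,
    },
}

DTHD_GY_CORRELATION = {
    "optimal": 0.17, "drought": -0.49, "severe_drought": -0.71,
    "late_heat": -0.15, "early_heat": 0.72,
}

# measurement dates per growth stage (Jan-May flight calendar)
DATE_COUNTS: dict[str, dict[str, int]] = {
    "optimal": {"VEG": 5, "GF": 3},
    "drought": {"VEG": 3, "GF": 3},
    "severe_drought": {"VEG": 2, "GF": 5},
    "late_heat": {"VEG": 1, "GF": 2},
    "early_heat": {"VEG": 4, "GF": 3},
}

TRAIT_MEANS = {
    "CT-GF": 28.0, "CT-VEG": 24.0, "GNDVI-GF": 0.55, "GNDVI-VEG": 0.65,
    "RNDVI-GF": 0.60, "RNDVI-VEG": 0.70, "GY": 6.0, "DTHD": 80.0,
}


@dataclass
class SimulationConfig:
    """Stated world of the simulated trial series; defaults mirror the study."""

    n_lines: int = 560
    n_markers: int = 2000
    environments: list[str] = field(default_factory=lambda: list(ENVIRONMENTS))
    traits: list[str] = field(default_factory=lambda: list(ALL_TRAITS))
    entries_per_trial: int = 30
    n_checks: int = 2
    n_reps: int = 3
    n_blocks: int = 6
    h_targets: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {e: dict(v) for e, v in H_TARGETS.items()}
    )
    gy_correlations: dict[str, dict[str, float]] = field(
        default_factory=lambda: {e: dict(v) for e, v in GY_CORRELATIONS.items()}
    )
    dthd_gy_correlation: dict[str, float] = field(
        default_factory=lambda: dict(DTHD_GY_CORRELATION)
    )
    date_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {e: dict(v) for e, v in DATE_COUNTS.items()}
    )
    between_env_correlation: float = 0.5
    dthd_h_line: float = 0.95
    # nuisance variance scales relative to unit genetic variance
    var_trial: float = 0.5
    var_date: float = 1.0
    var_rep: float = 0.25
    var_block: float = 0.25
    lodging_prevalence: float = 0.3
    lodging_effect: float = -0.3
    n_selfing_generations: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.entries_per_trial != self.n_blocks * (
            self.entries_per_trial // self.n_blocks
        ):
            raise ValueError("entries_per_trial must be divisible by n_blocks")
        if "GY" not in self.traits:
            raise ValueError("trait panel must include GY")
        unknown = sorted(set(self.traits) - set(ALL_TRAITS))
        if unknown:
            raise ValueError(f"unknown traits: {unknown}")
        for env in self.environments:
            if env not in self.h_targets:
                raise ValueError(f"no heritability targets for environment '{env}'")
            for trait, (hl, hp) in self.h_targets[env].items():
                if not (0 < hl <= 1 and 0 < hp <= 1):
                    raise ValueError(f"heritability target out of (0,1]: {env}/{trait}")


@dataclass
class TruthRecord:
    values: pd.DataFrame  # columns: line, environment, trait, value
    variance_components: dict[tuple[str, str], dict[str, float]]
    correlation_bend: dict[str, float]

    def pivot(self, environment: str) -> pd.DataFrame:
        sub = self.values[self.values["environment"] == environment]
        return sub.pivot(index="line", columns="trait", values="value")


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def scenario_presets(name: str, **overrides) -> SimulationConfig:
    """Single-environment config with that environment's published targets."""
    if name not in ENVIRONMENTS:
        raise ValueError(f"unknown preset '{name}'; valid: {ENVIRONMENTS}")
    cfg = SimulationConfig(environments=[name], **overrides)
    cfg.validate()
    return cfg


def _nearest_pd_correlation(c: np.ndarray, floor: float = 1e-4) -> tuple[np.ndarray, float]:
    """Eigenvalue-floored correlation matrix and the largest entry adjustment."""
    w, v = np.linalg.eigh(0.5 * (c + c.T))
    if w[0] >= floor:
        return c, 0.0
    w = np.maximum(w, floor)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m, float(np.max(np.abs(m - c)))


def environment_trait_correlation(cfg: SimulationConfig, env: str) -> tuple[pd.DataFrame, float]:
    """Full trait correlation matrix for one environment.

    GY and DTHD rows come from the configured targets.  Correlations among
    secondary traits are not published as a full matrix, so a structural
    default is used: 0.6 within a trait family across stages, 0.5 between
    vegetation indices at the same stage, 0.3 across stages, and -0.4/-0.25
    between CT and the indices (same/different stage); DTHD gets +/-0.2 by
    family.  The result is bent to the nearest positive-definite
    correlation matrix (eigenvalue floor 1e-4) and the max adjustment is
    returned.
    """
    traits = list(cfg.traits)
    t = len(traits)
    c = np.eye(t)

    def family(tr: str) -> str:
        return tr.split("-")[0]

    def stage(tr: str) -> str:
        return tr.split("-")[1] if "-" in tr else ""

    for i in range(t):
        for j in range(i + 1, t):
            a, b = traits[i], traits[j]
            if "GY" in (a, b) and {a, b} <= set(SECONDARY_TRAITS + ["GY"]):
                other = a if b == "GY" else b
                val = cfg.gy_correlations[env][other]
            elif {a, b} == {"GY", "DTHD"}:
                val = cfg.dthd_gy_correlation[env]
            elif "DTHD" in (a, b):
                other = a if b == "DTHD" else b
                val = -0.2 if family(other) == "CT" else 0.2
            else:
                fa, fb, sa, sb = family(a), family(b), stage(a), stage(b)
                if fa == fb:
                    val = 0.6
                elif "CT" in (fa, fb):
                    val = -0.4 if sa == sb else -0.25
                else:
                    val = 0.5 if sa == sb else 0.3
            c[i, j] = c[j, i] = val
    bent, adj = _nearest_pd_correlation(c)
    return pd.DataFrame(bent, index=traits, columns=traits), adj


def simulate_population(
    cfg: SimulationConfig,
) -> tuple[MarkerMatrix, Pedigree, TruthRecord]:
    """Markers, pedigree and true genetic values for lines and checks.

    Founders are fully inbred with allele frequencies U(0.05, 0.95);
    each line descends from a biparental cross followed by
    ``n_selfing_generations`` of selfing (recorded in the pedigree), with
    marker genotypes drawn as fully inbred recombinant lines.  True genetic
    values are ``Z alpha`` with marker effects alpha drawn under the
    per-environment trait correlation targets, an exchangeable
    between-environment correlation, and are standardized to unit sample
    variance per (environment, trait).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_lines + cfg.n_checks
    n_founders = max(16, cfg.n_lines // 14)
    founders = [f"F{i:03d}" for i in range(n_founders)]
    line_names = [f"L{i:04d}" for i in range(cfg.n_lines)] + [
        f"CHECK{i + 1}" for i in range(cfg.n_checks)
    ]

    p_founder = rng.uniform(0.05, 0.95, cfg.n_markers)
    founder_geno = np.where(
        rng.random((n_founders, cfg.n_markers)) < p_founder, 1.0, -1.0
    )

    ped_rows: list[dict] = []
    for f in founders:
        ped_rows.append(dict(line=f, parent1=None, parent2=None))
    calls = np.empty((n_total, cfg.n_markers))
    for ix, name in enumerate(line_names):
        f1, f2 = rng.choice(n_founders, size=2, replace=False)
        prev = f"{name}.X0"
        ped_rows.append(dict(line=prev, parent1=founders[f1], parent2=founders[f2]))
        for g in range(1, cfg.n_selfing_generations):
            nxt = f"{name}.X{g}"
            ped_rows.append(dict(line=nxt, parent1=prev, parent2=prev))
            prev = nxt
        ped_rows.append(dict(line=name, parent1=prev, parent2=prev))
        pick = rng.random(cfg.n_markers) < 0.5
        calls[ix] = np.where(pick, founder_geno[f1], founder_geno[f2])
    pedigree = Pedigree(pd.DataFrame(ped_rows))
    markers = MarkerMatrix(line_names, calls)

    envs = cfg.environments
    corr_blocks, bends = [], {}
    for env in envs:
        cdf, adj = environment_trait_correlation(cfg, env)
        corr_blocks.append(cdf.to_numpy())
        bends[env] = adj
    t = len(cfg.traits)
    n_env = len(envs)
    chol_blocks = [np.linalg.cholesky(c) for c in corr_blocks]
    env_corr = np.full((n_env, n_env), cfg.between_env_correlation)
    np.fill_diagonal(env_corr, 1.0)
    # Sigma = Lbig (C_env (x) I_t) Lbig' keeps each within-environment block
    # exactly at its target correlation matrix
    l_big = np.zeros((n_env * t, n_env * t))
    for e in range(n_env):
        l_big[e * t:(e + 1) * t, e * t:(e + 1) * t] = chol_blocks[e]
    mid = np.kron(env_corr, np.eye(t))
    sigma = l_big @ mid @ l_big.T
    sig_chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n_env * t))

    alpha = rng.standard_normal((cfg.n_markers, n_env * t)) @ sig_chol.T
    z = calls - calls.mean(axis=0)
    values = z @ alpha  # n_total x (env*trait)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    values = values / sd  # unit realized genetic variance per column

    rows = []
    for e, env in enumerate(envs):
        for j, trait in enumerate(cfg.traits):
            col = values[:, e * t + j]
            for ix, name in enumerate(line_names):
                rows.append(
                    dict(line=name, environment=env, trait=trait, value=col[ix])
                )
    truth = TruthRecord(
        values=pd.DataFrame(rows), variance_components={}, correlation_bend=bends
    )
    return markers, pedigree, truth


def _solve_trait_variances(
    hl: float, hp: float, ndate: int, nrep: int, env: str, trait: str
) -> tuple[float, float]:
    """(s2_gd, s2_e) hitting the heritability targets at unit genetic variance.

    Single-date traits have no genotype-by-date term and match the
    line-mean target only (both targets cannot hold at once with one
    free variance).
    """
    hl2, hp2 = hl * hl, hp * hp
    if ndate <= 1:
        return 0.0, nrep * (1.0 / hl2 - 1.0)
    a = 1.0 / hp2 - 1.0  # s2_gd/ndate + s2_e/ndate
    b = 1.0 / hl2 - 1.0  # s2_gd/ndate + s2_e/(nrep*ndate)
    s2e = (a - b) * ndate / (1.0 - 1.0 / nrep)
    s2gd = ndate * a - s2e
    if s2e <= 0:
        raise ValueError(
            f"infeasible heritability targets for {env}/{trait}: "
            f"H_line={hl}, H_plot={hp} imply nonpositive residual variance"
        )
    if s2gd < 0:
        # printed-precision targets can be marginally inconsistent (H_plot
        # closer to H_line than any s2_gd >= 0 allows); match H_line exactly
        # and let H_plot land a rounding step high
        return 0.0, nrep * ndate * b
    return s2gd, s2e


def simulate_trials(cfg: SimulationConfig, truth: TruthRecord) -> pd.DataFrame:
    """Plot-level long table for all environments in the config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    lines = sorted(truth.values["line"].unique())
    checks = [s for s in lines if s.startswith("CHECK")]
    entries = [s for s in lines if not s.startswith("CHECK")]
    per_trial = cfg.entries_per_trial - cfg.n_checks
    n_trials = int(np.ceil(len(entries) / per_trial))
    block_size = cfg.entries_per_trial // cfg.n_blocks

    shuffled = list(rng.permutation(entries))
    trial_members = {
        f"T{k + 1:02d}": shuffled[k * per_trial:(k + 1) * per_trial] + checks
        for k in range(n_trials)
    }

    rows: list[dict] = []
    for env in cfg.environments:
        tv = truth.pivot(env)
        counts = cfg.date_counts[env]
        lodging_line = {}
        if env == "optimal" and cfg.lodging_prevalence > 0:
            for s in lines:
                lodging_line[s] = (
                    float(rng.uniform(1, 5))
                    if rng.random() < cfg.lodging_prevalence
                    else 0.0
                )
        for trait in cfg.traits:
            if trait in ("GY", "DTHD"):
                dates = ["single"]
                hl, hp = (
                    cfg.h_targets[env]["GY"]
                    if trait == "GY"
                    else (cfg.dthd_h_line, cfg.dthd_h_line)
                )
            else:
                stg = trait.split("-")[1]
                dates = [f"{stg}{i + 1}" for i in range(counts[stg])]
                hl, hp = cfg.h_targets[env][trait]
            nrep = 1 if trait == "DTHD" else cfg.n_reps
            s2gd, s2e = _solve_trait_variances(
                hl, hp, len(dates), nrep, env, trait
            )
            truth.variance_components[(env, trait)] = dict(
                s2_g=1.0, s2_gd=s2gd, s2_e=s2e, ndate=len(dates), nrep=nrep
            )
            date_eff = {d: rng.normal(0, np.sqrt(cfg.var_date)) for d in dates}
            gd_eff = {
                (s, d): rng.normal(0, np.sqrt(s2gd)) for s in lines for d in dates
            } if s2gd > 0 else {}
            for trial, members in trial_members.items():
                t_eff = rng.normal(0, np.sqrt(cfg.var_trial))
                for d in dates:
                    reps = range(1, nrep + 1)
                    for rep in reps:
                        r_eff = rng.normal(0, np.sqrt(cfg.var_rep))
                        b_eff = rng.normal(
                            0, np.sqrt(cfg.var_block), cfg.n_blocks
                        )
                        perm = rng.permutation(len(members))
                        for pos, mix in enumerate(perm):
                            s = members[mix]
                            blk = pos // block_size + 1
                            g = float(tv.loc[s, trait])
                            val = (
                                TRAIT_MEANS.get(trait, 0.0)
                                + t_eff
                                + date_eff[d]
                                + r_eff
                                + b_eff[blk - 1]
                                + g
                                + gd_eff.get((s, d), 0.0)
                                + rng.normal(0, np.sqrt(s2e))
                            )
                            lodg = lodging_line.get(s, 0.0) if env == "optimal" else 0.0
                            if trait == "GY":
                                val += cfg.lodging_effect * lodg
                            rows.append(
                                dict(
                                    line=s,
                                    environment=env,
                                    trial=trial,
                                    replicate=rep,
                                    block=blk,
                                    date="" if trait in ("GY", "DTHD") else d,
                                    trait=trait,
                                    value=val,
                                    lodging=lodg,
                                )
                            )
    plots = pd.DataFrame(rows)
    plots["date"] = plots["date"].replace("", np.nan)
    return plots


def simulate_dataset(cfg: SimulationConfig):
    """Convenience wrapper: population + trials in one call."""
    markers, pedigree, truth = simulate_population(cfg)
    plots = simulate_trials(cfg, truth)
    return markers, pedigree, truth, plots
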