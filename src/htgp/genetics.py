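"""Genetic value estimation: BLUEs, validation BLUPs, heritabilities and
genetic correlations.

Per environment, line BLUEs come from a mixed model with genotype fixed and
trial, measurement date, replicate-within-trial-and-date and incomplete
block as independent random effects.  Single-measure traits (GY) drop the
date term; DTHD (scored once on one replicate) also drops replicate and
block; per-replicate BLUEs drop replicate and block and use one replicate's
records, emulating selection candidates grown without replication.

Validation BLUPs treat genotype as iid random and add a lodging covariate
where lodging occurred, optionally also a days-to-heading covariate.

Square-root heritabilities on a single-plot and line-mean basis are::

    H_plot = sqrt(s2_g / (s2_g + s2_gd/ndate + s2_e/ndate))
    H_line = sqrt(s2_g / (s2_g + s2_gd/ndate + s2_e/(nrep*ndate)))

with ``ndate = 1`` and no genotype-by-date term for single-measure traits.
Genetic correlations come from the multi-trait model on BLUEs with a
pedigree or genomic kernel; when both kernels are supplied the two
estimates are averaged elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMError, fit_lmm
from .multitrait import fit_multitrait
from .relationships import RelationshipMatrix

__all__ = [
    "TraitBLUEs",
    "HeritabilityRecord",
    "environment_blues",
    "across_env_blues",
    "validation_blups",
    "heritability",
    "heritability_components",
    "genetic_correlation_matrix",
    "line_covariate",
]


@dataclass
class TraitBLUEs:
    trait: str
    environment: str  # one environment, or "except:<env>" for across-env
    table: pd.DataFrame  # columns: line, value, weight
    replicate_scope: str = "all"  # "all" or "rep<k>"

    def series(self) -> pd.Series:
        return self.table.set_index("line")["value"]


@dataclass
class HeritabilityRecord:
    environment: str
    trait: str
    h_plot: float
    h_line: float
    ndate: int
    nrep: int
    dthd_corrected: bool = False
    varcomp: dict[str, float] = field(default_factory=dict)
    undefined: bool = False


def _trait_slice(plots: pd.DataFrame, trait: str, environment: str | None) -> pd.DataFrame:
    mask = plots["trait"].astype(str) == str(trait)
    if environment is not None:
        mask &= plots["environment"].astype(str) == str(environment)
    sl = plots.loc[mask].copy()
    if not len(sl):
        raise LMMError(f"no records for trait '{trait}' in '{environment}'")
    return sl


def line_covariate(plots: pd.DataFrame, environment: str, trait: str = "DTHD") -> pd.Series:
    """Per-line covariate values (e.g. DTHD) as the mean over its records."""
    sl = _trait_slice(plots, trait, environment)
    return sl.groupby(sl["line"].astype(str))["value"].mean()


def _blue_random_terms(sl: pd.DataFrame, *, drop_rep_block: bool, env_nested: bool) -> list[str]:
    multi_date = sl["date"].notna().any() and sl["date"].nunique() > 1
    suffix = ":environment" if env_nested else ""
    terms = [("trial" + suffix)]
    if env_nested:
        terms.insert(0, "environment")
    if multi_date:
        terms.append("date" + suffix)
        if not drop_rep_block:
            terms.append("replicate:trial:date" + suffix)
            terms.append("block:replicate:trial:date" + suffix)
    elif not drop_rep_block:
        terms.append("replicate:trial" + suffix)
        terms.append("block:replicate:trial" + suffix)
    return terms


def environment_blues(
    plots: pd.DataFrame,
    trait: str,
    environment: str,
    *,
    replicate: int | None = None,
) -> TraitBLUEs:
    """Per-line fixed-effect estimates of one trait in one environment.

    ``replicate`` switches to per-replicate BLUEs: only that replicate's
    records enter and the replicate/block effects are dropped.  DTHD, being
    unreplicated, always uses the reduced model.
    """
    sl = _trait_slice(plots, trait, environment)
    single_rep = sl["replicate"].nunique() < 2
    if replicate is not None:
        sl = sl.loc[sl["replicate"].astype(int) == int(replicate)]
        if not len(sl):
            raise LMMError(f"no records in replicate {replicate} for {trait}/{environment}")
    drop_rep_block = replicate is not None or single_rep
    terms = _blue_random_terms(sl, drop_rep_block=drop_rep_block, env_nested=False)
    res = fit_lmm(sl, "value", cell_means="line", random=terms)
    est = {
        name[len("line[") : -1]: val
        for name, val in res.beta.items()
        if name.startswith("line[")
    }
    counts = sl.groupby(sl["line"].astype(str)).size()
    tab = pd.DataFrame(
        {
            "line": list(est),
            "value": [est[s] for s in est],
            "weight": [int(counts[s]) for s in est],
        }
    )
    scope = "all" if replicate is None else f"rep{replicate}"
    return TraitBLUEs(trait, environment, tab, replicate_scope=scope)


def across_env_blues(
    plots: pd.DataFrame, trait: str, excluded_environment: str
) -> TraitBLUEs:
    """BLUEs across all environments except one (the validation environment).

    Environment is random and every design effect is nested within
    environment; the genotype effect is fixed across environments.
    """
    envs = plots["environment"].astype(str).unique()
    if str(excluded_environment) not in set(envs):
        raise LMMError(f"environment '{excluded_environment}' not present")
    keep = plots["environment"].astype(str) != str(excluded_environment)
    if plots.loc[keep, "environment"].nunique() < 2:
        raise LMMError("need >=2 environments after exclusion")
    sl = _trait_slice(plots.loc[keep], trait, None)
    single_rep = sl["replicate"].nunique() < 2
    terms = _blue_random_terms(sl, drop_rep_block=single_rep, env_nested=True)
    res = fit_lmm(sl, "value", cell_means="line", random=terms)
    est = {
        name[len("line[") : -1]: val
        for name, val in res.beta.items()
        if name.startswith("line[")
    }
    counts = sl.groupby(sl["line"].astype(str)).size()
    tab = pd.DataFrame(
        {
            "line": list(est),
            "value": [est[s] for s in est],
            "weight": [int(counts[s]) for s in est],
        }
    )
    return TraitBLUEs(trait, f"except:{excluded_environment}", tab)


def validation_blups(
    plots: pd.DataFrame,
    environment: str,
    *,
    trait: str = "GY",
    dthd_corrected: bool = False,
) -> pd.Series:
    """Genotype BLUPs of grain yield used as the cross-validation target.

    Genotype is iid random; trial, replicate-within-trial and block are
    random; lodging enters as a fixed covariate wherever it was scored, and
    ``dthd_corrected`` adds a per-line days-to-heading covariate.
    """
    sl = _trait_slice(plots, trait, environment).copy()
    fixed: list[str] = []
    if "lodging" in sl.columns and np.nan_to_num(sl["lodging"].to_numpy(float)).any():
        fixed.append("lodging")
    if dthd_corrected:
        dthd = line_covariate(plots, environment, "DTHD")
        sl["DTHD_cov"] = sl["line"].astype(str).map(dthd)
        if sl["DTHD_cov"].isna().any():
            missing = sorted(sl.loc[sl["DTHD_cov"].isna(), "line"].unique())
            raise LMMError(f"no DTHD records for lines: {missing[:10]}")
        fixed.append("DTHD_cov")
    terms = ["line", "trial", "replicate:trial", "block:replicate:trial"]
    res = fit_lmm(sl, "value", fixed=fixed, random=terms)
    return res.blups["line"].rename("GY_blup")


def heritability_components(
    plots: pd.DataFrame,
    trait: str,
    environment: str,
    *,
    dthd_corrected: bool = False,
) -> tuple[dict[str, float], int, int]:
    """Variance components for heritability: genotype random + genotype-by-date."""
    sl = _trait_slice(plots, trait, environment).copy()
    multi_date = sl["date"].notna().any() and sl["date"].nunique() > 1
    ndate = int(sl["date"].nunique()) if multi_date else 1
    nrep = int(sl["replicate"].nunique())
    fixed: list[str] = []
    if (
        trait == "GY"
        and "lodging" in sl.columns
        and np.nan_to_num(sl["lodging"].to_numpy(float)).any()
    ):
        fixed.append("lodging")
    if dthd_corrected:
        dthd = line_covariate(plots, environment, "DTHD")
        sl["DTHD_cov"] = sl["line"].astype(str).map(dthd)
        fixed.append("DTHD_cov")
    terms = ["line", "trial"]
    if multi_date:
        terms += ["date", "replicate:trial:date", "block:replicate:trial:date", "line:date"]
    elif nrep > 1:
        terms += ["replicate:trial", "block:replicate:trial"]
    res = fit_lmm(sl, "value", fixed=fixed, random=terms)
    out = {
        "s2_g": res.varcomp["line"],
        "s2_gd": res.varcomp.get("line:date", 0.0),
        "s2_e": res.varcomp["residual"],
    }
    return out, ndate, nrep


def heritability(
    components: dict[str, float],
    ndate: int,
    nrep: int,
    *,
    environment: str = "",
    trait: str = "",
    dthd_corrected: bool = False,
) -> HeritabilityRecord:
    """Square-root heritabilities on single-plot and line-mean bases."""
    s2g = max(components.get("s2_g", 0.0), 0.0)
    s2gd = max(components.get("s2_gd", 0.0), 0.0) if ndate > 1 else 0.0
    s2e = max(components.get("s2_e", 0.0), 0.0)
    if s2g <= 0 and s2gd <= 0 and s2e <= 0:
        return HeritabilityRecord(
            environment, trait, 0.0, 0.0, ndate, nrep,
            dthd_corrected=dthd_corrected, varcomp=dict(components), undefined=True,
        )
    denom_plot = s2g + s2gd / ndate + s2e / ndate
    denom_line = s2g + s2gd / ndate + s2e / (nrep * ndate)
    h_plot = np.sqrt(s2g / denom_plot) if denom_plot > 0 else 0.0
    h_line = np.sqrt(s2g / denom_line) if denom_line > 0 else 0.0
    return HeritabilityRecord(
        environment, trait, float(h_plot), float(h_line), ndate, nrep,
        dthd_corrected=dthd_corrected, varcomp=dict(components),
        undefined=bool(s2g <= 0),
    )


def environment_heritability(
    plots: pd.DataFrame, trait: str, environment: str, *, dthd_corrected: bool = False
) -> HeritabilityRecord:
    comp, ndate, nrep = heritability_components(
        plots, trait, environment, dthd_corrected=dthd_corrected
    )
    return heritability(
        comp, ndate, nrep, environment=environment, trait=trait,
        dthd_corrected=dthd_corrected,
    )


def genetic_correlation_matrix(
    blues: dict[str, TraitBLUEs],
    kernels: list[RelationshipMatrix],
    *,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    max_iter: int = 200,
) -> pd.DataFrame:
    """Genetic correlation table from multi-trait fits, averaged over kernels.

    ``covariates`` is an optional per-line frame (index = line) whose
    columns named in ``covariate_names`` enter every trait's fixed design
    (lodging, DTHD).  If the joint fit fails to converge for a kernel, the
    corresponding entries fall back to pairwise bivariate fits.
    """
    traits = list(blues)
    long = pd.concat(
        [
            b.table.assign(trait=name)[["line", "trait", "value", "weight"]]
            for name, b in blues.items()
        ],
        ignore_index=True,
    )
    fixed = None
    if covariates is not None and covariate_names:
        for c in covariate_names:
            long[c] = long["line"].astype(str).map(covariates[c])
        long = long.dropna(subset=covariate_names)
        fixed = list(covariate_names)

    per_kernel: list[pd.DataFrame] = []
    for kern in kernels:
        sub = kern.submatrix(sorted(long["line"].astype(str).unique()))
        try:
            fit = fit_multitrait(
                long, sub, trait_order=traits, fixed=fixed, max_iter=max_iter
            )
            corr = fit.genetic_correlations()
        except LMMError:
            corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
            for i, a in enumerate(traits):
                for j in range(i + 1, len(traits)):
                    b = traits[j]
                    pair = long[long["trait"].isin([a, b])]
                    try:
                        bi = fit_multitrait(
                            pair, sub, trait_order=[a, b], fixed=fixed,
                            max_iter=max_iter,
                        )
                        val = bi.genetic_correlations().iloc[0, 1]
                    except LMMError:
                        val = np.nan
                    corr.loc[a, b] = corr.loc[b, a] = val
        per_kernel.append(corr)
    avg = sum(c.to_numpy() for c in per_kernel) / len(per_kernel)
    return pd.DataFrame(avg, index=traits, columns=traits)
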