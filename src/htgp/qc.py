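"""Quality control of plot-level high-throughput phenotypes.

Within each trial (within environment) and for each trait, repeatability is
estimated from variance components of small mixed models:

* single date:  y = mu + genotype + replicate + residual, all random;
  ``r2 = s2_g / (s2_g + s2_e / nrep)``
* across dates: y = mu + genotype + date + replicate(date) +
  genotype.date + residual;
  ``r2_overall = s2_g / (s2_g + s2_gd / ndate + s2_e / (nrep * ndate))``

Records with a two-sided Studentized-residual p-value below ``alpha`` are
removed once and the model refit.  Dates whose single-date repeatability
falls below the threshold are dropped (greedily, worst first) when dropping
them improves overall repeatability, and trials where any trait ends below
the threshold are removed entirely.

``nrep`` and ``ndate`` are the realized counts in each slice, so unbalanced
slices after outlier removal use the correct divisors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import LMMError, fit_lmm, studentized_residuals

__all__ = [
    "RepeatabilityRecord",
    "QCReport",
    "within_date_repeatability",
    "overall_repeatability",
    "studentized_outlier_removal",
    "qc_pipeline",
    "apply_stage_map",
]

BASE_SECONDARY_TRAITS = ("CT", "GNDVI", "RNDVI")


@dataclass
class RepeatabilityRecord:
    trial: str
    trait: str
    scope: str  # "single_date" or "overall"
    r2: float
    varcomp: dict[str, float]
    ndate: int
    nrep: int
    date: str | None = None
    environment: str | None = None
    converged: bool = True


@dataclass
class QCReport:
    outliers: pd.DataFrame = field(default_factory=pd.DataFrame)
    dates_dropped: list[dict] = field(default_factory=list)
    trials_dropped: list[dict] = field(default_factory=list)
    repeatabilities: list[RepeatabilityRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                environment=r.environment,
                trial=r.trial,
                trait=r.trait,
                scope=r.scope,
                date=r.date,
                r2=r.r2,
                ndate=r.ndate,
                nrep=r.nrep,
            )
            for r in self.repeatabilities
        ]
        return pd.DataFrame(rows)


def _slice(
    plots: pd.DataFrame,
    trial,
    trait,
    date=None,
    environment=None,
) -> pd.DataFrame:
    mask = (plots["trial"].astype(str) == str(trial)) & (
        plots["trait"].astype(str) == str(trait)
    )
    if environment is not None:
        mask &= plots["environment"].astype(str) == str(environment)
    if date is not None:
        mask &= plots["date"].astype(str) == str(date)
    return plots.loc[mask]


def within_date_repeatability(
    plots: pd.DataFrame,
    trial,
    trait,
    date=None,
    *,
    environment=None,
) -> RepeatabilityRecord:
    """Repeatability of a single (trial, trait, date) slice."""
    sl = _slice(plots, trial, trait, date, environment)
    nrep = sl["replicate"].nunique()
    if nrep < 2:
        raise LMMError(
            f"trial {trial} trait {trait} date {date}: need >=2 replicates, have {nrep}"
        )
    try:
        res = fit_lmm(sl, "value", random=["line", "replicate"])
    except LMMError:
        return RepeatabilityRecord(
            str(trial), str(trait), "single_date", float("nan"), {},
            1, nrep, date=None if date is None else str(date),
            environment=environment, converged=False,
        )
    s2g = res.varcomp["line"]
    s2e = res.varcomp["residual"]
    r2 = s2g / (s2g + s2e / nrep) if (s2g + s2e) > 0 else 0.0
    return RepeatabilityRecord(
        str(trial), str(trait), "single_date", float(r2),
        {"s2_g": s2g, "s2_r": res.varcomp["replicate"], "s2_e": s2e},
        1, nrep, date=None if date is None else str(date),
        environment=environment,
    )


def overall_repeatability(
    plots: pd.DataFrame,
    trial,
    trait,
    *,
    environment=None,
) -> RepeatabilityRecord:
    """Across-date repeatability; requires at least two measurement dates."""
    sl = _slice(plots, trial, trait, None, environment)
    ndate = sl["date"].nunique()
    if ndate < 2:
        raise LMMError(
            f"trial {trial} trait {trait}: single date; use within_date_repeatability"
        )
    nrep = sl["replicate"].nunique()
    try:
        res = fit_lmm(
            sl, "value", random=["line", "date", "replicate:date", "line:date"]
        )
    except LMMError:
        return RepeatabilityRecord(
            str(trial), str(trait), "overall", float("nan"), {},
            ndate, nrep, environment=environment, converged=False,
        )
    s2g = res.varcomp["line"]
    s2gd = res.varcomp["line:date"]
    s2e = res.varcomp["residual"]
    denom = s2g + s2gd / ndate + s2e / (nrep * ndate)
    r2 = s2g / denom if denom > 0 else 0.0
    return RepeatabilityRecord(
        str(trial), str(trait), "overall", float(r2),
        {
            "s2_g": s2g,
            "s2_d": res.varcomp["date"],
            "s2_r": res.varcomp["replicate:date"],
            "s2_gd": s2gd,
            "s2_e": s2e,
        },
        ndate, nrep, environment=environment,
    )


def studentized_outlier_removal(
    sl: pd.DataFrame,
    *,
    alpha: float = 0.001,
    random=("line", "replicate"),
    external: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One remove-and-refit pass on a slice; returns (cleaned, removed)."""
    try:
        res = fit_lmm(sl, "value", random=list(random))
    except LMMError:
        return sl, sl.iloc[0:0]
    if res.resid_df < 2:
        return sl, sl.iloc[0:0]
    finite = sl.loc[np.isfinite(pd.to_numeric(sl["value"], errors="coerce"))]
    _, pvals = studentized_residuals(res, external=external)
    bad = pvals < alpha
    if not bad.any():
        return sl, sl.iloc[0:0]
    removed = finite.iloc[np.where(bad)[0]]
    cleaned = sl.drop(index=removed.index)
    return cleaned, removed


def qc_pipeline(
    plots: pd.DataFrame,
    *,
    r2_threshold: float = 0.01,
    alpha: float = 0.001,
    remove_outliers: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC: outliers, low-repeatability dates, low-repeatability trials.

    Traits are expected to be grouped into growth-stage traits already
    (``apply_stage_map``).  Single-date traits use their within-date
    repeatability wherever the overall value is called for.
    """
    report = QCReport()
    work = plots.copy()
    removed_frames: list[pd.DataFrame] = []
    kept_parts: list[pd.DataFrame] = []
    bad_trials: set[tuple[str, str]] = set()

    env_col = work["environment"].astype(str)
    trial_col = work["trial"].astype(str)
    trait_col = work["trait"].astype(str)
    grouped = work.groupby([env_col, trial_col, trait_col], sort=True)
    for (env, trial, trait), sub in grouped:
        if sub["replicate"].nunique() < 2:
            kept_parts.append(sub)  # unreplicated traits (DTHD) pass through
            continue
        dates = sorted(sub["date"].dropna().astype(str).unique())
        multi_date = len(dates) >= 2
        date_r2: dict[str | None, float] = {}
        clean_parts: list[pd.DataFrame] = []
        for date in dates if dates else [None]:
            sl = (
                sub[sub["date"].astype(str) == date]
                if date is not None
                else sub
            )
            if remove_outliers:
                sl, rem = studentized_outlier_removal(sl, alpha=alpha)
                if len(rem):
                    removed_frames.append(rem)
            rec = within_date_repeatability(sl, trial, trait, date, environment=env)
            report.repeatabilities.append(rec)
            date_r2[date] = rec.r2
            clean_parts.append(sl)
        sub = pd.concat(clean_parts)
        if multi_date:
            overall = overall_repeatability(sub, trial, trait, environment=env)
            report.repeatabilities.append(overall)
            best_r2 = overall.r2
            low_dates = sorted(
                [d for d in dates if not (date_r2.get(d, 1.0) >= r2_threshold)],
                key=lambda d: (np.nan_to_num(date_r2[d], nan=-1.0)),
            )
            kept = list(dates)
            for d in low_dates:
                if len(kept) < 3:
                    break  # the across-date model needs >=2 dates
                cand_sub = sub[sub["date"].astype(str) != d]
                cand = overall_repeatability(cand_sub, trial, trait, environment=env)
                if np.isfinite(cand.r2) and (
                    not np.isfinite(best_r2) or cand.r2 > best_r2
                ):
                    sub = cand_sub
                    report.dates_dropped.append(
                        dict(
                            environment=env, trial=trial, trait=trait, date=d,
                            r2_date=date_r2[d], r2_before=best_r2,
                            r2_after=cand.r2,
                        )
                    )
                    kept.remove(d)
                    best_r2 = cand.r2
            final_r2 = best_r2
        else:
            final_r2 = next(iter(date_r2.values()))
        if not np.isfinite(final_r2) or final_r2 < r2_threshold:
            bad_trials.add((env, trial))
            report.trials_dropped.append(
                dict(environment=env, trial=trial, trait=trait, r2=final_r2)
            )
        kept_parts.append(sub)

    cleaned = (
        pd.concat(kept_parts).sort_index() if kept_parts else work.iloc[0:0]
    )
    if bad_trials:
        key = list(
            zip(
                cleaned["environment"].astype(str),
                cleaned["trial"].astype(str),
            )
        )
        mask = [k not in bad_trials for k in key]
        cleaned = cleaned.loc[mask]
    report.outliers = (
        pd.concat(removed_frames) if removed_frames else plots.iloc[0:0]
    )
    return cleaned.reset_index(drop=True), report


def apply_stage_map(plots: pd.DataFrame, stage_map: pd.DataFrame) -> pd.DataFrame:
    """Rename secondary traits by growth stage and drop excluded dates.

    ``stage_map`` has columns (environment, date, stage) with stage in
    {VEG, GF, excluded}; secondary traits become e.g. ``CT-VEG``.  Traits
    outside :data:`BASE_SECONDARY_TRAITS` pass through untouched.
    """
    need = {"environment", "date", "stage"} - set(stage_map.columns)
    if need:
        raise ValueError(f"stage map missing columns: {sorted(need)}")
    out = plots.copy()
    key = out["environment"].astype(str) + "\x1f" + out["date"].astype(str)
    lookup = {
        f"{e}\x1f{d}": s
        for e, d, s in stage_map[["environment", "date", "stage"]].astype(str).itertuples(index=False)
    }
    stage = key.map(lookup)
    is_secondary = out["trait"].astype(str).isin(BASE_SECONDARY_TRAITS)
    drop = is_secondary & (stage.isna() | (stage.str.lower() == "excluded"))
    out = out.loc[~drop].copy()
    stage = stage.loc[out.index]
    sec = out["trait"].astype(str).isin(BASE_SECONDARY_TRAITS)
    out.loc[sec, "trait"] = out.loc[sec, "trait"].astype(str) + "-" + stage[sec]
    return out.reset_index(drop=True)
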