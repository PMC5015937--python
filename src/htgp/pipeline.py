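"""End-to-end orchestration: from a QC'd plot table and kernels to
cross-validated accuracies and the accuracy-gain regression inputs.

These helpers glue the per-module operations together the way the full
analysis runs: estimate training BLUEs (within one environment or across
all others), validation BLUPs and the line-mean selection accuracy, then
cross-validate univariate and multi-trait prediction for each kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import (
    TraitBLUEs,
    across_env_blues,
    environment_blues,
    environment_heritability,
    line_covariate,
    validation_blups,
)
from .lmm import LMMError
from .validation import (
    AccuracyResult,
    FoldAssignment,
    PredictionData,
    PredictionTask,
    cross_validate,
)
from .relationships import RelationshipMatrix

__all__ = [
    "prepare_environment_data",
    "accuracy_grid",
    "gain_table_from_grid",
    "DEFAULT_SECONDARY",
]

DEFAULT_SECONDARY = [
    "CT-GF", "CT-VEG", "GNDVI-GF", "GNDVI-VEG", "RNDVI-GF", "RNDVI-VEG",
]


def line_covariates(plots: pd.DataFrame, environment: str) -> pd.DataFrame:
    """Per-line lodging (mean over GY plots) and DTHD covariates."""
    out = {}
    gy = plots[
        (plots["trait"] == "GY")
        & (plots["environment"].astype(str) == str(environment))
    ]
    if "lodging" in gy.columns and len(gy):
        out["lodging"] = gy.groupby(gy["line"].astype(str))["lodging"].mean()
    try:
        out["DTHD"] = line_covariate(plots, environment, "DTHD")
    except LMMError:
        pass
    return pd.DataFrame(out)


def prepare_environment_data(
    plots: pd.DataFrame,
    environment: str,
    *,
    secondary_traits: list[str] | None = None,
    scope: str = "within",
    dthd_corrected: bool = False,
    include_1rep: bool = True,
) -> PredictionData:
    """Assemble the per-environment data bundle for cross-validation.

    ``scope="within"`` trains on the environment's own BLUEs;
    ``scope="across"`` trains on BLUEs pooled over all other environments
    (validation stays in the target environment either way).  Secondary
    single-replicate BLUEs come from replicate 1, emulating selection
    candidates grown in unreplicated plots.
    """
    if secondary_traits is None:
        secondary_traits = [
            t for t in DEFAULT_SECONDARY
            if t in set(plots["trait"].astype(str))
        ]
    if scope == "within":
        gy = environment_blues(plots, "GY", environment)
        sec = {
            t: environment_blues(plots, t, environment) for t in secondary_traits
        }
        sec1 = (
            {
                t: environment_blues(plots, t, environment, replicate=1)
                for t in secondary_traits
            }
            if include_1rep
            else {}
        )
    elif scope == "across":
        gy = across_env_blues(plots, "GY", environment)
        sec = {
            t: across_env_blues(plots, t, environment) for t in secondary_traits
        }
        rep1 = plots[plots["replicate"].astype(int) == 1]
        sec1 = (
            {t: across_env_blues(rep1, t, environment) for t in secondary_traits}
            if include_1rep
            else {}
        )
    else:
        raise ValueError(f"unknown scope '{scope}'")
    validation = validation_blups(plots, environment, dthd_corrected=dthd_corrected)
    h_line = environment_heritability(
        plots, "GY", environment, dthd_corrected=dthd_corrected
    ).h_line
    return PredictionData(
        environment=environment,
        gy_blues=gy,
        secondary=sec,
        secondary_1rep=sec1,
        validation=validation,
        h_line=h_line,
        covariates=line_covariates(plots, environment),
    )


@dataclass
class GridEntry:
    environment: str
    kernel: str
    secondary_mode: str
    dthd_corrected: bool
    scope: str
    result: AccuracyResult


def accuracy_grid(
    data: PredictionData,
    folds: FoldAssignment,
    kernels: dict[str, RelationshipMatrix],
    *,
    secondary_modes: tuple[str, ...] = ("none", "1rep", "3rep"),
    dthd_corrected: bool = False,
    scope: str = "within",
    max_iter: int = 200,
) -> list[GridEntry]:
    """Univariate and multivariate accuracy for every kernel in one environment."""
    out: list[GridEntry] = []
    for kind in kernels:
        for mode in secondary_modes:
            task = PredictionTask(
                kernel_kind=kind, secondary_mode=mode,
                dthd_corrected=dthd_corrected, scope=scope,
            )
            res = cross_validate(task, folds, data, kernels, max_iter=max_iter)
            out.append(
                GridEntry(
                    data.environment, kind, mode, dthd_corrected, scope, res
                )
            )
    return out


def grid_frame(entries: list[GridEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                environment=e.environment,
                kernel=e.kernel,
                secondary_mode=e.secondary_mode,
                dthd_corrected=e.dthd_corrected,
                scope=e.scope,
                r_p_mean=e.result.r_p_mean,
                h_line=e.result.h_line,
                r_g=e.result.r_g,
                se=e.result.se,
            )
            for e in entries
        ]
    )


def gain_table_from_grid(
    grid: pd.DataFrame,
    secondary_h: pd.DataFrame,
    gy_correlations: pd.DataFrame,
) -> pd.DataFrame:
    """Model-(7)-style gain table from a within-environment accuracy grid.

    ``secondary_h``: columns (environment, trait, h_line, h_plot);
    ``gy_correlations``: columns (environment, trait, r_g).  H-bar uses the
    line-mean basis for replicated secondary traits and the single-plot
    basis otherwise.
    """
    rows = []
    uv = grid[grid["secondary_mode"] == "none"].set_index(["environment", "kernel"])
    for (env, kern, mode), sub in grid[grid["secondary_mode"] != "none"].groupby(
        ["environment", "kernel", "secondary_mode"]
    ):
        basis = "h_line" if mode == "3rep" else "h_plot"
        h_env = secondary_h[secondary_h["environment"] == env]
        r_env = gy_correlations[gy_correlations["environment"] == env]
        rows.append(
            dict(
                kernel=kern,
                environment=env,
                secondary_mode=mode,
                h_bar=float(h_env[basis].mean()),
                r_bar=float(r_env["r_g"].abs().mean()),
                gain=float(sub["r_g"].iloc[0] - uv.loc[(env, kern), "r_g"]),
            )
        )
    return pd.DataFrame(rows)
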