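"""Genomic and pedigree relationship matrices for inbred breeding lines.

Markers are biallelic calls coded -1 (homozygous minor), 0 (heterozygous)
and 1 (homozygous major), with NaN for missing.  The genomic kernel is the
allele-frequency-scaled cross product G = Z Z' / (2 * sum_j p_j (1 - p_j))
with Z the column-centered call matrix.  The pedigree kernel is the additive
(numerator) relationship matrix, i.e. twice the coefficient of parentage,
built with the tabular method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Pedigree",
    "RelationshipMatrix",
    "MarkerFilterReport",
    "filter_and_impute_markers",
    "genomic_relationship",
    "pedigree_relationship",
]


class RelationshipError(ValueError):
    """Raised when a kernel or its inputs violate a structural invariant."""


@dataclass
class MarkerMatrix:
    """Lines x markers call matrix.

    ``calls`` is a float array; NaN marks missing genotypes.  Values are
    in {-1, 0, 1} before imputation and in [-1, 1] afterwards.
    """

    line_ids: list[str]
    calls: np.ndarray
    marker_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.line_ids):
            raise RelationshipError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} line ids"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            dups = pd.Series(self.line_ids)
            dups = sorted(dups[dups.duplicated()].unique())
            raise RelationshipError(f"duplicate line IDs: {dups}")
        if not self.marker_ids:
            self.marker_ids = [f"M{j}" for j in range(self.calls.shape[1])]
        elif len(self.marker_ids) != self.calls.shape[1]:
            raise RelationshipError("marker_ids length does not match calls")

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


@dataclass
class Pedigree:
    """Parentage records; empty-string or None parent means unknown."""

    records: pd.DataFrame  # columns: line, parent1, parent2

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, copy=True)
        missing = {"line", "parent1", "parent2"} - set(df.columns)
        if missing:
            raise RelationshipError(f"pedigree missing columns: {sorted(missing)}")
        for c in ("line", "parent1", "parent2"):
            df[c] = df[c].astype(object)
            df.loc[df[c].isna() | (df[c] == ""), c] = None
            df[c] = df[c].map(lambda v: None if v is None else str(v))
        if df["line"].duplicated().any():
            dups = sorted(df.loc[df["line"].duplicated(), "line"].unique())
            raise RelationshipError(f"duplicate pedigree records for: {dups}")
        self.records = df.reset_index(drop=True)
        self._check_acyclic()

    def parents(self) -> Mapping[str, tuple[str | None, str | None]]:
        out: dict[str, tuple[str | None, str | None]] = {}
        for line, p1, p2 in self.records.itertuples(index=False):
            out[line] = (p1, p2)
        return out

    def _check_acyclic(self) -> None:
        parents = self.parents()
        WHITE, GREY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(node: str, stack: list[str]) -> None:
            color[node] = GREY
            stack.append(node)
            for p in parents.get(node, (None, None)):
                if p is None:
                    continue
                c = color.get(p, WHITE)
                if c == GREY:
                    cycle = stack[stack.index(p):] + [p]
                    raise RelationshipError(
                        "pedigree cycle: " + " -> ".join(cycle)
                    )
                if c == WHITE:
                    visit(p, stack)
            stack.pop()
            color[node] = BLACK

        for line in parents:
            if color.get(line, WHITE) == WHITE:
                visit(line, [])


@dataclass
class RelationshipMatrix:
    """Symmetric kernel over an ordered set of line IDs."""

    line_ids: list[str]
    values: np.ndarray
    kind: str = "G"  # one of {"A", "G", "I"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(s) for s in self.line_ids]
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise RelationshipError(
                f"kernel shape {self.values.shape} does not match {n} ids"
            )
        asym = float(np.max(np.abs(self.values - self.values.T))) if n else 0.0
        if asym > 1e-8:
            raise RelationshipError(f"kernel asymmetric (max |K-K'| = {asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)

    @classmethod
    def identity(cls, line_ids: Sequence[str]) -> "RelationshipMatrix":
        return cls(list(line_ids), np.eye(len(line_ids)), kind="I")

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        index = {s: i for i, s in enumerate(self.line_ids)}
        missing = [s for s in ids if str(s) not in index]
        if missing:
            raise RelationshipError(f"lines absent from {self.kind} kernel: {missing[:10]}")
        idx = np.array([index[str(s)] for s in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def check_psd(self, tol_scale: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -tol_scale * max(w[-1], 1.0):
            raise RelationshipError(
                f"kernel not PSD: min eigenvalue {w[0]:.3g} vs max {w[-1]:.3g}"
            )


@dataclass
class MarkerFilterReport:
    """Counts of markers/lines removed at each QC step, in application order."""

    markers_missing_initial: int = 0
    markers_heterozygous: int = 0
    lines_missing: int = 0
    markers_maf: int = 0
    markers_missing_subset: int = 0
    n_markers_out: int = 0
    n_lines_out: int = 0


def _minor_allele_frequency(calls: np.ndarray) -> np.ndarray:
    """Per-marker MAF from -1/0/1 calls, ignoring missing."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(calls, axis=0)
    p_major = (mean + 1.0) / 2.0
    return np.minimum(p_major, 1.0 - p_major)


def filter_and_impute_markers(
    raw: MarkerMatrix,
    keep_ids: Iterable[str] | None = None,
    *,
    max_missing: float = 0.80,
    max_het: float = 0.20,
    min_maf: float = 0.01,
) -> tuple[MarkerMatrix, MarkerFilterReport]:
    """Marker QC and marker-mean imputation.

    Steps, in order: (a) drop markers with more than ``max_missing`` missing
    or more than ``max_het`` heterozygous calls; (b) drop lines with more
    than ``max_missing`` missing; (c) subset to ``keep_ids``; (d) drop
    markers with MAF below ``min_maf`` or missingness above ``max_missing``
    on the subset; (e) impute remaining missing calls with the marker mean.
    Thresholds are strict inequalities ("did not exceed").
    """
    calls = raw.calls.copy()
    bad = (~np.isin(calls, (-1.0, 0.0, 1.0))) & ~np.isnan(calls)
    if bad.any():
        raise RelationshipError("raw marker calls must be in {-1, 0, 1, NaN}")
    report = MarkerFilterReport()

    n_lines = calls.shape[0]
    miss_frac = np.isnan(calls).mean(axis=0)
    het_frac = (calls == 0.0).sum(axis=0) / n_lines
    keep_m = (miss_frac <= max_missing) & (het_frac <= max_het)
    report.markers_missing_initial = int((miss_frac > max_missing).sum())
    report.markers_heterozygous = int(
        ((het_frac > max_het) & (miss_frac <= max_missing)).sum()
    )
    calls = calls[:, keep_m]
    marker_ids = [m for m, k in zip(raw.marker_ids, keep_m) if k]

    line_miss = np.isnan(calls).mean(axis=1) if calls.shape[1] else np.zeros(n_lines)
    keep_l = line_miss <= max_missing
    report.lines_missing = int((~keep_l).sum())
    calls = calls[keep_l]
    line_ids = [s for s, k in zip(raw.line_ids, keep_l) if k]

    if keep_ids is not None:
        wanted = [str(s) for s in keep_ids]
        index = {s: i for i, s in enumerate(line_ids)}
        absent = [s for s in wanted if s not in index]
        if absent:
            raise RelationshipError(
                f"keep_ids absent from marker matrix (or dropped by line QC): {absent[:10]}"
            )
        calls = calls[[index[s] for s in wanted]]
        line_ids = wanted

    maf = _minor_allele_frequency(calls) if len(line_ids) else np.zeros(calls.shape[1])
    miss_frac = np.isnan(calls).mean(axis=0)
    low_maf = ~(maf >= min_maf)  # NaN-frequency (all-missing) markers also fail
    high_miss = miss_frac > max_missing
    report.markers_maf = int(low_maf.sum())
    report.markers_missing_subset = int((high_miss & ~low_maf).sum())
    keep_m2 = ~(low_maf | high_miss)
    calls = calls[:, keep_m2]
    marker_ids = [m for m, k in zip(marker_ids, keep_m2) if k]

    if calls.shape[1] == 0:
        raise RelationshipError("no markers survive QC")

    # frequency-consistent mean imputation: missing -> 2 p_j - 1
    col_mean = np.nanmean(calls, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(calls))
    calls[nan_r, nan_c] = col_mean[nan_c]

    report.n_markers_out = calls.shape[1]
    report.n_lines_out = calls.shape[0]
    return MarkerMatrix(line_ids, calls, marker_ids), report


def genomic_relationship(markers: MarkerMatrix) -> RelationshipMatrix:
    """Allele-frequency-scaled genomic kernel G = ZZ' / (2 sum p(1-p))."""
    calls = markers.calls
    if np.isnan(calls).any():
        raise RelationshipError("markers must be imputed (no missing calls)")
    mean = calls.mean(axis=0)
    p = (mean + 1.0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise RelationshipError("all markers monomorphic: G denominator is zero")
    z = calls - mean
    g = (z @ z.T) / denom
    return RelationshipMatrix(markers.line_ids, g, kind="G")


def pedigree_relationship(
    ped: Pedigree, ids: Sequence[str] | None = None
) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular method.

    Lines are processed parents-first;
    ``A_ii = 1 + 0.5 A(p1, p2)`` (the inbreeding term drops out if either
    parent is unknown) and ``A_ij = 0.5 (A(j, p1) + A(j, p2))`` for every
    previously processed ``j``.  Founders (no record or no known parents)
    are taken unrelated and non-inbred.  Returns the submatrix for ``ids``
    (all pedigree lines if None), equal to twice the coefficient of parentage.
    """
    parents = dict(ped.parents())
    # pedigree closure: parents that have no record are founders
    all_ids: list[str] = []
    seen: set[str] = set()

    def add(node: str) -> None:
        if node in seen:
            return
        seen.add(node)
        for p in parents.get(node, (None, None)):
            if p is not None:
                add(p)
        all_ids.append(node)  # post-order => parents precede offspring

    for line in parents:
        add(line)

    if ids is None:
        ids = list(parents)
    wanted = [str(s) for s in ids]
    absent = [s for s in wanted if s not in seen]
    if absent:
        raise RelationshipError(f"ids absent from pedigree closure: {absent[:10]}")

    n = len(all_ids)
    pos = {s: i for i, s in enumerate(all_ids)}
    a = np.zeros((n, n))
    for i, line in enumerate(all_ids):
        p1, p2 = parents.get(line, (None, None))
        i1 = pos[p1] if p1 is not None else None
        i2 = pos[p2] if p2 is not None else None
        if i1 is not None and i2 is not None:
            a[i, i] = 1.0 + 0.5 * a[i1, i2]
        else:
            a[i, i] = 1.0
        if i:
            row = np.zeros(i)
            if i1 is not None:
                row += 0.5 * a[:i, i1]
            if i2 is not None:
                row += 0.5 * a[:i, i2]
            a[i, :i] = row
            a[:i, i] = row

    idx = np.array([pos[s] for s in wanted], dtype=int)
    return RelationshipMatrix(wanted, a[np.ix_(idx, idx)], kind="A")
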