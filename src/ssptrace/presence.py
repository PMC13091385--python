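"""Presence/absence matrices and phylogenetic-profile correlation.

The final hit list is collapsed to a binary lineages x families matrix;
association between profiles is measured by the pairwise Pearson
product-moment correlation (which on binary vectors is the phi
coefficient), with a two-sided t test on n-2 degrees of freedom and a
per-pair significance threshold of p < 0.05 (no multiple-testing
correction by default, a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import log


@dataclass
class PresenceMatrix:
    """Binary lineages x families table plus the underlying hit counts."""

    cells: pd.DataFrame  # 0/1, index=lineages, columns=families
    counts: pd.DataFrame  # integer hit counts, same shape

    def __post_init__(self) -> None:
        if not self.cells.index.equals(self.counts.index) or not self.cells.columns.equals(
            self.counts.columns
        ):
            raise ValueError("cells and counts must share index and columns")
        if not ((self.counts > 0).astype(int) == self.cells).all().all():
            raise ValueError("cells must equal (counts > 0)")

    @property
    def lineages(self) -> list[str]:
        return list(self.cells.index)

    @property
    def families(self) -> list[str]:
        return list(self.cells.columns)

    def family_breadth(self) -> pd.Series:
        """Number of lineages in which each family is present."""
        return self.cells.sum(axis=0)


@dataclass(frozen=True)
class CorrelationResult:
    axis: str  # "lineages" | "families"
    label1: str
    label2: str
    r: float  # nan when undefined (constant vector)
    p: float  # nan when undefined
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)

    @property
    def significant(self) -> bool:
        return self.defined and self.p < 0.05


def build_presence_matrix(
    final_hits, lineages: Sequence[str], families: Sequence[str]
) -> PresenceMatrix:
    """Aggregate kept hits into the binary matrix; lineages/families with no
    hits still appear as all-zero rows/columns.  Hits carrying an unknown
    lineage label raise."""
    counts = pd.DataFrame(0, index=list(lineages), columns=list(families), dtype=int)
    for hit in final_hits:
        if not getattr(hit, "kept", True):
            continue
        if hit.lineage not in counts.index:
            raise ValueError(f"hit on {hit.subject_id!r} has unknown lineage {hit.lineage!r}")
        if hit.family not in counts.columns:
            raise ValueError(f"hit on {hit.subject_id!r} has unknown family {hit.family!r}")
        counts.loc[hit.lineage, hit.family] += 1
    return PresenceMatrix(cells=(counts > 0).astype(int), counts=counts)


def pearson_binary(
    x: Sequence[float], y: Sequence[float], axis: str = "families",
    label1: str = "x", label2: str = "y",
) -> CorrelationResult:
    """Pearson r with a two-sided t test (t = r*sqrt(n-2)/sqrt(1-r^2), n-2 df).

    On binary vectors this is the phi coefficient.  A constant vector makes
    the correlation undefined: the result is flagged (NaN), never raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return CorrelationResult(axis, label1, label2, float("nan"), float("nan"), n)
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = float(2 * _stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(axis, label1, label2, r, p, n)


def correlate_all_pairs(matrix: PresenceMatrix, axis: str = "families") -> list[CorrelationResult]:
    """All unordered pairs of rows (lineages) or columns (families)."""
    if axis == "families":
        vectors = {f: matrix.cells[f].to_numpy() for f in matrix.families}
    elif axis == "lineages":
        vectors = {l: matrix.cells.loc[l].to_numpy() for l in matrix.lineages}
    else:
        raise ValueError("axis must be 'families' or 'lineages'")
    out = []
    for a, b in itertools.combinations(vectors, 2):
        out.append(pearson_binary(vectors[a], vectors[b], axis=axis, label1=a, label2=b))
    n_undef = sum(not r.defined for r in out)
    if n_undef:
        log.info("correlate_all_pairs: %d undefined pairs (constant profiles)", n_undef)
    return out


def correlation_matrix(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Symmetric r matrix with unit diagonal, for heatmap-style export."""
    labels: list[str] = []
    for res in results:
        for lab in (res.label1, res.label2):
            if lab not in labels:
                labels.append(lab)
    m = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for res in results:
        m.loc[res.label1, res.label2] = res.r
        m.loc[res.label2, res.label1] = res.r
    return m


def breadth_vs_copy_number(
    breadth_per_family: Sequence[float], copies_per_family: Sequence[float]
) -> CorrelationResult:
    """Does a family's lineage breadth predict its gene copy number in a
    derived genome?  Plain Pearson on the two integer vectors."""
    return pearson_binary(
        breadth_per_family, copies_per_family,
        axis="families", label1="breadth", label2="copies",
    )


def benjamini_hochberg(results: Sequence[CorrelationResult], alpha: float = 0.05) -> list[bool]:
    """Optional FDR control over the defined pairs; returns per-result flags."""
    defined = [(i, r.p) for i, r in enumerate(results) if r.defined]
    flags = [False] * len(results)
    if not defined:
        return flags
    order = sorted(defined, key=lambda t: t[1])
    m = len(order)
    threshold_idx = -1
    for rank, (_, p) in enumerate(order, start=1):
        if p <= alpha * rank / m:
            threshold_idx = rank
    for rank, (i, _) in enumerate(order, start=1):
        if rank <= threshold_idx:
            flags[i] = True
    return flags


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "axis": r.axis,
                "label1": r.label1,
                "label2": r.label2,
                "r": r.r,
                "p": r.p,
                "n": r.n,
                "significant": r.significant,
            }
            for r in results
        ]
    )
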