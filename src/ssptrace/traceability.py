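"""Bidirectional motif evolutionary traceability.

Given a grouped motif alignment — land-plant reference rows (L-group) and
protistan candidate rows (P-group) — each reference motif position gets:

* P->L support frequency: the fraction of non-gap L-group residues at the
  column that fall inside the residue set observed in the P-group;
* L->P traceability frequency: the fraction of non-gap P-group residues
  that fall inside the residue set observed in the L-group;
* information content in bits, log2(20) - H of the L-group column, with a
  bootstrap standard deviation over L-group rows.

Both frequencies use the set-membership reading (does a residue fall in the
other group's observed set), which makes the two directions symmetric in
form; a stricter per-consensus-residue variant is available via
``consensus_only``.  Gaps never count, in numerator or denominator.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GAP, AMINO_ACIDS, AlignedBlock, log


@dataclass(frozen=True)
class GroupedAlignment:
    """An AlignedBlock split into land-plant (L) and protist (P) rows.

    ``reference_columns`` are the alignment columns that constitute the
    plant reference motif (1..len numbering of the motif positions): by
    default, the columns with non-gap residues in at least half of the
    L-group rows.
    """

    block: AlignedBlock
    l_rows: tuple[int, ...]
    p_rows: tuple[int, ...]
    reference_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.l_rows or not self.p_rows:
            raise ValueError("both L-group and P-group must be non-empty")
        if list(self.reference_columns) != sorted(set(self.reference_columns)):
            raise ValueError("reference_columns must be strictly increasing")

    @classmethod
    def from_block(
        cls, block: AlignedBlock, min_l_occupancy: float = 0.5
    ) -> "GroupedAlignment":
        l_rows = tuple(i for i, r in enumerate(block.records) if r.group == "land_plant")
        p_rows = tuple(i for i, r in enumerate(block.records) if r.group == "protist")
        if not l_rows or not p_rows:
            raise ValueError(
                "grouped alignment needs both land_plant (LP|) and protist (PR|) rows"
            )
        ref_cols = []
        for col in range(1, block.width + 1):
            column = block.column(col)
            nongap = sum(1 for i in l_rows if column[i] != GAP)
            if nongap >= min_l_occupancy * len(l_rows):
                ref_cols.append(col)
        return cls(block=block, l_rows=l_rows, p_rows=p_rows, reference_columns=tuple(ref_cols))

    def n_positions(self) -> int:
        return len(self.reference_columns)


@dataclass
class TraceabilityRow:
    position: int  # 1-based motif index
    l_set: frozenset[str]
    p_set: frozenset[str]
    freq_P_to_L: float  # nan when undefined
    freq_L_to_P: float
    ic_bits: float
    ic_sd: float


def column_residue_sets(
    galn: GroupedAlignment, position: int
) -> tuple[frozenset[str], frozenset[str], str, str]:
    """Non-gap residue supports and multisets of both groups at a motif
    position (1-based index into reference_columns)."""
    col = galn.reference_columns[position - 1]
    column = galn.block.column(col)
    l_residues = "".join(column[i] for i in galn.l_rows if column[i] != GAP)
    p_residues = "".join(column[i] for i in galn.p_rows if column[i] != GAP)
    if not p_residues:
        log.debug("position %d: P-group all-gap, P-dependent direction undefined", position)
    if not l_residues:
        log.debug("position %d: L-group all-gap, L-dependent direction undefined", position)
    return frozenset(l_residues), frozenset(p_residues), l_residues, p_residues


def support_frequency_P_to_L(
    galn: GroupedAlignment, position: int, consensus_only: bool = False
) -> float:
    """Fraction of land-plant residues at the column that match the residue
    set observed in protists; NaN when either side is all-gap."""
    l_set, p_set, l_res, p_res = column_residue_sets(galn, position)
    if not p_set or not l_res:
        return float("nan")
    target = _target_set(p_res, consensus_only)
    return sum(1 for c in l_res if c in target) / len(l_res)


def traceability_frequency_L_to_P(
    galn: GroupedAlignment, position: int, consensus_only: bool = False
) -> float:
    """Fraction of protistan residues at the column that match the residue
    set observed in land plants; NaN when either side is all-gap."""
    l_set, p_set, l_res, p_res = column_residue_sets(galn, position)
    if not l_set or not p_res:
        return float("nan")
    target = _target_set(l_res, consensus_only)
    return sum(1 for c in p_res if c in target) / len(p_res)


def _target_set(residues: str, consensus_only: bool) -> frozenset[str]:
    if not consensus_only:
        return frozenset(residues)
    counts = Counter(residues)
    top = max(counts.values())
    return frozenset(a for a, c in counts.items() if c == top)


def information_content(
    residues: str, alphabet_size: int = 20, small_sample_correction: bool = False
) -> float:
    """Shannon information content of a column in bits:
    IC = log2(alphabet_size) - H, with H over the observed residue
    frequencies.  The optional small-sample correction subtracts the
    standard (s-1)/(2*ln2*n) term used by sequence-logo tools."""
    if not residues:
        return float("nan")
    counts = Counter(residues)
    n = len(residues)
    h = -sum((c / n) * math.log2(c / n) for c in counts.values())
    ic = math.log2(alphabet_size) - h
    if small_sample_correction:
        ic -= (alphabet_size - 1) / (2 * math.log(2) * n)
    return max(ic, 0.0) if small_sample_correction else ic


def bootstrap_ic_sd(
    galn: GroupedAlignment,
    position: int,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    alphabet_size: int = 20,
) -> float:
    """Bootstrap SD of the L-group information content at one position.

    L-group rows are resampled with replacement ``reps`` times and the IC
    recomputed on each resample; the sample standard deviation is returned.
    Resampling covers the L-group only: the logo and its uncertainty are a
    land-plant reference property.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    col = galn.reference_columns[position - 1]
    column = galn.block.column(col)
    l_res = [column[i] for i in galn.l_rows if column[i] != GAP]
    if not l_res:
        return float("nan")
    arr = np.array(l_res)
    vals = np.empty(reps)
    for k in range(reps):
        draw = arr[rng.integers(0, len(arr), size=len(arr))]
        vals[k] = information_content("".join(draw), alphabet_size)
    if vals.max() == vals.min():  # every resample identical -> exactly zero
        return 0.0
    return float(vals.std(ddof=1))


def traceability_table(
    galn: GroupedAlignment,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    thresholds: tuple[float, float] = (0.70, 0.85),
) -> tuple[list[TraceabilityRow], dict]:
    """Per-position traceability statistics plus a threshold-exceedance
    summary (counts of positions whose frequency exceeds each threshold)."""
    if rng is None:
        rng = np.random.default_rng(0)
    rows: list[TraceabilityRow] = []
    for pos in range(1, galn.n_positions() + 1):
        l_set, p_set, l_res, p_res = column_residue_sets(galn, pos)
        rows.append(
            TraceabilityRow(
                position=pos,
                l_set=l_set,
                p_set=p_set,
                freq_P_to_L=support_frequency_P_to_L(galn, pos),
                freq_L_to_P=traceability_frequency_L_to_P(galn, pos),
                ic_bits=information_content(l_res),
                ic_sd=bootstrap_ic_sd(galn, pos, reps=reps, rng=rng),
            )
        )
    summary = {
        "n_positions": len(rows),
        "thresholds": thresholds,
    }
    for th in thresholds:
        key = f"{th:.2f}".replace("0.", "")
        summary[f"l2p_gt_{key}"] = sum(
            1 for r in rows if not math.isnan(r.freq_L_to_P) and r.freq_L_to_P > th
        )
        summary[f"p2l_gt_{key}"] = sum(
            1 for r in rows if not math.isnan(r.freq_P_to_L) and r.freq_P_to_L > th
        )
    return rows, summary


def table_to_frame(rows: Sequence[TraceabilityRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "freq_P_to_L": r.freq_P_to_L,
                "freq_L_to_P": r.freq_L_to_P,
                "ic_bits": r.ic_bits,
                "ic_sd": r.ic_sd,
                "l_set": "".join(sorted(r.l_set)),
                "p_set": "".join(sorted(r.p_set)),
            }
            for r in rows
        ]
    )


def logo_matrix(galn: GroupedAlignment) -> pd.DataFrame:
    """Position x residue frequency matrix of the L-group, consumable by
    standard sequence-logo tools."""
    data = []
    for pos in range(1, galn.n_positions() + 1):
        _ls, _ps, l_res, _pr = column_residue_sets(galn, pos)
        counts = Counter(l_res)
        n = max(len(l_res), 1)
        data.append({a: counts.get(a, 0) / n for a in AMINO_ACIDS})
    df = pd.DataFrame(data)
    df.insert(0, "position", range(1, len(data) + 1))
    return df
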