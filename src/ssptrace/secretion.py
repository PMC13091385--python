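"""Secreted-protein evidence: signal-peptide heuristic, transmembrane
hydropathy scan, and the C-terminal motif-position criterion.

All three signals are *supporting indicators*, never hard filters: candidate
hits are annotated with a confidence tier (high / medium / low) and carried
forward regardless, because transcriptome-derived proteins are frequently
truncated at the 5' end and a missing signal peptide is weak evidence of
absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import RunConfig
from .screen import ScreenHit

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

_SMALL = set("AGSC")  # small residues accepted at cleavage-site -3/-1


@dataclass
class SecretionAssessment:
    subject_id: str
    sp_called: bool
    sp_cleavage_pos: int | None
    sp_reason: str
    tm_segments: list[tuple[int, int]]
    motif_position_fraction: float
    confidence_tier: str = ""


def _hydropathy(seq: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])


def predict_signal_peptide_lite(
    seq: str,
    cleave_min: int = 14,
    cleave_max: int = 35,
    hyd_cutoff: float = 1.6,
) -> tuple[bool, int | None, str]:
    """Rule-based signal-peptide call on the N-terminal region.

    A signal peptide is called when all of
      (a) at least one Arg/Lys within residues 1-5 (the n-region charge),
      (b) residues 6-20 contain an 8-residue window of mean Kyte-Doolittle
          hydropathy >= ``hyd_cutoff`` (the h-region),
      (c) a small-X-small cleavage triplet ([AGSC]-X-[AGSC], canonically
          A-X-A) ending within residues ``cleave_min``..``cleave_max``.
    Returns (called, cleavage position = end of the triplet, reason).
    Sequences shorter than 15 residues return False with reason "too short"
    rather than raising: short transcript fragments are expected input.
    """
    if len(seq) < 15:
        return False, None, "too short"
    if not any(c in "RK" for c in seq[:5]):
        return False, None, "no basic residue in n-region"
    hyd = _hydropathy(seq[5:20])
    windows = [hyd[i : i + 8].mean() for i in range(len(hyd) - 7)]
    if not windows or max(windows) < hyd_cutoff:
        return False, None, "no hydrophobic h-region"
    for end in range(cleave_min, min(cleave_max, len(seq)) + 1):
        triplet = seq[end - 3 : end]
        if len(triplet) == 3 and triplet[0] in _SMALL and triplet[2] in _SMALL:
            return True, end, "ok"
    return False, None, "no cleavage triplet"


def predict_tm_segments(
    seq: str, window: int = 19, cutoff: float = 1.6
) -> list[tuple[int, int]]:
    """Kyte-Doolittle sliding-window scan for transmembrane-like stretches.

    Maximal runs of window centers with mean hydropathy >= cutoff are merged
    and reported as (start, end) residue segments (1-based inclusive, the
    full window extent of the run).  Sequences shorter than the window give
    an empty list.
    """
    n = len(seq)
    if n < window:
        return []
    hyd = _hydropathy(seq)
    means = np.convolve(hyd, np.ones(window) / window, mode="valid")  # len n-window+1
    segs: list[tuple[int, int]] = []
    run_start = None
    for i, m in enumerate(means):
        if m >= cutoff:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                segs.append((run_start + 1, i - 1 + window))
                run_start = None
    if run_start is not None:
        segs.append((run_start + 1, len(means) - 1 + window))
    return segs


def motif_position_fraction(hit: ScreenHit, protein_len: int) -> float:
    """Relative position of the motif end in the precursor: subject_end /
    protein length, in (0, 1]; 1.0 means the motif runs to the last residue."""
    if hit.aln.subject_end > protein_len:
        raise ValueError(
            f"subject_end {hit.aln.subject_end} beyond protein length {protein_len}"
        )
    return hit.aln.subject_end / protein_len


def assign_confidence(assessment: SecretionAssessment, config: RunConfig) -> str:
    """Combine the three supporting indicators into a tier.

    high   = signal peptide called AND motif-position fraction >= cterm_min
             AND no TM segment outside the signal-peptide region;
    medium = exactly one criterion failed; low = two or more failed.
    TM segments starting within the first ``sp_region`` residues are not
    counted against a candidate (signal peptides and TM helices share the
    same hydrophobic signature).
    """
    tm_outside = [s for s in assessment.tm_segments if s[0] > config.sp_region]
    failed = 0
    if not assessment.sp_called:
        failed += 1
    if assessment.motif_position_fraction < config.cterm_min:
        failed += 1
    if tm_outside:
        failed += 1
    tier = "high" if failed == 0 else ("medium" if failed == 1 else "low")
    assessment.confidence_tier = tier
    return tier


def assess_hits(
    hits, proteins_by_id, config: RunConfig
) -> list[SecretionAssessment]:
    """Annotate kept hits with secretion evidence and confidence tiers.

    Nothing is dropped here; tiers are written back onto the hits.
    """
    out = []
    for hit in hits:
        if not hit.kept:
            continue
        seq = proteins_by_id[hit.subject_id].seq
        called, pos, reason = predict_signal_peptide_lite(seq)
        segs = predict_tm_segments(seq)
        frac = motif_position_fraction(hit, len(seq))
        hit.motif_position_fraction = frac
        a = SecretionAssessment(
            subject_id=hit.subject_id,
            sp_called=called,
            sp_cleavage_pos=pos,
            sp_reason=reason,
            tm_segments=segs,
            motif_position_fraction=frac,
        )
        hit.confidence_tier = assign_confidence(a, config)
        out.append(a)
    return out
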