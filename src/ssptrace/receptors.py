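"""LRR receptor-like kinase candidate identification.

Mirrors the receptor arm of the screen: independent kinase-domain and
LRR-domain similarity searches, reciprocal intersection of their hit sets,
then rule-based validation that the protein carries the tripartite
LRR - transmembrane - kinase architecture in N-to-C order.  The rule-based
detectors stand in for domain-annotation services so everything runs
offline; the thresholds are configuration, not biology.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io import ProteinRecord, RunConfig, log_stage
from .screen import approximate_evalue, smith_waterman
from .secretion import predict_tm_segments

#: plant LRR consensus core LxxLxLxx with L matched by any of {L,I,V,F}
_LRR_RE = re.compile(r"(?=([LIVF]..[LIVF].[LIVF]..))")

#: kinase subdomain motifs, N-to-C: Gly-rich loop, beta-3 lysine, catalytic
#: HRD, activation-segment DFG
_KINASE_PATTERNS = (
    ("G.G..G", re.compile(r"G.G..G")),
    ("[VAI].K", re.compile(r"[VAI].K")),
    ("HRD", re.compile(r"HRD")),
    ("DFG", re.compile(r"DFG")),
)

KINASE_WINDOW = 350
LRR_MIN_REPEATS = 3


@dataclass(frozen=True)
class DomainAnnotation:
    kind: str  # LRR | TM | KINASE
    start: int  # 1-based inclusive
    end: int
    evidence: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain start must be <= end")


@dataclass(frozen=True)
class ArchitectureCall:
    subject_id: str
    annotations: tuple[DomainAnnotation, ...]
    verdict: bool
    reason: str


def detect_lrr_repeats(seq: str, min_repeats: int = LRR_MIN_REPEATS) -> DomainAnnotation | None:
    """Find a leucine-rich-repeat block.

    All (possibly overlapping) matches of the LxxLxLxx consensus are chained
    when consecutive match starts are adjacent (within one repeat unit,
    <= 8 aa) or one canonical LRR unit apart (20-30 aa); the longest chain
    with >= min_repeats matches is reported as the minimal spanning block.
    Matches sitting in a uniformly hydrophobic window (>= 7 of 8 residues
    in LIVFMAW) are rejected: an LRR unit alternates its leucine core with
    polar surface residues, whereas such windows are TM-helix-like.
    """
    starts = [
        m.start()
        for m in _LRR_RE.finditer(seq)
        if sum(c in "LIVFMAW" for c in m.group(1)) < 7
    ]
    if not starts:
        return None
    best_chain: list[int] = []
    chain = [starts[0]]
    for s in starts[1:]:
        gap = s - chain[-1]
        if gap <= 8 or 20 <= gap <= 30:
            chain.append(s)
        else:
            if len(chain) > len(best_chain):
                best_chain = chain
            chain = [s]
    if len(chain) > len(best_chain):
        best_chain = chain
    if len(best_chain) < min_repeats:
        return None
    return DomainAnnotation(
        kind="LRR",
        start=best_chain[0] + 1,
        end=best_chain[-1] + 8,
        evidence=f"{len(best_chain)} repeats",
    )


def detect_kinase_domain(seq: str, window: int = KINASE_WINDOW) -> DomainAnnotation | None:
    """Find a protein-kinase-like region from its ordered subdomain motifs.

    Searches for the Gly-rich loop, beta-3 lysine, HRD and DFG motifs; an
    annotation is returned iff at least 3 of the 4 occur in N-to-C order
    within a window of <= ``window`` residues.  The span runs from the first
    found motif's start to the last found motif's end.
    """
    occ: list[list[tuple[int, int]]] = []
    for _name, pat in _KINASE_PATTERNS:
        occ.append([(m.start(), m.end()) for m in pat.finditer(seq)])
    # longest ordered chain over motif classes (each used at most once, in
    # class order, positions strictly increasing); occurrence lists are tiny
    best: tuple[int, list[tuple[int, int, int]]] = (0, [])

    def extend(k: int, last_end: int, chain: list[tuple[int, int, int]]) -> None:
        nonlocal best
        if len(chain) + (len(occ) - k) <= best[0]:
            return
        if k == len(occ):
            if len(chain) > best[0]:
                best = (len(chain), chain[:])
            return
        extend(k + 1, last_end, chain)  # skip this motif class
        for s, e in occ[k]:
            if s >= last_end:
                chain.append((k, s, e))
                extend(k + 1, e, chain)
                chain.pop()

    extend(0, -1, [])
    count, chain = best
    if count < 3:
        return None
    start = chain[0][1]
    end = chain[-1][2]
    if end - start > window:
        return None
    names = [(_KINASE_PATTERNS[k][0]) for k, _s, _e in chain]
    return DomainAnnotation(
        kind="KINASE",
        start=start + 1,
        end=end,
        evidence=f"{count}/4: " + ",".join(names),
    )


def dual_search_intersection(
    kinase_hits: Iterable[str], lrr_hits: Iterable[str]
) -> set[str]:
    """Subjects recovered by both the kinase-domain and the LRR-domain
    searches (reciprocal-evidence rule)."""
    k = set(kinase_hits)
    l = set(lrr_hits)
    inter = k & l
    log_stage("dual_search_intersection", len(k) + len(l), len(inter))
    return inter


def validate_architecture(
    seq: str,
    subject_id: str = "",
    sp_region: int = 30,
    min_repeats: int = LRR_MIN_REPEATS,
) -> ArchitectureCall:
    """Verify the tripartite LRR -> TM -> kinase order on one protein.

    The transmembrane segment considered is the first hydropathy segment
    that starts after the LRR block and outside the first ``sp_region``
    residues (signal peptides mimic TM helices).  Verdict is true iff all
    three domains are present with LRR.end < TM.start <= TM.end < KINASE.start.
    """
    lrr = detect_lrr_repeats(seq, min_repeats=min_repeats)
    kin = detect_kinase_domain(seq)
    if lrr is None:
        return ArchitectureCall(subject_id, _anns(None, None, kin), False, "missing LRR")
    if kin is None:
        return ArchitectureCall(subject_id, _anns(lrr, None, None), False, "missing kinase")
    if kin.start <= lrr.end:
        return ArchitectureCall(subject_id, _anns(lrr, None, kin), False, "order violation")
    tm = None
    for s, e in predict_tm_segments(seq):
        if s > max(lrr.end, sp_region):
            tm = DomainAnnotation(kind="TM", start=s, end=e, evidence="hydropathy segment")
            break
    if tm is None:
        return ArchitectureCall(subject_id, _anns(lrr, None, kin), False, "missing TM")
    if not (lrr.end < tm.start <= tm.end < kin.start):
        return ArchitectureCall(subject_id, _anns(lrr, tm, kin), False, "order violation")
    return ArchitectureCall(subject_id, _anns(lrr, tm, kin), True, "valid")


def _anns(*doms: DomainAnnotation | None) -> tuple[DomainAnnotation, ...]:
    present = [d for d in doms if d is not None]
    return tuple(sorted(present, key=lambda d: d.start))


def screen_rlk_collection(
    kinase_refs: Sequence[ProteinRecord],
    lrr_refs: Sequence[ProteinRecord],
    proteins: Sequence[ProteinRecord],
    config: RunConfig,
) -> list[ArchitectureCall]:
    """Full receptor screen: domain similarity searches at the approximate
    e-value cutoff, reciprocal intersection, then architecture validation.
    Only verdict-true calls constitute the candidate list; all validated
    calls are returned for reporting."""
    if not kinase_refs or not lrr_refs:
        raise ValueError("kinase and LRR reference sets must both be non-empty")
    kin_ids = _domain_search(kinase_refs, proteins, config)
    lrr_ids = _domain_search(lrr_refs, proteins, config)
    inter = dual_search_intersection(kin_ids, lrr_ids)
    by_id = {p.id: p for p in proteins}
    calls = [
        validate_architecture(by_id[i].seq, subject_id=i, sp_region=config.sp_region)
        for i in sorted(inter)
    ]
    n_valid = sum(c.verdict for c in calls)
    log_stage("validate_architecture", len(calls), n_valid)
    return calls


def _domain_search(
    refs: Sequence[ProteinRecord], proteins: Sequence[ProteinRecord], config: RunConfig
) -> set[str]:
    found: set[str] = set()
    for prot in proteins:
        for ref in refs:
            if prot.id in found:
                break
            aln = smith_waterman(ref.seq, prot.seq, query_id=ref.id, subject_id=prot.id)
            if aln.score <= 0:
                continue
            ev = approximate_evalue(aln.score, len(ref.seq), len(prot.seq))
            if ev <= config.rlk_evalue_max:
                found.add(prot.id)
    log_stage("rlk_domain_search", len(proteins), len(found),
              evalue_max=config.rlk_evalue_max, refs=len(refs))
    return found


def calls_to_frame(calls: Sequence[ArchitectureCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        spans = {k: "" for k in ("LRR", "TM", "KINASE")}
        evid = {k: "" for k in ("LRR", "TM", "KINASE")}
        for d in c.annotations:
            spans[d.kind] = f"{d.start}-{d.end}"
            evid[d.kind] = d.evidence
        rows.append(
            {
                "subject_id": c.subject_id,
                "lrr_span": spans["LRR"],
                "lrr_repeats": evid["LRR"],
                "tm_span": spans["TM"],
                "kinase_span": spans["KINASE"],
                "kinase_motifs": evid["KINASE"],
                "verdict": c.verdict,
                "reason": c.reason,
            }
        )
    return pd.DataFrame(rows)
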