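"""Motif-anchored homology screening.

The discovery engine is an exhaustive affine-gap Smith-Waterman (Gotoh)
search of every reference motif against every candidate protein, standing in
for a permissive BLASTP pass: because the search is exhaustive, no e-value
pre-screen is needed, and hits are admitted purely by the coverage and
similarity filters.  An approximate Karlin-Altschul e-value column is still
emitted for interoperability.

Gap costs follow the BLASTP convention for BLOSUM62 (open 11, extend 1): a
gap of length k costs 11 + k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from .io import ProteinRecord, RunConfig, log, log_stage

# --- substitution matrix -----------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
MATRIX_ALPHABET = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_CODE = {ch: i for i, ch in enumerate(MATRIX_ALPHABET)}
SUB = np.asarray(_BLOSUM62, dtype=np.float64)

#: SSP families screened by the pipeline; CLE is carried as its two
#: subclades (CLV3-type and TDIF-type) throughout.
FAMILIES = (
    "CLE-CLV3", "CLE-TDIF", "PIP/PIPL", "CEP", "IDA/IDL",
    "CLEL", "PSY", "CIF", "PEP", "PSK",
)

#: Karlin-Altschul parameters for gapped BLOSUM62 (11/1), used only for the
#: clearly-labeled approximate e-value column.
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def encode(seq: str) -> np.ndarray:
    """Encode residues as indices into the BLOSUM62 alphabet."""
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in substitution matrix alphabet")


# --- dataclasses -------------------------------------------------------------

@dataclass(frozen=True)
class MotifQuery:
    """One SSP family's reference motif set (gap-free amino-acid strings)."""

    family: str
    motif_seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.motif_seqs:
            raise ValueError(f"family {self.family!r} has no reference motifs")
        for m in self.motif_seqs:
            if "-" in m or not m:
                raise ValueError(f"reference motif for {self.family!r} must be gap-free")


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment of a motif query against a subject protein.

    Coordinates are 1-based inclusive; an empty alignment (score 0) has all
    coordinates 0 and empty aligned strings.
    """

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str
    score: float

    @property
    def is_empty(self) -> bool:
        return self.score == 0.0 and not self.aligned_query


@dataclass
class ScreenHit:
    """A filtered motif hit with its screening metrics."""

    aln: LocalAlignment
    family: str
    lineage: str
    coverage: float
    similarity: float
    evalue: float
    reference: str
    profile_score: float = float("nan")
    empirical_p: float = float("nan")
    motif_position_fraction: float = float("nan")
    confidence_tier: str = ""
    kept: bool = True
    reason_dropped: str = ""

    @property
    def subject_id(self) -> str:
        return self.aln.subject_id


# --- Smith-Waterman (Gotoh) --------------------------------------------------

@njit(cache=False)
def _gotoh(q, s, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    m = q.shape[0]
    n = s.shape[0]
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - (gap_open + gap_extend)
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - (gap_open + gap_extend)
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback (diagonal preferred on ties, then gap-in-query, then
    # gap-in-subject; ties change the path, never the score)
    qa = np.empty(m + n, np.int64)
    sa = np.empty(m + n, np.int64)
    k = 0
    i = bi
    j = bj
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            if h == H[i - 1, j - 1] + sub[q[i - 1], s[j - 1]]:
                qa[k] = i - 1
                sa[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            qa[k] = -1
            sa[k] = j - 1
            k += 1
            if E[i, j] == E[i, j - 1] - gap_extend:
                j -= 1
                state = 1
            else:
                j -= 1
                state = 0
        else:
            qa[k] = i - 1
            sa[k] = -1
            k += 1
            if F[i, j] == F[i - 1, j] - gap_extend:
                i -= 1
                state = 2
            else:
                i -= 1
                state = 0
    return best, i, j, bi, bj, qa[:k], sa[:k]


def smith_waterman(
    query: str,
    subject: str,
    matrix: np.ndarray = SUB,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    query_id: str = "query",
    subject_id: str = "subject",
) -> LocalAlignment:
    """Optimal local alignment under affine gaps (gap of length k costs
    ``gap_open + k * gap_extend``).

    Returns an empty alignment (score 0) when no positive-scoring pairing
    exists.  Raises on residues outside the substitution-matrix alphabet.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    if "-" in query or "-" in subject:
        raise ValueError("smith_waterman expects gap-free sequences")
    q = encode(query)
    s = encode(subject)
    score, i0, j0, i1, j1, qa, sa = _gotoh(q, s, matrix, float(gap_open), float(gap_extend))
    if score <= 0.0 or len(qa) == 0:
        return LocalAlignment(query_id, subject_id, 0, 0, 0, 0, "", "", 0.0)
    qa = qa[::-1]
    sa = sa[::-1]
    aq = "".join("-" if x < 0 else query[x] for x in qa)
    asub = "".join("-" if x < 0 else subject[x] for x in sa)
    return LocalAlignment(
        query_id=query_id,
        subject_id=subject_id,
        query_start=i0 + 1,
        query_end=i1,
        subject_start=j0 + 1,
        subject_end=j1,
        aligned_query=aq,
        aligned_subject=asub,
        score=float(score),
    )


def approximate_evalue(score: float, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul e-value with default gapped BLOSUM62 parameters.

    Approximate by construction (no edge-effect or database-size scaling);
    emitted for interoperability only, never used to admit SSP motif hits.
    """
    return KA_K * query_len * subject_len * math.exp(-KA_LAMBDA * score)


def hit_metrics(aln: LocalAlignment, query_len: int) -> tuple[float, float]:
    """Coverage and similarity of a local alignment.

    coverage   = aligned query span / query length.
    similarity = fraction of alignment columns whose substitution score is
    positive (BLAST-style "positives"); gap columns count in the denominator
    only.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    if aln.is_empty:
        return 0.0, 0.0
    coverage = (aln.query_end - aln.query_start + 1) / query_len
    ncols = len(aln.aligned_query)
    positive = 0
    for a, b in zip(aln.aligned_query, aln.aligned_subject):
        if a != "-" and b != "-" and SUB[_CODE[a], _CODE[b]] > 0:
            positive += 1
    return coverage, positive / ncols


# --- collection screening ----------------------------------------------------

def screen_collection(
    queries: Sequence[MotifQuery],
    proteins: Sequence[ProteinRecord],
    config: RunConfig,
) -> list[ScreenHit]:
    """Align every reference motif against every protein and keep hits with
    coverage >= coverage_min and similarity >= similarity_min (both
    inclusive).  Per subject and family only the best reference's hit is
    retained (highest score, then longest coverage, then lexicographic
    reference id)."""
    if not proteins:
        log.warning("screen_collection called with an empty protein collection")
        return []
    best: dict[tuple[str, str], ScreenHit] = {}
    n_pairs = 0
    for mq in queries:
        for ri, ref in enumerate(mq.motif_seqs):
            ref_id = f"{mq.family}#{ri}"
            for prot in proteins:
                n_pairs += 1
                aln = smith_waterman(
                    ref, prot.seq, query_id=ref_id, subject_id=prot.id
                )
                cov, sim = hit_metrics(aln, len(ref))
                if cov < config.coverage_min or sim < config.similarity_min:
                    continue
                hit = ScreenHit(
                    aln=aln,
                    family=mq.family,
                    lineage=prot.lineage,
                    coverage=cov,
                    similarity=sim,
                    evalue=approximate_evalue(aln.score, len(ref), len(prot.seq)),
                    reference=ref_id,
                )
                key = (prot.id, mq.family)
                prev = best.get(key)
                if prev is None or _hit_rank(hit) > _hit_rank(prev):
                    best[key] = hit
    hits = sorted(best.values(), key=lambda h: (h.family, h.lineage, h.subject_id))
    log_stage(
        "screen_collection", n_pairs, len(hits),
        coverage_min=config.coverage_min, similarity_min=config.similarity_min,
    )
    return hits


def _hit_rank(h: ScreenHit) -> tuple:
    # higher is better; reference id compares inverted for lexicographic
    # "smallest wins" on the final tie-break
    return (h.aln.score, h.coverage, tuple(-ord(c) for c in h.reference))


# --- profile rescoring -------------------------------------------------------

def build_profile(refs: Sequence[str], background: np.ndarray | None = None) -> np.ndarray:
    """Position-specific log-odds profile from an equal-length reference set.

    Henikoff-style pseudocounts: with N sequences, B = sqrt(N) background-
    proportional pseudocounts per column; scores are log2(f/q).  Rows are
    motif positions, columns the 20 standard residues.
    """
    if len(refs) < 2:
        raise ValueError("need >=2 reference sequences for a profile")
    L = len(refs[0])
    if any(len(r) != L for r in refs):
        raise ValueError("reference motifs must share one length to build a profile")
    from .io import AMINO_ACIDS

    if background is None:
        background = np.full(20, 1 / 20)
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((L, 20))
    for r in refs:
        for p, ch in enumerate(r):
            if ch in idx:
                counts[p, idx[ch]] += 1
    n = counts.sum(axis=1, keepdims=True)
    B = np.sqrt(len(refs))
    freq = (counts + B * background) / (n + B)
    return np.log2(freq / background)


def _profile_score(pssm: np.ndarray, positions: Sequence[int], residues: str) -> float:
    from .io import AMINO_ACIDS

    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    total = 0.0
    for p, ch in zip(positions, residues):
        i = idx.get(ch)
        if i is not None:
            total += pssm[p, i]
    return total


def profile_frequencies(refs: Sequence[str], background: np.ndarray | None = None) -> np.ndarray:
    """Per-column residue frequency matrix of a reference set, with the same
    Henikoff-style pseudocounts as :func:`build_profile`."""
    if len(refs) < 2:
        raise ValueError("need >=2 reference sequences for a profile")
    L = len(refs[0])
    if any(len(r) != L for r in refs):
        raise ValueError("reference motifs must share one length to build a profile")
    from .io import AMINO_ACIDS

    if background is None:
        background = np.full(20, 1 / 20)
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((L, 20))
    for r in refs:
        for p, ch in enumerate(r):
            if ch in idx:
                counts[p, idx[ch]] += 1
    n = counts.sum(axis=1, keepdims=True)
    B = np.sqrt(len(refs))
    return (counts + B * background) / (n + B)


def subject_composition(seq: str) -> np.ndarray:
    """Laplace-smoothed residue composition of one subject sequence, the
    per-subject background used for composition-adjusted profile scoring."""
    from .io import AMINO_ACIDS

    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.ones(20)
    for ch in seq:
        i = idx.get(ch)
        if i is not None:
            counts[i] += 1
    return counts / counts.sum()


def _span_profile_score(freqs: np.ndarray, aln: LocalAlignment,
                        log_bg: np.ndarray) -> float:
    """Composition-adjusted profile score of a hit's subject span.

    Sum over aligned columns of log2(f_col(res) / q(res)), with q the
    subject's own composition — the analog of composition-based statistics,
    so a biased segment cannot look significant merely by sharing its
    composition with the profile."""
    from .io import AMINO_ACIDS

    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    qpos = aln.query_start - 1  # 0-based profile row of next query residue
    total = 0.0
    for a, b in zip(aln.aligned_query, aln.aligned_subject):
        if a != "-" and b != "-":
            i = idx.get(b)
            if i is not None:
                total += math.log2(freqs[qpos, i]) - log_bg[i]
        if a != "-":
            qpos += 1
    return total


def null_profile_scores(
    mq: MotifQuery,
    freqs: np.ndarray,
    n_draws: int,
    subject_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Selection-corrected null distribution for profile scores.

    Each draw generates a random background subject, aligns every family
    reference against it exactly the way the screen does, takes the
    best-scoring reference's span, and records that span's
    composition-adjusted profile score.  This is the distribution a hit's
    profile score follows when the subject carries no motif: a null over
    *search results*, not over shuffles of an already-selected span (the
    optimal local alignment of a random subject is itself far from a
    random arrangement).
    """
    from .io import AMINO_ACIDS

    scores = np.empty(n_draws)
    for k in range(n_draws):
        idx = rng.integers(0, 20, size=subject_len)
        subject = "".join(AMINO_ACIDS[i] for i in idx)
        best_aln = None
        for ref in mq.motif_seqs:
            aln = smith_waterman(ref, subject)
            if best_aln is None or aln.score > best_aln.score:
                best_aln = aln
        if best_aln.is_empty:
            scores[k] = -np.inf
        else:
            log_bg = np.log2(subject_composition(subject))
            scores[k] = _span_profile_score(freqs, best_aln, log_bg)
    return np.sort(scores)


def profile_rescore(
    hits: Sequence[ScreenHit],
    queries: Sequence[MotifQuery],
    config: RunConfig,
    rng: np.random.Generator,
    n_database: int | None = None,
    null_subject_len: int = 150,
    subjects: Mapping[str, str] | None = None,
) -> list[ScreenHit]:
    """Rescore each hit's subject motif span against its family's log-odds
    profile and keep hits that a profile search of the database would retain.

    Per family, the observed span score is compared against the empirical
    null of :func:`null_profile_scores`; empirical_p is the add-one
    exceedance fraction (in (0, 1]), and the database-scale e-value is
    empirical_p * n_database — the expected number of background sequences
    scoring as well in a search of the whole collection, the same quantity a
    profile-HMM search reports.  Hits are kept iff empirical_p <=
    profile_p_max AND e-value <= profile_evalue_max (default 10, the
    permissive profile-search retention bound, inclusive).

    When ``subjects`` (id -> sequence) is given, observed scores are
    composition-adjusted against each subject's own residue composition;
    otherwise the uniform background is used.

    Families whose reference sets cannot form a profile (<2 references, or
    unequal lengths) pass their hits through unchanged, logged.
    """
    by_family = {mq.family: mq for mq in queries}
    if n_database is None:
        n_database = len({h.subject_id for h in hits}) or 1
        log.info("profile_rescore: n_database not given, using %d distinct subjects",
                 n_database)
    live = [h for h in hits if h.kept]
    profiles: dict[str, np.ndarray | None] = {}
    nulls: dict[str, np.ndarray] = {}
    for fam in sorted(by_family):
        mq = by_family[fam]
        try:
            freqs = profile_frequencies(mq.motif_seqs)
        except ValueError:
            profiles[fam] = None
            log.info("profile_rescore: family %s passes through (no profile)", fam)
            continue
        profiles[fam] = freqs
        if any(h.family == fam for h in live):
            nulls[fam] = null_profile_scores(
                mq, freqs, config.profile_null_draws, null_subject_len, rng
            )
    uniform_log_bg = np.log2(np.full(20, 1 / 20))
    comp_cache: dict[str, np.ndarray] = {}
    out: list[ScreenHit] = []
    n_in = 0
    N = config.profile_null_draws
    for hit in hits:
        if not hit.kept:
            out.append(hit)
            continue
        n_in += 1
        freqs = profiles.get(hit.family)
        if freqs is None:
            out.append(hit)
            continue
        if subjects is not None and hit.subject_id in subjects:
            log_bg = comp_cache.get(hit.subject_id)
            if log_bg is None:
                log_bg = np.log2(subject_composition(subjects[hit.subject_id]))
                comp_cache[hit.subject_id] = log_bg
        else:
            log_bg = uniform_log_bg
        obs = _span_profile_score(freqs, hit.aln, log_bg)
        null = nulls[hit.family]
        n_ge = len(null) - np.searchsorted(null, obs, side="left")
        p = (1 + n_ge) / (N + 1)
        ev = p * n_database
        hit.profile_score = obs
        hit.empirical_p = float(p)
        if p > config.profile_p_max or ev > config.profile_evalue_max:
            hit.kept = False
            hit.reason_dropped = "profile rescoring: not above background"
        out.append(hit)
    n_out = sum(1 for h in out if h.kept)
    log_stage("profile_rescore", n_in, n_out, profile_p_max=config.profile_p_max,
              profile_evalue_max=config.profile_evalue_max, null_draws=N,
              n_database=n_database)
    return out


# --- family competition ------------------------------------------------------

def competitive_family_assignment(
    hits: Sequence[ScreenHit], scope: str = "subject", min_overlap: float = 0.5
) -> list[ScreenHit]:
    """Resolve multiple family assignments on one subject, clan-style.

    SSP family motifs share cores (the two CLE subclades most of all), so
    several family profiles can fire on one candidate.  As profile-HMM
    family databases do for overlapping models in a clan, competing hits
    are ranked (lowest empirical p, then highest profile score, then
    highest alignment score) and only the best-supported family keeps the
    subject.  With the default ``scope="subject"`` every kept hit on a
    subject competes — a precursor carries one mature-peptide family and is
    cataloged once; ``scope="span"`` competes only hits whose subject spans
    overlap by >= ``min_overlap`` of the shorter span, admitting
    multi-motif architectures.
    """
    if scope not in ("subject", "span"):
        raise ValueError("scope must be 'subject' or 'span'")
    out = list(hits)
    by_subject: dict[str, list[ScreenHit]] = {}
    for h in out:
        if h.kept:
            by_subject.setdefault(h.subject_id, []).append(h)
    n_in = sum(len(v) for v in by_subject.values())
    for subject, group in by_subject.items():
        if len(group) < 2:
            continue
        group.sort(key=_competition_rank)
        accepted: list[ScreenHit] = []
        for h in group:
            loser = None
            for winner in accepted:
                if scope == "subject" or _span_overlap(h.aln, winner.aln) >= min_overlap:
                    loser = winner
                    break
            if loser is None:
                accepted.append(h)
            else:
                h.kept = False
                h.reason_dropped = f"outcompeted by {loser.family}"
    n_out = sum(1 for v in by_subject.values() for h in v if h.kept)
    log_stage("family_competition", n_in, n_out, scope=scope)
    return out


def _competition_rank(h: ScreenHit) -> tuple:
    p = h.empirical_p if not math.isnan(h.empirical_p) else 2.0
    ps = h.profile_score if not math.isnan(h.profile_score) else -math.inf
    return (p, -ps, -h.aln.score, h.family)


def _span_overlap(a: LocalAlignment, b: LocalAlignment) -> float:
    lo = max(a.subject_start, b.subject_start)
    hi = min(a.subject_end, b.subject_end)
    if hi < lo:
        return 0.0
    shorter = min(a.subject_end - a.subject_start, b.subject_end - b.subject_start) + 1
    return (hi - lo + 1) / shorter


# --- annotation blacklist ----------------------------------------------------

def annotation_blacklist_filter(
    hits: Sequence[ScreenHit],
    annotations: Mapping[str, str],
    blacklist: Iterable[str],
) -> list[ScreenHit]:
    """Drop hits whose subject carries a blacklisted annotation label
    (case-insensitive exact match); unannotated subjects pass."""
    bl = {b.lower() for b in blacklist}
    out = []
    n_in = 0
    for hit in hits:
        if not hit.kept:
            out.append(hit)
            continue
        n_in += 1
        label = annotations.get(hit.subject_id, "")
        if label and label.lower() in bl:
            hit.kept = False
            hit.reason_dropped = f"annotated as blacklisted family: {label}"
        out.append(hit)
    n_out = sum(1 for h in out if h.kept)
    log_stage("annotation_blacklist", n_in, n_out, blacklist_size=len(bl))
    return out


# --- tabular export ----------------------------------------------------------

def hits_to_frame(hits: Sequence[ScreenHit]) -> pd.DataFrame:
    rows = [
        {
            "family": h.family,
            "lineage": h.lineage,
            "subject_id": h.subject_id,
            "subject_start": h.aln.subject_start,
            "subject_end": h.aln.subject_end,
            "score": h.aln.score,
            "evalue": h.evalue,
            "coverage": h.coverage,
            "similarity": h.similarity,
            "profile_score": h.profile_score,
            "empirical_p": h.empirical_p,
            "motif_position_fraction": h.motif_position_fraction,
            "confidence_tier": h.confidence_tier,
            "kept": h.kept,
            "reason_dropped": h.reason_dropped,
        }
        for h in hits
    ]
    return pd.DataFrame(rows)
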