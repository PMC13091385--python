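import itertools
import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from ssptrace import (MotifQuery, annotation_blacklist_filter, hit_metrics,
                      screen_collection, smith_waterman)
from ssptrace.io import ProteinRecord, RunConfig
from ssptrace.screen import (SUB, _CODE, ScreenHit, approximate_evalue,
                             build_profile, competitive_family_assignment,
                             null_profile_scores, profile_frequencies,
                             profile_rescore)

BL62 = substitution_matrices.load("BLOSUM62")


def _biopython_aligner():
    # gap of length k costs 11 + k  ->  open=-(11+1), extend=-1
    return PairwiseAligner(
        mode="local", substitution_matrix=BL62,
        open_gap_score=-12, extend_gap_score=-1,
    )


def _enumerate_local_score(q, s, gap_open=11, gap_extend=1):
    """Independent oracle: exhaustive DFS over all local alignments.

    Enumerates every monotone column path over every substring pair, scoring
    affine gaps as open + k*extend per gap run; the empty alignment scores 0.
    Feasible only for very short strings.
    """
    best = 0.0

    def walk(i, j, score, state):
        nonlocal best
        if score > best:
            best = score
        if i < len(q) and j < len(s):
            walk(i + 1, j + 1, score + BL62[q[i], s[j]], "M")
        if j < len(s):
            cost = gap_extend if state == "E" else gap_open + gap_extend
            walk(i, j + 1, score - cost, "E")
        if i < len(q):
            cost = gap_extend if state == "F" else gap_open + gap_extend
            walk(i + 1, j, score - cost, "F")

    for i0 in range(len(q)):
        for j0 in range(len(s)):
            walk(i0, j0, 0.0, "start")
    return best


class TestSmithWaterman:
    def test_self_alignment_score_from_matrix(self):
        # BLOSUM62: R.R=5, G.G=6, F.F=6
        aln = smith_waterman("RGF", "RGF")
        assert aln.score == 17
        assert (aln.query_start, aln.query_end) == (1, 3)
        assert aln.aligned_query == "RGF" and aln.aligned_subject == "RGF"

    def test_all_negative_pairs_give_empty_alignment(self):
        aln = smith_waterman("AAA", "WWW")
        assert aln.score == 0 and aln.is_empty

    @pytest.mark.parametrize("q", ["RGF", "DFRPTTPGHSPGVGH", "MKVL"])
    def test_identity_gives_full_coverage_and_similarity(self, q):
        aln = smith_waterman(q, q)
        cov, sim = hit_metrics(aln, len(q))
        assert cov == 1.0 and sim == 1.0

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError):
            smith_waterman("MK", "MJK")  # J not in the matrix alphabet

    def test_gapped_sequences_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("M-K", "MK")

    def test_matches_enumeration_oracle_on_tiny_strings(self):
        # exhaustive over a 4-letter sub-alphabet, lengths 1..3 (complete)
        alpha = "AGRW"
        seqs = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product(alpha, repeat=n)
        ]
        rng = np.random.default_rng(0)
        pairs = [(a, b) for a in seqs for b in seqs]
        for q, s in [pairs[i] for i in rng.choice(len(pairs), 500, replace=False)]:
            assert smith_waterman(q, s).score == _enumerate_local_score(q, s), (q, s)

    def test_matches_biopython_on_short_4letter_pairs(self):
        # sampled pairs of length <= 6 over a 4-letter sub-alphabet
        rng = np.random.default_rng(1)
        aligner = _biopython_aligner()
        alpha = np.array(list("AGRW"))
        for _ in range(2000):
            q = "".join(rng.choice(alpha, rng.integers(1, 7)))
            s = "".join(rng.choice(alpha, rng.integers(1, 7)))
            assert smith_waterman(q, s).score == aligner.score(q, s), (q, s)

    def test_matches_biopython_on_random_full_alphabet_pairs(self):
        rng = np.random.default_rng(2)
        aligner = _biopython_aligner()
        alpha = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(300):
            q = "".join(rng.choice(alpha, rng.integers(5, 25)))
            s = "".join(rng.choice(alpha, rng.integers(20, 120)))
            assert smith_waterman(q, s).score == aligner.score(q, s)

    def test_alignment_internal_consistency(self):
        rng = np.random.default_rng(3)
        alpha = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            q = "".join(rng.choice(alpha, 12))
            s = "".join(rng.choice(alpha, 60))
            aln = smith_waterman(q, s)
            if aln.is_empty:
                continue
            assert len(aln.aligned_query) == len(aln.aligned_subject)
            assert aln.aligned_query.replace("-", "") == q[aln.query_start - 1 : aln.query_end]
            assert aln.aligned_subject.replace("-", "") == s[aln.subject_start - 1 : aln.subject_end]
            # recompute the score from the aligned strings
            score, run = 0.0, None
            for a, b in zip(aln.aligned_query, aln.aligned_subject):
                if a == "-" or b == "-":
                    score -= 1 + (11 if run != ("E" if a == "-" else "F") else 0)
                    run = "E" if a == "-" else "F"
                else:
                    score += SUB[_CODE[a], _CODE[b]]
                    run = None
            assert score == aln.score


class TestHitMetrics:
    def test_partial_query_span_coverage(self):
        # 15-aa query aligned over query residues 4-10 -> coverage 7/15
        from ssptrace.screen import LocalAlignment

        aln = LocalAlignment("q", "s", 4, 10, 1, 7, "PTTPGHS", "PTTPGHS", 30.0)
        cov, _ = hit_metrics(aln, 15)
        assert cov == pytest.approx(7 / 15)

    def test_similarity_counts_gap_columns_in_denominator_only(self):
        from ssptrace.screen import LocalAlignment

        # 10 columns: 6 positive pairs, 2 negative pairs, 2 gap columns
        q = "RGFRGF" + "AW" + "-" + "R"
        s = "RGFRGF" + "WA" + "R" + "-"
        aln = LocalAlignment("q", "s", 1, 9, 1, 9, q, s, 1.0)
        _, sim = hit_metrics(aln, 9)
        assert sim == pytest.approx(0.6)

    def test_nonpositive_query_len_raises(self):
        aln = smith_waterman("RGF", "RGF")
        with pytest.raises(ValueError):
            hit_metrics(aln, 0)


def _records(*seqs):
    return [ProteinRecord(id=f"p{i}", seq=s, lineage="TSAR") for i, s in enumerate(seqs)]


class TestScreenCollection:
    def test_planted_verbatim_motif_is_reported_for_its_family(self, config):
        motif = "DFRPTTPGHSPGVGH"
        prot = _records("MKKLL" + "TSTNQ" * 8 + motif + "TS")[0]
        decoy = _records("TSNQE" * 12)[0]
        decoy = ProteinRecord(id="decoy", seq=decoy.seq, lineage="TSAR")
        hits = screen_collection(
            [MotifQuery("CEP", (motif, motif[:-1] + "Q"))], [prot, decoy], config
        )
        assert [h.subject_id for h in hits] == ["p0"]
        assert hits[0].coverage == 1.0
        span = prot.seq[hits[0].aln.subject_start - 1 : hits[0].aln.subject_end]
        assert motif in span or span in motif

    def test_thresholds_are_inclusive(self, config):
        # setting the thresholds to exactly an observed hit's metrics must
        # retain it; pushing either infinitesimally above must drop it
        motif = "DFRPTTPGHSPGVGH"
        prot = _records("TSNQE" * 8 + "DFRPWTPGHSP" + "TSNQE" * 3)[0]
        loose = config.with_(coverage_min=0.0, similarity_min=0.0)
        (hit,) = screen_collection([MotifQuery("CEP", (motif,))], [prot], loose)
        at = config.with_(coverage_min=hit.coverage, similarity_min=hit.similarity)
        assert len(screen_collection([MotifQuery("CEP", (motif,))], [prot], at)) == 1
        above = config.with_(coverage_min=min(1.0, hit.coverage + 1e-9))
        assert screen_collection([MotifQuery("CEP", (motif,))], [prot], above) == []

    def test_monotone_in_thresholds(self, small_run, config):
        _, collections, _, queries = small_run
        proteins = [p for recs in collections.values() for p in recs]
        loose = screen_collection(queries, proteins, config.with_(coverage_min=0.3))
        tight = screen_collection(queries, proteins, config.with_(coverage_min=0.7))
        base = screen_collection(queries, proteins, config)
        keys = lambda hs: {(h.subject_id, h.family) for h in hs}
        assert keys(tight) <= keys(base) <= keys(loose)

    def test_empty_collection_warns_and_returns_empty(self, config):
        assert screen_collection([MotifQuery("CEP", ("DFRPT",))], [], config) == []

    def test_best_reference_per_subject_and_family(self, config):
        motif = "DFRPTTPGHSPGVGH"
        prot = _records("MKK" + "TSNQE" * 6 + motif)[0]
        # second reference is an exact match, first is diverged: best must win
        weak = "DARPTTPGHSPGVGA"
        hits = screen_collection([MotifQuery("CEP", (weak, motif))], [prot], config)
        assert len(hits) == 1
        assert hits[0].reference == "CEP#1"


class TestProfileRescore:
    def _hits_for(self, queries, proteins, config):
        return screen_collection(queries, proteins, config)

    def test_reference_identical_span_gets_minimal_p(self, config, rng):
        motif = "DFRPTTPGHSPGVGH"
        mq = MotifQuery("CEP", (motif, motif[:-1] + "Q", "A" + motif[1:]))
        prot = _records("TSNQE" * 10 + motif)[0]
        hits = self._hits_for([mq], [prot], config)
        out = profile_rescore(hits, [mq], config, rng, n_database=1)
        assert out[0].kept
        assert out[0].empirical_p <= 2 / (config.profile_null_draws + 1)

    def test_random_subject_p_roughly_uniform(self, config):
        # the selection-corrected null makes background hits' p ~ U(0,1]
        rng = np.random.default_rng(7)
        motif = "DFRPTTPGHSPGVGH"
        mq = MotifQuery("CEP", (motif, motif[:-1] + "Q"))
        alpha = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        decoys = [
            ProteinRecord(id=f"d{i}", seq="".join(rng.choice(alpha, 150)), lineage="x")
            for i in range(120)
        ]
        cfg = config.with_(coverage_min=0.0, similarity_min=0.0)
        hits = self._hits_for([mq], decoys, cfg)
        out = profile_rescore(hits, [mq], cfg.with_(profile_p_max=1.0, profile_evalue_max=1e9),
                              np.random.default_rng(8), n_database=1)
        ps = np.array([h.empirical_p for h in out])
        assert len(ps) == 120
        # mean of U(0,1] is 0.5; tolerate Monte-Carlo noise
        assert 0.35 < ps.mean() < 0.65
        assert (ps > 0).all() and (ps <= 1).all()

    def test_deterministic_under_fixed_seed(self, config, small_run):
        _, collections, _, queries = small_run
        proteins = [p for recs in collections.values() for p in recs]
        hits1 = self._hits_for(queries, proteins, config)
        hits2 = self._hits_for(queries, proteins, config)
        out1 = profile_rescore(hits1, queries, config, np.random.default_rng(5), n_database=9)
        out2 = profile_rescore(hits2, queries, config, np.random.default_rng(5), n_database=9)
        assert [(h.subject_id, h.empirical_p, h.kept) for h in out1] == \
               [(h.subject_id, h.empirical_p, h.kept) for h in out2]

    def test_single_reference_family_passes_through(self, config, rng):
        mq = MotifQuery("CEP", ("DFRPTTPGHSPGVGH",))
        prot = _records("TSNQE" * 8 + "DFRPTTPGHSPGVGH")[0]
        hits = self._hits_for([mq], [prot], config)
        out = profile_rescore(hits, [mq], config, rng, n_database=1)
        assert out[0].kept and math.isnan(out[0].empirical_p)


class TestProfileBuild:
    def test_profile_prefers_consensus_residue(self):
        pssm = build_profile(["DFR", "DFR", "DFK"])
        from ssptrace.io import AMINO_ACIDS

        d = AMINO_ACIDS.index("D")
        w = AMINO_ACIDS.index("W")
        assert pssm[0, d] > 0 > pssm[0, w]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["DFR", "DF"])

    def test_frequencies_are_normalized(self):
        f = profile_frequencies(["DFR", "DFK"])
        assert np.allclose(f.sum(axis=1), 1.0)


class TestCompetitionAndBlacklist:
    def _hit(self, subject, family, p, score, s_start=1, s_end=10):
        from ssptrace.screen import LocalAlignment

        aln = LocalAlignment("q", subject, 1, 10, s_start, s_end, "A" * 10, "A" * 10, score)
        h = ScreenHit(aln=aln, family=family, lineage="TSAR", coverage=1.0,
                      similarity=1.0, evalue=1.0, reference=f"{family}#0")
        h.empirical_p = p
        h.profile_score = score
        return h

    def test_best_family_keeps_subject(self):
        hits = [self._hit("s", "CEP", 0.001, 50.0), self._hit("s", "PSY", 0.05, 20.0)]
        out = competitive_family_assignment(hits)
        kept = [h.family for h in out if h.kept]
        assert kept == ["CEP"]
        dropped = [h for h in out if not h.kept][0]
        assert "outcompeted by CEP" in dropped.reason_dropped

    def test_span_scope_keeps_disjoint_hits(self):
        hits = [self._hit("s", "CEP", 0.001, 50.0, 1, 10),
                self._hit("s", "PSY", 0.05, 20.0, 60, 70)]
        out = competitive_family_assignment(hits, scope="span")
        assert sum(h.kept for h in out) == 2

    def test_blacklisted_label_removed_unannotated_pass(self):
        hits = [self._hit("annotated", "CEP", 0.01, 5.0),
                self._hit("novel", "CEP", 0.01, 5.0)]
        out = annotation_blacklist_filter(
            hits, {"annotated": "Ribosomal Protein"}, ["ribosomal protein"]
        )
        assert [h.kept for h in out] == [False, True]

    def test_empty_blacklist_is_identity(self):
        hits = [self._hit("a", "CEP", 0.01, 5.0)]
        out = annotation_blacklist_filter(hits, {"a": "histone"}, [])
        assert all(h.kept for h in out)


def test_approximate_evalue_decreases_with_score():
    assert approximate_evalue(50, 15, 200) < approximate_evalue(30, 15, 200)
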