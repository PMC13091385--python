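# Methods

`ssptrace` models the computational problem of detecting homologs of plant
small secreted peptides (SSPs) and their LRR receptor-like kinase
(LRR-RLK) receptors in transcriptome-derived protein collections from
deeply branching eukaryotes, and of quantifying how traceable the plant
motifs are to those lineages. This note records the models, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the numerical decisions.

## The screening model

An SSP precursor is modeled as: signal peptide, unstructured prodomain,
and a conserved mature motif whose last residue lies near the C-terminus.
Only the motif carries cross-lineage signal, so homology detection is
motif-anchored: each family is represented by a small set of reference
motifs (12–23 aa), and candidates are found by optimal local alignment.

**Alignment engine.** Affine-gap Smith–Waterman (Gotoh) under BLOSUM62
with the BLASTP-default penalties — a gap of length *k* costs 11 + *k*.
Because the search is exhaustive over all (reference, protein) pairs, no
heuristic pre-screen or e-value gate is needed at this stage; a
Karlin–Altschul e-value column (gapped BLOSUM62 parameters λ = 0.267,
K = 0.041) is emitted for interoperability and is explicitly approximate
(no edge-effect or database-composition correction). The receptor arm
*does* use this approximate e-value (cutoff 1e−5) because its reference
domains are long enough for the Karlin–Altschul regime to be meaningful.

**Hit filters.** Coverage = aligned query span / query length;
similarity = alignment columns with positive substitution score / all
alignment columns (gap columns count in the denominator only — the
"positives" convention rather than percent identity; switchable in
principle by changing the column predicate). Both thresholds default to
0.5 and are inclusive. Per subject and family only the best-scoring
reference's hit is kept (ties: longer coverage, then lexicographic
reference id).

**Profile rescoring.** Each family with ≥ 2 equal-length references gets
a position-specific frequency profile with Henikoff-style pseudocounts
(B = √N background-proportional pseudocounts per column). A hit's subject
span is scored as Σ log₂ f(col, res) − log₂ q(res) with q the *subject's
own* Laplace-smoothed composition — composition-based statistics, which
prevents a biased segment (e.g. a polar prodomain) from looking
significant merely because the profile is built from polar-rich motifs.
Significance is empirical and selection-corrected: the null distribution
is obtained by generating random background subjects (uniform
composition, length = the database's median protein length), searching
them with the same reference set and scoring the best span the same way.
A shuffle of an already-selected span is *not* a valid null — the
optimal local alignment of anything is far from a random arrangement —
which is why the null is over search results. empirical_p is the add-one
exceedance fraction (in (0,1]); the retention rule is empirical_p ≤ 0.5
AND e-value = empirical_p × database size ≤ 10, the permissive
profile-search bound, inclusive. With 1,000 null draws the smallest
attainable p is ≈ 1/1001, so true motif spans (which outscore every null
draw) are retained for any database up to ~10⁴ sequences.

**Family competition.** SSP families share motif cores — the CLE
subclades (CLV3-type vs TDIF-type) most of all — so several family
profiles can legitimately fire on one candidate. As profile databases do
for models within a clan, competing hits on one subject are ranked
(lowest empirical p, then highest profile score, then highest alignment
score) and the best-supported family keeps the candidate: a precursor
carries one mature-peptide family and appears once in the catalog. A
span-scoped variant (compete only overlapping spans) is available for
multi-motif architectures. Misassignment between the two CLE subclades
remains possible at high divergence when a mutated motif genuinely looks
more like the sister subclade; this is a property of the biology, not of
the implementation.

**Secretion evidence is advisory.** The signal-peptide heuristic requires
(a) an Arg/Lys in residues 1–5, (b) an 8-residue window within residues
6–20 of mean Kyte–Doolittle hydropathy ≥ 1.6, (c) a small-X-small
([AGSC]-X-[AGSC]) cleavage triplet ending within residues 14–35. The TM
scan reports maximal runs of 19-residue windows with mean hydropathy
≥ 1.6; segments inside the first 30 residues are not held against a
candidate (signal peptides and TM helices share the same hydrophobic
signature). The motif-position criterion is subject_end / protein length
with a C-terminal default of 0.6 (the literature says "C-terminal region"
without a number; configurable and logged). The three indicators combine
into tiers — high (all pass), medium (one fails), low (≥ 2 fail) — and
never delete a candidate: transcriptome-derived proteins are frequently
truncated, so absence of a signal peptide is weak evidence. These
heuristics are rule-based surrogates for neural predictors, built for
offline testability; they are not reimplementations of those predictors
and should not be used as such on real data without the external-tool
adapters.

**Blacklist.** Candidates whose id carries a confident annotation to an
unrelated family (ribosomal protein, histone, tubulin, actin, heat-shock
protein, ubiquitin by default) are removed; unannotated candidates pass.

## Receptor architecture

The LRR detector chains matches of the plant consensus core LxxLxLxx
(L ∈ {L,I,V,F}) whose starts are adjacent (≤ 8 aa) or one canonical
repeat apart (20–30 aa), requiring ≥ 3 matches; uniformly hydrophobic
windows (≥ 7 of 8 residues in LIVFMAW) are rejected as TM-like, since a
real LRR alternates its leucine core with polar surface residues. The
kinase detector requires ≥ 3 of the 4 ordered subdomain anchors
(Gly-rich loop G.G..G, β3 [VAI].K, catalytic HRD, activation DFG) within
350 aa. Candidates must be recovered by *both* the kinase-domain and the
LRR-domain similarity searches (reciprocal intersection), then pass
ordered validation: LRR end < TM start ≤ TM end < kinase start, with the
TM taken as the first hydropathy segment after the LRR block and outside
the signal-peptide region. On 10,000 random uniform 500-aa decoys the
combined detectors produce no false architecture call (regression-tested
at ≤ 1%).

## Traceability

Given a grouped motif alignment with land-plant (L) and protistan (P)
rows, the reference positions are the columns with non-gap residues in
≥ 50% of L rows. Per position, with gaps excluded from numerators and
denominators everywhere:

* **P→L support frequency** — the fraction of L-group residues that fall
  in the P-group's observed residue set;
* **L→P traceability frequency** — the fraction of P-group residues that
  fall in the L-group's observed residue set.

The set-membership reading is used for both directions (the stricter
per-consensus-residue variant sits behind `consensus_only=True`): it
makes the two directions symmetric in form and reduces to the intuitive
"is this residue state attested in the other group". A direction is
undefined (NaN, flagged, never an exception) when either side of the
column is all-gap. Information content is IC = log₂20 − H in bits, no
small-sample correction by default (the logo-convention correction is
switchable); its uncertainty is the SD over bootstrap resamples of the
L-group rows only — the logo is a land-plant reference property. The
default 1,000 resamples cost milliseconds per position.

## Trees

Pairwise distances are Poisson-corrected, d = −ln(1 − p) over co-non-gap
columns, capped at 5.0 when saturated. Neighbor joining (exact on
additive matrices; negative branch estimates clamped to zero and flagged)
is delegated to scikit-bio behind the module surface. The bootstrap
resamples alignment columns with replacement. The basal-placement
frequency is the fraction of trees in which the land-plant leaves form a
clade containing no protist leaf, on the tree rooted at a user-designated
outgroup or, absent one, by midpoint — midpoint rooting biases toward the
longest path and is the documented fallback, not a recommendation.
Maximum-likelihood inference is out of scope; externally built Newick
trees can be fed to the statistic directly.

## The synthetic benchmark

The generator emulates a curated pan-eukaryotic database screen: seven
protistan supergroup collections, each with 200 background decoys
(uniform composition, 60–250 aa) and 20 planted SSP precursors per
occupied cell of the presence plan. Plant-side references diverge from
each family's canonical motif at 0.05 substitutions/site (four references
per family); protistan positives at 0.2 (a realistic deep-divergence
setting below the 0.3 regime where subclade identity starts to blur).
Ten percent of positives are generated without a signal peptide to
exercise the advisory-evidence policy. Decoys model *real* unrelated
proteins — the things a curated database contains and InterPro annotates —
so every decoy carries a confident mock annotation and planted SSPs carry
none; the blacklist stage therefore does on the benchmark exactly the job
the annotation filter does in a real screen. Receptor scaffolds confine
mutation to spacer positions with region-specific residue pools chosen so
no region can mimic another region's detector; class membership is thus
stable under divergence, which is what lets the valid/invalid mix test
the validator rather than the mutation process.

The default presence plan is a reconstruction of the reported SSP
distribution, satisfying simultaneously: the family breadths
(PSY/CEP/PEP/CLE-CLV3 in 4 lineages, CIF/CLE-TDIF/IDA-IDL in 3, CLEL in
TSAR and Obazoa only, PIP/PIPL and PSK absent), PSY and CEP shared by
Archaeplastida and Amoebozoa, PSY–CIF as the single strongest
family-profile correlation, Archaeplastida–Amoebozoa as the single
strongest lineage correlation, a positive PSY–CEP association, every
lineage occupied, and no pairwise correlation significant at p < 0.05 on
either axis. Cells beyond those constraints are free choices.

What the benchmark does **not** emulate: real transcriptome assembly
artifacts (frameshifts, chimeras, contamination), compositional drift
across lineages, paralog families with internal structure, gapped motif
alignments (generated alignments are substitution-only), and genuinely
novel unannotated background proteins. Passing the benchmark therefore
demonstrates that the machinery is correct and calibrated under its
stated model, not that real-data screens will reach the same recall or
false-discovery rates.

Reference motifs in `DEFAULT_MOTIFS` are synthetic stand-ins modeled on
the published consensus of each family's conserved region, sized 12–23 aa
so that coverage-based filtering is meaningful; they are not curated
sequences. The approximate Arabidopsis copy numbers used by the
breadth-vs-copy-number analysis are literature-compiled family sizes.

## Numerical and design decisions

* Coordinates are 1-based inclusive throughout the API; converters are
  internal.
* All randomness flows from one root seed; stage k draws from
  `default_rng([seed, k])`, so stages are independently reproducible and
  a rerun with the same config is byte-identical.
* Empirical p-values use the add-one estimator (never 0), and bootstrap
  SDs of degenerate (single-valued) resamples return exactly 0.
* Undefined correlations (constant profiles, e.g. the all-zero PIP/PIPL
  and PSK rows) are reported as NaN, excluded from significance counts;
  no multiple-testing correction is applied by default (a
  Benjamini–Hochberg helper exists, off by default) — the per-pair
  p < 0.05 convention is deliberate.
* Group membership (land-plant vs protist) is carried as input metadata
  (`LP|`/`PR|` id prefixes in alignments, explicit labels elsewhere) and
  never inferred from taxonomy.
* Every filtering stage logs input count, surviving count and active
  thresholds; the pipeline report preserves the funnel.

## Known limitations

* The signal-peptide/TM heuristics trade sensitivity for portability;
  real screens should use dedicated predictors through the adapter
  surface (external TSV parsing) and treat the built-ins as smoke tests.
* The CLE subclade boundary is intrinsically soft at high divergence;
  competition assigns borderline candidates to one subclade without an
  uncertainty estimate.
* Midpoint rooting can misplace the root when rate heterogeneity is
  extreme, inflating or deflating the basal-placement frequency; prefer
  an explicit outgroup.
* The profile e-value is calibrated to the screened collection's size and
  median length; screening collections of wildly heterogeneous lengths
  stretches the null's length assumption.
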