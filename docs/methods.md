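# Methods

## Problem setting

`casematch` implements case-based reasoning for diagnostic decision
support: given an index patient described by coded clinical concepts,
retrieve the most similar historical patients and use their primary
diagnoses as candidate diagnoses. The intended setting is
multi-specialty hospital data standardized to OMOP vocabularies
(SNOMED CT, LOINC, HPO, ICD-10-GM/CM, Cancer Modifier, OMOP
Extension), where rare and ambiguous conditions make supervised
learning impractical and an interpretable nearest-neighbor rationale
("these are the concepts your patient shares with case X") is a design
requirement.

## Record model and preparation

A patient record is a bag of concept tokens `VOCAB|ID`, with
laboratory tokens extended by the position of the result relative to
its reference range, `VOCAB|ID|below/within/above` (boundary values
count as *within*: flagged laboratory results are by convention
strictly outside the range). All mentions across visits collapse into
one record; no temporal structure is retained. Preparation removes
information that would leak the label:

1. every ICD-10 token coding one of the record's own primary
   diagnoses, at wildcard granularity (a `B15.-` diagnosis removes
   `B15.0`, `B15.9`, …);
2. every token on an explicit *directly indicative* exclusion list
   (matched on `VOCAB|ID`, ignoring the relation suffix). The list is
   supplied as configuration; no automatic detection is attempted
   because indicativeness is a clinical judgement.

Records with fewer than two remaining mentions are dropped; they
cannot support a meaningful similarity. Gender is stored but not
vectorized by default (a config switch can inject it as a
`GENDER|value` token): it plausibly shapes similarity but there is no
evidence it belongs in the concept space, so the default is
conservative.

## Weighting

Term frequency is the raw mention count, or a presence indicator in
binary mode. The inverse document frequency is the smoothed form

    idf(c) = log((1 + N) / (1 + df_c)) + 1

with natural log (a `log_base` switch gives log10 for sensitivity
analysis; the choice only rescales weights and rarely changes
rankings). The `+1` floor keeps ubiquitous concepts at weight 1
instead of discarding them. Document-frequency filters run on the
binary notion of df regardless of the binary flag: `min_df` (absolute)
removes near-unique noise, `max_df` (proportional) removes
uninformative ubiquitous concepts. Columns are ordered
lexicographically so matrices are identical across runs. Vectors are
not L2-normalized in the vectorizer — cosine retrieval divides by the
norms, so pre-normalization would be redundant work.

## Semantic normalization

Concept names are embedded with a medical-terminology encoder
(dimension 768 by default). From the pairwise cosine matrix `S`, names
with `S_ij ≥ θ` are merged by taking connected components of the
thresholded graph: thresholded similarity itself is not transitive,
but the induced equality of representatives is, and single-linkage
components are the minimal closure consistent with it. Each
component's representative is its highest-corpus-frequency name (ties:
lexicographic), favoring canonical phrasing. Applying the map rewrites
tokens onto the representative's base token while preserving the
reference-range relation, so an *above* result can never merge with a
*below* result. The map is built once on the whole corpus's names —
names carry no diagnosis information, so this leaks no labels — and is
applied before vectorizer fitting, letting merged synonyms pool their
document frequencies.

The default backend in tests is a deterministic mock
(hash-seeded random directions; planted synonym groups receive
near-identical vectors with in-group cosine ≥ 0.99, while independent
768-dimensional directions stay far below 0.5). A pretrained
multilingual medical encoder can be loaded by name at runtime when the
optional transformers stack is installed; no test depends on it.

## Retrieval and evaluation

Similarity is the cosine of raw weight vectors. Rankings sort by
descending score and break ties by ascending record id; scores are
rounded to 12 decimals before ranking so mathematically tied cosines
reach the id tie-break regardless of floating-point summation order.
A query or candidate with a zero weight vector cannot be scored: zero
candidates are excluded from the ranking, and a zero *index* vector is
an error in direct retrieval. Inside cross-validation it is counted as
an all-miss fold and reported (`n_skipped`) — dropping such folds
silently would overstate performance.

Evaluation is leave-one-out: each record once serves as the index; the
vectorizer (document frequencies, idf, filters) is refit on the
remaining N−1 records so the index never influences its own weighting.
A `refit_per_fold=False` fast path fits once globally; it is cheaper
but mildly optimistic, since the index then contributes to the idf it
is scored with. A retrieved neighbor is a true positive when it shares
at least one primary diagnosis with the index at the chosen
granularity. Reported per stratum and cutoff k ∈ {1, 3, 5, 10}:

* precision@k — mean fraction of true positives among the top k;
* success rate SR@k — fraction of indices with ≥ 1 true positive in
  the top k;

both with empirical *population* standard deviations (divisor N).
precision@1 ≡ SR@1 by construction. Diagnoses are stratified by
dataset occurrence — prevalent (> 10 records), infrequent (2–10),
singleton (1). A record with any prevalent diagnosis is evaluated in
the prevalent stratum (preventing double counting of mixed records);
records whose only diagnoses are singletons are excluded — no true
positive is possible for them. Infrequent indices are evaluated at
k = 1 only. The random baseline draws neighbors uniformly without
replacement; one repetition by default (the single-run convention),
configurable for tighter Monte-Carlo error. Grid search enumerates
binary × max_df × min_df (× θ for the semantic method), scores each
combination by top-1 precision over the combined eligible pool, and
orders results deterministically (objective, then SR, then
parameters).

## ICD-10 granularity

Codes are treated as opaque prefix-structured strings; no external
code-system file is used. Matching levels: full code (with `B15.-`
style categories acting as wildcards), 3-character category, chapter
(first letter), and medical specialty via a longest-prefix lookup
table. The shipped default table covers the synthetic catalog's
thirteen diagnoses across gastroenterology, pneumology and
endocrinology. Note that chapter→specialty coarsening is only monotone
when the specialty map is consistent with chapters; the default table
is *not* (chapter E splits into endocrinological and
gastroenterological prefixes), so monotonicity properties are asserted
with a chapter-consistent map. Chapter means first character only;
true ICD-10 chapters spanning letter ranges (C and D in chapter II)
are deliberately not merged.

## Synthetic cohort generator

Real cohorts of this kind cannot be redistributed, so the generator
emulates the structure of such a cohort: 4295 records; a
13-diagnosis catalog whose weights put bronchial carcinoma (C34.-) at
48.83% of diagnosis draws; 77/19/3/1% of records carrying 1/2/3/4
primary diagnoses (extra diagnoses drawn without replacement, which
slightly dilutes the dominant code's share within records); wildcard
catalog entries realized as random subcodes so full-code and
category-level matching differ; a log-normal mention budget with
mean-log 1.868 and sd-log 1.576 — fixed analytically so that ≈ 17.7%
of raw records fall below two prepared mentions and the mean matches
the corpus-wide ≈ 22.4 mentions per record — capped at 127 total and
109 distinct mentions; a 2054-concept background pool sized per the
per-vocabulary distinct counts with a Zipf(0.7) popularity profile and
vocabulary mix proportional to corpus totals; and a reference-range
relation on 72% of laboratory mentions.

The *diagnostic signal* is generator-specific plumbing: each catalog
diagnosis owns a disjoint signature of 5 tokens outside the background
pool; a record carrying the diagnosis includes each signature token
with probability `s` (`signal_strength`, default 0.8 — strong but
imperfect). Included signature tokens are ordered (each diagnosis's
first token first) and absorb a fixed fraction (0.6) of the record's
mention budget, with a floor of one mention per included token so
lightly documented records are essentially pure signature. This makes
`s = 1` recovery a construction property — any two records sharing a
diagnosis share its leading signature tokens and the majority of their
weighted mass — while `s = 0` severs concepts from diagnoses entirely,
so retrieval precision falls to the analytic random-match base rate.
Laboratory signature tokens carry a fixed abnormal relation
(consistently characteristic results); background laboratory relations
are drawn per record.

What the generator does **not** emulate: clinical language, visit
structure and temporal progression, inter-concept correlation beyond
the planted signatures, and gender-specific disease patterns. Passing
recovery tests therefore demonstrates the correctness of the pipeline
arithmetic and its behavior under controlled signal, not clinical
performance on real data.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at the emulated
cohort scale (4295 records) for structural checks and at 250–300
records for leave-one-out recovery studies, with random property
checks on bases of 5–12 records — sizes chosen so the full pipeline,
including per-fold refitting, is exercised end to end in seconds.
Degenerate inputs are errors, not silent defaults: empty vocabularies
after df filtering, zero query vectors in direct retrieval, empty
diagnosis sets, and inverted reference ranges all raise validation
errors naming the offending filter or record.

## Known limitations

* Laboratory results are reduced to a three-way relation; borderline
  and extreme abnormalities are indistinguishable.
* The concept map is name-keyed; homonyms (one name, two meanings)
  merge incorrectly if present.
* The specialty level requires a curated prefix map and refuses
  unmapped codes rather than guessing.
* No statistical testing between methods is provided — only empirical
  standard deviations.
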