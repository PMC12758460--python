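# casematch

Case-based reasoning over coded patient records: retrieve the
historical patients most similar to an index case and evaluate how
well their primary diagnoses predict the index diagnosis.

Rare and ambiguous diseases are hard to diagnose precisely because the
cases a physician would want to compare against are scarce and
scattered. `casematch` supports this comparison directly: patient
records standardized to OMOP vocabularies (SNOMED CT, LOINC, HPO,
ICD-10-GM/CM, …) are turned into sparse concept vectors, the nearest
historical cases are retrieved by cosine similarity with an explicit
list of shared concepts as the explanation, and the whole pipeline is
evaluated by leave-one-out cross-validation across diagnosis
prevalence strata and ICD-10 granularity levels.

## Model

Each record `p_i` is a bag of concept tokens `VOCAB|ID`, with
laboratory results extended by their reference-range relation
(`LOINC|1742-6|above`). Concept weights use term frequency and the
smoothed inverse document frequency

    w_ij = TF(c_j, p_i) · idf(c_j),   idf(c_j) = ln((1+N)/(1+df_j)) + 1

with optional binary TF and document-frequency filters (`min_df`,
`max_df`). An optional semantic step embeds concept *names* with a
medical-terminology encoder, merges names whose pairwise cosine
reaches a threshold θ (connected components; most frequent name as
representative), and pools the merged counts. Similarity between
records is the cosine

    cos(p_index, p_i) = (p_index · p_i) / (‖p_index‖ ‖p_i‖)

Retrieval quality is measured by precision@k and success rate SR@k
(share of index patients with ≥ 1 diagnosis-sharing case in the top k)
with empirical standard deviations, evaluated separately for prevalent
(> 10 occurrences) and infrequent (2–10) diagnoses, and at four code
granularities: full ICD-10 code, 3-character category, chapter letter,
medical specialty.

Because real clinical cohorts of this kind cannot be shared, the
package ships a seeded synthetic-cohort generator
(`casematch.synthetic_data`) that emulates the structure of a
multi-specialty hospital cohort — diagnosis catalog and frequencies,
multi-diagnosis distribution, per-record concept-count distribution,
vocabulary mix, laboratory reference-range coverage — with a tunable
planted diagnostic signal and full ground truth, so every stage is
testable end to end.

## Worked example

Simulate a 300-record cohort, evaluate TF-IDF retrieval, and query one
patient:

```sh
casematch simulate --out demo --n 300 --seed 11
casematch evaluate --data demo --method tfidf --ks 1,3,5,10 --out demo_eval --no-baseline
```

```
method level    stratum  k   n  precision  precision_sd  success_rate  success_rate_sd
 tfidf  full  prevalent  1 208   0.293269      0.455261      0.293269         0.455261
 tfidf  full  prevalent  3 208   0.298077      0.246420      0.687500         0.463512
 tfidf  full  prevalent  5 208   0.296154      0.198999      0.822115         0.382416
 tfidf  full  prevalent 10 208   0.288462      0.148264      0.942308         0.233161
 tfidf  full infrequent  1  35   0.200000      0.400000      0.200000         0.400000
 tfidf  full        all  1 243   0.279835      0.448918      0.279835         0.448918
```

Of the 300 simulated records, 243 survive preparation and carry a
non-singleton diagnosis. For prevalent diagnoses, 94% of index
patients have at least one diagnosis-sharing case among their ten
nearest neighbors (SR@10 = 0.94), while on average 29% of those ten
neighbors share a diagnosis (precision@10 = 0.29) — the
high-SR / moderate-precision profile typical of this retrieval task at
full-code granularity. Precision and SR coincide at k = 1 by
definition. Evaluating at `--level category3` instead of full codes
raises top-1 precision sharply, since sibling codes of one category
(e.g. `C34.1` vs `C34.9`) then count as matches.

```sh
casematch retrieve --data demo --person-id P005 --k 3
```

```json
{
  "index_id": "P005",
  "k": 3,
  "neighbors": [
    {
      "id": "P066",
      "score": 0.505940473443502,
      "shared_concepts": [
        "HPO|SIG-C34-1",
        "LOINC|SIG-C34-2|above",
        "LOINC|SIG-C34-3|above"
      ],
      "primary_diagnoses": ["C34.9"]
    },
    ...
  ]
}
```

Each neighbor comes with its similarity score, its diagnoses, and the
concepts it shares with the index patient — the explanation a
decision-support front end would display.

Other commands: `casematch gridsearch` (scan binary × max_df × min_df
× θ, ranked by top-1 precision) and `casematch rank-concepts` (top-N
concepts per diagnosis group by summed TF-IDF weight). The library API
mirrors the CLI: see `casematch.evaluation.loocv`,
`casematch.retrieval.top_k`, `casematch.semantic_map`,
`casematch.relevance`.

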