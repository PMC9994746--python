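# preprintmatch

Link preprints to their peer-reviewed published versions. For each
preprint, the pipeline decides which published paper (if any) is its
published version:

1. **Ingest** — published-paper metadata from MEDLINE/PubMed-dialect XML
   (with date canonicalization and language / publication-type filters)
   and preprint metadata from a JSON-lines schema.
2. **Embeddings** — subword-aware skip-gram word vectors trained
   separately on titles and abstracts; any text maps to a unit-norm
   sentence vector (normalized average of token vectors, with
   out-of-vocabulary tokens composed from character 3–6-grams).
3. **Retrieval** — all paper vectors live in a memory-mapped float32
   matrix; the candidate set for a preprint is the union of the top-100
   most cosine-similar titles and top-100 abstracts.
4. **Author similarity** — Jaccard over exactly-matching last names,
   with a flip check (paper last names vs preprint fore names, for
   records with swapped name fields); the higher score wins.
5. **Decision** — an RBF-kernel SVM over (title, abstract, author)
   similarity, trained on 100 matching and 100 hard-negative pairs
   (hard negatives: highest title×abstract product for unpublished
   preprints), plus a rule layer: rescues for identical 7-word abstract
   openings, identical pre-colon titles, and exactly matching >10-author
   sets; a veto for SVM positives with author Jaccard < 0.33 unless
   title or abstract similarity exceeds 0.999.
6. **Evaluation** — recall/precision/F1, consensus test-set
   construction with curation of conflicts, exact McNemar paired tool
   comparison, feature-subset ablations, and time-gap vs similarity
   reporting.

A synthetic-corpus generator (`preprintmatch.fixtures`) produces labeled
preprint/paper corpora with controlled text-revision and author-edit
noise, so the whole pipeline is exercisable and testable offline.

## CLI

Everything runs from one working directory driven by a YAML config:

```yaml
# config.yaml
fixture:    {n_pairs: 200, n_decoys: 300, n_unpublished: 100, seed: 1}
embedding:  {dimension: 100, sample_fraction: 1.0, seed: 0, min_count: 2, epochs: 5}
classifier: {n_pos: 100, n_neg: 60}
rules:      {top_k: 100}
```

```sh
# full synthetic run: generate fixtures, ingest, train, index, classify,
# match and evaluate; stages write manifests and skip when up to date
preprintmatch pipeline --config config.yaml --workdir run/

# individual stages
preprintmatch fixtures generate --config config.yaml --out run/
preprintmatch ingest pubmed --xml 'run/pubmed.xml' --out run/ --preprints run/preprints.jsonl
preprintmatch train-embeddings --workdir run/ --dim 100 --sample 0.1 --seed 0
preprintmatch build-index --workdir run/
preprintmatch train-classifier --workdir run/ --truth run/truth.jsonl
preprintmatch match --workdir run/
preprintmatch evaluate --workdir run/ --truth run/truth.jsonl [--compare other_tool.jsonl]
```

`match` writes `matches.jsonl` (one `{"doi", "pmid", "path", "scores"}`
object per preprint; `pmid` is null for no-match). `evaluate` writes
`report.json` with counts and metrics, plus a McNemar comparison when
`--compare` points at another tool's doi→pmid predictions.

Preprint input rows look like:

```json
{"doi": "10.1101/...", "title": "...", "abstract": "...",
 "posted_date": "2020-05-04", "authors": ["Mary Jane Watson", "..."],
 "announced_pub_id": "12345"}
```

(`authors` may also be `{"fore_name", "last_name"}` objects;
`announced_pub_id` is optional.)

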