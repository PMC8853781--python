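# dsds

Decision support for syndrome diagnosis over a clinical knowledge graph.

Per-visit clinical records (seven free-text diagnostic fields plus a
syndrome label) are segmented into symptom tokens by punctuation, assembled
into a typed knowledge graph linking symptoms to syndromes, and embedded in
complex vector space (triple score = real part of the Hermitian three-way
product, trained by logistic-loss SGD over sampled corruptions). An unseen
record is diagnosed by *dismantling* it into tail-missing queries — one per
resolvable symptom — scoring every candidate syndrome per query, and
aggregating per-query top-k shortlists by frequency voting into a top-N
recommendation. Weighted multiclass metrics and top-N accuracy close the
loop, and a synthetic-corpus generator with controllable cross-syndrome
symptom overlap makes the whole pipeline testable without clinical data.

## CLI

Everything hangs off a single `dsds` entry point:

```bash
# generate a synthetic corpus with planted structure
dsds simulate -o corpus.tsv --seed 7

# validate / segment a corpus
dsds corpus validate corpus.tsv --strict
dsds corpus segment corpus.tsv --punct "，；,;"

# build the knowledge graph and inspect redundancy statistics
dsds kg build corpus.tsv -o kg/
dsds kg stats corpus.tsv

# train embeddings and predict
dsds train kg/ --config train.yaml -o model.npz
dsds predict model.npz kg/ corpus.tsv --top-n 5 --shortlist-k 10

# split-evaluate (weighted precision/recall/F1, accuracy, top-1/3/5)
dsds evaluate corpus.tsv --seed 1 --top-n 1,3,5

# full pipeline from one YAML config
dsds run --config pipeline.yaml

# end-to-end recovery experiment on synthetic data
dsds simulate --recovery --seed 7
```

`train.yaml` keys mirror `TrainConfig` (`dim`, `epochs`, `learning_rate`,
`negatives`, `reg`, `batch_size`, `seed`, `resample_negatives`);
`pipeline.yaml` mirrors `PipelineConfig` (`corpus_path`, `out_dir`,
`punctuation`, `train:` sub-map, `shortlist_k`, `top_n_list`,
`train_fraction`, `seed`).

## Package layout

| Module | Contents |
| --- | --- |
| `dsds.corpus` | record model, punctuation segmentation, TSV/JSONL corpus I/O |
| `dsds.kg` | graph construction, entity statistics, triple file I/O |
| `dsds.embedding` | complex-embedding scoring, negative sampling, SGD training, ranking |
| `dsds.recommender` | dismantling, candidate matrix, score-and-vote aggregation |
| `dsds.metrics` | weighted multiclass metrics, top-N accuracy, split harness |
| `dsds.synthetic` | planted-structure corpus generator, recovery experiment |
| `dsds.pipeline` / `dsds.cli` | orchestration and the `dsds` command |
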