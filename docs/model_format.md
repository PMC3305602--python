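# Error-model file format (`.gem`)

A model file is a gzip-compressed UTF-8 JSON document. JSON keeps every
count an exact integer (no binary float drift), gzip keeps the sparse
nested tables small, and the format stays greppable after `zcat`.

## Top level

| key | type | meaning |
|---|---|---|
| `format` | string | version tag, currently `"gemsim-model/1"`; loaders must refuse anything else |
| `paired` | bool | paired-end model (two mate sub-models) |
| `mates` | array | 1 or 2 mate sub-model objects (below) |
| `insert_size_hist` | object | `{insert_bp: count}`, \|TLEN\| of properly paired first mates; empty for single-end |
| `n_pairs` | int | pairs seen (first-in-pair records) |
| `n_properly_paired` | int | pairs with both mates mapped; the properly-paired fraction is the quotient |
| `total_reads` | int | mapped reads accumulated |
| `min_word_count` | int | the backoff support threshold `x` the model was filled with |

## Mate sub-model

Context words are keyed `"<preceding>.<current>.<following>"`, e.g.
`"ACG.T.A"`; preceding may be 0–3 bases (read-start truncation or backoff
marginals), following may be empty (read end). Read positions are 0-based
sequencing cycles, serialized as string keys.

| key | layout | meaning |
|---|---|---|
| `counts` | `{pos: {word: [7 ints]}}` | raw observations; vector order: correct, mismatch→A, →C, →G, →T, insertion events, deletion events |
| `insertion_detail` | `{word: {inserted_string: count}}` | what was inserted after the word |
| `deletion_detail` | `{word: {length: count}}` | deletion lengths after the word |
| `quality_hist` | `{pos: {class: {phred: count}}}` | class ∈ `correct`, `mismatch`, `insertion` |
| `read_length_hist` | `{length: count}` | mapped read lengths |
| `filled` | `{pos: {word: [7 ints]}}` | backoff replacements for full-length words rarer than `x` in the control reference; consulted before `counts` at simulation time |
| `marginals` | `{pos: {word: [7 ints]}}` | suffix-aggregated cells for every shortened word; the simulation-time fall-through chain for zero-support lookups |

`counts` is the statistical record (summary statistics use it
exclusively); `filled` and `marginals` are derived tables materialized by
the sparse-context fill so that simulation never needs the control genome.

Loading a file that is truncated, not gzip/JSON, or carries a different
`format` tag fails with a `ValueError` naming the problem.
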