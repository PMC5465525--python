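# pprlink

Privacy-preserving record linkage (PPRL) with **cryptographic long-term keys
(CLKs)** and **multibit trees**:

- **Encoding** — personal identifiers (names, date of birth, sex, address…)
  are decomposed into unigrams/bigrams and hashed with a secret-keyed digest
  into a single fixed-length Bloom filter per record (default 1000 bits,
  10 hashes per gram, full random hashing).
- **Search** — CLKs are indexed in a popcount-binned forest of split-half
  trees; Tanimoto (Jaccard) threshold queries prune whole subtrees with a
  provable similarity upper bound, so results are exactly those of a
  brute-force scan.
- **Evaluation** — candidate pairs are scored against a truth set with
  pairwise precision, recall and F-measure, including threshold sweeps.
- **Synthetic data** — truth-linked populations with configurable duplicate
  rates, typographical corruption and per-field missingness profiles
  (`nsw_public`, `nsw_private`, `wa`), so everything is testable without
  access to restricted hospital data.

## CLI

All commands live under a single `pprlink` entry point. The hashing secret is
read from `$PPRLINK_SECRET` (or `--secret-file`), never from argv or config.

```sh
export PPRLINK_SECRET='choose-a-strong-secret'

# 1. generate a synthetic population with known truth
pprlink synth --n 10000 --dup-rate 0.5 --profile wa --typo-rate 0.05 \
    --seed 42 --out records.csv --truth truth.csv

# 2. encode records into CLKs (config optional; defaults shown in config.py)
pprlink encode --in records.csv --config cfg.yml --out clks.clk

# 3. de-duplicate above a Tanimoto threshold
pprlink dedup --clks clks.clk --threshold 0.85 --leaf-limit 1 --out pairs.csv

#    ... or with external blocking on year of birth
pprlink dedup --block-on dob:year --records records.csv --threshold 0.85 \
    --out pairs.csv

# 4. evaluate against the truth set
pprlink evaluate --pairs pairs.csv --truth truth.csv --ids clks.clk \
    --out report.json

# or sweep a threshold range in one pass
pprlink sweep --clks clks.clk --truth truth.csv \
    --thresholds 0.7,0.8,0.85,0.9,1.0 --out sweep.csv
```

Two-file linkage uses `pprlink link --left a.clk --right b.clk ...`.

A YAML config can set `column_map`, `parameter_set` (`set1`…`set4`),
`gram_modes`, `padding`, `l`, `k`, `scheme`
(`random_hashing`/`double_hashing`), `salt_field`, `field_tagging`,
`positional_unigrams`, `threshold` and `leaf_limit`; command-line flags
override it. Exit codes: 0 success, 1 usage error, 2 data/config error.

## Library

```python
from pprlink import (
    EncodingConfig, parameter_set, corruption_model,
    generate_population, encode_dataset, deduplicate, evaluate,
)

pop = generate_population(1000, 0.5, corruption_model("wa", typo_rate=0.05), seed=1)
clks = encode_dataset(pop.records, parameter_set("set1"),
                      EncodingConfig(secret="..."))
pairs = deduplicate(clks, threshold=0.85, leaf_limit=1)
report = evaluate(pairs, pop.truth, pop.record_ids(), threshold=0.85)
```

## Notes

- CLK files are line-oriented text: a header with `l`, `k`, scheme and
  parameter-set name, then `record_id TAB base64(bits) TAB popcount`
  (bit 0 = MSB of the first byte). Secrets never appear in any output.
- The multibit-tree query is exact: pruning uses a sound Tanimoto upper
  bound, and the candidate criterion is similarity **≥** threshold.
- Blocking keys are stored only as keyed hashes; records with a missing
  blocking field form their own block (logged, costs recall).
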