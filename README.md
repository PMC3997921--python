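# fragnet

Model-agnostic interpretation of binary (Q)SAR classifiers via feature
combination networks.

Given a query molecule and any binary predictor operating on structural
fingerprints, fragnet enumerates sub-features of the query — either
combinations of fingerprint bits (*bitset* approach) or connected fragments
from a reduced-graph fragmentation (*fragment* approach) — organises them
into a subset-ordered network (DAG), runs the model on every node, and
classifies each node as one of
`ACTIVATING / DEACTIVATED / DEACTIVATING / NEGATED / ACTIVITY_IDENTIFIED / IGNORE`.
The result is summarised as activating highlights and
(deactivating → deactivated) highlight pairs on the query's atoms and bonds,
without ever changing the model's prediction.

Also included:

- a fragment-dictionary **applicability domain** (a query is in domain iff
  training-set fragments occurring ≥ 4 times cover all of its atoms/bonds);
- **mining** of ACTIVATING features across a labelled dataset with
  occurrence / signal / accuracy statistics, plus SEN/SPEC/BAC/coverage
  metrics;
- deterministic **fixtures**: a seeded toy molecule generator with planted
  structural alerts, a rule-based mock predictor, random subset-lattice
  networks and an 11-node worked-example network;
- a toy trainable random-forest model behind the same predictor contract.

## Library quick start

```python
from fragnet import parse_structure, interpret
from fragnet.fixtures import default_oracle

query = parse_structure("O=[N+]([O-])c1cccc2ccccc12")   # 1-nitronaphthalene
summary, network = interpret(query, default_oracle())
print(summary.final_prediction)                # "active"
for a in summary.activations:
    print(sorted(a.highlight.atom_ids))        # [0, 1, 2] — the nitro group
```

Any object with a `predict(feature_vector) -> Prediction` method can be used
as the model. `RunConfig` selects the approach (`fragment` or `bitset`),
fingerprint scheme (`structural_keys` with a SMARTS key library, or
`hashed_path`), pruning level, fragmentation depth and domain threshold.

## Command line

```bash
fragnet fixtures export --n 40 --seed 1 --out toy.tsv     # smiles<TAB>label<TAB>name
fragnet train-toy --input toy.tsv --out model.joblib
fragnet interpret --model model.joblib --input toy.smi --out summaries.json
fragnet interpret --model oracle --input toy.smi --out summaries.json --dot net.dot
fragnet fragment --input toy.smi --out fragments.tsv
fragnet enumerate-bits --bits 1,3,7,8
fragnet domain build --input toy.smi --out dict.tsv --min-occurrence 4
fragnet domain check --dict dict.tsv --input queries.smi
fragnet mine --input toy.tsv --model oracle --out mined.tsv
```

Configuration can be supplied as YAML via `--config`; unknown keys are
rejected. Models are stored together with a fingerprint-settings hash and
refuse to run against mismatched descriptor configurations.

## Layout

| module | contents |
| --- | --- |
| `fragnet.chem_io` | structure parsing/standardisation, highlights, file I/O |
| `fragnet.fingerprints` | key library, structural-key & hashed-path fingerprints, fragment fingerprinting |
| `fragnet.fragmentation` | reduced graph, connected fragment enumeration |
| `fragnet.enumeration` | bit-combination enumeration and counting laws |
| `fragnet.network` | feature-network DAG, closures, JSON/DOT export |
| `fragnet.assessment` | node prediction, six-way classification, summaries, `interpret` |
| `fragnet.domain` | fragment-dictionary applicability domain |
| `fragnet.mining` | ACTIVATING-feature mining, SEN/SPEC/BAC/coverage |
| `fragnet.fixtures` | toy library, rule oracle, random networks, worked example |
| `fragnet.cli` | `fragnet` command group, toy model training |
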