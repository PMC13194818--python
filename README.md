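# varqa

Retrieval-augmented question answering for human genomic variants, together
with the machinery to benchmark it: a 50-template question registry, a
constrained benchmark sampler, a five-criterion scoring rubric with winner
tallies, and a battery of paired nonparametric statistics and inter-rater
agreement measures.

## What it does

The answer pipeline runs six steps over pluggable backends:

1. detect the single variant identifier (rs number or HGVS notation) in a
   free-text question;
2. normalise it to a GRCh38 genomic allele — locally for `chr{C}:g.{POS}{REF}>{ALT}`
   substitutions, otherwise through a recoder contract (a lookup-table
   fixture stands in for a live recoding service);
3. fetch the variant's integrated annotation record as JSON from a variant
   client (a deterministic fixture-directory mock stands in for the live
   API);
4. substitute the JSON into the three-section prompt template;
5. send the prompt to an LLM backend (a deterministic stub is shipped);
6. return an answer envelope with full provenance.

Questions without an identifier — or whose variant is unknown — fall back to
a retrieval-free baseline prompt that differs from the full prompt only in
the retrieval instruction.

The evaluation side builds a 1500-question pool (50 templates x 30 rs
numbers), samples 150 questions so every template appears at least once,
scores answers 0–10 on five criteria (accuracy, completeness, logical
consistency, clarity/conciseness, evidence support; total 0–50), tallies
per-question unique winners, and compares systems with Friedman/Kendall's W,
Holm-adjusted paired Wilcoxon tests and bootstrap CIs. Inter-rater agreement
is quantified with ICC(2,2), quadratic-weighted Cohen's kappa and absolute
score differences.

## Layout

| Module | Role |
| --- | --- |
| `varqa.identifiers` | rs/HGVS detection, genomic-HGVS parsing, GRCh38 normalisation |
| `varqa.variant_store` | variant-record model, JSON round-trip, mock client |
| `varqa.prompting` | three-section prompt assembly + baseline prompt |
| `varqa.rag_pipeline` | step 1–6 orchestration, batch answering |
| `varqa.benchmark` | template registry, pool builder, constrained sampler |
| `varqa.evaluation` | rubric scores, rater aggregation, winner tallies, LLM judge |
| `varqa.stat_battery` | bootstrap CIs, Friedman/W, Wilcoxon–Holm, ICC(2,2), weighted kappa |
| `varqa.synthetic_data` | fixture generation, stub backends, score-table simulation |

Packaged resources (`src/varqa/resources/`): the prompt template, the
50-template TSV registry, the judge rubric, the variant-record JSON schema,
and the worked-example record for rs34637584.

## CLI

```sh
varqa fixtures make --n 30 --seed 0 --out fixtures/
varqa ask "What is the clinical significance of rs34637584 in ClinVar?" \
    --fixture-dir fixtures/
varqa batch questions.txt --fixture-dir fixtures/ --out envelopes.jsonl

varqa benchmark pool --rs-file rs30.txt --out pool.jsonl
varqa benchmark sample --pool-file pool.jsonl --n 150 --seed 0 --out sample.jsonl

varqa evaluate judge --answers answers.jsonl --out scores.csv
varqa evaluate tally --scores scores.csv
varqa stats compare --scores scores.csv --by criterion
varqa stats agreement --scores scores.csv
varqa fixtures simulate-scores --config sim.json --out sim.csv
```

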