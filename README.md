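# metagenex

Pipeline for extracting condition-relevant genes from two-condition gene
expression matrices via nonnegative matrix factorization (NMF) under the
generalized Kullback–Leibler divergence.

Stages:

1. **synthetic_data** — planted two-condition studies: low-rank expression
   matrices with sparse marker blocks per latent factor, shared and
   condition-B-specific marker sets, Poisson or truncated-Gaussian noise,
   and an annotation table with symbol / cDNA / hypothetical / non-human /
   obsolete categories and duplicate symbols.
2. **nmf_core** — KL-NMF with multiplicative updates, multi-start random
   initialization (best run by final divergence), consensus clustering over
   restarts and cophenetic-correlation-based empirical rank selection.
3. **gene_extraction** — entropy-based gene scores on the basis matrix
   (1 = one-hot loading, 0 = uniform), selection when score > median + 3·MAD
   **and** row max > median(W), assignment to the argmax metagene, and choice
   of the most informative metagene (most selected genes).
4. **comparative_postprocess** — common/uncommon sets between the two
   conditions' extractions, probe→symbol mapping with category accounting,
   symbol deduplication, per-condition expression medians.
5. **validation_qc** — per-gene volcano statistics (two-sample t),
   first-principal-component summary, concatenated-matrix validation:
   rank bound check, column-normalized metagene sample weights, exact
   Wilcoxon rank-sum comparison of weights between conditions, and
   containment of the common set in the concatenated extraction.
6. **io_formats** — TSV/CSV matrix and annotation I/O, schema-versioned JSON
   reports, a GEO series-matrix convenience reader, and the CLI.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (update
monotonicity, exact-recovery limits, scoring/threshold oracle equivalence,
rank-selection recovery, end-to-end planted-marker recovery, set-algebra
identities and statistical-stage checks).

## CLI

```sh
metagenex simulate --outdir study --seed 0
metagenex fit --matrix study/X_a.tsv --rank 5 --n-runs 10 --seed 0 --outdir fit_a
metagenex survey --matrix study/X_a.tsv --ranks 2,3,4,5,6 --n-runs 20 --seed 0 --out survey.json
metagenex extract --model-dir fit_a --out-prefix a_
metagenex compare --sets-a a_metagene_sets.json --sets-b b_metagene_sets.json \
    --annotation study/annotation.tsv --matrix-a study/X_a.tsv \
    --matrix-b study/X_b.tsv --out-prefix cmp_
metagenex validate --matrix-a study/X_a.tsv --matrix-b study/X_b.tsv \
    --common cmp_comparison.json --rank 5 --out validation.json
metagenex qc --matrix study/X_a.tsv --labels A,A,A,A,B,B,B,B --out-prefix qc_
```

A JSON config file keyed by subcommand can pre-set any flag
(`metagenex --config cfg.json fit ...`); explicit flags win.

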