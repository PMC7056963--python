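# cgsea

Chemical gene set enrichment analysis: a permutation-based method for
scanning which chemicals are associated with a complex disease or trait,
given only genome-wide gene-level summary statistics.

Many chemicals act on disease by perturbing gene expression. The
Comparative Toxicogenomics Database (CTD) curates which genes each
chemical interacts with, and transcriptome-wide association studies
(TWAS) — or ordinary differential-expression analyses — provide a
Z-score per gene for a trait of interest. `cgsea` connects the two: for
each chemical it asks whether that chemical's CTD gene set is
concentrated at the top of the trait's ranked gene list. It is intended
for toxicogenomics and complex-trait researchers who have TWAS output
(e.g. from FUSION) or any gene→statistic table, and want a ranked,
FDR-annotated list of candidate chemicals.

## The statistic

Genes are ranked by their statistic L_i from maximum to minimum, giving
L^s = [L_1^s ≥ … ≥ L_N^s]. For a chemical's gene set C with N_C genes,
the enrichment score is the maximum of a weighted
Kolmogorov–Smirnov-like running sum:

    ES_C = max_j [ Σ_{g_i ∈ C, i ≤ j} |L_i^s|^w / N_R  −  Σ_{g_i ∉ C, i ≤ j} 1/(N − N_C) ]

with N_R = Σ_{g_i ∈ C} |L_i^s|^w and weight exponent w = 1 by default.
The null distribution ES_null is obtained by randomly shuffling the gene
labels P times (default P = 5000); the observed score is standardized to

    NES_C = (ES_C − mean(ES_null)) / SD(ES_null)

and the empirical P value is the add-one-corrected upper-tail fraction
of null NES values at or above the observed NES, so the smallest
attainable P is 1/(P+1) ≈ 0.0002 at the default P. Benjamini–Hochberg
q-values are added across chemicals.

## Worked example

No external data is needed: the package can simulate a study in which
one chemical's 20 member genes receive a +2 shift on their Z-scores
among 1000 genes and 49 decoy chemicals.

```sh
cgsea simulate --out-dir demo --n-genes 1000 --n-chemicals 50 \
      --set-size 20 20 --planted 1 --delta 2.0 --seed 7
cgsea run --annotations demo/annotations.tsv --stats demo/gene_stats.tsv \
      --out demo/run --permutations 5000 --seed 1
head -4 demo/run.results.tsv
```

```
chemical_id  chemical_name  set_size_annotated  set_size_used  es        nes      p_empirical  q_bh
D000001      CHEMICAL0001   20                  20             0.889108  5.24486  0.00019996   0.009998
D000025      CHEMICAL0025   20                  20             0.64355   3.23664  0.00079984   0.019996
D000009      CHEMICAL0009   20                  20             0.558364  2.59882  0.00559888   0.0874825
```

The planted chemical (`D000001`, per `demo/truth.tsv`) ranks first: its
running sum peaks at ES = 0.889, more than five null standard
deviations above the permutation mean (NES = 5.24), and no shuffled
ranking matched it, so the empirical P sits at the floor
1/5001 ≈ 0.0002 and survives FDR correction (q ≈ 0.01). The decoy
chemicals below it drift toward uniform P values.

For real analyses, point `--annotations` at a CTD `chem_gene_ixns.tsv`
download (the parser keeps human and mouse rows by default and accepts
gzip) and `--stats` at one or more FUSION TWAS output files or any
two-column gene/statistic TSV; repeat `--stats` to pool tissue panels
(duplicate genes collapse to the largest-magnitude Z by default).

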