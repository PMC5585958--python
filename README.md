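# mirset

Unbiased miRNA functional enrichment analysis: Monte Carlo empirical
p-values for the biological processes regulated by a group of miRNAs,
computed with fast bitset set algebra.

## The problem

A group of differentially expressed miRNAs regulates a biological process by
targeting the genes involved in it. Given (a) a miRNA-to-gene interaction
table (e.g. DIANA-microT, miRanda or TargetScan predictions), (b) a
gene-to-annotation table (GO/KEGG/PANTHER terms) and (c) a query miRNA
group, the analysis asks which annotation categories are over-represented
among the genes targeted by the group.

The classical answer — Fisher's exact test on the hypergeometric
distribution — treats genes as exchangeable units. But miRNA target sets
are strongly correlated with one another and with the structure of the
annotation (highly targeted genes are also heavily annotated), so the
gene-level test declares significance even for *randomly assembled* miRNA
groups. The unbiased alternative builds the null at the miRNA level:

* the **biological process overlap** of a miRNA group with category *C* is
  the proportion of *C*'s genes also targeted by the group,
  `k / |C|` with `k = |T(G) ∩ C|`, where `T(G)` is the union of the
  group members' target sets;
* sample *N* random miRNA groups of the same size as the query (without
  replacement within a group) from all miRNAs in the interaction table;
* the **empirical p-value** of category *C* is the fraction of random
  groups whose overlap strictly exceeds the query's:
  `p = #{i : k_i > k_query} / N`.

*N* controls the accuracy of the p-value grid; 10 000 is desk-fast,
1 000 000 is the accuracy-grade setting. Benjamini–Hochberg step-up FDR
marking is applied over the tested categories: `*` at level 0.05, `**` at
0.01. Categories sharing no gene with the query's targets are excluded from
testing and reported with `NA`.

Run naively this requires millions of set unions and billions of
intersections (a query of size 10 at *N* = 10⁶ already costs 10⁷ unions).
`mirset` represents target sets as fixed-width bit vectors over a gene
universe: group unions are bitwise-or folds, and each group-vs-category
overlap is counted by **bit-probing** — testing, for each gene of the small
category, the corresponding bit of the large group bitset. A plain hash-set
engine (`engine="naive"`, unions by folding, intersection sizes by
hash-join without materializing the intersection) is kept as a first-class
reference: both engines must produce byte-identical output for the same
seed, which the test suite and the acceptance script verify.

## Worked example

`examples/run_analysis.py` generates a synthetic dataset (120 miRNAs,
1 500 genes, 15 categories) in which the query group's targets were
constructed to cover category `CAT:0007` completely, then runs the analysis
at *N* = 10 000:

```
tested 15 categories (0 excluded for zero overlap); 60006 union ops, 3730373 probe ops

category   size overlap          p sig
CAT:0007     20      20     0.0000 **
CAT:0008     28       9     0.0068 *
CAT:0014     35      14     0.0078 *
CAT:0010     19       7     0.0118 *
CAT:0003     21       7     0.0159 *
```

The planted category leads with overlap 20/20 and empirical p = 0: no
random group of six miRNAs ever covered it better. The union counter is
exactly `N × group size + group size` (10 000 × 6 + 6): one fold step per
member bitset. The other examples demonstrate engine equivalence
(`engine_equivalence.py`), null calibration (`null_calibration.py`: the
fraction of null p-values below 0.05 sits near 0.05) and the Fisher bias
(`fisher_bias.py`: hypergeometric p < 0.05 for ~100% of *random* miRNA
groups on hub-correlated data, versus ~1–5% for the empirical p).

## Command line

```sh
mirset -i interactions.csv -a annotations.csv -m query.txt -o results.csv \
       --iterations 10000 --seed 17 --workers 4
```

Inputs are delimited text: interactions `miRNA,gene[,...]`, annotations
`gene,category[,name]`, query one miRNA per line. The output table has
columns `category_id, category_name, category_size, overlap_count,
overlap_proportion, empirical_p_value, significance`, sorted by ascending
p-value, and a JSON run report (`results.csv.report.json`) records the
seed, engine, operation counters, dropped identifiers and the number of
tested categories. `--engine naive` runs the hash-set reference end to end.
Exit codes: 2 missing input, 3 format error, 4 infeasible configuration.

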