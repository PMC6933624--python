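# mirna-synergy

Inference of **miRNA synergism** — sets of miRNAs that jointly regulate the
same target mRNAs at the *expression* level — from matched miRNA/mRNA
expression profiles, survival annotations, and putative binding interactions.

Most synergy predictors call two miRNAs synergistic whenever they share a
predicted target at the sequence level.  That criterion cannot distinguish
genuine simultaneous co-regulation from two miRNAs that act on the same gene
at different times or in different processes.  The decisive experiment would
be a *multiple* knock-down — silence a whole set of miRNAs at once and watch
the target — but the combinatorics make that infeasible at scale.  This
package simulates those multiple-intervention experiments with causal
inference on observational expression data.

## Method

With expression variables `V = {X_1..X_p (miRNAs), Y_1..Y_q (mRNAs)}` assumed
multivariate Gaussian and faithful to an unknown causal DAG without hidden
variables:

1. **Feature selection.**  Entities are screened by a univariate Cox
   proportional-hazards model on patient survival (Wald p < 0.05), after
   missingness filtering (> 30% missing removed), KNN imputation,
   `log2(x+1)` transform and per-gene z-scoring.
2. **Joint causal effects.**  The Markov equivalence class of causal DAGs is
   estimated as a CPDAG (PC-stable, Fisher-z partial-correlation tests).  For
   each member DAG, the joint total effect matrix `ef ∈ R^{p×q}` is computed:
   `ef_ij = E[Y_j | do(X_1=x_1,…,X_i=x_i+1,…)] − E[Y_j | do(X_1=x_1,…,X_i=x_i,…)]`,
   i.e. the response of `Y_j` to a unit change of `X_i` with every other
   intervened miRNA held fixed (edge coefficients by least squares on DAG
   parents, effects by path-coefficient sums on the graph with edges into the
   intervened set severed).  This yields a *multiset* of effects, one per
   equivalence-class DAG.
3. **Cumulative knock-off effect.**  For a miRNA subset `{X_1..X_m}` and
   target `Y_j`,
   `δ_j = Σ_{i=1..m} (0 − average(X_i)) · ef_ij`
   models knocking all m miRNAs off simultaneously (`average(X_i)` is the
   mean expression before standardisation).  The maximum of δ over the
   multiset is the estimated cumulative joint causal effect.
4. **Synergy network.**  Per significant mRNA, the subset of binding miRNAs
   maximising δ (exhaustive up to a size cap, greedy beyond) is its synergy
   set; all within-set miRNA pairs become network edges.
5. **Synergy modules.**  Maximal bicliques (≥ 2 miRNAs × ≥ 2 mRNAs) of the
   significant binding network are refined to the subset pair `(C*, D*)`
   maximising the summed per-mRNA δ.
6. **Characterisation.**  Power-law degree fit (`y = b·x^a` on log-log least
   squares), average clustering coefficient, characteristic path length with
   degree-preserving rewiring baselines, hub calling (top ~10% by degree),
   hypergeometric disease enrichment of modules
   (`p = 1 − Σ_{i<x} C(M,i)·C(N−M,K−i)/C(N,K)`), and Pearson co-expression
   classification of synergistic pairs (r > 0, p < 0.05).

A fully-featured synthetic-data module generates linear-Gaussian SEM
expression with a known miRNA→mRNA DAG, binding networks with controllable
sequence-level-only contamination, survival with hazard tied to a feature
subset, and the closed-form joint-effect oracle used as ground truth.

## Worked example

```bash
mirna-synergy simulate --p 8 --q 12 --n 400 --seed 7 --out demo/sim
mirna-synergy all --mirna demo/sim/mirna_expression.tsv \
    --mrna demo/sim/mrna_expression.tsv \
    --survival demo/sim/survival.tsv \
    --binding demo/sim/binding.tsv \
    --seed 7 --out demo/results
```

prints the per-stage counts (abridged):

```json
{
 "select":  {"significant_miRNAs": 7, "significant_mRNAs": 12},
 "network": {"candidate_targets": 12, "synergy_sets": 10,
             "nodes": 2, "edges": 1},
 "compare": {"sequence_level_pairs": 21, "n_both": 1,
             "n_sequence_only": 20, "n_expression_only": 0},
 "modules": {"bicliques": 28, "modules": 27},
 "coexpression": {"pairs": 1, "co_expressed": 1, "fraction": 1.0}
}
```

Reading this: 7 of 8 miRNAs and all 12 mRNAs survive the Cox screen; ten
targets have a positive-δ synergy set but only one set contains ≥ 2 miRNAs,
giving a single synergistic pair (`demo/results/synergy_network.tsv`):

```
miRNA_A  miRNA_B  supporting_mRNAs
miR-7    miR-8    gene-2
```

Of the 21 miRNA pairs sharing a binding target at the sequence level, 20 show
no joint expression-level effect — the central point of the method: shared
binding does not imply synergistic activity.  The one synergistic pair is
also co-expressed (r > 0, p < 0.05).  All outputs (GraphML network, module
JSON/TSV, topology JSON, co-expression TSV, `run_report.json` with every
parameter and count) land in `demo/results/`.

The same analysis is available as a library (`mirna_synergy.pipeline.
run_pipeline`) and stage-by-stage (`preprocess`, `select`, `modules`,
`analyze` subcommands).

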