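# Methods

## Model and assumptions

Expression variables (p miRNAs, q mRNAs) are modelled as multivariate
Gaussian and faithful to an acyclic causal structure with no hidden common
causes.  Under these assumptions the distribution identifies the causal DAG
only up to its Markov equivalence class, summarised by a CPDAG; every
quantity downstream is therefore computed per class member and reduced over
the resulting multiset.

Joint intervention effects follow intervention calculus: for an intervened
set X, edges into X are severed (the do-operation), each node's edge
coefficients are fitted by least squares on its DAG parents from the sample
covariance, and `ef_ij` is the sum over directed paths from `X_i` to `Y_j`
of fitted-coefficient products, computed as an entry of `(I − B)⁻¹` on the
surgered weight matrix (B is strictly triangular in a topological order, so
the inverse is exact path summation).  For |X| = 1 this reduces to the
classical single-intervention total effect.

The cumulative knock-off statistic for target j is
`δ_j = Σ_i (0 − average(X_i)) · ef_ij`.  **Averaging convention:** δ needs
the average expression level of each miRNA, but causal estimation runs on
z-scored data whose averages are ~0, which would make δ vanish identically.
The package resolves this by taking `average(X_i)` from the log2(x+1)
transformed values *before* z-scoring (the normalisation step returns these
means), while conditional-independence testing and coefficient fitting use
the standardised data.  ef is therefore on the standardised scale and the
knock-off contrast on the log2 scale; δ is a score used for ranking and
sign, not a quantity in expression units.

The multiset of δ values (one per equivalence-class DAG) is reduced by its
**signed maximum**.  Maximising |δ| instead is available
(`use_abs_delta`), since either reading of "maximum" is defensible; signed
is the default because knocking off genuine repressors should *raise* the
target, and sets whose best δ is ≤ 0 are discarded as non-synergistic.

## Pipeline stages and defaults

| parameter | default | meaning |
|---|---|---|
| `missing_threshold` | 0.30 | entities with a strictly greater missing fraction are removed |
| `knn_k` | 10 | neighbours for imputation (mean of the k nearest entities by Euclidean distance on jointly observed samples) |
| `alpha_cox` | 0.05 | two-sided Wald level of the univariate Cox screen (Efron ties); no multiple-testing correction, recorded in the run report |
| `alpha_pc` | 0.05 | Fisher-z partial-correlation test level in PC-stable |
| `equivalence_cap` | 256 | max DAGs enumerated per class (deterministic truncation, flagged) |
| `subset_cap` | 10 | exhaustive synergy-set search up to this candidate-set size (≤ 1023 subsets); greedy forward selection beyond |
| `module_exhaustive_cap` | 16 | exhaustive (C\*, D\*) search when r + l ≤ cap; alternating greedy otherwise |
| `alpha_corr` / `alpha_enrich` | 0.05 | co-expression and enrichment flag levels |
| `hub_fraction` | 0.10 | top-degree fraction called hubs (ceil, ties by degree then id) |
| `n_random` | 100 | randomised baseline instances |
| `scope` | local | CPDAG per target over {candidates} ∪ {target}; `global` over all selected entities exists but is expensive |

Graph learning defaults to **local scope**: for each target mRNA the CPDAG
is estimated over its binding candidates plus the target only.  Under the
bipartite candidate structure this preserves the effects needed for δ while
keeping the per-target cost independent of q; a global CPDAG over all
selected entities is available but scales poorly.

## Numerical and degenerate-input choices

- PC-stable removes edges level-by-level against an adjacency snapshot, so
  the skeleton is order-independent.  Singular or undefined partial
  correlations are treated as independence with a warning.  Conflicting
  v-structure orientations fall back to undirected; if orientation ever
  produces a directed cycle the graph reverts to its skeleton.
- A finite-sample PC output need not be a valid CPDAG.  The strict
  enumeration contract raises in that case; the pipeline's scorer instead
  enumerates all acyclic completions (warning logged) so that a target is
  never silently dropped.
- Tie-breaking everywhere is: larger objective, then smaller set, then
  lexicographic — outputs are byte-identical across runs for a fixed seed.
- Zero-variance entities are excluded at normalisation (z-score undefined);
  constant covariates are dropped by the Cox screen; zero-variance pair
  members yield an undefined co-expression call flagged false.
- The hypergeometric tail uses `scipy.stats.hypergeom.sf` (log-space
  stable); the test suite checks it against exact rational arithmetic for
  all backgrounds up to N = 15.
- Maximal bicliques are enumerated by completing each side of the bipartite
  graph internally and running maximal-clique enumeration; the brute-force
  subset-pair oracle in the tests is the correctness contract.

## Synthetic data: what it emulates, what it does not

`synthetic.make_bundle` draws a random DAG with miRNAs topologically before
mRNAs, linear-Gaussian structural equations (configurable weights, noise,
intercepts), and produces: raw SEM-scale expression; a non-negative
transform `2^(x+shift) − 1` so that `log2(v+1)` exactly recovers `x+shift`
(making the preprocessing path invertible and the pre-z-score averages
nontrivial); survival times exponential with hazard `∝ exp(βᵀz)` over a
random feature subset plus uniform censoring (~50%); and a binding network
equal to the true miRNA→mRNA edges plus a configurable fraction of
*sequence-level-only* pairs absent from the causal model — emulating shared
binding without expression-level co-regulation.  Ground-truth joint effects
come from the closed-form path-sum oracle.

Real tumour expression data violate this generator in known ways: counts
are not Gaussian on any scale, regulation is nonlinear and context
dependent, hidden confounders (copy number, purity, subtype) abound, and
binding databases are biased and incomplete.  Passing tests therefore
establish correctness of the *algorithms* under the stated assumptions, not
biological validity of any particular network.

Test and calibration problem sizes (5–8 miRNAs, 3–15 mRNAs, 400–5000
samples, 10–20 seeds) were chosen as the smallest configurations at which
the estimators are in their asymptotic regime; the acceptance script uses
the same scales.

## Known limitations

- No hidden-variable methods (FCI) and no fast Joint-IDA variants; class
  enumeration is exact but capped, so very large equivalence classes are
  truncated (flagged in the report).
- The duplication-model random baseline is an approximate growth process
  (duplicate a template node, keep each of its edges with a probability
  tuned to the target edge count); the degree-preserving rewire model is
  the default and the better-defined null.
- The power-law fit is ordinary least squares on log10 histogram counts;
  R² from alternative binnings or frequency normalisations will differ.
- Cox selection uses raw p-values by design; with thousands of entities the
  selected set contains the expected false-positive fraction.
- Module refinement beyond the exhaustive cap is a local search (one-step
  add/drop/swap, alternating sides) and may return a local optimum; the
  exhaustive-vs-greedy bound is asserted in tests on small instances.
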