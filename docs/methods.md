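# Methods

`celltreeage` implements a "cell tree age" clock: it treats the somatic
single-nucleotide variants accumulated by blood cells as natural lineage
barcodes, reconstructs per-sample cell phylogenies from single-cell SNV
call matrices, summarises each tree with 31 shape metrics, and regresses
chronological age on those metrics with a penalized linear model validated
by nested leave-one-sample-out cross-validation. This note documents the
model assumptions, parameter choices, numerical conventions and known
limitations.

## Pipeline model

**Variant filtering.** The input is a pair of sparse cells × sites UMI
count matrices (alternative/reference allele). Likely germline variants —
population minor allele frequency above 1%, with MAF folded as
`min(AF, 1 − AF)` — are removed first. Two consecutive detection filters
then suppress false-positive somatic calls: a site counts as *detected* in
a cell only when at least `min_umis = 8` alternative-allele UMIs support it
there (sub-threshold alt counts are zeroed, so downstream encoding sees a
clean presence/absence signal), and a site is retained only when detected
in at least `min_barcodes = 4` cells. Both filters are idempotent and
monotone in their thresholds. Whether the 8-UMI rule should count
alternative-supporting UMIs only or total site coverage is ambiguous in
the field's tooling; we count alternative-supporting UMIs (configurable).

**Pseudo-alignments.** Filtered matrices are encoded over a three-letter
alphabet: `A` (alternative detected), `R` (below threshold but reference
coverage present), `?` (no usable coverage). Five pseudo-replicates per
sample are drawn as independent uniform 700-of-~1400-cell subsets
(replicates overlap by design); columns that lose every `A` in a replicate
are uninformative there and are pruned from that replicate.

**Tree inference.** Pairwise distances are p-distances — the fraction of
jointly observed sites at which two cells differ — with pairwise deletion
of `?` (complete deletion is available behind a flag). Cell pairs with no
comparable site receive distance 0 with a logged count rather than an
error, because sparse subsamples can legitimately produce them. Trees are
built with UPGMA: size-weighted average-linkage agglomeration, new nodes
placed at half the merge distance, ties broken deterministically by the
first minimal pair in the current cluster order (input order, then merge
creation order). The output is rooted, binary and ultrametric by
construction (equal root-to-tip paths to 1e-9 relative tolerance). The
implementation is a simple O(n³) scan — n = 700 makes clarity worth more
than an optimal algorithm. Externally inferred rooted Newick trees (e.g.
maximum-likelihood) can be substituted at the feature layer.

## The 31 tree-shape metrics

Five groups; all metrics are invariant to tip relabelling and child-order
rotation, use natural logarithms and population variances, and return
defined sentinel values (never NaN) for degenerate trees.

* **Group I — spectral (8).** Let P be the patristic distance matrix over
  *all* vertices and MGL = diag(rowsums(P)) − P the distance ("modified
  graph") Laplacian. Metrics: `mMaxEigen` (largest MGL eigenvalue),
  `mMax_eigengap` (largest gap between consecutive descending
  eigenvalues), `eigengap_pos` (1-based position of that gap, a modality
  heuristic), `spec_skewness` / `spec_kurtosis` (excess) of the spectrum,
  `spec_entropy` (Shannon entropy of the spectrum normalized to sum 1,
  with 0·log 0 ≡ 0), `AC_2` (algebraic connectivity — second-smallest
  eigenvalue of the *unweighted* tree-graph Laplacian) and `lmax_graph`
  (largest eigenvalue of the branch-length-weighted Laplacian, edge weight
  = branch length). Scaling branch lengths by c scales `mMaxEigen`,
  `mMax_eigengap` and `lmax_graph` by c and leaves `AC_2` unchanged.
* **Group II — branch lengths (7).** Total, mean, median, population
  variance, maximum, entropy of the normalized branch-length distribution,
  and the internal/terminal length ratio (0 with a log message when the
  terminal sum is 0).
* **Group III — classical statistics (8).** Normalized Colless
  (Σ|L−R| / ((n−1)(n−2)/2)), mean topological tip depth (Sackin / n),
  cherries / ⌊n/2⌋, the Pybus–Harvey gamma statistic, treeness (internal
  over total branch length), B1, B2 and the maximal topological depth.
  Gamma on non-ultrametric input uses internal node depths as event times
  with the mean tip depth as the present — a convention, flagged here.
  Polytomies are resolved with zero-length edges; unary chains are
  collapsed.
* **Group IV — tip distances (6).** Mean/population variance/maximum of
  tip–tip patristic distances, `tipDistNorm` = mean tip distance / total
  branch length, and mean (`tipRootPatr`) and variance of root-to-tip
  distances.
* **Group V — powergraph (2).** Largest and second-smallest Laplacian
  eigenvalues of the square of the unweighted tree graph (vertices joined
  when at most two edges apart).

The metric set is registered by name, so alternates can be swapped without
touching the model layer. Patristic matrices are computed from LCA depths
with one vectorized block assignment per internal node (O(V²) total),
which keeps 1400-cell trees under a second.

## The age model

Each pseudo-replicate contributes one row: the 31 metrics, sex (F = 0,
M = 1) and 31 sex × metric interactions — 63 predictors; all replicates of
a sample carry the sample's age. The fit minimizes

    (1 / 2N_tot) Σ_ij (y_ij − μ − x_ijᵀβ)²
      + λ [ (1 − α)‖β‖₂²/2 + α‖β‖₁ ]

solved by scikit-learn's coordinate descent (whose objective is exactly
this with `alpha = λ`, `l1_ratio = α`); λ = 0 falls back to OLS. Because
penalized regression is scale-sensitive and the metrics have wildly
different units, the 31 metric columns are z-scored on each training
partition by default (test rows reuse the training transform), and
interactions are formed as sex × standardized metric; coefficients are
reported on that scale. Standardization can be switched off.

Accuracy is estimated by nested leave-one-sample-out cross-validation: the
outer loop holds out all replicates of one sample; the inner loop (LOO
over the remaining samples) scores every (λ, α) on the grid λ ∈ {0.1, 0.3,
1, 3, 10} × α ∈ {0.6, 0.7, 0.8, 0.9, 1} by held-out MAE, averaged equally
per replicate, ties resolved in grid order. Replicates are never split
across train and test. This yields exactly one prediction per
pseudo-replicate and one coefficient vector per outer fold. Performance is
MAE, median AE, RMSE and Pearson r (r² as explained variance) over all
(ŷ_ij, y_ij); the *age difference* is ŷ − y and the *age acceleration* the
residual of ŷ from the OLS line of ŷ on y (zero-mean by construction).

A dummy baseline predicts the training-mean age in each outer fold — it is
exactly the λ → ∞ limit of the elastic net, and the suite asserts that
equivalence. External-cohort testing is one step of the outer loop: inner
CV on the whole training cohort picks (λ, α), the model is refit on all
training rows and applied to every test replicate. Feature pre-selection
ranks the 63 predictors by mean |standardized coefficient| across the
outer-fold estimates (ties by fixed column order) and reruns the nested CV
on the top k for each requested k; k is chosen by MAE and deliberately not
tuned inside the inner loop — a pragmatic shortcut, so the per-k errors are
mildly optimistic. Clinical-marker associations are Pearson correlations
(two-sided t-distribution p-values, significance at p < 0.05, no
multiple-testing correction) of per-sample mean cell tree age and of
chronological age against numeric markers, overall and within sex strata.

## The cohort simulator

No public desk-scale dataset exercises this pipeline end to end, so the
package ships a generator that emulates the statistical structure the
method assumes: age-scaled somatic mutation accumulation on a cell
genealogy, age-increasing clonal imbalance, and sparse UMI observation.

A sample of age *a* grows from one founder by a discrete-generation birth
process: each lineage divides with probability 0.5 per generation, and the
number of generations is set so the expected divisions per surviving
lineage equal `divisions_base + divisions_per_year × a` (defaults 30 and
1.0/year — roughly the homeostatic division tempo of blood stem cells).
Each division deposits Poisson(`mu_div` = 0.3) new variants into one
uniformly chosen daughter; the infinite-sites assumption (no recurrence,
no loss) makes every variant's carrier set exactly one clade, an invariant
the suite checks exhaustively. With probability `clone_rate_per_year × a`
(capped at 1) a driver clone arises in one uniformly chosen lineage at a
uniformly chosen generation and divides at `clone_advantage` (= 2.0) times
the base probability thereafter, raising tree imbalance with age. The
population is capped at `pop_cap_factor × cells_per_sample` lineages by
uniform subsampling, and `cells_per_sample` (default 1400) tips are
sampled uniformly at the end. The cap models the stem-cell pool, which in
reality vastly exceeds the sampled cell count; because genealogy sampling
noise scales inversely with the pool size, the default factor of 16 is
the largest pool that stays comfortably desk-scale. Mutations are
materialized only on the sampled genealogy (a division bundle whose chosen
daughter leaves no sampled descendant is unobservable, and divisions with
one retained daughter carry their bundle with probability ½), which the
simulator's bookkeeping records so tests can verify the expected counts.

Observation: per cell and site, total UMI depth is Poisson(`depth_mean` =
12), zeroed with probability `dropout` = 0.6; carrier cells yield
alternative-allele UMIs, non-carriers reference UMIs. Under these defaults
a carrier passes the 8-UMI detection threshold with probability ≈ 0.36,
so the ≥4-barcode filter keeps roughly the variants carried by a dozen or
more cells — a realistic sparsity regime for UMI-based somatic calling.

What the simulator does *not* model: transcript expression and coverage
bias along genes, doublets, ambient contamination, recurrent artifacts
(e.g. RNA editing), chemistry differences between 3' and 5' libraries, and
any non-blood tissue composition. Passing tests therefore demonstrate the
pipeline's internal correctness and its ability to recover an age signal
of the assumed form — not calling accuracy on real sequencing data.

All randomness flows from a single integer seed through independent
per-sample `SeedSequence` streams (sample k's output is unchanged by the
presence of other samples), and identical configurations reproduce
byte-identical outputs.

## Problem sizes used by the test suite

The suite validates the numerical cores against independent oracles at
small sizes (brute-force p-distance ≤ 10 cells, naive UPGMA ≤ 32 tips,
dense eigendecompositions ≤ 32 tips, convex-solver elastic-net checks at
8 × 3) and runs the full pipeline at reduced scale: the parameter-recovery
check uses 30 samples of 300 cells with two 150-cell pseudo-replicates
each — the same age range and noise regime as the default configuration,
scaled down so a full nested cross-validation remains a couple of minutes
of compute. At that scale the cross-validated Pearson r between predicted
and true age is typically 0.5–0.8 with MAE clearly below the dummy
baseline; the fitted slope of predicted on true age stays below 1, the
familiar regression-to-the-mean shrinkage of penalized clocks (young
samples overestimated, old underestimated).

## Known limitations

* The 31-metric catalog fixes one concrete, group-faithful set; other
  definitions of the same families exist (e.g. eigengap as a modality
  count — exposed here as `eigengap_pos` alongside the gap magnitude, and
  `AC_2` on the unweighted Laplacian with the weighted variant available).
* UPGMA tie-breaking is implementation-defined across packages; topologies
  on data with many tied distances are reproducible within this package
  but not guaranteed to match other software tie for tie.
* The desk-scale genealogy has far fewer lineages than a real stem-cell
  pool, so per-sample tree-shape variance is larger than in real cohorts;
  cohort-level statistics (correlations, MAE) at 30 samples carry
  correspondingly wide seed-to-seed variability.
* Maximum-likelihood tree inference is intentionally out of scope; the
  feature and model layers accept external Newick trees instead.
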