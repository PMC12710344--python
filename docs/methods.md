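# Methods

This note documents the models, conventions and numerical choices behind
`mnetclass`, and what the synthetic benchmark does and does not show.

## Preprocessing

Counts are made comparable by total sum scaling; a sample column that sums
to zero is an error, not silently dropped. The rare-taxon filter retains a
taxon when its **mean** relative abundance across the niche's samples is
≥ `abundance_min` (default 2·10⁻⁴) **and** its prevalence (fraction of
samples with a strictly positive value) is ≥ `prevalence_min` (default
0.30). Boundary values survive. Whether the abundance cutoff should apply to
the per-sample maximum instead of the mean is genuinely ambiguous for this
kind of filter; both are supported (`abundance_mode='mean'|'max'`), mean is
the default. Columns are *not* re-normalized after filtering: every
downstream quantity is built from within-sample ranks, which a per-sample
monotone rescale cannot change.

## Correlation network

Spearman's ρ is computed as Pearson correlation of the within-taxon rank
transforms (average ranks on ties); significance uses the standard
t-approximation with k−2 degrees of freedom, which matches
`scipy.stats.spearmanr` to numerical precision while degrading gracefully
when a taxon is constant (such taxa get ρ = 0, p = 1 and a warning).
The p(p−1)/2 distinct tests are multiplicity-adjusted
(Benjamini–Hochberg by default; `none` and `bonferroni` available). An edge
is kept when |ρ| strictly exceeds the threshold and the adjusted p is below
α = 0.05; the stored weight keeps the sign of ρ.

**Threshold selection.** For each τ in {0, 0.1, …, 1} the degree–frequency
table (degree d ≥ 1 vs. number of nodes with that degree) of the sparsified
graph is fitted to f(d) = c·d^(−γ) by Levenberg–Marquardt least squares on
the raw (not log-log) pairs, with starting values from a log-log OLS line;
if the iteration fails to converge (common on permuted tables) R² is
evaluated at the starting values, keeping the procedure total and
deterministic. R² = 1 − SS_res/SS_tot; fewer than three distinct degrees
make the fit degenerate (R² = NA), since a two-parameter curve through ≤ 2
points is vacuous. Significance is a permutation test: frequencies are
shuffled across the observed degrees, the fit repeated (1000 permutations by
default, seeded), and p = (b+1)/(n+1) where b counts permuted R² ≥ observed.
The selected τ is the R² argmax among fits with p ≤ 0.05; ties prefer the
smaller τ. When no grid point reaches significance the caller may set a
manual threshold, or opt into a fallback that takes the R² argmax regardless
of significance (`fallback_best_r2=True`) — small sparse networks with few
distinct degrees often cannot reach p ≤ 0.05 at all, because almost any
arrangement of 3–5 frequency values is fitted well by a two-parameter curve.

## Random-walk partitioning

Negative correlations are folded to absolute values before the walk: the
transition matrix needs non-negative weights, and a strong negative
co-occurrence is still a strong association. With A = |W|,
D_ii = d(i) = Σ_j |a_ij| and P = D⁻¹A, nodes are compared through the
degree-weighted Euclidean distance between their t-step profiles
(t = 4 by default):

    r_ij² = Σ_k (Pᵗ_ik − Pᵗ_jk)² / d(k)

and communities through the same distance between their averaged profiles.
Starting from singletons, only **adjacent** (edge-connected) community pairs
may merge; at each step the pair minimizing the Ward-like cost
Δσ = |C₁||C₂|/(|C₁|+|C₂|) · r²_{C₁C₂} / n is fused (ties broken by the
smallest community-id pair, making the procedure deterministic). The flat
partition is the dendrogram level with maximum weighted Newman modularity
(computed on |ρ|); among tied levels the more merged one is kept, which
matches the behavior of the reference igraph implementation on cliques
(a clique collapses to a single community at modularity 0). Disconnected
components never merge — they are handled by the adjacency constraint
without special-casing. Degree-zero nodes bypass the walk and become
singleton communities at the API level; the *pipeline*, however, partitions
only the subgraph of taxa that appear in at least one retained correlated
pair, since the association network of a niche is defined by those pairs
and isolated taxa would otherwise flood the community list with singletons.

Scaling all edge weights by a positive constant leaves P and the partition
unchanged (the r distances scale by a common factor, which cannot reorder
merges).

## Topological indicators

Ten subnetwork indicators: node count, edge count, graph diameter, density
2m/(n(n−1)), average degree 2m/n, edge connectivity, node connectivity,
average (unweighted) clustering coefficient, internal modularity, average
path length. Path-based quantities (diameter, path length, and the
closeness/betweenness centralities) use the absolute correlation of an edge
**directly as its length** — the shortest path minimizes the summed |ρ| —
which is why a 5-clique with |ρ| ≈ 0.97 edges has a diameter below one.
An unweighted-path variant is available (`unweighted_paths=True`).
"Internal modularity" of a single subgraph is the weighted modularity of a
fresh random-walk partition of that subgraph: a cohesive clique that refuses
to split scores ≈ 0, a subnetwork with real substructure scores higher.
Single-node graphs get NaN for path metrics (ranked worst downstream).

Five node centralities: degree (edge count), weighted degree (summed
incident |ρ|), betweenness (number of weighted shortest paths through the
node, **unnormalized**), closeness (reciprocal of the summed weighted
distances to all reachable nodes, not scaled by n−1), and eigenvector
centrality (power iteration on |A|, tolerance 1e-10, ≤ 1000 iterations,
scaled so the maximum entry is 1).

## RSR-EWM composite scoring

For m objects × n indicators: min-max standardization maps each indicator to
[0, 1] (reversed for "smaller is better" columns; constant columns become
all-zero with a warning); within-indicator average ranks give the rank
matrix R (the best value receives rank m); entropy weights are
W_j = (1 − e_j)/Σ(1 − e_j) with e_j the normalized Shannon entropy of the
column proportions (0·ln 0 = 0); WRSR_i = (1/mn) Σ_j W_j R_ij. The
cumulative frequency of the ascending-sorted WRSR (average ranks over ties,
top item corrected to 1 − 1/(4m) to keep the quantile finite) is converted
to a probit unit Φ⁻¹(cum freq) + 5 via the inverse normal CDF, the line
WRSR = a + b·probit is fitted by OLS (slope expected positive; a warning
otherwise), and objects are binned into three reporting-only grades at
probit 4.5/5.5 and ranked by WRSR descending (ties broken by the larger raw
weighted rank sum, then object id).

Two deliberate conventions:

* **Weight basis.** The entropy weights default to proportions of the
  *rank matrix* (`weight_basis='ranks'`), not of the standardized values.
  With standardized proportions, any indicator on which a single object is
  an extreme outlier collapses to near-zero entropy and absorbs most of the
  weight — in practice a tiny clique (density = clustering = 1, maximal
  connectivity) would outrank every larger subnetwork. Scoring published
  indicator tables of this method shows the rank basis is what reproduces
  the known selections; the literal standardized-proportion formulation
  remains available (`weight_basis='standardized'`, and as the exported
  `entropy_weights` function). Under either basis a constant indicator
  carries zero weight, as it should.
* **Directions.** All ten subnetwork indicators default to "larger is
  better", *including* diameter and average path length: the model favors
  extensive, well-spread subcommunities over minimal cliques, and this is
  again the convention that reproduces published selections. Every flag is
  overridable per call.

Both the Eq.-(8)-scaled WRSR and the unscaled weighted rank sum are
reported; they order objects identically.

## Synthetic benchmark

`make_planted_abundance` emulates a bicluster benchmark: a 100 × 50 matrix
of N(0, 1) background noise plus, for each of 5 planted clusters (sizes
spread evenly over 10–15 taxa, consecutive disjoint rows), a rank-one signal
— the outer product of taxon loadings ~ N(0, 3) and sample factors ~ N(0, 1)
— over a block of 25 sample columns staggered evenly across the matrix. The
matrix is min-shifted to non-negativity and TSS-normalized. Block positions
and sizes are deterministic functions of the parameters; only loadings,
factors and noise depend on the seed, so datasets are bit-for-bit
reproducible. The defaults put the planted co-variation roughly three times
above the noise floor ("high signal") while leaving half of each taxon's
profile pure noise, so recovered correlations are strong but imperfect —
cluster members with small |loading| are genuinely hard to detect.

What the generator does *not* emulate: compositional count noise
(multinomial/Dirichlet sampling), zero inflation, taxon-taxon interactions
beyond rank-one blocks, or phylogenetic correlation among taxa. Passing
benchmarks therefore demonstrates correct recovery of block-correlated
structure, not performance on real sequencing data.

`run_benchmark` evaluates, per dataset, three predictions against the
planted labels via best-overlap matching (Sn = TP/|cluster|,
PPV = TP/|prediction|, Acc = √(Sn·PPV)): the composite-score selection, the
largest community (single-indicator baseline), and a size-matched random
taxon set. The two selectors agree on roughly 80% of datasets, so medians
over short runs are dominated by a handful of split decisions; the
acceptance suite therefore uses 100 repetitions (seeds 100–199), where the
composite selector's median Acc (~0.80) equals or exceeds the
largest-community baseline and is far above the ~0.23 random baseline. The
threshold scan inside the benchmark uses 99 permutations per grid point and
falls back to the R² argmax when no fit reaches permutation significance,
which on 100-taxa planted networks is common (see above).

## Determinism

Every stochastic step (permutation tests, benchmark data, random baselines)
is driven by an explicit integer seed through `numpy.random.default_rng`;
merge ties, ranking ties and community ordering are resolved by fixed
deterministic rules; writers emit sorted rows with fixed float formats.
Identical seeds and configurations therefore produce byte-identical
artifacts.

## Known limitations

* Correlation-based inference: compositionality-aware estimators (SparCC,
  CCLasso, SPIEC-EASI) are out of scope; Spearman on TSS data is the
  supported estimator.
* Negative edges participate only through their absolute values; genuinely
  antagonistic structure is not modeled.
* The permutation test for the scale-free fit shuffles frequencies across
  observed degrees; other schemes (bootstrap over nodes) would give
  different p-values and are not implemented.
* Hard communities only — no overlapping or fuzzy membership.
* The scale of the printed composite score in published node tables could
  not be reconciled with the 1/(mn) normalization; since the ordering is
  unaffected, both scaled and raw scores are emitted.
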