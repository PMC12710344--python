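# mnetclass

Control-free microbial co-occurrence network clustering: find the central
subcommunity of an ecological niche — and the hub taxa inside it — from a
single taxon abundance table, with no case/control design.

Most differential-network methods need matched case and control groups.
`mnetclass` instead characterizes one niche at a time: it builds a Spearman
co-occurrence network over the taxa of that niche, partitions it into
subcommunities with a random-walk algorithm, and ranks both the
subcommunities and their member taxa with an objective multi-criteria score.
It is aimed at microbiome researchers working with 16S/metagenomic genus- or
species-level tables (oral sites, gut cohorts, soil, ...) who want the
dominant interacting subcommunity of a niche rather than per-taxon
differential abundance.

## Method

Given a non-negative taxa × samples table:

1. **Preprocess** — total sum scaling (each sample column divided by its
   sum), then removal of taxa with mean relative abundance < 2·10⁻⁴ or
   prevalence < 30%.
2. **Network** — all-pairs Spearman ρ between taxa; keep edges with
   |ρ| > τ and Benjamini–Hochberg-adjusted p < 0.05. The threshold τ is
   chosen by scanning τ ∈ {0, 0.1, …, 1}: for each candidate the node degree
   distribution is fitted to a power law *f(d) = c·d<sup>−γ</sup>* by
   nonlinear least squares, and the τ with the highest R² among
   permutation-significant fits wins (scale-free criterion, as in
   co-expression network analysis).
3. **Partition** — Walktrap-style agglomeration on |ρ| weights. With
   transition matrix P = D⁻¹A and walk length t = 4, nodes/communities are
   compared through

   r<sub>ij</sub> = ‖D<sup>−1/2</sup>P<sup>t</sup><sub>i·</sub> −
   D<sup>−1/2</sup>P<sup>t</sup><sub>j·</sub>‖,

   adjacent communities are merged by the Ward-like minimum-Δσ rule, and the
   dendrogram is cut at maximum weighted modularity.
4. **Score** — the top-20% largest subcommunities are profiled on ten
   topological indicators (node/edge counts, diameter, density, average
   degree, edge/node connectivity, clustering coefficient, internal
   modularity, average path length) and ranked with the integrated rank-sum
   ratio / entropy-weight model (RSR-EWM): min-max standardization,
   within-indicator average ranks, entropy weights
   W<sub>j</sub> ∝ 1 − e<sub>j</sub>, weighted rank-sum ratio
   WRSR<sub>i</sub> = (1/mn) Σ<sub>j</sub> W<sub>j</sub>R<sub>ij</sub>,
   probit conversion of the cumulative WRSR frequencies
   (Φ⁻¹(cum freq) + 5), a WRSR ~ probit regression for grade binning, and a
   final ranking (rank 1 = central subcommunity). The same model applied to
   five node centralities (degree, weighted degree, betweenness, closeness,
   eigenvector) ranks the hub taxa of the winning subnetwork.

A planted-bicluster generator (`mnetclass.synthdata`) and Sn/PPV/Acc cluster
evaluation metrics (`mnetclass.evalmetrics`) provide a fully synthetic,
label-aware benchmark for the whole pipeline.

## Worked example

```python
import warnings
from mnetclass import (make_planted_abundance, run_comm, run_netscore,
                       run_nodescore, best_subnetwork_nodes, select_best)
from mnetclass.errors import MNetClassWarning
warnings.simplefilter("ignore", MNetClassWarning)

ds = make_planted_abundance(seed=3)          # 100 taxa x 50 samples, 5 planted blocks
comm = run_comm(ds.table(), threshold="auto", n_perm=99, seed=3,
                fallback_best_r2=True)
print(comm.config["threshold"], comm.network.n_edges,
      comm.partition.n_communities)
# 0.7 33 6
report = run_netscore(comm)
print(report.table()[["WRSR", "probit", "rank"]].round(4))
#                 WRSR  probit  rank
# subnetwork_1  0.0900  6.1503     1
# subnetwork_2  0.0600  5.0000     2
nodes = run_nodescore(comm, report)
print(select_best(nodes))
# taxon_025
```

The scale-free scan picks threshold 0.7 (R² = 0.918, permutation p = 0.04),
leaving 33 significant edges; the walk-based partition yields 6
subcommunities, the composite score selects the 9-taxon `subnetwork_1`
(WRSR 0.09, probit 6.15) as the central subcommunity, and `taxon_025` is its
top hub by composite centrality. On this planted dataset the selected taxa
lie inside one ground-truth cluster (Sn 0.75, PPV 1.0, Acc 0.87).

The same steps are available from the shell:

```bash
mnetclass comm      --input abundance.tsv --outdir out/   # network + partition
mnetclass netscore  --input abundance.tsv --outdir out/   # subnetwork ranking
mnetclass nodescore --input abundance.tsv --outdir out/   # hub-taxon ranking
mnetclass synth     --outdir data/ --n-datasets 50        # planted benchmark data
mnetclass eval      --outdir out/ --n-datasets 50         # Sn/PPV/Acc table
```

The `examples/` directory holds one short narrative script per capability.

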