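"""Build a thresholded Spearman co-occurrence network from an abundance table.

Generates a planted-cluster abundance matrix, TSS-normalizes and filters it,
scans correlation thresholds 0..1 for the best scale-free fit, and sparsifies
the correlation matrix at the selected threshold.
"""

import warnings

from mnetclass import (
    filter_taxa,
    make_planted_abundance,
    select_threshold,
    sparsify,
    spearman_matrix,
)
from mnetclass.errors import MNetClassWarning

warnings.simplefilter("ignore", MNetClassWarning)

ds = make_planted_abundance(seed=3)  # 100 taxa x 50 samples, 5 planted blocks
table, removed = filter_taxa(ds.table())
print(f"{table.n_taxa} taxa retained after the abundance/prevalence filter "
      f"({len(removed)} removed)")

threshold, fits = select_threshold(table, n_perm=99, seed=3)
print("\nthreshold   R^2      perm-p   edges")
for f in fits:
    r2 = "   --" if f.r2 != f.r2 else f"{f.r2:.3f}"
    pv = "   --" if f.pvalue != f.pvalue else f"{f.pvalue:.3f}"
    print(f"   {f.threshold:.1f}     {r2}    {pv}   {f.n_edges:5d}")
print(f"\nselected threshold: {threshold} "
      "(highest R^2 among permutation-significant power-law fits)")

rho, pvals = spearman_matrix(table)
net = sparsify(rho, pvals, threshold)
n_neg = sum(1 for _, _, d in net.graph.edges(data=True) if d["rho"] < 0)
print(f"network: {net.n_edges} edges ({n_neg} negative correlations), "
      f"{sum(1 for _, d in net.graph.degree() if d > 0)} connected taxa")
# Each edge is a taxon pair whose abundances co-vary strongly (|rho| above
# the threshold) and significantly (BH-adjusted p < 0.05) across samples.
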