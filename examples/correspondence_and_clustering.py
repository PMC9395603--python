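"""Correspondence analysis and codon clustering on a cohort RSCU matrix.

The genes x 59-codon RSCU matrix is decomposed with the chi-square metric;
the leading axes' inertia fractions say how concentrated codon-usage
variation is.  Codon columns are then clustered on correlation distance.
"""

import pandas as pd
from scipy.cluster import hierarchy

from cubkit import (
    SyntheticCohortSpec,
    codon_clustering,
    correspondence_analysis,
    count_codons,
    generate_cohort,
    linkage_to_newick,
    rscu,
)

genes = generate_cohort(SyntheticCohortSpec(n_genes=47, seed=3))
matrix = pd.DataFrame([rscu(count_codons(g)) for g in genes],
                      index=[g.id for g in genes])

ca = correspondence_analysis(matrix)
frac = ca.inertia_fraction
print(f"CA axes retained : {len(frac)}")
print(f"axis 1 inertia   : {100 * frac[0]:.2f}% of codon-usage variation")
print(f"axis 2 inertia   : {100 * frac[1]:.2f}%")
print("top codons on axis 1:",
      ", ".join(ca.col_coords["axis1"].abs().nlargest(4).index))

link, labels = codon_clustering(matrix)
two = hierarchy.fcluster(link, 2, criterion="maxclust")
sizes = pd.Series(two).value_counts().to_dict()
print(f"codon dendrogram : {len(labels)} codons, 2-cluster cut sizes {sizes}")
print("newick head      :", linkage_to_newick(link, labels)[:60], "...")
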