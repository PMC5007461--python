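"""Pairwise comparison of the two applied clusters.

Permutation-FDR volcano (s0=2, FDR 5%) on the imputed log2 matrix, Fisher
enrichment of the high-variability subset, and 1D annotation enrichment of
the cluster fold change. Writes results/volcano.csv, enrichment_fisher.csv
and enrichment_1d.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from protstrat import io
from protstrat.stats import (EnrichmentParams, ModeratedTestParams,
                             enrichment_1d, fisher_enrichment,
                             permutation_fdr)

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    matrix = io.read_protein_groups(ROOT / "matrix_imputed.tsv")
    applied = pd.read_csv(ROOT / "applied_clusters.csv",
                          index_col=0).iloc[:, 0]
    annotations = io.read_gmt(ROOT / "panel" / "annotations.gmt")

    volcano = permutation_fdr(matrix.values, applied,
                              ModeratedTestParams(s0=2.0, n_permutations=250,
                                                  fdr_threshold=0.05,
                                                  seed=SEED))
    volcano = volcano.assign(neg_log10_p=-np.log10(volcano["p"]))
    volcano.to_csv(ROOT / "volcano.csv", float_format="%.10g")
    n_sig = int(volcano["significant"].sum())
    print(f"volcano (s0=2, permutation FDR 5%): {n_sig} of {len(volcano)} "
          f"proteins differ between the two clusters")

    variability = pd.read_csv(ROOT / "variability.csv", index_col=0)
    high = set(variability.index[variability["high_variability"]])
    high &= set(matrix.proteins)
    fisher = fisher_enrichment(high, set(matrix.proteins), annotations,
                               EnrichmentParams(min_category_size=4,
                                                fdr_threshold=0.02))
    fisher.to_csv(ROOT / "enrichment_fisher.csv", index=False)
    n_fisher = int(fisher["significant"].sum()) if len(fisher) else 0
    print(f"Fisher enrichment of the high-variability subset: {n_fisher} "
          f"categories at BH FDR 0.02")

    one_d = enrichment_1d(volcano["difference"].dropna(), annotations,
                          EnrichmentParams(min_category_size=4,
                                           fdr_threshold=0.02))
    one_d.to_csv(ROOT / "enrichment_1d.csv", index=False)
    top = one_d.iloc[0]
    print(f"1D enrichment of the cluster fold change: top category "
          f"{top['category']} with position score {top['score']:+.2f} "
          f"(q = {top['q']:.2e})")


if __name__ == "__main__":
    main()
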