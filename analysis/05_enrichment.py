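#!/usr/bin/env python
"""GO overrepresentation of literature vs microarray up-sets.

Fisher's exact test with Bonferroni correction on each source's
overexpressed gene set, then the overlap between the two term lists
(both the Bonferroni-significant and the top-20 reading).
"""

import pandas as pd
from common import DATA, RESULTS, STUDY

from degbias import filter_degs, fisher_overrep, top_k_overlap
from degbias import io as dio
from degbias.comparison import direction_sets


def main() -> None:
    statements = dio.read_statements(RESULTS / "statements.tsv")
    annotations = dio.read_gene_terms(DATA / "annotations.tsv")
    diseases = [f"DIS{i:02d}" for i in range(1, STUDY.n_diseases + 1)]
    for d in diseases:
        de = pd.read_csv(RESULTS / f"de_{d}.tsv", sep="\t")
        universe = {str(g) for g in de["feature_id"]}
        lit, _ = direction_sets(statements, d)
        lit &= universe
        micro, _ = filter_degs(de, 0.0, 0.05)
        if not lit or not micro:
            print(f"{d}: empty study set, skipped")
            continue
        rows_l = fisher_overrep(lit, universe, annotations)
        rows_m = fisher_overrep(micro, universe, annotations)
        rows_l.to_csv(RESULTS / f"enrichment_{d}_literature.tsv", sep="\t",
                      index=False, float_format="%.6g")
        rows_m.to_csv(RESULTS / f"enrichment_{d}_microarray.tsv", sep="\t",
                      index=False, float_format="%.6g")
        ov = top_k_overlap(rows_l, rows_m, k=20, alpha=0.05)
        print(f"{d}: {ov['n_significant_a']} literature / "
              f"{ov['n_significant_b']} microarray Bonferroni-significant "
              f"terms, {ov['n_shared_significant']} shared; "
              f"{ov['n_shared_top_k']} of the top-20 shared")


if __name__ == "__main__":
    main()
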