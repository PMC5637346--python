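#!/usr/bin/env python
"""Generate the synthetic study world: corpus, matrices, popularity, GO.

Writes the annotated abstract corpus, one expression matrix per disease,
the popularity table, gene-term annotations and the planted ground truth
under results/data/.
"""

from common import DATA, STUDY

from degbias import (
    generate_corpus,
    generate_expression,
    generate_go_annotations,
    make_truth,
)
from degbias import io as dio


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    truth = make_truth(STUDY)
    docs = generate_corpus(STUDY, truth)
    dio.write_pubtator(docs, DATA / "corpus.pubtator")
    dio.write_popularity(truth.popularity, DATA / "popularity.tsv")
    dio.write_gene_terms(
        generate_go_annotations(STUDY, truth), DATA / "annotations.tsv"
    )
    dio.write_statements(truth.gold_statements, DATA / "gold_statements.tsv")
    truth.de_table.to_csv(DATA / "planted_log2fc.tsv", sep="\t",
                          index_label="gene")
    for d in truth.diseases:
        matrix, groups, _ = generate_expression(STUDY, d, truth)
        dio.write_expression(matrix, groups, DATA / f"expr_{d}.tsv",
                             DATA / f"groups_{d}.tsv")
    n_de = int((truth.de_table != 0).sum().sum())
    print(f"world: {STUDY.n_genes} genes x {STUDY.n_diseases} diseases, "
          f"{n_de} planted DE effects, {len(truth.gold_statements)} gold "
          f"statements in {len(docs)} abstracts -> {DATA}")


if __name__ == "__main__":
    main()
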