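#!/usr/bin/env python
"""Mine the corpus for gradable DEG statements and score against gold.

The tri-occurrence rule (gene + disease + trigger in one sentence) with the
qualifier lexicon recovers the planted statements; precision/recall against
the gold standard quantify the extractor.
"""

from common import DATA, RESULTS, STUDY

from degbias import evaluate_extraction, extract_statements
from degbias import io as dio


def main() -> None:
    docs = dio.read_pubtator(DATA / "corpus.pubtator")
    diseases = {f"DIS{i:02d}" for i in range(1, STUDY.n_diseases + 1)}
    statements = extract_statements(docs, target_diseases=diseases)
    dio.write_statements(statements, RESULTS / "statements.tsv",
                         corpus={d.pmid: d for d in docs})
    gold = dio.read_statements(DATA / "gold_statements.tsv")
    m = evaluate_extraction(statements, gold)
    print(f"extracted {len(statements)} statements from {len(docs)} "
          f"abstracts; precision={m['precision']:.3f} "
          f"recall={m['recall']:.3f} (vs {len(gold)} gold)")


if __name__ == "__main__":
    main()
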