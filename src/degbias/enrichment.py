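"""Term overrepresentation analysis and top-K overlap between term lists.

One-sided Fisher's exact test (upper hypergeometric tail) of each term's
membership in a study gene set versus a gene universe, with Bonferroni
family-wise correction. Genes without any annotation contribute to the
"unclassified" pseudo-term so that a fully unannotated study set is still
interpretable.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

UNCLASSIFIED = "unclassified"

ENRICHMENT_COLUMNS = ["term_id", "k", "K", "n", "N", "p", "p_bonf"]


def fisher_overrep(
    study_set: set[str],
    universe: set[str],
    annotations: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Overrepresentation of every annotated term in ``study_set``.

    p = P(X >= k) for X hypergeometric with universe size N, K term genes
    and a draw of n study genes; p_bonf = min(1, p * m) over the m tested
    terms. Rows are sorted by p then term id. Annotation genes outside the
    universe are dropped with a warning; an empty study set is an error.
    """
    if not study_set:
        raise ValueError("study set is empty")
    extra_study = study_set - universe
    if extra_study:
        raise ValueError(
            f"study genes outside the universe: {sorted(extra_study)[:5]}..."
        )
    dropped = [g for g in annotations if g not in universe]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} annotated genes outside the universe"
        )
    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        terms = annotations.get(gene) or {UNCLASSIFIED}
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(study_set)
    rows = []
    m = len(term_genes)
    for term, genes in term_genes.items():
        K = len(genes)
        k = len(genes & study_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term, "k": k, "K": K, "n": n, "N": N,
             "p": min(p, 1.0), "p_bonf": min(1.0, p * m)}
        )
    out = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    return out.sort_values(["p", "term_id"], kind="mergesort").reset_index(
        drop=True
    )


def top_k_overlap(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    k: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Overlap between two enrichment result lists.

    Reports both readings of "shared overrepresented classes": the
    intersection of Bonferroni-significant terms (p_bonf < alpha) and the
    intersection of the top-k terms by p-value.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    sig_a = set(rows_a.loc[rows_a["p_bonf"] < alpha, "term_id"])
    sig_b = set(rows_b.loc[rows_b["p_bonf"] < alpha, "term_id"])
    top_a = set(rows_a.nsmallest(k, "p")["term_id"]) if len(rows_a) else set()
    top_b = set(rows_b.nsmallest(k, "p")["term_id"]) if len(rows_b) else set()
    return {
        "shared_significant": sorted(sig_a & sig_b),
        "n_shared_significant": len(sig_a & sig_b),
        "n_significant_a": len(sig_a),
        "n_significant_b": len(sig_b),
        "shared_top_k": sorted(top_a & top_b),
        "n_shared_top_k": len(top_a & top_b),
    }
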