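"""Readers and writers for the plain-text formats the pipeline consumes.

PubTator corpora, expression matrices with a sample-group sidecar,
two-column tables (popularity, probe maps, gene->term annotations) and
statement tables. A minimal GEO series-matrix reader converts the
documented text layout into the canonical matrix + groups pair.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .extraction import AnnotatedDocument, DEGStatement, DeltaValue, Mention

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# PubTator
# ---------------------------------------------------------------------------

def write_pubtator(docs: Iterable[AnnotatedDocument], path: PathLike) -> None:
    """Write documents in PubTator format.

    The document text is stored as ``pmid|t|<first sentence-ish title>`` and
    ``pmid|a|<rest>``; mention offsets index into ``title + " " + abstract``.
    Here the full text round-trips through a synthetic split: everything up
    to the first space after the first period goes to the title line.
    """
    with open(path, "w") as fh:
        for doc in docs:
            cut = doc.text.find(". ")
            if cut == -1:
                title, abstract = doc.text, ""
            else:
                title, abstract = doc.text[: cut + 1], doc.text[cut + 2:]
            fh.write(f"{doc.pmid}|t|{title}\n")
            fh.write(f"{doc.pmid}|a|{abstract}\n")
            for m in doc.mentions:
                fh.write(
                    f"{doc.pmid}\t{m.start}\t{m.end}\t{m.text}\t{m.type}\t{m.identifier}\n"
                )
            fh.write("\n")


def read_pubtator(path_or_text: Union[PathLike, _io.StringIO]) -> list[AnnotatedDocument]:
    """Parse a PubTator file into annotated documents.

    Mention offsets are interpreted against ``title + " " + abstract``.
    A malformed annotation line raises ``ValueError`` naming the line.
    """
    if hasattr(path_or_text, "read"):
        lines = path_or_text.read().splitlines()
    else:
        lines = Path(path_or_text).read_text().splitlines()
    docs: list[AnnotatedDocument] = []
    title: dict[str, str] = {}
    abstract: dict[str, str] = {}
    mentions: dict[str, list[Mention]] = {}
    order: list[str] = []

    def flush():
        for pmid in order:
            text = title.get(pmid, "")
            if abstract.get(pmid):
                text = text + " " + abstract[pmid] if text else abstract[pmid]
            docs.append(
                AnnotatedDocument(
                    pmid=pmid, text=text, mentions=tuple(mentions.get(pmid, []))
                )
            )
        title.clear(); abstract.clear(); mentions.clear(); order.clear()

    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            flush()
            continue
        if "|t|" in line:
            pmid, _, t = line.split("|", 2)
            title[pmid] = t
            if pmid not in order:
                order.append(pmid)
        elif "|a|" in line:
            pmid, _, a = line.split("|", 2)
            abstract[pmid] = a
            if pmid not in order:
                order.append(pmid)
        else:
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"malformed annotation at line {lineno}: {line!r}")
            pmid, start, end, text, typ, ident = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"malformed annotation at line {lineno}: {line!r}"
                ) from exc
            mentions.setdefault(pmid, []).append(
                Mention(start=s, end=e, text=text, type=typ, identifier=ident)
            )
    flush()
    return docs


# ---------------------------------------------------------------------------
# statements
# ---------------------------------------------------------------------------

STATEMENT_COLUMNS = ["pmid", "gene", "disease", "delta", "sentence"]


def write_statements(
    statements: Sequence[DEGStatement],
    path: PathLike,
    corpus: Mapping[str, AnnotatedDocument] | None = None,
) -> None:
    rows = []
    for s in statements:
        sentence = ""
        if corpus is not None and s.pmid in corpus:
            a, b = s.sentence_span
            sentence = corpus[s.pmid].text[a:b].strip()
        rows.append((s.pmid, s.gene, s.disease, s.delta.label, sentence))
    pd.DataFrame(rows, columns=STATEMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_statements(path: PathLike) -> list[DEGStatement]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        DEGStatement(
            pmid=r.pmid, gene=r.gene, disease=r.disease,
            delta=DeltaValue.from_label(r.delta),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression(matrix: pd.DataFrame, groups: pd.Series,
                     matrix_path: PathLike, groups_path: PathLike) -> None:
    matrix.to_csv(matrix_path, sep="\t", index_label="feature")
    groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")


def read_expression(matrix_path: PathLike, groups_path: PathLike):
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    return matrix, groups


def read_geo_series_matrix(path: PathLike, disease_keyword: str = "disease"):
    """Convert a GEO series-matrix text file to (matrix, groups).

    Only the expression table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` plus the ``!Sample_title`` /
    ``!Sample_characteristics_ch1`` lines are used; a sample whose metadata
    contains ``disease_keyword`` (case-insensitive) is labelled ``disease``,
    all others ``normal``.
    """
    meta_lines: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
        elif line.startswith(("!Sample_title", "!Sample_characteristics_ch1")):
            meta_lines.append([f.strip('"') for f in line.split("\t")])
    if not table_lines:
        raise ValueError(f"no expression table found in {path}")
    matrix = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [c.strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip('"') for i in matrix.index]
    labels = []
    kw = disease_keyword.lower()
    for j, col in enumerate(matrix.columns, start=1):
        fields = " ".join(row[j] for row in meta_lines if len(row) > j)
        labels.append("disease" if kw in fields.lower() else "normal")
    groups = pd.Series(labels, index=matrix.columns, name="group")
    return matrix, groups


# ---------------------------------------------------------------------------
# two-column tables
# ---------------------------------------------------------------------------

def read_two_column(path: PathLike, key: str, value: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != [key, value]:
        df.columns = [key, value] + list(df.columns[2:])
    return df[[key, value]]


def read_popularity(path: PathLike) -> pd.Series:
    df = read_two_column(path, "gene", "popularity")
    return df.set_index("gene")["popularity"].astype(int)


def write_popularity(popularity: pd.Series, path: PathLike) -> None:
    popularity.rename("popularity").to_csv(path, sep="\t", index_label="gene")


def read_probe_map(path: PathLike) -> dict[str, str]:
    df = read_two_column(path, "probe", "gene")
    return dict(zip(df["probe"].astype(str), df["gene"].astype(str)))


def read_gene_terms(path: PathLike) -> dict[str, set[str]]:
    """Gene->term map from a two-column TSV or a GAF 2.x subset.

    GAF lines (tab-separated, comment lines start with ``!``) contribute
    (column 3 gene symbol, column 5 GO id); anything else is treated as a
    plain two-column table.
    """
    text = Path(path).read_text().splitlines()
    body = [l for l in text if l and not l.startswith("!")]
    out: dict[str, set[str]] = {}
    first = body[0].split("\t") if body else []
    if len(first) >= 15:  # GAF
        for line in body:
            f = line.split("\t")
            out.setdefault(f[2], set()).add(f[4])
        return out
    start = 1 if body and body[0].lower().split("\t")[:2] == ["gene", "term"] else 0
    for line in body[start:]:
        gene, term = line.split("\t")[:2]
        out.setdefault(gene, set()).add(term)
    return out


def write_gene_terms(annotations: Mapping[str, set[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tterm\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_universe(path: PathLike) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
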