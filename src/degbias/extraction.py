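"""Rule-based extraction of gradable differential-expression statements.

A statement is a tuple (PMID, gene, disease, delta) asserted by a single
sentence that satisfies *tri-occurrence*: it mentions a gene, a target
disease (or a locally-defined abbreviation of it) and contains a trigger
word signalling expression language. The direction and coarse magnitude of
the change (delta) is read off a gradable-qualifier lexicon with
longest-match-wins semantics; vague qualifiers ("aberrant", "altered", ...)
are explicitly excluded.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml


class DeltaValue(enum.IntEnum):
    """Ordinal direction/magnitude of a reported expression change."""

    HIGH_DECREASE = -2
    DECREASE = -1
    INCREASE = 1
    HIGH_INCREASE = 2

    @property
    def sign(self) -> int:
        return 1 if self.value > 0 else -1

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "DeltaValue":
        return cls[label.upper()]


@dataclass(frozen=True)
class Mention:
    """An entity annotation: character span, surface text, type, identifier.

    ``identifier`` may list several candidate identifiers separated by ';'
    (ambiguous gene names); mentions resolving to more than three symbols
    are dropped during extraction.
    """

    start: int
    end: int
    text: str
    type: str  # "Gene" | "Disease"
    identifier: str

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(i for i in self.identifier.split(";") if i)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.identifiers) > 3


@dataclass(frozen=True)
class AnnotatedDocument:
    pmid: str
    text: str  # title + " " + abstract; mention offsets index into this
    mentions: tuple[Mention, ...] = ()

    def __post_init__(self):
        for m in self.mentions:
            if not (0 <= m.start < m.end <= len(self.text)):
                raise ValueError(
                    f"mention span ({m.start},{m.end}) outside document {self.pmid}"
                )


@dataclass(frozen=True, order=True)
class DEGStatement:
    """One extracted (PMID, gene, disease, delta) assertion."""

    pmid: str
    gene: str
    disease: str
    delta: DeltaValue
    sentence_span: tuple[int, int] = field(default=(0, 0), compare=False)

    @property
    def key(self) -> tuple[str, str, str, DeltaValue]:
        return (self.pmid, self.gene, self.disease, self.delta)


@dataclass(frozen=True)
class QualifierLexicon:
    increase_phrases: frozenset[str]
    high_increase_phrases: frozenset[str]
    decrease_phrases: frozenset[str]
    high_decrease_phrases: frozenset[str]
    excluded_phrases: frozenset[str]
    trigger_substrings: tuple[str, ...] = (
        "express",
        "production",
        "produce",
        "transcription",
        "transcribe",
    )

    def __post_init__(self):
        sets = [
            self.increase_phrases,
            self.high_increase_phrases,
            self.decrease_phrases,
            self.high_decrease_phrases,
            self.excluded_phrases,
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"lexicon phrase sets overlap: {sorted(overlap)}")
        if not self.trigger_substrings:
            raise ValueError("trigger substring set must be non-empty")

    def delta_phrases(self) -> dict[str, DeltaValue]:
        out: dict[str, DeltaValue] = {}
        for phrases, delta in (
            (self.increase_phrases, DeltaValue.INCREASE),
            (self.high_increase_phrases, DeltaValue.HIGH_INCREASE),
            (self.decrease_phrases, DeltaValue.DECREASE),
            (self.high_decrease_phrases, DeltaValue.HIGH_DECREASE),
        ):
            for p in phrases:
                out[p.lower()] = delta
        return out

    def phrases_for(self, delta: DeltaValue) -> frozenset[str]:
        return {
            DeltaValue.INCREASE: self.increase_phrases,
            DeltaValue.HIGH_INCREASE: self.high_increase_phrases,
            DeltaValue.DECREASE: self.decrease_phrases,
            DeltaValue.HIGH_DECREASE: self.high_decrease_phrases,
        }[delta]

    @classmethod
    def from_yaml(cls, path_or_stream) -> "QualifierLexicon":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        return cls(
            increase_phrases=frozenset(p.lower() for p in raw["increase_phrases"]),
            high_increase_phrases=frozenset(
                p.lower() for p in raw["high_increase_phrases"]
            ),
            decrease_phrases=frozenset(p.lower() for p in raw["decrease_phrases"]),
            high_decrease_phrases=frozenset(
                p.lower() for p in raw["high_decrease_phrases"]
            ),
            excluded_phrases=frozenset(p.lower() for p in raw["excluded_phrases"]),
            trigger_substrings=tuple(
                t.lower() for t in raw.get(
                    "trigger_substrings",
                    ("express", "production", "produce", "transcription", "transcribe"),
                )
            ),
        )


def default_lexicon() -> QualifierLexicon:
    """The lexicon shipped with the package (``data/lexicon.yaml``)."""
    ref = resources.files("degbias").joinpath("data/lexicon.yaml")
    with ref.open("r") as fh:
        return QualifierLexicon.from_yaml(fh)


# ---------------------------------------------------------------------------
# sentence splitting
# ---------------------------------------------------------------------------

# Tokens after which a period is not a sentence boundary. Single capital
# letters ("E." in "E. coli") and initials are guarded separately.
_ABBREVIATIONS = {
    "vs", "al", "et", "fig", "figs", "e.g", "i.e", "ca", "approx", "cf",
    "dr", "st", "no", "ref", "refs", "spp", "sp",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(\s+)")


def split_sentences(document: AnnotatedDocument) -> list[tuple[int, int]]:
    """Partition a document's text into sentence spans.

    Rule-based: a run of terminal punctuation followed by whitespace and an
    uppercase letter or digit ends a sentence, unless the preceding token is
    a known abbreviation or a single capital letter (species initials,
    author initials), or the boundary would fall inside an entity mention.
    Spans tile the text exactly; a document with no terminal punctuation is
    a single span.
    """
    text = document.text
    if not text:
        raise ValueError("cannot split an empty document")
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        after = m.end()
        if after >= len(text):
            continue
        if not (text[after].isupper() or text[after].isdigit()):
            continue
        # token immediately before the punctuation
        before = text[: m.start()]
        tok = re.split(r"\s", before)[-1] if before else ""
        tok_clean = tok.rstrip(".").lower()
        if tok_clean in _ABBREVIATIONS:
            continue
        if re.fullmatch(r"[A-Z]", tok.rstrip(".")):  # "E. coli", initials
            continue
        if any(mn.start < after <= mn.end or mn.start < m.start() < mn.end
               for mn in document.mentions):
            continue
        boundaries.append(after)
    spans = []
    prev = 0
    for b in boundaries:
        spans.append((prev, b))
        prev = b
    spans.append((prev, len(text)))
    return spans


# ---------------------------------------------------------------------------
# trigger and qualifier detection
# ---------------------------------------------------------------------------

def detect_trigger(sentence: str, lexicon: QualifierLexicon) -> bool:
    """True iff some token contains a trigger substring (case-insensitive)."""
    for token in re.findall(r"\w+", sentence.lower()):
        if any(t in token for t in lexicon.trigger_substrings):
            return True
    return False


def _phrase_matches(sentence: str, phrases: Iterable[str]):
    """Yield (start, end, phrase) for word-bounded, case-insensitive matches."""
    low = sentence.lower()
    for phrase in phrases:
        for m in re.finditer(r"(?<!\w)" + re.escape(phrase) + r"(?!\w)", low):
            yield m.start(), m.end(), phrase


_NEGATION_TOKENS = {"not", "no", "neither", "nor", "without", "never"}


def _is_negated(sentence: str, match_start: int, window: int = 2) -> bool:
    before = re.findall(r"\w+", sentence[:match_start].lower())
    return any(tok in _NEGATION_TOKENS for tok in before[-window:])


def classify_delta(
    sentence: str, lexicon: QualifierLexicon, negation_guard: bool = False
) -> tuple[Optional[DeltaValue], Optional[str]]:
    """Map a sentence to a delta via its qualifier phrases.

    Returns ``(delta, None)`` for the longest matching gradable phrase,
    ``(None, "excluded")`` when only an excluded (vague) phrase matches, and
    ``(None, "no_qualifier")`` when nothing matches. With
    ``negation_guard=True`` a qualifier preceded within two tokens by a
    negation ("not increased") is ignored; the guard is off by default.
    """
    delta_map = lexicon.delta_phrases()
    matches = list(_phrase_matches(sentence, delta_map))
    if negation_guard:
        matches = [m for m in matches if not _is_negated(sentence, m[0])]
    if matches:
        start, end, phrase = max(matches, key=lambda t: (t[1] - t[0], -t[0]))
        return delta_map[phrase], None
    if any(True for _ in _phrase_matches(sentence, lexicon.excluded_phrases)):
        return None, "excluded"
    return None, "no_qualifier"


# ---------------------------------------------------------------------------
# abbreviation detection:  "ulcerative colitis (UC)"  maps "UC" -> disease id
# ---------------------------------------------------------------------------

_ABBR_RE = re.compile(r"\(([A-Za-z][A-Za-z0-9-]{1,9})\)")


def detect_abbreviations(document: AnnotatedDocument) -> dict[str, str]:
    """Map locally-defined short forms to disease identifiers.

    A parenthesised short form immediately following an annotated disease
    mention ("long form (SHORT)") is taken as an abbreviation of that
    disease for the rest of the document.
    """
    out: dict[str, str] = {}
    disease_mentions = [m for m in document.mentions if m.type.lower() == "disease"]
    for m in _ABBR_RE.finditer(document.text):
        open_paren = m.start()
        for dm in disease_mentions:
            gap = document.text[dm.end:open_paren]
            if dm.end <= open_paren and gap.strip() == "":
                out[m.group(1)] = dm.identifiers[0]
                break
    return out


# ---------------------------------------------------------------------------
# tri-occurrence extraction
# ---------------------------------------------------------------------------

def _tokens_with_spans(sentence: str):
    return [(m.start(), m.end()) for m in re.finditer(r"\S+", sentence)]


def _token_index(token_spans, char_pos: int) -> int:
    for i, (s, e) in enumerate(token_spans):
        if s <= char_pos < e:
            return i
    # position between tokens: nearest following token
    for i, (s, _) in enumerate(token_spans):
        if s >= char_pos:
            return i
    return len(token_spans) - 1


def _resolve_conflicting_delta(
    sentence: str,
    lexicon: QualifierLexicon,
    gene_pos: int,
    trigger_positions: Sequence[int],
    window: int,
) -> Optional[DeltaValue]:
    """Pick the qualifier for one gene when qualifiers of both signs co-occur.

    The nearest qualifier within ``window`` tokens of the gene mention (or
    of a trigger token) wins; if none is that close the pairing is ambiguous
    and no statement is emitted.
    """
    delta_map = lexicon.delta_phrases()
    token_spans = _tokens_with_spans(sentence)
    gene_tok = _token_index(token_spans, gene_pos)
    trig_toks = [_token_index(token_spans, p) for p in trigger_positions]
    best: tuple[int, int, Optional[DeltaValue]] = (window + 1, 0, None)
    for start, end, phrase in _phrase_matches(sentence, delta_map):
        q_tok = _token_index(token_spans, start)
        dist = min(
            [abs(q_tok - gene_tok)] + [abs(q_tok - t) for t in trig_toks]
        )
        length = end - start
        if dist <= window and (dist, -length) < (best[0], -best[1]):
            best = (dist, length, delta_map[phrase])
    return best[2]


def _trigger_positions(sentence: str, lexicon: QualifierLexicon) -> list[int]:
    out = []
    for m in re.finditer(r"\w+", sentence.lower()):
        if any(t in m.group(0) for t in lexicon.trigger_substrings):
            out.append(m.start())
    return out


def extract_statements(
    corpus: Iterable[AnnotatedDocument],
    lexicon: Optional[QualifierLexicon] = None,
    target_diseases: Optional[set[str]] = None,
    qualifier_window: int = 8,
) -> list[DEGStatement]:
    """Extract deduplicated DEG statements from an annotated corpus.

    For every sentence that contains at least one gene mention, at least one
    target-disease mention (or locally-defined abbreviation) and a trigger
    substring, emit one statement per resolved gene symbol with the
    sentence's delta. Gene mentions resolving to more than three symbols are
    dropped. Redundant (pmid, gene, disease, delta) tuples are discarded;
    per-document order is stable.
    """
    lexicon = lexicon or default_lexicon()
    seen: dict[tuple, DEGStatement] = {}
    for doc in corpus:
        abbr = detect_abbreviations(doc)
        spans = split_sentences(doc)
        for s_start, s_end in spans:
            sentence = doc.text[s_start:s_end]
            genes = [
                m for m in doc.mentions
                if m.type.lower() == "gene"
                and s_start <= m.start and m.end <= s_end
                and not m.is_ambiguous
            ]
            if not genes:
                continue
            diseases = {
                m.identifiers[0]
                for m in doc.mentions
                if m.type.lower() == "disease"
                and s_start <= m.start and m.end <= s_end
            }
            for short, did in abbr.items():
                if re.search(r"(?<!\w)" + re.escape(short) + r"(?!\w)", sentence):
                    diseases.add(did)
            if target_diseases is not None:
                diseases &= set(target_diseases)
            if not diseases:
                continue
            if not detect_trigger(sentence, lexicon):
                continue
            delta, _reason = classify_delta(sentence, lexicon)
            if delta is None:
                continue
            # conflicting signs in one sentence: per-gene adjacency rule
            delta_map = lexicon.delta_phrases()
            signs = {
                delta_map[p].sign
                for _, _, p in _phrase_matches(sentence, delta_map)
            }
            trig_pos = _trigger_positions(sentence, lexicon)
            for gm in genes:
                if len(signs) > 1:
                    g_delta = _resolve_conflicting_delta(
                        sentence, lexicon, gm.start - s_start, trig_pos,
                        qualifier_window,
                    )
                    if g_delta is None:
                        continue
                else:
                    g_delta = delta
                for symbol in gm.identifiers:
                    for did in sorted(diseases):
                        st = DEGStatement(
                            pmid=doc.pmid,
                            gene=symbol,
                            disease=did,
                            delta=g_delta,
                            sentence_span=(s_start, s_end),
                        )
                        seen.setdefault(st.key, st)
    return list(seen.values())


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_extraction(
    predicted: Sequence[DEGStatement], gold: Sequence[DEGStatement]
) -> dict[str, float]:
    """Set-based precision/recall/F1 over (pmid, gene, disease, delta) keys.

    Convention: precision is 1 when nothing was predicted, recall is 1 when
    the gold set is empty (no misses possible); F1 is 0 when both P and R
    are 0.
    """
    pset = {s.key for s in predicted}
    gset = {s.key for s in gold}
    tp = len(pset & gset)
    precision = tp / len(pset) if pset else 1.0
    recall = tp / len(gset) if gset else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": float(tp), "n_predicted": float(len(pset)),
            "n_gold": float(len(gset))}
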