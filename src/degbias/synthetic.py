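"""Synthetic corpora, expression matrices, popularity and GO annotations.

Every downstream stage of the pipeline is testable against planted ground
truth generated here. The generative model mirrors the structure of the
analyses it feeds:

* per (gene, disease), a planted log2 fold change (a configurable fraction
  of genes is truly differentially expressed; the rest are exactly 0);
* gene popularity with a power-law tail;
* a per-statement reporting model: the probability that a true DEG yields a
  literature mention follows
  logit^-1(intercept + alpha*|log2FC| + beta*log10(popularity)), with
  overexpressed genes up-weighted by a multiplicative over-reporting ratio
  — the generative analogue of the linear reporting models fitted
  downstream (the fitting stage still uses raw popularity);
* mention counts arise by aggregating per-statement Bernoulli draws, each
  phrased as a high-increase qualifier with a configurable rate;
* gene-to-GO annotations in which planted terms are over-represented among
  the up-regulated DE genes by a configurable odds factor.

Randomness is disciplined: one root seed, named per-component child
streams, so identical (config, seed) yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np
import pandas as pd

from .extraction import DEGStatement, DeltaValue, default_lexicon

_COMPONENT_STREAMS = {
    "truth": 0,
    "popularity": 1,
    "reporting": 2,
    "corpus": 3,
    "expression": 4,
    "go": 5,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic world.

    Defaults emulate the scale of the real comparison: a shared gene
    universe of a few thousand genes, four diseases, ~10% of genes truly DE
    per disease with at least a twofold planted change, unit-SD log2 noise,
    and a literature that over-reports overexpression roughly 3.5-fold.
    """

    n_genes: int = 2000
    n_diseases: int = 4
    n_samples_per_group: int = 10
    frac_de: float = 0.1
    lfc_scale: float = 1.0
    noise_sd: float = 0.5
    var_df: float = 10.0
    popularity_exponent: float = 1.5
    report_alpha: float = 0.6
    report_beta: float = 0.8
    report_intercept: float = -4.0
    over_report_ratio: float = 3.5
    high_qualifier_rate: float = 0.25
    mention_trials: int = 3
    statements_per_abstract: int = 1
    distractor_frac: float = 0.2
    n_go_terms: int = 50
    n_enriched_terms: int = 5
    enrichment_odds: float = 5.0
    go_baseline_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_diseases", "n_samples_per_group",
                     "mention_trials", "statements_per_abstract",
                     "n_go_terms", "n_enriched_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("frac_de", "high_qualifier_rate"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0 <= self.distractor_frac <= 1):
            raise ValueError("distractor_frac must lie in [0, 1]")
        for name in ("lfc_scale", "popularity_exponent", "over_report_ratio",
                     "enrichment_odds"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.var_df <= 2:
            raise ValueError("var_df must exceed 2 (finite variance of variances)")

    def rng(self, component: str) -> np.random.Generator:
        key = _COMPONENT_STREAMS[component]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def disease_ids(self) -> list[str]:
        return [f"DIS{i:02d}" for i in range(1, self.n_diseases + 1)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted parameters and the gold-standard statement set."""

    config: SyntheticConfig
    de_table: pd.DataFrame          # genes x diseases planted log2FC (0 = non-DE)
    popularity: pd.Series           # gene -> mention count in the wider literature
    gold_statements: list[DEGStatement]
    enriched_terms: list[str]
    mention_counts: pd.DataFrame = field(default=None)  # per (gene, disease)

    @property
    def genes(self) -> list[str]:
        return list(self.de_table.index)

    @property
    def diseases(self) -> list[str]:
        return list(self.de_table.columns)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def generate_popularity(config: SyntheticConfig) -> pd.Series:
    """Heavy-tailed integer popularity counts, one per gene, all >= 1.

    Discrete Pareto: floor(u^(-1/exponent)); larger exponents give lighter
    tails and therefore smaller sample maxima.
    """
    rng = config.rng("popularity")
    u = rng.uniform(size=config.n_genes)
    pop = np.floor(u ** (-1.0 / config.popularity_exponent)).astype(np.int64)
    pop = np.clip(pop, 1, 10_000_000)
    return pd.Series(pop, index=config.gene_ids(), name="popularity")


def _planted_lfc(config: SyntheticConfig) -> pd.DataFrame:
    """Per-disease planted log2FC: frac_de genes DE, |lfc| >= 1.5*lfc_scale.

    Magnitudes are shifted-exponential, lfc_scale*(1.5 + Exp(0.75)), so at
    the default scale every true effect clears the twofold threshold with a
    margin; signs are balanced.
    """
    rng = config.rng("truth")
    genes = config.gene_ids()
    table = pd.DataFrame(
        0.0, index=genes, columns=config.disease_ids(), dtype=float
    )
    n_de = round(config.frac_de * config.n_genes)
    for disease in table.columns:
        idx = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        mags = config.lfc_scale * (1.5 + rng.exponential(scale=0.75, size=n_de))
        table.iloc[idx, table.columns.get_loc(disease)] = signs * mags
    return table


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def reporting_probability(
    config: SyntheticConfig, lfc: np.ndarray, popularity: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel reporting model; every gene is eligible in either
    direction, so the literature can assert changes the arrays do not show.

    Channel base rates are
    ``logit^-1(intercept + alpha*max(+-log2FC, 0) + beta*log10(popularity))``
    so the true fold change raises the probability of being reported in its
    own direction while popularity raises both. The over channel is further
    multiplied by the over-reporting ratio; base rates are capped at
    0.95/ratio so the boost never saturates and the expected unique-gene
    over:under ratio equals the configured ratio. Returns
    (p_over, p_under, base_over, base_under); the bases are also the
    per-opportunity rates for additional mentions of a reported gene.
    """
    cap = 0.95 / max(config.over_report_ratio, 1.0)

    def base(direction_lfc: np.ndarray) -> np.ndarray:
        return np.minimum(
            _logistic(
                config.report_intercept
                + config.report_alpha * np.maximum(direction_lfc, 0.0)
                + config.report_beta * np.log10(np.maximum(popularity, 1))
            ),
            cap,
        )

    b_over, b_under = base(lfc), base(-lfc)
    return config.over_report_ratio * b_over, b_under, b_over, b_under


def make_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Plant effects, sample the reporting model, and fix the gold standard.

    Every gene can be reported over- or under-expressed in every disease
    (the literature is free to assert what the arrays do not show); the
    planted fold change only tilts the odds through the alpha coupling,
    popularity through beta, and the over channel through the
    over-reporting ratio. A reported (gene, disease, direction) yields
    1 + Binomial(mention_trials - 1, base rate) mentions, each phrased as
    a high qualifier with probability ``high_qualifier_rate``, and every
    mention becomes one gold statement with its own PMID.
    """
    de_table = _planted_lfc(config)
    popularity = generate_popularity(config)
    rng = config.rng("reporting")
    rows = []
    statements: list[DEGStatement] = []
    pmid_counter = 1
    for disease in de_table.columns:
        lfc = de_table[disease].to_numpy()
        p_over, p_under, b_over, b_under = reporting_probability(
            config, lfc, popularity.to_numpy()
        )
        mentions = {}
        for key, p, b in (("over", p_over, b_over),
                          ("under", p_under, b_under)):
            reported = rng.uniform(size=len(lfc)) < p
            extra = rng.binomial(config.mention_trials - 1, b)
            m = np.where(reported, 1 + extra, 0)
            mentions[key] = (m, rng.binomial(m, config.high_qualifier_rate))
        for gi, gene in enumerate(de_table.index):
            m_o, h_o = int(mentions["over"][0][gi]), int(mentions["over"][1][gi])
            m_u, h_u = int(mentions["under"][0][gi]), int(mentions["under"][1][gi])
            inc, hinc = m_o - h_o, h_o
            dec, hdec = m_u - h_u, h_u
            rows.append(
                {"gene": gene, "disease": disease, "log2fc": lfc[gi],
                 "increase_mentions": inc, "high_increase_mentions": hinc,
                 "decrease_mentions": dec, "high_decrease_mentions": hdec}
            )
            for delta, count in (
                (DeltaValue.INCREASE, inc),
                (DeltaValue.HIGH_INCREASE, hinc),
                (DeltaValue.DECREASE, dec),
                (DeltaValue.HIGH_DECREASE, hdec),
            ):
                for _ in range(count):
                    statements.append(
                        DEGStatement(
                            pmid=f"S{pmid_counter:07d}", gene=gene,
                            disease=disease, delta=delta,
                        )
                    )
                    pmid_counter += 1
    # pack statements into abstracts; identical (pmid, gene, disease, delta)
    # tuples inside one abstract would deduplicate downstream, so packing >1
    # is a corpus-compression knob, not a mention-count change at defaults
    spa = config.statements_per_abstract
    statements = [
        replace(st, pmid=f"S{i // spa + 1:07d}")
        for i, st in enumerate(statements)
    ]
    enriched = [f"TERM{i:03d}" for i in range(config.n_enriched_terms)]
    return SyntheticTruth(
        config=config,
        de_table=de_table,
        popularity=popularity,
        gold_statements=statements,
        enriched_terms=enriched,
        mention_counts=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    config: SyntheticConfig, disease: str, truth: Optional[SyntheticTruth] = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Two-group log2 expression matrix for one disease.

    Returns (matrix genes x 2n samples, sample->group labels, planted
    log2FC slice). Disease-group means are shifted by the planted log2FC on
    top of a gene-specific baseline; noise is i.i.d. Gaussian on the log2
    scale.
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    truth = truth if truth is not None else make_truth(config)
    if disease not in truth.de_table.columns:
        raise KeyError(f"unknown disease {disease!r}")
    # independent child stream per disease so matrices don't share noise
    d_index = list(truth.de_table.columns).index(disease)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.seed,
            spawn_key=(_COMPONENT_STREAMS["expression"], d_index),
        )
    )
    n = config.n_samples_per_group
    genes = truth.genes
    lfc = truth.de_table[disease].to_numpy()
    baseline = rng.uniform(5.0, 10.0, size=len(genes))
    # gene-wise true variances are scaled inverse chi-square around
    # noise_sd^2 (the hierarchical model the moderated t assumes), so the
    # shrinkage prior is estimable from the data
    var_scale = config.var_df / rng.chisquare(config.var_df, size=len(genes))
    sd = config.noise_sd * np.sqrt(var_scale)
    noise = rng.normal(0.0, 1.0, size=(len(genes), 2 * n)) * sd[:, None]
    vals = baseline[:, None] + noise
    vals[:, :n] += lfc[:, None]
    samples = [f"{disease}_case_{i+1:02d}" for i in range(n)] + [
        f"{disease}_ctrl_{i+1:02d}" for i in range(n)
    ]
    matrix = pd.DataFrame(vals, index=genes, columns=samples)
    groups = pd.Series(
        ["disease"] * n + ["normal"] * n, index=samples, name="group"
    )
    return matrix, groups, truth.de_table[disease].copy()


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

_DISEASE_NAMES = [
    "atopic dermatitis", "crohn disease", "psoriasis", "ulcerative colitis",
    "rheumatoid arthritis", "asthma", "multiple sclerosis", "lupus",
]

_GOLD_TEMPLATES = [
    "The expression of {gene} was {qualifier} in {disease}.",
    "{gene} expression was {qualifier} in patients with {disease}.",
    "Levels of {gene} were {qualifier} in {disease} lesions, consistent with its transcription profile.",
    "{gene} was found to be {qualifier} in {disease} tissue by expression profiling.",
]

_DISTRACTOR_NO_TRIGGER = [
    "{gene} levels correlated with {disease} severity.",
    "Serum {gene} was associated with {disease} outcome.",
    "{gene} polymorphisms were linked to {disease} risk.",
]

_DISTRACTOR_EXCLUDED = [
    "The expression of {gene} was {excluded} in {disease}.",
    "{gene} expression appeared {excluded} in patients with {disease}.",
]


def disease_display_name(config: SyntheticConfig, disease_id: str) -> str:
    idx = int(disease_id.replace("DIS", "")) - 1
    base = _DISEASE_NAMES[idx % len(_DISEASE_NAMES)]
    if idx >= len(_DISEASE_NAMES):
        base = f"{base} type {idx // len(_DISEASE_NAMES) + 1}"
    return base


def _render_sentence(template: str, gene: str, disease_name: str,
                     qualifier: str = "", excluded: str = "") -> tuple[str, int, int]:
    """Fill a template; return the sentence and gene/disease char offsets."""
    sentence = template.format(
        gene=gene, disease=disease_name, qualifier=qualifier,
        excluded=excluded,
    )
    g_start = sentence.index(gene)
    d_start = sentence.index(disease_name)
    return sentence, g_start, d_start


def generate_corpus(config: SyntheticConfig, truth: SyntheticTruth):
    """Render the gold statements as a PubTator-style annotated corpus.

    Each gold statement becomes one sentence in its own abstract (or packed
    ``statements_per_abstract`` at a time) with annotated gene and disease
    mentions, a trigger word and a qualifier phrase drawn from the shipped
    lexicon for its delta. Distractor sentences — trigger absent, or an
    excluded vague qualifier — are interleaved so that a fraction
    ``distractor_frac`` of all sentences carries no extractable statement.
    At distractor_frac = 1.0 the corpus contains only distractors (the
    degenerate no-signal case).
    """
    from .extraction import AnnotatedDocument, Mention

    lexicon = default_lexicon()
    rng = config.rng("corpus")
    known_genes = set(truth.genes)
    known_diseases = set(truth.diseases)
    qualifier_pool = {
        d: sorted(lexicon.phrases_for(d)) for d in DeltaValue
    }
    docs = []

    def build_doc(pmid: str, sentence_specs: list[dict]) -> AnnotatedDocument:
        title = "Expression profiling study of inflammatory disease."
        parts = [title]
        mentions = []
        offset = len(title)
        for spec in sentence_specs:
            sentence, g_off, d_off = spec["rendered"]
            start = offset + 1  # the joining space
            mentions.append(Mention(
                start=start + g_off, end=start + g_off + len(spec["gene"]),
                text=spec["gene"], type="Gene", identifier=spec["gene"],
            ))
            dn = spec["disease_name"]
            mentions.append(Mention(
                start=start + d_off, end=start + d_off + len(dn),
                text=dn, type="Disease", identifier=spec["disease"],
            ))
            parts.append(sentence)
            offset = start + len(sentence)
        return AnnotatedDocument(
            pmid=pmid, text=" ".join(parts), mentions=tuple(mentions)
        )

    gold_specs = []
    for st in truth.gold_statements:
        if st.gene not in known_genes or st.disease not in known_diseases:
            raise ValueError(
                f"gold statement references unknown ids: {st.gene}/{st.disease}"
            )
        dn = disease_display_name(config, st.disease)
        template = _GOLD_TEMPLATES[rng.integers(len(_GOLD_TEMPLATES))]
        pool = qualifier_pool[st.delta]
        qualifier = pool[rng.integers(len(pool))]
        gold_specs.append({
            "pmid": st.pmid, "gene": st.gene, "disease": st.disease,
            "disease_name": dn,
            "rendered": _render_sentence(template, st.gene, dn,
                                         qualifier=qualifier),
        })

    if config.distractor_frac >= 1.0:
        n_distract = max(len(gold_specs), 1)
        gold_specs = []
    else:
        f = config.distractor_frac
        n_distract = int(round(f / (1.0 - f) * len(gold_specs)))

    distract_specs = []
    genes, diseases = truth.genes, truth.diseases
    excluded_pool = sorted(lexicon.excluded_phrases)
    for i in range(n_distract):
        gene = genes[rng.integers(len(genes))]
        disease = diseases[rng.integers(len(diseases))]
        dn = disease_display_name(config, disease)
        if rng.uniform() < 0.5:
            template = _DISTRACTOR_NO_TRIGGER[
                rng.integers(len(_DISTRACTOR_NO_TRIGGER))]
            rendered = _render_sentence(template, gene, dn)
        else:
            template = _DISTRACTOR_EXCLUDED[
                rng.integers(len(_DISTRACTOR_EXCLUDED))]
            excl = excluded_pool[rng.integers(len(excluded_pool))]
            rendered = _render_sentence(template, gene, dn, excluded=excl)
        distract_specs.append({
            "pmid": f"D{i+1:07d}", "gene": gene, "disease": disease,
            "disease_name": dn, "rendered": rendered,
        })

    by_pmid: dict[str, list[dict]] = {}
    for spec in gold_specs:
        by_pmid.setdefault(spec["pmid"], []).append(spec)
    for pmid, specs in by_pmid.items():
        docs.append(build_doc(pmid, specs))
    for spec in distract_specs:
        docs.append(build_doc(spec["pmid"], [spec]))
    return docs


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

def generate_go_annotations(
    config: SyntheticConfig, truth: SyntheticTruth
) -> dict[str, set[str]]:
    """Gene->term map with planted enrichment among up-regulated DE genes.

    Every gene receives each background term with the baseline rate; for
    planted enriched terms the assignment odds among genes up-regulated in
    at least one disease are multiplied by ``enrichment_odds``. Each gene
    ends up with at least one term.
    """
    rng = config.rng("go")
    genes = truth.genes
    up_genes = set(
        truth.de_table.index[(truth.de_table > 0).any(axis=1)]
    )
    terms = [f"TERM{i:03d}" for i in range(config.n_go_terms)]
    enriched = set(truth.enriched_terms)
    p0 = config.go_baseline_rate
    odds0 = p0 / (1 - p0)
    p_enriched = (odds0 * config.enrichment_odds) / (
        1 + odds0 * config.enrichment_odds
    )
    up_mask = np.array([g in up_genes for g in genes])
    annotations: dict[str, set[str]] = {g: set() for g in genes}
    for term in terms:
        p = np.where(
            up_mask if term in enriched else False, p_enriched, p0
        )
        hits = rng.uniform(size=len(genes)) < p
        for g in np.asarray(genes, dtype=object)[hits]:
            annotations[g].add(term)
    fallback = [t for t in terms if t not in enriched] or terms
    for g in genes:
        if not annotations[g]:
            annotations[g].add(fallback[rng.integers(len(fallback))])
    return annotations
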