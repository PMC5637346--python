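# degbias

Quantifying reporting bias in the biomedical literature on differentially
expressed genes (DEGs), by comparing gradable expression statements mined
from entity-annotated abstracts against two-group microarray differential
expression across fold-change thresholds.

Literature and expression arrays are the two everyday sources of "gene X is
up/down in disease Y" evidence, and they disagree in systematic ways: the
literature prefers overexpression, popular genes, and genes reported in
several diseases. This package implements the complete measurement pipeline
for those biases and ships a synthetic-data generator with planted ground
truth, so every stage runs, and is tested, without any external downloads.
It is written for computational biologists studying literature bias, and for
anyone who wants a tested, reimplementable reference for the statistics
involved.

## What it computes

**Text mining.** Sentences satisfying *tri-occurrence* — a gene mention, a
disease mention (or a locally defined abbreviation), and a trigger word from
{express, production, produce, transcription, transcribe} — are classified
by a gradable-qualifier lexicon into Δ ∈ {high_decrease, decrease, increase,
high_increase} (longest match wins; vague qualifiers such as "aberrant" or
"altered" are excluded), yielding deduplicated statements (PMID, gene,
disease, Δ).

**Differential expression.** Per-gene two-sample statistics on log2
expression with empirical-Bayes variance shrinkage: the pooled variance
s²_g (d_g df) is combined with a moment-matched prior (d₀, s₀²) into
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and t = log2FC / (s̃_g √(1/n₁+1/n₂))
is referred to t with d₀ + d_g df, followed by Benjamini–Hochberg
adjustment and signed fold-change filtering (fc = sign(log2FC)·2^|log2FC|,
so "|FC| > 2" means |log2FC| > 1).

**Bias statistics.** Over:under reporting ratios of unique DEGs; the
positive likelihood ratio of gene-set overlap over a fixed universe,

LR+(A|B) = p(g∈A | g∈B) / p(g∈A | g∉B),

within and between diseases and as a function of the fold-change threshold;
cumulative reporting probability p(reported | FC > x); point-biserial
correlation between reporting and literature-wide popularity; two OLS
reporting models (high-increase mentions ~ α·FC + β·increase mentions + γ,
and increase mentions ~ α·log2FC + β·popularity + γ); and the zero-intercept
trend of mean high-increase mentions against overexpression mention count
(slope = Σxy/Σx², uncentred r²).

**Enrichment.** One-sided Fisher's exact (hypergeometric tail) term
overrepresentation with Bonferroni correction, plus the overlap between the
literature-derived and microarray-derived term lists.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
world (2,000 genes × 4 diseases, 10% of genes truly DE per disease, a
literature that over-reports overexpression 3.5-fold):

```sh
cd analysis
python 01_simulate.py
python 02_extract_statements.py
python 03_differential_expression.py
python 04_reporting_bias.py
python 05_enrichment.py
```

which prints (abridged):

```
extracted 942 statements from 1178 abstracts; precision=1.000 recall=1.000 (vs 942 gold)
DIS01: prior d0=10.0 s0^2=0.248; FC>0: 99 up / 115 down; |FC|>2: 94 up / 108 down
DIS01: literature 78.9% over (3.75:1); microarray FC>0 ratio 0.86:1
pooled: literature 77.2% over, ratio 3.39:1 (configured over-reporting 3.5x)
mean off-diagonal LR+: literature 1.14, microarray FC>0 0.76
DIS01: 0 literature / 4 microarray Bonferroni-significant terms, 0 shared; 10 of the top-20 shared
```

Reading: the extractor recovers the planted statement set exactly; the
moderated-t prior (true d₀ = 10, s₀² = 0.25) is recovered from the data;
microarray up/down calls are balanced while the literature lands at a
3.4:1 over:under ratio — the planted 3.5× reporting preference measured
back from the text. Tables (DE results, LR+ matrices, threshold curves,
enrichment lists) are written under `results/`.

The same stages are available as a CLI (`degbias simulate/extract/de/
compare/enrich/run`) and as plain library calls; see the docstrings in
`src/degbias/`.

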