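# Methods

## Problem setting

Two sources assert that a gene is differentially expressed (DE) in a
disease: free-text statements in abstracts ("TNF was markedly elevated in
psoriatic skin") and two-group expression experiments. The package measures
how the two sources relate — direction preferences, popularity effects,
fold-change sensitivity, and functional-class overlap — on any corpus +
expression data supplied in the documented plain-text formats, and on a
synthetic world with planted ground truth.

## Text mining

Statements are tuples (PMID, gene, disease, Δ) with Δ one of
{high_decrease, decrease, increase, high_increase}. A sentence yields a
statement when it contains a gene mention, a target-disease mention (or an
abbreviation locally defined by a "long form (SHORT)" pattern) and a token
containing one of the trigger substrings {express, production, produce,
transcription, transcribe}. Δ is assigned by the qualifier lexicon
(`src/degbias/data/lexicon.yaml`): case-insensitive, word-bounded,
longest-match-wins, so "greatly elevated" → high_increase beats
"elevated" → increase. Sentences whose only qualifier is in the exclusion
list (altered, aberrant, abnormal, dysregulation, expressed differentially,
modulated, discordant, ...) yield nothing. Redundant (PMID, gene, disease,
Δ) tuples are discarded.

Design choices where the procedure was genuinely open:

* **Sentence splitting** is rule-based (terminal punctuation + whitespace +
  capital/digit, guarded by an abbreviation list, single-capital initials
  like "E. coli", and entity-mention spans). A trained boundary detector
  was deliberately not reimplemented: the downstream statistics, not
  segmentation fidelity, are the subject here.
* **Lexicon content** ships as an editable data file; the four Δ sets and
  the exclusion set must be pairwise disjoint (validated on load).
* **Conflicting qualifiers** of opposite sign in one sentence are resolved
  per gene by adjacency: the nearest qualifier within 8 tokens of the gene
  or a trigger wins; otherwise the pairing is skipped as ambiguous.
* **Ambiguity**: gene mentions resolving to more than three symbols are
  dropped; mentions with 2–3 candidate symbols emit one statement per
  candidate.
* A **negation guard** ("not increased") exists but defaults to off, since
  such phrasing is rare in the synthetic corpus and its real-text frequency
  is unknown.

Extraction quality is reported as set-based precision/recall/F1 over
statement tuples, with the convention precision = 1 for an empty prediction
(and recall = 1 for an empty gold set).

## Differential expression

Input is a feature × sample log2 expression matrix with a disease/normal
labelling (≥ 2 samples per group); normalization and batch assessment are
out of scope and assumed done. Per feature: mean difference (disease −
normal), pooled residual variance s²_g with d_g = n₁+n₂−2 df. The prior
(d₀, s₀²) is estimated by matching moments of log s²_g: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess of Var(e) over
ψ′(d_g/2) identifies ψ′(d₀/2) (Newton inversion of the trigamma; if the
excess is non-positive, d₀ = ∞ with a logged fallback). Then
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g), t = Δ̄/(s̃_g√(1/n₁+1/n₂)) with
d₀+d_g df (normal when d₀ = ∞). The whole path is cross-checked in the test
suite against Bioconductor limma on a shared matrix (t, p, d₀, s₀² agree to
≤0.1%), and against the classical pooled t in the d₀→0 limit.

Degenerate cases: a feature with zero variance and zero difference gets
p = 1; zero variance with a nonzero difference gets |t| = ∞, p → 0; an
all-constant matrix is an error (the prior is unidentifiable).

BH adjustment is the literal step-up definition (verified against a
brute-force oracle and statsmodels). Probe→gene collapsing keeps the probe
with the smallest adjusted p (ties: larger |log2FC|, then lexicographic
probe id); `max_abs_fc` and `mean` rules are available because the
gene-level counting convention in published analyses is typically
unstated. Fold-change filtering uses the signed linear fold change
fc = sign(log2FC)·2^|log2FC|; "FC > 0" admits all significant genes by
sign, a cutoff of 2 means a twofold change in either direction.

## Comparison statistics

* **Over:under ratio** counts unique genes per direction; a gene reported
  both ways counts once per direction (configurable at the call site by
  pre-filtering the sets).
* **LR+** is computed exactly from the 2×2 membership counts over a fixed
  gene universe; zero cells give exactly 0 or ∞ (no continuity
  correction), matching the ratio-of-conditional-frequencies definition.
  A Haldane +0.5 variant exists for interval work. Conditioning on an
  empty or exhaustive set is undefined: an error for the scalar function,
  a flagged-undefined entry in the threshold curves. The universe is a
  parameter everywhere; analyses of real array + literature data should
  pass the intersection of the platform's and the corpus's gene
  vocabularies (n = 17,126 for the GPL570/PubTator pairing).
* **Threshold curves** rebuild the microarray up-set at each log2FC
  threshold and report LR+ both ways plus a one-sided Fisher exact p per
  threshold.
* **Eq. 1 / Eq. 2 reporting models** are ordinary least squares
  (statsmodels) of high-increase mentions on (linear FC, increase
  mentions) and of increase mentions on (log2FC, popularity).
  Popularity enters raw by default — as the printed models do — with a
  log10 option; standardized coefficients are reported alongside so the
  relative influence of the two regressors is scale-free.
* **Zero-intercept trend**: genes are binned by overexpression mention
  count (1–9), y is the mean high-increase count per bin; slope = Σxy/Σx²
  and the *uncentred* r² = 1 − SSres/Σy². The uncentred definition is the
  coherent one for a no-intercept fit (the centred version can be
  negative) and is stated prominently because it changes the numbers.
* **Popularity correlation** is the point-biserial Pearson r between a 0/1
  reporting indicator and the popularity count, two-sided t-based p,
  significance flagged at 0.05.

## Enrichment

One-sided Fisher's exact test (upper hypergeometric tail, scipy) of each
term against the universe, Bonferroni-corrected over the tested terms.
Genes without annotation contribute to an "unclassified" pseudo-term.
The overlap between two term lists is reported in both readings —
intersection of Bonferroni-significant terms and intersection of the
top-20 by p — because published "shared classes" counts rarely say which
was used. No GO-graph propagation or term-redundancy reduction is done;
any flat gene→term map (two-column TSV or GAF subset) is accepted.

## Synthetic world

The generator plants, per disease, a fraction `frac_de` (default 0.1) of
truly DE genes with balanced signs and magnitudes
|log2FC| = lfc_scale·(1.5 + Exp(0.75)) — every true effect clears the
twofold cutoff with margin at the default scale. Expression matrices are
baseline + effect + Gaussian noise on log2, with gene-wise true variances
scaled-inverse-chi-square around noise_sd² (df = var_df, default 10), i.e.
exactly the hierarchical model the moderated t assumes, making the prior
estimable (and estimated: d₀ ≈ 10, s₀² ≈ noise_sd² in the tests).
Popularity is discrete Pareto, floor(u^(−1/exponent)).

Reporting is two-channel: every gene can be reported over- or
under-expressed in every disease with base rate
logit⁻¹(intercept + α·max(±log2FC, 0) + β·log10 popularity), the over
channel multiplied by `over_report_ratio` (base rates capped at
0.95/ratio so the boost never saturates; the expected unique-gene
over:under ratio then equals the configured ratio). Letting non-DE genes
be reported is deliberate: the decoupling between literature and arrays is
the phenomenon under study, and a generator in which only true DEGs can be
reported would make fold change dominate every reporting model by
construction. Reported genes accrue 1 + Binomial(mention_trials − 1, base)
mentions, each phrased as a high qualifier with probability
`high_qualifier_rate`; each mention becomes a gold statement rendered as
one template sentence (gene + disease + trigger + lexicon qualifier) in
its own PubTator abstract, with distractor sentences (no trigger, or an
excluded qualifier) interleaved at rate `distractor_frac`. Note the
generator couples reporting to log10 popularity while the fitted model
uses raw popularity, mirroring the analysis convention; the fitted
coefficients therefore recover the *direction and relative strength* of
the couplings, not their numerical values.

GO annotations assign each background term at rate 0.05 per gene; planted
enriched terms are assigned to up-regulated DE genes at 5× odds
(configurable); every gene keeps ≥ 1 term.

Randomness: one root seed, named per-component child streams
(SeedSequence spawn keys), so identical configs are byte-identical across
runs — asserted via output checksums in the pipeline manifest.

What the synthetic world does **not** emulate: probe-level artifacts,
batch effects, correlated DE across diseases (each disease's DE set is
drawn independently, so cross-disease LR+ values sit near 1 rather than
in the tens as in real literature), naturalistic prose, gene-name
ambiguity beyond the annotation format, and historical publication
dynamics. Passing tests therefore certify the statistical machinery and
the planted-parameter recovery, not the real-world magnitudes of the
biases.

## Problem sizes and numerical choices

Simulation-based tests use 300–5,000 genes and 3–100 seed batteries,
chosen to keep each check statistically decisive (3-SD binomial envelopes,
95%-of-seeds criteria) at desk-scale runtime; the acceptance script uses
5,000-gene worlds averaged over 3 seeds for reporting quantities and a
2,000-gene world for the expression-side quantities. Oracle-equivalence
checks are exhaustive where feasible: all overlap configurations up to
universe 50 for LR+, all hypergeometric tails up to N = 25, 1,000 random
vectors for BH. Tolerances: 1e−12 relative for oracle identities, 1e−10
for OLS vs normal equations, ≤0.1% against limma (different linear-algebra
paths), statistical envelopes elsewhere. Ties in probe collapsing and in
BH sorting use stable mergesort, making outputs order-independent.

## Known limitations

* The qualifier lexicon is seeded with a small phrase set; real-corpus
  recall depends on extending it (the file is data, not code).
* Sentence splitting is approximate; statements whose evidence spans
  sentence boundaries (coreference) are out of scope by design.
* Only abstracts-style short documents are modelled; full text is not.
* The per-disease analyses assume one expression dataset per disease; no
  meta-analysis across series.
* LR+ significance uses Fisher's exact test per threshold without
  multiplicity adjustment across the threshold grid.
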