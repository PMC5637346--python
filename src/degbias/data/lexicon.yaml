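# Gradable-qualifier lexicon for differential-expression statements.
#
# Matching is case-insensitive and longest-match-wins, so "greatly elevated"
# takes precedence over "elevated" when both are present. The four delta sets
# and the exclusion set must be pairwise disjoint (substring overlap is fine).
# Editable: extend the phrase sets to tune recall; the extractor reloads the
# file at run time.

increase_phrases:
  - elevated
  - increased
  - overexpressed
  - over-expressed
  - upregulated
  - up-regulated
  - significantly overexpressed
  - significantly elevated
  - significantly increased
  - increased expression
  - higher expression
  - enhanced expression
  - upregulation
  - up-regulation
  - overexpression

high_increase_phrases:
  - greatly elevated
  - greatly increased
  - markedly increased
  - markedly elevated
  - markedly overexpressed
  - strongly overexpressed
  - strongly upregulated
  - dramatically increased
  - highly overexpressed
  - highly elevated
  - highly upregulated

decrease_phrases:
  - decreased
  - reduced
  - downregulated
  - down-regulated
  - underexpressed
  - under-expressed
  - significantly decreased
  - significantly reduced
  - decreased expression
  - lower expression
  - reduced expression
  - downregulation
  - down-regulation

high_decrease_phrases:
  - greatly decreased
  - greatly reduced
  - markedly decreased
  - markedly reduced
  - strongly downregulated
  - dramatically decreased
  - dramatically reduced
  - highly downregulated

excluded_phrases:
  - altered
  - alteration
  - aberrant
  - abnormal
  - dysregulation
  - dysregulated
  - expressed differentially
  - differentially expressed
  - modulated
  - discordant

trigger_substrings:
  - express
  - production
  - produce
  - transcription
  - transcribe
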