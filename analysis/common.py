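"""Shared study conditions for the numbered analysis scripts.

One synthetic world stands in for the four-disease comparison: a shared
universe of 2,000 genes, 10% truly DE per disease at |log2FC| >= 1.5, and
a literature that over-reports overexpression 3.5-fold. All scripts
re-derive the world deterministically from this config.
"""

from pathlib import Path

from degbias import SyntheticConfig

STUDY = SyntheticConfig(n_genes=2000, n_diseases=4, seed=1)

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"
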