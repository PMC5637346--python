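#!/usr/bin/env python
"""Moderated-t differential expression per disease.

Empirical-Bayes variance shrinkage, BH adjustment, and DEG counts at the
two fold-change cutoffs used throughout ("FC > 0" and "|FC| > 2").
"""

from common import DATA, RESULTS, STUDY

from degbias import ExpressionMatrix, filter_degs, fit_moderated_t
from degbias import io as dio


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for i in range(1, STUDY.n_diseases + 1):
        d = f"DIS{i:02d}"
        matrix, groups = dio.read_expression(DATA / f"expr_{d}.tsv",
                                             DATA / f"groups_{d}.tsv")
        res, params = fit_moderated_t(ExpressionMatrix(matrix, groups))
        res.to_csv(RESULTS / f"de_{d}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        up0, down0 = filter_degs(res, 0.0, 0.05)
        up2, down2 = filter_degs(res, 2.0, 0.05)
        print(f"{d}: prior d0={params.d0:.1f} s0^2={params.s0_sq:.3f}; "
              f"FC>0: {len(up0)} up / {len(down0)} down; "
              f"|FC|>2: {len(up2)} up / {len(down2)} down")


if __name__ == "__main__":
    main()
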