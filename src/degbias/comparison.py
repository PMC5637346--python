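"""Bias statistics comparing literature DEG reports with microarray results.

Implements the quantities used to contrast the two evidence sources:

* over/under reporting ratios among unique DEGs,
* the positive likelihood ratio LR+ of gene-set overlap,

      LR+(A|B) = p(g in A | g in B) / p(g in A | g not in B)

  over a fixed gene universe, within and between diseases and across
  fold-change thresholds,
* cumulative reporting-probability curves p(reported | FC > x),
* point-biserial correlation between reporting and literature popularity,
* two ordinary-least-squares models: high-increase mentions on
  (FC, increase mentions), and increase mentions on (log2FC, popularity),
* the zero-intercept trend of mean high-increase mentions against
  overexpression mention count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .extraction import DEGStatement


@dataclass(frozen=True)
class OverlapCounts:
    """2x2 membership counts over a universe of n_universe genes."""

    n_universe: int
    n_a: int
    n_b: int
    n_ab: int

    def __post_init__(self):
        if self.n_universe <= 0:
            raise ValueError("universe must be non-empty")
        if not (0 <= self.n_ab <= min(self.n_a, self.n_b)):
            raise ValueError("n_ab must be at most min(n_a, n_b)")
        if self.n_a > self.n_universe or self.n_b > self.n_universe:
            raise ValueError("set sizes cannot exceed the universe")
        if self.n_a + self.n_b - self.n_ab > self.n_universe:
            raise ValueError("union exceeds the universe")

    @classmethod
    def from_sets(cls, a: set, b: set, n_universe: int) -> "OverlapCounts":
        return cls(n_universe=n_universe, n_a=len(a), n_b=len(b),
                   n_ab=len(a & b))

    def table(self) -> np.ndarray:
        """2x2 contingency table [[AB, A not-B], [not-A B, not-A not-B]]."""
        return np.array(
            [
                [self.n_ab, self.n_a - self.n_ab],
                [self.n_b - self.n_ab,
                 self.n_universe - self.n_a - self.n_b + self.n_ab],
            ]
        )


@dataclass(frozen=True)
class LinearFit:
    alpha: float
    beta: float
    gamma: float
    p_alpha: float
    p_beta: float
    r_squared: float
    alpha_std: float = float("nan")  # coefficients on z-scored variables
    beta_std: float = float("nan")

    def __post_init__(self):
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared outside [0, 1]")


# ---------------------------------------------------------------------------
# reporting direction ratios
# ---------------------------------------------------------------------------

def direction_sets(
    statements: Iterable[DEGStatement], disease: Optional[str] = None
) -> tuple[set[str], set[str]]:
    """Unique genes reported over / under for one disease (or overall).

    A gene reported in both directions appears in both sets; it then counts
    once per direction in the percentages below.
    """
    over, under = set(), set()
    for s in statements:
        if disease is not None and s.disease != disease:
            continue
        (over if s.delta.sign > 0 else under).add(s.gene)
    return over, under


def over_under_ratio(over, under=None) -> tuple[float, float, float]:
    """Percentages of over- vs under-expressed unique DEGs and their ratio.

    Accepts either two gene sets or an iterable of statements. The ratio is
    over/under, infinity when nothing is reported under.
    """
    if under is None:
        over, under = direction_sets(over)
    n_over, n_under = len(over), len(under)
    total = n_over + n_under
    if total == 0:
        raise ValueError("no directed genes to compare")
    pct_over = 100.0 * n_over / total
    pct_under = 100.0 * n_under / total
    ratio = math.inf if n_under == 0 else n_over / n_under
    return pct_over, pct_under, ratio


# ---------------------------------------------------------------------------
# positive likelihood ratio
# ---------------------------------------------------------------------------

def lr_plus(counts: OverlapCounts) -> float:
    """LR+ = p(A|B) / p(A|not B) from 2x2 membership counts.

    Zero cells are reported exactly: LR+ = inf when A covers all of B's
    overlap potential (n_ab = n_a > 0) and 0 when the overlap is empty while
    A is not. n_a = 0 leaves both conditionals 0 and returns nan.
    Conditioning on an empty or exhaustive B is undefined and raises.
    """
    n, na, nb, nab = counts.n_universe, counts.n_a, counts.n_b, counts.n_ab
    if nb == 0 or nb == n:
        raise ValueError("conditioning set must be a strict non-empty subset")
    if na == 0:
        return float("nan")
    p_given_b = nab / nb
    p_given_not_b = (na - nab) / (n - nb)
    if p_given_not_b == 0:
        return math.inf if nab > 0 else float("nan")
    return p_given_b / p_given_not_b


def lr_plus_haldane(counts: OverlapCounts) -> float:
    """LR+ with a Haldane +0.5 continuity correction on all four cells."""
    n, na, nb, nab = counts.n_universe, counts.n_a, counts.n_b, counts.n_ab
    return ((nab + 0.5) / (nb + 1.0)) / ((na - nab + 0.5) / (n - nb + 1.0))


def pairwise_disease_lr(
    sets: Mapping[str, set[str]], universe_size: int
) -> pd.DataFrame:
    """LR+ matrix across diseases: entry (row Y1, column Y2) = LR+(Y1|Y2).

    Columns condition, rows predict; the matrix is not symmetric. The
    diagonal is infinity by definition (perfect self-containment) and is
    excluded from any summary.
    """
    names = list(sets)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for y1, y2 in itertools.product(names, repeat=2):
        if y1 == y2:
            mat.loc[y1, y2] = math.inf
            continue
        mat.loc[y1, y2] = lr_plus(
            OverlapCounts.from_sets(sets[y1], sets[y2], universe_size)
        )
    return mat


def multi_disease_overlap(
    sets: Mapping[str, set[str]], universe_size: int
) -> dict:
    """Gene counts by number of diseases and k-wise LR+ summaries.

    For each k, LR+ of membership in one disease given joint membership in
    a (k-1)-subset of the others, over all arrangements; entries whose
    conditioning intersection is empty or exhaustive are dropped as
    undefined. Reports min/mean/max per k.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two diseases")
    all_genes = set().union(*sets.values())
    membership = {g: sum(g in sets[d] for d in names) for g in all_genes}
    exact = {k: sum(1 for v in membership.values() if v == k)
             for k in range(1, len(names) + 1)}
    at_least = {k: sum(1 for v in membership.values() if v >= k)
                for k in range(1, len(names) + 1)}
    kwise: dict[int, dict] = {}
    for k in range(2, len(names) + 1):
        values = []
        for target in names:
            others = [d for d in names if d != target]
            for cond in itertools.combinations(others, k - 1):
                b = set.intersection(*(sets[d] for d in cond))
                if not b or len(b) >= universe_size:
                    continue
                values.append(
                    lr_plus(OverlapCounts.from_sets(sets[target], b,
                                                    universe_size))
                )
        finite = [v for v in values if math.isfinite(v)]
        kwise[k] = {
            "values": values,
            "min": min(values) if values else float("nan"),
            "max": max(values) if values else float("nan"),
            "mean": float(np.mean(finite)) if finite else float("nan"),
        }
    return {"exact_counts": exact, "at_least_counts": at_least,
            "kwise_lr": kwise}


def source_lr_vs_threshold(
    lit_set: set[str],
    de_table: pd.DataFrame,
    thresholds: Sequence[float],
    universe_size: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """LR+ between sources as a function of the log2FC threshold.

    At each threshold x the microarray up-set is {gene: p_adj < alpha and
    log2fc > x}. Two curves: LR+(microarray | literature) and
    LR+(literature | microarray); per-threshold significance is Fisher's
    exact test on the 2x2 membership table. Thresholds where the
    conditioning set is empty (or the whole universe) are flagged undefined
    rather than raised.
    """
    rows = []
    sig = de_table[de_table["p_adj"] < alpha]
    for x in thresholds:
        micro = set(sig.loc[sig["log2fc"] > x, "feature_id"].astype(str))
        row = {"threshold": float(x), "n_microarray": len(micro),
               "n_literature": len(lit_set)}
        for label, a, b in (
            ("micro_given_lit", micro, lit_set),
            ("lit_given_micro", lit_set, micro),
        ):
            if len(b) == 0 or len(b) >= universe_size:
                row[f"lr_{label}"] = float("nan")
                row[f"defined_{label}"] = False
                row[f"fisher_p_{label}"] = float("nan")
            else:
                counts = OverlapCounts.from_sets(a, b, universe_size)
                row[f"lr_{label}"] = lr_plus(counts)
                row[f"defined_{label}"] = True
                row[f"fisher_p_{label}"] = float(
                    stats.fisher_exact(counts.table(),
                                       alternative="greater")[1]
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cumulative reporting probability
# ---------------------------------------------------------------------------

def cumulative_reporting_prob(
    lit_set: set[str],
    de_results: pd.DataFrame,
    thresholds: Sequence[float],
    min_denominator: int = 10,
) -> pd.DataFrame:
    """p(gene reported | FC > x) over a grid of fold-change thresholds.

    Points whose denominator falls below ``min_denominator`` are flagged
    unstable but still reported.
    """
    fc = de_results["fc"].to_numpy(dtype=float)
    genes = de_results["feature_id"].astype(str).to_numpy()
    reported = np.isin(genes, list(lit_set))
    rows = []
    any_nonempty = False
    for x in thresholds:
        mask = fc > x
        denom = int(mask.sum())
        any_nonempty = any_nonempty or denom > 0
        prob = float(reported[mask].sum() / denom) if denom else float("nan")
        rows.append({"threshold": float(x), "probability": prob,
                     "n": denom, "stable": denom >= min_denominator})
    if not any_nonempty:
        raise ValueError("no genes above any threshold")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# popularity correlation
# ---------------------------------------------------------------------------

def popularity_correlation(
    indicator: Sequence[int], popularity: Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Point-biserial Pearson r between a 0/1 reporting indicator and
    popularity, with a two-sided t-based p and a significance flag."""
    ind = np.asarray(indicator, dtype=float)
    pop = np.asarray(popularity, dtype=float)
    if ind.size < 3:
        raise ValueError("need at least 3 genes")
    if np.all(ind == ind[0]):
        raise ValueError("indicator is constant; correlation undefined")
    r, p = stats.pearsonr(ind, pop)
    return float(r), float(p), bool(p < alpha)


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------

def _ols_fit(y: np.ndarray, x1: np.ndarray, x2: np.ndarray,
             names: tuple[str, str]) -> LinearFit:
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        const = names[0] if np.ptp(x1) == 0 else names[1]
        raise ValueError(f"degenerate regressor: {const} is constant")
    if abs(np.corrcoef(x1, x2)[0, 1]) > 1 - 1e-12:
        raise ValueError(f"collinear regressors: {names[0]} and {names[1]}")
    X = sm.add_constant(np.column_stack([x1, x2]))
    fit = sm.OLS(y, X).fit()
    sy = y.std(ddof=1)
    return LinearFit(
        alpha=float(fit.params[1]),
        beta=float(fit.params[2]),
        gamma=float(fit.params[0]),
        p_alpha=float(fit.pvalues[1]),
        p_beta=float(fit.pvalues[2]),
        r_squared=float(max(0.0, min(1.0, fit.rsquared))),
        alpha_std=float(fit.params[1] * x1.std(ddof=1) / sy) if sy > 0 else float("nan"),
        beta_std=float(fit.params[2] * x2.std(ddof=1) / sy) if sy > 0 else float("nan"),
    )


def fit_eq1(table: pd.DataFrame) -> LinearFit:
    """OLS of high-increase mentions on (linear FC, increase mentions).

    ``table`` needs columns high_increase_mentions, fc, increase_mentions.
    The fold change enters on the linear scale by default.
    """
    t = table.dropna(subset=["high_increase_mentions", "fc",
                             "increase_mentions"])
    if len(t) < 3:
        raise ValueError("need at least 3 genes")
    return _ols_fit(
        t["high_increase_mentions"].to_numpy(float),
        t["fc"].to_numpy(float),
        t["increase_mentions"].to_numpy(float),
        ("fc", "increase_mentions"),
    )


def fit_eq2(table: pd.DataFrame, log_popularity: bool = False) -> LinearFit:
    """OLS of increase mentions on (log2FC, popularity).

    Popularity enters raw by default; ``log_popularity=True`` uses log10,
    which tames the heavy tail but changes the coefficient scale.
    """
    t = table.dropna(subset=["increase_mentions", "log2fc", "popularity"])
    if len(t) < 3:
        raise ValueError("need at least 3 genes")
    pop = t["popularity"].to_numpy(float)
    if log_popularity:
        pop = np.log10(np.maximum(pop, 1.0))
    return _ols_fit(
        t["increase_mentions"].to_numpy(float),
        t["log2fc"].to_numpy(float),
        pop,
        ("log2fc", "popularity"),
    )


# ---------------------------------------------------------------------------
# zero-intercept trend (mention-count bins)
# ---------------------------------------------------------------------------

def zero_intercept_trend(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Least-squares line through the origin and its uncentred r^2.

    slope = sum(x*y) / sum(x^2); r^2 = 1 - SS_res / sum(y^2). The uncentred
    definition is the natural one for a no-intercept fit (the centred r^2
    can be negative there) and is what the headline 0.21 / 0.89 trend uses.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or np.all(x == 0):
        raise ValueError("x must contain a nonzero value")
    slope = float(np.sum(x * y) / np.sum(x * x))
    ss_tot = float(np.sum(y * y))
    if ss_tot == 0:
        return slope, 1.0
    r2 = 1.0 - float(np.sum((y - slope * x) ** 2)) / ss_tot
    return slope, float(r2)


def bin_mentions_for_trend(
    table: pd.DataFrame, max_mentions: int = 9
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate genes by overexpression mention count for the trend fit.

    Overexpression mentions = increase + high-increase mentions. For each
    count 1..max_mentions with at least one gene, y is the mean number of
    high-increase mentions over the genes in the bin.
    """
    total = (table["increase_mentions"] + table["high_increase_mentions"]).to_numpy()
    high = table["high_increase_mentions"].to_numpy(float)
    xs, ys = [], []
    for k in range(1, max_mentions + 1):
        mask = total == k
        if mask.any():
            xs.append(float(k))
            ys.append(float(high[mask].mean()))
    return np.asarray(xs), np.asarray(ys)


def mention_count_table(
    statements: Iterable[DEGStatement],
    disease: str,
    de_table: Optional[pd.DataFrame] = None,
    popularity: Optional[pd.Series] = None,
    universe: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene mention counts joined with DE results and popularity.

    Counts deduplicated statements: a gene's increase_mentions is the number
    of distinct (pmid, delta=increase) statements about it for ``disease``,
    and likewise for the other three delta values.
    """
    from .extraction import DeltaValue

    counts: dict[str, dict[str, int]] = {}
    for s in statements:
        if s.disease != disease:
            continue
        row = counts.setdefault(
            s.gene,
            {"increase_mentions": 0, "high_increase_mentions": 0,
             "decrease_mentions": 0, "high_decrease_mentions": 0},
        )
        row[s.delta.label + "_mentions"] += 1
    genes = list(universe) if universe is not None else sorted(counts)
    df = pd.DataFrame(
        [
            {
                "gene": g,
                **counts.get(
                    g,
                    {"increase_mentions": 0, "high_increase_mentions": 0,
                     "decrease_mentions": 0, "high_decrease_mentions": 0},
                ),
            }
            for g in genes
        ]
    ).set_index("gene")
    if de_table is not None:
        de = de_table.set_index(de_table["feature_id"].astype(str))
        df["log2fc"] = de["log2fc"].reindex(df.index)
        df["fc"] = de["fc"].reindex(df.index)
    if popularity is not None:
        df["popularity"] = popularity.reindex(df.index)
    return df.reset_index()
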