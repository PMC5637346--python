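"""Two-group differential expression with empirical-Bayes variance shrinkage.

Per-gene two-sample statistics on log2 expression, with gene-wise variances
shrunk toward a common prior estimated by moment matching on the log
variances (the standard moderated-t construction): the pooled residual
variance s_g^2 with d_g degrees of freedom is combined with a prior
(d0, s0^2) into

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_mod = log2fc / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a t
distribution with d0 + d_g degrees of freedom. Benjamini-Hochberg step-up
adjustment, probe-to-gene collapsing and fold-change filtering follow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

DE_COLUMNS = ["feature_id", "log2fc", "fc", "t_mod", "df_total", "p", "p_adj"]


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: d0 degrees of freedom, s0^2 prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (may be inf)")
        if not (self.s0_sq > 0 and math.isfinite(self.s0_sq)):
            raise ValueError("s0_sq must be positive and finite")


@dataclass
class ExpressionMatrix:
    """Feature-by-sample log2 expression with a disease/normal labelling."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> "disease" | "normal"

    def __post_init__(self):
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {"disease", "normal"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        counts = self.groups.value_counts()
        if counts.get("disease", 0) < 2 or counts.get("normal", 0) < 2:
            raise ValueError("need at least 2 samples per group")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Monotone decreasing target; the iteration below (on the scale suggested
    by the asymptotic trigamma(y) ~ 1/y) converges from y0 = 0.5 + 1/x for
    all positive x.
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        # Newton step on 1/trigamma(y) - 1/x, which is nearly linear in y
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif / y) < tol:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Moment-match (d0, s0^2) from log sample variances.

    e_g = log(s_g^2) - digamma(d_g/2) + log(d_g/2) is an unbiased estimate
    of log(sigma_g^2) whose excess variance over trigamma(d_g/2) identifies
    trigamma(d0/2). Non-positive excess variance (all variances essentially
    equal) yields d0 = inf.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all features have zero variance; prior undefined")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    if len(e) < 2:
        return ModerationParams(d0=math.inf, s0_sq=math.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return ModerationParams(d0=math.inf, s0_sq=math.exp(e_mean))
    half_d0 = trigamma_inverse(e_var)
    if not math.isfinite(half_d0):
        warnings.warn("trigamma inversion failed; falling back to d0=inf")
        return ModerationParams(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * half_d0
    s0_sq = math.exp(
        e_mean + special.digamma(half_d0) - math.log(half_d0)
    )
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: sign(log2fc) * 2**|log2fc|.

    The convention keeps over/under symmetry: log2fc = -1 maps to -2 rather
    than 0.5, so "|FC| > 2" is |log2fc| > 1 in either direction.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    return np.sign(log2fc) * np.exp2(np.abs(log2fc))


def fit_moderated_t(
    matrix: ExpressionMatrix,
    params: Optional[ModerationParams] = None,
    moderate: bool = True,
) -> tuple[pd.DataFrame, ModerationParams]:
    """Moderated two-sample t per feature (disease minus normal).

    ``params`` overrides the estimated prior; ``moderate=False`` is the
    classical pooled-variance t (equivalent to d0 = 0). Features with zero
    pooled variance get the pure prior variance; if additionally their mean
    difference is zero, p = 1 by convention.
    """
    vals = matrix.values.to_numpy(dtype=float)
    d_mask = (matrix.groups == "disease").to_numpy()
    n1, n2 = int(d_mask.sum()), int((~d_mask).sum())
    x1, x2 = vals[:, d_mask], vals[:, ~d_mask]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    df_res = float(n1 + n2 - 2)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_res

    if not moderate:
        fitted = ModerationParams(d0=np.nextafter(0, 1), s0_sq=1.0)
        post_var = s2.copy()
        df_total = np.full_like(s2, df_res)
    else:
        fitted = params if params is not None else estimate_prior(s2, df_res)
        if math.isinf(fitted.d0):
            post_var = np.full_like(s2, fitted.s0_sq)
            df_total = np.full_like(s2, math.inf)
        else:
            post_var = (fitted.d0 * fitted.s0_sq + df_res * s2) / (
                fitted.d0 + df_res
            )
            df_total = np.full_like(s2, fitted.d0 + df_res)

    se = np.sqrt(post_var * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.empty_like(t)
    finite_df = np.isfinite(df_total)
    p[finite_df] = 2.0 * stats.t.sf(np.abs(t[finite_df]), df_total[finite_df])
    p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t[~finite_df]))
    # degenerate features: no variance and no difference
    dead = (se == 0) & (diff == 0)
    t[dead] = 0.0
    p[dead] = 1.0
    sign_conflict = (se == 0) & (diff != 0)
    t[sign_conflict] = np.sign(diff[sign_conflict]) * np.inf
    p[sign_conflict] = 0.0
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    out = pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "log2fc": diff,
            "fc": signed_fold_change(diff),
            "t_mod": t,
            "df_total": df_total,
            "p": p,
            "p_adj": bh_adjust(p),
        }
    )
    return out, fitted


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, mapped back to
    the input order. Inputs must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("expected a non-empty 1-d array of p-values")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adj, 1.0)
    return out


def collapse_probes(
    results: pd.DataFrame,
    probe2gene: Mapping[str, str],
    rule: str = "min_padj",
) -> pd.DataFrame:
    """Collapse probe-level rows to one row per gene.

    Default rule keeps the probe with the smallest adjusted p-value,
    breaking ties by larger |log2fc| then lexicographic probe id.
    Alternatives: ``max_abs_fc`` (largest |log2fc| wins) and ``mean``
    (average log2fc/recomputed fc, min p, min p_adj). Unmapped probes are
    dropped.
    """
    df = results.copy()
    df["gene"] = df["feature_id"].map(lambda f: probe2gene.get(str(f)))
    df = df[df["gene"].notna()]
    if rule == "mean":
        grouped = df.groupby("gene", sort=True)
        out = grouped.agg(
            log2fc=("log2fc", "mean"),
            t_mod=("t_mod", "mean"),
            df_total=("df_total", "mean"),
            p=("p", "min"),
            p_adj=("p_adj", "min"),
        ).reset_index()
        out["fc"] = signed_fold_change(out["log2fc"].to_numpy())
        out["feature_id"] = out["gene"]
        return out[["feature_id", *DE_COLUMNS[1:], "gene"]].rename(
            columns={"gene": "gene_id"}
        ).rename(columns={"gene_id": "gene"})
    if rule == "min_padj":
        keys = ["p_adj", "neg_abs_fc", "feature_id"]
        df["neg_abs_fc"] = -df["log2fc"].abs()
    elif rule == "max_abs_fc":
        keys = ["neg_abs_fc", "p_adj", "feature_id"]
        df["neg_abs_fc"] = -df["log2fc"].abs()
    else:
        raise ValueError(f"unknown collapse rule: {rule}")
    df = df.sort_values(keys, kind="mergesort")
    out = df.drop_duplicates(subset="gene", keep="first").copy()
    out = out.sort_values("gene").reset_index(drop=True)
    out["probe_id"] = out["feature_id"]
    out["feature_id"] = out["gene"]
    return out[["feature_id", *DE_COLUMNS[1:], "gene", "probe_id"]]


def filter_degs(
    results: pd.DataFrame, fc_cutoff: float = 0.0, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Significant up/down gene sets at a signed linear fold-change cutoff.

    up = {gene: p_adj < alpha and fc > fc_cutoff}; down symmetric with
    fc < -fc_cutoff. ``fc_cutoff=0`` admits every significant gene by the
    sign of its fold change ("FC > 0"); a cutoff of 2 is a twofold change
    (|log2fc| > 1).
    """
    if fc_cutoff < 0:
        raise ValueError("fc_cutoff must be non-negative")
    sig = results[results["p_adj"] < alpha]
    up = set(sig.loc[sig["fc"] > fc_cutoff, "feature_id"].astype(str))
    down = set(sig.loc[sig["fc"] < -fc_cutoff, "feature_id"].astype(str))
    return up, down
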