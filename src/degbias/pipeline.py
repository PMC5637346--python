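"""End-to-end orchestration: extract -> DE -> compare -> enrich.

A single run configuration (synthetic world or user-supplied files) drives
every stage and produces a machine-readable report with nine sections plus
a manifest recording the config hash, seed, package version and a checksum
for every file written, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .comparison import (
    bin_mentions_for_trend,
    cumulative_reporting_prob,
    direction_sets,
    fit_eq1,
    fit_eq2,
    mention_count_table,
    multi_disease_overlap,
    over_under_ratio,
    pairwise_disease_lr,
    popularity_correlation,
    source_lr_vs_threshold,
    zero_intercept_trend,
)
from .de import ExpressionMatrix, collapse_probes, filter_degs, fit_moderated_t
from .enrichment import fisher_overrep, top_k_overlap
from .extraction import evaluate_extraction, extract_statements
from .synthetic import (
    SyntheticConfig,
    generate_corpus,
    generate_expression,
    generate_go_annotations,
    make_truth,
)

log = logging.getLogger("degbias.pipeline")

REPORT_SECTIONS = (
    "extraction",
    "differential_expression",
    "over_under_ratios",
    "high_increase_trend",
    "cumulative_reporting",
    "popularity_correlation",
    "linear_models",
    "lr_overlap",
    "enrichment",
)

DEFAULT_FC_GRID = (0.0, 2.0)
DEFAULT_LOG2FC_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)
DEFAULT_CUMULATIVE_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 4.0)


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``synthetic`` or the real-data paths must be provided.
    For real data, ``expression`` maps each disease to a (matrix TSV,
    groups TSV) pair and ``corpus`` points at a PubTator file.
    """

    outdir: Path
    synthetic: Optional[SyntheticConfig] = None
    corpus: Optional[Path] = None
    expression: Optional[dict[str, tuple[Path, Path]]] = None
    popularity: Optional[Path] = None
    annotations: Optional[Path] = None
    probe_map: Optional[Path] = None
    universe: Optional[Path] = None
    diseases: Optional[list[str]] = None
    alpha: float = 0.05
    fc_grid: Sequence[float] = DEFAULT_FC_GRID
    log2fc_grid: Sequence[float] = DEFAULT_LOG2FC_GRID
    cumulative_grid: Sequence[float] = DEFAULT_CUMULATIVE_GRID
    write_matrices: bool = False

    def validate(self) -> None:
        if self.synthetic is None:
            missing = [
                name
                for name, value in (
                    ("corpus (text_extraction stage)", self.corpus),
                    ("expression (differential-expression stage)", self.expression),
                    ("popularity (comparison stage)", self.popularity),
                    ("annotations (enrichment stage)", self.annotations),
                )
                if value is None
            ]
            if missing:
                raise ValueError(
                    "config is neither synthetic nor complete real-data; "
                    "missing inputs: " + "; ".join(missing)
                )
            for p in [self.corpus, self.popularity, self.annotations,
                      self.probe_map, self.universe]:
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)
            for matrix, groups in self.expression.values():
                for p in (matrix, groups):
                    if not Path(p).exists():
                        raise FileNotFoundError(p)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_json_safe(v) for v in sorted(obj) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if np.isnan(f):
            return "nan"
        if np.isinf(f):
            return "inf" if f > 0 else "-inf"
        return f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _json_safe(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _json_safe(obj.to_dict())
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _linear_fit_dict(fit) -> dict:
    return {
        "alpha": fit.alpha, "beta": fit.beta, "gamma": fit.gamma,
        "p_alpha": fit.p_alpha, "p_beta": fit.p_beta,
        "r_squared": fit.r_squared,
        "alpha_std": fit.alpha_std, "beta_std": fit.beta_std,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write tables, report.json and manifest.json.

    Returns the report as a dict with the sections in ``REPORT_SECTIONS``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # ---- stage 0: inputs --------------------------------------------------
    if config.synthetic is not None:
        syn = config.synthetic
        truth = make_truth(syn)
        docs = generate_corpus(syn, truth)
        diseases = truth.diseases
        universe = truth.genes
        popularity = truth.popularity
        annotations = generate_go_annotations(syn, truth)
        expression = {
            d: generate_expression(syn, d, truth)[:2] for d in diseases
        }
        probe_map = None
        corpus_path = outdir / "corpus.pubtator"
        dio.write_pubtator(docs, corpus_path)
        written.append(corpus_path)
        pop_path = outdir / "popularity.tsv"
        dio.write_popularity(popularity, pop_path)
        written.append(pop_path)
        ann_path = outdir / "annotations.tsv"
        dio.write_gene_terms(annotations, ann_path)
        written.append(ann_path)
        seed = syn.seed
        config_fingerprint = json.dumps(syn.to_dict(), sort_keys=True)
    else:
        docs = dio.read_pubtator(config.corpus)
        expression = {
            d: dio.read_expression(m, g)
            for d, (m, g) in config.expression.items()
        }
        diseases = config.diseases or sorted(expression)
        popularity = dio.read_popularity(config.popularity)
        annotations = dio.read_gene_terms(config.annotations)
        probe_map = (
            dio.read_probe_map(config.probe_map) if config.probe_map else None
        )
        truth = None
        seed = None
        config_fingerprint = json.dumps(
            {k: str(v) for k, v in vars(config).items()}, sort_keys=True
        )
        universe = (
            dio.read_universe(config.universe) if config.universe else None
        )

    # ---- stage 1: extraction ---------------------------------------------
    statements = extract_statements(docs, target_diseases=set(diseases))
    log.info("extracted %d statements from %d documents",
             len(statements), len(docs))
    doc_map = {d.pmid: d for d in docs}
    st_path = outdir / "statements.tsv"
    dio.write_statements(statements, st_path, corpus=doc_map)
    written.append(st_path)
    extraction_section = {
        "n_documents": len(docs),
        "n_statements": len(statements),
        "per_disease": {
            d: sum(1 for s in statements if s.disease == d) for d in diseases
        },
    }
    if truth is not None:
        extraction_section["metrics_vs_gold"] = evaluate_extraction(
            statements, truth.gold_statements
        )

    # ---- stage 2: differential expression ---------------------------------
    de_tables: dict[str, pd.DataFrame] = {}
    de_section = {}
    for d in diseases:
        matrix, groups = expression[d]
        if universe is None:
            universe = [str(i) for i in matrix.index]
        results, params = fit_moderated_t(ExpressionMatrix(matrix, groups))
        if probe_map is not None:
            results = collapse_probes(results, probe_map)
        de_tables[d] = results
        path = outdir / f"de_{d}.tsv"
        results.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        if config.write_matrices:
            mp, gp = outdir / f"expr_{d}.tsv", outdir / f"groups_{d}.tsv"
            dio.write_expression(matrix, groups, mp, gp)
            written.extend([mp, gp])
        counts = {}
        for cutoff in config.fc_grid:
            up, down = filter_degs(results, cutoff, config.alpha)
            counts[f"fc_gt_{cutoff:g}"] = {"up": len(up), "down": len(down)}
        de_section[d] = {
            "d0": params.d0, "s0_sq": params.s0_sq, "deg_counts": counts,
        }
    n_universe = len(universe)
    universe_set = set(universe)

    # ---- stage 3: over/under ratios ---------------------------------------
    lit_over: dict[str, set[str]] = {}
    lit_under: dict[str, set[str]] = {}
    ratios = {}
    for d in diseases:
        over, under = direction_sets(statements, d)
        lit_over[d], lit_under[d] = over & universe_set, under & universe_set
        entry = {}
        if over or under:
            po, pu, r = over_under_ratio(over, under)
            entry["literature"] = {"pct_over": po, "pct_under": pu,
                                   "ratio": r}
        for cutoff in config.fc_grid:
            up, down = filter_degs(de_tables[d], cutoff, config.alpha)
            if up or down:
                po, pu, r = over_under_ratio(up, down)
                entry[f"microarray_fc_gt_{cutoff:g}"] = {
                    "pct_over": po, "pct_under": pu, "ratio": r,
                }
        ratios[d] = entry
    over_all, under_all = direction_sets(statements)
    if over_all or under_all:
        po, pu, r = over_under_ratio(over_all, under_all)
        ratios["pooled"] = {
            "literature": {"pct_over": po, "pct_under": pu, "ratio": r}
        }

    # ---- stage 4: high-increase trend --------------------------------------
    mention_tables = {
        d: mention_count_table(
            statements, d, de_table=de_tables[d], popularity=popularity,
            universe=universe,
        )
        for d in diseases
    }
    pooled = pd.concat(mention_tables.values(), ignore_index=True)
    xs, ys = bin_mentions_for_trend(pooled)
    if len(xs):
        slope, r2 = zero_intercept_trend(xs, ys)
        trend_section = {"slope": slope, "r_squared": r2,
                         "bins": [{"mentions": x, "mean_high": y}
                                  for x, y in zip(xs, ys)]}
    else:
        trend_section = {"slope": "nan", "r_squared": "nan", "bins": []}

    # ---- stage 5: cumulative reporting curves ------------------------------
    cumulative_section = {}
    for d in diseases:
        curve = cumulative_reporting_prob(
            lit_over[d], de_tables[d], config.cumulative_grid
        )
        cumulative_section[d] = curve
        path = outdir / f"cumulative_{d}.tsv"
        curve.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    # ---- stage 6: popularity correlations ----------------------------------
    pop_vec = popularity.reindex(universe).fillna(1).to_numpy(float)
    pop_section = {}
    for d in diseases:
        entry = {}
        lit_ind = np.array([g in lit_over[d] for g in universe], dtype=int)
        if 0 < lit_ind.sum() < len(lit_ind):
            r, p, sig = popularity_correlation(lit_ind, pop_vec)
            entry["literature"] = {"r": r, "p": p, "significant": sig}
        for cutoff in config.fc_grid:
            up, _ = filter_degs(de_tables[d], cutoff, config.alpha)
            ind = np.array([g in up for g in universe], dtype=int)
            if 0 < ind.sum() < len(ind):
                r, p, sig = popularity_correlation(ind, pop_vec)
                entry[f"microarray_fc_gt_{cutoff:g}"] = {
                    "r": r, "p": p, "significant": sig,
                }
        pop_section[d] = entry

    # ---- stage 7: linear models --------------------------------------------
    models_section = {}
    for d in diseases:
        table = mention_tables[d]
        entry = {}
        mentioned = table[
            (table["increase_mentions"] + table["high_increase_mentions"]) > 0
        ]
        try:
            entry["eq1"] = _linear_fit_dict(fit_eq1(mentioned))
        except ValueError as exc:
            entry["eq1"] = {"error": str(exc)}
        try:
            entry["eq2"] = _linear_fit_dict(fit_eq2(table))
        except ValueError as exc:
            entry["eq2"] = {"error": str(exc)}
        models_section[d] = entry

    # ---- stage 8: LR+ overlap ----------------------------------------------
    lr_section = {}
    lit_sets = {d: lit_over[d] for d in diseases}
    if all(0 < len(s) < n_universe for s in lit_sets.values()):
        lr_section["literature"] = pairwise_disease_lr(lit_sets, n_universe)
        lr_section["literature_multi"] = multi_disease_overlap(
            lit_sets, n_universe
        )
    for cutoff in config.fc_grid:
        micro_sets = {
            d: filter_degs(de_tables[d], cutoff, config.alpha)[0]
            for d in diseases
        }
        if all(0 < len(s) < n_universe for s in micro_sets.values()):
            key = f"microarray_fc_gt_{cutoff:g}"
            lr_section[key] = pairwise_disease_lr(micro_sets, n_universe)
            lr_section[key + "_multi"] = multi_disease_overlap(
                micro_sets, n_universe
            )
    source_curves = {}
    for d in diseases:
        curve = source_lr_vs_threshold(
            lit_over[d], de_tables[d], config.log2fc_grid, n_universe,
            config.alpha,
        )
        source_curves[d] = curve
        path = outdir / f"source_lr_{d}.tsv"
        curve.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
    lr_section["source_vs_threshold"] = source_curves

    # ---- stage 9: enrichment -----------------------------------------------
    enrich_section = {}
    for d in diseases:
        entry = {}
        micro_up, _ = filter_degs(de_tables[d], config.fc_grid[0],
                                  config.alpha)
        rows = {}
        for label, gene_set in (("literature", lit_over[d]),
                                ("microarray", micro_up & universe_set)):
            if gene_set:
                rows[label] = fisher_overrep(
                    gene_set & universe_set, universe_set, annotations
                )
                path = outdir / f"enrichment_{d}_{label}.tsv"
                rows[label].to_csv(path, sep="\t", index=False,
                                   float_format="%.6g")
                written.append(path)
        if "literature" in rows and "microarray" in rows:
            entry["overlap"] = top_k_overlap(
                rows["literature"], rows["microarray"], k=20,
                alpha=config.alpha,
            )
        entry["n_terms_tested"] = int(
            len(rows["literature"]) if "literature" in rows else 0
        )
        enrich_section[d] = entry

    report = {
        "extraction": extraction_section,
        "differential_expression": de_section,
        "over_under_ratios": ratios,
        "high_increase_trend": trend_section,
        "cumulative_reporting": cumulative_section,
        "popularity_correlation": pop_section,
        "linear_models": models_section,
        "lr_overlap": lr_section,
        "enrichment": enrich_section,
    }
    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(_json_safe(report), indent=2, sort_keys=True) + "\n"
    )
    written.append(report_path)

    from . import __version__

    manifest = {
        "config_sha256": hashlib.sha256(
            config_fingerprint.encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "outputs": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return report
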