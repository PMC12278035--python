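"""End-to-end analysis pipeline: ingest -> features -> selection -> evaluation.

Stages, in order:

1. read labelled sequences (two FASTA files, or the synthetic generator)
   and drop those shorter than the minimum length;
2. extract the 188D descriptor block and, optionally, the cross-covariance
   block, into one deterministic feature matrix;
3. rank features by MRMD and (optionally) choose a compact subset by
   forward cross-validated evaluation;
4. evaluate: random forest on the full matrix, random forest on the
   selected subset, logistic regression on each of the top-ranked single
   features;
5. report the best single discriminative feature by canonical name and
   export its per-class values for scatter inspection.

All randomness (fold shuffling, synthetic data) flows from one master
seed, and reports contain no timestamps, so a run is byte-reproducible
from its config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .crosscov import DEFAULT_MAX_LAG, CrossCovarianceExtractor, cc_feature_names
from .ctd import CTD188Extractor, feature_names_188
from .evaluation import cross_validate, single_feature_model
from .matrix import FeatureMatrix
from .mrmd import rank_features, select_subset
from .properties import (DEFAULT_GROUPINGS, DEFAULT_INDEX_TABLES,
                         load_groupings, load_index_tables)
from .seqio import (ACID, ALKALINE, LABEL_TO_INT, filter_min_length,
                    read_fasta)
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, resolvable from one YAML file."""

    acid_fasta: str | None = None
    alkaline_fasta: str | None = None
    synthetic: SyntheticSpec | None = None
    min_length: int = 100
    strict: bool = True
    groupings_file: str | None = None
    cc_tables_file: str | None = None
    cc_max_lag: int = DEFAULT_MAX_LAG
    use_cc: bool = True
    selection: str = "mrmd"          # "mrmd" or "none"
    cv_folds: int = 10
    n_top_single: int = 5            # single-feature models evaluated
    seed: int = 1
    outdir: str = "enzyph_out"

    def __post_init__(self) -> None:
        have_files = self.acid_fasta is not None and self.alkaline_fasta is not None
        if not have_files and self.synthetic is None:
            raise ValueError("config needs either two FASTA paths or a synthetic spec")
        if self.selection not in ("mrmd", "none"):
            raise ValueError("selection must be 'mrmd' or 'none'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if "length_range" in synth:
                synth["length_range"] = tuple(synth["length_range"])
            synth = SyntheticSpec(**synth)
        return cls(synthetic=synth, **raw)


def load_records(config: PipelineConfig):
    """Stage 1: labelled records, minimum-length filtered."""
    if config.acid_fasta is not None and config.alkaline_fasta is not None:
        records = read_fasta(config.acid_fasta, ACID, strict=config.strict)
        records += read_fasta(config.alkaline_fasta, ALKALINE, strict=config.strict)
    else:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        records = generate_dataset(spec)
    return filter_min_length(records, config.min_length)


def build_feature_matrix(records, groupings=DEFAULT_GROUPINGS,
                         tables=DEFAULT_INDEX_TABLES,
                         max_lag: int = DEFAULT_MAX_LAG,
                         use_cc: bool = True) -> FeatureMatrix:
    """Stage 2: 188D block (plus CC block) for labelled records."""
    seqs = [r.sequence for r in records]
    X = CTD188Extractor(groupings).fit(seqs).transform(seqs)
    names = feature_names_188(groupings)
    if use_cc:
        Xcc = CrossCovarianceExtractor(tables, max_lag).fit(seqs).transform(seqs)
        X = np.hstack([X, Xcc])
        names = names + cc_feature_names(tables, max_lag)
    labels = np.array([LABEL_TO_INT[r.label] for r in records])
    return FeatureMatrix([r.id for r in records], labels, X, names)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the run's reports under ``config.outdir``.

    Outputs: ``features.csv`` (full matrix), ``mrmd_ranking.tsv``,
    ``eval_full_rf.json``, ``eval_selected_rf.json`` (selection on),
    ``eval_single_logistic.json`` (one entry per evaluated single feature),
    ``key_feature.json`` and ``key_feature_values.csv``, plus a combined
    ``report.json``.  Returns the report dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    groupings = (load_groupings(config.groupings_file)
                 if config.groupings_file else DEFAULT_GROUPINGS)
    tables = (load_index_tables(config.cc_tables_file)
              if config.cc_tables_file else DEFAULT_INDEX_TABLES)

    records = load_records(config)
    if not records:
        raise RuntimeError("ingest stage: no sequences left after filtering")
    logger.info("ingest: %d sequences", len(records))

    fm = build_feature_matrix(records, groupings, tables,
                              config.cc_max_lag, config.use_cc)
    fm.to_csv(outdir / "features.csv")
    logger.info("features: %d x %d matrix", fm.n_samples, fm.n_features)

    report: dict = {
        "n_sequences": fm.n_samples,
        "n_acid": int((fm.labels == 0).sum()),
        "n_alkaline": int((fm.labels == 1).sum()),
        "dimensions": {"full": fm.n_features},
        "seed": config.seed,
    }

    ranking = rank_features(fm.X, fm.labels, fm.names)
    with open(outdir / "mrmd_ranking.tsv", "w") as fh:
        fh.write("rank\tindex\tname\trelevance\tdistance\tscore\n")
        for fs in ranking:
            fh.write(f"{fs.rank}\t{fs.index}\t{fs.name}\t{fs.relevance:.10g}"
                     f"\t{fs.distance:.10g}\t{fs.score:.10g}\n")

    full_eval = cross_validate(fm.X, fm.labels, model="rf",
                               folds=config.cv_folds, seed=config.seed)
    full_eval.to_json(outdir / "eval_full_rf.json")
    report["full_rf"] = full_eval.to_dict()

    if config.selection == "mrmd":
        chosen, trace = select_subset(fm.X, fm.labels, fm.names,
                                      cv=config.cv_folds, seed=config.seed)
        report["dimensions"]["selected"] = len(chosen)
        report["selection_trace"] = trace
        sel_eval = cross_validate(fm.X[:, chosen], fm.labels, model="rf",
                                  folds=config.cv_folds, seed=config.seed)
        sel_eval.to_json(outdir / "eval_selected_rf.json")
        report["selected_rf"] = sel_eval.to_dict()
        report["selected_features"] = [fm.names[i] for i in chosen]
        candidate_idx = chosen
        logger.info("selection: %d -> %d features", fm.n_features, len(chosen))
    else:
        candidate_idx = [fs.index for fs in ranking]
        logger.info("selection: off (all %d features)", fm.n_features)

    # single-feature models on the top-ranked candidates
    rank_of = {fs.index: fs.rank for fs in ranking}
    top = sorted(candidate_idx, key=lambda i: rank_of[i])[: config.n_top_single]
    singles = {}
    for i in top:
        res = single_feature_model(fm.X, fm.labels, i,
                                   folds=config.cv_folds, seed=config.seed)
        singles[fm.names[i]] = {"index": i, "rank": rank_of[i], **res.to_dict()}
    _write_json(singles, outdir / "eval_single_logistic.json")
    report["single_feature"] = singles

    # best single feature: highest CV accuracy, ties by MRMD rank
    best_name = min(singles, key=lambda nm: (-singles[nm]["acc"], singles[nm]["rank"]))
    best = singles[best_name]
    report["dimensions"]["single"] = 1
    report["key_feature"] = {
        "name": best_name,
        "index_0based": best["index"],
        "index_1based": best["index"] + 1,
        "mrmd_rank": best["rank"],
        "acc": best["acc"],
    }
    _write_json(report["key_feature"], outdir / "key_feature.json")
    with open(outdir / "key_feature_values.csv", "w") as fh:
        fh.write(f"id,label,{best_name}\n")
        col = fm.column(best["index"])
        for rid, lab, val in zip(fm.ids, fm.labels, col):
            fh.write(f"{rid},{'alkaline' if lab else 'acid'},{val:.10g}\n")
    logger.info("key feature: %s (1-based index %d)", best_name, best["index"] + 1)

    _write_json(report, outdir / "report.json")
    return report
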