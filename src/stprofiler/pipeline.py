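"""End-to-end orchestration: score → filter/average → cluster →
characterize → match → summarize → rank → export, driven by one config.

Every run writes a manifest (config hash, package version, seed, stage
log) next to its outputs; rerunning with the same config and seed
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    characterize_clusters,
    characterize_histology,
    hierarchical_cluster,
)
from .cohort_io import (
    DEFAULT_EXCLUDED_PATHWAYS,
    average_replicates,
    filter_samples,
    read_expression_matrix,
    read_sample_metadata,
    select_pathways,
)
from .matching import (
    DEFAULT_MATCHING_PATHWAYS,
    TUMOR_HISTOLOGIES,
    export_radar,
    histology_coverage,
    match_nearest,
    rank_representatives,
    summarize_composition,
)
from .stp_model import ScoringConfig, STPProfile, load_pathway_definitions, score_cohort

__all__ = ["AnalysisConfig", "StageError", "run_full_analysis"]

log = logging.getLogger("stprofiler")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """All knobs of the full analysis.  See field names for units; alpha is
    the two-sided significance level shared by every test."""

    expression: str = ""
    metadata: str = ""
    definitions: str = ""
    out_dir: str = "stprofiler_out"
    excluded_pathways: list = field(
        default_factory=lambda: sorted(DEFAULT_EXCLUDED_PATHWAYS)
    )
    k: int = 7
    linkage: str = "ward"
    distance: str = "euclidean"
    alpha: float = 0.05
    correction: str | None = None
    matching_pathways: list = field(
        default_factory=lambda: list(DEFAULT_MATCHING_PATHWAYS)
    )
    ranking_rule: str = "majority-then-count"
    cohort_sizes: dict = field(default_factory=dict)
    slope: float = 1.0
    kappa: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not (0.0 < self.kappa < 0.5):
            raise ValueError(f"kappa must be in (0, 0.5), got {self.kappa}")
        for name in ("expression", "metadata", "definitions"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: path not found: {p!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _subset(profile: STPProfile, ids) -> STPProfile:
    ids = [i for i in profile.sample_ids if i in set(ids)]
    meta = profile.metadata.loc[ids] if profile.metadata is not None else None
    return STPProfile(
        scores=profile.scores.loc[ids],
        log2odds=profile.log2odds.loc[ids],
        metadata=meta,
    )


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write outputs under ``config.out_dir``.

    Returns a dict of in-memory results keyed by stage; raises
    :class:`StageError` naming the stage on the first failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stages: list[str] = []

    def run_stage(name, fn):
        try:
            log.info("stage %s", name)
            r = fn()
            stages.append(name)
            return r
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    def _load():
        matrix = read_expression_matrix(config.expression)
        meta = read_sample_metadata(config.metadata)
        defs = load_pathway_definitions(config.definitions)
        missing = [s for s in matrix.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        return matrix, meta.loc[list(matrix.columns)], defs

    matrix, meta, defs = run_stage("load", _load)
    log.info("loaded %d genes x %d samples, %d pathways",
             len(matrix), matrix.shape[1], len(defs))

    def _filter():
        eligible, exclusion_log = filter_samples(meta)
        with open(out / "exclusion_log.json", "w") as fh:
            json.dump(exclusion_log.to_dict(), fh, indent=1)
        return eligible, exclusion_log

    eligible, results["exclusion_log"] = run_stage("filter", _filter)
    log.info("%d/%d samples eligible", len(eligible), len(meta))

    def _score():
        sc = ScoringConfig(slope=config.slope, kappa=config.kappa)
        profile = score_cohort(
            matrix[list(eligible)], defs, config=sc, metadata=meta.loc[list(eligible)]
        )
        profile = select_pathways(profile, excluded=set(config.excluded_pathways))
        profile.to_csv(out / "stp_profile.csv")
        return profile

    profile = results["profile"] = run_stage("score", _score)

    def _average():
        m = profile.metadata
        cl = _subset(profile, m.index[m["tissue_class"] == "cell_line"])
        tm = _subset(profile, m.index[m["tissue_class"] == "tumor"])
        cl_avg = average_replicates(cl, cl.metadata) if cl.sample_ids else cl
        cl_avg.to_csv(out / "cellline_profile.csv")
        return cl_avg, tm

    celllines, tumors = run_stage("average_replicates", _average)
    results["celllines"], results["tumors"] = celllines, tumors
    log.info("%d cell-line entities, %d tumor samples",
             len(celllines.sample_ids), len(tumors.sample_ids))

    def _cluster():
        k = min(config.k, len(celllines.sample_ids))
        cr = hierarchical_cluster(
            celllines, k=k, method=config.linkage, metric=config.distance
        )
        (out / "dendrogram.nwk").write_text(cr.to_newick())
        cr.labels.to_csv(out / "clusters.csv", index_label="sample_id")
        return cr

    clusters = results["clusters"] = run_stage("cluster", _cluster)
    log.info("cluster sizes: %s", dict(clusters.sizes))

    def _characterize():
        tabs = {}
        if clusters.labels.nunique() >= 2:
            tabs["clusters"] = characterize_clusters(
                celllines, clusters, alpha=config.alpha, correction=config.correction
            )
            tabs["clusters"].to_csv(out / "characterization_clusters.csv")
        hist = celllines.metadata["histology_of_origin"]
        if hist.nunique() >= 2:
            tabs["histology"] = characterize_histology(
                celllines, hist, alpha=config.alpha, correction=config.correction
            )
            tabs["histology"].to_csv(out / "characterization_histology.csv")
        return tabs

    results["characterization"] = run_stage("characterize", _characterize)

    if tumors.sample_ids:
        def _match():
            mt = match_nearest(
                tumors, celllines, pathways=tuple(config.matching_pathways)
            )
            mt.to_csv(out / "matches.csv")
            return mt

        matches = results["matches"] = run_stage("match", _match)
        log.info("%d tumors matched to %d cell lines",
                 len(matches), matches.table["cell_line"].nunique())

        def _summarize():
            hist = tumors.metadata["histology_of_origin"]
            comp = summarize_composition(matches, hist)
            comp.to_csv(out / "match_composition.csv")
            sizes = dict(config.cohort_sizes) or {
                h: int((hist == h).sum()) for h in TUMOR_HISTOLOGIES
            }
            cov = histology_coverage(matches, hist, sizes)
            cov.to_csv(out / "histology_coverage.csv", index=False)
            return comp, cov

        comp, results["coverage"] = run_stage("summarize", _summarize)
        results["composition"] = comp

        def _rank():
            ranks = {}
            hist = tumors.metadata["histology_of_origin"]
            for h in sorted(hist.unique()):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ranks[h] = rank_representatives(
                        comp, h, rule=config.ranking_rule
                    )
            pd.concat(
                [df.assign(histology=h) for h, df in ranks.items()],
                ignore_index=True,
            ).to_csv(out / "representative_ranking.csv", index=False)
            return ranks

        results["ranking"] = run_stage("rank", _rank)

        def _radar():
            return export_radar(
                matches, tumors, celllines, out / "radar",
                histology=tumors.metadata["histology_of_origin"],
            )

        results["radar_files"] = run_stage("export_radar", _radar)

    manifest = {
        "package": "stprofiler",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": stages,
        "n_samples_input": int(matrix.shape[1]),
        "n_eligible": len(eligible),
        "n_cellline_entities": len(celllines.sample_ids),
        "n_tumors": len(tumors.sample_ids),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
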