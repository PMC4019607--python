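"""Config-driven orchestration of the full link-prediction workflow.

Stages run in a fixed order — normalize -> select -> scan -> refine ->
rank -> annotate-filter -> enrich -> link -> export — and a manifest
JSON records the config hash, input checksums, per-stage row counts and
wall-clock time so repeated runs can be compared mechanically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_filter import (
    DEFAULT_TERMS,
    TermQuery,
    filter_by_terms,
    intersect_targets,
    read_annotation,
)
from .enrichment import enrich_pathways, summary
from .errors import ConfigError, PipelineError
from .expression import (
    normalize_to_control,
    read_expression_table,
    select_differential,
    summarize_directions,
)
from .linkage import export_network, predict_links
from .seqio import read_fasta, read_gmt
from .target_prediction import (
    MatureMiRNA,
    UTRRecord,
    aggregate_and_rank,
    context_score,
    duplex_align,
    scan_sites,
)

log = logging.getLogger(__name__)

STAGES = (
    "normalize",
    "select",
    "scan",
    "refine",
    "rank",
    "annotate-filter",
    "enrich",
    "link",
    "export",
)


@dataclass
class PipelineConfig:
    """All paths, thresholds and flags for one pipeline run.

    Defaults mirror the workflow's standard constants: 5-fold selection,
    95th-percentile target cut, duplex threshold 80, alpha 0.05, top-30
    pathways.
    """

    expression: str = ""
    mirnas: str = ""
    utrs: str = ""
    annotation: str = ""
    pathways: str = ""
    trajectories: str = ""
    outdir: str = "mirlink_out"
    control_label: str = "control"
    floor: float = 1.0
    fold_threshold: float = 5.0
    percentile: float = 95.0
    duplex_threshold: float = 80.0
    alpha: float = 0.05
    terms: tuple[str, ...] = DEFAULT_TERMS
    min_evidence: int = 1
    top_k: int = 30
    rng_seed: int = 0
    refine: bool = False
    include_6mer: bool = False
    per_mirna_percentile: bool = False
    bh_adjust: bool = False
    negative_only: bool = True
    endpoint_only: bool = False
    replicate_mean: str = "arithmetic"
    log2_correlation: bool = True

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ConfigError(f"fold_threshold must exceed 1, got {self.fold_threshold}")
        if not 0 < self.percentile < 100:
            raise ConfigError(f"percentile must be in (0, 100), got {self.percentile}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.top_k < 1:
            raise ConfigError(f"top_k must be >= 1, got {self.top_k}")
        if self.floor <= 0:
            raise ConfigError(f"floor must be positive, got {self.floor}")
        if self.min_evidence < 0:
            raise ConfigError(f"min_evidence must be >= 0, got {self.min_evidence}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "terms" in raw:
            raw["terms"] = tuple(raw["terms"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "setup"
    inputs = {
        k: getattr(config, k)
        for k in ("expression", "mirnas", "utrs", "annotation", "pathways", "trajectories")
    }
    try:
        checksums = {k: _checksum(v) for k, v in inputs.items() if v}

        stage = "normalize"
        matrix = read_expression_table(config.expression, config.control_label)
        fc = normalize_to_control(
            matrix, floor=config.floor, method=config.replicate_mean
        )
        with open(outdir / "foldchanges.tsv", "w") as fh:
            fh.write("# fold change vs control per timepoint\n")
            fc.to_csv(fh, sep="\t", float_format="%.6f")
        counts["normalize"] = len(fc)

        stage = "select"
        calls = select_differential(
            fc, threshold=config.fold_threshold, endpoint_only=config.endpoint_only
        )
        n_up, n_down, n_total = summarize_directions(calls)
        calls_df = pd.DataFrame(
            [
                (c.entity_id, c.direction, c.extreme_fc, c.extreme_timepoint, c.ambiguous)
                for c in calls
            ],
            columns=["entity", "direction", "extreme_fc", "extreme_timepoint", "ambiguous"],
        )
        with open(outdir / "calls.tsv", "w") as fh:
            fh.write(f"# differential calls at {config.fold_threshold}-fold\n")
            calls_df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
        counts["select"] = n_total
        log.info("select: %d up, %d down, %d total", n_up, n_down, n_total)

        stage = "scan"
        selected = {c.entity_id for c in calls}
        mirnas = [
            MatureMiRNA(mid, seq)
            for mid, seq in read_fasta(config.mirnas)
            if mid in selected
        ]
        utrs = [UTRRecord(gid, seq) for gid, seq in read_fasta(config.utrs)]
        sites_by_pair = {}
        site_rows = []
        for mirna in mirnas:
            for utr in utrs:
                sites = scan_sites(mirna, utr)
                if not sites:
                    continue
                for s in sites:
                    s.context_score = context_score(s, utr)
                    site_rows.append(
                        (s.gene_id, s.mirna_id, s.start, s.end, s.site_type, s.context_score)
                    )
                sites_by_pair[(mirna.id, utr.gene_id)] = sites
        sites_df = pd.DataFrame(
            site_rows,
            columns=["gene", "mirna", "start", "end", "type", "context_score"],
        )
        with open(outdir / "sites.tsv", "w") as fh:
            fh.write("# seed sites; coordinates 0-based half-open on the UTR sense strand\n")
            sites_df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        counts["scan"] = len(sites_df)

        stage = "refine"
        mirna_map = {m.id: m for m in mirnas}
        utr_map = {u.gene_id: u for u in utrs}
        duplexes = {}
        for (mid, gid), sites in sites_by_pair.items():
            best = max(
                duplex_align(mirna_map[mid], utr_map[gid], s).score for s in sites
            )
            duplexes[(mid, gid)] = best
        counts["refine"] = sum(
            1 for v in duplexes.values() if v >= config.duplex_threshold
        )

        stage = "rank"
        predictions = aggregate_and_rank(
            sites_by_pair,
            duplexes,
            percentile=config.percentile,
            duplex_threshold=config.duplex_threshold,
            refine=config.refine,
            include_6mer=config.include_6mer,
            per_mirna=config.per_mirna_percentile,
        )
        pred_df = pd.DataFrame(
            [
                (
                    p.mirna_id,
                    p.gene_id,
                    len(p.sites),
                    p.aggregate_score,
                    p.percentile_rank,
                    p.refined,
                )
                for p in predictions
            ],
            columns=["mirna", "gene", "n_sites", "aggregate_score", "percentile_rank", "refined"],
        )
        with open(outdir / "predictions.tsv", "w") as fh:
            fh.write(f"# retained predictions at the {config.percentile}th percentile\n")
            pred_df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        counts["rank"] = len(predictions)

        stage = "annotate-filter"
        predicted_genes = {p.gene_id for p in predictions}
        annotation = read_annotation(config.annotation)
        query = TermQuery(terms=tuple(config.terms), min_evidence=config.min_evidence)
        annotated = filter_by_terms(predicted_genes, annotation, query)
        filtered = intersect_targets(predicted_genes, annotated)
        (outdir / "filtered_genes.txt").write_text(
            "".join(f"{g}\n" for g in filtered)
        )
        counts["annotate-filter"] = len(filtered)

        stage = "enrich"
        pathway_sets = read_gmt(config.pathways)
        results = enrich_pathways(
            set(filtered),
            pathway_sets,
            top_k=config.top_k,
            adjust="BH" if config.bh_adjust else "none",
        )
        enr_df = pd.DataFrame(
            [
                (r.rank, r.pathway_id, r.k, r.K, r.n, r.N, r.p_right, r.ratio, r.q)
                for r in results
            ],
            columns=["rank", "pathway", "k", "K", "n", "N", "p", "ratio", "q"],
        )
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("# right-tailed Fisher exact test per pathway\n")
            enr_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        enr_summary = summary(results, set(filtered), pathway_sets)
        with open(outdir / "enrichment_summary.json", "w") as fh:
            json.dump(enr_summary, fh, indent=1, sort_keys=True)
        counts["enrich"] = len(results)

        stage = "link"
        gene_trajs = pd.read_csv(
            config.trajectories, sep="\t", index_col=0, comment="#"
        )
        filtered_set = set(filtered)
        link_preds = [p for p in predictions if p.gene_id in filtered_set]
        call_map = {c.entity_id: c for c in calls}
        edges = predict_links(
            fc,
            gene_trajs,
            link_preds,
            alpha=config.alpha,
            mode="negative" if config.negative_only else "any",
            log2_transform=config.log2_correlation,
            calls=call_map,
        )
        counts["link"] = len(edges)

        stage = "export"
        export_network(edges, outdir / "edges.tsv", outdir / "network.graphml")
        counts["export"] = len(edges)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(stage, exc) from exc

    manifest = {
        "tool_version": __version__,
        "config_hash": config.config_hash(),
        "input_checksums": checksums,
        "stage_counts": counts,
        "selected_up": n_up,
        "selected_down": n_down,
        "wall_clock_s": round(time.time() - t0, 3),
        "enrichment_summary": enr_summary,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
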