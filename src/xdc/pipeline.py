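"""Stage orchestration: bundle -> records -> per-genome statistics ->
new/old comparison -> report files.

A bundle directory holds, per genome, ``<gid>.gtf``, ``<gid>.domains.tsv``,
``<gid>.disorder.tsv`` (per-predictor calls) and optionally
``<gid>.labels.tsv``, plus an optional ``manifest.json`` naming the
disorder predictors. Outputs are flat TSV/JSON files mirroring the study's
per-genome summary figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import annotation_io, boundary_stats, novelty, significance
from .coord_map import build_protein_record
from .models import GenomeSummary, NoveltyLabel, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; flags override file values."""

    bundle_dir: str = "."
    out_dir: str = "results"
    dialect: str = "GTF"
    stop_included: bool = True
    disorder_mode: str = "per_predictor"
    consensus_threshold: float = 0.75
    boundary_mode: str = "junction"
    alpha: float = 0.01
    min_multiexon_proteins: int = 200
    min_new_proteins: int = 10
    n_trials: int = 50_000
    seed: int = 0
    add_one: bool = False
    labels_path: str | None = None  # external labels for ALL genomes
    use_bundle_labels: bool = True  # else built-in presence/absence rule
    clade: list[str] | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def discover_genomes(bundle_dir) -> list[str]:
    return sorted(p.stem for p in Path(bundle_dir).glob("*.gtf"))


def _manifest_predictors(bundle_dir) -> list[str] | None:
    path = Path(bundle_dir) / "manifest.json"
    if path.exists():
        with open(path) as fh:
            return json.load(fh).get("predictors")
    return None


def load_genome_records(cfg: RunConfig, genome_id: str) -> list[ProteinRecord]:
    """Read one genome's files and map junctions to protein coordinates."""
    bundle = Path(cfg.bundle_dir)
    gtf = bundle / f"{genome_id}.gtf"
    dom_path = bundle / f"{genome_id}.domains.tsv"
    if not dom_path.exists():
        raise FileNotFoundError(dom_path)
    transcripts = annotation_io.read_annotation(
        gtf, cfg.dialect, genome_id=genome_id, stop_included=cfg.stop_included
    )
    lengths = {t.protein_id: t.protein_length for t in transcripts}
    domains = annotation_io.read_domains(dom_path, protein_lengths=lengths)
    dis_path = bundle / f"{genome_id}.disorder.tsv"
    disorder = []
    if dis_path.exists():
        disorder = annotation_io.read_disorder(
            dis_path,
            mode=cfg.disorder_mode,
            protein_lengths=lengths,
            threshold=cfg.consensus_threshold,
            predictors=_manifest_predictors(cfg.bundle_dir),
        )
    doms_by_pid: dict[str, list] = {}
    for d in domains:
        doms_by_pid.setdefault(d.protein_id, []).append(d)
    dis_by_pid: dict[str, list] = {}
    for r in disorder:
        dis_by_pid.setdefault(r.protein_id, []).append(r)
    return [
        build_protein_record(
            t,
            doms_by_pid.get(t.protein_id, []),
            dis_by_pid.get(t.protein_id, []),
            boundary_mode=cfg.boundary_mode,
        )
        for t in transcripts
    ]


def map_stage(cfg: RunConfig) -> dict[str, list[ProteinRecord]]:
    """Load every genome in the bundle; a genome whose inputs are broken
    or missing is skipped with a logged reason."""
    records: dict[str, list[ProteinRecord]] = {}
    genomes = discover_genomes(cfg.bundle_dir)
    if not genomes:
        raise FileNotFoundError(f"no *.gtf found in {cfg.bundle_dir}")
    for gid in genomes:
        try:
            records[gid] = load_genome_records(cfg, gid)
        except FileNotFoundError as exc:
            logger.warning("genome %s skipped: missing input %s", gid, exc)
    if not records:
        raise RuntimeError("every genome failed to load")
    return records


def stats_stage(
    cfg: RunConfig, records_by_genome: dict[str, list[ProteinRecord]]
) -> tuple[list[GenomeSummary], dict[str, list[ProteinRecord]], list[dict]]:
    """Per-genome observed/expected summaries for both boundary classes."""
    flat = [r for recs in records_by_genome.values() for r in recs]
    eligible, exclusions = boundary_stats.apply_filters(
        flat, cfg.min_multiexon_proteins
    )
    summaries = []
    for gid in sorted(eligible):
        for cls in ("domain", "disorder"):
            counts = boundary_stats.genome_counts(eligible[gid], cls)
            summaries.append(
                significance.summarize_genome(gid, counts, alpha=cfg.alpha)
            )
    return summaries, eligible, exclusions


def _labels_for(cfg: RunConfig, eligible: dict[str, list[ProteinRecord]]):
    flat = [r for recs in eligible.values() for r in recs]
    clade = set(cfg.clade) if cfg.clade else None

    def restrict(labels: list[NoveltyLabel]) -> list[NoveltyLabel]:
        # labels may cover proteins removed by the multi-exon/genome filters
        known = {r.protein_id for r in flat}
        kept = [lab for lab in labels if lab.protein_id in known]
        if len(kept) < len(labels):
            logger.info(
                "%d label(s) refer to filtered-out proteins and are ignored",
                len(labels) - len(kept),
            )
        return kept

    if cfg.labels_path:
        labels = restrict(annotation_io.read_labels(cfg.labels_path))
        return novelty.classify_new_old(flat, clade=clade, labels=labels)
    if cfg.use_bundle_labels:
        bundle = Path(cfg.bundle_dir)
        labels: list[NoveltyLabel] = []
        found = False
        for gid in eligible:
            path = bundle / f"{gid}.labels.tsv"
            if path.exists():
                found = True
                labels.extend(annotation_io.read_labels(path))
        if found:
            return novelty.classify_new_old(
                flat, clade=clade, labels=restrict(labels)
            )
    return novelty.classify_new_old(flat, clade=clade)


def new_old_stage(
    cfg: RunConfig, eligible: dict[str, list[ProteinRecord]]
) -> tuple[list[GenomeSummary], dict, list[dict]]:
    """Per-genome new/old ratios plus the cross-genome bootstrap test."""
    labels = _labels_for(cfg, eligible)
    flat = [r for recs in eligible.values() for r in recs]
    by_genome = novelty.group_labels_by_genome(labels, flat)
    retained, report = novelty.exclude_sparse_genomes(
        by_genome, cfg.min_new_proteins
    )
    label_of = {lab.protein_id: lab.label for lab in labels}

    summaries: list[GenomeSummary] = []
    genome_data = {}
    for gid in retained:
        recs = [
            r for r in eligible[gid] if r.domains and r.protein_id in label_of
        ]
        counts = [
            boundary_stats.protein_alignment_counts(r, "domain") for r in recs
        ]
        is_new = np.array(
            [label_of[r.protein_id] == "new" for r in recs], dtype=bool
        )
        obs = np.array([c.observed for c in counts], dtype=float)
        exp = np.array([c.expected for c in counts], dtype=float)
        genome_data[gid] = (obs, exp, is_new)
        for subset, mask in (("new", is_new), ("old", ~is_new)):
            agg = boundary_stats.genome_aggregate(
                [c for c, m in zip(counts, mask) if m], "domain"
            )
            summaries.append(
                significance.summarize_genome(
                    gid, agg, alpha=cfg.alpha, subset=subset
                )
            )
    boot = significance.bootstrap_new_old(
        genome_data, n_trials=cfg.n_trials, seed=cfg.seed, add_one=cfg.add_one
    )
    return summaries, boot.summary(), report


def report_stage(
    cfg: RunConfig,
    summaries: list[GenomeSummary],
    new_old_summaries: list[GenomeSummary],
) -> dict:
    """Ratio-ratio correlation and flat scatter tables."""
    dom = {s.genome_id: s for s in summaries if s.cls == "domain"}
    dis = {s.genome_id: s for s in summaries if s.cls == "disorder"}
    shared = sorted(set(dom) & set(dis))
    correlation: dict = {"n_genomes": len(shared)}
    if len(shared) >= 3:
        try:
            r, p = significance.pearson_ratio_correlation(
                [dom[g].ratio for g in shared], [dis[g].ratio for g in shared]
            )
            correlation.update({"pearson_r": r, "p_value": p})
        except ValueError as exc:
            correlation["undefined"] = str(exc)
    else:
        correlation["undefined"] = "fewer than 3 genomes"

    scatter_a = [
        {
            "genome_id": g,
            "ratio_domain": dom[g].ratio,
            "ratio_disorder": dis[g].ratio,
            "significant_domain": int(dom[g].significant),
            "significant_disorder": int(dis[g].significant),
        }
        for g in shared
    ]
    new = {s.genome_id: s for s in new_old_summaries if s.subset == "new"}
    old = {s.genome_id: s for s in new_old_summaries if s.subset == "old"}
    scatter_b = [
        {
            "genome_id": g,
            "ratio_old": old[g].ratio,
            "ratio_new": new[g].ratio,
        }
        for g in sorted(set(new) & set(old))
    ]
    return {
        "correlation": correlation,
        "scatter_domain_disorder": scatter_a,
        "scatter_new_old": scatter_b,
    }


def _write_tsv(rows: list[dict], path, sep: str = "\t") -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.12g")


def run_full(cfg: RunConfig) -> dict:
    """Run every stage and write the result files under ``cfg.out_dir``.

    Emits genome_summary.tsv, new_old_summary.tsv, bootstrap.json,
    correlation.json, exclusions.tsv and the two scatter CSVs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "run: seed=%d n_trials=%d alpha=%g boundary_mode=%s "
        "consensus_threshold=%g min_multiexon=%d min_new=%d",
        cfg.seed, cfg.n_trials, cfg.alpha, cfg.boundary_mode,
        cfg.consensus_threshold, cfg.min_multiexon_proteins,
        cfg.min_new_proteins,
    )
    records = map_stage(cfg)
    summaries, eligible, exclusions = stats_stage(cfg, records)
    annotation_io.write_genome_summary(summaries, out / "genome_summary.tsv")
    _write_tsv(exclusions, out / "exclusions.tsv")

    new_old_summaries, boot, sparse_report = new_old_stage(cfg, eligible)
    annotation_io.write_genome_summary(
        new_old_summaries, out / "new_old_summary.tsv"
    )
    with open(out / "bootstrap.json", "w") as fh:
        json.dump(boot, fh, indent=1, sort_keys=True)

    report = report_stage(cfg, summaries, new_old_summaries)
    with open(out / "correlation.json", "w") as fh:
        json.dump(report["correlation"], fh, indent=1, sort_keys=True)
    _write_tsv(report["scatter_domain_disorder"],
               out / "scatter_domain_disorder.csv", sep=",")
    _write_tsv(report["scatter_new_old"], out / "scatter_new_old.csv", sep=",")
    return {
        "summaries": summaries,
        "new_old_summaries": new_old_summaries,
        "bootstrap": boot,
        "report": report,
        "exclusions": exclusions,
        "sparse_report": sparse_report,
    }
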