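"""Synthetic multi-genome inputs with known planted structure.

Each synthetic protein gets a length from a log-normal, a number of CDS
exons (1 + Poisson), up to three non-overlapping domains, disorder regions
carved outside domains, and noisy per-predictor disorder tracks. Internal
splice junctions are planted at residue positions that, with probability
theta, are drawn uniformly over the protein's domain boundary-window set
(theta_new for planted-novel proteins, theta_disorder analogously for
disorder windows), and otherwise uniformly over the whole sequence. Drawing
enriched junctions uniformly over the window *residue set* makes the
genome-level ratio follow the closed form (theta + (1-theta)*w) / w, where
w is the boundary-weighted mean window fraction.

Junction residues are then realised as genomic CDS coordinates on a toy
chromosome with a random codon phase per junction and a random strand, so
the full parser and coordinate-mapping path is exercised.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .boundary_stats import build_boundary_windows
from .coord_map import build_protein_record
from .models import (
    DisorderRegion,
    DomainAssignment,
    NoveltyLabel,
    ProteinRecord,
    Transcript,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """All generator distributions and the planted enrichment parameters.

    Defaults emulate a compact eukaryote-like proteome: median protein of
    300 residues, ~4 junctions per protein, mostly single-domain proteins
    with domains of 40-150 residues, 8 disorder predictors with a 2%
    per-residue call error. All enrichments default to 0 (the null).
    """

    seed: int = 0
    n_genomes: int = 3
    n_proteins_per_genome: int = 300
    protein_length_median: float = 300.0
    protein_length_sigma: float = 0.6
    min_protein_length: int = 30
    n_exons_mean: float = 4.0
    domain_count_probs: tuple = (0.15, 0.55, 0.20, 0.10)
    domain_length_range: tuple = (40, 150)
    n_domain_families: int = 25
    disorder_n_predictors: int = 8
    disorder_error_rate: float = 0.02
    disorder_region_prob: float = 0.5
    min_disorder_segment: int = 8
    allow_overlap: bool = False
    theta_domain: float = 0.0
    theta_disorder: float = 0.0
    frac_new_proteins: float = 0.0
    theta_new: float = 0.0
    intron_length_range: tuple = (50, 2000)

    def __post_init__(self):
        for name in ("theta_domain", "theta_disorder", "theta_new",
                     "frac_new_proteins", "disorder_error_rate",
                     "disorder_region_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.theta_domain + self.theta_disorder > 1.0 + 1e-12:
            raise ValueError("theta_domain + theta_disorder must be <= 1")
        if abs(sum(self.domain_count_probs) - 1.0) > 1e-9:
            raise ValueError("domain_count_probs must sum to 1")
        if self.min_protein_length < 30:
            raise ValueError("min_protein_length must be >= 30")
        if self.n_exons_mean < 0:
            raise ValueError("n_exons_mean must be >= 0")

    @property
    def predictor_names(self) -> list[str]:
        return [f"pred{i}" for i in range(self.disorder_n_predictors)]


@dataclass
class GeneratedGenome:
    """In-memory bundle for one synthetic genome plus its ground truth."""

    genome_id: str
    transcripts: list[Transcript]
    domains: list[DomainAssignment]
    disorder_regions: list[DisorderRegion]  # planted consensus truth
    predictor_regions: list[DisorderRegion]  # noisy per-predictor calls
    labels: list[NoveltyLabel]
    truth: dict = field(default_factory=dict)  # protein_id -> planted facts
    n_fallback: int = 0


def _genome_rng(config: SyntheticConfig, genome_id: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, zlib.crc32(genome_id.encode()) & 0x7FFFFFFF]
    )


def _place_domains(rng, L, n_dom, lo, hi):
    """Non-overlapping uniform placement via stars-and-bars over free gaps."""
    lens = rng.integers(lo, hi + 1, size=n_dom)
    while n_dom > 0 and lens[:n_dom].sum() + n_dom + 1 > L:
        n_dom -= 1
    if n_dom == 0:
        return []
    lens = lens[:n_dom]
    free = L - int(lens.sum())
    bars = np.sort(rng.integers(0, free + 1, size=n_dom))
    doms = []
    cur = 1
    prev = 0
    for i in range(n_dom):
        gap = int(bars[i]) - prev
        prev = int(bars[i])
        start = cur + gap
        end = start + int(lens[i]) - 1
        doms.append((start, end))
        cur = end + 1
    return doms


def _carve_disorder(rng, L, dom_ranges, config: SyntheticConfig):
    """Disorder regions in the segments left free by domains.

    With ``allow_overlap`` some regions are instead anchored flush to a
    domain edge, sharing a boundary with it (and may run over a
    neighbouring domain), which induces correlated domain/disorder
    boundary windows.
    """
    regions = []
    segs = []
    prev_end = 0
    for s, e in dom_ranges:
        if s - prev_end - 1 >= config.min_disorder_segment:
            segs.append((prev_end + 1, s - 1))
        prev_end = e
    if L - prev_end >= config.min_disorder_segment:
        segs.append((prev_end + 1, L))
    for s, e in segs:
        if rng.random() >= config.disorder_region_prob:
            continue
        seg_len = e - s + 1
        rlen = int(rng.integers(4, seg_len + 1))
        rstart = s + int(rng.integers(0, seg_len - rlen + 1))
        regions.append((rstart, rstart + rlen - 1))
    if config.allow_overlap:
        for s, e in dom_ranges:
            if rng.random() >= config.disorder_region_prob / 2:
                continue
            rlen = int(rng.integers(4, 41))
            if rng.random() < 0.5 and e + 1 <= L:
                regions.append((e + 1, min(L, e + rlen)))
            elif s - 1 >= 1:
                regions.append((max(1, s - rlen), s - 1))
    # merge to keep regions maximal and non-overlapping
    merged: list[list[int]] = []
    for s, e in sorted(regions):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _plant_junctions(rng, k, L, w_dom, w_dis, theta_dom, theta_dis):
    """Junction residues: enriched draws from window sets, else uniform."""
    residues = np.empty(k, dtype=np.int64)
    n_fallback = 0
    for j in range(k):
        u = rng.random()
        if u < theta_dom:
            if w_dom.size:
                residues[j] = w_dom[rng.integers(w_dom.size)]
            else:
                residues[j] = rng.integers(1, L + 1)
                n_fallback += 1
        elif u < theta_dom + theta_dis:
            if w_dis.size:
                residues[j] = w_dis[rng.integers(w_dis.size)]
            else:
                residues[j] = rng.integers(1, L + 1)
                n_fallback += 1
        else:
            residues[j] = rng.integers(1, L + 1)
    return residues, n_fallback


def _residues_to_offsets(rng, residues, L):
    """Distinct spliced-CDS offsets realising the residues, random phases.

    Residue r admits offsets 3r-2, 3r-1, 3r (phases 1, 2, 0). Phase
    collisions are retried; a residue drawn more than three times (which
    can never yield distinct offsets) is redrawn uniformly.
    """
    k = residues.size
    if k > 3 * L:
        raise ValueError(f"{k} junctions cannot fit in a {L}-residue protein")
    for _ in range(200):
        phases = rng.integers(1, 4, size=k)
        offs = 3 * (residues - 1) + phases
        if np.unique(offs).size == k:
            return np.sort(offs)
        # a residue drawn >3 times can never yield distinct offsets: redraw
        vals, counts = np.unique(residues, return_counts=True)
        for v, c in zip(vals, counts):
            if c > 3:
                idx = np.flatnonzero(residues == v)[3:]
                residues[idx] = rng.integers(1, L + 1, size=idx.size)
    raise RuntimeError("could not realise distinct junction offsets")


def generate_genome(
    config: SyntheticConfig,
    genome_id: str,
    rng: np.random.Generator | None = None,
) -> GeneratedGenome:
    """Generate one genome's transcripts, annotations and ground truth."""
    if rng is None:
        rng = _genome_rng(config, genome_id)
    lo, hi = config.domain_length_range
    i_lo, i_hi = config.intron_length_range
    n_dom_choices = np.arange(len(config.domain_count_probs))

    transcripts: list[Transcript] = []
    domains: list[DomainAssignment] = []
    disorder_regions: list[DisorderRegion] = []
    predictor_regions: list[DisorderRegion] = []
    labels: list[NoveltyLabel] = []
    truth: dict = {}
    total_fallback = 0

    from .boundary_stats import runs_to_regions

    for i in range(config.n_proteins_per_genome):
        pid = f"{genome_id}_P{i:05d}"
        tid = f"{genome_id}_T{i:05d}"
        L = max(
            config.min_protein_length,
            int(round(rng.lognormal(np.log(config.protein_length_median),
                                    config.protein_length_sigma))),
        )
        is_new = bool(rng.random() < config.frac_new_proteins)
        n_dom = int(rng.choice(n_dom_choices, p=config.domain_count_probs))
        if is_new:
            n_dom = max(1, n_dom)
        dom_ranges = _place_domains(rng, L, n_dom, lo, hi)
        if is_new and not dom_ranges:
            is_new = False  # could not fit a domain in a short protein
        dom_ids = [
            f"SF{int(rng.integers(config.n_domain_families)):04d}"
            for _ in dom_ranges
        ]
        if is_new:
            dom_ids[int(rng.integers(len(dom_ids)))] = f"NOV.{genome_id}.{i}"
        for (s, e), did in zip(dom_ranges, dom_ids):
            domains.append(DomainAssignment(pid, did, s, e))

        dis_ranges = _carve_disorder(rng, L, dom_ranges, config)
        for s, e in dis_ranges:
            disorder_regions.append(DisorderRegion(pid, s, e, "consensus"))
        consensus = np.zeros(L, dtype=bool)
        for s, e in dis_ranges:
            consensus[s - 1 : e] = True
        for name in config.predictor_names:
            flips = rng.random(L) < config.disorder_error_rate
            track = consensus ^ flips
            for s, e in runs_to_regions(track):
                predictor_regions.append(
                    DisorderRegion(pid, s, e, f"predictor:{name}")
                )

        k = int(rng.poisson(config.n_exons_mean))  # n_exons = 1 + k
        w_dom = (
            np.array(sorted(build_boundary_windows(dom_ranges, L)))
            if dom_ranges
            else np.empty(0, dtype=np.int64)
        )
        w_dis = (
            np.array(sorted(build_boundary_windows(dis_ranges, L)))
            if dis_ranges
            else np.empty(0, dtype=np.int64)
        )
        theta = config.theta_new if is_new else config.theta_domain
        residues, n_fb = _plant_junctions(
            rng, k, L, w_dom, w_dis, theta, config.theta_disorder
        )
        total_fallback += n_fb
        offs = (
            _residues_to_offsets(rng, residues, L)
            if k
            else np.empty(0, dtype=np.int64)
        )
        planted = [int(-(-o // 3)) for o in offs]

        total_nt = 3 * L + 3  # stop codon included in the CDS
        bounds = np.concatenate([[0], offs, [total_nt]])
        exon_lens = np.diff(bounds).astype(int)
        strand = "+" if rng.random() < 0.5 else "-"
        introns = rng.integers(i_lo, i_hi + 1, size=k)
        gene_start = int(rng.integers(1, 1001))
        lens_asc = exon_lens if strand == "+" else exon_lens[::-1]
        asc = []
        cur = gene_start
        for j, ln in enumerate(lens_asc):
            asc.append((cur, cur + int(ln) - 1))
            cur += int(ln) + (int(introns[j]) if j < k else 0)
        cds_exons = asc if strand == "+" else asc[::-1]

        transcripts.append(
            Transcript(
                transcript_id=tid,
                protein_id=pid,
                genome_id=genome_id,
                chrom=f"chr_{tid}",
                strand=strand,
                cds_exons=cds_exons,
                protein_length=L,
            )
        )
        if dom_ranges:
            labels.append(NoveltyLabel(pid, "new" if is_new else "old"))
        truth[pid] = {
            "junction_residues": planted,
            "is_new": is_new,
            "theta": theta,
            "n_fallback": n_fb,
        }

    return GeneratedGenome(
        genome_id=genome_id,
        transcripts=transcripts,
        domains=domains,
        disorder_regions=disorder_regions,
        predictor_regions=predictor_regions,
        labels=labels,
        truth=truth,
        n_fallback=total_fallback,
    )


def generate_study(config: SyntheticConfig) -> list[GeneratedGenome]:
    """Generate ``config.n_genomes`` genomes G000, G001, ..."""
    return [
        generate_genome(config, f"G{i:03d}") for i in range(config.n_genomes)
    ]


def build_records(
    genome: GeneratedGenome, boundary_mode: str = "junction"
) -> list[ProteinRecord]:
    """Protein records straight from the in-memory genome (no file I/O),
    using the planted consensus disorder regions."""
    doms: dict[str, list[DomainAssignment]] = {}
    for d in genome.domains:
        doms.setdefault(d.protein_id, []).append(d)
    dis: dict[str, list[DisorderRegion]] = {}
    for r in genome.disorder_regions:
        dis.setdefault(r.protein_id, []).append(r)
    return [
        build_protein_record(
            t,
            doms.get(t.protein_id, []),
            dis.get(t.protein_id, []),
            boundary_mode=boundary_mode,
        )
        for t in genome.transcripts
    ]


def _gtf_lines(genome: GeneratedGenome) -> list[str]:
    rows = []
    for t in genome.transcripts:
        cum = 0
        feats = []
        for s, e in t.cds_exons:  # 5'->3'
            frame = (3 - cum % 3) % 3
            feats.append((s, e, frame))
            cum += e - s + 1
        attrs = (
            f'gene_id "{t.transcript_id}.g"; '
            f'transcript_id "{t.transcript_id}"; '
            f'protein_id "{t.protein_id}";'
        )
        for s, e, frame in sorted(feats):  # genomic order in the file
            rows.append(
                f"{t.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t{t.strand}\t{frame}\t{attrs}"
            )
    rows.sort(key=lambda line: (line.split("\t")[0], int(line.split("\t")[3])))
    return rows


def write_bundle(
    genomes: list[GeneratedGenome], out_dir, config: SyntheticConfig
) -> Path:
    """Write per-genome GTF + domain/disorder/label TSVs, a manifest and a
    ground-truth JSON under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "predictors": config.predictor_names,
        "config": asdict(config),
        "genomes": {},
    }
    truth_all = {}
    for g in genomes:
        gid = g.genome_id
        with open(out_dir / f"{gid}.gtf", "w") as fh:
            fh.write("\n".join(_gtf_lines(g)))
            if g.transcripts:
                fh.write("\n")
        with open(out_dir / f"{gid}.domains.tsv", "w") as fh:
            fh.write("protein_id\tdomain_id\tstart\tend\n")
            for d in g.domains:
                fh.write(f"{d.protein_id}\t{d.domain_id}\t{d.start}\t{d.end}\n")
        with open(out_dir / f"{gid}.disorder.tsv", "w") as fh:
            fh.write("protein_id\tstart\tend\tpredictor\n")
            for r in g.predictor_regions:
                name = r.source.split(":", 1)[1]
                fh.write(f"{r.protein_id}\t{r.start}\t{r.end}\t{name}\n")
        with open(out_dir / f"{gid}.labels.tsv", "w") as fh:
            fh.write("protein_id\tlabel\n")
            for lab in g.labels:
                fh.write(f"{lab.protein_id}\t{lab.label}\n")
        manifest["genomes"][gid] = {
            "n_transcripts": len(g.transcripts),
            "n_domains": len(g.domains),
            "n_disorder_regions": len(g.disorder_regions),
            "n_predictor_regions": len(g.predictor_regions),
            "n_labels": len(g.labels),
            "n_fallback_junctions": g.n_fallback,
        }
        truth_all[gid] = g.truth
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_all, fh, sort_keys=True)
    return out_dir
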