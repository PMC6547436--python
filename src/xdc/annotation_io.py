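"""Readers and writers for every external file the pipeline touches.

Gene annotations come in GTF or GFF3 (only CDS features are used); domain
assignments, disorder calls and novelty labels are tab-separated tables
with a header row; result summaries round-trip through TSV.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd
from gffutils.feature import feature_from_line

from .boundary_stats import consensus_call, runs_to_regions
from .models import (
    AlignmentCounts,
    DisorderRegion,
    DomainAssignment,
    GenomeSummary,
    NoveltyLabel,
    Transcript,
)

logger = logging.getLogger(__name__)

DIALECTS = ("GTF", "GFF3")

SUMMARY_COLUMNS = [
    "genome_id",
    "class",
    "subset",
    "n_proteins",
    "n_boundaries",
    "observed",
    "expected",
    "ratio",
    "chi2",
    "p_value",
    "significant",
    "n_window_residues",
    "n_residues",
]


def _transcript_and_protein_ids(attrs, dialect: str):
    def first(key):
        vals = attrs.get(key)
        return vals[0] if vals else None

    if dialect == "GTF":
        tid = first("transcript_id")
    else:
        tid = first("Parent") or first("transcript_id") or first("ID")
    return tid, first("protein_id")


def read_annotation(
    path,
    dialect: str = "GTF",
    genome_id: str | None = None,
    stop_included: bool = True,
) -> list[Transcript]:
    """Parse CDS features into one :class:`Transcript` per protein-coding
    transcript.

    Exons are returned in 5'->3' order (descending genomic coordinate on
    the '-' strand). When ``stop_included`` is true and the total CDS
    length is a multiple of 3, the final codon is taken to be the stop and
    the protein length is nt/3 - 1; otherwise nt/3. Transcripts whose CDS
    length is not a multiple of 3 are reported and dropped.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem.split(".")[0]

    groups: dict[str, dict] = {}
    skipped_no_pid: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ValueError(
                    f"{path}: unparseable line {lineno}: expected 9 "
                    f"tab-separated fields, found {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line, strict=False)
            except Exception as exc:
                raise ValueError(
                    f"{path}: unparseable line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != "CDS":
                continue
            tid, pid = _transcript_and_protein_ids(feat.attributes, dialect)
            if tid is None:
                raise ValueError(
                    f"{path}: line {lineno}: CDS feature lacks a transcript "
                    "identifier"
                )
            if pid is None:
                skipped_no_pid.add(tid)
                continue
            info = groups.setdefault(
                tid,
                {"protein_id": pid, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": []},
            )
            if info["chrom"] != feat.seqid or info["strand"] != feat.strand:
                raise ValueError(
                    f"{path}: transcript {tid} spans multiple chromosomes or "
                    "strands"
                )
            info["exons"].append((feat.start, feat.end))

    for tid in sorted(skipped_no_pid):
        logger.warning("transcript %s skipped: no protein id", tid)

    transcripts: list[Transcript] = []
    for tid in sorted(groups):
        info = groups[tid]
        exons = sorted(info["exons"])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"transcript {tid}: overlapping CDS exons "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        if info["strand"] == "-":
            exons = exons[::-1]
        total = sum(e - s + 1 for s, e in exons)
        if total % 3 != 0:
            logger.warning(
                "transcript %s dropped: CDS length %d not a multiple of 3",
                tid,
                total,
            )
            continue
        plen = total // 3 - 1 if stop_included else total // 3
        if plen < 1:
            logger.warning("transcript %s dropped: zero-length protein", tid)
            continue
        transcripts.append(
            Transcript(
                transcript_id=tid,
                protein_id=info["protein_id"],
                genome_id=genome_id,
                chrom=info["chrom"],
                strand=info["strand"],
                cds_exons=exons,
                protein_length=plen,
            )
        )
    if not transcripts:
        logger.warning("%s: no usable protein-coding transcripts", path)
    return transcripts


def _read_tsv(path, required: list[str], int_cols: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in int_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-integer {col!r} in row {bad[0] + 2}"
            )
        df[col] = coerced.astype(int)
    return df


def read_domains(
    path, protein_lengths: dict[str, int] | None = None
) -> list[DomainAssignment]:
    """SUPERFAMILY-style table: protein_id, domain_id, start, end.

    Duplicate rows are collapsed; assignments falling outside a known
    protein length are dropped with a warning.
    """
    df = _read_tsv(path, ["protein_id", "domain_id", "start", "end"],
                   ["start", "end"])
    out: dict[DomainAssignment, None] = {}
    for row in df.itertuples(index=False):
        dom = DomainAssignment(row.protein_id, row.domain_id, row.start, row.end)
        if dom.start < 1 or dom.end < dom.start:
            logger.warning("domain %s on %s: bad range (%d,%d), dropped",
                           dom.domain_id, dom.protein_id, dom.start, dom.end)
            continue
        if protein_lengths is not None:
            plen = protein_lengths.get(dom.protein_id)
            if plen is not None and dom.end > plen:
                logger.warning(
                    "domain %s on %s: end %d beyond protein length %d, dropped",
                    dom.domain_id, dom.protein_id, dom.end, plen,
                )
                continue
        out[dom] = None
    return list(out)


def _merge_regions(regions: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching ranges into maximal regions."""
    merged: list[list[int]] = []
    for s, e in sorted(regions):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_disorder(
    path,
    mode: str = "regions",
    protein_lengths: dict[str, int] | None = None,
    threshold: float = 0.75,
    predictors: list[str] | None = None,
) -> list[DisorderRegion]:
    """Disorder calls, either consensus regions or per-predictor tracks.

    ``regions`` mode reads rows (protein_id, start, end) as consensus
    regions, merging any overlapping/touching ones. ``per_predictor`` mode
    reads rows (protein_id, start, end, predictor), expands each
    predictor's calls to a binary track over the protein, applies the
    consensus threshold, and run-length-encodes the result into maximal
    regions. ``predictors`` fixes the consensus denominator; by default
    the distinct predictor names in the file are used.
    """
    if mode not in ("regions", "per_predictor"):
        raise ValueError(f"mode must be 'regions' or 'per_predictor', got {mode!r}")
    if mode == "regions":
        df = _read_tsv(path, ["protein_id", "start", "end"], ["start", "end"])
        out = []
        for pid, group in df.groupby("protein_id", sort=True):
            ranges = list(zip(group["start"], group["end"]))
            if protein_lengths is not None:
                plen = protein_lengths.get(pid)
                if plen is not None and any(e > plen or s < 1 for s, e in ranges):
                    raise ValueError(
                        f"{path}: disorder region outside protein {pid} "
                        f"(length {plen})"
                    )
            for s, e in _merge_regions(ranges):
                out.append(DisorderRegion(pid, s, e, "consensus"))
        return out

    if protein_lengths is None:
        raise ValueError("per_predictor mode requires protein_lengths")
    df = _read_tsv(
        path, ["protein_id", "start", "end", "predictor"], ["start", "end"]
    )
    if predictors is None:
        predictors = sorted(df["predictor"].unique())
    pred_index = {name: i for i, name in enumerate(predictors)}
    unknown = set(df["predictor"]) - set(pred_index)
    if unknown:
        raise ValueError(f"{path}: unknown predictor(s) {sorted(unknown)}")

    import numpy as np

    out = []
    for pid, group in df.groupby("protein_id", sort=True):
        plen = protein_lengths.get(pid)
        if plen is None:
            raise ValueError(f"{path}: unknown protein {pid}")
        tracks = np.zeros((len(predictors), plen), dtype=np.int8)
        for row in group.itertuples(index=False):
            if row.start < 1 or row.end > plen:
                raise ValueError(
                    f"{path}: predictor call ({row.start},{row.end}) outside "
                    f"protein {pid} of length {plen}"
                )
            tracks[pred_index[row.predictor], row.start - 1 : row.end] = 1
        consensus = consensus_call(tracks, threshold)
        for s, e in runs_to_regions(consensus):
            out.append(DisorderRegion(pid, s, e, "consensus"))
    return out


def read_labels(path) -> list[NoveltyLabel]:
    """Novelty labels: protein_id, label (new|old)."""
    df = _read_tsv(path, ["protein_id", "label"], [])
    bad = df[~df["label"].isin(["new", "old"])]
    if len(bad):
        raise ValueError(
            f"{path}: label must be 'new' or 'old', got "
            f"{bad['label'].iloc[0]!r}"
        )
    return [NoveltyLabel(r.protein_id, r.label) for r in df.itertuples(index=False)]


def write_genome_summary(summaries: list[GenomeSummary], path) -> None:
    """Write per-genome summaries as TSV; rereads round-trip."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "genome_id": s.genome_id,
                "class": s.cls,
                "subset": s.subset,
                "n_proteins": s.counts.n_proteins,
                "n_boundaries": s.counts.n_boundaries,
                "observed": s.counts.observed,
                "expected": s.counts.expected,
                "ratio": s.ratio,
                "chi2": s.chi2,
                "p_value": s.p_value,
                "significant": int(s.significant),
                "n_window_residues": s.counts.n_window_residues,
                "n_residues": s.counts.n_residues,
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_genome_summary(path) -> list[GenomeSummary]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        counts = AlignmentCounts(
            scope="genome",
            cls=row["class"],
            observed=int(row["observed"]),
            expected=float(row["expected"]),
            n_boundaries=int(row["n_boundaries"]),
            n_window_residues=int(row["n_window_residues"]),
            n_residues=int(row["n_residues"]),
            n_proteins=int(row["n_proteins"]),
        )
        out.append(
            GenomeSummary(
                genome_id=row["genome_id"],
                cls=counts.cls,
                counts=counts,
                ratio=float(row["ratio"]),
                chi2=float(row["chi2"]),
                p_value=float(row["p_value"]),
                significant=bool(row["significant"]),
                subset=row["subset"],
            )
        )
    return out
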