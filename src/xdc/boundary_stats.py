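"""Boundary windows and observed/expected alignment counts.

The core statistic: around the start and end of every domain (or disorder
region) lies a window of one residue either side — six residues per
interior interval. Observed is the number of internal splice junctions
falling in the union of a protein's windows; expected assumes junctions
are placed uniformly over the protein, i.e. n_boundaries times the window
fraction of the sequence. Per genome, both are summed over proteins that
carry at least one interval of the class under study.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from .models import AlignmentCounts, ProteinRecord

logger = logging.getLogger(__name__)

EPS = 1e-9


def consensus_call(tracks, threshold: float = 0.75) -> np.ndarray:
    """Binary consensus over per-predictor disorder tracks.

    Residue i is called disordered iff the fraction of predictors calling
    it is >= ``threshold`` (so 6 of 8 predictors meet the default 75%).
    """
    if len(tracks) == 0:
        raise ValueError("consensus requires at least one track")
    lengths = {len(t) for t in tracks}
    if len(lengths) > 1:
        raise ValueError(f"ragged track lengths: {sorted(lengths)}")
    arr = np.asarray(tracks, dtype=np.int8)
    counts = arr.sum(axis=0)
    # integer-safe >= threshold on the fraction called
    return (counts >= threshold * arr.shape[0] - EPS).astype(np.int8)


def runs_to_regions(track: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s in a binary track, as 1-based inclusive ranges."""
    track = np.asarray(track).astype(bool)
    if track.size == 0:
        return []
    padded = np.concatenate([[False], track, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def build_boundary_windows(
    intervals: list[tuple[int, int]], protein_length: int
) -> set[int]:
    """Union of boundary windows: {start-1,start,start+1, end-1,end,end+1}
    per interval, clipped to [1, protein_length]."""
    windows: set[int] = set()
    for start, end in intervals:
        if not (1 <= start <= end <= protein_length):
            raise ValueError(
                f"interval ({start},{end}) out of range for protein of "
                f"length {protein_length}"
            )
        for edge in (start, end):
            for r in (edge - 1, edge, edge + 1):
                if 1 <= r <= protein_length:
                    windows.add(r)
    return windows


def count_observed(junction_residues, window_set: set[int]) -> int:
    """Number of junction entries (multiset) whose residue is in a window."""
    return sum(1 for r in junction_residues if r in window_set)


def expected_aligned(
    n_boundaries: int, n_window_residues: int, protein_length: int
) -> float:
    """Expected aligned count under uniform junction placement."""
    if protein_length <= 0:
        raise ValueError("protein_length must be positive")
    if not 0 <= n_window_residues <= protein_length:
        raise ValueError("window residues must lie within the protein")
    return n_boundaries * n_window_residues / protein_length


def class_intervals(record: ProteinRecord, cls: str) -> list[tuple[int, int]]:
    if cls == "domain":
        return [(d.start, d.end) for d in record.domains]
    if cls == "disorder":
        return [(d.start, d.end) for d in record.disorder]
    raise ValueError(f"unknown class {cls!r}")


def protein_alignment_counts(record: ProteinRecord, cls: str) -> AlignmentCounts:
    """Observed/expected tally for one protein and one boundary class."""
    intervals = class_intervals(record, cls)
    windows = build_boundary_windows(intervals, record.length)
    n_b = len(record.junction_residues)
    return AlignmentCounts(
        scope="protein",
        cls=cls,
        observed=count_observed(record.junction_residues, windows),
        expected=expected_aligned(n_b, len(windows), record.length),
        n_boundaries=n_b,
        n_window_residues=len(windows),
        n_residues=record.length,
        n_proteins=1,
    )


def genome_aggregate(
    protein_counts: list[AlignmentCounts], cls: str
) -> AlignmentCounts:
    """Sum protein-scope counts into a genome-scope tally."""
    total = AlignmentCounts(
        scope="genome",
        cls=cls,
        observed=0,
        expected=0.0,
        n_boundaries=0,
        n_window_residues=0,
        n_residues=0,
        n_proteins=0,
    )
    for c in protein_counts:
        total.observed += c.observed
        total.expected += c.expected
        total.n_boundaries += c.n_boundaries
        total.n_window_residues += c.n_window_residues
        total.n_residues += c.n_residues
        total.n_proteins += c.n_proteins
    if total.expected == 0:
        logger.warning("genome-scope expected count is 0: ratio undefined")
    return total


def genome_counts(records: list[ProteinRecord], cls: str) -> AlignmentCounts:
    """Genome-scope tally over proteins with >=1 interval of ``cls``."""
    eligible = [r for r in records if class_intervals(r, cls)]
    return genome_aggregate(
        [protein_alignment_counts(r, cls) for r in eligible], cls
    )


def apply_filters(
    records: list[ProteinRecord], min_multiexon_proteins: int = 200
) -> tuple[dict[str, list[ProteinRecord]], list[dict]]:
    """Multi-exon filter plus whole-genome exclusion.

    Single-CDS-exon proteins are dropped everywhere. A genome is excluded
    when its number of multi-exon, domain-containing proteins falls below
    ``min_multiexon_proteins``.
    """
    by_genome: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        by_genome[rec.genome_id].append(rec)

    eligible: dict[str, list[ProteinRecord]] = {}
    report = []
    for gid in sorted(by_genome):
        recs = by_genome[gid]
        multi = [r for r in recs if r.n_cds_exons >= 2]
        n_with_domain = sum(1 for r in multi if r.domains)
        excluded = n_with_domain < min_multiexon_proteins
        report.append(
            {
                "genome_id": gid,
                "n_proteins": len(recs),
                "n_multiexon": len(multi),
                "n_multiexon_with_domain": n_with_domain,
                "excluded": excluded,
                "reason": (
                    f"multi-exon domain-containing proteins {n_with_domain} "
                    f"< {min_multiexon_proteins}"
                    if excluded
                    else ""
                ),
            }
        )
        if excluded:
            logger.warning(
                "genome %s excluded: %d multi-exon domain-containing "
                "proteins < %d",
                gid,
                n_with_domain,
                min_multiexon_proteins,
            )
        else:
            eligible[gid] = multi
    return eligible, report
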