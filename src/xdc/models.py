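"""Core data containers shared across the pipeline.

Coordinate conventions: genomic coordinates are 1-based inclusive (GTF/GFF
style); protein residues are 1-based inclusive (SUPERFAMILY-table style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(slots=True)
class Transcript:
    """CDS exon structure of one protein-coding transcript, strand-aware.

    ``cds_exons`` are (start, end) genomic coordinates in transcript
    (5'->3') order, i.e. in *descending* genomic order on the '-' strand.
    """

    transcript_id: str
    protein_id: str
    genome_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    protein_length: int

    @property
    def total_cds_nt(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def n_cds_exons(self) -> int:
        return len(self.cds_exons)

    @property
    def exon_nt_lengths(self) -> list[int]:
        """Exon lengths in 5'->3' order."""
        return [e - s + 1 for s, e in self.cds_exons]


@dataclass(frozen=True, slots=True)
class DomainAssignment:
    """One structural-domain assignment on a protein (residue range)."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class DisorderRegion:
    """A maximal run of residues called intrinsically disordered.

    ``source`` is ``"consensus"`` for consensus calls or
    ``"predictor:<name>"`` for a single predictor's track.
    """

    protein_id: str
    start: int
    end: int
    source: str = "consensus"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class NoveltyLabel:
    """new/old classification of a protein's domain architecture."""

    protein_id: str
    label: str  # "new" | "old"


@dataclass(slots=True)
class ProteinRecord:
    """A protein with its splice junctions mapped to residue coordinates.

    ``junction_residues`` is a multiset (list) of residue indices, one per
    internal splice junction in 5'->3' order (or two per junction in
    ``both_ends`` counting mode).
    """

    protein_id: str
    genome_id: str
    length: int
    junction_residues: list[int]
    n_cds_exons: int
    domains: list[DomainAssignment] = field(default_factory=list)
    disorder: list[DisorderRegion] = field(default_factory=list)
    architecture: str = ""


@dataclass(slots=True)
class AlignmentCounts:
    """Observed vs expected boundary-alignment tallies.

    At protein scope ``expected = n_boundaries * n_window_residues /
    n_residues``; at genome scope every field is the sum over the eligible
    protein set.
    """

    scope: str  # "protein" | "genome"
    cls: str  # "domain" | "disorder"
    observed: int
    expected: float
    n_boundaries: int
    n_window_residues: int
    n_residues: int
    n_proteins: int = 1

    @property
    def ratio(self) -> float:
        if self.expected > 0:
            return self.observed / self.expected
        return math.nan


@dataclass(slots=True)
class GenomeSummary:
    """Per-genome enrichment summary: ratio, chi-square significance."""

    genome_id: str
    cls: str  # "domain" | "disorder"
    counts: AlignmentCounts
    ratio: float
    chi2: float
    p_value: float
    significant: bool
    subset: str = "all"  # "all" | "new" | "old"
    taxon_group: str = ""


@dataclass(slots=True)
class BootstrapResult:
    """Outcome of the cross-genome label-repartition bootstrap."""

    n_trials: int
    n_genomes: int
    actual_count: int
    p_value: float
    trial_count_mean: float
    trial_count_std: float
    trial_counts: object = None  # np.ndarray, kept for diagnostics

    def summary(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_genomes": self.n_genomes,
            "actual_count": self.actual_count,
            "p_value": self.p_value,
            "trial_count_mean": self.trial_count_mean,
            "trial_count_std": self.trial_count_std,
        }
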