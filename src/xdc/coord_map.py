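"""Map splice junctions from genomic to protein residue coordinates.

A junction between exon i and exon i+1 sits after the last coding
nucleotide of exon i, at spliced-CDS offset c = sum of the CDS lengths of
exons 1..i. Its codon phase is c mod 3; phase-0 junctions fall between
codons, phase-1/2 junctions split a codon. In every case the junction is
assigned to the residue whose codon contains nucleotide c, i.e. residue
ceil(c / 3): for a split codon that residue is the one physically encoded
across the splice.
"""

from __future__ import annotations

import logging

from .models import DisorderRegion, DomainAssignment, ProteinRecord, Transcript
from .novelty import architecture_string

logger = logging.getLogger(__name__)

BOUNDARY_MODES = ("junction", "both_ends")


def junction_to_residue(cds_nt_index: int, total_cds_nt: int | None = None) -> int:
    """Residue index containing the CDS nucleotide at 1-based ``cds_nt_index``.

    ``cds_nt_index`` is counted along the spliced CDS; for a splice junction
    it is the last coding nucleotide of the upstream exon, so it must be
    strictly less than the total CDS length when that is supplied.
    """
    if cds_nt_index < 1:
        raise ValueError(f"cds_nt_index must be >= 1, got {cds_nt_index}")
    if total_cds_nt is not None and cds_nt_index >= total_cds_nt:
        raise ValueError(
            f"cds_nt_index {cds_nt_index} not an internal position of a "
            f"{total_cds_nt} nt CDS"
        )
    return -(-cds_nt_index // 3)  # ceil division


def build_protein_record(
    transcript: Transcript,
    domains: list[DomainAssignment] = (),
    disorder: list[DisorderRegion] = (),
    boundary_mode: str = "junction",
) -> ProteinRecord:
    """Assemble a :class:`ProteinRecord` from a transcript and annotations.

    In ``junction`` mode each internal splice junction contributes one
    boundary residue; in ``both_ends`` mode the end of exon i and the start
    of exon i+1 each contribute one (2(n-1) events for n exons).

    Junctions that map beyond ``protein_length`` (possible only when the
    junction lies inside the stop codon) are discarded with a warning.
    """
    if boundary_mode not in BOUNDARY_MODES:
        raise ValueError(f"unknown boundary_mode {boundary_mode!r}")
    pid = transcript.protein_id
    for ann in list(domains) + list(disorder):
        if ann.protein_id != pid:
            raise ValueError(
                f"annotation for {ann.protein_id!r} attached to transcript "
                f"of protein {pid!r}"
            )

    residues: list[int] = []
    cum = 0
    total = transcript.total_cds_nt
    for exon_len in transcript.exon_nt_lengths[:-1]:
        cum += exon_len
        if boundary_mode == "junction":
            residues.append(junction_to_residue(cum, total))
        else:
            residues.append(junction_to_residue(cum, total))  # end of exon i
            residues.append(junction_to_residue(cum + 1))  # start of exon i+1

    kept = [r for r in residues if r <= transcript.protein_length]
    if len(kept) < len(residues):
        logger.warning(
            "%s: discarded %d junction(s) mapping inside the stop codon",
            pid,
            len(residues) - len(kept),
        )

    return ProteinRecord(
        protein_id=pid,
        genome_id=transcript.genome_id,
        length=transcript.protein_length,
        junction_residues=kept,
        n_cds_exons=transcript.n_cds_exons,
        domains=list(domains),
        disorder=list(disorder),
        architecture=architecture_string(domains),
    )
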