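"""Classify proteins as carrying 'new' or 'old' domain architectures.

A protein's architecture is the ordered N->C sequence of its domain
identifiers. The built-in rule labels a protein 'new' when its architecture
occurs in exactly one genome of the clade under study (its own) — a strict
presence/absence criterion. Labels derived from an external ancestral
reconstruction can be supplied instead and win verbatim.
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .models import DomainAssignment, NoveltyLabel, ProteinRecord

logger = logging.getLogger(__name__)


def architecture_string(domains: list[DomainAssignment]) -> str:
    """Comma-joined domain ids in N->C order from non-overlapping assignments.

    Overlapping assignments are resolved by keeping the longer one (ties:
    the one with the smaller start), so the token is deterministic.
    """
    if not domains:
        return ""
    order = sorted(domains, key=lambda d: (-d.length, d.start, d.end, d.domain_id))
    kept: list[DomainAssignment] = []
    for d in order:
        if all(d.end < k.start or d.start > k.end for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: (d.start, d.end))
    return ",".join(d.domain_id for d in kept)


def build_catalogue(records: list[ProteinRecord]) -> dict[str, set[str]]:
    """Map each non-empty architecture to the set of genomes containing it."""
    catalogue: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        if rec.architecture:
            catalogue[rec.architecture].add(rec.genome_id)
    return dict(catalogue)


def classify_new_old(
    records: list[ProteinRecord],
    clade: set[str] | None = None,
    labels: list[NoveltyLabel] | None = None,
) -> list[NoveltyLabel]:
    """Label every domain-containing protein in the clade as new or old.

    If ``labels`` are given they are used verbatim (after checking all ids
    are known); otherwise a protein is 'new' iff its architecture occurs in
    no other genome of the clade. Proteins with no domains are unlabelled
    and excluded from the new/old analysis.
    """
    if clade is None:
        clade = {rec.genome_id for rec in records}
    in_clade = [rec for rec in records if rec.genome_id in clade]

    if labels is not None:
        known = {rec.protein_id for rec in in_clade}
        unknown = sorted({lab.protein_id for lab in labels} - known)
        if unknown:
            raise ValueError(
                f"labels reference unknown proteins: {', '.join(unknown[:10])}"
                + ("..." if len(unknown) > 10 else "")
            )
        with_domains = {rec.protein_id for rec in in_clade if rec.domains}
        return [lab for lab in labels if lab.protein_id in with_domains]

    if len(clade) == 1:
        logger.warning(
            "clade contains a single genome: every architecture is trivially "
            "unique, all proteins will be labelled 'new'"
        )
    catalogue = build_catalogue(in_clade)
    out = []
    for rec in in_clade:
        if not rec.architecture:
            continue
        label = "new" if len(catalogue[rec.architecture]) == 1 else "old"
        out.append(NoveltyLabel(rec.protein_id, label))
    return out


def group_labels_by_genome(
    labels: list[NoveltyLabel], records: list[ProteinRecord]
) -> dict[str, list[NoveltyLabel]]:
    genome_of = {rec.protein_id: rec.genome_id for rec in records}
    grouped: dict[str, list[NoveltyLabel]] = defaultdict(list)
    for lab in labels:
        grouped[genome_of[lab.protein_id]].append(lab)
    return dict(grouped)


def exclude_sparse_genomes(
    labels_by_genome: dict[str, list[NoveltyLabel]],
    min_new_proteins: int = 10,
) -> tuple[list[str], list[dict]]:
    """Drop genomes with too few 'new' proteins from the new/old analysis.

    Returns the retained genome ids and a per-genome report. Raises if no
    genome survives.
    """
    retained, report = [], []
    for gid in sorted(labels_by_genome):
        labs = labels_by_genome[gid]
        n_new = sum(1 for lab in labs if lab.label == "new")
        excluded = n_new < min_new_proteins
        report.append(
            {
                "genome_id": gid,
                "n_new": n_new,
                "n_old": len(labs) - n_new,
                "excluded": excluded,
                "reason": f"n_new {n_new} < {min_new_proteins}" if excluded else "",
            }
        )
        if not excluded:
            retained.append(gid)
        else:
            logger.warning(
                "genome %s excluded from new/old analysis (%d new proteins "
                "< %d)",
                gid,
                n_new,
                min_new_proteins,
            )
    if not retained:
        raise ValueError(
            "no genome retains enough novel-architecture proteins for the "
            "new/old analysis"
        )
    return retained, report
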