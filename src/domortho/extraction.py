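"""Cutting proteomes into domain-equivalent sequences.

Each protein is reduced to the set of sequences that the orthology engine
operates on: its annotated Pfam domain regions (after filtering out repeats
and heavily overlapping hits), every unannotated region longer than the
minimum unknown length (labelled UNK1, UNK2, ... in N-to-C order), and —
for proteins with no surviving annotation at all — the whole protein as a
single orphan sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    CATEGORY_ORPHAN,
    CATEGORY_PFAM,
    CATEGORY_UNKNOWN,
    ORPHAN_LABEL,
    Config,
    DomainAnnotation,
    DomainSequence,
    ProteinRecord,
    domain_sequence_id,
)

__all__ = [
    "filter_annotations",
    "extract_domain_sequences",
    "extract_proteome",
    "ExtractionReport",
]


@dataclass
class ExtractionReport:
    """Per-proteome extraction counts.

    Mirrors the per-species numbers the method reports: orphan proteins,
    unknown regions emitted, repeat-type annotations excluded and
    overlap-excluded domains, plus totals for bookkeeping.
    """

    species: str = ""
    n_proteins: int = 0
    n_orphan_proteins: int = 0
    n_pfam_domains: int = 0
    n_unknown_regions: int = 0
    n_repeats_excluded: int = 0
    n_overlap_excluded: int = 0
    n_regions_considered: int = 0
    n_regions_discarded: int = 0

    def merge(self, other: "ExtractionReport") -> None:
        for name in (
            "n_proteins", "n_orphan_proteins", "n_pfam_domains",
            "n_unknown_regions", "n_repeats_excluded", "n_overlap_excluded",
            "n_regions_considered", "n_regions_discarded",
        ):
            setattr(self, name, getattr(self, name) + getattr(other, name))


def _overlap(a: DomainAnnotation, b: DomainAnnotation) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def filter_annotations(
    annotations: list[DomainAnnotation],
    config: Config,
    report: ExtractionReport | None = None,
) -> list[DomainAnnotation]:
    """Apply the repeat and overlap filters to one protein's annotations.

    Repeat-type hits are removed first.  Then overlaps are resolved: if two
    annotations overlap by more than ``overlap_discard_fraction`` of the
    shorter one's length, the shorter is discarded and the longer kept.
    Candidates are processed in order of descending length (ties: smaller
    start coordinate first) so the longest domain always survives and the
    outcome is independent of input order.
    """
    kept_candidates = [a for a in annotations if a.family_type != "Repeat"]
    n_repeats = len(annotations) - len(kept_candidates)

    ordered = sorted(kept_candidates, key=lambda a: (-a.length, a.start, a.end, a.name))
    kept: list[DomainAnnotation] = []
    n_overlap_excluded = 0
    for cand in ordered:
        violates = any(
            _overlap(cand, k) > config.overlap_discard_fraction * cand.length
            for k in kept
        )
        if violates:
            n_overlap_excluded += 1
        else:
            kept.append(cand)

    if report is not None:
        report.n_repeats_excluded += n_repeats
        report.n_overlap_excluded += n_overlap_excluded
    return sorted(kept, key=lambda a: (a.start, a.end))


def extract_domain_sequences(
    protein: ProteinRecord,
    kept_annotations: list[DomainAnnotation],
    config: Config,
    report: ExtractionReport | None = None,
) -> list[DomainSequence]:
    """Cut one protein into its domain-equivalent sequences.

    Emits one ``pfam_domain`` cut per kept annotation and one
    ``unknown_region`` (UNKn) per maximal unannotated region — terminal
    regions included — of length strictly greater than
    ``config.min_unknown_len``.  A protein with no kept annotation yields a
    single orphan covering its full length.
    """
    for a in kept_annotations:
        if a.end > protein.length:
            raise ValueError(
                f"annotation {a.name!r} [{a.start}..{a.end}] exceeds bounds of "
                f"protein {protein.id!r} (length {protein.length})"
            )

    if not kept_annotations:
        if report is not None:
            report.n_orphan_proteins += 1
        return [
            DomainSequence(
                id=domain_sequence_id(protein.id, ORPHAN_LABEL, 1, protein.length),
                protein_id=protein.id,
                species=protein.species,
                start=1,
                end=protein.length,
                label=ORPHAN_LABEL,
                category=CATEGORY_ORPHAN,
                sequence=protein.sequence,
            )
        ]

    cuts: list[DomainSequence] = []
    for a in sorted(kept_annotations, key=lambda a: (a.start, a.end)):
        cuts.append(
            DomainSequence(
                id=domain_sequence_id(protein.id, a.name, a.start, a.end),
                protein_id=protein.id,
                species=protein.species,
                start=a.start,
                end=a.end,
                label=a.name,
                category=CATEGORY_PFAM,
                sequence=protein.sequence[a.start - 1:a.end],
            )
        )
    if report is not None:
        report.n_pfam_domains += len(cuts)

    # Maximal unannotated regions: complement of the union of kept
    # annotations over [1..length], N- and C-terminal stretches included.
    covered = sorted((a.start, a.end) for a in kept_annotations)
    merged: list[list[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps: list[tuple[int, int]] = []
    cursor = 1
    for s, e in merged:
        if s > cursor:
            gaps.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= protein.length:
        gaps.append((cursor, protein.length))

    unk_counter = 0
    unks: list[DomainSequence] = []
    for s, e in gaps:
        if report is not None:
            report.n_regions_considered += 1
        if e - s + 1 > config.min_unknown_len:
            unk_counter += 1
            label = f"UNK{unk_counter}"
            unks.append(
                DomainSequence(
                    id=domain_sequence_id(protein.id, label, s, e),
                    protein_id=protein.id,
                    species=protein.species,
                    start=s,
                    end=e,
                    label=label,
                    category=CATEGORY_UNKNOWN,
                    sequence=protein.sequence[s - 1:e],
                )
            )
        elif report is not None:
            report.n_regions_discarded += 1
    if report is not None:
        report.n_unknown_regions += len(unks)

    return sorted(cuts + unks, key=lambda d: (d.start, d.end))


def extract_proteome(
    proteome: list[ProteinRecord],
    annotations: list[DomainAnnotation],
    config: Config,
) -> tuple[list[DomainSequence], ExtractionReport]:
    """Extract domain-equivalent sequences for a whole proteome.

    Raises if any annotation references a protein id absent from the
    proteome.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        by_protein.setdefault(a.protein_id, []).append(a)

    known = {p.id for p in proteome}
    unresolved = sorted(set(by_protein) - known)
    if unresolved:
        raise ValueError(
            "annotations reference unknown protein ids: " + ", ".join(unresolved)
        )

    species = proteome[0].species if proteome else ""
    report = ExtractionReport(species=species, n_proteins=len(proteome))
    sequences: list[DomainSequence] = []
    for protein in proteome:
        kept = filter_annotations(by_protein.get(protein.id, []), config, report)
        sequences.extend(extract_domain_sequences(protein, kept, config, report))
    return sequences, report
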