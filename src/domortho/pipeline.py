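"""End-to-end pipeline: extract -> score -> infer -> project/discordant/merge.

All stages are deterministic; the only randomness in the package lives in
the synthetic generator and flows from the config seed.  Each stage's
output is written to disk so any downstream stage can be resumed from the
files alone, and a manifest (config snapshot, input digests, per-stage
record counts) is written last.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from .core import build_groups, groups_to_domain_pairs
from .extraction import extract_proteome
from .model import (
    Config,
    DomainAnnotation,
    OrthologGroup,
    ProteinRecord,
    write_discordance_table,
    write_domain_pair_table,
    write_fasta,
    write_group_table,
    write_hit_table,
    write_pair_table,
)
from .protein import (
    alpha_sweep,
    build_domain_map,
    find_discordant,
    merge_with_fulllength,
    project_protein_pairs,
)
from .similarity import all_vs_all, apply_hit_filters

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for the error report."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(
    config: Config,
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    annotations_a: list[DomainAnnotation],
    annotations_b: list[DomainAnnotation],
    out_dir: str | Path,
    fulllength_groups: Sequence[OrthologGroup] | None = None,
    blast_hits: tuple[list, list, list] | None = None,
) -> dict:
    """Run every stage and write the output bundle to ``out_dir``.

    ``blast_hits`` may supply imported (cross, within_a, within_b) hits in
    place of the built-in scorer.  Returns the manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    species_a = proteome_a[0].species if proteome_a else "A"
    species_b = proteome_b[0].species if proteome_b else "B"
    if species_a == species_b:
        raise PipelineError("setup", f"species tags must differ, got {species_a!r}")

    # --- extract ---------------------------------------------------------
    try:
        domains_a, report_a = extract_proteome(proteome_a, annotations_a, config)
        domains_b, report_b = extract_proteome(proteome_b, annotations_b, config)
    except ValueError as exc:
        raise PipelineError("extract", str(exc)) from exc
    with open(out / "domains.fasta", "w") as fh:
        write_fasta(sorted(domains_a + domains_b, key=lambda d: d.id), fh)
    for report in (report_a, report_b):
        logger.info(
            "extract[%s]: %d proteins -> %d domains, %d unknown regions, "
            "%d orphans; excluded %d repeats, %d overlaps",
            report.species, report.n_proteins, report.n_pfam_domains,
            report.n_unknown_regions, report.n_orphan_proteins,
            report.n_repeats_excluded, report.n_overlap_excluded,
        )
    counts["domain_sequences"] = len(domains_a) + len(domains_b)

    # --- score -----------------------------------------------------------
    lengths = {d.id: d.length for d in domains_a + domains_b}
    species_of = {d.id: d.species for d in domains_a + domains_b}
    try:
        if blast_hits is not None:
            cross, within_a, within_b = blast_hits
        else:
            cross, within_a, within_b = all_vs_all(domains_a, domains_b)
        cross = apply_hit_filters(cross, lengths, config)
        within_a = apply_hit_filters(within_a, lengths, config)
        within_b = apply_hit_filters(within_b, lengths, config)
    except ValueError as exc:
        raise PipelineError("score", str(exc)) from exc
    for name, hits in (("hits_cross.tsv", cross),
                       ("hits_within_a.tsv", within_a),
                       ("hits_within_b.tsv", within_b)):
        with open(out / name, "w") as fh:
            write_hit_table(hits, fh)
    counts["filtered_cross_hits"] = len(cross)
    logger.info("score: %d cross / %d + %d within hits pass filters",
                len(cross), len(within_a), len(within_b))

    # --- infer -----------------------------------------------------------
    groups = build_groups(cross, within_a, within_b, species_of,
                          species_a, species_b)
    domain_pairs = groups_to_domain_pairs(groups)
    with open(out / "groups.tsv", "w") as fh:
        write_group_table(groups, fh)
    with open(out / "domain_pairs.tsv", "w") as fh:
        write_domain_pair_table(domain_pairs, fh)
    counts["ortholog_groups"] = len(groups)
    counts["domain_pairs"] = len(domain_pairs)
    logger.info("infer: %d groups, %d orthologous domain pairs",
                len(groups), len(domain_pairs))

    # --- project / discordant -------------------------------------------
    domain_map = build_domain_map(domains_a + domains_b)
    protein_pairs = project_protein_pairs(groups, domain_map,
                                          config.alpha_threshold)
    with open(out / "protein_pairs.tsv", "w") as fh:
        write_pair_table(protein_pairs, fh)
    discordant = find_discordant(groups, domain_map)
    with open(out / "discordant.tsv", "w") as fh:
        write_discordance_table(discordant, fh)
    counts["protein_pairs"] = len(protein_pairs)
    counts["discordant_primaries"] = sum(1 for r in discordant if r.is_discordant)
    logger.info("project: %d protein pairs at alpha >= %.2f; %d discordant "
                "primaries", len(protein_pairs), config.alpha_threshold,
                counts["discordant_primaries"])

    # --- merge / compare (optional) --------------------------------------
    if fulllength_groups is not None:
        merge_pairs = project_protein_pairs(groups, domain_map,
                                            config.alpha_threshold_merge)
        merged = merge_with_fulllength(merge_pairs, fulllength_groups)
        with open(out / "merged_pairs.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\tprovenance\n")
            for pair, tag in merged:
                pa, pb = sorted(pair)
                fh.write(f"{pa}\t{pb}\t{tag}\n")
        thresholds = [round(0.1 * i, 1) for i in range(11)]
        sweep = alpha_sweep(groups, domain_map, fulllength_groups, thresholds)
        sweep.to_csv(out / "alpha_sweep.tsv", sep="\t", index=False)
        counts["merged_pairs"] = len(merged)

    # --- manifest --------------------------------------------------------
    manifest = {
        "tool_version": __version__,
        "rng_seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "input_digests": {
            "proteome_a": _digest("".join(f">{p.id}\n{p.sequence}\n"
                                          for p in proteome_a)),
            "proteome_b": _digest("".join(f">{p.id}\n{p.sequence}\n"
                                          for p in proteome_b)),
            "annotations_a": _digest(str(sorted(
                (a.protein_id, a.start, a.end, a.name) for a in annotations_a))),
            "annotations_b": _digest(str(sorted(
                (a.protein_id, a.start, a.end, a.name) for a in annotations_b))),
        },
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
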