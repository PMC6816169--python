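"""Projecting domain orthology onto proteins.

The alpha fraction of a cross-species protein pair is the number of domain
instances (over both proteins) lying in ortholog groups shared by the pair,
divided by the total number of domain-equivalent instances on both proteins
(unknown regions and orphans included).  Pairs at or above a threshold are
called protein-level orthologs.  This module also detects discordant domain
orthology (different domains of one protein orthologous to different
partner proteins), merges domain-derived pairs with a full-length method's
pairs, and computes consensus statistics between the two.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .model import DiscordanceRecord, DomainSequence, OrthologGroup, ProteinPair

__all__ = [
    "DomainInfo",
    "PairCategory",
    "build_domain_map",
    "compute_alpha",
    "project_protein_pairs",
    "find_discordant",
    "merge_with_fulllength",
    "classify_pairs",
    "jaccard_consensus",
    "alpha_sweep",
]


class PairCategory(str, Enum):
    """How a protein pair relates to the full-length method's assignments."""

    BOTH = "both"
    FULLLENGTH_ONLY = "fulllength_only"
    DOMAIN_CONFLICTING = "domain_conflicting"
    DOMAIN_ONE_MISSING = "domain_one_missing"
    DOMAIN_TWO_MISSING = "domain_two_missing"


class DomainInfo:
    """Lookup from domain-sequence ids to their parent protein and species.

    Also knows the total number of domain-equivalent instances per protein,
    which is the alpha denominator's per-protein contribution.
    """

    def __init__(self, domain_sequences: Sequence[DomainSequence]):
        self.protein_of: dict[str, str] = {}
        self.species_of: dict[str, str] = {}
        self.species_of_protein: dict[str, str] = {}
        self.domains_of_protein: dict[str, list[str]] = {}
        for d in domain_sequences:
            self.protein_of[d.id] = d.protein_id
            self.species_of[d.id] = d.species
            self.species_of_protein[d.protein_id] = d.species
            self.domains_of_protein.setdefault(d.protein_id, []).append(d.id)

    def n_instances(self, protein_id: str) -> int:
        return len(self.domains_of_protein.get(protein_id, ()))


def build_domain_map(domain_sequences: Sequence[DomainSequence]) -> DomainInfo:
    return DomainInfo(domain_sequences)


def _group_index(
    groups: Sequence[OrthologGroup], domain_map: DomainInfo
) -> dict[str, dict[str, list[str]]]:
    """group_id -> protein_id -> member domain ids of that protein."""
    index: dict[str, dict[str, list[str]]] = {}
    for g in groups:
        per_protein: dict[str, list[str]] = {}
        for m in g.members:
            pid = domain_map.protein_of[m.id]
            per_protein.setdefault(pid, []).append(m.id)
        index[g.group_id] = per_protein
    return index


def compute_alpha(
    protein_a: str,
    protein_b: str,
    domain_map: DomainInfo,
    groups: Sequence[OrthologGroup],
) -> ProteinPair:
    """Alpha fraction for one cross-species protein pair.

    The numerator counts, over both proteins, every domain instance that
    belongs to a group also containing at least one instance from the
    partner protein; the denominator counts all domain-equivalent instances
    on both proteins.
    """
    n_total = domain_map.n_instances(protein_a) + domain_map.n_instances(protein_b)
    if domain_map.n_instances(protein_a) == 0 or domain_map.n_instances(protein_b) == 0:
        raise ValueError(
            f"protein pair ({protein_a}, {protein_b}): a protein has no "
            "domain-equivalent instances"
        )
    n_shared = 0
    supporting: list[str] = []
    for g in groups:
        per_protein: dict[str, list[str]] = {}
        for m in g.members:
            pid = domain_map.protein_of[m.id]
            if pid in (protein_a, protein_b):
                per_protein.setdefault(pid, []).append(m.id)
        if protein_a in per_protein and protein_b in per_protein:
            n_shared += len(per_protein[protein_a]) + len(per_protein[protein_b])
            supporting.append(g.group_id)
    return ProteinPair(
        protein_a=protein_a,
        protein_b=protein_b,
        n_shared=n_shared,
        n_total=n_total,
        supporting_groups=tuple(sorted(supporting)),
    )


def _candidate_pairs(
    groups: Sequence[OrthologGroup], domain_map: DomainInfo
) -> set[tuple[str, str]]:
    """Cross-species protein pairs sharing at least one ortholog group."""
    candidates: set[tuple[str, str]] = set()
    for g in groups:
        proteins = sorted({domain_map.protein_of[m.id] for m in g.members})
        for i, pa in enumerate(proteins):
            for pb in proteins[i + 1:]:
                if domain_map.species_of_protein[pa] != domain_map.species_of_protein[pb]:
                    candidates.add((pa, pb))
    return candidates


def project_protein_pairs(
    groups: Sequence[OrthologGroup],
    domain_map: DomainInfo,
    alpha_threshold: float,
) -> list[ProteinPair]:
    """All cross-species protein pairs with alpha at or above the threshold."""
    if not 0.0 <= alpha_threshold <= 1.0:
        raise ValueError(f"alpha threshold must lie in [0,1], got {alpha_threshold}")
    pairs = [
        compute_alpha(pa, pb, domain_map, groups)
        for pa, pb in _candidate_pairs(groups, domain_map)
    ]
    kept = [p for p in pairs if p.alpha >= alpha_threshold]
    return sorted(kept, key=lambda p: (p.protein_a, p.protein_b))


def find_discordant(
    groups: Sequence[OrthologGroup],
    domain_map: DomainInfo,
    strict: bool = True,
) -> list[DiscordanceRecord]:
    """Detect discordant domain orthology.

    For every protein whose domains are orthologous to domains on more than
    one partner protein, a record lists each partner with the subset of the
    primary's domains it matches.  In strict mode (the default) the record
    is flagged discordant iff at least two partners hold mutually exclusive
    (disjoint) subsets; the relaxed mode flags any two partners with
    different subsets.
    """
    # primary protein -> partner protein -> set of primary-domain ids
    matches: dict[str, dict[str, set[str]]] = {}
    for g in groups:
        by_species: dict[str, list[str]] = {}
        for m in g.members:
            by_species.setdefault(m.species, []).append(m.id)
        species = sorted(by_species)
        if len(species) != 2:
            continue
        for da in by_species[species[0]]:
            for db in by_species[species[1]]:
                pa, pb = domain_map.protein_of[da], domain_map.protein_of[db]
                matches.setdefault(pa, {}).setdefault(pb, set()).add(da)
                matches.setdefault(pb, {}).setdefault(pa, set()).add(db)

    records: list[DiscordanceRecord] = []
    for primary in sorted(matches):
        partners = matches[primary]
        if len(partners) < 2:
            continue
        secondaries = sorted(
            (partner, frozenset(domains)) for partner, domains in partners.items()
        )
        subsets = [domains for _, domains in secondaries]
        if strict:
            flagged = any(
                subsets[i].isdisjoint(subsets[j])
                for i in range(len(subsets))
                for j in range(i + 1, len(subsets))
            )
        else:
            flagged = any(
                subsets[i] != subsets[j]
                for i in range(len(subsets))
                for j in range(i + 1, len(subsets))
            )
        records.append(
            DiscordanceRecord(primary=primary, secondaries=secondaries,
                              is_discordant=flagged)
        )
    return records


def _fulllength_pairs_and_assignment(
    fulllength_groups: Sequence[OrthologGroup],
) -> tuple[set[frozenset[str]], dict[str, str]]:
    """Co-membership pairs and protein -> group-id assignment."""
    pairs: set[frozenset[str]] = set()
    assignment: dict[str, str] = {}
    for g in fulllength_groups:
        by_species: dict[str, list[str]] = {}
        for m in g.members:
            assignment[m.id] = g.group_id
            by_species.setdefault(m.species, []).append(m.id)
        species = sorted(by_species)
        if len(species) != 2:
            continue
        for pa in by_species[species[0]]:
            for pb in by_species[species[1]]:
                pairs.add(frozenset((pa, pb)))
    return pairs, assignment


def merge_with_fulllength(
    domain_pairs: Sequence[ProteinPair],
    fulllength_groups: Sequence[OrthologGroup],
) -> list[tuple[frozenset[str], str]]:
    """Enrich a full-length method's pairs with domain-derived ones.

    Every full-length co-membership pair is kept.  A domain-derived pair is
    added unless the full-length method assigned both of its proteins to
    groups that do not place them together (a conflicting assignment, in
    which case the full-length calls stand).  Each merged pair is tagged
    ``both``, ``fulllength_only`` or ``domain_only``.
    """
    fl_pairs, assignment = _fulllength_pairs_and_assignment(fulllength_groups)
    domain_keys = {p.key for p in domain_pairs}

    merged: list[tuple[frozenset[str], str]] = []
    for pair in fl_pairs:
        tag = "both" if pair in domain_keys else "fulllength_only"
        merged.append((pair, tag))
    for pair in domain_keys - fl_pairs:
        pa, pb = sorted(pair)
        conflicting = (
            pa in assignment and pb in assignment and assignment[pa] != assignment[pb]
        )
        if not conflicting:
            merged.append((pair, "domain_only"))
    return sorted(merged, key=lambda t: (sorted(t[0]), t[1]))


def classify_pairs(
    domain_pairs: Sequence[ProteinPair],
    fulllength_groups: Sequence[OrthologGroup],
) -> dict[frozenset[str], PairCategory]:
    """Assign every pair in either set to exactly one category.

    Domain-only pairs are subdivided by how they map onto the full-length
    assignments: both proteins assigned but to different groups
    (conflicting), one protein unassigned (one missing), or neither
    assigned (two missing).
    """
    fl_pairs, assignment = _fulllength_pairs_and_assignment(fulllength_groups)
    domain_keys = {p.key for p in domain_pairs}

    categories: dict[frozenset[str], PairCategory] = {}
    for pair in fl_pairs | domain_keys:
        if pair in fl_pairs and pair in domain_keys:
            categories[pair] = PairCategory.BOTH
        elif pair in fl_pairs:
            categories[pair] = PairCategory.FULLLENGTH_ONLY
        else:
            pa, pb = sorted(pair)
            n_assigned = (pa in assignment) + (pb in assignment)
            if n_assigned == 2:
                categories[pair] = PairCategory.DOMAIN_CONFLICTING
            elif n_assigned == 1:
                categories[pair] = PairCategory.DOMAIN_ONE_MISSING
            else:
                categories[pair] = PairCategory.DOMAIN_TWO_MISSING
    return categories


def jaccard_consensus(
    pairs_a: set[frozenset[str]], pairs_b: set[frozenset[str]]
) -> float:
    """Jaccard index (intersection over union) of two pair sets."""
    union = pairs_a | pairs_b
    if not union:
        raise ValueError("Jaccard index undefined for two empty pair sets")
    return len(pairs_a & pairs_b) / len(union)


def alpha_sweep(
    groups: Sequence[OrthologGroup],
    domain_map: DomainInfo,
    fulllength_groups: Sequence[OrthologGroup],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Consensus statistics across alpha thresholds.

    One row per threshold with the counts of pairs found by both routes, by
    the domain route only, by the full-length route only, and the Jaccard
    index of the two pair sets.  The domain-pair count is non-increasing in
    the threshold.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    fl_pairs, _ = _fulllength_pairs_and_assignment(fulllength_groups)
    rows = []
    for t in thresholds:
        domain_keys = {p.key for p in project_protein_pairs(groups, domain_map, t)}
        union = domain_keys | fl_pairs
        rows.append({
            "alpha_threshold": t,
            "n_domain_pairs": len(domain_keys),
            "n_fulllength_pairs": len(fl_pairs),
            "n_both": len(domain_keys & fl_pairs),
            "n_domain_only": len(domain_keys - fl_pairs),
            "n_fulllength_only": len(fl_pairs - domain_keys),
            "jaccard": (jaccard_consensus(domain_keys, fl_pairs) if union else 0.0),
        })
    return pd.DataFrame(rows)
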