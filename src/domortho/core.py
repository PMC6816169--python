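"""InParanoid-style clustering of domain sequences into ortholog groups.

Given filtered cross-species and within-species similarity hits, mutual
best hits between the two species define seed ortholog pairs.  Around each
seed, within-species sequences whose bitscore to the seed member does not
fall below the seed pair's own bitscore are recruited as inparalogs.  Seeds
plus recruits form ortholog groups; overlapping groups are made disjoint by
keeping each shared member in the group with the stronger seed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .model import GroupMember, OrthologGroup, SeedPair, SimilarityHit

__all__ = [
    "find_seed_orthologs",
    "recruit_inparalogs",
    "resolve_group_conflicts",
    "groups_to_domain_pairs",
    "build_groups",
]

logger = logging.getLogger(__name__)


def find_seed_orthologs(
    cross_hits: Iterable[SimilarityHit],
    species_of: Mapping[str, str],
    species_a: str,
    species_b: str,
) -> list[SeedPair]:
    """Mutual best cross-species hits.

    ``(a, b)`` is a seed iff b is a's best-scoring hit in the other species
    and a is b's best.  The two hit orientations of a pair are merged (max
    bitscore) before ranking, so one-directional hit lists work too.  Ties
    are broken by the lexicographically smallest partner id, so each
    sequence has exactly one best partner.
    """
    pair_score: dict[tuple[str, str], float] = {}
    for hit in cross_hits:
        sq = species_of[hit.query_id]
        ss = species_of[hit.subject_id]
        if {sq, ss} != {species_a, species_b}:
            continue
        a, b = ((hit.query_id, hit.subject_id) if sq == species_a
                else (hit.subject_id, hit.query_id))
        key = (a, b)
        pair_score[key] = max(pair_score.get(key, 0.0), hit.bitscore)

    best_a: dict[str, tuple[str, float]] = {}
    best_b: dict[str, tuple[str, float]] = {}
    # Sorted iteration makes the lexicographic tie-break explicit: the first
    # partner reaching the maximal score wins.
    for (a, b), score in sorted(pair_score.items()):
        if a not in best_a or score > best_a[a][1]:
            best_a[a] = (b, score)
    for (a, b), score in sorted(pair_score.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if b not in best_b or score > best_b[b][1]:
            best_b[b] = (a, score)

    seeds: list[SeedPair] = []
    for a, (b, score) in sorted(best_a.items()):
        if best_b[b][0] == a:
            seeds.append(SeedPair(member_a=a, member_b=b, score=score))
    return seeds


def recruit_inparalogs(
    seed: SeedPair,
    within_hits_a: Iterable[SimilarityHit],
    within_hits_b: Iterable[SimilarityHit],
    species_a: str,
    species_b: str,
    group_id: str = "G1",
) -> OrthologGroup:
    """Recruit within-species inparalogs around one seed pair.

    A sequence s of the same species as seed member m joins the group iff
    its bitscore to m is at least the seed pair's bitscore ("does not fall
    below" — the boundary is inclusive).  Seed members are always included.
    """
    def recruits(seed_member: str, hits: Iterable[SimilarityHit]) -> dict[str, float]:
        scores: dict[str, float] = {}
        for h in hits:
            if h.subject_id == seed_member and h.query_id != seed_member:
                scores[h.query_id] = max(scores.get(h.query_id, 0.0), h.bitscore)
            elif h.query_id == seed_member and h.subject_id != seed_member:
                scores[h.subject_id] = max(scores.get(h.subject_id, 0.0), h.bitscore)
        return {s: sc for s, sc in scores.items() if sc >= seed.score}

    members = [
        GroupMember(id=seed.member_a, species=species_a,
                    score_to_seed=seed.score, is_seed=True),
        GroupMember(id=seed.member_b, species=species_b,
                    score_to_seed=seed.score, is_seed=True),
    ]
    for sid, score in sorted(recruits(seed.member_a, within_hits_a).items()):
        if sid != seed.member_a:
            members.append(GroupMember(id=sid, species=species_a,
                                       score_to_seed=score, is_seed=False))
    for sid, score in sorted(recruits(seed.member_b, within_hits_b).items()):
        if sid != seed.member_b:
            members.append(GroupMember(id=sid, species=species_b,
                                       score_to_seed=score, is_seed=False))
    return OrthologGroup(group_id=group_id, seed=seed, members=members)


def resolve_group_conflicts(groups: Sequence[OrthologGroup]) -> list[OrthologGroup]:
    """Make groups disjoint.

    A sequence appearing in several groups stays in the one with the higher
    seed score (tie: lexicographically smaller seed pair).  Groups reduced
    below one member per species are deleted, with the reason logged.
    """
    # Priority: higher seed score first, then smaller seed ids.
    def priority(g: OrthologGroup) -> tuple[float, str, str]:
        return (-g.seed.score, g.seed.member_a, g.seed.member_b)

    ordered = sorted(groups, key=priority)
    owner: dict[str, str] = {}
    for g in ordered:
        for m in g.members:
            owner.setdefault(m.id, g.group_id)

    resolved: list[OrthologGroup] = []
    for g in ordered:
        members = [m for m in g.members if owner[m.id] == g.group_id]
        species_present = {m.species for m in members}
        all_species = {m.species for m in g.members}
        if species_present == all_species and len(all_species) >= 2:
            resolved.append(OrthologGroup(group_id=g.group_id, seed=g.seed,
                                          members=members))
        else:
            logger.info(
                "group %s (seed %s/%s, %.1f bits) deleted: lost all members "
                "of one species to stronger groups",
                g.group_id, g.seed.member_a, g.seed.member_b, g.seed.score,
            )
    return sorted(resolved, key=lambda g: g.group_id)


def groups_to_domain_pairs(
    groups: Sequence[OrthologGroup],
) -> list[tuple[str, str, str]]:
    """All cross-species member pairs, annotated with their group id."""
    pairs: list[tuple[str, str, str]] = []
    for g in groups:
        species = g.species
        if len(species) != 2:
            continue
        sa, sb = species
        for ma in g.members_of(sa):
            for mb in g.members_of(sb):
                pairs.append((ma.id, mb.id, g.group_id))
    return sorted(pairs)


def build_groups(
    cross_hits: Sequence[SimilarityHit],
    within_hits_a: Sequence[SimilarityHit],
    within_hits_b: Sequence[SimilarityHit],
    species_of: Mapping[str, str],
    species_a: str,
    species_b: str,
) -> list[OrthologGroup]:
    """Full clustering: seeds -> inparalog recruitment -> conflict resolution.

    Group ids are assigned deterministically (descending seed score, then
    seed ids).
    """
    seeds = find_seed_orthologs(cross_hits, species_of, species_a, species_b)
    seeds = sorted(seeds, key=lambda s: (-s.score, s.member_a, s.member_b))
    width = max(4, len(str(len(seeds))))
    groups = [
        recruit_inparalogs(seed, within_hits_a, within_hits_b,
                           species_a, species_b, group_id=f"G{i + 1:0{width}d}")
        for i, seed in enumerate(seeds)
    ]
    return resolve_group_conflicts(groups)
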