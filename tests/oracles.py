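"""Independent reference implementations used only by the tests.

Deliberately naive: quadratic DP alignment, per-residue interval marking,
and a direct transcription of the seed/inparalog/conflict rules over plain
score dictionaries.  None of them share code with the package.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_raw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman raw score, affine gaps in the BLAST convention
    (a gap of length n costs gap_open + n * gap_extend)."""
    n, m = len(a), len(b)
    NEG = -10 ** 9
    best = 0
    h_prev = [0] * (m + 1)
    e_prev = [NEG] * (m + 1)
    for i in range(1, n + 1):
        h_cur = [0] * (m + 1)
        e_cur = [NEG] * (m + 1)
        f = NEG
        for j in range(1, m + 1):
            e_cur[j] = max(h_prev[j] - gap_open - gap_extend,
                           e_prev[j] - gap_extend)
            f = max(h_cur[j - 1] - gap_open - gap_extend, f - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            h_cur[j] = max(0, h_prev[j - 1] + s, e_cur[j], f)
            best = max(best, h_cur[j])
        h_prev, e_prev = h_cur, e_cur
    return int(best)


def bits_from_raw(raw: float, lam: float = 0.267, k: float = 0.041) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def union_coverage(intervals: list[tuple[int, int]], length: int) -> float:
    """Coverage fraction by per-residue marking (1-based inclusive)."""
    marked = [False] * (length + 1)
    for s, e in intervals:
        for i in range(s, e + 1):
            marked[i] = True
    return sum(marked[1:]) / length


def brute_force_cluster(
    cross: dict[tuple[str, str], float],
    within_a: dict[frozenset[str], float],
    within_b: dict[frozenset[str], float],
):
    """Direct transcription of the clustering rules.

    cross maps (a_id, b_id) -> bitscore (symmetric); within_* map unordered
    id pairs -> bitscore.  Returns a set of
    (seed_a, seed_b, frozenset(member ids)) triples for the surviving
    disjoint groups.
    """
    a_ids = sorted({a for a, _ in cross})
    b_ids = sorted({b for _, b in cross})
    # recruitment candidates include sequences that only have within hits
    all_a = sorted(set(a_ids) | {x for k in within_a for x in k})
    all_b = sorted(set(b_ids) | {x for k in within_b for x in k})

    def best(partners: list[tuple[str, float]]) -> str | None:
        if not partners:
            return None
        top = max(score for _, score in partners)
        return min(p for p, score in partners if score == top)

    best_a = {a: best([(b, cross[(a, b)]) for b in b_ids if (a, b) in cross])
              for a in a_ids}
    best_b = {b: best([(a, cross[(a, b)]) for a in a_ids if (a, b) in cross])
              for b in b_ids}
    seeds = [(a, best_a[a], cross[(a, best_a[a])])
             for a in a_ids
             if best_a[a] is not None and best_b[best_a[a]] == a]

    groups = []
    for a, b, score in seeds:
        members = {a: "A", b: "B"}
        for x in all_a:
            if x != a and within_a.get(frozenset((x, a)), -1.0) >= score:
                members[x] = "A"
        for y in all_b:
            if y != b and within_b.get(frozenset((y, b)), -1.0) >= score:
                members[y] = "B"
        groups.append((a, b, score, members))

    # Conflict resolution: strongest group (tie: smaller seed ids) keeps a
    # shared member; groups losing a whole species side are deleted.
    ordered = sorted(groups, key=lambda g: (-g[2], g[0], g[1]))
    owner: dict[str, tuple[str, str]] = {}
    for a, b, score, members in ordered:
        for mid in members:
            owner.setdefault(mid, (a, b))
    result = set()
    for a, b, score, members in ordered:
        kept = {mid: sp for mid, sp in members.items() if owner[mid] == (a, b)}
        if set(kept.values()) == {"A", "B"}:
            result.add((a, b, frozenset(kept)))
    return result


def alpha_by_hand(domains_x: list[str], domains_y: list[str],
                  group_members: list[set[str]]) -> tuple[int, int]:
    """Numerator and denominator of alpha, counted directly."""
    shared = 0
    for g in group_members:
        if g & set(domains_x) and g & set(domains_y):
            shared += len(g & set(domains_x)) + len(g & set(domains_y))
    return shared, len(domains_x) + len(domains_y)
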