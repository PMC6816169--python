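import random

import pytest

from domortho.model import DomainSequence, GroupMember, OrthologGroup, SeedPair
from domortho.protein import (
    PairCategory,
    alpha_sweep,
    build_domain_map,
    classify_pairs,
    compute_alpha,
    find_discordant,
    jaccard_consensus,
    merge_with_fulllength,
    project_protein_pairs,
)
from oracles import alpha_by_hand


def dseq(sid, protein_id, species, label="D", category="pfam_domain"):
    return DomainSequence(id=sid, protein_id=protein_id, species=species,
                          start=1, end=10, label=label, category=category,
                          sequence="ACDEFGHIKL")


def group(gid, members, score=100.0):
    """members: list of (domain_id, species); first two are the seed."""
    gm = [GroupMember(id=m, species=sp, score_to_seed=score, is_seed=i < 2)
          for i, (m, sp) in enumerate(members)]
    return OrthologGroup(group_id=gid,
                         seed=SeedPair(members[0][0], members[1][0], score),
                         members=gm)


def shared_architecture_case():
    """Protein X carries domains of families A, B, C; protein Y carries A
    and C; the A instances and the C instances each form a group."""
    domains = [
        dseq("X/A/1", "X", "spA"), dseq("X/B/1", "X", "spA"),
        dseq("X/C/1", "X", "spA"),
        dseq("Y/A/1", "Y", "spB"), dseq("Y/C/1", "Y", "spB"),
    ]
    groups = [
        group("G1", [("X/A/1", "spA"), ("Y/A/1", "spB")]),
        group("G2", [("X/C/1", "spA"), ("Y/C/1", "spB")]),
    ]
    return build_domain_map(domains), groups


class TestComputeAlpha:
    def test_partial_architecture_overlap(self):
        domain_map, groups = shared_architecture_case()
        pair = compute_alpha("X", "Y", domain_map, groups)
        assert (pair.n_shared, pair.n_total) == (4, 5)
        assert pair.alpha == pytest.approx(4 / 5)
        assert pair.supporting_groups == ("G1", "G2")

    def test_matches_hand_count(self):
        domain_map, groups = shared_architecture_case()
        pair = compute_alpha("X", "Y", domain_map, groups)
        by_hand = alpha_by_hand(
            ["X/A/1", "X/B/1", "X/C/1"], ["Y/A/1", "Y/C/1"],
            [{"X/A/1", "Y/A/1"}, {"X/C/1", "Y/C/1"}],
        )
        assert (pair.n_shared, pair.n_total) == by_hand

    def test_no_shared_groups_alpha_zero(self):
        domain_map, _ = shared_architecture_case()
        pair = compute_alpha("X", "Y", domain_map, [])
        assert pair.alpha == 0.0

    def test_single_domain_pair_alpha_one(self):
        domains = [dseq("X/A/1", "X", "spA"), dseq("Y/A/1", "Y", "spB")]
        groups = [group("G1", [("X/A/1", "spA"), ("Y/A/1", "spB")])]
        pair = compute_alpha("X", "Y", build_domain_map(domains), groups)
        assert (pair.n_shared, pair.n_total, pair.alpha) == (2, 2, 1.0)

    def test_monotonicity_in_shared_and_unshared_instances(self):
        domain_map, groups = shared_architecture_case()
        base = compute_alpha("X", "Y", domain_map, groups).alpha
        # dropping a shared group lowers alpha
        assert compute_alpha("X", "Y", domain_map, groups[:1]).alpha < base
        # adding a non-shared domain instance to X lowers alpha too
        domains_plus = [
            dseq("X/A/1", "X", "spA"), dseq("X/B/1", "X", "spA"),
            dseq("X/C/1", "X", "spA"), dseq("X/UNK1/1", "X", "spA", "UNK1",
                                            "unknown_region"),
            dseq("Y/A/1", "Y", "spB"), dseq("Y/C/1", "Y", "spB"),
        ]
        diluted = compute_alpha("X", "Y", build_domain_map(domains_plus), groups)
        assert diluted.alpha < base

    def test_unknown_and_orphan_instances_count_in_denominator(self):
        domains = [
            dseq("X/A/1", "X", "spA"),
            dseq("X/UNK1/1", "X", "spA", "UNK1", "unknown_region"),
            dseq("Y/ORPHAN/1", "Y", "spB", "ORPHAN", "orphan"),
        ]
        groups = [group("G1", [("X/A/1", "spA"), ("Y/ORPHAN/1", "spB")])]
        pair = compute_alpha("X", "Y", build_domain_map(domains), groups)
        assert (pair.n_shared, pair.n_total) == (2, 3)


class TestProjectProteinPairs:
    def test_threshold_inclusive(self):
        domain_map, groups = shared_architecture_case()
        assert [p.key for p in project_protein_pairs(groups, domain_map, 0.3)] \
               == [frozenset({"X", "Y"})]
        assert [p.key for p in project_protein_pairs(groups, domain_map, 0.8)] \
               == [frozenset({"X", "Y"})]
        assert project_protein_pairs(groups, domain_map, 0.9) == []

    def test_threshold_zero_reports_every_candidate(self):
        domain_map, groups = shared_architecture_case()
        assert len(project_protein_pairs(groups, domain_map, 0.0)) == 1

    def test_invalid_threshold_error(self):
        domain_map, groups = shared_architecture_case()
        with pytest.raises(ValueError):
            project_protein_pairs(groups, domain_map, 1.5)


def fusion_case():
    """A fused two-domain protein whose domains match two single-domain
    partner proteins."""
    domains = [
        dseq("F/PRK/1", "F", "spA"), dseq("F/UPRT/1", "F", "spA"),
        dseq("S1/PRK/1", "S1", "spB"), dseq("S2/UPRT/1", "S2", "spB"),
    ]
    groups = [
        group("G1", [("F/PRK/1", "spA"), ("S1/PRK/1", "spB")]),
        group("G2", [("F/UPRT/1", "spA"), ("S2/UPRT/1", "spB")]),
    ]
    return build_domain_map(domains), groups


class TestFindDiscordant:
    def test_fusion_scenario_flagged(self):
        domain_map, groups = fusion_case()
        records = {r.primary: r for r in find_discordant(groups, domain_map)}
        assert records["F"].is_discordant
        subsets = [d for _, d in records["F"].secondaries]
        assert subsets[0].isdisjoint(subsets[1])

    def test_single_partner_no_record(self):
        domains = [dseq("X/A/1", "X", "spA"), dseq("Y/A/1", "Y", "spB")]
        groups = [group("G1", [("X/A/1", "spA"), ("Y/A/1", "spB")])]
        assert find_discordant(groups, build_domain_map(domains)) == []

    def test_two_partners_same_domain_not_flagged(self):
        domains = [
            dseq("X/A/1", "X", "spA"),
            dseq("S1/A/1", "S1", "spB"), dseq("S2/A/1", "S2", "spB"),
        ]
        groups = [group("G1", [("X/A/1", "spA"), ("S1/A/1", "spB"),
                               ("S2/A/1", "spB")])]
        records = find_discordant(groups, build_domain_map(domains))
        rec = next(r for r in records if r.primary == "X")
        assert not rec.is_discordant

    def test_relaxed_mode_flags_different_subsets(self):
        # partner S1 matches {d1}, partner S2 matches {d1, d2}: different
        # but not disjoint
        domains = [
            dseq("X/A/1", "X", "spA"), dseq("X/B/1", "X", "spA"),
            dseq("S1/A/1", "S1", "spB"),
            dseq("S2/A/1", "S2", "spB"), dseq("S2/B/1", "S2", "spB"),
        ]
        groups = [
            group("G1", [("X/A/1", "spA"), ("S1/A/1", "spB"),
                         ("S2/A/1", "spB")]),
            group("G2", [("X/B/1", "spA"), ("S2/B/1", "spB")]),
        ]
        dm = build_domain_map(domains)
        strict = next(r for r in find_discordant(groups, dm) if r.primary == "X")
        relaxed = next(r for r in find_discordant(groups, dm, strict=False)
                       if r.primary == "X")
        assert not strict.is_discordant
        assert relaxed.is_discordant

    def test_flags_invariant_under_group_relabeling(self):
        domain_map, groups = fusion_case()
        relabeled = [OrthologGroup(group_id=f"Z{i}", seed=g.seed,
                                   members=g.members)
                     for i, g in enumerate(groups)]
        orig = {(r.primary, r.is_discordant)
                for r in find_discordant(groups, domain_map)}
        new = {(r.primary, r.is_discordant)
               for r in find_discordant(relabeled, domain_map)}
        assert orig == new


def fl_group(gid, a_members, b_members):
    members = [GroupMember(id=m, species="spA", score_to_seed=0.0,
                           is_seed=False) for m in a_members]
    members += [GroupMember(id=m, species="spB", score_to_seed=0.0,
                            is_seed=False) for m in b_members]
    return OrthologGroup(group_id=gid,
                         seed=SeedPair(a_members[0], b_members[0], 1.0),
                         members=members)


def ppair(a, b):
    from domortho.model import ProteinPair
    return ProteinPair(protein_a=a, protein_b=b, n_shared=2, n_total=2)


class TestMergeWithFulllength:
    def test_pair_in_both_emitted_once_tagged_both(self):
        merged = merge_with_fulllength([ppair("P", "Q")],
                                       [fl_group("F1", ["P"], ["Q"])])
        assert merged == [(frozenset({"P", "Q"}), "both")]

    def test_conflicting_domain_pair_dropped(self):
        fl = [fl_group("F1", ["P"], ["R"]), fl_group("F2", ["S"], ["Q"])]
        merged = merge_with_fulllength([ppair("P", "Q")], fl)
        tags = {tuple(sorted(p)): t for p, t in merged}
        assert ("P", "Q") not in tags
        assert tags == {("P", "R"): "fulllength_only",
                        ("Q", "S"): "fulllength_only"}

    def test_unassigned_domain_pair_added(self):
        fl = [fl_group("F1", ["X"], ["Y"])]
        merged = merge_with_fulllength([ppair("P", "Q")], fl)
        tags = {tuple(sorted(p)): t for p, t in merged}
        assert tags[("P", "Q")] == "domain_only"

    def test_output_superset_of_fulllength_pairs(self):
        fl = [fl_group("F1", ["P", "P2"], ["Q"]), fl_group("F2", ["R"], ["S"])]
        merged = {p for p, _ in merge_with_fulllength([ppair("P", "S")], fl)}
        assert {frozenset({"P", "Q"}), frozenset({"P2", "Q"}),
                frozenset({"R", "S"})} <= merged


class TestClassifyPairs:
    def test_categories_partition_pair_universe(self):
        fl = [fl_group("F1", ["P"], ["Q"]), fl_group("F2", ["R"], ["S"])]
        domain_pairs = [ppair("P", "Q"),   # both
                        ppair("P", "S"),   # conflicting
                        ppair("R", "T"),   # one missing
                        ppair("U", "V")]   # two missing
        cats = classify_pairs(domain_pairs, fl)
        assert cats[frozenset({"P", "Q"})] == PairCategory.BOTH
        assert cats[frozenset({"P", "S"})] == PairCategory.DOMAIN_CONFLICTING
        assert cats[frozenset({"R", "T"})] == PairCategory.DOMAIN_ONE_MISSING
        assert cats[frozenset({"U", "V"})] == PairCategory.DOMAIN_TWO_MISSING
        assert cats[frozenset({"R", "S"})] == PairCategory.FULLLENGTH_ONLY
        # every pair in either set categorized exactly once
        universe = {p.key for p in domain_pairs} | {frozenset({"P", "Q"}),
                                                    frozenset({"R", "S"})}
        assert set(cats) == universe


class TestJaccard:
    def test_identical_sets(self):
        s = {frozenset({"a", "b"})}
        assert jaccard_consensus(s, set(s)) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_consensus({frozenset({"a", "b"})},
                                 {frozenset({"c", "d"})}) == 0.0

    def test_partial_overlap(self):
        a = {frozenset({"a", str(i)}) for i in range(3)}
        b = set(list(a)[:2]) | {frozenset({"x", "y"})}
        assert jaccard_consensus(a, b) == pytest.approx(2 / 4)

    def test_both_empty_error(self):
        with pytest.raises(ValueError):
            jaccard_consensus(set(), set())

    def test_matches_brute_force_on_random_sets(self):
        rng = random.Random(21)
        for _ in range(30):
            a = {frozenset((f"p{rng.randint(0, 9)}", f"q{rng.randint(0, 9)}"))
                 for _ in range(rng.randint(1, 15))}
            b = {frozenset((f"p{rng.randint(0, 9)}", f"q{rng.randint(0, 9)}"))
                 for _ in range(rng.randint(1, 15))}
            inter = sum(1 for x in a if x in b)
            union = len(a) + len(b) - inter
            assert jaccard_consensus(a, b) == pytest.approx(inter / union)


class TestAlphaSweep:
    def test_eleven_thresholds_and_monotonicity(self):
        domain_map, groups = shared_architecture_case()
        fl = [fl_group("F1", ["X"], ["Y"])]
        thresholds = [round(0.1 * i, 1) for i in range(11)]
        table = alpha_sweep(groups, domain_map, fl, thresholds)
        assert len(table) == 11
        counts = table["n_domain_pairs"].tolist()
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == max(counts)

    def test_jaccard_column_matches_recomputation(self):
        domain_map, groups = shared_architecture_case()
        fl = [fl_group("F1", ["X"], ["Y"])]
        thresholds = [0.0, 0.5, 1.0]
        table = alpha_sweep(groups, domain_map, fl, thresholds)
        for _, row in table.iterrows():
            domain_pairs = {p.key for p in project_protein_pairs(
                groups, domain_map, row["alpha_threshold"])}
            fl_pairs = {frozenset({"X", "Y"})}
            assert row["jaccard"] == pytest.approx(
                jaccard_consensus(domain_pairs, fl_pairs))
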