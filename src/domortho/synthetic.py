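"""Synthetic two-species proteomes with known domain-level history.

Two descendant proteomes are generated from a shared ancestral proteome
built over an alphabet of unique ancestral domain families.  Each ancestral
protein is a chain of domains joined by linkers (or, once the family pool
is exhausted, a domain-free orphan), and evolves into the two species under
independent residue substitutions plus optional structural events applied
to the second lineage: fusion of two proteins, fission of a multi-domain
protein, whole-protein duplication (creating inparalogs), and single-domain
loss.  Because every family occurs exactly once in the ancestor, the
ground-truth orthology of every domain, linker and orphan is unambiguous
and is recorded event-by-event.

Substitutions replace a residue with a uniformly chosen different residue;
there are no indels, so true coordinates stay exact and the emitted
annotations can use them directly.  Linker lengths straddle the minimum
unknown-region length so that unknown-region emission is exercised on both
sides of the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import (
    AMINO_ACIDS,
    ORPHAN_LABEL,
    DomainAnnotation,
    ProteinRecord,
    domain_sequence_id,
)

__all__ = ["EvolutionScenario", "GroundTruth", "generate", "score_recovery"]


@dataclass
class EvolutionScenario:
    """Parameters of the two-species evolution simulation.

    ``substitution_rate`` is the expected fraction of substituted residues
    per lineage (each species' copy diverges independently from the
    ancestor at this rate).  Event probabilities apply per ancestral
    protein; structural events are mutually exclusive per protein and
    affect species B only.  ``min_unknown_len`` must match the extraction
    config for the recorded unknown-region truth to align with the
    pipeline's cuts.
    """

    n_ancestral_domains: int = 20
    domain_length_range: tuple[int, int] = (60, 150)
    linker_length_range: tuple[int, int] = (10, 50)
    n_proteins: int = 30
    p_fusion: float = 0.1
    p_fission: float = 0.1
    p_duplication: float = 0.1
    p_loss: float = 0.05
    substitution_rate: float = 0.1
    rng_seed: int = 0
    max_domains_per_protein: int = 3
    min_unknown_len: int = 30
    species_a: str = "spA"
    species_b: str = "spB"

    def __post_init__(self) -> None:
        for name in ("p_fusion", "p_fission", "p_duplication", "p_loss",
                     "substitution_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        for name in ("domain_length_range", "linker_length_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive (lo, hi) range")
        if self.n_ancestral_domains < 1 or self.n_proteins < 1:
            raise ValueError("counts must be positive")
        if self.max_domains_per_protein < 1:
            raise ValueError("max_domains_per_protein must be >= 1")


@dataclass
class GroundTruth:
    """True orthology of the generated proteomes.

    Pair sets are unordered (frozenset) id pairs; domain pairs use the same
    ``<protein>/<label>/<start>-<end>`` id scheme as the extraction stage.
    """

    true_domain_pairs: set[frozenset[str]] = field(default_factory=set)
    true_protein_pairs: set[frozenset[str]] = field(default_factory=set)
    true_discordant_primaries: set[str] = field(default_factory=set)


# Internal part representation: a protein architecture is a list of parts,
# each ("domain", family_name, ancestral_seq, part_uid) or
# ("linker", None, ancestral_seq, part_uid).  part_uid identifies the
# ancestral part so descendant cuts can be matched into truth pairs.
_Part = tuple[str, str | None, str, str]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        current = chars[i]
        choices = AMINO_ACIDS.replace(current, "")
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def _assemble(
    protein_id: str,
    species: str,
    parts: list[_Part],
    rate: float,
    rng: np.random.Generator,
    min_unknown_len: int,
) -> tuple[ProteinRecord, list[DomainAnnotation], dict[str, str]]:
    """Mutate and concatenate parts; return the protein, its annotations,
    and a part_uid -> emitted-cut-id map (linkers below the unknown-length
    threshold are absent from the map)."""
    seq_parts: list[str] = []
    annotations: list[DomainAnnotation] = []
    cut_ids: dict[str, str] = {}
    pos = 1
    unk_counter = 0
    for kind, family, ancestral, uid in parts:
        mutated = _mutate(ancestral, rate, rng)
        start, end = pos, pos + len(mutated) - 1
        if kind == "domain":
            annotations.append(
                DomainAnnotation(protein_id=protein_id, start=start, end=end,
                                 name=family, family_type="Domain",
                                 source="synthetic")
            )
            cut_ids[uid] = domain_sequence_id(protein_id, family, start, end)
        elif kind == "orphan":
            cut_ids[uid] = domain_sequence_id(protein_id, ORPHAN_LABEL, start, end)
        else:  # linker
            if len(mutated) > min_unknown_len:
                unk_counter += 1
                cut_ids[uid] = domain_sequence_id(
                    protein_id, f"UNK{unk_counter}", start, end
                )
        seq_parts.append(mutated)
        pos = end + 1
    record = ProteinRecord(id=protein_id, species=species,
                          sequence="".join(seq_parts))
    return record, annotations, cut_ids


def _strip_boundary_linkers(parts: list[_Part]) -> list[_Part]:
    while parts and parts[0][0] == "linker":
        parts = parts[1:]
    while parts and parts[-1][0] == "linker":
        parts = parts[:-1]
    return parts


def generate(
    scenario: EvolutionScenario,
) -> tuple[list[ProteinRecord], list[ProteinRecord],
           list[DomainAnnotation], list[DomainAnnotation], GroundTruth]:
    """Generate two proteomes, their annotations, and the ground truth."""
    rng = np.random.default_rng(scenario.rng_seed)
    lo_d, hi_d = scenario.domain_length_range
    lo_l, hi_l = scenario.linker_length_range

    # Ancestral domain family pool: each family is one unique sequence used
    # exactly once in the ancestral proteome.
    n_fam = scenario.n_ancestral_domains
    families = [
        (f"FAM{i + 1:04d}", _random_seq(rng, int(rng.integers(lo_d, hi_d + 1))))
        for i in range(n_fam)
    ]
    pool = list(families)

    # Architecture size distribution, truncated at the per-protein maximum.
    size_probs = np.array([0.5, 0.3, 0.2][: scenario.max_domains_per_protein])
    size_probs = size_probs / size_probs.sum()

    def new_linker(anc_id: str, idx: int) -> _Part:
        length = int(rng.integers(lo_l, hi_l + 1))
        return ("linker", None, _random_seq(rng, length), f"{anc_id}:L{idx}")

    ancestors: list[tuple[str, list[_Part]]] = []
    for p in range(scenario.n_proteins):
        anc_id = f"P{p + 1:03d}"
        if pool:
            k = min(int(rng.choice(np.arange(1, len(size_probs) + 1), p=size_probs)),
                    len(pool))
            parts: list[_Part] = []
            for j in range(k):
                fam, seq = pool.pop(0)
                if j > 0:
                    parts.append(new_linker(anc_id, j))
                parts.append(("domain", fam, seq, f"{anc_id}:D{fam}"))
        else:
            length = int(rng.integers(lo_d, hi_d + 1))
            parts = [("orphan", None, _random_seq(rng, length), f"{anc_id}:O")]
        ancestors.append((anc_id, parts))

    n_domains_of = {aid: sum(1 for k, *_ in parts if k == "domain")
                    for aid, parts in ancestors}
    if scenario.p_fission > 0 and not any(n >= 2 for n in n_domains_of.values()):
        raise ValueError(
            "fission requested but no ancestral protein has >= 2 domains"
        )

    # Structural events in the species-B lineage, mutually exclusive per
    # protein.  Fusion first: eligible proteins are marked and paired up in
    # order; the remaining proteins then draw fission / duplication / loss.
    fusion_marked = [
        aid for aid, _ in ancestors
        if n_domains_of[aid] >= 1 and rng.random() < scenario.p_fusion
    ]
    fusion_pairs = [
        (fusion_marked[i], fusion_marked[i + 1])
        for i in range(0, len(fusion_marked) - 1, 2)
    ]
    fused_parents = {aid for pair in fusion_pairs for aid in pair}

    events: dict[str, str] = {}
    for aid, _ in ancestors:
        if aid in fused_parents:
            events[aid] = "fusion"
            continue
        if n_domains_of[aid] >= 2 and rng.random() < scenario.p_fission:
            events[aid] = "fission"
        elif rng.random() < scenario.p_duplication:
            events[aid] = "duplication"
        elif n_domains_of[aid] >= 2 and rng.random() < scenario.p_loss:
            events[aid] = "loss"
        else:
            events[aid] = "none"

    # Species-B architecture plan: list of (protein_id, parts, parent_ids).
    parts_of = dict(ancestors)
    b_plan: list[tuple[str, list[_Part], list[str]]] = []
    handled: set[str] = set()
    for aid, parts in ancestors:
        if aid in handled:
            continue
        event = events[aid]
        pid = f"{scenario.species_b}_{aid}"
        if event == "fusion":
            partner = next(q for p, q in fusion_pairs if p == aid) \
                if any(p == aid for p, _ in fusion_pairs) else None
            if partner is None:
                # second member of a pair; emitted with its partner
                continue
            fused = (parts_of[aid] + [new_linker(f"{aid}+{partner}", 0)]
                     + parts_of[partner])
            b_plan.append((f"{scenario.species_b}_{aid}_{partner}", fused,
                           [aid, partner]))
            handled.update((aid, partner))
        elif event == "fission":
            dom_positions = [i for i, pt in enumerate(parts) if pt[0] == "domain"]
            split_after = int(rng.integers(0, len(dom_positions) - 1))
            cut = dom_positions[split_after] + 1
            left = _strip_boundary_linkers(parts[:cut])
            right = _strip_boundary_linkers(parts[cut:])
            b_plan.append((f"{pid}a", left, [aid]))
            b_plan.append((f"{pid}b", right, [aid]))
        elif event == "duplication":
            b_plan.append((pid, parts, [aid]))
            b_plan.append((f"{pid}dup", parts, [aid]))
        elif event == "loss":
            dom_positions = [i for i, pt in enumerate(parts) if pt[0] == "domain"]
            lost = dom_positions[int(rng.integers(0, len(dom_positions)))]
            reduced = parts[:max(0, lost - 1)] + parts[lost + 1:]
            b_plan.append((pid, _strip_boundary_linkers(reduced), [aid]))
        else:
            b_plan.append((pid, parts, [aid]))
        handled.add(aid)

    # Assemble both proteomes.  part_uid -> cut ids per side; species B may
    # contribute several cuts per ancestral part (duplication).
    proteome_a: list[ProteinRecord] = []
    proteome_b: list[ProteinRecord] = []
    annotations_a: list[DomainAnnotation] = []
    annotations_b: list[DomainAnnotation] = []
    a_cuts: dict[str, str] = {}
    b_cuts: dict[str, list[str]] = {}
    b_protein_of_parent: dict[str, list[str]] = {}

    for aid, parts in ancestors:
        record, anns, cut_ids = _assemble(
            f"{scenario.species_a}_{aid}", scenario.species_a, parts,
            scenario.substitution_rate, rng, scenario.min_unknown_len,
        )
        proteome_a.append(record)
        annotations_a.extend(anns)
        a_cuts.update(cut_ids)

    for pid, parts, parents in b_plan:
        record, anns, cut_ids = _assemble(
            pid, scenario.species_b, parts,
            scenario.substitution_rate, rng, scenario.min_unknown_len,
        )
        proteome_b.append(record)
        annotations_b.extend(anns)
        for uid, cid in cut_ids.items():
            b_cuts.setdefault(uid, []).append(cid)
        for parent in parents:
            b_protein_of_parent.setdefault(parent, []).append(pid)

    truth = GroundTruth()
    for uid, a_id in a_cuts.items():
        for b_id in b_cuts.get(uid, ()):
            truth.true_domain_pairs.add(frozenset((a_id, b_id)))
    for aid, _ in ancestors:
        a_pid = f"{scenario.species_a}_{aid}"
        for b_pid in b_protein_of_parent.get(aid, ()):
            truth.true_protein_pairs.add(frozenset((a_pid, b_pid)))

    # Discordance truth: a fused species-B protein holds domains orthologous
    # to its two species-A parents (disjoint subsets by construction); a
    # fissioned ancestor's species-A protein holds domains orthologous to
    # the two species-B fragments.
    for p, q in fusion_pairs:
        fused_pid = b_protein_of_parent[p][0]
        truth.true_discordant_primaries.add(fused_pid)
    for aid, event in events.items():
        if event == "fission":
            truth.true_discordant_primaries.add(f"{scenario.species_a}_{aid}")

    return proteome_a, proteome_b, annotations_a, annotations_b, truth


def score_recovery(
    inferred_pairs: Iterable[frozenset[str] | tuple[str, str]],
    truth_pairs: Iterable[frozenset[str] | tuple[str, str]],
) -> tuple[float, float]:
    """Precision and recall of an inferred pair set against the truth.

    Precision is defined as 1.0 for an empty inferred set; an empty truth
    set is an error.
    """
    inferred = {frozenset(p) for p in inferred_pairs}
    truth = {frozenset(p) for p in truth_pairs}
    if not truth:
        raise ValueError("truth pair set is empty")
    if not inferred:
        return 1.0, 0.0
    tp = len(inferred & truth)
    return tp / len(inferred), tp / len(truth)
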