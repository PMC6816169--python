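"""Similarity scoring between domain sequences.

The built-in scorer runs Smith-Waterman local alignment (BLOSUM62, affine
gaps, open 11 / extend 1 in the BLAST convention) and converts the raw
score S to bits with the gapped Karlin-Altschul constants for that scheme:

    bits = (lambda * S - ln K) / ln 2,   lambda = 0.267, K = 0.041

Alternatively, precomputed BLAST tabular hits can be imported through
``model.read_blast_tabular``; both routes feed the same filters and produce
identically structured hit sets.  The built-in scorer does not apply
low-complexity (SEG) masking; import BLAST output when that matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .model import EXTENDED_AMINO_ACIDS, Config, DomainSequence, SimilarityHit

__all__ = [
    "ScoringParams",
    "local_align_bitscore",
    "all_vs_all",
    "apply_hit_filters",
    "coverage_of_longer",
]


@dataclass(frozen=True)
class ScoringParams:
    """Scoring scheme of the built-in local aligner.

    Gap costs follow the BLAST convention: a gap of length n costs
    ``gap_open + n * gap_extend``.  The Karlin-Altschul constants are the
    gapped BLOSUM62-11-1 values.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def bits(self, raw_score: float) -> float:
        return (self.ka_lambda * raw_score - math.log(self.ka_k)) / math.log(2.0)


_MATRIX_CACHE: dict[str, SubstitutionMatrix] = {}


def _matrix(name: str) -> SubstitutionMatrix:
    if name not in _MATRIX_CACHE:
        if name == "BLOSUM62":
            _MATRIX_CACHE[name] = SubstitutionMatrix.std_protein_matrix()
        else:
            _MATRIX_CACHE[name] = SubstitutionMatrix(
                ProteinSequence.alphabet, ProteinSequence.alphabet, name
            )
    return _MATRIX_CACHE[name]


def _validate(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    bad = set(seq.upper()) - set(EXTENDED_AMINO_ACIDS)
    if bad:
        raise ValueError(
            f"{which} sequence contains non-amino-acid characters: "
            + "".join(sorted(bad))
        )


def local_align_bitscore(
    seq_a: str,
    seq_b: str,
    params: ScoringParams | None = None,
) -> tuple[float, tuple[int, int, int, int], int] | None:
    """Best local alignment of two amino-acid strings, in bits.

    Returns ``(bitscore, (qstart, qend, sstart, send), aligned_columns)``
    with 1-based inclusive segment coordinates, or ``None`` if no
    positive-scoring local alignment exists.  Symmetric in its arguments up
    to segment orientation.
    """
    params = params or ScoringParams()
    _validate(seq_a, "query")
    _validate(seq_b, "subject")
    # biotite charges open+(n-1)*extend for a length-n gap; shifting the
    # open penalty by one extend reproduces the BLAST open+n*extend cost.
    gap = (-(params.gap_open + params.gap_extend), -params.gap_extend)
    alignments = align_optimal(
        ProteinSequence(seq_a.upper()),
        ProteinSequence(seq_b.upper()),
        _matrix(params.matrix_name),
        gap_penalty=gap,
        local=True,
        max_number=1,
    )
    if not alignments:
        return None
    aln = alignments[0]
    if aln.score <= 0:
        return None
    trace = aln.trace
    q_cols = trace[:, 0][trace[:, 0] >= 0]
    s_cols = trace[:, 1][trace[:, 1] >= 0]
    if len(q_cols) == 0 or len(s_cols) == 0:
        return None
    segment = (
        int(q_cols.min()) + 1,
        int(q_cols.max()) + 1,
        int(s_cols.min()) + 1,
        int(s_cols.max()) + 1,
    )
    return params.bits(aln.score), segment, len(trace)


def _pair_hits(
    a: DomainSequence, b: DomainSequence, params: ScoringParams
) -> list[SimilarityHit]:
    """Hits for both orientations of one sequence pair (score is symmetric)."""
    result = local_align_bitscore(a.sequence, b.sequence, params)
    if result is None:
        return []
    bits, (qs, qe, ss, se), cols = result
    return [
        SimilarityHit(query_id=a.id, subject_id=b.id, bitscore=bits,
                      segments=[(qs, qe, ss, se)], aligned_columns=cols),
        SimilarityHit(query_id=b.id, subject_id=a.id, bitscore=bits,
                      segments=[(ss, se, qs, qe)], aligned_columns=cols),
    ]


def all_vs_all(
    domain_seqs_a: Sequence[DomainSequence],
    domain_seqs_b: Sequence[DomainSequence],
    params: ScoringParams | None = None,
) -> tuple[list[SimilarityHit], list[SimilarityHit], list[SimilarityHit]]:
    """All-vs-all similarity search.

    Returns ``(cross, within_a, within_b)``: hits for every ordered
    cross-species pair, plus each set against itself with self-pairs
    excluded.  Ordering of the output is deterministic and independent of
    input order.
    """
    params = params or ScoringParams()
    seqs_a = sorted(domain_seqs_a, key=lambda d: d.id)
    seqs_b = sorted(domain_seqs_b, key=lambda d: d.id)

    cross: list[SimilarityHit] = []
    for a in seqs_a:
        for b in seqs_b:
            cross.extend(_pair_hits(a, b, params))

    def within(seqs: Sequence[DomainSequence]) -> list[SimilarityHit]:
        hits: list[SimilarityHit] = []
        for i, a in enumerate(seqs):
            for b in seqs[i + 1:]:
                hits.extend(_pair_hits(a, b, params))
        return hits

    within_a = within(seqs_a)
    within_b = within(seqs_b)
    key = lambda h: (h.query_id, h.subject_id)
    return sorted(cross, key=key), sorted(within_a, key=key), sorted(within_b, key=key)


def coverage_of_longer(
    hit: SimilarityHit, len_query: int, len_subject: int
) -> float:
    """Fraction of the longer sequence covered by the union of its matched
    segments (per-residue union, not the enclosing span)."""
    if len_query >= len_subject:
        intervals = [(qs, qe) for qs, qe, _, _ in hit.segments]
        longer = len_query
    else:
        intervals = [(ss, se) for _, _, ss, se in hit.segments]
        longer = len_subject
    intervals.sort()
    covered = 0
    cursor = 0  # last covered position
    for s, e in intervals:
        s = max(s, cursor + 1)
        if e >= s:
            covered += e - s + 1
            cursor = max(cursor, e)
    return covered / longer


def apply_hit_filters(
    hits: Iterable[SimilarityHit],
    lengths: Mapping[str, int],
    config: Config,
) -> list[SimilarityHit]:
    """Keep hits passing the bitscore and the two coverage cutoffs.

    A hit survives iff bitscore >= ``bitscore_cutoff``, the union of its
    matched segments covers at least ``segment_coverage_cutoff`` of the
    longer sequence, and the total aligned columns span at least
    ``seq_overlap_cutoff`` of the longer sequence.  With both coverage
    cutoffs at 0 only the bitscore filter applies.
    """
    kept: list[SimilarityHit] = []
    for hit in hits:
        try:
            lq = lengths[hit.query_id]
            ls = lengths[hit.subject_id]
        except KeyError as exc:
            raise ValueError(f"hit references unknown sequence id {exc.args[0]!r}")
        if hit.bitscore < config.bitscore_cutoff:
            continue
        longer = max(lq, ls)
        cov = coverage_of_longer(hit, lq, ls)
        hit.coverage_longer = cov
        if cov < config.segment_coverage_cutoff:
            continue
        if min(1.0, hit.aligned_columns / longer) < config.seq_overlap_cutoff:
            continue
        kept.append(hit)
    return kept
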