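"""Core data types and readers/writers for every external format the
pipeline touches.

Coordinate convention: every external format (FASTA-derived annotation
tables, PfamScan output, BLAST tabular) is 1-based inclusive.  All
coordinates stored on the types below keep that convention; internal
arithmetic that needs half-open intervals converts locally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "DomainAnnotation",
    "DomainSequence",
    "Config",
    "SimilarityHit",
    "SeedPair",
    "GroupMember",
    "OrthologGroup",
    "ProteinPair",
    "DiscordanceRecord",
    "read_fasta",
    "write_fasta",
    "read_pfamscan",
    "write_pfamscan",
    "read_blast_tabular",
    "write_hit_table",
    "write_group_table",
    "read_group_table",
    "write_domain_pair_table",
    "write_pair_table",
    "read_pair_table",
    "write_discordance_table",
]

# Amino-acid alphabet accepted by the built-in scorer (20 standard residues
# plus the ambiguity codes BLOSUM62 defines scores for).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_AMINO_ACIDS = AMINO_ACIDS + "BZX"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein sequence from one species' proteome."""

    id: str
    species: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain-family hit on a protein (PfamScan row).

    ``start``/``end`` are the envelope coordinates, 1-based inclusive.
    """

    protein_id: str
    start: int
    end: int
    name: str
    family_type: str
    source: str = "pfamscan"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"annotation {self.name!r} on {self.protein_id!r}: "
                f"invalid coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Categories a domain-equivalent sequence can fall into.
CATEGORY_PFAM = "pfam_domain"
CATEGORY_UNKNOWN = "unknown_region"
CATEGORY_ORPHAN = "orphan"

#: Label used for orphan (whole-protein) domain-equivalents.
ORPHAN_LABEL = "ORPHAN"


@dataclass(frozen=True)
class DomainSequence:
    """A cut of a protein: the unit of orthology inference.

    Either a Pfam domain region, an unannotated ("UNKn") region longer than
    the minimum unknown length, or a whole annotation-free protein (orphan).
    """

    id: str
    protein_id: str
    species: str
    start: int
    end: int
    label: str
    category: str
    sequence: str

    def __post_init__(self) -> None:
        if self.category not in (CATEGORY_PFAM, CATEGORY_UNKNOWN, CATEGORY_ORPHAN):
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"domain sequence {self.id!r}: sequence length "
                f"{len(self.sequence)} != span {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def domain_sequence_id(protein_id: str, label: str, start: int, end: int) -> str:
    """Canonical id for a cut: ``<protein_id>/<label>/<start>-<end>``."""
    return f"{protein_id}/{label}/{start}-{end}"


@dataclass
class Config:
    """Tunable parameters of the whole pipeline.

    Defaults follow InParanoid's BLAST post-processing (40-bit minimum,
    50% coverage of the longer sequence) and the recommended alpha
    thresholds (0.3 standalone, 0.4 when merging with a full-length method).
    """

    bitscore_cutoff: float = 40.0
    seq_overlap_cutoff: float = 0.5
    segment_coverage_cutoff: float = 0.5
    min_unknown_len: int = 30
    overlap_discard_fraction: float = 0.5
    alpha_threshold: float = 0.3
    alpha_threshold_merge: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "seq_overlap_cutoff",
            "segment_coverage_cutoff",
            "overlap_discard_fraction",
            "alpha_threshold",
            "alpha_threshold_merge",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.bitscore_cutoff < 0:
            raise ValueError("bitscore_cutoff must be >= 0")
        if self.min_unknown_len < 0:
            raise ValueError("min_unknown_len must be >= 0")


@dataclass
class SimilarityHit:
    """Scored match between two domain sequences.

    ``segments`` holds all matched segments (HSPs) of the pair as
    ``(qstart, qend, sstart, send)`` tuples, 1-based inclusive.
    ``aligned_columns`` is the total alignment length summed over segments
    (gap columns included, as in BLAST tabular column 4).
    ``coverage_longer`` is filled in by the hit filters once sequence
    lengths are known.
    """

    query_id: str
    subject_id: str
    bitscore: float
    segments: list[tuple[int, int, int, int]] = field(default_factory=list)
    aligned_columns: int = 0
    coverage_longer: float | None = None

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass(frozen=True)
class SeedPair:
    """Mutual best-scoring cross-species pair nucleating an ortholog group."""

    member_a: str
    member_b: str
    score: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.member_a, self.member_b)


@dataclass(frozen=True)
class GroupMember:
    id: str
    species: str
    score_to_seed: float
    is_seed: bool


@dataclass
class OrthologGroup:
    """A seed ortholog pair plus recruited inparalogs.

    Cross-species co-members are orthologous (domain) sequences.
    """

    group_id: str
    seed: SeedPair
    members: list[GroupMember]

    def members_of(self, species: str) -> list[GroupMember]:
        return [m for m in self.members if m.species == species]

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for m in self.members:
            if m.species not in seen:
                seen.append(m.species)
        return seen


@dataclass(frozen=True)
class ProteinPair:
    """A candidate protein-level ortholog pair with its alpha fraction."""

    protein_a: str
    protein_b: str
    n_shared: int
    n_total: int
    supporting_groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_shared <= self.n_total:
            raise ValueError(
                f"pair ({self.protein_a},{self.protein_b}): "
                f"n_shared={self.n_shared} out of range for n_total={self.n_total}"
            )

    @property
    def alpha(self) -> float:
        return self.n_shared / self.n_total

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.protein_a, self.protein_b))


@dataclass
class DiscordanceRecord:
    """A primary protein whose domains are orthologous to several partners."""

    primary: str
    secondaries: list[tuple[str, frozenset[str]]]
    is_discordant: bool


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(stream: IO[str] | str, species: str) -> list[ProteinRecord]:
    """Parse a proteome multi-FASTA into :class:`ProteinRecord` objects.

    The record id is the first whitespace-delimited token of the header;
    sequences are uppercased with ``*`` and gap characters removed.
    Duplicate ids and empty files are errors.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(handle, "fasta"):
        seq = str(entry.seq).upper().replace("*", "").replace("-", "").replace(".", "")
        if entry.id in seen:
            raise ValueError(f"duplicate protein id {entry.id!r} in FASTA input")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, species=species, sequence=seq))
    if not records:
        raise ValueError("FASTA input contains no sequences")
    return records


def write_fasta(records: Iterable[ProteinRecord | DomainSequence], stream: IO[str],
                width: int = 60) -> None:
    for rec in records:
        stream.write(f">{rec.id}\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            stream.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# PfamScan tabular output
# ---------------------------------------------------------------------------

#: Column layout of pfam_scan.pl output (whitespace-delimited, 15 columns):
#: seq_id aln_start aln_end env_start env_end hmm_acc hmm_name type
#: hmm_start hmm_end hmm_length bit_score e_value significance clan
_PFAMSCAN_NCOL = 15


def read_pfamscan(stream: IO[str] | str) -> list[DomainAnnotation]:
    """Parse PfamScan tabular output into :class:`DomainAnnotation` objects.

    Envelope coordinates (columns 4-5) define the domain extent; the
    family type column is kept verbatim.  Comment lines (``#``) and blank
    lines are skipped.  Rows may reference proteins absent from the
    proteome; that is checked later, at extraction time.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    annotations: list[DomainAnnotation] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != _PFAMSCAN_NCOL:
            raise ValueError(
                f"PfamScan line {lineno}: expected {_PFAMSCAN_NCOL} columns, "
                f"got {len(fields)}"
            )
        start, end = int(fields[3]), int(fields[4])
        if end < start:
            raise ValueError(
                f"PfamScan line {lineno}: envelope end {end} < start {start}"
            )
        annotations.append(
            DomainAnnotation(
                protein_id=fields[0],
                start=start,
                end=end,
                name=fields[6],
                family_type=fields[7],
            )
        )
    return annotations


def write_pfamscan(annotations: Iterable[DomainAnnotation], stream: IO[str]) -> None:
    """Write annotations back out in the 15-column PfamScan layout.

    Alignment coordinates are set equal to the envelope; HMM bookkeeping
    columns are filled with placeholders so the file round-trips through
    :func:`read_pfamscan`.
    """
    stream.write("# <seq id> <alignment start> <alignment end> <envelope start> "
                 "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
                 "<hmm length> <bit score> <E-value> <significance> <clan>\n")
    for a in annotations:
        length = a.end - a.start + 1
        stream.write(
            f"{a.protein_id} {a.start} {a.end} {a.start} {a.end} "
            f"{a.name}.acc {a.name} {a.family_type} 1 {length} {length} "
            f"100.0 1e-10 1 No_clan\n"
        )


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tabular(stream: IO[str] | str) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular hits into :class:`SimilarityHit` objects.

    Multiple HSP rows for one (query, subject) pair are merged into a single
    hit: the pair bitscore is the maximum over HSPs and all matched segments
    are retained for coverage computation.  Self-hits are dropped.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    merged: dict[tuple[str, str], SimilarityHit] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(handle, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 12:
            raise ValueError(
                f"BLAST tabular line {lineno}: expected 12 columns, got {len(fields)}"
            )
        query, subject = fields[0], fields[1]
        if query == subject:
            continue
        try:
            bitscore = float(fields[11])
        except ValueError as exc:
            raise ValueError(
                f"BLAST tabular line {lineno}: non-numeric bitscore {fields[11]!r}"
            ) from exc
        aln_len = int(fields[3])
        qstart, qend = sorted((int(fields[6]), int(fields[7])))
        sstart, send = sorted((int(fields[8]), int(fields[9])))
        key = (query, subject)
        if key not in merged:
            merged[key] = SimilarityHit(query_id=query, subject_id=subject,
                                        bitscore=bitscore)
            order.append(key)
        hit = merged[key]
        hit.bitscore = max(hit.bitscore, bitscore)
        hit.segments.append((qstart, qend, sstart, send))
        hit.aligned_columns += aln_len
    return [merged[k] for k in order]


def write_hit_table(hits: Iterable[SimilarityHit], stream: IO[str]) -> None:
    """Write hits as BLAST-tabular-compatible rows (one row per segment)."""
    for hit in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
        for qs, qe, ss, se in hit.segments:
            aln = max(qe - qs, se - ss) + 1
            stream.write(
                f"{hit.query_id}\t{hit.subject_id}\t0.0\t{aln}\t0\t0\t"
                f"{qs}\t{qe}\t{ss}\t{se}\t0.0\t{hit.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# Output tables (TSV)
# ---------------------------------------------------------------------------

_GROUP_HEADER = "group_id\tseed_score\tspecies\tmember_id\tis_seed"


def write_group_table(groups: Sequence[OrthologGroup], stream: IO[str]) -> None:
    """Deterministic TSV: one row per group member, sorted by group id."""
    stream.write(_GROUP_HEADER + "\n")
    for group in sorted(groups, key=lambda g: g.group_id):
        for m in sorted(group.members, key=lambda m: (m.species, m.id)):
            stream.write(
                f"{group.group_id}\t{group.seed.score:g}\t{m.species}\t"
                f"{m.id}\t{int(m.is_seed)}\n"
            )


def read_group_table(stream: IO[str] | str) -> list[OrthologGroup]:
    """Read a group table written by :func:`write_group_table`.

    Also accepts tables from a full-length orthology run, for merging.
    """
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    header = handle.readline().strip()
    if header != _GROUP_HEADER:
        raise ValueError(f"unexpected group table header: {header!r}")
    rows: dict[str, list[tuple[float, str, str, bool]]] = {}
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        gid, score, species, member, is_seed = line.split("\t")
        rows.setdefault(gid, []).append(
            (float(score), species, member, bool(int(is_seed)))
        )
    groups: list[OrthologGroup] = []
    for gid in sorted(rows):
        entries = rows[gid]
        score = entries[0][0]
        members = [GroupMember(id=m, species=sp, score_to_seed=score if seed else 0.0,
                               is_seed=seed)
                   for score_, sp, m, seed in entries]
        seeds = [m for m in members if m.is_seed]
        if len(seeds) == 2:
            sa, sb = sorted(seeds, key=lambda m: m.species)
            seed_pair = SeedPair(member_a=sa.id, member_b=sb.id, score=score)
        else:
            # Full-length tables need not mark seeds; synthesize one.
            by_species: dict[str, str] = {}
            for m in members:
                by_species.setdefault(m.species, m.id)
            ids = [by_species[sp] for sp in sorted(by_species)]
            seed_pair = SeedPair(member_a=ids[0], member_b=ids[-1], score=score)
        groups.append(OrthologGroup(group_id=gid, seed=seed_pair, members=members))
    return groups


def write_domain_pair_table(pairs: Sequence[tuple[str, str, str]],
                            stream: IO[str]) -> None:
    stream.write("domain_a\tdomain_b\tgroup_id\n")
    for a, b, gid in sorted(pairs):
        stream.write(f"{a}\t{b}\t{gid}\n")


_PAIR_HEADER = "protein_a\tprotein_b\talpha\tn_shared\tn_total"


def write_pair_table(pairs: Sequence[ProteinPair], stream: IO[str]) -> None:
    stream.write(_PAIR_HEADER + "\n")
    for p in sorted(pairs, key=lambda p: (p.protein_a, p.protein_b)):
        stream.write(
            f"{p.protein_a}\t{p.protein_b}\t{p.alpha:.6g}\t{p.n_shared}\t{p.n_total}\n"
        )


def read_pair_table(stream: IO[str] | str) -> list[ProteinPair]:
    handle = io.StringIO(stream) if isinstance(stream, str) else stream
    header = handle.readline().strip()
    if header != _PAIR_HEADER:
        raise ValueError(f"unexpected pair table header: {header!r}")
    pairs: list[ProteinPair] = []
    for line in handle:
        line = line.rstrip("\n")
        if not line:
            continue
        a, b, _alpha, n_shared, n_total = line.split("\t")
        pairs.append(ProteinPair(protein_a=a, protein_b=b,
                                 n_shared=int(n_shared), n_total=int(n_total)))
    return pairs


def write_discordance_table(records: Sequence[DiscordanceRecord],
                            stream: IO[str]) -> None:
    stream.write("primary\tsecondary\torthologous_domains_of_primary\tis_discordant\n")
    for rec in sorted(records, key=lambda r: r.primary):
        for secondary, domains in sorted(rec.secondaries):
            stream.write(
                f"{rec.primary}\t{secondary}\t{','.join(sorted(domains))}\t"
                f"{int(rec.is_discordant)}\n"
            )
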