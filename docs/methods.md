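# Methods

## Model and procedure

`domortho` treats the protein domain, not the full-length protein, as the
unit of orthology. The working objects are *domain-equivalent sequences*:
Pfam domain cuts, unannotated regions longer than a minimum length
("UNK" regions, candidate novel or diverged domains), and whole
annotation-free proteins (orphans). Orthology between these units is
inferred with the classic two-species seed-ortholog/inparalog scheme:
reciprocal best hits nucleate groups, and within-species sequences at
least as similar to a seed member as the seeds are to each other join as
inparalogs (co-orthologs). Cross-species co-membership defines domain
orthology; the alpha fraction projects it onto proteins.

Assumptions inherited from this design: exactly two species per run;
similarity in bits is a usable proxy for evolutionary distance; domains
behave as independently evolving units, so a cut's best cross-species
match identifies its ortholog even when the parent proteins' architectures
disagree.

## Extraction rules

* Repeat-type annotations are removed first: short repeated units produce
  many near-identical cuts whose cross-matches are not informative about
  descent.
* Overlap resolution: if two annotations overlap by more than
  `overlap_discard_fraction` (default 0.5) of the **shorter** one's
  length, the shorter is discarded. The reference wording ("overlapping
  with more than half of its length … the longest sequence is kept")
  does not say which domain "its" refers to; reading it as the shorter is
  the interpretation consistent with keeping the longest. Candidates are
  processed in descending length (ties: smaller start coordinate first),
  which makes the outcome independent of input order. Surviving
  annotations may still overlap by up to the threshold; unknown regions
  are carved only from residues covered by no kept annotation, so UNK cuts
  never overlap domain cuts.
* Unannotated regions: every maximal uncovered region of length strictly
  greater than `min_unknown_len` (default 30) becomes a UNK cut, numbered
  N→C per protein. Terminal regions are included, not only interdomain
  ones — the operative definition is "any region", and terminal
  extensions can carry real domains. The boundary is strict: exactly 30
  residues is discarded, 31 is kept.
* PfamScan envelope coordinates (not alignment coordinates) define domain
  extent, the usual convention for the full domain region in Pfam
  practice.

## Scoring

The built-in scorer is plain Smith–Waterman (via biotite's `align_optimal`)
with BLOSUM62 and affine gap costs in the BLAST convention: a gap of
length *n* costs 11 + *n*. Raw scores are converted to bits with the
gapped Karlin–Altschul constants for that scheme, λ = 0.267, K = 0.041:
bits = (λ·S − ln K)/ln 2. These match the BLASTP defaults, so imported
BLAST tabular hits and built-in hits are interchangeable through the same
filters. The built-in scorer reports the single best local alignment as
one matched segment; imported BLAST hits may carry several HSP segments
per pair, in which case the pair bitscore is the maximum over HSPs (the
conservative aggregation) and coverage uses the union of all segments.
Low-complexity (SEG) masking is not applied by the built-in scorer; when
fidelity to BLAST masking matters, import BLAST tabular output instead.

Hit filters: bitscore ≥ 40 bits; union-of-segments coverage of the longer
sequence ≥ 50% (`segment_coverage_cutoff`); total aligned columns / longer
length ≥ 50% (`seq_overlap_cutoff`). The last two are deliberately kept as
two separate knobs — coverage counts matched residues once, aligned
columns count every alignment column including gaps — and both default to
0.5. Setting both to 0 leaves only the bitscore filter, the permissive
mode used to hunt speculative short-domain orthologs.

## Clustering details

* Mutual-best ties are broken by lexicographically smallest partner id;
  determinism matters more than any particular choice here.
* The inparalog boundary is inclusive: a within-species score exactly
  equal to the seed score recruits ("does not fall below").
* Overlapping groups are made disjoint by a single deterministic rule: a
  shared member stays in the group with the higher seed score (tie:
  lexicographically smaller seed pair); groups that lose all members of
  one species are deleted and the deletion logged. This is a deliberate
  simplification of InParanoid 4.1's multi-rule group merging (bootstrap
  confidences, merging heuristics), which is not part of this package's
  scope; the simple rule is fully specified and testable against a
  brute-force reference.

## Alpha projection and discordance

For a candidate pair (proteins sharing ≥ 1 ortholog group), the numerator
counts every domain instance on either protein belonging to a group that
also contains an instance from the partner; the denominator counts all
domain-equivalent instances on both proteins, **including** UNK and orphan
cuts. Counting UNK/orphan instances in the denominator penalises pairs
whose shared domains are a small part of their architectures, which is the
intended semantics of alpha. The default call threshold is α ≥ 0.3
(inclusive); for enriching a full-length method's pairs the stricter 0.4
is the default, since added pairs there should be conservative.

Discordance: a primary protein is any protein whose domains are
orthologous to domains on more than one partner protein. The flag requires
at least two partners with **disjoint** subsets of the primary's domains
(mutual exclusivity); a relaxed mode flagging merely *different* subsets
is available (`strict=False` / `--relaxed`) but not default, because
nested subsets usually reflect architecture-sharing paralogs rather than
fusion/fission.

Merging with a full-length method keeps every full-length pair; a
domain-derived pair is added unless both of its proteins were assigned by
the full-length method to groups that do not place them together, in which
case the full-length assignment stands. Pair classification
(both / full-length-only / conflicting / one-missing / two-missing) and
the Jaccard consensus sweep over the eleven thresholds 0.0–1.0 follow
directly from the two pair sets.

## Synthetic evolution generator

The generator emulates exactly the processes the pipeline must resolve: a
shared ancestral proteome of domain chains joined by linkers diverges into
two species by residue substitution, while the second lineage optionally
undergoes protein fusion, fission, duplication (inparalogs) and
single-domain loss. Default conditions: 20 ancestral domain families,
30 proteins per species, domain lengths 60–150, linker lengths 10–50
(straddling the 30-residue unknown threshold so UNK emission is exercised
on both sides of the boundary), event probabilities 0.1/0.1/0.1/0.05
(fusion/fission/duplication/loss), substitution rate 0.1 per lineage.

Design choices worth noting:

* Each ancestral family occurs exactly once in the ancestral proteome, so
  ground-truth orthology is unambiguous; proteins generated after the
  family pool is exhausted are domain-free orphans, exercising the orphan
  path. Consequence: within-proteome family repetition (a real feature of
  proteomes) is not modelled.
* Linkers are inherited and mutated like domains, so homologous UNK
  regions across species are part of the ground truth; the fresh linker
  inserted by a fusion event has no ortholog by construction.
* Substitutions replace a residue with a uniformly chosen different
  residue; there are no indels, so true coordinates stay exact and
  annotations can be emitted with them directly. Amino-acid frequencies
  are uniform over the 20 residues. Both simplifications mean the scorer
  sees somewhat unnatural sequence statistics; passing recovery tests
  shows the pipeline machinery is correct, not that recovery rates will
  match real proteome pairs, where composition bias, repeats and indels
  make both extraction and scoring harder.
* Ground-truth protein pairs are all cross-species descendant pairs of
  the same ancestral protein (duplication copies included; fusion/fission
  products count for each parent). Truth for domain pairs covers Pfam,
  UNK and orphan cuts.

At substitution rate 0 with no fusion/fission the pipeline recovers all
true domain and protein pairs exactly; recovery degrades gracefully with
divergence (short UNK regions are the first casualties, their bitscores
dropping below 40 bits around ~50% identity).

## Problem sizes and numerical choices

The test suite and the recovery analyses run on the default 20-family /
30-protein scenarios (a few thousand alignments, seconds per run) and on
random score matrices of ≤ 8 sequences per species for the clustering
equivalence checks (200+ random instances against a brute-force
reference). Alpha is stored as an exact integer ratio (`n_shared`,
`n_total`) and compared inclusively at thresholds, so no floating-point
tolerance enters any call decision; bitscore comparisons use the values as
computed, with the 40-bit cutoff applied inclusively.

## Known limitations

* Two species per run; multi-species analyses are outer loops left to the
  caller.
* No bootstrap/confidence values on groups; the conflict-resolution rule
  is a simplification (above).
* The built-in scorer computes one best local alignment per pair (single
  HSP) and no E-values or composition-based statistics.
* Nested or discontinuous domains are not modelled; annotations are
  treated as simple intervals.
* The generator's no-indel, single-occurrence-per-family assumptions
  (above) bound what the synthetic benchmarks can demonstrate.
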