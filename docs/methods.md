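# Methods

## Scope and model of the data

`allelescan` analyzes a set of genomic allele sequences of a single-copy,
plus-strand, intron-containing gene against one functional reference
allele. All coordinates are 1-based and inclusive on the unspliced
reference, with +1 the first base of the start codon — the convention used
for published lesion catalogues of this kind. Reverse-strand genes are
expected to be reverse-complemented upstream; multi-isoform models are out
of scope.

The biological template is the Myr II myrosinase architecture: 13 exons,
12 introns, canonical GT donors except a GC donor on intron 10, AG
acceptors throughout. Intron 10 is identified positionally (the 10th
intron of whatever model is in force), not by content, so the border
expectation survives upstream indels.

## Gene-model inference

`infer_model` maps a cDNA onto its genomic sequence by affine-gap global
alignment (gap of length k costs open + k·extend), so each intron emerges
as one contiguous cDNA-row gap run; unit-cost alignment is unsuitable here
because its co-optimal solutions fragment intron gaps around chance 1-base
matches. Each intron placement is then slid through its repeat-equivalence
window (positions reachable while the spliced product is unchanged) and
the placement maximizing border-dinucleotide agreement (donor, then
acceptor) is chosen; remaining ties go to the leftmost position. This
tie-break is this package's convention — sequence data alone cannot
distinguish equivalent placements, and published catalogues do not state
how such ties were resolved. Runs shorter than 4 bases, or cDNA bases
absent from the genomic sequence, raise an inference error; exons must be
at least 12 bases (the anchoring minimum) or inference is refused rather
than guessed.

## Alignment, normalization and coordinates

Pairwise alignment is delegated to Biopython's `PairwiseAligner`
(global mode). Default scores — match +1, mismatch −2, gap open 8, gap
extend 1 — are chosen so that isolated 1–208 base indels between ~85–97 %
identical alleles are recovered as single gap runs rather than split gaps;
they are overridable per call and through the CLI.

Because indel placement inside repeats is degenerate, every alignment is
canonicalized before event extraction: each gap run is shifted maximally
leftward whenever the displaced character pairs with an identical
character (score-preserving, idempotent). Insertions are then keyed to the
reference base immediately left of the inserted bases, matching the
"insertion at +N" phrasing of published catalogues and making event keys
reproducible across alleles and runs.

## Event detection and typing

From the normalized coordinate map, every deletion run and insertion run
is an event, regardless of length. Point substitutions are events only at
splice-border dinucleotides (read through the coordinate map and compared
to the model's expected set); other SNPs are population diversity. A
deletion overlapping a border dinucleotide is splice-disrupting in
addition to any frame shift; the predicted transcript consequence of a
border lesion (intron retention) is carried as an annotation, not
simulated. An event shifts the reading frame iff its exonic base count is
positive and not a multiple of three; codon-preserving (3n) exonic indels
are retained but flagged non-frameshifting.

Type identity is the exact tuple (kind, normalized start, end, length,
detail), so near-identical events at shifted positions are distinct types
— published catalogues distinguish same-length deletions 20 nucleotides
apart. Types are numbered Mu1… in ascending start order (ties: kind,
length, detail).

The presence matrix marks a cell *not applicable* when the allele carries
a larger deletion spanning the type's locus, since presence cannot be
scored there. Applied uniformly this rule also flags the insertion locus
inside the 17-base junction deletion in alleles carrying the latter; the
published table marks only the large-deletion/insertion case in one
ecotype, so the shipped fixture encodes the table as printed while the
computed path applies the rule consistently.

## Functionality calling

Disabling evidence is (a) any frameshifting or splice-disrupting event,
and (b) ORF defects of the allele's own spliced CDS (reference exon
boundaries projected through the alignment): missing ATG, CDS length not a
multiple of three, premature stop, or a protein length differing from the
reference (amino-acid substitutions are tolerated; length changes are
not). The ORF check is stricter than lesion absence alone — a nonsense
point substitution produces no indel event but must still disable the
allele. Whether the original analyses applied an equivalent ORF-level
guard is not stated; here it is an explicit convention, and a functional
call always has an empty reason list.

## Diversity statistics

Site handling follows the common "complete deletion" default of DnaSP-style
analyses: Hd, π, θ_w and the haplotype definition use only columns free of
gaps and N; indel sites (columns with ≥1 gap) are counted separately on
all columns. Per-kilobase densities divide by the total aligned length —
the convention under which published per-kb SNP densities times aligned
length give integer site counts. Exact reproduction of a published
diversity table from re-aligned sequences remains alignment-dependent
(the original multiple-alignment parameters are not stated).

Estimators and sampling standard deviations:

- Hd = n(1 − Σxᵢ²)/(n − 1); variance per Nei (1987) eq. 8.12.
- π = mean pairwise difference per complete site; variance per Nei (1987)
  eq. 10.7.
- θ_w = S/(aₙL) with aₙ = Σ_{i<n} 1/i; variance from Watterson (1975),
  Var(S) = a₁θL + a₂(θL)², evaluated at the estimate.

Partitioning projects the gene model through the reference row: insertion
columns inherit the region of the left flanking reference base, columns
outside the model count as non-coding, and the exon/intron column sets
always partition the alignment. Functional/disabled row subsets with fewer
than two members are skipped with a warning rather than reported.

## Distances, tree, loss counting

TN93 distances use empirical base frequencies pooled over the comparable
sites of each pair and separate purine/pyrimidine transition classes;
sites with a gap or N in either sequence are skipped (pairwise deletion).
Saturated pairs (non-positive logarithm argument) return +infinity rather
than a fabricated value. Neighbor joining follows Saitou–Nei with two
deterministic rules: Q-matrix ties join the lowest-index pair, and a
negative branch length is clamped to zero with the deficit moved to its
sibling. The published trees for this locus were maximum-likelihood with
bootstrap and a time axis; ML search and clock calibration are external
(MEGA-class) functionality and out of scope — the NJ tree is the testable
distance-level counterpart.

Independent losses are counted by small parsimony (unit-cost dynamic
programme over arbitrary node degrees) with the root constrained to the
functional state, formalizing "the gene was disabled many times
independently"; no published number exists for this count, so it is
property-tested (≤ number of disabled leaves, ≥ 1 iff any leaf disabled)
rather than compared to a reference value.

## Synthetic data generator

The generator emulates the study conditions: 29 alleles (one per ecotype),
exon lengths (170, 110, 96, 130, 70, 65, 120, 150, 240, 113, 90, 140, 45)
summing to a 1539 nt CDS (512 residues + stop), 85 nt introns, GC donor on
intron 10, neutral SNPs at 0.0075 per site, and an event plan that by
default replicates the published ecotype × mutation assignment. The exon
layout is fixed rather than random so that every catalogue coordinate
falls in its reported region — in particular intron 10 ends at +2114, so
the +2111..+2127 deletion removes 4 intron and 13 exon bases — and so that
the 208-base deletion removes 109 exonic bases, making its frame-shift
status derivable from the model (the published table does not print that
count).

Alleles descend from the reference in a star genealogy: independent
substitutions per site, then planted events applied right-to-left so truth
coordinates stay in reference space. Neutral substitutions draw uniformly
from the target bases that keep the codon sense, so every eligible site
mutates with probability exactly `snp_rate`; excluded are border
dinucleotides, the start and terminal stop codons, and a ±10 base flank
around every planted event (`EVENT_FLANK`). The flank is a correctness
guarantee of the truth ledger, not a tuning knob: a substitution inside an
indel's local alignment trade-off window can make the indel's normalized
placement ambiguous (the aligner absorbs the mismatch into a shifted,
better-scoring gap), and the planted coordinate would then not be the
canonical one. For the same reason the reference is regenerated (bounded,
seeded retries) until no planned deletion can slide left under gap
normalization, until all borders verify, and until the exon set is
exactly recoverable from the cDNA. Inserted bases are drawn once per
catalogue entry (identical across carrier alleles, never ending in the
left-flank base) so that shared insertions merge into one type.

What the generator does not emulate: coalescent genealogy and shared
polymorphism between alleles (every SNP is private, so simulated π ≈ 2μ
rather than μ), recombination, indel evolution beyond planted events, and
sequencing error. Recovery tests on this generator therefore demonstrate
correctness of detection, typing and calling under clean separations —
events ≥ 50 bp apart and SNP rates ≤ ~0.02 — not performance on tangled
real-world alignments; the optional accession-based integration test
covers a real data point when network access permits.

Determinism: all randomness flows from `numpy` `SeedSequence` streams
derived from the config seed, with per-allele substreams keyed by allele
index, so outputs are byte-identical across runs and stable under plan
reordering.

## Problem sizes in the shipped checks

The default validation suite runs the full 29-allele population scan,
20-seed × 30-allele end-to-end recovery, 200 random-alignment oracle
comparisons (n ≤ 12, L ≤ 300), exhaustive alignment enumeration to length
8, and 10-case TN93/NJ cross-checks — sizes chosen to exercise every code
path with exact or 1e-12 agreement while keeping the whole suite around a
minute on one core.
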