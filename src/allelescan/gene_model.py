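"""Gene architecture: exon/intron model, splicing, translation, splice borders.

The model describes a single plus-strand gene in 1-based inclusive
coordinates on the unspliced genomic sequence, with position +1 being the
first base of the start codon (the A of ATG). Myrosinase Myr II genes carry
13 exons and use the non-canonical GC donor for intron 10, so the default
border expectation is donor GT for every intron except intron 10 (GT or GC)
and acceptor AG everywhere.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in STANDARD_TABLE.items() if aa == "*")

# Unusual donor position: Myr II genes use GC/AG for intron 10 (1-based).
GC_DONOR_INTRON = 10
MIN_INTRON_LEN = 4
MIN_EXON_ANCHOR = 12


class CoordinateError(ValueError):
    """Model interval outside the sequence."""


class ModelError(ValueError):
    """Inconsistent exon/intron architecture."""


class InferenceError(ValueError):
    """cDNA could not be mapped onto the genomic sequence."""


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Exon intervals plus per-intron expected border dinucleotides."""

    exons: tuple[tuple[int, int], ...]
    donor_expect: tuple[frozenset[str], ...]
    acceptor_expect: tuple[frozenset[str], ...]

    @classmethod
    def from_exons(
        cls,
        exons: Sequence[tuple[int, int]],
        gc_donor_introns: Sequence[int] = (GC_DONOR_INTRON,),
    ) -> "GeneModel":
        """Build a model with the Myr II default border expectations.

        ``gc_donor_introns`` lists the 1-based intron indices where a GC
        donor is tolerated in addition to GT (default: intron 10 only).
        """
        exons = tuple((int(s), int(e)) for s, e in exons)
        if not exons:
            raise ModelError("gene model needs at least one exon")
        for s, e in exons:
            if s > e:
                raise ModelError(f"exon start {s} > end {e}")
            if s < 1:
                raise ModelError(f"exon start {s} < 1")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ModelError(
                    f"exons overlap or are unsorted: ({s1},{e1}) then ({s2},{e2})"
                )
        n_introns = len(exons) - 1
        donors = tuple(
            frozenset({"GT", "GC"}) if (i + 1) in set(gc_donor_introns) else frozenset({"GT"})
            for i in range(n_introns)
        )
        acceptors = tuple(frozenset({"AG"}) for _ in range(n_introns))
        return cls(exons=exons, donor_expect=donors, acceptor_expect=acceptors)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals (1-based inclusive), the gaps between exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(self.n_introns)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    def cds_length(self) -> int:
        return sum(self.exon_lengths())

    def region_of(self, pos: int) -> tuple[str, int]:
        """Classify a reference position as ('exon', k) / ('intron', k) (1-based k)."""
        for k, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return ("exon", k)
        for k, (s, e) in enumerate(self.introns, start=1):
            if s <= pos <= e:
                return ("intron", k)
        return ("upstream", 0) if pos < self.exons[0][0] else ("downstream", 0)

    def exonic_overlap(self, start: int, end: int) -> int:
        """Number of exonic bases inside the closed interval [start, end]."""
        total = 0
        for s, e in self.exons:
            total += max(0, min(end, e) - max(start, s) + 1)
        return total

    def border_positions(self, intron_index: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """((donor_pos1, donor_pos2), (acceptor_pos1, acceptor_pos2)) for an intron (1-based index)."""
        s, e = self.introns[intron_index - 1]
        if e - s + 1 < MIN_INTRON_LEN:
            raise ModelError(f"intron {intron_index} shorter than {MIN_INTRON_LEN} bases")
        return (s, s + 1), (e - 1, e)


@dataclasses.dataclass(frozen=True)
class BorderCheck:
    intron_index: int
    donor_obs: str
    acceptor_obs: str
    donor_ok: bool
    acceptor_ok: bool

    @property
    def ok(self) -> bool:
        return self.donor_ok and self.acceptor_ok


@dataclasses.dataclass(frozen=True)
class TranslationResult:
    """Protein product of a putative CDS plus the ORF-integrity flags."""

    protein: str                 # residues up to (not including) the first stop
    first_stop_codon: int | None  # 1-based codon index of the first stop, if any
    n_codons: int                # number of complete codons in the input
    starts_with_atg: bool
    length_multiple_of_three: bool

    @property
    def premature_stop(self) -> bool:
        """A stop strictly before the final complete codon."""
        return self.first_stop_codon is not None and self.first_stop_codon < self.n_codons

    @property
    def has_terminal_stop(self) -> bool:
        return self.first_stop_codon == self.n_codons


def splice(genomic: str, model: GeneModel) -> str:
    """Concatenate exon substrings (the in-silico mature CDS)."""
    if model.exons[-1][1] > len(genomic):
        raise CoordinateError(
            f"exon interval {model.exons[-1]} outside sequence of length {len(genomic)}"
        )
    return "".join(genomic[s - 1:e] for s, e in model.exons)


def translate(cds: str) -> TranslationResult:
    """Translate with the standard nuclear code, stopping at the first stop.

    A length not divisible by 3 is reported in the result flags, not raised:
    disabled alleles routinely violate it.
    """
    n_codons = len(cds) // 3
    protein = []
    first_stop = None
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        aa = STANDARD_TABLE.get(codon, "X")
        if aa == "*":
            first_stop = i + 1
            break
        protein.append(aa)
    return TranslationResult(
        protein="".join(protein),
        first_stop_codon=first_stop,
        n_codons=n_codons,
        starts_with_atg=cds[:3] == "ATG",
        length_multiple_of_three=len(cds) % 3 == 0,
    )


def check_borders(genomic: str, model: GeneModel) -> list[BorderCheck]:
    """Inspect every intron's first/last two bases against the expected sets."""
    if model.exons[-1][1] > len(genomic):
        raise CoordinateError("model extends beyond sequence")
    checks = []
    for k in range(1, model.n_introns + 1):
        (d1, _), (a1, _) = model.border_positions(k)
        donor = genomic[d1 - 1:d1 + 1]
        acceptor = genomic[a1 - 1:a1 + 1]
        checks.append(
            BorderCheck(
                intron_index=k,
                donor_obs=donor,
                acceptor_obs=acceptor,
                donor_ok=donor in model.donor_expect[k - 1],
                acceptor_ok=acceptor in model.acceptor_expect[k - 1],
            )
        )
    return checks


def infer_model(
    genomic: str,
    cdna: str,
    gc_donor_introns: Sequence[int] = (GC_DONOR_INTRON,),
    min_exon_len: int = MIN_EXON_ANCHOR,
) -> GeneModel:
    """Infer exon intervals by mapping the cDNA onto the genomic sequence.

    The cDNA is globally aligned to the genomic sequence with affine gap
    costs (so each intron emerges as one contiguous genomic-only gap run);
    intron-sized runs become introns, then each intron placement is slid
    within its local repeat-ambiguity window to the position that best
    matches the expected border dinucleotides, ties resolved leftmost.
    Border expectations are positional: the 10th intron of whatever model
    emerges tolerates the GC donor.
    """
    from .align import GAP, build_map, global_align, left_normalize

    if genomic == cdna:
        return GeneModel.from_exons([(1, len(genomic))], gc_donor_introns)
    aln = left_normalize(global_align(genomic, cdna))

    # Gap runs in the cDNA row are candidate introns; gap runs in the
    # genomic row mean cDNA bases with no genomic source - not splicing.
    if GAP in aln.ref_row:
        raise InferenceError("cDNA bases missing from the genomic sequence")
    cmap = build_map(aln)
    mismatches = sum(
        1 for p in range(1, cmap.ref_len + 1)
        if cmap.ref_to_alt[p] is not None
        and genomic[p - 1] != cdna[cmap.ref_to_alt[p] - 1]
    )
    intron_runs: list[tuple[int, int]] = []  # 1-based inclusive genomic intervals
    p = 1
    while p <= cmap.ref_len:
        if cmap.ref_to_alt[p] is None:
            q = p
            while q <= cmap.ref_len and cmap.ref_to_alt[q] is None:
                q += 1
            if q - p < MIN_INTRON_LEN:
                raise InferenceError(
                    f"unspliceable {q - p}-base genomic gap at position {p}"
                )
            intron_runs.append((p, q - 1))
            p = q
        else:
            p += 1

    n_introns = len(intron_runs)
    gc_set = set(gc_donor_introns)
    refined: list[tuple[int, int]] = []
    for k, (s, e) in enumerate(intron_runs, start=1):
        left_bound = refined[-1][1] + 1 if refined else 1
        right_bound = intron_runs[k][0] - 1 if k < n_introns else len(genomic)
        donor_exp = {"GT", "GC"} if k in gc_set else {"GT"}
        refined.append(
            _refine_intron(genomic, s, e, left_bound, right_bound, donor_exp, {"AG"})
        )

    # Exons are the complement of the refined introns.
    exons: list[tuple[int, int]] = []
    prev_end = 0
    for s, e in refined:
        exons.append((prev_end + 1, s - 1))
        prev_end = e
    exons.append((prev_end + 1, len(genomic)))
    for s, e in exons:
        if e - s + 1 < min_exon_len:
            raise InferenceError(
                f"inferred exon ({s},{e}) shorter than the {min_exon_len}-base anchor minimum"
            )
    model = GeneModel.from_exons(exons, gc_donor_introns)
    if model.cds_length() != len(cdna):
        raise InferenceError(
            f"inferred exons cover {model.cds_length()} bases, cDNA has {len(cdna)}"
        )
    if mismatches == 0 and splice(genomic, model) != cdna:  # pragma: no cover - guard
        raise InferenceError("inferred model does not splice back to the cDNA")
    return model


def _refine_intron(
    genomic: str,
    s: int,
    e: int,
    left_bound: int,
    right_bound: int,
    donor_expect: set[str],
    acceptor_expect: set[str],
) -> tuple[int, int]:
    """Slide an intron within its equivalence window; prefer matching borders, then leftmost.

    A shift left by one keeps the spliced product unchanged iff the base
    entering the intron on the left equals the base leaving it on the right
    (and symmetrically for right shifts).
    """
    placements = [(s, e)]
    cs, ce = s, e
    while cs - 1 >= max(left_bound, 2) and genomic[cs - 2] == genomic[ce - 1]:
        cs, ce = cs - 1, ce - 1
        placements.append((cs, ce))
    cs, ce = s, e
    while ce + 1 <= min(right_bound, len(genomic) - 1) and genomic[cs - 1] == genomic[ce]:
        cs, ce = cs + 1, ce + 1
        placements.append((cs, ce))

    def score(p: tuple[int, int]) -> int:
        ps, pe = p
        donor = genomic[ps - 1:ps + 1]
        acceptor = genomic[pe - 2:pe]
        return (donor in donor_expect) + (acceptor in acceptor_expect)

    best = max(score(p) for p in placements)
    return min(p for p in placements if score(p) == best)
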