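"""Detection and typing of gene-disabling lesions in allele sets.

An allele is scanned against the reference by affine-gap global alignment;
every insertion/deletion (any length) becomes an event, as does any
splice-border dinucleotide that no longer matches the model's expected set.
Point substitutions away from borders are population diversity, not events
— but a premature stop introduced by one is still caught by the ORF check
in the functionality call. Events are canonicalized into a catalogue of
types (Mu1, Mu2, ... in ascending reference-coordinate order) and
summarized as an allele x type presence matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignParams, CoordinateMap, DEFAULT_PARAMS, build_map, global_align, left_normalize
from .datasets import CatalogueEntry
from .gene_model import GeneModel, splice, translate
from .seqio import SequenceRecord

INSERTION = "insertion"
DELETION = "deletion"
SPLICE_DONOR_SUB = "splice_donor_sub"
SPLICE_ACCEPTOR_SUB = "splice_acceptor_sub"

PRESENT = "present"
ABSENT = "absent"
NOT_APPLICABLE = "not_applicable"

FUNCTIONAL = "functional"
DISABLED = "disabled"


@dataclasses.dataclass(frozen=True)
class MutationEvent:
    """A detected lesion, in reference coordinates (1-based from the A of ATG)."""

    allele_id: str
    kind: str
    ref_start: int
    ref_end: int
    length: int  # inserted/deleted bases; 0 for border substitutions
    regions: tuple[tuple[str, int], ...]
    exonic_bases: int
    frameshift: bool
    splice_disrupting: bool
    detail: str = ""

    @property
    def key(self) -> tuple:
        """Type identity: exact normalized coordinates plus kind/length/detail."""
        return (self.kind, self.ref_start, self.ref_end, self.length, self.detail)


@dataclasses.dataclass(frozen=True)
class MutationType:
    mu_id: str
    kind: str
    ref_start: int
    ref_end: int
    length: int
    detail: str
    frequency: int
    allele_ids: tuple[str, ...]

    @property
    def key(self) -> tuple:
        return (self.kind, self.ref_start, self.ref_end, self.length, self.detail)


@dataclasses.dataclass(frozen=True)
class FunctionalityCall:
    allele_id: str
    status: str
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.status == FUNCTIONAL and self.reasons:
            raise ValueError("functional call must carry no reasons")


@dataclasses.dataclass(frozen=True)
class MutationMatrix:
    """Allele x mutation-type presence matrix with functionality column."""

    allele_ids: tuple[str, ...]
    types: tuple[MutationType, ...]
    cells: Mapping[tuple[str, str], str]  # (allele_id, mu_id) -> PRESENT/ABSENT/NOT_APPLICABLE
    functionality: Mapping[str, str]      # allele_id -> FUNCTIONAL/DISABLED

    def cell(self, allele_id: str, mu_id: str) -> str:
        return self.cells[(allele_id, mu_id)]

    def to_dataframe(self) -> pd.DataFrame:
        symbol = {PRESENT: "+", ABSENT: "-", NOT_APPLICABLE: "N/A"}
        rows = {}
        for aid in self.allele_ids:
            row = {t.mu_id: symbol[self.cells[(aid, t.mu_id)]] for t in self.types}
            row["functionality"] = self.functionality[aid]
            rows[aid] = row
        return pd.DataFrame.from_dict(rows, orient="index")


@dataclasses.dataclass(frozen=True)
class MatrixSummary:
    n_alleles: int
    n_functional: int
    n_disabled: int
    n_types: int
    frequencies: Mapping[str, int]
    events_in_region: int | None = None


def _regions_overlapped(model: GeneModel, start: int, end: int) -> tuple[tuple[str, int], ...]:
    labels = []
    for k, (s, e) in enumerate(model.exons, start=1):
        if s <= end and start <= e:
            labels.append((("exon", k), s))
    for k, (s, e) in enumerate(model.introns, start=1):
        if s <= end and start <= e:
            labels.append((("intron", k), s))
    labels.sort(key=lambda x: x[1])
    return tuple(lab for lab, _ in labels)


def _border_position_set(model: GeneModel) -> dict[int, tuple[str, int]]:
    """Map reference position -> (border kind, intron index) for all border bases."""
    out: dict[int, tuple[str, int]] = {}
    for k in range(1, model.n_introns + 1):
        (d1, d2), (a1, a2) = model.border_positions(k)
        out[d1] = out[d2] = ("donor", k)
        out[a1] = out[a2] = ("acceptor", k)
    return out


def classify_frameshift(event: MutationEvent, model: GeneModel) -> MutationEvent:
    """(Re)compute the frame-shift flag from the event's exonic base count.

    An indel shifts the reading frame iff it adds/removes a non-multiple of
    three exonic bases; codon-preserving (3n) indels are retained but
    flagged non-frameshifting, and border substitutions never shift frame.
    """
    if event.kind in (SPLICE_DONOR_SUB, SPLICE_ACCEPTOR_SUB):
        return dataclasses.replace(event, frameshift=False)
    fs = event.exonic_bases > 0 and event.exonic_bases % 3 != 0
    return dataclasses.replace(event, frameshift=fs)


def scan_allele(
    allele: SequenceRecord,
    reference: SequenceRecord,
    model: GeneModel,
    params: AlignParams = DEFAULT_PARAMS,
) -> tuple[list[MutationEvent], CoordinateMap]:
    """Detect all indel and splice-border events in one allele.

    Returns the events (sorted by reference start) together with the
    normalized reference->allele coordinate map, which downstream
    functionality calling reuses to splice the allele's own CDS.
    """
    try:
        aln = left_normalize(global_align(reference.seq, allele.seq, params))
    except Exception as exc:
        raise RuntimeError(f"alignment failed for allele {allele.id!r}: {exc}") from exc
    cmap = build_map(aln)
    borders = _border_position_set(model)
    events: list[MutationEvent] = []

    # Deletions: maximal runs of reference positions absent from the allele.
    p = 1
    while p <= cmap.ref_len:
        if cmap.ref_to_alt[p] is None:
            q = p
            while q <= cmap.ref_len and cmap.ref_to_alt[q] is None:
                q += 1
            start, end = p, q - 1
            exonic = model.exonic_overlap(start, end)
            events.append(MutationEvent(
                allele_id=allele.id, kind=DELETION,
                ref_start=start, ref_end=end, length=end - start + 1,
                regions=_regions_overlapped(model, start, end),
                exonic_bases=exonic, frameshift=False,
                splice_disrupting=any(pos in borders for pos in range(start, end + 1)),
                detail="",
            ))
            p = q
        else:
            p += 1

    # Insertions: allele-only bases keyed to the left flanking reference base.
    for ref_key, alt_start, length in cmap.insertions:
        inserted = allele.seq[alt_start - 1:alt_start - 1 + length]
        if ref_key >= 1:
            region = model.region_of(ref_key)
            exonic = length if region[0] == "exon" else 0
            regions = (region,)
        else:
            regions, exonic = (("upstream", 0),), 0
        # An insertion splitting a border dinucleotide disrupts splicing.
        splits_border = any(
            ref_key == d1 for d1, _ in
            (pair for k in range(1, model.n_introns + 1) for pair in model.border_positions(k))
        )
        events.append(MutationEvent(
            allele_id=allele.id, kind=INSERTION,
            ref_start=ref_key, ref_end=ref_key, length=length,
            regions=regions, exonic_bases=exonic, frameshift=False,
            splice_disrupting=splits_border, detail=inserted,
        ))

    # Splice-border substitutions, read through the coordinate map.
    for k in range(1, model.n_introns + 1):
        (d1, d2), (a1, a2) = model.border_positions(k)
        for kind, pos1, pos2, expected in (
            (SPLICE_DONOR_SUB, d1, d2, model.donor_expect[k - 1]),
            (SPLICE_ACCEPTOR_SUB, a1, a2, model.acceptor_expect[k - 1]),
        ):
            ap1, ap2 = cmap.ref_to_alt[pos1], cmap.ref_to_alt[pos2]
            if ap1 is None or ap2 is None:
                continue  # border removed by a deletion event, flagged there
            obs = allele.seq[ap1 - 1] + allele.seq[ap2 - 1]
            if obs not in expected:
                ref_dinuc = reference.seq[pos1 - 1:pos2]
                events.append(MutationEvent(
                    allele_id=allele.id, kind=kind,
                    ref_start=pos1, ref_end=pos2, length=0,
                    regions=(("intron", k),), exonic_bases=0,
                    frameshift=False, splice_disrupting=True,
                    detail=f"{ref_dinuc}>{obs}",
                ))

    events = [classify_frameshift(ev, model) for ev in events]
    events.sort(key=lambda e: (e.ref_start, e.kind, e.length, e.detail))
    return events, cmap


def call_functionality(
    allele: SequenceRecord,
    events: Sequence[MutationEvent],
    model: GeneModel,
    reference: SequenceRecord,
    reference_protein_len: int = 512,
    coord_map: CoordinateMap | None = None,
    mu_ids: Mapping[tuple, str] | None = None,
    params: AlignParams = DEFAULT_PARAMS,
) -> FunctionalityCall:
    """Functional/disabled verdict with machine-checkable reasons.

    An allele is functional iff it carries no frame-shifting and no
    splice-disrupting event AND its own spliced CDS (the reference model
    projected through the alignment) starts with ATG, has a length that is
    a multiple of three, contains no premature stop, and yields a protein
    of the reference length (amino-acid substitutions are tolerated).
    """
    reasons: list[str] = []
    for ev in events:
        if ev.frameshift or ev.splice_disrupting:
            reasons.append(mu_ids.get(ev.key, _describe(ev)) if mu_ids else _describe(ev))

    if coord_map is None:
        aln = left_normalize(global_align(reference.seq, allele.seq, params))
        coord_map = build_map(aln)
    cds = _project_and_splice(allele, model, coord_map)
    tr = translate(cds)
    if not tr.starts_with_atg:
        reasons.append("no_atg_start")
    if not tr.length_multiple_of_three:
        reasons.append("cds_length_not_multiple_of_3")
    if tr.premature_stop:
        reasons.append("premature_stop")
    elif len(tr.protein) != reference_protein_len:
        reasons.append("protein_length_mismatch")

    status = FUNCTIONAL if not reasons else DISABLED
    return FunctionalityCall(allele_id=allele.id, status=status, reasons=tuple(reasons))


def _describe(ev: MutationEvent) -> str:
    if ev.kind == INSERTION:
        return f"{ev.kind}@+{ev.ref_start}({ev.length}bp)"
    if ev.kind == DELETION:
        return f"{ev.kind}@+{ev.ref_start}-{ev.ref_end}"
    return f"{ev.kind}@+{ev.ref_start}({ev.detail})"


def _project_and_splice(allele: SequenceRecord, model: GeneModel, cmap: CoordinateMap) -> str:
    """Splice the allele with the reference exon boundaries projected through the map."""
    parts = []
    for s, e in model.exons:
        # Shrink to the surviving mapped boundary positions.
        ap_s = next((cmap.ref_to_alt[p] for p in range(s, e + 1) if cmap.ref_to_alt[p]), None)
        ap_e = next((cmap.ref_to_alt[p] for p in range(e, s - 1, -1) if cmap.ref_to_alt[p]), None)
        if ap_s is None or ap_e is None:
            continue  # exon entirely deleted
        parts.append(allele.seq[ap_s - 1:ap_e])
    return "".join(parts)


def build_catalogue(events_by_allele: Mapping[str, Sequence[MutationEvent]]) -> list[MutationType]:
    """Merge identical events across alleles into Mu-numbered types.

    Types are ordered by ascending reference start, ties broken by kind
    then length then detail; identity requires exact normalized
    coordinates, so near-identical events at shifted positions stay
    distinct types.
    """
    carriers: dict[tuple, list[str]] = {}
    for allele_id, events in events_by_allele.items():
        for ev in events:
            carriers.setdefault(ev.key, [])
            if allele_id not in carriers[ev.key]:
                carriers[ev.key].append(allele_id)
    ordered = sorted(carriers, key=lambda k: (k[1], k[0], k[3], k[4]))
    types = []
    for i, key in enumerate(ordered, start=1):
        kind, start, end, length, detail = key
        ids = tuple(carriers[key])
        types.append(MutationType(
            mu_id=f"Mu{i}", kind=kind, ref_start=start, ref_end=end,
            length=length, detail=detail, frequency=len(ids), allele_ids=ids,
        ))
    return types


def build_matrix(
    allele_ids: Sequence[str],
    catalogue: Sequence[MutationType],
    events_by_allele: Mapping[str, Sequence[MutationEvent]],
    calls: Mapping[str, FunctionalityCall],
) -> MutationMatrix:
    """Presence/absence matrix; a cell is not_applicable when a larger
    deletion in that allele spans the type's locus so presence cannot be
    scored."""
    cells: dict[tuple[str, str], str] = {}
    for aid in allele_ids:
        keys = {ev.key for ev in events_by_allele.get(aid, ())}
        spans = [
            (ev.ref_start, ev.ref_end) for ev in events_by_allele.get(aid, ())
            if ev.kind == DELETION
        ]
        for t in catalogue:
            if t.key in keys:
                cells[(aid, t.mu_id)] = PRESENT
            elif any(s <= t.ref_start and t.ref_end <= e for s, e in spans
                     if (s, e) != (t.ref_start, t.ref_end)):
                cells[(aid, t.mu_id)] = NOT_APPLICABLE
            else:
                cells[(aid, t.mu_id)] = ABSENT
    functionality = {aid: calls[aid].status for aid in allele_ids}
    return MutationMatrix(
        allele_ids=tuple(allele_ids), types=tuple(catalogue),
        cells=cells, functionality=functionality,
    )


def fixture_matrix(
    distribution: Iterable[tuple[str, tuple[str, ...], str]],
    catalogue_entries: Sequence[CatalogueEntry],
    not_applicable: Iterable[tuple[str, str]] = (),
) -> MutationMatrix:
    """Encode a published allele x type table (e.g. the AtTGG6 distribution)."""
    dist = list(distribution)
    na = set(not_applicable)
    counts = {c.mu_id: 0 for c in catalogue_entries}
    cells: dict[tuple[str, str], str] = {}
    functionality: dict[str, str] = {}
    for allele_id, mus, status in dist:
        functionality[allele_id] = status
        for c in catalogue_entries:
            if c.mu_id in mus:
                cells[(allele_id, c.mu_id)] = PRESENT
                counts[c.mu_id] += 1
            elif (allele_id, c.mu_id) in na:
                cells[(allele_id, c.mu_id)] = NOT_APPLICABLE
            else:
                cells[(allele_id, c.mu_id)] = ABSENT
    types = tuple(
        MutationType(
            mu_id=c.mu_id, kind=c.kind, ref_start=c.ref_start, ref_end=c.ref_end,
            length=c.length, detail=c.detail, frequency=counts[c.mu_id],
            allele_ids=tuple(a for a, mus, _ in dist if c.mu_id in mus),
        )
        for c in catalogue_entries
    )
    return MutationMatrix(
        allele_ids=tuple(a for a, _, _ in dist), types=types,
        cells=cells, functionality=functionality,
    )


def intron10_border_region(model: GeneModel, flank: int = 15) -> tuple[int, int]:
    """Window around the 3' acceptor of intron 10, the locus's mutation hot spot."""
    _, (a1, a2) = model.border_positions(10)
    return (a1 - flank, a2 + flank)


def summarize_matrix(
    matrix: MutationMatrix,
    region: tuple[int, int] | None = None,
) -> MatrixSummary:
    """Headline counts: functional/disabled split, type count, per-type
    frequencies, and (optionally) type-occurrences whose locus overlaps a
    stated reference window."""
    n_functional = sum(1 for s in matrix.functionality.values() if s == FUNCTIONAL)
    frequencies = {
        t.mu_id: sum(
            1 for aid in matrix.allele_ids if matrix.cells[(aid, t.mu_id)] == PRESENT
        )
        for t in matrix.types
    }
    events_in_region = None
    if region is not None:
        lo, hi = region
        events_in_region = sum(
            frequencies[t.mu_id] for t in matrix.types
            if t.ref_start <= hi and lo <= t.ref_end
        )
    return MatrixSummary(
        n_alleles=len(matrix.allele_ids),
        n_functional=n_functional,
        n_disabled=len(matrix.allele_ids) - n_functional,
        n_types=len(matrix.types),
        frequencies=frequencies,
        events_in_region=events_in_region,
    )


def events_to_dataframe(events_by_allele: Mapping[str, Sequence[MutationEvent]],
                        mu_ids: Mapping[tuple, str] | None = None) -> pd.DataFrame:
    """Flat mutation report (one row per event), ready for TSV export."""
    rows = []
    for allele_id, events in events_by_allele.items():
        for ev in events:
            rows.append({
                "allele_id": allele_id,
                "mu_id": mu_ids.get(ev.key, "") if mu_ids else "",
                "kind": ev.kind,
                "ref_start": ev.ref_start,
                "ref_end": ev.ref_end,
                "length": ev.length,
                "regions": ";".join(f"{r}{k}" for r, k in ev.regions),
                "exonic_bases": ev.exonic_bases,
                "frameshift": ev.frameshift,
                "splice_disrupting": ev.splice_disrupting,
                "detail": ev.detail,
            })
    return pd.DataFrame(rows)
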