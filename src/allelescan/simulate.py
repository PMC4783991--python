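"""Synthetic allele-population generator with a machine-readable truth ledger.

The generator emulates a single-copy ~2.6 kb plant gene of 13 exons and 12
short introns (donor GT everywhere except the GC donor of intron 10,
acceptor AG everywhere) whose coding sequence translates to a 512-residue
preprotein. Alleles descend from the reference in a star genealogy: each
receives independent neutral substitutions at a fixed per-site rate, then
a planned set of disabling events (indels, splice-border substitutions,
nonsense substitutions) at reference-anchored coordinates. SNPs are placed
before events so that the truth ledger's coordinates stay in reference
space; placement avoids border dinucleotides, the start/stop codons, the
immediate flanks of planned events, and any substitution that would create
an in-frame stop, so that the intended functionality of every allele is
well defined.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datasets import (
    ATTGG6_CATALOGUE,
    ATTGG6_DISTRIBUTION,
    CatalogueEntry,
)
from .gene_model import (
    GeneModel,
    InferenceError,
    STOP_CODONS,
    check_borders,
    infer_model,
    splice,
    translate,
)
from .seqio import SequenceRecord, write_fasta, write_gene_model

INSERTION = "insertion"
DELETION = "deletion"
SPLICE_DONOR_SUB = "splice_donor_sub"
SPLICE_ACCEPTOR_SUB = "splice_acceptor_sub"
NONSENSE = "nonsense"

#: Default exon lengths (sum 1539 nt = 513 codons). The layout is chosen so
#: that the published AtTGG6 lesion coordinates fall in their reported
#: exons/introns: with 85 nt introns, intron 10 runs +2030..+2114 and the
#: 17-base deletion +2111..+2127 removes 4 intron-10 bases plus 13 bases of
#: exon 11, exactly as reported for the real locus.
DEFAULT_EXON_LENGTHS: tuple[int, ...] = (170, 110, 96, 130, 70, 65, 120, 150, 240, 113, 90, 140, 45)
DEFAULT_INTRON_LEN = 85

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)
_STOPS = tuple(sorted(STOP_CODONS))


class PlanError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PlannedEvent:
    """One disabling lesion to plant, in reference coordinates.

    kinds: insertion (ref_start = left flanking base, length = inserted
    bases), deletion (ref_start..ref_end inclusive), splice_donor_sub /
    splice_acceptor_sub (detail "AG>AT" style), nonsense (force a stop at
    the codon containing exonic position ref_start).
    """

    kind: str
    ref_start: int
    ref_end: int
    length: int = 0
    detail: str = ""

    def span(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    exon_lengths: tuple[int, ...] = DEFAULT_EXON_LENGTHS
    intron_len: int = DEFAULT_INTRON_LEN
    gc_donor_introns: tuple[int, ...] = (10,)
    n_alleles: int = 29
    snp_rate: float = 0.0075
    event_plan: Mapping[str, tuple[PlannedEvent, ...]] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 2:
            raise ConfigError("need >= 2 exons")
        if sum(self.exon_lengths) % 3 != 0:
            raise ConfigError("CDS length must be a multiple of 3")
        if self.intron_len < 4:
            raise ConfigError("introns must be >= 4 bases for GT..AG borders")
        if not (0 <= self.snp_rate < 1):
            raise ConfigError("snp_rate must lie in [0, 1)")
        if self.n_alleles < 1:
            raise ConfigError("need >= 1 allele")

    @property
    def cds_len(self) -> int:
        return sum(self.exon_lengths)

    @property
    def gene_len(self) -> int:
        return self.cds_len + (len(self.exon_lengths) - 1) * self.intron_len


@dataclasses.dataclass(frozen=True)
class PlantedAllele:
    allele_id: str
    events: tuple[PlannedEvent, ...]
    snp_positions: tuple[int, ...]
    intended_status: str  # functional / disabled


@dataclasses.dataclass(frozen=True)
class SimTruth:
    seed: int
    reference: SequenceRecord
    model: GeneModel
    alleles: tuple[PlantedAllele, ...]

    def status_of(self) -> dict[str, str]:
        return {a.allele_id: a.intended_status for a in self.alleles}


def _build_model(config: SimConfig) -> GeneModel:
    exons = []
    pos = 1
    for length in config.exon_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + config.intron_len
    return GeneModel.from_exons(exons, config.gc_donor_introns)


def _random_reference_seq(config: SimConfig, rng: np.random.Generator) -> str:
    n_codons = config.cds_len // 3
    codons = ["ATG"]
    codons += [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)]
    codons.append(_STOPS[rng.integers(0, len(_STOPS))])
    cds = "".join(codons)

    parts = []
    offset = 0
    for k, length in enumerate(config.exon_lengths):
        parts.append(cds[offset:offset + length])
        offset += length
        if k < len(config.exon_lengths) - 1:
            donor = "GC" if (k + 1) in config.gc_donor_introns else "GT"
            interior = "".join("ACGT"[i] for i in rng.integers(0, 4, config.intron_len - 4))
            parts.append(donor + interior + "AG")
    return "".join(parts)


def _deletions_left_stable(seq: str, plan: Mapping[str, tuple[PlannedEvent, ...]]) -> bool:
    """True when no planned deletion can slide left under gap normalization
    (which would shift its recovered coordinates off the planted ones)."""
    for events in plan.values():
        for ev in events:
            if ev.kind == DELETION:
                s, e = ev.ref_start, ev.ref_end
                if s >= 2 and seq[s - 2] == seq[e - 1]:
                    return False
    return True


def make_reference(
    config: SimConfig,
    plan: Mapping[str, tuple[PlannedEvent, ...]] | None = None,
    max_attempts: int = 200,
) -> tuple[SequenceRecord, GeneModel]:
    """Random reference honoring the exon/intron layout: CDS starts ATG,
    ends with a stop, no internal in-frame stop, all borders match their
    expected dinucleotides, and the exon intervals are recoverable exactly
    from the cDNA. Reproducible from the config seed.
    """
    model = _build_model(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9001]))
    plan = plan if plan is not None else config.event_plan
    for _ in range(max_attempts):
        seq = _random_reference_seq(config, rng)
        if not all(c.ok for c in check_borders(seq, model)):  # pragma: no cover - by construction
            continue
        if plan and not _deletions_left_stable(seq, plan):
            continue
        cdna = splice(seq, model)
        tr = translate(cdna)
        if tr.premature_stop or not tr.has_terminal_stop:  # pragma: no cover - by construction
            continue
        try:
            inferred = infer_model(seq, cdna, config.gc_donor_introns)
        except InferenceError:
            continue
        if inferred.exons != model.exons:
            continue
        return SequenceRecord(id="reference", seq=seq), model
    raise ConfigError(f"could not build a stable reference in {max_attempts} attempts")


def _ref_to_cds_map(model: GeneModel) -> dict[int, int]:
    mapping = {}
    idx = 0
    for s, e in model.exons:
        for p in range(s, e + 1):
            idx += 1
            mapping[p] = idx
    return mapping


#: Neutral SNPs stay this many bases away from a planted event: a
#: substitution closer than the local alignment trade-off window can make
#: the indel's normalized placement ambiguous (the aligner swallows the
#: mismatch into an equally- or better-scoring shifted gap), and the truth
#: ledger's coordinates would no longer be well defined.
EVENT_FLANK = 10


def _excluded_positions(model: GeneModel, events: Sequence[PlannedEvent], gene_len: int) -> set[int]:
    """Positions neutral SNPs must not touch for this allele."""
    excluded: set[int] = set()
    for k in range(1, model.n_introns + 1):
        (d1, d2), (a1, a2) = model.border_positions(k)
        excluded.update((d1, d2, a1, a2))
    cds_positions = [p for s, e in model.exons for p in range(s, e + 1)]
    excluded.update(cds_positions[:3])   # start codon
    excluded.update(cds_positions[-3:])  # terminal stop
    for ev in events:
        s, e = ev.span()
        excluded.update(range(max(1, s - EVENT_FLANK), min(gene_len, e + EVENT_FLANK) + 1))
    return excluded


def _is_splice_disrupting(ev: PlannedEvent, model: GeneModel) -> bool:
    if ev.kind in (SPLICE_DONOR_SUB, SPLICE_ACCEPTOR_SUB):
        return True
    if ev.kind == DELETION:
        borders = set()
        for k in range(1, model.n_introns + 1):
            for pair in model.border_positions(k):
                borders.update(pair)
        return any(ev.ref_start <= p <= ev.ref_end for p in borders)
    return False


def intended_status(events: Sequence[PlannedEvent], model: GeneModel) -> str:
    """disabled iff any planted event shifts frame, disrupts splicing, or is nonsense."""
    for ev in events:
        if ev.kind == NONSENSE:
            return "disabled"
        if _is_splice_disrupting(ev, model):
            return "disabled"
        if ev.kind in (INSERTION, DELETION):
            if ev.kind == DELETION:
                exonic = model.exonic_overlap(ev.ref_start, ev.ref_end)
            else:
                exonic = ev.length if model.region_of(ev.ref_start)[0] == "exon" else 0
            if exonic > 0 and exonic % 3 != 0:
                return "disabled"
    return "functional"


def _plant_insertion_bases(entry_key: tuple, length: int, ref: str, pos: int,
                           rng: np.random.Generator) -> str:
    """Inserted bases for one catalogue entry, identical across alleles and
    chosen so the insertion cannot slide left under gap normalization."""
    flank = ref[pos - 1] if pos >= 1 else ""
    for _ in range(100):
        bases = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        if not flank or bases[-1] != flank:
            return bases
    raise PlanError(f"could not draw stable insertion bases for {entry_key}")  # pragma: no cover


def simulate_alleles(
    reference: SequenceRecord,
    model: GeneModel,
    config: SimConfig,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Apply neutral SNPs then planned events to each allele; deterministic
    under the config seed (per-allele substreams are derived from the
    allele index, so reordering the plan does not change any sequence)."""
    ref = reference.seq
    gene_len = len(ref)
    plan = dict(config.event_plan)
    allele_ids = list(plan) if plan else [f"sim{i + 1:02d}" for i in range(config.n_alleles)]
    ref_to_cds = _ref_to_cds_map(model)
    cds_to_ref = {v: k for k, v in ref_to_cds.items()}

    for aid, events in plan.items():
        spans = sorted(ev.span() for ev in events)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise PlanError(f"allele {aid!r}: planted events overlap at +{s2}")
        for ev in events:
            if not (1 <= ev.ref_start <= ev.ref_end <= gene_len):
                raise PlanError(f"allele {aid!r}: event outside the gene: {ev}")

    # Draw the inserted bases once per distinct insertion entry.
    insert_bases: dict[tuple, str] = {}
    entry_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7002]))
    all_entries = sorted(
        {(ev.kind, ev.ref_start, ev.length) for events in plan.values()
         for ev in events if ev.kind == INSERTION}
    )
    for key in all_entries:
        _, pos, length = key
        insert_bases[key] = _plant_insertion_bases(key, length, ref, pos, entry_rng)

    records: list[SequenceRecord] = []
    planted: list[PlantedAllele] = []
    for idx, aid in enumerate(allele_ids):
        events = tuple(plan.get(aid, ()))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, idx]))
        seq = list(ref)

        # Neutral SNPs first: truth coordinates stay in reference space.
        excluded = _excluded_positions(model, events, gene_len)
        hits = np.nonzero(rng.random(gene_len) < config.snp_rate)[0] + 1
        snp_positions = []
        for pos in hits:
            pos = int(pos)
            if pos in excluded:
                continue
            old = seq[pos - 1]
            choices = [b for b in "ACGT" if b != old]
            if pos in ref_to_cds:
                # Restrict to substitutions that keep the codon sense, so
                # every eligible site still mutates with probability snp_rate.
                cds_idx = ref_to_cds[pos]
                codon_start = ((cds_idx - 1) // 3) * 3 + 1
                codon = [seq[cds_to_ref[codon_start + k] - 1] for k in range(3)]
                off = (cds_idx - 1) % 3

                def keeps_sense(base: str) -> bool:
                    trial = codon.copy()
                    trial[off] = base
                    return "".join(trial) not in STOP_CODONS

                choices = [b for b in choices if keeps_sense(b)]
                if not choices:  # pragma: no cover - no such codon exists
                    continue
            new = choices[rng.integers(0, len(choices))]
            seq[pos - 1] = new
            snp_positions.append(pos)

        # Planned events, applied right-to-left so coordinates stay valid.
        realized: list[PlannedEvent] = []
        for ev in sorted(events, key=lambda e: -e.ref_start):
            if ev.kind == DELETION:
                del seq[ev.ref_start - 1:ev.ref_end]
                realized.append(ev)
            elif ev.kind == INSERTION:
                bases = insert_bases[(ev.kind, ev.ref_start, ev.length)]
                seq[ev.ref_start:ev.ref_start] = list(bases)
                realized.append(dataclasses.replace(ev, detail=bases))
            elif ev.kind in (SPLICE_DONOR_SUB, SPLICE_ACCEPTOR_SUB):
                try:
                    _, target = ev.detail.split(">")
                except ValueError as exc:
                    raise PlanError(f"splice substitution needs 'XY>XZ' detail: {ev}") from exc
                if len(target) != ev.ref_end - ev.ref_start + 1:
                    raise PlanError(f"target dinucleotide length mismatch: {ev}")
                for off, base in enumerate(target):
                    seq[ev.ref_start - 1 + off] = base
                realized.append(ev)
            elif ev.kind == NONSENSE:
                if ev.ref_start not in ref_to_cds:
                    raise PlanError(f"nonsense event must target an exonic position: {ev}")
                cds_idx = ref_to_cds[ev.ref_start]
                codon_start = ((cds_idx - 1) // 3) * 3 + 1
                refpos = [cds_to_ref[codon_start + k] for k in range(3)]
                for p, base in zip(refpos, "TAA"):
                    seq[p - 1] = base
                realized.append(dataclasses.replace(ev, detail="TAA"))
            else:
                raise PlanError(f"unknown planted event kind {ev.kind!r}")
        realized.reverse()

        records.append(SequenceRecord(id=aid, seq="".join(seq)))
        planted.append(PlantedAllele(
            allele_id=aid,
            events=tuple(realized),
            snp_positions=tuple(snp_positions),
            intended_status=intended_status(events, model),
        ))

    truth = SimTruth(seed=config.seed, reference=reference, model=model, alleles=tuple(planted))
    return records, truth


def plan_from_distribution(
    distribution: Sequence[tuple[str, tuple[str, ...], str]] = ATTGG6_DISTRIBUTION,
    catalogue: Sequence[CatalogueEntry] = ATTGG6_CATALOGUE,
) -> dict[str, tuple[PlannedEvent, ...]]:
    """Event plan replicating a published ecotype x mutation assignment."""
    by_id = {c.mu_id: c for c in catalogue}
    plan = {}
    for allele_id, mus, _status in distribution:
        plan[allele_id] = tuple(
            PlannedEvent(
                kind=by_id[m].kind,
                ref_start=by_id[m].ref_start,
                ref_end=by_id[m].ref_end,
                length=by_id[m].length,
                detail=by_id[m].detail,
            )
            for m in mus
        )
    return plan


def simulate_dataset(config: SimConfig) -> tuple[SequenceRecord, GeneModel, list[SequenceRecord], SimTruth]:
    """Reference + allele population + truth in one call."""
    reference, model = make_reference(config, plan=config.event_plan)
    records, truth = simulate_alleles(reference, model, config)
    return reference, model, records, truth


def emit(records: Sequence[SequenceRecord], truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write alleles/reference FASTA, model TSV, and the truth ledger TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alleles": outdir / "alleles.fasta",
        "reference": outdir / "reference.fasta",
        "model": outdir / "model.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "truth_alleles": outdir / "truth_alleles.tsv",
    }
    write_fasta(records, paths["alleles"])
    write_fasta([truth.reference], paths["reference"])
    write_gene_model(truth.model, paths["model"])
    with open(paths["truth_events"], "w") as fh:
        fh.write("allele_id\tkind\tref_start\tref_end\tlength\tdetail\n")
        for allele in truth.alleles:
            for ev in allele.events:
                fh.write(
                    f"{allele.allele_id}\t{ev.kind}\t{ev.ref_start}\t{ev.ref_end}"
                    f"\t{ev.length}\t{ev.detail}\n"
                )
    with open(paths["truth_alleles"], "w") as fh:
        fh.write("allele_id\tintended_status\tn_events\tsnp_positions\n")
        for allele in truth.alleles:
            snps = ",".join(str(p) for p in allele.snp_positions)
            fh.write(
                f"{allele.allele_id}\t{allele.intended_status}\t{len(allele.events)}\t{snps}\n"
            )
    return paths


def read_truth_events(path: str | Path) -> dict[str, tuple[PlannedEvent, ...]]:
    """Reload the planted-event ledger written by :func:`emit`."""
    out: dict[str, list[PlannedEvent]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header[0] == "allele_id"
        for line in fh:
            aid, kind, s, e, length, detail = line.rstrip("\n").split("\t")
            out.setdefault(aid, []).append(PlannedEvent(
                kind=kind, ref_start=int(s), ref_end=int(e),
                length=int(length), detail=detail,
            ))
    return {k: tuple(v) for k, v in out.items()}
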