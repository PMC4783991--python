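"""Sequence and gene-model I/O.

FASTA reading/writing is delegated to Biopython; this module adds the
alphabet normalization and validation the downstream scanners rely on
(uppercase DNA over {A,C,G,T,N}, U mapped to T, unique record ids) and the
3-column TSV exchange format for single-gene exon models.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gene_model import GeneModel, ModelError

_ALPHABET = set("ACGTN")


class FastaFormatError(ValueError):
    """Malformed or invalid FASTA input."""


class GeneModelError(ValueError):
    """Malformed gene-model table."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, uppercase over {A,C,G,T,N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence record with empty id")
        if not self.seq:
            raise FastaFormatError(f"sequence record {self.id!r} is empty")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def normalize_dna(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against the DNA alphabet."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        raise FastaFormatError(f"{context} contains non-DNA characters: {sorted(bad)}")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-FASTA file into validated records, in file order.

    Lowercase input is uppercased and U is mapped to T. Empty files and
    duplicate ids are format errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = normalize_dna(str(rec.seq), context=f"record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, description=desc))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips through :func:`read_fasta`."""
    if width < 1:
        raise ValueError("line width must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def to_biopython(rec: SequenceRecord) -> SeqRecord:
    return SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)


def read_gene_model(path: str | Path) -> GeneModel:
    """Read the exon-interval TSV (columns exon_index, start, end; 1-based inclusive).

    Exons must be listed in ascending, non-overlapping order; introns are the
    gaps between consecutive exons.
    """
    path = Path(path)
    rows: list[tuple[int, int, int]] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["exon_index", "start", "end"]:
            raise GeneModelError(
                f"expected header 'exon_index\\tstart\\tend' in {path}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GeneModelError(f"{path}:{lineno}: expected 3 columns")
            try:
                idx, start, end = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GeneModelError(f"{path}:{lineno}: non-integer field") from exc
            rows.append((idx, start, end))
    if not rows:
        raise GeneModelError(f"no exon rows in {path}")
    rows.sort(key=lambda r: r[0])
    exons = [(start, end) for _, start, end in rows]
    try:
        return GeneModel.from_exons(exons)
    except ModelError as exc:
        raise GeneModelError(f"{path}: {exc}") from exc


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("exon_index\tstart\tend\n")
        for i, (start, end) in enumerate(model.exons, start=1):
            fh.write(f"{i}\t{start}\t{end}\n")
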