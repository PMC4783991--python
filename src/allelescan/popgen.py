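"""Population diversity statistics over an aligned allele set.

Site filtering follows the common "complete deletion" convention: the
haplotype, segregating-site, pi and theta-w computations use only columns
free of gaps and of N, while indel sites are counted on all columns
(a column with >= 1 gap is one indel site). Per-kilobase densities divide
by the total aligned length. Standard deviations are the classical ones:
Nei (1987) for haplotype and nucleotide diversity, Watterson (1975) for
the variance of S behind theta-w.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .gene_model import GeneModel
from .mutation_scan import FUNCTIONAL, FunctionalityCall
from .seqio import FastaFormatError

GAP = "-"
_ALLOWED = set("ACGTN-")


class AlignmentInputError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MultipleAlignment:
    """Rows of equal length over {A,C,G,T,N,-}; >= 2 rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentInputError("ids and rows differ in count")
        if len(self.rows) < 2:
            raise AlignmentInputError("alignment needs >= 2 rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise AlignmentInputError("rows differ in length")
        bad = set("".join(self.rows)) - _ALLOWED
        if bad:
            raise AlignmentInputError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows])


@dataclasses.dataclass(frozen=True)
class DiversityReport:
    partition_label: str
    n: int
    L_total: int
    L_ungapped: int
    S: int
    indel_sites: int
    n_haplotypes: int | None
    Hd: float | None
    Hd_sd: float | None
    pi: float | None
    pi_sd: float | None
    theta_w: float | None
    theta_w_sd: float | None
    snp_per_kb: float
    indel_per_kb: float
    pct_identity: float | None


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read a gapped multi-FASTA alignment."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace("U", "T"))
    if not ids:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows))


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def _complete_columns(aln: MultipleAlignment) -> np.ndarray:
    """Boolean mask of columns with no gap and no N (the analyzed sites)."""
    m = aln.matrix()
    return ~((m == GAP) | (m == "N")).any(axis=0)


def segregating_and_indel_sites(aln: MultipleAlignment) -> tuple[int, int, int]:
    """(S, indel site count, number of gap-free N-free columns)."""
    m = aln.matrix()
    complete = _complete_columns(aln)
    indel_sites = int((m == GAP).any(axis=0).sum())
    sub = m[:, complete]
    S = int((sub != sub[0]).any(axis=0).sum())
    return S, indel_sites, int(complete.sum())


def haplotype_diversity(aln: MultipleAlignment) -> tuple[float | None, float | None, int | None]:
    """(Hd, SD, number of haplotypes), haplotypes defined on complete columns.

    Hd = n(1 - sum x_i^2)/(n - 1); the SD is the square root of Nei's
    (1987, eq. 8.12) sampling variance.
    """
    n = aln.n
    m = aln.matrix()
    complete = _complete_columns(aln)
    if not complete.any():
        return None, None, None
    haplos = ["".join(row) for row in m[:, complete]]
    counts = pd.Series(haplos).value_counts().to_numpy()
    x = counts / n
    sum2 = float(np.sum(x ** 2))
    sum3 = float(np.sum(x ** 3))
    hd = n * (1.0 - sum2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2
    )
    return hd, math.sqrt(max(var, 0.0)), len(counts)


def _pairwise_stats(aln: MultipleAlignment) -> tuple[float | None, float | None, int]:
    """Mean pairwise difference and identity proportions on complete columns."""
    m = aln.matrix()
    complete = _complete_columns(aln)
    L = int(complete.sum())
    if L == 0:
        return None, None, 0
    sub = m[:, complete]
    n = aln.n
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((sub[i] != sub[j]).sum()))
    mean_diff = float(np.mean(diffs)) / L
    mean_ident = 1.0 - float(np.mean(diffs)) / L
    return mean_diff, mean_ident, L


def nucleotide_diversity(aln: MultipleAlignment) -> tuple[float | None, float | None]:
    """(pi, SD): mean pairwise difference per complete site; Nei (1987, eq. 10.7) SD."""
    pi, _, L = _pairwise_stats(aln)
    if pi is None:
        return None, None
    n = aln.n
    var = ((n + 1) * pi) / (3.0 * (n - 1) * L) + (
        2.0 * (n * n + n + 3) * pi * pi
    ) / (9.0 * n * (n - 1))
    return pi, math.sqrt(max(var, 0.0))


def harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i ** power for i in range(1, n))


def watterson_theta(aln: MultipleAlignment) -> tuple[float | None, float | None]:
    """(theta_w per site, SD) from S over complete columns.

    theta_w = S / (a_n * L); the SD comes from Watterson's variance of S,
    Var(S) = a1*theta*L + a2*(theta*L)^2, evaluated at the estimate.
    """
    S, _, L = segregating_and_indel_sites(aln)
    if L == 0:
        return None, None
    n = aln.n
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    theta_site = S / (a1 * L)
    theta_total = S / a1
    var_S = a1 * theta_total + a2 * theta_total ** 2
    var_site = var_S / (a1 * L) ** 2
    return theta_site, math.sqrt(max(var_site, 0.0))


def column_regions(aln: MultipleAlignment, model: GeneModel, ref_id: str) -> list[str]:
    """Assign every alignment column to 'exon' or 'intron' by projecting the
    model through the reference row; insertion columns (gap in the reference
    row) inherit the region of the left flanking reference base, and columns
    outside the model count as non-coding (intron partition)."""
    if ref_id not in aln.ids:
        raise AlignmentInputError(f"reference id {ref_id!r} not in alignment")
    ref_row = aln.rows[aln.ids.index(ref_id)]
    regions = []
    pos = 0
    current = "intron"  # left flank of any column before the first reference base
    for ch in ref_row:
        if ch != GAP:
            pos += 1
            kind, _ = model.region_of(pos)
            current = "exon" if kind == "exon" else "intron"
        regions.append(current)
    return regions


def partition_alignment(
    aln: MultipleAlignment, model: GeneModel, ref_id: str
) -> dict[str, MultipleAlignment]:
    """Split columns into the exonic and intronic sub-alignments; the two
    column sets partition the alignment."""
    regions = column_regions(aln, model, ref_id)
    out = {}
    for label in ("exons", "introns"):
        want = "exon" if label == "exons" else "intron"
        cols = [i for i, r in enumerate(regions) if r == want]
        rows = tuple("".join(row[i] for i in cols) for row in aln.rows)
        if cols:
            out[label] = MultipleAlignment(ids=aln.ids, rows=rows)
        else:
            out[label] = None
    return out


def subset_rows(
    aln: MultipleAlignment,
    calls: Mapping[str, FunctionalityCall] | Mapping[str, str],
    status: str,
) -> MultipleAlignment | None:
    """Rows whose functionality matches ``status``; None (with a warning)
    when fewer than two remain."""
    def status_of(rid: str) -> str:
        c = calls[rid]
        return c.status if isinstance(c, FunctionalityCall) else c

    keep = [i for i, rid in enumerate(aln.ids) if status_of(rid) == status]
    if len(keep) < 2:
        warnings.warn(
            f"partition {status!r} has {len(keep)} sequence(s); report skipped",
            stacklevel=2,
        )
        return None
    return MultipleAlignment(
        ids=tuple(aln.ids[i] for i in keep),
        rows=tuple(aln.rows[i] for i in keep),
    )


def diversity_report(aln: MultipleAlignment, label: str) -> DiversityReport:
    """All statistics for one partition."""
    S, indel_sites, L_ungapped = segregating_and_indel_sites(aln)
    hd, hd_sd, n_hap = haplotype_diversity(aln)
    pi, pi_sd = nucleotide_diversity(aln)
    tw, tw_sd = watterson_theta(aln)
    _, ident, _ = _pairwise_stats(aln)
    return DiversityReport(
        partition_label=label,
        n=aln.n,
        L_total=aln.length,
        L_ungapped=L_ungapped,
        S=S,
        indel_sites=indel_sites,
        n_haplotypes=n_hap,
        Hd=hd, Hd_sd=hd_sd,
        pi=pi, pi_sd=pi_sd,
        theta_w=tw, theta_w_sd=tw_sd,
        snp_per_kb=1000.0 * S / aln.length,
        indel_per_kb=1000.0 * indel_sites / aln.length,
        pct_identity=None if ident is None else 100.0 * ident,
    )


def five_partition_report(
    aln: MultipleAlignment,
    model: GeneModel,
    ref_id: str,
    calls: Mapping[str, FunctionalityCall] | Mapping[str, str],
) -> pd.DataFrame:
    """The standard layout: genomic / exons / introns / functional / nonfunctional."""
    reports: list[DiversityReport] = [diversity_report(aln, "genomic")]
    parts = partition_alignment(aln, model, ref_id)
    for label in ("exons", "introns"):
        if parts[label] is not None:
            reports.append(diversity_report(parts[label], label))
    for status, label in ((FUNCTIONAL, "functional"), ("disabled", "nonfunctional")):
        sub = subset_rows(aln, calls, status)
        if sub is not None:
            reports.append(diversity_report(sub, label))
    return pd.DataFrame([dataclasses.asdict(r) for r in reports])
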