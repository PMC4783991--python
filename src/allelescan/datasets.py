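"""Published AtTGG6 mutation catalogue and its distribution across ecotypes.

The 13 disabling mutation types (Mu1-Mu13) reported for the AtTGG6
myrosinase locus of *Arabidopsis thaliana* (GenBank KU301827-KU301855),
with coordinates counted from the first base of the start codon of the
functional Tsu-1 allele, and the published presence/absence matrix over
the 29 sequenced ecotypes. These serve both as a realistic event plan for
the allele simulator and as a fixture for the matrix-summary statistics.
"""

from __future__ import annotations

import dataclasses

INSERTION = "insertion"
DELETION = "deletion"
SPLICE_ACCEPTOR_SUB = "splice_acceptor_sub"
SPLICE_DONOR_SUB = "splice_donor_sub"


@dataclasses.dataclass(frozen=True)
class CatalogueEntry:
    """One canonical disabling lesion, in reference coordinates."""

    mu_id: str
    kind: str
    ref_start: int
    ref_end: int
    length: int  # inserted/deleted bases; 0 for border substitutions
    detail: str = ""


#: Disabling lesions at the AtTGG6 locus. Insertions are keyed to the
#: reference base immediately left of the inserted bases; intron 10 of the
#: reference runs +2030..+2114, so the AG->AT / AG->GG events substitute its
#: 3' acceptor dinucleotide at +2113..+2114.
ATTGG6_CATALOGUE: tuple[CatalogueEntry, ...] = (
    CatalogueEntry("Mu1", INSERTION, 155, 155, 2),
    CatalogueEntry("Mu2", DELETION, 437, 644, 208),
    CatalogueEntry("Mu3", INSERTION, 481, 481, 1),
    CatalogueEntry("Mu4", INSERTION, 1007, 1007, 1),
    CatalogueEntry("Mu5", INSERTION, 1158, 1158, 2),
    CatalogueEntry("Mu6", DELETION, 1739, 1742, 4),
    CatalogueEntry("Mu7", DELETION, 1804, 1817, 14),
    CatalogueEntry("Mu8", DELETION, 2111, 2127, 17),
    CatalogueEntry("Mu9", SPLICE_ACCEPTOR_SUB, 2113, 2114, 0, "AG>AT"),
    CatalogueEntry("Mu10", SPLICE_ACCEPTOR_SUB, 2113, 2114, 0, "AG>GG"),
    CatalogueEntry("Mu11", INSERTION, 2121, 2121, 1),
    CatalogueEntry("Mu12", DELETION, 2311, 2327, 17),
    CatalogueEntry("Mu13", DELETION, 2348, 2348, 1),
)

#: The published ecotype x mutation distribution: for each of the 29
#: ecotypes, the set of carried mutation types and the functionality verdict.
#: One cell was reported "not applicable": the Mu2 deletion in Pr-0 spans the
#: Mu3 locus, so Mu3 presence cannot be assessed there.
ATTGG6_DISTRIBUTION: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("Aa-0", ("Mu1",), "disabled"),
    ("Ag-0", (), "functional"),
    ("Ba-1", ("Mu13",), "disabled"),
    ("Col-0", ("Mu1", "Mu4", "Mu6", "Mu8", "Mu12"), "disabled"),
    ("Col-4", ("Mu1", "Mu4", "Mu6", "Mu8", "Mu12"), "disabled"),
    ("Col-J", ("Mu1", "Mu4", "Mu6", "Mu8", "Mu12"), "disabled"),
    ("Cvi-0", ("Mu1", "Mu4", "Mu6", "Mu8", "Mu12"), "disabled"),
    ("Bsch-0", (), "functional"),
    ("Edi-0", ("Mu13",), "disabled"),
    ("Gel-0", (), "functional"),
    ("Gre-0", ("Mu3", "Mu9"), "disabled"),
    ("JM-1", ("Mu4",), "disabled"),
    ("JM-2", ("Mu4",), "disabled"),
    ("Kas-1", ("Mu1",), "disabled"),
    ("La-0", (), "functional"),
    ("Ler-1", (), "functional"),
    ("Mir-0", ("Mu5", "Mu11"), "disabled"),
    ("Mz-0", ("Mu10",), "disabled"),
    ("Mr-0", (), "functional"),
    ("Oy-0", (), "functional"),
    ("Pr-0", ("Mu1", "Mu2", "Mu7"), "disabled"),
    ("Stw-0", ("Mu1", "Mu10"), "disabled"),
    ("Ts-6", ("Mu5",), "disabled"),
    ("Tsu-0", (), "functional"),
    ("Tul-0", ("Mu3", "Mu9"), "disabled"),
    ("Ty-0", (), "functional"),
    ("Van", ("Mu10",), "disabled"),
    ("Ws-0", ("Mu3",), "disabled"),
    ("Wil-0", (), "functional"),
)

#: Reported not-applicable cells (allele id, mu id): a larger deletion in
#: that allele spans the type's locus, so presence cannot be scored.
ATTGG6_NOT_APPLICABLE: tuple[tuple[str, str], ...] = (("Pr-0", "Mu3"),)


def catalogue_by_id() -> dict[str, CatalogueEntry]:
    return {entry.mu_id: entry for entry in ATTGG6_CATALOGUE}
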