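"""End-to-end population scan: align every allele against the reference,
type the lesions, call functionality, and assemble the matrix."""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from .align import AlignParams, DEFAULT_PARAMS
from .gene_model import GeneModel, splice, translate
from .mutation_scan import (
    FunctionalityCall,
    MutationEvent,
    MutationMatrix,
    MutationType,
    build_catalogue,
    build_matrix,
    call_functionality,
    scan_allele,
)
from .seqio import SequenceRecord


@dataclasses.dataclass(frozen=True)
class PopulationScan:
    reference: SequenceRecord
    model: GeneModel
    events: Mapping[str, tuple[MutationEvent, ...]]
    catalogue: tuple[MutationType, ...]
    calls: Mapping[str, FunctionalityCall]
    matrix: MutationMatrix

    @property
    def mu_ids(self) -> dict[tuple, str]:
        return {t.key: t.mu_id for t in self.catalogue}


def scan_population(
    alleles: Sequence[SequenceRecord],
    reference: SequenceRecord,
    model: GeneModel,
    params: AlignParams = DEFAULT_PARAMS,
) -> PopulationScan:
    """Scan every allele and summarize the population.

    The reference protein length is derived from the reference itself
    (its spliced CDS minus the terminal stop).
    """
    ref_tr = translate(splice(reference.seq, model))
    ref_protein_len = len(ref_tr.protein)

    events: dict[str, tuple[MutationEvent, ...]] = {}
    maps = {}
    for allele in alleles:
        evs, cmap = scan_allele(allele, reference, model, params)
        events[allele.id] = tuple(evs)
        maps[allele.id] = cmap

    catalogue = tuple(build_catalogue(events))
    mu_ids = {t.key: t.mu_id for t in catalogue}
    calls = {
        allele.id: call_functionality(
            allele, events[allele.id], model, reference,
            reference_protein_len=ref_protein_len,
            coord_map=maps[allele.id], mu_ids=mu_ids, params=params,
        )
        for allele in alleles
    }
    matrix = build_matrix([a.id for a in alleles], catalogue, events, calls)
    return PopulationScan(
        reference=reference, model=model, events=events,
        catalogue=catalogue, calls=calls, matrix=matrix,
    )
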