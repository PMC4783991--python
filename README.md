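# allelescan

Splice-aware scanning of gene allele sets for disabling mutations, with
partitioned population-diversity statistics and a distance phylogeny.

## The problem

Plant defense genes are repeatedly lost in lineages where the selection
pressure maintaining them has relaxed. A well-documented case is the pollen
myrosinase locus *AtTGG6* in *Arabidopsis thaliana*: across 29 natural
ecotypes, ten alleles encode an intact 512-residue Myr II myrosinase while
the other nineteen are pseudogenized by a highly polymorphic set of
frame-shift insertions/deletions and splice-border lesions — thirteen
distinct mutation types, concentrated around the unusual GC/AG splicing
border of intron 10. Deciding which alleles are functional, typing each
lesion reproducibly, and quantifying the diversity contrast between
functional and disabled alleles takes a small pipeline:

1. **Gene-model annotation** — exon/intron intervals on a reference allele,
   inferred by mapping its cDNA onto the genomic sequence, with per-intron
   expected splice dinucleotides (donor GT, or GC for intron 10; acceptor AG).
2. **Mutation scanning** — each allele is globally aligned to the reference
   with affine gap costs, gaps are left-normalized so indels get stable
   reference-anchored coordinates (counted from the first base of the start
   codon), and every indel plus every border dinucleotide that no longer
   matches its expected set becomes an event. Events shared across alleles
   are merged into catalogue types *Mu1…MuN*, ordered by position.
3. **Functionality calling** — an allele is *functional* iff it carries no
   frame-shifting event (exonic indel length ≢ 0 mod 3) and no
   splice-disrupting event, and its own spliced CDS starts with ATG, has no
   premature stop, and translates to the reference protein length.
4. **Diversity statistics** — haplotype diversity Hd = n(1 − Σxᵢ²)/(n − 1),
   nucleotide diversity π (mean pairwise differences per site), and
   Watterson's θ_w = S/(aₙL), each with the classical Nei (1987) /
   Watterson (1975) standard deviations, computed on gap- and N-free
   columns, reported for five partitions: whole gene, exons, introns,
   functional alleles, disabled alleles.
5. **Phylogeny** — Tamura–Nei (1993) distances (pairwise deletion) and a
   Saitou–Nei neighbor-joining tree, on which the minimum number of
   independent functional→disabled transitions is counted by small
   parsimony with the root constrained to the ancestral functional state.

A seeded simulator generates the study conditions — a ~2.6 kb gene of 13
exons and 12 introns with the GC donor on intron 10, neutral SNPs at
0.0075/site, and planted lesions from the published catalogue — together
with a machine-readable truth ledger, so every stage is validated by exact
recovery tests.

## Worked example

```python
from allelescan import (SimConfig, plan_from_distribution, simulate_dataset,
                        scan_population, summarize_matrix, intron10_border_region)

cfg = SimConfig(seed=1, event_plan=plan_from_distribution())
reference, model, records, truth = simulate_dataset(cfg)
scan = scan_population(records, reference, model)
s = summarize_matrix(scan.matrix, intron10_border_region(model))
print(f"alleles={s.n_alleles} functional={s.n_functional} disabled={s.n_disabled} "
      f"types={s.n_types} intron10_region_events={s.events_in_region}")
```

prints

```
alleles=29 functional=10 disabled=19 types=13 intron10_region_events=10
```

i.e. the scanner re-detects, from the simulated sequences alone, the
published split of 10 functional / 19 disabled alleles, all 13 mutation
types at their reference coordinates, and the 10 lesion occurrences
clustered at the intron-10 3′-border hot spot. Individual alleles carry
interpretable calls:

```python
print(scan.events["Col-0"])   # ins +155 (2 bp), ins +1007, del 1739-1742,
                              # del 2111-2127, del 2311-2327
print(scan.calls["Col-0"])    # disabled, reasons: Mu1, Mu4, Mu6, Mu8, Mu12, ...
```

The same objects feed the diversity report
(`allelescan.popgen.five_partition_report`) and the tree
(`allelescan.phylo.nj_tree` + `min_independent_losses`); on the simulated
population above the parsimony count is 7 independent loss events for the
19 disabled leaves.

The shell interface mirrors the library:

```bash
allelescan simulate --seed 4 --plan catalogue --out data/
allelescan annotate data/reference.fasta cdna.fasta --out model.tsv
allelescan scan data/alleles.fasta --reference data/reference.fasta \
    --model data/model.tsv --out scan/
allelescan diversity msa.fasta --model model.tsv --reference-id reference \
    --calls scan/calls.tsv --out diversity/
allelescan phylo msa.fasta --aligned --calls scan/calls.tsv --out phylo/
```

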