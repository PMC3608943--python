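# barcode-audit

A reusable pipeline for auditing DNA-barcode reference libraries of
megadiverse faunas — the analysis a large regional COI survey runs between
"we sequenced 1,200 fish" and "barcoding discriminates 99% of our species
and flags a dozen candidate cryptic ones".

It is aimed at molecular ecologists and taxonomists who hold a set of COI
barcodes with specimen-level taxonomy and want, reproducibly and offline:

* **Quality control** — reading-frame anchoring in the vertebrate
  mitochondrial code, stop-codon and indel screening, length filtering.
* **Divergence structure** — Kimura-2-parameter (K2P) distances with
  pairwise deletion, pooled min/mean/max/SE per taxonomic rank, divergence
  histograms and the barcode-gap ratio.
* **Cluster analysis** — neighbour-joining dendrograms with nonparametric
  (column-resampling) bootstrap support, and species-cohesion tests
  (is each species an exclusive cluster on the tree?).
* **Species delimitation** — nearest-neighbour distances, screening of
  species pairs below a divergence cutoff (2% by default), discrimination
  verdicts (shared haplotypes / non-exclusive clusters), deep-divergence
  flagging with single-linkage subcluster partitioning, per-genus cutoff
  calibration, and the subcluster-corrected intraspecific mean.
* **Character-based diagnostics** — exclusive and partial shared
  nucleotide diagnostics (NDs) within a comparison group, plus
  combination-based discrimination over the informative sites for species
  with no exclusive ND.
* **A seeded simulator** of survey-scale barcode datasets with the
  divergence structure of a recently radiated fauna and full truth tables,
  so the entire pipeline is testable without any download.

## The statistics at the core

For a sequence pair compared at *n* sites (sites with `N`/gaps in either
sequence are dropped pairwise), with observed transition and transversion
proportions *P* and *Q*, the K2P distance is

```
d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)
```

in substitutions/site (reported as %). Pairs with non-positive logarithm
arguments are *saturated* and recorded as undefined rather than clamped.

Divergences are pooled by the lowest taxonomic rank a specimen pair
shares (conspecific, congeneric, confamilial, ...). The barcode gap is
the ratio of the congeneric to the conspecific mean. A species is
*deep-divergent* when its maximum intraspecific distance exceeds the
cutoff; its specimens are then partitioned into single-linkage
subclusters (links cut strictly at the cutoff, or at the largest merge
gap to mimic visual delimitation), and treating each subcluster as an
independent unit yields the corrected intraspecific mean.

An alignment position is an *exclusive ND* for a species when the species
is fixed for a nucleotide absent from every other species in the group,
and a *partial shared ND* when that state is absent from some but not all
others. Species without exclusive NDs can still be discriminated by a
unique combination of states over the informative positions.

## Worked example

```python
import barcode_audit as ba

config = ba.SimConfig(n_orders=3, n_families_per_order=2, n_genera_per_family=2,
                      n_species_per_genus=(2, 3), specimens_mean=4.0, seed=11)
dataset = ba.simulate_dataset(config)           # 115 specimens, 30 species
dm = ba.pairwise_matrix(dataset.records)
taxonomy = ba.taxonomy_frame(dataset.records)

for s in ba.rank_summary_table(dm, taxonomy):
    if s.mean is not None:
        print(f"{s.rank:15s} n={s.n_comparisons:5d}  mean={s.mean:5.2f}%  max={s.max:5.2f}%")

tree = ba.nj(dm)
verdicts, success = ba.discrimination_status(dm, tree, taxonomy)
print(f"discrimination success: {100*success:.1f}%")
```

prints

```
within_species  n=  308  mean= 0.89%  max= 4.99%
within_genus    n=  428  mean= 4.28%  max=13.73%
within_family   n=  502  mean=17.50%  max=27.48%
within_order    n= 1250  mean=20.82%  max=36.86%
within_class    n= 4067  mean=22.22%  max=34.70%
discrimination success: 93.3%
```

Divergence rises with rank, and 28 of 30 species are discriminated — the
two failures are the simulator's injected shared-haplotype pair
(`Genus008 sp. 2/3`, distance 0, the one situation distance data cannot
resolve). Following the deep-divergence screen:

```python
flags = ba.deep_divergence_flags(dm, taxonomy, cutoff=0.02)
parts = [ba.subcluster_partition(dm, sp, taxonomy) for sp in flags["species"]]
corr = ba.rank_summary_table(dm, taxonomy, partition=ba.partition_units(parts))
```

reports `Genus011 sp. 1: max intra 5.0%, 3 subclusters (2.5-5.0%)` — a
candidate cryptic-species complex — and correcting for subclusters drops
the intraspecific mean from 0.89% to 0.48%, widening the barcode gap from
4.8x to 8.9x.

The same audit runs from the shell:

```
barcode-audit simulate --seed 7 --out data/
barcode-audit run --fasta data/sequences.fasta --meta data/metadata.tsv \
    --out report/ --boot 1000 --seed 7
```

producing a report bundle (QC table, distance matrix in TSV/PHYLIP, rank
summaries raw and corrected, histogram data, newick tree with supports,
NND/low-pair/discrimination/deep-divergence tables, ND reports, and a
JSON manifest echoing every parameter).

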