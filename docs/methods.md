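# Methods

This note records the models, conventions and design decisions behind
`barcode_audit`, in the order the pipeline applies them.

## Quality control and frame anchoring

COI barcodes are protein-coding, so the quality filters are: ungapped
length ≥ 500 bp (inclusive), no internal alignment gaps, and zero stop
codons of the vertebrate mitochondrial code (TAA, TAG, AGA, AGG) in the
best reading frame. All six frame/strand combinations are scanned on the
gap-stripped sequence; "best" is fewest stops among complete codons, ties
preferring the forward strand and then the lowest offset. Trailing
partial codons are ignored, so appending one or two bases never changes a
verdict for in-frame input. Ambiguity codes other than N carry no usable
signal under pairwise deletion and are normalised to N on input.

Rather than shipping an aligner, the pipeline *frame-anchors*: each
passing sequence is oriented to the forward strand, trimmed to start on a
codon boundary, and truncated to the common overlap (floored to whole
codons). This treats codon phase as the only alignment degree of
freedom, which is correct for coamplified, indel-free barcode fragments
of one locus and is exactly the regime the QC step enforces; it does not
handle indels (which fail QC) or non-homologous fragments.

QC failures are excluded from analysis by default and retained only on
request (`keep_failures`): flagged-and-excluded is the conservative
default when a study's handling of sub-length sequences is not recorded.

## K2P distances

Distances use the Kimura two-parameter closed form with *pairwise*
deletion — a site is dropped only for pairs in which either sequence has
N or a gap there — matching the defaults of the distance tools barcode
studies conventionally use and preserving per-pair information.
Saturated pairs (non-positive logarithm arguments) are stored as
undefined, NaN in the matrix, with the pair listed; downstream summaries
skip them with a count, and tree building refuses them explicitly rather
than clamping, since clamping would fabricate a finite distance with no
support in the data. Distances are proportions internally; every report
multiplies by 100.

## Rank summaries

Each specimen pair contributes to exactly one rank: the lowest rank at
which the two lineages share a name. Statistics are pooled over
comparisons; a per-taxon averaging mode exists because published summary
tables do not always state their pooling. SE is the standard deviation
of the pooled comparisons over √(count) — a choice documented here
because summary tables in the literature rarely define their SE column.
Interim "Genus sp. N" labels are full species-rank units. The taxon
count per rank counts taxa contributing at least one defined comparison
(for species, those with ≥ 2 specimens).

The corrected intraspecific mean restricts the within-species pool to
same-subcluster pairs, given a partition of deep-divergent species'
specimens. Dropping cross-subcluster pairs can only lower the mean for
threshold partitions (the dropped pairs sit above the linkage cutoff);
for arbitrary partitions this is not a theorem, which is why the property
test exercises the partitions the pipeline actually produces.

## Neighbour joining and bootstrap

NJ is implemented directly (Saitou–Nei Q-criterion, standard two-point
branch lengths) so that two behaviours are pinned: exact ties in Q break
on the lexicographically smallest pair of cluster representative labels
(determinism for tests and reruns), and negative branch-length estimates
are clamped to zero with the length transferred to the sister edge,
preserving the joined pair's distance. On additive matrices NJ is exact;
the suite verifies topology and branch lengths to 1e-9 against randomly
generated trees, and cross-checks topologies against an independent NJ
implementation on noisy matrices.

Bootstrap support resamples alignment columns with replacement, rebuilds
the K2P matrix and NJ tree per pseudoreplicate, and maps bipartition
frequencies onto the tree from the original alignment. Pseudoreplicates
that produce a saturated pair are dropped and counted. Pendant edges are
trivially supported and excluded from reports. 1,000 replicates is the
conventional default; tests and the acceptance script use far fewer
because support values enter only ordinal checks there.

## Delimitation

Species-to-species distance is the minimum over inter-specimen pairs (the
nearest-neighbour convention) for the NND table and the low-divergence
screen; strict inequalities apply at every cutoff (< for screening,
> for deep-divergence flagging), so a pair exactly at the 2% default is
neither screened nor flagged. Discrimination combines two signals: a
species fails by *shared haplotype* if any specimen is at distance
exactly zero from a heterospecific specimen, else by *non-exclusive
cluster* if its specimens are not one side of an edge of the unrooted NJ
tree; single-specimen species are trivially exclusive.

Subclusters are single-linkage clusters cut strictly below the cutoff —
provably identical to connected components of the sub-cutoff distance
graph, which the suite checks against an independent graph
implementation. Because visually delimited subclusters can be separated
by less than a fixed cutoff, a "largest-gap" mode instead cuts at the
biggest jump between consecutive merge heights. Note that single-linkage
chaining means a species can exceed the cutoff in diameter yet form one
subcluster. Between-subcluster distances are reported as min/mean/max
since either min or mean may be the quantity of interest.

The per-genus calibration table (genera with ≥ 3 species by default)
reports pooled interspecific min/mean/max and the range of per-species
intraspecific maxima, with an overlap flag when some species' spread
exceeds the genus' smallest interspecific gap — the situation in which a
global 2% cutoff is unsafe and a genus-specific one is needed.

## Nucleotide diagnostics

Within a comparison group, a species is *fixed* at a position when its
unambiguous states there reduce to one nucleotide; N/gaps never certify
presence or absence, and a species with no unambiguous state at a
position is treated as unknown, which conservatively blocks exclusivity
claims. Exclusive = fixed and absent from every other species; partial
shared = fixed and absent from some but not all. The published usage of
"partial shared" is not spelled out formally anywhere we know of; this
reading is the standard one and is the package's definition.

Combination discrimination compares state strings over the informative
positions with within-species polymorphic positions acting as wildcards
that match anything — the conservative rule, which never overstates
discrimination. Two species are separated at a position only when both
are fixed for different states. The minimal discriminating subset is a
set cover over separable pairs: exhaustive for ≤ 12 informative
positions, greedy above (minimality is then not guaranteed, but the
uniqueness verdicts, which are what matter, do not depend on it).
Positions are 1-based relative to the group alignment.

## The synthetic-data generator

The generator emulates a recently radiated, megadiverse freshwater fauna
at survey scale. Defaults: 10 orders, 2–5 families/order, 2–5
genera/family, 1–3 species/genus (~250 species); specimens per species
geometric with mean 4.9 clipped to 1–56; 648 bp sequences. Sequences
evolve from a stop-free random root by Poisson substitution: each event
picks a site with codon-position weights (2 : 1 : 4.5, putting ~60% of
events at third positions), applies a transition with odds κ = 6 against
the two transversions, and is resampled if it would create an internal
stop — so generated data always pass QC by construction.

Branch depths derive from rank divergence targets (congeneric 6.8%,
family 20.1%, order 23.3%, class 24.5%, each net of the 0.3% tip
contribution, halved per branch side). Species stem lengths are
*exponential* around the calibrated mean with a 0.25% floor — the
Yule-like age distribution of a recent radiation — which produces the
observed long left tail of congeneric divergences (species pairs below
the 2% screen, nearest-neighbour distances down to ~0.5%) while keeping
even the youngest pairs separable from intraspecific spread. Pooled
congeneric means of single replicates consequently wobble by ~±15%;
calibration checks and the acceptance script therefore average three
seeded replicates.

Intraspecific variation is star-like: half the specimens carry their
unit's modal haplotype exactly (surveys report most species as a unique
haplotype or tight cluster), the rest mutate from the centroid at a rate
rescaled so the expected within-unit divergence stays at θ = 0.3%. A
coalescent is deliberately not simulated: only pairwise-distance moments
feed the pipeline, and no intraspecific genealogical structure is being
tested.

Anomalies are injected last. Deep splits go to ~5.5% of species, drawn
with probability proportional to their intraspecific comparison count
(splits are only observable where comparisons exist) under two
constraints: at most one deep species per genus, and the split depth
(uniform 1.4–8%) must not exceed the species' centroid gap to its
nearest congener — a split deeper than that gap would not present as one
deeply divergent species. Lineage centroids sit at half the depth around
the species centroid, so lineages end up the configured depth apart
without inflating the congeneric pool. Shared-haplotype pairs re-centre
the second species on the first's centroid and copy one haplotype
exactly, reproducing a mutually cohesive, indistinguishable pair without
manufacturing a spurious deep split.

What passing tests on this generator do **not** show about real data:
there are no indels, no contamination, no misidentified vouchers, no
geographic structure, no rate variation among lineages beyond the
codon-position weights, and intraspecific variation has no genealogy.
Splits shallower than the cutoff are injected (the 1.4% end of the depth
range) and are correctly *not* recovered by a 2% screen; truth-table
recovery is exact only when depths clear the cutoff plus noise, which the
acceptance check exercises at a 4% depth.

Known limitation: in the simulated radiation, roughly 1% of species per
survey-scale replicate fail cohesion spuriously — extremely close
congeneric pairs (stems near the floor) whose stray haplotypes interleave
on the NJ tree, occasionally including a spontaneous identical haplotype
across species. Real surveys of comparable scale report almost none,
likely because real conspecific sampling is tighter than the star model;
the simulated discrimination success runs ~0.5–2 points below a real
survey's as a result.

## Problem sizes

The default test suite runs small configurations (30–120 specimens) plus
three survey-scale simulations for calibration, finishing in well under a
minute. The acceptance script audits three full survey-scale replicates
(~1,200 specimens each: distance matrix, NJ tree, full delimitation) in
about half a minute; bootstrap supports are omitted there because every
reported quantity is support-independent.
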