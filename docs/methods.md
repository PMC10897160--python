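# Methods

This note documents the models and procedures implemented in `ecckit`, the
parameter choices that matter, what the bundled simulator does and does not
emulate, and the numerical conventions used throughout.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to 1-based SAM
coordinates happens only in the pysam-backed readers and writers, and BED
output is 0-based half-open. Supplementary alignments follow the SAM `SA`
tag grammar `chrom,pos,strand,CIGAR,mapQ,NM;` with the position 1-based in
the tag and converted at the boundary.

## Deduplication

Duplicate read pairs are collapsed on the pair of clip-adjusted (unclipped)
5′ positions and orientations of both mates. The clip-aware key matters
here more than in ordinary WGS: split reads at circle junctions are
soft-clipped, and a clip-unaware key would treat each clipped copy of the
same fragment as a distinct position. Among duplicates the pair with the
highest summed mapping quality is kept (ties: lexicographically smallest
read name), so the choice is deterministic. Orphan reads deduplicate on
their single-end key.

## Chimeric (circle-supporting) reads

Split reads are primary records carrying at least one `SA` descriptor with
mapping quality strictly above 20. Discordant pairs are inter-chromosomal,
orientation-anomalous (everted RF — the signature of a pair straddling a
circular junction — or tandem FF/RR), or span more than `insert_threshold`
(default 1000 bp; typical short-insert libraries rarely exceed ~600 bp, so
1 kb is conservative). Pairs in tandem orientation with read 2 aligned
upstream of read 1 are treated as rolling-circle chimera artifacts ("R2R1"
reads) and removed from both sets by default; the definition is this
package's interpretation of an artifact class that is usually described
only loosely, and the filter can be disabled.

## CPR calling

Coverage is binned (100 bp default) counting each primary, non-duplicate
read in every bin it overlaps. Bins with
`count >= max(min_cov, enrichment_factor × background)` form candidate
runs, where the background is the 0.25 quantile of nonzero bin counts over
all non-excluded contigs. The low quantile is deliberate: after exonuclease
digestion the residual linear background is sparse (most bins empty, hits
mostly 1–2 reads), while circle footprints can account for a large share of
the *nonzero* bins; a median would then land inside the signal population
and inflate the threshold severely, whereas the first quartile stays in the
background population as long as background bins make up at least a quarter
of the nonzero bins. Defaults: `min_cov` 5 reads/bin, enrichment factor 4,
merge gap 1 kb, border refinement at 10% of the region maximum, minimum CPR
length 200 bp. Mitochondrial and spike-in contigs are excluded from calling
but kept for normalization and QC.

Border refinement moves each border outward over adjacent bins holding at
least `edge_fraction × region max` reads, then inward past sub-threshold
edge bins, never crossing the coverage apex. A plateau with sharp edges is
a fixed point.

## Junction clustering

Raw junctions (one per primary/supplementary pair of a split read) are
canonicalized with the genomically smaller breakend first and clustered by
single linkage: two raw junctions link when the paired breakends are each
within 500 bp. Clusters with fewer than 2 reads are discarded. The cluster
representative is the per-end lower weighted median (the smallest position
whose cumulative weight reaches half the total) — robust to stray split
positions and exactly reproducible by the brute-force oracle used in tests.
Junction support counts split reads only; discordant pairs corroborate CPRs
but never junction coordinates, since their breakpoints are only resolved
to within an insert length.

Span classes: *edge-joining* (both breakends within 500 bp of a CPR's
extremities), *internal* (inside a CPR but not edge-joining), *distal-intra*
(same chromosome, separation > 1 Mb, outside any one CPR), and
*inter-chromosomal*. A CPR is *simple* when all of its junctions (at most
2, allowing both strand representations of one junction) are edge-joining,
*complex* otherwise, *unclassified* with no junction.

## Classification model

For pseudo-bulk CPR *j*: `f_raw = N_pos/N_tot` with a cell positive when
one of its circles covers at least 10% of the CPR length; `j_raw` is the
mean over **all** cells of the Jaccard index between the CPR and the union
of the cell's overlapping circles (cells without overlap contribute 0; the
union is used because one region frequently yields several sub-circles in
a cell). Both are divided by the mitochondrial references and capped at 1;
`U = f_norm × j_norm`; labels use strict thresholds `f > 0.65`, `U > 0.3`
applied to the normalized frequency (switchable to `f_raw`). The same
thresholds define all four quadrants. The mitochondrial references are
computed by treating the mito contig as a full-length pseudo-CPR carried by
every cell with at least `min_mito_reads` (default 10) mito-mapped reads,
giving `f_mt = J_mt =` the carrying fraction.

All of these quantities are validated for exact equality against an
independent per-base set-arithmetic oracle on randomized toy populations.

## QC

Per-cell metrics: mapping rate (mapped primaries / all primaries, computed
before deduplication), circular spike-in enrichment (circular / all
spike-in reads), circle-read enrichment (fraction of reads with midpoint
inside a CPR), CPR count, and a mappability proxy (fraction of primary
reads with mapQ > 20; true mappability tracks would need external data).
Default filters: mapping rate ≥ 0.90, spike-in enrichment ≥ 0.80, ≥ 100
CPRs, mappability ≥ 0.70, failing on any violation; an alternative rule
applies the two read-level filters jointly. The 100-CPR floor is calibrated
to whole-genome data; on the ~1 Mb simulated genomes used in tests and in
the acceptance script the same fraction of territory corresponds to a floor
of a few CPRs, and the configs used there set `min_cprs = 3` accordingly.

## Landscape analyses

*Autocorrelation*: Pearson r between the binned circle-read signal and its
copy shifted by d, per contig, combined by bin-count weights; the null
baseline permutes the genomic order of bins (preserving the count
marginal), seeded. *GC comparison*: per-CPR GC against length- and
contig-matched random intervals rejected against CPR overlap, two-sided
rank-sum. *Meta-gene profiles*: read midpoints, gene bodies scaled to a
fixed number of columns with fixed-width flanks, minus-strand genes
reversed; placing reads by midpoint avoids double counting across bins.
*Feature overlap*: ≥ 1 bp intersection; the feature fraction is the share
of circle reads inside feature-overlapping CPRs. *Co-occurrence*: Pearson
correlation of per-cell presence vectors (binary by default, abundance
switchable) against an anchor region. *Expression correlation*: per-gene
Pearson correlation across cells between normalized eccDNA reads and
log1p-transformed expression; genes above 0.6 flagged. *CN-stratified
density*: CPR midpoints per 100 kb of copy-number-class territory, Welch
two-sided t-tests between classes. *Daughter distances*: Euclidean
distances between cells' normalized abundance vectors, reported separately
per label class. "Normalized eccDNA copy number" is defined as the
per-CPR circle-read count divided by the cell's mitochondrial read count
(consistent with the mitochondrial normalization of the classification
model); reads-per-million is available as an alternative.

## Topic model

The cells × bins matrix counts circle reads (midpoint rule) inside each
cell's own CPRs in 2-kb bins; all-zero bins are dropped and per-cell
normalized values are stored alongside the raw counts. LDA operates on the
raw counts — a multinomial count model — while the normalized matrix
serves the landscape analyses; this is why `BinMatrix` carries both. The
decomposition is batch variational EM (scikit-learn), seeded and therefore
deterministic. Priors are symmetric Dirichlet in the 50/K style, clamped
to the [0, 1] range the implementation accepts (so effectively α = 1 for
K ≤ 50) with β = 0.1. Model selection computes the log-likelihood across a
topic-number grid and picks the point of most negative discrete second
derivative (the elbow); ties break toward lower perplexity. Differential
topics use a two-sided rank-sum test with Benjamini–Hochberg adjustment in
place of a count-model GLM, because topic contributions are continuous
simplex values, keeping the published selection thresholds (fold change
> 2 on linear means, adjusted p < 0.5). UMAP embedding is an optional
seeded wrapper for visualization only.

## Simulator

The simulator writes per-cell SAM directly at the alignment level — no
aligner in the loop — which keeps the test bed deterministic, seedable and
dependency-free. A run is fully reproducible from (design, seed); the
manifest lists per-file SHA-256 checksums.

Default design (the benchmark study conditions): 20 cells; a 1 Mb two-contig
main genome at GC 0.41; 50 singleton circles per cell with lengths uniform
in 1–4 kb; 30× circle depth and 0.1× residual linear background; a 16-kb
mitochondrial surrogate and 2-kb circular/linear spike-in contigs at 30× /
0.3×; 150-bp paired reads with 300 ± 50 bp inserts; base error rate 0.001.
Planted circles keep ≥ 2 kb spacing within a cell so that distinct planted
circles remain distinct under the 1-kb merge rule — consistent with real
CPR landscapes, where circles cover a few percent of the genome. Uneven
single-cell amplification is modeled as a per-circle lognormal depth
multiplier (σ = 0.5, unit mean). Pair counts per circle are Poisson with
mean `length × depth / (2 × read length)`; fragment positions are uniform
modulo the circle length, so reads crossing the closure point are emitted
as soft-clipped primaries plus supplementary records with exact `SA`
descriptors (overhangs under 20 bp stay soft-clip only, mirroring aligner
behavior), and pairs straddling the closure come out everted. Complex
circles concatenate 2–4 segments, optionally across contigs, producing
inter-chromosomal junctions. The recurrent-circle design places one 10-kb
circle at a shared locus in a configurable fraction of cells, optionally
jittering each cell's borders by a fraction of the circle length.

What the simulator does **not** emulate: mapping ambiguity (all records get
mapQ 60; the mapQ filters are exercised by constructed toys instead),
PCR/optical duplicates, chimera artifacts beyond the R2R1 class, base
quality variation, indels, reverse-strand circle segments (complexity comes
from multi-segment composition), and replication-timing or GC coverage
biases. Passing the recovery benchmarks therefore demonstrates the
correctness of the algorithms under clean mapping, not robustness to
repeat-rich real genomes.

The planted-partition generator for topic benchmarks draws each cell's
reads from its group's disjoint bin block (95%) plus a uniform noise floor
(5%), 200 reads/cell — strong but not degenerate structure, enough for the
elbow rule to identify the true topic number.

## Problem sizes and determinism

Unit tests run on 3-cell populations over 0.5 Mb genomes; the recovery
benchmarks use the default 20-cell design above, a 20-cell classification
design (one recurrent circle in 90% of cells plus 10 singletons per cell,
with an identical-border and a ±20%-per-border jittered variant), and a
60-cell topic population. Every stochastic step takes an explicit seed;
reruns are byte-identical, and the acceptance script derives all seeds from
its `--seed` argument.

## Known limitations

- Circle reconstruction stops at junction calling and structure classes;
  full amplicon architecture assembly (ordered segment paths) is out of
  scope.
- The frequency/uniformity model assumes one pseudo-bulk per population;
  multi-donor harmonization is not attempted.
- The quantile background estimator assumes background bins are at least a
  quarter of nonzero bins; extremely circle-dense samples would need a
  lower quantile or an explicit background model.
- `cn_density` consumes externally produced integer copy-number segments;
  copy-number calling itself is not implemented.
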