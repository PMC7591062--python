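# Methods

This note documents the models, parameters and numerical conventions behind
`satellitome`, what the synthetic-data generator does and does not emulate,
and the design choices made where the protocol left the design open.

## The inference procedure

The pipeline mirrors a contig-screening satellitome protocol for the seven
diploid *Chenopodium album* aggregate species: tandem arrays are detected in
the longest assembled contigs, each new family receives a consensus monomer
and a conserved 9–12 bp motif, the remaining genomes are scanned with that
motif at zero mismatches, and a family counts as present in a genome only
when its hits form arrays — low-copy dispersed hits are treated as genetic
noise. Families present in all species are group-specific, in exactly one
species-specific, otherwise lineage-specific. Microsatellite load is
summarized as the number of exact (TTA)₆ hits in the 50,000 longest contigs
and reported relative to a reference genome. Long reads are screened with
the same motif-chaining machinery, and consensus monomers are related by a
distance tree.

## Tandem-array detection

**Periodicity score.** For a window `s` the score of period `p` is the mean
base identity between `s[i]` and `s[i+p]` over all valid `i` — a direct
autocorrelation for which an exact brute-force oracle exists (the unit tests
hold the optimized path equal to a naive reimplementation on every input up
to 2 kb). Candidate periods are local maxima above a floor of 0.60; a
multiple `kp` of an accepted fundamental is suppressed when its score is
within 0.03 of the fundamental's. The floor and tolerance are conventions:
at the generator's default 5 % copy divergence, a true period scores
`(1−d)² + d²/3 ≈ 0.90`, random background scores ≈ 0.25, and 0.60 splits the
two with a wide margin up to ~20 % divergence.

**Candidate windows.** Scoring every position of a megabase contig at every
period is wasteful; a position is marked repetitive when its exact 12-mer
recurs within the maximum period (500 bp), and marked runs merged across
≤ 500 bp gaps become the scored windows. At 5 % divergence an exact 12-mer
survives in a neighboring copy with probability ≈ 0.54, so true arrays are
densely marked, while a random 12-mer recurrence within 500 bp has
probability ≈ 3·10⁻⁵ per position and never forms a scoreable window.

**Boundary refinement.** Within a window the monomer grid is seeded at the
most self-consistent adjacent monomer pair (a global column majority would
mix phases when composite-array spacers desynchronize the grid), extended
monomer-by-monomer while identity to the running consensus is ≥ 0.70, and
then trimmed/extended base-by-base with a +1/−2 match/mismatch score
anchored one period inside the run; the boundary is the score argmax. At a
random flank the argmax can overshoot the true edge by a base or two when
background happens to continue the repeat — the boundary there is genuinely
ambiguous — so copy number is reported as `round(span/period)`, which is
exact for every embedded test geometry. If the refined consensus is an
exact self-repetition (a microsatellite caught at a multiple of its unit in
a mixed window) the period is reduced to the fundamental.

**Anchored mode.** A family whose conserved unit is followed by variable
spacers (the dispersed-motif structure) has no autocorrelation peak. For
windows where no period clears the floor, the most frequent exact 12-mer is
used as an anchor; its occurrences are chained, the unit length is the
minimum anchor gap, and unit-length windows at the anchors are consensused.
The unit estimate can be inflated by a few bases when the minimal-gap copy
pair lacks the exact anchor; clustering absorbs this (below).

**Merging and filters.** Same-period arrays separated by ≤ 500 bp are merged
(composite arrays — sub-arrays with 50–300 bp spacers — become one call;
arrays 1 kb apart stay separate). Calls overlapping > 50 % with different
periods keep the higher score (harmonic duplicates). The study's selection
filter then requires > 30 monomers for minisatellites and > 5 for satellites,
with the minisatellite/satellite boundary set at period 60 bp — the protocol
uses the two terms without defining the boundary; 60 bp covers the 21–60 bp
monomers on one side and the ~170 bp monomers on the other, and is
configurable.

## Consensus, motifs, families

Monomers are aligned by best circular rotation to a fixed reference — the
lexicographically smallest input monomer, which makes the consensus
invariant to input order — and consensused by column majority with ties
broken A<C<G<T; the consensus length is the modal monomer length. No indel
handling is attempted in v1 (the generator is substitution-only; real
satellites indel, and an indel-aware wraparound alignment is the natural
extension).

The conserved motif is the 9–12 bp consensus window (circular) contained
exactly by the largest fraction of monomers, ties preferring longer windows
then smaller offsets. Conservation is measured as exact-substring fraction
because the motif's downstream role is a zero-mismatch scan. With few
monomers the returned window can be a superset of the seeded motif (flank
columns conserved by chance); scanning and family identification are robust
to this.

Families are single-linkage clusters of array consensi: two arrays link when
their consensus lengths are within a 0.6 min/max ratio and their best
rotation-aligned, free-end-gap identity (over the shorter) is ≥ 0.80 — the
low end of the reported within-family similarity range. The length gate
exists because identity is measured over the shorter sequence, so without it
a short consensus could link into an unrelated long one through a chance
window; 0.6 still lets a unit with a slightly inflated anchored estimate
(e.g. 29 bp for a 21 bp unit) join its family, after which the joint
consensus is rebuilt from monomers near the median length. Family ids are
assigned by decreasing total member span. Clusters with units ≤ 6 bp are
reported as microsatellite families and excluded from the satDNA presence
matrix.

## Presence profiling

Exact motif hits (both strands — array orientation in contigs is arbitrary)
are chained per contig and strand while consecutive spacing is ≤ 4 monomer
lengths; a chain of ≥ 5 hits is an array and one array anywhere in the
genome's 1,000 longest contigs confirms presence. The protocol states the
array criterion but not the numbers: 5 echoes its "> 5 monomers" satellite
threshold, and 4× accommodates the dispersed-motif family, whose generator
spacing is at most 4 monomer lengths between consecutive conserved units.
Group-specific classification requires ≥ 2 species; a single-species dataset
classifies everything species-specific. Overlapping (TTA)₆ hits all count
(a pure convention, documented so counts are reproducible): a (TTA)₈ run
contributes hits at offsets 0, 3 and 6.

## Long-read structure

Read-level chains tolerate gaps up to 10 monomer lengths so a composite
array stays one call. Structure is classified by hit geometry: continuous
when the median spacing is within ±25 % of the monomer and no gap exceeds
2× monomer; composite when splitting at > 2× gaps yields ≥ 2 sub-chains of
≥ 3 hits whose spacings are ≥ 80 % uniform (within ±25 % of the monomer),
the sub-chains hold ≥ 60 % of all hits, and separating gaps are ≤ 10×
monomer; otherwise dispersed-motif. The uniformity and coverage conditions
keep irregular dispersed chains, which occasionally contain short
regular stretches, out of the composite class. All thresholds are
conventions (the source material describes the structures qualitatively)
and are function parameters.

Ultralong units are called from self-dot-plot word runs (16-mers, skipping
words occurring > 64 times): a separation ≥ 5 kb is a unit when runs sharing
it (within 1 %) cover ≥ 50 % of it — a perfect repeat yields a single
maximal run covering the unit entirely, so a lone run qualifies only with
≥ 90 % coverage; separations that are multiples of an accepted unit are
suppressed. Random reads up to 100 kb cannot reach 2.5 kb of coincident
16-mer coverage, so the false-positive rate is effectively zero (tested over
200 reads).

## Distance tree

Pairwise distances between consensi use the best circular-rotation,
free-end-gap substitution alignment of the shorter against the longer, with
distance = mismatches / aligned columns. A global multiple alignment is
ill-posed for monomers of arbitrary phase and lengths spanning 21–170 bp;
this pairwise substitution distance is the package's main methodological
substitution for an MSA-based distance and is exercised directly in tests.
The tree is standard neighbor joining (the agglomerative minimum-evolution
estimator) with Q-criterion ties broken by smallest leaf label and negative
branch lengths clamped to zero (logged). NJ provably recovers additive
matrices; tests verify this against exhaustive least-squares topology search
up to 8 taxa and against an independent NJ implementation.

## The synthetic study

The generator emulates the seven-genome study design: eight families with
the published conserved motifs, monomer lengths realized exactly at 40, 170,
170, 40, 48, 21, 21 and 60 bp (stated as approximate; exact integers give
recovery tests a sharp truth), the published 7×8 presence pattern, TTA
microsatellite arrays up to 1,500 bp with per-species loads proportional to
the published relative densities, one ultralong (~13 kb unit, 2–3 copy)
decayed-TE tandem repeat per genome, and adjacent placement of the two
colocalizing families when both are present. Genomes default to 1 Mb in
twenty 50 kb contigs — a scaled-down stand-in for the real 924–2,608 Mbp
genomes with relative family loads preserved; per-family array counts and
copy ranges (e.g. 300–1,000 copies for the dominant 40 bp family, 6–20 for
the 170 bp family reported at up to 20 copies, ~2.5 kb spans for the 40 bp
species-specific family) are chosen to respect both the reported array
geometries and the > 30/> 5 selection filter.

Divergence is substitution-only (default 5 %, the middle of the reported
80–96 % clone-to-consensus identity range), with the conserved-motif window
fully protected by default and the substitution budget concentrated on the
remaining positions so whole-copy identity still averages `1 − d`; a
configurable fraction of copies can mutate the motif to stress zero-mismatch
scanning. Monomers are uniform random fill around the published motifs (the
true consensi are not reproduced in the source), generated once per study so
all species share each family's monomer, and resampled until they contain no
other family's motif on either strand — the motifs are diagnostic probes by
construction. Background is i.i.d. uniform ACGT (GC knob available);
dispersed single motif copies of absent families are sprinkled at low
density by default as the noise that presence-calling must ignore. Long
reads are error-free substrings by default (substitution knob ≤ 0.1), with
per-read truth in read-local coordinates.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: indels and higher-order repeat structure within
arrays, nanopore error profiles (homopolymer bias), GC heterogeneity and
gene content of real contigs, organelle/rDNA contamination (the contig
exclusion filter is exercised with synthetic references), and any
quantitative genome-abundance figures, which depend on the real assemblies.
The per-species TTA relative densities of the real study are likewise not
reproducible from synthetic data; only the statistic's definition is
implemented, and the generator's loads make the synthetic relative densities
land near, not on, the published percentages.

## Problem sizes and determinism

Default test and acceptance runs use 1 Mb genomes (seven species), 20
simulation seeds for the family-recovery check, 100–200 seeds for
classification/consensus rate checks, and reads of tens of kb — sizes chosen
so the full suite completes in well under two minutes on one core while
keeping every statistical check at its stated confidence. All randomness
flows through numpy `default_rng` seed sequences; identical seeds give
byte-identical FASTA/GFF3 output.

## Known limitations

Substitution-only alignment throughout (no indel-aware consensus or
distances); no higher-order-repeat inference; no TE annotation (associating
families with transposable-element domains requires external domain
databases and is out of scope); reverse-complement array insertion is not
simulated by default, although scanning handles both strands; the anchored
unit-length estimator is biased upward by at most a few bases when anchor
coverage is sparse.
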