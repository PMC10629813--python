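# Methods

`tadreg` re-implements, as a tested pipeline over synthetic data, an
integrative chromatin analysis that links classes of transcription-factor
ChIP-seq peaks (ZMYM2-style zinc-finger repressor biology) to co-factor
occupancy, genomic features, retrotransposon classes, and regionally
scoped differential expression inside topologically associating domains
(TADs).  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic test bed does and does not show.

## Coordinate and data model

All intervals are 0-based half-open (`[start, end)`, BED convention).
Gene tables may declare 1-based coordinates with a `#coordinate_base=1`
header and are converted at load.  Chromosome names are matched exactly —
no `chr`-prefix coercion; two inputs sharing zero chromosome names trigger
a loud warning rather than silent emptiness.  A peak has two anchors with
different roles: the *summit* (peak-caller maximum, from the narrowPeak
offset column) anchors genomic-feature classification and motif windows;
the *centre* (`floor((start+end)/2)`) anchors signal windows, TAD
containment, and all distance statistics.  TADs must be non-overlapping per
chromosome; overlap is a load-time error, and containment of a position in
`[start, end)` is half-open, so a TSS exactly on a boundary belongs to the
downstream TAD only.

The reciprocal-overlap predicate used for peak-set comparisons requires
the shared span to cover at least 30% of *each* interval's length; the
threshold is a parameter (`frac`) with 0.3 as the analysis default.

## Signal clustering

For each peak the 10 kb window centred on the peak centre is split into
100 bins of 100 bp per coverage track; each bin holds the mean per-base
coverage from the bedGraph step function (positions beyond chromosome ends
contribute zero).  Before clustering, each track's columns are divided by
that track's global 95th-percentile bin value so a deeply sequenced track
cannot dominate Euclidean distance; raw mode is available.  Rows are
clustered with Lloyd's k-means, k = 3 by default, best of `n_init = 25`
seeded restarts.

k-means labels are arbitrary, so clusters are renumbered semantically:
with a designated "repressive" track (default TRIM28), the cluster with
the highest mean on that track becomes cluster 1; the remaining clusters
follow in order of descending overall mean signal, so the active cluster
(high ADNP/ATAC in the planted design) ranks 2 and the signal-poor cluster
ranks 3.  Descending overall signal was chosen over descending size for
the tail order because the two non-repressive planted classes are equally
sized by construction, which would leave the size rule deciding by noise.
Without a designated track the fallback is descending size.  Superimposing
a new track onto a retained clustering recomputes only the window matrix
of the new track and averages it under the existing labels.

## Genomic-feature classification

Five mutually exclusive categories per summit, with strand-aware windows:
promoter = 1 kb upstream to 0.1 kb downstream of the TSS; TTS = 0.1 kb
upstream to 1 kb downstream of the transcription end; exonic/intronic are
tested in the gene interior between those windows (genes without exon
lists count as single-exon); precedence across all genes is promoter >
tts > exonic > intronic, with distal intergenic as the residual.  The
genome-wide baseline is the bp fraction of each category under the same
windows and precedence (a declared choice; a random-region baseline would
be equally defensible).

## Repeat composition

A peak "contains" a repeat element if they overlap by at least
`min_overlap_bp` (default 1 bp — the most inclusive defensible reading of
"containing"; the flag makes the choice explicit).  Class-level fractions
are per cluster and may sum past 1 (a peak can contain several classes).
Family-level composition is restricted to a parent class and reported
relative to the peaks of the cluster containing that class.  A fixed
family-to-class lookup ships with the package; unknown families are only
accepted under class "other", and exact-duplicate repeat records are
dropped at load.

## Consensus motif scanning

IUPAC consensus matching (exact character-class match, both strands) in a
101 bp window centred on each summit.  The background is a seeded set of
equal-width regions placed uniformly on the same chromosomes, 10x the
region count by default.  On the synthetic random-ACGT genome the
background frequency of a 12-mer consensus is essentially zero, so the
peak-vs-background contrast is much starker than on a real genome, where
low-complexity and repeat-derived matches inflate the background; the
synthetic contrast validates the scanner, not the biological effect size.

## Differential expression integration

DE tables are consumed, not fitted: a gene is *up* when adjusted p < α and
fold change > f (defaults α = 0.01, f = 1.6; both strict inequalities),
*down* by the mirrored criterion, else *unchanged*.  A missing adjusted-p
column is an error — there is no silent fallback to raw p.  Directional
set overlaps are tested with the two-sided Fisher exact test and the
hypergeometric upper tail over the tested-gene universe.

The distance-bracket association asks, for each distance d in a strictly
increasing ladder (default 5, 10, 25, 50, 100 kb), whether a gene set
overlaps `K_d` — the universe genes whose TSS lies within d bp of any peak
centre — more than hypergeometric chance allows: p = P(X ≥ k | N, K_d, n).
Brackets are cumulative (nested windows), matching the "within the
indicated distances" reading; a disjoint-ring mode exists behind a flag.
The universe is the set of genes present in the DE table, conditioning
enrichment on testability.  No correction across brackets or gene sets is
applied by default (raw hypergeometric p is reported); Benjamini–Hochberg
is available as a helper.  Random-gene controls draw seeded, equal-sized
gene sets without replacement (default 10 sets) and report per-bracket
mean and sd overlap.

## TAD-scoped analyses

Peaks (centres) and genes (TSSs) are assigned to TADs by half-open
containment; items outside every TAD are listed unassigned and excluded
from regional statistics.  For the direction test, a TAD belongs to
category "cluster c" if it contains at least one cluster-c peak — a TAD
with peaks of several clusters counts in each such category (an exclusive
mode drops them) — and "no peak" if it contains none.  Per category the
up/down counts of contained DE genes are compared with the no-peak
category in a 2×2 Fisher test.  The statistical unit is the gene, which
overstates independence when regulation is genuinely regional
(pseudoreplication); the caveat is inherent to the design.

The co-localization test permutes gene labels, not peaks: observed =
fraction of up-genes whose TAD contains a peak; null = the same statistic
for random gene subsets of equal size drawn from all TAD-assigned genes,
preserving the genes-per-TAD structure the statistic conditions on.  The
estimator p = (1 + #{null ≥ obs}) / (1 + n_perm) never returns zero.

Peak-to-boundary distance is the bp from the peak centre to the nearer
boundary of its TAD (≤ half the TAD length by construction).  Controls are
uniform *points* within TAD-covered territory — distances are measured
from centres, and sampling outside TADs would leave the distance
undefined — with n = 2360 per set and two independent sets by default;
Welch's two-sided t-test compares each cluster against each control set.
For uniform positions in a TAD of length L the distance min(U, L−U) is
uniform on (0, L/2), hence mean L/4 — the closed form the tests check.

The adjacent-TAD mirror control takes every (peak, up-gene) pair sharing a
TAD, computes the centre-to-TSS distance d, and searches the opposite
direction for gene TSSs at distance (1 ± 0.25)·d whose TSS lies in a TAD
different from the peak's.  "Adjacent" defaults to *any other TAD* (the
search geometry almost always lands in a flanking one); a strict mode
restricts to the immediate neighbours.  Candidate genes are counted
uniquely across all qualifying peaks.

## Spectral-count filtering

The interactor filter removes proteins found in more than 50% of CRAPome
runs, ribosomal proteins (from a caller-supplied id list — no nomenclature
pattern matching), and proteins with a zero spectral count in any
replicate, then keeps proteins whose replicate-mean count is strictly
greater than 4.  Output is ranked by mean count, ties broken by protein
id.  The filter is monotone in both thresholds.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions.  Default scale: 2 chromosomes × 10 Mb, TADs tiled with uniform
lengths 250–400 kb (~63 TADs), 1200 genes (uniform placement, lengths
2–20 kb, random strand), 600 peaks in three archetypes of 200.  Each
archetype is hosted by a random quarter of the TADs (subsets may overlap;
the fraction is a floor and grows automatically if slot capacity falls
short at small scales), leaving roughly 40% of TADs peak-free for the
no-peak baseline.  Peak centres sit on a per-TAD grid spaced 12 kb with
±1 kb jitter, so 10 kb signal windows never collide.

Coverage: per-track Gaussian bumps (σ = 700 bp) at peak centres over a
background of λ = 0.5 per bp.  Bump apex heights are gamma-distributed
around the archetype mean (shape 8 — a gamma–Poisson/negative-binomial
noise model) and bin read counts are Poisson.  Archetype means encode the
planted contrasts: archetype 1 high ZMYM2/TRIM28/SUMO (30) and low
ATAC/H3K18ac (1); archetype 2 high ZMYM2/ADNP/ATAC/H3K18ac; archetype 3
ZMYM2 only.  Repeats are co-placed with peaks — LTR/ERV1 at rate 0.8 with
archetype 1, SINE (Alu or MIR) at 0.7 with archetype 2, LTR/ERVL at 0.7
with archetype 3 — over a uniform background of 600 elements of all
classes.

DE: null genes have log2FC ~ N(0, 0.4); a location-independent background
of 7.5% of genes per direction is shifted by ±2.0; 60% of the remaining
genes in archetype-1 TADs are shifted by +2.0 (the planted regional
effect).  p-values come from the z-score and are BH-adjusted, so the
thresholds behave coherently without simulating counts.  The background
DE is what makes the regional test well-posed when the regional effect is
removed (Δ = 0): up/down sets then exist but are independent of TAD
content, which is exactly the null the calibration checks.  These effect
and rate choices were fixed by a prospective power analysis: at the
defaults the cluster-1 direction test rejects at p < 0.01 in >99% of
simulations, and with Δ = 0 its p < 0.05 rate is ~5% (Fisher's discreteness
keeps it slightly conservative with these counts).

The genome is uniform random ACGT with a concrete realisation of the
consensus written at 15% of peak summits.  A toy 60-protein spectral-count
table plants 20 true interactors among CRAPome-frequent contaminants,
ribosomal proteins, and dropouts.

All randomness derives from one master seed through named numpy
`SeedSequence` sub-streams (one per stage), so the same config and seed
produce a byte-identical bundle, and consuming one stream never perturbs
another.

### What the synthetic bed does not show

Real ChIP-seq coverage has GC and mappability structure, fragment-length
autocorrelation, and input-dependent background, none of which are
modelled; real TADs are nested and cell-type variable; real DE effect
sizes are continuous rather than two-point; the random genome makes motif
backgrounds unrealistically clean.  Passing tests therefore demonstrate
correctness of the computations and recoverability of planted structure
at realistic scale — not biological conclusions about any real dataset.

## Numerical choices and degenerate inputs

Empty clusters are flagged, not errors; categories without DE genes and
clusters with fewer than two assigned peaks report NaN sentinels rather
than fabricated p-values.  Nearest-distance ties go to the first target in
sorted genomic order.  Distance from a position just past an interval's
half-open end is measured to the last contained base.  The hypergeometric
upper tail is `scipy.stats.hypergeom.sf(k-1, ...)`; Fisher tests are
`scipy.stats.fisher_exact` — both are cross-checked in the test suite
against full-enumeration oracles written from the probability mass
function.  Problem sizes in the replicated studies (100 planted and 1000
null simulations of the geometry-plus-DE layer; the full bundle for
single-run recovery) were chosen so the whole suite runs in well under a
minute per study on one core.

## Known limitations

The per-gene statistical unit in the direction test (above); single-end
"reads" are not simulated, so coverage noise is bin-wise independent;
`n_init = 25` stabilises but does not guarantee the global k-means
optimum; the family-level repeat fractions can exceed 1 in sum when a
peak carries several families of one class.
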