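# Methods

## Coordinates and overlap

All intervals are 0-based half-open (BED dialect), the convention of the
ENCODE track ecosystem the input formats come from. *Overlap* always means
at least one shared base; no minimum overlap width is imposed anywhere.
`merge_overlapping` also merges book-ended intervals (`a.end == b.start`),
matching `bedtools merge`; consequently `merge_within_gap(·, 0)` and
`merge_overlapping` coincide. Gap distance in `merge_within_gap` is
edge-to-edge (`next.start − prev.end`). Intervals produced near chromosome
boundaries (promoter windows, peak extensions) are truncated to
`[0, chromosome length)` rather than rejected or shifted.

## Cluster model

Peaks carry no strand, so the 2,000-bp extension is symmetric about the
peak midpoint; peaks already ≥2,000 bp long are left as called. Clusters
are the connected components of the extended-interval overlap graph,
computed by a single sorted sweep (equivalent to the O(n²) pairwise graph;
the test suite checks this equivalence against a scipy connected-components
oracle on hundreds of random instances). A cluster's *region* is the union
of its members' extended intervals — one contiguous span per component —
and is the coordinate used for every downstream overlap test, so reported
cluster lengths are extended-footprint lengths. Components smaller than
`min_cluster_size` (default 2, i.e. singletons) are returned separately,
and the peak-count partition identity |peaks| = Σ cluster sizes + Σ
singleton sizes holds for any size limit.

The shuffle null redraws each peak start independently and uniformly
within its chromosome, preserving peak length, factor and intensity. The
placeable span is `floor(mappability · L)` with mappability 0.88 (the
fraction of a chromosome alignable with 25-bp reads); starts are drawn
from `[0, mappability·L − length]` inclusive. Shuffled peaks may collide —
chance co-location is exactly what the null is meant to measure.

Intensity bins are equal-count quantile bins (not equal-width): peaks are
stably sorted by intensity and split into `n_bins` chunks whose sizes
differ by at most one, with the most intense peaks in the top bin. Ties
keep input order.

## Gene model

The nonredundant gene set groups genes transitively by same-strand exon
overlap and keeps the highest-expression gene per group (ties: longest
transcript, then lexicographic id). Expression tertiles are computed over
this nonredundant set, since it is the set every downstream mapping uses:
the top ⌊n/3⌋ genes with positive expression are `high`, genes with
expression exactly 0 are `zero`, the rest `medium_low`. The TSS of a
minus-strand gene is its `tx_end`; promoter windows (−2,000/+200 bp) and
10-kb upstream windows mirror accordingly.

Cluster gene context gives promoter precedence: a cluster overlapping any
promoter window is a promoter cluster; otherwise overlap with a gene body
or 10-kb upstream window makes it a gene cluster; otherwise it is
intergenic. When several genes qualify, the gene whose TSS is nearest the
cluster midpoint is assigned (the label itself never depends on this
choice). The 10-kb upstream window is not trimmed when it overlaps a
neighbouring gene's promoter; promoter precedence already resolves those
clusters.

## Transcript/enhancer rules

Mark domains enter the analysis twice: full length for the transcript
rules, and split left-to-right into ≤5,000-bp pieces for every overlap
statistic (broad domains would otherwise swamp region counts). The rules
are evaluated in the fixed order H3K36me3 → Pol II → linked H3K4me3 → Pol
III, which only determines the recorded provenance — the class is
order-independent, and adding mark regions can only move clusters from
enhancer to transcript. The H3K4me3 link test uses full-length domains on
both sides. Pol III calls use direct overlap, without the H3K4me3 link
(the link rule exists because H3K4me3 alone marks many non-transcribed
promoters; Pol III data are treated as independent transcription
evidence). Clusters whose members all belong to the excluded factor set
(default {CTCF, Rad21}, architectural rather than locally regulatory) are
dropped from classification; mixed clusters keep all their peaks.

## Composition and coverage

Composition vectors hold, per factor, the fraction of clusters in a group
containing ≥1 peak of that factor; groups are compared by Pearson's r on
identically ordered vectors (constant vectors raise rather than silently
returning 0). The six groups compared by default are promoter clusters of
transcribed/silent genes and gene clusters split by H3K4me
(me1∪me2∪me3) overlap and by host expression.

Coverage curves add factors in uniformly shuffled orders; a target counts
as covered once a qualifying peak of an already-added factor overlaps it.
Qualifying peaks are members of clusters computed **once on the full
factor panel** — re-clustering per prefix would change cluster identity as
factors are added — or every peak when singletons are included (the
singleton-inclusive curve therefore dominates elementwise). The curve is
the mean (not median) over orders, 100 by default; an exhaustive
enumeration mode over all permutations exists for small panels and is used
by the tests as the closed-form reference.

## Synthetic genome

The generator is the package's test bed: it emulates the *structure* the
pipeline is meant to detect, not the scale or messiness of real ENCODE
data. Defaults (chosen once as a realistic small-genome setting):

| parameter | default | rationale |
| --- | --- | --- |
| genome | 2 × 10 Mb | large enough for 50-kb intergenic clearances |
| genes | 240, 5–20 kb, 15–35 kb gaps | gaps leave room for 10-kb upstream windows |
| expression | zero-inflated log-normal (35% zeros, µ=2, σ=1.2) | the analysis only needs a zero class plus a continuous tail |
| elements | 70 active / 50 silent promoters, 120 genic / 180 intergenic enhancers, 80 intergenic transcript units | every context and class populated |
| peaks per element | one Bernoulli draw per factor from class composition, floor of 2 | occupancy fractions directly estimate the composition probabilities |
| peak length / intensity | 150–400 bp; log-normal (median 25) | element peaks outrank the noise peaks (median 8) in intensity bins |
| noise | 5 peaks/Mb uniform over the mappable span | enough to create chance clusters without drowning elements |
| element spacing | ≥3,000 bp | wider than the 2,000-bp extension, so elements map to distinct clusters |

Mark emission is two-layered: *signature* marks that define the expected
transcript/enhancer label (H3K36me3 spanning the host gene body plus Pol II
for active promoters; H3K36me3 with Pol II/Pol III for intergenic
transcript units) are emitted with probability 1, so a zero-dropout run is
exactly recoverable; *decoration* marks (H3K4me1/2/3, acetylation, OCR,
H3K27me3) are emitted per class with the probabilities above 0 and below 1
(enhancer classes emit H3K4me1 at 0.9 and H3K27ac at 0.4). An optional
dropout probability deletes any emission independently. Silent promoters
emit no transcription signature — their planted chromatin class is
"enhancer" — which models the clean separation the classifier assumes;
stalled-polymerase signals at silent promoters, which real data show, are
deliberately absent so that label recovery is well defined.

Enhancer-class elements are sited clear of every transcription-mark
footprint (genic enhancers only at genes that host no active promoter;
intergenic elements ≥50 kb from genes), and inter-element spacing exceeds
the peak extension, so at zero noise and zero dropout cluster construction,
gene-context assignment and classification all recover the manifest
exactly. With noise and dropout, recovery degrades smoothly and is
measured, not assumed.

What the generator does **not** model: summit offsets and read-level
noise, overlapping or nested genes beyond what nonredundant selection
needs, distance-dependent co-binding structure, bivalent domains,
cell-type mixtures, and empirical peak-count scales. Passing tests
demonstrate correctness of the procedures under the planted model, not
performance on real chromatin.

## Numerical and reporting choices

Pearson's r is computed with `numpy.corrcoef`. Cumulative (≥ s) counts are
used for real:shuffled ratio comparisons, with an empty shuffled class
treated as a count of 1 in ratio denominators (shuffled clusters above
size 5 are often absent at synthetic scale). All randomness — generation,
shuffling, coverage orders — flows from explicit integer seeds through
`numpy.random.default_rng`; the pipeline derives its coverage seed as
`seed + 1` so the shuffle and the coverage resampling are decoupled.
Pipeline outputs are plain tab-separated tables written deterministically;
re-running with the same inputs and seed reproduces every file byte for
byte. Problem sizes throughout (500 elements, 2,100 peaks, 100 coverage
orders, 300-element composition-recovery runs on a 4 × 20 Mb genome) keep
a full run and the entire test suite within seconds on one CPU.
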