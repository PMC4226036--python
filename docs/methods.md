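# Methods

This note records the models, algorithms, parameter choices and numerical
conventions behind `plastrep`, and what the synthetic-data tests do and do not
demonstrate about real genomes.

## Coordinates and records

All internal coordinates are 0-based half-open. GFF3 output is 1-based
inclusive and BED 0-based half-open, matching each format's standard. Circular
genomes are first-class: a 400 bp wraparound window (more than twice the
maximal small-repeat footprint) is appended virtually when scanning, hits
starting past the origin are remapped modulo the length and deduplicated, and
annotation features that straddle the origin are split into two parts sharing
a locus tag. Sequences are normalised to uppercase ACGTN on ingest;
ambiguity codes become N, and N never matches anything in any scorer.

Taxon-group labels (CASH = cryptophytes, alveolates, stramenopiles,
haptophytes; rhodophyte; green = chlorophytes, streptophytes and
chlorophyte-derived euglenids) are metadata supplied by the caller — per
genome or via a TSV membership table — because grouping is phylogenetic
information not derivable from the sequence.

## Small inverted repeats

An inverted repeat is a local alignment between the sequence and its own
reverse complement, i.e. a set of paired positions (i, q), i < q, read
inward. Three constraints define the search space: the footprint
(arm1 start → arm2 end) is below `max_extent` (default 200 bp), the innermost
pair leaves a loop of at most `max_loop` bases (default 30 bp, a standard
stem-loop plausibility cap applied at detection time), and stems must begin
and end on paired columns — a terminal mismatch is physically loop, and a
candidate whose best alignment under the loop cap would close on a mismatch
is rejected.

Because position i can only pair with positions within `max_extent`, the
alignment matrix collapses to a band of fewer than 200 anti-diagonals. The
dynamic programme is therefore exact (not seed-and-extend) and runs in
O(max_extent × n) time and memory, vectorised over pairing offsets with
numpy; a 105 kb plastid genome scans in well under a second. Scoring defaults
mirror einverted (match +3, mismatch −4, gap −12, minimum score 50); the
tool's parameterisation in comparative studies is rarely reported, so the
defaults are exposed in `IRParams` and a `--sweep` mode reports counts across
thresholds.

Redundancy resolution: hits sharing ≥ 50% of the smaller footprint keep only
the highest score, ties broken by smaller start, then shorter footprint. A
brute-force oracle that enumerates every gapless arm placement reproduces the
detector's output exactly on random sequences (the equivalence test runs both
sides with a prohibitive gap penalty, since enumerating gapped placements is
combinatorial; gapped behaviour is exercised by planted-truth tests and by
recomputing every reported hit's score with an independent global aligner).

## Tandem repeats

Arrays are located per candidate period p (1…200) from runs of agreement
between the sequence and itself shifted by p, using a deliberately light
mismatch penalty at this stage so that per-copy substitutions do not sever a
run. Each candidate region is then rescored against its own column-majority
consensus with Tandem Repeats Finder weights (match +2, mismatch −7, minimum
score 50) and trimmed to the maximal-scoring segment (Kadane decomposition);
ties in the consensus majority resolve to the alphabetically first base.

Redundancy is resolved in two stages. Descriptions of the same locus (mutual
overlap ≥ 70% of the larger footprint) collapse to the minimal period: a
doubled period absorbs per-copy substitutions into its consensus and would
otherwise outscore the true repeat unit. Partial overlaps (≥ 50% of the
smaller footprint) then keep the higher score. Copies are reported as region
length / period.

Limitations: the detector models substitutions between copies but not
insertions/deletions within copies (the `indel` weight in `TRParams` is
accepted for interface compatibility but unused); arrays whose copies have
diverged by indels will be reported fragmented or missed. A perfect array
shorter than 25 bp scores below the default threshold — the same behaviour as
the reference tool's defaults — and needs a lower `min_score`.

## Large ribosomal inverted repeat

The IR is located by genome self-comparison without an external aligner:
exact 21-mer matches between the forward strand and its reverse complement
are chained along anti-diagonals (drift ≤ 100 bp absorbs indels; unseeded
gaps ≤ 500 bp absorb locally divergent stretches such as spacers whose tRNA
content differs between copies), the longest chain spanning a 16S + 23S
operon is kept, and boundaries are pushed outward base by base until identity
over a trailing 50 bp window falls below 90%, then trimmed back to the
outermost matching pair. An IR is reported only when the match is ≥ 1 kb,
disjoint, and contains the rRNA operon; a genome with a single operon (or no
rRNA annotation) reports "No Inverted Repeat". The 90%/1 kb thresholds sit
safely below the near-identity of real plastid IRs (which are homogenised by
copy correction) while excluding chance self-matches. On circular genomes the
scan runs on the doubled sequence, so the result is invariant under rotation.

Copy divergence is counted from a global alignment of each duplicated rRNA
gene (copy B reverse-complemented into copy A's orientation): match +1,
mismatch −1, gap open −5, gap extend −2; SNPs are substitution columns and a
g-base gap contributes g indel counts, keeping the two classes separate. With
these scores a substitution is always preferred over an adjacent
insertion–deletion pair, so counts are stable between co-optimal alignments
at realistic divergence. Gene copies come from the annotation when both
copies are annotated; otherwise copy A's genes are projected onto copy B
through the IR alignment.

ISR classification lists the tRNAs between the 16S and 23S genes in each
copy; the arrangement is canonical if and only if both copies contain both
tRNA-Ile and tRNA-Ala. Asymmetric arrangements (one tRNA per copy, or both
tRNAs confined to one copy) are non-canonical.

## Gene–repeat association

A repeat and a gene are associated when the distance between their nearest
boundaries is ≤ 300 bp (default, configurable) from either gene end, measured
on the circle, with no annotated CDS/tRNA/rRNA feature lying strictly in the
gap; repeats overlapping the gene body count at distance 0. The reported
flank (5′/3′) respects gene strand. Conservation across a panel is the
fraction of gene-carrying genomes with at least one association; genomes not
carrying the gene are excluded from the denominator, and a gene absent from
the whole panel is flagged rather than given a fraction. Association counts
are non-decreasing in the search distance, and invariant under genome
rotation and whole-genome strand flip.

## Lineage statistics

Mean intergenic distance is the mean gap between consecutive feature
boundaries around the circle, overlaps clamped to zero; it needs at least two
features.

The tandem-versus-inverted contrast classifies each genome as
tandem-majority when tandem repeats strictly outnumber inverted repeats
(ties are not tandem-majority) and tests the resulting 2×2 group table with
two-sided Fisher's exact test — the total hypergeometric probability of all
tables with the observed margins no more probable than the observed one
(scipy's implementation; an independent enumeration over all tables with
fixed margins is kept as a test oracle).

Regressions of repeat number or mean repeat size on genome size or mean
intergenic distance are ordinary least squares within one taxon group, p from
the two-sided t-test on the slope; at least 3 genomes and a non-constant
predictor are required, and genomes with undefined values (no repeats, < 2
features) are dropped. The group-wise maximum repeat size (the CASH ~65 bp
size cap seen in comparative surveys) is reported descriptively, not tested.

Simulation calibration (see `synthetic.GroupParams`): the default group
distributions mirror the comparative survey's descriptive numbers — CASH-like
plastids draw ~17 inverted and ~8 tandem repeats (Poisson means, ~25 total,
inverted-majority, sizes capped at 65 bp), green-lineage plastids ~30
inverted and ~50 tandem (~80 total, tandem-majority), rhodophytes few of
either. At 15 genomes per group the Fisher contrast rejects in ≥ 90% of
panels; with identical balanced parameters in both groups the type-I rate
stays ≤ 7% at the nominal 5% level (Fisher is conservative at these counts).

## Signed reversal distance

Gene orders are taken from annotations: names are case-normalised through a
synonym table, genes duplicated within either genome are dropped from both,
and circular orders are linearised at the lexicographically smallest shared
gene, oriented so the anchor is positive (making the result
rotation-invariant). Unsigned input is rejected rather than heuristically
signed.

The distance is the Hannenhalli–Pevzner formula d = n + 1 − c + h + f on the
breakpoint graph of the doubled representation (+x → 2x−1,2x; −x → 2x,2x−1;
framed by 0 and 2n+1). c counts alternating cycles. Non-trivial cycles are
grouped into components by gray-edge interleaving; a component is oriented if
any gray edge joins same-parity positions. Hurdles are unoriented components
one of whose two circle arcs contains no other unoriented component; a
fortress (f = 1) requires an odd number of hurdles, all of them superhurdles
(hurdles whose deletion turns their protecting component into a new hurdle).

Correctness is established empirically against an exhaustive breadth-first
search over the reversal graph: every signed permutation with n ≤ 6, every
all-positive permutation at n = 7 (the hurdle-rich stratum, including 147
nested-unoriented configurations), and 1000 sampled signed n = 7. The
fortress branch cannot be reached at BFS-tractable sizes; it is validated on
a constructed three-superhurdle permutation by a descent-consistency check
(greedy descent reaches the identity with every reversal lowering the
computed distance by exactly 1, which an over- or under-count by one would
break). Published rearrangement totals for real genome trios depend on how
syntenic blocks were built from whole-genome alignment and are treated as
qualitative context, not reproduction targets.

## Composite repeat regions

A region is tiled greedily left to right against a unit library: at each
position the best-matching unit class at ≥ 80% identity is assigned
(longest unit preferred on ties), otherwise the position joins a spacer. The
80% class threshold separates full-unit identity from the partial
sub-homologies that unit classes in real mitochondrial repeat regions share
with each other. In auto mode the library is derived from the region's own
tandem structure (consensus of each detected array, merged at ≥ 80%
identity), labelled A, B, C… by decreasing unit length. The tiling covers the
region exactly (units plus spacers), and the genome fraction is
100·region/genome.

## Synthetic data

The generator assembles a genome left to right: gene features (annotation
only; their sequence is background), planted inverted repeats, planted tandem
arrays, and optionally a duplicated rRNA operon, separated by ≥ 50 bp gaps
drawn from an exponential with the configured mean intergenic spacing.
Background is i.i.d. per base at the target GC — no higher-order composition
model, since none of the analyses under test depends on one. Packing failures
raise before any output. One RNG stream per genome, seeded from the spec;
identical specs give byte-identical genomes.

Two deliberate artificialities make planted truth exactly recoverable:

- **Complement-free guard tracts.** Each planted element is flanked (and each
  stem-loop's loop filled) with 12 bases drawn from {A, C} only. Two
  positions inside such tracts can never be reverse-complement partners, so
  no inverted alignment can extend through them and detected coordinates
  provably equal planted coordinates. Tandem arrays get four phase-mismatched
  guard bases per side for the same reason. Real genomes have no such guards:
  on real data, hit boundaries can extend a few bases past the "true" repeat
  wherever flanking sequence happens to pair, which is correct detector
  behaviour, not an error.
- **Rejection sampling of planted sequence.** Tandem units are redrawn if the
  resulting array is itself a scoring inverted repeat (AT-rich periodic units
  are frequently self-reverse-complementary), and stem arms are redrawn if the
  stem-loop footprint carries tandem structure. Planted counts therefore
  match detected counts class by class — again a property of the test design,
  not of real genomes, where the two repeat classes genuinely overlap.

Planted arm mismatches are placed ≥ 2 bp from arm ends and array mutations
≥ 4 bp from array ends so that optimal trimming cannot move a boundary; rRNA
copy substitutions and single-base deletions are placed ≥ 30 bp from gene
boundaries and ≥ 10 bp apart so the divergence alignment cannot merge them.
The operon component lengths (16S 1491 bp, ISR ~300 bp with 73 bp tRNA slots,
23S 2616 bp, 5S 119 bp) are realistic plastid magnitudes; margins absorb the
configured total IR length. Spacer layouts: canonical (Ile+Ala both copies),
ctobin (Ala in copy A, Ile in copy B), phaeocystis (both in A, none in B),
none, and single-copy (no IR at all).

Consequently, a passing suite shows the algorithms are exact on their stated
optimisation problems and recover planted structure perfectly under the
study conditions; it does not show that einverted/TRF parameter defaults are
optimal for any particular real genome, nor that real repeat boundaries are
sharp. Panel-scale published fractions (e.g. a gene-association fraction over
a curated 44-genome panel) depend on panel composition and are exercised as
properties on synthetic panels instead.

## Problem sizes used by the test suite

Synthetic genomes of 5–60 kb (chloroplast census at 60 kb, divergence checks
at 26 kb); 100 divergence draws with up to 20 planted differences; reversal
distances checked exhaustively to n = 6 plus 1000 sampled n = 7; 500-panel
power and type-I simulations at 15 genomes per group via profile sampling;
oracle equivalence on 20 random 300 bp sequences. The full suite runs in
about a minute on one CPU; `scripts/acceptance.py` in ~10 s.
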