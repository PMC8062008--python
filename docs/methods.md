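# Methods

`mosaicscan` detects individual recombination events in nucleotide sequence
alignments, vets each signal against non-recombinational explanations, tests
breakpoint placement against genome annotation, and emits recombination-free
datasets.  This note records the model, the numerical choices, and what the
bundled simulator does and does not emulate.

## The triplet scan

For every triplet of sequences (a, b, c) the scan collects the
*triplet-informative* sites: alignment columns where all three residues are
unambiguous nucleotides and the states split exactly 2-vs-1.  Each informative
site supports one of three agreement patterns — ab, ac or bc — and under
clonal evolution the mixture of patterns is homogeneous along the genome.  A
recombination event interrupts that homogeneity: inside the transferred
region the recombinant agrees with its minor parent, so one pattern becomes
locally enriched.

A window of `window` consecutive informative sites (default 30) slides along
the profile in steps of `step` (default 1).  Windows are counted in
informative sites rather than alignment columns so the test statistic keeps a
constant sample size whatever the divergence of the triplet.  For each
pattern q, the count m of q-sites in the window is referred to a binomial
tail

    p_raw = P(X >= m),  X ~ Binomial(window, p̂)

where p̂ is the genome-wide proportion of pattern q among the triplet's
informative sites *excluding the current window* (leave-window-out, so the
window cannot inflate its own null).  When the out-of-window count is 0 or
saturated, p̂ is clamped half a count away from the boundary
(0.5/n_out), a standard continuity safeguard.  All three patterns are
candidates: the transferred pattern can itself be the genome-wide plurality
when the triplet holds no close relative of the recombinant, so no pattern is
exempted a priori.

A window is retained when `p_raw x F < alpha` with the Bonferroni factor
F = C(n,3) x (number of window placements in the triplet) in the default
`triplets_x_windows` mode (`triplets_only` is available for power studies).
Exact tails are evaluated only where a normal-approximation z-score exceeds
2.5; windows below that bound cannot come near the corrected threshold for
any realistic factor, so this is purely a computational shortcut.

### Region refinement and the second pass

Overlapping significant windows are merged into runs.  A raw run spans whole
windows and therefore drags in up to a window's worth of background sites on
each flank; the run is sharpened to the maximum-scoring contiguous segment
(Kadane's algorithm) under per-site log-odds scores log(p1/p0) for q-sites
and log((1-p1)/(1-p0)) otherwise, with p1 the in-run and p0 the
leave-run-out q-fraction.  The refined run is then trimmed to its first and
last q-supporting sites.

A strong region distorts the genome-wide pattern proportions — its own
pattern is inflated and the others deflated — which can make ordinary
stretches elsewhere in the triplet look enriched.  Every candidate is
therefore re-tested in a second pass against a background computed only from
sites outside *all* first-pass regions; only survivors are reported, with the
second-pass p-value.

### Breakpoints, naming, consolidation

Breakpoints are placed at the floor midpoint between the region's outermost
q-supporting site and the nearest flanking site supporting the background
pattern (the plurality pattern among sites outside the region); without a
flanking background site the alignment terminus is used.  Coordinates are
0-based half-open internally and 1-based inclusive in every report.

Within a triplet, the recombinant is the member common to the inside-region
and outside-region agreeing pairs, the minor parent its in-region partner,
the major parent its out-of-region partner.  A triplet alone, however,
cannot tell acceptor from donor (they are near-identical inside the region),
and a triplet made of the recombinant, one parent and a relative of that
parent names the relative.  Two mechanisms resolve this:

1. **Consolidation.** Events naming the same recombinant whose intervals
   overlap by >= 50% of the smaller interval are grouped (union-find) and
   represented by the minimum-p member.  Overlapping exemplars that disagree
   on the recombinant's name are then collapsed to the single minimum-p
   exemplar — one physical event, one report.
2. **Donor/acceptor resolution.** For the surviving event, the recombinant
   and minor parent swap roles if the minor parent's identity profile
   against the rest of the alignment shifts more across the region boundary.
   The acceptor temporarily joins the donor's neighbourhood inside the
   region, so its profile moves; the donor's barely does.  After a swap the
   major parent is re-anchored to the new recombinant's closest outside
   partner.

Ties everywhere break deterministically (smaller coordinate, then
lexicographic name), so identical input and configuration give byte-identical
event tables, and permuting the input row order changes only name bindings.

## False-positive vetting

Three independent checks flag events that may not reflect recombination.
Flagged events are excluded from dataset surgery by default.

**Pair incompatibility score.**  For two alignment columns with Vi and Vj
observed states, E distinct joint states and Cc connected components of the
bipartite state graph, the score E - (Vi + Vj) + Cc equals the minimum
number of extra mutations any unrooted tree must spend to accommodate both
columns.  The test suite enforces this against exhaustive Fitch parsimony
over all topologies on up to six taxa rather than assuming it.

**PHI.**  The pairwise homoplasy index is the mean incompatibility over
parsimony-informative site pairs at most `w` columns apart (default 100).
The permutation null (default 1000 permutations) shuffles column contents
among the informative positions while keeping positions fixed; p = (1 + #{PHI*
<= PHI_obs}) / (n_perm + 1).  Under recombination nearby pairs are more
compatible than distant ones, pushing the observed PHI below its null.  An
event is `phi_suspect` when PHI applied to the event neighbourhood — the
triplet plus its 5 nearest neighbours by identity, over the region padded by
one region-length on each side — fails to support recombination
(p_perm > 0.05).

**Four-gamete support.**  The Hudson–Kaplan machinery collects biallelic
column pairs exhibiting all four gametes; `hudson_kaplan_rm` prunes
intervals containing another interval and greedily counts disjoint
intervals, giving the classic lower bound Rm on the number of recombination
events.  For vetting, an event is `four_gamete_suspect` when no incompatible
pair in the neighbourhood sub-alignment straddles either detected
breakpoint — a genuine template switch must leave such a pair.

**Misalignment.**  `misalignment_suspect` marks events whose region is
gap-dense across the triplet (> 30% gaps) or overlaps a run of >= 15
consecutive columns each at least half gapped.  This is a deliberate
heuristic: alignment error is a major source of spurious signals, and gap
structure is its most accessible footprint.

## Breakpoint-distribution tests

Detected breakpoints (both ends of each unflagged event, terminus-truncated
ends excluded) are tested against three annotation-derived column
partitions: coding vs non-coding, per-gene (overlaps resolved to the nearest
gene start), and gene edges vs interiors (edge = first and last
ceil(0.1 x gene length) columns by default).  The null places each
breakpoint independently and uniformly over all columns; per-label two-tailed
p-values use distance from the null mean over 10 000 permutations, with
Benjamini–Hochberg adjustment across labels.  A uniform null is declared
rather than a "detectable-positions" null because the latter would require
an arbitrary detectability model; users comparing annotation schemes should
remember that breakpoint *detection* is itself easier in divergent regions.

## Dataset surgery

Four recombination-free outputs: strip (remove recombinant sequences), mask
(replace transferred fragments with `N` in the recombinant row only), split
(replace each recombinant by a backbone row plus one row per event; every
original column lives in exactly one derived row, so concatenating their
non-missing content reconstructs the original), and partition (cut the
alignment at breakpoint columns; concatenating the partitions is the exact
identity).  `N` is the default missing character rather than `-` so that
downstream phylogenetics treats removed fragments as unknown, not as
deletions.  Gene extraction splices CDS intervals in transcription order,
reverse-complements minus-strand genes, honours the initial phase, and (by
default) removes trailing partial codons and any codon containing a
frame-shifting gap — column-synchronously, so outputs stay aligned and their
lengths are multiples of three.

## The simulator

`simulate_clonal` grows a random ultrametric Yule tree (exponential waiting
times, branch lengths rescaled so every root-to-tip path equals
`mean_divergence` substitutions/site) and evolves sequences under
Jukes–Cantor with independent per-site substitution; multiple hits are
allowed, and discrete-gamma rate heterogeneity (4 categories) is available to
reproduce the inter-site rate-variation confounder that motivates the
vetting tests.  `implant_events` then copies donor columns into acceptors
(pairs at least `min_parent_divergence` apart in p-distance, non-overlapping
intervals per acceptor), so ground truth is exact by construction.

What this emulates: clonal background, clean mosaic transfer, rate
heterogeneity on demand.  What it does not: indels and alignment error (the
misalignment heuristic is therefore exercised only with synthetic gap
blocks), selection, rate variation across lineages, ancestral (shared)
recombination events, or circular genomes.  Passing tests demonstrate
calibration and recovery under these idealized conditions, not performance
on real, gappy, selectively constrained data.

## Trees

Per-partition trees are neighbour joining on Jukes–Cantor distances
(pairwise deletion; p >= 0.75 mapped to a saturation cap of 5
substitutions/site).  NJ uses the Saitou–Nei Q criterion with ties broken by
the smallest index pair, negative branch lengths clamped to zero with the
deficit moved to the sister branch, and 6-decimal branch formatting.  NJ
replaces likelihood tree inference deliberately: it is exact on additive
matrices (verified by Robinson–Foulds 0 recovery of random additive trees),
deterministic, and dependency-light; users wanting ML trees can pass the
partition alignments to an external program.

## Problem sizes and verification

The statistical checks run at these sizes, chosen to give stable Monte-Carlo
estimates while keeping the whole suite fast: pair-score oracle, 200 random
instances on <= 6 taxa; Rm oracle, 500 instances on <= 8 taxa x <= 12 sites;
PHI type-I, 200 clonal replicates of 20 taxa x 2 kb at 5% divergence with
1000 permutations (rejection rate must fall in the central 95% binomial band
[0.02, 0.09]); scan family-wise error, 200 clonal replicates of 10 taxa x
5 kb; breakpoint recovery, 100 mosaics of 10 taxa x 10 kb with one 1.5 kb
event between >= 10%-divergent parents (>= 90 detected, median breakpoint
error <= 25 columns) plus a 50-seed matched comparison across 2/5/10% parent
divergence; NJ recovery, 100 random 5–10 taxon additive matrices; the
mask-and-rescan negative control, 100 runs of 10 taxa x 4 kb.
`scripts/acceptance.py` recomputes the same quantities from scratch at
moderately reduced replicate counts (stated in its JSON output) so a full
reproduction stays under a few minutes on one CPU.

## Known limitations

Only the triplet method is implemented as the scan engine; the consolidation
step can merge two genuinely distinct events by different recombinants that
occupy near-identical coordinates; overlapping same-recombinant events share
columns in split mode via first-come assignment; GenBank parsing is limited
to `join`/`complement` location grammar; and the scan assumes a linear
genome (no breakpoint wrap-around).
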