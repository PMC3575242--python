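# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the order the pipeline runs them, together with what the
synthetic-data validation does and does not establish about real data.

## Alignment handling and coordinates

All statistics operate on a rectangular alignment from which every column
containing a gap or any IUPAC ambiguity code has been removed (complete
deletion). Ambiguous and indel columns generate spurious recombination
signal, so they are excluded *before* any detection; removal is per column
and conservative (one ambiguous base removes the whole column). Every
alignment carries a `column_map` giving, for each surviving column, its
1-based coordinate in the source alignment, so breakpoints, partitions and
fragment spans are always reported in source coordinates no matter how many
columns were stripped. Coordinates are 1-based and inclusive throughout.

Amino-acid polymorphism is tabulated on aligned codons (codons containing a
gap are skipped, so per-position counts may sum to fewer than n), and a
sequence is flagged frameshifted when its ungapped coding length differs
from the modal ungapped length by a non-multiple of 3 — a pragmatic rule:
real frameshifts are insertions/deletions relative to the population
consensus, and the modal length is the only consensus available without an
annotated reference. Internal stop codons are reported, not rejected;
pseudogenized element copies are expected in rDNA.

## The synthetic-data generator

The generator emulates the structure of a cloned-allele dataset: a handful
of divergent parental lineages, a few near-identical alleles within each
lineage, mosaic recombinants spliced from them, clone sampling within
isolates, and (optionally) PCR chimera artifacts.

**Substitution model.** Sites are independent. A site is invariant with
probability `p_inv` (default 0.633); otherwise its relative rate is drawn
from a 4-category discretized gamma with shape `alpha` (default 0.8423).
Rates are normalized to mean 1 so branch lengths are expected substitutions
per site. Along a branch of length t, a site of rate r receives
Poisson(t·r) substitution events; each event replaces the base using a
Kimura-style kernel with transition/transversion bias `kappa` (default 2).
Optional per-region rate multipliers impose the element's architecture
(a conserved first exon, a fast second exon).

**Calibration.** Parental lineages radiate from a random root on a star
topology. The branch length is solved numerically (Brent's method) so that
the *expected* pairwise p-distance between lineages — computed with the
Jukes–Cantor saturation correction averaged over the site-rate
distribution — equals the target divergence `d` (default 0.06). The same
inversion sets the within-lineage branch so allele pairs of one lineage
differ by `within_group_theta` (default 0.008, i.e. ≈99.2% within-group
identity; within-lineage diversity is not directly observable in the study
data, so this is a realism choice, fixed once). A target beyond the
saturation ceiling 0.75·(1 − p_inv) raises a configuration error. Realized
inter-parent distances land within a few percent of `d`; pooled diversity of
the default five-lineage dataset is π ≈ 0.05.

**Mosaics and truth.** Recombinants are exact splices of donor alleles at
stated breakpoints (post-splice mutation optional, default off, so the
truth is clean). Every simulated sequence carries an ordered donor-segment
record that tiles [1, L]; splicing from a donor that is itself recombinant
inherits and clips the donor's segments, so nested events resolve to
ultimate donors. PCR chimeras are single-crossover splices of two random
templates at a uniform position, flagged in the truth. Isolate sampling
draws 1–5 distinct alleles per isolate (optionally with the strong skew
toward one or two alleles that real screens show) and 10–12 clones with
replacement, reproducing cloning-depth under-sampling.

**What it does not emulate.** No coalescent ancestry within lineages (a
star tree, not genealogies), no indels by default, no rate correlation
along the sequence beyond the region multipliers, no selection, no
sequencing error. Passing the validation therefore shows the detectors
work when their assumptions hold at study-like divergence and rate
heterogeneity; it does not certify behavior under alignment error or
saturation, which real data can add.

## Diversity statistics

π is the mean pairwise proportion of differing sites, θ_W = S/(a_{n−1}L),
and mean similarity 100·(1 − mean p-distance), all on the stripped columns
(per-pair deletion is available as an option because legacy software totals
computed on full-length sequences may have used it; the two conventions
differ slightly in the presence of indels). Display rounding is 3 decimals
for π/θ and 1 for similarity; full precision is kept internally. Both
statistics equal brute-force pairwise-counting oracles to machine precision,
and on neutral coalescent simulations (msprime) their expectations agree.

The population recombination rate is the arithmetic combination
R = θ_LAM · r_LAM = (4N_e μ)(c/μ) = 4N_e c of externally supplied coalescent
estimates; the MCMC co-estimation that produces θ_LAM and r_LAM is outside
this package's scope, so they are inputs.

## Phi test

Parsimony-informative sites (≥2 states each carried by ≥2 sequences) are
recoded to their two most frequent states (ties broken by base order;
other rows treated as missing for that site). The statistic is the mean
four-gamete incompatibility over informative-site pairs within `window_w`
bp (default 100) of each other in source coordinates. Recombination makes
nearby sites *more* compatible than a random arrangement, so significance
is the one-sided permutation probability p = (1 + #{perm ≤ obs})/(1 + n_perm)
under random reassignment of site columns to positions. With fewer than two
informative sites (or no nearby pair) the result is returned as
not-testable rather than raising. On low-homoplasy clonal data the
statistic is often exactly zero for most permutations, so the test is
conservative there (observed null rejection ≈ 3% at α = 0.05, power ≈ 100%
at p < 0.01 on the default mosaic scenario).

## Stepwise maximum chi-square

**Statistic.** The alignment is condensed to its segregating columns — the
original method's convention, and the only one under which the 2×2 table is
well-behaved when divergence varies along the sequence. For each unordered
sequence pair, each candidate cut between condensed sites is scored by the
chi-square (no continuity correction) of the table
[[h − mmL, mmL], [h − mmR, mmR]], where mmL/mmR count the pair's mismatches
among the h segregating sites on each side. Window half-widths default to
{70, 80, 90, 100} condensed sites. A perfectly split window (h matches vs
h mismatches) gives χ² = 2h, the table total. Ties in the maximum break to
the leftmost cut; the maximization is restricted to cuts with at least one
pair-mismatch site on both sides so that a flanking interval exists. The
statistic depends only on the pattern of matches and mismatches, so it is
invariant to any relabeling of the nucleotides.

**Significance.** The null re-places the pair's mismatch sites uniformly at
random among the condensed columns (equivalently: permutes columns),
re-maximizing χ² each time. Because that law depends only on the segment
structure, the per-segment mismatch counts and h — not on which pair is
tested — null samples are cached and shared across pairs, with one
deterministic sub-seed per law. One placement stream serves all
half-widths. p-values are two-stage: a 1,000-replicate screen settles
clearly non-significant statistics (p̂ > 0.02); anything near the threshold
is referred to the full replicate count (default 10,000; the analysis-grade
setting is 100,000). Per-pair p-values are Bonferroni-corrected by the
number of pairs scanned in the step, and the scan demands
p_adj ≤ α (default 0.05).

**Stepwise protocol.** Accepted breakpoints delimit the segments within
which columns are permuted in later steps (conditioning sharpens the null,
exposing secondary breakpoints); a pair's own accepted cuts exclude their
±h neighbourhood from its later maximizations so the same junction is not
re-called. Within one step a junction may be called at every half-width.
The scan stops when a step accepts nothing new (cap: 5 steps).

**Reporting and merging.** A call's interval spans the two pair-polymorphic
sites flanking the maximizing cut, in source coordinates — the narrowest
region the pair's data can localize the exchange to. Note the maximizing
cut can sit one or two mismatch sites off the true junction when an
isolated within-lineage mismatch lies nearby (the χ² surface is nearly flat
there); at study conditions the planted breakpoint still falls inside the
reported interval of some significant call in ≥ 93% of runs per half-width,
with false-call runs near the nominal 5%. Calls are merged into events by
exact interval identity (overlapping-but-distinct intervals remain separate
events, matching how such analyses keep adjacent events apart); a Jaccard
rule is available. Events are labelled with roman numerals ordered by left
coordinate; merging is idempotent and order-independent.

## Lower bounds on recombination events

**Hudson–Kaplan R_m.** Over biallelic segregating sites, all pairs showing
four gametes define open intervals; intervals containing another are
removed, and a maximum set of pairwise-disjoint intervals (endpoint sharing
allowed — the events live strictly between the sites) is selected greedily
by right endpoint, which is optimal for interval scheduling. The result
equals a weighted-interval-scheduling oracle on hundreds of random
instances.

**Haplotype bound R_h.** For every contiguous interval of segregating
sites, the local bound is b = max(0, H − S − 1) with H the number of
distinct haplotypes and S the number of sites (computed by incremental
partition refinement, O(K²·n)). The four-gamete pair bound is folded in —
an interval whose endpoint sites are incompatible gets b ≥ 1 even when
compatible intervening sites inflate S — and local bounds are combined by
dynamic programming over chains of intervals that may share endpoint
sites. Both strengthenings are needed for the combined bound to provably
dominate R_m on arbitrary data; without them, random high-homoplasy
alignments produce counterexamples. R_h here is the classical haplotype
bound, *not* an ancestral-recombination-graph history count, which is a
different (much larger) quantity; no numerical agreement with such counts
is expected.

## Simplified multi-fragment scan

A stand-in for full phylogenetic breakpoint search: candidate cuts are
midpoints between informative sites (evenly subsampled to ≤ 40), and all
0-, 1- and 2-breakpoint segmentations are scored by the sum over segments
of the length-weighted least-squares misfit between the segment's
p-distance matrix and the path distances implied by its neighbor-joining
tree, plus a penalty per breakpoint. Splitting already pays an implicit
cost — shorter segments estimate noisier distances — so the explicit
penalty only absorbs the selection bias of optimizing over candidate cuts;
the default 0.1·(2n − 3)·p̄(1 − p̄) (p̄ the mean pairwise p-distance) sits
several times above the largest spurious improvement observed on
recombination-free data of the study's shape, and recombination-free runs
return the empty set in ≈100% of trials. Because the least-squares optimum
is diffuse (±50 bp), accepted cuts are re-localized by a parsimony
change-point: NJ topologies are built for the two flanking segments, each
column in a ±120 bp window is scored by Fitch parsimony on both, and the
cut is placed where the prefix sum of score differences is minimized —
taking the *centre* of a tied plateau, since the cut is unidentifiable
within a stretch of topology-indifferent columns and the centre minimizes
worst-case error. Planted double breakpoints (swapped middle segment,
d = 0.08) are recovered within ±30 bp in ≈85% of runs. The scan is
deterministic.

## Distances, trees and donor assignment

Pairwise distances: p (default — the dendrograms are descriptive, and at
≤6% divergence model corrections are nearly linear), JC69
(−(3/4)ln(1 − 4p/3)) and K2P; saturated pairs keep their p-distance and are
flagged rather than failing the whole matrix. Neighbor joining is
scikit-bio's Saitou–Nei implementation behind this package's interface,
made deterministic by sorting labels first; negative branch lengths are
clamped to zero. On additive matrices the generating topology and branch
lengths are recovered exactly (property-checked against path-sum oracles).
Fragments between breakpoints get one tree each; fragments with fewer than
3 variable sites are skipped with a warning.

Donor assignment: for each fragment, the donor of a recombinant is the
group minimizing the mean distance to it (the recombinant's own label and
unassigned sequences are excluded); the margin is the runner-up's mean
minus the best. Groups within 10% (relative) of the best distance are
reported as alternatives ("h or i") — ambiguity of exactly the kind seen
when two candidate donor groups are themselves closely related. On default
scenarios the planted donor pair is recovered for ≈100% of mosaics.

## In-silico PCR-RFLP

Primer matching is IUPAC-aware; by default no mismatches are tolerated,
and when mismatches are allowed the 3'-terminal 5 bases must still match
exactly (polymerase extension requires a matched 3' end). An amplicon runs
from the first base of a forward match to the last base of a
reverse-complement match of the reverse primer, all pairings within
300–5,000 bp. Enzymes are editable specs — DraI TTT^AAA, BspHI T^CATGA,
BstEII G^GTNACC ship as defaults (the canonical recognition sites of the
named enzymes); degenerate positions match any base, and non-palindromic
patterns are scanned on both strands. Cut positions agree with an
established restriction library on random sequences, and fragment lengths
always sum to the amplicon length. The three diagnostic windows default to
±25 bp around cuts at 380/790/1080 bp; bit k of the haplotype code is set
iff enzyme k cuts inside window k (first enzyme most significant), so codes
run 1 (no cuts) to 8 (all three). Gel banding collapses fragments within
40 bp (a 3% agarose resolution model — a modeling choice, not a measured
value); all eight conformations of the synthetic default amplicon are
pairwise distinguishable at that threshold. A chimeric splice of two
templates carries the left template's code bits left of the crossover and
the right template's bits right of it — the mechanism by which the screen
flags recombinant alleles. The synthetic amplicon itself is a labelled
stand-in (random background with sites planted at the nominal positions);
the real amplicon sequence is not distributed with the package.

## Pipeline and reproducibility

`run_pipeline` sequences strip → diversity → phi → max-χ² → R_m/R_h →
fragment scan → fragment trees → donor assignment → RFLP from one config.
A single global seed fans out to per-stage sub-seeds by stable hashing of
stage names, so any stage rerun in isolation reproduces its output; a
stage failure is recorded and its dependents skipped, and two runs with the
same config are byte-identical.

## Validation problem sizes

The validation experiments use: 500 random small alignments (n ≤ 8,
L ≤ 50) for the π/θ_W/R_m oracle checks and the R_h ≥ R_m ordering; 100
seeded runs (and 10,000 permutation replicates) each for breakpoint
recovery and false-call calibration, on a seven-lineage scenario whose
~240 segregating sites let the largest half-window (100 sites per side)
reach a centrally planted breakpoint — mirroring the fact that half-windows
of 70–100 sites are only usable on datasets with a couple of hundred
segregating sites; 50 runs each for the fragment-scan calibrations; 30 for
the phi rates; ten 25-sequence scenarios (100 mosaics) for donor
assignment; and a 41-isolate panel for the RFLP screen. These sizes give
binomial standard errors of a few percent on the reported rates.

## Known limitations

- Breakpoint intervals from max-χ² are flanking-site gaps; with dense
  divergence they can be only a few bp wide, and the maximizing cut can
  sit just outside the true junction's gap (see above). Interval-identity
  merging therefore over-counts events relative to a human curator who
  would pool near-identical intervals; the Jaccard rule approximates that
  curation.
- The phi test is conservative on data with little homoplasy.
- The fragment scan handles at most two global breakpoints and assumes the
  recombinant group is a noticeable fraction of the alignment.
- The generator's star topology makes parental lineages equidistant;
  deeply unbalanced parental trees (supplyable in principle) would change
  detection power.
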