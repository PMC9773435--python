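# Methods

## Model

A biallelic marker in a strain of ploidy `p` carries `a` alternate copies,
`0 ≤ a ≤ p`. Sequencing reads sample the copies, so the observed allele
ratio AO/DP concentrates around the ratio-group center `a/p`. Centers are
rounded to two decimals (0.33, not 1/3) so the printed values and the
interval arithmetic agree exactly; distances to centers are compared on a
nine-decimal grid, making the ±θ interval boundary-inclusive and immune to
binary-float representation noise (0.29 is exactly on the 0.25 + θ
boundary, and classifies to 0.25 in a tetraploid).

θ = 0.04 is half the distance between the closest adjacent centers across
ploidies (0.25 vs 0.33 and 0.67 vs 0.75, the pairs where ratio groups of
triploids and tetraploids start to overlap); it is applied globally for
all ploidies and is user-configurable. A ratio within θ of no center — or
exactly equidistant from two — is ambiguous and excluded from the marker
track entirely, since such ratios are exactly the classification
confounders θ exists to remove. At 80× coverage the binomial standard
deviation of a heterozygous ratio is ≈ 0.05, so a substantial fraction of
genuine markers is ambiguous in any one strain; the region caller's
marker-count rule makes the downstream calls robust to this thinning.

Allowed center-to-center moves are enumerated by copy-number arithmetic
from each heterozygous state `(a, p)`: same-total moves to `(a′, p)`
(LOH to 0, LOH to p, or a heterozygous change), single-homolog losses to
`(a−1 | a, p−1)` and gains to `(a | a+1, p+1)`, the latter capped at total
ploidy 4. Cross-ploidy moves carry a coverage requirement (`requires_ndoc`
loss/gain). Haploids are special-cased to the marker flips 1→0 and 0→1.
Transitions start only from heterozygous states: a homozygous marker has
no outgoing move, which also means the parent/recombinant comparison is
deliberately asymmetric (an LOH region seen parent→recombinant has no
mirror image when the roles are swapped, because the homozygous side's
reference-allele markers never appear in its VCF).

## Pairing and imputation

Parent markers are filtered (DP ≥ 20, QUAL > 200, AO ≥ max(5,
⌈20 · mean_DP/80⌉) — the AO rule is stated at 80× and rescaled to the
sample's genome-wide mean depth). Each surviving marker is matched in the
recombinant strain by (chromosome, position, alternate allele); a
different alternate allele at the same position is a new mutation, not a
ratio change, and is treated as recombinant-absent.

The recombinant side is matched against its *raw* record set: a position
genuinely absent from the recombinant VCF, but covered by ≥ min_dp reads
in its depth table, is imputed as ratio 0 (LOH toward the reference) —
this is the only way LOH_0 can be observed at all. A position present but
failing the quality cutoffs is dropped instead of imputed; conflating the
two would convert every borderline-AO record into a spurious LOH call.
The AO cutoff is waived for recombinant ratios classifying to 0.

Ploidy-change candidates (a recombinant center only explicable by a
±1-ploidy transition, same-ploidy explanations winning ties by parsimony)
are corroborated at marker level when the windowed NDoC track is
available, using the matched transition's own coverage requirement: a
"gain" candidate needs the covering window's NDoC above the gate, a
"loss" candidate below it. Uncorroborated candidates are demoted to
ambiguous. This matters quantitatively: with ratio noise ≈ 0.05, about a
fifth of true-invariant triploid markers land inside 0.25 ± θ, and
without coverage corroboration these would seed false regions in every
event-free genome. Without a windows argument `pair_markers` defers all
arbitration to the region level.

## Region calling

The non-ambiguous calls form a per-chromosome track of variant (V) and
invariant (I) markers, in marker-index adjacency (the rule counts alleles,
never base-pair distances). A region grows greedily while consecutive V
markers are separated by at most `max_invariant_gap = 2` invariant ones
(each V–V gap independently), is trimmed so both ends are V, and is kept
with at least `min_variant = 4` V markers. Region coordinates are the
outermost V marker positions, 1-based inclusive; breakpoint uncertainty
extends to the flanking markers. An exhaustive oracle
(`oracle_call_regions`) re-derives the segmentation by enumerating all
valid variant-bounded sub-segments and keeping the containment-maximal
ones; the two agree on every binary track of length ≤ 16 (tested
exhaustively). A region's event type is the majority status of its V
markers, with a fixed priority order breaking ties deterministically.

## Normalized depth of coverage

NDoC is the plain per-base ratio of recombinant to parent depth, averaged
in windows tiling each chromosome from position 1 (default 1 kb,
non-overlapping — the per-window output file and dot-per-window plots
imply tumbling windows; a smaller step gives a true sliding window).
Positions absent from a coverage table count as depth 0; windows with zero
parent depth have undefined NDoC. No library-size rescaling or
GC/mappability correction is applied. Window *flags* use the conventional
strict cutoffs (loss < 0.5, gain > 1.5, boundary values unflagged).

Candidate *arbitration* — both the marker-level gate and the region-level
resolution — instead defaults to the ploidy-aware midpoints `(p−0.5)/p`
and `(p+0.5)/p`: a single-homolog gain moves the expected NDoC to
`(p+1)/p` (1.5 in a diploid but only 4/3 in a triploid), so the fixed 1.5
cutoff would sit exactly on the diploid expectation and entirely above the
triploid one. A candidate region with neutral coverage is demoted to a
heterozygous change; with no overlapping window it stays unresolved and is
plotted black with the other heterozygous events.

## Synthetic data

The generator emulates FreeBayes-style biallelic records and GATK-style
per-base coverage: markers are placed uniformly at 2 per kb (the order of
the heterozygous marker density of an S288C/SK1 hybrid), with
DP ~ Poisson(80 · t/p) and AO ~ Binomial(DP, a/t) for local copy state
`(a, t)`; 80× is the coverage at which the default AO cutoff is stated. A
beta-binomial overdispersion knob (off by default) widens the ratio spread
beyond counting noise. Recombinant markers whose alternate count drops to
0 are omitted from the recombinant VCF but stay covered in its depth
table. Two percent of sites are emitted with QUAL 50 in *both* strains,
modelling locus-driven quality loss; per-strain-independent decoys would
instead plant false imputed-LOH markers. Planted events are validated
against the transition table and may not overlap. The default genome is
three chromosomes of 200/150/100 kb.

The tetrad generator phases all markers onto one parental haplotype, so a
spore carries either a chromosome segment's alternate alleles or none;
reciprocal crossovers exchange spore tails (conserving 2:2 segregation)
and a configurable marker fraction is gene-converted in one spore (3:1 or
1:3).

What the simulations do **not** model: alignment and mapping-bias
artifacts, PCR duplicates, indel-realignment effects, GC-dependent
coverage waves, shared sampling between the VCF counts and the coverage
table at the same base, and linkage between marker noise at neighbouring
positions. Passing recovery tests therefore demonstrates the logic of the
classification and segmentation under the stated counting-noise model,
not robustness to every real-data artifact.

## Verification conditions

The recovery harness plants one event per simulation on a 60-kb triploid
chromosome at 2 markers/kb and 80× depth: interstitial events (LOH to 0,
LOH to 1, heterozygous change) span 15 kb (~30 markers), gains and losses
span the chromosome. Over 100 seeds per kind, sensitivity, breakpoint
exactness (every called region starts and ends on planted-event marker
positions) and event-kind agreement are all ≥ 95% in the shipped tests.
The null false-positive check runs 100 event-free triploid simulations of
the full 450-kb default genome and requires zero called regions. These
problem sizes were chosen as the smallest at which every per-event
condition (≥ 10 markers per event, 80× depth) is comfortably met.

## Numerical and degenerate-input choices

* DP = 0 records carry an undefined ratio and are skip-eligible.
* Multiallelic sites are skipped by default; with `allow_multiallelic` the
  alternate with the largest AO is kept (ties: first listed), since the
  ratio-group model assumes one alternate allele per site.
* AO/DP are read from the single sample's FORMAT fields when present,
  from INFO otherwise; multi-sample VCFs are rejected (one VCF per
  strain).
* Indels are retained as markers, tagged so users can filter them.
* Empty tracks, header-only tables and zero-region outputs are all valid;
  writers emit a single header line and deterministic ordering (layout
  chromosome order, then position), and SVG output is byte-reproducible.
* The site QUAL column is taken as the "Phred quality" filter quantity —
  the only Phred-scaled per-site score available after variant calling —
  and the cutoff is strict (> 200).

## Limitations

Ploidy must be supplied by the user (1–4; no estimation from data).
Breakpoints are resolved to marker positions only. The NDoC signal is not
itself segmented — copy-number breakpoints come from the marker track,
coverage only corroborates. Diploid whole-chromosome losses look like LOH
in ratio space (0.5 → 0 or 1) and are distinguishable only by the
coverage drop, as reflected in the transition table's parsimony rule.
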