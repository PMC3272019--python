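# Methods

## Scope and data model

`mircensus` quantifies miRNA processing diversity from a small-RNA library
given three reference inputs: precursor hairpin sequences (FASTA), one
declared secondary structure per hairpin (dot-bracket, two lines per
record), and mature/star/-5p/-3p product intervals (5-column TSV or GFF3
with `Name`/`Derives_from`/optional `Class` attributes). Coordinates are
1-based inclusive along the hairpin 5′→3′ axis; sequences are stored in the
DNA alphabet (U→T) and rendered in RNA where display calls for it. Records
failing validation (structure/sequence length mismatch, unbalanced
brackets, annotations outside the hairpin) are rejected individually with
reasons rather than aborting the load. Multi-loop structures are tolerated
with a warning — deposited miRNA folds occasionally contain them — and the
terminal loop is taken as the longest unpaired span enclosed by an
innermost pair.

## Alignment and MMR

Tags are collapsed reads (15–35 nt); alignment is nucleotide-space
substring matching with at most `max_mismatches` substitutions (default 1),
on both strands of every hairpin and then, for hairpin-unmapped tags, on
the genome (placements capped at 10 per tag; beyond that the tag is set
aside as repetitive). Exact hits come from substring search; one-mismatch
hits from single-substitution variant search, which is exhaustive for the
default allowance.

The resolver's policy, declared here because published descriptions of such
stages rarely pin it down: per tag, (1) placements with the minimal
mismatch count survive — in particular a perfect placement silences all
mismatch placements; (2) sense hairpin placements outrank antisense ones,
which are retained unweighted for the antisense screen; (3) survivors
receive equal weights 1/k, so weighted counts are conserved exactly (up to
float rounding, ≤ 1e-9 relative in tests); (4) survivors tied across
hairpins that are sequence-identical over the placed interval are flagged
`identical-locus` so per-locus reports can aggregate them. Resolution is
deterministic and idempotent. The policy string is echoed into every
placement-table header.

Mismatch classes: a mismatch at the tag's final position is a non-templated
3′ addition, `nta(base)`; anywhere else an internal substitution recorded
as ref-to-tag (so A-to-I editing surfaces as A-to-G). Only single-base 3′
tails are called — a consequence of the one-mismatch allowance; longer
tails simply fail to place and are not interpreted.

## Variant taxonomy

The classifier anchors each sense placement to the nearest same-arm
annotation by |Δ5′|, breaking ties toward the smaller |Δ5′| and then the
higher-precedence class (mature > star > -5p/-3p); |Δ5′| ≤ 3 nt makes the
call generic. Δ3′ is always measured against the same anchor, even when
Δ5′ ≠ 0, so 3′-end histograms share one scale per miRNA.

Set-level calls use one phasing rule throughout: a tag set is *well-phased*
when its modal 5′ start (±1 nt) holds ≥ 50 % of the set's weighted count,
with a floor of 10 weighted tags. This codifies what is otherwise a
visual-inspection judgement into a testable rule; both constants are
configurable. Novel miR\* calls additionally check duplex geometry against
the opposite-arm annotation: with 2-nt 3′ overhangs the expected star 5′
start is partner(end(known) − 2), and a modal start within ±1 nt of it
upgrades the call to generic. e-miR candidates are clustered greedily
around modal starts (members within 5 nt); a cluster is reported when its
hairpin passes the 150-tag expression floor, it reaches ≥ 20 % of the
hairpin's weighted tags, its modal length lies in 18–26 nt and it is
well-phased; loop-overlapping e-miRs carry an `ago2_candidate` flag.
Loop-spanning individual placements are left `unassigned` (flagged
`ago2_candidate`) rather than forced into an arm.

Summaries report, per miRNA: weighted totals, 5′/3′ isomiR fractions
(weighted, among generic tags), length histograms, the > 24-nt long-tag
fraction, the dominant exact tag interval per arm, and flags at > 20 %
(high) and > 80 % (extreme) variant fractions. Cohort-level isomiR rates
are computed both ways — pooled weighted share and unweighted per-miRNA
mean — and labelled explicitly, since either reading of a global rate is
defensible.

## Arm bias and the differential filter

Arm fractions use generic tags only, so bias reflects competition between
annotated species rather than e-miR bookkeeping. Categories follow the
strict 80 %/20 % reading: fractions exactly at a boundary fall in the
inner (symmetrical) class. Hairpins below the 150-tag floor are
`not_assessed`; single-annotation hairpins default to concordant with a
flag. The two-condition filter normalizes to counts-per-million (the
simplest defensible choice, recorded in output metadata), computes M/A on
replicate-averaged CPM, and calls significance only when the fold exceeds
2 in the same direction in every replicate pair and every library exceeds
1000 raw tags.

## Processing-site analytics

Position profiles weight each miRNA's isomiRs by tag count, renormalize to
one frequency vector per position (first/last tag base from the tag itself,
so NTAs count as read; external positions from the hairpin), and exclude
miRNAs below the expression floor; external positions falling off the
hairpin are dropped per miRNA and the background simply uses whatever
positions exist. The background is the unweighted mean over all available
position vectors of all included miRNAs. Tests are two-sample
unequal-variance (Welch) t-tests of per-miRNA frequencies against the
per-miRNA background frequencies, per (arm, group, position, base), at
α = 0.01; groups smaller than 3 are reported `ns` with a flag. Groups
(major ≥ 80 %, minor ≤ 20 %, symmetric otherwise) reuse the arm-bias
bounds rather than introducing new constants.

Duplex reconstruction anchors on the dominant isomiR per arm. Overhangs:
Drosha end = end(3p) − partner(start(5p)); Dicer end =
end(5p) − partner(start(3p)); positive = 3′ overhang, 2/2 canonical. An
unpaired anchor steps inward to the nearest paired position with the gap
added back and the duplex flagged `unpaired_anchor`, so strict tallies can
exclude it. Distortion classification examines the 4 nt straddling each
cleavage boundary on both strands (2 outside, 2 inside; window
configurable): equal unpaired runs → symmetric internal loop (named by
total size 2, 4, other), a run on one strand → bulge, none → fully paired;
a Dicer boundary 0–1 nt from the terminal loop is classed
terminal-loop-adjacent first. This is a deterministic approximation of
what is otherwise a by-eye structure call.

One symmetry worth recording: reverse-complementing a hairpin description
(arms swapped, intervals remapped x → n+1−x) preserves each overhang's
magnitude but flips its sign — a 2-nt 3′ overhang becomes a 2-nt 5′
overhang. That is a real property of antisense transcripts of miRNA loci,
not an artifact, and the tests assert exactly this form.

## Folding and discovery

The default folding backend is a self-contained single-stem base-pair
maximizer: the sequence is Smith–Waterman-aligned against its own reverse
complement, where a "match" scores GC = 3, AU = 2, GU = 1 and mismatches
and gaps cost −4/−7, with a minimum loop of 3 nt; the best segment pair
becomes the stem, and the score is the alignment score. The harsh
interruption penalties encode the observation that genuine pri-miRNA stems
are near-contiguous helices; they keep the best "stem" of a random
sequence short, which the screening criteria rely on (shuffled controls
produce no accepted candidates). `RNAfold` (ViennaRNA) can be plugged in
behind the same `sequence → (dot-bracket, score)` contract; both backends
are deterministic.

Clusters group size-selected (18–26 nt) genome placements per
chromosome/strand within 30 nt of a greedily chosen modal biological 5′
start; clusters need ≥ 50 weighted tags (a declared default — the source
material gives no abundance cutoff) and phase fraction ≥ 0.5. Windows of
100 and 160 nt (bracketing typical murine pri-miRNA hairpins) are folded
with the cluster on each arm in turn and the best-scoring fold kept.
Mandatory criteria, each individually switchable and reported in the
verdict: candidate on one arm, ≥ 60 % of candidate bases paired, loop
3–30 nt, stem ≥ 16 bp, modal length 20–24 nt. miR\* support (a second
cluster within 2 nt of the 2-nt-overhang duplex position) is a recorded
confidence bonus, never mandatory. When a miR and its miR\* both pass, the
heavier cluster names the locus and the lighter is folded in as its star
(`rejected(duplex_partner)`), so one locus yields one candidate. Accepted
candidates are named miR-N1, miR-N2, … in coordinate order, stable across
re-runs. The antisense screen folds the reverse complement of the hairpin
locus, applies the same criteria, and additionally requires ≥ 1 tag on the
opposing arm; accepted calls are `<parent>-as`.

## Seed scanning

Seeds are positions 2–8 of the variant's own sequence (a +1 5′ isomiR
shifts the seed by one). The UTR scan is an exact 7-mer
reverse-complement match, labelled as such in every output — it is
deliberately **not** a TargetScan reimplementation (no context scoring, no
conservation), because set-membership questions (shared vs variant-specific
targets) only need exact site presence. Overlap reports give the Venn
split and per-term hypergeometric enrichment within each subset against
the id universe (default: all annotated or member ids), Benjamini–Hochberg
corrected at α = 0.01.

## The synthetic study

The generator defines the study conditions; its defaults are fixed, not
tuned per run. Hairpins are 76-nt stem-loops (33-bp stem, 10-nt loop) with
the mature product at 8–29 and its partner at 50–71 — canonical 2-nt
3′-overhang geometry, with 4 nt between the mature 3′ end and the loop so
3′ offsets up to +4 stay on the arm. Stems are random sequence with G:U
wobbles planted at every third eligible position: the declared fold stays
fully paired while the two strands become sequence-distinguishable, which
is what makes antisense reads separable from sense tags of the opposite
arm on real hairpins (a perfectly Watson–Crick stem is its own reverse
complement up to the loop). Even-indexed hairpins carry mature/star
annotations, odd-indexed -5p/-3p pairs; abundances are log-normal
(σ = 1.0); the 5′-arm share is 0.85 for mature/star and 0.5 for -5p/-3p
hairpins unless overridden per hairpin.

Default read-level distributions: 5′ offsets {−3…+3} with 95 % mass at 0;
3′ offsets {−4…+4} with 48 % at 0 (52 % 3′ variability), giving a modal
generic tag length of 22 nt with 5′-arm tags of 22–23 nt in comparable
proportions; single-base NTAs at rate 0.06 drawn A/U-rich from the
distribution excluding the templated next base; internal substitution
errors at rate 0.01, sparing the final position so errors never mimic
NTAs. Planted features: one e-miR set (interval 12–30, 30 % of its
hairpin's reads), one antisense locus (500 reads, 80/20 across arms), two
novel hairpins embedded at recorded coordinates in a 1-Mb uniform-random
genome (400 reads each, 30 % miR\*). The truth table (per-hairpin planted
parameters) is written before any read is drawn; per-read provenance is
appended during simulation. Identical spec + seed gives identical output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing-platform error profiles (only uniform
substitutions), multi-base 3′ tails, expression-dependent offset biases,
miRtron- or snoRNA-derived species, cross-mapping against a realistic
repeat-rich genome, and hairpins whose deposited fold disagrees with the
in-vivo fold (the e-miR "alternative fold" escape hatch is exercised only
structurally).

## Problem sizes and numerics

Default analyses use 20 hairpins × 50,000 reads and a 1-Mb genome; the
planted-recovery properties use 100 seeded replicates at reduced size (one
hairpin, 600 reads) and the arm-bias recovery 100 binomial replicates at
1,000 tags/hairpin — sizes chosen so the statistical claims (3-SE
recovery, ≥ 95 %/99 % replicate success) are meaningful while the suite
stays interactive. Frequency vectors sum to 1 within 1e-9; count
conservation holds to 1e-9 relative; BH adjusted p-values match an
independent implementation to 1e-12 and Welch p-values to 1e-9.
Tie-breaks are deterministic everywhere (smallest start on modal-weight
ties, mature-over-star on anchor ties, coordinate sort for candidate
serials). Degenerate inputs — empty read streams, all-dot structures,
zero-count hairpins, missing replicates — yield empty results or flagged
records with warnings, never exceptions.

## Known limitations

The one-mismatch allowance caps NTA calling at single bases and slightly
undercounts tags carrying both an error and an NTA. The single-stem folder
cannot represent multiloops; hairpins whose real fold is branched are
handled only through the declared reference structure. The e-miR clusterer
is greedy and can split a pathologically diffuse set into sub-threshold
fragments. The exact-7-mer scan overcalls targets relative to
context-aware predictors and is intended for set comparisons only.
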