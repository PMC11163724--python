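# Methods

## Coordinates and junction semantics

All in-memory coordinates are 0-based half-open on the forward genomic
strand; STAR `SJ.out.tab` (1-based inclusive intron coordinates, strand codes
0/1/2) and GTF (1-based inclusive) are converted at the I/O boundary and
nowhere else. A junction records one intron: `start` is the first intronic
base and `end` one past the last, so a junction whose `end` equals an exon's
`start` splices directly into that exon.

## PSI estimation

Per exon and sample, inclusion reads are counted at each splice site
separately: junctions whose boundary coincides with the exon's acceptor
(`I₃`) or donor (`I₅`), strand-aware (on '−', the acceptor is the
higher-coordinate boundary). Exclusion reads `E` are junctions spanning the
exon *strictly* (`start < exon.start` and `end > exon.end`) on the same
strand: a junction touching an exon boundary is inclusion evidence, never
exclusion. This strict-spanning denominator is the conservative reading of
"junctions from one exon to another"; it ignores overlapping-but-not-spanning
junctions (e.g. alternative 5′/3′ site usage), which are neither inclusion
nor exclusion evidence for the exon as a unit.

`PSI₃ = I₃/(I₃+E)` and `PSI₅ = I₅/(I₅+E)`; the combined PSI is their
arithmetic mean (both per-site values are always reported, so no information
is lost to the symmetric combination). A PSI is undefined when its
denominator is zero. The coverage gate `covered` requires both site totals
(`I₃+E` and `I₅+E`) to reach `min_reads` (default 10 informative reads — a
conventional junction-coverage floor; it is a parameter and is recorded in
the run manifest). Junctions with undefined strand ('.') are excluded from
PSI by default; a permissive flag lets them match exons on either strand.

Replicates are aggregated by **pooling reads** (sum counts within condition,
then take the ratio) by default; this is stable for low-coverage exons and is
the natural estimator for a binomial proportion. Averaging per-sample PSI is
available (`aggregator="mean"`). ΔPSI = PSI(treated) − PSI(control) is
defined only when both conditions are covered; otherwise the record carries
`covered_both=False` and no ΔPSI.

## Skiptic calling

Labels partition every exon: `low_coverage` (coverage gate failed in either
condition), `alternative` (control PSI ≤ 0.90 — not constitutive at
baseline), `skiptic` (control PSI > 0.90 and ΔPSI ≤ −0.20), else
`constitutive_unchanged`. The 0.90 constitutive threshold is the operational
field definition of a constitutive exon; the 0.20 ΔPSI skip threshold is a
deliberately conservative default for "aberrantly skipped" (observed skiptic
events range up to ~90% PSI loss) and both are parameters. Calls are
threshold-based point estimates with no multiple-testing machinery, matching
the descriptive, junction-count-based character of the analysis; users who
need error control should treat calls as candidates for orthogonal
validation. Species comparison takes an explicit ortholog exon map (pairs of
exon IDs); no liftover is computed internally — cross-species exon
equivalence is an input assertion, not something this package infers.

## UG-repeat metaprofiles

Per window: (1) every position participating in at least one UG or GU
dinucleotide is masked `Y` (overlaps union, so `UGUGUG…` is all `Y`; T ≡ U;
ambiguity codes and assembly N cannot support a UG and mask `N`); (2) a
maximal run qualifies when it contains ≥ `min_len` (default 5) `Y` and at
most `max_inner_n` (default 1) `N`, the `N` interior — flanked by `Y` on both
sides (`YYYYY`, `YNYYYY`, `YYNYYY`, …); (3) `Y` positions in qualifying runs
score 1, interior `N` scores 0; (4) indicators aligned on the splice site are
summed vertically and divided by the number of sequences. The `Y`-count (not
the total span) must reach `min_len`, since only the `Y` positions carry
value.

Window convention: offset 0 is the first exonic base at the 3′SS anchor and
the last exonic base at the 5′SS anchor (stated in every output header, since
any fixed origin is acceptable but must be declared); windows are
reverse-complemented for '−'-strand exons so offsets read 5′→3′ on the sense
strand, and windows truncated at contig ends are N-padded and flagged. The
window is always anchored on the splice site, even for exons shorter than the
window (the opposite site then simply lies inside it).

## NMD prediction

The default rule is frame arithmetic only: skipping an exon whose length is
not a multiple of 3 shifts the downstream reading frame and is predicted to
create a premature termination codon (PTC). The default is deliberately
annotation-free: it depends only on exon length, so its output cannot
silently change with the choice of CDS model. The full rule re-splices the
transcript without the exon, re-translates from the annotated coding start,
flags a PTC when a stop appears upstream of where the annotated stop lands in
the re-spliced mRNA, and predicts NMD when that PTC lies more than 50 nt
upstream of the final exon–exon junction (distance measured from the first
base of the stop codon; the classical boundary is 50–55 nt and the choice is
a constant, `LAST_JUNCTION_DISTANCE`). When an exon belongs to several
transcripts, the longest annotated coding transcript is used, with
lexicographic transcript-ID tie-break for determinism. Known limitation:
neither rule models NMD escape by long 3′UTRs, re-initiation, or
last-exon-proximal effects beyond the 50-nt rule.

## Dose model

Expression is in multiples of normal endogenous nuclear TDP-43. A wild-type
construct is fully nuclear (`total = endogenous + level`); an NLS-mutant
construct contributes only its passively diffusing fraction
(`total = endogenous + f·level`, default `f = 0.45`). Endogenous
autoregulation is an *input* (each observation carries its measured
endogenous level), not a model.

The skipping response vs. nuclear fold is fit as an isotonic piecewise-linear
curve (scikit-learn pool-adjacent-violators, equal weights; linear
interpolation between knots, terminal clamping beyond them) — an
interpolation rather than a parametric Hill/logistic fit, because only
monotonicity is assumed of the dose-response. The diffusion fraction is
estimated by equal-response matching: each NLS-mutant observation whose
skipping value the wild-type curve brackets is inverted to its equivalent
nuclear fold (leftmost preimage on flat segments), giving per-point estimates
`(fold − endogenous)/level`, reported as median plus min–max range — the
spread is informative, reflecting curve saturation, and is not collapsed to a
single value. The skipping-onset threshold is the smallest fold ≥ 1 whose
response reaches the detection floor (default 5% skipping, a parameter — "
begins to induce skipping" has no canonical floor), by linear inversion;
`inf` marks a floor that is never reached. With noisy observations the
lowest-dose response can clear a small floor by noise alone, clamping the
threshold at 1.0 — a property of the data, not of the inversion.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
overexpression experiment on a panel of three-exon genes (one target exon
with flanking exons; alternating strands; each gene on its own contig).

*Junction counts.* True control PSI is drawn uniformly from [0.92, 1.0]
(constitutive exons); planted skiptic exons shift treated PSI by a delta
drawn from [−0.9, −0.5], the deep repression regime of validated skipping
events; all other exons are unchanged. Counts use a Poisson factorization:
per exon and sample, `E ~ Poisson(d(1−ψ))` for the single exclusion junction
and `I ~ Poisson(dψ)` for each inclusion junction, with `d` the mean
informative depth per site (default 100; replicates default 3 per condition).
By Poisson thinning each site's total is Poisson(`d`) and the inclusion count
given the total is Binomial(total, ψ) — the exact sampling law the PSI
estimator assumes — while the single shared exclusion interval reproduces
what a junction caller actually sees. An optional beta-binomial mode
(concentration parameter) adds the overdispersion real junction counts show;
the default is dispersion-free, so recovery tests characterize estimator
behaviour, not biological variance.

*Genomes.* Background sequence is drawn over {A, C} on each gene's sense
strand ({T, G} on the reference for '−' genes), so no spurious UG/GU
dinucleotide can occur and metaprofile expectations are exact rather than
approximate; (TG)ₖ runs (default k = 10, short repeats in the flanking
introns: acceptor-side offset −60, donor-side offset +15) are planted at
specified sense-strand offsets, reverse-complemented into the reference for
'−' genes. This fixture validates coordinate arithmetic and the run-scoring
algorithm bit-exactly; it does not emulate genomic dinucleotide composition,
so profile *magnitudes* on real genomes carry background UG frequency that
the fixture deliberately excludes.

*Dose series.* A monotone true curve (default knots (1.0, 0), (1.1, 5),
(1.5, 40), (2.0, 90), (4.0, 95): onset between 1.1- and 1.5-fold, ~40%
skipping at 1.5-fold, near-saturation by 2-fold) generates wild-type and
NLS-mutant series at seven and six construct levels with true diffusion
fraction 0.45 and 5% multiplicative response noise. Wild-type levels are
chosen to place observations on every knot of the true curve, and NLS-mutant
levels keep the series inside the strictly increasing part of the wild-type
range, so noiseless recovery of the diffusion fraction is exact — a
closed-loop correctness check, not a claim about assay noise.

All draws descend from a single integer seed; identical configurations
produce byte-identical files.

## What passing tests do and do not show

Closed-loop tests on this generator demonstrate estimator correctness
(agreement with brute-force oracles, exact binomial behaviour, exact motif
expectations, exact parameter recovery) and calling performance under the
planted effect sizes and depths. They do not demonstrate performance on real
RNA-seq, where junction counts are overdispersed, annotations are incomplete,
PSI effects are graded, mapping artifacts exist, and UG background frequency
is nonzero. Problem sizes in the test suite and acceptance script (e.g. 578
exons at per-site depth 1000; 200 dose replicates; 10,000 random masks) were
chosen as the smallest sizes at which the statistical properties under test
are stable.

## Numerical choices and edge cases

- Undefined PSI (zero denominator) propagates as missing, never as 0 or 1;
  low-coverage exons are labelled, not dropped silently.
- Duplicate identical junction intervals are merged by summing reads, with a
  warning; mixed-sample junction sets are rejected at indexing.
- Isotonic-curve inversion returns the leftmost preimage on flat segments;
  diffusion estimates are clipped to [0, 1].
- The onset threshold at a detection floor exactly equal to a knot value
  returns the knot fold (e.g. floor 40 on a curve through (1.5, 40) gives
  exactly 1.5).
- Run-scoring marks a chain of Y-runs whose inter-run gaps fit the interior-N
  budget; marking the maximal chain from each start run covers every
  qualifying sub-chain, which is what makes the linear-time scan equivalent
  to exhaustive substring enumeration (property-tested exhaustively to length
  12).
- The GTF reader is non-lossy (identical exon intervals from different
  transcripts are all kept); deduplication by interval is an explicit
  downstream step before PSI, so per-transcript analyses remain possible.
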