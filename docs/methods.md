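# Methods

`msypipe` delineates the male-specific region (MSY) of a Y chromosome by
combining four lines of evidence — windowed X–Y sequence divergence,
male-limited RAD markers, pooled-sex SNP density, and repeat content/age —
and ships a seeded generator that plants all of that structure in synthetic
data so the whole route is testable without external downloads.  This note
records the models, the defaults and why they were chosen, and what the
synthetic scenario does and does not emulate.

## The scenario model

The generator derives a Y chromosome from a simulated X by applying two
region-specific edit processes on a single coordinate sweep:

* substitutions, one Bernoulli draw per base (`sub_rate_par`,
  `sub_rate_msy`);
* indel events, one Bernoulli draw per base (`indel_rate_par`,
  `indel_rate_msy`), geometric lengths with mean `indel_mean_len`,
  insertions and deletions equiprobable.

Edits are applied left to right on a coordinate map, so every planted edit
is known exactly in both X and Y frames; the truth set records SNP
positions, indel intervals, and the PAR/MSY boundary mapped onto Y
coordinates.  The expected windowed difference (mismatch plus gap columns
per aligned column) is approximately

    sub_rate + indel_rate * indel_mean_len

which the defaults place at ~1.0% in the PAR (0.008 + 0.0005·4) and ~6.0%
in the MSY (0.048 + 0.003·4), i.e. about fivefold — the regime of a
recently differentiated sex chromosome with a single stratum.  The default
geometry is a 28.5 Mb chromosome with the PAR/MSY transition at 23.5 Mb
(MSY ≈ 5 Mb).  Rates above a combined 50% expected divergence are rejected
because the X–Y alignment would no longer be identifiable.

(TTAGGG)n tracts overwrite the terminal `telomere_bp` bases of *both*
chromosomes.  Overwriting (rather than appending) keeps every truth
coordinate an exact multiple of `scale`; applying the same tract to X and Y
reflects that telomeres are a shared chromosome feature, not sex-specific
divergence, and preserves the identity X = Y when all rates are zero.
Edits that land inside an overwritten span are removed from the truth set.

All base-pair quantities are multiplied by `scale`; rate-type parameters
never scale.  Tests and the acceptance runs use `scale = 0.1` (a 2.85 Mb
chromosome with 1 kb windows standing in for 10 kb windows), chosen so a
full five-seed evaluation completes in minutes on one CPU while each window
still holds ~1000 aligned columns.

Randomness comes from one integer seed; each component (X–Y pair, RAD
cohort, pools, trio, genes, repeats) draws from a named sub-stream, so
regenerating one input never perturbs another.

### What the generator does not emulate

Uniform base composition and i.i.d. edits (no mutation-rate heterogeneity,
no CpG effects, no segmental duplications); no read-level error-model
realism (constant qualities, substitution-only errors in trio reads); a
single chromosome (no autosomal background, no Hi-C); RAD tags are exact Y
substrings (no restriction-site model, no allelic variants within a locus);
pool reads are allele draws rather than mapped reads.  Passing tests
therefore demonstrate that the algorithms recover planted structure under
clean conditions with realistic magnitudes — not that they are robust to
every artefact of real libraries.

## X–Y alignment and the divergence statistic

The alignment follows the classical chain/net route at desk scale:

1. **Seeding** — all maximal co-matches of k-mers that occur exactly once
   in each sequence (default k = 15).  Uniqueness makes seeds orthologous
   by construction and silently skips telomere and other repetitive
   tracts.
2. **Chaining** — dynamic programming over anchors sorted by target start,
   maximizing anchored bases minus an affine gap cost (`open + g·extend`
   with g the diagonal offset; open 2, extend 1).  A bounded predecessor
   window (64 anchors) keeps the DP linear; it is exact whenever the
   window covers all predecessors, which holds for the near-colinear
   scenarios the pipeline targets and for all oracle fixtures.
3. **Gap filling** — each inter-anchor gap is realigned globally with
   affine scores (match +1, mismatch −1, gap open −2, extend −1; a
   length-g gap costs 2 + g).  Gaps longer than `max_gap` (20 kb) on
   either side, or whose DP area exceeds `max_fill_area` (10⁶ cells), stay
   unaligned and are flagged; such deserts arise only between weakly
   chained anchors, never inside a well-anchored orthologous chain.  The
   outermost chain is extended to the sequence termini so chromosome ends
   are covered.
4. **Netting** — chains are accepted greedily by descending score; columns
   whose target coordinate falls in an already-kept span are trimmed, so
   the result is a single-coverage tiling of the Y.

Per window (default 10 kb, non-overlapping tiles; the step is
configurable), the statistic is

    divergence_pct = 100 · (mismatch + gap columns) / aligned columns.

Indels are counted as gap *columns* by default, which bounds the
proportion by one; an event-count mode is available because either
convention is defensible.  Columns are assigned to windows by the target
coordinate of their left flank; windows with covered fraction below 0.25
are flagged low-confidence and excluded from boundary detection.

On pairs up to ~2 kb the seeded route reproduces the divergence of a
direct full-matrix global alignment exactly in testing (tolerance 0.1
percentage points): unique anchors lie on optimal paths, and the filled
gaps are aligned with the same scoring.

**Boundary detection** scans every window edge for the single split that
minimizes total within-segment squared error (the paper-scale problem has
one stratum; a multi-split mode is out of scope).  Ties break to the
rightmost edge.  The call is flagged "no transition" when the
distal/proximal fold is below 1.5.  In the uniform-rate null experiment
the windows are kept at 10 kb *unscaled* so that each window holds the
same expected number of difference columns (~100 at 1%) as the full-scale
analysis; with 1 kb windows the per-window counting noise (~0.5
percentage points sd) would occasionally imitate a weak transition, which
is a property of tiny windows, not of the detector.

## RAD sex markers

Identical reads collapse per individual; catalogs merge across individuals
by single-linkage clustering at ≤ 2 substitutions between equal-length
tags (the published clustering convention).  Presence means depth ≥ 1 by
default — real data would want a higher threshold, which is exposed.
Male-only tags require presence in at least half the males and in no
female.  Tags are mapped back to Y by ungapped seed-and-extend (match +1,
mismatch −2) with the Karlin–Altschul E-value E = K·m·n·e^(−λS)
(λ = 1.28, K = 0.46) and an E ≤ 1e-40 cutoff; a simple ungapped model is
used because only the threshold, not the aligner's full model, is part of
the contract.  Enrichment in a region (by default the distal 16% of the
chromosome) is tested with a one-sided exact binomial against the region's
length share.

The generator places 70% of male-limited loci distal of the 24
Mb-equivalent cutoff and the remainder in the 20–23.5 Mb-equivalent band,
with 10% per-individual dropout — matching the observed distal
concentration of male-specific markers.

## Pooled-sex scan

The female pool draws alleles from X/X, the male pool from X/Y, so
Y-linked alleles sit at expected frequency 0.5 in males and 0 in females;
depths are Poisson.  A site is male-specific when some allele has male
frequency in [0.5 − 0.10, 0.5 + 0.10] and female frequency ≤ 0.05 with
both pools at depth ≥ 10 (female-specific symmetrically).  These
thresholds are conventions of pooled sex scans, not published values, and
are echoed in output headers.  Windows (50 kb scaled) report sex-SNP
counts and pool coverage means; windows below a coverage floor are flagged
`low_coverage` because an absence of SNPs there is not evidence of absence
— the generator reproduces this by scaling depth to 5% distal of the 26
Mb-equivalent mask start, emulating mapping failure against a highly
diverged terminus.

## Gene-evidence synthesis

Support for a model is computed from transcript coverage intervals and
observed junctions: per-exon covered fraction plus exact intron matches,
scored 0.5·(mean exon fraction) + 0.5·(matched junction fraction)
(single-exon models use the exon term alone).  The 0.5/0.5 weights and the
terminal-exon threshold τ = 0.5 are package choices — the underlying
procedure specifies only "best supported" and "poorly supported" — and are
configurable.  Clusters are connected components of same-strand exonic
overlap (≥ 1 bp; exon-level, not span-level, so nested-in-intron models
stay separate).  Ties on score go to the longer CDS, then the smaller
start.  Terminal-exon rescue replaces a terminal exon with coverage < τ by
an eliminated cluster member's strictly better-covered terminal exon,
provided the donor shares all of the kept model's internal junctions on
the affected side and the donor's bounding junction splices onto the kept
model's neighbouring exon; a replacement that would create overlapping
exons is rejected and logged.  "Fully supported" for ab initio recruitment
is strict (coverage 1.0 on every exon, every junction matched), reading
the word "fully" literally.  The merge is idempotent.

## Repeats

Kimura 2-parameter distances K = −½·ln((1 − 2P − Q)·√(1 − 2Q)) are
computed from per-element transition/transversion proportions supplied in
the input (repeat discovery and masking are out of scope; a helper derives
P and Q from paired element/consensus sequences).  No CpG-adjusted variant
is implemented.  Region repeat fractions merge overlapping intervals
first.  The PAR/MSY age contrast is a two-sided Mann–Whitney test on
per-element K values with medians reported — a checkable surrogate for the
"younger MSY elements" claim, flagged underpowered below 5 elements per
side.  The generator tiles regions to the configured densities (0.35 PAR,
0.55 MSY, the magnitudes of the two regions' repeat content) and draws
element divergence from normals with means 0.20 (PAR) and 0.15 (MSY),
split P = 0.7d, Q = 0.3d (transitions dominate).

## Evidence integration

The consensus MSY is the intersection of the divergence interval
[changepoint, chromosome end) with the smallest interval containing the
upper 90% mass of male-only hit positions — intersection rather than
union, because different marker sets can delimit different proximal
borders and the conservative call is the defensible one; every
per-evidence interval is kept in the report alongside the consensus.  Pool
windows and repeat summaries contribute supporting/neutral/conflicting
flags but do not move the consensus.  Reports are JSON plus TSV/BED, and
every output file carries a header with version, configuration hash and
seed; identical configurations reproduce byte-identical outputs.

## Problem sizes

The test suite runs the full route on 285–570 kb chromosomes (scales
0.01–0.02) and the acceptance evaluation on 2.85 Mb (scale 0.1, five
seeds); the uniform-rate null experiment uses 100 runs at 285 kb with
10 kb windows; trio binning is evaluated on 1000 reads from 200 kb
haplotypes at 2% divergence and 1% read error; the annotation merge on
40–60 genes per seed.  These sizes were chosen so every planted effect is
detected with comfortable statistical margins while a complete evaluation
stays within a few CPU-minutes.

## Known limitations

Chaining uses a bounded look-back rather than a full range-search DP, so
pathological anchor orderings could split a chain (netting then keeps the
pieces); no repeat-aware realignment or chain cleaning beyond net
trimming; minus-strand chains are supported in seeding/chaining/filling
but the synthetic scenario never exercises inversions; the pooled scan
consumes allele counts and cannot model reference-bias effects beyond the
terminal mask; gene merging trusts the supplied transcript evidence and
does not re-align reads.
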