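# Methods

## Packaging model

A circular reference genome of length G (default 86,193 bp at 49.07% GC,
drawn i.i.d. per base) is replicated into head-to-tail concatemers and cut
into linear virion molecules according to one of six strategies:

* **headful with a pac site** — processive series of S molecules are cut
  from a concatemer beginning exactly at the *pac* position; each molecule
  packages H bases with H > G, so the terminal redundancy is r = H/G − 1.
  The series-initiating cut is position-fixed; every subsequent cut is made
  "when the procapsid is full", which we model as a per-molecule headful
  length drawn Normal(H, σ_H). With σ_H = 0 the continuation starts are the
  deterministic offsets i·H; a positive σ_H (default 0.5% of H) disperses
  them, which is the physically realistic case: a capsid is a mechanical
  container, not a ruler. This choice matters — with σ_H = 0 the i·H
  offsets of every series coincide and the forward-strand SPC shows S
  equal spikes (ratio ≈ 1), whereas any appreciable σ_H leaves a single
  spike at *pac* whose height equals the number of series. At 200× depth,
  550 bp fragments and 251 bp reads, the molecule count is ≈ 210
  independent of G, i.e. ≈ 53 series at S = 4, so the expected peak ratio
  is ≈ 53 over the maximum of a Poisson(≈0.4) background — high single
  digits to low double digits, which is the band real pac-type libraries
  show.
* **headful random** — same headful geometry, starts uniform on the circle.
* **cos (5′ or 3′)** — every molecule identical, exactly G bases, with the
  cohesive overhang recorded as an annotation (the annealed duplex is one
  genome length; the overhang does not add sequence).
* **DTR (short/long)** — every molecule identical, G + dtr bases, the first
  dtr bases repeated verbatim at the end (defaults 500 b and 5,000 b).

An optional start "fuzz" on the series-initiating cut is deliberately
absent by default so that ground truth stays exact; σ_H applies only to
the *length* of each headful.

## Library model

Each molecule is partitioned by random breakpoints into fragments with
lengths Normal(550, 55) floored at 50 b; the last fragment absorbs the
remainder, so fragment lengths sum exactly to the molecule length and both
molecule termini are always fragment ends. Both ends of every fragment are
sequenced (251 b, truncated to short fragments): mate 1 forward from the
left end, mate 2 reverse from the right end. No base-calling errors,
quality variation, indels, chimeras or amplification bias are modelled:
the termini statistics depend only on read start positions, and errors
would perturb mapping, which is upstream of this package (alignments are
inputs). Consequently, passing tests demonstrate the statistical machinery
and its thresholds, not robustness to mapping artefacts in real libraries.

## Detection

The **starting-position coverage (SPC)** of a base is the number of reads
whose 5′ mapped end falls there, per strand; for a reverse read the 5′ end
is its rightmost aligned base, because that is the physical end of the
molecule the fragment came from. Coverage is tallied 3′-ward from each 5′
end, wrapping circularly.

A strand's peak is summarised by the highest count, the second-highest
count over the remaining positions, and their ratio R (reported to two
decimals; ties at the maximum give R = 1.00 and the lowest coordinate; a
zero second-highest gives an infinite R with a flag; an all-zero strand has
no defined ratio). A peak is **significant** when

* top count ≥ 20 (`min_top_count`),
* R ≥ 5.0 (`min_ratio`, chosen below the ~6.8 low end of ratios observed
  for real pac libraries, with margin), and
* P(X ≥ top) < 10⁻⁶ under Poisson with the strand-wise mean SPC as mean.

Decision table: one significant strand → `HEADFUL_PAC` at that peak; both
strands → fixed termini, subclassed `FIXED_TERMINI_DTR` when mean plain
coverage over the circular interval from the forward peak to the reverse
peak is ≥ 1.5× the genome-wide mean (2× is the theoretical value for a
fully repeated interval; 1.5 allows noise), else `FIXED_TERMINI_COS`;
neither → `HEADFUL_RANDOM_OR_PERMUTED`; no alignments → `UNDETERMINED`.
A mean depth below 200× sets `low_coverage_warning`. Note the DTR/cos
subclassing dilutes as the repeat grows: the genome-wide mean itself
includes the repeat, so a DTR approaching half the genome length would fall
below the 1.5× factor — far outside the hundreds-to-thousands of bases
regime the classes describe.

Reorganisation rotates the circular sequence so the packaging-initiation
base is position 1 (reverse-complementing first for a minus-strand peak).
We fix the convention "packaging start = position 1" for all downstream
coordinates. Terminal redundancy is evidenced by counting reads whose
covered interval spans the junction between the last and first base of the
reorganised genome; molecules of exactly one genome length cannot produce
such reads, molecules with H > G must.

## Digestion planning

Digestion operates on the linear pac-organised genome — the packaged
molecule is the experimental substrate, not the circular replication form.
Recognition motifs are IUPAC-aware; non-palindromic motifs are also scanned
as their reverse complement (a bottom-strand site at top-strand window
start i cuts the top strand at i + len − offset); palindromic motifs are
scanned once so a locus is never double-counted. Cut coordinates are the
first base of the right-hand fragment; a motif whose cut falls exactly on
the left edge (coordinate 1) produces no fragment boundary and is dropped.
Fragment lengths always sum to the sequence length; zero sites yield one
whole-genome fragment flagged `NO_SITES`.

The *pac* fragment is the terminal fragment containing position 1. Enzyme
ranking flags: `CPG_SENSITIVE` (motif contains CpG, hence blockable by
methylation — a warning, not an exclusion, since such enzymes are still
worth attempting), `FAINT_BAND` (pac fragment < 400 b, between a known
invisible 213 b band and a known visible 754 b band on 1% agarose),
`AMBIGUOUS_ON_GEL` (another fragment within 15% relative length). Ordering:
pac fragment inside the resolvable gel range [250, 10,000] first, then
fewest flags, then log-distance to the geometric mean of the gel range,
then enzyme name — deterministic under input permutation. All thresholds
are configurable.

Primer planning proposes only windows and orientations (a forward window in
the last `window` bases reading across the junction, a reverse window in
the first `window` bases reading toward the packaging start); no melting
temperature or primer-quality modelling.

## Clade propagation

For each strategy with verified tips, the MRCA of those tips on the rooted
tree (rooting is upstream; the tool never re-roots) defines a candidate
clade. If the clade contains a tip verified as a different strategy, the
group is paraphyletic: a conflict is reported and the strategy propagates
to **no** tips — we flag strategy breaks rather than partition them. If the
clade is pure and its MRCA branch support is ≥ 95 (the usual ultrafast-
bootstrap display convention; nodes without a support value count as 0,
never propagating through them), all unlabeled tips in the clade inherit
the strategy. A strategy with a single verified tip never extends beyond
that tip. Because the clades of one tree are laminar, a tip can inherit at
most one strategy; input labels are never overwritten. A minimum
branch-length separation requirement is a plausible additional guard for
very diverse trees but is not part of the rule and is not implemented.

## Problem sizes and determinism

Every generator takes a seed and is bit-reproducible. The self-evaluation
experiments use 20 headful simulations spanning 40,000–86,193 bp and a
5-strategy × 10-seed classification grid at 30,000 bp — detection
statistics at fixed depth are essentially independent of G because the
molecule count is set by depth — each at the full default depth of 200×.
Oracle-equivalence checks run the naive double-strand window scan against
200 random ≤ 2 kb sequences for all built-in enzymes, and exhaustive clade
enumeration against 200 random partially labelled trees of ≤ 32 tips.

## Known limitations

* SAM interchange linearises the circular reference; origin-wrapping reads
  are written with the wrapped tail soft-clipped and recovered on read-in
  by clip arithmetic. External aligners that discard clip information (or
  hard-trim reads) make wrap recovery impossible; the native alignment TSV
  is the lossless path.
* The concatemer-size (series-length) estimate is not computed; S enters
  the simulator as a parameter and is never inferred from data.
* Headful-random and circularly permuted populations are reported as a
  single class — read starts alone cannot separate them.
* The extent of terminal redundancy (H/G, default 1.04) is a free
  parameter; real pac phages vary and the default is an assumption, not an
  estimate.
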