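# Methods

## Array model

A resequencing array interrogates each base of a set of target regions
with a quartet of probes per strand.  Probes default to 25-mers with the
interrogated base at the centre; the reverse-strand probe for
substituted base *b* is defined as the reverse complement of the
forward-strand probe carrying *b*, so features on both strands are keyed
by the same nucleotide of the forward reference strand and a quartet on
either strand votes directly on the same allele.  The 25-mer default is
the length consistent with probe GC percentages reported in multiples of
4% (14/25 = 56%, 16/25 = 64%); it is configurable.

Coordinates are 0-based half-open internally (BED convention); VCF
export and human-readable output use 1-based positions.  Each BED
interval becomes one *tiled fragment* and one exon; window-based
operations (density filter, no-call stretches, intensity-drop scan)
never cross fragment boundaries.

Composition analytics per probe: G count, C count, GC fraction, and
"stack" flags for a run of ≥ *k* consecutive G or C (default *k* = 4).
Because the reverse-strand probe is a reverse complement, its G count
equals the forward probe's C count and a forward G-stack appears as a
reverse C-stack — the strand asymmetry the rescue algorithm exploits.

## Hybridization simulator

Each feature intensity is

```
I = B + S · a(probe) · m(genotype) · r(indels) · ε
```

* `B` — additive background, lognormal with median `background_mean`
  (default 25 a.u.) and log-sd `background_sd` (0.30).
* `S` — full-match signal scale (4000 a.u.).
* `a(probe) = exp(−βG·g − βC·c) · (βstack if G-stack)` — sequence
  affinity in (0, 1].  Defaults `βG = 0.10`, `βC = 0.01` encode the
  observation that G-richness degrades peak intensity much more than
  equal C-richness; `βstack = 0.20` is the extra multiplicative penalty
  for ≥ 4 consecutive Gs.
* `m` — allele match term: each present allele contributes its dosage
  (1 for a homozygous allele, `het_fraction = 0.5` per heterozygous
  allele) to its matching feature; non-matching features receive a
  `cross_hyb = 0.015` leakage fraction of the total dosage.  Probes
  whose footprint overlaps a deleted interval (or spans an insertion
  breakpoint) match no allele.
* `r` — regional indel factor: positions within `indel_halfwidth`
  (10 bp) of an indel are multiplied by `indel_drop` (default 1.0, i.e.
  no drop; set < 1 to emulate the regional intensity loss seen around
  larger deletions).
* `ε` — multiplicative lognormal noise with unit mean and coefficient of
  variation `noise_cv = 0.22`.

One global seed is expanded into independent per-array substreams
(`numpy.random.SeedSequence.spawn`), so batches are bit-reproducible and
each array's draw is independent of batch ordering.

### Default study conditions and calibration

The default batch is 24 arrays × 26,292 interrogated bases split over
180 fragments (one exon each, mirroring a short-range-PCR amplicon
layout), on a random reference with GC fraction 0.40.  Truth genotypes
emulate a patient cohort: 30 common polymorphic sites shared across the
batch with allele frequencies uniform on (0.05, 0.5) and Hardy–Weinberg
genotypes, plus Poisson(1.5) rare singleton variants per array — about
15 true variants per array.

The intensity defaults above were calibrated once, jointly, so that the
default batch reproduces the operating regime the rescue algorithm is
designed for: a primary no-call rate of roughly 2–3% of bases,
dominated by strand-asymmetric G-stack failures (one strand flat, the
other showing a clean reference signature).  Two couplings matter:

* `cross_hyb` bounds the achievable peak/second ratio at `1/cross_hyb`,
  so it simultaneously sets the caller's headroom and the spread of the
  wild-type ratio distribution from which rescue thresholds are learned;
* positions that are no-called in most arrays have few calls entering
  the wild-type proportion *w*, whose Laplace smoothing then pulls
  *w* → 0.5 and scales the rescue threshold up by ×(1 + α/2) exactly at
  rescueable positions.  A small `βC` keeps the complementary (C-rich)
  strand strong enough to clear that scaled threshold.

### What the simulator does not model

No saturation, no probe-level spatial artifacts, no PCR amplicon-length
or fragmentation effects, no batch effects, and no bulge-tolerant
hybridization: a probe overlapping any deletion matches no allele, so
even a 1-bp deletion silences its full probe footprint.  On real arrays
small indels often leave *no* visible signature because near-match
hybridization persists; the simulator therefore overstates their
visibility, and the indel scanner's recovery of simulated events should
not be read as sensitivity to real 1-bp events.  Likewise, the caller
produces essentially zero false-positive variant calls on simulated
data, because the artifacts that cause real-world false positives
(cross-hybridizing repeats, spatial defects) are absent; the
false-positive filters are validated on constructed call tables and on
`with_variant_assign` output rather than on the default batch alone.

## Primary caller

Per strand, quartet intensities are floored at 10⁻⁶ × the array median
and ranked (ties broken toward the lower base index).  With `r1` the
peak/second ratio and `r2` the second/third ratio:

* homozygous call *b*: both strands rank *b* first and `r1 ≥ r_call`
  (1.5) on both; quality = min over strands of log2 `r1`;
* heterozygous call {*b1*, *b2*}: both strands rank the same unordered
  pair in the top two and `r2 ≥ r_het` (1.3) on both; by default the
  pair must contain the reference base (appropriate to screens for
  recessive disease, configurable); quality = min over strands of
  log2 `r2`;
* otherwise, and whenever quality < `q_min` (3.0, i.e. a ratio of 8),
  the position is a no-call; its quality records the best score any
  route achieved.

Qualities are log2 ratios and are not comparable to any commercial
caller's score scale.  The caller is deliberately transparent — a
ratio-rule stand-in for likelihood-based commercial callers — so that
downstream improvements are attributable to the rescue step, not to
caller sophistication.  A pure-Python single-position implementation is
kept alongside the vectorized batch path and the two are tested against
each other.

## sPROFILER

Order of operations: stretch re-examination first (on primary calls
only, so stretch boundaries are unaffected by rescue), then no-call
resolution.

* Thresholds are fitted **per array** (each array's own wild-type
  bases); the wild-type proportion *w* is fitted **per batch**:
  `w(p) = (#arrays wild-type at p + 1) / (#arrays called at p + 2)`,
  which is strictly inside (0, 1) and equals 0.5 for uncalled
  positions.  Fitting requires ≥ 100 wild-type ratios per strand.
* Threshold statistic: empirical q-quantile (linear interpolation) of
  wild-type peak/second ratios, default `q = 0.05` — accepting 95% of
  genuine wild-type signatures per strand.  The scaling law
  `t_eff = t_s · (1 + α·(1 − w))` with default `α = 1` is the simplest
  monotone choice for "more conservative where the batch calls
  variants"; both q and α are configurable.
* Stretch re-examination: a no-call stretch is a run of ≥ `min_run`
  (default 5) no-calls within one fragment, allowing isolated single
  called positions as interruptions.  Wild-type calls inside a stretch
  are demoted to N unless **both** strands rank the reference first at
  `r1 ≥ t_eff`.  Wild-type calls outside stretches and all variant
  calls are never touched.
* Default mode rescues to wild-type only.  `with_variant_assign`
  additionally assigns a homozygous variant when every
  threshold-passing strand shows the same single alternate peak and no
  strand contradicts it; such calls always carry the
  `requires_confirmation` flag because they have not met the two-strand
  standard.

Resolved-count monotonicity: raising α or raising q can only shrink the
resolved set (a lower quantile q loosens the threshold).

## False-positive filters and indel scan

Variant calls are screened by (i) neighbourhood density — more than
`max_neighbors = 2` variant-or-N positions in a centred 25-base window
(fragment-bounded) — and (ii) quality below `q_filter = 3`.  Filtered
calls are demoted to N, which routes them into the same follow-up
channel as no-calls; they keep a flag (`density`, `lowq`) and are never
silently dropped.  The window and neighbour defaults are artifact
choices (tuned so that a 13-no-call stretch catches an embedded variant
call while isolated substitutions pass); no published values exist for
this platform.

Indel candidates come from two signatures: maximal runs of consecutive
variant-or-N positions containing ≥ `min_len = 8` no-calls, and regions
where the rolling median (window 15) of per-position peak intensity
falls below `drop_frac = 0.5` of the array-wide median.  Overlapping
candidates merge with evidence `both`.  `min_len = 8` sits between the
1-bp events that real arrays miss and the 13-no-call signature that a
real 8-bp deletion produced.

## Reporting conventions

* Call rate = percent of interrogated bases called (one decimal).
* Accuracy = percent of **called** bases concordant with truth
  (no-calls excluded) — this is what lets a 97.9% call rate coexist
  with a 99.8% accuracy.
* False positive = variant call at a truly homozygous-reference base
  (headline rate per interrogated base; variant FP rate per variant
  call).  False negative = true variant called wild-type.  Calls at
  true variant sites with the right position but wrong zygosity or
  allele form the separate het/hom-miss category and are excluded from
  FP/FN.
* The per-true-variant breakdown (correct / no-call / het-hom miss /
  called wild-type, split by common vs rare sites) partitions the true
  variants exactly.
* Exon triage: an exon needs follow-up sequencing iff it contains at
  least one no-call or one unconfirmed variant call.

## Problem sizes

The default batch (24 × 26,292 positions, ~5 million feature
intensities) simulates and analyzes in a few seconds on one CPU; the
full test suite, which runs that batch once plus all unit and property
tests, completes in well under a minute.  `scripts/acceptance.py`
recomputes the two headline metrics (fraction of no-calls resolved;
post-resolution accuracy) from a fresh batch at the given seed.
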