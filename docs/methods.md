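# Methods

## Assay model

A linear double-stranded donor amplicon is invaded by a homologous ssDNA
substrate, forming a D-loop: heteroduplex DNA between the invading strand
and the complementary (bottom) donor strand, with the other (top) donor
strand displaced as ssDNA.  Non-denaturing bisulfite deaminates cytosines
only in single-stranded DNA, so after PCR and single-molecule long-read
sequencing each top-strand read carries C→T conversions across the
D-loop interval, while bottom-strand reads — protected inside the
heteroduplex and duplexed everywhere else — carry only sporadic
background conversions from transient DNA breathing.  All coordinates are
on the top strand, 0-based half-open internally (1-based inclusive spans
in reports, BED output 0-based half-open).  Bottom-strand cytosines are
indexed at top-strand G positions; `N` bases belong to neither index.

## Strand assignment

Every read is aligned to the donor under four hypotheses (two
orientations × two strands).  Alignment is edit-distance based (edlib,
infix mode: the read lies within the amplicon with free reference end
gaps), with the hypothesis' conversion pair declared an additional base
equality — ref C : read T under the top hypothesis, ref G : read A under
the bottom hypothesis.  Edit distance with hypothesis-specific
equivalences was chosen over an affine-gap scoring scheme because it is
bit-parallel and orders of magnitude faster on thousands of ~1-kb reads
while ranking the four hypotheses identically in practice: the decision
rests on conversion-pair mismatch counts, which both schemes penalize
linearly.  Scores are reported as matched-base counts (read length −
edit distance).

Decision rule, in order:

1. *Length filter*: reads shorter than `min_length_frac` (default 0.5) of
   the amplicon are dropped (`too_short`).
2. *Identity floor*: if the best hypothesis matches fewer than
   `identity_floor` (default 0.70) of read bases, the read is dropped
   (`low_identity`).
3. *Orientation margin*: if the best alignment does not exceed the best
   alignment of the opposite orientation by ≥5% of its score, the read is
   `ambiguous` and excluded from all tallies (logged).  This margin
   guards palindromic or low-complexity references where orientation
   itself is undecidable; it is deliberately not applied between the two
   strand hypotheses, whose score gap is the conversion count — a handful
   of bases out of ~900 for weakly converted reads.
4. *Strand*: the higher of the two strand-hypothesis scores wins.  A read
   with zero conversions scores identically under both hypotheses — the
   molecules are genuinely indistinguishable from sequence alone — and
   the tie is resolved by the native sequencing-orientation convention
   (forward ⇒ top, reverse ⇒ bottom).  Consequently the strand call of
   conversion-free reads follows storage orientation; with ≥1 conversion
   the call is orientation-invariant.  The simulator therefore emits
   native-oriented reads by default (`orientation_random` off).

Conversion extraction walks the alignment path: each strand cytosine in
the aligned span scores CONVERTED if the read base is the deaminated base
(T at a top C; A at a reference G), UNCONVERTED at the reference base,
and MISSING for any other base or a gap.  Pre-aligned SAM/BAM input
bypasses alignment; the stored pairing is trusted and the strand chosen
by the same match-count rule, the SAM reverse flag breaking ties.

## Footprint calling

The caller slides a window of `w` consecutive *scorable* cytosines along
the profile and marks windows whose converted count reaches `⌈t·w⌉`
(a tie at exactly `t` qualifies; the integer criterion avoids float
artifacts such as `0.4 × 50 = 20.000000000000004`).  MISSING entries are
skipped when forming runs — they count neither way; a flag
(`missing_as_unconverted`) switches to the strictly more conservative
treatment.  Overlapping and adjacent qualifying windows are merged into
maximal runs; each run is trimmed so both boundaries are converted
cytosines, because the duplex-protected flanks are unconverted and an
untrimmed union would extend the call into them.  The untrimmed variant
is available (`trim=False`) for comparison.  Presets: `t40w50`
(t = 0.40, w = 50, default) and `t25w20` (t = 0.25, w = 20).  Lowering
`t` or `w` can only add qualifying windows, so the set of
footprint-bearing reads grows monotonically — verified by test.

Because a footprint must contain a full window, the shortest detectable
D-loop at `w = 50` is the tightest 50-cytosine run of the strand:
197 nt on the ds98-607 donor and 217 nt on ds98-931 (a ~120–200 nt floor
on cytosine-denser templates).

## Summaries

"% D-loops" is the percentage of reads on a strand with ≥1 footprint
(a multi-footprint read counts once; each of its footprints still enters
the length and position distributions).  The strand fold is
pct_top / pct_bottom, infinite when the bottom percentage is zero and
undefined when a strand has no reads.  Length SD is the sample SD
(ddof = 1); SEM = SD/√n; both mean ± SEM and mean ± SD are available.
Length clusters default to contiguous 250-nt intervals up to the homology
length (0–249 / 250–499 / 500–749 / 750–930 for a 931-nt homology),
percentages normalized to the sample's total footprints so samples with
different absolute levels are comparable.  Positional bins of 100 nt are
anchored at the homology start (last bin may be short); binning is
non-exclusive — a footprint increments every bin its inclusive interval
overlaps — so bin percentages need not sum to 100.  Footprint-map rows
are ordered deterministically: by footprint start (ties: longer span,
then read id), or grouped by length cluster then start.  The correlation
with gel-based quantification is the standard product-moment coefficient
(≥3 pairs, non-zero variance required).

## Simulator

Each molecule yields one full-length amplicon read.  Invasion is
Bernoulli(`frac_invaded`); an invaded molecule carries exactly one D-loop
whose length is fixed or truncated-normal (bounded by the homology
length, rejection-sampled on the single seeded stream) and whose
position is uniform in the homology or anchored at its 3′ end with a
configurable mixture weight (mirroring the 3′-end enrichment of
invasion).  Strand is per-read: a fair coin, a balanced alternation, or a
single-strand pool.  Top-strand reads of invaded molecules convert each
cytosine inside the D-loop with `p_conv`; every other strand cytosine —
including all of a bottom-strand read, which is heteroduplex-protected
and never carries D-loop conversions — converts with `p_bg`.
Substitution errors (uniform random other base) are applied last; indels
are not modeled.  All draws come from one `numpy` generator in a fixed
order, so equal seeds give byte-identical FASTQ and truth tables.

Defaults are the study conditions: `frac_invaded` 0.2 and 500-nt D-loops
give an invaded-sample composition typical of in-vitro reactions where
the uninvaded donor dominates; `p_conv` 0.7 and `p_bg` 0.01 are plausible
placeholders for ssDNA conversion efficiency and breathing background
(neither is measured at desk scale) chosen to reproduce the assay's
qualitative strand specificity and detection-limit behavior, and both
are exposed in the config.

The truth table records the D-loop interval only on top-strand reads of
invaded molecules — the reads on which a footprint is observable;
recovery scoring (reciprocal overlap ≥50% between a truth interval and a
called footprint on the same read) is therefore a rate over observable
D-loops, and the bottom-strand false-call rate is tracked separately.

What the simulator does not emulate about real data — incomplete or
context-biased bisulfite chemistry, PCR bias, chimeric or truncated
reads, indel sequencing error, multi-invasion molecules — bounds what
passing tests show: they validate the computational pipeline against its
own generative model, not the wet-lab assay.

## Numerical and design choices

- Window threshold comparison uses the integer criterion `⌈t·w⌉` with a
  1e-9 guard against float rounding.
- Called spans typically underestimate a fixed simulated D-loop length
  slightly (trim to the outermost converted cytosine, a `p_conv`-dependent
  margin of a few cytosine gaps), while rare background conversions
  adjacent to the D-loop fatten the upper tail; the median span is the
  meaningful location statistic and is what the recovery tests bound.
- Sample sizes in tests and in the acceptance script (10,000-read
  simulations for the strand-specificity measurements, 1,000 random
  profiles for caller/oracle equivalence) were chosen so binomial error
  is far below the margins being tested while runs stay interactive.
- Degenerate inputs: empty read files produce empty, well-formed outputs
  with a warning; a strand with zero reads has undefined percentages
  (reported as absent) and an undefined fold; regions with fewer than `w`
  cytosines raise an "undetectable region" error in detectability
  calculations and simply yield no windows in calling.
- Footprint coordinates are reported both amplicon-relative and
  (via `DonorReference.homology_relative`) homology-relative, since map
  figures may anchor either way.

## Known limitations

- Strand assignment of conversion-free reads depends on the orientation
  convention of the input (see above); in pools with random storage
  orientation, about half of such reads — a fraction `(1−p_bg)^{#C}` of
  the pool — would be mislabeled, inflating both denominators equally.
- Edit-distance scoring treats the conversion equivalence symmetrically
  (a ref T : read C pair also scores as a match under the top
  hypothesis); this is the standard in-silico bisulfite-conversion trick
  and is immaterial on references without converted-base ambiguity, but
  it slightly overestimates identity on T-rich templates.
- One D-loop per molecule: multi-invasion footprint phasing is out of
  scope, as is probabilistic (HMM) footprint segmentation.
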